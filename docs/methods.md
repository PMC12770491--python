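# Methods

`knowrare` implements knowledge-graph-guided domain adaptation for
predicting clinical outcomes of data-scarce ("rare") conditions from
structured ICU time series. This note documents the model, the synthetic
study design, the numerical choices, and what the bundled experiments do and
do not establish.

## Problem setting

A stay is a triple (X, C, y): a binned time-series grid X in R^{T x V}
(T steps of vital-sign/lab variables), a static context vector C
(age, sex, race), and a task label y (binary outcome, a 10-class remaining
length-of-stay interval, or 25 binary phenotypes). Each patient carries a
primary condition, the first three characters of the first-listed ICD-9-CM
code. A condition is *rare* when its prevalence is below 1/2000 in the
cohort. The goal is accurate prediction for a target condition with very few
training stays, by selectively transferring from clinically similar
conditions rather than pooling everything.

## Pipeline

1. **Preprocessing.** Stays shorter than the extraction window are dropped;
   conditions with fewer than 10 patients are excluded; events are averaged
   into fixed-width bins (2 h over the last 48 h for discharge-anchored
   tasks, 1 h over the first 24 h for ICU tasks; T = 24 either way); missing
   bins are filled by LOCF then NOCB then the training-split variable mean;
   variables are z-scored with training statistics; splits are patient-level,
   condition-stratified, 67/16/17.
2. **Condition knowledge graph.** Three relations over conditions:
   r1 row-normalised diagnosis co-occurrence
   w_ij = CoOcc(i,j)/sum_k CoOcc(i,k) (directed); r2 inverse-L2 similarity of
   condition signatures (element-wise mean and std of the imputed,
   normalised grids across the condition's patients, a 2TV-vector);
   r3 Jaccard similarity of condition drug sets. For r2 and r3 only the top
   half of candidate pairs by weight is retained (ties at the cut all kept).
3. **TuckER embedding and source selection.** Triples (v_i, r_k, v_j) from
   the graph are scored by the trilinear form W x1 E_i x2 R_k x3 E_j and
   trained with sigmoid binary cross-entropy: observed triples are positives
   weighted by their edge weight, uniformly corrupted tails are negatives
   (a corrupted sample that reproduces its own source triple is dropped —
   it would be the positive relabelled as negative). Sources for a target
   are the top-k conditions by cosine similarity of entity embeddings;
   because the subset objective is a sum of per-member cosines, top-k equals
   the exact subset arg-max.
4. **Condition-agnostic pre-training.** The encoder h_t =
   f_proj(f_temp(x_t), f_cont(C)) — a single-layer LSTM fused with a
   one-hidden-layer context branch through a tanh projection — is trained on
   every condition's training stays to predict the next step:
   L = 1/(T-1) sum_t ||X_{t+1} - f_dec(h_t)||^2.
5. **Joint adversarial adaptation.** The pre-trained encoder plus a task
   head is fine-tuned on the target and its k selected sources. A
   discriminator on the concatenation (h_T, y_hat) predicts which of the
   k+1 domains a sample came from; it is trained to minimise that
   cross-entropy while the encoder and classifier receive the sign-reversed
   gradient (gradient-reversal realisation of the minimax game), aligning
   the joint distribution of representation and prediction across domains.
   The prediction loss is cross-entropy with inverse-propensity sample
   weights w_v = 1/p(v) (training prevalence), normalised to mean 1 over the
   training pool so the adversarial weight and learning rate stay comparable
   across cohort compositions. Model selection keeps the epoch with the best
   target-validation AUPRC.

A note on the minimax orientation: the adversarial objective is stated as a
min-max over a cross-entropy that the total loss simultaneously asks the
encoder to minimise; the standard domain-adversarial convention resolves
this — the discriminator minimises the domain cross-entropy, the encoder
maximises it via gradient reversal — and that is what is implemented.

## Synthetic study design

Real credentialed ICU databases cannot be bundled, so every experiment runs
on a synthetic cohort generator whose structure is the minimal one under
which the method's premises hold and its failure modes are visible:

* a long-tailed condition prevalence (power law, exponent 1.0);
* conditions grouped into planted clusters that share, with mixing weight
  `cluster_similarity_strength` (default 0.9), a drug pool, a within-cluster
  comorbidity preference, AR(1) time-series dynamics around a common global
  trajectory with cluster-level deviations, and an outcome coefficient
  vector over time-series summaries and context;
* irregular event timestamps (uniform within bins, 1 + Poisson extra events
  per observed cell) and cell-level missingness (default 30%);
* outcomes drawn from logistic (binary), log-linear (length of stay) and
  independent-logistic (phenotype) models on a linear score of per-variable
  time means, age and sex.

In `confounded` mode, cluster coefficient vectors are mutually conflicting:
a sign flip for two clusters and, for K clusters, the simplex configuration
with pairwise cosine -1/(K-1). Every off-cluster condition's label model
then contradicts the target's, so pooling all conditions mixes
contradictory signals — the synthetic analogue of the data-volume paradox
in which more training data from dissimilar conditions degrades
performance. Crucially, the drug and diagnosis relations that carry most of
the cluster signal are never model inputs, so the knowledge graph can
identify similar conditions that the encoder alone cannot.

The trajectory model layers a shared global shape (sinusoids, amplitude
0.5-1.5) with cluster/condition deviations (amplitude ~0.5) and larger
patient-level deviations (amplitude ~1.2), plus AR(1) noise (sigma 0.4,
rho 0.6-0.9) and observation noise (0.1). Patient-level heterogeneity
exceeding the cluster deviation is deliberate: it models intra-condition
heterogeneity, so a single stay only weakly reveals its cluster, while
condition-level signature averages — which pool patient effects away —
still separate clusters for the knowledge graph. The outcome scale
(coefficient norm 4) was chosen once so that an oracle on the true score
attains AUROC in the mid-0.7s — comparable to published ICU mortality
benchmarks — while a 60-stay training set is clearly insufficient to
reach it.

What the generator does not emulate: real physiology, multi-centre
variation, variable-specific measurement schedules, informative
missingness, and coding noise in ICD assignment. Passing tests therefore
demonstrate the machinery and its comparative behaviour under the planted
assumptions, not clinical performance.

## Default experiment

The bundled transfer experiment (also run by `scripts/acceptance.py`) uses
a confounded cohort of 4,000 patients, 20 conditions in 4 clusters,
strength 0.9, V = 10 variables, T = 24 hourly bins, ICU-mortality labels.
The target is the least-prevalent condition that still supports evaluation
(at least 60 training stays before capping, and at least 8 positives and
negatives in its test split so AUPRC is measurable); its training set is
then capped at 60 stays. Arms share the cohort, preprocessing, pre-trained
encoder (hidden size 32) and seeds: `knowrare` (top-20% cosine-selected
sources, lambda = 0.1), `target_only`, `pool_all`, and `no_selection`
(all conditions as sources). Metrics are mean (std) of target-test AUPRC
and AUROC over 5 seeds.

## Numerical and design choices

* **No deep-learning framework.** All differentiable components run on a
  small reverse-mode autodiff engine over numpy (`knowrare.nn`),
  gradient-checked against central differences; Adam is the only optimiser.
* **TuckER scale.** d = 16, 1000 full-batch Adam steps at lr 0.01, 5
  negatives per positive. Full-batch training on graphs of tens of nodes
  needs on the order of a thousand steps; fewer leaves the embeddings near
  their random initialisation.
* **Graph sparsification.** The pipeline prunes the assembled graph to the
  top half of edges per relation before embedding (the sparsity knob the
  sweep harness exposes from 1% to 100%). The retained-signature relation
  otherwise carries many near-uniform cross-cluster edges whose triples
  wash cluster structure out of the embedding; the graph's own weighted
  neighbourhoods rank cluster-mates perfectly, and pruning lets the
  embedding inherit that ranking.
* **Retention cuts** keep ceil(fraction x n) candidates; ties at the cut
  weight are all retained, making the result order-independent.
* **Imputation order** is forward fill, then backward fill (which therefore
  supplies sequence heads), then the training mean; the z-scoring statistics
  are fitted on the imputed training tensors (the only complete grids),
  while the imputation fallback mean uses observed training cells only.
* **Boundary conventions**: stays of exactly the window length are kept;
  length-of-stay intervals are left-closed/right-open; rare flagging is a
  strict inequality; prevalence for rare flagging is computed on the full
  cohort before the <10-patient exclusion.
* **Primary diagnosis** is the first-listed code (configurable), truncated
  to three characters; race enters the context one-hot.
* **Batch composition** during adaptation guarantees target presence in
  every mini-batch (swapping in target samples when a shuffled batch has too
  few) so a 60-stay target is not starved next to large sources.
* **Seeds**: every stochastic stage derives an independent generator from
  the run seed and a stage label, so adding or removing a stage never
  shifts another stage's randomness; this also makes the lambda = 0,
  no-source reduction of `adapt` reproduce supervised fine-tuning
  step for step.
* **Evaluation power**: the experiment cohort size and the target
  eligibility floors (8 test positives/negatives, 3 in validation) exist
  because AUPRC on a test split with a handful of positives is dominated by
  placement noise of individual samples; the 60-stay cap is what models
  scarcity.
* **Metrics** delegate to scikit-learn (average precision without the
  interpolated envelope; AUROC as the rank statistic); multiclass and
  multilabel variants are macro one-vs-rest over classes with both labels
  present.

## Known limitations

* The adversarial component's benefit is modest at this scale; the dominant
  effect is the choice of source data, matching the ablation ordering the
  experiments measure.
* Condition signatures use the full 2TV element-wise grid; for large T x V
  a collapsed per-variable variant (`length 2V`) would be preferable.
* The generator draws one stay per patient; the patient-level split
  machinery supports multi-stay patients but is not exercised by generated
  data.
* eICU-style multi-centre effects are not modelled; a per-hospital random
  effect would be the natural extension.
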