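"""Multi-seed experiment orchestration: the full pipeline, ablations, sweeps.

A run executes simulate -> preprocess -> build-kg -> embed -> select ->
pretrain -> adapt -> evaluate for each seed and reports mean (std) metrics
per experimental arm. The default plan is the confounded transfer design: a
rare target condition capped at 60 training stays inside a cohort whose
condition clusters share outcome-generating structure, with mutually
conflicting coefficient directions across clusters so that pooling all
conditions mixes contradictory label models. The arms compare

* ``knowrare`` — knowledge-guided selection of top-k similar sources plus
  joint adversarial adaptation;
* ``target_only`` — supervised fine-tuning on the target's own stays;
* ``pool_all`` — supervised training on every condition pooled;
* ``no_selection`` — adversarial adaptation using all other conditions as
  sources (the "without domain selection" ablation);
* ``no_pretrain`` / ``no_adaptation`` — the other two module ablations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adapt import AdaptResult, LabeledData, adapt, fine_tune
from .config import AdaptConfig, PretrainConfig, SynthConfig, TaskSpec, spawn_rng
from .kg import build_condition_graph, prune_graph
from .metrics import MetricsReport, aggregate_runs, auprc, auroc
from .preprocess import PreprocessedCohort, preprocess_cohort
from .pretrain import pretrain
from .synthetic import generate_cohort
from .tucker import select_sources, train_tucker, triples_from_graph

logger = logging.getLogger(__name__)

__all__ = ["ExperimentPlan", "run_experiment", "run_single_seed", "sweep",
           "cluster_recovery", "labeled_split"]

DEFAULT_ARMS = ("knowrare", "target_only", "pool_all", "no_selection")


@dataclass(frozen=True)
class ExperimentPlan:
    synth: SynthConfig = field(default_factory=lambda: SynthConfig(
        confounded=True, n_patients=4000))
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    arms: tuple[str, ...] = DEFAULT_ARMS
    target_train_size: int = 60
    min_test_class_count: int = 8  # test positives and negatives for the target
    min_val_class_count: int = 3
    k_frac: float = 0.2
    source_fraction: float | None = None  # overrides k_frac (Fig.-2a-style sweep)
    edge_retention: float = 0.5  # post-assembly prune fraction (KG sparsity)
    kg_retain_fraction: float = 0.5  # r2/r3 construction cut
    tucker_dim: int = 16
    tucker_epochs: int = 1000
    pretrain_config: PretrainConfig = field(default_factory=PretrainConfig)
    adapt_config: AdaptConfig = field(default_factory=AdaptConfig)
    disable_pretraining: bool = False

    @property
    def task(self) -> TaskSpec:
        return self.synth.task


def labeled_split(pre: PreprocessedCohort, name: str) -> LabeledData:
    return LabeledData(pre.X[name], pre.C[name], pre.y[name], pre.condition[name])


def _tensors_by_condition(pre: PreprocessedCohort, split: str = "train") -> dict[str, np.ndarray]:
    conds = pre.condition[split]
    return {c: pre.X[split][conds == c] for c in np.unique(conds)}


def _build_embeddings(pre: PreprocessedCohort, plan: ExperimentPlan, seed: int):
    graph = build_condition_graph(pre.diagnosis_records, _tensors_by_condition(pre),
                                  pre.drug_sets,
                                  retain_fraction=plan.kg_retain_fraction,
                                  nodes=sorted(np.unique(pre.condition["train"])))
    if plan.edge_retention < 1.0:
        graph = prune_graph(graph, plan.edge_retention)
    params = train_tucker(triples_from_graph(graph), dim=plan.tucker_dim,
                          epochs=plan.tucker_epochs, seed=seed)
    return graph, params


def _choose_target(pre: PreprocessedCohort, plan: ExperimentPlan) -> str:
    """The least-prevalent condition that still supports evaluation: at least
    ``target_train_size`` training stays (the cap applied later is what makes
    the target data-scarce) and enough of both outcome classes in the
    validation and test splits for AUPRC to be measurable."""
    train_counts = pd.Series(pre.condition["train"]).value_counts()
    eligible = []
    for code, count in train_counts.items():
        if count < plan.target_train_size:
            continue
        y_val = pre.y["valid"][pre.condition["valid"] == code]
        y_test = pre.y["test"][pre.condition["test"] == code]
        if plan.task.label_kind == "binary":
            if min((y_val == 1).sum(), (y_val == 0).sum()) < plan.min_val_class_count:
                continue
            if min((y_test == 1).sum(), (y_test == 0).sum()) < plan.min_test_class_count:
                continue
        elif len(y_val) < 2 or len(y_test) < 2:
            continue
        eligible.append((count, code))
    if not eligible:
        raise ValueError("no condition satisfies the target eligibility rules")
    eligible.sort()
    return eligible[0][1]


def _target_data(pre: PreprocessedCohort, target: str, plan: ExperimentPlan,
                 seed: int) -> tuple[LabeledData, LabeledData, LabeledData]:
    train = labeled_split(pre, "train")
    t_idx = np.flatnonzero(train.condition == target)
    if len(t_idx) > plan.target_train_size:
        rng = spawn_rng(seed, "target-downsample")
        t_idx = np.sort(rng.choice(t_idx, size=plan.target_train_size, replace=False))
    t_train = train.subset(t_idx)
    val = labeled_split(pre, "valid")
    test = labeled_split(pre, "test")
    t_val = val.subset(np.flatnonzero(val.condition == target))
    t_test = test.subset(np.flatnonzero(test.condition == target))
    return t_train, t_val, t_test


def _sources_data(pre: PreprocessedCohort, codes: list[str]) -> dict[str, LabeledData]:
    train = labeled_split(pre, "train")
    return {c: train.subset(np.flatnonzero(train.condition == c)) for c in codes}


def _evaluate(result: AdaptResult, test: LabeledData) -> dict[str, float]:
    from .adapt import predict_scores

    scores = predict_scores(result.model, test.X, test.C)
    return {"auprc": auprc(scores, test.y), "auroc": auroc(scores, test.y)}


def run_single_seed(plan: ExperimentPlan, seed: int) -> list[dict]:
    """One full pipeline execution; returns one metrics row per arm."""
    cohort = generate_cohort(plan.synth.with_(seed=seed))
    pre = preprocess_cohort(cohort, plan.task, plan.synth.n_variables, seed=seed)
    _, tucker_params = _build_embeddings(pre, plan, seed)

    target = _choose_target(pre, plan)
    t_train, t_val, t_test = _target_data(pre, target, plan, seed)
    candidates = sorted(c for c in np.unique(pre.condition["train"]) if c != target)
    frac = plan.source_fraction if plan.source_fraction is not None else plan.k_frac
    k = max(1, int(np.ceil(frac * len(candidates))))
    selection = select_sources(tucker_params, target, candidates, k)
    logger.info("seed %d: target %s, selected sources %s", seed, target, selection.selected)

    encoder_init = None
    if not plan.disable_pretraining:
        all_train = labeled_split(pre, "train")
        all_val = labeled_split(pre, "valid")
        encoder_init, _ = pretrain(
            all_train.X, all_train.C,
            replace(plan.pretrain_config, seed=seed),
            X_val=all_val.X, C_val=all_val.C, conditions=all_train.condition)

    acfg = replace(plan.adapt_config, seed=seed)
    prevalence = pre.split.prevalence
    rows = []
    for arm in plan.arms:
        if arm == "knowrare":
            result = adapt(t_train, _sources_data(pre, selection.selected), t_val,
                           encoder_init, prevalence, plan.task, acfg)
        elif arm == "no_pretrain":
            result = adapt(t_train, _sources_data(pre, selection.selected), t_val,
                           None, prevalence, plan.task, acfg)
        elif arm == "no_selection":
            result = adapt(t_train, _sources_data(pre, candidates), t_val,
                           encoder_init, prevalence, plan.task, acfg)
        elif arm == "no_adaptation":
            pooled = LabeledData.concatenate(
                [t_train] + list(_sources_data(pre, selection.selected).values()))
            from .adapt import propensity_weights
            w = propensity_weights(prevalence, pooled.condition)
            result = fine_tune(pooled, t_val, encoder_init, plan.task, acfg,
                               sample_weight=w)
        elif arm == "target_only":
            result = fine_tune(t_train, t_val, encoder_init, plan.task, acfg)
        elif arm == "pool_all":
            others = sorted(c for c in np.unique(pre.condition["train"]) if c != target)
            pooled = LabeledData.concatenate(
                [t_train] + list(_sources_data(pre, others).values()))
            result = fine_tune(pooled, t_val, encoder_init, plan.task, acfg)
        else:
            raise ValueError(f"unknown arm {arm!r}")
        rows.append({"seed": seed, "arm": arm, "target": target,
                     **_evaluate(result, t_test)})
    return rows


def run_experiment(plan: ExperimentPlan) -> MetricsReport:
    """Execute the plan over all seeds and aggregate mean (std) per arm."""
    if not plan.seeds:
        raise ValueError("plan needs at least one seed")
    rows = []
    for seed in plan.seeds:
        rows.extend(run_single_seed(plan, seed))
    runs = pd.DataFrame(rows)
    return aggregate_runs(runs.drop(columns=["target"]))


def sweep(plan: ExperimentPlan, axis: str, grid: list[float]) -> pd.DataFrame:
    """Re-run the experiment along a grid of source fractions or KG edge
    retentions; returns one summary row per grid point and arm."""
    if not grid:
        raise ValueError("empty sweep grid")
    if axis not in ("source_fraction", "edge_retention"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    out = []
    for value in grid:
        if not 0 < value <= 1:
            raise ValueError("grid values must lie in (0, 1]")
        p = replace(plan, **{axis: value})
        report = run_experiment(p)
        for arm, row in report.summary.iterrows():
            out.append({axis: value, "arm": arm, **row.to_dict()})
    return pd.DataFrame(out)


def cluster_recovery(base_config: SynthConfig, seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
                     k: int | None = None, tucker_dim: int = 16,
                     tucker_epochs: int = 1000,
                     kg_retain_fraction: float = 0.5,
                     edge_retention: float = 0.5) -> float:
    """Planted-cluster recovery of knowledge-guided selection.

    For every condition as target, select k sources (default: planted cluster
    size minus one) and measure the fraction sharing the target's planted
    cluster; returns the mean over targets and seeds.
    """
    fractions = []
    for seed in seeds:
        cfg = base_config.with_(seed=seed)
        cohort = generate_cohort(cfg)
        truth = cohort.cluster_assignment
        pre = preprocess_cohort(cohort, cfg.task, cfg.n_variables, seed=seed)
        graph = build_condition_graph(pre.diagnosis_records, _tensors_by_condition(pre),
                                      pre.drug_sets, retain_fraction=kg_retain_fraction,
                                      nodes=sorted(np.unique(pre.condition["train"])))
        if edge_retention < 1.0:
            graph = prune_graph(graph, edge_retention)
        params = train_tucker(triples_from_graph(graph), dim=tucker_dim,
                              epochs=tucker_epochs, seed=seed)
        codes = sorted(np.unique(pre.condition["train"]))
        for target in codes:
            same = [c for c in codes if c != target and truth[c] == truth[target]]
            if not same:
                continue
            kk = k if k is not None else len(same)
            sel = select_sources(params, target, [c for c in codes if c != target], kk)
            hits = sum(1 for c in sel.selected if truth[c] == truth[target])
            fractions.append(hits / len(sel.selected))
    return float(np.mean(fractions))
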