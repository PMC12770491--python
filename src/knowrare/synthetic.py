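"""Synthetic ICU EHR cohort generator with planted condition-cluster structure.

Real ICU databases used for rare-condition transfer studies are credentialed
and cannot be bundled. This module generates cohorts whose statistical
structure mirrors what the downstream stages rely on: a long-tailed condition
prevalence distribution, clusters of clinically similar conditions that share
drug usage, co-occur as secondary diagnoses, share time-series dynamics and
share outcome-generating coefficients, plus irregular event timestamps with
missingness.

The generative model, per condition cluster:

* a smooth mean trajectory per variable (sum of a random sinusoid),
* an AR(1) persistence coefficient,
* a drug pool,
* an outcome coefficient vector over time-series summaries and context.

A condition blends the cluster-level object with its own independent draw,
with mixing weight ``cluster_similarity_strength``; at strength 1 same-cluster
conditions are identical in these respects, at 0 they are independent. In
``confounded`` mode cluster coefficient vectors are mutually conflicting (a
sign flip for two clusters, the regular-simplex configuration for more), so
pooling data across clusters mixes contradictory label models — the
synthetic analogue of the data-volume paradox where adding more (dissimilar)
training conditions hurts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import N_PHENOTYPES, SynthConfig

__all__ = [
    "ConditionCatalog",
    "SynthCohort",
    "generate_condition_universe",
    "generate_patients",
    "generate_cohort",
    "export_tables",
    "read_tables",
]

_EVENT_EXTRA_RATE = 0.3  # extra events per observed cell ~ Poisson(rate)
_OBS_NOISE = 0.1
_AR_SIGMA = 0.4
#: amplitudes of cluster/condition-level and patient-level trajectory
#: deviations around the shared global shape. Patient-level heterogeneity
#: exceeds the cluster-level deviation, so a single stay barely reveals its
#: cluster, while condition-level signature averages (which pool away
#: patient effects) still separate clusters.
_TRAJ_DEV = 0.5
_PATIENT_DEV = 1.2


@dataclass
class ConditionCatalog:
    """Per-condition generative parameters (ground truth for tests only)."""

    codes: list[str]
    cluster_id: np.ndarray  # (n_conditions,)
    prevalence: np.ndarray  # (n_conditions,), sums to 1
    drug_sets: list[frozenset[int]]
    comorbidity_profiles: np.ndarray  # (n_conditions, n_conditions), row-stochastic, 0 diag
    trajectories: np.ndarray  # (n_conditions, T, V)
    ar_rho: np.ndarray  # (n_conditions,)
    outcome_coef: np.ndarray  # (n_conditions, V + 2)
    pheno_coef: np.ndarray  # (n_conditions, N_PHENOTYPES, V + 2)

    @property
    def cluster_assignment(self) -> dict[str, int]:
        return {c: int(k) for c, k in zip(self.codes, self.cluster_id)}


@dataclass
class SynthCohort:
    """Generated EHR tables plus the ground-truth cluster sidecar."""

    patients: pd.DataFrame
    events: pd.DataFrame
    diagnoses: pd.DataFrame
    drugs: pd.DataFrame
    cluster_assignment: dict[str, int] | None
    config: SynthConfig | None = None


def _simplex_directions(k: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    """k unit vectors in R^dim with pairwise cosine -1/(k-1) (regular simplex).

    For k=2 this is a sign flip; for k>2 it is the maximally mutually
    conflicting configuration.
    """
    if dim < k:
        raise ValueError("simplex directions require dim >= n_clusters")
    if k == 1:
        v = rng.normal(size=dim)
        return (v / np.linalg.norm(v))[None]
    vertices = np.eye(k) - 1.0 / k  # rows: centred simplex, cosine -1/(k-1)
    vertices /= np.linalg.norm(vertices, axis=1, keepdims=True)
    basis, _ = np.linalg.qr(rng.normal(size=(dim, k)))  # random orthonormal embed
    return vertices @ basis.T  # (k, dim), unit rows


def generate_condition_universe(config: SynthConfig,
                                rng: np.random.Generator | None = None) -> ConditionCatalog:
    """Draw the condition catalogue: clusters, prevalences and shared structure."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, k = config.n_conditions, config.n_clusters
    s = config.cluster_similarity_strength
    T, V = config.task.n_steps, config.n_variables
    F = V + 2  # per-variable time means + age + sex

    codes = [f"{100 + i}" for i in range(n)]
    # round-robin so every cluster spans the prevalence range (each cluster
    # contains both common and rare members)
    cluster_id = np.arange(n) % k

    prevalence = (np.arange(1, n + 1, dtype=float)) ** (-config.prevalence_exponent)
    prevalence /= prevalence.sum()

    # drugs: disjoint cluster pools, a generic pool for idiosyncratic use
    m = config.drugs_per_condition
    cluster_pools = [list(range(c * m, (c + 1) * m)) for c in range(k)]
    generic_start = k * m
    n_shared = int(round(s * m))
    drug_sets: list[frozenset[int]] = []
    for i in range(n):
        shared = cluster_pools[cluster_id[i]][:n_shared]
        own = rng.choice(np.arange(generic_start, generic_start + 10 * n),
                         size=m - n_shared, replace=False)
        drug_sets.append(frozenset(int(d) for d in list(shared) + list(own)))

    # comorbidity sampling: within-cluster mass rises with strength
    within_mass = min(0.15 + 0.8 * s, 0.95)
    profiles = np.zeros((n, n))
    for i in range(n):
        same = (cluster_id == cluster_id[i]) & (np.arange(n) != i)
        other = (cluster_id != cluster_id[i])
        if same.any():
            profiles[i, same] = within_mass / same.sum()
            profiles[i, other] = (1.0 - within_mass) / other.sum()
        else:
            profiles[i, other] = 1.0 / other.sum()

    # trajectories: one global physiological shape shared by every condition,
    # plus cluster-level and condition-level deviations. The global component
    # dominates, so cluster membership is only weakly visible in any single
    # stay while condition-level signature averages still separate clusters.
    t_grid = np.arange(T)[None, :]  # (1, T)

    def _sinus(size_v: int, lo: float, hi: float) -> np.ndarray:
        amp = rng.uniform(lo, hi, size=(size_v, 1))
        freq = rng.uniform(0.5, 2.0, size=(size_v, 1))
        phase = rng.uniform(0, 2 * np.pi, size=(size_v, 1))
        return (amp * np.sin(2 * np.pi * freq * t_grid / T + phase)).T  # (T, V)

    global_traj = _sinus(V, 0.5, 1.5)
    dev = _TRAJ_DEV
    cluster_traj = np.stack([global_traj + _sinus(V, dev / 2, dev) for _ in range(k)])
    trajectories = np.empty((n, T, V))
    for i in range(n):
        own = global_traj + _sinus(V, dev / 2, dev)
        offset = rng.normal(scale=0.2, size=(1, V))
        trajectories[i] = s * cluster_traj[cluster_id[i]] + (1 - s) * own + offset

    cluster_rho = rng.uniform(0.6, 0.9, size=k)
    ar_rho = np.clip(s * cluster_rho[cluster_id] + (1 - s) * rng.uniform(0.6, 0.9, size=n),
                     0.0, 0.95)

    # outcome coefficients: one vector per cluster. Under `confounded` the
    # cluster vectors are mutually conflicting — for two clusters a sign flip,
    # for K clusters the simplex generalisation with pairwise cosine
    # -1/(K-1) — so every off-cluster condition's label model contradicts the
    # target's and the pooled-average signal cancels to zero.
    cluster_coef = np.empty((k, F))
    if config.confounded:
        directions = _simplex_directions(k, F, rng)
        for c in range(k):
            vec = directions[c] + 0.2 * rng.normal(size=F)
            cluster_coef[c] = vec / np.linalg.norm(vec)
    else:
        for c in range(k):
            vec = rng.normal(size=F)
            cluster_coef[c] = vec / np.linalg.norm(vec)
    outcome_coef = np.empty((n, F))
    for i in range(n):
        own = rng.normal(size=F)
        own /= np.linalg.norm(own)
        vec = s * cluster_coef[cluster_id[i]] + (1 - s) * own
        norm = np.linalg.norm(vec)
        outcome_coef[i] = config.outcome_scale * (vec / norm if norm > 0 else vec)

    cluster_pheno = np.empty((k, N_PHENOTYPES, F))
    if config.confounded:
        for label in range(N_PHENOTYPES):
            dirs = _simplex_directions(k, F, rng)
            cluster_pheno[:, label, :] = dirs + 0.2 * rng.normal(size=(k, F))
    else:
        cluster_pheno[:] = rng.normal(size=(k, N_PHENOTYPES, F))
    pheno_coef = np.empty((n, N_PHENOTYPES, F))
    for i in range(n):
        own = rng.normal(size=(N_PHENOTYPES, F))
        vec = s * cluster_pheno[cluster_id[i]] + (1 - s) * own
        norms = np.linalg.norm(vec, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        pheno_coef[i] = 0.6 * config.outcome_scale * vec / norms

    return ConditionCatalog(codes, cluster_id, prevalence, drug_sets, profiles,
                            trajectories, ar_rho, outcome_coef, pheno_coef)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def generate_patients(catalog: ConditionCatalog, config: SynthConfig,
                      rng: np.random.Generator) -> SynthCohort:
    """Sample patients, their event streams, diagnoses, drugs and labels."""
    T, V = config.task.n_steps, config.n_variables
    bin_hours = config.task.bin_hours
    n = config.n_patients
    n_cond = len(catalog.codes)

    pat_rows, event_chunks, diag_rows, drug_rows = [], [], [], []
    b0 = _logit(config.base_rate)
    b0_pheno = _logit(config.pheno_base_rate)

    for pid in range(n):
        patient_id = f"P{pid:06d}"
        ci = int(rng.choice(n_cond, p=catalog.prevalence))
        code = catalog.codes[ci]
        age = float(np.clip(rng.normal(65, 15), 18, 95))
        sex = int(rng.integers(0, 2))
        race = int(rng.integers(0, 4))
        stay_hours = config.task.window_hours + float(rng.exponential(24.0))

        # latent grid: condition trajectory + patient-level trajectory
        # heterogeneity + AR(1) + cell noise
        rho = catalog.ar_rho[ci]
        innov = rng.normal(scale=_AR_SIGMA, size=(T, V))
        ar = np.empty((T, V))
        ar[0] = innov[0] / np.sqrt(1 - rho**2)
        for t in range(1, T):
            ar[t] = rho * ar[t - 1] + innov[t]
        amp = rng.uniform(_PATIENT_DEV / 2, _PATIENT_DEV, size=(V, 1))
        freq = rng.uniform(0.5, 2.0, size=(V, 1))
        phase = rng.uniform(0, 2 * np.pi, size=(V, 1))
        personal = (amp * np.sin(2 * np.pi * freq * np.arange(T)[None, :] / T
                                 + phase)).T
        grid = (catalog.trajectories[ci] + personal + ar
                + rng.normal(scale=_OBS_NOISE, size=(T, V)))

        # irregular events: cells observed with prob 1-missing_rate,
        # 1 + Poisson extra events per observed cell, uniform within-bin times
        observed = rng.random((T, V)) >= config.missing_rate
        counts = np.where(observed, 1 + rng.poisson(_EVENT_EXTRA_RATE, size=(T, V)), 0)
        t_idx, v_idx = np.nonzero(counts)
        reps = counts[t_idx, v_idx]
        t_rep = np.repeat(t_idx, reps)
        v_rep = np.repeat(v_idx, reps)
        times = (t_rep + rng.random(t_rep.size)) * bin_hours
        values = grid[t_rep, v_rep] + rng.normal(scale=0.05, size=t_rep.size)
        event_chunks.append(pd.DataFrame({
            "patient_id": patient_id,
            "variable_id": v_rep.astype(np.int64),
            "hours_from_admit": times,
            "value": values,
        }))

        # outcome features: per-variable time means of the latent grid + context
        feats = np.concatenate([grid.mean(axis=0), [(age - 65.0) / 15.0, float(sex)]])
        score = float(catalog.outcome_coef[ci] @ feats)
        labels = {}
        for task in ("mortality_90d", "readmission_30d", "icu_mortality"):
            eps = rng.normal(scale=0.3)
            labels[f"label_{task}"] = int(rng.random() < 1 / (1 + np.exp(-(b0 + score + eps))))
        los_days = float(np.exp(0.7 + 0.5 * score + rng.normal(scale=0.5)))
        pheno_scores = catalog.pheno_coef[ci] @ feats
        pheno = (rng.random(N_PHENOTYPES) < 1 / (1 + np.exp(-(b0_pheno + pheno_scores)))).astype(int)

        pat_rows.append({
            "patient_id": patient_id, "age": age, "sex": sex, "race": race,
            "stay_hours": stay_hours, "condition_code": code,
            **labels,
            "remaining_los_days": los_days,
            "phenotypes": "".join(map(str, pheno)),
        })

        # diagnoses: primary first (first-listed rule), then secondaries
        profile = catalog.comorbidity_profiles[ci]
        n_sec = min(int(rng.poisson(config.mean_secondary_diagnoses)), n_cond - 1)
        diag_idx = [ci]
        if n_sec > 0 and profile.sum() > 0:
            sec = rng.choice(n_cond, size=n_sec, replace=False, p=profile)
            diag_idx.extend(int(j) for j in sec)
        for rank, j in enumerate(diag_idx):
            suffix = rng.integers(0, 10)
            diag_rows.append({"patient_id": patient_id,
                              "icd9_code": f"{catalog.codes[j]}{suffix}",
                              "rank": rank})

        # drugs: most of the condition's set, occasional off-profile drug
        for d in sorted(catalog.drug_sets[ci]):
            if rng.random() < 0.7:
                drug_rows.append({"patient_id": patient_id, "drug_id": d})
        if rng.random() < 0.1:
            drug_rows.append({"patient_id": patient_id,
                              "drug_id": int(rng.integers(0, 10 * n_cond + 100))})

    patients = pd.DataFrame(pat_rows, columns=[
        "patient_id", "age", "sex", "race", "stay_hours", "condition_code",
        "label_mortality_90d", "label_readmission_30d", "label_icu_mortality",
        "remaining_los_days", "phenotypes"])
    events = (pd.concat(event_chunks, ignore_index=True) if event_chunks
              else pd.DataFrame(columns=["patient_id", "variable_id", "hours_from_admit", "value"]))
    diagnoses = pd.DataFrame(diag_rows, columns=["patient_id", "icd9_code", "rank"])
    drugs = pd.DataFrame(drug_rows, columns=["patient_id", "drug_id"])
    return SynthCohort(patients, events, diagnoses, drugs,
                       catalog.cluster_assignment, config)


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Catalogue + patients from the config seed (the one-call entry point)."""
    rng = np.random.default_rng(config.seed)
    catalog = generate_condition_universe(config, rng)
    return generate_patients(catalog, config, rng)


def export_tables(cohort: SynthCohort, directory: str | Path) -> None:
    """Write the four delimited tables plus the ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.patients.to_csv(directory / "patients.csv", index=False)
    cohort.events.to_csv(directory / "events.csv", index=False)
    cohort.diagnoses.to_csv(directory / "diagnoses.csv", index=False)
    cohort.drugs.to_csv(directory / "drugs.csv", index=False)
    if cohort.cluster_assignment is not None:
        with open(directory / "truth.json", "w") as fh:
            json.dump({"cluster_assignment": cohort.cluster_assignment}, fh, indent=2)


def read_tables(directory: str | Path, load_truth: bool = False) -> SynthCohort:
    """Read the table schema back. The truth sidecar is never part of the
    pipeline inputs; it is loaded only on request (for evaluation harnesses)."""
    directory = Path(directory)
    patients = pd.read_csv(directory / "patients.csv",
                           dtype={"condition_code": str, "phenotypes": str})
    events = pd.read_csv(directory / "events.csv", dtype={"patient_id": str})
    diagnoses = pd.read_csv(directory / "diagnoses.csv",
                            dtype={"patient_id": str, "icd9_code": str})
    drugs = pd.read_csv(directory / "drugs.csv", dtype={"patient_id": str})
    truth = None
    truth_path = directory / "truth.json"
    if load_truth and truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)["cluster_assignment"]
    return SynthCohort(patients, events, diagnoses, drugs, truth)
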