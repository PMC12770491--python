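"""EHR preprocessing: cohort filters, condition assignment, binning,
LOCF/NOCB imputation, z-score normalisation, labels and stratified splits.

The pipeline mirrors standard ICU benchmark practice: stays shorter than the
extraction window are excluded, each patient receives a primary condition
defined as the first three characters of the first-listed ICD-9-CM code,
conditions with fewer than ten patients are dropped, event streams are
aggregated into fixed-width bins by within-bin mean, missing bins are filled
by last-observation-carried-forward then next-observation-carried-backward
then the training-split variable mean, and variables are z-scored with
training-split statistics. Splits are patient-level and stratified by
condition at 67/16/17.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TaskSpec
from .synthetic import SynthCohort

logger = logging.getLogger(__name__)

RARE_THRESHOLD = 1.0 / 2000.0
SPLIT_FRACTIONS = (0.67, 0.16, 0.17)
SPLIT_NAMES = ("train", "valid", "test")

__all__ = [
    "NormalizationStats",
    "CohortSplit",
    "PreprocessedCohort",
    "filter_stays",
    "assign_condition",
    "flag_rare",
    "drop_small_conditions",
    "bin_time_series",
    "bin_cohort",
    "impute",
    "fit_normalization",
    "apply_normalization",
    "stratified_patient_split",
    "build_labels",
    "encode_context",
    "preprocess_cohort",
]


@dataclass
class NormalizationStats:
    """Training-split variable statistics.

    ``impute_mean`` is the per-variable mean over *observed* training cells
    (the terminal imputation fallback); ``mean``/``std`` are fitted on the
    fully imputed training tensors and define the z-transform.
    """

    impute_mean: np.ndarray
    mean: np.ndarray | None = None
    std: np.ndarray | None = None


@dataclass
class CohortSplit:
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray
    prevalence: dict[str, float] = field(default_factory=dict)

    def ids(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class PreprocessedCohort:
    """Model-ready tensors and metadata, indexed per split."""

    task: TaskSpec
    X: dict[str, np.ndarray]  # (n, T, V) imputed + normalised
    mask: dict[str, np.ndarray]  # (n, T, V) observed pre-imputation
    C: dict[str, np.ndarray]  # (n, d_c) encoded context
    y: dict[str, np.ndarray]
    condition: dict[str, np.ndarray]  # (n,) level-3 codes
    patient_ids: dict[str, np.ndarray]
    stats: NormalizationStats = None
    split: CohortSplit = None
    rare_conditions: set[str] = field(default_factory=set)
    drug_sets: dict[str, set[int]] = field(default_factory=dict)
    diagnosis_records: list[set[str]] = field(default_factory=list)


# ---------------------------------------------------------------- filters --

def filter_stays(patients: pd.DataFrame, min_hours: float) -> pd.DataFrame:
    """Keep stays of duration >= min_hours ("less than" excluded, closed bound)."""
    if len(patients) == 0:
        return patients
    missing = patients["stay_hours"].isna()
    if missing.any():
        logger.info("filter_stays: dropping %d stays with missing duration", missing.sum())
    kept = patients.loc[~missing & (patients["stay_hours"] >= min_hours)]
    logger.info("filter_stays: kept %d of %d stays", len(kept), len(patients))
    return kept.reset_index(drop=True)


def assign_condition(diagnoses: pd.DataFrame, rule: str = "first") -> pd.Series:
    """Map patient -> level-3 condition code (first 3 characters of the
    primary diagnosis). ``rule='first'`` takes the first-listed code."""
    if rule != "first":
        raise ValueError(f"unknown primary-diagnosis rule {rule!r}")
    if len(diagnoses) == 0:
        return pd.Series(dtype=object, name="condition_code")
    df = diagnoses
    if "rank" in df.columns:
        df = df.sort_values(["patient_id", "rank"], kind="stable")
    primary = df.groupby("patient_id", sort=True)["icd9_code"].first()
    return primary.str[:3].rename("condition_code")


def flag_rare(counts: dict[str, int], n_patients: int,
              threshold: float = RARE_THRESHOLD) -> set[str]:
    """Conditions with prevalence strictly below the threshold (default 1/2000)."""
    return {v for v, c in counts.items() if c / n_patients < threshold}


def drop_small_conditions(patients: pd.DataFrame, min_patients: int = 10) -> pd.DataFrame:
    """Remove conditions with fewer than ``min_patients`` patients (and their patients)."""
    counts = patients.groupby("condition_code")["patient_id"].nunique()
    keep = set(counts.index[counts >= min_patients])
    dropped = len(patients) - patients["condition_code"].isin(keep).sum()
    if dropped:
        logger.info("drop_small_conditions: removed %d patients in small conditions", dropped)
    return patients[patients["condition_code"].isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------- binning --

def bin_time_series(events: pd.DataFrame, spec: TaskSpec,
                    stay_hours: float | None = None,
                    n_variables: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate one stay's events into a (T, V) grid of within-bin means.

    The extraction window covers the first ``window_hours`` of the stay
    (``window_side='first'``) or the last (``'last'``, anchored to
    discharge, which requires ``stay_hours``). Events outside the window are
    ignored. Empty bins are NaN with mask False.
    """
    T = spec.n_steps
    V = n_variables if n_variables is not None else int(events["variable_id"].max()) + 1
    X = np.full((T, V), np.nan)
    mask = np.zeros((T, V), dtype=bool)
    if spec.window_side == "last":
        if stay_hours is None:
            raise ValueError("last-window binning requires stay_hours")
        start = stay_hours - spec.window_hours
    else:
        start = 0.0
    rel = events["hours_from_admit"].to_numpy(dtype=float) - start
    inside = (rel >= 0) & (rel < spec.window_hours)
    n_out = int((~inside).sum())
    if n_out:
        logger.info("bin_time_series: ignored %d events outside the window", n_out)
    t_idx = np.floor(rel[inside] / spec.bin_hours).astype(int)
    v_idx = events["variable_id"].to_numpy()[inside].astype(int)
    vals = events["value"].to_numpy(dtype=float)[inside]
    sums = np.zeros((T, V))
    counts = np.zeros((T, V))
    np.add.at(sums, (t_idx, v_idx), vals)
    np.add.at(counts, (t_idx, v_idx), 1.0)
    observed = counts > 0
    X[observed] = sums[observed] / counts[observed]
    mask[observed] = True
    return X, mask


def bin_cohort(events: pd.DataFrame, patient_ids: np.ndarray, spec: TaskSpec,
               n_variables: int,
               stay_hours: pd.Series | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised binning for a whole cohort -> (n, T, V) values and mask."""
    n = len(patient_ids)
    T = spec.n_steps
    X = np.full((n, T, V := n_variables), np.nan)
    mask = np.zeros((n, T, V), dtype=bool)
    order = {p: i for i, p in enumerate(patient_ids)}
    ev = events[events["patient_id"].isin(order)]
    p_idx = ev["patient_id"].map(order).to_numpy()
    rel = ev["hours_from_admit"].to_numpy(dtype=float)
    if spec.window_side == "last":
        if stay_hours is None:
            raise ValueError("last-window binning requires stay_hours")
        starts = stay_hours.reindex(patient_ids).to_numpy(dtype=float) - spec.window_hours
        rel = rel - starts[p_idx]
    inside = (rel >= 0) & (rel < spec.window_hours)
    t_idx = np.floor(rel[inside] / spec.bin_hours).astype(int)
    v_idx = ev["variable_id"].to_numpy()[inside].astype(int)
    p_sel = p_idx[inside]
    vals = ev["value"].to_numpy(dtype=float)[inside]
    sums = np.zeros((n, T, V))
    counts = np.zeros((n, T, V))
    np.add.at(sums, (p_sel, t_idx, v_idx), vals)
    np.add.at(counts, (p_sel, t_idx, v_idx), 1.0)
    observed = counts > 0
    X[observed] = sums[observed] / counts[observed]
    mask[observed] = True
    return X, mask


# -------------------------------------------------------------- imputation --

def impute(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """LOCF along time, then NOCB, then the training variable mean.

    Accepts (T, V) or (n, T, V); NaN marks missing. The observation mask is
    not modified by imputation — callers keep it separately.
    """
    single = X.ndim == 2
    out = (X[None] if single else X).copy()
    n, T, V = out.shape
    if stats.impute_mean.shape[0] != V:
        raise ValueError("normalization stats do not cover all variables")
    # forward fill
    for t in range(1, T):
        nan = np.isnan(out[:, t])
        out[:, t][nan] = out[:, t - 1][nan]
    # backward fill
    for t in range(T - 2, -1, -1):
        nan = np.isnan(out[:, t])
        out[:, t][nan] = out[:, t + 1][nan]
    # terminal fallback: training mean
    nan = np.isnan(out)
    out[nan] = np.broadcast_to(stats.impute_mean, out.shape)[nan]
    return out[0] if single else out


def fit_normalization(train_X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variable mean/std over the (fully imputed) training tensors.

    Zero-variance variables receive std 1 so they map to 0 after centring.
    """
    flat = train_X.reshape(-1, train_X.shape[-1])
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    constant = flat.max(axis=0) == flat.min(axis=0)
    # constant variables: centre at the exact value so they map to 0, not eps
    mean[constant] = flat[0, constant]
    std[constant] = 1.0
    return mean, std


def apply_normalization(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return (X - stats.mean) / stats.std


# ------------------------------------------------------------------ splits --

def stratified_patient_split(patients: pd.DataFrame,
                             fractions: tuple[float, float, float] = SPLIT_FRACTIONS,
                             seed: int = 0) -> CohortSplit:
    """Patient-level condition-stratified split via largest-remainder counts.

    All stays of a patient land in one split. Conditions with fewer than 3
    patients go entirely to train (too small to stratify).
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    buckets: dict[str, list] = {name: [] for name in SPLIT_NAMES}
    for code in sorted(patients["condition_code"].unique()):
        pids = np.sort(patients.loc[patients["condition_code"] == code, "patient_id"].unique())
        if len(pids) < 3:
            buckets["train"].extend(pids)
            logger.info("split: condition %s has %d patients; all to train", code, len(pids))
            continue
        rng.shuffle(pids)
        quotas = np.array(fractions) * len(pids)
        counts = np.floor(quotas).astype(int)
        remainder = quotas - counts
        for j in np.argsort(-remainder)[: len(pids) - counts.sum()]:
            counts[j] += 1
        offsets = np.concatenate([[0], np.cumsum(counts)])
        for name, a, b in zip(SPLIT_NAMES, offsets[:-1], offsets[1:]):
            buckets[name].extend(pids[a:b])
    train = np.array(sorted(buckets["train"]), dtype=object)
    # prevalence on the training split, used for rare flagging context and
    # inverse-propensity weights downstream
    sub = patients[patients["patient_id"].isin(train)]
    counts = sub.groupby("condition_code")["patient_id"].nunique()
    prevalence = (counts / counts.sum()).to_dict()
    return CohortSplit(train,
                       np.array(sorted(buckets["valid"]), dtype=object),
                       np.array(sorted(buckets["test"]), dtype=object),
                       prevalence)


# ------------------------------------------------------------------ labels --

def build_labels(patients: pd.DataFrame, spec: TaskSpec) -> np.ndarray:
    """Task labels: binary columns pass through, remaining LoS is binned into
    its 10 left-closed day intervals, phenotypes parse to a (n, 25) matrix."""
    if spec.label_kind == "binary":
        col = f"label_{spec.name}"
        if col not in patients.columns:
            raise KeyError(f"missing label column {col}")
        return patients[col].to_numpy(dtype=int)
    if spec.name == "remaining_los":
        days = patients["remaining_los_days"].to_numpy(dtype=float)
        return np.digitize(days, spec.los_bin_edges, right=False)
    if spec.name == "phenotyping":
        mat = np.array([[int(ch) for ch in s] for s in patients["phenotypes"]])
        if mat.shape[1] != spec.n_outputs:
            raise ValueError("phenotype string length mismatch")
        return mat
    raise ValueError(f"cannot build labels for task {spec.name}")


def encode_context(patients: pd.DataFrame, train_ids: np.ndarray) -> np.ndarray:
    """Context C: z-scored age (training statistics), sex, one-hot race."""
    age = patients["age"].to_numpy(dtype=float)
    train_age = patients.loc[patients["patient_id"].isin(train_ids), "age"]
    mu, sd = float(train_age.mean()), float(train_age.std(ddof=0)) or 1.0
    race = patients["race"].to_numpy(dtype=int)
    onehot = np.eye(4)[race]
    return np.column_stack([(age - mu) / sd, patients["sex"].to_numpy(dtype=float), onehot])


# ---------------------------------------------------------------- pipeline --

def preprocess_cohort(cohort: SynthCohort, spec: TaskSpec, n_variables: int,
                      seed: int = 0, min_patients: int = 10,
                      rare_threshold: float = RARE_THRESHOLD) -> PreprocessedCohort:
    """Run the full preprocessing pipeline on raw cohort tables."""
    patients = filter_stays(cohort.patients, spec.window_hours)
    primary = assign_condition(cohort.diagnoses)
    patients = patients.drop(columns=["condition_code"], errors="ignore")
    patients = patients.merge(primary, left_on="patient_id", right_index=True, how="inner")
    counts = patients.groupby("condition_code")["patient_id"].nunique().to_dict()
    rare = flag_rare(counts, len(patients), rare_threshold)
    patients = drop_small_conditions(patients, min_patients)
    split = stratified_patient_split(patients, seed=seed)

    patients = patients.set_index("patient_id", drop=False)
    stay_hours = patients["stay_hours"]
    out_X, out_mask, out_C, out_y, out_cond, out_ids = {}, {}, {}, {}, {}, {}
    C_all = encode_context(patients, split.train)
    ctx_index = {p: i for i, p in enumerate(patients["patient_id"])}

    raw, masks = {}, {}
    for name in SPLIT_NAMES:
        ids = split.ids(name)
        raw[name], masks[name] = bin_cohort(cohort.events, ids, spec, n_variables,
                                            stay_hours=stay_hours)
    train_obs = raw["train"][masks["train"]]
    # observed-cell training means per variable
    impute_mean = np.array([
        raw["train"][..., v][masks["train"][..., v]].mean()
        if masks["train"][..., v].any() else 0.0
        for v in range(n_variables)])
    stats = NormalizationStats(impute_mean=impute_mean)
    del train_obs
    imputed = {name: impute(raw[name], stats) for name in SPLIT_NAMES}
    stats.mean, stats.std = fit_normalization(imputed["train"])

    for name in SPLIT_NAMES:
        ids = split.ids(name)
        sub = patients.loc[ids]
        out_X[name] = apply_normalization(imputed[name], stats)
        out_mask[name] = masks[name]
        out_C[name] = C_all[[ctx_index[p] for p in ids]]
        out_y[name] = build_labels(sub, spec)
        out_cond[name] = sub["condition_code"].to_numpy()
        out_ids[name] = np.asarray(ids)

    # auxiliary structures for the condition KG (training split only)
    train_set = set(split.train)
    diag = cohort.diagnoses[cohort.diagnoses["patient_id"].isin(train_set)]
    level3 = diag["icd9_code"].str[:3]
    records = [set(g) for _, g in level3.groupby(diag["patient_id"])]
    drug = cohort.drugs[cohort.drugs["patient_id"].isin(train_set)]
    cond_map = patients[["patient_id", "condition_code"]].reset_index(drop=True)
    drug = drug.merge(cond_map, on="patient_id")
    drug_sets = {code: set(g["drug_id"]) for code, g in drug.groupby("condition_code")}
    for code in patients.loc[list(train_set), "condition_code"].unique():
        drug_sets.setdefault(code, set())

    return PreprocessedCohort(task=spec, X=out_X, mask=out_mask, C=out_C, y=out_y,
                              condition=out_cond, patient_ids=out_ids, stats=stats,
                              split=split, rare_conditions=rare, drug_sets=drug_sets,
                              diagnosis_records=records)
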