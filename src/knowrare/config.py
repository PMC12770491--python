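"""Configuration dataclasses shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Remaining length-of-stay class boundaries in days. Ten left-closed,
#: right-open intervals: <1, 1-2, 2-3, 3-4, 4-5, 5-6, 6-7, 7-10, 10-14, >14.
LOS_BIN_EDGES_DAYS: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 10, 14)

N_PHENOTYPES = 25
N_LOS_CLASSES = 10


@dataclass(frozen=True)
class TaskSpec:
    """A clinical prediction task and its extraction window.

    ``window_side`` selects which end of the stay the window covers:
    ``"first"`` (ICU-admission tasks, eICU-style) or ``"last"``
    (discharge-anchored tasks, MIMIC-style).
    """

    name: str
    window_hours: int
    bin_hours: int
    label_kind: str  # binary | multiclass | multilabel
    n_outputs: int
    window_side: str = "first"
    los_bin_edges: tuple[float, ...] = LOS_BIN_EDGES_DAYS

    def __post_init__(self):
        if self.window_hours % self.bin_hours:
            raise ValueError("window_hours must be a multiple of bin_hours")
        if self.label_kind not in ("binary", "multiclass", "multilabel"):
            raise ValueError(f"unknown label_kind {self.label_kind!r}")
        if self.window_side not in ("first", "last"):
            raise ValueError(f"unknown window_side {self.window_side!r}")

    @property
    def n_steps(self) -> int:
        return self.window_hours // self.bin_hours

    @staticmethod
    def named(name: str) -> "TaskSpec":
        """The five bundled task definitions."""
        table = {
            "mortality_90d": TaskSpec("mortality_90d", 48, 2, "binary", 1, "last"),
            "readmission_30d": TaskSpec("readmission_30d", 48, 2, "binary", 1, "last"),
            "icu_mortality": TaskSpec("icu_mortality", 24, 1, "binary", 1, "first"),
            "remaining_los": TaskSpec("remaining_los", 24, 1, "multiclass", N_LOS_CLASSES, "first"),
            "phenotyping": TaskSpec("phenotyping", 24, 1, "multilabel", N_PHENOTYPES, "first"),
        }
        if name not in table:
            raise ValueError(f"unknown task {name!r}; one of {sorted(table)}")
        return table[name]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic EHR cohort generator.

    ``cluster_similarity_strength`` in [0, 1] controls how strongly conditions
    in the same planted cluster share drug usage, comorbidity sampling,
    time-series dynamics and outcome coefficients. ``confounded`` flips the
    sign of outcome coefficients between clusters so that naive pooling of
    all conditions mixes contradictory label models.
    """

    n_conditions: int = 20
    n_clusters: int = 4
    cluster_similarity_strength: float = 0.9
    prevalence_exponent: float = 1.0
    n_patients: int = 2000
    n_variables: int = 10
    task: TaskSpec = field(default_factory=lambda: TaskSpec.named("icu_mortality"))
    missing_rate: float = 0.3
    base_rate: float = 0.3
    pheno_base_rate: float = 0.15
    outcome_scale: float = 4.0
    drugs_per_condition: int = 8
    mean_secondary_diagnoses: float = 2.0
    confounded: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters > self.n_conditions:
            raise ValueError("n_clusters must not exceed n_conditions")
        if not 0.0 <= self.cluster_similarity_strength <= 1.0:
            raise ValueError("cluster_similarity_strength must lie in [0, 1]")
        if self.prevalence_exponent <= 0:
            raise ValueError("prevalence_exponent must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PretrainConfig:
    hidden_size: int = 32
    context_size: int = 16
    epochs: int = 12
    batch_size: int = 128
    learning_rate: float = 3e-3
    patience: int = 10
    seed: int = 0


@dataclass(frozen=True)
class AdaptConfig:
    lambda_adv: float = 0.1
    epochs: int = 35
    batch_size: int = 64
    learning_rate: float = 3e-3
    discriminator_lr: float = 3e-3
    discriminator_hidden: int = 64
    min_target_fraction: float = 0.25
    normalize_weights: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lambda_adv < 0:
            raise ValueError("lambda_adv must be non-negative")


def spawn_rng(seed: int, *labels: str) -> np.random.Generator:
    """Derive an independent generator from a run seed and stage labels.

    Every stochastic stage uses its own stream so that adding or removing a
    stage never shifts the randomness of the others.
    """
    entropy = [seed] + [int.from_bytes(label.encode(), "little") % (2**32) for label in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
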