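"""Synthetic fixtures with planted pattern structure and score-linked survival.

Expression is simulated directly on the log2 scale with Gaussian noise.  The
gene universe is partitioned into positive/negative "regulator" genes whose
means move with the latent pattern index, immune-signature genes with
configurable per-pattern mean shifts, and pure-noise genes.  A planted
per-sample score (standardized difference of mean positive minus mean
negative regulator expression) drives an exponential proportional-hazards
survival model with independent exponential censoring.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ubipattern.io import GeneSetCollection


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


@dataclass(frozen=True)
class ImmuneSetSpec:
    """One synthetic immune-cell signature: name, size, per-pattern mean shift."""

    name: str
    size: int
    pattern_shifts: tuple[float, ...]


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 200
    n_patterns: int = 3
    pattern_props: tuple[float, ...] | None = None
    n_regulator_genes: int = 100
    n_noise_genes: int = 100
    pattern_separation: float = 3.0
    immune_sets: tuple[ImmuneSetSpec, ...] = ()
    noise_sd: float = 1.0
    baseline_expression: float = 8.0
    survival_baseline_hazard: float = 0.02
    score_log_hr: float = 0.7
    censor_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern_props is None:
            props = tuple([1.0 / self.n_patterns] * self.n_patterns)
            object.__setattr__(self, "pattern_props", props)
        for fname in ("n_samples", "n_patterns", "n_regulator_genes", "n_noise_genes"):
            if getattr(self, fname) < 1:
                raise ConfigurationError(f"{fname} must be >= 1, got {getattr(self, fname)}")
        props = np.asarray(self.pattern_props, dtype=float)
        if len(props) != self.n_patterns:
            raise ConfigurationError(
                f"pattern_props has length {len(props)}, expected n_patterns={self.n_patterns}"
            )
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-12:
            raise ConfigurationError("pattern_props must be nonnegative and sum to 1")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.survival_baseline_hazard <= 0:
            raise ConfigurationError(
                f"survival_baseline_hazard must be > 0, got {self.survival_baseline_hazard}"
            )
        if self.censor_rate < 0:
            raise ConfigurationError(f"censor_rate must be >= 0, got {self.censor_rate}")
        for spec in self.immune_sets:
            if spec.size < 1:
                raise ConfigurationError(f"immune set {spec.name!r} has size < 1")
            if len(spec.pattern_shifts) != self.n_patterns:
                raise ConfigurationError(
                    f"immune set {spec.name!r} needs {self.n_patterns} pattern shifts"
                )

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticDataset:
    """Expression plus planted ground truth for every downstream stage."""

    expression: pd.DataFrame
    true_labels: pd.Series           # sample -> 0-based pattern index
    gene_roles: pd.Series            # gene -> role string
    planted_score: pd.Series         # sample -> standardized planted score
    clinical: pd.DataFrame | None = None
    config: SyntheticConfig | None = None

    def validate(self) -> None:
        samples = list(self.expression.columns)
        for name, obj in (("true_labels", self.true_labels),
                          ("planted_score", self.planted_score)):
            if list(obj.index) != samples:
                raise ConfigurationError(f"{name} does not cover expression samples")
        if list(self.gene_roles.index) != list(self.expression.index):
            raise ConfigurationError("gene_roles does not cover expression genes")
        if self.clinical is not None and set(self.clinical["sample"]) != set(samples):
            raise ConfigurationError("clinical table does not cover expression samples")


def generate_expression(config: SyntheticConfig) -> SyntheticDataset:
    """Simulate the expression matrix, roles, labels, and planted score.

    Positive-regulator means increase by ``pattern_separation * noise_sd`` per
    pattern step; negative regulators decrease symmetrically.  Immune-set
    genes receive their configured per-pattern shift; noise genes are i.i.d.
    The planted score is (mean positive-regulator) minus (mean
    negative-regulator) expression per sample, standardized to mean 0 / SD 1.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    k = config.n_patterns

    labels = rng.choice(k, size=n, p=np.asarray(config.pattern_props, dtype=float))
    samples = [f"S{i:04d}" for i in range(n)]

    n_pos = config.n_regulator_genes - config.n_regulator_genes // 2
    n_neg = config.n_regulator_genes // 2
    genes: list[str] = []
    roles: list[str] = []
    blocks: list[np.ndarray] = []

    step = config.pattern_separation * config.noise_sd
    base = config.baseline_expression

    def noise(rows: int) -> np.ndarray:
        return rng.normal(0.0, config.noise_sd, size=(rows, n))

    if n_pos:
        genes += [f"REG_POS_{i:03d}" for i in range(n_pos)]
        roles += ["positive-regulator"] * n_pos
        blocks.append(base + step * labels[None, :] + noise(n_pos))
    if n_neg:
        genes += [f"REG_NEG_{i:03d}" for i in range(n_neg)]
        roles += ["negative-regulator"] * n_neg
        blocks.append(base - step * labels[None, :] + noise(n_neg))
    for spec in config.immune_sets:
        genes += [f"IMM_{spec.name}_{i:03d}" for i in range(spec.size)]
        roles += [f"immune:{spec.name}"] * spec.size
        shifts = np.asarray(spec.pattern_shifts, dtype=float)[labels]
        blocks.append(base + shifts[None, :] + noise(spec.size))
    genes += [f"NOISE_{i:04d}" for i in range(config.n_noise_genes)]
    roles += ["noise"] * config.n_noise_genes
    blocks.append(base + noise(config.n_noise_genes))

    matrix = np.vstack(blocks)
    expr = pd.DataFrame(matrix, index=pd.Index(genes, name="gene"), columns=samples)

    role_s = pd.Series(roles, index=expr.index, name="role")
    pos_mask = role_s == "positive-regulator"
    neg_mask = role_s == "negative-regulator"
    raw = expr.loc[pos_mask].mean(axis=0)
    if neg_mask.any():
        raw = raw - expr.loc[neg_mask].mean(axis=0)
    sd = raw.std(ddof=0)
    if sd == 0:
        planted = raw - raw.mean()
    else:
        planted = (raw - raw.mean()) / sd
    planted.name = "planted_score"

    ds = SyntheticDataset(
        expression=expr,
        true_labels=pd.Series(labels, index=samples, name="pattern"),
        gene_roles=role_s,
        planted_score=planted,
        config=config,
    )
    ds.clinical = generate_survival(ds, config)
    ds.validate()
    return ds


def generate_survival(dataset: SyntheticDataset, config: SyntheticConfig) -> pd.DataFrame:
    """Exponential event times with hazard = baseline * exp(log_hr * score).

    Censoring is independent exponential at ``censor_rate``; the observed
    time is the earlier of event and censoring with the event flag set
    accordingly.  ``censor_rate == 0`` disables censoring.
    """
    if config.survival_baseline_hazard <= 0:
        raise ConfigurationError("survival_baseline_hazard must be > 0")
    # a dedicated stream so expression and survival noise do not interleave
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_919]))
    score = dataset.planted_score.to_numpy()
    hazard = config.survival_baseline_hazard * np.exp(config.score_log_hr * score)
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor_time = rng.exponential(1.0 / config.censor_rate, size=len(score))
    else:
        censor_time = np.full(len(score), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "sample": dataset.planted_score.index,
            "time_months": time,
            "event": event,
            "pattern": dataset.true_labels.to_numpy(),
        }
    )


def generate_gene_sets(dataset: SyntheticDataset) -> GeneSetCollection:
    """Emit one gene set per immune signature plus the regulator list."""
    roles = dataset.gene_roles
    coll = GeneSetCollection()
    immune_names: list[str] = []
    for role in roles.unique():
        if role.startswith("immune:"):
            immune_names.append(role.split(":", 1)[1])
    for name in immune_names:
        members = roles.index[roles == f"immune:{name}"].tolist()
        if not members:
            raise ConfigurationError(f"immune set {name!r} has no tagged genes")
        coll.add(name, members, "synthetic immune signature")
    regulators = roles.index[roles.isin(["positive-regulator", "negative-regulator"])].tolist()
    if not regulators:
        raise ConfigurationError("dataset contains no regulator genes")
    coll.add("REGULATORS", regulators, "synthetic regulator list")
    return coll


def default_immune_sets(n_patterns: int = 3) -> tuple[ImmuneSetSpec, ...]:
    """A small bundled immune-signature panel (shifts differ by pattern)."""
    specs = []
    for i in range(4):
        shifts = tuple(
            round(0.8 * np.sin(1.0 + i + 2.0 * p), 3) for p in range(n_patterns)
        )
        specs.append(ImmuneSetSpec(name=f"immune_cell_{i}", size=15, pattern_shifts=shifts))
    return tuple(specs)
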