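"""Synthetic two-group RNA-seq experiments with planted signal.

Emulates an aldosterone-vs-vehicle whole-retina experiment: two groups of
biological replicates, gene-level integer counts drawn from a negative
binomial, one focal decorin-like gene down-regulated in the treated group
by a known factor, and a GO-style annotation in which a handful of terms
are enriched among the differentially expressed genes.

Counts follow K_gj ~ NB(mean mu_gj, dispersion phi) with
var = mu + phi * mu**2 and

    mu_gj = s_j * q_g * 2**(beta_g * x_j)

where s_j is a per-sample library scale factor, q_g a baseline mean and
x_j the treated-group indicator. Everything is reproducible: a single
global seed is expanded into per-stage child seeds (annotation, signal,
counts) through ``numpy.random.SeedSequence(seed).spawn``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .landscape import AnnotationMap

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_annotation",
    "plant_signal",
    "simulate_counts",
    "simulate_experiment",
]

# Stage indices of the SeedSequence spawn: keep stable so individual
# stages stay reproducible across versions.
_STAGE_ANNOTATION = 0
_STAGE_SIGNAL = 1
_STAGE_COUNTS = 2

#: log2 range of the sample library scale factors s_j — non-trivial but
#: benign, so median-of-ratios normalization has something to undo.
SCALE_FACTOR_LOG2_RANGE = (-0.2, 0.2)


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic two-group experiment.

    Defaults mirror the study design being emulated: three biological
    replicates per group and a focal gene planted 2.64-fold DOWN in the
    treated group.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 3
    baseline_mean_log_range: tuple[float, float] = (1.0, 3.0)  # log10 counts
    dispersion: float = 0.1  # NB phi, var = mu + phi mu^2
    n_de_genes: int = 150
    de_log2fc_magnitude: float = 1.5
    focal_gene_factor: float = 2.64  # linear fold, planted down in treated
    n_terms: int = 200
    term_size_range: tuple[int, int] = (10, 30)
    n_planted_terms: int = 5
    planted_overlap_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be >= 1")
        if self.n_samples_per_group < 2:
            raise InvalidConfigError("need >= 2 replicates per group for testing")
        if self.dispersion <= 0:
            raise InvalidConfigError("dispersion must be > 0")
        if self.n_terms > 0 and not (1 <= lo <= hi <= self.n_genes):
            raise InvalidConfigError(
                f"term_size_range {self.term_size_range} outside [1, n_genes={self.n_genes}]"
            )
        if self.n_planted_terms > self.n_terms:
            raise InvalidConfigError("n_planted_terms exceeds n_terms")
        if not 0.0 <= self.planted_overlap_fraction <= 1.0:
            raise InvalidConfigError("planted_overlap_fraction must be in [0, 1]")
        if self.focal_gene_factor <= 0:
            raise InvalidConfigError("focal_gene_factor must be > 0")
        if self.n_de_genes > self.n_genes:
            raise InvalidConfigError("n_de_genes exceeds n_genes")

    def stage_rng(self, stage: int) -> np.random.Generator:
        child = np.random.SeedSequence(self.seed).spawn(3)[stage]
        return np.random.default_rng(child)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of a planted simulation.

    ``de_effects`` maps each planted DE gene to its signed log2 effect
    beta_g (treated relative to control); ``focal_gene`` carries beta =
    -log2(focal_gene_factor). ``group_design`` maps sample id to the
    treated indicator x_j.
    """

    de_effects: dict[str, float]
    focal_gene: str | None
    focal_factor: float
    planted_terms: frozenset[str]
    group_design: dict[str, int]
    gene_ids: tuple[str, ...] = field(repr=False, default=())

    @property
    def de_genes(self) -> frozenset[str]:
        return frozenset(self.de_effects)


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]


def _term_ids(n_terms: int) -> list[str]:
    return [f"GO:{i:07d}" for i in range(1, n_terms + 1)]


def simulate_annotation(
    n_genes: int,
    n_terms: int,
    term_size_range: tuple[int, int],
    seed: int | np.random.Generator,
) -> AnnotationMap:
    """Draw a flat gene/term annotation with independent uniform memberships.

    Each term's member set is sampled without replacement with size uniform
    in ``term_size_range``; genes may belong to zero or many terms. No DAG
    structure is modelled.
    """
    if n_terms > 0:
        lo, hi = term_size_range
        if not (1 <= lo <= hi <= n_genes):
            raise InvalidConfigError(
                f"term_size_range {term_size_range} outside [1, n_genes={n_genes}]"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = np.asarray(_gene_ids(n_genes))
    term_to_genes: dict[str, frozenset[str]] = {}
    for term in _term_ids(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        members = rng.choice(genes, size=size, replace=False)
        term_to_genes[term] = frozenset(members.tolist())
    return AnnotationMap.from_term_sets(term_to_genes)


def plant_signal(
    annotation: AnnotationMap,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> TruthRecord:
    """Choose DE genes, planted terms and the focal gene.

    Planted terms are drawn first; for each, at least
    ``ceil(planted_overlap_fraction * |term|)`` members are forced into the
    DE set. Remaining DE slots are filled uniformly from unannotated-or-not
    genes. One DE gene becomes the focal (decorin-like) gene with effect
    -log2(focal_gene_factor); every other DE gene gets +/-de_log2fc_magnitude
    with a random sign.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
        if seed is not None
        else config.stage_rng(_STAGE_SIGNAL)
    )
    genes = _gene_ids(config.n_genes)
    all_terms = sorted(annotation.terms)
    if config.n_planted_terms > len(all_terms):
        raise InvalidConfigError("fewer terms in annotation than n_planted_terms")

    planted = [
        all_terms[i]
        for i in rng.choice(len(all_terms), size=config.n_planted_terms, replace=False)
    ] if all_terms and config.n_planted_terms else []

    de: set[str] = set()
    for term in planted:
        members = sorted(annotation.genes_of(term))
        need = math.ceil(config.planted_overlap_fraction * len(members))
        # keep already-forced members first so overlapping terms share budget
        already = [g for g in members if g in de]
        fresh = [g for g in members if g not in de]
        extra = max(0, need - len(already))
        if extra:
            picked = rng.choice(len(fresh), size=min(extra, len(fresh)), replace=False)
            de.update(fresh[i] for i in picked)
    if len(de) > config.n_de_genes:
        raise InvalidConfigError(
            f"planted-term overlap needs {len(de)} DE genes but n_de_genes={config.n_de_genes}"
        )
    pool = [g for g in genes if g not in de]
    remaining = config.n_de_genes - len(de)
    if remaining:
        picked = rng.choice(len(pool), size=remaining, replace=False)
        de.update(pool[i] for i in picked)

    de_sorted = sorted(de)
    effects: dict[str, float] = {}
    focal: str | None = None
    if de_sorted:
        focal = de_sorted[int(rng.integers(len(de_sorted)))]
        for g in de_sorted:
            if g == focal:
                effects[g] = -math.log2(config.focal_gene_factor)
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                effects[g] = sign * config.de_log2fc_magnitude

    n = config.n_samples_per_group
    design = {f"ctrl_{j+1}": 0 for j in range(n)}
    design.update({f"trt_{j+1}": 1 for j in range(n)})
    return TruthRecord(
        de_effects=effects,
        focal_gene=focal,
        focal_factor=config.focal_gene_factor,
        planted_terms=frozenset(planted),
        group_design=design,
        gene_ids=tuple(genes),
    )


def simulate_counts(
    truth: TruthRecord,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
):
    """Draw the count matrix for a planted truth.

    Negative-binomial counts are generated as a gamma-Poisson mixture,
    which is exact for var = mu + phi mu^2 and numerically stable down to
    the Poisson limit phi -> 0.
    """
    from .de import CountMatrix  # local import: de depends on nothing here

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
        if seed is not None
        else config.stage_rng(_STAGE_COUNTS)
    )
    genes = list(truth.gene_ids) or _gene_ids(config.n_genes)
    samples = list(truth.group_design)
    x = np.array([truth.group_design[s] for s in samples], dtype=float)

    lo10, hi10 = config.baseline_mean_log_range
    q = 10.0 ** rng.uniform(lo10, hi10, size=len(genes))
    s = 2.0 ** rng.uniform(*SCALE_FACTOR_LOG2_RANGE, size=len(samples))
    beta = np.array([truth.de_effects.get(g, 0.0) for g in genes])

    mu = s[None, :] * q[:, None] * 2.0 ** (beta[:, None] * x[None, :])
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, scale=mu / shape)
    counts = rng.poisson(lam).astype(np.int64)
    groups = {sample: int(truth.group_design[sample]) for sample in samples}
    return CountMatrix(genes=genes, samples=samples, counts=counts, groups=groups)


def simulate_experiment(config: SimulationConfig):
    """Run all three stages off the config's single seed.

    Returns ``(annotation, truth, counts)``; each stage uses its own child
    seed so the triple is bit-reproducible from ``config`` alone.
    """
    annotation = simulate_annotation(
        config.n_genes,
        config.n_terms,
        config.term_size_range,
        config.stage_rng(_STAGE_ANNOTATION),
    )
    truth = plant_signal(annotation, config, config.stage_rng(_STAGE_SIGNAL))
    counts = simulate_counts(truth, config, config.stage_rng(_STAGE_COUNTS))
    return annotation, truth, counts
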