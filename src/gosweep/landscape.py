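"""Threshold-free GO over-representation sweep ("landscape").

Instead of testing enrichment at one arbitrary DE cut-off, the landscape
evaluates a one-sided hypergeometric over-representation test for every
annotated term at a grid of top-n selections taken from the significance-
ranked gene list, sweeping across the whole range of DE significance. The
result is a term x step matrix of raw and (column-wise, BH-adjusted)
p-values from which the most significant terms in the range, and the most
represented genes within those terms, are extracted and rendered as a
heatmap.

Multiplicity is controlled across terms WITHIN each step. The per-term
score (minimum adjusted p over steps) is not further adjusted across
steps and is reported as exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .de import bh_adjust

__all__ = [
    "AnnotationMap",
    "StepGrid",
    "ContingencyCounts",
    "LandscapeMatrix",
    "TermSummary",
    "GeneRepresentation",
    "build_step_grid",
    "contingency",
    "hypergeom_tail",
    "compute_landscape",
    "score_terms",
    "select_top_terms",
    "gene_representation",
    "heatmap_matrix",
]


class EmptyUniverseError(ValueError):
    """No gene is shared between the ranked list and the annotation."""


class EmptyLandscapeError(ValueError):
    """No term passes the minimum-size filter."""


class UnknownTermError(KeyError):
    pass


@dataclass(frozen=True)
class AnnotationMap:
    """Bidirectional gene <-> term membership.

    The two mappings are exact transposes by construction; term names are
    optional metadata.
    """

    gene_to_terms: dict[str, frozenset[str]]
    term_to_genes: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_term_sets(
        cls,
        term_to_genes: dict[str, frozenset[str]],
        term_names: dict[str, str] | None = None,
    ) -> "AnnotationMap":
        g2t: dict[str, set[str]] = {}
        t2g = {t: frozenset(gs) for t, gs in term_to_genes.items()}
        for term, members in t2g.items():
            for g in members:
                g2t.setdefault(g, set()).add(term)
        return cls(
            gene_to_terms={g: frozenset(ts) for g, ts in g2t.items()},
            term_to_genes=t2g,
            term_names=dict(term_names or {}),
        )

    @classmethod
    def from_pairs(
        cls, pairs, term_names: dict[str, str] | None = None
    ) -> "AnnotationMap":
        t2g: dict[str, set[str]] = {}
        for gene, term in pairs:
            t2g.setdefault(term, set()).add(gene)
        return cls.from_term_sets(
            {t: frozenset(gs) for t, gs in t2g.items()}, term_names
        )

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.term_to_genes)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_to_terms)

    def genes_of(self, term: str) -> frozenset[str]:
        try:
            return self.term_to_genes[term]
        except KeyError:
            raise UnknownTermError(term) from None

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene, frozenset())

    def __len__(self) -> int:
        return len(self.term_to_genes)


@dataclass(frozen=True)
class StepGrid:
    """Strictly increasing top-n selection sizes to sweep."""

    steps: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("step grid must contain at least one step")
        if any(b <= a for a, b in zip(self.steps, self.steps[1:])):
            raise ValueError("steps must be strictly increasing")
        if self.steps[0] < 1:
            raise ValueError("steps must be >= 1")

    def __iter__(self):
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class ContingencyCounts:
    """The 2x2 table behind one term/step test.

    N universe size, K term size within the universe, n selected genes,
    k overlap between selection and term.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"inconsistent contingency counts {self}")
        if not (max(0, self.n + self.K - self.N) <= self.k <= min(self.n, self.K)):
            raise ValueError(f"overlap k={self.k} outside hypergeometric support {self}")

    @property
    def enrichment_fold(self) -> float:
        """(k/n) / (K/N); defined as 0 when the term or selection is empty."""
        if self.n == 0 or self.K == 0:
            return 0.0
        return (self.k / self.n) / (self.K / self.N)


@dataclass(frozen=True)
class LandscapeMatrix:
    """Term x step raw and within-step BH-adjusted enrichment p-values."""

    terms: tuple[str, ...]
    grid: StepGrid
    raw_p: np.ndarray  # (n_terms, n_steps)
    adj_p: np.ndarray
    universe_size: int
    term_sizes: dict[str, int] = field(default_factory=dict)
    overlaps: np.ndarray | None = None  # (n_terms, n_steps) k values

    def row(self, term: str, adjusted: bool = True) -> np.ndarray:
        i = self.terms.index(term)
        return (self.adj_p if adjusted else self.raw_p)[i]


@dataclass(frozen=True)
class TermSummary:
    term: str
    best_adj_p: float
    best_step: int
    enrichment_fold: float
    term_size: int
    name: str = ""


@dataclass(frozen=True)
class GeneRepresentation:
    gene: str
    n_selected_terms: int
    best_rank: int


def build_step_grid(
    ranked_universe_p: np.ndarray,
    step_size: int = 25,
    max_alpha: float = 0.5,
) -> StepGrid:
    """Grid of top-n sizes covering the whole informative significance range.

    ``ranked_universe_p`` are raw p-values of the universe genes in rank
    order. Steps run at step_size, 2*step_size, ... up to the number of
    universe genes with p <= max_alpha; that endpoint is always included,
    so there is at least one step and the sweep never extends into genes
    indistinguishable from noise.
    """
    p = np.asarray(ranked_universe_p, dtype=float)
    if p.size == 0:
        raise EmptyUniverseError("ranked universe is empty")
    if step_size < 1:
        raise ValueError("step_size must be >= 1")
    endpoint = int(np.sum(p <= max_alpha))
    endpoint = max(endpoint, 1)
    steps = list(range(step_size, endpoint + 1, step_size))
    if not steps or steps[-1] != endpoint:
        steps.append(endpoint)
    return StepGrid(tuple(steps))


def contingency(
    step_n: int,
    term: str,
    annotation: AnnotationMap,
    ranked_universe: list[str] | tuple[str, ...],
) -> ContingencyCounts:
    """Build the 2x2 counts for one term at one top-n step.

    ``ranked_universe`` is the significance-ranked list restricted to the
    universe (genes present in both the ranking and the annotation).
    """
    if step_n > len(ranked_universe):
        raise ValueError("step exceeds universe size")
    universe = set(ranked_universe)
    members = annotation.genes_of(term) & universe
    top = set(ranked_universe[:step_n])
    return ContingencyCounts(
        N=len(ranked_universe),
        K=len(members),
        n=step_n,
        k=len(top & members),
    )


def hypergeom_tail(c: ContingencyCounts) -> float:
    """Exact one-sided over-representation p-value P(X >= k).

    X ~ Hypergeometric(N, K, n). Summed in log space over the upper
    support for numerical stability at extreme tails.
    """
    kmax = min(c.n, c.K)
    if c.k <= max(0, c.n + c.K - c.N):
        return 1.0
    ks = np.arange(c.k, kmax + 1)
    logp = stats.hypergeom.logpmf(ks, c.N, c.K, c.n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def _term_overlap_curve(member_positions: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """k at each step: members with 0-based rank position < n."""
    return np.searchsorted(member_positions, steps, side="left")


def compute_landscape(
    ranked_genes: list[str] | tuple[str, ...],
    annotation: AnnotationMap,
    grid: StepGrid | None = None,
    min_term_size: int = 3,
    step_size: int = 25,
    ranked_p: np.ndarray | None = None,
    max_alpha: float = 0.5,
) -> LandscapeMatrix:
    """Sweep every eligible term across the step grid.

    The universe is the intersection of the ranked list and the annotated
    genes; terms with fewer than ``min_term_size`` universe members are
    excluded entirely. Raw p-values come from the hypergeometric tail;
    adjusted p-values are BH across terms within each step (column-wise).

    If ``grid`` is omitted it is built from ``ranked_p`` (raw p-values
    aligned with ``ranked_genes``) via :func:`build_step_grid`.
    """
    annotated = annotation.genes
    ranked_universe = [g for g in ranked_genes if g in annotated]
    if not ranked_universe:
        raise EmptyUniverseError("no ranked gene carries any annotation")
    if grid is None:
        if ranked_p is None:
            raise ValueError("need either a grid or ranked_p to build one")
        p_lookup = dict(zip(ranked_genes, np.asarray(ranked_p, dtype=float)))
        universe_p = np.array([p_lookup[g] for g in ranked_universe])
        grid = build_step_grid(universe_p, step_size=step_size, max_alpha=max_alpha)
    N = len(ranked_universe)
    if max(grid.steps) > N:
        raise ValueError("grid step exceeds universe size")

    pos = {g: i for i, g in enumerate(ranked_universe)}
    universe = frozenset(ranked_universe)
    eligible: list[tuple[str, np.ndarray, int]] = []
    for term in sorted(annotation.terms):
        members = annotation.genes_of(term) & universe
        if len(members) < min_term_size:
            continue
        positions = np.sort(np.array([pos[g] for g in members]))
        eligible.append((term, positions, len(members)))
    if not eligible:
        raise EmptyLandscapeError(
            f"no term has >= {min_term_size} members in the universe"
        )

    steps = np.asarray(grid.steps)
    raw = np.empty((len(eligible), len(steps)))
    ks = np.empty((len(eligible), len(steps)), dtype=int)
    for i, (term, positions, K) in enumerate(eligible):
        k_curve = _term_overlap_curve(positions, steps)
        ks[i] = k_curve
        for j, (n, k) in enumerate(zip(steps, k_curve)):
            raw[i, j] = hypergeom_tail(ContingencyCounts(N=N, K=K, n=int(n), k=int(k)))
    adj = np.column_stack([bh_adjust(raw[:, j]) for j in range(len(steps))])

    return LandscapeMatrix(
        terms=tuple(t for t, _, _ in eligible),
        grid=grid,
        raw_p=raw,
        adj_p=adj,
        universe_size=N,
        term_sizes={t: K for t, _, K in eligible},
        overlaps=ks,
    )


def score_terms(landscape: LandscapeMatrix, annotation: AnnotationMap | None = None) -> list[TermSummary]:
    """Summarise each term by its best (minimum) adjusted p over the sweep.

    ``best_step`` is the smallest step attaining the minimum; the
    enrichment fold is evaluated at that step. The min-over-steps score
    carries no cross-step adjustment and is exploratory.
    """
    steps = np.asarray(landscape.grid.steps)
    out: list[TermSummary] = []
    for i, term in enumerate(landscape.terms):
        row = landscape.adj_p[i]
        j = int(np.argmin(row))  # argmin returns the FIRST minimum: smallest step
        K = landscape.term_sizes[term]
        k = int(landscape.overlaps[i, j]) if landscape.overlaps is not None else 0
        c = ContingencyCounts(N=landscape.universe_size, K=K, n=int(steps[j]), k=k)
        name = annotation.term_names.get(term, "") if annotation is not None else ""
        out.append(
            TermSummary(
                term=term,
                best_adj_p=float(row[j]),
                best_step=int(steps[j]),
                enrichment_fold=c.enrichment_fold,
                term_size=K,
                name=name,
            )
        )
    return out


def select_top_terms(summaries: list[TermSummary], top_t: int = 5) -> list[TermSummary]:
    """The most significant terms of the sweep, fully ordered.

    Ascending best adjusted p, ties by smaller best step, then term id.
    """
    if top_t < 1:
        raise ValueError("top_t must be >= 1")
    ordered = sorted(summaries, key=lambda s: (s.best_adj_p, s.best_step, s.term))
    return ordered[:top_t]


def gene_representation(
    selected_terms: list[TermSummary],
    annotation: AnnotationMap,
    ranked_genes: list[str] | tuple[str, ...],
) -> list[GeneRepresentation]:
    """Rank genes by how many selected terms annotate them.

    Only genes annotated to at least one selected term appear. Ties break
    by better (smaller) DE rank, then gene id.
    """
    if not selected_terms:
        raise ValueError("selected_terms must be non-empty")
    rank_of = {g: i + 1 for i, g in enumerate(ranked_genes)}
    selected_ids = [s.term for s in selected_terms]
    counts: dict[str, int] = {}
    for term in selected_ids:
        for g in annotation.genes_of(term):
            if g in rank_of:
                counts[g] = counts.get(g, 0) + 1
    reps = [
        GeneRepresentation(gene=g, n_selected_terms=c, best_rank=rank_of[g])
        for g, c in counts.items()
    ]
    reps.sort(key=lambda r: (-r.n_selected_terms, r.best_rank, r.gene))
    return reps


def heatmap_matrix(
    top_genes: list[GeneRepresentation],
    top_terms: list[TermSummary],
    annotation: AnnotationMap,
) -> np.ndarray:
    """Gene x term matrix for the output heatmap.

    cell(g, t) = -log10(best adjusted p of t) where gene g is annotated to
    term t, else 0 — each gene is shown at the maximum significance level
    its processes reached anywhere in the sweep. Rows follow the gene-
    representation order, columns the term selection order.
    """
    mat = np.zeros((len(top_genes), len(top_terms)))
    for j, summ in enumerate(top_terms):
        members = annotation.genes_of(summ.term)
        weight = -np.log10(max(summ.best_adj_p, np.finfo(float).tiny))
        for i, rep in enumerate(top_genes):
            if rep.gene in members:
                mat[i, j] = weight
    return mat
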