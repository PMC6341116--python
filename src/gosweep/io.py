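"""TSV readers/writers, GAF parsing and end-to-end orchestration.

All tables are tab-delimited UTF-8 with ``#`` comment lines and '.'
decimals. Reals round-trip at <= 1e-12 relative error (they are written
with repr-level precision); integers and ids round-trip exactly.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .de import (
    DE_TABLE_COLUMNS,
    CountMatrix,
    FilterConfig,
    run_de,
    select_de,
)
from .landscape import (
    AnnotationMap,
    LandscapeMatrix,
    compute_landscape,
    gene_representation,
    heatmap_matrix,
    score_terms,
    select_top_terms,
)
from .simulate import SimulationConfig, TruthRecord, simulate_experiment

logger = logging.getLogger("gosweep")

FLOAT_FMT = "%.17g"  # full double precision: losslessly round-trips


class ParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = path, lineno


class ConsistencyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# annotation


def read_gene2term(path) -> AnnotationMap:
    """Two-column TSV (gene, term); optional header; '#' comments.

    Duplicate pairs collapse to one membership.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
            if lineno == 1 and fields[0].lower() in {"gene", "gene_id"}:
                continue
            pairs.append((fields[0], fields[1]))
    if not pairs:
        logger.warning("annotation file %s is empty", path)
        return AnnotationMap.from_pairs([])
    return AnnotationMap.from_pairs(pairs)


def write_gene2term(annotation: AnnotationMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tterm\n")
        for term in sorted(annotation.terms):
            for gene in sorted(annotation.genes_of(term)):
                fh.write(f"{gene}\t{term}\n")


def read_gaf_subset(path) -> AnnotationMap:
    """Minimal GAF 2.x reader: DB Object ID (col 2) -> GO ID (col 5).

    '!' lines are comments; rows whose Qualifier (col 4) contains NOT are
    skipped; evidence codes are ignored; memberships are set-valued.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                raise ParseError(
                    path, lineno, f"GAF data row has {len(fields)} columns, expected >= 15"
                )
            qualifier = fields[3]
            if "NOT" in qualifier.split("|"):
                continue
            pairs.append((fields[1], fields[4]))
    return AnnotationMap.from_pairs(pairs)


# ---------------------------------------------------------------------------
# counts / groups


def write_counts(counts: CountMatrix, counts_path, groups_path) -> None:
    df = counts.to_frame()
    df.index.name = "gene"
    df.to_csv(counts_path, sep="\t")
    with open(groups_path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for s in counts.samples:
            fh.write(f"{s}\t{counts.groups[s]}\n")


def read_counts(counts_path, groups_path) -> CountMatrix:
    """Read a counts TSV plus a sample->group TSV, realigning by sample id.

    Rejects non-integer or negative counts, duplicate gene ids, and
    samples absent from the group table.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ConsistencyError(f"duplicate gene ids in {counts_path}: {dupes}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        as_float = values.astype(float)
        if np.any(as_float != np.floor(as_float)) or np.any(~np.isfinite(as_float)):
            raise ConsistencyError(f"non-integer counts in {counts_path}")
        values = as_float.astype(np.int64)
    if np.any(values < 0):
        raise ConsistencyError(f"negative counts in {counts_path}")

    groups_df = pd.read_csv(groups_path, sep="\t", comment="#")
    groups = dict(zip(groups_df.iloc[:, 0].astype(str), groups_df.iloc[:, 1].astype(int)))
    missing = [s for s in df.columns if s not in groups]
    if missing:
        raise ConsistencyError(f"samples missing from {groups_path}: {missing}")
    return CountMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        counts=values,
        groups={s: groups[s] for s in df.columns.astype(str)},
    )


# ---------------------------------------------------------------------------
# DE table / truth / landscape tables


def write_de_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in DE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ConsistencyError(f"DE table {path} lacks columns {missing}")
    return df


def write_truth(truth: TruthRecord, path) -> None:
    """Flat key=value text file recording the planted ground truth."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"focal_gene={truth.focal_gene or ''}\n")
        fh.write(f"focal_factor={truth.focal_factor!r}\n")
        fh.write(f"planted_terms={','.join(sorted(truth.planted_terms))}\n")
        fh.write(
            "de_effects="
            + ",".join(f"{g}:{b!r}" for g, b in sorted(truth.de_effects.items()))
            + "\n"
        )
        fh.write(
            "group_design="
            + ",".join(f"{s}:{x}" for s, x in truth.group_design.items())
            + "\n"
        )


def read_truth(path) -> TruthRecord:
    kv: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key] = value
    effects = {}
    if kv.get("de_effects"):
        for item in kv["de_effects"].split(","):
            g, _, b = item.partition(":")
            effects[g] = float(b)
    design = {}
    if kv.get("group_design"):
        for item in kv["group_design"].split(","):
            s, _, x = item.partition(":")
            design[s] = int(x)
    return TruthRecord(
        de_effects=effects,
        focal_gene=kv.get("focal_gene") or None,
        focal_factor=float(kv.get("focal_factor", "nan")),
        planted_terms=frozenset(t for t in kv.get("planted_terms", "").split(",") if t),
        group_design=design,
    )


def write_landscape(landscape: LandscapeMatrix, path) -> None:
    """Long-format TSV: term, step, raw_p, adj_p."""
    rows = []
    for i, term in enumerate(landscape.terms):
        for j, step in enumerate(landscape.grid.steps):
            rows.append(
                (term, step, landscape.raw_p[i, j], landscape.adj_p[i, j])
            )
    pd.DataFrame(rows, columns=["term", "step", "raw_p", "adj_p"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def write_term_summaries(summaries, path) -> None:
    pd.DataFrame(
        [
            {
                "term": s.term,
                "name": s.name,
                "term_size": s.term_size,
                "best_adj_p": s.best_adj_p,
                "best_step": s.best_step,
                "enrichment_fold": s.enrichment_fold,
            }
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_gene_representation(reps, path) -> None:
    pd.DataFrame(
        [
            {"gene": r.gene, "n_selected_terms": r.n_selected_terms, "de_rank": r.best_rank}
            for r in reps
        ]
    ).to_csv(path, sep="\t", index=False)


def write_heatmap_tsv(matrix: np.ndarray, genes, terms, path) -> None:
    df = pd.DataFrame(matrix, index=genes, columns=terms)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def plot_heatmap(matrix: np.ndarray, genes, terms, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(terms) + 2), max(3, 0.25 * len(genes) + 1.5))
    )
    im = ax.imshow(matrix, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(terms)), labels=terms, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(genes)), labels=genes, fontsize=6)
    ax.set_xlabel("GO term (selection order)")
    ax.set_ylabel("gene (representation order)")
    fig.colorbar(im, ax=ax, label=r"$-\log_{10}$ best adjusted $p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Everything one run needs; serialised into the run manifest."""

    counts_path: str | None = None
    groups_path: str | None = None
    de_table_path: str | None = None
    annotation_path: str | None = None
    annotation_format: str = "gene2term"  # or "gaf"
    filter: FilterConfig = field(default_factory=FilterConfig)
    step_size: int = 25
    max_alpha: float = 0.5
    min_term_size: int = 3
    top_t: int = 5
    top_genes: int = 30
    out_dir: str = "gosweep_out"
    seed: int = 0
    simulation: SimulationConfig | None = None

    def validate(self) -> None:
        has_counts = self.counts_path is not None and self.groups_path is not None
        has_de = self.de_table_path is not None
        if has_counts == has_de:
            raise ValueError("supply exactly one of {counts+groups, de_table}")
        for p in (self.counts_path, self.groups_path, self.de_table_path, self.annotation_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _read_annotation(config: PipelineConfig) -> AnnotationMap:
    if config.annotation_path is None:
        raise ValueError("an annotation file is required")
    if config.annotation_format == "gaf":
        return read_gaf_subset(config.annotation_path)
    return read_gene2term(config.annotation_path)


def write_manifest(config: PipelineConfig, path) -> None:
    payload = asdict(config)
    payload["gosweep_version"] = __version__
    payload["numpy_version"] = np.__version__
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")


def simulate_to_dir(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Generate one synthetic experiment and write all its files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation, truth, counts = simulate_experiment(config)
    paths = {
        "counts": out / "counts.tsv",
        "groups": out / "groups.tsv",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.txt",
    }
    write_counts(counts, paths["counts"], paths["groups"])
    write_gene2term(annotation, paths["annotation"])
    write_truth(truth, paths["truth"])
    return paths


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """DE stage (or external table) -> landscape -> selections -> heatmap.

    Writes every artifact plus a manifest into ``config.out_dir``; partial
    outputs are removed if a stage fails. Identical config+seed gives
    bit-identical numeric outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str, writer, *args) -> Path:
        path = out / name
        writer(*args, path)
        written.append(path)
        return path

    artifacts: dict[str, Path] = {}
    try:
        if config.de_table_path is not None:
            stage = "read external DE table"
            de = read_de_table(config.de_table_path).sort_values("rank").reset_index(drop=True)
        else:
            stage = "differential expression"
            counts = read_counts(config.counts_path, config.groups_path)
            de = run_de(counts)
        artifacts["de_table"] = _emit("de_table.tsv", write_de_table, de)

        stage = "DE selection"
        selected = select_de(de, config.filter)
        sel_path = out / "selected_genes.txt"
        sel_path.write_text("".join(f"{g}\n" for g in sorted(selected)), encoding="utf-8")
        written.append(sel_path)
        artifacts["selected_genes"] = sel_path
        logger.info("%d genes pass padj<=%g, |FC|>%g", len(selected),
                    config.filter.alpha, config.filter.fc_threshold)

        stage = "landscape"
        annotation = _read_annotation(config)
        ranked = de["gene"].tolist()
        landscape = compute_landscape(
            ranked,
            annotation,
            min_term_size=config.min_term_size,
            step_size=config.step_size,
            ranked_p=de["p"].to_numpy(),
            max_alpha=config.max_alpha,
        )
        artifacts["landscape"] = _emit("landscape.tsv", write_landscape, landscape)

        stage = "term and gene selection"
        summaries = score_terms(landscape, annotation)
        top_terms = select_top_terms(summaries, config.top_t)
        artifacts["term_summary"] = _emit(
            "term_summary.tsv", write_term_summaries,
            sorted(summaries, key=lambda s: (s.best_adj_p, s.best_step, s.term)),
        )
        reps = gene_representation(top_terms, annotation, ranked)[: config.top_genes]
        artifacts["gene_representation"] = _emit(
            "gene_representation.tsv", write_gene_representation, reps
        )

        stage = "heatmap"
        mat = heatmap_matrix(reps, top_terms, annotation)
        gene_ids = [r.gene for r in reps]
        term_ids = [s.term for s in top_terms]
        artifacts["heatmap_tsv"] = _emit(
            "heatmap.tsv", write_heatmap_tsv, mat, gene_ids, term_ids
        )
        artifacts["heatmap_png"] = _emit(
            "heatmap.png", lambda m, g, t, p: plot_heatmap(m, g, t, p), mat, gene_ids, term_ids
        )

        stage = "manifest"
        manifest = out / "manifest.json"
        write_manifest(config, manifest)
        written.append(manifest)
        artifacts["manifest"] = manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return artifacts
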