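"""Reading and writing the pipeline's tables, and end-to-end orchestration.

File formats are deliberately plain: tab-delimited matrices with a
header row ('#' comment lines ignored), CSV phenotype tables, JSON
summaries.  GFF3 is accepted as an alternative source of gene lengths
(sum of the merged exon spans of the canonical transcript).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expression import (
    GENETIC_TYPES,
    CountMatrix,
    ValidationError,
    aggregate_by_type,
    compute_rpkm,
    filter_expressed,
    spearman_correlation,
)
from .diffexpr import all_pairwise_de
from .inheritance import classify_all, hybrid_overlap, summarize_classes
from .phenostats import group_means, heterosis, pairwise_mwu
from .simulate import SimConfig, generate_counts

__all__ = [
    "read_counts",
    "read_lengths",
    "read_metadata",
    "read_phenotypes",
    "lengths_from_gff3",
    "write_count_matrix",
    "write_table",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("hybridexpr")

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValidationError(f"cannot parse {path}: {exc}") from exc


def read_counts(
    counts_path: str | Path,
    lengths_path: str | Path,
    metadata_path: str | Path,
) -> CountMatrix:
    """Assemble a validated CountMatrix from the three input tables.

    Genes present in the counts but missing a length (or vice versa) are
    dropped to the strict intersection with a logged warning listing the
    offenders -- a silent mismatch between the two files is the classic
    failure mode.
    """
    counts = _read_tsv(counts_path, index_col=0)
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            row = counts.index[vals.isna()][0]
            raise ValidationError(
                f"{counts_path}: non-numeric count for gene {row!r}, sample {col!r}"
            )
        if (vals < 0).any():
            row = counts.index[vals < 0][0]
            raise ValidationError(
                f"{counts_path}: negative count at gene {row!r}, sample {col!r}"
            )
        if (vals % 1 != 0).any():
            row = counts.index[vals % 1 != 0][0]
            raise ValidationError(
                f"{counts_path}: non-integer count at gene {row!r}, sample {col!r}"
            )
        counts[col] = vals.astype(np.int64)
    lengths = read_lengths(lengths_path)
    shared = counts.index.intersection(lengths.index)
    dropped = counts.index.symmetric_difference(lengths.index)
    if len(shared) == 0:
        raise ValidationError(
            f"no genes shared between {counts_path} and {lengths_path}"
        )
    if len(dropped):
        log.warning(
            "dropping %d genes absent from counts or lengths: %s%s",
            len(dropped),
            list(dropped[:10]),
            "..." if len(dropped) > 10 else "",
        )
    type_map = read_metadata(metadata_path)
    missing = counts.columns.difference(type_map.index)
    if len(missing):
        raise ValidationError(
            f"{metadata_path}: samples without genetic type: {list(missing)}"
        )
    return CountMatrix(
        counts=counts.loc[shared],
        lengths=lengths.loc[shared],
        type_map=type_map.loc[counts.columns],
    )


def read_lengths(path: str | Path) -> pd.Series:
    """Two-column TSV (gene_id, length_bp) or a GFF3 file (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return lengths_from_gff3(path)
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (gene_id, length_bp)")
    s = pd.Series(
        pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(),
        index=pd.Index(df.iloc[:, 0], name="gene_id"),
        name="length_bp",
    )
    if s.isna().any() or (s <= 0).any():
        bad = s.index[s.isna() | (s <= 0)]
        raise ValidationError(f"{path}: invalid lengths for genes {list(bad[:5])}")
    if s.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    return s.astype(np.int64)


def read_metadata(path: str | Path) -> pd.Series:
    """TSV sample metadata (sample_id, genetic_type)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns (sample_id, genetic_type)")
    s = pd.Series(
        df.iloc[:, 1].to_numpy(),
        index=pd.Index(df.iloc[:, 0], name="sample_id"),
        name="genetic_type",
    )
    unknown = set(s) - set(GENETIC_TYPES)
    if unknown:
        raise ValidationError(
            f"{path}: unknown genetic-type tokens {sorted(unknown)}; "
            f"expected one of {GENETIC_TYPES}"
        )
    return s


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """CSV phenotype table: individual_id, genetic_type, one column per trait."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    for col in ("individual_id", "genetic_type"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if df["individual_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate individual ids")
    unknown = set(df["genetic_type"]) - set(GENETIC_TYPES)
    if unknown:
        raise ValidationError(f"{path}: unknown genetic-type tokens {sorted(unknown)}")
    return df


def lengths_from_gff3(path: str | Path) -> pd.Series:
    """Per-gene transcript length from a GFF3: merged exon spans of the
    canonical (longest) transcript, coordinates 1-based inclusive."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    lengths: dict[str, int] = {}
    for gene in db.features_of_type("gene"):
        best = 0
        transcripts = list(
            db.children(gene, featuretype=("mRNA", "transcript"), level=1)
        )
        if transcripts:
            for tx in transcripts:
                exons = [(e.start, e.end) for e in db.children(tx, featuretype="exon")]
                best = max(best, _merged_span_length(exons))
        else:
            exons = [(e.start, e.end) for e in db.children(gene, featuretype="exon")]
            best = _merged_span_length(exons)
        if best == 0:  # no exon structure: fall back to the gene span
            best = gene.end - gene.start + 1
        lengths[gene.id] = best
    if not lengths:
        raise ValidationError(f"{path}: no gene features found")
    s = pd.Series(lengths, name="length_bp")
    s.index.name = "gene_id"
    return s.astype(np.int64)


def _merged_span_length(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by 1-based inclusive intervals, overlaps merged."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_start, cur_end = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_end + 1:
            cur_end = max(cur_end, e)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
    total += cur_end - cur_start + 1
    return total


def write_count_matrix(cm: CountMatrix, outdir: str | Path) -> dict[str, Path]:
    """Write counts/lengths/metadata TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "lengths": outdir / "gene_lengths.tsv",
        "metadata": outdir / "sample_metadata.tsv",
    }
    cm.counts.to_csv(paths["counts"], sep="\t")
    cm.lengths.to_csv(paths["lengths"], sep="\t")
    cm.type_map.to_csv(paths["metadata"], sep="\t")
    return paths


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> Path:
    """Write a results table with full float precision (round-trip stable)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Exactly one of (``counts_path`` + ``lengths_path`` + ``metadata_path``)
    or ``sim`` must be provided.  Thresholds default to the pipeline's
    standard values and appear here only.
    """

    counts_path: str | None = None
    lengths_path: str | None = None
    metadata_path: str | None = None
    library_sizes_path: str | None = None
    phenotypes_path: str | None = None
    sim: SimConfig | None = None
    expressed_rpkm: float = 1.0
    lfc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    margin: float = 0.2
    pseudocount: float = 1.0
    seed: int = 0
    outdir: str = "hybridexpr_run"
    run_de: bool = True

    def __post_init__(self) -> None:
        have_files = self.counts_path is not None
        if have_files == (self.sim is not None):
            raise ValidationError("provide exactly one of input paths or a SimConfig")
        if have_files and (self.lengths_path is None or self.metadata_path is None):
            raise ValidationError("counts input requires lengths and metadata paths")
        for name in ("expressed_rpkm", "lfc_threshold", "fdr_threshold", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.margin < 1:
            raise ValidationError("margin must lie in [0, 1)")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all result tables.

    Stages: (synthetic or file) counts -> RPKM -> type means -> expressed
    universe -> six pairwise DE tables -> transgressive classification and
    class summary -> phenotype statistics (when a phenotype table is
    given).  Returns a manifest with the config echo, input checksums and
    output paths; identical config and inputs give identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "inputs": {}, "outputs": {}}

    library_sizes = None
    if config.sim is not None:
        cm, truth = generate_counts(config.sim)
        # the generator knows its true sequencing depth; column sums are
        # only a surrogate for file inputs where depth is unavailable
        library_sizes = pd.Series(
            config.sim.library_sizes, index=cm.sample_ids, dtype=float
        )
        truth_path = write_table(truth, outdir / "truth_table.tsv")
        manifest["outputs"]["truth_table"] = str(truth_path)
    else:
        cm = read_counts(config.counts_path, config.lengths_path, config.metadata_path)
        for key in ("counts_path", "lengths_path", "metadata_path"):
            p = Path(getattr(config, key))
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
        if config.library_sizes_path is not None:
            df = _read_tsv(config.library_sizes_path)
            library_sizes = pd.Series(
                pd.to_numeric(df.iloc[:, 1]).to_numpy(), index=df.iloc[:, 0]
            )
            manifest["inputs"]["library_sizes_path"] = {
                "path": str(config.library_sizes_path),
                "sha256": _sha256(Path(config.library_sizes_path)),
            }
    for name, p in write_count_matrix(cm, outdir).items():
        manifest["outputs"][name] = str(p)
    log.info("counts: %d genes x %d samples", *cm.counts.shape)

    rpkm = compute_rpkm(cm, library_sizes=library_sizes)
    write_table(rpkm, outdir / "rpkm.tsv")
    manifest["outputs"]["rpkm"] = str(outdir / "rpkm.tsv")
    type_means = aggregate_by_type(rpkm, cm.type_map)
    write_table(type_means.means, outdir / "type_means.tsv")
    manifest["outputs"]["type_means"] = str(outdir / "type_means.tsv")

    expressed = filter_expressed(type_means, config.expressed_rpkm)
    log.info("expressed universe: %d of %d genes", len(expressed), cm.counts.shape[0])
    manifest["n_genes"] = int(cm.counts.shape[0])
    manifest["n_expressed"] = int(len(expressed))

    if config.run_de:
        de = all_pairwise_de(
            cm,
            genes=expressed,
            pseudocount=config.pseudocount,
            lfc_threshold=config.lfc_threshold,
            fdr_threshold=config.fdr_threshold,
        )
        deg_counts = {}
        for (a, b), table in de.items():
            p = write_table(table, outdir / f"de_{a}_vs_{b}.tsv")
            manifest["outputs"][f"de_{a}_vs_{b}"] = str(p)
            deg_counts[f"{a}_vs_{b}"] = int(table["is_deg"].sum())
        manifest["deg_counts"] = deg_counts
        rho = {
            f"{a}_vs_{b}": spearman_correlation(
                np.log2(type_means.means.loc[expressed, a] + 1),
                np.log2(type_means.means.loc[expressed, b] + 1),
            )
            for a, b in de
        }
        manifest["spearman_rho"] = rho

    calls = classify_all(type_means, expressed, margin=config.margin)
    write_table(calls, outdir / "transgressive_calls.tsv")
    manifest["outputs"]["transgressive_calls"] = str(outdir / "transgressive_calls.tsv")
    summary = summarize_classes(calls, universe=len(expressed))
    summary_dict = summary.to_dict()
    (outdir / "class_summary.json").write_text(
        json.dumps(summary_dict, indent=2, sort_keys=True) + "\n"
    )
    manifest["outputs"]["class_summary"] = str(outdir / "class_summary.json")
    manifest["class_summary"] = summary_dict
    # reciprocal-hybrid overlap table (both / BC-only / CB-only)
    both = summary.concordant + summary.discordant_II
    bc_only = int((calls["call_BC"] != "none").sum() - both)
    cb_only = int((calls["call_CB"] != "none").sum() - both)
    manifest["hybrid_overlap_table"] = {"both": both, "BC_only": bc_only, "CB_only": cb_only}

    if config.phenotypes_path is not None:
        pheno = read_phenotypes(config.phenotypes_path)
        manifest["inputs"]["phenotypes_path"] = {
            "path": str(config.phenotypes_path),
            "sha256": _sha256(Path(config.phenotypes_path)),
        }
        traits = [
            c for c in pheno.columns if c not in ("individual_id", "genetic_type")
        ]
        rows = []
        for trait in traits:
            means = group_means(pheno, trait)
            res = heterosis(means, trait=trait)
            mwu = pairwise_mwu(pheno, trait, adjust=True)
            row = {
                "trait": trait,
                **{f"mean_{t}": means[t] for t in GENETIC_TYPES},
                "heterosis_pct": res.heterosis_pct,
                "best_parent": res.best_parent,
                "heterobeltiosis_pct": res.heterobeltiosis_pct,
                "exceeds_best": res.exceeds_best,
            }
            for _, r in mwu.iterrows():
                row[f"p_{r['type_a']}_vs_{r['type_b']}"] = r["p"]
            rows.append(row)
        pheno_table = pd.DataFrame(rows).set_index("trait")
        p = write_table(pheno_table, outdir / "phenotype_stats.tsv")
        manifest["outputs"]["phenotype_stats"] = str(p)

    manifest["checksums"] = {
        name: _sha256(Path(p)) for name, p in manifest["outputs"].items()
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
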