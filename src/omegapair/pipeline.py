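"""Pair-level and cohort-level orchestration of the genome-pair analysis.

``run_pair_analysis`` executes the full chain for one genome pair:
ortholog detection (paralog collapsing + reciprocal best hits), protein
alignment back-threading to codons, dN/dS estimation (NG86 or YN00),
saturation filtering, the coding-capacity retention rule, and fragment
ANI.  ``run_cohort_analysis`` maps that over a cohort and assembles the
four correlation panels reported for published cohorts: mean dN/dS vs
genome size (CDS and bp), coding density vs size (bp), and mean dN/dS vs
ANI.  Correlations use only pairs that pass the retention rule; a pair's
"genome size" is the mean of its two genomes' sizes (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ani as ani_mod
from . import codon_evolution as ce
from . import orthology
from .genome_model import GenomeRecord, genome_size_metrics, read_genome
from .stats import CorrelationResult, spearman

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every pipeline threshold in one flat, serialisable document."""

    method: str = "YN00"
    table_id: int = 11
    cluster_identity: float = 90.0
    cluster_coverage: float = 90.0
    bbh_min_identity: float = 30.0
    bbh_min_coverage: float = 50.0
    ds_min: float = ce.DS_MIN
    ds_max: float = ce.DS_MAX
    omega_max: float = ce.OMEGA_MAX
    retention_fraction: float = ce.RETENTION_FRACTION
    compute_ani: bool = True
    ani_fragment_len: int = ani_mod.DEFAULT_FRAGMENT_LEN
    ani_min_identity: float = ani_mod.MIN_IDENTITY_PCT
    ani_min_coverage: float = ani_mod.MIN_COVERAGE_PCT
    ani_max_fragments: int | None = 200
    density_mode: str = "union"
    pair_size_summary: str = "mean"  # mean | min | max | first


_ORTHOLOG_COLUMNS = [
    "gene_a", "gene_b", "method", "n_codons", "pct_identity", "S", "N",
    "Sd", "Nd", "dS", "dN", "omega", "kappa", "filter_status", "reason",
]


def run_pair_analysis(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    config: PipelineConfig | None = None,
) -> tuple[ce.GenomePairSummary, pd.DataFrame]:
    """Full analysis of one genome pair.

    Returns the pair summary and the per-ortholog table (one row per BBH
    pair, with its estimate and filter outcome).  A pair with zero
    orthologs yields a keep=False summary, not an error.
    """
    cfg = config or PipelineConfig()
    tag = f"{genome_a.genome_id}~{genome_b.genome_id}"
    pairs = orthology.hybrid_ortholog_pairs(
        genome_a.proteome(),
        genome_b.proteome(),
        cluster_identity=cfg.cluster_identity,
        cluster_coverage=cfg.cluster_coverage,
        min_identity=cfg.bbh_min_identity,
        min_coverage=cfg.bbh_min_coverage,
    )
    logger.info("%s: orthology: %d reciprocal best hits", tag, len(pairs))

    estimates: list[ce.DnDsEstimate] = []
    n_removed_columns = 0
    for op in pairs:
        ca = ce.backthread_codon_alignment(
            op.alignment,
            genome_a.cds_by_id(op.gene_a).nt_seq,
            genome_b.cds_by_id(op.gene_b).nt_seq,
            table_id=cfg.table_id,
        )
        n_removed_columns += ca.n_columns_removed
        if not ca.codon_columns:
            continue
        estimates.append(ce.estimate_dnds(ca, method=cfg.method))
    logger.info(
        "%s: codon stage: %d estimates, %d columns dropped",
        tag, len(estimates), n_removed_columns,
    )

    retained, discarded = ce.apply_saturation_filters(
        estimates, cfg.ds_min, cfg.ds_max, cfg.omega_max
    )
    reasons: dict[str, int] = {}
    for _, reason in discarded:
        reasons[reason] = reasons.get(reason, 0) + 1
    logger.info(
        "%s: filters: %d retained, discards by reason %s",
        tag, len(retained), reasons,
    )

    ani_pct = None
    if cfg.compute_ani:
        ani_res = ani_mod.compute_ani(
            genome_a,
            genome_b,
            fragment_len=cfg.ani_fragment_len,
            min_identity=cfg.ani_min_identity,
            min_coverage=cfg.ani_min_coverage,
            max_fragments=cfg.ani_max_fragments,
        )
        ani_pct = ani_res.ani_pct
        logger.info(
            "%s: ANI %.4s%% from %d/%d fragments",
            tag, str(ani_pct), ani_res.n_fragments_used, ani_res.n_fragments_total,
        )

    ma = genome_size_metrics(genome_a, mode=cfg.density_mode)
    mb = genome_size_metrics(genome_b, mode=cfg.density_mode)
    summary = ce.summarize_genome_pair(
        retained,
        n_orthologs=len(pairs),
        cds_count_a=ma.size_cds,
        cds_count_b=mb.size_cds,
        ani_pct=ani_pct,
        genome_a=genome_a.genome_id,
        genome_b=genome_b.genome_id,
        size_a_bp=ma.size_bp,
        size_b_bp=mb.size_bp,
        coding_density_a=ma.coding_density_pct,
        coding_density_b=mb.coding_density_pct,
        retention_fraction=cfg.retention_fraction,
        discard_reasons=reasons,
    )

    status = {id(e): ("retained", "") for e in retained}
    for est, reason in discarded:
        status[id(est)] = ("discarded", reason)
    identity = {
        (op.gene_a, op.gene_b): op.alignment.pct_identity for op in pairs
    }
    rows = []
    for est in estimates:
        st, reason = status[id(est)]
        rows.append(
            {
                "gene_a": est.gene_a,
                "gene_b": est.gene_b,
                "method": est.method,
                "n_codons": est.n_codons,
                "pct_identity": identity.get((est.gene_a, est.gene_b)),
                "S": est.S,
                "N": est.N,
                "Sd": est.Sd,
                "Nd": est.Nd,
                "dS": est.dS,
                "dN": est.dN,
                "omega": est.omega,
                "kappa": est.kappa,
                "filter_status": st,
                "reason": reason,
            }
        )
    table = pd.DataFrame(rows, columns=_ORTHOLOG_COLUMNS)
    return summary, table


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortReport:
    """Per-pair summaries plus the four cohort correlation panels."""

    pair_table: pd.DataFrame
    correlations: dict[str, CorrelationResult | None]
    n_pairs: int
    n_kept: int
    notes: str = ""
    ortholog_tables: list = field(default_factory=list)


_PANELS = [
    ("mean_omega", "size_cds", "omega_vs_size_cds"),
    ("mean_omega", "size_bp", "omega_vs_size_bp"),
    ("coding_density", "size_bp", "density_vs_size_bp"),
    ("mean_omega", "ani_pct", "omega_vs_ani"),
]


def _pair_size(a: float, b: float, how: str) -> float:
    if how == "mean":
        return 0.5 * (a + b)
    if how == "min":
        return min(a, b)
    if how == "max":
        return max(a, b)
    if how == "first":
        return a
    raise ValueError(f"unknown pair_size_summary {how!r}")


def summaries_to_table(
    summaries: list[ce.GenomePairSummary], how: str = "mean"
) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "genome_a": s.genome_a,
                "genome_b": s.genome_b,
                "n_orthologs": s.n_orthologs,
                "n_retained": s.n_retained,
                "mean_omega": s.mean_omega,
                "sem_omega": s.sem_omega,
                "retained_fraction": s.retained_fraction_of_capacity,
                "keep": s.keep,
                "ani_pct": s.ani_pct,
                "size_cds": _pair_size(s.size_a_cds, s.size_b_cds, how),
                "size_bp": _pair_size(s.size_a_bp, s.size_b_bp, how),
                "coding_density": (
                    0.5 * (s.coding_density_a + s.coding_density_b)
                    if s.coding_density_a is not None
                    and s.coding_density_b is not None
                    else None
                ),
            }
        )
    return pd.DataFrame(rows)


def cohort_correlations(
    pair_table: pd.DataFrame,
) -> tuple[dict[str, CorrelationResult | None], str]:
    kept = pair_table[pair_table["keep"]]
    out: dict[str, CorrelationResult | None] = {}
    notes = []
    for ycol, xcol, name in _PANELS:
        sub = kept[[xcol, ycol]].dropna()
        if len(sub) < 3:
            out[name] = None
            notes.append(f"{name}: only {len(sub)} kept pairs (need >= 3)")
            continue
        try:
            out[name] = spearman(sub[xcol].to_numpy(), sub[ycol].to_numpy())
        except ValueError as exc:
            out[name] = None
            notes.append(f"{name}: {exc}")
    return out, "; ".join(notes)


def run_cohort_analysis(
    pairs: list[tuple[GenomeRecord, GenomeRecord]],
    config: PipelineConfig | None = None,
) -> CohortReport:
    """Analyse every genome pair of a cohort and correlate the summaries."""
    cfg = config or PipelineConfig()
    summaries = []
    tables = []
    for rec_a, rec_b in pairs:
        summary, table = run_pair_analysis(rec_a, rec_b, cfg)
        summaries.append(summary)
        tables.append(table)
    pair_table = summaries_to_table(summaries, cfg.pair_size_summary)
    correlations, notes = cohort_correlations(pair_table)
    n_kept = int(pair_table["keep"].sum()) if len(pair_table) else 0
    if n_kept < 3 and not notes:
        notes = f"only {n_kept} pairs passed the retention rule"
    return CohortReport(
        pair_table=pair_table,
        correlations=correlations,
        n_pairs=len(pairs),
        n_kept=n_kept,
        notes=notes,
        ortholog_tables=tables,
    )


def load_cohort(manifest_path: str | Path) -> list[tuple[GenomeRecord, GenomeRecord]]:
    """Read the genome pairs listed in a cohort manifest TSV."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    pairs = []
    for _, row in manifest.iterrows():
        rec_a = read_genome(
            base / row["fasta_a"], base / row["gff_a"], genome_id=f"{row['pair_id']}_A"
        )
        rec_b = read_genome(
            base / row["fasta_b"], base / row["gff_b"], genome_id=f"{row['pair_id']}_B"
        )
        pairs.append((rec_a, rec_b))
    return pairs


def correlations_to_table(
    correlations: dict[str, CorrelationResult | None],
) -> pd.DataFrame:
    rows = []
    for name, res in correlations.items():
        rows.append(
            {
                "panel": name,
                "rs": res.rs if res else None,
                "p_two_sided": res.p_two_sided if res else None,
                "n": res.n if res else 0,
                "method": res.method if res else "missing",
            }
        )
    return pd.DataFrame(rows)


def write_cohort_report(
    report: CohortReport, outdir: str | Path, config: PipelineConfig | None = None
) -> None:
    """Write pair table, correlation table and a run-config JSON.

    Floats are formatted with a fixed precision so identical runs produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.pair_table.to_csv(
        outdir / "pair_summaries.tsv", sep="\t", index=False, float_format="%.6g"
    )
    correlations_to_table(report.correlations).to_csv(
        outdir / "correlations.tsv", sep="\t", index=False, float_format="%.6g"
    )
    for table, (_, row) in zip(
        getattr(report, "ortholog_tables", []), report.pair_table.iterrows()
    ):
        name = f"orthologs_{row['genome_a']}_{row['genome_b']}.tsv"
        table.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")
    if config is not None:
        import json

        with open(outdir / "run_config.json", "w") as fh:
            json.dump(asdict(config), fh, indent=1, sort_keys=True)
    if report.notes:
        (outdir / "notes.txt").write_text(report.notes + "\n")


def plot_cohort(report: CohortReport, outdir: str | Path) -> list[Path]:
    """Optional scatter plots of the four correlation panels (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kept = report.pair_table[report.pair_table["keep"]]
    written = []
    for ycol, xcol, name in _PANELS:
        sub = kept[[xcol, ycol]].dropna()
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(sub[xcol], sub[ycol], s=18)
        res = report.correlations.get(name)
        title = name
        if res:
            title += f"  Rs={res.rs:.2f}, P={res.p_two_sided:.3g}"
        ax.set_xlabel(xcol)
        ax.set_ylabel(ycol)
        ax.set_title(title, fontsize=9)
        fig.tight_layout()
        path = outdir / f"{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
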