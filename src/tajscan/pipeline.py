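"""End-to-end runs: scan a bundle, compare two scans, contrast gene classes.

Each run writes TSV/JSON outputs plus a manifest describing inputs and
configuration, so deterministic stages reproduce bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .contrasts import (ContingencyTable2x2, ExpressionClass, chi_square_2x2,
                        fisher_exact_2x2, ks_two_sample, rank_sum_test,
                        selection_by_expression_contrast, two_sample_t)
from .empirical import TailConfig, build_distribution, classify_windows, empirical_limits
from .genes import classify_genes, gene_class_counts
from .genome_io import (MaskSet, load_genes, load_mask, load_reference_index,
                        load_variants)
from .windows import ScanConfig, WindowStatus, partition_genome, scan_summary, scan_windows

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ScanReport", "run_scan", "run_compare", "run_contrast",
           "run_simulate", "gene_classes_from_frame"]


@dataclass
class RunConfig:
    vcf: str
    fasta_index: str
    mask_bed: str | None = None
    gff3: str | None = None
    out_dir: str = "scan_out"
    strains: tuple[str, ...] | None = None
    scan: ScanConfig = ScanConfig()
    tail: TailConfig = TailConfig()
    gene_min_coverage: float = 0.5
    coverage: float = 0.95


@dataclass
class ScanReport:
    out_dir: Path
    summary: dict
    windows: pd.DataFrame
    genes: pd.DataFrame | None


def _fmt(x, nd=6):
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.{nd}g}" if isinstance(x, float) else str(x)


def run_scan(config: RunConfig) -> ScanReport:
    """Scan a genome: windows, D distribution, empirical limits, genes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = load_reference_index(config.fasta_index)
    mask = load_mask(config.mask_bed, index) if config.mask_bed else MaskSet()
    windows = partition_genome(index, config.scan)
    variants = list(load_variants(config.vcf, config.strains))
    stats = scan_windows(windows, variants, mask, config.scan)

    if variants:
        n_sequences = sum(len(gt) for gt in variants[0].genotypes)
    else:
        n_sequences = 2 * 5  # no variants at all; assume five diploids

    summary = scan_summary(stats)
    dist = build_distribution(stats, n_sequences,
                              include_partial=config.scan.include_partial,
                              coverage=config.coverage)
    empirical_limits(dist, config.tail)
    sig_counts = classify_windows(stats, dist)
    summary.update(sig_counts)

    analysed = [s for s in stats if s.status is WindowStatus.ANALYSED]
    summary.update({
        "n_sequences": n_sequences,
        "d_mean": dist.mean, "d_min": dist.min, "d_max": dist.max,
        "theoretical_lower": dist.theoretical_limits.lower
        if dist.theoretical_limits else None,
        "theoretical_upper": dist.theoretical_limits.upper
        if dist.theoretical_limits else None,
        "empirical_lower": dist.empirical_lower,
        "empirical_upper": dist.empirical_upper,
        "achieved_lower_mass": dist.achieved_lower_mass,
        "achieved_upper_mass": dist.achieved_upper_mass,
        "theta_mean": float(np.mean([s.diversity.theta_w for s in analysed])),
        "pi_site_mean": float(np.mean([s.diversity.pi_site for s in analysed])),
    })

    win_rows = []
    for s in stats:
        d = s.diversity
        win_rows.append({
            "window_id": s.window.id, "chrom": s.window.chrom,
            "start": s.window.start, "end": s.window.end,
            "is_partial": s.window.is_partial,
            "callable_fraction": round(s.callable_fraction, 6),
            "S": d.S if d else 0,
            "k_hat": round(d.k_hat, 6) if d else 0.0,
            "pi_site": round(d.pi_site, 8) if d else 0.0,
            "theta_window": round(d.theta_w, 6) if d else 0.0,
            "D": "NA" if (d is None or d.D is None) else round(d.D, 6),
            "status": s.status.value,
            "significance": s.significance.value,
        })
    windows_df = pd.DataFrame(win_rows)
    windows_df.to_csv(out / "windows.tsv", sep="\t", index=False)

    dvals = pd.Series(dist.values).value_counts().sort_index()
    pd.DataFrame({"D": dvals.index, "count": dvals.values}).to_csv(
        out / "distribution.tsv", sep="\t", index=False)

    windows_df[windows_df["significance"] != "ns"].to_csv(
        out / "significant_windows.tsv", sep="\t", index=False)

    genes_df = None
    if config.gff3:
        genes = load_genes(config.gff3, index)
        gclasses = classify_genes(genes, stats, config.gene_min_coverage)
        summary.update(gene_class_counts(gclasses))
        genes_df = pd.DataFrame([{
            "gene_id": gc.gene.gene_id, "chrom": gc.gene.chrom,
            "start": gc.gene.start, "end": gc.gene.end,
            "coverage_fraction": round(gc.coverage_fraction, 6),
            "class": gc.gene_class.value,
            "extreme_D": "NA" if gc.extreme_D is None else round(gc.extreme_D, 6),
            "supporting_windows": ",".join(map(str, gc.supporting_windows)) or ".",
            "mixed_signs": gc.mixed_signs,
        } for gc in gclasses])
        genes_df.to_csv(out / "genes.tsv", sep="\t", index=False)

    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
        fh.write("\n")
    _write_manifest(out, {
        "command": "scan",
        "inputs": {k: str(getattr(config, k)) for k in
                   ("vcf", "fasta_index", "mask_bed", "gff3")},
        "scan_config": asdict(config.scan),
        "tail_config": asdict(config.tail),
    })
    return ScanReport(out_dir=out, summary=summary, windows=windows_df,
                      genes=genes_df)


def _write_manifest(out: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["tajscan_version"] = __version__
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    payload["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")


def _load_scan_output(path: str | Path) -> tuple[pd.DataFrame, dict]:
    p = Path(path)
    windows = pd.read_csv(p / "windows.tsv", sep="\t", na_values=["NA"])
    with open(p / "report.json") as fh:
        report = json.load(fh)
    needed = {"D", "theta_window", "status"}
    if not needed <= set(windows.columns):
        raise ValueError(f"{p}/windows.tsv lacks columns {needed - set(windows.columns)}")
    return windows, report


def run_compare(dir_a: str | Path, dir_b: str | Path,
                out_path: str | Path | None = None) -> pd.DataFrame:
    """The four between-scan comparisons.

    K-S and rank-sum on the D distributions, t on per-window theta of
    analysed windows, and chi-square on invariable-vs-analysed proportions.
    """
    wa, ra = _load_scan_output(dir_a)
    wb, rb = _load_scan_output(dir_b)
    da = wa.loc[wa["status"] == "analysed", "D"].dropna().to_numpy(float)
    db = wb.loc[wb["status"] == "analysed", "D"].dropna().to_numpy(float)
    ta = wa.loc[wa["status"] == "analysed", "theta_window"].to_numpy(float)
    tb = wb.loc[wb["status"] == "analysed", "theta_window"].to_numpy(float)

    rows = []
    ks = ks_two_sample(da, db)
    rows.append({"comparison": "D_distribution", "method": ks.method,
                 "statistic": ks.statistic, "df": ks.df, "p_value": ks.p_value})
    w = rank_sum_test(da, db)
    rows.append({"comparison": "D_mean", "method": w.method,
                 "statistic": w.statistic, "df": w.df, "p_value": w.p_value})
    t = two_sample_t(ta, tb, pooled=True)
    rows.append({"comparison": "theta_mean", "method": t.method,
                 "statistic": t.statistic, "df": t.df, "p_value": t.p_value})
    table = ContingencyTable2x2(
        ra["windows_invariable"], ra["windows_with_d"],
        rb["windows_invariable"], rb["windows_with_d"])
    try:
        chi = chi_square_2x2(table)
        rows.append({"comparison": "invariable_proportion", "method": chi.method,
                     "statistic": chi.statistic, "df": chi.df,
                     "p_value": chi.p_value})
    except ValueError:
        # No invariable windows in either scan: the proportions are equal
        # and the chi-square statistic degenerates to 0.
        log.warning("invariable-window margin is zero; reporting chi2 = 0")
        rows.append({"comparison": "invariable_proportion",
                     "method": "chi_square_2x2", "statistic": 0.0, "df": 1,
                     "p_value": 1.0})
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def run_contrast(genes_tsv: str | Path | None = None,
                 expression_tsv: str | Path | None = None,
                 counts: Sequence[int] | None = None,
                 global_counts: dict | None = None,
                 out_path: str | Path | None = None) -> pd.DataFrame:
    """Expression-class contrast report, or a single test on printed counts.

    With ``counts`` = (a, b, c, d), runs Fisher's exact test (and the
    chi-square) on that one table. Otherwise joins a scanned genes.tsv
    against an expression-class TSV and emits the six Fisher comparisons.
    """
    if counts is not None:
        a, b, c, d = counts
        table = ContingencyTable2x2(a, b, c, d)
        fisher = fisher_exact_2x2(table)
        chi = chi_square_2x2(table)
        df = pd.DataFrame([
            {"comparison": "counts", "method": fisher.method,
             "statistic": fisher.statistic, "p_value": fisher.p_value},
            {"comparison": "counts", "method": chi.method,
             "statistic": chi.statistic, "p_value": chi.p_value},
        ])
    else:
        if genes_tsv is None or expression_tsv is None:
            raise ValueError("need genes_tsv and expression_tsv, or counts")
        genes = pd.read_csv(genes_tsv, sep="\t", na_values=["NA"])
        from .contrasts import load_expression_table
        expr = load_expression_table(expression_tsv)
        gene_classes = gene_classes_from_frame(genes)
        counts_df, tests_df = selection_by_expression_contrast(
            gene_classes, expr, global_counts)
        df = tests_df
        if out_path is not None:
            counts_df.to_csv(Path(out_path).with_suffix(".counts.tsv"),
                             sep="\t", index=False)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def gene_classes_from_frame(genes: pd.DataFrame):
    """Rehydrate GeneClassification objects from a genes.tsv frame."""
    from .genes import GeneClass, GeneClassification
    from .genome_io import GeneModel

    out = []
    for _, r in genes.iterrows():
        extreme = r.get("extreme_D")
        if pd.isna(extreme) or extreme == "NA":
            extreme = None
        gc = GeneClassification(
            gene=GeneModel(str(r["gene_id"]), str(r["chrom"]),
                           int(r["start"]), int(r["end"])),
            coverage_fraction=float(r["coverage_fraction"]),
            gene_class=GeneClass(r["class"]),
            extreme_D=None if extreme is None else float(extreme),
        )
        out.append(gc)
    return out


def run_simulate(spec, out_dir: str | Path):
    """Emit a synthetic genome bundle (thin wrapper kept for CLI symmetry)."""
    from .simulate import emit_genome_bundle
    return emit_genome_bundle(spec, out_dir)
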