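"""Coalescent synthetic-genome generator for benchmarking the scan.

Each 1-kb window gets an independent genealogy for n = strains x ploidy
haploid lineages (free recombination between windows, none within), and
infinite-sites mutations dropped on it at a per-window population mutation
rate theta, so that E[pairwise differences] = theta and E[S] = theta * a1(n).
Three regimes shape the genealogy:

* NEUTRAL  - standard Kingman coalescent;
* BALANCING - a neutral genealogy whose two root-adjacent branches are
  stretched, mimicking an anciently balanced split that piles variants at
  intermediate frequency (positive D);
* SWEEP - a star genealogy (all lineages coalesce at once), so every
  variant is a singleton (strongly negative D).

The emitted bundle (FASTA + .fai + VCF + BED mask + GFF3 + truth tables)
is byte-identical for identical seeds.
"""

from __future__ import annotations

import enum
import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .contrasts import ExpressionClass

__all__ = ["Regime", "SimSpec", "Genealogy", "simulate_genealogy",
           "drop_mutations", "Mutation", "emit_genome_bundle", "GenomeBundle",
           "make_regime_map", "plant_expression_classes"]

_BASES = np.array(list("ACGT"))


class Regime(enum.Enum):
    NEUTRAL = "neutral"
    BALANCING = "balancing"
    SWEEP = "sweep"


@dataclass
class SimSpec:
    """Study conditions for a synthetic bundle.

    Defaults emulate a scan of five diploid natural isolates in 1-kb
    windows at a mid-range per-window theta, with a modest masked fraction
    and gene models scattered over the contigs.
    """

    contig_lengths: tuple[int, ...] = (200_000, 100_000)
    n_strains: int = 5
    ploidy: int = 2
    theta_per_window: float = 5.0
    window_size: int = 1000
    balancing_fraction: float = 0.0
    sweep_fraction: float = 0.0
    balancing_root_stretch: float = 5.0
    masked_fraction: float = 0.05
    n_genes: int = 100
    seed: int = 0
    regime_map: dict[int, Regime] | None = None

    @property
    def n_sequences(self) -> int:
        return self.n_strains * self.ploidy

    @property
    def n_windows(self) -> int:
        return sum(-(-L // self.window_size) for L in self.contig_lengths)


@dataclass(frozen=True)
class Branch:
    leaves: frozenset[int]
    length: float


@dataclass
class Genealogy:
    """A rooted genealogy represented as its branch set.

    Each branch carries the set of leaves beneath it and its length in
    coalescent units; that is all that mutation dropping needs.
    """

    n: int
    branches: tuple[Branch, ...]
    height: float

    @property
    def total_length(self) -> float:
        return sum(b.length for b in self.branches)

    def pairwise_distance(self, i: int, j: int) -> float:
        """Path length between leaves i and j (sum of unshared branches)."""
        return sum(b.length for b in self.branches
                   if (i in b.leaves) != (j in b.leaves))


def simulate_genealogy(n: int, regime: Regime = Regime.NEUTRAL,
                       stretch: float = 5.0,
                       rng: np.random.Generator | None = None) -> Genealogy:
    """Draw one genealogy of n lineages under the given regime."""
    if n < 2:
        raise ValueError("need at least 2 lineages")
    rng = np.random.default_rng() if rng is None else rng

    if regime is Regime.SWEEP:
        # Star tree at half the expected neutral height 2(1 - 1/n).
        depth = 1.0 - 1.0 / n
        branches = tuple(Branch(frozenset({i}), depth) for i in range(n))
        return Genealogy(n=n, branches=branches, height=depth)

    active: list[tuple[frozenset[int], float]] = [
        (frozenset({i}), 0.0) for i in range(n)]
    t = 0.0
    branches: list[Branch] = []
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (leaves_j, birth_j) = active.pop(j)
        (leaves_i, birth_i) = active.pop(i)
        branches.append(Branch(leaves_i, t - birth_i))
        branches.append(Branch(leaves_j, t - birth_j))
        active.append((leaves_i | leaves_j, t))
    height = t
    if regime is Regime.BALANCING:
        # The last two recorded branches are the root's children.
        root_kids = branches[-2:]
        branches = branches[:-2] + [
            Branch(b.leaves, b.length * stretch) for b in root_kids]
        height += max(b.length for b in root_kids) * (stretch - 1.0)
    return Genealogy(n=n, branches=tuple(branches), height=height)


@dataclass(frozen=True)
class Mutation:
    position: int  # offset within the window
    carriers: frozenset[int]  # leaf indices bearing the derived allele


def drop_mutations(tree: Genealogy, theta: float, window_length: int,
                   rng: np.random.Generator) -> list[Mutation]:
    """Poisson infinite-sites mutations on the genealogy.

    The count is Poisson(theta/2 * total branch length); each mutation
    lands on a branch with probability proportional to its length and at a
    unique uniform position, the derived allele carried by the leaves
    below the branch. A saturated window caps the count at the number of
    available positions.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    L = tree.total_length
    count = int(rng.poisson(theta / 2.0 * L)) if theta > 0 else 0
    count = min(count, window_length)
    if count == 0:
        return []
    lengths = np.array([b.length for b in tree.branches])
    branch_idx = rng.choice(len(lengths), size=count, p=lengths / lengths.sum())
    positions = rng.choice(window_length, size=count, replace=False)
    muts = [Mutation(int(p), tree.branches[bi].leaves)
            for p, bi in zip(positions, branch_idx)]
    muts.sort(key=lambda m: m.position)
    return muts


def make_regime_map(n_windows: int, balancing_fraction: float,
                    sweep_fraction: float,
                    rng: np.random.Generator) -> dict[int, Regime]:
    """Assign regimes to window ids by random draw at the given fractions."""
    if balancing_fraction + sweep_fraction > 1.0:
        raise ValueError("regime fractions exceed 1")
    u = rng.random(n_windows)
    out = {}
    for i in range(n_windows):
        if u[i] < balancing_fraction:
            out[i] = Regime.BALANCING
        elif u[i] < balancing_fraction + sweep_fraction:
            out[i] = Regime.SWEEP
        else:
            out[i] = Regime.NEUTRAL
    return out


@dataclass
class GenomeBundle:
    """Paths and truth tables of one emitted synthetic bundle."""

    out_dir: Path
    fasta: Path
    fai: Path
    vcf: Path
    mask_bed: Path
    gff3: Path
    windows_truth: Path
    genes_truth: Path
    manifest: Path
    strains: tuple[str, ...]


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def _random_mask_intervals(length: int, fraction: float,
                           rng: np.random.Generator,
                           block: tuple[int, int] = (200, 800)) -> list[tuple[int, int]]:
    """Random non-overlapping blocks totalling ~fraction of the contig."""
    target = int(length * fraction)
    intervals: list[tuple[int, int]] = []
    covered = 0
    attempts = 0
    while covered < target and attempts < 10_000:
        attempts += 1
        size = int(rng.integers(block[0], block[1] + 1))
        start = int(rng.integers(0, max(1, length - size)))
        end = start + size
        if any(s < end and start < e for s, e in intervals):
            continue
        intervals.append((start, end))
        covered += size
    intervals.sort()
    return intervals


def _place_genes(contig_lengths: Sequence[int], n_genes: int,
                 rng: np.random.Generator,
                 size_range: tuple[int, int] = (500, 3000)) -> list[tuple[int, int, int]]:
    """Non-overlapping (contig_idx, start, end) spans, n_genes in total."""
    total = sum(contig_lengths)
    per_contig = [max(1, round(n_genes * L / total)) for L in contig_lengths]
    while sum(per_contig) > n_genes:
        per_contig[int(np.argmax(per_contig))] -= 1
    while sum(per_contig) < n_genes:
        per_contig[int(np.argmin(per_contig))] += 1
    genes: list[tuple[int, int, int]] = []
    for ci, (L, k) in enumerate(zip(contig_lengths, per_contig)):
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < k and attempts < 50_000:
            attempts += 1
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            start = int(rng.integers(0, max(1, L - size)))
            end = start + size
            if any(s < end and start < e for s, e in placed):
                continue
            placed.append((start, end))
        placed.sort()
        genes.extend((ci, s, e) for s, e in placed)
    return genes


def emit_genome_bundle(spec: SimSpec, out_dir: str | os.PathLike) -> GenomeBundle:
    """Write a complete synthetic bundle, fully determined by spec.seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    contigs = [f"contig{i + 1}" for i in range(len(spec.contig_lengths))]
    strains = tuple(f"strain{i + 1}" for i in range(spec.n_strains))

    # Reference sequences.
    seqs = {c: "".join(rng.choice(_BASES, size=L))
            for c, L in zip(contigs, spec.contig_lengths)}
    fasta = out / "reference.fa"
    with open(fasta, "w") as fh:
        for c in contigs:
            fh.write(f">{c}\n{_wrap(seqs[c])}\n")
    fai = out / "reference.fa.fai"
    with open(fai, "w") as fh:
        offset = 0
        for c in contigs:
            L = len(seqs[c])
            offset += len(c) + 2  # ">name\n"
            n_lines = -(-L // 60)
            fh.write(f"{c}\t{L}\t{offset}\t60\t61\n")
            offset += L + n_lines  # bases + newlines

    # Mask.
    mask_bed = out / "mask.bed"
    with open(mask_bed, "w") as fh:
        for c, L in zip(contigs, spec.contig_lengths):
            for s, e in _random_mask_intervals(L, spec.masked_fraction, rng):
                fh.write(f"{c}\t{s}\t{e}\n")

    # Genes.
    gene_spans = _place_genes(spec.contig_lengths, spec.n_genes, rng)
    gff3 = out / "genes.gff3"
    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for gi, (ci, s, e) in enumerate(gene_spans):
            strand = "+" if rng.random() < 0.5 else "-"
            fh.write(f"{contigs[ci]}\ttajscan-sim\tgene\t{s + 1}\t{e}\t.\t"
                     f"{strand}\t.\tID=gene{gi + 1}\n")

    # Regimes per window.
    if spec.regime_map is not None:
        regime_map = dict(spec.regime_map)
    else:
        regime_map = make_regime_map(spec.n_windows, spec.balancing_fraction,
                                     spec.sweep_fraction, rng)

    # Simulate per window, collect VCF records and truth.
    vcf_lines: list[str] = []
    truth_rows: list[dict] = []
    wid = 0
    for c, L in zip(contigs, spec.contig_lengths):
        start = 0
        while start < L:
            end = min(start + spec.window_size, L)
            regime = regime_map.get(wid, Regime.NEUTRAL)
            tree = simulate_genealogy(n, regime, spec.balancing_root_stretch, rng)
            muts = drop_mutations(tree, spec.theta_per_window, end - start, rng)
            for m in muts:
                pos = start + m.position
                ref = seqs[c][pos]
                alt = _BASES[(int(np.where(_BASES == ref)[0][0]) + 1) % 4]
                gts = []
                for si in range(spec.n_strains):
                    alleles = [
                        1 if (si * spec.ploidy + k) in m.carriers else 0
                        for k in range(spec.ploidy)]
                    gts.append("/".join(map(str, alleles)))
                vcf_lines.append(f"{c}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
                                 f"GT\t" + "\t".join(gts))
            truth_rows.append({
                "window_id": wid, "chrom": c, "start": start, "end": end,
                "regime": regime.value, "theta": spec.theta_per_window,
                "n_mutations": len(muts),
                "tree_length": round(tree.total_length, 6),
            })
            wid += 1
            start += spec.window_size

    vcf = out / "variants.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tajscan-sim\n")
        for c, L in zip(contigs, spec.contig_lengths):
            fh.write(f"##contig=<ID={c},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(strains) + "\n")
        fh.write("\n".join(vcf_lines))
        if vcf_lines:
            fh.write("\n")

    windows_truth = out / "windows_truth.tsv"
    with open(windows_truth, "w") as fh:
        cols = ["window_id", "chrom", "start", "end", "regime", "theta",
                "n_mutations", "tree_length"]
        fh.write("\t".join(cols) + "\n")
        for r in truth_rows:
            fh.write("\t".join(str(r[k]) for k in cols) + "\n")

    # Gene truth: regimes overlapped by each gene's windows.
    genes_truth = out / "genes_truth.tsv"
    with open(genes_truth, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tregimes\n")
        for gi, (ci, s, e) in enumerate(gene_spans):
            c = contigs[ci]
            regimes = sorted({
                r["regime"] for r in truth_rows
                if r["chrom"] == c and r["start"] < e and s < r["end"]})
            fh.write(f"gene{gi + 1}\t{c}\t{s}\t{e}\t{','.join(regimes)}\n")

    manifest = out / "manifest.json"
    spec_dict = asdict(spec)
    if spec_dict["regime_map"] is not None:
        spec_dict["regime_map"] = {
            str(k): v.value for k, v in spec.regime_map.items()}
    with open(manifest, "w") as fh:
        json.dump({"spec": spec_dict, "strains": list(strains),
                   "n_windows": wid}, fh, indent=2, default=str)
        fh.write("\n")

    return GenomeBundle(out_dir=out, fasta=fasta, fai=fai, vcf=vcf,
                        mask_bed=mask_bed, gff3=gff3,
                        windows_truth=windows_truth, genes_truth=genes_truth,
                        manifest=manifest, strains=strains)


def plant_expression_classes(genes_truth_path: str | os.PathLike,
                             enrichment: float,
                             rng: np.random.Generator,
                             base_rate: float = 1.0 / 3.0) -> dict[str, ExpressionClass]:
    """Assign expression classes with enriched DIFFERENTIAL odds for genes
    overlapping BALANCING windows.

    ``enrichment`` multiplies the odds of the DIFFERENTIAL label for
    balancing-overlap genes; float('inf') makes them all DIFFERENTIAL.
    """
    import pandas as pd

    truth = pd.read_csv(genes_truth_path, sep="\t",
                        dtype={"regimes": str}, keep_default_na=False)
    base_odds = base_rate / (1.0 - base_rate)
    out: dict[str, ExpressionClass] = {}
    for _, row in truth.iterrows():
        balancing = "balancing" in str(row["regimes"]).split(",")
        if balancing and np.isinf(enrichment):
            p = 1.0
        else:
            odds = base_odds * (enrichment if balancing else 1.0)
            p = odds / (1.0 + odds)
        out[row["gene_id"]] = (ExpressionClass.DIFFERENTIAL
                               if rng.random() < p
                               else ExpressionClass.NON_DIFFERENTIAL)
    return out
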