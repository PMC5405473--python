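"""Readers and writers for the formats the scan touches.

All coordinates are 0-based half-open internally; GFF3's 1-based inclusive
spans are converted at the boundary. BED masks are merged and clipped on
load. VCF access goes through cyvcf2 and keeps only SNVs by default.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

log = logging.getLogger(__name__)

_SNV_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class ReferenceIndex:
    """Ordered chromosome names and lengths, as in a .fai index."""

    names: tuple[str, ...]
    lengths: dict[str, int]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names in index")
        for name in self.names:
            if self.lengths[name] <= 0:
                raise ValueError(f"non-positive length for {name}")

    @property
    def total_length(self) -> int:
        return sum(self.lengths[n] for n in self.names)


def load_reference_index(path: str | os.PathLike) -> ReferenceIndex:
    """Read a samtools-style .fai (name, length in the first two columns)."""
    names: list[str] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            name, length = parts[0], int(parts[1])
            if name in lengths:
                raise ValueError(f"duplicate contig {name!r} in index")
            names.append(name)
            lengths[name] = length
    if not names:
        log.warning("reference index %s is empty", path)
    return ReferenceIndex(names=tuple(names), lengths=lengths)


@dataclass
class MaskSet:
    """Per-chromosome sorted, merged half-open intervals flagged uncallable."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def masked_bases(self, chrom: str, start: int, end: int) -> int:
        """Number of masked bases overlapping [start, end)."""
        iv = self.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return 0
        lo = np.minimum(np.maximum(iv[:, 0], start), end)
        hi = np.minimum(np.maximum(iv[:, 1], start), end)
        return int(np.sum(hi - lo))

    def is_masked(self, chrom: str, pos: int) -> bool:
        return self.masked_bases(chrom, pos, pos + 1) > 0

    def total_masked(self, index: ReferenceIndex) -> int:
        return sum(self.masked_bases(c, 0, index.lengths[c]) for c in index.names)


def _merge_intervals(iv: list[tuple[int, int]]) -> np.ndarray:
    if not iv:
        return np.empty((0, 2), dtype=np.int64)
    iv.sort()
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:  # overlapping or adjacent
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def load_mask(path: str | os.PathLike, index: ReferenceIndex) -> MaskSet:
    """Read a BED (0-based half-open) into a merged, clipped MaskSet.

    Records on chromosomes absent from the index are skipped with a
    warning; records with start >= end are rejected.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom not in index.lengths:
                log.warning("%s:%d unknown chromosome %s, skipping", path, ln, chrom)
                continue
            if start >= end:
                log.warning("%s:%d empty/inverted interval, rejecting", path, ln)
                continue
            start = max(0, start)
            end = min(end, index.lengths[chrom])
            if start < end:
                raw.setdefault(chrom, []).append((start, end))
    return MaskSet({c: _merge_intervals(iv) for c, iv in raw.items()})


def write_mask(mask: MaskSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask.intervals):
            for s, e in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


@dataclass(frozen=True)
class VariantSite:
    """One VCF record restricted to the requested strains.

    genotypes: one tuple per strain with ``ploidy`` allele indices each;
    None marks a missing call.
    """

    chrom: str
    position: int  # 0-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: tuple[tuple[int | None, ...], ...]

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)

    @property
    def fully_called(self) -> bool:
        return all(a is not None for gt in self.genotypes for a in gt)

    def allele_counts(self) -> tuple[int, ...]:
        counts = [0] * self.n_alleles
        for gt in self.genotypes:
            for a in gt:
                if a is not None:
                    counts[a] += 1
        return tuple(counts)


def load_variants(
    vcf_path: str | os.PathLike,
    strains: Sequence[str] | None = None,
    *,
    snvs_only: bool = True,
    require_pass: bool = True,
) -> Iterator[VariantSite]:
    """Stream VariantSite records from a multi-sample VCF.

    Records are restricted to ``strains`` in the given order (default: all
    samples in header order). Indels and symbolic alleles are dropped when
    ``snvs_only``; records failing FILTER are dropped when ``require_pass``.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(vcf_path))
    if strains is not None:
        missing = set(strains) - set(vcf.samples)
        if missing:
            raise ValueError(f"strains not in VCF header: {sorted(missing)}")
        vcf.set_samples(list(strains))
    for rec in vcf:
        if require_pass and rec.FILTER is not None:  # None == PASS or '.'
            continue
        alts = tuple(rec.ALT)
        if snvs_only:
            if len(rec.REF) != 1 or rec.REF not in _SNV_BASES:
                continue
            if not alts or any(len(a) != 1 or a not in _SNV_BASES for a in alts):
                continue
        gts = tuple(
            tuple(None if a < 0 else int(a) for a in g[:-1])
            for g in rec.genotypes
        )
        yield VariantSite(
            chrom=rec.CHROM,
            position=rec.start,
            ref_allele=rec.REF,
            alt_alleles=alts,
            genotypes=gts,
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene span in 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty span for gene {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


def load_genes(
    gff3_path: str | os.PathLike,
    index: ReferenceIndex,
    feature_types: Sequence[str] = ("gene",),
) -> list[GeneModel]:
    """Load gene features from GFF3, converting to 0-based half-open spans."""
    import gffutils

    db = gffutils.create_db(
        os.fspath(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for ftype in feature_types:
        for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
            if feat.seqid not in index.lengths:
                log.warning("gene %s on unknown chromosome %s, skipping",
                            feat.id, feat.seqid)
                continue
            if feat.end < feat.start:
                log.warning("gene %s has end < start, rejecting", feat.id)
                continue
            gid = feat.id
            if gid in seen:
                raise ValueError(f"duplicate gene id {gid!r}")
            seen.add(gid)
            genes.append(GeneModel(gene_id=gid, chrom=feat.seqid,
                                   start=feat.start - 1, end=feat.end,
                                   strand=feat.strand or "."))
    if not genes:
        log.warning("no %s features found in %s", "/".join(feature_types), gff3_path)
    return genes


def write_genes(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write GeneModels back out as minimal GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\ttajscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def export_variants_tsv(variants: Sequence[VariantSite],
                        strains: Sequence[str],
                        path: str | os.PathLike) -> None:
    """Inspection-friendly per-site table: chrom, pos, ref, alt, genotypes."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(strains) + "\n")
        for v in variants:
            gts = "\t".join(
                "/".join("." if a is None else str(a) for a in gt)
                for gt in v.genotypes
            )
            fh.write(f"{v.chrom}\t{v.position}\t{v.ref_allele}\t"
                     f"{','.join(v.alt_alleles)}\t{gts}\n")
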