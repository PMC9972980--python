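"""SNP calling, effect annotation and strain-heterogeneity scoring.

Variant calls follow the frequency/depth filters of the study design:
a position is reported when depth >= 8 and the most frequent
non-reference allele reaches >= 20% of reads; calls at >= 80% are
"dominant" (near-fixed).  Strain heterogeneity uses a deliberately
different 80% rule: a callable position counts as polymorphic when the
most frequent allele (reference or not) is at <= 80%, and a genome with
more than 5 such SNPs per kb is flagged as a probable strain mixture.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .genome import BASES, AnnotatedGenome, GenomeError
from .pileup import PileupTable

MIN_DEPTH = 8
MIN_VAF = 0.20
DOMINANT_VAF = 0.80
HETEROGENEITY_MAX_DOMINANT = 0.80
MULTI_STRAIN_SNPS_PER_KB = 5.0


@dataclass
class SnpCall:
    """One filtered single-nucleotide variant."""

    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    depth: int
    vaf: float
    region: Optional[str] = None  # 'coding' | 'intergenic'
    gene_id: Optional[str] = None
    effect: Optional[str] = None  # synonymous|nonsynonymous|nonsense|none
    dominant: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.alt)


@dataclass
class HeterogeneityReport:
    """Within-sample polymorphism rate and strain-mixture flag."""

    polymorphic_sites: int
    callable_bases: int
    snps_per_kb: float  # NaN when no base is callable
    multi_strain_flag: bool


def call_snps(
    pileup: PileupTable,
    min_depth: int = MIN_DEPTH,
    min_vaf: float = MIN_VAF,
) -> list[SnpCall]:
    """Call one variant per qualifying position.

    A position qualifies when its depth is at least ``min_depth`` and
    its most frequent non-reference allele reaches ``min_vaf`` of the
    depth.  Among tied alternative alleles the lexicographically
    smallest base is reported.
    """
    pileup.validate()
    df = pileup.df
    counts = df[["A", "C", "G", "T"]].to_numpy()
    depth = df["depth"].to_numpy()
    ref_idx = df["ref"].map({b: i for i, b in enumerate(BASES)}).to_numpy()

    nonref = counts.copy()
    nonref[np.arange(len(df)), ref_idx] = -1
    alt_idx = nonref.argmax(axis=1)  # first occurrence wins ties
    alt_count = nonref[np.arange(len(df)), alt_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt_count / np.maximum(depth, 1), 0.0)
    keep = (depth >= min_depth) & (alt_count > 0) & (vaf >= min_vaf)

    calls = []
    for i in np.flatnonzero(keep):
        calls.append(
            SnpCall(
                contig=df.at[i, "contig"],
                pos=int(df.at[i, "pos"]),
                ref=df.at[i, "ref"],
                alt=BASES[alt_idx[i]],
                depth=int(depth[i]),
                vaf=float(vaf[i]),
            )
        )
    return calls


def flag_dominant(
    calls: list[SnpCall], threshold: float = DOMINANT_VAF
) -> list[SnpCall]:
    """Mark calls with vaf >= threshold as dominant (order preserved)."""
    return [replace(c, dominant=c.vaf >= threshold) for c in calls]


def heterogeneity(
    pileup: PileupTable, min_depth: int = MIN_DEPTH
) -> HeterogeneityReport:
    """Score within-sample strain heterogeneity.

    Positions with depth >= ``min_depth`` are callable; a callable
    position is polymorphic unless its dominant allele frequency
    exceeds 80%.  More than 5 polymorphic sites per kb flags a probable
    multi-strain sample.
    """
    df = pileup.df
    counts = df[["A", "C", "G", "T"]].to_numpy()
    depth = df["depth"].to_numpy()
    callable_mask = depth >= min_depth
    n_callable = int(callable_mask.sum())
    if n_callable == 0:
        return HeterogeneityReport(0, 0, math.nan, False)
    top = counts[callable_mask].max(axis=1)
    frac = top / depth[callable_mask]
    n_poly = int((frac <= HETEROGENEITY_MAX_DOMINANT).sum())
    rate = 1000.0 * n_poly / n_callable
    return HeterogeneityReport(
        n_poly, n_callable, rate, rate > MULTI_STRAIN_SNPS_PER_KB
    )


def annotate_effect(call: SnpCall, genome: AnnotatedGenome) -> SnpCall:
    """Attach region/gene/effect by codon lookup (table 11, strand-aware)."""
    region, gene_id, effect = genome.classify_substitution(
        call.contig, call.pos, call.alt
    )
    return replace(call, region=region, gene_id=gene_id, effect=effect)


def annotate_all(calls: list[SnpCall], genome: AnnotatedGenome) -> list[SnpCall]:
    return [annotate_effect(c, genome) for c in calls]


# ----------------------------------------------------------------------
# serialization


def write_vcf(
    calls: list[SnpCall], genome: AnnotatedGenome, path: str | os.PathLike
) -> None:
    """Write calls as minimal VCF 4.2 (positions 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lumenstrain\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda x: (x.contig, x.pos)):
            fh.write(
                f"{c.contig}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                f"DP={c.depth};VAF={c.vaf:.4f}\n"
            )


def write_tsv(calls: list[SnpCall], path: str | os.PathLike) -> None:
    cols = [
        "contig", "pos", "ref", "alt", "depth", "vaf",
        "region", "gene_id", "effect", "dominant",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.depth}\t{c.vaf:.4f}\t"
                f"{c.region or ''}\t{c.gene_id or ''}\t{c.effect or ''}\t"
                f"{int(c.dominant)}\n"
            )
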