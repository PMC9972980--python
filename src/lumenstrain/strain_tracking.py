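"""Strain relationships across samples and sites.

Three complementary views of strain identity:

* SNP distances between a sample's reads and another sample's genome —
  the total and dominant (>= 80% allele fraction) counts used to decide
  which lumen site a fecal strain resembles most;
* minor-lineage detection — SNPs at 20-50% allele frequency shared
  identically (contig, position, variant base) across all lumen sites
  of an individual; 20 or more shared SNPs evidence a co-resident
  nondominant lineage;
* fragment-based average nucleotide identity (ANI) between genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import edlib
import numpy as np
import pandas as pd

from .genome import AnnotatedGenome
from .pileup import PileupTable
from .variants import DOMINANT_VAF, MIN_DEPTH, MIN_VAF, SnpCall, call_snps

logger = logging.getLogger(__name__)

MIN_SHARED_SNPS = 20
MINOR_MAX_VAF = 0.50


class TrackingError(ValueError):
    pass


@dataclass
class SnpDistance:
    """Total and near-fixed SNP counts between a read set and a genome."""

    pair: tuple[str, str]
    total_snps: int
    dominant_snps: int


@dataclass
class LineageEvidence:
    """Shared low-frequency SNP support for a minor co-resident lineage."""

    individual: str
    shared_snp_count: int
    sites_compared: int
    present: bool


@dataclass
class AniResult:
    pair: tuple[str, str]
    ani_percent: float  # NaN when no fragment aligns
    fragments_aligned: int


def snp_distance(
    pileup: PileupTable,
    min_depth: int = MIN_DEPTH,
    min_vaf: float = MIN_VAF,
    dominant_threshold: float = DOMINANT_VAF,
    pair: tuple[str, str] = ("A", "B"),
) -> SnpDistance:
    """Count SNPs between sample A's reads and sample B's genome.

    ``pileup`` is A's reads piled against B's genome.  Dominant SNPs are
    the subset with variant allele fraction >= ``dominant_threshold``.
    """
    if len(pileup) == 0:
        logger.warning("empty pileup for pair %s; reporting zero distances", pair)
        return SnpDistance(pair, 0, 0)
    calls = call_snps(pileup, min_depth=min_depth, min_vaf=min_vaf)
    dominant = sum(c.vaf >= dominant_threshold for c in calls)
    return SnpDistance(pair, len(calls), dominant)


def detect_minor_lineage(
    site_pileups: Mapping[str, PileupTable],
    reference: AnnotatedGenome,
    min_depth: int = MIN_DEPTH,
    min_vaf: float = MIN_VAF,
    max_vaf: float = MINOR_MAX_VAF,
    min_shared: int = MIN_SHARED_SNPS,
    individual: str = "individual",
) -> LineageEvidence:
    """Detect a nondominant lineage shared across all sites.

    Per site, calls are kept when ``min_vaf <= vaf <= max_vaf`` (variants
    above 50% are attributed to the major lineage and dropped; exactly
    50% is retained).  The shared set is the exact intersection of
    (contig, position, variant base) across every site.
    """
    if len(site_pileups) < 2:
        raise TrackingError("need pileups from at least two sites")
    shared: Optional[set[tuple[str, int, str]]] = None
    for site, pileup in site_pileups.items():
        _check_reference(pileup, reference, site)
        calls = call_snps(pileup, min_depth=min_depth, min_vaf=min_vaf)
        keys = {c.key for c in calls if c.vaf <= max_vaf}
        shared = keys if shared is None else (shared & keys)
    count = len(shared or ())
    return LineageEvidence(
        individual=individual,
        shared_snp_count=count,
        sites_compared=len(site_pileups),
        present=count >= min_shared,
    )


def _check_reference(
    pileup: PileupTable, reference: AnnotatedGenome, site: str, sample: int = 500
) -> None:
    """Cheap guard that all sites were piled against the same reference."""
    df = pileup.df
    unknown = set(df["contig"].unique()) - set(reference.contigs)
    if unknown:
        raise TrackingError(
            f"site {site} mapped against unknown contigs {sorted(unknown)}"
        )
    head = df.head(sample)
    for contig, sub in head.groupby("contig", sort=False):
        seq = reference.contigs[contig]
        pos = sub["pos"].to_numpy()
        if (pos >= len(seq)).any():
            raise TrackingError(f"site {site} has positions beyond {contig}")
        want = np.array([seq[p] for p in pos])
        if (want != sub["ref"].to_numpy()).any():
            raise TrackingError(
                f"site {site} pileup reference bases disagree with the "
                "supplied genome; were sites mapped to different references?"
            )


# ----------------------------------------------------------------------
# fragment-based ANI


def _kmer_index(seqs: Mapping[str, str], k: int = 16, stride: int = 4):
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in seqs.items():
        for i in range(0, len(seq) - k + 1, stride):
            index.setdefault(seq[i : i + k], []).append((name, i))
    return index


def _identity(frag: str, window: str) -> float:
    if not window:
        return 0.0
    res = edlib.align(frag, window, mode="HW", task="distance")
    d = res["editDistance"]
    if d < 0:
        return 0.0
    return 1.0 - d / len(frag)


def ani(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    fragment: int = 1000,
    min_identity_to_count: float = 0.8,
) -> AniResult:
    """Fragment-based average nucleotide identity of A against B.

    A is cut into non-overlapping fragments; each fragment is aligned
    (infix, edit distance) against the colinear window of B when a
    same-named contig exists, with a k-mer-seeded search over all of B
    as fallback for rearranged or renamed contigs.  ANI is the mean
    identity over fragments whose best identity reaches
    ``min_identity_to_count``.
    """
    if not genome_a.contigs or not genome_b.contigs:
        raise TrackingError("both genomes must be non-empty")
    margin = max(50, fragment // 10)
    kindex = None
    identities: list[float] = []
    for contig, seq in genome_a.contigs.items():
        bseq = genome_b.contigs.get(contig)
        for start in range(0, len(seq) - fragment + 1, fragment):
            frag = seq[start : start + fragment]
            best = 0.0
            if bseq is not None:
                window = bseq[max(0, start - margin) : start + fragment + margin]
                best = _identity(frag, window)
            if best < min_identity_to_count:
                if kindex is None:
                    kindex = _kmer_index(genome_b.contigs)
                best = max(best, _seeded_identity(frag, genome_b, kindex, margin))
            if best >= min_identity_to_count:
                identities.append(best)
    if not identities:
        return AniResult(("A", "B"), float("nan"), 0)
    return AniResult(("A", "B"), 100.0 * float(np.mean(identities)), len(identities))


def _seeded_identity(
    frag: str,
    genome_b: AnnotatedGenome,
    kindex: dict[str, list[tuple[str, int]]],
    margin: int,
    k: int = 16,
) -> float:
    best = 0.0
    seen: set[tuple[str, int]] = set()
    for off in range(0, len(frag) - k + 1, max(1, len(frag) // 4)):
        for name, hit in kindex.get(frag[off : off + k], ())[:8]:
            anchor = (name, (hit - off) // 100)
            if anchor in seen:
                continue
            seen.add(anchor)
            seq = genome_b.contigs[name]
            w0 = max(0, hit - off - margin)
            window = seq[w0 : hit - off + len(frag) + margin]
            best = max(best, _identity(frag, window))
    return best


def ani_matrix(
    genomes: Mapping[str, AnnotatedGenome], fragment: int = 1000
) -> pd.DataFrame:
    """Square ANI matrix (percent) over a set of labeled genomes."""
    names = list(genomes)
    mat = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            mat.iloc[i, j] = ani(genomes[a], genomes[b], fragment=fragment).ani_percent
    return mat


def assign_fecal_site(
    distances: Mapping[str, SnpDistance],
) -> tuple[Optional[str], bool]:
    """Site whose genome the fecal reads match best (fewest total SNPs).

    Returns (site, ambiguous); ties are reported as ambiguous with no
    winner rather than broken arbitrarily.
    """
    if not distances:
        return None, False
    totals = {site: d.total_snps for site, d in distances.items()}
    best = min(totals.values())
    winners = [s for s, t in totals.items() if t == best]
    if len(winners) > 1:
        return None, True
    return winners[0], False
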