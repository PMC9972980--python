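"""Selection-regime analysis: dN/dS, fixed mutations, divergence time,
and ciprofloxacin-resistance genotyping.

The dN/dS estimator operates on a *quasi-coding sequence*: the codons
holding each filtered coding SNP are concatenated, once with the
reference allele and once with the variant allele, giving a pair of
aligned codon strings that differ at exactly one base per codon.
Synonymous/nonsynonymous sites and differences are then counted in the
Nei-Gojobori (1986) style with equal mutation-path weighting; because
every codon pair differs at a single position, no multiple-hit
correction is needed.  omega = (Nd/N) / (Sd/S): below 1 indicates
purifying selection, near 1 neutrality, above 1 positive selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

from .genome import BASES, CODON_TO_AA, AnnotatedGenome, GenomeError, complement
from .variants import SnpCall

QUASI_MIN_DEPTH = 10
QUASI_MIN_VAF = 0.50
FIXED_VAF = 0.80
DEFAULT_MU = 7e-7  # substitutions per base per year (enteric bacteria scale)

#: wild-type residues of the quinolone-resistance-determining region,
#: E. coli numbering; substitutions at all three confer full
#: ciprofloxacin resistance.
QRDR_WILDTYPE: dict[str, dict[int, str]] = {
    "gyrA": {83: "S", 87: "D"},
    "parC": {80: "S"},
}


class SelectionError(ValueError):
    pass


@dataclass
class QuasiCds:
    """Aligned reference/variant codon strings from filtered coding SNPs."""

    ref_seq: str
    var_seq: str
    snp_index: list[SnpCall]

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.var_seq) or len(self.ref_seq) % 3:
            raise SelectionError("quasi-CDS strings must be equal, codon-aligned")

    @property
    def n_codons(self) -> int:
        return len(self.ref_seq) // 3


@dataclass
class SelectionSummary:
    Sd: float  # observed synonymous differences
    Nd: float  # observed nonsynonymous differences
    S: float  # expected synonymous sites
    N: float  # expected nonsynonymous sites
    omega: float  # NaN when undefined (Sd == 0)
    interpretation: Optional[str]  # purifying | neutral | positive


@dataclass
class DivergenceEstimate:
    fixed_mutations: int
    genome_size: int
    mu: float
    per_genome_rate: float  # mutations per genome per year
    years: float


@dataclass
class ResistanceGenotype:
    gyrA_codon83: str
    gyrA_codon87: str
    parC_codon80: str
    n_resistance_mutations: int
    category: str  # sensitive | partial | resistant


# ----------------------------------------------------------------------


def build_quasi_cds(
    calls: list[SnpCall],
    genome: AnnotatedGenome,
    min_mean_depth: int = QUASI_MIN_DEPTH,
    min_vaf: float = QUASI_MIN_VAF,
) -> QuasiCds:
    """Concatenate the codons of filtered coding SNPs.

    Only coding SNPs with depth >= ``min_mean_depth`` and variant allele
    fraction >= ``min_vaf`` contribute; each contributes its reference
    codon and the codon with the variant base substituted, in genome
    order.  Calls lacking gene context (unannotated or intergenic) are
    skipped.
    """
    ref_parts: list[str] = []
    var_parts: list[str] = []
    kept: list[SnpCall] = []
    for call in sorted(calls, key=lambda c: (c.contig, c.pos)):
        if call.region != "coding":
            continue
        if call.depth < min_mean_depth or call.vaf < min_vaf:
            continue
        gene = genome.gene_at(call.contig, call.pos)
        if gene is None:
            continue
        codon, off = genome.codon_context(gene, call.contig, call.pos)
        alt = call.alt if gene.strand == "+" else complement(call.alt)
        var_codon = codon[:off] + alt + codon[off + 1 :]
        ref_parts.append(codon)
        var_parts.append(var_codon)
        kept.append(call)
    return QuasiCds("".join(ref_parts), "".join(var_parts), kept)


def _site_counts(codon: str) -> tuple[float, float]:
    """Expected synonymous/nonsynonymous sites of one codon.

    Each of the nine single-base mutation paths carries weight 1/3;
    paths producing a stop codon are excluded from both counts.
    """
    aa = CODON_TO_AA[codon]
    s = n = 0.0
    for i, ref_base in enumerate(codon):
        for b in BASES:
            if b == ref_base:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            mut_aa = CODON_TO_AA[mut]
            if mut_aa == "*":
                continue
            if mut_aa == aa:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def dnds(q: QuasiCds) -> SelectionSummary:
    """Counting dN/dS on a quasi-coding sequence.

    Expected sites are computed on the reference codons only (each
    codon pair differs by a single base, so averaging ref and variant
    site counts would change nothing material).  When no synonymous
    difference is observed, omega is undefined (NaN) and no
    interpretation is given.
    """
    if q.n_codons == 0:
        raise SelectionError("empty quasi-coding sequence")
    S = N = Sd = Nd = 0.0
    for i in range(q.n_codons):
        rc = q.ref_seq[3 * i : 3 * i + 3]
        vc = q.var_seq[3 * i : 3 * i + 3]
        s, n = _site_counts(rc)
        S += s
        N += n
        if rc != vc:
            if CODON_TO_AA[vc] == CODON_TO_AA[rc]:
                Sd += 1
            else:
                Nd += 1  # includes nonsense changes
    if Sd == 0:
        return SelectionSummary(Sd, Nd, S, N, math.nan, None)
    omega = (Nd / N) / (Sd / S)
    if omega < 1:
        interp = "purifying"
    elif omega > 1:
        interp = "positive"
    else:
        interp = "neutral"
    return SelectionSummary(Sd, Nd, S, N, omega, interp)


def fixed_mutations(
    calls: list[SnpCall], threshold: float = FIXED_VAF
) -> list[SnpCall]:
    """Fixed / near-fixed mutations: vaf >= threshold, coding and intergenic."""
    return [c for c in calls if c.vaf >= threshold]


def divergence_time(
    m: int, genome_size: int, mu: float = DEFAULT_MU
) -> DivergenceEstimate:
    """Years of divergence implied by ``m`` fixed mutations.

    With a per-base rate ``mu`` (default 7e-7 per base per year) a
    genome of G bases accumulates mu*G mutations per year, so m fixed
    mutations correspond to m / (mu*G) years.
    """
    if m < 0:
        raise SelectionError("fixed-mutation count must be non-negative")
    if genome_size <= 0 or mu <= 0:
        raise SelectionError("genome size and mutation rate must be positive")
    rate = mu * genome_size
    return DivergenceEstimate(m, genome_size, mu, rate, m / rate)


def resistance_genotype(
    genome: AnnotatedGenome,
    gyrA_id: str,
    parC_id: str,
    wildtype: Mapping[str, Mapping[int, str]] = QRDR_WILDTYPE,
) -> ResistanceGenotype:
    """Type the ciprofloxacin QRDR positions of gyrA and parC.

    Translates both genes and compares gyrA residues 83/87 and parC
    residue 80 (1-based protein numbering) against the wild-type
    Ser83/Asp87/Ser80.  Three substituted positions give full
    resistance, zero sensitivity, anything else partial resistance.
    The ``wildtype`` map can be overridden for other species/numbering.
    """
    residues: dict[tuple[str, int], str] = {}
    for gene_name, gene_id in (("gyrA", gyrA_id), ("parC", parC_id)):
        protein = genome.translate_gene(gene_id)
        for codon_no in wildtype[gene_name]:
            if codon_no > len(protein):
                raise SelectionError(
                    f"{gene_name} shorter than codon {codon_no}"
                )
            residues[(gene_name, codon_no)] = protein[codon_no - 1]
    n_mut = sum(
        residues[(g, c)] != wt
        for g, codons in wildtype.items()
        for c, wt in codons.items()
    )
    n_positions = sum(len(c) for c in wildtype.values())
    if n_mut == n_positions:
        category = "resistant"
    elif n_mut == 0:
        category = "sensitive"
    else:
        category = "partial"
    return ResistanceGenotype(
        gyrA_codon83=residues[("gyrA", 83)] if ("gyrA", 83) in residues else "?",
        gyrA_codon87=residues[("gyrA", 87)] if ("gyrA", 87) in residues else "?",
        parC_codon80=residues[("parC", 80)] if ("parC", 80) in residues else "?",
        n_resistance_mutations=n_mut,
        category=category,
    )
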