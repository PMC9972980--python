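"""Synthetic founder-diversification data with full ground truth.

The generator emulates the study design the rest of the package
analyzes: one founder strain of a gut bacterium colonizes several
intestinal sites (terminal ileum, cecum, descending colon, plus feces)
and accumulates substitutions independently at each site on top of a
set of pre-split shared changes.  Optionally a minor co-resident
lineage segregates at 20-50% allele frequency with one SNP set shared
identically across all sites, and whole genes can be deleted per
individual (gene content differs between, not within, individuals).

Per-site observables are a pileup table (per-position depth and A/C/G/T
counts, with a bidirectional origin->terminus replication gradient,
Poisson depth noise and uniform base-call error) and a mapped-read
summary (intervals plus mismatch counts).  Every implanted change is
recorded in a :class:`TruthBundle` so estimators can be scored against
truth.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .genome import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    AnnotatedGenome,
    Gene,
    revcomp,
)
from .pileup import COLUMNS as PILEUP_COLUMNS
from .pileup import PileupTable

DEFAULT_SITES = ("TI", "cecum", "DC", "feces")
LUMEN_SITES = ("TI", "cecum", "DC")

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


class ScenarioError(ValueError):
    """Invalid simulation parameters."""


@dataclass
class SimScenario:
    """Parameter set for one simulated individual.

    Defaults are scaled-down but structurally faithful study conditions:
    a ~100 kb genome standing in for a MAG, ~85% coding, tens of fixed
    substitutions per site (a few years of within-host divergence at
    ~7e-7 per base per year), dN/dS 0.2 (strong purifying selection), a
    minor lineage at 30% frequency with 25 shared SNPs, an E. coli-scale
    replication gradient (PTR 1.46) and ~0.2% base-call error.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_contigs: int = 2
    gene_fraction: float = 0.85
    mean_gene_length: int = 900
    sites: tuple[str, ...] = DEFAULT_SITES
    per_site_substitutions: int = 20
    shared_substitutions: int = 10
    omega_true: float = 0.2
    minor_lineage_freq: float = 0.3
    minor_lineage_snps: int = 25
    ptr_true: float = 1.46
    mean_depth: float = 50.0
    error_rate: float = 0.002
    deleted_genes_per_individual: int = 0
    read_length: int = 100
    species_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ScenarioError("genome_length must be positive")
        if self.n_contigs < 1:
            raise ScenarioError("n_contigs must be >= 1")
        if not 0 <= self.gene_fraction < 1:
            raise ScenarioError("gene_fraction must be in [0, 1)")
        if self.mean_gene_length > self.genome_length:
            raise ScenarioError("mean_gene_length exceeds genome_length")
        if not 0 <= self.minor_lineage_freq <= 0.5:
            raise ScenarioError("minor_lineage_freq must be in [0, 0.5]")
        if self.ptr_true < 1:
            raise ScenarioError("ptr_true must be >= 1")
        if not 0 <= self.error_rate < 0.25:
            raise ScenarioError("error_rate must be in [0, 0.25)")
        if self.mean_depth <= 0:
            raise ScenarioError("mean_depth must be positive")
        for name in (
            "per_site_substitutions",
            "shared_substitutions",
            "minor_lineage_snps",
            "deleted_genes_per_individual",
        ):
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be non-negative")
        if not 0 < self.species_fraction <= 1:
            raise ScenarioError("species_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ImplantedSnp:
    """Ground-truth record for one implanted substitution."""

    contig: str
    pos: int
    ref: str
    alt: str
    sites: tuple[str, ...]
    lineage: str  # 'major' or 'minor'
    region: str
    gene_id: Optional[str]
    effect: str


@dataclass
class TruthBundle:
    """Everything the simulator knows that an analyst would not."""

    founder: AnnotatedGenome
    site_genomes: dict[str, AnnotatedGenome]
    implanted_snps: list[ImplantedSnp]
    minor_lineage_positions: list[tuple[str, int, str]]  # (contig, pos, alt)
    deleted_gene_ids: list[str]
    ptr_true: dict[str, float]
    omega_true: float
    origin: tuple[str, int]
    terminus: tuple[str, int]

    def major_snps(self, site: str) -> list[ImplantedSnp]:
        return [
            s for s in self.implanted_snps
            if s.lineage == "major" and site in s.sites
        ]

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "implanted_snps": [asdict(s) for s in self.implanted_snps],
            "minor_lineage_positions": self.minor_lineage_positions,
            "deleted_gene_ids": self.deleted_gene_ids,
            "ptr_true": self.ptr_true,
            "omega_true": self.omega_true,
            "origin": self.origin,
            "terminus": self.terminus,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ----------------------------------------------------------------------
# founder generation


def _draw_gene_length(rng: np.random.Generator, mean: int) -> int:
    codons = max(30, int(round(rng.normal(mean, mean / 6.0))) // 3)
    return 3 * codons


def generate_founder(scenario: SimScenario) -> AnnotatedGenome:
    """Build a random founder genome with non-overlapping ORFs.

    Genes alternate with intergenic gaps along each contig; each gene is
    a complete open reading frame (ATG start, sense codons, one stop),
    placed on a random strand, and gene bases cover approximately
    ``gene_fraction`` of the genome.  Deterministic for a fixed seed.
    """
    if scenario.gene_fraction >= 1:
        raise ScenarioError("gene_fraction must be < 1")
    rng = np.random.default_rng([scenario.seed, 11])
    L, n = scenario.genome_length, scenario.n_contigs
    lengths = [L // n + (1 if i < L % n else 0) for i in range(n)]

    contigs: dict[str, str] = {}
    genes: list[Gene] = []
    gidx = 0
    f = scenario.gene_fraction
    mean_gap = scenario.mean_gene_length * (1 - f) / f if f > 0 else 0.0

    for ci, clen in enumerate(lengths):
        name = f"contig_{ci + 1}"
        if f == 0:
            contigs[name] = "".join(
                np.array(list(BASES))[rng.integers(0, 4, clen)]
            )
            continue
        parts: list[str] = []
        pos = 0
        while True:
            gap = max(2, int(round(rng.gamma(4.0, mean_gap / 4.0))))
            glen = _draw_gene_length(rng, scenario.mean_gene_length)
            if pos + gap + glen > clen:
                parts.append(
                    "".join(np.array(list(BASES))[rng.integers(0, 4, clen - pos)])
                )
                break
            parts.append("".join(np.array(list(BASES))[rng.integers(0, 4, gap)]))
            n_internal = glen // 3 - 2
            body = "".join(
                SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_internal)
            )
            orf = "ATG" + body + STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(orf if strand == "+" else revcomp(orf))
            gidx += 1
            genes.append(
                Gene(f"gene_{gidx:05d}", name, pos + gap, pos + gap + glen, strand)
            )
            pos += gap + glen
        contigs[name] = "".join(parts)

    return AnnotatedGenome(contigs, genes)


# ----------------------------------------------------------------------
# diversification


def _flat_to_coord(genome: AnnotatedGenome, flat: int) -> tuple[str, int]:
    for name, seq in genome.contigs.items():
        if flat < len(seq):
            return name, flat
        flat -= len(seq)
    raise ValueError("flat position outside genome")


def _draw_substitution(
    genome: AnnotatedGenome,
    rng: np.random.Generator,
    used: set[tuple[str, int]],
    omega: float,
    max_attempts: int = 2_000_000,
) -> tuple[str, int, str, str, str, Optional[str], str]:
    """Draw one accepted substitution.

    Candidates are uniform over (position, alternative base).  Changes
    that would create a premature stop are always rejected; under
    purifying regimes (omega < 1) nonsynonymous candidates are accepted
    with probability omega, under positive regimes (omega > 1)
    synonymous candidates are accepted with probability 1/omega, so the
    realized substitution spectrum targets the requested dN/dS.
    """
    L = genome.length
    for _ in range(max_attempts):
        contig, pos = _flat_to_coord(genome, int(rng.integers(L)))
        if (contig, pos) in used:
            continue
        ref = genome.base(contig, pos)
        alts = [b for b in BASES if b != ref]
        alt = alts[int(rng.integers(3))]
        region, gene_id, effect = genome.classify_substitution(contig, pos, alt)
        if effect == "nonsense":
            continue
        if effect == "nonsynonymous" and omega < 1 and rng.random() >= omega:
            continue
        if effect == "synonymous" and omega > 1 and rng.random() >= 1.0 / omega:
            continue
        used.add((contig, pos))
        return contig, pos, ref, alt, region, gene_id, effect
    raise ScenarioError("could not place substitution (genome saturated?)")


def _apply_snps(
    genome: AnnotatedGenome, snps: list[ImplantedSnp]
) -> AnnotatedGenome:
    muts: dict[str, list[tuple[int, str]]] = {}
    for s in snps:
        muts.setdefault(s.contig, []).append((s.pos, s.alt))
    contigs = {}
    for name, seq in genome.contigs.items():
        if name in muts:
            arr = bytearray(seq, "ascii")
            for pos, alt in muts[name]:
                arr[pos] = ord(alt)
            contigs[name] = arr.decode("ascii")
        else:
            contigs[name] = seq
    return AnnotatedGenome(contigs, genome.genes)


def diversify(founder: AnnotatedGenome, scenario: SimScenario) -> TruthBundle:
    """Evolve the founder independently at each site.

    Each site genome is founder + shared (pre-split) substitutions +
    site-private substitutions.  Minor-lineage SNPs are drawn at
    positions untouched by the major lineage and are never applied to
    the site genomes — the minor lineage exists only in the read pools.
    """
    sites = list(scenario.sites)
    n_minor = scenario.minor_lineage_snps if scenario.minor_lineage_freq > 0 else 0
    needed = (
        scenario.shared_substitutions
        + scenario.per_site_substitutions * len(sites)
        + n_minor
    )
    if needed > founder.length:
        raise ScenarioError("requested substitutions exceed genome size")

    rng = np.random.default_rng([scenario.seed, 23])
    used: set[tuple[str, int]] = set()
    snps: list[ImplantedSnp] = []

    for _ in range(scenario.shared_substitutions):
        c, p, r, a, reg, gid, eff = _draw_substitution(
            founder, rng, used, scenario.omega_true
        )
        snps.append(ImplantedSnp(c, p, r, a, tuple(sites), "major", reg, gid, eff))
    for site in sites:
        for _ in range(scenario.per_site_substitutions):
            c, p, r, a, reg, gid, eff = _draw_substitution(
                founder, rng, used, scenario.omega_true
            )
            snps.append(ImplantedSnp(c, p, r, a, (site,), "major", reg, gid, eff))
    minor_positions: list[tuple[str, int, str]] = []
    for _ in range(n_minor):
        c, p, r, a, reg, gid, eff = _draw_substitution(
            founder, rng, used, scenario.omega_true
        )
        snps.append(ImplantedSnp(c, p, r, a, tuple(sites), "minor", reg, gid, eff))
        minor_positions.append((c, p, a))

    site_genomes = {
        site: _apply_snps(
            founder,
            [s for s in snps if s.lineage == "major" and site in s.sites],
        )
        for site in sites
    }

    deleted: list[str] = []
    if scenario.deleted_genes_per_individual:
        if scenario.deleted_genes_per_individual > len(founder.genes):
            raise ScenarioError("more deletions requested than genes exist")
        pick = rng.choice(
            len(founder.genes), scenario.deleted_genes_per_individual, replace=False
        )
        deleted = sorted(founder.genes[i].gene_id for i in pick)

    offsets = founder.contig_offsets()
    half = founder.length // 2
    terminus = _flat_to_coord(founder, half)
    first_contig = next(iter(founder.contigs))
    del offsets  # origin/terminus fixed by convention below

    return TruthBundle(
        founder=founder,
        site_genomes=site_genomes,
        implanted_snps=snps,
        minor_lineage_positions=minor_positions,
        deleted_gene_ids=deleted,
        ptr_true={site: float(scenario.ptr_true) for site in sites},
        omega_true=scenario.omega_true,
        origin=(first_contig, 0),
        terminus=terminus,
    )


# ----------------------------------------------------------------------
# pileups and reads


def _expected_depth(L: int, ptr: float, mean_depth: float) -> np.ndarray:
    """Per-position coverage expectation under bidirectional replication.

    log2 coverage interpolates linearly from log2(ptr * d_ter) at the
    origin (position 0) to log2(d_ter) at the terminus (genome
    midpoint), symmetrically on both replichores; d_ter is chosen so the
    genome-wide mean equals ``mean_depth``.
    """
    x = np.arange(L)
    u = np.minimum(x, L - x) / (L / 2.0)  # 0 at origin, 1 at terminus
    if ptr == 1.0:
        return np.full(L, mean_depth)
    d_ter = mean_depth * np.log(ptr) / (ptr - 1.0)
    return d_ter * np.power(ptr, 1.0 - u)


def _deleted_mask(genome: AnnotatedGenome, deleted: list[str]) -> np.ndarray:
    offsets = genome.contig_offsets()
    mask = np.zeros(genome.length, dtype=bool)
    wanted = set(deleted)
    for g in genome.genes:
        if g.gene_id in wanted:
            off = offsets[g.contig]
            mask[off + g.start : off + g.end] = True
    return mask


def _flat_bases(genome: AnnotatedGenome) -> np.ndarray:
    cat = "".join(genome.contigs.values())
    arr = np.frombuffer(cat.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for b, i in _BASE_IDX.items():
        lut[ord(b)] = i
    return lut[arr]


def simulate_pileups(
    truth: TruthBundle,
    scenario: SimScenario,
    reference: AnnotatedGenome | None = None,
) -> dict[str, PileupTable]:
    """Simulate a per-site pileup table against ``reference``.

    Depth is Poisson around the replication-gradient expectation; read
    bases mix the major lineage (1 - minor_lineage_freq), the minor
    lineage (minor_lineage_freq) and uniform miscalls (error_rate).  The
    ``ref`` column reports the reference genome's base (default: the
    founder, playing the role of the assembled MAG).
    """
    if scenario.mean_depth <= 0:
        raise ScenarioError("mean_depth must be positive")
    ref_genome = reference if reference is not None else truth.founder
    L = truth.founder.length
    offsets = truth.founder.contig_offsets()
    ref_flat = _flat_bases(ref_genome)
    minor_flat = _flat_bases(truth.founder).copy()
    for contig, pos, alt in truth.minor_lineage_positions:
        minor_flat[offsets[contig] + pos] = _BASE_IDX[alt]
    del_mask = _deleted_mask(truth.founder, truth.deleted_gene_ids)

    contig_names = np.concatenate(
        [np.full(len(seq), name, dtype=object) for name, seq in truth.founder.contigs.items()]
    )
    contig_pos = np.concatenate(
        [np.arange(len(seq)) for seq in truth.founder.contigs.values()]
    )
    ref_col = np.array(list(BASES))[ref_flat]

    f = scenario.minor_lineage_freq
    err = scenario.error_rate
    out: dict[str, PileupTable] = {}
    for k, site in enumerate(scenario.sites):
        rng = np.random.default_rng([scenario.seed, 37, k])
        mu = _expected_depth(L, truth.ptr_true[site], scenario.mean_depth)
        depth = rng.poisson(mu)
        depth[del_mask] = 0

        major_flat = _flat_bases(truth.site_genomes[site])
        p_true = np.zeros((L, 4))
        p_true[np.arange(L), major_flat] += 1.0 - f
        p_true[np.arange(L), minor_flat] += f
        p_call = p_true * (1.0 - err) + (1.0 - p_true) * (err / 3.0)
        counts = rng.multinomial(depth, p_call)

        df = pd.DataFrame(
            {
                "contig": contig_names,
                "pos": contig_pos,
                "ref": ref_col,
                "depth": depth,
                "A": counts[:, 0],
                "C": counts[:, 1],
                "G": counts[:, 2],
                "T": counts[:, 3],
            }
        )
        out[site] = PileupTable(df, validate=False)
    return out


def simulate_reads(
    truth: TruthBundle, scenario: SimScenario
) -> dict[str, tuple[pd.DataFrame, int]]:
    """Simulate mapped-read summaries per site.

    Each row is one read mapped to the founder reference: id, contig,
    half-open interval, and mismatch count (implanted differences within
    the interval plus binomial sequencing errors).  Returns, per site,
    the DataFrame plus the sample's total read count (mapped reads are a
    ``species_fraction`` of the whole metagenome).
    """
    L = truth.founder.length
    rl = scenario.read_length
    offsets = truth.founder.contig_offsets()
    lens = {name: len(seq) for name, seq in truth.founder.contigs.items()}
    names = list(truth.founder.contigs)
    starts_all = np.array([offsets[n] for n in names])
    del_mask = _deleted_mask(truth.founder, truth.deleted_gene_ids)
    del_cum = np.concatenate([[0], np.cumsum(del_mask)])

    ref_flat = _flat_bases(truth.founder)
    n_reads_target = int(round(L * scenario.mean_depth / rl))
    out: dict[str, tuple[pd.DataFrame, int]] = {}
    for k, site in enumerate(scenario.sites):
        rng = np.random.default_rng([scenario.seed, 53, k])
        diff_flat = (_flat_bases(truth.site_genomes[site]) != ref_flat)
        diff_cum = np.concatenate([[0], np.cumsum(diff_flat)])

        # oversample, then drop reads crossing contig ends or deletions
        cand = rng.integers(0, L - rl + 1, int(n_reads_target * 1.4) + 100)
        ci = np.searchsorted(starts_all, cand, side="right") - 1
        contig_end = starts_all[ci] + np.array([lens[names[i]] for i in ci])
        ok = cand + rl <= contig_end
        ok &= (del_cum[cand + rl] - del_cum[cand]) == 0
        cand = cand[ok][:n_reads_target]
        ci = ci[ok][:n_reads_target]

        mism = (diff_cum[cand + rl] - diff_cum[cand]).astype(int)
        mism += rng.binomial(rl, scenario.error_rate, cand.size)
        df = pd.DataFrame(
            {
                "read_id": [f"{site}_read_{i}" for i in range(cand.size)],
                "contig": [names[i] for i in ci],
                "start": cand - starts_all[ci],
                "end": cand - starts_all[ci] + rl,
                "mismatches": mism,
            }
        )
        total = int(round(cand.size / scenario.species_fraction))
        out[site] = (df, total)
    return out


def write_read_summary(
    df: pd.DataFrame, total_reads: int, path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# total_reads={total_reads}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_read_summary(path: str | os.PathLike) -> tuple[pd.DataFrame, Optional[int]]:
    total = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# total_reads="):
            total = int(first.strip().split("=", 1)[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    return df, total


# ----------------------------------------------------------------------
# convenience wrappers


def mutate_genome(
    genome: AnnotatedGenome, rate: float, seed: int
) -> tuple[AnnotatedGenome, int]:
    """Apply an exact count of round(rate * length) random substitutions.

    Positions are drawn without replacement and no coding constraint is
    applied; used to calibrate identity-based comparisons (e.g. ANI
    versus substitution rate).
    """
    rng = np.random.default_rng([seed, 71])
    L = genome.length
    n = int(round(rate * L))
    flat = rng.choice(L, size=n, replace=False)
    snps = []
    for fp in sorted(int(x) for x in flat):
        contig, pos = _flat_to_coord(genome, fp)
        ref = genome.base(contig, pos)
        alt = [b for b in BASES if b != ref][int(rng.integers(3))]
        snps.append(
            ImplantedSnp(contig, pos, ref, alt, (), "major", "unknown", None, "unknown")
        )
    return _apply_snps(genome, snps), n


@dataclass
class SimulatedIndividual:
    scenario: SimScenario
    truth: TruthBundle
    pileups: dict[str, PileupTable]
    reads: dict[str, tuple[pd.DataFrame, int]]


def simulate_individual(scenario: SimScenario) -> SimulatedIndividual:
    """Founder -> diversified sites -> pileups and read summaries."""
    founder = generate_founder(scenario)
    truth = diversify(founder, scenario)
    pileups = simulate_pileups(truth, scenario)
    reads = simulate_reads(truth, scenario)
    return SimulatedIndividual(scenario, truth, pileups, reads)


def write_individual(ind: SimulatedIndividual, outdir: str | os.PathLike) -> None:
    """Emit FASTA/GFF3/BED genomes, TSV pileups and read summaries, truth JSON."""
    os.makedirs(outdir, exist_ok=True)
    ind.truth.founder.to_fasta(os.path.join(outdir, "founder.fa"))
    ind.truth.founder.to_gff3(os.path.join(outdir, "founder.gff3"))
    ind.truth.founder.to_bed(os.path.join(outdir, "founder.bed"))
    for site, genome in ind.truth.site_genomes.items():
        genome.to_fasta(os.path.join(outdir, f"{site}.fa"))
    for site, pt in ind.pileups.items():
        pt.to_tsv(os.path.join(outdir, f"{site}.pileup.tsv"))
    for site, (df, total) in ind.reads.items():
        write_read_summary(df, total, os.path.join(outdir, f"{site}.reads.tsv"))
    ind.truth.to_json(os.path.join(outdir, "truth.json"))
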