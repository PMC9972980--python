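"""Reference genomes with gene annotations.

An :class:`AnnotatedGenome` bundles contig sequences with non-overlapping
gene intervals and is the coordinate frame for every downstream analysis:
variant calling, effect annotation, gene-level read counting and
resistance genotyping all resolve positions against it.

Coordinates are 0-based, half-open internally.  Emitted GFF3 and BED use
their native conventions (1-based inclusive and 0-based half-open,
respectively).  Translation uses the bacterial/archaeal code
(translation table 11).
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_TABLE11 = unambiguous_dna_by_id[11]
#: codon -> one-letter amino acid, stop codons mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE11.stop_codons})

STOP_CODONS = tuple(_TABLE11.stop_codons)
SENSE_CODONS = tuple(sorted(set(CODON_TO_AA) - set(STOP_CODONS)))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


class GenomeError(ValueError):
    """Raised for positions or genes that do not fit the genome."""


@dataclass(frozen=True)
class Gene:
    """One coding gene: a half-open interval [start, end) on a contig."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise GenomeError(f"empty interval for {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


class AnnotatedGenome:
    """Contig sequences plus an ordered set of non-overlapping genes.

    Parameters
    ----------
    contigs
        Mapping of contig name to uppercase DNA sequence.  Insertion
        order defines the genomic (concatenated) coordinate used by the
        replication-gradient machinery.
    genes
        Gene intervals.  Genes on the same contig must not overlap.
    """

    def __init__(self, contigs: dict[str, str], genes: Iterable[Gene] = ()):
        self.contigs: dict[str, str] = {k: v.upper() for k, v in contigs.items()}
        self.genes: list[Gene] = sorted(genes, key=lambda g: (g.contig, g.start))
        self._index: dict[str, tuple[list[int], list[int], list[Gene]]] = {}
        for g in self.genes:
            if g.contig not in self.contigs:
                raise GenomeError(f"gene {g.gene_id} on unknown contig {g.contig}")
            if g.end > len(self.contigs[g.contig]):
                raise GenomeError(f"gene {g.gene_id} extends past contig end")
            starts, ends, glist = self._index.setdefault(g.contig, ([], [], []))
            if starts and g.start < ends[-1]:
                raise GenomeError(f"gene {g.gene_id} overlaps {glist[-1].gene_id}")
            starts.append(g.start)
            ends.append(g.end)
            glist.append(g)

    # ------------------------------------------------------------------
    # basic queries

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def contig_offsets(self) -> dict[str, int]:
        """Start of each contig in the concatenated genomic coordinate."""
        offsets, cum = {}, 0
        for name, seq in self.contigs.items():
            offsets[name] = cum
            cum += len(seq)
        return offsets

    def base(self, contig: str, pos: int) -> str:
        seq = self.contigs.get(contig)
        if seq is None or not 0 <= pos < len(seq):
            raise GenomeError(f"position {contig}:{pos} outside the genome")
        return seq[pos]

    def gene_at(self, contig: str, pos: int) -> Optional[Gene]:
        """Gene covering ``pos`` on ``contig``, or None if intergenic."""
        idx = self._index.get(contig)
        if idx is None:
            return None
        starts, ends, glist = idx
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return glist[i]
        return None

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise GenomeError(f"no gene named {gene_id}")

    def gene_sequence(self, gene: Gene | str) -> str:
        """Coding-strand sequence of a gene (5'->3' of its ORF)."""
        if isinstance(gene, str):
            gene = self.gene(gene)
        raw = self.contigs[gene.contig][gene.start : gene.end]
        return raw if gene.strand == "+" else revcomp(raw)

    def translate_gene(self, gene: Gene | str) -> str:
        return str(Seq(self.gene_sequence(gene)).translate(table=11))

    # ------------------------------------------------------------------
    # codon context and substitution effects

    def codon_context(self, gene: Gene, contig: str, pos: int) -> tuple[str, int]:
        """Reference codon containing ``pos`` and the within-codon offset.

        Both are expressed in the gene's reading orientation: offset 0 is
        the first base of the codon as translated.
        """
        if gene.contig != contig or not gene.start <= pos < gene.end:
            raise GenomeError(f"{contig}:{pos} not inside {gene.gene_id}")
        seq = self.contigs[contig]
        if gene.strand == "+":
            i = pos - gene.start
            ci, off = divmod(i, 3)
            codon = seq[gene.start + 3 * ci : gene.start + 3 * ci + 3]
        else:
            i = gene.end - 1 - pos
            ci, off = divmod(i, 3)
            codon = revcomp(seq[gene.end - 3 * ci - 3 : gene.end - 3 * ci])
        return codon, off

    def classify_substitution(
        self, contig: str, pos: int, alt: str
    ) -> tuple[str, Optional[str], str]:
        """Classify a single-base substitution.

        Returns ``(region, gene_id, effect)`` where region is ``coding``
        or ``intergenic`` and effect is ``synonymous``, ``nonsynonymous``,
        ``nonsense`` (variant codon is a stop) or ``none`` (intergenic).
        """
        ref = self.base(contig, pos)
        if alt == ref:
            raise GenomeError(f"alt equals reference base at {contig}:{pos}")
        gene = self.gene_at(contig, pos)
        if gene is None:
            return "intergenic", None, "none"
        codon, off = self.codon_context(gene, contig, pos)
        alt_in_frame = alt if gene.strand == "+" else complement(alt)
        var_codon = codon[:off] + alt_in_frame + codon[off + 1 :]
        ref_aa = CODON_TO_AA[codon]
        var_aa = CODON_TO_AA[var_codon]
        if var_aa == ref_aa:
            effect = "synonymous"
        elif var_aa == "*":
            effect = "nonsense"
        else:
            effect = "nonsynonymous"
        return "coding", gene.gene_id, effect

    # ------------------------------------------------------------------
    # I/O

    def to_fasta(self, path: str | os.PathLike) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, os.fspath(path), "fasta")

    def to_gff3(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.contigs.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in self.genes:
                fh.write(
                    f"{g.contig}\tlumenstrain\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}\n"
                )

    def to_bed(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(
                    f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
                )

    @classmethod
    def from_files(
        cls, fasta: str | os.PathLike, gff3: str | os.PathLike | None = None
    ) -> "AnnotatedGenome":
        contigs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(os.fspath(fasta), "fasta")
        }
        genes: list[Gene] = []
        if gff3 is not None:
            with open(gff3) as fh:
                for line in fh:
                    if line.startswith("#") or not line.strip():
                        continue
                    f = line.rstrip("\n").split("\t")
                    if len(f) < 9 or f[2] not in ("CDS", "gene"):
                        continue
                    attrs = dict(
                        kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                    )
                    gid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
                    genes.append(Gene(gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
        return cls(contigs, genes)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AnnotatedGenome)
            and self.contigs == other.contigs
            and self.genes == other.genes
        )

    def __repr__(self) -> str:
        return (
            f"AnnotatedGenome({len(self.contigs)} contigs, "
            f"{self.length} bp, {len(self.genes)} genes)"
        )
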