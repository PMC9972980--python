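"""Per-position allele-count tables ("pileup tables").

The pileup table is the central per-sample input: for every reference
position it records depth and the A/C/G/T read counts of one sample's
reads mapped against one reference genome.  The native serialization is
a TSV with columns ``contig pos ref depth A C G T`` (``pos`` 0-based);
samtools-style ``mpileup`` text can be ingested as well.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

COLUMNS = ["contig", "pos", "ref", "depth", "A", "C", "G", "T"]


class PileupError(ValueError):
    """Malformed pileup input."""


class PileupTable:
    """Validated wrapper around a per-position allele-count DataFrame."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise PileupError(f"pileup table missing columns {missing}")
        self.df = df.reset_index(drop=True)[COLUMNS]
        if validate:
            self.validate()

    def validate(self) -> None:
        df = self.df
        counts = df[["A", "C", "G", "T"]].to_numpy()
        bad = np.flatnonzero(counts.sum(axis=1) != df["depth"].to_numpy())
        if bad.size:
            i = int(bad[0])
            raise PileupError(
                f"row {i} ({df.at[i, 'contig']}:{df.at[i, 'pos']}): "
                "allele counts do not sum to depth"
            )
        if not df["ref"].isin(list("ACGT")).all():
            i = int(np.flatnonzero(~df["ref"].isin(list("ACGT")))[0])
            raise PileupError(f"row {i}: reference base not in ACGT")
        if df.duplicated(["contig", "pos"]).any():
            raise PileupError("duplicate (contig, pos) rows")

    def __len__(self) -> int:
        return len(self.df)

    # ------------------------------------------------------------------

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "PileupTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df)

    @classmethod
    def from_samtools_pileup(cls, lines: Iterable[str] | str | os.PathLike) -> "PileupTable":
        """Parse ``samtools mpileup`` text (1-based positions).

        Read-base strings are decoded per the mpileup conventions:
        ``.``/``,`` count toward the reference, explicit bases toward
        themselves; mapping-start (``^`` + quality), read-end (``$``),
        indel runs (``+n``/``-n`` + bases) and deletion placeholders
        (``*``, ``<``, ``>``) are skipped.  Depth is recomputed from the
        decoded counts so the table invariant holds.
        """
        if isinstance(lines, (str, os.PathLike)) and os.path.exists(os.fspath(lines)):
            with open(lines) as fh:
                lines = fh.readlines()
        elif isinstance(lines, str):
            lines = lines.splitlines()
        rows = []
        for line in lines:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            contig, pos, ref, bases = f[0], int(f[1]) - 1, f[2].upper(), f[4]
            counts = dict.fromkeys("ACGT", 0)
            i = 0
            while i < len(bases):
                c = bases[i]
                if c == "^":
                    i += 2
                    continue
                if c == "$" or c in "*<>":
                    i += 1
                    continue
                if c in "+-":
                    j = i + 1
                    while j < len(bases) and bases[j].isdigit():
                        j += 1
                    i = j + int(bases[i + 1 : j])
                    continue
                if c in ".,":
                    if ref in counts:
                        counts[ref] += 1
                elif c.upper() in counts:
                    counts[c.upper()] += 1
                i += 1
            depth = sum(counts.values())
            rows.append(
                [contig, pos, ref, depth, counts["A"], counts["C"], counts["G"], counts["T"]]
            )
        return cls(pd.DataFrame(rows, columns=COLUMNS))

    # ------------------------------------------------------------------

    def depth_vector(self, contig_order: list[str] | None = None) -> np.ndarray:
        """Depths in genomic order over the concatenated contigs.

        Positions absent from the table get depth 0; the vector spans
        position 0 .. max recorded position of each contig.
        """
        order = contig_order or list(dict.fromkeys(self.df["contig"]))
        chunks = []
        for contig in order:
            sub = self.df[self.df["contig"] == contig]
            if sub.empty:
                continue
            n = int(sub["pos"].max()) + 1
            vec = np.zeros(n, dtype=float)
            vec[sub["pos"].to_numpy()] = sub["depth"].to_numpy()
            chunks.append(vec)
        if not chunks:
            return np.zeros(0)
        return np.concatenate(chunks)
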