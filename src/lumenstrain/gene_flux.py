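"""Gene gain/loss detection and gene-content dissimilarity.

Gene presence is read-count based: a gene is called missing from a
target sample when fewer than 3 of its reads map to the gene interval
while the reference sample has at least 10 there.  Content similarity
across samples is summarized by Jaccard distances on presence/absence,
ordinated by classical PCoA, and partitioned by a permutational
ANOVA (PERMANOVA) on the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .genome import AnnotatedGenome

MISSING_MAX_TARGET_READS = 3  # exclusive
MISSING_MIN_REFERENCE_READS = 10  # inclusive


class FluxError(ValueError):
    pass


@dataclass
class FluxCall:
    gene_id: str
    reference_sample: str
    target_sample: str
    status: str  # 'missing' | 'retained'


def gene_read_counts(
    reads: pd.DataFrame, genes: AnnotatedGenome, sample_id: str = "sample"
) -> pd.Series:
    """Count reads overlapping each gene interval (any overlap, once per gene).

    ``reads`` needs columns contig/start/end (half-open); unmapped rows
    (contig ``*``) are ignored.  A read spanning two genes increments
    both.
    """
    counts = np.zeros(len(genes.genes), dtype=int)
    gene_pos = {g.gene_id: i for i, g in enumerate(genes.genes)}
    by_contig: dict[str, list] = {}
    for g in genes.genes:
        by_contig.setdefault(g.contig, []).append(g)

    mapped = reads[reads["contig"] != "*"]
    for contig, sub in mapped.groupby("contig", sort=False):
        if contig not in genes.contigs:
            raise FluxError(f"reads mapped to unknown contig {contig}")
        clen = len(genes.contigs[contig])
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts < 0).any() or (ends > clen).any():
            raise FluxError(f"read interval beyond contig {contig} bounds")
        glist = by_contig.get(contig, [])
        if not glist:
            continue
        gstarts = np.array([g.start for g in glist])
        gends = np.array([g.end for g in glist])
        lo = np.searchsorted(gends, starts, side="right")
        hi = np.searchsorted(gstarts, ends, side="left")
        # each read covers the gene run [lo, hi); accumulate via diff array
        diff = np.zeros(len(glist) + 1, dtype=int)
        valid = hi > lo
        np.add.at(diff, lo[valid], 1)
        np.add.at(diff, hi[valid], -1)
        per_gene = np.cumsum(diff[:-1])
        for g, c in zip(glist, per_gene):
            counts[gene_pos[g.gene_id]] = c
    return pd.Series(counts, index=[g.gene_id for g in genes.genes], name=sample_id)


def detect_flux(
    table: pd.DataFrame,
    reference_sample: str,
    target_sample: str,
    max_target: int = MISSING_MAX_TARGET_READS,
    min_reference: int = MISSING_MIN_REFERENCE_READS,
) -> list[FluxCall]:
    """Per-gene missing/retained status of target relative to reference."""
    for s in (reference_sample, target_sample):
        if s not in table.columns:
            raise FluxError(f"unknown sample {s!r}")
    ref = table[reference_sample]
    tgt = table[target_sample]
    out = []
    for gene_id in table.index:
        missing = tgt[gene_id] < max_target and ref[gene_id] >= min_reference
        out.append(
            FluxCall(gene_id, reference_sample, target_sample,
                     "missing" if missing else "retained")
        )
    return out


def presence_matrix(
    table: pd.DataFrame, min_reads: int = MISSING_MIN_REFERENCE_READS
) -> pd.DataFrame:
    """Boolean gene x sample presence from a read-count table."""
    return table >= min_reads


def jaccard_matrix(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances between sample columns.

    d(i, j) = 1 - |intersection| / |union| of the present-gene sets.
    Pairs involving a sample with no present genes are NaN (undefined).
    """
    if presence.shape[1] < 2:
        raise FluxError("need at least two samples")
    x = presence.to_numpy(dtype=bool).T
    with np.errstate(invalid="ignore"):
        dm = squareform(pdist(x, metric="jaccard"))
    empty = ~x.any(axis=1)
    dm[empty, :] = np.nan
    dm[:, empty] = np.nan
    np.fill_diagonal(dm, 0.0)
    return pd.DataFrame(dm, index=presence.columns, columns=presence.columns)


# ----------------------------------------------------------------------
# PERMANOVA (distance-based pseudo-F permutation test)


@dataclass
class PermanovaResult:
    r2: float
    p_value: float
    f_stat: float
    permutations: int


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R2 from squared distances and integer group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups: Mapping[str, str] | pd.Series | list,
    permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    R2 = SS_between / SS_total from the standard distance-based sum of
    squares decomposition; the p-value is the permutation tail
    probability of the pseudo-F statistic with the +1 correction,
    p = (1 + #{F_perm >= F_obs}) / (1 + permutations).
    """
    if isinstance(dist, pd.DataFrame):
        sample_ids = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        sample_ids = list(range(d.shape[0]))
    if isinstance(groups, Mapping):
        labels_raw = [groups[s] for s in sample_ids]
    elif isinstance(groups, pd.Series):
        labels_raw = [groups[s] for s in sample_ids]
    else:
        labels_raw = list(groups)
    _, labels = np.unique(labels_raw, return_inverse=True)
    counts = np.bincount(labels)
    if len(counts) < 2:
        raise FluxError("need at least two groups")
    if (counts < 2).any():
        raise FluxError("every group needs at least two samples")

    d2 = d ** 2
    f_obs, r2 = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        f_perm, _ = _pseudo_f(d2, rng.permutation(labels))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return PermanovaResult(float(r2), float(p), float(f_obs), permutations)


# ----------------------------------------------------------------------
# classical PCoA


def pcoa(dist: pd.DataFrame | np.ndarray, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) scaling of a distance matrix.

    Negative eigenvalues (non-Euclidean distances) are dropped; each
    retained axis's sign is fixed so its largest-magnitude loading is
    positive, making plots reproducible across runs.
    """
    if isinstance(dist, pd.DataFrame):
        index = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        index = list(range(d.shape[0]))
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise FluxError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    coords = np.zeros((n, k))
    for axis in range(min(k, n)):
        if w[axis] > 1e-10:
            col = v[:, axis] * np.sqrt(w[axis])
            if col[np.argmax(np.abs(col))] < 0:
                col = -col
            coords[:, axis] = col
    return pd.DataFrame(
        coords, index=index, columns=[f"PCo{i + 1}" for i in range(k)]
    )
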