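"""Gene-level read counting, flux calls, Jaccard/PCoA/PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from lumenstrain.gene_flux import (
    FluxError,
    detect_flux,
    gene_read_counts,
    jaccard_matrix,
    pcoa,
    permanova,
    presence_matrix,
)
from lumenstrain.genome import AnnotatedGenome, Gene
from lumenstrain.syndata import SimScenario, diversify, simulate_individual, simulate_reads


@pytest.fixture
def two_gene_genome():
    # adjacent genes [10, 40) and [40, 70) on a 100 bp contig
    return AnnotatedGenome(
        {"c1": "A" * 100},
        [Gene("g1", "c1", 10, 40, "+"), Gene("g2", "c1", 40, 70, "+")],
    )


def reads_df(intervals):
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(intervals))],
            "contig": [c for c, _, _ in intervals],
            "start": [s for _, s, _ in intervals],
            "end": [e for _, _, e in intervals],
            "mismatches": 0,
        }
    )


class TestGeneReadCounts:
    def test_no_reads_gives_zero_column(self, two_gene_genome):
        counts = gene_read_counts(reads_df([]), two_gene_genome)
        assert (counts == 0).all() and list(counts.index) == ["g1", "g2"]

    def test_read_spanning_two_genes_counted_in_both(self, two_gene_genome):
        counts = gene_read_counts(
            reads_df([("c1", 35, 45)]), two_gene_genome
        )
        assert counts["g1"] == 1 and counts["g2"] == 1

    def test_touching_but_not_overlapping_not_counted(self, two_gene_genome):
        # read [0, 10) ends exactly where g1 starts: zero shared bases
        counts = gene_read_counts(reads_df([("c1", 0, 10)]), two_gene_genome)
        assert counts["g1"] == 0

    def test_uniform_coverage_matches_window_count_formula(self):
        """20x coverage with 100 b reads over a 1 kb gene: a read overlaps
        the gene iff its start falls in one of (gene + read - 1) windows,
        giving ~ depth * (L + r - 1) / r = 220 expected reads."""
        genome = AnnotatedGenome(
            {"c1": "A" * 10_000}, [Gene("g1", "c1", 4_000, 5_000, "+")]
        )
        rng = np.random.default_rng(11)
        n_reads = 10_000 * 20 // 100
        starts = rng.integers(0, 10_000 - 100 + 1, n_reads)
        df = reads_df([("c1", int(s), int(s) + 100) for s in starts])
        counts = gene_read_counts(df, genome)
        expected = 20 * (1000 + 100 - 1) / 100
        assert counts["g1"] == pytest.approx(expected, rel=0.12)

    def test_read_beyond_contig_errors(self, two_gene_genome):
        with pytest.raises(FluxError):
            gene_read_counts(reads_df([("c1", 90, 120)]), two_gene_genome)


class TestDetectFlux:
    table = pd.DataFrame(
        {"ref": [12, 12, 12, 0], "tgt": [2, 3, 12, 0]},
        index=["a", "b", "c", "d"],
    )

    def test_threshold_boundaries(self):
        calls = {c.gene_id: c.status for c in detect_flux(self.table, "ref", "tgt")}
        assert calls["a"] == "missing"  # 2 < 3 and 12 >= 10
        assert calls["b"] == "retained"  # 3 is not fewer than 3
        assert calls["c"] == "retained"
        assert calls["d"] == "retained"  # reference lacks evidence too

    def test_identical_samples_no_missing(self):
        t = pd.DataFrame({"a": [20, 30], "b": [20, 30]}, index=["g1", "g2"])
        assert all(c.status == "retained" for c in detect_flux(t, "a", "b"))

    def test_unknown_sample_errors(self):
        with pytest.raises(FluxError):
            detect_flux(self.table, "ref", "nope")

    def test_simulated_deletions_recovered_exactly(self):
        """10 implanted gene deletions at 20x: all found, no false calls."""
        base = dict(
            genome_length=200_000, mean_gene_length=300, mean_depth=20.0,
            sites=("TI", "cecum", "DC"),
        )
        ind_a = simulate_individual(SimScenario(seed=31, **base))
        founder = ind_a.truth.founder
        assert len(founder.genes) >= 500
        sc_b = SimScenario(seed=32, deleted_genes_per_individual=10, **base)
        truth_b = diversify(founder, sc_b)
        reads_b = simulate_reads(truth_b, sc_b)
        table = pd.DataFrame(
            {
                "A": gene_read_counts(ind_a.reads["TI"][0], founder, "A"),
                "B": gene_read_counts(reads_b["TI"][0], founder, "B"),
            }
        )
        missing = sorted(
            c.gene_id for c in detect_flux(table, "A", "B") if c.status == "missing"
        )
        assert missing == truth_b.deleted_gene_ids

    def test_within_individual_site_pairs_have_no_flux(self, clean_individual):
        founder = clean_individual.truth.founder
        table = pd.DataFrame(
            {
                s: gene_read_counts(clean_individual.reads[s][0], founder, s)
                for s in ("TI", "cecum", "DC")
            }
        )
        for a in table.columns:
            for b in table.columns:
                if a != b:
                    assert all(
                        c.status == "retained" for c in detect_flux(table, a, b)
                    )


class TestJaccard:
    def test_hand_computed_cases(self):
        presence = pd.DataFrame(
            {
                "s1": [1, 1, 1, 0],
                "s2": [0, 1, 1, 1],
                "s3": [1, 1, 1, 0],
                "s4": [0, 0, 0, 1],
            },
            index=list("abcd"),
            dtype=bool,
        )
        d = jaccard_matrix(presence)
        assert d.loc["s1", "s3"] == 0.0  # identical sets
        assert d.loc["s1", "s4"] == 1.0  # disjoint sets
        assert d.loc["s1", "s2"] == pytest.approx(0.5)  # {a,b,c} vs {b,c,d}

    def test_empty_sample_gives_nan_sentinel(self):
        presence = pd.DataFrame(
            {"s1": [1, 0], "s2": [0, 0], "s3": [1, 1]}, dtype=bool
        )
        d = jaccard_matrix(presence)
        assert np.isnan(d.loc["s1", "s2"])
        assert not np.isnan(d.loc["s1", "s3"])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        presence = pd.DataFrame(
            rng.random((12, 5)) < 0.6, columns=[f"s{i}" for i in range(5)]
        )
        # guarantee no empty sample
        presence.iloc[0, :] = True
        d = jaccard_matrix(presence).to_numpy()
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestPermanova:
    @staticmethod
    def _structured(n_per=5, gap=10.0, jitter=0.01, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.concatenate(
            [rng.normal(g * gap, jitter, size=(n_per, 2)) for g in range(3)]
        )
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [g for g in "abc" for _ in range(n_per)]
        return d, labels

    def test_separated_groups_limiting_case(self):
        d, labels = self._structured()
        res = permanova(d, labels, permutations=999, seed=5)
        assert res.r2 > 0.99
        assert res.p_value == pytest.approx(1 / 1000)

    def test_sample_order_invariance(self):
        d, labels = self._structured(jitter=1.0)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(labels))
        res1 = permanova(d, labels, permutations=99, seed=7)
        res2 = permanova(
            d[np.ix_(perm, perm)], [labels[i] for i in perm],
            permutations=99, seed=7,
        )
        assert res1.r2 == pytest.approx(res2.r2)
        assert res1.f_stat == pytest.approx(res2.f_stat)

    def test_matches_skbio_pseudo_f(self):
        d, labels = self._structured(jitter=2.0, seed=9)
        ours = permanova(d, labels, permutations=9, seed=0)
        ids = [str(i) for i in range(len(labels))]
        theirs = skbio_permanova(
            DistanceMatrix(d, ids), grouping=labels, permutations=9
        )
        assert ours.f_stat == pytest.approx(theirs["test statistic"])

    def test_group_of_one_errors(self):
        d = np.zeros((3, 3))
        with pytest.raises(FluxError):
            permanova(d, ["a", "a", "b"], permutations=9)


class TestPcoa:
    def test_equilateral_for_three_equidistant_samples(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords = pcoa(d, k=2).to_numpy()
        dists = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        off = dists[np.triu_indices(3, 1)]
        assert np.allclose(off, off[0])

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords = pcoa(d, k=2).to_numpy()
        back = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(back, d, atol=1e-8)

    def test_rank_deficient_axes_are_zero(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = np.abs(pts - pts.T)
        coords = pcoa(d, k=3).to_numpy()
        assert np.allclose(coords[:, 1:], 0.0)

    def test_asymmetric_input_errors(self):
        with pytest.raises(FluxError):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_matches_skbio_up_to_axis_sign(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours = pcoa(d, k=3).to_numpy()
        theirs = skbio_pcoa(
            DistanceMatrix(d, [str(i) for i in range(7)]), number_of_dimensions=3
        ).samples.to_numpy()
        for axis in range(3):
            a, b = ours[:, axis], theirs[:, axis]
            assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)


def test_presence_matrix_threshold():
    t = pd.DataFrame({"a": [0, 9, 10, 50]}, index=list("wxyz"))
    p = presence_matrix(t)
    assert p["a"].tolist() == [False, False, True, True]
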