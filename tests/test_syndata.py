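"""Simulator contracts: founder structure, diversification, pileups, truth."""

import numpy as np
import pytest

from lumenstrain.genome import CODON_TO_AA, STOP_CODONS
from lumenstrain.syndata import (
    ScenarioError,
    SimScenario,
    _apply_snps,
    diversify,
    generate_founder,
    mutate_genome,
    simulate_pileups,
    simulate_reads,
    write_individual,
    simulate_individual,
)


class TestFounder:
    def test_gene_coverage_and_no_overlap(self):
        sc = SimScenario(seed=1, genome_length=100_000, gene_fraction=0.85)
        g = generate_founder(sc)
        covered = sum(gene.length for gene in g.genes)
        assert abs(covered - 85_000) <= 3_000
        for contig in g.contigs:
            spans = sorted(
                (x.start, x.end) for x in g.genes if x.contig == contig
            )
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_every_gene_is_an_orf(self):
        g = generate_founder(SimScenario(seed=3, genome_length=30_000))
        assert g.genes
        for gene in g.genes:
            orf = g.gene_sequence(gene)
            assert len(orf) % 3 == 0
            assert orf.startswith("ATG")
            codons = [orf[i : i + 3] for i in range(0, len(orf), 3)]
            assert codons[-1] in STOP_CODONS
            assert all(CODON_TO_AA[c] != "*" for c in codons[:-1])

    def test_same_seed_byte_identical_files(self, tmp_path):
        sc = SimScenario(seed=5, genome_length=20_000)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            g = generate_founder(sc)
            d.mkdir()
            g.to_fasta(d / "g.fa")
            g.to_gff3(d / "g.gff3")
        assert (d1 / "g.fa").read_bytes() == (d2 / "g.fa").read_bytes()
        assert (d1 / "g.gff3").read_bytes() == (d2 / "g.gff3").read_bytes()

    def test_zero_gene_fraction(self):
        g = generate_founder(SimScenario(seed=2, genome_length=5_000, gene_fraction=0.0))
        assert g.genes == [] and g.length == 5_000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gene_fraction": 1.5},
            {"mean_gene_length": 10_000, "genome_length": 5_000},
            {"genome_length": -1},
            {"minor_lineage_freq": 0.7},
            {"ptr_true": 0.5},
            {"error_rate": 0.5},
            {"per_site_substitutions": -3},
        ],
    )
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ScenarioError):
            SimScenario(seed=0, **kwargs)


class TestDiversify:
    def test_no_substitutions_means_identical_sites(self):
        sc = SimScenario(
            seed=8, genome_length=10_000, per_site_substitutions=0,
            shared_substitutions=0, minor_lineage_freq=0.0,
        )
        founder = generate_founder(sc)
        truth = diversify(founder, sc)
        assert all(g == founder for g in truth.site_genomes.values())

    def test_omega_zero_bars_nonsynonymous_changes(self):
        sc = SimScenario(
            seed=9, genome_length=40_000, per_site_substitutions=40,
            shared_substitutions=10, omega_true=0.0, minor_lineage_freq=0.0,
        )
        truth = diversify(generate_founder(sc), sc)
        coding = [s for s in truth.implanted_snps if s.region == "coding"]
        assert coding  # synonymous changes must still land in genes
        assert all(s.effect == "synonymous" for s in coding)

    def test_pairwise_site_distance_is_twice_private_count(self):
        sc = SimScenario(
            seed=10, genome_length=60_000, per_site_substitutions=30,
            shared_substitutions=15, minor_lineage_freq=0.0,
            sites=("TI", "cecum", "DC"),
        )
        truth = diversify(generate_founder(sc), sc)
        a = truth.site_genomes["TI"]
        b = truth.site_genomes["cecum"]
        diffs = sum(
            x != y
            for ca, cb in zip(a.contigs.values(), b.contigs.values())
            for x, y in zip(ca, cb)
        )
        assert diffs == 60  # shared changes cancel; 30 private per site

    def test_truth_reproduces_site_genomes(self, clean_individual):
        truth = clean_individual.truth
        for site, genome in truth.site_genomes.items():
            rebuilt = _apply_snps(
                truth.founder,
                [s for s in truth.implanted_snps
                 if s.lineage == "major" and site in s.sites],
            )
            assert rebuilt == genome

    def test_minor_positions_disjoint_from_major(self, default_individual):
        truth = default_individual.truth
        major = {(s.contig, s.pos) for s in truth.implanted_snps if s.lineage == "major"}
        minor = {(c, p) for c, p, _ in truth.minor_lineage_positions}
        assert not major & minor

    def test_truth_effects_match_annotator(self, default_individual):
        """Cross-module oracle: truth labels equal fresh classification."""
        truth = default_individual.truth
        for s in truth.implanted_snps:
            region, gene_id, effect = truth.founder.classify_substitution(
                s.contig, s.pos, s.alt
            )
            assert (region, gene_id, effect) == (s.region, s.gene_id, s.effect)

    def test_oversized_request_errors(self):
        kwargs = dict(genome_length=60, gene_fraction=0.0, mean_gene_length=30)
        founder = generate_founder(SimScenario(seed=1, **kwargs))
        sc = SimScenario(seed=1, per_site_substitutions=1000, **kwargs)
        with pytest.raises(ScenarioError):
            diversify(founder, sc)


class TestPileups:
    def test_error_free_single_lineage_counts_are_pure(self):
        sc = SimScenario(
            seed=11, genome_length=8_000, ptr_true=1.0, error_rate=0.0,
            minor_lineage_freq=0.0, mean_depth=30,
        )
        ind = simulate_individual(sc)
        site = "TI"
        pt = ind.pileups[site].df
        genome = ind.truth.site_genomes[site]
        counts = pt[["A", "C", "G", "T"]].to_numpy()
        top_base = np.array(list("ACGT"))[counts.argmax(axis=1)]
        flat = "".join(genome.contigs.values())
        covered = pt["depth"].to_numpy() > 0
        assert (counts.max(axis=1) == pt["depth"].to_numpy()).all()
        assert (top_base[covered] == np.array(list(flat))[covered]).all()

    def test_minor_lineage_vaf_near_its_frequency(self):
        sc = SimScenario(
            seed=12, genome_length=20_000, minor_lineage_freq=0.3,
            minor_lineage_snps=40, mean_depth=100, error_rate=0.0,
            ptr_true=1.0, per_site_substitutions=0, shared_substitutions=0,
        )
        ind = simulate_individual(sc)
        pt = ind.pileups["TI"].df.set_index(["contig", "pos"])
        vafs = []
        for contig, pos, alt in ind.truth.minor_lineage_positions:
            row = pt.loc[(contig, pos)]
            vafs.append(row[alt] / row["depth"])
        mean_vaf = float(np.mean(vafs))
        # 40 positions x depth 100: binomial SE of the mean ~ 0.007
        assert abs(mean_vaf - 0.3) < 0.03

    def test_replication_gradient_in_emitted_depths(self):
        sc = SimScenario(
            seed=13, genome_length=50_000, ptr_true=2.0, mean_depth=60,
            minor_lineage_freq=0.0, error_rate=0.0, n_contigs=1,
        )
        ind = simulate_individual(sc)
        depth = ind.pileups["TI"].depth_vector()
        L = depth.size
        origin_mean = depth[: L // 10].mean()
        terminus_mean = depth[int(L * 0.45) : int(L * 0.55)].mean()
        # closed-form window averages of the log-linear gradient:
        # u (origin distance / half-length) spans [0, 0.2] over the first
        # genomic decile and [0.9, 1] over the terminus decile.
        ln2 = np.log(2.0)

        def window_mean(u0, u1):
            return (2.0 ** (1 - u0) - 2.0 ** (1 - u1)) / ((u1 - u0) * ln2)

        expected = window_mean(0.0, 0.2) / window_mean(0.9, 1.0)
        assert origin_mean / terminus_mean == pytest.approx(expected, rel=0.05)
        assert origin_mean / terminus_mean > 1.6  # clear gradient toward 2x

    def test_pileups_deterministic_per_seed(self):
        sc = SimScenario(seed=14, genome_length=6_000)
        a = simulate_individual(sc)
        b = simulate_individual(sc)
        for site in sc.sites:
            assert a.pileups[site].df.equals(b.pileups[site].df)
            assert a.reads[site][0].equals(b.reads[site][0])

    def test_mean_depth_must_be_positive(self):
        with pytest.raises(ScenarioError):
            SimScenario(seed=1, mean_depth=0)


class TestReadsAndOutputs:
    def test_reads_avoid_deleted_genes(self):
        sc = SimScenario(
            seed=15, genome_length=30_000, deleted_genes_per_individual=3,
            mean_depth=20,
        )
        ind = simulate_individual(sc)
        deleted = [
            g for g in ind.truth.founder.genes
            if g.gene_id in ind.truth.deleted_gene_ids
        ]
        df = ind.reads["TI"][0]
        for g in deleted:
            sub = df[df["contig"] == g.contig]
            overlap = (sub["start"] < g.end) & (sub["end"] > g.start)
            assert not overlap.any()

    def test_write_individual_emits_standard_formats(self, tmp_path):
        sc = SimScenario(seed=16, genome_length=5_000)
        ind = simulate_individual(sc)
        out = tmp_path / "ind"
        write_individual(ind, out)
        for name in (
            "founder.fa", "founder.gff3", "founder.bed", "truth.json",
            "TI.pileup.tsv", "TI.reads.tsv",
        ):
            assert (out / name).exists(), name

    def test_mutate_genome_exact_count(self):
        g = generate_founder(SimScenario(seed=17, genome_length=10_000))
        mut, n = mutate_genome(g, 0.01, seed=5)
        assert n == 100
        diffs = sum(
            x != y
            for ca, cb in zip(g.contigs.values(), mut.contigs.values())
            for x, y in zip(ca, cb)
        )
        assert diffs == 100
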