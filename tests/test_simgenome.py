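import math

import numpy as np
import pytest

from polyhekit.alnio import decode, revcomp
from polyhekit.simgenome import (
    CNVEvent,
    HEEvent,
    LTRBurst,
    SimConfig,
    apply_sample_variation,
    derive_parent,
    evolve_lineage,
    generate_ancestor,
    generate_study,
    insert_ltr_burst,
    make_tetraploid,
    read_matrix,
    simulate_reads,
)

STOPS = {"TAA", "TAG", "TGA"}


class TestAncestor:
    def test_size_contract(self):
        cfg = SimConfig(n_chromosomes=1, ancestor_length=10_000, n_genes=5, gene_length=300, ltr_bursts=(), seed=1)
        anc = generate_ancestor(cfg)
        assert anc.seqs["chr1"].size == 10_000
        assert len(anc.genes) == 5
        ivs = sorted((g.start, g.end) for g in anc.genes)
        assert all(e - s == 300 for s, e in ivs)
        assert all(ivs[i][1] <= ivs[i + 1][0] for i in range(len(ivs) - 1))

    def test_orfs_have_no_internal_stops(self):
        cfg = SimConfig(n_chromosomes=1, ancestor_length=10_000, n_genes=5, gene_length=300, ltr_bursts=(), seed=1)
        anc = generate_ancestor(cfg)
        for g in anc.genes:
            s = decode(anc.seqs[g.chrom][g.start : g.end])
            assert not any(s[i : i + 3] in STOPS for i in range(0, len(s), 3))

    def test_deterministic(self):
        cfg = SimConfig(n_chromosomes=1, ancestor_length=10_000, n_genes=5, gene_length=300, ltr_bursts=(), seed=1)
        a1 = generate_ancestor(cfg)
        a2 = generate_ancestor(cfg)
        assert np.array_equal(a1.seqs["chr1"], a2.seqs["chr1"])
        assert [(g.id, g.start) for g in a1.genes] == [(g.id, g.start) for g in a2.genes]

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError):
            SimConfig(n_chromosomes=1, ancestor_length=1_000, n_genes=5, gene_length=300, ltr_bursts=())


class TestEvolveLineage:
    def test_zero_years_identity(self, rng):
        seq = rng.integers(0, 4, 1000, dtype=np.uint8)
        assert np.array_equal(evolve_lineage(seq, 0.0, 1e-8, rng), seq)

    def test_negative_years_raises(self, rng):
        with pytest.raises(ValueError):
            evolve_lineage(np.zeros(10, np.uint8), -1.0, 1e-8, rng)

    @pytest.mark.parametrize(
        "branch,expected",
        [
            (0.065, 0.75 * (1 - math.exp(-4 / 3 * 0.065))),  # ~0.0623
            (10.0, 0.75 * (1 - math.exp(-4 / 3 * 10.0))),  # saturation -> ~0.75
        ],
    )
    def test_jc_expected_mismatch(self, rng, branch, expected):
        n = 100_000
        seq = rng.integers(0, 4, n, dtype=np.uint8)
        out = evolve_lineage(seq, branch / 1e-8, 1e-8, rng)
        p = float(np.count_nonzero(out != seq)) / n
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(p - expected) < 3 * se

    def test_two_lineage_divergence_matches_jc(self, rng):
        # two lineages with total branch 2*mu*T = 0.065
        n = 100_000
        seq = rng.integers(0, 4, n, dtype=np.uint8)
        a = evolve_lineage(seq, 0.0325 / 1e-8, 1e-8, rng)
        b = evolve_lineage(seq, 0.0325 / 1e-8, 1e-8, rng)
        expected = 0.75 * (1 - math.exp(-4 / 3 * 0.065))
        p = float(np.count_nonzero(a != b)) / n
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(p - expected) < 3 * se


class TestLTRBurst:
    def test_age_zero_repeats_identical(self, rng):
        cfg = SimConfig(n_chromosomes=1, ancestor_length=50_000, n_genes=5, gene_length=300, ltr_bursts=(), seed=3)
        anc = generate_ancestor(cfg)
        burst = LTRBurst("A", 0.0, 10, 2_000, 700)
        g = insert_ltr_burst(anc, burst, rng)
        assert len(g.tes) == 10
        for te in g.tes:
            seq = g.seqs[te.chrom]
            r5 = seq[te.start : te.start + te.ltr_length]
            r3 = seq[te.end - te.ltr_length : te.end]
            assert np.array_equal(r5, r3)
            assert te.age == 0.0

    def test_insertions_avoid_genes(self, rng):
        cfg = SimConfig(n_chromosomes=1, ancestor_length=50_000, n_genes=10, gene_length=600, ltr_bursts=(), seed=4)
        anc = generate_ancestor(cfg)
        g = insert_ltr_burst(anc, LTRBurst("A", 1000.0, 15, 1_500, 500), rng)
        for te in g.tes:
            for gene in g.genes:
                assert te.end <= gene.start or te.start >= gene.end
        # gene sequences are unchanged by insertion (coordinates track)
        for gene, old in zip(g.genes, anc.genes):
            assert np.array_equal(
                g.seqs[gene.chrom][gene.start : gene.end],
                anc.seqs[old.chrom][old.start : old.end],
            )

    def test_repeat_pair_divergence_tracks_2muT(self, rng):
        cfg = SimConfig(n_chromosomes=1, ancestor_length=100_000, n_genes=2, gene_length=300, ltr_bursts=(), seed=5)
        anc = generate_ancestor(cfg)
        age, mu, L = 340_000.0, 1.3e-8, 2_000
        g = insert_ltr_burst(anc, LTRBurst("A", age, 60, 5_000, L), rng, mu_ltr=mu)
        ps = []
        for te in g.tes:
            seq = g.seqs[te.chrom]
            r5 = seq[te.start : te.start + L]
            r3 = seq[te.end - L : te.end]
            ps.append(float(np.count_nonzero(r5 != r3)) / L)
        expected = 0.75 * (1 - math.exp(-4 / 3 * 2 * mu * age))  # ~2*mu*T
        assert abs(np.mean(ps) - expected) / expected < 0.15


class TestTetraploid:
    def test_no_he_equals_concatenated_parents(self, tiny_parents):
        parent_a, parent_b, truth = tiny_parents
        assert truth.he_truth == []
        assert np.array_equal(truth.seqs["chr1A"], parent_a.seqs["chr1"])
        assert np.array_equal(truth.seqs["chr1B"], parent_b.seqs["chr1"])
        assert len(truth.genes) == len(parent_a.genes) + len(parent_b.genes)

    def test_he_segment_is_donor_substring(self, tiny_parents):
        parent_a, parent_b, _ = tiny_parents
        ev = HEEvent("chr1B", 20_000, 36_000, "A")
        truth = make_tetraploid(parent_a, parent_b, [ev])
        recs = [t for t in truth.he_truth if t[0] == "chr1B"]
        assert len(recs) == 1
        chrom, s, e, donor = recs[0]
        assert donor == "A" and e - s == 16_000
        seg = truth.seqs["chr1B"][s:e]
        assert np.array_equal(seg, parent_a.seqs["chr1"][20_000:36_000])

    def test_he_identity_vs_parents(self, tiny_parents):
        parent_a, parent_b, _ = tiny_parents
        truth = make_tetraploid(parent_a, parent_b, [HEEvent("chr1B", 20_000, 36_000, "A")])
        chrom, s, e, donor = [t for t in truth.he_truth if t[0] == "chr1B"][0]
        seg = truth.seqs["chr1B"][s:e]
        id_a = np.mean(seg == parent_a.seqs["chr1"][s:e])
        id_b = np.mean(seg == parent_b.seqs["chr1"][s:e])
        d_ab = np.mean(parent_a.seqs["chr1"] != parent_b.seqs["chr1"])
        assert id_a >= 0.99
        assert id_b <= 1 - d_ab / 2  # B-side identity drops to parental level

    def test_reciprocal_swap_records_both_sides(self, tiny_parents):
        parent_a, parent_b, _ = tiny_parents
        truth = make_tetraploid(parent_a, parent_b, [HEEvent("chr1B", 20_000, 36_000, "A")])
        donors = sorted((c, d) for c, _, _, d in truth.he_truth)
        assert donors == [("chr1A", "B"), ("chr1B", "A")]
        # gene complement is conserved by a clean swap
        assert len(truth.genes) == len(parent_a.genes) + len(parent_b.genes)

    def test_overlapping_events_raise(self, tiny_parents):
        parent_a, parent_b, _ = tiny_parents
        with pytest.raises(ValueError, match="overlap"):
            make_tetraploid(
                parent_a,
                parent_b,
                [HEEvent("chr1B", 20_000, 36_000, "A"), HEEvent("chr1B", 30_000, 40_000, "A")],
            )


class TestSampleVariation:
    def test_no_events_identical_haplotypes(self, tiny_parents, rng):
        *_, truth = tiny_parents
        sg = apply_sample_variation(truth, "s0", rng)
        for chrom in truth.seqs:
            assert np.array_equal(sg.haplotypes[f"{chrom}|hap1"], truth.seqs[chrom])
            assert np.array_equal(sg.haplotypes[f"{chrom}|hap2"], truth.seqs[chrom])

    def test_heterozygous_deletion_hits_one_haplotype(self, tiny_parents, rng):
        *_, truth = tiny_parents
        ev = CNVEvent("s1", "chr1A", 10_000, 14_000, 0.5)
        sg = apply_sample_variation(truth, "s1", rng, cnv_events=[ev])
        sizes = sorted(
            sg.haplotypes[f"chr1A|hap{h}"].size for h in (1, 2)
        )
        assert sizes == [truth.seqs["chr1A"].size - 4_000, truth.seqs["chr1A"].size]

    def test_pav_deletion_removes_gene_sequence(self, tiny_parents, rng):
        *_, truth = tiny_parents
        gene = next(g for g in truth.genes if g.chrom == "chr1A")
        gene_seq = decode(truth.seqs["chr1A"][gene.start : gene.end])
        sg = apply_sample_variation(truth, "s1", rng, pav_genes=[gene.id])
        for h in (1, 2):
            hap = decode(sg.haplotypes[f"chr1A|hap{h}"])
            assert gene_seq not in hap
        assert ("s1", gene.id, "lost") in truth.pav_truth

    def test_overlapping_cnvs_raise(self, tiny_parents, rng):
        *_, truth = tiny_parents
        evs = [
            CNVEvent("s1", "chr1A", 10_000, 14_000, 0.0),
            CNVEvent("s1", "chr1A", 12_000, 16_000, 2.0),
        ]
        with pytest.raises(ValueError):
            apply_sample_variation(truth, "s1", rng, cnv_events=evs)


class TestReadSimulator:
    def test_depth_zero_empty(self, tiny_parents, rng):
        *_, truth = tiny_parents
        rs = simulate_reads(truth.seqs, 0.0, 150, 350, 0.0, rng)
        assert len(rs) == 0

    def test_pair_count_arithmetic(self, rng):
        seqs = {"chr1": rng.integers(0, 4, 1_000_000, dtype=np.uint8)}
        rs = simulate_reads(seqs, 10.0, 150, 350, 0.0, np.random.default_rng(1))
        assert len(rs) == 33_333  # round(10 * 1e6 / 300)

    def test_error_free_reads_are_exact_substrings(self, tiny_parents):
        *_, truth = tiny_parents
        rs = simulate_reads(truth.seqs, 0.5, 150, 350, 0.0, np.random.default_rng(2))
        genome = {c: decode(s) for c, s in truth.seqs.items()}
        for i in range(0, len(rs), 37):
            name = rs.names[i]
            chrom = name.split("|chrom=")[1].split("|")[0]
            pos = int(name.split("|pos=")[1].split("|")[0])
            r1 = decode(rs.r1[i])
            r2 = decode(rs.r2[i])
            assert genome[chrom][pos : pos + 150] == r1
            assert genome[chrom][pos + 200 : pos + 350] == revcomp(r2)

    def test_insert_shorter_than_read_raises(self, tiny_parents, rng):
        *_, truth = tiny_parents
        with pytest.raises(ValueError):
            simulate_reads(truth.seqs, 1.0, 150, 100, 0.0, rng)


def test_full_study_deterministic():
    cfg = SimConfig(
        n_chromosomes=1,
        ancestor_length=60_000,
        n_genes=6,
        gene_length=300,
        ltr_bursts=(LTRBurst("A", 10_000.0, 3, 1_200, 400),),
        he_events=(HEEvent("chr1B", 10_000, 18_000, "A"),),
        seed=99,
    )
    out = []
    for _ in range(2):
        pa, pb, truth = generate_study(cfg)
        rs = simulate_reads(truth.seqs, 2.0, 150, 350, 0.01, np.random.default_rng(cfg.seed))
        mat, names = read_matrix(rs)
        out.append(
            (
                {c: s.tobytes() for c, s in truth.seqs.items()},
                truth.he_truth,
                [(g.id, g.chrom, g.start) for g in truth.genes],
                mat.tobytes(),
                tuple(names),
            )
        )
    assert out[0] == out[1]
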