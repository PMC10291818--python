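import math

import numpy as np
import pytest

from polyhekit import alnio, origin
from polyhekit.alnio import AlignmentRecord, KmerIndex, decode, encode
from polyhekit.origin import (
    ClassifierParams,
    DiagnosticVariant,
    classify_by_primary_mapping,
    classify_read_llr,
    classify_reads_llr,
    find_diagnostic_variants,
    tag_and_remap,
)
from polyhekit.simgenome import read_matrix, simulate_reads


class TestDiagnosticVariants:
    def test_identical_sequences_no_variants(self):
        assert find_diagnostic_variants("ACGTACGTAC", "ACGTACGTAC") == []

    def test_single_substitution(self):
        vs = find_diagnostic_variants("ACGTACGTAC", "ACCTACGTAC")
        assert len(vs) == 1
        v = vs[0]
        assert (v.pos_a, v.pos_b, v.allele_a, v.allele_b) == (2, 2, "G", "C")

    def test_gap_exclusion_zone(self):
        # pre-aligned pair with a 3 bp gap; a mismatch 2 bp from the gap
        # must be suppressed, one 3 bp away must survive
        a = "ACGTACGTAC" + "TTT" + "GACGTACGTA"
        b = "ACGTACGTAC" + "---" + "GACCTACGTA"
        vs = find_diagnostic_variants(a, b, aligned=True)
        assert [v.pos_a for v in vs] == [16]

    def test_low_identity_raises(self):
        rng = np.random.default_rng(0)
        a = decode(rng.integers(0, 4, 300, dtype=np.uint8))
        b = decode(rng.integers(0, 4, 300, dtype=np.uint8))
        with pytest.raises(ValueError, match="identity"):
            find_diagnostic_variants(a, b, aligned=True)

    def test_equal_alleles_invalid(self):
        with pytest.raises(ValueError):
            DiagnosticVariant("p", 0, 0, "A", "A")

    def test_vcf_export(self, tmp_path):
        vs = find_diagnostic_variants("ACGTACGTAC", "ACCTACGTAC")
        p = tmp_path / "x.vcf"
        origin.write_vcf(p, vs)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        chrom, pos, _, ref, alt = lines[0].split("\t")[:5]
        assert (int(pos), ref, alt) == (3, "G", "C")  # 1-based


def _rec(seq: str, start: int, read_id: str = "r") -> AlignmentRecord:
    return AlignmentRecord(
        read_id, "chr1", start, "+", len(seq), 0, len(seq), seq_codes=encode(seq)
    )


class TestLLRClassifier:
    def test_no_covered_sites_ambiguous(self):
        variants = [DiagnosticVariant("p", 500, 500, "A", "C")]
        call = classify_read_llr(_rec("ACGT" * 10, 0), variants)
        assert (call.origin, call.llr, call.n_sites) == ("U", 0.0, 0)

    def test_three_matching_sites(self):
        # per-site term ln((1-eps)/(eps/3)) = ln(297) at eps = 0.01
        variants = [
            DiagnosticVariant("p", 2, 2, "G", "C"),
            DiagnosticVariant("p", 5, 5, "C", "T"),
            DiagnosticVariant("p", 8, 8, "A", "G"),
        ]
        read = "ACGTACGTAC"  # matches allele_a at all three sites
        call = classify_read_llr(_rec(read, 0), variants)
        assert call.origin == "A" and call.n_sites == 3
        assert call.llr == pytest.approx(3 * math.log(297), rel=1e-12)
        assert call.llr == pytest.approx(17.08, abs=0.01)

    def test_allele_swap_negates_llr(self):
        variants = [
            DiagnosticVariant("p", 2, 2, "G", "C"),
            DiagnosticVariant("p", 5, 5, "C", "T"),
            DiagnosticVariant("p", 8, 8, "A", "G"),
        ]
        swapped = [DiagnosticVariant("p", v.pos_a, v.pos_b, v.allele_b, v.allele_a) for v in variants]
        rec = _rec("ACGTACGTAC", 0)
        c1 = classify_read_llr(rec, variants)
        c2 = classify_read_llr(rec, swapped)
        assert c2.llr == -c1.llr and c2.origin == "B"

    def test_batch_matches_single(self):
        rng = np.random.default_rng(1)
        variants = [
            DiagnosticVariant("p", int(i), int(i), "A", "C") for i in range(10, 200, 17)
        ]
        recs = [_rec(decode(rng.integers(0, 4, 80, dtype=np.uint8)), int(s), f"r{s}") for s in (0, 40, 100)]
        batch = classify_reads_llr(recs, variants)
        for rec, call in zip(recs, batch):
            single = classify_read_llr(rec, variants)
            assert (call.origin, call.n_sites) == (single.origin, single.n_sites)
            assert call.llr == pytest.approx(single.llr, abs=1e-9)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ClassifierParams(eps=0.3)
        with pytest.raises(ValueError):
            ClassifierParams(tau=-1)


@pytest.fixture(scope="module")
def diverged_parents():
    rng = np.random.default_rng(2)
    anc = rng.integers(0, 4, 40_000, dtype=np.uint8)
    a = anc.copy()
    b = anc.copy()
    # diverge everywhere except a shared identical region [20k, 24k)
    for seq in (a, b):
        m = rng.random(seq.size) < 0.03
        m[20_000:24_000] = False
        idx = np.nonzero(m)[0]
        seq[idx] = (seq[idx] + rng.integers(1, 4, idx.size).astype(np.uint8)) % 4
    return {"chrA": a, "chrB": b}


class TestPrimaryMapping:
    def test_origin_calls(self, diverged_parents):
        idx = KmerIndex(diverged_parents)
        reads = [
            decode(diverged_parents["chrA"][1_000:1_150]),  # diverged A region
            decode(diverged_parents["chrB"][5_000:5_150]),  # diverged B region
            decode(diverged_parents["chrA"][21_000:21_150]),  # identical region
        ]
        calls, recs = classify_by_primary_mapping(reads, idx, read_ids=["a", "b", "tie"])
        assert calls[0].origin == "A" and calls[0].llr > 0
        assert calls[1].origin == "B" and calls[1].llr < 0
        assert calls[2].origin == "U"

    def test_unmapped_read_is_novel(self, diverged_parents):
        idx = KmerIndex(diverged_parents)
        foreign = decode(np.random.default_rng(9).integers(0, 4, 150, dtype=np.uint8))
        calls, _ = classify_by_primary_mapping([foreign], idx, read_ids=["x"])
        assert calls[0].origin == "N"


class TestTagAndRemap:
    def test_missing_call_raises(self, tiny_parents):
        *_, truth = tiny_parents
        tidx = KmerIndex(truth.seqs)
        read = decode(truth.seqs["chr1A"][100:250])
        with pytest.raises(ValueError, match="no origin call"):
            tag_and_remap([read], {}, tidx, read_ids=["r0"])

    def test_tags_survive_sam_round_trip(self, tiny_parents, tmp_path):
        parent_a, parent_b, truth = tiny_parents
        tidx = KmerIndex(truth.seqs)
        reads = [decode(truth.seqs["chr1A"][s : s + 150]) for s in (100, 5_000, 9_000)]
        calls = {f"r{i}": origin.OriginCall(f"r{i}", t, 1.0) for i, t in enumerate("ABU")}
        tagged = tag_and_remap(reads, calls, tidx, read_ids=["r0", "r1", "r2"])
        p = tmp_path / "tagged.sam"
        alnio.write_sam(p, tagged, truth.chrom_lengths())
        back = alnio.read_sam(p)
        assert [r.origin_tag for r in back] == ["A", "B", "U"]


def test_strategies_agree_on_unambiguous_calls(tiny_parents):
    """Likelihood and competitive-mapping classification agree on >= 95%
    of the reads both call unambiguously."""
    parent_a, parent_b, _ = tiny_parents
    variants = find_diagnostic_variants(
        decode(parent_a.seqs["chr1"]), decode(parent_b.seqs["chr1"]), pair_id="chr1"
    )
    reads = simulate_reads(
        {"chr1A": parent_a.seqs["chr1"], "chr1B": parent_b.seqs["chr1"]},
        2.0, 150, 350, 0.0, np.random.default_rng(3),
    )
    mat, names = read_matrix(reads)
    idx_a = KmerIndex({"chr1": parent_a.seqs["chr1"]})
    recs_a = alnio.map_reads(mat, idx_a, read_ids=names)
    llr_calls = classify_reads_llr(recs_a, variants)
    pidx = KmerIndex({"chr1A": parent_a.seqs["chr1"], "chr1B": parent_b.seqs["chr1"]})
    pm_calls, _ = classify_by_primary_mapping(mat, pidx, read_ids=names)
    agree = total = 0
    for c1, c2 in zip(llr_calls, pm_calls):
        if c1.origin in "AB" and c2.origin in "AB":
            total += 1
            agree += c1.origin == c2.origin
    assert total > 100
    assert agree / total >= 0.95


def test_accuracy_monotone_in_error_rate(tiny_parents):
    """LLR accuracy does not increase when base errors increase."""
    parent_a, parent_b, _ = tiny_parents
    variants = find_diagnostic_variants(
        decode(parent_a.seqs["chr1"]), decode(parent_b.seqs["chr1"]), pair_id="chr1"
    )
    idx_a = KmerIndex({"chr1": parent_a.seqs["chr1"]})
    accs = []
    for err in (0.0, 0.03, 0.10):
        reads = simulate_reads(
            {"chr1A": parent_a.seqs["chr1"], "chr1B": parent_b.seqs["chr1"]},
            2.0, 150, 350, err, np.random.default_rng(4),
        )
        mat, names = read_matrix(reads)
        recs = alnio.map_reads(mat, idx_a, read_ids=names)
        calls = classify_reads_llr(recs, variants)
        ok = n = 0
        for call, name in zip(calls, names):
            if call.origin in "AB":
                n += 1
                ok += call.origin == name.split("|origin=")[1][0]
        accs.append(ok / n)
    assert accs[0] == 1.0
    assert accs[0] >= accs[1] >= accs[2] - 0.005  # small MC slack at the tail
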