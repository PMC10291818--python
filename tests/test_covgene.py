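import numpy as np
import pandas as pd
import pytest

from polyhekit.alnio import AlignmentRecord
from polyhekit.covgene import (
    CNVParams,
    CNVSegment,
    PAVParams,
    call_gene_status,
    core_dispensable,
    depth_profile,
    gene_breadth,
    refine_breakpoints,
    segment_cnv,
)
from polyhekit.simgenome import GeneFeature

CHROMS = {"chr1A": 100_000}


def _aln(start, length=150, chrom="chr1A", read_id="r", partner=None, sl=0, sr=0):
    return AlignmentRecord(
        read_id, chrom, start, "+", length, 0, length,
        soft_left=sl, soft_right=sr, clipped_partner=partner,
    )


def _tile(chrom_len=100_000, step=50, length=150, chrom="chr1A", skip=lambda s: False):
    return [
        _aln(s, length, chrom, f"t{s}")
        for s in range(0, chrom_len - length, step)
        if not skip(s)
    ]


class TestGeneBreadth:
    def test_fully_covered(self):
        g = GeneFeature("g", "chr1A", 1_000, 1_300)
        b = gene_breadth(_tile(5_000), [g], CHROMS)
        assert b["g"] == 1.0

    def test_single_read_half_coverage(self):
        g = GeneFeature("g", "chr1A", 1_000, 1_300)
        b = gene_breadth([_aln(1_075)], [g], CHROMS)
        assert b["g"] == pytest.approx(0.5)

    def test_no_reads_zero(self):
        g = GeneFeature("g", "chr1A", 1_000, 1_300)
        assert gene_breadth([], [g], CHROMS)["g"] == 0.0

    def test_gene_outside_chromosome_raises(self):
        g = GeneFeature("g", "chr1A", 99_900, 100_400)
        with pytest.raises(ValueError, match="outside"):
            gene_breadth([], [g], CHROMS)


class TestGeneStatus:
    @pytest.mark.parametrize(
        "bs,bo,expected",
        [
            (0.15, 0.10, "lost"),
            (0.15, 0.95, "within-HE"),
            (0.99, 0.99, "present"),
            (0.20, 0.99, "present"),  # at the threshold = not lost
        ],
    )
    def test_rule(self, bs, bo, expected):
        assert call_gene_status(bs, bo) == expected

    def test_raising_lost_threshold_never_shrinks_lost_set(self):
        rng = np.random.default_rng(0)
        pairs = rng.random((200, 2))
        prev = set()
        for lt in (0.05, 0.2, 0.4, 0.6):
            lost = {
                i
                for i, (bs, bo) in enumerate(pairs)
                if call_gene_status(bs, bo, PAVParams(lt, 0.95)) == "lost"
            }
            assert prev <= lost
            prev = lost

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            PAVParams(0.9, 0.2)


class TestCoreDispensable:
    def test_all_present(self):
        df = pd.DataFrame("present", index=[f"g{i}" for i in range(5)], columns=["s1", "s2"])
        core, disp = core_dispensable(df)
        assert len(core) == 5 and disp == set()

    def test_one_lost_call(self):
        df = pd.DataFrame("present", index=[f"g{i}" for i in range(5)], columns=list("abc"))
        df.loc["g2", "b"] = "lost"
        core, disp = core_dispensable(df)
        assert core == {"g0", "g1", "g3", "g4"} and disp == {"g2"}

    def test_partition(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.choice(["present", "lost", "within-HE"], size=(50, 4)),
            index=[f"g{i}" for i in range(50)],
        )
        core, disp = core_dispensable(df)
        assert core | disp == set(df.index) and not core & disp

    def test_ragged_table_raises(self):
        df = pd.DataFrame({"a": ["present", None]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="ragged"):
            core_dispensable(df)


class TestDepthProfile:
    def test_uniform_coverage_near_one(self):
        prof, mean, med = depth_profile(_tile(), CHROMS, window=10_000)
        assert np.allclose(prof["chr1A"][:-1], 1.0, atol=0.05)
        assert med > 0

    def test_deleted_and_het_regions(self):
        # no reads in [30k, 40k); half density in [60k, 70k)
        reads = _tile(skip=lambda s: 30_000 <= s < 40_000 or (60_000 <= s < 70_000 and s % 100 == 0))
        prof, _, _ = depth_profile(reads, CHROMS, window=10_000)
        p = prof["chr1A"]
        assert p[3] < 0.1
        assert abs(p[6] - 0.5) < 0.1

    def test_zero_length_genome_raises(self):
        with pytest.raises(ValueError):
            depth_profile([], {}, window=1_000)


class TestSegmentCNV:
    PARAMS = CNVParams(window=10_000, min_segment=30_000)

    def test_flat_profile_single_segment(self):
        prof = {"chr1A": np.ones(100)}
        segs = segment_cnv(prof, self.PARAMS)
        assert len(segs) == 1
        s = segs[0]
        assert (s.start, s.end, s.state) == (0, 1_000_000, 1.0)

    def test_half_state_stretch_recovered(self):
        prof = {"chr1A": np.ones(100)}
        prof["chr1A"][40:60] = 0.5  # 200 kb stretch
        segs = segment_cnv(prof, self.PARAMS)
        states = [(s.start, s.end, s.state) for s in segs]
        assert (400_000, 600_000, 0.5) in states
        assert len(segs) == 3

    def test_duplication_stretch(self):
        prof = {"chr1A": np.ones(100)}
        prof["chr1A"][10:40] = 2.0
        segs = segment_cnv(prof, self.PARAMS)
        assert any(s.state == 2.0 and s.start == 100_000 and s.end == 400_000 for s in segs)

    def test_nocall_windows_inherit(self):
        prof = {"chr1A": np.ones(100)}
        prof["chr1A"][50] = 0.72  # between states, not callable
        segs = segment_cnv(prof, self.PARAMS)
        assert len(segs) == 1 and segs[0].state == 1.0

    def test_short_runs_absorbed(self):
        prof = {"chr1A": np.ones(100)}
        prof["chr1A"][50:52] = 0.0  # 20 kb < min_segment 30 kb
        segs = segment_cnv(prof, self.PARAMS)
        assert len(segs) == 1 and segs[0].state == 1.0

    def test_segments_partition_chromosome(self):
        rng = np.random.default_rng(2)
        prof = {"chr1A": np.abs(1.0 + 0.05 * rng.standard_normal(100))}
        prof["chr1A"][20:35] = 0.5
        prof["chr1A"][70:90] = 2.0
        segs = segment_cnv(prof, self.PARAMS, {"chr1A": 998_500})
        segs.sort(key=lambda s: s.start)
        assert segs[0].start == 0 and segs[-1].end == 998_500
        for s1, s2 in zip(segs, segs[1:]):
            assert s1.end == s2.start
            assert s1.state != s2.state


class TestRefineBreakpoints:
    def _segments(self):
        return [
            CNVSegment("chr1A", 0, 400_000, 1.0, 1.0),
            CNVSegment("chr1A", 400_000, 600_000, 0.0, 0.0),
            CNVSegment("chr1A", 600_000, 1_000_000, 1.0, 1.0),
        ]

    def test_no_split_reads_flagged_approximate(self):
        segs = refine_breakpoints(self._segments(), [])
        mid = [s for s in segs if s.state == 0.0][0]
        assert not mid.left_exact and not mid.right_exact
        assert (mid.start, mid.end) == (400_000, 600_000)

    def test_clustered_clips_snap_boundary(self):
        # deletion truth [400_123, 599_987): right-clipped reads end at the
        # left junction partnering the right junction, and vice versa
        splits = []
        for i in range(5):
            splits.append(
                _aln(400_123 - 100 - i, length=100 + i, read_id=f"l{i}",
                     sr=50, partner=("chr1A", 599_987))
            )
            splits.append(
                _aln(599_987, length=100 + i, read_id=f"r{i}",
                     sl=50, partner=("chr1A", 400_123))
            )
        segs = refine_breakpoints(self._segments(), splits, search=10_500)
        mid = [s for s in segs if s.state == 0.0][0]
        assert (mid.start, mid.end) == (400_123, 599_987)
        assert mid.left_exact and mid.right_exact
        assert mid.partner == ("chr1A", 400_123)
        # the partition is preserved
        segs.sort(key=lambda s: s.start)
        assert segs[0].end == mid.start and segs[2].start == mid.end

    def test_single_split_read_insufficient(self):
        splits = [_aln(400_023, length=100, read_id="only", sr=50, partner=("chr1A", 600_000))]
        segs = refine_breakpoints(self._segments(), splits, search=10_500)
        mid = [s for s in segs if s.state == 0.0][0]
        assert not mid.left_exact
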