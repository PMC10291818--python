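"""Breadth-of-coverage gene presence/absence and depth-based CNV calling.

Gene loss follows the breadth-of-coverage resequencing rule: a gene with
< 20% of its bases covered in a sample is lost (dispensable); if the
matching opposite-subgenome evidence covers > 90% it is instead a gene
within a homoeologous exchange. Large duplications/deletions are called by
quantizing windowed, median-normalized depth onto relative copy states
{0, 1/2, 1, 3/2, 2} (half-states are haplotype-specific events in a
tetraploid sample) and refined to base precision with split reads
clustering at the junctions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alnio import AlignmentRecord


@dataclass(frozen=True)
class PAVParams:
    lost_thresh: float = 0.20  # breadth below which a gene is lost
    he_thresh: float = 0.90  # opposite-parent breadth above which it is an HE gene

    def __post_init__(self):
        if not 0 < self.lost_thresh < self.he_thresh <= 1:
            raise ValueError("need 0 < lost_thresh < he_thresh <= 1")


@dataclass(frozen=True)
class CNVParams:
    window: int = 10_000
    states: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    state_tolerance: float = 0.15
    min_segment: int = 50_000

    def __post_init__(self):
        if not 0 < self.state_tolerance < 0.25:
            raise ValueError("state_tolerance must be below half the state gap (0.25)")


@dataclass
class CNVSegment:
    chrom: str
    start: int
    end: int
    state: float
    mean_depth: float
    left_exact: bool = False
    right_exact: bool = False
    partner: tuple[str, int] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# coverage primitives
# ---------------------------------------------------------------------------


def _coverage_arrays(
    records: Sequence[AlignmentRecord],
    chrom_lengths: Mapping[str, int],
    tag_in: set[str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-base depth from confidently placed primary alignments.

    Ambiguous placements (score ties, the MAPQ-0 equivalents) are
    excluded: a tied read carries no positional evidence and would paint
    coverage onto loci its twin copy could equally own.
    """
    diffs = {c: np.zeros(L + 1, dtype=np.int32) for c, L in chrom_lengths.items()}
    for rec in records:
        if rec is None or not rec.is_primary or rec.ambiguous_placement:
            continue
        if tag_in is not None and rec.origin_tag not in tag_in:
            continue
        d = diffs.get(rec.ref_name)
        if d is None:
            raise ValueError(f"alignment to unknown chromosome {rec.ref_name}")
        d[rec.ref_start] += 1
        d[min(rec.ref_end, d.size - 1)] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diffs.items()}


def gene_breadth(
    records: Sequence[AlignmentRecord],
    genes: Sequence,
    chrom_lengths: Mapping[str, int],
    tag_in: set[str] | None = None,
) -> dict[str, float]:
    """Fraction of each gene's bases covered by >= 1 primary alignment.

    ``tag_in`` restricts to alignments with those origin tags (used to
    split concordant vs discordant evidence for HE-gene calling).
    """
    cov = _coverage_arrays(records, chrom_lengths, tag_in)
    out = {}
    for g in genes:
        if g.chrom not in cov:
            raise ValueError(f"gene {g.id} on unknown chromosome {g.chrom}")
        if g.end > chrom_lengths[g.chrom] or g.start < 0:
            raise ValueError(f"gene {g.id} outside chromosome {g.chrom}")
        out[g.id] = float(np.count_nonzero(cov[g.chrom][g.start : g.end]) / (g.end - g.start))
    return out


def call_gene_status(
    breadth_self: float,
    breadth_opposite: float,
    params: PAVParams = PAVParams(),
) -> str:
    """'present', 'lost', or 'within-HE' from the two breadth fractions."""
    if breadth_self < params.lost_thresh:
        if breadth_opposite > params.he_thresh:
            return "within-HE"
        return "lost"
    return "present"


def sample_gene_status(
    records: Sequence[AlignmentRecord],
    genes: Sequence,
    chrom_lengths: Mapping[str, int],
    params: PAVParams = PAVParams(),
    expected: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Gene status for one sample from its tagged tetraploid alignments.

    Self breadth counts reads whose origin tag agrees with the gene's own
    subgenome; opposite breadth counts discordantly tagged reads
    (ambiguous-origin reads are uninformative and count toward neither).
    Untagged alignments make everything concordant, reducing to plain
    lost/present calling.
    """
    expected = expected or {c: c[-1] for c in chrom_lengths}
    tags = {rec.origin_tag for rec in records if rec is not None}
    if tags == {None}:
        breadth = gene_breadth(records, genes, chrom_lengths)
        return {g.id: call_gene_status(breadth[g.id], 0.0, params) for g in genes}
    out = {}
    for role in ("A", "B"):
        role_genes = [g for g in genes if expected[g.chrom] == role]
        if not role_genes:
            continue
        conc = gene_breadth(records, role_genes, chrom_lengths, tag_in={role, None})
        opp = "B" if role == "A" else "A"
        disc = gene_breadth(records, role_genes, chrom_lengths, tag_in={opp})
        for g in role_genes:
            out[g.id] = call_gene_status(conc[g.id], disc[g.id], params)
    return out


def core_dispensable(status: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Split the gene universe into core and dispensable sets.

    ``status`` is genes x samples with values in
    {'present', 'lost', 'within-HE'}; a ragged table (missing values) is an
    error. Core genes are present in every sample; the rest are
    dispensable. The two sets partition the universe.
    """
    if status.isna().any().any():
        raise ValueError("ragged status table")
    bad = ~status.isin(["present", "lost", "within-HE"]).all(axis=1)
    if bad.any():
        raise ValueError("unknown status values")
    core = set(status.index[(status == "present").all(axis=1)])
    dispensable = set(status.index) - core
    return core, dispensable


# ---------------------------------------------------------------------------
# depth profiling and CNV segmentation
# ---------------------------------------------------------------------------


def depth_profile(
    records: Sequence[AlignmentRecord],
    chrom_lengths: Mapping[str, int],
    window: int = 10_000,
) -> tuple[dict[str, np.ndarray], float, float]:
    """Median-normalized mean depth per window, plus the raw genome-wide
    mean and median window depths (the two guide lines of the coverage
    plots)."""
    if sum(chrom_lengths.values()) == 0:
        raise ValueError("zero-length genome")
    cov = _coverage_arrays(records, chrom_lengths)
    raw: dict[str, np.ndarray] = {}
    allw = []
    for c, arr in cov.items():
        nw = -(-arr.size // window)
        pad = np.pad(arr.astype(np.float64), (0, nw * window - arr.size), constant_values=np.nan)
        raw[c] = np.nanmean(pad.reshape(nw, window), axis=1)
        allw.append(raw[c])
    flat = np.concatenate(allw)
    med = float(np.median(flat))
    mean = float(np.mean(flat))
    if med == 0:
        raise ValueError("median window depth is zero; cannot normalize")
    return {c: a / med for c, a in raw.items()}, mean, med


def segment_cnv(
    profile: Mapping[str, np.ndarray],
    params: CNVParams = CNVParams(),
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[CNVSegment]:
    """Quantize windows to the nearest copy state and merge runs.

    Windows farther than ``state_tolerance`` from every state are no-calls
    and inherit the nearest called neighbor (leftward preference). Runs of
    equal state become segments; segments shorter than ``min_segment`` are
    absorbed into the longer flanking neighbor. Segments partition each
    chromosome exactly.
    """
    states = np.array(params.states)
    segs: list[CNVSegment] = []
    for chrom, prof in profile.items():
        nw = prof.size
        if nw == 0:
            continue
        dist = np.abs(prof[:, None] - states[None, :])
        nearest = np.argmin(dist, axis=1)
        called = dist[np.arange(nw), nearest] <= params.state_tolerance
        st = states[nearest].astype(float)
        st[~called] = np.nan
        if np.isnan(st).all():
            st[:] = 1.0
        else:
            # forward fill, then backward fill for a leading no-call run
            last = None
            for i in range(nw):
                if not np.isnan(st[i]):
                    last = st[i]
                elif last is not None:
                    st[i] = last
            nxt = None
            for i in range(nw - 1, -1, -1):
                if not np.isnan(st[i]):
                    nxt = st[i]
                elif nxt is not None:
                    st[i] = nxt
        runs: list[list] = []
        for i in range(nw):
            if runs and runs[-1][2] == st[i]:
                runs[-1][1] = i + 1
            else:
                runs.append([i, i + 1, st[i]])
        win = params.window
        changed = True
        while changed and len(runs) > 1:
            changed = False
            for j, r in enumerate(runs):
                if (r[1] - r[0]) * win < params.min_segment:
                    ln = runs[j - 1] if j > 0 else None
                    rn = runs[j + 1] if j + 1 < len(runs) else None
                    tgt = max(
                        (x for x in (ln, rn) if x is not None),
                        key=lambda x: x[1] - x[0],
                    )
                    r[2] = tgt[2]
                    merged = []
                    for rr in runs:
                        if merged and merged[-1][2] == rr[2]:
                            merged[-1][1] = rr[1]
                        else:
                            merged.append(rr)
                    runs = merged
                    changed = True
                    break
        clamp = chrom_lengths.get(chrom, nw * win) if chrom_lengths else nw * win
        for s_w, e_w, state in runs:
            segs.append(
                CNVSegment(
                    chrom=chrom,
                    start=s_w * win,
                    end=min(e_w * win, clamp),
                    state=float(state),
                    mean_depth=float(np.nanmean(prof[s_w:e_w])),
                )
            )
    return segs


def refine_breakpoints(
    segments: Sequence[CNVSegment],
    split_records: Sequence[AlignmentRecord],
    search: int | None = None,
    cluster_radius: int = 500,
    min_support: int = 2,
) -> list[CNVSegment]:
    """Snap segment boundaries to clustered split-read clip positions.

    Depth segmentation places boundaries only to window precision, so each
    boundary of a non-reference-state segment is searched within ``search``
    bp (default: the depth window, inferred from the coarsest boundary
    spacing, plus 500) for a cluster of >= ``min_support`` split reads
    whose clip positions agree within ``cluster_radius`` bp. The boundary
    moves to the modal clip position; the partner locus becomes the modal
    clipped-partner locus (linking, e.g., a duplication to the homoeologous
    deleted region it resides in). Boundaries without split support stay
    where depth put them and are flagged approximate.
    """
    if search is None:
        gcd = 0
        for seg in segments:
            gcd = np.gcd(gcd, np.gcd(seg.start, seg.end))
        search = int(gcd if gcd > 0 else 10_000) + cluster_radius
    # every junction read supports both breakends: its clip position, and
    # the locus its clipped tail re-aligned to
    clips: dict[str, list[tuple[int, tuple[str, int]]]] = {}
    for rec in split_records:
        if rec is None or rec.clipped_partner is None:
            continue
        if rec.soft_right >= rec.soft_left:
            pos = rec.ref_end
        else:
            pos = rec.ref_start
        clips.setdefault(rec.ref_name, []).append((pos, rec.clipped_partner))
        pc, pp = rec.clipped_partner
        clips.setdefault(pc, []).append((pp, (rec.ref_name, pos)))
    out = []
    for seg in segments:
        seg = CNVSegment(**{**seg.__dict__})
        cand = clips.get(seg.chrom, []) if seg.state != 1.0 else []
        for side in ("left", "right"):
            b = seg.start if side == "left" else seg.end
            near = [(p, pt) for p, pt in cand if abs(p - b) <= search]
            if not near:
                continue
            modal_pos = Counter(p for p, _ in near).most_common(1)[0][0]
            cluster = [(p, pt) for p, pt in near if abs(p - modal_pos) <= cluster_radius]
            if len(cluster) < min_support:
                continue
            modal_partner = Counter(pt for _, pt in cluster).most_common(1)[0][0]
            if side == "left":
                seg.start = modal_pos
                seg.left_exact = True
            else:
                seg.end = modal_pos
                seg.right_exact = True
            seg.partner = modal_partner
        out.append(seg)
    # keep the partition: neighbors share refined boundaries
    out.sort(key=lambda s: (s.chrom, s.start))
    for s1, s2 in zip(out, out[1:]):
        if s1.chrom == s2.chrom:
            if s2.left_exact and not s1.right_exact:
                s1.end = s2.start
                s1.right_exact = True
            elif s1.right_exact and not s2.left_exact:
                s2.start = s1.end
                s2.left_exact = True
    return out
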