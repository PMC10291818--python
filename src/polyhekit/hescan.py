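"""Subgenome painting and homoeologous-exchange (HE) block calling.

Origin-tagged alignments on the tetraploid are binned into fixed windows
(counts of A-, B-, ambiguous- and novel-tagged reads). Windows whose reads
overwhelmingly carry the *wrong* parent's tag for their chromosome seed HE
blocks; nearby seeds merge and short blocks are dropped. Long reads allow painting
per coordinate; with short reads windowed majority voting is the stable
equivalent, so every threshold lives in :class:`HECallParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alnio import AlignmentRecord


@dataclass(frozen=True)
class HECallParams:
    w: int = 1000  # window size (bp)
    min_frac: float = 0.8  # discordant fraction to seed a block
    min_reads: int = 5  # informative reads per window
    min_len: int = 2000  # minimum block length (bp)
    merge_gap: int = 2000  # max gap between merged seed runs (bp)

    def __post_init__(self):
        if not 0.5 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0.5, 1]")
        if min(self.w, self.min_len, self.merge_gap, self.min_reads) <= 0:
            raise ValueError("window/length parameters must be positive")


@dataclass
class OriginTrack:
    """Per-window origin counts for every chromosome."""

    w: int
    chrom_lengths: dict[str, int]
    n_a: dict[str, np.ndarray] = field(default_factory=dict)
    n_b: dict[str, np.ndarray] = field(default_factory=dict)
    n_u: dict[str, np.ndarray] = field(default_factory=dict)
    n_novel: dict[str, np.ndarray] = field(default_factory=dict)

    def n_windows(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.w)

    def total_counted(self) -> int:
        return int(
            sum(
                arr.sum()
                for d in (self.n_a, self.n_b, self.n_u, self.n_novel)
                for arr in d.values()
            )
        )


@dataclass
class HEBlock:
    chrom: str
    start: int
    end: int
    donor: str
    recipient: str
    mean_discordant_frac: float
    supporting_reads: int

    @property
    def length(self) -> int:
        return self.end - self.start


def paint(
    records: Sequence[AlignmentRecord],
    chrom_lengths: Mapping[str, int],
    params: HECallParams = HECallParams(),
) -> OriginTrack:
    """Bin origin-tagged primary alignments into windows of their start.

    Ambiguous-placement alignments are excluded (they carry no positional
    information); total window counts equal the number of included
    alignments.
    """
    w = params.w
    track = OriginTrack(w=w, chrom_lengths=dict(chrom_lengths))
    for chrom, L in chrom_lengths.items():
        nw = -(-L // w)
        track.n_a[chrom] = np.zeros(nw, dtype=np.int64)
        track.n_b[chrom] = np.zeros(nw, dtype=np.int64)
        track.n_u[chrom] = np.zeros(nw, dtype=np.int64)
        track.n_novel[chrom] = np.zeros(nw, dtype=np.int64)
    for rec in records:
        if rec is None or not rec.is_primary or rec.ambiguous_placement:
            continue
        if rec.ref_name not in track.n_a:
            raise ValueError(f"alignment to unknown chromosome {rec.ref_name}")
        wi = rec.ref_start // w
        tag = rec.origin_tag
        if tag == "A":
            track.n_a[rec.ref_name][wi] += 1
        elif tag == "B":
            track.n_b[rec.ref_name][wi] += 1
        elif tag == "N":
            track.n_novel[rec.ref_name][wi] += 1
        else:
            track.n_u[rec.ref_name][wi] += 1
    return track


def call_blocks(
    track: OriginTrack,
    expected: Mapping[str, str],
    params: HECallParams = HECallParams(),
    records: Sequence[AlignmentRecord] | None = None,
) -> list[HEBlock]:
    """Call HE blocks where window origin contradicts the expected parent.

    Seed windows have >= ``min_reads`` informative (A+B) reads and a
    discordant fraction >= ``min_frac``; seed runs separated by
    <= ``merge_gap`` merge; merged blocks shorter than ``min_len`` are
    dropped. If ``records`` is supplied, block boundaries are refined to
    the outermost discordant read extents within one window of the seeds.
    """
    w = track.w
    by_chrom: dict[str, list[AlignmentRecord]] = {}
    if records is not None:
        for rec in records:
            if rec is None or not rec.is_primary or rec.ambiguous_placement:
                continue
            by_chrom.setdefault(rec.ref_name, []).append(rec)
    blocks: list[HEBlock] = []
    for chrom in track.chrom_lengths:
        if chrom not in expected:
            raise ValueError(f"no expected origin for chromosome {chrom}")
        exp = expected[chrom]
        na, nb = track.n_a[chrom], track.n_b[chrom]
        disc = nb if exp == "A" else na
        tot = na + nb
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, disc / np.maximum(tot, 1), 0.0)
        seeds = (tot >= params.min_reads) & (frac >= params.min_frac)
        idx = np.nonzero(seeds)[0]
        if idx.size == 0:
            continue
        gap_w = params.merge_gap // w
        runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
        for i in idx[1:]:
            if int(i) - runs[-1][1] - 1 <= gap_w:
                runs[-1][1] = int(i)
            else:
                runs.append([int(i), int(i)])
        donor = "B" if exp == "A" else "A"
        for s_w, e_w in runs:
            start = s_w * w
            end = min((e_w + 1) * w, track.chrom_lengths[chrom])
            if end - start < params.min_len:
                continue
            if chrom in by_chrom:
                lo, hi = start, end
                for rec in by_chrom[chrom]:
                    if rec.origin_tag != donor:
                        continue
                    if start - w <= rec.ref_start < start + w:
                        lo = min(lo, rec.ref_start)
                    if end - w <= rec.ref_end <= end + w:
                        hi = max(hi, rec.ref_end)
                start, end = lo, hi
            sel = slice(s_w, e_w + 1)
            support = int(disc[sel].sum())
            informative = int(tot[sel].sum())
            blocks.append(
                HEBlock(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    donor=donor,
                    recipient=exp,
                    mean_discordant_frac=float(disc[sel].sum() / max(informative, 1)),
                    supporting_reads=support,
                )
            )
    blocks.sort(key=lambda b: (b.chrom, b.start))
    return blocks


def coordinate_class(
    track: OriginTrack,
    expected: Mapping[str, str],
    params: HECallParams = HECallParams(),
) -> pd.DataFrame:
    """Label every window infirma-derived (A), supina-derived (B), novel,
    or no-call, by majority origin among informative reads."""
    rows = []
    for chrom in track.chrom_lengths:
        if chrom not in expected:
            raise ValueError(f"no expected origin for chromosome {chrom}")
        na, nb, nn = track.n_a[chrom], track.n_b[chrom], track.n_novel[chrom]
        for wi in range(track.n_windows(chrom)):
            a, b, nv = int(na[wi]), int(nb[wi]), int(nn[wi])
            if nv > a + b and nv >= params.min_reads:
                label = "novel"
            elif a + b < params.min_reads:
                label = "no-call"
            elif a >= b:
                label = "infirma-derived" if a > b else "no-call"
            else:
                label = "supina-derived"
            rows.append(
                dict(
                    chrom=chrom,
                    start=wi * track.w,
                    end=min((wi + 1) * track.w, track.chrom_lengths[chrom]),
                    label=label,
                )
            )
    return pd.DataFrame(rows)


def he_gene_overlap(
    blocks: Sequence[HEBlock],
    genes: Sequence,
    min_overlap: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene HE status (>= 50% of the gene inside a block) and
    directional counts for the bias statistics."""
    rows = []
    counts = {"AtoB": 0, "BtoA": 0}
    for g in genes:
        within = False
        direction = None
        for b in blocks:
            if b.chrom != g.chrom:
                continue
            ov = min(g.end, b.end) - max(g.start, b.start)
            if ov > 0 and ov / (g.end - g.start) >= min_overlap:
                within = True
                direction = f"{b.donor}to{b.recipient}"
                break
        if within:
            counts[direction] += 1
        rows.append(dict(gene=g.id, chrom=g.chrom, within_he=within, direction=direction))
    return pd.DataFrame(rows), counts


def blocks_to_bed(blocks: Sequence[HEBlock]) -> list[tuple]:
    """Sorted BED-ready tuples (chrom, start, end, donor->recipient)."""
    return [
        (b.chrom, b.start, b.end, f"{b.donor}to{b.recipient}", b.supporting_reads)
        for b in sorted(blocks, key=lambda b: (b.chrom, b.start))
    ]
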