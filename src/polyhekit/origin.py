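"""Parent-of-origin read classification.

Two strategies, mirroring the two data types they are canonical for:

* :func:`classify_read_llr` -- per-read log-likelihood ratio over
  diagnostic variants between the two parental homoeologs (the RNA-read
  route). With per-base error probability ``eps``, a read base b at a
  diagnostic site contributes log P(b|A) - log P(b|B) where
  P(b|o) = 1 - eps if b matches parent o's allele and eps/3 otherwise.
* :func:`classify_by_primary_mapping` -- competitive mapping of each read
  against a concatenation of both parental genomes; the parent owning the
  best-scoring primary alignment wins (the DNA-read / HE route). Score
  ties are ambiguous; the reported "llr" is the raw score difference and
  is *not* on the probabilistic scale.

A read drawn from inside an A-to-B homoeologous exchange maps best to
parent A although it resides on a B chromosome -- that discordance is the
HE signal picked up downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alnio import AlignmentRecord, KmerIndex, decode, map_reads

GAP_EXCLUSION = 2  # diagnostic sites closer than this to an alignment gap are dropped
MIN_PAIR_IDENTITY = 0.80


@dataclass(frozen=True)
class DiagnosticVariant:
    """A position where the two parental sequences carry different bases."""

    pair_id: str
    pos_a: int
    pos_b: int
    allele_a: str
    allele_b: str

    def __post_init__(self):
        if self.allele_a == self.allele_b:
            raise ValueError("diagnostic variant alleles must differ")


@dataclass(frozen=True)
class ClassifierParams:
    eps: float = 0.01  # per-base error probability
    tau: float = math.log(10.0)  # |llr| needed for a call
    min_sites: int = 1

    def __post_init__(self):
        if not 0 < self.eps < 0.25:
            raise ValueError("eps must be in (0, 0.25)")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass(frozen=True)
class OriginCall:
    read_id: str
    origin: str  # 'A', 'B' or 'U' (ambiguous)
    llr: float  # log-likelihood ratio of A over B (or score difference)
    n_sites: int = 0


# ---------------------------------------------------------------------------
# diagnostic variants
# ---------------------------------------------------------------------------


def _anchor_align(a: str, b: str, k: int = 21) -> tuple[str, str]:
    """Anchor-and-extend pairwise alignment of near-identical sequences.

    Unique shared k-mers are chained collinearly; equal-length inter-anchor
    segments are aligned column-wise, unequal ones are padded with gaps
    (their columns are excluded from variant calling anyway).
    """
    if len(a) == len(b):
        return a, b

    def kmer_map(s):
        m: dict[str, int] = {}
        seen = set()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if w in seen:
                m.pop(w, None)
            else:
                seen.add(w)
                m[w] = i
        return m

    ma, mb = kmer_map(a), kmer_map(b)
    shared = sorted((ia, mb[w]) for w, ia in ma.items() if w in mb)
    # longest strictly increasing chain in the second coordinate
    chain: list[tuple[int, int]] = []
    for ia, ib in shared:
        if not chain or (ia > chain[-1][0] and ib > chain[-1][1]):
            chain.append((ia, ib))
    out_a, out_b = [], []
    pa = pb = 0
    for ia, ib in chain + [(len(a), len(b))]:
        sa, sb = a[pa:ia], b[pb:ib]
        if len(sa) == len(sb):
            out_a.append(sa)
            out_b.append(sb)
        else:
            n = max(len(sa), len(sb))
            out_a.append(sa + "-" * (n - len(sa)))
            out_b.append(sb + "-" * (n - len(sb)))
        if ia < len(a):
            out_a.append(a[ia : ia + k])
            out_b.append(b[ib : ib + k])
            pa, pb = ia + k, ib + k
    return "".join(out_a), "".join(out_b)


def find_diagnostic_variants(
    seq_a: str,
    seq_b: str,
    pair_id: str = "pair",
    aligned: bool = False,
) -> list[DiagnosticVariant]:
    """Column-wise variants between homologous parental sequences.

    Pass pre-aligned sequences (with ``-`` gaps) via ``aligned=True``;
    otherwise a k-mer anchor alignment is computed internally. Columns
    inside or within ``GAP_EXCLUSION`` bp of a gap are excluded. Raises if
    alignment identity falls below 80% -- the sequences are then too
    diverged for diagnostic-site classification.
    """
    if aligned:
        aa, ab = seq_a.upper(), seq_b.upper()
        if len(aa) != len(ab):
            raise ValueError("aligned sequences must have equal length")
    else:
        aa, ab = _anchor_align(seq_a.upper(), seq_b.upper())
    cols = len(aa)
    gap_mask = np.zeros(cols, dtype=bool)
    for i in range(cols):
        if aa[i] == "-" or ab[i] == "-":
            gap_mask[max(0, i - GAP_EXCLUSION) : i + GAP_EXCLUSION + 1] = True
    matched = sum(1 for x, y in zip(aa, ab) if x == y and x != "-")
    comparable = sum(1 for x, y in zip(aa, ab) if x != "-" and y != "-")
    if comparable == 0 or matched / comparable < MIN_PAIR_IDENTITY:
        raise ValueError(
            f"alignment identity {matched / max(comparable, 1):.2f} below "
            f"{MIN_PAIR_IDENTITY:.0%}; sequences not homologous enough"
        )
    out = []
    pa = pb = 0
    for i in range(cols):
        ca, cb = aa[i], ab[i]
        if ca != "-" and cb != "-" and ca != cb and not gap_mask[i]:
            out.append(DiagnosticVariant(pair_id, pa, pb, ca, cb))
        if ca != "-":
            pa += 1
        if cb != "-":
            pb += 1
    return out


def write_vcf(path, variants: Sequence[DiagnosticVariant], contig: str = "A") -> None:
    """Minimal VCF export of diagnostic variants on the A coordinate."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##INFO=<ID=PB,Number=1,Type=Integer,Description=\"Position on B\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{contig}\t{v.pos_a + 1}\t{v.pair_id}\t{v.allele_a}\t{v.allele_b}"
                f"\t.\t.\tPB={v.pos_b + 1}\n"
            )


# ---------------------------------------------------------------------------
# likelihood classification
# ---------------------------------------------------------------------------


def classify_read_llr(
    record: AlignmentRecord,
    variants: Sequence[DiagnosticVariant],
    params: ClassifierParams = ClassifierParams(),
    side: str = "A",
) -> OriginCall:
    """Classify one aligned read by its bases at covered diagnostic sites.

    ``record`` is an alignment of the read to one parental coordinate
    system (``side``); only sites inside the aligned (non-clipped) segment
    are used. Fewer than ``min_sites`` covered sites forces ambiguous.
    """
    if record is None:
        return OriginCall("unmapped", "U", 0.0, 0)
    seq = decode(record.seq_codes) if record.seq_codes is not None else None
    if seq is None:
        raise ValueError("record lacks sequence; map with store_seq=True")
    match_term = math.log((1 - params.eps) / (params.eps / 3.0))
    llr = 0.0
    n = 0
    for v in variants:
        pos = v.pos_a if side == "A" else v.pos_b
        off = pos - record.ref_start
        if 0 <= off < record.aln_len:
            b = seq[record.soft_left + off]
            n += 1
            if b == v.allele_a:
                llr += match_term
            elif b == v.allele_b:
                llr -= match_term
    if n < params.min_sites or abs(llr) <= params.tau:
        return OriginCall(record.read_id, "U", llr, n)
    return OriginCall(record.read_id, "A" if llr > 0 else "B", llr, n)


def classify_reads_llr(
    records: Sequence[AlignmentRecord | None],
    variants: Sequence[DiagnosticVariant],
    params: ClassifierParams = ClassifierParams(),
    side: str = "A",
) -> list[OriginCall]:
    """Vectorized :func:`classify_read_llr` over many alignments to one
    parental coordinate system."""
    from .alnio import encode as _enc

    pos = np.array([v.pos_a if side == "A" else v.pos_b for v in variants], dtype=np.int64)
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    al_a = np.array([_enc(v.allele_a)[0] for v in variants], dtype=np.uint8)[order]
    al_b = np.array([_enc(v.allele_b)[0] for v in variants], dtype=np.uint8)[order]
    term = math.log((1 - params.eps) / (params.eps / 3.0))
    out = []
    for rec in records:
        if rec is None:
            out.append(OriginCall("unmapped", "U", 0.0, 0))
            continue
        lo = int(np.searchsorted(pos, rec.ref_start, side="left"))
        hi = int(np.searchsorted(pos, rec.ref_start + rec.aln_len, side="left"))
        n = hi - lo
        if n == 0:
            out.append(OriginCall(rec.read_id, "U", 0.0, 0))
            continue
        offs = pos[lo:hi] - rec.ref_start + rec.soft_left
        bases = rec.seq_codes[offs]
        llr = term * (
            int(np.count_nonzero(bases == al_a[lo:hi])) - int(np.count_nonzero(bases == al_b[lo:hi]))
        )
        if n < params.min_sites or abs(llr) <= params.tau:
            out.append(OriginCall(rec.read_id, "U", llr, n))
        else:
            out.append(OriginCall(rec.read_id, "A" if llr > 0 else "B", llr, n))
    return out


# ---------------------------------------------------------------------------
# competitive primary mapping
# ---------------------------------------------------------------------------


def role_of_reference(name: str) -> str:
    """Subgenome letter encoded as the trailing A/B of a sequence name."""
    base = name.split("|")[0]
    return base[-1] if base and base[-1] in "AB" else "?"


def classify_by_primary_mapping(
    reads,
    parents_index: KmerIndex,
    read_ids: Sequence[str] | None = None,
    records: Sequence[AlignmentRecord | None] | None = None,
) -> tuple[list[OriginCall], list[AlignmentRecord | None]]:
    """Competitively map reads against both parents and call the winner.

    The index must span a concatenation of both parental genomes with
    reference names ending in their subgenome letter. Returns the calls and
    the parent alignments (for reuse). Pre-computed ``records`` (mapped
    with ``group_fn=role_of_reference``) are accepted to skip remapping.
    """
    if records is None:
        records = map_reads(reads, parents_index, read_ids=read_ids, group_fn=role_of_reference)
    calls: list[OriginCall] = []
    for i, rec in enumerate(records):
        rid = rec.read_id if rec is not None else (read_ids[i] if read_ids else f"read{i}")
        if rec is None:
            calls.append(OriginCall(rid, "N", 0.0, 0))  # mapped to neither parent
            continue
        groups = rec.alt_scores or {}
        sa = groups.get("A")
        sb = groups.get("B")
        if sa is None and sb is None:
            calls.append(OriginCall(rid, "U", 0.0, 0))
        elif sb is None:
            calls.append(OriginCall(rid, "A", float(sa), 0))
        elif sa is None:
            calls.append(OriginCall(rid, "B", float(-sb), 0))
        elif sa == sb:
            calls.append(OriginCall(rid, "U", 0.0, 0))
        else:
            calls.append(OriginCall(rid, "A" if sa > sb else "B", float(sa - sb), 0))
    return calls, list(records)


def tag_and_remap(
    reads,
    calls: Mapping[str, OriginCall] | Sequence[OriginCall],
    tetraploid_index: KmerIndex,
    read_ids: Sequence[str] | None = None,
) -> list[AlignmentRecord]:
    """Re-map reads to the tetraploid and attach their origin tags.

    Every mapped read must have an origin call ('A', 'B', 'U' ambiguous, or
    'N' unmapped on both parents = novel); a missing call is an error.
    """
    if not isinstance(calls, Mapping):
        calls = {c.read_id: c for c in calls}
    records = map_reads(reads, tetraploid_index, read_ids=read_ids)
    out = []
    for rec in records:
        if rec is None:
            continue
        call = calls.get(rec.read_id)
        if call is None:
            raise ValueError(f"no origin call for read {rec.read_id}")
        rec.origin_tag = call.origin
        out.append(rec)
    return out
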