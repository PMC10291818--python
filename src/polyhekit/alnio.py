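"""Sequence/annotation I/O and a minimal deterministic read mapper.

The mapper is an exact-k-mer seed-and-extend aligner (ungapped, M/S CIGARs
only) so the whole pipeline runs without external binaries. Externally
produced SAM is accepted as an alternative backend through :func:`read_sam`.

Coordinates are 0-based half-open everywhere in memory; GFF3 is written
1-based closed per the standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

# ---------------------------------------------------------------------------
# DNA codec
# ---------------------------------------------------------------------------

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return _DEC[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[np.asarray(codes, dtype=np.uint8)][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode(seq)
    return np.asarray(seq, dtype=np.uint8)


# ---------------------------------------------------------------------------
# Alignment record
# ---------------------------------------------------------------------------


@dataclass
class AlignmentRecord:
    """One ungapped alignment: reference span plus soft-clipped tails.

    ``clipped_partner`` is the junction-side locus where the soft-clipped
    tail re-aligns (split read): for a right clip it is the partner's start,
    for a left clip the partner's end, so that deletion/duplication
    junctions point at the far breakpoint.
    """

    read_id: str
    ref_name: str
    ref_start: int
    strand: str  # '+' or '-'
    aln_len: int
    mismatches: int
    score: int
    soft_left: int = 0
    soft_right: int = 0
    clipped_partner: tuple[str, int] | None = None
    is_primary: bool = True
    ambiguous_placement: bool = False
    origin_tag: str | None = None
    seq_codes: np.ndarray | None = field(default=None, repr=False)
    alt_scores: dict | None = field(default=None, repr=False)

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.aln_len

    @property
    def read_len(self) -> int:
        return self.soft_left + self.aln_len + self.soft_right


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------


def _horner_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Pack k consecutive 2-bit bases into int64 keys, row-wise."""
    out = np.zeros(mat.shape[:-1] + (mat.shape[-1] - k + 1,), dtype=np.int64)
    n = mat.shape[-1] - k + 1
    for j in range(k):
        out *= 4
        out += mat[..., j : j + n]
    return out


class KmerIndex:
    """Exact k-mer -> position index over both strands of a genome.

    Only the forward strand is stored; queries look up the read and its
    reverse complement. Positions are in a concatenated coordinate space;
    :meth:`pos_to_ref` converts back to (name, local position).
    """

    def __init__(self, seqs: Mapping[str, object], k: int = 17, max_hits: int = 32):
        if not 8 <= k <= 31:
            raise ValueError(f"k must be in [8, 31], got {k}")
        names, lengths, offsets, parts = [], [], [], []
        off = 0
        for name, s in seqs.items():
            codes = _as_codes(s)
            names.append(name)
            lengths.append(codes.size)
            offsets.append(off)
            parts.append(codes)
            off += codes.size
        if off == 0:
            raise ValueError("cannot index an empty genome")
        self.k = k
        self.max_hits = max_hits
        self.names = names
        self.lengths = np.array(lengths, dtype=np.int64)
        self.offsets = np.array(offsets, dtype=np.int64)
        self.cat = np.concatenate(parts)
        total = self.cat.size
        if total < k:
            raise ValueError("genome shorter than k")
        keys = _horner_codes(self.cat, k)
        valid = np.ones(total - k + 1, dtype=bool)
        for o in self.offsets[1:]:
            valid[max(0, o - k + 1) : o] = False  # windows crossing a boundary
        bad = np.concatenate(([0], np.cumsum(self.cat > 3)))
        valid &= (bad[k:] - bad[:-k]) == 0
        pos = np.nonzero(valid)[0]
        keys = keys[pos]
        order = np.argsort(keys, kind="stable")
        self._keys = keys[order]
        self._pos = pos[order].astype(np.int64)

    def pos_to_ref(self, pos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, pos, side="right")) - 1
        return self.names[i], int(pos - self.offsets[i])

    def ref_bounds(self, pos: int) -> tuple[int, int, int]:
        """(ref index, concatenated start, concatenated end) containing pos."""
        i = int(np.searchsorted(self.offsets, pos, side="right")) - 1
        return i, int(self.offsets[i]), int(self.offsets[i] + self.lengths[i])

    def lookup(self, kmer: str) -> np.ndarray:
        codes = encode(kmer)
        if codes.size != self.k or (codes > 3).any():
            raise ValueError("bad k-mer")
        key = 0
        for c in codes:
            key = key * 4 + int(c)
        lo = int(np.searchsorted(self._keys, key, side="left"))
        hi = int(np.searchsorted(self._keys, key, side="right"))
        return np.sort(self._pos[lo:hi])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, KmerIndex)
            and self.k == other.k
            and self.names == other.names
            and np.array_equal(self._keys, other._keys)
            and np.array_equal(self._pos, other._pos)
        )


def build_index(seqs: Mapping[str, object], k: int = 17, max_hits: int = 32) -> KmerIndex:
    """Build the exact k-mer index (8 <= k <= 31) over a genome."""
    return KmerIndex(seqs, k=k, max_hits=max_hits)


# ---------------------------------------------------------------------------
# seed-and-extend mapping
# ---------------------------------------------------------------------------

MIN_SCORE = 40  # matches - 2*mismatches; ~a clean 40 bp anchor
PARTNER_MIN = 20  # smallest soft clip worth a split-read partner search


def _seed_offsets(read_len: int, k: int, n: int = 5) -> np.ndarray:
    span = read_len - k
    n = max(2, min(n, span + 1)) if span >= 1 else 1
    return np.unique(np.round(np.linspace(0, span, n)).astype(np.int64))


def _locate_segment(index: KmerIndex, codes: np.ndarray) -> tuple[str, int, int] | None:
    """Ungapped placement of a short segment (split-read partner search)."""
    L = codes.size
    k = index.k
    if L < k:
        return None
    best = None
    offs = [0, L - k] if L > k else [0]
    seen = set()
    for off in offs:
        key = 0
        for c in codes[off : off + k]:
            if c > 3:
                key = -1
                break
            key = key * 4 + int(c)
        if key < 0:
            continue
        lo = int(np.searchsorted(index._keys, key, side="left"))
        hi = int(np.searchsorted(index._keys, key, side="right"))
        if hi - lo == 0 or hi - lo > index.max_hits:
            continue
        for p in index._pos[lo:hi]:
            d = int(p) - off
            if d in seen:
                continue
            seen.add(d)
            _, co, ce = index.ref_bounds(int(p))
            if d < co or d + L > ce:
                continue
            mm = int(np.count_nonzero(index.cat[d : d + L] != codes))
            if mm > 0.1 * L + 1:
                continue
            score = L - 3 * mm
            cand = (score, -d)
            if best is None or cand > best[0]:
                best = (cand, d)
    if best is None:
        return None
    d = best[1]
    name, local = index.pos_to_ref(d)
    return name, local, local + L


def map_reads(
    reads,
    index: KmerIndex,
    read_ids: Sequence[str] | None = None,
    min_score: int = MIN_SCORE,
    partner_min: int = PARTNER_MIN,
    store_seq: bool = True,
    group_fn=None,
) -> list[AlignmentRecord | None]:
    """Map a batch of equal-length reads; returns one record (or None) per read.

    Seeds are exact k-mers at fixed offsets; loci need a chain of >= 2 seeds
    on one diagonal (ungapped, so diagonals are exact). The best-scoring
    locus (score = matches - 2*mismatches over the retained segment) is the
    primary alignment; score ties are broken by (reference name, position)
    and flagged as ambiguous placement. Unextendable tails become soft
    clips; clips >= ``partner_min`` are re-seeded to find a split-read
    partner. With ``group_fn`` the best score per reference group is kept
    on ``alt_scores`` (used for competitive parent classification).
    """
    if isinstance(reads, np.ndarray):
        mat = reads
    else:
        seqs = list(reads)
        if not seqs:
            return []
        mat = np.vstack([_as_codes(s) for s in seqs])
    n, L = mat.shape
    if read_ids is None:
        read_ids = [f"read{i}" for i in range(n)]
    k = index.k
    if L < k:
        raise ValueError("reads shorter than index k")
    offs = _seed_offsets(L, k)
    min_chain = 2 if offs.size >= 2 else 1
    rev = _COMP[mat][:, ::-1]
    strands = (mat, rev)
    seed_lo, seed_hi = [], []
    for sm in strands:
        codes = np.stack([_horner_codes(sm[:, o : o + k], k)[:, 0] for o in offs], axis=1)
        # windows containing non-ACGT bases get an impossible key
        badbase = np.stack([(sm[:, o : o + k] > 3).any(axis=1) for o in offs], axis=1)
        codes[badbase] = -1
        seed_lo.append(np.searchsorted(index._keys, codes, side="left"))
        seed_hi.append(np.searchsorted(index._keys, codes, side="right"))

    group_names = None
    if group_fn is not None:
        group_names = [group_fn(nm) for nm in index.names]

    cat = index.cat
    ipos = index._pos
    max_hits = index.max_hits
    out: list[AlignmentRecord | None] = []
    for i in range(n):
        cands: dict[tuple[int, int], list[int]] = {}
        for si in range(2):
            lo_row = seed_lo[si][i]
            hi_row = seed_hi[si][i]
            for oi in range(offs.size):
                cnt = hi_row[oi] - lo_row[oi]
                if cnt == 0 or cnt > max_hits:
                    continue
                o = int(offs[oi])
                for p in ipos[lo_row[oi] : hi_row[oi]]:
                    d = int(p) - o
                    if d < 0:
                        continue
                    entry = cands.get((si, d))
                    if entry is None:
                        cands[(si, d)] = [1, o, o]
                    else:
                        entry[0] += 1
                        entry[2] = o
        best = None
        best_key = None
        n_best_ties = 0
        groups: dict | None = {} if group_fn is not None else None
        for (si, d), (cnt, omin, omax) in cands.items():
            if cnt < min_chain:
                continue
            ri, co, ce = index.ref_bounds(d + omin)
            a = max(d, co)
            b = min(d + L, ce)
            cola = a - d
            colb = b - d
            row = strands[si][i]
            mm = cat[a:b] != row[cola:colb]
            vals = np.where(mm, -2, 1)
            P = np.concatenate(([0], np.cumsum(vals)))
            s_rel = omin - cola
            e_rel = omax + k - cola
            i_star = int(np.argmin(P[: s_rel + 1]))
            j_star = e_rel + int(np.argmax(P[e_rel:]))
            score = int(P[j_star] - P[i_star])
            if groups is not None:
                g = group_names[ri]
                if score > groups.get(g, -(1 << 30)):
                    groups[g] = score
            if score < min_score:
                continue
            local = a + i_star - int(index.offsets[ri])
            key = (-score, index.names[ri], local)
            if best_key is None or key < best_key:
                if best_key is not None and score == -best_key[0]:
                    n_best_ties += 1
                else:
                    n_best_ties = 0
                best_key = key
                best = dict(
                    si=si,
                    ref=index.names[ri],
                    start=local,
                    aln_len=j_star - i_star,
                    mm=int(np.count_nonzero(mm[i_star:j_star])),
                    score=score,
                    sl=cola + i_star,
                    sr=L - (cola + j_star),
                )
            elif score == -best_key[0]:
                n_best_ties += 1
        if best is None:
            out.append(None)
            continue
        row = strands[best["si"]][i]
        partner = None
        sl, sr = best["sl"], best["sr"]
        if max(sl, sr) >= partner_min:
            if sr >= sl:
                seg = _locate_segment(index, row[L - sr :])
                if seg is not None:
                    partner = (seg[0], seg[1])  # partner start = junction side
            else:
                seg = _locate_segment(index, row[:sl])
                if seg is not None:
                    partner = (seg[0], seg[2])  # partner end = junction side
        rec = AlignmentRecord(
            read_id=read_ids[i],
            ref_name=best["ref"],
            ref_start=best["start"],
            strand="+" if best["si"] == 0 else "-",
            aln_len=best["aln_len"],
            mismatches=best["mm"],
            score=best["score"],
            soft_left=sl,
            soft_right=sr,
            clipped_partner=partner,
            ambiguous_placement=n_best_ties > 0,
            seq_codes=row.copy() if store_seq else None,
            alt_scores=groups,
        )
        out.append(rec)
    return out


def map_read(read, index: KmerIndex, **kw) -> AlignmentRecord | None:
    """Map a single read (convenience wrapper over :func:`map_reads`)."""
    seq = _as_codes(read)
    return map_reads(seq[None, :], index, read_ids=["read0"], **kw)[0]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    with open(path) as fh:
        return {title.split()[0]: seq.upper() for title, seq in SimpleFastaParser(fh)}


def write_fasta(path, seqs: Mapping[str, object], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, s in seqs.items():
            if not isinstance(s, str):
                s = decode(s)
            fh.write(f">{name}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    with open(path) as fh:
        return [(t.split()[0], s, q) for t, s, q in FastqGeneralIterator(fh)]


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------


def write_bed(path, intervals: Iterable[tuple]) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: malformed BED at line {ln}")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise ValueError(f"{path}: malformed BED at line {ln}") from e
            rows.append((f[0], start, end) + tuple(f[3:6]))
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    width = max((len(r) for r in rows), default=3)
    return pd.DataFrame(rows, columns=cols[:width])


def write_gff3(path, features: Iterable) -> None:
    """Write gene/TE features (objects with chrom/start/end/id attributes).

    0-based half-open in memory -> 1-based closed on disk. TE features with
    an ``age`` attribute get an ``ltr_age`` GFF attribute.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            ftype = getattr(f, "ftype", "gene")
            attrs = [f"ID={f.id}"]
            if getattr(f, "age", None) is not None:
                attrs.append(f"ltr_age={f.age:g}")
            if getattr(f, "ltr_length", None) is not None:
                attrs.append(f"ltr_length={f.ltr_length}")
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "polyhekit",
                        ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        getattr(f, "strand", "+"),
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: malformed GFF3 at line {ln}")
            try:
                start, end = int(f[3]) - 1, int(f[4])
            except ValueError as e:
                raise ValueError(f"{path}: malformed GFF3 at line {ln}") from e
            attrs = dict(a.split("=", 1) for a in f[8].split(";") if "=" in a)
            rows.append(
                dict(
                    chrom=f[0],
                    ftype=f[2],
                    start=start,
                    end=end,
                    strand=f[6],
                    id=attrs.get("ID", "."),
                    ltr_age=float(attrs["ltr_age"]) if "ltr_age" in attrs else np.nan,
                    ltr_length=int(attrs["ltr_length"]) if "ltr_length" in attrs else -1,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _sam_header(ref_lengths: Mapping[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": n, "LN": int(l)} for n, l in ref_lengths.items()],
        }
    )


def write_sam(path, records: Iterable[AlignmentRecord], ref_lengths: Mapping[str, int]) -> None:
    """Write records as SAM (M/S CIGARs, NM/AS tags, XO origin, XP partner)."""
    header = _sam_header(ref_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in records:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.reference_name = r.ref_name
            a.reference_start = r.ref_start
            a.mapping_quality = 0 if r.ambiguous_placement else 60
            flag = 0
            if r.strand == "-":
                flag |= 16
            if not r.is_primary:
                flag |= 256
            a.flag = flag
            cig = []
            if r.soft_left:
                cig.append((4, r.soft_left))
            cig.append((0, r.aln_len))
            if r.soft_right:
                cig.append((4, r.soft_right))
            a.cigartuples = cig
            if r.seq_codes is not None:
                a.query_sequence = decode(r.seq_codes)
                a.query_qualities = pysam.qualitystring_to_array("I" * len(a.query_sequence))
            tags = [("NM", r.mismatches), ("AS", r.score)]
            if r.origin_tag is not None:
                tags.append(("XO", r.origin_tag))
            if r.clipped_partner is not None:
                tags.append(("XP", f"{r.clipped_partner[0]},{r.clipped_partner[1]}"))
            a.set_tags(tags)
            fh.write(a)


def read_sam(path) -> list[AlignmentRecord]:
    """Parse a SAM file (ours or external) into AlignmentRecords.

    Only fields the pipeline uses are read; gapped external CIGARs are
    reduced to reference span + terminal soft clips.
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            sl = sr = 0
            ct = a.cigartuples or []
            if ct and ct[0][0] in (4, 5):
                sl = ct[0][1]
            if len(ct) > 1 and ct[-1][0] in (4, 5):
                sr = ct[-1][1]
            nm = a.get_tag("NM") if a.has_tag("NM") else 0
            aln_len = a.reference_end - a.reference_start
            score = a.get_tag("AS") if a.has_tag("AS") else aln_len - 3 * nm
            partner = None
            if a.has_tag("XP"):
                pn, pp = a.get_tag("XP").rsplit(",", 1)
                partner = (pn, int(pp))
            out.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    ref_name=a.reference_name,
                    ref_start=a.reference_start,
                    strand="-" if a.is_reverse else "+",
                    aln_len=aln_len,
                    mismatches=int(nm),
                    score=int(score),
                    soft_left=sl,
                    soft_right=sr,
                    clipped_partner=partner,
                    is_primary=not a.is_secondary,
                    ambiguous_placement=(a.mapping_quality == 0),
                    origin_tag=a.get_tag("XO") if a.has_tag("XO") else None,
                    seq_codes=encode(a.query_sequence) if a.query_sequence else None,
                )
            )
    return out
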