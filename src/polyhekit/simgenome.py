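"""Synthetic allotetraploid generator.

Builds a random ancestor with gene annotations, evolves two parental
lineages under Jukes-Cantor (JC69), inserts subgenome-specific LTR
retrotransposon bursts of known age, concatenates the parents into an
allotetraploid carrying homoeologous exchanges (HEs) at known coordinates,
applies per-sample gene deletions and large duplications/deletions, and
simulates paired-end short reads. Every downstream stage of the pipeline
can therefore be checked against exact ground truth.

Model choices
-------------
* JC69 substitutions only; no indels in the evolver. All structural
  variation enters through LTR insertions, HEs and CNVs.
* Synonymous-capable gene sites (third codon positions, plus first
  positions of Leu/Arg codons) evolve at the full neutral rate; the other
  coding sites at ``coding_rate_fraction`` of it (default 0.2), so Ks
  between homoeologous coding pairs tracks the neutral branch length.
* An LTR element is two identical terminal repeats flanking an internal
  region; after insertion each copy's two repeats evolve independently for
  ``age`` years at ``mu_ltr``, so the expected repeat-pair divergence is
  K = 2*mu_ltr*age -- the quantity the dating module inverts.
* Coordinates are 0-based half-open; read names carry ``|origin=X|`` truth
  tags which analysis modules never look at.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .alnio import decode, encode

STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODON_CODES = [
    (a, b, c)
    for a in range(4)
    for b in range(4)
    for c in range(4)
    if decode(np.array([a, b, c], dtype=np.uint8)) not in STOP_CODONS
]


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LTRBurst:
    role: str  # 'A' or 'B' subgenome the burst belongs to
    age: float  # years before present
    n_copies: int
    element_length: int
    ltr_length: int

    def __post_init__(self):
        if self.role not in ("A", "B"):
            raise ValueError("burst role must be 'A' or 'B'")
        if self.age < 0:
            raise ValueError("burst age must be >= 0")
        if self.element_length < 2 * self.ltr_length:
            raise ValueError("element shorter than its two terminal repeats")


@dataclass(frozen=True)
class HEEvent:
    chrom: str  # recipient tetraploid chromosome, e.g. 'chr1B'
    start: int
    end: int
    donor: str  # 'A' or 'B'

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ValueError("bad HE interval")
        if self.donor not in ("A", "B"):
            raise ValueError("donor must be 'A' or 'B'")


@dataclass(frozen=True)
class CNVEvent:
    sample: str
    chrom: str
    start: int
    end: int
    state: float  # 0, 0.5, 1.5 or 2 copies relative to the reference

    def __post_init__(self):
        if self.state not in (0.0, 0.5, 1.5, 2.0):
            raise ValueError("copy state must be one of 0, 0.5, 1.5, 2")
        if self.end <= self.start or self.start < 0:
            raise ValueError("bad CNV interval")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic allotetraploid.

    Defaults are the toy scale the whole pipeline is exercised at: two 1 Mb
    chromosomes per parent, 200 homoeologous gene pairs, a parental
    divergence of 2*mu*T ~ 0.065 at neutral sites, and LTR bursts at
    ~340 ky (A subgenome) and ~50 ky (B subgenome).
    """

    n_chromosomes: int = 2
    ancestor_length: int = 1_000_000  # per chromosome
    n_genes: int = 200  # total, spread over chromosomes
    gene_length: int = 2400
    substitution_rate: float = 5.76174e-9  # per synonymous site per year
    parent_divergence_years: float = 5.64e6  # per lineage, so 2*mu*T ~ 0.065
    coding_rate_fraction: float = 0.2  # rate scale at nonsynonymous coding sites
    mu_ltr: float = 1.3e-8  # per site per year, for aging LTR repeats
    ltr_bursts: tuple[LTRBurst, ...] = (
        LTRBurst("A", 340_000.0, 150, 26_000, 12_000),
        LTRBurst("B", 50_000.0, 150, 26_000, 12_000),
    )
    he_events: tuple[HEEvent, ...] = ()
    pav_deletions: tuple[tuple[str, str], ...] = ()  # (sample, gene id)
    cnv_events: tuple[CNVEvent, ...] = ()
    read_length: int = 150
    insert_size: int = 350
    depth: float = 15.0
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.ancestor_length < self.genes_per_chrom_max() * self.gene_length:
            raise ValueError(
                f"cannot pack {self.n_genes} genes of {self.gene_length} bp "
                f"into {self.n_chromosomes} x {self.ancestor_length} bp"
            )
        if self.gene_length % 3:
            raise ValueError("gene_length must be a multiple of 3")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length")
        by_chrom: dict[str, list[HEEvent]] = {}
        for ev in self.he_events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for evs in by_chrom.values():
            evs = sorted(evs, key=lambda e: e.start)
            for e1, e2 in zip(evs, evs[1:]):
                if e2.start < e1.end:
                    raise ValueError(f"overlapping HE events on {e1.chrom}")
        by_sc: dict[tuple[str, str], list[CNVEvent]] = {}
        for cv in self.cnv_events:
            by_sc.setdefault((cv.sample, cv.chrom), []).append(cv)
        for evs in by_sc.values():
            evs = sorted(evs, key=lambda e: e.start)
            for e1, e2 in zip(evs, evs[1:]):
                if e2.start < e1.end:
                    raise ValueError("overlapping CNV events in one sample")

    def genes_per_chrom_max(self) -> int:
        return -(-self.n_genes // self.n_chromosomes)


@dataclass
class GeneFeature:
    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    ftype: str = "gene"


@dataclass
class TEFeature:
    id: str
    chrom: str
    start: int
    end: int
    ltr_length: int
    age: float
    strand: str = "+"
    ftype: str = "LTR_retrotransposon"


@dataclass
class ParentalGenome:
    """One diploid genome: sequences, annotations and an ancestor map.

    ``inserts`` records, per chromosome, (ancestor position, length) of
    every inserted element, which defines the piecewise-linear map between
    ancestor and parent coordinates used to find homologous ranges.
    """

    role: str  # 'ancestor', 'A' or 'B'
    seqs: dict[str, np.ndarray]
    genes: list[GeneFeature] = field(default_factory=list)
    tes: list[TEFeature] = field(default_factory=list)
    inserts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(s.size) for c, s in self.seqs.items()}

    def _ins_arrays(self, chrom):
        ins = sorted(self.inserts.get(chrom, []))
        anc = np.array([p for p, _ in ins], dtype=np.int64)
        cum = np.concatenate(([0], np.cumsum([l for _, l in ins]))).astype(np.int64)
        return anc, cum

    def anc_to_parent(self, chrom: str, anc_pos: int) -> int:
        """Parent coordinate of an ancestor position (after local inserts)."""
        anc, cum = self._ins_arrays(chrom)
        i = int(np.searchsorted(anc, anc_pos, side="right"))
        return int(anc_pos + cum[i])

    def parent_to_anc(self, chrom: str, pos: int) -> int:
        """Ancestor coordinate of a parent position (inserted bases map to
        their insertion point)."""
        anc, cum = self._ins_arrays(chrom)
        # parent start of insert j is anc[j] + cum[j]
        starts = anc + cum[:-1]
        j = int(np.searchsorted(starts, pos, side="right"))
        if j == 0:
            return int(pos)
        a, c, l = int(anc[j - 1]), int(cum[j - 1]), int(cum[j] - cum[j - 1])
        p_start = a + c
        if pos < p_start + l:  # inside insert j-1
            return a
        return int(pos - cum[j])


@dataclass
class TetraploidTruth:
    """Simulated allotetraploid plus every ground-truth set."""

    seqs: dict[str, np.ndarray]
    genes: list[GeneFeature]
    tes: list[TEFeature]
    he_truth: list[tuple[str, int, int, str]]  # (chrom, start, end, donor)
    pav_truth: list[tuple[str, str, str]] = field(default_factory=list)
    cnv_truth: list[CNVEvent] = field(default_factory=list)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(s.size) for c, s in self.seqs.items()}

    def expected_origin(self) -> dict[str, str]:
        return {c: c[-1] for c in self.seqs}

    def homoeolog_pairs(self) -> dict[str, tuple[str | None, str | None]]:
        """pair id -> (A gene id, B gene id) for genes present on each side."""
        pairs: dict[str, list] = {}
        for g in self.genes:
            base, role = g.id[:-1], g.id[-1]
            pairs.setdefault(base, [None, None])["AB".index(role)] = g.id
        return {k: tuple(v) for k, v in pairs.items()}


# ---------------------------------------------------------------------------
# ancestor
# ---------------------------------------------------------------------------


def generate_ancestor(config: SimConfig, rng: np.random.Generator | None = None) -> ParentalGenome:
    """Uniform-random genome with non-overlapping, stop-free gene ORFs.

    Deterministic for a fixed config seed. Raises if the requested genes
    cannot be packed into a chromosome.
    """
    rng = rng or np.random.default_rng(config.seed)
    seqs: dict[str, np.ndarray] = {}
    genes: list[GeneFeature] = []
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    gid = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = config.ancestor_length
        seq = rng.integers(0, 4, size=L, dtype=np.uint8)
        k = per_chrom[ci]
        total_gap = L - k * config.gene_length
        if total_gap < 0:
            raise ValueError("infeasible gene packing")
        cuts = np.sort(rng.integers(0, total_gap + 1, size=k))
        starts = cuts + np.arange(k) * config.gene_length
        for s in starts:
            s = int(s)
            e = s + config.gene_length
            n_codons = config.gene_length // 3
            idx = rng.integers(0, len(_CODON_CODES), size=n_codons)
            cod = np.array([_CODON_CODES[j] for j in idx], dtype=np.uint8).ravel()
            seq[s:e] = cod
            genes.append(GeneFeature(id=f"g{gid:04d}", chrom=chrom, start=s, end=e))
            gid += 1
        seqs[chrom] = seq
    return ParentalGenome(role="ancestor", seqs=seqs, genes=genes)


# ---------------------------------------------------------------------------
# JC69 lineage evolution
# ---------------------------------------------------------------------------


def evolve_lineage(
    seq: np.ndarray | str,
    years: float,
    rate: float,
    rng: np.random.Generator,
    site_scale: np.ndarray | None = None,
) -> np.ndarray | str:
    """Evolve a sequence under JC69 for ``years`` at ``rate`` subs/site/yr.

    Sampling uses the exact JC69 transition kernel at branch length
    b = rate*years (optionally scaled per site), equivalent in law to a
    per-site Poisson substitution process: a site differs from its input
    with probability (3/4)(1 - exp(-4/3 b)) and the replacement base is
    uniform over the other three.
    """
    if years < 0:
        raise ValueError("years must be >= 0")
    as_str = isinstance(seq, str)
    codes = encode(seq) if as_str else np.asarray(seq, dtype=np.uint8).copy()
    b = rate * years
    if site_scale is None:
        p = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * b))
        changed = rng.random(codes.size) < p
    else:
        p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * b * np.asarray(site_scale)))
        changed = rng.random(codes.size) < p
    idx = np.nonzero(changed)[0]
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
        codes[idx] = (codes[idx] + shift) % 4
    return decode(codes) if as_str else codes


# codons whose first position admits a synonymous change (Leu/Arg blocks);
# their pos-1 sites stay neutral so NG86's synonymous-site counting sees a
# single rate across all synonymous sites
_POS1_SYN = {"CTA", "CTG", "TTA", "TTG", "CGA", "CGG", "AGA", "AGG"}


def _coding_site_scale(
    seq: np.ndarray, genes: Sequence[GeneFeature], fraction: float
) -> np.ndarray:
    """Per-site rate multipliers: 1 at synonymous-capable sites (third
    positions, plus first positions of Leu/Arg codons), ``fraction`` at the
    remaining coding sites, 1 outside genes. Codon identity is taken from
    the input (ancestral) sequence."""
    scale = np.ones(seq.size)
    for g in genes:
        n_codons = (g.end - g.start) // 3
        block = np.tile([fraction, fraction, 1.0], n_codons)
        codons = decode(seq[g.start : g.end])
        for ci in range(n_codons):
            if codons[3 * ci : 3 * ci + 3] in _POS1_SYN:
                block[3 * ci] = 1.0
        scale[g.start : g.end] = block
    return scale


_STOP_IDX = np.array([48, 50, 56])  # TAA, TAG, TGA as c0*16 + c1*4 + c2


def _repair_stops(evolved: np.ndarray, ancestral: np.ndarray, genes: Sequence[GeneFeature]) -> None:
    """Purifying selection against nonsense: any gene codon that evolved
    into a stop has the minimal offending substitution(s) reverted, leaving
    other (synonymous) changes in the codon untouched."""
    for g in genes:
        ev = evolved[g.start : g.end].reshape(-1, 3)
        an = ancestral[g.start : g.end].reshape(-1, 3)
        idx = ev[:, 0].astype(np.int16) * 16 + ev[:, 1] * 4 + ev[:, 2]
        for ci in np.nonzero(np.isin(idx, _STOP_IDX))[0]:
            cod = ev[ci].copy()
            fixed = False
            for pos in range(3):
                if cod[pos] != an[ci, pos]:
                    trial = cod.copy()
                    trial[pos] = an[ci, pos]
                    if trial[0] * 16 + trial[1] * 4 + trial[2] not in _STOP_IDX:
                        ev[ci] = trial
                        fixed = True
                        break
            if not fixed:
                ev[ci] = an[ci]


def derive_parent(
    ancestor: ParentalGenome,
    role: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> ParentalGenome:
    """Evolve one lineage from the ancestor for the configured divergence
    time, then apply the role's LTR bursts."""
    seqs = {}
    for chrom, seq in ancestor.seqs.items():
        chrom_genes = [g for g in ancestor.genes if g.chrom == chrom]
        scale = _coding_site_scale(seq, chrom_genes, config.coding_rate_fraction)
        evolved = evolve_lineage(
            seq, config.parent_divergence_years, config.substitution_rate, rng, site_scale=scale
        )
        _repair_stops(evolved, seq, chrom_genes)
        seqs[chrom] = evolved
    parent = ParentalGenome(
        role=role,
        seqs=seqs,
        genes=[replace(g) for g in ancestor.genes],
        inserts={c: [] for c in seqs},
    )
    for bi, burst in enumerate(config.ltr_bursts):
        if burst.role == role:
            parent = insert_ltr_burst(parent, burst, rng, mu_ltr=config.mu_ltr, tag=f"{role}{bi}")
    return parent


# ---------------------------------------------------------------------------
# LTR bursts
# ---------------------------------------------------------------------------


def insert_ltr_burst(
    genome: ParentalGenome,
    burst: LTRBurst,
    rng: np.random.Generator,
    mu_ltr: float = 1.3e-8,
    tag: str = "",
) -> ParentalGenome:
    """Insert ``n_copies`` of one LTR family at random intergenic points.

    All copies descend from a single random founder element whose two
    terminal repeats are identical at insertion; each copy's repeats (and
    internal region) then evolve independently for ``age`` years at
    ``mu_ltr``. Annotations record the true age.
    """
    lt, el = burst.ltr_length, burst.element_length
    founder_ltr = rng.integers(0, 4, size=lt, dtype=np.uint8)
    founder_int = rng.integers(0, 4, size=el - 2 * lt, dtype=np.uint8)

    # candidate insertion points: intergenic, per chromosome
    chroms = list(genome.seqs)
    chrom_sizes = np.array([genome.seqs[c].size for c in chroms], dtype=float)
    picks = rng.choice(len(chroms), size=burst.n_copies, p=chrom_sizes / chrom_sizes.sum())
    points: dict[str, list[int]] = {c: [] for c in chroms}
    for ci in picks:
        chrom = chroms[ci]
        L = genome.seqs[chrom].size
        gene_iv = [(g.start, g.end) for g in genome.genes if g.chrom == chrom]
        for _ in range(200):
            p = int(rng.integers(0, L + 1))
            if all(not (s < p < e) for s, e in gene_iv):
                points[chrom].append(p)
                break
        else:
            raise ValueError("no intergenic insertion point found")

    new = ParentalGenome(
        role=genome.role,
        seqs={},
        genes=[replace(g) for g in genome.genes],
        tes=[replace(t) for t in genome.tes],
        inserts={c: list(v) for c, v in genome.inserts.items()} or {c: [] for c in chroms},
    )
    copy_n = 0
    for chrom in chroms:
        seq = genome.seqs[chrom]
        pts = sorted(points[chrom])
        pieces = []
        prev = 0
        shift = 0
        for p in pts:
            pieces.append(seq[prev:p])
            r5 = evolve_lineage(founder_ltr, burst.age, mu_ltr, rng)
            r3 = evolve_lineage(founder_ltr, burst.age, mu_ltr, rng)
            mid = evolve_lineage(founder_int, burst.age, mu_ltr, rng)
            element = np.concatenate([r5, mid, r3])
            pieces.append(element)
            new_start = p + shift
            new.tes.append(
                TEFeature(
                    id=f"ltr_{genome.role}{tag}_{copy_n:04d}",
                    chrom=chrom,
                    start=new_start,
                    end=new_start + el,
                    ltr_length=lt,
                    age=burst.age,
                )
            )
            new.inserts.setdefault(chrom, []).append((genome.parent_to_anc(chrom, p), el))
            shift += el
            prev = p
            copy_n += 1
        pieces.append(seq[prev:])
        new.seqs[chrom] = np.concatenate(pieces) if pieces else seq.copy()
        # shift annotations lying at/after insertion points
        pts_arr = np.array(pts, dtype=np.int64)
        for g in new.genes:
            if g.chrom == chrom:
                d = int(np.searchsorted(pts_arr, g.start, side="right")) * el
                g.start += d
                g.end += d
        for t in new.tes:
            if t.chrom == chrom and not t.id.startswith(f"ltr_{genome.role}{tag}_"):
                d = int(np.searchsorted(pts_arr, t.start, side="right")) * el
                t.start += d
                t.end += d
    return new


# ---------------------------------------------------------------------------
# tetraploid assembly with HEs
# ---------------------------------------------------------------------------


def make_tetraploid(
    parent_a: ParentalGenome,
    parent_b: ParentalGenome,
    he_events: Sequence[HEEvent],
    rng: np.random.Generator | None = None,
    reciprocal: bool = True,
) -> TetraploidTruth:
    """Union of both parents' chromosomes with HE segments exchanged.

    Each HE replaces the recipient interval with the donor's homologous
    sequence (found through the shared ancestor coordinate map, so
    parent-specific LTR insertions travel with their parent). By default
    the exchange is reciprocal -- a crossover swaps the homologous
    segments, so the donor chromosome receives the recipient's sequence in
    return and every locus stays single-copy; ``reciprocal=False`` gives a
    one-way (gene-conversion-like) replacement that duplicates the donor
    segment. ``he_truth`` records every foreign segment (both sides of a
    reciprocal swap) in final tetraploid coordinates.

    Genes and TEs fully inside an exchanged segment travel with it;
    features straddling a junction are dropped (disrupted).
    """
    parents = {"A": parent_a, "B": parent_b}
    seqs: dict[str, np.ndarray] = {}
    genes: list[GeneFeature] = []
    tes: list[TEFeature] = []
    for role in ("A", "B"):
        par = parents[role]
        for chrom, seq in par.seqs.items():
            seqs[f"{chrom}{role}"] = seq.copy()
        for g in par.genes:
            genes.append(replace(g, id=f"{g.id}{role}", chrom=f"{g.chrom}{role}"))
        for t in par.tes:
            tes.append(replace(t, chrom=f"{t.chrom}{role}"))

    def _segment_features(par: ParentalGenome, pchrom: str, lo: int, hi: int, role: str):
        gs = [
            replace(g, id=f"{g.id}{role}", start=g.start - lo, end=g.end - lo)
            for g in par.genes
            if g.chrom == pchrom and g.start >= lo and g.end <= hi
        ]
        ts = [
            replace(t, start=t.start - lo, end=t.end - lo)
            for t in par.tes
            if t.chrom == pchrom and t.start >= lo and t.end <= hi
        ]
        return gs, ts

    # per tetraploid chromosome: (start, end, new segment, genes, tes, donor role)
    ops: dict[str, list[tuple]] = {}
    for ev in he_events:
        if ev.chrom not in seqs:
            raise ValueError(f"unknown recipient chromosome {ev.chrom}")
        recip_role = ev.chrom[-1]
        if ev.donor == recip_role:
            raise ValueError("HE donor equals recipient subgenome")
        pchrom = ev.chrom[:-1]
        recip, donor = parents[recip_role], parents[ev.donor]
        if ev.end > recip.seqs[pchrom].size:
            raise ValueError("HE interval outside recipient chromosome")
        anc_s = recip.parent_to_anc(pchrom, ev.start)
        anc_e = recip.parent_to_anc(pchrom, ev.end)
        ds = donor.anc_to_parent(pchrom, anc_s)
        de = donor.anc_to_parent(pchrom, anc_e)
        if de > donor.seqs[pchrom].size or de <= ds:
            raise ValueError("HE interval not homologous in the donor")
        gs, ts = _segment_features(donor, pchrom, ds, de, ev.donor)
        ops.setdefault(ev.chrom, []).append(
            (ev.start, ev.end, donor.seqs[pchrom][ds:de], gs, ts, ev.donor)
        )
        if reciprocal:
            gs_r, ts_r = _segment_features(recip, pchrom, ev.start, ev.end, recip_role)
            ops.setdefault(f"{pchrom}{ev.donor}", []).append(
                (ds, de, recip.seqs[pchrom][ev.start : ev.end], gs_r, ts_r, recip_role)
            )

    he_truth: list[tuple[str, int, int, str]] = []
    for chrom, chrom_ops in ops.items():
        chrom_ops.sort(key=lambda o: o[0])
        for o1, o2 in zip(chrom_ops, chrom_ops[1:]):
            if o2[0] < o1[1]:
                raise ValueError(f"overlapping HE events on {chrom}")
        pieces = []
        prev = 0
        offset = 0
        new_genes: list[GeneFeature] = []
        new_tes: list[TEFeature] = []
        bounds = [(o[0], o[1], o[1] - o[0], len(o[2])) for o in chrom_ops]

        def _shift(pos: int) -> int:
            d = 0
            for s, e, old_len, new_len in bounds:
                if pos >= e:
                    d += new_len - old_len
            return pos + d

        for s, e, seg, gs, ts, donor_role in chrom_ops:
            pieces.append(seqs[chrom][prev:s])
            pieces.append(seg)
            new_s = s + offset
            new_e = new_s + seg.size
            he_truth.append((chrom, new_s, new_e, donor_role))
            for g in gs:
                new_genes.append(replace(g, chrom=chrom, start=g.start + new_s, end=g.end + new_s))
            for t in ts:
                new_tes.append(replace(t, chrom=chrom, start=t.start + new_s, end=t.end + new_s))
            offset += seg.size - (e - s)
            prev = e
        pieces.append(seqs[chrom][prev:])
        seqs[chrom] = np.concatenate(pieces)
        kept_g = []
        for g in genes:
            if g.chrom != chrom:
                kept_g.append(g)
            elif any(g.start < e and g.end > s for s, e, *_ in chrom_ops):
                continue
            else:
                kept_g.append(replace(g, start=_shift(g.start), end=_shift(g.end)))
        genes = kept_g + new_genes
        kept_t = []
        for t in tes:
            if t.chrom != chrom:
                kept_t.append(t)
            elif any(t.start < e and t.end > s for s, e, *_ in chrom_ops):
                continue
            else:
                kept_t.append(replace(t, start=_shift(t.start), end=_shift(t.end)))
        tes = kept_t + new_tes
    genes.sort(key=lambda g: (g.chrom, g.start))
    tes.sort(key=lambda t: (t.chrom, t.start))
    return TetraploidTruth(seqs=seqs, genes=genes, tes=tes, he_truth=sorted(he_truth))


# ---------------------------------------------------------------------------
# per-sample variation
# ---------------------------------------------------------------------------


@dataclass
class SampleGenome:
    sample: str
    haplotypes: dict[str, np.ndarray]  # '<chrom>|hap1' and '<chrom>|hap2'

    def total_length(self) -> int:
        return sum(int(s.size) for s in self.haplotypes.values())


def apply_sample_variation(
    truth: TetraploidTruth,
    sample: str,
    rng: np.random.Generator,
    pav_genes: Sequence[str] = (),
    cnv_events: Sequence[CNVEvent] = (),
) -> SampleGenome:
    """Two haplotype copies of the tetraploid with this sample's variation.

    Gene deletions (PAV) remove the gene interval from both haplotypes.
    CNV states 0/2 delete/tandem-duplicate in both haplotypes, 0.5/1.5 in
    one randomly chosen haplotype. Truth entries are appended to
    ``truth.pav_truth`` / ``truth.cnv_truth`` in reference coordinates.
    """
    gene_by_id = {g.id: g for g in truth.genes}
    edits: dict[tuple[str, int], list[tuple[int, int, str]]] = {}

    def _add(chrom: str, haps: Sequence[int], start: int, end: int, kind: str):
        for h in haps:
            edits.setdefault((chrom, h), []).append((start, end, kind))

    for ev in cnv_events:
        if ev.sample != sample:
            continue
        if ev.chrom not in truth.seqs:
            raise ValueError(f"unknown chromosome {ev.chrom}")
        if ev.end > truth.seqs[ev.chrom].size:
            raise ValueError(f"CNV interval outside {ev.chrom}")
        if ev.state in (0.0, 2.0):
            haps = (1, 2)
        else:
            haps = (int(rng.integers(1, 3)),)
        kind = "del" if ev.state in (0.0, 0.5) else "dup"
        _add(ev.chrom, haps, ev.start, ev.end, kind)
        truth.cnv_truth.append(ev)
    for gid in pav_genes:
        g = gene_by_id.get(gid)
        if g is None:
            raise ValueError(f"unknown gene {gid}")
        for ev in cnv_events:
            if ev.sample == sample and ev.chrom == g.chrom and g.start < ev.end and g.end > ev.start:
                raise ValueError(f"PAV gene {gid} overlaps a CNV interval")
        _add(g.chrom, (1, 2), g.start, g.end, "del")
        truth.pav_truth.append((sample, gid, "lost"))

    haplotypes: dict[str, np.ndarray] = {}
    for chrom, seq in truth.seqs.items():
        for h in (1, 2):
            evs = sorted(edits.get((chrom, h), []))
            for e1, e2 in zip(evs, evs[1:]):
                if e2[0] < e1[1]:
                    raise ValueError(f"overlapping edits on {chrom} hap{h}")
            pieces = []
            prev = 0
            for s, e, kind in evs:
                pieces.append(seq[prev:s])
                if kind == "dup":
                    pieces.append(seq[s:e])
                    pieces.append(seq[s:e])
                prev = e
            pieces.append(seq[prev:])
            haplotypes[f"{chrom}|hap{h}"] = np.concatenate(pieces) if evs else seq.copy()
    return SampleGenome(sample=sample, haplotypes=haplotypes)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    names: list[str]
    r1: np.ndarray  # (n, read_length) uint8 codes, forward fragment end
    r2: np.ndarray  # (n, read_length) uint8 codes, reverse-complemented end

    def __len__(self) -> int:
        return len(self.names)

    def fastq_records(self, mate: int):
        mat = self.r1 if mate == 1 else self.r2
        qual = "I" * mat.shape[1] if len(self) else ""
        for i, name in enumerate(self.names):
            yield f"{name}/{mate}", decode(mat[i]), qual


def simulate_reads(
    seqs: dict[str, np.ndarray],
    depth: float,
    read_length: int,
    insert_size: int,
    error_rate: float,
    rng: np.random.Generator,
) -> ReadSet:
    """Paired-end reads at uniform coverage with i.i.d. substitution errors.

    The number of pairs is round(depth * total_length / (2 * read_length));
    fragments of fixed ``insert_size`` are uniform over the supplied
    sequences. Read names carry ``|origin=X|chrom=...|pos=...`` truth tags
    (X is the subgenome letter in the source sequence name); analysis
    modules never read them.
    """
    if insert_size < read_length:
        raise ValueError("insert_size must be >= read_length")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    names_ref = [c for c in seqs if seqs[c].size >= insert_size]
    lengths = np.array([seqs[c].size for c in names_ref], dtype=np.int64)
    total = int(sum(int(s.size) for s in seqs.values()))
    n_pairs = int(round(depth * total / (2 * read_length)))
    if n_pairs == 0 or not names_ref:
        empty = np.zeros((0, read_length), dtype=np.uint8)
        return ReadSet(names=[], r1=empty, r2=empty)
    starts_max = lengths - insert_size
    weights = lengths / lengths.sum()
    chrom_idx = rng.choice(len(names_ref), size=n_pairs, p=weights)
    starts = (rng.random(n_pairs) * (starts_max[chrom_idx] + 1)).astype(np.int64)
    r1 = np.empty((n_pairs, read_length), dtype=np.uint8)
    r2 = np.empty((n_pairs, read_length), dtype=np.uint8)
    names: list[str] = [""] * n_pairs
    col = np.arange(read_length)
    for ci, cname in enumerate(names_ref):
        mask = chrom_idx == ci
        if not mask.any():
            continue
        st = starts[mask]
        seq = seqs[cname]
        r1[mask] = seq[st[:, None] + col]
        tail = seq[(st + insert_size - read_length)[:, None] + col]
        r2[mask] = _COMP_MAT[tail][:, ::-1]
        base = cname.split("|")[0]
        origin = base[-1] if base[-1] in "AB" else "?"
        idxs = np.nonzero(mask)[0]
        for j, p in zip(idxs, st):
            names[j] = f"r{j:07d}|origin={origin}|chrom={cname}|pos={int(p)}|frag={insert_size}"
    if error_rate > 0:
        for mat in (r1, r2):
            err = rng.random(mat.shape) < error_rate
            idx = np.nonzero(err)
            if idx[0].size:
                mat[idx] = (mat[idx] + rng.integers(1, 4, size=idx[0].size).astype(np.uint8)) % 4
    return ReadSet(names=names, r1=r1, r2=r2)


_COMP_MAT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def read_matrix(rs: ReadSet) -> tuple[np.ndarray, list[str]]:
    """Stack both mates into one matrix with /1 and /2 name suffixes."""
    mat = np.vstack([rs.r1, rs.r2])
    names = [f"{n}/1" for n in rs.names] + [f"{n}/2" for n in rs.names]
    return mat, names


# ---------------------------------------------------------------------------
# one-call generation
# ---------------------------------------------------------------------------


def generate_study(config: SimConfig):
    """Ancestor -> parents -> tetraploid (+HEs) in one deterministic call.

    Returns (parent_a, parent_b, tetraploid_truth). Sample variation and
    reads are applied separately so callers can branch per sample.
    """
    rng = np.random.default_rng(config.seed)
    anc = generate_ancestor(config, rng)
    parent_a = derive_parent(anc, "A", config, rng)
    parent_b = derive_parent(anc, "B", config, rng)
    tetra = make_tetraploid(parent_a, parent_b, config.he_events, rng)
    return parent_a, parent_b, tetra
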