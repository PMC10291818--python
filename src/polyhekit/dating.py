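"""Molecular dating from synonymous and LTR repeat-pair divergence.

Divergence K converts to time through T = K / (2*mu): both lineages (or
both terminal repeats of an LTR element, identical at insertion)
accumulate substitutions independently, so the pairwise divergence is
twice the per-lineage branch. The same formula underpins both dating
routes: a Ks = 1 peak (the grass rho whole-genome duplication) corresponds
to ~87 Mya at the Poaceae synonymous rate, and LTR repeat-pair divergence
at the rice neutral rate dates element insertions.

Synonymous divergence uses the Nei-Gojobori (1986) counting method:
fractional synonymous/nonsynonymous site counts per codon, observed
differences averaged over minimal mutational pathways, and Jukes-Cantor
correction Ks = -(3/4) ln(1 - (4/3) p_s). It is a closed-form stand-in
for codon-model maximum likelihood, adequate in the Ks <= 0.1 regime this
pipeline dates in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import gaussian_kde

from .alnio import encode

MU_KS = 5.76174e-9  # substitutions per synonymous site per year (Poaceae)
MU_LTR = 1.3e-8  # substitutions per site per year (rice neutral rate)

_BASES = "ACGT"
_STOPS = set(standard_dna_table.stop_codons)
_AA = dict(standard_dna_table.forward_table)


@dataclass(frozen=True)
class RateConstants:
    mu_ks: float = MU_KS
    mu_ltr: float = MU_LTR

    def __post_init__(self):
        if self.mu_ks <= 0 or self.mu_ltr <= 0:
            raise ValueError("rates must be positive")


@dataclass(frozen=True)
class KsEstimate:
    pair_id: str
    ks: float  # JC-corrected synonymous substitutions per synonymous site
    syn_sites: float
    syn_diffs: float
    saturated: bool = False  # p_s >= 3/4: JC correction undefined


@dataclass(frozen=True)
class InsertionAge:
    element_id: str
    k: float  # repeat-pair divergence
    t: float  # years, = k / (2 * mu_ltr)


# ---------------------------------------------------------------------------
# NG86 synonymous divergence
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Fractional synonymous sites of one codon (stop targets count as
    nonsynonymous)."""
    aa = _AA[codon]
    s = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt not in _STOPS and _AA[alt] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons averaged
    over minimal mutational pathways; pathways through stop codons are
    excluded unless all are."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in _STOPS:
                through_stop = True
            if nxt in _STOPS or cur in _STOPS or _AA.get(cur) != _AA.get(nxt):
                nd += 1
            else:
                sd += 1
            cur = nxt
        paths.append((through_stop, sd, nd))
    usable = [p for p in paths if not p[0]] or paths
    sd = sum(p[1] for p in usable) / len(usable)
    nd = sum(p[2] for p in usable) / len(usable)
    return sd, nd


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction of a raw mismatch fraction."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ks_ng86(cds_a: str, cds_b: str, pair_id: str = "pair") -> KsEstimate:
    """Nei-Gojobori synonymous divergence between two in-frame CDSs.

    Requires equal lengths, a multiple of 3, and no internal stop codons.
    Saturated pairs (p_s >= 3/4) are flagged, not raised.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("coding sequences differ in length")
    if len(a) % 3:
        raise ValueError("length must be a multiple of 3")
    s_a = s_b = sd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca in _STOPS or cb in _STOPS:
            raise ValueError(f"internal stop codon at position {i}")
        s_a += _syn_sites(ca)
        s_b += _syn_sites(cb)
        d_s, _ = _pathway_diffs(ca, cb)
        sd += d_s
    S = 0.5 * (s_a + s_b)
    if S == 0:
        raise ValueError("no synonymous sites")
    ps = sd / S
    if ps >= 0.75:
        return KsEstimate(pair_id, math.inf, S, sd, saturated=True)
    return KsEstimate(pair_id, jc_correct(ps), S, sd)


# ---------------------------------------------------------------------------
# density peaks
# ---------------------------------------------------------------------------


def _kde_peaks(
    values: np.ndarray,
    bandwidth: float | None = None,
    bw_floor_quantum: bool = False,
    grid_size: int = 2048,
) -> list[float]:
    """Gaussian-KDE density peaks, densest first.

    Divergence values are scale quantities with right-skewed sampling
    distributions, so (as in the usual log-scale Ks plots) the density is
    estimated on log values whenever all values are positive; an explicit
    ``bandwidth`` is interpreted on the working (log or linear) scale.
    With ``bw_floor_quantum`` the bandwidth never drops below 1.5x the
    discretization quantum of the data (integer mismatch counts on short
    repeats), so the peak tracks the distribution rather than one atom.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 values for a density peak")
    if np.ptp(values) == 0:
        return [float(values[0])]
    log_space = bool(values.min() > 0)
    x = np.log(values) if log_space else values
    std = float(x.std(ddof=1))
    bw = bandwidth
    if bw is None:
        bw = std * x.size ** (-1.0 / 5.0)  # Scott's rule
    if bw_floor_quantum:
        gaps = np.diff(np.unique(x))
        gaps = gaps[gaps > 1e-12]
        if gaps.size:
            bw = max(bw, 1.5 * float(np.median(gaps)))
    kde = gaussian_kde(x, bw_method=bw / std)
    xs = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_size)
    ys = kde(xs)
    inner = (ys[1:-1] >= ys[:-2]) & (ys[1:-1] > ys[2:])
    peaks = xs[1:-1][inner]
    dens = ys[1:-1][inner]
    order = np.argsort(-dens)
    out = peaks[order]
    if log_space:
        out = np.exp(out)
    return [float(p) for p in out]


def ks_peak(values, bandwidth: float | None = None) -> list[float]:
    """Gaussian-KDE density peaks of a Ks distribution, densest first."""
    return _kde_peaks(np.asarray(list(values), dtype=float), bandwidth=bandwidth)


def half_height_interval(values, bandwidth: float | None = None) -> tuple[float, float]:
    """Width of the primary KDE peak at half its height (a simple
    uncertainty band for the peak date)."""
    values = np.asarray(list(values), dtype=float)
    if np.ptp(values) == 0:
        return float(values[0]), float(values[0])
    std = float(values.std(ddof=1))
    bw = bandwidth or std * values.size ** (-1.0 / 5.0)
    kde = gaussian_kde(values, bw_method=bw / std)
    xs = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, 2048)
    ys = kde(xs)
    imax = int(np.argmax(ys))
    half = ys[imax] / 2
    lo = imax
    while lo > 0 and ys[lo] > half:
        lo -= 1
    hi = imax
    while hi < ys.size - 1 and ys[hi] > half:
        hi += 1
    return float(xs[lo]), float(xs[hi])


# ---------------------------------------------------------------------------
# divergence -> time
# ---------------------------------------------------------------------------


def divergence_time(k: float, mu: float) -> float:
    """T = K / (2*mu) in years."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if k < 0:
        raise ValueError("K must be >= 0")
    return k / (2.0 * mu)


def ltr_pair_divergence(repeat5, repeat3, jc: bool = True) -> float:
    """Divergence K between the two terminal repeats of an LTR element.

    Repeats are compared ungapped after end-trimming to equal length
    (simulated repeats have no indels; supply externally aligned repeats
    for gapped real data). Saturation returns inf.
    """
    a = encode(repeat5) if isinstance(repeat5, str) else np.asarray(repeat5, dtype=np.uint8)
    b = encode(repeat3) if isinstance(repeat3, str) else np.asarray(repeat3, dtype=np.uint8)
    n = min(a.size, b.size)
    if n == 0:
        raise ValueError("empty repeat")
    a, b = a[:n], b[:n]
    p = float(np.count_nonzero(a != b)) / n
    if not jc:
        return p
    if p >= 0.75:
        return math.inf
    return jc_correct(p)


def insertion_age_distribution(
    k_values,
    mu_ltr: float = MU_LTR,
    bandwidth: float | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Ages T = K/(2*mu) for a set of LTR elements plus KDE density peaks.

    Mismatch counts on short repeats make the age distribution discretized;
    the KDE bandwidth is floored at 1.5x the discretization quantum so the
    reported burst age follows the distribution rather than one atom.
    """
    ks = np.asarray(list(k_values), dtype=float)
    ages = ks / (2.0 * mu_ltr)
    peaks = _kde_peaks(ages, bandwidth=bandwidth, bw_floor_quantum=bandwidth is None)
    return ages, peaks
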