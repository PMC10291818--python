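"""Subgenome bias statistics.

Directional asymmetries (e.g. genes moved A->B vs B->A by homoeologous
exchange) are tested with a 1-df chi-square goodness of fit against equal
expectation, chi2 = (a-b)^2/(a+b); small totals fall back to an exact
binomial test. Genome-wide homoeolog expression bias is the two-sided
Wilcoxon signed-rank test of per-pair log2 count ratios against zero --
the standard genome-level inference for whether an allopolyploid
preferentially expresses one subgenome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PSEUDOCOUNT = 0.5  # added to both counts before log ratios


@dataclass(frozen=True)
class DirectionalCounts:
    n_a_to_b: int
    n_b_to_a: int
    label: str = ""

    def __post_init__(self):
        if self.n_a_to_b < 0 or self.n_b_to_a < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_a_to_b + self.n_b_to_a


@dataclass(frozen=True)
class BiasResult:
    statistic: float
    p_value: float
    direction: str  # 'A', 'B' or 'none'
    n: int
    exact: bool = False  # exact-binomial fallback used


def chisq_equal(counts: DirectionalCounts) -> BiasResult:
    """Chi-square test of a directional count pair against 50:50.

    ``direction`` is 'A' when A->B movement dominates (the A subgenome is
    the net donor), 'B' when B->A dominates. Totals below 10 use an exact
    binomial test, flagged on the result.
    """
    a, b = counts.n_a_to_b, counts.n_b_to_a
    n = a + b
    if n == 0:
        raise ValueError("cannot test an empty count pair")
    direction = "A" if a > b else ("B" if b > a else "none")
    if n < 10:
        p = stats.binomtest(a, n, 0.5).pvalue
        return BiasResult(float("nan"), float(p), direction, n, exact=True)
    chi2 = (a - b) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return BiasResult(float(chi2), p, direction, n)


def proportion(counts: DirectionalCounts) -> int:
    """Percent of the total in the A->B direction, rounded half-up."""
    if counts.total == 0:
        raise ValueError("zero total")
    x = 100.0 * counts.n_a_to_b / counts.total
    return int(np.floor(x + 0.5))


def fold_and_share(larger: float, smaller: float) -> tuple[float, float]:
    """Disambiguated '63% more' style comparisons: returns
    (fold = larger/smaller, share = larger/(larger+smaller))."""
    if smaller <= 0 or larger <= 0:
        raise ValueError("values must be positive")
    return larger / smaller, larger / (larger + smaller)


# ---------------------------------------------------------------------------
# homoeolog expression counting
# ---------------------------------------------------------------------------


def homoeolog_counts(
    records: Sequence,
    genes: Sequence,
    pair_map: Mapping[str, tuple[str | None, str | None]],
) -> tuple[pd.DataFrame, int]:
    """Count unambiguously origin-tagged alignments per homoeolog pair.

    Each alignment tagged 'A' or 'B' that overlaps a gene increments that
    gene's pair row in the tag's column (ties on overlap go to the longer
    overlap, then first gene). Reads overlapping no gene are skipped;
    genes missing from the pair map land in an 'unpaired' bucket returned
    as the second value. Column sums equal the number of included
    alignments plus the bucket.
    """
    gene_to_pair = {}
    for pid, (ga, gb) in pair_map.items():
        if ga:
            gene_to_pair[ga] = pid
        if gb:
            gene_to_pair[gb] = pid
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)
    counts: dict[str, list[int]] = {pid: [0, 0] for pid in pair_map}
    unpaired = 0
    for rec in records:
        if rec is None or rec.origin_tag not in ("A", "B") or not rec.is_primary:
            continue
        best = None
        for g in by_chrom.get(rec.ref_name, []):
            ov = min(rec.ref_end, g.end) - max(rec.ref_start, g.start)
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, g)
        if best is None:
            continue
        pid = gene_to_pair.get(best[1].id)
        if pid is None:
            unpaired += 1
            continue
        counts[pid]["AB".index(rec.origin_tag)] += 1
    df = pd.DataFrame(
        [(pid, c[0], c[1]) for pid, c in counts.items()],
        columns=["pair", "count_A", "count_B"],
    ).set_index("pair")
    return df, unpaired


def expression_bias_test(
    matrix: pd.DataFrame,
    min_total: int = 10,
    chrom_of_pair: Mapping[str, str] | None = None,
) -> tuple[BiasResult, dict[str, BiasResult]]:
    """Genome-wide Wilcoxon signed-rank test of homoeolog expression bias.

    Pairs with count_A + count_B >= ``min_total`` are testable (at least 20
    required). Per pair the statistic is log2((count_B + 1/2)/(count_A +
    1/2)); the two-sided signed-rank test asks whether the log-ratios are
    centred on zero, with direction from the median sign ('B' = B
    subgenome more highly expressed). Repeated per chromosome pair when
    ``chrom_of_pair`` is given.
    """
    sub = matrix[(matrix["count_A"] + matrix["count_B"]) >= min_total]
    if len(sub) < 20:
        raise ValueError(f"only {len(sub)} testable pairs (< 20)")

    def _test(df: pd.DataFrame) -> BiasResult:
        lr = np.log2((df["count_B"] + PSEUDOCOUNT) / (df["count_A"] + PSEUDOCOUNT)).to_numpy()
        nz = lr[lr != 0]
        if nz.size == 0:
            return BiasResult(0.0, 1.0, "none", len(df))
        res = stats.wilcoxon(nz, alternative="two-sided")
        med = float(np.median(lr))
        direction = "none"
        if res.pvalue < 0.05:
            direction = "B" if med > 0 else ("A" if med < 0 else "none")
        return BiasResult(float(res.statistic), float(res.pvalue), direction, len(df))

    genome = _test(sub)
    per_chrom: dict[str, BiasResult] = {}
    if chrom_of_pair is not None:
        groups: dict[str, list[str]] = {}
        for pid in sub.index:
            c = chrom_of_pair.get(pid)
            if c is not None:
                groups.setdefault(c, []).append(pid)
        for c, pids in sorted(groups.items()):
            if len(pids) >= 5:
                per_chrom[c] = _test(sub.loc[pids])
    return genome, per_chrom
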