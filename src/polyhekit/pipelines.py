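"""End-to-end scenario runners on the synthetic allotetraploid.

Each runner builds a named study scenario (configuration + ground truth),
executes the relevant pipeline stages, and returns both the raw objects
and recovery metrics against the truth sets. The acceptance script and the
integration tests call these; nothing here reads external data.

Scenarios
---------
resequencing_study : two 1 Mb chromosomes per parent, ten HEs of 8-30 kb,
    one reference-like individual sequenced at 15x with 0.5% base error
    (HE recovery), and three variant samples at 15x carrying ten gene
    deletions plus one >= 200 kb CNV each (heterozygous deletion,
    homozygous deletion, duplication) for PAV/CNV recovery.
dating_study : default-scale parents (2*mu*T ~ 0.065 at neutral sites, LTR
    bursts at 340 ky on A and 50 ky on B) for Ks- and LTR-dating recovery.
classifier_study : burst-free 200 kb parents, error-free reads, for
    diagnostic-site classification accuracy and llr antisymmetry.
wilcoxon_null_calibration : type-I error of the expression-bias test on
    symmetric Poisson count matrices.
"""

from __future__ import annotations

import zlib
from dataclasses import replace

import numpy as np
import pandas as pd

from . import biastats, covgene, dating, hescan, origin
from .alnio import KmerIndex, decode, map_reads
from .simgenome import (
    CNVEvent,
    HEEvent,
    LTRBurst,
    SimConfig,
    apply_sample_variation,
    generate_study,
    read_matrix,
    simulate_reads,
)


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(tag.encode()) % (2**31)])


def _sub_seed(seed: int, tag: str) -> int:
    return (int(seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


def parents_index(parent_a, parent_b, k: int = 17) -> KmerIndex:
    """Index over the concatenation of both parents, names suffixed with
    their subgenome letter (the competitive-mapping reference)."""
    seqs = {}
    for role, par in (("A", parent_a), ("B", parent_b)):
        for chrom, seq in par.seqs.items():
            seqs[f"{chrom}{role}"] = seq
    return KmerIndex(seqs, k=k)


# ---------------------------------------------------------------------------
# HE + resequencing scenario
# ---------------------------------------------------------------------------

# five reciprocal crossovers = ten foreign segments (8-30 kb) in the
# tetraploid, five A-derived on B chromosomes and five B-derived on A
_HE_EVENTS = (
    HEEvent("chr1B", 100_000, 113_000, "A"),
    HEEvent("chr1B", 350_000, 358_000, "A"),
    HEEvent("chr2A", 150_000, 162_000, "B"),
    HEEvent("chr2A", 400_000, 428_000, "B"),
    HEEvent("chr2B", 250_000, 280_000, "A"),
)

# (chromosome, requested interval, copy state) for samples s1..s3; the
# builder snaps boundaries into intergenic gaps so no gene is split
_CNV_PLAN = {
    "s1": ("chr1A", 600_000, 820_000, 0.5),
    "s2": ("chr2A", 730_000, 960_000, 0.0),
    "s3": ("chr1B", 600_000, 820_000, 2.0),
}
_N_PAV = {"s1": 4, "s2": 3, "s3": 3}


def resequencing_config(seed: int) -> SimConfig:
    return SimConfig(
        n_chromosomes=2,
        ancestor_length=1_000_000,
        n_genes=200,
        gene_length=600,
        ltr_bursts=(
            LTRBurst("A", 340_000.0, 15, 1_000, 300),
            LTRBurst("B", 50_000.0, 15, 1_000, 300),
        ),
        he_events=_HE_EVENTS,
        depth=15.0,
        error_rate=0.005,
        seed=_sub_seed(seed, "reseq"),
    )


def _snap_intergenic(truth, chrom: str, pos: int) -> int:
    """Move a coordinate out of any gene it falls in (to just past it)."""
    for g in truth.genes:
        if g.chrom == chrom and g.start <= pos < g.end:
            return g.end + 1
    return pos


def _plan_sample_variation(truth):
    """Pick PAV genes and snap CNV intervals for the three samples."""
    cnv_events = []
    for sample, (chrom, s, e, state) in _CNV_PLAN.items():
        s2 = _snap_intergenic(truth, chrom, s)
        e2 = _snap_intergenic(truth, chrom, e)
        cnv_events.append(CNVEvent(sample, chrom, s2, e2, state))
    blocked = [(c.chrom, c.start - 2000, c.end + 2000) for c in cnv_events]
    blocked += [(c, s - 2000, e + 2000) for c, s, e, _ in truth.he_truth]
    lengths = truth.chrom_lengths()
    eligible = []
    for g in truth.genes:
        if g.start < 5000 or g.end > lengths[g.chrom] - 5000:
            continue
        if any(c == g.chrom and g.start < e and g.end > s for c, s, e in blocked):
            continue
        eligible.append(g.id)
    step = max(1, len(eligible) // (sum(_N_PAV.values()) + 1))
    picked = eligible[::step]
    pav = {}
    i = 0
    for sample, n in _N_PAV.items():
        pav[sample] = picked[i : i + n]
        i += n
    return pav, cnv_events


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def run_he_detection(parent_a, parent_b, truth, reads, he_params=None) -> dict:
    """Classify reads against the parents, re-map them origin-tagged to the
    tetraploid, paint windows and call HE blocks."""
    he_params = he_params or hescan.HECallParams()
    pidx = parents_index(parent_a, parent_b)
    tidx = KmerIndex(truth.seqs)
    mat, names = read_matrix(reads)
    calls, _ = origin.classify_by_primary_mapping(mat, pidx, read_ids=names)
    tagged = origin.tag_and_remap(mat, calls, tidx, read_ids=names)
    track = hescan.paint(tagged, truth.chrom_lengths(), he_params)
    blocks = hescan.call_blocks(track, truth.expected_origin(), he_params, records=tagged)
    return dict(calls=calls, tagged=tagged, track=track, blocks=blocks, tetra_index=tidx)


def evaluate_he_recovery(blocks, he_truth, min_len: int) -> dict:
    per_truth = []
    for chrom, s, e, donor in he_truth:
        best = 0.0
        for b in blocks:
            if b.chrom == chrom and b.donor == donor:
                best = max(best, jaccard((s, e), (b.start, b.end)))
        per_truth.append(best)
    false_blocks = [
        b
        for b in blocks
        if b.length >= min_len
        and not any(b.chrom == c and min(b.end, e) - max(b.start, s) > 0 for c, s, e, _ in he_truth)
    ]
    return dict(
        jaccards=per_truth,
        min_jaccard=min(per_truth) if per_truth else 0.0,
        n_truth=len(he_truth),
        n_recovered=sum(j >= 0.9 for j in per_truth),
        n_false=len(false_blocks),
    )


def resequencing_study(seed: int, with_samples: bool = True) -> dict:
    """Full HE + PAV + CNV recovery run; returns metrics and objects."""
    cfg = resequencing_config(seed)
    parent_a, parent_b, truth = generate_study(cfg)
    he_params = hescan.HECallParams()

    reads0 = simulate_reads(
        truth.seqs,
        cfg.depth,
        cfg.read_length,
        cfg.insert_size,
        cfg.error_rate,
        _rng(seed, "reads-ref"),
    )
    det = run_he_detection(parent_a, parent_b, truth, reads0, he_params)
    he_eval = evaluate_he_recovery(det["blocks"], truth.he_truth, he_params.min_len)
    out = dict(
        config=cfg,
        truth=truth,
        parents=(parent_a, parent_b),
        blocks=det["blocks"],
        track=det["track"],
        he_eval=he_eval,
    )
    if not with_samples:
        return out

    rng = _rng(seed, "samples")
    pav_plan, cnv_events = _plan_sample_variation(truth)
    tidx = det["tetra_index"]
    chrom_lengths = truth.chrom_lengths()
    cnv_params = covgene.CNVParams()
    statuses: dict[str, dict[str, str]] = {}
    cnv_evals = []
    for sample in ("s1", "s2", "s3"):
        sg = apply_sample_variation(
            truth,
            sample,
            rng,
            pav_genes=pav_plan[sample],
            cnv_events=[c for c in cnv_events if c.sample == sample],
        )
        # depth/2 per haplotype = configured depth on the reference scale
        reads = simulate_reads(
            sg.haplotypes,
            cfg.depth / 2.0,
            cfg.read_length,
            cfg.insert_size,
            0.0,
            _rng(seed, f"reads-{sample}"),
        )
        mat, names = read_matrix(reads)
        recs = [r for r in map_reads(mat, tidx, read_ids=names, store_seq=False) if r is not None]
        statuses[sample] = covgene.sample_gene_status(recs, truth.genes, chrom_lengths)
        prof, _, _ = covgene.depth_profile(recs, chrom_lengths, cnv_params.window)
        segs = covgene.segment_cnv(prof, cnv_params, chrom_lengths)
        splits = [r for r in recs if r.clipped_partner is not None]
        segs = covgene.refine_breakpoints(segs, splits, search=cnv_params.window + 500)
        for ev in (c for c in cnv_events if c.sample == sample):
            match = None
            for s in segs:
                if s.chrom == ev.chrom and s.state == ev.state:
                    if jaccard((s.start, s.end), (ev.start, ev.end)) > 0.5:
                        match = s
            cnv_evals.append(
                dict(
                    sample=sample,
                    truth=ev,
                    found=match is not None,
                    bp_err_left=abs(match.start - ev.start) if match else None,
                    bp_err_right=abs(match.end - ev.end) if match else None,
                    split_support=bool(match and match.left_exact and match.right_exact),
                    partner=match.partner if match else None,
                )
            )
        del recs

    status_df = pd.DataFrame(statuses).reindex([g.id for g in truth.genes])
    lost_truth = {(s, g) for s, g, _ in truth.pav_truth}
    for ev in cnv_events:
        if ev.state == 0.0:
            for g in truth.genes:
                if g.chrom == ev.chrom and g.start >= ev.start and g.end <= ev.end:
                    lost_truth.add((ev.sample, g.id))
    lost_called = {
        (s, g) for s in statuses for g, st in statuses[s].items() if st == "lost"
    }
    tp = len(lost_called & lost_truth)
    pav_eval = dict(
        n_truth=len(lost_truth),
        n_called=len(lost_called),
        n_pav_deletions=len(truth.pav_truth),
        precision=tp / len(lost_called) if lost_called else 0.0,
        recall=tp / len(lost_truth) if lost_truth else 1.0,
    )
    core, dispensable = covgene.core_dispensable(status_df)
    out.update(
        status=status_df,
        pav_eval=pav_eval,
        cnv_evals=cnv_evals,
        core=core,
        dispensable=dispensable,
        pav_plan=pav_plan,
        cnv_events=cnv_events,
    )
    return out


# ---------------------------------------------------------------------------
# dating scenario
# ---------------------------------------------------------------------------


def dating_study(seed: int) -> dict:
    """Recover parental divergence (Ks peak) and LTR burst ages from a
    default-scale simulation; dating needs no reads."""
    cfg = SimConfig(seed=_sub_seed(seed, "dating"))
    parent_a, parent_b, _ = generate_study(replace(cfg, he_events=()))
    genes_b = {g.id: g for g in parent_b.genes}
    ks_vals = []
    for g in parent_a.genes:
        gb = genes_b.get(g.id)
        if gb is None:
            continue
        ca = decode(parent_a.seqs[g.chrom][g.start : g.end])
        cb = decode(parent_b.seqs[gb.chrom][gb.start : gb.end])
        try:
            est = dating.ks_ng86(ca, cb, pair_id=g.id)
        except ValueError:
            continue  # lineage evolution occasionally creates an internal stop
        if not est.saturated:
            ks_vals.append(est.ks)
    peak = dating.ks_peak(ks_vals)[0]
    t_div = dating.divergence_time(peak, cfg.substitution_rate)
    ages = {}
    for role, par in (("A", parent_a), ("B", parent_b)):
        kv = []
        for te in par.tes:
            seq = par.seqs[te.chrom]
            k = dating.ltr_pair_divergence(
                seq[te.start : te.start + te.ltr_length],
                seq[te.end - te.ltr_length : te.end],
            )
            if np.isfinite(k):
                kv.append(k)
        _, peaks = dating.insertion_age_distribution(kv, cfg.mu_ltr)
        ages[role] = dict(n=len(kv), peak=peaks[0])
    return dict(
        config=cfg,
        n_pairs=len(ks_vals),
        ks_peak=peak,
        t_div_years=t_div,
        true_2muT=2 * cfg.substitution_rate * cfg.parent_divergence_years,
        ltr=ages,
        ltr_truth={b.role: b.age for b in cfg.ltr_bursts},
    )


# ---------------------------------------------------------------------------
# classifier scenario
# ---------------------------------------------------------------------------


def classifier_config(seed: int) -> SimConfig:
    return SimConfig(
        n_chromosomes=1,
        ancestor_length=200_000,
        n_genes=40,
        gene_length=600,
        ltr_bursts=(),
        depth=4.0,
        error_rate=0.0,
        seed=_sub_seed(seed, "classifier"),
    )


def classifier_study(seed: int) -> dict:
    """Error-free reads from both parents classified by diagnostic-site
    likelihood against parent-A coordinates; truth from read names."""
    cfg = classifier_config(seed)
    parent_a, parent_b, _ = generate_study(cfg)
    seq_a = decode(parent_a.seqs["chr1"])
    seq_b = decode(parent_b.seqs["chr1"])
    variants = origin.find_diagnostic_variants(seq_a, seq_b, pair_id="chr1")
    reads = simulate_reads(
        {"chr1A": parent_a.seqs["chr1"], "chr1B": parent_b.seqs["chr1"]},
        cfg.depth,
        cfg.read_length,
        cfg.insert_size,
        0.0,
        _rng(seed, "reads-classifier"),
    )
    mat, names = read_matrix(reads)
    idx_a = KmerIndex({"chr1": parent_a.seqs["chr1"]})
    recs = map_reads(mat, idx_a, read_ids=names)
    calls = origin.classify_reads_llr(recs, variants, side="A")
    swapped = [
        origin.DiagnosticVariant(v.pair_id, v.pos_a, v.pos_b, v.allele_b, v.allele_a)
        for v in variants
    ]
    calls_swapped = origin.classify_reads_llr(recs, swapped, side="A")
    n_eval = n_correct = 0
    antisym_ok = True
    for c, cs, name in zip(calls, calls_swapped, names):
        if abs(c.llr + cs.llr) > 1e-9:
            antisym_ok = False
        if c.n_sites < 1 or c.origin == "U":
            continue
        truth_origin = name.split("|origin=")[1][0]
        n_eval += 1
        n_correct += c.origin == truth_origin
    return dict(
        config=cfg,
        n_variants=len(variants),
        n_evaluated=n_eval,
        accuracy=n_correct / n_eval if n_eval else 0.0,
        llr_antisymmetric=antisym_ok,
        calls=calls,
        records=recs,
        names=names,
        variants=variants,
        parents=(parent_a, parent_b),
    )


# ---------------------------------------------------------------------------
# Wilcoxon null calibration
# ---------------------------------------------------------------------------


def wilcoxon_null_calibration(
    seed: int, n_reps: int = 500, n_pairs: int = 200, lam: float = 20.0, alpha: float = 0.05
) -> dict:
    """Type-I error of the expression-bias test on symmetric Poisson counts."""
    rng = _rng(seed, "wilcoxon-null")
    hits = 0
    for _ in range(n_reps):
        m = pd.DataFrame(
            {
                "count_A": rng.poisson(lam, n_pairs),
                "count_B": rng.poisson(lam, n_pairs),
            }
        )
        res, _ = biastats.expression_bias_test(m)
        hits += res.p_value < alpha
    return dict(n_reps=n_reps, alpha=alpha, type1_rate=hits / n_reps)
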