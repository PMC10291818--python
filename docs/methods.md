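# Methods

This note documents the models behind polyhekit, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions. Coordinates are 0-based half-open internally;
GFF3/VCF are 1-based on disk.

## The synthetic allotetraploid (simgenome)

A random ancestor (uniform base composition) carries non-overlapping gene
ORFs whose codons are drawn uniformly from the 61 sense codons. Two
lineages then evolve independently for `parent_divergence_years` T under
Jukes–Cantor (JC69): each site changes with probability
(3/4)(1 − e^(−4/3 µt)) and, conditional on change, moves uniformly to one
of the other three bases — the exact CTMC marginal, equivalent in law to a
per-site Poisson substitution process. There are no indels; all structural
variation enters through LTR insertions, HEs and CNVs.

**Coding sites.** Synonymous-capable sites — third codon positions plus
first positions of the Leu/Arg codons (CTA/CTG/TTA/TTG, CGA/CGG/AGA/AGG) —
evolve at the full neutral rate; the remaining coding sites at
`coding_rate_fraction` (default 0.2) of it. Giving the Leu/Arg first
positions full rate keeps the realized synonymous rate uniform across the
sites that NG86 counts as synonymous, so Ks between homoeologous coding
pairs is an unbiased estimate of the neutral branch length; damping *all*
first/second positions instead deflates Ks by ~5% by construction. Codon
identity for this per-site scaling is read from the ancestral sequence.
Any codon that evolves into a stop has the minimal offending
substitution(s) reverted (nonsense-purifying selection); synonymous
changes in such codons are untouched.

**Default conditions.** µ = 5.76174×10⁻⁹ /synonymous site/yr and
T = 5.64 My, so the simulated neutral divergence is 2µT ≈ 0.065 and the
true divergence date sits centrally in the 5.5–6.3 My window the Ks peak
is expected to date to. LTR bursts default to ages 340 ky (A subgenome)
and 50 ky (B), µ_LTR = 1.3×10⁻⁸ /site/yr.

**LTR bursts.** Each burst inserts copies of one founder element (two
identical terminal repeats flanking an internal region) at random
intergenic points; each copy's two repeats then evolve independently for
`age` years at µ_LTR, so the expected repeat-pair divergence is
K = 2µ_LTR·age. Defaults are 150 copies/burst of 26 kb elements with
12 kb repeats. The repeat length is an estimator-validity choice: the
dating module's density peak needs the expected number of mismatches per
repeat pair, λ = 2µ_LTR·age·L, to be well above the discreteness scale
(λ ≈ 16 for the 50 ky burst at L = 12 kb); with short repeats the age
distribution collapses onto a few mismatch-count atoms and any
peak-finding method becomes unstable. Copy counts and element lengths are
therefore chosen together so that the toy genomes stay in the megabase
range while λ stays large.

**Homoeologous exchanges.** `make_tetraploid` concatenates the two
parents (chromosome names suffixed A/B) and applies each configured HE as
a **reciprocal** exchange by default: the recipient interval is replaced
by the donor's homologous sequence (located through the shared ancestor
coordinate map, so parent-specific LTR insertions travel with their
parent) and the donor chromosome receives the recipient's sequence in
return. Reciprocity is the crossover mechanism and keeps every locus
single-copy; a one-way replacement (`reciprocal=False`, a
gene-conversion-like event) duplicates the donor segment, and reads from
either copy then multi-map and are deliberately excluded from painting as
ambiguous — such events are invisible to short-read painting by
construction. `he_truth` records every foreign segment (both sides of a
swap) with exact final coordinates; genes and TEs fully inside a segment
travel with it, features straddling a junction are dropped as disrupted.

**Samples and reads.** Per-sample variation produces two haplotype
sequences: PAV gene deletions cut the gene interval from both haplotypes;
CNV states 0/2 delete/tandem-duplicate in both, 0.5/1.5 in one randomly
chosen haplotype. The read simulator draws
round(depth × total_length / (2·read_length)) fixed-insert fragments
uniformly, with i.i.d. substitution errors; read names carry
`|origin=X|chrom=...|pos=...|` truth tags that analysis code never reads.
When both haplotypes are supplied, a per-haplotype depth of d/2 gives
reference-scale depth d where both copies are present, 0.5·d in
heterozygous deletions and 2·d in duplications.

## Read mapping (alnio)

The built-in mapper indexes exact k-mers (k = 17 by default, both strands
queried via the read and its reverse complement) and requires a chain of
≥ 2 seeds on one diagonal — exact, because alignment is ungapped (the
simulator produces substitutions only; gapped real data can enter as
external SAM). Extension keeps the maximal-scoring run
(match +1 / mismatch −2) containing the seed chain; the rest of the read
becomes soft clips. The best-scoring locus is primary; ties are broken by
(reference name, position) and flagged as ambiguous placement, which
excludes them from painting and coverage (the MAPQ-0 convention —
a tied read carries no positional evidence). Soft clips ≥ 25 bp are
re-seeded to find a split-read partner; the stored partner coordinate is
the junction-proximal end of the partner alignment, so deletion and
duplication junctions point at the far breakpoint. Seeds with more than
`max_hits` (32) index hits are skipped, so reads wholly inside
high-copy repeats go unmapped rather than exploding the candidate list.

## Origin classification (origin)

Diagnostic variants are columns with distinct non-gap bases in a pairwise
alignment of homologous parental sequences (equal-length inputs compare
directly; otherwise unique shared 21-mers are chained and equal-length
inter-anchor segments compared, unequal ones padded as gaps). Columns
within 2 bp of a gap are excluded; pairs below 80% identity are rejected
as non-homologous. The likelihood classifier uses
P(b|parent) = 1−ε on an allele match, ε/3 otherwise
(ε default 0.01), calling A when llr > τ and B when llr < −τ with
τ = ln 10 — one clean diagnostic site suffices for a call, matching how a
single confident SNP identifies the homoeolog of origin. The defaults are
this package's own calibration; both are exposed. The competitive
strategy maps each read against the concatenation of both parents and
assigns the parent owning the best primary score (ties → ambiguous); its
reported "llr" is the raw score difference and is not on the
probabilistic scale. Reads mapped to the tetraploid but to neither parent
are tagged novel.

## HE calling (hescan)

With long reads the origin of every coordinate can be painted directly;
with short reads the stable equivalent is windowed majority voting:
1 kb windows, ≥ 5 informative (A+B) reads, discordant fraction ≥ 0.8 to
seed, seed runs ≤ 2 kb apart merged, blocks < 2 kb dropped, and
boundaries refined to the outermost discordant read extents within one
window of the seeds. These thresholds are package calibrations -- genome-scale
HE counts are sensitive to them and there is no universal standard -- and
all live in `HECallParams`. Per-window labels
(infirma-derived / supina-derived / novel / no-call) export as BED.

## PAV and CNV (covgene)

Gene breadth is the fraction of gene bases covered by ≥ 1 confidently
placed primary alignment. Status: breadth < 0.20 → lost, unless
discordant-origin breadth > 0.90 → within-HE. The within-HE evidence is
deliberately *origin-tagged* coverage at the gene's own locus: coverage of
the opposite parent's homologous interval cannot separate "lost" from
"within an HE" in a tetraploid, because the intact homoeolog's own reads
always cover that interval. With untagged alignments the rule reduces to
lost/present. A known limitation follows: a sample-specific HE whose
sequence is absent from the reference re-maps to the opposite homoeolog
and is indistinguishable from loss in this breadth scheme.

Depth is windowed (10 kb), normalized by the genome-wide median window,
quantized to the nearest state in {0, ½, 1, 1½, 2} within ±0.15 (no-calls
inherit a neighbor), and runs shorter than 50 kb are absorbed. Boundaries
of non-reference-state segments are snapped to split-read clusters: within
one depth window of the boundary, ≥ 2 clips agreeing within 500 bp move
the boundary to the modal clip position, and the modal clipped-partner
locus is recorded — reproducing the linkage logic that ties a duplication
to the homoeologous deleted region it resides in. Unsupported boundaries
stay at window precision and are flagged approximate.

## Dating (dating)

NG86: per codon, each position contributes (synonymous alternatives)/3
synonymous sites, with changes to stops counted nonsynonymous; observed
codon differences are averaged over minimal mutational pathways, excluding
pathways through stops unless all pass one; Ks = −(3/4)ln(1 − (4/3)p_s),
flagged saturated at p_s ≥ 3/4. It is a closed-form replacement for
codon-model maximum likelihood, adequate in the Ks ≤ 0.1 regime the
pipeline dates in, and is verified against a brute-force pathway
enumeration oracle in the tests. LTR repeat pairs are compared ungapped
after end-trimming (raw-identity mode available), JC-corrected by default.

Density peaks are Gaussian KDEs computed on **log** values whenever all
values are positive, as in the usual log-scale Ks plots: divergence
distributions are right-skewed scale distributions, and a linear-scale KDE
peak systematically undershoots the divergence the sample is centred on.
Bandwidth defaults to Scott's rule; for insertion ages the bandwidth is
floored at 1.5× the discretization quantum of the data so the peak tracks
the burst age rather than one mismatch-count atom. The primary peak's
half-height interval is available as a simple uncertainty band.
T = K/(2µ) applies to both Ks and LTR dating (the factor 2 is what places
a Ks = 1 peak at ≈ 87 Mya at the Poaceae synonymous rate).

## Bias statistics (biastats)

χ² = (a−b)²/(a+b) with 1 df against equal expectation; totals below 10
fall back to an exact binomial test (flagged). Percentages are rounded
half-up to match printed integers. The expression-bias test computes
log₂((count_B + ½)/(count_A + ½)) per homoeolog pair (pseudocount ½,
configurable), requires ≥ 20 testable pairs (pair total ≥ 10), and runs
the two-sided Wilcoxon signed-rank test against zero, genome-wide and per
chromosome; direction is the median sign when significant. Per-pair
differential expression modeling is out of scope — the genome-wide
signed-rank procedure is the inference this package reports.

## Scenario scales and what passing shows

The bundled scenarios are sized to run in minutes on one CPU: the
HE/resequencing scenario uses two 1 Mb chromosomes per parent, ten 8–30 kb
exchanged segments, 15× coverage (0.5% error for the HE sample, error-free
for the three PAV/CNV samples, matching the error-free recovery contracts),
and ≥ 200 kb CNVs; the dating scenario uses 200 gene pairs of 2.4 kb and
300 LTR copies. The generator emulates substitution divergence, repeat
structure and large structural variation, but not sequencing-quality
profiles, indels, GC bias, paired-end insert-size variance, nested/solo
LTRs, or post-hybridization divergence between HE copies. Recovery on
this synthetic data therefore demonstrates the correctness of the
algorithms under their stated models, not their calibration on real
libraries — on real data, mapper choice, duplicate marking and
base-quality handling would dominate.

## Degenerate inputs and tie-breaks

Empty genomes, k outside [8, 31], reads shorter than k, genes outside
chromosomes, overlapping HE/CNV intervals, missing origin calls, ragged
status tables, zero count pairs and non-positive rates raise errors.
Score ties in mapping break lexicographically and are flagged; equal A/B
window counts are no-calls; KDE on constant data returns that constant;
saturation (p ≥ 3/4) is flagged, not raised, wherever a divergence is
estimated. All randomness flows from explicit `numpy` generators seeded
by the caller; equal configuration and seed reproduce byte-identical
outputs.
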