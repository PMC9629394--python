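# Methods

This note records the models implemented in `recsup`, the parameter
defaults and why they hold, the numerical choices that matter, and what
the synthetic benchmark does and does not demonstrate.

## Genetic-map comparison

Two linkage maps sharing markers are compared on their shared, *skeletal*
marker set: markers cosegregating at one cM position collapse to a single
representative (lexicographically smallest name) before interval
construction, so zero-length test intervals cannot arise from
cosegregation. Shared markers must be collinear; discordant order raises
an error naming the markers, since the method presumes conserved order.

For each consecutive shared pair the ratio `d_ref/d_test` is taken with
the *reference* (unsuppressed) map in the numerator, so compression in the
test cross produces ratios > 1. A zero test distance with a nonzero
reference distance is flagged as an infinite ratio and treated as
qualifying. An interval qualifies when its ratio exceeds both

* `ratio_min` (default **3.0**, the lower edge of the 3–3.5× compression
  criterion used for interspecific wheat crosses), and
* `fold_over_coeff × C` (default fold **2.0**), where
  `C = Σd_ref / Σd_test` is the whole-map reduction coefficient over the
  shared span (typically 1.5–1.7 for the motivating crosses).

Maximal runs of qualifying intervals merge into one region flanked by the
run's outer markers. With several reference maps, an interval must qualify
against every reference (consensus across crosses). Both rules are
invariant under uniform rescaling of the cM axis. Physical anchoring takes
the left flank's start and the right flank's end coordinate on the
pseudomolecule; spans are reported in bp and Mb (one decimal).

Whether the compression criterion applies to single intervals or windowed
averages is not fixed by the motivating analysis; this implementation uses
single intervals with run-merging, which is the more sensitive reading and
recovers planted regions to within one marker interval.

## Satellite clustering

Tandem-repeat hits are consumed in the Tandem Repeats Finder `.dat` table
dialect (1-based inclusive coordinates, converted internally to 0-based
half-open). Grouping is a single sweep over start-sorted hits: a hit joins
the current group when its start lies less than `merge_gap` (default
**100 bp**, strict `<`) past the group's rightmost end — this one rule
covers nesting, overlap and near-adjacency, and equals the transitive
closure of the pairwise relation (verified against a union–find oracle).
Groups whose genomic *span* is under `min_len` (default **1 kb**) are
discarded; cluster length is the span, not the sum of member lengths,
matching how pool sizes reflect genomic extent.

Periodicity class uses the median member period against the base unit
(default **118 bp**): within ±4 bp of 1×, 2× or 3× the base →
monomer/dimer/trimer (the tolerance covers 235–236 and 353–354 bp
annotations of a 118-bp unit); otherwise "other".

Consensus building cuts monomer copies from the cluster span *in register
with the reference*: the start phase (0…117) maximizing identity with the
family reference is chosen in both orientations, because repeat-finder
motifs are rotationally ambiguous. Strand is the orientation with the
higher identity; below 50 % in both, the cluster is flagged unclassified.
The consensus is the per-column majority over the phased copies, and the
reported identity is the mean copy-versus-consensus identity. Pairwise
identities use global alignment with free end gaps (match +1, mismatch −1,
gap −2) — simple and adequate for ~118-bp units. Clusters separated by at
most `pool_gap` (default **200 kb**; a package choice, no canonical value
exists) group into pools.

## DNA shape

Curvature is predicted with the classical dinucleotide *wedge* model: each
base-pair step deflects the helix axis by a fixed roll/tilt wedge while
the duplex twists ~34.3° per step. The shipped 16-dinucleotide
(twist, wedge, direction) table is a Trifonov-school parameter set with
large AA/TT wedges; complementary steps carry mirrored wedge directions.
The table is a plain dict argument (`wedge_table=`) and can be swapped for
any other parameterization. Key consequences, used as tests: homopolymer
runs are nearly straight (per-step wedges cancel over one helical turn),
while A-tracts repeated in phase with the screw (~10 bp) compound into
macroscopic curvature.

The path accumulates one unit rise per bp; curvature in a sliding window
(default **40 bp**, step **1 bp**) is the angle between the mean axis
directions of the window's first and last helical turns (10 bp), divided
by the number of turns separating them — units of **degrees per helical
turn**, scale-free across windows. A straight helix scores ≈ 0.

Reverse-complement symmetry holds up to a one-window-position registration
shift with < 0.5°/turn residual (the step-wise frame accumulation is not
exactly palindromic); the tests encode exactly this tolerance. Curvature
is exactly invariant under rigid motion of the path.

Periodicity uses fixed-length DFT segments: the track is cut into
`fs`-sample segments (default **fs = 1024** at 1 bp/sample, so bin *k* ↔
period `1024/k` bp; 60 bp ↔ bin 17, 118 bp ↔ bin 9 — note `1024/9 ≈
113.8`, so the "118-bp" label of bin 9 is approximate and the exact
`fs/bin` period is always reported). Segments are mean-centred before
transforming, the last is zero-padded, one-sided power is averaged across
segments (Parseval's identity holds per full segment), and phase comes
from the first segment, wrapped to (−180°, 180°]. A/T-tract phasing is
measured on impulse trains at tract centres: the phase difference (A − T)
at the bin nearest `fs/at_period` equals `360° × offset / period` for
offset tract families.

A-tract detection uses the *n* > 3 rule: maximal runs of ≥ 4 A (or T);
any other character, including N, breaks a run.

## LTR insertion dating

Elements need both LTRs ≥ **180 bp**; the first **150 bp** of each LTR are
aligned globally with free end gaps. Affine gap costs (open −3, extend −1,
match +1, mismatch −1) keep a multi-bp indel in a single gap run so it
counts as **one** evolutionary event; substitutions count per column;
`events = k + gap runs`. The 150-bp fragment is taken from the 5′ end;
the age arithmetic below confirms 150 as the divergence denominator.

The mismatch histogram is modelled two ways:

1. **Negative binomial** by profile maximum likelihood
   (`p̂(r) = r/(r + mean)`, so the fitted mean matches the sample mean
   exactly; method-of-moments initialization). Underdispersed data fall
   back to a Poisson-regime sentinel (`r = ∞`). The NBD is a Poisson with
   Gamma-distributed rate (shape `r`, scale `(1−p)/p`); the mode of that
   mixing Gamma, `(r−1)(1−p)/p` for `r > 1` else 0, is the **modal
   divergence**, and its rounded value is the default young/old threshold.
   (Deriving the threshold from the mixing-Gamma parameterization is an
   interpretation; it is exposed for override via `young_threshold`.)
2. **Poisson mixture** by EM on the weighted histogram. The log-likelihood
   is asserted non-decreasing each iteration; components are reported
   sorted by λ; goodness of fit is the coefficient of determination *r*²
   between observed relative frequencies and the fitted PMF on the
   observed support. The component count defaults to the minimum-BIC
   choice over 1–4.

Ages use `T = d/2μ` with `d = k/fragment` — divergence accrues on both
copies — and `μ = 1.3×10⁻⁸` substitutions/site/year (plant LTR
retrotransposons). Five mismatches over 150 bp give
`5/(2·1.3×10⁻⁸·150) ≈ 1.28` million years.

Enrichment of young elements is scanned in sliding windows of **10**
elements (step **1**, ordered by start coordinate, ties by id) against the
whole analyzed population using exact hypergeometric tails:
`p_over = P(X ≥ k)`, `p_under = P(X ≤ k)`. Raw p-values are reported
(single-region usage); the tails satisfy
`p_over + p_under = 1 + P(X = k)` and match exhaustive enumeration.

## Collinearity

Fragments below **3 kb** or **75 %** identity are removed (both thresholds
inclusive). "Most representative assembly" is interpreted as the
maximum-total-aligned-length consistent set: per strand, a weighted
longest-increasing-subsequence dynamic program over fragments that are
non-overlapping and concordantly ordered in both genomes ('+': query
ascends with reference; '−': query descends). Ties prefer fewer fragments,
then the leftmost chain; the heavier strand wins ('+' on a tie). Chain
optimality equals exhaustive subset search (pairwise consistency is
sufficient for chainability) and the result is invariant under input
permutation. Overlapping fragments are excluded by the DP rather than
trimmed, keeping fragments atomic.

Chain gaps (including chromosome ends) are measured on both genomes:
both ≥ `hdr_min` (default **50 kb**) → HDR; exactly one ≥ `indel_min`
(default **50 kb**) with the other < `collinear_slop` (default **10 kb**)
→ insertion in the genome with the large gap. These thresholds are package
choices calibrated to the 0.1–2 Mb scale of the events of interest and are
all configurable; upstream analyses drew such boundaries by dot-plot
inspection, so no canonical values exist. A planted inversion appears as a
minus-strand fragment excluded from the plus chain and is therefore called
as an HDR-scale gap; candidate inversions are visible as heavier
minus-strand sub-chains and are not auto-resolved. Coverage maps report
the per-window (default **10 kb**) covered fraction of the union of
≥ 80 %-identity fragment spans.

## Synthetic data: what it emulates, and what it does not

The generator builds genome A on an i.i.d. uniform ACGT background —
deliberately neutral, so planted periodic signals dominate the curvature
spectra — and derives genome B by applying the planted edits. Defaults
define the demo conditions: a 2-Mb pair; two satellite pools (three and
two arrays of a 118-bp monomer with three A-tracts phased at 20 bp;
2 % per-base copy divergence, which puts copy-to-consensus identities in
the high-90s and keeps pool sizes exact); 60 LTR elements (200-bp LTRs,
400-bp internal region) whose mismatch counts draw from a Poisson mixture
with rates (2, 9) and weights (0.4, 0.6), with elements in the 0.4–0.7 Mb
neighbourhood drawn from the low-rate component to plant a young-element
hotspot; two ≥ 50-kb InDels (one per genome) plus one 8-kb InDel below
the calling threshold; one 60-kb inversion; and a 41-marker map pair with
global coefficient 1.6 and a 4× suppressed interval at 0.75–1.3 Mb.
Planted LTR substitutions are confined to the first 150 bp of the LTR so
the planted count is exactly the quantity the divergence alignment
measures. Indel lengths inside LTRs are 1–5 bp, keeping the 150-bp
alignment well-posed. Alignment fragments covering every unedited segment
(split at 200 kb; minus-strand inside the inversion; 99 % nominal
identity) are emitted in PAF form, playing the role of upstream aligner
output, since running the aligner itself is out of scope.

Everything is deterministic per seed (byte-identical files on
regeneration). Internal coordinates are 0-based half-open; exported GFF3
is 1-based closed and BED 0-based half-open. The sum of signed planted
InDel lengths equals the genome length difference by construction.

What passing tests on this benchmark do **not** show: real chromosomes
have non-uniform composition, nested/truncated TEs, satellite
higher-order structure and assembly gaps; repeat finding, alignment and
LTR prediction are performed by external tools whose output quirks the
truth tables do not imitate; and the genome-scale counts of the motivating
study (e.g. cluster totals per chromosome arm, region-specific p-values)
require the actual pseudomolecules. The benchmark validates the
*operations* — thresholds, chaining, model fits, scan statistics — not
tool-level preprocessing. The tract-phase example in the shape analysis
likewise plants the A/T offset it measures; on real satellites the offset
is a property of the monomer.

## Problem sizes and runtime

The demo scale (2 Mb, 60 elements, 5 arrays, 41 markers) was chosen so
the full pipeline completes in a few seconds on one CPU while every
recovery check remains statistically meaningful; model-recovery tests use
n = 5,000–10,000 draws, and oracle tests enumerate instances small enough
for exhaustive search (12 fragments; hypergeometric populations ≤ 12).
Curvature profiling is O(L) per window position in pure Python/numpy and
is run on satellite arrays (kilobases), not whole chromosomes.
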