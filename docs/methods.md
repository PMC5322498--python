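# Methods

`clonetrace` analyses lentiviral-barcode tracking of haematopoietic stem
cell (HSC) clones after competitive transplantation, and ships a synthetic
data generator that reproduces the statistical structure such experiments
have, so that every stage is testable without sequencing data.

## The experimental model

Donor HSCs are transduced with a barcode library: each transduced (GFP+)
cell acquires one heritable 27 bp DNA tag, and its entire progeny carries
it. After transplantation alongside unbarcoded competitor cells, four
donor-derived read-outs are sorted per recipient long after engraftment —
peripheral B cells, T cells, myeloid cells and bone-marrow erythroid
progenitors (CFU-E) — and a 238 bp amplicon containing the barcode plus a
7 bp library ID is deep-sequenced per (mouse, lineage) sample.

A clone is one barcode in one mouse. Its **clone type** is the subset of
the four lineages in which its barcode is detected (15 non-empty subsets,
labelled in fixed M/B/T/E order, e.g. `M/E`, `M/B/T/E`). Its **clone
size** in a lineage is its share of the donor output there.

## Pipeline stages

### Tag extraction (`extract`)

Reads are anchored at fixed amplicon offsets: the 20 bp left flank, the
8 bp spacer between barcode and library ID, and a 10 bp right-flank anchor
are compared against the constant reference; a read is kept iff it is long
enough to contain the complete barcode and library-ID windows and the
constant context matches with at most `max_flank_mismatch` (default 2)
mismatches ('N' counts as a mismatch). Rejections are tallied per reason
(`incomplete_tag`, `flank_mismatch`, `library_id_mismatch`), so kept +
rejected reads always equal the FASTQ record count. The library ID is then
required within Hamming distance `max_id_mismatch` (default 1) of the
library's ID. There is no indel handling: the amplicon is produced by a
high-fidelity polymerase and the dominant error mode modelled is
substitution.

### Error collapse

Sequencing errors inside the barcode window spawn low-count "satellite"
barcodes around every real clone. `collapse_errors` processes barcodes in
descending count order (ties lexicographic): a barcode within Hamming
`max_distance` (default 2) of an already-accepted parent and with count
strictly below `ratio_threshold` (default 1/8) times the parent's count is
merged into the nearest such parent (ties: larger parent count, then
lexicographically smaller sequence); otherwise it is accepted as its own
clone. The greedy pass is **iterated to a fixpoint**, which makes the
operation idempotent — a single pass is not, because a parent's count
grows by absorption and can newly qualify a previously accepted barcode.
Total reads are conserved exactly, and the result is independent of input
order. The defaults are conservative for a library whose true barcodes sit
at pairwise Hamming distance >= 3: a 2-mismatch satellite can never be
closer to a wrong true barcode than to its parent.

### Quantification (`quantify`)

Counts become per-sample fractions (reads / total barcode reads in the
(mouse, lineage) sample). The **detection cutoff** is `1 / round(cells
transplanted x transduction fraction)` — one part per GFP+ cell
transplanted; a fraction strictly below it is noise and removed ("below"
is read literally: a fraction exactly at the threshold is kept). The
expected GFP+ cell count is rounded to the nearest integer because cell
counts are integral: 6,900 x 29% -> 2,001 cells -> 1/2001; 1,000 x 31% ->
310 -> 1/310. Fractions are *not* renormalised after filtering — noise is
omitted, not redistributed — so clone sizes remain comparable across mice.
Clone size = fraction / GFP+ donor fraction of the lineage; per sample,
clone sizes over all barcodes sum to 1/gfp_fraction.

### Clone typing and group comparison (`clonetype`)

Detected barcodes are intersected across lineages per mouse. Clone-type
frequencies are percentages of each mouse's detected clones, summarised as
mean +/- sample s.d. (n-1) across a group's mice; mice with zero detected
clones are excluded with a warning. Lineage *contribution* (the fraction
of clones with any output in a lineage) is computed pooled across a
group's mice by default, with a per-mouse variant for t-tests — the
pooled/per-mouse choice is exposed because either denominator is
defensible. Group contrasts use unpaired two-tailed t-tests at alpha 0.05
with **no multiple-testing correction**, deliberately mirroring the
original analysis rather than best current practice.

Barcodes recovered from iPS lines (Sanger) are matched back: full-length
(27 bp) queries exactly, inheriting the parental clone type and
per-lineage fractions; shorter queries are reported as `truncated` with
all detected barcodes containing them as substrings (candidates only — no
type is assigned to a truncated read); unmatched full-length queries are
`unaffiliated`. Barcode namespaces are per mouse: the same sequence in two
mice is two clones.

### Age-signature panel (`panel`)

Bulk selection: genes below an intensity floor (default 50) in *all*
samples are noise; survivors need an aged/young fold-change (max of the
ratio and its inverse) of at least 1.5. A zero young mean with non-zero
aged mean is an infinite fold (retained, logged). Candidates are split
into up-/down-with-age sets and scored against the log2 fold-change
ranking with the standard weighted running-sum enrichment statistic: hits
increment by |stat|^p normalised over the set (p default 1; p=0 gives the
unweighted +-1-bounded form), misses decrement by 1/(N - n_set); the
leading edge is the set members at or before the peak (at or after, for a
negative score). The shipped 45-gene panel (`SYNTHETIC_AGE_PANEL`:
Age01..Age42 + Actb/Hprt/Gapdh) is a synthetic placeholder — the original
panel membership is not available in machine-readable form.

Single-cell qPCR preprocessing: failed panel reactions are imputed at the
limit of detection `lod_ct` (default 30 cycles, the run length);
expression = `lod_ct - Ct` (log2-like, higher = more). Each cell is
centred by the mean expression of its *observed* reference reactions — a
failed housekeeping assay is a technical dropout, not evidence of absent
expression, so it is skipped rather than imputed (imputing it at the
detection limit was measured to inject ~5 cycles of centring error into
~14% of cells at 10% dropout). Cells failing more than `max_dropout`
(default 50%) of panel assays, or all three reference reactions, are
excluded with a warning. PCA runs on per-gene unit-variance standardised
expression (constant genes dropped); the separation report gives centroid
distances between all group pairs in the top-k (default 2) component
space, and the fraction of iPS-HSC cells whose nearest centroid — young
vs aged, fit without the iPS cells — is the young one.

## The synthetic generator

The generator's reference configurations ARE the study design: five young
mice at 1,000 transplanted cells / 31% transduction and five aged mice at
6,900 cells / 29% transduction, read depth 100,000 per sample, 0.5%
per-base substitution error.

**Clone draw.** Clones per mouse ~ Binomial(cells, transduction); each
clone gets a barcode (drawn without replacement per mouse from a
distance->=3 library), a clone type from the group's 15-type distribution,
and independent mean-1 log-normal output weights per potential lineage.
The published record prints only part of the type distributions (M 6/13%,
M/E 10/19%, M/B/T/E 13/1% young/aged) plus pooled lineage contributions
(myeloid 38/60%, T cell 45/3%, B and erythroid "similar" across age). The
default distributions were constructed once to satisfy all of these
simultaneously (giving B 51/51% and E 63/67% contributions); the remaining
mass was spread plausibly over the unprinted types. They are defaults, not
data.

**Reads.** Per (mouse, lineage) sample, one multinomial over clones and a
competitor sink: clone i receives probability (w_i / sum w) x gfp_fraction
and the unbarcoded competitor class 1 - gfp_fraction; competitor reads are
counted but not emitted. Each emitted read is the constant 238 bp amplicon
(layout: 20 bp flank | 27 bp barcode | 8 bp spacer | 7 bp library ID |
176 bp right flank) with i.i.d. substitutions and constant 'I' qualities
(the pipeline never uses qualities). Emitted + competitor reads equal the
read depth exactly, and a fixed seed yields byte-identical FASTQ. The
per-lineage GFP+ donor fractions (young 0.20 everywhere; aged B 0.620,
T 0.465, M 0.765, E 0.845) were derived once so the reference design
reproduces the published 20-/29-/39-fold young:aged mean clone-size ratios
in B/E/M and parity in T, given the printed doses and transductions.

**Output-weight dispersion.** `sigma_log` defaults to 0.1. The choice is a
detectability calibration, not a fit: the detection cutoff equals 1/(mean
number of clones), so in a lineage where a fraction c of clones
contribute, the mean clone fraction is only 1/c times the cutoff (1.49x in
the tightest case, aged erythroid). At sigma 0.1 the expected loss of true
detections there is under 1%, so the cutoff acts as the noise filter the
analysis assumes; at sigma 0.5 it would silently drop >10% of real clones
and the detected type distribution would no longer represent the clone
pool. Real clone sizes are far more dispersed; raise `sigma_log` to study
that regime, with the caveat that detected and generated distributions
then diverge by construction.

**Single-cell arm.** Ct values are Gaussian (s.d. 1 cycle) around
per-gene baselines with a per-cell offset (s.d. 0.8 cycles — what
reference centring removes); the aged group is shifted gene-wise by the
effect sizes (default +-1.5 cycles alternating sign, ~2.8-fold), mid-aged
by 0.6x the effect, and iPS-HSC cells are drawn from the young
distribution. Dropouts (default 10%) are NaN; values are clipped into
(0, lod_ct]. The "large-effect" regime used for the nearest-centroid
check is 3 cycles (8-fold), the strong end of published age-regulated HSC
markers; at the moderate 1.5-cycle default, limit-of-detection imputation
noise alone misassigns ~10% of cells, which is a property of the
imputation, not of PCA. A bulk-array generator
(`simulate_bulk_expression`) provides young/aged matrices (6 samples per
age) with designed up/down truth sets for the panel filters.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: PCR amplification bias and chimeras, indels,
quality-score structure, library-composition skew, homing/engraftment
failure, contamination between sorted fractions, and cell-to-cell
correlation structure in qPCR beyond a scalar offset. Recovery results on
synthetic data bound the pipeline's algorithmic error, not these
experimental effects.

## Numerical and testing choices

* All randomness flows from one `numpy` Generator per run, consumed in a
  documented order (library, transplant, then samples mouse-by-mouse in
  B/T/M/E order); seeds derived from a user seed stay below 2^31.
* Greedy-collapse ties are broken lexicographically; the enrichment-score
  peak takes the first index of maximal |running sum| (a positive and a
  negative excursion of equal magnitude is a genuine tie; tests treat
  either sign as valid at float precision).
* Statistical tolerances in the test suite use theoretical standard
  errors under the generating model, sqrt(p(1-p)/m)/sqrt(n_mice) with m =
  round(cells x transduction); an observed s.d. across five mice has four
  degrees of freedom and randomly shrinks or inflates the window. Where a
  recovered quantity is compared per-type against the generating
  distribution, a >3 s.e. deviation is accepted only when attributable to
  the truth draw itself (the pipeline's own contribution must stay below
  1 s.e.), so pipeline bias still fails.
* Test problem sizes (e.g. 300-600 Monte-Carlo replicates for the
  binomial checks, two-mouse experiments for unit round-trips, the full
  ten-mouse study for the end-to-end checks) were chosen as the smallest
  sizes at which the tested statistics are well resolved.

## Known limitations

* The error collapse assumes fixed-length, substitution-only artefacts;
  barcodes of unequal length are rejected.
* Lineage contribution and fold-difference pooling choices change numbers
  at the percent level; both variants are exposed but only the defaults
  are exercised end-to-end.
* `match_ips_barcode` reports substring candidates for truncated queries
  but deliberately assigns no type; whether truncated barcodes can be
  rescued is left to the analyst.
* The t-test layer reproduces the original statistics verbatim, including
  the absence of multiple-testing correction.
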