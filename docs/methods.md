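# Methods

## Scope and design

micromuscle models the computational core of a small-RNA-seq study of
skeletal-muscle miRNA regulation: quantification of mature miRNAs in
pre-miRNA hairpin space, negative-binomial differential expression, isomiR
end-modification profiling, inference of transcript-level vs
posttranscriptional deregulation from genomic-cluster and 5p/3p-arm
concordance, and time-course trajectory analysis.  Every stage is exercised
on synthetic data with planted ground truth; no external sequence database
is required.

## Synthetic data generator

The generator emulates a single-end, 3′-adapter-ligated small-RNA library
built on 4N-random-flank chemistry (4 random nt ligated to each side of the
insert before the adapter; generation of flanks is on by default and
toggleable, so flank trimming can be exercised both ways).

* **Hairpins** are random sequences of 60–110 nt structured as
  lead | 5p arm (20–23 nt) | loop (≥ 10 nt) | 3p arm (20–23 nt) | tail.
  No secondary-structure realism is attempted: folding plays no role in any
  downstream computation.  The four bases flanking each arm inside the
  hairpin are drawn from {G, C} so that planted non-templated A/U tails
  always mismatch the template — the planted modification class is then
  unambiguous by construction.
* **Genomic placement**: each cluster occupies its own chromosome and
  strand, members within a `cluster_span_bp` window (default 40 kb, below
  the 50 kb polycistron threshold used downstream); singletons are isolated
  by > 200 kb.
* **Counts** are negative binomial per mature per sample, mean
  baseline × 2^(sum of applicable planted log₂ fold changes), baseline drawn
  log-normal (defaults: location 5.0, scale 1.2 on the natural-log scale,
  i.e. typical means of tens to hundreds of counts), dispersion 0.05 by
  default (Poisson at 0).  The default group design is 3 replicates per
  condition, matching typical bulk small-RNA-seq experiments.
* **Planted effects** come in two scopes: `cluster` (applied identically to
  every arm of every hairpin in a genomic cluster — the transcript-level
  mechanism) and `mirna` (one mature id — posttranscriptional).  Truth
  labels follow the scope; a mature with both kinds of effect is labelled
  transcript-level, mirroring the "at least partially transcript-level"
  reading used in the inference stage.
* **isomiR structure**: at most one planted modification per read — 3′ or
  5′ trimming, templated 3′ extension, or a non-templated poly-U / poly-A
  tail, with geometric tail/trim lengths (default success probability 0.6).
  Read names encode the origin mature, sample, serial and modification
  (`mature|sample|serial|tag`) — a non-standard but FASTQ-legal convention
  consumed only by oracle tests.
* **Time courses**: each mature follows one named template over the time
  points (default panel P1/P5/P14/P90, emulating postnatal muscle
  development), scaled to an amplitude in log₂ units (default 3).  The six
  non-flat templates (monotone up/down, transient up/down, late step-up,
  early step-down) were chosen to be mutually distinguishable under the
  correlation distance (max pairwise |r| ≈ 0.67); an earlier smooth
  "late-up" variant (x⁴) was replaced because it was nearly collinear
  (r ≈ 0.87) with the linear template and does not represent a distinct
  dynamic class.

What the generator does **not** emulate: sequencing errors, UMIs, adapter
dimers, other small-RNA classes (an optional uniform random-read fraction is
the only contamination model), GC or ligation bias, and genuine hairpin
folding.  Tests passing on these data therefore demonstrate correctness of
the algorithms under the stated model, not robustness to every artefact of
real libraries.

## Preprocessing

Adapter matching is exact-prefix: the read is cut at the leftmost occurrence
of the adapter's first `min_adapter_overlap` (default 8) bases; reads
without a match are discarded.  No mismatches are tolerated in the adapter
match — deterministic and sufficient at the simulated error rate (zero).
Thresholds are inclusive: the quantification branch keeps clipped inserts of
10–35 nt; the modification branch keeps ≥ 12 nt and requires ≥ 95 % of
bases at Phred ≥ 20.  The quality filter is applied only in the modification
branch by default (configurable), mirroring the workflow's placement of the
filter.  Reads containing N are dropped before collapsing since exact-match
mapping cannot place them.  Collapsing preserves total counts
(in = out + dropped, both reported per stage).

## Quantification

Reads are matched to hairpins by exact full-length sense substring search;
all occurrences are reported.  A read is counted toward a mature arm iff
some placement lies **entirely inside** the mature interval widened by 2 nt
each side (clipped at the hairpin ends).  Containment rather than overlap is
deliberate: it excludes loop-spanning fragments and is the natural reading
of a "mature ± 2 nt region".  A multi-mapping read contributes its full
count to every qualifying mature (`multimap="all"`, default) because the
counting rule sums *all* reads in each region; an even fractional split is
available (`"fractional"`).  The expression filter keeps features with
baseMean (mean of size-factor-normalized counts over all samples) strictly
above 10.

## Differential expression

The DE engine is a deliberately transparent NB analogue of the standard
count-based frameworks, not a bit-compatible clone of any of them; agreement
with an established implementation is verified in the test suite by rank
concordance of fold changes on simulated data.

* Size factors: median-of-ratios; when no feature is positive in all
  samples, geometric means fall back to positive entries only (warned).
* Dispersion: per-feature method of moments on normalized counts within
  conditions, φ = max((s² − μ)/μ², 10⁻⁸); a trend a₀ + a₁/μ fitted by least
  squares across features; final φ* = max(feature-wise, trend, 0.01).
  Taking the maximum is conservative by construction and, with n = 3
  per group, yields a measured null false-positive rate of ≈ 0.035 at
  nominal 0.05 (slightly conservative; see the acceptance report).
* Wald test: log₂FC = log₂((m_B + ½)/(m_A + ½)) on group means of
  normalized counts.  The pseudocount ½ bounds fold changes at zero counts.
  SE by the delta method, Var(log μ̂) = (1 + φμ)/(nμ); two-sided normal p.
  No independent filtering, shrinkage, or outlier refitting is performed
  (documented divergence from the reference framework).
* LRT: full model one NB mean per time point (estimated as the mean of
  normalized counts, exact MLE under equal size factors), reduced model a
  single mean, dispersion fixed at φ*; 2Δℓ ~ χ²(T − 1).  The reported
  log₂FC contrasts the last time point against the first.
* BH: step-up with monotonicity, NaN p values propagated and excluded from
  the test count; applied within the baseMean-filtered universe.

Known behaviour: median-of-ratios normalization absorbs part of the signal
when a large fraction of expressed features shift in one direction (as in
the worked example, where 6 of 24 features carry a 4-fold effect); null
features then acquire a small opposite apparent fold change.  This is
inherent to the normalization, shared with the reference framework, and is
why calibration tests plant sign-balanced or minority effects.

## isomiR classification

Reads are placed at every sense offset with ≤ 2 substitutions; placements
may overhang the hairpin 3′ end by ≤ 4 nt, each overhanging base counting as
a mismatch, so long tails remain classifiable within the budget.  For each
placement: (1) the arm with maximal overlap is assigned, requiring
≥ max(10 nt, 50 % of arm length); (2) terminal contiguous mismatches are
peeled — 3′ before 5′ — as candidate non-templated additions; the remaining
core must match the hairpin exactly (internal variants are out of scope and
rejected); (3) core ends are compared with mature ends to score trimming and
templated extension.  A terminal base that matches the template is by
definition templated; a mismatched one is non-templated — ties cannot arise
under this rule, and attribution is deterministic.  Among alternative
placements the call with the fewest mismatches, then the fewest modified
positions, wins (then hairpin id and offset for determinism).

Profiles count calls with collapsed-read support ≥ 2 (the configured
read-count threshold), weighted by read count (a unique-sequence weighting
switch exists since either convention is defensible).  `f_add3` counts any
3′ addition (templated or not); uridylation/adenylation frequencies require
a homopolymer U/A tail, oligoU/oligoA a homopolymer of length ≥ 2.  Group
comparison uses a two-sample t test on per-sample frequencies with BH across
modification classes — a pragmatic choice; the underlying workflow does not
name its test.

Consequence of the mismatch budget: non-templated tails longer than 2 nt
are not classifiable (≥ 3 mismatches) and are excluded from profile
denominators; recovery guarantees are therefore stated for "in-budget"
reads.

## Regulation inference

Clusters: single-linkage chaining of located hairpins per chromosome and
strand with a 50 kb consecutive-gap threshold — "within ~50 kb" is read as
neighbour spacing, so a chain may span more than 50 kb end to end; the
threshold is configurable.  Arm pairs: the two mature records of one
hairpin.  A significant miRNA (padj < α) is:

* `transcript_level` if ≥ 1 cluster- or arm-mate is significant with the
  same fold-change sign (`rule="any"`; `"all"` requires every significant
  mate to be concordant);
* `posttranscriptional_candidate` if it has expressed mates but none
  concordant-significant (opposite-sign significant mates land here, with
  the evidence retained);
* `unassigned` if no mate passes the expression filter.

Evidence for every expressed mate (id, relation, log₂FC, padj, concordance)
is serialized with each call.  Model comparison intersects significant sets
with both expressed universes and reports overlap counts, Pearson r with p
on the shared significant set, the sign-concordant fraction, and an optional
|log₂FC| threshold variant.

## Development analyses

Trajectory clustering operates on per-miRNA profiles (mean normalized count
per time point) z-scored across time points, so clusters capture shape, not
level; distance is 1 − Pearson r, linkage is average, and the tree is cut at
k = 6 groups by default.  Zero-variance profiles are excluded (undefined
z-score).  Monotone centroids are labelled by shape; labels are kept unique
across clusters.  The shift analysis takes the miRNAs significant in both a
developmental contrast and a knockout contrast and reports the global
Pearson r of the two fold-change vectors plus `fraction_negative`, the
fraction of opposite-sign pairs — the per-miRNA reading of "negatively
correlated", reported separately because the two readings differ.
Time points are ordered by their numeric suffix (P1 < P5 < P14 < P90) when
unambiguous, else by order of appearance in the sample sheet.

## Utilities

PSI = 100·inc/(inc + exc), undefined when both signals are zero; ΔPSI is the
difference in percentage points.  2^−ΔΔCt uses target-minus-reference Ct
differences between conditions.  Motif scanning expands IUPAC codes
(Y = C/T, with U read as T) and reports all overlapping match starts.  The
target-set shift uses a two-sample Kolmogorov–Smirnov test of target vs
non-target log₂ fold changes (vs all genes, switchable) plus the signed
median difference.

## Numerical and reproducibility choices

All randomness flows from one integer seed through per-stage
`SeedSequence(seed, stage)` streams; equal seeds give byte-identical FASTA,
GFF3, FASTQ and TSV outputs, which the pipeline manifest certifies with
SHA-256 checksums.  Internal coordinates are 0-based half-open; GFF3 I/O
converts to 1-based inclusive.  Sequences are held in the DNA alphabet
(U → T on input).  Means are floored at 10⁻⁸ in NB likelihoods; LRT
statistics are clipped at 0; size factors of identical columns are exactly 1.

Verification problem sizes (acceptance script and test suite) were chosen so
each check is statistically informative at desk scale: 200 random instances
for the counting oracle, 2000-feature null and power simulations at n = 3/3,
~10⁴ reads per isomiR recovery run, 60–120 miRNAs for trajectory and shift
recovery over 3 replicate simulations.

## Known limitations

* The DE engine omits empirical-Bayes dispersion shrinkage, independent
  filtering and outlier handling; its padj values agree with reference
  implementations in rank but not digit-for-digit.
* The two-tier quantification (exact for counts, ≤ 2 mismatches for
  isomiRs) follows the modelled workflow; neither tier handles indels.
* Cluster concordance is a proxy for shared pri-miRNA transcription; it
  cannot distinguish co-transcription from co-regulation of adjacent
  independent promoters.
* The t test on modification frequencies treats per-sample frequencies as
  approximately normal; with very low assigned-read counts a count-based
  test would be preferable.
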