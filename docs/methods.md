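# Methods

This note records the models, numerical conventions and design choices
behind `chorline`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Copy-number calling from panel coverage

Each targeted-panel interval is called independently from its mean
sequencing depth: `log2_ratio_i = log2(depth_i / m)` where `m` is the
sample mean depth — by default the unweighted arithmetic mean over
intervals (a length-weighted mean is available via
`compute_log2_profile(..., length_weighted=True)`; with near-constant
target lengths the two coincide). Calls use fixed symmetric cutoffs with
strict inequalities: gain when log2 > +0.2, loss when log2 < −0.2,
balanced otherwise. No segmentation, smoothing, GC or length
normalization is applied: the procedure is deliberately the simplest one
that resolves single-copy events at ~100× panel depth, and each interval
stands on its own.

Numerical conventions: zero-depth intervals map to a finite floor ratio
(default −8, configurable) rather than −∞ so downstream arithmetic stays
finite; intervals below an optional `min_depth` are marked *missing* and
excluded from calling and from consensus tallies (numerator and
denominator). Coordinates are 0-based half-open (BED) internally; VCF
positions stay 1-based end to end, since variant identity keys mirror the
VCF record directly. Two-channel array profiles use `log2(ch1/ch2)` per
probe with the same call rules; probes with a zero reference channel are
missing, not errors.

The ±0.2 cutoff on a log2 ratio corresponds to ~±15 % depth deviation.
Its adequacy therefore hinges on the spread of per-interval ratios. With
`mean` estimated over thousands of intervals, the spread is governed by
per-interval noise alone; see the noise model below.

Consensus profiles report, per interval, `100 · n_gain / n_called` and
likewise for losses, where `n_called` excludes missing calls. Profile
comparison reports the fraction of shared (coordinate-matched), mutually
called intervals with identical state plus a full confusion table;
intervals missing in either profile are tabulated but not counted in the
concordance denominator. Chromosome-arm summaries (a reporting
convenience, not part of the calling) assign intervals to arms by
midpoint against approximate hg19 centromere positions and label an arm
aberrant when more than half of its called intervals agree in direction.

## Coverage noise model (synthetic data)

An interval's "depth" is the mean per-base coverage of the reads
overlapping it, so the natural Poisson quantity is the *read count*, not
the depth value itself: the generator draws
`reads ~ Poisson(depth · L / read_length)` and reports
`depth = reads · read_length / L` (negative binomial with user dispersion
optionally, for overdispersed panels). With the defaults — 100× expected
depth, 500 bp targets, 100 bp reads, hence ~500 reads per diploid
interval — the log2-ratio standard deviation is ≈ 1/(ln 2 · √500) ≈ 0.065,
and the ±0.2 cutoffs sit at ≈ 3σ: single-copy losses (expected ratio −1)
and gains (+0.585) separate cleanly while diploid intervals are
mis-called at ~0.2 %. Placing the Poisson directly on the depth *value*
(σ ≈ 0.144 at 100×) would instead mis-call ~18 % of diploid intervals —
that model corresponds to one read per unit depth and does not describe
mean per-interval coverage. Copy number 0 yields exactly zero reads; a
contamination fraction `f` (default 0) blends the expected copy number
with the diploid baseline, `cn_eff = (1−f)·cn + f·2`, to model
normal-cell impurity.

The shipped default scenario encodes the Chor-IN-1 alterations (monosomy
2q and 3q, 8q21.3 microdeletion, 11q13.1 amplification, 13q21.31-qter
duplication, trisomy 7, biallelic 9p21 deletion) on approximate hg19
coordinates; a five-line panel variant adds the recurrent shared events
(1p monosomy, trisomy 7 and 9p21 loss in all lines but JHC7; 22
monosomy in three lines) so that consensus percentages have known truth
(e.g. 80 % chr7 gain). What the simulations do **not** model: GC and
mappability bias, alignment artifacts, replication-timing waves,
correlated noise along the genome, subclonality. Passing recovery tests
therefore shows the caller is correct *given* well-behaved coverage, not
that ±0.2 thresholds are optimal for any particular instrument.

## Variant filtering and somatic subtraction

A record is retained iff it is non-synonymous, its population minor
allele frequency is unknown (not in dbSNP) or ≤ 0.02, DP ≥ 20 and
ADV ≥ 7. All boundaries are strict as stated (DP = 20, ADV = 7 and
MAF = 0.02 pass); records failing several rules are counted under each;
`ADV > DP` is a malformed input, not a filterable record. Multi-allelic
records must be pre-split — the readers reject comma-separated ALT.
Somatic calls are exact set algebra, `(cell ∩ tumor) \ normal`, on
(chrom, pos, ref, alt). Because the "highly consistent (>80 %)"
convention for two variant sets is ambiguous, three metrics are always
reported and named: Jaccard (∩/∪), overlap (∩/min) and containment
(∩/|A|); two empty sets score 1.0 by convention. A `near_misses` report
lists records failing exactly one rule within a margin (defaults: DP
within 5, ADV within 3, MAF within 0.01) — the margins are this
package's choice, mirroring the manual rescue inspection of variants
called just below threshold in low-coverage regions.

The variant generator plants germline variants in all three samples,
tumor-only variants in cell line + tumor, and normal-only variants in the
normal; effect and dbSNP-frequency annotations are exact quotas over the
germline pool (deterministic counts per seed), and per-sample DP/ADV are
Poisson/binomial around a 100× mean so that planted variants pass the
coverage filters with overwhelming probability.

## STR identity

Scoring counts alleles over loci typed in both profiles, homozygotes
canonicalized to a single designation. Default algorithm is Tanabe
(`100·2·shared/(n_q+n_r)`); Masters query/reference variants divide by
one profile's count instead. Amelogenin is excluded by default (a sex
marker, not a polymorphic STR) and can be included by flag; the
conventional ≥ 80 % threshold flags an authenticated match, with ties in
database searches broken lexicographically. The profile mutator replaces
a chosen allele with a designation previously unused at that locus so
shared-allele counting stays unambiguous; a heterozygous X/Y amelogenin
has no unused designation and is therefore not mutable.

## Kinome expression

Size factors re-implement the median-of-ratios estimator: genes with a
zero in any sample are excluded from the geometric-mean reference, and
each sample's factor is the median ratio to that reference; a single
sample gets factor 1. Expression is `log2(count/sf + 1)`; the +1
pseudocount maps zero counts to exactly 0 and is the main transform
choice left open by convention (no variance-stabilizing transform, no
length normalization — amplicon inserts are near-constant length).

Tiers: gene vectors are clustered with complete linkage under the
Chebyshev (maximum-coordinate) distance and the dendrogram is cut into 3
clusters labeled high/medium/low by descending mean expression. Genes
are sorted lexicographically before clustering so exact merge-height
ties resolve deterministically; a cut that fails to produce three
non-empty clusters raises rather than silently relabeling.

Differential analysis is one line vs the rest with a single replicate
per line, so a two-group test is impossible; the package uses a
two-sided one-sample t-test of the other lines' values against the
target's value (df = n_others − 1). Significance is raw p < α (default
0.05) **and** |log2 FC| ≥ log2(2); no multiple-testing correction enters
the call, but a Benjamini–Hochberg column is emitted for transparency.
Zero variance among the rest with a nonzero shift is reported as p = 0
and flagged degenerate. Note the target value appears in both the shift
and the test, so the null distribution is only approximately t — with
the |FC| ≥ 1 gate the realized false-positive rate on simulated nulls is
well below α (~1 %), which the acceptance script measures rather than
assumes. The count generator is negative binomial
(`var = m + φ·m²`, Poisson at φ = 0) with gene means drawn log-uniform
from 50–5000, unit scale factors unless specified, and exact ±3 log2
one-sample shifts for six named kinases (ULK4, NPR1, CDKL4 up; FGFR3,
KDR, WNK2 down); dispersion 0.05 reflects technical-replicate-level
noise of a targeted amplicon assay, not biological replication.

## ΔΔCt and doubling time

ΔCt(s, g) = Ct(s, g) − mean of the three reference-gene Cts in s
(arithmetic mean of Cts = geometric mean of expression levels);
ΔΔCt subtracts the calibrator sample's ΔCt; RQ = 2^(−ΔΔCt) with
amplification efficiency fixed at 2. Replicate reactions are averaged
first. RQ is exactly invariant to any per-sample additive Ct offset and
the calibrator's RQ is identically 1.

Doubling time uses DT = Δt / Δlog2 N — hours per doubling. (The
printed convention DT = Δlog2 N / Δt is dimensionally doublings per
hour; the reciprocal is implemented so that a 7-day culture reports
168 h.) `two_point` uses the window endpoints; `regression` takes the
reciprocal slope of a least-squares fit of log2(count) on time. Both
agree exactly on noiseless exponential data; non-positive growth raises
"no exponential growth". The exponential window defaults to the full
series — no automatic changepoint detection.

## Randomness and problem sizes

All generators draw from per-stream substreams of a single seed
(`SeedSequence([seed, crc32(stream)])`), so adding one generator call
never perturbs another stream and every simulator is byte-reproducible.
The test-suite and acceptance problem sizes — ~30 k intervals for
copy-number recovery, 1,000 random fixtures for the set-algebra oracles,
487 genes × 5 samples × 20 replicates for the differential screen — were
chosen to give stable empirical rates at a few seconds of runtime each;
they are the package's own defaults, and all scale up by argument.

## Known limitations

- Approximate hg19 chromosome sizes and centromere midpoints are built
  in for scenario validation and arm summaries; supply your own
  centromere table for other builds.
- The consensus reader ingests percentage profiles (e.g. exported
  clinical-cohort consensus tracks) but no external database access is
  provided or attempted.
- Effect annotation, dbSNP lookup and variant calling itself are out of
  scope: the pipeline starts from called, annotated variant tables.
- The one-sample differential design cannot distinguish biological from
  technical variation in the target line; with a single target replicate
  that is a property of the design, not the test.
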