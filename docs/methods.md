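# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the known limitations of `mediptile`.

## The analysis model

MeDIP-chip hybridizes immunoprecipitated methylated DNA (MeDIP channel)
and total input DNA (input channel) of the same sample to a promoter
tiling array. The per-probe enrichment log2(MeDIP/Input) cancels the
probe's sequence-dependent affinity, which multiplies both channels.
Given replicate arrays for a control and a treated group, the per-probe
group difference is

    M′ = mean_treated[log2(MeDIP/Input)] − mean_control[log2(MeDIP/Input)]

and the replicate consistency of a probe is summarized by the coefficient
of variation of its *linear-scale* ratio 2^log2ratio (sd/mean across
replicates, per group). CV is computed on the linear scale because the CV
of a log ratio near zero is ill-defined (the mean sits at 0).

### Probe-level significance

The published MeDIP-chip workflow scores probes with a proprietary
sliding-window peak finder; this package defines the probe statistic
explicitly. For each probe, the *window* is every probe of the same
promoter within ±window/2 (window = 750 bp by default) of it. The window's
evidence is its set of replicate-pair differences — treated minus control
log ratio per replicate index, three values per probe at n = 3 — compared
with the experiment-wide pool of the same differences by a one-sided
Kolmogorov–Smirnov test in the direction of the window's mean difference.

Two numerical points matter here:

* With the pool three to four orders of magnitude larger than any window,
  the null distribution of the one-sided statistic D is that of the
  one-sample case; the p-value uses the exact Birnbaum–Tingey tail
  (`scipy.stats.ksone.sf`) rather than the asymptotic `exp(−2D²n)`
  formula, which is inaccurate at window sizes of 6–21 samples.
* The test's direction is chosen from the data (the sign of the window
  mean). The reported p therefore doubles the one-sided tail; without the
  doubling the probe p-value is anti-conservative by a factor of ~2, which
  we verified by simulation against a null pool.

Probes with exactly zero mean difference (possible in noiseless synthetic
data) get p = 1 and no direction.

### Peaks and the DEP filter

A candidate peak is a maximal run of ≥ 2 consecutive probes with p ≤ 0.1
sharing a direction; runs also break where adjacent probes lie more than
the merge gap (500 bp) apart, and candidate runs separated by ≤ 500 bp are
merged (every probe spanned by the merged interval becomes a member, so
the filter's "half of the probes in a peak" criterion operates on the
physical peak, not only on its significant probes). Peak-level scores:

* PeakScore = mean of −log10(probe p) over member probes;
* peak P = Fisher's combination of member probe p-values (χ², 2k df).

A peak is reported as a DMR iff all of the following hold (defaults are
the published thresholds; every one is a config key):

1. max over groups of the within-peak median log2 ratio ≥ 0.3, and the
   within-peak median M′ is non-zero — its sign assigns hyper/hypo;
2. ≥ half of the member probes have CV ≤ 0.8 in **both** groups;
3. PeakScore ≥ 2 and peak P ≤ 0.01.

No multiple-testing correction is applied across peaks (the original
workflow applies none either); the output header records this.

### The false-positive floor

Member probes of a run share roughly two thirds of their window samples at
the default geometry (750 bp window, ~225 bp probe spacing), so one noise
excursion in a window produces a qualifying 2–3 probe run, not an isolated
probe. With a correctly calibrated probe-level p this puts the cascade's
null call rate at ~1% of promoters (measured over 20 null simulations:
1.2%). Consequently, when 5% of promoters carry a true effect, precision
plateaus around 0.85: the false calls are marginal excursions with
PeakScore just above 2 and |median M′| around 0.3–0.7, against ~1.0 for
true spikes. This floor is intrinsic to the probe-run design — it can be
lowered only by raising the score/P thresholds or requiring longer runs,
both of which trade directly against sensitivity. Users who need higher
precision should raise `min_peakscore` (e.g. to 3) and accept the
sensitivity cost; we deliberately ship the published thresholds as
defaults.

### CpG-density classes

Promoter sequences are scanned with 500 bp windows (step 5 bp; an
exhaustive step-1 scan is available and used as the oracle in tests) on
both the given strand and its reverse complement — CpG is palindromic but
GC windows differ at the edges. Per window: GC fraction, and CpG
observed/expected = (#CpG × N)/(#C × #G) with N the number of unambiguous
bases; windows with > 10% ambiguous bases are skipped, and ambiguous bases
are excluded from all counts. Classes: HCP if any window has GC > 0.55 and
o/e > 0.75; LCP if no window has o/e > 0.48; ICP otherwise. Because the
step-5 scan sees a subset of the step-1 windows it can only downgrade a
class (HCP→ICP or ICP→LCP), never upgrade — a property asserted in tests.

### Gene-set over-representation

The query is the set of genes owning at least one DMR (multiple DMRs per
gene count once); the background is all genes represented on the array,
the only defensible universe for a promoter-array design. Raw p is the
hypergeometric upper tail P(X ≥ k); fold enrichment is (k/n)/(K/N);
BH-FDR is computed for every collection. Significance follows the dual
scheme: ≥ 2 query genes, and for pathway-type collections FDR < 0.05 with
fold ≥ 1.50, for ontology-type collections raw P < 0.01 with fold ≥ 1.10
(the FDR column is still reported for ontology results). An EASE-style
conservative variant (tail at k−1) is available behind a flag.

### qPCR

Relative expression uses the comparative-Ct method: ΔCt = Ct(target) −
Ct(reference gene) per sample, ΔΔCt subtracts the mean ΔCt of the
reference cell of the 2×2 design (default: control-mother,
control-diet offspring), fold = 2^−ΔΔCt — so the reference group has
geometric-mean fold exactly 1. MeDIP-qPCR enrichment is percent of input
with dilution correction, %input = 100·2^((Ct_input − log2 f) − Ct_IP).
Group comparisons use a two-factor ANOVA with type-II sums of squares,
which equals the classical balanced decomposition at equal cell sizes and
remains well-defined for unbalanced synthetic designs; effects with zero
sum of squares report F = 0, P = 1 rather than 0/0.

## The synthetic-data generator

The generator emulates a scaled-down two-channel promoter tiling design:
2,000 promoters × 8 evenly spaced probes across a strand-aware
−1300..+500 bp TSS window, three replicate arrays per group (the full
22,327-promoter geometry is a config choice; the scale-down keeps a
pipeline run under a minute). Chromosomes cycle through the 21 mouse
chromosome names.

Intensity model, all on the log2 scale: probe affinity ~ N(10, 1) drawn
once per probe and shared by both channels; promoter methylation state is
two-valued — a minority (40%) methylated with enrichment ~ N(1.0, 0.25),
the rest unmethylated ~ N(0, 0.1) — shared by both groups; i.i.d. N(0,
0.25) noise per probe, array and channel. A fraction (5%) of promoters is
spiked by ±1.0 in the treated group's MeDIP channel across all their
probes: gains of methylation at unmethylated promoters, losses at
methylated ones — the only directions the starting states admit (a
promoter cannot lose methylation it never had). The two-state baseline is
what gives the DEP filter's median-enrichment criterion real work to do;
with a flat baseline it would be vacuous.

Promoter sequences are drawn i.i.d. at a class-specific GC content and
then CpG-thinned to a class-specific retention factor (HCP: GC 0.65,
retention 1.0; ICP: 0.50/0.55; LCP: 0.30/0.05), which lands each class
safely inside its window-rule region; the classifier recovers the intended
class for ≥ 95% of sequences (measured: ~100%). Gene sets are uniform
draws over the array's genes, with a configurable number of sets enriched
for the spiked promoters. qPCR tables are Gaussian ΔCt around configured
cell means of the 2×2 design.

All stage RNGs derive deterministically from one top-level seed
(`numpy.random.SeedSequence.spawn`); identical config ⇒ byte-identical
output files.

What the generator does **not** model: dye bias, spatial artifacts,
GC-dependent affinity curves, fragment-level autocorrelation beyond the
promoter effect, partial-promoter methylation changes. Passing spike-in
benchmarks therefore demonstrates the pipeline's statistical behavior
under its own assumptions, not performance on raw scanner data.

## Problem sizes used in tests and the acceptance script

Unit and oracle tests run on fixtures of tens of promoters; the spike-in
benchmark uses ten experiments of 2,000 promoters (16,000 probes, 6
arrays) and twenty 300-promoter null experiments; the classifier benchmark
uses 300 sequences of 1,800 bp. These sizes were chosen so a full
benchmark finishes in well under a minute while keeping ≥ 1,000 true
spikes and ≥ 100,000 null probes behind the measured rates.

## Known limitations

* No claim of equivalence with the proprietary scanner software's
  normalization or peak scores; the probe statistic here is an explicit,
  documented stand-in with the same architecture (windowed KS against the
  array-wide distribution, average −log10 p peak scores).
* Inter-array normalization is per-array median centering (or none);
  loess/quantile normalization is out of scope.
* The enrichment module tests user-supplied GMT collections; it does not
  ship or download any term database.
* Peak boundaries are probe positions, not fragment boundaries; reported
  intervals are tight spans of member probes (BED 0-based half-open).
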