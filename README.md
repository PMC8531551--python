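# mediptile

Differential DNA-methylation analysis for two-channel MeDIP promoter tiling
arrays (MeDIP-chip), built around the workflow used to compare offspring
brown-adipose-tissue methylomes between maternal-diet groups: per-probe
enrichment ratios, the M′ group-difference statistic, sliding-window peak
calling with a multi-criterion DEP filter, CpG-density promoter classes
(HCP/ICP/LCP), gene-set over-representation with dual significance rules,
and the accompanying qPCR computations (2^−ΔΔCt, percent input, two-factor
ANOVA). A synthetic array generator with spike-in ground truth drives every
stage, so the whole pipeline can be exercised and benchmarked without any
array download.

## Who this is for

Anyone who needs a transparent, scriptable reimplementation of the classic
NimbleGen-style MeDIP-chip promoter analysis — to reanalyse legacy
two-channel data, to sanity-check published DMR lists, or to study how the
filter cascade behaves under known ground truth.

## The method

Each probe carries two channels: MeDIP (immunoprecipitated, Cy5) and input
(total DNA, Cy3). The working quantity is the enrichment ratio
log2(MeDIP/Input), which cancels probe affinity. For groups of replicate
arrays (control vs treated, e.g. NC-CD vs DIO-CD):

* **M′** per probe: `M′ = mean_treated[log2(MeDIP/Input)] − mean_control[log2(MeDIP/Input)]`.
* **Peak finding**: every probe gets a one-sided KS p-value comparing its
  750 bp window's replicate-pair differences with the experiment-wide
  difference pool; runs of ≥ 2 consecutive significant probes (p ≤ 0.1)
  form peaks, merged across gaps ≤ 500 bp.
* **DEP filter**: a peak is a DMR iff (i) at least one group has a
  within-peak median log2 ratio ≥ 0.3 and the median M′ is non-zero (its
  sign sets the hyper/hypo direction); (ii) at least half its probes have a
  replicate CV ≤ 0.8 in both groups; and PeakScore ≥ 2 (mean of −log10
  probe p) with combined P ≤ 0.01.
* **CpG classes**: a promoter is HCP if some 500 bp window has GC > 0.55
  and CpG observed/expected > 0.75; LCP if no window reaches o/e > 0.48;
  ICP otherwise.
* **Enrichment**: hypergeometric upper tail against the array's gene
  universe; significant iff ≥ 2 query genes and — pathway collections:
  BH-FDR P < 0.05 with fold ≥ 1.50; ontology collections: raw P < 0.01 with
  fold ≥ 1.10.
* **qPCR**: fold change `2^−ΔΔCt` vs a reference cell of the 2×2
  maternal × offspring diet design; MeDIP-qPCR
  `%input = 100 · 2^{(Ct_input − log2 dilution) − Ct_IP}`; group effects by
  two-way ANOVA (type-II SS).

## Worked example

```python
import mediptile as mt

cfg = mt.SimConfig(n_promoters=1000, seed=1)     # 8 probes/promoter, n=3/group
layout = mt.generate_annotation(cfg)
tables, truth = mt.simulate_intensities(cfg, layout)

arrays = [mt.log_ratio_array(df, k, k.split("_")[0], int(k[-1]))
          for k, df in tables.items()]
stats = mt.compute_probe_stats([a for a in arrays if a.group == "control"],
                               [a for a in arrays if a.group == "treated"])
dmrs = mt.filter_deps(mt.find_peaks(stats))
```

Running `python examples/02_dmr_calling.py` (exactly this analysis) prints:

```
probes           : 8000
candidate peaks  : 228
DMRs after filter: 63
spiked promoters : 50
recovered        : 50 (100.0% sensitivity, 79.4% precision)

first three DMRs:
  chr1:898811-900388  G00336  hyper M'=+1.18  score=6.86  P=1.52e-44
  ...
```

All 50 planted methylation differences are recovered with the correct
direction; the extra calls are the filter cascade's false-positive floor
(see `docs/methods.md` for why it sits where it does). The other example
scripts cover the full pipeline run, CpG classification and composition
summaries, gene-set enrichment, and the qPCR computations; each prints the
numbers it computes and what they mean.

A thin CLI mirrors the library:

```bash
medip-tile run --config run.yaml          # full pipeline
medip-tile simulate --seed 1 --out sim/   # just the generator
medip-tile call --in sim/ --out dmrs.tsv  # just the caller
```

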