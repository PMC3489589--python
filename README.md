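# ligbias

Ligation-bias analysis for small-RNA sequencing libraries.

Small-RNA libraries are made by two successive RNA-ligase reactions: a
3' adapter is attached by truncated T4 RNA ligase 2, then a 5' adapter
by T4 RNA ligase 1.  Both enzymes care about the secondary structure at
the junction they seal, so the probability that a given small RNA is
cloned depends on how it folds with the adapters.  The result is
heavily distorted read counts: sequencing a nominally equimolar
degenerate pool misses a large share of its sequences outright, and in
biological samples the same effect scrambles miRNA abundance ranks and
arm annotation.  "High-definition" (HD) adapters — standard adapters
carrying a fully degenerate 4-nt tag at the ligation end, i.e. a pool
of 256 adapter variants per side and 65,536 tag pairs — average the
preference out.

`ligbias` is a Python library for people who make or analyse such
libraries: it quantifies the bias, profiles the ligases' structure
preferences, evaluates HD-adapter designs, and ships a generative
simulator so every statistic can be validated against known ground
truth.

## What it computes

* **Poisson count model.**  For a pool of `p` possible molecules
  sequenced to depth `n`, unbiased sampling makes each read count
  Poisson with λ = n/p.  `summarize_counts` tests the observed
  multiplicity histogram against this null (Pearson χ², tail bins
  pooled to expected ≥ 5, dof = bins − 1) and `capture_fraction`
  reports the share of the pool seen at least once (null expectation
  `1 − e^(−λ)`).
* **Junction structure profiles.**  `pairing_profile` folds
  insert/adapter concatenations (built-in deterministic folder, or
  ViennaRNA via `engine="vienna"`) and averages per-position
  base-pairing; `junction_pairing_fraction` reads the base flanking a
  ligation point, and `mfe_abundance_correlation` gives the R² between
  a sequence's MFE (folded with the 3' adapter) and log10(count + 1).
* **HD adapter diagnostics.**  Tag-space combinatorics, the number of
  distinct structures one insert forms across tag combinations, and
  per-insert barcode-pair capture histograms.
* **miRNA quantification.**  Reads-per-million ranking, detection-
  threshold curves, wild-type/knockout fold-change concordance between
  protocols, arm-switch detection (dominant strand per protocol on
  duplexes above 10 RPM; direction −1 marks a switch), and the
  fold-change > 1.4 + star-strand filter for new miRNA candidates.
* **Platform bias.**  MFE distributions of miRNA + adapter
  concatenations for platform-labelled sets, compared with a two-sided
  Wilcoxon rank-sum test.
* **Simulator.**  A seeded generative model of two-step ligation: each
  pool molecule gets weight `exp(β₃·s₃ + β₅·s₅ − γ·MFE)` where s₃/s₅
  encode pairing upstream of the 3' junction and single-strandedness
  at the 5' junction; reads are a multinomial sample of the weights,
  and HD arms average weights over sampled degenerate tags.  β = 0 is
  exactly the unbiased null.

## Worked example

```python
from ligbias import (AdapterSet, SimulationConfig, simulate_library,
                     summarize_counts, capture_fraction)

adapters = AdapterSet("GUUCAGAGUU", "AUCUCGUAUG", tag_length=0)
for label, beta in (("unbiased", 0.0), ("ligation-biased", 3.0)):
    cfg = SimulationConfig(insert_length=6, pool_size=4**6, depth=20_000,
                           beta3=beta, beta5=beta, seed=1)
    lib = simulate_library(cfg, adapters)
    s = summarize_counts(lib.table, 4**6)
    print(label, f"chi2={s.chi2:.1f} p={s.pvalue:.3g} "
                 f"capture={capture_fraction(lib.table, 4**6):.1%}")
```

prints

```
unbiased chi2=9.8 p=0.709 capture=99.3%
ligation-biased chi2=372442.4 p=0 capture=34.4%
```

Both libraries have λ = 20,000/4,096 ≈ 4.9, so an unbiased run fits the
Poisson null (p = 0.71) and captures essentially the whole pool, while
the biased run is rejected beyond any doubt and leaves two-thirds of
the pool unseen — the same qualitative fingerprint degenerate-pool
sequencing shows in practice.  The `examples/` directory has one short
script per capability (count model, junction profiles, HD diagnostics,
miRNA quantification, platform bias), each printing the numbers it
computes and what they mean.

A thin CLI mirrors the library for shell use:

```
ligbias simulate --insert-length 9 --depth 1000000 --seed 1 -o run/
ligbias countmodel run/counts.tsv -p 262144 -o run/cm/
ligbias hd --tag-length 4 -o run/hd/
```

Every run directory contains a `config.yaml` from which the run can be
reproduced exactly.

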