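# Methods

## The problem

Small-RNA sequencing libraries are built by ligating adapters onto RNA
inserts: a pre-adenylated 3' adapter joined by truncated T4 RNA ligase 2
(Rnl2), then a 5' adapter joined by T4 RNA ligase 1 (Rnl1).  Both
ligases are sensitive to the secondary structure at the junction they
seal — Rnl2 favours a double-stranded context immediately upstream of
its junction, Rnl1 favours single-stranded ligation sites — so the
efficiency with which a given insert is cloned depends on how it folds
with the adapters.  In a nominally equimolar degenerate pool this
appears as gross departure from the sampling statistics expected of an
unbiased library; in biological samples it distorts miRNA read counts,
ranks, arm annotations, and which miRNAs get discovered at all.
"High-definition" (HD) adapters carry a fully degenerate tag of 4 nt at
each ligation-proximal end, so every insert meets a pool of 256 adapter
variants per side (65,536 pairs) and the structure preference is
averaged out.

`ligbias` implements the statistical read-outs of this phenomenon and a
generative model of it, so that every analysis stage can be exercised
and validated without access to any particular sequencing run.

## Count model

Sequencing an equimolar pool of `p` distinct molecules to depth `n` is
a sampling process with very small per-molecule probabilities, so each
molecule's read count is approximately Poisson with rate λ = n/p.
`counts.summarize_counts` compares the observed multiplicity histogram
(number of distinct sequences seen exactly k times, including the
unobserved k = 0 class, `p − #distinct`) with `p·PoissonPMF(k; λ)` using
a Pearson χ² statistic.

Binning: adjacent count values are pooled greedily from the high-count
tail inward until every bin has expected frequency ≥ 5 (the left tail,
which is equally thin once λ exceeds a few units, is absorbed by the
same pass; a leftover remainder joins its neighbour).  Degrees of
freedom are `#bins − 1`; λ is fixed at n/p rather than fitted, so no
additional degree is subtracted.  If fewer than two adequate bins
remain the test is refused as degenerate rather than reported.

The capture fraction is the proportion of the `p` possible molecules
observed at least once; under the unbiased null its expectation is
`1 − e^(−λ)`, which the test suite uses as an independent check on the
simulator.

## Folding engines

Structure statistics are engine-agnostic: every profile and MFE
operation takes an `engine` argument satisfying one contract
(`fold(seq, temperature) -> SecondaryStructure` with a balanced
dot-bracket of sequence length and a non-positive MFE).

* **builtin** — a Nussinov-style dynamic program maximizing
  stacking-weighted pair scores (G-C 3, A-U 2, G·U 1, +1 per stacked
  pair), minimum hairpin loop 3 nt.  Ties are broken deterministically:
  pairing is preferred over bifurcation, then the smallest 5' index and
  largest 3' index.  The reported energy is the negated score × 0.5, in
  kcal/mol-like units; temperature only rescales the energy by the
  inverse absolute temperature relative to 22 °C and never changes the
  chosen structure — a stated limitation, accepted because the engine
  exists for hermetic testability, not thermodynamic realism.  The test
  suite proves it optimal against exhaustive structure enumeration for
  all tested sequences up to 12 nt.
* **vienna** — the ViennaRNA (RNAfold) Python bindings, default model
  with the temperature set per call (22 °C throughout this package's
  defaults).  This is the engine to use when comparing against
  RNAfold-derived numbers; single-MFE structures only, no ensemble.

Only one optimal structure is reported per sequence; partition-function
quantities and pseudoknots are out of scope.

## Junction profiles

Constructs are concatenations `adapter5 + tag5 + insert + tag3 +
adapter3` (segments dropped per mode), with each ligation junction
indexed at the first base of its downstream segment; for HD adapters
the junction lies between the degenerate tag and the insert, because
the tag is the ligated end of the adapter.  A pairing profile is the
per-position mean of paired/unpaired indicators over the molecules'
MFE structures, and "pairing at the ligation site" reads the single
base immediately adjacent to the junction on the stated side (the
window is deliberately one base; wider windows can be had by averaging
profile positions).  Profile similarity is the squared Pearson
correlation of two frequency vectors.  The abundance transform for the
MFE–abundance correlation is `log10(count + 1)`; the choice is recorded
here because reasonable alternatives (rank, raw count) exist — the
pseudo-count keeps zero-read sequences finite and the log matches the
heavy-tailed count distributions the bias produces.

## Simulator

`simulate.simulate_library` draws `pool_size` distinct inserts
uniformly from the 4^L sequence space, folds the relevant construct for
each (insert + 3' adapter when only the 3' step is biased; the full
construct when the 5' step is too), and assigns the Boltzmann-like
ligation weight

    w = exp(beta3·s3 + beta5·s5 − gamma_mfe·MFE)

with `s3 = +1` if the base upstream of the 3' junction is paired (else
−1) and `s5 = +1` if the base downstream of the 5' junction is unpaired
(else −1).  The two indicators encode the two ligase rules directly;
the optional MFE term adds overall-stability selection.  Reads are a
multinomial sample of size `depth` from the normalized weights, so
`beta3 = beta5 = gamma_mfe = 0` reproduces the uniform (Poisson-
compatible) null exactly and requires no folding.  For HD adapters each
molecule's weight is the mean over `tag_samples` uniformly drawn tag
pairs — the averaging mechanism itself — and each read carries its tag
pair as provenance for barcode-capture analysis.

Defaults emulate an N9 experiment: insert length 9, the full 4^9 pool,
depth 10^6, unbiased.  A single integer seed drives every random
stream; paired standard/HD arms share the insert pool through
deterministic substreams, so arm differences isolate the adapter
effect.

What the generator does **not** model: sequencing errors, PCR
amplification bias, synthesis inequality of the degenerate pool, and
ligation kinetics beyond the junction-structure indicators.  Passing
tests therefore demonstrate that the statistics detect and the HD
mechanism mitigates *structure-coupled sampling bias*; they do not
certify behaviour under error-contaminated or amplification-biased
real data.

The duplex-count generator (`simulate_duplex_counts`) plants a known
fraction of protocol-dependent arm switches among precursors with
log-normal expression and dominant-arm shares in [0.75, 0.95], Poisson
counts per replicate library — strong, clean effects by design, so the
detector's recall is measured against unambiguous truth.

## miRNA statistics

RPM normalization divides by the total reads assigned to known miRNAs
(configurable to total trimmed reads); ranks break count ties
lexicographically so they are a permutation.  Arm-switch detection sums
replicate libraries per protocol, analyses duplexes whose more abundant
strand exceeds 10 RPM in at least one protocol, calls the dominant
strand per protocol by the higher cumulative count (ties yield "no
call" rather than an arbitrary winner), and flags direction −1 when the
dominant strands differ.  All ratio computations use a pseudo-count of
1 raw read.  The new-candidate filter retains a hairpin candidate only
when its wild-type/knockout fold change strictly exceeds 1.4 and a star
strand has been observed.  The platform comparison uses the two-sided
Wilcoxon rank-sum (Mann–Whitney) test with normal approximation and
tie correction; a fully tied comparison warns and reports p = 1.

## Adapter trimming

The 3' adapter core is located by exact match of its first 8 nt
(leftmost occurrence); the match and everything after it are removed,
along with `tag_length` bases on each side of the insert for HD reads.
No mismatch rescue is attempted — reads whose tag-adjacent bases carry
sequencing errors are rejected as `no-adapter`, a deliberate,
deterministic policy for a package whose inputs are mostly synthetic or
pre-tallied.  Reads containing N are dropped and counted, not
corrected.  The minimum insert length defaults to 16 nt, below the
20–32 nt small-RNA range so that toy tests have margin.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale, chosen once: χ² calibration
uses 4^6 pools at depth 20,000 (λ ≈ 4.9) over hundreds of seeds;
bias-power and HD-comparison runs use pools of 256–1,024 molecules with
short adapters and bias strengths β = 3 (weight ratio e^6 between
favourable and unfavourable junctions — strong but not degenerate);
control junction fractions use 1,000 random 21-mers with full-length
standard adapter sequences at 22 °C.  The full-space structural-
diversity sweep (65,536 tag pairs) is guarded behind an explicit flag;
diversity defaults to exhaustive evaluation only for tag lengths ≤ 2.
Random-subset evaluation never increases the distinct-structure count,
and the census always sums to the number of pairs evaluated.

## Known limitations

* The built-in folder's energies are not Turner free energies; figures
  tied to a specific RNAfold version (absolute MFE distributions,
  structure counts for a particular insert) are engine-dependent.
* Variable-length insert profiling is unsupported; profiles require
  fixed-length inserts.
* miRBase retrieval is out of scope: platform labels and sequences are
  user-supplied tables, and star-strand detection is an input flag, not
  a search.
* Genome mapping, hairpin discovery, and quality-score filtering are
  out of scope.
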