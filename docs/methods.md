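# Methods

## Domain catalog and tally

A gene product is modeled as a 1-based residue interval `[1, L]` with an
ordered, non-overlapping set of named domain intervals; coordinates are
protein-space only (no transcript or genomic liftover). The packaged Trio-9
model uses `L = 3097` (from the cited RefSeq protein) and fixes the DH1
subdomain at `[1290, 1464]` — exactly 175 residues, containing the published
DH1-region mutation positions (1312, 1329, 1368, 1428, 1431, 1461) and
excluding the PH1 control position 1575. The remaining boundaries are
plausible reconstructions of the canonical Trio architecture; boundaries are
shipped as data (TSV/JSON) and fully user-overridable, because they are not
derivable from code.

Each variant record carries a residue position (plus an end position for
CNV/truncation ranges), a class (`missense`, `lof`, `synonymous`) and a
cohort (`case_de_novo`, `inherited`, `control`). Tallying counts each record
exactly once into a 6-row (class × cohort) by domain matrix with an
`inter-domain` spill column; `total_case` and `total_control` rows are
always derived, never stored, so their identities hold by construction.
Point records take the domain of their residue. Ranged records take the
domain of their first affected residue when annotated, otherwise the first
annotated domain overlapped by the range — a deletion sweeping several
domains is counted once, in the first domain it destroys. (A strict
"first-residue" rule would send the packaged 1149–1889 deletion to the
spill column; the range rule reproduces the reference tally and matches how
such events are conventionally credited.) Multi-domain attribution is
available as an explicit opt-in.

The enrichment score is the signed excess of case de novo over control
events per domain. The 11 case records comprise 9 missense + 2 loss of
function; whole-gene burden counts all 11.

## Poisson hotspot statistics

Expected gene-wide de novo count over a cohort: `λ_gene = 2·n·p_gene`
(two transmitted haplotypes per individual; `p_gene` is the per-generation,
per-haplotype mutation probability from a background mutational model).
`λ_gene` can also be supplied directly so that a published expectation
(1.07 events over 4890 individuals for Trio) is usable verbatim.

Domain expectation under the equal-probability null: `λ_d = λ_gene·L_d/L`
using amino-acid lengths (equivalent to coding-base lengths under the
uniform assumption). Rescaling is bilinear and sums over a partition of the
protein to `λ_gene`.

The burden statistic is the exact upper tail `P(X ≥ k)`, `X ~ Poisson(λ_d)`,
computed by direct term summation: the first term is seeded in log space
and successive terms use the recursion `t_{j+1} = t_j·λ/(j+1)`, accumulated
relative to the first term. This avoids the catastrophic cancellation of
`1 − CDF` and is accurate to better than 6 significant digits down to at
least 1e-300 (cross-checked against `scipy.special`-based survival
functions and brute-force summation in the tests). Significance uses a
single genome-wide threshold of 1e-6 by default, with an optional (off by
default) Bonferroni correction over tested domains.

The DH1 test takes its observed count explicitly: the raw tally credits 8
case events to DH1 (6 missense, 1 truncation, 1 CNV deletion), while the
published subdomain test used 7; both are computed and reported rather than
hard-coding either. At the rounded expectation λ = 0.06, `P(X ≥ 7)` ≈
5.27e-13; at the unrounded λ = 0.0605 it is ≈ 5.56e-13 — the ~5% spread is
pure rounding of λ and the package reports the tail at the printed
expectation for comparability.

A seeded null simulator draws per-domain counts from `Poisson(λ_d)` and
measures the test's empirical size. Because the statistic is discrete, the
test is conservative: at nominal 0.05 the realized size per Trio domain is
well below 0.05 (the largest domain reaches ≈ 0.046).

## ΔΔG classification and interface distances

Predicted binding (`ΔΔG_bind`) and stability (`ΔΔG_stability`) changes, in
kcal/mol with positive = destabilizing, are consumed from a table — the
underlying force-field calculation is out of scope. The rule is strict:
disruptive iff either value `> 2`; values exactly at the threshold are
non-disruptive, and the verdict is monotone in both energies.
Truncation/deletion records carry no energies and are
`interface_eliminated`; a record with exactly one energy is rejected. The
packaged table also carries the upstream prediction flags, and
`star_mismatches` surfaces any disagreement between flag and rule instead
of silently reconciling them (on the packaged table there are none).

Interface proximity is the minimum Euclidean distance over all pairs of a
residue's atoms and the partner chain's atoms, hydrogens excluded by
default (crystal structures typically lack them and interface statements at
this resolution refer to heavy atoms), flagged at 6 Å. Parsing uses gemmi;
any two-chain PDB works, and a synthetic toy complex is bundled for tests.

## Phasor FLIM-FRET

The phasor of a decay histogram at harmonic `n` of `ω = 2π/period` is
`g = Σc_t·cos(nωt)/Σc_t`, `s = Σc_t·sin(nωt)/Σc_t` over bin midpoints
(midpoints are unbiased for piecewise-constant histograms; at 256 bins the
residual binning attenuation is ~2.5e-5, far below photon noise). The first
harmonic is the default; the harmonic is a parameter. The default period is
12.5 ns (80 MHz repetition). Useful exact facts used by the tests: a
single-exponential decay truncated to one period has exactly the ideal
phasor `g = 1/(1+(ωτ)²)`, `s = ωτ/(1+(ωτ)²)` at harmonic frequencies; the
phasor of a summed decay is the intensity-weighted mean of component
phasors; any non-negative decay lies inside the unit circle.

Calibration is the unique rotation + scaling about the origin (one complex
factor) mapping a measured single-lifetime reference (default τ = 2.55 ns,
the coumarin-6 standard) onto its theoretical phasor. No fuller instrument
response deconvolution is attempted.

The FRET trajectory evaluates, for each efficiency `E`, the quenched-donor
phasor at `τ_D(1−E)` mixed with fixed background and unquenched-donor pools
by the linear-combination rule; the fractions and background phasor are
user-supplied (determined independently in practice), with defaults of a
pure donor pool. Efficiency estimation projects a measured phasor onto the
trajectory: a 2001-point grid plus bounded scalar minimization (resolution
≤ 1e-4 in E) for single points, and a two-stage vectorized grid search
(coarse 512-point grid, then an 81-point fine grid spanning ±2 coarse
steps, ~1e-4 resolution) for whole images, chunked to bound memory. Cluster
selection is a disc in phasor space returning an image-aligned mask,
centroid and pixel count; an optional (off by default) 3×3 median smoothing
of phasor maps is provided.

## Quantal CV analysis

Amplitudes are sign-rectified magnitudes; fast-receptor responses are the
baseline-subtracted peak in a 50 ms post-stimulus window, slow (NMDAR)
responses the baseline-subtracted value 150 ms after the stimulus where the
fast component has decayed. Recordings whose series resistance varies by
more than 25% are discarded; the paired-pulse ratio is peak2/peak1 at the
caller's inter-stimulus interval.

Under binomial release (N sites, probability p, quantal size q, quantal CV
γ) the sweep mean is `Npq` and `CV⁻² = mean²/variance = Np/(1−p+γ²)` — a
function of quantal content only. For a transfected/control pair the point
`(mean ratio, CV⁻² ratio)` is classified in log-log coordinates by
proximity to the horizontal line (CV⁻² ratio = 1, quantal-size change)
versus the diagonal (equal ratios, quantal-content change): Euclidean
distances `|log r_cv|` versus `|log r_cv − log r_mean|/√2`, with points
whose distances differ by < 0.05 called ambiguous (a numeric stand-in for
the visual-proximity convention). Noise-variance subtraction from the
sample variance is available but off by default. The group centroid
(mean ± SEM of both ratios) is classified with the same rule — this is the
experiment-level call, mirroring the mean marker on a CV scatter plot, and
it is the unit at which discrimination is quantified: a single 60-sweep
pair carries too little variance information for reliable per-pair calls
(~86–91% correct at a factor-0.5 manipulation), whereas the 7-pair centroid
classifies essentially perfectly.

Wilcoxon tests are two-sided throughout. The signed-rank null (zero
differences dropped, average ranks for ties) and the rank-sum null are
computed exactly for n ≤ 25 (signed-rank) / combined n ≤ 20 (rank-sum)
via generating-polynomial dynamic programming over doubled ranks —
mathematically identical to enumerating all `2^n` sign vectors or
`C(n+m,n)` assignments, which the tests retain as an independent oracle —
with the two-sided p as `min(1, 2·min(P(W ≤ w), P(W ≥ w)))`. Beyond those
sizes a normal approximation with continuity and tie corrections is used.

## Synthetic generators

All generators require an explicit seed (numpy PCG64) and are
bit-reproducible for a fixed seed and version.

* **Null mutations**: positions i.i.d. uniform on `[1, L]`, class missense,
  cohort case de novo — the equal-probability null of the hotspot test.
* **FLIM stacks**: per pixel, a Poisson photon total (default 100
  counts/pixel, the intended photon budget) whose arrival times are drawn
  by exact inverse-CDF from the truncated-periodic exponential of the
  pixel's component (quenched donor at `τ_D(1−E)`, unquenched donor, or
  uniform background per the mixing fractions), binned into 256 bins over a
  12.5 ns period. Default test image size is 64×64 (256×256 available to
  mirror a full acquisition). The generator emulates shot noise and pool
  mixing; it does not emulate detector IRF width, afterpulsing or dark
  counts, so recovery results bound estimator error under ideal photon
  statistics, not instrument artifacts.
* **Paired recordings**: per sweep, amplitude `q·(r + γ√r·Z)` with
  `r ~ Binomial(N, p)` (distributionally identical to summing `r`
  independent quanta `q(1+γZ_i)`), floored at zero; the transfected train
  scales q (`scale_q`) or N (`scale_N`). Defaults N = 100, p = 0.3,
  q = 10 pA, γ = 0.3, 60 sweeps per cell — a typical paired-recording
  scale. The generator does not simulate full current waveforms beyond the
  double-exponential EPSC shape used for amplitude-extraction tests, nor
  stimulus artifacts or series-resistance errors.

## Problem sizes and numerical choices

The recovery analyses run at 64×64 pixels × 100 counts (FLIM) and
500 classified experiments of 7 pairs × 60 sweeps (CV discrimination);
null calibration uses 20,000 replicates. Tail accuracy targets ≥ 6
significant digits; calibration round-trips are exact to complex-arithmetic
precision (≲1e-12); efficiency estimation resolves E to ≤ 1e-4. Degenerate
inputs fail loudly: empty decays, zero-modulus calibration references,
zero-variance sweep trains and all-zero difference vectors raise rather
than return sentinel values; degenerate pairs inside a group analysis are
skipped with a warning so one bad recording does not void an experiment.

## Known limitations

* Domain boundaries outside DH1 and the non-DH1 mutation positions in the
  packaged fixtures are reconstructions consistent with the per-domain
  tallies, not published residue-level data.
* The uniform-null rescaling ignores trinucleotide-context variation in
  mutability along the gene; a context-aware per-domain expectation is out
  of scope.
* ΔΔG values are consumed, not computed; classifications inherit whatever
  biases the upstream energy model has.
* FRET efficiency estimation assumes known, fixed background/unquenched
  fractions; no joint fraction + efficiency fitting is attempted.
* CV analysis assumes stationarity across sweeps and uncorrelated release
  sites; rundown, facilitation trends or correlated release violate the
  binomial identities.
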