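# Methods

## Scientific setting

`glyquant` quantifies relative N-glycan abundances between two cell
populations that were metabolically labeled through the hexosamine pathway:
one population grown on ordinary (amide-¹⁴N) glutamine, the other on
amide-¹⁵N glutamine. Because the glutamine amide nitrogen is the sole
nitrogen source of aminosugar biosynthesis, every HexNAc and NeuAc residue
of a glycan carries exactly one label-sensitive nitrogen. A glycan with
composition HexNAc_a Hex_b Fuc_c NeuAc_d therefore appears in a mixed
light/heavy MALDI spectrum as two isotopic envelopes separated by

    Δm = (a + d) × (m(¹⁵N) − m(¹⁴N)) = (a + d) × 0.99703 Da,

and the light/heavy intensity ratio estimates the abundance ratio of the two
populations. The packaged reference panel is the 17-glycan secretome
comparison of the ovarian cancer line SKOV3 (heavy) and its metastatic
derivative SKOV3-ip (light), in which every bisecting-GlcNAc glycoform is
depleted in the metastatic derivative.

## Mass and envelope model

Residue masses are monoisotopic, computed from the NIST atomic-mass table
shipped with `pyteomics` (residue = free monosaccharide − water; glycan =
Σ residues + water; sodiated ion adds m(Na) − m(e⁻)). Theoretical m/z values
of the panel agree with the published column to one decimal place.

Isotopic envelopes are *aggregated* (one peak per extra-neutron count), the
appropriate model for a QIT-TOF at roughly unit resolution over m/z
1400–2800. Each element contributes a distribution over extra neutrons; the
molecular distribution is their convolution (computed exactly in float64 by
exponentiation-by-squaring, trailing bins below 1e−12 pruned). Each
aggregated peak's m/z is the abundance-weighted centroid of its
isotopologues. Envelopes default to 10 peaks and are renormalized to sum
to 1; the truncated mass is far below 1e−6 for every panel glycan.

Heavy-channel envelopes treat the (a + d) labeled amide nitrogens as an
independent binomial(enrichment) ¹⁵N pool convolved with the natural
envelope of all remaining atoms. `enrichment = 1.0` (complete incorporation)
is the pipeline default; 0.98 reproduces the isotopic purity of commercial
amide-¹⁵N-Gln and produces the characteristic −1 Da single-¹⁴N satellite.
Tests verify the engine against an exhaustive isotopologue enumeration to
1e−10 per peak.

Permethylated masses (one CH₂ per residue hydroxyl/amide methylation site,
3 for Hex and HexNAc, 2 for Fuc, 5 for NeuAc, plus a C₂H₆O end-group for
the reducing-end O-methyl and non-reducing methyl) are provided for
annotation of permethylated acquisitions; they reproduce the standard
permethylated biantennary reference point (HexNAc₄Hex₅ [M+Na]⁺ ≈ 2070.0).
Quantification operates on native glycans.

## Spectral processing

Profile spectra are Gaussian-smoothed (default σ 0.08 Da; non-uniform grids
are linearly resampled first; total ion current is preserved) and centroided
by threshold-25% peak detection: a local maximum above an absolute offset
(default 0.5, in the spectrum's own intensity units) defines a peak whose
centroid is the intensity-weighted mean over the contiguous region ≥ 25% of
the apex; intensity is the apex height and area the trapezoidal integral.
Base-peak normalization scales intensities and areas by the same factor
(base peak = 100), so it provably cannot change any ratio downstream.

## Assignment and classification

Observed peaks are matched to an enumerated composition library (defaults
HexNAc 2–8, Hex 3–10, Fuc 0–2, NeuAc 0–4) by nearest theoretical m/z within
0.3 Da; ties break on smaller error then composition order, unassigned peaks
are reported rather than dropped. The pipeline deisotopes greedily in
ascending m/z: a matched peak that sits on an expected isotopologue position
(light or heavy) of an already-accepted composition is a satellite, not a
new species.

Glycan classes (high mannose, hybrid, complex biantennary, tri-/tetra-
antennary, bisecting GlcNAc) cannot all be decided from composition alone —
HexNAc₅Hex₅ is equally a bisected biantennary or an agalacto-triantennary.
A curated map (shipped as `data/curated_classes.csv`, encoding the panel's
MS/MS- and database-supported assignments, with sialylated variants
inheriting their desialylated parent's class) takes precedence; outside it a
composition heuristic applies (HexNAc 2 → high mannose, 3 → hybrid, 4 →
biantennary), flagged `ambiguous` from HexNAc 5 up. Composition-level B/Y
fragment masses (sodiated, with −H₂O variants, satisfying
m(B) + m(Y) = m(precursor) + m(Na⁺)) support manual confirmation of
bisecting structures from tandem spectra.

## Ratio estimation

The label shift of a HexNAc₂ glycan is only 1.994 Da, so the heavy
monoisotopic peak falls on the light M+2 isotopologue; a naive
monoisotopic-height ratio is biased (by >10% at a true ratio of 0.5 for
HexNAc₂Hex₆). The default estimator therefore models the observed centroid
areas at the union of expected isotopologue positions (positions closer
than 0.2 Da — unresolvable at unit resolution — are merged) as a
non-negative linear combination of the two normalized theoretical
envelopes, solved by NNLS; ratio = light/heavy. It is exact on noise-free
input, equals the summed-intensity ratio when the shift exceeds the
envelope support, and matches a brute-force grid search of the same
objective. A monoisotopic-height estimator is retained as an option
(`estimator: height`) because the original acquisition software's exact
protocol is not fully specified; the package default is the deconvolving
estimator. A zero heavy amount yields a flagged NaN ratio (never ∞); window
signal below a floor yields a low-signal flag; >25% unexplained window
signal flags a high residual.

Replicates aggregate as the arithmetic mean and CV% = 100 × sd(n−1)/mean.
Change calls use the panel's thresholds: ratio < 0.83 → down, > 1.20 → up,
otherwise no change (boundaries inclusive of "no"); a CV above the 20%
quality gate is flagged, not censored. Ratios are reported as
numerator-sample / denominator-sample per the mandatory channel declaration
in the config; declaring the heavy-labeled sample as numerator inverts
every per-replicate ratio before aggregation. No renormalization (e.g.
median centering) is applied to the 1:1 mixing assumption.

## Synthetic data generator

The generator emulates the study design — a 1:1 light/heavy mixture
acquired as 3 independent mixtures × 3 spots (n = 9) — with, per glycan:
light amount = base abundance, heavy amount = abundance / true ratio, each
multiplied by lognormal noise with a mixture-level component (σ 0.03,
shared by the three spots of a mixture) and a spot-level component
(σ 0.06), plus per-peak multiplicative noise (σ 0.02) and m/z jitter
(σ 0.008 Da). These defaults give replicate ratio CVs of roughly 5–15%,
inside the 2.4–18.1% range of the reference study. Sticks can be emitted
directly as centroids or rendered as Gaussians (σ 0.12 Da, unit-resolution
regime) on a 0.02 Da grid with a small positive baseline. All randomness
derives from one scenario seed via per-(mixture, spot) substreams, so
output is bit-identical under a fixed seed. The default scenario
(`table1_scenario()`) transcribes the 17-glycan panel with its published
ratios; base abundances are a fixed decreasing series loosely tracking the
published spectrum's intensity fall-off with mass.

What the generator does **not** model: ionization and desorption bias,
detector saturation, matrix clusters, in-source decay of sialylated
species, chemical baseline structure, and mass-dependent resolution. Tests
passing on these fixtures demonstrate the correctness of the deconvolution
and calling machinery under the stated noise model, not instrument-level
robustness on real acquisitions.

## Numerical choices and edge cases

- Envelope truncation: 10 peaks, renormalized; intermediate pruning 1e−12.
- Template/peak matching tolerance 0.3 Da (published observed-vs-theoretical
  deviations are ≤ 0.2 Da); template positions merged below 0.2 Da.
- Degenerate inputs: empty compositions, empty spectra, pure-light signal,
  sub-floor windows and < 2 finite replicate ratios all produce flags or
  typed errors, never silent NaN/∞ propagation.
- Sorting and tie-breaks are fully specified (m/z then composition order),
  so every pipeline output is deterministic byte-for-byte given inputs and
  config.

## Problem sizes

The default library enumeration is 7 × 8 × 3 × 5 = 840 compositions; the
default synthetic experiment is 17 glycans × 9 replicates (~400 centroid
peaks each, or ~70k-point profiles). A full pipeline run completes in
seconds on one core.

## Downstream biological context (not computed here)

In the reference study the glycomics finding — uniform depletion of
bisecting-GlcNAc glycoforms in the metastatic derivative, ratios 0.73 down
to 0.12 — was followed up at the glycosyltransferase level: MGAT3 (the
enzyme installing the bisecting GlcNAc) was strongly reduced in SKOV3-ip at
mRNA and protein level, MGAT3 overexpression/knockdown modulated migration,
and MGAT3 staining separated low- from high-grade tumors. Those wet-lab
results (qPCR fold changes, transwell migration percentages,
immunohistochemistry staining fractions) are biological validation outside
the scope of a desk-computable package and are deliberately not represented
in its API.

## Known limitations

- Composition-level only: no topology or linkage inference; isomers are
  resolved solely through the curated class map.
- Aggregated envelopes assume unit resolution; fine isotopic structure and
  resolution-dependent peak shapes are out of scope.
- The NNLS fit assumes at most two species per analysis window; co-eluting
  third species inflate the residual flag rather than being modeled.
- Sodiated, singly charged ions by default (H⁺/K⁺ supported); no multiply
  charged species.
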