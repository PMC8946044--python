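# Methods

## Dose model

A planar minibeam field is modelled as a one-dimensional lattice of
Gaussian line beams across the transverse coordinate *x* (µm), uniform
along the beam direction *y* over the 5 mm beam length with hard edges:

D(x) = Σᵢ P · exp(−(x − xᵢ)² / 2σ²).

Default layout: four beams symmetric about the insert center at
±1250 µm and ±3750 µm (center-to-center distance ctc = 2500 µm), matching
the experimental arrangement on an 8 mm culture insert. The single-beam
amplitude *P* is fixed by requiring the mean dose over one **central unit
cell** (one ctc period about the insert center) to equal the prescribed
mean dose (2 Gy); the mean is evaluated in closed form with the Gaussian
error function. This periodic idealization is the reproducible
normalization choice; the original dose computation additionally used an
unspecified holder geometry, so the model reproduces the quasi-homogeneous
920 µm summaries closely (PVDR 1.32 vs 1.35 published, peak 2.28 vs 2.3 Gy)
but idealizes the narrow-beam peak values (30.2 vs 27 Gy for 66 µm, 4.89 vs
4.5 Gy and PVDR 54.6 vs 45 for 408 µm). These deviations are documented
tolerances, not calibration targets.

Summaries over the central unit cell: `D_peak` and `D_valley` are grid
extrema refined by local parabolic interpolation (the cell boundaries are
included exactly, with a one-sample extension so boundary peaks are
refined with both neighbours); PVDR is reported as infinite when the
valley falls below 1 mGy; the irradiated fraction is the measure of
{dose ≥ threshold} with threshold-crossing positions interpolated in
log-dose (the Gaussian flank is exponential, so log-linear interpolation
is essentially exact). Default threshold 0.1 Gy — the dose the study
treats as biologically meaningful in the 408 µm valleys — giving 17.8%
for the 66 µm geometry ("~17% of cells irradiated"). Default grid step
σ/20 capped at 5 µm; steps coarser than σ/5 are rejected.

The ion-count operation evaluates N = D·ρ·A/LET in SI units (Gy = J/kg,
g/cm³ → kg/m³, mm² → m², keV/µm → J/m). For 2 Gy, unit density, the
12.5 mm² unit cell and LET 2.6 keV/µm this gives ≈ 6.0 × 10⁷ protons. The
published worked example prints 610,531,562 for the same inputs, which is
dimensionally inconsistent with the formula (a ~10× arithmetic slip); the
implementation follows the formula. Likewise the LET is taken as
2.6 keV/µm (physically correct for 20 MeV protons), not the 2.66 keV/mm
typo.

Film fitting: each transverse film profile is fitted by nonlinear least
squares with a Gaussian-plus-constant-baseline model, center initialized
at the profile maximum and width from the half-maximum span; the beam
width estimate is the mean ± SD of σ over (by default) 10 locations along
the beam, non-converging locations excluded. The synthetic film generator
produces single-beam profiles with multiplicative Gaussian noise
(default 5%, 10 µm sampling), emulating radiochromic-film grain.

## Synthetic tissue

A cross-section is a horizontal band of nuclei (default 8000 µm long —
the insert diameter — and 60 µm thick) on a support membrane, with
1483 ± 236 nuclei per section (truncated normal) split into
basal/suprabasal/cornified layers by fixed height fractions (0.25 / 0.45
/ 0.30 of the band). Positions are uniform along the strip; a soft
minimum-separation rule (1.8× nucleus radius, bounded retries, overlap
accepted when crowded) keeps rendered nuclei segmentable without biasing
the positional distribution. Nucleus radii are normal (4 ± 0.4 µm). Each
nucleus receives the analytic dose at its position (zero for sham).

**Mechanistic damage mode** (used for spatial-structure results): DSBs ~
Poisson(dsb_yield · dose) with dsb_yield = 1000/27 ≈ 37 DSB/Gy, anchored
to ~1000 DSBs at the 27 Gy peak; visible foci ~ Binomial(DSB, ε·m(t))
with detection efficiency ε = 0.1 — the fraction of breaks that appear as
countable discrete foci in a 5 µm physical section — and piecewise repair
multipliers m(t) = 1 / 0.7 / 0.3 / 0.05 at 0.5 / 6 / 24 / 72 h (the study
reports time points, not a rate law, so no exponential is fitted). With
these defaults the mean visible count at the 2.3 Gy wide-field peak is
≈ 8.5 foci, consistent with the reported "up to 12" per nucleus. Nuclei
with dose ≥ 4 Gy at ≤ 6 h, or with visible counts above the saturation
cap (20), are pan-γ-H2AX: the phospho-mark is confluent, discrete
counting is impossible, and their focus counts are reported as zero.
Background damage: 20% of cells carry 1–2 background 53BP1 foci
(70%/30% split), reproducing the sham baseline.

**Empirical damage mode** (used for time-course results): per-condition
damaged-cell probabilities drive a Bernoulli per nucleus with a
zero-truncated Poisson focus count (λ = 1.3 sham, 2 narrow, 4 wide —
free choices; the source reports only "up to 12"). The calibration table
follows the measured courses: sham 20/40/20/20% at 0.5/6/24/72 h (the 6 h
elevation is a calibration entry only; no handling-stress mechanism is
modelled); 920 µm 70% at 0.5 h declining after 6 h; 408 µm ~90% at 0.5 h
with immediate decline; 66 µm a transient doubling of sham at 0.5 h.
The two modes exist because the printed 70% vs ~90% wide-field fractions
cannot both emerge from one simple dose→foci default; spatial-structure
results use the mechanistic mode, time-course recovery the empirical
mode. Empirical probabilities apply to all nuclei and pan-positive nuclei
are subsequently excluded from counting, so the observed
percent-with-foci is p·(1−p_pan); this only matters for the 66 µm early
points, where ~13% of cells are pan (observed ≈35% vs the nominal 40%).
Damaged cells are placed uniformly; the possibility that the narrow-beam
"extra" damaged cells concentrate in the beam flanks is not modelled in
this mode (in the mechanistic mode flank enrichment emerges from the dose
profile itself).

Channel structure: each 53BP1 focus is shared with γ-H2AX with
probability 0.2; additional γ-H2AX-only foci keep the expected 3:1
53BP1:γ-H2AX count ratio — hence shared/γ-H2AX → 0.6 and shared/53BP1 →
0.2 in large samples, the reported colocalization fractions. Shared foci
get identical coordinates; distinct foci are kept ≥ 0.7 µm apart because
sub-PSF pairs would not be resolvable as separate foci (this also keeps
coordinate-based matching consistent with what an image-based detector
can see). Apoptosis: caspase-3⁺ flags follow a per-condition schedule
(sham 0.14% at 24 h, 0.4% at 72 h; elevated late after irradiation) and
imply pan-γ-H2AX at 24/72 h (apoptotic DNA fragmentation); late pan cells
are scattered, decoupled from the dose peaks.

Reproducibility: all draws come from one `numpy` Generator seeded per
section; identical (spec, geometry, model, time, seed) gives bit-identical
tables.

Curvature: sections can be bent along a circular arc (radius > L/π) or an
arc-length-parametrised sinusoid, nuclei and foci mapped as
centerline + signed-normal offsets; ground-truth arc-length positions are
retained for round-trip validation.

Rendering: 3 channels (DAPI, 53BP1/Cy3, γ-H2AX/Cy5), float32, default
0.25 µm pixels. Nuclei are filled discs with Gaussian-softened edges;
foci are Gaussian PSF blobs (σ 0.3 µm); pan nuclei are uniformly filled
in the γ-H2AX channel; channels carry a dim nuclear fill, constant
background and additive Gaussian noise.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analysis depends on —
counts, fractions, spatial clustering, channel ratios, curvature — not
optical realism: no keratin texture, no autofluorescence gradients, no
3D stacks, no stain deconvolution, no cell-cycle or bystander
mechanisms. Passing pipeline-recovery tests therefore demonstrates that
the *operators* are correct and calibrated on data with the study's
reported structure; it does not re-establish the biology from raw data,
which was not deposited.

## Image analysis

Explicit open operators replace the interactive commercial platforms; all
thresholds live in `AnalysisParams`. Segmentation: Gaussian smoothing
(0.5 µm), Otsu global threshold, hole filling, distance-transform
watershed with minimum marker separation 3 µm, area filter 10–400 µm².
Two guards return "no nuclei" instead of hallucinating masks on blank or
pure-noise images (foreground fraction > 45%, or foreground/background
contrast < 4 SD). Cutoffs: mean + k·SD (k = 3) of negative-staining
pixels; in the end-to-end path the negative population is the all-nuclei
pixel set with iterative sigma-clipping, a deterministic replacement for
interactively flagging undamaged nuclei. Focus channels are
matched-filtered at the PSF scale (0.3 µm) before cutoff estimation and
detection — without it, mean+3SD on raw noise calls isolated noise
pixels as foci. Foci are local maxima above the cutoff with ≥ 0.6 µm
separation, restricted to nucleus masks; pan-positive nuclei (mean
intensity above cutoff and ≥ 80% of the nuclear area above the focus
cutoff) bypass focus counting. A channel whose estimated cutoff exceeds
80% of its maximum is declared unanalyzable, mirroring the exclusion of
the high-background γ-H2AX channel at 72 h. Colocalization: greedy
one-to-one nearest-pair matching within 0.5 µm inside each nucleus; an
exhaustive maximum-bipartite matcher is the test oracle (at biological
densities the two agree). Analysis is 2D throughout — the sections are
5–7 µm thick, effectively one plane.

## Spatial mapping

The centerline is a low-order polynomial (default degree 5, reduced for
small clouds) fitted to the nucleus cloud after principal-axis rotation,
anchored at the left end (the study annotated the left end of each
section). Nuclei are projected to (arc length s, signed normal offset d)
via a dense arc-length lookup with local quadratic refinement;
projections beyond the curve ends are clamped with a warning. Whether the
original platform used splines or manual control points is unknown; only
the contract (round-trip recovery within 1% of the section length,
preserved ordering and attributes) is asserted.

Damage clusters: Gaussian kernel density (bandwidth 150 µm ≈ 2σ of the
narrow beam's damage streak) over pan-positive positions; peaks must
exceed 3× the section-wide mean pan density. A 5× floor was considered
but rejects true clusters under the default conditions: a fully-pan
265 µm track smoothed at 150 µm peaks at only ~4.7× the mean when four
tracks span an 8 mm section. At 3× true clusters are kept while
late-time scattered pan cells (uniform, KDE fluctuations < ~3× mean)
are still suppressed. Valley statistics are computed over bins farther
than 3σ + 300 µm from every detected peak.

## Statistics

The replication unit is the section (3 models × 3 sections = n 9, n 6
supported), matching the study's figure legends, although sections within
a model are pseudo-replicates — a documented limitation. Group values are
unweighted means ± SD of section percentages; with equal section sizes
this equals the pooled rate. Percentages are compared untransformed,
mirroring the source; one-way ANOVA (per time point across geometries,
`scipy.stats.f_oneway`) is followed by Tukey's HSD
(`statsmodels pairwise_tukeyhsd`), α = 0.05. Tests validate the F
statistic against a from-scratch sum-of-squares oracle (10⁻⁸) and the
adjusted p values against the studentized-range distribution; a
1000-null simulation checks type-I calibration of both procedures using
the critical-value form of the identical decision rules (full
`pairwise_tukeyhsd` calls are ~0.3 s each, so the calibration loop uses
the equivalent vectorized rule after verifying equivalence on a
subsample).

## Problem sizes and determinism

Acceptance computations use the study's own scales: full 8 mm sections of
~1483 cells, 9 sections per recovery target, 10⁴ damaged nuclei for
colocalization, 10 film profiles for the width fit, 3 sections for
cluster spacing. Image-based tests run on small rendered fixtures
(~40 nuclei, 0.25 µm pixels). All stochastic stages draw from seeds
derived from a single root seed via `numpy.random.SeedSequence`.

## Known limitations

No proton transport or in-tissue scattering (the surface σ is an input);
no film calibration-curve modelling; hard beam ends along y; no
mixed-effects models; no 2D cluster detection across serial sections; the
empirical damage mode is a calibration table, not a mechanism; segmented
nuclei inherit no layer labels (not observable in the DAPI channel alone).
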