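# minibeam

Planar proton-minibeam dosimetry and spatially resolved DNA-damage analysis
for 3D human epidermis models.

Proton minibeam radiotherapy (pMBRT) spatially fractionates a proton field
into narrow parallel beams so that most of the superficial tissue — skin in
particular — sits in unirradiated "valleys" and is spared. This package
implements the quantitative core of a skin-model pMBRT experiment as a
tested, reproducible pipeline:

* **Dosimetry** — planar Gaussian beam lattices, peak/valley doses, the
  peak-to-valley dose ratio (PVDR), irradiated-tissue fractions, ion-count
  bookkeeping, and Gaussian beam-width fits of radiochromic-film profiles.
* **Synthetic tissue** — a generator of epidermis cross-sections
  (~1483 ± 236 nuclei in a stratified band) with dose-dependent γ-H2AX/53BP1
  focus counts, pan-nuclear γ-H2AX above ~4 Gy, repair time courses,
  rare caspase-3⁺ apoptotic cells, and optional rendered 3-channel
  fluorescence images — so every downstream stage is testable without
  instrument data.
* **Image analysis** — nucleus segmentation (Otsu + watershed), intensity
  cutoffs relative to negative-staining regions, focus detection,
  pan-nuclear classification, and distance-based channel colocalization.
* **Spatial mapping** — digital straightening of curved sections to
  arc-length coordinates and kernel-density detection of damage-cell
  clusters at the beam tracks.
* **Statistics** — per-section summary tables (percent cells with foci,
  foci per damaged cell, pan and caspase fractions) with one-way ANOVA and
  Tukey HSD group comparisons.

## The model in brief

A planar minibeam array is a sum of Gaussian line beams across *x*:

```
D(x) = Σᵢ P · exp(−(x − xᵢ)² / 2σ²)
```

with σ ∈ {66, 408, 920} µm, center-to-center distance 2.5 mm, and the
amplitude *P* set so the mean dose over one central unit cell equals the
prescribed 2 Gy. The field is summarized by `PVDR = D_peak / D_valley` and
by the fraction of the unit cell above a 0.1 Gy threshold. Per nucleus,
double-strand breaks are Poisson with yield ≈ 37 DSB/Gy (≈1000 DSB at
27 Gy), a fraction ε ≈ 0.1 of which appear as countable repair foci in a
thin section; nuclei above ~4 Gy show a confluent pan-nuclear γ-H2AX signal
instead of countable foci. 53BP1 foci outnumber γ-H2AX foci ~3:1 with 20%
of 53BP1 foci shared, so ~60% of γ-H2AX foci colocalize with 53BP1.

## Worked example

```bash
python examples/01_dose_profiles.py
```

```
σ =  66 µm | peak 30.22 Gy | valley 7.68e-77 Gy | PVDR   inf | irradiated  17.8 %
σ = 408 µm | peak  4.89 Gy | valley   0.0895 Gy | PVDR 54.60 | irradiated  94.6 %
σ = 920 µm | peak  2.28 Gy | valley     1.72 Gy | PVDR  1.32 | irradiated 100.0 %
```

The 920 µm field is quasi-homogeneous (PVDR 1.3, every cell close to the
2 Gy mean); the 66 µm field concentrates a ~30 Gy peak on ~18% of the
unit-cell width and leaves the valleys at essentially zero dose — the
spatial-fractionation regime in which valley tissue behaves like a sham
control. `examples/04_straighten_and_clusters.py` continues the story on a
bent synthetic section:

```
damage clusters detected  : 4
adjacent spacings (µm)    : [2490, 2505, 2490]  (2500 expected)
valley cells with foci    : 19.5 % of 817 cells (≈20% sham level — spared tissue)
```

The remaining examples cover synthetic-section generation, image-based
recovery of per-nucleus measurements, and the replicated time-course
statistics. A thin CLI mirrors the library
(`minibeam simulate-dose | generate-tissue | analyze-section | map-spatial |
report | run-all`).

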