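"""Generator tests: reproducibility, damage structure, curvature, rendering."""

import math

import numpy as np
import pandas as pd
import pytest

from minibeam.dosimetry import GEOMETRY_PRESETS, BeamGeometry
from minibeam.synthetic_tissue import (
    ArcCurvature,
    DamageModel,
    SinusoidCurvature,
    TissueSpec,
    apply_curvature,
    generate_damaged_nuclei,
    generate_section,
    render_images,
)


def _zero_schedule():
    times = {0.5: 0.0, 6.0: 0.0, 24.0: 0.0, 72.0: 0.0}
    return {k: dict(times) for k in ("sham", "66", "408", "920")}


def test_identical_seed_reproduces_tables_exactly(full_spec, geom66, mech_model):
    a = generate_section(full_spec, geom66, mech_model, 0.5, seed=7)
    b = generate_section(full_spec, geom66, mech_model, 0.5, seed=7)
    pd.testing.assert_frame_equal(a.nuclei, b.nuclei)
    pd.testing.assert_frame_equal(a.foci, b.foci)


def test_different_seeds_differ(full_spec, geom66, mech_model):
    a = generate_section(full_spec, geom66, mech_model, 0.5, seed=7)
    b = generate_section(full_spec, geom66, mech_model, 0.5, seed=8)
    assert not a.nuclei["x_um"].equals(b.nuclei["x_um"])


def test_focus_count_conservation(section_66_early):
    nuc = section_66_early.nuclei
    assert (nuc["foci_shared"] <= np.minimum(nuc["foci_53bp1"], nuc["foci_gh2ax"])).all()
    for col in ("foci_53bp1", "foci_gh2ax", "foci_shared"):
        assert (nuc[col] >= 0).all()
        assert nuc[col].dtype.kind in "iu"


def test_positions_within_section(section_66_early):
    nuc = section_66_early.nuclei
    assert nuc["x_um"].between(0, section_66_early.spec.section_length).all()
    half = section_66_early.spec.thickness_band / 2
    assert nuc["y_um"].between(-half, half).all()


def test_sham_background_fraction(full_spec, mech_model):
    """~20% of sham cells carry at least one (background) DSB focus."""
    frames = [
        generate_section(full_spec, None, mech_model, 0.5, seed=s).nuclei
        for s in range(4)
    ]
    nuc = pd.concat(frames)
    cwf = ((nuc["foci_53bp1"] + nuc["foci_gh2ax"]) > 0).mean()
    n = len(nuc)
    assert abs(cwf - 0.20) < 3 * math.sqrt(0.2 * 0.8 / n) + 0.005


def test_null_model_zero_everything(full_spec):
    model = DamageModel(
        background_focus_prob=0.0,
        pan_schedule=_zero_schedule(),
        apoptosis_schedule=_zero_schedule(),
    )
    sec = generate_section(full_spec, None, model, 0.5, seed=3)
    assert (sec.nuclei["foci_53bp1"] == 0).all()
    assert (sec.nuclei["foci_gh2ax"] == 0).all()
    assert not sec.nuclei["pan_gh2ax"].any()
    assert not sec.nuclei["caspase3"].any()
    assert len(sec.foci) == 0


def test_mean_visible_foci_tracks_dose(full_spec, geom920):
    """Mean 53BP1 foci per nucleus ≈ ε·yield·dose (+ background mean)."""
    model = DamageModel(background_focus_prob=0.0)
    frames = [
        generate_section(full_spec, geom920, model, 0.5, seed=s).nuclei for s in range(3)
    ]
    nuc = pd.concat(frames)
    not_pan = ~nuc["pan_gh2ax"].astype(bool)
    observed = nuc.loc[not_pan, "foci_53bp1"].mean()
    expected = (
        model.detection_efficiency * model.dsb_yield * nuc.loc[not_pan, "dose_gy"]
    ).mean()
    assert observed == pytest.approx(expected, rel=0.05)
    # at the 2.3 Gy peak the analytic mean is ~8.5, consistent with the
    # reported "up to 12" foci per nucleus
    assert model.detection_efficiency * model.dsb_yield * 2.3 == pytest.approx(8.5, abs=0.2)


def test_colocalization_structure_law_of_large_numbers(mech_model):
    """shared/γ-H2AX → 0.6 and shared/53BP1 → 0.2 as n grows."""
    foci = generate_damaged_nuclei(mech_model, 10_000, focus_lambda=4.0, seed=5)
    n_b = (foci["channel"] == "53bp1").sum()
    n_g = (foci["channel"] == "gh2ax").sum()
    n_shared = (foci.loc[foci["channel"] == "53bp1", "shared"]).sum()
    assert n_shared / n_g == pytest.approx(0.6, abs=0.02)
    assert n_shared / n_b == pytest.approx(0.2, abs=0.01)


def test_pan_cells_confined_to_high_dose(section_66_early, geom66, mech_model):
    """Early pan-γ-H2AX cells occur only at doses near/above the ~4 Gy mark."""
    nuc = section_66_early.nuclei
    pan = nuc[nuc["pan_gh2ax"].astype(bool)]
    assert len(pan) > 50
    assert (pan["dose_gy"] >= 0.8 * mech_model.pan_dose_threshold).all()
    # spatial confinement: within ±σ√(2 ln(D_peak/threshold)) of a beam center
    from minibeam.dosimetry import evaluate_dose, peak_amplitude

    d_peak = peak_amplitude(geom66) * 1.0
    half_width = geom66.sigma * math.sqrt(
        2 * math.log(d_peak / (0.8 * mech_model.pan_dose_threshold))
    )
    centers = geom66.positions + section_66_early.spec.section_length / 2
    dist = np.min(np.abs(pan["x_um"].to_numpy()[:, None] - centers[None, :]), axis=1)
    assert (dist <= half_width + 1e-6).all()


def test_saturated_nuclei_become_pan(full_spec):
    geometry = BeamGeometry(sigma=920.0, mean_dose=30.0)  # far above pan threshold
    sec = generate_section(full_spec, geometry, DamageModel(), 0.5, seed=2)
    assert sec.nuclei["pan_gh2ax"].all()
    assert (sec.nuclei["foci_53bp1"] == 0).all()


def test_empirical_mode_matches_schedule(full_spec, geom920, emp_model):
    sec = generate_section(full_spec, geom920, emp_model, 0.5, seed=21)
    cwf = ((sec.nuclei["foci_53bp1"] + sec.nuclei["foci_gh2ax"]) > 0).mean()
    p = emp_model.cwf_schedule["920"][0.5]
    assert abs(cwf - p) < 4 * math.sqrt(p * (1 - p) / len(sec.nuclei))


def test_unknown_time_point_rejected(full_spec, mech_model):
    with pytest.raises(ValueError):
        generate_section(full_spec, None, mech_model, 3.0, seed=0)


def test_invalid_probability_rejected():
    with pytest.raises(ValueError):
        DamageModel(background_focus_prob=1.5)
    with pytest.raises(ValueError):
        DamageModel(mode="magic")


def test_late_apoptosis_implies_pan(full_spec, geom920):
    model = DamageModel(
        mode="empirical",
        apoptosis_schedule={k: {0.5: 0, 6: 0, 24: 0.2, 72: 0.2} for k in ("sham", "920")},
    )
    sec = generate_section(full_spec, geom920, model, 72.0, seed=9)
    cas = sec.nuclei[sec.nuclei["caspase3"].astype(bool)]
    assert len(cas) > 0
    assert cas["pan_gh2ax"].all()


class TestCurvature:
    def test_none_is_identity(self, sham_section):
        assert apply_curvature(sham_section, None) is sham_section

    def test_arc_chord_shorter_than_arc(self, sham_section):
        bent = apply_curvature(sham_section, ArcCurvature(radius=10_000.0))
        nuc = bent.nuclei
        assert "x_true_um" in nuc.columns
        # ground truth arc length preserved in metadata columns
        pd.testing.assert_series_equal(
            nuc["x_true_um"], sham_section.nuclei["x_um"], check_names=False
        )
        left = nuc.loc[nuc["x_true_um"].idxmin()]
        right = nuc.loc[nuc["x_true_um"].idxmax()]
        chord = math.hypot(right.x_um - left.x_um, right.y_um - left.y_um)
        arc = right.x_true_um - left.x_true_um
        assert chord < arc

    def test_too_tight_arc_rejected(self, sham_section):
        with pytest.raises(ValueError):
            apply_curvature(sham_section, ArcCurvature(radius=2000.0))

    def test_sinusoid_self_intersection_rejected(self, sham_section):
        with pytest.raises(ValueError):
            apply_curvature(sham_section, SinusoidCurvature(amplitude=500.0, period=600.0))

    def test_arc_preserves_normal_offset(self, sham_section):
        """Arc bending is an isometry of the centerline: |offset| preserved."""
        bent = apply_curvature(sham_section, ArcCurvature(radius=10_000.0))
        r = 10_000.0
        nuc = bent.nuclei
        cx = nuc["x_true_um"] - sham_section.spec.section_length / 2
        theta = cx / r
        px = r * np.sin(theta) + sham_section.spec.section_length / 2
        py = r * (1 - np.cos(theta))
        dist = np.hypot(nuc["x_um"] - px, nuc["y_um"] - py)
        np.testing.assert_allclose(dist, np.abs(nuc["y_true_um"]), atol=1e-8)


class TestRendering:
    def test_empty_section_background_only(self, small_spec, mech_model):
        model = DamageModel(
            background_focus_prob=0.0,
            pan_schedule=_zero_schedule(),
            apoptosis_schedule=_zero_schedule(),
        )
        spec = TissueSpec(
            section_length=50.0, thickness_band=20.0, mean_cells_per_section=1.0, cells_sd=0.1
        )
        sec = generate_section(spec, None, model, 0.5, seed=1)
        sec.nuclei = sec.nuclei.iloc[0:0]
        sec.foci = sec.foci.iloc[0:0]
        rendered = render_images(sec, pixel_size=0.5, noise_sd=0.01, background=0.02, seed=0)
        assert rendered.stack.max() < 0.02 + 6 * 0.01

    def test_foci_become_local_maxima(self, small_spec):
        """A nucleus rendered with 3 separated 53BP1 foci shows 3 maxima."""
        spec = TissueSpec(
            section_length=60.0, thickness_band=30.0, mean_cells_per_section=1.0, cells_sd=0.1
        )
        model = DamageModel(
            background_focus_prob=0.0,
            pan_schedule=_zero_schedule(),
            apoptosis_schedule=_zero_schedule(),
        )
        sec = generate_section(spec, None, model, 0.5, seed=1)
        sec.nuclei = sec.nuclei.iloc[:1].copy()
        x0, y0 = sec.nuclei.iloc[0][["x_um", "y_um"]]
        sec.nuclei.loc[:, ["foci_53bp1", "foci_gh2ax", "foci_shared"]] = [3, 0, 0]
        sec.foci = pd.DataFrame(
            {
                "nucleus_id": [0, 0, 0],
                "channel": ["53bp1"] * 3,
                "x_um": [x0 - 2.0, x0, x0 + 2.0],
                "y_um": [y0, y0 + 2.0, y0],
                "shared": [False] * 3,
            }
        )
        rendered = render_images(sec, pixel_size=0.25, noise_sd=0.005, seed=0)
        from skimage.feature import peak_local_max

        chan = rendered.stack[1]
        peaks = peak_local_max(chan, min_distance=3, threshold_abs=0.3)
        assert len(peaks) == 3

    def test_pixel_size_limit(self, sham_section):
        with pytest.raises(ValueError):
            render_images(sham_section, pixel_size=2.0)
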