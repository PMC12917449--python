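"""Uptake analytics: compartment reduction, nighttime baseline, depletion
ratio, RWU rates, theta->psi conversion, radial profiles and transition
detection — including one full noiseless recovery run against the model
ground truth."""

import numpy as np
import pandas as pd
import pytest

from rhizoflux import drydown as D
from rhizoflux import dynamics as Y
from rhizoflux import hydraulics as H
from rhizoflux import processing as P
from rhizoflux import segmentation as G
from rhizoflux import simulate as sim
from conftest import chain_run


def _uniform_maps(values, shape=(16, 16)):
    return [
        P.WaterContentMap(theta=np.full(shape, v), valid_mask=np.ones(shape, bool))
        for v in values
    ]


def _meta(n, cadence_min=15.0, light=None):
    return pd.DataFrame(
        {
            "time_min": np.arange(n) * cadence_min,
            "light": np.ones(n, int) if light is None else light,
        }
    )


def _masks(shape=(16, 16)):
    skel = np.zeros(shape, bool)
    skel[4, 2:12] = True
    return G.build_masks(skel, np.ones(shape, bool), 2)


# ---------------------------------------------------------------------------
# compartment series
# ---------------------------------------------------------------------------

def test_uniform_map_gives_equal_compartments(default_box):
    maps = _uniform_maps([0.3, 0.3])
    cs = Y.compartment_series(maps, _masks(), _meta(2), default_box)
    assert np.allclose(cs.theta_rhizo, 0.3)
    assert np.allclose(cs.theta_bulk, 0.3)


def test_swapped_masks_swap_series(default_box):
    shape = (16, 16)
    rng = np.random.default_rng(0)
    maps = [
        P.WaterContentMap(
            theta=rng.uniform(0.1, 0.4, shape), valid_mask=np.ones(shape, bool)
        )
        for _ in range(3)
    ]
    region_a = np.zeros(shape, bool)
    region_a[:8] = True
    none = np.zeros(shape, bool)
    ms = G.MaskSet(skeleton=none, rhizosphere=region_a, bulk=~region_a,
                   dilation_radius_px=0)
    swapped = G.MaskSet(skeleton=none, rhizosphere=~region_a, bulk=region_a,
                        dilation_radius_px=0)
    a = Y.compartment_series(maps, ms, _meta(3), default_box)
    b = Y.compartment_series(maps, swapped, _meta(3), default_box)
    np.testing.assert_allclose(a.theta_rhizo, b.theta_bulk)
    np.testing.assert_allclose(a.theta_bulk, b.theta_rhizo)


def test_empty_mask_rejected(default_box):
    shape = (16, 16)
    empty = G.MaskSet(
        skeleton=np.zeros(shape, bool),
        rhizosphere=np.zeros(shape, bool),
        bulk=np.ones(shape, bool),
        dilation_radius_px=0,
    )
    with pytest.raises(ValueError, match="non-empty"):
        Y.compartment_series(_uniform_maps([0.3]), empty, _meta(1), default_box)


# ---------------------------------------------------------------------------
# nighttime baseline
# ---------------------------------------------------------------------------

def test_baseline_identity_line():
    s = pd.DataFrame(
        {
            "time_min": [0, 15, 30, 45],
            "theta_bulk": [0.30, 0.28, 0.26, 0.24],
            "theta_rhizo": [0.30, 0.28, 0.26, 0.24],
            "light": [0, 0, 0, 0],
        }
    )
    fit = Y.night_baseline(s)
    assert fit.slope == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)


def test_baseline_recovers_constructed_slope():
    tb = np.linspace(0.30, 0.20, 8)
    s = pd.DataFrame(
        {
            "time_min": np.arange(8) * 15.0,
            "theta_bulk": tb,
            "theta_rhizo": 0.5 * tb + 0.1,
            "light": 0,
        }
    )
    fit = Y.night_baseline(s)
    assert fit.slope == pytest.approx(0.5)
    assert fit.intercept == pytest.approx(0.1)
    assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)


def test_baseline_needs_three_night_frames():
    s = pd.DataFrame(
        {
            "time_min": [0, 15],
            "theta_bulk": [0.3, 0.29],
            "theta_rhizo": [0.3, 0.29],
            "light": [0, 0],
        }
    )
    with pytest.raises(ValueError, match="night frames"):
        Y.night_baseline(s)


def test_night_uptake_inflates_baseline():
    """The measured baseline with nocturnal transpiration is at least the
    zero-night-uptake slope — the conservatism argument for the reported
    shift."""
    slopes = {}
    for frac in (0.0, 0.05):
        scn = D.sand_scenario(e_night_frac=frac, duration_h=72.0)
        traj = D.simulate_drydown(scn)
        night = ~traj.light
        slopes[frac] = np.polyfit(
            traj.theta_bulk[night], traj.theta_rhizo[night], 1
        )[0]
    assert slopes[0.05] >= slopes[0.0] - 1e-6


# ---------------------------------------------------------------------------
# depletion ratio
# ---------------------------------------------------------------------------

def test_identical_drying_gives_unit_ratio():
    n = 12
    tb = 0.30 - 0.002 * np.arange(n)
    s = pd.DataFrame(
        {"time_min": np.arange(n) * 15.0, "theta_bulk": tb, "theta_rhizo": tb, "light": 1}
    )
    rs = Y.depletion_ratio(s)
    assert rs.defined.all()
    assert np.allclose(rs.ratio, 1.0)


def test_constant_bulk_is_undefined():
    n = 8
    s = pd.DataFrame(
        {
            "time_min": np.arange(n) * 15.0,
            "theta_bulk": np.full(n, 0.30),
            "theta_rhizo": 0.30 - 0.002 * np.arange(n),
            "light": 1,
        }
    )
    rs = Y.depletion_ratio(s)
    assert not rs.defined.any()


# ---------------------------------------------------------------------------
# RWU
# ---------------------------------------------------------------------------

def test_linear_drawdown_recovered_exactly(default_box):
    """Savitzky-Golay reproduces polynomials up to its order, so a linear
    total-water decline yields the exact uptake rate everywhere."""
    n = 30
    t = np.arange(n) * 15.0
    w = 20.0 - 0.01 * t  # cm3, b = 0.01 cm3/min
    s = pd.DataFrame({"time_min": t, "total_water": w, "light": 1})
    rwu, mean_rwu = Y.rwu_series(s)
    assert np.allclose(rwu.rwu_cm3_h, 0.01 * 60.0, rtol=1e-12)
    assert mean_rwu == pytest.approx(0.6)


def test_constant_water_zero_uptake():
    n = 20
    s = pd.DataFrame(
        {"time_min": np.arange(n) * 15.0, "total_water": np.full(n, 7.5), "light": 1}
    )
    rwu, mean_rwu = Y.rwu_series(s)
    assert np.allclose(rwu.rwu_cm3_h, 0.0, atol=1e-12)
    assert mean_rwu == pytest.approx(0.0, abs=1e-12)


def test_rwu_parameter_validation():
    s = pd.DataFrame(
        {"time_min": np.arange(20) * 15.0, "total_water": np.zeros(20), "light": 1}
    )
    with pytest.raises(ValueError, match="odd"):
        Y.rwu_series(s, sg_window=8)
    with pytest.raises(ValueError, match="cadence"):
        Y.rwu_series(s, diff_min=5.0)
    short = s.iloc[:5]
    with pytest.raises(ValueError, match="shorter"):
        Y.rwu_series(short)


# ---------------------------------------------------------------------------
# theta -> psi
# ---------------------------------------------------------------------------

def test_theta_to_psi_roundtrip(sand):
    assert Y.theta_to_psi(sand.theta_s, sand) == pytest.approx(0.0, abs=1e-9)
    psi = -np.geomspace(0.1, 100, 10)
    back = Y.theta_to_psi(H.theta_of_psi(sand, psi), sand)
    np.testing.assert_allclose(back, psi, rtol=1e-8)


def test_theta_to_psi_clamps_out_of_range(sand):
    psi = Y.theta_to_psi(np.array([0.01, 0.99]), sand)
    assert psi[0] <= -1e5  # below residual -> very dry, not an exception
    assert psi[1] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# radial depletion profile
# ---------------------------------------------------------------------------

def test_identical_maps_give_zero_profile(small_box):
    geom = sim.generate_root_system(small_box, seed=13)
    theta = sim.render_theta_field(geom, small_box, 0.25, 0.10)
    skel = geom.skeleton(small_box.grid)
    prof = Y.radial_depletion_profile(
        theta, theta, skel, small_box.pixel_size, dt_h=1.0
    )
    filled = prof[prof.n_pixels > 0]
    assert np.allclose(filled.dtheta_per_h, 0.0)


def test_profile_antisymmetric_under_frame_swap(small_box):
    geom = sim.generate_root_system(small_box, seed=13)
    early = sim.render_theta_field(geom, small_box, 0.25, 0.25)
    late = sim.render_theta_field(geom, small_box, 0.22, 0.08)
    skel = geom.skeleton(small_box.grid)
    a = Y.radial_depletion_profile(early, late, skel, small_box.pixel_size, 1.0)
    b = Y.radial_depletion_profile(late, early, skel, small_box.pixel_size, 1.0)
    filled = a.n_pixels > 0
    np.testing.assert_allclose(
        a.dtheta_per_h[filled], -b.dtheta_per_h[filled], rtol=1e-12
    )


def test_half_decline_distance_matches_annulus_width(small_box):
    """The painted depletion annulus is 0.1 cm wide with a linear blend,
    so the radius at which the depletion rate halves must sit within
    0.05 cm of 0.1 cm."""
    geom = sim.generate_root_system(small_box, seed=14)
    early = sim.render_theta_field(geom, small_box, 0.25, 0.25)
    late = sim.render_theta_field(geom, small_box, 0.24, 0.05)
    prof = Y.radial_depletion_profile(
        early, late, geom.skeleton(small_box.grid), small_box.pixel_size, 10.0,
        max_dist_cm=0.3,
    )
    prof = prof[prof.n_pixels > 0]
    near = prof.dtheta_per_h.iloc[0]
    below = prof[np.abs(prof.dtheta_per_h) <= 0.5 * np.abs(near)]
    d_half = below.dist_cm.iloc[0]
    assert abs(d_half - 0.1) <= 0.05


def test_empty_skeleton_rejected(small_box):
    theta = np.zeros(small_box.grid)
    with pytest.raises(ValueError, match="empty"):
        Y.radial_depletion_profile(
            theta, theta, np.zeros(small_box.grid, bool), small_box.pixel_size, 1.0
        )


# ---------------------------------------------------------------------------
# transition detection
# ---------------------------------------------------------------------------

def _ratio_frame(psis, ratios):
    return pd.DataFrame(
        {
            "time_min": np.arange(len(psis)) * 30.0,
            "ratio": ratios,
            "psi_bulk": psis,
            "since_light_on_min": 90.0,
            "defined": True,
        }
    )


def test_no_transition_at_baseline_level():
    base = Y.BaselineFit(slope=1.0, intercept=0.0, n_points=10, residual_sd=0.0)
    rs = _ratio_frame(-np.linspace(1, 30, 20), np.ones(20))
    res = Y.detect_transition(rs, base)
    assert res.psi_transition is None


def test_step_ratio_transition_at_step():
    base = Y.BaselineFit(slope=1.0, intercept=0.0, n_points=10, residual_sd=0.0)
    psis = -np.linspace(2, 20, 19)
    ratios = np.where(psis > -10.0, 1.0, 3.0)
    res = Y.detect_transition(_ratio_frame(psis, ratios), base)
    assert res.psi_transition == pytest.approx(-10.0)


def test_persistence_requirement():
    base = Y.BaselineFit(slope=1.0, intercept=0.0, n_points=10, residual_sd=0.0)
    ratios = np.ones(20)
    ratios[5] = 10.0  # single-window spike must not trigger
    res = Y.detect_transition(_ratio_frame(-np.linspace(1, 20, 20), ratios), base)
    assert res.psi_transition is None


# ---------------------------------------------------------------------------
# noiseless end-to-end recovery
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def noiseless_chain(default_box, atten):
    return chain_run(
        D.sand_scenario, default_box, atten, geometry_seed=21, noise_seed=None
    )


def test_bulk_series_tracks_ground_truth(noiseless_chain, default_box):
    scenario, traj, geometry, maps, meta = noiseless_chain
    masks = G.build_masks(
        geometry.skeleton(default_box.grid), np.ones(default_box.grid, bool), 5
    )
    cs = Y.compartment_series(maps, masks, meta, default_box)
    assert len(cs) == len(traj.time_h)
    assert np.max(np.abs(cs.theta_bulk.to_numpy() - traj.theta_bulk)) < 0.002


def test_rwu_matches_model_uptake(noiseless_chain, default_box):
    scenario, traj, geometry, maps, meta = noiseless_chain
    masks = G.build_masks(
        geometry.skeleton(default_box.grid), np.ones(default_box.grid, bool), 5
    )
    cs = Y.compartment_series(maps, masks, meta, default_box)
    rwu, _ = Y.rwu_series(cs)
    model_u_cm3_h = np.interp(rwu.time_min, traj.time_h * 60.0, traj.U) / 24.0
    day = (rwu.light == 1).to_numpy()
    # compare away from the light transitions where the finite difference
    # straddles the forcing discontinuity
    period = (scenario.light_on_h + scenario.light_off_h) * 60.0
    interior = day & ((rwu.time_min % period) > 60) & (
        (rwu.time_min % period) < scenario.light_on_h * 60.0 - 60
    )
    err = rwu.rwu_cm3_h[interior] - model_u_cm3_h[interior]
    rms = np.sqrt(np.mean(err**2))
    assert rms < 0.02 * np.max(model_u_cm3_h)


def test_recovered_psi_tracks_model(noiseless_chain, default_box, sand):
    scenario, traj, geometry, maps, meta = noiseless_chain
    masks = G.build_masks(
        geometry.skeleton(default_box.grid), np.ones(default_box.grid, bool), 5
    )
    cs = Y.compartment_series(maps, masks, meta, default_box)
    psi = Y.theta_to_psi(cs.theta_bulk.to_numpy(), sand)
    assert np.max(np.abs(psi - traj.psi_bulk) / np.abs(traj.psi_bulk)) < 0.05


def test_transition_recovered_within_factor_two(noiseless_chain, default_box, sand):
    scenario, traj, geometry, maps, meta = noiseless_chain
    masks = G.build_masks(
        geometry.skeleton(default_box.grid), np.ones(default_box.grid, bool), 5
    )
    cs = Y.compartment_series(maps, masks, meta, default_box)
    baseline = Y.night_baseline(cs)
    ratio = Y.depletion_ratio(cs, soil=sand)
    res = Y.detect_transition(ratio, baseline)
    gt = D.ground_truth_transition(traj)
    assert res.psi_transition is not None and gt is not None
    assert 0.5 <= abs(res.psi_transition) / abs(gt) <= 2.0
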