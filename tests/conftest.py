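"""Shared fixtures: soil parameter sets, desk-scale boxes and a tiny
synthetic experiment generated once per session."""

from __future__ import annotations

import pytest

from rhizoflux import drydown, hydraulics
from rhizoflux import simulate as sim


@pytest.fixture(scope="session")
def sand():
    return hydraulics.SAND


@pytest.fixture(scope="session")
def loam():
    return hydraulics.LOAM


@pytest.fixture(scope="session")
def geometry_std():
    """The root-geometry used for the critical-potential comparisons."""
    return hydraulics.RadialGeometry(r0=0.015, rb=0.5, L=1.0)


@pytest.fixture(scope="session")
def small_box():
    """128 x 128 px box for fast imaging tests."""
    return sim.RhizoboxSpec(width=2.56, height=2.56, grid=(128, 128))


@pytest.fixture(scope="session")
def default_box():
    return sim.RhizoboxSpec()


@pytest.fixture(scope="session")
def atten():
    return sim.AttenuationParams()


@pytest.fixture(scope="session")
def tiny_experiment(tmp_path_factory, small_box, atten):
    """A short noisy sand experiment written to disk once per session."""
    out = tmp_path_factory.mktemp("tiny_exp")
    scenario = drydown.sand_scenario(duration_h=4.0, dt_out_min=15.0)
    return sim.generate_experiment(
        scenario,
        small_box,
        atten,
        geometry_seed=11,
        noise_seed=11,
        out_dir=out,
        n_laterals=4,
    )


def chain_run(
    scenario_maker,
    box,
    atten,
    geometry_seed,
    noise_seed,
    n_laterals=20,
    theta_root=0.9,
):
    """Full in-memory forward+inverse chain for one seed.

    Generates a root system, rescales the scenario to its rendered
    geometry, simulates the drydown, renders/processes every frame and
    returns (scenario, trajectory, geometry, water maps, metadata frame).
    """
    import dataclasses

    import pandas as pd

    from rhizoflux import processing

    geometry = sim.generate_root_system(box, n_laterals=n_laterals, seed=geometry_seed)
    vols = sim.effective_volumes(geometry, box)
    base = scenario_maker()
    scenario = scenario_maker(
        V_bulk=vols["V_bulk"],
        V_rhizo=vols["V_rhizo"],
        geometry=dataclasses.replace(
            base.geometry, L=geometry.total_length_cm(box.pixel_size)
        ),
    )
    trajectory = drydown.simulate_drydown(scenario)
    refs = sim.render_references(box, atten)
    corrections, dry_ot = processing.make_corrections(
        refs["flat"].counts,
        refs["dark"].counts,
        refs["dry"].counts,
        scatter_frac=atten.scatter_frac,
    )
    maps, meta = [], []
    for frame in sim.synthesize_series(
        trajectory, geometry, box, atten, noise_seed=noise_seed, theta_root=theta_root
    ):
        maps.append(processing.process_frame(frame, corrections, dry_ot, atten, box))
        meta.append({"time_min": frame.timestamp_min, "light": int(frame.light)})
    return scenario, trajectory, geometry, maps, pd.DataFrame(meta)
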