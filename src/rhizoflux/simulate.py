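"""Forward neutron-imaging model: synthetic rhizobox radiograph series.

Turns a drydown trajectory plus a randomly generated branching root system
into a time series of detector-count images with known per-pixel ground
truth.  The imaging physics is Beer-Lambert attenuation through three
components along the ~1 cm beam path (water, dry soil, aluminum walls),
modulated by a flat-field gain map, offset by dark current and an additive
scattering term, with Poisson counting noise::

    E = dark + flat_field * I0 * (exp(-(mu_al*d_al
                                        + mu_soil*rho*d
                                        + mu_w*theta*d)) + scatter_frac)
    counts ~ Poisson(E)

The open-beam (flat-field) reference frame is rendered without the
scattering term: scattering here models neutrons scattered by the sample,
which is absent in the open beam.  This makes the inverse chain in
:mod:`rhizoflux.processing` an exact inversion of the forward model.

Pixel water content is the path-averaged volumetric water content across
the box thickness.  Columns containing a root mix the root chord (tissue
water ``theta_root``) with the local soil blend, which is what gives roots
their (modest) radiographic contrast even when rhizosphere and bulk soil
hold the same soil water content.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.ndimage import distance_transform_edt
from skimage.draw import line as draw_line

from .drydown import DrydownScenario, DrydownTrajectory, simulate_drydown

__all__ = [
    "RhizoboxSpec",
    "AttenuationParams",
    "RootGeometry",
    "RadiographFrame",
    "detector_pixel_size_um",
    "generate_root_system",
    "rasterize_skeleton",
    "render_theta_field",
    "render_radiograph",
    "render_references",
    "effective_volumes",
    "synthesize_series",
    "generate_experiment",
]


def detector_pixel_size_um(fov_mm: float, n_pixels: int) -> float:
    """Detector pixel pitch in micrometers from field of view and array size."""
    return fov_mm / n_pixels * 1000.0


@dataclass(frozen=True)
class RhizoboxSpec:
    """Geometry and packing of the imaged rhizobox.

    Defaults are a desk-scale stand-in for the experimental configuration:
    a 512 x 512 grid at 0.02 cm pixels (10.24 cm square window) through a
    1 cm soil path, sand packing density.
    """

    width: float = 10.24  # cm
    height: float = 10.24  # cm
    path_thickness: float = 1.0  # cm along the beam
    al_thickness: float = 0.4  # cm, both walls combined
    bulk_density: float = 1.88  # g cm-3 dry soil
    pixel_size: float = 0.02  # cm
    grid: tuple[int, int] = (512, 512)  # rows x cols

    def __post_init__(self) -> None:
        for name in ("width", "height", "path_thickness", "al_thickness",
                     "bulk_density", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        rows, cols = self.grid
        if abs(self.width - cols * self.pixel_size) > 0.5 * self.pixel_size:
            raise ValueError(
                f"width {self.width} cm inconsistent with {cols} columns of "
                f"{self.pixel_size} cm pixels"
            )
        if abs(self.height - rows * self.pixel_size) > 0.5 * self.pixel_size:
            raise ValueError(
                f"height {self.height} cm inconsistent with {rows} rows of "
                f"{self.pixel_size} cm pixels"
            )

    @property
    def soil_volume(self) -> float:
        """Imaged soil volume (cm3)."""
        rows, cols = self.grid
        return rows * cols * self.pixel_size**2 * self.path_thickness


@dataclass(frozen=True)
class AttenuationParams:
    """Neutron attenuation and detector parameters.

    Order-of-magnitude physical values; exact beamline calibration is out
    of scope.  ``mu_w`` and ``mu_al`` are linear attenuation coefficients
    (cm-1), ``mu_soil`` is the mass attenuation of dry soil (cm2 g-1).
    ``flat_field`` is a per-pixel gain map with mean ~1 (scalar 1.0 means
    a perfectly uniform detector).
    """

    mu_w: float = 3.5
    mu_soil: float = 0.02
    mu_al: float = 0.1
    I0: float = 1.0e4
    dark: float = 100.0
    flat_field: np.ndarray | float = 1.0
    scatter_frac: float = 0.05

    def __post_init__(self) -> None:
        for name in ("mu_w", "mu_soil", "mu_al", "scatter_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.I0 <= 0:
            raise ValueError("I0 must be > 0")
        if np.any(np.asarray(self.flat_field) <= 0):
            raise ValueError("flat_field must be strictly positive")

    def gain(self, shape: tuple[int, int]) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.flat_field, dtype=float), shape)


@dataclass
class RootGeometry:
    """Synthetic root system: polylines of (row, col) pixel vertices.

    ``polylines`` holds float vertex arrays of shape (n, 2); the first is
    the primary axis, the rest are laterals.  ``root_radius`` is the
    reference (lateral) radius; ``branch_radii`` optionally assigns one
    radius per polyline (a maize primary axis is several times thicker
    than its laterals).  ``rhizo_width`` is the radial extent of the
    depletion annulus.  All radii/widths in cm.
    """

    polylines: list[np.ndarray]
    root_radius: float = 0.025
    rhizo_width: float = 0.1
    branch_radii: list[float] | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.max_radius >= self.rhizo_width:
            raise ValueError("root radii must be smaller than rhizo_width")
        if self.branch_radii is not None and len(self.branch_radii) != len(self.polylines):
            raise ValueError("branch_radii must match the number of polylines")

    @property
    def radii(self) -> list[float]:
        if self.branch_radii is not None:
            return list(self.branch_radii)
        return [self.root_radius] * len(self.polylines)

    @property
    def max_radius(self) -> float:
        return max(self.radii) if self.polylines else self.root_radius

    def total_length_cm(self, pixel_size: float) -> float:
        return sum(
            float(np.sum(np.hypot(*np.diff(p, axis=0).T))) for p in self.polylines
        ) * pixel_size

    def skeleton(self, shape: tuple[int, int]) -> np.ndarray:
        key = ("skel", shape)
        if key not in self._cache:
            self._cache[key] = rasterize_skeleton(self.polylines, shape)
        return self._cache[key]

    def distance_cm(self, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        """Euclidean distance (cm) of every pixel to the rasterized skeleton."""
        key = ("dist", shape, pixel_size)
        if key not in self._cache:
            self._cache[key] = (
                distance_transform_edt(~self.skeleton(shape)) * pixel_size
            )
        return self._cache[key]

    def root_mask(self, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        """Boolean mask of pixels whose center lies inside a root."""
        key = ("rootmask", shape, pixel_size)
        if key not in self._cache:
            mask = np.zeros(shape, dtype=bool)
            for poly, radius in zip(self.polylines, self.radii):
                d = distance_transform_edt(~rasterize_skeleton([poly], shape))
                mask |= d * pixel_size <= radius
            self._cache[key] = mask
        return self._cache[key]


def rasterize_skeleton(polylines, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize vertex polylines to a 1-px-wide boolean skeleton (Bresenham)."""
    skel = np.zeros(shape, dtype=bool)
    for poly in polylines:
        v = np.rint(np.asarray(poly, dtype=float)).astype(int)
        for (r0, c0), (r1, c1) in zip(v[:-1], v[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            skel[rr, cc] = True
    return skel


def generate_root_system(
    box: RhizoboxSpec,
    n_laterals: int = 20,
    seed: int = 0,
    jitter: float = 1.0,
    root_radius: float = 0.025,
    primary_radius: float = 0.05,
    rhizo_width: float = 0.1,
) -> RootGeometry:
    """Seeded random branching root system inside the box.

    One primary axis grows vertically from the top with bounded lateral
    jitter; ``n_laterals`` first-order laterals branch at uniformly sampled
    depths with downward-biased headings.  The primary axis is thicker
    (``primary_radius``) than the laterals (``root_radius``), as for a
    young maize root system.  Deterministic for a fixed seed; all
    polylines stay inside the pixel grid.
    """
    if n_laterals < 0:
        raise ValueError("n_laterals must be >= 0")
    rows, cols = box.grid
    margin = int(np.ceil(max(root_radius, primary_radius) / box.pixel_size)) + 2
    if rows <= 2 * margin or cols <= 2 * margin:
        raise ValueError("box grid too small for the requested root radius")
    rng = np.random.default_rng(seed)

    step = 2.0  # px advance per segment
    col = cols / 2 + rng.uniform(-0.05, 0.05) * cols
    r, c = float(margin), float(col)
    primary = [(r, c)]
    max_row = rows - margin - 1
    while r < max_row:
        r = min(r + step, max_row)
        c = float(np.clip(c + jitter * rng.normal(0.0, 0.6), margin, cols - margin - 1))
        primary.append((r, c))
    primary = np.array(primary)

    polylines = [primary]
    if n_laterals > 0:
        depths = rng.uniform(0.08, 0.85, size=n_laterals)
        for d in np.sort(depths):
            i = int(d * (len(primary) - 1))
            r, c = primary[i]
            side = 1.0 if rng.random() < 0.5 else -1.0
            # heading below horizontal by 15-60 degrees, drifting downward
            ang = np.deg2rad(rng.uniform(15.0, 60.0))
            length_px = rng.uniform(0.3, 0.7) * min(rows, cols)
            pts = [(r, c)]
            travelled = 0.0
            while travelled < length_px:
                dr = step * np.sin(ang) + jitter * abs(rng.normal(0.0, 0.3))
                dc = side * step * np.cos(ang) + jitter * rng.normal(0.0, 0.5)
                r2 = r + dr
                c2 = c + dc
                if not (margin <= r2 <= max_row and margin <= c2 <= cols - margin - 1):
                    break
                travelled += np.hypot(r2 - r, c2 - c)
                r, c = r2, c2
                pts.append((r, c))
            if len(pts) > 1:
                polylines.append(np.array(pts))
    radii = [primary_radius] + [root_radius] * (len(polylines) - 1)
    return RootGeometry(
        polylines=polylines,
        root_radius=root_radius,
        rhizo_width=rhizo_width,
        branch_radii=radii,
    )


def render_theta_field(
    geometry: RootGeometry,
    box: RhizoboxSpec,
    theta_bulk: float,
    theta_rhizo: float,
    theta_root: float | None = None,
) -> np.ndarray:
    """Paint the per-pixel (path-averaged) water-content map.

    Soil water blends linearly with distance from the rasterized skeleton:
    ``theta_rhizo`` on the skeleton, ``theta_bulk`` at and beyond
    ``rhizo_width``.  If ``theta_root`` is given, pixels within the root
    radius additionally mix the root chord of tissue water into the beam
    path (fraction ``2*sqrt(r0^2 - d^2)/path_thickness``).
    """
    for th in (theta_bulk, theta_rhizo):
        if not (0.0 <= th <= 1.0):
            raise ValueError("water contents must lie in [0, 1]")
    shape = box.grid
    dist = geometry.distance_cm(shape, box.pixel_size)
    w = np.clip(dist / geometry.rhizo_width, 0.0, 1.0)
    theta = theta_rhizo + w * (theta_bulk - theta_rhizo)
    if theta_root is not None:
        f = _root_fraction(geometry, box)
        theta = (1.0 - f) * theta + f * theta_root
    return theta


def _root_fraction(geometry: RootGeometry, box: RhizoboxSpec) -> np.ndarray:
    """Per-pixel fraction of the beam path occupied by root tissue.

    Each branch contributes the chord of its cylinder along the beam,
    ``2*sqrt(r^2 - d^2)``; where branches overlap the thickest chord wins
    (roots do not stack along the thin box axis).
    """
    key = ("rootfrac", box.grid, box.pixel_size, box.path_thickness)
    if key not in geometry._cache:
        chord = np.zeros(box.grid, dtype=float)
        for radius in sorted(set(geometry.radii)):
            polys = [
                p for p, r in zip(geometry.polylines, geometry.radii) if r == radius
            ]
            d = (
                distance_transform_edt(~rasterize_skeleton(polys, box.grid))
                * box.pixel_size
            )
            np.maximum(
                chord, 2.0 * np.sqrt(np.clip(radius**2 - d**2, 0.0, None)), out=chord
            )
        geometry._cache[key] = (
            np.minimum(chord, box.path_thickness) / box.path_thickness
        )
    return geometry._cache[key]


def effective_volumes(geometry: RootGeometry, box: RhizoboxSpec) -> dict[str, float]:
    """Compartment volumes implied by the painted weight maps.

    With the linear annulus blend, total rendered soil water equals
    ``V_bulk*theta_bulk + V_rhizo*theta_rhizo + V_root*theta_root`` exactly
    when the volumes are computed from the same weights used to paint:
    ``V_rhizo = d * sum((1-f)(1-w)) * px^2`` etc.  Using these volumes in
    the drydown scenario makes sealed-box conservation exact by
    construction.
    """
    dist = geometry.distance_cm(box.grid, box.pixel_size)
    w = np.clip(dist / geometry.rhizo_width, 0.0, 1.0)
    f = _root_fraction(geometry, box)
    cell = box.pixel_size**2 * box.path_thickness
    v_rhizo = float(np.sum((1.0 - f) * (1.0 - w)) * cell)
    v_root = float(np.sum(f) * cell)
    v_bulk = float(np.sum((1.0 - f) * w) * cell)
    return {"V_bulk": v_bulk, "V_rhizo": v_rhizo, "V_root": v_root}


@dataclass
class RadiographFrame:
    """One detector exposure: a count image plus acquisition metadata."""

    counts: np.ndarray
    timestamp_min: float = 0.0
    light: bool = True
    exposure_id: str = ""


def _expected_counts(theta: np.ndarray, box: RhizoboxSpec, atten: AttenuationParams):
    ot = (
        atten.mu_al * box.al_thickness
        + atten.mu_soil * box.bulk_density * box.path_thickness
        + atten.mu_w * theta * box.path_thickness
    )
    gain = atten.gain(theta.shape)
    return atten.dark + gain * atten.I0 * (np.exp(-ot) + atten.scatter_frac)


def render_radiograph(
    theta_map: np.ndarray,
    box: RhizoboxSpec,
    atten: AttenuationParams,
    noise_seed: int | None = None,
) -> RadiographFrame:
    """Render one radiograph from a water-content map.

    ``noise_seed=None`` returns the noiseless expectation (float counts);
    otherwise counts are Poisson-distributed with that seed.
    """
    theta_map = np.asarray(theta_map, dtype=float)
    if theta_map.shape != tuple(box.grid):
        raise ValueError(f"theta map shape {theta_map.shape} != box grid {box.grid}")
    expected = _expected_counts(theta_map, box, atten)
    if np.any(expected <= 0.0):
        raise ValueError("expected counts must be positive; check parameters")
    if noise_seed is None:
        counts = expected
    else:
        counts = np.random.default_rng(noise_seed).poisson(expected).astype(np.float64)
    return RadiographFrame(counts=counts)


def render_references(
    box: RhizoboxSpec,
    atten: AttenuationParams,
    noise_seed: int | None = None,
) -> dict[str, RadiographFrame]:
    """Render the flat-field (open beam), dark and dry-box reference frames.

    The open beam carries no sample scattering; the dry box is the full
    forward model at theta = 0.
    """
    shape = tuple(box.grid)
    gain = atten.gain(shape)
    flat = atten.dark + gain * atten.I0
    dark = np.full(shape, atten.dark)
    dry = _expected_counts(np.zeros(shape), box, atten)
    frames = {}
    seeds = {"flat": None, "dark": None, "dry": None}
    if noise_seed is not None:
        ss = np.random.SeedSequence(noise_seed).spawn(3)
        seeds = dict(zip(("flat", "dark", "dry"), ss))
    for name, expected in (("flat", flat), ("dark", dark), ("dry", dry)):
        if seeds[name] is None:
            counts = np.asarray(expected, dtype=float).copy()
        else:
            counts = (
                np.random.default_rng(seeds[name]).poisson(expected).astype(np.float64)
            )
        frames[name] = RadiographFrame(counts=counts, exposure_id=name)
    return frames


def synthesize_series(
    trajectory: DrydownTrajectory,
    geometry: RootGeometry,
    box: RhizoboxSpec,
    atten: AttenuationParams,
    noise_seed: int | None = None,
    theta_root: float | None = 0.9,
):
    """Yield ``RadiographFrame`` objects, one per trajectory sample.

    Frames are rendered lazily so that long series never hold the whole
    stack in memory.
    """
    child = None
    if noise_seed is not None:
        child = np.random.SeedSequence(noise_seed).spawn(len(trajectory.time_h))
    for i, t_h in enumerate(trajectory.time_h):
        theta = render_theta_field(
            geometry,
            box,
            theta_bulk=float(trajectory.theta_bulk[i]),
            theta_rhizo=float(trajectory.theta_rhizo[i]),
            theta_root=theta_root,
        )
        frame = render_radiograph(
            theta, box, atten, noise_seed=None if child is None else child[i]
        )
        frame.timestamp_min = float(t_h) * 60.0
        frame.light = bool(trajectory.light[i])
        frame.exposure_id = f"frame_{i:04d}"
        yield frame


def _to_uint16(counts: np.ndarray) -> np.ndarray:
    if np.any(counts > 65535):
        warnings.warn("detector saturation: counts clipped at 65535", stacklevel=2)
    return np.clip(np.rint(counts), 0, 65535).astype(np.uint16)


def generate_experiment(
    scenario: DrydownScenario,
    box: RhizoboxSpec,
    atten: AttenuationParams,
    geometry_seed: int,
    noise_seed: int | None,
    out_dir,
    n_laterals: int = 20,
    theta_root: float | None = 0.9,
) -> dict:
    """Run the full forward chain and write a radiograph data set to disk.

    Generates a root system, rescales the scenario's compartment volumes
    and root length to the rendered geometry, simulates the drydown, and
    writes one 16-bit TIFF per sample plus flat/dark/dry reference frames,
    ``frames.csv`` acquisition metadata, ``truth.csv`` ground truth and
    ``config.yaml``.  Fully reproducible from the two seeds.

    Returns a dict of output paths plus the in-memory geometry, scenario
    and trajectory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = generate_root_system(box, n_laterals=n_laterals, seed=geometry_seed)
    vols = effective_volumes(geometry, box)
    scenario = scenario.replace(
        V_bulk=vols["V_bulk"],
        V_rhizo=vols["V_rhizo"],
        geometry=dataclasses.replace(
            scenario.geometry, L=geometry.total_length_cm(box.pixel_size)
        ),
    )
    trajectory = simulate_drydown(scenario)

    refs = render_references(box, atten, noise_seed=None)
    for name, frame in refs.items():
        tifffile.imwrite(out / f"{name}.tif", _to_uint16(frame.counts))

    meta = []
    for i, frame in enumerate(
        synthesize_series(
            trajectory, geometry, box, atten, noise_seed=noise_seed, theta_root=theta_root
        )
    ):
        fname = f"frame_{i:04d}.tif"
        tifffile.imwrite(out / fname, _to_uint16(frame.counts))
        meta.append(
            {
                "index": i,
                "filename": fname,
                "time_min": frame.timestamp_min,
                "light": int(frame.light),
            }
        )
    frames_csv = out / "frames.csv"
    pd.DataFrame(meta).to_csv(frames_csv, index=False)

    truth_csv = out / "truth.csv"
    trajectory.to_frame().to_csv(truth_csv, index=False)

    config = {
        "scenario": _scenario_dict(scenario),
        "box": dataclasses.asdict(box),
        "attenuation": {
            k: (float(v) if np.ndim(v) == 0 else "per-pixel map")
            for k, v in dataclasses.asdict(atten).items()
        },
        "geometry_seed": geometry_seed,
        "noise_seed": noise_seed,
        "n_laterals": n_laterals,
        "theta_root": theta_root,
        "root_radius_cm": geometry.root_radius,
        "rhizo_width_cm": geometry.rhizo_width,
        "root_length_cm": geometry.total_length_cm(box.pixel_size),
        "volumes": vols,
    }
    config_yaml = out / "config.yaml"
    with open(config_yaml, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    skeleton_csv = out / "skeleton.csv"
    export_polylines(geometry.polylines, skeleton_csv)

    return {
        "out_dir": out,
        "frames_csv": frames_csv,
        "truth_csv": truth_csv,
        "config_yaml": config_yaml,
        "skeleton_csv": skeleton_csv,
        "references": {name: out / f"{name}.tif" for name in refs},
        "geometry": geometry,
        "scenario": scenario,
        "trajectory": trajectory,
    }


def _scenario_dict(scn: DrydownScenario) -> dict:
    d = dataclasses.asdict(scn)
    d["soil_bulk"] = dataclasses.asdict(scn.soil_bulk)
    d["soil_rhizo"] = dataclasses.asdict(scn.soil_rhizo)
    d["geometry"] = dataclasses.asdict(scn.geometry)
    return d


def export_polylines(polylines, path) -> None:
    """Write polylines as a branch/vertex CSV (columns branch,row,col)."""
    rows = [
        {"branch": b, "row": float(r), "col": float(c)}
        for b, poly in enumerate(polylines)
        for r, c in np.asarray(poly, dtype=float)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
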