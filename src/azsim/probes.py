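"""Circle-probe evaluation, peak detection and scenario comparison.

Concentrations are quantified on rings of sample points around the (virtual)
T-bar socket center: radius R = n_r * delta_r, height H = n_h * delta_h above
the membrane, n_phi_max points per ring.  The ring average of the trilinearly
interpolated field is the primary readout; scenario ratios compare these
averages at matched action-potential peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometrySpec, SubdomainU, VoxelGrid
from .kinetics import APTrainSpec

__all__ = [
    "CircleProbe",
    "TimeSeries",
    "ScenarioComparison",
    "circle_points",
    "trilinear_sampler",
    "circle_average",
    "detect_peaks",
    "scenario_ratios",
    "radial_profile",
    "subdomain_U_average",
    "grid_convergence",
]


@dataclass(frozen=True)
class CircleProbe:
    """Ring of sample points at radius n_r*delta_r and height n_h*delta_h."""

    base_point: tuple[float, float, float]
    n_h: int
    n_r: int
    delta_h: float = 0.01
    delta_r: float = 0.01
    n_phi_max: int = 64

    def __post_init__(self):
        if self.n_h < 1 or self.n_r < 1:
            raise ValueError("n_h and n_r must be positive")
        if self.n_phi_max < 4:
            raise ValueError("need at least 4 points per circle")
        if self.delta_h <= 0 or self.delta_r <= 0:
            raise ValueError("raster spacings must be positive")

    @property
    def radius(self) -> float:
        return self.n_r * self.delta_r

    @property
    def height(self) -> float:
        return self.n_h * self.delta_h

    @classmethod
    def at(cls, base_point, radius: float, height: float,
           delta: float = 0.01, n_phi_max: int = 64) -> "CircleProbe":
        """Probe at an (R, H) location on the default 10 nm raster."""
        n_r = round(radius / delta)
        n_h = round(height / delta)
        if abs(n_r * delta - radius) > 1e-9 or abs(n_h * delta - height) > 1e-9:
            raise ValueError("radius/height must sit on the probe raster")
        return cls(base_point=tuple(base_point), n_h=n_h, n_r=n_r,
                   delta_h=delta, delta_r=delta, n_phi_max=n_phi_max)


@dataclass
class TimeSeries:
    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")


@dataclass
class ScenarioComparison:
    """Peak-matched comparison of the three anatomies at one (R, H) probe."""

    radius: float
    height: float
    peak_index: int
    values: dict          # scenario name -> peak value (μM)
    percent_excess: float  # 100 (tbar - clustered) / clustered
    fold: dict            # scenario name -> tbar / value
    percent_excess_baseline_subtracted: float
    fold_baseline_subtracted: dict


def circle_points(probe: CircleProbe, spec: GeometrySpec | None = None,
                  box_dims: tuple[float, float, float] | None = None,
                  phase: float = 0.0) -> np.ndarray:
    """Evenly spaced points of the probe ring; rejects rings that touch the
    socket, the obstacle, or leave the box."""
    if spec is not None and spec.has_tbar:
        if probe.radius <= spec.leg_radius:
            raise ValueError("evaluation radius lies inside the T-bar socket")
        under_roof = probe.height <= spec.leg_height + spec.roof_thickness
        if under_roof and probe.radius <= spec.leg_radius:
            raise ValueError("probe intersects the leg")
    phi = phase + 2.0 * np.pi * np.arange(probe.n_phi_max) / probe.n_phi_max
    bx, by, bz = probe.base_point
    pts = np.column_stack([
        bx + probe.radius * np.cos(phi),
        by + probe.radius * np.sin(phi),
        np.full(probe.n_phi_max, bz + probe.height),
    ])
    dims = box_dims if box_dims is not None else (spec.box_dims if spec is not None else None)
    if dims is not None:
        if (pts < 0).any() or (pts > np.asarray(dims)).any():
            raise ValueError("probe points leave the computational box")
    if spec is not None and spec.has_tbar:
        r = np.hypot(pts[:, 0] - bx, pts[:, 1] - by)
        z = pts[:, 2]
        # open-set test: points on the obstacle surface are in the fluid
        in_leg = (r < spec.leg_radius) & (z < spec.leg_height)
        in_roof = ((r < spec.roof_radius) & (z > spec.leg_height)
                   & (z < spec.leg_height + spec.roof_thickness))
        if in_leg.any() or in_roof.any():
            raise ValueError("probe points lie inside the T-bar obstacle")
    return pts


class trilinear_sampler:
    """Precomputed trilinear interpolation of fluid-cell fields at fixed points.

    Stencil corners inside the obstacle are dropped and the remaining
    weights renormalized (nearest-fluid fallback); affected points are
    flagged.  Exact for constant and linear fields away from obstacles.
    """

    def __init__(self, grid: VoxelGrid, points: np.ndarray):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = grid.spacing
        nx, ny, nz = grid.shape
        # continuous index relative to cell centers
        u = (pts - np.asarray(grid.origin)) / h - 0.5
        i0 = np.floor(u).astype(int)
        frac = u - i0
        corners = []
        weights = []
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    ci = np.clip(i0[:, 0] + dx, 0, nx - 1)
                    cj = np.clip(i0[:, 1] + dy, 0, ny - 1)
                    ck = np.clip(i0[:, 2] + dz, 0, nz - 1)
                    w = (np.where(dx, frac[:, 0], 1 - frac[:, 0])
                         * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                         * np.where(dz, frac[:, 2], 1 - frac[:, 2]))
                    corners.append(grid.fluid_index[ci, cj, ck])
                    weights.append(w)
        idx = np.stack(corners, axis=1)          # (P, 8)
        w = np.stack(weights, axis=1)            # (P, 8)
        valid = idx >= 0
        w = np.where(valid, w, 0.0)
        norm = w.sum(axis=1)
        if (norm <= 0).any():
            raise ValueError("sample point has no fluid cell in its stencil")
        self.flagged = (~valid & (np.stack(weights, axis=1) > 1e-12)).any(axis=1)
        self.weights = w / norm[:, None]
        self.indices = np.where(valid, idx, 0)

    def __call__(self, values_flat: np.ndarray) -> np.ndarray:
        return (values_flat[self.indices] * self.weights).sum(axis=1)


def circle_average(values_flat: np.ndarray, grid: VoxelGrid, probe: CircleProbe,
                   spec: GeometrySpec | None = None,
                   sampler: trilinear_sampler | None = None) -> float:
    """Arithmetic mean of the interpolated field over the probe ring (μM)."""
    if sampler is None:
        pts = circle_points(probe, spec=spec, box_dims=grid.box_dims)
        sampler = trilinear_sampler(grid, pts)
    return float(sampler(values_flat).mean())


def detect_peaks(ts: TimeSeries, train: APTrainSpec) -> list[tuple[float, float]]:
    """One maximum per spike-period window aligned to the spike onsets."""
    t, v = ts.times, ts.values
    # the trace must at least reach past the first spike's depolarization
    if t[-1] < train.t_delay:
        raise ValueError("time series does not cover one full stimulation peak")
    peaks = []
    k = 0
    while k * train.period < t[-1] - 1e-12:
        lo, hi = k * train.period, (k + 1) * train.period
        m = (t >= lo - 1e-12) & (t < hi - 1e-12)
        if m.any():
            i = np.argmax(v[m])
            peaks.append((float(t[m][i]), float(v[m][i])))
        k += 1
    return peaks


def _peak_value(result, radius, height, peak_index, at_time=None):
    ts = result.probe_series(radius, height)
    if at_time is not None:
        i = int(np.argmin(np.abs(ts.times - at_time)))
        return float(ts.values[i])
    pk = detect_peaks(ts, result.train)
    if peak_index >= len(pk):
        raise ValueError(f"peak {peak_index} not covered by the run")
    return pk[peak_index][1]


def scenario_ratios(results: dict, radius: float, height: float,
                    peak_index: int = 0, baseline: float | None = None,
                    at_time: float | None = None) -> ScenarioComparison:
    """Percent excess and fold ratios between scenarios at matched peaks.

    ``results`` maps scenario names to ScenarioResult; the T-bar scenario
    and the no-T-bar clustered scenario drive the percent-excess readout.
    By default each scenario's own peak time is used ("matched peaks"); pass
    ``at_time`` to evaluate all scenarios at one fixed time instead.
    """
    names = list(results)
    cfgs = {n: r.config_echo for n, r in results.items()}
    probes0 = cfgs[names[0]].get("probes")
    for n in names[1:]:
        if cfgs[n].get("probes") != probes0:
            raise ValueError("scenario probe definitions differ")
        if cfgs[n].get("train") != cfgs[names[0]].get("train"):
            raise ValueError("scenario stimulation trains differ")

    vals = {n: _peak_value(r, radius, height, peak_index, at_time)
            for n, r in results.items()}
    tbar_name = next((n for n in names if results[n].has_tbar), names[0])
    clustered_name = next(
        (n for n in names if not results[n].has_tbar and results[n].channels_clustered),
        names[-1],
    )
    tv, cv = vals[tbar_name], vals[clustered_name]
    base = baseline if baseline is not None else 0.0
    excess = 100.0 * (tv - cv) / cv
    excess_bs = 100.0 * ((tv - base) - (cv - base)) / (cv - base)
    fold = {n: tv / v for n, v in vals.items()}
    fold_bs = {n: (tv - base) / (v - base) for n, v in vals.items()}
    return ScenarioComparison(
        radius=radius, height=height, peak_index=peak_index, values=vals,
        percent_excess=excess, fold=fold,
        percent_excess_baseline_subtracted=excess_bs,
        fold_baseline_subtracted=fold_bs,
    )


def radial_profile(result, height: float, at_time: float) -> tuple[np.ndarray, np.ndarray]:
    """Probe values over the R raster at one height and time."""
    radii = sorted({r for (r, hh) in result.probe_keys() if abs(hh - height) < 1e-12})
    vals = []
    for r in radii:
        ts = result.probe_series(r, height)
        i = int(np.argmin(np.abs(ts.times - at_time)))
        vals.append(ts.values[i])
    return np.asarray(radii), np.asarray(vals)


def subdomain_U_average(values_flat: np.ndarray, U: SubdomainU) -> float:
    """Volume-weighted mean over the subdomain-U cells (equal cell volumes)."""
    if U.cell_indices.size == 0:
        raise ValueError("subdomain U is empty")
    return float(values_flat[U.cell_indices].mean())


def grid_convergence(values_by_level: list[dict]) -> list[dict]:
    """Relative differences |v_l - v_{l+1}| / |v_{l+1}| per probe key.

    ``values_by_level`` is ordered coarse -> fine; each entry maps a probe
    key to a scalar readout on that refinement level.
    """
    if len(values_by_level) < 2:
        raise ValueError("need at least two refinement levels")
    keys = set(values_by_level[0])
    for lv in values_by_level[1:]:
        if set(lv) != keys:
            raise ValueError("refinement levels report different probe keys")
    out = []
    for coarse, fine in zip(values_by_level[:-1], values_by_level[1:]):
        diffs = {k: abs(coarse[k] - fine[k]) / abs(fine[k]) for k in keys}
        diffs["max"] = max(diffs.values())
        out.append(diffs)
    return out
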