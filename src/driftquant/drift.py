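"""Individual-based model of larval herring drift.

Larvae hatch at weighted spawning grounds along the Norwegian coast with a
Gaussian-shaped hatching intensity inside a fixed spring window, are advected
by daily-mean currents (4th-order Runge-Kutta over trilinear/linear
interpolated velocities), perform diel vertical migration between a shallow
night depth and a deep day depth by swimming at 0.1 body lengths per second,
and grow linearly from 9 mm at 0.4 mm per day. Particles that touch land
beach irreversibly; particles that leave the grid are frozen as exited.

The stepping kernel is vectorised over particles; :func:`advect_step` exposes
the same update for a single particle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .flowfield import EARTH_RADIUS_M, FlowField
from .solar import is_night

__all__ = [
    "HATCH_LENGTH_MM",
    "GROWTH_MM_PER_DAY",
    "SWIM_BL_PER_S",
    "DVM_BAND_M",
    "SpawningGround",
    "ReleaseConfig",
    "ParticleState",
    "ParticleEnsemble",
    "SimulationResult",
    "DensityGrid",
    "release_particles",
    "largest_remainder_counts",
    "diel_target_depth",
    "advect_step",
    "run_simulation",
    "density_grid",
]

HATCH_LENGTH_MM = 9.0       # length at hatch
GROWTH_MM_PER_DAY = 0.4     # linear growth rate
SWIM_BL_PER_S = 0.1         # swimming speed, body lengths per second
DVM_BAND_M = (5.0, 40.0)    # night (shallow) and day (deep) depths

_ACTIVE, _BEACHED, _EXITED = 0, 1, 2
_STATUS_NAMES = np.array(["active", "beached", "exited"])


@dataclass(frozen=True)
class SpawningGround:
    """A named release site with its share of the total release.

    ``polygon`` (sequence of (lon, lat) vertices) spreads releases uniformly
    over an area; otherwise particles start at the point, optionally jittered
    within ``jitter_km``.
    """

    name: str
    lon: float
    lat: float
    fraction: float
    polygon: tuple | None = None
    jitter_km: float = 0.0

    def __post_init__(self):
        if self.fraction < 0:
            raise ValueError(f"ground {self.name}: fraction must be >= 0")


@dataclass(frozen=True)
class ReleaseConfig:
    """Release schedule: how many larvae hatch, where, and when.

    Hatching intensity is Gaussian in time, truncated to
    [hatch_start, hatch_end]. When unspecified, the Gaussian mean is the
    window midpoint and the standard deviation one sixth of the window
    length, so the window covers +/- 3 sd.
    """

    grounds: tuple
    total_particles: int = 198_580
    hatch_start: str = "2017-03-15"
    hatch_end: str = "2017-04-20"
    hatch_mean: str | None = None
    hatch_sd_days: float | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if not self.grounds:
            raise ValueError("at least one spawning ground is required")
        if self.total_particles < 0:
            raise ValueError("total_particles must be >= 0")
        total = sum(g.fraction for g in self.grounds)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ground fractions sum to {total!r}, expected 1")
        start, end = pd.Timestamp(self.hatch_start), pd.Timestamp(self.hatch_end)
        if not start < end:
            raise ValueError("hatch window start must precede end")
        if self.hatch_sd_days is not None and self.hatch_sd_days <= 0:
            raise ValueError("hatch_sd_days must be > 0")

    @property
    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return pd.Timestamp(self.hatch_start), pd.Timestamp(self.hatch_end)

    @property
    def mean_ts(self) -> pd.Timestamp:
        if self.hatch_mean is not None:
            return pd.Timestamp(self.hatch_mean)
        start, end = self.window
        return start + (end - start) / 2

    @property
    def sd_days(self) -> float:
        if self.hatch_sd_days is not None:
            return float(self.hatch_sd_days)
        start, end = self.window
        return (end - start) / pd.Timedelta(days=1) / 6.0

    def digest(self) -> str:
        blob = json.dumps(
            {
                "total": self.total_particles,
                "window": [str(self.hatch_start), str(self.hatch_end)],
                "mean": str(self.mean_ts),
                "sd_days": self.sd_days,
                "seed": self.rng_seed,
                "grounds": [
                    [g.name, g.lon, g.lat, g.fraction, g.jitter_km] for g in self.grounds
                ],
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ParticleState:
    """One simulated larva."""

    id: int
    lon: float
    lat: float
    depth: float
    length: float
    hatch_time: pd.Timestamp
    age: float  # days since hatch
    ground: str
    status: str = "active"

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0 (positive down)")
        if self.age < 0:
            raise ValueError("age must be >= 0")


class ParticleEnsemble:
    """Struct-of-arrays particle container; indexing yields ParticleState."""

    def __init__(self, ids, lon, lat, depth, length, hatch_time, age, ground, status):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.lon = np.asarray(lon, dtype=float)
        self.lat = np.asarray(lat, dtype=float)
        self.depth = np.asarray(depth, dtype=float)
        self.length = np.asarray(length, dtype=float)
        self.hatch_time = pd.DatetimeIndex(hatch_time)
        self.age = np.asarray(age, dtype=float)
        self.ground = np.asarray(ground, dtype=object)
        self.status = np.asarray(status, dtype=np.int8)

    def __len__(self) -> int:
        return self.ids.size

    def __getitem__(self, i: int) -> ParticleState:
        return ParticleState(
            id=int(self.ids[i]), lon=float(self.lon[i]), lat=float(self.lat[i]),
            depth=float(self.depth[i]), length=float(self.length[i]),
            hatch_time=self.hatch_time[i], age=float(self.age[i]),
            ground=str(self.ground[i]), status=str(_STATUS_NAMES[self.status[i]]),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids, "lon": self.lon, "lat": self.lat,
                "depth": self.depth, "length": self.length,
                "hatch_time": self.hatch_time, "age": self.age,
                "ground": self.ground, "status": _STATUS_NAMES[self.status],
            }
        )


@dataclass
class SimulationResult:
    """Per-snapshot particle states plus run metadata."""

    snapshot_times: list
    snapshots: list  # list of pandas DataFrames, one per snapshot time
    metadata: dict = field(default_factory=dict)

    def at(self, date) -> pd.DataFrame:
        t = pd.Timestamp(date)
        for when, snap in zip(self.snapshot_times, self.snapshots):
            if when == t:
                return snap
        raise KeyError(f"no snapshot stored at {t}")


@dataclass
class DensityGrid:
    """Binned particle counts with an optional display transform."""

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    counts: np.ndarray  # (lat, lon) raw counts
    transform: str = "raw"

    _TRANSFORMS = ("raw", "log_n", "sqrt_n")

    def __post_init__(self):
        if self.transform not in self._TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.transform!r}; expected one of {self._TRANSFORMS}"
            )

    @property
    def values(self) -> np.ndarray:
        if self.transform == "raw":
            return self.counts.astype(float)
        if self.transform == "log_n":
            return np.log(self.counts + 1.0)
        return np.sqrt(self.counts)

    def to_dataframe(self) -> pd.DataFrame:
        lon_c = 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])
        lat_c = 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])
        lon_g, lat_g = np.meshgrid(lon_c, lat_c)
        return pd.DataFrame(
            {
                "lon": lon_g.ravel(), "lat": lat_g.ravel(),
                "count": self.counts.ravel(), "value": self.values.ravel(),
                "transform": self.transform,
            }
        )


# --------------------------------------------------------------------------- #
# Release
# --------------------------------------------------------------------------- #

def largest_remainder_counts(total: int, fractions: Sequence[float]) -> np.ndarray:
    """Integer split of ``total`` by ``fractions`` whose sum is exact.

    Each share is floored and the leftover units go to the largest
    fractional remainders (ties broken by position).
    """
    fr = np.asarray(fractions, dtype=float)
    raw = total * fr
    counts = np.floor(raw).astype(np.int64)
    short = int(round(total - counts.sum()))
    if short:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _truncated_normal_times(
    n: int, mean: pd.Timestamp, sd_days: float,
    window: tuple[pd.Timestamp, pd.Timestamp], rng: np.random.Generator,
) -> pd.DatetimeIndex:
    from scipy.stats import truncnorm

    start, end = window
    mean_d = (mean - start) / pd.Timedelta(days=1)
    span_d = (end - start) / pd.Timedelta(days=1)
    a, b = (0.0 - mean_d) / sd_days, (span_d - mean_d) / sd_days
    days = truncnorm.rvs(a, b, loc=mean_d, scale=sd_days, size=n, random_state=rng)
    return start + pd.to_timedelta(days, unit="D")


def _sample_polygon(polygon, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    from shapely.geometry import Point, Polygon

    poly = Polygon(polygon)
    minx, miny, maxx, maxy = poly.bounds
    lons = np.empty(n)
    lats = np.empty(n)
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        inside = np.fromiter(
            (poly.contains(Point(x, y)) for x, y in zip(xs, ys)), bool, count=m
        )
        take = min(inside.sum(), n - got)
        lons[got:got + take] = xs[inside][:take]
        lats[got:got + take] = ys[inside][:take]
        got += take
    return lons, lats


def release_particles(config: ReleaseConfig) -> ParticleEnsemble:
    """Create the initial particle set for a release schedule.

    Per-ground counts follow the configured fractions with largest-remainder
    rounding so the grand total is exact; hatch times are drawn from the
    truncated Gaussian hatching intensity. Deterministic for a given seed.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.total_particles
    counts = largest_remainder_counts(n, [g.fraction for g in config.grounds])

    lons = np.empty(n)
    lats = np.empty(n)
    grounds = np.empty(n, dtype=object)
    pos = 0
    for g, c in zip(config.grounds, counts):
        sl = slice(pos, pos + c)
        if g.polygon is not None:
            lons[sl], lats[sl] = _sample_polygon(g.polygon, c, rng)
        else:
            lons[sl] = g.lon
            lats[sl] = g.lat
            if g.jitter_km > 0:
                r = g.jitter_km * 1000.0 * np.sqrt(rng.uniform(size=c))
                th = rng.uniform(0, 2 * np.pi, size=c)
                lats[sl] += np.rad2deg(r * np.sin(th) / EARTH_RADIUS_M)
                lons[sl] += np.rad2deg(
                    r * np.cos(th) / (EARTH_RADIUS_M * np.cos(np.deg2rad(g.lat)))
                )
        grounds[sl] = g.name
        pos += c

    hatch = _truncated_normal_times(n, config.mean_ts, config.sd_days, config.window, rng)
    return ParticleEnsemble(
        ids=np.arange(n), lon=lons, lat=lats,
        depth=np.full(n, DVM_BAND_M[0]), length=np.full(n, HATCH_LENGTH_MM),
        hatch_time=hatch, age=np.zeros(n), ground=grounds,
        status=np.zeros(n, dtype=np.int8),
    )


# --------------------------------------------------------------------------- #
# Behavior and advection
# --------------------------------------------------------------------------- #

def diel_target_depth(time, lon, lat, dvm_band=DVM_BAND_M):
    """Target depth of the diel vertical migration at this time and place.

    Shallow bound at night, deep bound during day; under midnight sun the
    night window is a fixed interval around the daily solar-elevation
    minimum (see :func:`driftquant.solar.is_night`).
    """
    shallow, deep = dvm_band
    night = is_night(time, lon, lat)
    return np.where(night, shallow, deep) if np.ndim(night) else (shallow if night else deep)


def _deg_rates(field: FlowField, t_s, lon, lat, depth):
    """(dlon/dt, dlat/dt) in degrees per second; NaN outside the grid."""
    u, v = field.velocity(t_s, lon, lat, depth)
    dlat = np.rad2deg(v / EARTH_RADIUS_M)
    dlon = np.rad2deg(u / (EARTH_RADIUS_M * np.cos(np.deg2rad(lat))))
    return dlon, dlat


def _step_arrays(field: FlowField, t: pd.Timestamp, dt: float,
                 lon, lat, depth, length, dvm_band=DVM_BAND_M):
    """One RK4 + DVM + growth update; returns new arrays and status changes.

    Velocities are sampled trilinearly in space and linearly in time; the
    vertical update moves toward the diel target depth at 0.1 body lengths
    per second, clamped to the migration band.
    """
    t_s = field.seconds_since_start(t)

    k1x, k1y = _deg_rates(field, t_s, lon, lat, depth)
    k2x, k2y = _deg_rates(field, t_s + dt / 2, lon + k1x * dt / 2, lat + k1y * dt / 2, depth)
    k3x, k3y = _deg_rates(field, t_s + dt / 2, lon + k2x * dt / 2, lat + k2y * dt / 2, depth)
    k4x, k4y = _deg_rates(field, t_s + dt, lon + k3x * dt, lat + k3y * dt, depth)
    new_lon = lon + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    new_lat = lat + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)

    # A NaN stage means an RK sample left the grid: the particle exits.
    exited = ~np.isfinite(new_lon) | ~np.isfinite(new_lat)
    exited |= ~field.in_domain(np.where(exited, lon, new_lon),
                               np.where(exited, lat, new_lat))
    new_lon = np.where(exited, lon, new_lon)
    new_lat = np.where(exited, lat, new_lat)

    beached = field.is_land(new_lon, new_lat) & ~exited
    new_lon = np.where(beached, lon, new_lon)
    new_lat = np.where(beached, lat, new_lat)

    # Diel vertical migration at 0.1 BL/s, clamped to the band
    shallow, deep = dvm_band
    target = np.asarray(
        diel_target_depth(t, np.atleast_1d(new_lon), np.atleast_1d(new_lat), dvm_band),
        dtype=float,
    )
    vspeed = SWIM_BL_PER_S * length / 1000.0  # m/s; length in mm
    dz = np.clip(target - depth, -vspeed * dt, vspeed * dt)
    new_depth = np.clip(depth + dz, shallow, deep)

    return new_lon, new_lat, new_depth, exited, beached


def advect_step(p: ParticleState, field: FlowField, t, dt: float) -> ParticleState:
    """Advance a single active particle by one time step of ``dt`` seconds."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if p.status != "active":
        raise ValueError(f"particle {p.id} is not active")
    t = pd.Timestamp(t)

    lon = np.array([p.lon]); lat = np.array([p.lat])
    depth = np.array([p.depth]); length = np.array([p.length])
    new_lon, new_lat, new_depth, exited, beached = _step_arrays(
        field, t, dt, lon, lat, depth, length
    )
    new_age = p.age + dt / 86400.0
    status = "exited" if exited[0] else ("beached" if beached[0] else "active")
    return replace(
        p,
        lon=float(new_lon[0]), lat=float(new_lat[0]), depth=float(new_depth[0]),
        age=new_age, length=HATCH_LENGTH_MM + GROWTH_MM_PER_DAY * new_age,
        status=status,
    )


# --------------------------------------------------------------------------- #
# Simulation driver
# --------------------------------------------------------------------------- #

def run_simulation(
    config: ReleaseConfig,
    field: FlowField,
    end_date,
    dt: float = 3600.0,
    snapshot_every: float = 86400.0,
) -> SimulationResult:
    """Run the drift model from the hatch-window start to ``end_date``.

    Each particle starts moving at its hatch time; until then it sits at its
    release point with zero age. Snapshots of every particle are stored at
    the requested cadence (default daily). The particle budget
    (active + beached + exited = released) holds at every snapshot.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    start, _ = config.window
    end = pd.Timestamp(end_date)
    if field.time[-1] < start:
        raise ValueError("flow field ends before the hatch window starts")
    if end < start:
        raise ValueError("end_date precedes the hatch window")

    ens = release_particles(config)
    hatch_s = (ens.hatch_time.asi8 - pd.Timestamp(start).value) / 1e9

    def snapshot(now: pd.Timestamp) -> pd.DataFrame:
        df = ens.to_dataframe()
        df.insert(0, "time", now)
        return df

    times = [start]
    snaps = [snapshot(start)]
    n_steps = int(np.ceil((end - start) / pd.Timedelta(seconds=dt)))
    next_snap = snapshot_every

    t = start
    for k in range(n_steps):
        elapsed = k * dt
        step = min(dt, (end - t) / pd.Timedelta(seconds=1))
        moving = (ens.status == _ACTIVE) & (hatch_s <= elapsed)
        if moving.any():
            idx = np.flatnonzero(moving)
            new_lon, new_lat, new_depth, exited, beached = _step_arrays(
                field, t, step,
                ens.lon[idx], ens.lat[idx], ens.depth[idx], ens.length[idx],
            )
            ens.lon[idx] = new_lon
            ens.lat[idx] = new_lat
            ens.depth[idx] = new_depth
            ens.status[idx[exited]] = _EXITED
            ens.status[idx[beached]] = _BEACHED
        t = t + pd.Timedelta(seconds=step)
        elapsed_end = elapsed + step
        # Age/length accrue from each particle's own hatch time.
        hatched = hatch_s <= elapsed_end
        ens.age[hatched] = (elapsed_end - hatch_s[hatched]) / 86400.0
        ens.length[hatched] = HATCH_LENGTH_MM + GROWTH_MM_PER_DAY * ens.age[hatched]
        if elapsed_end + 1e-9 >= next_snap or k == n_steps - 1:
            times.append(t)
            snaps.append(snapshot(t))
            next_snap += snapshot_every

    meta = {
        "dt": dt, "seed": config.rng_seed, "config_digest": config.digest(),
        "start": str(start), "end": str(end), "n_particles": len(ens),
    }
    return SimulationResult(snapshot_times=times, snapshots=snaps, metadata=meta)


def density_grid(result: SimulationResult, date, lon_edges, lat_edges,
                 transform: str = "raw") -> DensityGrid:
    """Bin active particles at a snapshot into a lon/lat grid.

    Cells are half-open (lower edge inclusive) except the last, following
    ``numpy.histogram2d``. The raw count total equals the number of active
    in-grid particles at the snapshot.
    """
    snap = result.at(date)
    act = snap[snap["status"] == "active"]
    counts, _, _ = np.histogram2d(
        act["lat"].to_numpy(), act["lon"].to_numpy(),
        bins=[np.asarray(lat_edges, dtype=float), np.asarray(lon_edges, dtype=float)],
    )
    return DensityGrid(
        lon_edges=np.asarray(lon_edges, dtype=float),
        lat_edges=np.asarray(lat_edges, dtype=float),
        counts=counts.astype(np.int64), transform=transform,
    )
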