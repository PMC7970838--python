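"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators make the whole pipeline runnable offline:

* :func:`gen_flow_field` — an idealised northward coastal jet (cross-shore
  Gaussian profile, core speed in the 0.15-0.40 m/s band typical of the
  Norwegian Coastal Current, capped at 1.0 m/s) with optional
  streamfunction-derived eddies and a land mask along a straight coastline.
  The construction is divergence-free on the grid by design.
* :func:`gen_droplet_data` — droplet partitioning of template at a known
  concentration, either directly from the binomial partition law or by
  placing individual molecules into droplets (the brute-force oracle).
* :func:`gen_stomach_survey` — a two-year, multi-station stomach survey:
  lognormal station effects on the gene-copy signal, fish- and
  replicate-level lognormal noise, empty stomachs with optional residual
  signal, droplet counts produced through the inverse of the quantification
  chain, visual counts with saturating detection, and plankton/trawl station
  tables spanning the observed density ranges.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ddpcr import (
    EMPTY_STOMACH_TISSUE_G,
    DropletReaction,
    StomachRecord,
    SubsampleRecord,
)
from .errors import ConfigurationError
from .flowfield import EARTH_RADIUS_M, FlowField
from .surveys import PlanktonStation, TrawlStation, VisualRecord
from . import tables

__all__ = [
    "ScenarioConfig",
    "SurveyData",
    "gen_flow_field",
    "gen_droplet_data",
    "gen_stomach_survey",
    "discrete_divergence",
]


# --------------------------------------------------------------------------- #
# Flow field
# --------------------------------------------------------------------------- #

def gen_flow_field(
    *,
    lon_min: float = 2.0,
    lon_max: float = 16.0,
    lat_min: float = 62.0,
    lat_max: float = 72.0,
    dlon: float = 0.25,
    dlat: float = 0.125,
    depths=(0.0, 10.0, 20.0, 30.0, 50.0),
    start: str = "2017-03-15",
    n_days: int = 100,
    jet_speed: float = 0.3,
    jet_center_lon: float = 8.0,
    jet_width_deg: float = 1.5,
    eddy_amplitude: float = 0.0,
    n_eddies: int = 3,
    eddy_radius_deg: float = 1.0,
    coast_lon: float = 13.0,
    max_speed: float = 1.0,
    seed: int = 0,
) -> FlowField:
    """Build a northward coastal-jet flow field on a regular grid.

    The jet is northward with a Gaussian cross-shore profile centred at
    ``jet_center_lon``; its core speed must stay below ``max_speed``.
    Optional eddies come from Gaussian streamfunctions differentiated with
    centred finite differences on a fixed-latitude metric, so the discrete
    horizontal divergence vanishes identically in the interior. Cells east
    of ``coast_lon`` are land with zero velocity.
    """
    if jet_speed > max_speed:
        raise ConfigurationError(
            f"jet core speed {jet_speed} m/s exceeds the {max_speed} m/s cap"
        )
    rng = np.random.default_rng(seed)
    lon = np.arange(lon_min, lon_max + dlon / 2, dlon)
    lat = np.arange(lat_min, lat_max + dlat / 2, dlat)
    depth = np.asarray(depths, dtype=float)
    time = pd.date_range(start, periods=n_days, freq="D")
    ny, nx = lat.size, lon.size

    v2d = jet_speed * np.exp(-(((lon - jet_center_lon) / jet_width_deg) ** 2))
    v2d = np.broadcast_to(v2d, (ny, nx)).copy()
    u2d = np.zeros((ny, nx))

    if eddy_amplitude > 0 and n_eddies > 0:
        lat_ref = 0.5 * (lat_min + lat_max)
        dx = np.deg2rad(dlon) * EARTH_RADIUS_M * np.cos(np.deg2rad(lat_ref))
        dy = np.deg2rad(dlat) * EARTH_RADIUS_M
        lon_g, lat_g = np.meshgrid(lon, lat)
        psi = np.zeros((ny, nx))
        for _ in range(n_eddies):
            c_lon = rng.uniform(lon_min + 2, min(coast_lon, lon_max) - 2)
            c_lat = rng.uniform(lat_min + 1, lat_max - 1)
            sign = rng.choice([-1.0, 1.0])
            r2 = ((lon_g - c_lon) / eddy_radius_deg) ** 2 + (
                (lat_g - c_lat) / eddy_radius_deg
            ) ** 2
            # Peak swirl of a Gaussian streamfunction is A e^{-1/2} / sigma
            sigma_m = np.deg2rad(eddy_radius_deg) * EARTH_RADIUS_M
            amp = sign * eddy_amplitude * sigma_m * np.sqrt(np.e)
            psi += amp * np.exp(-r2 / 2.0)
        ue = np.zeros_like(psi)
        ve = np.zeros_like(psi)
        ue[1:-1, :] = -(psi[2:, :] - psi[:-2, :]) / (2 * dy)
        ve[:, 1:-1] = (psi[:, 2:] - psi[:, :-2]) / (2 * dx)
        u2d += ue
        v2d += ve

    speed = np.hypot(u2d, v2d)
    if speed.max() > max_speed:
        # Shrink the (linear, divergence-free) eddy part until the cap holds
        excess = speed.max() / max_speed
        u2d /= excess
        v2d /= excess

    mask = np.broadcast_to(lon >= coast_lon, (ny, nx)).copy()
    u2d[mask] = 0.0
    v2d[mask] = 0.0

    u = np.broadcast_to(u2d, (time.size, depth.size, ny, nx)).copy()
    v = np.broadcast_to(v2d, (time.size, depth.size, ny, nx)).copy()
    return FlowField(lon=lon, lat=lat, depth=depth, time=time.values,
                     u=u, v=v, land_mask=mask, max_speed=max_speed)


def discrete_divergence(field: FlowField, t_index: int = 0, z_index: int = 0) -> np.ndarray:
    """Centred-difference horizontal divergence (s^-1) on the fixed-latitude
    metric used by :func:`gen_flow_field`; NaN where the stencil touches land
    or the boundary."""
    u = field.u[t_index, z_index]
    v = field.v[t_index, z_index]
    lat_ref = 0.5 * (field.lat[0] + field.lat[-1])
    dx = np.deg2rad(field.lon[1] - field.lon[0]) * EARTH_RADIUS_M * np.cos(np.deg2rad(lat_ref))
    dy = np.deg2rad(field.lat[1] - field.lat[0]) * EARTH_RADIUS_M
    div = np.full_like(u, np.nan)
    div[1:-1, 1:-1] = (u[1:-1, 2:] - u[1:-1, :-2]) / (2 * dx) + (
        v[2:, 1:-1] - v[:-2, 1:-1]
    ) / (2 * dy)
    wet = ~field.land_mask
    stencil_wet = np.zeros_like(wet)
    stencil_wet[1:-1, 1:-1] = (
        wet[1:-1, 1:-1] & wet[1:-1, 2:] & wet[1:-1, :-2] & wet[2:, 1:-1] & wet[:-2, 1:-1]
    )
    div[~stencil_wet] = np.nan
    return div


# --------------------------------------------------------------------------- #
# Droplet data
# --------------------------------------------------------------------------- #

def gen_droplet_data(
    true_conc: float,
    n_droplets: int,
    *,
    v_droplet: float = 0.85e-3,
    rng=None,
    seed: int | None = None,
    mode: str = "binomial",
    molecules: str = "poisson",
    well: str = "W1",
    stomach: str = "S1",
    replicate: int = 1,
    dilution: float = 1.0,
) -> DropletReaction:
    """Simulate one ddPCR well at a known template concentration.

    ``true_conc`` is in copies per uL of reaction, so the mean occupancy is
    ``lambda = true_conc * v_droplet`` copies per droplet.

    mode="binomial" draws the positive count directly from the partition
    law: each droplet is positive independently with probability
    ``1 - exp(-lambda)``. mode="multinomial" is the brute-force oracle: it
    places individual molecules uniformly at random into droplets and counts
    occupied droplets. With ``molecules="poisson"`` the molecule count is
    Poisson(lambda * n) — exactly the independent-Poisson partition model,
    so the two modes agree in distribution; ``molecules="fixed"`` uses a
    deterministic round(lambda * n) count (underdispersed; kept for
    sensitivity analysis).
    """
    if true_conc < 0 or n_droplets <= 0 or v_droplet <= 0:
        raise ValueError("true_conc must be >= 0 and n_droplets, v_droplet positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    lam = true_conc * v_droplet

    if mode == "binomial":
        p = -np.expm1(-lam)
        n_pos = int(rng.binomial(n_droplets, p)) if lam > 0 else 0
    elif mode == "multinomial":
        if molecules == "poisson":
            m = int(rng.poisson(lam * n_droplets))
        elif molecules == "fixed":
            m = int(round(lam * n_droplets))
        else:
            raise ValueError(f"unknown molecules policy {molecules!r}")
        n_pos = np.unique(rng.integers(0, n_droplets, size=m)).size if m else 0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return DropletReaction(
        well=well, stomach=stomach, replicate=replicate,
        n_total=n_droplets, n_positive=n_pos,
        dilution=dilution, v_droplet=v_droplet,
    )


# --------------------------------------------------------------------------- #
# Stomach survey
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for the synthetic stomach survey.

    Sizes mirror the field campaign: two June cruises (2017 with 11
    stations, 2018 with 9), up to ten randomly selected mackerel per trawl,
    five replicate subsamples per stomach. Gene-copy signal is lognormal:
    a per-station mean on the log10 scale, fish-level scatter of 0.5 and
    replicate-level scatter of 0.2 log10 units (conventions — the field data
    report only that variability was high). The base level of ~10^6.5
    copies/g sits inside the observed range (below detection to ~4x10^10).
    """

    rng_seed: int = 0
    years: tuple = (2017, 2018)
    stations_per_year: tuple = (11, 9)
    fish_per_station: int = 10
    replicates_per_stomach: int = 5
    base_log10_copies: float = 6.5
    station_sd_log10: float = 0.5
    fish_sd_log10: float = 0.5
    replicate_sd_log10: float = 0.2
    station_effects: tuple | None = None  # explicit per-station log10 offsets
    empty_prob: float = 0.07
    empty_residual_factor: float = 1e-3
    droplets_low: int = 15_000
    droplets_high: int = 20_000
    v_droplet: float = 0.85e-3
    v_elution: float = 150.0
    pbs_ratio: float = 3.0
    mean_wet_weight: float = 0.2
    visual_max_mean: float = 4.0
    visual_half_saturation: float = 1.0e8
    trawl_density_range: tuple = (39.0, 13_230.0)
    effective_width_nm: float = 0.01
    tow_distance_nm: float = 2.0
    patch_density_per10m3: float = 60.0

    def __post_init__(self):
        if not 0.0 <= self.empty_prob <= 1.0:
            raise ConfigurationError("empty_prob must be in [0, 1]")
        for name in ("station_sd_log10", "fish_sd_log10", "replicate_sd_log10"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if len(self.years) != len(self.stations_per_year):
            raise ConfigurationError("years and stations_per_year must align")


@dataclass
class SurveyData:
    """All generated tables plus the ground truth behind them."""

    stomachs: list
    subsamples: list
    reactions: list
    visual: list
    plankton: list
    trawl: list
    truth: pd.DataFrame  # per-stomach true copies/g and station effects

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables.write_stomachs(self.stomachs, out / "stomachs.csv")
        tables.write_subsamples(self.subsamples, out / "subsamples.csv")
        tables.write_droplets(self.reactions, out / "droplets.csv")
        tables.write_visual(self.visual, out / "visual.csv")
        tables.write_plankton(self.plankton, out / "plankton.csv")
        tables.write_trawl(self.trawl, out / "trawl.csv")
        self.truth.to_csv(out / "truth.csv", index=False)


_DILUTIONS = (1.0, 10.0, 40.0, 100.0)


def _pick_dilution(conc_at_dilution1: float, v_droplet: float) -> float:
    """Smallest protocol dilution keeping droplet occupancy out of saturation."""
    for d in _DILUTIONS:
        lam = conc_at_dilution1 / d * v_droplet
        if lam <= 1.5:
            return d
    return _DILUTIONS[-1]


def _station_labels(n_total: int):
    from string import ascii_uppercase

    labels = list(ascii_uppercase)
    while len(labels) < n_total:
        labels += [a + b for a in ascii_uppercase for b in ascii_uppercase]
    return labels[:n_total]


def gen_stomach_survey(cfg: ScenarioConfig = ScenarioConfig()) -> SurveyData:
    """Generate the full two-year survey: stomach, droplet and station tables.

    Droplet counts are produced through the inverse of the quantification
    chain, so feeding the tables to the ddPCR stage recovers the configured
    per-station signal. The ``truth`` table carries per-stomach true
    copies/g and per-station effects for parameter-recovery checks.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    labels = _station_labels(sum(cfg.stations_per_year))

    stomachs, subsamples, reactions, visual = [], [], [], []
    plankton, trawl, truth_rows = [], [], []

    v_react, v_templ = 22.0, 5.5
    station_idx = 0
    for year, n_stations in zip(cfg.years, cfg.stations_per_year):
        # Stations strung south-to-north along the coast
        lats = np.linspace(66.0, 71.5, n_stations)
        lons = np.linspace(8.0, 12.0, n_stations)
        if cfg.station_effects is not None:
            effects = np.asarray(cfg.station_effects, dtype=float)[:n_stations]
        else:
            effects = rng.normal(0.0, cfg.station_sd_log10, size=n_stations)

        dens_lo, dens_hi = cfg.trawl_density_range
        patch_station = rng.integers(0, n_stations)
        for s in range(n_stations):
            st = labels[station_idx]
            station_idx += 1
            date = f"{year}-06-{10 + s % 15:02d}"

            # --- plankton haul -------------------------------------------- #
            log_d = rng.normal(0.3, 0.7)
            density = 10.0 ** log_d
            if s == patch_station:
                density = max(density, cfg.patch_density_per10m3 * rng.uniform(1.0, 1.5))
            volume = rng.uniform(150.0, 400.0)
            count = int(rng.poisson(density * volume / 10.0))
            plankton.append(PlanktonStation(st, lons[s], lats[s], date, count, volume))

            # --- trawl haul ----------------------------------------------- #
            swept_density = 10.0 ** rng.uniform(np.log10(dens_lo), np.log10(dens_hi))
            catch = swept_density * cfg.tow_distance_nm * cfg.effective_width_nm
            trawl.append(TrawlStation(st, lons[s], lats[s], date, catch,
                                      cfg.tow_distance_nm, cfg.effective_width_nm))

            # --- fish at this station ------------------------------------- #
            mu_station = cfg.base_log10_copies + effects[s]
            for f in range(cfg.fish_per_station):
                sid = f"{year}-{st}-{f + 1:02d}"
                fish_weight = float(np.clip(rng.normal(420.0, 60.0), 200.0, None))
                is_empty = bool(rng.uniform() < cfg.empty_prob)
                true_fish = 10.0 ** rng.normal(mu_station, cfg.fish_sd_log10)
                if is_empty:
                    true_fish *= cfg.empty_residual_factor
                    content_weight = EMPTY_STOMACH_TISSUE_G
                else:
                    content_weight = float(np.clip(rng.normal(8.0, 3.0), 0.5, None))
                stomachs.append(StomachRecord(sid, st, year, fish_weight,
                                              content_weight, is_empty))

                rep_truths = []
                for rep in range(1, cfg.replicates_per_stomach + 1):
                    wet = float(np.clip(rng.normal(cfg.mean_wet_weight, 0.02), 0.05, None))
                    sub = SubsampleRecord(sid, rep, wet, cfg.pbs_ratio, cfg.v_elution)
                    subsamples.append(sub)

                    rep_value = true_fish * 10.0 ** rng.normal(0.0, cfg.replicate_sd_log10)
                    tissue = EMPTY_STOMACH_TISSUE_G if is_empty else sub.tissue_g
                    # invert: copies/g -> copies/uL reaction at dilution 1
                    conc1 = rep_value * tissue / (cfg.v_elution * (v_react / v_templ))
                    dil = _pick_dilution(conc1, cfg.v_droplet)
                    n_drop = int(rng.integers(cfg.droplets_low, cfg.droplets_high + 1))
                    rxn = gen_droplet_data(
                        conc1 / dil, n_drop, v_droplet=cfg.v_droplet, rng=rng,
                        well=f"{sid}-r{rep}", stomach=sid, replicate=rep, dilution=dil,
                    )
                    reactions.append(rxn)
                    rep_truths.append(rep_value)

                # ground truth: the fish-level signal and the DNA actually
                # present in the drawn subsamples (what the assay measures)
                truth_rows.append({
                    "stomach": sid, "station": st, "year": year,
                    "true_copies_per_g": true_fish,
                    "true_measured_copies_per_g": float(np.mean(rep_truths)),
                    "station_effect_log10": effects[s],
                })

                # visual counts saturate with the true signal
                mean_l = cfg.visual_max_mean * true_fish / (true_fish + cfg.visual_half_saturation)
                larvae = int(rng.poisson(mean_l))
                otoliths = int(rng.poisson(0.3 * mean_l))
                visual.append(VisualRecord(st, sid, larvae, otoliths))

    return SurveyData(
        stomachs=stomachs, subsamples=subsamples, reactions=reactions,
        visual=visual, plankton=plankton, trawl=trawl,
        truth=pd.DataFrame(truth_rows),
    )
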