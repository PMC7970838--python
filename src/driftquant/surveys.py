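"""Survey statistics linking predator distribution, larval density and the
molecular predation signal.

Covers the field-data arithmetic and tests of the stomach-survey analysis:

* larval density from plankton hauls (individuals per 10 m^3 filtered water);
* mackerel biomass density from trawl hauls as a swept-area estimate
  (catch weight / (tow distance x effective gear width), kg per NM^2);
* one-way ANOVA with Tukey HSD post-hoc tests on log10(copies + 1) gene-copy
  values across stations, with residual diagnostics;
* Pearson correlations between gene copies and predator covariates
  (fish weight, stomach-content weight);
* the visual-vs-molecular comparison with hat-matrix leverage diagnostics,
  since a single extreme station can dominate that regression;
* a per-station overlap table with an optional Schoener's D index.

Outliers are diagnosed (leverage, studentized residuals) but never dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "PlanktonStation",
    "TrawlStation",
    "VisualRecord",
    "StationTestResult",
    "CorrelationResult",
    "larval_density",
    "swept_area_density",
    "log_copies",
    "station_anova",
    "tukey_hsd",
    "pearson_predictor_cor",
    "leverage",
    "visual_vs_molecular",
    "schoeners_d",
    "overlap_summary",
]


@dataclass(frozen=True)
class PlanktonStation:
    """One plankton haul with its flowmeter-derived filtered volume."""

    station: str
    lon: float
    lat: float
    date: str
    larval_count: int
    filtered_volume: float  # m^3

    def __post_init__(self):
        if self.filtered_volume <= 0:
            raise ValueError(f"station {self.station}: filtered_volume must be > 0")
        if self.larval_count < 0:
            raise ValueError(f"station {self.station}: larval_count must be >= 0")


@dataclass(frozen=True)
class TrawlStation:
    """One pelagic trawl haul with swept-area geometry."""

    station: str
    lon: float
    lat: float
    date: str
    catch_weight: float      # kg
    tow_distance: float      # nautical miles
    effective_width: float   # nautical miles

    def __post_init__(self):
        if self.tow_distance <= 0 or self.effective_width <= 0:
            raise ValueError(f"station {self.station}: tow geometry must be positive")
        if self.catch_weight < 0:
            raise ValueError(f"station {self.station}: catch_weight must be >= 0")


@dataclass(frozen=True)
class VisualRecord:
    """Stereomicroscope counts of larvae and otoliths in one stomach."""

    station: str
    stomach: str
    larvae_seen: int
    otoliths_seen: int

    def __post_init__(self):
        if self.larvae_seen < 0 or self.otoliths_seen < 0:
            raise ValueError("visual counts must be >= 0")


@dataclass
class StationTestResult:
    """One-way ANOVA across stations with Tukey HSD post-hoc matrix."""

    F: float
    df_between: int
    df_within: int
    p: float
    tukey_p: pd.DataFrame
    year: int | None = None
    diagnostics: dict = field(default_factory=dict)


@dataclass
class CorrelationResult:
    """Pearson correlation with its t statistic and df = n - 2."""

    r: float
    t: float
    df: int
    p: float
    predictor: str = ""


def larval_density(st: PlanktonStation) -> float:
    """Larval density in individuals per 10 m^3 of filtered water."""
    return 10.0 * st.larval_count / st.filtered_volume


def swept_area_density(st: TrawlStation) -> float:
    """Swept-area biomass density in kg per square nautical mile."""
    return st.catch_weight / (st.tow_distance * st.effective_width)


def log_copies(values) -> np.ndarray:
    """The analysis response scale: log10(copies + 1), defined at zero."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise DataError("gene-copy values must be >= 0")
    return np.log10(v + 1.0)


def tukey_hsd(groups: dict) -> pd.DataFrame:
    """Tukey HSD (Tukey-Kramer for unbalanced groups) pairwise p-values.

    Exact studentized-range tail probabilities; returns a symmetric matrix
    with NaN on the diagonal.
    """
    labels = list(groups)
    k = len(labels)
    ns = np.array([len(groups[g]) for g in labels], dtype=float)
    means = np.array([np.mean(groups[g]) for g in labels])
    df_within = int(ns.sum()) - k
    mse = sum(np.sum((np.asarray(groups[g]) - m) ** 2) for g, m in zip(labels, means)) / df_within

    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = np.abs(means[i] - means[j]) / se if se > 0 else np.inf
            pv = float(stats.studentized_range.sf(q, k, df_within))
            p[i, j] = p[j, i] = min(max(pv, 0.0), 1.0)
    return pd.DataFrame(p, index=labels, columns=labels)


def station_anova(copies, stations, *, year: int | None = None) -> StationTestResult:
    """One-way ANOVA of log10(copies + 1) across sampling stations.

    Stations with fewer than two stomachs are excluded with a warning.
    Attaches Tukey HSD pairwise p-values and residual diagnostics
    (Shapiro-Wilk normality, Levene homoscedasticity).
    """
    y = log_copies(copies)
    s = np.asarray(stations)
    if y.shape != s.shape:
        raise ValueError("copies and stations must align")

    groups: dict[str, np.ndarray] = {}
    for g in pd.unique(s):
        vals = y[s == g]
        if len(vals) < 2:
            warnings.warn(f"station {g!r} has fewer than 2 stomachs; excluded from ANOVA")
            continue
        groups[g] = vals
    if len(groups) < 2:
        raise DataError("ANOVA needs at least 2 stations with >= 2 stomachs each")
    if np.ptp(np.concatenate(list(groups.values()))) == 0:
        raise DataError("all responses identical; F is undefined")

    k = len(groups)
    n = sum(len(v) for v in groups.values())
    F, p = stats.f_oneway(*groups.values())

    resid = np.concatenate([v - v.mean() for v in groups.values()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shapiro_p = float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else np.nan
        levene_p = float(stats.levene(*groups.values()).pvalue)

    return StationTestResult(
        F=float(F), df_between=k - 1, df_within=n - k, p=float(p),
        tukey_p=tukey_hsd(groups), year=year,
        diagnostics={"shapiro_p": shapiro_p, "levene_p": levene_p,
                     "n": n, "k": k},
    )


def simulate_anova_rejection_rate(
    *,
    n_sims: int,
    k: int = 10,
    n_per: int = 8,
    station_sd: float = 0.0,
    noise_sd: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo rejection rate of the one-way station ANOVA.

    Responses are already on the log scale: per-station effects are drawn
    N(0, station_sd) and per-fish noise N(0, noise_sd), mirroring the
    lognormal gene-copy model. With ``station_sd = 0`` this estimates the
    type-I error; with a positive spread it estimates power. Fully
    vectorised, so thousands of simulated surveys run in milliseconds.
    """
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, station_sd, size=(n_sims, k, 1)) if station_sd > 0 else 0.0
    y = mu + rng.normal(0.0, noise_sd, size=(n_sims, k, n_per))
    gmean = y.mean(axis=2)
    grand = y.mean(axis=(1, 2))
    ssb = n_per * ((gmean - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((y - gmean[:, :, None]) ** 2).sum(axis=(1, 2))
    df_b, df_w = k - 1, k * n_per - k
    F = (ssb / df_b) / (ssw / df_w)
    p = stats.f.sf(F, df_b, df_w)
    return float((p < alpha).mean())


def pearson_predictor_cor(copies, predictor, label: str = "") -> CorrelationResult:
    """Pearson correlation of gene copies against a predator covariate."""
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(copies, dtype=float)
    if x.size != y.size:
        raise ValueError("copies and predictor must align")
    if x.size < 3:
        raise DataError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise DataError("predictor is constant; correlation undefined")
    r, p = stats.pearsonr(x, y)
    df = x.size - 2
    denom = np.sqrt(max(1.0 - r * r, np.finfo(float).tiny))
    t = r * np.sqrt(df) / denom
    return CorrelationResult(r=float(r), t=float(t), df=df, p=float(p), predictor=label)


def leverage(x) -> np.ndarray:
    """Hat-matrix diagonal for simple regression on ``x``:
    h_i = 1/n + (x_i - xbar)^2 / sum_j (x_j - xbar)^2. Sums to 2."""
    x = np.asarray(x, dtype=float)
    n = x.size
    d = x - x.mean()
    ss = np.sum(d * d)
    if ss == 0:
        raise DataError("predictor is constant; leverage undefined")
    return 1.0 / n + d * d / ss


def visual_vs_molecular(visual: list, copies_by_stomach: dict,
                        *, leverage_factor: float = 2.0) -> dict:
    """Compare visual prey counts with the molecular signal per stomach.

    Correlates gene copies against larvae seen, otoliths seen, and their
    pooled sum, and attaches hat-matrix leverage for the pooled simple
    regression; points with h_i above ``leverage_factor * 2/n`` are flagged
    as high-leverage (they can single-handedly steer the fitted line).
    """
    rows = [
        (v.station, v.stomach, v.larvae_seen, v.otoliths_seen,
         copies_by_stomach[v.stomach])
        for v in visual if v.stomach in copies_by_stomach
    ]
    if not rows:
        raise DataError("no stomachs joinable between visual records and copy results")
    df = pd.DataFrame(rows, columns=["station", "stomach", "larvae", "otoliths", "copies"])
    df["pooled"] = df["larvae"] + df["otoliths"]

    correlations = {}
    for col in ("larvae", "otoliths", "pooled"):
        try:
            correlations[col] = pearson_predictor_cor(df["copies"], df[col], label=col)
        except DataError:
            correlations[col] = None

    h = leverage(df["pooled"].to_numpy())
    cutoff = leverage_factor * 2.0 / len(df)
    df["leverage"] = h
    df["high_leverage"] = h > cutoff
    return {"table": df, "correlations": correlations, "leverage_cutoff": cutoff}


def schoeners_d(p, q) -> float:
    """Schoener's overlap index D = 1 - 0.5 * sum |p_i - q_i| between two
    distributions, each normalised to sum 1. D = 0 disjoint, D = 1 identical."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise ValueError("distributions must share a grid")
    ps, qs = p.sum(), q.sum()
    if ps <= 0 or qs <= 0:
        raise DataError("distributions must have positive mass")
    return float(1.0 - 0.5 * np.abs(p / ps - q / qs).sum())


def overlap_summary(larval: dict, mackerel: dict, copies: dict) -> pd.DataFrame:
    """Per-station table of larval density, predator biomass and mean copies.

    Inputs map station id to larval density (per 10 m^3), swept-area biomass
    (kg NM^-2) and mean gene copies per gram. Stations present in any input
    appear; missing entries are NaN. Raises if no station is shared by at
    least two inputs.
    """
    keys = sorted(set(larval) | set(mackerel) | set(copies))
    shared = (set(larval) & set(mackerel)) | (set(larval) & set(copies)) | (set(mackerel) & set(copies))
    if not shared:
        raise DataError("no common station keys across inputs")
    return pd.DataFrame(
        {
            "station": keys,
            "larval_density": [larval.get(k, np.nan) for k in keys],
            "mackerel_density": [mackerel.get(k, np.nan) for k in keys],
            "mean_copies_per_g": [copies.get(k, np.nan) for k in keys],
        }
    ).set_index("station")
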