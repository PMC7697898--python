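"""Per-cluster identification diagnostics and rule-based source labeling.

Each cluster of the polar solution is summarized by the diagnostics that
receptor-model practice uses to recognize source types: diurnal/weekly/
seasonal time variation, weekend-to-weekday ratio, fine-vs-coarse edge-line
slopes, least-squares dependence of contributions on wind speed /
temperature / relative humidity, polar geometry (sector coverage, whether
the cluster encloses the origin), and the apportionment of co-measured
gases (CO, NOx, NO2, SO2) across clusters.

The mapping from diagnostics to a source label is a transparent rule set:
every clause is a named, thresholded predicate collected in
:class:`RuleConfig`, scores are unweighted counts of fired clauses, and the
label is the argmax (ties broken by a fixed archetype priority), falling
back to ``unidentified`` below a score floor. Only the wood-smoke fine-
fraction cut (0.7) is anchored in receptor-model practice; every other
cut-point is a declared, overridable implementation choice. The relative-
humidity response of wood smoke is computed as a sign only and excluded
from default scoring (its magnitude is not established).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .polar_cluster import ClusterSolution, central_cluster_candidates, contribution_series
from .io_qc import PolarFeatures

ARCHETYPE_PRIORITY = ("rwb", "traffic", "aeolian", "industrial", "regional")


@dataclass
class MetDependence:
    slope: float
    correlation: float
    r2: float


@dataclass
class ClusterDiagnostics:
    """Computable rule metrics for one cluster (None = unavailable)."""

    diurnal_profile: np.ndarray | None = None  # 24 hourly means
    peak_hours: tuple[int, int] | None = None  # top-2 diurnal hours
    weekend_ratio: float | None = None
    cold_warm_ratio: float | None = None
    fine_coarse_upper: float | None = None
    fine_coarse_lower: float | None = None
    ws_slope: MetDependence | None = None
    temp_slope: MetDependence | None = None
    rh_slope: MetDependence | None = None
    sector_coverage: float | None = None
    hull_contains_origin: bool | None = None
    gas_shares: dict[str, float] = field(default_factory=dict)
    no2_nox_ratio: float | None = None
    low_ws_share: float | None = None  # contribution fraction below the calm cut


def time_variation(series: pd.Series) -> dict[str, pd.DataFrame]:
    """Diurnal, weekday (Monday-first) and monthly profiles with SEs."""
    idx = pd.DatetimeIndex(series.index)

    def strat(keys, domain):
        g = series.groupby(keys)
        mean = g.mean().reindex(domain)
        se = (g.std(ddof=1) / np.sqrt(g.count())).reindex(domain)
        return pd.DataFrame({"mean": mean, "se": se})

    return {
        "diurnal": strat(idx.hour, range(24)),
        "weekday": strat(idx.dayofweek, range(7)),
        "monthly": strat(idx.month, range(1, 13)),
    }


def weekend_ratio(series: pd.Series) -> float:
    """(Sat-Sun mean) / (Mon-Fri mean); NaN if a stratum is empty or the
    weekday mean is zero."""
    idx = pd.DatetimeIndex(series.index)
    weekend = idx.dayofweek >= 5
    if not weekend.any() or weekend.all():
        return float("nan")
    wk = series[~weekend].mean()
    if wk == 0:
        return float("nan")
    return float(series[weekend].mean() / wk)


def edge_slopes(
    pm25: pd.Series,
    pm10: pd.Series,
    tau_low: float = 0.05,
    tau_high: float = 0.95,
    pm10_floor: float = 5.0,
    min_pairs: int = 30,
) -> tuple[float, float] | None:
    """Lower/upper limiting edge-line slopes of the fine-vs-coarse scatter.

    Estimated as empirical quantiles of the per-hour PM2.5/PM10 ratio over
    pairs with PM10 at or above ``pm10_floor`` (ratio quantiles rather than
    regressions through the origin: monotone and robust). Returns None when
    fewer than ``min_pairs`` usable pairs exist.
    """
    pair = pd.DataFrame({"pm25": pm25, "pm10": pm10}).dropna()
    pair = pair[pair["pm10"] >= pm10_floor]
    if len(pair) < min_pairs:
        return None
    ratio = pair["pm25"] / pair["pm10"]
    return float(ratio.quantile(tau_low)), float(ratio.quantile(tau_high))


def met_dependence(series: pd.Series, met: pd.Series, min_pairs: int = 30) -> MetDependence | None:
    """OLS slope of contribution on a met variable, with Pearson r and r^2."""
    pair = pd.DataFrame({"y": series, "x": met}).dropna()
    if len(pair) < min_pairs or pair["x"].nunique() < 2:
        return None
    res = stats.linregress(pair["x"], pair["y"])
    return MetDependence(
        slope=float(res.slope),
        correlation=float(res.rvalue),
        r2=float(res.rvalue**2),
    )


def gas_apportionment(
    table: pd.DataFrame, solution: ClusterSolution, gases=("co", "nox", "no2", "so2")
) -> tuple[pd.DataFrame, pd.Series]:
    """Fraction of each gas's total mass falling in each cluster's hours,
    plus the within-cluster mean NO2 / mean NOx ratio.

    Shares per gas sum to 1 over clusters (retained, non-missing hours).
    An all-missing gas is omitted.
    """
    idx = solution.labels.index
    sub = table.set_index(pd.DatetimeIndex(table["timestamp"])).reindex(idx)
    shares = {}
    for gas in gases:
        if gas not in sub.columns or sub[gas].notna().sum() == 0:
            continue
        total = sub[gas].sum()
        if total == 0:
            continue
        shares[gas] = {
            cl: float(sub.loc[solution.labels == cl, gas].sum() / total)
            for cl in range(1, solution.k + 1)
        }
    share_df = pd.DataFrame(shares)
    share_df.index.name = "cluster"

    no2_nox = {}
    for cl in range(1, solution.k + 1):
        rows = sub.loc[solution.labels == cl]
        if "no2" in rows and "nox" in rows and rows["nox"].mean():
            no2_nox[cl] = float(rows["no2"].mean() / rows["nox"].mean())
        else:
            no2_nox[cl] = float("nan")
    return share_df, pd.Series(no2_nox, name="no2_nox_ratio")


def _cold_warm_months(table: pd.DataFrame) -> tuple[list[int], list[int]]:
    """4 coldest and 4 warmest calendar months from the input's own
    temperature climatology (hemisphere-agnostic)."""
    idx = pd.DatetimeIndex(table["timestamp"])
    clim = table["temp"].groupby(idx.month).mean().sort_values()
    return list(clim.index[:4]), list(clim.index[-4:])


def compute_diagnostics(
    table: pd.DataFrame,
    solution: ClusterSolution,
    features: PolarFeatures,
    pollutant: str,
    low_ws_cut: float = 4.0,
) -> dict[int, ClusterDiagnostics]:
    """Assemble the full diagnostics panel for every cluster."""
    contrib = contribution_series(table, solution, pollutant)
    geometry = central_cluster_candidates(solution, features)
    gas_shares, no2_nox = gas_apportionment(table, solution)
    cold, warm = _cold_warm_months(table)

    sub = table.set_index(pd.DatetimeIndex(table["timestamp"])).reindex(contrib.index)
    months = contrib.index.month

    out: dict[int, ClusterDiagnostics] = {}
    for cl in range(1, solution.k + 1):
        series = contrib[cl]
        members = solution.labels.reindex(contrib.index) == cl
        d = ClusterDiagnostics()

        tv = time_variation(series)["diurnal"]["mean"]
        if tv.notna().all():
            d.diurnal_profile = tv.to_numpy()
            top2 = tv.sort_values(ascending=False).index[:2]
            d.peak_hours = (int(top2[0]), int(top2[1]))
        d.weekend_ratio = weekend_ratio(series)

        cold_mean = series[np.isin(months, cold)].mean()
        warm_mean = series[np.isin(months, warm)].mean()
        if warm_mean and not np.isnan(warm_mean):
            d.cold_warm_ratio = float(cold_mean / warm_mean)

        if {"pm25", "pm10"} <= set(sub.columns):
            edges = edge_slopes(sub.loc[members, "pm25"], sub.loc[members, "pm10"])
            if edges is not None:
                d.fine_coarse_lower, d.fine_coarse_upper = edges

        cluster_vals = series[members]
        for attr, col in (("ws_slope", "ws"), ("temp_slope", "temp"), ("rh_slope", "rh")):
            if col in sub.columns:
                setattr(d, attr, met_dependence(cluster_vals, sub.loc[members, col]))

        if cl in geometry.index:
            d.sector_coverage = float(geometry.loc[cl, "sector_coverage"])
            if not geometry.loc[cl, "hull_test_skipped"]:
                d.hull_contains_origin = bool(geometry.loc[cl, "hull_contains_origin"])

        if not gas_shares.empty and cl in gas_shares.index:
            d.gas_shares = {g: float(v) for g, v in gas_shares.loc[cl].dropna().items()}
        if cl in no2_nox.index and np.isfinite(no2_nox[cl]):
            d.no2_nox_ratio = float(no2_nox[cl])

        total = series.sum()
        if "ws" in sub.columns and total > 0:
            calm = sub["ws"] < low_ws_cut
            d.low_ws_share = float(series[calm.to_numpy()].sum() / total)
        out[cl] = d
    return out


@dataclass
class RuleConfig:
    """Every identification cut-point in one overridable block."""

    rwb_upper_edge_min: float = 0.7  # wood smoke is fine-dominated
    rwb_lower_edge_min: float = 0.5  # ... and single-source: narrow band
    rwb_cold_warm_min: float = 2.0
    rwb_peak_hours: tuple[int, ...] = (22, 23, 0, 1)  # near-midnight peak
    traffic_weekend_max: float = 0.85
    traffic_lower_edge_max: float = 0.3  # road-dust end member
    morning_rush: tuple[int, int] = (6, 10)
    evening_rush: tuple[int, int] = (16, 21)
    rush_peak_fraction: float = 0.75  # both rush maxima vs the global max
    steady_weekend_band: tuple[float, float] = (0.85, 1.15)
    confined_sector_max: float = 0.25
    aeolian_low_ws_share_max: float = 0.05
    aeolian_upper_edge_max: float = 0.5
    aeolian_lower_edge_max: float = 0.25
    regional_no2_nox_factor: float = 1.25  # vs the across-cluster median
    unidentified_floor: int = 2


@dataclass
class SourceLabelMap:
    """Cluster -> source label with scores and fired-clause rationale."""

    labels: dict[int, str]
    scores: dict[int, dict[str, int]]
    rationale: dict[int, list[str]]

    def merge_map(self) -> dict[int, str]:
        return dict(self.labels)


def _in_window(hour: int, window: tuple[int, int]) -> bool:
    lo, hi = window
    return lo <= hour <= hi if lo <= hi else hour >= lo or hour <= hi


def classify_clusters(
    diagnostics: dict[int, ClusterDiagnostics],
    config: RuleConfig | None = None,
) -> SourceLabelMap:
    """Score every cluster against each archetype's rule clauses.

    Scores are unweighted clause counts; label = argmax (ties resolved by
    a fixed priority order), or ``unidentified`` when the best score falls
    below ``config.unidentified_floor``. Unavailable diagnostics simply
    fail their clauses; nothing crashes. Deterministic and invariant to
    cluster numbering.
    """
    cfg = config or RuleConfig()
    so2_by_cluster = {
        cl: d.gas_shares.get("so2") for cl, d in diagnostics.items()
    }
    so2_vals = [v for v in so2_by_cluster.values() if v is not None]
    max_so2 = max(so2_vals) if so2_vals else None
    nn_vals = [d.no2_nox_ratio for d in diagnostics.values() if d.no2_nox_ratio is not None]
    median_no2_nox = float(np.median(nn_vals)) if nn_vals else None
    k = max(len(diagnostics), 1)

    labels, scores, rationale = {}, {}, {}
    for cl, d in diagnostics.items():
        clauses: dict[str, list[tuple[str, bool]]] = {}

        clauses["rwb"] = [
            # single-source straight line: high fine fraction with BOTH
            # edges high (traffic's exhaust end member also reaches an
            # upper edge near 1:1, but its road-dust lower edge is small)
            (f"fine-dominated single-source band (upper >= {cfg.rwb_upper_edge_min}, "
             f"lower >= {cfg.rwb_lower_edge_min})",
             d.fine_coarse_upper is not None and d.fine_coarse_lower is not None
             and d.fine_coarse_upper >= cfg.rwb_upper_edge_min
             and d.fine_coarse_lower >= cfg.rwb_lower_edge_min),
            (f"cold/warm seasonality >= {cfg.rwb_cold_warm_min}",
             d.cold_warm_ratio is not None and d.cold_warm_ratio >= cfg.rwb_cold_warm_min),
            ("cluster hull encloses the origin", bool(d.hull_contains_origin)),
            ("negative temperature slope",
             d.temp_slope is not None and d.temp_slope.slope < 0),
            ("diurnal peak near midnight",
             d.peak_hours is not None and d.peak_hours[0] in cfg.rwb_peak_hours),
        ]
        # rule-2 double peak: both rush-window maxima near the global
        # diurnal maximum, which itself falls in a rush window
        rush_ok = False
        if d.diurnal_profile is not None:
            prof = np.asarray(d.diurnal_profile, float)
            top = float(prof.max())
            peak_hr = int(prof.argmax())
            morning = max(prof[h] for h in range(24) if _in_window(h, cfg.morning_rush))
            evening = max(prof[h] for h in range(24) if _in_window(h, cfg.evening_rush))
            rush_ok = (
                top > 0
                and min(morning, evening) >= cfg.rush_peak_fraction * top
                and (_in_window(peak_hr, cfg.morning_rush) or _in_window(peak_hr, cfg.evening_rush))
            )
        clauses["traffic"] = [
            (f"weekend ratio <= {cfg.traffic_weekend_max}",
             d.weekend_ratio is not None and d.weekend_ratio <= cfg.traffic_weekend_max),
            ("morning and evening rush-hour peaks", rush_ok),
            ("negative wind-speed slope",
             d.ws_slope is not None and d.ws_slope.slope < 0),
            (f"road-dust lower edge <= {cfg.traffic_lower_edge_max}",
             d.fine_coarse_lower is not None
             and d.fine_coarse_lower <= cfg.traffic_lower_edge_max),
        ]
        steady = (
            d.weekend_ratio is not None
            and cfg.steady_weekend_band[0] <= d.weekend_ratio <= cfg.steady_weekend_band[1]
        )
        confined = (
            d.sector_coverage is not None and d.sector_coverage <= cfg.confined_sector_max
        )
        clauses["industrial"] = [
            ("positive wind-speed slope (fumigation)",
             d.ws_slope is not None and d.ws_slope.slope > 0),
            ("confined direction sector", confined),
            ("largest SO2 share of all clusters",
             max_so2 is not None
             and so2_by_cluster[cl] is not None
             and so2_by_cluster[cl] >= max_so2),
            ("weekday-invariant (steady) contributions", steady),
        ]
        clauses["aeolian"] = [
            (f"contribution vanishes below the calm cut "
             f"(share <= {cfg.aeolian_low_ws_share_max})",
             d.low_ws_share is not None and d.low_ws_share <= cfg.aeolian_low_ws_share_max),
            ("positive wind-speed slope",
             d.ws_slope is not None and d.ws_slope.slope > 0),
            (f"coarse-dominated upper edge <= {cfg.aeolian_upper_edge_max}",
             d.fine_coarse_upper is not None
             and d.fine_coarse_upper <= cfg.aeolian_upper_edge_max),
            (f"coarse-dominated lower edge <= {cfg.aeolian_lower_edge_max}",
             d.fine_coarse_lower is not None
             and d.fine_coarse_lower <= cfg.aeolian_lower_edge_max),
        ]
        clauses["regional"] = [
            ("confined arrival sector", confined),
            ("weekday-invariant (steady) contributions", steady),
            ("persistent SO2 share (>= uniform share)",
             so2_by_cluster[cl] is not None and so2_by_cluster[cl] >= 1.0 / k),
            ("aged air: elevated NO2/NOx ratio",
             median_no2_nox is not None
             and d.no2_nox_ratio is not None
             and d.no2_nox_ratio >= cfg.regional_no2_nox_factor * median_no2_nox),
        ]

        clauses = {
            arch: [(text, bool(fired)) for text, fired in cl_list]
            for arch, cl_list in clauses.items()
        }
        score = {arch: sum(fired for _, fired in cl_list) for arch, cl_list in clauses.items()}
        best = max(ARCHETYPE_PRIORITY, key=lambda a: score[a])
        # ties resolve to the earliest archetype in the fixed priority order
        for arch in ARCHETYPE_PRIORITY:
            if score[arch] == score[best]:
                best = arch
                break
        label = best if score[best] >= cfg.unidentified_floor else "unidentified"
        labels[cl] = label
        scores[cl] = score
        rationale[cl] = [
            f"{arch}: {text}" for arch, cl_list in clauses.items() for text, fired in cl_list if fired
        ]
    return SourceLabelMap(labels=labels, scores=scores, rationale=rationale)
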