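"""Small built-in reference tables and default speciation profiles.

The two published comparison tables below (a wood-smoke-dominated
temperate city, winter 2014 weekly campaign; a large metropolitan site,
winter 2004 monthly averages) are used as worked-example inputs: the
package's table-building operations must recompute their printed footer
averages and seasonal totals exactly at printed precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .receptor_models import ProfileMatrix

#: Default species set for synthetic speciation fixtures (mass fractions).
DEFAULT_SPECIES = ["OC", "EC", "K", "Si", "Ca", "Fe", "SO4", "NO3"]

_DEFAULT_PROFILES = {
    # fractions of PM2.5 mass; rows sum to <= 1 (the rest is unspeciated)
    "traffic": [0.25, 0.20, 0.005, 0.08, 0.04, 0.06, 0.04, 0.05],
    "rwb": [0.52, 0.08, 0.040, 0.005, 0.005, 0.003, 0.02, 0.01],
    "industrial": [0.08, 0.04, 0.002, 0.02, 0.01, 0.10, 0.30, 0.02],
    "aeolian": [0.03, 0.01, 0.010, 0.25, 0.10, 0.08, 0.01, 0.005],
    "regional": [0.20, 0.03, 0.010, 0.01, 0.005, 0.005, 0.35, 0.10],
}


def default_profiles(
    sources: list[str], sigma_rel: float = 0.0
) -> ProfileMatrix:
    """Profile matrix for the named sources, optionally with relative
    per-entry uncertainties ``sigma_rel``."""
    F = pd.DataFrame(
        {s: _DEFAULT_PROFILES[s] for s in sources}, index=DEFAULT_SPECIES
    ).T
    sigma_f = F * sigma_rel if sigma_rel > 0 else None
    return ProfileMatrix(F=F, sigma_f=sigma_f)


def _stat_frame(index, data: dict[str, list[tuple[float, float]]]) -> pd.DataFrame:
    cols = {}
    for source, pairs in data.items():
        cols[(source, "mean")] = [m for m, _ in pairs]
        cols[(source, "se")] = [s for _, s in pairs]
    out = pd.DataFrame(cols, index=index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["source", "stat"])
    return out


def temuco_weekly_campaign() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Published 8-week winter 2014 weekly comparison (ug/m3): cluster-
    analysis vs chemical-mass-balance estimates for wood smoke (rwb) and
    traffic at the Temuco monitoring site. Returns (ca, rm) period frames."""
    weeks = [f"Week {i}" for i in range(1, 9)]
    ca = _stat_frame(
        weeks,
        {
            "rwb": [(35.3, 4.1), (64.3, 7.1), (15.2, 2.8), (47.9, 5.6),
                    (52.9, 6.6), (43.7, 4.4), (23.1, 4.2), (57.6, 9.0)],
            "traffic": [(0.9, 0.5), (0.5, 0.5), (3.2, 1.0), (0.0, 0.0),
                        (3.7, 1.1), (2.7, 1.0), (5.1, 1.1), (1.1, 0.3)],
        },
    )
    rm = _stat_frame(
        weeks,
        {
            "rwb": [(42.7, 5.9), (75.9, 7.1), (18.6, 5.0), (52.6, 6.3),
                    (56.9, 6.7), (42.8, 6.1), (23.5, 5.0), (48.6, 7.8)],
            "traffic": [(2.2, 0.2), (2.4, 0.5), (1.4, 0.1), (2.3, 0.2),
                        (2.6, 0.2), (2.5, 0.2), (1.5, 0.1), (2.8, 0.2)],
        },
    )
    return ca, rm


def santiago_monthly_by_cluster() -> pd.DataFrame:
    """Published monthly PM2.5 contributions (ug/m3) by cluster, Santiago
    Las Condes site, year 2004, for the eight-cluster solution."""
    data = np.array(
        [
            [2.1, 0.3, 10.4, 5.8, 0.0, 0.9, 0.0, 0.1],
            [2.7, 0.6, 11.4, 9.1, 0.0, 1.8, 0.0, 0.0],
            [1.8, 0.3, 11.0, 10.7, 0.0, 2.4, 0.0, 0.2],
            [1.7, 0.2, 5.8, 13.3, 0.02, 3.7, 0.7, 0.5],
            [0.4, 0.1, 5.7, 17.4, 0.0, 6.6, 6.5, 0.4],
            [0.1, 0.0, 4.0, 16.7, 0.0, 5.9, 4.5, 1.3],
            [0.0, 0.0, 3.1, 16.0, 0.0, 4.7, 3.9, 0.9],
            [0.2, 0.0, 4.7, 9.2, 0.0, 3.2, 6.8, 0.4],
            [0.4, 0.0, 6.3, 10.8, 0.0, 3.1, 2.1, 0.4],
            [1.0, 0.1, 6.3, 8.0, 0.0, 2.8, 0.6, 0.3],
            [1.5, 0.3, 7.7, 6.0, 0.0, 3.2, 0.1, 0.4],
            [2.4, 0.5, 10.4, 5.7, 0.0, 1.5, 0.0, 0.3],
        ]
    )
    return pd.DataFrame(
        data, index=pd.RangeIndex(1, 13, name="month"),
        columns=[f"C{i}" for i in range(1, 9)],
    )


def santiago_winter_comparison() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Published May-August 2004 monthly PM2.5 apportionment (ug/m3) at the
    Santiago Las Condes site: cluster analysis (clusters 3+4 = traffic,
    cluster 7 = wood smoke, cluster 6 = regional) vs the PMF receptor
    model. Returns (ca, rm) period frames indexed by month number."""
    months = pd.Index([5, 6, 7, 8], name="month")
    ca = _stat_frame(
        months,
        {
            "traffic": [(25.2, 2.5), (20.8, 1.9), (21.6, 2.1), (14.8, 1.8)],
            "rwb": [(7.4, 2.4), (6.4, 2.1), (4.0, 1.6), (8.1, 2.3)],
            "regional": [(6.3, 1.2), (7.9, 1.3), (6.7, 1.7), (4.0, 1.1)],
        },
    )
    rm = _stat_frame(
        months,
        {
            "traffic": [(14.7, 1.2), (17.6, 1.7), (16.8, 1.5), (9.3, 0.8)],
            "rwb": [(15.1, 1.6), (13.8, 1.2), (12.7, 1.3), (7.3, 0.7)],
            "regional": [(17.7, 2.2), (11.6, 1.1), (12.7, 1.7), (12.3, 1.3)],
        },
    )
    return ca, rm
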