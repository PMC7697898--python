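"""Fuse cluster-analysis (CA) and receptor-model (RM) apportionments.

Labeled clusters are merged into per-source hourly series (clusters sharing
a label are summed, so additivity to the observed concentration is
preserved exactly), aligned to a filter-campaign sampling schedule, and laid
side by side with RM estimates in weekly or monthly comparison tables with
propagated standard errors.

Error propagation: the SE of a period mean computed from hourly data is
sd/sqrt(n) over the period's retained hours (hours treated as
exchangeable; autocorrelation is ignored, a documented limitation). SEs of
sums and of averages of period values combine in quadrature. Printed-
precision checks round half away from zero, matching how such tables are
typeset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rules_engine import SourceLabelMap


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (0.25 -> 0.3 at 1 decimal)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def merge_labeled_clusters(
    contrib: pd.DataFrame, labels: SourceLabelMap | dict[int, str]
) -> pd.DataFrame:
    """Sum member-cluster contribution series into per-source series.

    ``labels`` must cover every cluster column; the hourly sum across
    sources equals the sum across clusters (additivity preserved).
    """
    label_map = labels.merge_map() if isinstance(labels, SourceLabelMap) else dict(labels)
    missing = [cl for cl in contrib.columns if cl not in label_map]
    if missing:
        raise ValueError(f"labels missing for clusters: {missing}")
    out = {}
    for source in dict.fromkeys(label_map.values()):  # insertion order
        members = [cl for cl in contrib.columns if label_map[cl] == source]
        out[source] = contrib[members].sum(axis=1)
    merged = pd.DataFrame(out, index=contrib.index)
    merged.attrs.update(contrib.attrs)
    return merged


def align_to_schedule(
    series: pd.DataFrame, schedule: list[pd.DatetimeIndex]
) -> pd.DataFrame:
    """Period means +/- SE over only the scheduled hours of each period.

    Mirrors a filter campaign that samples the same subset of days per
    week: only those days' retained hours enter the CA period mean, so CA
    and RM estimates cover identical air. A scheduled period with no
    retained hours is flagged empty (all-NaN row).
    """
    rows = {}
    for i, hours in enumerate(schedule, start=1):
        sub = series.loc[series.index.intersection(hours)]
        label = f"period_{i}"
        row = {}
        for col in series.columns:
            if len(sub) == 0:
                row[(col, "mean")] = np.nan
                row[(col, "se")] = np.nan
            else:
                row[(col, "mean")] = sub[col].mean()
                row[(col, "se")] = (
                    sub[col].std(ddof=1) / np.sqrt(len(sub)) if len(sub) > 1 else np.nan
                )
        rows[label] = row
    out = pd.DataFrame(rows).T
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["source", "stat"])
    return out


@dataclass
class ComparisonTable:
    """Side-by-side CA and RM period estimates with footer averages.

    ``ca``/``rm``: period x (source, mean|se). ``footer``: per (source,
    method) the arithmetic mean of the column's period values, with SEs
    combined in quadrature / n. ``agreement``: per period and common
    source, whether |CA - RM| <= 2 sqrt(SE_CA^2 + SE_RM^2).
    """

    ca: pd.DataFrame
    rm: pd.DataFrame
    footer: pd.DataFrame
    agreement: pd.DataFrame

    def footer_value(self, source: str, method: str, decimals: int = 1) -> float:
        """Footer average at printed precision."""
        return round_half_away(self.footer.loc[(source, "mean"), method], decimals)


def _footer_col(frame: pd.DataFrame) -> pd.Series:
    out = {}
    for source in frame.columns.get_level_values(0).unique():
        vals = frame[(source, "mean")]
        out[(source, "mean")] = vals.mean()
        se = frame[(source, "se")]
        out[(source, "se")] = (
            float(np.sqrt((se.dropna() ** 2).sum()) / len(vals)) if se.notna().any() else np.nan
        )
    return pd.Series(out)


def build_comparison(ca: pd.DataFrame, rm: pd.DataFrame) -> ComparisonTable:
    """Assemble the CA-vs-RM comparison for matching periods.

    Both inputs are period x (source, mean|se) frames; the period indexes
    must match exactly (mismatches are an error listing them).
    """
    if not ca.index.equals(rm.index):
        only_ca = ca.index.difference(rm.index).tolist()
        only_rm = rm.index.difference(ca.index).tolist()
        raise ValueError(
            f"mismatched periods: only in CA {only_ca}, only in RM {only_rm}"
        )
    footer = pd.DataFrame({"CA": _footer_col(ca), "RM": _footer_col(rm)})

    common = [
        s
        for s in ca.columns.get_level_values(0).unique()
        if s in rm.columns.get_level_values(0)
    ]
    agreement = {}
    for s in common:
        tol = 2.0 * np.sqrt(ca[(s, "se")] ** 2 + rm[(s, "se")] ** 2)
        agreement[s] = (ca[(s, "mean")] - rm[(s, "mean")]).abs() <= tol
    return ComparisonTable(
        ca=ca, rm=rm, footer=footer, agreement=pd.DataFrame(agreement)
    )


def monthly_table(series: pd.DataFrame, year: int | None = None) -> pd.DataFrame:
    """Months x sources matrix of monthly mean contributions.

    ``series`` is an hourly per-source frame; restrict to ``year`` when
    given. Row index is the calendar month number.
    """
    idx = pd.DatetimeIndex(series.index)
    sub = series[idx.year == year] if year is not None else series
    if sub.empty:
        raise ValueError(f"series does not cover year {year}")
    return sub.groupby(pd.DatetimeIndex(sub.index).month).mean().rename_axis("month")


def subset_sum_average(
    monthly: pd.DataFrame,
    columns: list[str] | None = None,
    months: list[int] | None = None,
) -> float:
    """Sum selected source columns per month, then average over months.

    The multi-source, multi-month summary used when comparing a CA total
    against an RM total over a season (e.g. traffic + wood smoke +
    regional over the winter months).
    """
    sub = monthly if columns is None else monthly[columns]
    if months is not None:
        sub = sub.loc[months]
    return float(sub.sum(axis=1).mean())
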