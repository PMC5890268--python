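"""Period x topographic-zone statistics: summaries, ANOVA, hot moments.

Summaries report mean, s.d., s.e.m. and the 90th percentile of a variable
per drought-period x zone cell.  The flux record is analysed with a
repeated-measures two-way ANOVA (chamber as subject, drought period as the
within-subject factor, zone as the between-subject factor) followed by
Tukey's HSD; soil chemistry uses an ordinary two-way ANOVA with interaction.
Hot moments are observations above the per-period 90th-percentile flux.

Quantiles use linear interpolation between order statistics (NumPy's
default, R type 7); reported 90th percentiles are convention-sensitive, so
this choice is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnovaResult",
    "anova_two_way",
    "assign_periods",
    "hot_moments",
    "summarize",
]


def assign_periods(
    df: pd.DataFrame,
    breakpoint_dates: Sequence,
    date_col: str = "date",
    period_names: Sequence[str] = ("pre_drought", "drought", "recovery",
                                   "post_drought"),
) -> pd.DataFrame:
    """Label each row with its drought period from the breakpoint dates.

    ``breakpoint_dates`` may be a sequence of dates or a segmentation result
    carrying ``breakpoint_dates``.  A date equal to a breakpoint belongs to
    the following period (half-open periods).
    """
    bps = getattr(breakpoint_dates, "breakpoint_dates", breakpoint_dates)
    bps = [pd.Timestamp(b) for b in bps]
    if len(bps) != len(period_names) - 1:
        raise ValueError(
            f"{len(bps)} breakpoints cannot define {len(period_names)} periods")
    d = pd.to_datetime(df[date_col])
    idx = np.searchsorted(np.array(bps, dtype="datetime64[ns]"),
                          d.to_numpy(), side="right")
    out = df.copy()
    out["period"] = np.asarray(period_names, dtype=object)[idx]
    return out


def summarize(
    df: pd.DataFrame,
    value_col: str,
    by: Sequence[str] = ("period", "zone"),
) -> pd.DataFrame:
    """Per-cell n, mean, sd, sem and 90th percentile; empty cells omitted.

    Invariant: sem == sd / sqrt(n); row order of the input is irrelevant.
    """
    by = list(by)
    grouped = df.groupby(by, sort=True, observed=True)[value_col]
    out = grouped.agg(
        n="count",
        mean="mean",
        sd=lambda v: v.std(ddof=1),
        p90=lambda v: float(np.percentile(v, 90)),
    ).reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out["variable"] = value_col
    return out[["variable", *by, "n", "mean", "sd", "sem", "p90"]]


@dataclass
class AnovaResult:
    """F table per factor plus optional Tukey HSD pair tables."""

    response: str
    design: str                     # "two_way" | "two_way_repeated"
    log_transformed: bool
    table: pd.DataFrame             # index: period, zone, interaction
    tukey: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_dropped_nonpositive: int = 0

    def p(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])


def _check_cells(df: pd.DataFrame, a: str, b: str, response: str) -> None:
    counts = df.groupby([a, b], observed=True)[response].count()
    full = pd.MultiIndex.from_product(
        [df[a].unique(), df[b].unique()], names=[a, b])
    missing = full.difference(counts[counts > 0].index)
    if len(missing) > 0:
        cell = tuple(missing[0])
        raise ValueError(
            f"singular design: no observations in cell {a}={cell[0]!r}, "
            f"{b}={cell[1]!r}")


def _tukey_table(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(values.to_numpy(), groups.to_numpy())
    frame = pd.DataFrame(res.summary().data[1:],
                         columns=res.summary().data[0])
    return frame.rename(columns={
        "group1": "level_a", "group2": "level_b",
        "meandiff": "diff", "p-adj": "adjusted_p"})[
        ["level_a", "level_b", "diff", "adjusted_p"]]


def anova_two_way(
    df: pd.DataFrame,
    response: str,
    repeated: bool = False,
    log_transform: bool = False,
    subject_col: str = "chamber_id",
    aggregate: str | None = None,
    alpha: float = 0.05,
) -> AnovaResult:
    """Two-way (optionally repeated-measures) ANOVA of response on
    drought period x topographic zone, with Tukey HSD on significant
    main factors.

    For the repeated design the chamber is the subject: zone is a
    between-subject factor (each chamber sits in one zone) and period a
    within-subject factor; observations are aggregated to chamber x period
    means by default, tempering the serial correlation of repeated closures.
    For the plain design chamber-day means can be requested via
    ``aggregate="chamber_day"``; soil-chemistry replicates need none.

    ``log_transform`` drops non-positive observations (with a count kept in
    the result) and takes natural logs — appropriate for CO2, never applied
    to sign-indefinite CH4 by callers.
    """
    data = df.copy()
    for col in ("period", "zone", response):
        if col not in data.columns:
            raise ValueError(f"missing required column {col!r}")
    for col in ("period", "zone"):
        if data[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has a single level")

    n_dropped = 0
    if log_transform:
        bad = data[response] <= 0
        n_dropped = int(bad.sum())
        data = data.loc[~bad].copy()
        data[response] = np.log(data[response])

    if aggregate is None:
        aggregate = "chamber_period" if repeated else "none"
    if aggregate == "chamber_period":
        data = (data.groupby([subject_col, "zone", "period"], observed=True)
                [response].mean().reset_index())
    elif aggregate == "chamber_day":
        keys = [subject_col, "zone", "period", "date"]
        data = (data.groupby(keys, observed=True)[response].mean()
                .reset_index())
    elif aggregate != "none":
        raise ValueError(f"unknown aggregation {aggregate!r}")

    _check_cells(data, "period", "zone", response)

    if repeated:
        import pingouin as pg

        per_subject = data.groupby(subject_col, observed=True)["period"].nunique()
        n_periods = data["period"].nunique()
        lacking = per_subject[per_subject < n_periods]
        if len(lacking) > 0:
            raise ValueError(
                f"subject {lacking.index[0]!r} lacks some periods; "
                "repeated design needs every subject in every period")
        aov = pg.mixed_anova(data=data, dv=response, within="period",
                             subject=subject_col, between="zone")
        aov = aov.set_index("Source")
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        table = pd.DataFrame({
            "F": [aov.loc["period", "F"], aov.loc["zone", "F"],
                  aov.loc["Interaction", "F"]],
            "df1": [aov.loc["period", "DF1"], aov.loc["zone", "DF1"],
                    aov.loc["Interaction", "DF1"]],
            "df2": [aov.loc["period", "DF2"], aov.loc["zone", "DF2"],
                    aov.loc["Interaction", "DF2"]],
            "p": [aov.loc["period", p_col], aov.loc["zone", p_col],
                  aov.loc["Interaction", p_col]],
        }, index=["period", "zone", "interaction"])
        design = "two_way_repeated"
    else:
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        model = smf.ols(f"Q('{response}') ~ C(period) * C(zone)", data=data).fit()
        tab = anova_lm(model, typ=2)
        table = pd.DataFrame({
            "F": [tab.loc["C(period)", "F"], tab.loc["C(zone)", "F"],
                  tab.loc["C(period):C(zone)", "F"]],
            "df1": [tab.loc["C(period)", "df"], tab.loc["C(zone)", "df"],
                    tab.loc["C(period):C(zone)", "df"]],
            "df2": [tab.loc["Residual", "df"]] * 3,
            "p": [tab.loc["C(period)", "PR(>F)"], tab.loc["C(zone)", "PR(>F)"],
                  tab.loc["C(period):C(zone)", "PR(>F)"]],
        }, index=["period", "zone", "interaction"])
        design = "two_way"

    tukey: dict[str, pd.DataFrame] = {}
    for factor in ("period", "zone"):
        if table.loc[factor, "p"] < alpha:
            tukey[factor] = _tukey_table(data[response], data[factor])

    return AnovaResult(response=response, design=design,
                       log_transformed=log_transform, table=table,
                       tukey=tukey, n_dropped_nonpositive=n_dropped)


def hot_moments(
    df: pd.DataFrame,
    value_col: str = "flux",
    quantile: float = 0.9,
    period_col: str = "period",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-period hot-moment threshold (default the 90th percentile) and the
    observations strictly above it.

    Returns ``(thresholds, flagged)`` where ``thresholds`` has one row per
    period and ``flagged`` is the input with a boolean ``hot`` column.
    Requires at least 10 observations per period.
    """
    counts = df.groupby(period_col, observed=True)[value_col].count()
    thin = counts[counts < 10]
    if len(thin) > 0:
        raise ValueError(
            f"period {thin.index[0]!r} has only {int(thin.iloc[0])} "
            "observations (< 10) — percentile threshold unreliable")
    thresholds = (df.groupby(period_col, observed=True)[value_col]
                  .quantile(quantile).rename("threshold").reset_index())
    out = df.merge(thresholds, on=period_col, how="left")
    out["hot"] = out[value_col] > out["threshold"]
    return thresholds, out
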