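"""Combined iconicity–stability–L1 table and the stratified linear regressions.

The combined table crosses every concept with every registry group (so 344
concepts × 54 groups give 18 576 rows), joins the per-group stability rate
and the earlier/later L1 acquisition codings, and is then analysed by
ordinary least squares of log iconic value on stability, over all rows and
separately for consonants and vowels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sound_classes import (
    GroupRegistry,
    L1Matrix,
    L1_AXES,
    default_l1_matrix,
    default_registry,
    l1_coding,
)

__all__ = [
    "RegressionResult",
    "combine",
    "fit_regression",
    "summarize_stability",
    "l1_separation",
]


def combine(
    ico: pd.DataFrame,
    sst: pd.DataFrame,
    l1: L1Matrix | None = None,
    registry: GroupRegistry | None = None,
) -> pd.DataFrame:
    """Join the (pre-filter) iconicity table with stability and L1 codings.

    One row per (concept, group) in the cross product; ``sst`` is joined by
    group (NA for sparse-excluded or unobserved groups); each L1 axis is
    coded independently, so e.g. "voiced stop" is earlier on the manner axis
    and later on the voicing axis.
    """
    l1 = l1 or default_l1_matrix()
    registry = registry or default_registry()
    unknown = set(ico["group"]) - set(registry.names)
    if unknown:
        raise KeyError(f"groups absent from registry: {sorted(unknown)}")

    df = ico.copy()
    if "center" in df.columns:
        df = df.rename(columns={"center": "ico"})
    sst_flat = sst.reset_index() if "group" not in sst.columns else sst
    df = df.merge(sst_flat[["group", "sst"]], on="group", how="left")
    df["major"] = [registry[g].major for g in df["group"]]
    for axis in L1_AXES:
        df[f"l1_{axis}"] = [
            l1_coding(registry[g], axis=axis, l1=l1) for g in df["group"]
        ]
    return df


@dataclass(frozen=True)
class RegressionResult:
    """OLS summary for one stratum of the combined table."""

    subset: str
    n: int
    f_stat: float
    df1: int
    df2: int
    p: float
    r2: float
    slope: float
    intercept: float


def fit_regression(
    rows: pd.DataFrame,
    subset: str = "all",
    log_response: bool = True,
) -> RegressionResult:
    """OLS of (log) iconic value on stability over one stratum.

    Rows are filtered to iconic value ≥ 1 and defined sst; ``subset`` is
    "all", "consonants" or "vowels".  The F statistic tests the slope
    (df1 = 1, df2 = n − 2).
    """
    df = rows
    if subset == "consonants":
        df = df[df["major"] == "consonant"]
    elif subset == "vowels":
        df = df[df["major"] == "vowel"]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    df = df[(df["ico"] >= 1.0) & df["sst"].notna()]
    n = len(df)
    if n < 3:
        raise ValueError(f"insufficient data for regression ({n} usable rows)")
    y = np.log(df["ico"].to_numpy()) if log_response else df["ico"].to_numpy()
    X = sm.add_constant(df["sst"].to_numpy())
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        subset=subset,
        n=n,
        f_stat=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        p=float(fit.f_pvalue),
        r2=float(fit.rsquared),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
    )


def summarize_stability(sst: pd.DataFrame) -> pd.DataFrame:
    """Order groups from most to least stable with their outcome proportions.

    Groups with NA stability (sparse-excluded or unobserved) sort last and
    are flagged in the ``excluded`` column.
    """
    df = sst.reset_index()[
        ["group", "feature_class", "major", "p_stable", "p_shift_in", "p_shift_out", "p_indel", "sst"]
    ].rename(columns={"sst": "stability_rate"})
    df["excluded"] = df["stability_rate"].isna()
    df = df.sort_values(
        ["excluded", "stability_rate", "group"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def l1_separation(rows: pd.DataFrame, axis: str) -> dict:
    """Split combined rows into earlier/later strata on one L1 axis.

    Rows coded "none" on the axis are dropped.  Returns the two sub-tables
    and their mean stability and iconic value (NaN when a stratum is empty).
    """
    if axis not in L1_AXES:
        raise ValueError(f"unknown L1 axis {axis!r}")
    col = f"l1_{axis}"
    out = {}
    for label in ("earlier", "later"):
        sub = rows[rows[col] == label]
        out[label] = sub
        out[f"{label}_mean_sst"] = float(sub["sst"].mean()) if len(sub) else float("nan")
        out[f"{label}_mean_ico"] = float(sub["ico"].mean()) if len(sub) else float("nan")
    return out
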