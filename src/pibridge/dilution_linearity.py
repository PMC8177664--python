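"""Endogenous parallel-dilution linearity and fold-change recovery.

A pooled plasma is measured at several dilutions (1x ... 8x). Linearity is
assessed two ways:

* per-species unweighted regression of PAR against relative concentration
  (1/dilution factor), flagging non-responsive species by R^2;
* pairwise fold-change recovery: for every unordered pair of dilution
  levels, the observed PAR ratio divided by the nominal ratio, summarized
  per species by empirical P10/P90, a t-based 95% CI of the mean, and the
  fraction of recoveries outside the 70-130% accuracy window.

Fold changes are computed within the same replicate index (each replicate
is an independently prepared dilution series).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ParTable, PeakTable


def _dilution_frame(table: PeakTable | ParTable) -> pd.DataFrame:
    """Tidy (analyte, factor, replicate, par) view of a dilution series."""
    if isinstance(table, PeakTable):
        df = table.data.copy()
        df["par"] = df["area"] / df["is_area"]
        if "replicate" not in df.columns:
            # replicate = order of appearance of each factor
            df["replicate"] = df.groupby(["analyte", "nominal_dilution"]).cumcount()
        return df[["analyte", "nominal_dilution", "replicate", "par"]].rename(
            columns={"nominal_dilution": "factor"}
        )
    meta, par = table.meta, table.par
    rep = (
        meta["replicate"]
        if "replicate" in meta.columns
        else meta.groupby("nominal_dilution").cumcount()
    )
    long = par.copy()
    long["factor"] = meta["nominal_dilution"].to_numpy()
    long["replicate"] = np.asarray(rep)
    out = long.melt(id_vars=["factor", "replicate"], var_name="analyte", value_name="par")
    return out[["analyte", "factor", "replicate", "par"]]


@dataclass
class DilutionRegression:
    """Per-species linear response vs relative concentration."""

    table: pd.DataFrame  # species, slope, intercept, r_squared, omitted
    r2_threshold: float

    @property
    def omitted_species(self) -> list[str]:
        return self.table.loc[self.table["omitted"], "species"].tolist()


def regress_dilution(
    table: PeakTable | ParTable,
    factors: Optional[Sequence[float]] = None,
    r2_threshold: float = 0.98,
) -> DilutionRegression:
    """Unweighted per-species regression of PAR on 1/dilution.

    Species whose R^2 falls below ``r2_threshold`` are flagged as omitted
    (poor response), the treatment applied to non-responsive analytes when
    qualifying dilutional linearity.
    """
    df = _dilution_frame(table)
    if factors is not None:
        df = df[df["factor"].isin([float(f) for f in factors])]
    if df["factor"].nunique() < 3:
        raise ValueError("dilution regression requires at least 3 dilution levels")
    rows = []
    for species, grp in df.groupby("analyte", sort=True):
        x = 1.0 / grp["factor"].to_numpy(dtype=float)
        y = grp["par"].to_numpy(dtype=float)
        b, a = np.polyfit(x, y, 1)
        pred = a + b * x
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        # a flat response has no variance to explain: R^2 := 0 (relative
        # threshold guards against rounding residue of a constant series)
        degenerate = ss_tot <= 1e-20 * float(np.sum(y * y))
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if not degenerate else 0.0
        rows.append(
            {"species": species, "slope": float(b), "intercept": float(a),
             "r_squared": r2, "omitted": r2 < r2_threshold}
        )
    return DilutionRegression(table=pd.DataFrame(rows), r2_threshold=r2_threshold)


def fold_change_recovery(
    table: PeakTable | ParTable,
    factors: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Pairwise fold-change recovery for every species and dilution pair.

    For each unordered pair of dilution factors (f_i < f_j, i.e. f_i the
    less dilute sample) within the same replicate:

        observed_fold = PAR(f_i) / PAR(f_j)
        nominal_fold  = f_j / f_i
        recovery      = observed_fold / nominal_fold

    Six levels therefore give C(6,2) = 15 pairs per species per replicate.
    Zero PAR in a denominator yields a missing recovery (kept as NaN, never
    silently dropped).
    """
    df = _dilution_frame(table)
    if factors is not None:
        df = df[df["factor"].isin([float(f) for f in factors])]
    levels = sorted(df["factor"].unique())
    if len(levels) < 2:
        raise ValueError("fold-change recovery requires at least 2 dilution levels")
    wide = df.pivot_table(
        index=["analyte", "replicate"], columns="factor", values="par", aggfunc="first"
    )
    rows = []
    for (species, rep), vals in wide.iterrows():
        for fi, fj in combinations(levels, 2):  # fi < fj: fi less dilute
            pi, pj = vals.get(fi, np.nan), vals.get(fj, np.nan)
            nominal = fj / fi
            observed = pi / pj if pj and not np.isnan(pj) and not np.isnan(pi) else np.nan
            rows.append(
                {"species": species, "replicate": rep,
                 "dilution_i": fi, "dilution_j": fj,
                 "nominal_fold": nominal, "observed_fold": observed,
                 "recovery": observed / nominal if not np.isnan(observed) else np.nan}
            )
    return pd.DataFrame(rows)


@dataclass
class RecoverySummary:
    """Per-species and pooled fold-change recovery summary."""

    per_species: pd.DataFrame  # species, n, p10, p90, ci_low, ci_high, frac_outside
    pooled_frac_outside: float
    window: tuple[float, float]


def summarize_recovery(
    recoveries: pd.DataFrame,
    window: tuple[float, float] = (0.7, 1.3),
    ci_level: float = 0.95,
) -> RecoverySummary:
    """Summarize fold-change recoveries per species.

    P10/P90 are empirical quantiles with linear interpolation between
    order statistics (the default "linear" convention). The CI of the mean
    uses the t distribution. ``frac_outside`` counts recoveries outside
    the accuracy window (default 70-130%); missing recoveries are excluded
    from every statistic but reported in ``n_missing``.
    """
    lo, hi = window
    rows = []
    for species, grp in recoveries.groupby("species", sort=True):
        vals = grp["recovery"].to_numpy(dtype=float)
        missing = int(np.isnan(vals).sum())
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            raise ValueError(f"species {species!r} has fewer than 2 recovery values")
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        tq = stats.t.ppf(0.5 + ci_level / 2.0, df=len(vals) - 1)
        rows.append(
            {
                "species": species,
                "n": len(vals),
                "n_missing": missing,
                "mean": mean,
                "p10": float(np.quantile(vals, 0.10)),
                "p90": float(np.quantile(vals, 0.90)),
                "ci_low": mean - tq * sem,
                "ci_high": mean + tq * sem,
                "frac_outside": float(np.mean((vals < lo) | (vals > hi))),
            }
        )
    per_species = pd.DataFrame(rows)
    all_vals = recoveries["recovery"].to_numpy(dtype=float)
    all_vals = all_vals[~np.isnan(all_vals)]
    pooled = float(np.mean((all_vals < lo) | (all_vals > hi)))
    return RecoverySummary(per_species=per_species, pooled_frac_outside=pooled, window=window)
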