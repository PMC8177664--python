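"""Evaluation layer over normalized PAR data.

QC acceptance against the designed HQC:LQC fold, PCA batch diagnostics,
the symmetric %Difference statistic for cross-study bridging with its
+-35% acceptance window, the variance-of-%difference comparison of QC
anchor strategies, healthy-population reference ranges and composition
profiles, and Welch-test cohort comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .serrf import NormalizationResult
from .tables import ParTable, qc_pairs


# ---------------------------------------------------------------------------
# %Difference


def percent_difference(par_a, par_b):
    """Signed symmetric percent difference 100*(a-b)/((a+b)/2).

    Antisymmetric in its arguments, zero iff a == b, invariant to a common
    rescaling, and bounded in (-200, 200) for positive inputs. Undefined
    (NaN) when both inputs are zero.
    """
    a = np.asarray(par_a, dtype=float)
    b = np.asarray(par_b, dtype=float)
    denom = 0.5 * (a + b)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (a - b) / denom
    out = np.where(denom == 0, np.nan, out)
    if np.isscalar(par_a) and np.isscalar(par_b):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# QC acceptance


def qc_acceptance(
    par_table: ParTable,
    expected_fold: float = 8.0,
    window: tuple[float, float] = (0.70, 1.30),
) -> pd.DataFrame:
    """Check each QC pair's HQC/LQC ratio against the designed fold.

    A pair passes for a species when ratio/expected_fold lies inside
    ``window`` (inclusive at both boundaries). Zero LQC fails with reason.
    Returns one row per species per pair with columns ``species, study_id,
    batch_id, pair, ratio, ratio_of_expected, passed, reason``.
    """
    pairs = qc_pairs(par_table.meta)
    if pairs.empty:
        raise ValueError("no LQC/HQC pairs in table")
    lo, hi = window
    rows = []
    for _, p in pairs.iterrows():
        lvals = par_table.par.loc[p["lqc_row"]]
        hvals = par_table.par.loc[p["hqc_row"]]
        for sp in par_table.species:
            lv, hv = float(lvals[sp]), float(hvals[sp])
            if lv == 0:
                rows.append({"species": sp, "study_id": p["study_id"],
                             "batch_id": p["batch_id"], "pair": p["pair"],
                             "ratio": np.nan, "ratio_of_expected": np.nan,
                             "passed": False, "reason": "zero LQC PAR"})
                continue
            ratio = hv / lv
            rel = ratio / expected_fold
            ok = lo <= rel <= hi
            rows.append({"species": sp, "study_id": p["study_id"],
                         "batch_id": p["batch_id"], "pair": p["pair"],
                         "ratio": ratio, "ratio_of_expected": rel,
                         "passed": ok, "reason": "" if ok else "outside window"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA batch diagnostic


@dataclass
class PcaDiagnostic:
    scores: pd.DataFrame  # PC1, PC2 + batch_id, study_id, role
    batch_separation: float
    explained_variance_ratio: tuple[float, ...]


def pca_batch_diagnostic(par_table: ParTable, n_components: int = 2) -> PcaDiagnostic:
    """PCA of log, per-species-standardized PAR with a batch-separation score.

    batch_separation is the between-batch share of the total sum of
    squares of the PC1-PC2 scores (0 = batches indistinguishable, 1 =
    perfectly separated). A single batch scores 0 by convention.
    Constant species are dropped with a warning-free mask (they carry no
    information for the rotation).
    """
    if par_table.n_injections < 3:
        raise ValueError("PCA diagnostic requires at least 3 injections")
    logp = np.log(par_table.par.clip(lower=1e-300))
    sd = logp.std(ddof=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("need at least 2 non-constant species for PCA")
    z = (logp.loc[:, keep] - logp.loc[:, keep].mean()) / sd[keep]
    n_components = min(n_components, z.shape[1], z.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    scores_df = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(n_components)])
    for col in ("batch_id", "study_id", "role"):
        if col in par_table.meta.columns:
            scores_df[col] = par_table.meta[col].to_numpy()
    batches = par_table.meta["batch_id"].to_numpy()
    if len(set(batches)) < 2:
        sep = 0.0
    else:
        pts = scores[:, : min(2, scores.shape[1])]
        grand = pts.mean(axis=0)
        tss = float(np.sum((pts - grand) ** 2))
        bss = 0.0
        for b in set(batches):
            sub = pts[batches == b]
            bss += len(sub) * float(np.sum((sub.mean(axis=0) - grand) ** 2))
        sep = bss / tss if tss > 0 else 0.0
    return PcaDiagnostic(
        scores=scores_df, batch_separation=float(sep),
        explained_variance_ratio=tuple(float(v) for v in pca.explained_variance_ratio_),
    )


# ---------------------------------------------------------------------------
# cross-study bridging


@dataclass
class BridgeReport:
    """Per-species cross-study concordance of shared samples."""

    per_sample: pd.DataFrame  # species, sample_id, par_a, par_b, percent_difference
    per_species: pd.DataFrame  # species, n, frac_within, accepted
    threshold_pct: float
    min_frac: float
    accept_direction: str


def _sample_medians(par_table: ParTable, sample_ids: Sequence[str]) -> pd.DataFrame:
    meta = par_table.meta
    sel = meta["sample_id"].isin(sample_ids).to_numpy()
    sub = par_table.par.loc[sel].copy()
    sub["sample_id"] = meta.loc[sel, "sample_id"].to_numpy()
    return sub.groupby("sample_id").median()


def bridge_report(
    norm_a: ParTable | NormalizationResult,
    norm_b: ParTable | NormalizationResult,
    shared_sample_ids: Sequence[str],
    threshold_pct: float = 35.0,
    min_frac: float = 0.67,
    accept_direction: str = "within",
) -> BridgeReport:
    """Compare shared samples measured in two (jointly normalized) studies.

    For each species and shared sample, the signed symmetric %difference
    between the two studies' PAR is computed; ``frac_within`` is the
    fraction of shared samples with |%difference| <= ``threshold_pct``
    (inclusive). With ``accept_direction='within'`` (default) a species is
    accepted when frac_within >= min_frac; 'outside' inverts the rule
    (accepting species whose frac_within <= 1 - min_frac), kept selectable
    because the acceptance direction is a reporting convention.
    """
    if accept_direction not in ("within", "outside"):
        raise ValueError("accept_direction must be 'within' or 'outside'")
    ta = norm_a.normalized if isinstance(norm_a, NormalizationResult) else norm_a
    tb = norm_b.normalized if isinstance(norm_b, NormalizationResult) else norm_b
    med_a = _sample_medians(ta, shared_sample_ids)
    med_b = _sample_medians(tb, shared_sample_ids)
    common = med_a.index.intersection(med_b.index)
    if len(common) == 0:
        raise ValueError("no shared samples present in both tables")
    med_a, med_b = med_a.loc[common], med_b.loc[common]
    species = [c for c in med_a.columns if c in med_b.columns]
    rows = []
    for sp in species:
        pd_vals = percent_difference(med_a[sp].to_numpy(), med_b[sp].to_numpy())
        for sid, pa, pb, d in zip(common, med_a[sp], med_b[sp], pd_vals):
            rows.append({"species": sp, "sample_id": sid, "par_a": pa, "par_b": pb,
                         "percent_difference": d})
    per_sample = pd.DataFrame(rows)
    per_species_rows = []
    for sp, grp in per_sample.groupby("species", sort=True):
        d = grp["percent_difference"].to_numpy()
        valid = ~np.isnan(d)
        frac = float(np.mean(np.abs(d[valid]) <= threshold_pct)) if valid.any() else np.nan
        accepted = (
            frac >= min_frac if accept_direction == "within" else frac <= 1.0 - min_frac
        )
        per_species_rows.append(
            {"species": sp, "n": int(valid.sum()), "frac_within": frac, "accepted": accepted}
        )
    return BridgeReport(
        per_sample=per_sample, per_species=pd.DataFrame(per_species_rows),
        threshold_pct=threshold_pct, min_frac=min_frac, accept_direction=accept_direction,
    )


# ---------------------------------------------------------------------------
# anchor comparison (variance of %difference from average)


def anchor_variance_comparison(
    results: Mapping[str, ParTable | NormalizationResult],
    roles: tuple[str, ...] = ("sample",),
    equalize_scale: bool = True,
) -> pd.DataFrame:
    """Compare normalizations anchored on different QC levels.

    For each sample and species, the three normalized values (one per
    anchor) are averaged; the %difference of each anchor's value from that
    average is computed; and the per-species variance of those
    %differences over samples is returned (one row per species per
    anchor). The anchor giving the smallest variance tracks the study
    samples best.

    Because each anchor strategy leaves the data on its own QC level's
    scale, ``equalize_scale`` first divides each result's species column
    by its median over the compared samples (a per-species constant, which
    cannot change relative scatter) so the averages are meaningful.
    """
    tables = {
        k: (v.normalized if isinstance(v, NormalizationResult) else v)
        for k, v in results.items()
    }
    if len(tables) < 2:
        raise ValueError("need at least two normalizations to compare")
    first = next(iter(tables.values()))
    sel = first.meta["role"].isin(roles).to_numpy()
    mats = {}
    for k, t in tables.items():
        if len(t.meta) != len(first.meta):
            raise ValueError("normalizations cover different injection sets")
        m = t.par.loc[sel].to_numpy(dtype=float)
        if equalize_scale:
            m = m / np.median(m, axis=0, keepdims=True)
        mats[k] = m
    species = first.species
    avg = np.mean(list(mats.values()), axis=0)
    rows = []
    for k, m in mats.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            pdiff = 100.0 * (m - avg) / avg
        var = np.nanvar(pdiff, axis=0, ddof=1)
        for sp, v in zip(species, var):
            rows.append({"anchor": k, "species": sp, "variance_pct2": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population profiling


@dataclass
class ReferenceRange:
    per_species: pd.DataFrame  # species, lo, hi, median
    composition: pd.DataFrame  # individuals x species, rows sum to 1
    lo_pct: float
    hi_pct: float


def reference_range(
    population: ParTable,
    lo_pct: float = 2.5,
    hi_pct: float = 97.5,
) -> ReferenceRange:
    """Percentile reference range and composition profile of a population.

    The composition of an individual is each species' share of that
    individual's total PAR (shares sum to 1), which is far more stable
    across individuals than the raw abundances.
    """
    if population.n_injections < 3:
        raise ValueError("reference range requires at least 3 individuals")
    par = population.par.copy()
    par.index = population.meta["sample_id"].to_numpy()
    rows = []
    for sp in population.species:
        v = par[sp].to_numpy(dtype=float)
        rows.append({"species": sp,
                     "lo": float(np.percentile(v, lo_pct)),
                     "hi": float(np.percentile(v, hi_pct)),
                     "median": float(np.median(v))})
    total = par.sum(axis=1)
    composition = par.div(total, axis=0)
    return ReferenceRange(
        per_species=pd.DataFrame(rows), composition=composition,
        lo_pct=lo_pct, hi_pct=hi_pct,
    )


# ---------------------------------------------------------------------------
# cohort comparison


@dataclass
class CohortComparison:
    per_species: pd.DataFrame
    # species, median_a, median_b, sem_a, sem_b, t, df, p_value


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, Welch-Satterthwaite df, p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), np.nan
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def cohort_compare(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
) -> CohortComparison:
    """Two-sided Welch (heteroscedastic) t-test per species.

    ``group_a`` / ``group_b`` are samples-by-species PAR frames (one row
    per subject). Medians and SEMs are reported alongside t, the
    Welch-Satterthwaite degrees of freedom, and the two-sided p-value.
    Species with zero variance in both groups get a missing p-value.
    """
    species = [c for c in group_a.columns if c in group_b.columns]
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = []
    for sp in species:
        a = group_a[sp].to_numpy(dtype=float)
        b = group_b[sp].to_numpy(dtype=float)
        t, df, p = welch_t(a, b)
        rows.append({
            "species": sp,
            "median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "sem_a": float(a.std(ddof=1) / np.sqrt(len(a))),
            "sem_b": float(b.std(ddof=1) / np.sqrt(len(b))),
            "t": t, "df": df, "p_value": p,
        })
    return CohortComparison(per_species=pd.DataFrame(rows))


def longitudinal_summary(
    values: pd.DataFrame,
    visit_col: str = "visit",
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-visit, per-group median and SEM of each species (long input).

    ``values`` is long-format with columns ``visit, group, species, par``.
    """
    rows = []
    for (visit, group, sp), grp in values.groupby([visit_col, group_col, "species"]):
        v = grp["par"].to_numpy(dtype=float)
        rows.append({
            visit_col: visit, group_col: group, "species": sp,
            "median": float(np.median(v)),
            "sem": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
            "n": len(v),
        })
    return pd.DataFrame(rows)
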