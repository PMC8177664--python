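"""QC-anchored batch-effect normalization: SERRF and comparators.

SERRF (Systematic Error Removal using Random Forest) treats the
systematic component of each analyte's intensity — batch offsets plus
injection-order drift — as predictable from (a) the injection order and
(b) the concurrent intensities of the analytes most correlated with the
target. A random-forest regressor is trained per target analyte on the QC
(anchor) injections only, where the true level is constant, and its
prediction for every injection is divided out. Because the anchor level is
constant, whatever the forest predicts beyond noise *is* systematic error.

Three anchor strategies are supported:

* ``LQC`` / ``HQC`` — the low (8x-diluted pool) or high (undiluted pool)
  QC series;
* ``MAAQC`` — mean-adjusted average QC: each QC series is scaled to its
  own mean (so both become mean-one drift profiles), the two scaled
  series are averaged pairwise, and the average is rescaled by the
  geometric mean of the two series means. This pools the drift
  information of both QC levels into one pseudo-QC series at an
  intermediate level. (An alternative ``grand_mean`` construction —
  adjusting both series to their common grand mean before averaging — is
  available behind a switch.)

Modelling choices, all exposed as arguments: log-scale modelling,
within-batch centering of predictor intensities (separately per sample
role, so QC and sample level differences never leak into the features),
absolute Pearson correlation for predictor selection, injection order as
a feature, per-batch forests when each batch holds at least
``min_anchors_split`` anchors (otherwise one pooled forest with batch
indicator features), and median-anchor rescaling so jointly normalized
studies land on the scale of the shared QC lot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .tables import ParTable, qc_pairs

logger = logging.getLogger(__name__)

ANCHOR_KINDS = ("LQC", "HQC", "MAAQC")
COMPARATOR_METHODS = ("batch_median", "qc_loess", "none")


# ---------------------------------------------------------------------------
# anchors


@dataclass
class QcAnchor:
    """An anchor series: per-species PAR of the anchor observations.

    ``meta`` carries study/batch/injection-order per anchor observation
    (for MAAQC, the pair midpoint); ``par`` is aligned row-wise. For MAAQC,
    ``pair_rows`` maps each anchor observation to the positional (lqc, hqc)
    rows of the source table.
    """

    kind: str
    meta: pd.DataFrame
    par: pd.DataFrame
    pair_rows: Optional[list[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if self.kind not in ANCHOR_KINDS:
            raise ValueError(f"anchor kind must be one of {ANCHOR_KINDS}")
        counts = self.meta.groupby("batch_id").size()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"anchor needs >=2 observations per batch; too few in {bad}")


def compute_maaqc(
    lqc_series: pd.DataFrame | np.ndarray,
    hqc_series: pd.DataFrame | np.ndarray,
    construction: str = "own_mean",
) -> pd.DataFrame | np.ndarray:
    """Build the mean-adjusted average QC series from paired LQC/HQC series.

    Rows are QC pair positions in acquisition order, columns species (or a
    1-D series for one species). ``own_mean`` (default): scale each series
    by its own mean, average position-wise, rescale by the geometric mean
    of the two means. ``grand_mean``: scale both series to their common
    grand mean before averaging (kept as an alternative reading of the
    construction, which is not uniquely determined).
    """
    l = np.asarray(lqc_series, dtype=float)
    h = np.asarray(hqc_series, dtype=float)
    if l.shape != h.shape:
        raise ValueError(f"LQC and HQC series shapes differ: {l.shape} vs {h.shape}")
    lm = l.mean(axis=0)
    hm = h.mean(axis=0)
    if np.any(lm <= 0) or np.any(hm <= 0):
        raise ValueError("anchor series means must be strictly positive")
    if construction == "own_mean":
        out = 0.5 * (l / lm + h / hm) * np.sqrt(lm * hm)
    elif construction == "grand_mean":
        gm = 0.5 * (lm + hm)
        out = 0.5 * (l * (gm / lm) + h * (gm / hm)) * np.sqrt(lm * hm) / gm
    else:
        raise ValueError(f"unknown MAAQC construction {construction!r}")
    if isinstance(lqc_series, pd.DataFrame):
        return pd.DataFrame(out, index=lqc_series.index, columns=lqc_series.columns)
    return out


def build_anchor(
    par_table: ParTable, kind: str, maaqc_construction: str = "own_mean"
) -> QcAnchor:
    """Extract the anchor series of one kind from a PAR table."""
    if kind in ("LQC", "HQC"):
        rows = par_table.meta.index[par_table.meta["role"] == kind].to_numpy()
        if len(rows) == 0:
            raise ValueError(f"no {kind} injections in table")
        meta = par_table.meta.loc[rows, ["study_id", "batch_id", "injection_index", "role"]]
        return QcAnchor(kind=kind, meta=meta.reset_index(drop=True),
                        par=par_table.par.loc[rows].reset_index(drop=True))
    if kind != "MAAQC":
        raise ValueError(f"anchor kind must be one of {ANCHOR_KINDS}")
    pairs = qc_pairs(par_table.meta)
    if pairs.empty:
        raise ValueError("no LQC/HQC pairs in table; cannot build MAAQC anchor")
    lqc = par_table.par.loc[pairs["lqc_row"].to_numpy()].reset_index(drop=True)
    hqc = par_table.par.loc[pairs["hqc_row"].to_numpy()].reset_index(drop=True)
    maaqc = compute_maaqc(lqc, hqc, construction=maaqc_construction)
    idx_l = par_table.meta.loc[pairs["lqc_row"], "injection_index"].to_numpy(dtype=float)
    idx_h = par_table.meta.loc[pairs["hqc_row"], "injection_index"].to_numpy(dtype=float)
    meta = pd.DataFrame(
        {
            "study_id": pairs["study_id"],
            "batch_id": pairs["batch_id"],
            "injection_index": 0.5 * (idx_l + idx_h),
            "role": "MAAQC",
        }
    )
    return QcAnchor(
        kind="MAAQC", meta=meta, par=maaqc,
        pair_rows=list(zip(pairs["lqc_row"].tolist(), pairs["hqc_row"].tolist())),
    )


# ---------------------------------------------------------------------------
# feature construction


def _role_group(role: str) -> str:
    return role if role in ("LQC", "HQC") else "sample"


def _centered_log_features(par_table: ParTable) -> pd.DataFrame:
    """Log PAR centered within (batch, role group) for every injection.

    Centering removes batch offsets and role-level differences from the
    feature space, leaving drift and correlated noise — the signal SERRF
    exploits — while the (constant-level) anchor target retains the batch
    offset for the forest to learn.
    """
    logp = np.log(par_table.par.clip(lower=1e-300))
    grp = pd.Series(
        [_role_group(r) for r in par_table.meta["role"]], index=logp.index
    )
    keys = pd.MultiIndex.from_arrays([par_table.meta["batch_id"], grp])
    centered = logp - logp.groupby(keys).transform("mean")
    return centered


def _order_feature(meta: pd.DataFrame) -> pd.Series:
    """Injection order scaled to [0, 1] within each batch."""
    idx = meta["injection_index"].astype(float)
    lo = idx.groupby(meta["batch_id"]).transform("min")
    hi = idx.groupby(meta["batch_id"]).transform("max")
    span = (hi - lo).replace(0.0, 1.0)
    return (idx - lo) / span


@dataclass
class SerrfModel:
    """Fitted per-species SERRF correction models."""

    anchor: QcAnchor
    predictors: dict[str, list[str]]
    forests: dict[str, dict[str, RandomForestRegressor]]  # species -> batch|'pooled' -> RF
    per_batch: bool
    batch_levels: list[str]
    n_predictors: int
    n_trees: int
    seed: int

    def species(self) -> list[str]:
        return list(self.forests)


def _anchor_features(
    par_table: ParTable, anchor: QcAnchor, centered: pd.DataFrame, order: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix and order feature for the anchor observations."""
    if anchor.kind in ("LQC", "HQC"):
        rows = par_table.meta.index[par_table.meta["role"] == anchor.kind].to_numpy()
        return (
            centered.loc[rows].reset_index(drop=True),
            order.loc[rows].reset_index(drop=True),
        )
    feats = []
    ords = []
    for lo, hi in anchor.pair_rows or ():
        feats.append(0.5 * (centered.loc[lo] + centered.loc[hi]))
        ords.append(0.5 * (order.loc[lo] + order.loc[hi]))
    return pd.DataFrame(feats).reset_index(drop=True), pd.Series(ords)


def _select_predictors(
    anchor_feats: pd.DataFrame, target: str, n_predictors: int
) -> list[str]:
    """Most |Pearson|-correlated companion species on the anchor series."""
    others = [c for c in anchor_feats.columns if c != target]
    y = anchor_feats[target].to_numpy()
    scores = {}
    ysd = y.std()
    for c in others:
        x = anchor_feats[c].to_numpy()
        if ysd == 0 or x.std() == 0:
            scores[c] = 0.0
        else:
            scores[c] = abs(float(np.corrcoef(x, y)[0, 1]))
    ranked = sorted(others, key=lambda c: (-scores[c], c))
    return ranked[: min(n_predictors, len(ranked))]


def fit_serrf(
    par_table: ParTable,
    anchor: QcAnchor | str = "MAAQC",
    n_predictors: int = 10,
    n_trees: int = 500,
    seed: int = 0,
    min_anchors_split: int = 5,
    maaqc_construction: str = "own_mean",
) -> SerrfModel:
    """Train one random-forest systematic-error model per species.

    For each target species: select the ``n_predictors`` companion species
    most correlated with it across anchor observations (absolute Pearson
    correlation of within-batch-centered log intensities), then regress the
    target's log anchor intensity on the companions' centered log
    intensities plus scaled injection order. When every batch has at least
    ``min_anchors_split`` anchors, one forest is trained per batch;
    otherwise a single forest is trained on all batches with batch
    indicator features (small batches starve per-batch forests). The
    pooled forest draws no bootstrap samples (tree diversity comes from
    per-split feature subsampling instead): with a handful of anchors per
    batch, bootstrapping would let individual trees miss a batch entirely
    and bias its correction.
    """
    if isinstance(anchor, str):
        anchor = build_anchor(par_table, anchor, maaqc_construction=maaqc_construction)
    species = par_table.species
    if len(species) < n_predictors + 1:
        raise ValueError(
            f"panel has {len(species)} species; need at least n_predictors+1 "
            f"({n_predictors + 1})"
        )
    centered = _centered_log_features(par_table)
    order = _order_feature(par_table.meta)
    anchor_feats, anchor_order = _anchor_features(par_table, anchor, centered, order)

    batch_levels = par_table.batch_ids()
    anchor_batches = anchor.meta["batch_id"].to_numpy()
    counts = anchor.meta.groupby("batch_id").size()
    missing_batches = set(batch_levels) - set(counts.index)
    if missing_batches:
        raise ValueError(f"no anchors in batches {sorted(missing_batches)}")
    per_batch = bool((counts >= min_anchors_split).all())

    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(len(species) * (len(batch_levels) + 1))
    log_anchor = np.log(anchor.par.clip(lower=1e-300))

    predictors: dict[str, list[str]] = {}
    forests: dict[str, dict[str, RandomForestRegressor]] = {}
    for si, target in enumerate(species):
        preds = _select_predictors(anchor_feats, target, n_predictors)
        predictors[target] = preds
        y = log_anchor[target].to_numpy()
        forests[target] = {}
        if per_batch:
            for bi, batch in enumerate(batch_levels):
                mask = anchor_batches == batch
                X = np.column_stack(
                    [anchor_feats.loc[mask, preds].to_numpy(),
                     anchor_order.to_numpy()[mask, None]]
                )
                rf = RandomForestRegressor(
                    n_estimators=n_trees,
                    random_state=int(states[si * (len(batch_levels) + 1) + bi] % (2**31)),
                    n_jobs=1,
                )
                rf.fit(X, y[mask])
                forests[target][batch] = rf
        else:
            dummies = np.column_stack(
                [(anchor_batches == b).astype(float) for b in batch_levels]
            )
            X = np.column_stack(
                [anchor_feats[preds].to_numpy(), anchor_order.to_numpy()[:, None], dummies]
            )
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                bootstrap=False,
                max_features="sqrt",
                random_state=int(states[si * (len(batch_levels) + 1)] % (2**31)),
                n_jobs=1,
            )
            rf.fit(X, y)
            forests[target]["pooled"] = rf
    return SerrfModel(
        anchor=anchor, predictors=predictors, forests=forests, per_batch=per_batch,
        batch_levels=batch_levels, n_predictors=n_predictors, n_trees=n_trees, seed=seed,
    )


def predict_systematic(model: SerrfModel, par_table: ParTable) -> pd.DataFrame:
    """Predicted systematic component (PAR scale) for every injection/species."""
    centered = _centered_log_features(par_table)
    order = _order_feature(par_table.meta).to_numpy()
    batches = par_table.meta["batch_id"].to_numpy()
    out = {}
    for target, preds in model.predictors.items():
        feats = centered[preds].to_numpy()
        yhat = np.empty(len(par_table.meta))
        if model.per_batch:
            for batch, rf in model.forests[target].items():
                mask = batches == batch
                if mask.any():
                    X = np.column_stack([feats[mask], order[mask, None]])
                    yhat[mask] = rf.predict(X)
        else:
            dummies = np.column_stack(
                [(batches == b).astype(float) for b in model.batch_levels]
            )
            X = np.column_stack([feats, order[:, None], dummies])
            yhat[:] = model.forests[target]["pooled"].predict(X)
        out[target] = np.exp(yhat)
    return pd.DataFrame(out, columns=list(model.predictors))


# ---------------------------------------------------------------------------
# normalization results and diagnostics


@dataclass
class NormalizationResult:
    """A normalized PAR table plus QC diagnostics.

    ``diagnostics`` holds:
      * ``qc_rsd`` — per species/batch/QC-role RSD (%) before and after;
      * ``rse`` — per species/study %RSE (100*SEM/mean over QC injections);
      * ``qc_ratio`` — per-species median post-normalization HQC/LQC ratio;
      * ``pred_floor_clips`` — count of predictions clipped to the floor.
    """

    normalized: ParTable
    method: str
    anchor: Optional[str]
    diagnostics: dict = field(default_factory=dict)


def _qc_rsd(par_table: ParTable) -> pd.DataFrame:
    rows = []
    meta = par_table.meta
    for role in ("LQC", "HQC"):
        sel = meta["role"] == role
        for batch, grp in par_table.par.loc[sel].groupby(meta.loc[sel, "batch_id"]):
            mean = grp.mean()
            rsd = 100.0 * grp.std(ddof=1) / mean
            for sp in par_table.species:
                rows.append({"species": sp, "batch_id": batch, "role": role,
                             "rsd_pct": float(rsd[sp])})
    return pd.DataFrame(rows)


def _qc_rse(par_table: ParTable) -> pd.DataFrame:
    """%RSE = 100 * (SD/sqrt(n)) / mean over QC injections, per study/role."""
    rows = []
    meta = par_table.meta
    for role in ("LQC", "HQC"):
        sel = meta["role"] == role
        for study, grp in par_table.par.loc[sel].groupby(meta.loc[sel, "study_id"]):
            n = len(grp)
            if n < 2:
                continue
            rse = 100.0 * grp.std(ddof=1) / np.sqrt(n) / grp.mean()
            for sp in par_table.species:
                rows.append({"species": sp, "study_id": study, "role": role,
                             "rse_pct": float(rse[sp])})
    return pd.DataFrame(rows)


def _qc_ratio(par_table: ParTable) -> pd.Series:
    """Per-species median HQC/LQC PAR ratio over adjacent QC pairs."""
    pairs = qc_pairs(par_table.meta)
    if pairs.empty:
        return pd.Series(dtype=float)
    h = par_table.par.loc[pairs["hqc_row"].to_numpy()].reset_index(drop=True)
    l = par_table.par.loc[pairs["lqc_row"].to_numpy()].reset_index(drop=True)
    return (h / l).median()


def _diagnostics(pre: ParTable, post: ParTable) -> dict:
    rsd_pre = _qc_rsd(pre).rename(columns={"rsd_pct": "rsd_pre_pct"})
    rsd_post = _qc_rsd(post).rename(columns={"rsd_pct": "rsd_post_pct"})
    qc_rsd = rsd_pre.merge(rsd_post, on=["species", "batch_id", "role"])
    return {
        "qc_rsd": qc_rsd,
        "rse": _qc_rse(post),
        "qc_ratio": _qc_ratio(post),
    }


def serrf_normalize(
    par_table: ParTable,
    model: SerrfModel,
    floor_factor: float = 1e-6,
) -> NormalizationResult:
    """Divide out the predicted systematic error and re-anchor the scale.

    normalized(i, s) = raw(i, s) / pred(i, s) * location(s), where
    location(s) is the median anchor value of species s over all batches —
    the scale of the shared QC lot, which is what makes jointly normalized
    studies directly comparable. Non-positive or tiny predictions are
    clipped to ``floor_factor`` times the species' median raw PAR.
    """
    pred = predict_systematic(model, par_table)
    floor = floor_factor * par_table.par.median()
    clipped = int((pred.lt(floor, axis=1)).to_numpy().sum())
    if clipped:
        logger.warning("clipped %d systematic-error predictions to the floor", clipped)
    pred = pred.clip(lower=floor, axis=1)
    location = model.anchor.par.median()
    normalized = par_table.par / pred * location
    post = par_table.with_par(normalized)
    diag = _diagnostics(par_table, post)
    diag["pred_floor_clips"] = clipped
    return NormalizationResult(
        normalized=post, method="SERRF", anchor=model.anchor.kind, diagnostics=diag
    )


def run_serrf(
    par_table: ParTable,
    anchor: str = "MAAQC",
    n_predictors: int = 10,
    n_trees: int = 500,
    seed: int = 0,
    maaqc_construction: str = "own_mean",
) -> NormalizationResult:
    """Convenience wrapper: build anchor, fit, and normalize in one call."""
    model = fit_serrf(
        par_table, anchor, n_predictors=n_predictors, n_trees=n_trees, seed=seed,
        maaqc_construction=maaqc_construction,
    )
    return serrf_normalize(par_table, model)


# ---------------------------------------------------------------------------
# comparator normalizations


def _batch_median_factors(par_table: ParTable) -> pd.DataFrame:
    """Per-batch QC level per species: geometric mean of LQC and HQC medians."""
    meta = par_table.meta
    factors = {}
    for batch in par_table.batch_ids():
        sel = meta["batch_id"] == batch
        med_l = par_table.par.loc[sel & (meta["role"] == "LQC")].median()
        med_h = par_table.par.loc[sel & (meta["role"] == "HQC")].median()
        if med_l.isna().any() or med_h.isna().any():
            raise ValueError(f"batch {batch!r} lacks QC injections for batch_median")
        factors[batch] = np.sqrt(med_l * med_h)
    return pd.DataFrame(factors).T  # batches x species


def comparator_normalize(
    par_table: ParTable,
    method: str = "batch_median",
    loess_frac: Optional[float] = None,
) -> NormalizationResult:
    """Reference normalizations to benchmark SERRF against.

    * ``batch_median`` — divide each batch by its per-species QC level
      (geometric mean of the LQC and HQC medians) and rescale to the
      global QC level. Exact for pure batch offsets.
    * ``qc_loess`` — per batch and species, LOWESS-smooth the
      role-adjusted QC log intensities against injection order, divide the
      batch through by the smooth drift curve, then apply
      ``batch_median``. Falls back to ``batch_median`` (with a warning)
      in batches with fewer than 4 QC injections.
    * ``none`` — identity.
    """
    if method not in COMPARATOR_METHODS:
        raise ValueError(f"method must be one of {COMPARATOR_METHODS}")
    if method == "none":
        post = par_table.copy()
        return NormalizationResult(
            normalized=post, method="none", anchor=None,
            diagnostics=_diagnostics(par_table, post),
        )
    if method == "batch_median":
        factors = _batch_median_factors(par_table)
        global_level = np.exp(np.log(factors).mean())  # geometric mean over batches
        scale = factors.loc[par_table.meta["batch_id"]].reset_index(drop=True)
        normalized = par_table.par / scale * global_level
        post = par_table.with_par(normalized)
        return NormalizationResult(
            normalized=post, method="batch_median", anchor=None,
            diagnostics=_diagnostics(par_table, post),
        )

    # qc_loess
    from statsmodels.nonparametric.smoothers_lowess import lowess

    meta = par_table.meta
    corrected = par_table.par.copy()
    fell_back = []
    for batch in par_table.batch_ids():
        sel = (meta["batch_id"] == batch).to_numpy()
        qc_sel = sel & meta["role"].isin(["LQC", "HQC"]).to_numpy()
        n_qc = int(qc_sel.sum())
        if n_qc < 4:
            fell_back.append(batch)
            continue
        x_qc = meta.loc[qc_sel, "injection_index"].to_numpy(dtype=float)
        x_all = meta.loc[sel, "injection_index"].to_numpy(dtype=float)
        frac = loess_frac if loess_frac is not None else min(1.0, max(0.6, 5.0 / n_qc))
        for sp in par_table.species:
            y = np.log(par_table.par.loc[qc_sel, sp].to_numpy(dtype=float))
            # remove the L/H level difference, keep the drift residual
            roles = meta.loc[qc_sel, "role"].to_numpy()
            for role in ("LQC", "HQC"):
                m = roles == role
                y[m] = y[m] - y[m].mean()
            smooth = lowess(y, x_qc, frac=frac, xvals=x_all)
            corrected.loc[sel, sp] = par_table.par.loc[sel, sp].to_numpy() / np.exp(smooth)
    if fell_back:
        logger.warning(
            "qc_loess: batches %s have <4 QCs; fell back to batch_median there", fell_back
        )
    detrended = par_table.with_par(corrected)
    result = comparator_normalize(detrended, "batch_median")
    result.method = "qc_loess"
    result.diagnostics = _diagnostics(par_table, result.normalized)
    result.diagnostics["loess_fallback_batches"] = fell_back
    return result
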