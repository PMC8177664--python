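"""Synthetic MRM peak-area data with the statistical structure of a
batched, QC-anchored targeted lipidomics study.

The generator emulates, with known ground truth:

* ~31 PI species whose mean peak-area ratios (PAR) span three orders of
  magnitude;
* >10-fold inter-individual spread of total PI with comparatively stable
  composition across individuals;
* per-batch multiplicative offsets and smooth within-batch injection-order
  drift, with multiplicative lognormal measurement noise (heteroscedastic
  in raw scale, homoscedastic in log scale);
* inflated noise for low-abundance species, mimicking the poorer
  fold-change recovery of weak signals;
* interleaved LQC/HQC pairs (HQC = undiluted pooled plasma, LQC = the same
  pool at 8-fold dilution) and a two-study design sharing one QC plasma lot.

Every simulation returns the generated :class:`~pibridge.tables.PeakTable`
together with a ground-truth record, so downstream accuracy claims are
testable as parameter recovery. All randomness derives from a single seed
via ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lipid_panel import PiSpecies, default_panel, endogenous_names
from .tables import PeakTable

DEFAULT_CALIBRATION_LEVELS = (0.5, 1.0, 4.0, 10.0, 40.0, 100.0, 250.0, 500.0, 1000.0)
DEFAULT_DILUTION_FACTORS = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0)


@dataclass
class SimulationConfig:
    """Parameters of the simulated acquisition.

    Dispersions are lognormal sigmas in natural-log space unless noted.

    Attributes
    ----------
    n_samples
        Study samples per study.
    n_batches
        Acquisition batches per study; samples are split evenly.
    batch_effect_sd
        Log-space SD of per-batch, per-species multiplicative offsets.
    drift_amplitude
        Peak-to-peak fractional within-batch drift of response with
        injection order (smooth half-cosine with random phase per batch).
    drift_level_gamma
        Level dependence of the drift: the drift curve is raised to the
        power ``1 + gamma * log10(level / undiluted pool level)``, so more
        dilute material experiences attenuated drift. Models the mild
        signal-level dependence of matrix/instrument response; 0 disables.
    noise_cv
        Fractional CV of residual multiplicative measurement noise for the
        most abundant species.
    low_signal_noise
        Noise inflation across the abundance range: the least abundant
        species gets ``noise_cv * (1 + low_signal_noise)``, interpolated
        linearly in log-abundance in between.
    abundance
        Per-species mean PAR of the undiluted pooled plasma. Defaults to a
        log-spaced profile over three decades across the endogenous panel.
    interindividual_sd
        Log-space SD of the per-individual total-PI scale (shared across
        species within an individual); 0.8 gives >10-fold max/min spread
        across ~49 individuals with high probability.
    species_jitter_sd
        Log-space SD of small per-individual, per-species composition
        jitter.
    qc_fold
        Designed HQC:LQC fold difference (the QC pool dilution), default 8.
    sample_dilution
        Dilution at which study samples are measured (the clinical protocol
        measures all samples at the LQC dilution).
    cohort_effect
        Multiplicative PI-level factor applied to study-specific subjects
        of the *second* study in a bridged two-study design (models a lower
        PI level in the disease cohort); shared individuals and QCs are
        unaffected.
    """

    panel: list[PiSpecies] = field(default_factory=default_panel)
    n_samples: int = 60
    n_batches: int = 2
    batch_effect_sd: float = 0.3
    drift_amplitude: float = 0.15
    drift_level_gamma: float = 0.6
    noise_cv: float = 0.10
    low_signal_noise: float = 0.5
    abundance: Optional[dict[str, float]] = None
    interindividual_sd: float = 0.8
    species_jitter_sd: float = 0.15
    qc_fold: float = 8.0
    sample_dilution: float = 8.0
    cohort_effect: float = 0.6
    qc_interval: int = 15
    is_area_mean: float = 5.0e5
    is_area_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_effect_sd", "drift_amplitude", "noise_cv",
                     "interindividual_sd", "species_jitter_sd", "low_signal_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.qc_fold <= 1:
            raise ValueError("qc_fold must be > 1")
        if self.n_samples < 1 or self.n_batches < 1:
            raise ValueError("n_samples and n_batches must be >= 1")

    @property
    def species_names(self) -> list[str]:
        return endogenous_names(self.panel)

    def abundance_profile(self) -> pd.Series:
        """Mean PAR of the undiluted pool per species, spanning 3 decades."""
        names = self.species_names
        if self.abundance is not None:
            prof = pd.Series(self.abundance, dtype=float).reindex(names)
            if prof.isna().any():
                raise ValueError("abundance profile missing species present in panel")
            return prof
        # log-spaced from 3.0 down to 0.003 PAR across the panel
        vals = np.logspace(np.log10(3.0), np.log10(3.0e-3), num=len(names))
        return pd.Series(vals, index=names)

    def species_noise_cv(self) -> pd.Series:
        """Per-species noise CV with low-signal inflation."""
        ab = self.abundance_profile()
        la = np.log10(ab)
        span = la.max() - la.min()
        rel = (la.max() - la) / span if span > 0 else la * 0.0
        return self.noise_cv * (1.0 + self.low_signal_noise * rel)


def _ln_sigma(cv: float | np.ndarray) -> np.ndarray:
    """Log-space sigma of a mean-one lognormal with the given fractional CV."""
    return np.sqrt(np.log1p(np.square(cv)))


def _lognormal_noise(rng: np.random.Generator, cv: np.ndarray, size: tuple) -> np.ndarray:
    sigma = np.broadcast_to(_ln_sigma(cv), size)
    z = rng.standard_normal(size)
    return np.exp(sigma * z - 0.5 * sigma**2)


def build_injection_sequence(n_samples: int, qc_interval: int = 15) -> list[dict]:
    """Design the injection order of one batch.

    Layout: a system-suitability injection, an opening LQC/HQC pair, study
    samples with an LQC/HQC pair after every ``qc_interval`` samples, a
    closing pair after any final partial block (never doubled when the last
    full block's pair coincides with it), and a final system-suitability
    injection.

    Returns a list of dicts with ``injection_index`` (1-based), ``role``,
    and ``sample_slot`` (0-based index into the batch's sample list for
    sample rows, else None).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if qc_interval < 1:
        raise ValueError("qc_interval must be >= 1")
    seq: list[dict] = [{"role": "system_suitability", "sample_slot": None}]

    def qc_pair() -> None:
        seq.append({"role": "LQC", "sample_slot": None})
        seq.append({"role": "HQC", "sample_slot": None})

    qc_pair()
    since_pair = 0
    for slot in range(n_samples):
        seq.append({"role": "sample", "sample_slot": slot})
        since_pair += 1
        if since_pair == qc_interval:
            qc_pair()
            since_pair = 0
    if since_pair > 0:
        qc_pair()
    seq.append({"role": "system_suitability", "sample_slot": None})
    for i, rec in enumerate(seq):
        rec["injection_index"] = i + 1
    return seq


def _drift_curve(n: int, amplitude: float, phase: float) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
    return 1.0 + 0.5 * amplitude * np.cos(np.pi * t + phase)


def _sample_truth(
    config: SimulationConfig,
    sample_ids: Sequence[str],
    rng: np.random.Generator,
    level_scale: float = 1.0,
) -> pd.DataFrame:
    """Per-sample true undiluted-plasma PAR (rows: samples, cols: species).

    ``level_scale`` multiplies the whole profile (cohort-level effects).
    """
    names = config.species_names
    ab = config.abundance_profile().to_numpy()
    indiv = np.exp(config.interindividual_sd * rng.standard_normal(len(sample_ids)))
    jitter = np.exp(
        config.species_jitter_sd * rng.standard_normal((len(sample_ids), len(names)))
    )
    truth = level_scale * ab[None, :] * indiv[:, None] * jitter
    return pd.DataFrame(truth, index=list(sample_ids), columns=names)


def simulate_study(
    config: SimulationConfig,
    study_id: str = "S1",
    seed_seq: Optional[np.random.SeedSequence] = None,
    sample_truth: Optional[pd.DataFrame] = None,
    sample_ids: Optional[Sequence[str]] = None,
) -> tuple[PeakTable, dict]:
    """Simulate one batched clinical study.

    Observed area(i, s) = IS_area(i) * truth_par(i, s) * batch_factor(b, s)
    * drift(i)^(1 + gamma*log10(level)) * lognormal noise. LQC truth is the
    HQC (pooled plasma) truth divided by ``qc_fold``; study samples are
    measured at ``sample_dilution``. The QC truth profile is the abundance
    profile itself, hence shared by every study built from the same config
    (one QC plasma lot).

    Returns the peak table and a ground-truth record holding the
    per-injection true PAR, batch factors, drift curves and sample truths.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    names = config.species_names
    ab = config.abundance_profile()

    if sample_ids is None:
        sample_ids = [f"{study_id}-SUBJ-{i + 1:03d}" for i in range(config.n_samples)]
    if len(sample_ids) != config.n_samples:
        raise ValueError("sample_ids length must equal n_samples")

    ss_truth, ss_batch, ss_noise = seed_seq.spawn(3)
    rng_truth = np.random.default_rng(ss_truth)
    rng_batch = np.random.default_rng(ss_batch)
    rng_noise = np.random.default_rng(ss_noise)

    if sample_truth is None:
        sample_truth = _sample_truth(config, sample_ids, rng_truth)
    else:
        sample_truth = sample_truth.reindex(index=list(sample_ids), columns=names)
        if sample_truth.isna().any().any():
            raise ValueError("provided sample_truth does not cover all samples/species")

    # per-batch, per-species multiplicative offsets; standard normals are
    # drawn independently of batch_effect_sd so the offset magnitude scales
    # monotonically with the configured sd at a fixed seed
    z_batch = rng_batch.standard_normal((config.n_batches, len(names)))
    batch_factors = pd.DataFrame(
        np.exp(config.batch_effect_sd * z_batch),
        index=[f"{study_id}-B{b + 1}" for b in range(config.n_batches)],
        columns=names,
    )
    phases = rng_batch.uniform(0.0, 2.0 * np.pi, size=config.n_batches)

    # split samples across batches as evenly as possible
    splits = np.array_split(np.arange(config.n_samples), config.n_batches)
    cv = config.species_noise_cv().to_numpy()

    qc_truth_h = ab.to_numpy()
    qc_truth_l = qc_truth_h / config.qc_fold

    rows_meta: list[dict] = []
    areas: list[np.ndarray] = []
    truth_rows: list[np.ndarray] = []
    drift_curves: dict[str, np.ndarray] = {}

    for b, slots in enumerate(splits):
        batch_id = batch_factors.index[b]
        seq = build_injection_sequence(len(slots), config.qc_interval)
        drift = _drift_curve(len(seq), config.drift_amplitude, phases[b])
        drift_curves[batch_id] = drift
        bf = batch_factors.iloc[b].to_numpy()
        for rec in seq:
            role = rec["role"]
            if role == "sample":
                sid = sample_ids[slots[rec["sample_slot"]]]
                truth = sample_truth.loc[sid].to_numpy() / config.sample_dilution
                nominal_dilution = config.sample_dilution
            elif role == "HQC":
                sid, truth, nominal_dilution = f"{study_id}-HQC", qc_truth_h, 1.0
            elif role in ("LQC", "system_suitability"):
                sid = f"{study_id}-{'LQC' if role == 'LQC' else 'SS'}"
                truth, nominal_dilution = qc_truth_l, config.qc_fold
            else:  # pragma: no cover - sequence only emits the roles above
                raise AssertionError(role)
            # level relative to the undiluted pool sets the drift exponent
            level = truth / ab.to_numpy()
            expo = np.maximum(0.0, 1.0 + config.drift_level_gamma * np.log10(level))
            d = drift[rec["injection_index"] - 1] ** expo
            noise = _lognormal_noise(rng_noise, cv, (len(names),))
            is_area = config.is_area_mean * _lognormal_noise(
                rng_noise, np.asarray(config.is_area_cv), (1,)
            )[0]
            true_par = truth
            observed_par = true_par * bf * d * noise
            rows_meta.append(
                {
                    "injection_index": rec["injection_index"],
                    "sample_id": sid,
                    "role": role,
                    "batch_id": batch_id,
                    "study_id": study_id,
                    "nominal_dilution": nominal_dilution,
                    "is_area": is_area,
                }
            )
            areas.append(observed_par * is_area)
            truth_rows.append(true_par)

    meta = pd.DataFrame(rows_meta)
    long = meta.loc[meta.index.repeat(len(names))].reset_index(drop=True)
    long["analyte"] = np.tile(names, len(meta))
    long["area"] = np.concatenate(areas)
    table = PeakTable(long[
        ["injection_index", "sample_id", "role", "batch_id", "study_id",
         "nominal_dilution", "analyte", "area", "is_area"]
    ])
    truth = {
        "true_par": pd.DataFrame(np.vstack(truth_rows), columns=names),
        "meta": meta.drop(columns=["is_area"]),
        "sample_truth": sample_truth,
        "batch_factors": batch_factors,
        "drift_curves": drift_curves,
        "abundance": ab,
        "config": config,
    }
    return table, truth


def simulate_bridged_studies(
    config: SimulationConfig,
    study_ids: tuple[str, str] = ("SAD", "MAD"),
    n_shared: int = 49,
) -> tuple[PeakTable, PeakTable, dict]:
    """Simulate two studies sharing one QC lot and a shared-individual set.

    ``n_shared`` individuals (the bridging set) are measured in both
    studies with identical true PAR profiles; each study additionally
    measures its own study-specific subjects. Study-specific subjects of
    the second study carry the ``cohort_effect`` level factor. Both studies
    inherit the same QC truth profile (the abundance profile), emulating a
    single pooled-plasma QC lot.
    """
    if n_shared > config.n_samples:
        raise ValueError("n_shared cannot exceed n_samples")
    root = np.random.SeedSequence(config.seed)
    ss_shared, ss_a, ss_b = root.spawn(3)
    shared_ids = [f"IND-{i + 1:03d}" for i in range(n_shared)]
    rng_shared = np.random.default_rng(ss_shared)
    shared_truth = _sample_truth(config, shared_ids, rng_shared)

    tables = []
    truths = []
    for study_id, ss, effect in (
        (study_ids[0], ss_a, 1.0),
        (study_ids[1], ss_b, config.cohort_effect),
    ):
        n_own = config.n_samples - n_shared
        own_ids = [f"{study_id}-SUBJ-{i + 1:03d}" for i in range(n_own)]
        ss_own, ss_run = ss.spawn(2)
        own_truth = _sample_truth(
            config, own_ids, np.random.default_rng(ss_own), level_scale=effect
        )
        all_ids = shared_ids + own_ids
        truth_df = pd.concat([shared_truth, own_truth])
        table, truth = simulate_study(
            config, study_id=study_id, seed_seq=ss_run,
            sample_truth=truth_df, sample_ids=all_ids,
        )
        tables.append(table)
        truths.append(truth)
    combined_truth = {
        "shared_ids": shared_ids,
        "shared_truth": shared_truth,
        study_ids[0]: truths[0],
        study_ids[1]: truths[1],
    }
    return tables[0], tables[1], combined_truth


def simulate_calibration_series(
    levels: Sequence[float] = DEFAULT_CALIBRATION_LEVELS,
    n_reps: int = 3,
    noise_cv: float = 0.10,
    slope: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Surrogate-analyte calibration series: PAR = slope * conc * noise.

    Default levels are the nine-point 0.5-1000 nM series. Returns a tidy
    frame with columns ``nominal_conc, replicate, par``.
    """
    levels = [float(x) for x in levels]
    if any(x <= 0 for x in levels):
        raise ValueError("calibration levels must be positive")
    if len(set(levels)) != len(levels):
        raise ValueError("calibration levels must be distinct")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for conc in levels:
        noise = _lognormal_noise(rng, np.asarray(noise_cv), (n_reps,))
        for r in range(n_reps):
            rows.append({"nominal_conc": conc, "replicate": r, "par": slope * conc * noise[r]})
    return pd.DataFrame(rows)


def simulate_dilution_series(
    factors: Sequence[float] = DEFAULT_DILUTION_FACTORS,
    config: Optional[SimulationConfig] = None,
    n_reps: int = 3,
    seed: Optional[int] = None,
) -> tuple[PeakTable, dict]:
    """Parallel dilution of one pooled plasma: truth PAR(s, f) = abundance(s)/f.

    Default factors are the six-level 1x-8x series. Low-abundance species
    inherit the inflated noise CV from the config.
    """
    factors = [float(f) for f in factors]
    if any(f < 1 for f in factors):
        raise ValueError("dilution factors must be >= 1")
    if len(set(factors)) != len(factors):
        raise ValueError("dilution factors must be distinct")
    if len(factors) < 2:
        raise ValueError("need at least two dilution levels")
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed if seed is None else seed))
    names = config.species_names
    ab = config.abundance_profile().to_numpy()
    cv = config.species_noise_cv().to_numpy()
    rows_meta, areas, truth_rows = [], [], []
    idx = 0
    for rep in range(n_reps):
        for f in factors:
            idx += 1
            truth = ab / f
            noise = _lognormal_noise(rng, cv, (len(names),))
            is_area = config.is_area_mean * _lognormal_noise(
                rng, np.asarray(config.is_area_cv), (1,)
            )[0]
            rows_meta.append(
                {
                    "injection_index": idx,
                    "sample_id": f"DIL-{f:g}x-r{rep}",
                    "role": "dilution",
                    "batch_id": "DIL-B1",
                    "study_id": "DIL",
                    "nominal_dilution": f,
                    "replicate": rep,
                    "is_area": is_area,
                }
            )
            areas.append(truth * noise * is_area)
            truth_rows.append(truth)
    meta = pd.DataFrame(rows_meta)
    long = meta.loc[meta.index.repeat(len(names))].reset_index(drop=True)
    long["analyte"] = np.tile(names, len(meta))
    long["area"] = np.concatenate(areas)
    table = PeakTable(long[
        ["injection_index", "sample_id", "role", "batch_id", "study_id",
         "nominal_dilution", "analyte", "area", "is_area"]
    ])
    truth = {
        "true_par": pd.DataFrame(np.vstack(truth_rows), columns=names),
        "meta": meta,
        "abundance": config.abundance_profile(),
        "factors": factors,
    }
    return table, truth


def simulate_population(
    n_individuals: int = 49,
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
) -> tuple[PeakTable, dict]:
    """A healthy-donor panel: one injection per individual, single batch.

    The per-individual scale is lognormal and shared across species within
    an individual (plus small per-species jitter), so total PI varies more
    than 10-fold across ~49 donors while the composition profile stays
    comparatively stable.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    config = config or SimulationConfig()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    ss_truth, ss_noise = root.spawn(2)
    ids = [f"IND-{i + 1:03d}" for i in range(n_individuals)]
    truth_df = _sample_truth(config, ids, np.random.default_rng(ss_truth))
    rng = np.random.default_rng(ss_noise)
    names = config.species_names
    cv = config.species_noise_cv().to_numpy()
    rows_meta, areas = [], []
    for i, sid in enumerate(ids):
        noise = _lognormal_noise(rng, cv, (len(names),))
        is_area = config.is_area_mean * _lognormal_noise(
            rng, np.asarray(config.is_area_cv), (1,)
        )[0]
        rows_meta.append(
            {
                "injection_index": i + 1,
                "sample_id": sid,
                "role": "population",
                "batch_id": "POP-B1",
                "study_id": "POP",
                "is_area": is_area,
            }
        )
        areas.append(truth_df.loc[sid].to_numpy() * noise * is_area)
    meta = pd.DataFrame(rows_meta)
    long = meta.loc[meta.index.repeat(len(names))].reset_index(drop=True)
    long["analyte"] = np.tile(names, len(meta))
    long["area"] = np.concatenate(areas)
    table = PeakTable(long[
        ["injection_index", "sample_id", "role", "batch_id", "study_id",
         "analyte", "area", "is_area"]
    ])
    return table, {"true_par": truth_df, "abundance": config.abundance_profile()}
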