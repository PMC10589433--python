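"""Synthetic data with known ground truth for every pipeline stage.

Generators for (i) the hypercapnia gas paradigm — 12 minutes alternating
2 min medical air with 3 min 6% CO2-enriched air; (ii) breath-resolved
EtCO2 traces whose underlying level follows a first-order exponential
response to the block stimulus; (iii) ROI-mean BOLD series with known CVR,
hemodynamic delay, linear drift and Gaussian noise; (iv) phantom mask
volumes exercising the mask-conditioning morphology; and (v) patient
cohorts with SVD feature distributions and known regression coefficients
linking features to regional CVR.

The BOLD generator writes

    S_k = S0 * (1 + c/100 * (x_k - mean(x)) + d/100 * (k/n - mean(k/n))) + noise

where x_k is the EtCO2 trace sampled at the (delayed) volume time.  Both
regressors are centred at their temporal means, so in the noiseless case
mean(S) = S0 and the generating CVR ``c`` is exactly the slope of the
percent-of-mean-normalised signal on EtCO2 — i.e. the quantity the
estimator in :mod:`cvrkit.model` recovers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from cvrkit.errors import InvalidArgumentError
from cvrkit.physio import EtCO2Trace, sample_trace, volume_times
from cvrkit.roi import ROIMaskSet

__all__ = [
    "GasParadigm",
    "SimulationConfig",
    "CohortSimConfig",
    "make_gas_paradigm",
    "etco2_level",
    "simulate_etco2",
    "simulate_bold_roi",
    "simulate_phantom_masks",
    "simulate_cohort",
    "calibrate_residual_sd",
    "COHORT_ROIS",
]

COHORT_ROIS = ("sgm", "nawm", "wmh")


@dataclass(frozen=True)
class GasParadigm:
    """Ordered sequence of (gas_state, duration_s) blocks; states alternate."""

    block_sequence: tuple  # of ("air" | "co2", duration_s)
    co2_fraction: float = 0.06

    def __post_init__(self) -> None:
        if not self.block_sequence:
            raise InvalidArgumentError("paradigm must contain at least one block")
        states = [s for s, _ in self.block_sequence]
        durations = [d for _, d in self.block_sequence]
        if any(d <= 0 for d in durations):
            raise InvalidArgumentError("block durations must be positive")
        if any(s not in ("air", "co2") for s in states):
            raise InvalidArgumentError("gas states must be 'air' or 'co2'")
        if any(a == b for a, b in zip(states, states[1:])):
            raise InvalidArgumentError("gas states must alternate")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.block_sequence))

    def block_starts_s(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([d for _, d in self.block_sequence])[:-1]])


def make_gas_paradigm(air_min: float, co2_min: float, total_min: float) -> GasParadigm:
    """Alternating air/CO2 block paradigm starting with air, truncated to fit.

    The default protocol is ``make_gas_paradigm(2, 3, 12)``: 2 min air,
    3 min CO2, repeated over a 12-minute scan.
    """
    if air_min <= 0 or co2_min <= 0 or total_min <= 0:
        raise InvalidArgumentError("all durations must be positive")
    if total_min < air_min:
        raise InvalidArgumentError("total duration must accommodate one full air block")
    blocks = []
    elapsed = 0.0
    state_cycle = (("air", air_min * 60.0), ("co2", co2_min * 60.0))
    total_s = total_min * 60.0
    i = 0
    while elapsed < total_s - 1e-9:
        state, dur = state_cycle[i % 2]
        dur = min(dur, total_s - elapsed)
        blocks.append((state, dur))
        elapsed += dur
        i += 1
    return GasParadigm(block_sequence=tuple(blocks))


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic subject's CVR acquisition.

    Defaults follow the acquisition the package targets: TR 1.55 s over a
    12-minute scan (464 volumes), EtCO2 stepping 8 mmHg above a 38 mmHg
    baseline with a 15 s transition time constant, breaths every 4 s, and an
    NAWM-like generating CVR of 0.042 %/mmHg with a 10 s hemodynamic delay.
    """

    tr_s: float = 1.55
    n_volumes: int = 464
    etco2_baseline_mmHg: float = 38.0
    etco2_delta_mmHg: float = 8.0
    transition_tau_s: float = 15.0
    breath_interval_s: float = 4.0
    breath_jitter_sd_s: float = 0.3
    true_cvr_pct_per_mmHg: float = 0.042
    true_delay_s: float = 10.0
    drift_pct_per_scan: float = 0.0
    noise_sd_pct: float = 0.0
    baseline_signal: float = 1000.0
    volume_timing: str = "middle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise InvalidArgumentError("tr_s must be positive")
        if self.n_volumes < 2:
            raise InvalidArgumentError("n_volumes must be >= 2")
        if self.noise_sd_pct < 0:
            raise InvalidArgumentError("noise_sd_pct must be >= 0")

    @property
    def scan_duration_s(self) -> float:
        return self.n_volumes * self.tr_s


def etco2_level(
    paradigm: GasParadigm,
    times_s: np.ndarray,
    baseline_mmHg: float,
    delta_mmHg: float,
    tau_s: float,
) -> np.ndarray:
    """Noise-free EtCO2 level at arbitrary times.

    The level relaxes exponentially (time constant ``tau_s``) toward
    baseline during air blocks and baseline + delta during CO2 blocks,
    starting from baseline at t = 0.  Piecewise-exact: block-boundary levels
    are propagated recursively, so no numerical integration error.
    """
    if tau_s <= 0:
        raise InvalidArgumentError("transition tau must be positive")
    times = np.asarray(times_s, dtype=float)
    starts = paradigm.block_starts_s()
    durations = np.array([d for _, d in paradigm.block_sequence])
    targets = np.array(
        [baseline_mmHg + (delta_mmHg if s == "co2" else 0.0) for s, _ in paradigm.block_sequence]
    )
    # level at the start of each block, by exact recursion
    start_levels = np.empty(len(starts))
    level = baseline_mmHg
    for i, (tgt, dur) in enumerate(zip(targets, durations)):
        start_levels[i] = level
        level = tgt + (level - tgt) * np.exp(-dur / tau_s)

    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(starts) - 1)
    dt = np.clip(times - starts[idx], 0.0, None)
    out = targets[idx] + (start_levels[idx] - targets[idx]) * np.exp(-dt / tau_s)
    # times past the paradigm end continue relaxing within the final block
    return out


def simulate_etco2(paradigm: GasParadigm, config: SimulationConfig) -> EtCO2Trace:
    """Breath-resolved EtCO2 trace: the exponential block response sampled at
    jittered breath times.  Deterministic for a fixed seed."""
    if config.breath_interval_s <= 0:
        raise InvalidArgumentError("breath_interval_s must be positive")
    rng = np.random.default_rng(config.seed)
    horizon = max(paradigm.total_duration_s, config.scan_duration_s)
    n_breaths = int(np.ceil(horizon / config.breath_interval_s)) + 2
    increments = config.breath_interval_s + rng.normal(
        0.0, config.breath_jitter_sd_s, size=n_breaths
    )
    increments = np.clip(increments, 0.5, None)  # keep breaths strictly ordered
    times = np.cumsum(increments)
    times = times[times <= horizon + config.breath_interval_s]
    values = etco2_level(
        paradigm,
        times,
        config.etco2_baseline_mmHg,
        config.etco2_delta_mmHg,
        config.transition_tau_s,
    )
    return EtCO2Trace(times_s=times, values_mmHg=values, source="simulated")


def simulate_bold_roi(trace: EtCO2Trace, config: SimulationConfig) -> np.ndarray:
    """ROI-mean BOLD series driven by the (delayed) EtCO2 trace.

    Returns an array of length ``config.n_volumes``.  The EtCO2 regressor and
    the linear drift ramp are centred at their temporal means (see module
    docstring), so ``true_cvr_pct_per_mmHg`` is the percent-of-mean signal
    change per mmHg and ``drift_pct_per_scan`` the percent change across the
    whole scan.
    """
    if abs(config.true_delay_s) >= config.scan_duration_s:
        raise InvalidArgumentError("true_delay_s must be smaller than the scan duration")
    times = volume_times(config.n_volumes, config.tr_s, config.volume_timing)
    x = sample_trace(trace, times - config.true_delay_s)
    xc = x - x.mean()
    ramp = np.arange(config.n_volumes) / config.n_volumes
    ramp = ramp - ramp.mean()
    signal = config.baseline_signal * (
        1.0
        + config.true_cvr_pct_per_mmHg / 100.0 * xc
        + config.drift_pct_per_scan / 100.0 * ramp
    )
    if config.noise_sd_pct > 0:
        rng = np.random.default_rng(config.seed)
        signal = signal + rng.normal(
            0.0, config.noise_sd_pct / 100.0 * config.baseline_signal, size=config.n_volumes
        )
    return signal


# ---------------------------------------------------------------------------
# phantom masks


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / max(r, 0.5)) ** 2
    return acc <= 1.0


def simulate_phantom_masks(shape=(32, 32, 32), spacing_mm=(2.5, 2.5, 2.5), seed: int = 0) -> ROIMaskSet:
    """Phantom mask set: nested ellipsoid brain, central ventricles, a WMH
    rim adjacent to the ventricles, lateral SGM blobs, and an NAWM shell.

    Masks are pairwise disjoint by construction; WMH voxels touch the
    ventricle mask (26-connectivity) so the ventricle-dilation subtraction is
    always exercised.  Identical seed and shape give identical volumes.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 16:
        raise InvalidArgumentError("phantom shape must be at least 16 voxels per axis")
    rng = np.random.default_rng(seed)
    center = np.array([(s - 1) / 2.0 for s in shape])
    jitter = rng.integers(-1, 2, size=3)

    brain = _ellipsoid(shape, center, [0.45 * s for s in shape])
    vent = _ellipsoid(
        shape,
        center + jitter * 0.0,
        [0.08 * shape[0], 0.20 * shape[1], 0.10 * shape[2]],
    )
    vent &= brain
    # WMH: shell hugging the ventricles, thick enough that an outer rim
    # survives subtraction of the dilated ventricle mask downstream
    wmh = ndimage.binary_dilation(vent, iterations=4) & ~vent & brain

    sgm = np.zeros(shape, dtype=bool)
    for sign in (-1.0, 1.0):
        c = center + np.array([sign * 0.24 * shape[0], 0.0, 0.0]) + jitter
        sgm |= _ellipsoid(shape, c, [0.09 * s for s in shape])
    sgm &= brain
    sgm &= ~(vent | wmh)

    interior = ndimage.binary_erosion(brain, iterations=2)
    nawm = interior & ~(vent | wmh | sgm)

    masks = {"sgm": sgm, "nawm": nawm, "wmh": wmh, "ventricles": vent}
    for label, m in masks.items():
        if not m.any():
            raise InvalidArgumentError(f"shape {shape} too small to host structure {label!r}")
    affine = np.diag(list(spacing_mm) + [1.0])
    return ROIMaskSet(
        masks=masks,
        voxel_spacing_mm=tuple(spacing_mm),
        affine=affine,
        provenance=[f"simulated phantom seed={seed}"],
    )


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortSimConfig:
    """Generating model for a synthetic SVD patient cohort.

    ``coefficient_map`` maps predictor column names (e.g. ``n_lacunes``,
    ``wmh_log10_pct_icv``, ``svd_score``) to per-ROI true regression
    coefficients in %/mmHg per predictor unit.  Regional CVR is

        CVR_roi = intercept_roi + sum_j B_j,roi * x_j + eps,   eps ~ N(0, sd_roi)

    Defaults reproduce the study conditions: 182 subjects, covariate
    marginals matching the published population summaries, regional CVR
    intercepts at the published medians, and the published missingness
    pattern (7 empty WMH ROIs, 3 missing MoCA, 6 missing PVS volumes).
    """

    n_subjects: int = 182
    coefficient_map: dict = field(default_factory=dict)
    intercepts: dict = field(
        default_factory=lambda: {"sgm": 0.171, "nawm": 0.042, "wmh": 0.040}
    )
    residual_sd: dict = field(
        default_factory=lambda: {"sgm": 0.053, "nawm": 0.016, "wmh": 0.029}
    )
    wmh_cvr_missing_n: int = 7
    moca_missing_n: int = 3
    pvs_volume_missing_n: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < len(self.coefficient_map) + 2:
            raise InvalidArgumentError("n_subjects must exceed the number of model terms + 2")
        if any(sd <= 0 for sd in self.residual_sd.values()):
            raise InvalidArgumentError("residual SDs must be positive")


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariate and SVD-feature draws matching the published Table-1 marginals."""
    df = pd.DataFrame(index=range(n))
    df["subject_id"] = [f"sub-{i:04d}" for i in range(n)]
    df["age_years"] = np.clip(rng.normal(66.0, 14.0, n), 35.0, 95.0)
    df["sex"] = np.where(rng.random(n) < 0.68, "male", "female")
    df["map_mmHg"] = rng.normal(106.0, 12.0, n)
    df["smoking"] = rng.choice(
        ["current_recent", "ex_gt1y", "never"], size=n, p=[0.15, 0.39, 0.46]
    )
    df["hypertension"] = (rng.random(n) < 0.70).astype(int)
    df["diabetes"] = (rng.random(n) < 0.20).astype(int)
    df["hypercholesterolaemia"] = (rng.random(n) < 0.74).astype(int)
    # WMH volume: log10(%ICV) ~ N(log10(0.51), 0.50) -> median 0.51, IQR ~[0.24, 1.14]
    df["wmh_pct_icv"] = 10.0 ** rng.normal(np.log10(0.51), 0.50, n)
    df["fazekas_pv"] = rng.choice([0, 1, 2, 3], size=n, p=[0.10, 0.45, 0.30, 0.15])
    df["fazekas_deep"] = rng.choice([0, 1, 2, 3], size=n, p=[0.10, 0.45, 0.30, 0.15])
    df["fazekas_total"] = df["fazekas_pv"] + df["fazekas_deep"]
    # lacunes: geometric with mean 1.9 -> median 1, IQR [0, 3]
    df["n_lacunes"] = rng.negative_binomial(1, 1.0 / 2.9, n)
    # microbleeds: zero-inflated (80% zero), geometric mean 3 among carriers
    carrier = rng.random(n) < 0.20
    df["n_microbleeds"] = np.where(carrier, rng.negative_binomial(1, 0.25, n), 0)
    df["atrophy_deep"] = rng.binomial(6, 0.5, n)
    df["atrophy_superficial"] = rng.binomial(6, 0.5, n)
    df["atrophy_total"] = df["atrophy_deep"] + df["atrophy_superficial"]
    df["brain_pct_icv"] = np.clip(rng.normal(67.5, 4.7, n), 45.0, 90.0)
    df["pvs_bg_score"] = rng.choice([0, 1, 2, 3, 4], size=n, p=[0.10, 0.25, 0.30, 0.25, 0.10])
    df["pvs_cso_score"] = rng.choice([0, 1, 2, 3, 4], size=n, p=[0.05, 0.15, 0.45, 0.25, 0.10])
    df["pvs_total_score"] = df["pvs_bg_score"] + df["pvs_cso_score"]
    df["pvs_bg_pct_roiv"] = 10.0 ** rng.normal(np.log10(4.9), 0.20, n)
    df["pvs_cso_pct_roiv"] = 10.0 ** rng.normal(np.log10(3.3), 0.30, n)
    df["pvs_total_pct_roiv"] = 10.0 ** rng.normal(np.log10(3.6), 0.28, n)
    df["svd_score"] = rng.choice([0, 1, 2, 3, 4], size=n, p=[0.30, 0.30, 0.20, 0.15, 0.05])
    df["nihss"] = rng.poisson(1.3, n)
    df["mrs"] = rng.choice([0, 1, 2], size=n, p=[0.15, 0.65, 0.20])
    df["moca"] = np.clip(np.round(rng.normal(24.3, 3.6, n)), 0, 30)
    df["wmh_log10_pct_icv"] = np.log10(df["wmh_pct_icv"])
    return df


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Draw a synthetic cohort table with known CVR generating coefficients.

    If a predictor named in ``coefficient_map`` comes out constant (singular
    design), a warning is issued and the cohort is regenerated with the next
    seed.
    """
    seed = config.seed
    for _attempt in range(5):
        rng = np.random.default_rng(seed)
        df = _simulate_covariates(config.n_subjects, rng)
        bad = [
            k
            for k in config.coefficient_map
            if k not in df.columns or df[k].std() == 0
        ]
        unknown = [k for k in config.coefficient_map if k not in df.columns]
        if unknown:
            raise InvalidArgumentError(f"unsupported predictors in coefficient_map: {unknown}")
        if not bad:
            break
        warnings.warn(
            f"singular design (constant predictor {bad}); regenerating with seed {seed + 1}"
        )
        seed += 1
    for roi in COHORT_ROIS:
        mu = np.full(config.n_subjects, config.intercepts.get(roi, 0.0))
        for pred, per_roi in config.coefficient_map.items():
            beta = per_roi.get(roi, 0.0) if isinstance(per_roi, dict) else float(per_roi)
            mu = mu + beta * df[pred].to_numpy(dtype=float)
        eps = rng.normal(0.0, config.residual_sd.get(roi, 0.0), config.n_subjects)
        df[f"cvr_{roi}"] = mu + eps
    # published missingness pattern
    if config.wmh_cvr_missing_n:
        idx = rng.choice(config.n_subjects, size=config.wmh_cvr_missing_n, replace=False)
        df.loc[idx, "cvr_wmh"] = np.nan
    if config.moca_missing_n:
        idx = rng.choice(config.n_subjects, size=config.moca_missing_n, replace=False)
        df.loc[idx, "moca"] = np.nan
    if config.pvs_volume_missing_n:
        idx = rng.choice(config.n_subjects, size=config.pvs_volume_missing_n, replace=False)
        df.loc[idx, ["pvs_bg_pct_roiv", "pvs_cso_pct_roiv", "pvs_total_pct_roiv"]] = np.nan
    df.attrs["seed"] = config.seed
    return df


def calibrate_residual_sd(
    ci_low: float,
    ci_high: float,
    predictor_sd: float,
    n: int,
    n_model_params: int = 10,
) -> float:
    """Back-solve the residual SD that reproduces a printed 95% CI width.

    For OLS with the focal predictor independent of the other covariates,
    SE(B) ~= sigma / (sd(x) * sqrt(n)); the printed CI half-width equals
    t_{0.975, n - p} * SE(B).  ``n_model_params`` is p, the number of
    regression parameters including the intercept (10 for the adjusted
    models: intercept, predictor, age, sex, MAP, 2 smoking contrasts, and 3
    vascular-risk diagnoses).
    """
    if ci_high <= ci_low:
        raise InvalidArgumentError("ci_high must exceed ci_low")
    if predictor_sd <= 0 or n <= n_model_params:
        raise InvalidArgumentError("need positive predictor SD and n > n_model_params")
    half_width = (ci_high - ci_low) / 2.0
    se = half_width / stats.t.ppf(0.975, n - n_model_params)
    return se * predictor_sd * np.sqrt(n)
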