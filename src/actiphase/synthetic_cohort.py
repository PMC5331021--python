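"""Synthetic inpatient cohorts: minute-level activity series + demographics.

No raw recordings are deposited for the study population this package
targets, so a generator stands in: it emulates ~22-h wrist-actigraphy
recordings (1-min epochs, starting mid-day) for inpatients in one of
three acute bipolar phases, such that the twelve extracted active-period
features reproduce the published phase-specific group means.

Mechanism (each knob maps monotonically to one target feature):

- a piecewise circadian envelope: a low zero-inflated night level
  (00:00–06:00) and phase-specific stationary day regimes for the
  morning (06:00–15:00) and evening (15:00–24:00) windows;
- within a day regime, counts are X_t = μ·ℓ·((1−β) + β·L_t) where
  L_t = f(G_t) is a mean-1 gamma marginal obtained by quantile
  transform of a standard Gaussian latent G_t that mixes an AR(1)
  with white noise:
  * the gamma shape is set analytically from the target coefficient
    of variation,
  * the latent lag-1 correlation is solved through the Hermite
    expansion of f (which maps latent to observed autocorrelations)
    from the target lag-1 autocorrelation, with a small-sample bias
    adjustment for 64-point segments,
  * the AR(1) coefficient φ is solved by bisection so the exact
    finite-n expected periodogram of the process ACF matches the
    target high/low-frequency variance ratio,
  * β ∈ (0, 1] ("burstiness") shapes the marginal at fixed CV — small β
    means a steady base with occasional large bursts, whose
    standardized segments are more self-similar — and is the
    sample-entropy knob;
- ℓ is a subject-level lognormal multiplier (between-subject spread of
  mean level), and small mean-preserving jitters on the CV, lag-1 and
  spectral targets give the group means realistic subject-to-subject
  scatter; RMSSD needs no knob of its own because the published values
  are jointly consistent with SD% and lag-1 autocorrelation
  (RMSSD ≈ SD·sqrt(2(1−r₁))).

Because 64-point sample statistics of skewed, autocorrelated counts are
biased relative to their population values, each phase-period carries
four small frozen calibration constants (``cv_gain``, ``r1_shift``,
``fourier_gain``, ``burstiness``) determined once by the iterative
Monte-Carlo routine :func:`calibrate_profiles`, which pushes the mean
*extracted* features (through the real slice → active-period → feature
pipeline) onto the targets.

Counts are rounded and floored at zero; identical config + seed gives
bit-identical cohorts (one spawned random stream per subject).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .actigraphy_io import MinuteSeries
from .errors import ConfigurationError

__all__ = [
    "PeriodTargets",
    "PhaseProfile",
    "ZeroRunInjection",
    "GeneratorConfig",
    "default_profiles",
    "default_config",
    "generate_subject",
    "generate_cohort",
    "calibrate_profiles",
]

SEGMENT_LENGTH = 64

#: Additive small-sample bias adjustment for the lag-1 correlogram at n=64:
#: E[r̂₁] ≈ ρ − (1 + 3ρ)/n, so the population target is raised by (1+3ρ)/n.
_R1_BIAS_N = SEGMENT_LENGTH


@dataclass(frozen=True)
class PeriodTargets:
    """Target feature values for one day period of one phase, plus the
    frozen Monte-Carlo calibration constants of the generator."""

    mean_cpm: float
    sd_pct: float
    rmssd_pct: float
    autocorr_lag1: float
    sampen: float
    fourier_ratio: float
    #: SampEn calibration knob, ∈ (0, 1]: fraction of the level carried by
    #: the gamma burst component (1 = plain gamma marginal).
    burstiness: float = 1.0
    #: multiplicative correction from target SD% to the population CV fed
    #: to the process (compensates 64-point sample-SD shrinkage)
    cv_gain: float = 1.0
    #: additive correction to the lag-1 target beyond the analytic
    #: small-sample adjustment
    r1_shift: float = 0.0
    #: multiplicative correction from target band ratio to the analytic
    #: expected-periodogram target (Jensen gap of the ratio statistic)
    fourier_gain: float = 1.0

    def validate(self) -> None:
        values = [
            self.mean_cpm,
            self.sd_pct,
            self.rmssd_pct,
            self.autocorr_lag1,
            self.sampen,
            self.fourier_ratio,
            self.burstiness,
        ]
        if not all(np.isfinite(values)):
            raise ConfigurationError("non-finite period target")
        if not -1.0 < self.autocorr_lag1 < 1.0:
            raise ConfigurationError("autocorr_lag1 must lie strictly inside (-1, 1)")
        if min(self.mean_cpm, self.sd_pct, self.rmssd_pct, self.sampen, self.fourier_ratio) < 0:
            raise ConfigurationError("targets must be non-negative")
        if not 0.0 < self.burstiness <= 1.0:
            raise ConfigurationError("burstiness must be in (0, 1]")


@dataclass(frozen=True)
class PhaseProfile:
    """Per-phase generator targets: feature means, demographics, cohort share."""

    phase: str
    morning: PeriodTargets
    evening: PeriodTargets
    age_mean: float
    age_sd: float
    group_fraction: float

    def validate(self) -> None:
        self.morning.validate()
        self.evening.validate()
        if not (np.isfinite(self.age_mean) and np.isfinite(self.age_sd) and self.age_sd > 0):
            raise ConfigurationError(f"{self.phase}: invalid age distribution")
        if not 0 < self.group_fraction <= 1:
            raise ConfigurationError(f"{self.phase}: invalid group fraction")


@dataclass(frozen=True)
class ZeroRunInjection:
    """Optional rule placing runs of zero counts inside the day windows to
    exercise the active-period tolerance search."""

    run_length: int
    runs_per_window: int

    def validate(self) -> None:
        if self.run_length < 1 or self.runs_per_window < 0:
            raise ConfigurationError("invalid zero-run injection rule")


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 34
    seed: int = 0
    recording_hours: float = 22.0
    recording_start_clock: str = "12:41"
    recording_date: str = "2017-01-02"
    epoch_seconds: int = 60
    phase_profiles: tuple[PhaseProfile, ...] = ()
    female_fraction: float = 0.56
    min_age: float = 18.0
    #: between-subject CV of the subject level multiplier ℓ
    level_cv: float = 0.45
    #: lognormal sd of the per-period CV jitter
    cv_jitter: float = 0.10
    #: additive sd of the per-period lag-1 target jitter
    r1_jitter: float = 0.07
    #: lognormal sd of the per-period spectral-ratio target jitter
    fourier_jitter: float = 0.15
    night_mean_cpm: float = 20.0
    night_active_fraction: float = 0.5
    zero_run_injection: ZeroRunInjection | None = None

    def validate(self, stratified: bool = True) -> None:
        profiles = self.phase_profiles or default_profiles()
        if self.epoch_seconds != 60:
            raise ConfigurationError("epoch length is fixed at 60 s")
        if stratified and self.n_subjects < len(profiles):
            raise ConfigurationError(
                f"n_subjects={self.n_subjects} cannot cover {len(profiles)} phases"
            )
        total = sum(p.group_fraction for p in profiles)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"group fractions sum to {total}, expected 1")
        for profile in profiles:
            profile.validate()
        if self.zero_run_injection is not None:
            self.zero_run_injection.validate()

    def resolved_profiles(self) -> tuple[PhaseProfile, ...]:
        return self.phase_profiles or default_profiles()


def default_profiles() -> tuple[PhaseProfile, ...]:
    """The three study phase profiles.

    Feature targets are the published phase-specific group means for the
    64-min active morning/evening periods; ages are the group means with
    SDs back-computed from the reported t-based 95% CIs at the group
    sizes (n = 12, 16, 6); group fractions are the study's 12/34, 16/34,
    6/34 split. Burstiness values are the frozen sample-entropy
    calibration for this generator.
    """
    return (
        PhaseProfile(
            phase="bipolar_depression",
            morning=PeriodTargets(
                218.53, 117.42, 108.12, 0.56, 1.05, 0.67,
                burstiness=1.0000, cv_gain=1.0885, r1_shift=0.0405, fourier_gain=1.3364,
            ),
            evening=PeriodTargets(
                154.86, 129.48, 124.81, 0.53, 1.03, 0.77,
                burstiness=1.0000, cv_gain=1.0876, r1_shift=0.0419, fourier_gain=1.4076,
            ),
            age_mean=39.92,
            age_sd=15.62,
            group_fraction=12 / 34,
        ),
        PhaseProfile(
            phase="mania",
            morning=PeriodTargets(
                229.80, 90.04, 88.75, 0.49, 1.41, 0.90,
                burstiness=1.0000, cv_gain=1.0434, r1_shift=0.0139, fourier_gain=1.8486,
            ),
            evening=PeriodTargets(
                239.34, 92.11, 90.75, 0.49, 1.36, 1.05,
                burstiness=0.9776, cv_gain=1.0624, r1_shift=0.0238, fourier_gain=3.6307,
            ),
            age_mean=51.22,
            age_sd=14.34,
            group_fraction=16 / 34,
        ),
        PhaseProfile(
            phase="mixed",
            morning=PeriodTargets(
                281.72, 85.68, 84.71, 0.51, 1.55, 0.97,
                burstiness=1.0000, cv_gain=1.0361, r1_shift=0.0038, fourier_gain=3.3399,
            ),
            evening=PeriodTargets(
                254.49, 111.13, 97.61, 0.60, 0.96, 0.58,
                burstiness=1.0000, cv_gain=1.0720, r1_shift=0.0405, fourier_gain=1.3474,
            ),
            age_mean=42.00,
            age_sd=14.62,
            group_fraction=6 / 34,
        ),
    )


def default_config(n_subjects: int = 34, seed: int = 0) -> GeneratorConfig:
    return GeneratorConfig(n_subjects=n_subjects, seed=seed, phase_profiles=default_profiles())


# ---------------------------------------------------------------------------
# latent-process solving

_HERMITE_TERMS = 40
_QUAD_NODES = 240


def _hermite_weights(cv_l: float) -> np.ndarray:
    """Squared-coefficient weights w_j = c_j²·j! of the Hermite expansion
    of the mean-1 gamma quantile transform f(z) = Qγ(Φ(z); k)/k with
    shape k = 1/cv_l².

    The latent→observed autocorrelation map is then
    r_X(ρ) = Σ_{j≥1} w_j ρ^j / Σ_{j≥1} w_j.
    """
    shape = 1.0 / (cv_l * cv_l)
    nodes, quad_w = np.polynomial.hermite_e.hermegauss(_QUAD_NODES)
    quad_w = quad_w / math.sqrt(2 * math.pi)
    u = np.clip(stats.norm.cdf(nodes), 1e-300, 1.0 - 1e-14)
    f_vals = stats.gamma.ppf(u, a=shape) / shape
    weights = np.empty(_HERMITE_TERMS)
    log_fact = 0.0
    for j in range(1, _HERMITE_TERMS + 1):
        basis = np.polynomial.hermite_e.hermeval(nodes, [0.0] * j + [1.0])
        log_fact += math.log(j)
        c_j = float(quad_w @ (f_vals * basis)) / math.exp(log_fact)
        weights[j - 1] = c_j * c_j * math.exp(log_fact)
    return weights


def _gamma_sample(rng_latent: np.ndarray, cv_l: float) -> np.ndarray:
    """Map standard-normal latent values through the mean-1 gamma
    quantile transform with CV ``cv_l``."""
    shape = 1.0 / (cv_l * cv_l)
    u = np.clip(stats.norm.cdf(rng_latent), 1e-300, 1.0 - 1e-14)
    return stats.gamma.ppf(u, a=shape) / shape


def _expected_band_ratio(acf: np.ndarray, n: int = SEGMENT_LENGTH) -> float:
    """HF/LF band ratio of the exact finite-n expected periodogram of a
    stationary process with the given ACF (lags 0..n−1)."""
    lags = np.arange(1, n)
    taper = 1.0 - lags / n
    k = np.arange(1, n // 2 + 1)
    cosines = np.cos(2 * np.pi * np.outer(k, lags) / n)
    power = acf[0] + 2.0 * cosines @ (taper * acf[1:])
    power = np.clip(power, 0.0, None)
    weights = np.full(k.size, 2.0)
    weights[-1] = 1.0  # Nyquist
    bin_var = weights * power
    lf = bin_var[: n // 8].sum()  # periods 8..n min  (k = 1..n/8)
    hf = bin_var[n // 8 :].sum()  # periods 2..8 min  (k = n/8+1..n/2)
    if lf <= 0:
        return np.inf
    return float(hf / lf)


def _solve_period_process(
    cv: float, r1_measured: float, fourier_ratio: float, burstiness: float
) -> tuple[float, float, float]:
    """Map (CV, lag-1 target, band ratio, β) to latent knobs (cv_l, φ, w).

    The gamma CV comes from the marginal identity SD_X/μ = β·CV_L; the
    latent lag-1 correlation c₁ from inverting the Hermite ACF map at
    the bias-adjusted lag-1 target; φ from a bisection matching the
    expected-periodogram band ratio, with white-noise share w = 1−c₁/φ.
    """
    cv_l = cv / burstiness
    weights = _hermite_weights(cv_l)
    total = weights.sum()
    powers = np.arange(1, _HERMITE_TERMS + 1)

    def acf_map(rho: np.ndarray) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        return (rho[..., None] ** powers @ weights) / total

    r1_pop = min(r1_measured + (1.0 + 3.0 * r1_measured) / _R1_BIAS_N, 0.98)
    if acf_map(np.array(0.9995)) <= r1_pop:
        c1 = 0.9995
    else:
        c1 = brentq(lambda rho: acf_map(np.array(rho)) - r1_pop, 1e-6, 0.9995, xtol=1e-8)

    lags = np.arange(SEGMENT_LENGTH)

    def acf_x(phi: float) -> np.ndarray:
        r_g = np.empty(SEGMENT_LENGTH)
        r_g[0] = 1.0
        r_g[1:] = c1 * phi ** (lags[1:] - 1.0)
        return np.concatenate(([1.0], acf_map(r_g[1:])))

    def objective(phi: float) -> float:
        return _expected_band_ratio(acf_x(phi)) - fourier_ratio

    # The band ratio is U-shaped in φ: a pure AR(1) at φ=c1 is the most
    # high-frequency ACF, larger φ smooths the segment, but as φ→1 the
    # within-window process degenerates to constant + white (flat
    # demeaned spectrum) and the ratio rises again. Bisect only on the
    # decreasing branch up to the interior minimum.
    lo, hi = c1, 0.995
    grid = np.linspace(lo, hi, 25)
    values = np.array([objective(phi) for phi in grid])
    i_min = int(np.argmin(values))
    if values[0] <= 0:  # even the fastest-decaying ACF is too smooth
        phi = lo
    elif values[i_min] >= 0:  # target smoother than achievable: closest point
        phi = float(grid[i_min])
    else:
        hi_branch = float(grid[i_min]) if i_min > 0 else hi
        phi = brentq(objective, lo, hi_branch, xtol=1e-6)
    w = 1.0 - c1 / phi
    return cv_l, phi, min(max(w, 0.0), 1.0)


def _simulate_regime(
    rng: np.random.Generator,
    n_minutes: int,
    level: float,
    targets: PeriodTargets,
    cv: float,
    r1: float,
    fourier: float,
) -> np.ndarray:
    """One stationary day-regime series of float intensities (counts/min)."""
    if cv < 1e-9:  # degenerate noise-free regime: constant level
        return np.full(n_minutes, level)
    cv_l, phi, w = _solve_period_process(cv, r1, fourier, targets.burstiness)
    eps = rng.standard_normal(n_minutes)
    ar = np.empty(n_minutes)
    ar[0] = eps[0]
    scale = math.sqrt(1.0 - phi * phi)
    for t in range(1, n_minutes):
        ar[t] = phi * ar[t - 1] + scale * eps[t]
    latent = math.sqrt(1.0 - w) * ar + math.sqrt(w) * rng.standard_normal(n_minutes)
    bursts = _gamma_sample(latent, cv_l)
    beta = targets.burstiness
    return level * ((1.0 - beta) + beta * bursts)


def _minute_regimes(start_minute_of_day: int, n_minutes: int) -> np.ndarray:
    """Regime id per minute: 0 night (<06:00), 1 morning, 2 evening."""
    minute_of_day = (start_minute_of_day + np.arange(n_minutes)) % 1440
    regime = np.zeros(n_minutes, dtype=np.int8)
    regime[(minute_of_day >= 360) & (minute_of_day < 900)] = 1
    regime[minute_of_day >= 900] = 2
    return regime


def generate_subject(
    profile: PhaseProfile,
    seed,
    subject_id: str = "S001",
    config: GeneratorConfig | None = None,
) -> MinuteSeries:
    """Generate one subject's ~22-h minute-count recording.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; the same
    profile and seed always produce the identical series.
    """
    cfg = config if config is not None else GeneratorConfig()
    profile.validate()
    rng = np.random.default_rng(seed)
    n_minutes = int(round(cfg.recording_hours * 60))
    hour, minute = map(int, cfg.recording_start_clock.split(":"))
    start_minute = hour * 60 + minute
    start_time = pd.Timestamp(f"{cfg.recording_date} {cfg.recording_start_clock}")

    # subject-level draws (one stream: adding knobs never perturbs peers)
    tau = math.sqrt(math.log1p(cfg.level_cv**2))
    level_mult = math.exp(tau * rng.standard_normal() - 0.5 * tau * tau)
    period_knobs = {}
    for name, targets in (("morning", profile.morning), ("evening", profile.evening)):
        cv = (targets.sd_pct / 100.0) * targets.cv_gain * math.exp(
            cfg.cv_jitter * rng.standard_normal() - 0.5 * cfg.cv_jitter**2
        )
        r1 = float(
            np.clip(
                targets.autocorr_lag1
                + targets.r1_shift
                + cfg.r1_jitter * rng.standard_normal(),
                0.05,
                0.90,
            )
        )
        fourier = (
            targets.fourier_ratio
            * targets.fourier_gain
            * math.exp(cfg.fourier_jitter * rng.standard_normal() - 0.5 * cfg.fourier_jitter**2)
        )
        period_knobs[name] = (cv, r1, fourier)

    regimes = _minute_regimes(start_minute, n_minutes)
    intensity = np.zeros(n_minutes)
    for regime_id, name, targets in (
        (1, "morning", profile.morning),
        (2, "evening", profile.evening),
    ):
        mask = regimes == regime_id
        if mask.any():
            cv, r1, fourier = period_knobs[name]
            level = targets.mean_cpm * level_mult
            intensity[mask] = _simulate_regime(
                rng, int(mask.sum()), level, targets, cv, r1, fourier
            )
    night = regimes == 0
    if night.any():
        n_night = int(night.sum())
        night_counts = rng.poisson(cfg.night_mean_cpm, size=n_night) * (
            rng.random(n_night) < cfg.night_active_fraction
        )
        intensity[night] = night_counts

    counts = np.clip(np.round(intensity), 0, None).astype(np.int64)

    if cfg.zero_run_injection is not None:
        rule = cfg.zero_run_injection
        for regime_id in (1, 2):
            idx = np.flatnonzero(regimes == regime_id)
            if idx.size < rule.run_length:
                continue
            for _ in range(rule.runs_per_window):
                at = int(rng.integers(0, idx.size - rule.run_length + 1))
                counts[idx[at : at + rule.run_length]] = 0

    return MinuteSeries(subject_id, start_time, counts)


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    base = [int(math.floor(v)) for v in raw]
    short = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def generate_cohort(config: GeneratorConfig) -> tuple[list[MinuteSeries], pd.DataFrame]:
    """Generate a stratified cohort: one recording per subject plus a
    subject table (subject_id, phase, age, gender).

    Phase counts follow the profile group fractions by largest-remainder
    rounding; ages are normal per phase (truncated at ``min_age``);
    gender is Bernoulli(female_fraction).
    """
    config.validate(stratified=True)
    profiles = config.resolved_profiles()
    sizes = _largest_remainder(config.n_subjects, [p.group_fraction for p in profiles])
    if min(sizes) < 1:
        raise ConfigurationError("a phase received zero subjects; increase n_subjects")

    root = np.random.SeedSequence(config.seed)
    demo_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.spawn(config.n_subjects + 1)[1:]

    series: list[MinuteSeries] = []
    rows = []
    k = 0
    for profile, size in zip(profiles, sizes):
        for _ in range(size):
            subject_id = f"S{k + 1:03d}"
            age = float(demo_rng.normal(profile.age_mean, profile.age_sd))
            while age < config.min_age:
                age = float(demo_rng.normal(profile.age_mean, profile.age_sd))
            gender = "female" if demo_rng.random() < config.female_fraction else "male"
            series.append(
                generate_subject(profile, subject_seeds[k], subject_id=subject_id, config=config)
            )
            rows.append(
                {
                    "subject_id": subject_id,
                    "phase": profile.phase,
                    "age": round(age, 1),
                    "gender": gender,
                }
            )
            k += 1
    subjects = pd.DataFrame(rows)
    return series, subjects


def write_cohort_csv(series: Sequence[MinuteSeries], path) -> None:
    """Write generated minute-count series as one cohort CSV
    (subject_id, timestamp, activity_count)."""
    from .actigraphy_io import write_minute_series

    write_minute_series(series, path)


# ---------------------------------------------------------------------------
# Monte-Carlo calibration of the per-period correction constants


def _mean_extracted_features(
    profile: PhaseProfile, config: GeneratorConfig, n_replicates: int, seed
) -> dict[str, dict[str, float]]:
    """Mean features per period over replicate subjects, extracted through
    the real slice → active-period → feature pipeline."""
    from .actigraphy_io import EVENING, MORNING, slice_window
    from .active_period import find_active_segment
    from .errors import UndefinedFeatureError
    from .features import compute_features

    sums: dict[str, dict[str, float]] = {
        "morning": {}, "evening": {},
    }
    counts = {"morning": 0, "evening": 0}
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for child in root.spawn(n_replicates):
        series = generate_subject(profile, child, config=config)
        for window, direction in ((MORNING, "forward"), (EVENING, "backward")):
            sub = slice_window(series, window)
            segment = find_active_segment(sub, direction, window_label=window.label)
            try:
                values = compute_features(segment.counts).as_dict()
            except UndefinedFeatureError:
                continue
            bucket = sums[window.label]
            for name, value in values.items():
                bucket[name] = bucket.get(name, 0.0) + value
            counts[window.label] += 1
    return {
        label: {name: total / counts[label] for name, total in bucket.items()}
        for label, bucket in sums.items()
    }


def calibrate_profiles(
    profiles: Sequence[PhaseProfile] | None = None,
    n_replicates: int = 150,
    n_rounds: int = 6,
    seed: int = 20170301,
    damping: float = 0.8,
    config: GeneratorConfig | None = None,
    verbose: bool = False,
) -> tuple[PhaseProfile, ...]:
    """Iteratively fit the per-period correction constants.

    Each round simulates ``n_replicates`` subjects per phase, extracts the
    12 features through the real pipeline, and nudges ``cv_gain``
    (multiplicatively, toward the SD% target), ``r1_shift`` (additively),
    ``fourier_gain`` (multiplicatively) and ``burstiness``
    (multiplicatively on the SampEn mismatch, clipped to (0.05, 1]).
    This is how the frozen constants in :func:`default_profiles` were
    produced; rerunning it reproduces them up to Monte-Carlo noise.
    """
    profiles = tuple(profiles) if profiles is not None else default_profiles()
    base_cfg = config if config is not None else GeneratorConfig()
    root = np.random.SeedSequence(seed)
    for round_idx in range(n_rounds):
        updated = []
        for profile in profiles:
            measured = _mean_extracted_features(profile, base_cfg, n_replicates, root.spawn(1)[0])
            new_periods = {}
            for label in ("morning", "evening"):
                t: PeriodTargets = getattr(profile, label)
                m = measured[label]
                new_periods[label] = replace(
                    t,
                    cv_gain=float(
                        np.clip(t.cv_gain * (t.sd_pct / m["sd_pct"]) ** damping, 0.7, 2.2)
                    ),
                    r1_shift=float(
                        np.clip(
                            t.r1_shift + damping * (t.autocorr_lag1 - m["autocorr_lag1"]),
                            -0.25,
                            0.3,
                        )
                    ),
                    fourier_gain=float(
                        np.clip(
                            t.fourier_gain * (t.fourier_ratio / m["fourier_ratio"]) ** damping,
                            0.25,
                            4.0,
                        )
                    ),
                    burstiness=float(
                        np.clip(t.burstiness * (t.sampen / m["sampen"]) ** damping, 0.05, 1.0)
                    ),
                )
                if verbose:
                    print(
                        f"round {round_idx + 1} {profile.phase}/{label}: "
                        + ", ".join(f"{k}={m[k]:.3f}" for k in sorted(m))
                    )
            updated.append(replace(profile, morning=new_periods["morning"], evening=new_periods["evening"]))
        profiles = tuple(updated)
        if verbose:
            for profile in profiles:
                for label in ("morning", "evening"):
                    t = getattr(profile, label)
                    print(
                        f"  -> {profile.phase}/{label}: burstiness={t.burstiness:.3f} "
                        f"cv_gain={t.cv_gain:.3f} r1_shift={t.r1_shift:+.3f} "
                        f"fourier_gain={t.fourier_gain:.3f}"
                    )
    return profiles
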