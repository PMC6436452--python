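"""Synthetic listener cohorts with trial-by-trial progressive-track responses.

The generator emulates the normative study's cohort end to end:

1. demographics — age from a truncated normal on [18, 80] whose realized
   mean/SD match the study sample (46.74 / 18.66 years), and bilateral
   standard PTA from a truncated linear-Gaussian model given age, calibrated
   so the marginal PTA has mean 12.48 dB HL, SD 8.89, support [0, 45], and
   an age–PTA correlation of .51;
2. latent thresholds — each listener's true colocated and separated TMR
   thresholds follow the published average-run normative regressions plus an
   individual deviation whose SD equals the model error, with a persistent
   component shared between runs and a practice improvement applied to the
   run-2 latent threshold (−0.7 dB colocated, −1.4 dB separated);
3. responses — every trial of the 20-trial descending track is a Bernoulli
   draw from a logistic psychometric function with a 1/32 guessing floor
   (closed response set of 4 colors × 8 numbers) and no lapses.

Latent thresholds are expressed on the estimator's scale: by default the
psychometric function is positioned so the progressive track's expected
estimate equals the latent threshold (see :func:`track_location`).  All
sampling is driven by a single seeded :class:`numpy.random.Generator`, so a
given config + seed reproduces a cohort bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scoring import estimate_threshold, synthesize_audiogram
from .types import (
    AUDIOGRAM_FREQS,
    CONDITIONS,
    CohortTable,
    NormativeModel,
    ParticipantRecord,
    TrialBlock,
    TRACK_LEVELS,
    TRACK_SCHEDULE,
    format_freq,
)

# Published average-run normative coefficients used as generative truth.
GENERATIVE_COLOCATED = NormativeModel(
    condition="colocated", run="average", predictors=("age",),
    constant=0.549, beta_age=0.033, model_error=1.045,
)
GENERATIVE_SEPARATED = NormativeModel(
    condition="separated", run="average", predictors=("age", "pta"),
    constant=-8.617, beta_age=0.053, beta_pta=0.164, model_error=1.864,
)
GENERATIVE_SRM = NormativeModel(
    condition="srm", run="average", predictors=("pta",),
    constant=9.166, beta_pta=-0.171, model_error=1.830,
)

#: Retest-delay mixture: (category, lo days, hi days, count in the study cohort).
RETEST_DELAY_MIXTURE: tuple[tuple[str, int, int, int], ...] = (
    ("same_day", 0, 0, 16),
    ("day_to_week", 1, 7, 7),
    ("week_to_month", 8, 30, 12),
    ("month_to_year", 31, 365, 14),
    ("over_year", 366, 1095, 33),
)


@dataclass
class GenerativeConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the normative study's cohort structure; the
    psychometric slope and the between-run persistence are not reported for
    these listeners and are documented, configurable assumptions.
    """

    n: int = 82
    seed: int = 0
    # age: truncated normal calibrated to the realized sample moments
    age_mean: float = 46.74
    age_sd: float = 18.66
    age_bounds: tuple[float, float] = (18.0, 80.0)
    # PTA | age: truncated linear-Gaussian, calibrated to the marginal targets
    pta_mean: float = 12.48
    pta_sd: float = 8.89
    pta_bounds: tuple[float, float] = (0.0, 45.0)
    age_pta_corr: float = 0.51
    # latent threshold structure
    colocated_model: NormativeModel = field(
        default_factory=lambda: replace(GENERATIVE_COLOCATED)
    )
    separated_model: NormativeModel = field(
        default_factory=lambda: replace(GENERATIVE_SEPARATED)
    )
    deviation_sd: dict = field(
        default_factory=lambda: {"colocated": 1.045, "separated": 1.864}
    )
    run_persistence: float = 0.8  # corr of the individual deviation across runs
    practice_run2: dict = field(
        default_factory=lambda: {"colocated": -0.7, "separated": -1.4}
    )
    # psychometric listener
    slope: float = 2.0  # dB, logistic scale parameter
    chance: float = 1.0 / 32.0  # closed set: 4 colors x 8 numbers
    track_calibration: bool = True
    # cosmetic demographics
    male_fraction: float = 49.0 / 82.0
    hearing_aid_rate: float = 5.0 / 82.0
    srt_offset_sd: float = 2.0

    def model_for(self, condition: str) -> NormativeModel:
        return {"colocated": self.colocated_model, "separated": self.separated_model}[
            condition
        ]

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size n must be positive")
        for name in ("age_sd", "pta_sd", "srt_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if any(sd < 0 for sd in self.deviation_sd.values()):
            raise ValueError("deviation SDs must be nonnegative")
        for name in ("age_bounds", "pta_bounds"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} out of order")
        if not 0.0 <= self.run_persistence <= 1.0:
            raise ValueError("run persistence must lie in [0, 1]")
        if not 0.0 < self.chance < 1.0:
            raise ValueError("chance rate must lie in (0, 1)")
        if self.slope <= 0:
            raise ValueError("psychometric slope must be positive")
        if not -1.0 < self.age_pta_corr < 1.0:
            raise ValueError("age-PTA correlation must lie in (-1, 1)")


@dataclass(frozen=True)
class LatentListener:
    """A participant plus their true (latent) thresholds per condition × run."""

    record: ParticipantRecord
    theta: dict  # (condition, run int) -> dB


# --- distribution calibration ----------------------------------------------


@lru_cache(maxsize=64)
def _truncnorm_latent(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Latent (mu, sigma) of a truncated normal whose realized moments hit the targets.

    Solved as bounded least squares: a target SD can sit at or beyond the
    distribution's attainable limit (a truncated normal on [lo, hi] can never
    exceed the uniform limit (hi-lo)/sqrt(12)), in which case the closest
    attainable moments are used.
    """

    def resid(v):
        mu, log_sig = v
        sig = math.exp(log_sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, var = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(m) - mean, math.sqrt(float(var)) - sd]

    span = hi - lo
    sol = optimize.least_squares(
        resid,
        [mean, math.log(min(sd, span))],
        bounds=([lo - span, math.log(span * 1e-3)], [hi + span, math.log(span * 4)]),
    )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _age_quadrature(mu: float, sig: float, lo: float, hi: float, order: int = 80):
    """Nodes and normalized weights of the truncated-normal age density."""
    x, w = np.polynomial.legendre.leggauss(order)
    x = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    a, b = (lo - mu) / sig, (hi - mu) / sig
    wt = w * stats.truncnorm.pdf(x, a, b, loc=mu, scale=sig)
    wt = wt / wt.sum()
    return x, wt


@lru_cache(maxsize=64)
def _pta_model_params(
    age_mu: float, age_sig: float, age_lo: float, age_hi: float,
    pta_mean: float, pta_sd: float, pta_lo: float, pta_hi: float, corr: float,
) -> tuple[float, float, float]:
    """Calibrate (intercept, slope, residual SD) of the truncated PTA | age model.

    Solves three moment equations (marginal mean, marginal SD, age–PTA
    correlation of the truncated conditional model) by quadrature over the
    age density and analytic truncated-normal conditional moments.
    """
    x, wt = _age_quadrature(age_mu, age_sig, age_lo, age_hi)
    ea = float((wt * x).sum())
    va = float((wt * x * x).sum() - ea**2)

    def moments(a0, b0, se):
        loc = a0 + b0 * x
        al, be = (pta_lo - loc) / se, (pta_hi - loc) / se
        m, v = stats.truncnorm.stats(al, be, loc=loc, scale=se, moments="mv")
        m1 = float((wt * m).sum())
        m2 = float((wt * (v + m * m)).sum())
        var = m2 - m1 * m1
        cov = float((wt * x * m).sum()) - ea * m1
        return m1, math.sqrt(var), cov / math.sqrt(va * var)

    # moment-matching start ignoring truncation
    b0 = corr * pta_sd / math.sqrt(va)
    start = [pta_mean - b0 * ea, b0, math.log(pta_sd * math.sqrt(1 - corr**2))]

    def resid(v):
        m1, sd1, r1 = moments(v[0], v[1], math.exp(v[2]))
        return [m1 - pta_mean, sd1 - pta_sd, r1 - corr]

    sol = optimize.least_squares(resid, start)
    return float(sol.x[0]), float(sol.x[1]), float(math.exp(sol.x[2]))


# --- demographics -----------------------------------------------------------


def sample_demographics(
    config: GenerativeConfig, rng: np.random.Generator | None = None
) -> list[ParticipantRecord]:
    """Sample ``config.n`` participants with the study's demographic structure."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    a_lo, a_hi = config.age_bounds
    if config.age_sd == 0:
        ages = np.full(n, np.clip(config.age_mean, a_lo, a_hi))
    else:
        mu, sig = _truncnorm_latent(config.age_mean, config.age_sd, a_lo, a_hi)
        a, b = (a_lo - mu) / sig, (a_hi - mu) / sig
        ages = stats.truncnorm.ppf(rng.random(n), a, b, loc=mu, scale=sig)
    ages = np.clip(np.rint(ages), a_lo, a_hi).astype(int)

    p_lo, p_hi = config.pta_bounds
    if config.pta_sd == 0:
        ptas = np.full(n, float(np.clip(config.pta_mean, p_lo, p_hi)))
    elif config.age_sd == 0:
        # degenerate age: the conditional model collapses to the marginal
        mu, sig = _truncnorm_latent(config.pta_mean, config.pta_sd, p_lo, p_hi)
        al, be = (p_lo - mu) / sig, (p_hi - mu) / sig
        ptas = stats.truncnorm.ppf(rng.random(n), al, be, loc=mu, scale=sig)
    else:
        icpt, slope, resid_sd = _pta_model_params(
            *_truncnorm_latent(config.age_mean, config.age_sd, a_lo, a_hi),
            a_lo, a_hi,
            config.pta_mean, config.pta_sd, p_lo, p_hi, config.age_pta_corr,
        )
        loc = icpt + slope * ages
        al, be = (p_lo - loc) / resid_sd, (p_hi - loc) / resid_sd
        ptas = stats.truncnorm.ppf(rng.random(n), al, be, loc=loc, scale=resid_sd)

    genders = np.where(rng.random(n) < config.male_fraction, "M", "F")
    aids = rng.random(n) < config.hearing_aid_rate
    counts = np.array([c for *_, c in RETEST_DELAY_MIXTURE], dtype=float)
    cats = rng.choice(len(RETEST_DELAY_MIXTURE), size=n, p=counts / counts.sum())
    delays = np.array(
        [
            rng.integers(RETEST_DELAY_MIXTURE[c][1], RETEST_DELAY_MIXTURE[c][2] + 1)
            for c in cats
        ]
    )
    srt_noise = rng.normal(0.0, config.srt_offset_sd, size=(n, 2))

    records = []
    for i in range(n):
        aud = synthesize_audiogram(float(ptas[i]))
        records.append(
            ParticipantRecord(
                id=f"S{i + 1:04d}",
                age=int(ages[i]),
                audiogram=aud,
                gender=str(genders[i]),
                hearing_aid_user=bool(aids[i]),
                # SRT tracks the ear's own standard-frequency average plus noise
                srt_left=round(float(np.mean([aud.left[f] for f in (0.5, 1, 2, 4)]) + 2.0 + srt_noise[i, 0]), 2),
                srt_right=round(float(np.mean([aud.right[f] for f in (0.5, 1, 2, 4)]) + 2.0 + srt_noise[i, 1]), 2),
                retest_delay_days=int(delays[i]),
            )
        )
    return records


# --- latent thresholds ------------------------------------------------------


def predict_from_model(model: NormativeModel, age, pta):
    """Linear normative prediction over the model's included terms (vectorized)."""
    out = np.full_like(np.asarray(age, dtype=float), model.constant)
    if model.beta_age is not None:
        out = out + model.beta_age * np.asarray(age, dtype=float)
    if model.beta_pta is not None:
        out = out + model.beta_pta * np.asarray(pta, dtype=float)
    if model.beta_age_pta is not None:
        out = out + model.beta_age_pta * np.asarray(age, dtype=float) * np.asarray(pta, dtype=float)
    return out


def assign_latent_thresholds(
    records: list[ParticipantRecord],
    config: GenerativeConfig,
    rng: np.random.Generator | None = None,
) -> list[LatentListener]:
    """Attach true thresholds per condition × run to each participant.

    For each condition: theta_run1 = prediction + u with u ~ N(0, deviation SD);
    theta_run2 = prediction + rho*u + sqrt(1-rho^2)*eps + practice shift, so both
    runs share the marginal deviation SD and correlate at rho.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(records)
    ages = np.array([r.age for r in records], dtype=float)
    ptas = np.array(
        [np.mean([r.audiogram.left[f] for f in (0.5, 1, 2, 4)]
                 + [r.audiogram.right[f] for f in (0.5, 1, 2, 4)]) for r in records]
    )
    rho = config.run_persistence
    thetas: dict[str, dict[int, np.ndarray]] = {}
    for cond in CONDITIONS:
        model = config.model_for(cond)
        sd = float(config.deviation_sd[cond])
        pred = predict_from_model(model, ages, ptas)
        u = rng.normal(0.0, 1.0, n) * sd
        eps = rng.normal(0.0, 1.0, n) * sd
        thetas[cond] = {
            1: pred + u,
            2: pred + rho * u + math.sqrt(1.0 - rho**2) * eps
            + float(config.practice_run2[cond]),
        }
    return [
        LatentListener(
            record=records[i],
            theta={(c, r): float(thetas[c][r][i]) for c in CONDITIONS for r in (1, 2)},
        )
        for i in range(n)
    ]


# --- psychometric listener and progressive track ----------------------------


def psychometric_p(tmr, location, slope: float, chance: float):
    """Probability of a correct closed-set response at a given TMR.

    ``chance + (1 - chance) * logistic((tmr - location) / slope)``: strictly
    increasing in TMR, approaching the guessing floor far below the
    psychometric location and 1 far above it.
    """
    if slope <= 0:
        raise ValueError("psychometric slope must be positive")
    z = (np.asarray(tmr, dtype=float) - np.asarray(location, dtype=float)) / slope
    return chance + (1.0 - chance) * (0.5 * (1.0 + np.tanh(z / 2.0)))


def _expected_estimate(location, slope: float, chance: float):
    """Analytic expected track estimate for a psychometric location (vectorized)."""
    loc = np.atleast_1d(np.asarray(location, dtype=float))
    p = psychometric_p(np.array(TRACK_LEVELS, dtype=float)[None, :], loc[:, None], slope, chance)
    return 10.0 - 2.0 * p.sum(axis=1)


def track_location(theta, slope: float, chance: float):
    """Psychometric location(s) at which the track's expected estimate equals theta.

    The progressive track's estimate is biased relative to the logistic 50%
    point (its level grid is centered at +1 dB and the guessing floor inflates
    the correct count), while the latent thresholds of the generative model
    live on the estimator's scale.  This inverts the analytic expected-estimate
    curve by bisection; thetas outside the attainable open interval
    (−10, 10 − 20·chance) are clamped to a saturating location.
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    scalar = np.isscalar(theta) or np.asarray(theta).ndim == 0
    if slope < 1e-6:
        # step-listener limit: a location of theta + 1 centers the transition
        # between the grid levels bracketing theta
        out = th + 1.0
        return float(out[0]) if scalar else out
    e_max = 10.0 - 20.0 * chance
    lo = np.minimum(th, -10.0) - 16.0 * slope - 2.0
    hi = np.maximum(th, e_max) + 16.0 * slope + 2.0
    target = np.clip(th, -10.0 + 1e-9, e_max - 1e-9)
    for _ in range(80):  # bisection: _expected_estimate is increasing in location
        mid = 0.5 * (lo + hi)
        too_high = _expected_estimate(mid, slope, chance) > target
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    out = 0.5 * (lo + hi)
    return float(out[0]) if scalar else out


def simulate_estimates(
    theta: float,
    n_tracks: int,
    config: GenerativeConfig,
    rng: np.random.Generator,
    condition: str = "separated",
) -> np.ndarray:
    """Vectorized Monte-Carlo: ``n_tracks`` track estimates at one latent theta."""
    loc = track_location(theta, config.slope, config.chance) if config.track_calibration else theta
    p = psychometric_p(np.array(TRACK_SCHEDULE, dtype=float), loc, config.slope, config.chance)
    correct = rng.random((n_tracks, 20)) < p[None, :]
    return 10 - correct.sum(axis=1)


def simulate_track(
    theta: float,
    config: GenerativeConfig,
    rng: np.random.Generator,
    condition: str = "separated",
) -> tuple[TrialBlock, int]:
    """Simulate one 20-trial progressive track; return the block and its estimate."""
    loc = track_location(theta, config.slope, config.chance) if config.track_calibration else theta
    p = psychometric_p(np.array(TRACK_SCHEDULE, dtype=float), loc, config.slope, config.chance)
    correct = tuple(bool(b) for b in rng.random(20) < p)
    block = TrialBlock(condition=condition, schedule=TRACK_SCHEDULE, correct=correct)
    return block, estimate_threshold(block)


# --- cohort orchestration ---------------------------------------------------


def simulate_cohort(
    config: GenerativeConfig, return_trials: bool = False
) -> CohortTable | tuple[CohortTable, pd.DataFrame]:
    """Generate a full two-condition, two-run cohort (optionally with trial rows).

    Deterministic given ``config.seed``; the returned :class:`CohortTable`
    carries observed (track-estimated) thresholds plus all derived columns.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records = sample_demographics(config, rng)
    listeners = assign_latent_thresholds(records, config, rng)
    n = len(listeners)

    observed: dict[tuple[str, int], np.ndarray] = {}
    trial_rows = []
    for cond in CONDITIONS:
        for run in (1, 2):
            th = np.array([lst.theta[(cond, run)] for lst in listeners])
            loc = (
                track_location(th, config.slope, config.chance)
                if config.track_calibration
                else th
            )
            p = psychometric_p(
                np.array(TRACK_SCHEDULE, dtype=float)[None, :],
                loc[:, None], config.slope, config.chance,
            )
            correct = rng.random((n, 20)) < p
            observed[(cond, run)] = 10 - correct.sum(axis=1)
            if return_trials:
                for i, lst in enumerate(listeners):
                    trial_rows += [
                        {
                            "id": lst.record.id, "condition": cond, "run": run,
                            "trial": t + 1, "tmr": TRACK_SCHEDULE[t],
                            "correct": bool(correct[i, t]),
                        }
                        for t in range(20)
                    ]

    rows = []
    for i, lst in enumerate(listeners):
        r = lst.record
        row = {"id": r.id, "age": r.age, "gender": r.gender,
               "hearing_aid_user": r.hearing_aid_user,
               "srt_left": r.srt_left, "srt_right": r.srt_right,
               "retest_delay_days": r.retest_delay_days}
        for ear, side in (("L", r.audiogram.left), ("R", r.audiogram.right)):
            for f in AUDIOGRAM_FREQS:
                row[f"{ear}_{format_freq(f)}"] = side[f]
        for cond in CONDITIONS:
            for run in (1, 2):
                row[f"{cond}_{run}"] = int(observed[(cond, run)][i])
        rows.append(row)
    cohort = CohortTable(pd.DataFrame(rows))
    if return_trials:
        return cohort, pd.DataFrame(trial_rows)
    return cohort


# --- parameter-recovery cohorts ---------------------------------------------


def make_recovery_cohort(
    truth: NormativeModel,
    n: int,
    seed: int,
    noise_sd: float | None = None,
    age_dist: str = "uniform",
) -> CohortTable:
    """Cohort whose chosen outcome is drawn exactly from a generative regression.

    Used for parameter-recovery studies: ages are sampled (uniform integers on
    [18, 80] by default, or the study's truncated normal), PTA follows the
    calibrated truncated conditional model, and the outcome named by
    ``truth.condition`` equals ``truth`` prediction + Normal(0, noise_sd)
    exactly (no track simulation, no range clipping).  The remaining threshold
    columns are neutral fillers.
    """
    cfg = GenerativeConfig()
    rng = np.random.default_rng(seed)
    a_lo, a_hi = cfg.age_bounds
    if age_dist == "uniform":
        ages = rng.integers(int(a_lo), int(a_hi) + 1, size=n)
    elif age_dist == "study":
        mu, sig = _truncnorm_latent(cfg.age_mean, cfg.age_sd, a_lo, a_hi)
        a, b = (a_lo - mu) / sig, (a_hi - mu) / sig
        ages = np.rint(stats.truncnorm.ppf(rng.random(n), a, b, loc=mu, scale=sig)).astype(int)
    else:
        raise ValueError(f"unknown age_dist {age_dist!r}")
    icpt, slope, resid_sd = _pta_model_params(
        *_truncnorm_latent(cfg.age_mean, cfg.age_sd, a_lo, a_hi), a_lo, a_hi,
        cfg.pta_mean, cfg.pta_sd, *cfg.pta_bounds, cfg.age_pta_corr,
    )
    loc = icpt + slope * ages
    al, be = (cfg.pta_bounds[0] - loc) / resid_sd, (cfg.pta_bounds[1] - loc) / resid_sd
    ptas = stats.truncnorm.ppf(rng.random(n), al, be, loc=loc, scale=resid_sd)

    sd = truth.model_error if noise_sd is None else noise_sd
    y = predict_from_model(truth, ages, ptas) + rng.normal(0.0, sd, size=n)

    if truth.condition == "srm":
        colo = {1: y / 2.0, 2: y / 2.0}
        sep = {1: -y / 2.0, 2: -y / 2.0}
    elif truth.condition == "separated":
        sep = {1: y, 2: y}
        colo = {1: np.zeros(n), 2: np.zeros(n)}
    else:
        colo = {1: y, 2: y}
        sep = {1: np.full(n, -4.0), 2: np.full(n, -4.0)}

    rows = []
    for i in range(n):
        aud = synthesize_audiogram(float(ptas[i]))
        row = {"id": f"R{i + 1:05d}", "age": int(ages[i])}
        for ear, side in (("L", aud.left), ("R", aud.right)):
            for f in AUDIOGRAM_FREQS:
                row[f"{ear}_{format_freq(f)}"] = side[f]
        for run in (1, 2):
            row[f"colocated_{run}"] = float(colo[run][i])
            row[f"separated_{run}"] = float(sep[run][i])
        rows.append(row)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CohortTable(pd.DataFrame(rows), warn=False)
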