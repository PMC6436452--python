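"""Domain types shared across the package.

The vocabulary follows clinical psychoacoustics: thresholds are
target-to-masker ratios (TMR, dB) measured in a colocated and a spatially
separated two-masker configuration; spatial release from masking (SRM) is
the colocated minus the separated threshold; hearing loss is summarized as
a bilateral pure-tone average (PTA, dB HL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Audiometric frequencies carried by an audiogram, in kHz.
AUDIOGRAM_FREQS: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)

#: Frequencies entering the standard four-frequency PTA (kHz).
PTA_STANDARD_FREQS: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)

#: Frequencies entering the high-frequency PTA (kHz).
PTA_HIGH_FREQS: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)

#: The two spatial configurations of the test.
CONDITIONS: tuple[str, str] = ("colocated", "separated")

#: Outcome measures: the two conditions plus their difference.
MEASURES: tuple[str, str, str] = ("colocated", "separated", "srm")

#: Run labels for which norms are fitted.
RUN_LABELS: tuple[str, str, str] = ("1", "2", "average")

#: Fixed descending TMR schedule of the 20-trial progressive track (dB).
TRACK_LEVELS: tuple[int, ...] = (10, 8, 6, 4, 2, 0, -2, -4, -6, -8)

#: Per-trial schedule: two consecutive trials at each level.
TRACK_SCHEDULE: tuple[int, ...] = tuple(lv for lv in TRACK_LEVELS for _ in range(2))

#: Structural range of a track-estimated threshold (dB TMR).
THRESHOLD_RANGE: tuple[float, float] = (-10.0, 10.0)

#: Supported ranges of the normative functions; predictions outside are
#: computed but tagged as extrapolation.
AGE_RANGE: tuple[float, float] = (18.0, 80.0)
PTA_RANGE: tuple[float, float] = (0.0, 45.0)


class CohortValidationWarning(UserWarning):
    """A cohort row violates a soft invariant (reported, never dropped)."""


class ExtrapolationWarning(UserWarning):
    """A normative prediction was requested outside the supported range."""


def format_freq(freq: float) -> str:
    """Render a frequency in kHz the way audiogram columns are named (``0.5``, ``4``)."""
    return str(int(freq)) if float(freq).is_integer() else str(freq)


@dataclass(frozen=True)
class Audiogram:
    """Per-ear pure-tone thresholds (dB HL) at the standard audiometric frequencies."""

    left: Mapping[float, float]
    right: Mapping[float, float]

    def __post_init__(self) -> None:
        for ear_name, ear in (("left", self.left), ("right", self.right)):
            for f, thr in ear.items():
                if f not in AUDIOGRAM_FREQS:
                    raise ValueError(f"{ear_name} ear: unsupported frequency {f} kHz")
                if not -10.0 <= thr <= 120.0:
                    raise ValueError(
                        f"{ear_name} ear at {f} kHz: threshold {thr} dB HL outside [-10, 120]"
                    )
            missing = [f for f in PTA_STANDARD_FREQS if f not in ear or ear[f] is None]
            if missing:
                raise ValueError(
                    f"{ear_name} ear missing standard-PTA frequencies: {missing}"
                )


@dataclass
class ParticipantRecord:
    """One listener: demographics plus audiometric summaries."""

    id: str
    age: int
    audiogram: Audiogram
    gender: str | None = None
    hearing_aid_user: bool | None = None
    srt_left: float | None = None
    srt_right: float | None = None
    retest_delay_days: int | None = None

    def __post_init__(self) -> None:
        if not AGE_RANGE[0] <= self.age <= AGE_RANGE[1]:
            warnings.warn(
                f"participant {self.id}: age {self.age} outside supported range "
                f"[{AGE_RANGE[0]:.0f}, {AGE_RANGE[1]:.0f}]",
                CohortValidationWarning,
                stacklevel=2,
            )
        if self.retest_delay_days is not None and self.retest_delay_days < 0:
            raise ValueError(f"participant {self.id}: negative retest delay")


@dataclass(frozen=True)
class TrialBlock:
    """One 20-trial progressive track: fixed TMR schedule plus correctness flags.

    A trial counts as correct only when both the color and the number of the
    closed-set response match the target sentence; upstream producers deliver
    that conjunction as a single boolean.
    """

    condition: str
    schedule: tuple[int, ...]
    correct: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.schedule) != 20 or len(self.correct) != 20:
            raise ValueError("a progressive track holds exactly 20 trials")
        if sorted(self.schedule) != sorted(TRACK_SCHEDULE):
            raise ValueError(
                "schedule must present two trials at each of the 10 levels "
                f"{TRACK_LEVELS}"
            )


@dataclass(frozen=True)
class ThresholdRecord:
    """A scored TMR threshold for one condition and run label."""

    condition: str
    run: str
    tmr_threshold: float

    def __post_init__(self) -> None:
        if self.run not in RUN_LABELS:
            raise ValueError(f"unknown run label {self.run!r}")
        lo, hi = THRESHOLD_RANGE
        if not lo <= self.tmr_threshold <= hi:
            raise ValueError(f"threshold {self.tmr_threshold} outside [{lo}, {hi}]")
        if self.run in ("1", "2") and self.tmr_threshold != int(self.tmr_threshold):
            raise ValueError("single-run thresholds are integers")


@dataclass(frozen=True)
class SrmRecord:
    """Spatial release from masking for one run label (colocated − separated, dB)."""

    run: str
    srm: float


@dataclass
class NormativeModel:
    """A fitted (or generative) normative regression for one measure × run.

    predicted TMR threshold = constant + age·β_age + PTA·β_PTA
    over whichever predictors survived elimination; ``model_error`` is the SD
    used as the Z-score denominator.
    """

    condition: str
    run: str
    predictors: tuple[str, ...]
    constant: float
    beta_age: float | None = None
    beta_pta: float | None = None
    beta_age_pta: float | None = None
    model_error: float = 0.0
    error_method: str = "rmse"
    adj_r2: float | None = None
    n: int | None = None
    p_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in MEASURES:
            raise ValueError(f"unknown measure {self.condition!r}")
        if self.run not in RUN_LABELS:
            raise ValueError(f"unknown run label {self.run!r}")
        if self.model_error < 0:
            raise ValueError("model error must be nonnegative")
        for name, beta in (
            ("age", self.beta_age),
            ("pta", self.beta_pta),
            ("age_x_pta", self.beta_age_pta),
        ):
            if (name in self.predictors) != (beta is not None):
                raise ValueError(
                    f"predictor {name!r}: inclusion and coefficient disagree"
                )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)} | {
            "predictors": list(self.predictors)
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormativeModel":
        d = dict(d)
        d["predictors"] = tuple(d.get("predictors", ()))
        d["p_values"] = dict(d.get("p_values", {}))
        return cls(**d)


@dataclass(frozen=True)
class ZReportEntry:
    """Observed vs normatively predicted threshold for one measure."""

    participant_id: str | None
    measure: str  # e.g. "separated_avg"
    observed: float
    predicted: float
    z: float
    flagged: bool
    extrapolated: bool = False


# --- cohort table -----------------------------------------------------------

THRESHOLD_COLUMNS: tuple[str, ...] = (
    "colocated_1",
    "colocated_2",
    "separated_1",
    "separated_2",
)

DERIVED_COLUMNS: tuple[str, ...] = (
    "colocated_avg",
    "separated_avg",
    "srm_1",
    "srm_2",
    "srm_avg",
    "pta_st",
    "pta_hf",
    "asym_max",
    "asym_max_below_2k",
)

OPTIONAL_COLUMNS: tuple[str, ...] = (
    "gender",
    "hearing_aid_user",
    "srt_left",
    "srt_right",
    "retest_delay_days",
)


def audiogram_columns() -> list[str]:
    """Canonical audiogram column names, left ear then right, low to high."""
    return [f"{ear}_{format_freq(f)}" for ear in ("L", "R") for f in AUDIOGRAM_FREQS]


def required_columns() -> list[str]:
    return ["id", "age", *audiogram_columns(), *THRESHOLD_COLUMNS]


def measure_column(condition: str, run: str) -> str:
    """Column name of an outcome measure, e.g. ('srm', 'average') -> 'srm_avg'."""
    if condition not in MEASURES or run not in RUN_LABELS:
        raise ValueError(f"unknown measure ({condition!r}, {run!r})")
    return f"{condition}_{'avg' if run == 'average' else run}"


class CohortTable:
    """A cohort of listeners with per-condition, per-run TMR thresholds.

    Wraps a :class:`pandas.DataFrame` with a canonical column set.  Derived
    quantities (run averages, SRM, PTA variants, asymmetry) are always
    recomputed from the stored columns so they cannot drift from the data.
    """

    def __init__(self, df: pd.DataFrame, *, warn: bool = True) -> None:
        missing = [c for c in required_columns() if c not in df.columns]
        if missing:
            raise KeyError(f"cohort is missing required columns: {missing}")
        self.df = df.reset_index(drop=True).copy()
        self._derive()
        issues = self.validate()
        if warn and issues:
            warnings.warn(
                "cohort validation: " + "; ".join(issues),
                CohortValidationWarning,
                stacklevel=2,
            )

    def _derive(self) -> None:
        df = self.df
        df["colocated_avg"] = (df["colocated_1"] + df["colocated_2"]) / 2.0
        df["separated_avg"] = (df["separated_1"] + df["separated_2"]) / 2.0
        df["srm_1"] = df["colocated_1"] - df["separated_1"]
        df["srm_2"] = df["colocated_2"] - df["separated_2"]
        df["srm_avg"] = df["colocated_avg"] - df["separated_avg"]
        st_cols = [
            f"{ear}_{format_freq(f)}" for ear in ("L", "R") for f in PTA_STANDARD_FREQS
        ]
        hf_cols = [
            f"{ear}_{format_freq(f)}" for ear in ("L", "R") for f in PTA_HIGH_FREQS
        ]
        df["pta_st"] = df[st_cols].mean(axis=1)
        df["pta_hf"] = df[hf_cols].mean(axis=1)
        diffs = np.abs(
            df[[f"L_{format_freq(f)}" for f in AUDIOGRAM_FREQS]].to_numpy()
            - df[[f"R_{format_freq(f)}" for f in AUDIOGRAM_FREQS]].to_numpy()
        )
        below = [i for i, f in enumerate(AUDIOGRAM_FREQS) if f < 2.0]
        df["asym_max"] = diffs.max(axis=1)
        df["asym_max_below_2k"] = diffs[:, below].max(axis=1)

    def validate(self) -> list[str]:
        """Return human-readable descriptions of every soft-invariant violation.

        Row numbers are 1-based data rows (matching a spreadsheet view of the
        CSV without its header).
        """
        issues: list[str] = []
        lo, hi = THRESHOLD_RANGE
        for col in THRESHOLD_COLUMNS:
            bad = self.df.index[(self.df[col] < lo) | (self.df[col] > hi)]
            issues += [
                f"row {i + 1}, column {col!r}: threshold "
                f"{self.df.at[i, col]:g} outside [{lo:g}, {hi:g}]"
                for i in bad
            ]
        bad_age = self.df.index[
            (self.df["age"] < AGE_RANGE[0]) | (self.df["age"] > AGE_RANGE[1])
        ]
        issues += [
            f"row {i + 1}: age {self.df.at[i, 'age']:g} outside supported "
            f"[{AGE_RANGE[0]:g}, {AGE_RANGE[1]:g}]"
            for i in bad_age
        ]
        bad_pta = self.df.index[self.df["pta_st"] > PTA_RANGE[1]]
        issues += [
            f"row {i + 1}: bilateral standard PTA {self.df.at[i, 'pta_st']:.2f} "
            f"exceeds the {PTA_RANGE[1]:g} dB HL inclusion criterion"
            for i in bad_pta
        ]
        for col in audiogram_columns():
            bad = self.df.index[(self.df[col] < -10) | (self.df[col] > 120)]
            issues += [
                f"row {i + 1}, column {col!r}: audiometric threshold outside [-10, 120]"
                for i in bad
            ]
        return issues

    # -- convenience ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def outcome(self, condition: str, run: str) -> pd.Series:
        return self.df[measure_column(condition, run)]

    def ids(self) -> list[str]:
        return [str(x) for x in self.df["id"]]

    def records(self) -> Iterable[ParticipantRecord]:
        """Yield participants as :class:`ParticipantRecord` objects."""
        for _, row in self.df.iterrows():
            aud = Audiogram(
                left={f: float(row[f"L_{format_freq(f)}"]) for f in AUDIOGRAM_FREQS},
                right={f: float(row[f"R_{format_freq(f)}"]) for f in AUDIOGRAM_FREQS},
            )

            def opt(col, cast):
                v = row.get(col)
                return None if v is None or (isinstance(v, float) and np.isnan(v)) else cast(v)

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", CohortValidationWarning)
                yield ParticipantRecord(
                    id=str(row["id"]),
                    age=int(row["age"]),
                    audiogram=aud,
                    gender=opt("gender", str),
                    hearing_aid_user=opt("hearing_aid_user", bool),
                    srt_left=opt("srt_left", float),
                    srt_right=opt("srt_right", float),
                    retest_delay_days=opt("retest_delay_days", lambda v: int(float(v))),
                )
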