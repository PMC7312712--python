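"""Seeded synthetic cohorts with the structure of a wrist-CT angle study.

No raw subject-level data are available for the study this package
emulates, so cohorts are simulated: n subjects with sex, age, and three
repeated measurements of the hamate hook curvature angle whose
arithmetic mean is the subject's final angle.  The default configuration
matches the published cohort summaries: n = 91 (51 male / 40 female),
angle ~ Normal(122.55, 8.20) truncated to [97.20, 139.31] degrees, and
right-skewed per-sex age distributions with women older on average.

True angles are drawn by rejection sampling from the truncated normal;
measurement replicates add independent Gaussian noise (default SD 0.5
degrees, small against the 8.2-degree between-subject SD).  Identical
config (including seed) gives byte-identical CSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Subject",
    "CohortConfig",
    "AgeParams",
    "generate_cohort",
    "cohort_to_csv",
    "cohort_to_dataframe",
    "read_cohort",
    "CohortParseError",
]

COHORT_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "angle_1",
    "angle_2",
    "angle_3",
    "angle_mean",
]


class CohortParseError(ValueError):
    """Raised when a cohort CSV is malformed; names the offending row/column."""


@dataclass(frozen=True)
class AgeParams:
    """Shifted-gamma age model for one sex: age ~ loc + Gamma(shape, scale).

    Gamma gives the right skew of an adult imaging cohort; the location
    shift sets the youngest plausible age.  Defaults (see CohortConfig)
    put the overall median near 34 years with the female median above
    the male median.
    """

    loc: float
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if self.loc < 0:
            raise ValueError("age location must be non-negative")


@dataclass(frozen=True)
class Subject:
    subject_id: str
    sex: str  # "male" | "female"
    age: int
    angle_measurements: Tuple[float, float, float]
    angle_mean: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        for m in self.angle_measurements:
            if not 0.0 < m < 180.0:
                raise ValueError(
                    f"angle measurement {m!r} outside (0, 180) degrees"
                )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator settings; defaults are the emulated study's values."""

    n: int = 91
    male_fraction: float = 51.0 / 91.0
    angle_mean: float = 122.55
    angle_sd: float = 8.20
    angle_min: float = 97.20
    angle_max: float = 139.31
    measurement_sd: float = 0.5
    age_params: Dict[str, AgeParams] = field(
        default_factory=lambda: {
            "male": AgeParams(loc=10.0, shape=2.0, scale=12.5),
            "female": AgeParams(loc=10.0, shape=2.6, scale=11.5),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"cohort size n must be positive, got {self.n}")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.angle_min >= self.angle_max:
            raise ValueError("angle_min must be below angle_max")
        if self.angle_sd <= 0:
            raise ValueError("angle_sd must be positive")
        if self.measurement_sd < 0:
            raise ValueError("measurement_sd must be non-negative")
        for sex in ("male", "female"):
            if sex not in self.age_params:
                raise ValueError(f"age_params missing entry for {sex!r}")


def _sample_truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Rejection-sample n draws of Normal(mean, sd) restricted to [lo, hi]."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        # Oversample by the inverse acceptance probability estimate.
        draw = rng.normal(mean, sd, size=max(n - filled, 16) * 2)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_cohort(config: CohortConfig) -> List[Subject]:
    """Generate a deterministic synthetic cohort from the configuration.

    Sex is Bernoulli(male_fraction); each subject's true angle is a
    truncated-normal draw; its three recorded measurements add
    independent N(0, measurement_sd) noise (clamped inside (0, 180));
    ages come from the per-sex shifted-gamma model, rounded to integer
    years.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    is_male = rng.random(n) < config.male_fraction
    true_angle = _sample_truncated_normal(
        rng, n, config.angle_mean, config.angle_sd, config.angle_min, config.angle_max
    )
    noise = rng.normal(0.0, config.measurement_sd, size=(n, 3)) if config.measurement_sd > 0 else np.zeros((n, 3))
    eps = 1e-9
    meas = np.clip(true_angle[:, None] + noise, eps, 180.0 - eps)

    ages = np.empty(n)
    for sex, mask in (("male", is_male), ("female", ~is_male)):
        p = config.age_params[sex]
        k = int(mask.sum())
        if k:
            ages[mask] = p.loc + rng.gamma(p.shape, p.scale, size=k)
    ages = np.rint(ages).astype(int)

    width = max(4, len(str(n)))
    cohort = []
    for i in range(n):
        m = tuple(float(x) for x in meas[i])
        cohort.append(
            Subject(
                subject_id=f"S{i + 1:0{width}d}",
                sex="male" if is_male[i] else "female",
                age=int(ages[i]),
                angle_measurements=m,  # type: ignore[arg-type]
                angle_mean=float(np.mean(meas[i])),
            )
        )
    return cohort


def cohort_to_dataframe(cohort: Sequence[Subject]) -> pd.DataFrame:
    rows = [
        (
            s.subject_id,
            s.sex,
            s.age,
            s.angle_measurements[0],
            s.angle_measurements[1],
            s.angle_measurements[2],
            s.angle_mean,
        )
        for s in cohort
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def cohort_to_csv(cohort: Sequence[Subject], path) -> None:
    """Write the cohort as UTF-8 CSV; full float precision (repr round-trip)."""
    df = cohort_to_dataframe(cohort)
    df.to_csv(path, index=False, float_format=None)


def read_cohort(path) -> List[Subject]:
    """Read a cohort CSV back into Subject records, validating each row.

    Raises :class:`CohortParseError` naming the first offending row and
    column for missing columns, non-numeric fields, or angles outside
    (0, 180) degrees.  A header-only file yields an empty cohort.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise CohortParseError(f"malformed cohort CSV {path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(
            f"cohort CSV {path} missing column(s): {', '.join(missing)}"
        )
    cohort: List[Subject] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, counting the header line
        sex = row["sex"]
        if sex not in ("male", "female"):
            raise CohortParseError(
                f"row {rowno}, column 'sex': expected male/female, got {sex!r}"
            )
        def _num(col: str) -> float:
            try:
                return float(row[col])
            except ValueError as exc:
                raise CohortParseError(
                    f"row {rowno}, column {col!r}: not a number ({row[col]!r})"
                ) from exc
        angles = tuple(_num(f"angle_{k}") for k in (1, 2, 3))
        for col, a in zip(("angle_1", "angle_2", "angle_3"), angles):
            if not 0.0 < a < 180.0:
                raise CohortParseError(
                    f"row {rowno}, column {col!r}: angle {a} outside (0, 180)"
                )
        try:
            age = int(float(row["age"]))
        except ValueError as exc:
            raise CohortParseError(
                f"row {rowno}, column 'age': not a number ({row['age']!r})"
            ) from exc
        cohort.append(
            Subject(
                subject_id=row["subject_id"],
                sex=sex,
                age=age,
                angle_measurements=angles,  # type: ignore[arg-type]
                angle_mean=_num("angle_mean"),
            )
        )
    return cohort
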