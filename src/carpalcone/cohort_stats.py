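"""Statistical stage: descriptives, normality, rank-sum tests, correlation,
and ROC-based cutoff search over a cohort of angle measurements.

The pipeline mirrors a small observational imaging study: Shapiro-Wilk
normality screening, Mann-Whitney U for two-group comparisons, Pearson
and Spearman correlation between the hook angle and the modelled tunnel
volume, and a Youden-J cutoff search whose "no suitable cutoff" verdict
is driven by the equivalence between the empirical AUC and the
Mann-Whitney statistic (AUC = U / (n1*n2)).

The Mann-Whitney test is implemented here from midranks.  Exact mode
enumerates the permutation null over the observed pooled data (so ties
need no correction); approximate mode uses the normal approximation
with tie and continuity corrections.  Two-sided p-values throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from . import cone_model

__all__ = [
    "TestResult",
    "SummaryStats",
    "CutoffReport",
    "descriptive_summary",
    "normality_check",
    "mann_whitney_u",
    "correlation",
    "find_cutoff",
    "analyze_cohort",
    "EXACT_ENUMERATION_BOUND",
]

#: Exact-mode Mann-Whitney is auto-selected while C(n1+n2, n1) stays
#: at or below this many group assignments.
EXACT_ENUMERATION_BOUND = 20_000


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    extras: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")

    def to_dict(self) -> Dict[str, object]:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "extras": dict(self.extras),
        }


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float

    def to_dict(self) -> Dict[str, float]:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "min": self.min,
            "max": self.max,
        }


@dataclass(frozen=True)
class CutoffReport:
    threshold: float
    youden_j: float
    auc: float
    p_value: float
    cutoff_found: bool
    verdict: str
    n_positive: int
    n_negative: int

    def to_dict(self) -> Dict[str, object]:
        return {
            "threshold": self.threshold,
            "youden_j": self.youden_j,
            "auc": self.auc,
            "p_value": self.p_value,
            "cutoff_found": self.cutoff_found,
            "verdict": self.verdict,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def _as_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def descriptive_summary(values: Sequence[float]) -> SummaryStats:
    """n, mean, sample SD (n-1 denominator), median, min, max.

    Median uses the midpoint of the two central order statistics for
    even n.  SD is NaN for a single observation.
    """
    arr = _as_array(values, "values")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return SummaryStats(
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        median=float(np.median(arr)),
        min=float(np.min(arr)),
        max=float(np.max(arr)),
    )


def normality_check(values: Sequence[float], alpha_level: float = 0.05) -> TestResult:
    """Shapiro-Wilk normality test with an explicit accept/reject decision.

    Needs at least 3 observations and non-zero variance.  The decision
    at ``alpha_level`` is recorded in ``extras['reject_normality']``.
    """
    arr = _as_array(values, "values")
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    stat, p = sps.shapiro(arr)
    return TestResult(
        method="shapiro-wilk",
        statistic=float(stat),
        p_value=float(p),
        extras={
            "alpha_level": alpha_level,
            "reject_normality": bool(p < alpha_level),
        },
    )


def _u_statistic(pooled_ranks: np.ndarray, idx_a: Sequence[int], n1: int) -> float:
    # U1 from the rank-sum identity; midranks make this tie-safe.
    return float(np.sum(pooled_ranks[list(idx_a)]) - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: Literal["exact", "approximate", "auto"] = "auto",
) -> TestResult:
    """Two-sided Mann-Whitney U test from midranks.

    ``exact`` enumerates every assignment of the pooled observations to
    the two groups (the permutation null of the observed data, so ties
    need no special handling) and reports
    P(|U - n1*n2/2| >= |u_obs - n1*n2/2|), using the symmetry of the
    permutation distribution of U about n1*n2/2.  ``approximate`` uses
    the normal approximation with midrank tie correction and a 0.5
    continuity correction.  ``auto`` picks exact while the number of
    assignments C(n1+n2, n1) <= EXACT_ENUMERATION_BOUND.
    """
    a = _as_array(group_a, "group_a")
    b = _as_array(group_b, "group_b")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks, range(n1), n1)

    n_comb = math.comb(n1 + n2, n1)
    if mode == "auto":
        mode_used = "exact" if n_comb <= EXACT_ENUMERATION_BOUND else "approximate"
    else:
        mode_used = mode

    mu = n1 * n2 / 2.0
    if mode_used == "exact":
        dev = abs(u_obs - mu)
        hits = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = float(ranks[list(idx)].sum() - offset)
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        p = hits / n_comb
        extras: Dict[str, object] = {"mode": "exact", "assignments": n_comb}
    else:
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0  # all observations tied: no evidence of a shift
            z = 0.0
        else:
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * float(sps.norm.sf(z)))
        extras = {"mode": "approximate", "z": z, "tie_correction": tie_term > 0}
    return TestResult(
        method="mann-whitney-u",
        statistic=u_obs,
        p_value=p,
        extras=extras,
    )


def correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> TestResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    Spearman is Pearson on midranks (t-approximation for p).  Zero
    variance in either argument is a degenerate input.
    """
    xa = _as_array(x, "x")
    ya = _as_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("correlation requires at least 3 points")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(xa, ya)
    elif method == "spearman":
        r, p = sps.spearmanr(xa, ya)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return TestResult(
        method=method, statistic=float(r), p_value=float(p), extras={"n": int(xa.size)}
    )


def find_cutoff(
    values: Sequence[float],
    labels: Sequence[int],
    alpha_level: float = 0.05,
) -> CutoffReport:
    """Youden-J cutoff search with an AUC-vs-0.5 significance gate.

    Candidate thresholds are the midpoints between consecutive sorted
    distinct values (plus open ends); a subject is called positive when
    its value exceeds the threshold (orientation flipped when the AUC
    is below 0.5).  The report carries the J-maximizing threshold, the
    empirical AUC, and the two-sided Mann-Whitney p-value for the
    separation; the verdict is "no suitable cutoff" when that test does
    not reject at ``alpha_level`` (AUC indistinguishable from 0.5).
    """
    vals = _as_array(values, "values")
    lab = np.asarray(labels)
    if lab.shape != vals.shape:
        raise ValueError("values and labels must have equal length")
    if not set(np.unique(lab)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    n_pos = int(np.sum(lab == 1))
    n_neg = int(np.sum(lab == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")

    auc = float(roc_auc_score(lab, vals))
    score = vals if auc >= 0.5 else -vals  # orient so higher score => class 1
    pos = np.sort(score[lab == 1])
    neg = np.sort(score[lab == 0])
    distinct = np.unique(score)
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if distinct.size > 1 else np.array([])
    candidates = np.concatenate(
        [[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]]
    )
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        sens = float(np.mean(pos > t))
        spec = float(np.mean(neg <= t))
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    if auc < 0.5:
        best_t = -best_t  # report on the original value scale

    mw = mann_whitney_u(vals[lab == 1], vals[lab == 0], mode="auto")
    found = bool(mw.p_value < alpha_level)
    return CutoffReport(
        threshold=best_t,
        youden_j=best_j,
        auc=auc,
        p_value=mw.p_value,
        cutoff_found=found,
        verdict="cutoff found" if found else "no suitable cutoff",
        n_positive=n_pos,
        n_negative=n_neg,
    )


def _summaries_block(values: np.ndarray) -> Dict[str, float]:
    return descriptive_summary(values).to_dict()


def analyze_cohort(
    cohort,
    calibration: Optional[cone_model.Calibration] = None,
    r2: float = cone_model.DEFAULTS["r2"],
    L: float = cone_model.DEFAULTS["L"],
    pi_volume: float = cone_model.DEFAULTS["pi_volume"],
    alpha_level: float = 0.05,
) -> Dict[str, object]:
    """Full cohort analysis: per-subject modelled volumes plus statistics.

    Each subject's tunnel volume is computed from its mean hook angle
    through the calibrated frustum model.  The report (a JSON-friendly
    dict) contains descriptive summaries overall and by sex for angle,
    volume, and age; Shapiro-Wilk normality decisions; the male-female
    rank-sum comparisons of angle and age; Pearson and Spearman
    angle-volume correlations; and a Youden-J cutoff search of the
    angle against sex labels (male coded 1).  Comparative procedures
    that need both sexes or a minimum sample size are marked skipped
    rather than raising.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if calibration is None:
        calibration = cone_model.default_calibration()

    angles = np.array([s.angle_mean for s in cohort])
    ages = np.array([float(s.age) for s in cohort])
    sexes = np.array([s.sex for s in cohort])
    volumes = np.array(
        [
            cone_model.frustum_volume(
                cone_model.FrustumModel(
                    r1=cone_model.outlet_radius(a, calibration),
                    r2=r2,
                    L=L,
                    pi_volume=pi_volume,
                )
            )
            for a in angles
        ]
    )

    report: Dict[str, object] = {
        "n": len(cohort),
        "alpha_level": alpha_level,
        "calibration": {
            "alpha0_deg": calibration.alpha0_deg,
            "r1_0": calibration.r1_0,
            "B": calibration.B,
        },
        "per_subject": [
            {
                "subject_id": s.subject_id,
                "sex": s.sex,
                "angle_mean": float(a),
                "volume_mm3": float(v),
            }
            for s, a, v in zip(cohort, angles, volumes)
        ],
    }

    desc: Dict[str, object] = {
        "overall": {
            "angle_deg": _summaries_block(angles),
            "volume_mm3": _summaries_block(volumes),
            "age_years": _summaries_block(ages),
        }
    }
    for sex in ("male", "female"):
        mask = sexes == sex
        desc[sex] = (
            {
                "angle_deg": _summaries_block(angles[mask]),
                "volume_mm3": _summaries_block(volumes[mask]),
                "age_years": _summaries_block(ages[mask]),
            }
            if mask.any()
            else {"skipped": "no subjects"}
        )
    report["descriptives"] = desc

    tests: Dict[str, object] = {}
    for name, arr in (("angle_deg", angles), ("age_years", ages)):
        if arr.size >= 3 and np.ptp(arr) > 0:
            tests[f"normality_{name}"] = normality_check(arr, alpha_level).to_dict()
        else:
            tests[f"normality_{name}"] = {"skipped": "insufficient data"}

    male, female = angles[sexes == "male"], angles[sexes == "female"]
    if male.size and female.size:
        tests["sex_vs_angle"] = mann_whitney_u(male, female).to_dict()
        tests["sex_vs_age"] = mann_whitney_u(
            ages[sexes == "male"], ages[sexes == "female"]
        ).to_dict()
    else:
        tests["sex_vs_angle"] = {"skipped": "single class"}
        tests["sex_vs_age"] = {"skipped": "single class"}

    if angles.size >= 3 and np.ptp(angles) > 0:
        for method in ("pearson", "spearman"):
            tests[f"angle_volume_{method}"] = correlation(
                angles, volumes, method
            ).to_dict()
    else:
        tests["angle_volume_pearson"] = {"skipped": "insufficient data"}
        tests["angle_volume_spearman"] = {"skipped": "insufficient data"}
    report["tests"] = tests

    labels = (sexes == "male").astype(int)
    if 0 < labels.sum() < labels.size:
        report["cutoff"] = find_cutoff(angles, labels, alpha_level).to_dict()
    else:
        report["cutoff"] = {"skipped": "single class"}
    return report
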