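"""Within-image and between-timepoint statistics for SFA parameters.

The study design compares the two SFA parameters between an injured and an
adjacent healthy region drawn in the *same* image (controlling for machine
settings), with:

* paired two-sided t-tests between regions at time of injury, on both the
  involved and the contralateral limb, with Anderson–Darling normality
  checks reported alongside;
* unpaired two-sided Wilcoxon rank-sum tests comparing the within-image
  differences (Healthy − Injured) between time of injury and return to
  sport, with Hodges–Lehmann location-shift estimates and confidence
  intervals derived from the ordered pairwise differences;
* minimum detectable change (MDC) thresholds from a reliability study
  (MDC = z·√2·SEM, SEM = SD·√(1−ICC)) against which the return-to-sport
  differences are judged.

The rank-sum statistic follows the Mann–Whitney convention
``W = #{(i,j): x_i > y_j} + ties/2`` with range ``0..n_x·n_y``; p-values are
exact (full enumeration of the null distribution) for small tie-free
samples and normal-approximated with tie and continuity corrections
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientSampleError, ValidationError
from .sfa_core import ROIResult

__all__ = [
    "StudyRecord",
    "PairedTestResult",
    "RankSumResult",
    "MDCInputs",
    "MDCComparison",
    "within_image_difference",
    "paired_ttest",
    "anderson_darling",
    "wilcoxon_rank_sum",
    "rank_sum_null_distribution",
    "minimum_detectable_change",
    "compare_to_mdc",
    "summarize_table2",
    "summarize_table3",
]

#: Published MDC thresholds for the two parameters (PSFR in cycles/mm,
#: Mmax% in percentage points), usable directly when the underlying
#: reliability data are not at hand.
MDC_PSFR = 0.19
MDC_MMAX = 0.60


@dataclass
class StudyRecord:
    """One (athlete, limb, timepoint, region) observation."""

    athlete_id: str
    limb: str  # involved | contralateral
    timepoint: str  # TOI | RTS
    region: str  # injured | adjacent (mirrored labels map onto these)
    roi_result: ROIResult


@dataclass
class PairedTestResult:
    n: int
    mean_diff: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    ad_stat: float
    ad_p: float
    degenerate: bool = False


@dataclass
class RankSumResult:
    n_x: int
    n_y: int
    w: float
    p: float
    hl_estimate: float
    ci_low: float
    ci_high: float
    exact: bool
    degenerate: bool = False


@dataclass
class MDCInputs:
    """Reliability quantities from which an MDC threshold derives."""

    sd_pooled: float
    icc: float
    z: float = 1.96

    def __post_init__(self) -> None:
        if self.sd_pooled < 0:
            raise ValidationError("sd_pooled must be >= 0")
        if not 0.0 <= self.icc <= 1.0:
            raise ValidationError("icc must lie in [0, 1]")

    @property
    def sem(self) -> float:
        return self.sd_pooled * math.sqrt(1.0 - self.icc)


@dataclass
class MDCComparison:
    below: list[bool]
    median_difference: float
    median_below_mdc: bool
    mdc: float


def within_image_difference(healthy: float, injured: float) -> float:
    """Healthy − Injured; positive = adjacent tissue has the larger value."""
    return healthy - injured


def paired_ttest(x, y) -> PairedTestResult:
    """Classical paired two-sided t-test on d = x − y with a 95% CI.

    Anderson–Darling normality of the differences is reported alongside as a
    warning indicator, never as an automatic gate. Zero-variance differences
    yield a degenerate-flagged result (t, p, CI all NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    n = len(x)
    if n < 3:
        raise InsufficientSampleError("paired t-test needs n >= 3 pairs")
    d = x - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    try:
        ad_stat, ad_p = anderson_darling(d)
    except (InsufficientSampleError, ValidationError):
        ad_stat, ad_p = float("nan"), float("nan")
    if sd == 0:
        return PairedTestResult(n, mean, float("nan"), float("nan"), float("nan"),
                                float("nan"), ad_stat, ad_p, degenerate=True)
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    tcrit = float(sps.t.ppf(0.975, n - 1))
    return PairedTestResult(n, mean, t, p, mean - tcrit * se, mean + tcrit * se,
                            ad_stat, ad_p)


def anderson_darling(values) -> tuple[float, float]:
    """Anderson–Darling test for normality with estimated mean and SD.

    Uses the small-sample correction ``A*² = A²(1 + 0.75/n + 2.25/n²)`` and
    the standard piecewise-exponential p-value approximation for the
    composite-normality case.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 5:
        raise InsufficientSampleError("Anderson-Darling needs n >= 5")
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise ValidationError("Anderson-Darling undefined for constant data")
    z = (v - np.mean(v)) / sd
    logcdf = sps.norm.logcdf(z)
    logsf = sps.norm.logsf(z)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (logcdf + logsf[::-1]))
    a2c = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2c >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2c + 0.0186 * a2c**2)
    elif a2c >= 0.34:
        p = math.exp(0.9177 - 4.279 * a2c - 1.38 * a2c**2)
    elif a2c >= 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2c - 59.938 * a2c**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2c - 223.73 * a2c**2)
    return float(a2), float(min(max(p, 0.0), 1.0))


@lru_cache(maxsize=256)
def rank_sum_null_distribution(m: int, n: int) -> tuple[float, ...]:
    """Exact null pmf of the Mann–Whitney U statistic for group sizes (m, n).

    Subset-sum dynamic programme over the ranks 1..m+n; ``pmf[u]`` is the
    probability that exactly ``u`` of the ``m·n`` pairs have x above y.
    """
    # ways[k][s]: subsets of size k of ranks seen so far with rank-sum s
    max_sum = (2 * (m + n) - m + 1) * m // 2
    ways = np.zeros((m + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for rank in range(1, m + n + 1):
        for k in range(min(m, rank), 0, -1):
            ways[k, rank:] += ways[k - 1, :-rank] if rank else ways[k - 1, :]
    min_sum = m * (m + 1) // 2
    counts = ways[m, min_sum : min_sum + m * n + 1]
    return tuple((counts / counts.sum()).tolist())


def _exact_two_sided_p(w: float, m: int, n: int) -> float:
    """P(|U − mn/2| >= |w − mn/2|) under the exact (symmetric) null."""
    pmf = np.array(rank_sum_null_distribution(m, n))
    center = m * n / 2.0
    dev = abs(w - center)
    u = np.arange(m * n + 1)
    return float(pmf[np.abs(u - center) >= dev - 1e-12].sum())


def wilcoxon_rank_sum(x, y, exact_max_total: int = 20) -> RankSumResult:
    """Unpaired two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    ``W = #{(i,j): x_i > y_j} + ½·#ties``. The p-value is exact by
    enumeration when ``n_x + n_y <= exact_max_total`` and there are no ties,
    otherwise a normal approximation with tie and continuity corrections is
    used. The Hodges–Lehmann estimate is the median of all pairwise
    differences ``x_i − y_j``; its 95% CI comes from the ordered pairwise
    differences at the exact (or approximated) rank-sum critical values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise InsufficientSampleError("rank-sum test needs >= 2 per group")

    diffs = (x[:, None] - y[None, :]).ravel()
    w = float(np.sum(diffs > 0) + 0.5 * np.sum(diffs == 0))
    hl = float(np.median(diffs))
    has_ties = len(np.unique(np.concatenate([x, y]))) < m + n
    degenerate = np.all(np.concatenate([x, y]) == x[0])

    if degenerate:
        return RankSumResult(m, n, w, float("nan"), hl, float("nan"), float("nan"),
                             exact=False, degenerate=True)

    exact = (m + n) <= exact_max_total and not has_ties
    if exact:
        p = _exact_two_sided_p(w, m, n)
    else:
        combined = np.concatenate([x, y])
        _, tie_counts = np.unique(combined, return_counts=True)
        nn = m + n
        var = m * n / 12.0 * ((nn + 1) - np.sum(tie_counts**3 - tie_counts) / (nn * (nn - 1)))
        if var <= 0:
            p = float("nan")
        else:
            zstat = (abs(w - m * n / 2.0) - 0.5) / math.sqrt(var)
            p = 2.0 * float(sps.norm.sf(max(zstat, 0.0)))
    p = min(p, 1.0) if not math.isnan(p) else p

    # Hodges-Lehmann CI from ordered pairwise differences
    sorted_diffs = np.sort(diffs)
    k = _hl_critical_k(m, n, alpha=0.05)
    if k is None or k + 1 > m * n - k:
        ci_low, ci_high = float(sorted_diffs[0]), float(sorted_diffs[-1])
    else:
        ci_low = float(sorted_diffs[k])          # D_(k+1), 1-indexed
        ci_high = float(sorted_diffs[m * n - 1 - k])  # D_(mn-k)
    return RankSumResult(m, n, w, float(p), hl, ci_low, ci_high, exact=exact)


def _hl_critical_k(m: int, n: int, alpha: float) -> int | None:
    """Largest k with P(U <= k) <= alpha/2 under the null; None if no such k."""
    if m * n <= 400:
        pmf = np.array(rank_sum_null_distribution(m, n))
        cdf = np.cumsum(pmf)
        ks = np.nonzero(cdf <= alpha / 2 + 1e-12)[0]
        return int(ks[-1]) if len(ks) else None
    z = float(sps.norm.ppf(1 - alpha / 2))
    k = int(math.floor(m * n / 2.0 - z * math.sqrt(m * n * (m + n + 1) / 12.0)))
    return k if k >= 0 else None


def minimum_detectable_change(inputs: MDCInputs) -> float:
    """MDC = z·√2·SEM with SEM = SD·√(1−ICC); 0 at perfect reliability."""
    return inputs.z * math.sqrt(2.0) * inputs.sem


def compare_to_mdc(differences, mdc: float) -> MDCComparison:
    """Flag each within-image difference against a detectability threshold.

    A |difference| below the MDC is indistinguishable from measurement
    error; a median below the MDC indicates group-level resolution of
    injured and healthy texture has been lost (tissue resembles healthy).
    """
    if mdc < 0:
        raise ValidationError("mdc must be >= 0")
    d = np.asarray(differences, dtype=float)
    below = [bool(abs(v) < mdc) for v in d]
    med = float(np.median(d))
    return MDCComparison(below, med, abs(med) < mdc, mdc)


# ---------------------------------------------------------------------------
# report-shaped summaries
# ---------------------------------------------------------------------------


def _records_frame(records: list[StudyRecord]) -> pd.DataFrame:
    rows = [
        {
            "athlete_id": r.athlete_id,
            "limb": r.limb,
            "timepoint": r.timepoint,
            "region": r.region,
            "psfr": r.roi_result.mean_psfr,
            "mmax": r.roi_result.mean_mmax_pct,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    if len(df) != len(df.drop_duplicates(["athlete_id", "limb", "timepoint", "region"])):
        raise ValidationError("duplicate (athlete, limb, timepoint, region) records")
    return df


def summarize_table2(
    records: list[StudyRecord],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-limb, per-region means (SD) with paired t-tests at time of injury.

    Athletes missing either member of an injured/adjacent pair are excluded
    from that limb (listwise) and reported in the returned exclusion log.
    """
    df = _records_frame(records)
    df = df[df.timepoint == "TOI"]
    rows = []
    exclusions: list[str] = []
    for param in ("psfr", "mmax"):
        for limb in ("involved", "contralateral"):
            sub = df[df.limb == limb].pivot(
                index="athlete_id", columns="region", values=param
            )
            if sub.empty or "injured" not in sub or "adjacent" not in sub:
                continue
            incomplete = sub.index[sub[["injured", "adjacent"]].isna().any(axis=1)]
            for a in incomplete:
                exclusions.append(f"{limb}/{param}: athlete {a} missing a pair member")
            sub = sub.dropna(subset=["injured", "adjacent"])
            n = len(sub)
            test: PairedTestResult | None = None
            if n >= 3:
                test = paired_ttest(sub["adjacent"].to_numpy(), sub["injured"].to_numpy())
            for region in ("injured", "adjacent"):
                rows.append(
                    {
                        "parameter": param,
                        "limb": limb,
                        "region": region,
                        "n": n,
                        "mean": float(sub[region].mean()),
                        "sd": float(sub[region].std(ddof=1)) if n > 1 else float("nan"),
                        "p_value": test.p if test else float("nan"),
                        "ci_low": test.ci_low if test else float("nan"),
                        "ci_high": test.ci_high if test else float("nan"),
                        "flag": "" if test else "insufficient-n",
                    }
                )
    return pd.DataFrame(rows), exclusions


def summarize_table3(
    toi_differences: dict[str, np.ndarray],
    rts_differences: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, dict[str, RankSumResult]]:
    """Medians [IQR] of within-image differences per timepoint, with the
    rank-sum comparison (time of injury vs return to sport) per parameter.

    Quartiles use linear interpolation (type 7), the numpy default.
    """
    rows = []
    tests: dict[str, RankSumResult] = {}
    for param in sorted(set(toi_differences) | set(rts_differences)):
        toi = np.asarray(toi_differences.get(param, []), dtype=float)
        rts = np.asarray(rts_differences.get(param, []), dtype=float)
        res = None
        if len(toi) >= 2 and len(rts) >= 2:
            res = wilcoxon_rank_sum(toi, rts)
            tests[param] = res
        for label, vals in (("TOI", toi), ("RTS", rts)):
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "parameter": param,
                    "timepoint": label,
                    "n": len(vals),
                    "median": float(np.median(vals)),
                    "iqr_low": float(np.percentile(vals, 25)),
                    "iqr_high": float(np.percentile(vals, 75)),
                    "W": res.w if res and label == "TOI" else float("nan"),
                    "p_value": res.p if res and label == "TOI" else float("nan"),
                    "hl_estimate": res.hl_estimate if res and label == "TOI" else float("nan"),
                    "ci_low": res.ci_low if res and label == "TOI" else float("nan"),
                    "ci_high": res.ci_high if res and label == "TOI" else float("nan"),
                }
            )
    return pd.DataFrame(rows), tests
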