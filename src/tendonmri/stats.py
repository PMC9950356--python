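"""Method-comparison statistics: Spearman rank correlation (tie-aware,
with an exact permutation p-value at small n), Bland–Altman limits of
agreement on log-transformed data (ratio scale), and percent agreement for
binary lesion detection.

The log-scale Bland–Altman analysis backtransforms the mean and the
1.96·SD limits of the pairwise log-differences, yielding the geometric
mean ratio between two measurement methods and the interval expected to
contain ~95% of between-method ratios.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InputError, UndefinedResultError

#: permutation p-values are exact up to this sample size; above it a
#: t-distribution approximation is used.
EXACT_PERMUTATION_MAX_N = 10


@dataclass
class BlandAltmanResult:
    """Ratio-scale limits of agreement between two measurement methods."""

    mean_ratio: float
    loa_lower: float
    loa_upper: float
    n: int
    #: per-pair ratios a_i/b_i and geometric means sqrt(a_i·b_i), plot-ready
    ratios: np.ndarray = field(repr=False, default=None)
    pair_means: np.ndarray = field(repr=False, default=None)


@dataclass
class AgreementResult:
    """Container for the statistics of one method comparison.

    Only the fields produced by the analyses actually run are populated;
    the rest stay None.
    """

    n: int
    spearman_r: float | None = None
    p_value: float | None = None
    mean_ratio: float | None = None
    loa_lower: float | None = None
    loa_upper: float | None = None
    percent_agreement: float | None = None

    def __post_init__(self) -> None:
        if self.mean_ratio is not None:
            if not (self.loa_lower <= self.mean_ratio <= self.loa_upper):
                raise InputError("limits of agreement must bracket the mean ratio")


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise UndefinedResultError("correlation undefined for a constant vector")
    return float(xc @ yc) / denom


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided p by full enumeration of the n! orderings of one rank vector."""
    n = rx.size
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    threshold = abs(r_obs) - 1e-12
    count = 0
    total = 0
    chunk: list = []
    chunk_size = 40320
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == chunk_size:
            s = np.abs(ryc[np.array(chunk)] @ rxc) / denom
            count += int(np.count_nonzero(s >= threshold))
            total += len(chunk)
            chunk = []
    if chunk:
        s = np.abs(ryc[np.array(chunk)] @ rxc) / denom
        count += int(np.count_nonzero(s >= threshold))
        total += len(chunk)
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a tie-aware r and a two-sided p.

    r is the Pearson correlation of mid-ranks (correct under ties, unlike
    the Σd² shortcut).  For n ≤ 10 the p-value is exact, enumerating all
    n! permutations; for larger n the usual t-approximation with n − 2
    degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise InputError("Spearman correlation needs at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("inputs must be finite")
    rx, ry = _midranks(x), _midranks(y)
    r = _pearson(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, r)
    else:
        r_clipped = min(max(r, -1.0), 1.0)
        if abs(r_clipped) == 1.0:
            p = 0.0
        else:
            t = r_clipped * math.sqrt((n - 2) / (1.0 - r_clipped ** 2))
            p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return r, p


def bland_altman_log(method_a, method_b) -> BlandAltmanResult:
    """Ratio-scale Bland–Altman limits of agreement.

    Computes d_i = ln(a_i) − ln(b_i) and backtransforms mean(d) and
    mean(d) ± 1.96·SD(d) (sample SD, n − 1) through exp, giving the
    geometric mean ratio a/b and its 95% limits of agreement.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("methods must be 1-D arrays of equal length")
    if a.size < 2:
        raise InputError("limits of agreement need at least 2 pairs")
    for name, arr in (("a", a), ("b", b)):
        bad = np.flatnonzero(~(arr > 0) | ~np.isfinite(arr))
        if bad.size:
            raise InputError(
                f"method {name} has a non-positive value at pair index {bad[0]}"
            )
    d = np.log(a) - np.log(b)
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_ratio=math.exp(mean_d),
        loa_lower=math.exp(mean_d - 1.96 * sd_d),
        loa_upper=math.exp(mean_d + 1.96 * sd_d),
        n=int(a.size),
        ratios=a / b,
        pair_means=np.exp((np.log(a) + np.log(b)) / 2.0),
    )


def percent_agreement(detect_a, detect_b) -> float:
    """Share (%) of positions where two binary detection vectors agree."""
    a = np.asarray(detect_a, dtype=bool)
    b = np.asarray(detect_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("detection vectors must be 1-D and of equal length")
    if a.size < 1:
        raise InputError("detection vectors must be non-empty")
    return 100.0 * float(np.count_nonzero(a == b)) / a.size


def compare_methods(
    a,
    b,
    *,
    correlation: bool = True,
    limits: bool = True,
) -> AgreementResult:
    """Convenience wrapper bundling Spearman r/p and ratio-scale limits."""
    a = np.asarray(a, dtype=float)
    result = AgreementResult(n=int(a.size))
    if correlation:
        result.spearman_r, result.p_value = spearman(a, b)
    if limits:
        ba = bland_altman_log(a, b)
        result.mean_ratio = ba.mean_ratio
        result.loa_lower = ba.loa_lower
        result.loa_upper = ba.loa_upper
    return result
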