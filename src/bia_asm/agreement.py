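"""Method-comparison statistics between predicted and reference ASM.

Implements the Sheiner–Beal bias/precision pair — mean error
ME = mean(predicted - reference) and RMSE = sqrt(mean d^2) — with 95%
confidence intervals, Bland–Altman 95% limits of agreement
ME +/- 1.96 * SD(d), the Pearson correlation and the paired t-test.

The difference orientation is predicted - reference throughout, so a
negative ME means the equation underestimates the reference method.

Numerical notes: SD(d) uses the n-1 denominator while the RMSE uses the
1/n mean square, which gives the exact identity
RMSE^2 = ME^2 + SD(d)^2 * (n-1)/n.  The RMSE CI is a delta-method interval
on the mean square (MSE +/- t * SD(d^2)/sqrt(n), endpoints square-rooted,
lower endpoint floored at 0); a seeded nonparametric bootstrap is available
as a cross-check since published reports rarely state their RMSE CI method.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UndefinedCorrelationError, ValidationError

#: conventional Bland-Altman multiplier (normal 97.5% point, not a t-quantile)
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedSeries:
    """Aligned predicted/reference ASM vectors (kg) for one stratum."""

    predicted: np.ndarray
    reference: np.ndarray
    stratum_label: str = ""

    def __post_init__(self):
        pred = np.asarray(self.predicted, dtype=float)
        ref = np.asarray(self.reference, dtype=float)
        if pred.shape != ref.shape or pred.ndim != 1:
            raise ValidationError(
                f"predicted and reference must be equal-length 1-d vectors, "
                f"got shapes {pred.shape} and {ref.shape}"
            )
        if not (np.isfinite(pred).all() and np.isfinite(ref).all()):
            raise ValidationError("paired series contain non-finite values; drop pairs upstream")
        if pred.size < 2:
            raise InsufficientDataError(f"need at least 2 pairs, got {pred.size}")
        object.__setattr__(self, "predicted", pred)
        object.__setattr__(self, "reference", ref)

    @property
    def n(self) -> int:
        return int(self.predicted.size)

    @property
    def differences(self) -> np.ndarray:
        return self.predicted - self.reference


@dataclass(frozen=True)
class AgreementResult:
    """Full agreement summary for one (equation, stratum) cell."""

    n: int
    mean_error: float
    me_ci: Tuple[float, float]
    rmse: float
    rmse_ci: Tuple[float, float]
    pearson_r: Optional[float]
    pearson_p: Optional[float]
    loa: Tuple[float, float]
    paired_t_p: float
    sd_diff: float
    degenerate_variance: bool = False
    rmse_ci_bootstrap: Optional[Tuple[float, float]] = None


def _as_pairs(pairs) -> PairedSeries:
    if isinstance(pairs, PairedSeries):
        return pairs
    pred, ref = pairs
    return PairedSeries(np.asarray(pred, float), np.asarray(ref, float))


def mean_error(pairs) -> Tuple[float, Tuple[float, float], float]:
    """Sheiner-Beal bias: ME, its 95% t-interval, and the paired-t p-value.

    With zero variance of the differences the CI degenerates to (ME, ME)
    and the p-value is 0 or 1 depending on whether ME is nonzero.
    """
    pairs = _as_pairs(pairs)
    d = pairs.differences
    n = pairs.n
    me = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return me, (me, me), (1.0 if me == 0.0 else 0.0)
    tq = stats.t.ppf(0.975, n - 1)
    half = tq * sd / np.sqrt(n)
    t_stat = me / (sd / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t_stat), n - 1))
    return me, (me - half, me + half), p


def rmse(pairs) -> Tuple[float, Tuple[float, float]]:
    """Sheiner-Beal precision: RMSE and its delta-method 95% CI."""
    pairs = _as_pairs(pairs)
    d = pairs.differences
    n = pairs.n
    d2 = d**2
    mse = float(d2.mean())
    value = float(np.sqrt(mse))
    sd_d2 = float(d2.std(ddof=1))
    if sd_d2 == 0.0:
        return value, (value, value)
    tq = stats.t.ppf(0.975, n - 1)
    half = tq * sd_d2 / np.sqrt(n)
    lo = float(np.sqrt(max(mse - half, 0.0)))
    hi = float(np.sqrt(mse + half))
    return value, (lo, hi)


def rmse_bootstrap_ci(pairs, n_boot: int = 2000, seed: int = 0) -> Tuple[float, float]:
    """Percentile bootstrap 95% CI for the RMSE (seeded, 2000 resamples)."""
    pairs = _as_pairs(pairs)
    d = pairs.differences
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    boots = np.sqrt((d[idx] ** 2).mean(axis=1))
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return float(lo), float(hi)


def bland_altman(pairs) -> Tuple[float, float]:
    """95% limits of agreement ME +/- 1.96 * SD(d), SD with n-1 denominator."""
    pairs = _as_pairs(pairs)
    d = pairs.differences
    me = float(d.mean())
    sd = float(d.std(ddof=1))
    return me - LOA_MULTIPLIER * sd, me + LOA_MULTIPLIER * sd


def pearson(pairs) -> Tuple[float, float]:
    """Sample Pearson correlation and its two-sided p-value."""
    pairs = _as_pairs(pairs)
    if pairs.n < 3:
        raise InsufficientDataError(f"Pearson correlation needs n >= 3, got {pairs.n}")
    if np.ptp(pairs.predicted) == 0.0 or np.ptp(pairs.reference) == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    res = stats.pearsonr(pairs.predicted, pairs.reference)
    return float(res.statistic), float(res.pvalue)


def compare(
    pairs,
    bootstrap_check: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementResult:
    """All agreement statistics for one stratum in a single result object.

    When ``bootstrap_check`` is set, the bootstrap RMSE CI is computed and
    attached whenever either endpoint disagrees with the delta-method CI by
    more than 10% (relative to the RMSE), flagging strata where the CI
    method matters.
    """
    pairs = _as_pairs(pairs)
    me, me_ci, p = mean_error(pairs)
    rm, rm_ci = rmse(pairs)
    loa = bland_altman(pairs)
    sd = float(pairs.differences.std(ddof=1))
    try:
        r, r_p = pearson(pairs)
    except (InsufficientDataError, UndefinedCorrelationError):
        r, r_p = None, None
    boot_ci = None
    if bootstrap_check and rm > 0:
        candidate = rmse_bootstrap_ci(pairs, n_boot=n_boot, seed=seed)
        rel = max(abs(candidate[0] - rm_ci[0]), abs(candidate[1] - rm_ci[1])) / rm
        if rel > 0.10:
            boot_ci = candidate
    return AgreementResult(
        n=pairs.n,
        mean_error=me,
        me_ci=me_ci,
        rmse=rm,
        rmse_ci=rm_ci,
        pearson_r=r,
        pearson_p=r_p,
        loa=loa,
        paired_t_p=p,
        sd_diff=sd,
        degenerate_variance=(sd == 0.0),
        rmse_ci_bootstrap=boot_ci,
    )
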