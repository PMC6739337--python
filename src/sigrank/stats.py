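"""One-tailed tests comparing observed and randomized rank distributions.

The alternative hypothesis in both tests is that the observed values are
stochastically *greater* than the randomized control:

* one-tailed Kolmogorov-Smirnov: D+ = sup_x [ECDF_null(x) - ECDF_obs(x)],
  with the one-sided asymptotic tail bound p = exp(-2 m n D+^2 / (m+n)).
  Larger observed values push the observed ECDF below the null ECDF and
  so increase D+ and shrink p.
* one-tailed paired t: on entity-aligned differences d = observed - null,
  t = mean(d) / (sd(d)/sqrt(n)) with the upper-tail Student-t p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .data_model import ValidationError

__all__ = ["TestResult", "ks_one_tailed", "paired_t_one_tailed"]

ALTERNATIVE = "observed stochastically greater than null"


@dataclass(frozen=True)
class TestResult:
    test_name: str  # "ks_one_tailed" | "paired_t_one_tailed"
    statistic: float
    p_value: float
    alternative: str
    n_observed: int
    n_null: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError(f"p-value outside [0, 1]: {self.p_value}")

    @property
    def summary(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "n_observed": self.n_observed,
            "n_null": self.n_null,
        }


def _clean(sample, name: str) -> np.ndarray:
    arr = np.asarray(sample, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name} sample is empty")
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name} sample contains non-finite values")
    return arr


def ks_one_tailed(observed, null_sample) -> TestResult:
    """One-sided two-sample Kolmogorov-Smirnov test.

    D+ is the largest excess of the null ECDF over the observed ECDF; the
    p-value uses the one-sided asymptotic bound
    exp(-2 m n D+^2 / (m + n)).
    """
    obs = np.sort(_clean(observed, "observed"))
    nul = np.sort(_clean(null_sample, "null"))
    m, n = obs.size, nul.size
    grid = np.concatenate([obs, nul])
    ecdf_obs = np.searchsorted(obs, grid, side="right") / m
    ecdf_nul = np.searchsorted(nul, grid, side="right") / n
    d_plus = float(max(np.max(ecdf_nul - ecdf_obs), 0.0))
    p = float(min(1.0, np.exp(-2.0 * m * n * d_plus**2 / (m + n))))
    return TestResult(
        test_name="ks_one_tailed",
        statistic=d_plus,
        p_value=p,
        alternative=ALTERNATIVE,
        n_observed=m,
        n_null=n,
    )


def paired_t_one_tailed(observed, null_sample) -> TestResult:
    """One-sided paired t-test on entity-aligned samples.

    Tests whether the mean of observed - null differences is greater than
    zero.  The caller is responsible for aligning the two samples on the
    same entities, in the same order.
    """
    obs = _clean(observed, "observed")
    nul = _clean(null_sample, "null")
    if obs.size != nul.size:
        raise ValidationError(
            f"paired samples differ in length: {obs.size} vs {nul.size}"
        )
    if obs.size < 2:
        raise ValidationError("paired t-test needs at least 2 pairs")
    d = obs - nul
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise ValidationError("zero-variance differences; paired t degenerate")
    n = d.size
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(sps.t.sf(t, df=n - 1))
    return TestResult(
        test_name="paired_t_one_tailed",
        statistic=t,
        p_value=p,
        alternative=ALTERNATIVE,
        n_observed=n,
        n_null=n,
    )
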