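"""Replicate-level hypothesis tests.

The two t-tests applied to per-locus replicate statistics (Welch's unpaired
unequal-variance test for cut-vs-uncut contrasts, the paired test for
within-replicate contrasts) are implemented from first principles: the test
statistic and Welch-Satterthwaite degrees of freedom are computed here, with
only the t distribution's survival function taken from scipy.  All p-values
are two-sided.  No multiple-testing correction is applied: the pipeline
tests a handful of named loci and reports raw per-locus p-values.

``binomial_density_test`` is the exact two-sided binomial test used to
compare per-nucleotide read densities across a pol-III terminator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    kind: str  # "welch_unpaired" or "paired"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not (0.0 <= self.p <= 1.0):
                raise ValueError(f"p-value out of range: {self.p}")
            if self.df <= 0:
                raise ValueError(f"df must be > 0, got {self.df}")


def _two_sided_p(t: float, df: float) -> float:
    return float(2.0 * sps.t.sf(abs(t), df))


def welch_ttest(x, y) -> TTestResult:
    """Welch's unpaired, unequal-variance two-sample t-test (two-sided).

    t = (x̄ − ȳ) / sqrt(s²ₓ/nₓ + s²ᵧ/nᵧ) with Welch–Satterthwaite degrees
    of freedom.  Requires >= 2 values per sample; two zero-variance samples
    with equal means are flagged degenerate (no scale to test against).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("welch_ttest needs >= 2 values per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        delta = float(x.mean() - y.mean())
        if delta == 0.0:
            return TTestResult(0.0, float(nx + ny - 2), 1.0, "welch_unpaired", True)
        # zero variance but distinct means: the limit is certainty
        return TTestResult(
            math.copysign(math.inf, delta), float(nx + ny - 2), 0.0,
            "welch_unpaired", True,
        )
    t = float((x.mean() - y.mean()) / math.sqrt(se2))
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return TTestResult(t, float(df), _two_sided_p(t, df), "welch_unpaired")


def paired_ttest(x, y) -> TTestResult:
    """Paired two-sided t-test: one-sample t on d = x − y, df = n − 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired_ttest needs equal-length samples")
    n = len(x)
    if n < 2:
        raise ValueError("paired_ttest needs >= 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        mean = float(d.mean())
        if mean == 0.0:
            return TTestResult(0.0, float(n - 1), 1.0, "paired", True)
        # all differences identical and nonzero: limit case of vanishing noise
        return TTestResult(math.copysign(math.inf, mean), float(n - 1), 0.0,
                           "paired", True)
    t = float(d.mean() / (sd / math.sqrt(n)))
    df = float(n - 1)
    return TTestResult(t, df, _two_sided_p(t, df), "paired")


def binomial_density_test(
    up_count: int, up_len: int, down_count: int, down_len: int
) -> float | None:
    """Exact two-sided binomial test of equal per-nt read density.

    Under the null the ``up_count + down_count`` reads fall upstream with
    probability ``up_len / (up_len + down_len)``; the two-sided p-value sums
    all outcomes no more likely than the observed one.  Returns ``None``
    (undefined) when there are no reads at all.
    """
    if up_count < 0 or down_count < 0:
        raise ValueError("counts must be >= 0")
    if up_len <= 0 or down_len <= 0:
        raise ValueError("segment lengths must be > 0")
    n = up_count + down_count
    if n == 0:
        return None
    p0 = up_len / (up_len + down_len)
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    # minlike two-sided: sum outcomes with probability <= observed (within fp slack)
    observed = pmf[up_count]
    p = float(pmf[pmf <= observed * (1 + 1e-10)].sum())
    return min(1.0, p)
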