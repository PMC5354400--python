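"""Closed-form assay quantifications and the shared group test.

Three small calculations used across the bench assays: population
doubling time under constant exponential growth, relative qPCR
expression by the delta-delta-Ct method against a housekeeping
reference, and the unpaired Student t-test (pooled variance) that backs
every group comparison, with significance declared strictly below the
5% level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GrowthMeasurement", "QpcrSample", "doubling_time",
           "ddct_fold", "unpaired_t", "NoGrowthError"]


class NoGrowthError(ValueError):
    """Raised when nt == n0: the doubling time is undefined."""


@dataclass
class GrowthMeasurement:
    """Viable-cell signal at t = 0 and after t hours of culture."""

    n0: float
    nt: float
    t: float

    def __post_init__(self):
        if self.n0 <= 0 or self.nt <= 0 or self.t <= 0:
            raise ValueError("n0, nt and t must all be positive")


@dataclass
class QpcrSample:
    """Cycle thresholds of the target and the reference gene."""

    ct_target: float
    ct_reference: float

    def __post_init__(self):
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and positive")

    @property
    def dct(self):
        return self.ct_target - self.ct_reference


def doubling_time(m):
    """Doubling time DT = t * ln2 / ln(nt / n0), in the units of t.

    Assumes a constant growth rate between the two measurements. A
    declining culture (nt < n0) returns a negative DT together with a
    decline flag rather than raising, so batch tables never abort.

    Returns (dt, declining).
    """
    if isinstance(m, (tuple, list)):
        m = GrowthMeasurement(*m)
    if m.nt == m.n0:
        raise NoGrowthError("nt equals n0: no net growth, DT undefined")
    dt = m.t * math.log(2.0) / math.log(m.nt / m.n0)
    return dt, dt < 0


def ddct_fold(condition, control):
    """Relative expression 2^(-ddCt) of condition versus control.

    dCt = Ct_target - Ct_reference within each sample; ddCt is the
    condition-minus-control difference of dCt.
    """
    if isinstance(condition, (tuple, list)):
        condition = QpcrSample(*condition)
    if isinstance(control, (tuple, list)):
        control = QpcrSample(*control)
    ddct = condition.dct - control.dct
    return 2.0 ** (-ddct)


def unpaired_t(a, b, alpha=0.05):
    """Student t-test for unpaired samples (pooled variance).

    Returns (t, df, p, significant) with significance strictly below
    ``alpha``. Identical constant samples give t = 0, p = 1. A Welch
    variant is available via ``equal_var=False`` on scipy directly; the
    pooled test is the contract here because it is the named test
    behind all the group comparisons.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):                      # zero pooled variance
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = math.inf if a.mean() > b.mean() else -math.inf, 0.0
    df = a.size + b.size - 2
    return float(t), int(df), float(p), bool(p < alpha)
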