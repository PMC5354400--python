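"""Differential-expression screen for a two-group intensity matrix.

A gene is called differentially expressed when its absolute variation
factor — the folded linear ratio max(r, 1/r) of the two group means —
is at least ``fc_threshold`` (default 2.3) AND its Benjamini–Hochberg
adjusted p-value is strictly below ``alpha`` (default 0.05). The
per-gene p comes from a two-sample Student t-test (pooled variance) on
log2 intensities — the unpaired Student test is the one test the study
design names, and with triplicate groups the pooled test retains far
more power than the Welch variant, whose degrees of freedom collapse at
n = 3. Welch is available via ``welch=True``; moderated-variance tests
are deliberately out of scope.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["gene_stats", "bh_adjust", "select_degs", "deg_screen"]

FC_THRESHOLD = 2.3
ALPHA = 0.05


def _split_groups(matrix, groups):
    cols_a = [c for c in matrix.columns if groups[c] == "A"]
    cols_b = [c for c in matrix.columns if groups[c] == "B"]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 samples per group")
    return matrix[cols_a].to_numpy(float), matrix[cols_b].to_numpy(float)


def gene_stats(matrix, groups, input_scale="linear", welch=False):
    """Per-gene means, variation factor, direction and raw t-test p.

    Parameters
    ----------
    matrix : DataFrame, genes x samples, positive linear intensities
        (or log2 values with ``input_scale="log2"``).
    groups : mapping sample -> "A" | "B".
    welch : use the unequal-variance test instead of the pooled one.

    The variation factor is the folded linear ratio
    ``max(mean_B/mean_A, mean_A/mean_B)``; the raw p is a two-sided
    two-sample t-test on log2 values. Genes with zero variance in both
    groups get p = 1 when the means agree and p = 0 (with a warning)
    when they do not.
    """
    matrix = pd.DataFrame(matrix)
    if input_scale == "log2":
        matrix = 2.0 ** matrix
    elif input_scale != "linear":
        raise ValueError("input_scale must be 'linear' or 'log2'")
    vals = matrix.to_numpy(float)
    if np.any(~np.isfinite(vals)):
        raise ValueError("matrix contains missing or non-finite values")
    if np.any(vals <= 0):
        raise ValueError("linear intensities must be strictly positive")

    a, b = _split_groups(matrix, groups)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    r = mean_b / mean_a
    vf = np.maximum(r, 1.0 / r)
    direction = np.where(np.isclose(r, 1.0), "none",
                         np.where(r > 1.0, "up", "down"))

    la, lb = np.log2(a), np.log2(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=not welch)
    degenerate = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    equal_means = np.isclose(la.mean(axis=1), lb.mean(axis=1))
    p = np.where(degenerate & equal_means, 1.0, p)
    if np.any(degenerate & ~equal_means):
        warnings.warn("genes with zero within-group variance but unequal "
                      "means: p set to 0", stacklevel=2)
        p = np.where(degenerate & ~equal_means, 0.0, p)
    p = np.nan_to_num(p, nan=1.0)

    return pd.DataFrame({
        "mean_A": mean_a, "mean_B": mean_b,
        "variation_factor": vf, "direction": direction,
        "p_raw": p,
    }, index=matrix.index)


def bh_adjust(p_values):
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min over j >= i of p_(j) * m / j on the ascending sort,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(gstats, fc_threshold=FC_THRESHOLD, alpha=ALPHA):
    """Apply the dual DEG criterion to a gene_stats table.

    A gene is flagged when variation_factor >= fc_threshold (non-strict,
    so a factor of exactly 2.3 qualifies) and BH-adjusted p < alpha
    (strict, so adjusted p of exactly 0.05 does not).
    """
    out = gstats.copy()
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["is_deg"] = (out["variation_factor"] >= fc_threshold) & \
        (out["p_adj"] < alpha)
    return out


def deg_screen(matrix, groups, fc_threshold=FC_THRESHOLD, alpha=ALPHA,
               input_scale="linear"):
    """Full screen: stats + BH + selection. Returns the DEGTable."""
    return select_degs(gene_stats(matrix, groups, input_scale=input_scale),
                       fc_threshold=fc_threshold, alpha=alpha)


def deg_list(table):
    """Ordered list of gene ids flagged as DEGs."""
    return list(table.index[table["is_deg"]])
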