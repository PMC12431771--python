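"""Empirical significance machinery for resampled population statistics.

Population-level quantities in this package come as distributions over
resampling runs rather than as single numbers, so hypothesis tests on them
are empirical: to test whether ``x`` exceeds ``y`` (a paired run
distribution or a constant), count the runs where it fails and divide by
the number of runs.  Ties count against significance by default
(conservative).  Standard single-neuron tests (signed-rank, rank-sum,
ANOVA) are used directly from scipy elsewhere; this module only adds what
the resampling scheme requires, plus Benjamini–Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["EmpiricalComparison", "empirical_paired_pvalue", "fdr_adjust"]


@dataclass(frozen=True)
class EmpiricalComparison:
    """One-sided empirical p-value for ``x > y`` over paired runs.

    ``r`` counts failures (runs with ``x - y < 0``, plus ties under the
    default tie rule); ``p = r / M``.  When no run fails the p-value is
    censored at ``1 / M`` (reported as "< 1/M").
    """

    r: int
    M: int
    p: float
    censored: bool


def empirical_paired_pvalue(
    x_runs: np.ndarray,
    y_runs_or_constant: np.ndarray | float,
    ties: str = "fail",
) -> EmpiricalComparison:
    """Empirical one-sided p-value that ``x`` exceeds ``y`` across runs.

    Parameters
    ----------
    x_runs : array of per-run values.
    y_runs_or_constant : paired per-run values, or a scalar reference
        (e.g. the chance level).
    ties : ``"fail"`` (default) counts runs with ``x == y`` against
        significance; ``"strict"`` counts only ``x - y < 0``.

    The statistic is invariant under any strictly monotone transform
    applied to both sides.
    """
    x = np.asarray(x_runs, dtype=float)
    y = np.asarray(y_runs_or_constant, dtype=float)
    if y.ndim == 0:
        y = np.full_like(x, float(y))
    if x.shape != y.shape:
        raise ValueError("x and y must have equal run counts")
    M = len(x)
    if M < 1:
        raise ValueError("need at least one run")
    if ties not in ("fail", "strict"):
        raise ValueError("ties must be 'fail' or 'strict'")
    d = x - y
    r = int(np.sum(d < 0))
    if ties == "fail":
        r += int(np.sum(d == 0))
    if r == 0:
        return EmpiricalComparison(r=0, M=M, p=1.0 / M, censored=True)
    return EmpiricalComparison(r=r, M=M, p=r / M, censored=False)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    return multipletests(p, method="fdr_bh")[1]
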