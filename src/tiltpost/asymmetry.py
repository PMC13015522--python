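"""Direction-asymmetry index from pairwise MAPE distributions.

To quantify how mirror-symmetric the responses to opposite perturbation
directions are (left vs right roll, forward vs backward pitch), two
distributions of pairwise mean absolute percentage error (MAPE) are built
from the per-trial response traces:

- within-direction: MAPE over all trial pairs within direction 1 plus all
  pairs within direction 2, combined;
- across-direction: one direction's traces are inverted and pooled with
  the other's, and MAPE is computed over all pairs of the pooled set
  regardless of direction (so same-direction pairs re-enter; a
  cross-direction-only mode is available).

The asymmetry index is mean(across) - mean(within): 0 for perfectly
mirror-symmetric responses, positive when opposite directions differ more
than repeats of the same direction.  Significance is assessed with a
two-tailed Welch t-test between the two MAPE distributions (null:
symmetry), and per-(animal, stimulus) p-values are combined across the
dataset with Fisher's method.

MAPE normalization: per-sample percentage error is unstable for
zero-crossing traces, so the default normalizes the mean absolute
difference by the time-mean |reference| of the first trace of the pair;
a symmetric variant normalizes by the mean of both traces' levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AsymmetryResult",
    "pairwise_mape",
    "asymmetry_index",
    "fisher_combine",
]


def pairwise_mape(a: np.ndarray, b: np.ndarray, mode: str = "reference") -> float:
    """Mean absolute percentage error between two equal-length traces, %.

    ``mode="reference"`` normalizes by mean |a| (the first trace);
    ``mode="symmetric"`` by the average of mean |a| and mean |b|, which
    makes the value invariant to swapping the pair.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be equal-length 1-D arrays")
    if mode == "reference":
        denom = float(np.mean(np.abs(a)))
    elif mode == "symmetric":
        denom = 0.5 * (float(np.mean(np.abs(a))) + float(np.mean(np.abs(b))))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0.0:
        raise ValueError("degenerate normalization: reference trace is identically zero")
    return 100.0 * float(np.mean(np.abs(a - b))) / denom


def _pair_mapes(traces: list[np.ndarray], mode: str) -> np.ndarray:
    """MAPE over all unordered pairs (i < j) of a trace list."""
    n = len(traces)
    vals = [
        pairwise_mape(traces[i], traces[j], mode=mode)
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return np.asarray(vals)


@dataclass(frozen=True)
class AsymmetryResult:
    """Within/across MAPE distributions and the derived index."""

    within_mapes: np.ndarray  # %
    across_mapes: np.ndarray  # %
    index: float  # mean(across) - mean(within), %
    t_statistic: float
    p_value: float  # two-tailed Welch t-test

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def asymmetry_index(
    dir1_traces: list[np.ndarray],
    dir2_traces: list[np.ndarray],
    mode: str = "reference",
    across: str = "all-pairs",
) -> AsymmetryResult:
    """Asymmetry index between two opposite-direction trial sets.

    ``dir1_traces`` and ``dir2_traces`` are per-trial response traces of
    the two directions on a shared grid (>= 2 trials each), typically
    restricted to the platform-motion span.  ``across="all-pairs"`` uses
    every pair of the pooled set {dir1 u inverted dir2};
    ``across="cross-only"`` restricts to pairs spanning the directions.
    """
    if len(dir1_traces) < 2 or len(dir2_traces) < 2:
        raise ValueError("need at least 2 trials per direction")
    within = np.concatenate(
        [_pair_mapes(list(dir1_traces), mode), _pair_mapes(list(dir2_traces), mode)]
    )
    inverted = [-np.asarray(tr, dtype=float) for tr in dir2_traces]
    if across == "all-pairs":
        pooled = [np.asarray(tr, dtype=float) for tr in dir1_traces] + inverted
        across_vals = _pair_mapes(pooled, mode)
    elif across == "cross-only":
        across_vals = np.asarray(
            [pairwise_mape(a, b, mode=mode) for a in dir1_traces for b in inverted]
        )
    else:
        raise ValueError(f"unknown across mode {across!r}")
    t_stat, p = sps.ttest_ind(across_vals, within, equal_var=False)
    if np.isnan(p):  # zero-variance degenerate case (identical distributions)
        t_stat, p = 0.0, 1.0
    return AsymmetryResult(
        within_mapes=within,
        across_mapes=across_vals,
        index=float(np.mean(across_vals) - np.mean(within)),
        t_statistic=float(t_stat),
        p_value=float(p),
    )


def fisher_combine(p_values: list[float]) -> float:
    """Combine independent p-values with Fisher's method.

    X = -2 * sum(ln p_i) is chi-square with 2k degrees of freedom under
    the global null; returns its upper-tail probability.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError(
            "p-values must lie in (0, 1]; clip exact zeros to a small floor "
            "(e.g. 1e-300) before combining"
        )
    x = -2.0 * float(np.sum(np.log(p)))
    return float(sps.chi2.sf(x, df=2 * p.size))
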