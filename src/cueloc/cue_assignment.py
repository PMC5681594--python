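"""Pre-cueing assignment: flag poorly learned associations, then split the
remaining objects into cued and uncued sets whose mean immediate-test errors
are as close as possible.

The split search is exhaustive by default: for 16 objects there are only
C(16,8)/2 = 6,435 unordered 8-vs-8 partitions, so enumeration is cheap and
guarantees the optimum.  A seeded random-restart heuristic is available for
larger designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd

from .memory_metrics import flag_high_error_trials

__all__ = ["AssignmentResult", "select_flagged", "balanced_partition",
           "balanced_partition_heuristic", "assign_cues"]


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of the cue-assignment procedure.

    ``cued``/``uncued``/``flagged`` partition the full object set;
    ``achieved_abs_mean_diff`` is |mean(cued errors) - mean(uncued errors)|
    in pixels, minimal over the searched partitions.
    """

    cued: tuple
    uncued: tuple
    flagged: tuple
    achieved_abs_mean_diff: float
    n_partitions_searched: int


def select_flagged(immediate_errors: pd.Series, n_flag: int = 2,
                   rng=None, k_sd: float = 2.0) -> tuple:
    """Choose the associations excluded from the cued/uncued comparison.

    All objects whose immediate error exceeds mean + ``k_sd``*SD are flagged.
    If more than ``n_flag`` exceed the threshold, the ``n_flag`` largest
    errors are kept; if fewer, the set is filled up to ``n_flag`` uniformly
    at random from the unflagged objects (seeded via ``rng``).
    """
    errors = pd.Series(immediate_errors)
    if n_flag >= len(errors):
        raise ValueError("n_flag must be smaller than the number of objects")
    idx = flag_high_error_trials(errors.to_numpy(), k_sd=k_sd)
    outliers = list(errors.index[idx])
    if len(outliers) > n_flag:
        # keep the largest errors
        outliers.sort(key=lambda o: -errors[o])
        outliers = outliers[:n_flag]
    elif len(outliers) < n_flag:
        rng = np.random.default_rng(rng)
        pool = [o for o in errors.index if o not in outliers]
        extra = rng.choice(len(pool), size=n_flag - len(outliers),
                           replace=False)
        outliers += [pool[i] for i in sorted(extra)]
    return tuple(outliers)


@lru_cache(maxsize=8)
def _partition_masks(n: int) -> np.ndarray:
    """Boolean matrix of all unordered n/2-vs-n/2 partitions of n items.

    Row order is lexicographic in the index set containing item 0, which is
    the tie-break order of :func:`balanced_partition`.
    """
    half = n // 2
    combos = [c for c in combinations(range(n), half) if c[0] == 0]
    masks = np.zeros((len(combos), n), dtype=bool)
    for i, c in enumerate(combos):
        masks[i, list(c)] = True
    return masks


def balanced_partition(errors: pd.Series) -> AssignmentResult:
    """Exhaustive 8-vs-8 split of 16 objects minimizing the absolute
    difference in mean immediate error between the two halves.

    Ties are broken by the lexicographically smallest first half (in the
    stable order of ``errors.index``).  The first half is labeled ``cued``;
    use :func:`assign_cues` for a seeded coin-flip of the labels.
    """
    errors = pd.Series(errors)
    n = len(errors)
    if n != 16:
        raise ValueError(f"balanced_partition expects 16 objects, got {n}")
    vals = errors.to_numpy(dtype=float)
    masks = _partition_masks(n)
    half = n // 2
    diffs = np.abs(masks @ vals - (~masks) @ vals) / half
    best = int(np.argmin(diffs))  # argmin takes the first: lexicographic tie-break
    ids = np.asarray(errors.index)
    cued = tuple(ids[masks[best]])
    uncued = tuple(ids[~masks[best]])
    return AssignmentResult(cued=cued, uncued=uncued, flagged=(),
                            achieved_abs_mean_diff=float(diffs[best]),
                            n_partitions_searched=len(masks))


def balanced_partition_heuristic(errors: pd.Series, n_restarts: int = 1000,
                                 seed=None) -> AssignmentResult:
    """Random-restart search for designs too large to enumerate."""
    errors = pd.Series(errors)
    n = len(errors)
    if n % 2:
        raise ValueError("need an even number of objects")
    half = n // 2
    vals = errors.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best_diff = np.inf
    best_mask = None
    for _ in range(n_restarts):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:half]] = True
        diff = abs(vals[mask].mean() - vals[~mask].mean())
        if diff < best_diff:
            best_diff, best_mask = diff, mask
    ids = np.asarray(errors.index)
    return AssignmentResult(cued=tuple(ids[best_mask]),
                            uncued=tuple(ids[~best_mask]), flagged=(),
                            achieved_abs_mean_diff=float(best_diff),
                            n_partitions_searched=n_restarts)


def assign_cues(immediate_errors: pd.Series, n_flag: int = 2, seed=None,
                deterministic_labels: bool = False) -> AssignmentResult:
    """Full assignment: flag ``n_flag`` associations, then optimally split
    the remainder into cued and uncued halves.

    Because the two halves have matched means, which half is *cued* is
    arbitrary; by default a seeded coin flip decides, avoiding any
    systematic bias from the tie-break order.  ``deterministic_labels=True``
    keeps the lexicographic side as cued.
    """
    errors = pd.Series(immediate_errors)
    rng = np.random.default_rng(seed)
    flagged = select_flagged(errors, n_flag=n_flag, rng=rng)
    remaining = errors.drop(list(flagged))
    res = balanced_partition(remaining)
    cued, uncued = res.cued, res.uncued
    if not deterministic_labels and rng.random() < 0.5:
        cued, uncued = uncued, cued
    return AssignmentResult(cued=cued, uncued=uncued, flagged=flagged,
                            achieved_abs_mean_diff=res.achieved_abs_mean_diff,
                            n_partitions_searched=res.n_partitions_searched)
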