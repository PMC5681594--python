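"""Spatial-error and placement-stability measures.

All placement memory analyses reduce to Euclidean distances between pairs
of screen positions: delayed placement vs. the *studied* (trained) location,
delayed placement vs. the *remembered* location (placement on the immediate
test), and placement drift across repeated delayed tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GridSpec, DEFAULT_GRID

__all__ = [
    "euclidean_error",
    "stability_error",
    "across_round_stability",
    "error_table",
    "fraction_closer_to_remembered",
    "flag_high_error_trials",
    "px_to_cm",
    "cm_to_px",
]


def euclidean_error(a, b):
    """Euclidean distance in pixels between points ``a`` and ``b``.

    Accepts single ``(x, y)`` pairs or ``(n, 2)`` arrays (vectorized).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("points must be finite")
    d = a - b
    return np.hypot(d[..., 0], d[..., 1])


def _xy(df: pd.DataFrame, prefix: str) -> np.ndarray:
    return df[[f"{prefix}_x", f"{prefix}_y"]].to_numpy(dtype=float)


def stability_error(trials: pd.DataFrame, round: int) -> pd.Series:
    """Distance between delayed placement (round 1 or 2) and the immediate
    placement — the memory-stability measure (smaller = more stable)."""
    if round not in (1, 2):
        raise ValueError("round must be 1 or 2")
    d = euclidean_error(_xy(trials, f"delayed{round}"), _xy(trials, "immediate"))
    return pd.Series(d, index=trials.index, name=f"stability_r{round}")


def across_round_stability(trials: pd.DataFrame) -> pd.Series:
    """Distance between the two delayed-test placements of each object."""
    d = euclidean_error(_xy(trials, "delayed1"), _xy(trials, "delayed2"))
    return pd.Series(d, index=trials.index, name="across_round")


def error_table(trials: pd.DataFrame, grid: GridSpec = DEFAULT_GRID) -> pd.DataFrame:
    """Long-format table of delayed placement errors.

    One row per (participant, object, round, anchor_mode) with the error in
    pixels and centimetres; anchor_mode is ``studied`` (trained location) or
    ``remembered`` (immediate-test placement).
    """
    rows = []
    for rnd in (1, 2):
        placed = _xy(trials, f"delayed{rnd}")
        for mode, prefix in (("studied", "studied"), ("remembered", "immediate")):
            err = euclidean_error(placed, _xy(trials, prefix))
            rows.append(pd.DataFrame({
                "participant_id": trials["participant_id"].to_numpy(),
                "object_id": trials["object_id"].to_numpy(),
                "round": rnd,
                "anchor_mode": mode,
                "error_px": err,
            }))
    out = pd.concat(rows, ignore_index=True)
    out["error_cm"] = px_to_cm(out["error_px"].to_numpy(), grid)
    return out


def fraction_closer_to_remembered(trials: pd.DataFrame,
                                  rounds=(1, 2)) -> float:
    """Proportion of delayed trials placed strictly closer to the remembered
    location than to the studied location.

    Ties (a measure-zero event under continuous placement) count as
    not-closer.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    closer = []
    for rnd in np.atleast_1d(rounds):
        placed = _xy(trials, f"delayed{int(rnd)}")
        e_rem = euclidean_error(placed, _xy(trials, "immediate"))
        e_stu = euclidean_error(placed, _xy(trials, "studied"))
        closer.append(e_rem < e_stu)
    return float(np.mean(np.concatenate(closer)))


def flag_high_error_trials(errors, k_sd: float = 2.0) -> np.ndarray:
    """Indices of errors more than ``k_sd`` sample SDs *above* the mean.

    One-sided with strict inequality; SD uses the unbiased (n-1)
    denominator.  Invariant under uniform rescaling of the errors.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 3:
        raise ValueError("need at least 3 errors to flag outliers")
    mu = errors.mean()
    sd = errors.std(ddof=1)
    return np.flatnonzero(errors > mu + k_sd * sd)


def px_to_cm(px, grid: GridSpec = DEFAULT_GRID):
    return np.asarray(px, dtype=float) / grid.px_per_cm


def cm_to_px(cm, grid: GridSpec = DEFAULT_GRID):
    return np.asarray(cm, dtype=float) * grid.px_per_cm
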