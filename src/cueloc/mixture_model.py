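"""Two-parameter mixture model of continuous-report spatial memory.

Each delayed placement is modeled as coming from one of two processes:

* associative memory success, with probability ``p_success`` — the placement
  is an isotropic 2D Gaussian around its anchor (the studied or remembered
  location) with standard deviation ``sigma_px``;
* guessing, with probability ``1 - p_success`` — the placement is uniform
  over the screen, with density 1 / (width * height) per square pixel.

The two free parameters are estimated by constrained maximum likelihood
(``p`` in [0, 1], ``sigma`` in [1, 800] px) with a multi-start local search,
and individual trials are labeled as memory successes by comparing the
fitted Gaussian density at the placement against the uniform guessing
density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datatypes import GridSpec, DEFAULT_GRID

__all__ = [
    "SIGMA_BOUNDS",
    "MixtureParams",
    "MixtureFit",
    "guessing_density",
    "mixture_nll",
    "fit_mixture",
    "classify_trials",
    "group_fit",
    "participant_success_rates",
    "compare_anchor_precision",
]

#: box constraint on the Gaussian SD, pixels
SIGMA_BOUNDS = (1.0, 800.0)

#: per-trial likelihood floor, guards the log against underflow at p -> 1
_LIK_FLOOR = 1e-300

#: default multi-start grid (p, sigma_px): corners and the center of the
#: plausible region, so both near-ceiling and heavy-guessing optima are found
_DEFAULT_STARTS = ((0.9, 80.0), (0.5, 30.0), (0.99, 200.0),
                   (0.9, 30.0), (0.5, 200.0))


@dataclass(frozen=True)
class MixtureParams:
    p_success: float
    sigma_px: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_success <= 1.0:
            raise ValueError("p_success must be in [0, 1]")
        if not SIGMA_BOUNDS[0] <= self.sigma_px <= SIGMA_BOUNDS[1]:
            raise ValueError(f"sigma_px must be in {SIGMA_BOUNDS}")


@dataclass(frozen=True)
class MixtureFit:
    params: MixtureParams
    nll: float
    anchor_mode: str
    n_trials: int
    converged: bool
    n_starts: int


def guessing_density(grid: GridSpec = DEFAULT_GRID) -> float:
    """Uniform guessing density: 1 / screen area, per square pixel."""
    return 1.0 / grid.area_px2


def _sq_dists(anchors, placements) -> np.ndarray:
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    placements = np.atleast_2d(np.asarray(placements, dtype=float))
    d = placements - anchors
    return d[:, 0] ** 2 + d[:, 1] ** 2


def _nll_from_sq(p: float, sigma: float, sq: np.ndarray, g: float) -> float:
    dens = np.exp(-sq / (2.0 * sigma * sigma)) / (2.0 * np.pi * sigma * sigma)
    lik = p * dens + (1.0 - p) * g
    return float(-np.sum(np.log(np.maximum(lik, _LIK_FLOOR))))


def mixture_nll(params: MixtureParams, anchors, placements,
                grid: GridSpec = DEFAULT_GRID) -> float:
    """Negative log-likelihood of the mixture at ``params``.

    ``anchors`` and ``placements`` are (n, 2) pixel coordinates; each trial
    keeps its own anchor.
    """
    sq = _sq_dists(anchors, placements)
    if sq.size == 0:
        raise ValueError("need at least one trial")
    return _nll_from_sq(params.p_success, params.sigma_px, sq,
                        guessing_density(grid))


def fit_mixture(anchors, placements, grid: GridSpec = DEFAULT_GRID,
                anchor_mode: str = "remembered", n_starts: int = 5,
                seed=None) -> MixtureFit:
    """Constrained maximum-likelihood fit of (p_success, sigma_px).

    Runs a box-constrained local optimizer (L-BFGS-B) from ``n_starts``
    starting points — the five fixed points of ``_DEFAULT_STARTS`` plus, if
    more are requested, seeded uniform draws over the box — and keeps the
    best converged solution.
    """
    sq = _sq_dists(anchors, placements)
    if sq.size < 2:
        raise ValueError("need at least 2 trials to fit the mixture")
    g = guessing_density(grid)

    starts = list(_DEFAULT_STARTS[:max(1, n_starts)])
    if n_starts > len(_DEFAULT_STARTS):
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - len(_DEFAULT_STARTS)):
            starts.append((rng.uniform(0.05, 0.99),
                           rng.uniform(*SIGMA_BOUNDS)))

    best = None
    any_converged = False
    for p0, s0 in starts:
        res = minimize(lambda th: _nll_from_sq(th[0], th[1], sq, g),
                       x0=np.array([p0, s0]), method="L-BFGS-B",
                       bounds=[(0.0, 1.0), SIGMA_BOUNDS])
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = MixtureParams(p_success=float(np.clip(best.x[0], 0.0, 1.0)),
                           sigma_px=float(np.clip(best.x[1], *SIGMA_BOUNDS)))
    return MixtureFit(params=params, nll=float(best.fun),
                      anchor_mode=anchor_mode, n_trials=int(sq.size),
                      converged=any_converged, n_starts=len(starts))


def classify_trials(fit: MixtureFit, anchors, placements,
                    grid: GridSpec = DEFAULT_GRID,
                    weighted: bool = False) -> pd.DataFrame:
    """Label each trial as a memory success or a guess.

    The default rule compares the raw component densities: success iff the
    fitted Gaussian density at the placement exceeds the uniform guessing
    density (equivalently, the radial error is below the fixed cutoff
    ``r* = sigma * sqrt(-2 ln(2 pi sigma^2 g))`` when that argument is
    positive).  ``weighted=True`` instead compares the mixing-weighted
    posteriors ``p*phi`` vs ``(1-p)*g``.
    """
    if not fit.converged:
        raise ValueError("cannot classify trials from a non-converged fit")
    sq = _sq_dists(anchors, placements)
    sigma = fit.params.sigma_px
    g = guessing_density(grid)
    dens = np.exp(-sq / (2 * sigma * sigma)) / (2 * np.pi * sigma * sigma)
    if weighted:
        p = fit.params.p_success
        success = p * dens > (1.0 - p) * g
    else:
        success = dens > g
    return pd.DataFrame({"gaussian_density": dens,
                         "guessing_density": g,
                         "success": success})


_ANCHOR_PREFIX = {"studied": "studied", "remembered": "immediate"}


def _anchor_placement(trials: pd.DataFrame, anchor_mode: str, rounds=(1, 2)):
    """Stack (anchor, placement) pairs over delayed rounds; returns arrays
    plus the matching (participant_id, object_id, round) key frame."""
    prefix = _ANCHOR_PREFIX[anchor_mode]
    anchors, placements, keys = [], [], []
    for rnd in rounds:
        anchors.append(trials[[f"{prefix}_x", f"{prefix}_y"]].to_numpy(float))
        placements.append(
            trials[[f"delayed{rnd}_x", f"delayed{rnd}_y"]].to_numpy(float))
        keys.append(pd.DataFrame({
            "participant_id": trials["participant_id"].to_numpy(),
            "object_id": trials["object_id"].to_numpy(),
            "cue_status": trials["cue_status"].to_numpy(),
            "round": rnd}))
    return (np.vstack(anchors), np.vstack(placements),
            pd.concat(keys, ignore_index=True))


def group_fit(trials: pd.DataFrame, anchor_mode: str = "remembered",
              condition: str | None = None, grid: GridSpec = DEFAULT_GRID,
              rounds=(1, 2), **kwargs) -> MixtureFit:
    """Group-level fit pooling trials across participants.

    With eight trials per condition per participant, per-participant
    per-condition fits are too unstable, so a single model is fitted over
    the pooled cued + uncued trials (each trial keeping its own anchor);
    pass ``condition`` to restrict to one condition instead.
    """
    sub = trials[trials["cue_status"] != "flagged"]
    if condition is not None:
        sub = sub[sub["cue_status"] == condition]
    anchors, placements, _ = _anchor_placement(sub, anchor_mode, rounds)
    return fit_mixture(anchors, placements, grid=grid,
                       anchor_mode=anchor_mode, **kwargs)


def participant_success_rates(trials: pd.DataFrame, fit: MixtureFit,
                              grid: GridSpec = DEFAULT_GRID,
                              rounds=(1, 2)) -> pd.DataFrame:
    """Per-participant, per-condition, per-round mean memory-success rate
    under the group-level classification rule."""
    sub = trials[trials["cue_status"] != "flagged"]
    anchors, placements, keys = _anchor_placement(sub, fit.anchor_mode, rounds)
    labels = classify_trials(fit, anchors, placements, grid=grid)
    keys = keys.assign(success=labels["success"].to_numpy().astype(float))
    return (keys.groupby(["participant_id", "cue_status", "round"],
                         as_index=False)["success"].mean())


def compare_anchor_precision(trials: pd.DataFrame,
                             grid: GridSpec = DEFAULT_GRID) -> pd.DataFrame:
    """Per-participant fitted sigma for studied vs. remembered anchors.

    Each participant's model uses all trials from both delayed rounds.
    Returns one row per participant with ``sigma_studied`` and
    ``sigma_remembered`` (px); pair them with a t-test to ask which anchor
    yields the more precise memory component.
    """
    rows = []
    for pid, grp in trials.groupby("participant_id"):
        sigmas = {}
        for mode in ("studied", "remembered"):
            anchors, placements, _ = _anchor_placement(grp, mode)
            fit = fit_mixture(anchors, placements, grid=grid, anchor_mode=mode)
            sigmas[f"sigma_{mode}"] = fit.params.sigma_px
            sigmas[f"p_{mode}"] = fit.params.p_success
        rows.append({"participant_id": pid, **sigmas})
    return pd.DataFrame(rows)
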