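"""Generative simulator of the object-location cueing experiment.

Emulates a full two-day awake targeted-memory-reactivation session per
participant: 18 object-location associations learned to criterion on a
1280x1024-pixel grid, an immediate placement test, a 96-trial lexical
decision cover task with long arrow-filled inter-trial intervals during
which 8 of the objects are each briefly re-exposed 3 times, two rounds of
delayed placement testing ~24 h later, and a 4-option cue-discrimination
rating for every object.

The generative model is deliberately conjugate to the analysis models:

* Participant ability ``lam_i ~ Normal(0, 1)`` scales placement noise
  (log-linearly) and the expected number of training rounds, so "worse
  learners" are slower to criterion *and* less precise.
* Placements are guessing + Gaussian mixtures: with the guessing
  probability the placement is uniform on the grid, otherwise it is an
  isotropic 2D Gaussian around its anchor.  Off-grid Gaussian draws are
  redrawn by default (no truncation bias); a flag disables redrawing.
* Delayed round-1 placements are anchored on the *immediate* placement
  (not the studied location), reproducing the empirical result that
  delayed recall tracks the remembered rather than the veridical location.
* Cued items get their delayed noise SD reduced by a benefit term
  ``base + ability_coupling*lam_i + vigilance_coupling*vbar_j`` (floored),
  where ``vbar_j`` is the mean of the latent ITI-level vigilance draws of
  that object's three re-exposure intervals — the same latent that shifts
  the arrow RTs, giving a controllable ground-truth RT-benefit coupling.
* Discrimination ratings follow an equal-variance signal-detection model
  with per-participant d' and three criteria.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (GridSpec, DEFAULT_GRID, ITI_DURATIONS_S,
                        TRIALS_COLUMNS, LDT_COLUMNS, RATINGS_COLUMNS)
from .cue_assignment import assign_cues
from .memory_metrics import euclidean_error

__all__ = ["SimulationConfig", "ExperimentData", "generate_experiment",
           "generate_mixture_sample"]


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters; defaults encode the study's design.

    Design constants (participants, objects, grid, session structure) match
    the experiment; behavioral parameters are set so the simulated effect
    sizes sit in the empirically reported range (see docs/methods.md).
    """

    n_participants: int = 23
    n_objects: int = 18
    n_cued: int = 8
    n_uncued: int = 8
    n_flagged: int = 2
    grid: GridSpec = field(default_factory=lambda: DEFAULT_GRID)
    # placement noise
    sigma_immediate_base: float = 55.0      # px; immediate-test Gaussian SD
    participant_ability_sd: float = 0.3     # log-SD multiplier per ability unit
    rounds_link: float = 0.4                # ability -> log expected extra rounds
    rounds_mean_base: float = 0.55          # Poisson mean of rounds beyond 2
    sigma_delay_uncued: float = 42.0        # px; delayed drift SD, uncued
    cueing_benefit_base: float = 6.0        # px; SD reduction for cued items
    benefit_ability_coupling: float = 3.0   # px per ability SD (worse -> more)
    vigilance_benefit_coupling: float = 0.2  # px per ms of ITI vigilance draw
    sigma_round2: float = 30.0              # px; round-1 -> round-2 drift SD
    sigma_delay_floor: float = 5.0          # px; lower bound on cued SD
    guess_prob_immediate: float = 0.02
    guess_prob_delayed: float = 0.05
    # cover-task reaction times
    rt_mean_ms: float = 550.0               # arrow-task baseline
    rt_participant_sd_ms: float = 80.0
    rt_iti_sd_ms: float = 60.0              # ITI-level vigilance draw SD
    rt_arrow_jitter_ms: float = 40.0        # within-ITI arrow-to-arrow noise
    lexical_rt_offset_ms: float = 150.0     # lexical baseline above arrow RT
    lexical_rt_noise_ms: float = 80.0
    post_cue_rt_inflation_ms: float = 32.0  # slowing after a re-exposure
    # cue discrimination (equal-variance SDT)
    discrimination_dprime_mean: float = 1.0
    discrimination_dprime_sd: float = 0.8
    # studied-location sampling (the study does not report these)
    placement_margin_px: float = 125.0
    min_separation_px: float = 100.0
    redraw_offgrid: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cued + self.n_uncued + self.n_flagged != self.n_objects:
            raise ValueError("n_cued + n_uncued + n_flagged must equal "
                             "n_objects")
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for name in ("sigma_immediate_base", "sigma_delay_uncued",
                     "sigma_delay_floor", "rt_participant_sd_ms",
                     "rt_iti_sd_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma_round2 < 0:
            raise ValueError("sigma_round2 must be >= 0")
        for name in ("guess_prob_immediate", "guess_prob_delayed"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_json(self) -> str:
        d = asdict(self)
        d["grid"] = asdict(self.grid)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        if "grid" in d:
            d["grid"] = GridSpec(**d["grid"])
        return cls(**d)


@dataclass
class ExperimentData:
    """One simulated (or loaded) experiment: the three trial tables plus
    the generating config when simulated."""

    trials: pd.DataFrame
    ldt: pd.DataFrame
    ratings: pd.DataFrame
    config: SimulationConfig | None = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials[TRIALS_COLUMNS].to_csv(out / "trials.csv", index=False)
        ldt = self.ldt.copy()
        ldt["arrow_rts_ms"] = ldt["arrow_rts_ms"].map(
            lambda v: ";".join(f"{x:.3f}" for x in v))
        ldt[LDT_COLUMNS].to_csv(out / "ldt.csv", index=False)
        self.ratings[RATINGS_COLUMNS].to_csv(out / "ratings.csv", index=False)
        if self.config is not None:
            (out / "config.json").write_text(self.config.to_json())

    @classmethod
    def read(cls, in_dir) -> "ExperimentData":
        d = Path(in_dir)
        trials = pd.read_csv(d / "trials.csv")
        ldt = pd.read_csv(d / "ldt.csv")
        ldt["arrow_rts_ms"] = ldt["arrow_rts_ms"].map(
            lambda s: np.array([float(x) for x in str(s).split(";")]))
        ldt["cue_object_id"] = ldt["cue_object_id"].astype("object").where(
            ldt["cue_object_id"].notna(), None)
        ratings = pd.read_csv(d / "ratings.csv")
        cfg_path = d / "config.json"
        cfg = SimulationConfig.from_json(cfg_path.read_text()) \
            if cfg_path.exists() else None
        return cls(trials=trials, ldt=ldt, ratings=ratings, config=cfg)


# ---------------------------------------------------------------------------
# placement helpers

def _uniform_points(rng, grid: GridSpec, n: int) -> np.ndarray:
    return np.column_stack([rng.uniform(0, grid.width_px, n),
                            rng.uniform(0, grid.height_px, n)])


def _gaussian_placements(rng, anchors: np.ndarray, sigmas, grid: GridSpec,
                         redraw: bool) -> np.ndarray:
    """Isotropic Gaussian draws around anchors; off-grid draws are redrawn
    (up to a cap) when ``redraw``, otherwise returned as-is."""
    sigmas = np.broadcast_to(np.asarray(sigmas, float), (len(anchors),))
    pts = anchors + rng.normal(size=anchors.shape) * sigmas[:, None]
    if redraw:
        for _ in range(100):
            bad = ~grid.contains(pts[:, 0], pts[:, 1])
            if not bad.any():
                break
            pts[bad] = (anchors[bad] + rng.normal(size=(bad.sum(), 2))
                        * sigmas[bad, None])
        else:  # pathological sigma: clip the stragglers
            pts[:, 0] = np.clip(pts[:, 0], 0, grid.width_px)
            pts[:, 1] = np.clip(pts[:, 1], 0, grid.height_px)
    return pts


def _mixture_placements(rng, anchors, sigmas, guess_prob, grid, redraw):
    n = len(anchors)
    pts = _gaussian_placements(rng, anchors, sigmas, grid, redraw)
    guess = rng.random(n) < guess_prob
    if guess.any():
        pts[guess] = _uniform_points(rng, grid, int(guess.sum()))
    return pts


def _studied_locations(rng, grid: GridSpec, n: int, margin: float,
                       min_sep: float) -> np.ndarray:
    """Uniform within margins, rejection-sampled to a minimum pairwise
    separation (relaxed if the constraint proves infeasible)."""
    lo = np.array([margin, margin])
    hi = np.array([grid.width_px - margin, grid.height_px - margin])
    for attempt in range(50):
        pts = []
        tries = 0
        sep = min_sep * (0.9 ** attempt)
        while len(pts) < n and tries < 2000:
            cand = rng.uniform(lo, hi)
            if all(np.hypot(*(cand - p)) >= sep for p in pts):
                pts.append(cand)
            tries += 1
        if len(pts) == n:
            return np.array(pts)
    raise RuntimeError("could not place studied locations")


# ---------------------------------------------------------------------------
# cover-task session

def _build_ldt(rng, cued_ids) -> pd.DataFrame:
    """One structurally valid 96-trial session.

    Per third of the session (32 trials): 8 trials of each ITI duration,
    half word half pseudo-word, and 8 cue events — one per cued object, two
    per ITI duration (one on a word trial, one on a pseudo-word trial).
    Totals: 24 cue events, 6 per duration, 12 word / 12 pseudo-word.
    """
    cued_ids = list(cued_ids)
    assert len(cued_ids) == 8
    rows = []
    idx = 0
    for third in range(3):
        trials = []
        for dur in ITI_DURATIONS_S:
            is_word = [True] * 4 + [False] * 4
            cue_word = rng.integers(4)          # which word trial carries a cue
            cue_pseudo = 4 + rng.integers(4)    # which pseudo trial does
            for k in range(8):
                trials.append({"iti_duration_s": dur, "is_word": is_word[k],
                               "has_cue": k in (cue_word, cue_pseudo)})
        objs = list(rng.permutation(np.array(cued_ids, dtype=object)))
        order = rng.permutation(len(trials))
        for j in order:
            t = dict(trials[j])
            t["cue_object_id"] = objs.pop() if t.pop("has_cue") else None
            t["trial_index"] = idx
            rows.append(t)
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

def generate_experiment(config: SimulationConfig) -> ExperimentData:
    """Simulate a complete experiment; bit-reproducible from the config.

    Per-participant random substreams are spawned deterministically from
    the master seed, so adding participants does not perturb earlier ones.
    """
    root_ss = np.random.SeedSequence(config.seed)
    streams = root_ss.spawn(config.n_participants)
    grid = config.grid
    trial_rows, ldt_frames, rating_rows = [], [], []

    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"p{i:03d}"
        lam = rng.normal()
        sigma_imm = config.sigma_immediate_base * np.exp(
            config.participant_ability_sd * lam)
        arrow_base = rng.normal(config.rt_mean_ms, config.rt_participant_sd_ms)
        dprime = rng.normal(config.discrimination_dprime_mean,
                            config.discrimination_dprime_sd)

        object_ids = [f"o{k:02d}" for k in range(config.n_objects)]
        studied = _studied_locations(rng, grid, config.n_objects,
                                     config.placement_margin_px,
                                     config.min_separation_px)
        immediate = _mixture_placements(rng, studied, sigma_imm,
                                        config.guess_prob_immediate, grid,
                                        config.redraw_offgrid)
        rounds = 2 + rng.poisson(
            config.rounds_mean_base * np.exp(config.rounds_link * lam),
            size=config.n_objects)

        # cue assignment from immediate-test errors, as in the live session
        imm_err = pd.Series(euclidean_error(immediate, studied),
                            index=object_ids)
        assign = assign_cues(imm_err, n_flag=config.n_flagged,
                             seed=rng.integers(2 ** 31))
        status = {o: "flagged" for o in assign.flagged}
        status.update({o: "cued" for o in assign.cued})
        status.update({o: "uncued" for o in assign.uncued})

        # cover task: latent vigilance per ITI drives both RTs and benefits
        sess = _build_ldt(rng, assign.cued)
        n_tr = len(sess)
        vig = rng.normal(0.0, config.rt_iti_sd_ms, n_tr)
        arrow_rts = []
        for j in range(n_tr):
            n_arrows = sess.loc[j, "iti_duration_s"] // 2
            rts = (arrow_base + vig[j]
                   + rng.normal(0, config.rt_arrow_jitter_ms, n_arrows))
            arrow_rts.append(np.maximum(rts, 150.0))
        sess["arrow_rts_ms"] = arrow_rts
        is_cue = sess["cue_object_id"].notna()
        lex = (arrow_base + config.lexical_rt_offset_ms
               + rng.normal(0, config.lexical_rt_noise_ms, n_tr)
               + np.where(is_cue, config.post_cue_rt_inflation_ms, 0.0))
        sess["lexical_rt_ms"] = np.maximum(lex, 200.0)
        sess.insert(0, "participant_id", pid)
        vbar = {obj: vig[sess.index[sess["cue_object_id"] == obj]].mean()
                for obj in assign.cued}

        # delayed placements, anchored on the immediate placement
        sd_delay = np.full(config.n_objects, config.sigma_delay_uncued)
        for k, obj in enumerate(object_ids):
            if status[obj] == "cued":
                benefit = (config.cueing_benefit_base
                           + config.benefit_ability_coupling * lam
                           + config.vigilance_benefit_coupling * vbar[obj])
                sd_delay[k] = max(config.sigma_delay_floor,
                                  config.sigma_delay_uncued - max(benefit, 0.0))
        delayed1 = _mixture_placements(rng, immediate, sd_delay,
                                       config.guess_prob_delayed, grid,
                                       config.redraw_offgrid)
        if config.sigma_round2 > 0 or config.guess_prob_delayed > 0:
            delayed2 = _mixture_placements(
                rng, delayed1, max(config.sigma_round2, 1e-12),
                config.guess_prob_delayed, grid, config.redraw_offgrid)
        else:
            delayed2 = delayed1.copy()

        # discrimination ratings: equal-variance SDT, criteria around d'/2
        mid = dprime / 2.0
        cuts = np.array([mid - 0.8, mid, mid + 0.8])
        for k, obj in enumerate(object_ids):
            signal = dprime if status[obj] == "cued" else 0.0
            ev = rng.normal(signal, 1.0)
            rating = ("HC_uncued", "LC_uncued", "LC_cued",
                      "HC_cued")[int(np.searchsorted(cuts, ev))]
            rating_rows.append({"participant_id": pid, "object_id": obj,
                                "rating": rating})
            trial_rows.append({
                "participant_id": pid, "object_id": obj,
                "studied_x": studied[k, 0], "studied_y": studied[k, 1],
                "immediate_x": immediate[k, 0], "immediate_y": immediate[k, 1],
                "delayed1_x": delayed1[k, 0], "delayed1_y": delayed1[k, 1],
                "delayed2_x": delayed2[k, 0], "delayed2_y": delayed2[k, 1],
                "n_training_rounds": int(rounds[k]),
                "cue_status": status[obj], "rating": rating,
            })
        ldt_frames.append(sess)

    trials = pd.DataFrame(trial_rows, columns=TRIALS_COLUMNS)
    ldt = pd.concat(ldt_frames, ignore_index=True)[LDT_COLUMNS]
    ratings = pd.DataFrame(rating_rows, columns=RATINGS_COLUMNS)
    return ExperimentData(trials=trials, ldt=ldt, ratings=ratings,
                          config=config)


def generate_mixture_sample(p_success: float, sigma_px: float, n: int,
                            grid: GridSpec = DEFAULT_GRID, seed=None,
                            redraw_offgrid: bool = False):
    """Draws from the guessing + Gaussian placement mixture itself.

    Used as the parameter-recovery harness for the mixture fitter: with
    probability ``p_success`` a placement is Gaussian(``sigma_px``) around
    its anchor, otherwise uniform on the grid.  Anchors are uniform over
    the central region of the grid.  Returns ``(anchors, placements)``,
    each ``(n, 2)``.  Off-grid Gaussian draws are kept by default so the
    sample exactly follows the fitted density.
    """
    if not 0.0 <= p_success <= 1.0:
        raise ValueError("p_success must be in [0, 1]")
    if not 1.0 <= sigma_px <= 800.0:
        raise ValueError("sigma_px must be within the fit constraints "
                         "[1, 800]")
    rng = np.random.default_rng(seed)
    margin = min(100.0, grid.width_px / 4, grid.height_px / 4)
    anchors = np.column_stack([
        rng.uniform(margin, grid.width_px - margin, n),
        rng.uniform(margin, grid.height_px - margin, n)])
    placements = anchors + rng.normal(size=(n, 2)) * sigma_px
    if redraw_offgrid:
        placements = _gaussian_placements(rng, anchors, sigma_px, grid, True)
    guess = rng.random(n) < (1.0 - p_success)
    if guess.any():
        placements[guess] = _uniform_points(rng, grid, int(guess.sum()))
    return anchors, placements
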