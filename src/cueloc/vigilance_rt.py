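"""Cover-task reaction times as item-level vigilance covariates, and the
per-association cueing benefit they are regressed against.

Arrow-task reaction time during the long inter-trial intervals indexes
external task engagement (vigilance) immediately before each cue
re-exposure; slower responding is read as a more internally-oriented state.
RTs are normalized within participant by subtracting a reference mean so
that item-level values are comparable across participants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import memory_metrics
from .group_inference import TTestResult, paired_t

__all__ = ["normalize_rts", "cueing_benefit", "item_level_table",
           "post_cue_rt_contrast"]

_MODES = ("noncued_itis", "all_itis")


def _arrow_means(ldt: pd.DataFrame) -> pd.Series:
    """Mean arrow RT per LDT trial's ITI (NaN if no arrow responses)."""
    def m(v):
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        return v.mean() if v.size else np.nan
    return ldt["arrow_rts_ms"].map(m)


def normalize_rts(ldt: pd.DataFrame, mode: str = "noncued_itis") -> pd.DataFrame:
    """Normalized pre-cue and post-cue RT per cued object.

    For each cued object, ``pre_cue_rt`` is the mean over its three
    re-exposure ITIs of the within-ITI mean arrow RT, minus the reference
    mean — the mean ITI RT across non-cued ITIs (``mode="noncued_itis"``,
    the primary normalization) or across all ITIs (``mode="all_itis"``).
    ``post_cue_rt`` applies the same normalization to the lexical-decision
    RT on the trials following each object's re-exposures.  The two modes
    differ only by a per-participant constant.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    out = []
    for pid, sess in ldt.groupby("participant_id"):
        iti_rt = _arrow_means(sess)
        is_cue = sess["cue_object_id"].notna()
        counts = sess.loc[is_cue, "cue_object_id"].value_counts()
        if (counts != 3).any():
            raise ValueError(
                f"participant {pid}: every cued object needs exactly 3 "
                "re-exposures")
        if mode == "noncued_itis":
            ref_arrow = iti_rt[~is_cue].mean()
            ref_lex = sess.loc[~is_cue, "lexical_rt_ms"].mean()
        else:
            ref_arrow = iti_rt.mean()
            ref_lex = sess["lexical_rt_ms"].mean()
        cued = sess[is_cue].assign(iti_rt=iti_rt[is_cue])
        agg = cued.groupby("cue_object_id").agg(
            pre_cue_rt=("iti_rt", "mean"),
            post_cue_rt=("lexical_rt_ms", "mean"))
        agg["pre_cue_rt"] -= ref_arrow
        agg["post_cue_rt"] -= ref_lex
        agg = agg.reset_index().rename(columns={"cue_object_id": "object_id"})
        agg.insert(0, "participant_id", pid)
        agg["normalization_mode"] = mode
        out.append(agg)
    return pd.concat(out, ignore_index=True)


def cueing_benefit(trials: pd.DataFrame, per_round: bool = False) -> pd.DataFrame:
    """Per-association cueing benefit, pixels.

    For each cued association, the benefit is that participant's mean
    stability error over all *uncued* associations minus the association's
    own stability error; positive values mean cueing reduced error.
    Stability error (delayed vs. remembered placement) is averaged over the
    two delayed rounds unless ``per_round``.

    Exact aggregation identity: the participant-mean of benefits equals
    (mean uncued error - mean cued error) for that participant.
    """
    err = 0.5 * (memory_metrics.stability_error(trials, 1)
                 + memory_metrics.stability_error(trials, 2))
    work = trials[["participant_id", "object_id", "cue_status"]].copy()
    if per_round:
        work["error_r1"] = memory_metrics.stability_error(trials, 1)
        work["error_r2"] = memory_metrics.stability_error(trials, 2)
    work["stability_px"] = err
    out = []
    for pid, grp in work.groupby("participant_id"):
        uncued_mean = grp.loc[grp["cue_status"] == "uncued",
                              "stability_px"].mean()
        cued = grp[grp["cue_status"] == "cued"].copy()
        cued["benefit_px"] = uncued_mean - cued["stability_px"]
        if per_round:
            for r in (1, 2):
                um = grp.loc[grp["cue_status"] == "uncued",
                             f"error_r{r}"].mean()
                cued[f"benefit_r{r}_px"] = um - cued[f"error_r{r}"]
        out.append(cued)
    return pd.concat(out, ignore_index=True)


def item_level_table(trials: pd.DataFrame, ldt: pd.DataFrame,
                     mode: str = "noncued_itis") -> pd.DataFrame:
    """Merge normalized RTs and cueing benefits into the item-level table
    used for the vigilance-benefit regression (one row per cued
    association across all participants)."""
    rts = normalize_rts(ldt, mode=mode)
    ben = cueing_benefit(trials)
    return rts.merge(
        ben[["participant_id", "object_id", "benefit_px"]],
        on=["participant_id", "object_id"], how="inner")


def post_cue_rt_contrast(ldt: pd.DataFrame) -> tuple[pd.DataFrame, TTestResult]:
    """Did re-exposure slow the following lexical decision?

    Per participant, mean lexical RT on trials preceded by a cue event vs.
    trials without one; paired t-test across participants.
    """
    rows = []
    for pid, sess in ldt.groupby("participant_id"):
        is_cue = sess["cue_object_id"].notna()
        rows.append({
            "participant_id": pid,
            "post_cue_mean_ms": sess.loc[is_cue, "lexical_rt_ms"].mean(),
            "no_cue_mean_ms": sess.loc[~is_cue, "lexical_rt_ms"].mean(),
        })
    tab = pd.DataFrame(rows)
    test = paired_t(tab["post_cue_mean_ms"].to_numpy(),
                    tab["no_cue_mean_ms"].to_numpy())
    return tab, test
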