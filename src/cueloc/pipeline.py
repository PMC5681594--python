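"""End-to-end orchestration: run every analysis stage in order on one
dataset and collect a JSON-serializable report bundle plus a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import GridSpec, DEFAULT_GRID, validate_trials, validate_ldt
from . import memory_metrics, mixture_model, vigilance_rt, robust_stats
from . import group_inference as gi
from .synthetic_data import ExperimentData

log = logging.getLogger(__name__)

__all__ = ["run_full_analysis", "write_report"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (pd.DataFrame, pd.Series)):
        return json.loads(obj.to_json(orient="split"))
    return obj


def _validate(data: ExperimentData) -> None:
    validate_trials(data.trials)
    validate_ldt(data.ldt)
    t_pids = set(data.trials["participant_id"])
    l_pids = set(data.ldt["participant_id"])
    if t_pids != l_pids:
        missing = sorted(t_pids ^ l_pids)
        raise ValueError("participants missing from one of trials/ldt "
                         f"tables: {missing}")


def run_full_analysis(data: ExperimentData, grid: GridSpec = DEFAULT_GRID,
                      seed: int = 0, n_perm: int = 2000) -> dict:
    """Run the full analysis chain and return the report bundle.

    Stages, in order: immediate-memory summary -> cue-assignment balance
    check -> studied/remembered anchoring contrasts -> cued/uncued
    stability contrasts -> group mixture fits and memory-success rates ->
    vigilance-benefit robust regression with permutation null -> initial
    learning analyses (PCA factor, split-half) -> cue-discrimination
    analyses.  Deterministic given (data, seed).
    """
    _validate(data)
    trials, ldt = data.trials, data.ldt
    report: dict = {}

    # ---- immediate memory and assignment balance -------------------------
    imm_err = memory_metrics.euclidean_error(
        trials[["immediate_x", "immediate_y"]].to_numpy(float),
        trials[["studied_x", "studied_y"]].to_numpy(float))
    work = trials.assign(imm_err=imm_err)
    per_subj_imm = work.groupby("participant_id")["imm_err"].mean()
    cond_imm = (work[work["cue_status"] != "flagged"]
                .groupby(["participant_id", "cue_status"])["imm_err"]
                .mean().unstack())
    n_flagged_outliers = work.groupby("participant_id")["imm_err"].apply(
        lambda e: len(memory_metrics.flag_high_error_trials(e.to_numpy())))
    report["immediate"] = {
        "mean_error_px": float(per_subj_imm.mean()),
        "mean_error_cm": float(memory_metrics.px_to_cm(
            per_subj_imm.to_numpy(), grid).mean()),
        "mean_outlier_trials": float(n_flagged_outliers.mean()),
        "cued_mean_px": float(cond_imm["cued"].mean()),
        "uncued_mean_px": float(cond_imm["uncued"].mean()),
        "cued_uncued_abs_diff_px": float(
            (cond_imm["cued"] - cond_imm["uncued"]).abs().mean()),
    }

    # ---- anchoring: studied vs remembered --------------------------------
    etab = memory_metrics.error_table(trials, grid)
    cell = (etab.groupby(["participant_id", "anchor_mode", "round"],
                         as_index=False)["error_px"].mean())
    report["anchoring"] = {
        "anova": gi.rm_anova(cell, "error_px", ["anchor_mode", "round"],
                             "participant_id"),
        "fraction_closer_to_remembered":
            memory_metrics.fraction_closer_to_remembered(trials),
        "fraction_closer_r1":
            memory_metrics.fraction_closer_to_remembered(trials, rounds=(1,)),
        "fraction_closer_r2":
            memory_metrics.fraction_closer_to_remembered(trials, rounds=(2,)),
        "mean_error_remembered_px": float(
            etab[etab["anchor_mode"] == "remembered"]["error_px"].mean()),
        "mean_error_studied_px": float(
            etab[etab["anchor_mode"] == "studied"]["error_px"].mean()),
    }

    # ---- cueing effect on stability --------------------------------------
    nonflag = trials[trials["cue_status"] != "flagged"].copy()
    stab = []
    for rnd in (1, 2):
        s = nonflag[["participant_id", "cue_status"]].copy()
        s["round"] = rnd
        s["stability_px"] = memory_metrics.stability_error(nonflag, rnd)
        stab.append(s)
    stab = pd.concat(stab, ignore_index=True)
    stab_cells = stab.groupby(["participant_id", "cue_status", "round"],
                              as_index=False)["stability_px"].mean()
    subj_means = stab_cells.groupby(["participant_id", "cue_status"])[
        "stability_px"].mean().unstack()
    nonflag["across_round_px"] = memory_metrics.across_round_stability(nonflag)
    across = nonflag.groupby(["participant_id", "cue_status"])[
        "across_round_px"].mean().unstack()
    report["cueing"] = {
        "anova": gi.rm_anova(stab_cells, "stability_px",
                             ["cue_status", "round"], "participant_id"),
        "paired_t": gi.paired_t(subj_means["uncued"].to_numpy(),
                                subj_means["cued"].to_numpy()),
        "cued_mean_px": float(subj_means["cued"].mean()),
        "uncued_mean_px": float(subj_means["uncued"].mean()),
        "mean_benefit_px": float((subj_means["uncued"]
                                  - subj_means["cued"]).mean()),
        "across_round_t": gi.paired_t(across["uncued"].to_numpy(),
                                      across["cued"].to_numpy()),
    }
    # secondary: error relative to studied locations
    stud = etab[(etab["anchor_mode"] == "studied")].merge(
        trials[["participant_id", "object_id", "cue_status"]],
        on=["participant_id", "object_id"])
    stud = stud[stud["cue_status"] != "flagged"]
    stud_cells = stud.groupby(["participant_id", "cue_status", "round"],
                              as_index=False)["error_px"].mean()
    report["cueing_studied_anchor"] = {
        "anova": gi.rm_anova(stud_cells, "error_px", ["cue_status", "round"],
                             "participant_id")}

    # ---- mixture models ---------------------------------------------------
    mix: dict = {}
    for mode in ("remembered", "studied"):
        fit = mixture_model.group_fit(trials, anchor_mode=mode, grid=grid)
        rates = mixture_model.participant_success_rates(trials, fit, grid=grid)
        cond_rates = rates.groupby(["participant_id", "cue_status"])[
            "success"].mean().unstack()
        mix[mode] = {
            "fit": fit,
            "anova": gi.rm_anova(rates, "success", ["cue_status", "round"],
                                 "participant_id"),
            "success_cued": float(cond_rates["cued"].mean()),
            "success_uncued": float(cond_rates["uncued"].mean()),
        }
    precision = mixture_model.compare_anchor_precision(trials, grid=grid)
    mix["anchor_precision"] = {
        "per_participant": precision,
        "paired_t": gi.paired_t(precision["sigma_studied"].to_numpy(),
                                precision["sigma_remembered"].to_numpy()),
        "sigma_studied_cm": float(memory_metrics.px_to_cm(
            precision["sigma_studied"].to_numpy(), grid).mean()),
        "sigma_remembered_cm": float(memory_metrics.px_to_cm(
            precision["sigma_remembered"].to_numpy(), grid).mean()),
    }
    report["mixture"] = mix

    # ---- vigilance x benefit ---------------------------------------------
    items = vigilance_rt.item_level_table(trials, ldt)
    x = items["pre_cue_rt"].to_numpy()
    y = items["benefit_px"].to_numpy()
    post_tab, post_test = vigilance_rt.post_cue_rt_contrast(ldt)
    report["vigilance"] = {
        "n_items": int(len(items)),
        "robust": robust_stats.irls_regression(x, y),
        "robust_permutation": robust_stats.permutation_test_slope(
            x, y, n_perm=n_perm, seed=seed),
        "ols_excluded": robust_stats.ols_with_exclusion(x, y, k_sd=3.0),
        "post_cue_rt_contrast": post_test,
        "post_cue_rt_diff_ms": float((post_tab["post_cue_mean_ms"]
                                      - post_tab["no_cue_mean_ms"]).mean()),
        "post_cue_robust": robust_stats.irls_regression(
            items["post_cue_rt"].to_numpy(), y),
    }

    # ---- initial learning -------------------------------------------------
    subj_rounds = trials.groupby("participant_id")["n_training_rounds"].mean()
    factor = gi.learning_factor(per_subj_imm, subj_rounds)
    benefit_by_subj = (subj_means["uncued"] - subj_means["cued"]).reindex(
        factor.scores.index)
    learn: dict = {
        "measure_correlation": robust_stats.irls_regression(
            per_subj_imm.to_numpy(), subj_rounds.to_numpy()),
        "factor_loadings": factor.loadings,
        "factor_variance_explained": factor.variance_explained,
        "factor_vs_benefit": robust_stats.irls_regression(
            factor.scores.to_numpy(), benefit_by_subj.to_numpy()),
        "immediate_vs_benefit": robust_stats.irls_regression(
            per_subj_imm.to_numpy(), benefit_by_subj.to_numpy()),
        "rounds_vs_benefit": robust_stats.irls_regression(
            subj_rounds.to_numpy(), benefit_by_subj.to_numpy()),
    }
    strat = gi.split_half_by_initial_memory(trials)
    strat = strat[strat["cue_status"] != "flagged"].copy()
    srows = []
    for rnd in (1, 2):
        s = strat[["participant_id", "cue_status", "initial_stratum"]].copy()
        s["round"] = rnd
        s["stability_px"] = memory_metrics.stability_error(strat, rnd)
        srows.append(s)
    sh = pd.concat(srows, ignore_index=True)
    sh_cells = sh.groupby(
        ["participant_id", "initial_stratum", "cue_status", "round"],
        as_index=False)["stability_px"].mean()
    learn["split_half_anova"] = gi.rm_anova(
        sh_cells, "stability_px", ["initial_stratum", "cue_status", "round"],
        "participant_id")
    for stratum in ("low", "high"):
        cells = (sh_cells[sh_cells["initial_stratum"] == stratum]
                 .groupby(["participant_id", "cue_status"])["stability_px"]
                 .mean().unstack())
        learn[f"{stratum}_error_t"] = gi.paired_t(
            cells["uncued"].to_numpy(), cells["cued"].to_numpy())
    report["learning"] = learn

    # ---- cue discrimination ----------------------------------------------
    ratings = data.ratings.merge(
        trials[["participant_id", "object_id", "cue_status"]],
        on=["participant_id", "object_id"])
    props = gi.rating_distribution(ratings)
    long_props = props.melt(id_vars=["participant_id", "cue_status"],
                            var_name="option", value_name="proportion")
    disc = gi.discrimination_chi2(ratings)
    labels = pd.Series({d.participant_id: d.label for d in disc})
    benefit_all = benefit_by_subj.reindex(labels.index)
    is_disc = labels == "discriminator"
    disc_block: dict = {
        "rating_anova": gi.rm_anova(long_props, "proportion",
                                    ["cue_status", "option"],
                                    "participant_id"),
        "per_participant": disc,
        "n_discriminators": int(is_disc.sum()),
        "n_non_discriminators": int((~is_disc).sum()),
    }
    if 2 <= is_disc.sum() <= len(labels) - 2:
        disc_block["benefit_disc_vs_non_t"] = gi.unpaired_t(
            benefit_all[~is_disc].to_numpy(), benefit_all[is_disc].to_numpy())
        disc_block["benefit_non_discriminators_t"] = gi.paired_t(
            subj_means.loc[labels.index[~is_disc], "uncued"].to_numpy(),
            subj_means.loc[labels.index[~is_disc], "cued"].to_numpy())
    for subset in ("rated_uncued_only", "rated_cued_only"):
        disc_block[subset] = gi.labeled_subset_contrast(trials, subset)
    report["discrimination"] = disc_block

    return report


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode()).hexdigest()[:16]


def write_report(report: dict, data: ExperimentData, out_dir,
                 seed: int = 0) -> Path:
    """Serialize the report bundle (JSON), a markdown summary, and the run
    manifest into ``out_dir``; returns the JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = _jsonable(report)
    json_path = out / "report.json"
    json_path.write_text(json.dumps(blob, indent=2, allow_nan=True))
    manifest = {
        "software": {"cueloc": __version__},
        "seed": seed,
        "config": json.loads(data.config.to_json())
        if data.config is not None else None,
        "input_hashes": {"trials": _hash_df(data.trials),
                         "ratings": _hash_df(data.ratings)},
        "stages": sorted(report.keys()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.md").write_text(_markdown_report(report))
    return json_path


def _fmt_anova(anova: dict) -> str:
    lines = []
    for name, a in anova.items():
        lines.append(f"  - {name}: F({a.df_num},{a.df_den}) = {a.F:.2f}, "
                     f"p = {a.p:.3g}, partial eta^2 = {a.partial_eta_sq:.2f}")
    return "\n".join(lines)


def _fmt_t(t) -> str:
    return (f"t({t.df}) = {t.t:.2f}, p = {t.p:.3g}, "
            f"Cohen's d = {t.cohens_d:.2f}")


def _markdown_report(report: dict) -> str:
    r = report
    parts = ["# Object-location cueing analysis report", ""]
    imm = r["immediate"]
    parts += ["## Immediate memory",
              f"- mean error {imm['mean_error_px']:.1f} px "
              f"({imm['mean_error_cm']:.2f} cm); "
              f"cued {imm['cued_mean_px']:.1f} px vs uncued "
              f"{imm['uncued_mean_px']:.1f} px after assignment", ""]
    an = r["anchoring"]
    parts += ["## Studied vs remembered anchoring",
              _fmt_anova(an["anova"]),
              f"- fraction of delayed trials closer to remembered: "
              f"{100 * an['fraction_closer_to_remembered']:.1f}%", ""]
    cue = r["cueing"]
    parts += ["## Cueing effect on memory stability",
              _fmt_anova(cue["anova"]),
              f"- cueing benefit (uncued minus cued stability error): "
              f"{_fmt_t(cue['paired_t'])}; "
              f"mean benefit {cue['mean_benefit_px']:.1f} px", ""]
    vig = r["vigilance"]
    rb = vig["robust"]
    parts += ["## Vigilance and cueing benefit",
              f"- robust slope beta = {rb.beta:.2f} +/- {rb.se_beta:.2f}, "
              f"r = {rb.r:.2f}, t({rb.df}) = {rb.t_stat:.2f}, "
              f"p = {rb.p_value:.3g}; permutation p = "
              f"{vig['robust_permutation'].p_value:.4g}", ""]
    lr = r["learning"]
    fb = lr["factor_vs_benefit"]
    parts += ["## Initial learning and cueing benefit",
              f"- learning factor vs benefit: beta = {fb.beta:.2f}, "
              f"r = {fb.r:.2f}, p = {fb.p_value:.3g}",
              _fmt_anova(lr["split_half_anova"]), ""]
    dc = r["discrimination"]
    parts += ["## Cue discrimination",
              f"- {dc['n_discriminators']} discriminators / "
              f"{dc['n_non_discriminators']} non-discriminators",
              _fmt_anova(dc["rating_anova"]), ""]
    return "\n".join(parts)
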