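"""Group-level inference: repeated-measures ANOVA, t-tests with effect
sizes, the PCA learning factor, the within-participant split-half strata,
and the cue-discrimination chi-squared classifier."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "AnovaResult", "TTestResult", "LearningFactor", "DiscriminationResult",
    "rm_anova", "paired_t", "unpaired_t", "learning_factor",
    "split_half_by_initial_memory", "discrimination_chi2", "chi2_2x2",
    "rating_distribution", "labeled_subset_contrast",
]


@dataclass(frozen=True)
class AnovaResult:
    """One within-subject effect: F(df_num, df_den), p, partial eta^2."""
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    degenerate: bool = False


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    paired: bool
    n: int


@dataclass(frozen=True)
class LearningFactor:
    """First principal component of (mean immediate error, mean training
    rounds), z-scored; oriented so higher scores mean worse learning."""
    scores: pd.Series
    loadings: np.ndarray
    variance_explained: float


@dataclass(frozen=True)
class DiscriminationResult:
    participant_id: object
    chi_sq: float
    p: float
    label: str
    hc_hit_rate: float
    hc_fa_rate: float


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str
             ) -> dict[str, AnovaResult]:
    """Fully within-subject repeated-measures ANOVA.

    ``data`` is long format with one (aggregated) observation per subject
    per cell; all subjects must contribute every cell of the crossed
    ``within`` factors.  Each effect is tested against its interaction with
    subjects (the standard univariate decomposition), and partial eta^2 is
    ``F*df_num / (F*df_num + df_den)``.  Cells with zero error variance
    yield a flagged degenerate result rather than an exception.
    """
    from statsmodels.stats.anova import AnovaRM

    within = list(within)
    counts = data.groupby([subject, *within], observed=True)[dv].count()
    if (counts != 1).any():
        # aggregate replicates to cell means; missing cells raise below
        data = (data.groupby([subject, *within], observed=True,
                             as_index=False)[dv].mean())
    n_cells = int(np.prod([data[w].nunique() for w in within]))
    per_subj = data.groupby(subject, observed=True)[dv].count()
    if (per_subj != n_cells).any():
        raise ValueError("incomplete design: every subject must contribute "
                         "every cell")
    zero_var = bool(np.ptp(data[dv].to_numpy()) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tab = AnovaRM(data, depvar=dv, subject=subject,
                      within=within).fit().anova_table
    out: dict[str, AnovaResult] = {}
    for effect, row in tab.iterrows():
        F = float(row["F Value"])
        dfn, dfd = int(row["Num DF"]), int(row["Den DF"])
        degenerate = zero_var or not np.isfinite(F)
        if degenerate:
            F, p, eta = 0.0, float("nan"), float("nan")
        else:
            p = float(row["Pr > F"])
            eta = F * dfn / (F * dfn + dfd)
        out[effect] = AnovaResult(effect=effect, F=F, df_num=dfn, df_den=dfd,
                                  p=p, partial_eta_sq=eta,
                                  degenerate=degenerate)
    return out


def _cohens_d_paired(diff: np.ndarray) -> float:
    sd = diff.std(ddof=1)
    return float(diff.mean() / sd) if sd > 0 else 0.0


def paired_t(a, b) -> TTestResult:
    """Paired t-test; Cohen's d = mean difference / SD of differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diff = a - b
    if np.allclose(diff, 0):
        return TTestResult(t=0.0, df=len(diff) - 1, p=1.0, cohens_d=0.0,
                           paired=True, n=len(diff))
    t, p = stats.ttest_rel(a, b)
    return TTestResult(t=float(t), df=len(a) - 1, p=float(p),
                       cohens_d=_cohens_d_paired(diff), paired=True, n=len(a))


def unpaired_t(a, b) -> TTestResult:
    """Independent-samples t-test; Cohen's d uses the pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = stats.ttest_ind(a, b)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
    return TTestResult(t=float(t), df=na + nb - 2, p=float(p), cohens_d=d,
                       paired=False, n=na + nb)


def learning_factor(mean_immediate_error: pd.Series,
                    mean_rounds: pd.Series) -> LearningFactor:
    """Single factor summarizing initial learning across two measures.

    Both inputs are z-scored (n-1 SD) and the first principal component of
    their 2x2 correlation matrix extracted; the sign is aligned so that the
    score correlates positively with immediate error (higher score = worse
    memory and slower learning).
    """
    x = pd.Series(mean_immediate_error).astype(float)
    y = pd.Series(mean_rounds).astype(float)
    if not x.index.equals(y.index):
        y = y.reindex(x.index)
    Z = np.column_stack([
        (x - x.mean()) / x.std(ddof=1),
        (y - y.mean()) / y.std(ddof=1),
    ])
    C = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    v = evecs[:, -1]
    if v[0] < 0:
        v = -v
    scores = pd.Series(Z @ v, index=x.index, name="learning_score")
    return LearningFactor(scores=scores, loadings=v,
                          variance_explained=float(evals[-1] / evals.sum()))


def split_half_by_initial_memory(trials: pd.DataFrame) -> pd.DataFrame:
    """Median split of each participant's cued and uncued associations by
    immediate-test error.

    Within each (participant, condition) set of associations, the half with
    the lowest immediate errors is labeled ``low`` and the rest ``high``;
    ties are resolved by stable object-id order.  Returns a copy of
    ``trials`` with an ``initial_stratum`` column (flagged trials get NaN).
    """
    from .memory_metrics import euclidean_error
    out = trials.copy()
    err = euclidean_error(
        out[["immediate_x", "immediate_y"]].to_numpy(float),
        out[["studied_x", "studied_y"]].to_numpy(float))
    out["_imm_err"] = err
    out["initial_stratum"] = pd.NA
    for (pid, status), grp in out.groupby(["participant_id", "cue_status"]):
        if status == "flagged":
            continue
        order = grp.sort_values(["_imm_err", "object_id"],
                                kind="stable").index
        half = len(order) // 2
        out.loc[order[:half], "initial_stratum"] = "low"
        out.loc[order[half:], "initial_stratum"] = "high"
    return out.drop(columns="_imm_err")


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared for a 2x2 table [[a, b], [c, d]], df = 1, no
    continuity correction; a zero margin returns chi2 = 0 by convention."""
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        return 0.0, 1.0
    chi = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    return float(chi), float(stats.chi2.sf(chi, df=1))


def discrimination_chi2(ratings: pd.DataFrame,
                        alpha: float = 0.1) -> list[DiscriminationResult]:
    """Classify each participant as a cue discriminator or not.

    Per participant, a 2x2 table of cue status (cued / uncued) by rating
    ("high-confident cued" vs. any other option) is tested with a Pearson
    chi-squared (df = 1).  A participant is a ``discriminator`` if even a
    trend toward significance is present (p < ``alpha``, default 0.1).
    ``ratings`` needs columns participant_id, cue_status, rating; flagged
    associations are excluded.
    """
    results = []
    sub = ratings[ratings["cue_status"] != "flagged"]
    for pid, grp in sub.groupby("participant_id"):
        cued = grp["cue_status"] == "cued"
        hc = grp["rating"] == "HC_cued"
        a = int((cued & hc).sum())
        b = int((cued & ~hc).sum())
        c = int((~cued & hc).sum())
        d = int((~cued & ~hc).sum())
        chi, p = chi2_2x2(a, b, c, d)
        exp_min = min((a + b) * (a + c), (a + b) * (b + d),
                      (c + d) * (a + c), (c + d) * (b + d)) / max(a + b + c + d, 1)
        if 0 < exp_min < 5:
            log.warning("participant %s: expected 2x2 cell count below 5 "
                        "(min %.2f); chi-squared approximation is rough",
                        pid, exp_min)
        results.append(DiscriminationResult(
            participant_id=pid, chi_sq=chi, p=p,
            label="discriminator" if p < alpha else "non_discriminator",
            hc_hit_rate=a / max(a + b, 1), hc_fa_rate=c / max(c + d, 1)))
    return results


def rating_distribution(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-participant proportion of each response option within each cue
    condition (rows sum to 1 within participant x condition)."""
    from .datatypes import RATING_OPTIONS
    sub = ratings[ratings["cue_status"] != "flagged"]
    counts = (sub.groupby(["participant_id", "cue_status", "rating"],
                          observed=True).size()
              .unstack("rating", fill_value=0)
              .reindex(columns=list(RATING_OPTIONS), fill_value=0))
    props = counts.div(counts.sum(axis=1), axis=0)
    return props.reset_index()


def labeled_subset_contrast(trials: pd.DataFrame,
                            subset: str = "rated_uncued_only"
                            ) -> dict:
    """Cued vs. uncued memory stability restricted by discrimination rating.

    ``rated_uncued_only`` keeps associations the participant labeled as NOT
    seen during the cover task (excluding correctly/incorrectly recognized
    "cued"-rated objects); ``rated_cued_only`` keeps the complement.
    Participants without at least one cued and one uncued association in
    the subset are dropped; returns the paired contrast and retained n.
    """
    from .memory_metrics import stability_error
    if subset == "rated_uncued_only":
        keep_ratings = ("LC_uncued", "HC_uncued")
    elif subset == "rated_cued_only":
        keep_ratings = ("LC_cued", "HC_cued")
    else:
        raise ValueError("subset must be rated_uncued_only or rated_cued_only")
    work = trials[trials["cue_status"] != "flagged"].copy()
    work["stability_px"] = 0.5 * (stability_error(work, 1)
                                  + stability_error(work, 2))
    work = work[work["rating"].isin(keep_ratings)]
    cells = (work.groupby(["participant_id", "cue_status"])["stability_px"]
             .mean().unstack("cue_status"))
    cells = cells.dropna(subset=["cued", "uncued"])
    test = paired_t(cells["cued"].to_numpy(), cells["uncued"].to_numpy()) \
        if len(cells) >= 2 else None
    return {"per_participant": cells.reset_index(), "test": test,
            "n_retained": int(len(cells)), "subset": subset}
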