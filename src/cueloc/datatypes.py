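"""Shared domain types and table schemas.

Coordinates are 0-based screen pixels, origin at the top-left corner,
x increasing rightward and y increasing downward.  Trial-level data are
carried as :class:`pandas.DataFrame` objects with the column schemas
defined here (one row per object-location association, per lexical-decision
trial, or per discrimination rating).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GridSpec",
    "DEFAULT_GRID",
    "CUE_STATUSES",
    "RATING_OPTIONS",
    "TRIALS_COLUMNS",
    "LDT_COLUMNS",
    "RATINGS_COLUMNS",
    "ITI_DURATIONS_S",
]

#: allowed values of the per-association cue status
CUE_STATUSES = ("cued", "uncued", "flagged")

#: four-option confidence scale of the cue-discrimination test,
#: ordered from strongest "seen during the cover task" to strongest "not seen"
RATING_OPTIONS = ("HC_cued", "LC_cued", "LC_uncued", "HC_uncued")

#: inter-trial-interval durations of the cover task, seconds (2 s per arrow)
ITI_DURATIONS_S = (10, 12, 14, 16)

TRIALS_COLUMNS = [
    "participant_id",
    "object_id",
    "studied_x",
    "studied_y",
    "immediate_x",
    "immediate_y",
    "delayed1_x",
    "delayed1_y",
    "delayed2_x",
    "delayed2_y",
    "n_training_rounds",
    "cue_status",
    "rating",
]

LDT_COLUMNS = [
    "participant_id",
    "trial_index",
    "iti_duration_s",
    "arrow_rts_ms",
    "lexical_rt_ms",
    "is_word",
    "cue_object_id",
]

RATINGS_COLUMNS = ["participant_id", "object_id", "rating"]


@dataclass(frozen=True)
class GridSpec:
    """Placement grid: screen dimensions and the pixel/centimetre scale.

    The default scale of 38.697 px/cm is reconstructed from the dual-unit
    error values a 1280x1024 display at this viewing geometry produces
    (264.3 px = 6.83 cm); it can be overridden for other monitors.
    """

    width_px: int = 1280
    height_px: int = 1024
    px_per_cm: float = 38.697

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")

    @property
    def area_px2(self) -> float:
        """Screen area in square pixels (the support of the guessing density)."""
        return float(self.width_px) * float(self.height_px)

    def contains(self, x, y) -> bool | "np.ndarray":  # noqa: F821
        return (x >= 0) & (x <= self.width_px) & (y >= 0) & (y <= self.height_px)


DEFAULT_GRID = GridSpec()


def validate_trials(df) -> None:
    """Raise ValueError if a trials table is structurally invalid."""
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials table missing columns: {missing}")
    bad = set(df["cue_status"].unique()) - set(CUE_STATUSES)
    if bad:
        raise ValueError(f"unknown cue_status values: {sorted(bad)}")
    if (df["n_training_rounds"] < 2).any():
        raise ValueError("n_training_rounds must be >= 2 (criterion requires "
                         "two consecutive passing tests)")


def validate_ldt(df) -> None:
    """Raise ValueError on a structurally invalid cover-task (LDT) table.

    Per participant: 96 trials, 24 cue events, each cued object re-exposed
    exactly three times, one re-exposure per third of the session.
    """
    missing = [c for c in LDT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ldt table missing columns: {missing}")
    for pid, grp in df.groupby("participant_id"):
        if len(grp) != 96:
            raise ValueError(f"participant {pid}: expected 96 LDT trials, "
                             f"got {len(grp)}")
        cued = grp[grp["cue_object_id"].notna()]
        if len(cued) != 24:
            raise ValueError(f"participant {pid}: expected 24 cue events, "
                             f"got {len(cued)}")
        counts = cued["cue_object_id"].value_counts()
        if (counts != 3).any():
            raise ValueError(f"participant {pid}: each cued object must be "
                             "re-exposed exactly 3 times")
        per_third = cued.groupby("cue_object_id")[
            "trial_index"].apply(lambda t: sorted(t // 32))
        if any(v != [0, 1, 2] for v in per_third):
            raise ValueError(f"participant {pid}: re-exposures must fall one "
                             "per third of the session")
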