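"""Trial exclusion rules and descriptive condition summaries.

Two exclusion rules are applied to the raw trial table:

* RT outliers: within each participant's experimental cell, raw RTs
  farther than 2.5 sample SDs from the cell mean are removed. Single
  pass, correct and error trials pooled. By default the cell is the full
  design cell (language x stimulus type x length); ``pool_lengths=True``
  instead pools lengths within language x type. The default is the
  symmetric choice: with one pooled cutoff, intrinsically slower cells
  (long pseudo-words) lose more of their tail than fast ones, a
  length-correlated selection artifact that attenuates fitted length
  slopes; per-design-cell cutoffs trim every cell alike.
* Bad items: items answered incorrectly by strictly more than 40% of the
  participants who saw them are removed entirely. Item error fractions are
  computed on the data before RT filtering (item difficulty is a stimulus
  property, not an RT property); the two exclusion sets are then unioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RT_SD_CRITERION = 2.5
ITEM_ERROR_THRESHOLD = 0.40


@dataclass
class ExclusionReport:
    """Bookkeeping for one pass of the exclusion rules."""

    n_trials_in: int
    n_rt_outliers: int = 0
    n_items_excluded: int = 0
    n_item_trials_excluded: int = 0
    n_trials_out: int = 0
    excluded_items: list[str] = field(default_factory=list)
    per_participant_fraction: dict[int, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"n_trials_in\t{self.n_trials_in}",
            f"n_rt_outliers\t{self.n_rt_outliers}",
            f"n_items_excluded\t{self.n_items_excluded}",
            f"n_item_trials_excluded\t{self.n_item_trials_excluded}",
            f"n_trials_out\t{self.n_trials_out}",
            f"excluded_items\t{','.join(self.excluded_items) if self.excluded_items else '-'}",
        ]
        for p, frac in sorted(self.per_participant_fraction.items()):
            lines.append(f"participant_{p}_excluded_fraction\t{frac:.4f}")
        for note in self.notes:
            lines.append(f"note\t{note}")
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())


def _rt_outlier_mask(
    trials: pd.DataFrame, notes: list[str], pool_lengths: bool = False
) -> pd.Series:
    """True where a trial is an RT outlier in its participant's cell
    (|rt - mean| > 2.5 * sample SD over all trials of the cell)."""
    keys = ["participant", "language", "type"]
    if not pool_lengths:
        keys.append("length")
    mask = pd.Series(False, index=trials.index)
    for key, cell in trials.groupby(keys, sort=False):
        if len(cell) < 2:
            notes.append(f"cell {key} has <2 trials; RT filter skipped")
            warnings.warn(f"cell {key} has <2 trials; RT filter skipped", stacklevel=3)
            continue
        rt = cell["rt_s"]
        sd = rt.std(ddof=1)
        if sd == 0:
            continue
        mask.loc[cell.index] = (rt - rt.mean()).abs() > RT_SD_CRITERION * sd
    return mask


def exclude_rt_outliers(
    trials: pd.DataFrame, pool_lengths: bool = False
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove per-cell 2.5 SD RT outliers (single pass)."""
    report = ExclusionReport(n_trials_in=len(trials))
    mask = _rt_outlier_mask(trials, report.notes, pool_lengths)
    kept = trials.loc[~mask]
    report.n_rt_outliers = int(mask.sum())
    report.n_trials_out = len(kept)
    report.per_participant_fraction = _participant_fractions(trials, mask)
    return kept.reset_index(drop=True), report


def _item_error_fractions(trials: pd.DataFrame) -> pd.Series:
    """Per item, fraction of participants (who saw it) answering incorrectly."""
    per_pp = trials.groupby(["item", "participant"])["correct"].mean() < 1.0
    return per_pp.groupby("item").mean()


def exclude_bad_items(trials: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove items with error fraction strictly above 40% of participants."""
    report = ExclusionReport(n_trials_in=len(trials))
    frac = _item_error_fractions(trials)
    bad = frac.index[frac > ITEM_ERROR_THRESHOLD].tolist()
    mask = trials["item"].isin(bad)
    kept = trials.loc[~mask]
    report.n_items_excluded = len(bad)
    report.excluded_items = sorted(bad)
    report.n_item_trials_excluded = int(mask.sum())
    report.n_trials_out = len(kept)
    report.per_participant_fraction = _participant_fractions(trials, mask)
    return kept.reset_index(drop=True), report


def _participant_fractions(trials: pd.DataFrame, mask: pd.Series) -> dict[int, float]:
    frac = mask.groupby(trials["participant"]).mean()
    return {int(p): float(f) for p, f in frac.items()}


def apply_exclusions(
    trials: pd.DataFrame, pool_lengths: bool = False
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Both rules, each computed on the raw data, removals unioned."""
    report = ExclusionReport(n_trials_in=len(trials))
    rt_mask = _rt_outlier_mask(trials, report.notes, pool_lengths)
    frac = _item_error_fractions(trials)
    bad = frac.index[frac > ITEM_ERROR_THRESHOLD].tolist()
    item_mask = trials["item"].isin(bad)
    removed = rt_mask | item_mask
    kept = trials.loc[~removed]
    report.n_rt_outliers = int(rt_mask.sum())
    report.n_items_excluded = len(bad)
    report.excluded_items = sorted(bad)
    report.n_item_trials_excluded = int(item_mask.sum())
    report.n_trials_out = len(kept)
    report.per_participant_fraction = _participant_fractions(trials, removed)
    return kept.reset_index(drop=True), report


def condition_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean correct/error RT and % error per language x stimulus type.

    Participant-level means are computed first and then averaged across
    participants; the reported SD is the between-participant SD. Cells with
    a single participant report SD 0 and are flagged.
    """
    per_pp = (
        trials.assign(err=~trials["correct"])
        .groupby(["language", "type", "participant"])
        .apply(
            lambda g: pd.Series(
                {
                    "rt_correct": g.loc[g["correct"], "rt_s"].mean(),
                    "rt_error": g.loc[~g["correct"], "rt_s"].mean(),
                    "pct_error": 100.0 * g["err"].mean(),
                }
            ),
            include_groups=False,
        )
    )
    rows = []
    for (lang, stype), cell in per_pp.groupby(level=["language", "type"]):
        n = len(cell)
        row = {"language": lang, "type": stype, "n_participants": n, "single_participant": n == 1}
        for col in ("rt_correct", "rt_error", "pct_error"):
            vals = cell[col].dropna()
            row[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
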