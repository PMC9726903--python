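"""Descriptive summaries: accuracy and constant-error tables.

All aggregation is two-stage: a mean per subject first, then mean and
sample (n-1) SD across subjects, so subjects with equal trial counts
contribute equally and the SD describes between-subject variability.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd


def accuracy_table(
    records: pd.DataFrame,
    grouping: Sequence[str] = ("group", "isi_ms"),
) -> pd.DataFrame:
    """Mean accuracy per cell of ``grouping`` factors.

    ``records`` is a tidy response table with ``subject_id`` and
    ``correct`` columns; extra factors such as ``delta_level`` or
    ``longer_first`` may be added to the grouping.  Returns one row per
    non-empty cell with mean_accuracy, sd (across subjects) and
    n_subjects.
    """
    grouping = list(grouping)
    missing = [g for g in grouping + ["subject_id", "correct"] if g not in records]
    if missing:
        raise KeyError(f"records table lacks columns {missing}")
    per_subject = (
        records.groupby(grouping + ["subject_id"], sort=True, observed=True)["correct"]
        .mean()
        .rename("accuracy")
        .reset_index()
    )
    cells = (
        per_subject.groupby(grouping, sort=True, observed=True)["accuracy"]
        .agg(mean_accuracy="mean", sd=lambda s: s.std(ddof=1), n_subjects="count")
        .reset_index()
    )
    cells.loc[cells["n_subjects"] == 1, "sd"] = 0.0
    return cells


def ce_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the constant error per group × ISI.

    Expects a fits table (``group``, ``isi``, ``ce_ms``; optionally an
    ``excluded`` flag, which drops those rows with a warning).  A
    single-subject cell reports SD 0.
    """
    use = fits
    if "excluded" in fits.columns and fits["excluded"].any():
        warnings.warn("dropping excluded fits from CE table", stacklevel=2)
        use = fits.loc[~fits["excluded"]]
    cells = (
        use.groupby(["group", "isi"], sort=True, observed=True)["ce_ms"]
        .agg(mean_ce="mean", sd=lambda s: s.std(ddof=1), n_subjects="count")
        .reset_index()
    )
    cells.loc[cells["n_subjects"] == 1, "sd"] = 0.0
    return cells


def slope_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the psychometric slope (probit SD, ms) per group × ISI."""
    use = fits if "excluded" not in fits.columns else fits.loc[~fits["excluded"]]
    cells = (
        use.groupby(["group", "isi"], sort=True, observed=True)["jnd_ms"]
        .agg(mean_slope="mean", sd=lambda s: s.std(ddof=1), n_subjects="count")
        .reset_index()
    )
    cells.loc[cells["n_subjects"] == 1, "sd"] = 0.0
    return cells
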