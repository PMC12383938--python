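"""Surviving fractions and SOBP-window summaries from colony counts.

A well's surviving fraction is its colony count divided by the mean colony
count of the designated unirradiated control wells (which folds plating
efficiency into the normalization).  Values above 1 are legitimate — sampling
noise at 100 cells per well routinely produces them — and are never clipped.

Window summaries report mean and sample standard deviation (n-1 denominator)
over the per-column values inside an inclusive column range; the default
window, columns 3-10, is the SOBP plateau of the 12-step jig.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ControlError, WindowError

SOBP_WINDOW: tuple[int, int] = (3, 10)


@dataclass(frozen=True)
class WindowSummary:
    """Mean +/- sample SD of per-column values over an inclusive column range."""

    window: tuple[int, int]
    mean: float
    sample_sd: float
    n: int


def control_reference(counts: pd.DataFrame, control_col: int | None = None,
                      control_label: str | None = None) -> float:
    """Mean colony count of the control wells.

    Controls may be a plate column (``control_col``) or all wells with a given
    ``dose_label`` (``control_label``, e.g. an unirradiated plate).
    """
    if (control_col is None) == (control_label is None):
        raise ValueError("specify exactly one of control_col or control_label")
    if control_col is not None:
        sel = counts[counts["col"] == control_col]
    else:
        sel = counts[counts["dose_label"] == control_label]
    if sel.empty:
        raise ControlError("no control wells matched the selection")
    return float(sel["colony_count"].mean())


def surviving_fractions(counts: pd.DataFrame, control_ref: float) -> pd.DataFrame:
    """Normalize per-well colony counts to surviving fractions.

    ``SF = colony_count / control_ref`` per well.  Returns a survival table
    with columns ``column_index, dose_label, replicate_id, surviving_fraction``.
    """
    if not control_ref > 0:
        raise ControlError(f"control reference must be > 0, got {control_ref}")
    out = pd.DataFrame(
        {
            "column_index": counts["col"].astype(int),
            "dose_label": counts["dose_label"],
            "replicate_id": counts["replicate_id"]
            if "replicate_id" in counts
            else pd.factorize(counts["plate_id"].astype(str) + "/" + counts["row"].astype(str))[0],
            "surviving_fraction": counts["colony_count"] / control_ref,
        }
    )
    return out.reset_index(drop=True)


def per_column_means(survival: pd.DataFrame, dose_label: str | None = None) -> pd.Series:
    """Mean surviving fraction per column (over replicate wells).

    These per-column means are the values summarized over the SOBP window and
    fed to the RBE stage; replicate-level SFs stay available for t-tests.
    """
    df = survival
    if dose_label is not None:
        df = df[df["dose_label"] == dose_label]
    return df.groupby("column_index")["surviving_fraction"].mean()


def summarize_window(
    values: Mapping[int, float] | pd.Series,
    window: tuple[int, int] = SOBP_WINDOW,
) -> WindowSummary:
    """Mean and sample SD of per-column values over an inclusive window.

    ``values`` maps column index -> value (a pandas Series indexed by column
    works directly).  At least two columns must fall inside the window.
    """
    lo, hi = window
    if lo > hi:
        raise WindowError(f"empty window {window}")
    s = pd.Series(values)
    sel = s[(s.index >= lo) & (s.index <= hi)].astype(float)
    if len(sel) < 2:
        raise WindowError(
            f"window {window} selects {len(sel)} column(s); need >= 2 for a sample SD"
        )
    return WindowSummary(
        window=(lo, hi),
        mean=float(sel.mean()),
        sample_sd=float(sel.std(ddof=1)),
        n=int(len(sel)),
    )
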