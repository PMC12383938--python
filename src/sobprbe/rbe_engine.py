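"""Isoeffect-dose inversion of the photon LQ model and per-column RBE.

RBE is the ratio of the photon dose producing a given surviving fraction
(the isoeffect dose, from inverting the fitted photon LQ model) to the proton
dose that actually produced it.  Two aggregation pathways are supported over
the SOBP window:

* **per-column** (pathway A): invert each column's SF, divide by the proton
  dose, then average the per-column RBEs (mean +/- sample SD);
* **aggregate-SF** (pathway B): average the window SFs first, then invert the
  mean SF once.

The two coincide only when the window SFs are equal; with the convex LQ
inverse they generally differ, so results always record which pathway
produced them.

Columns whose SF exceeds 1 can fall outside the range of the photon model
(negative discriminant or only negative roots); the ``no_root_policy``
decides whether such columns are excluded from the summary or abort the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clonogenic_stats import SOBP_WINDOW, WindowSummary
from .errors import NoIsoeffectDoseError
from .lq_model import LQFit
from .synthetic_plate import ColumnPhysics


@dataclass(frozen=True)
class AnalysisConfig:
    """Windowing and policy choices for the RBE stage."""

    sobp_window: tuple[int, int] = SOBP_WINDOW
    proton_doses: tuple[float, ...] = (2.0, 4.0)
    no_root_policy: str = "exclude"
    reference_fit: LQFit | None = None

    def __post_init__(self):
        lo, hi = self.sobp_window
        if not (1 <= lo <= hi <= 12):
            raise ValueError("sobp_window must lie within columns 1-12")
        if any(d <= 0 for d in self.proton_doses):
            raise ValueError("proton_doses must be > 0")
        if self.no_root_policy not in ("exclude", "error"):
            raise ValueError("no_root_policy must be 'exclude' or 'error'")


@dataclass(frozen=True)
class RBEProfile:
    """Per-column isoeffect doses and RBEs plus the window summary."""

    records: pd.DataFrame  # column_index, let_d, proton_dose_gy, sf,
    #                        isoeffect_dose_gy, rbe, status
    summary: WindowSummary
    pathway: str  # "per-column" or "aggregate-SF"
    proton_dose: float


def isoeffect_dose(sf: float, alpha: float, beta: float) -> float:
    """Photon dose D >= 0 with exp(-(alpha*D + beta*D^2)) equal to ``sf``.

    Solves beta*D^2 + alpha*D + ln(sf) = 0.  For beta > 0 and sf < 1 the root
    ``(-alpha + sqrt(alpha^2 - 4*beta*ln sf)) / (2*beta)`` is the unique
    nonnegative solution, including for negative alpha; beta = 0 falls back to
    the purely linear model D = -ln(sf)/alpha.  Raises
    :class:`NoIsoeffectDoseError` when the discriminant is negative or no
    root is nonnegative.
    """
    if not sf > 0:
        raise ValueError(f"sf must be > 0, got {sf}")
    log_sf = math.log(sf)
    if log_sf == 0.0:
        return 0.0
    if beta == 0.0:
        if alpha == 0.0:
            raise NoIsoeffectDoseError(sf, alpha, beta)
        d = -log_sf / alpha
        if d < 0:
            raise NoIsoeffectDoseError(sf, alpha, beta)
        return d
    disc = alpha * alpha - 4.0 * beta * log_sf
    if disc < 0:
        raise NoIsoeffectDoseError(sf, alpha, beta)
    sq = math.sqrt(disc)
    roots = [(-alpha + sq) / (2.0 * beta), (-alpha - sq) / (2.0 * beta)]
    nonneg = sorted(r for r in roots if r >= 0.0)
    if not nonneg:
        raise NoIsoeffectDoseError(sf, alpha, beta)
    return nonneg[0]


def _window_sfs(
    sfs: Mapping[int, float] | pd.Series, window: tuple[int, int]
) -> "pd.Series":
    s = pd.Series(sfs).astype(float)
    lo, hi = window
    sel = s[(s.index >= lo) & (s.index <= hi)].sort_index()
    missing = set(range(lo, hi + 1)) - set(sel.index)
    if missing:
        raise ValueError(f"surviving fractions missing for window columns {sorted(missing)}")
    return sel


def rbe_profile(
    sfs: Mapping[int, float] | pd.Series,
    physics: Sequence[ColumnPhysics],
    proton_dose: float,
    config: AnalysisConfig,
) -> RBEProfile:
    """Per-column (pathway A) RBE profile over the SOBP window.

    For each window column, the photon isoeffect dose at that column's SF is
    divided by the delivered proton dose; the summary is the mean +/- sample
    SD over columns with a real nonnegative root ("ok" status).  Columns with
    no root are excluded or fatal per ``config.no_root_policy``.
    """
    fit = config.reference_fit
    if fit is None:
        raise ValueError("config.reference_fit is required")
    sel = _window_sfs(sfs, config.sobp_window)
    let_by_col = {ph.column_index: ph.let_d for ph in physics}

    records = []
    for col, sf in sel.items():
        try:
            d_iso = isoeffect_dose(float(sf), fit.alpha, fit.beta)
            rbe = d_iso / proton_dose
            status = "ok"
        except NoIsoeffectDoseError as exc:
            if config.no_root_policy == "error":
                raise NoIsoeffectDoseError(
                    exc.sf, exc.alpha, exc.beta, column_index=int(col)
                ) from None
            d_iso, rbe, status = float("nan"), float("nan"), "no-real-root"
        records.append(
            (int(col), let_by_col.get(int(col), float("nan")), proton_dose,
             float(sf), d_iso, rbe, status)
        )
    df = pd.DataFrame(
        records,
        columns=["column_index", "let_d", "proton_dose_gy", "sf",
                 "isoeffect_dose_gy", "rbe", "status"],
    )
    ok = df.loc[df["status"] == "ok", "rbe"]
    summary = WindowSummary(
        window=config.sobp_window,
        mean=float(ok.mean()) if len(ok) else float("nan"),
        sample_sd=float(ok.std(ddof=1)) if len(ok) >= 2 else float("nan"),
        n=int(len(ok)),
    )
    return RBEProfile(records=df, summary=summary, pathway="per-column",
                      proton_dose=proton_dose)


def rbe_aggregate(
    sfs: Mapping[int, float] | pd.Series,
    proton_dose: float,
    config: AnalysisConfig,
) -> float:
    """Aggregate-SF (pathway B) RBE: invert the window-mean SF once.

    Averaging first lets columns with SF > 1 contribute — the window mean can
    still be inside the photon model's range even when individual columns are
    not.  A :class:`NoIsoeffectDoseError` on the aggregate propagates.
    """
    fit = config.reference_fit
    if fit is None:
        raise ValueError("config.reference_fit is required")
    sel = _window_sfs(sfs, config.sobp_window)
    mean_sf = float(sel.mean())
    return isoeffect_dose(mean_sf, fit.alpha, fit.beta) / proton_dose
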