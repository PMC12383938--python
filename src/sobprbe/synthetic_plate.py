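"""Synthetic 96-well clonogenic-assay data for a 12-step proton irradiation jig.

The experiment this module emulates irradiates cells seeded at 100 per well in
96-well plates through a multi-step range shifter, so each of the 12 plate
columns receives a different fraction of the prescription dose and a different
dose-averaged LET.  Three generators are provided:

* a packaged physics fixture (per-column relative dose modulation factor and
  LET_d) for the jig,
* binomially noisy colony counts drawn from a linear-quadratic survival law
  with an optional linear LET modifier of alpha,
* rendered 8-bit grayscale plate images with ground-truth per-well counts,
  for exercising the colony-counting stage.

All randomness flows from explicit seeds through ``numpy.random.default_rng``;
no global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidTruthError, NotFoundError, PlacementError

ROW_LABELS = "ABCDEFGHIJKLMNOP"

_FIXTURES = {
    "table1": "table1_physics.csv",
}


@dataclass(frozen=True)
class ColumnPhysics:
    """Per-column beam physics: relative dose factor and dose-averaged LET.

    ``prescription_dose * dose_modulation_factor`` is the dose delivered to
    wells in this column; ``let_d`` is the dose-averaged LET in keV/um.
    """

    column_index: int
    dose_modulation_factor: float
    let_d: float

    def __post_init__(self):
        if self.dose_modulation_factor < 0:
            raise ValueError(
                f"dose_modulation_factor must be >= 0, got {self.dose_modulation_factor}"
            )
        if self.let_d < 0:
            raise ValueError(f"let_d must be >= 0, got {self.let_d}")


@dataclass(frozen=True)
class PlateLayout:
    """Geometry and seeding of a clonogenic 96-well plate."""

    n_rows: int = 8
    n_cols: int = 12
    cells_seeded_per_well: int = 100
    control_label: str = "0Gy"

    def __post_init__(self):
        for name in ("n_rows", "n_cols", "cells_seeded_per_well"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth survival parameters for recovery tests.

    ``alpha_true`` (1/Gy) and ``beta_true`` (1/Gy^2) define the LQ law; for
    proton columns alpha is modified linearly with LET as
    ``alpha_true + let_alpha_slope * let_d``.  ``plating_efficiency`` is the
    fraction of unirradiated seeded cells that form a countable colony.
    """

    alpha_true: float
    beta_true: float
    let_alpha_slope: float = 0.0
    plating_efficiency: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (math.isfinite(self.beta_true) and math.isfinite(self.plating_efficiency)):
            raise ValueError("beta_true and plating_efficiency must be finite")
        if not 0.0 < self.plating_efficiency <= 1.0:
            raise ValueError("plating_efficiency must be in (0, 1]")


@dataclass(frozen=True)
class ImageScene:
    """Specification of a rendered plate image.

    ``wells`` lists (row, col, colony_count) with zero-based plate coordinates.
    Colonies are rendered as disks with radius drawn uniformly from
    ``colony_radius_px``; the default minimum radius of 2.0 px keeps the
    rasterized area of every disk at 12 pixels or more regardless of subpixel
    center placement, comfortably above the 4-px counting cutoff.  The stain
    gray level is drawn per well from a normal with the given mean/spread
    (staining varies between wells far more than within one), and
    ``noise_sd`` adds optional Gaussian pixel noise — the default is a clean
    flat background, under which threshold-based counting is exact; see the
    package docs for how counting degrades as noise grows.  ``polarity``
    selects colonies darker or brighter than background.
    """

    wells: tuple[tuple[int, int, int], ...]
    n_rows: int = 8
    n_cols: int = 12
    well_pitch_px: int = 48
    roi_radius_px: float = 20.0
    colony_radius_px: tuple[float, float] = (2.0, 3.0)
    stain_intensity: tuple[float, float] = (65.0, 5.0)
    background_level: float = 200.0
    noise_sd: float = 0.0
    colony_margin_px: float = 4.0
    polarity: str = "dark"

    def __post_init__(self):
        for r, c, n in self.wells:
            if n < 0:
                raise ValueError("colony_count must be >= 0")
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"well ({r}, {c}) outside plate grid")
        for level in (self.background_level, *self.stain_intensity[:1]):
            if not 0 <= level <= 255:
                raise ValueError("intensities must lie within 8-bit range")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")

    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.n_rows * self.well_pitch_px, self.n_cols * self.well_pitch_px)

    def well_center(self, row: int, col: int) -> tuple[float, float]:
        p = self.well_pitch_px
        return ((row + 0.5) * p, (col + 0.5) * p)


def load_fixture_physics(name: str = "table1") -> list[ColumnPhysics]:
    """Load a packaged per-column physics table.

    The ``"table1"`` fixture ships the 12-step jig profile used throughout the
    package: modulation factors ~1.0 across the SOBP plateau (columns 3-10),
    a distal high-LET step at column 11, and a near-zero-dose column 12.
    """
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise NotFoundError(
            f"unknown physics fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    with resources.files("sobprbe").joinpath("fixtures", fname).open("r") as fh:
        df = pd.read_csv(fh)
    return [
        ColumnPhysics(int(r.column_index), float(r.dose_modulation_factor), float(r.let_kev_um))
        for r in df.itertuples()
    ]


def fixture_physics_path(name: str = "table1"):
    """Filesystem path of a packaged physics fixture (for checksum/CLI use)."""
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise NotFoundError(f"unknown physics fixture {name!r}") from None
    return resources.files("sobprbe").joinpath("fixtures", fname)


def lq_survival_probability(dose: float, alpha: float, beta: float) -> float:
    # kept local to avoid a circular import with lq_model
    return math.exp(-(alpha * dose + beta * dose * dose))


def simulate_survival_counts(
    layout: PlateLayout,
    physics: Sequence[ColumnPhysics],
    truth: SyntheticTruth,
    prescription_dose: float,
    n_replicates: int = 8,
) -> pd.DataFrame:
    """Draw per-well colony counts under binomial colony-formation noise.

    Each well in column ``c`` receives ``prescription_dose * factor_c`` Gy; the
    per-cell colony probability is ``PE * S(D)`` with the LQ survival law and
    ``alpha = alpha_true + let_alpha_slope * let_d_c``.  Replicate wells fill
    plate rows top to bottom, spilling onto additional plates when
    ``n_replicates`` exceeds ``layout.n_rows``.

    Returns a table with columns ``plate_id, row, col, dose_label,
    colony_count`` plus ``replicate_id`` and ``delivered_dose_gy`` for
    convenience.  Identical ``truth.seed`` (and arguments) gives a bit-identical
    table.
    """
    if prescription_dose < 0:
        raise ValueError("prescription_dose must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    probs = {}
    for ph in physics:
        dose = prescription_dose * ph.dose_modulation_factor
        alpha = truth.alpha_true + truth.let_alpha_slope * ph.let_d
        p = truth.plating_efficiency * lq_survival_probability(dose, alpha, truth.beta_true)
        if not (0.0 <= p <= 1.0) or not math.isfinite(p):
            raise InvalidTruthError(
                f"column {ph.column_index}: colony probability {p:.6g} outside [0, 1] "
                f"(alpha={alpha:.6g}, dose={dose:.6g} Gy)"
            )
        probs[ph.column_index] = (p, dose)

    # Independent streams per prescription dose, all derived from truth.seed.
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed, int(round(prescription_dose * 1000))])
    )
    dose_label = f"{prescription_dose:g}Gy"
    records = []
    for rep in range(n_replicates):
        plate_id = rep // layout.n_rows
        row = ROW_LABELS[rep % layout.n_rows]
        for ph in physics:
            p, dose = probs[ph.column_index]
            count = int(rng.binomial(layout.cells_seeded_per_well, p))
            records.append(
                (plate_id, row, ph.column_index, dose_label, rep, dose, count)
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "plate_id", "row", "col", "dose_label",
            "replicate_id", "delivered_dose_gy", "colony_count",
        ],
    )


def _place_colonies(
    rng: np.random.Generator,
    n: int,
    roi_radius: float,
    radius_range: tuple[float, float],
    margin: float = 6.0,
    max_attempts_per_colony: int = 500,
    max_restarts: int = 50,
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping colony (dy, dx, r) offsets in a circular ROI.

    The rim-to-rim ``margin`` (default 6 px) keeps rasterized colonies disjoint
    under 8-connectivity even when a short chain of noise-darkened background
    pixels sits between them.  When a dense well jams, placement restarts from an
    empty well rather than failing on the first bad configuration.
    """
    for _ in range(max_restarts):
        placed: list[tuple[float, float, float]] = []
        for _ in range(n):
            r = rng.uniform(*radius_range)
            rmax = roi_radius - r - 1.0
            if rmax <= 0:
                raise PlacementError("colony radius exceeds ROI radius")
            for _ in range(max_attempts_per_colony):
                rho = rmax * math.sqrt(rng.uniform())
                phi = rng.uniform(0.0, 2.0 * math.pi)
                dy, dx = rho * math.sin(phi), rho * math.cos(phi)
                if all(
                    math.hypot(dy - py, dx - px) >= r + pr + margin
                    for py, px, pr in placed
                ):
                    placed.append((dy, dx, r))
                    break
            else:
                break  # this configuration jammed; restart the well
        if len(placed) == n:
            return placed
    raise PlacementError(f"could not place {n} non-overlapping colonies in the ROI")


def render_plate_image(scene: ImageScene, seed: int) -> tuple[np.ndarray, pd.DataFrame]:
    """Render an 8-bit grayscale plate image and its ground-truth counts.

    Each requested colony becomes a disk (area >= 5 px at the default radius
    range) on the configured polarity side of the background, disks within a
    well never touch, and Gaussian pixel noise is added last.  The same scene
    and seed give bit-identical pixels.

    Returns ``(image, truth)`` where ``truth`` has columns
    ``row, col, colony_count``.
    """
    rng = np.random.default_rng(seed)
    img = np.full(scene.image_shape, scene.background_level, dtype=float)
    mean_int, spread_int = scene.stain_intensity
    yy, xx = np.mgrid[0 : scene.image_shape[0], 0 : scene.image_shape[1]]

    truth_records = []
    for row, col, count in scene.wells:
        cy, cx = scene.well_center(row, col)
        # stain intensity varies well to well (staining/washing gradients);
        # within a well colonies share one level, keeping the histogram bimodal
        level = float(np.clip(rng.normal(mean_int, spread_int), 0, 255))
        offsets = _place_colonies(rng, count, scene.roi_radius_px, scene.colony_radius_px,
                                  margin=scene.colony_margin_px)
        for dy, dx, r in offsets:
            disk = (yy - (cy + dy)) ** 2 + (xx - (cx + dx)) ** 2 <= r * r
            img[disk] = level
        truth_records.append((row, col, count))

    if scene.noise_sd > 0:
        img += rng.normal(0.0, scene.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(truth_records, columns=["row", "col", "colony_count"])
    return img, truth
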