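"""Electrophoretic mobility model, MinBS, and virtual gel rendering.

Migration distance of a DNA fragment in agarose is close to linear in the
logarithm of its size, ``distance = a - b * ln(size + c)``; the nonlinearity
is why a fixed bp gap between amplicons is the wrong separability criterion
(a 50 bp gap separates 100 from 150 bp easily, but 1000 from 1050 bp barely
moves).  The shipped model is a least-squares fit of this law to a 1% agarose
calibration ladder (100 bp - 3 kb, 60 mm lane); other gels can be fitted from
a user ladder with :meth:`GelModel.fit`.

MinBS (minimum band spacing) is the smallest pairwise difference in predicted
migration distance among a candidate combination's amplicons; a multiplex
combination is accepted only if MinBS clears a configured threshold (default
3 mm) so its bands are separable by eye.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GelModel",
    "VirtualGelLane",
    "ExtrapolationWarning",
    "predict_mobility",
    "min_band_spacing",
    "ladder_lane",
    "render_virtual_gel",
    "render_virtual_gel_image",
    "DEFAULT_MINBS_MM",
    "LADDER_SIZES",
]

DEFAULT_MINBS_MM = 3.0
LADDER_SIZES = (100, 150, 200, 300, 400, 500, 700, 1000, 1500, 2000, 3000)


class ExtrapolationWarning(UserWarning):
    """Mobility requested outside the calibrated size range."""


@dataclass(frozen=True)
class GelModel:
    """Calibrated size -> migration-distance mapping for one gel recipe."""

    a: float
    b: float
    c: float
    gel_percentage: float = 1.0
    lane_length: float = 60.0
    valid_size_range: Tuple[int, int] = (100, 3000)

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be > 0 (distance must decrease with size)")
        if self.valid_size_range[0] + self.c <= 0:
            raise ValueError("size offset c leaves log undefined over the valid range")

    def predict(self, size: float) -> float:
        """Migration distance (mm) of a fragment, clamped to [0, lane_length]."""
        lo, hi = self.valid_size_range
        if not (lo <= size <= hi):
            warnings.warn(
                f"size {size} bp outside calibrated range {self.valid_size_range}; extrapolating",
                ExtrapolationWarning,
                stacklevel=2,
            )
        d = self.a - self.b * math.log(size + self.c)
        return min(max(d, 0.0), self.lane_length)

    @classmethod
    def fit(
        cls,
        sizes: Sequence[float],
        distances: Sequence[float],
        gel_percentage: float = 1.0,
        lane_length: float = 60.0,
    ) -> "GelModel":
        """Least-squares fit of the log-size law to a measured ladder."""
        from scipy.optimize import curve_fit

        sizes = np.asarray(sizes, dtype=float)
        distances = np.asarray(distances, dtype=float)
        if sizes.size < 3:
            raise ValueError("need >= 3 ladder points to fit (a, b, c)")
        popt, _ = curve_fit(
            lambda s, a, b, c: a - b * np.log(s + c),
            sizes, distances, p0=(100.0, 13.0, 0.0), maxfev=20000,
        )
        return cls(
            a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
            gel_percentage=gel_percentage, lane_length=lane_length,
            valid_size_range=(int(sizes.min()), int(sizes.max())),
        )

    @classmethod
    def default(cls) -> "GelModel":
        return _default_model()


@lru_cache(maxsize=1)
def _default_model() -> GelModel:
    params = {}
    with resources.as_file(
        resources.files("plexprimer.data").joinpath("gel_model_1pct.tsv")
    ) as path:
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("parameter"):
                continue
            key, value = line.split("\t")
            params[key] = float(value)
    return GelModel(
        a=params["a"], b=params["b"], c=params["c"],
        gel_percentage=params["gel_percentage"],
        lane_length=params["lane_length_mm"],
        valid_size_range=(int(params["min_size_bp"]), int(params["max_size_bp"])),
    )


@lru_cache(maxsize=1)
def default_ladder() -> Tuple[Tuple[int, ...], Tuple[float, ...]]:
    """(sizes, distances) of the shipped 1% agarose calibration ladder."""
    sizes: List[int] = []
    dists: List[float] = []
    with resources.as_file(
        resources.files("plexprimer.data").joinpath("ladder_1pct_agarose.tsv")
    ) as path:
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            s, d = line.split("\t")
            sizes.append(int(s))
            dists.append(float(d))
    return tuple(sizes), tuple(dists)


def predict_mobility(size: float, model: Optional[GelModel] = None) -> float:
    """Migration distance (mm) of one fragment under the given (or default) model."""
    model = model or GelModel.default()
    return model.predict(size)


def min_band_spacing(sizes: Sequence[float], model: Optional[GelModel] = None) -> float:
    """Minimum pairwise migration-distance difference (mm); +inf for < 2 bands."""
    model = model or GelModel.default()
    if len(sizes) == 0:
        raise ValueError("need at least one band size")
    if len(sizes) == 1:
        return math.inf
    positions = [model.predict(s) for s in sizes]
    return min(
        abs(positions[i] - positions[j])
        for i in range(len(positions))
        for j in range(i + 1, len(positions))
    )


@dataclass(frozen=True)
class VirtualGelLane:
    """One gel lane: a label and the band sizes (positions follow the model)."""

    label: str
    sizes: Tuple[int, ...]
    intensities: Optional[Tuple[float, ...]] = None

    def positions(self, model: GelModel) -> Tuple[float, ...]:
        return tuple(model.predict(s) for s in self.sizes)


def ladder_lane(model: Optional[GelModel] = None, label: str = "ladder") -> VirtualGelLane:
    model = model or GelModel.default()
    lo, hi = model.valid_size_range
    return VirtualGelLane(label, tuple(s for s in LADDER_SIZES if lo <= s <= hi))


def render_virtual_gel(
    lanes: Sequence[VirtualGelLane],
    model: Optional[GelModel] = None,
    include_ladder: bool = True,
    row_mm: float = 1.5,
) -> str:
    """Deterministic text-art electrophotogram (byte-stable for golden files).

    Rows are ``row_mm``-wide migration bins from the well downward; a band is
    drawn as ``======`` in its lane column with its size printed alongside in
    the annotation column.
    """
    model = model or GelModel.default()
    if not lanes:
        raise ValueError("no lanes to render")
    all_lanes = ([ladder_lane(model)] if include_ladder else []) + list(lanes)
    width = max(8, max(len(l.label) for l in all_lanes) + 2)
    n_rows = int(math.ceil(model.lane_length / row_mm)) + 1
    grid = [["" for _ in all_lanes] for _ in range(n_rows)]
    for col, lane in enumerate(all_lanes):
        for size in sorted(lane.sizes, reverse=True):
            pos = model.predict(size)
            row = min(n_rows - 1, int(pos / row_mm))
            cell = grid[row][col]
            grid[row][col] = (cell + "," if cell else "") + str(int(size))
    lines = []
    header = "  mm  |" + "".join(l.label.center(width) + "|" for l in all_lanes)
    lines.append(header)
    lines.append("-" * len(header))
    for row in range(n_rows):
        cells = []
        for col in range(len(all_lanes)):
            tag = grid[row][col]
            cells.append(("=== " + tag + " ===").center(width) if tag else " " * width)
        lines.append(f"{row * row_mm:5.1f} |" + "|".join(cells) + "|")
    return "\n".join(lines) + "\n"


def render_virtual_gel_image(
    lanes: Sequence[VirtualGelLane],
    path,
    model: Optional[GelModel] = None,
    include_ladder: bool = True,
) -> None:
    """PNG/SVG electrophotogram: white bands on a dark lane, well at the top."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    model = model or GelModel.default()
    all_lanes = ([ladder_lane(model)] if include_ladder else []) + list(lanes)
    fig, ax = plt.subplots(figsize=(1.0 + 0.9 * len(all_lanes), 5.0))
    ax.set_facecolor("#101018")
    for x, lane in enumerate(all_lanes):
        for size in lane.sizes:
            pos = model.predict(size)
            ax.plot([x - 0.32, x + 0.32], [pos, pos], color="white", linewidth=3)
            if lane.label == "ladder":
                ax.annotate(str(int(size)), (x + 0.38, pos), color="#cccccc",
                            fontsize=6, va="center")
    ax.set_xticks(range(len(all_lanes)))
    ax.set_xticklabels([l.label for l in all_lanes], rotation=45, ha="right", fontsize=7)
    ax.set_ylim(model.lane_length, -2)
    ax.set_ylabel("migration distance (mm)")
    ax.set_xlim(-0.6, len(all_lanes) - 0.4 + 0.9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
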