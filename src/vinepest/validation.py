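"""Pixel-by-pixel accuracy assessment of the binary affection raster.

The assessment follows the standard remote-sensing recipe: rasterize
hand-digitized truth polygons onto the prediction grid, count the
confusion matrix over a validation region, and report

    OA  = 100 (TP + TN) / (TP + TN + FP + FN)     overall accuracy
    SPA = 100 TP / (TP + FN)                      success % of affection
    SPN = 100 TN / (TN + FP)                      success % of no affection

plus commission (FP) and omission (FN) error rates, overall and per
validation cell.  Percentages are reported rounded to one decimal,
half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from shapely.geometry import box

from .grids import GeoRaster, GridSpec
from .geomatic_io import PolygonSet, rasterize_polygons

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "confusion_matrix",
    "accuracy_metrics",
    "error_maps",
    "make_validation_mesh",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention of printed report
    tables), as opposed to banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Pixel counts: TP = affected predicted affected, FP = unaffected
    predicted affected, FN = affected predicted unaffected, TN =
    unaffected predicted unaffected."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy percentages; SPA/SPN are None when their class is absent
    (undefined, not zero)."""

    oa: float
    spa: float | None
    spn: float | None
    commission_error: float
    omission_error: float
    cm: ConfusionMatrix

    def rounded(self, ndigits: int = 1) -> dict:
        rnd = lambda v: None if v is None else round_half_up(v, ndigits)
        return {
            "OA": rnd(self.oa),
            "SPA": rnd(self.spa),
            "SPN": rnd(self.spn),
            "commission_error": rnd(self.commission_error),
            "omission_error": rnd(self.omission_error),
            "TP": self.cm.tp,
            "FP": self.cm.fp,
            "FN": self.cm.fn,
            "TN": self.cm.tn,
            "total": self.cm.total,
        }


def confusion_matrix(
    pred: GeoRaster,
    truth: GeoRaster,
    region: GeoRaster | None = None,
) -> ConfusionMatrix:
    """Count the confusion matrix pixel by pixel over the considered
    region (region mask = 1 and valid data in both rasters)."""
    if not pred.grid.same_grid(truth.grid):
        raise ValueError("prediction and truth are on different grids")
    considered = pred.valid_mask() & truth.valid_mask()
    if region is not None:
        if not region.grid.same_grid(pred.grid):
            raise ValueError("region mask is on a different grid")
        considered &= (region.data == 1) & region.valid_mask()
    p = pred.data[considered] == 1
    t = truth.data[considered] == 1
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionMatrix(tp, fp, fn, tn)


def accuracy_metrics(cm: ConfusionMatrix) -> AccuracyReport:
    """OA, SPA, SPN and commission/omission error rates from counts."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    oa = 100.0 * (cm.tp + cm.tn) / cm.total
    spa = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    spn = 100.0 * cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else None
    return AccuracyReport(
        oa=oa,
        spa=spa,
        spn=spn,
        commission_error=100.0 * cm.fp / cm.total,
        omission_error=100.0 * cm.fn / cm.total,
        cm=cm,
    )


def make_validation_mesh(
    grid: GridSpec, cell_side: float = 10.0, gap: float = 10.0
) -> PolygonSet:
    """Checkerboard validation mesh: square polygons of ``cell_side``
    separated by ``gap`` in both axes, aligned to the grid origin."""
    xmin, ymin, xmax, ymax = grid.extent
    period = cell_side + gap
    polys, props = [], []
    i = 0
    y = ymax
    while y - cell_side > ymin - 1e-9:
        x = xmin
        while x + cell_side < xmax + 1e-9:
            polys.append(box(x, y - cell_side, x + cell_side, y))
            props.append({"cell_id": i})
            i += 1
            x += period
        y -= period
    return PolygonSet(polys, label="validation-cell", properties=props)


def error_maps(
    pred: GeoRaster,
    truth: GeoRaster,
    validation_cells: PolygonSet,
) -> list[dict]:
    """Per-validation-cell accuracy breakdown.

    For each cell: the confusion matrix restricted to the cell plus OA
    and two normalizations of commission/omission error — over the
    cell's own considered pixels and over all considered pixels of the
    mesh.  Cells with no considered pixels are flagged and carry no
    rates.
    """
    mesh_region = rasterize_polygons(validation_cells, pred.grid)
    total_considered = confusion_matrix(pred, truth, mesh_region).total
    out = []
    for i, poly in enumerate(validation_cells.polygons):
        cell_mask = rasterize_polygons(
            PolygonSet([poly], label="cell"), pred.grid
        )
        cm = confusion_matrix(pred, truth, cell_mask)
        rec: dict = {"cell_id": i, "considered": cm.total}
        if cm.total == 0:
            rec["empty"] = True
        else:
            rep = accuracy_metrics(cm)
            rec.update(
                {
                    "TP": cm.tp,
                    "FP": cm.fp,
                    "FN": cm.fn,
                    "TN": cm.tn,
                    "OA": rep.oa,
                    "commission_pct_of_cell": 100.0 * cm.fp / cm.total,
                    "omission_pct_of_cell": 100.0 * cm.fn / cm.total,
                    "commission_pct_of_total": 100.0 * cm.fp / total_considered,
                    "omission_pct_of_total": 100.0 * cm.fn / total_considered,
                }
            )
        out.append(rec)
    return out
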