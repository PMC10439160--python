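"""Spatial statistics of portal-tract remnants in the desmoplastic rim.

Portal triads trapped in the capsule persist as remnants: an isolated artery
in portal stroma ("A") or artery plus bile duct ("A_BD"); the portal vein is
typically obliterated.  For each pin the minimal distances to the liver-rim
and rim-tumor interfaces are measured and combined into a relative distance
d_liver / (d_liver + d_tumor) ∈ [0, 1] — 0 at the liver side of the capsule,
1 at the tumor side — which makes positions comparable across rims of varying
thickness.  A vs A_BD positional shifts are compared with a two-sided
Wilcoxon rank-sum (Mann–Whitney) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import LineString, Polygon

from capsulezone.annotations_io import PortalTractPin
from capsulezone.errors import ValidationError

logger = logging.getLogger(__name__)

#: samples with combined n at or below this use exact p-value enumeration
EXACT_THRESHOLD = 12


@dataclass
class PinMeasurement:
    """Distances of one portal-tract pin to the two rim interfaces."""

    pin: PortalTractPin
    d_liver: float
    d_tumor: float
    valid: bool = True

    @property
    def relative_distance(self) -> float:
        """d_liver / (d_liver + d_tumor); 0 = liver side, 1 = tumor side."""
        total = self.d_liver + self.d_tumor
        if total <= 0:
            return float("nan")
        return self.d_liver / total


def measure_pins(
    pins: Sequence[PortalTractPin],
    liver_border: LineString | np.ndarray,
    tumor_border: LineString | np.ndarray,
) -> list[PinMeasurement]:
    """Minimal pin-to-polyline distances to both rim interfaces.

    A pin lying exactly on a border gets distance 0 to it; a (degenerate) pin
    on both borders simultaneously is flagged invalid.
    """
    if pins is None or len(pins) == 0:
        raise ValidationError("no pins to measure")
    liver = LineString(liver_border) if not isinstance(liver_border, LineString) else liver_border
    tumor = LineString(tumor_border) if not isinstance(tumor_border, LineString) else tumor_border
    points = shapely.points([p.position for p in pins])
    d_liver = shapely.distance(points, liver)
    d_tumor = shapely.distance(points, tumor)
    out = []
    for pin, dl, dt in zip(pins, d_liver, d_tumor):
        valid = (dl + dt) > 0
        if not valid:
            logger.warning("pin on slide %s touches both borders; flagged invalid", pin.slide_id)
        out.append(PinMeasurement(pin=pin, d_liver=float(dl), d_tumor=float(dt), valid=valid))
    return out


def pt_density(pins: Sequence[PortalTractPin], rim_polygon: Polygon) -> float:
    """Portal-tract density in the rim, as pins per mm².

    Pins outside the rim polygon are excluded with a warning (the boundary
    counts as inside).
    """
    if rim_polygon.area <= 0:
        raise ValidationError("rim polygon has zero area")
    if len(pins) == 0:
        return 0.0
    xy = np.asarray([p.position for p in pins])
    inside = shapely.intersects_xy(rim_polygon, xy[:, 0], xy[:, 1])
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("%d pin(s) outside the rim excluded from density", n_out)
    area_mm2 = rim_polygon.area / 1e6  # µm² → mm²
    return float(inside.sum()) / area_mm2


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "normal"] = "auto",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Returns (U statistic for the first sample, two-sided p).  With
    ``mode="auto"``, p is computed by exact enumeration when the combined
    sample size is at most 12 and there are no ties, otherwise by the normal
    approximation with tie and continuity corrections.  If every value is
    tied across both samples, p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValidationError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        logger.warning("all values tied across both samples; p = 1")
        u = len(x) * len(y) / 2.0
        return u, 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if mode == "exact" or (mode == "auto" and len(x) + len(y) <= EXACT_THRESHOLD):
        # tie-free small samples use the exact null distribution; tied small
        # samples enumerate all group assignments (permutation test)
        method = "exact" if not has_ties else stats.PermutationMethod(n_resamples=1_000_000)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_pt_subtypes(measurements: Sequence[PinMeasurement]) -> dict:
    """Compare the relative distances of A vs A_BD remnants.

    Returns a report with per-subtype counts and median relative distances
    and, when both subtypes are present, the two-sided Wilcoxon rank-sum
    U and p on the relative distances.  An absent subtype yields a report
    with the comparison fields set to None.
    """
    groups: dict[str, list[float]] = {"A": [], "A_BD": []}
    for m in measurements:
        if m.valid and np.isfinite(m.relative_distance):
            groups[m.pin.subtype].append(m.relative_distance)
    report = {
        "n_A": len(groups["A"]),
        "n_A_BD": len(groups["A_BD"]),
        "median_A": float(np.median(groups["A"])) if groups["A"] else None,
        "median_A_BD": float(np.median(groups["A_BD"])) if groups["A_BD"] else None,
        "U": None,
        "p": None,
    }
    if groups["A"] and groups["A_BD"]:
        u, p = wilcoxon_rank_sum(groups["A"], groups["A_BD"])
        report["U"] = u
        report["p"] = p
    else:
        logger.warning("a portal-tract subtype is absent; comparison skipped")
    return report
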