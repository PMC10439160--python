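"""Capsule zonation: zone construction, tiling, standardized distances, profiles.

The slide is partitioned into three concentric regions around an encapsulated
metastasis: the desmoplastic rim (DR, the fibrotic capsule), the perimetastatic
liver parenchyma (PLP, obtained by expanding the DR outward by a fixed
distance — 1500 µm for IHC/IF, 1000 µm for ISH), and the tumor center (TC).
Portal-tract and necrosis polygons are subtracted from DR and PLP and excluded
from quantification.

Each region is divided into 25 µm × 25 µm tiles.  A tile's raw distance is the
minimal distance from its centroid to the liver–tumor interface (the outer,
liver-rim border) for PLP and DR tiles, or to the DR's inner border for TC
tiles.  Because rim and tumor widths vary per case, distances are normalized
per case and zone::

    standardized distance = 100 / max_distance * tile_distance

signed so that the liver–tumor interface sits at 0%, the full PLP width at
+100%, the full DR width at −100% and the full TC depth at −200%.

Marker intensities are averaged per 5%-wide standardized-distance bin within
each case, then across cases (with a t-based 95% CI), and finally smoothed
with a rolling window of 5 bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import LineString, Polygon
from shapely.ops import unary_union

from capsulezone.errors import ValidationError

logger = logging.getLogger(__name__)

TILE_UM = 25.0
EXPANSION_UM = {"ihc": 1500.0, "if": 1500.0, "ish": 1000.0}

#: standardized-distance axis: 5%-wide bins spanning the TC (−200..−100),
#: DR (−100..0) and PLP (0..100) ranges
BIN_WIDTH = 5.0
BIN_EDGES = np.arange(-200.0, 100.0 + BIN_WIDTH, BIN_WIDTH)
BIN_MIDS = (BIN_EDGES[:-1] + BIN_EDGES[1:]) / 2.0


@dataclass
class ZoneSet:
    """The three quantification zones of one case, portal tracts removed."""

    dr: Polygon
    plp: Polygon
    tc: Polygon
    expansion_um: float
    tc_excluded: bool = False  # extensive necrosis

    def __post_init__(self) -> None:
        smallest = min(z.area for z in (self.dr, self.plp, self.tc) if z.area > 0)
        for a, b, names in (
            (self.dr, self.plp, "DR/PLP"),
            (self.dr, self.tc, "DR/TC"),
            (self.plp, self.tc, "PLP/TC"),
        ):
            if a.intersection(b).area > 1e-6 * smallest:
                raise ValidationError(f"zones {names} overlap")


@dataclass
class Tile:
    """One 25 µm quantification tile."""

    centroid: tuple[float, float]
    zone: Literal["PLP", "DR", "TC"]
    raw_distance: float
    standardized_distance: float = float("nan")
    size: float = TILE_UM
    intensities: dict[str, float] = field(default_factory=dict)


@dataclass
class StainVectors:
    """Unit RGB optical-density vectors for 2–3 stains (rows).

    With two stains the residual third vector is the normalized cross
    product, as in standard color-deconvolution practice.
    """

    vectors: np.ndarray
    stain_names: tuple[str, ...]

    def __post_init__(self) -> None:
        mat = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if mat.shape[1] != 3 or mat.shape[0] not in (2, 3):
            raise ValidationError("stain vectors must be 2 or 3 rows of RGB OD")
        norms = np.linalg.norm(mat, axis=1)
        if np.any(norms <= 0):
            raise ValidationError("stain vectors must be nonzero")
        mat = mat / norms[:, None]
        if mat.shape[0] == 2:
            residual = np.cross(mat[0], mat[1])
            if np.linalg.norm(residual) < 1e-12:
                raise ValidationError("two stain vectors are collinear")
            mat = np.vstack([mat, residual / np.linalg.norm(residual)])
            self.stain_names = (*self.stain_names, "residual")
        if abs(np.linalg.det(mat)) < 1e-12:
            raise ValidationError("stain vector matrix is singular")
        self.vectors = mat


@dataclass
class ZonationProfile:
    """Binned and smoothed cohort expression curve for one marker."""

    marker: str
    bin_mids: np.ndarray
    case_means: pd.DataFrame  # index: case ids, columns: bin midpoints
    cohort_mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    smoothed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker,
                "bin_mid": self.bin_mids,
                "cohort_mean": self.cohort_mean,
                "ci_lo": self.ci_lower,
                "ci_hi": self.ci_upper,
                "smoothed": self.smoothed,
            }
        )


# ---------------------------------------------------------------------------
# zone construction


def build_zones(
    dr: Polygon,
    tumor: Polygon,
    pt_polygons: Sequence[Polygon] = (),
    necrosis: Sequence[Polygon] = (),
    expansion_um: float = 1500.0,
    necrosis_tc_threshold: float = 0.5,
) -> ZoneSet:
    """Build the PLP/DR/TC zone set of one case.

    PLP is the DR buffered outward by ``expansion_um`` minus the DR and the
    tumor.  TC is the tumor minus the DR.  Portal-tract polygons are
    subtracted from DR and PLP (a PT polygon outside DR∪PLP is ignored with a
    warning); necrosis polygons are subtracted from DR and PLP as well, and a
    necrosis area fraction of the TC above ``necrosis_tc_threshold`` flags the
    case's TC as excluded from quantification.
    """
    if dr.area <= 0:
        raise ValidationError("degenerate DR polygon (zero area)")
    if expansion_um <= 0:
        raise ValidationError("expansion_um must be positive")
    plp = dr.buffer(expansion_um).difference(dr).difference(tumor)
    tc = tumor.difference(dr)
    rim_region = unary_union([dr, plp])
    excluded = []
    for pt in pt_polygons:
        if pt.intersection(rim_region).area <= 0:
            logger.warning("portal-tract polygon outside DR and PLP; ignored")
            continue
        excluded.append(pt)
    necrosis_union = unary_union(list(necrosis)) if necrosis else None
    dr_clean = dr
    plp_clean = plp
    if excluded:
        cut = unary_union(excluded)
        dr_clean = dr_clean.difference(cut)
        plp_clean = plp_clean.difference(cut)
    tc_excluded = False
    if necrosis_union is not None:
        dr_clean = dr_clean.difference(necrosis_union)
        plp_clean = plp_clean.difference(necrosis_union)
        if tc.area > 0:
            tc_excluded = necrosis_union.intersection(tc).area / tc.area > necrosis_tc_threshold
    return ZoneSet(dr=dr_clean, plp=plp_clean, tc=tc,
                   expansion_um=expansion_um, tc_excluded=tc_excluded)


# ---------------------------------------------------------------------------
# tiling and distances


def tile_zone(zone: Polygon, tile_um: float = TILE_UM) -> list[Tile]:
    """Divide a zone polygon into axis-aligned square tiles.

    The grid is anchored at the coordinate origin (multiples of ``tile_um``);
    a tile belongs to the zone iff its centroid lies inside the polygon, with
    the boundary counting as inside.  Distances are filled in later.
    """
    if zone.is_empty or zone.area <= 0:
        return []
    minx, miny, maxx, maxy = zone.bounds
    ix = np.arange(np.floor(minx / tile_um), np.ceil(maxx / tile_um) + 1)
    iy = np.arange(np.floor(miny / tile_um), np.ceil(maxy / tile_um) + 1)
    gx, gy = np.meshgrid((ix + 0.5) * tile_um, (iy + 0.5) * tile_um)
    gx, gy = gx.ravel(), gy.ravel()
    inside = shapely.intersects_xy(zone, gx, gy)  # boundary-inclusive
    return [
        Tile(centroid=(float(x), float(y)), zone="", raw_distance=float("nan"),
             size=tile_um)
        for x, y in zip(gx[inside], gy[inside])
    ]


def standardize_distance(
    raw_distance: float | np.ndarray,
    max_distance_in_zone: float,
    zone: Literal["PLP", "DR", "TC"],
) -> float | np.ndarray:
    """Map a raw tile distance onto the signed standardized-distance axis.

    s = 100·raw/max; PLP → +s, DR → −s, TC → −100 − s.  Raw distances
    slightly above the per-zone maximum are clamped with a warning.
    """
    if max_distance_in_zone <= 0:
        raise ValidationError("max_distance_in_zone must be positive")
    raw = np.asarray(raw_distance, dtype=float)
    if np.any(raw < 0):
        raise ValidationError("raw distances must be non-negative")
    if np.any(raw > max_distance_in_zone):
        logger.warning("raw distance exceeds zone maximum; clamped")
        raw = np.minimum(raw, max_distance_in_zone)
    # guard the closed end of the range against floating rounding above 100
    s = np.minimum(100.0 * raw / max_distance_in_zone, 100.0)
    if zone == "PLP":
        out = s
    elif zone == "DR":
        out = -s
    elif zone == "TC":
        out = -100.0 - s
    else:
        raise ValidationError(f"unknown zone {zone!r}")
    return out if out.ndim else float(out)


def measure_tiles(
    zones: ZoneSet,
    liver_rim_border: LineString | np.ndarray,
    rim_tumor_border: LineString | np.ndarray,
    tile_um: float = TILE_UM,
) -> list[Tile]:
    """Tile all zones of a case and assign raw + standardized distances.

    PLP and DR tiles measure the minimal distance from their centroid to the
    liver–tumor interface (liver-rim border); TC tiles measure it to the DR's
    inner (rim–tumor) border.  The normalization maximum is the per-zone
    maximum raw tile distance of this case.  A TC flagged for extensive
    necrosis yields no TC tiles.
    """
    liver = LineString(liver_rim_border) if not isinstance(liver_rim_border, LineString) else liver_rim_border
    inner = LineString(rim_tumor_border) if not isinstance(rim_tumor_border, LineString) else rim_tumor_border
    out: list[Tile] = []
    for zone_name, polygon, ref in (
        ("PLP", zones.plp, liver),
        ("DR", zones.dr, liver),
        ("TC", None if zones.tc_excluded else zones.tc, inner),
    ):
        if polygon is None or polygon.is_empty:
            continue
        tiles = tile_zone(polygon, tile_um)
        if not tiles:
            continue
        points = shapely.points([t.centroid for t in tiles])
        # a centroid exactly on the reference border would land on the closed
        # end of the zone's half-open range; nudge it inward by a nanometer
        raw = np.maximum(shapely.distance(points, ref), 1e-3)
        # tiles whose centroid sits exactly on the reference border get raw 0;
        # strictly positive maximum is guaranteed for any 2-D zone
        max_raw = float(raw.max())
        if max_raw <= 0:
            continue
        std = standardize_distance(raw, max_raw, zone_name)
        # keep the zero-distance tile out of the open end of the DR/TC ranges
        for tile, r, s in zip(tiles, raw, std):
            tile.zone = zone_name
            tile.raw_distance = float(r)
            tile.standardized_distance = float(s)
            out.append(tile)
    return out


def tiles_to_frame(tiles: Sequence[Tile]) -> pd.DataFrame:
    """Flatten tiles to a DataFrame (one row per tile, markers as columns)."""
    records = []
    for t in tiles:
        rec = {
            "x": t.centroid[0],
            "y": t.centroid[1],
            "zone": t.zone,
            "raw_distance": t.raw_distance,
            "standardized_distance": t.standardized_distance,
        }
        rec.update(t.intensities)
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# binning, averaging, smoothing


def rolling_smooth(values: np.ndarray, window: int = 5, center: bool = True) -> np.ndarray:
    """Rolling mean that shrinks at the edges and skips missing bins."""
    s = pd.Series(values)
    return s.rolling(window=window, center=center, min_periods=1).mean().to_numpy()


def bin_and_average(
    tiles_per_case: Mapping[str, pd.DataFrame | Sequence[Tile]],
    markers: Sequence[str],
    ci_method: Literal["t", "normal"] = "t",
    window: int = 5,
    center: bool = True,
) -> dict[str, ZonationProfile]:
    """Binned, cohort-averaged and smoothed zonation profiles per marker.

    For each case, tile intensities are averaged inside 5%-wide standardized-
    distance bins spanning [−200, 100].  The cohort curve is the mean of case
    means per bin with a 95% CI (t-based across cases by default), smoothed
    with a centered rolling window of 5 bins that shrinks at the edges.
    Empty bins propagate as missing values, not zeros.
    """
    if not tiles_per_case:
        raise ValidationError("no cases supplied")
    frames = {
        case: (tiles_to_frame(v) if not isinstance(v, pd.DataFrame) else v)
        for case, v in tiles_per_case.items()
    }
    profiles: dict[str, ZonationProfile] = {}
    for marker in markers:
        rows = {}
        for case, frame in frames.items():
            if marker not in frame.columns:
                raise ValidationError(f"case {case!r} has no intensities for marker {marker!r}")
            sub = frame.dropna(subset=[marker])
            binned = sub.groupby(
                pd.cut(sub["standardized_distance"], BIN_EDGES, right=True),
                observed=False,
            )[marker].mean()
            rows[case] = binned.to_numpy()
        case_means = pd.DataFrame.from_dict(rows, orient="index", columns=BIN_MIDS)
        mean = case_means.mean(axis=0, skipna=True).to_numpy()
        n = case_means.notna().sum(axis=0).to_numpy().astype(float)
        sd = case_means.std(axis=0, ddof=1, skipna=True).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            sem = sd / np.sqrt(n)
            if ci_method == "t":
                crit = np.where(n > 1, stats.t.ppf(0.975, np.maximum(n - 1, 1)), np.nan)
            else:
                crit = np.full_like(n, stats.norm.ppf(0.975))
            half = crit * sem
        ci_lo = np.where(n > 1, mean - half, mean)
        ci_hi = np.where(n > 1, mean + half, mean)
        profiles[marker] = ZonationProfile(
            marker=marker,
            bin_mids=BIN_MIDS.copy(),
            case_means=case_means,
            cohort_mean=mean,
            ci_lower=ci_lo,
            ci_upper=ci_hi,
            smoothed=rolling_smooth(mean, window=window, center=center),
        )
    return profiles


# ---------------------------------------------------------------------------
# intensity corrections


def color_deconvolve(rgb_mean: Sequence[float], vectors: StainVectors) -> np.ndarray:
    """Unmix mean RGB transmittances into per-stain optical densities.

    OD = −log10(transmittance) per channel; the stain amounts solve
    OD = Vᵀ·a for the unit stain-vector matrix V.  Negative amounts are
    clamped to 0 with a warning (they arise from noise outside the stain
    simplex).
    """
    rgb = np.asarray(rgb_mean, dtype=float)
    if rgb.shape != (3,) or np.any(rgb <= 0) or np.any(rgb > 1):
        raise ValidationError("rgb_mean must be three transmittances in (0, 1]")
    od = -np.log10(rgb)
    amounts = np.linalg.solve(vectors.vectors.T, od)
    if np.any(amounts < -1e-12):
        logger.warning("negative stain amounts clamped to 0")
    return np.maximum(amounts, 0.0)


def subtract_autofluorescence(signal: np.ndarray, af_channel: np.ndarray) -> np.ndarray:
    """Autofluorescence correction: max(signal − AF, 0), elementwise."""
    sig = np.asarray(signal, dtype=float)
    af = np.asarray(af_channel, dtype=float)
    if sig.shape != af.shape:
        raise ValidationError("signal and autofluorescence shapes differ")
    return np.maximum(sig - af, 0.0)
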