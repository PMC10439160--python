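"""Domain types for whole-slide annotations and a GeoJSON interchange format.

Annotations live in planar micrometer coordinates, origin at the slide's
top-left corner, with y increasing downward (image convention).  The
interchange format is a GeoJSON FeatureCollection (RFC 7946) in which every
feature carries ``properties.role`` ∈ {``interface``, ``zone``, ``pin``,
``border``}, a ``label``, a ``slide_id`` and optionally a ``patient_id``:

* ``interface`` — LineString along the tumor–liver interface, labeled with a
  growth pattern (``encapsulated``, ``replacement``, ``pushing``; replacement
  subtypes 1/2 are accepted on input and merged to ``replacement``).
* ``zone`` — Polygon labeled ``DR`` (desmoplastic rim), ``PLP`` (perimetastatic
  liver parenchyma), ``TC`` (tumor center), ``PT`` (portal tract) or
  ``necrosis``.
* ``pin`` — Point marking a portal-tract remnant, labeled ``A`` (isolated
  artery) or ``A_BD`` (artery plus bile duct).
* ``border`` — LineString naming one of the two rim interfaces:
  ``liver_rim_interface`` (outer) or ``rim_tumor_interface`` (inner).

Reading is strict: every feature is either mapped to exactly one domain type
or rejected with an error naming the feature; silent drops are forbidden.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from capsulezone.errors import AnnotationParseError, ValidationError

logger = logging.getLogger(__name__)

PATTERN_LABELS = ("encapsulated", "replacement", "pushing")
ZONE_LABELS = ("DR", "PLP", "TC", "PT", "necrosis")
PIN_SUBTYPES = ("A", "A_BD")
BORDER_NAMES = ("liver_rim_interface", "rim_tumor_interface")

# replacement subtypes are merged on load, following consensus scoring
# guidelines under which types 1 and 2 are not reproducibly distinguished
_REPLACEMENT_ALIASES = {
    "replacement type 1": "replacement",
    "replacement type 2": "replacement",
    "replacement_1": "replacement",
    "replacement_2": "replacement",
    "replacement1": "replacement",
    "replacement2": "replacement",
}


def _canonical_pattern(label: str) -> str:
    key = label.strip().lower()
    key = _REPLACEMENT_ALIASES.get(key, key)
    if key == "desmoplastic":
        key = "encapsulated"
    if key not in PATTERN_LABELS:
        raise ValidationError(f"unknown growth-pattern label: {label!r}")
    return key


def _dedupe_vertices(vertices: np.ndarray) -> np.ndarray:
    """Collapse consecutive duplicate vertices (zero-length segments)."""
    if len(vertices) < 2:
        return vertices
    keep = np.ones(len(vertices), dtype=bool)
    keep[1:] = np.any(np.diff(vertices, axis=0) != 0.0, axis=1)
    return vertices[keep]


def polyline_length(vertices: Sequence[Sequence[float]]) -> float:
    """Total Euclidean length of a polyline, in the units of its coordinates.

    Parameters
    ----------
    vertices
        Ordered (x, y) coordinates; at least two are required.

    Returns
    -------
    float
        Sum of per-segment Euclidean lengths (non-negative).
    """
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValidationError("a polyline needs at least two (x, y) vertices")
    if not np.isfinite(arr).all():
        raise ValidationError("polyline contains non-finite coordinates")
    return float(np.sum(np.hypot(*np.diff(arr, axis=0).T)))


@dataclass
class InterfaceSegment:
    """One annotated stretch of the tumor–liver interface.

    ``pattern_label`` is the growth pattern of the stretch; its polyline
    length is the weight used by the scoring formula.
    """

    vertices: np.ndarray
    pattern_label: str
    slide_id: str

    def __post_init__(self) -> None:
        self.vertices = _dedupe_vertices(np.asarray(self.vertices, dtype=float))
        self.pattern_label = _canonical_pattern(self.pattern_label)
        if self.vertices.ndim != 2 or len(self.vertices) < 2:
            raise ValidationError(
                f"interface segment on slide {self.slide_id!r} needs >=2 distinct vertices"
            )
        if not np.isfinite(self.vertices).all():
            raise ValidationError("interface segment has non-finite coordinates")
        if self.length <= 0:
            raise ValidationError("interface segment has zero length")

    @property
    def length(self) -> float:
        return polyline_length(self.vertices)


@dataclass
class ZonePolygon:
    """A labeled region polygon (rim, parenchyma band, tumor center, ...)."""

    rings: list[np.ndarray]  # outer ring first, then holes
    zone_label: str
    slide_id: str

    def __post_init__(self) -> None:
        if self.zone_label not in ZONE_LABELS:
            raise ValidationError(f"unknown zone label: {self.zone_label!r}")
        self.rings = [np.asarray(r, dtype=float) for r in self.rings]
        poly = self.to_shapely()
        if not poly.is_valid:
            raise ValidationError(
                f"zone {self.zone_label!r} on slide {self.slide_id!r} is not a valid polygon"
            )
        if poly.area <= 0:
            raise ValidationError(f"zone {self.zone_label!r} has zero area")

    def to_shapely(self):
        from shapely.geometry import Polygon

        return Polygon(self.rings[0], self.rings[1:])

    @property
    def area(self) -> float:
        return float(self.to_shapely().area)


@dataclass
class PortalTractPin:
    """Point annotation of a portal-tract remnant in or near the rim."""

    position: np.ndarray
    subtype: str
    slide_id: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(2)
        if not np.isfinite(self.position).all():
            raise ValidationError("pin position must be finite")
        sub = self.subtype.strip().replace("+", "_").replace(" ", "")
        sub = {"A_B": "A_BD", "ABD": "A_BD", "A_BD": "A_BD", "A": "A"}.get(sub, sub)
        if sub not in PIN_SUBTYPES:
            raise ValidationError(f"unknown pin subtype: {self.subtype!r}")
        self.subtype = sub


@dataclass
class SlideAnnotationSet:
    """All annotations of one slide, in micrometer coordinates."""

    slide_id: str
    patient_id: str = ""
    microns_per_unit: float = 1.0
    interface_segments: list[InterfaceSegment] = field(default_factory=list)
    zones: list[ZonePolygon] = field(default_factory=list)
    pins: list[PortalTractPin] = field(default_factory=list)
    interface_border_polylines: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.microns_per_unit <= 0:
            raise ValidationError("microns_per_unit must be positive")
        for member in (*self.interface_segments, *self.zones, *self.pins):
            if member.slide_id != self.slide_id:
                raise ValidationError(
                    f"member slide_id {member.slide_id!r} != set slide_id {self.slide_id!r}"
                )
        for name in self.interface_border_polylines:
            if name not in BORDER_NAMES:
                raise ValidationError(f"unknown border polyline name: {name!r}")
        if len(self.interface_border_polylines) == 2:
            a, b = (self.interface_border_polylines[n] for n in BORDER_NAMES)
            if a.shape == b.shape and np.allclose(a, b):
                raise ValidationError("the two rim border polylines must be distinct")

    def zones_by_label(self, label: str) -> list[ZonePolygon]:
        return [z for z in self.zones if z.zone_label == label]


# ---------------------------------------------------------------------------
# GeoJSON interchange


def _coords(geometry: dict, expected_type: str, where: str) -> np.ndarray:
    if geometry.get("type") != expected_type:
        raise AnnotationParseError(
            f"{where}: expected {expected_type}, got {geometry.get('type')!r}"
        )
    return np.asarray(geometry["coordinates"], dtype=float)


def read_annotations(path: str | Path, scale: float = 1.0) -> SlideAnnotationSet:
    """Read a slide's annotations from the GeoJSON interchange format.

    Parameters
    ----------
    path
        GeoJSON FeatureCollection following the documented schema.
    scale
        Micrometers per coordinate unit; all coordinates are multiplied by it
        so the returned set is in µm.
    """
    if scale <= 0 or not math.isfinite(scale):
        raise ValidationError("scale must be a positive finite µm-per-unit factor")
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(f"{path}: malformed JSON ({exc})") from exc
    if doc.get("type") != "FeatureCollection":
        raise AnnotationParseError(f"{path}: not a GeoJSON FeatureCollection")

    slide_id: str | None = doc.get("slide_id")
    patient_id: str = doc.get("patient_id", "")
    segments: list[InterfaceSegment] = []
    zones: list[ZonePolygon] = []
    pins: list[PortalTractPin] = []
    borders: dict[str, np.ndarray] = {}
    seen_interfaces: set[bytes] = set()

    for i, feature in enumerate(doc.get("features", [])):
        where = f"{path} feature #{i}"
        props = feature.get("properties") or {}
        role = props.get("role")
        label = props.get("label")
        fid = props.get("slide_id")
        if fid is None:
            raise ValidationError(f"{where}: missing slide_id property")
        if slide_id is None:
            slide_id = fid
        patient_id = patient_id or props.get("patient_id", "")
        geom = feature.get("geometry") or {}

        if role == "interface":
            verts = _coords(geom, "LineString", where) * scale
            seg = InterfaceSegment(verts, label, fid)
            key = seg.vertices.tobytes()
            if key in seen_interfaces:
                # the source protocol does not say how duplicated interface
                # annotations were handled; they are preserved and flagged
                logger.warning("%s: duplicate interface geometry preserved", where)
            seen_interfaces.add(key)
            segments.append(seg)
        elif role == "zone":
            rings = _coords(geom, "Polygon", where)
            zones.append(ZonePolygon([np.asarray(r) * scale for r in rings], label, fid))
        elif role == "pin":
            pos = _coords(geom, "Point", where) * scale
            pins.append(PortalTractPin(pos, label, fid))
        elif role == "border":
            if label not in BORDER_NAMES:
                raise ValidationError(f"{where}: unknown border name {label!r}")
            borders[label] = _coords(geom, "LineString", where) * scale
        else:
            raise ValidationError(f"{where}: unknown role {role!r}")

    if slide_id is None:
        raise ValidationError(f"{path}: empty collection without a slide_id header")
    return SlideAnnotationSet(
        slide_id=slide_id,
        patient_id=patient_id,
        microns_per_unit=1.0,  # coordinates already scaled to µm
        interface_segments=segments,
        zones=zones,
        pins=pins,
        interface_border_polylines=borders,
    )


def _feature(role: str, label: str, slide_id: str, patient_id: str, geometry: dict) -> dict:
    return {
        "type": "Feature",
        "properties": {
            "role": role,
            "label": label,
            "slide_id": slide_id,
            "patient_id": patient_id,
        },
        "geometry": geometry,
    }


def write_annotations(annotation_set: SlideAnnotationSet, path: str | Path) -> None:
    """Write a slide annotation set as GeoJSON (coordinates in µm, scale 1).

    Feature order is deterministic: interfaces, zones, pins, borders, each in
    insertion order (borders by name), so identical sets produce identical
    bytes.
    """
    s = annotation_set
    features: list[dict] = []
    for seg in s.interface_segments:
        features.append(
            _feature("interface", seg.pattern_label, seg.slide_id, s.patient_id,
                     {"type": "LineString", "coordinates": seg.vertices.tolist()})
        )
    for zone in s.zones:
        features.append(
            _feature("zone", zone.zone_label, zone.slide_id, s.patient_id,
                     {"type": "Polygon", "coordinates": [r.tolist() for r in zone.rings]})
        )
    for pin in s.pins:
        features.append(
            _feature("pin", pin.subtype, pin.slide_id, s.patient_id,
                     {"type": "Point", "coordinates": pin.position.tolist()})
        )
    for name in BORDER_NAMES:
        if name in s.interface_border_polylines:
            features.append(
                _feature("border", name, s.slide_id, s.patient_id,
                         {"type": "LineString",
                          "coordinates": np.asarray(
                              s.interface_border_polylines[name]).tolist()})
            )
    doc = {
        "type": "FeatureCollection",
        "slide_id": s.slide_id,
        "patient_id": s.patient_id,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=None, separators=(",", ":"), sort_keys=True)
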