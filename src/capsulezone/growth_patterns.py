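"""Length-weighted growth-pattern scoring and related cohort statistics.

The percentage of each growth pattern on a slide is the total annotated
interface length of that pattern divided by the total annotated interface
length on the slide, times 100.  Patient- or tumor-level percentages pool
raw lengths across slides (never averages of percentages).  Strata follow
the encapsulation cut-offs <33% / 33–<100% / 100% and the complementary
replacement cut-offs 0% / >0–<66% / 66–100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from capsulezone.annotations_io import PATTERN_LABELS, SlideAnnotationSet
from capsulezone.errors import NoInterfaceError, ValidationError

logger = logging.getLogger(__name__)

#: tie-break order for the predominant pattern: prognostically worse first,
#: so exact ties classify conservatively. Configurable via classify_predominant.
DEFAULT_TIE_ORDER = ("replacement", "pushing", "encapsulated")


@dataclass
class PatternFractions:
    """Per-unit (slide, tumor or patient) growth-pattern percentages."""

    unit_id: str
    percent_encapsulated: float
    percent_replacement: float
    percent_pushing: float
    total_interface_length: float
    predominant: str = "indeterminate"
    viable_tumor_percent: float | None = None

    def __post_init__(self) -> None:
        pcts = self.as_dict()
        for name, value in pcts.items():
            if not 0.0 <= value <= 100.0 + 1e-9:
                raise ValidationError(f"{name} out of [0, 100]: {value}")
        if self.total_interface_length > 0:
            total = sum(pcts.values())
            if abs(total - 100.0) > 1e-6:
                raise ValidationError(f"percentages sum to {total}, not 100")

    def as_dict(self) -> dict[str, float]:
        return {
            "encapsulated": self.percent_encapsulated,
            "replacement": self.percent_replacement,
            "pushing": self.percent_pushing,
        }


@dataclass(frozen=True)
class StrataLabel:
    """Encapsulation and replacement strata of one unit."""

    encapsulation_stratum: Literal["low", "medium", "high"]
    replacement_stratum: Literal["none", "mid", "high"]


def score_slide(annotation_set: SlideAnnotationSet) -> PatternFractions:
    """Score one slide from its labeled interface polylines.

    Each pattern's percentage is 100 × (sum of lengths of segments with that
    label) / (sum of all interface segment lengths).

    Raises
    ------
    NoInterfaceError
        If the slide carries no interface segments (it is excluded upstream).
    """
    segments = annotation_set.interface_segments
    if not segments:
        raise NoInterfaceError(f"slide {annotation_set.slide_id!r} has no interface")
    lengths = {p: 0.0 for p in PATTERN_LABELS}
    for seg in segments:
        lengths[seg.pattern_label] += seg.length
    total = sum(lengths.values())
    if total <= 0:
        raise NoInterfaceError(f"slide {annotation_set.slide_id!r} has zero interface length")
    fractions = PatternFractions(
        unit_id=annotation_set.slide_id,
        percent_encapsulated=100.0 * lengths["encapsulated"] / total,
        percent_replacement=100.0 * lengths["replacement"] / total,
        percent_pushing=100.0 * lengths["pushing"] / total,
        total_interface_length=total,
    )
    fractions.predominant = classify_predominant(fractions)
    return fractions


def aggregate(units: Sequence[PatternFractions], unit_id: str = "pooled") -> PatternFractions:
    """Pool slide-level fractions to a tumor or patient by summed length.

    The pooled percentage for a pattern is the sum over slides of that
    pattern's annotated length divided by the total annotated length across
    all slides — a length-weighted pooling, not a mean of percentages.
    Viability, where present, is pooled by the same length weights.
    """
    units = [u for u in units if u.total_interface_length > 0]
    if not units:
        raise ValidationError("no units with positive interface length to aggregate")
    total = sum(u.total_interface_length for u in units)
    pooled = {
        p: sum(u.as_dict()[p] / 100.0 * u.total_interface_length for u in units) / total * 100.0
        for p in PATTERN_LABELS
    }
    viable = [
        (u.viable_tumor_percent, u.total_interface_length)
        for u in units if u.viable_tumor_percent is not None
    ]
    viable_pooled = (
        sum(v * w for v, w in viable) / sum(w for _, w in viable) if viable else None
    )
    fractions = PatternFractions(
        unit_id=unit_id,
        percent_encapsulated=pooled["encapsulated"],
        percent_replacement=pooled["replacement"],
        percent_pushing=pooled["pushing"],
        total_interface_length=total,
        viable_tumor_percent=viable_pooled,
    )
    fractions.predominant = classify_predominant(fractions)
    return fractions


def classify_predominant(
    fractions: PatternFractions,
    tie_order: Sequence[str] = DEFAULT_TIE_ORDER,
) -> str:
    """Pattern with the largest length-weighted share.

    Exact ties resolve by ``tie_order`` (default: replacement > pushing >
    encapsulated, i.e. toward the prognostically worse pattern).
    """
    if fractions.total_interface_length <= 0:
        return "indeterminate"
    pcts = fractions.as_dict()
    best = max(pcts.values())
    for pattern in tie_order:
        if pcts[pattern] == best:
            return pattern
    raise ValidationError(f"tie_order {tie_order!r} does not cover all patterns")


def assign_strata(fractions: PatternFractions) -> StrataLabel:
    """Encapsulation stratum (<33 low, 33–<100 medium, 100 high) and the
    complementary replacement stratum (0 none, >0–<66 mid, 66–100 high)."""
    enc = fractions.percent_encapsulated
    repl = fractions.percent_replacement
    if enc >= 100.0 - 1e-12:
        enc_stratum = "high"
    elif enc >= 33.0:
        enc_stratum = "medium"
    else:
        enc_stratum = "low"
    if repl <= 0.0:
        repl_stratum = "none"
    elif repl < 66.0:
        repl_stratum = "mid"
    else:
        repl_stratum = "high"
    return StrataLabel(enc_stratum, repl_stratum)


def exclude_complete_regression(
    patients: Iterable[tuple[str, Sequence[PatternFractions]]],
) -> list[tuple[str, list[PatternFractions]]]:
    """Drop patients whose every slide shows 0% viable tumor.

    Tumors with complete pathological regression carry no scorable interface
    biology; they are excluded from growth-pattern scoring (the caller keeps
    them for clinical tables).  Patients with missing viability on any slide
    are flagged in the log but retained.
    """
    kept: list[tuple[str, list[PatternFractions]]] = []
    for patient_id, slides in patients:
        slides = list(slides)
        viable = [s.viable_tumor_percent for s in slides]
        if any(v is None for v in viable):
            logger.warning("patient %s: missing viability on some slides; retained", patient_id)
            kept.append((patient_id, slides))
        elif all(v == 0.0 for v in viable):
            logger.info("patient %s: complete regression, excluded from scoring", patient_id)
        else:
            kept.append((patient_id, slides))
    return kept


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Unweighted Cohen's kappa between two categorical raters.

    κ = (p_o − p_e) / (1 − p_e), with p_o the observed agreement and p_e the
    chance agreement from the product of the raters' marginal frequencies.
    When both raters are constant and identical (p_e = 1), κ is defined as 1.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("rating vectors must be 1-D and equal length")
    n = len(a)
    if n < 2:
        raise ValidationError("need at least two rated items")
    categories = np.union1d(a, b)
    p_o = float(np.mean(a == b))
    p_e = float(
        sum(np.mean(a == c) * np.mean(b == c) for c in categories)
    )
    if p_e >= 1.0 - 1e-15:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def correlate_viability(
    encapsulation_percents: Sequence[float],
    viable_percents: Sequence[float],
    method: Literal["spearman", "pearson"] = "spearman",
) -> tuple[float, float]:
    """Correlation between encapsulation and viable-tumor percentages.

    Returns (r, two-sided p). Spearman (rank) is the default, matching the
    human-cohort analysis; Pearson matches the mouse analysis.
    """
    x = np.asarray(encapsulation_percents, dtype=float)
    y = np.asarray(viable_percents, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need >=3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    if method == "spearman":
        res = stats.spearmanr(x, y)
    elif method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
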