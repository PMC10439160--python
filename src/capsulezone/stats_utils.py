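"""Shared small statistics: power calculation, group comparisons, summaries.

The sample-size calculation is the two-sample normal-approximation formula
for comparing two means with unequal standard deviations,

    n = ceil( (z_{1−α} + z_{power})² · (sd_a² + sd_b²/ratio) / (mean_a − mean_b)² ),

the design used to size the mouse growth-pattern experiments (e.g. means
95% vs 80% replacement, SDs 5% vs 15%, power 0.8, α 0.05 one-sided, ratio 1
give n = 7 per group).  α is one-sided by default; pass ``sided="two"`` to
use α/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from capsulezone.errors import ValidationError
from capsulezone.portal_tracts import wilcoxon_rank_sum


@dataclass
class PowerSpec:
    """Design parameters of the two-mean normal-approximation comparison."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    power: float = 0.8
    alpha: float = 0.05
    ratio: float = 1.0  # n_b / n_a allocation

    def __post_init__(self) -> None:
        if self.mean_a == self.mean_b:
            raise ValidationError("zero effect: means are equal")
        if self.sd_a <= 0 or self.sd_b <= 0:
            raise ValidationError("standard deviations must be positive")
        if not (0 < self.power < 1 and 0 < self.alpha < 1 and self.ratio > 0):
            raise ValidationError("power and alpha must be in (0,1), ratio > 0")


def sample_size_two_means(spec: PowerSpec, sided: Literal["one", "two"] = "one") -> int:
    """Per-group n for detecting the difference of two normal means.

    Normal-approximation formula with unpooled variances; the returned n is
    the smallest integer whose analytic power reaches the target.
    """
    alpha = spec.alpha if sided == "one" else spec.alpha / 2.0
    z_alpha = stats.norm.ppf(1.0 - alpha)
    z_power = stats.norm.ppf(spec.power)
    effect = spec.mean_a - spec.mean_b
    n = (z_alpha + z_power) ** 2 * (spec.sd_a**2 + spec.sd_b**2 / spec.ratio) / effect**2
    return max(int(math.ceil(n - 1e-12)), 1)


def power_two_means(spec: PowerSpec, n: int, sided: Literal["one", "two"] = "one") -> float:
    """Analytic power of the two-mean z-test at per-group size ``n``.

    Inverse of :func:`sample_size_two_means`; used as its independent check.
    """
    if n < 1:
        return 0.0
    alpha = spec.alpha if sided == "one" else spec.alpha / 2.0
    z_alpha = stats.norm.ppf(1.0 - alpha)
    se = math.sqrt(spec.sd_a**2 / n + spec.sd_b**2 / (n * spec.ratio))
    return float(stats.norm.cdf(abs(spec.mean_a - spec.mean_b) / se - z_alpha))


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and interquartile range bounds (Q1, Q3), the Box-and-Whisker
    summary numbers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("empty sample")
    return (
        float(np.median(v)),
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )


def compare_group_fractions(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Two-sided Wilcoxon comparison of two groups of percentages.

    Used e.g. for encapsulation % in chemotherapy-treated vs chemonaive
    patients.  Reports medians and IQRs per group alongside U and p.
    """
    u, p = wilcoxon_rank_sum(group_a, group_b)
    med_a, q1_a, q3_a = median_iqr(group_a)
    med_b, q1_b, q3_b = median_iqr(group_b)
    return {
        "n_a": len(group_a),
        "n_b": len(group_b),
        "median_a": med_a, "iqr_a": (q1_a, q3_a),
        "median_b": med_b, "iqr_b": (q1_b, q3_b),
        "U": u, "p": p,
    }


def augment_with_progressors(
    treated_fractions: Sequence[float],
    progressor_fractions: Sequence[float],
    naive_fractions: Sequence[float],
    add_fraction: float = 0.078,
    seed: int = 0,
) -> dict:
    """Selection-bias check: re-compare after adding hypothesized progressors.

    Patients whose resection was canceled because of progression under
    chemotherapy leave no histology; to bound the resulting selection bias the
    treated group is augmented so progressor-like patients make up
    ``add_fraction`` of it — round(add_fraction·n/(1−add_fraction)) patients
    sampled with replacement (seeded) from the progressor pool — and the
    treated-vs-naive comparison is re-run.
    """
    treated = np.asarray(treated_fractions, dtype=float)
    pool = np.asarray(progressor_fractions, dtype=float)
    if treated.size == 0 or np.asarray(naive_fractions).size == 0:
        raise ValidationError("treated and naive groups must be non-empty")
    if not 0 <= add_fraction < 1:
        raise ValidationError("add_fraction must be in [0, 1)")
    if add_fraction > 0 and pool.size == 0:
        raise ValidationError("empty progressor pool")
    n_add = int(round(add_fraction * treated.size / (1.0 - add_fraction)))
    rng = np.random.default_rng(seed)
    pseudo = rng.choice(pool, size=n_add, replace=True) if n_add else np.empty(0)
    augmented = np.concatenate([treated, pseudo])
    report = compare_group_fractions(augmented, naive_fractions)
    report["n_pseudo_added"] = n_add
    return report
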