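"""Per-group sample size for the mouse growth-pattern experiment.

Two-sample normal-approximation design: vehicle mice average 95% replacement
growth (SD 5%), treated mice 80% (SD 15%); power 0.8 at a one-sided 5%
type-I error with 1:1 allocation.
"""

from capsulezone import PowerSpec, sample_size_two_means
from capsulezone.stats_utils import power_two_means

spec = PowerSpec(mean_a=95, sd_a=5, mean_b=80, sd_b=15, power=0.8, alpha=0.05, ratio=1)
n = sample_size_two_means(spec, sided="one")
print(f"required mice per group: n = {n}")
print(f"analytic power at n = {n}: {power_two_means(spec, n):.3f}")
print(f"analytic power at n = {n - 1}: {power_two_means(spec, n - 1):.3f} (below target)")
print(f"two-sided design for comparison: n = {sample_size_two_means(spec, sided='two')}")
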