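"""Statistical power for two-sample MR with a binary outcome.

The calculation follows the standard non-centrality normal
approximation used by the mRnd calculator: with an outcome GWAS of n
individuals, case fraction K, instruments explaining R²_xz of the
exposure variance and a hypothesized odds ratio OR per SD of exposure,
the non-centrality is

    μ = |ln OR| · √(n · R²_xz · K(1−K))

and the two-sided power at level α is Φ(−z_{1−α/2} + μ) + Φ(−z_{1−α/2} − μ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerParams", "mr_power_binary"]


@dataclass(frozen=True)
class PowerParams:
    """Inputs to the binary-outcome MR power calculation.

    n: outcome GWAS sample size (cases + controls);
    case_fraction: K, proportion of cases, in (0,1);
    r2_xz: variance of the exposure explained by the instruments, in (0,1);
    true_or: hypothesized odds ratio per SD of exposure;
    alpha: two-sided significance level.
    """

    n: float
    case_fraction: float
    r2_xz: float
    true_or: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")
        if not (0 < self.r2_xz < 1):
            raise ValueError("r2_xz must lie in (0, 1)")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def mr_power_binary(params: PowerParams) -> float:
    """Two-sided power; equals alpha at OR = 1 and is monotone in n,
    r2_xz and |ln OR|."""
    k = params.case_fraction
    mu = abs(math.log(params.true_or)) * math.sqrt(params.n * params.r2_xz * k * (1 - k))
    z = stats.norm.ppf(1 - params.alpha / 2)
    return float(stats.norm.cdf(-z + mu) + stats.norm.cdf(-z - mu))
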