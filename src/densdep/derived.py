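"""Management quantities derived from fitted growth rates.

If the protected population grows at λ_protected = exp(−M) (M the natural
mortality rate, assumed equal inside and outside) and the fished one at
λ_unprotected = exp(−Z) with Z = M + F, the fishing mortality rate is

    F = ln(λ_protected / λ_unprotected)   [year⁻¹]

and the fraction of the population removed by fishing each year is
1 − exp(−F).  M and Z are not separately estimable from the two growth
rates; only F is computed.  This is an upper-bound attribution: it ascribes
the whole growth-rate gap to fishing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["MortalityPartition", "fishing_mortality", "removal_fraction"]


@dataclass(frozen=True)
class MortalityPartition:
    """Fishing-mortality attribution between a protected and a fished site.

    ``net_subsidy`` flags a negative F (the "unprotected" population grows
    faster — a net subsidy rather than a removal).
    """

    lambda_protected: float
    lambda_unprotected: float
    F: float
    removal_fraction: float
    net_subsidy: bool


def removal_fraction(F: float) -> float:
    """Annual removal fraction 1 − exp(−F); in [0, 1) for F ≥ 0."""
    return 1.0 - math.exp(-F)


def fishing_mortality(lambda_protected: float, lambda_unprotected: float) -> MortalityPartition:
    """F = ln(λ_protected/λ_unprotected) and the implied annual removal.

    Both growth rates must be positive.  A negative F is returned as-is
    with ``net_subsidy=True`` rather than clipped.
    """
    if lambda_protected <= 0 or lambda_unprotected <= 0:
        raise ValueError("finite growth rates must be positive")
    F = math.log(lambda_protected / lambda_unprotected)
    return MortalityPartition(
        lambda_protected=float(lambda_protected),
        lambda_unprotected=float(lambda_unprotected),
        F=F,
        removal_fraction=removal_fraction(F),
        net_subsidy=F < 0,
    )
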