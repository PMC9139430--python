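"""Dose-unit conversions: EQD2 and isodose-percent to absolute dose.

EQD2 converts a fractionation scheme (total dose D delivered in fractions of
d Gy) to the biologically equivalent dose in 2 Gy fractions under the
linear-quadratic model:

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)

Alpha/beta defaults to 10 Gy, the conventional tumor value; organs at risk
use lower values and can pass their own.

Rounding to one decimal is a *formatting* concern: computation is exact and
`round_dose` is applied only when printing report values.
"""

from __future__ import annotations

from typing import Union

from .types import FractionationScheme

SchemeLike = Union[FractionationScheme, None]


def eqd2(
    total_dose: float,
    dose_per_fraction: float,
    alpha_beta: float = 10.0,
) -> float:
    """Equivalent dose in 2 Gy fractions (Gy).

    For the reference fractionation (d = 2 Gy) EQD2 equals the physical dose
    regardless of alpha/beta.
    """
    scheme = FractionationScheme(total_dose, dose_per_fraction, alpha_beta)
    return scheme.total_dose * (scheme.dose_per_fraction + scheme.alpha_beta) / (
        2.0 + scheme.alpha_beta
    )


def eqd2_scheme(scheme: FractionationScheme) -> float:
    return eqd2(scheme.total_dose, scheme.dose_per_fraction, scheme.alpha_beta)


def isodose_to_gy(level_pct: float, prescription_gy: float) -> float:
    """Absolute dose (Gy) corresponding to an isodose level in % of prescription."""
    if level_pct < 0:
        raise ValueError(f"isodose level must be >= 0, got {level_pct}")
    if prescription_gy <= 0:
        raise ValueError(f"prescription must be > 0, got {prescription_gy}")
    return level_pct / 100.0 * prescription_gy


def round_dose(dose_gy: float, decimals: int = 1) -> float:
    """Report-level rounding (0.1 Gy by default); never used inside computations."""
    return float(round(dose_gy, decimals))
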