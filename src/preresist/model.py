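"""Closed-form probability that a tumor harbors pre-existing resistant cells.

The model follows the Luria-Delbruck logic applied to a growing tumor: during
expansion to its detected size, every cell division carries a small probability
``u`` of producing a daughter with a resistance-conferring point mutation.
Cells divide at rate ``l`` and die at rate ``d``; a fraction ``a`` of divisions
are symmetric-differentiating (both daughters leave the self-renewing pool) and
a fraction ``b`` asymmetric (one daughter leaves).  For a self-renewing
population of size ``M`` the probability that at least one resistant lineage is
present is

    P_R = 1 - exp(-u * M * F),

where the effective division factor

    F = (1 - a/2 - b)/(1 - a - b)
        * l*(1 - a - b) / (d + l*b)
        * ln[ l*(1 - a - b) / (l*(1 - a - 2b) - d) ]

converts population size into expected mutation opportunities.  F -> 1 in the
pure-birth limit (a = b = d = 0), recovering 1 - exp(-u*M).

Tumor size is converted from diameter assuming a sphere at a fixed cell
density, discounted by tumor purity (the non-tumor stromal admixture) and by
the fraction of cells with self-renewal capacity (for GIST, modeled on
interstitial-cells-of-Cajal progenitors, 6.2e-3 of all cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

__all__ = [
    "ParameterError",
    "ModelParameters",
    "TumorGeometry",
    "ResistanceEstimate",
    "total_cells",
    "stem_cells",
    "effective_division_factor",
    "prob_preexisting_resistance",
    "expected_resistant_fraction",
    "estimate_for_diameter",
    "prob_double_resistance",
    "diameter_for_probability",
    "combine_lesion_probabilities",
    "DEFAULT_MUTATION_RATE_PER_BASE",
    "DEFAULT_N_RESISTANCE_POSITIONS",
]

#: Somatic point mutation rate per base per cell division (conservative end
#: of the 1e-9 .. 1e-8 literature range).
DEFAULT_MUTATION_RATE_PER_BASE = 1e-9

#: Number of distinct point mutations known to confer imatinib resistance
#: (a conservative lower bound; the catalogued number is larger).
DEFAULT_N_RESISTANCE_POSITIONS = 10


class ParameterError(ValueError):
    """A model parameter or geometry value violates its domain constraint."""


@dataclass(frozen=True)
class ModelParameters:
    """Evolutionary-dynamics parameters of the growing cell population.

    Parameters
    ----------
    u : float
        Probability that a division produces a resistant daughter
        (dimensionless, per division).  Default 1e-8 = per-base rate 1e-9
        times 10 resistance-conferring positions.
    l : float
        Cell birth rate, per unit time.  Results depend only on rate ratios,
        so the time unit is arbitrary.
    d : float
        Cell death rate, per unit time.
    a : float
        Probability of a symmetric differentiating division.
    b : float
        Probability of an asymmetric division.
    limit_threshold : float
        When (d + l*b) < limit_threshold * l the effective division factor is
        evaluated by its analytic limit instead of the raw expression, which
        would suffer catastrophic cancellation (0/0 of a vanishing logarithm).
    """

    u: float = DEFAULT_MUTATION_RATE_PER_BASE * DEFAULT_N_RESISTANCE_POSITIONS
    l: float = 1.0
    d: float = 0.0
    a: float = 0.0
    b: float = 0.0
    limit_threshold: float = 1e-12

    def __post_init__(self) -> None:
        if not 0.0 <= self.u < 1.0:
            raise ParameterError(f"mutation probability u must satisfy 0 <= u < 1, got {self.u}")
        if not self.l > 0.0:
            raise ParameterError(f"birth rate l must be positive, got {self.l}")
        if self.d < 0.0:
            raise ParameterError(f"death rate d must be non-negative, got {self.d}")
        if self.a < 0.0 or self.b < 0.0:
            raise ParameterError(f"division-mode probabilities must be non-negative, got a={self.a}, b={self.b}")
        if not self.a + 2.0 * self.b < 1.0:
            raise ParameterError(f"division-mode probabilities must satisfy a + 2b < 1, got a + 2b = {self.a + 2 * self.b}")
        if not self.l * (1.0 - self.a - 2.0 * self.b) > self.d:
            raise ParameterError(
                "supercriticality violated: require l*(1 - a - 2b) > d, got "
                f"l*(1 - a - 2b) = {self.l * (1 - self.a - 2 * self.b)} <= d = {self.d}"
            )
        if self.limit_threshold <= 0.0:
            raise ParameterError("limit_threshold must be positive")


@dataclass(frozen=True)
class TumorGeometry:
    """Tumor diameter and the constants converting it to a cell count.

    Defaults: 1e9 cells per cm^3 of tumoral mass, halved (purity 0.5) to
    discount stromal and other non-tumor cells, and a self-renewing fraction
    of 6.2e-3.
    """

    diameter_cm: float
    cell_density_per_cm3: float = 1e9
    tumor_purity: float = 0.5
    stem_fraction: float = 6.2e-3

    def __post_init__(self) -> None:
        if self.diameter_cm < 0.0:
            raise ParameterError(f"diameter must be non-negative, got {self.diameter_cm}")
        if not self.cell_density_per_cm3 > 0.0:
            raise ParameterError("cell density must be positive")
        if not 0.0 < self.tumor_purity <= 1.0:
            raise ParameterError(f"tumor purity must lie in (0, 1], got {self.tumor_purity}")
        if not 0.0 < self.stem_fraction <= 1.0:
            raise ParameterError(f"stem fraction must lie in (0, 1], got {self.stem_fraction}")

    def with_diameter(self, diameter_cm: float) -> "TumorGeometry":
        """Same conversion constants, different diameter."""
        return replace(self, diameter_cm=diameter_cm)


@dataclass(frozen=True)
class ResistanceEstimate:
    """All derived quantities for one tumor diameter.

    ``expected_resistant_lineages`` is the Poisson mean lambda = u*M*F over
    surviving resistant lineages in the self-renewing compartment of size M;
    ``p_resistance`` = 1 - exp(-lambda).
    """

    diameter_cm: float
    total_cells: float
    stem_cells: float
    effective_division_factor: float
    expected_resistant_lineages: float
    p_resistance: float
    expected_resistant_fraction: float

    def to_dict(self) -> dict:
        return {
            "diameter_cm": self.diameter_cm,
            "total_cells": self.total_cells,
            "stem_cells": self.stem_cells,
            "division_factor": self.effective_division_factor,
            "lambda": self.expected_resistant_lineages,
            "p_resistance": self.p_resistance,
            "resistant_fraction": self.expected_resistant_fraction,
        }


def total_cells(geometry: TumorGeometry) -> float:
    """Number of tumor cells in a sphere of the given diameter.

    (pi/6) * D^3 * density * purity.
    """
    return (math.pi / 6.0) * geometry.diameter_cm ** 3 * geometry.cell_density_per_cm3 * geometry.tumor_purity


def stem_cells(geometry: TumorGeometry) -> float:
    """Number of self-renewing cells: total cells times the stem fraction."""
    return total_cells(geometry) * geometry.stem_fraction


def effective_division_factor(params: ModelParameters) -> float:
    """The factor F converting population size into mutation opportunities.

    Evaluated as
    ``[(1-a/2-b)/(1-a-b)] * [N/x] * (-log1p(-x/N))`` with ``N = l*(1-a-b)``
    and ``x = d + l*b``; for ``x < limit_threshold*l`` the analytic limit
    ``(1-a/2-b)/(1-a-b)`` is returned (so F = 1 when a = b = d = 0).
    """
    a, b, d, l = params.a, params.b, params.d, params.l
    geometric = (1.0 - a / 2.0 - b) / (1.0 - a - b)
    x = d + l * b
    if x < params.limit_threshold * l:
        return geometric
    n = l * (1.0 - a - b)
    # supercriticality guarantees n - x = l*(1-a-2b) - d > 0, so the log is finite
    return geometric * (n / x) * (-math.log1p(-x / n))


def prob_preexisting_resistance(params: ModelParameters, n_stem: float) -> float:
    """P(>= 1 resistant lineage) = 1 - exp(-u * n_stem * F)."""
    if n_stem < 0.0:
        raise ParameterError(f"stem-cell count must be non-negative, got {n_stem}")
    lam = params.u * n_stem * effective_division_factor(params)
    return -math.expm1(-lam)


def expected_resistant_fraction(params: ModelParameters) -> float:
    """Expected fraction of tumor cells carrying a resistance mutation.

    Each resistant self-renewing lineage is credited its proportional share of
    non-self-renewing progeny, so the stem-fraction factors cancel and the
    fraction is u * F — about 1 resistant cell per 1e8 at the defaults.
    """
    return params.u * effective_division_factor(params)


def estimate_for_diameter(params: ModelParameters, geometry: TumorGeometry) -> ResistanceEstimate:
    """Full derived record for one tumor: counts, lambda, probability, fraction."""
    n_total = total_cells(geometry)
    n_stem = n_total * geometry.stem_fraction
    factor = effective_division_factor(params)
    lam = params.u * n_stem * factor
    return ResistanceEstimate(
        diameter_cm=geometry.diameter_cm,
        total_cells=n_total,
        stem_cells=n_stem,
        effective_division_factor=factor,
        expected_resistant_lineages=lam,
        p_resistance=-math.expm1(-lam),
        expected_resistant_fraction=params.u * factor,
    )


def prob_double_resistance(params: ModelParameters, u2: float, n_stem: float) -> float:
    """Probability that a doubly resistant cell pre-exists (combination therapy).

    First-order sequential-mutation approximation: the expected number of
    doubly hit lineages is the second-drug mutation rate times the expected
    divisions occurring inside first-drug-resistant lineages, giving
    1 - exp(-u * u2 * F^2 * n_stem).  Always bounded above by the single-drug
    probability for either mutation rate.
    """
    if not 0.0 <= u2 < 1.0:
        raise ParameterError(f"second mutation probability u2 must satisfy 0 <= u2 < 1, got {u2}")
    if n_stem < 0.0:
        raise ParameterError(f"stem-cell count must be non-negative, got {n_stem}")
    factor = effective_division_factor(params)
    lam = params.u * u2 * factor * factor * n_stem
    return -math.expm1(-lam)


def _diameter_closed_form(params: ModelParameters, geometry_template: TumorGeometry, p_target: float) -> float:
    lam_star = -math.log1p(-p_target)
    if lam_star == 0.0:
        return 0.0
    factor = effective_division_factor(params)
    if params.u * factor == 0.0:
        raise ParameterError("p_target > 0 is unreachable when u = 0")
    n_stem = lam_star / (params.u * factor)
    n_total = n_stem / geometry_template.stem_fraction
    volume = n_total / (geometry_template.cell_density_per_cm3 * geometry_template.tumor_purity)
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)


def diameter_for_probability(
    params: ModelParameters,
    geometry_template: TumorGeometry,
    p_target: float,
    method: str = "bisect",
) -> float:
    """Diameter at which the pre-existing resistance probability equals p_target.

    The inverse of the diameter -> P curve.  ``method="bisect"`` solves by
    root bracketing (Brent) to relative tolerance 1e-9; ``method="closed_form"``
    inverts analytically via D = [6*lambda*/(pi*density*purity*f_s*u*F)]^(1/3)
    with lambda* = -ln(1 - p_target).  The two agree to solver tolerance.
    """
    if not 0.0 <= p_target < 1.0:
        raise ParameterError(f"target probability must satisfy 0 <= p < 1 (p = 1 is unreachable), got {p_target}")
    d_exact = _diameter_closed_form(params, geometry_template, p_target)
    if method == "closed_form":
        return d_exact
    if method != "bisect":
        raise ValueError(f"unknown method {method!r}")
    if d_exact == 0.0:
        return 0.0

    def objective(diam: float) -> float:
        est = estimate_for_diameter(params, geometry_template.with_diameter(diam))
        return est.p_resistance - p_target

    lo, hi = 0.0, 2.0 * d_exact
    while objective(hi) < 0.0:  # safety net; closed form already brackets
        hi *= 2.0
    return brentq(objective, lo, hi, rtol=1e-12, xtol=1e-15)


def combine_lesion_probabilities(probabilities) -> float:
    """Probability that at least one of several independent lesions carries
    resistance: 1 - prod(1 - P_i)."""
    log_none = 0.0
    for p in probabilities:
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"probabilities must lie in [0, 1], got {p}")
        if p == 1.0:
            return 1.0
        log_none += math.log1p(-p)
    return -math.expm1(log_none)
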