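"""Scalar epidemiological derivations feeding the threshold model.

These are the desk calculations that turn published twin/family recurrence
rates into the constants the model consumes: the intrauterine-adjusted
penetrance, the fraction of the population genetically susceptible (point
estimate and worst-case bound), the Finnish twin-cohort lower bound on
genetic MS, the twin-table concordance statistics, penetrance constraints,
and the allelic odds ratio for the HLA association.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from .genetics import allele_from_carrier, c_star

__all__ = [
    "EpidemiologicalConstants",
    "TwinTable",
    "adjusted_penetrance",
    "pg_point_and_bound",
    "finland_lower_bound",
    "pairwise_concordance",
    "adjust_probandwise",
    "allelic_odds_ratio",
    "penetrance_bounds",
    "genetic_fraction_lower_bound",
    "derivation_chain",
]


@dataclass(frozen=True)
class EpidemiologicalConstants:
    """Observed rates the model is anchored to (northern Europe / Canada)."""

    P_MS: float = 0.0015
    CR_MZ: float = 0.25
    CR_DZ: float = 0.054
    CR_S: float = 0.029
    CR_PC: float = 0.020          # parent/child midpoint of 1.8-2.1%
    CR_AU: float = 0.010          # second-degree midpoint-ish of 0.9-1.6%
    CR_FC: float = 0.009
    h: float = 0.24
    h_m: float = 0.55
    a_hm: float = 0.328           # HLA allele frequency among cases (UCSF)
    C_obs: float = 0.45
    P_MSE_max: float = 0.0015     # non-genetic MS can be at most the prevalence

    @property
    def dz_sib_ratio(self) -> float:
        return self.CR_DZ / self.CR_S

    @property
    def CR_IG(self) -> float:
        return adjusted_penetrance(self.CR_MZ, self.CR_DZ, self.CR_S)


@dataclass(frozen=True)
class TwinTable:
    """MZ-twin concordance counts split by the proband's HLA carrier status."""

    concordant_pos: int = 9
    discordant_pos: int = 31
    concordant_neg: int = 11
    discordant_neg: int = 42

    def __post_init__(self) -> None:
        for v in (self.concordant_pos, self.discordant_pos,
                  self.concordant_neg, self.discordant_neg):
            if v < 0:
                raise ValueError("pair counts must be non-negative")

    @property
    def totals(self) -> tuple[int, int, int]:
        pos = self.concordant_pos + self.discordant_pos
        neg = self.concordant_neg + self.discordant_neg
        return (pos, neg, pos + neg)

    def pairwise(self) -> tuple[float | None, float | None]:
        """Pairwise concordance C/(C+D) per HLA column; None for an empty column."""
        pos, neg, _ = self.totals
        zpos = self.concordant_pos / pos if pos else None
        zneg = self.concordant_neg / neg if neg else None
        return (zpos, zneg)


def adjusted_penetrance(CR_MZ: float, CR_DZ: float, CR_S: float) -> float:
    """Remove the shared-intrauterine effect from the MZ concordance rate.

    The DZ/sibling recurrence ratio isolates the intrauterine/early-postnatal
    boost (twins and siblings share genetics identically in expectation), so
    ``CR_IG = CR_MZ . CR_S / CR_DZ``.
    """
    for name, v in (("CR_MZ", CR_MZ), ("CR_DZ", CR_DZ), ("CR_S", CR_S)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if CR_DZ == 0.0:
        raise ValueError("CR_DZ must be positive")
    if CR_DZ < CR_S:
        warnings.warn(
            "CR_DZ < CR_S: adjustment would inflate the penetrance instead of "
            "removing a shared-environment boost", stacklevel=2,
        )
    return CR_MZ * (CR_S / CR_DZ)


def pg_point_and_bound(P_MS: float, b_prime: float) -> tuple[float, float]:
    """Fraction of the population genetically susceptible: point and bound.

    Point estimate ``P(G) = P(MS) / b'`` (b' is the per-genotype disease
    probability, estimated by the adjusted MZ concordance); the worst-case
    penetrance heterogeneity between the above-average and below-average
    penetrance classes doubles it, capped at 1.
    """
    if b_prime <= 0.0:
        raise ValueError("b_prime must be positive")
    point = P_MS / b_prime
    return point, min(2.0 * point, 1.0)


def finland_lower_bound(
    concordant: int, ascertained_pairs: int, participating_pairs: int,
    cohort_pairs: int,
) -> float:
    """Population-cohort lower bound on genetic MS, per 100,000.

    Concordant pairs among participants, up-weighted by the ascertained /
    participating ratio, relative to the full twin cohort.
    """
    if participating_pairs < 1:
        raise ValueError("participating_pairs must be >= 1")
    if min(concordant, ascertained_pairs, cohort_pairs) < 0 or cohort_pairs == 0:
        raise ValueError("counts must be non-negative and cohort_pairs positive")
    return concordant * (ascertained_pairs / participating_pairs) / cohort_pairs * 1e5


def pairwise_concordance(concordant: int, discordant: int) -> float:
    """C / (C + D); undefined (raises) for an empty column."""
    if concordant < 0 or discordant < 0:
        raise ValueError("counts must be non-negative")
    total = concordant + discordant
    if total == 0:
        raise ValueError("empty column: pairwise concordance undefined")
    return concordant / total


def adjust_probandwise(probandwise: float, sib_dz_ratio: float) -> float:
    """Down-weight a proband-wise concordance by the sibling/DZ ratio.

    The proband-wise rates themselves (e.g. 31%, 29%) are accepted as data:
    their ascertainment correction is not recomputable from the pair counts.
    """
    return probandwise * sib_dz_ratio


def allelic_odds_ratio(a_case: float, a_control: float) -> float:
    """Allelic odds ratio between case and control allele frequencies."""
    for name, v in (("a_case", a_case), ("a_control", a_control)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1): OR degenerate at {v}")
    return (a_case / (1.0 - a_case)) / (a_control / (1.0 - a_control))


def penetrance_bounds(
    Pt_mean: float, C_obs: float, h: float, C_star_max: float = 0.79
) -> tuple[float, float, float]:
    """Bounds on the HLA/non-HLA penetrance split from the C* ceiling.

    The observed HLA-negative case fraction dilutes as the HLA penetrance
    advantage grows; at the ceiling ``C* = C_star_max`` the ratio
    ``Pt1/Pt0`` is maximal.  Solving
    ``C_obs = C_true Pt0 / [(1 - C_true) Pt1 + C_true Pt0]`` at
    ``C_true = C_star_max (1 - h)`` gives the max ratio, and the mean
    penetrance constraint ``(1-C_obs) Pt1 + C_obs Pt0 = Pt_mean`` pins
    ``Pt1_max`` and ``Pt0_min``.

    Returns (max ratio, Pt1_max, Pt0_min).
    """
    for name, v in (("Pt_mean", Pt_mean), ("C_obs", C_obs), ("h", h),
                    ("C_star_max", C_star_max)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if Pt_mean == 0.0:
        return (1.0, 0.0, 0.0)
    c_true = C_star_max * (1.0 - h)
    if C_obs <= 0.0 or C_obs >= 1.0 or c_true <= 0.0 or c_true >= 1.0:
        raise ValueError("infeasible constraint set: degenerate C fractions")
    ratio = c_true * (1.0 - C_obs) / (C_obs * (1.0 - c_true))
    if ratio < 1.0 - 1e-12:
        raise ValueError(
            "infeasible constraint set: C_star_max below the observed C*"
        )
    pt0 = Pt_mean / ((1.0 - C_obs) * ratio + C_obs)
    pt1 = ratio * pt0
    return (ratio, pt1, pt0)


def genetic_fraction_lower_bound(CR: float, P_MSE_max: float) -> float:
    """Lower bound on the genetic fraction of familial cases, 1 - P_MSE/CR."""
    if CR <= 0.0:
        raise ValueError("CR must be positive")
    return min(max(1.0 - P_MSE_max / CR, 0.0), 1.0)


def derivation_chain(constants: EpidemiologicalConstants | None = None) -> dict:
    """Run the full scalar derivation and return every intermediate value.

    Mirrors the desk chain: carrier -> allele frequency, C*, the DZ/sibling
    ratio, the adjusted penetrance, the susceptible-fraction point estimate
    and bound, the twin-table statistics, the Finnish cohort bound, and the
    HLA allelic odds ratio.
    """
    k = constants or EpidemiologicalConstants()
    table = TwinTable()
    a_h = allele_from_carrier(k.h)
    cr_ig = adjusted_penetrance(k.CR_MZ, k.CR_DZ, k.CR_S)
    pg, pg_bound = pg_point_and_bound(k.P_MS, cr_ig)
    zpos, zneg = table.pairwise()
    return {
        "a_h": a_h,
        "a_hm": k.a_hm,
        "C_star": c_star(k.C_obs, k.h),
        "dz_sib_ratio": k.dz_sib_ratio,
        "CR_IG": cr_ig,
        "P_G": pg,
        "P_G_bound": pg_bound,
        "pairwise_pos": zpos,
        "pairwise_neg": zneg,
        "adjusted_probandwise_pos": adjust_probandwise(0.31, 1.0 / k.dz_sib_ratio),
        "adjusted_probandwise_neg": adjust_probandwise(0.29, 1.0 / k.dz_sib_ratio),
        "finland_per_100k": finland_lower_bound(3, 21, 10, 3083),
        "allelic_OR": allelic_odds_ratio(k.a_hm, a_h),
        "genetic_fraction_bound": genetic_fraction_lower_bound(k.CR_S, k.P_MSE_max),
    }
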