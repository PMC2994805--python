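"""Hardy-Weinberg allele algebra and relative-class transmission probabilities.

Closed forms for (a) converting between carrier / susceptible-state
frequencies and allele frequencies under Hardy-Weinberg equilibrium, and
(b) the probability that a relative of a proband is in a susceptible state at
a locus where a susceptibility allele is known to be "necessarily present" in
the proband's parents.  The printed closed forms are deliberate
approximations in places (a dominant-locus proband is treated as having a
single transmitting parent); exact conditional-enumeration variants are
provided for diagnostics and are never silently substituted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import DominanceMode, RelativeClass

__all__ = [
    "allele_from_carrier",
    "carrier_from_allele",
    "susceptible_state_allele_freq",
    "susceptible_state_freq",
    "c_star",
    "transmission_prob",
    "hla_transmission_prob",
    "conjugal_transmission_prob",
    "conjugal_hla_transmission_prob",
    "TransmissionProbabilitySet",
    "transmission_probs",
    "sibling_carrier_exact",
]


# ---------------------------------------------------------------------------
# allele-frequency algebra

def carrier_from_allele(a: float) -> float:
    """Carrier probability ``2a - a^2`` under HWE (at least one copy)."""
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {a!r}")
    return 2.0 * a - a * a


def allele_from_carrier(h: float) -> float:
    """Allele frequency solving ``2a - a^2 = h``; the root in [0, 1]."""
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"carrier frequency must lie in [0, 1], got {h!r}")
    return 1.0 - math.sqrt(1.0 - h)


def susceptible_state_allele_freq(mode: DominanceMode, F: float) -> float:
    """Allele frequency producing susceptible-state frequency ``F``.

    dominant: state = carry >=1 copy, so ``a = 1 - (1-F)^(1/2)``;
    recessive: state = homozygous, so ``a = F^(1/2)``;
    mixed: a locus with one dominant-acting and one recessive-acting allele
    of equal frequency has state frequency ``2a``, so ``a = F / 2``.
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"susceptible-state frequency must lie in [0, 1], got {F!r}")
    mode = DominanceMode(mode)
    if mode is DominanceMode.DOMINANT:
        return 1.0 - math.sqrt(1.0 - F)
    if mode is DominanceMode.RECESSIVE:
        return math.sqrt(F)
    return F / 2.0


def susceptible_state_freq(mode: DominanceMode, a: float) -> float:
    """Inverse of :func:`susceptible_state_allele_freq` (genotype frequencies)."""
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {a!r}")
    mode = DominanceMode(mode)
    if mode is DominanceMode.DOMINANT:
        return 2.0 * a - a * a
    if mode is DominanceMode.RECESSIVE:
        return a * a
    # mixed: (>=1 dominant allele) or (recessive homozygote):
    # a^2 + 2a(1-2a) + 2a*a + a^2 = 2a
    return 2.0 * a


def c_star(C: float, h: float) -> float:
    """``C* = C / (1 - h)``: HLA-negative susceptible fraction with the
    baseline probability of non-carriage divided out."""
    if not 0.0 <= C <= 1.0:
        raise ValueError(f"C must lie in [0, 1], got {C!r}")
    if not 0.0 <= h < 1.0:
        raise ValueError("h = 1 is an invalid parameterization (division by zero)")
    return C / (1.0 - h)


# ---------------------------------------------------------------------------
# transmission probabilities for "necessarily present" loci

_FIRST_DEGREE = (RelativeClass.SIBLING, RelativeClass.DZ_TWIN, RelativeClass.PARENT_CHILD)


def transmission_prob(relative: RelativeClass, mode: DominanceMode, a: float) -> float:
    """P(relative in a susceptible state | locus necessarily present).

    The printed closed form for the requested (relative, mode) cell.  DZ twins
    and siblings share identical formulas (equal genetic sharing; the twin
    difference enters through penetrance, not transmission).  MZ twins share
    the state with certainty and are not handled here; the offspring of two
    affected parents has its own form (:func:`conjugal_transmission_prob`).
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {a!r}")
    relative = RelativeClass(relative)
    mode = DominanceMode(mode)
    if relative is RelativeClass.MZ_TWIN:
        raise NotImplementedError(
            "(mz_twin, *): an MZ co-twin shares every allelic state with probability 1"
        )
    if relative is RelativeClass.CONJUGAL_OFFSPRING:
        raise NotImplementedError(
            "(conjugal_offspring, *): use conjugal_transmission_prob(mode, a, n, x)"
        )

    if mode is DominanceMode.MIXED:
        p1 = transmission_prob(relative, DominanceMode.DOMINANT, a)
        p2 = transmission_prob(relative, DominanceMode.RECESSIVE, a)
        # weight a/2: probability the proband's known state is the recessive one
        return (1.0 - a / 2.0) * p1 + (a / 2.0) * p2

    if relative in _FIRST_DEGREE:
        if mode is DominanceMode.DOMINANT:
            return 0.5 * (1.0 + 2.0 * a - a * a)
        if relative is RelativeClass.PARENT_CHILD:
            # recessive: parent and child necessarily share one allele copy
            return a
        return 0.25 * (1.0 + a) ** 2
    if relative is RelativeClass.AUNT_UNCLE:
        if mode is DominanceMode.DOMINANT:
            return 0.25 * (1.0 + 6.0 * a - 3.0 * a * a)
        return 0.0625 * (1.0 + 3.0 * a) ** 2
    if relative is RelativeClass.FIRST_COUSIN:
        if mode is DominanceMode.DOMINANT:
            return 0.125 * (1.0 + 14.0 * a - 7.0 * a * a)
        return 0.015625 * (1.0 + 7.0 * a) ** 2
    raise NotImplementedError(f"({relative.value}, {mode.value}) has no transmission formula")


def hla_transmission_prob(
    relative: RelativeClass, a_h: float, proband_carrier: bool
) -> float:
    """P(relative carries the HLA allele | proband's carrier status).

    ``P_H`` (carrier proband) or ``P_h1`` (non-carrier proband) for the
    relative class, as printed.  The second-/third-degree ``P_h1`` forms carry
    the paper's rounded coefficients (0.56, 0.77).
    """
    if not 0.0 <= a_h <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {a_h!r}")
    relative = RelativeClass(relative)
    if relative is RelativeClass.MZ_TWIN:
        return 1.0 if proband_carrier else 0.0
    if relative is RelativeClass.CONJUGAL_OFFSPRING:
        raise NotImplementedError(
            "(conjugal_offspring, hla): use conjugal_hla_transmission_prob"
        )
    if proband_carrier:
        if relative in _FIRST_DEGREE:
            return 0.5 * (1.0 + 2.0 * a_h - a_h * a_h)
        if relative is RelativeClass.AUNT_UNCLE:
            return 0.25 * (1.0 + 6.0 * a_h - 3.0 * a_h * a_h)
        return 0.125 * (1.0 + 14.0 * a_h - 7.0 * a_h * a_h)
    if relative in _FIRST_DEGREE:
        return a_h - 0.25 * a_h * a_h
    if relative is RelativeClass.AUNT_UNCLE:
        return 1.5 * a_h - 0.56 * a_h * a_h
    return 1.75 * a_h - 0.77 * a_h * a_h


def conjugal_transmission_prob(
    mode: DominanceMode, a: float, n: int, x: int
) -> float:
    """Susceptible-state probability for the child of two affected parents.

    Mixture with weight ``(n/x)^2`` on the branch where *both* parents are in
    a susceptible state at the locus, ``1 - (n/x)^2`` on the one-parent branch.
    """
    if x <= 0:
        raise ValueError("x must be positive for the conjugal mixture weight (n/x)^2")
    if not 1 <= n <= x:
        raise ValueError("require 1 <= n <= x")
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {a!r}")
    mode = DominanceMode(mode)
    w = (n / x) ** 2
    if mode is DominanceMode.DOMINANT:
        one = 0.5 * (1.0 + 2.0 * a - a * a)
        both = 0.75 + 0.5 * a - 0.25 * a * a
        return (1.0 - w) * one + w * both
    if mode is DominanceMode.RECESSIVE:
        # one-parent branch is the parent/child form `a`; both-parents branch is 1
        return a + w * (1.0 - a)
    p1 = conjugal_transmission_prob(DominanceMode.DOMINANT, a, n, x)
    p2 = conjugal_transmission_prob(DominanceMode.RECESSIVE, a, n, x)
    return (1.0 - a / 2.0) * p1 + (a / 2.0) * p2


def conjugal_hla_transmission_prob(
    a_h: float, parent_carrier: bool, corrected: bool = False
) -> float:
    """HLA carriage probability for the child of two affected parents.

    The printed form for a carrier parent is ``(0.5)[1 + 2a + a^2]``, with a
    ``+a^2`` where every analogous formula has ``-a^2``; ``corrected=True``
    switches the sign.
    """
    if not 0.0 <= a_h <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {a_h!r}")
    if parent_carrier:
        sign = -1.0 if corrected else 1.0
        return 0.5 * (1.0 + 2.0 * a_h + sign * a_h * a_h)
    return a_h - 0.25 * a_h * a_h


# ---------------------------------------------------------------------------
# bundled view

@dataclass(frozen=True)
class TransmissionProbabilitySet:
    """All transmission probabilities for one relative class at one model point."""

    relative: RelativeClass
    P_H: float
    P_h1: float
    P_A1: float
    P_A2: float
    P_A3: float
    P_a_baseline: float


def transmission_probs(
    relative: RelativeClass,
    a_h: float,
    F: float,
    n: int | None = None,
    x: int | None = None,
    conjugal_ph_corrected: bool = False,
) -> TransmissionProbabilitySet:
    """Assemble the full probability set for a relative class.

    ``F`` is the non-HLA susceptible-state frequency; per-mode allele
    frequencies are derived from it.  ``n`` and ``x`` are required for the
    conjugal-offspring class only.
    """
    relative = RelativeClass(relative)
    a1 = susceptible_state_allele_freq(DominanceMode.DOMINANT, F)
    a2 = susceptible_state_allele_freq(DominanceMode.RECESSIVE, F)
    a3 = susceptible_state_allele_freq(DominanceMode.MIXED, F)
    if relative is RelativeClass.CONJUGAL_OFFSPRING:
        if n is None or x is None:
            raise ValueError("conjugal_offspring requires n and x")
        return TransmissionProbabilitySet(
            relative=relative,
            P_H=conjugal_hla_transmission_prob(a_h, True, conjugal_ph_corrected),
            P_h1=conjugal_hla_transmission_prob(a_h, False),
            P_A1=conjugal_transmission_prob(DominanceMode.DOMINANT, a1, n, x),
            P_A2=conjugal_transmission_prob(DominanceMode.RECESSIVE, a2, n, x),
            P_A3=conjugal_transmission_prob(DominanceMode.MIXED, a3, n, x),
            P_a_baseline=F,
        )
    if relative is RelativeClass.MZ_TWIN:
        return TransmissionProbabilitySet(relative, 1.0, 0.0, 1.0, 1.0, 1.0, F)
    return TransmissionProbabilitySet(
        relative=relative,
        P_H=hla_transmission_prob(relative, a_h, True),
        P_h1=hla_transmission_prob(relative, a_h, False),
        P_A1=transmission_prob(relative, DominanceMode.DOMINANT, a1),
        P_A2=transmission_prob(relative, DominanceMode.RECESSIVE, a2),
        P_A3=transmission_prob(relative, DominanceMode.MIXED, a3),
        P_a_baseline=F,
    )


# ---------------------------------------------------------------------------
# exact-enumeration diagnostics

def sibling_carrier_exact(a: float, proband_carrier: bool) -> float:
    """Exact P(sibling carries >=1 copy | proband's carrier status).

    Enumeration over HWE parental diplotypes conditioned on the proband's
    status at a dominant (carrier-defined) locus.  For a non-carrier proband
    this reproduces the printed ``P_h1 = a - 0.25 a^2`` exactly; for a carrier
    proband the printed ``P_H = 0.5 (1 + 2a - a^2)`` is an approximation that
    ignores homozygous probands, and this function quantifies the gap.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {a!r}")
    q = 1.0 - a
    # parental genotype (copies, HWE prob, transmission prob of the allele)
    genos = [(2, a * a, 1.0), (1, 2 * a * q, 0.5), (0, q * q, 0.0)]
    num = 0.0
    den = 0.0
    for _, p1, t1 in genos:
        for _, p2, t2 in genos:
            w = p1 * p2
            p_noncarrier_child = (1.0 - t1) * (1.0 - t2)
            p_cond = p_noncarrier_child if not proband_carrier else 1.0 - p_noncarrier_child
            p_sib_carrier = 1.0 - p_noncarrier_child
            num += w * p_cond * p_sib_carrier
            den += w * p_cond
    if den == 0.0:
        raise ValueError("conditioning event has probability zero")
    return num / den
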