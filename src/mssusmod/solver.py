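"""Locus-count constraint solver and prevalence / recurrence predictors.

The central constraint ties the observed HLA-negative fraction among
susceptible individuals (``C* = C / (1 - h)``) to the number of non-HLA loci:
for a susceptible individual, the chance that none of the ``n`` susceptible
states sits at the HLA locus is the falling-factorial ratio

    x (x-1) ... (x-n+1)  /  (x+r)(x+r-1) ... (x+r-n+1)

which is strictly increasing in ``x``.  Solving it for ``x`` (continuously,
and as an integer scan with a tolerance band ``C* +- tol``) yields the range
of locus counts compatible with one (n, r).  Prevalence and familial
recurrence risks then follow from binomial tail probabilities over the
susceptible-state counts, with transmission-conditioned success
probabilities at the loci an affected proband pins down.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom, poisson

from .genetics import (
    conjugal_hla_transmission_prob,
    hla_transmission_prob,
    susceptible_state_allele_freq,
    transmission_probs,
)
from .parameters import DominanceMode, ModelParameters, RelativeClass

__all__ = [
    "hla_negative_fraction",
    "SolutionRange",
    "solve_x",
    "prevalence",
    "limit_prevalence",
    "recurrence_risk",
    "expected_recurrence",
]

X_SCAN_MIN = 4
X_SCAN_MAX = 2000


def hla_negative_fraction(x, n: int, r: float):
    """Falling-factorial ratio: P(all n susceptible states are non-HLA).

    Accepts scalar or array ``x`` (real-valued allowed); equals 0 at
    ``x = n - 1`` and increases strictly to 1 as ``x`` grows.  ``n = 0``
    gives the empty product, 1.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    xs = np.asarray(x, dtype=float)
    if np.any(xs < n - 1):
        raise ValueError(f"x must be >= n - 1 = {n - 1}")
    out = np.ones_like(xs)
    for k in range(n):
        out *= (xs - k) / (xs + r - k)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class SolutionRange:
    """Integer x-interval satisfying the constraint for one (n, r)."""

    n: int
    r: float
    c_star: float
    tol: float
    x_continuous: float
    x_low: int | None
    x_high: int | None

    @property
    def feasible(self) -> bool:
        return self.x_low is not None

    @property
    def endpoints(self) -> tuple[int, int]:
        if not self.feasible:
            raise ValueError(f"no integer solution for n={self.n}, r={self.r}")
        return (self.x_low, self.x_high)


def solve_x(
    n: int,
    r: float,
    c_star: float,
    tol: float = 0.05,
    x_min: int = X_SCAN_MIN,
    x_max: int = X_SCAN_MAX,
) -> SolutionRange:
    """Solve the HLA-negative-fraction constraint for the locus count ``x``.

    ``x_continuous`` is the unique real root > n - 1 of
    ``hla_negative_fraction(x) = c_star`` (monotone bisection);
    ``x_low``/``x_high`` bound the integers in ``[max(n, x_min), x_max]``
    whose fraction lies in the inclusive band ``[c_star - tol, c_star + tol]``.
    An empty band is reported (``x_low = x_high = None``), not raised.
    """
    if not 0.0 < c_star < 1.0:
        raise ValueError("c_star must lie strictly in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")

    lo = n - 1 + 1e-9
    hi = float(max(n + 1, 8))
    while hla_negative_fraction(hi, n, r) < c_star:
        hi *= 2.0
        if hi > 1e15:  # pragma: no cover - c_star < 1 guarantees termination
            raise RuntimeError("bracket expansion failed")
    root = brentq(lambda t: hla_negative_fraction(t, n, r) - c_star, lo, hi, xtol=1e-10)

    xs = np.arange(max(n, x_min), x_max + 1)
    x_low = x_high = None
    if xs.size:
        vals = hla_negative_fraction(xs, n, r)
        mask = (vals >= c_star - tol) & (vals <= c_star + tol)
        if mask.any():
            inside = xs[mask]
            x_low, x_high = int(inside[0]), int(inside[-1])
    return SolutionRange(n=n, r=r, c_star=c_star, tol=tol,
                         x_continuous=float(root), x_low=x_low, x_high=x_high)


# ---------------------------------------------------------------------------
# prevalence

def prevalence(params: ModelParameters) -> float:
    """Model prevalence: P(susceptible) x penetrance, summed over HLA status.

    With ``B ~ Binomial(x, h/r)`` counting susceptible non-HLA states,

        P(MS) = sum_{i in {0,1}} Pt_i* . P(HLA copies state = i)
                                . P(B >= n - i)

    where ``i`` is the HLA susceptible-state indicator (carrier frequency h).
    Summation bounds beyond ``x`` truncate automatically through the
    binomial tail.
    """
    F = params.F
    total = 0.0
    for i, pt in ((0, params.Pt0_star), (1, params.Pt1_star)):
        w = params.h if i == 1 else 1.0 - params.h
        # P(B >= n - i) = sf(n - i - 1)
        total += pt * w * float(binom.sf(params.n - i - 1, params.x, F))
    return total


def limit_prevalence(n: int, h: float, c_star: float, pt_star: float) -> float:
    """Prevalence floor as the non-HLA state frequency vanishes (r -> inf).

    Under the constraint the ratio tends to ``(x/(x+r))^n = C*`` so the
    binomial count converges to a Poisson with mean
    ``lam = h C*^{1/n} / (1 - C*^{1/n})``, giving

        Pt* [ h P(Pois(lam) >= n-1) + (1-h) P(Pois(lam) >= n) ].
    """
    if not 0.0 < c_star < 1.0:
        raise ValueError("c_star must lie strictly in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    u = c_star ** (1.0 / n)
    lam = h * u / (1.0 - u)
    tail_carrier = float(poisson.sf(n - 2, lam))  # P(>= n-1)
    tail_noncarrier = float(poisson.sf(n - 1, lam))  # P(>= n)
    return pt_star * (h * tail_carrier + (1.0 - h) * tail_noncarrier)


# ---------------------------------------------------------------------------
# recurrence risks

def _binom_pmf_vec(k: int, p: float) -> np.ndarray:
    if k == 0:
        return np.array([1.0])
    return binom.pmf(np.arange(k + 1), k, p)


def _count_pmf(parts: list[tuple[int, float]]) -> np.ndarray:
    """pmf of a sum of independent binomials, by direct convolution."""
    pmfs = [_binom_pmf_vec(k, p) for k, p in parts if k > 0]
    if not pmfs:
        return np.array([1.0])
    return reduce(np.convolve, pmfs)


def recurrence_risk(
    params: ModelParameters,
    relative: RelativeClass,
    proband_hla_positive: bool,
    conjugal_ph_corrected: bool = False,
) -> float:
    """P(relative develops MS | proband affected, proband's HLA status).

    The relative's susceptible-state count is the HLA indicator (Bernoulli
    with the class's ``P_H`` or ``P_h1``) plus independent binomials over the
    ``n1/n2/n3`` necessarily-present dominant/recessive/mixed loci (success
    ``P_A1/P_A2/P_A3``) and the remaining ``x - (n1+n2+n3)`` unconstrained
    loci (success ``h/r``); the risk is the penetrance-weighted probability
    the total reaches ``n``.  DZ twins use the unadjusted penetrance; an MZ
    co-twin is genetically identical, so the risk is the penetrance itself.
    """
    relative = RelativeClass(relative)
    if relative is RelativeClass.MZ_TWIN:
        return params.Pt1 if proband_hla_positive else params.Pt0

    probs = transmission_probs(
        relative, params.a_h, params.F, n=params.n, x=params.x,
        conjugal_ph_corrected=conjugal_ph_corrected,
    )
    p_hla = probs.P_H if proband_hla_positive else probs.P_h1

    if relative is RelativeClass.CONJUGAL_OFFSPRING:
        # With both parents affected every locus is elevated: the (n/x)
        # weights inside the conjugal mixture already encode the chance that
        # a given locus sits among an affected parent's susceptible states,
        # so the mixture applies across all x loci and none remain at
        # baseline frequency.
        n1, n2, n3 = params.x1, params.x2, params.x3
    else:
        n1, n2, n3 = params.necessary_partition(proband_hla_positive)
    free = params.x - (n1 + n2 + n3)
    pmf = _count_pmf([
        (n1, probs.P_A1), (n2, probs.P_A2), (n3, probs.P_A3), (free, params.F),
    ])
    cdf = np.cumsum(pmf)

    def tail(threshold: int) -> float:
        # P(count >= threshold)
        if threshold <= 0:
            return 1.0
        if threshold > pmf.size - 1:
            return 0.0
        return float(1.0 - cdf[threshold - 1])

    if relative is RelativeClass.DZ_TWIN:
        pt0, pt1 = params.Pt0, params.Pt1
    else:
        pt0, pt1 = params.Pt0_star, params.Pt1_star
    risk = (1.0 - p_hla) * pt0 * tail(params.n)
    risk += p_hla * pt1 * tail(params.n - 1)
    return risk


def expected_recurrence(
    params: ModelParameters,
    relative: RelativeClass,
    conjugal_ph_corrected: bool = False,
) -> float:
    """C-weighted mixture of the HLA-positive / HLA-negative proband risks.

    The weight on the HLA-negative branch is ``C`` (fraction of affected
    probands lacking the allele); for the offspring of two affected parents
    it is ``C^2`` (neither parent carries).  Valid as the expectation when
    ``Pt1 = Pt0`` so that the case mix equals the susceptible mix.
    """
    relative = RelativeClass(relative)
    w_neg = params.C ** 2 if relative is RelativeClass.CONJUGAL_OFFSPRING else params.C
    pos = recurrence_risk(params, relative, True, conjugal_ph_corrected)
    neg = recurrence_risk(params, relative, False, conjugal_ph_corrected)
    return (1.0 - w_neg) * pos + w_neg * neg
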