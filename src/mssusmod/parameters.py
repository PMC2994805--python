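"""Model configuration for the multilocus threshold model of MS susceptibility.

The model supposes ``x + 1`` unlinked susceptibility loci (one of them the HLA
DRB1 haplotype, carrier frequency ``h``), each of which is either in a
"susceptible allelic state" or not, and declares an individual genetically
susceptible iff at least ``n`` of the ``x + 1`` loci are in such a state.
Non-HLA loci share a mean susceptible-state frequency ``F = h / r``, and each
acts through a dominant, recessive or mixed (two-allele) susceptibility allele.
Susceptible individuals develop disease with penetrance ``Pt1*`` (HLA carriers)
or ``Pt0*`` (non-carriers); the star marks the downward adjustment that removes
the shared intrauterine / early-postnatal effect seen in twins.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import yaml


class DominanceMode(str, Enum):
    """Mode of action of the susceptibility allele(s) at a non-HLA locus."""

    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    MIXED = "mixed"


_SHARING: dict[str, float | None] = {
    "mz_twin": 1.0,
    "dz_twin": 0.5,
    "sibling": 0.5,
    "parent_child": 0.5,
    "aunt_uncle": 0.25,
    "first_cousin": 0.125,
    # offspring of two affected parents: not a single IBD fraction
    "conjugal_offspring": None,
}

_DEGREE: dict[str, int | None] = {
    "mz_twin": 0,
    "dz_twin": 1,
    "sibling": 1,
    "parent_child": 1,
    "aunt_uncle": 2,
    "first_cousin": 3,
    "conjugal_offspring": None,
}


class RelativeClass(str, Enum):
    """Relationship of the relative to the proband."""

    MZ_TWIN = "mz_twin"
    DZ_TWIN = "dz_twin"
    SIBLING = "sibling"
    PARENT_CHILD = "parent_child"
    AUNT_UNCLE = "aunt_uncle"
    FIRST_COUSIN = "first_cousin"
    CONJUGAL_OFFSPRING = "conjugal_offspring"

    @property
    def genetic_sharing(self) -> float | None:
        """Expected identity-by-descent allele sharing with the proband.

        ``None`` for the offspring of two affected parents, whose conditioning
        is not captured by a single sharing fraction.
        """
        return _SHARING[self.value]

    @property
    def degree(self) -> int | None:
        """Degree of the relationship (0 for an MZ co-twin)."""
        return _DEGREE[self.value]


def largest_remainder_split(total: int, weights: tuple[float, ...]) -> tuple[int, ...]:
    """Split ``total`` into integer parts proportional to ``weights``.

    Largest-remainder (Hamilton) rounding; ties broken by lower index.
    Deterministic, so the allocation of "necessarily present" loci to
    dominance classes is reproducible.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    wsum = float(sum(weights))
    if wsum <= 0:
        raise ValueError("weights must have a positive sum")
    quotas = [total * w / wsum for w in weights]
    parts = [math.floor(q) for q in quotas]
    short = total - sum(parts)
    order = sorted(range(len(weights)), key=lambda i: (-(quotas[i] - parts[i]), i))
    for i in order[:short]:
        parts[i] += 1
    return tuple(parts)


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ModelParameters:
    """One configuration of the threshold model.

    Parameters
    ----------
    n : loci (of the ``x + 1``) required in a susceptible state for
        genetic susceptibility; must be >= 1.
    r : ratio of the HLA carrier frequency to the mean non-HLA
        susceptible-state frequency, ``F = h / r``.
    x : total number of non-HLA susceptibility loci.
    x1, x2, x3 : counts of dominant / recessive / mixed non-HLA loci
        (must sum to ``x``).
    h : HLA DRB1*1501 carrier frequency in the general population.
    h_m : same carrier frequency in the MS population.
    Pt0_star, Pt1_star : adjusted penetrances for susceptible individuals
        without / with the HLA allele.
    C : fraction of susceptible individuals who lack the HLA allele
        (equals ``1 - h_m`` when ``Pt1 = Pt0``).
    dz_sib_ratio : DZ-twin to non-twin-sibling recurrence ratio used to
        undo the penetrance adjustment for twins (default 5.4/2.9).
    P_MS_target : observed population prevalence the model is fitted to.
    """

    n: int
    r: float
    x: int
    x1: int
    x2: int
    x3: int
    h: float = 0.24
    h_m: float = 0.55
    Pt0_star: float = 0.134
    Pt1_star: float = 0.134
    C: float = 0.45
    dz_sib_ratio: float = 5.4 / 2.9
    P_MS_target: float = 0.0015

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be a positive integer")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.x < 0 or min(self.x1, self.x2, self.x3) < 0:
            raise ValueError("locus counts must be non-negative")
        if self.x1 + self.x2 + self.x3 != self.x:
            raise ValueError("x1 + x2 + x3 must equal x")
        for name in ("h", "h_m", "Pt0_star", "Pt1_star", "C", "P_MS_target"):
            _check_prob(name, getattr(self, name))
        if self.h >= 1.0 and self.C > 0:
            raise ValueError("h = 1 leaves no HLA-negative individuals")
        if self.F > 1.0 + 1e-12:
            raise ValueError(f"F = h/r = {self.F:.4g} exceeds 1; invalid (h, r)")

    # -- derived quantities -------------------------------------------------

    @property
    def a_h(self) -> float:
        """HLA allele frequency implied by the carrier frequency ``h``."""
        return 1.0 - math.sqrt(1.0 - self.h)

    @property
    def F(self) -> float:
        """Mean susceptible-state frequency at non-HLA loci, ``h / r``."""
        return self.h / self.r

    @property
    def C_star(self) -> float:
        """``C / (1 - h)``: HLA-negative fraction net of baseline non-carriage."""
        return self.C / (1.0 - self.h)

    @property
    def Pt0(self) -> float:
        """Unadjusted penetrance (shared-intrauterine scale), HLA-negative."""
        return self.Pt0_star * self.dz_sib_ratio

    @property
    def Pt1(self) -> float:
        """Unadjusted penetrance (shared-intrauterine scale), HLA-positive."""
        return self.Pt1_star * self.dz_sib_ratio

    @property
    def composition(self) -> tuple[float, float, float]:
        """Fractions of dominant / recessive / mixed non-HLA loci."""
        if self.x == 0:
            return (0.0, 0.0, 0.0)
        return (self.x1 / self.x, self.x2 / self.x, self.x3 / self.x)

    # -- structure helpers --------------------------------------------------

    def necessary_partition(self, proband_hla_positive: bool) -> tuple[int, int, int]:
        """Split the loci "necessarily present" in the proband's parents.

        An affected proband carries at least ``n`` susceptible states; one of
        them is the HLA locus when the proband is a carrier, so ``n - 1``
        (carrier) or ``n`` (non-carrier) non-HLA loci are known to be
        transmissible in the family.  The split across dominance classes is
        proportional to (x1, x2, x3) with largest-remainder rounding.
        """
        m = self.n - 1 if proband_hla_positive else self.n
        if m > self.x:
            raise ValueError(
                f"infeasible partition: {m} necessarily-present loci but only x={self.x}"
            )
        if self.x == 0:
            return (0, 0, 0)
        n1, n2, n3 = largest_remainder_split(m, (self.x1, self.x2, self.x3))
        if n1 > self.x1 or n2 > self.x2 or n3 > self.x3:
            raise ValueError("infeasible partition: class count exceeds class size")
        return (n1, n2, n3)

    def with_x(self, x: int) -> "ModelParameters":
        """Same configuration at a different total locus count ``x``,
        re-splitting the dominance composition."""
        x1, x2, x3 = largest_remainder_split(x, self.composition if self.x else (1, 0, 0))
        return replace(self, x=x, x1=x1, x2=x2, x3=x3)

    # -- constructors -------------------------------------------------------

    @classmethod
    def with_composition(
        cls,
        n: int,
        r: float,
        x: int,
        composition: tuple[float, float, float] = (0.0, 1.0, 0.0),
        **kwargs,
    ) -> "ModelParameters":
        """Build parameters from dominance *fractions* instead of counts."""
        if abs(sum(composition) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        x1, x2, x3 = largest_remainder_split(x, composition)
        return cls(n=n, r=r, x=x, x1=x1, x2=x2, x3=x3, **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        data = dict(data)
        comp = data.pop("composition", None)
        if comp is not None:
            comp = (
                float(comp.get("dominant", 0.0)),
                float(comp.get("recessive", 0.0)),
                float(comp.get("mixed", 0.0)),
            )
            return cls.with_composition(
                n=int(data.pop("n")), r=float(data.pop("r")), x=int(data.pop("x")),
                composition=comp, **data,
            )
        return cls(**data)

    @classmethod
    def from_config(cls, path: str | Path) -> "ModelParameters":
        """Load from a YAML or JSON file with keys named after the model symbols."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)
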