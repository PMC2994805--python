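"""Forward Mendelian simulator: the model's assumptions made generative.

Draws founder diplotypes at ``x + 1`` unlinked biallelic loci in
Hardy-Weinberg equilibrium, transmits alleles through small fixed pedigree
structures (sib pairs, twins, parent-child, grandparental chains for
aunt/uncle and first-cousin pairs, two-affected-parent families), scores the
per-locus susceptible states by dominance mode, applies the >= n threshold,
and draws affection as a Bernoulli penetrance by HLA carrier status.  This
is both the synthetic-data generator and the brute-force oracle against
which every closed-form prediction can be checked.

Reproducibility: one root seed; independent child streams are spawned per
fixed-size batch, so increasing the family count appends batches without
reshuffling families already generated.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import DominanceMode, ModelParameters, RelativeClass

__all__ = [
    "LocusSpec",
    "SimulationConfig",
    "Cohort",
    "PedigreeSet",
    "loci_from_params",
    "simulate_cohort",
    "simulate_pedigrees",
    "empirical_stats",
    "recurrence_estimate",
    "carrier_sharing_estimate",
    "mean_ibd_sharing",
    "write_individuals_tsv",
    "write_plink",
]

_BATCH = 8192
_MODE_CODE = {DominanceMode.DOMINANT: 0, DominanceMode.RECESSIVE: 1,
              DominanceMode.MIXED: 2}


@dataclass(frozen=True)
class LocusSpec:
    """One susceptibility locus: mode of action and allele frequency."""

    mode: DominanceMode
    allele_freq: float
    is_hla: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_freq <= 1.0:
            raise ValueError("allele_freq must lie in [0, 1]")
        if self.mode is DominanceMode.MIXED and self.allele_freq > 0.5:
            raise ValueError("mixed locus carries two alleles of this frequency")


def loci_from_params(params: ModelParameters) -> list[LocusSpec]:
    """HLA locus (dominant, frequency a_h) followed by the x non-HLA loci."""
    from .genetics import susceptible_state_allele_freq

    loci = [LocusSpec(DominanceMode.DOMINANT, params.a_h, is_hla=True)]
    for mode, count in ((DominanceMode.DOMINANT, params.x1),
                        (DominanceMode.RECESSIVE, params.x2),
                        (DominanceMode.MIXED, params.x3)):
        a = susceptible_state_allele_freq(mode, params.F)
        loci.extend(LocusSpec(mode, a) for _ in range(count))
    return loci


@dataclass(frozen=True)
class SimulationConfig:
    """What to simulate: model point, family count, structure, root seed."""

    params: ModelParameters
    n_families: int
    seed: int
    structure: RelativeClass = RelativeClass.SIBLING
    dz_uses_unadjusted_penetrance: bool = True

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")


# ---------------------------------------------------------------------------
# low-level genotype machinery

def _locus_arrays(loci: list[LocusSpec]) -> tuple[np.ndarray, np.ndarray]:
    af = np.array([l.allele_freq for l in loci])
    mode = np.array([_MODE_CODE[l.mode] for l in loci], dtype=np.int8)
    return af, mode


def _draw_founders(rng: np.random.Generator, n: int, af: np.ndarray,
                   mode: np.ndarray) -> np.ndarray:
    """HWE diplotypes; allele codes 0 = neutral, 1 = susceptibility allele,
    2 = the second (recessive-acting) allele at a mixed locus."""
    u = rng.random((n, af.size, 2))
    alleles = (u < af[None, :, None]).astype(np.int8)
    second = (mode[None, :, None] == 2) & (u >= af[None, :, None]) \
        & (u < 2.0 * af[None, :, None])
    alleles[second] = 2
    return alleles


def _mate(rng: np.random.Generator, mom: np.ndarray, dad: np.ndarray) -> np.ndarray:
    n, L, _ = mom.shape
    a = np.take_along_axis(mom, rng.integers(0, 2, size=(n, L, 1)), axis=2)
    b = np.take_along_axis(dad, rng.integers(0, 2, size=(n, L, 1)), axis=2)
    return np.concatenate([a, b], axis=2)


def _states(alleles: np.ndarray, mode: np.ndarray) -> np.ndarray:
    """Per-locus susceptible-state indicators (n_ind, L)."""
    has_dom = (alleles == 1).any(axis=2)
    hom_main = (alleles == 1).all(axis=2)
    hom_second = (alleles == 2).all(axis=2)
    out = np.where(mode[None, :] == 0, has_dom,
                   np.where(mode[None, :] == 1, hom_main, has_dom | hom_second))
    return out


# topology: role -> parent roles (None = founder; "=proband" = MZ copy)
_TOPOLOGIES: dict[RelativeClass, tuple[list[tuple[str, object]], tuple[str, ...], str]] = {
    RelativeClass.SIBLING: (
        [("mother", None), ("father", None),
         ("proband", ("mother", "father")), ("relative", ("mother", "father"))],
        ("proband",), "relative"),
    RelativeClass.DZ_TWIN: (
        [("mother", None), ("father", None),
         ("proband", ("mother", "father")), ("relative", ("mother", "father"))],
        ("proband",), "relative"),
    RelativeClass.MZ_TWIN: (
        [("mother", None), ("father", None),
         ("proband", ("mother", "father")), ("relative", "=proband")],
        ("proband",), "relative"),
    RelativeClass.PARENT_CHILD: (
        [("mother", None), ("father", None), ("proband", ("mother", "father"))],
        ("proband",), "mother"),
    RelativeClass.AUNT_UNCLE: (
        [("grandmother", None), ("grandfather", None),
         ("parent", ("grandmother", "grandfather")),
         ("relative", ("grandmother", "grandfather")),
         ("spouse", None), ("proband", ("parent", "spouse"))],
        ("proband",), "relative"),
    RelativeClass.FIRST_COUSIN: (
        [("grandmother", None), ("grandfather", None),
         ("parent_a", ("grandmother", "grandfather")),
         ("parent_b", ("grandmother", "grandfather")),
         ("spouse_a", None), ("spouse_b", None),
         ("proband", ("parent_a", "spouse_a")),
         ("relative", ("parent_b", "spouse_b"))],
        ("proband",), "relative"),
    RelativeClass.CONJUGAL_OFFSPRING: (
        [("mother", None), ("father", None), ("relative", ("mother", "father"))],
        ("mother", "father"), "relative"),
}


# ---------------------------------------------------------------------------
# containers

@dataclass
class Cohort:
    """Unrelated individuals drawn from the model's population."""

    params: ModelParameters
    seed: int
    alleles: np.ndarray          # (N, L, 2) int8
    states: np.ndarray           # (N, L) bool
    susceptible: np.ndarray      # (N,) bool
    hla_carrier: np.ndarray      # (N,) bool
    affected: np.ndarray         # (N,) bool

    @property
    def n(self) -> int:
        return self.susceptible.size

    def to_frame(self) -> pd.DataFrame:
        return _individual_frame({"individual": self}, family_ids=np.arange(self.n))


@dataclass
class PedigreeSet:
    """Structured families: per-role genotype/phenotype arrays."""

    params: ModelParameters
    seed: int
    structure: RelativeClass
    proband_roles: tuple[str, ...]
    relative_role: str
    members: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        any_role = next(iter(self.members.values()))
        return any_role["susceptible"].size

    def proband_affected_mask(self) -> np.ndarray:
        mask = np.ones(self.n_families, dtype=bool)
        for role in self.proband_roles:
            mask &= self.members[role]["affected"]
        return mask

    def to_frame(self) -> pd.DataFrame:
        return _individual_frame(
            {role: _MemberView(m) for role, m in self.members.items()},
            family_ids=np.arange(self.n_families),
        )


class _MemberView:
    """Adapter so member dicts and Cohort share the frame writer."""

    def __init__(self, member: dict[str, np.ndarray]) -> None:
        self.alleles = member["alleles"]
        self.states = member["states"]
        self.susceptible = member["susceptible"]
        self.hla_carrier = member["hla_carrier"]
        self.affected = member["affected"]


def _individual_frame(roles: dict, family_ids: np.ndarray) -> pd.DataFrame:
    rows = []
    for role, m in roles.items():
        hla_copies = (m.alleles[:, 0, :] == 1).sum(axis=1)
        states_str = ["".join("1" if s else "0" for s in row) for row in m.states]
        rows.append(pd.DataFrame({
            "family": family_ids,
            "role": role,
            "affected": m.affected.astype(int),
            "susceptible": m.susceptible.astype(int),
            "hla_copies": hla_copies,
            "n_susceptible_loci": m.states.sum(axis=1),
            "locus_states": states_str,
        }))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["family", "role"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# simulation drivers

def _batch_seeds(seed: int, n_batches: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n_batches)


def _penetrances(config: SimulationConfig) -> tuple[float, float]:
    p = config.params
    if (config.structure in (RelativeClass.DZ_TWIN, RelativeClass.MZ_TWIN)
            and config.dz_uses_unadjusted_penetrance):
        return p.Pt0, p.Pt1
    return p.Pt0_star, p.Pt1_star


def _phenotypes(rng: np.random.Generator, alleles: np.ndarray, mode: np.ndarray,
                n_needed: int, pt0: float, pt1: float
                ) -> dict[str, np.ndarray]:
    st = _states(alleles, mode)
    susceptible = st.sum(axis=1) >= n_needed
    hla = st[:, 0]
    pt = np.where(hla, pt1, pt0)
    affected = susceptible & (rng.random(susceptible.size) < pt)
    return {"alleles": alleles, "states": st, "susceptible": susceptible,
            "hla_carrier": hla, "affected": affected}


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """``n_families`` *unrelated* individuals from the model population."""
    params = config.params
    af, mode = _locus_arrays(loci_from_params(params))
    pt0, pt1 = params.Pt0_star, params.Pt1_star
    chunks = []
    seeds = _batch_seeds(config.seed, -(-config.n_families // _BATCH))
    remaining = config.n_families
    for ss in seeds:
        rng = np.random.default_rng(ss)
        n = min(_BATCH, remaining)
        remaining -= n
        alleles = _draw_founders(rng, n, af, mode)
        chunks.append(_phenotypes(rng, alleles, mode, params.n, pt0, pt1))
    merged = {k: np.concatenate([c[k] for c in chunks]) for k in chunks[0]}
    return Cohort(params=params, seed=config.seed,
                  alleles=merged["alleles"], states=merged["states"],
                  susceptible=merged["susceptible"],
                  hla_carrier=merged["hla_carrier"], affected=merged["affected"])


def simulate_pedigrees(config: SimulationConfig) -> PedigreeSet:
    """Families with the requested structure, founders from HWE."""
    if config.structure not in _TOPOLOGIES:
        raise ValueError(f"unsupported pedigree structure: {config.structure!r}")
    topo, proband_roles, relative_role = _TOPOLOGIES[config.structure]
    params = config.params
    af, mode = _locus_arrays(loci_from_params(params))
    pt0, pt1 = _penetrances(config)

    role_chunks: dict[str, list[dict[str, np.ndarray]]] = {r: [] for r, _ in topo}
    seeds = _batch_seeds(config.seed, -(-config.n_families // _BATCH))
    remaining = config.n_families
    for ss in seeds:
        rng = np.random.default_rng(ss)
        n = min(_BATCH, remaining)
        remaining -= n
        genotypes: dict[str, np.ndarray] = {}
        for role, parents in topo:
            if parents is None:
                genotypes[role] = _draw_founders(rng, n, af, mode)
            elif parents == "=proband":
                genotypes[role] = genotypes["proband"].copy()
            else:
                genotypes[role] = _mate(rng, genotypes[parents[0]], genotypes[parents[1]])
        for role, _ in topo:
            role_chunks[role].append(
                _phenotypes(rng, genotypes[role], mode, params.n, pt0, pt1))
    members = {
        role: {k: np.concatenate([c[k] for c in chunks]) for k in chunks[0]}
        for role, chunks in role_chunks.items()
    }
    return PedigreeSet(params=params, seed=config.seed, structure=config.structure,
                       proband_roles=proband_roles, relative_role=relative_role,
                       members=members)


# ---------------------------------------------------------------------------
# empirical summaries

def _proportion_ci(k: int, n: int) -> tuple[float, float, float]:
    est = k / n
    se = float(np.sqrt(est * (1.0 - est) / n))
    return est, max(est - 1.96 * se, 0.0), min(est + 1.96 * se, 1.0)


def empirical_stats(cohort: Cohort) -> dict:
    """Population summaries: prevalence, case HLA carriage, allelic OR."""
    n = cohort.n
    if n == 0:
        raise ValueError("empty cohort")
    affected = cohort.affected
    n_cases = int(affected.sum())
    out: dict = {"n": n, "n_cases": n_cases,
                 "prevalence": n_cases / n,
                 "susceptible_fraction": float(cohort.susceptible.mean())}
    hla_copies = (cohort.alleles[:, 0, :] == 1).sum(axis=1)
    if n_cases == 0:
        out.update({"hm_hat": None, "c_hat": None, "allelic_or": None})
        return out
    out["hm_hat"] = float(cohort.hla_carrier[affected].mean())
    out["c_hat"] = 1.0 - out["hm_hat"]
    a_case = float(hla_copies[affected].mean() / 2.0)
    controls = ~affected
    a_ctrl = float(hla_copies[controls].mean() / 2.0)
    if 0.0 < a_case < 1.0 and 0.0 < a_ctrl < 1.0:
        out["allelic_or"] = (a_case / (1 - a_case)) / (a_ctrl / (1 - a_ctrl))
    else:
        out["allelic_or"] = None
    return out


def recurrence_estimate(ped: PedigreeSet, proband_hla: bool | None = None) -> dict:
    """P(relative affected | proband(s) affected [, proband HLA status])."""
    mask = ped.proband_affected_mask()
    if proband_hla is not None:
        carrier = ped.members[ped.proband_roles[0]]["hla_carrier"]
        mask &= carrier if proband_hla else ~carrier
    n_cond = int(mask.sum())
    acceptance = n_cond / ped.n_families
    if acceptance < 1e-4:
        warnings.warn(
            f"conditioning acceptance {acceptance:.2e} below 1e-4; "
            "estimates will be noisy", stacklevel=2)
    if n_cond == 0:
        return {"estimate": None, "n": 0, "ci": (None, None)}
    k = int(ped.members[ped.relative_role]["affected"][mask].sum())
    est, lo, hi = _proportion_ci(k, n_cond)
    return {"estimate": est, "n": n_cond, "ci": (lo, hi)}


def carrier_sharing_estimate(ped: PedigreeSet, proband_carrier: bool = True) -> dict:
    """P(relative carries the HLA allele | proband's carrier status),
    unconditional on affection (checks the transmission algebra directly)."""
    carrier = ped.members[ped.proband_roles[0]]["hla_carrier"]
    mask = carrier if proband_carrier else ~carrier
    n_cond = int(mask.sum())
    if n_cond == 0:
        return {"estimate": None, "n": 0, "ci": (None, None)}
    k = int(ped.members[ped.relative_role]["hla_carrier"][mask].sum())
    est, lo, hi = _proportion_ci(k, n_cond)
    return {"estimate": est, "n": n_cond, "ci": (lo, hi)}


def mean_ibd_sharing(structure: RelativeClass, n_families: int, seed: int) -> float:
    """Monte Carlo identity-by-descent sharing between proband and relative.

    Founders at a single neutral locus get globally unique allele labels;
    sharing is twice the kinship estimate (0.5 sibs, 0.25 avuncular,
    0.125 first cousins, 1.0 MZ twins).
    """
    topo, proband_roles, relative_role = _TOPOLOGIES[RelativeClass(structure)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    label_counter = [0]

    def draw_labels(n: int) -> np.ndarray:
        start = label_counter[0]
        label_counter[0] += 2 * n
        return np.arange(start, start + 2 * n, dtype=np.int64).reshape(n, 1, 2)

    genotypes: dict[str, np.ndarray] = {}
    for role, parents in topo:
        if parents is None:
            genotypes[role] = draw_labels(n_families)
        elif parents == "=proband":
            genotypes[role] = genotypes["proband"].copy()
        else:
            genotypes[role] = _mate(rng, genotypes[parents[0]], genotypes[parents[1]])
    a = genotypes[proband_roles[0]][:, 0, :]
    b = genotypes[relative_role][:, 0, :]
    matches = (a[:, :, None] == b[:, None, :]).mean(axis=(1, 2))
    return float(2.0 * matches.mean())


# ---------------------------------------------------------------------------
# text export

def write_individuals_tsv(obj: Cohort | PedigreeSet, path) -> None:
    """One row per person: family, role, phenotype, HLA copies, locus states."""
    obj.to_frame().to_csv(path, sep="\t", index=False)


def write_plink(ped: PedigreeSet, prefix) -> None:
    """Minimal PLINK-style PED/MAP text pair for interoperability.

    Allele codes: 1 = neutral, 2 = susceptibility allele, 3 = second
    (recessive-acting) allele at a mixed locus.  Phenotype 2 = affected.
    """
    prefix = str(prefix)
    n_loci = next(iter(ped.members.values()))["alleles"].shape[1]
    with open(prefix + ".map", "w") as fh:
        for j in range(n_loci):
            name = "HLA" if j == 0 else f"L{j}"
            fh.write(f"1\t{name}\t0\t{j + 1}\n")
    with open(prefix + ".ped", "w") as fh:
        for fam in range(ped.n_families):
            for role, m in ped.members.items():
                geno = m["alleles"][fam] + 1
                geno_str = "\t".join(f"{a}\t{b}" for a, b in geno)
                pheno = 2 if m["affected"][fam] else 1
                fh.write(f"{fam}\t{role}\t0\t0\t0\t{pheno}\t{geno_str}\n")
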