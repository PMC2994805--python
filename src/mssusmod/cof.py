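"""Grid search over (r, n, dominance composition) with a closeness-of-fit score.

For every grid point the locus-count constraint is solved, the model's
prevalence and relative recurrence risks are evaluated at the low and high
ends of the admissible x-range, and the squared relative deviations of those
high/low estimates from the observed epidemiological targets are summed into
the Closeness-of-Fit (CoF) statistic

    CoF = sum_targets [ (H - E)/E + (L - E)/E ]^2

treated like a chi-square with one degree of freedom: configurations with
CoF < 4 are "reasonably close".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from . import solver
from .parameters import ModelParameters, RelativeClass

__all__ = ["FitTarget", "FitTargets", "GridCell", "cof", "predictions_for",
           "sweep", "find_optimum", "grid_frame"]

R_GRID_DEFAULT = (0.25, 0.33, 0.5, 1, 2, 4, 8, 16)
N_RANGE_DEFAULT = range(5, 61)

#: outcome name -> relative class evaluated for it (prevalence has none)
OUTCOME_RELATIVES: dict[str, RelativeClass | None] = {
    "prevalence": None,
    "sibling": RelativeClass.SIBLING,
    "conjugal_offspring": RelativeClass.CONJUGAL_OFFSPRING,
    "parent_child": RelativeClass.PARENT_CHILD,
    "second_degree": RelativeClass.AUNT_UNCLE,
    "third_degree": RelativeClass.FIRST_COUSIN,
}


@dataclass(frozen=True)
class FitTarget:
    """Observed range (low, high) and CoF reference point E, as fractions."""

    low: float
    high: float
    E: float

    def __post_init__(self) -> None:
        if not self.low <= self.high:
            raise ValueError("target range must satisfy low <= high")


@dataclass(frozen=True)
class FitTargets:
    """The six observed epidemiological targets, all as plain fractions.

    The conjugal-offspring observation ("~10%") has no published range, so
    low = high = E there.  The relative deviations entering CoF are
    unit-free; rescaling a target's (low, high, E) together leaves CoF
    unchanged.
    """

    prevalence: FitTarget = FitTarget(0.001, 0.002, 0.0015)
    sibling: FitTarget = FitTarget(0.029, 0.038, 0.030)
    conjugal_offspring: FitTarget = FitTarget(0.10, 0.10, 0.10)
    parent_child: FitTarget = FitTarget(0.018, 0.021, 0.020)
    second_degree: FitTarget = FitTarget(0.009, 0.016, 0.010)
    third_degree: FitTarget = FitTarget(0.009, 0.009, 0.009)

    def as_dict(self) -> dict[str, FitTarget]:
        return {name: getattr(self, name) for name in OUTCOME_RELATIVES}


def cof(cells: dict[str, tuple[float, float, float]],
        include: tuple[str, ...] | None = None) -> float:
    """Closeness of fit from per-target (H, L, E) triples.

    ``include`` restricts the summed targets (all by default; the original
    text speaks of five summands while listing six targets, so the inclusion
    list is configurable).  Targets with E = 0 are skipped with a warning.
    """
    total = 0.0
    for name, (high, low, e) in cells.items():
        if include is not None and name not in include:
            continue
        if e == 0.0:
            warnings.warn(f"target {name!r} has E = 0 and is excluded from CoF",
                          stacklevel=2)
            continue
        total += ((high - e) / e + (low - e) / e) ** 2
    return total


def predictions_for(params: ModelParameters, x_low: int, x_high: int,
                    conjugal_ph_corrected: bool = False) -> dict[str, tuple[float, float]]:
    """(low, high) model predictions for every outcome over an x-range.

    Evaluated at the two endpoints only, matching the convention that the
    ends of the admissible range give the high and low estimates.
    """
    out: dict[str, tuple[float, float]] = {}
    p_lo, p_hi = params.with_x(x_low), params.with_x(x_high)
    for name, rel in OUTCOME_RELATIVES.items():
        if rel is None:
            vals = (solver.prevalence(p_lo), solver.prevalence(p_hi))
        else:
            vals = (
                solver.expected_recurrence(p_lo, rel, conjugal_ph_corrected),
                solver.expected_recurrence(p_hi, rel, conjugal_ph_corrected),
            )
        out[name] = (min(vals), max(vals))
    return out


@dataclass(frozen=True)
class GridCell:
    """One (r, n) grid point: solved x-range, predictions, CoF."""

    r: float
    n: int
    composition: tuple[float, float, float]
    solution: solver.SolutionRange
    predictions: dict[str, tuple[float, float]] = field(default_factory=dict)
    cof: float | None = None

    @property
    def feasible(self) -> bool:
        return self.solution.feasible


def sweep(
    r_grid=R_GRID_DEFAULT,
    n_range=N_RANGE_DEFAULT,
    composition: tuple[float, float, float] = (0.2, 0.8, 0.0),
    targets: FitTargets | None = None,
    base: ModelParameters | None = None,
    tol: float = 0.05,
    include: tuple[str, ...] | None = None,
    x_min: int = solver.X_SCAN_MIN,
    x_max: int = solver.X_SCAN_MAX,
) -> list[GridCell]:
    """Sweep the (r, n) grid at a fixed dominance composition.

    ``base`` carries the epidemiological constants (h, penetrances, C);
    only its (n, r, x) fields are overridden per cell.  Cells whose x-scan
    band is empty are returned infeasible, with no predictions.
    """
    if not r_grid or not len(list(n_range)):
        raise ValueError("grids must be non-empty")
    targets = targets or FitTargets()
    tdict = targets.as_dict()
    proto = base or ModelParameters.with_composition(n=5, r=1.0, x=10, composition=composition)
    cells: list[GridCell] = []
    for r in r_grid:
        for n in n_range:
            params = ModelParameters.with_composition(
                n=n, r=float(r), x=max(n, x_min), composition=composition,
                h=proto.h, h_m=proto.h_m, Pt0_star=proto.Pt0_star,
                Pt1_star=proto.Pt1_star, C=proto.C,
                dz_sib_ratio=proto.dz_sib_ratio, P_MS_target=proto.P_MS_target,
            )
            sol = solver.solve_x(n, float(r), params.C_star, tol=tol,
                                 x_min=x_min, x_max=x_max)
            if not sol.feasible:
                cells.append(GridCell(r=float(r), n=n, composition=composition,
                                      solution=sol))
                continue
            preds = predictions_for(params, sol.x_low, sol.x_high)
            triples = {
                name: (preds[name][1], preds[name][0], tdict[name].E)
                for name in preds
            }
            cells.append(GridCell(
                r=float(r), n=n, composition=composition, solution=sol,
                predictions=preds, cof=cof(triples, include=include),
            ))
    return cells


def find_optimum(cells: list[GridCell], threshold: float = 4.0
                 ) -> tuple[GridCell, list[GridCell]]:
    """Best-fitting feasible cell and the acceptable set {CoF < threshold}.

    Ties on CoF break toward smaller n, then smaller r.
    """
    feasible = [c for c in cells if c.feasible and c.cof is not None]
    if not feasible:
        raise ValueError("all grid cells are infeasible")
    best = min(feasible, key=lambda c: (c.cof, c.n, c.r))
    acceptable = [c for c in feasible if c.cof < threshold]
    return best, acceptable


def grid_frame(cells: list[GridCell]) -> pd.DataFrame:
    """Tidy table: one row per (r, n); predictions as low/high columns."""
    rows = []
    for c in cells:
        row = {
            "r": c.r, "n": c.n,
            "dominant_frac": c.composition[0],
            "recessive_frac": c.composition[1],
            "mixed_frac": c.composition[2],
            "x_low": c.solution.x_low, "x_high": c.solution.x_high,
            "x_continuous": c.solution.x_continuous,
            "feasible": c.feasible, "cof": c.cof,
        }
        for name, (lo, hi) in c.predictions.items():
            row[f"{name}_low"] = lo
            row[f"{name}_high"] = hi
        rows.append(row)
    return pd.DataFrame(rows)
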