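"""Chemical-equilibrium speciation of Hg(II) and MeHg in sulfidic brackish water.

The equilibrium problem is posed as a standard tableau: a set of *components*
(Hg2+, CH3Hg+, H+, Cl-, HS-, DOM thiolate RS-, H2O) and *species* formed from
them by mass action,

    log10 c_i = logK_i + sum_j nu_ij * log10 a_j ,

where ``a_j`` is the free concentration of component ``j`` (activity
coefficients are unity; the shipped constants are conditioned to brackish
ionic strength).  Components are either *total* mode (a mass balance must
close) or *fixed* mode (free concentration imposed, e.g. H+ via pH).  One
solid phase, metacinnabar HgS(s), may form; it is handled by a two-stage
algorithm: solve aqueous-only, and if the solid is supersaturated re-solve
with its saturation index pinned at zero and its amount as an extra unknown.

The quantity of biogeochemical interest is the fraction of total Hg(II)
present as *dissolved* Hg-sulfide species (HgS2H-, Hg(SH)2, HgS2^2-) — the
pool available to methylating microorganisms — as opposed to thiol-bound or
solid HgS(s) pools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Component",
    "SpeciesDef",
    "SpeciationTableau",
    "SpeciationInput",
    "SpeciationResult",
    "load_tableau",
    "default_tableau",
    "thiol_from_doc",
    "solve_equilibrium",
    "diss_sulfide_fraction",
    "regime_scan",
    "RegimeScanResult",
    "speciate_profile",
    "representative_input",
]

# molar mass of carbon, g/mol, for DOC -> thiol-site conversion
_CARBON_G_PER_MOL = 12.011
# weight fraction of DOC carbon carrying reduced-sulfur (thiol) binding sites
_THIOL_FRACTION_OF_DOC = 0.0015

# solver settings
_RESIDUAL_TOL = 1e-11
_MAX_ITER = 200
_MAX_STEP_LOG = 3.0  # max Newton step per unknown, log10 units
# deterministic multi-start: free/total dilution factors tried in order
_START_DILUTIONS = (1e-6, 1e-2, 1e-10)


# ---------------------------------------------------------------------------
# tableau data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    """One chemical component (building block) of the tableau.

    ``mode`` is ``"total"`` (a mass balance over all species must close on
    ``total_conc``) or ``"fixed"`` (the free concentration/activity is imposed,
    used for H+ at a given pH, Cl- and H2O).
    """

    name: str
    mode: str = "total"
    total_conc: float = 0.0
    fixed_free_value: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("total", "fixed"):
            raise ValueError(f"component {self.name}: unknown mode {self.mode!r}")
        if self.mode == "total" and self.total_conc < 0:
            raise ValueError(f"component {self.name}: negative total")
        if self.mode == "fixed" and (
            self.fixed_free_value is None or self.fixed_free_value <= 0
        ):
            raise ValueError(f"component {self.name}: fixed mode needs a positive free value")


@dataclass(frozen=True)
class SpeciesDef:
    """A species formed from components: stoichiometry vector and log10 K."""

    name: str
    stoichiometry: tuple[int, ...]
    logK: float
    phase: str = "aqueous"

    def __post_init__(self) -> None:
        if self.phase not in ("aqueous", "solid"):
            raise ValueError(f"species {self.name}: unknown phase {self.phase!r}")


@dataclass(frozen=True)
class SpeciationTableau:
    """Components + species defining one equilibrium problem."""

    components: tuple[Component, ...]
    species: tuple[SpeciesDef, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        n = len(self.components)
        for sp in self.species:
            if len(sp.stoichiometry) != n:
                raise ValueError(
                    f"species {sp.name}: stoichiometry length {len(sp.stoichiometry)}"
                    f" != {n} components"
                )
        if sum(1 for sp in self.species if sp.phase == "solid") > 1:
            raise ValueError("at most one solid phase is supported")

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def component_index(self, name: str) -> int:
        return self.component_names.index(name)

    def stoich_matrix(self, phase: str | None = None) -> np.ndarray:
        """(n_species, n_components) signed stoichiometry; optionally one phase."""
        rows = [
            s.stoichiometry
            for s in self.species
            if phase is None or s.phase == phase
        ]
        return np.array(rows, dtype=float).reshape(len(rows), len(self.components))

    def with_totals(self, totals: dict[str, float]) -> "SpeciationTableau":
        """Return a copy with total concentrations set for named components."""
        comps = []
        for c in self.components:
            if c.name in totals:
                if c.mode != "total":
                    raise ValueError(f"component {c.name} is fixed-mode, cannot set total")
                comps.append(Component(c.name, "total", float(totals[c.name])))
            else:
                comps.append(c)
        return SpeciationTableau(tuple(comps), self.species, self.version)


def load_tableau(path_or_stream) -> SpeciationTableau:
    """Load a tableau from a YAML config (components, species rows, version)."""
    if hasattr(path_or_stream, "read"):
        doc = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            doc = yaml.safe_load(fh)
    comps = tuple(
        Component(
            name=c["name"],
            mode=c.get("mode", "total"),
            total_conc=float(c.get("total_conc", 0.0)),
            fixed_free_value=(
                float(c["fixed_free_value"]) if "fixed_free_value" in c else None
            ),
        )
        for c in doc["components"]
    )
    names = [c.name for c in comps]
    species = []
    for s in doc["species"]:
        stoich = [0] * len(comps)
        for comp_name, nu in s["stoichiometry"].items():
            if comp_name not in names:
                raise ValueError(f"species {s['name']} references unknown component {comp_name}")
            stoich[names.index(comp_name)] = int(nu)
        species.append(
            SpeciesDef(s["name"], tuple(stoich), float(s["logK"]), s.get("phase", "aqueous"))
        )
    return SpeciationTableau(comps, tuple(species), str(doc.get("version", "unversioned")))


def default_tableau() -> SpeciationTableau:
    """The shipped Baltic-conditions tableau (7 components, 24 species)."""
    ref = resources.files("hgstrat.data").joinpath("tableau_baltic_v1.yaml")
    with ref.open() as fh:
        return load_tableau(fh)


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

def thiol_from_doc(doc: float) -> float:
    """Thiol binding-site concentration (mol/L) from DOC (mg C/L).

    Thiol sites are estimated as 0.15 % of DOC carbon on a molar basis:
    ``0.0015 * doc / 12.011 * 1e-3`` mol sites per litre.
    """
    if doc < 0:
        raise ValueError("DOC must be non-negative")
    return _THIOL_FRACTION_OF_DOC * doc / _CARBON_G_PER_MOL * 1e-3


@dataclass(frozen=True)
class SpeciationInput:
    """Per-sample totals driving one equilibrium solve.

    ``hg2_total`` is inorganic Hg(II), computed upstream as HgT - MeHg.
    Concentrations in mol/L; pH fixed (default 7.3), Cl- free fixed
    (default 90 mM, brackish Baltic value).
    """

    hg2_total: float
    mehg_total: float
    h2s_total: float
    doc: float
    pH: float = 7.3
    cl_free: float = 0.090

    def __post_init__(self) -> None:
        for name in ("hg2_total", "mehg_total", "h2s_total", "doc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @classmethod
    def from_observations(
        cls, hgt: float, mehg: float, h2s: float, doc: float, **kw
    ) -> "SpeciationInput":
        """Build from observed HgT/MeHg; Hg(II) = HgT - MeHg (must be >= 0)."""
        if hgt < mehg:
            raise ValueError(f"HgT ({hgt}) < MeHg ({mehg}): Hg(II) would be negative")
        return cls(hg2_total=hgt - mehg, mehg_total=mehg, h2s_total=h2s, doc=doc, **kw)


def representative_input(h2s_total: float = 1e-5) -> SpeciationInput:
    """Representative euxinic-zone water: Hg(II) 2.4 pM, MeHg 1 pM, DOC 4 mg/L."""
    return SpeciationInput(
        hg2_total=2.4e-12, mehg_total=1.0e-12, h2s_total=h2s_total, doc=4.0
    )


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

@dataclass
class SpeciationResult:
    """Solved equilibrium state at one depth/sample."""

    species_conc: dict[str, float]
    solid_amount: float
    free_conc: dict[str, float]
    hg_fractions: dict[str, float]
    diss_sulfide_fraction: float
    converged: bool
    iterations: int
    saturation_index: float = float("-inf")
    tableau_version: str = "unversioned"

    def to_json(self) -> str:
        return json.dumps(
            {
                "species_conc": self.species_conc,
                "solid_amount": self.solid_amount,
                "free_conc": self.free_conc,
                "hg_fractions": self.hg_fractions,
                "diss_sulfide_fraction": self.diss_sulfide_fraction,
                "converged": self.converged,
                "iterations": self.iterations,
                "tableau_version": self.tableau_version,
            }
        )


def _apply_input(tableau: SpeciationTableau, inp: SpeciationInput) -> SpeciationTableau:
    comps = []
    for c in tableau.components:
        if c.name == "Hg2":
            comps.append(Component("Hg2", "total", inp.hg2_total))
        elif c.name == "MeHg":
            comps.append(Component("MeHg", "total", inp.mehg_total))
        elif c.name == "HS":
            comps.append(Component("HS", "total", inp.h2s_total))
        elif c.name == "RS":
            comps.append(Component("RS", "total", thiol_from_doc(inp.doc)))
        elif c.name == "H":
            comps.append(Component("H", "fixed", fixed_free_value=10.0 ** (-inp.pH)))
        elif c.name == "Cl":
            comps.append(Component("Cl", "fixed", fixed_free_value=inp.cl_free))
        else:
            comps.append(c)
    return SpeciationTableau(tuple(comps), tableau.species, tableau.version)


class _Problem:
    """Index bookkeeping for one solve: active unknowns, fixed logs, matrices."""

    def __init__(self, tableau: SpeciationTableau):
        self.tableau = tableau
        self.aq_idx = [i for i, s in enumerate(tableau.species) if s.phase == "aqueous"]
        solid_idx = [i for i, s in enumerate(tableau.species) if s.phase == "solid"]
        self.solid_idx = solid_idx[0] if solid_idx else None

        n_comp = len(tableau.components)
        self.log_fixed = np.zeros(n_comp)  # log10 activity of fixed comps
        self.unknown = []   # component indices solved by Newton
        self.zeroed = []    # total-mode comps with total == 0
        self.totals = np.zeros(n_comp)
        for j, c in enumerate(tableau.components):
            if c.mode == "fixed":
                self.log_fixed[j] = np.log10(c.fixed_free_value)
            elif c.total_conc > 0:
                self.unknown.append(j)
                self.totals[j] = c.total_conc
            else:
                self.zeroed.append(j)

        S = tableau.stoich_matrix()
        # species that involve a zeroed component with positive stoichiometry
        # have zero concentration; species consuming a zeroed component are
        # not representable (would be infinite) -> also zero, flagged invalid
        self.dead_species = {
            i
            for i in range(len(tableau.species))
            if any(S[i, j] != 0 for j in self.zeroed)
        }
        self.S = S
        self.logK = np.array([s.logK for s in tableau.species])

    def species_log_conc(self, x_log: np.ndarray) -> np.ndarray:
        """log10 concentration of every species given unknown free logs."""
        log_free = self.log_fixed.copy()
        log_free[self.unknown] = x_log
        # zeroed comps never contribute (dead species masked separately)
        logc = self.logK + self.S @ log_free
        return np.clip(logc, -300.0, 300.0)

    def residual(self, x_log: np.ndarray, n_solid: float | None) -> np.ndarray:
        logc = self.species_log_conc(x_log)
        c = 10.0 ** logc
        for i in self.dead_species:
            c[i] = 0.0
        res = []
        for k, j in enumerate(self.unknown):
            tot = 10.0 ** x_log[k]  # free component itself
            for i in self.aq_idx:
                if self.S[i, j] != 0:
                    tot += self.S[i, j] * c[i]
            if n_solid is not None and self.solid_idx is not None:
                tot += self.S[self.solid_idx, j] * n_solid
            res.append((tot - self.totals[j]) / self.totals[j])
        if n_solid is not None and self.solid_idx is not None:
            res.append(self.saturation_index(x_log))
        return np.array(res)

    def jacobian(self, x_log: np.ndarray, n_solid: float | None) -> np.ndarray:
        logc = self.species_log_conc(x_log)
        c = 10.0 ** logc
        for i in self.dead_species:
            c[i] = 0.0
        ln10 = np.log(10.0)
        m = len(self.unknown)
        extra = 1 if (n_solid is not None and self.solid_idx is not None) else 0
        J = np.zeros((m + extra, m + extra))
        for a, j in enumerate(self.unknown):
            for b, k in enumerate(self.unknown):
                acc = 10.0 ** x_log[a] if a == b else 0.0
                for i in self.aq_idx:
                    if self.S[i, j] != 0 and self.S[i, k] != 0:
                        acc += self.S[i, j] * self.S[i, k] * c[i]
                J[a, b] = ln10 * acc / self.totals[j]
            if extra:
                J[a, m] = self.S[self.solid_idx, j] / self.totals[j]
        if extra:
            for b, k in enumerate(self.unknown):
                J[m, b] = self.S[self.solid_idx, k]
            J[m, m] = 0.0
        return J

    def saturation_index(self, x_log: np.ndarray) -> float:
        """log10(IAP/Ksp) for the solid; > 0 means supersaturated."""
        if self.solid_idx is None:
            return float("-inf")
        if self.solid_idx in self.dead_species:
            return float("-inf")
        log_free = self.log_fixed.copy()
        log_free[self.unknown] = x_log
        i = self.solid_idx
        return float(self.logK[i] + self.S[i] @ log_free)


def _newton(problem: _Problem, x0: np.ndarray, with_solid: bool,
            n_solid0: float = 0.0) -> tuple[np.ndarray, float, bool, int]:
    """Damped Newton iteration; returns (x_log, n_solid, converged, iters)."""
    x = x0.copy()
    n_s = n_solid0
    m = len(problem.unknown)
    use_solid = with_solid and problem.solid_idx is not None
    r = problem.residual(x, n_s if use_solid else None)
    rnorm = np.max(np.abs(r)) if r.size else 0.0
    it = 0
    for it in range(1, _MAX_ITER + 1):
        if rnorm < _RESIDUAL_TOL:
            return x, n_s, True, it - 1
        J = problem.jacobian(x, n_s if use_solid else None)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        # damp the log-space part of the step
        if m:
            big = np.max(np.abs(step[:m]))
            if big > _MAX_STEP_LOG:
                step *= _MAX_STEP_LOG / big
        # backtracking line search on the residual norm
        lam = 1.0
        for _ in range(30):
            x_new = x + lam * step[:m]
            n_new = n_s + lam * step[m] if use_solid else n_s
            r_new = problem.residual(x_new, n_new if use_solid else None)
            rn_new = np.max(np.abs(r_new)) if r_new.size else 0.0
            if np.all(np.isfinite(r_new)) and rn_new < rnorm:
                break
            lam *= 0.5
        else:
            return x, n_s, rnorm < _RESIDUAL_TOL, it
        x, n_s, r, rnorm = x_new, n_new, r_new, rn_new
    return x, n_s, rnorm < _RESIDUAL_TOL, it


def solve_equilibrium(
    tableau: SpeciationTableau, inp: SpeciationInput | None = None
) -> SpeciationResult:
    """Solve the equilibrium problem; two-stage aqueous/solid algorithm.

    If ``inp`` is given, the tableau's Hg2/MeHg/HS/RS totals and H+/Cl- fixed
    values are set from it first (RS from DOC via :func:`thiol_from_doc`).
    A non-converged solve is returned flagged, never raised.
    """
    if inp is not None:
        tableau = _apply_input(tableau, inp)
    problem = _Problem(tableau)

    # trivially empty problem (all totals zero)
    if not problem.unknown:
        return _package_result(tableau, problem, np.zeros(0), 0.0, True, 0)

    totals_log = np.log10(problem.totals[problem.unknown])
    best = None
    total_iters = 0
    for dil in _START_DILUTIONS:
        x0 = totals_log + np.log10(dil)
        x, n_s, ok, iters = _newton(problem, x0, with_solid=False)
        total_iters += iters
        if ok:
            best = (x, iters)
            break
    if best is None:
        return _package_result(tableau, problem, x, 0.0, False, total_iters)

    x, _ = best
    si = problem.saturation_index(x)
    n_solid = 0.0
    converged = True
    if si > 1e-9 and problem.solid_idx is not None:
        # supersaturated: re-solve with the solid pinned at saturation
        i = problem.solid_idx
        caps = [
            problem.totals[j] / problem.S[i, j]
            for j in problem.unknown
            if problem.S[i, j] > 0
        ]
        n0 = 0.5 * min(caps) if caps else 0.0
        x2, n_solid, ok2, iters2 = _newton(problem, x, with_solid=True, n_solid0=n0)
        total_iters += iters2
        if ok2 and n_solid > 0:
            x, si = x2, problem.saturation_index(x2)
        else:
            # solid dropped out (negative amount) or failed: keep aqueous
            n_solid = 0.0
            converged = ok2 or converged
            if ok2:
                x, si = x2, problem.saturation_index(x2)
    return _package_result(tableau, problem, x, n_solid, converged, total_iters, si)


def _package_result(
    tableau: SpeciationTableau,
    problem: _Problem,
    x_log: np.ndarray,
    n_solid: float,
    converged: bool,
    iterations: int,
    si: float | None = None,
) -> SpeciationResult:
    names = tableau.species_names
    conc = 10.0 ** problem.species_log_conc(x_log)
    for i in problem.dead_species:
        conc[i] = 0.0
    species_conc = {}
    for i, s in enumerate(tableau.species):
        species_conc[s.name] = 0.0 if s.phase == "solid" else float(conc[i])

    free = {}
    for j, c in enumerate(tableau.components):
        if c.mode == "fixed":
            free[c.name] = float(c.fixed_free_value)
        elif j in problem.zeroed:
            free[c.name] = 0.0
        else:
            free[c.name] = float(10.0 ** x_log[problem.unknown.index(j)])

    hg_fractions, dsf = _hg_partition(tableau, species_conc, n_solid, free)
    if si is None:
        si = problem.saturation_index(x_log) if len(problem.unknown) else float("-inf")
    return SpeciationResult(
        species_conc=species_conc,
        solid_amount=float(n_solid),
        free_conc=free,
        hg_fractions=hg_fractions,
        diss_sulfide_fraction=dsf,
        converged=converged,
        iterations=iterations,
        saturation_index=float(si),
        tableau_version=tableau.version,
    )


def _hg_partition(
    tableau: SpeciationTableau,
    species_conc: dict[str, float],
    n_solid: float,
    free: dict[str, float],
) -> tuple[dict[str, float], float]:
    """Per-species share of total Hg(II), and the dissolved-sulfide fraction."""
    if "Hg2" not in tableau.component_names:  # toy tableaus without Hg
        return {}, 0.0
    j_hg = tableau.component_index("Hg2")
    j_hs = tableau.component_index("HS") if "HS" in tableau.component_names else None
    contributions: dict[str, float] = {}
    total = free.get("Hg2", 0.0)
    if free.get("Hg2", 0.0) > 0:
        contributions["Hg2+"] = free["Hg2"]
    diss_sulf = 0.0
    for s in tableau.species:
        nu = s.stoichiometry[j_hg]
        if nu <= 0:
            continue
        amount = n_solid if s.phase == "solid" else species_conc[s.name]
        contributions[s.name] = nu * amount
        total += nu * amount
        if (
            s.phase == "aqueous"
            and j_hs is not None
            and s.stoichiometry[j_hs] > 0
        ):
            diss_sulf += nu * amount
    if total <= 0:
        return {}, 0.0
    fractions = {k: v / total for k, v in contributions.items()}
    return fractions, diss_sulf / total


def diss_sulfide_fraction(result: SpeciationResult) -> float:
    """Fraction of total Hg(II) present as dissolved Hg-sulfide species.

    Sum of aqueous species containing both Hg and sulfide over total Hg(II)
    including any solid; 0 by convention when there is no Hg(II).
    """
    if not result.converged:
        raise ValueError("diss_sulfide_fraction requires a converged result")
    return result.diss_sulfide_fraction


# ---------------------------------------------------------------------------
# regime scan
# ---------------------------------------------------------------------------

_POOLS = ("thiol-bound", "HgS(s)", "dissolved-sulfide", "other")


def _pool_of_species(tableau: SpeciationTableau, name: str) -> str:
    if name == "Hg2+":
        return "other"
    sp = tableau.species[tableau.species_names.index(name)]
    j_hs = tableau.component_index("HS")
    j_rs = tableau.component_index("RS")
    if sp.phase == "solid":
        return "HgS(s)"
    if sp.stoichiometry[j_hs] > 0:
        return "dissolved-sulfide"
    if sp.stoichiometry[j_rs] > 0:
        return "thiol-bound"
    return "other"


@dataclass
class RegimeScanResult:
    h2s_grid: np.ndarray
    pool_fractions: pd.DataFrame  # index h2s, columns pools
    dominant: list[str]
    crossovers: list[tuple[str, str, float]]  # (from_pool, to_pool, h2s mol/L)
    excluded: list[float]  # grid points that failed to converge


def regime_scan(
    tableau: SpeciationTableau,
    template_input: SpeciationInput,
    h2s_grid: Sequence[float],
) -> RegimeScanResult:
    """Dominant Hg(II) pool along an H2S gradient, with crossover locations.

    At each grid point the template input is solved with that ``h2s_total``;
    species are grouped into thiol-bound, solid HgS(s), dissolved-sulfide and
    other pools, the largest pool is the dominant one, and dominance switches
    are located by log-linear interpolation of the leading pools' fraction
    difference between bracketing grid points (linear when a bracketing H2S
    is zero).
    """
    grid = np.asarray(h2s_grid, dtype=float)
    if grid.size < 3 or np.any(np.diff(grid) <= 0):
        raise ValueError("h2s_grid must be strictly increasing with >= 3 points")

    rows, dominant, kept, excluded = [], [], [], []
    for h2s in grid:
        inp = SpeciationInput(
            hg2_total=template_input.hg2_total,
            mehg_total=template_input.mehg_total,
            h2s_total=float(h2s),
            doc=template_input.doc,
            pH=template_input.pH,
            cl_free=template_input.cl_free,
        )
        res = solve_equilibrium(tableau, inp)
        if not res.converged:
            excluded.append(float(h2s))
            continue
        pools = dict.fromkeys(_POOLS, 0.0)
        for name, frac in res.hg_fractions.items():
            pools[_pool_of_species(tableau, name)] += frac
        rows.append(pools)
        dominant.append(max(pools, key=pools.get))
        kept.append(float(h2s))

    frame = pd.DataFrame(rows, index=pd.Index(kept, name="h2s_total"))
    crossovers = []
    for a in range(1, len(kept)):
        p_prev, p_next = dominant[a - 1], dominant[a]
        if p_prev == p_next:
            continue
        d0 = frame.iloc[a - 1][p_prev] - frame.iloc[a - 1][p_next]
        d1 = frame.iloc[a][p_prev] - frame.iloc[a][p_next]
        x0, x1 = kept[a - 1], kept[a]
        if d0 == d1:
            xc = 0.5 * (x0 + x1)
        elif x0 > 0:
            lx = np.log10(x0) + (np.log10(x1) - np.log10(x0)) * d0 / (d0 - d1)
            xc = 10.0 ** lx
        else:
            xc = x0 + (x1 - x0) * d0 / (d0 - d1)
        crossovers.append((p_prev, p_next, float(xc)))
    return RegimeScanResult(grid, frame, dominant, crossovers, excluded)


# ---------------------------------------------------------------------------
# profile driver
# ---------------------------------------------------------------------------

def speciate_profile(
    tableau: SpeciationTableau, profile: pd.DataFrame
) -> pd.DataFrame:
    """Solve speciation for each row of a depth profile.

    Expects columns ``depth_m, hgt_fM, mehg_fM, h2s_uM, doc_mgL`` (fM/uM as
    observed units; converted internally to mol/L).  Rows that violate
    preconditions (HgT < MeHg) or fail to converge are flagged via the
    ``valid``/``converged`` columns rather than raised.
    """
    out = []
    for _, row in profile.iterrows():
        rec = {"depth_m": row["depth_m"]}
        try:
            inp = SpeciationInput.from_observations(
                hgt=row["hgt_fM"] * 1e-15,
                mehg=row["mehg_fM"] * 1e-15,
                h2s=row["h2s_uM"] * 1e-6,
                doc=row["doc_mgL"],
            )
        except ValueError as exc:
            rec.update(valid=False, converged=False, error=str(exc),
                       diss_sulfide_fraction=np.nan, diss_sulfide_conc_M=np.nan,
                       solid_fraction=np.nan)
            out.append(rec)
            continue
        res = solve_equilibrium(tableau, inp)
        hg_tot = inp.hg2_total
        rec.update(
            valid=True,
            converged=res.converged,
            error="",
            diss_sulfide_fraction=res.diss_sulfide_fraction,
            diss_sulfide_conc_M=res.diss_sulfide_fraction * hg_tot,
            solid_fraction=(res.solid_amount / hg_tot) if hg_tot > 0 else 0.0,
        )
        out.append(rec)
    return pd.DataFrame(out, columns=[
        "depth_m", "valid", "converged", "error",
        "diss_sulfide_fraction", "diss_sulfide_conc_M", "solid_fraction",
    ])
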