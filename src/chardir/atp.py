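"""Flux-balance ATP accounting: parsimonious flux fits and source attribution.

Given a stoichiometric model S and a cell line's measured exchange rates
(uptake negative, secretion positive), the flux distribution is the
solution of the parsimonious flux-balance LP

    min Σ_r |v_r|   s.t.   S·v = 0,  lb ≤ v ≤ ub,  measured exchanges fixed,

solved by splitting each flux into non-negative forward/backward parts.
Total ATP turnover is read off the positive ATP stoichiometry of the fitted
fluxes (production equals consumption at pseudo-steady state).  ATP is then
attributed to its sources: lactic fermentation of glucose is credited at
1 ATP per lactate secreted (canonical Embden–Meyerhof substrate-level
phosphorylation, 2 ATP per glucose fermented to 2 lactate; configurable),
and each branched-chain amino acid (Leu/Ile/Val) at its model-derived
maximal ATP yield per unit uptake — "full degradation and oxidation" —
computed by a secondary LP with all other organic uptakes closed.

Sign convention throughout: an exchange reaction carries one metabolite
across the system boundary; its *export rate* is −coeff·v, so with the
usual ``{met: -1}`` stoichiometry a positive flux secretes and a negative
flux takes up, matching the measured-rate convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger("chardir")

STEADY_STATE_TOL = 1e-9
_LP_OPTS = {"primal_feasibility_tolerance": 1e-10, "dual_feasibility_tolerance": 1e-10}

BCAA_ROLES = ("leucine", "isoleucine", "valine")


class ModelError(ValueError):
    pass


class FluxFitError(RuntimeError):
    pass


@dataclass
class MetabolicModel:
    """Stoichiometric network with flux bounds and exchange annotations.

    ``roles`` maps physiological names ("glucose", "lactate", "leucine",
    "isoleucine", "valine") to metabolite ids so that uptake tables and ATP
    attribution are independent of the model's naming scheme.
    ``inorganic`` lists boundary metabolites (O2, CO2, ammonium, ...) whose
    exchanges stay open during substrate-yield calculations.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray                      # metabolites × reactions
    lb: np.ndarray
    ub: np.ndarray
    exchange_map: dict[str, str]       # metabolite id -> exchange reaction id
    atp_meta: str
    inorganic: frozenset[str] = field(default_factory=frozenset)
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        nm, nr = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (nm, nr):
            raise ModelError(f"S shape {self.S.shape} != ({nm}, {nr})")
        if self.lb.shape != (nr,) or self.ub.shape != (nr,):
            raise ModelError("bounds must have one entry per reaction")
        for j, rid in enumerate(self.reaction_ids):
            if self.lb[j] > self.ub[j]:
                raise ModelError(f"reaction {rid!r}: lb {self.lb[j]} > ub {self.ub[j]}")
        if self.atp_meta not in self.metabolite_ids:
            raise ModelError(f"ATP species {self.atp_meta!r} not among metabolites")
        ridx = {r: j for j, r in enumerate(self.reaction_ids)}
        for met, rid in self.exchange_map.items():
            if met not in self.metabolite_ids:
                raise ModelError(f"exchange metabolite {met!r} unknown")
            if rid not in ridx:
                raise ModelError(f"exchange reaction {rid!r} unknown")
            col = self.S[:, ridx[rid]]
            if np.count_nonzero(col) != 1:
                raise ModelError(
                    f"exchange reaction {rid!r} must have exactly one nonzero "
                    f"stoichiometric entry, found {np.count_nonzero(col)}"
                )

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def exchange_coeff(self, met: str) -> tuple[int, float]:
        """Column index and stoichiometric coefficient of a metabolite's exchange."""
        rid = self.exchange_map.get(met)
        if rid is None:
            raise ModelError(f"metabolite {met!r} has no exchange reaction")
        j = self.reaction_index(rid)
        i = self.metabolite_ids.index(met)
        c = self.S[i, j]
        if c == 0:
            raise ModelError(f"exchange {rid!r} does not carry {met!r}")
        return j, c


@dataclass
class UptakeProfile:
    """Measured exchange rates of one cell line (uptake < 0, secretion > 0)."""

    cell_line: str
    measured: dict[str, float]   # metabolite id -> signed rate

    def __post_init__(self) -> None:
        for met, rate in self.measured.items():
            if not np.isfinite(rate):
                raise ValueError(f"{self.cell_line}: non-finite rate for {met}")


@dataclass
class FluxDistribution:
    reaction_ids: list[str]
    v: np.ndarray
    objective: float             # Σ|v| at the optimum

    def flux(self, rid: str) -> float:
        return float(self.v[self.reaction_ids.index(rid)])


@dataclass
class ATPBreakdown:
    """Per-cell-line ATP total and source fractions (Fig-5-style stacked data)."""

    cell_line: str
    total_atp: float
    frac_lactate: float
    frac_leu: float
    frac_ile: float
    frac_val: float
    frac_other: float

    def __post_init__(self) -> None:
        fracs = [self.frac_lactate, self.frac_leu, self.frac_ile, self.frac_val, self.frac_other]
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be non-negative")
        if self.total_atp > 0 and abs(sum(fracs) - 1.0) > 1e-6:
            raise ValueError(f"fractions sum to {sum(fracs)}, not 1")

    @property
    def frac_bcaa(self) -> float:
        return self.frac_leu + self.frac_ile + self.frac_val


# ---------------------------------------------------------------------------
# Model I/O
# ---------------------------------------------------------------------------

def model_from_dict(d: Mapping) -> MetabolicModel:
    mets = list(d["metabolites"])
    met_idx = {m: i for i, m in enumerate(mets)}
    rxns = d["reactions"]
    rids, lb, ub = [], [], []
    S = np.zeros((len(mets), len(rxns)))
    exchange_map: dict[str, str] = {}
    for j, r in enumerate(rxns):
        rid = r["id"]
        rids.append(rid)
        for met, coeff in r["stoich"].items():
            if met not in met_idx:
                raise ModelError(f"reaction {rid!r} references unknown metabolite {met!r}")
            S[met_idx[met], j] = float(coeff)
        lb.append(float(r.get("lb", -1000.0)))
        ub.append(float(r.get("ub", 1000.0)))
        if r.get("exchange", False):
            nz = [m for m, c in r["stoich"].items() if c != 0]
            if len(nz) != 1:
                raise ModelError(
                    f"exchange reaction {rid!r} must carry exactly one metabolite"
                )
            exchange_map[nz[0]] = rid
    return MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        exchange_map=exchange_map,
        atp_meta=d["atp"],
        inorganic=frozenset(d.get("inorganic", [])),
        roles=dict(d.get("roles", {})),
    )


def model_to_dict(model: MetabolicModel) -> dict:
    exch_rxns = set(model.exchange_map.values())
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        stoich = {
            m: float(model.S[i, j])
            for i, m in enumerate(model.metabolite_ids)
            if model.S[i, j] != 0
        }
        reactions.append(
            {"id": rid, "stoich": stoich, "lb": float(model.lb[j]),
             "ub": float(model.ub[j]), "exchange": rid in exch_rxns}
        )
    return {
        "metabolites": list(model.metabolite_ids),
        "reactions": reactions,
        "atp": model.atp_meta,
        "inorganic": sorted(model.inorganic),
        "roles": dict(model.roles),
    }


def load_model(path) -> MetabolicModel:
    """Load a model from the JSON dialect (see module docstring)."""
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def save_model(model: MetabolicModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)


def write_sbml(model: MetabolicModel, path) -> None:
    """Export to SBML Level 3 core (stoichiometry + reversibility only).

    Bounds beyond the reversible flag, the ATP species tag, roles and the
    inorganic list are not representable in plain L3 core and are dropped.
    """
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    m = doc.createModel()
    m.setId("chardir_model")
    comp = m.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    for met in model.metabolite_ids:
        sp = m.createSpecies()
        sp.setId(met)
        sp.setCompartment("cell")
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
    for j, rid in enumerate(model.reaction_ids):
        r = m.createReaction()
        r.setId(rid)
        r.setReversible(bool(model.lb[j] < 0))
        r.setFast(False)
        for i, met in enumerate(model.metabolite_ids):
            c = model.S[i, j]
            if c == 0:
                continue
            sr = r.createReactant() if c < 0 else r.createProduct()
            sr.setSpecies(met)
            sr.setStoichiometry(abs(float(c)))
            sr.setConstant(True)
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelError(f"failed to write SBML to {path}")


def read_sbml(path, atp_meta: str, default_bound: float = 1000.0,
              inorganic=(), roles: Optional[Mapping[str, str]] = None) -> MetabolicModel:
    """Import an SBML Level 3 core model.

    Bounds are reconstructed from the reversible flag as
    [-default_bound, default_bound] or [0, default_bound]; exchanges are
    detected as single-metabolite reactions.  The ATP species must be named
    explicitly since plain SBML does not tag it.
    """
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelError(f"SBML parse errors in {path}: "
                         f"{doc.getErrorLog().toString()}")
    m = doc.getModel()
    mets = [m.getSpecies(i).getId() for i in range(m.getNumSpecies())]
    reactions = []
    for i in range(m.getNumReactions()):
        r = m.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(r.getNumReactants()):
            sr = r.getReactant(k)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for k in range(r.getNumProducts()):
            sr = r.getProduct(k)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        lb = -default_bound if r.getReversible() else 0.0
        reactions.append({"id": r.getId(), "stoich": stoich, "lb": lb,
                          "ub": default_bound,
                          "exchange": len([c for c in stoich.values() if c != 0]) == 1})
    return model_from_dict({"metabolites": mets, "reactions": reactions,
                            "atp": atp_meta, "inorganic": list(inorganic),
                            "roles": dict(roles or {})})


# ---------------------------------------------------------------------------
# LP machinery
# ---------------------------------------------------------------------------

def _split_bounds(lb: np.ndarray, ub: np.ndarray) -> list[tuple[float, float]]:
    """Bounds for the forward/backward split v = f − r with f, r >= 0."""
    fwd = [(max(0.0, l), max(0.0, u)) for l, u in zip(lb, ub)]
    bwd = [(max(0.0, -u), max(0.0, -l)) for l, u in zip(lb, ub)]
    return fwd + bwd


def _apply_measurements(
    model: MetabolicModel, profile: UptakeProfile
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Fix measured exchange fluxes by collapsing their bounds.

    Returns adjusted (lb, ub) and the list of fixed reaction ids; raises if
    a measured rate violates the model's bounds.
    """
    lb, ub = model.lb.copy(), model.ub.copy()
    fixed = []
    violations = []
    for met, rate in profile.measured.items():
        j, c = model.exchange_coeff(met)
        target = rate / (-c)  # flux giving export rate == measured rate
        if target < model.lb[j] - 1e-12 or target > model.ub[j] + 1e-12:
            violations.append(f"{model.reaction_ids[j]} (target {target}, "
                              f"bounds [{model.lb[j]}, {model.ub[j]}])")
            continue
        lb[j] = ub[j] = target
        fixed.append(model.reaction_ids[j])
    if violations:
        raise FluxFitError(
            f"{profile.cell_line}: measured exchanges violate model bounds: "
            + "; ".join(violations)
        )
    return lb, ub, fixed


def fit_fluxes(model: MetabolicModel, profile: UptakeProfile) -> FluxDistribution:
    """Parsimonious flux fit: min Σ|v| s.t. S·v = 0 with measured exchanges fixed."""
    lb, ub, fixed = _apply_measurements(model, profile)
    nr = model.n_reactions
    cost = np.ones(2 * nr)
    A_eq = np.hstack([model.S, -model.S])
    b_eq = np.zeros(model.S.shape[0])
    res = linprog(cost, A_eq=A_eq, b_eq=b_eq, bounds=_split_bounds(lb, ub),
                  method="highs", options=_LP_OPTS)
    if res.status == 2:
        raise FluxFitError(
            f"{profile.cell_line}: flux fit infeasible with fixed exchanges {fixed}"
        )
    if res.status != 0:
        raise FluxFitError(f"{profile.cell_line}: LP failed: {res.message}")
    v = res.x[:nr] - res.x[nr:]
    resid = float(np.abs(model.S @ v).max()) if nr else 0.0
    if resid > STEADY_STATE_TOL:
        raise FluxFitError(f"steady-state residual {resid} exceeds {STEADY_STATE_TOL}")
    return FluxDistribution(reaction_ids=list(model.reaction_ids), v=v,
                            objective=float(res.fun))


def total_atp(model: MetabolicModel, flux: FluxDistribution) -> float:
    """Total ATP synthesis rate: Σ_r max(0, stoich_ATP(r) · v_r).

    By the pseudo-steady-state row S·v = 0 for ATP, production equals
    consumption, so this is also the cell's total ATP turnover.
    """
    i = model.metabolite_ids.index(model.atp_meta)
    contrib = model.S[i, :] * flux.v
    return float(np.clip(contrib, 0.0, None).sum())


def substrate_atp_yield(model: MetabolicModel, metabolite: str) -> float:
    """Maximal ATP per unit uptake of one substrate ("full oxidation" yield).

    LP: maximize total ATP consumption (equal to production at steady
    state, assuming ATP-consuming reactions run forward) subject to S·v = 0
    and bounds, with uptake of *metabolite* fixed at 1 and every other
    organic uptake closed; oxygen and the other inorganic exchanges stay
    open.  Returns 0 when the substrate cannot be metabolized (infeasible).
    """
    j_target, c_target = model.exchange_coeff(metabolite)
    lb, ub = model.lb.copy(), model.ub.copy()
    for met in model.exchange_map:
        if met == metabolite or met in model.inorganic:
            continue
        j, c = model.exchange_coeff(met)
        if c < 0:       # export-form exchange: uptake is negative flux
            lb[j] = max(lb[j], 0.0)
        else:           # import-form: uptake is positive flux
            ub[j] = min(ub[j], 0.0)
        if lb[j] > ub[j]:
            lb[j] = ub[j] = 0.0
    target_flux = (-1.0) / (-c_target)   # export rate −1 == uptake of 1 unit
    if target_flux < model.lb[j_target] - 1e-12 or target_flux > model.ub[j_target] + 1e-12:
        return 0.0
    lb[j_target] = ub[j_target] = target_flux

    i_atp = model.metabolite_ids.index(model.atp_meta)
    s_atp = model.S[i_atp, :]
    consume = np.clip(-s_atp, 0.0, None)       # coefficients of ATP consumers
    cost = -np.concatenate([consume, -consume])  # maximize consumption of net flux
    A_eq = np.hstack([model.S, -model.S])
    res = linprog(cost, A_eq=A_eq, b_eq=np.zeros(model.S.shape[0]),
                  bounds=_split_bounds(lb, ub), method="highs", options=_LP_OPTS)
    if res.status == 2:
        return 0.0
    if res.status == 3:
        raise ModelError(f"ATP yield of {metabolite!r} unbounded; model defect")
    if res.status != 0:
        raise ModelError(f"yield LP failed for {metabolite!r}: {res.message}")
    return max(0.0, float(-res.fun))


def atp_breakdown(
    model: MetabolicModel,
    flux: FluxDistribution,
    profile: UptakeProfile,
    atp_per_lactate: float = 1.0,
) -> ATPBreakdown:
    """Attribute total ATP to lactic fermentation, Leu/Ile/Val oxidation, and rest.

    Lactate-linked ATP = secretion rate × ``atp_per_lactate`` (default 1,
    i.e. 2 ATP per glucose fermented to 2 lactate).  Each BCAA contributes
    uptake × its model-derived maximal yield.  ``frac_other`` is the
    remainder (chiefly oxidative phosphorylation on other substrates).
    """
    for role in ("lactate",) + tuple(BCAA_ROLES):
        if role not in model.roles:
            raise ModelError(f"model roles must name the {role!r} metabolite")
    lac_met = model.roles["lactate"]
    lac_rate = profile.measured.get(lac_met, 0.0)
    if lac_rate < -1e-9:
        raise ValueError(
            f"{profile.cell_line}: lactate exchange {lac_rate} is an uptake; "
            "attribution assumes net secretion"
        )
    atp_lac = max(0.0, lac_rate) * atp_per_lactate
    atp_aa = {}
    for role in BCAA_ROLES:
        met = model.roles[role]
        uptake = max(0.0, -profile.measured.get(met, 0.0))
        atp_aa[role] = uptake * substrate_atp_yield(model, met) if uptake > 0 else 0.0

    total = total_atp(model, flux)
    sources = atp_lac + sum(atp_aa.values())
    if total <= 0:
        if sources > 1e-9:
            raise ValueError(
                f"{profile.cell_line}: attributed sources {sources} but total ATP is 0"
            )
        return ATPBreakdown(profile.cell_line, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def frac(x: float) -> float:
        f = x / total
        if f < -1e-6:
            raise ValueError(f"negative ATP fraction {f}")
        return max(0.0, f)

    f_lac = frac(atp_lac)
    f_leu = frac(atp_aa["leucine"])
    f_ile = frac(atp_aa["isoleucine"])
    f_val = frac(atp_aa["valine"])
    f_other = 1.0 - (f_lac + f_leu + f_ile + f_val)
    if f_other < -1e-6:
        raise ValueError(
            f"{profile.cell_line}: attributed ATP exceeds total "
            f"(other fraction {f_other})"
        )
    f_other = max(0.0, f_other)
    return ATPBreakdown(profile.cell_line, total, f_lac, f_leu, f_ile, f_val, f_other)


def breakdown_table(breakdowns: list[ATPBreakdown]):
    import pandas as pd

    return pd.DataFrame([vars(b) for b in breakdowns]).set_index("cell_line")


def read_uptake_profiles(path) -> list[UptakeProfile]:
    """Read a TSV of cell lines × metabolites with signed exchange rates."""
    import pandas as pd

    tab = pd.read_csv(path, sep="\t", index_col=0)
    return [
        UptakeProfile(cell_line=str(line), measured={m: float(v) for m, v in row.items()})
        for line, row in tab.iterrows()
    ]


def write_uptake_profiles(profiles: list[UptakeProfile], path) -> None:
    import pandas as pd

    tab = pd.DataFrame([p.measured for p in profiles],
                       index=[p.cell_line for p in profiles])
    tab.index.name = "cell_line"
    tab.to_csv(path, sep="\t", float_format="%.17g")
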