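"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators mirror the three data families the analysis consumes:

* two-class expression matrices (tumorigenic "case" vs healthy-dividing
  "control") with genes planted up/down in the case class — log-normal
  baseline intensities with Gaussian log-scale noise;
* latent-regulon matrices where member genes of each regulon are driven by
  a shared per-sample latent activity, with a configurable correlation
  (coupling) between the latent activities of different regulons;
* a toy core metabolic network (glycolytic fermentation, a lumped
  respiration, Leu/Ile/Val oxidation routes with authored ATP yields) plus
  uniformly drawn cell-line uptake/secretion tables that are feasible for
  it by construction.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atp import MetabolicModel, UptakeProfile, model_from_dict
from .expr_io import CASE, CONTROL, ExpressionMatrix, GeneSet, SampleAnnotation

# Baseline log2-intensity distribution (microarray-like): mean and SD chosen
# to resemble RMA-normalized intensities.
BASELINE_MEAN = 7.0
BASELINE_SD = 2.0


@dataclass(frozen=True)
class LatentRegulon:
    name: str
    size: int
    loading: float = 1.0
    latent: int = 0           # regulons sharing a latent id share its activity


@dataclass
class SimulationSpec:
    """Parameters of the synthetic two-class / latent-regulon generators."""

    n_genes: int = 1000
    n_case: int = 20
    n_ctrl: int = 20
    planted_up: int = 10
    planted_down: int = 10
    effect_size: float = 3.0          # class shift in units of noise_sd (log scale)
    latent_regulons: Sequence[LatentRegulon] = field(default_factory=tuple)
    latent_coupling: float = 0.0      # correlation between distinct latent activities
    noise_sd: float = 1.0
    rpkm_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_up + self.planted_down > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not -1.0 <= self.latent_coupling <= 1.0:
            raise ValueError("latent_coupling must be in [-1, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _annotation(case_ids: list[str], ctrl_ids: list[str]) -> SampleAnnotation:
    tab = pd.DataFrame(
        {
            "class_label": [CASE] * len(case_ids) + [CONTROL] * len(ctrl_ids),
            "cell_type": ["cancer_line"] * len(case_ids) + ["healthy_dividing"] * len(ctrl_ids),
            "origin": ["synthetic"] * (len(case_ids) + len(ctrl_ids)),
        },
        index=case_ids + ctrl_ids,
    )
    tab.index.name = "sample_id"
    return SampleAnnotation(tab)


def simulate_two_class(
    spec: SimulationSpec, sample_stream: int = 0
) -> tuple[ExpressionMatrix, SampleAnnotation, GeneSet, GeneSet]:
    """Two-class expression matrix with planted up/down genes in the case class.

    Gene-level parameters (baseline means, the identity of planted genes)
    depend only on ``spec.seed``; per-sample noise additionally depends on
    ``sample_stream``, so independent cohorts over the same gene structure
    (e.g. a discovery and a held-out validation set) are obtained by
    varying ``sample_stream`` alone.
    """
    gene_rng = _rng(spec.seed, 0)
    noise_rng = _rng(spec.seed, 1 + sample_stream)

    genes = _gene_ids(spec.n_genes)
    baseline = gene_rng.normal(BASELINE_MEAN, BASELINE_SD, spec.n_genes)
    planted = gene_rng.choice(spec.n_genes, spec.planted_up + spec.planted_down, replace=False)
    up_idx = planted[: spec.planted_up]
    down_idx = planted[spec.planted_up :]

    n = spec.n_case + spec.n_ctrl
    vals = baseline[:, None] + noise_rng.normal(0.0, spec.noise_sd, (spec.n_genes, n))
    shift = spec.effect_size * spec.noise_sd
    vals[up_idx, : spec.n_case] += shift
    vals[down_idx, : spec.n_case] -= shift

    case_ids = [f"case{i:03d}" for i in range(spec.n_case)]
    ctrl_ids = [f"ctrl{i:03d}" for i in range(spec.n_ctrl)]
    if spec.rpkm_mode:
        data = pd.DataFrame(np.exp2(vals), index=genes, columns=case_ids + ctrl_ids)
        em = ExpressionMatrix(data, scale_tag="linear")
    else:
        em = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=case_ids + ctrl_ids))
    up = GeneSet.from_iterable("planted_up", (genes[i] for i in up_idx), "up") \
        if spec.planted_up else GeneSet("planted_up", frozenset(), "up")
    down = GeneSet.from_iterable("planted_down", (genes[i] for i in down_idx), "down") \
        if spec.planted_down else GeneSet("planted_down", frozenset(), "down")
    return em, _annotation(case_ids, ctrl_ids), up, down


def simulate_latent_regulons(
    spec: SimulationSpec, sample_stream: int = 0
) -> tuple[ExpressionMatrix, list[GeneSet], pd.DataFrame]:
    """Expression matrix whose regulon member genes track shared latent activities.

    Each sample draws one activity per latent id from a standard normal
    with pairwise correlation ``spec.latent_coupling``; a member gene's
    expression is ``loading × activity + noise`` on top of its baseline.
    Regulon members are assigned to consecutive gene indices starting at 0,
    so regulons are disjoint by construction.  Returns the matrix, the
    regulon gene sets, and the ground-truth latent activities
    (samples × latent ids).
    """
    regs = list(spec.latent_regulons)
    if len(regs) < 2:
        raise ValueError("need at least two latent regulons")
    if sum(r.size for r in regs) > spec.n_genes:
        raise ValueError("regulon sizes exceed n_genes")
    latent_ids = sorted({r.latent for r in regs})
    L = len(latent_ids)
    rho = spec.latent_coupling
    C = np.full((L, L), rho)
    np.fill_diagonal(C, 1.0)
    chol = np.linalg.cholesky(C) if L > 1 else np.array([[1.0]])

    gene_rng = _rng(spec.seed, 0)
    noise_rng = _rng(spec.seed, 1 + sample_stream)
    n = spec.n_case + spec.n_ctrl
    genes = _gene_ids(spec.n_genes)
    baseline = gene_rng.normal(BASELINE_MEAN, BASELINE_SD, spec.n_genes)
    z = noise_rng.standard_normal((n, L)) @ chol.T     # samples × latents
    vals = baseline[:, None] + noise_rng.normal(0.0, spec.noise_sd, (spec.n_genes, n))

    sets: list[GeneSet] = []
    start = 0
    lat_col = {lid: k for k, lid in enumerate(latent_ids)}
    for reg in regs:
        idx = np.arange(start, start + reg.size)
        start += reg.size
        vals[idx, :] += reg.loading * z[:, lat_col[reg.latent]][None, :]
        sets.append(GeneSet.from_iterable(reg.name, (genes[i] for i in idx)))

    sample_ids = [f"s{i:03d}" for i in range(n)]
    em = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=sample_ids))
    latents = pd.DataFrame(z, index=sample_ids,
                           columns=[f"latent{lid}" for lid in latent_ids])
    return em, sets, latents


# ---------------------------------------------------------------------------
# Toy core metabolic network
# ---------------------------------------------------------------------------

# Authored ATP yields per unit substrate fully oxidized (toy constants for
# testability, not claims about human metabolism; distinct per BCAA so that
# attribution errors are detectable).
GLUCOSE_FERMENTATION_ATP = 2.0   # canonical Embden–Meyerhof: glc -> 2 lac + 2 ATP
GLUCOSE_RESPIRATION_ATP = 30.0
LEU_ATP_YIELD = 33.0
ILE_ATP_YIELD = 31.0
VAL_ATP_YIELD = 25.0


def toy_core_model_dict() -> dict:
    """JSON-dialect dict of the toy core network (see toy_core_model)."""
    return {
        "metabolites": ["glc_e", "lac_e", "o2_e", "co2_e", "nh4_e",
                        "leu_e", "ile_e", "val_e", "atp_c"],
        "reactions": [
            {"id": "EX_glc", "stoich": {"glc_e": -1}, "lb": -10.0, "ub": 0.0, "exchange": True},
            {"id": "EX_lac", "stoich": {"lac_e": -1}, "lb": 0.0, "ub": 1000.0, "exchange": True},
            {"id": "EX_o2", "stoich": {"o2_e": -1}, "lb": -1000.0, "ub": 0.0, "exchange": True},
            {"id": "EX_co2", "stoich": {"co2_e": -1}, "lb": 0.0, "ub": 1000.0, "exchange": True},
            {"id": "EX_nh4", "stoich": {"nh4_e": -1}, "lb": 0.0, "ub": 1000.0, "exchange": True},
            {"id": "EX_leu", "stoich": {"leu_e": -1}, "lb": -10.0, "ub": 0.0, "exchange": True},
            {"id": "EX_ile", "stoich": {"ile_e": -1}, "lb": -10.0, "ub": 0.0, "exchange": True},
            {"id": "EX_val", "stoich": {"val_e": -1}, "lb": -10.0, "ub": 0.0, "exchange": True},
            {"id": "GLYC_FERM",
             "stoich": {"glc_e": -1, "lac_e": 2, "atp_c": GLUCOSE_FERMENTATION_ATP},
             "lb": 0.0, "ub": 1000.0, "exchange": False},
            {"id": "RESP_GLC",
             "stoich": {"glc_e": -1, "o2_e": -6, "co2_e": 6, "atp_c": GLUCOSE_RESPIRATION_ATP},
             "lb": 0.0, "ub": 1000.0, "exchange": False},
            {"id": "LEU_OX",
             "stoich": {"leu_e": -1, "o2_e": -7.5, "co2_e": 6, "nh4_e": 1, "atp_c": LEU_ATP_YIELD},
             "lb": 0.0, "ub": 1000.0, "exchange": False},
            {"id": "ILE_OX",
             "stoich": {"ile_e": -1, "o2_e": -7.5, "co2_e": 6, "nh4_e": 1, "atp_c": ILE_ATP_YIELD},
             "lb": 0.0, "ub": 1000.0, "exchange": False},
            {"id": "VAL_OX",
             "stoich": {"val_e": -1, "o2_e": -6.5, "co2_e": 5, "nh4_e": 1, "atp_c": VAL_ATP_YIELD},
             "lb": 0.0, "ub": 1000.0, "exchange": False},
            {"id": "ATP_DEMAND", "stoich": {"atp_c": -1}, "lb": 0.0, "ub": 1000.0,
             "exchange": False},
        ],
        "atp": "atp_c",
        "inorganic": ["o2_e", "co2_e", "nh4_e"],
        "roles": {"glucose": "glc_e", "lactate": "lac_e", "leucine": "leu_e",
                  "isoleucine": "ile_e", "valine": "val_e"},
    }


def toy_core_model() -> MetabolicModel:
    """Deterministic ~14-reaction core network with hand-checkable ATP yields.

    Contains glucose fermentation to lactate (2 ATP/glucose), a lumped
    respiration (30 ATP/glucose), separate Leu/Ile/Val oxidation lumps
    (33/31/25 ATP per unit), O2/CO2/NH4 exchanges and an ATP demand sink.
    """
    return model_from_dict(toy_core_model_dict())


DEFAULT_UPTAKE_RANGES: dict[str, tuple[float, float]] = {
    # magnitudes, mmol·gDW⁻¹·h⁻¹ nominal; lactate secretion <= 2× glucose
    # uptake for every draw, so each profile is feasible for the toy model
    "glucose": (0.25, 0.6),
    "lactate": (0.05, 0.5),
    "leucine": (0.005, 0.12),
    "isoleucine": (0.005, 0.12),
    "valine": (0.005, 0.12),
}


def simulate_uptake_profiles(
    n_lines: int,
    ranges: Optional[dict[str, tuple[float, float]]] = None,
    seed: int = 0,
    model: Optional[MetabolicModel] = None,
) -> list[UptakeProfile]:
    """Uniformly drawn cell-line exchange-rate tables for the toy model.

    ``ranges`` gives per-role magnitude intervals for glucose uptake,
    lactate secretion and Leu/Ile/Val uptakes; the spread of the defaults
    makes the BCAA share of ATP range from a few percent to most of the
    budget across lines.  Signs are applied by convention (uptake negative,
    secretion positive).  A range specification that could produce lactate
    secretion above twice the glucose uptake is rejected as infeasible.
    """
    model = model or toy_core_model()
    ranges = dict(DEFAULT_UPTAKE_RANGES, **(ranges or {}))
    required = ("glucose", "lactate", "leucine", "isoleucine", "valine")
    for role in required:
        if role not in ranges:
            raise ValueError(f"ranges must cover {role!r}")
        lo, hi = ranges[role]
        if lo < 0 or hi < lo:
            raise ValueError(f"bad range for {role!r}: ({lo}, {hi})")
    if ranges["lactate"][1] > 2.0 * ranges["glucose"][0] + 1e-12:
        raise ValueError(
            "infeasible ranges: max lactate secretion exceeds 2x min glucose uptake"
        )
    rng = _rng(seed, 7)
    profiles = []
    for i in range(n_lines):
        draw = {role: rng.uniform(*ranges[role]) for role in required}
        measured = {
            model.roles["glucose"]: -draw["glucose"],
            model.roles["lactate"]: +draw["lactate"],
            model.roles["leucine"]: -draw["leucine"],
            model.roles["isoleucine"]: -draw["isoleucine"],
            model.roles["valine"]: -draw["valine"],
        }
        profiles.append(UptakeProfile(cell_line=f"line{i:03d}", measured=measured))
    return profiles
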