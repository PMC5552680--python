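"""End-to-end recipes: discovery, validation, regulon correlation, RNA-seq
consensus, and ATP accounting, with a manifest for auditability.

Every stage logs the gene/sample counts after each filter (the intermediate
numbers a user must be able to audit on their own data) and every output
file carries the configuration hash in a ``#`` header line, so a rerun with
the same configuration and seeds reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import atp as atp_mod
from .direction import (CharacteristicDirection, characteristic_direction,
                        gene_significance, project_samples)
from .expr_io import (ExpressionMatrix, GeneSet, SampleAnnotation, align_matrices,
                      read_expression_table, read_gene_sets, read_sample_annotation)
from .overlap import consensus_genes, overlap_enrichment_sets
from .regulons import activity_correlation, regulon_activity
from .rnaseq import differential_expression

logger = logging.getLogger("chardir")


@dataclass
class PipelineConfig:
    """Flat key-value configuration of the full pipeline."""

    expr: Optional[str] = None
    ann: Optional[str] = None
    validation_expr: Optional[str] = None
    validation_ann: Optional[str] = None
    regulons_gmt: Optional[str] = None
    regulon_pairs: list[str] = field(default_factory=list)   # "A:B" strings
    rpkm_expr: Optional[str] = None
    rpkm_ann: Optional[str] = None
    model: Optional[str] = None
    uptake: Optional[str] = None
    gamma: float = 0.5
    n_perm: int = 1000
    alpha: float = 0.05
    fc_threshold: float = 2.0
    pseudocount: float = 1.0
    universe: str = "shared"
    seed: int = 0
    outdir: str = "chardir_out"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.universe not in ("shared",):
            raise ValueError(f"unknown universe policy {self.universe!r}")

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location is not
        part of the result's identity, so ``outdir`` is excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def check_inputs(self, keys: list[str]) -> None:
        """Fail before any computation if a referenced input file is missing."""
        for key in keys:
            path = getattr(self, key)
            if path is None:
                raise FileNotFoundError(f"config key {key!r} is required but unset")
            if not Path(path).exists():
                raise FileNotFoundError(f"config {key}: file not found: {path}")


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.12g")


def read_artifact(path) -> pd.DataFrame:
    """Read a pipeline TSV artifact, skipping ``#`` header lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def cd_from_artifact(path, gamma: float = np.nan) -> CharacteristicDirection:
    tab = read_artifact(path)
    b = tab["b"].to_numpy(float)
    b = b / np.linalg.norm(b)
    p = tab["p"].to_numpy(float) if tab["p"].notna().all() else None
    q = tab["q"].to_numpy(float) if tab["q"].notna().all() else None
    return CharacteristicDirection(gene_ids=list(tab["gene_id"]), b=b,
                                   gamma=gamma, p=p, q=q)


def chardir_directions(cd: CharacteristicDirection, alpha: float = 0.05) -> pd.DataFrame:
    """DE-like (gene_id, direction) calls from a significance-annotated direction."""
    if cd.q is None:
        raise ValueError("direction has no significance annotations")
    direction = np.where(cd.q < alpha, np.where(cd.b > 0, "up", "down"), "ns")
    return pd.DataFrame({"gene_id": cd.gene_ids, "direction": direction})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_discovery(config: PipelineConfig) -> dict[str, Path]:
    """Fit the characteristic direction, assess significance, project samples."""
    config.check_inputs(["expr", "ann"])
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()

    X = read_expression_table(config.expr)
    ann = read_sample_annotation(config.ann)
    logger.info("discovery: %d genes × %d samples", *X.shape)
    cd = characteristic_direction(X, ann, gamma=config.gamma)
    cd = gene_significance(cd, X, ann, n_perm=config.n_perm, seed=config.seed)
    scores = project_samples(cd, X)
    sig = cd.significant_genes(config.alpha)
    logger.info("discovery: %d genes significant at q < %g", len(sig), config.alpha)

    paths = {
        "cd": outdir / "cd.tsv",
        "scores": outdir / "scores.tsv",
        "significant_genes": outdir / "significant_genes.tsv",
    }
    _write_tsv(cd.as_frame(), paths["cd"], h)
    _write_tsv(scores.as_series().rename("score").rename_axis("sample_id").reset_index(),
               paths["scores"], h)
    _write_tsv(sig, paths["significant_genes"], h)
    return paths


def run_validation(config: PipelineConfig, cd: CharacteristicDirection) -> dict:
    """Project an independently normalized matrix; summarize class separation."""
    config.check_inputs(["validation_expr"])
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()

    Y = read_expression_table(config.validation_expr)
    shared = len(set(Y.gene_ids) & set(cd.gene_ids))
    frac = shared / len(cd.gene_ids)
    if shared == 0:
        raise ValueError("validation matrix shares no genes with the direction")
    if frac < 0.5:
        logger.warning("validation matrix shares only %.0f%% of direction genes", 100 * frac)
    scores = project_samples(cd, Y)
    out = {"scores_path": outdir / "validation_scores.tsv", "separation": None}
    _write_tsv(scores.as_series().rename("score").rename_axis("sample_id").reset_index(),
               out["scores_path"], h)
    if config.validation_ann and Path(config.validation_ann).exists():
        vann = read_sample_annotation(config.validation_ann)
        mask = vann.class_mask(Y.sample_ids)
        margin = float(scores.scores[mask].min() - scores.scores[~mask].max())
        out["separation"] = margin
        logger.info("validation separation margin (min case − max control): %g", margin)
    return out


def run_regulons(config: PipelineConfig, cd: CharacteristicDirection) -> dict:
    """Regulon activity projections and pairwise activity correlations."""
    config.check_inputs(["expr", "regulons_gmt"])
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()

    X = read_expression_table(config.expr)
    regulons = {g.name: g for g in read_gene_sets(config.regulons_gmt)}
    acts = {name: regulon_activity(cd, X, reg) for name, reg in regulons.items()}
    act_tab = pd.DataFrame({n: s.scores for n, s in acts.items()}, index=X.sample_ids)
    _write_tsv(act_tab.rename_axis("sample_id").reset_index(), outdir / "activities.tsv", h)

    rows = []
    for pair in config.regulon_pairs:
        a, b = pair.split(":")
        res = activity_correlation(acts[a], acts[b], method="pearson")
        rows.append({"a": a, "b": b, "method": res.method, "r": res.r,
                     "p": res.p, "n": res.n})
        logger.info("activity correlation %s vs %s: r = %.3f", a, b, res.r)
    corr = pd.DataFrame(rows, columns=["a", "b", "method", "r", "p", "n"])
    _write_tsv(corr, outdir / "activity_correlations.tsv", h)
    return {"activities": outdir / "activities.tsv",
            "correlations": outdir / "activity_correlations.tsv"}


def run_rnaseq_consensus(config: PipelineConfig, cd: CharacteristicDirection) -> dict:
    """RNA-seq DE, consensus with the discriminant calls, overlap enrichment."""
    config.check_inputs(["rpkm_expr", "rpkm_ann"])
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()

    R = read_expression_table(config.rpkm_expr, mode="linear")
    rann = read_sample_annotation(config.rpkm_ann)
    de = differential_expression(R, rann, alpha=config.alpha,
                                 pseudocount=config.pseudocount,
                                 fc_threshold=config.fc_threshold)
    _write_tsv(de, outdir / "de.tsv", h)
    logger.info("rnaseq: %d genes tested, %d up, %d down", len(de),
                int((de["direction"] == "up").sum()),
                int((de["direction"] == "down").sum()))

    array_calls = chardir_directions(cd, config.alpha)
    universe = sorted(set(de["gene_id"]) & set(array_calls["gene_id"]))
    logger.info("rnaseq: consensus universe (shared measured genes): %d", len(universe))
    rows = []
    # down-consensus is tested for enrichment, up-consensus for depletion
    # (the directional claims the analysis makes)
    for direction, side in (("down", "greater"), ("up", "less")):
        cset = consensus_genes(array_calls, de, direction)
        query = GeneSet.from_iterable(
            f"array_{direction}",
            array_calls.loc[array_calls["direction"] == direction, "gene_id"],
        ) if (array_calls["direction"] == direction).any() else None
        annotated_ids = de.loc[de["direction"] == direction, "gene_id"]
        logger.info("consensus_%s: %d genes", direction, len(cset.genes))
        if query is None or annotated_ids.empty:
            continue
        annotated = GeneSet.from_iterable(f"rnaseq_{direction}", annotated_ids)
        res = overlap_enrichment_sets(query, annotated, universe, test_side=side)
        rows.append({"direction": direction, **vars(res)})
    overlap_tab = pd.DataFrame(rows)
    _write_tsv(overlap_tab, outdir / "consensus_overlap.tsv", h)
    return {"de": outdir / "de.tsv", "overlap": outdir / "consensus_overlap.tsv"}


def run_atp(config: PipelineConfig) -> dict:
    """Parsimonious flux fits and ATP source attribution for every cell line."""
    config.check_inputs(["model", "uptake"])
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()

    model = atp_mod.load_model(config.model)
    profiles = atp_mod.read_uptake_profiles(config.uptake)
    breakdowns = []
    for prof in profiles:
        flux = atp_mod.fit_fluxes(model, prof)
        breakdowns.append(atp_mod.atp_breakdown(model, flux, prof))
    tab = atp_mod.breakdown_table(breakdowns)
    _write_tsv(tab.reset_index(), outdir / "atp.tsv", h)
    logger.info("atp: %d cell lines, BCAA fraction %.3f–%.3f", len(breakdowns),
                min(b.frac_bcaa for b in breakdowns),
                max(b.frac_bcaa for b in breakdowns))
    return {"atp": outdir / "atp.tsv"}


STAGES = ("discovery", "validation", "regulons", "rnaseq", "atp")


def run_full(config: PipelineConfig) -> dict:
    """Execute all five recipes; write a manifest of inputs, params and outputs.

    A stage failure is recorded in the manifest and does not stop later
    stages; the manifest's ``ok`` flag is False if anything failed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": {},
    }
    cd: Optional[CharacteristicDirection] = None

    def record(stage: str, fn):
        nonlocal cd
        try:
            result = fn()
            manifest["stages"][stage] = {"status": "completed"}
            if isinstance(result, dict):
                for k, v in result.items():
                    if isinstance(v, Path):
                        manifest["outputs"][f"{stage}/{k}"] = {
                            "path": str(v), "sha256": _sha256(v)}
                    elif v is not None:
                        manifest["stages"][stage][k] = v
        except Exception as exc:  # noqa: BLE001 — stage isolation is the contract
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}

    record("discovery", lambda: run_discovery(config))
    if manifest["stages"]["discovery"]["status"] == "completed":
        cd = cd_from_artifact(Path(config.outdir) / "cd.tsv", gamma=config.gamma)
    if cd is not None:
        record("validation", lambda: run_validation(config, cd))
        record("regulons", lambda: run_regulons(config, cd))
        record("rnaseq", lambda: run_rnaseq_consensus(config, cd))
    else:
        for stage in ("validation", "regulons", "rnaseq"):
            manifest["stages"][stage] = {"status": "failed",
                                         "error": "discovery did not produce a direction"}
    record("atp", lambda: run_atp(config))

    manifest["ok"] = all(s["status"] == "completed" for s in manifest["stages"].values())
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
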