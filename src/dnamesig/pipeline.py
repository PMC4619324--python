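"""End-to-end orchestration: simulate/load -> discover -> score -> survive -> meta.

``run_pipeline`` wires the stages together from a single config (YAML/JSON
or an in-memory :class:`PipelineConfig`), writes every intermediate artifact
as TSV/JSON under the output directory, and returns a :class:`RunManifest`
listing each artifact with its SHA-256 checksum.  One global seed is fanned
out deterministically to per-stage seeds, so identical configs produce
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import (
    Cohort,
    ValidationError,
    assemble_cohort,
    read_beta_matrix,
    read_sample_sheet,
)
from .discovery import partition_by_direction, rank_cpgs, select_signature_cv
from .meta import fisher_combined, geneset_enrichment, read_gene_set
from .scoring import optimize_cutoff, random_signature_null, score_cohort, scores_frame
from .simulate import SimulationConfig, simulate_cohort, write_simulated_cohort
from .survival import FitError, cox_fit, interaction_lrt, km_estimate, select_covariates

logger = logging.getLogger(__name__)

_STAGE_NAMES = ("simulate_discovery", "simulate_validation", "cv", "null")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage, self.code = stage, code
        super().__init__(f"[{stage}/{code}] {message}")


@dataclass
class CohortSource:
    """Where one cohort comes from: file paths XOR a simulation block."""

    beta_path: str | None = None
    samples_path: str | None = None
    simulation: dict | None = None

    def validate(self, role: str) -> None:
        has_paths = self.beta_path is not None or self.samples_path is not None
        if has_paths and self.simulation is not None:
            raise PipelineError("config", "ambiguous_source",
                                f"{role}: give cohort paths or a simulation block, not both")
        if not has_paths and self.simulation is None:
            raise PipelineError("config", "missing_source", f"{role}: no cohort source given")
        if has_paths and (self.beta_path is None or self.samples_path is None):
            raise PipelineError("config", "incomplete_source",
                                f"{role}: both beta and samples paths are required")


@dataclass
class PipelineConfig:
    discovery: CohortSource = field(default_factory=lambda: CohortSource(simulation={}))
    validation: CohortSource = field(default_factory=lambda: CohortSource(simulation={}))
    candidate_sizes: list[int] = field(default_factory=lambda: [10, 25, 50, 100])
    folds: int = 10
    top_n: int = 500
    fdr_max: float = 0.3
    min_coverage: float = 0.8
    target_sens: float = 0.8
    target_spec: float = 0.8
    covariate_candidates: list[str] = field(default_factory=lambda: ["age"])
    alpha: float = 0.05
    n_draws: int = 100
    gene_set_path: str | None = None
    probe_genes_path: str | None = None
    seed: int = 0
    outdir: str = "dnamesig_run"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for role in ("discovery", "validation"):
            if role in raw and isinstance(raw[role], dict):
                raw[role] = CohortSource(**raw[role])
        return cls(**raw)

    def validate(self) -> None:
        self.discovery.validate("discovery")
        self.validation.validate("validation")
        if not self.candidate_sizes:
            raise PipelineError("config", "no_candidates", "candidate_sizes must be non-empty")

    def echo(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        for role in ("discovery", "validation"):
            d[role] = dict(d[role].__dict__)
        return d


@dataclass
class RunManifest:
    """Provenance record: config echo, version, artifact checksums, stamps."""

    config: dict
    version: str
    artifacts: dict[str, str]  # relative path -> sha256
    started: float
    finished: float

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config": self.config,
                    "version": self.version,
                    "artifacts": self.artifacts,
                    "started": self.started,
                    "finished": self.finished,
                },
                indent=2,
                sort_keys=True,
                default=str,
            )
            + "\n"
        )


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort(source: CohortSource, role: str, seed: int, outdir: Path) -> tuple[Cohort, object]:
    if source.simulation is not None:
        block = dict(source.simulation)
        block.setdefault("seed", _stage_seed(seed, f"simulate_{role}"))
        # simulated discovery and validation cohorts share one population
        # (same planted probes and baselines), as real paired cohorts would
        block.setdefault("population_seed", _stage_seed(seed, "population"))
        cfg = SimulationConfig.from_dict(block)
        cohort, truth = simulate_cohort(cfg, name=role)
        write_simulated_cohort(cohort, truth, cfg, outdir)
        return cohort, truth
    beta = read_beta_matrix(source.beta_path)
    samples = read_sample_sheet(source.samples_path)
    return assemble_cohort(beta, samples, on_mismatch="intersect", name=role), None


def _arm_survival(cohort: Cohort, calls: dict[str, str], outdir: Path) -> dict:
    """Per-treatment-arm survival of high vs low signature calls."""
    out: dict = {}
    clin = cohort.clinical_frame()
    clin["call"] = [calls.get(s, "unscored") for s in clin.index]
    usable = clin.dropna(subset=["time", "event"])
    usable = usable[usable["call"].isin(["high", "low"])]
    for arm in sorted(usable["treatment"].unique()):
        sub = usable[usable["treatment"] == arm]
        entry: dict = {"n": int(len(sub))}
        hi = sub[sub["call"] == "high"]
        lo = sub[sub["call"] == "low"]
        if len(hi) >= 2 and len(lo) >= 2 and sub["event"].sum() >= 1:
            try:
                fit = cox_fit(sub["time"], sub["event"], pd.DataFrame({"high": (sub["call"] == "high").astype(int)}))
                entry.update(
                    hazard_ratio=fit.hazard_ratio("high"),
                    ci=[float(fit.table.loc["high", "ci_lower"]), float(fit.table.loc["high", "ci_upper"])],
                    wald_p=float(fit.table.loc["high", "wald_p"]),
                    lrt_p=fit.lrt_p,
                    n_events=fit.n_events,
                )
            except (FitError, ValidationError) as exc:
                entry["error"] = str(exc)
            for label, grp in (("high", hi), ("low", lo)):
                if grp["event"].sum() >= 1 or len(grp):
                    km = km_estimate(grp["time"], grp["event"])
                    km.to_frame().to_csv(outdir / f"km_{arm}_{label}.tsv", sep="\t", index=False)
        out[arm] = entry
    return out


def run_pipeline(config: PipelineConfig | dict | str | Path) -> RunManifest:
    """Run every stage and return the manifest.

    Stages: simulate/load both cohorts -> rank + CV-select the signature ->
    hyper/hypo partition -> discovery scoring + frozen cutoff -> validation
    scoring and per-arm survival -> marker x treatment interaction on both
    cohorts -> Fisher combined meta-analysis -> optional gene-set enrichment
    -> random-signature null on the validation cohort.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_file(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    config.validate()
    started = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    discovery, _ = _load_cohort(config.discovery, "discovery", config.seed, outdir)
    validation, _ = _load_cohort(config.validation, "validation", config.seed, outdir)

    try:
        ranking = rank_cpgs(discovery)
        signature = select_signature_cv(
            discovery, config.candidate_sizes, folds=config.folds,
            seed=_stage_seed(config.seed, "cv"),
        )
    except ValidationError as exc:
        raise PipelineError("discover", "discovery_failed", str(exc)) from exc
    ranking.table.to_csv(outdir / "ranking.tsv", sep="\t", index=False)
    signature.write(outdir / "signature.tsv")
    (outdir / "signature.json").write_text(
        json.dumps(
            {"size": signature.size, "fdr_at_size": signature.fdr_at_size,
             "provenance": signature.provenance},
            indent=2, sort_keys=True,
        ) + "\n"
    )
    hyper, hypo = partition_by_direction(ranking, min(config.top_n, len(ranking.table)), config.fdr_max)
    (outdir / "partition.json").write_text(
        json.dumps({"n_hyper": len(hyper), "n_hypo": len(hypo),
                    "hyper": hyper, "hypo": hypo}, indent=2) + "\n"
    )

    try:
        disc_scores = score_cohort(discovery, signature, min_coverage=config.min_coverage)
        labels = discovery.marker_mask()
        cutoff = optimize_cutoff(disc_scores, labels, config.target_sens, config.target_spec)
        val_scores = score_cohort(validation, signature, cutoff, min_coverage=config.min_coverage)
    except ValidationError as exc:
        raise PipelineError("score", "scoring_failed", str(exc)) from exc
    scores_frame(disc_scores).to_csv(outdir / "discovery_scores.tsv", sep="\t", index=False)
    (outdir / "cutoff.json").write_text(cutoff.to_json() + "\n")
    scores_frame(val_scores).to_csv(outdir / "validation_scores.tsv", sep="\t", index=False)

    calls = {s.sample_id: s.call for s in val_scores}
    survival_summary = _arm_survival(validation, calls, outdir)
    (outdir / "survival.json").write_text(json.dumps(survival_summary, indent=2, sort_keys=True) + "\n")

    # interaction on each cohort (marker status x treatment), then combine
    interactions = {}
    for cohort in (discovery, validation):
        clin = cohort.clinical_frame().dropna(subset=["time", "event"])
        clin = clin[clin["marker_status"].isin(["positive", "negative"])]
        clin = clin[clin["treatment"].isin(["carboplatin", "cisplatin"])]
        try:
            cand = clin[[c for c in config.covariate_candidates if c in clin.columns]]
            chosen = select_covariates(clin["time"], clin["event"], cand, alpha=config.alpha)
            res = interaction_lrt(
                clin["time"], clin["event"],
                (clin["marker_status"] == "positive").astype(int),
                clin["treatment"],
                covariates=clin[chosen] if chosen else None,
            )
            interactions[cohort.name] = {
                "p": res.p, "lrt_statistic": res.lrt_statistic, "df": res.df,
                "covariates": chosen, "n": res.full.n, "n_events": res.full.n_events,
            }
        except (FitError, ValidationError) as exc:
            interactions[cohort.name] = {"error": str(exc)}
    (outdir / "interaction.json").write_text(json.dumps(interactions, indent=2, sort_keys=True) + "\n")

    usable_ps = [(k, v["p"]) for k, v in interactions.items() if "p" in v]
    meta_out: dict = {}
    if usable_ps:
        combined = fisher_combined([p for _, p in usable_ps], labels=[k for k, _ in usable_ps])
        meta_out = {"statistic": combined.statistic, "df": combined.df, "p": combined.p,
                    "inputs": dict(usable_ps)}
    (outdir / "meta.json").write_text(json.dumps(meta_out, indent=2, sort_keys=True) + "\n")

    if config.gene_set_path and config.probe_genes_path:
        gene_set = read_gene_set(config.gene_set_path)
        probe_genes = pd.read_csv(config.probe_genes_path, sep="\t", dtype=str)
        mapping = dict(zip(probe_genes["probe_id"], probe_genes["gene_symbols"].fillna("")))
        background = sorted({g for gs in mapping.values() for g in gs.split(";") if g})
        sig_genes = sorted({g for p in hyper for g in mapping.get(p, "").split(";") if g})
        if sig_genes:
            enr = geneset_enrichment(sig_genes, gene_set, background)
            (outdir / "enrichment.json").write_text(
                json.dumps(
                    {"overlap": enr.overlap, "signature_size": enr.signature_size,
                     "geneset_size": enr.geneset_size, "background_size": enr.background_size,
                     "fold_enrichment": enr.fold_enrichment, "p": enr.p},
                    indent=2, sort_keys=True,
                ) + "\n"
            )

    try:
        null = random_signature_null(
            validation, signature, discovery,
            n_draws=config.n_draws, seed=_stage_seed(config.seed, "null"),
            min_coverage=config.min_coverage,
        )
    except (FitError, ValidationError) as exc:
        raise PipelineError("null", "null_failed", str(exc)) from exc
    pd.DataFrame({"draw": np.arange(null.n_draws), "statistic": null.draws}).to_csv(
        outdir / "null_draws.tsv", sep="\t", index=False
    )
    (outdir / "null.json").write_text(
        json.dumps(
            {"observed": null.observed, "n_draws": null.n_draws,
             "empirical_p": null.empirical_p, "statistic": null.statistic,
             "seed": null.seed},
            indent=2, sort_keys=True,
        ) + "\n"
    )

    artifacts = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config=config.echo(), version=__version__, artifacts=artifacts,
        started=started, finished=time.time(),
    )
    manifest.write(outdir / "manifest.json")
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return manifest
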