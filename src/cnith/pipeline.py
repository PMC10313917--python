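"""Orchestration: run the analysis stages on a directory of input tables.

Stages run in dependency order — distances -> clone threshold -> per-patient
clones/topology/relapse patterns; HR scar scoring; gene-level CN; signature
heterogeneity; spatial (Mantel) — each writing its tables into the run
directory.  A provenance manifest lists every output with the config hash and
seeds, so a rerun with the same config and inputs is byte-identical for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clonality import (
    CloneThresholdModel,
    patient_evolution_report,
    pool_pair_distances,
)
from .distance import DistanceMatrix, distance_matrix
from .errors import ValidationError
from .features import gene_cn_table, patient_exposure_heterogeneity
from .hrd import fit_ambiguity_model, filter_scorable, patient_hr_status, score_cohort
from .io import (
    metadata_by_sample,
    read_genes,
    read_genome,
    read_matrix,
    read_metadata,
    read_segment_table,
)
from .spatial import cohort_mantel_summary, patient_mantel_tests

logger = logging.getLogger(__name__)

ALL_STAGES = ("distances", "clones", "hrd", "genes", "signatures", "spatial")


@dataclass
class RunConfig:
    """Inputs, stage toggles, and thresholds for one pipeline run.

    Defaults reproduce the published constants: HRD call at a scar sum of 42,
    purity cut 0.3, complete-linkage clustering.
    """

    segments: str = "segments.tsv"
    metadata: str = "metadata.tsv"
    genome: str = "genome.tsv"
    genes: str | None = None
    exposures: str | None = None
    outdir: str = "cnith_run"
    stages: tuple[str, ...] = ALL_STAGES
    clone_threshold: float | None = None   # override; None -> fit from the cohort
    hrd_cut: int = 42
    purity_cut: float = 0.3
    include_relapse_in_fit: bool = False
    n_perm: int = 999
    seed: int = 0
    exposure_mode: str = "sum_squared"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run(cfg: RunConfig) -> Path:
    """Execute the enabled stages; returns the run directory."""
    for stage in cfg.stages:
        if stage not in ALL_STAGES:
            raise ValidationError(f"unknown stage {stage!r} (choose from {ALL_STAGES})")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "outputs": [],
    }

    def require(path: str | None, stage: str) -> Path:
        if path is None or not Path(path).exists():
            raise ValidationError(f"stage {stage!r} requires input file {path!r}")
        return Path(path)

    genome = read_genome(require(cfg.genome, "all"))
    profiles = read_segment_table(require(cfg.segments, "all"), genome=genome)
    meta = read_metadata(require(cfg.metadata, "all"))
    by_sample = metadata_by_sample(meta)

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["outputs"].append(name)

    dmat: DistanceMatrix | None = None
    threshold = cfg.clone_threshold
    if "distances" in cfg.stages or "clones" in cfg.stages:
        dmat = distance_matrix(profiles)
        emit("distance_matrix.tsv", dmat.write)

    if "clones" in cfg.stages:
        assert dmat is not None
        if threshold is None:
            pool = pool_pair_distances(dmat, by_sample,
                                       include_relapse=cfg.include_relapse_in_fit)
            results = CloneThresholdModel(pool).fit()
            threshold = results.threshold
            emit("clone_threshold.json", lambda p: Path(p).write_text(
                json.dumps({"threshold": results.threshold,
                            "intercept": results.intercept,
                            "slope": results.slope,
                            "diagnostics": results.fit_diagnostics}, indent=1)))
        reports = []
        for pid in sorted({r.patient_id for r in meta}):
            ids = [s for s in dmat.sample_ids if by_sample[s].patient_id == pid]
            if len(ids) < 2:
                logger.info("patient %s has <2 samples; skipped", pid)
                continue
            rep = patient_evolution_report(pid, dmat.submatrix(ids), by_sample, threshold)
            reports.append(rep)
        emit("patient_evolution.json", lambda p: Path(p).write_text(
            json.dumps([r.to_dict() for r in reports], indent=1)))
        emit("patient_evolution.tsv", lambda p: pd.DataFrame([
            {"patient": r.patient_id, "n_clones": r.n_clones, "topology": r.topology,
             "relapse_pattern": r.relapse_pattern or "", "threshold": r.threshold}
            for r in reports]).to_csv(p, sep="\t", index=False))
        emit("patient_trees.nwk", lambda p: Path(p).write_text(
            "".join(r.newick + "\n" for r in reports)))

    if "hrd" in cfg.stages:
        scorable, exclusions = filter_scorable(profiles, by_sample, genome,
                                               min_purity=cfg.purity_cut)
        table = score_cohort(scorable, genome, hrd_threshold=cfg.hrd_cut)
        emit("hrd_scores.tsv", lambda p: table.to_csv(p, sep="\t", index=False))
        emit("hrd_exclusions.tsv", lambda p: pd.DataFrame(
            [{"sample": e.sample_id, "reason": e.reason} for e in exclusions]
        ).to_csv(p, sep="\t", index=False))
        calls = dict(zip(table["sample"], table["call"]))
        status = patient_hr_status(calls, by_sample)
        emit("patient_hr_status.tsv", lambda p: pd.DataFrame(
            [{"patient": s.patient_id, "status": s.status,
              "n_samples": len(s.sample_calls)} for s in status.values()]
        ).to_csv(p, sep="\t", index=False))
        scores = dict(zip(table["sample"], table["hrd_sum"]))
        try:
            amb = fit_ambiguity_model(scores, by_sample, threshold=cfg.hrd_cut)
            emit("hrd_ambiguity.json", lambda p: Path(p).write_text(json.dumps({
                "intercept": amb.intercept, "slope": amb.slope,
                "threshold": amb.threshold,
                "curve": amb.curve().to_dict(orient="list")}, indent=1)))
        except Exception as exc:  # degenerate outcomes are data-dependent
            logger.warning("ambiguity model not fitted: %s", exc)

    if "genes" in cfg.stages:
        genes = read_genes(require(cfg.genes, "genes"), genome)
        table = gene_cn_table(profiles, genes, by_sample)
        emit("gene_cn.tsv", lambda p: table.to_csv(p, sep="\t", index=False))

    if "signatures" in cfg.stages:
        exposures = read_matrix(require(cfg.exposures, "signatures"))
        het = patient_exposure_heterogeneity(exposures, by_sample, mode=cfg.exposure_mode)
        alt = "euclidean" if cfg.exposure_mode == "sum_squared" else "sum_squared"
        het_alt = patient_exposure_heterogeneity(exposures, by_sample, mode=alt)
        emit("signature_heterogeneity.tsv", lambda p: pd.concat(
            [het, het_alt], ignore_index=True).to_csv(p, sep="\t", index=False))

    if "spatial" in cfg.stages:
        if dmat is None:
            dmat = distance_matrix(profiles)
        mantel = patient_mantel_tests(dmat, by_sample, n_perm=cfg.n_perm, seed=cfg.seed)
        emit("mantel_per_patient.tsv", lambda p: mantel.to_csv(p, sep="\t", index=False))
        if len(mantel) >= 3:
            summary = cohort_mantel_summary(mantel)
            emit("mantel_cohort.json", lambda p: Path(p).write_text(
                json.dumps(summary, indent=1)))
        else:
            logger.warning("fewer than 3 patient Mantel results; cohort summary skipped")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
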