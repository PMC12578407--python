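"""End-to-end orchestration: simulate -> meta -> network -> kda -> annotate
-> signature-status -> shortlist.

``run_pipeline`` executes the stages in order, writes every stage's output
as plain text (TSV/JSON) under an output directory, and finishes with a
JSON manifest recording the configuration, seeds, file checksums, package
versions and a per-stage log. A rerun with the same config and seed
reproduces byte-identical outputs. A stage failure aborts with the stage
name while earlier outputs are preserved on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .candidates import CandidateAnnotation, filter_candidates
from .coexpr import meta_edge_table, significant_edges
from .drivers import key_driver_analysis, key_driver_table
from .enrichment import annotate_modules, signature_status
from .expression import ExpressionMatrix
from .io import read_expression_tsv, read_gmt, write_gmt
from .network import PlanarNetwork, build_pmfg, detect_modules_multiscale, GeneModule
from .simulate import (
    GroundTruth,
    SignatureDefinition,
    SyntheticStudySpec,
    default_signature_from_background,
    generate_multi_cohort,
    plant_signature_response,
    write_fixtures,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with their defaults."""

    # meta-analysis
    n_perm: int = 1000
    n_resample: int = 10000
    edge_fdr: float = 0.05
    top_var: int = 500
    correlation_method: str = "pearson"
    # network / modules
    scales: tuple = (0.5, 1.0, 2.0)
    min_module_size: int = 10
    module_scale: float = 1.0  # scale whose modules feed KDA
    # key drivers
    n_max: int = 5
    # GSEA / signature status
    gsea_n_perm: int = 500
    weight_exponent: float = 1.0
    status_fdr: float = 0.25
    # signature carved from background genes in synthetic mode
    signature_n_poor: int = 15
    signature_n_good: int = 15
    seed: int = 0

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(self.scales)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_edge_table(edges: pd.DataFrame, path) -> Path:
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def write_network_json(network: PlanarNetwork, path) -> Path:
    with open(path, "w") as fh:
        json.dump(network.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return Path(path)


def read_network_json(path) -> PlanarNetwork:
    with open(path) as fh:
        return PlanarNetwork.from_json_dict(json.load(fh))


def write_module_table(modules, path) -> Path:
    rows = [
        {"gene": g, "module_id": m.module_id, "scale": m.scale,
         "scale_free_r2": m.scale_free_r2}
        for m in modules
        for g in sorted(m.members)
    ]
    pd.DataFrame(rows, columns=["gene", "module_id", "scale", "scale_free_r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return Path(path)


def read_module_table(path) -> list[GeneModule]:
    df = pd.read_csv(path, sep="\t")
    modules = []
    for (mid, scale), grp in df.groupby(["module_id", "scale"], sort=True):
        r2 = float(grp["scale_free_r2"].iloc[0])
        modules.append(GeneModule(str(mid), frozenset(grp["gene"].astype(str)), float(scale), r2))
    return modules


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    spec: SyntheticStudySpec | None = None,
    cohort_paths=None,
    signature_path=None,
    gene_set_path=None,
    annotations=None,
) -> dict:
    """Run the full discovery pipeline.

    Either ``spec`` (synthetic mode: data, signature, gene-set collection
    and candidate annotations are all derived from the planted study) or
    ``cohort_paths`` (TSV matrices; signature/gene sets/annotations
    supplied by the caller) must be given. Returns the manifest dict, also
    written to ``out_dir/manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict] = []
    files: dict[str, str] = {}

    def record(path: Path):
        files[path.name] = _sha256(path)

    def run_stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # pragma: no cover - error path
            stage_log.append({"stage": name, "status": "failed", "error": str(exc)})
            _write_manifest(out_dir, config, files, stage_log, failed=name)
            raise PipelineError(name, exc) from exc
        stage_log.append({"stage": name, "status": "ok"})
        return result

    truth: GroundTruth | None = None
    signature: SignatureDefinition | None = None
    test_matrix = ref_matrix = None
    collections = None

    # ---- stage: inputs -------------------------------------------------
    def stage_inputs():
        nonlocal truth, signature, test_matrix, ref_matrix, collections
        if spec is not None:
            matrices, truth_ = generate_multi_cohort(spec)
            truth = truth_
            signature = default_signature_from_background(
                truth, config.signature_n_poor, config.signature_n_good
            )
            ref_matrix = matrices[0]
            test_matrix = plant_signature_response(
                ref_matrix,
                signature,
                ["injured"] * ref_matrix.n_samples,
                spec.signature_effect,
                truth=truth,
            )
            collections = [
                (mid, "planted module", sorted(truth.module_members(mid)))
                for mid in sorted(truth.driver_genes)
            ]
            manifest = write_fixtures(matrices, truth, out_dir / "fixtures",
                                      signature=signature, spec=spec)
            for info in manifest["files"].values():
                files[Path(info["path"]).name] = info["sha256"]
            return matrices
        if not cohort_paths:
            raise ValueError("either a synthetic spec or cohort paths are required")
        matrices = [read_expression_tsv(p) for p in cohort_paths]
        if signature_path is not None:
            signature = SignatureDefinition.from_gmt_sets(
                Path(signature_path).stem, read_gmt(signature_path)
            )
            ref_matrix = matrices[0]
            test_matrix = None
        if gene_set_path is not None:
            collections = read_gmt(gene_set_path)
        return matrices

    matrices = run_stage("inputs", stage_inputs)

    # ---- stage: meta ---------------------------------------------------
    def stage_meta():
        edges = meta_edge_table(
            matrices,
            n_perm=config.n_perm,
            seed=config.seed,
            top_var=config.top_var,
            n_resample=config.n_resample,
            method=config.correlation_method,
        )
        record(write_edge_table(edges, out_dir / "edges.tsv"))
        return edges

    edge_stats = run_stage("meta", stage_meta)

    # ---- stage: network ------------------------------------------------
    def stage_network():
        sig = significant_edges(edge_stats, config.edge_fdr)
        if len(sig) == 0:
            raise ValueError("no significant edges at the configured FDR")
        nodes = sorted(set(sig["gene_a"]) | set(sig["gene_b"]))
        net = build_pmfg(sig.itertuples(index=False, name=None), nodes)
        record(write_network_json(net, out_dir / "network.json"))
        modules = detect_modules_multiscale(net, config.scales, config.min_module_size)
        record(write_module_table(modules, out_dir / "modules.tsv"))
        return net, modules

    net, modules = run_stage("network", stage_network)
    kda_modules = [m for m in modules if m.scale == config.module_scale]

    # ---- stage: kda ----------------------------------------------------
    def stage_kda():
        results = [
            key_driver_analysis(net, m, n_max=config.n_max) for m in kda_modules
        ]
        table = key_driver_table(results)
        table.to_csv(out_dir / "drivers.tsv", sep="\t", index=False, float_format="%.10g")
        record(out_dir / "drivers.tsv")
        return results

    kda_results = run_stage("kda", stage_kda)

    # ---- stage: annotate -----------------------------------------------
    def stage_annotate():
        if not collections:
            logger.info("no gene-set collection supplied; annotation skipped")
            return None
        table = annotate_modules(kda_modules, collections, set(net.graph.nodes))
        table.to_csv(out_dir / "annotation.tsv", sep="\t", index=False, float_format="%.10g")
        record(out_dir / "annotation.tsv")
        return table

    run_stage("annotate", stage_annotate)

    # ---- stage: signature-status ---------------------------------------
    def stage_status():
        if signature is None or test_matrix is None or ref_matrix is None:
            logger.info("no signature comparison available; status stage skipped")
            return None
        status = signature_status(
            test_matrix,
            ref_matrix,
            signature,
            n_perm=config.gsea_n_perm,
            seed=config.seed,
            fdr_cut=config.status_fdr,
            weight_exponent=config.weight_exponent,
        )
        payload = {
            "call": status.call,
            "poor": dataclasses.asdict(status.poor_result),
            "good": dataclasses.asdict(status.good_result),
        }
        with open(out_dir / "signature_status.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        record(out_dir / "signature_status.json")
        return status

    run_stage("signature_status", stage_status)

    # ---- stage: shortlist ----------------------------------------------
    def stage_shortlist():
        anns = annotations
        if anns is None and truth is not None:
            planted = {g for drvs in truth.driver_genes.values() for g in drvs}
            anns = [
                CandidateAnnotation(g, True, True, True, "planted driver")
                if g in planted
                else CandidateAnnotation(g, False, False, False)
                for g in sorted(net.graph.nodes)
            ]
        if anns is None:
            logger.info("no candidate annotations supplied; shortlist skipped")
            return None
        flat = [r for sub in kda_results for r in sub]
        flat.sort(key=lambda r: (r.module_id, r.rank))
        table = filter_candidates(flat, anns)
        table.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
        record(out_dir / "candidates.tsv")
        return table

    shortlist = run_stage("shortlist", stage_shortlist)

    manifest = _write_manifest(out_dir, config, files, stage_log)
    manifest["_shortlist"] = shortlist
    return manifest


def _write_manifest(out_dir: Path, config: PipelineConfig, files, stage_log, failed=None) -> dict:
    import networkx
    import numpy
    import scipy

    manifest = {
        "config": config.to_json_dict(),
        "seed": config.seed,
        "files": dict(sorted(files.items())),
        "stages": stage_log,
        "versions": {
            "hepnet": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
        },
    }
    if failed:
        manifest["failed_stage"] = failed
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
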