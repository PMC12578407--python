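"""Synthetic multi-cohort expression studies with planted ground truth.

The generator emulates the design the discovery pipeline is meant for:
several independent patient cohorts that share block-correlated gene
modules, each module organized around one or more hub "driver" genes whose
signal propagates to the module members, plus unstructured background genes
and per-cohort batch shifts. A separate operation plants a
condition-dependent induction/suppression response on the poor/good subsets
of a prognostic signature, so the GSEA status classifier can be exercised
end to end without any external download.

Construction (per cohort, per module): a latent factor ``f ~ N(0, 1)`` is
drawn per sample; each driver gene equals ``f`` plus small noise
(sd ``0.1 * noise_sd``); each member gene equals ``beta * driver + eps``
with ``eps`` scaled so that the expected member-member correlation equals
``rho`` when ``noise_sd = 1`` and tends to 1 as ``noise_sd`` tends to 0.
Background genes are independent ``N(0, noise_sd)``. A per-gene baseline
(shared across cohorts) and a per-cohort per-gene batch shift are added on
top; neither changes any within-cohort correlation. Values are on log2
scale by convention.

Randomness: one numpy ``SeedSequence`` per study; cohort ``i`` draws from
the PCG64 stream seeded with ``[seed, i]`` and the baseline from
``[seed, 2**16]``, so adding a cohort never perturbs earlier cohorts and
identical spec + seed reproduces bit-identical matrices on any platform.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .io import write_expression_tsv, write_gmt

__all__ = [
    "ModuleSpec",
    "SyntheticStudySpec",
    "GroundTruth",
    "SignatureDefinition",
    "generate_multi_cohort",
    "plant_signature_response",
    "write_fixtures",
    "default_study_spec",
]

_BASELINE_STREAM = 1 << 16  # cohort indices can never reach this


@dataclass(frozen=True)
class ModuleSpec:
    """One planted coexpression module."""

    module_id: str
    n_members: int  # total members, drivers included
    rho: float  # target within-module member-member correlation

    def __post_init__(self):
        if self.n_members < 2:
            raise ValueError(f"module {self.module_id}: needs >= 2 members")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"module {self.module_id}: rho must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Full description of a synthetic multi-cohort study."""

    n_cohorts: int = 3
    samples_per_cohort: int = 80
    modules: tuple = (
        ModuleSpec("M1", 12, 0.6),
        ModuleSpec("M2", 16, 0.6),
        ModuleSpec("M3", 20, 0.6),
    )
    n_background_genes: int = 50
    drivers_per_module: int = 1
    driver_loading: float = 0.9  # beta
    noise_sd: float = 1.0  # global noise scale; rho is exact at 1.0
    batch_shift_sd: float = 0.3
    signature_effect: float = 2.0  # delta, log2 units
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")
        if self.samples_per_cohort < 1:
            raise ValueError("samples_per_cohort must be positive")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.drivers_per_module < 1:
            raise ValueError("drivers_per_module must be >= 1")
        if not (0.0 < self.driver_loading <= 1.0):
            raise ValueError("driver_loading must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        for m in self.modules:
            if self.drivers_per_module >= m.n_members:
                raise ValueError(
                    f"module {m.module_id}: drivers_per_module must leave >= 1 non-driver member"
                )

    @property
    def n_genes(self) -> int:
        return sum(m.n_members for m in self.modules) + self.n_background_genes


@dataclass
class GroundTruth:
    """Machine-readable planted truth for a synthetic study.

    ``module_assignment`` maps every gene to its module id or
    ``"background"``; ``driver_genes`` maps module id to its driver list;
    ``signature_direction`` maps ``(condition, subset)`` to
    induced/suppressed/null once a signature response has been planted.
    """

    module_assignment: dict = field(default_factory=dict)
    driver_genes: dict = field(default_factory=dict)
    signature_direction: dict = field(default_factory=dict)

    def __post_init__(self):
        for mod, drivers in self.driver_genes.items():
            for g in drivers:
                if self.module_assignment.get(g) != mod:
                    raise ValueError(f"driver {g} not assigned to module {mod}")

    def module_members(self, module_id: str) -> list[str]:
        return [g for g, m in self.module_assignment.items() if m == module_id]

    def to_json_dict(self) -> dict:
        return {
            "module_assignment": self.module_assignment,
            "driver_genes": self.driver_genes,
            "signature_direction": {
                f"{cond}|{subset}": direction
                for (cond, subset), direction in self.signature_direction.items()
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        sig = {}
        for key, direction in d.get("signature_direction", {}).items():
            cond, subset = key.split("|", 1)
            sig[(cond, subset)] = direction
        return cls(d["module_assignment"], d["driver_genes"], sig)


@dataclass(frozen=True)
class SignatureDefinition:
    """A two-subset prognostic signature: genes whose induction marks poor
    prognosis and genes whose induction marks good prognosis."""

    name: str
    poor_genes: frozenset
    good_genes: frozenset

    def __post_init__(self):
        poor = frozenset(self.poor_genes)
        good = frozenset(self.good_genes)
        object.__setattr__(self, "poor_genes", poor)
        object.__setattr__(self, "good_genes", good)
        if not poor or not good:
            raise ValueError("both signature subsets must be non-empty")
        if poor & good:
            raise ValueError(f"signature subsets overlap: {sorted(poor & good)[:5]}")

    @classmethod
    def from_gmt_sets(cls, name: str, sets) -> "SignatureDefinition":
        """Build from GMT triples whose set names contain 'poor'/'good'."""
        poor = good = None
        for set_name, _desc, members in sets:
            low = set_name.lower()
            if "poor" in low:
                poor = members
            elif "good" in low:
                good = members
        if poor is None or good is None:
            raise ValueError("signature GMT must contain one 'poor' and one 'good' set")
        return cls(name, frozenset(poor), frozenset(good))

    def to_gmt_sets(self):
        return [
            (f"{self.name}_poor_prognosis", "poor-prognosis subset", sorted(self.poor_genes)),
            (f"{self.name}_good_prognosis", "good-prognosis subset", sorted(self.good_genes)),
        ]


def _gene_names(spec: SyntheticStudySpec) -> tuple[list[str], GroundTruth]:
    assignment: dict[str, str] = {}
    drivers: dict[str, list[str]] = {}
    genes: list[str] = []
    for m in spec.modules:
        mod_drivers = [f"{m.module_id}_DRV{i + 1}" for i in range(spec.drivers_per_module)]
        members = [
            f"{m.module_id}_G{j + 1:03d}"
            for j in range(m.n_members - spec.drivers_per_module)
        ]
        drivers[m.module_id] = mod_drivers
        for g in mod_drivers + members:
            assignment[g] = m.module_id
            genes.append(g)
    for j in range(spec.n_background_genes):
        g = f"BG_G{j + 1:03d}"
        assignment[g] = "background"
        genes.append(g)
    return genes, GroundTruth(assignment, drivers)


def generate_multi_cohort(spec: SyntheticStudySpec):
    """Generate one expression matrix per cohort plus the planted truth.

    Returns
    -------
    (list of ExpressionMatrix, GroundTruth)
        Gene identifiers are shared across cohorts; sample ids are
        ``{cohort}_S{j}``.
    """
    genes, truth = _gene_names(spec)
    n_genes = len(genes)
    s = spec.samples_per_cohort

    baseline_rng = np.random.default_rng([spec.seed, _BASELINE_STREAM])
    baseline = spec.baseline_mean + baseline_rng.normal(0.0, 1.0, n_genes)

    driver_noise_sd = 0.1 * spec.noise_sd
    var_d = 1.0 + 0.01  # driver variance at noise_sd = 1
    beta = spec.driver_loading

    matrices = []
    for ci in range(spec.n_cohorts):
        rng = np.random.default_rng([spec.seed, ci])
        cohort_id = f"cohort{ci + 1}"
        batch = rng.normal(0.0, spec.batch_shift_sd, n_genes) if spec.batch_shift_sd > 0 else np.zeros(n_genes)
        values = np.empty((n_genes, s))
        row = 0
        for m in spec.modules:
            factor = rng.standard_normal(s)
            driver_rows = []
            for _ in range(spec.drivers_per_module):
                d = factor + driver_noise_sd * rng.standard_normal(s)
                driver_rows.append(d)
                values[row] = d
                row += 1
            # member noise: rho exact at noise_sd = 1, correlations -> 1 as noise_sd -> 0
            if m.rho > 0:
                member_sd = spec.noise_sd * math.sqrt(beta * beta * var_d * (1 - m.rho) / m.rho)
            else:
                member_sd = spec.noise_sd * 10.0 * beta * math.sqrt(var_d)
            n_plain = m.n_members - spec.drivers_per_module
            for j in range(n_plain):
                d = driver_rows[j % len(driver_rows)]
                values[row] = beta * d + member_sd * rng.standard_normal(s)
                row += 1
        n_bg = spec.n_background_genes
        if n_bg:
            values[row : row + n_bg] = rng.normal(0.0, spec.noise_sd, (n_bg, s))
            row += n_bg
        assert row == n_genes
        values = values + baseline[:, None] + batch[:, None]
        df = pd.DataFrame(
            values,
            index=genes,
            columns=[f"{cohort_id}_S{j + 1}" for j in range(s)],
        )
        matrices.append(ExpressionMatrix(df, cohort_id))
    return matrices, truth


def plant_signature_response(
    matrix: ExpressionMatrix,
    signature: SignatureDefinition,
    condition_labels,
    delta: float,
    injured_label: str = "injured",
    reference_label: str = "reference",
    truth: GroundTruth | None = None,
) -> ExpressionMatrix:
    """Plant a poor-prognosis injury response on a matrix.

    Adds ``+delta`` to the poor-prognosis genes and ``-delta`` to the
    good-prognosis genes in samples labelled ``injured_label``; other
    entries are untouched. ``delta`` may be negative, which models the
    reversal of a previously planted injury. If ``truth`` is given its
    ``signature_direction`` is updated.
    """
    labels = list(condition_labels)
    if len(labels) != matrix.n_samples:
        raise ValueError(
            f"{len(labels)} labels for {matrix.n_samples} samples"
        )
    known = {injured_label, reference_label}
    unknown = sorted(set(labels) - known)
    if unknown:
        raise ValueError(f"unknown condition label(s): {unknown}")
    missing = (signature.poor_genes | signature.good_genes) - set(matrix.gene_ids)
    if missing:
        raise KeyError(f"signature gene(s) absent from matrix: {sorted(missing)[:5]}")

    out = matrix.values.copy()
    injured_cols = [s for s, lab in zip(out.columns, labels) if lab == injured_label]
    if injured_cols and delta != 0:
        out.loc[sorted(signature.poor_genes), injured_cols] += delta
        out.loc[sorted(signature.good_genes), injured_cols] -= delta
    if truth is not None:
        if delta > 0:
            poor_dir, good_dir = "induced", "suppressed"
        elif delta < 0:
            poor_dir, good_dir = "suppressed", "induced"
        else:
            poor_dir = good_dir = "null"
        truth.signature_direction[(injured_label, "poor")] = poor_dir
        truth.signature_direction[(injured_label, "good")] = good_dir
    return ExpressionMatrix(out, matrix.cohort_id)


def default_signature_from_background(
    truth: GroundTruth, n_poor: int = 15, n_good: int = 15, name: str = "synthetic_pls"
) -> SignatureDefinition:
    """Carve a two-subset signature out of the background genes so that a
    planted signature response leaves the coexpression structure alone."""
    background = sorted(truth.module_members("background"))
    if len(background) < n_poor + n_good:
        raise ValueError("not enough background genes for the requested signature")
    return SignatureDefinition(
        name,
        frozenset(background[:n_poor]),
        frozenset(background[n_poor : n_poor + n_good]),
    )


def default_study_spec(seed: int = 0, **overrides) -> SyntheticStudySpec:
    """The package's reference study: 3 cohorts x 80 samples (on the order
    of the smallest clinical cohort such analyses draw on), three modules
    of 12/16/20 genes (one hub driver each) at rho 0.6, beta 0.9, 50
    background genes."""
    return SyntheticStudySpec(seed=seed, **overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixtures(
    matrices,
    truth: GroundTruth,
    directory,
    signature: SignatureDefinition | None = None,
    spec: SyntheticStudySpec | None = None,
) -> dict:
    """Write cohort TSVs, ground-truth JSON and (optionally) the signature
    GMT into ``directory``; returns a manifest with paths and sha256
    checksums."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}

    for mat in matrices:
        p = write_expression_tsv(mat, directory / f"{mat.cohort_id}.tsv")
        files[p.name] = {"path": str(p), "sha256": _sha256(p)}

    truth_path = directory / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    files[truth_path.name] = {"path": str(truth_path), "sha256": _sha256(truth_path)}

    if signature is not None:
        sig_path = write_gmt(signature.to_gmt_sets(), directory / "signature.gmt")
        files[sig_path.name] = {"path": str(sig_path), "sha256": _sha256(sig_path)}

    manifest = {"files": files}
    if spec is not None:
        d = asdict(spec)
        d["modules"] = [asdict(m) for m in spec.modules]
        manifest["spec"] = d
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
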