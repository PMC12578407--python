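"""Candidate shortlist filtering and small study utilities.

After key-driver ranking, candidate targets are shortlisted by external
evidence flags: high expression in liver tissue, association with liver
disease in patients, and druggability of the encoded protein. Flags are
tri-state (True / False / None-unknown) so absence of evidence is
distinguishable from negative evidence; a required flag fails on unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["CandidateAnnotation", "filter_candidates", "tumor_volume"]

FLAG_FIELDS = ("liver_expression_high", "liver_disease_association", "druggable")


@dataclass(frozen=True)
class CandidateAnnotation:
    """External evidence for one gene; flags are True/False/None (unknown)."""

    gene: str
    liver_expression_high: bool | None = None
    liver_disease_association: bool | None = None
    druggable: bool | None = None
    evidence_note: str = ""


def filter_candidates(drivers, annotations, require=FLAG_FIELDS) -> pd.DataFrame:
    """Shortlist ranked drivers by required annotation flags.

    ``drivers`` is a list of KeyDriverResult (or anything with ``gene`` and
    ``rank``); ``annotations`` a list of CandidateAnnotation keyed by gene;
    ``require`` names the flags that must be True (unknown fails). Driver
    order is preserved. Genes without any annotation row are kept in a
    separate ``"unannotated"`` section rather than silently dropped; the
    returned DataFrame carries a ``section`` column in
    {"shortlist", "rejected", "unannotated"}.
    """
    require = list(require)
    unknown_flags = [f for f in require if f not in FLAG_FIELDS]
    if unknown_flags:
        raise ValueError(f"unknown flag(s): {unknown_flags}")
    by_gene = {}
    for ann in annotations:
        if ann.gene in by_gene:
            raise ValueError(f"duplicate annotation row for {ann.gene}")
        by_gene[ann.gene] = ann

    rows = []
    for drv in drivers:
        ann = by_gene.get(drv.gene)
        if ann is None:
            section = "unannotated"
            flags = {f: None for f in FLAG_FIELDS}
            note = ""
        else:
            flags = {f: getattr(ann, f) for f in FLAG_FIELDS}
            note = ann.evidence_note
            section = "shortlist" if all(flags[f] is True for f in require) else "rejected"
        rows.append(
            {
                "gene": drv.gene,
                "module_id": getattr(drv, "module_id", ""),
                "rank": getattr(drv, "rank", None),
                "section": section,
                **flags,
                "evidence_note": note,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "module_id", "rank", "section", *FLAG_FIELDS, "evidence_note"],
    )
    # shortlist first (driver order preserved within each section)
    order = {"shortlist": 0, "rejected": 1, "unannotated": 2}
    df["_o"] = df["section"].map(order)
    df = df.sort_values("_o", kind="stable").drop(columns="_o").reset_index(drop=True)
    return df


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume, 0.5 * L * W^2 (mm -> mm^3)."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    return 0.5 * length * width * width
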