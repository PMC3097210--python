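"""End-to-end orchestration: identify -> domains -> classify -> structure ->
report.

``run_full_pipeline`` screens a proteome for candidate chitinase and
chitinase-like proteins, annotates their domain architectures, assigns
groups I–VIII against labeled anchors, detects tandem-duplication clusters
and per-group chromosome tallies from the catalogue, and serializes a
catalogue report. Every stage is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

from . import __version__
from .architecture import ArchitectureProfile, summarize_architecture
from .genome_structure import (
    DEFAULT_CLUSTER_THRESHOLD,
    GeneCluster,
    detect_tandem_clusters,
    group_chromosome_tally,
)
from .motifs import CandidateCall, classify_candidate
from .phylogeny import GROUPS, GroupAssignment, assign_groups
from .seqio import CatalogueEntry, ProteinRecord

logger = logging.getLogger("chitfam.pipeline")

__all__ = ["CatalogueReport", "run_full_pipeline"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class CatalogueReport:
    """Aggregated result of a full pipeline run."""

    schema_version: int
    n_input_proteins: int
    candidates: list[CandidateCall] = field(default_factory=list)
    architectures: list[ArchitectureProfile] = field(default_factory=list)
    assignments: list[GroupAssignment] = field(default_factory=list)
    group_members: dict[str, list[str]] = field(default_factory=dict)
    clusters: list[GeneCluster] = field(default_factory=list)
    chromosome_tallies: dict[str, dict[str, int]] = field(default_factory=dict)
    species_totals: dict[str, int] = field(default_factory=dict)
    nomenclature: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["clusters"] = [asdict(c) for c in self.clusters]
        return json.dumps(payload, indent=2, default=str)


def run_full_pipeline(
    proteome: Sequence[ProteinRecord],
    anchors: Sequence[tuple[ProteinRecord, str]] | None = None,
    catalogue: Sequence[CatalogueEntry] | None = None,
    cluster_threshold: int = DEFAULT_CLUSTER_THRESHOLD,
    seed: int = 0,
) -> CatalogueReport:
    """Run the full analysis; any stage failure is re-raised with the stage
    name. With an empty proteome the catalogue-derived sections are still
    produced and a warning recorded."""
    report = CatalogueReport(
        schema_version=REPORT_SCHEMA_VERSION, n_input_proteins=len(proteome)
    )
    logger.info(
        "pipeline start: %d proteins, threshold=%d, seed=%d (chitfam %s)",
        len(proteome), cluster_threshold, seed, __version__,
    )
    if not proteome:
        report.warnings.append("empty proteome: sequence stages skipped")

    candidates: list[ProteinRecord] = []
    try:
        for rec in proteome:
            call = classify_candidate(rec)
            report.candidates.append(call)
            if call.is_candidate:
                candidates.append(rec)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"identify stage failed: {exc}") from exc

    try:
        for rec in candidates:
            report.architectures.append(summarize_architecture(rec))
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"domains stage failed: {exc}") from exc

    if anchors and candidates:
        try:
            arch_by_id = {a.protein_id: a for a in report.architectures}
            queries = []
            for rec in candidates:
                prof = arch_by_id[rec.id]
                cat = [d for d in prof.domains if d.kind == "catalytic"]
                if cat:
                    region = rec.sequence[cat[0].start - 1 : cat[0].end]
                    queries.append(ProteinRecord(rec.id, region))
                else:
                    queries.append(rec)
            report.assignments = assign_groups(queries, anchors)
        except Exception as exc:
            raise RuntimeError(f"classify stage failed: {exc}") from exc
        members: dict[str, list[str]] = {g: [] for g in GROUPS}
        for a in report.assignments:
            members[a.group].append(a.protein_id)
        report.group_members = {g: sorted(v) for g, v in members.items() if v}

    if catalogue:
        try:
            report.clusters = detect_tandem_clusters(catalogue, cluster_threshold)
            for g in GROUPS:
                tally = group_chromosome_tally(catalogue, g)
                if tally:
                    report.chromosome_tallies[g] = tally
            totals: dict[str, int] = {}
            for e in catalogue:
                if e.new_name is not None:
                    totals[e.species] = totals.get(e.species, 0) + 1
            report.species_totals = totals
            report.nomenclature = {
                e.old_name: e.new_name
                for e in catalogue
                if e.old_name and e.new_name and e.old_name != e.new_name
            }
        except Exception as exc:
            raise RuntimeError(f"structure stage failed: {exc}") from exc

    n_assigned = len(report.assignments)
    logger.info(
        "pipeline done: %d candidates, %d assigned, %d clusters",
        len(candidates), n_assigned, len(report.clusters),
    )
    return report
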