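"""Exon–intron summaries, tandem-duplication clusters and per-group
chromosome tallies.

Gene-family expansions by tandem duplication leave runs of paralogs close
together on one chromosome arm (the five chitinase-5 genes on 2R are the
canonical case in this family); cluster detection chains genes whose
intergenic gap stays within a threshold, 20 kb by default.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Sequence

from .seqio import CatalogueEntry, GeneModel

__all__ = [
    "ExonIntronSummary",
    "GeneCluster",
    "DEFAULT_CLUSTER_THRESHOLD",
    "summarize_gene_structure",
    "detect_tandem_clusters",
    "group_chromosome_tally",
]

DEFAULT_CLUSTER_THRESHOLD = 20_000  # bp


@dataclass(frozen=True)
class ExonIntronSummary:
    gene_id: str
    n_exons: int
    n_introns: int
    intron_sizes: tuple[int, ...]
    gene_span: int


@dataclass(frozen=True)
class GeneCluster:
    chromosome: str
    members: tuple[str, ...]  # ordered by start
    max_gap: int  # largest intergenic gap inside the cluster (bp)

    @property
    def size(self) -> int:
        return len(self.members)


def summarize_gene_structure(model: GeneModel) -> ExonIntronSummary:
    """Exon/intron counts and intron sizes for one gene model."""
    introns = model.introns
    return ExonIntronSummary(
        gene_id=model.gene_id,
        n_exons=len(model.exons),
        n_introns=len(introns),
        intron_sizes=tuple(i.span for i in introns),
        gene_span=model.interval.span,
    )


def detect_tandem_clusters(
    entries: Sequence[CatalogueEntry],
    threshold: int = DEFAULT_CLUSTER_THRESHOLD,
    include_singletons: bool = False,
) -> list[GeneCluster]:
    """Chain genes on the same arm whose intergenic gap is <= threshold.

    The intergenic gap between consecutive genes (sorted by start) is
    ``next.start - prev.end - 1``; overlapping genes (gap <= 0) always
    chain. Clusters of size >= 2 are reported, singletons optionally.
    """
    by_chrom: dict[str, list[CatalogueEntry]] = defaultdict(list)
    for e in entries:
        if e.interval is None:
            continue
        by_chrom[e.interval.chromosome].append(e)
    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda e: (e.interval.start, e.new_name or ""))
        run: list[CatalogueEntry] = [genes[0]]
        gaps: list[int] = []
        for prev, nxt in zip(genes, genes[1:]):
            gap = nxt.interval.start - prev.interval.end - 1
            if gap <= threshold:
                run.append(nxt)
                gaps.append(gap)
            else:
                clusters.append(_make_cluster(chrom, run, gaps))
                run, gaps = [nxt], []
        clusters.append(_make_cluster(chrom, run, gaps))
    if not include_singletons:
        clusters = [c for c in clusters if c.size >= 2]
    return clusters


def _make_cluster(chrom: str, run: list[CatalogueEntry], gaps: list[int]) -> GeneCluster:
    return GeneCluster(
        chromosome=chrom,
        members=tuple(e.new_name for e in run),
        max_gap=max(gaps) if gaps else 0,
    )


def group_chromosome_tally(
    entries: Sequence[CatalogueEntry], group: str
) -> dict[str, int]:
    """Counts of a group's members per chromosome arm (entries lacking an
    interval are skipped)."""
    tally: Counter[str] = Counter()
    for e in entries:
        if e.group == group and e.interval is not None:
            tally[e.interval.chromosome] += 1
    return dict(tally)
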