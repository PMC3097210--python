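"""Synthetic chitinase-family generator with a known truth manifest.

Emulates the structures the pipeline analyses: multi-domain proteins
carrying the four signature motifs (optionally with the catalytic-E
substituted), ChtBD2-like cysteine-sextet chitin-binding domains,
hydrophobic signal-peptide/transmembrane N-termini, sequences diverged
along a two-level tree (group ancestors, then members), multi-exon gene
models with a tandem-duplicated cluster, and qPCR Ct tables with known
fold changes and primer efficiency.

The substitution model is deliberately simple — i.i.d. per-site
replacement drawn uniformly from a neutral residue pool, with signature
positions protected — sufficient for recovery benchmarks, not a model of
real protein evolution. Identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .motifs import PRIMARY_MOTIF_NAME, SIGNATURE_MOTIFS
from .seqio import GeneModel, GenomicInterval, ProteinRecord
from .expression import CtRecord

__all__ = [
    "ArchitecturePlan",
    "SimulationConfig",
    "TruthManifest",
    "simulate_family",
    "simulate_gene_models",
    "simulate_qpcr",
    "default_group_plans",
]

GROUPS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

# Hydropathy-neutral, cysteine- and methionine-free pool for linkers and
# mutable sites: avoids spurious CBD sextets, TM windows and start-M signals.
NEUTRAL_POOL = "GSTNQDEKRAP"
HYDROPHOBIC_POOL = "ILVF"


@dataclass(frozen=True)
class ArchitecturePlan:
    """Planned domain content of one protein."""

    n_catalytic: int = 1
    n_cbd: int = 0
    signal: bool = False
    n_tm: int = 0


def default_group_plans() -> dict[str, ArchitecturePlan]:
    """Architecture plans mirroring the family's group layouts: most groups
    one catalytic domain; group II a 4-catalytic/4-CBD giant; group III
    2 catalytic with N-terminal transmembrane segments; group I secreted
    with one CBD."""
    return {
        "I": ArchitecturePlan(n_catalytic=1, n_cbd=1, signal=True),
        "II": ArchitecturePlan(n_catalytic=4, n_cbd=4, signal=True),
        "III": ArchitecturePlan(n_catalytic=2, n_tm=2),
        "IV": ArchitecturePlan(n_catalytic=1, signal=True),
        "V": ArchitecturePlan(n_catalytic=1, signal=True),
        "VI": ArchitecturePlan(n_catalytic=1, n_cbd=1, signal=True),
        "VII": ArchitecturePlan(n_catalytic=1),
        "VIII": ArchitecturePlan(n_catalytic=1),
    }


@dataclass
class SimulationConfig:
    seed: int
    n_groups: int = 8
    members_per_group: int | Mapping[str, int] = 3
    divergence: float = 0.05  # expected substitutions/site, ancestor -> member
    group_divergence: float = 0.30  # root -> group ancestor
    plans: Mapping[str, ArchitecturePlan] = field(default_factory=default_group_plans)
    ablate_motifs: bool = False  # substitute the catalytic E (E -> Q)
    # gene-model plan
    n_genes: int = 12
    exon_count_range: tuple[int, int] = (1, 19)
    intron_size_range: tuple[int, int] = (80, 2200)
    exon_size_range: tuple[int, int] = (100, 400)
    cluster_size: int = 5
    cluster_gap: int = 2000  # intergenic bp inside the tandem cluster
    # qPCR plan
    true_folds: Mapping[str, float] = field(
        default_factory=lambda: {"egg": 1.0, "larva": 8.0, "pupa": 0.5, "adult": 2.0}
    )
    target_gene: str = "AgCht5-1"
    reference_gene: str = "AgRPS3"
    baseline_ct: float = 24.0
    reference_ct: float = 18.0
    efficiency: float = 1.0
    ct_noise_sd: float = 0.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.divergence < 0 or self.group_divergence < 0:
            raise ValueError("divergence must be >= 0")
        if any(f <= 0 for f in self.true_folds.values()):
            raise ValueError("true fold changes must be > 0")


@dataclass
class ProteinTruth:
    group: str
    plan: ArchitecturePlan
    domains: tuple[tuple[str, int, int], ...]  # (kind, start, end), 1-based
    motif_positions: tuple[tuple[str, int], ...]  # (motif name, 1-based start)
    catalytic_sequence: str  # the member's (single-copy) catalytic domain


@dataclass
class GeneTruth:
    n_exons: int
    intron_sizes: tuple[int, ...]
    in_cluster: bool


@dataclass
class TruthManifest:
    proteins: dict[str, ProteinTruth] = field(default_factory=dict)
    ancestor_domains: dict[str, str] = field(default_factory=dict)
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    cluster_members: tuple[str, ...] = ()
    folds: dict[tuple[str, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Protein families

_MOTIF_OFFSETS = {  # planted offsets within the ~200-residue catalytic domain
    "KXXXXXGGW": 20,
    "FDGXDLDWEYP": 70,
    "MXYDXXG": 120,
    "GXXXWXXDXD": 160,
}
_DOMAIN_LENGTH = 200
_INTERDOMAIN_LINKER = 260  # keeps tandem catalytic regions > gap threshold apart


def _random_neutral(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NEUTRAL_POOL), size=n))


def _realize_motif(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        rng.choice(list(NEUTRAL_POOL)) if c == "X" else c for c in pattern
    )


def _build_root_domain(rng: np.random.Generator) -> tuple[str, set[int]]:
    """A catalytic domain with the four signatures planted at fixed offsets.
    Returns the sequence and the 0-based protected (non-X) positions."""
    seq = list(_random_neutral(rng, _DOMAIN_LENGTH))
    protected: set[int] = set()
    for motif in SIGNATURE_MOTIFS:
        off = _MOTIF_OFFSETS[motif.name]
        realized = _realize_motif(rng, motif.pattern)
        for k, (pat_c, res) in enumerate(zip(motif.pattern, realized)):
            seq[off + k] = res
            if pat_c != "X":
                protected.add(off + k)
    return "".join(seq), protected


def _evolve(
    rng: np.random.Generator, seq: str, protected: set[int], divergence: float
) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < divergence:
            choices = [c for c in NEUTRAL_POOL if c != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _cbd(rng: np.random.Generator) -> str:
    gaps = (10, 5, 12, 12, 8)  # within the ChtBD2 spacing ranges
    parts = []
    for g in gaps:
        parts.append("C" + _random_neutral(rng, g))
    return "".join(parts) + "C"


def _ablate(domain: str) -> str:
    return domain.replace("DWEYP", "DWQYP")


def simulate_family(config: SimulationConfig) -> tuple[list[ProteinRecord], TruthManifest]:
    """Generate a family of proteins with known groups, domains and motifs.

    A root catalytic domain carrying the four signatures is evolved into
    ``n_groups`` group ancestors (at ``group_divergence``) and then into
    members (at ``divergence``); signature non-X positions never mutate
    unless ``ablate_motifs`` is set, in which case the catalytic E is
    substituted (E -> Q) in every emitted member. Proteins are assembled
    per the group's architecture plan.
    """
    if config.n_groups < 1 or config.n_groups > len(GROUPS):
        raise ValueError(f"n_groups must be in 1..{len(GROUPS)}")
    rng = np.random.default_rng(config.seed)
    root, protected = _build_root_domain(rng)
    manifest = TruthManifest()
    records: list[ProteinRecord] = []
    groups = GROUPS[: config.n_groups]
    for group in groups:
        plan = config.plans.get(group, ArchitecturePlan())
        if plan.n_catalytic < 1:
            raise ValueError(f"group {group}: plans need >= 1 catalytic domain")
        ancestor = _evolve(rng, root, protected, config.group_divergence)
        manifest.ancestor_domains[group] = ancestor
        if isinstance(config.members_per_group, int):
            n_members = config.members_per_group
        else:
            n_members = config.members_per_group.get(group, 1)
        for k in range(1, n_members + 1):
            member_domain = _evolve(rng, ancestor, protected, config.divergence)
            if config.ablate_motifs:
                member_domain = _ablate(member_domain)
            name = f"{group}_{k}"
            seq, truth = _assemble(rng, name, group, plan, member_domain)
            records.append(ProteinRecord(name, seq, description=f"group {group}"))
            manifest.proteins[name] = truth
    return records, manifest


def _assemble(
    rng: np.random.Generator,
    name: str,
    group: str,
    plan: ArchitecturePlan,
    domain: str,
) -> tuple[str, ProteinTruth]:
    parts: list[str] = []
    domains: list[tuple[str, int, int]] = []
    motif_positions: list[tuple[str, int]] = []
    pos = 0  # 0-based running length

    def add(piece: str) -> int:
        nonlocal pos
        parts.append(piece)
        start = pos
        pos += len(piece)
        return start

    if plan.signal:
        piece = "M" + "".join(rng.choice(list(HYDROPHOBIC_POOL), size=11))
        start = add(piece)
        domains.append(("signal_peptide", start + 1, pos))
        add(_random_neutral(rng, 15))
    for _ in range(plan.n_tm):
        # strongly hydrophilic spacer so consecutive TM windows cannot bridge
        add("".join(rng.choice(list("DENKR"), size=15)))
        start = add("".join(rng.choice(list(HYDROPHOBIC_POOL), size=19)))
        domains.append(("transmembrane", start + 1, pos))
    add(_random_neutral(rng, 20))
    for d in range(plan.n_catalytic):
        if d > 0:
            add(_random_neutral(rng, _INTERDOMAIN_LINKER))
        start = add(domain)
        domains.append(("catalytic", start + 1, pos))
        for motif_name, off in _MOTIF_OFFSETS.items():
            motif_positions.append((motif_name, start + off + 1))
    for _ in range(plan.n_cbd):
        add(_random_neutral(rng, 25))
        start = add(_cbd(rng))
        domains.append(("CBD", start + 1, pos))
    add(_random_neutral(rng, 20))
    truth = ProteinTruth(
        group=group,
        plan=plan,
        domains=tuple(domains),
        motif_positions=tuple(sorted(motif_positions, key=lambda x: x[1])),
        catalytic_sequence=domain,
    )
    return "".join(parts), truth


# ---------------------------------------------------------------------------
# Gene models


def simulate_gene_models(config: SimulationConfig) -> tuple[list[GeneModel], TruthManifest]:
    """Emit GFF3-serializable gene models with known exon layouts, including
    a tandem-cluster block of ``cluster_size`` genes within ``cluster_gap``
    of each other on arm 2R; the remaining genes are spread far apart on
    other arms."""
    rng = np.random.default_rng(config.seed + 1)
    manifest = TruthManifest()
    models: list[GeneModel] = []
    lo_e, hi_e = config.exon_count_range
    if lo_e < 1:
        raise ValueError("exon counts must be >= 1")

    def make_gene(gene_id: str, chrom: str, start: int, in_cluster: bool) -> GeneModel:
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        exons = []
        cursor = start
        intron_sizes = []
        for i in range(n_exons):
            size = int(rng.integers(config.exon_size_range[0], config.exon_size_range[1] + 1))
            exons.append(GenomicInterval(chrom, cursor, cursor + size - 1))
            cursor += size
            if i < n_exons - 1:
                intron = int(
                    rng.integers(config.intron_size_range[0], config.intron_size_range[1] + 1)
                )
                intron_sizes.append(intron)
                cursor += intron
        interval = GenomicInterval(chrom, start, exons[-1].end)
        manifest.genes[gene_id] = GeneTruth(
            n_exons=n_exons, intron_sizes=tuple(intron_sizes), in_cluster=in_cluster
        )
        return GeneModel(gene_id, interval, tuple(exons))

    cursor = 100_000
    cluster_ids = []
    for k in range(config.cluster_size):
        gid = f"simCht5-{k + 1}"
        gene = make_gene(gid, "2R", cursor, in_cluster=True)
        cluster_ids.append(gid)
        gap = int(rng.integers(50, max(51, config.cluster_gap)))
        cursor = gene.interval.end + 1 + gap
        models.append(gene)
    manifest.cluster_members = tuple(cluster_ids)
    arms = ["2L", "3L", "3R", "X"]
    cursors = {arm: 500_000 for arm in arms}
    for k in range(config.n_genes - config.cluster_size):
        arm = arms[k % len(arms)]
        gid = f"simCht{k + 10}"
        gene = make_gene(gid, arm, cursors[arm], in_cluster=False)
        cursors[arm] = gene.interval.end + 1 + 100_000  # far beyond any threshold
        models.append(gene)
    return models, manifest


# ---------------------------------------------------------------------------
# qPCR tables


def simulate_qpcr(config: SimulationConfig) -> tuple[list[CtRecord], TruthManifest]:
    """Ct tables with known fold changes.

    Ct = baseline - log2(fold) / log2(1 + E) + N(0, sd); the reference gene
    is constant across samples. The first sample with fold 1 (or the first
    sample) is the intended calibrator.
    """
    rng = np.random.default_rng(config.seed + 2)
    manifest = TruthManifest()
    records: list[CtRecord] = []
    log_base = np.log2(1.0 + config.efficiency)
    for sample, fold in config.true_folds.items():
        manifest.folds[(sample, config.target_gene)] = float(fold)
        manifest.folds[(sample, config.reference_gene)] = 1.0
        for rep in range(1, config.n_replicates + 1):
            noise_t = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
            noise_r = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
            ct_target = config.baseline_ct - float(np.log2(fold)) / float(log_base) + noise_t
            records.append(CtRecord(sample, config.target_gene, rep, ct_target))
            records.append(
                CtRecord(sample, config.reference_gene, rep, config.reference_ct + noise_r)
            )
    return records, manifest
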