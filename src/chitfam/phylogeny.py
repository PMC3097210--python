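"""Catalytic-domain phylogenetics: alignment, distances, neighbor joining,
bootstrap supports and group I–VIII assignment.

The family classification rests on a distance phylogeny of catalytic-domain
amino-acid sequences: sequences are aligned (progressive alignment over a
UPGMA guide tree), pairwise distances computed (p-distance or its Poisson
correction -ln(1-p)), a neighbor-joining tree built, and internal-edge
supports estimated by bootstrap resampling of alignment columns. Queries
are assigned to one of the eight groups (I–VIII) by their placement
relative to labeled anchor sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from skbio import DistanceMatrix, TreeNode

from .seqio import ProteinRecord

__all__ = [
    "Alignment",
    "GroupAssignment",
    "GROUPS",
    "pairwise_global_align",
    "build_msa",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "assign_groups",
    "write_newick",
    "read_newick",
]

GROUPS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

GAP = "-"
GAP_OPEN = -10.0
GAP_EXTEND = -1.0


@dataclass(frozen=True)
class Alignment:
    """A multiple alignment: taxon ids plus equal-length gapped rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)]


@dataclass(frozen=True)
class GroupAssignment:
    protein_id: str
    group: str
    support: float  # patristic distance to the nearest anchor of the group


def _scoring_matrix(extra: set[str]) -> substitution_matrices.Array:
    """BLOSUM62 extended so that residues absent from the matrix score 0
    against everything."""
    base = substitution_matrices.load("BLOSUM62")
    known = set(base.alphabet)
    missing = sorted(extra - known)
    if not missing:
        return base
    alphabet = "".join(base.alphabet) + "".join(missing)
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in base.alphabet:
        for b in base.alphabet:
            mat[a, b] = base[a, b]
    return mat


def pairwise_global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: substitution_matrices.Array | None = None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> Alignment:
    """Optimal global (Needleman–Wunsch, affine-gap) alignment of two
    proteins under BLOSUM62 by default. A gap of length k costs
    ``gap_open + (k-1) * gap_extend``. Deterministic."""
    if not a.sequence or not b.sequence:
        raise ValueError("pairwise alignment requires non-empty sequences")
    if matrix is None:
        matrix = _scoring_matrix(set(a.sequence) | set(b.sequence))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a.sequence, b.sequence)[0]
    return Alignment(ids=(a.id, b.id), rows=(str(aln[0]), str(aln[1])))


def alignment_score(a: ProteinRecord, b: ProteinRecord, **kw) -> float:
    matrix = kw.pop("matrix", None)
    if matrix is None:
        matrix = _scoring_matrix(set(a.sequence) | set(b.sequence))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = kw.pop("gap_open", GAP_OPEN)
    aligner.extend_gap_score = kw.pop("gap_extend", GAP_EXTEND)
    return float(aligner.score(a.sequence, b.sequence))


def _pair_p_distance(row_a: str, row_b: str) -> float:
    compared = mismatch = 0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            mismatch += 1
    if compared == 0:
        return 1.0
    return mismatch / compared


# ---------------------------------------------------------------------------
# Progressive multiple alignment

_ALPHA = "ACDEFGHIKLMNPQRSTVWYX"
_ALPHA_INDEX = {c: i for i, c in enumerate(_ALPHA)}


def _profile(rows: Sequence[str]) -> np.ndarray:
    """Per-column residue-frequency profile; gaps contribute nothing, so
    gappy columns are down-weighted in the sum-of-pairs score."""
    n_rows = len(rows)
    n_cols = len(rows[0])
    prof = np.zeros((n_cols, len(_ALPHA)))
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                prof[j, _ALPHA_INDEX.get(c, _ALPHA_INDEX["X"])] += 1.0
    return prof / n_rows


def _submatrix_array(matrix) -> np.ndarray:
    m = np.zeros((len(_ALPHA), len(_ALPHA)))
    for i, a in enumerate(_ALPHA):
        for j, b in enumerate(_ALPHA):
            m[i, j] = matrix[a, b]
    return m


def _profile_align(
    rows_a: list[str], rows_b: list[str], score_m: np.ndarray,
    gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND,
) -> tuple[list[str], list[str]]:
    """Affine-gap (Gotoh) alignment of two profiles under average
    sum-of-pairs scoring; returns the two row sets padded with the new gap
    columns."""
    pa = _profile(rows_a)
    pb = _profile(rows_b)
    sp = pa @ score_m @ pb.T  # column-vs-column scores
    la, lb = sp.shape
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    Ix = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A)
    Iy = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, la + 1):
        spi = sp[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Ixi, Ixi1 = Ix[i], Ix[i - 1]
        Iyi, Iyi1 = Iy[i], Iy[i - 1]
        for j in range(1, lb + 1):
            best = Mi1[j - 1]
            if Ixi1[j - 1] > best:
                best = Ixi1[j - 1]
            if Iyi1[j - 1] > best:
                best = Iyi1[j - 1]
            Mi[j] = best + spi[j - 1]
            Ixi[j] = max(Mi1[j] + gap_open, Ixi1[j] + gap_extend,
                         Iyi1[j] + gap_open)
            Iyi[j] = max(Mi[j - 1] + gap_open, Iyi[j - 1] + gap_extend,
                         Ixi[j - 1] + gap_open)
    # traceback: prefer match, then gap-in-B, then gap-in-A
    i, j = la, lb
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and state == 0:
            ops.append("M")
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            target = M[i, j] - sp[i - 1, j - 1]
            state = int(np.argmax([1 if abs(p - target) < 1e-6 else 0 for p in prev])) \
                if any(abs(p - target) < 1e-6 for p in prev) else int(np.argmax(prev))
            i -= 1
            j -= 1
        elif i > 0 and (state == 1 or j == 0):
            ops.append("X")
            cands = [M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend,
                     Iy[i - 1, j] + gap_open]
            target = Ix[i, j]
            state = next((k for k, p in enumerate(cands) if abs(p - target) < 1e-6),
                         int(np.argmax(cands)))
            i -= 1
        else:
            ops.append("Y")
            cands = [M[i, j - 1] + gap_open, Ix[i, j - 1] + gap_open,
                     Iy[i, j - 1] + gap_extend]
            target = Iy[i, j]
            state = next((k for k, p in enumerate(cands) if abs(p - target) < 1e-6),
                         int(np.argmax(cands)))
            j -= 1
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "M":
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ia += 1
            ib += 1
        elif op == "X":
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def build_msa(records: Sequence[ProteinRecord]) -> Alignment:
    """Progressive multiple alignment.

    Guide tree: UPGMA (average linkage) on pairwise p-distances from
    optimal pairwise global alignments; profiles are then merged in
    guide-tree order under average sum-of-pairs BLOSUM62 scoring with
    affine gaps.
    """
    if len(records) < 2:
        raise ValueError("multiple alignment requires at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in MSA input")
    matrix = _scoring_matrix(set("".join(r.sequence for r in records)))
    score_m = _submatrix_array(matrix)
    n = len(records)
    if n == 2:
        pair = pairwise_global_align(records[0], records[1], matrix=matrix)
        return pair
    # pairwise distances for the guide tree
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = pairwise_global_align(records[i], records[j], matrix=matrix)
            d = _pair_p_distance(pair.rows[0], pair.rows[1])
            dist[i, j] = dist[j, i] = d
    condensed = dist[np.triu_indices(n, k=1)]
    merges = linkage(condensed, method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([records[i].id], [records[i].sequence]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(merges):
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        new_a, new_b = _profile_align(rows_a, rows_b, score_m)
        clusters[n + step] = (ids_a + ids_b, new_a + new_b)
    final_ids, final_rows = clusters.popitem()[1]
    # keep the caller's input order in the output
    row_of = dict(zip(final_ids, final_rows))
    return Alignment(ids=tuple(ids), rows=tuple(row_of[i] for i in ids))


# ---------------------------------------------------------------------------
# Distances and neighbor joining


def distance_matrix(aln: Alignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gapped columns.

    ``p`` is the proportion of differing sites among columns where both
    rows are ungapped; ``poisson`` applies the multiple-hit correction
    d = -ln(1 - p).
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    n = len(aln.ids)
    if n < 2:
        raise ValueError("distance matrix requires >= 2 rows")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb = aln.rows[i], aln.rows[j]
            compared = sum(1 for x, y in zip(ra, rb) if x != GAP and y != GAP)
            if compared == 0:
                raise ValueError(
                    f"no comparable sites for pair ({aln.ids[i]}, {aln.ids[j]})"
                )
            p = _pair_p_distance(ra, rb)
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        "Poisson correction undefined at p=1 for pair "
                        f"({aln.ids[i]}, {aln.ids[j]})"
                    )
                val = -math.log(1.0 - p)
            else:
                val = p
            d[i, j] = d[j, i] = val
    return DistanceMatrix(d, ids=list(aln.ids))


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing
    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); branch lengths by
    the standard NJ formulas, with negative lengths clamped to 0 (the raw
    value is kept on the node as ``raw_length``). Q ties are broken by the
    lexicographically smallest pair of cluster labels, where a cluster is
    labeled by its smallest leaf name; this makes the output invariant to
    input taxon order.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    D = np.array(dm.data, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")

    def make_leaf(name: str) -> TreeNode:
        node = TreeNode(name=name)
        return node

    nodes: list[TreeNode] = [make_leaf(name) for name in ids]
    labels: list[str] = list(ids)  # smallest leaf label per cluster

    def set_length(node: TreeNode, raw: float) -> None:
        node.raw_length = raw
        node.length = max(0.0, raw)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            ((i, j) for i, j in cand if i < j),
            key=lambda ij: tuple(sorted((labels[ij[0]], labels[ij[1]]))),
        )
        i, j = best
        dij = D[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        set_length(nodes[i], li)
        set_length(nodes[j], lj)
        parent.append(nodes[i])
        parent.append(nodes[j])
        new_d = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.zeros((len(keep) + 1, len(keep) + 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = new_d[keep]
        D_new[:-1, -1] = new_d[keep]
        D = D_new
        new_label = min(labels[i], labels[j])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [new_label]

    # terminal 3-cluster join: star root with closed-form branch lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = (d01 + d02 - d12) / 2.0
    l1 = (d01 + d12 - d02) / 2.0
    l2 = (d02 + d12 - d01) / 2.0
    root = TreeNode()
    for node, ln in zip(nodes, (l0, l1, l2)):
        set_length(node, ln)
        root.append(node)
    return root


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized to
    the side not containing the alphabetically first taxon."""
    ref = min(taxa)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if ref in side:
            side = taxa - side
        parts.add(side)
    return parts


def bootstrap_support(
    aln: Alignment,
    replicates: int,
    seed: int,
    model: str = "poisson",
    tree_builder: Callable[[DistanceMatrix], TreeNode] = neighbor_joining,
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports.

    Alignment columns are resampled with replacement per replicate
    (gapped columns included); the support of each internal edge of the
    full-data tree is the percentage of replicate trees containing the
    same bipartition. Reproducible given the seed. Replicates whose
    resampled distance matrix is undefined (e.g. a pair with no comparable
    sites) are skipped and the denominator reduced accordingly.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if aln.n_columns < 2:
        raise ValueError("bootstrap requires an alignment of >= 2 columns")
    rng = np.random.default_rng(seed)
    tree = tree_builder(distance_matrix(aln, model=model))
    taxa = frozenset(aln.ids)
    counts: dict[frozenset[str], int] = {p: 0 for p in _bipartitions(tree, taxa)}
    effective = 0
    n_cols = aln.n_columns
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rows = tuple("".join(row[c] for c in cols) for row in aln.rows)
        try:
            rep_dm = distance_matrix(Alignment(aln.ids, rows), model=model)
            rep_tree = tree_builder(rep_dm)
        except ValueError:
            continue
        effective += 1
        rep_parts = _bipartitions(rep_tree, taxa)
        for part in counts:
            if part in rep_parts:
                counts[part] += 1
    denom = max(1, effective)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if min(taxa) in side:
            side = taxa - side
        if side in counts:
            # skbio's newick writer emits `support` as the internal label
            node.support = 100.0 * counts[side] / denom
    return tree


def write_newick(tree: TreeNode) -> str:
    import io

    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    import io

    return TreeNode.read(io.StringIO(text))


# ---------------------------------------------------------------------------
# Group assignment


def assign_groups(
    queries: Sequence[ProteinRecord],
    anchors: Sequence[tuple[ProteinRecord, str]],
    model: str = "poisson",
) -> list[GroupAssignment]:
    """Assign each query to one of the eight groups (I–VIII) by placement
    in a joint NJ tree with labeled anchors.

    A query takes the group of the anchor set whose smallest enclosing
    clade contains it (smallest clade wins; ties go to the lower group
    numeral). Queries contained in no proper anchor clade fall back to the
    nearest anchor by patristic distance.
    """
    anchor_groups = {rec.id: g for rec, g in anchors}
    covered = set(anchor_groups.values())
    missing = [g for g in GROUPS if g not in covered]
    if missing:
        raise ValueError(f"anchors missing groups: {', '.join(missing)}")
    query_ids = {q.id for q in queries}
    records = list(queries) + [rec for rec, _ in anchors if rec.id not in query_ids]
    aln = build_msa(records)
    dm = distance_matrix(aln, model=model)
    tree = neighbor_joining(dm)
    tips = {t.name: t for t in tree.tips()}
    n_taxa = len(tips)
    patristic = tree.tip_tip_distances()

    group_rank = {g: k for k, g in enumerate(GROUPS)}
    clades: list[tuple[str, frozenset[str], int]] = []
    for g in sorted(covered, key=lambda x: group_rank[x]):
        members = [tips[aid] for aid, gg in anchor_groups.items() if gg == g]
        lca = members[0] if len(members) == 1 else tree.lowest_common_ancestor(members)
        clade_tips = frozenset(t.name for t in lca.tips()) if not lca.is_tip() \
            else frozenset([lca.name])
        clades.append((g, clade_tips, len(clade_tips)))

    out = []
    for q in queries:
        containing = [
            (size, group_rank[g], g)
            for g, clade_tips, size in clades
            if q.id in clade_tips and size < n_taxa
        ]
        if containing:
            containing.sort()
            group = containing[0][2]
        else:
            group = None
        # nearest anchor distance (also the fallback assignment)
        nearest = sorted(
            (float(patristic[q.id, aid]), group_rank[g], aid, g)
            for aid, g in anchor_groups.items()
        )
        if group is None:
            group = nearest[0][3]
        dist_to_group = min(
            float(patristic[q.id, aid])
            for aid, g in anchor_groups.items()
            if g == group
        )
        out.append(GroupAssignment(q.id, group, dist_to_group))
    return out
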