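"""BLOSUM-rescaled distances, neighbour joining and PR-SET class assignment.

The residue distance is derived from a BLOSUM-style substitution matrix B
as D(x, y) = -B(x, y) + (B(x, x) + B(y, y)) / 2, which is zero on the
diagonal, symmetric, and non-negative whenever off-diagonal scores do not
exceed the mean of the corresponding diagonal entries (true of BLOSUM62).
The distance between two aligned sequences is the mean of D over the
columns where *both* carry an unambiguous residue. Trees are built with
classic Saitou–Nei neighbour joining (deterministic lexicographic
tie-break) and rooted on an outgroup; classes are assigned by an
average-linkage cut of the pairwise distance matrix, numbered by
increasing mean distance to a designated reference sequence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

__all__ = [
    "RESIDUES",
    "SubstitutionMatrix",
    "RescaledDistanceMatrix",
    "PairwiseDistanceMatrix",
    "ClassAssignment",
    "load_substitution_matrix",
    "rescale_substitution_matrix",
    "aligned_pair_distance",
    "pairwise_distance_matrix",
    "neighbor_joining",
    "root_by_outgroup",
    "assign_classes",
]

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RES_INDEX = {a: i for i, a in enumerate(RESIDUES)}


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric 20x20 residue score matrix in :data:`RESIDUES` order."""

    name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.shape != (20, 20):
            raise ValueError("expected a 20x20 matrix")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")
        diag = np.diag(self.scores)
        off = self.scores[~np.eye(20, dtype=bool)]
        if diag.min() < off.max():
            log.warning(
                "%s: some off-diagonal scores exceed the smallest diagonal "
                "entry", self.name,
            )


@dataclass(frozen=True)
class RescaledDistanceMatrix:
    """Residue distances D(x,y) = -B(x,y) + (B(x,x) + B(y,y)) / 2."""

    name: str
    distances: np.ndarray  # (20, 20)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        x, y = pair
        return float(self.distances[_RES_INDEX[x], _RES_INDEX[y]])


@dataclass
class PairwiseDistanceMatrix:
    """Mean residue distances between aligned sequences."""

    labels: list[str]
    matrix: np.ndarray      # (n, n); NaN where no columns overlap
    n_aligned: np.ndarray   # (n, n) int

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {
            (a, b): float(self.matrix[i, j])
            for i, a in enumerate(self.labels)
            for j, b in enumerate(self.labels)
        }


@dataclass
class ClassAssignment:
    """Cluster labels 1..k ordered by similarity to the reference row."""

    labels: dict[str, int]
    k: int
    reference: str

    _ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI",
              7: "VII", 8: "VIII", 9: "IX", 10: "X"}

    def roman(self, label: str) -> str:
        cls = self.labels[label]
        return self._ROMAN.get(cls, str(cls))


def load_substitution_matrix(source: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a substitution matrix by name (Biopython's collection) or from a
    matrix text file in the standard layout (comment lines, residue header)."""
    try:
        mat = substitution_matrices.load(source)
        name = source
    except (FileNotFoundError, ValueError):
        mat = substitution_matrices.read(source)
        name = str(getattr(mat, "name", None) or source)
    scores = np.empty((20, 20))
    for i, x in enumerate(RESIDUES):
        for j, y in enumerate(RESIDUES):
            scores[i, j] = mat[x, y]
    return SubstitutionMatrix(name=name, scores=scores)


def rescale_substitution_matrix(
    B: SubstitutionMatrix,
) -> RescaledDistanceMatrix:
    """Exact rescaling D(x,y) = -B(x,y) + (B(x,x) + B(y,y)) / 2."""
    diag = np.diag(B.scores)
    D = -B.scores + (diag[:, None] + diag[None, :]) / 2.0
    return RescaledDistanceMatrix(name=B.name, distances=D)


def _encode(row: str) -> np.ndarray:
    """Residue indices; gaps and unknown/ambiguous residues become -1."""
    return np.array(
        [_RES_INDEX.get(ch, -1) for ch in row.upper()], dtype=np.int64
    )


def aligned_pair_distance(
    row_a: str, row_b: str, D: RescaledDistanceMatrix
) -> float:
    """Mean residue distance over columns where both rows carry residues.

    Gap and unknown characters (anything outside the 20 canonical residues)
    are excluded from the aligned set; a pair with no overlapping residue
    columns raises.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    ia, ib = _encode(row_a), _encode(row_b)
    mask = (ia >= 0) & (ib >= 0)
    if not mask.any():
        raise ValueError("rows share no aligned residue columns")
    return float(D.distances[ia[mask], ib[mask]].mean())


def pairwise_distance_matrix(
    alignment, D: RescaledDistanceMatrix
) -> PairwiseDistanceMatrix:
    """All unordered pair distances over an alignment.

    Accepts [(id, row)] pairs or SeqRecord iterables. Pairs with no
    overlapping residue columns are recorded as NaN with a warning.
    """
    rows: list[tuple[str, str]] = []
    for item in alignment:
        if isinstance(item, tuple):
            rows.append((item[0], str(item[1]).upper()))
        else:
            rows.append((item.id, str(item.seq).upper()))
    if len(rows) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(rows[0][1])
    if any(len(seq) != length for _, seq in rows):
        raise ValueError("ragged alignment: rows differ in length")
    labels = [rid for rid, _ in rows]
    enc = np.vstack([_encode(seq) for _, seq in rows])
    n = len(rows)
    mat = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for i, j in itertools.combinations(range(n), 2):
        mask = (enc[i] >= 0) & (enc[j] >= 0)
        m = int(mask.sum())
        counts[i, j] = counts[j, i] = m
        if m == 0:
            log.warning(
                "pair (%s, %s) shares no aligned residues", labels[i],
                labels[j],
            )
            mat[i, j] = mat[j, i] = np.nan
        else:
            d = float(D.distances[enc[i, mask], enc[j, mask]].mean())
            mat[i, j] = mat[j, i] = d
    np.fill_diagonal(counts, (enc >= 0).sum(axis=1))
    return PairwiseDistanceMatrix(labels=labels, matrix=mat, n_aligned=counts)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(M: PairwiseDistanceMatrix) -> dendropy.Tree:
    """Classic Saitou–Nei neighbour joining.

    Q-criterion pair selection with ties broken by the lexicographically
    smallest (label, label) pair, standard branch-length formulas,
    agglomeration down to three clusters resolved by the closed-form
    three-point formulas. Negative branch lengths are clamped to zero with
    the deficit logged. Returns an unrooted dendropy tree.
    """
    if np.isnan(M.matrix).any():
        raise ValueError("distance matrix has missing entries")
    n = len(M.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(M.labels)
    nodes: dict[str, dendropy.Node] = {}
    for lab in M.labels:
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(lab)
        nodes[lab] = nd
    # active cluster labels: the lexicographically smallest member leaf
    active = list(M.labels)
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(M.labels):
        for j, b in enumerate(M.labels):
            if i < j:
                key = (min(a, b), max(a, b))
                dist[key] = float(M.matrix[i, j])

    def d(a: str, b: str) -> float:
        return 0.0 if a == b else dist[(min(a, b), max(a, b))]

    def clamp(length: float, where: str) -> float:
        if length < 0:
            log.info("clamped negative branch length %.6g at %s", length,
                     where)
            return 0.0
        return length

    while len(active) > 3:
        r = len(active)
        R = {a: sum(d(a, b) for b in active) for a in active}
        best = None
        best_q = np.inf
        for a, b in itertools.combinations(sorted(active), 2):
            q = (r - 2) * d(a, b) - R[a] - R[b]
            if q < best_q - 1e-12:
                best_q, best = q, (a, b)
        a, b = best
        la = d(a, b) / 2 + (R[a] - R[b]) / (2 * (r - 2))
        lb = d(a, b) - la
        parent = dendropy.Node()
        ca, cb = nodes.pop(a), nodes.pop(b)
        parent.add_child(ca)
        parent.add_child(cb)
        ca.edge.length = clamp(la, a)
        cb.edge.length = clamp(lb, b)
        new_label = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            nd = (d(a, c) + d(b, c) - d(a, b)) / 2
            dist[(min(new_label, c), max(new_label, c))] = nd
        active = sorted(set(active) - {a, b} | {new_label})
        nodes[new_label] = parent

    a, b, c = sorted(active)
    center = dendropy.Node()
    la = (d(a, b) + d(a, c) - d(b, c)) / 2
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2
    for lab, length in ((a, la), (b, lb), (c, lc)):
        nd = nodes.pop(lab)
        center.add_child(nd)
        nd.edge.length = clamp(length, lab)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def root_by_outgroup(tree: dendropy.Tree, leaf_label: str) -> dendropy.Tree:
    """Root at the midpoint of the outgroup's pendant branch.

    The outgroup becomes a direct child of the new root; the leaf set is
    unchanged and re-rooting by the same leaf is topologically idempotent.
    """
    tree = tree.clone(depth=1)
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == leaf_label:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup leaf {leaf_label!r} not in tree")
    length = leaf.edge.length or 0.0
    tree.reroot_at_edge(
        leaf.edge, length1=length / 2, length2=length / 2,
        update_bipartitions=False,
    )
    tree.is_rooted = True
    return tree


def assign_classes(
    M: PairwiseDistanceMatrix, k: int = 4, reference: str | None = None
) -> ClassAssignment:
    """Average-linkage cut of the distance matrix into k classes.

    Classes are renumbered 1..k by increasing mean distance of their
    members to the ``reference`` sequence (default: the first label), so
    class 1 (I) is the most reference-similar.
    """
    n = len(M.labels)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    if np.isnan(M.matrix).any():
        raise ValueError("distance matrix has missing entries")
    reference = reference if reference is not None else M.labels[0]
    if reference not in M.labels:
        raise ValueError(f"reference {reference!r} not among labels")
    sym = (M.matrix + M.matrix.T) / 2
    np.fill_diagonal(sym, 0.0)
    Z = linkage(squareform(sym, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    ref_idx = M.labels.index(reference)
    cluster_ids = sorted(set(raw))
    means = {
        cid: float(sym[ref_idx, raw == cid].mean()) for cid in cluster_ids
    }
    order = sorted(cluster_ids, key=lambda cid: means[cid])
    remap = {cid: rank + 1 for rank, cid in enumerate(order)}
    labels = {
        lab: remap[raw[i]] for i, lab in enumerate(M.labels)
    }
    return ClassAssignment(labels=labels, k=k, reference=reference)
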