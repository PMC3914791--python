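"""Distance-based phylogenetics of NBS domains.

The workflow mirrors the classic Phylip pipeline: protein distances from a
multiple alignment (Dayhoff-style ML distances or Kimura-corrected
p-distances), Saitou–Nei neighbor joining, column-resampled bootstrap
replicates, and a strict majority-rule consensus with per-node supports.
On top of the trees sit the clade analyses: genus-specific (single-group)
maximal clades and monophyly checks of externally defined clades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import minimize_scalar

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "dayhoff_rate_matrix",
    "protein_distance",
    "neighbor_joining",
    "bootstrap_trees",
    "majority_rule_consensus",
    "genus_specific_clades",
    "assign_clades",
    "tree_splits",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Dayhoff 1978 equilibrium amino-acid frequencies.
DAYHOFF_FREQS = {
    "A": 0.087, "R": 0.041, "N": 0.040, "D": 0.047, "C": 0.033,
    "Q": 0.038, "E": 0.050, "G": 0.089, "H": 0.034, "I": 0.037,
    "L": 0.085, "K": 0.081, "M": 0.015, "F": 0.040, "P": 0.051,
    "S": 0.070, "T": 0.058, "W": 0.010, "Y": 0.030, "V": 0.065,
}


@dataclass
class Alignment:
    """Gapped protein alignment: unique labels, equal-length rows."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("alignment labels must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have differing lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.labels)

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        idx = rng.integers(0, self.n_columns, size=self.n_columns)
        return Alignment(
            labels=list(self.labels),
            rows=["".join(row[i] for i in idx) for row in self.rows],
        )


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


# ---------------------------------------------------------------------------
# Dayhoff-style rate matrix and distances

_rate_cache: dict[str, tuple] = {}


def dayhoff_rate_matrix() -> tuple[np.ndarray, np.ndarray]:
    """Reversible empirical rate matrix (Q, freqs) in Dayhoff's style.

    Exchangeabilities come from the symmetric relatedness odds of the Dayhoff
    mutation-data log-odds matrix (``10**S_ij``), combined with the Dayhoff
    equilibrium frequencies into a GTR-form generator ``Q_ij = s_ij * f_j``,
    normalized to one expected substitution per site per unit time.
    """
    if "Q" in _rate_cache:
        return _rate_cache["Q"]
    S = substitution_matrices.load("DAYHOFF")
    f = np.array([DAYHOFF_FREQS[a] for a in AMINO_ACIDS])
    f = f / f.sum()
    n = 20
    Q = np.zeros((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                Q[i, j] = (10.0 ** S[a][b]) * f[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(f * np.diag(Q)).sum()
    Q /= rate
    _rate_cache["Q"] = (Q, f)
    return Q, f


def _transition_decomposition():
    """Symmetric eigendecomposition of Q for fast matrix exponentials."""
    if "eig" in _rate_cache:
        return _rate_cache["eig"]
    Q, f = dayhoff_rate_matrix()
    d = np.sqrt(f)
    B = (Q * d[:, None]) / d[None, :]
    B = (B + B.T) / 2  # symmetric up to rounding by reversibility
    w, U = np.linalg.eigh(B)
    _rate_cache["eig"] = (w, U, d, f)
    return _rate_cache["eig"]


def transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Q t) under the Dayhoff-style model."""
    w, U, d, _ = _transition_decomposition()
    P = (U * np.exp(w * t)) @ U.T
    P = P / d[:, None] * d[None, :]
    return np.clip(P, 1e-300, None)


def _pair_counts(row_a: str, row_b: str) -> np.ndarray:
    counts = np.zeros((20, 20))
    for x, y in zip(row_a, row_b):
        i = _AA_INDEX.get(x)
        j = _AA_INDEX.get(y)
        if i is not None and j is not None:
            counts[i, j] += 1
    return counts


def _ml_distance(counts: np.ndarray, ceiling: float) -> tuple[float, bool]:
    _, _, _, f = _transition_decomposition()

    def neg_ll(t: float) -> float:
        P = transition_matrix(t)
        return -float((counts * np.log(f[:, None] * P)).sum())

    if counts.sum() == counts.trace():
        return 0.0, False
    res = minimize_scalar(neg_ll, bounds=(1e-6, ceiling), method="bounded")
    t = float(res.x)
    if t >= ceiling * 0.999:
        return ceiling, True
    return t, False


def protein_distance(
    alignment: Alignment,
    model: str = "dayhoff_ml",
    gap_mode: str = "pairwise",
    ceiling: float = 10.0,
) -> DistanceMatrix:
    """Pairwise distances from a protein alignment.

    ``dayhoff_ml`` maximizes the likelihood of the observed residue pairs
    under the Dayhoff-style rate matrix (scalar optimization per pair);
    ``kimura_corrected`` is ``-ln(1 - p - 0.2 p**2)`` on the mismatch
    proportion ``p``.  ``gap_mode="pairwise"`` drops columns gapped in either
    member of a pair; ``"complete"`` drops columns gapped anywhere.
    Saturated pairs get ``ceiling`` and are flagged.
    """
    if model not in ("dayhoff_ml", "kimura_corrected"):
        raise ValueError(f"unknown model {model!r}")
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    rows = alignment.rows
    if gap_mode == "complete":
        keep = [
            c for c in range(alignment.n_columns) if all(r[c] != "-" for r in rows)
        ]
        rows = ["".join(r[c] for c in keep) for r in rows]
    n = len(alignment)
    values = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = [], []
            for x, y in zip(rows[i], rows[j]):
                if x != "-" and y != "-":
                    pa.append(x)
                    pb.append(y)
            if not pa:
                raise ValueError(
                    f"no comparable columns between {alignment.labels[i]!r} "
                    f"and {alignment.labels[j]!r}"
                )
            sa, sb = "".join(pa), "".join(pb)
            if model == "kimura_corrected":
                p = sum(1 for x, y in zip(sa, sb) if x != y) / len(sa)
                arg = 1.0 - p - 0.2 * p * p
                if arg <= 0:
                    d, sat = ceiling, True
                else:
                    d, sat = -math.log(arg), False
            else:
                d, sat = _ml_distance(_pair_counts(sa, sb), ceiling)
            values[i, j] = values[j, i] = d
            if sat:
                saturated.add((alignment.labels[i], alignment.labels[j]))
    return DistanceMatrix(list(alignment.labels), values, saturated)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion are broken by the smallest (sorted) pair of
    subtree label keys, where a subtree's key is its lexicographically
    smallest leaf label.  Negative branch lengths are clamped to zero and
    the deficit moved to the sibling branch.  Returns an unrooted tree with
    a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    taxa = dendropy.TaxonNamespace(list(dm.labels))
    nodes: list[dendropy.Node] = []
    keys: list[str] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
        keys.append(label)
    D = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qc = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qc, np.inf)
        qmin = Qc.min()
        candidates = [
            (tuple(sorted((keys[active[a]], keys[active[b]]))), a, b)
            for a, b in zip(*np.nonzero(Qc <= qmin + 1e-12))
            if a < b
        ]
        _, ai, bi = min(candidates)
        i, j = active[ai], active[bi]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = max(li, 0.0)
        nj.edge.length = max(lj, 0.0)
        # distances from the new node
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # join the last three nodes at a trifurcating root
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, lk in zip((a, b, c), (la, lb, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def bootstrap_trees(
    alignment: Alignment,
    n_reps: int = 500,
    seed: int = 0,
    model: str = "kimura_corrected",
    gap_mode: str = "pairwise",
) -> tuple[list[dendropy.Tree], int]:
    """Column-resampled bootstrap replicates of the NJ tree.

    Fully reproducible from ``seed``.  Returns ``(trees, n_warned)`` where
    ``n_warned`` counts replicates that contained a saturated pair (those
    replicates are retained, with the saturated distances at the ceiling).
    """
    if len(alignment) == 0 or alignment.n_columns == 0:
        raise ValueError("alignment is empty")
    rng = np.random.default_rng(seed)
    trees: list[dendropy.Tree] = []
    n_warned = 0
    for _ in range(n_reps):
        rep = alignment.resample_columns(rng)
        dm = protein_distance(rep, model=model, gap_mode=gap_mode)
        if dm.saturated:
            n_warned += 1
        trees.append(neighbor_joining(dm))
    return trees, n_warned


# ---------------------------------------------------------------------------
# Consensus and clade analyses

def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as canonical leaf-label sets.

    Each split is the side not containing the alphabetically first leaf, so
    identical bipartitions compare equal regardless of rooting.
    """
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    full = frozenset(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = full - below if ref in below else below
        if 1 < len(side) < len(full) - 1:
            splits.add(side)
    return splits


def majority_rule_consensus(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Strict majority-rule consensus with integer percent supports.

    Keeps exactly the splits occurring in more than half of the input trees
    (no greedy extension with minority splits); the support on each internal
    node is ``round(100 * frequency)``.  All trees must share one leaf set.
    """
    if not trees:
        raise ValueError("no trees given")
    leaf_sets = [frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees]
    if len(set(leaf_sets)) != 1:
        diff = set.union(*map(set, leaf_sets)) - set.intersection(*map(set, leaf_sets))
        raise ValueError(f"trees differ in leaf sets; disputed leaves: {sorted(diff)}")
    leaves = sorted(leaf_sets[0])
    n = len(trees)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for s in tree_splits(t):
            counts[s] = counts.get(s, 0) + 1
    majority = {s: c for s, c in counts.items() if 2 * c > n}

    taxa = dendropy.TaxonNamespace(leaves)
    root = dendropy.Node()
    leaf_nodes: dict[str, dendropy.Node] = {}
    for label in leaves:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        root.add_child(node)
        leaf_nodes[label] = node
    cluster_of: dict[dendropy.Node, frozenset[str]] = {
        node: frozenset([label]) for label, node in leaf_nodes.items()
    }
    cluster_of[root] = frozenset(leaves)
    # splits of a majority-rule set are pairwise compatible: insert largest first
    for split, c in sorted(
        majority.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
    ):
        sides = [split, frozenset(leaves) - split]
        placed = False
        for side in sides:
            host = root
            descended = True
            while descended:
                descended = False
                for child in host.child_nodes():
                    if side <= cluster_of[child]:
                        host = child
                        descended = True
                        break
            movers = [ch for ch in host.child_nodes() if cluster_of[ch] <= side]
            if frozenset().union(*(cluster_of[m] for m in movers)) == side:
                new = dendropy.Node()
                new.label = str(round(100.0 * c / n))
                for m in movers:
                    host.remove_child(m)
                    new.add_child(m)
                host.add_child(new)
                cluster_of[new] = side
                placed = True
                break
        if not placed:  # pragma: no cover - majority splits are compatible
            raise RuntimeError(f"could not place split {sorted(split)}")
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def genus_specific_clades(
    tree: dendropy.Tree,
    leaf_to_group: dict[str, str],
    min_size: int = 2,
) -> tuple[list[tuple[str, tuple[str, ...]]], dict[frozenset[str], int]]:
    """Maximal single-group clades and the mixed-clade inventory.

    A reported clade is an internal node whose leaves all carry one group
    label, with at least ``min_size`` leaves, and whose parent's leaf set is
    multi-group (so nested single-group clades collapse to the largest).
    Returns ``(clades, mixed)`` where ``clades`` is a list of
    ``(group, sorted leaf tuple)`` and ``mixed`` counts, per internal node
    with several groups, the combination of groups it contains.
    """
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    unmapped = sorted(set(leaves) - set(leaf_to_group))
    if unmapped:
        raise ValueError(f"leaves without a group: {unmapped}")

    groups_below: dict[dendropy.Node, set[str]] = {}
    labels_below: dict[dendropy.Node, list[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            labels_below[node] = [node.taxon.label]
            groups_below[node] = {leaf_to_group[node.taxon.label]}
        else:
            labels_below[node] = [
                x for ch in node.child_nodes() for x in labels_below[ch]
            ]
            groups_below[node] = set().union(
                *(groups_below[ch] for ch in node.child_nodes())
            )

    clades: list[tuple[str, tuple[str, ...]]] = []
    mixed: dict[frozenset[str], int] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        gs = groups_below[node]
        if len(gs) > 1:
            mixed[frozenset(gs)] = mixed.get(frozenset(gs), 0) + 1
            continue
        parent = node.parent_node
        parent_multi = parent is None or len(groups_below[parent]) > 1
        if parent_multi and len(labels_below[node]) >= min_size:
            clades.append((next(iter(gs)), tuple(sorted(labels_below[node]))))
    clades.sort()
    return clades, mixed


def assign_clades(
    tree: dendropy.Tree,
    clade_definitions: dict[str, set[str]],
) -> tuple[dict[str, str], dict[str, bool]]:
    """Label leaves with externally defined clades and check monophyly.

    Definitions must not overlap.  A clade is monophyletic when the smallest
    subtree (or, on this unrooted tree, its complement) spanning its leaves
    contains exactly those leaves.  Returns ``(leaf -> clade_id,
    clade_id -> monophyletic)``.
    """
    seen: dict[str, str] = {}
    for cid, members in clade_definitions.items():
        for leaf in members:
            if leaf in seen:
                raise ValueError(
                    f"leaf {leaf!r} appears in clades {seen[leaf]!r} and {cid!r}"
                )
            seen[leaf] = cid
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    clusters: set[frozenset[str]] = {all_leaves}
    for node in tree.preorder_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        clusters.add(below)
        clusters.add(all_leaves - below)
    monophyly = {
        cid: frozenset(members) in clusters
        for cid, members in clade_definitions.items()
    }
    return seen, monophyly
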