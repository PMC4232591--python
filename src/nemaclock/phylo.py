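"""Distance-based phylogenetics: p-distances, Poisson/gamma corrections,
neighbor joining, bootstrap supports, concatemers, Newick I/O.

Protein distances are computed with pairwise deletion (for each sequence pair
only sites where both rows are non-gap count), corrected either by the Poisson
model ``d = -ln(1 - p)`` or its gamma-rates generalization
``d = alpha * ((1 - p)**(-1/alpha) - 1)``.  Trees come from the Saitou–Nei
neighbor-joining agglomeration with a deterministic lexicographic tie-break;
bootstrap supports are the percentage of column-resampled replicates whose NJ
tree contains each bipartition of the full-data tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import MSA

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tree container and Newick I/O
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self):
        return [l.name for l in self.leaves()]

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()


def write_newick(tree: TreeNode, *, with_supports: bool = True) -> str:
    def fmt(node, is_root=False):
        if node.is_leaf():
            base = node.name
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_supports and node.support is not None:
                label = f"{node.support:g}"
            base = f"({inner}){label}"
        if is_root:
            return base
        return f"{base}:{node.length:.10g}"

    return fmt(tree, is_root=True) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse Newick via dendropy and convert; internal labels become supports."""
    import dendropy

    dt = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )

    def conv(dnode):
        node = TreeNode(
            name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
            length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
        )
        if dnode.label is not None:
            try:
                node.support = float(dnode.label)
            except ValueError:
                node.name = dnode.label
        node.children = [conv(c) for c in dnode.child_nodes()]
        return node

    return conv(dt.seed_node)


def bipartitions(tree: TreeNode):
    """Non-trivial leaf-set splits of internal edges, normalized to frozensets.

    Each split is represented by the side NOT containing the lexicographically
    smallest leaf, so representation is rooting-invariant.
    """
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    splits = {}
    for node in tree.preorder():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        key = side if anchor not in side else all_leaves - side
        splits[key] = node
    return splits


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray
    usable_sites: np.ndarray | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def to_tsv(self, path, phylip_header: bool = False) -> None:
        with open(path, "w") as fh:
            if phylip_header:
                fh.write(f"{len(self.labels)}\n")
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def encode_gapped(msa: MSA) -> np.ndarray:
    """Rows as int codes, gaps as -1 (internal helper shared with bootstrap)."""
    arr = np.zeros((len(msa), msa.ncols), dtype=np.int16)
    for r, (_, seq) in enumerate(msa.records):
        arr[r] = np.frombuffer(seq.encode(), dtype=np.uint8)
    arr[arr == ord("-")] = -1
    return arr


def _p_matrix(arr: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    n = arr.shape[0]
    p = np.zeros((n, n))
    usable = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] >= 0) & (arr[j] >= 0)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no usable (both non-gap) sites for pair ({labels[i]}, {labels[j]})"
                )
            diff = int((arr[i][ok] != arr[j][ok]).sum())
            p[i, j] = p[j, i] = diff / m
            usable[i, j] = usable[j, i] = m
    return p, usable


def p_distance(msa: MSA, deletion: str = "pairwise") -> DistanceMatrix:
    """Uncorrected proportion of differing sites per sequence pair."""
    if len(msa) < 2:
        raise ValueError("p_distance requires at least 2 rows")
    arr = encode_gapped(msa)
    if deletion == "complete":
        keep = (arr >= 0).all(axis=0)
        arr = arr[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    p, usable = _p_matrix(arr, msa.ids)
    return DistanceMatrix(list(msa.ids), p, usable)


def poisson_correct(p):
    """Poisson multiple-hit correction ``d = -ln(1 - p)``."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("p must satisfy 0 <= p < 1 (saturated pair)")
    d = -np.log1p(-p)
    return float(d) if d.ndim == 0 else d

def gamma_correct(p, alpha: float):
    """Gamma-rates corrected distance ``d = alpha * ((1-p)**(-1/alpha) - 1)``."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("p must satisfy 0 <= p < 1 (saturated pair)")
    d = alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)
    return float(d) if d.ndim == 0 else d


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(labels, dmat: np.ndarray) -> TreeNode:
    """Saitou–Nei neighbor joining on a plain distance array.

    Returns an unrooted tree represented with a trifurcating root.  Ties in
    the Q criterion break on the lexicographically smallest (taxon, taxon)
    label pair, internal nodes keyed by their smallest descendant leaf.
    Negative branch lengths are clamped to zero with the deficit moved to the
    sister branch (logged).
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = np.asarray(dmat, dtype=float).copy()
    nodes = [TreeNode(name=lab) for lab in labels]
    keys = list(labels)  # deterministic sort key per active node

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        cands = [(i, j) for i, j in cands if i < j]
        i, j = min(cands, key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))))
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        if li < 0:
            log.info("clamped negative branch %.3g on %s", li, keys[i])
            lj += li
            li = 0.0
        if lj < 0:
            log.info("clamped negative branch %.3g on %s", lj, keys[j])
            li += lj
            lj = 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[:, i] + D[:, j] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.empty((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        newkey = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [newkey]

    # three-point closed form for the final trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    ls = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for k, l in enumerate(ls):
        if l < 0:
            log.info("clamped negative terminal branch %.3g on %s", l, keys[k])
            sister = min((m for m in range(3) if m != k), key=lambda m: ls[m])
            ls[sister] += l
            ls[k] = 0.0
        nodes[k].length = max(ls[k], 0.0)
    order = np.argsort([keys[k] for k in range(3)])
    return TreeNode(children=[nodes[k] for k in order])


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    return nj_tree(D.labels, D.matrix)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def _tree_from_encoded(arr, labels, correction):
    p, _ = _p_matrix(arr, labels)
    d = correction(p)
    np.fill_diagonal(d, 0.0)
    return nj_tree(labels, d)


def bootstrap(msa: MSA, n: int = 1000, seed: int = 0, correction=poisson_correct) -> TreeNode:
    """Full-data NJ tree with bootstrap supports mapped onto its branches.

    Columns are resampled with replacement ``n`` times; the full pipeline
    (pairwise-deletion p-distance -> correction -> NJ) runs per replicate, and
    each internal branch of the full-data tree gets the percentage of
    replicates containing its bipartition.
    """
    if n < 1:
        raise ValueError("bootstrap requires n >= 1")
    arr = encode_gapped(msa)
    labels = list(msa.ids)
    tree = _tree_from_encoded(arr, labels, correction)
    splits = bipartitions(tree)
    counts = {k: 0 for k in splits}
    rng = np.random.default_rng(seed)
    ncols = arr.shape[1]
    for _ in range(n):
        cols = rng.integers(0, ncols, size=ncols)
        rep = _tree_from_encoded(arr[:, cols], labels, correction)
        rep_splits = bipartitions(rep)
        for k in counts:
            if k in rep_splits:
                counts[k] += 1
    for k, node in splits.items():
        node.support = 100.0 * counts[k] / n
    return tree


# ---------------------------------------------------------------------------
# Concatemers
# ---------------------------------------------------------------------------


def build_concatemer(alignments: dict, species_map: dict) -> MSA:
    """Concatenate per-gene alignments into one supermatrix row per species.

    ``alignments`` maps gene name -> :class:`MSA`; ``species_map`` maps
    species -> {gene name: row id in that gene's alignment}.  Genes are
    concatenated in sorted gene-name order.  A species missing from a gene is
    filled with gaps (logged); a species present in no gene is an error.
    """
    order = sorted(alignments)
    rows = []
    for sp in species_map:
        pieces = []
        found = 0
        for gene in order:
            rid = species_map[sp].get(gene)
            aln = alignments[gene]
            if rid is None:
                log.info("species %s missing from alignment %s: gap-filled", sp, gene)
                pieces.append("-" * aln.ncols)
            else:
                pieces.append(aln.row(rid))
                found += 1
        if found == 0:
            raise ValueError(f"species {sp!r} absent from all alignments")
        rows.append((sp, "".join(pieces)))
    return MSA(rows)
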