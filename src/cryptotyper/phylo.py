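"""Distance-based phylogenetics and patristic-distance statistics.

The genotype delimitation rests on the contrast between within-genotype and
between-genotype distances measured on trees. This module provides:

* uncorrected p-distance matrices from alignments (pairwise deletion of
  gap/ambiguous columns),
* a deterministic neighbor-joining tree builder (Saitou-Nei Q criterion,
  lowest-index tie-breaking, negative branch lengths clamped to zero),
* nonparametric bootstrap support for the bipartitions of a tree,
* patristic distance matrices from any newick tree (own NJ trees or
  externally computed maximum-likelihood trees are equally welcome), and
* within/between-group summary statistics (median, 2.5/97.5 percentile
  interval, min, max) plus a barcode-gap delimitation test.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

from .seqalign import AlignmentBlock


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix in substitutions per site."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise PhyloError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise PhyloError("non-finite distances")
        if not np.allclose(self.values, self.values.T):
            raise PhyloError("matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise PhyloError("nonzero diagonal")
        if np.any(self.values < 0):
            raise PhyloError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("," + ",".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "," + ",".join(f"{v:.12g}" for v in row) + "\n")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")[1:]
            rows = []
            labels = []
            for line in fh:
                parts = line.rstrip("\n").split(",")
                if len(parts) < 2:
                    continue
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if labels != header:
            raise PhyloError("row and column labels differ")
        return cls(labels, np.array(rows))


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_alignment(align: AlignmentBlock, retained_only: bool = True) -> tuple[np.ndarray, list[str]]:
    """Integer-encode an alignment: A,C,G,T -> 0..3; anything else
    (gaps, N, other ambiguity codes) -> 4, excluded from comparisons."""
    cols = align.retained_indices() if retained_only else np.arange(align.length)
    mat = np.full((align.n_rows, len(cols)), 4, dtype=np.int8)
    for i, rec in enumerate(align.rows):
        arr = np.array([_CODE.get(c, 4) for c in rec.bases], dtype=np.int8)
        mat[i] = arr[cols]
    return mat, align.ids


def _pdist_from_codes(mat: np.ndarray, labels: list[str]) -> DistanceMatrix:
    valid = mat < 4
    comp = valid[:, None, :] & valid[None, :, :]
    diff = (mat[:, None, :] != mat[None, :, :]) & comp
    n_comp = comp.sum(axis=-1)
    n = len(labels)
    offdiag = ~np.eye(n, dtype=bool)
    if np.any(n_comp[offdiag] == 0):
        i, j = np.argwhere((n_comp == 0) & offdiag)[0]
        raise PhyloError(
            f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        d = diff.sum(axis=-1) / np.where(n_comp == 0, 1, n_comp)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, (d + d.T) / 2)


def p_distance_matrix(align: AlignmentBlock, retained_only: bool = True) -> DistanceMatrix:
    """Observed (uncorrected) pairwise distances: mismatches / compared sites.

    Columns where either row holds a gap or an ambiguity code are deleted
    pairwise; only retained columns are used unless ``retained_only`` is
    False.
    """
    if align.n_rows < 2:
        raise PhyloError("need at least 2 rows")
    mat, labels = encode_alignment(align, retained_only)
    return _pdist_from_codes(mat, labels)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class PhyloTree:
    """Leaf-labelled tree with branch lengths, backed by a dendropy tree.

    Newick is the exchange format. Bootstrap supports are read either from
    internal-node labels or from ``[...]`` comments holding a bare number —
    both dialects occur in the wild.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls(dt)

    @classmethod
    def from_path(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        s = self._dtree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._dtree.leaf_node_iter()]

    def support_values(self) -> dict[frozenset, float]:
        """Bipartition -> support percent, from node labels or comments."""
        out = {}
        for node, split in self._internal_splits():
            val = None
            if node.label is not None:
                try:
                    val = float(node.label)
                except ValueError:
                    val = None
            if val is None and node.comments:
                for c in node.comments:
                    c = c.strip().lstrip("&").split("=")[-1]
                    try:
                        val = float(c)
                        break
                    except ValueError:
                        continue
            if val is None:
                # hot comments like [&support=95] are parsed as annotations
                for a in node.annotations:
                    try:
                        val = float(a.value)
                        break
                    except (TypeError, ValueError):
                        continue
            if val is not None:
                out[split] = val
        return out

    # -- splits -------------------------------------------------------

    def _internal_splits(self):
        """Yield (node, canonical bipartition) for internal, non-root edges."""
        all_leaves = frozenset(self.leaf_labels)
        for node in self._dtree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
                continue  # trivial split
            yield node, canonical_split(side, all_leaves)

    def splits(self) -> set[frozenset]:
        return {s for _, s in self._internal_splits()}


def canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Orientation-free representation of a bipartition."""
    return frozenset({side, all_leaves - side})


def patristic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Sum of branch lengths along the leaf-to-leaf path, for all pairs."""
    dt = tree._dtree
    for edge in dt.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else (head.label or "<internal>")
            raise PhyloError(f"edge above {name!r} has no branch length")
    pdm = dt.phylogenetic_distance_matrix()
    taxa = sorted(dt.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining (Saitou-Nei) tree from a distance matrix.

    Deterministic: ties on the Q criterion are broken toward the pair with
    the lowest (row, column) index in the current active ordering. Negative
    branch lengths are clamped to zero (the clamped deficit is recorded on
    the returned tree as ``nj_clamped_deficit``).
    """
    n = len(dm)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    D = dm.values.astype(float).copy()
    reprs = list(dm.labels)  # newick fragment per active node
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first occurrence = lowest (i, j)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        d_ij = sub[i, j]
        li = clamp(0.5 * d_ij + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(d_ij - (0.5 * d_ij + (r[i] - r[j]) / (2 * (m - 2))))
        gi, gj = active[i], active[j]
        new_repr = f"({reprs[gi]}:{li:.12g},{reprs[gj]}:{lj:.12g})"
        # distances from the new node u to every other active node k
        new_row = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (gi, gj):
                continue
            new_row[k] = 0.5 * (D[gi, k] + D[gj, k] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        reprs.append(new_repr)
        active = [k for k in active if k not in (gi, gj)] + [D.shape[0] - 1]

    # terminal 3-star: center node with closed-form branch lengths
    a, b, c = active
    va = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    vb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    vc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    newick = f"({reprs[a]}:{va:.12g},{reprs[b]}:{vb:.12g},{reprs[c]}:{vc:.12g});"
    tree = PhyloTree.from_newick(newick)
    tree.nj_clamped_deficit = deficit  # type: ignore[attr-defined]
    return tree


def bootstrap_support(
    align: AlignmentBlock,
    n_replicates: int = 500,
    seed: int = 0,
    builder=nj_tree,
) -> tuple[PhyloTree, dict[frozenset, float]]:
    """Nonparametric bootstrap support for the bipartitions of the
    full-alignment tree.

    Retained columns are resampled with replacement per pseudo-replicate;
    support is the percent of replicate trees containing each original
    internal bipartition. Reproducible for a given seed.
    """
    if n_replicates < 1:
        raise PhyloError("need at least one bootstrap replicate")
    if align.n_rows < 4:
        raise PhyloError("bootstrap needs at least 4 rows")
    mat, labels = encode_alignment(align)
    base_tree = builder(_pdist_from_codes(mat, labels))
    target_splits = base_tree.splits()
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    L = mat.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_dm = _pdist_from_codes(mat[:, cols], labels)
        rep_splits = builder(rep_dm).splits()
        for s in target_splits & rep_splits:
            counts[s] += 1
    support = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    all_leaves = frozenset(base_tree.leaf_labels)
    for node, split in base_tree._internal_splits():
        node.label = f"{support[split]:g}"
    return base_tree, support


# ---------------------------------------------------------------------------
# Patristic summary statistics and delimitation
# ---------------------------------------------------------------------------


@dataclass
class DistanceSummary:
    """Median, 95% nonparametric interval (2.5/97.5 percentiles), min and
    max of a multiset of pairwise distances."""

    median: float
    ci_low: float
    ci_high: float
    min: float
    max: float
    n_pairs: int

    @classmethod
    def from_values(cls, values) -> "DistanceSummary":
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise PhyloError("empty distance set")
        lo, hi = np.percentile(v, [2.5, 97.5])
        return cls(float(np.median(v)), float(lo), float(hi),
                   float(v.min()), float(v.max()), int(v.size))


def _pairs_within(dm: DistanceMatrix, members: list[str]) -> list[float]:
    idx = [dm.labels.index(m) for m in members]
    return [float(dm.values[a, b]) for k, a in enumerate(idx) for b in idx[k + 1:]]


def _pairs_between(dm: DistanceMatrix, g1: list[str], g2: list[str]) -> list[float]:
    i1 = [dm.labels.index(m) for m in g1]
    i2 = [dm.labels.index(m) for m in g2]
    return [float(dm.values[a, b]) for a in i1 for b in i2]


def group_summary(dm: DistanceMatrix, groups: dict[str, str], mode) -> DistanceSummary:
    """Summary over eligible pairwise distances.

    ``mode`` is ``("within", g)`` (all unordered pairs inside group g,
    self-pairs excluded) or ``("between", g1, g2)`` (all cross pairs).
    """
    if mode[0] == "within":
        members = [l for l in dm.labels if groups.get(l) == mode[1]]
        vals = _pairs_within(dm, members)
    elif mode[0] == "between":
        g1 = [l for l in dm.labels if groups.get(l) == mode[1]]
        g2 = [l for l in dm.labels if groups.get(l) == mode[2]]
        vals = _pairs_between(dm, g1, g2)
    else:
        raise PhyloError(f"unknown mode {mode!r}")
    if not vals:
        raise PhyloError(f"no eligible pairs for mode {mode!r}")
    return DistanceSummary.from_values(vals)


def intra_individual_summary(
    dm: DistanceMatrix, clone_to_specimen: dict[str, str]
) -> dict[str, DistanceSummary]:
    """Per-specimen summaries of distances between clones of one individual."""
    specimens: dict[str, list[str]] = {}
    for clone, spec in clone_to_specimen.items():
        if clone in dm.labels:
            specimens.setdefault(spec, []).append(clone)
    out = {}
    for spec, clones in sorted(specimens.items()):
        if len(clones) >= 2:
            out[spec] = DistanceSummary.from_values(_pairs_within(dm, clones))
    if not out:
        raise PhyloError("no specimen with at least 2 clones")
    return out


@dataclass
class DelimitationReport:
    """Barcode-gap delimitation verdict plus the underlying summaries."""

    distinct: bool
    within: dict[str, DistanceSummary]
    between: DistanceSummary
    gap: float  # between-min minus the larger within 97.5th percentile


def delimit(dm: DistanceMatrix, groups: dict[str, str]) -> DelimitationReport:
    """Two groups are delimited when the minimum between-group distance
    exceeds both within-group 97.5th percentiles (a barcode gap)."""
    names = sorted({g for l, g in groups.items() if l in dm.labels})
    if len(names) != 2:
        raise PhyloError(f"delimitation needs exactly 2 groups, got {names}")
    g1, g2 = names
    for g in names:
        if sum(1 for l in dm.labels if groups.get(l) == g) < 2:
            raise PhyloError(f"group {g!r} needs at least 2 members")
    within = {g: group_summary(dm, groups, ("within", g)) for g in names}
    between = group_summary(dm, groups, ("between", g1, g2))
    ceiling = max(s.ci_high for s in within.values())
    gap = between.min - ceiling
    return DelimitationReport(gap > 0, within, between, gap)
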