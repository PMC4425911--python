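"""Distance phylogenetics and integration-time dating.

Kimura-2-parameter distances feed a neighbor-joining tree builder with
nonparametric bootstrap supports; two dating procedures estimate when a
provirus entered the germ line: the LTR molecular clock (the two LTRs are
identical at integration and diverge afterwards at twice the substitution
rate) and single-gain Dollo placement of a presence/absence character on a
dated species tree, which brackets the integration between the age of the
most recent common ancestor of carrier species and the age of its parent
node.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .seqcore import global_align, k2p_distance


class MissingLTRError(ValueError):
    """LTR-clock dating is not applicable (an LTR is absent)."""


# ---------------------------------------------------------------------------
# distance matrices

@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match taxa")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if (self.matrix < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


def k2p_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """Pairwise K2P distances from a (gapped) multiple alignment."""
    taxa = list(alignment)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = k2p_distance(alignment[taxa[i]], alignment[taxa[j]])
    return DistanceMatrix(taxa=taxa, matrix=d)


# ---------------------------------------------------------------------------
# neighbor joining

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return self.name
        inner = ",".join(
            f"{child._newick()}:{length:.6f}" for child, length in self.children
        )
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}"


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Neighbor-joining (Saitou-Nei) with deterministic tie-breaking.

    When several pairs minimize the Q criterion, the lexicographically
    smallest pair of subtree labels is joined (a subtree is labelled by its
    smallest leaf name).  Negative branch lengths are clamped to zero with a
    warning.  On additive matrices the true tree is recovered exactly.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.taxa]
    labels: list[str] = list(D.taxa)
    d = D.matrix.copy()

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0")
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((labels[i], labels[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and pair_key < best[1]
                ):
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        li = clamp(d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(d[i, j] - d[i, j] / 2 - (r[i] - r[j]) / (2 * (m - 2)))
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_label = min(labels[i], labels[j])
        dnew = np.array([
            (d[i, k] + d[j, k] - d[i, j]) / 2 for k in range(m) if k not in (i, j)
        ])
        keep = [k for k in range(m) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = dnew
        d[:-1, -1] = dnew
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [new_label]

    # final three-way join (three-point formulas)
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    l0 = clamp((d01 + d02 - d12) / 2)
    l1 = clamp((d01 + d12 - d02) / 2)
    l2 = clamp((d02 + d12 - d01) / 2)
    return TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])


def tree_path_lengths(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths (for additivity checks)."""
    dists: dict[str, dict[str, float]] = {}

    def down(node: TreeNode, acc: float, store: dict[str, float]):
        if node.is_leaf:
            store[node.name] = acc
            return
        for child, length in node.children:
            down(child, acc + length, store)

    def collect(node: TreeNode):
        for child, length in node.children:
            collect(child)
        # paths through this node between child subtrees
        stores = []
        for child, length in node.children:
            s: dict[str, float] = {}
            down(child, length, s)
            stores.append(s)
        for a, b in combinations(range(len(stores)), 2):
            for la, da in stores[a].items():
                for lb, db in stores[b].items():
                    dists.setdefault(la, {})[lb] = da + db
                    dists.setdefault(lb, {})[la] = da + db

    collect(tree)
    out = {}
    for a in dists:
        for b, v in dists[a].items():
            if a < b:
                out[(a, b)] = v
    return out


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Leaf bipartitions induced by internal edges (normalized sides)."""
    all_leaves = frozenset(tree.leaves())
    parts: set[frozenset] = set()

    def walk(node: TreeNode):
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                other = all_leaves - side
                parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
            walk(child)

    walk(tree)
    return parts


def bootstrap_support(
    alignment: dict[str, str], replicates: int = 10000, seed: int = 0
) -> TreeNode:
    """NJ tree with bootstrap supports from site resampling.

    Columns are resampled with replacement; K2P + NJ is run per replicate
    and each internal edge of the full-data tree is annotated with the
    percentage of replicates containing its bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if len(alignment) < 4:
        raise ValueError("bootstrap supports need at least 4 taxa")
    taxa = list(alignment)
    ncols = len(next(iter(alignment.values())))
    mat = np.array([list(alignment[t]) for t in taxa])
    tree = nj_tree(k2p_matrix(alignment))
    target = {p: 0 for p in bipartitions(tree)}

    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        sub = {t: "".join(mat[i, cols]) for i, t in enumerate(taxa)}
        rep_parts = bipartitions(nj_tree(k2p_matrix(sub)))
        for p in target:
            if p in rep_parts:
                target[p] += 1

    def annotate(node: TreeNode):
        all_leaves = frozenset(tree.leaves())
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                key = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
                child.support = 100.0 * target[key] / replicates
            annotate(child)

    annotate(tree)
    return tree


# ---------------------------------------------------------------------------
# LTR molecular clock

@dataclass(frozen=True)
class ClockEstimate:
    divergence: float  # substitutions/site between the two LTRs
    rate: float        # substitutions/site/year
    age_years: float

    @property
    def age_myr(self) -> float:
        return self.age_years / 1e6


def ltr_clock(ltr5: str | None, ltr3: str | None, rate: float) -> ClockEstimate:
    """Integration age from 5'/3' LTR divergence: age = d / (2 * rate).

    Refuses to date a provirus missing either LTR (for a 5'-truncated
    provirus the clock is undefined), raising :class:`MissingLTRError`.
    """
    if not ltr5 or not ltr3:
        raise MissingLTRError("both LTRs are required for molecular-clock dating")
    if rate <= 0:
        raise ValueError("substitution rate must be > 0")
    if len(ltr5) == len(ltr3):
        d = k2p_distance(ltr5, ltr3)
    else:
        aln = global_align(ltr5, ltr3)
        d = k2p_distance(aln.seq_a, aln.seq_b)
    return ClockEstimate(divergence=d, rate=rate, age_years=d / (2.0 * rate))


# ---------------------------------------------------------------------------
# Dollo presence/absence dating

@dataclass
class SpeciesNode:
    name: str | None
    age: float  # MYA; 0 at the tips
    children: list["SpeciesNode"] = field(default_factory=list)

    def tips(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.tips())
        return out


@dataclass
class DatedSpeciesTree:
    """Rooted species tree with node ages (MYA) and tip presence flags."""

    root: SpeciesNode
    presence: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        def check(node: SpeciesNode):
            for c in node.children:
                if c.age >= node.age:
                    raise ValueError("node ages must decrease from root to tips")
                check(c)
        check(self.root)

    @classmethod
    def from_newick(cls, text: str, presence=None) -> "DatedSpeciesTree":
        """Parse newick where internal-node labels are ages in MYA."""
        text = text.strip().rstrip(";")
        pos = 0

        def parse() -> SpeciesNode:
            nonlocal pos
            if text[pos] == "(":
                pos += 1
                children = [parse()]
                while text[pos] == ",":
                    pos += 1
                    children.append(parse())
                if text[pos] != ")":
                    raise ValueError("unbalanced newick")
                pos += 1
                label = _read_token(text, pos)
                pos_end = pos + len(label)
                age = float(label) if label else float("nan")
                node = SpeciesNode(name=None, age=age, children=children)
                return _advance(node, pos_end)
            label = _read_token(text, pos)
            node = SpeciesNode(name=label, age=0.0)
            return _advance(node, pos + len(label))

        def _advance(node, new_pos):
            nonlocal pos
            pos = new_pos
            if pos < len(text) and text[pos] == ":":  # branch lengths ignored
                pos += 1
                tok = _read_token(text, pos)
                pos += len(tok)
            return node

        def _read_token(s, i):
            j = i
            while j < len(s) and s[j] not in "(),:;":
                j += 1
            return s[i:j]

        root = parse()
        tree = cls(root=root)
        if presence is not None:
            tree.set_presence(presence)
        return tree

    def set_presence(self, present_tips) -> None:
        tips = set(self.root.tips())
        unknown = set(present_tips) - tips
        if unknown:
            raise KeyError(f"unknown tips: {sorted(unknown)}")
        self.presence = {t: (t in set(present_tips)) for t in tips}


def date_integration(tree: DatedSpeciesTree) -> tuple[float, float, int]:
    """Single-gain Dollo dating of a presence/absence character.

    The gain is placed on the stem edge of the MRCA of all presence tips:
    the integration happened between ``lower`` = age of that MRCA and
    ``upper`` = age of the MRCA's parent (the adjacent older divergence; the
    root's age if the MRCA is the root).  ``losses`` is the minimal number
    of loss edges explaining absence tips inside the carrier clade (count of
    maximal all-absent subtrees).
    """
    present = {t for t, flag in tree.presence.items() if flag}
    if not present:
        raise ValueError("no presence tips: cannot date the integration")

    parent_of: dict[int, SpeciesNode] = {}

    def index(node: SpeciesNode):
        for c in node.children:
            parent_of[id(c)] = node
            index(c)

    index(tree.root)

    def find_mrca(node: SpeciesNode) -> SpeciesNode | None:
        carriers = [c for c in node.children if present & set(c.tips())]
        if len(carriers) == 1:
            return find_mrca(carriers[0])
        return node

    if len(present) == 1:
        tip_name = next(iter(present))

        def find_tip(node):
            if node.name == tip_name:
                return node
            for c in node.children:
                hit = find_tip(c)
                if hit is not None:
                    return hit
            return None

        mrca = find_tip(tree.root)
    else:
        mrca = find_mrca(tree.root)

    parent = parent_of.get(id(mrca))
    lower = mrca.age
    upper = parent.age if parent is not None else tree.root.age

    def count_losses(node: SpeciesNode) -> int:
        tips = set(node.tips())
        if not (tips & present):
            return 1  # one loss explains this whole absent subtree
        if not node.children:
            return 0
        return sum(count_losses(c) for c in node.children)

    losses = sum(count_losses(c) for c in mrca.children) if mrca.children else 0
    return lower, upper, losses


# Fig-style dated primate tree used throughout: NWM/OWM split 25 MYA,
# baboon vs macaque+AGM 10 MYA, human-chimp 6 MYA.
PRIMATE_TREE_NEWICK = (
    "(NWM,((orangutan,(gorilla,(human,chimpanzee)6)8)16,"
    "(baboon,(macaque,AGM)5)10)20)25;"
)
K222_PRESENCE = {"baboon", "orangutan", "gorilla", "chimpanzee", "human"}
K111_PRESENCE = {"human", "chimpanzee"}


def default_primate_tree(presence=frozenset(K222_PRESENCE)) -> DatedSpeciesTree:
    return DatedSpeciesTree.from_newick(PRIMATE_TREE_NEWICK, presence=presence)
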