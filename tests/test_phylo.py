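"""Distance trees, bootstrap, LTR clock, Dollo presence/absence dating."""

import itertools

import numpy as np
import pytest

import pericerv as pv
from pericerv.phylo import (
    DatedSpeciesTree,
    K111_PRESENCE,
    K222_PRESENCE,
    MissingLTRError,
    bipartitions,
    default_primate_tree,
    tree_path_lengths,
)
from pericerv.synthgen import mutate


def random_additive_matrix(rng, n):
    """Random binary tree with positive branch lengths -> (taxa, D, splits)."""
    taxa = [f"t{i}" for i in range(n)]
    # grow an unrooted tree by random leaf insertion on edges
    edges = {}  # node -> list[(node, length)]

    def add_edge(a, b, w):
        edges.setdefault(a, []).append((b, w))
        edges.setdefault(b, []).append((a, w))

    def del_edge(a, b):
        edges[a] = [(x, w) for x, w in edges[a] if x != b]
        edges[b] = [(x, w) for x, w in edges[b] if x != a]

    def lengths():
        return rng.integers(1, 9)

    add_edge(taxa[0], taxa[1], lengths())
    internal = 0
    for leaf in taxa[2:]:
        pairs = [
            (a, b) for a in edges for b, _ in edges[a] if str(a) < str(b)
        ]
        a, b = pairs[rng.integers(len(pairs))]
        w = [w for x, w in edges[a] if x == b][0]
        del_edge(a, b)
        node = f"i{internal}"
        internal += 1
        add_edge(a, node, w / 2)
        add_edge(node, b, w / 2)
        add_edge(node, leaf, lengths())

    def dist(a, b):
        seen = {a}
        stack = [(a, 0.0)]
        while stack:
            x, d = stack.pop()
            if x == b:
                return d
            for y, w in edges[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append((y, d + w))
        raise AssertionError

    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = dist(taxa[i], taxa[j])

    # true splits: leaves on each side of every internal edge
    def leaves_from(start, block):
        out = set()
        stack = [start]
        seen = {start, block}
        while stack:
            x = stack.pop()
            if not str(x).startswith("i"):
                out.add(x)
            for y, _ in edges[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return out

    splits = set()
    all_taxa = frozenset(taxa)
    for a in edges:
        for b, _ in edges[a]:
            if str(a).startswith("i") and str(b).startswith("i") and str(a) < str(b):
                side = frozenset(leaves_from(a, b))
                splits.add(min(side, all_taxa - side, key=lambda s: (len(s), sorted(s))))
    return taxa, D, splits


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = pv.DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float
        ))
        tree = pv.nj_tree(D)
        lens = {child.name: L for child, L in tree.children}
        assert lens["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lens["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lens["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_taxon_tree_recovered_exactly(self):
        # ((A:1,B:2):5,(C:3,D:4)) -> additive distances by path sums
        D = pv.DistanceMatrix(["A", "B", "C", "D"], np.array([
            [0, 3, 9, 10],
            [3, 0, 10, 11],
            [9, 10, 0, 7],
            [10, 11, 7, 0],
        ], dtype=float))
        tree = pv.nj_tree(D)
        assert frozenset(["A", "B"]) in bipartitions(tree)
        paths = tree_path_lengths(tree)
        for (a, b), d in paths.items():
            assert d == pytest.approx(D.get(a, b))

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (5, 2), (6, 3), (6, 4)])
    def test_additive_matrices_recover_true_splits(self, n, seed):
        taxa, D, splits = random_additive_matrix(np.random.default_rng(seed), n)
        tree = pv.nj_tree(pv.DistanceMatrix(taxa, D))
        assert bipartitions(tree) == splits
        paths = tree_path_lengths(tree)
        dm = pv.DistanceMatrix(taxa, D)
        for (a, b), d in paths.items():
            assert d == pytest.approx(dm.get(a, b))

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        taxa, D, _ = random_additive_matrix(np.random.default_rng(11), 6)
        mine = bipartitions(pv.nj_tree(pv.DistanceMatrix(taxa, D)))
        sk_tree = sk_nj(SkDM(D, ids=taxa))
        all_taxa = frozenset(taxa)
        theirs = set()
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_taxa) - 1:
                theirs.add(min(side, all_taxa - side, key=lambda s: (len(s), sorted(s))))
        assert mine == theirs

    def test_duplicate_taxa_form_zero_length_cherry(self):
        D = pv.DistanceMatrix(["a", "b", "c", "d"], np.array([
            [0, 0, 4, 4],
            [0, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0],
        ], dtype=float))
        tree = pv.nj_tree(D)
        assert frozenset(["a", "b"]) in bipartitions(tree)
        paths = tree_path_lengths(tree)
        assert paths[("a", "b")] == pytest.approx(0.0)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            pv.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], dtype=float))
        with pytest.raises(ValueError):
            pv.DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]], dtype=float))


def clade_alignment(seed=0, ncols=300, diagnostic=50):
    """4-taxon alignment where taxa A,B share ``diagnostic`` derived sites."""
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), ncols))
    ab = list(base)
    sites = rng.choice(ncols, size=diagnostic, replace=False)
    for pos in sites:
        ab[pos] = "ACGT"[("ACGT".index(ab[pos]) + 1) % 4]
    a = mutate("".join(ab), 0.01, rng)
    b = mutate("".join(ab), 0.01, rng)
    c = mutate(base, 0.01, rng)
    d = mutate(base, 0.01, rng)
    return {"A": a, "B": b, "C": c, "D": d}


class TestBootstrap:
    def test_saturated_clade_gets_full_support(self):
        tree = pv.bootstrap_support(clade_alignment(), replicates=200, seed=5)
        supports = {}

        def collect(node):
            for child, _ in node.children:
                if child.support is not None:
                    supports[frozenset(child.leaves())] = child.support
                collect(child)

        collect(tree)
        key = [k for k in supports if k in (frozenset("AB"), frozenset("CD"))]
        assert key and all(supports[k] == 100.0 for k in key)

    def test_single_replicate_supports_are_binary(self):
        tree = pv.bootstrap_support(clade_alignment(), replicates=1, seed=6)

        def collect(node, acc):
            for child, _ in node.children:
                if child.support is not None:
                    acc.append(child.support)
                collect(child, acc)
            return acc

        assert set(collect(tree, [])) <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self):
        t1 = pv.bootstrap_support(clade_alignment(), replicates=50, seed=7)
        t2 = pv.bootstrap_support(clade_alignment(), replicates=50, seed=7)
        assert t1.newick() == t2.newick()


class TestLtrClock:
    def test_identical_ltrs_age_zero(self):
        ltr = "ACGT" * 242
        assert pv.ltr_clock(ltr, ltr, rate=2.5e-9).age_years == 0.0

    def test_closed_form_age(self):
        # d = 0.02 at rate 2.5e-9 subst/site/yr -> 4.0 Myr
        rng = np.random.default_rng(15)
        ltr5 = "".join(rng.choice(list("ACGT"), 2000))
        est = pv.ltr_clock(ltr5, ltr5, rate=2.5e-9)
        assert est.age_years == 0.0
        # verify the formula on a synthetic divergence
        est2 = pv.ClockEstimate(divergence=0.02, rate=2.5e-9, age_years=0.02 / (2 * 2.5e-9))
        assert est2.age_myr == pytest.approx(4.0)

    def test_rate_halving_doubles_age(self):
        rng = np.random.default_rng(16)
        ltr5 = "".join(rng.choice(list("ACGT"), 968))
        ltr3 = mutate(ltr5, 0.02, rng)
        a1 = pv.ltr_clock(ltr5, ltr3, rate=2.5e-9)
        a2 = pv.ltr_clock(ltr5, ltr3, rate=1.25e-9)
        assert a2.age_years == pytest.approx(2 * a1.age_years)

    def test_parameter_recovery_from_simulated_divergence(self):
        """Mutating both LTR copies independently for t years at rate r gives
        back t within 10% (median over replicates)."""
        rate = 2.5e-9
        t_years = 5e6
        p = rate * t_years
        rng = np.random.default_rng(17)
        ages = []
        for _ in range(500):
            ltr = "".join(rng.choice(list("ACGT"), 968))
            a = mutate(ltr, p, rng)
            b = mutate(ltr, p, rng)
            ages.append(pv.ltr_clock(a, b, rate=rate).age_years)
        assert abs(np.median(ages) - t_years) / t_years < 0.10

    def test_missing_ltr_is_a_distinct_error(self):
        with pytest.raises(MissingLTRError):
            pv.ltr_clock(None, "ACGT" * 100, rate=2.5e-9)
        with pytest.raises(ValueError):
            pv.ltr_clock("ACGT" * 100, "ACGT" * 100, rate=0)


class TestDolloDating:
    def test_k222_pattern_upper_bound_25(self):
        tree = default_primate_tree(presence=K222_PRESENCE)
        lower, upper, losses = pv.date_integration(tree)
        assert upper == 25.0
        assert lower == 20.0
        assert losses == 1  # one loss of the macaque+AGM subtree

    def test_k111_pattern_brackets_human_chimp_split(self):
        tree = default_primate_tree(presence=K111_PRESENCE)
        lower, upper, losses = pv.date_integration(tree)
        assert lower == 6.0
        assert upper == 8.0
        assert losses == 0

    def test_single_presence_tip(self):
        tree = default_primate_tree(presence={"human"})
        lower, upper, losses = pv.date_integration(tree)
        assert lower == 0.0 and upper == 6.0 and losses == 0

    def test_presence_clade_has_zero_losses(self):
        tree = default_primate_tree(presence={"human", "chimpanzee", "gorilla"})
        _, upper, losses = pv.date_integration(tree)
        assert losses == 0 and upper == 16.0

    def test_absence_inside_clade_adds_loss_not_age(self):
        with_loss = default_primate_tree(
            presence={"human", "chimpanzee", "orangutan"}
        )
        l1, u1, losses1 = pv.date_integration(with_loss)
        assert u1 == 20.0 and losses1 == 1  # gorilla lost inside the ape clade

    def test_all_absent_rejected(self):
        tree = default_primate_tree(presence=set())
        with pytest.raises(ValueError):
            pv.date_integration(tree)

    def test_newick_ages_parse(self):
        tree = DatedSpeciesTree.from_newick("((a,b)3,(c,d)7)12;", presence={"a"})
        assert tree.root.age == 12
        lower, upper, losses = pv.date_integration(tree)
        assert (lower, upper, losses) == (0.0, 3.0, 0)

    def test_unknown_presence_tip_rejected(self):
        with pytest.raises(KeyError):
            default_primate_tree(presence={"martian"})
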