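import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from siderokit.phylo import (
    LabeledAlignment,
    bootstrap_support,
    classify_query,
    neighbor_joining,
    pdistance_matrix,
)
from siderokit.synthetic import PhyloSimConfig, simulate_protein_family


def _aln(pairs, labels=()):
    return LabeledAlignment(sequences=tuple(pairs), labels=tuple(labels))


class TestPDistance:
    def test_identical_sequences(self):
        d = pdistance_matrix(_aln([("a", "ACDE"), ("b", "ACDE")]))
        assert d["a", "b"] == 0.0

    def test_one_mismatch_in_four(self):
        d = pdistance_matrix(_aln([("a", "AAAA"), ("b", "AAAT")]))
        assert d["a", "b"] == 0.25

    def test_pairwise_gap_deletion(self):
        d = pdistance_matrix(_aln([("a", "A-CD"), ("b", "AAC-")]))
        # comparable columns: 1 and 3 -> zero mismatches
        assert d["a", "b"] == 0.0

    def test_no_comparable_columns_names_the_pair(self):
        with pytest.raises(ValueError, match="'a'.*'b'"):
            pdistance_matrix(_aln([("a", "A--"), ("b", "-AA")]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_recount(self, seed):
        rng = np.random.default_rng(seed)
        alpha = list("ACDEFG-")
        s1 = "".join(rng.choice(alpha, 60))
        s2 = "".join(rng.choice(alpha, 60))
        mism = comp = 0
        for x, y in zip(s1, s2):
            if x == "-" or y == "-":
                continue
            comp += 1
            mism += x != y
        if comp == 0:
            pytest.skip("degenerate draw")
        d = pdistance_matrix(_aln([("a", s1), ("b", s2)]))
        assert d["a", "b"] == pytest.approx(mism / comp)


def _tip_dist(tree, a, b):
    return tree.find(a).distance(tree.find(b))


class TestNeighborJoining:
    def test_three_taxa_star_resolution(self):
        d = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"])
        tree = neighbor_joining(d)
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}
        assert _tip_dist(tree, "a", "b") == pytest.approx(3)

    def test_additive_four_taxon_metric_recovered(self):
        # generating tree: ((a:2,b:3):1,c:4,d:6) with cd split length via e
        d = DistanceMatrix(
            [[0, 5, 7, 9], [5, 0, 8, 10], [7, 8, 0, 10], [9, 10, 10, 0]],
            ["a", "b", "c", "d"],
        )
        tree = neighbor_joining(d)
        for i in "abcd":
            for j in "abcd":
                if i < j:
                    assert _tip_dist(tree, i, j) == pytest.approx(d[i, j])
        # a and b must be sisters
        parent = tree.find("a").parent
        assert {t.name for t in parent.tips()} == {"a", "b"}

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_reference_nj_on_additive_metrics(self, seed):
        """Independent oracle: scikit-bio's NJ recovers the same topology on
        a metric derived from a random tree."""
        rng = np.random.default_rng(seed)
        n = 6
        names = [f"t{i}" for i in range(n)]
        # random additive metric: random binary tree with random edge lengths
        ref = skbio_nj(
            DistanceMatrix(_random_metric(rng, n), names)
        )
        metric = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                metric[i, j] = metric[j, i] = ref.find(names[i]).distance(
                    ref.find(names[j])
                )
        ours = neighbor_joining(DistanceMatrix(metric, names))
        theirs = skbio_nj(DistanceMatrix(metric, names))
        assert ours.compare_rfd(theirs, rooted=False) == 0

    def test_nonsymmetric_input_rejected(self):
        with pytest.raises(Exception):
            neighbor_joining(np.array([[0, 1], [2, 0]]), ids=["a", "b"])

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = _random_metric(rng, 7)
            tree = neighbor_joining(DistanceMatrix(m, [f"t{i}" for i in range(7)]))
            for node in tree.traverse():
                if node.length is not None:
                    assert node.length >= 0


def _random_metric(rng, n):
    """A random symmetric matrix obeying the triangle inequality well enough
    for NJ to run (point-to-point Euclidean distances)."""
    pts = rng.uniform(0, 10, size=(n, 3))
    m = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(m, 0.0)
    return m


class TestClassifyQuery:
    def _tree(self):
        return TreeNode.read(
            ["(((r1:1,r2:1):1,(r3:1,q:1):0.5):1,((s1:1,s2:1):1,s3:1):1);"]
        )

    LABELS = {"r1": "3R", "r2": "3R", "r3": "3R", "s1": "3S", "s2": "3S",
              "s3": "3S", "q": "query"}

    def test_query_inside_pure_clade(self):
        res = classify_query(self._tree(), self.LABELS)
        assert res["call"] == "3R"

    def test_no_references_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            classify_query(self._tree(), {"q": "query"})

    def test_equidistant_between_mixed_clades_is_ambiguous(self):
        tree = TreeNode.read(["((r1:1,s1:1):1,q:1);"])
        res = classify_query(tree, {"r1": "3R", "s1": "3S", "q": "query"})
        assert res["call"] == "ambiguous"

    def test_leaf_order_permutation_invariance(self):
        cfg = PhyloSimConfig(n_per_clade=4, seq_length=120)
        aln, truth = simulate_protein_family(cfg, np.random.default_rng(7))
        perm_aln = LabeledAlignment(
            sequences=tuple(reversed(aln.sequences)), labels=aln.labels
        )
        for a in (aln, perm_aln):
            tree = neighbor_joining(pdistance_matrix(a))
            for q, clade in truth.items():
                assert classify_query(tree, a.label_map, query=q)["call"] == clade


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self):
        aln, _ = simulate_protein_family(
            PhyloSimConfig(n_per_clade=3, seq_length=100), np.random.default_rng(0)
        )
        tree = bootstrap_support(aln, n_replicates=1, seed=0)
        sup = [n.support for n in tree.non_tips(include_self=False)
               if getattr(n, "support", None) is not None]
        assert sup and set(sup) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self):
        aln, _ = simulate_protein_family(
            PhyloSimConfig(n_per_clade=3, seq_length=100), np.random.default_rng(1)
        )
        t1 = bootstrap_support(aln, n_replicates=25, seed=42)
        t2 = bootstrap_support(aln, n_replicates=25, seed=42)
        assert str(t1) == str(t2)

    def test_well_separated_clades_get_high_support(self):
        aln, _ = simulate_protein_family(
            PhyloSimConfig(n_per_clade=4, seq_length=300,
                           within_clade_sub_prob=0.05,
                           between_clade_sub_prob=0.4),
            np.random.default_rng(5),
        )
        tree = bootstrap_support(aln, n_replicates=100, seed=5)
        clade_3r = frozenset(n for n, l in aln.labels if l != "3S"
                             or n.startswith("query_3R"))
        # find the edge splitting the 3R side (refs + its query) from the rest
        best = 0.0
        r_names = {n for n, l in aln.labels
                   if l == "3R" or n.startswith("query_3R")}
        for node in tree.non_tips(include_self=False):
            side = {t.name for t in node.tips()}
            if side in (r_names, set(aln.names) - r_names):
                best = max(best, getattr(node, "support", 0.0) or 0.0)
        assert best >= 95.0


class TestAlignmentValidation:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            _aln([("a", "ACD"), ("b", "AC")])

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            _aln([("a", "AC1")])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            _aln([("a", "ACD")], labels=[("a", "3Q")])
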