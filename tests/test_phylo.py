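import numpy as np
import pytest

from noxevo.phylo import (
    PhyloError,
    SubstitutionModel,
    bootstrap_alignments,
    discretize_gamma,
    distance_matrix,
    felsenstein_support,
    log_likelihood,
    midpoint_root,
    neighbor_joining,
    tbe_support,
)
from noxevo.sequences import Alignment
from noxevo.trees import Tree

from oracles import (
    additive_distances,
    bipartition_set,
    enumerate_unrooted_topologies,
    least_squares_sse,
    transfer_support_oracle,
)


def random_additive_tree(ids, rng):
    """Random unrooted binary topology with branch lengths in [0.1, 1]."""
    topologies = enumerate_unrooted_topologies(ids)
    t = topologies[rng.integers(0, len(topologies))].copy()
    for n in t.postorder():
        if n.parent is not None:
            n.length = float(rng.uniform(0.1, 1.0))
    return t


class TestDistanceMatrix:
    def test_identical_rows_give_zero(self):
        aln = Alignment(ids=["a", "b"], rows=["MKVL", "MKVL"])
        _, D = distance_matrix(aln)
        assert D[0, 1] == 0.0

    def test_closed_form_p_and_poisson(self):
        aln = Alignment(ids=["a", "b"], rows=["MKVL", "MKIL"])
        _, Dp = distance_matrix(aln, "p-distance")
        assert Dp[0, 1] == pytest.approx(0.25)
        _, Dc = distance_matrix(aln, "Poisson-corrected")
        assert Dc[0, 1] == pytest.approx(-np.log(0.75))

    def test_gaps_excluded_from_denominator(self):
        aln = Alignment(ids=["a", "b"], rows=["MK-L", "MA-L"])
        _, D = distance_matrix(aln)  # comparable columns: M, K/A, L
        assert D[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns_errors_naming_pair(self):
        aln = Alignment(ids=["a", "b"], rows=["M-", "-M"])
        with pytest.raises(PhyloError, match="'a'.*'b'"):
            distance_matrix(aln)

    def test_saturated_pair_errors_under_poisson(self):
        aln = Alignment(ids=["a", "b"], rows=["MK", "LV"])
        with pytest.raises(PhyloError):
            distance_matrix(aln, "Poisson-corrected")

    def test_simulated_matrix_symmetric_nonnegative(self, default_bundle):
        _, D = distance_matrix(default_bundle.alignment)
        assert np.allclose(D, D.T) and (D >= 0).all()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(ids, D)
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_distances_recover_topology_vs_exhaustive_ls(self, rng):
        ids = list("abcde")
        topologies = enumerate_unrooted_topologies(ids)
        assert len(topologies) == 15
        for _ in range(20):
            true = random_additive_tree(ids, rng)
            D = additive_distances(true, ids)
            nj = neighbor_joining(ids, D)
            # oracle: the least-squares-best topology over all 15
            sses = [least_squares_sse(t, ids, D) for t in topologies]
            best = topologies[int(np.argmin(sses))]
            assert bipartition_set(nj) == bipartition_set(best)
            assert bipartition_set(nj) == bipartition_set(true)
            # and NJ reproduces the additive branch lengths
            got = nj.leaf_path_lengths()
            for pair, d in true.leaf_path_lengths().items():
                assert got[pair] == pytest.approx(d, abs=1e-9)

    def test_identical_taxa_join_first(self):
        ids = list("abcd")
        D = np.array([
            [0.0, 0.0, 5.0, 5.0],
            [0.0, 0.0, 5.0, 5.0],
            [5.0, 5.0, 0.0, 2.0],
            [5.0, 5.0, 2.0, 0.0],
        ])
        tree = neighbor_joining(ids, D)
        # the identical pair forms a cherry (the a,b | c,d split) at distance 0
        assert bipartition_set(tree) == {frozenset("cd")}
        assert tree.leaf_path_lengths()[("a", "b")] == pytest.approx(0.0)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(PhyloError):
            neighbor_joining(list("abc"), D)


class TestMidpointRoot:
    def test_two_leaf_midpoint(self):
        tree = Tree.from_newick("(a:1,b:3);")
        rooted = midpoint_root(tree)
        lengths = {l.name: l.length for l in rooted.leaves()}
        assert lengths["a"] == pytest.approx(2.0)
        assert lengths["b"] == pytest.approx(2.0)

    def test_root_bisects_diameter_path(self, rng):
        for _ in range(10):
            t = random_additive_tree(list("abcdef"[:5]), rng)
            d = t.leaf_path_lengths()
            diameter = max(d.values())
            rooted = midpoint_root(t)
            dr = rooted.leaf_path_lengths()
            # path lengths preserved
            for pair, v in d.items():
                assert dr[pair] == pytest.approx(v, abs=1e-9)
            # the two depth-maximal leaves sit at diameter/2
            depths = {}
            for leaf in rooted.leaves():
                depth, n = 0.0, leaf
                while n.parent is not None:
                    depth += n.length or 0.0
                    n = n.parent
                depths[leaf.name] = depth
            assert max(depths.values()) == pytest.approx(diameter / 2, abs=1e-9)

    def test_idempotent_on_midpoint_rooted_tree(self):
        t = Tree.from_newick("((a:1,b:2):1,(c:1.5,d:0.5):1);", rooted=True)
        again = midpoint_root(t)
        assert bipartition_set(again) == bipartition_set(t)
        d0, d1 = t.leaf_path_lengths(), again.leaf_path_lengths()
        for pair in d0:
            assert d1[pair] == pytest.approx(d0[pair])

    def test_zero_length_tree_errors(self):
        with pytest.raises(PhyloError):
            midpoint_root(Tree.from_newick("(a:0,b:0,(c:0,d:0):0);"))


class TestBootstrap:
    def test_deterministic_under_seed(self, default_bundle):
        aln = default_bundle.alignment
        a = bootstrap_alignments(aln, 3, seed=42)
        b = bootstrap_alignments(aln, 3, seed=42)
        assert [x.rows for x in a] == [y.rows for y in b]
        c = bootstrap_alignments(aln, 3, seed=43)
        assert [x.rows for x in a] != [z.rows for z in c]

    def test_columns_drawn_from_original(self):
        aln = Alignment(ids=["a", "b"], rows=["MKVL", "MKIL"])
        reps = bootstrap_alignments(aln, 5, seed=0)
        original = {aln.column(j) for j in range(aln.length)}
        for rep in reps:
            assert rep.length == aln.length
            for j in range(rep.length):
                assert rep.column(j) in original


class TestBranchSupport:
    def make_trees(self):
        ref = Tree.from_newick("(((a:1,b:1):1,(c:1,d:1):1):1,(e:1,f:1):1);")
        reps = [
            Tree.from_newick("(((a:1,b:1):1,(c:1,d:1):1):1,(e:1,f:1):1);"),
            Tree.from_newick("(((a:1,c:1):1,(b:1,d:1):1):1,(e:1,f:1):1);"),
            Tree.from_newick("((((a:1,b:1):1,c:1):1,d:1):1,(e:1,f:1):1);"),
        ]
        return ref, reps

    def test_branch_in_every_replicate_has_unit_support(self):
        ref, reps = self.make_trees()
        out = tbe_support(ref, [reps[0], reps[0]])
        for n in out.internal_nodes():
            if n.support is not None:
                assert n.support == pytest.approx(1.0)

    @staticmethod
    def _clade_names(node):
        stack, names = [node], set()
        while stack:
            m = stack.pop()
            if m.is_leaf:
                names.add(m.name)
            stack.extend(m.children)
        return names

    def test_cherry_support_equals_presence_fraction(self):
        ref, reps = self.make_trees()
        out = tbe_support(ref, reps)
        # cherry (a,b): present in replicates 1 and 3, absent (delta=1) in 2
        ab = next(n for n in out.postorder()
                  if not n.is_leaf and self._clade_names(n) == {"a", "b"})
        assert ab.support == pytest.approx(2 / 3)

    def test_tbe_matches_exhaustive_oracle_on_handcrafted_replicates(self):
        ref, reps = self.make_trees()
        out = tbe_support(ref, reps)
        oracle = transfer_support_oracle(ref, reps)
        checked = 0
        for n in out.postorder():
            if n.is_leaf or n.parent is None or n.support is None:
                continue
            names = frozenset(self._clade_names(n))
            assert n.support == pytest.approx(oracle[names], abs=1e-9)
            checked += 1
        assert checked >= 3

    def test_tbe_at_least_felsenstein(self, default_bundle, rng):
        aln = default_bundle.alignment
        ids, D = distance_matrix(aln)
        ref = midpoint_root(neighbor_joining(ids, D))
        boots = []
        for rep in bootstrap_alignments(aln, 10, seed=9):
            rids, RD = distance_matrix(rep)
            boots.append(neighbor_joining(rids, RD))
        t_tbe = tbe_support(ref, boots)
        t_fb = felsenstein_support(ref, boots)
        for a, b in zip(t_tbe.postorder(), t_fb.postorder()):
            if a.support is not None:
                assert a.support >= b.support - 1e-12

    def test_leaf_set_mismatch_errors(self):
        ref, _ = self.make_trees()
        bad = Tree.from_newick("((a:1,b:1):1,(c:1,x:1):1);")
        with pytest.raises(PhyloError):
            tbe_support(ref, [bad])


class TestGammaAndModel:
    def test_single_category_is_unit_rate(self):
        assert discretize_gamma(1.347, 1) == pytest.approx([1.0])

    def test_four_category_rates_match_quadrature_oracle(self):
        # independent oracle: numeric quadrature of the conditional means
        from scipy import integrate
        from scipy.stats import gamma as g
        alpha, k = 1.347, 4
        edges = g.ppf(np.linspace(0, 1, k + 1), alpha, scale=1 / alpha)
        oracle = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(
                lambda x: x * g.pdf(x, alpha, scale=1 / alpha), lo,
                min(hi, 1e3))
            oracle.append(val * k)
        rates = discretize_gamma(alpha, k)
        assert rates == pytest.approx(oracle, abs=1e-6)
        assert np.all(np.diff(rates) > 0)
        assert rates.mean() == pytest.approx(1.0, abs=1e-10)

    def test_large_alpha_limit_has_no_rate_variation(self):
        # category means concentrate as 1 + O(1/sqrt(alpha))
        rates = discretize_gamma(1e8, 4)
        assert np.allclose(rates, 1.0, atol=1e-3)
        spread6 = np.abs(discretize_gamma(1e6, 4) - 1.0).max()
        assert spread6 < 2e-3

    def test_invalid_parameters(self):
        with pytest.raises(PhyloError):
            discretize_gamma(-1.0, 4)
        with pytest.raises(PhyloError):
            discretize_gamma(1.0, 0)

    def test_rate_matrix_rows_sum_to_zero_and_mean_rate_one(self):
        for name in ("LG", "Poisson"):
            m = SubstitutionModel(name)
            assert np.allclose(m.rate_matrix.sum(axis=1), 0.0, atol=1e-12)
            mu = -np.dot(m.frequencies, np.diag(m.rate_matrix))
            assert mu == pytest.approx(1.0)
            assert m.frequencies.sum() == pytest.approx(1.0)

    def test_transition_matrix_rows_are_distributions(self):
        m = SubstitutionModel("LG")
        for t in (0.0, 0.1, 2.0):
            P = m.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert (P >= 0).all()
        assert np.allclose(m.transition_matrix(0.0), np.eye(20), atol=1e-12)


class TestLogLikelihood:
    def test_single_leaf_site_is_log_pi(self):
        m = SubstitutionModel("LG")
        aln = Alignment(ids=["a"], rows=["A"])
        tree = Tree.from_newick("a;")
        total, per_site = log_likelihood(tree, aln, m)
        idx = "ARNDCQEGHILKMFPSTWYV".index("A")
        assert total == pytest.approx(np.log(m.frequencies[idx]))

    def test_two_leaves_poisson_closed_form(self):
        # Poisson model: P(same) = 1/20 + 19/20 exp(-20 t / 19)
        m = SubstitutionModel("Poisson")
        t1, t2 = 0.13, 0.27
        tree = Tree.from_newick(f"(a:{t1},b:{t2});", rooted=True)
        mu = 20.0 / 19.0
        for rows, same in ((["A", "A"], True), (["A", "C"], False)):
            aln = Alignment(ids=["a", "b"], rows=rows)
            total, _ = log_likelihood(tree, aln, m)
            p_same = 1 / 20 + 19 / 20 * np.exp(-mu * (t1 + t2))
            expected = (1 / 20) * (p_same if same else (1 - p_same) / 19)
            assert total == pytest.approx(np.log(expected), abs=1e-10)

    def test_invariant_under_rerooting(self, lg_g4):
        aln = Alignment(ids=list("abcd"),
                        rows=["MKVDEF", "MKIDQF", "MRVEEY", "LKVDEF"])
        unrooted = Tree.from_newick("((a:0.1,b:0.2):0.05,c:0.3,d:0.15);")
        base, _ = log_likelihood(unrooted, aln, lg_g4)
        rooted = midpoint_root(unrooted)
        again, _ = log_likelihood(rooted, aln, lg_g4)
        assert again == pytest.approx(base, abs=1e-9)

    def test_matches_independent_reference_value(self, lg_g4):
        # frozen value computed with the R package phangorn (pml, LG, k=4,
        # shape=1.347) on this exact fixture
        aln = Alignment(ids=list("abcd"),
                        rows=["MKVDEF", "MKIDQF", "MRVEEY", "LKVDEF"])
        tree = Tree.from_newick("((a:0.1,b:0.2):0.05,c:0.3,d:0.15);")
        total, _ = log_likelihood(tree, aln, lg_g4)
        assert total == pytest.approx(-38.9727733549, abs=1e-6)
        m1 = SubstitutionModel("LG")
        total1, _ = log_likelihood(tree, aln, m1)
        assert total1 == pytest.approx(-37.4402223184, abs=1e-6)

    def test_gaps_are_missing_data(self, lg_g4):
        # a column observed in one row only has likelihood pi of that residue
        gapped = Alignment(ids=["a", "b"], rows=["M-", "MK"])
        tree = Tree.from_newick("(a:0.1,b:0.1);", rooted=True)
        _, ps = log_likelihood(tree, gapped, lg_g4)
        idx = "ARNDCQEGHILKMFPSTWYV".index("K")
        assert ps[1] == pytest.approx(np.log(lg_g4.frequencies[idx]))

    def test_likelihood_peaks_near_true_branch_length(self, rng):
        # local monotonicity around the simulated value at desk scale
        from noxevo.simulate import evolve
        from noxevo.sequences import ProteinRecord
        m = SubstitutionModel("LG")
        t_true = 0.4
        tree = Tree.from_newick(f"(a:{t_true / 2},b:{t_true / 2});", rooted=True)
        root = ProteinRecord(id="r", seq="".join(
            rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=2000)))
        fam = evolve(tree, root, m, seed=11)
        lls = []
        for t in (0.05, t_true, 2.5):
            t2 = Tree.from_newick(f"(a:{t / 2},b:{t / 2});", rooted=True)
            lls.append(log_likelihood(t2, fam.alignment, m)[0])
        assert lls[1] > lls[0] and lls[1] > lls[2]
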