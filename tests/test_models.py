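import itertools
import math

import numpy as np
import pytest

from uceflow.models import (LikelihoodEngine, ModelFit, SaturationError,
                            aicc, empirical_freqs, fit_models,
                            gamma_category_rates, group_partitions,
                            jc_distance, pruning_lnL, rate_matrix,
                            _TransitionCache)
from uceflow.simulate import simulate_sequences
from uceflow.trees import Node, TreeError, from_newick, nj_tree


class TestJcDistance:
    def test_identical_is_zero(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_p_ten_percent(self):
        d = jc_distance("A" * 90 + "C" * 10, "A" * 90 + "G" * 10)
        assert d == pytest.approx(0.107326, abs=1e-6)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jc_distance("A" * 25 + "C" * 75, "A" * 25 + "G" * 75)
        capped = jc_distance("A" * 25 + "C" * 75, "A" * 25 + "G" * 75,
                             cap=True)
        assert math.isfinite(capped)

    def test_gaps_excluded_from_comparison(self):
        d = jc_distance("ACGT----", "ACGTAAAA")
        assert d == 0.0


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        # distances from ((A:1,B:2):1,(C:3,D:1))
        names = ["A", "B", "C", "D"]
        dist = np.array([[0, 3, 5, 3], [3, 0, 6, 4],
                         [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float)
        tree = nj_tree(names, dist)
        lengths = {}
        for node in tree.postorder():
            if node.is_leaf:
                lengths[node.name] = node.length
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0}
        # internal edge of length 1 separates AB from CD
        from uceflow.trees import topology_key
        expected = topology_key(from_newick("((A:1,B:2):1,(C:3,D:1):0);"))
        assert topology_key(tree) == expected
        internal = [n for n in tree.postorder()
                    if not n.is_leaf and n is not tree]
        assert internal[0].length == pytest.approx(1.0)

    def test_three_taxa_star(self):
        tree = nj_tree(["A", "B", "C"],
                       np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float))
        assert len(tree.children) == 3

    def test_preconditions(self):
        with pytest.raises(TreeError):
            nj_tree(["A", "B"], np.zeros((2, 2)))
        with pytest.raises(TreeError):
            nj_tree(["A", "B", "C"],
                    np.array([[0, -1, 1], [-1, 0, 1], [1, 1, 0]], float))

    def test_agrees_with_dendropy_on_random_distances(self, rng):
        """Cross-check against dendropy's independent NJ implementation."""
        import io as _io

        import dendropy

        from uceflow.trees import from_dendropy, topology_key
        names = [f"t{i}" for i in range(7)]
        base = rng.uniform(0.1, 1.0, size=(7, 7))
        dist = (base + base.T) / 2
        np.fill_diagonal(dist, 0.0)
        ours = nj_tree(names, dist)
        csv = "," + ",".join(names) + "\n" + "\n".join(
            names[i] + "," + ",".join(str(dist[i, j]) for j in range(7))
            for i in range(7))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_io.StringIO(csv))
        theirs = pdm.nj_tree()
        assert topology_key(ours) == topology_key(from_dendropy(theirs))


class TestPruningLikelihood:
    def test_identical_pair_zero_branch(self):
        aln = {"A": "ACGTACGTAC", "B": "ACGTACGTAC"}
        tree = Node(children=[Node("A", 0.0), Node("B", 0.0)])
        assert pruning_lnL(aln, tree, "JC69") == \
            pytest.approx(10 * math.log(0.25))

    def test_two_taxon_ml_matches_jc_closed_form(self):
        from scipy.optimize import minimize_scalar
        aln = {"A": "A" * 90 + "C" * 10, "B": "A" * 90 + "G" * 10}

        def neg(t):
            tree = Node(children=[Node("A", t / 2), Node("B", t / 2)])
            return -pruning_lnL(aln, tree, "JC69")

        res = minimize_scalar(neg, bounds=(1e-6, 2.0), method="bounded",
                              options={"xatol": 1e-8})
        assert res.x == pytest.approx(0.107326, abs=1e-4)

    @pytest.mark.parametrize("model,params", [
        ("JC69", {}),
        ("K80", {"kappa": 4.0}),
        ("GTR+G", {"rates": np.array([2.0, 6.0, 1.0, 1.2, 8.0]),
                   "freqs": np.array([0.35, 0.25, 0.25, 0.15]),
                   "alpha": 0.7}),
    ])
    def test_matches_exhaustive_state_sum(self, rng, model, params):
        """Pruning equals the brute-force sum over internal-node states on
        4-taxon, 10-site alignments, to 1e-8."""
        aln = {t: "".join(rng.choice(list("ACGT-"), 10,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
               for t in "ABCD"}
        branch = {"U": 0.08, "V": 0.1, "A": 0.12, "B": 0.3,
                  "C": 0.2, "D": 0.05}
        tree = from_newick("((A:0.12,B:0.3):0.08,(C:0.2,D:0.05):0.1);")
        result = pruning_lnL(aln, tree, model, params)

        Q, freqs = rate_matrix(model, params)
        cache = _TransitionCache(Q, freqs)
        rates = (gamma_category_rates(params["alpha"])
                 if "+G" in model else [1.0])
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = 0.0
        for site in range(10):
            site_lik = 0.0
            for rate in rates:
                P = {k: cache.P(v * rate) for k, v in branch.items()}
                for r, u, v in itertools.product(range(4), repeat=3):
                    term = freqs[r] * P["U"][r, u] * P["V"][r, v]
                    for leaf, anc in (("A", u), ("B", u), ("C", v), ("D", v)):
                        c = aln[leaf][site]
                        term *= P[leaf][anc, idx[c]] if c in idx else 1.0
                    site_lik += term / len(rates)
            expected += math.log(site_lik)
        assert result == pytest.approx(expected, abs=1e-8)

    def test_true_topology_has_highest_likelihood(self):
        """On data simulated under one resolved quartet, that topology's
        optimized lnL beats the two alternatives nearly always."""
        from uceflow.models import LikelihoodEngine, _optimize_branches
        topologies = ["((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);",
                      "((A:0.1,C:0.1):0.05,(B:0.1,D:0.1):0.05);",
                      "((A:0.1,D:0.1):0.05,(B:0.1,C:0.1):0.05);"]
        true_tree = from_newick(topologies[0])
        wins = 0
        n_reps = 20
        for rep in range(n_reps):
            aln = simulate_sequences(true_tree, "JC69", 1000, seed=900 + rep)
            engine = LikelihoodEngine(aln)
            scores = []
            for nwk in topologies:
                tree = from_newick(nwk)
                scores.append(_optimize_branches(engine, tree, "JC69", {},
                                                 rounds=1))
            wins += int(np.argmax(scores)) == 0
        assert wins >= 0.95 * n_reps

    def test_aicc_invariant_under_site_permutation(self, rng):
        tree = from_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
        aln = simulate_sequences(tree, "K80", 300, seed=3,
                                 params={"kappa": 3.0})
        perm = rng.permutation(300)
        shuffled = {t: "".join(s[i] for i in perm) for t, s in aln.items()}
        _, best_a = fit_models("a", aln, candidates=("JC69", "K80"))
        _, best_b = fit_models("b", shuffled, candidates=("JC69", "K80"))
        assert best_a.model == best_b.model
        assert best_a.aicc == pytest.approx(best_b.aicc, abs=0.2)


class TestAicc:
    def test_formula_arithmetic(self):
        assert aicc(-100.0, 10, 100) == pytest.approx(222.4719, abs=1e-4)

    def test_degenerate_zero(self):
        assert aicc(0.0, 0, 100) == 0.0

    def test_infinite_when_undersampled(self):
        assert aicc(-10.0, 40, 41) == math.inf


class TestFitModels:
    def test_too_short_alignment_flagged(self, random_seq):
        # 20 taxa -> K >= 37 branch lengths; 30 sites cannot support any fit
        seq = random_seq(30)
        aln = {f"t{i:02d}": seq for i in range(20)}
        fits, best = fit_models("short", aln)
        assert best is None
        assert fits[0].status == "too_short"

    def test_fit_reports_consistent_aicc(self):
        tree = from_newick("((A:0.15,B:0.15):0.05,(C:0.15,D:0.15):0.05);")
        aln = simulate_sequences(tree, "JC69", 400, seed=11)
        fits, best = fit_models("L", aln, candidates=("JC69", "K80", "HKY85"))
        for fit in fits:
            assert fit.aicc == pytest.approx(
                aicc(fit.lnL, fit.K, fit.n), abs=1e-9)
        assert best.aicc == min(f.aicc for f in fits)


class TestGroupPartitions:
    def _fit(self, locus, model, status="ok"):
        return ModelFit(locus, model, -100.0, 10, 500, 220.0, status=status)

    def test_shared_models_group(self):
        fits = [self._fit("L1", "HKY85"), self._fit("L2", "HKY85"),
                self._fit("L3", "GTR")]
        parts, models, excluded = group_partitions(fits)
        assert parts == {"p_GTR": ["L3"], "p_HKY85": ["L1", "L2"]}
        assert models == {"p_GTR": "GTR", "p_HKY85": "HKY85"}
        assert excluded == []

    def test_single_partition_when_uniform(self):
        fits = [self._fit(f"L{i}", "JC69") for i in range(5)]
        parts, _, _ = group_partitions(fits)
        assert list(parts) == ["p_JC69"]
        assert len(parts["p_JC69"]) == 5

    def test_too_short_loci_excluded(self):
        fits = [self._fit("L1", "JC69"), self._fit("L2", "", "too_short"),
                self._fit("L3", "JC69"), self._fit("L4", "", "too_short")]
        parts, _, excluded = group_partitions(fits)
        assert excluded == ["L2", "L4"]
        assert sum(len(v) for v in parts.values()) == 2


class TestEmpiricalFreqs:
    def test_counts_only_unambiguous(self):
        freqs = empirical_freqs({"a": "AACC", "b": "AANN--"})
        assert freqs == pytest.approx([4 / 6, 2 / 6, 0.0, 0.0], abs=1e-5)
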