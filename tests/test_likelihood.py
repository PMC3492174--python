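"""Likelihood engine: closed forms, brute-force oracles, fitting, rates."""

import itertools
import warnings

import numpy as np
import pytest

from sitesieve.phylolik import (
    HypothesisSet,
    PruningEngine,
    estimate_site_rates,
    fit_on_topology,
    gene_rate_stats,
    loglik,
    nj_tree,
    remove_fast_genes,
    search_ml_tree,
    site_lls_for_hypotheses,
)
from sitesieve.seqio import Alignment
from sitesieve.substmodel import (
    SubstitutionModel,
    discrete_gamma_rates,
    transition_matrix,
)
from sitesieve.trees import Tree

from conftest import random_alignment, random_gtr


class TestTransitionMatrix:
    def test_t_zero_is_identity(self, rng):
        m = random_gtr(rng)
        assert np.allclose(transition_matrix(m, 0.0), np.eye(4), atol=1e-12)

    def test_jc_closed_form(self):
        m = SubstitutionModel.jc()
        for t in (0.01, 0.3, 1.5):
            p = transition_matrix(m, t)
            diag = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            off = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
            assert np.allclose(np.diag(p), diag, atol=1e-12)
            assert p[0, 1] == pytest.approx(off, abs=1e-12)

    def test_rows_sum_to_one_and_nonnegative(self, rng):
        m = random_gtr(rng)
        p = transition_matrix(m, 0.7)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert (p >= 0).all()

    def test_long_branch_reaches_stationarity(self, rng):
        m = random_gtr(rng)
        p = transition_matrix(m, 300.0)
        assert np.allclose(p, np.tile(m.freqs, (4, 1)), atol=1e-6)

    def test_freqs_override_changes_equilibrium(self):
        m = SubstitutionModel.jc()
        target = np.array([0.1, 0.4, 0.4, 0.1])
        p = transition_matrix(m, 300.0, freqs_override=target)
        assert np.allclose(p, np.tile(target, (4, 1)), atol=1e-6)

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(
                SubstitutionModel.jc(), 0.1, freqs_override=[0.5, 0.5, 0.5, 0.5]
            )

    def test_gamma_rates_mean_one(self):
        for alpha in (0.2, 1.0, 5.0):
            r = discrete_gamma_rates(alpha, 4)
            assert r.mean() == pytest.approx(1.0, abs=1e-12)
            assert (np.diff(r) > 0).all()
        assert discrete_gamma_rates(1.0, 1).tolist() == [1.0]


def brute_force_site_loglik(aln, tree, model):
    """Exhaustive sum over internal-node state assignments (oracle)."""
    states = model.states
    cats = model.category_rates()
    rooted = tree
    nodes = rooted.postorder()
    internal = [n for n in nodes if n.children]
    out = np.zeros(aln.n_sites)
    tip = {t: aln.row(t) for t in aln.taxa}
    for s in range(aln.n_sites):
        total = 0.0
        for r in cats:
            pmats = {
                id(n): transition_matrix(model, (n.length or 0.0) * r)
                for n in nodes
                if n.parent is not None
            }
            cat_sum = 0.0
            for assign in itertools.product(range(len(states)), repeat=len(internal)):
                st = {id(n): a for n, a in zip(internal, assign)}
                for n in nodes:
                    if not n.children:
                        st[id(n)] = states.index(tip[n.name][s])
                prob = model.freqs[st[id(rooted.root)]]
                for n in nodes:
                    if n.parent is not None:
                        prob *= pmats[id(n)][st[id(n.parent)], st[id(n)]]
                cat_sum += prob
            total += cat_sum / len(cats)
        out[s] = np.log(total)
    return out


class TestPruning:
    def test_two_taxa_identical_t_zero(self, jc):
        aln = Alignment(["a", "b"], np.array([["A"], ["A"]]))
        tot, site = loglik(aln, Tree.from_newick("(a:0,b:0);"), jc)
        assert tot == pytest.approx(np.log(0.25), abs=1e-12)

    def test_two_taxa_brute_force(self, jc):
        aln = Alignment(["a", "b"], np.array([["A"], ["G"]]))
        tot, _ = loglik(aln, Tree.from_newick("(a:0.1,b:0.2);"), jc)
        p1, p2 = transition_matrix(jc, 0.1), transition_matrix(jc, 0.2)
        brute = sum(0.25 * p1[x, 0] * p2[x, 2] for x in range(4))
        assert tot == pytest.approx(np.log(brute), abs=1e-12)

    @pytest.mark.parametrize("newick,alpha", [
        ("((a:0.1,b:0.25):0.07,c:0.3);", None),
        ("((a:0.1,b:0.25):0.07,(c:0.3,d:0.12):0.2);", 0.6),
        ("((a:0.05,b:0.4):0.1,(c:0.3,(d:0.12,e:0.2):0.15):0.08);", 1.2),
    ])
    def test_matches_internal_state_enumeration(self, rng, newick, alpha):
        tree = Tree.from_newick(newick)
        model = random_gtr(rng, alpha=alpha)
        aln = random_alignment(rng, tree.leaf_names, 7)
        _, site = loglik(aln, tree, model)
        oracle = brute_force_site_loglik(aln, tree, model)
        assert np.abs(site - oracle).max() < 1e-10

    def test_ambiguity_is_union_of_states(self, jc):
        tree = Tree.from_newick("(a:0.2,b:0.3);")
        # R = A or G: likelihood must equal sum of the two resolutions
        amb = Alignment(["a", "b"], np.array([["R"], ["C"]]))
        la = np.exp(loglik(Alignment(["a", "b"], np.array([["A"], ["C"]])), tree, jc)[0])
        lg = np.exp(loglik(Alignment(["a", "b"], np.array([["G"], ["C"]])), tree, jc)[0])
        assert loglik(amb, tree, jc)[0] == pytest.approx(np.log(la + lg), abs=1e-10)

    def test_rooting_invariance(self, rng):
        tree = Tree.from_newick("((a:0.1,b:0.25):0.07,(c:0.3,d:0.12):0.2);")
        model = random_gtr(rng, alpha=0.8)
        aln = random_alignment(rng, tree.leaf_names, 50)
        ref = loglik(aln, tree, model)[0]
        for leaf in "abcd":
            assert loglik(aln, tree.reroot_at_leaf(leaf), model)[0] == pytest.approx(
                ref, abs=1e-8
            )

    def test_single_gamma_category_equals_homogeneous(self, rng):
        tree = Tree.from_newick("((a:0.1,b:0.25):0.07,(c:0.3,d:0.12):0.2);")
        aln = random_alignment(rng, tree.leaf_names, 60)
        m1 = random_gtr(rng)
        mk = SubstitutionModel(m1.exchangeabilities, m1.freqs, 1e9, 4, "nt")
        l1 = loglik(aln, tree, m1)[0]
        # alpha -> infinity collapses the mixture to rate 1 as well
        lk = loglik(aln, tree, mk)[0]
        assert lk == pytest.approx(l1, abs=1e-4)
        m_onecat = SubstitutionModel(m1.exchangeabilities, m1.freqs, 0.5, 1, "nt")
        assert loglik(aln, tree, m_onecat)[0] == pytest.approx(l1, abs=1e-10)

    def test_per_site_sums_to_total(self, rng):
        tree = Tree.from_newick("((a:0.1,b:0.25):0.07,(c:0.3,d:0.12):0.2);")
        model = random_gtr(rng, alpha=0.5)
        aln = random_alignment(rng, tree.leaf_names, 200)
        tot, site = loglik(aln, tree, model)
        assert tot == pytest.approx(site.sum(), abs=1e-8)

    def test_outside_inside_identity_on_every_edge(self, rng):
        """For any edge, the pi-weighted outside array contracted with the
        inside message reproduces the total log-likelihood exactly."""
        tree = Tree.from_newick("((a:0.1,b:0.25):0.07,(c:0.3,d:0.12):0.2);")
        model = random_gtr(rng, alpha=0.9)
        aln = random_alignment(rng, tree.leaf_names, 80)
        engine = PruningEngine(aln, model)
        ref = engine.loglik(tree)
        rates = engine.cat_rates
        k = len(rates)
        post, L, S, scale, O, oscale = engine._outside(tree, rates)
        for v in post:
            if v.parent is None:
                continue
            tot = np.clip((O[id(v)] * S[id(v)]).sum(axis=2), 1e-300, None)
            site = np.logaddexp.reduce(
                np.log(tot) + scale[id(v)] + oscale[id(v)] - np.log(k), axis=0
            )
            assert float(site @ engine.weights) == pytest.approx(ref, abs=1e-8)

    def test_missing_leaf_rejected(self, jc):
        aln = Alignment(["a", "b"], np.array([["A"], ["A"]]))
        with pytest.raises(ValueError, match="absent"):
            loglik(aln, Tree.from_newick("(a:0.1,zz:0.1);"), jc)

    def test_polytomy_rejected(self, jc):
        aln = Alignment(["a", "b", "c", "d"], np.array([["A"]] * 4))
        with pytest.raises(ValueError, match="polytomy|resolved"):
            loglik(aln, Tree.from_newick("(a:1,b:1,c:1,d:1);"), jc)


class TestFitOnTopology:
    def test_two_taxon_ml_distance_closed_form(self, rng):
        n = 3000
        anc = rng.choice(list("ACGT"), n)
        der = anc.copy()
        hit = rng.random(n) < 0.12
        der[hit] = rng.choice(list("ACGT"), hit.sum())
        p = (anc != der).mean()
        aln = Alignment(["a", "b"], np.array([anc, der]))
        fit = fit_on_topology(
            aln, Tree.from_newick("(a:0.1,b:0.1);"), SubstitutionModel.jc(),
            optimize=("branch_lengths",),
        )
        expected = -0.75 * np.log(1 - 4 * p / 3)
        assert sum(fit.tree.branch_lengths()) == pytest.approx(expected, abs=1e-4)

    def test_identical_sequences_hit_lower_bound(self, jc):
        aln = Alignment(["a", "b", "c"], np.array([list("ACGTACGT")] * 3))
        fit = fit_on_topology(
            aln, Tree.from_newick("((a:0.1,b:0.1):0.1,c:0.1);"), jc,
            optimize=("branch_lengths",),
        )
        assert max(fit.tree.branch_lengths()) <= 1e-4

    def test_loglik_never_decreases_from_start(self, rng):
        tree = Tree.from_newick("((a:0.3,b:0.02):0.2,(c:0.15,d:0.4):0.1);")
        model = random_gtr(rng)
        aln = random_alignment(rng, tree.leaf_names, 150)
        start_ll = loglik(aln, tree, model)[0]
        fit = fit_on_topology(aln, tree, model, optimize=("branch_lengths",))
        assert fit.loglik >= start_ll - 1e-9


class TestSiteLls:
    def _setup(self, rng):
        tree = Tree.from_newick("((a:0.1,b:0.2):0.15,(c:0.1,d:0.3):0.1);")
        aln = random_alignment(rng, tree.leaf_names, 120)
        h = HypothesisSet(
            {
                "h1": Tree.from_newick("((a,b),(c,d));"),
                "h2": Tree.from_newick("((a,c),(b,d));"),
            }
        )
        return aln, h

    def test_columns_sum_to_totals(self, rng):
        aln, h = self._setup(rng)
        lls, fits = site_lls_for_hypotheses(
            aln, h, SubstitutionModel.jc(), ("branch_lengths",)
        )
        for name in h.names:
            assert lls.df[name].sum() == pytest.approx(
                fits[name].loglik, abs=1e-8
            )

    def test_duplicate_hypothesis_gives_identical_columns(self, rng):
        aln, _ = self._setup(rng)
        h = HypothesisSet(
            {
                "x": Tree.from_newick("((a,b),(c,d));"),
                "y": Tree.from_newick("((b,a),(d,c));"),
            }
        )
        lls, _ = site_lls_for_hypotheses(
            aln, h, SubstitutionModel.jc(), ("branch_lengths",)
        )
        # independent optimizations of the same topology agree to the
        # branch-length convergence tolerance
        assert np.allclose(lls.df["x"], lls.df["y"], atol=2e-3)

    def test_tsv_and_sitelh_roundtrip(self, rng, tmp_path):
        aln, h = self._setup(rng)
        lls, _ = site_lls_for_hypotheses(
            aln, h, SubstitutionModel.jc(), ("branch_lengths",)
        )
        from sitesieve.phylolik import SiteLikelihoodMatrix

        p = tmp_path / "lls.tsv"
        lls.to_tsv(p)
        back = SiteLikelihoodMatrix.from_tsv(p)
        assert np.allclose(back.values, lls.values, atol=1e-6)
        lls.to_sitelh(tmp_path / "x.sitelh")
        first = (tmp_path / "x.sitelh").read_text().splitlines()[0].split()
        assert first == ["2", str(aln.n_sites)]


class TestSiteRates:
    def _fit(self, rng, n=150):
        tree = Tree.from_newick("((a:0.2,b:0.3):0.1,(c:0.2,d:0.25):0.1);")
        aln = random_alignment(rng, tree.leaf_names, n)
        # make the first 10 sites constant
        aln.matrix[:, :10] = "A"
        fit = fit_on_topology(
            aln, tree, SubstitutionModel.jc(), optimize=("branch_lengths",)
        )
        return aln, fit

    def test_constant_sites_at_zero(self, rng):
        aln, fit = self._fit(rng)
        rates = estimate_site_rates(aln, [fit])
        assert (rates[:10] == 0.0).all()

    def test_matches_dense_grid_oracle(self, rng):
        aln, fit = self._fit(rng, n=40)
        rates = estimate_site_rates(aln, [fit])
        model = SubstitutionModel(fit.model.exchangeabilities, fit.model.freqs,
                                  None, 1, "nt")
        engine = PruningEngine(aln, model)
        grid = np.linspace(0.0, 50.0, 2001)
        lls = np.stack(
            [
                engine.pattern_loglik(
                    fit.tree, pattern_rates=np.full(engine.n_patterns, r)
                )
                for r in grid
            ]
        )
        oracle_r = grid[lls.argmax(axis=0)]
        oracle_ll = lls.max(axis=0)
        pat_rates = np.empty(engine.n_patterns)
        pat_rates[engine.pattern_index] = rates
        mine_ll = engine.pattern_loglik(fit.tree, pattern_rates=pat_rates)
        # at each pattern: agree with the grid argmax to grid resolution, or
        # sit on a likelihood plateau at least as high as the grid optimum
        close = np.abs(pat_rates - oracle_r) <= 0.025 + 1e-9
        flat = mine_ll >= oracle_ll - 1e-6
        assert np.all(close | flat)
        assert mine_ll.min() >= oracle_ll.min() - 1e-6  # never worse overall

    def test_fast_sites_rank_above_slow_sites(self):
        from sitesieve.simulate import SimPartition, SimScenario, gc_freqs, simulate_nonstationary
        from scipy.stats import mannwhitneyu

        slow = Tree.from_newick("((a:0.05,b:0.05):0.025,(c:0.05,d:0.05):0.025);")
        fast = Tree.from_newick("((a:0.8,b:0.8):0.4,(c:0.8,d:0.8):0.4);")
        scen = SimScenario(
            [SimPartition("slow", slow, 500), SimPartition("fast", fast, 500)]
        )
        aln = simulate_nonstationary(scen, seed=5)
        tree = Tree.from_newick("((a:0.4,b:0.4):0.2,(c:0.4,d:0.4):0.2);")
        fit = fit_on_topology(aln, tree, SubstitutionModel.jc(),
                              optimize=("branch_lengths",))
        rates = estimate_site_rates(aln, [fit])
        stat = mannwhitneyu(rates[500:], rates[:500], alternative="greater")
        assert stat.pvalue < 1e-3


class TestGeneRates:
    PRINTED = (
        "(((A1:0.05,A2:0.05):0.5,(B1:0.05,B2:0.05):0.02):0.05,"
        "((C1:0.05,C2:0.05):0.02,(D1:0.05,D2:0.05):0.5):0.05);"
    )

    def test_printed_tree_stats(self):
        stats = gene_rate_stats(Tree.from_newick(self.PRINTED))
        assert stats["n_branches"] == 14
        assert stats["tree_length"] == pytest.approx(1.54)
        assert stats["mean_branch_length"] == pytest.approx(0.11)

    def test_star_tree(self):
        stats = gene_rate_stats(Tree.from_newick("(a:0.1,b:0.1,c:0.1);"))
        assert stats["tree_length"] == pytest.approx(0.3)
        assert stats["mean_branch_length"] == pytest.approx(0.1)

    def test_missing_length_rejected(self):
        with pytest.raises(ValueError):
            gene_rate_stats(Tree.from_newick("(a:0.1,b);"))

    def test_fastest_quarter_of_75_genes_is_19(self):
        lengths = {f"g{i}": 0.001 * (i + 1) for i in range(75)}
        retained, removed = remove_fast_genes(lengths, fraction=0.25)
        assert len(removed) == 19
        assert len(retained) == 56
        assert all(lengths[r] > max(lengths[k] for k in retained) - 1e-12
                   for r in removed)

    def test_fraction_zero_and_high_cutoff(self):
        lengths = {"a": 0.1, "b": 0.2}
        assert remove_fast_genes(lengths, fraction=0.0)[1] == []
        assert remove_fast_genes(lengths, cutoff=0.5)[1] == []
        assert remove_fast_genes(lengths, cutoff=0.15)[1] == ["b"]


class TestPartitionedFit:
    def test_per_gene_parameters_with_shared_branches(self):
        from sitesieve.phylolik import fit_partitioned
        from sitesieve.simulate import (
            SimPartition, SimScenario, gc_freqs, simulate_nonstationary,
        )

        truth = Tree.from_newick("((a:0.2,b:0.3):0.15,(c:0.25,d:0.2):0.15);")
        # two genes with very different base composition
        scen = SimScenario(
            [SimPartition("at_rich", truth, 400)],
            root_freqs=gc_freqs(0.25), default_freqs=gc_freqs(0.25),
        )
        g1 = simulate_nonstationary(scen, seed=1)
        scen2 = SimScenario(
            [SimPartition("gc_rich", truth, 400)],
            root_freqs=gc_freqs(0.75), default_freqs=gc_freqs(0.75),
        )
        g2 = simulate_nonstationary(scen2, seed=2)
        from sitesieve.seqio import GenePartitionSet, concatenate_genes

        aln = concatenate_genes(
            GenePartitionSet({"at_rich": g1, "gc_rich": g2}, g1.taxa)
        )
        tree, models, ll = fit_partitioned(
            aln, truth,
            optimize=("branch_lengths", "frequencies"),
            max_sweeps=8, tol=1e-3,
        )
        gc1 = models["at_rich"].freqs[1] + models["at_rich"].freqs[2]
        gc2 = models["gc_rich"].freqs[1] + models["gc_rich"].freqs[2]
        assert gc1 < 0.4 < 0.6 < gc2
        # a single unpartitioned model cannot fit both compositions
        joint = fit_on_topology(
            aln, truth, optimize=("branch_lengths", "frequencies"),
            max_sweeps=8, tol=1e-3,
        )
        assert ll > joint.loglik

    def test_remove_fast_genes_accepts_trees(self):
        slow = Tree.from_newick("(a:0.01,b:0.01);")
        fast = Tree.from_newick("(a:0.5,b:0.5);")
        retained, removed = remove_fast_genes(
            {"slow": slow, "fast": fast}, fraction=0.5
        )
        assert removed == ["fast"]


class TestSearch:
    def test_three_taxa_single_topology(self, rng, jc):
        aln = random_alignment(rng, ["a", "b", "c"], 60)
        tree, ll = search_ml_tree(aln, jc, strategy="exhaustive", fit_model=False)
        assert sorted(tree.leaf_names) == ["a", "b", "c"]
        assert np.isfinite(ll)

    def test_exhaustive_recovers_quartet_with_long_internal(self, jc):
        from sitesieve.simulate import SimPartition, SimScenario, simulate_nonstationary

        truth = Tree.from_newick("((a:0.1,b:0.1):0.5,(c:0.1,d:0.1):0.5);")
        scen = SimScenario([SimPartition("g", truth, 800)])
        aln = simulate_nonstationary(scen, seed=11)
        tree, _ = search_ml_tree(aln, jc, strategy="exhaustive", fit_model=False)
        assert tree.same_topology(truth)

    def test_nni_agrees_with_exhaustive_on_quartet(self, jc):
        from sitesieve.simulate import SimPartition, SimScenario, simulate_nonstationary

        truth = Tree.from_newick("((a:0.2,b:0.3):0.4,(c:0.15,d:0.25):0.4);")
        scen = SimScenario([SimPartition("g", truth, 600)])
        aln = simulate_nonstationary(scen, seed=3)
        t_ex, _ = search_ml_tree(aln, jc, strategy="exhaustive", fit_model=False)
        t_nni, _ = search_ml_tree(aln, jc, strategy="nni", fit_model=False)
        assert t_ex.same_topology(t_nni)

    def test_exhaustive_over_eight_taxa_rejected(self, rng, jc):
        aln = random_alignment(rng, [f"t{i}" for i in range(9)], 10)
        with pytest.raises(ValueError, match="nni"):
            search_ml_tree(aln, jc, strategy="exhaustive")

    def test_nj_tree_covers_taxa(self, rng):
        aln = random_alignment(rng, [f"t{i}" for i in range(6)], 100)
        tree = nj_tree(aln)
        assert sorted(tree.leaf_names) == sorted(aln.taxa)
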