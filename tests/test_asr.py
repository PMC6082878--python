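import itertools

import numpy as np
import pandas as pd
import pytest

import hybridscan as hs
from hybridscan.asr import DiscreteTrait, MkTraitModel, mk_transition_matrix
from hybridscan.errors import ConfigurationError, DegenerateTraitError


def brute_force_mk(tree_spec, tip_states, k, alpha):
    """Exhaustive-enumeration oracle: joint likelihood summed over all
    internal-state assignments, plus marginal posteriors per internal node.

    ``tree_spec``: dict node -> (parent, branch_length); root has parent None.
    """
    nodes = list(tree_spec)
    internal = [n for n in nodes if n not in tip_states]
    P = {
        n: mk_transition_matrix(k, alpha, bl)
        for n, (parent, bl) in tree_spec.items()
        if parent is not None
    }
    total = 0.0
    marg = {n: np.zeros(k) for n in internal}
    for assign in itertools.product(range(k), repeat=len(internal)):
        state = dict(zip(internal, assign))
        state.update(tip_states)
        like = 1.0 / k  # flat root prior
        for n, (parent, _bl) in tree_spec.items():
            if parent is None:
                continue
            like *= P[n][state[parent], state[n]]
        total += like
        for n in internal:
            marg[n][state[n]] += like
    return np.log(total), {n: v / total for n, v in marg.items()}


FIVE_TAXON_SPEC = {
    "root": (None, 0.0),
    "n1": ("root", 0.4),
    "n2": ("root", 0.7),
    "n3": ("n2", 0.3),
    "A": ("n1", 1.0),
    "B": ("n1", 0.5),
    "C": ("n2", 0.8),
    "D": ("n3", 0.2),
    "E": ("n3", 0.9),
}
FIVE_TAXON_NEWICK = "((A:1.0,B:0.5)n1:0.4,(C:0.8,(D:0.2,E:0.9)n3:0.3)n2:0.7)root;"


class TestLoglik:
    def test_two_state_single_branch_closed_form(self):
        # k=2: P(change over t) = (1 - e^{-2 alpha t}) / 2
        for alpha, t in [(0.3, 1.0), (1.2, 0.4)]:
            P = mk_transition_matrix(2, alpha, t)
            assert P[0, 1] == pytest.approx((1 - np.exp(-2 * alpha * t)) / 2)
            assert np.allclose(P.sum(axis=1), 1.0)

    def test_zero_length_branch_is_identity(self):
        assert np.allclose(mk_transition_matrix(3, 0.7, 0.0), np.eye(3))

    @pytest.mark.parametrize("alpha", [0.05, 0.3, 1.5])
    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_enumeration(self, alpha, k):
        states = "xyz"[:k]
        tip_states = {"A": 0, "B": 1 % k, "C": 0, "D": k - 1, "E": 1 % k}
        tree = hs.read_newick(FIVE_TAXON_NEWICK, rooted=True)
        trait = DiscreteTrait(
            "t", list(states), {n: states[s] for n, s in tip_states.items()}
        )
        model = MkTraitModel(tree, trait)
        ll_oracle, _ = brute_force_mk(FIVE_TAXON_SPEC, tip_states, k, alpha)
        assert model.loglik(alpha) == pytest.approx(ll_oracle, abs=1e-10)

    def test_unknown_tips_integrate_over_states(self):
        tree = hs.read_newick(FIVE_TAXON_NEWICK, rooted=True)
        trait = DiscreteTrait("t", ["x", "y"], {"A": "x", "B": "y", "C": "x"})
        ll = MkTraitModel(tree, trait).loglik(0.5)
        # oracle: sum over the two unknown tips' states as well
        total = 0.0
        for d, e in itertools.product(range(2), repeat=2):
            tips = {"A": 0, "B": 1, "C": 0, "D": d, "E": e}
            total += np.exp(brute_force_mk(FIVE_TAXON_SPEC, tips, 2, 0.5)[0])
        assert ll == pytest.approx(np.log(total), abs=1e-10)

    def test_trait_taxa_must_be_on_tree(self):
        tree = hs.read_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        with pytest.raises(ConfigurationError):
            MkTraitModel(tree, {"A": "x", "Z": "y", "B": "x", "C": "y", "D": "y"})


class TestMarginalPosteriors:
    @pytest.mark.parametrize("alpha", [0.1, 0.6, 2.0])
    def test_match_exhaustive_oracle(self, alpha):
        tip_states = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 0}
        tree = hs.read_newick(FIVE_TAXON_NEWICK, rooted=True)
        trait = DiscreteTrait("t", ["x", "y"], {n: "xy"[s] for n, s in tip_states.items()})
        res = MkTraitModel(tree, trait).fit(alpha=alpha)
        _, marg = brute_force_mk(FIVE_TAXON_SPEC, tip_states, 2, alpha)
        for node in ("root", "n1", "n2", "n3"):
            assert np.allclose(
                res.posteriors.loc[node].to_numpy(), marg[node], atol=1e-10
            ), node

    def test_posteriors_sum_to_one(self):
        tree = hs.read_newick(FIVE_TAXON_NEWICK, rooted=True)
        res = MkTraitModel(
            tree, {"A": "x", "B": "x", "C": "y", "D": "y", "E": "x"}
        ).fit(alpha=0.4)
        assert np.allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_root_posterior_equals_pruning_root_posterior(self):
        tree = hs.read_newick(FIVE_TAXON_NEWICK, rooted=True)
        model = MkTraitModel(tree, {"A": "x", "B": "x", "C": "y", "D": "y", "E": "x"})
        res = model.fit(alpha=0.4)
        L, _ = model._down_partials(0.4)
        direct = L[model._cache.root] / L[model._cache.root].sum()
        assert np.allclose(res.posteriors.loc["root"].to_numpy(), direct, atol=1e-12)

    def test_low_rate_limit_pins_all_nodes_to_shared_state(self):
        tree = hs.read_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        trait = DiscreteTrait("t", ["x", "y"], {t: "x" for t in "ABCD"})
        res = MkTraitModel(tree, trait).fit(alpha=1e-8)
        assert np.all(res.posteriors["x"].to_numpy() > 0.999999)

    def test_high_rate_limit_is_uniform(self):
        tree = hs.read_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        res = MkTraitModel(tree, {"A": "x", "B": "x", "C": "y", "D": "y"}).fit(alpha=1e3)
        internal = [i for i in res.posteriors.index if i.startswith("nd")]
        assert np.allclose(res.posteriors.loc[internal].to_numpy(), 0.5, atol=1e-6)

    def test_invariant_to_tip_input_order(self):
        tree = hs.read_newick(FIVE_TAXON_NEWICK, rooted=True)
        values = {"A": "x", "B": "x", "C": "y", "D": "y", "E": "x"}
        shuffled = dict(reversed(list(values.items())))
        a = MkTraitModel(tree, values).fit(alpha=0.4).posteriors
        b = MkTraitModel(tree, shuffled).fit(alpha=0.4).posteriors
        pd.testing.assert_frame_equal(a, b)


class TestFit:
    def test_monomorphic_trait_is_degenerate(self):
        tree = hs.read_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        with pytest.raises(DegenerateTraitError):
            MkTraitModel(tree, {t: "x" for t in "ABCD"}, name="flat").fit()

    def test_mle_beats_grid(self):
        tree = hs.read_newick(FIVE_TAXON_NEWICK, rooted=True)
        model = MkTraitModel(tree, {"A": "x", "B": "x", "C": "y", "D": "y", "E": "x"})
        res = model.fit()
        for a in [0.01, 0.05, 0.2, 0.5, 1.0, 3.0, 10.0]:
            assert res.loglik_ >= model.loglik(a) - 1e-9

    def test_alpha_recovery_within_factor_two(self):
        def balanced(labels):
            if len(labels) == 1:
                return labels[0] + ":1"
            h = len(labels) // 2
            return f"({balanced(labels[:h])},{balanced(labels[h:])}):1"

        tree = hs.read_newick(balanced([f"t{i}" for i in range(64)]) + ";", rooted=True)
        base = MkTraitModel(tree, DiscreteTrait("sim", ["a", "b", "c"], {}))
        hits = 0
        for rep in range(20):
            trait = base.simulate_trait(alpha=0.2, seed=500 + rep)
            try:
                r = MkTraitModel(tree, trait).fit()
            except DegenerateTraitError:
                continue
            hits += 0.1 <= r.alpha_ <= 0.4
        assert hits >= 0.9 * 20


class TestCallChanges:
    def _fitted(self):
        tree = hs.read_newick(FIVE_TAXON_NEWICK, rooted=True)
        return MkTraitModel(
            tree, {"A": "x", "B": "x", "C": "x", "D": "y", "E": "y"}
        ).fit(alpha=0.02)

    def test_high_confidence_transition_called_once(self):
        res = self._fitted()
        cs = res.call_changes(threshold=0.85)
        # one regime shift: into the (D,E) clade, i.e. along the n2 -> n3 branch
        assert cs.changes == [("n2", "n3", "x", "y")]

    def test_exact_threshold_is_unassigned(self):
        res = self._fitted()
        node = res.posteriors.index[len(res.posteriors) // 2]
        doctored = res.posteriors.copy()
        doctored.loc[node] = [0.85, 0.15]
        res.posteriors = doctored
        cs = res.call_changes(threshold=0.85)
        assert cs.assigned[node] is None  # 0.85 is not > 0.85

    def test_no_changes_when_all_agree(self):
        tree = hs.read_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        trait = DiscreteTrait("t", ["x", "y"], {t: "x" for t in "ABCD"})
        res = MkTraitModel(tree, trait).fit(alpha=1e-6)
        cs = res.call_changes()
        assert cs.changes == []
        # every branch sits inside the single-state background partition
        n_branches = sum(1 for p in res.model._cache.parent if p is not None)
        assert len(cs.foreground["x"]) == n_branches
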