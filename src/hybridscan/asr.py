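"""Mk-model marginal ancestral-state reconstruction (re-rooting method).

Discrete ecological characters (e.g. diet, habitat, breeding mode, colour
dimorphism) evolve on the fixed reference topology under the k-state Mk
model: a single symmetric rate alpha, flat stationary distribution, and
transition probabilities

    P_ii(t) = 1/k + (k-1)/k * exp(-k alpha t)
    P_ij(t) = 1/k - 1/k   * exp(-k alpha t)   (i != j).

The rate is estimated by maximum likelihood (Felsenstein pruning); each
node's marginal posterior is the normalized product of the likelihoods of
the subtrees hanging off that node under a flat prior — exactly what one
gets by re-rooting the tree at the node and running the pruning algorithm,
computed here with a single up/down message pass (the model is reversible,
so the two are identical). Nodes whose maximum posterior exceeds a
confidence threshold (default 0.85, strict) are assigned a state; branches
whose two assigned endpoints differ are called character changes, and the
per-state branch sets are emitted as foreground/background partitions for
downstream rate analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import ConfigurationError, DegenerateTraitError


@dataclass
class DiscreteTrait:
    """A named discrete character: state alphabet plus taxon -> state map."""

    name: str
    states: list[str]
    values: dict[str, str | None]  # None / "" = unknown

    def __post_init__(self) -> None:
        bad = {
            v for v in self.values.values() if v not in (None, "") and v not in self.states
        }
        if bad:
            raise ConfigurationError(f"trait {self.name}: states {sorted(bad)} not in alphabet")

    @classmethod
    def from_mapping(cls, name: str, values: dict[str, str | None]) -> "DiscreteTrait":
        states = sorted({v for v in values.values() if v not in (None, "")})
        return cls(name, states, dict(values))

    def observed(self) -> dict[str, str]:
        return {t: v for t, v in self.values.items() if v not in (None, "")}


def mk_transition_matrix(k: int, alpha: float, t: float) -> np.ndarray:
    """Closed-form equal-rates Mk transition probability matrix."""
    e = np.exp(-k * alpha * t)
    off = (1.0 - e) / k
    P = np.full((k, k), off)
    np.fill_diagonal(P, off + e)
    return P


class _TreeCache:
    """Post-order node list, child links, branch lengths, stable node ids."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.ids: list[str] = []
        counter = 0
        for n in self.nodes:
            if n.is_leaf():
                self.ids.append(n.taxon.label)
            else:
                label = getattr(n, "label", None)
                if label:
                    self.ids.append(str(label))
                else:
                    self.ids.append(f"nd{counter}")
                    counter += 1
        self.children = [
            [self.index[id(c)] for c in n.child_nodes()] for n in self.nodes
        ]
        self.blen = [
            (n.edge.length if n.edge.length is not None else 0.0) for n in self.nodes
        ]
        self.root = len(self.nodes) - 1
        self.is_leaf = [not c for c in self.children]
        self.parent = [None] * len(self.nodes)
        for i, kids in enumerate(self.children):
            for c in kids:
                self.parent[c] = i


class MkTraitModel:
    """Equal-rates Mk model of one discrete trait on a fixed rooted tree.

    Unknown tip states are integrated over (partial likelihoods of ones), so
    the full tree shape is preserved in the branch-partition output.
    """

    def __init__(self, tree: dendropy.Tree, trait: DiscreteTrait | dict, name: str = "trait"):
        if isinstance(trait, dict):
            trait = DiscreteTrait.from_mapping(name, trait)
        self.tree = tree
        self.trait = trait
        self.states = list(trait.states)
        self.k = len(self.states)
        if self.k < 2:
            raise DegenerateTraitError(
                f"trait {trait.name!r} needs >= 2 states in its alphabet"
            )
        self._cache = _TreeCache(tree)
        observed = trait.observed()
        tip_labels = {
            self._cache.ids[i]
            for i in range(len(self._cache.nodes))
            if self._cache.is_leaf[i]
        }
        missing_on_tree = set(observed) - tip_labels
        if missing_on_tree:
            raise ConfigurationError(
                f"trait taxa not on tree: {sorted(missing_on_tree)[:5]}"
            )
        sidx = {s: i for i, s in enumerate(self.states)}
        self._tip_partials: dict[int, np.ndarray] = {}
        for i in range(len(self._cache.nodes)):
            if not self._cache.is_leaf[i]:
                continue
            label = self._cache.ids[i]
            state = observed.get(label)
            v = np.ones(self.k)
            if state is not None:
                v = np.zeros(self.k)
                v[sidx[state]] = 1.0
            self._tip_partials[i] = v

    # -- likelihood ---------------------------------------------------------

    def _down_partials(self, alpha: float):
        """Post-order conditional likelihoods L_v(s) with log scaling."""
        c = self._cache
        L = [None] * len(c.nodes)
        logscale = 0.0
        for i, _node in enumerate(c.nodes):
            if c.is_leaf[i]:
                L[i] = self._tip_partials[i]
                continue
            part = np.ones(self.k)
            for ci in c.children[i]:
                P = mk_transition_matrix(self.k, alpha, c.blen[ci])
                part = part * (P @ L[ci])
            mx = part.max()
            if mx > 0:
                part = part / mx
                logscale += np.log(mx)
            L[i] = part
        return L, logscale

    def loglik(self, alpha: float) -> float:
        """Pruning-algorithm log-likelihood under a flat root prior."""
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        L, logscale = self._down_partials(alpha)
        root_like = np.mean(L[self._cache.root])  # flat prior 1/k
        return float(np.log(root_like) + logscale)

    def fit(self, alpha: float | None = None, bounds=(1e-8, 1e3)) -> "MkTraitResults":
        """ML-fit the rate (or evaluate at a fixed alpha) and reconstruct.

        Raises ``DegenerateTraitError`` if fewer than two distinct states are
        observed at the tips (the rate is then unidentifiable).
        """
        n_obs = len({v for v in self.trait.observed().values()})
        converged = True
        if alpha is None:
            if n_obs < 2:
                raise DegenerateTraitError(
                    f"trait {self.trait.name!r} is monomorphic at the tips"
                )
            # optimize on the log scale: the bracket spans 11 decades and the
            # likelihood plateaus at both ends, which defeats plain Brent
            res = minimize_scalar(
                lambda u: -self.loglik(float(np.exp(u))),
                bounds=(np.log(bounds[0]), np.log(bounds[1])),
                method="bounded",
            )
            alpha = float(np.exp(res.x))
            converged = bool(res.success)
        ll = self.loglik(alpha)
        posteriors = self._marginal_posteriors(alpha)
        return MkTraitResults(
            model=self, alpha_=alpha, loglik_=ll, converged=converged,
            posteriors=posteriors,
        )

    # -- marginal reconstruction -------------------------------------------

    def _marginal_posteriors(self, alpha: float) -> pd.DataFrame:
        """Marginal posterior state distribution at every node.

        Up/down message passing equivalent to re-rooting the (reversible)
        model at each node: posterior_v(s) is proportional to U_v(s) L_v(s),
        where L is the below-likelihood and U the rest-of-tree likelihood
        with the flat prior folded in.
        """
        c = self._cache
        L, _ = self._down_partials(alpha)
        U = [None] * len(c.nodes)
        U[c.root] = np.full(self.k, 1.0 / self.k)
        post = np.empty((len(c.nodes), self.k))
        for i in reversed(range(len(c.nodes))):  # pre-order
            kids = c.children[i]
            if kids:
                msgs = []
                for ci in kids:
                    P = mk_transition_matrix(self.k, alpha, c.blen[ci])
                    msgs.append(P @ L[ci])
                for pos, ci in enumerate(kids):
                    s_excl = U[i].copy()
                    for other, m in enumerate(msgs):
                        if other != pos:
                            s_excl = s_excl * m
                    P = mk_transition_matrix(self.k, alpha, c.blen[ci])
                    u = P.T @ s_excl
                    mx = u.max()
                    U[ci] = u / mx if mx > 0 else u
            joint = U[i] * L[i]
            total = joint.sum()
            post[i] = joint / total if total > 0 else np.full(self.k, 1.0 / self.k)
        return pd.DataFrame(post, index=c.ids, columns=self.states)

    def simulate_trait(self, alpha: float, seed: int | None = None) -> DiscreteTrait:
        """Evolve the trait forward along the tree (for parameter recovery)."""
        rng = np.random.default_rng(seed)
        c = self._cache
        states = {}
        order = list(reversed(range(len(c.nodes))))
        node_state = {c.root: int(rng.integers(0, self.k))}
        for i in order:
            for ci in c.children[i]:
                P = mk_transition_matrix(self.k, alpha, c.blen[ci])
                node_state[ci] = int(rng.choice(self.k, p=P[node_state[i]]))
            if c.is_leaf[i]:
                states[c.ids[i]] = self.states[node_state[i]]
        return DiscreteTrait(self.trait.name, list(self.states), states)


@dataclass
class ChangeSet:
    """Thresholded reconstruction: node assignments, change branches, partitions."""

    assigned: dict[str, str | None]
    changes: list[tuple[str, str, str, str]]  # (parent, child, from, to)
    foreground: dict[str, list[tuple[str, str]]]  # state -> branches within it
    threshold: float


@dataclass
class MkTraitResults:
    """Fitted rate, log-likelihood, and per-node marginal posteriors."""

    model: MkTraitModel
    alpha_: float
    loglik_: float
    converged: bool
    posteriors: pd.DataFrame

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "trait": self.model.trait.name,
                "n_states": self.model.k,
                "alpha": self.alpha_,
                "loglik": self.loglik_,
                "converged": self.converged,
                "n_nodes": len(self.posteriors),
            }
        )

    def call_changes(self, threshold: float = 0.85) -> ChangeSet:
        """Assign states where max posterior strictly exceeds ``threshold``;
        branches whose two assigned endpoints differ are character changes.

        Also emits, per state, the branches lying wholly within that state's
        region — the foreground/background partitions consumed by
        branch-partitioned selection analyses.
        """
        c = self.model._cache
        maxp = self.posteriors.max(axis=1)
        argmax = self.posteriors.idxmax(axis=1)
        assigned = {
            node_id: (argmax[node_id] if maxp[node_id] > threshold else None)
            for node_id in self.posteriors.index
        }
        changes = []
        foreground: dict[str, list[tuple[str, str]]] = {s: [] for s in self.model.states}
        for i, parent in enumerate(c.parent):
            if parent is None:
                continue
            pid, cid = c.ids[parent], c.ids[i]
            ps, cs = assigned[pid], assigned[cid]
            if ps is not None and cs is not None:
                if ps != cs:
                    changes.append((pid, cid, ps, cs))
                else:
                    foreground[ps].append((pid, cid))
        return ChangeSet(assigned, changes, foreground, threshold)


# functional surface ---------------------------------------------------------


def mk_loglik(tree, trait, alpha: float) -> float:
    return MkTraitModel(tree, trait).loglik(alpha)


def fit_rate_ml(tree, trait) -> "MkTraitResults":
    return MkTraitModel(tree, trait).fit()


def marginal_posteriors(tree, trait, alpha: float) -> pd.DataFrame:
    return MkTraitModel(tree, trait).fit(alpha=alpha).posteriors


def read_trait_table(path, trait: str) -> dict[str, str | None]:
    """Extract one trait column from the tab-separated assignment table."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "individual" not in df.columns or trait not in df.columns:
        raise ConfigurationError(f"table must have 'individual' and {trait!r} columns")
    return {
        row["individual"]: (row[trait] or None) for _, row in df.iterrows()
    }
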