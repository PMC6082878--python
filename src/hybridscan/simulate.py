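"""Multispecies-coalescent simulator with tree-switch introgression.

The generator makes every downstream stage of the pipeline testable without
external data: gene trees are drawn under the multispecies coalescent (MSC)
on a species tree with branch lengths in coalescent units (2N generations),
sequences evolve along each gene tree under JC69, and a configurable fraction
of cells is masked as missing data.

Introgression follows a *tree-switch* model: an event (recipient, donor,
inheritance probability gamma, time) re-routes the entire recipient lineage
onto the donor branch at the event time for a gamma fraction of loci, after
which ordinary MSC coalescence runs within the modified species history.
This is the simplest generative model that produces the ABBA/BABA asymmetry
the D statistic detects, while incomplete lineage sorting alone leaves the
two discordant site patterns equally frequent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import dendropy
import yaml

from .alignments import LocusAlignment
from .errors import ModelValidationError
from .trees import read_newick

_ULTRAMETRIC_TOL = 1e-6


class _SNode:
    """Species-tree node with an absolute age (0 at the tips)."""

    __slots__ = ("name", "age", "children", "parent")

    def __init__(self, name=None, age=0.0):
        self.name = name
        self.age = age
        self.children: list[_SNode] = []
        self.parent: _SNode | None = None

    def add(self, child: "_SNode") -> None:
        child.parent = self
        self.children.append(child)

    def leaves(self):
        if not self.children:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


class GNode:
    """Gene-tree node; age in coalescent units, 0 at the tips."""

    __slots__ = ("name", "age", "children")

    def __init__(self, name=None, age=0.0, children=()):
        self.name = name
        self.age = age
        self.children = list(children)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class GeneTree:
    """A simulated coalescent gene tree with node ages."""

    root: GNode

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.walk() if not n.children]

    def pairwise_coalescent_times(self) -> dict[frozenset, float]:
        """Age of the MRCA for every leaf pair."""
        times: dict[frozenset, float] = {}

        def below(node: GNode) -> list[str]:
            if not node.children:
                return [node.name]
            sets = [below(c) for c in node.children]
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    for a in sets[i]:
                        for b in sets[j]:
                            times[frozenset((a, b))] = node.age
            return [x for s in sets for x in s]

        below(self.root)
        return times

    def topology_groups_first(self, trio: tuple[str, str, str]) -> tuple[str, str]:
        """The pair among ``trio`` that coalesces first (the gene-tree sisters)."""
        t = self.pairwise_coalescent_times()
        pairs = [(trio[0], trio[1]), (trio[0], trio[2]), (trio[1], trio[2])]
        return min(pairs, key=lambda p: t[frozenset(p)])

    def newick(self) -> str:
        def fmt(node: GNode, parent_age: float | None) -> str:
            if node.children:
                inner = ",".join(fmt(c, node.age) for c in node.children)
                core = f"({inner})"
            else:
                core = node.name
            if parent_age is None:
                return core
            return f"{core}:{parent_age - node.age:.10g}"

        return fmt(self.root, None) + ";"

    def to_dendropy(self) -> dendropy.Tree:
        return read_newick(self.newick(), rooted=True)


@dataclass(frozen=True)
class IntrogressionEvent:
    """Gene flow from ``donor`` into ``recipient`` at ``time`` with probability gamma.

    ``gamma`` is the inheritance probability: the fraction of loci whose
    recipient lineage follows the donor history instead of the species tree.
    ``time`` (coalescent units) must fall on the recipient's pendant branch
    and within the donor branch's span.
    """

    recipient: str
    donor: str
    gamma: float
    time: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ModelValidationError(f"gamma must be in [0,1], got {self.gamma}")
        if self.time <= 0:
            raise ModelValidationError("event time must be positive (older than tips)")


@dataclass
class SimConfig:
    """Simulation bookkeeping: locus count/length, mutation scale, missingness."""

    n_loci: int
    locus_length: int
    theta: float  # expected substitutions/site per coalescent unit
    missing_fraction: float = 0.051
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0 or self.locus_length <= 0:
            raise ModelValidationError("n_loci and locus_length must be positive")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ModelValidationError("missing_fraction must be in [0, 1)")
        if self.theta < 0:
            raise ModelValidationError("theta must be nonnegative")


class SpeciesTreeModel:
    """A rooted, ultrametric species tree in coalescent units, plus sampling.

    ``samples`` maps species label -> number of sampled haplotypes (default 1
    each). Multi-sample species get tip labels ``<species>_1 .. _n``.
    """

    def __init__(self, tree, samples: dict[str, int] | None = None):
        if isinstance(tree, str):
            tree = read_newick(tree, rooted=True)
        self.root = _from_dendropy(tree)
        self.species = [lf.name for lf in self.root.leaves()]
        if len(set(self.species)) != len(self.species):
            raise ModelValidationError("duplicate species labels")
        self.samples = {sp: 1 for sp in self.species}
        if samples:
            for sp, n in samples.items():
                if sp not in self.samples:
                    raise ModelValidationError(f"unknown species {sp!r}")
                if n < 1:
                    raise ModelValidationError("need >= 1 sample per species")
                self.samples[sp] = int(n)

    def tip_labels(self) -> list[str]:
        out = []
        for sp in self.species:
            n = self.samples[sp]
            out.extend([sp] if n == 1 else [f"{sp}_{i+1}" for i in range(n)])
        return out

    def validate_events(self, events) -> None:
        recipients = [e.recipient for e in events]
        if len(set(recipients)) != len(recipients):
            raise ModelValidationError("at most one introgression event per recipient")
        for e in events:
            _switched_history(self.root, e)  # raises on geometry problems


def _from_dendropy(tree: dendropy.Tree) -> _SNode:
    """Convert, computing absolute node ages; enforces ultrametricity."""

    def conv(dnode) -> tuple[_SNode, float]:
        if dnode.is_leaf():
            node = _SNode(name=dnode.taxon.label, age=0.0)
            return node, 0.0
        node = _SNode(name=getattr(dnode, "label", None))
        ages = []
        for child in dnode.child_nodes():
            cnode, _ = conv(child)
            bl = child.edge.length
            if bl is None:
                raise ModelValidationError("species tree needs branch lengths")
            if bl < 0:
                raise ModelValidationError("negative branch length")
            ages.append(cnode.age + bl)
            node.add(cnode)
        if max(ages) - min(ages) > _ULTRAMETRIC_TOL * max(1.0, max(ages)):
            raise ModelValidationError(
                f"species tree not ultrametric at node (child ages {ages})"
            )
        node.age = float(np.mean(ages))
        return node, node.age

    root, _ = conv(tree.seed_node)
    return root


def _clone(root: _SNode) -> _SNode:
    new = _SNode(root.name, root.age)
    for c in root.children:
        new.add(_clone(c))
    return new


def _find_leaf(root: _SNode, name: str) -> _SNode:
    for lf in root.leaves():
        if lf.name == name:
            return lf
    raise ModelValidationError(f"no species named {name!r}")


def _switched_history(root: _SNode, event: IntrogressionEvent) -> _SNode:
    """Species history with the recipient lineage re-attached to the donor branch."""
    root = _clone(root)
    rec = _find_leaf(root, event.recipient)
    if rec.parent is None or event.time >= rec.parent.age:
        raise ModelValidationError(
            f"event time {event.time} not on the pendant branch of {event.recipient!r}"
        )
    # detach recipient, splice out its (now unary) parent
    parent = rec.parent
    parent.children.remove(rec)
    rec.parent = None
    if len(parent.children) == 1:
        only = parent.children[0]
        if parent.parent is None:
            root = only
            only.parent = None
        else:
            gp = parent.parent
            gp.children[gp.children.index(parent)] = only
            only.parent = gp
    # locate the donor branch spanning the event time
    node = next(
        (n for n in root.walk() if n.name == event.donor and n is not rec), None
    )
    if node is None:
        raise ModelValidationError(f"no donor lineage named {event.donor!r}")
    while node.parent is not None and node.parent.age <= event.time:
        node = node.parent
    if node.age > event.time or (node.parent is None and node.age > event.time):
        raise ModelValidationError(
            f"donor branch of {event.donor!r} does not span time {event.time}"
        )
    if node.parent is None:
        # attach above the root
        new = _SNode(age=event.time if event.time > node.age else node.age)
        if event.time <= node.age:
            raise ModelValidationError("event time below donor root age")
        new.add(node)
        new.add(rec)
        return new
    gp = node.parent
    new = _SNode(age=event.time)
    gp.children[gp.children.index(node)] = new
    new.parent = gp
    new.add(node)
    new.add(rec)
    return root


def _sim_gene_tree(root: _SNode, samples: dict[str, int], rng) -> GNode:
    """One MSC draw: coalesce lineages within each species-tree branch."""

    def recurse(snode: _SNode) -> list[GNode]:
        if not snode.children:
            n = samples.get(snode.name, 1)
            names = [snode.name] if n == 1 else [f"{snode.name}_{i+1}" for i in range(n)]
            lineages = [GNode(name=nm, age=0.0) for nm in names]
        else:
            lineages = []
            for c in snode.children:
                lineages.extend(recurse(c))
        t = snode.age
        top = snode.parent.age if snode.parent is not None else np.inf
        k = len(lineages)
        while k > 1:
            t += rng.exponential(2.0 / (k * (k - 1)))
            if t >= top:
                break
            i, j = rng.choice(k, size=2, replace=False)
            if i > j:
                i, j = j, i
            merged = GNode(age=t, children=(lineages[i], lineages[j]))
            lineages[i] = merged
            lineages.pop(j)
            k -= 1
        return lineages

    out = recurse(root)
    assert len(out) == 1
    return out[0]


def _locus_rng(seed: int, locus_index: int):
    # counter-based per-locus streams: reproducible regardless of evaluation order
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, locus_index])


def simulate_gene_trees(
    model: SpeciesTreeModel,
    events: list[IntrogressionEvent],
    cfg: SimConfig,
) -> tuple[list[GeneTree], list[str]]:
    """Draw ``cfg.n_loci`` gene trees; each locus independently follows the
    introgressed history with probability gamma (tree-switch model).

    Returns the gene trees and per-locus history flags
    (``"species"`` / ``"introgressed"``), deterministic given ``cfg.seed``.
    """
    model.validate_events(events)
    # species histories for every subset of applied events (usually tiny)
    histories: dict[tuple[int, ...], _SNode] = {(): model.root}

    def history_for(applied: tuple[int, ...]) -> _SNode:
        if applied not in histories:
            root = model.root
            for idx in applied:
                root = _switched_history(root, events[idx])
            histories[applied] = root
        return histories[applied]

    trees, flags = [], []
    for i in range(cfg.n_loci):
        rng = _locus_rng(cfg.seed, i)
        applied = tuple(
            j for j, e in enumerate(events) if rng.random() < e.gamma
        )
        root = history_for(applied)
        g = _sim_gene_tree(root, model.samples, rng)
        trees.append(GeneTree(g))
        flags.append("introgressed" if applied else "species")
    return trees, flags


_DECODE_BYTES = b"ACGT"


def simulate_sequences(
    gene_tree: GeneTree,
    locus_length: int,
    theta: float,
    seed: int | None = None,
    rng=None,
    locus_id: str = "locus",
) -> LocusAlignment:
    """Evolve one alignment along a gene tree under JC69.

    Each site is independent; the root state is uniform over {A,C,G,T}; a
    branch carrying ``m = theta * length_in_coalescent_units`` expected
    substitutions/site changes each site with probability
    ``(3/4)(1 - exp(-4m/3))``, uniformly to one of the other three bases.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    root = gene_tree.root
    states = rng.integers(0, 4, locus_length, dtype=np.int8)
    leaves: dict[str, np.ndarray] = {}
    stack = [(root, states)]
    while stack:
        node, st = stack.pop()
        for child in node.children:
            m = theta * (node.age - child.age)
            p_change = 0.75 * (1.0 - np.exp(-4.0 * m / 3.0))
            cs = st.copy()
            if p_change > 0:
                mask = rng.random(locus_length) < p_change
                n = int(mask.sum())
                if n:
                    cs[mask] = (cs[mask] + rng.integers(1, 4, n, dtype=np.int8)) % 4
            if child.children:
                stack.append((child, cs))
            else:
                leaves[child.name] = cs
    taxa = sorted(leaves)
    lut = np.frombuffer(_DECODE_BYTES, dtype=np.uint8)
    seqs = [lut[leaves[t]].tobytes().decode("ascii") for t in taxa]
    return LocusAlignment(locus_id, taxa, seqs)


def inject_missing(
    aln: LocusAlignment, fraction: float, seed: int | None = None, rng=None
) -> LocusAlignment:
    """Mask exactly ``round(fraction * cells)`` uniformly chosen cells with '?'."""
    if not 0.0 <= fraction < 1.0:
        raise ModelValidationError("missing fraction must be in [0, 1)")
    if fraction == 0.0 or aln.n_taxa == 0 or aln.length == 0:
        return aln
    if rng is None:
        rng = np.random.default_rng(seed)
    mat = np.vstack(
        [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in aln.sequences]
    ).copy()
    n_cells = mat.size
    n_mask = int(round(fraction * n_cells))
    idx = rng.choice(n_cells, size=n_mask, replace=False)
    flat = mat.reshape(-1)
    flat[idx] = ord("?")
    seqs = [mat[i].tobytes().decode("ascii") for i in range(aln.n_taxa)]
    return LocusAlignment(aln.locus_id, list(aln.taxa), seqs)


@dataclass
class SimulatedDataset:
    """Gene trees + alignments + per-locus truth flags for one simulation."""

    gene_trees: list[GeneTree]
    alignments: list[LocusAlignment]
    flags: list[str] = field(default_factory=list)

    def truth_table(self) -> "object":
        import pandas as pd

        return pd.DataFrame(
            {
                "locus_id": [a.locus_id for a in self.alignments],
                "history": self.flags,
            }
        )


def simulate_dataset(
    model: SpeciesTreeModel,
    events: list[IntrogressionEvent],
    cfg: SimConfig,
) -> SimulatedDataset:
    """Full generator: gene trees, JC69 alignments, missing-data mask, flags."""
    model.validate_events(events)
    histories: dict[tuple[int, ...], _SNode] = {(): model.root}
    trees, alns, flags = [], [], []
    for i in range(cfg.n_loci):
        rng = _locus_rng(cfg.seed, i)
        applied = tuple(j for j, e in enumerate(events) if rng.random() < e.gamma)
        if applied not in histories:
            root = model.root
            for idx in applied:
                root = _switched_history(root, events[idx])
            histories[applied] = root
        g = _sim_gene_tree(histories[applied], model.samples, rng)
        gt = GeneTree(g)
        aln = simulate_sequences(
            gt, cfg.locus_length, cfg.theta, rng=rng, locus_id=f"locus{i:04d}"
        )
        aln = inject_missing(aln, cfg.missing_fraction, rng=rng)
        trees.append(gt)
        alns.append(aln)
        flags.append("introgressed" if applied else "species")
    return SimulatedDataset(trees, alns, flags)


def expected_site_patterns(
    model: SpeciesTreeModel,
    events: list[IntrogressionEvent],
    roles: tuple[str, str, str, str],
    n_loci: int = 20000,
    seed: int = 0,
) -> dict[str, float]:
    """Monte-Carlo oracle for P(ABBA) and P(BABA) under the model.

    Simulates gene trees (one sample per species) and drops a single mutation
    uniformly at random along the branches of each tree; the resulting
    biallelic site is classified with the outgroup allele as ancestral, so a
    mutation subtending {P2,P3} or {P1,O} is ABBA and {P1,P3} or {P2,O} is
    BABA. Returns estimates plus binomial standard errors.
    """
    if len(model.species) != 4 or any(v != 1 for v in model.samples.values()):
        raise ModelValidationError("site-pattern oracle needs 4 species, 1 sample each")
    p1, p2, p3, o = roles
    cfg = SimConfig(n_loci=n_loci, locus_length=1, theta=0.0, seed=seed)
    trees, _ = simulate_gene_trees(model, events, cfg)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 7_777])
    abba = baba = 0
    abba_sets = ({p2, p3}, {p1, o})
    baba_sets = ({p1, p3}, {p2, o})
    for gt in trees:
        edges = []  # (length, derived leaf set)
        def collect(node: GNode) -> set[str]:
            if not node.children:
                below = {node.name}
            else:
                below = set()
                for c in node.children:
                    sub = collect(c)
                    edges.append(((node.age - c.age), sub))
                    below |= sub
            return below

        collect(gt.root)
        lengths = np.array([e[0] for e in edges])
        total = lengths.sum()
        if total <= 0:
            continue
        k = rng.choice(len(edges), p=lengths / total)
        derived = edges[k][1]
        if derived in abba_sets:
            abba += 1
        elif derived in baba_sets:
            baba += 1
    n = len(trees)
    p_abba, p_baba = abba / n, baba / n
    return {
        "p_abba": p_abba,
        "p_baba": p_baba,
        "se_abba": float(np.sqrt(p_abba * (1 - p_abba) / n)),
        "se_baba": float(np.sqrt(p_baba * (1 - p_baba) / n)),
        "n": n,
    }


# ---------------------------------------------------------------------------
# plain-text model configuration


def read_sim_config(path) -> tuple[SpeciesTreeModel, list[IntrogressionEvent], SimConfig]:
    """Load a YAML simulation config (species tree, samples, events, locus specs)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    model = SpeciesTreeModel(doc["species_tree"], doc.get("samples"))
    events = [
        IntrogressionEvent(
            recipient=e["recipient"],
            donor=e["donor"],
            gamma=float(e["gamma"]),
            time=float(e["time"]),
        )
        for e in doc.get("events", [])
    ]
    cfg = SimConfig(
        n_loci=int(doc["n_loci"]),
        locus_length=int(doc["locus_length"]),
        theta=float(doc["theta"]),
        missing_fraction=float(doc.get("missing_fraction", 0.051)),
        seed=int(doc.get("seed", 0)),
    )
    return model, events, cfg
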