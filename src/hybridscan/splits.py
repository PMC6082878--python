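"""Locus-tree split support, conflict reports, and gene-jackknife recovery.

Instead of drawing split networks, conflict among locus trees is summarized
directly on bipartitions: count how many locus trees support each split
(restriction handles incomplete taxon sampling), filter weakly supported
splits (default: fewer than 50 supporting trees), and report well-supported
splits that are incompatible with the reference topology — these are the
candidate hybridization signals handed to the D-test harness. The two
published thresholds (>= 50 trees; >= 20% of trees) are kept.

Gene jackknifing measures how reference-tree support accumulates with data:
for each subset size, many random locus subsets are drawn, a tree is
inferred per subset with a pluggable estimator, and each reference split's
recovery frequency is recorded. The headline number is the percentage of
reference splits recovered in more than 75% of replicates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .alignments import LocusAlignment
from .errors import ConfigurationError, SaturatedDistanceError, TooFewTaxaError
from .trees import (
    Bipartition,
    are_compatible,
    bipartitions,
    leaf_labels,
    read_newick,
    tree_from_splits,
    tree_splits_cached,
)


@dataclass
class SplitSupportTable:
    """Bipartition -> supporting locus-tree count, with supporter IDs."""

    counts: dict[Bipartition, int]
    n_trees: int
    supporters: dict[Bipartition, list[int]] = field(default_factory=dict)
    taxa: frozenset[str] = frozenset()

    def fraction(self, split: Bipartition) -> float:
        return self.counts.get(split, 0) / self.n_trees


def _supports(tree_splits: set[Bipartition], tree_taxa: frozenset[str],
              candidate: Bipartition) -> bool:
    """Does a (possibly partially sampled) tree support a full-set split?

    The candidate is restricted to the tree's leaf set; support requires the
    restriction to stay nontrivial and to be one of the tree's own splits.
    """
    if tree_taxa >= candidate.taxa:
        restricted = candidate
    else:
        restricted = candidate.restrict(tree_taxa & candidate.taxa)
        if restricted is None:
            return False
    return restricted in tree_splits


def split_support(
    locus_trees: list[dendropy.Tree],
    taxa_of_interest,
    candidate_splits: set[Bipartition] | None = None,
) -> SplitSupportTable:
    """Count, per candidate split, the locus trees that display it.

    Candidates default to the union of splits of trees that sample the full
    taxon set (partially sampled trees then contribute support through the
    restriction rule, the role Z-closure plays for supernetworks). Supply
    ``candidate_splits`` explicitly to score a fixed split collection.
    """
    if not locus_trees:
        raise ConfigurationError("need at least one locus tree")
    full = frozenset(taxa_of_interest)
    per_tree: list[tuple[frozenset[str], set[Bipartition]]] = []
    for t in locus_trees:
        leaves = frozenset(leaf_labels(t)) & full
        if len(leaves) < 4:
            raise TooFewTaxaError("each locus tree needs >= 4 leaves of interest")
        splits = {
            r for s in tree_splits_cached(t)
            if (r := s.restrict(leaves)) is not None
        }
        per_tree.append((leaves, splits))
    if candidate_splits is None:
        candidate_splits = set()
        for leaves, splits in per_tree:
            if leaves == full:
                candidate_splits |= splits
    counts: dict[Bipartition, int] = {}
    supporters: dict[Bipartition, list[int]] = {}
    for cand in candidate_splits:
        ids = [
            i for i, (leaves, splits) in enumerate(per_tree)
            if _supports(splits, leaves, cand)
        ]
        if ids:
            counts[cand] = len(ids)
            supporters[cand] = ids
    return SplitSupportTable(counts, len(locus_trees), supporters, full)


def filter_splits(table: SplitSupportTable, min_count: int = 50) -> SplitSupportTable:
    """Drop splits supported by fewer than ``min_count`` locus trees."""
    if min_count < 0:
        raise ValueError("min_count must be nonnegative")
    keep = {s: c for s, c in table.counts.items() if c >= min_count}
    return SplitSupportTable(
        keep, table.n_trees,
        {s: table.supporters[s] for s in keep if s in table.supporters},
        table.taxa,
    )


@dataclass
class ConflictReport:
    """Well-supported splits that contradict the reference topology."""

    rows: pd.DataFrame  # split, count, fraction, conflicting reference splits
    min_fraction: float

    def top_splits(self) -> list[Bipartition]:
        return list(self.rows["split"])


def find_conflicts(
    table: SplitSupportTable,
    reference: dendropy.Tree,
    min_fraction: float = 0.20,
) -> ConflictReport:
    """Report splits with support fraction >= ``min_fraction`` that are
    incompatible with at least one reference split, sorted by support.

    These are the candidate reticulations: groupings many locus trees insist
    on that the species tree cannot display.
    """
    ref_splits = bipartitions(reference)
    records = []
    for split, count in table.counts.items():
        frac = count / table.n_trees
        if frac < min_fraction:
            continue
        conflicting = [r for r in ref_splits if not are_compatible(split, r)]
        if conflicting:
            records.append(
                {"split": split, "count": count, "fraction": frac,
                 "conflicts_with": conflicting}
            )
    rows = pd.DataFrame(records, columns=["split", "count", "fraction", "conflicts_with"])
    if len(rows):
        rows = rows.sort_values("count", ascending=False, ignore_index=True)
    return ConflictReport(rows, min_fraction)


# ---------------------------------------------------------------------------
# built-in desk-scale tree estimators


def jc_distance_matrix(loci: list[LocusAlignment]) -> tuple[np.ndarray, list[str]]:
    """Jukes-Cantor-corrected pairwise distances from concatenated loci.

    p-distances use only sites where both sequences carry a called base
    (A/C/G/T); d = -(3/4) ln(1 - (4/3) p). A pair at or beyond the JC
    ceiling (p >= 0.75) is a saturated-distance error.
    """
    taxa = sorted(set.intersection(*(set(a.taxa) for a in loci)))
    if len(taxa) < 4:
        raise TooFewTaxaError("need >= 4 taxa shared across loci")
    mats = [np.vstack([a.row(t) for t in taxa]) for a in loci]
    codes = np.concatenate(mats, axis=1)
    n = len(taxa)
    called = codes >= 0
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            m = int(both.sum())
            if m == 0:
                raise SaturatedDistanceError(
                    f"no comparable sites between {taxa[i]} and {taxa[j]}",
                    (taxa[i], taxa[j]),
                )
            p = float((codes[i, both] != codes[j, both]).mean())
            if p >= 0.75:
                raise SaturatedDistanceError(
                    f"p-distance {p:.3f} >= 0.75 between {taxa[i]} and {taxa[j]}",
                    (taxa[i], taxa[j]),
                )
            dist[i, j] = dist[j, i] = -0.75 * np.log(1.0 - (4.0 / 3.0) * p)
    return dist, taxa


def estimator_nj_concat(
    loci: list[LocusAlignment], locus_trees=None
) -> dendropy.Tree:
    """Neighbor joining on JC-corrected distances of the concatenated loci."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dist, taxa = jc_distance_matrix(loci)
    tree = nj(DistanceMatrix(dist, ids=taxa))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return read_newick(buf.getvalue())


def estimator_greedy_consensus(
    loci=None, locus_trees: list[dendropy.Tree] | None = None
) -> dendropy.Tree:
    """Greedy consensus of the locus trees: accept splits in descending
    frequency order whenever compatible with everything already accepted."""
    if not locus_trees:
        raise ConfigurationError("greedy consensus needs locus trees")
    taxa = set()
    counter: dict[Bipartition, int] = {}
    for t in locus_trees:
        taxa |= set(leaf_labels(t))
        for s in tree_splits_cached(t):
            counter[s] = counter.get(s, 0) + 1
    ordered = sorted(
        counter.items(),
        key=lambda kv: (-kv[1], tuple(sorted(kv[0].split))),
    )
    accepted: list[Bipartition] = []
    for split, _count in ordered:
        if all(are_compatible(split, a) for a in accepted):
            accepted.append(split)
    return tree_from_splits(accepted, taxa)


@dataclass
class JackknifeResult:
    """Per-size reference-split recovery frequencies and headline percents."""

    sizes: list[int]
    n_rep: int
    recovery: dict[int, dict[Bipartition, float]]  # size -> split -> frequency
    percent_high: dict[int, float]  # size -> % reference splits with freq > threshold
    support_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "percent_high_support": [self.percent_high[s] for s in self.sizes],
            }
        )


def jackknife_recovery(
    loci: list[LocusAlignment],
    locus_trees: list[dendropy.Tree] | None,
    reference: dendropy.Tree,
    sizes=(10, 100, 200, 300, 400, 500),
    n_rep: int = 100,
    estimator=estimator_nj_concat,
    support_threshold: float = 0.75,
    seed: int | None = None,
) -> JackknifeResult:
    """Gene jackknife: how reference-split recovery grows with locus count.

    For each size, ``n_rep`` locus subsets are drawn without replacement
    (independently across replicates); the ``estimator`` callable
    ``(alignments, locus_trees) -> Tree`` infers a tree per subset. Reports
    each reference split's recovery frequency and the percentage of splits
    with frequency strictly above ``support_threshold``.
    """
    n_loci = len(loci) if loci else len(locus_trees or [])
    if any(s > n_loci for s in sizes):
        raise ConfigurationError(f"jackknife size exceeds available loci ({n_loci})")
    ref_splits = bipartitions(reference)
    rng = np.random.default_rng(seed)
    recovery: dict[int, dict[Bipartition, float]] = {}
    percent_high: dict[int, float] = {}
    for size in sizes:
        hits = {s: 0 for s in ref_splits}
        for _ in range(n_rep):
            idx = rng.choice(n_loci, size=size, replace=False)
            sub_alns = [loci[i] for i in idx] if loci else None
            sub_trees = [locus_trees[i] for i in idx] if locus_trees else None
            est = estimator(sub_alns, sub_trees)
            est_splits = bipartitions(est)
            est_taxa = frozenset(leaf_labels(est))
            for s in ref_splits:
                r = s if s.taxa <= est_taxa else s.restrict(est_taxa)
                if r is not None and r in est_splits:
                    hits[s] += 1
        freqs = {s: h / n_rep for s, h in hits.items()}
        recovery[size] = freqs
        percent_high[size] = 100.0 * np.mean(
            [f > support_threshold for f in freqs.values()]
        )
    return JackknifeResult(list(sizes), n_rep, recovery, percent_high, support_threshold)
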