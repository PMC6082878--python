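"""Hypothesis-level D testing: individual permutations, FDR control, locus scans.

A hybridization hypothesis names four lineage groups (P1, P2, P3, outgroup).
:class:`PattersonDTest` evaluates Patterson's D on *every* individual
quadruple in the Cartesian product of the groups, producing a distribution
of D statistics whose consistency — not any single value — is the evidence
for gene flow. P-values are Benjamini-Hochberg adjusted within the
hypothesis, and "significant" means both Z > 3 and adjusted p < 0.05.

:func:`per_locus_scan` runs the pooled (allele-frequency) D separately per
locus to localize the introgression signal; loci with fewer than five
ABBA+BABA sites carry too little information and are flagged unusable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .alignments import LocusAlignment
from .dstat import (
    DResult,
    QuartetSelection,
    compute_d,
    compute_d_pooled,
    direction_call,
)
from .errors import ConfigurationError, NoInformativeSitesError
from .groups import GroupAssignment, HybridizationHypothesis


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Monotonicity is enforced and values are capped at 1; out-of-range inputs
    are a domain error.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _row_seeds(seed, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32)]


class PattersonDTest:
    """Model object for one hybridization hypothesis on a locus collection.

    Parameters
    ----------
    loci : list of LocusAlignment
    hypothesis : HybridizationHypothesis or GroupAssignment
    mode : "single" (one haplotype per role; every quartet in the product of
        the groups is tested) — the pooled form is exposed via
        :func:`per_locus_scan` and :func:`hybridscan.dstat.compute_d_pooled`.
    """

    def __init__(self, loci, hypothesis, mode: str = "single"):
        if isinstance(hypothesis, GroupAssignment):
            hypothesis = HybridizationHypothesis("hypothesis", hypothesis)
        self.loci = list(loci)
        self.hypothesis = hypothesis
        self.mode = mode

    def quartets(self) -> list[QuartetSelection]:
        g = self.hypothesis.groups
        product = itertools.product(
            sorted(g.p1), sorted(g.p2), sorted(g.p3), sorted(g.outgroup)
        )
        qs = [QuartetSelection(*labels) for labels in product]
        if not qs:
            raise ConfigurationError("empty quartet product")
        return qs

    def fit(
        self,
        n_boot: int = 100,
        seed: int | None = None,
        z_threshold: float = 3.0,
        p_threshold: float = 0.05,
        bootstrap: str = "locus",
    ) -> "PermutationResults":
        quartets = self.quartets()
        seeds = _row_seeds(seed, len(quartets))
        records = []
        for q, s in zip(quartets, seeds):
            rec = {"p1": q.p1, "p2": q.p2, "p3": q.p3, "o": q.o}
            try:
                r = compute_d(self.loci, q, n_boot=n_boot, seed=s, bootstrap=bootstrap)
                rec.update(
                    nabba=r.nabba, nbaba=r.nbaba, d=r.d, boot_sd=r.boot_sd,
                    z=r.z, p=r.p_two_sided, n_sites_used=r.n_sites_used, ok=True,
                )
                rec["_result"] = r
            except NoInformativeSitesError as err:
                rec.update(
                    nabba=0.0, nbaba=0.0, d=np.nan, boot_sd=np.nan, z=np.nan,
                    p=np.nan, n_sites_used=err.n_sites_used, ok=False, _result=None,
                )
            records.append(rec)
        frame = pd.DataFrame(records)
        results = frame.pop("_result")
        frame["p_adj"] = np.nan
        ok = frame["ok"].to_numpy()
        if ok.any():
            frame.loc[ok, "p_adj"] = bh_adjust(frame.loc[ok, "p"].to_numpy())
        frame["significant"] = (
            ok & (frame["z"].abs() > z_threshold) & (frame["p_adj"] < p_threshold)
        )
        frame["direction"] = [
            direction_call(r, adjusted_p=pa, z_threshold=z_threshold,
                           p_threshold=p_threshold)
            if r is not None else "none"
            for r, pa in zip(results, frame["p_adj"])
        ]
        return PermutationResults(
            model=self, frame=frame, n_boot=n_boot, seed=seed,
            z_threshold=z_threshold, p_threshold=p_threshold,
        )


@dataclass
class PermutationResults:
    """Distribution of per-quartet D results for one hypothesis."""

    model: PattersonDTest
    frame: pd.DataFrame
    n_boot: int
    seed: int | None
    z_threshold: float
    p_threshold: float

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def summary(self) -> pd.Series:
        ok = self.frame[self.frame["ok"]]
        d = ok["d"]
        frac_sig = float(self.frame["significant"].mean()) if len(self.frame) else np.nan
        signs = np.sign(d[d != 0])
        sign_consistency = (
            float(max((signs > 0).mean(), (signs < 0).mean())) if len(signs) else np.nan
        )
        return pd.Series(
            {
                "label": self.model.hypothesis.label,
                "n_quartets": self.n_rows,
                "n_failed": int((~self.frame["ok"]).sum()),
                "mean_d": float(d.mean()) if len(d) else np.nan,
                "median_d": float(d.median()) if len(d) else np.nan,
                "q25_d": float(d.quantile(0.25)) if len(d) else np.nan,
                "q75_d": float(d.quantile(0.75)) if len(d) else np.nan,
                "fraction_significant": frac_sig,
                "sign_consistency": sign_consistency,
            }
        )

    def consensus_direction(self) -> str:
        """Majority direction among significant rows ('none' if no majority)."""
        sig = self.frame[self.frame["significant"]]
        if sig.empty:
            return "none"
        counts = sig["direction"].value_counts()
        top = counts.idxmax()
        return top if counts[top] > len(sig) / 2 else "none"

    def plot_violin(self, path=None, ax=None):
        """Violin plot of the D distribution (presentational only)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        own = ax is None
        if own:
            _, ax = plt.subplots(figsize=(3, 4))
        d = self.frame.loc[self.frame["ok"], "d"].to_numpy()
        ax.violinplot([d], showmedians=True)
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_ylabel("Patterson's D")
        ax.set_xticks([1], [self.model.hypothesis.label])
        if path is not None and own:
            plt.savefig(path, bbox_inches="tight")
            plt.close()
        return ax


def run_permutation_tests(
    loci, hypothesis, n_boot: int = 100, seed: int | None = None, **kwargs
) -> PermutationResults:
    """Functional wrapper: fit a :class:`PattersonDTest` in one call."""
    return PattersonDTest(loci, hypothesis).fit(n_boot=n_boot, seed=seed, **kwargs)


def summarize_distribution(results: PermutationResults, plot_path=None) -> pd.Series:
    """Summary statistics of a permutation distribution; optional violin file."""
    if not results.frame["ok"].any():
        raise ConfigurationError("no evaluable quartet rows to summarize")
    if plot_path is not None:
        results.plot_violin(path=plot_path)
    return results.summary()


MIN_INFORMATIVE_SITES = 5  # ABBA+BABA threshold below which a locus is unusable


def per_locus_scan(
    loci: list[LocusAlignment],
    groups: GroupAssignment,
    n_boot: int = 100,
    seed: int | None = None,
    min_informative: int = MIN_INFORMATIVE_SITES,
) -> pd.DataFrame:
    """Pooled D per locus; rank usable loci by |D|.

    A locus is usable only with at least ``min_informative`` ABBA+BABA
    weighted sites; unusable loci are kept in the table (flagged) but
    excluded from the ranking.
    """
    seeds = _row_seeds(seed, len(loci))
    records = []
    for aln, s in zip(loci, seeds):
        rec = {"locus_id": aln.locus_id}
        try:
            # within one locus the resampling unit is the site
            r = compute_d_pooled([aln], groups, n_boot=n_boot, seed=s,
                                 bootstrap="site")
            rec.update(
                nabba=r.nabba, nbaba=r.nbaba, d=r.d, boot_sd=r.boot_sd, z=r.z,
                p=r.p_two_sided, n_sites_used=r.n_sites_used,
                usable=(r.nabba + r.nbaba) >= min_informative,
            )
        except NoInformativeSitesError as err:
            rec.update(
                nabba=0.0, nbaba=0.0, d=np.nan, boot_sd=np.nan, z=np.nan,
                p=np.nan, n_sites_used=err.n_sites_used, usable=False,
            )
        records.append(rec)
    frame = pd.DataFrame(records)
    frame["abs_d"] = frame["d"].abs()
    frame["rank"] = np.nan
    usable = frame["usable"]
    frame.loc[usable, "rank"] = (
        frame.loc[usable, "abs_d"].rank(ascending=False, method="first")
    )
    return frame.drop(columns="abs_d")
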