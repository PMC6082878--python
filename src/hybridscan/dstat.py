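"""Patterson's D (ABBA/BABA) with site-resampling bootstrap significance.

Given a quartet (P1, P2, P3, outgroup) on an asymmetric tree
(((P1,P2),P3),O), incomplete lineage sorting alone produces the two
discordant biallelic site patterns ABBA and BABA at equal expected
frequencies; gene flow between P3 and one of P1/P2 skews the balance.
Patterson's D = (nABBA - nBABA)/(nABBA + nBABA) measures that skew; its
significance is assessed with a bootstrap (Z = D / SD_boot). The default
resampling unit is the locus (block bootstrap): sites within a locus share
one gene tree, so their ABBA/BABA outcomes are correlated and a per-site
bootstrap understates the variance of D. Per-site resampling remains
available (``bootstrap="site"``) and is the right unit within a single
locus, where sites are conditionally independent given its gene tree.

Two forms are provided: the single-haplotype count form (one sequence per
role) and the pooled allele-frequency form of Durand et al., in which each
role is a set of taxa and sites contribute weights
ABBA = (1-p1) p2 p3 (1-p4), BABA = p1 (1-p2) p3 (1-p4) from derived-allele
frequencies. With singleton groups the two forms coincide exactly.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .alignments import LocusAlignment, encode_sequence
from .errors import DegenerateBootstrapWarning, NoInformativeSitesError
from .groups import GroupAssignment


class SitePattern(enum.Enum):
    ABBA = "ABBA"
    BABA = "BABA"
    OTHER = "OTHER"
    UNUSABLE = "UNUSABLE"


@dataclass(frozen=True)
class QuartetSelection:
    """One taxon per role; the unit of an individual-based permutation test."""

    p1: str
    p2: str
    p3: str
    o: str

    def __post_init__(self) -> None:
        labels = (self.p1, self.p2, self.p3, self.o)
        if len(set(labels)) != 4:
            raise ValueError(f"quartet labels must be distinct: {labels}")

    def labels(self) -> tuple[str, str, str, str]:
        return self.p1, self.p2, self.p3, self.o


def classify_site(p1: str, p2: str, p3: str, o: str) -> SitePattern:
    """Classify one site of a single-haplotype quartet.

    The outgroup allele is taken as ancestral (A); the site is informative
    only if it is biallelic with P3 carrying the derived allele (B). Then
    (P1,P2) = (A,B) is ABBA and (B,A) is BABA; (A,A)/(B,B) and any site with
    a gap, missing or ambiguous base, or more than two alleles, is not.
    """
    codes = [encode_sequence(c)[0] for c in (p1, p2, p3, o)]
    if any(c < 0 for c in codes):
        return SitePattern.UNUSABLE
    c1, c2, c3, co = codes
    if c3 == co:
        return SitePattern.OTHER
    if c1 == co and c2 == c3:
        return SitePattern.ABBA
    if c1 == c3 and c2 == co:
        return SitePattern.BABA
    return SitePattern.OTHER


def _classify_codes(c1, c2, c3, co):
    """Vectorized site classification on code arrays; returns masks."""
    usable = (c1 >= 0) & (c2 >= 0) & (c3 >= 0) & (co >= 0)
    informative = usable & (c3 != co)
    abba = informative & (c1 == co) & (c2 == c3)
    baba = informative & (c1 == c3) & (c2 == co)
    return abba, baba, usable


@dataclass
class DResult:
    """Counts, D, bootstrap SD, Z and two-sided normal p for one test."""

    nabba: float
    nbaba: float
    d: float
    boot_sd: float
    z: float
    p_two_sided: float
    n_boot: int
    n_sites_used: int
    seed: int | None
    mode: str = "single"
    n_loci_used: int = 0
    n_loci_skipped: int = 0

    def significant(self, z_threshold: float = 3.0, p_threshold: float = 0.05,
                    adjusted_p: float | None = None) -> bool:
        p = self.p_two_sided if adjusted_p is None else adjusted_p
        return abs(self.z) > z_threshold and p < p_threshold


def _finalize(a_w, b_w, locus_ids, n_boot, seed, mode, n_loci_used, n_loci_skipped,
              bootstrap="locus") -> DResult:
    n_sites = a_w.size
    nabba = float(a_w.sum())
    nbaba = float(b_w.sum())
    if nabba + nbaba == 0:
        raise NoInformativeSitesError(
            "no ABBA or BABA signal in the pooled sites", n_sites_used=n_sites
        )
    d = (nabba - nbaba) / (nabba + nbaba)
    rng = np.random.default_rng(seed)
    if bootstrap == "site":
        reps = _site_bootstrap(a_w, b_w, n_boot, rng)
    elif bootstrap == "locus":
        reps = _locus_bootstrap(a_w, b_w, locus_ids, n_boot, rng)
    else:
        raise ValueError("bootstrap must be 'site' or 'locus'")
    boot_sd = float(np.std(reps, ddof=1)) if reps.size > 1 else 0.0
    if boot_sd == 0.0:
        warnings.warn(
            "bootstrap SD is zero; Z reported as signed infinity",
            DegenerateBootstrapWarning,
            stacklevel=3,
        )
        z = float(np.sign(d) * np.inf) if d != 0 else 0.0
    else:
        z = d / boot_sd
    p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if z == 0.0 and boot_sd == 0.0:
        p = 1.0
    return DResult(
        nabba=nabba, nbaba=nbaba, d=d, boot_sd=boot_sd, z=z, p_two_sided=p,
        n_boot=n_boot, n_sites_used=n_sites, seed=seed, mode=mode,
        n_loci_used=n_loci_used, n_loci_skipped=n_loci_skipped,
    )


def _site_bootstrap(a_w, b_w, n_boot, rng) -> np.ndarray:
    """Resample usable sites with replacement; D per replicate.

    Replicates whose resample carries zero ABBA+BABA weight are dropped.
    """
    n = a_w.size
    reps = np.empty(n_boot)
    kept = 0
    # chunked to bound the index matrix at ~8M entries
    chunk = max(1, min(n_boot, int(8e6 // max(n, 1)) or 1))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        sa = a_w[idx].sum(axis=1)
        sb = b_w[idx].sum(axis=1)
        denom = sa + sb
        ok = denom > 0
        k = int(ok.sum())
        reps[kept : kept + k] = (sa[ok] - sb[ok]) / denom[ok]
        kept += k
        done += m
    return reps[:kept]


def _locus_bootstrap(a_w, b_w, locus_ids, n_boot, rng) -> np.ndarray:
    """Block bootstrap: resample whole loci with replacement."""
    uniq = np.unique(locus_ids)
    per_a = np.array([a_w[locus_ids == u].sum() for u in uniq])
    per_b = np.array([b_w[locus_ids == u].sum() for u in uniq])
    idx = rng.integers(0, uniq.size, size=(n_boot, uniq.size))
    sa = per_a[idx].sum(axis=1)
    sb = per_b[idx].sum(axis=1)
    denom = sa + sb
    ok = denom > 0
    return (sa[ok] - sb[ok]) / denom[ok]


def compute_d(
    loci: list[LocusAlignment],
    quartet: QuartetSelection,
    n_boot: int = 100,
    seed: int | None = None,
    bootstrap: str = "locus",
) -> DResult:
    """Patterson's D for one individual quartet, pooled over loci.

    Loci missing any of the four taxa are skipped (counted in
    ``n_loci_skipped``). Sites with a gap/missing/ambiguous base in any role
    are unusable; the rest form the pooled site vector that the bootstrap
    resamples. Deterministic given ``seed``.
    """
    a_parts, b_parts, lid_parts = [], [], []
    used = skipped = 0
    for li, aln in enumerate(loci):
        try:
            rows = [aln.row(t) for t in quartet.labels()]
        except ValueError:
            skipped += 1
            continue
        abba, baba, usable = _classify_codes(*rows)
        a_parts.append(abba[usable].astype(np.float64))
        b_parts.append(baba[usable].astype(np.float64))
        lid_parts.append(np.full(int(usable.sum()), li, dtype=np.int32))
        used += 1
    if not a_parts:
        raise NoInformativeSitesError("no locus contains all four taxa", 0)
    a_w = np.concatenate(a_parts)
    b_w = np.concatenate(b_parts)
    lids = np.concatenate(lid_parts)
    return _finalize(a_w, b_w, lids, n_boot, seed, "single", used, skipped, bootstrap)


def _pooled_locus_weights(aln: LocusAlignment, role_members: dict[str, list[str]]):
    """Per-site ABBA/BABA weights from derived-allele frequencies, one locus.

    Ancestral = the outgroup majority allele (ties make the site unusable);
    sites where any role has no called base are unusable; sites with more
    than one distinct derived allele get zero weight but stay usable.
    Returns (abba_w, baba_w, usable_mask).
    """
    L = aln.length
    counts = {}
    for role, members in role_members.items():
        rows = np.vstack([aln.row(t) for t in members])
        counts[role] = np.stack([(rows == b).sum(axis=0) for b in range(4)])
    called = {r: counts[r].sum(axis=0) for r in counts}
    oc = counts["O"]
    anc = oc.argmax(axis=0)
    tie = (oc == oc.max(axis=0)).sum(axis=0) > 1
    usable = ~tie
    for r in counts:
        usable &= called[r] > 0
    pres = np.zeros((4, L), dtype=bool)
    for r in counts:
        pres |= counts[r] > 0
    cols = np.arange(L)
    pres_derived = pres.copy()
    pres_derived[anc, cols] = False
    one_derived = pres_derived.sum(axis=0) == 1
    p = {}
    for r in counts:
        with np.errstate(divide="ignore", invalid="ignore"):
            p[r] = np.where(
                called[r] > 0, 1.0 - counts[r][anc, cols] / called[r], 0.0
            )
    abba = (1.0 - p["P1"]) * p["P2"] * p["P3"] * (1.0 - p["O"])
    baba = p["P1"] * (1.0 - p["P2"]) * p["P3"] * (1.0 - p["O"])
    informative = usable & one_derived
    abba = np.where(informative, abba, 0.0)
    baba = np.where(informative, baba, 0.0)
    return abba, baba, usable


def compute_d_pooled(
    loci: list[LocusAlignment],
    groups: GroupAssignment | dict[str, set[str]],
    n_boot: int = 100,
    seed: int | None = None,
    bootstrap: str = "locus",
) -> DResult:
    """Allele-frequency (pooled) Patterson's D over role taxon sets.

    Per site, with derived-allele frequencies p1..p4 in P1, P2, P3 and the
    outgroup (derived = allele other than the outgroup majority), weights are
    ABBA = (1-p1) p2 p3 (1-p4) and BABA = p1 (1-p2) p3 (1-p4); D is the
    normalized weight difference and the bootstrap resamples usable sites.
    With singleton role sets this reproduces :func:`compute_d` exactly.
    """
    roles = groups.roles if isinstance(groups, GroupAssignment) else groups
    a_parts, b_parts, lid_parts = [], [], []
    used = skipped = 0
    for li, aln in enumerate(loci):
        present = set(aln.taxa)
        members = {r: sorted(set(roles[r]) & present) for r in ("P1", "P2", "P3", "O")}
        if any(not m for m in members.values()):
            skipped += 1
            continue
        abba, baba, usable = _pooled_locus_weights(aln, members)
        a_parts.append(abba[usable])
        b_parts.append(baba[usable])
        lid_parts.append(np.full(int(usable.sum()), li, dtype=np.int32))
        used += 1
    if not a_parts:
        raise NoInformativeSitesError("no locus covers all four role sets", 0)
    a_w = np.concatenate(a_parts)
    b_w = np.concatenate(b_parts)
    lids = np.concatenate(lid_parts)
    return _finalize(a_w, b_w, lids, n_boot, seed, "pooled", used, skipped, bootstrap)


def direction_call(
    d: DResult,
    adjusted_p: float | None = None,
    z_threshold: float = 3.0,
    p_threshold: float = 0.05,
) -> str:
    """Interpret a significant D as a gene-flow direction.

    D > 0 (ABBA excess) implicates P2-P3 flow, D < 0 (BABA excess) P1-P3
    flow; anything non-significant (|Z| <= z_threshold or p >= p_threshold,
    using the BH-adjusted p when supplied) is 'none'.
    """
    if not d.significant(z_threshold, p_threshold, adjusted_p):
        return "none"
    if d.d > 0:
        return "P2-P3"
    if d.d < 0:
        return "P1-P3"
    return "none"
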