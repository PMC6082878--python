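import itertools

import numpy as np
import pytest

import hybridscan as hs
from hybridscan.dstat import SitePattern
from hybridscan.errors import DegenerateBootstrapWarning, NoInformativeSitesError

from conftest import make_alignment, random_toy_alignment

VALID = "ACGT"
NONCALLED = "-N?RYSWKMBDHV"


def oracle_classify(b1, b2, b3, bo):
    """Independent site-pattern rule: written from the ABBA/BABA definition."""
    bases = (b1, b2, b3, bo)
    if any(b.upper() not in VALID for b in bases):
        return "UNUSABLE"
    b1, b2, b3, bo = (b.upper() for b in bases)
    alleles = {b1, b2, b3, bo}
    if len(alleles) != 2:
        return "OTHER"
    anc = bo
    der = (alleles - {anc}).pop()
    if b3 != der:
        return "OTHER"
    if (b1, b2) == (anc, der):
        return "ABBA"
    if (b1, b2) == (der, anc):
        return "BABA"
    return "OTHER"


def oracle_counts(aln, quartet):
    rows = [aln.sequence(t) for t in quartet.labels()]
    nab = nba = usable = 0
    for site in zip(*rows):
        c = oracle_classify(*site)
        if c != "UNUSABLE":
            usable += 1
        nab += c == "ABBA"
        nba += c == "BABA"
    return nab, nba, usable


class TestClassifySite:
    def test_examples(self):
        assert hs.classify_site("A", "C", "C", "A") is SitePattern.ABBA
        assert hs.classify_site("C", "A", "C", "A") is SitePattern.BABA
        assert hs.classify_site("C", "C", "A", "A") is SitePattern.OTHER
        assert hs.classify_site("A", "C", "G", "A") is SitePattern.OTHER
        assert hs.classify_site("A", "-", "C", "A") is SitePattern.UNUSABLE
        assert hs.classify_site("A", "R", "C", "A") is SitePattern.UNUSABLE

    def test_full_enumeration_against_rule_table(self):
        chars = "ACGT-R?"
        for quad in itertools.product(chars, repeat=4):
            assert hs.classify_site(*quad).value == oracle_classify(*quad), quad


class TestComputeD:
    def _engineered(self):
        # 3 ABBA sites, 1 BABA site, 2 OTHER, 1 UNUSABLE
        rows = {
            "P1": "AAA" + "C" + "AA" + "A",
            "P2": "CCC" + "A" + "AC" + "C",
            "P3": "CCC" + "C" + "GC" + "C",
            "O":  "AAA" + "A" + "AC" + "-",
        }
        return make_alignment(rows)

    def test_arithmetic(self, quartet):
        r = hs.compute_d([self._engineered()], quartet, n_boot=50, seed=0)
        assert (r.nabba, r.nbaba) == (3.0, 1.0)
        assert r.d == pytest.approx(0.5)
        assert r.n_sites_used == 6

    def test_symmetric_counts_give_zero(self, quartet):
        rows = {"P1": "AC", "P2": "CA", "P3": "CC", "O": "AA"}
        r = hs.compute_d([make_alignment(rows)], quartet, n_boot=50, seed=0)
        assert r.d == 0.0

    def test_counts_match_bruteforce_oracle(self, quartet):
        rng = np.random.default_rng(123)
        for _ in range(50):
            aln = random_toy_alignment(rng)
            nab, nba, usable = oracle_counts(aln, quartet)
            if nab + nba == 0:
                with pytest.raises(NoInformativeSitesError):
                    hs.compute_d([aln], quartet, n_boot=10, seed=1)
                continue
            r = hs.compute_d([aln], quartet, n_boot=10, seed=1)
            assert (r.nabba, r.nbaba, r.n_sites_used) == (nab, nba, usable)

    def test_swapping_p1_p2_negates_d(self, quartet_model, quartet):
        ev = hs.IntrogressionEvent("P2", "P3", 0.5, 0.5)
        ds = hs.simulate_dataset(
            quartet_model, [ev], hs.SimConfig(50, 300, 0.0025, seed=6)
        )
        r = hs.compute_d(ds.alignments, quartet, seed=2)
        swapped = hs.QuartetSelection("P2", "P1", "P3", "O")
        r2 = hs.compute_d(ds.alignments, swapped, seed=2)
        assert r2.d == -r.d
        assert (r2.nabba, r2.nbaba) == (r.nbaba, r.nabba)

    def test_outgroup_swap_keeps_significant_sign(self, quartet):
        model = hs.SpeciesTreeModel(
            "(((P1:1,P2:1):1,P3:2):1,O:3);", samples={"O": 2}
        )
        ev = hs.IntrogressionEvent("P2", "P3", 0.5, 0.5)
        ds = hs.simulate_dataset(model, [ev], hs.SimConfig(200, 300, 0.0025, seed=7))
        signs = []
        for o in ("O_1", "O_2"):
            q = hs.QuartetSelection("P1", "P2", "P3", o)
            r = hs.compute_d(ds.alignments, q, seed=3)
            if abs(r.z) > 3:
                signs.append(np.sign(r.d))
        assert signs and len(set(signs)) == 1

    def test_no_informative_sites_error_carries_count(self, quartet):
        rows = {"P1": "AAAA", "P2": "AAAA", "P3": "AAAA", "O": "AAAA"}
        with pytest.raises(NoInformativeSitesError) as exc:
            hs.compute_d([make_alignment(rows)], quartet, seed=0)
        assert exc.value.n_sites_used == 4

    def test_degenerate_bootstrap_warns_and_reports_infinite_z(self, quartet):
        rows = {"P1": "A", "P2": "C", "P3": "C", "O": "A"}  # single ABBA site
        with pytest.warns(DegenerateBootstrapWarning):
            r = hs.compute_d([make_alignment(rows)], quartet, n_boot=20, seed=0)
        assert r.d == 1.0 and r.z == np.inf and r.p_two_sided == 0.0

    def test_locus_bootstrap_mode_runs(self, quartet, quartet_model):
        ds = hs.simulate_dataset(
            quartet_model, [], hs.SimConfig(40, 300, 0.0025, seed=8)
        )
        r = hs.compute_d(ds.alignments, quartet, seed=4, bootstrap="locus")
        assert -1 <= r.d <= 1 and r.boot_sd >= 0


class TestComputeDPooled:
    def test_singleton_groups_reduce_to_counts_exactly(
        self, quartet, singleton_groups
    ):
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(30):
            alns = [random_toy_alignment(rng) for _ in range(3)]
            try:
                r1 = hs.compute_d(alns, quartet, n_boot=40, seed=5)
            except NoInformativeSitesError:
                with pytest.raises(NoInformativeSitesError):
                    hs.compute_d_pooled(alns, singleton_groups, n_boot=40, seed=5)
                continue
            r2 = hs.compute_d_pooled(alns, singleton_groups, n_boot=40, seed=5)
            assert (r1.nabba, r1.nbaba) == (r2.nabba, r2.nbaba)
            assert r1.d == r2.d and r1.boot_sd == r2.boot_sd
            assert r1.z == r2.z and r1.p_two_sided == r2.p_two_sided
            assert r1.n_sites_used == r2.n_sites_used
            checked += 1
        assert checked >= 10

    def test_full_weight_abba_site(self):
        groups = hs.GroupAssignment(
            {"P1": {"a"}, "P2": {"b"}, "P3": {"c"}, "O": {"d"}}
        )
        rows = {"a": "AC", "b": "CA", "c": "CC", "d": "AA"}
        r = hs.compute_d_pooled([make_alignment(rows)], groups, n_boot=20, seed=0)
        assert (r.nabba, r.nbaba) == (1.0, 1.0)

    def test_half_frequency_weights(self):
        # p2 = p3 = 0.5, p1 = p4 = 0 at every site -> all weight ABBA, D = 1
        groups = hs.GroupAssignment(
            {"P1": {"a1", "a2"}, "P2": {"b1", "b2"}, "P3": {"c1", "c2"}, "O": {"d1", "d2"}}
        )
        rows = {
            "a1": "AA", "a2": "AA",
            "b1": "CC", "b2": "AA",
            "c1": "CC", "c2": "AA",
            "d1": "AA", "d2": "AA",
        }
        with pytest.warns(DegenerateBootstrapWarning):
            r = hs.compute_d_pooled([make_alignment(rows)], groups, n_boot=20, seed=0)
        assert r.d == 1.0
        assert r.nabba == pytest.approx(2 * (1.0 * 0.5 * 0.5 * 1.0))
        assert r.nbaba == 0.0

    def test_outgroup_tie_makes_site_unusable(self):
        groups = hs.GroupAssignment(
            {"P1": {"a"}, "P2": {"b"}, "P3": {"c"}, "O": {"d1", "d2"}}
        )
        rows = {"a": "A", "b": "C", "c": "C", "d1": "A", "d2": "C"}
        with pytest.raises(NoInformativeSitesError) as exc:
            hs.compute_d_pooled([make_alignment(rows)], groups, n_boot=10, seed=0)
        assert exc.value.n_sites_used == 0


class TestDirectionCall:
    def _result(self, d, z, p=1e-6):
        return hs.DResult(
            nabba=10, nbaba=1, d=d, boot_sd=0.1, z=z, p_two_sided=p,
            n_boot=100, n_sites_used=100, seed=0,
        )

    def test_significant_negative_d_is_p1_p3_flow(self):
        # a strongly negative D (BABA excess) reads as P1-P3 gene flow
        assert hs.direction_call(self._result(-0.74, -8.0)) == "P1-P3"

    def test_positive_but_weak_is_none(self):
        assert hs.direction_call(self._result(0.4, 1.0, p=0.3)) == "none"

    def test_zero_d_is_none(self):
        assert hs.direction_call(self._result(0.0, 0.0, p=1.0)) == "none"

    def test_adjusted_p_overrides_raw(self):
        r = self._result(0.5, 5.0, p=1e-6)
        assert hs.direction_call(r, adjusted_p=0.2) == "none"
        assert hs.direction_call(r, adjusted_p=0.01) == "P2-P3"
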