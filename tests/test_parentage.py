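"""Parentage LOD/Delta scoring, MHC trio logic, and case resolution."""

import itertools
import math

import numpy as np
import pytest

from captivekin.parentage import (
    delta_ranking,
    mhc_trio_check,
    parentage_lod,
    resolve_parentage_case,
    transition_prob,
)
from tests.conftest import freqs_from_arrays


@pytest.fixture(scope="module")
def freq_arrays():
    rng = np.random.default_rng(13)
    return [rng.dirichlet(np.ones(7)) for _ in range(14)]


def draw_geno(f, rng):
    a, b = rng.choice(len(f), size=2, p=f) + 1
    return (int(min(a, b)), int(max(a, b)))


def make_trio(freq_arrays, rng):
    """True dam, sire and their offspring over all loci."""
    dam, sire, off = {}, {}, {}
    for j, f in enumerate(freq_arrays):
        loc = f"L{j + 1:02d}"
        dam[loc] = draw_geno(f, rng)
        sire[loc] = draw_geno(f, rng)
        a = dam[loc][rng.integers(0, 2)]
        b = sire[loc][rng.integers(0, 2)]
        off[loc] = (min(a, b), max(a, b))
    return dam, sire, off


class TestTransitionProb:
    def test_untransmissible_allele(self):
        f = {1: 0.5, 2: 0.3, 3: 0.2}
        assert transition_prob((1, 1), (2, 3), None, f) == 0.0

    def test_all_homozygous(self):
        f = {1: 0.9, 2: 0.1}
        assert transition_prob((1, 1), (1, 1), (1, 1), f) == 1.0

    def test_single_parent_integrates_population(self):
        f = {1: 0.7, 2: 0.3}
        # parent gives allele 1 for sure; population supplies allele 2
        assert transition_prob((1, 2), (1, 1), None, f) == pytest.approx(0.3)

    @pytest.mark.parametrize("with_other", [True, False])
    def test_sums_to_one_over_offspring(self, with_other):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(4))
        f = {i + 1: float(x) for i, x in enumerate(p)}
        genos = [(i, j) for i in range(1, 5) for j in range(i, 5)]
        parent = (1, 3)
        other = (2, 2) if with_other else None
        total = sum(transition_prob(g, parent, other, f) for g in genos)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_unknown_allele_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            transition_prob((1, 9), (1, 1), None, {1: 1.0})


class TestLod:
    def test_true_parents_usually_positive(self, freq_arrays):
        rng = np.random.default_rng(17)
        freqs = freqs_from_arrays(freq_arrays)
        positive = 0
        n = 500
        for _ in range(n):
            dam, sire, off = make_trio(freq_arrays, rng)
            res = parentage_lod(off, dam, sire, freqs, epsilon=0.0)
            positive += res.lod > 0
        assert positive / n >= 0.95

    def test_unrelated_candidates_negative_on_average(self, freq_arrays):
        rng = np.random.default_rng(18)
        freqs = freqs_from_arrays(freq_arrays)
        lods = []
        for _ in range(500):
            dam, sire, off = make_trio(freq_arrays, rng)
            stranger = {
                loc: draw_geno(freq_arrays[j], rng)
                for j, loc in enumerate(dam)
            }
            res = parentage_lod(off, stranger, None, freqs, epsilon=0.01)
            if not math.isinf(res.lod):
                lods.append(res.lod)
        assert np.mean(lods) < 0

    def test_single_mismatch_excludes_at_zero_epsilon(self, freq_arrays):
        freqs = freqs_from_arrays(freq_arrays)
        off = {f"L{j + 1:02d}": (1, 1) for j in range(14)}
        cand = {f"L{j + 1:02d}": (1, 1) for j in range(14)}
        cand["L03"] = (2, 3)
        res = parentage_lod(off, cand, None, freqs, epsilon=0.0)
        assert res.lod == -math.inf
        assert res.mismatches == 1
        assert res.decision == "excluded"

    def test_epsilon_softens_exclusion_monotonically(self, freq_arrays):
        # increasing error tolerance never turns support into exclusion
        rng = np.random.default_rng(19)
        freqs = freqs_from_arrays(freq_arrays)
        dam, sire, off = make_trio(freq_arrays, rng)
        decisions = []
        for eps in (0.0, 0.01, 0.05, 0.1):
            decisions.append(parentage_lod(off, dam, sire, freqs, epsilon=eps).decision)
        if decisions[0] == "supported":
            assert "excluded" not in decisions[1:]

    def test_no_cotyped_loci_rejected(self, freq_arrays):
        freqs = freqs_from_arrays(freq_arrays)
        with pytest.raises(ValueError):
            parentage_lod({"L01": (1, 1)}, {"L02": (1, 1)}, None, freqs)


class TestDeltaRanking:
    def test_delta_is_lod_gap(self, freq_arrays):
        rng = np.random.default_rng(23)
        freqs = freqs_from_arrays(freq_arrays)
        dam, sire, off = make_trio(freq_arrays, rng)
        stranger = {
            loc: draw_geno(freq_arrays[j], rng) for j, loc in enumerate(dam)
        }
        ranked = delta_ranking(
            off, {"dam": dam, "stranger": stranger}, sire, freqs, epsilon=0.01
        )
        assert ranked[0].delta == pytest.approx(ranked[0].lod - ranked[1].lod)

    def test_identical_candidates_tie_ambiguous(self, freq_arrays):
        rng = np.random.default_rng(24)
        freqs = freqs_from_arrays(freq_arrays)
        dam, sire, off = make_trio(freq_arrays, rng)
        ranked = delta_ranking(
            off, {"twin1": dict(dam), "twin2": dict(dam)}, sire, freqs, epsilon=0.01
        )
        assert ranked[0].delta == 0.0
        assert ranked[0].decision == "ambiguous"

    def test_true_sire_beats_full_brother(self, freq_arrays):
        # the documented uncertain-paternity scenario: two full brothers
        rng = np.random.default_rng(25)
        freqs = freqs_from_arrays(freq_arrays)
        wins = 0
        n = 500
        for _ in range(n):
            gpa, gma, sire = make_trio(freq_arrays, rng)
            _, _, brother = make_trio(freq_arrays, rng)
            # regenerate brother from the same grandparents
            brother = {}
            for j, f in enumerate(freq_arrays):
                loc = f"L{j + 1:02d}"
                a = gpa[loc][rng.integers(0, 2)]
                b = gma[loc][rng.integers(0, 2)]
                brother[loc] = (min(a, b), max(a, b))
            dam = {
                loc: draw_geno(freq_arrays[j], rng) for j, loc in enumerate(sire)
            }
            off = {}
            for j, f in enumerate(freq_arrays):
                loc = f"L{j + 1:02d}"
                a = sire[loc][rng.integers(0, 2)]
                b = dam[loc][rng.integers(0, 2)]
                off[loc] = (min(a, b), max(a, b))
            ranked = delta_ranking(
                off, {"sire": sire, "brother": brother}, dam, freqs, epsilon=0.01
            )
            wins += ranked[0].candidate == "sire"
        assert wins / n >= 0.80

    def test_single_candidate_delta_none(self, freq_arrays):
        rng = np.random.default_rng(26)
        freqs = freqs_from_arrays(freq_arrays)
        dam, sire, off = make_trio(freq_arrays, rng)
        ranked = delta_ranking(off, {"dam": dam}, sire, freqs)
        assert ranked[0].delta is None


class TestMhcTrio:
    def test_impossible_combination(self):
        res = mhc_trio_check(("A3", "B6"), ("B6", "B6"), ("A2", "A4"))
        assert not res.consistent

    def test_unique_transmission_inferred(self):
        res = mhc_trio_check(("A3", "B6"), ("B6", "B7"), ("A3", "A4"))
        assert res.consistent
        assert res.transmitted == {"dam": "B6", "sire": "A3"}

    def test_unknown_parent_accepts_anything(self):
        res = mhc_trio_check(("B6", "B6"), ("B6", "A1"), None)
        assert res.consistent
        assert res.transmitted.get("dam") == "B6"

    def test_symmetric_under_role_swap(self):
        rng = np.random.default_rng(27)
        labels = [f"H{i}" for i in range(4)]
        for _ in range(50):
            off = tuple(rng.choice(labels, 2))
            dam = tuple(rng.choice(labels, 2))
            sire = tuple(rng.choice(labels, 2))
            assert (
                mhc_trio_check(off, dam, sire).consistent
                == mhc_trio_check(off, sire, dam).consistent
            )


class TestResolveCase:
    @pytest.fixture
    def scenario(self, freq_arrays):
        rng = np.random.default_rng(28)
        freqs = freqs_from_arrays(freq_arrays)
        dam, sire, off = make_trio(freq_arrays, rng)
        brother = {}
        for j, f in enumerate(freq_arrays):
            loc = f"L{j + 1:02d}"
            brother[loc] = draw_geno(f, rng)
        genos = {"kid": off, "dam": dam, "s1": sire, "s2": brother}
        return freqs, genos

    def test_mhc_veto_leaves_one_supported(self, freq_arrays):
        # both brothers genotypically identical -> microsatellites tie,
        # MHC excludes one
        rng = np.random.default_rng(29)
        freqs = freqs_from_arrays(freq_arrays)
        dam, sire, off = make_trio(freq_arrays, rng)
        genos = {"kid": off, "dam": dam, "s1": dict(sire), "s2": dict(sire)}
        mhc = {
            "kid": ("A3", "B6"),
            "dam": ("B6", "B6"),
            "s1": ("A3", "A4"),
            "s2": ("B7", "B7"),  # cannot supply A3
        }
        report = resolve_parentage_case(
            "kid", "sire", ["s1", "s2"], genos, freqs,
            other_parent_id="dam", mhc_pairs=mhc, epsilon=0.01,
        )
        assert report["decision"] == "supported"
        assert report["supported_candidate"] == "s1"

    def test_uninformative_mhc_tie_stays_ambiguous(self, freq_arrays):
        rng = np.random.default_rng(30)
        freqs = freqs_from_arrays(freq_arrays)
        dam, sire, off = make_trio(freq_arrays, rng)
        genos = {"kid": off, "dam": dam, "s1": dict(sire), "s2": dict(sire)}
        mhc = {"kid": ("B6", "B6"), "dam": ("B6", "B6"),
               "s1": ("B6", "B6"), "s2": ("B6", "B6")}
        report = resolve_parentage_case(
            "kid", "sire", ["s1", "s2"], genos, freqs,
            other_parent_id="dam", mhc_pairs=mhc, epsilon=0.01,
        )
        assert report["decision"] == "ambiguous"

    def test_all_excluded_means_unsampled_parent(self, freq_arrays):
        freqs = freqs_from_arrays(freq_arrays)
        off = {f"L{j + 1:02d}": (1, 1) for j in range(14)}
        bad1 = {f"L{j + 1:02d}": (2, 3) for j in range(14)}
        bad2 = {f"L{j + 1:02d}": (2, 2) for j in range(14)}
        genos = {"kid": off, "c1": bad1, "c2": bad2}
        report = resolve_parentage_case(
            "kid", "sire", ["c1", "c2"], genos, freqs, epsilon=0.0
        )
        assert report["decision"] == "true parent unsampled"

    def test_recorded_dam_outranked_by_true_dam(self, freq_arrays):
        # studbook-error pattern: true dam's full sister recorded instead
        rng = np.random.default_rng(31)
        freqs = freqs_from_arrays(freq_arrays)
        wins = 0
        n = 200
        for _ in range(n):
            gpa, gma, true_dam = make_trio(freq_arrays, rng)
            sister = {}
            for j, f in enumerate(freq_arrays):
                loc = f"L{j + 1:02d}"
                a = gpa[loc][rng.integers(0, 2)]
                b = gma[loc][rng.integers(0, 2)]
                sister[loc] = (min(a, b), max(a, b))
            sire = {loc: draw_geno(freq_arrays[j], rng) for j, loc in enumerate(true_dam)}
            off = {}
            for j, f in enumerate(freq_arrays):
                loc = f"L{j + 1:02d}"
                a = true_dam[loc][rng.integers(0, 2)]
                b = sire[loc][rng.integers(0, 2)]
                off[loc] = (min(a, b), max(a, b))
            genos = {"kid": off, "true": true_dam, "recorded": sister, "sire": sire}
            ranked = delta_ranking(
                off, {"true": true_dam, "recorded": sister}, sire, freqs, epsilon=0.01
            )
            wins += ranked[0].candidate == "true"
        assert wins / n >= 0.80
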