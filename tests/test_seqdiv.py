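"""Sequence diversity statistics, neutrality tests, phasing, and the MSN."""

import itertools
import math

import numpy as np
import pytest

from captivekin.io import IndividualRecord, SequencePanel, Sex
from captivekin.pedigree import build_pedigree
from captivekin.seqdiv import (
    build_msn,
    collapse_haplotypes,
    diversity_stats,
    fu_li_d_star,
    genotype_signature,
    pairwise_differences,
    phase_pairs,
    tajima_d,
    tn93_distance_matrix,
)

BASES = "ACGT"


def random_panel(rng, n_haps, length, n_inds, diploid=False):
    """Random aligned panel with random assignments."""
    seqs = {}
    base = rng.choice(list(BASES), size=length)
    for h in range(n_haps):
        s = base.copy()
        nmut = rng.integers(0, max(1, length // 4) + 1)
        for pos in rng.choice(length, size=nmut, replace=False):
            s[pos] = rng.choice([b for b in BASES if b != s[pos]])
        seqs[f"H{h}"] = "".join(s)
    labels = list(seqs)
    assignments = {}
    for i in range(n_inds):
        if diploid:
            assignments[f"i{i}"] = tuple(sorted(rng.choice(labels, size=2)))
        else:
            assignments[f"i{i}"] = str(rng.choice(labels))
    return SequencePanel(sequences=seqs, assignments=assignments)


def brute_force_stats(panel):
    """All-pairs oracle for k, pi, Hd on complete sites."""
    copies = panel.assigned_copies()
    seqs = [panel.sequences[c] for c in copies]
    keep = [
        i for i in range(len(seqs[0]))
        if all(s[i] in BASES for s in seqs)
    ]
    seqs = ["".join(s[i] for i in keep) for s in seqs]
    n = len(seqs)
    diffs = [
        sum(x != y for x, y in zip(a, b))
        for a, b in itertools.combinations(seqs, 2)
    ]
    k = sum(diffs) / len(diffs)
    pi = k / len(keep) if keep else 0.0
    counts = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    hsum = sum((c / n) ** 2 for c in counts.values())
    hd = 0.0 if len(counts) == 1 else n / (n - 1) * (1 - hsum)
    return k, pi, hd


class TestCollapse:
    def test_two_haplotype_frequencies(self):
        seqs = {"S2": "A" * 308, "Z1": "A" * 305 + "GGG"}
        assignments = {f"i{k}": ("S2" if k < 65 else "Z1") for k in range(109)}
        panel = SequencePanel(sequences=seqs, assignments=assignments)
        haps = collapse_haplotypes(panel)
        freq = dict(zip(haps.haplotype, haps.frequency))
        assert freq["S2"] == pytest.approx(0.596, abs=5e-4)
        assert freq["Z1"] == pytest.approx(0.404, abs=5e-4)

    def test_all_identical_collapse_to_one(self):
        panel = SequencePanel(
            sequences={"a": "ACGT", "b": "ACGT"},
            assignments={"i1": "a", "i2": "b", "i3": "a"},
        )
        haps = collapse_haplotypes(panel)
        assert len(haps) == 1 and haps.frequency.iloc[0] == 1.0

    def test_n_treated_as_wildcard(self):
        panel = SequencePanel(
            sequences={"a": "ACGT", "b": "ACNT"},
            assignments={"i1": "a", "i2": "b"},
        )
        assert len(collapse_haplotypes(panel)) == 1

    def test_empty_assignments_error(self):
        panel = SequencePanel(sequences={"a": "ACGT"})
        with pytest.raises(ValueError):
            collapse_haplotypes(panel)


class TestDiversityStats:
    def test_two_class_alignment_matches_formula(self):
        # 65 + 44 copies differing at 3 of 308 sites
        seqs = {"S2": "A" * 308, "Z1": "A" * 305 + "GGG"}
        assignments = {f"i{k}": ("S2" if k < 65 else "Z1") for k in range(109)}
        st = diversity_stats(SequencePanel(sequences=seqs, assignments=assignments))
        assert st.k == pytest.approx(8580 / 5886, abs=1e-9)
        assert st.Hd == pytest.approx(0.4859, abs=2e-4)
        assert st.S == 3 and st.n == 109 and st.L == 308

    def test_identical_sequences_zero_diversity(self):
        panel = SequencePanel(
            sequences={"a": "ACGTACGT"},
            assignments={f"i{k}": "a" for k in range(5)},
        )
        st = diversity_stats(panel)
        assert st.S == 0 and st.k == 0 and st.pi == 0 and st.Hd == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, n_haps=int(rng.integers(2, 5)), length=40,
                             n_inds=int(rng.integers(4, 30)))
        st = diversity_stats(panel)
        k, pi, hd = brute_force_stats(panel)
        assert st.k == pytest.approx(k, abs=1e-12)
        assert st.pi == pytest.approx(pi, abs=1e-12)
        assert st.Hd == pytest.approx(hd, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_jc_correction_inflates(self, seed):
        rng = np.random.default_rng(100 + seed)
        panel = random_panel(rng, n_haps=3, length=60, n_inds=10)
        st = diversity_stats(panel)
        if st.S >= 1:
            assert st.pi_jc > st.pi
        else:
            assert st.pi_jc == st.pi == 0.0

    def test_jc_undefined_at_saturation(self):
        panel = SequencePanel(
            sequences={"a": "AAAA", "b": "GGGG"},
            assignments={"i1": "a", "i2": "b"},
        )
        with pytest.raises(ValueError, match="Jukes-Cantor"):
            diversity_stats(panel)

    def test_ts_tv_partition(self):
        # A<->G transition at one site, A<->C transversion at another
        panel = SequencePanel(
            sequences={"a": "AAAA", "b": "GAAA", "c": "ACAA"},
            assignments={"i1": "a", "i2": "b", "i3": "c"},
        )
        st = diversity_stats(panel)
        assert (st.transitions, st.transversions) == (1, 1)
        assert st.transitions + st.transversions >= st.S


class TestNeutrality:
    def test_singleton_heavy_sample_gives_negative_d(self):
        # 6 sequences, every variant a singleton
        seqs = {
            "h0": "AAAAAA", "h1": "GAAAAA", "h2": "AGAAAA",
            "h3": "AAGAAA", "h4": "AAAGAA", "h5": "AAAAGA",
        }
        panel = SequencePanel(
            sequences=seqs, assignments={f"i{k}": f"h{k}" for k in range(6)}
        )
        st = diversity_stats(panel)
        D = tajima_d(st.n, st.S, st.k)
        Dstar = fu_li_d_star(6, 5, 5)
        assert D < 0
        assert Dstar < 0

    def test_balanced_two_class_gives_positive_d(self):
        seqs = {"a": "A" * 20, "b": "A" * 17 + "GGG"}
        panel = SequencePanel(
            sequences=seqs,
            assignments={f"i{k}": ("a" if k < 10 else "b") for k in range(20)},
        )
        st = diversity_stats(panel)
        assert tajima_d(st.n, st.S, st.k) > 0

    def test_undefined_without_segregation(self):
        with pytest.raises(ValueError):
            tajima_d(10, 0, 0.0)
        with pytest.raises(ValueError):
            fu_li_d_star(10, 0, 0)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_tajima_matches_tskit_oracle(self, seed):
        # independent implementation check on coalescent genotypes
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_mutations(
            msprime.sim_ancestry(
                samples=10, ploidy=1, population_size=1, random_seed=seed
            ),
            rate=2.0, random_seed=seed, discrete_genome=False,
        )
        if ts.num_sites == 0:
            pytest.skip("no mutations drawn")
        G = ts.genotype_matrix()  # sites x samples
        n = G.shape[1]
        # restrict to biallelic sites (the classical statistic's domain)
        bi = [i for i in range(G.shape[0]) if len(np.unique(G[i])) == 2]
        G = G[bi]
        S = G.shape[0]
        if S == 0:
            pytest.skip("no biallelic sites")
        derived = (G > 0).sum(axis=1)
        k = float((derived * (n - derived)).sum() / (n * (n - 1) / 2))
        assert tajima_d(n, S, k) == pytest.approx(float(ts.Tajimas_D()), abs=2e-2)


class TestNeutralCalibration:
    def test_fu_li_dstar_null_distribution(self):
        # a correctly standardized statistic has near-zero mean and
        # near-unit spread under neutrality; badly transcribed variance
        # constants would wreck both
        msprime = pytest.importorskip("msprime")
        from captivekin.seqdiv import fu_li_d_star

        vals = []
        for rep in range(400):
            ts = msprime.sim_mutations(
                msprime.sim_ancestry(
                    samples=20, ploidy=1, population_size=1,
                    random_seed=50_000 + rep,
                ),
                rate=2.5, random_seed=60_000 + rep, discrete_genome=False,
            )
            if ts.num_sites == 0:
                continue
            G = ts.genotype_matrix()
            n = G.shape[1]
            derived = (G > 0).sum(axis=1)
            eta_s = int(((derived == 1) | (derived == n - 1)).sum())
            vals.append(fu_li_d_star(n, G.shape[0], eta_s))
        assert abs(np.mean(vals)) <= 0.15
        assert 0.6 <= np.std(vals) <= 1.3

    def test_internal_coalescent_engine_matches_msprime(self):
        # the built-in genealogy simulator behind the significance flags
        # must agree with an independent coalescent engine
        msprime = pytest.importorskip("msprime")
        from captivekin.seqdiv import simulate_neutral_statistics, tajima_d

        internal = simulate_neutral_statistics(20, 15, 800, seed=3)["tajima_D"]
        external = []
        for rep in range(800):
            ts = msprime.sim_mutations(
                msprime.sim_ancestry(
                    samples=20, ploidy=1, population_size=1,
                    random_seed=70_000 + rep,
                ),
                rate=2.0, random_seed=80_000 + rep, discrete_genome=False,
            )
            if ts.num_sites == 0:
                continue
            G = ts.genotype_matrix()
            n = G.shape[1]
            derived = (G > 0).sum(axis=1)
            k = float((derived * (n - derived)).sum() / (n * (n - 1) / 2))
            external.append(tajima_d(n, G.shape[0], k))
        assert np.mean(internal) == pytest.approx(np.mean(external), abs=0.15)
        assert np.std(internal) == pytest.approx(np.std(external), abs=0.25)


class TestPhasing:
    @pytest.fixture
    def mhc_panel(self):
        seqs = {
            "A3": "AACC", "A4": "AATT", "B6": "GGCC", "B7": "GGTT",
        }
        return SequencePanel(sequences=seqs)

    def test_homozygote_probability_one(self, mhc_panel):
        sig = genotype_signature(mhc_panel, "B6", "B6")
        res = phase_pairs({"x": sig}, mhc_panel)
        assert res[0].pair == ("B6", "B6")
        assert res[0].probability == 1.0 and res[0].method == "homozygote"

    def test_ambiguous_pair_resolved_by_pedigree(self, mhc_panel):
        # {A3,B7} and {A4,B6} produce the same site-wise signature;
        # a B6/B6 dam forces the offspring pair to contain B6
        sig = genotype_signature(mhc_panel, "A3", "B7")
        assert sig == genotype_signature(mhc_panel, "A4", "B6")
        ped = build_pedigree(
            [
                IndividualRecord("dam", sex=Sex.FEMALE),
                IndividualRecord("sire", sex=Sex.MALE),
                IndividualRecord("kid", sire_id="sire", dam_id="dam"),
            ]
        )
        obs = {
            "dam": genotype_signature(mhc_panel, "B6", "B6"),
            "kid": sig,
        }
        res = {r.individual: r for r in phase_pairs(obs, mhc_panel, pedigree=ped)}
        assert res["kid"].pair == ("A4", "B6")
        assert res["kid"].method == "pedigree"

    def test_inconsistent_genotype_names_individual(self, mhc_panel):
        bad = tuple(frozenset("X") for _ in range(4))
        with pytest.raises(ValueError, match="bad_ind"):
            phase_pairs({"bad_ind": bad}, mhc_panel)

    def test_em_resolves_simulated_population(self):
        # ten haplotypes at realistic frequencies; most genotypes are
        # unambiguous, the EM must get >= 95% of resolved pairs right
        rng = np.random.default_rng(5)
        labels = [f"H{i}" for i in range(10)]
        freqs = np.array([0.03, 0.03, 0.16, 0.13, 0.07, 0.04, 0.015, 0.43, 0.05, 0.045])
        freqs = freqs / freqs.sum()
        L = 12
        seqs = {}
        for h in labels:
            seqs[h] = "".join(rng.choice(list(BASES), size=L))
        panel = SequencePanel(sequences=seqs)
        truth = {}
        obs = {}
        for i in range(100):
            a, b = rng.choice(10, size=2, p=freqs)
            pair = tuple(sorted((labels[a], labels[b])))
            truth[f"i{i}"] = pair
            obs[f"i{i}"] = genotype_signature(panel, *pair)
        res = phase_pairs(obs, panel)
        resolved = [r for r in res if r.resolved]
        correct = sum(1 for r in resolved if r.pair == truth[r.individual])
        assert len(resolved) >= 90
        assert correct / len(resolved) >= 0.95


class TestMsn:
    def test_forced_triangle(self):
        seqs = {"a": "AAAAA", "b": "GGAAA", "c": "GGGTT"}
        # distances: a-b 2, b-c 3, a-c 5
        panel = SequencePanel(sequences=seqs, assignments={"i": "a"})
        net = build_msn(panel)
        weights = sorted(w for _, _, w in net.edges)
        assert weights == [2, 3]
        assert net.total_weight == 5

    @pytest.mark.parametrize("seed", range(5))
    def test_weight_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(3, 8))
        panel = random_panel(rng, n_haps=n, length=30, n_inds=5)
        labels = sorted(panel.sequences)
        if len(labels) < 3:
            pytest.skip("degenerate draw")
        net = build_msn(panel)
        assert len(net.edges) == len(labels) - 1
        # brute force: minimum over all spanning trees
        dist = {
            (a, b): pairwise_differences(panel.sequences[a], panel.sequences[b])
            for a, b in itertools.combinations(labels, 2)
        }
        all_edges = list(dist)
        best = math.inf
        for subset in itertools.combinations(all_edges, len(labels) - 1):
            nodes = {labels[0]}
            edges = list(subset)
            grew = True
            while grew:
                grew = False
                for a, b in edges:
                    if (a in nodes) != (b in nodes):
                        nodes.update((a, b))
                        grew = True
            if len(nodes) == len(labels):
                best = min(best, sum(dist[e] for e in subset))
        assert net.total_weight == best

    def test_deterministic_tie_break(self):
        seqs = {"a": "AA", "b": "AG", "c": "GA"}
        panel = SequencePanel(sequences=seqs, assignments={"i": "a"})
        assert build_msn(panel).edges == build_msn(panel).edges

    def test_single_haplotype_rejected(self):
        panel = SequencePanel(sequences={"a": "ACGT"}, assignments={"i": "a"})
        with pytest.raises(ValueError):
            build_msn(panel)


class TestTn93:
    def test_symmetric_nonnegative(self):
        rng = np.random.default_rng(7)
        panel = random_panel(rng, n_haps=4, length=100, n_inds=4)
        mat = tn93_distance_matrix(panel)
        assert np.allclose(mat.values, mat.values.T)
        assert (mat.values >= 0).all()
        assert np.allclose(np.diag(mat.values), 0)
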