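"""Synthetic pedigreed genotype data with the structure the pipeline assumes.

Generates a multi-generation captive pedigree founded by unrelated
individuals, drops marker data through it (Mendelian transmission of
unlinked microsatellites, strictly maternal transmission of a
mitochondrial haplotype, biparental transmission of one MHC haplotype
pair), and optionally corrupts the result with per-allele genotyping
error, per-call missingness, and studbook recording errors (a dam
swapped with a full sister; a sire replaced by his brother or by an
unsampled male). Every generator is deterministic given its seed, and
every corruption is logged in a ledger sufficient to reconstruct the
truth.

The default profile mirrors a small managed carnivore population:
~110-130 individuals descending from 28 founders over two descendant
generations, 14 microsatellite loci with 4-14 alleles each, two
mitochondrial haplotypes near frequencies 0.6/0.4, and ten MHC
haplotypes with one dominant (~0.43) haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GenotypeTable, IndividualRecord, Sex
from .pedigree import Pedigree, build_pedigree

__all__ = [
    "SimConfig",
    "FounderPools",
    "SimTruth",
    "sim_founders",
    "sim_pedigree",
    "gene_drop",
    "inject_genotyping_noise",
    "inject_studbook_errors",
    "sim_wright_fisher",
    "simulate_dataset",
]

#: Default MHC founder-haplotype frequency profile: ten haplotypes in two
#: divergent lineages with one dominant haplotype, as typed in managed
#: painted-dog populations.
DEFAULT_MHC_FREQS = {
    "A1": 0.0288, "A2": 0.0337, "A3": 0.1587, "A4": 0.1298, "B2": 0.0673,
    "B4": 0.0433, "B5": 0.0144, "B6": 0.4279, "B7": 0.0529, "B11": 0.0433,
}

#: Default mitochondrial haplotype frequencies among founder matrilines.
DEFAULT_MT_FREQS = {"S2": 0.596, "Z1": 0.404}


@dataclass
class SimConfig:
    n_founders: int = 28
    n_generations: int = 2
    litter_mean: float = 3.0
    litter_dispersion: float | None = None  # None -> Poisson; else NB size
    n_loci: int = 14
    alleles_min: int = 4
    alleles_max: int = 14
    dirichlet_concentration: float = 1.0
    n_mt_haplotypes: int = 2
    n_mhc_haplotypes: int = 10
    error_rate: float = 0.0
    missing_rate: float = 0.0
    dam_swap_rate: float = 0.0
    sire_swap_rate: float = 0.0
    allow_inbreeding: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        for r in (self.error_rate, self.missing_rate, self.dam_swap_rate, self.sire_swap_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        for c in (self.n_founders, self.n_generations, self.n_loci,
                  self.n_mt_haplotypes, self.n_mhc_haplotypes):
            if c < 1:
                raise ValueError("counts must be positive")
        if self.alleles_min > self.alleles_max or self.alleles_min < 1:
            raise ValueError("invalid allele count range")


@dataclass
class FounderPools:
    locus_names: list[str]
    locus_freqs: list[np.ndarray]  # per locus, frequencies of alleles 1..A
    founder_genotypes: GenotypeTable
    mt_haplotypes: dict[str, str]  # founder id -> haplotype label
    mhc_pairs: dict[str, tuple[str, str]]
    mt_labels: list[str]
    mhc_labels: list[str]
    mhc_freqs: np.ndarray


@dataclass
class SimTruth:
    pedigree: Pedigree
    records: list[IndividualRecord]
    genotypes: GenotypeTable  # pre-error truth
    mt_haplotypes: dict[str, str]
    mhc_pairs: dict[str, tuple[str, str]]
    locus_freqs: list[np.ndarray]
    error_ledger: pd.DataFrame | None = None
    studbook_ledger: pd.DataFrame | None = None
    observed_genotypes: GenotypeTable | None = None
    observed_records: list[IndividualRecord] | None = None


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def _founder_records(config: SimConfig) -> list[IndividualRecord]:
    records = []
    for i in range(config.n_founders):
        sex = Sex.MALE if i % 2 == 0 else Sex.FEMALE
        records.append(IndividualRecord(id=f"F{i + 1:03d}", sex=sex, birth_year=2000))
    return records


def sim_founders(config: SimConfig, rng: np.random.Generator | None = None) -> FounderPools:
    """Draw marker pools and founder genotypes.

    Per-locus allele frequencies come from a symmetric Dirichlet;
    founder diploid genotypes are Hardy-Weinberg draws. Every founder
    carries a mitochondrial haplotype (only females transmit it) and an
    MHC haplotype pair drawn from the configured haplotype frequencies.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    locus_names = [f"L{j + 1:02d}" for j in range(config.n_loci)]
    locus_freqs = []
    for _ in locus_names:
        n_all = int(rng.integers(config.alleles_min, config.alleles_max + 1))
        f = rng.dirichlet(np.full(n_all, config.dirichlet_concentration))
        locus_freqs.append(f)
    records = _founder_records(config)
    ids = [r.id for r in records]
    calls = np.zeros((len(ids), config.n_loci, 2), dtype=np.int64)
    for j, f in enumerate(locus_freqs):
        calls[:, j, :] = rng.choice(len(f), size=(len(ids), 2), p=f) + 1
    table = GenotypeTable(ids, locus_names, calls)

    if config.n_mt_haplotypes == len(DEFAULT_MT_FREQS):
        mt_labels = list(DEFAULT_MT_FREQS)
        mt_p = np.array(list(DEFAULT_MT_FREQS.values()))
    else:
        mt_labels = [f"M{i + 1}" for i in range(config.n_mt_haplotypes)]
        mt_p = rng.dirichlet(np.full(config.n_mt_haplotypes, 5.0))
    mt_p = mt_p / mt_p.sum()
    mt = {i: mt_labels[k] for i, k in zip(ids, rng.choice(len(mt_labels), size=len(ids), p=mt_p))}

    if config.n_mhc_haplotypes == len(DEFAULT_MHC_FREQS):
        mhc_labels = list(DEFAULT_MHC_FREQS)
        mhc_p = np.array(list(DEFAULT_MHC_FREQS.values()))
    else:
        mhc_labels = [f"H{i + 1}" for i in range(config.n_mhc_haplotypes)]
        mhc_p = rng.dirichlet(np.full(config.n_mhc_haplotypes, 1.0))
    mhc_p = mhc_p / mhc_p.sum()
    draws = rng.choice(len(mhc_labels), size=(len(ids), 2), p=mhc_p)
    mhc = {
        i: tuple(sorted((mhc_labels[a], mhc_labels[b])))
        for i, (a, b) in zip(ids, draws)
    }
    return FounderPools(
        locus_names=locus_names,
        locus_freqs=locus_freqs,
        founder_genotypes=table,
        mt_haplotypes=mt,
        mhc_pairs=mhc,
        mt_labels=mt_labels,
        mhc_labels=mhc_labels,
        mhc_freqs=mhc_p,
    )


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def sim_pedigree(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[IndividualRecord]:
    """Simulate a monogamously pairing multi-generation pedigree.

    Each generation, unpaired adults are matched into monogamous pairs;
    unless ``allow_inbreeding`` is set, pairs with nonzero studbook
    kinship are refused (so no parent-offspring or sibling matings).
    Litter sizes are Poisson (or negative binomial when a dispersion is
    configured). A generation with no pairable candidates is truncated
    with a warning entry.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    records = _founder_records(config)
    current = list(records)
    year = 2001
    counter = 0
    for gen in range(config.n_generations):
        ped = build_pedigree(records)
        males = [r for r in current if r.sex == Sex.MALE]
        females = [r for r in current if r.sex == Sex.FEMALE]
        rng.shuffle(males)
        rng.shuffle(females)
        pairs = []
        used_m: set[str] = set()
        for f in females:
            for m in males:
                if m.id in used_m:
                    continue
                if not config.allow_inbreeding and ped.kinship(m.id, f.id) > 0:
                    continue
                pairs.append((m, f))
                used_m.add(m.id)
                break
        offspring: list[IndividualRecord] = []
        for sire, dam in pairs:
            if config.litter_dispersion is None:
                size = int(rng.poisson(config.litter_mean))
            else:
                k = config.litter_dispersion
                p = k / (k + config.litter_mean)
                size = int(rng.negative_binomial(k, p))
            for _ in range(size):
                counter += 1
                offspring.append(
                    IndividualRecord(
                        id=f"D{counter:04d}",
                        sire_id=sire.id,
                        dam_id=dam.id,
                        sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                        birth_year=year + gen,
                    )
                )
        if not offspring:
            break
        records.extend(offspring)
        current = offspring
    return records


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def gene_drop(
    records: list[IndividualRecord],
    pools: FounderPools,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SimTruth:
    """Drop founder marker data through the pedigree.

    Each offspring receives one uniformly chosen allele per parent per
    locus, its dam's mitochondrial haplotype, and one MHC haplotype
    from each parent. Parents absent from the founder pools (externals)
    get founder-style draws first.
    """
    rng = rng if rng is not None else np.random.default_rng(seed if seed is not None else 1)
    ped = build_pedigree(records)
    order = [i for i in _topological_ids(ped)]
    n_loci = len(pools.locus_names)
    geno: dict[str, np.ndarray] = {}
    mt: dict[str, str] = {}
    mhc: dict[str, tuple[str, str]] = {}
    founder_tab = pools.founder_genotypes
    for i in order:
        sire, dam = ped.parents(i)
        if sire is None and dam is None:
            if i in founder_tab._row:
                geno[i] = founder_tab.calls[founder_tab._row[i]].copy()
                mt[i] = pools.mt_haplotypes[i]
                mhc[i] = pools.mhc_pairs[i]
            else:
                # external founder-like individual: fresh population draws
                g = np.zeros((n_loci, 2), dtype=np.int64)
                for j, f in enumerate(pools.locus_freqs):
                    g[j] = rng.choice(len(f), size=2, p=f) + 1
                geno[i] = g
                mt[i] = pools.mt_labels[
                    rng.choice(len(pools.mt_labels))
                ]
                pair = rng.choice(len(pools.mhc_labels), size=2, p=pools.mhc_freqs)
                mhc[i] = tuple(sorted((pools.mhc_labels[pair[0]], pools.mhc_labels[pair[1]])))
        else:
            if sire is None or dam is None:
                raise ValueError(f"individual {i!r} has exactly one known parent")
            gs, gd = geno[sire], geno[dam]
            pick_s = rng.integers(0, 2, size=n_loci)
            pick_d = rng.integers(0, 2, size=n_loci)
            g = np.stack(
                [gs[np.arange(n_loci), pick_s], gd[np.arange(n_loci), pick_d]], axis=1
            )
            geno[i] = g
            mt[i] = mt[dam]
            mhc[i] = tuple(
                sorted((mhc[sire][rng.integers(0, 2)], mhc[dam][rng.integers(0, 2)]))
            )
    ids = [r.id for r in records]
    calls = np.stack([geno[i] for i in ids])
    table = GenotypeTable(ids, pools.locus_names, calls)
    return SimTruth(
        pedigree=ped,
        records=list(records),
        genotypes=table,
        mt_haplotypes={i: mt[i] for i in ids},
        mhc_pairs={i: mhc[i] for i in ids},
        locus_freqs=pools.locus_freqs,
    )


def _topological_ids(ped: Pedigree):
    import networkx as nx

    return nx.topological_sort(ped.graph)


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

def inject_genotyping_noise(
    table: GenotypeTable,
    error_rate: float,
    missing_rate: float,
    locus_freqs: list[np.ndarray],
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Apply per-allele error and per-call missingness; return a ledger.

    With probability ``error_rate`` each allele copy is replaced by a
    frequency-weighted draw from the locus allele pool; with
    probability ``missing_rate`` each call is erased. The ledger lists
    every alteration (individual, locus, kind, before, after).
    """
    if not (0.0 <= error_rate < 1.0 and 0.0 <= missing_rate <= 1.0):
        raise ValueError("rates out of range")
    rng = rng if rng is not None else np.random.default_rng(seed if seed is not None else 1)
    calls = table.calls.copy()
    entries = []
    n, L, _ = calls.shape
    err = rng.random((n, L, 2)) < error_rate
    for i, j, c in np.argwhere(err):
        if calls[i, j, 0] == 0:
            continue
        f = locus_freqs[j]
        old = int(calls[i, j, c])
        new = int(rng.choice(len(f), p=f)) + 1
        calls[i, j, c] = new
        entries.append(
            {
                "individual": table.ids[i], "locus": table.loci[j],
                "kind": "allele_error", "before": old, "after": new,
            }
        )
    miss = rng.random((n, L)) < missing_rate
    for i, j in np.argwhere(miss):
        if calls[i, j, 0] == 0:
            continue
        entries.append(
            {
                "individual": table.ids[i], "locus": table.loci[j],
                "kind": "missing", "before": f"{calls[i, j, 0]}/{calls[i, j, 1]}",
                "after": "0/0",
            }
        )
        calls[i, j] = 0
    ledger = pd.DataFrame(entries, columns=["individual", "locus", "kind", "before", "after"])
    return GenotypeTable(table.ids, table.loci, np.sort(calls, axis=2)), ledger


def inject_studbook_errors(
    records: list[IndividualRecord],
    dam_swap_rate: float = 0.0,
    sire_swap_rate: float = 0.0,
    unsampled_sire_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[list[IndividualRecord], pd.DataFrame]:
    """Corrupt recorded parentage; genotypes stay truthful.

    Error classes: the recorded dam replaced by one of her full
    sisters; the recorded sire replaced by one of his (full or half)
    brothers; the recorded sire replaced by an unsampled external male.
    Offspring with no eligible substitute are skipped (logged as such
    only when a swap was drawn).
    """
    rng = rng if rng is not None else np.random.default_rng(seed if seed is not None else 1)
    ped = build_pedigree(records)
    out = []
    entries = []
    ext_counter = 0
    for r in records:
        new = r
        if r.dam_id is not None and rng.random() < dam_swap_rate:
            sisters = [
                s for s in ped.siblings(r.dam_id, full=True)
                if ped.records[s].sex == Sex.FEMALE and s != r.sire_id
            ]
            if sisters:
                chosen = sisters[rng.integers(0, len(sisters))]
                entries.append(
                    {"individual": r.id, "kind": "dam_swap_full_sister",
                     "true": r.dam_id, "recorded": chosen}
                )
                new = replace(new, dam_id=chosen)
            else:
                entries.append(
                    {"individual": r.id, "kind": "dam_swap_skipped_no_sister",
                     "true": r.dam_id, "recorded": r.dam_id}
                )
        if r.sire_id is not None and rng.random() < sire_swap_rate:
            brothers = [
                s for s in ped.siblings(r.sire_id)
                if ped.records[s].sex == Sex.MALE and s != new.dam_id
            ]
            if brothers:
                chosen = brothers[rng.integers(0, len(brothers))]
                entries.append(
                    {"individual": r.id, "kind": "sire_swap_brother",
                     "true": r.sire_id, "recorded": chosen}
                )
                new = replace(new, sire_id=chosen)
            else:
                entries.append(
                    {"individual": r.id, "kind": "sire_swap_skipped_no_brother",
                     "true": r.sire_id, "recorded": r.sire_id}
                )
        elif r.sire_id is not None and rng.random() < unsampled_sire_rate:
            ext_counter += 1
            ext = f"X{ext_counter:03d}"
            entries.append(
                {"individual": r.id, "kind": "sire_unsampled",
                 "true": r.sire_id, "recorded": ext}
            )
            new = replace(new, sire_id=ext)
        out.append(new)
    ledger = pd.DataFrame(entries, columns=["individual", "kind", "true", "recorded"])
    return out, ledger


# ---------------------------------------------------------------------------
# Wright-Fisher sampler for Ne validation
# ---------------------------------------------------------------------------

def sim_wright_fisher(
    ne_true: int,
    sample_size: int,
    n_loci: int = 14,
    n_alleles: int = 8,
    n_generations: int = 20,
    mating: str = "random",
    seed: int = 1,
) -> GenotypeTable:
    """Discrete-generation constant-size population; final-generation sample.

    Random mating draws each offspring's parents independently (distinct
    individuals); monogamous mating pairs the population into Ne/2
    couples and draws each offspring's parents as one couple. Initial
    genotypes are uniform draws over ``n_alleles`` equifrequent alleles.
    Raises if every locus fixes (advises a larger allele count).
    """
    if ne_true < 2:
        raise ValueError("ne_true must be at least 2")
    if n_generations < 5:
        raise ValueError("need at least 5 generations")
    rng = np.random.default_rng(seed)
    N = ne_true
    geno = rng.integers(1, n_alleles + 1, size=(N, n_loci, 2))
    for _ in range(n_generations):
        if mating == "random":
            sires = rng.integers(0, N, size=N)
            dams = (sires + 1 + rng.integers(0, N - 1, size=N)) % N
        elif mating == "monogamous":
            perm = rng.permutation(N)
            n_pairs = N // 2
            couple = rng.integers(0, n_pairs, size=N)
            sires = perm[2 * couple]
            dams = perm[2 * couple + 1]
        else:
            raise ValueError("mating must be 'random' or 'monogamous'")
        pick_s = rng.integers(0, 2, size=(N, n_loci))
        pick_d = rng.integers(0, 2, size=(N, n_loci))
        rows = np.arange(n_loci)
        new = np.empty_like(geno)
        for i in range(N):
            new[i, :, 0] = geno[sires[i], rows, pick_s[i]]
            new[i, :, 1] = geno[dams[i], rows, pick_d[i]]
        geno = new
    poly = [(np.unique(geno[:, j, :]).size > 1) for j in range(n_loci)]
    if not any(poly):
        raise ValueError(
            "all loci fixed during the simulation; increase n_alleles or reduce generations"
        )
    take = rng.choice(N, size=min(sample_size, N), replace=False)
    ids = [f"S{i + 1:03d}" for i in range(len(take))]
    loci = [f"L{j + 1:02d}" for j in range(n_loci)]
    return GenotypeTable(ids, loci, np.sort(geno[take], axis=2))


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SimTruth:
    """Full generator: pedigree, gene drop, and configured corruption."""
    rng = np.random.default_rng(config.seed)
    pools = sim_founders(config, rng)
    records = sim_pedigree(config, rng)
    truth = gene_drop(records, pools, rng)
    observed_tab, err_ledger = inject_genotyping_noise(
        truth.genotypes, config.error_rate, config.missing_rate,
        pools.locus_freqs, rng,
    )
    observed_recs, sb_ledger = inject_studbook_errors(
        records, config.dam_swap_rate, config.sire_swap_rate, rng=rng
    )
    truth.error_ledger = err_ledger
    truth.studbook_ledger = sb_ledger
    truth.observed_genotypes = observed_tab
    truth.observed_records = observed_recs
    return truth
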