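"""Microsatellite (and MHC-as-one-locus) diversity statistics and tests.

Per-locus statistics: allele counts, rarefied allelic richness,
observed and unbiased expected heterozygosity, F_IS = 1 - H_O/H_E,
and the probabilities of identity for unrelated individuals and for
full siblings. Hardy-Weinberg and pairwise linkage-disequilibrium
departures are assessed by Monte-Carlo permutation; p-values use
(b + 1)/(m + 1) smoothing so they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import GenotypeTable

__all__ = [
    "AlleleFrequencies",
    "allele_frequencies",
    "unbiased_expected_heterozygosity",
    "allelic_richness",
    "locus_diversity",
    "probability_identity",
    "hwe_test",
    "ld_test",
    "burrows_delta",
]


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequency maps plus typed-gene-copy counts."""

    per_locus: dict[str, dict[int, float]]
    gene_copies: dict[str, int]

    def freqs(self, locus: str) -> dict[int, float]:
        return self.per_locus[locus]

    @property
    def loci(self) -> list[str]:
        return list(self.per_locus)


def allele_frequencies(table: GenotypeTable) -> AlleleFrequencies:
    """Relative allele frequencies per locus, from typed gene copies only."""
    per_locus: dict[str, dict[int, float]] = {}
    copies: dict[str, int] = {}
    for locus in table.loci:
        calls = table.locus_array(locus)
        alleles = calls[calls[:, 0] > 0].ravel()
        if alleles.size == 0:
            raise ValueError(f"locus {locus!r} has no typed individuals")
        vals, counts = np.unique(alleles, return_counts=True)
        n = alleles.size
        per_locus[locus] = {int(a): c / n for a, c in zip(vals, counts)}
        copies[locus] = int(n)
    return AlleleFrequencies(per_locus, copies)


def unbiased_expected_heterozygosity(freqs, n_individuals: int) -> float:
    """Nei's unbiased gene diversity (2n/(2n-1)) (1 - sum p_i^2)."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, dtype=float)
    two_n = 2 * n_individuals
    return two_n / (two_n - 1) * (1.0 - float((p**2).sum()))


def allelic_richness(allele_counts, g: int) -> float:
    """Rarefied allele count expected in a sample of ``g`` gene copies.

    R_S(g) = sum_a [1 - C(N - N_a, g) / C(N, g)] with N total typed
    copies and N_a copies of allele a (hypergeometric rarefaction).
    """
    counts = np.asarray(
        list(allele_counts.values()) if isinstance(allele_counts, dict) else allele_counts,
        dtype=np.int64,
    )
    N = int(counts.sum())
    if g > N:
        raise ValueError(f"rarefaction size {g} exceeds typed gene copies {N}")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = 0.0
    for Na in counts:
        if N - Na < g:
            out += 1.0
        else:
            out += 1.0 - float(np.exp(log_comb(N - Na, g) - log_comb(N, g)))
    return out


def locus_diversity(
    table: GenotypeTable, g: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-locus diversity statistics plus across-locus means +- SD.

    ``g`` is the rarefaction size in gene copies; by default twice the
    minimum number of typed individuals over loci (the FSTAT
    convention). F_IS is left NaN at monomorphic loci.
    """
    freqs = allele_frequencies(table)
    pid = probability_identity(freqs)
    min_typed = min(table.n_typed(loc) for loc in table.loci)
    if g is None:
        g = 2 * min_typed
    if g > 2 * min_typed:
        raise ValueError(
            f"rarefaction size {g} exceeds the minimum typed gene copies {2 * min_typed}"
        )
    rows = []
    for locus in table.loci:
        calls = table.locus_array(locus)
        typed = calls[calls[:, 0] > 0]
        n = typed.shape[0]
        het = float((typed[:, 0] != typed[:, 1]).mean())
        p = np.array(list(freqs.freqs(locus).values()))
        he = unbiased_expected_heterozygosity(p, n)
        counts = {a: round(f * freqs.gene_copies[locus]) for a, f in freqs.freqs(locus).items()}
        rs = allelic_richness(counts, g)
        fis = 1.0 - het / he if he > 0 else float("nan")
        rows.append(
            {
                "locus": locus,
                "n_typed": n,
                "N_A": len(p),
                "R_S": rs,
                "H_O": het,
                "H_E": he,
                "F_IS": fis,
                "P_ID": pid.loc[pid["locus"] == locus, "P_ID"].iloc[0],
                "P_ID_sib": pid.loc[pid["locus"] == locus, "P_ID_sib"].iloc[0],
            }
        )
    frame = pd.DataFrame(rows)
    summary = {
        "g": g,
        "means": {
            c: float(frame[c].mean()) for c in ("N_A", "R_S", "H_O", "H_E", "F_IS")
        },
        "sds": {
            c: float(frame[c].std(ddof=1)) for c in ("N_A", "R_S", "H_O", "H_E", "F_IS")
        },
        "P_ID_multilocus": float(frame["P_ID"].prod()),
        "P_ID_sib_multilocus": float(frame["P_ID_sib"].prod()),
    }
    return frame, summary


def probability_identity(freqs: AlleleFrequencies) -> pd.DataFrame:
    """Per-locus and cumulative P(ID) and P(ID)sib.

    P_ID = sum p_i^4 + sum_{i<j} (2 p_i p_j)^2;
    P_ID_sib = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4.
    Multilocus values are products over loci (independent loci).
    """
    rows = []
    for locus in freqs.loci:
        p = np.array(list(freqs.freqs(locus).values()))
        s2 = float((p**2).sum())
        s4 = float((p**4).sum())
        # sum_{i<j} (2 p_i p_j)^2 = 2 (s2^2 - s4)
        pid = s4 + 2.0 * (s2**2 - s4)
        pid_sib = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
        rows.append({"locus": locus, "P_ID": pid, "P_ID_sib": pid_sib})
    frame = pd.DataFrame(rows)
    frame["P_ID_cum"] = frame["P_ID"].cumprod()
    frame["P_ID_sib_cum"] = frame["P_ID_sib"].cumprod()
    return frame


@dataclass
class HweResult:
    locus: str
    n_typed: int
    observed_het: int
    p_het_excess: float | None
    p_het_deficit: float | None
    skipped: bool = False


def hwe_test(
    table: GenotypeTable, locus: str, n_reps: int = 10_000, seed: int = 1
) -> HweResult:
    """Monte-Carlo Hardy-Weinberg test at one locus.

    Alleles at the locus are pooled and re-paired at random among the
    typed individuals; the tail probabilities of the observed
    heterozygote count give one-sided p-values for heterozygote excess
    and deficit (the deficit tail is the homozygote-excess diagnostic).
    Monomorphic loci are skipped.
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be at least 1000")
    calls = table.locus_array(locus)
    typed = calls[calls[:, 0] > 0]
    alleles = typed.ravel()
    if np.unique(alleles).size < 2:
        return HweResult(locus, typed.shape[0], 0, None, None, skipped=True)
    obs_het = int((typed[:, 0] != typed[:, 1]).sum())
    rng = np.random.default_rng(seed)
    m = n_reps
    het_counts = np.empty(m, dtype=np.int64)
    batch = max(1, min(m, 2_000_000 // max(1, alleles.size)))
    done = 0
    while done < m:
        b = min(batch, m - done)
        tiled = np.tile(alleles, (b, 1))
        perm = rng.permuted(tiled, axis=1)
        het_counts[done:done + b] = (perm[:, 0::2] != perm[:, 1::2]).sum(axis=1)
        done += b
    p_excess = (1 + int((het_counts >= obs_het).sum())) / (m + 1)
    p_deficit = (1 + int((het_counts <= obs_het).sum())) / (m + 1)
    return HweResult(locus, typed.shape[0], obs_het, p_excess, p_deficit)


def burrows_delta(x_dose: np.ndarray, y_dose: np.ndarray) -> float:
    """Burrows composite disequilibrium for one allele pair.

    ``x_dose``/``y_dose`` are 0/1/2 allele-dose vectors over the same
    individuals. Delta = mean(X Y)/2 - 2 pA pB, which estimates the sum
    of gametic and non-gametic disequilibrium without assuming HWE.
    """
    x = np.asarray(x_dose, dtype=float)
    y = np.asarray(y_dose, dtype=float)
    pa = x.mean() / 2.0
    pb = y.mean() / 2.0
    return float((x * y).mean() / 2.0 - 2.0 * pa * pb)


def _dose_matrix(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(doses, alleles): doses is (typed_n, A) allele-dose matrix."""
    typed = calls[calls[:, 0] > 0]
    alleles = np.unique(typed)
    doses = (typed[:, :, None] == alleles[None, None, :]).sum(axis=1)
    return doses.astype(float), alleles


def _ld_statistic(xa: np.ndarray, yb: np.ndarray) -> float:
    """Sum of squared Burrows deltas over all allele pairs of two loci."""
    n = xa.shape[0]
    pa = xa.mean(axis=0) / 2.0
    pb = yb.mean(axis=0) / 2.0
    cross = (xa.T @ yb) / n / 2.0  # mean(X Y)/2 per allele pair
    delta = cross - 2.0 * np.outer(pa, pb)
    return float((delta**2).sum())


@dataclass
class LdResult:
    locus_a: str
    locus_b: str
    n: int
    statistic: float | None
    p_value: float | None
    skipped: bool = False


def ld_test(
    table: GenotypeTable,
    locus_a: str,
    locus_b: str,
    n_reps: int = 10_000,
    seed: int = 1,
) -> LdResult:
    """Monte-Carlo linkage-disequilibrium test for a locus pair.

    The statistic is the sum over allele pairs of squared Burrows
    composite disequilibria; the null distribution is built by
    permuting one locus's genotypes (both alleles together) across the
    co-typed individuals.
    """
    ca = table.locus_array(locus_a)
    cb = table.locus_array(locus_b)
    both = (ca[:, 0] > 0) & (cb[:, 0] > 0)
    ca, cb = ca[both], cb[both]
    if np.unique(ca).size < 2 or np.unique(cb).size < 2:
        return LdResult(locus_a, locus_b, int(both.sum()), None, None, skipped=True)
    xa, _ = _dose_matrix(ca)
    yb, _ = _dose_matrix(cb)
    obs = _ld_statistic(xa, yb)
    rng = np.random.default_rng(seed)
    n = xa.shape[0]
    count = 0
    for _ in range(n_reps):
        perm = rng.permutation(n)
        if _ld_statistic(xa, yb[perm]) >= obs:
            count += 1
    p = (count + 1) / (n_reps + 1)
    return LdResult(locus_a, locus_b, n, obs, p)


def ld_test_all_pairs(
    table: GenotypeTable, n_reps: int = 10_000, seed: int = 1
) -> pd.DataFrame:
    rows = []
    for i, (a, b) in enumerate(combinations(table.loci, 2)):
        res = ld_test(table, a, b, n_reps=n_reps, seed=seed + i)
        rows.append(
            {
                "locus_a": a,
                "locus_b": b,
                "n": res.n,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "skipped": res.skipped,
            }
        )
    return pd.DataFrame(rows)
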