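"""Single-sample effective population size from linkage disequilibrium.

In a closed population of effective size Ne, drift generates
association between physically unlinked loci; the squared correlation
of allele frequencies r^2, after subtracting the expectation due to the
finite sample (E(r^2_sample)), can be inverted for Ne. This module
implements the bias-corrected LD method: Burrows composite
disequilibrium per allele pair (no HWE assumption), exclusion of
alleles rarer than P_crit, the small-sample corrections, the random-
and monogamous-mating inversions, and a delete-one-individual jackknife
confidence interval.

Inversion formulas (r2' = mean r^2 - E(r^2_sample)):

    random:      Ne = (1/3 + sqrt(1/9 - 2.76 r2')) / (2 r2')
    monogamous:  Ne = (2/3 + sqrt(4/9 - 7.2  r2')) / (2 r2')

with E(r^2_sample) = 1/S + 3.19/S^2 for S >= 30 and
0.0018 + 0.907/S + 4.44/S^2 below; r2' <= 0 yields an infinite
estimate. The same sampling expectation is used for both mating
systems; the mating system enters through the inversion constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io import GenotypeTable

__all__ = [
    "NeEstimate",
    "burrows_r2",
    "expected_r2_sample",
    "ne_from_r2prime",
    "ne_point",
    "ne_jackknife_ci",
]


@dataclass
class NeEstimate:
    ne_point: float
    ci_low: float | None
    ci_high: float | None
    mating: str
    p_crit: float
    mean_r2: float
    expected_r2_sample: float
    n_comparisons: int
    harmonic_S: float


def _retained_alleles(calls: np.ndarray, p_crit: float) -> np.ndarray:
    typed = calls[calls[:, 0] > 0]
    alleles, counts = np.unique(typed, return_counts=True)
    freqs = counts / (2.0 * typed.shape[0])
    return alleles[freqs >= p_crit]


def burrows_r2(
    table: GenotypeTable,
    locus_a: str,
    locus_b: str,
    p_crit: float = 0.0,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Burrows-composite r^2 for every retained allele pair of two loci.

    Alleles with overall frequency below ``p_crit`` are dropped (allele
    frequencies for the threshold are taken over the full sample,
    before pairwise deletion). Individuals missing either locus are
    excluded pairwise. Returns (r^2 values, S individuals used); an
    empty array when fewer than two alleles survive at either locus.

    ``mask`` optionally restricts the individuals considered (used by
    the jackknife).
    """
    ca = table.locus_array(locus_a)
    cb = table.locus_array(locus_b)
    if mask is not None:
        ca, cb = ca[mask], cb[mask]
    keep_a = _retained_alleles(ca, p_crit)
    keep_b = _retained_alleles(cb, p_crit)
    if len(keep_a) < 2 or len(keep_b) < 2:
        return np.empty(0), 0
    both = (ca[:, 0] > 0) & (cb[:, 0] > 0)
    ca, cb = ca[both], cb[both]
    S = ca.shape[0]
    if S < 2:
        return np.empty(0), S
    xa = (ca[:, :, None] == keep_a[None, None, :]).sum(axis=1).astype(float)
    yb = (cb[:, :, None] == keep_b[None, None, :]).sum(axis=1).astype(float)
    pa = xa.mean(axis=0) / 2.0
    pb = yb.mean(axis=0) / 2.0
    cross = (xa.T @ yb) / S / 2.0
    # S/(S-1) is the standard finite-sample factor on the composite
    # covariance; the sampling-expectation calibration assumes it
    delta = (cross - 2.0 * np.outer(pa, pb)) * S / (S - 1.0)
    # composite-correlation denominator: p(1-p) + D with D the
    # within-locus Hardy-Weinberg departure (hom freq - p^2); equals
    # Var(dose)/2, so no HWE assumption enters the normalization
    da = (xa == 2).mean(axis=0) - pa**2
    db = (yb == 2).mean(axis=0) - pb**2
    denom = np.outer(pa * (1.0 - pa) + da, pb * (1.0 - pb) + db)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, delta**2 / denom, np.nan)
    # a squared correlation cannot exceed 1; the finite-sample factor
    # can push perfectly associated pairs slightly past it
    r2 = np.minimum(r2, 1.0)
    return r2[np.isfinite(r2)].ravel(), S


def expected_r2_sample(S: float) -> float:
    """Expected r^2 due to sampling S diploid individuals."""
    if S <= 0:
        raise ValueError("S must be positive")
    if S >= 30:
        return 1.0 / S + 3.19 / S**2
    return 0.0018 + 0.907 / S + 4.44 / S**2


def ne_from_r2prime(r2p: float, mating: str) -> float:
    """Invert the drift component of r^2 for Ne; r2' <= 0 -> infinity."""
    if r2p <= 0:
        return math.inf
    if mating == "random":
        disc = 1.0 / 9.0 - 2.76 * r2p
        num = 1.0 / 3.0
    elif mating == "monogamous":
        disc = 4.0 / 9.0 - 7.2 * r2p
        num = 2.0 / 3.0
    else:
        raise ValueError("mating must be 'random' or 'monogamous'")
    disc = max(disc, 0.0)
    return (num + math.sqrt(disc)) / (2.0 * r2p)


def _pooled_r2(
    table: GenotypeTable, p_crit: float, mask: np.ndarray | None = None
) -> tuple[float, float, int, float]:
    """(mean r2, E(r2 sample), comparisons, harmonic S) over locus pairs.

    Every allele-pair comparison within a locus pair carries equal
    weight, so locus pairs contribute proportionally to their number of
    comparisons; the harmonic mean S over locus pairs (weighted the
    same way) feeds the sampling correction.
    """
    total = 0.0
    n_comp = 0
    inv_s = 0.0
    for a, b in combinations(table.loci, 2):
        r2, S = burrows_r2(table, a, b, p_crit, mask=mask)
        if r2.size == 0:
            continue
        total += float(r2.sum())
        n_comp += r2.size
        inv_s += r2.size / S
    if n_comp == 0:
        raise ValueError("no usable locus pairs after allele exclusion")
    mean_r2 = total / n_comp
    harm_S = n_comp / inv_s
    return mean_r2, expected_r2_sample(harm_S), n_comp, harm_S


def ne_point(
    table: GenotypeTable,
    p_crit: float = 0.006,
    mating: str = "random",
) -> NeEstimate:
    """Point estimate of Ne from the pooled LD signal (no CI)."""
    mean_r2, exp_r2, n_comp, harm_S = _pooled_r2(table, p_crit)
    r2p = mean_r2 - exp_r2
    return NeEstimate(
        ne_point=ne_from_r2prime(r2p, mating),
        ci_low=None,
        ci_high=None,
        mating=mating,
        p_crit=p_crit,
        mean_r2=mean_r2,
        expected_r2_sample=exp_r2,
        n_comparisons=n_comp,
        harmonic_S=harm_S,
    )


def ne_jackknife_ci(
    table: GenotypeTable,
    p_crit: float = 0.006,
    mating: str = "random",
    alpha: float = 0.05,
) -> NeEstimate:
    """Ne with a delete-one-individual jackknife 95% confidence interval.

    The delete-one jackknife variance of the mean r^2 is converted into
    an effective chi-square degrees-of-freedom n' = 2 / CV^2; the
    chi-square interval for the mean r^2 is then shifted by the
    sampling expectation and pushed through the monotone r2' -> Ne
    inversion (which preserves interval ordering and produces the
    asymmetric intervals this estimator's skewed sampling distribution
    requires).
    """
    n = table.n_individuals
    if n < 10:
        raise ValueError("jackknife CI requires at least 10 individuals")
    est = ne_point(table, p_crit, mating)
    pseudo = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mean_r2, _, _, _ = _pooled_r2(table, p_crit, mask=mask)
        pseudo[i] = mean_r2
    theta_bar = pseudo.mean()
    var = (n - 1) / n * float(((pseudo - theta_bar) ** 2).sum())
    if var == 0.0:
        est.ci_low = est.ci_high = est.ne_point
        return est
    from scipy.stats import chi2

    n_eff = 2.0 * est.mean_r2**2 / var  # effective df from jackknife CV
    lo_r2 = n_eff * est.mean_r2 / chi2.ppf(1.0 - alpha / 2.0, n_eff)
    hi_r2 = n_eff * est.mean_r2 / chi2.ppf(alpha / 2.0, n_eff)
    # Ne decreases in r2': the upper r^2 bound gives the lower Ne bound
    est.ci_low = ne_from_r2prime(hi_r2 - est.expected_r2_sample, mating)
    est.ci_high = ne_from_r2prime(lo_r2 - est.expected_r2_sample, mating)
    return est
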