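"""Dyadic maximum-likelihood relatedness from unlinked codominant loci.

A dyad's genotype pair at one locus has probability

    P(g1, g2 | k) = k0 P0 + k1 P1 + k2 P2

where (k0, k1, k2) are the probabilities that the pair shares 0, 1 or 2
alleles identical by descent, P0 assumes independent Hardy-Weinberg
draws, P2 requires identical genotypes, and P1 conditions on the single
shared allele being drawn from the population frequencies with the
remaining alleles drawn independently. The relatedness coefficient is
r = k1/2 + k2. Estimation maximizes the summed log-likelihood over the
k-simplex by grid search with local refinement; relationship
classification evaluates the likelihood at the canonical coefficients
of unrelated, half-sib, full-sib and parent-offspring dyads.

Genotyping error is deliberately ignored here (it enters only the
parentage likelihoods), matching common relatedness-software defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .msatdiv import AlleleFrequencies

__all__ = [
    "CATEGORY_K",
    "IBDCoefficients",
    "RelatednessResult",
    "dyad_likelihood",
    "dyad_locus_probs",
    "estimate_r",
    "classify_relationship",
    "relationship_ci",
    "compare_categories",
]

#: Canonical IBD coefficients (k0, k1, k2) per relationship category,
#: ordered least related first (the tie-breaking order).
CATEGORY_K = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}
CATEGORIES = list(CATEGORY_K)


@dataclass(frozen=True)
class IBDCoefficients:
    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        for v in (self.k0, self.k1, self.k2):
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError("IBD coefficients must lie in [0, 1]")
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-9:
            raise ValueError("IBD coefficients must sum to 1")

    @property
    def r(self) -> float:
        return self.k1 / 2.0 + self.k2


@dataclass
class RelatednessResult:
    dyad: tuple[str, str]
    r_hat: float
    k_hat: IBDCoefficients
    best_category: str
    lnl: dict[str, float]
    ci_categories: frozenset | None = None
    n_loci: int = 0


# ---------------------------------------------------------------------------
# single-locus machinery
# ---------------------------------------------------------------------------

def _p_hw(g: tuple[int, int], freqs: dict[int, float]) -> float:
    a, b = g
    pa = freqs[a]
    if a == b:
        return pa * pa
    return 2.0 * pa * freqs[b]


def _p_given_ibd(g: tuple[int, int], x: int, freqs: dict[int, float]) -> float:
    """P(unordered genotype g | one allele is the IBD copy x)."""
    a, b = g
    if a == b:
        return freqs[a] if x == a else 0.0
    if x == a:
        return freqs[b]
    if x == b:
        return freqs[a]
    return 0.0


def dyad_locus_probs(
    g1: tuple[int, int], g2: tuple[int, int], freqs: dict[int, float]
) -> tuple[float, float, float]:
    """(P0, P1, P2): genotype-pair probabilities under 0/1/2 shared IBD alleles."""
    for g in (g1, g2):
        for a in g:
            if a not in freqs:
                raise ValueError(f"allele {a} absent from frequency table")
    p0 = _p_hw(g1, freqs) * _p_hw(g2, freqs)
    shared = set(g1) & set(g2)
    p1 = sum(
        freqs[x] * _p_given_ibd(g1, x, freqs) * _p_given_ibd(g2, x, freqs)
        for x in shared
    )
    p2 = _p_hw(g1, freqs) if tuple(sorted(g1)) == tuple(sorted(g2)) else 0.0
    return p0, p1, p2


def dyad_likelihood(
    g1: tuple[int, int],
    g2: tuple[int, int],
    k: IBDCoefficients | tuple[float, float, float],
    freqs: dict[int, float],
) -> float:
    """P(g1, g2 | k) at one locus."""
    if isinstance(k, IBDCoefficients):
        k = (k.k0, k.k1, k.k2)
    p0, p1, p2 = dyad_locus_probs(g1, g2, freqs)
    return k[0] * p0 + k[1] * p1 + k[2] * p2


def _locus_prob_matrix(
    genos1: dict[str, tuple[int, int]],
    genos2: dict[str, tuple[int, int]],
    freqs: AlleleFrequencies,
) -> np.ndarray:
    """(L, 3) matrix of (P0, P1, P2) over co-typed loci."""
    shared_loci = [l for l in genos1 if l in genos2 and l in freqs.per_locus]
    if not shared_loci:
        raise ValueError("dyad has no co-typed loci")
    return np.array(
        [dyad_locus_probs(genos1[l], genos2[l], freqs.freqs(l)) for l in shared_loci]
    )


@lru_cache(maxsize=8)
def _simplex_grid(step_inv: int) -> np.ndarray:
    """All (k0, k1, k2) on the simplex at resolution 1/step_inv."""
    pts = []
    for i in range(step_inv + 1):
        for j in range(step_inv + 1 - i):
            pts.append((i, j, step_inv - i - j))
    return np.array(pts, dtype=float) / step_inv


def _grid_lnl(P: np.ndarray, grid: np.ndarray) -> np.ndarray:
    like = grid @ P.T  # (G, L)
    with np.errstate(divide="ignore"):
        return np.log(like).sum(axis=1)


def _feasible(k: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Mask of k-points satisfying the genetic constraint k1^2 >= 4 k0 k2."""
    return k[:, 1] ** 2 >= 4.0 * k[:, 0] * k[:, 2] - tol


def estimate_r(
    genos1: dict[str, tuple[int, int]],
    genos2: dict[str, tuple[int, int]],
    freqs: AlleleFrequencies,
    grid_step: float = 0.01,
    feasible_only: bool = True,
) -> tuple[float, IBDCoefficients]:
    """Maximum-likelihood (r_hat, k_hat) for a dyad.

    Grid search over the k-simplex at ``grid_step`` resolution followed
    by a local refinement pass at one tenth of the step. Loci untyped
    in either member are skipped. By default the search is restricted
    to the genetically feasible region k1^2 >= 4 k0 k2 (all canonical
    relationships lie inside it); the spurious infeasible maxima that
    the unrestricted simplex admits inflate r_hat for unrelated pairs.
    Set ``feasible_only=False`` for the unrestricted estimator.
    """
    P = _locus_prob_matrix(genos1, genos2, freqs)
    step_inv = round(1.0 / grid_step)
    grid = _simplex_grid(step_inv)
    if feasible_only:
        grid = grid[_feasible(grid)]
    lnl = _grid_lnl(P, grid)
    best = grid[int(np.argmax(lnl))]
    # local refinement on a finer lattice around the winner
    fine = grid_step / 10.0
    offsets = np.arange(-10, 11) * fine
    cand = []
    for d0 in offsets:
        for d2 in offsets:
            k0 = best[0] + d0
            k2 = best[2] + d2
            k1 = 1.0 - k0 - k2
            if k0 >= -1e-12 and k2 >= -1e-12 and k1 >= -1e-12:
                cand.append((max(k0, 0.0), max(k1, 0.0), max(k2, 0.0)))
    cand = np.array(cand)
    cand /= cand.sum(axis=1, keepdims=True)
    if feasible_only:
        cand = cand[_feasible(cand)]
    lnl_f = _grid_lnl(P, cand)
    k0, k1, k2 = cand[int(np.argmax(lnl_f))]
    k_hat = IBDCoefficients(float(k0), float(k1), float(k2))
    return k_hat.r, k_hat


def classify_relationship(
    genos1: dict[str, tuple[int, int]],
    genos2: dict[str, tuple[int, int]],
    freqs: AlleleFrequencies,
    dyad: tuple[str, str] = ("a", "b"),
) -> RelatednessResult:
    """Best relationship category among U/HS/FS/PO plus ML (r, k).

    Ties in log-likelihood are broken toward the less related category,
    which avoids inflating relatedness claims.
    """
    P = _locus_prob_matrix(genos1, genos2, freqs)
    lnl = {}
    for cat, k in CATEGORY_K.items():
        like = P @ np.array(k)
        with np.errstate(divide="ignore"):
            lnl[cat] = float(np.log(like).sum())
    best = max(CATEGORIES, key=lambda c: (lnl[c], -CATEGORIES.index(c)))
    r_hat, k_hat = estimate_r(genos1, genos2, freqs)
    return RelatednessResult(
        dyad=tuple(dyad),
        r_hat=r_hat,
        k_hat=k_hat,
        best_category=best,
        lnl=lnl,
        n_loci=P.shape[0],
    )


# ---------------------------------------------------------------------------
# simulation-based confidence sets
# ---------------------------------------------------------------------------

def _simulate_dyads_under_k(
    k: tuple[float, float, float],
    loci: list[str],
    freqs: AlleleFrequencies,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Simulate n dyads at the given loci by parametric gene dropping.

    Returns per-locus allele index arrays g1, g2 of shape (n, L, 2) and
    the per-locus frequency vectors (allele order fixed per locus).
    """
    L = len(loci)
    g1 = np.empty((n, L, 2), dtype=np.int64)
    g2 = np.empty((n, L, 2), dtype=np.int64)
    pvecs = []
    state = rng.choice(3, size=(n, L), p=list(k))
    for j, locus in enumerate(loci):
        p = np.array(list(freqs.freqs(locus).values()))
        pvecs.append(p)
        draws = rng.choice(len(p), size=(n, 4), p=p)
        a1, a2, b1, b2 = draws.T
        s = state[:, j]
        # 1 shared IBD allele: first allele of each is the common draw
        b1 = np.where(s >= 1, a1, b1)
        # 2 shared: both alleles copied
        b2 = np.where(s == 2, a2, b2)
        g1[:, j, 0], g1[:, j, 1] = a1, a2
        g2[:, j, 0], g2[:, j, 1] = b1, b2
    return g1, g2, pvecs


def _vectorized_locus_probs(
    g1: np.ndarray, g2: np.ndarray, pvecs: list[np.ndarray]
) -> np.ndarray:
    """(n, L, 3) probabilities for simulated allele-index genotype pairs."""
    n, L, _ = g1.shape
    out = np.empty((n, L, 3))
    for j in range(L):
        p = pvecs[j]
        a = np.minimum(g1[:, j, 0], g1[:, j, 1])
        b = np.maximum(g1[:, j, 0], g1[:, j, 1])
        c = np.minimum(g2[:, j, 0], g2[:, j, 1])
        d = np.maximum(g2[:, j, 0], g2[:, j, 1])
        pa, pb, pc, pd = p[a], p[b], p[c], p[d]
        hw1 = np.where(a == b, pa * pa, 2 * pa * pb)
        hw2 = np.where(c == d, pc * pc, 2 * pc * pd)
        out[:, j, 0] = hw1 * hw2
        out[:, j, 2] = np.where((a == c) & (b == d), hw1, 0.0)
        # P1: sum over candidate IBD alleles x of p_x w(g1|x) w(g2|x)
        p1 = np.zeros(n)
        for x_arr in (a, b):
            w1 = _w_vec(a, b, x_arr, p)
            w2 = _w_vec(c, d, x_arr, p)
            p1 += p[x_arr] * w1 * w2
        # x iterated over g1's two alleles; halve double-counted hets where a==b
        dup = a == b
        p1 = np.where(dup, p1 / 2.0, p1)
        # if g1 het with a != b both candidates are distinct: fine
        out[:, j, 1] = p1
    return out


def _w_vec(a, b, x, p):
    """Vectorized P(genotype {a,b} | IBD allele x)."""
    het = a != b
    w = np.where(
        het,
        np.where(x == a, p[b], 0.0) + np.where(x == b, p[a], 0.0),
        np.where(x == a, p[a], 0.0),
    )
    return w


def relationship_ci(
    genos1: dict[str, tuple[int, int]],
    genos2: dict[str, tuple[int, int]],
    freqs: AlleleFrequencies,
    n_randomizations: int = 100_000,
    seed: int = 1,
    alpha: float = 0.05,
) -> RelatednessResult:
    """Confidence set of relationship categories by parametric bootstrap.

    For each non-best category R', dyads are simulated under R' (gene
    dropping from the allele frequencies, restricted to the loci
    co-typed in the observed dyad). R' is rejected when the observed
    log-likelihood difference (best minus R') exceeds the (1 - alpha)
    quantile of the simulated differences; the confidence set is the
    non-rejected categories plus the best category.
    """
    if n_randomizations < 1000:
        raise ValueError("n_randomizations must be at least 1000")
    result = classify_relationship(genos1, genos2, freqs)
    best = result.best_category
    loci = [l for l in genos1 if l in genos2 and l in freqs.per_locus]
    obs_diff = {
        cat: result.lnl[best] - result.lnl[cat] for cat in CATEGORIES if cat != best
    }
    rng = np.random.default_rng(seed)
    keep = {best}
    k_best = np.array(CATEGORY_K[best])
    for cat in CATEGORIES:
        if cat == best:
            continue
        k_alt = np.array(CATEGORY_K[cat])
        g1, g2, pvecs = _simulate_dyads_under_k(
            tuple(k_alt), loci, freqs, n_randomizations, rng
        )
        P = _vectorized_locus_probs(g1, g2, pvecs)
        with np.errstate(divide="ignore"):
            lnl_best = np.log(np.maximum(P @ k_best, 1e-300)).sum(axis=1)
            lnl_alt = np.log(np.maximum(P @ k_alt, 1e-300)).sum(axis=1)
        crit = float(np.quantile(lnl_best - lnl_alt, 1.0 - alpha))
        if not math.isinf(obs_diff[cat]) and obs_diff[cat] <= crit:
            keep.add(cat)
        elif math.isinf(obs_diff[cat]):
            pass  # alternative is impossible for the observed data
    result.ci_categories = frozenset(keep)
    return result


# ---------------------------------------------------------------------------
# category comparison (ANOVA + Tukey HSD)
# ---------------------------------------------------------------------------

def compare_categories(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA plus pairwise Tukey HSD over r-value groups.

    Groups with fewer than two observations are dropped with a note.
    Q is the studentized-range statistic |mean_i - mean_j| / SE with
    SE = sqrt(MSW/2 (1/n_i + 1/n_j)); p-values come from the
    studentized-range distribution with k groups and N - k df.
    """
    dropped = [g for g, v in groups.items() if len(v) < 2]
    kept = {g: np.asarray(v, dtype=float) for g, v in groups.items() if len(v) >= 2}
    if len(kept) < 2:
        raise ValueError("need at least two groups with >= 2 observations")
    names = sorted(kept)
    values = [kept[g] for g in names]
    F, p = stats.f_oneway(*values)
    if math.isnan(F):
        means = [v.mean() for v in values]
        if max(means) - min(means) == 0:  # no between-group signal at all
            F, p = 0.0, 1.0
    N = sum(len(v) for v in values)
    kgr = len(values)
    grand = np.concatenate(values)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in values)
    dfw = N - kgr
    msw = ssw / dfw if dfw else float("nan")
    rows = []
    for i in range(kgr):
        for j in range(i + 1, kgr):
            vi, vj = values[i], values[j]
            se = math.sqrt(msw / 2.0 * (1.0 / len(vi) + 1.0 / len(vj)))
            q = abs(vi.mean() - vj.mean()) / se if se > 0 else 0.0
            pq = float(stats.studentized_range.sf(q, kgr, dfw)) if se > 0 else 1.0
            rows.append(
                {"group_a": names[i], "group_b": names[j], "Q": q, "p": pq}
            )
    return {
        "F": float(F),
        "p": float(p),
        "df_between": kgr - 1,
        "df_within": dfw,
        "tukey": pd.DataFrame(rows),
        "dropped_groups": dropped,
        "group_means": {g: float(v.mean()) for g, v in kept.items()},
    }
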