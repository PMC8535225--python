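"""Sequence diversity, neutrality tests, haplotype phasing, and networks.

Works on small panels of aligned haplotype sequences (a mitochondrial
control-region fragment and an MHC exon). Statistics follow the classic
sample formulas:

* ``k`` — mean number of pairwise nucleotide differences over all
  C(n, 2) pairs of assigned gene copies,
* ``pi`` — per-site nucleotide diversity (k / sites analysed),
* ``pi_jc`` — mean of per-pair Jukes-Cantor corrected distances,
  JC(p) = -(3/4) ln(1 - 4p/3),
* ``Hd`` — haplotype (gene) diversity n/(n-1) (1 - sum p_i^2),
* Tajima's D and Fu & Li's D* from the frequency spectrum.

Sites containing an ambiguity code or gap in any sequence are excluded
from the distance and polymorphism computations (complete deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SequencePanel
from .pedigree import Pedigree

__all__ = [
    "SeqDiversityStats",
    "HaplotypeNetwork",
    "PhasedPair",
    "collapse_haplotypes",
    "diversity_stats",
    "neutrality_tests",
    "tajima_d",
    "fu_li_d_star",
    "phase_pairs",
    "genotype_signature",
    "candidate_pairs",
    "build_msn",
    "pairwise_differences",
    "tn93_distance_matrix",
    "simulate_neutral_statistics",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass
class SeqDiversityStats:
    n: int
    L: int
    sites_analysed: int
    S: int
    transitions: int
    transversions: int
    k: float
    pi: float
    pi_jc: float
    Hd: float


@dataclass
class HaplotypeNetwork:
    """Minimum spanning network: nodes with counts, edges with step counts."""

    nodes: dict[str, int]
    edges: list[tuple[str, str, int]]

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)


@dataclass
class PhasedPair:
    individual: str
    pair: tuple[str, str]
    probability: float
    method: str  # homozygote | panel_unique | pedigree | em
    resolved: bool = True


# ---------------------------------------------------------------------------
# haplotype collapsing
# ---------------------------------------------------------------------------

def _compatible(a: str, b: str) -> bool:
    """True if sequences differ only at sites where either is ambiguous."""
    return all(
        x == y or x not in _VALID or y not in _VALID for x, y in zip(a, b)
    )


def collapse_haplotypes(panel: SequencePanel) -> pd.DataFrame:
    """Merge identical sequences and tabulate per-copy frequencies.

    Sequences differing only at N/gap positions are merged (the
    ambiguous copy cannot be distinguished from the resolved one).
    Frequencies are over assigned gene copies and sum to 1.
    """
    copies = panel.assigned_copies()
    if not copies:
        raise ValueError("no individuals assigned to the panel")
    classes: list[list[str]] = []  # member labels, representative first
    for label in sorted(panel.sequences):
        seq = panel.sequences[label]
        for cls in classes:
            if _compatible(seq, panel.sequences[cls[0]]):
                cls.append(label)
                break
        else:
            classes.append([label])
    rep_of = {m: cls[0] for cls in classes for m in cls}
    counts: dict[str, int] = {}
    for label in copies:
        rep = rep_of[label]
        counts[rep] = counts.get(rep, 0) + 1
    total = sum(counts.values())
    frame = pd.DataFrame(
        [
            {"haplotype": h, "count": c, "frequency": c / total}
            for h, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
    )
    return frame


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

def _copy_matrix(panel: SequencePanel) -> tuple[np.ndarray, int]:
    """Encode assigned copies as an integer matrix on complete sites.

    Returns (matrix of shape (copies, sites_analysed), alignment length).
    """
    copies = panel.assigned_copies()
    if len(copies) < 2:
        raise ValueError("need at least 2 assigned gene copies")
    seqs = [panel.sequences[c] for c in copies]
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    is_valid = np.isin(arr, [b"A", b"C", b"G", b"T"])
    valid_site = is_valid.all(axis=0)
    code = np.zeros_like(arr, dtype=np.int8)
    for k, ch in enumerate((b"A", b"C", b"G", b"T")):
        code[arr == ch] = k
    return code[:, valid_site], arr.shape[1]


def _site_mutation_counts(col: np.ndarray) -> tuple[int, int]:
    """(transitions, transversions) implied by the bases at one site.

    A site with b distinct bases carries at least b - 1 mutations;
    changes within {A,G} or {C,T} are transitions, the rest
    transversions. With more than two bases the assignment of the b - 1
    changes is made parsimoniously, counting within-class (transition)
    changes first.
    """
    bases = sorted(set(col.tolist()))
    if len(bases) < 2:
        return 0, 0
    pur = [b for b in bases if b in (0, 2)]  # A, G
    pyr = [b for b in bases if b in (1, 3)]  # C, T
    ts = (len(pur) - 1 if len(pur) > 1 else 0) + (len(pyr) - 1 if len(pyr) > 1 else 0)
    total = len(bases) - 1
    tv = total - ts
    return ts, tv


def pairwise_differences(a: str, b: str) -> int:
    """Raw nucleotide differences between two sequences.

    Sites where either sequence carries an ambiguity code or gap are
    skipped.
    """
    return sum(
        1
        for x, y in zip(a, b)
        if x != y and x in _VALID and y in _VALID
    )


def diversity_stats(panel: SequencePanel) -> SeqDiversityStats:
    """Standard diversity statistics over the assigned gene copies."""
    code, L = _copy_matrix(panel)
    n, sites = code.shape

    # distinct haplotype rows with multiplicities: pair counts via classes
    uniq, inverse, counts = np.unique(code, axis=0, return_inverse=True, return_counts=True)
    h = uniq.shape[0]
    diff = np.zeros((h, h), dtype=np.int64)
    for i in range(h):
        diff[i, i + 1:] = (uniq[i + 1:] != uniq[i]).sum(axis=1)
        diff[i + 1:, i] = diff[i, i + 1:]

    n_pairs = n * (n - 1) / 2.0
    # sum over pairs of differences, via class counts
    w = counts.astype(float)
    total_diff = 0.0
    total_jc = 0.0
    for i in range(h):
        for j in range(i + 1, h):
            npair = w[i] * w[j]
            d = diff[i, j]
            total_diff += npair * d
            p = d / sites if sites else 0.0
            if p >= 0.75:
                raise ValueError(
                    f"Jukes-Cantor correction undefined for p-distance {p:.3f} >= 0.75"
                )
            total_jc += npair * (-0.75 * math.log1p(-4.0 * p / 3.0))
    k = total_diff / n_pairs
    pi = (k / sites) if sites else 0.0
    pi_jc = total_jc / n_pairs

    poly = np.array([len(set(code[:, s].tolist())) > 1 for s in range(sites)])
    S = int(poly.sum())
    ts = tv = 0
    for s in np.nonzero(poly)[0]:
        a, b = _site_mutation_counts(code[:, s])
        ts += a
        tv += b

    freqs = counts / n
    Hd = 0.0 if h == 1 else n / (n - 1) * (1.0 - float((freqs**2).sum()))
    return SeqDiversityStats(
        n=n, L=L, sites_analysed=sites, S=S, transitions=ts, transversions=tv,
        k=float(k), pi=float(pi), pi_jc=float(pi_jc), Hd=float(Hd),
    )


# ---------------------------------------------------------------------------
# neutrality tests
# ---------------------------------------------------------------------------

def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float((1.0 / i).sum()), float((1.0 / i**2).sum())


def tajima_d(n: int, S: int, k: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise diffs."""
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S < 1:
        raise ValueError("Tajima's D undefined with S = 0")
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fu_li_d_star(n: int, eta: int, eta_s: int) -> float:
    """Fu & Li's D* (no outgroup) from total mutations and singletons.

    Uses the corrected variance constants (Simonsen et al. 1995), the
    form in common software use; singletons are mutations carried by
    exactly one sequence in the sample.
    """
    if n < 4:
        raise ValueError("Fu & Li's D* requires n >= 4")
    if eta < 1:
        raise ValueError("Fu & Li's D* undefined with no mutations")
    a_n, b_n = _harmonics(n)
    a_n1 = a_n + 1.0 / n  # a_{n+1}
    c_n = 2.0 * (n * a_n - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    d_n = (
        c_n
        + (n - 2.0) / (n - 1) ** 2
        + (2.0 / (n - 1)) * (1.5 - (2.0 * a_n1 - 3.0) / (n - 2) - 1.0 / n)
    )
    nf = float(n)
    v = (
        (nf / (nf - 1)) ** 2 * b_n
        + a_n**2 * d_n
        - 2.0 * (nf * a_n * (a_n + 1)) / (nf - 1) ** 2
    ) / (a_n**2 + b_n)
    u = (nf / (nf - 1)) * (a_n - nf / (nf - 1)) - v
    return ((nf / (nf - 1)) * eta - a_n * eta_s) / math.sqrt(u * eta + v * eta**2)


@dataclass
class NeutralityResult:
    tajima_D: float | None
    tajima_p: float | None
    fu_li_Dstar: float | None
    fu_li_p: float | None
    defined: bool
    S: int
    eta: int
    eta_singletons: int


def _spectrum_counts(code: np.ndarray) -> tuple[int, int, int, float]:
    """(S, eta, eta_singletons, k) from a copies x sites integer matrix."""
    n, sites = code.shape
    S = 0
    eta = 0
    eta_s = 0
    for s in range(sites):
        col = code[:, s]
        vals, cnt = np.unique(col, return_counts=True)
        if len(vals) < 2:
            continue
        S += 1
        eta += len(vals) - 1
        # a singleton mutation: an allele carried by exactly one sequence
        eta_s += int((cnt == 1).sum())
    # mean pairwise differences
    total = 0.0
    uniq, counts = np.unique(code, axis=0, return_counts=True)
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            total += counts[i] * counts[j] * (uniq[i] != uniq[j]).sum()
    k = total / (n * (n - 1) / 2.0)
    return S, eta, eta_s, float(k)


def neutrality_tests(
    panel: SequencePanel,
    n_replicates: int = 2000,
    seed: int = 1,
) -> NeutralityResult:
    """Tajima's D and Fu & Li's D* with coalescent-simulation p-values.

    Significance is assessed by simulating ``n_replicates`` neutral
    Kingman genealogies conditioned on the observed number of
    segregating mutations, recomputing both statistics on each, and
    reporting two-tailed empirical p-values. With S = 0 both statistics
    are flagged undefined.
    """
    code, _ = _copy_matrix(panel)
    n = code.shape[0]
    S, eta, eta_s, k = _spectrum_counts(code)
    if S == 0:
        return NeutralityResult(None, None, None, None, False, 0, 0, 0)
    D = tajima_d(n, S, k)
    Dstar = fu_li_d_star(n, eta, eta_s)
    sim = simulate_neutral_statistics(n, eta, n_replicates, seed)
    p_D = _two_tailed(sim["tajima_D"], D)
    p_Ds = _two_tailed(sim["fu_li_Dstar"], Dstar)
    return NeutralityResult(D, p_D, Dstar, p_Ds, True, S, eta, eta_s)


def _two_tailed(sim: np.ndarray, obs: float) -> float:
    m = len(sim)
    upper = (1 + int((sim >= obs).sum())) / (m + 1)
    lower = (1 + int((sim <= obs).sum())) / (m + 1)
    return min(1.0, 2.0 * min(upper, lower))


def simulate_neutral_statistics(
    n: int, n_mutations: int, n_replicates: int, seed: int = 1
) -> dict[str, np.ndarray]:
    """Null distributions of (D, D*) under the standard neutral coalescent.

    Simulates Kingman genealogies for ``n`` tips, scatters a fixed
    number of mutations on branches proportionally to branch length
    (infinite sites), and evaluates both statistics from the resulting
    frequency spectrum. Self-contained oracle used for significance
    flags; independent of the data path.
    """
    rng = np.random.default_rng(seed)
    Ds = np.empty(n_replicates)
    Dstars = np.empty(n_replicates)
    n_pairs = n * (n - 1) / 2.0
    for rep in range(n_replicates):
        sizes, lengths = _kingman_branches(n, rng)
        probs = lengths / lengths.sum()
        muts = rng.multinomial(n_mutations, probs)
        counts = np.repeat(sizes, muts)  # derived-allele count of each mutation
        S = len(counts)
        if S == 0:
            Ds[rep] = 0.0
            Dstars[rep] = 0.0
            continue
        k = float((counts * (n - counts)).sum() / n_pairs)
        eta_s = int(((counts == 1) | (counts == n - 1)).sum())
        Ds[rep] = tajima_d(n, S, k)
        Dstars[rep] = fu_li_d_star(n, S, eta_s)
    return {"tajima_D": Ds, "fu_li_Dstar": Dstars}


def _kingman_branches(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one coalescent genealogy; return branch (tip-count, length) arrays."""
    active = [[1, 0.0] for _ in range(n)]  # [descendant tips, branch start time]
    t = 0.0
    sizes: list[int] = []
    lengths: list[float] = []
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        if i > j:
            i, j = j, i
        a = active[i]
        b = active[j]
        sizes.append(a[0])
        lengths.append(t - a[1])
        sizes.append(b[0])
        lengths.append(t - b[1])
        merged = [a[0] + b[0], t]
        active[i] = merged
        active.pop(j)
        k -= 1
    return np.array(sizes), np.array(lengths)


# ---------------------------------------------------------------------------
# haplotype-pair phasing against a known panel
# ---------------------------------------------------------------------------

def genotype_signature(panel: SequencePanel, h1: str, h2: str) -> tuple[frozenset, ...]:
    """Per-site observed base sets produced by sequencing both copies together."""
    a, b = panel.sequences[h1], panel.sequences[h2]
    return tuple(frozenset((x, y)) for x, y in zip(a, b))


def candidate_pairs(
    panel: SequencePanel, signature: Sequence[frozenset]
) -> list[tuple[str, str]]:
    """All unordered panel pairs whose combined signature matches."""
    labels = sorted(panel.sequences)
    out = []
    for i, h1 in enumerate(labels):
        for h2 in labels[i:]:
            if genotype_signature(panel, h1, h2) == tuple(signature):
                out.append((h1, h2))
    return out


def phase_pairs(
    observations: Mapping[str, Sequence],
    panel: SequencePanel,
    pedigree: Pedigree | None = None,
    min_posterior: float = 0.9,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> list[PhasedPair]:
    """Resolve each individual's haplotype pair against a known panel.

    ``observations`` maps individual id to either a per-site genotype
    signature (sequence of base sets, one per alignment column) or a
    pre-enumerated collection of candidate label pairs.

    Resolution order: (1) homozygotes and signatures matching exactly
    one panel pair get probability 1; (2) pairs impossible under a
    resolved parent's haplotypes are eliminated (an offspring must
    receive one haplotype from each parent); (3) remaining ambiguity is
    resolved by EM on panel haplotype frequencies, and pairs whose
    posterior falls below ``min_posterior`` are reported unresolved.
    """
    cand: dict[str, list[tuple[str, str]]] = {}
    for ind, obs in observations.items():
        obs_list = list(obs)
        if obs_list and isinstance(obs_list[0], (tuple, list)) and all(
            isinstance(x, str) for pair in obs_list for x in pair
        ):
            pairs = [tuple(sorted(p)) for p in obs_list]
        else:
            pairs = candidate_pairs(panel, obs_list)
        pairs = sorted(set(pairs))
        if not pairs:
            raise ValueError(
                f"genotype of {ind!r} is inconsistent with every panel haplotype pair"
            )
        cand[ind] = pairs

    results: dict[str, PhasedPair] = {}
    for ind, pairs in cand.items():
        if len(pairs) == 1:
            h1, h2 = pairs[0]
            method = "homozygote" if h1 == h2 else "panel_unique"
            results[ind] = PhasedPair(ind, (h1, h2), 1.0, method)

    # pedigree transmission constraints using already-resolved parents
    if pedigree is not None:
        changed = True
        while changed:
            changed = False
            for ind, pairs in cand.items():
                if ind in results or ind not in pedigree.records:
                    continue
                sire, dam = pedigree.parents(ind)
                filtered = [
                    p for p in pairs
                    if _pair_possible(p, results.get(dam), results.get(sire))
                ]
                if filtered and len(filtered) < len(pairs):
                    cand[ind] = filtered
                    changed = True
                    if len(filtered) == 1:
                        results[ind] = PhasedPair(ind, filtered[0], 1.0, "pedigree")

    # EM on haplotype frequencies over all individuals
    unresolved = [ind for ind in cand if ind not in results]
    if unresolved:
        labels = sorted(panel.sequences)
        idx = {h: i for i, h in enumerate(labels)}
        freqs = np.full(len(labels), 1.0 / len(labels))
        for _ in range(max_iter):
            counts = np.zeros(len(labels))
            for ind, pairs in cand.items():
                w = np.array(
                    [freqs[idx[a]] * freqs[idx[b]] * (2.0 if a != b else 1.0) for a, b in pairs]
                )
                if w.sum() == 0:
                    w = np.ones(len(pairs))
                w /= w.sum()
                for (a, b), wi in zip(pairs, w):
                    counts[idx[a]] += wi
                    counts[idx[b]] += wi
            new = counts / counts.sum()
            if np.abs(new - freqs).max() < tol:
                freqs = new
                break
            freqs = new
        for ind in unresolved:
            pairs = cand[ind]
            w = np.array(
                [freqs[idx[a]] * freqs[idx[b]] * (2.0 if a != b else 1.0) for a, b in pairs]
            )
            if w.sum() == 0:
                w = np.ones(len(pairs))
            w /= w.sum()
            best = int(np.argmax(w))
            post = float(w[best])
            results[ind] = PhasedPair(
                ind, pairs[best], post, "em", resolved=post >= min_posterior
            )
    return [results[ind] for ind in observations]


def _pair_possible(pair, dam: PhasedPair | None, sire: PhasedPair | None) -> bool:
    a, b = pair
    dam_h = set(dam.pair) if dam is not None and dam.probability == 1.0 else None
    sire_h = set(sire.pair) if sire is not None and sire.probability == 1.0 else None
    for mine_from_dam, mine_from_sire in ((a, b), (b, a)):
        ok_dam = dam_h is None or mine_from_dam in dam_h
        ok_sire = sire_h is None or mine_from_sire in sire_h
        if ok_dam and ok_sire:
            return True
    return False


# ---------------------------------------------------------------------------
# minimum spanning network
# ---------------------------------------------------------------------------

def build_msn(panel: SequencePanel) -> HaplotypeNetwork:
    """Minimum spanning tree over haplotypes, weighted by raw differences.

    Kruskal with deterministic tie-breaking: edges sorted by (weight,
    label pair). Node counts come from the panel assignments (zero if
    no individuals are assigned).
    """
    labels = sorted(panel.sequences)
    if len(labels) < 2:
        raise ValueError("network needs at least 2 distinct haplotypes")
    counts: dict[str, int] = {h: 0 for h in labels}
    for lab in panel.assigned_copies():
        counts[lab] += 1
    edges = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            edges.append(
                (pairwise_differences(panel.sequences[a], panel.sequences[b]), a, b)
            )
    edges.sort()
    parent = {h: h for h in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen: list[tuple[str, str, int]] = []
    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            chosen.append((a, b, int(w)))
            if len(chosen) == len(labels) - 1:
                break
    return HaplotypeNetwork(nodes=counts, edges=chosen)


def tn93_distance_matrix(panel: SequencePanel) -> pd.DataFrame:
    """Tamura-Nei (1993) distances between panel haplotypes, for reference.

    Uses the analytical TN93 formula with empirical base frequencies
    pooled over each pair (complete deletion per pair). Falls back to
    the raw p-distance if a logarithm argument is non-positive.
    """
    labels = sorted(panel.sequences)
    mat = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            mat[i, j] = mat[j, i] = _tn93(panel.sequences[a], panel.sequences[b])
    return pd.DataFrame(mat, index=labels, columns=labels)


def _tn93(s1: str, s2: str) -> float:
    pairs = [(x, y) for x, y in zip(s1, s2) if x in _VALID and y in _VALID]
    L = len(pairs)
    if L == 0:
        return float("nan")
    base_counts = {b: 0 for b in "ACGT"}
    for x, y in pairs:
        base_counts[x] += 1
        base_counts[y] += 1
    tot = 2.0 * L
    gA, gC, gG, gT = (base_counts[b] / tot for b in "ACGT")
    gR, gY = gA + gG, gC + gT
    P1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / L  # purine ts
    P2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / L  # pyrimidine ts
    Q = sum(
        1 for x, y in pairs if x != y and not ({x, y} <= PURINES or {x, y} <= PYRIMIDINES)
    ) / L
    try:
        k1 = 2.0 * gA * gG / gR if gR else 0.0
        k2 = 2.0 * gC * gT / gY if gY else 0.0
        k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
        term1 = -k1 * math.log(1 - P1 / k1 - Q / (2 * gR)) if k1 else 0.0
        term2 = -k2 * math.log(1 - P2 / k2 - Q / (2 * gY)) if k2 else 0.0
        term3 = -k3 * math.log(1 - Q / (2 * gR * gY)) if gR and gY else 0.0
        return term1 + term2 + term3
    except ValueError:
        return (P1 + P2 + Q)
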