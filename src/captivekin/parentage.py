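"""Likelihood-based parentage: LOD scores, Delta ranking, MHC trio checks.

A candidate parent is scored per locus by the ratio of the Mendelian
transmission probability of the offspring genotype (given the candidate
and, when typed, the other recorded parent) to the probability of the
same genotype were the candidate unrelated. Genotyping error enters as
a simple per-locus mixture: L1 = (1 - eps) T + eps P_HW, the classic
simplification of the Marshall error model. LOD is the natural log of
the product ratio over co-typed loci; Delta is the LOD gap between the
two top-ranked candidates. Inheritance of MHC haplotype pairs provides
an independent veto/confirmation for candidates that microsatellites
cannot separate (e.g. full brothers as alternative sires).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .msatdiv import AlleleFrequencies

__all__ = [
    "ParentageResult",
    "MhcTrioCheck",
    "transition_prob",
    "parentage_lod",
    "delta_ranking",
    "mhc_trio_check",
    "resolve_parentage_case",
]


@dataclass
class ParentageResult:
    offspring: str
    candidate: str
    other_parent: str | None
    lod: float
    mismatches: int
    n_loci: int
    delta: float | None = None
    decision: str = "ambiguous"  # supported | excluded | ambiguous


@dataclass
class MhcTrioCheck:
    offspring_pair: tuple[str, str]
    dam_pair: tuple[str, str] | None
    sire_pair: tuple[str, str] | None
    consistent: bool
    transmitted: dict = field(default_factory=dict)  # parent role -> haplotype


# ---------------------------------------------------------------------------
# Mendelian transmission
# ---------------------------------------------------------------------------

def _gamete_probs(genotype: tuple[int, int] | None, freqs: dict[int, float]) -> dict[int, float]:
    """Allele -> transmission probability from a parent (or the population)."""
    if genotype is None:
        return dict(freqs)
    a, b = genotype
    if a == b:
        return {a: 1.0}
    return {a: 0.5, b: 0.5}


def transition_prob(
    offspring: tuple[int, int],
    parent: tuple[int, int] | None,
    other_parent: tuple[int, int] | None,
    freqs: dict[int, float],
) -> float:
    """Exact Mendelian probability of the offspring genotype at one locus.

    ``parent`` is the candidate; ``other_parent`` may be None, in which
    case its gamete is integrated over the population allele
    frequencies under Hardy-Weinberg.
    """
    for g in (offspring, parent, other_parent):
        if g is None:
            continue
        for a in g:
            if a not in freqs:
                raise ValueError(f"allele {a} absent from frequency table")
    x, y = offspring
    g1 = _gamete_probs(parent, freqs)
    g2 = _gamete_probs(other_parent, freqs)
    p = g1.get(x, 0.0) * g2.get(y, 0.0)
    if x != y:
        p += g1.get(y, 0.0) * g2.get(x, 0.0)
    return p


def _p_hw(g: tuple[int, int], freqs: dict[int, float]) -> float:
    a, b = g
    return freqs[a] ** 2 if a == b else 2.0 * freqs[a] * freqs[b]


def parentage_lod(
    offspring_genos: Mapping[str, tuple[int, int]],
    candidate_genos: Mapping[str, tuple[int, int]],
    other_parent_genos: Mapping[str, tuple[int, int]] | None,
    freqs: AlleleFrequencies,
    epsilon: float = 0.01,
    offspring_id: str = "offspring",
    candidate_id: str = "candidate",
    other_parent_id: str | None = None,
) -> ParentageResult:
    """LOD score for one candidate parent.

    Per locus: L1 = (1 - eps) T_candidate + eps P_HW(offspring) and
    L2 = (1 - eps) T_unrelated + eps P_HW(offspring), where
    T_unrelated integrates the candidate's gamete over the population
    (with the recorded other parent treated identically in both
    hypotheses). LOD = sum ln(L1/L2). Mismatches count loci where the
    raw transmission probability is zero; with eps = 0 a single
    mismatch drives LOD to -infinity and the decision to 'excluded'.
    """
    lod = 0.0
    mismatches = 0
    n_loci = 0
    for locus, off in offspring_genos.items():
        cand = candidate_genos.get(locus)
        if cand is None or locus not in freqs.per_locus:
            continue
        other = other_parent_genos.get(locus) if other_parent_genos else None
        f = freqs.freqs(locus)
        t = transition_prob(off, cand, other, f)
        t_unrel = transition_prob(off, None, other, f)
        hw = _p_hw(off, f)
        l1 = (1.0 - epsilon) * t + epsilon * hw
        l2 = (1.0 - epsilon) * t_unrel + epsilon * hw
        n_loci += 1
        if t == 0.0:
            mismatches += 1
        if l1 == 0.0:
            lod = -math.inf
        elif not math.isinf(lod):
            lod += math.log(l1 / l2)
    if n_loci == 0:
        raise ValueError(
            f"candidate {candidate_id!r} shares no co-typed loci with {offspring_id!r}"
        )
    decision = "excluded" if math.isinf(lod) else ("supported" if lod > 0 else "ambiguous")
    return ParentageResult(
        offspring=offspring_id,
        candidate=candidate_id,
        other_parent=other_parent_id,
        lod=lod,
        mismatches=mismatches,
        n_loci=n_loci,
        decision=decision,
    )


def delta_ranking(
    offspring_genos: Mapping[str, tuple[int, int]],
    candidates: Mapping[str, Mapping[str, tuple[int, int]]],
    other_parent_genos: Mapping[str, tuple[int, int]] | None,
    freqs: AlleleFrequencies,
    epsilon: float = 0.01,
    offspring_id: str = "offspring",
    other_parent_id: str | None = None,
) -> list[ParentageResult]:
    """Rank candidate parents by LOD; attach Delta to the top candidate.

    Delta is the LOD difference between the two best candidates; a tie
    (Delta = 0, e.g. genotypically identical candidates) leaves the top
    candidate 'ambiguous'.
    """
    if len(candidates) < 2:
        results = [
            parentage_lod(
                offspring_genos, genos, other_parent_genos, freqs, epsilon,
                offspring_id=offspring_id, candidate_id=cid,
                other_parent_id=other_parent_id,
            )
            for cid, genos in candidates.items()
        ]
        if results:
            results[0].delta = None
        return results
    results = [
        parentage_lod(
            offspring_genos, genos, other_parent_genos, freqs, epsilon,
            offspring_id=offspring_id, candidate_id=cid,
            other_parent_id=other_parent_id,
        )
        for cid, genos in candidates.items()
    ]
    results.sort(key=lambda r: r.lod, reverse=True)
    top, second = results[0], results[1]
    if math.isinf(top.lod) and top.lod < 0:
        top.delta = 0.0
    else:
        top.delta = top.lod - second.lod if not math.isinf(second.lod) else math.inf
    if top.delta == 0.0:
        top.decision = "ambiguous"
    return results


# ---------------------------------------------------------------------------
# MHC haplotype trio logic
# ---------------------------------------------------------------------------

def mhc_trio_check(
    offspring_pair: tuple[str, str],
    dam_pair: tuple[str, str] | None,
    sire_pair: tuple[str, str] | None,
) -> MhcTrioCheck:
    """Can the offspring's haplotype pair be produced by these parents?

    Consistent iff some assignment gives one offspring haplotype to the
    dam and the other to the sire, with each assigned haplotype present
    in that parent's pair; an unknown parent accepts anything. When the
    assignment is unique, the transmitted haplotypes are reported.
    """
    h1, h2 = offspring_pair
    valid = []
    for from_dam, from_sire in ((h1, h2), (h2, h1)):
        ok_dam = dam_pair is None or from_dam in dam_pair
        ok_sire = sire_pair is None or from_sire in sire_pair
        if ok_dam and ok_sire:
            valid.append((from_dam, from_sire))
    transmitted: dict = {}
    if valid:
        dams = {v[0] for v in valid}
        sires = {v[1] for v in valid}
        if len(dams) == 1 and dam_pair is not None:
            transmitted["dam"] = next(iter(dams))
        if len(sires) == 1 and sire_pair is not None:
            transmitted["sire"] = next(iter(sires))
    return MhcTrioCheck(
        offspring_pair=tuple(sorted(offspring_pair)),
        dam_pair=tuple(sorted(dam_pair)) if dam_pair else None,
        sire_pair=tuple(sorted(sire_pair)) if sire_pair else None,
        consistent=bool(valid),
        transmitted=transmitted,
    )


# ---------------------------------------------------------------------------
# combined case resolution
# ---------------------------------------------------------------------------

def resolve_parentage_case(
    offspring_id: str,
    role: str,
    candidate_ids: Sequence[str],
    genotypes: Mapping[str, Mapping[str, tuple[int, int]]],
    freqs: AlleleFrequencies,
    other_parent_id: str | None = None,
    mhc_pairs: Mapping[str, tuple[str, str]] | None = None,
    epsilon: float = 0.01,
) -> dict:
    """Resolve one uncertain-parentage case with the combined evidence.

    Pipeline: (1) Mendelian exclusion at eps = 0 semantics (mismatching
    loci counted), (2) LOD/Delta ranking among candidates, (3) MHC
    haplotype trio check as veto/confirmation, (4) decision. The
    decision is 'supported' for a uniquely surviving positive-LOD
    candidate, 'true parent unsampled' when every candidate is
    excluded, otherwise 'ambiguous'.

    ``role`` is 'dam' or 'sire' (which side the candidates are for);
    ``other_parent_id`` names the recorded parent on the other side, if
    genotyped.
    """
    if role not in ("dam", "sire"):
        raise ValueError("role must be 'dam' or 'sire'")
    if not candidate_ids:
        raise ValueError("candidate set must be nonempty")
    mhc_pairs = mhc_pairs or {}
    off_genos = genotypes[offspring_id]
    other_genos = genotypes.get(other_parent_id) if other_parent_id else None
    ranked = delta_ranking(
        off_genos,
        {cid: genotypes[cid] for cid in candidate_ids},
        other_genos,
        freqs,
        epsilon=epsilon,
        offspring_id=offspring_id,
        other_parent_id=other_parent_id,
    )
    off_mhc = mhc_pairs.get(offspring_id)
    other_mhc = mhc_pairs.get(other_parent_id) if other_parent_id else None
    table = []
    survivors = []
    for res in ranked:
        mhc_verdict = "untyped"
        if off_mhc is not None and mhc_pairs.get(res.candidate) is not None:
            cand_mhc = mhc_pairs[res.candidate]
            dam_pair = cand_mhc if role == "dam" else other_mhc
            sire_pair = cand_mhc if role == "sire" else other_mhc
            check = mhc_trio_check(off_mhc, dam_pair, sire_pair)
            mhc_verdict = "consistent" if check.consistent else "excluded"
        mendelian_excluded = res.mismatches > 0 and epsilon == 0.0
        excluded = mendelian_excluded or math.isinf(res.lod) or mhc_verdict == "excluded"
        table.append(
            {
                "candidate": res.candidate,
                "lod": res.lod,
                "mismatches": res.mismatches,
                "delta": res.delta,
                "mhc": mhc_verdict,
                "excluded": excluded,
            }
        )
        if not excluded:
            survivors.append(res)
    if not survivors:
        decision, supported = "true parent unsampled", None
    elif len(survivors) == 1 and survivors[0].lod > 0:
        decision, supported = "supported", survivors[0].candidate
    else:
        top = survivors[0]
        runner = survivors[1] if len(survivors) > 1 else None
        if (
            top.lod > 0
            and runner is not None
            and top.lod - runner.lod > 0
            and top is ranked[0]
            and (top.delta or 0) > 0
        ):
            decision, supported = "supported", top.candidate
        else:
            decision, supported = "ambiguous", None
    return {
        "offspring": offspring_id,
        "role": role,
        "other_parent": other_parent_id,
        "candidates": table,
        "decision": decision,
        "supported_candidate": supported,
        "epsilon": epsilon,
    }
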