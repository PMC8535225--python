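"""Studbook graph, kinship, dyad classification, and reconciliation.

The studbook is treated as a directed acyclic graph from parents to
offspring. Founders (both parents unknown) are assumed mutually
unrelated and non-inbred — the standard studbook convention, and
precisely the assumption the genetic reconciliation downstream is meant
to stress-test. Kinship is the classic path-counting recursion
(Wright/Malecot): f(i,i) = (1 + F_i)/2 and f(i,j) averages over the
later-born member's parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io import IndividualRecord, Sex

__all__ = [
    "Pedigree",
    "build_pedigree",
    "classify_dyad",
    "consistency_report",
    "overlay_markers",
    "EXPECTED_R",
    "CONSISTENT_GENETIC",
]

#: Expected relatedness per studbook category on a non-inbred pedigree.
EXPECTED_R = {"PO": 0.5, "FS": 0.5, "HS": 0.25, "AV": 0.25, "GP": 0.25, "FC": 0.125, "U": 0.0}

#: Genetic best-categories considered consistent with each studbook category.
#: A 4-category genetic classifier cannot name avuncular/grandparental/cousin
#: links; those studbook categories are accepted as HS or U.
CONSISTENT_GENETIC = {
    "PO": {"PO"},
    "FS": {"FS"},
    "HS": {"HS"},
    "U": {"U"},
    "AV": {"HS", "U"},
    "GP": {"HS", "U"},
    "FC": {"HS", "U"},
}

#: Relatedness above which a dyad is flagged as unexpectedly high.
HIGH_R_THRESHOLD = 0.6


class Pedigree:
    """Acyclic studbook graph with kinship and classification helpers."""

    def __init__(self, records: Sequence[IndividualRecord], warnings: list[str] | None = None):
        self.records: dict[str, IndividualRecord] = {r.id: r for r in records}
        self.warnings = warnings or []
        self._kinship_cache: dict[frozenset, float] = {}
        g = nx.DiGraph()
        g.add_nodes_from(self.records)
        for r in self.records.values():
            for p in (r.sire_id, r.dam_id):
                if p is not None:
                    g.add_edge(p, r.id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"pedigree contains a cycle: {cycle}")
        self.graph = g
        self.depth: dict[str, int] = {}
        for node in nx.topological_sort(g):
            preds = list(g.predecessors(node))
            self.depth[node] = 0 if not preds else 1 + max(self.depth[p] for p in preds)

    # -- structure --------------------------------------------------------
    def parents(self, i: str) -> tuple[str | None, str | None]:
        r = self.records[i]
        return r.sire_id, r.dam_id

    @property
    def founders(self) -> list[str]:
        return [i for i, r in self.records.items() if r.is_founder]

    def __contains__(self, i: str) -> bool:
        return i in self.records

    def __len__(self) -> int:
        return len(self.records)

    # -- kinship ----------------------------------------------------------
    def kinship(self, i: str, j: str) -> float:
        """Malecot kinship coefficient f(i, j); founders unrelated."""
        return self._kinship(i, j)

    def inbreeding(self, i: str) -> float:
        """F_i = kinship of i's parents (0 for founders/unknown parents)."""
        s, d = self.parents(i)
        if s is None or d is None:
            return 0.0
        return self._kinship(s, d)

    def _kinship(self, i: str, j: str) -> float:
        key = frozenset((i, j))
        cached = self._kinship_cache.get(key)
        if cached is not None:
            return cached
        if i == j:
            f = 0.5 * (1.0 + self.inbreeding(i))
        else:
            # recurse on the later-generation member so descent always
            # moves toward founders
            a, b = (i, j) if self.depth[i] >= self.depth[j] else (j, i)
            s, d = self.parents(a)
            fs = self._kinship(s, b) if s is not None else 0.0
            fd = self._kinship(d, b) if d is not None else 0.0
            f = 0.5 * (fs + fd)
        self._kinship_cache[key] = f
        return f

    def relatedness(self, i: str, j: str) -> float:
        """Expected coefficient of relatedness r = 2 f(i, j)."""
        return 2.0 * self._kinship(i, j)

    # -- sibling helpers --------------------------------------------------
    def siblings(self, i: str, full: bool | None = None) -> list[str]:
        """Siblings of i: full=True/False/None for full/half/either."""
        si, di = self.parents(i)
        out = []
        for j, r in self.records.items():
            if j == i:
                continue
            cat = _sib_category(si, di, r.sire_id, r.dam_id)
            if cat is None:
                continue
            if full is None or (full and cat == "FS") or (not full and cat == "HS"):
                out.append(j)
        return out


def _sib_category(s1, d1, s2, d2) -> str | None:
    shared = 0
    if s1 is not None and s1 == s2:
        shared += 1
    if d1 is not None and d1 == d2:
        shared += 1
    if shared == 2:
        return "FS"
    if shared == 1:
        return "HS"
    return None


def build_pedigree(records: Sequence[IndividualRecord]) -> Pedigree:
    """Build a pedigree, creating external-parent placeholders as needed.

    A parent referenced but absent from the records is added as an
    unknown-pedigree placeholder and reported in ``Pedigree.warnings``.
    """
    by_id = {r.id: r for r in records}
    extended = list(records)
    warnings: list[str] = []
    for r in records:
        for p, sex in ((r.sire_id, Sex.MALE), (r.dam_id, Sex.FEMALE)):
            if p is not None and p not in by_id:
                placeholder = IndividualRecord(id=p, sex=sex)
                by_id[p] = placeholder
                extended.append(placeholder)
                warnings.append(f"parent {p!r} referenced but absent; placeholder created")
    return Pedigree(extended, warnings=warnings)


def classify_dyad(ped: Pedigree, i: str, j: str) -> str:
    """Studbook relationship category for a dyad.

    Categories, from closest: PO, FS, HS, AV (avuncular), GP
    (grandparental), FC (first cousins), U. When several apply the one
    with the highest expected relatedness wins.
    """
    if i == j:
        raise ValueError("dyad must contain two distinct individuals")
    si, di = ped.parents(i)
    sj, dj = ped.parents(j)
    if i in (sj, dj) or j in (si, di):
        return "PO"
    sib = _sib_category(si, di, sj, dj)
    if sib is not None:
        return sib
    # grandparental: i is a parent of one of j's parents (or vice versa)
    if _is_grandparent(ped, i, j) or _is_grandparent(ped, j, i):
        return "GP"
    # avuncular: i is a (full or half) sibling of one of j's parents
    if _is_avuncular(ped, i, j) or _is_avuncular(ped, j, i):
        return "AV"
    # first cousins: a parent of i and a parent of j are siblings
    for pi in (si, di):
        for pj in (sj, dj):
            if pi is None or pj is None or pi == pj:
                continue
            psi, pdi = ped.parents(pi)
            psj, pdj = ped.parents(pj)
            if _sib_category(psi, pdi, psj, pdj) is not None:
                return "FC"
    return "U"


def _is_grandparent(ped: Pedigree, i: str, j: str) -> bool:
    for p in ped.parents(j):
        if p is not None and i in ped.parents(p):
            return True
    return False


def _is_avuncular(ped: Pedigree, i: str, j: str) -> bool:
    si, di = ped.parents(i)
    for p in ped.parents(j):
        if p is None or p == i:
            continue
        ps, pd = ped.parents(p)
        if _sib_category(si, di, ps, pd) is not None:
            return True
    return False


def consistency_report(
    ped: Pedigree,
    relatedness_results: Iterable,
    ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Compare studbook dyad categories with genetic best categories.

    ``relatedness_results`` are objects with ``dyad`` (id pair),
    ``best_category`` and ``r_hat`` attributes (see
    :mod:`captivekin.relatedness`). A dyad is consistent when the
    genetic category lies in the acceptance set of the studbook
    category; avuncular/grandparental/first-cousin studbook links are
    accepted as genetic HS or U because the 4-category classifier cannot
    name them. Dyads with r_hat above 0.6 are flagged as unexpectedly
    high relatedness.
    """
    rows = []
    missing = 0
    results = {tuple(sorted(res.dyad)): res for res in relatedness_results}
    if ids is None:
        seen = sorted({i for pair in results for i in pair})
        ids = seen
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            i, j = ids[a_idx], ids[b_idx]
            res = results.get(tuple(sorted((i, j))))
            if res is None:
                missing += 1
                continue
            sb = classify_dyad(ped, i, j)
            genetic = res.best_category
            consistent = genetic in CONSISTENT_GENETIC[sb]
            rows.append(
                {
                    "id_a": i,
                    "id_b": j,
                    "studbook_category": sb,
                    "genetic_category": genetic,
                    "consistent": consistent,
                    "r_hat": res.r_hat,
                    "flag_high_r": res.r_hat > HIGH_R_THRESHOLD,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "id_a", "id_b", "studbook_category", "genetic_category",
            "consistent", "r_hat", "flag_high_r",
        ],
    )
    n = len(frame)
    summary = {
        "n_dyads": n,
        "n_consistent": int(frame["consistent"].sum()) if n else 0,
        "consistent_fraction": float(frame["consistent"].mean()) if n else float("nan"),
        "n_high_r": int(frame["flag_high_r"].sum()) if n else 0,
        "n_missing_genetic": missing,
    }
    return frame, summary


def overlay_markers(
    ped: Pedigree,
    mt_assignments: Mapping[str, str] | None = None,
    mhc_pairs: Mapping[str, tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Annotate the pedigree with marker data and flag transmission violations.

    Violations: an offspring whose mtDNA haplotype differs from its
    recorded dam's (both typed), and an offspring whose MHC haplotype
    pair cannot be produced by its recorded parents' pairs.
    """
    from .parentage import mhc_trio_check

    mt_assignments = mt_assignments or {}
    mhc_pairs = mhc_pairs or {}
    violations: list[dict] = []
    rows = []
    for i, rec in ped.records.items():
        mt = mt_assignments.get(i)
        mhc = mhc_pairs.get(i)
        flags = []
        if mt is not None and rec.dam_id is not None:
            dam_mt = mt_assignments.get(rec.dam_id)
            if dam_mt is not None and dam_mt != mt:
                flags.append("mtDNA_mismatch_dam")
                violations.append(
                    {"id": i, "type": "mtDNA", "detail": f"offspring {mt}, dam {dam_mt}"}
                )
        if mhc is not None:
            dam_pair = mhc_pairs.get(rec.dam_id) if rec.dam_id else None
            sire_pair = mhc_pairs.get(rec.sire_id) if rec.sire_id else None
            if dam_pair is not None or sire_pair is not None:
                check = mhc_trio_check(mhc, dam_pair, sire_pair)
                if not check.consistent:
                    flags.append("MHC_trio_violation")
                    violations.append(
                        {
                            "id": i,
                            "type": "MHC",
                            "detail": f"offspring {mhc}, dam {dam_pair}, sire {sire_pair}",
                        }
                    )
        rows.append(
            {
                "id": i,
                "sire_id": rec.sire_id or "",
                "dam_id": rec.dam_id or "",
                "depth": ped.depth[i],
                "mt_haplotype": mt or "",
                "mhc_pair": "/".join(mhc) if mhc else "",
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows), violations
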