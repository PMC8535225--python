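"""Data model and file I/O shared by every pipeline stage.

The package works from three kinds of input:

* a studbook table (one row per animal: id, recorded sire/dam, sex, birth
  year, alive flag),
* a diploid microsatellite genotype table (two allele columns per locus,
  alleles scored as fragment sizes but treated as opaque categories),
* pre-aligned FASTA panels of haplotype sequences (a maternally inherited
  mitochondrial control-region fragment and an MHC exon typed as one
  nuclear locus), together with per-individual haplotype assignments.

Downstream modules consume only the in-memory types defined here; no
analysis stage reads files directly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Sex",
    "IndividualRecord",
    "GenotypeTable",
    "SequencePanel",
    "AnalysisConfig",
    "read_genotype_table",
    "write_genotype_table",
    "read_studbook",
    "write_studbook",
    "read_fasta",
    "read_assignments",
    "write_table",
    "write_json_summary",
]

#: Accepted spellings of an unknown parent on input.
UNKNOWN_PARENT = {"", "UNK", "UNKNOWN", "NA"}

#: IUPAC nucleotide codes plus alignment gap.
IUPAC_DNA = set("ACGTRYSWKMBDHVN-")


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "U"


@dataclass(frozen=True)
class IndividualRecord:
    """One studbook row. ``sire_id``/``dam_id`` are ``None`` when unknown."""

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    birth_year: int | None = None
    alive: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("individual id must be nonempty")
        if self.id in (self.sire_id, self.dam_id):
            raise ValueError(f"individual {self.id!r} listed as its own parent")
        if self.sire_id is not None and self.sire_id == self.dam_id:
            raise ValueError(
                f"individual {self.id!r}: sire and dam are the same individual"
            )

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None


class GenotypeTable:
    """Individuals x loci diploid genotype calls.

    Calls are stored as an ``(n, L, 2)`` integer array of allele labels
    with 0 meaning missing; a call is either fully present or fully
    missing, and present calls are normalized smaller-allele-first.
    """

    def __init__(self, ids: Sequence[str], loci: Sequence[str], calls: np.ndarray):
        ids = list(ids)
        loci = list(loci)
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(ids), len(loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(ids)}, {len(loci)}, 2)"
            )
        dup = _first_duplicate(ids)
        if dup is not None:
            raise ValueError(f"duplicate individual id {dup!r}")
        if (calls < 0).any():
            raise ValueError("allele labels must be positive integers (0 = missing)")
        half = (calls == 0).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing call for individual {ids[i]!r} at locus {loci[j]!r}"
            )
        self.ids = ids
        self.loci = loci
        self.calls = np.sort(calls, axis=2)  # smaller allele first
        self._row = {v: k for k, v in enumerate(ids)}
        self._col = {v: k for k, v in enumerate(loci)}

    # -- basic access -----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def get(self, individual: str, locus: str) -> tuple[int, int] | None:
        a, b = self.calls[self._row[individual], self._col[locus]]
        return None if a == 0 else (int(a), int(b))

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is present."""
        return self.calls[:, :, 0] > 0

    def n_typed(self, locus: str) -> int:
        return int(self.typed_mask()[:, self._col[locus]].sum())

    def locus_array(self, locus: str) -> np.ndarray:
        """(n, 2) calls at one locus, 0 = missing."""
        return self.calls[:, self._col[locus], :]

    def genotypes_of(self, individual: str) -> dict[str, tuple[int, int]]:
        row = self.calls[self._row[individual]]
        return {
            loc: (int(a), int(b))
            for loc, (a, b) in zip(self.loci, row)
            if a > 0
        }

    def subset(self, ids: Sequence[str] | None = None,
               loci: Sequence[str] | None = None) -> "GenotypeTable":
        ids = list(ids) if ids is not None else self.ids
        loci = list(loci) if loci is not None else self.loci
        ri = [self._row[i] for i in ids]
        ci = [self._col[l] for l in loci]
        return GenotypeTable(ids, loci, self.calls[np.ix_(ri, ci)])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self.ids == other.ids
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeTable({self.n_individuals} individuals, {self.n_loci} loci)"


@dataclass
class SequencePanel:
    """Aligned haplotype sequences plus per-individual assignments.

    ``assignments`` maps an individual id to one label (haploid marker)
    or an unordered pair of labels (diploid marker).
    """

    sequences: dict[str, str]
    assignments: dict[str, str | tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            for label, s in self.sequences.items():
                if len(s) != len(next(iter(self.sequences.values()))):
                    raise ValueError(
                        f"sequence {label!r} has length {len(s)}; panel is not aligned"
                    )
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        for label, s in self.sequences.items():
            bad = set(s) - IUPAC_DNA
            if bad:
                raise ValueError(
                    f"sequence {label!r} contains non-IUPAC characters {sorted(bad)}"
                )
        for ind, lab in self.assignments.items():
            labels = (lab,) if isinstance(lab, str) else tuple(lab)
            for l in labels:
                if l not in self.sequences:
                    raise ValueError(
                        f"assignment for {ind!r} refers to unknown haplotype {l!r}"
                    )
        # normalize pairs to sorted tuples
        self.assignments = {
            ind: (lab if isinstance(lab, str) else tuple(sorted(lab)))
            for ind, lab in self.assignments.items()
        }

    @property
    def length(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))

    def assigned_copies(self) -> list[str]:
        """Haplotype labels, one per gene copy carried by assigned individuals."""
        copies: list[str] = []
        for lab in self.assignments.values():
            if isinstance(lab, str):
                copies.append(lab)
            else:
                copies.extend(lab)
        return copies


@dataclass
class AnalysisConfig:
    """Run-level knobs shared across the pipeline.

    p_crit
        minimum allele frequency admitted into the LD-based Ne
        computation (alleles rarer than this are dropped).
    mating_system
        'random' or 'monogamous'; selects the r2' -> Ne inversion.
    error_rate
        per-locus genotyping error used in parentage likelihoods.
    n_randomizations
        Monte-Carlo replicates for permutation tests and relationship
        confidence sets.
    rarefaction_size
        gene copies for allelic-richness rarefaction; None means
        2 x (minimum typed individuals over loci).
    """

    p_crit: float = 0.006
    mating_system: str = "random"
    error_rate: float = 0.01
    n_randomizations: int = 100_000
    rng_seed: int = 1
    rarefaction_size: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_crit <= 1.0:
            raise ValueError("p_crit must be in [0, 1]")
        if self.mating_system not in ("random", "monogamous"):
            raise ValueError("mating_system must be 'random' or 'monogamous'")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be positive")
        if self.rarefaction_size is not None:
            if self.rarefaction_size < 2 or self.rarefaction_size % 2:
                raise ValueError("rarefaction_size must be a positive even integer")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_genotype_table(path: str | Path) -> GenotypeTable:
    """Read a genotype CSV: header ``id`` then ``<locus>.1,<locus>.2`` pairs.

    Missing calls are encoded as 0 or an empty cell. A call with exactly
    one empty/zero cell is an error (it would otherwise fabricate a
    phantom allele).
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if not header or header[0].lower() != "id":
        raise ValueError(f"{path}: first header column must be 'id'")
    cols = header[1:]
    if len(cols) % 2:
        raise ValueError(f"{path}: odd number of allele columns")
    loci: list[str] = []
    for i in range(0, len(cols), 2):
        a, b = cols[i], cols[i + 1]
        if not (a.endswith(".1") and b.endswith(".2") and a[:-2] == b[:-2]):
            raise ValueError(
                f"{path}: allele columns {a!r},{b!r} are not a '<locus>.1','<locus>.2' pair"
            )
        loci.append(a[:-2])

    ids: list[str] = []
    calls = np.zeros((len(rows) - 1, len(loci), 2), dtype=np.int64)
    for r, row in enumerate(rows[1:], start=1):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise ValueError(f"{path}: row {r + 1} has {len(row)} cells, expected {len(header)}")
        ids.append(row[0].strip())
        for j, loc in enumerate(loci):
            cell1 = row[1 + 2 * j].strip()
            cell2 = row[2 + 2 * j].strip()
            a = int(cell1) if cell1 else 0
            b = int(cell2) if cell2 else 0
            if (a == 0) != (b == 0):
                raise ValueError(
                    f"{path}: half-missing call for {row[0].strip()!r} at "
                    f"{loc}.{1 if a == 0 else 2}"
                )
            if a < 0 or b < 0:
                raise ValueError(f"{path}: negative allele label at row {r + 1}")
            calls[len(ids) - 1, j] = (a, b)
    calls = calls[: len(ids)]
    dup = _first_duplicate(ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate individual id {dup!r}")
    return GenotypeTable(ids, loci, calls)


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["id"]
        for loc in table.loci:
            header += [f"{loc}.1", f"{loc}.2"]
        w.writerow(header)
        for i, ind in enumerate(table.ids):
            row: list = [ind]
            for j in range(table.n_loci):
                a, b = table.calls[i, j]
                row += [int(a), int(b)]
            w.writerow(row)


def _parse_parent(cell: str) -> str | None:
    cell = cell.strip()
    return None if cell.upper() in UNKNOWN_PARENT else cell


def read_studbook(path: str | Path) -> list[IndividualRecord]:
    """Read a studbook CSV with columns id,sire_id,dam_id,sex,birth_year,alive.

    Unknown parents may be empty or ``UNK``; unknown sex ``U``; unknown
    birth year empty. Cross-record sanity checks: an individual listed
    as a sire must not be recorded female, a dam must not be male.
    """
    records: list[IndividualRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "sire_id", "dam_id", "sex", "birth_year", "alive"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: studbook header must contain {sorted(required)}")
        for row in reader:
            year = row["birth_year"].strip()
            records.append(
                IndividualRecord(
                    id=row["id"].strip(),
                    sire_id=_parse_parent(row["sire_id"]),
                    dam_id=_parse_parent(row["dam_id"]),
                    sex=Sex(row["sex"].strip().upper() or "U"),
                    birth_year=int(year) if year else None,
                    alive=row["alive"].strip() in ("1", "true", "True", "yes"),
                )
            )
    dup = _first_duplicate(r.id for r in records)
    if dup is not None:
        raise ValueError(f"{path}: duplicate individual id {dup!r}")
    sex_of = {r.id: r.sex for r in records}
    for r in records:
        if r.sire_id is not None and sex_of.get(r.sire_id) == Sex.FEMALE:
            raise ValueError(f"{path}: sire {r.sire_id!r} of {r.id!r} is recorded female")
        if r.dam_id is not None and sex_of.get(r.dam_id) == Sex.MALE:
            raise ValueError(f"{path}: dam {r.dam_id!r} of {r.id!r} is recorded male")
    return records


def write_studbook(records: Sequence[IndividualRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "sire_id", "dam_id", "sex", "birth_year", "alive"])
        for r in records:
            w.writerow(
                [
                    r.id,
                    r.sire_id or "",
                    r.dam_id or "",
                    r.sex.value,
                    "" if r.birth_year is None else r.birth_year,
                    int(r.alive),
                ]
            )


def read_fasta(path: str | Path) -> SequencePanel:
    """Read a pre-aligned FASTA into a panel (labels = first header token)."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"{path}: duplicate sequence label {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"{path}: no sequences found")
    length = len(next(iter(sequences.values())))
    for label, s in sequences.items():
        if len(s) != length:
            raise ValueError(
                f"{path}: sequence {label!r} has length {len(s)}, expected {length}"
            )
    return SequencePanel(sequences=sequences)


def read_assignments(path: str | Path) -> dict[str, str | tuple[str, str]]:
    """Read id -> haplotype assignment CSV (columns id,hap1[,hap2])."""
    out: dict[str, str | tuple[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ValueError(f"{path}: assignment file needs an 'id' column")
        for row in reader:
            h1 = row.get("hap1", "").strip()
            h2 = (row.get("hap2") or "").strip()
            if not h1:
                continue
            out[row["id"].strip()] = (h1, h2) if h2 else h1
    return out


def write_table(frame, path: str | Path) -> None:
    """Write a pandas DataFrame as the package's standard TSV output."""
    frame.to_csv(path, sep="\t", index=False)


def write_json_summary(summary: Mapping, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Enum):
            return o.value
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_default)
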