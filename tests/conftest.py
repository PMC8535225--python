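"""Shared fixtures and small simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from captivekin.io import GenotypeTable, IndividualRecord, Sex
from captivekin.msatdiv import AlleleFrequencies


def freqs_from_arrays(arrays, loci=None) -> AlleleFrequencies:
    """Build an AlleleFrequencies object from per-locus frequency vectors.

    Allele labels are 1..A per locus; gene-copy counts are nominal.
    """
    loci = loci or [f"L{j + 1:02d}" for j in range(len(arrays))]
    per_locus = {
        loc: {i + 1: float(p) for i, p in enumerate(arr)}
        for loc, arr in zip(loci, arrays)
    }
    return AlleleFrequencies(per_locus, {loc: 1000 for loc in loci})


def draw_genotype(freq: np.ndarray, rng: np.random.Generator) -> tuple[int, int]:
    a, b = rng.choice(len(freq), size=2, p=freq) + 1
    return (int(min(a, b)), int(max(a, b)))


def simulate_dyad(category: str, freq_arrays, rng: np.random.Generator):
    """One dyad's multilocus genotypes under a canonical relationship.

    Plain explicit gene dropping: draw parental/population alleles per
    locus according to the category's IBD mechanism. Kept deliberately
    simple and separate from the package's own simulators.
    """
    k_by_cat = {
        "U": (1.0, 0.0, 0.0),
        "HS": (0.5, 0.5, 0.0),
        "FS": (0.25, 0.5, 0.25),
        "PO": (0.0, 1.0, 0.0),
    }
    k = k_by_cat[category]
    g1, g2 = {}, {}
    for j, f in enumerate(freq_arrays):
        loc = f"L{j + 1:02d}"
        state = rng.choice(3, p=k)
        a1, a2, b1, b2 = rng.choice(len(f), size=4, p=f) + 1
        if state >= 1:
            b1 = a1
        if state == 2:
            b2 = a2
        g1[loc] = (int(min(a1, a2)), int(max(a1, a2)))
        g2[loc] = (int(min(b1, b2)), int(max(b1, b2)))
    return g1, g2


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_table():
    """2 individuals x 2 loci with one missing call."""
    calls = np.array(
        [
            [[120, 124], [8, 8]],
            [[120, 120], [0, 0]],
        ]
    )
    return GenotypeTable(["A", "B"], ["FH1", "FH2"], calls)


@pytest.fixture
def trio_records():
    return [
        IndividualRecord("A", sex=Sex.MALE, birth_year=2010),
        IndividualRecord("B", sex=Sex.FEMALE, birth_year=2011),
        IndividualRecord("C", sire_id="A", dam_id="B", sex=Sex.FEMALE, birth_year=2014),
    ]
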