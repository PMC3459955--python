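from __future__ import annotations

from typing import Sequence

import pytest

from triopoo.trio_data import Individual, Snp, SnpMap

RISK, OTHER = "A", "B"


def _genotype(dose: int | None) -> tuple[str, str] | None:
    if dose is None:
        return None
    return ((OTHER, OTHER), (RISK, OTHER), (RISK, RISK))[dose]


def individuals_from_doses(
    per_snp_doses: Sequence[Sequence[tuple[int | None, int | None, int | None]]],
) -> tuple[list[Individual], SnpMap]:
    """Build a trio cohort from explicit (M, P, C) dose triples.

    ``per_snp_doses[j][i]`` is the dose triple of trio ``i`` at SNP ``j``;
    all SNPs must list the same number of trios.  Risk allele is 'A'.
    """
    n_trios = {len(doses) for doses in per_snp_doses}
    assert len(n_trios) == 1, "all SNPs must cover the same trios"
    n = n_trios.pop()
    individuals: list[Individual] = []
    for i in range(n):
        fam = f"fam{i + 1:04d}"
        mother_g = [_genotype(doses[i][0]) for doses in per_snp_doses]
        father_g = [_genotype(doses[i][1]) for doses in per_snp_doses]
        child_g = [_genotype(doses[i][2]) for doses in per_snp_doses]
        individuals.append(Individual(fam, "1", None, None, "male", "no", father_g))
        individuals.append(Individual(fam, "2", None, None, "female", "no", mother_g))
        individuals.append(Individual(fam, "3", "1", "2", "female", "yes", child_g))
    snp_map = SnpMap(
        Snp(f"snp{j + 1:04d}", "1", (j + 1) * 1000, RISK, OTHER, RISK)
        for j in range(len(per_snp_doses))
    )
    return individuals, snp_map


def doses_from_cell_counts(cell_counts) -> list[tuple[int, int, int]]:
    """Expand a 15-cell count vector into one dose triple per trio."""
    from triopoo.trio_data import CELL_ORDER

    doses = []
    for cell, count in zip(CELL_ORDER, cell_counts):
        doses.extend([cell] * int(count))
    return doses


@pytest.fixture
def trio_cohort_builder():
    return individuals_from_doses
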