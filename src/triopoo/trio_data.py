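"""Trio genotype data handling: PED/MAP input, pedigree assembly, QC, and
tabulation of case-parent trios into the 15-cell triad table.

A trio is classified at each SNP by the risk-allele dose carried by the
mother (M), father (P) and affected child (C).  Of the 27 ordered dose
triples only 15 are compatible with Mendelian transmission; the counts over
those 15 cells are the sufficient data for the log-linear parent-of-origin
model in :mod:`triopoo.loglinear`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_ORDER",
    "CELL_INDEX",
    "Individual",
    "Snp",
    "SnpMap",
    "Trio",
    "TrioGenotype",
    "CellTable",
    "PedData",
    "QCResult",
    "PedigreeError",
    "PedParseError",
    "parse_ped",
    "parse_map",
    "write_ped",
    "write_map",
    "build_trios",
    "individual_call_rate",
    "snp_call_rate",
    "apply_qc",
    "mendel_check",
    "classify_cell",
    "tabulate",
    "tabulate_doses",
    "flip_risk_allele",
    "trio_mendel_error_rate",
    "mendel_screen",
]

# The fixed cell order of the 15 Mendelian-compatible (M, P, C) dose triples.
# Cells are referred to by their 1-based index throughout.
CELL_ORDER: tuple[tuple[int, int, int], ...] = (
    (2, 2, 2),  # 1
    (2, 1, 2),  # 2
    (2, 1, 1),  # 3
    (1, 2, 2),  # 4
    (1, 2, 1),  # 5
    (2, 0, 1),  # 6
    (0, 2, 1),  # 7
    (1, 1, 2),  # 8
    (1, 1, 1),  # 9
    (1, 1, 0),  # 10
    (1, 0, 1),  # 11
    (1, 0, 0),  # 12
    (0, 1, 1),  # 13
    (0, 1, 0),  # 14
    (0, 0, 0),  # 15
)

#: (M, P, C) triple -> 1-based cell index.
CELL_INDEX: dict[tuple[int, int, int], int] = {
    cell: i + 1 for i, cell in enumerate(CELL_ORDER)
}

# Flat lookup over all 27 ordered triples, keyed by 9*M + 3*P + C;
# -1 marks a Mendelian inconsistency.  Used for vectorised tabulation.
_CELL_LUT = np.full(27, -1, dtype=np.int64)
for _cell, _idx in CELL_INDEX.items():
    _CELL_LUT[9 * _cell[0] + 3 * _cell[1] + _cell[2]] = _idx - 1

# Permutation applied to the 15 counts when the risk allele is flipped,
# i.e. every dose d maps to 2 - d.
_FLIP_PERM = np.array(
    [CELL_INDEX[(2 - m, 2 - p, 2 - c)] - 1 for (m, p, c) in CELL_ORDER]
)


class PedParseError(ValueError):
    """Raised for malformed PED/MAP input; message names the offending line."""


class PedigreeError(ValueError):
    """Raised for internally inconsistent pedigree structure."""


@dataclass
class Individual:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # 'male' | 'female' | 'unknown'
    affected: str  # 'yes' | 'no' | 'unknown'
    #: one (allele, allele) tuple per SNP in map order; None = missing call
    genotypes: list[tuple[str, str] | None] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.individual_id)


@dataclass
class Snp:
    snp_id: str
    chromosome: str
    position: int
    allele_a: str | None = None
    allele_b: str | None = None
    risk_allele: str | None = None


class SnpMap:
    """Ordered collection of SNPs with lookup by id."""

    def __init__(self, snps: Iterable[Snp]):
        self.snps: list[Snp] = list(snps)
        self._index: dict[str, int] = {}
        for i, s in enumerate(self.snps):
            if s.snp_id in self._index:
                raise PedParseError(f"duplicate SNP id {s.snp_id!r} in map")
            self._index[s.snp_id] = i

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def __getitem__(self, snp_id: str) -> Snp:
        return self.snps[self.index_of(snp_id)]

    def set_risk_allele(self, snp_id: str, risk_allele: str) -> None:
        snp = self[snp_id]
        known = {a for a in (snp.allele_a, snp.allele_b) if a is not None}
        if known and risk_allele not in known:
            raise ValueError(
                f"risk allele {risk_allele!r} for {snp_id} is not among the "
                f"observed alleles {sorted(known)}"
            )
        snp.risk_allele = risk_allele

    def subset(self, keep: Sequence[int]) -> "SnpMap":
        return SnpMap(self.snps[i] for i in keep)


@dataclass
class Trio:
    child: Individual
    mother: Individual
    father: Individual

    @property
    def family_id(self) -> str:
        return self.child.family_id


@dataclass(frozen=True)
class TrioGenotype:
    """Risk-allele dose triple (M, P, C) at one SNP; None = missing."""

    M: int | None
    P: int | None
    C: int | None


@dataclass
class CellTable:
    """Counts of trios over the 15 Mendelian-compatible (M, P, C) cells."""

    counts: np.ndarray
    n_excluded_missing: int = 0
    n_mendel_errors: int = 0
    snp_id: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (15,):
            raise ValueError("CellTable requires exactly 15 cell counts")
        if (self.counts < 0).any():
            raise ValueError("cell counts must be non-negative")

    @property
    def n_trios(self) -> int:
        return int(self.counts.sum()) + self.n_excluded_missing + self.n_mendel_errors

    @property
    def n_complete(self) -> int:
        return int(self.counts.sum())


@dataclass
class PedData:
    individuals: list[Individual]
    snp_map: SnpMap
    warnings: list[str] = field(default_factory=list)


@dataclass
class QCResult:
    individuals: list[Individual]
    snp_map: SnpMap
    report: pd.DataFrame  # columns: entity, type, call_rate, action, reason

    @property
    def empty(self) -> bool:
        return len(self.individuals) == 0 or len(self.snp_map) == 0


# ---------------------------------------------------------------------------
# PED / MAP I/O
# ---------------------------------------------------------------------------

_SEX = {"1": "male", "2": "female"}
_AFFECTION = {"2": "yes", "1": "no"}


def parse_map(map_path: str | Path) -> SnpMap:
    """Parse a PLINK-style MAP file (chrom, snp_id, [cM,] position)."""
    snps = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 4:
                chrom, snp_id, _cm, pos = fields
            elif len(fields) == 3:
                chrom, snp_id, pos = fields
            else:
                raise PedParseError(
                    f"{map_path}:{lineno}: expected 3 or 4 columns, got {len(fields)}"
                )
            try:
                position = int(pos)
            except ValueError:
                raise PedParseError(
                    f"{map_path}:{lineno}: position {pos!r} is not an integer"
                ) from None
            snps.append(Snp(snp_id=snp_id, chromosome=chrom, position=position))
    return SnpMap(snps)


def parse_ped(ped_path: str | Path, map_path: str | Path) -> PedData:
    """Parse whitespace-delimited PED + MAP files.

    The PED dialect: 6 pedigree columns (family, individual, father, mother,
    sex, affection) followed by two allele tokens per SNP in map order;
    allele ``"0"`` marks a missing call (a half-missing genotype is treated
    as missing).  Sex 1=male/2=female, affection 2=affected/1=unaffected,
    anything else unknown.
    """
    snp_map = parse_map(map_path)
    n_snps = len(snp_map)
    individuals: list[Individual] = []
    seen: set[tuple[str, str]] = set()
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6 or (len(fields) - 6) % 2:
                raise PedParseError(
                    f"{ped_path}:{lineno}: expected 6 pedigree columns plus an "
                    f"even number of allele columns, got {len(fields)} fields"
                )
            n_geno = (len(fields) - 6) // 2
            if n_geno != n_snps:
                raise PedParseError(
                    f"{ped_path}:{lineno}: {n_geno} genotypes but the map "
                    f"lists {n_snps} SNPs"
                )
            fam, iid, fid, mid, sex, aff = fields[:6]
            genotypes: list[tuple[str, str] | None] = []
            for j in range(n_snps):
                a, b = fields[6 + 2 * j], fields[7 + 2 * j]
                genotypes.append(None if a == "0" or b == "0" else (a, b))
            ind = Individual(
                family_id=fam,
                individual_id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_SEX.get(sex, "unknown"),
                affected=_AFFECTION.get(aff, "unknown"),
                genotypes=genotypes,
            )
            if ind.key in seen:
                raise PedParseError(
                    f"{ped_path}:{lineno}: duplicate individual "
                    f"{iid!r} in family {fam!r}"
                )
            seen.add(ind.key)
            individuals.append(ind)

    # Observed alleles per SNP, for risk-allele validation downstream.
    for j, snp in enumerate(snp_map):
        alleles = sorted(
            {a for ind in individuals if ind.genotypes[j] for a in ind.genotypes[j]}
        )
        if len(alleles) > 2:
            raise PedParseError(
                f"SNP {snp.snp_id} has {len(alleles)} distinct alleles "
                f"{alleles}; only biallelic SNPs are supported"
            )
        snp.allele_a = alleles[0] if alleles else None
        snp.allele_b = alleles[1] if len(alleles) > 1 else None

    warn: list[str] = []
    for ind in individuals:
        for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
            if pid is not None and (ind.family_id, pid) not in seen:
                warn.append(
                    f"{role} {pid!r} of {ind.individual_id!r} "
                    f"(family {ind.family_id!r}) is not in the file"
                )
    return PedData(individuals=individuals, snp_map=snp_map, warnings=warn)


_SEX_CODE = {"male": "1", "female": "2", "unknown": "0"}
_AFF_CODE = {"yes": "2", "no": "1", "unknown": "0"}


def write_ped(individuals: Iterable[Individual], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind in individuals:
            cols = [
                ind.family_id,
                ind.individual_id,
                ind.father_id or "0",
                ind.mother_id or "0",
                _SEX_CODE[ind.sex],
                _AFF_CODE[ind.affected],
            ]
            for g in ind.genotypes:
                cols.extend(g if g is not None else ("0", "0"))
            fh.write("\t".join(cols) + "\n")


def write_map(snp_map: SnpMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for snp in snp_map:
            fh.write(f"{snp.chromosome}\t{snp.snp_id}\t0\t{snp.position}\n")


# ---------------------------------------------------------------------------
# Pedigree assembly
# ---------------------------------------------------------------------------


def build_trios(
    individuals: Sequence[Individual],
) -> tuple[list[Trio], list[str]]:
    """Assemble affected-child case-parent trios.

    Returns the trios plus a report of affected children that could not be
    placed in a complete trio (they are reported, never silently dropped).
    Raises :class:`PedigreeError` if a recorded mother is male or a recorded
    father is female.
    """
    by_key = {ind.key: ind for ind in individuals}
    trios: list[Trio] = []
    report: list[str] = []
    for ind in individuals:
        if ind.affected != "yes":
            continue
        mother = by_key.get((ind.family_id, ind.mother_id)) if ind.mother_id else None
        father = by_key.get((ind.family_id, ind.father_id)) if ind.father_id else None
        if mother is not None and mother.sex == "male":
            raise PedigreeError(
                f"recorded mother {mother.individual_id!r} of "
                f"{ind.individual_id!r} (family {ind.family_id!r}) is male"
            )
        if father is not None and father.sex == "female":
            raise PedigreeError(
                f"recorded father {father.individual_id!r} of "
                f"{ind.individual_id!r} (family {ind.family_id!r}) is female"
            )
        if mother is None or father is None:
            missing = [
                role
                for role, parent in (("mother", mother), ("father", father))
                if parent is None
            ]
            report.append(
                f"affected child {ind.individual_id!r} (family "
                f"{ind.family_id!r}) lacks {' and '.join(missing)}; excluded"
            )
            continue
        trios.append(Trio(child=ind, mother=mother, father=father))
    return trios, report


# ---------------------------------------------------------------------------
# Call rates and QC
# ---------------------------------------------------------------------------


def individual_call_rate(individual: Individual) -> float:
    if not individual.genotypes:
        raise ValueError("individual has no genotypes")
    called = sum(g is not None for g in individual.genotypes)
    return called / len(individual.genotypes)


def snp_call_rate(snp_id: str, individuals: Sequence[Individual], snp_map: SnpMap) -> float:
    if not individuals:
        raise ValueError("no individuals")
    j = snp_map.index_of(snp_id)
    called = sum(ind.genotypes[j] is not None for ind in individuals)
    return called / len(individuals)


def apply_qc(
    individuals: Sequence[Individual],
    snp_map: SnpMap,
    individual_threshold: float = 0.95,
    snp_threshold: float = 0.98,
) -> QCResult:
    """Call-rate QC: drop individuals below ``individual_threshold``, then
    SNPs below ``snp_threshold`` recomputed on the survivors.

    Removing any member of a trio removes the whole trio.  Every removal is
    listed in the report with its reason.  The operation is idempotent.
    """
    for name, thr in (
        ("individual_threshold", individual_threshold),
        ("snp_threshold", snp_threshold),
    ):
        if not (0 < thr <= 1):
            raise ValueError(f"{name} must be in (0, 1], got {thr}")

    records: list[dict] = []
    failed: set[tuple[str, str]] = set()
    rates: dict[tuple[str, str], float] = {}
    for ind in individuals:
        r = individual_call_rate(ind)
        rates[ind.key] = r
        if r < individual_threshold:
            failed.add(ind.key)
            records.append(
                {
                    "entity": f"{ind.family_id}/{ind.individual_id}",
                    "type": "individual",
                    "call_rate": r,
                    "action": "removed",
                    "reason": f"call rate {r:.4f} < {individual_threshold}",
                }
            )

    # A failed member takes its whole trio with it.
    trios, _ = build_trios(individuals)
    casualties: set[tuple[str, str]] = set()
    for trio in trios:
        members = {trio.child.key, trio.mother.key, trio.father.key}
        hit = members & failed
        if hit:
            for ind in (trio.child, trio.mother, trio.father):
                if ind.key not in failed and ind.key not in casualties:
                    casualties.add(ind.key)
                    records.append(
                        {
                            "entity": f"{ind.family_id}/{ind.individual_id}",
                            "type": "individual",
                            "call_rate": rates[ind.key],
                            "action": "removed",
                            "reason": "trio member failed call-rate QC",
                        }
                    )
    removed = failed | casualties
    kept = [ind for ind in individuals if ind.key not in removed]

    keep_cols: list[int] = []
    if kept:
        for j, snp in enumerate(snp_map):
            r = sum(ind.genotypes[j] is not None for ind in kept) / len(kept)
            if r < snp_threshold:
                records.append(
                    {
                        "entity": snp.snp_id,
                        "type": "snp",
                        "call_rate": r,
                        "action": "removed",
                        "reason": f"call rate {r:.4f} < {snp_threshold}",
                    }
                )
            else:
                keep_cols.append(j)
        if len(keep_cols) < len(snp_map):
            kept = [
                replace(ind, genotypes=[ind.genotypes[j] for j in keep_cols])
                for ind in kept
            ]
    new_map = snp_map.subset(keep_cols) if kept else snp_map.subset([])

    report = pd.DataFrame(
        records, columns=["entity", "type", "call_rate", "action", "reason"]
    )
    return QCResult(individuals=kept, snp_map=new_map, report=report)


# ---------------------------------------------------------------------------
# Mendelian classification and tabulation
# ---------------------------------------------------------------------------


def _check_dose(value: int | None, label: str) -> None:
    if value is not None and value not in (0, 1, 2):
        raise ValueError(f"{label} dose must be in {{0, 1, 2}}, got {value!r}")


def mendel_check(t: TrioGenotype) -> str:
    """Classify a dose triple as 'consistent', 'inconsistent' or 'incomplete'."""
    for v, label in ((t.M, "maternal"), (t.P, "paternal"), (t.C, "child")):
        _check_dose(v, label)
    if t.M is None or t.P is None or t.C is None:
        return "incomplete"
    return "consistent" if (t.M, t.P, t.C) in CELL_INDEX else "inconsistent"


def classify_cell(t: TrioGenotype) -> int:
    """1-based cell index of a complete, Mendelian-consistent triple."""
    status = mendel_check(t)
    if status != "consistent":
        raise ValueError(f"classify_cell requires a consistent triple, got {status}")
    return CELL_INDEX[(t.M, t.P, t.C)]


def _dose(genotype: tuple[str, str] | None, risk_allele: str) -> int | None:
    if genotype is None:
        return None
    return sum(a == risk_allele for a in genotype)


def trio_doses(trio: Trio, snp_index: int, risk_allele: str) -> TrioGenotype:
    return TrioGenotype(
        M=_dose(trio.mother.genotypes[snp_index], risk_allele),
        P=_dose(trio.father.genotypes[snp_index], risk_allele),
        C=_dose(trio.child.genotypes[snp_index], risk_allele),
    )


def tabulate(
    trios: Sequence[Trio],
    snp_id: str,
    snp_map: SnpMap,
    risk_allele: str | None = None,
) -> CellTable:
    """Count trios into the 15-cell triad table for one SNP.

    Doses count copies of the risk allele (from ``risk_allele`` or the
    SnpMap entry).  Trios with any missing member genotype are tallied in
    ``n_excluded_missing``; Mendelian-inconsistent complete triples in
    ``n_mendel_errors``; each remaining trio increments exactly one cell.
    """
    j = snp_map.index_of(snp_id)
    ra = risk_allele if risk_allele is not None else snp_map[snp_id].risk_allele
    if ra is None:
        raise ValueError(f"no risk allele configured for SNP {snp_id}")
    counts = np.zeros(15, dtype=np.int64)
    n_missing = 0
    n_mendel = 0
    for trio in trios:
        t = trio_doses(trio, j, ra)
        status = mendel_check(t)
        if status == "incomplete":
            n_missing += 1
        elif status == "inconsistent":
            n_mendel += 1
        else:
            counts[CELL_INDEX[(t.M, t.P, t.C)] - 1] += 1
    return CellTable(
        counts=counts,
        n_excluded_missing=n_missing,
        n_mendel_errors=n_mendel,
        snp_id=snp_id,
    )


def tabulate_doses(
    M: np.ndarray, P: np.ndarray, C: np.ndarray, snp_id: str | None = None
) -> CellTable:
    """Vectorised tabulation from dose arrays; -1 encodes a missing dose."""
    M = np.asarray(M, dtype=np.int64)
    P = np.asarray(P, dtype=np.int64)
    C = np.asarray(C, dtype=np.int64)
    complete = (M >= 0) & (P >= 0) & (C >= 0)
    if ((M > 2) | (P > 2) | (C > 2)).any():
        raise ValueError("doses must be in {0, 1, 2} or -1 for missing")
    code = 9 * M[complete] + 3 * P[complete] + C[complete]
    cells = _CELL_LUT[code]
    consistent = cells >= 0
    counts = np.bincount(cells[consistent], minlength=15)
    return CellTable(
        counts=counts,
        n_excluded_missing=int((~complete).sum()),
        n_mendel_errors=int((~consistent).sum()),
        snp_id=snp_id,
    )


def flip_risk_allele(table: CellTable) -> CellTable:
    """CellTable after relabelling doses d -> 2 - d (an involution)."""
    return CellTable(
        counts=table.counts[_FLIP_PERM],
        n_excluded_missing=table.n_excluded_missing,
        n_mendel_errors=table.n_mendel_errors,
        snp_id=table.snp_id,
    )


def trio_mendel_error_rate(trio: Trio, snp_map: SnpMap) -> float:
    """Fraction of complete per-SNP dose triples that are inconsistent.

    Doses are counted against allele_a; Mendelian consistency does not
    depend on which allele is counted.
    """
    n_complete = 0
    n_bad = 0
    for j, snp in enumerate(snp_map):
        ra = snp.risk_allele or snp.allele_a
        if ra is None:
            continue
        status = mendel_check(trio_doses(trio, j, ra))
        if status == "incomplete":
            continue
        n_complete += 1
        n_bad += status == "inconsistent"
    return n_bad / n_complete if n_complete else 0.0


def mendel_screen(
    trios: Sequence[Trio], snp_map: SnpMap, threshold: float = 0.05
) -> list[tuple[Trio, float]]:
    """Flag trios whose Mendelian-error rate exceeds ``threshold``.

    A gross excess of Mendelian inconsistencies within a trio indicates an
    incorrect family relationship (e.g. non-paternity or a sample swap).
    """
    flagged = []
    for trio in trios:
        rate = trio_mendel_error_rate(trio, snp_map)
        if rate > threshold:
            flagged.append((trio, rate))
            warnings.warn(
                f"trio in family {trio.family_id!r} has Mendelian-error "
                f"rate {rate:.3f} > {threshold}; possible pedigree error",
                stacklevel=2,
            )
    return flagged
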