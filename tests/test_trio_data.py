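"""Unit and property tests for PED input, QC, and triad tabulation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import mendelian_child_doses
from conftest import individuals_from_doses
from triopoo.trio_data import (
    CELL_ORDER,
    CellTable,
    PedigreeError,
    PedParseError,
    TrioGenotype,
    apply_qc,
    build_trios,
    classify_cell,
    flip_risk_allele,
    individual_call_rate,
    mendel_check,
    parse_ped,
    snp_call_rate,
    tabulate,
    tabulate_doses,
    trio_mendel_error_rate,
)

MINIMAL_PED = """\
fam1 1 0 0 1 1 A A A G
fam1 2 0 0 2 1 A G G G
fam1 3 1 2 2 2 A A 0 0
"""

MINIMAL_MAP = """\
1 snp1 0 1000
1 snp2 0 2000
"""


@pytest.fixture
def minimal_files(tmp_path):
    ped = tmp_path / "trio.ped"
    mp = tmp_path / "trio.map"
    ped.write_text(MINIMAL_PED)
    mp.write_text(MINIMAL_MAP)
    return ped, mp


class TestParsePed:
    def test_minimal_well_formed_file(self, minimal_files):
        data = parse_ped(*minimal_files)
        assert len(data.individuals) == 3
        assert all(len(ind.genotypes) == 2 for ind in data.individuals)
        father = data.individuals[0]
        assert father.sex == "male" and father.affected == "no"
        child = data.individuals[2]
        assert child.father_id == "1" and child.mother_id == "2"
        assert child.affected == "yes"
        assert data.warnings == []

    def test_zero_allele_is_missing(self, minimal_files):
        data = parse_ped(*minimal_files)
        assert data.individuals[2].genotypes[1] is None

    def test_wrong_allele_count_names_line(self, tmp_path):
        ped = tmp_path / "bad.ped"
        # 5 allele columns for a 2-SNP map
        ped.write_text("fam1 1 0 0 1 1 A A G G A\n")
        mp = tmp_path / "bad.map"
        mp.write_text(MINIMAL_MAP)
        with pytest.raises(PedParseError, match=r":1:"):
            parse_ped(ped, mp)

    def test_genotype_count_must_match_map(self, tmp_path):
        ped = tmp_path / "short.ped"
        ped.write_text("fam1 1 0 0 1 1 A A\n")
        mp = tmp_path / "short.map"
        mp.write_text(MINIMAL_MAP)
        with pytest.raises(PedParseError, match="1 genotypes"):
            parse_ped(ped, mp)

    def test_unresolved_parent_reference_warns(self, tmp_path):
        ped = tmp_path / "orphan.ped"
        ped.write_text("fam1 3 1 2 2 2 A A\n")
        mp = tmp_path / "one.map"
        mp.write_text("1 snp1 0 1000\n")
        data = parse_ped(ped, mp)
        assert len(data.warnings) == 2  # both parents absent


class TestBuildTrios:
    def test_complete_trio(self, minimal_files):
        data = parse_ped(*minimal_files)
        trios, report = build_trios(data.individuals)
        assert len(trios) == 1 and report == []
        assert trios[0].mother.sex == "female"

    def test_single_parent_child_is_reported(self):
        inds, _ = individuals_from_doses([[(1, 1, 1)]])
        del inds[0]  # drop the father
        trios, report = build_trios(inds)
        assert trios == []
        assert len(report) == 1 and "father" in report[0]

    def test_two_families_two_trios(self):
        inds, _ = individuals_from_doses([[(1, 1, 1), (0, 0, 0)]])
        trios, _ = build_trios(inds)
        assert len(trios) == 2

    def test_male_mother_is_pedigree_error(self):
        inds, _ = individuals_from_doses([[(1, 1, 1)]])
        mother = next(i for i in inds if i.individual_id == "2")
        mother.sex = "male"
        with pytest.raises(PedigreeError, match="mother"):
            build_trios(inds)


class TestCallRates:
    def test_individual_call_rate(self):
        inds, _ = individuals_from_doses([[(1, 1, 1)]] * 20)
        ind = inds[0]
        ind.genotypes[0] = None
        assert individual_call_rate(ind) == pytest.approx(0.95)

    def test_snp_fully_called(self):
        inds, snp_map = individuals_from_doses([[(1, 1, 1), (0, 0, 0)]])
        assert snp_call_rate("snp0001", inds, snp_map) == 1.0

    def test_snp_partially_called(self):
        # 100 individuals, 3 missing at the SNP
        doses = [[(1, 1, 1)] * 34]  # 34 trios -> 102 individuals; trim to 100
        inds, snp_map = individuals_from_doses(doses)
        inds = inds[:100]
        for ind in inds[:3]:
            ind.genotypes[0] = None
        assert snp_call_rate("snp0001", inds, snp_map) == pytest.approx(0.97)

    def test_unknown_snp_raises(self):
        inds, snp_map = individuals_from_doses([[(1, 1, 1)]])
        with pytest.raises(KeyError):
            snp_call_rate("nope", inds, snp_map)


class TestApplyQC:
    def _cohort(self, n_trios=10, n_snps=20):
        return individuals_from_doses([[(1, 1, 1)] * n_trios] * n_snps)

    def test_identity_when_all_called(self):
        inds, snp_map = self._cohort()
        res = apply_qc(inds, snp_map)
        assert len(res.individuals) == len(inds)
        assert len(res.snp_map) == len(snp_map)
        assert res.report.empty

    def test_low_call_rate_parent_removes_whole_trio(self):
        inds, snp_map = self._cohort()
        father = inds[0]
        for j in range(2):  # 18/20 = 0.90 < 0.95
            father.genotypes[j] = None
        res = apply_qc(inds, snp_map)
        trios, _ = build_trios(res.individuals)
        assert len(trios) == 9
        removed = res.report[res.report["type"] == "individual"]
        assert len(removed) == 3  # the parent plus its two trio members
        assert any("call rate" in r for r in removed["reason"])

    def test_snp_below_threshold_removed_after_individuals(self):
        inds, snp_map = self._cohort(n_trios=34)  # 102 individuals
        for ind in inds[:3]:
            ind.genotypes[0] = None  # snp0001 call rate 99/102 = 0.971 < 0.98
        res = apply_qc(inds, snp_map)
        assert "snp0001" not in res.snp_map
        assert len(res.snp_map) == 19
        assert all(len(ind.genotypes) == 19 for ind in res.individuals)

    def test_idempotent(self):
        inds, snp_map = self._cohort()
        inds[0].genotypes[0] = None
        inds[3].genotypes = [None] * 20
        once = apply_qc(inds, snp_map)
        twice = apply_qc(once.individuals, once.snp_map)
        assert [i.key for i in twice.individuals] == [i.key for i in once.individuals]
        assert len(twice.snp_map) == len(once.snp_map)
        assert twice.report.empty

    def test_empty_result_state(self):
        inds, snp_map = self._cohort(n_trios=2)
        for ind in inds:
            ind.genotypes = [None] * 20
        res = apply_qc(inds, snp_map)
        assert res.empty and len(res.individuals) == 0

    def test_synthetic_cohort_retains_243_of_249_trios(self):
        """Six of 249 trios fail call-rate QC, leaving 243 for analysis."""
        inds, snp_map = individuals_from_doses([[(1, 1, 1)] * 249] * 20)
        # One member of each of six distinct trios drops to 90% call rate.
        for k in range(6):
            member = inds[3 * k + (k % 3)]
            member.genotypes[0] = None
            member.genotypes[1] = None
        res = apply_qc(inds, snp_map)
        trios, _ = build_trios(res.individuals)
        assert len(trios) == 243


class TestMendelClassification:
    @pytest.mark.parametrize(
        "triple, expected",
        [((0, 0, 1), "inconsistent"), ((2, 2, 2), "consistent"),
         ((2, 0, 0), "inconsistent"), ((1, None, 1), "incomplete")],
    )
    def test_examples(self, triple, expected):
        assert mendel_check(TrioGenotype(*triple)) == expected

    def test_dose_domain_error(self):
        with pytest.raises(ValueError):
            mendel_check(TrioGenotype(3, 0, 0))

    def test_enumeration_of_all_27_triples(self):
        """Exactly 15 of the 27 dose triples are Mendelian-consistent, and
        classification agrees with an allele-level transmission oracle."""
        consistent = []
        for m in range(3):
            for p in range(3):
                for c in range(3):
                    t = TrioGenotype(m, p, c)
                    ours = mendel_check(t)
                    oracle = "consistent" if c in mendelian_child_doses(m, p) else "inconsistent"
                    assert ours == oracle
                    if ours == "consistent":
                        consistent.append((m, p, c))
                        assert 1 <= classify_cell(t) <= 15
                    else:
                        with pytest.raises(ValueError):
                            classify_cell(t)
        assert len(consistent) == 15
        assert set(consistent) == set(CELL_ORDER)

    def test_cell_indices(self):
        assert classify_cell(TrioGenotype(1, 0, 1)) == 11
        assert classify_cell(TrioGenotype(1, 1, 1)) == 9
        assert classify_cell(TrioGenotype(2, 2, 2)) == 1

    def test_classify_rejects_incomplete(self):
        with pytest.raises(ValueError):
            classify_cell(TrioGenotype(1, 1, None))


class TestTabulate:
    def test_all_wildtype_trios(self):
        inds, snp_map = individuals_from_doses([[(0, 0, 0)] * 10])
        trios, _ = build_trios(inds)
        table = tabulate(trios, "snp0001", snp_map)
        assert table.counts[14] == 10 and table.counts.sum() == 10

    def test_missing_child_genotype_excluded(self):
        inds, snp_map = individuals_from_doses([[(1, 1, None)]])
        trios, _ = build_trios(inds)
        table = tabulate(trios, "snp0001", snp_map)
        assert table.n_excluded_missing == 1
        assert table.counts.sum() == 0

    def test_risk_allele_flip_permutes_cells(self):
        inds, snp_map = individuals_from_doses([[(2, 2, 2)] * 3 + [(1, 0, 1)] * 2])
        trios, _ = build_trios(inds)
        table_a = tabulate(trios, "snp0001", snp_map, risk_allele="A")
        table_b = tabulate(trios, "snp0001", snp_map, risk_allele="B")
        # (2,2,2) <-> (0,0,0) i.e. cell 1 <-> 15; (1,0,1) -> (1,2,1) = cell 5
        assert table_b.counts[14] == 3 and table_b.counts[4] == 2
        np.testing.assert_array_equal(flip_risk_allele(table_a).counts, table_b.counts)

    @given(
        st.lists(
            st.tuples(
                st.one_of(st.none(), st.integers(0, 2)),
                st.one_of(st.none(), st.integers(0, 2)),
                st.one_of(st.none(), st.integers(0, 2)),
            ),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_of_trios(self, doses):
        """sum(counts) + missing + Mendel errors equals the input trio count."""
        inds, snp_map = individuals_from_doses([doses])
        trios, _ = build_trios(inds)
        table = tabulate(trios, "snp0001", snp_map)
        assert table.n_trios == len(doses)
        M = np.array([-1 if d[0] is None else d[0] for d in doses])
        P = np.array([-1 if d[1] is None else d[1] for d in doses])
        C = np.array([-1 if d[2] is None else d[2] for d in doses])
        fast = tabulate_doses(M, P, C)
        np.testing.assert_array_equal(fast.counts, table.counts)
        assert fast.n_excluded_missing == table.n_excluded_missing
        assert fast.n_mendel_errors == table.n_mendel_errors

    @given(st.lists(st.integers(0, 50), min_size=15, max_size=15))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_flip_is_an_involution(self, counts):
        table = CellTable(np.array(counts))
        np.testing.assert_array_equal(
            flip_risk_allele(flip_risk_allele(table)).counts, table.counts
        )

    def test_mendel_error_rate_per_trio(self):
        # 1 inconsistent of 2 complete triples -> rate 0.5
        inds, snp_map = individuals_from_doses([[(0, 0, 0)], [(0, 0, 2)], [(1, 1, None)]])
        trios, _ = build_trios(inds)
        assert trio_mendel_error_rate(trios[0], snp_map) == pytest.approx(0.5)
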