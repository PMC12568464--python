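"""Family partition models, closed forms, entropy tables, consistency checks."""

import math

import pytest
import sympy as sp

from topoentropy import (
    DescriptorSpec,
    closed_form_expression,
    closed_form_index,
    index_from_partition,
    kekulene_partition,
    reference_entropy_table,
    sierpinski_partition,
    validate_partition_realizability,
    verify_closed_forms,
)
from topoentropy.families import (
    FamilyError,
    family_entropy_table,
    family_partition,
    printed_closed_form,
    symbolic_entropy_expression,
    n as n_sym,
)


class TestPartitionModels:
    @pytest.mark.parametrize(
        "stage,expected",
        [
            (1, {(2, 2): 6, (2, 3): 36, (3, 3): 18}),
            (2, {(2, 2): 24, (2, 3): 288, (3, 3): 216}),
            (3, {(2, 2): 192, (2, 3): 2304, (3, 3): 2592}),
        ],
    )
    def test_kekulene_counts(self, stage, expected):
        assert kekulene_partition(stage) == expected

    def test_sierpinski_stage_one(self):
        part = sierpinski_partition(1)
        assert part == {(1, 3): 6, (2, 2): 48, (2, 3): 84, (3, 3): 54, (3, 6): 18}
        assert part.total_edges == 210

    def test_sierpinski_stage_ten_quadratic_class(self):
        assert sierpinski_partition(10)[(2, 2)] == 2649

    @pytest.mark.parametrize("bad", [0, -1, 1.5, "x"])
    def test_invalid_stage_rejected(self, bad):
        with pytest.raises(FamilyError):
            kekulene_partition(bad)

    def test_unknown_family_rejected(self):
        with pytest.raises(FamilyError):
            family_partition("XY", 1)

    @pytest.mark.parametrize("family", ["KE", "SE"])
    def test_counts_nonnegative_integers_up_to_twenty(self, family):
        for stage in range(1, 21):
            part = family_partition(family, stage)
            assert all(isinstance(c, int) and c >= 0 for c in part.values())

    @pytest.mark.parametrize("family", ["KE", "SE"])
    def test_partitions_realizable_up_to_ten(self, family):
        for stage in range(1, 11):
            assert validate_partition_realizability(family_partition(family, stage)).feasible


class TestClosedForms:
    @pytest.mark.parametrize(
        "family,name,stage,expected",
        [
            ("SE", "M1", 1, 1122.0),
            ("SE", "HM", 2, 18544.0),  # 2985*4 + 3223*2 + 158
            ("KE", "HM", 1, 1644.0),
            ("KE", "M1", 2, 2832.0),  # 1200 - 1656 + 1440 + 1296 + 552
        ],
    )
    def test_values(self, family, name, stage, expected):
        assert closed_form_index(family, DescriptorSpec(name), stage) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("family", ["KE", "SE"])
    def test_closed_form_equals_partition_sum(self, family):
        specs = [DescriptorSpec(nm) for nm in ("M1", "R", "GA", "ABC", "H")] + [
            DescriptorSpec("R_alpha", 0.5),
            DescriptorSpec("CHI_alpha", -1.0),
        ]
        for stage in (1, 3, 7):
            part = family_partition(family, stage)
            for spec in specs:
                assert closed_form_index(family, spec, stage) == pytest.approx(
                    index_from_partition(part, spec), rel=1e-12
                )

    def test_zagreb_polynomials_are_exact_integer_identities(self):
        """The published SE Zagreb/hyper-Zagreb polynomials match the
        partition sums exactly at every integer stage."""
        for name, printed in [("M1", None), ("M2", None), ("HM", None)]:
            expr = printed_closed_form("SE", name)
            for stage in range(1, 11):
                exact = int(expr.subs(n_sym, stage))
                part_sum = index_from_partition(
                    sierpinski_partition(stage), DescriptorSpec(name)
                )
                assert part_sum == exact

    def test_published_ke_forms_simplify_to_partition_sums(self):
        for name in ("M1", "M2", "R", "SCI", "HM", "GA", "ABC", "H"):
            diff = sp.simplify(
                printed_closed_form("KE", name) - closed_form_expression("KE", DescriptorSpec(name))
            )
            assert diff == 0


class TestConsistencyVerifier:
    def test_se_harmonic_flagged(self):
        report = verify_closed_forms("SE", range(1, 11))
        assert report.flagged_descriptors() == ["H"]
        bad = [e for e in report.mismatches if e.stage == 1][0]
        assert bad.partition_value == pytest.approx(82.6, rel=1e-9)
        assert bad.closed_form_value == pytest.approx(151.1, rel=1e-9)
        assert "H" in report.known_errata

    def test_se_zagrebs_unflagged(self):
        report = verify_closed_forms("SE", range(1, 11))
        clean = {e.descriptor for e in report.entries if e.match}
        assert {"M1", "M2", "HM"} <= clean

    def test_kekulene_all_consistent(self):
        report = verify_closed_forms("KE", range(1, 11))
        assert report.mismatches == []

    def test_worked_example_coefficient_recorded_exactly(self):
        """The quadratic coefficient of the SE hyper-Zagreb entropy numerator
        is ~10648.4, not the published rounded 10645.4."""
        report = verify_closed_forms("SE", range(1, 3))
        note = next(nt for nt in report.notes if "n^2 coefficient" in nt)
        assert "10648.4" in note
        exact = (
            384 * math.log(16) + 900 * math.log(25)
            + 972 * math.log(36) + 729 * math.log(81)
        )
        assert exact == pytest.approx(10648.4, abs=0.05)

    def test_report_round_trips_to_dict(self):
        d = verify_closed_forms("SE", [1, 2]).to_dict()
        assert d["family"] == "SE" and d["flagged_descriptors"] == ["H"]
        assert len(d["entries"]) == 16  # 8 descriptors x 2 stages


class TestEntropyTables:
    def test_generic_table_shape_and_values(self):
        frame = family_entropy_table("KE", 3)
        assert list(frame.index) == [1, 2, 3]
        assert frame.loc[1, "M1"] == pytest.approx(4.0876, abs=2e-4)

    @pytest.mark.parametrize(
        "family,stage,column,expected",
        [
            ("KE", 1, "EM1", 4.0876),
            ("KE", 1, "EGA", 4.0943),
            ("SE", 1, "ESCI1", 5.3413),
            ("SE", 10, "EH", 9.2524),
        ],
    )
    def test_reference_cells(self, family, stage, column, expected):
        frame = reference_entropy_table(family, n_max=stage)
        assert frame.loc[stage, column] == pytest.approx(expected, abs=2e-3)

    def test_ke_parametric_columns_duplicate_plain_ones(self):
        frame = reference_entropy_table("KE", 4)
        assert (frame["ER"] - frame["ERa"]).abs().max() < 1e-12
        assert (frame["ES1"] - frame["ESa"]).abs().max() < 1e-12

    def test_se_chi_column_equals_harmonic_column(self):
        frame = reference_entropy_table("SE", 4)
        assert (frame["EChia"] - frame["EH"]).abs().max() < 1e-12

    def test_entropy_growth_rate_approaches_log_twelve(self):
        """KE entropies grow linearly in n with slope -> log 12: the (3,3)
        class, growing like 12^n, dominates the edge distribution."""
        frame = family_entropy_table("KE", 41, [DescriptorSpec("M1")], n_min=40)
        spacing = frame["M1"].diff().iloc[-1]
        assert spacing == pytest.approx(math.log(12), abs=1e-3)


class TestSymbolicEntropy:
    def test_symbolic_matches_numeric_hyper_zagreb(self):
        expr = symbolic_entropy_expression("SE", DescriptorSpec("HM"))
        from topoentropy import entropy_from_partition

        for stage in (1, 4, 9):
            symbolic = float(expr.subs(n_sym, stage).evalf(30))
            numeric = entropy_from_partition(
                sierpinski_partition(stage), DescriptorSpec("HM")
            ).value
            assert symbolic == pytest.approx(numeric, abs=1e-12)
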