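"""Index parsing, cost matrices, objective functions and deviation analytics."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sgcopt.genetic_code import (
    AA_INDEX,
    CODON_INDEX,
    GeneticCode,
    SENSE_CODON_INDICES,
    random_code,
)
from sgcopt.objectives import (
    AAindexFormatError,
    AminoAcidIndex,
    CostMatrix,
    DEFAULT_ACCESSIONS,
    DegenerateIndexError,
    cost_matrix,
    deviation_table,
    evaluate_objectives,
    objective_value,
    parse_aaindex,
    spearman,
    write_aaindex,
)


def make_index(values, accession="TEST000001"):
    return AminoAcidIndex(accession, np.asarray(values, dtype=float))


class TestParseAAindex:
    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        original = [make_index(rng.random(20), f"RT{i:07d}") for i in range(3)]
        buf = io.StringIO()
        write_aaindex(original, buf)
        back = parse_aaindex(buf.getvalue())
        assert [i.accession for i in back] == [i.accession for i in original]
        for a, b in zip(original, back):
            np.testing.assert_allclose(a.values, b.values, atol=1e-6)

    def test_constant_record_accepted(self):
        buf = io.StringIO()
        write_aaindex([make_index(np.ones(20))], buf)
        (idx,) = parse_aaindex(buf.getvalue())
        assert idx.is_constant

    @pytest.mark.parametrize(
        "record,match",
        [
            ("H BAD0000001\nI h\n 1 2 3\n//", "expected 20"),
            ("I h\n" + " 1" * 20 + "\n//", "without an H"),
            ("H NAX0000001\nI h\n" + " 1" * 19 + " NA\n//", "NA"),
        ],
    )
    def test_malformed_records(self, record, match):
        with pytest.raises(AAindexFormatError, match=match):
            parse_aaindex(record)


class TestBuiltinIndices:
    def test_eight_accessions_with_finite_values(self, indices8):
        assert tuple(i.accession for i in indices8) == DEFAULT_ACCESSIONS
        for idx in indices8:
            assert np.isfinite(idx.values).all() and not idx.is_constant

    def test_deviations_match_reference_grid(self, indices8, ref_table):
        """Every builtin scale reproduces the reference deviation profile."""
        table = deviation_table(indices8)
        for idx in indices8:
            got = table[idx.accession].round(3)
            want = ref_table[idx.accession]
            assert (got == want).all(), idx.accession

    def test_row_averages_match_reference(self, indices8, ref_table):
        table = deviation_table(indices8)
        acc = list(DEFAULT_ACCESSIONS)
        # the reference averages come from unrounded deviations, so both the
        # recomputed averages and the tabulated row means agree to 0.001
        printed_mean = ref_table[acc].mean(axis=1)
        assert (printed_mean - ref_table["average"]).abs().max() <= 0.001
        assert (table["average"].round(3) - ref_table["average"]).abs().max() <= 0.001


class TestCostMatrix:
    def test_constant_index_degenerate(self):
        m = cost_matrix(make_index(np.ones(20)))
        assert m.degenerate and (m.costs == 0).all()

    def test_two_level_example(self):
        # Gly = 0, Ala = 1, everything else 0.5
        values = np.full(20, 0.5)
        values[AA_INDEX["G"]] = 0.0
        values[AA_INDEX["A"]] = 1.0
        m = cost_matrix(make_index(values))
        g, a, s = AA_INDEX["G"], AA_INDEX["A"], AA_INDEX["S"]
        assert m.costs[g, a] == 1.0
        assert m.costs[g, s] == 0.25
        assert m.costs.max() == 1.0

    def test_symmetry_and_diagonal(self, matrices8):
        for m in matrices8:
            assert np.allclose(m.costs, m.costs.T)
            assert (np.diag(m.costs) == 0).all()
            assert m.costs.max() == 1.0 and m.costs.min() >= 0.0

    @settings(derandomize=True, max_examples=40)
    @given(
        a=st.floats(min_value=-50, max_value=50).filter(lambda x: abs(x) > 1e-3),
        b=st.floats(min_value=-50, max_value=50),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(77)
        v = rng.random(20)
        base = cost_matrix(make_index(v)).costs
        scaled = cost_matrix(make_index(a * v + b)).costs
        np.testing.assert_allclose(scaled, base, atol=1e-9)


class TestObjectiveValue:
    def test_constant_matrix_gives_zero(self, sgc, pairs_sense):
        m = cost_matrix(make_index(np.ones(20)))
        assert objective_value(sgc, m, pairs_sense) == 0.0

    def test_isolated_costly_pair(self, pairs_sense):
        """A code whose only costly contacts are AAA(Gly) vs its Ala
        neighbours scores 8: AAA has 9 neighbours, one of them a stop."""
        arr = np.full(64, AA_INDEX["A"], dtype=np.int8)
        for stop in ("UAA", "UAG", "UGA"):
            arr[CODON_INDEX[stop]] = 20
        arr[CODON_INDEX["AAA"]] = AA_INDEX["G"]
        # park the other 18 amino acids on codons that are neither AAA nor
        # any of its single-substitution neighbours
        others = [a for a in range(20) if a not in (AA_INDEX["A"], AA_INDEX["G"])]
        parking = [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 12, 13, 15, 16, 17, 18, 19, 20]
        for aa, ci in zip(others, parking):
            arr[ci] = aa
        code = GeneticCode(arr, model="US")
        costs = np.zeros((20, 20))
        costs[AA_INDEX["A"], AA_INDEX["G"]] = 1.0
        costs[AA_INDEX["G"], AA_INDEX["A"]] = 1.0
        m = CostMatrix(costs, "HAND000001")
        assert objective_value(code, m, pairs_sense) == 8.0

    def test_matches_brute_force(self, matrices8, pairs_sense,
                                 brute_force_objective):
        rng = np.random.default_rng(21)
        for _ in range(12):
            code = random_code(rng.choice(["BS", "US"]), rng)
            m = matrices8[int(rng.integers(len(matrices8)))]
            fast = objective_value(code, m, pairs_sense)
            assert fast == pytest.approx(brute_force_objective(code, m))

    def test_relabeling_invariance(self, matrices8, pairs_sense):
        """Renaming amino acids consistently in code and matrix is a no-op."""
        rng = np.random.default_rng(31)
        perm = rng.permutation(20)
        inv = np.argsort(perm)
        code = random_code("US", rng)
        relabeled = code.assignment.copy()
        sense = SENSE_CODON_INDICES
        relabeled[sense] = perm[code.assignment[sense]]
        recoded = GeneticCode(relabeled, model="US")
        for m in matrices8[:3]:
            # relabeled_costs[perm[a], perm[b]] == costs[a, b]
            relabeled_m = CostMatrix(
                m.costs[np.ix_(inv, inv)], m.source_accession
            )
            before = objective_value(code, m, pairs_sense)
            after = objective_value(recoded, relabeled_m, pairs_sense)
            assert after == pytest.approx(before)


class TestEvaluateObjectives:
    def test_vector_shape_and_order(self, sgc, matrices8):
        vec = evaluate_objectives(sgc, matrices8)
        assert len(vec) == 8
        assert vec.accessions == DEFAULT_ACCESSIONS
        assert (vec.values > 0).all()

    def test_duplicate_matrices_equal_components(self, sgc, matrices8):
        vec = evaluate_objectives(sgc, [matrices8[0], matrices8[0]])
        assert vec.values[0] == vec.values[1]

    def test_all_constant_gives_zero_vector(self, sgc):
        mats = [cost_matrix(make_index(np.ones(20)))] * 3
        assert (evaluate_objectives(sgc, mats).values == 0).all()

    def test_bs_codes_same_permutation_same_vector(self, matrices8):
        rng = np.random.default_rng(9)
        perm = rng.permutation(20)
        c1 = GeneticCode.from_permutation(perm)
        c2 = GeneticCode.from_permutation(perm.copy())
        v1 = evaluate_objectives(c1, matrices8).values
        v2 = evaluate_objectives(c2, matrices8).values
        np.testing.assert_array_equal(v1, v2)


class TestDeviationTable:
    def test_threonine_row_average(self, indices8):
        table = deviation_table(indices8)
        assert round(table.loc["Thr", "average"], 3) == 0.130

    def test_two_index_averaging(self):
        rng = np.random.default_rng(3)
        i1 = make_index(rng.random(20), "SYN0000A1")
        i2 = make_index(rng.random(20) + 0.5, "SYN0000A2")
        table = deviation_table([i1, i2])
        expected = (table["SYN0000A1"] + table["SYN0000A2"]) / 2
        np.testing.assert_allclose(table["average"], expected)
        assert ((table["average"] >= 0) & (table["average"] <= 1)).all()

    def test_value_at_mean_deviates_zero(self):
        # build an index whose Ala value equals the mean of all 20 values
        v = np.linspace(0.2, 1.0, 20)
        target = (v.sum() - v[AA_INDEX["A"]]) / 19
        v[AA_INDEX["A"]] = target  # now mean == target
        table = deviation_table([make_index(v / v.max())])
        assert table.loc["Ala"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_index_rejected(self):
        with pytest.raises(DegenerateIndexError):
            deviation_table([make_index(np.ones(20))])


class TestSpearman:
    def test_reference_correlations(self, ref_table):
        rho, p = spearman(ref_table["codons_best_us"], ref_table["average"])
        assert round(rho, 3) == -0.659
        assert round(p, 4) == 0.0016
        rho2, p2 = spearman(ref_table["codons_sgc"], ref_table["average"])
        assert round(rho2, 3) == -0.163
        assert round(p2, 2) == 0.49

    def test_monotone_is_one(self):
        x = np.arange(20, dtype=float)
        assert spearman(x, x ** 3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateIndexError):
            spearman(np.ones(20), np.arange(20, dtype=float))
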