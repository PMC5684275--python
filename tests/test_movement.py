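import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zlink import movement as mv


def oracle_polarise(bm, co, nd, ts):
    """Independent per-gene application of the polarisation rules, written
    directly from their verbal statement (True = Z-linked).

    Returns (ancestral, at_ditrysia_adelidae_node, unpolarized,
    onto branches, off branches)."""
    onto, off = [], []
    ancestral = ts and (bm or co or nd)
    at_node = ancestral or (bm and co and nd and not ts)
    unpolarized = ts and not (bm or co or nd)
    if ancestral:
        if (not bm) and (not co):
            off.append("ditrysia_root")  # autosomal in the two Ditrysia only
        else:
            if not bm:
                off.append("bmori")
            if not co:
                off.append("cohridella")
        if not nd:
            off.append("ndegeerella")
    elif not ts:
        if bm and co and nd:
            onto.append("ditrysia_plus_adelidae")
        elif bm and co:
            onto.append("ditrysia_root")  # Z in the two Ditrysia only
        else:
            for name, state in (("bmori", bm), ("cohridella", co),
                                ("ndegeerella", nd)):
                if state:
                    onto.append(name)
    return ancestral, at_node, unpolarized, onto, off


def oracle_summary(matrix: pd.DataFrame):
    """Brute-force per-gene accumulation over the classified rows."""
    onto = {b: 0 for b in mv.BRANCHES}
    off = {b: 0 for b in mv.BRANCHES}
    ancestral = at_node = unpol = 0
    classified = 0
    for _, row in matrix.iterrows():
        states = [row[sp] for sp in mv.SPECIES]
        if any(s not in ("Z", "A") for s in states):
            continue
        classified += 1
        a, n_, u, o, f = oracle_polarise(*(s == "Z" for s in states))
        ancestral += a
        at_node += n_
        unpol += u
        for b in o:
            onto[b] += 1
        for b in f:
            off[b] += 1
    return classified, ancestral, at_node, unpol, onto, off


def assert_matches_oracle(matrix):
    summary = mv.infer_movement(matrix)
    classified, anc, at_node, unpol, onto, off = oracle_summary(matrix)
    assert summary.n_classified == classified
    assert summary.ancestral_z_count == anc
    assert summary.ancestral_ditrysia_adelidae_count == at_node
    assert summary.unpolarized_outgroup_only == unpol
    assert summary.onto_z == onto
    assert summary.off_z == off


def matrix_from(rows):
    df = pd.DataFrame(rows, columns=list(mv.SPECIES))
    df.index = pd.Index([f"g{i}" for i in range(len(df))], name="gene")
    return df


class TestPatternRules:
    def test_all_16_patterns_match_oracle(self):
        for pattern in itertools.product("ZA", repeat=4):
            rule = mv.PATTERN_RULES[tuple(s == "Z" for s in pattern)]
            a, n_, u, onto, off = oracle_polarise(*(s == "Z" for s in pattern))
            assert rule.ancestral_z == a, pattern
            assert rule.at_ditrysia_adelidae_node == n_, pattern
            assert rule.unpolarized == u, pattern
            assert sorted(rule.onto_z) == sorted(onto), pattern
            assert sorted(rule.off_z) == sorted(off), pattern

    def test_every_pattern_in_exactly_one_category(self):
        """Ancestral / gained somewhere / outgroup-only / all-autosomal
        partition the 16 Z/A patterns."""
        for flags, rule in mv.PATTERN_RULES.items():
            all_a = not any(flags)
            categories = [rule.ancestral_z, bool(rule.onto_z),
                          rule.unpolarized, all_a]
            assert sum(categories) == 1, flags

    def test_losses_only_from_ancestral_genes(self):
        for flags, rule in mv.PATTERN_RULES.items():
            if rule.off_z:
                assert rule.ancestral_z, flags


class TestInferMovement:
    def test_all_autosomal_matrix_yields_zero_everywhere(self):
        summary = mv.infer_movement(matrix_from([("A",) * 4] * 20))
        assert summary.ancestral_z_count == 0
        assert set(summary.onto_z.values()) == {0}
        assert set(summary.off_z.values()) == {0}

    def test_all_ancestral_z_yields_zero_moves(self):
        summary = mv.infer_movement(matrix_from([("Z",) * 4] * 20))
        assert summary.ancestral_z_count == 20
        assert set(summary.onto_z.values()) == {0}
        assert set(summary.off_z.values()) == {0}

    def test_six_gene_matrix_covering_each_rule(self):
        rows = [
            ("Z", "Z", "Z", "Z"),  # ancestral, no events
            ("A", "Z", "Z", "Z"),  # ancestral, off bmori
            ("Z", "Z", "A", "A"),  # onto at Ditrysia root
            ("A", "Z", "A", "A"),  # onto cohridella
            ("A", "A", "A", "Z"),  # outgroup-only, unpolarized
            ("A", "A", "A", "A"),  # nothing
        ]
        assert_matches_oracle(matrix_from(rows))
        summary = mv.infer_movement(matrix_from(rows))
        assert summary.ancestral_z_count == 2
        assert summary.onto_z["ditrysia_root"] == 1
        assert summary.onto_z["cohridella"] == 1
        assert summary.off_z["bmori"] == 1
        assert summary.unpolarized_outgroup_only == 1

    def test_rows_with_u_are_excluded(self):
        rows = [("Z", "Z", "Z", "Z"), ("Z", "U", "Z", "Z")]
        summary = mv.infer_movement(matrix_from(rows))
        assert summary.n_classified == 1

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(
        st.tuples(*[st.sampled_from(["Z", "A", "U"])] * 4),
        min_size=0, max_size=40,
    ))
    def test_random_matrices_match_brute_force(self, rows):
        assert_matches_oracle(matrix_from(rows))


class TestBuildLinkageMatrix:
    def _inputs(self):
        labels = {
            sp: pd.Series({"sZ": "Z", "sA": "A", "sU": "unclassified"})
            for sp in mv.SPECIES
        }
        placements = {
            sp: pd.Series({"g1": "sZ", "g2": "sA", "g3": "sU"})
            for sp in mv.SPECIES
        }
        return labels, placements

    def test_gene_states_inherit_scaffold_labels(self):
        labels, placements = self._inputs()
        matrix = mv.build_linkage_matrix(labels, placements)
        assert (matrix.loc["g1"] == "Z").all()
        assert (matrix.loc["g2"] == "A").all()

    def test_unclassified_scaffold_excludes_gene(self):
        labels, placements = self._inputs()
        matrix = mv.build_linkage_matrix(labels, placements)
        assert (matrix.loc["g3"] == "U").all()
        assert "g3" not in mv.classified_subset(matrix).index

    def test_gene_missing_in_one_species_gets_u(self):
        labels, placements = self._inputs()
        placements["bmori"] = placements["bmori"].drop("g1")
        matrix = mv.build_linkage_matrix(labels, placements)
        assert matrix.loc["g1", "bmori"] == "U"
        assert "g1" not in mv.classified_subset(matrix).index

    def test_duplicate_gene_placement_is_error(self):
        labels, placements = self._inputs()
        dup = pd.Series(["sZ", "sA"], index=["g1", "g1"])
        placements["bmori"] = dup
        with pytest.raises(ValueError, match="g1"):
            mv.build_linkage_matrix(labels, placements)


class TestRescaleTotal:
    def test_in_sample_worked_example(self):
        raw, rounded = mv.rescale_total(5, 86, 654)
        assert rounded == 38
        assert raw == pytest.approx(5 * 654 / 86)
        assert mv.sampling_fraction_percent(86, 654) == 13

    def test_zero_moves(self):
        assert mv.rescale_total(0, 50, 500) == (0.0, 0)

    def test_factor_two_fraction(self):
        assert mv.rescale_total(10, 100, 200)[1] == 20

    def test_linear_in_moves_and_inverse_in_fraction(self):
        base, _ = mv.rescale_total(7, 90, 600)
        assert mv.rescale_total(14, 90, 600)[0] == pytest.approx(2 * base)
        assert mv.rescale_total(7, 45, 600)[0] == pytest.approx(2 * base)

    def test_zero_sampling_fraction_is_error(self):
        with pytest.raises(ValueError):
            mv.rescale_total(5, 0, 654)


class TestCompareBranchRates:
    def test_identical_rates_give_zero_statistic(self):
        res = mv.compare_branch_rates({"x": 5, "y": 5}, {"x": 50, "y": 50})
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_2x2_matches_closed_form(self):
        # chi2 = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) without continuity corr.
        a, b, c, d = 5, 72, 10, 70
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        res = mv.compare_branch_rates({"x": a, "y": c}, {"x": a + b, "y": c + d})
        assert res["statistic"] == pytest.approx(expected)
        assert res["df"] == 1

    def test_extreme_excess_branch_is_significant(self):
        res = mv.compare_branch_rates({"c": 91, "others": 5},
                                      {"c": 168, "others": 77})
        assert res["p"] < 0.05

    def test_tiny_expected_cell_warns(self):
        with pytest.warns(UserWarning, match="exact"):
            mv.compare_branch_rates({"x": 0, "y": 1}, {"x": 3, "y": 400})
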