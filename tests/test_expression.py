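import itertools
import math

import numpy as np
import pytest

from chitfam.expression import (
    CtRecord,
    DilutionSeries,
    arcsine_sqrt,
    lsd_letters,
    lsd_significance_matrix,
    primer_efficiency,
    relative_expression,
    replicate_folds,
)


class TestPrimerEfficiency:
    def test_perfect_doubling_slope_gives_full_efficiency(self):
        slope = -math.log2(10)  # -3.3219: Ct rises 3.3219 per 10-fold dilution
        series = DilutionSeries((0, -1, -2, -3), tuple(20 + slope * x for x in (0, -1, -2, -3)))
        eff, m, accepted = primer_efficiency(series)
        assert eff == pytest.approx(1.0, abs=1e-9)
        assert m == pytest.approx(slope)
        assert accepted

    def test_shallow_slope_rejected_under_the_ninety_percent_rule(self):
        series = DilutionSeries((0, -1, -2, -3), (20.0, 23.6, 27.2, 30.8))  # slope -3.6
        eff, slope, accepted = primer_efficiency(series)
        assert slope == pytest.approx(-3.6)
        assert eff == pytest.approx(10 ** (1 / 3.6) - 1, abs=1e-9)  # ~0.8957
        assert eff < 0.9 and not accepted

    def test_zero_variance_series_errors(self):
        with pytest.raises(ValueError):
            primer_efficiency(DilutionSeries((0, 0, 0), (20, 21, 22)))
        with pytest.raises(ValueError):
            primer_efficiency(DilutionSeries((0, -1, -2), (20, 20, 20)))


def _ct(sample, gene, rep, ct):
    return CtRecord(sample, gene, rep, ct)


class TestRelativeExpression:
    def test_identical_cts_give_unit_fold_everywhere(self):
        records = []
        for s in ("egg", "larva"):
            for g in ("target", "ref"):
                records += [_ct(s, g, r, 24.0) for r in (1, 2, 3)]
        results = relative_expression(records, "ref", "egg")
        assert all(r.fold_change == pytest.approx(1.0) for r in results)

    def test_one_cycle_advantage_doubles_expression(self):
        records = [
            _ct("egg", "t", 1, 24.0), _ct("egg", "ref", 1, 20.0),
            _ct("larva", "t", 1, 23.0), _ct("larva", "ref", 1, 20.0),
        ]
        by_sample = {r.sample: r for r in relative_expression(records, "ref", "egg")}
        assert by_sample["larva"].fold_change == pytest.approx(2.0)
        assert by_sample["egg"].fold_change == pytest.approx(1.0)

    def test_total_rna_mode_ignores_reference(self):
        records = [
            _ct("egg", "t", 1, 24.0),
            _ct("larva", "t", 1, 21.0),
        ]
        by_sample = {
            r.sample: r
            for r in relative_expression(records, None, "egg", mode="total_rna")
        }
        assert by_sample["larva"].fold_change == pytest.approx(8.0)

    def test_reference_gene_against_itself_is_unity(self):
        # a target with the reference gene's exact Ct values normalizes to 1
        rng = np.random.default_rng(0)
        records = []
        for s in ("a", "b", "c"):
            ct = float(rng.uniform(18, 25))
            records += [_ct(s, "ref", r, ct) for r in (1, 2)]
            records += [_ct(s, "refcopy", r, ct) for r in (1, 2)]
        results = relative_expression(records, "ref", "a")
        assert results and all(
            r.fold_change == pytest.approx(1.0) and r.rev == pytest.approx(1.0)
            for r in results
        )

    def test_fold_invariant_to_adding_constant_to_all_cts(self):
        rng = np.random.default_rng(1)
        base = []
        for s in ("a", "b"):
            for g in ("t", "ref"):
                base += [_ct(s, g, r, float(rng.uniform(18, 28))) for r in (1, 2, 3)]
        shifted = [_ct(r.sample, r.gene, r.replicate, r.ct + 3.7) for r in base]
        f1 = {(r.sample, r.gene): r.fold_change for r in relative_expression(base, "ref", "a")}
        f2 = {(r.sample, r.gene): r.fold_change
              for r in relative_expression(shifted, "ref", "a")}
        for key in f1:
            assert f1[key] == pytest.approx(f2[key])

    def test_random_tables_match_step_by_step_oracle(self):
        rng = np.random.default_rng(2)
        samples = ["s1", "s2", "s3"]
        records = []
        truth_ct = {}
        for s in samples:
            for g in ("t", "ref"):
                cts = rng.uniform(18, 30, size=3)
                truth_ct[(s, g)] = cts
                records += [_ct(s, g, k + 1, float(c)) for k, c in enumerate(cts)]
        results = {
            r.sample: r for r in relative_expression(records, "ref", "s1")
        }
        for s in samples:
            dct = truth_ct[(s, "t")].mean() - truth_ct[(s, "ref")].mean()
            dct_cal = truth_ct[("s1", "t")].mean() - truth_ct[("s1", "ref")].mean()
            assert results[s].delta_ct == pytest.approx(dct)
            assert results[s].fold_change == pytest.approx(2 ** -(dct - dct_cal))
            assert results[s].rev == pytest.approx(2 ** -dct)

    def test_missing_reference_names_the_sample(self):
        records = [
            _ct("egg", "t", 1, 24.0), _ct("egg", "ref", 1, 20.0),
            _ct("larva", "t", 1, 23.0),
        ]
        with pytest.raises(ValueError, match="larva"):
            relative_expression(records, "ref", "egg")

    def test_replicate_folds_pair_by_index(self):
        records = [
            _ct("a", "t", 1, 24.0), _ct("a", "t", 2, 25.0),
            _ct("a", "ref", 1, 20.0), _ct("a", "ref", 2, 20.0),
            _ct("b", "t", 1, 22.0), _ct("b", "t", 2, 23.0),
            _ct("b", "ref", 1, 20.0), _ct("b", "ref", 2, 20.0),
        ]
        folds = replicate_folds(records, "t", "ref", "a")
        cal_dct = (24.5 - 20.0)
        assert folds["b"] == pytest.approx([2 ** -(2.0 - cal_dct), 2 ** -(3.0 - cal_dct)])


class TestLsdLetters:
    def test_transform_endpoints(self):
        assert arcsine_sqrt(0.0) == 0.0
        assert arcsine_sqrt(1.0) == pytest.approx(math.pi / 2)

    def test_identical_groups_share_one_letter(self):
        letters = lsd_letters({"a": [0.5, 0.5, 0.5], "b": [0.5, 0.5, 0.5]})
        assert letters["a"] == letters["b"]

    def test_widely_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(3)
        low = list(0.05 + 0.001 * rng.standard_normal(3))
        high = list(0.9 + 0.001 * rng.standard_normal(3))
        letters = lsd_letters({"lo": low, "hi": high})
        assert set(letters["lo"]).isdisjoint(set(letters["hi"]))

    def test_letters_consistent_with_pairwise_matrix_on_fuzzed_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            k = int(rng.integers(2, 6))
            values = {
                f"g{i}": list(rng.uniform(0.05, 1.0) + 0.02 * rng.standard_normal(4))
                for i in range(k)
            }
            values = {n: [min(max(v, 1e-3), 5.0) for v in vs] for n, vs in values.items()}
            sig = lsd_significance_matrix(values)
            letters = lsd_letters(values)
            for a, b in itertools.combinations(sorted(values), 2):
                share = bool(set(letters[a]) & set(letters[b]))
                assert share != sig[(a, b)], (
                    f"{a},{b}: significant={sig[(a, b)]} letters={letters}"
                )

    def test_single_replicate_group_rejected(self):
        with pytest.raises(ValueError):
            lsd_letters({"a": [0.5], "b": [0.4, 0.5]})
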