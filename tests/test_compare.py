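"""Condition comparisons, significance, conformational classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scamflux import ConfigurationError
from scamflux import compare


def _cmp(a, b, **kw):
    return compare.compare_conditions(
        {i + 1: v for i, v in enumerate(a)}, {i + 1: v for i, v in enumerate(b)}, **kw
    )


class TestFoldChange:
    def test_printed_cytoplasmic_rate_constants(self):
        # reporter cysteine vs cysteine-less background, MTSEA
        assert compare.fold_change(11.97, 0.05) == pytest.approx(239.4)

    def test_control_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            compare.fold_change(1.0, 0.0)


class TestCompareConditions:
    def test_identical_values_unchanged(self):
        res = _cmp([2.0, 2.1, 1.9], [2.0, 2.1, 1.9])
        assert res.fold == pytest.approx(1.0)
        assert res.direction == "unchanged"
        assert res.p_value == 1.0

    def test_paired_t_statistic_matches_closed_form(self):
        """Hand-checkable oracle: p = 2 * sf(t) with sf(t) for df = 2 equal
        to (1 - t/sqrt(t^2 + 2))/2."""
        a, b = [2.0, 2.1, 1.9], [1.0, 1.05, 0.95]
        diffs = np.subtract(a, b)
        t = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(3))
        p_oracle = 1.0 - t / math.sqrt(t**2 + 2.0)
        res = _cmp(a, b)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)
        assert res.fold == pytest.approx(2.0, rel=0.01)
        assert res.direction == "increased"

    def test_unpaired_experiments_rejected(self):
        with pytest.raises(ConfigurationError, match="unpaired"):
            compare.compare_conditions({1: 1.0, 2: 1.0}, {1: 1.0, 3: 1.0})

    def test_needs_two_pairs(self):
        with pytest.raises(ConfigurationError):
            compare.compare_conditions({1: 1.0}, {1: 2.0})

    def test_small_fold_stays_unchanged_even_if_significant(self):
        res = _cmp([1.05, 1.051, 1.049], [1.0, 1.001, 0.999], min_fold=1.1)
        assert res.direction == "unchanged"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        vals=st.lists(
            st.tuples(st.floats(0.1, 10.0), st.floats(0.1, 10.0)), min_size=3, max_size=6
        )
    )
    def test_swapping_inverts_fold_and_preserves_p(self, vals):
        a = [x for x, _ in vals]
        b = [y for _, y in vals]
        fwd, rev = _cmp(a, b), _cmp(b, a)
        assert fwd.fold * rev.fold == pytest.approx(1.0, rel=1e-9)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-9)

    def test_false_positive_rate_controlled(self):
        """With no true effect (fold 1) and experiment-level noise, the
        'significant' rate at alpha 0.05 stays at or below 7%."""
        rng = np.random.default_rng(123)
        hits = 0
        n = 200
        for _ in range(n):
            base = rng.lognormal(math.log(70), 0.05, 3)
            cond = base * rng.lognormal(0.0, 0.08, 3)
            ctrl = base * rng.lognormal(0.0, 0.08, 3)
            if _cmp(cond, ctrl).direction != "unchanged":
                hits += 1
        assert hits / n <= 0.07


class TestConformationCalls:
    @staticmethod
    def _result(direction, fold, pathway):
        return compare.ComparisonResult(
            condition="drug", control="none", fold=fold, per_experiment_folds={},
            p_value=0.01 if direction != "unchanged" else 0.5,
            direction=direction, pathway=pathway,
        )

    def test_antidepressant_pattern_is_outward_open(self):
        call = compare.call_conformation(
            self._result("increased", 2.0, "extracellular"),
            self._result("decreased", 0.5, "cytoplasmic"),
        )
        assert call.call == "outward-open stabilized"

    def test_substrate_pattern_is_inward_open(self):
        call = compare.call_conformation(
            self._result("decreased", 0.5, "extracellular"),
            self._result("increased", 2.0, "cytoplasmic"),
        )
        assert call.call == "inward-open shifted"

    def test_weak_inward_pattern_is_partial(self):
        call = compare.call_conformation(
            self._result("decreased", 0.75, "extracellular"),
            self._result("increased", 1.4, "cytoplasmic"),
        )
        assert call.call == "partial/intermediate"

    def test_inert_ligand_pattern_is_no_change(self):
        call = compare.call_conformation(
            self._result("unchanged", 1.0, "extracellular"),
            self._result("unchanged", 1.0, "cytoplasmic"),
        )
        assert call.call == "no change"

    def test_same_direction_both_pathways_is_discordant(self):
        call = compare.call_conformation(
            self._result("increased", 2.0, "extracellular"),
            self._result("increased", 2.0, "cytoplasmic"),
        )
        assert call.call == "discordant"

    def test_mismatched_controls_rejected(self):
        ex = self._result("increased", 2.0, "extracellular")
        cy = compare.ComparisonResult(
            condition="drug", control="other", fold=0.5, per_experiment_folds={},
            p_value=0.01, direction="decreased", pathway="cytoplasmic",
        )
        with pytest.raises(ConfigurationError):
            compare.call_conformation(ex, cy)


class TestIonPanelAnalysis:
    @staticmethod
    def _k_by_medium(folds, base=70.0, sd=0.04, seed=5):
        rng = np.random.default_rng(seed)
        return {
            medium: {e: base * f * rng.lognormal(0, sd) for e in (1, 2, 3)}
            for medium, f in folds.items()
        }

    EX_FOLDS = {
        "NMDG-gluconate": 1.0, "NMDG-Cl": 1.0, "Na-isethionate": 1.8,
        "NaCl": 1.4, "NaCl+5-HT": 0.7,
    }

    def test_extracellular_pattern_recovered(self):
        panel = compare.ion_panel_analysis(self._k_by_medium(self.EX_FOLDS), "extracellular")
        d = {(c.condition, c.control): c.direction for c in panel.comparisons}
        assert d[("Na-isethionate", "NMDG-gluconate")] == "increased"
        assert d[("NaCl+5-HT", "NaCl")] == "decreased"
        assert panel.cl_signature

    def test_cytoplasmic_mirror_pattern(self):
        folds = {m: 1.0 / f for m, f in self.EX_FOLDS.items()}
        panel = compare.ion_panel_analysis(
            self._k_by_medium(folds, base=12.0), "cytoplasmic"
        )
        d = {(c.condition, c.control): c.direction for c in panel.comparisons}
        assert d[("Na-isethionate", "NMDG-gluconate")] == "decreased"
        assert d[("NaCl+5-HT", "NaCl")] == "increased"
        assert panel.cl_signature

    def test_equal_media_show_no_contrasts(self):
        folds = {m: 1.0 for m in self.EX_FOLDS}
        panel = compare.ion_panel_analysis(self._k_by_medium(folds), "extracellular")
        assert all(c.direction == "unchanged" for c in panel.comparisons)
        assert not panel.cl_signature

    def test_missing_medium_listed_in_error(self):
        ks = self._k_by_medium(self.EX_FOLDS)
        del ks["NaCl"]
        with pytest.raises(ConfigurationError, match="NaCl"):
            compare.ion_panel_analysis(ks, "extracellular")


def test_holm_adjustment_is_monotone_and_bounded():
    results = [
        compare.ComparisonResult("a", "c", 1.0, {}, p, "unchanged")
        for p in (0.001, 0.02, 0.04, 0.8)
    ]
    adj = compare.holm_adjust(results)
    assert adj == sorted(adj)
    assert all(0 <= p <= 1 for p in adj)
    assert adj[0] == pytest.approx(0.004)
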