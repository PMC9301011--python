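"""qPCR, MeRIP-qPCR, decay-fit and LC-MS calibration arithmetic."""

import numpy as np
import pandas as pd
import pytest

from meriplite import (
    delta_delta_ct,
    fit_decay,
    fit_decay_table,
    group_expression_summary,
    m6a_ratio_lcms,
    merip_qpcr_enrichment,
)


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])


class TestDeltaDeltaCt:
    def test_worked_example_fold_two(self):
        tbl = _ct_table(
            [
                ("t1", "treated", "tgt", 20.0),
                ("t1", "treated", "ref", 15.0),
                ("c1", "control", "tgt", 21.0),
                ("c1", "control", "ref", 15.0),
            ]
        )
        res = delta_delta_ct(tbl, "ref", "control")
        treated = res[res["sample_id"] == "t1"].iloc[0]
        assert treated["ddct"] == -1.0
        assert treated["rel_expr"] == 2.0

    def test_calibrator_group_summary_is_unity(self):
        tbl = _ct_table(
            [
                ("c1", "ctl", "tgt", 21.0),
                ("c2", "ctl", "tgt", 23.0),
                ("c1", "ctl", "ref", 15.0),
                ("c2", "ctl", "ref", 15.5),
                ("t1", "trt", "tgt", 19.0),
                ("t1", "trt", "ref", 15.0),
            ]
        )
        res = delta_delta_ct(tbl, "ref", "ctl")
        summ = group_expression_summary(res)
        ctl = summ[(summ["group"] == "ctl") & (summ["gene"] == "tgt")]["rel_expr"].iloc[0]
        assert ctl == 1.0

    def test_replicates_averaged_before_dct(self):
        tbl = _ct_table(
            [
                ("s1", "g", "tgt", 20.0),
                ("s1", "g", "tgt", 22.0),
                ("s1", "g", "ref", 15.0),
            ]
        )
        res = delta_delta_ct(tbl, "ref", "g")
        assert res["dct"].iloc[0] == 6.0

    def test_constant_shift_invariance(self, rng):
        rows = []
        for s, grp in [("a", "ctl"), ("b", "trt")]:
            for gene in ("tgt", "ref"):
                rows.append((s, grp, gene, float(rng.uniform(15, 30))))
        tbl = _ct_table(rows)
        res1 = delta_delta_ct(tbl, "ref", "ctl")
        shifted = tbl.copy()
        shifted["ct"] += 3.7  # every well in every sample shifts equally
        res2 = delta_delta_ct(shifted, "ref", "ctl")
        np.testing.assert_allclose(res1["rel_expr"], res2["rel_expr"], rtol=1e-12)

    def test_matches_hand_recomputation(self, rng):
        samples = [("s1", "ctl"), ("s2", "ctl"), ("s3", "trt")]
        rows = [
            (s, g, gene, float(rng.uniform(14, 32)))
            for s, g in samples
            for gene in ("tgt", "ref")
        ]
        tbl = _ct_table(rows)
        res = delta_delta_ct(tbl, "ref", "ctl").set_index("sample_id")
        ct = {(r[0], r[2]): r[3] for r in rows}
        dct = {s: ct[(s, "tgt")] - ct[(s, "ref")] for s, _ in samples}
        cal = (dct["s1"] + dct["s2"]) / 2
        for s, _ in samples:
            assert res.loc[s, "rel_expr"] == pytest.approx(2.0 ** -(dct[s] - cal), rel=1e-12)

    def test_missing_reference_named_in_error(self):
        tbl = _ct_table([("s1", "g", "tgt", 20.0)])
        with pytest.raises(ValueError, match="s1"):
            delta_delta_ct(tbl, "ref", "g")


class TestMeripQpcr:
    def _tbl(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "gene", "library_kind", "ct"])

    def test_identical_kinetics_enrichment_one(self):
        tbl = self._tbl(
            [
                ("s1", "tgt", "IP", 25.0),
                ("s1", "tgt", "input", 20.0),
                ("s1", "GAPDH", "IP", 25.0),
                ("s1", "GAPDH", "input", 20.0),
            ]
        )
        res = merip_qpcr_enrichment(tbl)
        assert res[res["gene"] == "tgt"]["enrichment"].iloc[0] == 1.0

    def test_ratio_arithmetic(self):
        # target ratio 1/16, normalizer 1/32 -> enrichment 2
        tbl = self._tbl(
            [
                ("s1", "tgt", "IP", 24.0),
                ("s1", "tgt", "input", 20.0),
                ("s1", "GAPDH", "IP", 25.0),
                ("s1", "GAPDH", "input", 20.0),
            ]
        )
        res = merip_qpcr_enrichment(tbl)
        assert res[res["gene"] == "tgt"]["enrichment"].iloc[0] == 2.0

    def test_normalizer_self_enrichment_is_one(self, rng):
        tbl = self._tbl(
            [("s1", "GAPDH", k, float(rng.uniform(18, 28))) for k in ("IP", "input")]
        )
        res = merip_qpcr_enrichment(tbl)
        assert res["enrichment"].iloc[0] == 1.0

    def test_forward_model_round_trip(self):
        """A site 4x enriched over a 1x normalizer under an exact Ct model."""
        # Ct = -log2(amount); IP amount = beta * input amount
        def ct(amount):
            return -np.log2(amount)

        tbl = self._tbl(
            [
                ("s1", "site", "input", ct(1e-6)),
                ("s1", "site", "IP", ct(4e-6)),
                ("s1", "GAPDH", "input", ct(5e-6)),
                ("s1", "GAPDH", "IP", ct(5e-6)),
            ]
        )
        res = merip_qpcr_enrichment(tbl)
        assert res[res["gene"] == "site"]["enrichment"].iloc[0] == pytest.approx(4.0, rel=1e-12)

    def test_missing_pair_member_rejected(self):
        tbl = self._tbl([("s1", "tgt", "IP", 25.0)])
        with pytest.raises(ValueError):
            merip_qpcr_enrichment(tbl)

    def test_percent_input_option(self):
        tbl = self._tbl(
            [
                ("s1", "tgt", "IP", 22.0),
                ("s1", "tgt", "input", 20.0),
                ("s1", "GAPDH", "IP", 25.0),
                ("s1", "GAPDH", "input", 20.0),
            ]
        )
        res = merip_qpcr_enrichment(tbl, percent_input=True)
        assert res[res["gene"] == "tgt"]["percent_input"].iloc[0] == 25.0


class TestDecay:
    def test_exact_exponential_recovered(self):
        fit = fit_decay([0, 2, 4, 8], [1, 0.5, 0.25, 0.0625])
        assert fit.k == pytest.approx(np.log(2) / 2, rel=1e-12)
        assert fit.half_life == pytest.approx(2.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_expression_not_estimable(self):
        fit = fit_decay([0, 2, 4, 8], [1.0, 1.0, 1.0, 1.0])
        assert not fit.estimable
        assert np.isinf(fit.half_life)

    def test_increasing_expression_flagged_no_decay(self):
        fit = fit_decay([0, 2, 4], [1.0, 2.0, 4.0])
        assert not fit.estimable
        assert "no decay" in fit.note

    def test_nonpositive_points_excluded(self):
        fit = fit_decay([0, 2, 4, 8], [1.0, 0.5, 0.0, 0.25])
        assert fit.n_points == 3
        assert fit.estimable

    def test_too_few_points_not_estimable(self):
        fit = fit_decay([0, 2], [1.0, 0.5])
        assert not fit.estimable

    def test_noisy_recovery_median_error_under_ten_percent(self, rng):
        t = np.array([0.0, 2.0, 4.0, 8.0])
        errors = []
        for _ in range(100):
            half = rng.uniform(1, 10)
            k = np.log(2) / half
            y = np.exp(-k * t) * np.exp(rng.normal(0, 0.05, size=t.size))
            fit = fit_decay(t, y)
            errors.append(abs(fit.half_life - half) / half)
        assert np.median(errors) <= 0.10

    def test_table_interface(self):
        tbl = pd.DataFrame(
            {
                "gene": ["a"] * 4 + ["b"] * 4,
                "time_h": [0, 2, 4, 8] * 2,
                "expression": [1, 0.5, 0.25, 0.0625, 1, 1, 1, 1],
            }
        )
        res = fit_decay_table(tbl).set_index("gene")
        assert res.loc["a", "half_life"] == pytest.approx(2.0, rel=1e-12)
        assert not res.loc["b", "estimable"]


class TestLcms:
    def _standards(self, slope_m6a=2.0, slope_a=2.0, intercept=0.0, noise=None, rng=None):
        conc = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        out = {}
        for nuc, slope in (("m6A", slope_m6a), ("A", slope_a)):
            area = slope * conc + intercept
            if noise:
                area = area * (1 + rng.normal(0, noise, size=conc.size))
            out[nuc] = pd.DataFrame({"concentration": conc, "area": area})
        return out

    def test_exact_linear_standards(self):
        with pytest.warns(UserWarning, match="outside calibration range"):
            res = m6a_ratio_lcms({"m6A": 4.0, "A": 800.0}, self._standards())
        assert res["conc_m6A"] == pytest.approx(2.0, rel=1e-12)
        assert res["ratio"] == pytest.approx(2.0 / 400.0, rel=1e-10)

    def test_zero_m6a_area_gives_zero_ratio(self):
        with pytest.warns(UserWarning, match="outside calibration range"):
            res = m6a_ratio_lcms({"m6A": 0.0, "A": 8.0}, self._standards())
        assert res["ratio"] == 0.0

    def test_out_of_range_sample_warns(self):
        with pytest.warns(UserWarning, match="outside calibration range"):
            m6a_ratio_lcms({"m6A": 100.0, "A": 8.0}, self._standards())

    def test_nonpositive_a_concentration_rejected(self):
        with pytest.raises(ValueError, match="A concentration"), pytest.warns(
            UserWarning, match="outside calibration range"
        ):
            m6a_ratio_lcms({"m6A": 4.0, "A": 0.0}, self._standards())

    def test_noisy_standards_recover_ratio_within_five_percent(self, rng):
        errs = []
        for _ in range(100):
            std = self._standards(noise=0.01, rng=rng)
            res = m6a_ratio_lcms({"m6A": 2.0 * 1.0, "A": 2.0 * 4.0}, std)
            errs.append(abs(res["ratio"] - 0.25) / 0.25)
        assert np.median(errs) <= 0.05
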