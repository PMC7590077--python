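"""Decision flowchart, majority voting, confusion metrics, threshold curve."""

import numpy as np
import pytest

from nirscreen.decision_eval import (
    DecisionConfig,
    ScanPrediction,
    SpectrumVerdict,
    concentration_fit_metrics,
    confusion_report,
    decide_sample,
    decide_spectrum,
    loso_cross_validate,
    threshold_curve,
)
from nirscreen.knn_engine import KnnResult, Neighbor, NeighborSet
from nirscreen.spectral_core import (
    CocaineForm,
    SampleMeta,
    Spectrum,
    build_library,
)
from nirscreen.synthetic_data import generate_library


def knn_ok(conc, identity="cocaine HCl"):
    ns = NeighborSet(by_distance=[Neighbor(0, 0.01, 0.999)])
    return KnnResult("ok", identity, conc, ns)


def knn_abstain():
    return KnnResult("no_match", None, None, NeighborSet())


class TestDecideSpectrum:
    # hand-enumerated truth table over
    # {knn ok / no_match} x {conc > / = / < threshold} x {form assigned / unassigned}
    TRUTH_TABLE = [
        # (knn, (form, b_conc), expected_result, expected_decider)
        (knn_ok(35.0), ("base", 55.0), "positive", "knn"),
        (knn_ok(35.0), ("unassigned", None), "positive", "knn"),
        (knn_ok(20.0), ("base", 55.0), "negative", "knn"),  # equal -> negative
        (knn_ok(20.0), ("unassigned", None), "negative", "knn"),
        (knn_ok(5.0), ("base", 55.0), "negative", "knn"),
        (knn_ok(5.0), ("unassigned", None), "negative", "knn"),
        (knn_abstain(), ("hcl", 55.0), "positive", "ann_treebag"),
        (knn_abstain(), ("base", 55.0), "positive", "ann_treebag"),
        (knn_abstain(), ("hcl", 20.0), "negative", "ann_treebag"),
        (knn_abstain(), ("base", 5.0), "negative", "ann_treebag"),
        (knn_abstain(), ("unassigned", None), "negative", "ann_treebag"),
        (knn_abstain(), ("unassigned", 90.0), "negative", "ann_treebag"),
    ]

    @pytest.mark.parametrize("knn,b,expected,decider", TRUTH_TABLE)
    def test_truth_table(self, knn, b, expected, decider):
        v = decide_spectrum(knn, b, DecisionConfig(), scan_id="x", sample_id="S")
        assert v.result == expected
        assert v.decided_by == decider

    def test_knn_result_overrides_submodel_b(self):
        # kNN says 35 -> positive even if submodel B would say negative
        v = decide_spectrum(knn_ok(35.0), ("unassigned", None), DecisionConfig())
        assert v.result == "positive"
        assert v.predicted_conc == 35.0

    def test_flowchart_is_deterministic(self):
        for knn, b, expected, _ in self.TRUTH_TABLE:
            for _ in range(3):
                assert decide_spectrum(knn, b).result == expected


def _verdicts(results, sample_id="S"):
    return [
        SpectrumVerdict(f"sc{i}", sample_id, r, "knn", None, None)
        for i, r in enumerate(results)
    ]


class TestDecideSample:
    def test_two_positive_three_negative_is_negative(self):
        # the published worked example: 2/5 positive -> overall negative
        v = decide_sample(_verdicts(["positive"] * 2 + ["negative"] * 3))
        assert v.result == "negative"
        assert (v.n_positive, v.n_negative) == (2, 3)

    def test_unanimous_positive(self):
        assert decide_sample(_verdicts(["positive"] * 5)).result == "positive"

    def test_even_tie_resolves_negative(self):
        assert decide_sample(_verdicts(["positive", "positive", "negative", "negative"])).result == "negative"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            decide_sample([])

    def test_identity_is_mode_over_knn_decided_scans(self):
        verdicts = [
            SpectrumVerdict("a", "S", "positive", "knn", 80.0, "cocaine HCl", 0.02),
            SpectrumVerdict("b", "S", "positive", "knn", 78.0, "cocaine HCl", 0.02),
            SpectrumVerdict("c", "S", "positive", "knn", 75.0, "levamisole", 0.01),
            SpectrumVerdict("d", "S", "negative", "ann_treebag", 5.0, None),
        ]
        assert decide_sample(verdicts).predicted_identity == "cocaine HCl"

    def test_identity_tie_breaks_by_mean_distance(self):
        verdicts = [
            SpectrumVerdict("a", "S", "positive", "knn", 80.0, "far", 0.09),
            SpectrumVerdict("b", "S", "positive", "knn", 78.0, "near", 0.01),
        ]
        assert decide_sample(verdicts).predicted_identity == "near"

    def test_flipping_one_verdict_needs_a_small_margin_to_matter(self):
        # one flip moves the positive-negative margin by exactly 2, so a
        # result can only change when the margin was at most 2 (the
        # tie-to-negative rule makes margin-2 positives vulnerable)
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            results = ["positive" if rng.random() < 0.5 else "negative" for _ in range(n)]
            before = decide_sample(_verdicts(results)).result
            i = int(rng.integers(n))
            flipped = list(results)
            flipped[i] = "positive" if flipped[i] == "negative" else "negative"
            after = decide_sample(_verdicts(flipped)).result
            margin = abs(results.count("positive") - results.count("negative"))
            if margin > 2:
                assert before == after


META = {
    **{
        f"P{i}": SampleMeta(f"P{i}", "cocaine HCl", CocaineForm.HCL, 80.0, "A")
        for i in range(10)
    },
    **{
        f"N{i}": SampleMeta(f"N{i}", "caffeine", CocaineForm.NONE, 0.0, "B")
        for i in range(10)
    },
    "SUB": SampleMeta("SUB", "cocaine HCl", CocaineForm.HCL, 10.0, "REF"),
}


class TestConfusionReport:
    def test_all_correct_gives_perfect_rates(self):
        verdicts = [
            SpectrumVerdict(f"p{i}", f"P{i}", "positive", "knn", 80.0, None)
            for i in range(10)
        ] + [
            SpectrumVerdict(f"n{i}", f"N{i}", "negative", "knn", 0.0, None)
            for i in range(10)
        ]
        rep = confusion_report(verdicts, META, DecisionConfig(), "scan")
        assert (rep.tp_rate, rep.tn_rate) == (100.0, 100.0)

    def test_single_false_positive_rate(self):
        verdicts = [
            SpectrumVerdict(f"n{i}", f"N{i}", "positive" if i == 0 else "negative", "knn", None, None)
            for i in range(10)
        ]
        rep = confusion_report(verdicts, META, DecisionConfig(), "scan")
        assert rep.fp == 1 and rep.fp_rate == pytest.approx(10.0)

    def test_subthreshold_cocaine_excluded_by_default(self):
        verdicts = [SpectrumVerdict("s", "SUB", "negative", "knn", 5.0, None)]
        rep = confusion_report(verdicts, META, DecisionConfig(), "scan")
        assert rep.n_excluded == 1
        assert rep.tp + rep.fn + rep.tn + rep.fp == 0
        rep2 = confusion_report(
            verdicts, META, DecisionConfig(), "scan", include_subthreshold=True
        )
        assert rep2.fn == 1

    def test_counts_match_independent_tally(self):
        rng = np.random.default_rng(1)
        verdicts = []
        for i in range(200):
            sid = rng.choice([f"P{i % 10}", f"N{i % 10}"])
            res = "positive" if rng.random() < 0.5 else "negative"
            verdicts.append(SpectrumVerdict(f"v{i}", sid, res, "knn", None, None))
        rep = confusion_report(verdicts, META, DecisionConfig(), "scan")
        # brute-force tally
        tp = sum(1 for v in verdicts if v.sample_id.startswith("P") and v.result == "positive")
        fn = sum(1 for v in verdicts if v.sample_id.startswith("P") and v.result == "negative")
        tn = sum(1 for v in verdicts if v.sample_id.startswith("N") and v.result == "negative")
        fp = sum(1 for v in verdicts if v.sample_id.startswith("N") and v.result == "positive")
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (tp, fn, tn, fp)

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            confusion_report(
                [SpectrumVerdict("x", "ghost", "negative", "knn", None, None)],
                META,
                DecisionConfig(),
                "scan",
            )


class TestConcentrationFitMetrics:
    def test_perfect_prediction(self):
        r2, rmse = concentration_fit_metrics([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert (r2, rmse) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_constant_offset(self):
        known = [10.0, 20.0, 30.0, 40.0]
        r2, rmse = concentration_fit_metrics([k + 3 for k in known], known)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(3.0)

    def test_five_pair_hand_computed_example(self):
        # exact-rational oracle: predicted = [12, 28, 35, 52, 71],
        # known = [10, 30, 40, 50, 70] -> r^2 = cov^2/(vp*vk) = 0.98194147...,
        # rmse = sqrt((4+4+25+4+1)/5) = sqrt(38/5)
        r2, rmse = concentration_fit_metrics(
            [12.0, 28.0, 35.0, 52.0, 71.0], [10.0, 30.0, 40.0, 50.0, 70.0]
        )
        assert r2 == pytest.approx(0.9819414738479487, abs=1e-12)
        assert rmse == pytest.approx(np.sqrt(38 / 5), abs=1e-12)

    def test_missing_predictions_dropped(self):
        r2, rmse = concentration_fit_metrics(
            [10.0, None, 30.0, None, 50.0], [10.0, 99.0, 30.0, 99.0, 50.0]
        )
        assert rmse == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            concentration_fit_metrics([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


def _predictions(rng, n=300):
    preds = []
    for i in range(n):
        positive = i % 2 == 0
        sid = f"P{i % 10}" if positive else f"N{i % 10}"
        conc = float(np.clip(rng.normal(75 if positive else 5, 15), 0.0, 100.0))
        if rng.random() < 0.3:
            preds.append(
                ScanPrediction(f"s{i}", sid, "no_match", None, None, None,
                               "hcl" if rng.random() < 0.5 else "unassigned", conc)
            )
        else:
            preds.append(
                ScanPrediction(f"s{i}", sid, "ok", conc, "cocaine HCl", 0.02,
                               "unassigned", None)
            )
    return preds


class TestThresholdCurve:
    def test_rates_weakly_decrease_with_threshold(self):
        preds = _predictions(np.random.default_rng(2))
        curve = threshold_curve(preds, META, np.arange(0.0, 101.0, 1.0))
        assert np.all(np.diff(curve.fp_rate) <= 1e-9)
        assert np.all(np.diff(curve.tp_rate) <= 1e-9)

    def test_perfect_predictions_attain_ideal_point(self):
        preds = [
            ScanPrediction(f"p{i}", f"P{i}", "ok", 80.0, None, 0.01, "unassigned", None)
            for i in range(10)
        ] + [
            ScanPrediction(f"n{i}", f"N{i}", "ok", 0.0, None, 0.01, "unassigned", None)
            for i in range(10)
        ]
        curve = threshold_curve(preds, META, np.arange(0.0, 101.0, 1.0))
        ideal = (curve.fp_rate == 0.0) & (curve.tp_rate == 100.0)
        assert ideal.any()
        assert curve.zero_fp_threshold is not None

    def test_threshold_100_kills_all_positives(self):
        preds = _predictions(np.random.default_rng(3))
        curve = threshold_curve(preds, META, [100.0])
        assert curve.tp_rate[0] == 0.0

    def test_operating_points_match_brute_force(self):
        preds = _predictions(np.random.default_rng(4))
        grid = np.arange(0.0, 101.0, 1.0)
        curve = threshold_curve(preds, META, grid)
        if curve.zero_fp_threshold is not None:
            j = int(np.nonzero(grid == curve.zero_fp_threshold)[0][0])
            assert curve.fp_rate[j] == 0.0
            assert np.all(curve.fp_rate[:j] > 0.0)
        assert curve.accuracy[int(np.argmax(curve.accuracy))] == curve.accuracy.max()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            threshold_curve(_predictions(np.random.default_rng(5)), META, [])


class TestLosoCrossValidate:
    def test_mutually_distant_two_sample_library_abstains(self, grid):
        lam = grid.wavelengths
        a = 1.0 + np.exp(-((lam - 800.0) ** 2) / 800.0)
        b = 1.0 + np.exp(-((lam - 1000.0) ** 2) / 800.0)
        rng = np.random.default_rng(0)
        scans = []
        for i in range(6):
            v = (a if i < 3 else b) + rng.normal(0, 1e-4, lam.size)
            scans.append(Spectrum(f"s{i}", "A" if i < 3 else "B", "sc", i, v))
        meta = [
            SampleMeta("A", "cocaine HCl", CocaineForm.HCL, 90.0, "A"),
            SampleMeta("B", "cocaine base", CocaineForm.BASE, 80.0, "A"),
        ]
        lib = build_library(scans, meta)
        res = loso_cross_validate(lib, n_folds=2, seed=0)
        assert all(p.knn_status == "no_match" for p in res.scan_predictions)
        assert all(v.decided_by == "ann_treebag" for v in res.spectrum_verdicts)

    def test_duplicated_sample_resolves_as_zero_distance_neighbours(self, grid):
        lam = grid.wavelengths
        base = 1.0 + 0.4 * np.exp(-((lam - 900.0) ** 2) / 1500.0)
        rng = np.random.default_rng(1)
        scans, meta = [], []
        for sid, centre in (("A1", 900.0), ("A2", 900.0), ("B1", 820.0), ("B2", 820.0)):
            sig = 1.0 + 0.4 * np.exp(-((lam - centre) ** 2) / 1500.0)
            for r in range(3):
                scans.append(
                    Spectrum(f"{sid}.{r}", sid, "sc", r, sig + rng.normal(0, 1e-5, lam.size))
                )
        meta = [
            SampleMeta("A1", "cocaine HCl", CocaineForm.HCL, 80.0, "A"),
            SampleMeta("A2", "cocaine HCl", CocaineForm.HCL, 80.0, "A"),
            SampleMeta("B1", "cocaine base", CocaineForm.BASE, 60.0, "A"),
            SampleMeta("B2", "cocaine base", CocaineForm.BASE, 60.0, "A"),
        ]
        lib = build_library(scans, meta)
        res = loso_cross_validate(lib, n_folds=2, seed=0)
        for p in res.scan_predictions:
            assert p.knn_status == "ok"
            assert p.knn_mean_distance < 0.01
        for v in res.sample_verdicts:
            assert v.result == "positive"

    def test_single_sample_rejected(self, toy_library):
        toy_library.scan_meta["sample_id"] = "S1"
        toy_library.sample_meta.pop("S2")
        with pytest.raises(ValueError, match="2 samples"):
            loso_cross_validate(toy_library)
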