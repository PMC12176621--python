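"""Benthic-minimum smooth: fitting, prediction, classification, serialisation."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from benthicsplit import (
    DepthHorizon,
    HorizonEnvelope,
    classify,
    fit_benthic_minima_model,
    load_model,
    predict_benthic_min,
    save_model,
)
from benthicsplit.cloud_model import ModelError

from conftest import make_records

HORIZON_DEPTHS = [100.0, 250.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0,
                  2500.0, 3000.0, 3500.0, 4000.0, 4500.0, 5000.0, 6000.0]


def envelopes_from(x, y):
    return [
        HorizonEnvelope(
            horizon=DepthHorizon(xi, 0.01 * xi),
            benthic_min_m=yi,
            benthic_max_m=max(xi, yi),
            chosen_k=2,
        )
        for xi, yi in zip(x, y)
    ]


class TestFit:
    def test_exact_line_reproduced(self):
        x = np.array(HORIZON_DEPTHS)
        model = fit_benthic_minima_model(envelopes_from(x, 0.8 * x))
        pred, _ = predict_benthic_min(model, x, clamp=False)
        assert np.max(np.abs(pred - 0.8 * x) / (0.8 * x)) < 1e-6

    def test_constant_reproduced(self):
        x = np.array(HORIZON_DEPTHS)
        model = fit_benthic_minima_model(envelopes_from(x, np.full(14, 500.0)))
        pred, _ = predict_benthic_min(model, x, clamp=False)
        np.testing.assert_allclose(pred, 500.0, rtol=1e-8)

    def test_noisy_smooth_recovery(self):
        rng = np.random.default_rng(17)
        x = np.array(HORIZON_DEPTHS)
        g = lambda z: 0.92 * z - 40
        model = fit_benthic_minima_model(envelopes_from(x, g(x) + rng.normal(0, 5, 14)))
        zg = np.linspace(x.min(), x.max(), 300)
        pred, _ = predict_benthic_min(model, zg, clamp=False)
        rmse = float(np.sqrt(np.mean((pred - g(zg)) ** 2)))
        assert rmse <= 15.0

    def test_too_few_pairs_errors(self):
        x = np.array(HORIZON_DEPTHS[:5])
        with pytest.raises(ModelError, match=">= 6"):
            fit_benthic_minima_model(envelopes_from(x, 0.8 * x))

    def test_duplicate_depths_named(self):
        x = np.array([100.0, 100.0, 500.0, 1000.0, 2000.0, 3000.0])
        with pytest.raises(ModelError, match="100m"):
            fit_benthic_minima_model(envelopes_from(x, 0.8 * x))

    def test_diagnostics_populated(self):
        rng = np.random.default_rng(3)
        x = np.array(HORIZON_DEPTHS)
        model = fit_benthic_minima_model(envelopes_from(x, 0.9 * x + rng.normal(0, 10, 14)))
        assert 0 < model.edf < 14
        assert 0 <= model.deviance_explained <= 1
        table = model.diagnostics_table()
        assert len(table) == 14
        assert (table.ci_lower_m <= table.ci_upper_m).all()

    def test_monotone_data_gives_near_monotone_fit(self):
        x = np.array(HORIZON_DEPTHS)
        y = 0.9 * x - 30  # strictly increasing minima
        model = fit_benthic_minima_model(envelopes_from(x, y))
        fitted, _ = predict_benthic_min(model, x, clamp=False)
        ci_width = model.ci_upper_m - model.ci_lower_m
        assert np.all(np.diff(fitted) > -np.maximum(ci_width[:-1], 1e-6))


class TestPredict:
    @pytest.fixture()
    def line_model(self):
        x = np.array(HORIZON_DEPTHS)
        return fit_benthic_minima_model(envelopes_from(x, 0.95 * x))

    def test_clamped_to_seabed(self):
        # force a raw prediction above the seabed via a steep line
        x = np.array(HORIZON_DEPTHS)
        model = fit_benthic_minima_model(envelopes_from(x, 0.99 * x))
        thr, _ = predict_benthic_min(model, 100.0)
        assert thr <= 100.0

    def test_clamped_to_seabed_when_shallow(self, line_model):
        thr, extrap = predict_benthic_min(line_model, 31.0)
        assert thr == pytest.approx(31.0)  # raw ~ 95, clamped down to the seabed
        assert extrap

    def test_clamped_to_global_minimum_floor(self):
        # minima hugging the 30 m floor: raw extension below 100 m stays ~30,
        # and the floor clamp guarantees the threshold never dips under 30
        x = np.array(HORIZON_DEPTHS)
        model = fit_benthic_minima_model(envelopes_from(x, 30.0 + 0.9 * (x - 100.0)))
        thr, extrap = predict_benthic_min(model, 60.0)
        assert thr == pytest.approx(30.0, abs=1e-6)
        assert extrap

    def test_extrapolation_flag(self, line_model):
        _, extrap_in = predict_benthic_min(line_model, 3000.0)
        _, extrap_below = predict_benthic_min(line_model, 50.0)
        _, extrap_above = predict_benthic_min(line_model, 9000.0)
        assert not extrap_in and extrap_below and extrap_above

    def test_nonpositive_seabed_errors(self, line_model):
        with pytest.raises(ModelError):
            predict_benthic_min(line_model, 0.0)

    def test_threshold_always_in_bounds(self, line_model):
        z = np.linspace(31, 9000, 500)
        thr, _ = predict_benthic_min(line_model, z)
        assert np.all(thr >= 30.0) and np.all(thr <= z)


class TestClassify:
    @pytest.fixture()
    def model(self):
        x = np.array(HORIZON_DEPTHS)
        return fit_benthic_minima_model(envelopes_from(x, 0.8 * x))

    def test_labels_and_partition(self, model):
        records = make_records(
            [0, 0, 0], [0, 0, 0], [900.0, 500.0, 800.0],
            seabed=[1000.0, 1000.0, 1000.0],
        )
        out, counts = classify(records, model)
        assert out.label.tolist() == ["benthic", "pelagic", "benthic"]  # 800 == threshold
        assert counts["n_benthic"] + counts["n_pelagic"] == counts["n_input"] == 3

    def test_deeper_than_seabed_is_benthic_with_qc_flag(self, model):
        records = make_records([0], [0], [1300.0], seabed=[1000.0])
        out, counts = classify(records, model)
        assert out.label.tolist() == ["benthic"]
        assert out.qc_flag.tolist() == [True]
        assert counts["n_qc_flagged"] == 1

    def test_missing_seabed_errors(self, model):
        records = make_records([0], [0], [100.0])
        with pytest.raises(ModelError, match="seabed"):
            classify(records, model)


def test_serialisation_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    x = np.array(HORIZON_DEPTHS)
    model = fit_benthic_minima_model(envelopes_from(x, 0.9 * x + rng.normal(0, 8, 14)))
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    z = np.linspace(50, 7000, 200)
    p1, e1 = predict_benthic_min(model, z)
    p2, e2 = predict_benthic_min(back, z)
    np.testing.assert_array_equal(p1, p2)
    np.testing.assert_array_equal(e1, e2)


def test_matches_mgcv_reference_fit(tmp_path):
    """Independent cross-check: an mgcv GAM (Gaussian, identity, one smooth,
    GCV) fitted to the same 14 pairs predicts within a few metres RMSE of the
    in-package penalized spline over the training range."""
    rng = np.random.default_rng(17)
    x = np.array(HORIZON_DEPTHS)
    y = 0.92 * x - 40 + rng.normal(0, 5, 14)
    zg = np.linspace(x.min(), x.max(), 100)
    data = tmp_path / "pairs.csv"
    pd.DataFrame({"x": x, "y": y}).to_csv(data, index=False)
    grid = tmp_path / "grid.csv"
    pd.DataFrame({"x": zg}).to_csv(grid, index=False)
    out = tmp_path / "pred.csv"
    script = tmp_path / "fit.R"
    script.write_text(
        textwrap.dedent(
            f"""
            library(mgcv)
            d <- read.csv("{data}")
            g <- read.csv("{grid}")
            m <- gam(y ~ s(x, k = 10), family = gaussian(), data = d, method = "GCV.Cp")
            write.csv(data.frame(pred = predict(m, newdata = g)), "{out}", row.names = FALSE)
            """
        )
    )
    subprocess.run(["Rscript", "--vanilla", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(out)["pred"].to_numpy()
    model = fit_benthic_minima_model(envelopes_from(x, y))
    pred, _ = predict_benthic_min(model, zg, clamp=False)
    rmse = float(np.sqrt(np.mean((pred - ref) ** 2)))
    assert rmse <= 15.0
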