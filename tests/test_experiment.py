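import numpy as np
import pandas as pd
import pytest

from imcoal import IMParams, PARAM_NAMES, ScenarioConfig, run_experiment, summarize, trend_slope


def _tiny_config(**kw):
    defaults = dict(
        truth=IMParams(10, 10, 10, 0, 0, 10),
        rho=0.0,
        loci_counts=(10,),
        replicates=2,
        seed=50,
        n_starts=3,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


def test_result_table_shape():
    results = run_experiment(_tiny_config())
    assert len(results) == 2  # replicates x loci counts
    for name in PARAM_NAMES:
        assert name in results.columns
    assert (results["error"] == "").all()


def test_identical_root_seed_gives_identical_tables():
    a = run_experiment(_tiny_config())
    b = run_experiment(_tiny_config())
    pd.testing.assert_frame_equal(a, b)


def test_invalid_scenarios_rejected():
    with pytest.raises(ValueError):
        _tiny_config(replicates=0)
    with pytest.raises(ValueError):
        _tiny_config(loci_counts=())


class TestSummarize:
    def _results(self, estimates, n_loci=10):
        rows = []
        for i, est in enumerate(estimates):
            row = {"rho": 0.0, "replicate": i, "n_loci": n_loci, "error": ""}
            row.update({name: est for name in PARAM_NAMES})
            rows.append(row)
        return pd.DataFrame(rows)

    def test_bias_and_se(self):
        table = summarize(self._results([9.0, 10.0, 11.0]), IMParams(10, 10, 10, 10, 10, 10))
        row = table[table["parameter"] == "theta3"].iloc[0]
        assert row["bias"] == pytest.approx(0.0, abs=1e-12)
        assert row["se"] == pytest.approx(1 / np.sqrt(3), abs=1e-12)
        assert row["n_replicates"] == 3

    def test_exact_recovery_has_zero_bias_and_se(self):
        table = summarize(self._results([10.0, 10.0, 10.0]), IMParams(10, 10, 10, 10, 10, 10))
        assert (table["bias"] == 0).all()
        assert (table["se"] == 0).all()

    def test_single_replicate_cell_rejected(self):
        with pytest.raises(ValueError):
            summarize(self._results([10.0]), IMParams(10, 10, 10))


class TestTrendSlope:
    def test_perfect_linear_trend(self):
        rhos = [0.0, 1.0, 2.0] * 5
        estimates = [1.0, 2.0, 3.0] * 5
        slope, p = trend_slope(rhos, estimates)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-9

    def test_constant_estimates_give_zero_slope(self):
        slope, _ = trend_slope([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            trend_slope([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            trend_slope([0.0, 1.0], [1.0, 2.0])
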