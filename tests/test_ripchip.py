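"""Spot ratios, normalization, QC exclusion and differential enrichment."""

import numpy as np
import pandas as pd
import pytest

from pprchip.errors import UsageError
from pprchip.ripchip import (
    ExperimentDesign,
    fragment_enrichment,
    genome_order_series,
    normalize_arrays,
    rank_peaks,
    spot_ratios,
)
from pprchip.simulate import SimulationConfig, gen_ripchip_dataset

DESIGN = ExperimentDesign(treatment_arrays=["T1", "T2"], mock_arrays=["M1", "M2"])


def _spot(array_id, fragment_id, f635_fg, f635_bg, f532_fg, f532_bg, flag="pass"):
    return {
        "array_id": array_id, "fragment_id": fragment_id,
        "f635_fg": f635_fg, "f635_bg": f635_bg,
        "f532_fg": f532_fg, "f532_bg": f532_bg, "flag": flag,
    }


def _constant_spots(array_id, fragment_id, n, log2_ratio, flag="pass"):
    """n spots whose background-subtracted ratio is exactly 2**log2_ratio."""
    return [
        _spot(array_id, fragment_id, 100 + 1000 * 2.0 ** log2_ratio, 100,
              1100, 100, flag)
        for _ in range(n)
    ]


class TestSpotRatios:
    @pytest.mark.parametrize("f635_fg,f635_bg,f532_fg,f532_bg,expected", [
        (200, 100, 200, 100, 0.0),
        (900, 100, 300, 100, 2.0),
    ])
    def test_valid_ratio_arithmetic(self, f635_fg, f635_bg, f532_fg, f532_bg,
                                    expected):
        df = spot_ratios(pd.DataFrame(
            [_spot("T1", "f1", f635_fg, f635_bg, f532_fg, f532_bg)]
        ))
        assert df.loc[0, "valid"]
        assert df.loc[0, "log2_ratio"] == pytest.approx(expected)

    @pytest.mark.parametrize("spot,reason", [
        (_spot("T1", "f1", 500, 100, 90, 100), "F532 below background"),
        (_spot("T1", "f1", 90, 100, 500, 100), "F635 not above background"),
        (_spot("T1", "f1", 500, 100, 500, 100, flag="fail"), "manual flag"),
    ])
    def test_invalidity_is_a_status_not_an_exception(self, spot, reason):
        df = spot_ratios(pd.DataFrame([spot]))
        assert not df.loc[0, "valid"]
        assert df.loc[0, "invalid_reason"] == reason


class TestNormalization:
    def test_constant_ratios_center_to_zero(self):
        df = spot_ratios(pd.DataFrame(_constant_spots("T1", "f1", 3, 1.0)))
        out = normalize_arrays(df)
        np.testing.assert_allclose(out["log2_ratio"], 0.0, atol=1e-12)

    def test_median_subtraction(self):
        rows = (_constant_spots("T1", "f1", 1, 0.0)
                + _constant_spots("T1", "f2", 1, 2.0)
                + _constant_spots("T1", "f3", 1, 4.0))
        out = normalize_arrays(spot_ratios(pd.DataFrame(rows)))
        np.testing.assert_allclose(
            sorted(out["log2_ratio"]), [-2.0, 0.0, 2.0], atol=1e-12
        )

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rows = []
        for i, r in enumerate(rng.normal(0, 1, size=50)):
            rows += _constant_spots("T1", f"f{i}", 1, r)
        once = normalize_arrays(spot_ratios(pd.DataFrame(rows)))
        twice = normalize_arrays(once)
        np.testing.assert_allclose(
            once["log2_ratio"].to_numpy(), twice["log2_ratio"].to_numpy(),
            atol=1e-12,
        )

    def test_array_without_valid_spots_dropped(self, caplog):
        rows = (_constant_spots("T1", "f1", 2, 1.0)
                + _constant_spots("T2", "f1", 2, 1.0, flag="fail"))
        out = normalize_arrays(spot_ratios(pd.DataFrame(rows)))
        assert set(out["array_id"]) == {"T1"}


class TestFragmentEnrichment:
    def _dataset(self, n_treat_pass, n_mock_pass):
        rows = []
        for arr, k in (("T1", (n_treat_pass + 1) // 2), ("T2", n_treat_pass // 2)):
            rows += _constant_spots(arr, "f1", k, 2.0)
            rows += _constant_spots(arr, "f1", 12 - k, 2.0, flag="fail")
        for arr, k in (("M1", (n_mock_pass + 1) // 2), ("M2", n_mock_pass // 2)):
            rows += _constant_spots(arr, "f1", k, 0.5)
            rows += _constant_spots(arr, "f1", 12 - k, 0.5, flag="fail")
        # spread of other fragments so per-array medians are not degenerate
        for arr in ("T1", "T2", "M1", "M2"):
            for i in range(2, 30):
                rows += _constant_spots(arr, f"f{i}", 13, 0.0)
        return spot_ratios(pd.DataFrame(rows))

    @pytest.mark.parametrize("n_treat,n_mock,included", [
        (12, 24, False),   # one experiment below the 13-spot rule
        (24, 12, False),
        (13, 13, True),    # boundary: exactly 13 passes
        (24, 24, True),
    ])
    def test_thirteen_spot_exclusion_rule(self, n_treat, n_mock, included):
        res = fragment_enrichment(self._dataset(n_treat, n_mock), DESIGN)
        row = res[res["fragment_id"] == "f1"].iloc[0]
        assert bool(row["included"]) is included
        assert bool(np.isnan(row["differential"])) is (not included)

    def test_differential_of_constant_spots(self):
        res = fragment_enrichment(self._dataset(24, 24), DESIGN)
        row = res[res["fragment_id"] == "f1"].iloc[0]
        # medians of constants survive median-centering differences
        assert row["differential"] == pytest.approx(1.5, abs=1e-9)

    def test_fragment_without_spots_is_excluded(self):
        res = fragment_enrichment(
            self._dataset(24, 24), DESIGN, fragment_ids=["f1", "ghost"]
        )
        ghost = res[res["fragment_id"] == "ghost"].iloc[0]
        assert not ghost["included"]
        assert ghost["n_pass_treatment"] == 0


class TestRankPeaks:
    def _results(self, diffs, included=None):
        n = len(diffs)
        return pd.DataFrame({
            "fragment_id": [f"f{i:03d}" for i in range(n)],
            "differential": diffs,
            "included": included if included is not None else [True] * n,
        })

    def test_spiked_fragments_occupy_top_ranks(self):
        rng = np.random.default_rng(1)
        diffs = list(rng.normal(0, 0.05, size=196)) + [2.0, 2.1, 1.9, 2.2]
        res = self._results(diffs)
        top = rank_peaks(res, 4)
        assert set(top["fragment_id"]) == {"f196", "f197", "f198", "f199"}

    def test_ties_break_by_position(self):
        res = self._results([0.0, 0.0, 0.0])
        defs = pd.DataFrame({
            "fragment_id": ["f000", "f001", "f002"],
            "genome_start": [300, 100, 200],
            "genome_end": [399, 199, 299],
        })
        top = rank_peaks(res, 2, fragment_defs=defs)
        assert list(top["fragment_id"]) == ["f001", "f002"]

    def test_k_truncates_to_included(self):
        res = self._results([1.0, 2.0, 3.0], included=[True, False, True])
        assert len(rank_peaks(res, 10)) == 2

    def test_invalid_k_rejected(self):
        with pytest.raises(UsageError):
            rank_peaks(self._results([1.0]), 0)


class TestGenomeOrder:
    def test_excluded_fragment_becomes_gap(self):
        res = pd.DataFrame({
            "fragment_id": ["a", "b", "c"],
            "differential": [1.0, 2.0, 3.0],
            "included": [True, False, True],
        })
        defs = pd.DataFrame({
            "fragment_id": ["a", "b", "c"],
            "genome_start": [1, 101, 201],
            "genome_end": [100, 200, 300],
            "annotation": ["", "", ""],
        })
        series = genome_order_series(res, defs)
        assert list(series["fragment_id"]) == ["a", "b", "c"]
        assert np.isnan(series["differential"].iloc[1])
        assert series["differential"].iloc[0] == 1.0


class TestCalibrationAndRecovery:
    def test_mock_vs_mock_differentials_center_at_zero(self):
        """No-spike data: per-fragment differentials are noise around 0."""
        config = SimulationConfig(seed=11, n_fragments=120, spike_effect=0.0,
                                  noise_sd=0.3, flag_fail_rate=0.0)
        frags, spots, design = gen_ripchip_dataset(config)
        res = fragment_enrichment(
            normalize_arrays(spot_ratios(spots)), design,
            fragment_ids=list(frags["fragment_id"]),
        )
        diffs = res.loc[res["included"], "differential"].to_numpy()
        assert len(diffs) >= 100
        assert np.mean(np.abs(diffs)) <= 0.1
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 3 * se

    @pytest.mark.parametrize("effect", [1.0, 2.0, 3.0])
    def test_spike_effect_recovered(self, effect):
        """Median estimated differential within 0.15 of truth over 20 seeds."""
        estimates = []
        for seed in range(20):
            config = SimulationConfig(
                seed=seed, genome_length=4000, n_fragments=20, n_spikes=2,
                spike_effect=effect, noise_sd=0.3, flag_fail_rate=0.0,
            )
            frags, spots, design = gen_ripchip_dataset(config)
            res = fragment_enrichment(
                normalize_arrays(spot_ratios(spots)), design,
                fragment_ids=list(frags["fragment_id"]),
            )
            spiked = config.spiked_ids()
            est = res.loc[res["fragment_id"].isin(spiked), "differential"]
            estimates.extend(est)
        assert abs(np.median(estimates) - effect) <= 0.15

    def test_flag_failure_drives_exclusion(self):
        config = SimulationConfig(seed=3, genome_length=2000, n_fragments=10,
                                  flag_fail_rate=1.0)
        frags, spots, design = gen_ripchip_dataset(config)
        df = spot_ratios(spots)
        assert not df["valid"].any()
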