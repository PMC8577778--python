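"""Exposure protocol: wave sets, scaling, aggregation and trends."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from aedosim.constants import C0
from aedosim.dielectric import DebyeParameters
from aedosim.exposure import (
    AggregateSummary,
    ExposureConfig,
    ExposureResult,
    aggregate,
    far_field_min_distance,
    ks_two_sample,
    random_waves,
    run_protocol,
    scale_pabs,
    sensitivity_suite,
    standard_12_waves,
)
from aedosim.synthetic import PhantomSpec, make_phantom, make_sphere_phantom
from conftest import TABLE_ROWS


class TestStandardWaves:
    def test_twelve_orthonormal_waves(self):
        waves = standard_12_waves(60e9)
        assert len(waves) == 12
        for _, w in waves:
            k = np.asarray(w.k_hat)
            e = np.asarray(w.e_hat)
            assert np.linalg.norm(k) == pytest.approx(1.0)
            assert np.linalg.norm(e) == pytest.approx(1.0)
            assert abs(k @ e) < 1e-12

    def test_four_waves_per_polarization_axis(self):
        waves = standard_12_waves(60e9)
        for axis in range(3):
            count = sum(1 for _, w in waves if abs(w.e_hat[axis]) > 0.5)
            assert count == 4

    def test_labels_are_unique_and_deterministic(self):
        a = [label for label, _ in standard_12_waves(60e9)]
        b = [label for label, _ in standard_12_waves(2e9)]
        assert a == b
        assert len(set(a)) == 12


class TestRandomWaves:
    def test_reproducible_under_seed(self):
        a = random_waves(30, seed=42, f=60e9)
        b = random_waves(30, seed=42, f=60e9)
        assert len(a) == 30
        for (_, wa), (_, wb) in zip(a, b):
            assert wa.k_hat == wb.k_hat and wa.e_hat == wb.e_hat

    def test_directions_are_isotropic(self):
        n = 10_000
        ks = np.array([w.k_hat for _, w in random_waves(n, seed=1, f=1e9)])
        # Mean of a uniform direction is 0 with per-axis SE = 1/sqrt(3n).
        se = 1.0 / math.sqrt(3 * n)
        assert np.all(np.abs(ks.mean(axis=0)) < 3 * se)

    def test_polarization_orthogonal(self):
        for _, w in random_waves(50, seed=3, f=1e9):
            assert abs(np.dot(w.k_hat, w.e_hat)) < 1e-9


class TestScaling:
    def test_identity_at_one_volt_per_meter(self):
        assert scale_pabs(2.5e-9, 1.0) == 2.5e-9

    def test_icnirp_reference_level_factor(self):
        # 61.5 V/m (the 2 GHz general-public reference level) -> x 3782.25
        assert scale_pabs(1.0, 61.5) == pytest.approx(3782.25)

    def test_half_field_quarter_power(self):
        assert scale_pabs(1.0, 0.5) == pytest.approx(0.25)

    def test_far_field_distance(self):
        assert far_field_min_distance(0.0, 60e9) == 0.0
        assert far_field_min_distance(4e-3, 60e9) == pytest.approx(6.41e-3, rel=1e-3)
        f = np.array([1e9, 10e9, 100e9])
        d = [far_field_min_distance(4e-3, fi) for fi in f]
        assert d[0] < d[1] < d[2]


class TestKolmogorovSmirnov:
    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        d, p = ks_two_sample(x, x)
        assert d == 0.0
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_fully_separated_samples_give_one(self):
        d, _ = ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert d == 1.0

    def test_matches_scipy_statistic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 80)
        y = rng.normal(0.5, 1.3, 60)
        d, p = ks_two_sample(x, y)
        ref = ks_2samp(x, y)
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=0.02)


def _toy_result(model_id, pabs_by_freq):
    rows = [
        {
            "model": model_id,
            "frequency_hz": f,
            "wave_id": i + 1,
            "wave_label": f"w{i}",
            "pabs_w": p,
        }
        for f, powers in pabs_by_freq.items()
        for i, p in enumerate(powers)
    ]
    return ExposureResult(
        model_id=model_id,
        table=pd.DataFrame(rows),
        parts=pd.DataFrame(),
        config=ExposureConfig(frequencies_ghz=tuple(f / 1e9 for f in pabs_by_freq)),
    )


class TestAggregate:
    def test_single_result_mean_equals_min_and_max(self):
        res = _toy_result("m", {6e9: [0.3]})
        summary = aggregate([res])
        row = summary.per_model.iloc[0]
        assert row["mean"] == row["min"] == row["max"] == 0.3

    def test_headline_frequency_ratio(self):
        # Overall means 0.1 nW at 6 GHz vs 1.6 nW at 60 GHz -> ratio 16.
        res = _toy_result("m", {6e9: [0.1e-9] * 3, 60e9: [1.6e-9] * 3})
        summary = aggregate([res])
        assert summary.frequency_ratio(60e9, 6e9) == pytest.approx(16.0)

    def test_group_comparison(self):
        males = _toy_result("m1", {6e9: [0.1, 0.2, 0.3]})
        females = _toy_result("f1", {6e9: [0.4, 0.5, 0.6]})
        summary = aggregate(
            [males, females], groups={"male": ["m1"], "female": ["f1"]}
        )
        assert summary.ks_statistic == 1.0
        assert summary.per_group.shape[0] == 2

    def test_empty_group_rejected(self):
        res = _toy_result("m", {6e9: [0.1]})
        with pytest.raises(ValueError):
            aggregate([res], groups={"male": []})


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = ExposureConfig(frequencies_ghz=(6.0, 60.0), seed=3, e_rms=2.0)
        path = tmp_path / "run.yaml"
        cfg.to_yaml(path)
        back = ExposureConfig.from_yaml(path)
        assert back == cfg
        assert back.config_hash() == cfg.config_hash()

    def test_invalid_frequency_rejected_before_simulation(self):
        with pytest.raises(ValueError):
            ExposureConfig(frequencies_ghz=(6.0, -1.0))

    def test_invalid_wave_set_rejected(self):
        with pytest.raises(ValueError):
            ExposureConfig(waves="everything")


@pytest.fixture(scope="module")
def tiny_sphere_model():
    _, model = make_sphere_phantom(0.3e-3, h=60e-6)
    return model


class TestRunProtocol:
    def test_lossless_tissue_absorbs_nothing(self, tiny_sphere_model):
        lossless = DebyeParameters(eps_inf=3.0, relaxations=(), sigma_s=0.0)
        cfg = ExposureConfig(frequencies_ghz=(60.0,), waves=("random", 2))
        res = run_protocol(tiny_sphere_model, lossless, cfg)
        assert np.all(res.table["pabs_w"] == 0.0)

    def test_empty_model_rejected(self):
        from aedosim.geometry import VoxelModel

        empty = VoxelModel(
            spacing=1e-4, origin=np.zeros(3), occupancy=np.zeros((4, 4, 4), bool)
        )
        with pytest.raises(ValueError):
            run_protocol(empty, TABLE_ROWS[0], ExposureConfig(frequencies_ghz=(6.0,)))


class TestProtocolTrends:
    """Physics of the frequency sweep on the mosquito phantom."""

    def test_mean_pabs_increases_2_to_90_ghz(self, phantom_sweep):
        s = phantom_sweep.summary().set_index("frequency_hz")["mean"]
        rising = [s[f] for f in (2e9, 6e9, 12e9, 24e9, 60e9, 90e9)]
        assert np.all(np.diff(rising) > 0)

    def test_sweep_is_unimodal_with_peak_at_or_above_60ghz(self, phantom_sweep):
        s = phantom_sweep.summary().sort_values("frequency_hz")
        means = s["mean"].to_numpy()
        freqs = s["frequency_hz"].to_numpy()
        peak = int(np.argmax(means))
        assert freqs[peak] >= 60e9
        assert np.all(np.diff(means[: peak + 1]) > 0)
        assert np.all(np.diff(means[peak:]) < 0) or peak == len(means) - 1

    def test_three_polarization_bundles_at_6ghz(self, phantom_sweep):
        t = phantom_sweep.table
        t6 = t[np.isclose(t["frequency_hz"], 6e9)]
        assert len(t6) == 12
        for axis in "xyz":
            bundle = t6[t6["wave_label"].str.endswith(f"e{axis}")]["pabs_w"].to_numpy()
            assert bundle.size == 4
            assert (bundle.max() - bundle.min()) / bundle.mean() < 0.10

    def test_random_orientations_stay_within_standard_envelope(
        self, male_phantom, phantom_sweep
    ):
        """Random incidences at 60 GHz do not leave the 12-wave range by
        more than 10% on the near-symmetric phantom."""
        _, model = male_phantom
        cfg = ExposureConfig(frequencies_ghz=(60.0,), waves=("random", 12), seed=19)
        res = run_protocol(model, TABLE_ROWS, cfg)
        t = phantom_sweep.table
        std = t[np.isclose(t["frequency_hz"], 60e9)]["pabs_w"]
        lo, hi = std.min(), std.max()
        rnd = res.table["pabs_w"].to_numpy()
        assert np.all(rnd >= lo * 0.9)
        assert np.all(rnd <= hi * 1.1)

    def test_larger_phantom_absorbs_at_least_as_much(
        self, phantom_sweep, female_sweep
    ):
        """Volume monotonicity: the bigger female-like phantom does not
        absorb less than the male-like one at 6 or 60 GHz."""
        for f in (6e9, 60e9):
            assert female_sweep.mean_pabs(f) >= phantom_sweep.mean_pabs(f)

    def test_group_aggregation_on_sweeps(self, phantom_sweep, female_sweep):
        summary = aggregate(
            [phantom_sweep, female_sweep],
            groups={"female": ["female"], "male": ["male"]},
        )
        assert isinstance(summary, AggregateSummary)
        assert 0.0 <= summary.ks_statistic <= 1.0
        assert 0.0 <= summary.ks_pvalue <= 1.0

    def test_per_part_absorption_recorded(self, phantom_sweep):
        parts = phantom_sweep.parts
        assert set(parts["part"]) == {"head", "thorax", "abdomen"}
        assert (parts["pabs_w"] >= 0).all()
        # Part powers cannot exceed the whole-body power of the same run.
        merged = parts.merge(
            phantom_sweep.table,
            on=["model", "frequency_hz", "wave_id"],
            suffixes=("_part", "_body"),
        )
        grouped = merged.groupby(["frequency_hz", "wave_id"]).agg(
            part_sum=("pabs_w_part", "sum"), body=("pabs_w_body", "first")
        )
        assert np.all(grouped["part_sum"] <= grouped["body"] * (1 + 1e-9))


@pytest.fixture(scope="module")
def small_config():
    return ExposureConfig(frequencies_ghz=(60.0,), waves=("random", 2), seed=5)


class TestSensitivity:
    def test_zero_perturbation_gives_zero_deviation(self, male_phantom, small_config):
        _, model = male_phantom
        report = sensitivity_suite(
            model,
            TABLE_ROWS,
            small_config,
            eps_rel=0.0,
            sigma_rel=0.0,
            include=("dielectric",),
        )
        assert np.all(report["max_rel_deviation"] == 0.0)

    def test_dielectric_perturbation_is_first_order(self, male_phantom, small_config):
        _, model = male_phantom
        report = sensitivity_suite(
            model, TABLE_ROWS, small_config, include=("dielectric", "legs")
        ).set_index("perturbation")
        for name, magnitude in (
            ("eps+", 0.0404),
            ("eps-", 0.0404),
            ("sigma+", 0.0581),
            ("sigma-", 0.0581),
        ):
            assert report.loc[name, "max_rel_deviation"] < 3.0 * magnitude
        # Removing the legs removes absorbing tissue.
        assert report.loc["legs_removed", "mean_ratio"] < 1.0
        assert report.loc["legs_removed", "volume_fraction"] < 1.0
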