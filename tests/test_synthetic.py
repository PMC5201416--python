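"""Synthetic cytometry generator: distributional contracts and determinism."""

import numpy as np
import pandas as pd
import pytest

from il2field.expression import classify_condition, precursor_frequency
from il2field.synthetic import (
    GeneratorConfig,
    MixtureSpec,
    generate_cfse_profile,
    generate_dataset,
    marker_model,
    read_dataset,
    sample_events,
    write_dataset,
)


@pytest.fixture(scope="module")
def config():
    return GeneratorConfig(events_per_condition=500, seed=7)


class TestMixtureSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            MixtureSpec((1.0, 2.0), (0.3, 0.3), (0.5, 0.6))      # weights sum
        with pytest.raises(ValueError):
            MixtureSpec((2.0, 1.0), (0.3, 0.3), (0.5, 0.5))      # unordered
        with pytest.raises(ValueError):
            MixtureSpec((1.0,), (0.0,), (1.0,))                  # scale <= 0


class TestMarkerModel:
    def test_il2_binary_contract(self, config):
        """Antigen dose moves only the producing-component weight, never the
        per-cell IL-2 level."""
        zero = marker_model("IL2", "Th_tg", 0.0, 14.0, config)
        lo = marker_model("IL2", "Th_tg", 125.0, 14.0, config)
        hi = marker_model("IL2", "Th_tg", 2000.0, 14.0, config)
        assert zero.weights[1] == 0.0
        assert lo.log_locations == hi.log_locations
        assert hi.weights[1] > lo.weights[1] > 0.0
        assert hi.weights[1] == pytest.approx(0.75)

    def test_il2_weight_monotone_in_dose(self, config):
        w = [marker_model("IL2", "Th_tg", d, 14.0, config).weights[1]
             for d in config.dose_grid]
        assert all(b >= a for a, b in zip(w, w[1:]))

    def test_cd25_graded_contract(self, config):
        lo = marker_model("CD25", "Th_tg", 8.0, 14.0, config)
        hi = marker_model("CD25", "Th_tg", 2000.0, 14.0, config)
        assert lo.n_components == hi.n_components == 1
        assert hi.log_locations[0] > lo.log_locations[0]

    def test_cd25_treg_exceeds_th_at_zero_dose(self, config):
        th = marker_model("CD25", "Th_tg", 0.0, 14.0, config)
        treg = marker_model("CD25", "Treg_tg", 0.0, 14.0, config)
        assert treg.log_locations[0] > th.log_locations[0]

    def test_endogenous_th_stays_at_baseline(self, config):
        base = marker_model("CD25", "Th_endo", 0.0, 14.0, config)
        high = marker_model("CD25", "Th_endo", 2000.0, 14.0, config)
        assert base.log_locations == high.log_locations
        ps = marker_model("pSTAT5", "Th_endo", 2000.0, 14.0, config)
        assert ps.weights[1] <= 0.01

    def test_unknown_marker_population(self, config):
        with pytest.raises(ValueError):
            marker_model("CD3", "Th_tg", 0.0, 14.0, config)
        with pytest.raises(ValueError):
            marker_model("IL2", "NK", 0.0, 14.0, config)


class TestSampleEvents:
    def test_single_component_log_mean(self):
        spec = MixtureSpec((2.0,), (0.3,), (1.0,))
        x = sample_events(spec, 100000, seed=1)
        se = 0.3 / np.sqrt(len(x))
        assert abs(np.log10(x).mean() - 2.0) < 3 * se

    def test_two_component_split_fraction(self):
        spec = MixtureSpec((1.0, 3.0), (0.2, 0.2), (0.25, 0.75))
        x = sample_events(spec, 100000, seed=2)
        frac_hi = np.mean(np.log10(x) > 2.0)
        assert frac_hi == pytest.approx(0.75, abs=0.01)

    def test_determinism(self):
        spec = MixtureSpec((1.0, 3.0), (0.2, 0.2), (0.5, 0.5))
        assert np.array_equal(sample_events(spec, 100, seed=3),
                              sample_events(spec, 100, seed=3))


class TestGenerateDataset:
    def test_factorial_row_count(self, config):
        df = generate_dataset(config, populations=("Th_tg", "Treg_tg"),
                              doses=(0.0, 2000.0), times=(14.0,),
                              markers=("IL2", "CD25"))
        assert len(df) == 2 * 2 * 1 * 2 * config.events_per_condition
        assert (df.fi > 0).all()

    def test_il2_cd25_independent_within_condition(self):
        cfg = GeneratorConfig(events_per_condition=8000, seed=3)
        df = generate_dataset(cfg, populations=("Th_tg",), doses=(0.0, 2000.0),
                              times=(14.0,), markers=("IL2", "CD25"))
        wide = df[df.dose_ug == 2000].pivot(index="event_id", columns="marker",
                                            values="fi")
        pos = (np.log10(wide.IL2) > 1.5).astype(float)
        r = np.corrcoef(pos, wide.CD25)[0, 1]
        assert abs(r) < 0.03

    def test_cfos_coupled_nfat_not(self):
        cfg = GeneratorConfig(events_per_condition=8000, seed=4)
        df = generate_dataset(cfg, populations=("Th_tg",), doses=(500.0,),
                              times=(14.0,), markers=("IL2", "cFos", "NFATc2"))
        wide = df.pivot(index="event_id", columns="marker", values="fi")
        pos = (np.log10(wide.IL2) > 1.5).astype(float)
        assert np.corrcoef(pos, np.log10(wide.cFos))[0, 1] > 0.3
        assert abs(np.corrcoef(pos, np.log10(wide.NFATc2))[0, 1]) < 0.05

    def test_seed_fixes_every_byte(self, config, tmp_path):
        kw = dict(populations=("Th_tg",), doses=(0.0, 125.0), times=(14.0,),
                  markers=("IL2",))
        a, b = generate_dataset(config, **kw), generate_dataset(config, **kw)
        pd.testing.assert_frame_equal(a, b)
        write_dataset(a, tmp_path / "a.csv", config)
        write_dataset(b, tmp_path / "b.csv", config)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        pd.testing.assert_frame_equal(read_dataset(tmp_path / "a.csv"), a,
                                      check_dtype=False)

    def test_generation_analysis_round_trip(self):
        """Percent-positive recovered by the mixture stage matches the
        generating weight within Monte-Carlo error."""
        cfg = GeneratorConfig(events_per_condition=20000, seed=11)
        df = generate_dataset(cfg, populations=("Th_tg",), doses=(0.0, 500.0),
                              times=(14.0,), markers=("IL2",))
        x = df[df.dose_ug == 500].fi.to_numpy()
        truth = 100 * marker_model("IL2", "Th_tg", 500.0, 14.0, cfg).weights[1]
        s = classify_condition(x, n_boot=100, seed=0)
        assert s.expression_call == "binary"
        assert s.percent_positive == pytest.approx(truth, abs=2.0)


class TestCfse:
    def test_extremes(self):
        none = generate_cfse_profile(100, 0.0, [1.0], seed=0)
        assert none.generation_counts == (100, 0)
        allg1 = generate_cfse_profile(100, 1.0, [1.0], seed=0)
        assert allg1.generation_counts == (0, 200)

    def test_round_trip_recovers_dividing_fraction(self):
        prof = generate_cfse_profile(10000, 0.5, np.ones(4) / 4, seed=5)
        assert precursor_frequency(prof) == pytest.approx(50.0, abs=2.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            generate_cfse_profile(0, 0.5, [1.0])
        with pytest.raises(ValueError):
            generate_cfse_profile(10, 1.5, [1.0])
        with pytest.raises(ValueError):
            generate_cfse_profile(10, 0.5, [0.6, 0.6])
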