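"""Synthetic cohort generator: contracts, determinism, ON/OFF structure."""

import numpy as np
import pytest

import pdvoice as pv
from pdvoice.errors import ConfigurationError
from pdvoice.pac import quantize
from pdvoice.synthetic import (
    ATTRIBUTES,
    CohortConfig,
    PROTOCOLS,
    PhoneAttributeMap,
    effect_multipliers,
    generate_cohort,
    single_informative_config,
    synthesize_audio,
    synthesize_posteriors,
)


class TestAttributeInventory:
    def test_21_attributes_with_silence(self):
        assert len(ATTRIBUTES) == 21
        assert len(set(ATTRIBUTES)) == 21
        assert "silence" in ATTRIBUTES

    def test_named_distinctive_features_present(self):
        named = {
            "continuant", "tense", "voice", "fricative", "retroflex", "velar",
            "high", "coronal", "mid", "back", "vocalic", "anterior", "labial",
        }
        assert named <= set(ATTRIBUTES)

    def test_silence_phone_is_pure_silence(self):
        amap = PhoneAttributeMap.default()
        v = amap.vector("sil")
        assert v[ATTRIBUTES.index("silence")] == 1.0 and v.sum() == 1.0

    def test_open_vowel_composition(self):
        # /a/ carries continuant, back, vocalic and voice
        v = PhoneAttributeMap.default().vector("a")
        for name in ("continuant", "back", "vocalic", "voice"):
            assert v[ATTRIBUTES.index(name)] == 1.0

    def test_every_vector_has_21_entries(self):
        amap = PhoneAttributeMap.default()
        assert all(vec.size == 21 for vec in amap.vectors.values())

    def test_unknown_phone_rejected(self):
        with pytest.raises(ConfigurationError):
            PhoneAttributeMap.default().vector("zz")


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_patients=1),
            dict(protocols=("pataka", "nonsense")),
            dict(dropout_prob_off=1.5),
            dict(rate_factor_off=0.0),
            dict(effect_sizes={"fricative": 2.0}),
            dict(effect_sizes={"no_such_attr": 0.1}),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            CohortConfig(**kw).validate()

    def test_null_config_zeroes_every_effect(self):
        cfg = CohortConfig.null()
        assert cfg.dropout_prob_off == 0 and cfg.silence_boost_off == 0
        assert cfg.rate_factor_off == 1.0 and not cfg.effect_sizes
        assert cfg.gain_reduction_db == 0 and cfg.pitch_jitter == 0


class TestPosteriorSynthesis:
    def test_zero_noise_limit_is_exactly_canonical(self):
        cfg = CohortConfig(noise_sd=0.0)
        stream = synthesize_posteriors("pataka", "ON", 1.0, seed=0, config=cfg)
        amap = PhoneAttributeMap.default()
        canonical = {tuple(v) for v in amap.vectors.values()}
        assert {tuple(row) for row in stream.posteriors} <= canonical

    def test_values_always_in_unit_interval(self):
        for protocol in PROTOCOLS:
            s = synthesize_posteriors(protocol, "OFF", 1.3, seed=3)
            assert s.posteriors.min() >= 0.0 and s.posteriors.max() <= 1.0
            assert s.posteriors.shape[1] == 21

    def test_full_dropout_suppresses_all_active_attributes(self):
        cfg = CohortConfig(dropout_prob_off=1.0, silence_boost_off=0.0, noise_sd=0.0)
        off = synthesize_posteriors("pataka", "OFF", 1.0, seed=0, config=cfg)
        on = synthesize_posteriors("pataka", "ON", 1.0, seed=0, config=cfg)
        bits_off = quantize(off).sum(axis=1).mean()
        bits_on = quantize(on).sum(axis=1).mean()
        # OFF keeps only silence-frame bits; every articulated frame is empty
        assert bits_off < bits_on
        non_sil = np.delete(quantize(off), ATTRIBUTES.index("silence"), axis=1)
        assert non_sil.sum() == 0

    def test_off_codes_sparser_whenever_dropout_positive(self):
        for seed in range(3):
            on = synthesize_posteriors("months", "ON", 1.0, seed=seed)
            off = synthesize_posteriors("months", "OFF", 1.0, seed=seed)
            assert quantize(off).sum(axis=1).mean() < quantize(on).sum(axis=1).mean()

    def test_pataka_varies_the_four_reported_attributes(self):
        s = synthesize_posteriors("pataka", "ON", 1.0, seed=1)
        q = quantize(s)
        for name in ("silence", "continuant", "tense", "voice"):
            col = q[:, ATTRIBUTES.index(name)]
            assert col.min() == 0 and col.max() == 1, name

    def test_off_duration_scaled_by_rate_factor(self):
        cfg = CohortConfig(rate_factor_off=1.5, noise_sd=0.0, silence_boost_off=0.0)
        on = synthesize_posteriors("vowels", "ON", 1.0, seed=0, config=cfg)
        off = synthesize_posteriors("vowels", "OFF", 1.0, seed=0, config=cfg)
        assert off.n_frames > on.n_frames * 1.3


class TestAudioSynthesis:
    def test_rate_and_duration_contract(self):
        w = synthesize_audio("digits", "ON", 1.0, seed=0)
        assert w.rate == 44_100
        assert w.duration >= 10.0
        assert np.abs(w.samples).max() <= 1.0

    def test_null_effect_makes_states_identical(self):
        on = synthesize_audio("vowels", "ON", 0.0, seed=7)
        off = synthesize_audio("vowels", "OFF", 0.0, seed=7)
        assert np.allclose(on.samples, off.samples)

    def test_six_db_gain_reduction_halves_rms(self):
        cfg = CohortConfig(
            gain_reduction_db=6.0, aspiration_level=0.0, pitch_jitter=0.0,
            rate_factor_off=1.0,
        )
        on = synthesize_audio("vowels", "ON", 1.0, seed=5, config=cfg)
        off = synthesize_audio("vowels", "OFF", 1.0, seed=5, config=cfg)
        ratio = np.sqrt((off.samples**2).mean() / (on.samples**2).mean())
        assert ratio == pytest.approx(0.5, abs=0.05)


class TestCohortAssembly:
    def test_manifest_counts_14_by_7_by_2(self):
        cohort = generate_cohort(CohortConfig(n_patients=14, seed=9), audio=False)
        assert len(cohort.manifest) == 14 * 7 * 2
        assert set(cohort.manifest["state"]) == {"ON", "OFF"}
        assert len(cohort.streams) == 196

    def test_generation_is_bit_reproducible(self, tmp_path):
        cfg = CohortConfig(n_patients=2, protocols=("pataka", "vowels"), seed=5)
        generate_cohort(cfg, out_dir=tmp_path / "a", audio=False)
        generate_cohort(cfg, out_dir=tmp_path / "b", audio=False)
        for f in sorted((tmp_path / "a").glob("*.csv")):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_clinical_table_tracks_effect_multiplier(self):
        cohort = generate_cohort(CohortConfig(n_patients=12, seed=2), audio=False)
        delta = (
            cohort.clinical["III Total OFF"] - cohort.clinical["III Total ON"]
        ).to_numpy(dtype=float)
        r = np.corrcoef(delta, cohort.multipliers.mean(axis=1))[0, 1]
        assert r > 0.5
        assert (cohort.clinical["III Total OFF"] >= cohort.clinical["III Total ON"]).all()

    def test_explicit_multiplier_matrix_respected(self):
        cfg = single_informative_config(n_patients=4, seed=0)
        mult = effect_multipliers(cfg)
        assert mult.shape == (4, 3)
        assert np.count_nonzero(mult) == 4  # one informative protocol each

    def test_files_written_and_listed(self, tmp_path):
        cfg = CohortConfig(n_patients=2, protocols=("vowels",), seed=1)
        cohort = generate_cohort(cfg, out_dir=tmp_path, audio=True)
        for row in cohort.manifest.itertuples(index=False):
            assert (tmp_path / f"p{row.patient_id:02d}_{row.protocol}_{row.state}.csv").exists()
            assert (tmp_path / f"p{row.patient_id:02d}_{row.protocol}_{row.state}.wav").exists()
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "clinical_scores.csv").exists()
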