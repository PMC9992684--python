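"""Cohort and map generator: distributions, ground truth, determinism."""

import dataclasses

import numpy as np
import pytest

from regionage.synthetic import (
    FA,
    GM,
    SubjectRecord,
    SyntheticConfig,
    ModalitySpec,
    generate_bold,
    generate_region_maps,
    generate_subjects,
    informative_correlation,
    inject_pathology,
    make_atlas,
    slope_for_correlation,
    subjects_to_frame,
)


def small_cfg(**kw) -> SyntheticConfig:
    base = dict(
        n_hc_train=40, n_hc_test=0, n_scz=0,
        atlas_spec={GM: ModalitySpec(3, 30, baseline=10.0, value_scale=1.0, slope_sign=-1)},
        effect_spec={},
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestSubjects:
    def test_training_cohort_size_and_age_range(self):
        cfg = SyntheticConfig(n_hc_train=230, n_hc_test=0, n_scz=0, effect_spec={})
        subs = generate_subjects(cfg, np.random.default_rng(0))
        assert len(subs) == 230
        assert all(s.group == "HC" for s in subs)
        ages = [s.chronological_age for s in subs]
        assert min(ages) >= 20 and max(ages) <= 84

    def test_no_patients_means_no_clinical_fields(self):
        subs = generate_subjects(small_cfg(), np.random.default_rng(0))
        assert all(s.group == "HC" for s in subs)
        assert all(s.panss_positive is None and s.cpz_dose is None
                   and s.illness_duration is None for s in subs)

    def test_patient_records_carry_consistent_clinical_fields(self):
        cfg = small_cfg(n_scz=80)
        subs = [s for s in generate_subjects(cfg, np.random.default_rng(3))
                if s.group == "SCZ"]
        assert len(subs) == 80
        for s in subs:
            assert s.age_of_onset is not None and s.age_of_onset < s.chronological_age
            assert s.illness_duration is not None and s.illness_duration > 0
            assert s.panss_positive is not None
        # dose recorded for only part of the group, never for controls
        dosed = sum(s.cpz_dose is not None for s in subs)
        assert 0 < dosed < len(subs)

    def test_fixed_seed_reproduces_records_exactly(self):
        cfg = small_cfg(n_scz=10)
        a = generate_subjects(cfg, np.random.default_rng(42))
        b = generate_subjects(cfg, np.random.default_rng(42))
        assert [dataclasses.asdict(x) for x in a] == [dataclasses.asdict(x) for x in b]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(age_range=(84, 20))
        with pytest.raises(ValueError):
            SyntheticConfig(n_hc_train=0)
        with pytest.raises(ValueError):
            SyntheticConfig(signal_fraction=1.5)

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            SubjectRecord("x", 30.0, "M", "HC", 29, 15, panss_positive=12.0)
        with pytest.raises(ValueError):
            SubjectRecord("x", 30.0, "M", "SCZ", 25, 12, age_of_onset=35.0)

    def test_frame_columns_match_record_fields(self):
        subs = generate_subjects(small_cfg(), np.random.default_rng(0))
        df = subjects_to_frame(subs)
        assert list(df.columns)[:4] == ["subject_id", "chronological_age", "sex", "group"]
        assert len(df) == len(subs)


class TestRegionMaps:
    def test_zero_slope_gives_no_age_correlation(self):
        cfg = small_cfg(n_hc_train=230, signal_slope=0.0)
        atlas = make_atlas(GM, 3, 30)
        rng = np.random.default_rng(5)
        subs = generate_subjects(cfg, rng)
        maps = generate_region_maps(subs, atlas, cfg, rng)
        ages = np.array([s.chronological_age for s in subs])
        bound = 3.0 / np.sqrt(len(subs))
        rs = np.concatenate([
            np.corrcoef(np.c_[maps.values[rid], ages], rowvar=False)[-1, :-1]
            for rid in maps.values])
        assert np.mean(np.abs(rs) < bound) >= 0.99

    def test_noiseless_full_signal_is_exactly_linear_in_age(self):
        cfg = small_cfg(noise_sd=0.0, signal_fraction=1.0)
        atlas = make_atlas(GM, 3, 30)
        rng = np.random.default_rng(5)
        subs = generate_subjects(cfg, rng)
        maps = generate_region_maps(subs, atlas, cfg, rng)
        ages = np.array([s.chronological_age for s in subs])
        for rid, vals in maps.values.items():
            r = np.corrcoef(np.c_[vals, ages], rowvar=False)[-1, :-1]
            assert np.allclose(np.abs(r), 1.0, atol=1e-12)

    def test_informative_voxel_correlation_matches_closed_form(self):
        # slope/noise chosen for population |r| = 0.6; observed mean within 0.05
        cfg = SyntheticConfig(
            n_hc_train=230, n_hc_test=0, n_scz=0,
            atlas_spec={GM: ModalitySpec(5, 200, baseline=10.0, slope_sign=-1)},
            effect_spec={}, signal_fraction=0.2)
        assert informative_correlation(cfg.signal_slope, cfg.noise_sd, cfg.age_sd) == \
            pytest.approx(0.6, abs=1e-12)
        atlas = make_atlas(GM, 5, 200)
        rng = np.random.default_rng(11)
        subs = generate_subjects(cfg, rng)
        maps = generate_region_maps(subs, atlas, cfg, rng)
        ages = np.array([s.chronological_age for s in subs])
        obs = []
        for rid, vals in maps.values.items():
            info = maps.informative[rid]
            r = np.corrcoef(np.c_[vals[:, info], ages], rowvar=False)[-1, :-1]
            obs.append(np.abs(r).mean())
        assert np.mean(obs) == pytest.approx(0.6, abs=0.05)

    def test_slope_for_correlation_inverts_closed_form(self):
        s = slope_for_correlation(0.45, 2.0, 18.0)
        assert informative_correlation(s, 2.0, 18.0) == pytest.approx(0.45, abs=1e-12)

    def test_fa_maps_bounded_and_finite(self):
        cfg = SyntheticConfig(
            n_hc_train=50, n_hc_test=0, n_scz=0,
            atlas_spec={FA: ModalitySpec(4, 50, baseline=0.5, value_scale=0.3, slope_sign=-1)},
            effect_spec={})
        atlas = make_atlas(FA, 4, 50)
        rng = np.random.default_rng(2)
        subs = generate_subjects(cfg, rng)
        maps = generate_region_maps(subs, atlas, cfg, rng)
        for vals in maps.values.values():
            assert np.isfinite(vals).all()
            assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_fixed_seed_reproduces_maps_bitwise(self):
        cfg = small_cfg()
        atlas = make_atlas(GM, 3, 30)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            subs = generate_subjects(cfg, rng)
            out.append(generate_region_maps(subs, atlas, cfg, rng))
        for rid in out[0].values:
            assert np.array_equal(out[0].values[rid], out[1].values[rid])
            assert np.array_equal(out[0].informative[rid], out[1].informative[rid])


class TestInjectPathology:
    def _setup(self, n_scz=20, **kw):
        cfg = small_cfg(n_scz=n_scz, **kw)
        atlas = make_atlas(GM, 3, 30)
        rng = np.random.default_rng(31)
        subs = generate_subjects(cfg, rng)
        maps = generate_region_maps(subs, atlas, cfg, rng)
        return cfg, subs, maps

    def test_empty_spec_is_identity(self):
        cfg, subs, maps = self._setup()
        out = inject_pathology(maps, subs, {}, cfg)
        for rid in maps.values:
            assert np.array_equal(out.values[rid], maps.values[rid])

    def test_injected_shift_equals_gap_times_slope(self):
        cfg, subs, maps = self._setup()
        out = inject_pathology(maps, subs, {1: 5.0}, cfg)
        spec = cfg.atlas_spec[GM]
        scz = np.array([s.group == "SCZ" for s in subs])
        info = maps.informative[1]
        delta = out.values[1] - maps.values[1]
        expected = spec.slope_sign * spec.value_scale * cfg.signal_slope * 5.0
        assert np.allclose(delta[np.ix_(scz, info)], expected)
        # controls and untouched regions unchanged
        assert np.all(delta[~scz] == 0)
        assert np.array_equal(out.values[2], maps.values[2])

    def test_duration_scaling_is_mean_normalized(self):
        # scaled shift = unscaled shift * duration / mean(duration); in
        # particular a patient at the cohort-mean duration is unchanged
        cfg, subs, maps = self._setup()
        out_u = inject_pathology(maps, subs, {1: 5.0}, cfg, duration_scaled=False)
        out_s = inject_pathology(maps, subs, {1: 5.0}, cfg, duration_scaled=True)
        info = maps.informative[1]
        durs = np.array([s.illness_duration for s in subs if s.group == "SCZ"])
        scz_rows = [i for i, s in enumerate(subs) if s.group == "SCZ"]
        du = (out_u.values[1] - maps.values[1])[np.ix_(scz_rows, info)]
        ds = (out_s.values[1] - maps.values[1])[np.ix_(scz_rows, info)]
        assert np.allclose(ds, du * (durs / durs.mean())[:, None])

    def test_unknown_region_raises(self):
        cfg, subs, maps = self._setup()
        with pytest.raises(KeyError):
            inject_pathology(maps, subs, {99: 5.0}, cfg)


class TestBold:
    def _cfg(self, **kw):
        kw.setdefault("bold_n_timepoints", 80)
        return small_cfg(n_hc_train=6, **kw)

    def test_zero_idiosyncratic_noise_gives_perfect_correlations(self):
        cfg = self._cfg(bold_idio_sd=0.0)
        atlas = make_atlas(GM, 1, 8)
        rng = np.random.default_rng(4)
        subs = generate_subjects(cfg, rng)
        series, weights = generate_bold(subs, atlas, cfg, rng)
        for sid, ts in series.items():
            corr = np.corrcoef(ts)
            assert np.allclose(np.abs(corr), 1.0, atol=1e-10)

    def test_zero_common_weight_gives_near_zero_mean_correlation(self):
        cfg = self._cfg(bold_common_weight=0.0, bold_weight_age_slope=0.0,
                        bold_n_timepoints=200)
        atlas = make_atlas(GM, 1, 30)
        rng = np.random.default_rng(4)
        subs = generate_subjects(cfg, rng)
        series, weights = generate_bold(subs, atlas, cfg, rng)
        assert all(w == 0.0 for w in weights.values())
        offdiag = []
        for ts in series.values():
            c = np.corrcoef(ts)
            offdiag.append(c[np.triu_indices_from(c, k=1)].mean())
        assert abs(np.mean(offdiag)) < 0.05

    def test_weights_increase_with_age(self):
        cfg = self._cfg()
        atlas = make_atlas(GM, 1, 4)
        rng = np.random.default_rng(4)
        subs = generate_subjects(cfg, rng)
        _, weights = generate_bold(subs, atlas, cfg, rng)
        ages = np.array([s.chronological_age for s in subs])
        ws = np.array([weights[s.subject_id] for s in subs])
        assert np.corrcoef(ages, ws)[0, 1] > 0.99

    def test_fixed_seed_reproduces_series(self):
        cfg = self._cfg()
        atlas = make_atlas(GM, 1, 5)
        subs = generate_subjects(cfg, np.random.default_rng(4))
        a, _ = generate_bold(subs, atlas, cfg, np.random.default_rng(8))
        b, _ = generate_bold(subs, atlas, cfg, np.random.default_rng(8))
        for sid in a:
            assert np.array_equal(a[sid], b[sid])

    def test_too_short_series_rejected(self):
        cfg = self._cfg(bold_n_timepoints=1)
        atlas = make_atlas(GM, 1, 5)
        subs = generate_subjects(cfg, np.random.default_rng(4))
        with pytest.raises(ValueError):
            generate_bold(subs, atlas, cfg, np.random.default_rng(8))
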