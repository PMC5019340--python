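"""Synthetic cohort generator: profiles, mixing, noise statistics, determinism."""

import numpy as np
import pytest

from desilasso.io import CLASSES, MassAxis
from desilasso.synthetic import (
    NoiseModel,
    Region,
    SyntheticCohortConfig,
    TissueLayout,
    banded_layout,
    class_template,
    default_class_profiles,
    generate_cohort,
    generate_pixel_spectrum,
    generate_sample,
    mixed_layout,
    sample_patient_effect,
)


class TestDefaultProfiles:
    def test_named_lipid_peaks_present(self):
        prof = default_class_profiles()
        glands_mz = {p.mz for p in prof["glands"].peaks}
        # free fatty acids and their dimers
        assert {255.3, 281.2, 303.3, 537.0, 563.0} <= glands_mz
        cancer_mz = {p.mz for p in prof["cancer"].peaks}
        assert {303.3, 331.2, 773.6, 792.4, 794.4, 885.6} <= cancer_mz
        stroma_mz = {p.mz for p in prof["stroma"].peaks}
        assert {255.3, 281.2, 788.8, 816.5, 885.6} <= stroma_mz

    def test_stroma_has_lower_total_abundance(self):
        prof = default_class_profiles()
        assert prof["stroma"].total_abundance_scale < prof["glands"].total_abundance_scale
        assert prof["stroma"].total_abundance_scale < prof["cancer"].total_abundance_scale


class TestPixelSpectrum:
    def test_pure_composition_is_exact_template(self, small_axis, small_profiles, noise_off):
        spec = generate_pixel_spectrum(
            (1, 0, 0), small_profiles, noise_off, axis=small_axis
        )
        expected = class_template(small_profiles["cancer"], small_axis)
        assert np.array_equal(spec, expected)

    def test_half_mix_is_arithmetic_mean(self, small_axis, small_profiles, noise_off):
        spec = generate_pixel_spectrum(
            (0.5, 0.5, 0), small_profiles, noise_off, axis=small_axis
        )
        t_c = class_template(small_profiles["cancer"], small_axis)
        t_g = class_template(small_profiles["glands"], small_axis)
        assert np.allclose(spec, 0.5 * (t_c + t_g))

    def test_composition_must_sum_to_one(self, small_axis, small_profiles, noise_off):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_pixel_spectrum((0.5, 0.5, 0.1), small_profiles, noise_off,
                                    axis=small_axis)

    def test_noisy_mean_recovers_template(self, small_axis, small_profiles, rng):
        """Monte-Carlo: the mean over many draws matches template + baseline."""
        noise = NoiseModel(multiplicative_cv=0.3, baseline_level=1.0)
        comp = (0.2, 0.5, 0.3)
        draws = np.stack([
            generate_pixel_spectrum(comp, small_profiles, noise, rng=rng,
                                    axis=small_axis)
            for _ in range(10000)
        ])
        expected = sum(
            c * class_template(small_profiles[k], small_axis)
            for c, k in zip(comp, CLASSES)
        ) + noise.baseline_level
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        # compare only channels with non-trivial signal
        sel = expected > 0.5
        assert np.all(np.abs(draws.mean(axis=0) - expected)[sel] <= 3 * se[sel] + 1e-9)


class TestLayouts:
    def test_banded_layout_partitions(self):
        layout = banded_layout((12, 10), {"glands": 0.5, "cancer": 0.3, "stroma": 0.2})
        cover = np.zeros((12, 10), dtype=int)
        for reg in layout.regions:
            cover += reg.pixel_mask
        assert cover.max() == 1 and cover.sum() == 120

    def test_zero_area_region_rejected(self):
        with pytest.raises(ValueError, match="zero area"):
            Region("empty", np.zeros((3, 3), dtype=bool), (1.0, 0, 0))

    def test_overlapping_regions_rejected(self):
        m = np.ones((2, 2), dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            TissueLayout((2, 2), (Region("a", m, (1, 0, 0)), Region("b", m, (0, 1, 0))))


class TestGenerateSample:
    def test_pure_region_labels(self, small_axis, small_profiles, noise_off, rng):
        layout = banded_layout((6, 6), {"glands": 1.0})
        sample, mask = generate_sample(
            layout, small_profiles, noise_off, rng, axis=small_axis
        )
        assert (mask.labels == 2).all()  # every pixel labeled glands

    def test_noise_off_spectra_are_convex_blends(self, small_axis, small_profiles,
                                                 noise_off, rng):
        comp = np.array([0.3, 0.0, 0.7])
        layout = mixed_layout((5, 5), comp)
        beta = 0.4
        sample, mask = generate_sample(
            layout, small_profiles, noise_off, rng, axis=small_axis, beta=beta
        )
        t = np.stack([class_template(small_profiles[c], small_axis) for c in CLASSES])
        t_mix = comp @ t
        for (r, c) in zip(*np.nonzero(sample.tissue)):
            lab = mask.labels[r, c] - 1
            expected = (1 - beta) * t[lab] + beta * t_mix
            assert np.allclose(sample.spectra[r, c], expected)

    def test_label_fractions_follow_composition(self, small_axis, small_profiles,
                                                noise_off, rng):
        """Binomial oracle: cancer-label fraction ~ 0.15 within 3 sigma."""
        layout = mixed_layout((100, 100), (0.15, 0.85, 0.0))
        _, mask = generate_sample(layout, small_profiles, noise_off, rng,
                                  axis=small_axis)
        frac = (mask.labels == 1).mean()
        sigma = np.sqrt(0.15 * 0.85 / 10000)
        assert abs(frac - 0.15) <= 3 * sigma

    def test_batch_peaks_added_everywhere(self, small_axis, small_profiles,
                                          noise_off, rng):
        layout = banded_layout((4, 4), {"stroma": 1.0})
        sample, _ = generate_sample(
            layout, small_profiles, noise_off, rng, axis=small_axis,
            batch_peaks=[(106.0, 50.0, 0.2)],
        )
        ch = np.argmin(np.abs(small_axis.mz_values - 106.0))
        assert (sample.spectra[sample.tissue][:, ch] > 25).all()


class TestGenerateCohort:
    def _config(self, axis, profiles, **kw):
        layout = banded_layout((5, 5), {"glands": 0.6, "cancer": 0.4})
        base = dict(n_patients=3, layouts=[layout], seed=42, axis=axis,
                    profiles=profiles)
        base.update(kw)
        return SyntheticCohortConfig(**base)

    def test_same_seed_identical(self, small_axis, small_profiles):
        cfg = self._config(small_axis, small_profiles)
        c1, m1 = generate_cohort(cfg)
        c2, m2 = generate_cohort(cfg)
        assert m1.equals(m2)
        for (s1, k1), (s2, k2) in zip(c1, c2):
            assert np.array_equal(s1.spectra, s2.spectra)
            assert np.array_equal(k1.labels, k2.labels)

    def test_seed_recorded_in_manifest(self, small_axis, small_profiles):
        _, manifest = generate_cohort(self._config(small_axis, small_profiles))
        assert (manifest["seed"] == 42).all()

    def test_patients_differ_only_through_patient_effect(self, small_axis,
                                                         small_profiles):
        """With patient_effect_sd = 0 and noise off, patients are replicas."""
        noise = NoiseModel(shot_noise=False, multiplicative_cv=0.0,
                           baseline_level=0.0, patient_effect_sd=0.0)
        layout = banded_layout((4, 4), {"glands": 1.0})
        cfg = SyntheticCohortConfig(n_patients=2, layouts=[layout], seed=1,
                                    axis=small_axis, profiles=small_profiles,
                                    noise=noise)
        cohort, _ = generate_cohort(cfg)
        assert np.array_equal(cohort[0][0].spectra, cohort[1][0].spectra)
        noise2 = NoiseModel(shot_noise=False, multiplicative_cv=0.0,
                            baseline_level=0.0, patient_effect_sd=0.5)
        cfg2 = SyntheticCohortConfig(n_patients=2, layouts=[layout], seed=1,
                                     axis=small_axis, profiles=small_profiles,
                                     noise=noise2)
        cohort2, _ = generate_cohort(cfg2)
        assert not np.array_equal(cohort2[0][0].spectra, cohort2[1][0].spectra)


def test_patient_effect_multipliers_positive(small_profiles, rng):
    eff = sample_patient_effect(small_profiles, 0.3, rng)
    for label, prof in small_profiles.items():
        assert eff[label].shape == (len(prof.peaks),)
        assert (eff[label] > 0).all()
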