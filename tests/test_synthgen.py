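import dataclasses

import numpy as np
import pytest

from libspec import synthgen
from libspec.io_core import WavelengthAxis
from libspec.synthgen import (
    GeneratorConfig,
    LineSpec,
    baseline_channel_mask,
    between_class_distance,
    default_config,
    default_lines,
    default_profiles,
    generate_dataset,
    render_clean_spectrum,
    signature_profiles,
)


@pytest.fixture(scope="module")
def axis():
    return WavelengthAxis(np.linspace(229.0, 878.0, 4000))


class TestRenderCleanSpectrum:
    def test_empty_line_list_is_zero(self, axis):
        out = render_clean_spectrum((), (), axis)
        assert np.all(out == 0)

    def test_linearity_in_multiplier(self, axis):
        line = (LineSpec(center=500.0, width=0.5, base_intensity=2.0),)
        one = render_clean_spectrum(line, [1.0], axis)
        two = render_clean_spectrum(line, [2.0], axis)
        np.testing.assert_allclose(two, 2.0 * one)

    def test_integral_adds_over_nonoverlapping_lines(self, axis):
        """Two well-separated Gaussians: the quadrature integral of the sum
        equals the sum of the analytic per-line integrals A·sigma·sqrt(2*pi)."""
        lines = (
            LineSpec(center=400.0, width=0.8, base_intensity=3.0),
            LineSpec(center=700.0, width=0.5, base_intensity=1.5),
        )
        out = render_clean_spectrum(lines, [1.0, 1.0], axis)
        numeric = np.trapezoid(out, axis.values)
        analytic = sum(
            ln.base_intensity * ln.width * np.sqrt(2 * np.pi) for ln in lines
        )
        assert numeric == pytest.approx(analytic, rel=1e-4)


class TestDesignArithmetic:
    def test_full_survey_counts(self):
        cfg = default_config()
        assert sum(cfg.plants_per_origin) == 118
        assert cfg.n_records == 3776

    def test_generated_counts_match_design(self):
        # the sampling hierarchy, not the spectral axis, fixes the counts
        cfg = dataclasses.replace(default_config(), n_variables=80)
        ds = generate_dataset(cfg)
        assert ds.n_spectra == 3776
        assert len(ds.meta["tablet_id"].unique()) == 236
        assert set(ds.meta["origin"]) == set(range(1, 13))


class TestGenerateDataset:
    def test_seeded_runs_are_bit_identical(self, fixture_config):
        a = generate_dataset(fixture_config)
        b = generate_dataset(fixture_config)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        c = generate_dataset(dataclasses.replace(fixture_config, seed=99))
        assert not np.array_equal(a.intensities, c.intensities)

    def test_zero_noise_makes_origin_spectra_identical(self, fixture_config):
        cfg = dataclasses.replace(
            fixture_config,
            noise_sd=0.0,
            profiles=tuple(
                dataclasses.replace(p, jitter_sd=0.0) for p in fixture_config.profiles
            ),
        )
        ds = generate_dataset(cfg)
        sub = ds.select_part("underground")
        one_origin = sub.intensities[(sub.meta["origin"] == 4).to_numpy()]
        assert np.all(one_origin == one_origin[0])

    def test_baseline_channels_are_near_silent(self, fixture_config, small_dataset):
        """Planted pure-noise channels have SDs far below the line channels."""
        baseline = baseline_channel_mask(fixture_config)
        assert baseline.sum() == int(0.85 * fixture_config.n_variables)
        sd = small_dataset.intensities.std(axis=0, ddof=1)
        assert sd[baseline].max() < 1e-3 * np.median(sd[~baseline])

    def test_invalid_config_rejected(self):
        lines = default_lines()
        with pytest.raises(Exception):
            GeneratorConfig(
                n_variables=100,
                axis_range=(229.0, 878.0),
                lines=lines,
                profiles=default_profiles(lines),
                plants_per_origin=(2,) * 11,  # must match the 12 profiles
            )


class TestSeparability:
    def test_wider_origin_effects_do_not_reduce_separability(self):
        lines = default_lines()
        dists = []
        for scale in (0.1, 0.4, 0.8):
            cfg = GeneratorConfig(
                n_variables=2000,
                axis_range=(229.0, 878.0),
                lines=lines,
                profiles=default_profiles(lines, effect_scale=scale),
                plants_per_origin=(1,) * 12,
            )
            dists.append(between_class_distance(cfg))
        assert dists[0] <= dists[1] <= dists[2]

    def test_signature_profiles_are_equidistant(self):
        lines = default_lines()
        profiles = signature_profiles(lines, effect_scale=1.0)
        mult = np.stack([p.multipliers for p in profiles])
        logm = np.log(mult)
        d = [
            np.linalg.norm(logm[i] - logm[j])
            for i in range(12)
            for j in range(i + 1, 12)
        ]
        assert np.ptp(d) / np.mean(d) < 0.25  # near-uniform pairwise distances
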