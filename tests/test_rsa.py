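"""Feature extraction ordering, similarity timecourses, baselining."""

import numpy as np
import pytest

from intersep.coherence import FeatureTemplate
from intersep.rsa import (
    Z_CLIP,
    baseline_contrast,
    extract_ab_features,
    fisher_z,
    neighborhood_topography,
    similarity_timecourse,
    window_average,
)
from intersep.tfr import TimeFrequencyCube


def _cube(data, t0=0.0, dt=0.02, scale="db", valid=None):
    data = np.asarray(data, float)
    n_f, n_t = data.shape[-2:]
    return TimeFrequencyCube(
        data=data,
        freqs_hz=np.arange(3.0, 3.0 + n_f),
        times_s=t0 + np.arange(n_t) * dt,
        scale=scale,
        valid=valid,
    )


def _full_template(n_ch, n_f, n_t, t0=0.0, dt=0.02):
    return FeatureTemplate(
        segment_name="joint_context",
        mask=np.ones((n_ch, n_f, n_t), bool),
        freqs_hz=np.arange(3.0, 3.0 + n_f),
        times_s=t0 + np.arange(n_t) * dt,
    )


class TestExtractFeatures:
    def test_vector_ordering_channel_major(self):
        """2 channels x 3 frequencies full mask -> length-6 vector ordered
        ch0(f0,f1,f2), ch1(f0,f1,f2)."""
        data = np.zeros((2, 3, 4))
        for c in range(2):
            for f in range(3):
                data[c, f, :] = 10 * c + f
        fv = extract_ab_features(_cube(data), _full_template(2, 3, 4), "AB00")
        np.testing.assert_array_equal(fv.values, [0, 1, 2, 10, 11, 12])
        np.testing.assert_array_equal(fv.cell_channels, [0, 0, 0, 1, 1, 1])

    def test_constant_over_time_returns_constants(self, rng):
        vals = rng.standard_normal((2, 3, 1))
        data = np.repeat(vals, 8, axis=-1)
        fv = extract_ab_features(_cube(data), _full_template(2, 3, 8), "AB00")
        np.testing.assert_allclose(fv.values, vals[:, :, 0].ravel())

    def test_median_over_template_times_only(self):
        data = np.zeros((1, 1, 5))
        data[0, 0] = [0.0, 1.0, 2.0, 50.0, 60.0]
        tmpl = _full_template(1, 1, 5)
        tmpl.mask[0, 0] = [True, True, True, False, False]
        fv = extract_ab_features(_cube(data), tmpl, "AB00")
        assert fv.values[0] == 1.0  # median of the masked times

    def test_empty_template_refused(self):
        tmpl = _full_template(1, 2, 3)
        tmpl.mask[:] = False
        with pytest.raises(ValueError, match="empty template"):
            extract_ab_features(_cube(np.zeros((1, 2, 3))), tmpl, "AB00")

    def test_96_vectors_for_24_movies_4_segments(self):
        """The acquisition design yields 24 x 4 = 96 anchor vectors per
        participant."""
        n_movies, n_segments = 24, 4
        vectors = [
            extract_ab_features(
                _cube(np.random.default_rng(m * 7 + s).standard_normal((2, 3, 4))),
                _full_template(2, 3, 4),
                f"AB{m:02d}",
            )
            for m in range(n_movies)
            for s in range(n_segments)
        ]
        assert len(vectors) == 96


class TestSimilarityTimecourse:
    def test_identical_slice_hits_clip_ceiling(self, rng):
        anchor_map = rng.standard_normal((2, 3))
        data = np.repeat(anchor_map[:, :, None], 6, axis=-1)
        tmpl = _full_template(2, 3, 6)
        fv = extract_ab_features(_cube(data), tmpl, "AB00")
        series = similarity_timecourse(fv, _cube(data), tmpl)
        np.testing.assert_allclose(series.z, np.arctanh(Z_CLIP))

    def test_null_similarity_near_zero(self):
        """Independent anchor and target: mean z within +-3 SEM of 0 over
        20 seeded draws."""
        means = []
        tmpl = _full_template(4, 10, 5)
        for seed in range(20):
            r = np.random.default_rng(seed)
            fv = extract_ab_features(_cube(r.standard_normal((4, 10, 5))), tmpl, "AB00")
            target = _cube(r.standard_normal((4, 10, 200)))
            series = similarity_timecourse(fv, target, tmpl)
            means.append(np.nanmean(series.z))
        means = np.asarray(means)
        sem = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * sem + 1e-12

    def test_one_z_per_timepoint_at_20ms(self, rng):
        n_t = 700  # 14 s at 0.02 s
        tmpl = _full_template(2, 4, 10)
        fv = extract_ab_features(_cube(rng.standard_normal((2, 4, 10))), tmpl, "AB00")
        series = similarity_timecourse(fv, _cube(rng.standard_normal((2, 4, n_t))), tmpl)
        assert len(series.z) == n_t

    def test_zero_variance_timepoint_invalid(self, rng):
        tmpl = _full_template(2, 3, 4)
        fv = extract_ab_features(_cube(rng.standard_normal((2, 3, 4))), tmpl, "AB00")
        data = rng.standard_normal((2, 3, 5))
        data[:, :, 2] = 1.0  # flat pattern at t=2
        series = similarity_timecourse(fv, _cube(data), tmpl)
        assert np.isnan(series.z[2])
        assert np.isfinite(np.delete(series.z, 2)).all()

    def test_affine_rescaling_invariance(self, rng):
        """Pearson r is invariant to per-vector affine rescaling."""
        tmpl = _full_template(3, 4, 6)
        base = rng.standard_normal((3, 4, 6))
        fv = extract_ab_features(_cube(base), tmpl, "AB00")
        target = rng.standard_normal((3, 4, 50))
        z1 = similarity_timecourse(fv, _cube(target), tmpl).z
        fv2 = extract_ab_features(_cube(2.5 * base - 1.0), tmpl, "AB00")
        z2 = similarity_timecourse(fv2, _cube(3.0 * target + 7.0), tmpl).z
        np.testing.assert_allclose(z1, z2, atol=1e-9)


class TestBaselineContrast:
    def _series(self, rng, n_t=50):
        tmpl = _full_template(2, 3, 4)
        fv = extract_ab_features(_cube(rng.standard_normal((2, 3, 4))), tmpl, "AB00")
        return similarity_timecourse(fv, _cube(rng.standard_normal((2, 3, n_t))), tmpl)

    def test_self_baseline_gives_zero(self, rng):
        s = self._series(rng)
        c = baseline_contrast(s, [s, s], "vs_xy")
        np.testing.assert_allclose(c.z, 0.0, atol=1e-12)

    def test_shift_invariance(self, rng):
        from dataclasses import replace

        s = self._series(rng)
        b1, b2 = self._series(rng), self._series(rng)
        c1 = baseline_contrast(s, [b1, b2], "vs_xy")
        shift = 0.37
        c2 = baseline_contrast(
            replace(s, z=s.z + shift),
            [replace(b1, z=b1.z + shift), replace(b2, z=b2.z + shift)],
            "vs_xy",
        )
        np.testing.assert_allclose(c1.z, c2.z, atol=1e-12)

    def test_empty_baselines_rejected(self, rng):
        with pytest.raises(ValueError, match="empty baseline"):
            baseline_contrast(self._series(rng), [], "vs_xy")


class TestWindowAverage:
    def test_constant_series(self, rng):
        from dataclasses import replace

        s = self._make(rng)
        s = replace(s, z=np.full_like(s.z, 0.01))
        assert window_average(s, (0.1, 0.5)) == pytest.approx(0.01)

    def test_single_timepoint_window(self, rng):
        s = self._make(rng)
        assert window_average(s, (0.10, 0.12)) == pytest.approx(s.z[5])

    def test_matches_enumeration_oracle(self, rng):
        s = self._make(rng)
        lo, hi = 0.2, 0.66
        manual = np.mean([z for t, z in zip(s.times_s, s.z) if lo <= t < hi])
        assert window_average(s, (lo, hi)) == pytest.approx(manual)

    def test_all_invalid_window_raises(self, rng):
        s = self._make(rng)
        s.z[:] = np.nan
        with pytest.raises(ValueError, match="no valid timepoint"):
            window_average(s, (0.1, 0.3))

    def _make(self, rng, n_t=50):
        tmpl = _full_template(2, 3, 4)
        fv = extract_ab_features(_cube(rng.standard_normal((2, 3, 4))), tmpl, "AB00")
        return similarity_timecourse(fv, _cube(rng.standard_normal((2, 3, n_t))), tmpl)


class TestNeighborhoodTopography:
    CHANNELS = ["c0", "c1", "c2", "c3"]
    GRAPH = {"c0": ("c1",), "c1": ("c0", "c2"), "c2": ("c1", "c3"), "c3": ("c2",)}

    def test_identical_maps_hit_ceiling(self, rng):
        tmpl = _full_template(4, 5, 6)
        base = rng.standard_normal((4, 5, 6))
        fv = extract_ab_features(_cube(base), tmpl, "AB00")
        target = np.repeat(np.median(base, axis=-1)[:, :, None], 10, axis=-1)
        topo = neighborhood_topography(fv, _cube(target), tmpl, self.GRAPH, self.CHANNELS)
        np.testing.assert_allclose(topo, np.arctanh(Z_CLIP))

    def test_local_effect_ranks_top_channels(self):
        """Anchor-matching pattern planted in channels 0-1 only: those
        channels' neighborhoods score highest."""
        r = np.random.default_rng(5)
        tmpl = _full_template(4, 8, 6)
        base = r.standard_normal((4, 8, 6))
        fv = extract_ab_features(_cube(base), tmpl, "AB00")
        target = r.standard_normal((4, 8, 40)) * 0.1
        anchor_map = np.median(base, axis=-1)
        target[0] += anchor_map[0][:, None]
        target[1] += anchor_map[1][:, None]
        topo = neighborhood_topography(fv, _cube(target), tmpl, self.GRAPH, self.CHANNELS)
        mean_z = np.nanmean(topo, axis=1)
        assert set(np.argsort(mean_z)[-2:]) == {0, 1}

    def test_edgeless_graph_uses_single_channels(self, rng):
        graph = {c: () for c in self.CHANNELS}
        tmpl = _full_template(4, 5, 6)
        base = rng.standard_normal((4, 5, 6))
        fv = extract_ab_features(_cube(base), tmpl, "AB00")
        target = _cube(rng.standard_normal((4, 5, 20)))
        topo = neighborhood_topography(fv, target, tmpl, graph, self.CHANNELS)
        # each channel used alone: 5 cells per neighborhood, all valid
        assert np.isfinite(topo).all()
        # cross-check channel 2 against a manual single-channel correlation
        a = fv.values[fv.cell_channels == 2]
        X = target.data[2]
        r_manual = np.array(
            [np.corrcoef(a, X[:, t])[0, 1] for t in range(X.shape[-1])]
        )
        np.testing.assert_allclose(topo[2], fisher_z(r_manual), atol=1e-9)

    def test_isolated_channel_with_one_cell_invalid(self, rng):
        tmpl = _full_template(4, 1, 6)  # one frequency -> one cell per channel
        base = rng.standard_normal((4, 1, 6))
        fv = extract_ab_features(_cube(base), tmpl, "AB00")
        graph = {c: () for c in self.CHANNELS}
        topo = neighborhood_topography(
            fv, _cube(rng.standard_normal((4, 1, 10))), tmpl, graph, self.CHANNELS
        )
        assert np.isnan(topo).all()


def test_series_to_tsv_long_format(rng):
    from intersep.rsa import series_to_tsv

    tmpl = _full_template(2, 3, 4)
    fv = extract_ab_features(_cube(rng.standard_normal((2, 3, 4))), tmpl, "AB00")
    s = similarity_timecourse(
        fv, _cube(rng.standard_normal((2, 3, 5))), tmpl,
        target_movie="BC00", target_role="BC", target_repetition=2,
    )
    tsv = series_to_tsv([s], participant=3)
    lines = tsv.strip().split("\n")
    assert lines[0].startswith("participant\tanchor")
    assert len(lines) == 6
    assert lines[1].split("\t")[1] == "AB00"
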