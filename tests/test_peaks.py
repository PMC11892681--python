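import numpy as np
import pandas as pd
import pytest

from msipd.masses import adduct_mz
from msipd.msi_io import MSIDataset, Spectrum, rebin_spectrum, rms_normalise, uniform_axis
from msipd.peaks import (
    AnnotationConfig,
    Peak,
    PeakTable,
    annotate_peaks,
    detect_peaks_gradient,
    integrate_dataset_streaming,
    integrate_peaks,
    match_peaks_across_experiments,
    render_ion_image,
)


def _table(centers, eid="e1", w=0.001, mass_range=(100.0, 1000.0)):
    peaks = [Peak(c, c - 0.01, c + 0.01, 1.0) for c in sorted(centers)]
    return PeakTable(experiment_id=eid, peaks=peaks, bin_width=w, mass_range=mass_range)


class TestDetect:
    def test_single_maximum_with_bounds_at_edges(self):
        s = Spectrum(100.0 + np.arange(5) * 0.001, [0.0, 1.0, 3.0, 1.0, 0.0])
        t = detect_peaks_gradient(s, min_apex=0.0)
        assert len(t) == 1
        p = t.peaks[0]
        assert (p.left_idx, p.apex_idx, p.right_idx) == (0, 2, 4)

    def test_monotone_ramp_has_no_peaks(self):
        s = Spectrum(100.0 + np.arange(6) * 0.001, np.arange(6.0))
        assert len(detect_peaks_gradient(s, min_apex=0.0)) == 0

    def test_two_gaussians_centres_within_one_bin(self):
        axis = uniform_axis((199.0, 301.0), 0.001)
        v = 10 * np.exp(-((axis - 200.0) ** 2) / (2 * 0.01**2)) + 5 * np.exp(
            -((axis - 300.0) ** 2) / (2 * 0.01**2)
        )
        t = detect_peaks_gradient(Spectrum(axis, v), min_apex=1.0)
        # oracle: brute-force strict local maxima above the floor
        brute = [
            i
            for i in range(1, len(v) - 1)
            if v[i] > v[i - 1] and v[i] > v[i + 1] and v[i] >= 1.0
        ]
        assert [p.apex_idx for p in t.peaks] == brute
        assert len(t) == 2
        assert abs(t.peaks[0].center_mz - 200.0) <= 0.001
        assert abs(t.peaks[1].center_mz - 300.0) <= 0.001

    def test_min_apex_discards_small_peaks(self):
        s = Spectrum(100.0 + np.arange(7) * 0.001, [0, 5, 0, 0, 1, 0, 0.0])
        assert len(detect_peaks_gradient(s, min_apex=2.0)) == 1

    def test_non_uniform_axis_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks_gradient(Spectrum([1.0, 2.0, 4.0], [0.0, 1.0, 0.0]))

    def test_windows_are_disjoint_and_apexes_strict_maxima(self, rng):
        axis = uniform_axis((100.0, 110.0), 0.01)
        v = np.zeros_like(axis)
        for c in rng.uniform(101, 109, 12):
            v += rng.uniform(1, 5) * np.exp(-((axis - c) ** 2) / (2 * 0.05**2))
        t = detect_peaks_gradient(Spectrum(axis, v), min_apex=0.5)
        spans = [(p.left_idx, p.right_idx) for p in t.peaks]
        for (l1, r1), (l2, r2) in zip(spans, spans[1:]):
            assert r1 < l2  # non-overlapping index ranges
        for p in t.peaks:
            assert v[p.apex_idx] > v[p.apex_idx - 1] and v[p.apex_idx] > v[p.apex_idx + 1]


class TestIntegrate:
    def _dataset(self, intensities, axis):
        return MSIDataset(
            pixels=[(0, 0)],
            spectra=[Spectrum(axis, intensities)],
            tissue_id="t",
            experiment_id="e1",
            arm="vehicle",
            mass_range=(float(axis[0]), float(axis[-1])),
        )

    def test_sum_under_bounds(self):
        axis = 100.0 + np.arange(5) * 0.001
        ds = self._dataset([0.0, 1.0, 3.0, 1.0, 0.0], axis)
        table = PeakTable(
            "e1",
            [Peak(axis[2], axis[1], axis[3], 3.0, left_idx=1, apex_idx=2, right_idx=3)],
            0.001,
            (axis[0], axis[-1]),
        )
        pm = integrate_peaks(ds, table)
        assert pm.values[0, 0] == 5.0

    def test_zero_signal_window_and_zero_padding_invariance(self):
        axis = 100.0 + np.arange(7) * 0.001
        ds = self._dataset([0.0, 0.0, 1.0, 3.0, 1.0, 0.0, 0.0], axis)
        narrow = PeakTable(
            "e1", [Peak(axis[3], axis[2], axis[4], 3.0, 2, 3, 4)], 0.001, (axis[0], axis[-1])
        )
        wide = PeakTable(
            "e1", [Peak(axis[3], axis[0], axis[6], 3.0, 0, 3, 6)], 0.001, (axis[0], axis[-1])
        )
        assert integrate_peaks(ds, narrow).values[0, 0] == integrate_peaks(ds, wide).values[0, 0]
        empty = PeakTable(
            "e1", [Peak(axis[1], axis[0], axis[2], 0.0, 0, 1, 1)], 0.001, (axis[0], axis[-1])
        )
        assert integrate_peaks(ds, empty).values[0, 0] == 0.0

    def test_axis_mismatch_rejected(self):
        axis = 100.0 + np.arange(5) * 0.001
        ds = self._dataset([0.0, 1.0, 3.0, 1.0, 0.0], axis)
        table = PeakTable("e1", [Peak(200.0, 199.9, 200.1, 1.0, 0, 1, 2)], 0.005, (100.0, 101.0))
        with pytest.raises(ValueError):
            integrate_peaks(ds, table)

    def test_streaming_equals_dense_rebin_normalise_integrate(self, rng):
        """The streamed integrator must agree with the explicit chain."""
        mass_range = (100.0, 120.0)
        w = 0.01
        pixels, spectra = [], []
        for i in range(4):
            mz = np.sort(rng.uniform(101, 119, 30))
            spectra.append(Spectrum(mz, rng.uniform(0.1, 5, 30)))
            pixels.append((i, 0))
        ds = MSIDataset(pixels=pixels, spectra=spectra, tissue_id="t",
                        experiment_id="e1", arm="vehicle", mass_range=mass_range)
        axis = uniform_axis(mass_range, w)
        dense = [rms_normalise(rebin_spectrum(s, w, mass_range)) for s in spectra]
        ds_dense = MSIDataset(pixels=pixels, spectra=dense, tissue_id="t",
                              experiment_id="e1", arm="vehicle", mass_range=mass_range)
        table = PeakTable(
            "e1",
            [
                Peak(axis[500], axis[300], axis[700], 1.0, 300, 500, 700),
                Peak(axis[1200], axis[900], axis[1500], 1.0, 900, 1200, 1500),
            ],
            w,
            mass_range,
        )
        a = integrate_dataset_streaming(ds, table, normalise=True).values
        b = integrate_peaks(ds_dense, table).values
        np.testing.assert_allclose(a, b, rtol=1e-5)


class TestIonImage:
    def _matrix(self, values):
        frame = pd.DataFrame(
            dict(
                tissue_id="t1",
                experiment="e1",
                arm="vehicle",
                x=np.arange(len(values)) % 10,
                y=np.arange(len(values)) // 10,
            )
        )
        frame["mz_100.0000"] = values
        from msipd.peaks import PeakMatrix

        return PeakMatrix(frame)

    def test_values_clipped_at_pooled_95th_percentile(self):
        values = np.arange(1.0, 101.0)
        img = render_ion_image([self._matrix(values)], "mz_100.0000")["t1"]
        cap = np.percentile(values, 95)  # brute-force oracle on the sorted vector
        assert np.nanmax(img) == pytest.approx(cap)
        assert np.nansum(img == cap) == np.sum(values >= cap)

    def test_uniform_image_unchanged_and_clipping_idempotent(self):
        values = np.full(20, 7.0)
        img = render_ion_image([self._matrix(values)], "mz_100.0000")["t1"]
        assert np.nanmax(img) == 7.0 and np.nanmin(img) == 7.0


class TestAnnotate:
    def _config(self, inclusion=300.0, accuracy=70.0):
        db = pd.DataFrame(
            dict(name=["AZD2014", "ATP"], neutral_mass=[462.2379, 506.9957])
        )
        return AnnotationConfig(database=db, inclusion_ppm=inclusion, accuracy_ppm=accuracy)

    def test_drug_ion_theoretical_mass_and_zero_ppm_match(self):
        cfg = self._config()
        out = annotate_peaks(np.array([463.2452]), cfg, "positive")
        best = out[out.retained].iloc[0]
        assert best["name"] == "AZD2014"
        assert best["adduct"] == "[M+H]+"
        assert best["theoretical_mz"] == pytest.approx(463.2452, abs=5e-5)
        assert abs(best["ppm"]) < 0.1

    def test_large_ppm_error_rejected_under_tight_window(self):
        cfg = self._config(inclusion=10.0, accuracy=10.0)  # DESI positive windows
        out = annotate_peaks(np.array([463.3000]), cfg, "positive")
        assert len(out) == 0  # ~118 ppm is outside even the inclusion window

    def test_inclusion_vs_accuracy_nesting(self):
        cfg = self._config(inclusion=300.0, accuracy=70.0)
        observed = 463.2452 * (1 + 100e-6)  # 100 ppm high: candidate, not retained
        out = annotate_peaks(np.array([observed]), cfg, "positive")
        assert len(out) >= 1 and not out["retained"].any()

    def test_shrinking_accuracy_never_adds_assignments(self):
        cfg_wide = self._config(accuracy=70.0)
        cfg_tight = self._config(accuracy=5.0)
        obs = np.array([463.2452 * (1 + 30e-6), 505.99])
        wide = annotate_peaks(obs, cfg_wide, "positive")
        tight = annotate_peaks(obs, cfg_tight, "positive")
        kept_wide = set(map(tuple, wide[wide.retained][["peak_mz", "name", "adduct"]].to_numpy()))
        kept_tight = set(map(tuple, tight[tight.retained][["peak_mz", "name", "adduct"]].to_numpy()))
        assert kept_tight <= kept_wide

    def test_unconfigured_polarity_rejected(self):
        cfg = self._config()
        with pytest.raises(ValueError):
            annotate_peaks(np.array([100.0]), cfg, "tripolar")

    def test_accuracy_above_inclusion_rejected(self):
        with pytest.raises(ValueError):
            self._config(inclusion=10.0, accuracy=70.0)


class TestMatch:
    def test_common_peak_found_across_three_experiments(self):
        mz = adduct_mz(462.2379, "[M+H]+")
        tables = [
            _table([mz * (1 + off * 1e-6)], eid=f"e{i}")
            for i, off in enumerate((-2.0, 0.0, 2.0))
        ]
        out = match_peaks_across_experiments(tables, match_ppm=10.0)
        assert len(out) == 1
        assert out.peaks[0].consensus_mz == pytest.approx(mz, rel=1e-6)

    def test_peak_missing_from_one_experiment_excluded(self):
        tables = [_table([200.0, 300.0]), _table([200.0, 300.0], "e2"), _table([300.0], "e3")]
        out = match_peaks_across_experiments(tables, match_ppm=10.0)
        assert [p.consensus_mz for p in out.peaks] == [300.0]

    def test_empty_intersection(self):
        out = match_peaks_across_experiments([_table([200.0]), _table([300.0], "e2")], 10.0)
        assert len(out) == 0

    def test_invariant_under_table_order(self):
        tables = [_table([200.0, 300.0, 400.0], f"e{i}") for i in range(3)]
        fwd = match_peaks_across_experiments(tables, 10.0)
        rev = match_peaks_across_experiments(tables[::-1], 10.0)
        assert sorted(p.consensus_mz for p in fwd.peaks) == sorted(
            p.consensus_mz for p in rev.peaks
        )

    def test_ambiguous_table_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            match_peaks_across_experiments(
                [_table([200.0, 200.0005]), _table([200.0], "e2")], match_ppm=10.0
            )

    def test_needs_two_tables(self):
        with pytest.raises(ValueError):
            match_peaks_across_experiments([_table([200.0])], 10.0)
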