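"""TCSPC decay fitting, averaged lifetimes and anisotropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import guvflim as gf
from guvflim import decay as dc


def make_fit(taus, amps):
    return dc.LifetimeFit.from_amplitudes(
        np.asarray(taus, float), np.asarray(amps, float), background=0.0, chi2_reduced=1.0
    )


class TestAveragedLifetimes:
    @pytest.mark.parametrize(
        "taus, amps, expected",
        [
            ([3.0], [1.0], 3.0),
            ([1.0, 3.0], [0.5, 0.5], 2.0),
            # ergosterol-membrane organization fractions over the library lifetimes
            ([0.35, 1.8, 6.8], [39.6, 27.3, 33.1], 2.881),
        ],
    )
    def test_amplitude_averaged(self, taus, amps, expected):
        assert dc.amplitude_averaged_lifetime(make_fit(taus, amps)) == pytest.approx(
            expected, abs=2e-3
        )

    def test_all_zero_amplitudes_rejected(self):
        with pytest.raises(dc.FitError):
            make_fit([1.0, 3.0], [0.0, 0.0])

    def test_fractions_sum_to_100(self):
        fit = make_fit([0.35, 1.8, 6.8], [0.123, 7.7, 0.01])
        assert fit.fractions_pct.sum() == pytest.approx(100.0, abs=1e-6)


class TestAnisotropyAlgebra:
    @pytest.mark.parametrize(
        "fp, fs, G, expected",
        [
            (1.0, 1.0, 1.0, 0.0),
            (3.0, 1.0, 1.0, 0.4),
            (3.0, 1.0, 1.044, (3 - 1.044) / (3 + 2 * 1.044)),
        ],
    )
    def test_anisotropy_values(self, fp, fs, G, expected):
        assert dc.anisotropy(fp, fs, G) == pytest.approx(expected, abs=1e-9)

    def test_anisotropy_peak_condition(self):
        # r = 0.4 exactly when F_par = 3 G F_perp
        for G in (0.9, 1.0, 1.044):
            assert dc.anisotropy(3 * G * 7.0, 7.0, G) == pytest.approx(0.4, abs=1e-12)

    def test_zero_intensity_is_missing(self):
        assert np.isnan(dc.anisotropy(0.0, 0.0, 1.0))

    @pytest.mark.parametrize(
        "fp, fs, G, expected",
        [(1.0, 1.0, 1.0, 3.0), (3.0, 1.0, 1.044, 5.088), (0.0, 0.0, 2.0, 0.0)],
    )
    def test_total_fluorescence(self, fp, fs, G, expected):
        assert dc.total_fluorescence(fp, fs, G) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=300)
    @given(
        fp=st.floats(0.0, 1e9),
        fs=st.floats(0.0, 1e9),
        G=st.floats(0.5, 2.0),
    )
    def test_anisotropy_bounded(self, fp, fs, G):
        r = dc.anisotropy(fp, fs, G)
        if not np.isnan(r):
            assert -0.5 - 1e-12 <= r <= 1.0 + 1e-12


class TestFreeFits:
    def test_single_exponential_recovery(self):
        hist = gf.simulate_decay_histogram(((1.8, 1.0),), 1_000_000, seed=3)
        fit = dc.fit_decay_free(hist, 1)
        (tau, _), = fit.components
        assert tau == pytest.approx(1.8, abs=0.02)
        assert 0.8 <= fit.chi2_reduced <= 1.2

    def test_two_exponential_recovery(self):
        hist = gf.simulate_decay_histogram(((1.8, 0.5), (6.8, 0.5)), 1_000_000, seed=4)
        fit = dc.fit_decay_free(hist, 2, library=dc.AMB_LIBRARY)
        taus = [t for t, _ in fit.components]
        assert taus[0] == pytest.approx(1.8, rel=0.05)
        assert taus[1] == pytest.approx(6.8, rel=0.05)
        assert fit.fractions_pct == pytest.approx([50.0, 50.0], abs=2.0)
        assert fit.names[0] == "parallel_dimer"  # within the 0.1 ns match tolerance

    def test_empty_histogram_rejected(self):
        edges = np.linspace(0.0, 25.0, 4097)
        hist = dc.DecayHistogram(edges, np.zeros(4096, dtype=int))
        with pytest.raises(dc.FitError):
            dc.fit_decay_free(hist, 1)

    def test_consistency_bias_shrinks_with_photons(self):
        """The MLE is consistent: absolute lifetime error falls with budget."""
        def err(n, seeds):
            es = []
            for s in seeds:
                h = gf.simulate_decay_histogram(((1.8, 1.0),), n, seed=s)
                es.append(abs(dc.fit_decay_free(h, 1).components[0][0] - 1.8))
            return np.mean(es)

        assert err(10_000_000, (1, 2, 3)) < err(100_000, (1, 2, 3))


class TestLibraryFits:
    def test_pure_antiparallel_dimer_full_library(self):
        hist = gf.simulate_decay_histogram(((6.8, 1.0),), 1_000_000, seed=5)
        fit = dc.fit_decay_fixed(
            hist, subset=("tetramer", "parallel_dimer", "monomer", "antiparallel_dimer")
        )
        assert fit.fraction("antiparallel_dimer") == pytest.approx(100.0, abs=1.0)
        for other in ("tetramer", "parallel_dimer", "monomer"):
            assert fit.fraction(other) <= 1.0

    def test_pure_lipid_column(self):
        """Sterol-free membrane: the parallel dimer carries ~99% of the amplitude."""
        comps = ((0.35, 0.2), (1.8, 99.0), (6.8, 0.8))
        hist = gf.simulate_decay_histogram(comps, 1_000_000, seed=6)
        fit = dc.fit_decay_fixed(hist)
        assert fit.fraction("parallel_dimer") == pytest.approx(99.0, abs=1.0)

    def test_ergosterol_column_tetramer(self):
        comps = ((0.35, 39.6), (1.8, 27.3), (6.8, 33.1))
        hist = gf.simulate_decay_histogram(comps, 1_000_000, seed=7)
        fit = dc.fit_decay_fixed(hist)
        assert fit.fraction("tetramer") == pytest.approx(39.6, abs=3.0)

    def test_fractions_sum_and_sigmas(self):
        comps = ((0.35, 17.6), (1.8, 29.0), (6.8, 53.4))
        hist = gf.simulate_decay_histogram(comps, 500_000, seed=8)
        fit = dc.fit_decay_fixed(hist)
        assert fit.fractions_pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert fit.fraction_sigmas_pct is not None
        assert np.all(fit.fraction_sigmas_pct >= 0)

    def test_empty_subset_rejected(self):
        hist = gf.simulate_decay_histogram(((1.8, 1.0),), 10_000, seed=9)
        with pytest.raises(ValueError):
            dc.fit_decay_fixed(hist, subset=())

    def test_monomer_selectable(self):
        hist = gf.simulate_decay_histogram(((3.0, 1.0),), 300_000, seed=10)
        fit = dc.fit_decay_fixed(hist, subset=("tetramer", "monomer", "antiparallel_dimer"))
        assert fit.fraction("monomer") == pytest.approx(100.0, abs=2.0)


class TestComponentLibrary:
    def test_default_forms(self):
        assert dc.AMB_LIBRARY.tau("tetramer") == 0.35
        assert dc.AMB_LIBRARY.tau("parallel_dimer") == 1.8
        assert dc.AMB_LIBRARY.tau("monomer") == 3.0
        assert dc.AMB_LIBRARY.tau("antiparallel_dimer") == 6.8

    def test_matching_tolerance(self):
        assert dc.AMB_LIBRARY.match(1.85) == "parallel_dimer"
        assert dc.AMB_LIBRARY.match(2.4) is None

    def test_subset_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            dc.AMB_LIBRARY.subset(("pentamer",))


class TestAnisotropyDecayFit:
    def test_recovers_r0(self):
        par, perp = gf.simulate_anisotropy_traces(0.397, 0.5, 3.0, 10_000_000, G=1.044, seed=1)
        fit = dc.fit_anisotropy_decay(par, perp, G=1.044)
        assert fit.r0 == pytest.approx(0.397, abs=0.01)
        assert fit.theta_rot_ns == pytest.approx(0.5, rel=0.1)

    def test_zero_anisotropy(self):
        par, perp = gf.simulate_anisotropy_traces(0.0, 0.5, 3.0, 10_000_000, seed=2)
        fit = dc.fit_anisotropy_decay(par, perp, G=1.044)
        assert fit.r0 == pytest.approx(0.0, abs=0.01)

    def test_immobilized_fluorophore_is_flat(self):
        par, perp = gf.simulate_anisotropy_traces(0.4, np.inf, 3.0, 10_000_000, seed=3, G=1.0)
        with pytest.warns(UserWarning):
            fit = dc.fit_anisotropy_decay(par, perp, G=1.0)
        assert fit.r0 == pytest.approx(0.4, abs=0.01)
        assert not fit.rotation_resolved

    def test_g_correction_is_undone(self):
        r0s = []
        for G in (1.0, 2.0):
            par, perp = gf.simulate_anisotropy_traces(0.3, 0.5, 3.0, 10_000_000, G=G, seed=5)
            r0s.append(dc.fit_anisotropy_decay(par, perp, G=G).r0)
        assert r0s[0] == pytest.approx(r0s[1], abs=0.01)

    def test_mismatched_binning_rejected(self):
        par, _ = gf.simulate_anisotropy_traces(0.3, 0.5, 3.0, 100_000, seed=6)
        _, perp = gf.simulate_anisotropy_traces(0.3, 0.5, 3.0, 100_000, seed=6, n_bins=2048)
        with pytest.raises(ValueError, match="binning"):
            dc.fit_anisotropy_decay(par, perp)


class TestHistogramIO:
    def test_csv_round_trip(self, tmp_path):
        hist = gf.simulate_decay_histogram(((1.8, 1.0),), 50_000, seed=11)
        path = tmp_path / "decay.csv"
        dc.write_decay_csv(hist, path)
        back = dc.read_decay_csv(path)
        np.testing.assert_array_equal(back.counts, hist.counts)
        np.testing.assert_allclose(back.bin_edges_ns, hist.bin_edges_ns, atol=1e-9)

    def test_invalid_histograms_rejected(self):
        with pytest.raises(ValueError):
            dc.DecayHistogram(np.array([0.0, 1.0, 3.0]), np.array([1, 2]))  # uneven bins
        with pytest.raises(ValueError):
            dc.DecayHistogram(np.array([0.0, 1.0, 2.0]), np.array([1, -2]))
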