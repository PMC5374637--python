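import numpy as np
import pytest

from seqtf import synth_periodic, synth_random
from seqtf.core import (
    TFKernel,
    ambiguity,
    cohen_distribution,
    correlation_function,
    instantaneous_correlation,
    series_spectrum,
    spectrum,
    symmetry_function,
    tf_marginal_spectrum,
    wigner_ville,
)

from _brute import (
    brute_ambiguity,
    brute_circular_correlation,
    brute_correlation,
    brute_dft_lags,
    brute_instantaneous,
    brute_symmetry,
    brute_wigner_ville,
)


class TestInstantaneousCorrelation:
    def test_boundary_rule(self, dna_identity):
        rc = instantaneous_correlation("AA", sim=dna_identity, max_lag=1)
        at = dict(zip(rc.lags.tolist(), range(3)))
        assert rc.values[0, at[0]] == 1.0
        assert rc.values[0, at[1]] == 1.0
        assert rc.values[1, at[1]] == 0.0          # y[2] out of range
        assert rc.values[0, at[-1]] == 0.0         # y[-1] out of range

    def test_period_four_repeat_lag_structure(self, dna_identity):
        x = "ACGTACGT"
        rc = instantaneous_correlation(x, sim=dna_identity, max_lag=7)
        brute = brute_instantaneous(x, x, dna_identity.lookup, 7)
        assert np.array_equal(rc.values, brute)
        j4 = list(rc.lags).index(4)
        j1 = list(rc.lags).index(1)
        assert all(rc.values[n, j4] == 1.0 for n in range(4))
        assert all(rc.values[n, j1] == 0.0 for n in range(8))

    def test_numeric_constant_ones(self):
        x = np.ones(5)
        rc = instantaneous_correlation(x, sim="product", max_lag=2)
        brute = brute_instantaneous(
            [1.0] * 5, [1.0] * 5, lambda a, b: a * b, 2)
        assert np.array_equal(rc.values, brute)
        assert rc.values[2, :].tolist() == [1.0] * 5

    def test_symmetric_convention_even_in_halflag(self, random_similarity, random_dna):
        S = random_similarity(0, symmetric=True)
        rc = instantaneous_correlation(random_dna(20, 1), sim=S,
                                       max_lag=10, convention="symmetric")
        assert np.allclose(rc.values, rc.values[:, ::-1])

    def test_invalid_max_lag_rejected(self, dna_identity):
        with pytest.raises(ValueError):
            instantaneous_correlation("ACGT", sim=dna_identity, max_lag=4)

    def test_mismatched_alphabets_rejected(self, dna_identity):
        from seqtf.sequence_io import GenomicSequence
        from seqtf.similarity import Alphabet
        seq = GenomicSequence("s", "AB", Alphabet(("A", "B")))
        with pytest.raises(ValueError, match="alphabet"):
            instantaneous_correlation(seq, sim=dna_identity, max_lag=1)


class TestCorrelationFunction:
    def test_linear_sums(self, dna_identity):
        rc = instantaneous_correlation("ACGTACGT", sim=dna_identity, max_lag=7)
        R = correlation_function(rc)
        at = dict(zip(R.lags.tolist(), R.values.tolist()))
        assert at[0] == 8.0
        assert at[1] == 0.0
        assert at[4] == 4.0

    def test_circular_wraps(self, dna_identity):
        rc = instantaneous_correlation("ACGTACGT", sim=dna_identity, max_lag=7)
        R = correlation_function(rc, mode="circular")
        assert R.values[4] == 8.0
        assert np.array_equal(
            R.values, brute_circular_correlation("ACGTACGT", "ACGTACGT",
                                                 dna_identity.lookup))

    def test_circular_fft_route_matches_direct(self, dna_identity, random_dna):
        """The one-hot FFT path used for long sequences equals the direct
        rolled sum used below the size cutoff."""
        x = random_dna(5000, 3)                      # > 4096: FFT route
        rc = instantaneous_correlation(x, sim=dna_identity, max_lag=1)
        R = correlation_function(rc, mode="circular")
        codes = rc._x_codes
        for t in [0, 1, 13, 999, 2500, 4999]:
            assert abs(R.values[t] - (codes == np.roll(codes, -t)).sum()) < 1e-6

    def test_auto_argmax_at_zero_lag(self, dna_identity):
        for seed in range(5):
            s = synth_periodic("ACGT", 300, 0.2, seed=seed)
            R = correlation_function(
                instantaneous_correlation(s, sim=dna_identity, max_lag=100))
            assert R.lags[np.argmax(R.values)] == 0

    def test_per_overlap_mean(self, dna_identity):
        rc = instantaneous_correlation("AAAA", sim=dna_identity, max_lag=3)
        R = correlation_function(rc, normalization="per-overlap-mean")
        assert np.allclose(R.values, 1.0)            # every overlap matches

    def test_even_in_lag_for_symmetric_similarity(self, random_similarity, random_dna):
        S = random_similarity(5, symmetric=True)
        R = correlation_function(
            instantaneous_correlation(random_dna(30, 2), sim=S, max_lag=20))
        assert np.allclose(R.values, R.values[::-1], atol=1e-12)

    def test_symmetric_convention_rejected(self, dna_identity):
        rc = instantaneous_correlation("ACGT", sim=dna_identity, max_lag=2,
                                       convention="symmetric")
        with pytest.raises(ValueError):
            correlation_function(rc)


class TestSymmetryFunction:
    def test_palindrome_counts_signed_lags(self, dna_identity):
        s = symmetry_function("ACA", sim=dna_identity, max_half_lag=1)
        assert s.values[1] == 3.0    # m = -1, 0, +1 all score 1
        assert s.values[0] == 1.0    # only m = 0 in range

    def test_homopolymer_counts_in_range_pairs(self, dna_identity):
        s = symmetry_function("AAAA", sim=dna_identity, max_half_lag=3)
        expected = brute_symmetry("AAAA", dna_identity.lookup, 3)
        assert np.array_equal(s.values, expected)
        for n in range(4):
            count = sum(1 for m in range(-3, 4) if 0 <= n - m < 4 and 0 <= n + m < 4)
            assert s.values[n] == count

    def test_nonnegative_for_nonnegative_similarity(self, dna_identity, random_dna):
        s = symmetry_function(random_dna(50, 7), sim=dna_identity, max_half_lag=20)
        assert np.all(s.values >= 0)


class TestSpectrum:
    def test_period_four_circular_peak_at_quarter(self, dna_identity):
        rc = instantaneous_correlation("ACGT" * 16, sim=dna_identity, max_lag=63)
        sp = spectrum(correlation_function(rc, mode="circular"))
        k = np.argmax(sp.values[1:]) + 1             # ties -> lowest frequency
        assert sp.freqs[k] == 0.25

    def test_constant_sequence_is_all_dc(self, dna_identity):
        rc = instantaneous_correlation("A" * 32, sim=dna_identity, max_lag=31)
        sp = spectrum(correlation_function(rc, mode="circular"))
        assert np.all(sp.values[1:] < 1e-9 * sp.values[0])

    def test_long_random_spectrum_is_flat(self, dna_identity):
        """White-noise check: non-DC magnitudes of a uniform random
        sequence stay within a decade of their median."""
        for seed in range(10):
            x = synth_random(100_000, seed=seed)
            rc = instantaneous_correlation(x, sim=dna_identity, max_lag=1)
            R = correlation_function(rc, mode="circular",
                                     normalization="per-overlap-mean")
            sp = spectrum(R)
            nd = sp.values[2:]
            assert nd.max() < 10 * np.median(nd)

    def test_real_for_even_series(self, random_similarity, random_dna):
        S = random_similarity(11, symmetric=True)
        R = correlation_function(
            instantaneous_correlation(random_dna(24, 3), sim=S, max_lag=16))
        sp = spectrum(R)
        assert np.max(np.abs(sp.complex_values.imag)) < 1e-9 * max(
            1.0, np.max(np.abs(sp.complex_values)))


class TestWignerVille:
    def test_two_block_rows_peak_at_their_period(self, dna_identity):
        x = "AC" * 50 + "ACGT" * 25
        wv = wigner_ville(instantaneous_correlation(x, sim=dna_identity, max_lag=16))
        guard = 2
        argmax = wv.freqs[guard + np.argmax(wv.values[:, guard:], axis=1)]
        assert np.all(argmax[20:80] == 0.5)
        assert np.all(argmax[120:190] == 0.25)

    def test_marginals(self, dna_identity, random_dna):
        x = random_dna(20, 4)
        rc = instantaneous_correlation(x, sim=dna_identity, max_lag=10)
        wv = wigner_ville(rc)
        # DC bin = lag sum; mean over frequency = zero-lag value
        np.testing.assert_allclose(wv.complex_values[:, 0].real,
                                   rc.values.sum(axis=1), atol=1e-9)
        j0 = list(rc.lags).index(0)
        np.testing.assert_allclose(wv.complex_values.mean(axis=1).real,
                                   rc.values[:, j0], atol=1e-9)

    def test_symmetric_convention_halves_frequency_axis(self, dna_identity):
        s = synth_periodic("ACGT", 256, 0.0, seed=0)
        rc = instantaneous_correlation(s, sim=dna_identity, convention="symmetric")
        wv = wigner_ville(rc)
        assert wv.freqs[-1] == 0.25
        sp = tf_marginal_spectrum(wv)
        k = np.argmax(sp.values[2:]) + 2
        assert sp.freqs[k] == 0.25

    def test_numeric_exponential_peaks_at_its_frequency(self):
        n = np.arange(128)
        for f0 in (0.11, 0.23, 0.37):
            x = np.exp(2j * np.pi * f0 * n)
            wv = wigner_ville(instantaneous_correlation(x, sim="product", max_lag=64))
            rows = wv.values[32:96]
            peak = np.median(wv.freqs[np.argmax(rows, axis=1)])
            assert abs(peak - f0) <= 1.0 / wv.fft_length


class TestAmbiguity:
    def test_origin_value_is_sequence_length(self, dna_identity, random_dna):
        for n in (16, 33):
            af = ambiguity(instantaneous_correlation(
                random_dna(n, 6), sim=dna_identity, max_lag=n - 1))
            assert abs(af.at_origin() - n) < 1e-9

    def test_magnitude_max_at_origin(self, random_similarity, random_dna):
        S = random_similarity(8, symmetric=True, nonneg=True)
        af = ambiguity(instantaneous_correlation(random_dna(40, 9), sim=S, max_lag=39))
        mag = af.magnitude
        i, j = np.unravel_index(np.argmax(mag), mag.shape)
        assert af.etas[i] == 0.0
        assert af.lags[j] == 0

    def test_periodic_energy_concentrates_at_zero_doppler(self, dna_identity):
        """Stationary (periodic) sequences concentrate ambiguity energy in
        the tau direction around eta = 0, unlike random ones."""
        def band_fraction(seq):
            af = ambiguity(instantaneous_correlation(seq, sim=dna_identity))
            m = af.magnitude
            band = np.abs(af.etas) <= 1.0 / len(seq.symbols)
            return m[band].sum() / m.sum()

        for seed in range(10):
            per = band_fraction(synth_periodic("ACGT", 200, 0.0, seed=seed))
            ran = band_fraction(synth_random(200, seed=seed))
            assert per > ran


class TestCohen:
    @pytest.fixture
    def small_rc(self, dna_identity):
        s = synth_periodic("ACGT", 32, 0.1, seed=3)
        return instantaneous_correlation(s, sim=dna_identity, max_lag=15)

    def test_identity_kernel_reproduces_wigner_ville(self, small_rc):
        wv = wigner_ville(small_rc)
        coh = cohen_distribution(small_rc, TFKernel(kind="none"))
        np.testing.assert_allclose(coh.values, wv.values, atol=1e-9)

    @pytest.mark.parametrize("kind", ["gaussian", "choi-williams"])
    def test_total_mass_preserved(self, small_rc, kind):
        wv = wigner_ville(small_rc)
        coh = cohen_distribution(small_rc, TFKernel(kind=kind))
        total = wv.complex_values.sum()
        assert abs(coh.complex_values.sum() - total) < 1e-6 * abs(total)

    @pytest.mark.parametrize("kind", ["none", "gaussian", "choi-williams"])
    def test_ambiguity_and_convolution_paths_agree(self, small_rc, kind):
        k = TFKernel(kind=kind)
        a = cohen_distribution(small_rc, k, path="ambiguity")
        b = cohen_distribution(small_rc, k, path="tf-convolution")
        scale = np.max(np.abs(a.complex_values))
        assert np.max(np.abs(a.complex_values - b.complex_values)) < 1e-6 * scale

    def test_unknown_kernel_rejected(self, small_rc):
        with pytest.raises(ValueError):
            cohen_distribution(small_rc, TFKernel(kind="hamming"))


class TestOracleEquivalence:
    """Fast FFT paths vs literal double/triple sums on random inputs,
    including negative-valued similarity matrices."""

    @pytest.mark.parametrize("seed", range(5))
    def test_all_transforms_match_brute_force(self, seed, random_similarity, random_dna):
        rng = np.random.default_rng(seed + 100)
        n = int(rng.integers(8, 64))
        L = int(rng.integers(1, n))
        x = random_dna(n, seed)
        S = random_similarity(seed, symmetric=bool(seed % 2))
        rc = instantaneous_correlation(x, sim=S, max_lag=L)
        brute_rc = brute_instantaneous(x, x, S.lookup, L)
        np.testing.assert_allclose(rc.values, brute_rc, atol=1e-9)

        R = correlation_function(rc)
        np.testing.assert_allclose(R.values, brute_correlation(brute_rc), atol=1e-9)

        M = min(L, n - 1)
        s = symmetry_function(x, sim=S, max_half_lag=M)
        np.testing.assert_allclose(s.values, brute_symmetry(x, S.lookup, M), atol=1e-9)

        sp = spectrum(R)
        lags = np.arange(-L, L + 1)
        np.testing.assert_allclose(
            sp.complex_values, brute_dft_lags(R.values, lags, sp.fft_length), atol=1e-9)

        wv = wigner_ville(rc)
        np.testing.assert_allclose(
            wv.complex_values, brute_wigner_ville(rc.values, lags, wv.fft_length),
            atol=1e-9)

        af = ambiguity(rc)
        np.testing.assert_allclose(
            af.values, np.fft.fftshift(brute_ambiguity(rc.values, n), axes=0),
            atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_pathway_commutativity(self, seed, random_similarity, random_dna):
        """Summing WV rows over position equals the spectrum of the summed
        correlation; the ambiguity plane inverse-transforms back to the
        lag grid."""
        x = random_dna(24, seed + 50)
        S = random_similarity(seed + 50, symmetric=True)
        rc = instantaneous_correlation(x, sim=S, max_lag=12)
        wv = wigner_ville(rc)
        sp = spectrum(correlation_function(rc), fft_length=wv.fft_length)
        np.testing.assert_allclose(
            wv.complex_values.sum(axis=0), sp.complex_values, atol=1e-9)
        marg = tf_marginal_spectrum(wv)
        np.testing.assert_allclose(marg.values, sp.values, atol=1e-9)

        af = ambiguity(rc)
        back = np.fft.ifft(np.fft.ifftshift(af.values, axes=0), axis=0)
        np.testing.assert_allclose(back.real, rc.values, atol=1e-9)
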