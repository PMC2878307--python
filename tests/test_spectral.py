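"""Step encoding, Welch-windowed spectra and S/N periodicity detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alunuc.io_annotation import GenomeSequence
from alunuc.spectral import (
    SpectrumResult,
    average_spectrum,
    band_excess,
    encode_step,
    find_peaks,
    get_step,
    power_spectrum,
    random_control,
    sample_fragments,
    sn_ratio,
    step_classes,
    welch_window,
)


def brute_dft_power(bits: np.ndarray, window: np.ndarray) -> np.ndarray:
    """O(N^2) direct evaluation of |sum B W e^{-2pi i nk/N}|^2, the oracle
    the FFT path must reproduce."""
    b = (bits - bits.mean()) * window
    N = len(b)
    k = np.arange(N)
    return np.array(
        [np.abs(np.sum(b * np.exp(-2j * np.pi * n * k / N))) ** 2 for n in range(N // 2)]
    )


class TestStepClasses:
    def test_twelve_classes_partition_words(self):
        classes = step_classes()
        assert len(classes) == 12
        mono = [c for c in classes if c.kind == "mono"]
        di = [c for c in classes if c.kind == "di"]
        assert len(mono) == 2 and len(di) == 10
        assert set().union(*(c.members for c in mono)) == set("ACGT")
        di_words = [w for c in di for w in c.members]
        assert sorted(di_words) == sorted(a + b for a in "ACGT" for b in "ACGT")

    def test_lookup_by_either_orientation(self):
        assert get_step("AA/TT") is not None
        assert get_step("TT/AA").members == frozenset({"AA", "TT"})
        assert get_step("CG").members == frozenset({"CG"})
        with pytest.raises(KeyError):
            get_step("XX")


class TestEncodeStep:
    @pytest.mark.parametrize(
        "seq,label,bits",
        [
            ("CTTGAAT", "AA/TT", "010010"),
            ("AAAA", "AA/TT", "111"),  # overlapping occurrences
            ("ACGT", "G/C", "011"),  # mono indicator truncated to L-1
            ("ACGT", "A/T", "100"),
        ],
    )
    def test_examples(self, seq, label, bits):
        got = encode_step(seq, get_step(label))
        assert "".join(str(int(x)) for x in got) == bits

    def test_n_rejected(self):
        with pytest.raises(ValueError):
            encode_step("ACNGT", get_step("AA/TT"))

    @given(st.text(alphabet="ACGT", min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_di_classes_partition_every_position(self, seq):
        total = sum(encode_step(seq, c) for c in step_classes() if c.kind == "di")
        assert np.all(total == 1)


class TestWelchWindow:
    def test_small_windows(self):
        assert np.allclose(welch_window(3), [0, 1, 0])
        assert np.allclose(welch_window(5), [0, 0.75, 1, 0.75, 0])

    def test_symmetry_and_bounds(self):
        w = welch_window(101)
        assert np.allclose(w, w[::-1])
        assert w.max() == 1.0 and w.min() == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            welch_window(2)


class TestPowerSpectrum:
    def test_all_zero_input_gives_zero_spectrum(self):
        assert np.all(power_spectrum(np.zeros(16)) == 0)

    def test_matches_brute_force_dft(self, rng):
        for L in (8, 12, 16, 33, 64):
            bits = rng.integers(0, 2, L).astype(float)
            F = power_spectrum(bits)
            ref = brute_dft_power(bits, welch_window(L))
            assert np.allclose(F, ref, rtol=1e-9, atol=1e-12)

    def test_period4_indicator_flat_window(self):
        # with an all-ones window and no centering, a period-4 comb of
        # length 8 has power only at n in {0, 2}
        bits = np.array([1, 0, 0, 0, 1, 0, 0, 0], dtype=float)
        F = power_spectrum(bits, window=np.ones(8), center=False)
        assert F[0] > 0 and F[2] > 0
        assert np.allclose(F[[1, 3]], 0, atol=1e-20)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.array([]))


class TestSnRatio:
    def test_flat_spectrum_is_identically_one(self):
        assert np.allclose(sn_ratio(np.array([7.0, 3, 3, 3, 3])), 1.0)

    def test_mean_of_reported_bins_is_one(self, rng):
        F = rng.random(100) + 0.1
        assert np.isclose(sn_ratio(F).mean(), 1.0)

    def test_arithmetic_example(self):
        # mean over reported bins of (2, 4) is 3 -> R = (2/3, 4/3)
        assert np.allclose(sn_ratio(np.array([123.0, 2, 4])), [2 / 3, 4 / 3])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sn_ratio(np.zeros(10))


class TestSampleFragments:
    def _genome(self, seq):
        return GenomeSequence({"c1": seq})

    def test_all_n_genome_rejected(self):
        with pytest.raises(ValueError, match="33"):
            sample_fragments(self._genome("N" * 100), 5, frag_len=33)

    def test_fragments_full_length_and_n_free(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000)) + "N" * 50 + "ACGT" * 200
        frags = sample_fragments(self._genome(seq), 20, frag_len=257, rng_seed=1)
        assert all(len(f) == 257 and "N" not in f for f in frags)

    def test_seed_reproducibility(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 3000))
        g = self._genome(seq)
        assert sample_fragments(g, 10, 513, 7) == sample_fragments(g, 10, 513, 7)


class TestRandomControl:
    def test_degenerate_composition(self):
        frags = random_control((1.0, 0, 0, 0), 3, 50, 0)
        assert all(f == "A" * 50 for f in frags)

    def test_composition_within_binomial_noise(self):
        p = {"A": 0.4, "C": 0.1, "G": 0.2, "T": 0.3}
        frags = random_control(p, 20, 1000, 5)
        joined = "".join(frags)
        n = len(joined)
        for b, pb in p.items():
            sd = (pb * (1 - pb) / n) ** 0.5
            assert abs(joined.count(b) / n - pb) < 3 * sd + 1e-9

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            random_control((-0.1, 0.5, 0.3, 0.3), 1, 10, 0)

    def test_seed_reproducibility(self):
        assert random_control((0.25,) * 4, 4, 64, 9) == random_control((0.25,) * 4, 4, 64, 9)


class TestAverageSpectrum:
    def test_single_fragment_equals_sn_ratio(self, rng):
        frag = "".join(rng.choice(list("ACGT"), 129))
        step = get_step("AA/TT")
        res = average_spectrum([frag], step)
        direct = sn_ratio(power_spectrum(encode_step(frag, step)))
        assert np.allclose(res.sn, direct)

    def test_order_invariance(self, rng):
        frags = ["".join(rng.choice(list("ACGT"), 129)) for _ in range(5)]
        step = get_step("GC")
        a = average_spectrum(frags, step)
        b = average_spectrum(frags[::-1], step)
        assert np.allclose(a.sn, b.sn)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            average_spectrum(["ACGTACGTA", "ACGT"], get_step("AA/TT"))

    def test_planted_period16_recovered(self, rng):
        unit = "A" * 9 + "CGCGCGC"  # period 16, half-duty AA run
        base = unit * 70
        frags = [base[int(rng.integers(16)):][:1025] for _ in range(50)]
        res = average_spectrum(frags, get_step("AA/TT"))
        n_star = int(np.argmax(res.sn)) + 1
        assert abs(n_star - 1024 / 16) <= 1

    def test_period_axis_decreasing(self, rng):
        frag = "".join(rng.choice(list("ACGT"), 65))
        res = average_spectrum([frag], get_step("A/T"))
        assert np.all(np.diff(res.period) < 0)


class TestFindPeaks:
    def _result(self, sn):
        sn = np.asarray(sn, dtype=float)
        return SpectrumResult(get_step("AA/TT"), 1, sn, N=2 * (len(sn) + 1))

    def test_flat_spectrum_has_no_peaks(self):
        assert find_peaks(self._result(np.ones(100)), (4, 50)) == []

    def test_single_planted_peak_found_first(self):
        sn = np.ones(200)
        sn[39] = 5.0  # n = 40
        res = self._result(sn)
        peaks = find_peaks(res, (2, 402), top_k=1)
        assert len(peaks) == 1
        assert abs(peaks[0][0] - res.N / 40) < 1e-9

    def test_tie_breaks_toward_longer_period(self):
        sn = np.ones(300)
        sn[49] = sn[99] = 4.0  # two equal peaks at n=50 and n=100
        peaks = find_peaks(self._result(sn), (2, 602), top_k=2)
        assert peaks[0][0] > peaks[1][0]

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            find_peaks(self._result(np.ones(50)), (10, 10))


def test_band_excess_of_identical_spectra_is_zero(rng):
    frags = ["".join(rng.choice(list("ACGT"), 257)) for _ in range(4)]
    a = average_spectrum(frags, get_step("AA/TT"))
    assert band_excess(a, a, (8, 64)) == 0.0
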