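"""Chord predictors: worked examples, brute-force oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bp_affect import features as feat
from bp_affect import scales


def _chord(pitches):
    """Wrap explicit MIDI pitches in a RealizedChord for the predictors."""
    return scales.RealizedChord(
        scales.ChordPattern(1, 2), 0, tuple(float(p) for p in pitches), "manual"
    )


class TestHarmonicSpectrum:
    def test_single_harmonic(self):
        s = feat.hct_spectrum(1)
        assert s.cents == pytest.approx([0.0])
        assert s.weights == pytest.approx([1.0])

    def test_harmonic_positions_and_weights(self):
        s = feat.hct_spectrum(64)
        assert s.cents[1] == pytest.approx(1200.0)
        assert s.weights[1] == pytest.approx(0.5)
        # harmonic 3 sits a tritave above the fundamental
        assert s.cents[2] == pytest.approx(1901.955, abs=1e-3)
        assert np.all(np.diff(s.weights) < 0)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            feat.hct_spectrum(0)


class TestRoughness:
    def test_coincident_partials_contribute_zero(self):
        # two partials at the same frequency produce no beating
        pair = feat.ROUGHNESS_MODELS["sethares"]
        f = np.array([440.0])
        assert pair(f, f, np.array([1.0]), np.array([1.0])) == pytest.approx(0.0)

    def test_unknown_model_errors(self, chords66_et):
        with pytest.raises(ValueError, match="unknown roughness model"):
            feat.roughness(chords66_et[0], model="nope")

    def test_cluster_chord_is_roughest(self, chords66_et):
        vals = {c.pattern.label: feat.roughness(c) for c in chords66_et}
        assert max(vals, key=vals.get) == "0 1 2"

    @pytest.mark.parametrize("model", ["sethares", "hutchinson_knopoff"])
    def test_vectorized_equals_naive_double_loop(self, et_scale, model):
        chord = scales.realize_chord(et_scale, scales.ChordPattern(6, 10), 0, 60.0)
        got = feat.roughness(chord, model=model, n_harmonics=16)
        cents, w = feat._chord_partials(chord, 16)
        freqs = np.asarray(scales.midi_to_freq(cents / 100.0))
        pair = feat.ROUGHNESS_MODELS[model]
        naive = 0.0
        for i in range(len(freqs)):
            for j in range(i + 1, len(freqs)):
                lo, hi = sorted((freqs[i], freqs[j]))
                naive += float(
                    pair(np.array([lo]), np.array([hi]),
                         np.array([w[i]]), np.array([w[j]]))[0]
                )
        assert got == pytest.approx(naive, rel=1e-9)

    def test_roughness_varies_with_transposition(self, et_scale):
        pat = scales.ChordPattern(6, 10)
        a = feat.roughness(scales.realize_chord(et_scale, pat, 0, 52.0))
        b = feat.roughness(scales.realize_chord(et_scale, pat, 0, 60.0))
        assert a != pytest.approx(b)


class TestExpectationMatrix:
    @pytest.fixture(scope="class")
    def worked(self):
        # the four-pitch worked example: a 12-TET major-seventh shape
        spectrum = feat.HarmonicSpectrum(
            cents=np.array([0.0, 400.0, 700.0, 1100.0]),
            weights=np.array([1.0, 0.5, 0.5, 1.0]),
        )
        return feat.build_triad_expectation_matrix(
            spectrum, kernel_sd=6.0, domain_max=1300.0
        )

    @pytest.mark.parametrize(
        "entry,expected",
        [((400, 700), 0.25), ((400, 1100), 0.5), ((700, 1100), 0.5),
         ((300, 700), 0.25)],
    )
    def test_worked_example_entries(self, worked, entry, expected):
        assert worked.raw_value_at(*entry) == pytest.approx(expected)

    def test_smoothing_conserves_mass(self, worked):
        assert worked.total_smoothed_mass == pytest.approx(
            worked.total_raw_mass, rel=1e-6
        )

    def test_two_pitches_give_empty_matrix(self):
        spectrum = feat.HarmonicSpectrum(
            cents=np.array([0.0, 700.0]), weights=np.array([1.0, 1.0])
        )
        m = feat.build_triad_expectation_matrix(spectrum, domain_max=800.0)
        assert m.total_raw_mass == 0.0

    def test_matches_brute_force_triple_loop(self):
        spectrum = feat.hct_spectrum(12)
        m = feat.build_triad_expectation_matrix(spectrum, domain_max=1902.0)
        brute = np.zeros_like(m.raw)
        c, w = spectrum.cents, spectrum.weights
        for i in range(12):
            for j in range(i + 1, 12):
                for k in range(j + 1, 12):
                    dj, dk = c[j] - c[i], c[k] - c[i]
                    if dk > m.domain_max_cents:
                        continue
                    brute[
                        round(dj) + m.pad_cells, round(dk) + m.pad_cells
                    ] += w[i] * w[j] * w[k]
        assert np.allclose(m.raw, brute, atol=1e-12)

    def test_pair_weighting_excludes_reference(self):
        spectrum = feat.HarmonicSpectrum(
            cents=np.array([0.0, 400.0, 700.0]), weights=np.array([0.5, 0.5, 0.5])
        )
        triple = feat.build_triad_expectation_matrix(
            spectrum, domain_max=800.0, pair_weighting="triple"
        )
        pair = feat.build_triad_expectation_matrix(
            spectrum, domain_max=800.0, pair_weighting="pair"
        )
        assert triple.raw_value_at(400, 700) == pytest.approx(0.125)
        assert pair.raw_value_at(400, 700) == pytest.approx(0.25)


class TestHarmonicity:
    def test_bp_major_maximal_among_66(self, chords66_et, expectation_matrix):
        vals = {
            c.pattern.label: feat.harmonicity(c, expectation_matrix)
            for c in chords66_et
        }
        assert max(vals, key=vals.get) == "0 6 10"

    def test_translation_invariant(self, et_scale, expectation_matrix):
        pat = scales.ChordPattern(4, 7)
        a = feat.harmonicity(
            scales.realize_chord(et_scale, pat, 0, 52.0), expectation_matrix
        )
        b = feat.harmonicity(
            scales.realize_chord(et_scale, pat, 0, 61.0), expectation_matrix
        )
        assert a == pytest.approx(b, rel=1e-12)

    def test_harmonic_triad_beats_displaced_triad(self, expectation_matrix):
        # harmonics 3:5:7 sit at ~(884, 1467) cents; displacing the lookup
        # by 50 cents falls off the Gaussian-smoothed peak
        on_peak = expectation_matrix.value_at(884.36, 1466.87)
        off_peak = expectation_matrix.value_at(934.36, 1516.87)
        assert on_peak > off_peak

    def test_out_of_domain_errors(self, chords66_et, expectation_matrix):
        with pytest.raises(ValueError, match="outside matrix domain"):
            expectation_matrix.value_at(-200.0, 500.0)


class TestSpectralEntropy:
    def test_bounded_by_log2_of_cells(self, chords66_et):
        h = feat.spectral_entropy(chords66_et[0])
        assert 0.0 <= h
        # composite spectrum spans < 2^14 one-cent cells
        assert h < 14.0

    def test_near_identical_tones_match_single_tone(self):
        # tones closer than the grid resolution superpose cell-by-cell, so
        # normalization cancels the factor three
        trip = feat.spectral_entropy(_chord([60.0, 60.0 + 1e-9, 60.0 + 2e-9]))
        one = feat.spectral_entropy(_chord([60.0, 60.0 + 1e-9, 60.0 + 2e-9]),
                                    n_harmonics=64)
        solo_cents, solo_w = feat.hct_spectrum(64).cents, feat.hct_spectrum(64).weights
        # single-tone entropy via the same smoothing pipeline
        from scipy.ndimage import gaussian_filter1d

        pad = 8 * 10.0
        lo = solo_cents.min() - pad
        n = int(np.ceil(solo_cents.max() + pad - lo)) + 1
        g = np.zeros(n)
        np.add.at(g, np.round(solo_cents - lo).astype(int), solo_w)
        g = gaussian_filter1d(g, 10.0, mode="constant", truncate=8.0)
        x = g / g.sum()
        x = x[x > 0]
        solo = float(-(x * np.log2(x)).sum())
        assert trip == pytest.approx(solo, abs=1e-9)
        assert one == trip

    def test_published_ordinal_relation(self, et_scale):
        h_0910 = feat.spectral_entropy(
            scales.realize_chord(et_scale, scales.ChordPattern(9, 10), 0, 52.0)
        )
        h_0811 = feat.spectral_entropy(
            scales.realize_chord(et_scale, scales.ChordPattern(8, 11), 0, 52.0)
        )
        assert h_0910 > h_0811

    def test_translation_invariant(self, et_scale):
        pat = scales.ChordPattern(5, 9)
        a = feat.spectral_entropy(scales.realize_chord(et_scale, pat, 0, 52.0))
        b = feat.spectral_entropy(scales.realize_chord(et_scale, pat, 0, 58.0))
        assert a == pytest.approx(b, abs=1e-9)


class TestAveragePitch:
    def test_worked_example(self):
        assert feat.average_pitch(_chord([60.0, 68.78, 74.63])) == pytest.approx(
            67.8, abs=0.05
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        p=st.floats(40, 80), d1=st.floats(0.5, 10), d2=st.floats(0.5, 10),
        delta=st.floats(-10, 10),
    )
    def test_translation_equivariant(self, p, d1, d2, delta):
        base = feat.average_pitch(_chord([p, p + d1, p + d1 + d2]))
        moved = feat.average_pitch(
            _chord([p + delta, p + d1 + delta, p + d1 + d2 + delta])
        )
        assert moved - base == pytest.approx(delta, abs=1e-9)


def _tet12_oracle(chord, grid_step=0.001):
    """Offset grid search plus the exact L1 breakpoints (the optimum of a
    piecewise-linear objective lies at a breakpoint)."""
    p1, p2, p3 = chord.pitches_midi
    i1, i2 = p2 - p1, p3 - p1
    best = np.inf
    for m1 in (round(i1) - 1, round(i1), round(i1) + 1):
        for m2 in (round(i2) - 1, round(i2), round(i2) + 1):
            anchors = np.array([p1, p2 - m1, p3 - m2])
            ts = np.concatenate(
                [np.arange(anchors.min(), anchors.max() + grid_step, grid_step),
                 anchors]
            )
            vals = (
                np.abs(p1 - ts) + np.abs(p2 - (ts + m1)) + np.abs(p3 - (ts + m2))
            )
            best = min(best, float(vals.min()))
    return best


class TestTet12Dissimilarity:
    def test_worked_example(self):
        assert feat.tet12_dissimilarity(_chord([60.0, 68.78, 74.63])) == (
            pytest.approx(0.37, abs=1e-9)
        )

    def test_integer_interval_chords_score_zero(self):
        assert feat.tet12_dissimilarity(_chord([60.3, 64.3, 67.3])) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_median_closed_form_matches_grid_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p1 = rng.uniform(45, 70)
            pitches = [p1, p1 + rng.uniform(0.5, 10), 0]
            pitches[2] = pitches[1] + rng.uniform(0.5, 10)
            chord = _chord(pitches)
            assert feat.tet12_dissimilarity(chord) == pytest.approx(
                _tet12_oracle(chord), abs=1e-6
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        p=st.floats(40, 75), d1=st.floats(0.3, 9), d2=st.floats(0.3, 9),
        delta=st.floats(-7, 7),
    )
    def test_translation_invariant_and_nonnegative(self, p, d1, d2, delta):
        a = feat.tet12_dissimilarity(_chord([p, p + d1, p + d1 + d2]))
        b = feat.tet12_dissimilarity(
            _chord([p + delta, p + d1 + delta, p + d1 + d2 + delta])
        )
        assert a >= 0
        assert a == pytest.approx(b, abs=1e-9)


class TestFeatureTable:
    def test_standardized_columns_are_zscores(self, features66):
        for col in feat.PREDICTORS:
            z = features66[col + "_z"]
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std(ddof=0) == pytest.approx(1.0, rel=1e-12)

    def test_roughness_pitch_correlation_negative(self, ji_features):
        # over the full transposed stimulus set, rough chords sit low
        r = np.corrcoef(ji_features["roughness"], ji_features["average_pitch"])[0, 1]
        assert r < 0

    def test_deterministic(self, chords66_et, expectation_matrix):
        a = feat.feature_table(chords66_et[:5], matrix=expectation_matrix)
        b = feat.feature_table(chords66_et[:5], matrix=expectation_matrix)
        assert a.equals(b)

    def test_too_few_chords(self, chords66_et, expectation_matrix):
        with pytest.raises(ValueError):
            feat.feature_table(chords66_et[:1], matrix=expectation_matrix)
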