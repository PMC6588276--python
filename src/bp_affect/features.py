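"""Chord-level affect predictors for Bohlen-Pierce triads.

Five intrinsic/extrinsic predictors of chord affect are computed from the
theoretical spectrum of each chord (three harmonic complex tones with 64
partials of magnitude 1/n):

* **roughness** -- summed pairwise sensory dissonance of all partials
  (Sethares' curve by default, Hutchinson-Knopoff available);
* **harmonicity** -- the value of a smoothed triad expectation matrix of a
  single harmonic complex tone, read at the chord's interval pair;
* **spectral entropy** -- Shannon entropy of the chord's smoothed,
  normalized composite magnitude spectrum on a cents grid;
* **average pitch height** -- mean MIDI pitch (and its square);
* **12-TET dissimilarity** -- minimal L1 pitch distance to any freely
  transposed chord whose internal intervals are integer semitones.

All cents-domain computations share a Gaussian pitch-uncertainty kernel
(default SD 10 cents) and a 1-cent grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .scales import RealizedChord, midi_to_freq

__all__ = [
    "HarmonicSpectrum",
    "ExpectationMatrix",
    "FeatureConfig",
    "hct_spectrum",
    "roughness",
    "build_triad_expectation_matrix",
    "harmonicity",
    "spectral_entropy",
    "average_pitch",
    "tet12_dissimilarity",
    "feature_table",
    "standardize",
    "ROUGHNESS_MODELS",
    "PREDICTORS",
]

#: Canonical predictor column order used throughout the package.
PREDICTORS = (
    "roughness",
    "harmonicity",
    "spectral_entropy",
    "tet12_dissimilarity",
    "average_pitch",
    "average_pitch_sq",
)

DEFAULT_KERNEL_SD = 10.0  # cents; perceptual pitch-uncertainty smoothing
DEFAULT_RESOLUTION = 1.0  # cents per grid cell
DEFAULT_N_HARMONICS = 64


@dataclass(frozen=True)
class HarmonicSpectrum:
    """Partials of a harmonic complex tone as cents above f0 with weights."""

    cents: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.cents) != len(self.weights):
            raise ValueError("cents and weights must align")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")

    @property
    def n_partials(self) -> int:
        return len(self.cents)


def hct_spectrum(n_harmonics: int = DEFAULT_N_HARMONICS) -> HarmonicSpectrum:
    """Harmonic complex tone: partial n at 1200*log2(n) cents, weight 1/n."""
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    n = np.arange(1, n_harmonics + 1, dtype=float)
    return HarmonicSpectrum(1200.0 * np.log2(n), 1.0 / n)


def _chord_partials(
    chord: RealizedChord, n_harmonics: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled partials of the chord's three tones: (cents, weights).

    The three tones' magnitudes superpose linearly; masking is not
    modelled.
    """
    spec = hct_spectrum(n_harmonics)
    cents = np.concatenate([100.0 * p + spec.cents for p in chord.pitches_midi])
    weights = np.tile(spec.weights, 3)
    return cents, weights


# --- roughness --------------------------------------------------------------


def _sethares_pair(
    f_lo: np.ndarray, f_hi: np.ndarray, a1: np.ndarray, a2: np.ndarray
) -> np.ndarray:
    # Sethares (1993) parametrization of the Plomp-Levelt curve; the
    # critical-band scaling keeps the dissonance maximum near 1/4 CB.
    s = 0.24 / (0.0207 * f_lo + 18.96)
    x = s * (f_hi - f_lo)
    return a1 * a2 * (np.exp(-3.51 * x) - np.exp(-5.75 * x))


def _hutchinson_knopoff_pair(
    f_lo: np.ndarray, f_hi: np.ndarray, a1: np.ndarray, a2: np.ndarray
) -> np.ndarray:
    # Hutchinson & Knopoff (1978): critical bandwidth 1.72 * fbar^0.65,
    # dissonance factor g(y) = (y/0.25 * e^(1 - y/0.25))^2 peaking at
    # a quarter of the critical band.
    fbar = 0.5 * (f_lo + f_hi)
    cbw = 1.72 * fbar**0.65
    y = (f_hi - f_lo) / cbw
    g = (y / 0.25 * np.exp(1.0 - y / 0.25)) ** 2
    return a1 * a2 * g


ROUGHNESS_MODELS: dict[str, Callable] = {
    "sethares": _sethares_pair,
    "hutchinson_knopoff": _hutchinson_knopoff_pair,
}


def roughness(
    chord: RealizedChord,
    model: str = "sethares",
    n_harmonics: int = DEFAULT_N_HARMONICS,
) -> float:
    """Summed pairwise roughness of the chord's pooled partials.

    Operates in frequency (Hz), so unlike the other spectral predictors it
    is *not* invariant under transposition.  Pair contributions are
    weighted by the product of the partial amplitudes.
    """
    try:
        pair_fn = ROUGHNESS_MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown roughness model {model!r}; "
            f"choose from {sorted(ROUGHNESS_MODELS)}"
        ) from None
    cents, weights = _chord_partials(chord, n_harmonics)
    freqs = np.asarray(midi_to_freq(cents / 100.0))
    i, j = np.triu_indices(len(freqs), k=1)
    f_lo = np.minimum(freqs[i], freqs[j])
    f_hi = np.maximum(freqs[i], freqs[j])
    return float(np.sum(pair_fn(f_lo, f_hi, weights[i], weights[j])))


# --- harmonicity ------------------------------------------------------------


@dataclass
class ExpectationMatrix:
    """Smoothed weighted counts of ordered interval pairs in a spectrum.

    ``grid`` is indexed by (lower interval, outer interval) in cents at
    ``resolution_cents`` per cell; the axes are padded by ``pad_cells`` on
    each side so that the Gaussian smoothing conserves mass.  ``raw``
    holds the unsmoothed spikes on the same padded grid.
    """

    grid: np.ndarray
    raw: np.ndarray
    resolution_cents: float
    kernel_sd_cents: float
    domain_max_cents: float
    pad_cells: int
    pair_weighting: str

    def _index(self, interval_cents: float) -> int:
        idx = int(round(interval_cents / self.resolution_cents)) + self.pad_cells
        lo, hi = self.pad_cells, self.pad_cells + int(
            round(self.domain_max_cents / self.resolution_cents)
        )
        if not lo <= idx <= hi:
            raise ValueError(
                f"interval {interval_cents:.1f} cents outside matrix domain "
                f"[0, {self.domain_max_cents}]"
            )
        return idx

    def value_at(self, interval1_cents: float, interval2_cents: float) -> float:
        """Nearest-cell lookup in the smoothed matrix."""
        return float(
            self.grid[self._index(interval1_cents), self._index(interval2_cents)]
        )

    def raw_value_at(self, interval1_cents: float, interval2_cents: float) -> float:
        """Nearest-cell lookup in the unsmoothed spike matrix."""
        return float(
            self.raw[self._index(interval1_cents), self._index(interval2_cents)]
        )

    @property
    def total_raw_mass(self) -> float:
        return float(self.raw.sum())

    @property
    def total_smoothed_mass(self) -> float:
        return float(self.grid.sum())


def build_triad_expectation_matrix(
    spectrum: HarmonicSpectrum | None = None,
    kernel_sd: float = DEFAULT_KERNEL_SD,
    resolution: float = DEFAULT_RESOLUTION,
    domain_max: float = 1902.0,
    pair_weighting: str = "triple",
) -> ExpectationMatrix:
    """Triad expectation matrix of a spectrum.

    For every reference partial i and ordered pair of higher partials
    (j, k) -- intervals d_j < d_k above the reference -- a spike is
    deposited at (d_j, d_k).  With ``pair_weighting="triple"`` the spike
    weight is w_i*w_j*w_k (the reference participates in the count); with
    ``"pair"`` it is w_j*w_k.  Coincident pairs accumulate additively.
    The spikes are then convolved with an isotropic 2-D Gaussian kernel
    modelling pitch-perception uncertainty.

    Pairs whose outer interval exceeds ``domain_max`` are dropped.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    if pair_weighting not in ("triple", "pair"):
        raise ValueError("pair_weighting must be 'triple' or 'pair'")
    spectrum = spectrum or hct_spectrum()
    if spectrum.n_partials == 0:
        raise ValueError("spectrum is empty")

    truncate = 6.0
    pad = int(np.ceil(truncate * kernel_sd / resolution))
    n_domain = int(round(domain_max / resolution))
    n = n_domain + 2 * pad + 1
    raw = np.zeros((n, n))

    c, w = spectrum.cents, spectrum.weights
    m = spectrum.n_partials
    for i in range(m - 2):
        d = c[i + 1 :] - c[i]
        wi, w_above = w[i], w[i + 1 :]
        keep = d <= domain_max
        d, w_above = d[keep], w_above[keep]
        if len(d) < 2:
            continue
        j, k = np.triu_indices(len(d), k=1)
        spikes = w_above[j] * w_above[k]
        if pair_weighting == "triple":
            spikes = wi * spikes
        rows = np.round(d[j] / resolution).astype(int) + pad
        cols = np.round(d[k] / resolution).astype(int) + pad
        np.add.at(raw, (rows, cols), spikes)

    grid = gaussian_filter(
        raw, sigma=kernel_sd / resolution, mode="constant", truncate=truncate
    )
    return ExpectationMatrix(
        grid=grid,
        raw=raw,
        resolution_cents=resolution,
        kernel_sd_cents=kernel_sd,
        domain_max_cents=domain_max,
        pad_cells=pad,
        pair_weighting=pair_weighting,
    )


def harmonicity(chord: RealizedChord, matrix: ExpectationMatrix) -> float:
    """Expectation-matrix value at the chord's (lower, outer) interval pair.

    Depends only on the chord's intervals, not its absolute pitch.
    """
    lo, hi = chord.intervals_cents
    return matrix.value_at(lo, hi)


# --- spectral entropy -------------------------------------------------------


def spectral_entropy(
    chord: RealizedChord,
    kernel_sd: float = DEFAULT_KERNEL_SD,
    resolution: float = DEFAULT_RESOLUTION,
    n_harmonics: int = DEFAULT_N_HARMONICS,
    base: float = 2.0,
) -> float:
    """Entropy (bits by default) of the chord's smoothed composite spectrum.

    The three tones' partial magnitudes are superposed on a common cents
    grid, smoothed with a Gaussian kernel, normalized to a probability
    mass function x, and H(x) = -sum x_n log x_n is returned.  Cells with
    zero mass contribute nothing.  The measure depends only on the
    chord's intervals (a translation on the cents grid).
    """
    cents, weights = _chord_partials(chord, n_harmonics)
    if len(cents) == 0:
        raise ValueError("composite spectrum is empty")
    truncate = 8.0
    pad = truncate * kernel_sd
    lo = cents.min() - pad
    n = int(np.ceil((cents.max() + pad - lo) / resolution)) + 1
    grid = np.zeros(n)
    np.add.at(grid, np.round((cents - lo) / resolution).astype(int), weights)
    grid = gaussian_filter1d(
        grid, sigma=kernel_sd / resolution, mode="constant", truncate=truncate
    )
    x = grid / grid.sum()
    x = x[x > 0]
    return float(-(x * (np.log(x) / np.log(base))).sum())


# --- pitch height and 12-TET dissimilarity ---------------------------------


def average_pitch(chord: RealizedChord) -> float:
    """Arithmetic mean of the chord's MIDI pitches."""
    return float(np.mean(chord.pitches_midi))


def tet12_dissimilarity(chord: RealizedChord) -> float:
    """Minimal L1 distance to a freely transposed integer-interval chord.

    Minimizes |p1 - t| + |p2 - (t + m1)| + |p3 - (t + m2)| over integer
    interval patterns (m1, m2) and continuous transposition t.  For a
    fixed pattern the optimal t is the median of (p1, p2 - m1, p3 - m2);
    the L1 optimum cannot round an interval by more than one semitone,
    so the nine candidate patterns around the rounded intervals suffice.
    """
    p1, p2, p3 = chord.pitches_midi
    i1, i2 = p2 - p1, p3 - p1
    best = np.inf
    for m1 in (round(i1) - 1, round(i1), round(i1) + 1):
        for m2 in (round(i2) - 1, round(i2), round(i2) + 1):
            t = float(np.median([p1, p2 - m1, p3 - m2]))
            total = abs(p1 - t) + abs(p2 - (t + m1)) + abs(p3 - (t + m2))
            best = min(best, total)
    return float(best)


# --- feature table ----------------------------------------------------------


@dataclass(frozen=True)
class FeatureConfig:
    """Shared parameters of the predictor computations."""

    kernel_sd: float = DEFAULT_KERNEL_SD
    resolution: float = DEFAULT_RESOLUTION
    n_harmonics: int = DEFAULT_N_HARMONICS
    roughness_model: str = "sethares"
    pair_weighting: str = "triple"
    domain_max: float = 1902.0

    def to_dict(self) -> dict:
        return {
            "kernel_sd": self.kernel_sd,
            "resolution": self.resolution,
            "n_harmonics": self.n_harmonics,
            "roughness_model": self.roughness_model,
            "pair_weighting": self.pair_weighting,
            "domain_max": self.domain_max,
        }


def standardize(df: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    """Append z-scored ``<col>_z`` columns (population SD over the rows)."""
    if len(df) < 2:
        raise ValueError("standardization needs at least 2 rows")
    out = df.copy()
    for col in columns:
        x = df[col].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        out[col + "_z"] = (x - x.mean()) / sd
    return out


def feature_table(
    chords: Sequence[RealizedChord],
    config: FeatureConfig | None = None,
    matrix: ExpectationMatrix | None = None,
) -> pd.DataFrame:
    """Raw and standardized predictors, one row per chord.

    The squared pitch term is the square of the raw average pitch,
    z-scored afterwards.  Standardization is over the supplied chord set.
    """
    config = config or FeatureConfig()
    if matrix is None:
        matrix = build_triad_expectation_matrix(
            hct_spectrum(config.n_harmonics),
            kernel_sd=config.kernel_sd,
            resolution=config.resolution,
            domain_max=config.domain_max,
            pair_weighting=config.pair_weighting,
        )
    rows = []
    for chord in chords:
        ap = average_pitch(chord)
        rows.append(
            {
                "chord_id": chord.pattern.label,
                "pattern_a": chord.pattern.a,
                "pattern_b": chord.pattern.b,
                "root_step": chord.root_step,
                "scale_name": chord.scale_name,
                "roughness": roughness(
                    chord, config.roughness_model, config.n_harmonics
                ),
                "harmonicity": harmonicity(chord, matrix),
                "spectral_entropy": spectral_entropy(
                    chord, config.kernel_sd, config.resolution, config.n_harmonics
                ),
                "average_pitch": ap,
                "average_pitch_sq": ap**2,
                "tet12_dissimilarity": tet12_dissimilarity(chord),
            }
        )
    return standardize(pd.DataFrame(rows), PREDICTORS)
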