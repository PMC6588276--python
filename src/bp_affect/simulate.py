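"""Synthetic rating data with the structure the regression models assume.

The generator mirrors the fitted model exactly -- Gaussian likelihood,
linear predictor over the six standardized chord predictors and their
musical-sophistication interactions, correlated per-participant random
effects, and a first-order carry-over on the previous response -- so that
parameter recovery is a well-posed check of the modelling stage.

A session emulates the published design: 60 participants, 4 blocks of 66
trials (two consonance blocks, two valence blocks, order randomized), each
block a permutation of the 66 tritave-free triad patterns, each trial
rooted on a random chromatic degree 0-12 above a bass of MIDI 52, and
responses recorded on a 700-point slider.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import features as feat
from .scales import ScaleDef, build_ji_scale, enumerate_patterns, realize_chord

__all__ = [
    "Coefficients",
    "SimulationConfig",
    "CONSONANCE_TRUTH",
    "VALENCE_TRUTH",
    "make_design",
    "stimulus_features",
    "simulate_ratings",
    "quantize_slider",
    "dequantize_slider",
]

GMSI_POPULATION_MEAN = 81.58


@dataclass(frozen=True)
class Coefficients:
    """Population-level truth for one response type (standardized units)."""

    intercept: float = 0.0
    gmsi_main: float = 0.10
    beta: tuple[float, ...] = (0.0,) * 6      # aligned with feat.PREDICTORS
    gamma: tuple[float, ...] = (0.0,) * 6     # GMSI interactions, same order

    def as_dict(self) -> dict[str, float]:
        d = {"intercept": self.intercept, "gmsi": self.gmsi_main}
        for name, b, g in zip(feat.PREDICTORS, self.beta, self.gamma):
            d[name] = b
            d[f"gmsi:{name}"] = g
        return d


#: Published posterior means for the consonance model (predictor order:
#: roughness, harmonicity, spectral entropy, 12-TET dissimilarity,
#: average pitch, average pitch squared).
CONSONANCE_TRUTH = Coefficients(
    beta=(-0.14, 0.08, -0.11, -0.12, 0.15, 0.03),
    gamma=(-0.02, 0.07, 0.03, -0.06, -0.11, 0.02),
)

#: Published posterior means for the valence model.
VALENCE_TRUTH = Coefficients(
    beta=(-0.08, 0.06, -0.06, -0.04, 0.40, 0.16),
    gamma=(-0.03, 0.03, 0.00, 0.00, -0.12, 0.02),
)


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 60
    n_blocks: int = 4
    trials_per_block: int = 66
    truth: dict = field(
        default_factory=lambda: {
            "consonance": CONSONANCE_TRUTH,
            "valence": VALENCE_TRUTH,
        }
    )
    #: SD of the participant random intercept and the six random slopes.
    participant_sd: tuple[float, ...] = (0.1,) * 7
    #: Exchangeable correlation between random effects.
    re_correlation: float = 0.2
    #: Carry-over weight on the previous standardized response.
    ar_coefficient: float = 0.3
    #: Exposure effects on z-scored (TrialNo, TrialNo^2, ChordNo, ChordNo^2);
    #: zero by default (no short-term learning).
    learning: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    #: Residual SD; "auto" solves for unit total latent variance.
    noise_sd: float | str = "auto"
    gmsi_mean: float = GMSI_POPULATION_MEAN
    gmsi_sd: float = 20.0
    slider_levels: int = 700
    #: Latent interval mapped onto the slider.
    latent_range: tuple[float, float] = (-3.0, 3.0)
    base_midi: float = 52.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.participant_sd):
            raise ValueError("random-effect SDs must be non-negative")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1")
        if self.slider_levels < 2:
            raise ValueError("slider needs at least 2 levels")
        if self.n_blocks % 2:
            raise ValueError("blocks split evenly between response types")


def quantize_slider(
    latent: np.ndarray | float,
    levels: int = 700,
    latent_range: tuple[float, float] = (-3.0, 3.0),
) -> np.ndarray:
    """Affine map of the latent interval onto 0..levels-1, half-up, clipped."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    lo, hi = latent_range
    x = (np.asarray(latent, dtype=float) - lo) / (hi - lo) * (levels - 1)
    return np.clip(np.floor(x + 0.5), 0, levels - 1).astype(int)


def dequantize_slider(
    raw: np.ndarray | int,
    levels: int = 700,
    latent_range: tuple[float, float] = (-3.0, 3.0),
) -> np.ndarray:
    """Inverse affine map: slider integers back onto the latent scale."""
    lo, hi = latent_range
    return lo + np.asarray(raw, dtype=float) / (levels - 1) * (hi - lo)


def make_design(config: SimulationConfig) -> pd.DataFrame:
    """Trial table (no ratings): blocks, response types, chords, roots.

    Per participant: a random order of two consonance and two valence
    blocks; within each block a permutation of the 66 tritave-free
    patterns with an independent random root 0-12 per trial.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    patterns = enumerate_patterns(include_tritave=False)
    if config.trials_per_block != len(patterns):
        raise ValueError("trials_per_block must equal the 66 patterns")
    half = config.n_blocks // 2
    rows = []
    for pid in range(1, config.n_participants + 1):
        block_types = np.array(["consonance"] * half + ["valence"] * half)
        rng.shuffle(block_types)
        trial_no = 0
        for b, btype in enumerate(block_types):
            order = rng.permutation(len(patterns))
            roots = rng.integers(0, 13, size=len(patterns))
            for idx, root in zip(order, roots):
                trial_no += 1
                pat = patterns[idx]
                rows.append(
                    (pid, b + 1, btype, trial_no, pat.label, pat.a, pat.b, int(root))
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "block_index",
            "block_type",
            "trial_number",
            "chord_id",
            "pattern_a",
            "pattern_b",
            "root_step",
        ],
    )


def stimulus_features(
    scale: ScaleDef | None = None,
    config: feat.FeatureConfig | None = None,
    base_midi: float = 52.0,
) -> pd.DataFrame:
    """Raw predictors for all 66 patterns x 13 roots of a tuning.

    The realization id identifies the chord's interval content at 0.1
    cent, the grouping under which just-intonation realizations are
    distinct (414 classes) while equal-tempered ones collapse to 66.
    """
    scale = scale or build_ji_scale()
    fconfig = config or feat.FeatureConfig()
    chords = [
        realize_chord(scale, pat, root, base_midi)
        for pat in enumerate_patterns(include_tritave=False)
        for root in range(13)
    ]
    table = feat.feature_table(chords, fconfig)
    real_ids = [
        "{:.1f}_{:.1f}".format(*chord.intervals_cents) for chord in chords
    ]
    table.insert(4, "realization_id", real_ids)
    return table


def _exchangeable_cov(sds: np.ndarray, rho: float) -> np.ndarray:
    q = len(sds)
    corr = np.full((q, q), rho)
    np.fill_diagonal(corr, 1.0)
    return corr * np.outer(sds, sds)


def simulate_ratings(
    design: pd.DataFrame,
    features: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Generate slider ratings for a trial design.

    latent = intercept + sum_k beta_k x_k + gmsi*(gmsi_main + sum_k
    gamma_k x_k) + participant intercept/slopes + ar*previous + noise,
    with x_k the predictors z-scored over the design's trials and gmsi
    centred at the published population mean and scaled by the population
    SD.  The latent value is quantized to the slider; the recorded
    standardized rating is the quantized value mapped back to the latent
    scale, so the carry-over term uses exactly what a later analysis can
    reconstruct.  The first trial of each block has no carry-over.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    data = design.merge(
        features, on=["pattern_a", "pattern_b", "root_step"], how="left",
        suffixes=("", "_feat"),
    )
    if data[list(feat.PREDICTORS)].isna().any().any():
        missing = data[data[list(feat.PREDICTORS)].isna().any(axis=1)]
        raise KeyError(
            "design rows without feature rows, e.g. "
            f"{missing[['chord_id', 'root_step']].iloc[0].tolist()}"
        )
    data = data.sort_values(["participant_id", "trial_number"], kind="stable")
    data = data.reset_index(drop=True)

    # Standardize predictors over the trials of this design.
    X = np.column_stack(
        [
            (data[c].to_numpy() - data[c].mean()) / data[c].std(ddof=0)
            for c in feat.PREDICTORS
        ]
    )
    n = len(data)

    participants = data["participant_id"].unique()
    gmsi_raw = rng.normal(config.gmsi_mean, config.gmsi_sd, size=len(participants))
    gmsi_std = (gmsi_raw - GMSI_POPULATION_MEAN) / config.gmsi_sd
    gmsi_by_pid = dict(zip(participants, zip(gmsi_raw, gmsi_std)))

    sds = np.asarray(config.participant_sd, dtype=float)
    cov = _exchangeable_cov(sds, config.re_correlation)
    re_draws = rng.multivariate_normal(np.zeros(len(sds)), cov, size=len(participants))
    re_by_pid = dict(zip(participants, re_draws))

    truths = {k: np.array(v.beta) for k, v in config.truth.items()}
    gammas = {k: np.array(v.gamma) for k, v in config.truth.items()}

    # Exposure (short-term learning) terms on z-scored counters.
    chord_no = (
        data.groupby(["participant_id", "chord_id"]).cumcount().to_numpy() + 1.0
    )
    learn = np.zeros(n)
    if any(config.learning):
        t_cnt = data["trial_number"].to_numpy(float)

        def _z(v):
            return (v - v.mean()) / v.std()

        # Quadratics square the centred counters (near-orthogonal to the
        # linear terms), matching the learning model's construction.
        cols = (_z(t_cnt), _z(_z(t_cnt) ** 2), _z(chord_no), _z(_z(chord_no) ** 2))
        for coef, col in zip(config.learning, cols):
            if coef:
                learn += coef * col

    # Deterministic part of the linear predictor for every trial.
    pid_codes, pid_levels = pd.factorize(data["participant_id"], sort=False)
    g_arr = np.array([gmsi_by_pid[p][1] for p in pid_levels])[pid_codes]
    u_arr = np.array([re_by_pid[p] for p in pid_levels])[pid_codes]
    signal = u_arr[:, 0] + np.einsum("nk,nk->n", u_arr[:, 1:], X) + learn
    for btype, coefs in config.truth.items():
        rows = (data["block_type"] == btype).to_numpy()
        signal[rows] += (
            coefs.intercept
            + X[rows] @ truths[btype]
            + g_arr[rows] * (coefs.gmsi_main + X[rows] @ gammas[btype])
        )

    # Residual SD: explicit, or solved so total latent variance is ~1 per
    # response type (keeps the slider's standardized scale aligned with
    # the generating coefficients).
    noise_by_type: dict[str, float] = {}
    for btype in config.truth:
        if config.noise_sd == "auto":
            var_signal = float(np.var(signal[data["block_type"] == btype]))
            var_eps = (1.0 - config.ar_coefficient**2) - var_signal
            noise_by_type[btype] = float(np.sqrt(max(var_eps, 0.05**2)))
        else:
            noise_by_type[btype] = float(config.noise_sd)

    eps = rng.standard_normal(n)
    noise_arr = np.array([noise_by_type[b] for b in data["block_type"]])
    block_arr = data["block_index"].to_numpy()
    new_block = np.ones(n, dtype=bool)
    new_block[1:] = (pid_codes[1:] != pid_codes[:-1]) | (
        block_arr[1:] != block_arr[:-1]
    )
    lo, hi = config.latent_range
    levels = config.slider_levels
    rating_raw = np.empty(n, dtype=int)
    rating_std = np.empty(n)
    previous = np.zeros(n)
    prev_val = 0.0
    for i in range(n):
        if new_block[i]:
            prev_val = 0.0
        previous[i] = prev_val
        latent = signal[i] + config.ar_coefficient * prev_val + noise_arr[i] * eps[i]
        q = int(
            min(max(np.floor((latent - lo) / (hi - lo) * (levels - 1) + 0.5), 0),
                levels - 1)
        )
        rating_raw[i] = q
        prev_val = lo + q / (levels - 1) * (hi - lo)
        rating_std[i] = prev_val

    out = data[
        [
            "participant_id",
            "block_index",
            "block_type",
            "trial_number",
            "chord_id",
            "realization_id",
            "pattern_a",
            "pattern_b",
            "root_step",
            "scale_name",
        ]
        + list(feat.PREDICTORS)
    ].copy()
    out["experiment"] = np.where(out["scale_name"] == "bp_ji", 1, 2)
    out["gmsi"] = [gmsi_by_pid[p][0] for p in out["participant_id"]]
    out["gmsi_standardized"] = [gmsi_by_pid[p][1] for p in out["participant_id"]]
    out["previous_rating_standardized"] = previous
    out["rating_raw"] = rating_raw
    out["rating_standardized"] = rating_std
    # Exposure counters for the learning-effects model.
    out["chord_no"] = out.groupby(["participant_id", "chord_id"]).cumcount() + 1
    return out


def simulate_dataset(
    config: SimulationConfig,
    scale: ScaleDef | None = None,
    feature_config: feat.FeatureConfig | None = None,
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Design + features + ratings in one call (convenience wrapper)."""
    if features is None:
        features = stimulus_features(scale, feature_config, config.base_midi)
    return simulate_ratings(make_design(config), features, config)
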