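"""Predictor correlations, marginal-effects grids, figures, and the pipeline.

The pipeline runs scales -> features -> simulate -> fit -> report and
writes every table as delimited text plus a manifest recording seeds,
configuration and a content hash, so a rerun with the same seeds is
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import PREDICTORS, FeatureConfig
from .gibbs import PosteriorFit, SamplerConfig
from .models import (
    ModelSpec,
    bayes_r2,
    fit_predictive_model,
    hypothesis_table,
)
from .scales import build_et_scale, build_ji_scale, read_scl
from .simulate import SimulationConfig, make_design, simulate_ratings, stimulus_features

__all__ = [
    "predictor_correlations",
    "MarginalGrid",
    "marginal_effects",
    "plot_marginal_effects",
    "run_pipeline",
]


def predictor_correlations(
    data: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations among rating, predictors and GMSI.

    Constant columns yield NaN rows/columns and are reported in the
    result's ``attrs["constant_columns"]`` rather than silently dropped.
    """
    if columns is None:
        columns = [
            c
            for c in ["rating_standardized", *PREDICTORS, "gmsi"]
            if c in data.columns
        ]
    if len(data) < 3:
        raise ValueError("correlations need at least 3 rows")
    sub = data[columns].astype(float)
    constant = [c for c in columns if sub[c].nunique() <= 1]
    corr = sub.corr()
    corr.attrs["constant_columns"] = constant
    return corr


@dataclass
class MarginalGrid:
    """Fitted mean and 95% interval of one predictor at GMSI levels."""

    predictor: str
    table: pd.DataFrame  # columns: gmsi_level, x, mean, q2.5, q97.5


def marginal_effects(
    fit: PosteriorFit,
    predictor: str,
    gmsi_levels: tuple[float, ...] = (-1.0, 0.0, 1.0),
    grid: np.ndarray | None = None,
) -> MarginalGrid:
    """Fitted regression line over a predictor grid at fixed GMSI levels.

    All other predictors are held at 0 (their mean); the GMSI main effect
    and, when present, the predictor's GMSI interaction are included.
    """
    if predictor not in fit.fixed_names:
        raise KeyError(f"{predictor!r} not among fitted effects")
    grid = np.linspace(-2, 2, 41) if grid is None else np.asarray(grid, float)
    b0 = fit.beta_draws("intercept")
    b = fit.beta_draws(predictor)
    b_g = fit.beta_draws("gmsi") if "gmsi" in fit.fixed_names else 0.0
    inter = f"gmsi:{predictor}"
    b_int = fit.beta_draws(inter) if inter in fit.fixed_names else 0.0
    rows = []
    for m in gmsi_levels:
        for x in grid:
            d = b0 + b * x + np.asarray(b_g) * m + np.asarray(b_int) * m * x
            rows.append(
                {
                    "gmsi_level": m,
                    "x": x,
                    "mean": d.mean(),
                    "q2.5": np.quantile(d, 0.025),
                    "q97.5": np.quantile(d, 0.975),
                }
            )
    return MarginalGrid(predictor, pd.DataFrame(rows))


def plot_marginal_effects(grid: MarginalGrid, path: str | Path) -> None:
    """Static marginal-effects figure, one line per GMSI level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for m, sub in grid.table.groupby("gmsi_level"):
        ax.plot(sub["x"], sub["mean"], label=f"GMSI {m:+.0f}")
        ax.fill_between(sub["x"], sub["q2.5"], sub["q97.5"], alpha=0.2)
    ax.set_xlabel(f"{grid.predictor} (standardized)")
    ax.set_ylabel("fitted rating (standardized)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    outdir: str | Path,
    scale: str = "et",
    sim_config: SimulationConfig | None = None,
    feature_config: FeatureConfig | None = None,
    sampler: SamplerConfig | None = None,
    responses: tuple[str, ...] = ("consonance",),
    seed: int = 0,
) -> dict:
    """End-to-end run: tuning, features, simulated ratings, fits, report.

    Returns the manifest (also written to ``manifest.json``), which
    records package version, configuration, seeds, per-stage wall time
    and content hashes of the data artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_config = sim_config or SimulationConfig(seed=seed)
    feature_config = feature_config or FeatureConfig()
    sampler = sampler or SamplerConfig(seed=seed)

    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "scale": scale,
        "simulation": {
            k: (v if not hasattr(v, "as_dict") else v.as_dict())
            for k, v in sim_config.__dict__.items()
            if k != "truth"
        },
        "truth": {k: v.as_dict() for k, v in sim_config.truth.items()},
        "features_config": feature_config.to_dict(),
        "sampler": {k: v for k, v in sampler.__dict__.items()},
        "stages": {},
        "artifacts": {},
    }

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                manifest["stages"][name] = round(time.perf_counter() - self.t0, 3)

        return _T()

    with stage("scales"):
        if scale == "et":
            scl = build_et_scale()
        elif scale == "ji":
            scl = build_ji_scale()
        else:
            scl = read_scl(scale)
    with stage("features"):
        feats = stimulus_features(scl, feature_config, sim_config.base_midi)
        fpath = outdir / "features.csv"
        feats.to_csv(fpath, index=False)
    with stage("simulate"):
        design = make_design(sim_config)
        ratings = simulate_ratings(design, feats, sim_config)
        rpath = outdir / "ratings.csv"
        ratings.to_csv(rpath, index=False)
    manifest["artifacts"]["features.csv"] = _hash_file(fpath)
    manifest["artifacts"]["ratings.csv"] = _hash_file(rpath)

    for response in responses:
        with stage(f"fit_{response}"):
            fit = fit_predictive_model(
                ratings, ModelSpec(response=response), sampler=sampler
            )
        with stage(f"report_{response}"):
            fit.summary().to_csv(outdir / f"posterior_{response}.csv")
            hypothesis_table(fit).to_csv(
                outdir / f"hypotheses_{response}.csv", index=False
            )
            corr = predictor_correlations(ratings[ratings["block_type"] == response])
            corr.to_csv(outdir / f"correlations_{response}.csv")
            manifest.setdefault("results", {})[response] = {
                "bayes_r2": round(bayes_r2(fit), 4),
                "n_obs": int(fit.meta.get("n_obs", 0)),
            }
            for art in (
                f"posterior_{response}.csv",
                f"hypotheses_{response}.csv",
                f"correlations_{response}.csv",
            ):
                manifest["artifacts"][art] = _hash_file(outdir / art)

    canon = json.dumps(
        {k: manifest[k] for k in ("seed", "scale", "simulation", "truth",
                                  "features_config", "artifacts")},
        sort_keys=True, default=str,
    )
    manifest["config_hash"] = hashlib.sha256(canon.encode()).hexdigest()[:16]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
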