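"""Ground-truth validation experiments.

Each function runs a small simulation study against the synthetic
generator's known truth and returns the measured operating
characteristic: type-I error and power of the multi-predictor PGLS,
patch-count recovery of the color clustering, and imputation accuracy /
model recovery.  They are used by the acceptance machinery and are handy
for re-checking calibration after configuration changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import color as colormod
from .phylo import (
    DISPLAY_HEIGHT_LEVELS,
    PROXIMITY_LEVELS,
    Phylogeny,
    fit_trait_model,
    impute_missing,
    mpgls_model,
    simulate_traits,
)
from .synthetic import gen_cone_catch_image

MEASURE_COLUMNS = [
    "color_richness", "color_diversity", "behavior_richness",
    "behavior_diversity", "acoustic_richness", "acoustic_diversity",
]


def _trait_frame(tree: Phylogeny, z: np.ndarray) -> pd.DataFrame:
    """Positive six-measure table from three latent (log-scale) traits,
    with balanced display covariates."""
    n = tree.n_tips
    cols = np.column_stack([z[:, 0], z[:, 0], z[:, 1], z[:, 1], z[:, 2], z[:, 2]])
    df = pd.DataFrame(np.exp(cols), index=tree.tip_labels,
                      columns=MEASURE_COLUMNS)
    df["display_height"] = [DISPLAY_HEIGHT_LEVELS[i % 3] for i in range(n)]
    df["proximity"] = [PROXIMITY_LEVELS[(i // 3) % 3] for i in range(n)]
    return df


def mpgls_type1_error(
    tree: Phylogeny,
    reps: int = 1000,
    seed: int = 0,
    level: float = 0.05,
    sigma2: float = 0.04,
) -> float:
    """Rejection rate of the behavioral-diversity slope in the acoustic
    mPGLS when the three signal traits evolve independently under BM."""
    rej = 0
    base = seed * 1_000_003 % (2**31)
    for r in range(reps):
        z = simulate_traits(tree, "BM", 3, 0.0, sigma2=sigma2,
                            seed=(base + r) % (2**31)).to_numpy()
        fit = mpgls_model(_trait_frame(tree, z), "acoustic_diversity", tree)
        rej += fit.pvalues["behavior_diversity"] < level
    return rej / reps


def mpgls_power(
    tree: Phylogeny,
    reps: int = 200,
    rho: float = 0.8,
    seed: int = 0,
    level: float = 0.05,
    sigma2: float = 0.04,
) -> float:
    """Fraction of replicates recovering a positive, significant
    behavioral-diversity slope when behavior and acoustic diversity
    evolve with cross-trait correlation ``rho`` under BM."""
    R = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, rho], [0.0, rho, 1.0]])
    hits = 0
    base = (seed * 1_000_003 + 7_777) % (2**31)
    for r in range(reps):
        z = simulate_traits(tree, "BM", 3, R, sigma2=sigma2,
                            seed=(base + r) % (2**31)).to_numpy()
        fit = mpgls_model(_trait_frame(tree, z), "acoustic_diversity", tree)
        hits += (fit.params["behavior_diversity"] > 0
                 and fit.pvalues["behavior_diversity"] < level)
    return hits / reps


def color_patch_recovery(
    ks=range(1, 9),
    seed: int = 0,
    image_size: tuple = (20, 20),
    separation_jnd: float = 8.0,
    noise_sd: float = 0.01,
) -> float:
    """Fraction of synthetic k-patch images whose measured color richness
    equals k after blur + JND clustering (patches > 2 thresholds apart,
    sub-threshold pixel noise)."""
    m = colormod.VisualModel()
    params = colormod.ClusterParams()
    correct = 0
    ks = list(ks)
    for i, k in enumerate(ks):
        rng = np.random.default_rng((seed * 97 + i) % (2**31))
        img, _ = gen_cone_catch_image(k, m, image_size, separation_jnd,
                                      noise_sd, rng)
        cm = colormod.cluster_image(colormod.median_blur(img, 1), m, params)
        correct += colormod.color_complexity(cm).richness == k
    return correct / len(ks)


def imputation_loo_rmse(
    tree: Phylogeny, reps: int = 100, seed: int = 0
) -> tuple[float, float]:
    """Leave-one-out RMSE of BM phylogenetic imputation vs the naive
    observed-mean predictor on BM-simulated traits."""
    e_phylo, e_naive = [], []
    base = (seed * 1_000_003 + 13) % (2**31)
    n = tree.n_tips
    for r in range(reps):
        z = simulate_traits(tree, "BM", 1, 0.0, seed=(base + r) % (2**31))
        y = z.iloc[:, 0].to_numpy()
        drop = r % n
        ymiss = y.astype(float).copy()
        ymiss[drop] = np.nan
        df = pd.DataFrame({"x": ymiss}, index=tree.tip_labels)
        out, _ = impute_missing(df, tree, candidate_models=("BM",))
        e_phylo.append((out["x"].iloc[drop] - y[drop]) ** 2)
        e_naive.append((np.nanmean(ymiss) - y[drop]) ** 2)
    return float(np.sqrt(np.mean(e_phylo))), float(np.sqrt(np.mean(e_naive)))


def aic_model_recovery(
    tree: Phylogeny, reps: int = 100, seed: int = 0, alpha_strength: float = 8.0
) -> float:
    """Fraction of OU-simulated replicates (decay ``alpha_strength`` /
    tree height) in which AIC prefers OU over BM."""
    alpha = alpha_strength / tree.height
    correct = 0
    base = (seed * 1_000_003 + 29) % (2**31)
    for r in range(reps):
        z = simulate_traits(tree, "OU", 1, alpha=alpha,
                            seed=(base + r) % (2**31))
        y = z.iloc[:, 0].to_numpy()
        fits = {m: fit_trait_model(y, tree, m) for m in ("BM", "OU")}
        correct += fits["OU"].aic < fits["BM"].aic
    return correct / reps
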