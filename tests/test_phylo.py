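"""OU-correlated PGLS, trait simulation and phylogenetic imputation."""

import numpy as np
import pandas as pd
import pytest

from signaldiv.phylo import (
    DISPLAY_HEIGHT_LEVELS,
    PROXIMITY_LEVELS,
    Phylogeny,
    composite_diversity,
    fit_trait_model,
    gls_fit,
    impute_missing,
    mpgls_model,
    ou_correlation,
    pgls_ou,
    simulate_traits,
)

# ---------------------------------------------------------------------------
# tree and OU correlation


def test_phylogeny_basics(tree5):
    assert tree5.n_tips == 5
    assert tree5.height == pytest.approx(5.0)
    D = tree5.distances
    assert np.allclose(D, D.T)
    assert np.all(np.diag(D) == 0)
    i, j = tree5.tip_labels.index("A"), tree5.tip_labels.index("B")
    assert D[i, j] == pytest.approx(4.0)
    k = tree5.tip_labels.index("C")
    assert D[i, k] == pytest.approx(10.0)


def test_bm_covariance_is_mrca_depth(tree5):
    V = tree5.bm_covariance
    lab = tree5.tip_labels
    a, b, c = lab.index("A"), lab.index("B"), lab.index("C")
    assert V[a, a] == pytest.approx(5.0)
    assert V[a, b] == pytest.approx(3.0)  # split 2 My ago on a 5 My tree
    assert V[a, c] == pytest.approx(0.0)  # root split


def test_non_ultrametric_rejected():
    with pytest.raises(ValueError, match="ultrametric"):
        Phylogeny.from_newick("((A:1,B:2):1,C:3);")
    with pytest.warns(UserWarning, match="ultrametric"):
        Phylogeny.from_newick("((A:1,B:2):1,C:3);", strict=False)


def test_ou_correlation_limits(tree5):
    C0 = ou_correlation(tree5, 0.0)
    assert np.allclose(C0, 1.0)
    Cinf = ou_correlation(tree5, 1e6)
    assert np.allclose(Cinf, np.eye(5), atol=1e-12)
    with pytest.raises(ValueError):
        ou_correlation(tree5, -0.1)


def test_ou_correlation_hand_computed():
    tree = Phylogeny.from_newick("((A:1,B:1):2,C:3);")
    C = ou_correlation(tree, 0.5)
    lab = tree.tip_labels
    a, b, c = lab.index("A"), lab.index("B"), lab.index("C")
    assert C[a, b] == pytest.approx(np.exp(-0.5 * 2.0))
    assert C[a, c] == pytest.approx(np.exp(-0.5 * 6.0))
    assert C[a, a] == 1.0


# ---------------------------------------------------------------------------
# GLS


def test_gls_identity_reproduces_ols():
    rng = np.random.default_rng(0)
    n = 30
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = X @ [1.0, 2.0, -0.5] + rng.normal(size=n)
    fit = gls_fit(y, X, np.eye(n))
    import statsmodels.api as sm

    ols = sm.OLS(y, X).fit()
    assert np.allclose(fit.params.values, ols.params, atol=1e-10)
    assert np.allclose(fit.bse.values, ols.bse, atol=1e-10)
    assert np.allclose(fit.pvalues.values, ols.pvalues, atol=1e-10)


@pytest.mark.parametrize("seed", range(25))
def test_gls_matches_dense_oracle(seed):
    """Cholesky-path GLS equals the explicit matrix-inverse estimator on
    random small instances to 1e-8."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    p = int(rng.integers(1, min(n - 1, 4) + 1))
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))]) if p > 1 \
        else np.ones((n, 1))
    y = rng.normal(size=n)
    A = rng.normal(size=(n, n))
    C = A @ A.T + n * np.eye(n)
    fit = gls_fit(y, X, C)
    Ci = np.linalg.inv(C)
    beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
    assert np.allclose(fit.params.values, beta, atol=1e-8)
    r = y - X @ beta
    s2 = (r @ Ci @ r) / (n - p)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ Ci @ X)))
    assert np.allclose(fit.bse.values, se, atol=1e-8)


def test_gls_exact_on_noiseless_data(tree5):
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(5), rng.normal(size=5)])
    beta = np.array([2.0, -1.5])
    y = X @ beta
    fit = gls_fit(y, X, ou_correlation(tree5, 0.1))
    assert np.allclose(fit.params.values, beta, atol=1e-10)


def test_gls_statsmodels_crosscheck(tree5):
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    C = ou_correlation(tree5, 0.2)
    X = np.column_stack([np.ones(5), rng.normal(size=5)])
    y = rng.normal(size=5)
    fit = gls_fit(y, X, C)
    smf = sm.GLS(y, X, sigma=C).fit()
    assert np.allclose(fit.params.values, smf.params, atol=1e-10)
    assert np.allclose(fit.bse.values, smf.bse, atol=1e-10)


def test_gls_rejects_bad_inputs(tree5):
    y = np.arange(5.0)
    with pytest.raises(ValueError, match="rank"):
        gls_fit(y, np.ones((5, 2)), np.eye(5))
    with pytest.raises(ValueError, match="positive definite"):
        gls_fit(y, np.column_stack([np.ones(5), y]), np.zeros((5, 5)))


def test_profile_alpha_is_local_maximum(tree40):
    """The returned alpha maximizes the profile likelihood against a local
    grid around it."""
    rng = np.random.default_rng(3)
    C = ou_correlation(tree40, 0.15)
    L = np.linalg.cholesky(C)
    X = np.column_stack([np.ones(40), rng.normal(size=40)])
    y = X @ [0.5, 1.0] + L @ rng.normal(size=40)
    fit = pgls_ou(y, X, tree40)
    from signaldiv.phylo import _profile_negll

    base = _profile_negll(fit.alpha, y, X, tree40)
    for f in (0.9, 0.95, 1.05, 1.1):
        assert _profile_negll(fit.alpha * f, y, X, tree40) >= base - 1e-9


# ---------------------------------------------------------------------------
# trait simulation


def test_simulate_traits_reproducible(tree40):
    a = simulate_traits(tree40, "BM", 3, 0.5, seed=42)
    b = simulate_traits(tree40, "BM", 3, 0.5, seed=42)
    pd.testing.assert_frame_equal(a, b)
    c = simulate_traits(tree40, "BM", 3, 0.5, seed=43)
    assert not a.equals(c)


def test_simulate_traits_cross_correlation(tree40):
    """Empirical cross-trait correlation of phylogenetic contrasts tracks
    the generating value."""
    L = np.linalg.cholesky(tree40.bm_covariance)
    Li = np.linalg.inv(L)
    for rho in (0.0, 0.8):
        rs = []
        for rep in range(60):
            z = simulate_traits(tree40, "BM", 2, rho, seed=1000 + rep)
            w = Li @ z.to_numpy()  # decorrelate the phylogeny
            rs.append(np.corrcoef(w[:, 0], w[:, 1])[0, 1])
        assert np.mean(rs) == pytest.approx(rho, abs=0.08)


def test_simulate_traits_ou_high_alpha_iid(tree40):
    """At a large OU decay rate tip values are nearly independent."""
    z = simulate_traits(tree40, "OU", 1, alpha=500.0 / tree40.height, seed=5)
    # neighbor pairs should show no more similarity than random pairs
    V = ou_correlation(tree40, 500.0 / tree40.height)
    off = V[~np.eye(40, dtype=bool)]
    assert np.max(off) < 0.05


def test_simulate_traits_invalid_correlation(tree40):
    R = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PSD
    with pytest.raises(ValueError):
        simulate_traits(tree40, "BM", cross_correlation=R)


# ---------------------------------------------------------------------------
# mPGLS design


def _toy_traits(tree, rng, effect=0.0):
    z = simulate_traits(tree, "BM", 6, 0.0, sigma2=0.04, seed=rng)
    df = pd.DataFrame(
        np.exp(z.to_numpy()),
        index=z.index,
        columns=[
            "color_richness", "color_diversity", "behavior_richness",
            "behavior_diversity", "acoustic_richness", "acoustic_diversity",
        ],
    )
    n = tree.n_tips
    df["display_height"] = [DISPLAY_HEIGHT_LEVELS[i % 3] for i in range(n)]
    df["proximity"] = [PROXIMITY_LEVELS[(i // 3) % 3] for i in range(n)]
    return df


def test_mpgls_design_reference_coding(tree40):
    rng = np.random.default_rng(7)
    df = _toy_traits(tree40, rng)
    fit = mpgls_model(df, "acoustic_diversity", tree40)
    terms = list(fit.params.index)
    assert terms == [
        "intercept", "color_diversity", "behavior_diversity",
        "height[understory]", "height[canopy]",
        "proximity[exploded_lek]", "proximity[lek]",
    ]


def test_mpgls_unknown_level_rejected(tree40):
    rng = np.random.default_rng(8)
    df = _toy_traits(tree40, rng)
    df.iloc[0, df.columns.get_loc("display_height")] = "treetop"
    with pytest.raises(ValueError, match="unknown"):
        mpgls_model(df, "acoustic_diversity", tree40)


def test_mpgls_recovers_planted_slope(tree40):
    """A strong planted dependence of acoustic on behavioral diversity is
    recovered with a positive, significant slope in most replicates."""
    hits = 0
    for rep in range(25):
        rng = np.random.default_rng(300 + rep)
        z = simulate_traits(tree40, "BM", 2, 0.0, sigma2=0.04, seed=rng)
        beh = z.iloc[:, 0]
        aco = 0.8 * beh + 0.3 * z.iloc[:, 1]
        df = _toy_traits(tree40, rng)
        df["behavior_diversity"] = np.exp(beh)
        df["acoustic_diversity"] = np.exp(aco)
        fit = mpgls_model(df, "acoustic_diversity", tree40)
        ok = (fit.params["behavior_diversity"] > 0
              and fit.pvalues["behavior_diversity"] < 0.05)
        hits += ok
    assert hits >= 20


# ---------------------------------------------------------------------------
# imputation


def test_star_tree_bm_imputation_is_observed_mean():
    """On a star phylogeny tips are exchangeable under BM, so the
    conditional expectation for a missing tip is exactly the observed
    mean."""
    n = 8
    nwk = "(" + ",".join(f"T{i}:1" for i in range(n)) + ");"
    star = Phylogeny.from_newick(nwk)
    y = np.array([1.0, 2.0, 4.0, 8.0, 3.0, 5.0, 7.0, np.nan])
    df = pd.DataFrame({"x": y}, index=star.tip_labels)
    out, report = impute_missing(df, star, candidate_models=("BM",))
    assert out.loc["T7", "x"] == pytest.approx(np.nanmean(y), rel=1e-10)


def test_zero_distance_duplicate_tip_imputed_exactly(tree40):
    """A missing tip at zero phylogenetic distance from an observed tip
    takes that tip's value exactly."""
    nwk = "((A:0.0,B:0.0):2,(C:1,D:1):1);"
    tr = Phylogeny.from_newick(nwk)
    df = pd.DataFrame({"x": [3.7, np.nan, 1.0, 2.0]},
                      index=["A", "B", "C", "D"]).loc[tr.tip_labels]
    out, _ = impute_missing(df, tr, candidate_models=("BM",))
    assert out.loc["B", "x"] == pytest.approx(3.7, abs=1e-8)


def test_imputation_beats_naive_mean(tree40):
    """Leave-one-out RMSE of BM imputation on BM-simulated traits is below
    the naive observed-mean RMSE."""
    err_phylo, err_naive = [], []
    for rep in range(30):
        z = simulate_traits(tree40, "BM", 1, 0.0, seed=2000 + rep)
        y = z.iloc[:, 0].to_numpy()
        drop = rep % 40
        ymiss = y.astype(float).copy()
        ymiss[drop] = np.nan
        df = pd.DataFrame({"x": ymiss}, index=tree40.tip_labels)
        out, _ = impute_missing(df, tree40, candidate_models=("BM",))
        err_phylo.append((out["x"].iloc[drop] - y[drop]) ** 2)
        err_naive.append((np.nanmean(ymiss) - y[drop]) ** 2)
    assert np.sqrt(np.mean(err_phylo)) < np.sqrt(np.mean(err_naive))


def test_aic_model_selection_recovers_generator(tree40):
    """AIC comparison across BM and OU picks the generating model in the
    majority of replicates (strong OU decay, 40 tips)."""
    alpha = 8.0 / tree40.height
    correct = 0
    reps = 30
    for rep in range(reps):
        z = simulate_traits(tree40, "OU", 1, alpha=alpha, seed=3000 + rep)
        fits = {m: fit_trait_model(z.iloc[:, 0].to_numpy(), tree40, m)
                for m in ("BM", "OU")}
        if fits["OU"].aic < fits["BM"].aic:
            correct += 1
    assert correct > reps / 2


def test_imputation_report_shape(tree40):
    z = simulate_traits(tree40, "BM", 2, 0.0, seed=9)
    df = pd.DataFrame(z.to_numpy(), index=tree40.tip_labels, columns=["a", "b"])
    df.iloc[0, 0] = np.nan
    out, report = impute_missing(df, tree40)
    assert set(report["model"]) == {"BM", "OU", "EB", "lambda"}
    assert report.groupby("trait")["selected"].sum().eq(1).all()
    assert not out[["a", "b"]].isna().any().any()
    assert out.loc[tree40.tip_labels[0], "a_imputed"]


def test_all_missing_trait_fails(tree40):
    df = pd.DataFrame({"x": np.full(40, np.nan)}, index=tree40.tip_labels)
    with pytest.raises(ValueError, match="observed"):
        impute_missing(df, tree40)


# ---------------------------------------------------------------------------
# invariances and composite


def test_tip_permutation_invariance(tree40):
    rng = np.random.default_rng(10)
    df = _toy_traits(tree40, rng)
    fit1 = mpgls_model(df, "color_diversity", tree40)
    fit2 = mpgls_model(df.sample(frac=1.0, random_state=1), "color_diversity",
                       tree40)
    assert np.allclose(fit1.params.values, fit2.params.values, atol=1e-9)
    assert fit1.alpha == pytest.approx(fit2.alpha, rel=1e-6)


def test_composite_diversity_arithmetic():
    df = pd.DataFrame(
        {
            "color_diversity": [1.0, 2.0, 3.0],
            "behavior_diversity": [4.0, 4.0, 8.0],
            "acoustic_diversity": [2.0, 6.0, 10.0],
        },
        index=["X", "Y", "Z"],
    )
    out = composite_diversity(df)
    assert out.loc["Z", "composite"] == pytest.approx(3.0)
    assert out.loc["X", "composite"] == pytest.approx(0.0)
    assert out.loc["Y", "composite"] == pytest.approx(0.5 + 0.0 + 0.5)


def test_composite_constant_column_warns():
    df = pd.DataFrame(
        {
            "color_diversity": [2.0, 2.0],
            "behavior_diversity": [1.0, 3.0],
            "acoustic_diversity": [1.0, 2.0],
        }
    )
    with pytest.warns(UserWarning, match="constant"):
        out = composite_diversity(df)
    assert (out["color_diversity_scaled"] == 0).all()
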