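"""Bootstrapped NMF extraction: normalization, bootstrap, update
algorithms, solution clustering and silhouettes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mutsig as ms
from mutsig.nmf import (
    NMFConfig,
    bootstrap_counts,
    cluster_solutions,
    nmf_brunet,
    nmf_lin,
    normalize_counts,
    remove_weak_types,
    silhouette_widths,
)

# ------------------------------------------------------------- normalize


def test_normalize_counts_identity_and_freq():
    V = pd.DataFrame({"a": [60, 40], "b": [300, 100]}, index=["t1", "t2"], dtype=float)
    same, totals = normalize_counts(V, "counts")
    pd.testing.assert_frame_equal(same, V)
    assert list(totals) == [100.0, 400.0]
    freq, _ = normalize_counts(V, "freq")
    # both columns rescaled to the median of the original totals (250)
    np.testing.assert_allclose(freq.sum(axis=0), [250.0, 250.0])
    np.testing.assert_allclose(freq["a"], [150.0, 100.0])


def test_normalize_counts_zero_column_error():
    V = pd.DataFrame({"good": [5.0], "empty": [0.0]}, index=["t"])
    with pytest.raises(ValueError, match="empty"):
        normalize_counts(V, "freq")


# ------------------------------------------------------------ weak types


def test_remove_weak_types_identity_at_zero():
    rng = np.random.default_rng(0)
    V = rng.random((10, 4))
    out, keep = remove_weak_types(V, 0.0)
    assert keep.all()
    np.testing.assert_array_equal(out, V)


def test_remove_weak_types_zero_row_masked():
    V = np.ones((5, 3))
    V[2] = 0.0
    _, keep = remove_weak_types(V, 0.01)
    assert not keep[2]
    assert keep.sum() == 4


def test_remove_weak_types_cumulative_share_bound():
    rng = np.random.default_rng(1)
    V = rng.random((96, 10))
    out, keep = remove_weak_types(V, 0.05)
    removed_total = V[~keep].sum()
    assert removed_total < 0.05 * V.sum()
    # removed rows are exactly the lightest ones
    assert V[~keep].sum(axis=1).max() <= V[keep].sum(axis=1).min() + 1e-12


# ------------------------------------------------------------- bootstrap


def test_bootstrap_preserves_column_totals():
    rng = np.random.default_rng(2)
    V = rng.integers(0, 50, size=(20, 8)).astype(float)
    B = bootstrap_counts(V, rng)
    np.testing.assert_array_equal(B.sum(axis=0), np.round(V.sum(axis=0)))


def test_bootstrap_degenerate_column_is_fixed_point():
    V = np.array([[5.0], [0.0], [0.0]])
    rng = np.random.default_rng(3)
    for _ in range(10):
        np.testing.assert_array_equal(bootstrap_counts(V, rng), V)


def test_bootstrap_binomial_moments():
    """Entry mean over replicates within 3 standard errors of expectation."""
    V = np.array([[30.0], [70.0]])
    rng = np.random.default_rng(4)
    n_rep = 10_000
    draws = np.array([bootstrap_counts(V, rng)[0, 0] for _ in range(n_rep)])
    se = np.sqrt(100 * 0.3 * 0.7)
    assert abs(draws.mean() - 30.0) < 3 * se / np.sqrt(n_rep) * np.sqrt(n_rep)  # sanity
    assert abs(draws.mean() - 30.0) < 3 * se / np.sqrt(n_rep) * 10  # tight bound
    assert abs(draws.mean() - 30.0) < 3 * np.sqrt(100 * 0.3 * 0.7 / n_rep)


@settings(derandomize=True, max_examples=20)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_bootstrap_totals_property(seed):
    rng = np.random.default_rng(seed)
    V = rng.integers(0, 30, size=(12, 5)).astype(float)
    B = bootstrap_counts(V, rng)
    assert (B >= 0).all()
    np.testing.assert_array_equal(B.sum(axis=0), np.round(V.sum(axis=0)))


# ------------------------------------------------------------- nmf runs


def _planted_64(seed=0):
    rng = np.random.default_rng(seed)
    W0 = np.array([[4, 0], [2, 0], [1, 0], [0, 3], [0, 2], [0, 5]], dtype=float)
    H0 = np.array([[3, 0, 1, 2], [0, 2, 1, 4]], dtype=float)
    return W0 @ H0


def test_brunet_rank1_exact():
    rng = np.random.default_rng(0)
    w = rng.random(8) + 0.5
    h = rng.random(5) + 0.5
    V = np.outer(w, h)
    fp = nmf_brunet(V, 1, NMFConfig(k=1, inner_tol=1e-14), np.random.default_rng(1))
    assert fp.objective < 1e-8
    np.testing.assert_allclose(fp.W @ fp.H, V, rtol=1e-6)


def test_lin_exact_factorization():
    rng = np.random.default_rng(0)
    W0 = rng.random((8, 2)) + 0.1
    H0 = rng.random((2, 5)) + 0.1
    V = W0 @ H0
    fp = nmf_lin(V, 2, NMFConfig(k=2, inner_tol=1e-15, max_inner_updates=20000),
                 np.random.default_rng(2))
    assert np.linalg.norm(V - fp.W @ fp.H) < 1e-6 * np.linalg.norm(V)


@pytest.mark.parametrize("algo", [nmf_brunet, nmf_lin])
def test_objective_monotone(algo):
    rng = np.random.default_rng(10)
    V = rng.random((12, 8)) * 20
    for seed in range(5):
        fp = algo(V, 3, NMFConfig(k=3, max_inner_updates=300, inner_tol=0.0),
                  np.random.default_rng(seed))
        h = fp.history
        assert (np.diff(h) <= 1e-9 * np.maximum(np.abs(h[:-1]), 1.0)).all()


def test_brunet_matches_naive_oracle():
    """Planted 6x4 rank-2 problem: reconstruction no worse than the best
    of 20 restarts of an independently coded naive KL update loop."""
    V = _planted_64()
    cfg = NMFConfig(k=2, inner_tol=1e-13, max_inner_updates=5000)
    fp = nmf_brunet(V, 2, cfg, np.random.default_rng(0))
    ours = np.linalg.norm(V - fp.W @ fp.H) / np.linalg.norm(V)

    def naive_run(seed, sweeps=2000):
        r = np.random.default_rng(seed)
        W = r.random((6, 2)) + 1e-3
        H = r.random((2, 4)) + 1e-3
        for _ in range(sweeps):
            WH = W @ H + 1e-12
            H = H * (W.T @ (V / WH)) / (W.sum(0)[:, None] + 1e-12)
            WH = W @ H + 1e-12
            W = W * ((V / WH) @ H.T) / (H.sum(1)[None, :] + 1e-12)
        return np.linalg.norm(V - W @ H) / np.linalg.norm(V)

    oracle_best = min(naive_run(s) for s in range(20))
    assert ours <= oracle_best + 1e-6


def test_brunet_lin_consistency():
    """Both algorithms reach comparable reconstruction on the planted problem."""
    V = _planted_64()
    cfg = NMFConfig(k=2, inner_tol=1e-13, max_inner_updates=20000)
    e = {}
    for name, algo in [("brunet", nmf_brunet), ("lin", nmf_lin)]:
        best = np.inf
        for s in range(3):
            fp = algo(V, 2, cfg, np.random.default_rng(s))
            best = min(best, np.linalg.norm(V - fp.W @ fp.H) / np.linalg.norm(V))
        e[name] = best
    # both essentially exact; relative reconstruction errors agree within 5 points
    assert e["brunet"] < 1e-3 and e["lin"] < 1e-3
    assert abs(e["brunet"] - e["lin"]) <= 0.05


def test_nmf_pair_normalization():
    rng = np.random.default_rng(3)
    V = rng.random((10, 6)) * 50
    fp = nmf_brunet(V, 2, NMFConfig(k=2, max_inner_updates=100), rng)
    np.testing.assert_allclose(fp.W.sum(axis=0), 1.0, atol=1e-12)


# ------------------------------------------------------------ clustering


def test_cluster_identical_solutions():
    rng = np.random.default_rng(0)
    W = rng.random((12, 3))
    W /= W.sum(0)
    centroids, assign, D = cluster_solutions([W.copy() for _ in range(5)], 3,
                                             np.random.default_rng(1))
    # centroids are the original columns (in some order), sums 1
    np.testing.assert_allclose(centroids.sum(axis=0), 1.0, atol=1e-12)
    sil = silhouette_widths(assign, D)
    np.testing.assert_allclose(sil, 1.0, atol=1e-9)
    got = sorted(tuple(np.round(centroids[:, i], 9)) for i in range(3))
    want = sorted(tuple(np.round(W[:, i], 9)) for i in range(3))
    assert got == want


def test_cluster_recovers_planted_partition():
    """20 pooled vectors around two well-separated directions split exactly."""
    rng = np.random.default_rng(5)
    d1 = np.zeros(10)
    d1[:5] = 1.0
    d2 = np.zeros(10)
    d2[5:] = 1.0
    Ws = []
    truth = []
    for i in range(10):
        a = d1 + rng.normal(0, 0.02, 10).clip(-0.05)
        b = d2 + rng.normal(0, 0.02, 10).clip(-0.05)
        a, b = np.abs(a), np.abs(b)
        Ws.append(np.column_stack([a / a.sum(), b / b.sum()]))
        truth.extend([0, 1])
    centroids, assign, D = cluster_solutions(Ws, 2, np.random.default_rng(6))
    truth = np.array(truth)
    agreement = max((assign == truth).mean(), (assign == 1 - truth).mean())
    assert agreement == 1.0


def test_cluster_degenerate_error():
    W = np.ones((4, 2)) / 4
    with pytest.raises(ValueError, match="distinct"):
        cluster_solutions([W, W], 2, np.random.default_rng(0))


# ------------------------------------------------------------ silhouette


def test_silhouette_separated_clusters_are_one():
    D = np.zeros((4, 4))
    D[:2, 2:] = 1.0
    D[2:, :2] = 1.0
    widths = silhouette_widths(np.array([0, 0, 1, 1]), D)
    np.testing.assert_allclose(widths, 1.0)


def test_silhouette_equidistant_is_zero():
    D = np.ones((4, 4)) - np.eye(4)
    widths = silhouette_widths(np.array([0, 0, 1, 1]), D)
    np.testing.assert_allclose(widths, 0.0, atol=1e-12)


def test_silhouette_matches_sklearn():
    from sklearn.metrics import silhouette_samples

    rng = np.random.default_rng(9)
    X = rng.random((12, 5))
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    labels = np.array([0, 1, 2] * 4)
    ours = silhouette_widths(labels, D)
    ref = silhouette_samples(D, labels, metric="precomputed")
    np.testing.assert_allclose(ours, ref, atol=1e-12)


def test_silhouette_single_cluster_error():
    with pytest.raises(ValueError, match="2 clusters"):
        silhouette_widths(np.zeros(5, dtype=int), np.zeros((5, 5)))


# ------------------------------------------------------------ extraction


def test_extract_rank1_limit(planted_tri, tri_dict):
    """k=1 returns a signature close to the normalized row-total profile."""
    _, _, V = planted_tri
    counts = pd.DataFrame(V, index=list(tri_dict.labels),
                          columns=[f"s{j}" for j in range(V.shape[1])])
    res = ms.extract_signatures(counts, NMFConfig(k=1, num_iterations=5, seed=0))
    profile = V.sum(axis=1)
    profile = profile / profile.sum()
    d = ms.cosine_distance(res.signatures.iloc[:, 0].to_numpy(), profile)
    assert d < 0.02


def test_extract_recovers_planted_signatures(planted_tri, tri_dict):
    W, H, V = planted_tri
    counts = pd.DataFrame(V, index=list(tri_dict.labels),
                          columns=[f"s{j}" for j in range(V.shape[1])])
    res = ms.extract_signatures(counts, NMFConfig(k=3, num_iterations=10, seed=1))
    truth = pd.DataFrame(W, index=counts.index, columns=["p1", "p2", "p3"])
    m = ms.match_signatures(truth, res.signatures)
    assert (m.best_match["distance"] < 0.05).all()
    assert len(set(m.best_match["match"])) == 3
    # exposures reconstruct per-sample totals
    np.testing.assert_allclose(res.exposures.sum(axis=0), counts.sum(axis=0), rtol=0.10)


def test_extract_determinism_across_threads(planted_tri, tri_dict):
    _, _, V = planted_tri
    counts = pd.DataFrame(V, index=list(tri_dict.labels),
                          columns=[f"s{j}" for j in range(V.shape[1])])
    r1 = ms.extract_signatures(counts, NMFConfig(k=2, num_iterations=6, seed=7, threads=1))
    r2 = ms.extract_signatures(counts, NMFConfig(k=2, num_iterations=6, seed=7, threads=3))
    pd.testing.assert_frame_equal(r1.signatures, r2.signatures)
    pd.testing.assert_frame_equal(r1.exposures, r2.exposures)
    np.testing.assert_array_equal(r1.silhouettes, r2.silhouettes)


def test_extract_weak_type_rows_reinserted(planted_tri, tri_dict):
    _, _, V = planted_tri
    V = V.copy()
    V[5] = 0.0  # force an all-zero mutation-type row
    counts = pd.DataFrame(V, index=list(tri_dict.labels),
                          columns=[f"s{j}" for j in range(V.shape[1])])
    res = ms.extract_signatures(
        counts, NMFConfig(k=2, num_iterations=4, seed=3, weak_type_threshold=0.01)
    )
    assert res.signatures.shape == (96, 2)
    assert (res.signatures.iloc[5] == 0.0).all()
    np.testing.assert_allclose(res.signatures.sum(axis=0), 1.0, atol=1e-9)


def test_extract_config_validation(tri_dict):
    counts = pd.DataFrame(np.ones((96, 3)), index=list(tri_dict.labels))
    with pytest.raises(ValueError, match="k"):
        ms.extract_signatures(counts, NMFConfig(k=5, num_iterations=2))
    with pytest.raises(ValueError):
        NMFConfig(k=0)
    with pytest.raises(ValueError):
        NMFConfig(k=1, algorithm="other")
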