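"""De novo signature extraction by bootstrapped non-negative matrix
factorization.

The count matrix V (m mutation types x n samples) is approximately
factorized as V ~ W H, where the k columns of W are mutational
signatures (probability vectors over mutation types) and the rows of H
are the corresponding per-sample activities. A single NMF run is not
reliable: the objective is non-convex and the data are noisy. The
extraction therefore repeats, many times, a multinomial bootstrap of
each sample's counts followed by an NMF run, pools all per-run signature
columns, clusters them into k groups under cosine distance, and reports
the cluster centroids as the extracted signatures. Silhouette widths of
the clustered solutions measure how reproducible each signature is
across bootstrap replicates.

Two multiplicative-update algorithms are provided: Brunet's updates for
the Kullback-Leibler divergence D(V || WH), and Lin's modified updates
for the Frobenius objective, which shift the denominators to avoid
zero-locking and guarantee convergence. Both decrease their objective at
every sweep.

Samples with extreme mutation burden (hyper-mutators) dominate the raw
objective; the optional ``freq`` normalization rescales every sample to
a common total (the rounded median of the original totals) so all
samples carry equal weight while the matrix stays on a count-like scale
for the multinomial bootstrap.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .deconvolution import fcnnls

_EPS = float(np.finfo(float).eps)


@dataclass
class NMFConfig:
    """Parameters of one extraction run.

    Attributes
    ----------
    k : number of signatures to extract.
    num_iterations : bootstrap + NMF repetitions pooled before
        clustering. Production analyses use several hundred; the
        default of 100 is a desk-scale compromise.
    algorithm : ``brunet`` (KL divergence) or ``lin`` (Frobenius).
    approach : ``counts`` (raw) or ``freq`` (sample-wise normalization).
    weak_type_threshold : fraction of the grand total below which the
        lightest mutation-type rows are set aside before factorization
        (0 disables the step; removed rows are re-inserted as zeros).
    inner_tol : relative objective-change convergence tolerance of one
        NMF run.
    max_inner_updates : cap on multiplicative-update sweeps per run.
    seed : master RNG seed; per-iteration substreams are spawned from it
        so results do not depend on execution order or thread count.
    threads : worker threads for the bootstrap/NMF repetitions.
    """

    k: int
    num_iterations: int = 100
    algorithm: str = "brunet"
    approach: str = "counts"
    weak_type_threshold: float = 0.0
    inner_tol: float = 1e-9
    max_inner_updates: int = 10_000
    seed: int | None = None
    eps: float = _EPS
    threads: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.num_iterations < 1:
            raise ValueError("num_iterations must be >= 1")
        if self.algorithm not in ("brunet", "lin"):
            raise ValueError(f"unknown algorithm: {self.algorithm!r}")
        if self.approach not in ("counts", "freq"):
            raise ValueError(f"unknown approach: {self.approach!r}")
        if not (0.0 <= self.weak_type_threshold < 1.0):
            raise ValueError("weak_type_threshold must be in [0, 1)")


@dataclass
class FactorPair:
    """One NMF solution, rescaled so W columns sum to 1."""

    W: np.ndarray
    H: np.ndarray
    objective: float
    history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ExtractionResult:
    """Clustered output of a full bootstrapped extraction."""

    signatures: pd.DataFrame  # m x k, columns sum to 1
    exposures: pd.DataFrame  # k x n, mutation-count units
    silhouettes: np.ndarray  # one width per clustered solution vector
    assignments: np.ndarray  # cluster id per solution vector
    config: NMFConfig


def normalize_counts(V: pd.DataFrame, approach: str = "counts") -> tuple[pd.DataFrame, pd.Series]:
    """Optionally rescale every sample to a common mutation total.

    ``counts`` returns V unchanged; ``freq`` divides each column by its
    total and multiplies by the rounded median of the original totals,
    equalizing sample weights while keeping count-like magnitudes. The
    original totals are returned for downstream back-scaling.
    """
    totals = V.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    if approach == "counts":
        return V.copy(), totals
    if approach == "freq":
        const = float(np.round(np.median(totals.to_numpy())))
        return V / totals * const, totals
    raise ValueError(f"unknown approach: {approach!r}")


def remove_weak_types(V: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Set aside the lightest mutation-type rows.

    Rows are sorted ascending by total and removed while their
    cumulative share of the grand total stays below ``threshold``. The
    boolean mask of kept rows is returned so callers can re-insert the
    removed rows as zeros.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    V = np.asarray(V, dtype=float)
    m = V.shape[0]
    keep = np.ones(m, dtype=bool)
    if threshold == 0.0:
        return V, keep
    totals = V.sum(axis=1)
    grand = totals.sum()
    order = np.argsort(totals, kind="stable")
    cum = 0.0
    for i in order:
        cum += totals[i]
        if grand > 0 and cum / grand < threshold:
            keep[i] = False
        else:
            break
    return V[keep], keep


def bootstrap_counts(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multinomial bootstrap of each sample's mutation-type counts.

    Column j is one draw from Multinomial(N_j, p_j) with N_j the rounded
    column total and p_j the column's empirical type frequencies; column
    totals are therefore preserved exactly. Zero columns map to zero.
    """
    V = np.asarray(V, dtype=float)
    out = np.zeros_like(V)
    totals = V.sum(axis=0)
    for j in range(V.shape[1]):
        if totals[j] <= 0:
            continue
        n = int(np.round(totals[j]))
        out[:, j] = rng.multinomial(n, V[:, j] / totals[j])
    return out


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    pos = V > 0
    return float(np.sum(V[pos] * np.log(V[pos] / WH[pos])) - V.sum() + WH.sum())


def _normalize_pair(W: np.ndarray, H: np.ndarray, objective: float, history) -> FactorPair:
    scale = W.sum(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return FactorPair(W=W / scale, H=H * scale[:, None], objective=objective,
                      history=np.asarray(history))


def nmf_brunet(V: np.ndarray, k: int, config: NMFConfig, rng: np.random.Generator) -> FactorPair:
    """Multiplicative-update NMF for the KL divergence D(V || WH).

    W and H start from uniform positive random values; each sweep
    updates H then W with the standard eps-guarded Brunet updates. The
    run stops when the relative change of the divergence falls below
    ``config.inner_tol`` or after ``config.max_inner_updates`` sweeps.
    The divergence is non-increasing across sweeps.
    """
    V = np.asarray(V, dtype=float)
    m, n = V.shape
    eps = config.eps
    W = rng.uniform(eps, 1.0, size=(m, k))
    H = rng.uniform(eps, 1.0, size=(k, n))
    history = []
    prev = np.inf
    for sweep in range(config.max_inner_updates):
        WH = np.maximum(W @ H, eps)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
        WH = np.maximum(W @ H, eps)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
        obj = _kl_divergence(V, W @ H)
        if not np.isfinite(obj):
            raise FloatingPointError(f"non-finite KL divergence at sweep {sweep}")
        history.append(obj)
        if np.isfinite(prev) and abs(prev - obj) <= config.inner_tol * max(abs(prev), eps):
            break
        prev = obj
    return _normalize_pair(W, H, history[-1], history)


def nmf_lin(V: np.ndarray, k: int, config: NMFConfig, rng: np.random.Generator) -> FactorPair:
    """Lin's modified multiplicative updates for 1/2 ||V - WH||_F^2.

    Denominators are shifted by a small delta and variables at zero with
    a negative gradient are lifted to a positivity floor sigma before
    the step, which removes the zero-locking of the classical updates
    and guarantees a monotone decrease to a stationary point. Stopping
    matches :func:`nmf_brunet`.
    """
    V = np.asarray(V, dtype=float)
    m, n = V.shape
    eps = config.eps
    sigma = 1e-9
    delta = 1e-12
    W = rng.uniform(eps, 1.0, size=(m, k))
    H = rng.uniform(eps, 1.0, size=(k, n))
    history = []
    prev = np.inf
    for sweep in range(config.max_inner_updates):
        WtW = W.T @ W
        grad_H = WtW @ H - W.T @ V
        Hbar = np.where(grad_H >= 0, H, np.maximum(H, sigma))
        H = H - Hbar / (WtW @ Hbar + delta) * grad_H
        HHt = H @ H.T
        grad_W = W @ HHt - V @ H.T
        Wbar = np.where(grad_W >= 0, W, np.maximum(W, sigma))
        W = W - Wbar / (Wbar @ HHt + delta) * grad_W
        obj = 0.5 * float(np.linalg.norm(V - W @ H) ** 2)
        if not np.isfinite(obj):
            raise FloatingPointError(f"non-finite objective at sweep {sweep}")
        history.append(obj)
        if np.isfinite(prev) and abs(prev - obj) <= config.inner_tol * max(abs(prev), eps):
            break
        prev = obj
    return _normalize_pair(W, H, history[-1], history)


_ALGORITHMS = {"brunet": nmf_brunet, "lin": nmf_lin}


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    return X / np.where(norms > 0, norms, 1.0)


def cluster_solutions(
    W_list: list[np.ndarray],
    k: int,
    rng: np.random.Generator | None = None,
    n_restarts: int = 10,
    max_rounds: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition pooled per-iteration signature columns into k clusters.

    All columns of all bootstrap solutions are pooled and clustered by
    k-means-style iteration under cosine distance: the first restart is
    seeded with the columns of the first iteration, the remaining
    restarts with random pooled vectors, and the best restart by
    within-cluster cosine-distance sum wins. Centroids are the means of
    member columns renormalized to sum 1, ordered by descending cluster
    size (ties by first occurrence).

    Returns ``(centroids m x k, assignments, pooled distance matrix)``.
    """
    if len(W_list) < 2:
        raise ValueError("clustering requires at least 2 bootstrap iterations")
    if rng is None:
        rng = np.random.default_rng()
    pooled = np.hstack(W_list).T  # (T*k) x m
    T = pooled.shape[0]
    U = _unit_rows(pooled)
    if np.unique(np.round(U, 12), axis=0).shape[0] < k:
        raise ValueError("fewer distinct solution vectors than clusters requested")
    D = np.clip(1.0 - U @ U.T, 0.0, None)
    np.fill_diagonal(D, 0.0)

    best_assign = None
    best_score = np.inf
    for restart in range(n_restarts):
        if restart == 0:
            idx = np.arange(k)
        else:
            idx = rng.choice(T, size=k, replace=False)
        centers = U[idx].copy()
        assign = np.full(T, -1)
        for _ in range(max_rounds):
            sims = U @ centers.T
            new_assign = sims.argmax(axis=1)
            for c in range(k):  # re-seed empty clusters with the worst-fit point
                if not (new_assign == c).any():
                    new_assign[sims.max(axis=1).argmin()] = c
            if (new_assign == assign).all():
                break
            assign = new_assign
            for c in range(k):
                members = U[assign == c]
                centers[c] = _unit_rows(members.mean(axis=0)[None, :])[0]
        score = float(np.sum(1.0 - (U * centers[assign]).sum(axis=1)))
        if score < best_score - 1e-12:
            best_score = score
            best_assign = assign.copy()

    # order clusters by descending membership, stable in first occurrence
    sizes = np.bincount(best_assign, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    assignments = relabel[best_assign]
    centroids = np.zeros((pooled.shape[1], k))
    for c in range(k):
        members = pooled[assignments == c]
        cen = members.mean(axis=0)
        s = cen.sum()
        centroids[:, c] = cen / s if s > 0 else cen
    return centroids, assignments, D


def silhouette_widths(assignments: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Classical silhouette widths from a precomputed distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a the mean intra-cluster
    distance (self excluded) and b the smallest mean distance to another
    cluster. Members of singleton clusters get 0 by convention.
    """
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if labels.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = len(assignments)
    widths = np.zeros(n)
    for i in range(n):
        own = assignments[i]
        same = assignments == own
        if same.sum() == 1:
            widths[i] = 0.0
            continue
        a = D[i, same].sum() / (same.sum() - 1)
        b = min(D[i, assignments == other].mean() for other in labels if other != own)
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return widths


def extract_signatures(counts: pd.DataFrame, config: NMFConfig) -> ExtractionResult:
    """Full bootstrapped extraction pipeline.

    normalize -> set aside weak mutation-type rows -> repeat
    ``num_iterations`` x (multinomial bootstrap -> NMF) -> cluster the
    pooled signature columns -> silhouette assessment -> re-insert weak
    rows as zeros -> recompute final exposures against the ORIGINAL
    (un-normalized, un-bootstrapped) counts so activities come out in
    mutation units. Per-iteration RNG substreams are spawned from the
    master seed, so the result is reproducible at any thread count.
    """
    zero_cols = counts.columns[counts.sum(axis=0) == 0]
    if len(zero_cols):
        warnings.warn(f"dropping all-zero sample column(s): {list(zero_cols)}")
        counts = counts.drop(columns=zero_cols)
    m, n = counts.shape
    if config.k > min(m, n):
        raise ValueError(f"k={config.k} exceeds min(m, n)={min(m, n)}")

    Vn, _totals = normalize_counts(counts, config.approach)
    Vr, keep = remove_weak_types(Vn.to_numpy(dtype=float), config.weak_type_threshold)
    if keep.sum() <= config.k:
        raise ValueError(
            f"weak_type_threshold={config.weak_type_threshold} leaves "
            f"{int(keep.sum())} rows for k={config.k} signatures"
        )

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.num_iterations + 1)
    algo = _ALGORITHMS[config.algorithm]

    def one_iteration(i: int) -> np.ndarray:
        rng = np.random.default_rng(children[i])
        Vb = bootstrap_counts(Vr, rng)
        return algo(Vb, config.k, config, rng).W

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            W_list = list(pool.map(one_iteration, range(config.num_iterations)))
    else:
        W_list = [one_iteration(i) for i in range(config.num_iterations)]

    cluster_rng = np.random.default_rng(children[-1])
    centroids, assignments, D = cluster_solutions(W_list, config.k, cluster_rng)
    sil = silhouette_widths(assignments, D) if config.k > 1 else np.ones(len(assignments))

    W_full = np.zeros((m, config.k))
    W_full[keep] = centroids
    sig_names = [f"signature_{i + 1:02d}" for i in range(config.k)]
    signatures = pd.DataFrame(W_full, index=counts.index, columns=sig_names)

    res = fcnnls(W_full, counts.to_numpy(dtype=float))
    exposures = pd.DataFrame(res.exposures, index=sig_names, columns=counts.columns)
    return ExtractionResult(
        signatures=signatures,
        exposures=exposures,
        silhouettes=sil,
        assignments=assignments,
        config=replace(config),
    )
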