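"""Signature matching and downstream activity analysis.

Signatures are compared by cosine distance (0 = identical direction,
~1 = maximally dissimilar for non-negative profiles). Relative
activities are per-sample exposures normalized to sum 1. Because
relative activities of k signatures are constrained to the simplex,
negative pairwise correlations arise by construction; the Monte-Carlo
null quantifies how negative they are expected to be, by simulating
activity matrices whose per-signature mean and standard deviation track
the observed ones and recording the minimum pairwise Spearman
coefficient of each simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class MatchResult:
    """Cosine-distance comparison of two signature sets."""

    distance_matrix: pd.DataFrame  # |S1| x |S2|
    best_match: pd.DataFrame  # per S1 signature: best S2 match + distance
    threshold: float

    @property
    def matched(self) -> pd.DataFrame:
        """Rows of ``best_match`` whose distance is below the threshold."""
        return self.best_match[self.best_match["distance"] < self.threshold]


@dataclass
class CorrelationNullResult:
    """Observed pairwise Spearman correlations against a simulated null."""

    observed: pd.DataFrame  # k x k Spearman matrix
    observed_min: float
    null_min_distribution: np.ndarray  # one minimum per simulation
    p_value: float  # fraction of simulated minima <= observed minimum


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cos(angle) between two profiles; 0 means identical direction."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("profiles have different lengths")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - (a @ b) / (na * nb))


def match_signatures(
    S1: pd.DataFrame, S2: pd.DataFrame, threshold: float = 0.2
) -> MatchResult:
    """All-pairs cosine distances between two signature sets.

    Rows (mutation types) are aligned by label; a mismatch in the label
    sets is an error. For every signature in ``S1`` the closest ``S2``
    signature is reported; a match is called when its distance is below
    ``threshold``.
    """
    missing = [l for l in S1.index if l not in S2.index]
    extra = [l for l in S2.index if l not in S1.index]
    if missing or extra:
        raise ValueError(
            f"row labels do not match: only in S1 {missing[:5]}, only in S2 {extra[:5]}"
        )
    S2a = S2.loc[S1.index]
    A = S1.to_numpy(dtype=float)
    B = S2a.to_numpy(dtype=float)
    An = A / np.linalg.norm(A, axis=0, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    D = np.clip(1.0 - An.T @ Bn, 0.0, None)
    dist = pd.DataFrame(D, index=S1.columns, columns=S2.columns)
    best_idx = D.argmin(axis=1)
    best = pd.DataFrame(
        {
            "match": [S2.columns[j] for j in best_idx],
            "distance": D[np.arange(D.shape[0]), best_idx],
        },
        index=S1.columns,
    )
    return MatchResult(distance_matrix=dist, best_match=best, threshold=threshold)


def relative_exposures(H: pd.DataFrame) -> pd.DataFrame:
    """Activities normalized by each sample's total mutation count."""
    totals = H.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return H / totals


def _pairwise_spearman(X: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix across the rows of X (mid-rank ties)."""
    ranks = rankdata(X, axis=1)
    return np.corrcoef(ranks)


def _min_offdiag(C: np.ndarray) -> float:
    k = C.shape[0]
    mask = ~np.eye(k, dtype=bool)
    return float(C[mask].min())


def mc_correlation_null(
    relH: pd.DataFrame | np.ndarray,
    nsim: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> CorrelationNullResult:
    """Monte-Carlo null for the minimum pairwise activity correlation.

    Each simulation draws, for every signature, n relative activities
    from a normal distribution with that signature's observed mean and
    standard deviation, truncates at zero, renormalizes each sample
    (column) to sum 1, and records the minimum pairwise Spearman
    coefficient. The p-value is the fraction of simulated minima at or
    below the observed minimum, i.e. the probability of seeing an
    anti-correlation this strong from simplex closure alone.
    """
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = relH.to_numpy(dtype=float) if isinstance(relH, pd.DataFrame) else np.asarray(relH, float)
    k, n = X.shape
    if k < 2 or n < 3:
        raise ValueError("need at least 2 signatures and 3 samples")
    if k == 2:
        warnings.warn(
            "with 2 signatures the relative activities are deterministic "
            "complements (Spearman = -1); the null test is degenerate"
        )
    names = list(relH.index) if isinstance(relH, pd.DataFrame) else [f"s{i}" for i in range(k)]
    obs = _pairwise_spearman(X)
    obs_min = _min_offdiag(obs)

    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    minima = np.empty(nsim)
    for s in range(nsim):
        sim = rng.normal(mu[:, None], sd[:, None], size=(k, n))
        np.clip(sim, 0.0, None, out=sim)
        colsum = sim.sum(axis=0)
        colsum[colsum == 0] = 1.0
        sim /= colsum
        minima[s] = _min_offdiag(_pairwise_spearman(sim))
    p = float(np.mean(minima <= obs_min))
    return CorrelationNullResult(
        observed=pd.DataFrame(obs, index=names, columns=names),
        observed_min=obs_min,
        null_min_distribution=minima,
        p_value=p,
    )
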