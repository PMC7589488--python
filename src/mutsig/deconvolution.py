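"""Exposure estimation against known signatures.

Given a mutation-count matrix V (m types x n samples) and a signature
matrix W (m x k, columns are probability vectors), the exposures H solve

    min ||V - W H||_F   subject to   H >= 0,

one non-negative least-squares problem per sample. The solver below is
the fast combinatorial strategy of Van Benthem & Keenan: columns of V
that share the same passive (unconstrained) set are grouped and their
normal equations are solved once per group, with active/passive-set
exchanges iterated to optimality. W'W and W'V are computed a single
time, which is what makes the approach fast for many right-hand sides.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DeconvolutionResult:
    """Non-negative exposures with per-sample diagnostics."""

    exposures: np.ndarray  # k x n
    residual: np.ndarray  # per-sample Frobenius residual ||v - W h||
    passive_sets: np.ndarray  # k x n boolean: entries solved unconstrained


def _cssls(CtC: np.ndarray, CtB: np.ndarray, passive: np.ndarray | None = None) -> np.ndarray:
    """Solve the normal equations for groups of columns sharing a passive set.

    With ``passive is None`` all entries are unconstrained. Singular
    subsystems fall back to the pseudo-inverse with a warning.
    """
    k, n = CtB.shape
    K = np.zeros((k, n))
    if passive is None or passive.all():
        try:
            return np.linalg.solve(CtC, CtB)
        except np.linalg.LinAlgError:
            warnings.warn("singular normal equations; using pseudo-inverse")
            return np.linalg.lstsq(CtC, CtB, rcond=None)[0]
    # group columns by passive-set pattern
    codes = np.packbits(passive, axis=0).T  # n x ceil(k/8)
    _, inverse = np.unique(codes, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        cols = np.flatnonzero(inverse == g)
        pset = passive[:, cols[0]]
        if not pset.any():
            continue
        sub = CtC[np.ix_(pset, pset)]
        rhs = CtB[np.ix_(pset, cols)]
        try:
            sol = np.linalg.solve(sub, rhs)
        except np.linalg.LinAlgError:
            warnings.warn("singular passive-set subsystem; using pseudo-inverse")
            sol = np.linalg.lstsq(sub, rhs, rcond=None)[0]
        K[np.ix_(pset, cols)] = sol
    return K


def fcnnls(
    W: np.ndarray,
    V: np.ndarray,
    tol: float = 1e-10,
    max_rounds_per_k: int = 30,
) -> DeconvolutionResult:
    """Fast combinatorial non-negative least squares, H in V ~ W H.

    Parameters
    ----------
    W : (m, k) array of known signatures (full column rank expected).
    V : (m, n) array of non-negative observations, one column per sample.
    tol : optimality tolerance on gradient components of 1/2 ||v - Wh||^2.
    max_rounds_per_k : cap on active/passive exchange rounds, scaled by k;
        if exceeded the best feasible iterate is returned with a warning.
    """
    W = np.asarray(W, dtype=float)
    V = np.asarray(V, dtype=float)
    m, k = W.shape
    if V.ndim == 1:
        V = V[:, None]
    if V.shape[0] != m:
        raise ValueError(f"shape mismatch: W has {m} rows, V has {V.shape[0]}")
    if m < k:
        raise ValueError("underdetermined system: fewer mutation types than signatures")
    if np.linalg.matrix_rank(W) < k:
        warnings.warn("signature matrix is rank-deficient; solutions may be non-unique")
    n = V.shape[1]

    CtC = W.T @ W
    CtA = W.T @ V

    K = _cssls(CtC, CtA)  # unconstrained start
    P = K > 0
    D = np.where(P, K, 0.0)  # last feasible iterate
    Fset = np.flatnonzero(~P.all(axis=0))
    K = np.where(P, K, 0.0)

    max_iter = max_rounds_per_k * k
    it = 0
    outer = 0
    while Fset.size:
        outer += 1
        if outer > max_iter:
            warnings.warn(
                "fcnnls: outer exchange cap reached; returning best feasible iterate"
            )
            K[:, Fset] = D[:, Fset]
            break
        K[:, Fset] = _cssls(CtC, CtA[:, Fset], P[:, Fset])
        infeasible = Fset[np.flatnonzero((K[:, Fset] < -tol).any(axis=0))]
        # restore feasibility by stepping from the last feasible iterate
        while infeasible.size and it < max_iter:
            it += 1
            Kh = K[:, infeasible]
            Dh = D[:, infeasible]
            neg = (Kh < -tol) & P[:, infeasible]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(neg, Dh / (Dh - Kh), np.inf)
            alpha = ratio.min(axis=0)
            Dh = Dh + alpha[None, :] * (Kh - Dh)
            D[:, infeasible] = Dh
            P[:, infeasible] &= Dh > tol
            K[:, infeasible] = _cssls(CtC, CtA[:, infeasible], P[:, infeasible])
            infeasible = infeasible[np.flatnonzero((K[:, infeasible] < -tol).any(axis=0))]
        if it >= max_iter and infeasible.size:
            warnings.warn(
                "fcnnls: exchange-round cap reached; returning best feasible iterate"
            )
            K[:, infeasible] = D[:, infeasible]
            break
        K[:, Fset] = np.where(P[:, Fset], K[:, Fset], 0.0)
        D[:, Fset] = K[:, Fset]
        # optimality: gradient of 1/2||v - Wh||^2 is CtC h - CtA; optimal when
        # the negative gradient on the active set is <= tol
        Wgrad = CtA[:, Fset] - CtC @ K[:, Fset]
        off_passive = ~P[:, Fset]
        optimal = ~(np.where(off_passive, Wgrad, -np.inf) > tol).any(axis=0)
        not_opt = Fset[~optimal]
        Fset = not_opt
        if Fset.size:
            # bring the most promising active variable into the passive set
            Wf = CtA[:, Fset] - CtC @ K[:, Fset]
            Wf = np.where(~P[:, Fset], Wf, -np.inf)
            P[Wf.argmax(axis=0), Fset] = True
            if it >= max_iter:
                warnings.warn(
                    "fcnnls: exchange-round cap reached before optimality; "
                    "returning best feasible iterate"
                )
                break

    K = np.maximum(K, 0.0)
    residual = np.linalg.norm(V - W @ K, axis=0)
    return DeconvolutionResult(exposures=K, residual=residual, passive_sets=P)


def resolve_exposures(counts: pd.DataFrame, signatures: pd.DataFrame) -> pd.DataFrame:
    """Per-sample signature exposures, labels aligned by mutation type.

    ``counts`` rows are reordered to match ``signatures``; a label
    present in one but not the other is an error. Counts enter raw, so
    exposures come out in mutation-count units. Under-represented
    signatures are retained — no automatic pruning is applied.
    """
    sig_labels = list(signatures.index)
    missing = [l for l in sig_labels if l not in counts.index]
    extra = [l for l in counts.index if l not in signatures.index]
    if missing or extra:
        raise ValueError(
            f"mutation-type labels do not match: missing from counts {missing[:5]}, "
            f"unmatched in counts {extra[:5]}"
        )
    aligned = counts.loc[sig_labels]
    res = fcnnls(signatures.to_numpy(dtype=float), aligned.to_numpy(dtype=float))
    return pd.DataFrame(res.exposures, index=signatures.columns, columns=counts.columns)
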