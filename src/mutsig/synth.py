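"""Synthetic genomes, variants and count matrices with planted structure.

Every stage of the signature pipeline can be exercised without external
downloads: a toy multi-chromosome genome with uniform base composition,
per-sample variant sets drawn from known signature mixtures (so the
planted W and H are ground truth), and count matrices V = W H with
multinomial sampling noise, optionally including a hyper-mutator
outlier sample driven by a dedicated signature.

Planted signatures are sparse blocks over disjoint mutation-type
subsets, which makes them maximally separated under cosine distance and
gives recovery thresholds a clear meaning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (
    ContextShape,
    MutationTypeDictionary,
    ReferenceStore,
    TRI,
    VariantRecord,
    parse_label,
    reverse_complement,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationSpec:
    """Planted ground truth for an end-to-end simulation."""

    n_chrom: int = 2
    chrom_length: int = 10_000
    W_true: np.ndarray | None = None  # m x k, column-stochastic
    H_true: np.ndarray | None = None  # k x n, mutations per sample per signature
    outlier: tuple[int, float, np.ndarray] | None = None  # (sample idx, burden multiplier, signature)
    seed: int | None = None


def make_toy_genome(
    n_chrom: int = 2,
    chrom_length: int = 10_000,
    rng: np.random.Generator | int | None = None,
    shape: ContextShape = TRI,
    fasta_path: str | Path | None = None,
    max_tries: int = 10,
) -> ReferenceStore:
    """Uniform-random toy genome guaranteed to contain every context.

    Chromosome sequences are i.i.d. uniform over A/C/G/T. The generator
    verifies that every pyrimidine-oriented context of ``shape`` occurs
    at least once (on either strand) and redraws from a spawned
    substream otherwise, so simulated variants can realize any mutation
    type. Optionally writes the genome as FASTA.
    """
    if chrom_length < 100:
        raise ValueError("chrom_length must be >= 100")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    needed = 4 ** (shape.n_up + shape.n_down) * 2  # contexts x {C, T} center
    for _ in range(max_tries):
        seqs = {
            f"chr{i + 1}": "".join(rng.choice(list("ACGT"), size=chrom_length))
            for i in range(n_chrom)
        }
        store = ReferenceStore.from_sequences(seqs)
        if len(_context_index(store, shape)) == needed:
            break
    else:
        raise RuntimeError(
            f"could not cover all {needed} contexts in {max_tries} tries; "
            "increase chrom_length"
        )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
    return store


def _context_index(
    store: ReferenceStore, shape: ContextShape
) -> dict[tuple[str, str, str], list[tuple[str, int, str]]]:
    """Map pyrimidine-oriented (up, ref, down) to genome (chrom, pos, strand).

    A genomic window whose central base is a purine contributes through
    its reverse complement, with strand '-'.
    """
    w = shape.window
    index: dict[tuple[str, str, str], list[tuple[str, int, str]]] = {}
    for chrom in store.chroms:
        seq = store.fetch(chrom, 1, store.length(chrom))
        for i in range(w, len(seq) - w):
            window = seq[i - w : i + w + 1]
            if "N" in window:
                continue
            strand = "+"
            if window[w] in "AG":
                window = reverse_complement(window)
                strand = "-"
            up = window[w - shape.n_up : w]
            down = window[w + 1 : w + 1 + shape.n_down]
            index.setdefault((up, window[w], down), []).append((chrom, i + 1, strand))
    return index


def planted_signatures(m: int, k: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """k column-stochastic signatures on disjoint mutation-type blocks.

    Types are split into k contiguous blocks; signature j puts random
    positive mass on block j only, so pairwise cosine distance is 1.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if k > m:
        raise ValueError("more signatures than mutation types")
    W = np.zeros((m, k))
    bounds = np.linspace(0, m, k + 1).astype(int)
    for j in range(k):
        block = slice(bounds[j], bounds[j + 1])
        vals = rng.uniform(0.2, 1.0, size=bounds[j + 1] - bounds[j])
        W[block, j] = vals / vals.sum()
    return W


def planted_exposures(
    k: int,
    n: int,
    rng: np.random.Generator | int | None = None,
    total_low: float = 400.0,
    total_high: float = 600.0,
    alpha: float = 0.5,
) -> np.ndarray:
    """k x n planted activities with realistic sample-to-sample variation.

    Per-sample mixture weights are Dirichlet(alpha) draws, scaled by a
    uniform total burden. Alpha below 1 yields sparse mixtures — most
    samples dominated by one or two signatures — as observed in tumor
    cohorts; this variation is also what renders the factorization
    identifiable (with every signature active at a similar level in
    every sample, V = W H admits a continuum of equally good factor
    pairs and no method can single out the planted one).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mix = rng.dirichlet([alpha] * k, size=n).T
    totals = rng.uniform(total_low, total_high, size=n)
    return mix * totals


def simulate_variants(
    store: ReferenceStore,
    W_true: np.ndarray,
    H_true: np.ndarray,
    dictionary: MutationTypeDictionary,
    rng: np.random.Generator | int | None = None,
    sample_names: list[str] | None = None,
) -> list[VariantRecord]:
    """Emit variants whose mutation-type composition follows W_true, H_true.

    For sample j and signature s, ``H_true[s, j]`` mutation types are
    drawn from Multinomial(., W_true[:, s]); each drawn type is placed
    uniformly at random on a genome position presenting that
    pyrimidine-oriented context (on either strand; the emitted ref/alt
    are complemented when the genome shows the purine strand).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    W_true = np.asarray(W_true, dtype=float)
    H_true = np.asarray(H_true, dtype=float)
    m, k = W_true.shape
    if len(dictionary) != m:
        raise ValueError("dictionary size does not match W_true rows")
    if H_true.shape[0] != k:
        raise ValueError("H_true rows do not match W_true columns")
    n = H_true.shape[1]
    if sample_names is None:
        sample_names = [f"sample_{j + 1:02d}" for j in range(n)]
    index = _context_index(store, dictionary.shape)
    parsed = [parse_label(lab) for lab in dictionary.labels]
    records: list[VariantRecord] = []
    for j in range(n):
        for s in range(k):
            n_mut = int(np.round(H_true[s, j]))
            if n_mut <= 0:
                continue
            type_counts = rng.multinomial(n_mut, W_true[:, s])
            for t in np.flatnonzero(type_counts):
                up, ref, alt, down = parsed[t]
                positions = index.get((up, ref, down))
                if not positions:
                    raise RuntimeError(
                        f"context {up}[{ref}]{down} absent from the toy genome"
                    )
                for _ in range(type_counts[t]):
                    chrom, pos, strand = positions[rng.integers(len(positions))]
                    if strand == "+":
                        records.append(VariantRecord(chrom, pos, ref, alt, sample_names[j]))
                    else:
                        records.append(
                            VariantRecord(chrom, pos, _COMP[ref], _COMP[alt], sample_names[j])
                        )
    return records


def simulate_counts(
    W_true: np.ndarray,
    H_true: np.ndarray,
    rng: np.random.Generator | int | None = None,
    mode: str = "multinomial",
) -> np.ndarray:
    """Count matrix V from planted factors.

    ``exact`` returns round(W H). ``multinomial`` draws each sample
    column from Multinomial(N_j, p_j) with N_j the rounded planted
    column total and p_j the normalized W H column, adding realistic
    sampling noise while preserving totals.
    """
    if mode not in ("exact", "multinomial"):
        raise ValueError(f"unknown mode: {mode!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    M = np.asarray(W_true, float) @ np.asarray(H_true, float)
    if mode == "exact":
        return np.round(M)
    out = np.zeros_like(M)
    totals = M.sum(axis=0)
    for j in range(M.shape[1]):
        if totals[j] <= 0:
            continue
        out[:, j] = rng.multinomial(int(np.round(totals[j])), M[:, j] / totals[j])
    return out


def counts_frame(V: np.ndarray, labels, sample_names=None) -> pd.DataFrame:
    """Wrap a raw count matrix as a labelled DataFrame."""
    if sample_names is None:
        sample_names = [f"sample_{j + 1:02d}" for j in range(V.shape[1])]
    return pd.DataFrame(V, index=list(labels), columns=sample_names)
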