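"""Mutual-information coupling matrices and the ΔMI differencing step.

Per-pair MI (bits) is estimated from the discrete conformational
trajectories with a preprocessing chain that controls discretization bias:
each residue's symbol row is reparametrized to [0,1] (MI is invariant to
reparametrization of the marginals, but this removes alphabet-size
differences), perturbed by tiny zero-mean Gaussian noise (variance ~1e-12,
a tie-breaker that smooths the empirical distribution), then binned by
fixed-frequency discretization. Pairs whose MI is indistinguishable from a
permutation null are filtered to zero, and the bound−unbound difference
forms the ΔMI matrix whose large entries mark binding-induced coupling
changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rotamer_sampling import TrajectoryMatrix

__all__ = [
    "MIConfig",
    "MIMatrix",
    "DeltaMIMatrix",
    "reparametrize",
    "jitter",
    "ffd_discretize",
    "entropy",
    "joint_entropy",
    "mutual_information",
    "mi_matrix",
    "null_filter",
    "delta_mi",
]


@dataclass
class MIConfig:
    jitter_sd: float = 1e-6       # noise sd, i.e. variance 1e-12
    samples_per_bin: int = 30     # FFD frequency m
    n_null_permutations: int = 20
    null_sd_multiplier: float = 3.0
    seed: int = 0
    #: never refine the discretization beyond the residue's own alphabet
    cap_bins_to_alphabet: bool = True

    def __post_init__(self) -> None:
        if (self.jitter_sd <= 0 or self.samples_per_bin <= 0
                or self.n_null_permutations <= 0
                or self.null_sd_multiplier <= 0):
            raise ValueError("all MIConfig parameters must be positive")


@dataclass
class MIMatrix:
    """Symmetric residue × residue MI (bits); diagonal = per-residue entropy."""

    values: np.ndarray
    residue_ids: list[int]
    state_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T):
            raise ValueError("MI matrix must be symmetric")
        if (self.values < -1e-12).any():
            raise ValueError("MI must be nonnegative")


@dataclass
class DeltaMIMatrix:
    """Signed (bound − unbound), absolute and [0,1]-normalized ΔMI."""

    signed: np.ndarray
    residue_ids: list[int]

    def __post_init__(self) -> None:
        self.signed = np.asarray(self.signed, dtype=float)

    @property
    def absolute(self) -> np.ndarray:
        return np.abs(self.signed)

    @property
    def normalized(self) -> np.ndarray:
        a = self.absolute
        m = a.max()
        return a / m if m > 0 else a.copy()


def reparametrize(symbols: np.ndarray, alphabet_size: int) -> np.ndarray:
    """Map symbol index i of a size-k alphabet to i/(k−1); k = 1 maps to 0."""
    symbols = np.asarray(symbols)
    if symbols.size == 0:
        raise ValueError("need at least one snapshot")
    if alphabet_size <= 1:
        return np.zeros(symbols.shape, dtype=float)
    return symbols.astype(float) / (alphabet_size - 1)


def jitter(values: np.ndarray, jitter_sd: float,
           rng: np.random.Generator) -> np.ndarray:
    """Add elementwise N(0, jitter_sd²) noise."""
    if jitter_sd <= 0:
        raise ValueError("jitter_sd must be positive")
    return np.asarray(values, float) + rng.normal(0.0, jitter_sd,
                                                  size=np.shape(values))


def ffd_discretize(values: np.ndarray, m: int) -> np.ndarray:
    """Fixed-frequency discretization: consecutive runs of m sorted samples
    share a bin label; the last bin absorbs the remainder. Equal values are
    never split across bins (a run of ties takes the bin of its first
    element in stable sort order)."""
    values = np.asarray(values)
    n = values.size
    if m < 1:
        raise ValueError("m must be ≥ 1")
    if m > n:
        raise ValueError(f"m = {m} exceeds sample count n = {n}")
    order = np.argsort(values, kind="stable")
    n_bins = n // m
    ranked = np.minimum(np.arange(n) // m, n_bins - 1)
    # equal values must share a bin: give a run of ties the bin of its head
    sorted_vals = values[order]
    run_start = np.concatenate(([True], sorted_vals[1:] != sorted_vals[:-1]))
    ranked = ranked[np.maximum.accumulate(
        np.where(run_start, np.arange(n), 0))]
    labels = np.empty(n, dtype=np.int64)
    labels[order] = ranked
    return labels


def _counts_entropy(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    n = counts.sum()
    p = counts / n
    return float(-(p * np.log2(p)).sum())


def entropy(labels: np.ndarray) -> float:
    """Plug-in Shannon entropy in bits from empirical frequencies."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("need at least one sample")
    _, counts = np.unique(labels, return_counts=True)
    return _counts_entropy(counts)


def joint_entropy(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Plug-in joint Shannon entropy H(A,B) in bits."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    if labels_a.size == 0:
        raise ValueError("need at least one sample")
    _, ia = np.unique(labels_a, return_inverse=True)
    kb, ib = np.unique(labels_b, return_inverse=True)
    pair = ia * kb.size + ib
    _, counts = np.unique(pair, return_counts=True)
    return _counts_entropy(counts)


def mutual_information(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """I(A,B) = H(A) + H(B) − H(A,B), floored at 0 (bits)."""
    return max(0.0, entropy(labels_a) + entropy(labels_b)
               - joint_entropy(labels_a, labels_b))


def _preprocess(traj: TrajectoryMatrix, config: MIConfig,
                rng: np.random.Generator) -> list[np.ndarray]:
    """reparametrize → jitter → FFD, per residue row."""
    n = traj.n_snapshots
    labels = []
    for i in range(traj.n_residues):
        k = traj.alphabet_sizes[i]
        x = reparametrize(traj.symbols[i], k)
        x = jitter(x, config.jitter_sd, rng)
        m = config.samples_per_bin
        if config.cap_bins_to_alphabet and k > 0:
            m = max(m, math.ceil(n / k))
        m = min(m, n)
        labels.append(ffd_discretize(x, m))
    return labels


def mi_matrix(traj: TrajectoryMatrix, config: MIConfig | None = None) -> MIMatrix:
    """Pairwise MI matrix after the full preprocessing chain.

    Diagonal entries hold the per-residue entropies H(i).
    """
    config = config or MIConfig()
    if traj.n_residues < 2:
        raise ValueError("need at least two residues")
    rng = np.random.default_rng(config.seed)
    labels = _preprocess(traj, config, rng)
    n = traj.n_residues
    h = np.array([entropy(l) for l in labels])
    out = np.zeros((n, n))
    np.fill_diagonal(out, h)
    for i in range(n):
        for j in range(i + 1, n):
            mi = max(0.0, h[i] + h[j] - joint_entropy(labels[i], labels[j]))
            out[i, j] = out[j, i] = mi
    return MIMatrix(out, list(traj.residue_ids), traj.state_label)


def null_filter(mi: MIMatrix, traj: TrajectoryMatrix,
                config: MIConfig | None = None) -> MIMatrix:
    """Zero out pairs whose MI is consistent with a permutation null.

    For each pair the MI is recomputed on independently shuffled copies of
    one residue's labels; an entry survives only if the observed MI exceeds
    mean_null + null_sd_multiplier × sd_null. Diagonal entropies are kept.
    """
    config = config or MIConfig()
    rng = np.random.default_rng(config.seed)
    labels = _preprocess(traj, config, rng)
    perm_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(1)[0])
    n = traj.n_residues
    values = mi.values.copy()
    for i in range(n):
        hi = entropy(labels[i])
        for j in range(i + 1, n):
            if values[i, j] == 0.0:
                continue
            hj = entropy(labels[j])
            null = np.empty(config.n_null_permutations)
            for p in range(config.n_null_permutations):
                shuffled = perm_rng.permutation(labels[j])
                null[p] = max(0.0, hi + hj
                              - joint_entropy(labels[i], shuffled))
            cutoff = null.mean() + config.null_sd_multiplier * null.std()
            if values[i, j] <= cutoff:
                values[i, j] = values[j, i] = 0.0
    return MIMatrix(values, mi.residue_ids, mi.state_label)


def delta_mi(bound: MIMatrix, unbound: MIMatrix) -> DeltaMIMatrix:
    """Signed ΔMI = bound − unbound (off-diagonal couplings only)."""
    if bound.residue_ids != unbound.residue_ids:
        raise ValueError("bound and unbound matrices cover different residues")
    signed = bound.values - unbound.values
    np.fill_diagonal(signed, 0.0)  # diagonal carries entropies, not couplings
    return DeltaMIMatrix(signed, list(bound.residue_ids))


def write_matrix_tsv(values: np.ndarray, residue_ids, path) -> None:
    df = pd.DataFrame(np.asarray(values), index=list(residue_ids),
                      columns=list(residue_ids))
    df.to_csv(path, sep="\t", index_label="residue", float_format="%.6g")


def read_matrix_tsv(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [int(c) if str(c).lstrip("-").isdigit() else str(c)
           for c in df.columns]
    return df.to_numpy(dtype=float), ids
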