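"""Synthetic inputs for exercising the whole pipeline without real data.

Three generators cover the pipeline's input surface: toy peptide
structures (idealized Cα traces with pseudo side chains), multi-model
ensembles with a planted per-residue flexibility profile, and two-state
discrete conformational trajectories with planted coupling changes. The
coupling model is a copy-with-probability channel, chosen because its
mutual information has a closed form and therefore yields analytic oracles
for the estimator tests:

    residue j copies residue i's symbol with probability c, otherwise it
    draws uniformly from its alphabet of size k, so
    I(i,j) = log2 k − H(c + (1−c)/k, (1−c)/k, …, (1−c)/k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rotamer_sampling import TrajectoryMatrix
from .structio import Ensemble, Residue, StructureModel, write_structure

__all__ = [
    "CouplingSpec",
    "make_toy_structure",
    "make_coupled_trajectories",
    "make_flex_ensemble",
    "copy_channel_mi",
]

# residue types cycled through generated structures (methyl-bearing heavy)
_AA_CYCLE = "LVAITKSEMF"

# helix geometry: radius/rise/turn giving consecutive Cα–Cα ≈ 3.8 Å
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN_DEG = 100.0


@dataclass
class CouplingSpec:
    """Planted two-state coupling structure for synthetic trajectories."""

    n_residues: int
    alphabet_sizes: list[int] | int = 4
    #: (i, j, c_unbound, c_bound) with coupling strengths in [0, 1]
    coupled_pairs: list[tuple[int, int, float, float]] = field(
        default_factory=list)
    n_snapshots: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.alphabet_sizes, int):
            self.alphabet_sizes = [self.alphabet_sizes] * self.n_residues
        if len(self.alphabet_sizes) != self.n_residues:
            raise ValueError("alphabet_sizes length must equal n_residues")
        for i, j, cu, cb in self.coupled_pairs:
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues):
                raise ValueError("coupled pair references invalid residue")
            if not (0.0 <= cu <= 1.0 and 0.0 <= cb <= 1.0):
                raise ValueError("coupling strengths must lie in [0, 1]")


def copy_channel_mi(k: int, c: float) -> float:
    """Closed-form MI (bits) of the copy-with-probability-c channel on a
    uniform alphabet of size k."""
    if k <= 1:
        return 0.0
    p_same = c + (1.0 - c) / k
    p_other = (1.0 - c) / k
    h_cond = -(p_same * math.log2(p_same) if p_same > 0 else 0.0)
    if p_other > 0:
        h_cond -= (k - 1) * p_other * math.log2(p_other)
    return math.log2(k) - h_cond


def _build_model(n_residues: int, geometry: str,
                 rng: np.random.Generator) -> StructureModel:
    residues = []
    for i in range(n_residues):
        if geometry == "helix":
            theta = math.radians(_HELIX_TURN_DEG) * i
            ca = np.array([_HELIX_RADIUS * math.cos(theta),
                           _HELIX_RADIUS * math.sin(theta),
                           _HELIX_RISE * i])
            out = np.array([math.cos(theta), math.sin(theta), 0.0])
        elif geometry == "strand":
            ca = np.array([3.7 * i, 0.45 * (-1.0) ** i, 0.0])
            out = np.array([0.0, (-1.0) ** i, 0.3])
            out = out / np.linalg.norm(out)
        else:
            raise ValueError(f"unknown geometry {geometry!r}")
        aa = _AA_CYCLE[i % len(_AA_CYCLE)]
        axis = np.array([0.0, 0.0, 1.0])
        tangent = np.cross(axis, out)
        atoms = {
            "N": ca + 1.46 * (-0.6 * tangent + 0.8 * out * 0.0
                              + np.array([0.0, 0.0, -0.55])),
            "CA": ca,
            "C": ca + 1.52 * (0.6 * tangent + np.array([0.0, 0.0, 0.55])),
        }
        atoms["O"] = atoms["C"] + np.array([0.4, 0.4, 1.1])
        if aa != "G":
            atoms["CB"] = ca + 1.53 * out
            if aa != "A":
                atoms["CG"] = ca + (1.53 + 1.52) * out
        residues.append(Residue(i + 1, aa, atoms))
    return StructureModel(0, residues, source="synthetic")


def make_toy_structure(n_residues: int, geometry: str = "helix",
                       seed: int = 0, path=None) -> Ensemble:
    """A chemically plausible single-model toy structure.

    Backbone N/CA/C/O plus CB and a CG pseudo-atom per residue (Gly/Ala
    truncated accordingly), on an idealized helix or strand trace with
    consecutive Cα–Cα distances near 3.8 Å. Deterministic under the seed;
    written as a valid PDB file when ``path`` is given.
    """
    if n_residues < 2:
        raise ValueError("need at least two residues")
    rng = np.random.default_rng(seed)
    ensemble = Ensemble([_build_model(n_residues, geometry, rng)])
    if path is not None:
        write_structure(ensemble, path)
    return ensemble


def make_coupled_trajectories(spec: CouplingSpec
                              ) -> tuple[TrajectoryMatrix, TrajectoryMatrix]:
    """Two-state trajectories with planted coupling changes.

    Uncoupled residues are i.i.d. uniform over their alphabets; for a
    coupled pair (i, j, c) residue j copies i's symbol (mod its own
    alphabet) with probability c. Returns (bound, unbound).
    """
    ss = np.random.SeedSequence(spec.seed)
    seeds = ss.spawn(2)
    out = []
    for state, label in ((0, "bound"), (1, "unbound")):
        rng = np.random.default_rng(seeds[state])
        n = spec.n_snapshots
        sym = np.empty((spec.n_residues, n), dtype=np.int64)
        for r, k in enumerate(spec.alphabet_sizes):
            sym[r] = rng.integers(k, size=n)
        for i, j, cu, cb in spec.coupled_pairs:
            c = cb if label == "bound" else cu
            copy_mask = rng.random(n) < c
            kj = spec.alphabet_sizes[j]
            sym[j, copy_mask] = sym[i, copy_mask] % kj
        out.append(TrajectoryMatrix(sym, list(spec.alphabet_sizes),
                                    list(range(spec.n_residues)), label))
    return out[0], out[1]


def make_flex_ensemble(n_residues: int, n_models: int, sigma_profile,
                       seed: int = 0, geometry: str = "helix",
                       state_label: str = "", path=None) -> Ensemble:
    """Multi-model ensemble with a planted per-residue flexibility profile.

    Each model is the base structure with every residue rigidly displaced
    by an isotropic Gaussian offset of per-residue σ (Å), then re-embedded
    under a random global rigid motion so that downstream superposition has
    real work to do.
    """
    if n_models < 2:
        raise ValueError("need at least two models")
    sigma = np.asarray(sigma_profile, dtype=float)
    if sigma.shape != (n_residues,):
        raise ValueError("sigma_profile must have one σ per residue")
    rng = np.random.default_rng(seed)
    base = _build_model(n_residues, geometry, rng)
    models = []
    for m in range(n_models):
        model = base.copy()
        model.model_id = m
        for r, res in enumerate(model.residues):
            offset = rng.normal(0.0, sigma[r], size=3)
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + offset
        rot = _random_rotation(rng)
        trans = rng.uniform(-20.0, 20.0, size=3)
        for res in model.residues:
            for name in res.atoms:
                res.atoms[name] = rot @ res.atoms[name] + trans
        models.append(model)
    ensemble = Ensemble(models, state_label=state_label)
    if path is not None:
        write_structure(ensemble, path)
    return ensemble


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix, sign-fixed to a proper rotation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
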