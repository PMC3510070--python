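"""Discrete side-chain conformational sampling.

A residue's conformational state space is a fine-grained alphabet of χ
dihedral combinations on a uniform grid. Domain conformations are sampled
with Metropolis Monte-Carlo at 298 K against a pluggable energy function;
snapshots recorded at fixed intervals form the trajectory matrix whose rows
are the per-residue random variables of the downstream mutual-information
analysis.
"""

from __future__ import annotations

import abc
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structio import Ensemble, StructureModel

__all__ = [
    "GAS_CONSTANT_KCAL",
    "N_CHI",
    "RotamerAlphabet",
    "SamplerConfig",
    "EnergyFunction",
    "FlatEnergy",
    "TableEnergy",
    "SoftSphereEnergy",
    "TrajectoryMatrix",
    "build_alphabet",
    "metropolis_accept",
    "sample_ensemble",
]

#: Gas constant in kcal·mol⁻¹·K⁻¹.
GAS_CONSTANT_KCAL = 1.987e-3

#: Number of rotatable χ dihedrals per amino acid (one-letter codes).
N_CHI = {
    "A": 0, "G": 0,
    "C": 1, "S": 1, "T": 1, "V": 1,
    "D": 2, "F": 2, "H": 2, "I": 2, "L": 2, "N": 2, "P": 2, "W": 2, "Y": 2,
    "E": 3, "M": 3, "Q": 3,
    "K": 4, "R": 4,
}

#: Side-chain torsion chain used to locate each χ axis (backbone N, CA first).
CHI_CHAIN = {
    "R": ["N", "CA", "CB", "CG", "CD", "NE", "CZ"],
    "N": ["N", "CA", "CB", "CG", "OD1"],
    "D": ["N", "CA", "CB", "CG", "OD1"],
    "C": ["N", "CA", "CB", "SG"],
    "Q": ["N", "CA", "CB", "CG", "CD", "OE1"],
    "E": ["N", "CA", "CB", "CG", "CD", "OE1"],
    "H": ["N", "CA", "CB", "CG", "ND1"],
    "I": ["N", "CA", "CB", "CG1", "CD1"],
    "L": ["N", "CA", "CB", "CG", "CD1"],
    "K": ["N", "CA", "CB", "CG", "CD", "CE", "NZ"],
    "M": ["N", "CA", "CB", "CG", "SD", "CE"],
    "F": ["N", "CA", "CB", "CG", "CD1"],
    "P": ["N", "CA", "CB", "CG", "CD"],
    "S": ["N", "CA", "CB", "OG"],
    "T": ["N", "CA", "CB", "OG1"],
    "W": ["N", "CA", "CB", "CG", "CD1"],
    "Y": ["N", "CA", "CB", "CG", "CD1"],
    "V": ["N", "CA", "CB", "CG1"],
}

# PDB remoteness codes order side-chain atoms outward from CA; χ_k rotates
# every atom strictly beyond the k-th side-chain shell.
_REMOTENESS = {"B": 1, "G": 2, "D": 3, "E": 4, "Z": 5, "H": 6}


@dataclass
class RotamerAlphabet:
    """Per-residue list of symbols; a symbol is a tuple of χ angles (deg)."""

    symbols: list[list[tuple[float, ...]]]
    residue_ids: list[int]

    @property
    def sizes(self) -> list[int]:
        return [len(s) for s in self.symbols]

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class SamplerConfig:
    temperature_K: float = 298.0
    snapshot_interval: int = 1000
    n_snapshots_target: int = 5000
    n_chains: int | None = None  # default: one chain per backbone model
    seed: int = 0
    energy_model: str = "soft_sphere"
    burn_in: bool = True

    #: snapshot count used for the published full-scale runs
    FULL_SCALE_SNAPSHOTS = 751500

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        for name in ("snapshot_interval", "n_snapshots_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_chains is not None and self.n_chains <= 0:
            raise ValueError("n_chains must be positive")


@dataclass
class TrajectoryMatrix:
    """residues × snapshots integer symbol indices from sampling."""

    symbols: np.ndarray  # shape (n_residues, n_snapshots), int
    alphabet_sizes: list[int]
    residue_ids: list[int]
    state_label: str = ""

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 2:
            raise ValueError("trajectory must be residues × snapshots")
        for i, k in enumerate(self.alphabet_sizes):
            row = self.symbols[i]
            if row.size and (row.min() < 0 or row.max() >= k):
                raise ValueError(f"symbol index out of range for residue row {i}")

    @property
    def n_residues(self) -> int:
        return self.symbols.shape[0]

    @property
    def n_snapshots(self) -> int:
        return self.symbols.shape[1]

    def to_tsv(self, path, sidecar: dict | None = None) -> None:
        """Rows = residues (first column residue id), columns = snapshots."""
        with open(path, "w") as fh:
            fh.write("residue\t" + "\t".join(
                f"s{i}" for i in range(self.n_snapshots)) + "\n")
            for rid, row in zip(self.residue_ids, self.symbols):
                fh.write(str(rid) + "\t" + "\t".join(map(str, row)) + "\n")
        meta = {"alphabet_sizes": list(map(int, self.alphabet_sizes)),
                "residue_ids": list(map(int, self.residue_ids)),
                "state_label": self.state_label}
        if sidecar is not None:
            meta.update(sidecar)
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_tsv(cls, path) -> "TrajectoryMatrix":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        rows = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                rows.append([int(x) for x in line.split()[1:]])
        return cls(np.asarray(rows), meta["alphabet_sizes"],
                   meta["residue_ids"], meta.get("state_label", ""))


def build_alphabet(ensemble: Ensemble, bins_per_chi: int = 6) -> RotamerAlphabet:
    """Uniform χ-binned conformational alphabet for every residue.

    Each rotatable χ contributes ``bins_per_chi`` bin centers in [−180, 180);
    a residue's symbols are the cartesian product over its χ angles.
    Alanine and glycine have no rotatable χ and get a single symbol.
    """
    if bins_per_chi < 2:
        raise ValueError("bins_per_chi must be ≥ 2")
    step = 360.0 / bins_per_chi
    centers = [-180.0 + (i + 0.5) * step for i in range(bins_per_chi)]
    symbols = []
    for res in ensemble.models[0].residues:
        if res.aa_type not in N_CHI:
            raise ValueError(f"unknown residue type {res.aa_type!r} "
                             f"at position {res.seq_index}")
        nchi = N_CHI[res.aa_type]
        if nchi == 0:
            symbols.append([()])
        else:
            symbols.append([tuple(c) for c in
                            itertools.product(centers, repeat=nchi)])
    return RotamerAlphabet(symbols, ensemble.residue_ids)


def metropolis_accept(delta_g: float, temperature_K: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with p = min(1, exp(−ΔG/RT))."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    if delta_g <= 0:
        return True
    p = math.exp(-delta_g / (GAS_CONSTANT_KCAL * temperature_K))
    return bool(rng.random() < p)


class EnergyFunction(abc.ABC):
    """Free-energy change of a proposed single-residue symbol move.

    Deterministic given the current state and the move; finite for
    clash-free states. A wrapper around an external force field can be
    plugged here for full-scale runs.
    """

    @abc.abstractmethod
    def delta_g(self, state: np.ndarray, res_index: int,
                new_symbol: int) -> float:
        """ΔG (kcal/mol) of switching residue ``res_index`` to ``new_symbol``."""

    def on_move(self, state: np.ndarray, res_index: int,
                new_symbol: int) -> None:
        """Hook called after an accepted move (for cached geometries)."""


class FlatEnergy(EnergyFunction):
    """ΔG ≡ 0: every state equally favourable (uniform stationary law)."""

    def delta_g(self, state, res_index, new_symbol) -> float:
        return 0.0


class TableEnergy(EnergyFunction):
    """Additive per-residue, per-symbol energies (kcal/mol).

    The stationary distribution of each residue is the exact Boltzmann law
    of its table, which makes this the reference model for sampler tests.
    """

    def __init__(self, tables: Sequence[Sequence[float]]):
        self.tables = [np.asarray(t, dtype=float) for t in tables]

    def delta_g(self, state, res_index, new_symbol) -> float:
        t = self.tables[res_index]
        return float(t[new_symbol] - t[state[res_index]])


class SoftSphereEnergy(EnergyFunction):
    """Steric stand-in energy: soft-sphere repulsion + torsion preference.

    Side-chain coordinates for each symbol are generated by rotating the
    deposited side chain about its χ axes to the symbol's grid angles
    (χ angles whose defining atoms are missing are left untouched). The
    energy of a state is the sum over residue pairs of a soft-core overlap
    penalty between heavy atoms closer than ``clash_distance``, plus a
    3-fold cosine torsion term favouring staggered χ.
    """

    def __init__(self, model: StructureModel, alphabet: RotamerAlphabet,
                 clash_distance: float = 3.2, repulsion_k: float = 10.0,
                 torsion_k: float = 0.3):
        self.model = model
        self.alphabet = alphabet
        self.clash_distance = clash_distance
        self.repulsion_k = repulsion_k
        self.torsion_k = torsion_k
        self._coords = [self._symbol_coords(i) for i in range(len(alphabet))]
        self._torsion = [
            np.array([torsion_k * sum(1.0 + math.cos(3.0 * math.radians(c))
                                      for c in sym)
                      for sym in alphabet.symbols[i]])
            for i in range(len(alphabet))]

    # -- geometry ---------------------------------------------------------
    def _symbol_coords(self, i: int) -> list[np.ndarray]:
        """Heavy-atom coordinates of residue i for each alphabet symbol."""
        res = self.model.residues[i]
        names = sorted(res.heavy_atoms())
        base = np.array([res.atoms[n] for n in names]) if names else \
            np.zeros((0, 3))
        out = []
        for sym in self.alphabet.symbols[i]:
            out.append(_apply_chis(res.aa_type, names, base.copy(), sym))
        self._atom_names = getattr(self, "_atom_names", {})
        self._atom_names[i] = names
        return out

    def _pair_energy(self, ci: np.ndarray, cj: np.ndarray) -> float:
        if not len(ci) or not len(cj):
            return 0.0
        d = np.sqrt(((ci[:, None, :] - cj[None, :, :]) ** 2).sum(-1))
        overlap = np.clip(1.0 - d / self.clash_distance, 0.0, None)
        return float(self.repulsion_k * (overlap ** 2).sum())

    def delta_g(self, state, res_index, new_symbol) -> float:
        old_c = self._coords[res_index][state[res_index]]
        new_c = self._coords[res_index][new_symbol]
        dg = (self._torsion[res_index][new_symbol]
              - self._torsion[res_index][state[res_index]])
        for j in range(len(self._coords)):
            if j == res_index:
                continue
            cj = self._coords[j][state[j]]
            dg += self._pair_energy(new_c, cj) - self._pair_energy(old_c, cj)
        return dg


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])


def _apply_chis(aa: str, names: list[str], coords: np.ndarray,
                chis: tuple[float, ...]) -> np.ndarray:
    """Rotate side-chain atoms so that each defined χ equals the target."""
    chain = CHI_CHAIN.get(aa)
    if chain is None or not chis:
        return coords
    idx = {n: k for k, n in enumerate(names)}
    for k, target in enumerate(chis):
        quad = chain[k:k + 4]
        if len(quad) < 4 or any(q not in idx for q in quad):
            continue
        p = [coords[idx[q]] for q in quad]
        current = _dihedral(*p)
        rot = _rotation_about_axis(p[2] - p[1], target - current)
        pivot = p[2]
        # rotate every side-chain atom beyond the k-th shell
        for n, j in idx.items():
            rem = _REMOTENESS.get(n[1] if len(n) > 1 else "", 0)
            if rem > k + 1:
                coords[j] = rot @ (coords[j] - pivot) + pivot
    return coords


def _greedy_minimize(state: np.ndarray, energy: EnergyFunction,
                     sizes: list[int], max_sweeps: int = 100) -> np.ndarray:
    """Greedy best-symbol descent until no single move lowers the energy."""
    for _ in range(max_sweeps):
        improved = False
        for i, k in enumerate(sizes):
            if k < 2:
                continue
            dgs = [energy.delta_g(state, i, s) for s in range(k)]
            best = int(np.argmin(dgs))
            if dgs[best] < -1e-12 and best != state[i]:
                state[i] = best
                energy.on_move(state, i, best)
                improved = True
        if not improved:
            break
    return state


def sample_ensemble(ensemble: Ensemble, alphabet: RotamerAlphabet,
                    config: SamplerConfig,
                    energy: EnergyFunction | None = None) -> TrajectoryMatrix:
    """Metropolis Monte-Carlo sampling of side-chain conformations.

    One chain is run per backbone model (models cycled to reach
    ``config.n_chains``); each chain starts from a greedy energy
    minimization, then proposes single-residue symbol changes (residue and
    symbol both uniform) and records the full domain state every
    ``snapshot_interval`` iterations. Chains are concatenated into one
    trajectory; the run is reproducible given the seed.
    """
    sizes = alphabet.sizes
    n_res = len(sizes)
    n_chains = config.n_chains or ensemble.n_models
    base = config.n_snapshots_target // n_chains
    extra = config.n_snapshots_target % n_chains
    per_chain = [base + (1 if c < extra else 0) for c in range(n_chains)]
    if sum(per_chain) == 0:
        raise ValueError("zero snapshots requested")

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(n_chains)
    movable = [i for i, k in enumerate(sizes) if k > 1]
    blocks = []
    for c in range(n_chains):
        if per_chain[c] == 0:
            continue
        rng = np.random.default_rng(chain_seeds[c])
        model = ensemble.models[c % ensemble.n_models]
        e = energy if energy is not None else \
            SoftSphereEnergy(model, alphabet)
        state = np.zeros(n_res, dtype=np.int64)
        if config.burn_in:
            state = _greedy_minimize(state, e, sizes)
        block = np.empty((n_res, per_chain[c]), dtype=np.int64)
        if not movable:
            block[:] = state[:, None]
            blocks.append(block)
            continue
        col = 0
        for it in range(1, per_chain[c] * config.snapshot_interval + 1):
            i = movable[rng.integers(len(movable))]
            s = int(rng.integers(sizes[i]))
            if s != state[i]:
                dg = e.delta_g(state, i, s)
                if metropolis_accept(dg, config.temperature_K, rng):
                    state[i] = s
                    e.on_move(state, i, s)
            if it % config.snapshot_interval == 0:
                block[:, col] = state
                col += 1
        blocks.append(block)
    return TrajectoryMatrix(np.concatenate(blocks, axis=1), sizes,
                            alphabet.residue_ids, ensemble.state_label)
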