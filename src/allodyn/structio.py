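"""Structure and ensemble I/O plus shared geometric primitives.

Reads single-model crystal files and multi-model NMR ensembles from PDB
format, exposes residues in author numbering, and provides Kabsch
superposition, RMSD between equivalent atoms and pairwise sequence identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from Bio import Align
from Bio.PDB import PDBParser
from Bio.Data.IUPACData import protein_letters_3to1, protein_letters_1to3

__all__ = [
    "Residue",
    "StructureModel",
    "Ensemble",
    "METHYL_BEARING",
    "read_structure",
    "write_structure",
    "kabsch",
    "rmsd_equivalent_atoms",
    "sequence_identity",
]

#: One-letter codes of the NMR-observable methyl side chains.
METHYL_BEARING = frozenset("AVLITM")

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}
_1TO3 = {k: v.upper() for k, v in protein_letters_1to3.items()}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class Residue:
    """One amino-acid residue: author-numbered index, type and atoms (Å)."""

    seq_index: int
    aa_type: str  # one-letter code
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def is_methyl_bearing(self) -> bool:
        return self.aa_type in METHYL_BEARING

    @property
    def label(self) -> str:
        """Residue label in the field's convention, e.g. ``I35``."""
        return f"{self.aa_type}{self.seq_index}"

    def heavy_atoms(self) -> dict[str, np.ndarray]:
        return {n: c for n, c in self.atoms.items() if not n.startswith("H")}

    def copy(self) -> "Residue":
        return Residue(self.seq_index, self.aa_type,
                       {n: c.copy() for n, c in self.atoms.items()})


@dataclass
class StructureModel:
    model_id: int
    residues: list[Residue]
    source: str = ""

    def residue_by_index(self, seq_index: int) -> Residue:
        for r in self.residues:
            if r.seq_index == seq_index:
                return r
        raise KeyError(f"no residue with author index {seq_index}")

    @property
    def sequence(self) -> str:
        return "".join(r.aa_type for r in self.residues)

    def copy(self) -> "StructureModel":
        return StructureModel(self.model_id, [r.copy() for r in self.residues],
                              self.source)


@dataclass
class Ensemble:
    """A set of same-sequence models for one state of the domain."""

    models: list[StructureModel]
    state_label: str = ""

    def __post_init__(self) -> None:
        seqs = {m.sequence for m in self.models}
        if len(seqs) > 1:
            raise ValueError("ensemble models must share one residue sequence")

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def residue_ids(self) -> list[int]:
        return [r.seq_index for r in self.models[0].residues]

    def copy(self) -> "Ensemble":
        return Ensemble([m.copy() for m in self.models], self.state_label)


def read_structure(path, chain: str = "A",
                   models: Literal["all", "first"] = "all",
                   state_label: str = "") -> Ensemble:
    """Read a PDB file into an :class:`Ensemble`.

    One :class:`StructureModel` per MODEL record (crystal files yield one).
    Residues keep author numbering; hydrogens are retained if deposited;
    for altloc'd atoms the highest-occupancy conformer is kept (Biopython's
    default disordered-atom selection).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    out: list[StructureModel] = []
    for model in structure:
        chains = {c.id for c in model}
        if chain not in chains:
            raise ValueError(
                f"chain {chain!r} not in {path}; available chains: "
                f"{sorted(chains)}")
        residues = []
        for res in model[chain]:
            het, seq_index, _icode = res.id
            if het.strip():  # skip waters / heteroatoms
                continue
            aa3 = res.get_resname().upper()
            aa1 = _3TO1.get(aa3, "X")
            atoms = {a.get_name(): np.asarray(a.get_coord(), dtype=float)
                     for a in res}
            residues.append(Residue(seq_index, aa1, atoms))
        out.append(StructureModel(model.id, residues,
                                  source=f"{path}:{chain}"))
        if models == "first":
            break
    if not out or not out[0].residues:
        raise ValueError(f"no ATOM records for chain {chain!r} in {path}")
    return Ensemble(out, state_label=state_label)


def write_structure(ensemble: Ensemble, path, chain: str = "A") -> None:
    """Write a minimal (multi-)model PDB file."""
    multi = ensemble.n_models > 1
    with open(path, "w") as fh:
        for k, model in enumerate(ensemble.models, start=1):
            if multi:
                fh.write(f"MODEL     {k:4d}\n")
            serial = 1
            for res in model.residues:
                aa3 = _1TO3.get(res.aa_type, "UNK")
                for name, xyz in res.atoms.items():
                    pdb_name = name if len(name) == 4 else f" {name:<3s}"
                    element = name[0]
                    fh.write(
                        f"ATOM  {serial:5d} {pdb_name}{'':1s}{aa3:>3s} "
                        f"{chain}{res.seq_index:4d}    "
                        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n")
                    serial += 1
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid fit of ``mobile`` onto ``target``.

    Returns ``(R, t)`` with the convention ``fitted = mobile @ R.T + t``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    return rot, trans


def _equivalent_coords(a: StructureModel, b: StructureModel,
                       atom_selection: str) -> tuple[np.ndarray, np.ndarray]:
    xa, xb = [], []
    res_b = {r.seq_index: r for r in b.residues}
    for ra in a.residues:
        rb = res_b.get(ra.seq_index)
        if rb is None:
            continue
        if atom_selection == "CA":
            names = ["CA"] if "CA" in ra.atoms and "CA" in rb.atoms else []
        elif atom_selection == "heavy":
            names = sorted(set(ra.heavy_atoms()) & set(rb.heavy_atoms()))
        elif atom_selection == "all":
            names = sorted(set(ra.atoms) & set(rb.atoms))
        else:
            raise ValueError(f"unknown atom_selection {atom_selection!r}")
        for n in names:
            xa.append(ra.atoms[n])
            xb.append(rb.atoms[n])
    if not xa:
        raise ValueError("no common atoms between the two models")
    return np.asarray(xa), np.asarray(xb)


def rmsd_equivalent_atoms(a: StructureModel, b: StructureModel,
                          atom_selection: str = "CA",
                          superpose: bool = True) -> float:
    """RMSD between equivalent atoms of two models (Å).

    ``atom_selection`` is ``"CA"``, ``"heavy"`` or ``"all"``. With
    ``superpose`` the optimal Kabsch rotation/translation is applied first.
    """
    xa, xb = _equivalent_coords(a, b, atom_selection)
    if superpose:
        rot, trans = kabsch(xa, xb)
        xa = xa @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def transform_model(model: StructureModel, rot: np.ndarray,
                    trans: np.ndarray) -> None:
    """Apply a rigid motion to every atom of ``model`` in place."""
    for res in model.residues:
        for name in res.atoms:
            res.atoms[name] = rot @ res.atoms[name] + trans


def sequence_identity(a: str | Iterable[str], b: str | Iterable[str]) -> float:
    """Percent identity from a global alignment (match +1, affine gaps).

    Identity = matches / alignment columns, excluding terminal overhangs.
    """
    a = "".join(a)
    b = "".join(b)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    # gaps mildly penalized on the match=+1 scale; a gap must never beat a
    # mismatch (two end-to-end gaps cost more than one mismatch column)
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    # terminal overhangs are free so they can be excluded cleanly
    aligner.end_gap_score = 0.0
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # trim terminal overhang columns (gap in either sequence at the ends)
    start = 0
    end = len(sa)
    while start < end and (sa[start] == "-" or sb[start] == "-"):
        start += 1
    while end > start and (sa[end - 1] == "-" or sb[end - 1] == "-"):
        end -= 1
    cols = end - start
    if cols == 0:
        return 0.0
    matches = sum(1 for i in range(start, end) if sa[i] == sb[i]
                  and sa[i] != "-")
    return 100.0 * matches / cols


def methyl_residues(model: StructureModel) -> list[Residue]:
    """The methyl-group bearing residues (Ala/Val/Leu/Ile/Thr/Met)."""
    return [r for r in model.residues if r.is_methyl_bearing]
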