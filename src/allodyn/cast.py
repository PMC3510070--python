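"""Cluster Affinity Search Technique (CAST) on the |ΔMI| matrix.

CAST grows cliques of strongly coupled residues against an affinity
threshold t: a residue's affinity to a clique is the summed |ΔMI| coupling
to its members, and membership requires the *average* coupling to stay at
or above t. The union of non-singleton cliques is the informative group —
the set of residues predicted to take part in the binding-induced
dynamical changes. Sweeping t from high to low yields the inclusion
ranking used for the ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CastResult",
    "InclusionRanking",
    "affinity",
    "cast_cluster",
    "inclusion_ranking",
]


@dataclass
class CastResult:
    threshold: float
    cliques: list[list]            # disjoint; union = all residues
    informative_group: set = field(default_factory=set)
    affinity_trace: dict = field(default_factory=dict)


@dataclass
class InclusionRanking:
    """Residues ordered by the largest t at which each enters the group."""

    order: list                    # residue ids
    entry_threshold: dict          # residue id → t (0 if never included)


def _check_matrix(dmi: np.ndarray) -> np.ndarray:
    dmi = np.asarray(dmi, dtype=float)
    if dmi.ndim != 2 or dmi.shape[0] != dmi.shape[1]:
        raise ValueError("ΔMI matrix must be square")
    if not np.allclose(dmi, dmi.T):
        raise ValueError("ΔMI matrix must be symmetric")
    return dmi


def affinity(r: int, clique, dmi: np.ndarray) -> float:
    """a(r, C) = Σ_{c ∈ C, c ≠ r} |ΔMI(r, c)| (positional indices)."""
    return float(sum(abs(dmi[r, c]) for c in clique if c != r))


def cast_cluster(dmi: np.ndarray, t: float,
                 residue_ids: list | None = None,
                 max_rounds: int = 10000) -> CastResult:
    """Partition residues into CAST cliques at affinity threshold ``t``.

    A new cluster is seeded with the unassigned residue of maximal total
    affinity to the other unassigned residues. The algorithm then
    alternates: add the unassigned residue maximizing a(r, C) while
    a(r, C) ≥ t·|C|, and remove any member whose affinity to the rest
    falls below t·|C∖{r}|, until the clique is stable. All ties break to
    the lowest residue index, so the output is deterministic.
    """
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    dmi = np.abs(_check_matrix(dmi))
    n = dmi.shape[0]
    ids = list(residue_ids) if residue_ids is not None else list(range(n))
    unassigned = set(range(n))
    cliques: list[list[int]] = []
    trace: dict = {}
    while unassigned:
        pool = sorted(unassigned)
        totals = [affinity(r, pool, dmi) for r in pool]
        seed = pool[int(np.argmax(totals))]  # argmax takes first ⇒ lowest idx
        clique = {seed}
        unassigned.discard(seed)
        for _ in range(max_rounds):
            changed = False
            # add phase
            while True:
                cands = sorted(unassigned)
                if not cands:
                    break
                affs = [affinity(r, clique, dmi) for r in cands]
                best = int(np.argmax(affs))
                if affs[best] >= t * len(clique):
                    r = cands[best]
                    clique.add(r)
                    unassigned.discard(r)
                    trace[ids[r]] = affs[best]
                    changed = True
                else:
                    break
            # remove phase
            while len(clique) > 1:
                members = sorted(clique)
                affs = [affinity(r, clique - {r}, dmi) for r in members]
                worst = int(np.argmin(affs))
                if affs[worst] < t * (len(clique) - 1):
                    r = members[worst]
                    clique.discard(r)
                    unassigned.add(r)
                    changed = True
                else:
                    break
            if not changed:
                break
        cliques.append(sorted(clique))
    group = set()
    for c in cliques:
        if len(c) >= 2:
            group.update(ids[r] for r in c)
    return CastResult(threshold=t,
                      cliques=[[ids[r] for r in c] for c in cliques],
                      informative_group=group,
                      affinity_trace=trace)


def inclusion_ranking(dmi: np.ndarray, t_grid,
                      residue_ids: list | None = None) -> InclusionRanking:
    """First-entry threshold per residue over a descending threshold sweep.

    Residues never entering the informative group get threshold 0 and rank
    last, tie-broken by total affinity (then residue index).
    """
    t_grid = list(t_grid)
    if len(t_grid) < 2:
        raise ValueError("need a grid of at least two thresholds")
    if any(b >= a for a, b in zip(t_grid, t_grid[1:])):
        raise ValueError("threshold grid must be strictly decreasing")
    dmi = np.abs(_check_matrix(dmi))
    n = dmi.shape[0]
    ids = list(residue_ids) if residue_ids is not None else list(range(n))
    entry = {rid: 0.0 for rid in ids}
    seen: set = set()
    for t in t_grid:
        group = cast_cluster(dmi, t, residue_ids=ids).informative_group
        for rid in group - seen:
            entry[rid] = t
        seen |= group
    totals = {ids[r]: affinity(r, range(n), dmi) for r in range(n)}
    pos = {rid: i for i, rid in enumerate(ids)}
    order = sorted(ids, key=lambda rid: (-entry[rid], -totals[rid], pos[rid]))
    return InclusionRanking(order=order, entry_threshold=entry)
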