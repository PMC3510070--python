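"""Backbone flexibility from NMR ensembles and bound−unbound z-scores.

After iterative least-squares superposition of all models onto their
evolving mean, each residue's flexibility is the mean distance of its Cα
across models from the Cα centroid. Differencing the bound and unbound
profiles and standardizing gives per-residue z-scores; the flexible
terminal residues (four on each end by default) are excluded before
standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import Ensemble, kabsch, transform_model

__all__ = [
    "FlexibilityProfile",
    "DeltaFlexibility",
    "superpose_ensemble",
    "flexibility_profile",
    "delta_flex_zscores",
]


@dataclass
class FlexibilityProfile:
    residue_ids: list[int]
    flexibility: dict         # residue id → Å (residues missing Cα absent)
    state_label: str = ""


@dataclass
class DeltaFlexibility:
    residue_ids: list[int]    # included residues, ordered by author index
    delta: dict               # residue id → Δflex (bound − unbound, Å)
    zscore: dict              # residue id → z
    tier: dict                # residue id → "most" | "moderate" | "background"
    excluded: list[int]       # residues dropped (termini or missing data)


def _ca_matrix(e: Ensemble) -> tuple[np.ndarray, list[int]]:
    """(n_models, n_common, 3) Cα coordinates over residues with Cα in all
    models, plus their residue ids."""
    common = [r.seq_index for r in e.models[0].residues if "CA" in r.atoms]
    for m in e.models[1:]:
        has = {r.seq_index for r in m.residues if "CA" in r.atoms}
        common = [rid for rid in common if rid in has]
    if not common:
        raise ValueError("no residue has a Cα atom in every model")
    coords = np.array([[m.residue_by_index(rid).atoms["CA"] for rid in common]
                       for m in e.models])
    return coords, common


def superpose_ensemble(e: Ensemble, tol: float = 1e-9,
                       max_iter: int = 1000) -> Ensemble:
    """Iterative Kabsch superposition of all models onto the evolving mean.

    Models are repeatedly aligned on Cα to their evolving mean coordinates
    until the mean structure moves by less than ``tol`` Å RMSD. Starting
    from the raw coordinate mean makes the procedure idempotent: on an
    already-superposed ensemble the first alignment is the identity, so
    re-running it leaves every atom in place. Only rigid transforms are
    applied, to every atom.
    """
    if e.n_models < 2:
        raise ValueError("superposition needs at least two models")
    e = e.copy()
    coords, _ = _ca_matrix(e)
    ref = coords.mean(axis=0)
    for _ in range(max_iter):
        for k, model in enumerate(e.models):
            rot, trans = kabsch(coords[k], ref)
            transform_model(model, rot, trans)
            coords[k] = coords[k] @ rot.T + trans
        mean = coords.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((mean - ref) ** 2, axis=1))))
        ref = mean
        if shift < tol:
            break
    return e


def flexibility_profile(e: Ensemble, state_label: str | None = None
                        ) -> FlexibilityProfile:
    """Mean Cα-to-centroid distance per residue over a superposed ensemble."""
    coords, common = _ca_matrix(e)
    centroid = coords.mean(axis=0)
    dist = np.linalg.norm(coords - centroid[None], axis=2).mean(axis=0)
    return FlexibilityProfile(
        residue_ids=list(common),
        flexibility={rid: float(d) for rid, d in zip(common, dist)},
        state_label=state_label if state_label is not None else e.state_label)


def delta_flex_zscores(bound: FlexibilityProfile,
                       unbound: FlexibilityProfile,
                       n_term_excluded: int = 4,
                       c_term_excluded: int = 4,
                       tier_most: float = 2.0,
                       tier_moderate: float = 1.0) -> DeltaFlexibility:
    """Bound−unbound flexibility differences standardized to z-scores.

    The flexible terminal residues are excluded before standardization
    (population sd). Tiers: |z| ≥ 2 most significant, 1 ≤ |z| < 2 moderate,
    else background.
    """
    shared = sorted(set(bound.flexibility) & set(unbound.flexibility))
    if c_term_excluded > 0:
        included = shared[n_term_excluded:len(shared) - c_term_excluded]
    else:
        included = shared[n_term_excluded:]
    if len(included) < 3:
        raise ValueError("fewer than 3 residues left after terminal exclusion")
    excluded = [rid for rid in shared if rid not in set(included)]
    delta = np.array([bound.flexibility[r] - unbound.flexibility[r]
                      for r in included])
    sd = float(delta.std())  # population sd
    if sd == 0.0:
        raise ValueError("degenerate ensembles: flexibility differences have "
                         "zero variance, z-scores undefined")
    z = (delta - delta.mean()) / sd
    tiers = {}
    for rid, zi in zip(included, z):
        if abs(zi) >= tier_most:
            tiers[rid] = "most"
        elif abs(zi) >= tier_moderate:
            tiers[rid] = "moderate"
        else:
            tiers[rid] = "background"
    return DeltaFlexibility(
        residue_ids=list(included),
        delta={r: float(d) for r, d in zip(included, delta)},
        zscore={r: float(zi) for r, zi in zip(included, z)},
        tier=tiers,
        excluded=excluded)
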