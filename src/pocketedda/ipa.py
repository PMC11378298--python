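"""In-pocket analysis: hydrogen-only refinement and per-residue maps.

Each ligand–residue pair is treated as a supermolecule.  Hydrogen
positions (the only coordinates an X-ray structure leaves genuinely
uncertain at typical resolution) are relaxed by local minimization with
every heavy atom frozen; the pair interaction energy is then computed
and collected into an :class:`~pocketedda.maps.InteractionMap` with
componentwise sums.

Pairs are refined independently from the original pocket geometry —
the pairwise partition of the analysis is preserved — and the monomer
energies of the supermolecule formula keep the pair-refined hydrogen
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import (BackendConfig, EnergyComponents, pair_interaction_energy,
                     total_energy_and_gradient)
from .errors import ArgumentError, GeometryError, PocketEddaError
from .external import external_engine_energy
from .maps import InteractionMap, PairInteraction
from .pocket import PocketModel, enumerate_pairs
from .records import Fragment, merge_fragments

FD_STEP = 1e-4  # Å, central-difference step for external-engine gradients


@dataclass
class RefineResult:
    """Outcome of a hydrogen refinement."""

    fragment: Fragment
    initial_energy: float
    final_energy: float
    n_steps: int
    converged: bool


def _energy_grad(fragment: Fragment, mobile: np.ndarray,
                 config: BackendConfig):
    """Energy and gradient restricted to mobile atoms, per backend."""
    if config.engine == "classical":
        e, g = total_energy_and_gradient(fragment, config)
        g[~mobile] = 0.0
        return e, g
    # external engine: central finite differences on mobile coordinates
    e0 = external_engine_energy(fragment, config)
    g = np.zeros((len(fragment.atoms), 3))
    for i in np.flatnonzero(mobile):
        for k in range(3):
            orig = fragment.atoms[i].coords[k]
            fragment.atoms[i].coords[k] = orig + FD_STEP
            ep = external_engine_energy(fragment, config)
            fragment.atoms[i].coords[k] = orig - FD_STEP
            em = external_engine_energy(fragment, config)
            fragment.atoms[i].coords[k] = orig
            g[i, k] = (ep - em) / (2.0 * FD_STEP)
    return e0, g


def _descend(fragment: Fragment, mobile: np.ndarray, config: BackendConfig,
             tol: float, max_iter: int) -> RefineResult:
    """Gradient descent with backtracking line search on mobile atoms.

    Deterministic, strictly monotone: a step is accepted only if it
    lowers the energy (Armijo condition); otherwise the step halves.
    Immobile coordinates are never touched.
    """
    frag = fragment.copy()
    e, g = _energy_grad(frag, mobile, config)
    if not np.isfinite(e):
        raise GeometryError("non-finite energy at refinement start")
    n_accepted = 0
    converged = False
    e_init = e
    for _ in range(max_iter):
        gnorm2 = float(np.sum(g * g))
        if gnorm2 == 0.0:
            converged = True
            break
        alpha = 1.0 / max(1.0, np.sqrt(gnorm2))
        accepted = False
        for _ in range(40):
            trial = frag.copy()
            for i in np.flatnonzero(mobile):
                trial.atoms[i].coords = frag.atoms[i].coords - alpha * g[i]
            try:
                e_new, g_new = _energy_grad(trial, mobile, config)
            except GeometryError:
                alpha *= 0.5
                continue
            if np.isfinite(e_new) and e_new <= e - 1e-4 * alpha * gnorm2:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            converged = True
            break
        de = e - e_new
        frag, e, g = trial, e_new, g_new
        n_accepted += 1
        if de < tol:
            converged = True
            break
    return RefineResult(fragment=frag, initial_energy=e_init,
                        final_energy=e, n_steps=n_accepted,
                        converged=converged)


def refine_hydrogens(union: Fragment, config: BackendConfig,
                     tol: float = 1e-6, max_iter: int = 500) -> RefineResult:
    """Relax mobile hydrogens of a pair supermolecule, heavy atoms frozen.

    The energy is non-increasing across accepted steps; termination on
    an energy change below ``tol`` (kcal/mol) or ``max_iter`` steps.
    Deterministic given the input atom order.
    """
    mobile = np.array([a.mobile for a in union.atoms])
    if not mobile.any():
        raise ArgumentError("no mobile hydrogens to refine")
    for i in np.flatnonzero(mobile):
        if not union.atoms[i].is_hydrogen:
            raise ArgumentError("mobile flag set on a heavy atom")
    return _descend(union, mobile, config, tol, max_iter)


def minimize_all_atoms(fragment: Fragment, config: BackendConfig,
                       tol: float = 1e-6,
                       max_iter: int = 2000) -> RefineResult:
    """Full relaxation (all atoms mobile); classical backend only.

    Used to build the reference conformer for deformation energies when
    the user supplies none.
    """
    if config.engine != "classical":
        raise ArgumentError(
            "full minimization requires the classical backend")
    mobile = np.ones(len(fragment.atoms), dtype=bool)
    return _descend(fragment, mobile, config, tol, max_iter)


def in_pocket_analysis(pocket: PocketModel, config: BackendConfig,
                       refine: bool = False,
                       mode_label: str = "") -> InteractionMap:
    """Per-residue interaction map of a pocket.

    For each ligand–residue pair: optionally refine hydrogens on the
    pair supermolecule, then evaluate the pair interaction energy.  The
    map carries per-residue records and their componentwise sum.
    Backend errors are re-raised annotated with the residue label.
    """
    pairs = enumerate_pairs(pocket)
    records = []
    for pc in pairs:
        ligand, residue = pc.ligand, pc.residue
        refined = False
        try:
            if refine:
                union = merge_fragments(ligand, residue)
                if any(a.mobile for a in union.atoms):
                    res = refine_hydrogens(union, config)
                    n_lig = len(ligand.atoms)
                    ligand = Fragment(
                        label=ligand.label,
                        atoms=res.fragment.atoms[:n_lig],
                        formal_charge=ligand.formal_charge,
                        source_residue_ids=ligand.source_residue_ids,
                        topology=ligand.topology)
                    residue = Fragment(
                        label=residue.label,
                        atoms=res.fragment.atoms[n_lig:],
                        formal_charge=residue.formal_charge,
                        source_residue_ids=residue.source_residue_ids,
                        topology=residue.topology)
                    refined = True
            if config.engine == "classical":
                comp = pair_interaction_energy(ligand, residue, config)
            else:
                e_union = external_engine_energy(
                    merge_fragments(ligand, residue), config)
                e_l = external_engine_energy(ligand, config)
                e_r = external_engine_energy(residue, config)
                # components other than the total are unavailable here
                comp = EnergyComponents(total=e_union - e_l - e_r)
        except PocketEddaError as exc:
            raise type(exc)(
                f"[residue {residue.label}] {exc}") from exc
        ids = residue.source_residue_ids
        records.append(PairInteraction(
            residue_label=residue.label, components=comp,
            closest_contact=pc.closest_contact, refined=refined,
            chain=ids[0][0] if ids else "",
            resnum=ids[0][1] if ids else None))
    imap = InteractionMap(mode_label=mode_label, pairs=records)
    imap.recompute_sum()
    return imap
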