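"""Energy decomposition and deconvolution across binding modes.

A *binding mode* is a pocket in which the same protein fragments face a
different ligand pose (here, typically a ring flipped by 180°, the
classic planar-group ambiguity of medium-resolution electron density).
The decomposition ledger per mode contains

* the per-residue interaction map, split by physical force,
* the pocket-level desolvation (supermolecule generalized-Born term of
  the whole pocket minus all monomers),
* the ligand deformation (strain) energy, and
* a score = summed interaction + desolvation + deformation.

Comparing two modes yields per-residue, per-component deltas (A − B)
and a verdict: "dual" when the score gap is within a near-degeneracy
threshold (0.5 kcal/mol by default), else the preferred mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .energy import (BackendConfig, EnergyComponents, fragment_energy,
                     gb_cross)
from .errors import ArgumentError, ComparisonError
from .external import external_engine_energy
from .ipa import in_pocket_analysis, minimize_all_atoms
from .maps import InteractionMap
from .pocket import PocketModel
from .records import Fragment


@dataclass
class BindingMode:
    """A labeled ligand pose inside a fixed protein pocket."""

    label: str
    pocket: PocketModel


@dataclass
class ModeResult:
    """Single-mode decomposition ledger."""

    label: str
    map: InteractionMap
    interaction: float        # gas-phase cross terms summed, kcal/mol
    desolvation: float        # pocket-level GB supermolecule term
    deformation: float        # ligand strain vs reference conformer
    score: float              # interaction + desolvation + deformation
    unavailable: list = field(default_factory=list)

    def check(self, tol: float = 1e-9) -> None:
        if abs(self.interaction + self.desolvation + self.deformation
               - self.score) > tol:
            raise ArgumentError("mode score inconsistent with its parts")


@dataclass
class EDDAReport:
    """Decomposition of one or two binding modes plus their comparison."""

    modes: dict                      # label -> ModeResult
    deltas: dict = field(default_factory=dict)   # residue -> EnergyComponents
    total_delta: Optional[float] = None          # score(A) − score(B)
    verdict: Optional[str] = None
    threshold: float = 0.5


def deformation_energy(bound: Fragment, reference: Optional[Fragment],
                       config: BackendConfig) -> float:
    """Ligand strain: E_intra(bound) − E_intra(reference), kcal/mol.

    With ``reference=None`` the reference conformer is generated by
    minimizing the bound pose with all atoms mobile (classical backend
    only), making the result non-negative up to convergence noise.
    """
    if reference is not None and len(reference.atoms) != len(bound.atoms):
        raise ArgumentError(
            f"conformers differ in atom count "
            f"({len(bound.atoms)} vs {len(reference.atoms)})")
    if reference is None:
        reference = minimize_all_atoms(bound, config).fragment
    if config.engine == "classical":
        return (fragment_energy(bound, config).total
                - fragment_energy(reference, config).total)
    return (external_engine_energy(bound, config)
            - external_engine_energy(reference, config))


def _pocket_desolvation(pocket: PocketModel, config: BackendConfig) -> dict:
    """Supermolecule GB desolvation of the whole pocket, distributed.

    The GB model is strictly pairwise, so the pocket-level term is the
    sum of fragment-pair cross terms.  Residue r's (approximate) share
    is its ligand cross term plus half of each residue–residue term it
    participates in; shares sum exactly to the pocket-level total.
    """
    frags = pocket.residues
    shares = {f.label: gb_cross(pocket.ligand, f, config) for f in frags}
    for i in range(len(frags)):
        for j in range(i + 1, len(frags)):
            c = gb_cross(frags[i], frags[j], config)
            shares[frags[i].label] += 0.5 * c
            shares[frags[j].label] += 0.5 * c
    return shares


def edda_decompose(mode: BindingMode, config: BackendConfig,
                   refine: bool = False,
                   reference_conformer: Optional[Fragment] = None,
                   compute_deformation: bool = True) -> ModeResult:
    """Decompose one binding mode into its component ledger.

    Per-residue desolvation in the returned map is replaced by the
    pocket-level shares (see :func:`_pocket_desolvation`), so the map's
    summed desolvation equals the pocket supermolecule term and the
    component sums reproduce the score exactly.
    """
    imap = in_pocket_analysis(mode.pocket, config, refine=refine,
                              mode_label=mode.label)
    unavailable = []
    if config.engine == "classical":
        shares = _pocket_desolvation(mode.pocket, config)
        for p in imap.pairs:
            c = p.components
            p.components = EnergyComponents.from_parts(
                electrostatic=c.electrostatic, dispersion=c.dispersion,
                repulsion=c.repulsion, hbond=c.hbond,
                desolvation=shares[p.residue_label], bonded=c.bonded)
        imap.recompute_sum()
        desolv = imap.summed.desolvation
        interaction = imap.summed.total - desolv
    else:
        unavailable = ["electrostatic", "dispersion", "repulsion",
                       "hbond", "per-residue desolvation"]
        desolv = 0.0   # folded into the engine totals
        interaction = imap.summed.total
    deformation = 0.0
    if compute_deformation:
        deformation = deformation_energy(mode.pocket.ligand,
                                         reference_conformer, config)
    score = interaction + desolv + deformation
    return ModeResult(label=mode.label, map=imap, interaction=interaction,
                      desolvation=desolv, deformation=deformation,
                      score=score, unavailable=unavailable)


def _check_identical_residues(a: PocketModel, b: PocketModel) -> None:
    mismatched = []
    if len(a.residues) != len(b.residues):
        raise ComparisonError(
            f"modes have {len(a.residues)} vs {len(b.residues)} residues")
    for fa, fb in zip(a.residues, b.residues):
        same = (fa.label == fb.label and len(fa.atoms) == len(fb.atoms)
                and all(x.element == y.element
                        for x, y in zip(fa.atoms, fb.atoms))
                and np.allclose(fa.coords, fb.coords, atol=1e-8))
        if not same:
            mismatched.append(fa.label)
    if mismatched:
        raise ComparisonError(
            f"residue fragments differ between modes: {mismatched}")


def compare_binding_modes(mode_a: BindingMode, mode_b: BindingMode,
                          config: BackendConfig, threshold: float = 0.5,
                          refine: bool = False,
                          reference_conformer: Optional[Fragment] = None,
                          compute_deformation: bool = True) -> EDDAReport:
    """Comparative decomposition of two binding modes (A − B).

    Both modes must share identical residue fragments atom-for-atom.
    The verdict is "dual" when |score(A) − score(B)| is within the
    near-degeneracy threshold, else the label of the preferred (lower
    scoring) mode.
    """
    _check_identical_residues(mode_a.pocket, mode_b.pocket)
    ra = edda_decompose(mode_a, config, refine=refine,
                        reference_conformer=reference_conformer,
                        compute_deformation=compute_deformation)
    rb = edda_decompose(mode_b, config, refine=refine,
                        reference_conformer=reference_conformer,
                        compute_deformation=compute_deformation)
    by_a, by_b = ra.map.by_residue(), rb.map.by_residue()
    deltas = {label: by_a[label].components - by_b[label].components
              for label in by_a}
    total_delta = ra.score - rb.score
    if abs(total_delta) <= threshold:
        verdict = "dual"
    else:
        verdict = mode_a.label if total_delta < 0 else mode_b.label
    return EDDAReport(modes={ra.label: ra, rb.label: rb}, deltas=deltas,
                      total_delta=total_delta, verdict=verdict,
                      threshold=threshold)


def report_to_dict(report: EDDAReport) -> dict:
    """JSON-serializable form of an EDDA report."""
    out = {"modes": {}, "threshold": report.threshold,
           "verdict": report.verdict, "total_delta": report.total_delta}
    for label, mr in report.modes.items():
        out["modes"][label] = {
            "interaction": mr.interaction,
            "desolvation": mr.desolvation,
            "deformation": mr.deformation,
            "score": mr.score,
            "unavailable_components": mr.unavailable,
            "residues": {p.residue_label: p.components.as_dict()
                         for p in mr.map.pairs},
        }
    out["deltas"] = {label: c.as_dict() for label, c in report.deltas.items()}
    return out
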