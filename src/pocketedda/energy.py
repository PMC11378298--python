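"""Classical energy backend: nonbonded + generalized-Born solvation.

Implements the energy contract used by the in-pocket analysis (IPA) and
the energy decomposition (EDDA): per-component fragment energies and
supermolecule pair interaction energies

    E_int = E(L ∪ R) − E(L) − E(R)

which, for this strictly pairwise backend, reduce to direct
cross-fragment atom-pair sums.  Components:

* electrostatic — Coulomb, k_e·q_i·q_j/(ε_in·r)
* dispersion    — attractive Lennard-Jones branch, −4ε(σ/r)⁶
* repulsion     — repulsive branch, +4ε(σ/r)¹²
* hbond         — electrostatic + LJ of H···acceptor pairs whose
  X–H···A geometry passes the hydrogen-bond gates (reattributed, so the
  total is independent of the gates)
* desolvation   — generalized-Born polarization (Still-type effective
  radii), ΔG_pol = −½·k_e·(1/ε_in − 1/ε_out)·Σ_ij q_i q_j / f_GB with
  f_GB = sqrt(r² + a_i a_j exp(−r²/(4 a_i a_j)))
* bonded        — toy harmonic bond terms ½k(r−r0)² when a topology is
  attached

Lennard-Jones cross parameters use Lorentz–Berthelot combining rules.
No cutoffs or neighbor lists: exact double sums over small pockets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ArgumentError, GeometryError, ParameterError
from .records import Fragment, Topology, merge_fragments

COULOMB_K = 332.0637          # kcal·Å/(mol·e²)
HARTREE_TO_KCAL = 627.5095
MIN_CONTACT = 0.1             # Å; closer cross-fragment atoms are an error
HBOND_ACCEPTORS = {"N", "O", "S"}


@dataclass
class EnergyComponents:
    """Energy split by physical force, kcal/mol.  total = sum of parts."""

    electrostatic: float = 0.0
    dispersion: float = 0.0
    repulsion: float = 0.0
    hbond: float = 0.0
    desolvation: float = 0.0
    bonded: float = 0.0
    total: float = 0.0

    FIELDS = ("electrostatic", "dispersion", "repulsion", "hbond",
              "desolvation", "bonded")

    @classmethod
    def from_parts(cls, **kw) -> "EnergyComponents":
        obj = cls(**kw)
        obj.total = sum(getattr(obj, f) for f in cls.FIELDS)
        return obj

    def check(self, tol: float = 1e-9) -> None:
        s = sum(getattr(self, f) for f in self.FIELDS)
        if abs(s - self.total) > tol:
            raise ArgumentError(
                f"component sum {s} differs from total {self.total}")

    def __add__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(
            **{f: getattr(self, f) + getattr(other, f)
               for f in self.FIELDS},
            total=self.total + other.total)

    def __sub__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(
            **{f: getattr(self, f) - getattr(other, f)
               for f in self.FIELDS},
            total=self.total - other.total)

    def __neg__(self) -> "EnergyComponents":
        return EnergyComponents(
            **{f: -getattr(self, f) for f in self.FIELDS}, total=-self.total)

    def as_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.FIELDS}
        d["total"] = self.total
        return d


@dataclass
class BackendConfig:
    """Parameters of the energy model and engine selection."""

    coulomb_constant: float = COULOMB_K
    interior_dielectric: float = 1.0
    solvent_dielectric: float = 78.5
    hbond_distance: float = 2.5        # H···A gate, Å
    hbond_angle: float = 120.0         # D–H···A gate, degrees
    engine: str = "classical"          # {"classical", "external"}
    external_command: Optional[str] = None   # template; {xyz} placeholder
    external_pattern: Optional[str] = None   # regex with one float group
    solvation: bool = True

    def __post_init__(self):
        if self.interior_dielectric < 1 or self.solvent_dielectric < 1:
            raise ArgumentError("dielectric constants must be >= 1")
        if self.hbond_distance <= 0:
            raise ArgumentError("hbond_distance must be > 0")
        if self.engine not in ("classical", "external"):
            raise ArgumentError(f"unknown engine {self.engine!r}")

    @property
    def gb_prefactor(self) -> float:
        """−½·k_e·(1/ε_in − 1/ε_out); zero when solvation is disabled."""
        if not self.solvation:
            return 0.0
        tau = 1.0 / self.interior_dielectric - 1.0 / self.solvent_dielectric
        return -0.5 * self.coulomb_constant * tau


def _require_params(fragment: Fragment) -> None:
    for i, a in enumerate(fragment.atoms):
        if a.lj_epsilon is None or a.lj_sigma is None or a.born_radius is None:
            raise ParameterError(
                f"unresolved parameters for atom {i} ({a.name}) in "
                f"fragment {fragment.label!r}")


def gb_polarization(fragment: Fragment, config: BackendConfig) -> float:
    """Total GB polarization energy of a fragment (self + pair terms)."""
    pref = config.gb_prefactor
    if pref == 0.0:
        return 0.0
    q = fragment.charges
    a = np.array([at.born_radius for at in fragment.atoms])
    x = fragment.coords
    r2 = cdist(x, x) ** 2
    aij = np.outer(a, a)
    f = np.sqrt(r2 + aij * np.exp(-r2 / (4.0 * aij)))
    return pref * float(np.sum(np.outer(q, q) / f))


def gb_cross(a: Fragment, b: Fragment, config: BackendConfig) -> float:
    """GB polarization cross term: ΔG_pol(A∪B) − ΔG_pol(A) − ΔG_pol(B)."""
    pref = config.gb_prefactor
    if pref == 0.0:
        return 0.0
    qa, qb = a.charges, b.charges
    ra = np.array([at.born_radius for at in a.atoms])
    rb = np.array([at.born_radius for at in b.atoms])
    r2 = cdist(a.coords, b.coords) ** 2
    aij = np.outer(ra, rb)
    f = np.sqrt(r2 + aij * np.exp(-r2 / (4.0 * aij)))
    # ordered pairs (i∈A, j∈B) and (j, i) both appear in the union sum
    return pref * 2.0 * float(np.sum(np.outer(qa, qb) / f))


def _bonded_energy(fragment: Fragment) -> float:
    if fragment.topology is None:
        return 0.0
    e = 0.0
    x = fragment.coords
    for i, j, k, r0 in fragment.topology.bonds:
        r = float(np.linalg.norm(x[i] - x[j]))
        e += 0.5 * k * (r - r0) ** 2
    return e


def fragment_energy(fragment: Fragment, config: BackendConfig) -> EnergyComponents:
    """Intrafragment energy: nonbonded + bonded + GB polarization.

    Nonbonded pairs closer than 3 bonds are excluded when a topology is
    attached; with no topology every pair interacts.
    """
    _require_params(fragment)
    n = len(fragment.atoms)
    excl = (fragment.topology.excluded_pairs(n)
            if fragment.topology is not None else set())
    x = fragment.coords
    q = fragment.charges
    eps = np.array([a.lj_epsilon for a in fragment.atoms])
    sig = np.array([a.lj_sigma for a in fragment.atoms])
    ke = config.coulomb_constant / config.interior_dielectric

    elec = disp = rep = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            r = float(np.linalg.norm(x[i] - x[j]))
            if r < MIN_CONTACT:
                raise GeometryError(
                    f"nonbonded atoms {i} and {j} of fragment "
                    f"{fragment.label!r} overlap (r = {r:.3f} Å)")
            elec += ke * q[i] * q[j] / r
            eij = math.sqrt(eps[i] * eps[j])
            if eij > 0:
                s6 = ((sig[i] + sig[j]) / (2.0 * r)) ** 6
                disp += -4.0 * eij * s6
                rep += 4.0 * eij * s6 * s6
    return EnergyComponents.from_parts(
        electrostatic=elec, dispersion=disp, repulsion=rep,
        desolvation=gb_polarization(fragment, config),
        bonded=_bonded_energy(fragment))


def _donor_index(fragment: Fragment, h_index: int) -> Optional[int]:
    """Heavy atom covalently carrying hydrogen ``h_index``.

    With a topology: the bonded heavy neighbor.  Without: the nearest
    heavy atom, preferring one within covalent range (1.3 Å).
    """
    atoms = fragment.atoms
    if fragment.topology is not None:
        for i, j, _, _ in fragment.topology.bonds:
            if i == h_index and not atoms[j].is_hydrogen:
                return j
            if j == h_index and not atoms[i].is_hydrogen:
                return i
    best, best_r = None, math.inf
    xh = atoms[h_index].coords
    for i, a in enumerate(atoms):
        if a.is_hydrogen:
            continue
        r = float(np.linalg.norm(a.coords - xh))
        if r < best_r:
            best, best_r = i, r
    return best  # nearest heavy atom; fragments are covalent units


def _hbond_gated(donor_frag: Fragment, h_idx: int,
                 acceptor_frag: Fragment, a_idx: int,
                 config: BackendConfig) -> bool:
    """True if X–H···A passes the geometric hydrogen-bond gates."""
    h = donor_frag.atoms[h_idx]
    acc = acceptor_frag.atoms[a_idx]
    if not h.is_hydrogen or acc.element not in HBOND_ACCEPTORS:
        return False
    d_ha = float(np.linalg.norm(h.coords - acc.coords))
    if d_ha > config.hbond_distance:
        return False
    x_idx = _donor_index(donor_frag, h_idx)
    if x_idx is None:
        return False
    v1 = donor_frag.atoms[x_idx].coords - h.coords
    v2 = acc.coords - h.coords
    denom = float(np.linalg.norm(v1) * np.linalg.norm(v2))
    if denom == 0.0:
        return False
    cosang = float(np.dot(v1, v2)) / denom
    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    return angle >= config.hbond_angle


def pair_interaction_energy(ligand: Fragment, residue: Fragment,
                            config: BackendConfig) -> EnergyComponents:
    """Supermolecule interaction energy of two atom-disjoint fragments.

    For the pairwise classical model this is the direct cross-fragment
    sum; hydrogen-bond-gated H···acceptor pairs are reported under
    ``hbond`` instead of electrostatic/dispersion/repulsion, leaving the
    total unchanged.
    """
    _require_params(ligand)
    _require_params(residue)
    ke = config.coulomb_constant / config.interior_dielectric
    xa, xb = ligand.coords, residue.coords
    qa, qb = ligand.charges, residue.charges
    elec = disp = rep = hb = 0.0
    for i, ai in enumerate(ligand.atoms):
        for j, bj in enumerate(residue.atoms):
            r = float(np.linalg.norm(xa[i] - xb[j]))
            if r < MIN_CONTACT:
                raise GeometryError(
                    f"cross-fragment overlap between atom {i} of "
                    f"{ligand.label!r} and atom {j} of {residue.label!r} "
                    f"(r = {r:.3f} Å)")
            e_el = ke * qa[i] * qb[j] / r
            eij = math.sqrt(ai.lj_epsilon * bj.lj_epsilon)
            e_disp = e_rep = 0.0
            if eij > 0:
                s6 = ((ai.lj_sigma + bj.lj_sigma) / (2.0 * r)) ** 6
                e_disp = -4.0 * eij * s6
                e_rep = 4.0 * eij * s6 * s6
            gated = (_hbond_gated(ligand, i, residue, j, config)
                     or _hbond_gated(residue, j, ligand, i, config))
            if gated:
                hb += e_el + e_disp + e_rep
            else:
                elec += e_el
                disp += e_disp
                rep += e_rep
    return EnergyComponents.from_parts(
        electrostatic=elec, dispersion=disp, repulsion=rep, hbond=hb,
        desolvation=gb_cross(ligand, residue, config))


# ---------------------------------------------------------------------------
# Energy + analytic gradient over a single atom set (used by refinement
# and by full minimization for deformation references).
# ---------------------------------------------------------------------------

def total_energy_and_gradient(fragment: Fragment, config: BackendConfig):
    """Total classical energy of a fragment and its Cartesian gradient.

    Uses the fragment_energy model (nonbonded with topology exclusions,
    bonded terms, GB polarization).  Returns ``(energy, gradient)`` with
    gradient shaped (n_atoms, 3), kcal/mol/Å.  The hydrogen-bond gates
    do not enter: reattribution conserves the total by construction.
    """
    _require_params(fragment)
    n = len(fragment.atoms)
    excl = (fragment.topology.excluded_pairs(n)
            if fragment.topology is not None else set())
    x = fragment.coords
    q = fragment.charges
    eps = np.array([a.lj_epsilon for a in fragment.atoms])
    sig = np.array([a.lj_sigma for a in fragment.atoms])
    born = np.array([a.born_radius for a in fragment.atoms])
    ke = config.coulomb_constant / config.interior_dielectric
    pref = config.gb_prefactor

    energy = 0.0
    grad = np.zeros((n, 3))

    # GB self terms (constant in coordinates)
    if pref != 0.0:
        energy += pref * float(np.sum(q * q / born))

    for i in range(n):
        for j in range(i + 1, n):
            u = x[i] - x[j]
            r = float(np.linalg.norm(u))
            if r == 0.0:
                raise GeometryError(
                    f"atoms {i}/{j} coincide during energy evaluation")
            uhat = u / r
            if (i, j) not in excl:
                if r < MIN_CONTACT:
                    raise GeometryError(
                        f"nonbonded atoms {i}/{j} overlap during "
                        f"energy evaluation")
                e_el = ke * q[i] * q[j] / r
                energy += e_el
                de = -e_el / r
                eij = math.sqrt(eps[i] * eps[j])
                if eij > 0:
                    sij = (sig[i] + sig[j]) / 2.0
                    s6 = (sij / r) ** 6
                    energy += 4.0 * eij * (s6 * s6 - s6)
                    de += 4.0 * eij * (-12.0 * s6 * s6 + 6.0 * s6) / r
                g = de * uhat
                grad[i] += g
                grad[j] -= g
            if pref != 0.0:
                aij = born[i] * born[j]
                expo = math.exp(-r * r / (4.0 * aij))
                f = math.sqrt(r * r + aij * expo)
                # ordered pairs (i,j) and (j,i): factor 2
                e_gb = pref * 2.0 * q[i] * q[j] / f
                energy += e_gb
                dfdr = r * (1.0 - expo / 4.0) / f
                de_gb = -e_gb / f * dfdr
                g = de_gb * uhat
                grad[i] += g
                grad[j] -= g

    if fragment.topology is not None:
        for i, j, k, r0 in fragment.topology.bonds:
            u = x[i] - x[j]
            r = float(np.linalg.norm(u))
            energy += 0.5 * k * (r - r0) ** 2
            if r > 0:
                g = k * (r - r0) * (u / r)
                grad[i] += g
                grad[j] -= g

    return energy, grad
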