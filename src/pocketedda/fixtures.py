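"""Desk-scale synthetic pockets with closed-form energetics.

These generators stand in for a crystallographic binding pocket: a
planar five-site ring "ligand" surrounded by a few small residue-like
fragments (point ions, water-like, methylamine-like) at chosen radial
distances.  Every fragment carries full backend parameters, and the
generator records the closed-form expected Coulomb energies alongside
the geometry, so each pipeline stage can be checked without any
external file.

The *flip fixture* mimics the planar-ring ambiguity of real electron
density (an oxadiazole-style group readable in two 180°-flipped
orientations): the same residues face the ring in its original and
flipped pose.  The pentagon is mirror-symmetric as a point set, so
with a mirror-symmetric charge pattern the two modes are exactly
degenerate; a charge asymmetry ±ε on the mirror-paired sites produces
an inter-mode energy difference with a closed form recorded alongside.

:func:`brute_force_pair_energy` is the independent oracle for
:func:`~pocketedda.energy.pair_interaction_energy`: a naive pure-Python
double loop with no shared code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .edda import BindingMode
from .energy import BackendConfig, EnergyComponents, HBOND_ACCEPTORS
from .errors import ArgumentError
from .pocket import PocketModel
from .records import AtomRecord, Fragment

DEFAULT_SEED = 20240819
RING_RADIUS = 1.2          # Å
MIN_PLACEMENT = 2.2        # Å between residue centers and to the ring
# mirror-symmetric base pattern: sites 1/4 and 2/3 are the mirror pairs
DEFAULT_RING_CHARGES = (0.0, 0.25, -0.25, -0.25, 0.25)

ARCHETYPES = ("point-ion", "cation", "anion", "water-like",
              "methylamine-like")


@dataclass
class FixtureSpec:
    """Recipe for a deterministic toy pocket."""

    n_residues: int = 3
    distances: Optional[List[float]] = None       # Å from ligand center
    archetypes: Optional[List[str]] = None
    directions: Optional[List[Tuple[float, float, float]]] = None
    ligand_charges: Tuple[float, ...] = DEFAULT_RING_CHARGES
    asymmetry: float = 0.0                        # e, on the mirror pair
    seed: int = DEFAULT_SEED
    lj: bool = True                               # False → all ε = 0

    def __post_init__(self):
        if self.distances is None:
            self.distances = [3.5 + 1.0 * i for i in range(self.n_residues)]
        if self.archetypes is None:
            cycle = ["point-ion", "water-like", "methylamine-like"]
            self.archetypes = [cycle[i % 3] for i in range(self.n_residues)]
        if len(self.distances) != self.n_residues:
            raise ArgumentError("one distance per residue required")
        if len(self.archetypes) != self.n_residues:
            raise ArgumentError("one archetype per residue required")
        for a in self.archetypes:
            if a not in ARCHETYPES:
                raise ArgumentError(f"unknown archetype {a!r}")
        if len(self.ligand_charges) != 5:
            raise ArgumentError("ligand archetype has exactly 5 sites")
        if any(d <= RING_RADIUS + 1.0 for d in self.distances):
            raise ArgumentError(
                f"residue distance below the contact threshold "
                f"({RING_RADIUS + 1.0:.1f} Å)")


def _ring_ligand(charges, lj: bool, asymmetry: float = 0.0) -> Fragment:
    """Planar five-site ring in the xy-plane, one vertex on +x."""
    q = list(charges)
    q[1] += asymmetry
    q[4] -= asymmetry
    atoms = []
    for i in range(5):
        ang = math.radians(72.0 * i)
        atoms.append(AtomRecord(
            element="C", name=f"C{i + 1}",
            coords=(RING_RADIUS * math.cos(ang),
                    RING_RADIUS * math.sin(ang), 0.0),
            charge=q[i],
            lj_epsilon=0.05 if lj else 0.0, lj_sigma=3.4, born_radius=1.7))
    total = sum(q)
    return Fragment(label="LIG", atoms=atoms,
                    formal_charge=int(round(total)))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _build_archetype(name: str, center: np.ndarray, index: int,
                     rng: np.random.Generator, lj: bool) -> Fragment:
    eps = (lambda e: e if lj else 0.0)
    label = f"RES{index + 1}"
    if name in ("point-ion", "cation", "anion"):
        if name == "point-ion":
            q = 1.0 if index % 2 == 0 else -1.0
        else:
            q = 1.0 if name == "cation" else -1.0
        elem = "Na" if q > 0 else "Cl"
        atom = AtomRecord(element=elem, name=elem.upper(), coords=center,
                          charge=q, lj_epsilon=eps(0.1), lj_sigma=3.3,
                          born_radius=2.0)
        return Fragment(label=label, atoms=[atom],
                        formal_charge=int(q))
    if name == "water-like":
        # O with two H at 0.96 Å, 104.5° apart, randomly oriented
        b1 = _unit(rng.normal(size=3))
        tmp = rng.normal(size=3)
        perp = _unit(tmp - np.dot(tmp, b1) * b1)
        half = math.radians(104.5 / 2.0)
        h1 = center + 0.96 * (math.cos(half) * b1 + math.sin(half) * perp)
        h2 = center + 0.96 * (math.cos(half) * b1 - math.sin(half) * perp)
        atoms = [
            AtomRecord("O", "O", center, charge=-0.8,
                       lj_epsilon=eps(0.21), lj_sigma=2.96, born_radius=1.52),
            AtomRecord("H", "H1", h1, charge=0.4, lj_epsilon=eps(0.0157),
                       lj_sigma=2.65, born_radius=1.2, mobile=True),
            AtomRecord("H", "H2", h2, charge=0.4, lj_epsilon=eps(0.0157),
                       lj_sigma=2.65, born_radius=1.2, mobile=True),
        ]
        return Fragment(label=label, atoms=atoms, formal_charge=0)
    # methylamine-like: N(H2)–C, four sites
    b1 = _unit(rng.normal(size=3))
    tmp = rng.normal(size=3)
    perp = _unit(tmp - np.dot(tmp, b1) * b1)
    c = center + 1.47 * b1
    h1 = center + 1.01 * _unit(-b1 + 0.9 * perp)
    h2 = center + 1.01 * _unit(-b1 - 0.9 * perp)
    atoms = [
        AtomRecord("N", "N", center, charge=-0.6, lj_epsilon=eps(0.17),
                   lj_sigma=3.25, born_radius=1.55),
        AtomRecord("C", "C", c, charge=0.0, lj_epsilon=eps(0.086),
                   lj_sigma=3.4, born_radius=1.7),
        AtomRecord("H", "HN1", h1, charge=0.3, lj_epsilon=eps(0.0157),
                   lj_sigma=2.65, born_radius=1.2, mobile=True),
        AtomRecord("H", "HN2", h2, charge=0.3, lj_epsilon=eps(0.0157),
                   lj_sigma=2.65, born_radius=1.2, mobile=True),
    ]
    return Fragment(label=label, atoms=atoms, formal_charge=0)


def _closed_form_coulomb(ligand: Fragment, residue: Fragment,
                         coulomb_k: float) -> float:
    """Independent Coulomb sum: plain math, no backend code."""
    e = 0.0
    for a in ligand.atoms:
        for b in residue.atoms:
            dx = a.coords[0] - b.coords[0]
            dy = a.coords[1] - b.coords[1]
            dz = a.coords[2] - b.coords[2]
            e += coulomb_k * a.charge * b.charge / math.sqrt(
                dx * dx + dy * dy + dz * dz)
    return e


def make_toy_pocket(spec: FixtureSpec,
                    coulomb_k: float = 332.0637) -> PocketModel:
    """Deterministic toy pocket with a closed-form Coulomb record.

    ``provenance["expected_electrostatic"]`` maps each residue label to
    the analytic cross-fragment Coulomb energy, computed here from the
    generated geometry, independent of the energy backend.
    """
    rng = np.random.default_rng(spec.seed)
    ligand = _ring_ligand(spec.ligand_charges, spec.lj, spec.asymmetry)
    residues = []
    centers = []
    for i in range(spec.n_residues):
        if spec.directions is not None:
            d = _unit(np.asarray(spec.directions[i], dtype=float))
        else:
            for _ in range(200):
                d = _unit(rng.normal(size=3))
                c = d * spec.distances[i]
                if all(np.linalg.norm(c - p) >= MIN_PLACEMENT
                       for p in centers):
                    break
            else:
                raise ArgumentError(
                    "could not place residues without overlap")
        center = d * spec.distances[i]
        if any(np.linalg.norm(center - p) < MIN_PLACEMENT for p in centers):
            raise ArgumentError("overlapping residue placement")
        centers.append(center)
        residues.append(_build_archetype(spec.archetypes[i], center, i,
                                         rng, spec.lj))
    expected = {r.label: _closed_form_coulomb(ligand, r, coulomb_k)
                for r in residues}
    cutoff = max(spec.distances, default=3.5) + 3.0
    return PocketModel(
        ligand=ligand, residues=residues, cutoff=cutoff,
        source_id=f"toy-pocket-seed{spec.seed}",
        provenance={"seed": spec.seed,
                    "expected_electrostatic": expected})


def flip_ligand(ligand: Fragment) -> Fragment:
    """180° rotation about the ring's in-plane x-axis: (x,y,z)→(x,−y,−z)."""
    out = ligand.copy()
    for a in out.atoms:
        a.coords = np.array([a.coords[0], -a.coords[1], -a.coords[2]])
    return out


def make_flip_fixture(asymmetry: float = 0.0, seed: int = DEFAULT_SEED,
                      config: Optional[BackendConfig] = None
                      ) -> Tuple[BindingMode, BindingMode]:
    """Two binding modes differing only by a 180° ring flip.

    At asymmetry 0 the charge pattern is mirror-symmetric, so both
    modes are energetically identical.  With asymmetry ε, the
    mirror-paired ring sites carry q±ε and the inter-mode energy
    difference has a closed form, recorded in both pockets' provenance
    as ``expected_total_delta`` (Coulomb + generalized-Born terms at
    the given backend configuration).
    """
    if abs(asymmetry) > 0.5:
        raise ArgumentError("|asymmetry| must be ≤ 0.5 e")
    if config is None:
        config = BackendConfig()
    rng = np.random.default_rng(seed)
    # probe ion off the mirror plane, so the flip is energetically visible
    for _ in range(100):
        d = _unit(rng.normal(size=3))
        if abs(d[1]) >= 0.3:
            break
    probe_center = d * 3.6
    probe = _build_archetype("cation", probe_center, 0, rng, lj=True)
    counter = _build_archetype("anion", np.array([-4.2, 0.0, 0.0]), 1,
                               rng, lj=True)
    counter.label = "RES2"

    lig_a = _ring_ligand(DEFAULT_RING_CHARGES, lj=True, asymmetry=asymmetry)
    lig_b = flip_ligand(lig_a)

    # closed-form inter-mode delta: only the asymmetric mirror pair
    # (sites 1 and 4) survives the set-symmetry of the pentagon
    k = config.coulomb_constant / config.interior_dielectric
    pref = config.gb_prefactor
    dq = 2.0 * asymmetry                     # q1 − q4
    r1 = lig_a.atoms[1].coords
    r4 = lig_a.atoms[4].coords
    delta = 0.0
    for res in (probe, counter):
        for b in res.atoms:
            d1 = float(np.linalg.norm(r1 - b.coords))
            d4 = float(np.linalg.norm(r4 - b.coords))
            delta += k * b.charge * dq * (1.0 / d1 - 1.0 / d4)
            if pref != 0.0:
                aij = 1.7 * b.born_radius
                f1 = math.sqrt(d1 * d1 + aij * math.exp(
                    -d1 * d1 / (4.0 * aij)))
                f4 = math.sqrt(d4 * d4 + aij * math.exp(
                    -d4 * d4 / (4.0 * aij)))
                delta += pref * 2.0 * b.charge * dq * (1.0 / f1 - 1.0 / f4)

    prov = {"seed": seed, "asymmetry": asymmetry,
            "expected_total_delta": delta}
    pocket_a = PocketModel(ligand=lig_a, residues=[probe, counter],
                           cutoff=6.0, source_id="flip-fixture",
                           provenance=dict(prov))
    pocket_b = PocketModel(ligand=lig_b,
                           residues=[probe.copy(), counter.copy()],
                           cutoff=6.0, source_id="flip-fixture",
                           provenance=dict(prov))
    return (BindingMode(label="N-C analog", pocket=pocket_a),
            BindingMode(label="N-O analog", pocket=pocket_b))


def brute_force_pair_energy(a: Fragment, b: Fragment,
                            config: BackendConfig) -> EnergyComponents:
    """Naive double-loop oracle for the pair interaction energy.

    Pure-Python scalar arithmetic, classical backend only; independent
    of the vectorized implementation in :mod:`pocketedda.energy`.
    """
    if config.engine != "classical":
        raise ArgumentError("oracle supports the classical backend only")
    ke = config.coulomb_constant / config.interior_dielectric
    pref = config.gb_prefactor
    elec = disp = rep = hb = desolv = 0.0

    def dist(p, q):
        return math.sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2
                         + (p[2] - q[2]) ** 2)

    def donor(frag, h_idx):
        best, best_r = None, math.inf
        for i, at in enumerate(frag.atoms):
            if at.is_hydrogen:
                continue
            r = dist(at.coords, frag.atoms[h_idx].coords)
            if r < best_r:
                best, best_r = i, r
        return best

    def gated(dfrag, h_idx, afrag, a_idx):
        h, acc = dfrag.atoms[h_idx], afrag.atoms[a_idx]
        if not h.is_hydrogen or acc.element not in HBOND_ACCEPTORS:
            return False
        d_ha = dist(h.coords, acc.coords)
        if d_ha > config.hbond_distance:
            return False
        x = donor(dfrag, h_idx)
        if x is None:
            return False
        v1 = [dfrag.atoms[x].coords[k] - h.coords[k] for k in range(3)]
        v2 = [acc.coords[k] - h.coords[k] for k in range(3)]
        n1 = math.sqrt(sum(v * v for v in v1))
        n2 = math.sqrt(sum(v * v for v in v2))
        if n1 == 0 or n2 == 0:
            return False
        cosang = sum(p * q for p, q in zip(v1, v2)) / (n1 * n2)
        ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        return ang >= config.hbond_angle

    for i, ai in enumerate(a.atoms):
        for j, bj in enumerate(b.atoms):
            r = dist(ai.coords, bj.coords)
            e_el = ke * ai.charge * bj.charge / r
            eij = math.sqrt(ai.lj_epsilon * bj.lj_epsilon)
            e_d = e_r = 0.0
            if eij > 0:
                s6 = ((ai.lj_sigma + bj.lj_sigma) / (2.0 * r)) ** 6
                e_d = -4.0 * eij * s6
                e_r = 4.0 * eij * s6 * s6
            if gated(a, i, b, j) or gated(b, j, a, i):
                hb += e_el + e_d + e_r
            else:
                elec += e_el
                disp += e_d
                rep += e_r
            if pref != 0.0:
                aij = ai.born_radius * bj.born_radius
                f = math.sqrt(r * r + aij * math.exp(-r * r / (4.0 * aij)))
                desolv += pref * 2.0 * ai.charge * bj.charge / f
    return EnergyComponents.from_parts(
        electrostatic=elec, dispersion=disp, repulsion=rep, hbond=hb,
        desolvation=desolv)
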