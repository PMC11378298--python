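"""Binding free-energy bookkeeping and affinity conversions.

The binding Gibbs energy decomposes as

    ΔG_bind = ΔE_bind + ΔE_def + ΔH_TRV + ΔG_solv − T·(ΔS_TRV + ΔS_conf)

where ΔE_bind is the gas-phase binding energy, ΔE_def the deformation
(strain) penalty, ΔH_TRV the translational–rotational–vibrational
enthalpy, ΔG_solv the solvation term, and the entropies cover binding
and conformational-freedom losses.  Terms a calculation cannot supply
stay *unset* and are tracked in a ledger, never silently zeroed; the
decomposition minimum is ΔE_bind + ΔG_solv.

Relative affinities convert through the standard 1 M standard-state
expression ΔΔG(A−B) = R·T·ln(K_A/K_B); with IC50 inputs the output is
a relative, IC50-proxy quantity and labeled as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .errors import ArgumentError, IncompleteBreakdownError

R_KCAL = 1.98720425864083e-3   # kcal/(mol·K)
DEFAULT_TEMPERATURE = 298.15   # K

ENTHALPY_TERMS = ("e_bind", "e_def", "h_trv", "g_solv")
ENTROPY_TERMS = ("s_trv", "s_conf")


@dataclass
class BindingEnergyBreakdown:
    """Terms of the binding Gibbs energy; ``None`` means unset."""

    e_bind: Optional[float] = None    # kcal/mol
    e_def: Optional[float] = None     # kcal/mol
    h_trv: Optional[float] = None     # kcal/mol
    g_solv: Optional[float] = None    # kcal/mol
    s_trv: Optional[float] = None     # kcal/(mol·K)
    s_conf: Optional[float] = None    # kcal/(mol·K)
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if not (self.temperature > 0):
            raise ArgumentError("temperature must be positive")


def assemble_binding_energy(b: BindingEnergyBreakdown) -> Tuple[float, dict]:
    """Sum the set terms of the breakdown; report what was omitted.

    Returns ``(value, ledger)`` where the ledger lists included and
    omitted term names explicitly.  ΔE_bind and ΔG_solv are mandatory
    (the decomposition minimum); their absence raises
    :class:`IncompleteBreakdownError`.
    """
    if b.e_bind is None:
        raise IncompleteBreakdownError("e_bind is unset")
    if b.g_solv is None:
        raise IncompleteBreakdownError("g_solv is unset")
    included, omitted = [], []
    value = 0.0
    for name in ENTHALPY_TERMS:
        term = getattr(b, name)
        if term is None:
            omitted.append(name)
        else:
            value += term
            included.append(name)
    for name in ENTROPY_TERMS:
        term = getattr(b, name)
        if term is None:
            omitted.append(name)
        else:
            value -= b.temperature * term
            included.append(name)
    ledger = {"included": included, "omitted": omitted,
              "temperature": b.temperature}
    return value, ledger


@dataclass
class ConformerEnsemble:
    """Conformer energies with a parallel property list."""

    energies: List[float]          # kcal/mol
    values: List[float]            # property to average
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if not self.energies:
            raise ArgumentError("ensemble is empty")
        if len(self.energies) != len(self.values):
            raise ArgumentError("energies and values differ in length")


def boltzmann_weights(energies: List[float],
                      temperature: float = DEFAULT_TEMPERATURE) -> List[float]:
    """Population weights exp(−(E_i − E_min)/RT)/Z.

    Shifting by the minimum energy keeps the exponentials finite for
    arbitrarily large energy gaps.
    """
    if not (temperature > 0):
        raise ArgumentError("temperature must be positive")
    e_min = min(energies)
    rt = R_KCAL * temperature
    raw = [math.exp(-(e - e_min) / rt) for e in energies]
    z = sum(raw)
    return [w / z for w in raw]


def boltzmann_average(ens: ConformerEnsemble) -> float:
    """Population-weighted mean of the ensemble property."""
    w = boltzmann_weights(ens.energies, ens.temperature)
    return sum(wi * xi for wi, xi in zip(w, ens.values))


def ddg_from_affinity_ratio(k_a: float, k_b: float,
                            temperature: float = DEFAULT_TEMPERATURE) -> float:
    """ΔΔG(A−B) = R·T·ln(K_A/K_B), kcal/mol.

    Negative when A binds tighter (smaller affinity constant).  Both
    affinities must be positive and share units; IC50 values act as
    relative-affinity proxies (output is then "relative, IC50-proxy").
    """
    if not (k_a > 0 and k_b > 0):
        raise ArgumentError("affinities must be positive")
    if not (temperature > 0):
        raise ArgumentError("temperature must be positive")
    return R_KCAL * temperature * math.log(k_a / k_b)
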