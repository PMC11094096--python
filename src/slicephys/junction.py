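"""Liquid junction potential via the generalized Henderson equation.

For a junction between the pipette solution (P) and the bath (B), with
ionic concentrations c_i, valences z_i and relative mobilities u_i
(limiting equivalent conductances), the generalized Henderson equation
gives

    V = V_bath - V_pipette
      = -(RT/F) * [ sum_i z_i u_i (c_iB - c_iP) / sum_i z_i^2 u_i (c_iB - c_iP) ]
                * ln( sum_i z_i^2 u_i c_iB / sum_i z_i^2 u_i c_iP )

The sign convention reports the bath relative to the pipette, so a
K-gluconate internal against a NaCl-rich ACSF yields a *positive* value
(the pipette sits negative, gluconate being far less mobile than Cl).
Weak acids/bases are encoded at their dominant ionization near pH 7.2-7.4
(e.g. HEPES, pKa 7.5, contributes ~1/3 of its total as the anion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .core import ParameterError

FARADAY = 96485.33212  # C/mol
GAS_R = 8.314462618    # J/(mol K)


class MissingMobilityError(KeyError):
    pass


def load_mobility_table() -> dict:
    """Mobility table shipped with the package: name -> {z, lambda}."""
    text = resources.files("slicephys").joinpath("data/mobilities.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class SolutionComposition:
    """Ionic composition of a solution: species name -> concentration (mM).

    Species names must match the mobility table.  ``temperature`` is the
    junction temperature in Celsius (34-36 C for heated slice baths).
    """

    species: dict
    temperature: float = 35.0
    name: str = ""

    def __post_init__(self):
        for sp, c in self.species.items():
            if c < 0:
                raise ParameterError(f"negative concentration for {sp}")


def henderson_ljp(pipette: SolutionComposition, bath: SolutionComposition,
                  mobilities: dict | None = None) -> float:
    """Liquid junction potential V_bath - V_pipette, in mV."""
    mob = mobilities or load_mobility_table()
    all_species = set(pipette.species) | set(bath.species)
    for sp in all_species:
        if sp not in mob:
            raise MissingMobilityError(f"no mobility entry for species {sp!r}")

    T = 273.15 + (pipette.temperature + bath.temperature) / 2.0
    rt_f = GAS_R * T / FARADAY * 1e3  # mV

    num = den = s_pip = s_bath = 0.0
    for sp in all_species:
        z = mob[sp]["z"]
        u = mob[sp]["lambda"] / abs(z)  # per-ion mobility
        cp = pipette.species.get(sp, 0.0)
        cb = bath.species.get(sp, 0.0)
        num += z * u * (cb - cp)
        den += z * z * u * (cb - cp)
        s_pip += z * z * u * cp
        s_bath += z * z * u * cb
    if s_pip <= 0 or s_bath <= 0:
        raise ParameterError("solutions must contain charged species")
    if den == 0:  # identical ionic strength profiles: no junction potential
        return 0.0
    return float(-rt_f * (num / den) * np.log(s_bath / s_pip))


def _hepes_anion_fraction(pH: float = 7.2, pKa: float = 7.5) -> float:
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


def k_gluconate_internal(pH: float = 7.2, temperature: float = 35.0) -> SolutionComposition:
    """The K-gluconate intracellular solution used for excitatory recordings.

    120 K-gluconate, 10 HEPES, 10 EGTA, 2 MgCl2, 5 Na2-phosphocreatine,
    2 Na2ATP, 0.5 Na2GTP, 5 QX-314 Cl, pH 7.2.  Salts are split into their
    ions; HEPES enters at its anionic fraction, EGTA as the divalent anion
    dominant near pH 7.2.
    """
    f = _hepes_anion_fraction(pH)
    return SolutionComposition(name="K-gluconate internal", temperature=temperature, species={
        "K": 120.0,
        "gluconate": 120.0,
        "HEPES": 10.0 * f,
        "EGTA": 10.0,
        "Mg": 2.0,
        "Na": 5.0 * 2 + 2.0 * 2 + 0.5 * 2,   # phosphocreatine + ATP + GTP sodium
        "phosphocreatine": 5.0,
        "ATP": 2.0,
        "GTP": 0.5,
        "QX314": 5.0,
        "Cl": 2.0 * 2 + 5.0,                  # MgCl2 + QX-314 Cl
    })


def kcl_internal(pH: float = 7.2, temperature: float = 35.0) -> SolutionComposition:
    """The KCl intracellular solution used for inhibitory recordings.

    125 KCl, 4 NaCl, 10 HEPES, 10 EGTA, 1 CaCl2, 4 MgATP, 0.5 Na2GTP, pH 7.2.
    """
    f = _hepes_anion_fraction(pH)
    return SolutionComposition(name="KCl internal", temperature=temperature, species={
        "K": 125.0,
        "Na": 4.0 + 0.5 * 2,
        "Cl": 125.0 + 4.0 + 1.0 * 2,
        "HEPES": 10.0 * f,
        "EGTA": 10.0,
        "Ca": 1.0,
        "Mg": 4.0,
        "ATP": 4.0,
        "GTP": 0.5,
    })


def acsf(temperature: float = 35.0) -> SolutionComposition:
    """Bicarbonate-buffered ACSF: 124 NaCl, 2.5 KCl, 26 NaHCO3, 1 NaH2PO4,
    2 CaCl2, 1 MgCl2, 10 glucose (neutral, omitted)."""
    return SolutionComposition(name="ACSF", temperature=temperature, species={
        "Na": 124.0 + 26.0 + 1.0,
        "K": 2.5,
        "Ca": 2.0,
        "Mg": 1.0,
        "Cl": 124.0 + 2.5 + 2.0 * 2 + 1.0 * 2,
        "HCO3": 26.0,
        "H2PO4": 1.0,
    })


def solution_from_yaml(path) -> SolutionComposition:
    """Read a solution from YAML: {name, temperature_C, species: {name: mM}}."""
    data = yaml.safe_load(open(path))
    return SolutionComposition(species=data["species"],
                               temperature=data.get("temperature_C", 35.0),
                               name=data.get("name", ""))
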