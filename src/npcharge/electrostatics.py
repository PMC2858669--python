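"""Screened-Coulomb model of electrostatic translocation energetics.

The nuclear pore is approximated as a cylinder lined by FG-nucleoporins
whose net positive charge produces a local charge Q_NPC within one
Debye screening length of a translocating particle's surface. The
electrostatic enthalpy of bringing a particle of net charge Q_NTR into the
pore is the screened Coulomb interaction

    Delta_H = Q_NTR * Q_NPC * e^2 / (4 pi eps0 eps lambda)    (in k_B T)

with lambda ~ 1 nm the cytoplasmic screening length and eps the dielectric
constant of water. Q_NPC is estimated as a uniform-density expectation:
(species x copies) nucleoporins in the pore volume, times the hemisphere-
to-pore volume ratio, times the median nucleoporin net charge. The free
energy barrier is Delta_G = Delta_H - T Delta_S with the entropic cost of
confinement supplied by the user (it is not modelled here).

With the default geometry and census the model linearizes to
Delta_H ~ 0.05 * Q_NTR k_B T: a negatively charged particle gains energy
on entering the pore, a positively charged one pays a penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import constants

from .io import ComplexManifest, ProteinRecord
from .ionization import DEFAULT_IONIZATION, DEFAULT_PH, IonizationModel, net_charge
from .profiler import Subject, _complex_net_charge

#: Default (room) temperature, K.
DEFAULT_TEMPERATURE_K = 298.15

#: Default median FG-nucleoporin net charge, e. The FG-domains owe their
#: positive charge chiefly to lysine-rich spacers; +14 e with the
#: conservative census below gives a per-unit-charge coupling of
#: ~0.05 k_B T per elementary charge.
DEFAULT_MEDIAN_NUP_CHARGE_E = 14.0


@dataclass(frozen=True)
class NPCModel:
    """Pore geometry, nucleoporin census and screening parameters.

    Defaults describe the yeast NPC: a cylinder of radius 19 nm and height
    37 nm containing 13 FG-nucleoporin species at the conservative copy
    number of 8, screening length 1 nm, dielectric constant of water 80.
    ``q_npc_e`` may be supplied directly, bypassing the census estimate.
    """

    radius_nm: float = 19.0
    height_nm: float = 37.0
    n_species: int = 13
    copies_per_species: int = 8
    median_nup_charge_e: float | None = DEFAULT_MEDIAN_NUP_CHARGE_E
    nup_charges_e: tuple[float, ...] | None = None
    q_npc_e: float | None = None
    screening_length_nm: float = 1.0
    dielectric: float = 80.0
    temperature_k: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        for name in ("radius_nm", "height_nm", "screening_length_nm", "temperature_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dielectric < 1.0:
            raise ValueError("dielectric constant must be >= 1")
        if self.n_species < 1 or self.copies_per_species < 1:
            raise ValueError("nucleoporin census must be positive")

    @classmethod
    def from_config(cls, path: str | Path) -> "NPCModel":
        """Load parameters from a YAML/JSON config; unset keys keep defaults."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError("unknown NPC parameter(s): " + ", ".join(sorted(unknown)))
        if "nup_charges_e" in cfg and cfg["nup_charges_e"] is not None:
            cfg["nup_charges_e"] = tuple(float(x) for x in cfg["nup_charges_e"])
        return cls(**cfg)

    def summary(self) -> str:
        lines = [
            "NPC electrostatic model",
            "-" * 47,
            f"pore cylinder          : r = {self.radius_nm} nm, h = {self.height_nm} nm",
            f"pore volume            : {pore_volume(self):.1f} nm^3",
            f"FG-nucleoporin census  : {self.n_species} species x {self.copies_per_species} copies",
            f"screening length       : {self.screening_length_nm} nm",
            f"dielectric constant    : {self.dielectric}",
            f"temperature            : {self.temperature_k} K",
            f"local charge Q_NPC     : {local_npc_charge(self):.4f} e",
            f"coupling dH/dQ_NTR     : {translocation_enthalpy(1.0, self):+.4f} k_B T / e",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class EnergyPrediction:
    """Per-particle energy prediction in thermal units.

    ``delta_h_kbt`` is the modelled electrostatic enthalpy of entering the
    pore; when an entropic cost ``t_delta_s_kbt`` is supplied, the barrier
    ``delta_g_kbt = delta_h_kbt - t_delta_s_kbt`` is filled in.
    """

    subject_id: str
    q_ntr_e: float
    delta_h_kbt: float
    t_delta_s_kbt: float | None = None
    delta_g_kbt: float | None = None
    label: str = "unknown"


def pore_volume(model: NPCModel) -> float:
    """Cylinder volume pi r^2 h, nm^3."""
    return math.pi * model.radius_nm**2 * model.height_nm


def hemisphere_volume(radius_nm: float) -> float:
    """(2/3) pi r^3, nm^3."""
    return (2.0 / 3.0) * math.pi * radius_nm**3


def local_npc_charge(model: NPCModel) -> float:
    """Expected nucleoporin charge within a screening-length hemisphere, e.

    Uniform-density expectation: the census places N = species x copies
    nucleoporins of median charge q in the pore volume V, so a hemisphere
    of radius lambda at the particle surface contains charge
    N * q * (2/3) pi lambda^3 / V. A directly supplied ``q_npc_e``
    short-circuits the estimate.
    """
    if model.q_npc_e is not None:
        return model.q_npc_e
    if model.nup_charges_e is not None:
        median_charge = float(np.median(model.nup_charges_e))
    elif model.median_nup_charge_e is not None:
        median_charge = model.median_nup_charge_e
    else:
        raise ValueError(
            "NPCModel needs nucleoporin charges, a median charge, or q_npc_e"
        )
    n_nups = model.n_species * model.copies_per_species
    fraction = hemisphere_volume(model.screening_length_nm) / pore_volume(model)
    return n_nups * median_charge * fraction


def pair_energy(
    q1_e: float,
    q2_e: float,
    screening_length_nm: float = 1.0,
    dielectric: float = 80.0,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Screened Coulomb energy of charges q1, q2 (e) at one screening length.

    E = q1 q2 e^2 / (4 pi eps0 eps lambda), returned in units of k_B T.
    """
    if screening_length_nm <= 0:
        raise ValueError("screening length must be positive")
    if dielectric < 1.0:
        raise ValueError("dielectric constant must be >= 1")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    lam_m = screening_length_nm * 1e-9
    energy_j = (
        q1_e
        * q2_e
        * constants.elementary_charge**2
        / (4.0 * math.pi * constants.epsilon_0 * dielectric * lam_m)
    )
    return energy_j / (constants.Boltzmann * temperature_k)


def translocation_enthalpy(q_ntr_e: float, model: NPCModel) -> float:
    """Electrostatic enthalpy Delta_H of a particle of charge Q_NTR, k_B T."""
    return pair_energy(
        q_ntr_e,
        local_npc_charge(model),
        model.screening_length_nm,
        model.dielectric,
        model.temperature_k,
    )


def barrier(delta_h_kbt: float, t_delta_s_kbt: float) -> float:
    """Free-energy barrier Delta_G = Delta_H - T Delta_S, k_B T."""
    if not (math.isfinite(delta_h_kbt) and math.isfinite(t_delta_s_kbt)):
        raise ValueError("enthalpy and entropy terms must be finite")
    return delta_h_kbt - t_delta_s_kbt


def phosphorylation_shift(
    n_sites: int, model: NPCModel, charge_per_site_e: float = -1.0
) -> float:
    """Change in Delta_H from phosphorylating *n_sites* residues, k_B T.

    Each site adds one negative elementary charge by default; the shift is
    linear in the added charge, ~ -0.05 k_B T per site with the default
    model.
    """
    if n_sites < 0:
        raise ValueError("number of sites must be >= 0")
    return translocation_enthalpy(n_sites * charge_per_site_e, model)


def predict_particle(
    subject: Subject,
    model: NPCModel | None = None,
    ionization: IonizationModel = DEFAULT_IONIZATION,
    ph: float = DEFAULT_PH,
    t_delta_s_kbt: float | None = None,
) -> EnergyPrediction:
    """Net charge at *ph* fed through the translocation enthalpy model.

    Complexes sum member charges (copy-weighted, each chain keeping its own
    termini). Supplying the entropic cost ``t_delta_s_kbt`` also fills in
    the barrier Delta_G.
    """
    npc = model if model is not None else NPCModel()
    if isinstance(subject, ComplexManifest):
        q = _complex_net_charge(subject, ph, ionization)
        sid, label = subject.name, subject.label
    else:
        q = net_charge(subject.sequence, ph, ionization)
        sid, label = subject.id, subject.label
    dh = translocation_enthalpy(q, npc)
    dg = None if t_delta_s_kbt is None else barrier(dh, t_delta_s_kbt)
    return EnergyPrediction(
        subject_id=sid,
        q_ntr_e=q,
        delta_h_kbt=dh,
        t_delta_s_kbt=t_delta_s_kbt,
        delta_g_kbt=dg,
        label=label,
    )


def predict_particles(
    subjects: Iterable[Subject],
    model: NPCModel | None = None,
    ionization: IonizationModel = DEFAULT_IONIZATION,
    ph: float = DEFAULT_PH,
    t_delta_s_kbt: float | None = None,
) -> pd.DataFrame:
    """Vectorised :func:`predict_particle`; one row per subject."""
    preds = [
        predict_particle(s, model, ionization, ph, t_delta_s_kbt) for s in subjects
    ]
    df = pd.DataFrame(
        {
            "label": [p.label for p in preds],
            "q_ntr_e": [p.q_ntr_e for p in preds],
            "delta_h_kbt": [p.delta_h_kbt for p in preds],
        },
        index=pd.Index([p.subject_id for p in preds], name="id"),
    )
    if t_delta_s_kbt is not None:
        df["t_delta_s_kbt"] = t_delta_s_kbt
        df["delta_g_kbt"] = [p.delta_g_kbt for p in preds]
    return df
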