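"""Net charge at fixed pH and isoelectric point.

The net charge of a protein is the Henderson-Hasselbalch sum over every
ionizable side chain occurrence (C, D, E, H, K, R, Y) plus one amino- and
one carboxyl-terminus per chain:

    Q(pH) = sum_basic 1 / (1 + 10^(pH - pKa))
          - sum_acidic 1 / (1 + 10^(pKa - pH))

in units of the elementary charge e. Q is strictly decreasing in pH, so the
isoelectric point (the root Q(pI) = 0) is unique and found by bisection.

The default pKa set follows the EMBOSS ``iep`` convention so that charges
are reproducible across installations; every value can be overridden from a
YAML/JSON config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .io import STANDARD_RESIDUES, validate_sequence

#: Intracellular pH used throughout unless the caller overrides it.
DEFAULT_PH = 7.2

AMINO_TERMINUS = "nterm"
CARBOXYL_TERMINUS = "cterm"

#: EMBOSS-style side-chain and terminus pKa values.
DEFAULT_PKA: dict[str, float] = {
    AMINO_TERMINUS: 8.6,
    CARBOXYL_TERMINUS: 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

#: +1 for groups that are charged when protonated (bases), -1 for acids.
GROUP_SIGN: dict[str, int] = {
    AMINO_TERMINUS: +1,
    CARBOXYL_TERMINUS: -1,
    "C": -1,
    "D": -1,
    "E": -1,
    "H": +1,
    "K": +1,
    "R": +1,
    "Y": -1,
}


@dataclass(frozen=True)
class IonizationModel:
    """pKa values and charge signs for the ionizable groups.

    ``pka`` maps group name (one-letter residue code, ``"nterm"`` or
    ``"cterm"``) to its pKa; ``sign`` maps the same keys to +1 (basic) or
    -1 (acidic).
    """

    pka: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))
    sign: Mapping[str, int] = field(default_factory=lambda: dict(GROUP_SIGN))

    def __post_init__(self) -> None:
        if set(self.pka) != set(self.sign):
            raise ValueError("pKa and sign tables must cover the same groups")
        for group, value in self.pka.items():
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa for group '{group}' must lie in (0, 14), got {value}")
        for group, s in self.sign.items():
            if s not in (-1, +1):
                raise ValueError(f"sign for group '{group}' must be +1 or -1, got {s}")

    @classmethod
    def from_config(cls, path: str | Path) -> "IonizationModel":
        """Build a model from a YAML/JSON config with partial pKa overrides.

        Recognised keys: ``pka`` (mapping group -> value). Groups not listed
        keep their defaults.
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        pka = dict(DEFAULT_PKA)
        pka.update({str(k): float(v) for k, v in (cfg.get("pka") or {}).items()})
        unknown = set(pka) - set(GROUP_SIGN)
        if unknown:
            raise ValueError("unknown ionizable group(s): " + ", ".join(sorted(unknown)))
        return cls(pka=pka, sign=dict(GROUP_SIGN))

    def group_charge(self, group: str, ph: float) -> float:
        """Fractional charge of one occurrence of *group* at *ph*."""
        pka = self.pka[group]
        if self.sign[group] > 0:
            return 1.0 / (1.0 + 10.0 ** (ph - pka))
        return -1.0 / (1.0 + 10.0 ** (pka - ph))


DEFAULT_IONIZATION = IonizationModel()


def net_charge(
    sequence: str,
    ph: float = DEFAULT_PH,
    ionization: IonizationModel = DEFAULT_IONIZATION,
    termini: bool = True,
) -> float:
    """Net charge of *sequence* at *ph*, in elementary charges.

    Sums the Henderson-Hasselbalch fractional charge of every ionizable
    side-chain occurrence, plus one amino- and one carboxyl-terminus when
    ``termini`` is true (each chain of a non-covalent complex keeps its own
    termini).
    """
    validate_sequence(sequence)
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH must lie in [0, 14], got {ph}")
    ionizable = set(ionization.pka) - {AMINO_TERMINUS, CARBOXYL_TERMINUS}
    q = 0.0
    for group in ionizable:
        n = sequence.count(group)
        if n:
            q += n * ionization.group_charge(group, ph)
    if termini:
        q += ionization.group_charge(AMINO_TERMINUS, ph)
        q += ionization.group_charge(CARBOXYL_TERMINUS, ph)
    return q


def isoelectric_point(
    sequence: str,
    ionization: IonizationModel = DEFAULT_IONIZATION,
    tolerance: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Termini always supply one acidic and one basic group, so Q crosses zero
    and, being strictly decreasing in pH, the root is unique.
    """
    lo, hi = 0.0, 14.0
    q_lo = net_charge(sequence, lo, ionization)
    q_hi = net_charge(sequence, hi, ionization)
    if not (q_lo > 0.0 > q_hi):  # termini guarantee this; belt and braces
        raise ValueError("net charge does not change sign on [0, 14]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        q_mid = net_charge(sequence, mid, ionization)
        if abs(q_mid) < tolerance:
            return mid
        if q_mid > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
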