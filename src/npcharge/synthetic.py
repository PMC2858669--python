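"""Synthetic protein cohorts with the compositional structure of the study.

Four sequence classes are emulated, differing only in residue composition
(no attempt at foldability -- composition is all the downstream analysis
sees):

* ``receptor_like``   -- acidic and hydrophobic (D/E and L/I/F/V enriched),
  long chains in the importin-beta size range;
* ``cargo_like``      -- basic (K/R enriched), typical cellular sizes;
* ``fg_nup_like``     -- explicit FxFG/GLFG repeats separated by
  lysine-rich hydrophilic spacers (K/S/N/T enriched, phenylalanine
  confined to the motifs so the repeat count is exact by construction);
* ``background``      -- proteome-average residue frequencies, bundled as
  a data file.

All sampling is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import STANDARD_RESIDUES, ProteinRecord, write_fasta

#: Enrichment factor applied to class-defining residues before renormalization.
DEFAULT_BOOST = 1.6

#: Residues enriched in each preset.
RECEPTOR_RESIDUES = "DELIFV"
CARGO_RESIDUES = "KR"
SPACER_RESIDUES = "KSNT"

MIN_LENGTH = 20

CLASS_NAMES = ("receptor_like", "cargo_like", "fg_nup_like", "background")


def _load_background_frequencies() -> dict[str, float]:
    source = resources.files("npcharge.data") / "background_frequencies.tsv"
    with resources.as_file(source) as p:
        df = pd.read_csv(p, sep="\t")
    freqs = dict(zip(df["residue"], df["frequency"].astype(float)))
    total = sum(freqs.values())
    return {r: f / total for r, f in freqs.items()}


@dataclass(frozen=True)
class CompositionProfile:
    """Residue frequencies plus a log-normal length distribution.

    ``length_median`` and ``length_shape`` parametrise
    ``length = round(median * exp(shape * Z))``, clamped at 20 residues.
    """

    name: str
    frequencies: Mapping[str, float]
    length_median: float = 450.0
    length_shape: float = 0.45

    def __post_init__(self) -> None:
        missing = sorted(set(STANDARD_RESIDUES) - set(self.frequencies))
        if missing:
            raise ValueError(
                f"profile '{self.name}': missing residue(s) " + ", ".join(missing)
            )
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"profile '{self.name}': frequencies sum to {total}, expected 1"
            )
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError(f"profile '{self.name}': negative frequency")

    def frequency_array(self) -> np.ndarray:
        return np.array([self.frequencies[r] for r in STANDARD_RESIDUES])

    def boosted(
        self, residues: str, factor: float, name: str | None = None
    ) -> "CompositionProfile":
        """Multiply the given residues' frequencies by *factor*, renormalize."""
        freqs = {r: f * (factor if r in residues else 1.0) for r, f in self.frequencies.items()}
        total = sum(freqs.values())
        return CompositionProfile(
            name=name or self.name,
            frequencies={r: f / total for r, f in freqs.items()},
            length_median=self.length_median,
            length_shape=self.length_shape,
        )

    def without(self, residues: str, name: str | None = None) -> "CompositionProfile":
        """Zero the given residues' frequencies, renormalize."""
        freqs = {r: (0.0 if r in residues else f) for r, f in self.frequencies.items()}
        total = sum(freqs.values())
        return CompositionProfile(
            name=name or self.name,
            frequencies={r: f / total for r, f in freqs.items()},
            length_median=self.length_median,
            length_shape=self.length_shape,
        )

    def sample_length(self, rng: np.random.Generator) -> int:
        length = int(round(self.length_median * np.exp(self.length_shape * rng.standard_normal())))
        return max(MIN_LENGTH, length)


def background_profile() -> CompositionProfile:
    """Proteome-average composition (the yellow background cloud)."""
    return CompositionProfile(
        name="background", frequencies=_load_background_frequencies()
    )


def receptor_like_profile(boost: float = DEFAULT_BOOST) -> CompositionProfile:
    """Acidic + hydrophobic composition at importin-beta-family sizes."""
    prof = background_profile().boosted(RECEPTOR_RESIDUES, boost, name="receptor_like")
    return CompositionProfile(
        name=prof.name,
        frequencies=prof.frequencies,
        length_median=1000.0,
        length_shape=0.25,
    )


def cargo_like_profile(boost: float = DEFAULT_BOOST) -> CompositionProfile:
    """Basic (K/R-enriched) composition at typical cellular sizes."""
    return background_profile().boosted(CARGO_RESIDUES, boost, name="cargo_like")


def fg_spacer_profile() -> CompositionProfile:
    """Hydrophilic, lysine-rich spacer composition; no phenylalanine.

    Natively unfolded FG-spacers are dominated by small polar residues
    (S/N/T/Q/G), carry their positive charge chiefly as lysine, and are
    strongly depleted in hydrophobic and aromatic residues. Excluding F
    keeps every F inside an inserted motif, making repeat counts exact.
    """
    prof = background_profile().without("FWYC", name="fg_spacer")
    prof = prof.boosted("LIVM", 0.25).boosted("DE", 0.5)
    prof = prof.boosted("K", 2.0).boosted("SNTQG", 1.5)
    return CompositionProfile(
        name="fg_spacer",
        frequencies=prof.frequencies,
        length_median=12.0,
        length_shape=0.4,
    )


def preset_profile(class_name: str) -> CompositionProfile:
    if class_name == "receptor_like":
        return receptor_like_profile()
    if class_name == "cargo_like":
        return cargo_like_profile()
    if class_name == "background":
        return background_profile()
    if class_name == "fg_nup_like":
        return fg_spacer_profile()
    raise ValueError(f"unknown class '{class_name}'")


def sample_sequence(
    profile: CompositionProfile,
    length: int,
    rng: np.random.Generator,
    record_id: str = "synthetic",
    label: str | None = None,
) -> ProteinRecord:
    """i.i.d. residues from the profile's frequency vector."""
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    residues = rng.choice(
        list(STANDARD_RESIDUES), size=length, p=profile.frequency_array()
    )
    return ProteinRecord(
        id=record_id, sequence="".join(residues), label=label or profile.name
    )


def generate_fg_domain(
    n_repeats: int,
    rng: np.random.Generator,
    motif: str = "GLFG",
    spacer_length: int | tuple[float, float] = (12.0, 0.4),
    spacer_profile: CompositionProfile | None = None,
    record_id: str = "fg_domain",
    label: str = "fg_nup_like",
) -> ProteinRecord:
    """Alternating motif/spacer construction of an FG-domain.

    ``motif`` is ``"GLFG"`` or ``"FxFG"`` (the x drawn from the spacer
    profile). ``spacer_length`` is either a fixed integer (0 concatenates
    the motifs) or ``(median, shape)`` log-normal parameters. Exactly
    *n_repeats* motifs are inserted and, because the spacer profile
    contains no F, exactly *n_repeats* motif occurrences result.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if motif not in ("GLFG", "FxFG"):
        raise ValueError(f"motif must be 'GLFG' or 'FxFG', got '{motif}'")
    profile = spacer_profile if spacer_profile is not None else fg_spacer_profile()
    if profile.frequencies.get("F", 0.0) > 0:
        raise ValueError("spacer profile must exclude F to keep repeat counts exact")

    def draw_spacer() -> str:
        if isinstance(spacer_length, tuple):
            n = int(round(spacer_length[0] * np.exp(spacer_length[1] * rng.standard_normal())))
            n = max(0, n)
        else:
            n = int(spacer_length)
        if n == 0:
            return ""
        return "".join(
            rng.choice(list(STANDARD_RESIDUES), size=n, p=profile.frequency_array())
        )

    def draw_motif() -> str:
        if motif == "GLFG":
            return "GLFG"
        x = rng.choice(
            [r for r in STANDARD_RESIDUES if r not in "FG"],
            p=_renormalize(profile, exclude="FG"),
        )
        return f"F{x}FG"

    parts = [draw_spacer()]
    for _ in range(n_repeats):
        parts.append(draw_motif())
        parts.append(draw_spacer())
    sequence = "".join(parts)
    if len(sequence) < MIN_LENGTH:  # degenerate parameter corner
        pad = rng.choice(
            [r for r in STANDARD_RESIDUES if r != "F"],
            size=MIN_LENGTH - len(sequence),
        )
        sequence = sequence + "".join(pad)
    return ProteinRecord(id=record_id, sequence=sequence, label=label)


def _renormalize(profile: CompositionProfile, exclude: str) -> np.ndarray:
    keep = [r for r in STANDARD_RESIDUES if r not in exclude]
    weights = np.array([profile.frequencies[r] for r in keep])
    return weights / weights.sum()


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort sizes, seed, and the pH used for label sanity checks."""

    counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "receptor_like": 50,
            "cargo_like": 50,
            "fg_nup_like": 13,
            "background": 200,
        }
    )
    seed: int = 0
    ph: float = 7.2
    boost: float = DEFAULT_BOOST
    fg_motifs: tuple[str, ...] = ("GLFG", "FxFG")
    fg_repeats_median: float = 28.0
    fg_repeats_shape: float = 0.3

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(CLASS_NAMES)
        if unknown:
            raise ValueError("unknown class name(s): " + ", ".join(sorted(unknown)))
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("class counts must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if "counts" in cfg:
            cfg["counts"] = {str(k): int(v) for k, v in cfg["counts"].items()}
        if "fg_motifs" in cfg:
            cfg["fg_motifs"] = tuple(cfg["fg_motifs"])
        return cls(**cfg)


def generate_cohort(
    config: GeneratorConfig | None = None,
    out_dir: str | Path | None = None,
) -> list[ProteinRecord]:
    """Generate the labeled cohort; optionally write FASTA + labels + metadata.

    Deterministic: the same config (including seed) always yields the same
    records, and the same files byte for byte.
    """
    cfg = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    records: list[ProteinRecord] = []
    for class_name in CLASS_NAMES:  # fixed order => reproducibility
        n = cfg.counts.get(class_name, 0)
        if class_name == "fg_nup_like":
            spacer = fg_spacer_profile()
            for i in range(n):
                n_rep = max(
                    1,
                    int(
                        round(
                            cfg.fg_repeats_median
                            * np.exp(cfg.fg_repeats_shape * rng.standard_normal())
                        )
                    ),
                )
                motif = cfg.fg_motifs[i % len(cfg.fg_motifs)]
                records.append(
                    generate_fg_domain(
                        n_rep,
                        rng,
                        motif=motif,
                        spacer_profile=spacer,
                        record_id=f"fg_nup_like_{i + 1:03d}",
                    )
                )
        else:
            if class_name == "receptor_like":
                profile = receptor_like_profile(cfg.boost)
            elif class_name == "cargo_like":
                profile = cargo_like_profile(cfg.boost)
            else:
                profile = background_profile()
            for i in range(n):
                length = profile.sample_length(rng)
                records.append(
                    sample_sequence(
                        profile, length, rng, record_id=f"{class_name}_{i + 1:03d}"
                    )
                )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out / "cohort.fasta")
        labels = pd.DataFrame(
            {"id": [r.id for r in records], "label": [r.label for r in records]}
        )
        labels.to_csv(out / "labels.tsv", sep="\t", index=False)
        meta = {
            "seed": cfg.seed,
            "ph": cfg.ph,
            "boost": cfg.boost,
            "counts": dict(cfg.counts),
            "classes": {
                name: dict(preset_profile(name).frequencies) for name in CLASS_NAMES
            },
        }
        with open(out / "metadata.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
    return records
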