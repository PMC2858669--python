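"""Regime classification in the charge/hydrophobicity property space.

The 2D plane is partitioned into quadrants: net negative charge with
above-threshold hydrophobicity is the translocation-competent regime
(transport receptors and their complexes); net positive charge with low
hydrophobicity is the cargo-like regime for soluble proteins, or the
barrier-like regime for FG-nucleoporin subjects. The charge boundary is the
physically natural 0 e; the hydrophobicity boundary defaults to the median
of a designated background (proteome-like) cohort. Points exactly on a
boundary are labelled ``other``.

Large proteins that nevertheless fall in the translocation-competent
regime are predicted to self-translocate without a transport receptor
(the beta-catenin-like case).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqUtils import molecular_weight

from .axes import AGGREGATE_HYDROPHOBICITY
from .io import ComplexManifest, ProteinRecord
from .profiler import NET_CHARGE, Subject

TRANSLOCATION_COMPETENT = "translocation_competent"
CARGO_LIKE = "cargo_like"
FG_BARRIER_LIKE = "fg_barrier_like"
OTHER = "other"

REGIMES = (TRANSLOCATION_COMPETENT, CARGO_LIKE, FG_BARRIER_LIKE, OTHER)

#: Labels treated as nucleoporin subjects for the barrier-like regime.
NUCLEOPORIN_LABELS = frozenset(
    {"nucleoporin_fg", "nucleoporin_scaffold", "fg_domain", "fg_nup_like"}
)

#: Upper bound of passive diffusion through the pore, Da.
PASSIVE_DIFFUSION_LIMIT_DA = 40_000.0


@dataclass(frozen=True)
class RegimeThresholds:
    """Quadrant boundaries: charge in e, hydrophobicity in aggregate units."""

    charge_e: float = 0.0
    hydrophobicity: float = 0.0

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.charge_e) and math.isfinite(self.hydrophobicity)):
            raise ValueError("thresholds must be finite")


def compute_thresholds(background: pd.DataFrame) -> RegimeThresholds:
    """Thresholds from a background property-space table.

    Charge threshold is 0 e; the hydrophobicity threshold is the median
    aggregate hydrophobicity of the background cohort.
    """
    if background is None or len(background) == 0:
        raise ValueError("background table must have at least one row")
    if AGGREGATE_HYDROPHOBICITY not in background.columns:
        raise ValueError(f"background table lacks '{AGGREGATE_HYDROPHOBICITY}' column")
    return RegimeThresholds(
        charge_e=0.0,
        hydrophobicity=float(background[AGGREGATE_HYDROPHOBICITY].median()),
    )


def classify(
    charge_e: float,
    hydrophobicity: float,
    thresholds: RegimeThresholds,
    nucleoporin: bool = False,
) -> str:
    """Regime of a single (charge, aggregate hydrophobicity) point.

    Boundary points (either coordinate equal to its threshold) are
    ``other``; the positive-charge/low-hydrophobicity quadrant is read as
    ``fg_barrier_like`` for nucleoporin-labelled subjects and
    ``cargo_like`` otherwise.
    """
    below_q = charge_e < thresholds.charge_e
    above_q = charge_e > thresholds.charge_e
    above_h = hydrophobicity > thresholds.hydrophobicity
    below_h = hydrophobicity < thresholds.hydrophobicity
    if below_q and above_h:
        return TRANSLOCATION_COMPETENT
    if above_q and below_h:
        return FG_BARRIER_LIKE if nucleoporin else CARGO_LIKE
    return OTHER


def classify_table(
    space: pd.DataFrame, thresholds: RegimeThresholds
) -> pd.DataFrame:
    """Append a ``regime`` column to a property-space table."""
    for col in (NET_CHARGE, AGGREGATE_HYDROPHOBICITY):
        if col not in space.columns:
            raise ValueError(f"property-space table lacks '{col}' column")
    labels = space["label"] if "label" in space.columns else pd.Series("unknown", index=space.index)
    out = space.copy()
    out["regime"] = [
        classify(
            float(row[NET_CHARGE]),
            float(row[AGGREGATE_HYDROPHOBICITY]),
            thresholds,
            nucleoporin=str(labels.loc[idx]) in NUCLEOPORIN_LABELS,
        )
        for idx, row in space.iterrows()
    ]
    return out


def subject_molecular_weight(subject: Subject) -> float:
    """Average molecular weight in Da (copy-weighted for complexes)."""
    if isinstance(subject, ComplexManifest):
        return sum(
            count * molecular_weight(rec.sequence, seq_type="protein")
            for rec, count in subject.members
        )
    return float(molecular_weight(subject.sequence, seq_type="protein"))


def predict_self_translocators(
    subjects: Sequence[Subject],
    space: pd.DataFrame,
    thresholds: RegimeThresholds,
    size_limit_da: float = PASSIVE_DIFFUSION_LIMIT_DA,
) -> pd.DataFrame:
    """Subjects in the translocation-competent regime, flagged by size.

    Returns one row per flagged subject with its coordinates, molecular
    weight and ``above_passive_limit`` -- large flagged proteins are the
    interesting predictions, able to cross the pore unassisted despite
    exceeding the passive-diffusion limit.
    """
    classified = classify_table(space, thresholds)
    by_id = {}
    for s in subjects:
        sid = s.name if isinstance(s, ComplexManifest) else s.id
        by_id[sid] = s
    rows = []
    for sid, row in classified.iterrows():
        if row["regime"] != TRANSLOCATION_COMPETENT:
            continue
        mw = subject_molecular_weight(by_id[sid]) if sid in by_id else float("nan")
        rows.append(
            {
                "id": sid,
                "label": row.get("label", "unknown"),
                NET_CHARGE: row[NET_CHARGE],
                AGGREGATE_HYDROPHOBICITY: row[AGGREGATE_HYDROPHOBICITY],
                "molecular_weight_da": mw,
                "above_passive_limit": bool(mw > size_limit_da),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "label",
            NET_CHARGE,
            AGGREGATE_HYDROPHOBICITY,
            "molecular_weight_da",
            "above_passive_limit",
        ],
    ).set_index("id")
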