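"""Score-cutoff calibration from differential-expression evidence.

Operons or monocistronic units up-regulated on ECF overexpression
(log2 fold change > 2, adjusted p < 0.05) carry a functional off-target
promoter in their upstream region.  For each such unit the Pareto-optimal
placements with respect to the -35 and -10 box scores are collected; over
the union of these fronts the *worst* values — the most negative -35, -10
and total scores and the largest E-value — become minimal cutoffs, which
are then relaxed by an uncertainty factor (default 5%) to counter
overfitting.  Because scores are negative, multiplying them by
(1 + relax) moves every cutoff away from 0, i.e. makes it more
permissive; the E-value cutoff is likewise multiplied and capped at 1.

All four cutoffs are applied conjunctively, with inclusive boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .scan import PromoterHit

__all__ = [
    "RegulatedUnit",
    "CutoffSet",
    "pareto_front",
    "calibrate_cutoffs",
    "apply_cutoffs",
    "read_de_table",
    "write_de_table",
]

DE_LOG2FC_MIN = 2.0
DE_PADJ_MAX = 0.05


@dataclass(frozen=True)
class RegulatedUnit:
    """One operon or monocistronic unit with its DE statistics."""

    unit_id: str
    members: tuple[str, ...]
    log2fc: float
    padj: float

    def is_regulated(
        self, log2fc_min: float = DE_LOG2FC_MIN, padj_max: float = DE_PADJ_MAX
    ) -> bool:
        """Strict thresholds: log2fc > 2 and padj < 0.05."""
        return self.log2fc > log2fc_min and self.padj < padj_max


@dataclass
class CutoffSet:
    """Calibrated minimal scores and maximal E-value, relaxation applied.

    ``min_s35``/``min_s10``/``min_total``/``max_evalue`` are the filters
    actually applied; the ``raw_*`` fields record the unrelaxed worst
    values they were derived from.  ``provenance`` lists the unit ids that
    contributed (a ``"!"`` prefix marks regulated units excluded for
    having no hits).
    """

    min_s35: float
    min_s10: float
    min_total: float
    max_evalue: float
    relax_factor: float = 0.05
    provenance: list[str] = field(default_factory=list)
    raw_min_s35: float | None = None
    raw_min_s10: float | None = None
    raw_min_total: float | None = None
    raw_max_evalue: float | None = None

    def __post_init__(self) -> None:
        for raw, relaxed, kind in (
            (self.raw_min_s35, self.min_s35, "score"),
            (self.raw_min_s10, self.min_s10, "score"),
            (self.raw_min_total, self.min_total, "score"),
            (self.raw_max_evalue, self.max_evalue, "evalue"),
        ):
            if raw is None:
                continue
            ok = relaxed <= raw + 1e-12 if kind == "score" else relaxed >= raw - 1e-12
            if not ok:
                raise ValueError("relaxed cutoffs must not be stricter than raw ones")

    def to_dict(self) -> dict:
        return {
            "min_s35": self.min_s35,
            "min_s10": self.min_s10,
            "min_total": self.min_total,
            "max_evalue": self.max_evalue,
            "relax_factor": self.relax_factor,
            "provenance": list(self.provenance),
            "raw_min_s35": self.raw_min_s35,
            "raw_min_s10": self.raw_min_s10,
            "raw_min_total": self.raw_min_total,
            "raw_max_evalue": self.raw_max_evalue,
        }


def pareto_front(hits: list[PromoterHit]) -> list[PromoterHit]:
    """Placements not dominated in both box scores (maximisation).

    A hit is dominated when another hit has s35 >= and s10 >= with at
    least one strict inequality; duplicates of identical (s35, s10) are
    all retained.  Output is ordered by descending s35 (then descending
    s10 for determinism).
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: (-h.s35, -h.s10))
    front: list[PromoterHit] = []
    best_s10 = float("-inf")  # best s10 among strictly higher s35 groups
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j].s35 == ordered[i].s35:
            j += 1
        group = ordered[i:j]
        group_max_s10 = group[0].s10  # sorted descending within group
        if group_max_s10 > best_s10:
            front.extend(h for h in group if h.s10 == group_max_s10)
            best_s10 = group_max_s10
        i = j
    return front


def calibrate_cutoffs(
    units: list[RegulatedUnit],
    hits_by_unit: dict[str, list[PromoterHit]],
    relax: float = 0.05,
    fixed_max_evalue: float | None = None,
) -> CutoffSet:
    """Worst-value cutoffs over the union of per-unit Pareto fronts.

    Units failing the DE thresholds are ignored; regulated units with no
    hits are excluded with a warning and recorded in the provenance with
    a ``"!"`` prefix.  ``fixed_max_evalue`` bypasses the front-derived
    E-value cutoff (e.g. to pin it at 0.05).
    """
    if relax < 0:
        raise ValueError("relax must be >= 0")
    provenance: list[str] = []
    union: list[PromoterHit] = []
    for unit in units:
        if not unit.is_regulated():
            continue
        hits = hits_by_unit.get(unit.unit_id, [])
        if not hits:
            warnings.warn(
                f"regulated unit {unit.unit_id} has no promoter hits; excluded "
                "from calibration",
                stacklevel=2,
            )
            provenance.append(f"!{unit.unit_id}")
            continue
        provenance.append(unit.unit_id)
        union.extend(pareto_front(hits))
    if not union:
        raise ValueError("no regulated unit contributed any hit; cannot calibrate")
    raw_s35 = min(h.s35 for h in union)
    raw_s10 = min(h.s10 for h in union)
    raw_total = min(h.total for h in union)
    if fixed_max_evalue is None:
        missing = [h for h in union if h.evalue is None]
        if missing:
            raise ValueError(
                f"hit {missing[0].window_id} lacks an E-value; compute E-values "
                "before calibration or pass fixed_max_evalue"
            )
        raw_e = max(h.evalue for h in union)
    else:
        raw_e = float(fixed_max_evalue)
    f = 1.0 + relax
    return CutoffSet(
        min_s35=raw_s35 * f,
        min_s10=raw_s10 * f,
        min_total=raw_total * f,
        max_evalue=min(1.0, raw_e * f),
        relax_factor=relax,
        provenance=provenance,
        raw_min_s35=raw_s35,
        raw_min_s10=raw_s10,
        raw_min_total=raw_total,
        raw_max_evalue=raw_e,
    )


def apply_cutoffs(hits: list[PromoterHit], cutoffs: CutoffSet) -> list[PromoterHit]:
    """Keep hits passing all four cutoffs (inclusive boundaries)."""
    tol = 1e-12
    kept = []
    for h in hits:
        if h.evalue is None:
            raise ValueError(
                f"hit in window {h.window_id} has no E-value; compute it first"
            )
        if (
            h.s35 >= cutoffs.min_s35 - tol
            and h.s10 >= cutoffs.min_s10 - tol
            and h.total >= cutoffs.min_total - tol
            and h.evalue <= cutoffs.max_evalue + tol
        ):
            kept.append(h)
    return kept


def read_de_table(path: str | Path) -> list[RegulatedUnit]:
    """Read a DE table TSV: unit_id, members (comma-separated), log2fc, padj."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"unit_id", "members", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    return [
        RegulatedUnit(
            unit_id=str(r.unit_id),
            members=tuple(str(r.members).split(",")),
            log2fc=float(r.log2fc),
            padj=float(r.padj),
        )
        for r in df.itertuples(index=False)
    ]


def write_de_table(units: list[RegulatedUnit], path: str | Path) -> None:
    pd.DataFrame(
        [
            (u.unit_id, ",".join(u.members), u.log2fc, u.padj)
            for u in units
        ],
        columns=["unit_id", "members", "log2fc", "padj"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
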