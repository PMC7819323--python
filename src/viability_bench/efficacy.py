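"""The spike-in PMA efficacy statistic.

A known 1:1 live:dead *E. coli* spike-in calibrates how much relic DNA a
PMA treatment actually removes.  With four arms per sample type —

* A: plain (no spike, no PMA)
* B: PMA-treated, no spike
* C: spiked, no PMA
* D: spiked and PMA-treated

— and a per-arm signal defined as (mean relative abundance of the
reference family) × (mean log10 16S copies from qPCR), the efficacy is

    efficacy = 1 − (D − B) / (C − A)

The spike contributes C − A of signal before treatment and D − B after;
the ratio is the surviving spike share, and one minus it the removed
share.  Since half the spike is dead, an ideal treatment yields exactly
0.5; values below 0.5 indicate incomplete relic-DNA depletion and values
above 0.5 (possibly exceeding 1) indicate toxicity to viable cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from viability_bench.tables_io import AbundanceTable, QpcrTable, SampleMetadata

__all__ = [
    "QuadrupletSignal",
    "EfficacyEstimate",
    "UndefinedEfficacyError",
    "pma_efficacy",
    "build_quadruplet",
    "efficacy_by_type",
]

#: classification half-width around the ideal value 0.5
IDEAL_TOLERANCE = 0.05


class UndefinedEfficacyError(ValueError):
    """Raised when the spike signal is not detected above background
    (C ≤ A), leaving the efficacy undefined."""


@dataclass
class QuadrupletSignal:
    """The four arm signals entering the efficacy formula."""

    A: float
    B: float
    C: float
    D: float
    sample_type: str = ""
    reference_taxon: str = "Enterobacteriaceae"

    def __post_init__(self) -> None:
        for name in "ABCD":
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"signal {name} must be finite and ≥ 0, got {v}")


@dataclass
class EfficacyEstimate:
    """An efficacy value with its interpretation.

    ``incomplete`` (< 0.5 − tol): relic DNA survived the treatment;
    ``ideal`` (within tol of 0.5): exactly the dead spike half removed;
    ``toxic`` (> 0.5 + tol): viable cells were also removed.  A type
    whose spike was not detected above background is ``undefined`` with a
    NaN value.
    """

    value: float
    classification: Literal["incomplete", "ideal", "toxic", "undefined"]
    reference_taxon: str = "Enterobacteriaceae"
    sample_type: str = ""


def pma_efficacy(
    q: QuadrupletSignal, ideal_tolerance: float = IDEAL_TOLERANCE
) -> EfficacyEstimate:
    """``1 − (D − B)/(C − A)`` with classification against 0.5.

    The value is not clamped: toxicity can push it above 1 (all spike
    signal plus some background removed) and pathological inputs below 0.
    """
    if q.C <= q.A:
        raise UndefinedEfficacyError(
            f"undefined efficacy: spike signal not detected above background "
            f"(C={q.C} ≤ A={q.A})"
        )
    value = 1.0 - (q.D - q.B) / (q.C - q.A)
    if abs(value - 0.5) <= ideal_tolerance:
        cls = "ideal"
    elif value < 0.5:
        cls = "incomplete"
    else:
        cls = "toxic"
    return EfficacyEstimate(value, cls, q.reference_taxon, q.sample_type)


def _matches_reference(
    taxon_id: str, lineage: str | None, reference: str
) -> bool:
    """Case-insensitive substring match against the lineage (preferred)
    or the taxon ID itself."""
    ref = reference.lower()
    if lineage is not None and ref in lineage.lower():
        return True
    return ref in taxon_id.lower()


def reference_taxon_abundance(
    table: AbundanceTable, reference: str = "Enterobacteriaceae"
) -> dict[str, float]:
    """Per-sample summed relative abundance of all taxa matching the
    reference at any rank (lineage-substring match)."""
    rel = table.to_relative()
    taxonomy = table.taxonomy or {}
    cols = [
        j
        for j, t in enumerate(rel.taxon_ids)
        if _matches_reference(t, taxonomy.get(t), reference)
    ]
    if not cols:
        raise ValueError(f"reference taxon {reference!r} absent from table")
    sums = rel.values[:, cols].sum(axis=1)
    return dict(zip(rel.sample_ids, sums))


_ARMS = {
    "A": (False, False),
    "B": (True, False),
    "C": (False, True),
    "D": (True, True),
}


def build_quadruplet(
    table: AbundanceTable,
    meta: Sequence[SampleMetadata],
    qpcr: QpcrTable,
    sample_type: str,
    reference_taxon: str = "Enterobacteriaceae",
    copies_scale: Literal["log10", "linear"] = "log10",
) -> QuadrupletSignal:
    """Per-arm signals for one sample type.

    Each arm's signal is mean(reference relative abundance over the
    arm's samples) × mean(qPCR copies over the arm's samples) — means of
    the two factors, not the mean of per-sample products.  The default
    copy scale is log10, matching the published normalization; the
    ``linear`` option multiplies by mean 10^copies_log10 instead, which
    makes the signal proportional to absolute reference amount.
    """
    abund = reference_taxon_abundance(table, reference_taxon)
    signals: dict[str, float] = {}
    for arm, (treated, spiked) in _ARMS.items():
        sids = [
            m.sample_id
            for m in meta
            if m.sample_type == sample_type
            and m.pma_treated == treated
            and m.spiked == spiked
        ]
        if not sids:
            raise ValueError(
                f"missing arm {arm} ({'PMA' if treated else 'no PMA'}, "
                f"{'spiked' if spiked else 'unspiked'}) for sample type "
                f"{sample_type!r}"
            )
        mean_abund = float(np.mean([abund[s] for s in sids]))
        if copies_scale == "log10":
            mean_copies = qpcr.mean_log10(sids)
        elif copies_scale == "linear":
            vals = []
            for s in sids:
                e = qpcr.get(s)
                vals.append(0.0 if e.below_detection else 10.0 ** e.copies_log10)
            mean_copies = float(np.mean(vals))
        else:
            raise ValueError(f"unknown copies_scale {copies_scale!r}")
        signals[arm] = mean_abund * mean_copies
    return QuadrupletSignal(
        signals["A"], signals["B"], signals["C"], signals["D"],
        sample_type=sample_type, reference_taxon=reference_taxon,
    )


def efficacy_by_type(
    table: AbundanceTable,
    meta: Sequence[SampleMetadata],
    qpcr: QpcrTable,
    reference_taxon: str = "Enterobacteriaceae",
    copies_scale: Literal["log10", "linear"] = "log10",
) -> dict[str, EfficacyEstimate]:
    """Efficacy per sample type; undefined types are reported as such
    (NaN value, classification ``undefined``) rather than dropped."""
    out: dict[str, EfficacyEstimate] = {}
    types: list[str] = []
    for m in meta:
        if m.sample_type not in types:
            types.append(m.sample_type)
    for st in types:
        try:
            q = build_quadruplet(table, meta, qpcr, st, reference_taxon, copies_scale)
            out[st] = pma_efficacy(q)
        except (UndefinedEfficacyError, ValueError):
            out[st] = EfficacyEstimate(float("nan"), "undefined", reference_taxon, st)
    return out
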