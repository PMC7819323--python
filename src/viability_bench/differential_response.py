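"""Per-taxon PMA response: normalized abundance changes and rankings.

For each taxon and sample type, mean relative abundances are compared
between PMA-free and PMA-treated sample groups.  The normalized change is

    change = (abund_free − abund_pma) / abund_free

(positive = depleted by the treatment), while a separate floored ratio —
``max(free, floor) / max(pma, floor)`` or its reciprocal, whichever ≥ 1 —
drives the >100-fold highlight.  Taxa with the largest average changes
across sample types are "PMA-responsive"; those with the smallest are
"PMA-resilient".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from viability_bench.tables_io import AbundanceTable, SampleMetadata

__all__ = ["FoldChangeRecord", "ResponseRanking", "fold_change", "rank_responses"]

#: default detection floor, one order of magnitude below the smallest
#: relative abundance resolvable at typical library depths (~1e-5)
DEFAULT_FLOOR = 1e-6

LARGE_CHANGE_RATIO = 100.0


@dataclass
class FoldChangeRecord:
    """Abundance change of one taxon in one sample type.

    ``change`` is the normalized difference (see module docstring);
    ``ratio`` is the ≥ 1 floored fold ratio in either direction;
    ``censored`` records zero means ("undetectable" in one arm);
    ``large_change`` flags ratios above 100.
    """

    taxon_id: str
    sample_type: str
    abund_free: float
    abund_pma: float
    change: float
    ratio: float
    censored: Literal["none", "undetectable_before", "undetectable_after"]
    large_change: bool

    @property
    def detected(self) -> bool:
        """Present in at least one arm."""
        return self.abund_free > 0 or self.abund_pma > 0


@dataclass
class ResponseRanking:
    """Disjoint ordered lists of the most and least PMA-affected taxa."""

    responsive: list[str]
    resilient: list[str]
    top_n: int = 30
    min_types: int = 2

    def __post_init__(self) -> None:
        if set(self.responsive) & set(self.resilient):
            raise ValueError("responsive and resilient lists overlap")
        if len(self.responsive) > self.top_n or len(self.resilient) > self.top_n:
            raise ValueError("ranking lists longer than top_n")


def fold_change(
    table: AbundanceTable,
    meta: Sequence[SampleMetadata],
    sample_type: str,
    floor: float = DEFAULT_FLOOR,
) -> list[FoldChangeRecord]:
    """Normalized change of every taxon between the PMA-free and
    PMA-treated arms of one sample type.

    Arm abundances are arithmetic means of per-sample relative
    abundances over all the type's samples in that arm.  The change is
    ``(abund_free − abund_pma) / max(abund_free, floor)`` so that taxa
    appearing after treatment ("undetectable before") get large negative
    changes instead of a division by zero.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    rel = table.to_relative()
    free_ids = [
        m.sample_id for m in meta if m.sample_type == sample_type and not m.pma_treated
    ]
    pma_ids = [
        m.sample_id for m in meta if m.sample_type == sample_type and m.pma_treated
    ]
    if not free_ids or not pma_ids:
        raise ValueError(
            f"sample type {sample_type!r} lacks a "
            f"{'PMA-free' if not free_ids else 'PMA-treated'} arm"
        )
    idx = {s: i for i, s in enumerate(rel.sample_ids)}
    free_rows = rel.values[[idx[s] for s in free_ids]]
    pma_rows = rel.values[[idx[s] for s in pma_ids]]
    free_mean = free_rows.mean(axis=0)
    pma_mean = pma_rows.mean(axis=0)
    records = []
    for j, taxon in enumerate(rel.taxon_ids):
        af, ap = float(free_mean[j]), float(pma_mean[j])
        change = (af - ap) / max(af, floor)
        r = max(af, floor) / max(ap, floor)
        ratio = r if r >= 1 else 1.0 / r
        if af == 0 and ap == 0:
            censored = "undetectable_before"  # absent everywhere; both flags apply
        elif af == 0:
            censored = "undetectable_before"
        elif ap == 0:
            censored = "undetectable_after"
        else:
            censored = "none"
        records.append(
            FoldChangeRecord(
                taxon_id=taxon,
                sample_type=sample_type,
                abund_free=af,
                abund_pma=ap,
                change=change,
                ratio=ratio,
                censored=censored,
                large_change=ratio > LARGE_CHANGE_RATIO,
            )
        )
    return records


def rank_responses(
    records: Sequence[FoldChangeRecord],
    top_n: int = 30,
    min_types: int = 2,
) -> ResponseRanking:
    """Rank taxa by their average |change| across sample types.

    A taxon is scored over the sample types where it is detected in at
    least one arm; only taxa scored in ≥ ``min_types`` types are
    eligible.  ``responsive`` lists the ``top_n`` largest averages
    (descending), ``resilient`` the smallest (ascending), drawn from the
    remaining taxa so the lists never overlap.  Ties break
    lexicographically by taxon ID, so reruns are deterministic.
    """
    per_taxon: dict[str, list[float]] = {}
    for rec in records:
        if rec.detected:
            per_taxon.setdefault(rec.taxon_id, []).append(abs(rec.change))
    scores = {
        t: float(np.mean(ch))
        for t, ch in per_taxon.items()
        if len(ch) >= min_types
    }
    desc = sorted(scores, key=lambda t: (-scores[t], t))
    responsive = desc[:top_n]
    remaining = [t for t in scores if t not in set(responsive)]
    asc = sorted(remaining, key=lambda t: (scores[t], t))
    resilient = asc[:top_n]
    return ResponseRanking(responsive, resilient, top_n, min_types)
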