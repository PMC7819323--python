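"""Deterministic expected outcomes of ideal PMA treatment.

Under ideal PMA action every dead cell's DNA is removed and no live cell
is touched, so the expected post-treatment composition of a declared
mixture is simply its live fractions renormalized — e.g. a community of
50% live *E. coli*, 25% live and 25% dead *S. sanguinis* is expected to
read out as 67% / 33% after treatment, and an all-dead community yields
no nucleotides at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from viability_bench.synthetic_data import CommunityDesign
from viability_bench.tables_io import AbundanceTable

__all__ = ["ExpectedProfile", "expected_post_pma", "compare_observed_expected", "ComparisonResult"]


@dataclass
class ExpectedProfile:
    """Expected composition after ideal PMA treatment.

    ``fractions`` sum to 1 (within 1e-12) unless ``empty``;
    ``expected_signal_reduction`` is the share of signal removed (the
    dead mass share, copy-weighted when requested);  ``design_taxa``
    records the full taxon set of the source design so that an empty
    profile can still be compared against observations.
    """

    fractions: dict[str, float]
    empty: bool
    expected_signal_reduction: float
    design_taxa: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.empty:
            if self.fractions:
                raise ValueError("empty profile must have no fractions")
        else:
            s = sum(self.fractions.values())
            if abs(s - 1.0) > 1e-12:
                raise ValueError(f"fractions sum to {s}, not 1")
        if not (0 <= self.expected_signal_reduction <= 1):
            raise ValueError("expected_signal_reduction must be in [0, 1]")


def expected_post_pma(
    design: CommunityDesign, copy_weighted: bool = False
) -> ExpectedProfile:
    """Expected composition and signal reduction under ideal PMA.

    All dead cells are removed and all live cells kept, so fractions are
    the live cell fractions renormalized.  With ``copy_weighted=True``
    the weights (and the reduction) are 16S-copy-number weighted,
    reflecting what an amplicon readout would see; the default is the
    plain cell-fraction arithmetic.
    """
    live_w: dict[str, float] = {}
    dead_w = 0.0
    for c in design.components:
        w = c.cell_fraction
        if copy_weighted:
            w *= design.copy_number[c.taxon_id]
        if c.state == "live":
            live_w[c.taxon_id] = live_w.get(c.taxon_id, 0.0) + w
        else:
            dead_w += w
    total = sum(live_w.values()) + dead_w
    taxa = tuple(design.taxa)
    if not live_w:
        return ExpectedProfile({}, True, 1.0 if total > 0 else 0.0, taxa)
    live_total = sum(live_w.values())
    fractions = {t: w / live_total for t, w in live_w.items()}
    # exact unit sum despite float division
    drift = 1.0 - sum(fractions.values())
    last = next(reversed(fractions))
    fractions[last] += drift
    reduction = dead_w / total if total > 0 else 0.0
    return ExpectedProfile(fractions, False, reduction, taxa)


@dataclass
class ComparisonResult:
    """Per-taxon deviation of an observed profile from an expectation."""

    deviations: dict[str, float]
    tv_distance: float


def compare_observed_expected(
    observed: AbundanceTable | Mapping[str, float],
    expected: ExpectedProfile,
) -> ComparisonResult:
    """Absolute per-taxon deviations and total variation distance.

    ``observed`` may be a one-or-more-sample table (averaged over samples
    after conversion to relative abundance) or a taxon → fraction map.
    TV distance is ½ Σ |obs − exp| over the union of taxa, in [0, 1].
    For an *empty* expectation the community should contribute no reads,
    so the comparison reduces to the total observed mass on the design's
    own (non-contaminant) taxa.
    """
    if isinstance(observed, AbundanceTable):
        rel = observed.to_relative()
        obs = dict(zip(rel.taxon_ids, rel.values.mean(axis=0)))
    else:
        obs = dict(observed)
    if expected.empty:
        mass = sum(obs.get(t, 0.0) for t in expected.design_taxa)
        devs = {t: obs.get(t, 0.0) for t in expected.design_taxa}
        return ComparisonResult(devs, float(mass))
    taxa = sorted(set(obs) | set(expected.fractions))
    devs = {t: abs(obs.get(t, 0.0) - expected.fractions.get(t, 0.0)) for t in taxa}
    tv = 0.5 * sum(devs.values())
    return ComparisonResult(devs, float(tv))
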