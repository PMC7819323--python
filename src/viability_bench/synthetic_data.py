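"""Generative models of live/dead microbial communities under PMA treatment.

The simulator mirrors a three-part bench design:

1. ten two-strain live/dead *E. coli* / *S. sanguinis* mixtures at
   10^5 CFU/ml (:func:`make_two_strain_designs`);
2. complex background communities at two biomass levels receiving a 1:1
   live:dead *E. coli* spike-in across a four-arm factorial
   (plain / PMA / spike / spike+PMA; :func:`make_spiked_scenario`);
3. arbitrary surface communities for treated-vs-untreated comparisons.

PMA action is modeled per taxon as binomial thinning: a dead cell's DNA is
removed with probability ``p_dead_removed`` (scaled by a matrix-attenuation
factor for soil/saliva-like backgrounds where particles sequester DNA from
intercalation) and a live cell's with ``p_live_removed`` (dye toxicity).
Sequencing draws reads multinomially with weights proportional to
cell mass × 16S copy number, with a per-read bleed-through/contamination
channel that fills near-empty libraries.  qPCR totals get lognormal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from viability_bench.tables_io import (
    AbundanceTable,
    QpcrEntry,
    QpcrTable,
    SampleMetadata,
)

__all__ = [
    "Component",
    "CommunityDesign",
    "PmaActionModel",
    "SequencingModel",
    "SpikeInSpec",
    "apply_pma",
    "sequence_community",
    "qpcr_total",
    "make_two_strain_designs",
    "make_background",
    "make_spiked_scenario",
    "simulate_spike_experiment",
    "ECOLI",
    "SSANGUINIS",
    "DEFAULT_COPY_NUMBERS",
    "SPIKE_LINEAGE",
]

ECOLI = "Escherichia_coli"
SSANGUINIS = "Streptococcus_sanguinis"

#: 16S rRNA operon copies per genome (literature values for the two
#: reference strains; used wherever copy-number weighting applies).
DEFAULT_COPY_NUMBERS: dict[str, int] = {ECOLI: 7, SSANGUINIS: 4}

#: Greengenes-style lineage of the *E. coli* spike; the efficacy statistic
#: aggregates the whole Enterobacteriaceae family, so the simulated spike
#: taxon carries the family label in its lineage.
SPIKE_LINEAGE = (
    "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; "
    "o__Enterobacteriales; f__Enterobacteriaceae; g__Escherichia"
)

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class Component:
    """One (taxon, viability state) slice of a community."""

    taxon_id: str
    state: Literal["live", "dead"]
    cell_fraction: float

    def __post_init__(self) -> None:
        if self.state not in ("live", "dead"):
            raise ValueError(f"state must be 'live' or 'dead', got {self.state!r}")
        if not (0 <= self.cell_fraction <= 1):
            raise ValueError(f"cell_fraction {self.cell_fraction} outside [0, 1]")


@dataclass
class CommunityDesign:
    """A declared mixture of (taxon, viability state, cell proportion).

    ``copy_number`` maps each component taxon to its 16S copies per cell;
    ``total_cells`` is the absolute community size.  An empty design
    (``components=[]``, ``total_cells=0``) represents a community whose
    signal was entirely removed.
    """

    components: list[Component]
    copy_number: dict[str, int]
    total_cells: float

    def __post_init__(self) -> None:
        if self.total_cells < 0:
            raise ValueError("total_cells must be ≥ 0")
        if not self.components:
            if self.total_cells != 0:
                raise ValueError("empty design must have total_cells = 0")
            return
        if self.total_cells == 0:
            raise ValueError("non-empty design must have total_cells > 0")
        s = sum(c.cell_fraction for c in self.components)
        if abs(s - 1.0) > _FRACTION_TOL:
            raise ValueError(f"cell fractions sum to {s}, not 1")
        for c in self.components:
            cn = self.copy_number.get(c.taxon_id)
            if cn is None or cn <= 0:
                raise ValueError(f"missing/invalid copy number for {c.taxon_id!r}")

    @property
    def is_empty(self) -> bool:
        return not self.components

    @property
    def taxa(self) -> list[str]:
        """Distinct taxon IDs in component order."""
        seen: list[str] = []
        for c in self.components:
            if c.taxon_id not in seen:
                seen.append(c.taxon_id)
        return seen

    def cell_mass(self, taxon_id: str, state: str | None = None) -> float:
        """Absolute cells of a taxon (optionally restricted to one state)."""
        return self.total_cells * sum(
            c.cell_fraction
            for c in self.components
            if c.taxon_id == taxon_id and (state is None or c.state == state)
        )

    def taxon_masses(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for c in self.components:
            out[c.taxon_id] = out.get(c.taxon_id, 0.0) + c.cell_fraction * self.total_cells
        return out

    def total_16s_copies(self) -> float:
        return sum(m * self.copy_number[t] for t, m in self.taxon_masses().items())


@dataclass
class PmaActionModel:
    """Per-taxon PMA removal probabilities.

    ``p_dead_removed[t]`` — probability a dead cell's DNA is tagged and
    removed; ``p_live_removed[t]`` — probability a live cell's DNA is
    removed (toxicity); ``matrix_attenuation`` multiplies the dead-cell
    probability to emulate matrix effects (soil particles, salivary host
    DNA) that shield relic DNA.  Taxa absent from the maps fall back to
    ``default_p_dead`` / ``default_p_live``.
    """

    p_dead_removed: dict[str, float] = field(default_factory=dict)
    p_live_removed: dict[str, float] = field(default_factory=dict)
    matrix_attenuation: float = 1.0
    default_p_dead: float = 1.0
    default_p_live: float = 0.0

    def __post_init__(self) -> None:
        for name, mp in (("p_dead_removed", self.p_dead_removed),
                         ("p_live_removed", self.p_live_removed)):
            for t, p in mp.items():
                if not (0 <= p <= 1):
                    raise ValueError(f"{name}[{t!r}] = {p} outside [0, 1]")
        if not (0 <= self.matrix_attenuation <= 1):
            raise ValueError("matrix_attenuation must be in [0, 1]")
        for p in (self.default_p_dead, self.default_p_live):
            if not (0 <= p <= 1):
                raise ValueError("default probabilities must be in [0, 1]")

    def removal_probability(self, taxon_id: str, state: str) -> float:
        if state == "dead":
            p = self.p_dead_removed.get(taxon_id, self.default_p_dead)
            return p * self.matrix_attenuation
        return self.p_live_removed.get(taxon_id, self.default_p_live)


@dataclass
class SequencingModel:
    """Amplicon + qPCR readout parameters.

    ``depth`` — reads per sample (the bench's sequencing yielded a median
    of ~48k reads/sample; the default is scaled to that order);
    ``contamination_rate`` — per-read probability of a bleed-through draw
    from ``contaminant_pool``; ``qpcr_sigma_log10`` — s.d. of lognormal
    qPCR noise on the log10 scale.
    """

    depth: int = 50_000
    contamination_rate: float = 0.0
    contaminant_pool: dict[str, float] = field(default_factory=dict)
    qpcr_sigma_log10: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be ≥ 1")
        if not (0 <= self.contamination_rate <= 1):
            raise ValueError("contamination_rate must be in [0, 1]")
        if self.qpcr_sigma_log10 < 0:
            raise ValueError("qpcr_sigma_log10 must be ≥ 0")
        if self.contaminant_pool:
            s = sum(self.contaminant_pool.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"contaminant weights sum to {s}, not 1")
        elif self.contamination_rate > 0:
            raise ValueError("contamination_rate > 0 requires a contaminant pool")


@dataclass
class SpikeInSpec:
    """A live/dead *E. coli* spike-in (default ratio 1:1)."""

    taxon_id: str = "Escherichia_spike"
    live_cells: float = 5e5
    dead_cells: float = 5e5
    copy_number: int = 7

    def __post_init__(self) -> None:
        if self.live_cells <= 0 or self.dead_cells <= 0:
            raise ValueError("live_cells and dead_cells must be > 0")

    @property
    def total_cells(self) -> float:
        return self.live_cells + self.dead_cells


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# stochastic operations


def apply_pma(
    design: CommunityDesign,
    model: PmaActionModel,
    rng_seed: int | np.random.Generator | None = None,
) -> CommunityDesign:
    """Binomially thin each component by its PMA removal probability.

    Each component's cell count is thinned with retention ``1 − p`` where
    ``p`` is the (attenuated) dead-removal probability for dead cells and
    the toxicity probability for live cells.  Fractions are renormalized
    over surviving mass and ``total_cells`` scaled by overall survival.
    If nothing survives, the result is the empty design.
    """
    if design.is_empty:
        return CommunityDesign([], dict(design.copy_number), 0.0)
    rng = _as_rng(rng_seed)
    surviving: list[tuple[Component, float]] = []
    for comp in design.components:
        n = int(round(comp.cell_fraction * design.total_cells))
        p_remove = model.removal_probability(comp.taxon_id, comp.state)
        kept = int(rng.binomial(n, 1.0 - p_remove)) if n > 0 else 0
        if kept > 0:
            surviving.append((comp, float(kept)))
    total = sum(k for _, k in surviving)
    if total == 0:
        return CommunityDesign([], dict(design.copy_number), 0.0)
    components = [
        replace(comp, cell_fraction=k / total) for comp, k in surviving
    ]
    # exact renormalization: guard the 1e-9 sum invariant against float drift
    s = sum(c.cell_fraction for c in components)
    components[-1] = replace(
        components[-1], cell_fraction=components[-1].cell_fraction + (1.0 - s)
    )
    return CommunityDesign(components, dict(design.copy_number), total)


def sequence_community(
    design: CommunityDesign,
    seqmodel: SequencingModel,
    rng_seed: int | np.random.Generator | None = None,
    sample_id: str = "S1",
) -> AbundanceTable:
    """Draw one sample's read counts multinomially.

    Taxon weights are proportional to cell mass × 16S copy number.  Each
    read is independently replaced by a contaminant-pool draw with
    probability ``contamination_rate``; an empty design yields a library
    composed purely of contaminant reads (bleed-through filling a
    near-empty library), or an all-zero row if contamination is off.
    """
    rng = _as_rng(rng_seed if rng_seed is not None else seqmodel.seed)
    masses = design.taxon_masses()
    taxa = list(masses)
    weights = np.array([masses[t] * design.copy_number[t] for t in taxa], dtype=float)
    pool_taxa = list(seqmodel.contaminant_pool)
    pool_w = np.array([seqmodel.contaminant_pool[t] for t in pool_taxa], dtype=float)

    all_taxa = taxa + [t for t in pool_taxa if t not in taxa]
    counts = {t: 0 for t in all_taxa}

    if weights.sum() <= 0:
        n_contam = seqmodel.depth if seqmodel.contamination_rate > 0 else 0
        n_comm = 0
    else:
        n_contam = int(rng.binomial(seqmodel.depth, seqmodel.contamination_rate))
        n_comm = seqmodel.depth - n_contam
    if n_comm > 0:
        draw = rng.multinomial(n_comm, weights / weights.sum())
        for t, c in zip(taxa, draw):
            counts[t] += int(c)
    if n_contam > 0:
        draw = rng.multinomial(n_contam, pool_w / pool_w.sum())
        for t, c in zip(pool_taxa, draw):
            counts[t] += int(c)

    values = np.array([[counts[t] for t in all_taxa]], dtype=float)
    return AbundanceTable([sample_id], all_taxa, values, "counts")


def qpcr_total(
    design: CommunityDesign,
    seqmodel: SequencingModel,
    rng_seed: int | np.random.Generator | None = None,
    sample_id: str = "S1",
) -> QpcrEntry:
    """Total 16S copies on the log10 scale with lognormal noise.

    ``copies_log10 = log10(Σ cell_mass × copy_number) + N(0, σ)``; a
    zero-copy community is flagged below detection.
    """
    rng = _as_rng(rng_seed if rng_seed is not None else seqmodel.seed)
    total = design.total_16s_copies()
    if total <= 0:
        return QpcrEntry(sample_id, 0.0, below_detection=True)
    noise = rng.normal(0.0, seqmodel.qpcr_sigma_log10) if seqmodel.qpcr_sigma_log10 else 0.0
    return QpcrEntry(sample_id, math.log10(total) + noise)


# ---------------------------------------------------------------------------
# scenario builders


def make_two_strain_designs(
    copy_numbers: Mapping[str, int] | None = None,
    total_cells: float = 1e5,
) -> list[CommunityDesign]:
    """The ten two-strain live/dead mixtures at 10^5 CFU/ml.

    Groups (1-based): 1) 100% live E. coli; 2) 100% dead E. coli;
    3) 100% live S. sanguinis; 4) 100% dead S. sanguinis; 5) 50% live
    E. coli + 50% live S. sanguinis; 6) 50% dead E. coli + 50% dead
    S. sanguinis; 7) 50% live E. coli + 25% live + 25% dead S. sanguinis;
    8) 25% live + 25% dead E. coli + 50% live S. sanguinis; 9) 50% live
    E. coli + 50% dead S. sanguinis; 10) 50% dead E. coli + 50% live
    S. sanguinis.
    """
    cn = dict(copy_numbers or DEFAULT_COPY_NUMBERS)
    E, S = ECOLI, SSANGUINIS
    mixtures: list[list[tuple[str, str, float]]] = [
        [(E, "live", 1.0)],
        [(E, "dead", 1.0)],
        [(S, "live", 1.0)],
        [(S, "dead", 1.0)],
        [(E, "live", 0.5), (S, "live", 0.5)],
        [(E, "dead", 0.5), (S, "dead", 0.5)],
        [(E, "live", 0.5), (S, "live", 0.25), (S, "dead", 0.25)],
        [(E, "live", 0.25), (E, "dead", 0.25), (S, "live", 0.5)],
        [(E, "live", 0.5), (S, "dead", 0.5)],
        [(E, "dead", 0.5), (S, "live", 0.5)],
    ]
    return [
        CommunityDesign(
            [Component(t, st, f) for t, st, f in mix], dict(cn), total_cells
        )
        for mix in mixtures
    ]


def make_background(
    n_taxa: int = 50,
    total_cells: float = 1e3,
    live_fraction: float = 0.8,
    rng_seed: int | np.random.Generator | None = None,
    logseries_theta: float = 0.995,
    taxon_prefix: str = "bg",
    copy_number_range: tuple[int, int] = (1, 10),
) -> CommunityDesign:
    """A log-series background community with a live/dead split per taxon.

    Species-abundance distributions of environmental communities are well
    approximated by Fisher's log-series; taxon weights are drawn from
    ``logser(theta)`` and normalized.  Presets used in this package:
    screen/mouse-like low-biomass backgrounds (50 taxa, 10^3 cells) and
    soil/saliva-like high-biomass backgrounds (500 taxa, 10^7 cells).
    """
    if not (0 <= live_fraction <= 1):
        raise ValueError("live_fraction must be in [0, 1]")
    rng = _as_rng(rng_seed)
    weights = stats.logser.rvs(logseries_theta, size=n_taxa, random_state=rng).astype(float)
    weights /= weights.sum()
    comps: list[Component] = []
    copy_number: dict[str, int] = {}
    lo, hi = copy_number_range
    for i, w in enumerate(weights):
        taxon = f"{taxon_prefix}_{i:04d}"
        copy_number[taxon] = int(rng.integers(lo, hi + 1))
        if live_fraction > 0:
            comps.append(Component(taxon, "live", w * live_fraction))
        if live_fraction < 1:
            comps.append(Component(taxon, "dead", w * (1 - live_fraction)))
    # snap fraction sum to exactly 1
    s = sum(c.cell_fraction for c in comps)
    comps[-1] = replace(comps[-1], cell_fraction=comps[-1].cell_fraction + (1.0 - s))
    return CommunityDesign(comps, copy_number, total_cells)


def make_spiked_scenario(
    background: CommunityDesign,
    spike: SpikeInSpec,
) -> dict[str, CommunityDesign]:
    """The four-arm factorial of the spike-in calibration experiment.

    Returns pre-treatment designs keyed ``plain`` (no spike, no PMA),
    ``pma`` (no spike, to be PMA-treated), ``spike`` (spiked, no PMA) and
    ``spike_pma`` (spiked, to be PMA-treated).  PMA itself is applied
    downstream with :func:`apply_pma`; the two PMA arms start from the
    same composition as their untreated counterparts.  Low-biomass
    backgrounds pair with ~500 spike cells, high-biomass with 10^6.
    """
    if background.is_empty:
        raise ValueError("background must be non-empty")
    plain = CommunityDesign(
        list(background.components), dict(background.copy_number), background.total_cells
    )
    b, s = background.total_cells, spike.total_cells
    total = b + s
    comps = [
        replace(c, cell_fraction=c.cell_fraction * b / total)
        for c in background.components
    ]
    comps.append(Component(spike.taxon_id, "live", spike.live_cells / total))
    comps.append(Component(spike.taxon_id, "dead", spike.dead_cells / total))
    frac_sum = sum(c.cell_fraction for c in comps)
    comps[-1] = replace(
        comps[-1], cell_fraction=comps[-1].cell_fraction + (1.0 - frac_sum)
    )
    cn = dict(background.copy_number)
    cn[spike.taxon_id] = spike.copy_number
    spiked = CommunityDesign(comps, cn, total)
    return {
        "plain": plain,
        "pma": plain,
        "spike": spiked,
        "spike_pma": spiked,
    }


def simulate_spike_experiment(
    background: CommunityDesign,
    spike: SpikeInSpec,
    pma_model: PmaActionModel,
    seqmodel: SequencingModel,
    sample_type: str,
    n_replicates: int = 4,
    rng_seed: int | np.random.Generator | None = None,
) -> tuple[AbundanceTable, list[SampleMetadata], QpcrTable]:
    """Run the four-arm spike design end to end for one sample type.

    For every arm × replicate the pre-treatment design is (for the PMA
    arms) thinned with :func:`apply_pma`, then sequenced and qPCR'd.
    Returns a combined counts table over the union of observed taxa, the
    matching metadata, and the qPCR table.  The spike taxon carries the
    Enterobacteriaceae lineage so family-level reference matching works.
    """
    rng = _as_rng(rng_seed)
    arms = make_spiked_scenario(background, spike)
    arm_flags = {
        "plain": (False, False),
        "pma": (True, False),
        "spike": (False, True),
        "spike_pma": (True, True),
    }
    rows: list[tuple[str, dict[str, float]]] = []
    meta: list[SampleMetadata] = []
    qpcr_entries: list[QpcrEntry] = []
    for arm, design in arms.items():
        treated, spiked = arm_flags[arm]
        for rep in range(1, n_replicates + 1):
            sid = f"{sample_type}_{arm}_r{rep}"
            d = apply_pma(design, pma_model, rng) if treated else design
            one = sequence_community(d, seqmodel, rng, sample_id=sid)
            rows.append((sid, one.sample_row(sid)))
            meta.append(SampleMetadata(sid, sample_type, treated, spiked, rep))
            entry = qpcr_total(d, seqmodel, rng, sample_id=sid)
            qpcr_entries.append(entry)
    all_taxa: list[str] = []
    for _, row in rows:
        for t in row:
            if t not in all_taxa:
                all_taxa.append(t)
    values = np.array(
        [[row.get(t, 0.0) for t in all_taxa] for _, row in rows], dtype=float
    )
    taxonomy = {spike.taxon_id: SPIKE_LINEAGE} if spike.taxon_id in all_taxa else None
    table = AbundanceTable([sid for sid, _ in rows], all_taxa, values, "counts", taxonomy)
    return table, meta, QpcrTable(qpcr_entries)
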