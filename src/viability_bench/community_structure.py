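"""Compositional statistics: Bray–Curtis, PCoA, PERMANOVA.

Bray–Curtis dissimilarity, d(x, y) = 1 − 2 Σ min(xᵢ, yᵢ) / (Σxᵢ + Σyᵢ),
is computed on relative abundances.  Ordination uses classical metric
scaling (PCoA): eigendecomposition of the double-centered −½D² matrix,
coordinates scaled by √eigenvalue.  Group effects are tested with one-way
PERMANOVA: a pseudo-F on sums of squared distances, with a permutation
(or, for tiny designs, exact-enumeration) p-value.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from viability_bench.tables_io import AbundanceTable, SampleMetadata

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "Ordination",
    "GroupDistanceSummary",
    "bray_curtis",
    "group_distance_summary",
    "pcoa",
    "permanova",
    "permanova_by_factor",
]


@dataclass
class DistanceMatrix:
    """A symmetric sample × sample dissimilarity matrix in [0, 1]."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate sample IDs")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if self.values.min(initial=0) < -1e-12 or self.values.max(initial=0) > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class PermanovaResult:
    """One-way PERMANOVA outcome for a single grouping factor."""

    factor: str
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.r_squared <= 1):
            raise ValueError("r_squared must be in [0, 1]")
        if self.pseudo_f < 0:
            raise ValueError("pseudo_f must be ≥ 0")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")


@dataclass
class Ordination:
    """Classical-scaling coordinates with eigenvalue diagnostics."""

    ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


@dataclass
class GroupDistanceSummary:
    """Distance distributions for one sample type: all unordered pairs
    within each PMA arm, plus replicate-matched between-arm pairs."""

    sample_type: str
    within_free: np.ndarray
    within_treated: np.ndarray
    between_paired: np.ndarray


# ---------------------------------------------------------------------------


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarities between all sample pairs.

    Counts are converted to relative abundances first.  A pair of empty
    (all-zero) samples is undefined under the formula and is set to 0
    with a warning.
    """
    rel = table.to_relative()
    vals = rel.values
    with np.errstate(invalid="ignore", divide="ignore"):
        dm = squareform(pdist(vals, metric="braycurtis"))
    empty = vals.sum(axis=1) == 0
    if empty.any():
        nan_mask = np.isnan(dm)
        if nan_mask.any():
            warnings.warn(
                "Bray–Curtis between two empty samples is undefined; set to 0"
            )
            dm[nan_mask] = 0.0
    np.fill_diagonal(dm, 0.0)
    dm = np.clip((dm + dm.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(dm, 0.0)
    return DistanceMatrix(list(rel.sample_ids), dm)


def group_distance_summary(
    dm: DistanceMatrix,
    meta: Sequence[SampleMetadata],
    sample_type: str,
) -> GroupDistanceSummary:
    """Within-arm and between-arm distance distributions for one type.

    Within-arm distributions contain all unordered pairs inside the
    PMA-free (resp. PMA-treated) arm; the between distribution contains
    only replicate-matched pairs (same replicate and spike status, one
    treated and one not).
    """
    of_type = [m for m in meta if m.sample_type == sample_type]
    free = [m for m in of_type if not m.pma_treated]
    treated = [m for m in of_type if m.pma_treated]
    if not free or not treated:
        raise ValueError(f"sample type {sample_type!r} lacks one of the PMA arms")

    def pairs_within(group: list[SampleMetadata]) -> np.ndarray:
        return np.array(
            [dm.get(a.sample_id, b.sample_id) for a, b in itertools.combinations(group, 2)]
        )

    between = []
    for f in free:
        for t in treated:
            if f.replicate == t.replicate and f.spiked == t.spiked:
                between.append(dm.get(f.sample_id, t.sample_id))
    return GroupDistanceSummary(
        sample_type,
        pairs_within(free),
        pairs_within(treated),
        np.array(between),
    )


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Principal coordinate analysis (classical metric scaling).

    The squared distance matrix is double-centered (B = −½ J D² J),
    eigendecomposed, and coordinates are eigenvectors scaled by the
    square root of their (positive) eigenvalues, ordered by decreasing
    eigenvalue.  Negative eigenvalues (non-Euclidean input) are excluded
    from the ``proportion_explained`` denominator and yield no axis.
    """
    d2 = dm.values ** 2
    n = dm.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0])) if n else eigvals > 0
    pos_vals = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(pos_vals)
    if n_axes is not None:
        coords = coords[:, :n_axes]
        pos_vals = pos_vals[:n_axes]
    denom = eigvals[eigvals > 0].sum()
    prop = pos_vals / denom if denom > 0 else np.zeros_like(pos_vals)
    return Ordination(list(dm.ids), coords, pos_vals, prop)


# ---------------------------------------------------------------------------
# PERMANOVA


def _pseudo_f_and_r2(
    d2: np.ndarray, groups: np.ndarray, group_codes: np.ndarray
) -> tuple[float, float]:
    """Pseudo-F and R² from squared distances for integer group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in group_codes:
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(group_codes)
    if ss_within <= 0:
        f = math.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(min(max(r2, 0.0), 1.0))


def permanova(
    dm: DistanceMatrix,
    labels: Sequence[str],
    n_permutations: int = 9999,
    seed: int | None = None,
    factor: str = "group",
    method: Literal["permutation", "exact"] = "permutation",
) -> PermanovaResult:
    """One-way PERMANOVA of a grouping factor on a distance matrix.

    ``SS_total = Σ_{i<j} d²ᵢⱼ / n``, ``SS_within`` analogously per group,
    pseudo-F = (SS_between/(a−1)) / (SS_within/(n−a)).  The p-value is
    ``(1 + #{F_perm ≥ F_obs}) / (1 + n_permutations)`` under random label
    permutation with a fixed seed; ``method="exact"`` enumerates every
    distinct label assignment instead (only for small n) and reports
    ``#{F ≥ F_obs} / #assignments``.
    """
    labels = list(labels)
    if len(labels) != dm.n:
        raise ValueError("labels length does not match distance matrix")
    codes, uniques = _encode(labels)
    if len(uniques) < 2:
        raise ValueError("PERMANOVA needs ≥ 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = [u for u, c in zip(uniques, counts) if c < 2]
        raise ValueError(f"each group needs ≥ 2 samples; too small: {small}")
    d2 = dm.values ** 2
    group_codes = np.arange(len(uniques))
    f_obs, r2 = _pseudo_f_and_r2(d2, codes, group_codes)

    if method == "exact":
        perms = {tuple(p) for p in itertools.permutations(codes)}
        f_perm = np.array(
            [_pseudo_f_and_r2(d2, np.array(p), group_codes)[0] for p in perms]
        )
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        return PermanovaResult(factor, r2, f_obs, p, len(perms), seed)

    if n_permutations < 99:
        raise ValueError("n_permutations must be ≥ 99")
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = codes.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        f_p, _ = _pseudo_f_and_r2(d2, perm, group_codes)
        if f_p >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(factor, r2, f_obs, p, n_permutations, seed)


def _encode(labels: list[str]) -> tuple[np.ndarray, list[str]]:
    uniques: list[str] = []
    for l in labels:
        if l not in uniques:
            uniques.append(l)
    return np.array([uniques.index(l) for l in labels]), uniques


def permanova_by_factor(
    dm: DistanceMatrix,
    meta: Sequence[SampleMetadata],
    factors: Sequence[str] = ("sample_type", "pma_treated", "spiked"),
    n_permutations: int = 9999,
    seed: int | None = None,
) -> dict[str, PermanovaResult]:
    """Marginal one-way PERMANOVA per metadata factor with
    Benjamini–Hochberg adjustment of the p-values across factors."""
    by_id = {m.sample_id: m for m in meta}
    results: dict[str, PermanovaResult] = {}
    for i, factor in enumerate(factors):
        labels = [str(getattr(by_id[s], factor)) for s in dm.ids]
        sub_seed = None if seed is None else seed + i
        results[factor] = permanova(
            dm, labels, n_permutations=n_permutations, seed=sub_seed, factor=factor
        )
    pvals = [r.p_value for r in results.values()]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results.values(), p_adj):
        r.p_adjusted = float(q)
    return results
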