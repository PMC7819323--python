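"""Abundance-table I/O, genus collapsing and prevalence/abundance filtering.

Tables follow the common OTU-table convention: taxa as rows, samples as
columns, first header cell ``#OTU ID`` (or any taxon-ID label), and an
optional trailing ``taxonomy`` column carrying Greengenes-style lineage
strings (``k__Bacteria; p__...; g__Escherichia``).  In memory the table is
stored samples × taxa.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "QpcrEntry",
    "QpcrTable",
    "FilterParams",
    "read_table",
    "write_table",
    "collapse_to_genus",
    "filter_taxa",
    "read_metadata",
    "write_metadata",
    "read_qpcr",
    "write_qpcr",
    "concat_samples",
]

#: Greengenes rank prefixes ordered from kingdom to species.
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
GENUS_INDEX = RANK_PREFIXES.index("g__")

_REL_SUM_TOL = 1e-9


@dataclass
class AbundanceTable:
    """A samples × taxa matrix of counts or relative abundances.

    Parameters
    ----------
    sample_ids :
        Unique sample identifiers (rows of ``values``).
    taxon_ids :
        Unique taxon identifiers (columns of ``values``).
    values :
        Non-negative matrix of shape ``(n_samples, n_taxa)``.
    mode :
        ``"counts"`` for integer read counts, ``"relative"`` for
        per-sample fractions.  Relative rows must sum to 1 within 1e-9
        unless the row is all-zero (a "no signal" sample).
    taxonomy :
        Optional map from taxon ID to a semicolon-separated lineage string.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    mode: Literal["counts", "relative"]
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.sample_ids),
            len(self.taxon_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon IDs")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "relative" and self.values.size:
            # rows sum to 1 within 1e-9; all-zero rows mark "no signal"
            # samples; sums below 1 arise from non-renormalized filtering
            sums = self.values.sum(axis=1)
            bad = sums > 1.0 + _REL_SUM_TOL
            if bad.any():
                i = int(np.argmax(bad))
                raise ValueError(
                    f"relative-mode row {self.sample_ids[i]!r} sums to {sums[i]!r} > 1"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def empty_samples(self) -> list[str]:
        """Sample IDs whose rows are all-zero (no signal)."""
        mask = self.values.sum(axis=1) == 0
        return [s for s, m in zip(self.sample_ids, mask) if m]

    def to_relative(self) -> "AbundanceTable":
        """Convert counts to per-sample relative abundances.

        All-zero rows stay all-zero (flagged via :attr:`empty_samples`)
        rather than becoming NaN.
        """
        if self.mode == "relative":
            return self
        totals = self.values.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(totals > 0, self.values / np.where(totals == 0, 1, totals), 0.0)
        return AbundanceTable(
            list(self.sample_ids), list(self.taxon_ids), rel, "relative",
            dict(self.taxonomy) if self.taxonomy else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Samples × taxa :class:`pandas.DataFrame` view."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def sample_row(self, sample_id: str) -> dict[str, float]:
        """Mapping taxon → value for one sample."""
        i = self.sample_ids.index(sample_id)
        return dict(zip(self.taxon_ids, self.values[i]))


@dataclass
class SampleMetadata:
    """Per-sample experimental annotations."""

    sample_id: str
    sample_type: str
    pma_treated: bool
    spiked: bool
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be ≥ 1, got {self.replicate}")


@dataclass
class QpcrEntry:
    """Total 16S rRNA gene copies for one sample, on a log10 scale.

    A sample with no amplifiable signal is flagged ``below_detection``
    instead of carrying −inf.
    """

    sample_id: str
    copies_log10: float
    below_detection: bool = False

    def __post_init__(self) -> None:
        if not self.below_detection and not math.isfinite(self.copies_log10):
            raise ValueError(
                f"copies_log10 must be finite for {self.sample_id!r}; "
                "use below_detection=True for zero-copy samples"
            )


@dataclass
class QpcrTable:
    """Collection of per-sample qPCR totals."""

    entries: list[QpcrEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample IDs in qPCR table")

    def get(self, sample_id: str) -> QpcrEntry:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        raise KeyError(sample_id)

    def mean_log10(self, sample_ids: Iterable[str]) -> float:
        """Mean ``copies_log10`` over the given samples.

        Below-detection entries are excluded with a warning; if every
        entry is below detection the mean is 0.
        """
        vals = []
        for sid in sample_ids:
            e = self.get(sid)
            if e.below_detection:
                warnings.warn(f"sample {sid!r} below qPCR detection; excluded from mean")
            else:
                vals.append(e.copies_log10)
        return float(np.mean(vals)) if vals else 0.0


@dataclass
class FilterParams:
    """Prevalence/abundance filter: keep taxa exceeding ``min_rel_abund``
    (strictly) in at least ``min_prevalence`` of all samples."""

    min_rel_abund: float = 1e-4
    min_prevalence: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.min_rel_abund < 1):
            raise ValueError("min_rel_abund must be in [0, 1)")
        if not (0 < self.min_prevalence <= 1):
            raise ValueError("min_prevalence must be in (0, 1]")


# ---------------------------------------------------------------------------
# reading / writing


def _infer_mode(values: np.ndarray) -> str:
    """Integer-valued tables are counts; fractional tables are relative."""
    if values.size == 0:
        return "counts"
    return "counts" if np.all(values == np.round(values)) else "relative"


def read_table(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Read an abundance table from TSV or BIOM 1.0 JSON.

    TSV layout: taxa as rows, samples as columns, first column the taxon
    ID (header cell ``#OTU ID`` accepted), optional last column
    ``taxonomy``.  Mode is inferred: all-integer values → counts,
    otherwise relative (columns must then sum to 1 within tolerance).
    """
    path = Path(path)
    if format == "biom_json":
        return _read_biom_json(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    df = df.set_index(df.columns[0])
    taxonomy = None
    if df.columns[-1].lower() in ("taxonomy", "lineage"):
        taxonomy = {str(t): str(l) for t, l in df.iloc[:, -1].items()}
        df = df.iloc[:, :-1]
    values = df.to_numpy(dtype=float).T  # rows were taxa
    taxon_ids = [str(t) for t in df.index]
    if len(set(taxon_ids)) != len(taxon_ids):
        dupes = sorted({t for t in taxon_ids if taxon_ids.count(t) > 1})
        raise ValueError(f"duplicate taxon IDs in {path}: {dupes}")
    sample_ids = [str(c) for c in df.columns]
    mode = _infer_mode(values)
    if mode == "relative":
        # rows within 1e-5 of unity (rounding in upstream exports) are
        # snapped to exactly 1; other sums (filtered tables) pass through
        sums = values.sum(axis=1, keepdims=True)
        near_one = np.isclose(sums, 1.0, atol=1e-5) & ~np.isclose(sums, 0.0)
        values = np.where(near_one, values / np.where(sums == 0, 1, sums), values)
    return AbundanceTable(sample_ids, taxon_ids, values, mode, taxonomy)


def _read_biom_json(path: Path) -> AbundanceTable:
    """Minimal BIOM 1.0 (JSON) reader: dense or sparse matrices, row
    (observation) taxonomy metadata."""
    with open(path) as fh:
        doc = json.load(fh)
    n_rows, n_cols = doc["shape"]
    values = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type", "sparse") == "dense":
        values[:] = np.asarray(doc["data"], dtype=float)
    else:
        for r, c, v in doc["data"]:
            values[int(r), int(c)] = v
    taxon_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    if len(set(taxon_ids)) != len(taxon_ids):
        raise ValueError(f"duplicate taxon IDs in {path}")
    taxonomy = {}
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        lineage = meta.get("taxonomy")
        if lineage is not None:
            if isinstance(lineage, (list, tuple)):
                lineage = "; ".join(str(x) for x in lineage)
            taxonomy[str(r["id"])] = str(lineage)
    mat = values.T  # BIOM rows are observations
    return AbundanceTable(
        sample_ids, taxon_ids, mat, _infer_mode(mat), taxonomy or None
    )


def write_table(table: AbundanceTable, path: str | Path, format: str = "tsv") -> None:
    """Write a table as TSV (taxa as rows), preserving column order.

    Count tables round-trip bit-exactly; relative tables round-trip to
    full float precision (``repr`` formatting).
    """
    if format != "tsv":
        raise ValueError("only tsv writing is supported")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        header = ["#OTU ID"] + list(table.sample_ids)
        if table.taxonomy:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for j, taxon in enumerate(table.taxon_ids):
            col = table.values[:, j]
            if table.mode == "counts":
                cells = [str(int(v)) for v in col]
            else:
                cells = [repr(float(v)) for v in col]
            row = [taxon] + cells
            if table.taxonomy:
                row.append(table.taxonomy.get(taxon, ""))
            fh.write("\t".join(row) + "\n")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample metadata from a TSV with columns sample_id,
    sample_type, pma_treated, spiked, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                sample_type=row["sample_type"],
                pma_treated=str(row["pma_treated"]).strip().lower() in ("1", "true", "yes"),
                spiked=str(row["spiked"]).strip().lower() in ("1", "true", "yes"),
                replicate=int(row.get("replicate", 1)),
            )
        )
    return out


def write_metadata(meta: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "sample_type": [m.sample_type for m in meta],
            "pma_treated": [m.pma_treated for m in meta],
            "spiked": [m.spiked for m in meta],
            "replicate": [m.replicate for m in meta],
        }
    ).to_csv(path, sep="\t", index=False)


def read_qpcr(path: str | Path) -> QpcrTable:
    """Read per-sample log10 16S copies from TSV (columns sample_id,
    copies_log10; the literal value ``below_detection`` flags no signal)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    for _, row in df.iterrows():
        raw = str(row["copies_log10"]).strip()
        if raw.lower() == "below_detection":
            entries.append(QpcrEntry(row["sample_id"], 0.0, below_detection=True))
        else:
            entries.append(QpcrEntry(row["sample_id"], float(raw)))
    return QpcrTable(entries)


def write_qpcr(qpcr: QpcrTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tcopies_log10\n")
        for e in qpcr.entries:
            val = "below_detection" if e.below_detection else repr(e.copies_log10)
            fh.write(f"{e.sample_id}\t{val}\n")


def concat_samples(tables: Sequence[AbundanceTable]) -> AbundanceTable:
    """Stack single- or multi-sample tables over the union of their taxa.

    Missing taxa are filled with 0; all inputs must share the same mode.
    Taxonomy maps are merged (first occurrence wins).
    """
    if not tables:
        raise ValueError("no tables to concatenate")
    modes = {t.mode for t in tables}
    if len(modes) > 1:
        raise ValueError(f"mixed modes {modes}")
    taxa: list[str] = []
    for t in tables:
        for tx in t.taxon_ids:
            if tx not in taxa:
                taxa.append(tx)
    sample_ids: list[str] = []
    rows = []
    taxonomy: dict[str, str] = {}
    for t in tables:
        col = {tx: j for j, tx in enumerate(t.taxon_ids)}
        for i, sid in enumerate(t.sample_ids):
            sample_ids.append(sid)
            rows.append([t.values[i, col[tx]] if tx in col else 0.0 for tx in taxa])
        if t.taxonomy:
            for tx, lin in t.taxonomy.items():
                taxonomy.setdefault(tx, lin)
    return AbundanceTable(
        sample_ids, taxa, np.array(rows, dtype=float), modes.pop(), taxonomy or None
    )


# ---------------------------------------------------------------------------
# genus collapsing


def _parse_lineage(lineage: str) -> dict[str, str]:
    """Split ``k__Bacteria; p__X; ...`` into prefix → name (empty names
    dropped)."""
    out: dict[str, str] = {}
    for part in lineage.split(";"):
        part = part.strip()
        for pref in RANK_PREFIXES:
            if part.startswith(pref):
                name = part[len(pref):].strip()
                if name:
                    out[pref] = name
                break
    return out


def _collapse_label(lineage: str) -> str:
    """Genus label if assigned, else the terminal assigned rank with its
    Greengenes prefix (e.g. ``f__Enterobacteriaceae``)."""
    ranks = _parse_lineage(lineage)
    if "g__" in ranks:
        return "g__" + ranks["g__"]
    for pref in reversed(RANK_PREFIXES):
        if pref == "s__":
            continue  # a species without a genus is not meaningful
        if pref in ranks:
            return pref + ranks[pref]
    return "unclassified"


def _truncate_lineage(lineage: str, label: str) -> str:
    """Lineage truncated at (and including) the collapsed rank."""
    parts = [p.strip() for p in lineage.split(";")]
    kept = []
    for part in parts:
        kept.append(part)
        if part == label or part.replace(" ", "") == label.replace(" ", ""):
            break
    return "; ".join(kept)


def collapse_to_genus(table: AbundanceTable) -> AbundanceTable:
    """Condense OTUs to genus level; genus-unassigned OTUs are summed at
    their terminal assigned rank (``f__``, ``o__``, ... prefixed labels).

    Per-sample totals are conserved exactly.
    """
    if table.taxonomy is None:
        raise ValueError("collapse_to_genus requires taxonomy")
    missing = [t for t in table.taxon_ids if t not in table.taxonomy]
    if missing:
        raise ValueError(f"missing taxonomy for OTUs: {missing}")
    labels = [_collapse_label(table.taxonomy[t]) for t in table.taxon_ids]
    order: list[str] = []
    cols: dict[str, np.ndarray] = {}
    lineages: dict[str, str] = {}
    for j, label in enumerate(labels):
        if label not in cols:
            order.append(label)
            cols[label] = np.zeros(table.n_samples)
            lineages[label] = _truncate_lineage(table.taxonomy[table.taxon_ids[j]], label)
        cols[label] = cols[label] + table.values[:, j]
    values = np.column_stack([cols[l] for l in order]) if order else np.zeros((table.n_samples, 0))
    return AbundanceTable(list(table.sample_ids), order, values, table.mode, lineages)


# ---------------------------------------------------------------------------
# prevalence/abundance filter


def filter_taxa(
    table: AbundanceTable,
    params: FilterParams | None = None,
    renormalize: bool = False,
) -> AbundanceTable:
    """Keep taxa whose relative abundance strictly exceeds
    ``params.min_rel_abund`` in at least ``ceil(params.min_prevalence ×
    n_samples)`` samples.

    Counts are converted per-sample to relative abundances for the test;
    the returned table keeps the input's values and mode.  Rows are not
    renormalized unless ``renormalize=True`` (then the result is
    relative-mode).
    """
    params = params or FilterParams()
    if table.n_samples == 0 or table.n_taxa == 0:
        raise ValueError("cannot filter an empty table")
    rel = table.to_relative()
    prevalence = (rel.values > params.min_rel_abund).sum(axis=0)
    need = math.ceil(params.min_prevalence * table.n_samples)
    keep = prevalence >= need
    if not keep.any():
        warnings.warn("prevalence/abundance filter removed every taxon")
    taxon_ids = [t for t, k in zip(table.taxon_ids, keep) if k]
    values = table.values[:, keep]
    taxonomy = (
        {t: table.taxonomy[t] for t in taxon_ids if t in table.taxonomy}
        if table.taxonomy
        else None
    )
    if renormalize:
        sums = values.sum(axis=1, keepdims=True)
        values = np.where(sums > 0, values / np.where(sums == 0, 1, sums), 0.0)
        return AbundanceTable(list(table.sample_ids), taxon_ids, values, "relative", taxonomy)
    return AbundanceTable(list(table.sample_ids), taxon_ids, values, table.mode, taxonomy)
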