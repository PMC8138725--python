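"""Core data containers and delimited-text IO.

The pipeline's on-disk formats are deliberately plain: gene-by-sample count
tables (genes in rows, one header row of sample IDs, first column gene
symbols), a six-column sample-metadata table, and gene-by-compound profile
tables.  Tab is the canonical delimiter; comma is accepted on input.

Gene identity is the symbol string, case-sensitive.  No alias resolution is
attempted anywhere: silently remapping or reordering genes is the classic way
a biomarker pipeline goes wrong, so readers preserve on-disk order exactly and
writers refuse (rather than reorder) when gene lists disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleMetadata",
    "CompoundProfile",
    "read_count_matrix",
    "write_count_matrix",
    "read_metadata",
    "write_metadata",
    "read_profiles",
    "write_profiles",
    "read_labels",
    "write_labels",
]

#: recognised class labels for samples / compounds
CLASS_LABELS = ("HDACi", "non-HDACi", "control", "qc", "unknown")

METADATA_COLUMNS = (
    "sample_id",
    "compound",
    "class_label",
    "replicate",
    "vehicle_control_id",
    "batch",
)


@dataclass(frozen=True)
class SampleMetadata:
    """One sequencing library: which compound, which class, which control.

    ``vehicle_control_id`` names the matched solvent-control sample the
    treated sample is ratioed against; it is empty for control, qc and water
    samples themselves.
    """

    sample_id: str
    compound: str
    class_label: str
    replicate: int
    vehicle_control_id: str = ""
    batch: str = ""

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label {self.class_label!r} for sample {self.sample_id!r} "
                f"not one of {CLASS_LABELS}"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


class CountMatrix:
    """Gene x sample matrix of raw read counts or CPM.

    Parameters
    ----------
    values
        DataFrame with gene symbols as index and sample IDs as columns.
        All entries must be finite and non-negative.
    unit
        ``"raw"`` for read counts, ``"cpm"`` for counts-per-million.
    metadata
        Optional mapping sample_id -> :class:`SampleMetadata`.  When given,
        every sample column must have a record.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        unit: str = "raw",
        metadata: Mapping[str, SampleMetadata] | None = None,
    ) -> None:
        if unit not in ("raw", "cpm"):
            raise ValueError(f"unit must be 'raw' or 'cpm', got {unit!r}")
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol: {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("count matrix contains non-finite values")
        if (arr < 0).any():
            raise ValueError("count matrix contains negative values")
        if metadata is not None:
            missing = [s for s in values.columns if s not in metadata]
            if missing:
                raise ValueError(f"samples without metadata record: {missing}")
        self.values = values
        self.unit = unit
        self.metadata = dict(metadata) if metadata is not None else None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def with_metadata(self, records: Iterable[SampleMetadata]) -> "CountMatrix":
        """Attach metadata records (validating coverage) without copying values."""
        meta = {r.sample_id: r for r in records}
        return CountMatrix(self.values, unit=self.unit, metadata=meta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.values.shape
        return f"<CountMatrix {g} genes x {s} samples, unit={self.unit}>"


@dataclass
class CompoundProfile:
    """One compound's control-normalized, replicate-averaged log2 profile."""

    compound: str
    class_label: str
    genes: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.genes) != self.values.shape[0]:
            raise ValueError(
                f"profile {self.compound!r}: {len(self.genes)} genes but "
                f"{self.values.shape[0]} values"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"profile {self.compound!r} contains non-finite values")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class_label {self.class_label!r}")


# ---------------------------------------------------------------------------
# delimiter sniffing
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    return "\t" if "\t" in header else ","


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, unit: str = "raw") -> CountMatrix:
    """Read a genes-in-rows count table (GEO supplementary TXT style).

    First column: gene symbols.  Header row: sample IDs.  Tab-delimited
    preferred, comma accepted.  Row and column order are preserved exactly as
    on disk.  ``unit`` is caller-declared ('raw' counts or 'cpm').
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows/columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[int(np.argmax(bad.isna().to_numpy()))]
            raise ValueError(
                f"{path}: non-numeric value at gene {row!r}, sample {col!r}"
            )
    return CountMatrix(df.astype(float), unit=unit)


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as tab-delimited text at full double precision."""
    _write_table(m.values, Path(path), index_label="gene")


def _write_table(df: pd.DataFrame, path: Path, index_label: str) -> None:
    # repr-precision floats so read(write(x)) is the identity to >=12 sig digits
    with open(path, "w") as fh:
        fh.write(index_label + "\t" + "\t".join(map(str, df.columns)) + "\n")
        for idx, row in zip(df.index, df.to_numpy()):
            fh.write(str(idx) + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read and validate the six-column sample-metadata table.

    Every non-empty ``vehicle_control_id`` must name a sample in the table
    whose class_label is ``control``; (compound, replicate, batch) must be
    unique.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required metadata column(s) {missing}")
    records = [
        SampleMetadata(
            sample_id=row["sample_id"],
            compound=row["compound"],
            class_label=row["class_label"],
            replicate=int(row["replicate"]),
            vehicle_control_id=row["vehicle_control_id"],
            batch=row["batch"],
        )
        for _, row in df.iterrows()
    ]
    validate_metadata(records)
    return records


def validate_metadata(records: Sequence[SampleMetadata]) -> None:
    by_id = {r.sample_id: r for r in records}
    if len(by_id) != len(records):
        seen: set[str] = set()
        for r in records:
            if r.sample_id in seen:
                raise ValueError(f"duplicate sample_id {r.sample_id!r}")
            seen.add(r.sample_id)
    keys = set()
    for r in records:
        key = (r.compound, r.replicate, r.batch)
        if key in keys:
            raise ValueError(f"duplicate (compound, replicate, batch): {key}")
        keys.add(key)
        if r.vehicle_control_id:
            ctrl = by_id.get(r.vehicle_control_id)
            if ctrl is None:
                raise ValueError(
                    f"sample {r.sample_id!r} references absent control "
                    f"{r.vehicle_control_id!r}"
                )
            if ctrl.class_label != "control":
                raise ValueError(
                    f"sample {r.sample_id!r} references {r.vehicle_control_id!r} "
                    f"whose class_label is {ctrl.class_label!r}, not 'control'"
                )


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "compound": r.compound,
                "class_label": r.class_label,
                "replicate": r.replicate,
                "vehicle_control_id": r.vehicle_control_id,
                "batch": r.batch,
            }
            for r in records
        ],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# compound profiles
# ---------------------------------------------------------------------------

def write_profiles(profiles: Sequence[CompoundProfile], path: str | Path) -> None:
    """Write profiles as a genes-in-rows, compounds-in-columns TSV.

    All profiles must share an *identical* (same order) gene list; profiles
    whose gene lists merely contain the same set are refused rather than
    silently reordered.  Use :func:`tgx_hdaci.biomarker.subset_profile` for
    explicit alignment.
    """
    if not profiles:
        raise ValueError("no profiles to write")
    genes = profiles[0].genes
    for p in profiles[1:]:
        if p.genes != genes:
            raise ValueError(
                f"profile {p.compound!r} has a different gene list/order than "
                f"{profiles[0].compound!r}; refusing to reorder"
            )
    df = pd.DataFrame(
        np.column_stack([p.values for p in profiles]),
        index=list(genes),
        columns=[p.compound for p in profiles],
    )
    _write_table(df, Path(path), index_label="gene")


def read_profiles(
    path: str | Path, labels: Mapping[str, str] | None = None
) -> list[CompoundProfile]:
    """Read a profiles TSV; ``labels`` optionally maps compound -> class."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    genes = tuple(str(g) for g in df.index)
    labels = labels or {}
    return [
        CompoundProfile(
            compound=str(c),
            class_label=labels.get(str(c), "unknown"),
            genes=genes,
            values=df[c].to_numpy(dtype=float),
        )
        for c in df.columns
    ]


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a compound -> class_label table (columns: compound, class_label)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("compound", "class_label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return dict(zip(df["compound"], df["class_label"]))


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"compound": list(labels), "class_label": [labels[c] for c in labels]}
    ).to_csv(path, sep="\t", index=False)
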