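"""Core data structures and file I/O for OTU count tables.

The central container is :class:`OtuTable`, an integer matrix of read
(copy) counts with OTUs as rows and samples as columns.  Replicate
structure — which samples are technical replicates of the same stool
specimen — lives in :class:`ReplicateDesign`; taxonomic lineages in
:class:`TaxonomyTable`.  I/O covers the mothur ``.shared`` dialect
(samples as rows), generic TSV matrices, and greengenes-style taxonomy
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "ReplicateDesign",
    "TaxonomyTable",
    "FilterResult",
    "OtuTableError",
    "read_shared",
    "write_shared",
    "read_tsv_table",
    "write_tsv_table",
    "read_design",
    "write_design",
    "read_taxonomy",
    "write_taxonomy",
    "total_reads",
]

_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class OtuTableError(ValueError):
    """Raised on malformed input files or invariant violations."""


class OtuTable:
    """Integer OTU-by-sample count matrix.

    Parameters
    ----------
    counts : array-like or DataFrame, shape (n_otus, n_samples)
        Non-negative integer read counts.  If a DataFrame, its index and
        columns supply the identifiers.
    otu_ids, sample_ids : sequences of str, optional
        Row and column identifiers; required when ``counts`` is a bare
        array.

    Notes
    -----
    Counts are stored as exact integers; relative abundances are always
    derived on demand so that filtering operates on copies.  An OTU is
    "detected" in a sample iff its count is >= 1.
    """

    def __init__(self, counts, otu_ids=None, sample_ids=None):
        if isinstance(counts, pd.DataFrame):
            df = counts.copy()
            if otu_ids is not None:
                df.index = list(otu_ids)
            if sample_ids is not None:
                df.columns = list(sample_ids)
        else:
            arr = np.asarray(counts)
            if arr.ndim != 2:
                raise OtuTableError("counts must be a 2-D matrix")
            if otu_ids is None:
                otu_ids = [f"Otu{i + 1:04d}" for i in range(arr.shape[0])]
            if sample_ids is None:
                sample_ids = [f"S{j + 1}" for j in range(arr.shape[1])]
            df = pd.DataFrame(arr, index=list(otu_ids), columns=list(sample_ids))
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise OtuTableError(f"duplicate OTU ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise OtuTableError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise OtuTableError("counts must be integer-valued")
            df = df.astype(np.int64)
        else:
            df = df.astype(np.int64) if values.size else df.astype(np.int64)
        if df.size and (df.to_numpy() < 0).any():
            raise OtuTableError("counts must be non-negative")
        self._df = df
        self._df.index.name = "otu_id"
        self._df.columns.name = "sample_id"

    # -- accessors ---------------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an (n_otus, n_samples) int array (copy)."""
        return self._df.to_numpy(copy=True)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    @property
    def n_otus(self) -> int:
        return self._df.shape[0]

    @property
    def n_samples(self) -> int:
        return self._df.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    def sample(self, sample_id: str) -> np.ndarray:
        """Count vector of one sample."""
        if sample_id not in self._df.columns:
            raise KeyError(sample_id)
        return self._df[sample_id].to_numpy(copy=True)

    def subset_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self._df.columns]
        if missing:
            raise OtuTableError(f"unknown sample ids: {missing}")
        return OtuTable(self._df.loc[:, sample_ids])

    def drop_empty_otus(self) -> "OtuTable":
        """Remove OTU rows whose counts are zero in every sample."""
        keep = self._df.sum(axis=1) > 0
        return OtuTable(self._df.loc[keep])

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self._df.sum(axis=0)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise OtuTableError(f"samples with zero total reads: {empty}")
        return self._df / totals

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"OtuTable({self.n_otus} OTUs x {self.n_samples} samples)"


@dataclass(frozen=True)
class ReplicateDesign:
    """Mapping of each sample to the specimen (individual) it replicates.

    Every sample of the associated table must be assigned to exactly one
    specimen; samples missing from the design are a hard error, never a
    silent exclusion.
    """

    sample_to_specimen: Mapping[str, str]

    @property
    def specimens(self) -> list[str]:
        seen: dict[str, None] = {}
        for spec in self.sample_to_specimen.values():
            seen.setdefault(spec, None)
        return list(seen)

    def samples_of(self, specimen: str) -> list[str]:
        return [s for s, g in self.sample_to_specimen.items() if g == specimen]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, spec in self.sample_to_specimen.items():
            out.setdefault(spec, []).append(sample)
        return out

    def validate(self, table: OtuTable, require_triplicates: bool = False) -> None:
        missing = [s for s in table.sample_ids if s not in self.sample_to_specimen]
        if missing:
            raise OtuTableError(
                f"samples absent from the replicate design: {missing}"
            )
        if require_triplicates:
            in_table = set(table.sample_ids)
            for spec, samples in self.groups().items():
                present = [s for s in samples if s in in_table]
                if len(present) != 3:
                    raise OtuTableError(
                        f"specimen {spec!r} has {len(present)} replicates in the "
                        "table; triplicate operations require exactly 3"
                    )

    def labels_for(self, sample_ids: Iterable[str]) -> list[str]:
        """Specimen label per sample, in the given order."""
        out = []
        for s in sample_ids:
            if s not in self.sample_to_specimen:
                raise OtuTableError(f"sample {s!r} absent from the replicate design")
            out.append(self.sample_to_specimen[s])
        return out


@dataclass(frozen=True)
class TaxonomyTable:
    """OTU -> ranked lineage (kingdom ... genus); phylum is the rank the
    composition summaries use."""

    otu_to_lineage: Mapping[str, tuple[str, ...]]

    def phylum(self, otu_id: str) -> str:
        lineage = self.otu_to_lineage.get(otu_id)
        if lineage is None or len(lineage) < 2 or not lineage[1]:
            return "unclassified"
        return lineage[1]

    def rank(self, otu_id: str, rank: str) -> str:
        try:
            level = _RANKS.index(rank)
        except ValueError:
            raise OtuTableError(f"unknown rank {rank!r}; expected one of {_RANKS}")
        lineage = self.otu_to_lineage.get(otu_id, ())
        if level < len(lineage) and lineage[level]:
            return lineage[level]
        return "unclassified"


@dataclass
class FilterResult:
    """Outcome of one filtering method: the filtered table plus per-sample
    removal accounting.

    Invariant: for every sample, pre-filter total = post-filter total +
    ``reads_removed_per_sample``.
    """

    table: OtuTable
    reads_removed_per_sample: dict[str, int]
    otus_zeroed: dict[str, set[str]]
    method_label: str

    def total_reads_removed(self) -> int:
        return int(sum(self.reads_removed_per_sample.values()))


# -- totals ----------------------------------------------------------------

def total_reads(table: OtuTable) -> tuple[dict[str, int], int]:
    """Per-sample read totals and the pooled grand total.

    Returns ``(per_sample, grand_total)``.  The mean reads per sample is
    ``grand_total / n_samples``; for display the integer part is used.
    """
    sums = table.to_dataframe().sum(axis=0)
    per_sample = {s: int(v) for s, v in sums.items()}
    return per_sample, int(sums.sum())


# -- mothur .shared dialect ------------------------------------------------

def read_shared(path) -> OtuTable:
    """Read a mothur ``.shared``-style file (one row per sample).

    Expected layout: tab-delimited with header
    ``label<TAB>Group<TAB>numOtus<TAB>Otu0001<TAB>...`` and integer counts.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if not lines:
        raise OtuTableError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "label" or header[1] != "Group" or header[2] != "numOtus":
        raise OtuTableError(
            f"{path}: malformed header; expected 'label\\tGroup\\tnumOtus\\t...', "
            f"got {header[:3]}"
        )
    otu_ids = header[3:]
    samples: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise OtuTableError(
                f"{path}: row {lineno} has {len(fields)} fields, expected {len(header)}"
            )
        group = fields[1]
        if group in samples:
            raise OtuTableError(f"{path}: duplicate Group {group!r} at row {lineno}")
        counts = []
        for otu, val in zip(otu_ids, fields[3:]):
            try:
                counts.append(int(val))
            except ValueError:
                raise OtuTableError(
                    f"{path}: non-integer count {val!r} at row {lineno}, column {otu}"
                ) from None
        samples.append(group)
        rows.append(counts)
    matrix = np.array(rows, dtype=np.int64).T if rows else np.empty((len(otu_ids), 0), dtype=np.int64)
    return OtuTable(matrix, otu_ids=otu_ids, sample_ids=samples)


def write_shared(table: OtuTable, path, label: str = "0.03") -> None:
    """Write an :class:`OtuTable` in the mothur ``.shared`` dialect."""
    path = Path(path)
    df = table.to_dataframe()
    with path.open("w") as fh:
        fh.write("\t".join(["label", "Group", "numOtus", *table.otu_ids]) + "\n")
        n = str(table.n_otus)
        for sample in table.sample_ids:
            row = df[sample].astype(str).tolist()
            fh.write("\t".join([label, sample, n, *row]) + "\n")


# -- generic TSV matrix ----------------------------------------------------

def read_tsv_table(path, orientation: str = "otus_as_rows") -> OtuTable:
    """Read a rectangular TSV count matrix.

    ``orientation`` selects whether rows are OTUs (``"otus_as_rows"``,
    first column = OTU ids, remaining columns = samples) or samples
    (``"samples_as_rows"``).
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise OtuTableError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with path.open() as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if not lines:
        raise OtuTableError(f"{path}: empty file")
    header = lines[0].split("\t")
    width = len(header)
    col_ids = header[1:]
    row_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != width:
            raise OtuTableError(
                f"{path}: ragged row {lineno} ({len(fields)} fields, expected {width})"
            )
        row_ids.append(fields[0])
        vals = []
        for col, val in zip(col_ids, fields[1:]):
            try:
                v = int(val)
            except ValueError:
                raise OtuTableError(
                    f"{path}: non-integer count {val!r} at row {lineno}, column {col}"
                ) from None
            if v < 0:
                raise OtuTableError(
                    f"{path}: negative count {v} at row {lineno}, column {col}"
                )
            vals.append(v)
        rows.append(vals)
    matrix = np.array(rows, dtype=np.int64) if rows else np.empty((0, len(col_ids)), dtype=np.int64)
    if orientation == "samples_as_rows":
        return OtuTable(matrix.T, otu_ids=col_ids, sample_ids=row_ids)
    return OtuTable(matrix, otu_ids=row_ids, sample_ids=col_ids)


def write_tsv_table(table: OtuTable, path, orientation: str = "otus_as_rows") -> None:
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise OtuTableError(f"unknown orientation {orientation!r}")
    df = table.to_dataframe()
    if orientation == "samples_as_rows":
        df = df.T
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# -- replicate design ------------------------------------------------------

def read_design(path) -> ReplicateDesign:
    """Read a two-column TSV ``sample_id<TAB>specimen_id`` (header optional)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise OtuTableError(f"{path}: row {lineno} needs two columns")
            if lineno == 1 and fields[0].lower() in ("sample", "sample_id"):
                continue
            sample, specimen = fields[0], fields[1]
            if sample in mapping:
                raise OtuTableError(f"{path}: duplicate sample {sample!r} at row {lineno}")
            mapping[sample] = specimen
    if not mapping:
        raise OtuTableError(f"{path}: empty design file")
    return ReplicateDesign(mapping)


def write_design(design: ReplicateDesign, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tspecimen_id\n")
        for sample, specimen in design.sample_to_specimen.items():
            fh.write(f"{sample}\t{specimen}\n")


# -- taxonomy --------------------------------------------------------------

def _parse_lineage(text: str) -> tuple[str, ...]:
    """Parse a greengenes-style lineage string, or plain ';'-separated ranks."""
    parts = [p.strip() for p in text.rstrip(";").split(";")]
    ranks = []
    for part in parts:
        if "__" in part:
            part = part.split("__", 1)[1]
        ranks.append(part)
    return tuple(ranks)


def read_taxonomy(path) -> TaxonomyTable:
    """Read a taxonomy TSV: ``otu_id<TAB>k__...;p__...;...`` or an
    ``otu_id`` column followed by plain rank columns."""
    path = Path(path)
    mapping: dict[str, tuple[str, ...]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("otu", "otu_id"):
                continue
            if len(fields) < 2:
                raise OtuTableError(f"{path}: row {lineno} needs otu_id and lineage")
            otu = fields[0]
            if otu in mapping:
                raise OtuTableError(f"{path}: duplicate OTU {otu!r} at row {lineno}")
            if len(fields) == 2:
                mapping[otu] = _parse_lineage(fields[1])
            else:
                mapping[otu] = tuple(fields[1:])
    if not mapping:
        raise OtuTableError(f"{path}: empty taxonomy file")
    return TaxonomyTable(mapping)


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    prefixes = ("k__", "p__", "c__", "o__", "f__", "g__")
    with Path(path).open("w") as fh:
        fh.write("otu_id\tlineage\n")
        for otu, lineage in taxonomy.otu_to_lineage.items():
            tagged = [
                f"{prefixes[i] if i < len(prefixes) else ''}{name}"
                for i, name in enumerate(lineage)
            ]
            fh.write(f"{otu}\t{';'.join(tagged)}\n")
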