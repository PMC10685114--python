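"""Core data containers and readers/writers for count, metadata and composition tables.

Amplicon counts are held as a samples × taxa integer matrix (the taxonomically
agglomerated ASV counts); per-sample metadata lives in a pandas DataFrame with a
controlled vocabulary; compositions (sample, topic or centroid rows over taxa)
are row-stochastic matrices.  Orientation is fixed samples-in-rows everywhere;
files stored taxa-in-rows must be read with ``transpose=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

COHORTS = ("NP-UAB", "P-UAB", "P-SU")
RACE_LEVELS = ("Black", "White", "Other")


class DataError(ValueError):
    """Raised when an input table violates a structural precondition."""


@dataclass
class CountMatrix:
    """Samples × taxa nonnegative integer counts.

    ``library_sizes`` is always the exact per-sample row sum; it is recomputed
    at construction and never stored independently.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray  # (n_samples, n_taxa) integer
    library_sizes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DataError("counts must be a 2-D samples × taxa array")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac, _ = np.modf(self.counts.astype(float))
            bad = np.argwhere(frac != 0)
            if bad.size:
                r, c = bad[0]
                raise DataError(
                    f"non-integer count at sample {self.sample_ids[r]!r}, "
                    f"taxon {self.taxon_ids[c]!r}: {self.counts[r, c]}"
                )
            self.counts = self.counts.astype(np.int64)
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            r, c = neg[0]
            raise DataError(
                f"negative count at sample {self.sample_ids[r]!r}, "
                f"taxon {self.taxon_ids[c]!r}: {self.counts[r, c]}"
            )
        for name, ids in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({x for x in ids if ids.count(x) > 1})
                raise DataError(f"duplicate {name} ids: {dup}")
        self.library_sizes = self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class CompositionMatrix:
    """Row-stochastic proportions: rows are samples, topics or centroids."""

    row_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.taxon_ids)):
            raise DataError("values shape does not match row/taxon ids")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise DataError("proportions must lie in [0, 1]")
        rs = self.values.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-8):
            bad = [self.row_ids[i] for i in np.where(~np.isclose(rs, 1.0, atol=1e-8))[0]]
            raise DataError(f"rows do not sum to 1: {bad[:5]}")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.taxon_ids)


def validate_sample_table(meta: pd.DataFrame, cm: CountMatrix | None = None) -> pd.DataFrame:
    """Validate a per-sample metadata table against the controlled vocabulary.

    Expected columns: participant, cohort, pregnant, race, day; optional
    preterm, ph, bleeding.  Index = sample ids.
    """
    required = {"participant", "cohort", "pregnant", "race", "day"}
    missing = required - set(meta.columns)
    if missing:
        raise DataError(f"metadata missing columns: {sorted(missing)}")
    bad_cohort = set(meta["cohort"]) - set(COHORTS)
    if bad_cohort:
        raise DataError(f"unknown cohort values: {sorted(bad_cohort)}")
    bad_race = set(meta["race"]) - set(RACE_LEVELS)
    if bad_race:
        raise DataError(f"race must be one of {RACE_LEVELS}; got {sorted(bad_race)}")
    if "bleeding" in meta.columns:
        has_bleed = meta["bleeding"].notna()
        if (meta.loc[has_bleed, "cohort"] != "NP-UAB").any():
            raise DataError("bleeding scores are only defined for the non-pregnant cohort")
        scores = meta.loc[has_bleed, "bleeding"]
        if ((scores < 0) | (scores > 3)).any():
            raise DataError("bleeding scores must lie in 0..3")
    if cm is not None:
        missing_rows = set(cm.sample_ids) - set(meta.index)
        if missing_rows:
            raise DataError(f"samples without metadata rows: {sorted(missing_rows)[:5]}")
        if meta.index.has_duplicates:
            raise DataError("duplicate sample ids in metadata")
    return meta


# ---------------------------------------------------------------------------
# I/O


def load_counts(path: str | Path, format: str | None = None, transpose: bool = False) -> CountMatrix:
    """Load a count table from TSV, CSV or BIOM (JSON or HDF5 dialect).

    TSV/CSV layout: header row of taxon labels, first column sample ids.
    ``format`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".biom": "biom"}.get(path.suffix.lower())
        if format is None:
            raise DataError(f"cannot infer format from suffix of {path}")
    if format in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if format == "tsv" else ",", index_col=0)
        if transpose:
            df = df.T
        return CountMatrix(
            sample_ids=[str(x) for x in df.index],
            taxon_ids=[str(x) for x in df.columns],
            counts=df.to_numpy(),
        )
    if format == "biom":
        return _load_biom(path, transpose=transpose)
    raise DataError(f"unknown format {format!r}")


def _load_biom(path: Path, transpose: bool = False) -> CountMatrix:
    # BIOM convention: rows = observations (taxa), columns = samples.
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        import h5py

        with h5py.File(path, "r") as f:
            taxon_ids = [x.decode() for x in f["observation/ids"][:]]
            sample_ids = [x.decode() for x in f["sample/ids"][:]]
            data = f["observation/matrix/data"][:]
            indices = f["observation/matrix/indices"][:]
            indptr = f["observation/matrix/indptr"][:]
        from scipy.sparse import csr_matrix

        mat = csr_matrix(
            (data, indices, indptr), shape=(len(taxon_ids), len(sample_ids))
        ).toarray()
    else:
        with open(path) as fh:
            doc = json.load(fh)
        taxon_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        mat = np.zeros(doc["shape"], dtype=float)
        if doc.get("matrix_type") == "dense":
            mat[:] = np.asarray(doc["data"])
        else:
            for r, c, v in doc["data"]:
                mat[int(r), int(c)] = v
    counts = mat.T  # samples in rows
    if transpose:
        counts = counts.T
        sample_ids, taxon_ids = taxon_ids, sample_ids
    return CountMatrix(sample_ids=list(sample_ids), taxon_ids=list(taxon_ids), counts=counts)


def write_counts(cm: CountMatrix, path: str | Path, format: str | None = None) -> Path:
    """Write a count table as TSV/CSV (samples in rows) or JSON-dialect BIOM."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".biom": "biom"}.get(path.suffix.lower(), "tsv")
    if format in ("tsv", "csv"):
        cm.to_frame().to_csv(path, sep="\t" if format == "tsv" else ",")
    elif format == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "vmtopics",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [cm.n_taxa, cm.n_samples],
            "rows": [{"id": t, "metadata": None} for t in cm.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in cm.sample_ids],
            "data": [
                [int(j), int(i), int(cm.counts[i, j])]
                for j in range(cm.n_taxa)
                for i in range(cm.n_samples)
                if cm.counts[i, j] != 0
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise DataError(f"unknown format {format!r}")
    return path


def load_sample_table(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return validate_sample_table(meta)


# ---------------------------------------------------------------------------
# Transformations


def to_relative(cm: CountMatrix) -> CompositionMatrix:
    """Convert counts to per-sample relative abundances."""
    zero = np.where(cm.library_sizes == 0)[0]
    if zero.size:
        ids = [cm.sample_ids[i] for i in zero]
        raise DataError(f"zero-count samples cannot be normalized: {ids}")
    values = cm.counts / cm.library_sizes[:, None]
    return CompositionMatrix(list(cm.sample_ids), list(cm.taxon_ids), values)


def aggregate_taxa(cm: CountMatrix, mapping: Mapping[str, str]) -> CountMatrix:
    """Sum counts of taxa mapped to the same group (identity mapping allowed).

    Per-sample totals are conserved exactly.  Group order follows first
    appearance in ``cm.taxon_ids``.
    """
    unmapped = [t for t in cm.taxon_ids if t not in mapping]
    if unmapped:
        raise DataError(f"taxa without a group mapping: {unmapped}")
    groups: list[str] = []
    for t in cm.taxon_ids:
        g = mapping[t]
        if g not in groups:
            groups.append(g)
    out = np.zeros((cm.n_samples, len(groups)), dtype=cm.counts.dtype)
    gidx = {g: i for i, g in enumerate(groups)}
    for j, t in enumerate(cm.taxon_ids):
        out[:, gidx[mapping[t]]] += cm.counts[:, j]
    return CountMatrix(sample_ids=list(cm.sample_ids), taxon_ids=groups, counts=out)


def filter_min_prevalence(cm: CountMatrix, min_prevalence: float) -> CountMatrix:
    """Optional prevalence filter: keep taxa present in ≥ min_prevalence of samples."""
    prev = (cm.counts > 0).mean(axis=0)
    keep = prev >= min_prevalence
    if not keep.any():
        raise DataError("prevalence filter removed all taxa")
    return CountMatrix(
        sample_ids=list(cm.sample_ids),
        taxon_ids=[t for t, k in zip(cm.taxon_ids, keep) if k],
        counts=cm.counts[:, keep],
    )
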