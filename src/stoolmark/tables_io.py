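"""Tabular I/O and preprocessing for OTU abundance tables.

The on-disk convention is the common OTU-table layout: a tab-separated file
with features (OTUs) in rows, one header row of sample identifiers, a first
column ``#OTU_ID`` and an optional trailing ``taxonomy`` column holding a
semicolon-delimited lineage.  In memory the orientation is samples x features
(a :class:`pandas.DataFrame` with samples in rows), which matches the matrix
semantics of every downstream stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("stoolmark")

__all__ = [
    "OtuTable",
    "CohortMetadata",
    "MalformedDataError",
    "DuplicateIdError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "drop_zero_variance",
    "to_relative_abundance",
    "aggregate_taxa",
    "RANKS",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_GG_PREFIXES = {"k": 0, "p": 1, "c": 2, "o": 3, "f": 4, "g": 5, "s": 6}
_REL_TOL = 1e-6  # a table is 'relative' if every non-zero row sums to 1 +/- this


class MalformedDataError(ValueError):
    """Raised when a table contains values that violate its contract."""


class DuplicateIdError(ValueError):
    """Raised when sample or feature identifiers are duplicated."""


@dataclass
class OtuTable:
    """Samples x features abundance matrix with per-feature taxonomy.

    Parameters
    ----------
    data
        DataFrame with sample ids in the index and feature ids in the
        columns; values are read counts or relative abundances.
    taxonomy
        Per-feature lineage strings (semicolon-delimited, ranks optional),
        indexed like ``data.columns``.  Empty strings are allowed.
    kind
        ``"counts"`` or ``"relative"``.
    zero_samples
        Sample ids whose row was all zero (flagged, kept as all-zero).
    """

    data: pd.DataFrame
    taxonomy: pd.Series
    kind: str = "counts"
    zero_samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise DuplicateIdError(f"duplicated sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise DuplicateIdError(f"duplicated feature ids: {dups}")
        vals = self.data.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            r, c = np.argwhere(vals < 0)[0]
            raise MalformedDataError(
                f"negative value at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        self.taxonomy = self.taxonomy.reindex(self.data.columns).fillna("")
        if self.kind == "relative" and vals.size:
            sums = vals.sum(axis=1)
            nz = sums > 0
            if not np.allclose(sums[nz], 1.0, atol=1e-9):
                bad = self.data.index[nz][~np.isclose(sums[nz], 1.0, atol=1e-9)][0]
                raise MalformedDataError(
                    f"relative table row {bad!r} does not sum to 1"
                )
            self.zero_samples = tuple(self.data.index[~nz])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class CohortMetadata:
    """Per-sample diagnosis and symptom score.

    ``frame`` is indexed by sample id with columns ``group`` (values
    ``control``/``case``) and ``symptom_score`` (GUPI-like total, 0-45).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise DuplicateIdError("duplicated sample ids in metadata")
        missing = {"group", "symptom_score"} - set(self.frame.columns)
        if missing:
            raise MalformedDataError(f"metadata missing columns: {sorted(missing)}")
        bad = set(self.frame["group"].unique()) - {"control", "case"}
        if bad:
            raise MalformedDataError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def group(self) -> pd.Series:
        return self.frame["group"]

    @property
    def symptom_score(self) -> pd.Series:
        return self.frame["symptom_score"].astype(float)

    def is_case(self) -> np.ndarray:
        return (self.frame["group"] == "case").to_numpy()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_kind(values: np.ndarray) -> str:
    if values.size == 0:
        return "counts"
    if np.allclose(values, np.round(values)):
        return "counts"
    sums = values.sum(axis=1)
    nz = sums > 0
    if nz.any() and np.all(np.abs(sums[nz] - 1.0) <= _REL_TOL):
        return "relative"
    warnings.warn(
        "table is neither integer counts nor rows summing to 1; treating as counts",
        stacklevel=3,
    )
    return "counts"


def read_otu_table(path: str | Path, orientation: str = "features_in_rows") -> OtuTable:
    """Read a tab-separated OTU table.

    ``orientation`` declares the on-disk layout: ``features_in_rows``
    (default, first column ``#OTU_ID``, optional last column ``taxonomy``)
    or ``samples_in_rows``.  Comment lines (``#`` followed by whitespace)
    are skipped; the ``#OTU_ID`` header line is not a comment.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    # comment lines are "# ..." (hash + space); "#OTU_ID"/"#SampleID" headers are data
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("# ")
    ]
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None

    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df.pop("taxonomy").astype(str).replace("nan", "")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise MalformedDataError(f"non-numeric value in {path.name}: {exc}") from exc
    if orientation == "features_in_rows":
        values = values.T
        tax = taxonomy if taxonomy is not None else pd.Series("", index=values.columns)
    else:
        tax = pd.Series("", index=values.columns)
    values.columns = values.columns.astype(str)
    arr = values.to_numpy()
    if arr.size and arr.min() < 0:
        r, c = np.argwhere(arr < 0)[0]
        raise MalformedDataError(
            f"negative value at sample {values.index[r]!r}, feature {values.columns[c]!r}"
        )
    kind = _infer_kind(arr)
    if kind == "counts" and np.allclose(arr, np.round(arr)):
        values = values.round().astype(np.int64)
    return OtuTable(data=values, taxonomy=tax, kind=kind)


def write_otu_table(
    t: OtuTable, path: str | Path, orientation: str = "features_in_rows",
    seed: int | None = None,
) -> None:
    """Write an OTU table in the on-disk convention, with a provenance header."""
    from . import __version__

    path = Path(path)
    header = f"# stoolmark v{__version__}" + (f" seed={seed}" if seed is not None else "")
    if orientation == "features_in_rows":
        out = t.data.T.copy()
        out.insert(len(out.columns), "taxonomy", t.taxonomy.reindex(out.index))
        out.index.name = "#OTU_ID"
    elif orientation == "samples_in_rows":
        out = t.data.copy()
        out.index.name = "#SampleID"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, "w") as fh:
        fh.write(header + "\n")
        out.to_csv(fh, sep="\t")


def read_metadata(path: str | Path) -> CohortMetadata:
    from io import StringIO

    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("# ")
    ]
    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    df["symptom_score"] = df["symptom_score"].astype(float)
    if df["symptom_score"].isna().any() or df["group"].isna().any():
        raise MalformedDataError("metadata has missing group or symptom_score")
    return CohortMetadata(frame=df)


def write_metadata(meta: CohortMetadata, path: str | Path, seed: int | None = None) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# stoolmark v{__version__}" + (f" seed={seed}" if seed is not None else "") + "\n")
        meta.frame.rename_axis("sample_id").to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def drop_zero_variance(t: OtuTable) -> OtuTable:
    """Drop features whose value vector is constant across samples.

    Survivor order is preserved; removed feature ids are logged.  Idempotent.
    """
    vals = t.data.to_numpy()
    keep = (vals != vals[0:1, :]).any(axis=0) if len(t.data) else np.ones(vals.shape[1], bool)
    removed = [f for f, k in zip(t.data.columns, keep) if not k]
    if removed:
        logger.info("drop_zero_variance: removed %d features: %s", len(removed), removed)
    kept = t.data.loc[:, keep]
    return OtuTable(
        data=kept, taxonomy=t.taxonomy.loc[kept.columns], kind=t.kind,
        zero_samples=t.zero_samples,
    )


def to_relative_abundance(t: OtuTable) -> OtuTable:
    """Convert a counts table to per-sample relative abundance.

    Each sample row is divided by its own total; all-zero samples stay
    all-zero and are flagged in ``zero_samples``.  Passing an already
    relative table warns and returns it unchanged.
    """
    if t.kind == "relative":
        warnings.warn("table already relative; no-op", stacklevel=2)
        return t
    vals = t.data.to_numpy(dtype=float)
    sums = vals.sum(axis=1)
    nz = sums > 0
    out = np.zeros_like(vals)
    out[nz] = vals[nz] / sums[nz, None]
    data = pd.DataFrame(out, index=t.data.index, columns=t.data.columns)
    return OtuTable(data=data, taxonomy=t.taxonomy, kind="relative")


def parse_rank(lineage: str, rank: str) -> str:
    """Extract the label at ``rank`` from a lineage string.

    Accepts greengenes-style prefixes (``p__Firmicutes``) and bare labels
    (positional: kingdom;phylum;class;order;family;genus;species).  Returns
    ``"unclassified"`` when the rank is absent or empty.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    idx = RANKS.index(rank)
    parts = [p.strip() for p in lineage.split(";")] if lineage else []
    prefixed = any(len(p) > 2 and p[1:3] == "__" and p[0].lower() in _GG_PREFIXES for p in parts)
    if prefixed:
        for p in parts:
            if len(p) >= 3 and p[1:3] == "__" and _GG_PREFIXES.get(p[0].lower()) == idx:
                label = p[3:].strip()
                return label if label else "unclassified"
        return "unclassified"
    if idx < len(parts) and parts[idx]:
        return parts[idx]
    return "unclassified"


def aggregate_taxa(t: OtuTable, rank: str) -> OtuTable:
    """Sum features sharing the same label at ``rank``.

    Features whose lineage does not resolve at that rank are pooled into an
    ``unclassified`` feature.  Per-sample totals are conserved exactly for
    integer counts.
    """
    labels = [parse_rank(t.taxonomy.get(f, ""), rank) for f in t.data.columns]
    grouped = t.data.T.groupby(pd.Index(labels, name=None), sort=False).sum().T
    tax = pd.Series(grouped.columns, index=grouped.columns).astype(str)
    return OtuTable(data=grouped, taxonomy=tax, kind=t.kind, zero_samples=t.zero_samples)
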