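"""OTU tables and sample metadata.

The OTU table — an integer read-count matrix with OTUs as rows and
sequencing libraries as columns — is the currency every stage of the
pipeline consumes and produces.  Columns carry :class:`SampleMeta`
describing what the library is: an individually sequenced size fraction
(S < 2 mm, M > 2 mm, L > 4 mm, XL > 8 mm), a lysate pool made with one of
the named pooling strategies (g, equ, invg, fibo, log, 4x), or an
extraction negative control.

Files are plain UTF-8 tab-delimited text: OTU identifiers in the first
column, one column per library, an optional trailing ``taxonomy`` column.
Sample metadata comes either from a companion TSV or, as a fallback, from
a naming convention such as ``L1_S_r1`` (source sample, fraction or
strategy, replicate) and ``neg_1`` for negative controls.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Size fractions, smallest first.  Order matters: argmax ties elsewhere in
#: the package resolve toward the smaller class.
FRACTIONS: tuple[str, ...] = ("S", "M", "L", "XL")

#: Named lysate pooling strategies.  ``g`` is dry-weight proportional
#: (simulating an unsorted sample); the others enrich small fractions.
STRATEGIES: tuple[str, ...] = ("g", "equ", "invg", "fibo", "log", "4x")

CATEGORIES: tuple[str, ...] = ("fraction", "pooled_lysate", "negative_control")

_NEGATIVE_PREFIXES = ("neg", "nc", "ntc", "blank")


class OTUTableError(ValueError):
    """Raised when a table or its metadata violates an invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one library (one column of an OTU table)."""

    sample_id: str
    source: str | None = None
    category: str = "fraction"
    fraction: str | None = None
    strategy: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise OTUTableError(
                f"{self.sample_id!r}: unknown category {self.category!r}"
            )
        if self.category == "fraction":
            if self.fraction not in FRACTIONS:
                raise OTUTableError(
                    f"{self.sample_id!r}: category 'fraction' requires a "
                    f"fraction in {FRACTIONS}, got {self.fraction!r}"
                )
        elif self.category == "pooled_lysate":
            if not self.strategy:
                raise OTUTableError(
                    f"{self.sample_id!r}: category 'pooled_lysate' requires a strategy"
                )
        else:  # negative_control
            if self.fraction is not None or self.strategy is not None:
                raise OTUTableError(
                    f"{self.sample_id!r}: negative controls carry neither "
                    "fraction nor strategy"
                )

    @property
    def library(self) -> str | None:
        """Fraction or strategy label, whichever applies."""
        return self.fraction if self.category == "fraction" else self.strategy

    def merged(self) -> "SampleMeta":
        """Metadata for the column obtained by merging extraction replicates."""
        base = f"{self.source}_{self.library}" if self.source else str(self.library)
        return dataclasses.replace(self, sample_id=base, replicate=None)


def parse_sample_id(sample_id: str) -> SampleMeta:
    """Infer :class:`SampleMeta` from a conventional sample name.

    Recognized forms: ``<source>_<fraction|strategy>[_r<k>]`` (e.g.
    ``L1_S_r1``, ``L2_log_r2``, ``L3_g``) and negative controls starting
    with ``neg``/``NC``/``NTC``/``blank``.
    """
    low = sample_id.lower()
    if any(low.startswith(p) for p in _NEGATIVE_PREFIXES):
        return SampleMeta(sample_id, category="negative_control")
    parts = sample_id.split("_")
    if len(parts) >= 2:
        source, token = parts[0], parts[1]
        replicate = None
        if len(parts) >= 3:
            m = re.fullmatch(r"r?(\d+)", parts[2])
            if m:
                replicate = int(m.group(1))
        if token in FRACTIONS:
            return SampleMeta(sample_id, source=source, category="fraction",
                              fraction=token, replicate=replicate)
        if token in STRATEGIES:
            return SampleMeta(sample_id, source=source, category="pooled_lysate",
                              strategy=token, replicate=replicate)
    raise OTUTableError(
        f"cannot infer metadata from sample id {sample_id!r}; "
        "provide an explicit metadata table"
    )


class OTUTable:
    """An OTU x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with unique OTU ids as index and unique sample ids as
        columns.  Values must be non-negative and integral.
    samples
        One :class:`SampleMeta` per column, in column order.  If omitted,
        metadata is inferred from the column names via
        :func:`parse_sample_id`.
    taxonomy
        Optional text per OTU, aligned to the index.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: Sequence[SampleMeta] | None = None,
        taxonomy: pd.Series | None = None,
    ) -> None:
        counts = pd.DataFrame(counts).copy()
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise OTUTableError(f"duplicate OTU ids: {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise OTUTableError(f"duplicate sample ids: {dup}")
        values = counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise OTUTableError("counts must be numeric")
            if (values < 0).any():
                r, c = np.argwhere(values < 0)[0]
                raise OTUTableError(
                    f"negative count at OTU {counts.index[r]!r}, "
                    f"sample {counts.columns[c]!r}"
                )
            if not np.issubdtype(values.dtype, np.integer):
                if np.any(values != np.floor(values)):
                    r, c = np.argwhere(values != np.floor(values))[0]
                    raise OTUTableError(
                        f"non-integral count at OTU {counts.index[r]!r}, "
                        f"sample {counts.columns[c]!r}"
                    )
        counts = counts.astype(np.int64) if counts.size else counts.astype(np.int64)
        counts.index = counts.index.astype(str)
        counts.index.name = "OTU_ID"
        counts.columns = counts.columns.astype(str)

        if samples is None:
            samples = [parse_sample_id(c) for c in counts.columns]
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        if ids != list(counts.columns):
            raise OTUTableError(
                f"sample metadata {ids} does not match columns {list(counts.columns)}"
            )
        if taxonomy is not None:
            taxonomy = pd.Series(taxonomy).reindex(counts.index)

        self._counts = counts
        self.samples = samples
        self.taxonomy = taxonomy

    # -- basic accessors ---------------------------------------------------

    @property
    def counts(self) -> pd.DataFrame:
        return self._counts

    @property
    def otu_ids(self) -> list[str]:
        return list(self._counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._counts.shape

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def column(self, sample_id: str) -> pd.Series:
        return self._counts[sample_id]

    # -- transforms --------------------------------------------------------

    def relative_abundance(self) -> pd.DataFrame:
        """Per-column relative abundances; all-zero columns stay zero."""
        totals = self._counts.sum(axis=0)
        safe = totals.replace(0, 1)
        return self._counts / safe

    def select(self, **criteria) -> "OTUTable":
        """Subset columns by metadata fields (category, source, fraction, ...)."""
        keep = []
        for s in self.samples:
            if all(getattr(s, k) == v for k, v in criteria.items()):
                keep.append(s)
        ids = [s.sample_id for s in keep]
        return OTUTable(self._counts[ids], keep, self.taxonomy)

    def drop_samples(self, sample_ids: Iterable[str]) -> "OTUTable":
        drop = set(sample_ids)
        keep = [s for s in self.samples if s.sample_id not in drop]
        return OTUTable(self._counts[[s.sample_id for s in keep]], keep, self.taxonomy)

    def drop_zero_otus(self) -> "OTUTable":
        mask = self._counts.sum(axis=1) > 0
        tax = self.taxonomy[mask] if self.taxonomy is not None else None
        return OTUTable(self._counts.loc[mask], self.samples, tax)

    def with_counts(self, counts: pd.DataFrame,
                    samples: Sequence[SampleMeta] | None = None) -> "OTUTable":
        """New table with the same taxonomy and (by default) metadata subset."""
        if samples is None:
            by_id = {s.sample_id: s for s in self.samples}
            samples = [by_id[c] for c in counts.columns]
        tax = None
        if self.taxonomy is not None:
            tax = self.taxonomy.reindex(counts.index)
        return OTUTable(counts, samples, tax)

    def equals(self, other: "OTUTable") -> bool:
        if not self._counts.equals(other._counts):
            return False
        if self.samples != other.samples:
            return False
        if (self.taxonomy is None) != (other.taxonomy is None):
            return False
        if self.taxonomy is not None and not self.taxonomy.equals(other.taxonomy):
            return False
        return True

    def __repr__(self) -> str:
        n, m = self.shape
        return f"<OTUTable {n} OTUs x {m} samples>"


# -- file I/O --------------------------------------------------------------


def _check_header(path: Path) -> None:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    dups = [h for h in header if h in seen or seen.add(h)]  # type: ignore[func-returns-value]
    if dups:
        raise OTUTableError(f"duplicate column names in {path}: {sorted(set(dups))}")


def read_sample_metadata(path: str | Path) -> dict[str, SampleMeta]:
    """Read a metadata TSV (sample_id, source, category, fraction, strategy, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise OTUTableError(f"metadata file {path} lacks a 'sample_id' column")
    metas: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        def get(col: str) -> str | None:
            v = row.get(col)
            return None if v is None or pd.isna(v) or v == "" else str(v)

        rep = get("replicate")
        meta = SampleMeta(
            sample_id=str(row["sample_id"]),
            source=get("source"),
            category=get("category") or "fraction",
            fraction=get("fraction"),
            strategy=get("strategy"),
            replicate=int(float(rep)) if rep is not None else None,
        )
        if meta.sample_id in metas:
            raise OTUTableError(f"duplicate sample_id in metadata: {meta.sample_id}")
        metas[meta.sample_id] = meta
    return metas


def read_otu_table(
    path: str | Path,
    metadata: str | Path | Mapping[str, SampleMeta] | None = None,
) -> OTUTable:
    """Read a tab-delimited OTU table.

    First column holds OTU ids; remaining columns integer counts; an
    optional column named ``taxonomy`` (any position, conventionally last)
    holds text.  ``metadata`` may be a TSV path, a mapping from sample id
    to :class:`SampleMeta`, or None to fall back on the naming convention.
    """
    path = Path(path)
    _check_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy = None
    for col in list(df.columns):
        if col.lower() == "taxonomy":
            taxonomy = df.pop(col).astype(str)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise OTUTableError(
                f"non-numeric count at OTU {row!r}, sample {col!r} in {path}"
            )
        df[col] = numeric
    df = df.fillna(0)

    if metadata is None:
        samples = None
    else:
        if not isinstance(metadata, Mapping):
            metadata = read_sample_metadata(metadata)
        missing = [c for c in df.columns if c not in metadata]
        if missing:
            raise OTUTableError(f"metadata missing for samples: {missing}")
        samples = [metadata[c] for c in df.columns]
    return OTUTable(df, samples, taxonomy)


def write_otu_table(table: OTUTable, path: str | Path) -> None:
    """Write a table as TSV; taxonomy, if present, becomes the last column."""
    out = table.counts.copy()
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy
    out.to_csv(path, sep="\t")


def write_sample_metadata(table: OTUTable, path: str | Path) -> None:
    rows = [dataclasses.asdict(s) for s in table.samples]
    df = pd.DataFrame(rows)
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype("Int64")
    df.to_csv(path, sep="\t", index=False)
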