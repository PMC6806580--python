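"""Sample × OTU count tables: data model, I/O, rarefaction and abundance transforms.

The :class:`OtuTable` is the universal input of the pipeline: a matrix of
non-negative integer read counts (rows = samples, columns = OTUs) with
optional per-OTU taxonomy lineages and per-sample metadata (season label,
longitude, latitude, site id).  All downstream statistics operate either on
this table directly or on its relative-abundance / Hellinger transforms.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio.stats import subsample_counts

logger = logging.getLogger(__name__)

#: canonical rank order for lineages, most to least inclusive
RANKS = ("kingdom", "supergroup", "phylum", "class", "order", "family", "genus")


class OtuTableError(ValueError):
    """Raised when a table violates the count-table contract."""


@dataclass
class OtuTable:
    """Sample × OTU count matrix with optional taxonomy and sample metadata.

    Parameters
    ----------
    counts:
        DataFrame of non-negative integers, index = sample ids,
        columns = OTU ids.  Both axes must be unique.
    taxonomy:
        Optional mapping OTU id -> lineage tuple ordered kingdom→genus.
        May cover a subset of the OTUs.
    sample_meta:
        Optional DataFrame indexed by sample id; recognised columns are
        ``season``, ``longitude``, ``latitude``, ``site``.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, tuple[str, ...]] | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = pd.DataFrame(self.counts)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise OtuTableError(f"duplicate sample ids: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise OtuTableError(f"duplicate OTU ids: {dup}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise OtuTableError("counts must be numeric")
        if arr.size:
            if np.any(~np.isfinite(arr.astype(float))):
                raise OtuTableError("counts must be finite")
            if np.any(arr < 0):
                i, j = np.argwhere(arr < 0)[0]
                raise OtuTableError(
                    f"negative count at sample {c.index[i]!r}, OTU {c.columns[j]!r}"
                )
            if np.any(arr.astype(float) != np.round(arr.astype(float))):
                i, j = np.argwhere(arr.astype(float) != np.round(arr.astype(float)))[0]
                raise OtuTableError(
                    f"non-integer count at sample {c.index[i]!r}, OTU {c.columns[j]!r}"
                )
        self.counts = c.astype(np.int64)
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(c.columns)
            if unknown:
                raise OtuTableError(
                    f"taxonomy refers to unknown OTUs: {sorted(unknown)[:5]}"
                )
        if self.sample_meta is not None:
            self.sample_meta = pd.DataFrame(self.sample_meta)
            missing = set(c.index) - set(self.sample_meta.index)
            if missing:
                raise OtuTableError(
                    f"sample_meta lacks rows for samples: {sorted(missing)[:5]}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        """Restrict to the given samples, dropping OTUs that become all-zero."""
        sub = self.counts.loc[list(sample_ids)]
        return self._rebuild(sub, drop_empty_otus=True)

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        """Restrict to the given OTUs (samples are kept even if emptied)."""
        keep = [o for o in self.otu_ids if o in set(otu_ids)]
        if not keep:
            warnings.warn("OTU subset is empty", stacklevel=2)
        sub = self.counts[keep]
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in keep if o in self.taxonomy}
        return OtuTable(sub, taxonomy=tax, sample_meta=self._meta_for(sub.index))

    def _meta_for(self, idx: pd.Index) -> pd.DataFrame | None:
        if self.sample_meta is None:
            return None
        return self.sample_meta.loc[idx]

    def _rebuild(self, counts: pd.DataFrame, drop_empty_otus: bool = False) -> "OtuTable":
        if drop_empty_otus:
            empty = counts.columns[counts.sum(axis=0) == 0]
            if len(empty):
                logger.warning("dropping %d all-zero OTUs after subsetting", len(empty))
                counts = counts.drop(columns=empty)
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in counts.columns if o in self.taxonomy}
        return OtuTable(counts, taxonomy=tax, sample_meta=self._meta_for(counts.index))


@dataclass
class RelAbundTable:
    """Per-sample relative abundances (rows sum to 1) tied to a source table."""

    values: pd.DataFrame
    source: OtuTable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size:
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise OtuTableError("relative abundances must lie in [0, 1]")
            rs = arr.sum(axis=1)
            if np.any(np.abs(rs - 1) > 1e-9):
                raise OtuTableError("relative-abundance rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, format: str = "tsv") -> OtuTable:
    """Read an OTU table from disk.

    ``tsv`` layout: first column OTU id, one column per sample, optional
    trailing ``taxonomy`` column holding a semicolon-delimited lineage.
    ``json-table`` is the paired writer's sidecar-free JSON interchange form.
    A ``<stem>.meta.json`` file next to a TSV, if present, is read as
    per-sample metadata keyed by sample id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "json-table":
        return _read_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    taxonomy = None
    if "taxonomy" in df.columns:
        tax_col = df.pop("taxonomy")
        taxonomy = {
            otu: tuple(t.strip() for t in lineage.split(";"))
            for otu, lineage in tax_col.items()
            if isinstance(lineage, str) and lineage.strip()
        }
    mat = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise OtuTableError(
                f"non-numeric count {df.loc[row, col]!r} at OTU {row!r}, sample {col!r}"
            )
        if (converted < 0).any():
            row = converted.index[converted < 0][0]
            raise OtuTableError(
                f"negative count {df.loc[row, col]!r} at OTU {row!r}, sample {col!r}"
            )
        mat[col] = converted
    meta_path = path.with_suffix(".meta.json")
    sample_meta = None
    if meta_path.exists():
        with open(meta_path) as fh:
            sample_meta = pd.DataFrame.from_dict(json.load(fh), orient="index")
    # on-disk layout is OTU rows × sample columns; in memory it is the transpose
    out = mat.T
    out.index.name = None
    out.columns.name = None
    return OtuTable(out, taxonomy=taxonomy, sample_meta=sample_meta)


def _read_json(path: Path) -> OtuTable:
    with open(path) as fh:
        payload = json.load(fh)
    counts = pd.DataFrame(
        payload["counts"], index=payload["sample_ids"], columns=payload["otu_ids"]
    )
    taxonomy = None
    if payload.get("taxonomy"):
        taxonomy = {k: tuple(v) for k, v in payload["taxonomy"].items()}
    sample_meta = None
    if payload.get("sample_meta"):
        sample_meta = pd.DataFrame.from_dict(payload["sample_meta"], orient="index")
        sample_meta = sample_meta.loc[payload["sample_ids"]]
    return OtuTable(counts, taxonomy=taxonomy, sample_meta=sample_meta)


def write_otu_table(table: OtuTable, path: str | Path, format: str = "tsv") -> None:
    """Write a table so that :func:`read_otu_table` round-trips it losslessly."""
    path = Path(path)
    if format == "tsv":
        out = table.counts.T.copy()
        out.index.name = "otu_id"
        if table.taxonomy is not None:
            out["taxonomy"] = [
                ";".join(table.taxonomy.get(o, ())) for o in out.index
            ]
        out.to_csv(path, sep="\t", lineterminator="\n")
        if table.sample_meta is not None:
            with open(path.with_suffix(".meta.json"), "w") as fh:
                json.dump(
                    {s: row.dropna().to_dict() for s, row in table.sample_meta.iterrows()},
                    fh,
                    indent=1,
                )
    elif format == "json-table":
        payload = {
            "sample_ids": table.sample_ids,
            "otu_ids": table.otu_ids,
            "counts": table.counts.to_numpy().tolist(),
            "taxonomy": {k: list(v) for k, v in (table.taxonomy or {}).items()} or None,
            "sample_meta": (
                {s: row.dropna().to_dict() for s, row in table.sample_meta.iterrows()}
                if table.sample_meta is not None
                else None
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def rarefy(
    table: OtuTable,
    depth: int,
    seed: int,
    drop_short: bool = False,
    mean_of: int = 1,
) -> OtuTable:
    """Rarefy every sample to ``depth`` reads without replacement.

    Subsampling is hypergeometric (without replacement), the convention of
    MOTHUR/QIIME-style normalisation.  Samples with fewer than ``depth``
    reads raise unless ``drop_short`` is set, in which case they are dropped
    with a logged warning.  With ``mean_of > 1`` the per-cell counts are the
    rounded mean over that many independent draws (row sums are then
    re-adjusted to hit ``depth`` exactly by largest-remainder rounding).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    sums = table.sample_sums()
    short = sums.index[sums < depth].tolist()
    counts = table.counts
    if short:
        if not drop_short:
            raise OtuTableError(
                f"samples below depth {depth}: {short} (use drop_short=True to drop)"
            )
        logger.warning("dropping %d samples below depth %d: %s", len(short), depth, short)
        counts = counts.drop(index=short)
        if counts.empty:
            raise OtuTableError("no samples remain after dropping shallow ones")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(counts.shape[0] * max(mean_of, 1)).reshape(
        counts.shape[0], -1
    )
    rows = []
    for i, (_, row) in enumerate(counts.iterrows()):
        vec = row.to_numpy()
        draws = np.stack(
            [
                subsample_counts(vec, depth, seed=int(child_seeds[i, k]))
                for k in range(max(mean_of, 1))
            ]
        )
        if mean_of <= 1:
            rows.append(draws[0])
        else:
            rows.append(_largest_remainder(draws.mean(axis=0), depth))
    out = pd.DataFrame(np.array(rows), index=counts.index, columns=counts.columns)
    result = OtuTable(out, taxonomy=table.taxonomy, sample_meta=table._meta_for(out.index))
    return result._rebuild(result.counts, drop_empty_otus=True)


def _largest_remainder(values: np.ndarray, total: int) -> np.ndarray:
    floors = np.floor(values).astype(np.int64)
    deficit = int(total - floors.sum())
    if deficit > 0:
        order = np.argsort(-(values - floors), kind="stable")
        floors[order[:deficit]] += 1
    return floors


def relative_abundance(table: OtuTable) -> RelAbundTable:
    """Counts divided by per-sample totals; errors on an all-zero sample."""
    sums = table.sample_sums()
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise OtuTableError(f"all-zero samples: {zero}")
    vals = table.counts.div(sums, axis=0)
    return RelAbundTable(vals, source=table)


def hellinger_transform(table: OtuTable) -> pd.DataFrame:
    """Square root of relative abundances; each row's squared values sum to 1.

    The Hellinger transform makes community count data suitable for linear
    (Euclidean-geometry) ordination such as RDA.
    """
    rel = relative_abundance(table)
    return np.sqrt(rel.values)


def collapse_taxonomy(table: OtuTable, rank: str) -> OtuTable:
    """Aggregate OTU counts at a taxonomic rank.

    OTUs whose lineage does not reach ``rank`` (or that lack taxonomy) pool
    into ``"unclassified"``.  The grand total is conserved.
    """
    if table.taxonomy is None or not table.taxonomy:
        raise OtuTableError("table has no taxonomy to collapse")
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    level = RANKS.index(rank)
    labels = {}
    for otu in table.otu_ids:
        lineage = table.taxonomy.get(otu, ())
        if len(lineage) > level and str(lineage[level]).strip():
            labels[otu] = ";".join(lineage[: level + 1])
        else:
            labels[otu] = "unclassified"
    grouped = table.counts.T.groupby(pd.Series(labels)).sum().T
    return OtuTable(grouped, taxonomy=None, sample_meta=table.sample_meta)
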