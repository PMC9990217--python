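"""Count-table I/O, filter-fraction merging, rarefaction and normalisation.

The central container is :class:`CountTable`, an ASV-by-sample matrix of
non-negative integer read counts backed by a :class:`pandas.DataFrame`
(rows = ASVs, columns = samples). Sample metadata travels as a DataFrame
indexed by sample id with the categorical columns ``site``,
``land_use_class``, ``date``, ``year``; any additional numeric columns are
treated as environmental covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger("aquacore")

LAND_USE_CLASSES = ("agri_ditch", "agri_stream", "mixed", "forest")

METADATA_REQUIRED = ("sample_id", "site", "land_use_class", "date")


@dataclass(frozen=True)
class CountTable:
    """An ASV x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    data
        DataFrame with unique ASV ids as the index and unique sample ids as
        the columns. Values must be non-negative integers (integral floats
        are cast).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        dup_asv = df.index[df.index.duplicated()].unique().tolist()
        if dup_asv:
            raise ValidationError(f"duplicate ASV ids: {dup_asv[:5]}")
        dup_smp = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_smp:
            raise ValidationError(f"duplicate sample ids: {dup_smp[:5]}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            bad = _first_offender(df, lambda v: not _is_number(v))
            raise ValidationError(f"non-numeric count at {bad}")
        if values.size:
            fv = values.astype(float)
            if np.any(fv < 0):
                bad = _first_offender(df, lambda v: float(v) < 0)
                raise ValidationError(f"negative count at {bad}")
            if np.any(fv != np.floor(fv)):
                bad = _first_offender(df, lambda v: float(v) != int(v))
                raise ValidationError(f"non-integer count at {bad}")
        if not np.issubdtype(values.dtype, np.integer):
            df = df.astype(np.int64)
        df = df.rename_axis(index="asv_id", columns=None)
        object.__setattr__(self, "data", df)

    # -- accessors ---------------------------------------------------------
    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return CountTable(self.data.loc[:, list(sample_ids)])

    def subset_taxa(self, asv_ids) -> "CountTable":
        missing = [a for a in asv_ids if a not in self.data.index]
        if missing:
            raise ValidationError(f"unknown ASV ids: {missing[:5]}")
        return CountTable(self.data.loc[list(asv_ids)])

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def taxon_sums(self) -> pd.Series:
        return self.data.sum(axis=1)


@dataclass(frozen=True)
class RelativeAbundanceTable:
    """Column-normalised proportions on the same axes as a CountTable.

    ``zero_samples`` lists samples whose column total was zero; their values
    are left at 0 rather than divided.
    """

    data: pd.DataFrame
    zero_samples: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if vals.size and (vals.min() < 0 or vals.max() > 1 + 1e-12):
            raise ValidationError("relative abundances must lie in [0, 1]")
        sums = vals.sum(axis=0)
        nonzero = [
            c
            for c, s in zip(self.data.columns, sums)
            if c not in self.zero_samples and abs(s - 1.0) > 1e-9
        ]
        if nonzero:
            raise ValidationError(
                f"sample columns do not sum to 1: {nonzero[:5]}"
            )


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _first_offender(df: pd.DataFrame, pred) -> str:
    for col in df.columns:
        for idx, v in df[col].items():
            try:
                hit = pred(v)
            except (TypeError, ValueError):
                hit = True
            if hit:
                return f"(ASV {idx!r}, sample {col!r}): {v!r}"
    return "(unknown cell)"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path, format: str = "tsv", transpose: bool = False) -> CountTable:
    """Read an ASV count table.

    TSV layout: first column ASV ids, header row of sample ids. ``transpose``
    accepts samples-in-rows tables. ``format="biom"`` reads BIOM 1.0/2.x via
    the biom-format package (observations = ASVs).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "biom":
        import biom

        table = biom.load_table(str(path))
        df = pd.DataFrame(
            table.matrix_data.toarray(),
            index=[str(i) for i in table.ids("observation")],
            columns=[str(i) for i in table.ids("sample")],
        )
    else:
        raise ValueError(f"unknown count-table format: {format!r}")
    if transpose:
        df = df.T
    return CountTable(df)


def write_count_table(table: CountTable, path, header_comments: list[str] | None = None) -> None:
    """Write a CountTable as TSV (ASVs in rows); optional ``#`` header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments or ():
            fh.write(f"# {line}\n")
        table.data.to_csv(fh, sep="\t", index_label="asv_id")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, site, land_use_class, date, ...).

    Dates are parsed as ISO-8601; a ``year`` column is derived when absent.
    Any remaining numeric column is kept as an environmental covariate.
    """
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate metadata sample ids: {dup[:5]}")
    bad_class = sorted(set(meta["land_use_class"]) - set(LAND_USE_CLASSES))
    if bad_class:
        raise ValidationError(f"unknown land_use_class values: {bad_class}")
    meta = meta.copy()
    meta["date"] = pd.to_datetime(meta["date"], format="ISO8601").dt.normalize()
    if "year" not in meta.columns:
        meta["year"] = meta["date"].dt.year
    return meta.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False)


def validate_metadata(table: CountTable, meta: pd.DataFrame) -> None:
    """Every sample in the table must have exactly one metadata row."""
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:5]}")


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def merge_fraction_tables(a: CountTable, b: CountTable, strict: bool = True) -> CountTable:
    """Sum per-sample counts of two filter-fraction tables for the same water
    samples (e.g. DNA from 0.22 um and 0.7 um filters sequenced separately).

    ASVs present in only one input get zeros in the other. With
    ``strict=True`` the two sample sets must match exactly; lenient mode
    treats a sample missing from one table as all-zero and logs a warning.
    """
    sa, sb = set(a.sample_ids), set(b.sample_ids)
    if strict and sa != sb:
        raise ValidationError(
            f"sample sets differ: only-in-a={sorted(sa - sb)[:5]}, "
            f"only-in-b={sorted(sb - sa)[:5]}"
        )
    if not strict and sa != sb:
        logger.warning(
            "merge_fraction_tables: %d unmatched samples treated as zero",
            len(sa ^ sb),
        )
    samples = list(a.sample_ids) + [s for s in b.sample_ids if s not in sa]
    asvs = list(a.asv_ids) + [x for x in b.asv_ids if x not in set(a.asv_ids)]
    da = a.data.reindex(index=asvs, columns=samples, fill_value=0)
    db = b.data.reindex(index=asvs, columns=samples, fill_value=0)
    return CountTable(da + db)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample without replacement to a common ``depth``.

    Each retained column is an exact multivariate-hypergeometric draw of
    ``depth`` reads from the sample's observed reads, so column sums equal
    ``depth`` exactly and no count can exceed its input. Samples with fewer
    than ``depth`` total reads are dropped and logged. The same seed always
    yields an identical table.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    dropped = [s for s in table.sample_ids if sums[s] < depth]
    if dropped:
        logger.warning(
            "rarefy: dropping %d samples below depth %d: %s",
            len(dropped), depth, dropped[:10],
        )
    kept = [s for s in table.sample_ids if sums[s] >= depth]
    out = {}
    for s in kept:
        col = table.data[s].to_numpy()
        if sums[s] == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.data.index, columns=kept)
    return CountTable(df)


def to_relative_abundance(table: CountTable) -> RelativeAbundanceTable:
    """Divide each sample column by its total; all-zero columns are flagged."""
    sums = table.sample_sums()
    zero = tuple(s for s in table.sample_ids if sums[s] == 0)
    if zero:
        logger.warning("to_relative_abundance: all-zero samples flagged: %s", zero)
    safe = sums.replace(0, 1)
    df = table.data.astype(float).div(safe, axis=1)
    return RelativeAbundanceTable(df, zero_samples=zero)
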