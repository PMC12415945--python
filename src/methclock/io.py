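"""Reading, writing and filtering of per-sample CpG methylation calls.

Reduced-representation bisulphite pipelines emit one record per cytosine per
strand.  A CpG dinucleotide is palindromic: the forward-strand C at position
``p`` and the reverse-strand C at ``p + 1`` interrogate the same site, so the
two records are merged (counts summed) before any site-level analysis.  All
coordinates are 1-based and merged sites are keyed to the forward-strand C.

Two filters operate on the merged (or, for the pre-fledging preset, per-strand)
records:

* a coverage filter removing sites covered fewer than ``min_coverage`` times
  and sites above a high coverage percentile (PCR-duplicate / repeat guard);
* a variability filter removing sites whose methylation ratio is nearly
  constant across samples (mean outside [mean_low, mean_high] or sample
  standard deviation below ``min_sd``), since invariant sites carry no age
  signal.

Boundary semantics are strict readings of the thresholds: coverage exactly
``min_coverage`` survives, coverage exactly at the percentile cap survives,
mean exactly ``mean_low``/``mean_high`` survives, and SD exactly ``min_sd``
survives.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MethylationIOError",
    "MethylationParseError",
    "DuplicateRecordError",
    "FilterOrder",
    "FilterConfig",
    "read_calls",
    "write_calls",
    "read_bismark_cov",
    "merge_complementary",
    "coverage_cap",
    "filter_coverage",
    "filter_variability",
    "apply_sample_filters",
    "site_ids",
    "build_ratio_matrix",
    "write_matrix",
    "read_matrix",
]

CALL_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth"]
SITE_COLUMNS = ["chrom", "pos", "meth", "unmeth", "ratio"]


class MethylationIOError(Exception):
    """Base class for methylation-call I/O failures."""


class MethylationParseError(MethylationIOError):
    """A call file line could not be parsed; the message names the line."""


class DuplicateRecordError(MethylationIOError):
    """Two records share (chromosome, position, strand) within one sample."""


class FilterOrder(str, enum.Enum):
    """Order of strand merging relative to the coverage filter.

    ``merge_first`` merges complementary dinucleotides and then coverage-filters
    the merged sites (post-fledging processing).  ``filter_first`` coverage-
    filters the per-strand records and merges afterwards (pre-fledging
    processing).
    """

    MERGE_FIRST = "merge_first"
    FILTER_FIRST = "filter_first"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for per-sample and cross-sample site filtering.

    Parameters
    ----------
    min_coverage
        Minimum total coverage for a site (inclusive).
    max_coverage_percentile
        Sites with coverage strictly above this percentile of the sample's
        coverages are removed (guards against collapsed repeats).
    mean_low, mean_high
        Inclusive bounds on the cross-sample mean methylation ratio.
    min_sd
        Inclusive lower bound on the cross-sample standard deviation
        (``n - 1`` denominator) of the methylation ratio.
    order
        See :class:`FilterOrder`.
    """

    min_coverage: int = 10
    max_coverage_percentile: float = 99.9
    mean_low: float = 0.05
    mean_high: float = 0.95
    min_sd: float = 0.05
    order: FilterOrder = FilterOrder.MERGE_FIRST

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not (0.0 <= self.mean_low < self.mean_high <= 1.0):
            raise ValueError("require 0 <= mean_low < mean_high <= 1")
        if not (0.0 < self.max_coverage_percentile <= 100.0):
            raise ValueError("max_coverage_percentile must be in (0, 100]")
        if self.min_sd < 0:
            raise ValueError("min_sd must be >= 0")
        object.__setattr__(self, "order", FilterOrder(self.order))


# ---------------------------------------------------------------------------
# call-file reading / writing
# ---------------------------------------------------------------------------

_STRANDS = {"+", "-"}


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated methylation call file.

    Expected columns (header optional): chromosome, position (1-based,
    forward-strand C of the CpG for ``+`` records, reverse-strand C for
    ``-`` records), strand (``+``/``-``), methylated count, unmethylated
    count.

    Returns a DataFrame with columns ``chrom, pos, strand, meth, unmeth``.

    Raises
    ------
    MethylationParseError
        On a malformed line (wrong field count, non-integer counts,
        unknown strand, or zero coverage); the message names the 1-based
        line number.
    """
    path = Path(path)
    records: list[tuple[str, int, str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) != 5:
                raise MethylationParseError(
                    f"{path}: line {lineno}: expected 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s = fields
            if strand not in _STRANDS:
                raise MethylationParseError(
                    f"{path}: line {lineno}: strand must be '+' or '-', got {strand!r}"
                )
            try:
                pos, meth, unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise MethylationParseError(
                    f"{path}: line {lineno}: non-integer field ({exc})"
                ) from None
            if pos < 1 or meth < 0 or unmeth < 0:
                raise MethylationParseError(
                    f"{path}: line {lineno}: negative count or non-positive position"
                )
            if meth + unmeth < 1:
                raise MethylationParseError(
                    f"{path}: line {lineno}: record has zero coverage"
                )
            records.append((chrom, pos, strand, meth, unmeth))
    df = pd.DataFrame(records, columns=CALL_COLUMNS)
    if df.empty:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=np.int64),
                "strand": pd.Series(dtype=str),
                "meth": pd.Series(dtype=np.int64),
                "unmeth": pd.Series(dtype=np.int64),
            }
        )
    return df


def _looks_like_header(fields: list[str]) -> bool:
    if len(fields) < 2:
        return False
    try:
        int(fields[1])
    except ValueError:
        return True
    return False


def write_calls(calls: pd.DataFrame, path: str | Path, header: bool = True) -> None:
    """Write a call table in the TSV dialect accepted by :func:`read_calls`."""
    out = calls[CALL_COLUMNS]
    out.to_csv(
        path,
        sep="\t",
        index=False,
        header=(
            ["chromosome", "position", "strand", "count_methylated", "count_unmethylated"]
            if header
            else False
        ),
    )


def read_bismark_cov(path: str | Path) -> pd.DataFrame:
    """Read a bismark ``.cov``-dialect file into a call table.

    The dialect carries no strand column (chrom, start, end, percent
    methylation, methylated count, unmethylated count; 1-based start), so
    records are ingested as forward-strand, already strand-collapsed sites.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "pct", "meth", "unmeth"],
            dtype={"chrom": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MethylationParseError(f"{path}: unparseable bismark cov file: {exc}") from exc
    bad = (df["meth"] + df["unmeth"]) < 1
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise MethylationParseError(f"{path}: line {lineno}: record has zero coverage")
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(np.int64),
            "strand": "+",
            "meth": df["meth"].astype(np.int64),
            "unmeth": df["unmeth"].astype(np.int64),
        }
    )


# ---------------------------------------------------------------------------
# strand merging
# ---------------------------------------------------------------------------

def merge_complementary(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge complementary CpG dinucleotide records of one sample.

    A forward record at (chrom, p) and a reverse record at (chrom, p + 1)
    describe the same CpG; their counts are summed into one site keyed at
    (chrom, p).  Unpaired records pass through, with reverse records shifted
    to the forward-strand coordinate (p − 1).

    Returns a site table ``chrom, pos, meth, unmeth, ratio`` sorted by
    (chrom, pos), unique per (chrom, pos).

    Raises
    ------
    DuplicateRecordError
        If two input records share (chrom, pos, strand).
    """
    if calls.empty:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=np.int64),
                "meth": pd.Series(dtype=np.int64),
                "unmeth": pd.Series(dtype=np.int64),
                "ratio": pd.Series(dtype=float),
            }
        )
    dup = calls.duplicated(subset=["chrom", "pos", "strand"], keep=False)
    if dup.any():
        row = calls[dup].iloc[0]
        raise DuplicateRecordError(
            f"duplicate record at {row['chrom']}:{row['pos']} strand {row['strand']}"
        )
    key = calls["pos"].to_numpy(np.int64) - (calls["strand"] == "-").to_numpy(np.int64)
    merged = (
        calls.assign(pos=key)
        .groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "unmeth"]]
        .sum()
    )
    merged["ratio"] = merged["meth"] / (merged["meth"] + merged["unmeth"])
    return merged[SITE_COLUMNS]


# ---------------------------------------------------------------------------
# coverage filter
# ---------------------------------------------------------------------------

def coverage_cap(table: pd.DataFrame, max_coverage_percentile: float = 99.9) -> float:
    """Linear-interpolation percentile of a table's total coverages."""
    cov = (table["meth"] + table["unmeth"]).to_numpy()
    return float(np.percentile(cov, max_coverage_percentile, method="linear"))


def filter_coverage(
    table: pd.DataFrame,
    min_coverage: int = 10,
    max_coverage_percentile: float = 99.9,
    cap: float | None = None,
) -> pd.DataFrame:
    """Remove low- and extreme-coverage records.

    A record survives iff ``min_coverage <= coverage <= cap`` where ``cap``
    is the ``max_coverage_percentile`` linear-interpolation quantile of the
    coverages in *this* table (one sample), or a frozen ``cap`` if given.
    Works on per-strand call tables and on merged site tables alike.
    Empty input yields empty output.
    """
    if table.empty:
        return table.copy()
    cov = table["meth"] + table["unmeth"]
    if cap is None:
        cap = coverage_cap(table, max_coverage_percentile)
    keep = (cov >= min_coverage) & (cov <= cap)
    return table[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# variability filter
# ---------------------------------------------------------------------------

def filter_variability(
    matrix: pd.DataFrame,
    mean_low: float = 0.05,
    mean_high: float = 0.95,
    min_sd: float = 0.05,
) -> pd.Index:
    """Select variable sites from a sites × samples ratio matrix.

    A site survives iff ``mean_low <= mean <= mean_high`` and the sample
    standard deviation (``n - 1`` denominator) is ``>= min_sd``.  Rows must
    be complete: the matrix is assumed to be restricted to universal sites.

    Returns the surviving row index.
    """
    if matrix.isna().any().any():
        bad = matrix.index[matrix.isna().any(axis=1)][0]
        raise ValueError(
            f"missing ratio at site {bad}: variability filter requires a "
            "complete (universal-site) matrix"
        )
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    keep = (means >= mean_low) & (means <= mean_high) & (sds >= min_sd)
    return matrix.index[keep]


# ---------------------------------------------------------------------------
# per-sample filtering orchestration and matrix assembly
# ---------------------------------------------------------------------------

def apply_sample_filters(calls: pd.DataFrame, config: FilterConfig) -> pd.DataFrame:
    """Merge and coverage-filter one sample's calls in the configured order.

    ``merge_first``: merge complementary dinucleotides, then coverage-filter
    the merged sites.  ``filter_first``: coverage-filter the per-strand
    records (the percentile computed over per-strand coverages), then merge.
    """
    if config.order is FilterOrder.MERGE_FIRST:
        sites = merge_complementary(calls)
        return filter_coverage(
            sites, config.min_coverage, config.max_coverage_percentile
        )
    filtered = filter_coverage(
        calls, config.min_coverage, config.max_coverage_percentile
    )
    return merge_complementary(filtered)


def site_ids(sites: pd.DataFrame) -> pd.Index:
    """``chrom:pos`` identifiers of a site table."""
    return pd.Index(
        sites["chrom"].astype(str) + ":" + sites["pos"].astype(str), name="site"
    )


def build_ratio_matrix(
    sample_sites: Mapping[str, pd.DataFrame],
    sites: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Assemble a sites × samples methylation-ratio matrix.

    Parameters
    ----------
    sample_sites
        Mapping of sample id to merged site table.
    sites
        Site ids (``chrom:pos``) to include; defaults to the exact
        intersection over samples (universal sites).

    The returned matrix has site ids as index and sample ids as columns and
    contains no missing values.
    """
    if not sample_sites:
        raise ValueError("no samples given")
    columns = {}
    for sample, table in sample_sites.items():
        columns[sample] = pd.Series(
            table["ratio"].to_numpy(), index=site_ids(table), name=sample
        )
    if sites is None:
        ids: pd.Index | None = None
        for series in columns.values():
            ids = series.index if ids is None else ids.intersection(series.index)
        sites = ids
    index = pd.Index(list(sites), name="site")
    matrix = pd.DataFrame(
        {sample: series.reindex(index) for sample, series in columns.items()}
    )
    if matrix.isna().any().any():
        missing = matrix.index[matrix.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"sites not covered in every sample: {missing}")
    return matrix


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="site")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site")
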