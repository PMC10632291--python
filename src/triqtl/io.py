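"""Core data containers and tabular input/output.

Three input tables drive an analysis:

* a genotype matrix of fully homozygous lines, one row per line and one
  column per biallelic marker, coded -1/+1 by parental origin (first parent
  = +1 by convention) with an optional missing sentinel;
* a linkage map assigning each marker to a linkage group at a centimorgan
  position;
* a long-format phenotype table of replicated observations per line, from
  which per-line means (the regression response) and per-line variances
  (the weights of the weighted fit) are derived.

Results are written as TSV with a stable column order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("triqtl")

#: default missing-value sentinel in genotype files
DEFAULT_MISSING = "NA"


class FormatError(ValueError):
    """Raised when an input table violates the documented format."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dupes}")


@dataclass
class GenotypeMatrix:
    """Lines x markers grid of homozygous-line genotypes.

    Raw entries are -1/+1 (or NaN when missing); imputed entries may be any
    real value in [-1, +1] (conditional expectations of the +/-1 genotype).
    """

    line_ids: list
    marker_ids: list
    values: np.ndarray  # float array, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise FormatError(
                f"genotype grid shape {self.values.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        _check_unique(self.line_ids, "line ids")
        _check_unique(self.marker_ids, "marker ids")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise FormatError("genotype entries must lie in [-1, +1]")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def marker_index(self, marker_id) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def column(self, marker_id) -> np.ndarray:
        return self.values[:, self.marker_index(marker_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.line_ids, name="line_id"),
                            columns=self.marker_ids)


@dataclass
class LinkageMap:
    """marker_id -> (linkage group, position in cM)."""

    table: pd.DataFrame  # columns: marker_id, group, position_cM

    def __post_init__(self) -> None:
        required = ["marker_id", "group", "position_cM"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"linkage map missing columns {missing}")
        _check_unique(self.table["marker_id"], "marker ids in map")
        pos = pd.to_numeric(self.table["position_cM"], errors="raise")
        if (pos < 0).any():
            bad = self.table.loc[pos < 0, "marker_id"].tolist()
            raise FormatError(f"negative cM position for markers {bad}")
        self.table = self.table.assign(position_cM=pos.astype(float)).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, marker_id) -> bool:
        return marker_id in set(self.table["marker_id"])

    @property
    def groups(self) -> list:
        return list(pd.unique(self.table["group"]))

    def markers_in_group(self, group) -> list:
        sub = self.table[self.table["group"] == group]
        return sub.sort_values(["position_cM", "marker_id"], kind="stable")["marker_id"].tolist()

    def position(self, marker_id) -> float:
        row = self.table[self.table["marker_id"] == marker_id]
        if row.empty:
            raise KeyError(f"marker {marker_id!r} not on map")
        return float(row["position_cM"].iloc[0])

    def group_of(self, marker_id):
        row = self.table[self.table["marker_id"] == marker_id]
        if row.empty:
            raise KeyError(f"marker {marker_id!r} not on map")
        return row["group"].iloc[0]


@dataclass
class PhenotypeSet:
    """Replicated phenotype observations in long format.

    ``line_means`` is the response vector of the regression models;
    ``line_variances`` the per-line replicate variances used as weights in
    the weighted fit. Lines with fewer than two replicates have no raw
    variance; :meth:`line_variances` substitutes the median of the available
    variances there, and falls back to unit weights (with a warning) when no
    line is replicated, in which case weighted = unweighted.
    """

    records: pd.DataFrame  # columns: line_id, rep, value
    trait: str = "trait"

    def __post_init__(self) -> None:
        required = ["line_id", "rep", "value"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise FormatError(f"phenotype table missing columns {missing}")
        vals = pd.to_numeric(self.records["value"], errors="coerce")
        if vals.isna().any():
            bad = self.records.loc[vals.isna()].head()
            raise FormatError(f"non-numeric phenotype values, e.g.:\n{bad}")
        self.records = self.records.assign(value=vals.astype(float)).reset_index(drop=True)

    @property
    def line_ids(self) -> list:
        return list(pd.unique(self.records["line_id"]))

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def replicate_counts(self, order=None) -> pd.Series:
        counts = self.records.groupby("line_id", sort=False)["value"].count()
        return counts.reindex(order) if order is not None else counts

    def line_means(self, order=None) -> pd.Series:
        means = self.records.groupby("line_id", sort=False)["value"].mean()
        if order is not None:
            means = means.reindex(order)
            if means.isna().any():
                missing = list(means.index[means.isna()])
                raise KeyError(f"lines without phenotype records: {missing}")
        return means

    def raw_line_variances(self, order=None) -> pd.Series:
        """Sample variance per line; NaN where fewer than 2 replicates."""
        var = self.records.groupby("line_id", sort=False)["value"].var(ddof=1)
        return var.reindex(order) if order is not None else var

    def line_variances(self, order=None) -> pd.Series:
        var = self.raw_line_variances(order)
        if var.notna().any():
            med = float(var.dropna().median())
            if var.isna().any():
                logger.info(
                    "substituting median variance %.4g for %d single-replicate lines",
                    med, int(var.isna().sum()),
                )
            var = var.fillna(med)
            # a line whose replicates are identical gets the median too:
            # zero variance would give it infinite weight
            zero = var <= 0
            if zero.any() and med > 0:
                var[zero] = med
        else:
            warnings.warn(
                "no line has >=2 replicates; falling back to unit weights "
                "(weighted regression equals unweighted)",
                stacklevel=2,
            )
            var = pd.Series(1.0, index=var.index)
        return var

    def pooled_error(self) -> tuple[float, int]:
        """Pooled within-line mean square and its degrees of freedom."""
        grouped = self.records.groupby("line_id", sort=False)["value"]
        counts = grouped.count()
        df = int((counts - 1).clip(lower=0).sum())
        if df == 0:
            raise ValueError(
                "no replicated lines: within-line error variance is not "
                "estimable; supply an external error variance"
            )
        ss = float((grouped.var(ddof=1) * (counts - 1)).sum())
        return ss / df, df


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path, missing_code: str = DEFAULT_MISSING) -> GenotypeMatrix:
    """Read a genotype CSV: header ``line_id,<marker ids...>``, entries -1/1
    or *missing_code*."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("genotype file needs a line_id column and >=1 marker")
    line_ids = df.iloc[:, 0].tolist()
    marker_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:]
    values = np.full(raw.shape, np.nan)
    for j, marker in enumerate(marker_ids):
        col = raw.iloc[:, j].str.strip()
        is_missing = col.isna() | (col == missing_code)
        parsed = pd.to_numeric(col.where(~is_missing), errors="coerce")
        bad = ~is_missing & (parsed.isna() | ~parsed.isin([-1, 1]))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"invalid genotype {col.iloc[i]!r} at line {line_ids[i]!r}, "
                f"marker {marker!r}: expected -1, 1 or {missing_code!r}"
            )
        values[:, j] = parsed.to_numpy(dtype=float)
    return GenotypeMatrix(line_ids, marker_ids, values)


def read_map(path) -> LinkageMap:
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"linkage map {path} is empty", stacklevel=2)
        df = pd.DataFrame(columns=["marker_id", "group", "position_cM"])
    return LinkageMap(df)


def read_phenotypes(path, trait: str | None = None) -> PhenotypeSet:
    """Read a long phenotype CSV ``line_id,rep,value`` (or
    ``line_id,rep,<trait columns...>``; *trait* selects the column)."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 3:
        raise FormatError("phenotype file needs columns line_id, rep, value")
    if trait is None:
        trait = "value" if "value" in cols else cols[2]
    if trait not in cols:
        raise FormatError(f"trait column {trait!r} not in {cols}")
    out = df[[cols[0], cols[1], trait]].copy()
    out.columns = ["line_id", "rep", "value"]
    return PhenotypeSet(out, trait=trait)


def phenotype_traits(path) -> list[str]:
    """Trait column names in a (possibly multi-trait) phenotype file."""
    cols = list(pd.read_csv(path, nrows=0).columns)
    return cols[2:]


# ---------------------------------------------------------------------------
# writers


def write_genotypes(g: GenotypeMatrix, path, missing_code: str = DEFAULT_MISSING) -> None:
    df = g.to_frame()

    def fmt(v):
        if np.isnan(v):
            return missing_code
        if v == int(v):
            return str(int(v))
        return repr(float(v))

    df.map(fmt).to_csv(path)


def write_map(m: LinkageMap, path) -> None:
    m.table.to_csv(path, index=False)


def write_phenotypes(p: PhenotypeSet, path) -> None:
    p.records.to_csv(path, index=False)


#: column order of the per-triple results table
TRIPLES_COLUMNS = [
    "trait", "QTL1", "QTL2", "QTL3",
    "aaa_gu", "p_gu", "pct_var_gu",
    "aaa_gw", "p_gw", "pct_var_gw",
]

#: column order of the per-trait totals table
TOTALS_COLUMNS = [
    "trait", "n_qtls",
    "n_aaa_gu", "aaa_gu_min", "aaa_gu_max", "aaa_gu_total",
    "n_aaa_gw", "aaa_gw_min", "aaa_gw_max", "aaa_gw_total",
]


def write_table(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    """Write a results table as TSV in the documented column order."""
    if columns is not None:
        df = df.reindex(columns=columns)
    df.to_csv(path, sep="\t", index=False)
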