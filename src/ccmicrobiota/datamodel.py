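"""Data containers and flat-file I/O for abundance and metadata tables.

The whole analysis operates on two aligned tables: a samples x taxa
abundance matrix (microarray-style hybridization signal or relative
abundance, genus-like groups as flat labels) and a per-sample covariate
table that links each stool sample to an infant, a care group (center-based
childcare ``CC`` vs home care ``HOME``) and a sampling occasion (``PRE``,
before childcare entry, and ``POST``, four weeks later).

Every container validates its invariants on construction, so downstream
stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("CC", "HOME")
TIMEPOINTS = ("PRE", "POST")

#: Required columns of a metadata table, in canonical order.
METADATA_COLUMNS = [
    "sample_id",
    "infant_id",
    "group",
    "timepoint",
    "age_days",
    "bf_rate",
    "bf_rate_prior_period",
    "sibling",
    "csection",
]

#: Columns that may legitimately contain missing values (breastfeeding only).
BF_COLUMNS = ["bf_rate", "bf_rate_prior_period"]

_ROW_SUM_TOL = 1e-9


class Scale(str, Enum):
    """Measurement scale of an abundance table."""

    SIGNAL = "signal"
    RELATIVE = "relative"


class Orientation(str, Enum):
    """Layout of an abundance file on disk."""

    TAXA_AS_ROWS = "taxa_as_rows"
    SAMPLES_AS_ROWS = "samples_as_rows"


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise ValueError(f"duplicate {what} id(s): {sorted(map(str, dups))}")


@dataclass
class AbundanceTable:
    """Samples x taxa nonnegative abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with taxon ids as columns. All
        entries must be finite and nonnegative.
    scale:
        ``Scale.SIGNAL`` for raw hybridization-style signal,
        ``Scale.RELATIVE`` for row-closed relative abundance (each row must
        then sum to 1 within 1e-9).
    """

    data: pd.DataFrame
    scale: Scale = Scale.SIGNAL

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.scale = Scale(self.scale)
        _check_unique(list(self.data.index), "sample")
        _check_unique(list(self.data.columns), "taxon")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite abundance at sample "
                f"{self.data.index[i]!r}, taxon {self.data.columns[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative abundance at sample "
                f"{self.data.index[i]!r}, taxon {self.data.columns[j]!r}: "
                f"{values[i, j]!r}"
            )
        if self.scale is Scale.RELATIVE:
            sums = values.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > _ROW_SUM_TOL)[0]
            if bad.size:
                raise ValueError(
                    f"relative-scale rows must sum to 1; sample "
                    f"{self.data.index[bad[0]]!r} sums to {sums[bad[0]]!r}"
                )

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]


@dataclass
class ClrMatrix:
    """Centered-log-ratio transformed abundances; every row sums to zero."""

    data: pd.DataFrame
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        sums = self.data.to_numpy(dtype=float).sum(axis=1)
        bad = np.where(np.abs(sums) > 1e-8)[0]
        if bad.size:
            raise ValueError(
                f"clr rows must sum to 0; sample {self.data.index[bad[0]]!r} "
                f"sums to {sums[bad[0]]!r}"
            )
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SampleMetadata:
    """Per-sample covariates for a two-group, two-timepoint cohort.

    One row per stool sample; each infant contributes exactly one PRE and
    one POST row. Breastfeeding rates (average feedings/day over the period
    preceding the sample, and over the period before that) are the only
    covariates allowed to be missing; missingness is encoded as NaN and is
    never silently filled.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"metadata missing column(s): {missing_cols}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["infant_id"] = df["infant_id"].astype(str)
        _check_unique(list(df["sample_id"]), "sample")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown group label(s): {sorted(bad_group)}")
        bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoint label(s): {sorted(bad_tp)}")

        counts = df.groupby(["infant_id", "timepoint"], observed=True).size()
        per_infant = counts.groupby(level=0).size()
        dup = counts[counts > 1]
        if len(dup):
            raise ValueError(
                f"infant(s) with repeated timepoint rows: "
                f"{sorted({i for i, _ in dup.index})}"
            )
        incomplete = per_infant[per_infant != 2]
        if len(incomplete):
            raise ValueError(
                f"infant(s) without both PRE and POST rows: "
                f"{sorted(incomplete.index.tolist())}"
            )

        age = df["age_days"].to_numpy(dtype=float)
        if np.any(~np.isfinite(age)) or np.any(age <= 0):
            raise ValueError("age_days must be positive and finite")
        wide = df.pivot(index="infant_id", columns="timepoint", values="age_days")
        regress = wide.index[wide["POST"] <= wide["PRE"]].tolist()
        if regress:
            raise ValueError(
                f"POST age must exceed PRE age; offending infant(s): {regress}"
            )

        for col in BF_COLUMNS:
            vals = df[col].to_numpy(dtype=float)
            observed = vals[~np.isnan(vals)]
            if np.any(observed < 0):
                raise ValueError(f"{col} must be nonnegative where observed")
        for col in ("sibling", "csection"):
            df[col] = df[col].astype(bool)
        self.data = df.reset_index(drop=True)

    @property
    def infant_ids(self) -> list[str]:
        return sorted(self.data["infant_id"].unique())

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_infants(self) -> int:
        return self.data["infant_id"].nunique()

    def bf_missing_infants(self) -> list[str]:
        """Infants whose breastfeeding covariates are missing on every row."""
        miss = self.data[BF_COLUMNS].isna().all(axis=1)
        by_infant = miss.groupby(self.data["infant_id"]).all()
        return sorted(by_infant.index[by_infant].tolist())

    def has_missing_bf(self) -> bool:
        return bool(self.data[BF_COLUMNS].isna().any().any())

    def aligned_to(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        """Rows reordered to match an abundance table's sample ids."""
        df = self.data.set_index("sample_id", drop=False)
        try:
            out = df.loc[list(sample_ids)]
        except KeyError as exc:
            raise ValueError(f"metadata lacks sample id(s): {exc}") from exc
        return SampleMetadata(out.reset_index(drop=True))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_header_ids(path: Path, sep: str) -> list[str]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    return header[1:]


def read_abundance_table(
    path: str | Path,
    orientation: Orientation | str = Orientation.TAXA_AS_ROWS,
    scale: Scale | str = Scale.SIGNAL,
) -> AbundanceTable:
    """Read a tab-separated abundance table.

    ``orientation`` names the on-disk layout; the returned table is always
    samples x taxa. Duplicate ids and negative values are hard errors.
    """
    path = Path(path)
    orientation = Orientation(orientation)
    header_ids = _read_header_ids(path, "\t")
    what = "sample" if orientation is Orientation.TAXA_AS_ROWS else "taxon"
    _check_unique(header_ids, what)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = header_ids  # undo pandas' silent dedup-renaming
    if orientation is Orientation.TAXA_AS_ROWS:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceTable(df, scale=Scale(scale))


def write_abundance_table(
    table: AbundanceTable,
    path: str | Path,
    orientation: Orientation | str = Orientation.TAXA_AS_ROWS,
) -> None:
    df = table.data
    if Orientation(orientation) is Orientation.TAXA_AS_ROWS:
        df = df.T
    df.to_csv(path, sep="\t", index_label="id")


def write_clr_matrix(clr: ClrMatrix, path: str | Path) -> None:
    clr.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a metadata CSV; empty breastfeeding cells become missing values."""
    df = pd.read_csv(path)
    for col in ("sibling", "csection"):
        if col in df.columns and df[col].dtype == object:
            df[col] = (
                df[col]
                .astype(str)
                .str.strip()
                .str.lower()
                .map({"true": True, "false": False, "yes": True, "no": False,
                      "1": True, "0": False})
            )
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.data.to_csv(path, index=False)
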