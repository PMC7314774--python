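"""Deterministic compositional transforms and community summaries.

Covers the descriptive layer of the analysis: closure to relative
abundance, the centered-log-ratio (clr) transform that maps compositions
into an unconstrained space where linear models apply, Shannon alpha
diversity, detection-threshold richness, and per-taxon coefficients of
variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .datamodel import AbundanceTable, ClrMatrix, Scale


def _require_relative(table: AbundanceTable, op: str) -> None:
    if table.scale is not Scale.RELATIVE:
        raise ValueError(
            f"{op} expects a relative-abundance table; call "
            "to_relative_abundance first"
        )


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample to unit sum. Idempotent on relative tables."""
    values = table.values
    sums = values.sum(axis=1)
    zero = np.where(sums == 0)[0]
    if zero.size:
        raise ValueError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total abundance"
        )
    rel = values / sums[:, None]
    return AbundanceTable(
        pd.DataFrame(rel, index=table.data.index, columns=table.data.columns),
        scale=Scale.RELATIVE,
    )


def default_pseudocount(table: AbundanceTable) -> float:
    """Half the smallest positive entry; 0 if the table has no zeros."""
    values = table.values
    if not np.any(values == 0):
        return 0.0
    return float(values[values > 0].min()) / 2.0


def clr_transform(
    table: AbundanceTable, pseudocount: float | None = None
) -> ClrMatrix:
    """Centered log-ratio: log(x + c) minus its per-sample mean.

    ``pseudocount`` defaults to half the smallest positive relative
    abundance when zeros are present, and to 0 otherwise. A nonpositive
    pseudocount combined with zeros is rejected.
    """
    _require_relative(table, "clr_transform")
    values = table.values
    if pseudocount is None:
        pseudocount = default_pseudocount(table)
    if pseudocount <= 0 and np.any(values == 0):
        raise ValueError(
            "table contains zeros; a positive pseudocount is required"
        )
    logx = np.log(values + pseudocount)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return ClrMatrix(
        pd.DataFrame(clr, index=table.data.index, columns=table.data.columns),
        pseudocount=float(pseudocount),
    )


def shannon_diversity(table: AbundanceTable, base: float | None = None) -> pd.Series:
    """Shannon index H = -sum p_i log p_i per sample (natural log default)."""
    _require_relative(table, "shannon_diversity")
    h = entropy(table.values, base=base, axis=1)
    return pd.Series(h, index=table.data.index, name="shannon")


def richness(
    table: AbundanceTable, detection_quantile: float = 0.8
) -> pd.Series:
    """Per-sample count of features detected above a per-feature threshold.

    For every feature (probe- or taxon-level row of the transposed table)
    the detection threshold is that feature's ``detection_quantile``
    quantile across samples (linear-interpolation quantile); the feature
    counts as present in a sample when its signal strictly exceeds the
    threshold. A constant feature is therefore present nowhere.
    """
    if not 0 <= detection_quantile <= 1:
        raise ValueError("detection_quantile must be in [0, 1]")
    if table.n_samples < 2:
        raise ValueError(
            "richness needs at least two samples to define per-feature "
            "detection thresholds"
        )
    values = table.values
    thresholds = np.quantile(values, detection_quantile, axis=0)
    present = values > thresholds[None, :]
    return pd.Series(
        present.sum(axis=1), index=table.data.index, name="richness"
    )


@dataclass
class CoVVector:
    """Per-taxon coefficient of variation with an explicit undefined flag."""

    values: pd.Series
    undefined: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cov": self.values, "undefined": self.undefined})


def coefficient_of_variation(table: AbundanceTable) -> CoVVector:
    """Sample SD (ddof=1) over mean, per taxon across samples.

    Taxa with zero mean get a NaN value and an ``undefined`` flag instead of
    silently propagating NaN into downstream summaries.
    """
    _require_relative(table, "coefficient_of_variation")
    values = table.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    undefined = mean == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(undefined, np.nan, sd / np.where(undefined, 1.0, mean))
    taxa = table.data.columns
    return CoVVector(
        values=pd.Series(cov, index=taxa, name="cov"),
        undefined=pd.Series(undefined, index=taxa, name="undefined"),
    )
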