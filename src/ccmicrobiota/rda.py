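"""Redundancy analysis (RDA) from first principles.

RDA is the constrained ordination behind the multivariate layer of the
analysis: a PCA of the fitted values from multivariate least-squares
regression of the (clr-transformed) community matrix on explanatory
variables. Partial RDA first removes a set of conditioning variables from
both response and predictors. Significance is assessed by permutation
F-tests — full row permutation for simple effects, reduced-model residual
permutation for conditional effects — and explained variance is
decomposed over predictor blocks by inclusion-exclusion (the Venn
partition).

Inertia is reported as variance (sums of squares divided by n-1), so the
"Variance" column of the effects table matches the convention of classical
constrained-ordination software.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ClrMatrix, SampleMetadata


def _as_matrix(Y) -> np.ndarray:
    if isinstance(Y, ClrMatrix):
        return Y.values
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0, keepdims=True)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns that do not increase the rank when added left to right."""
    bad, kept = [], np.empty((X.shape[0], 0))
    rank = 0
    for j in range(X.shape[1]):
        cand = np.hstack([kept, X[:, j : j + 1]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            bad.append(names[j])
    return bad


def _orthonormal_basis(M: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing via SVD)."""
    if M.shape[1] == 0:
        return np.empty((M.shape[0], 0))
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    r = int(np.sum(s > tol * max(M.shape) * (s[0] if s.size else 1.0)))
    return U[:, :r]


@dataclass
class RdaResult:
    """Constrained-ordination summary.

    Inertias satisfy total = constrained + residual; for a partial RDA the
    total refers to the variance remaining after the conditioning variables
    have been removed.
    """

    total_inertia: float
    constrained_inertia: float
    residual_inertia: float
    r2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float = float("nan")
    n_perm: int = 0
    eigenvalues: np.ndarray | None = None
    site_scores: pd.DataFrame | None = None
    species_scores: pd.DataFrame | None = None
    biplot_scores: pd.DataFrame | None = None


@dataclass
class PartitionResult:
    """Venn decomposition of explained variance over predictor blocks.

    ``fractions`` maps each nonempty block subset to the variance fraction
    exclusive to exactly that subset (singletons = unique fractions; small
    negatives are a known feature of the decomposition and are reported,
    not clipped). The fractions sum to the full-model R² by construction.
    """

    fractions: dict[tuple[str, ...], float]
    simple_r2: dict[str, float]
    unique_r2: dict[str, float]
    total_r2: float
    residual: float
    adjusted: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": " & ".join(k), "order": len(k), "fraction": v}
            for k, v in sorted(self.fractions.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ]
        rows.append({"subset": "residual", "order": 0, "fraction": self.residual})
        return pd.DataFrame(rows)


def _prepare(Y, X, Z):
    Yc = _center(_as_matrix(Y))
    Xm = _as_matrix(X)
    Zm = _as_matrix(Z) if Z is not None and np.size(Z) else None
    n = Yc.shape[0]
    if Xm.shape[0] != n or (Zm is not None and Zm.shape[0] != n):
        raise ValueError("Y, X and Z must have the same number of rows")
    Xc = _center(Xm)
    if Zm is not None:
        Qz = _orthonormal_basis(_center(Zm))
        Yr = Yc - Qz @ (Qz.T @ Yc)
        Xr = Xc - Qz @ (Qz.T @ Xc)
        df_z = Qz.shape[1]
    else:
        Qz, Yr, Xr, df_z = None, Yc, Xc, 0
    return Yc, Yr, Xr, Qz, df_z, n


def fit_rda(
    Y,
    X,
    Z=None,
    *,
    x_names: list[str] | None = None,
    compute_scores: bool = False,
    n_axes: int = 2,
    allow_rank_deficient: bool = False,
) -> RdaResult:
    """Fit (partial) RDA of ``Y`` on ``X``, conditioning on ``Z``.

    ``Y`` is column-centered; with ``Z`` given, response and predictors are
    replaced by their residuals on ``Z``. Constrained inertia is the sum of
    squares of the fitted values; the pseudo-F statistic is the ratio of
    constrained to residual mean squares. Rank-deficient predictor sets are
    rejected with the offending columns named.
    """
    if isinstance(X, pd.DataFrame) and x_names is None:
        x_names = [str(c) for c in X.columns]
    Yc, Yr, Xr, Qz, df_z, n = _prepare(Y, X, Z)
    names = x_names or [f"x{j}" for j in range(Xr.shape[1])]
    rank = np.linalg.matrix_rank(Xr) if Xr.shape[1] else 0
    if Xr.shape[1] == 0:
        raise ValueError("X must contain at least one column")
    if rank < Xr.shape[1] and not allow_rank_deficient:
        bad = _collinear_columns(Xr, names)
        raise ValueError(
            f"rank-deficient predictor matrix; collinear column(s): {bad}"
        )
    Qx = _orthonormal_basis(Xr)
    fitted = Qx @ (Qx.T @ Yr)

    denom = n - 1
    total = float(np.sum(Yr**2)) / denom
    constrained = float(np.sum(fitted**2)) / denom
    residual = total - constrained
    df_x = Qx.shape[1]
    df_res = n - 1 - df_x - df_z
    if df_res <= 0:
        raise ValueError("not enough samples for the requested design")
    if df_x == 0:  # informationless predictors (rank 0 after centering)
        f_stat, r2 = float("nan"), 0.0
    else:
        f_stat = (
            (constrained / df_x) / (residual / df_res) if residual > 0 else np.inf
        )
        r2 = constrained / total if total > 0 else 0.0

    result = RdaResult(
        total_inertia=total,
        constrained_inertia=constrained,
        residual_inertia=residual,
        r2=r2,
        f_stat=f_stat,
        df=(df_x, df_res),
    )
    if compute_scores:
        U, s, Vt = np.linalg.svd(fitted / np.sqrt(denom), full_matrices=False)
        k = min(n_axes, df_x, s.size)
        eig = s**2
        axes = [f"RDA{i + 1}" for i in range(k)]
        result.eigenvalues = eig[: max(df_x, 1)]
        # correlation-style (scaling 2) scores
        tot_ev = eig[:k].sum() or 1.0
        site = U[:, :k] * s[:k]
        species = Vt.T[:, :k] * np.sqrt(eig[:k] / tot_ev)
        y_index = Y.data.index if isinstance(Y, ClrMatrix) else (
            Y.index if isinstance(Y, pd.DataFrame) else pd.RangeIndex(n)
        )
        y_cols = Y.data.columns if isinstance(Y, ClrMatrix) else (
            Y.columns if isinstance(Y, pd.DataFrame) else pd.RangeIndex(Yc.shape[1])
        )
        result.site_scores = pd.DataFrame(site, index=y_index, columns=axes)
        result.species_scores = pd.DataFrame(species, index=y_cols, columns=axes)
        with np.errstate(invalid="ignore", divide="ignore"):
            Xn = Xr / np.where(Xr.std(axis=0) == 0, 1.0, Xr.std(axis=0))
            sn = site / np.where(site.std(axis=0) == 0, 1.0, site.std(axis=0))
            biplot = (Xn.T @ sn) / n
        result.biplot_scores = pd.DataFrame(biplot, index=names, columns=axes)
    return result


def _block_permutation(rng, n, blocks):
    """Permutation respecting repeated-measures structure.

    Whole subject blocks are permuted against each other and the rows
    *within* each block are independently shuffled, so both between- and
    within-subject predictors see a valid exchangeable null.
    """
    if blocks is None:
        return rng.permutation(n)
    uniq, inv = np.unique(blocks, return_inverse=True)
    rows_of = [np.where(inv == b)[0] for b in range(uniq.size)]
    sizes = {r.size for r in rows_of}
    if len(sizes) != 1:
        raise ValueError("permutation blocks must be equally sized")
    order = rng.permutation(uniq.size)
    perm = np.empty(n, dtype=int)
    pos = 0
    for b in order:
        rows = rows_of[b]
        rows = rows[rng.permutation(rows.size)]
        perm[pos : pos + rows.size] = rows
        pos += rows.size
    # destination slots follow the block layout of the original matrix
    dest = np.concatenate(rows_of)
    out = np.empty(n, dtype=int)
    out[dest] = perm
    return out


def permutation_test(
    Y,
    X,
    Z=None,
    n_perm: int = 999,
    seed: int = 0,
    blocks=None,
) -> tuple[float, float]:
    """Permutation pseudo-F test; returns ``(F_observed, p)``.

    Simple effects (no ``Z``) permute rows of ``Y``; conditional effects
    use reduced-model permutation: the residuals of ``Y`` on ``Z`` are
    permuted and added back to the ``Z``-fitted values, preserving the
    conditioning structure under the null.

    With ``blocks`` (one label per row, e.g. the infant id in a PRE/POST
    design), whole blocks are permuted and rows are shuffled within
    blocks. Repeated measures make free row permutation anti-conservative
    for subject-level predictors such as the care group, because the two
    samples of an infant are correlated; the block scheme restores the
    nominal error rate. ``p`` has floor 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Yc, Yr, Xr, Qz, df_z, n = _prepare(Y, X, Z)
    rank = np.linalg.matrix_rank(Xr)
    if rank < Xr.shape[1]:
        raise ValueError("rank-deficient predictor matrix")
    Qx = _orthonormal_basis(Xr)
    df_x = Qx.shape[1]
    df_res = n - 1 - df_x - df_z
    if blocks is not None:
        blocks = np.asarray(blocks)
        if blocks.size != n:
            raise ValueError("blocks must have one label per row")

    def f_of(Yp: np.ndarray) -> float:
        if Qz is not None:
            Yp = Yp - Qz @ (Qz.T @ Yp)
        tot = np.sum(Yp**2)
        fit = np.sum((Qx.T @ Yp) ** 2)
        res = tot - fit
        if res <= 0:
            return np.inf
        return (fit / df_x) / (res / df_res)

    f_obs = f_of(Yr if Qz is None else Yc)
    # note: f_of re-residualizes internally, so pass the pre-partial matrix
    rng = np.random.default_rng(seed)
    if Qz is not None:
        fitted_z = Yc - Yr
    count = 0
    for _ in range(n_perm):
        perm = _block_permutation(rng, n, blocks)
        Yp = Yr[perm] if Qz is None else fitted_z + Yr[perm]
        if f_of(Yp) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


def covariate_frame(metadata: SampleMetadata) -> pd.DataFrame:
    """Numeric covariates for ordination, indexed by sample id.

    Breastfeeding enters as the two per-infant period averages (birth->PRE
    and PRE->POST), both attached to every row of that infant, which is why
    the breastfeeding block carries two degrees of freedom.
    """
    df = metadata.data
    pre = df[df["timepoint"] == "PRE"].set_index("infant_id")
    post = df[df["timepoint"] == "POST"].set_index("infant_id")
    bf_before = df["infant_id"].map(pre["bf_rate"])
    bf_during = df["infant_id"].map(post["bf_rate"])
    cc = (df["group"] == "CC").astype(float)
    time = (df["timepoint"] == "POST").astype(float)
    out = pd.DataFrame(
        {
            "time": time,
            "cc": cc,
            "age": df["age_days"].astype(float),
            "sib": df["sibling"].astype(float),
            "csec": df["csection"].astype(float),
            "bf_before": bf_before.astype(float),
            "bf_during": bf_during.astype(float),
            "cc_x_time": cc * time,
        }
    )
    out.index = df["sample_id"]
    return out


def default_blocks() -> dict[str, list[str]]:
    """Named predictor blocks of the standard effects table."""
    return {
        "Time": ["time"],
        "CC": ["cc"],
        "Age": ["age"],
        "Sibling": ["sib"],
        "Birth-mode": ["csec"],
        "Breastfeeding": ["bf_before", "bf_during"],
        "CC x Time": ["cc", "time", "cc_x_time"],
    }


def effects_table(
    Y,
    covariates: pd.DataFrame,
    blocks: dict[str, list[str]] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    drop_incomplete: bool = True,
    subjects=None,
) -> pd.DataFrame:
    """Simple and conditional permutation tests for every predictor block.

    Simple effects regress the community on one block alone; conditional
    effects partial out the union of all other blocks (minus any columns
    shared with the tested block, so overlapping interaction blocks are
    well-defined). Rows with missing covariates are dropped, mirroring a
    complete-case multivariate analysis. ``subjects`` (one label per row)
    activates subject-block permutation for the repeated-measures design.
    """
    blocks = blocks or default_blocks()
    Ym = _as_matrix(Y)
    cov = covariates.copy()
    subj = None if subjects is None else np.asarray(subjects)
    if drop_incomplete:
        keep = ~cov.isna().any(axis=1)
        cov = cov.loc[keep]
        Ym = Ym[keep.to_numpy()]
        if subj is not None:
            subj = subj[keep.to_numpy()]
    rng = np.random.default_rng(seed)
    # constant columns carry no information and would make designs singular
    usable = [c for c in cov.columns if cov[c].std(ddof=0) > 0]
    rows = []
    for name, cols in blocks.items():
        cols = [c for c in cols if c in usable]
        if not cols:
            rows.append(
                {
                    "effect": name, "mode": "simple", "df": 0, "variance": 0.0,
                    "F": np.nan, "p": np.nan, "r2": 0.0, "n_perm": n_perm,
                }
            )
            continue
        Xb = cov[cols]
        modes = [("simple", None)]
        other = [
            c
            for bname, bcols in blocks.items()
            if bname != name
            for c in bcols
            if c not in cols and c in usable
        ]
        other = list(dict.fromkeys(other))
        modes.append(("conditional", cov[other] if other else None))
        for mode, Zb in modes:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = fit_rda(Ym, Xb, Zb)
            f_stat, p = permutation_test(
                Ym, Xb, Zb, n_perm=n_perm, seed=sub_seed, blocks=subj
            )
            rows.append(
                {
                    "effect": name,
                    "mode": mode,
                    "df": res.df[0],
                    "variance": res.constrained_inertia,
                    "F": f_stat,
                    "p": p,
                    "r2": res.constrained_inertia / res.total_inertia
                    if mode == "simple"
                    else _conditional_r2(Ym, Xb, Zb),
                    "n_perm": n_perm,
                }
            )
    return pd.DataFrame(rows)


def _conditional_r2(Y, X, Z) -> float:
    """Constrained inertia of the partial model over the *total* inertia."""
    full = fit_rda(Y, X, Z)
    Yc = _center(_as_matrix(Y))
    total = float(np.sum(Yc**2)) / (Yc.shape[0] - 1)
    return full.constrained_inertia / total if total > 0 else 0.0


def adjusted_r2(r2: float, n: int, df: int) -> float:
    """Ezekiel adjustment, as used by classical variance partitioning."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - df)


def variance_partition(
    Y,
    covariates: pd.DataFrame,
    blocks: dict[str, list[str]],
    adjusted: bool = False,
) -> PartitionResult:
    """Inclusion-exclusion Venn partition of explained variance.

    Fits an RDA for every nonempty subset of 2-4 column-disjoint blocks and
    solves the linear system R²(S) = sum of fractions of Venn cells touched
    by S. Unique fractions may come out slightly negative; they are
    reported as-is.
    """
    names = list(blocks)
    k = len(names)
    if not 2 <= k <= 4:
        raise ValueError("variance_partition supports 2 to 4 blocks")
    all_cols = [c for cols in blocks.values() for c in cols]
    if len(all_cols) != len(set(all_cols)):
        raise ValueError("blocks must be column-disjoint for partitioning")
    Ym = _as_matrix(Y)
    cov = covariates
    keep = ~cov[all_cols].isna().any(axis=1)
    cov = cov.loc[keep]
    Ym = Ym[keep.to_numpy()]
    n = Ym.shape[0]

    subsets = []
    for r in range(1, k + 1):
        subsets.extend(itertools.combinations(range(k), r))

    r2_of: dict[tuple[int, ...], float] = {}
    for S in subsets:
        cols = [c for i in S for c in blocks[names[i]]]
        res = fit_rda(Ym, cov[cols], allow_rank_deficient=True)
        r2 = res.r2
        if adjusted:
            r2 = adjusted_r2(r2, n, res.df[0])
        r2_of[S] = r2

    m = len(subsets)
    M = np.zeros((m, m))
    for a, Sp in enumerate(subsets):
        for b, S in enumerate(subsets):
            if set(S) & set(Sp):
                M[a, b] = 1.0
    rhs = np.array([r2_of[S] for S in subsets])
    f = np.linalg.solve(M, rhs)

    fractions = {
        tuple(names[i] for i in S): float(f[b]) for b, S in enumerate(subsets)
    }
    full_r2 = r2_of[tuple(range(k))]
    return PartitionResult(
        fractions=fractions,
        simple_r2={names[i]: float(r2_of[(i,)]) for i in range(k)},
        unique_r2={
            names[i]: float(fractions[(names[i],)]) for i in range(k)
        },
        total_r2=float(full_r2),
        residual=float(1.0 - full_r2),
        adjusted=adjusted,
    )
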