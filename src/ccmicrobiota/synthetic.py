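"""Synthetic two-group, two-timepoint infant-cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes: a Bifidobacterium-dominated, highly variable early-infant gut
community observed in 49 childcare-entry (CC) and 49 home-care (HOME)
infants at a PRE sample (~10 weeks of age) and a POST sample four weeks
later, with realistic covariate distributions and a small block of
completely missing breastfeeding data (4 CC infants, 1 HOME infant).

Compositions follow a logistic-normal (softmax of Gaussian logits) model:

    logit_s = base + u_infant + sum_c effect_c * x_c(s) + noise_s
    p_s     = softmax(logit_s)

so per-taxon covariate effects are additive on a clr-like scale, matching
the assumptions of the downstream linear models. Base logits are calibrated
by fixed-seed Monte-Carlo moment matching so that the population-mean
relative abundance of the dominant taxon is 0.51 and the five dominant taxa
jointly average above 0.75, mirroring the community structure the analysis
targets. Optional ``diversity_effects`` impose exact additive Shannon
shifts (in nats) via a per-sample power transform of the composition.

The realized effect vectors, subject intercepts and Shannon shifts are
returned as :class:`CohortTruth`, the oracle for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import entropy, truncnorm

from .datamodel import BF_COLUMNS, SampleMetadata, AbundanceTable, Scale

#: Population-mean relative-abundance targets of the five dominant
#: genus-like groups (Bifidobacterium-like, Streptococcus-like,
#: Enterococcus-like, Lactobacillus-like, Granulicatella-like).
HEAD_TARGETS = (0.51, 0.168, 0.034, 0.029, 0.010)

#: Age (days) truncated-normal parameters per (group, timepoint):
#: (mean, sd, min, max).
AGE_PARAMS = {
    ("CC", "PRE"): (87.8, 16.0, 58.0, 123.0),
    ("HOME", "PRE"): (76.7, 6.3, 68.0, 90.0),
    ("CC", "POST"): (118.4, 16.1, 90.0, 154.0),
    ("HOME", "POST"): (106.5, 5.9, 97.0, 116.0),
}

#: Breastfeeding (feedings/day, birth->PRE period): (mean, sd, min, max).
BF_PRE_PARAMS = {"CC": (5.4, 2.9, 0.0, 11.4), "HOME": (5.7, 2.3, 0.0, 8.9)}
#: PRE->POST breastfeeding = decay * previous period + noise, clipped.
BF_DECAY = 0.70
BF_NOISE_SD = 1.5
BF_POST_MAX = {"CC": 8.5, "HOME": 8.2}

#: Sibling / C-section prevalences per group (counts out of 49).
SIBLING_P = {"CC": 25 / 49, "HOME": 32 / 49}
CSECTION_P = {"CC": 6 / 49, "HOME": 3 / 49}

#: Weekly childcare half-days pmf (median 4, interquartile range 3-4).
HALFDAYS_VALUES = (2, 3, 4, 5, 6)
HALFDAYS_PROBS = (0.10, 0.25, 0.45, 0.15, 0.05)

#: Covariate keys accepted in ``effects`` and ``diversity_effects``.
COVARIATE_KEYS = ("cc", "time", "cc_x_time", "age", "bf", "sib", "csec")

_CALIBRATION_SEED = 20_200_624
_CALIBRATION_MC = 20000


@dataclass
class CohortConfig:
    """Conditions under which a synthetic cohort is generated.

    ``subject_sd`` and ``noise_sd`` are the between-infant and
    within-infant SDs of the taxon logits; their defaults (1.2 and 0.8)
    make between-infant variation dominate and spread the dominant taxon
    over most of the unit interval, the "large inter- and intra-individual
    variability" regime. ``effects`` maps covariate names to per-taxon
    logit effect vectors (default: no effects, the no-childcare-effect
    null). ``diversity_effects`` maps covariate names to additive Shannon
    shifts in nats.
    """

    n_per_group: int = 49
    n_taxa: int = 130
    seed: int = 0
    taxon_mean_targets: tuple[float, ...] | None = None
    taxon_mean_logits: np.ndarray | None = None
    subject_sd: float = 1.2
    noise_sd: float = 0.8
    effects: dict[str, np.ndarray] = field(default_factory=dict)
    diversity_effects: dict[str, float] = field(default_factory=dict)
    bf_missing_cc: int = 4
    bf_missing_home: int = 1

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_taxa < 2:
            raise ValueError("need at least 1 infant per group and 2 taxa")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("subject_sd and noise_sd must be nonnegative")
        if self.bf_missing_cc + self.bf_missing_home > 2 * self.n_per_group:
            raise ValueError("more missing-bf infants than infants")
        if self.taxon_mean_logits is not None:
            self.taxon_mean_logits = np.asarray(self.taxon_mean_logits, float)
            if self.taxon_mean_logits.shape != (self.n_taxa,):
                raise ValueError("taxon_mean_logits length must equal n_taxa")
        for name, vec in self.effects.items():
            if name not in COVARIATE_KEYS:
                raise ValueError(f"unknown effect covariate {name!r}")
            arr = np.asarray(vec, float)
            if arr.shape != (self.n_taxa,):
                raise ValueError(f"effect vector {name!r} must have n_taxa entries")
            self.effects[name] = arr
        for name in self.diversity_effects:
            if name not in COVARIATE_KEYS:
                raise ValueError(f"unknown diversity covariate {name!r}")


@dataclass
class CohortTruth:
    """Ground truth realized during generation; oracle for recovery tests."""

    base_logits: np.ndarray
    subject_intercepts: pd.DataFrame  # infants x taxa
    effects: dict[str, np.ndarray]
    diversity_effects: dict[str, float]
    seed: int


def default_taxon_targets(n_taxa: int) -> np.ndarray:
    """Dominance profile: five heavy genus-like groups plus a geometric tail."""
    if n_taxa <= len(HEAD_TARGETS):
        head = np.asarray(HEAD_TARGETS[:n_taxa], float)
        return head / head.sum()
    head = np.asarray(HEAD_TARGETS, float)
    tail_mass = 1.0 - head.sum()
    n_tail = n_taxa - len(head)
    tail = 0.95 ** np.arange(n_tail)
    tail = tail / tail.sum() * tail_mass
    return np.concatenate([head, tail])


@lru_cache(maxsize=32)
def _calibrated_logits(
    targets_key: tuple[float, ...], total_sd: float
) -> np.ndarray:
    """Logits whose logistic-normal mean composition matches ``targets``.

    E[softmax(a + sd*z)] differs from softmax(a); the offset is solved by
    iterative proportional fitting against a fixed-seed Monte-Carlo estimate
    of the mean (common random numbers across iterations).
    """
    targets = np.asarray(targets_key, float)
    a = np.log(targets)
    if total_sd == 0:
        return a - a.mean()
    rng = np.random.default_rng(_CALIBRATION_SEED)
    z = rng.standard_normal((_CALIBRATION_MC, targets.size))
    for _ in range(15):
        logits = a[None, :] + total_sd * z
        p = _softmax(logits)
        m = p.mean(axis=0)
        a = a + np.log(targets) - np.log(m)
    return a - a.mean()


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def base_logits_for(config: CohortConfig) -> np.ndarray:
    if config.taxon_mean_logits is not None:
        return np.asarray(config.taxon_mean_logits, float)
    targets = (
        np.asarray(config.taxon_mean_targets, float)
        if config.taxon_mean_targets is not None
        else default_taxon_targets(config.n_taxa)
    )
    total_sd = float(np.hypot(config.subject_sd, config.noise_sd))
    return _calibrated_logits(tuple(np.round(targets, 12)), round(total_sd, 12))


def _truncnorm_rvs(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _shift_shannon(p: np.ndarray, delta: float) -> np.ndarray:
    """Power-transform a composition so its Shannon index moves by ``delta``.

    H(p^gamma / Z) is continuous and decreasing in gamma, so the target is
    bracketed and solved exactly; targets outside the attainable range are
    clipped to it.
    """
    if delta == 0:
        return p
    k = p.size
    h0 = float(entropy(p))
    target = float(np.clip(h0 + delta, 1e-6, np.log(k) - 1e-12))

    def h_of(gamma: float) -> float:
        logq = gamma * np.log(p)
        logq -= logq.max()
        q = np.exp(logq)
        q /= q.sum()
        return float(entropy(q)) - target

    lo, hi = 1.0, 1.0
    # expand bracket: gamma>1 sharpens (lower H), gamma<1 flattens (higher H)
    while h_of(hi) > 0 and hi < 1e4:
        hi *= 2.0
    while h_of(lo) < 0 and lo > 1e-6:
        lo /= 2.0
    if h_of(hi) > 0 or h_of(lo) < 0:
        gamma = hi if delta < 0 else lo
    else:
        gamma = brentq(h_of, lo, hi, xtol=1e-12)
    logq = gamma * np.log(p)
    logq -= logq.max()
    q = np.exp(logq)
    return q / q.sum()


def _make_infant_frame(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-infant covariates drawn from the cohort's demographic profile."""
    rows = []
    for group in ("CC", "HOME"):
        n = config.n_per_group
        prefix = "CC" if group == "CC" else "HM"
        ids = [f"{prefix}{i + 1:03d}" for i in range(n)]
        mean, sd, lo, hi = AGE_PARAMS[(group, "PRE")]
        age_pre = _truncnorm_rvs(mean, sd, lo, hi, n, rng)
        post_gap_mean = AGE_PARAMS[(group, "POST")][0] - mean
        age_post = age_pre + np.maximum(rng.normal(post_gap_mean, 2.0, n), 14.0)
        bmean, bsd, blo, bhi = BF_PRE_PARAMS[group]
        bf_pre = _truncnorm_rvs(bmean, bsd, blo, bhi, n, rng)
        bf_post = np.clip(
            BF_DECAY * bf_pre + rng.normal(0.0, BF_NOISE_SD, n),
            0.0,
            BF_POST_MAX[group],
        )
        sibling = rng.random(n) < SIBLING_P[group]
        csection = rng.random(n) < CSECTION_P[group]
        halfdays = (
            rng.choice(HALFDAYS_VALUES, size=n, p=HALFDAYS_PROBS)
            if group == "CC"
            else np.full(n, np.nan)
        )
        rows.append(
            pd.DataFrame(
                {
                    "infant_id": ids,
                    "group": group,
                    "age_pre": age_pre,
                    "age_post": age_post,
                    "bf_pre_period": bf_pre,
                    "bf_post_period": bf_post,
                    "sibling": sibling,
                    "csection": csection,
                    "cc_halfdays": halfdays,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _infant_frame_to_metadata(infants: pd.DataFrame) -> SampleMetadata:
    recs = []
    for _, r in infants.iterrows():
        for tp in ("PRE", "POST"):
            recs.append(
                {
                    "sample_id": f"{r.infant_id}_{tp}",
                    "infant_id": r.infant_id,
                    "group": r.group,
                    "timepoint": tp,
                    "age_days": r.age_pre if tp == "PRE" else r.age_post,
                    # bf_rate: feedings/day in the period preceding this
                    # sample; prior-period value repeats the birth->PRE rate.
                    "bf_rate": r.bf_pre_period if tp == "PRE" else r.bf_post_period,
                    "bf_rate_prior_period": r.bf_pre_period,
                    "sibling": bool(r.sibling),
                    "csection": bool(r.csection),
                    "cc_halfdays": r.cc_halfdays,
                }
            )
    return SampleMetadata(pd.DataFrame(recs))


def covariate_values(metadata: SampleMetadata) -> pd.DataFrame:
    """Numeric covariate codes used when applying generator effects.

    Binary covariates are 0/1; age and breastfeeding are standardized over
    the cohort so effect vectors are per-SD on the logit scale.
    """
    df = metadata.data
    cc = (df["group"] == "CC").astype(float)
    time = (df["timepoint"] == "POST").astype(float)
    age = df["age_days"].astype(float)
    bf = df["bf_rate"].astype(float)
    out = pd.DataFrame(
        {
            "cc": cc,
            "time": time,
            "cc_x_time": cc * time,
            "age": (age - age.mean()) / age.std(ddof=0),
            "bf": (bf - bf.mean()) / (bf.std(ddof=0) or 1.0),
            "sib": df["sibling"].astype(float),
            "csec": df["csection"].astype(float),
        }
    )
    out.index = df["sample_id"]
    return out


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[AbundanceTable, SampleMetadata, CohortTruth]:
    """Generate one cohort: relative abundances, metadata and ground truth.

    Deterministic under a fixed ``config.seed``; all draws flow from a
    single :func:`numpy.random.default_rng` stream in a fixed order.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    infants = _make_infant_frame(config, rng)
    metadata = _infant_frame_to_metadata(infants)
    covs = covariate_values(metadata)

    base = base_logits_for(config)
    n_inf = len(infants)
    u = rng.standard_normal((n_inf, config.n_taxa)) * config.subject_sd
    infant_index = {iid: k for k, iid in enumerate(infants["infant_id"])}

    taxa = [f"taxon_{i + 1:03d}" for i in range(config.n_taxa)]
    taxa[0] = "Bifidobacterium_like"

    df = metadata.data
    noise = rng.standard_normal((len(df), config.n_taxa)) * config.noise_sd
    logits = base[None, :] + noise
    for s, (_, row) in enumerate(df.iterrows()):
        logits[s] += u[infant_index[row["infant_id"]]]
    for name, vec in config.effects.items():
        logits += np.outer(covs[name].to_numpy(), vec)

    p = _softmax(logits)

    if config.diversity_effects:
        delta = np.zeros(len(df))
        for name, shift in config.diversity_effects.items():
            delta += shift * covs[name].to_numpy()
        for s in range(len(df)):
            if delta[s] != 0.0:
                p[s] = _shift_shannon(p[s], float(delta[s]))

    table = AbundanceTable(
        pd.DataFrame(p, index=df["sample_id"].tolist(), columns=taxa),
        scale=Scale.RELATIVE,
    )
    miss_seed = int(rng.integers(0, 2**31 - 1))
    metadata = inject_missingness(
        metadata, config.bf_missing_cc, config.bf_missing_home, seed=miss_seed
    )
    truth = CohortTruth(
        base_logits=base,
        subject_intercepts=pd.DataFrame(
            u, index=infants["infant_id"].tolist(), columns=taxa
        ),
        effects={k: v.copy() for k, v in config.effects.items()},
        diversity_effects=dict(config.diversity_effects),
        seed=config.seed,
    )
    return table, metadata, truth


def inject_missingness(
    metadata: SampleMetadata, n_cc: int, n_home: int, seed: int = 0
) -> SampleMetadata:
    """Blank breastfeeding covariates for randomly chosen infants (MCAR).

    Exactly ``n_cc`` CC infants and ``n_home`` HOME infants lose both
    breastfeeding fields at both timepoints.
    """
    rng = np.random.default_rng(seed)
    df = metadata.data.copy()
    chosen: list[str] = []
    for group, n in (("CC", n_cc), ("HOME", n_home)):
        infants = sorted(df.loc[df["group"] == group, "infant_id"].unique())
        if n > len(infants):
            raise ValueError(
                f"cannot blank {n} infants in group {group}; only "
                f"{len(infants)} available"
            )
        if n:
            chosen.extend(rng.choice(infants, size=n, replace=False))
    if chosen:
        mask = df["infant_id"].isin(chosen)
        df.loc[mask, BF_COLUMNS] = np.nan
    return SampleMetadata(df)


def null_config(seed: int, **overrides) -> CohortConfig:
    """Default cohort with all covariate effects zero (the headline null)."""
    return replace(CohortConfig(seed=seed), **overrides)
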