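"""End-to-end orchestration of the cohort analysis.

Runs generate (or load) -> compositional metrics -> descriptives ->
imputation -> RDA -> robust Bayesian models -> Random Forest, binding all
stage outputs into one run directory with a JSON manifest (seed, config
hash, package versions). Stages are cached by config hash, so rerunning an
identical configuration reuses existing outputs and cheap stages are not
blocked by the expensive Bayesian one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import RobustModelSpec, fit_all_taxa, fit_diversity
from .datamodel import (
    SampleMetadata,
    read_abundance_table,
    read_metadata,
    write_abundance_table,
    write_clr_matrix,
    write_metadata,
)
from .impute import pmm_impute
from .metrics import (
    clr_transform,
    coefficient_of_variation,
    shannon_diversity,
    to_relative_abundance,
)
from .rda import covariate_frame, default_blocks, effects_table, variance_partition
from .rf import classify_groups
from .synthetic import CohortConfig, generate_cohort

def _version() -> str:
    from . import __version__

    return __version__


_CONTINUOUS_VARS = [
    ("Age (days) PRE", lambda df: df[df.timepoint == "PRE"], "age_days"),
    ("Age (days) POST", lambda df: df[df.timepoint == "POST"], "age_days"),
    ("Breastfeeding (birth - PRE)", lambda df: df[df.timepoint == "PRE"], "bf_rate"),
    ("Breastfeeding (PRE - POST)", lambda df: df[df.timepoint == "POST"], "bf_rate"),
]
_CATEGORICAL_VARS = [("Siblings", "sibling"), ("C-section", "csection")]


def descriptives_table(metadata: SampleMetadata) -> pd.DataFrame:
    """Group-comparison table of demographic variables.

    Continuous variables get per-group mean/sd/min/max and a Welch t-test
    p-value; categorical variables get per-group counts and a chi-squared
    p-value. Zero-variance comparisons are flagged rather than producing a
    silent NaN.
    """
    df = metadata.data
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("descriptives need both CC and HOME groups")
    rows = []
    for name, subset, col in _CONTINUOUS_VARS:
        sub = subset(df)
        a = sub.loc[sub.group == "CC", col].dropna().to_numpy(dtype=float)
        b = sub.loc[sub.group == "HOME", col].dropna().to_numpy(dtype=float)
        sd_a = a.std(ddof=1) if a.size > 1 else 0.0
        sd_b = b.std(ddof=1) if b.size > 1 else 0.0
        degenerate = sd_a == 0 and sd_b == 0
        if a.size < 2 or b.size < 2:
            p, note = float("nan"), "too few observations"
        elif degenerate:
            p = 1.0 if a.mean() == b.mean() else 0.0
            note = "zero variance in both groups"
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            note = ""
        rows.append(
            {
                "variable": name,
                "type": "continuous",
                "cc_mean": a.mean(), "cc_sd": a.std(ddof=1),
                "cc_min": a.min(), "cc_max": a.max(),
                "home_mean": b.mean(), "home_sd": b.std(ddof=1),
                "home_min": b.min(), "home_max": b.max(),
                "p_value": p,
                "test": "welch_t",
                "note": note,
            }
        )
    infants = df[df.timepoint == "PRE"]
    for name, col in _CATEGORICAL_VARS:
        tab = pd.crosstab(infants["group"], infants[col].astype(bool))
        tab = tab.reindex(columns=[False, True], fill_value=0)
        if (tab.to_numpy() == 0).any(axis=0).all() or tab.shape[0] < 2:
            p, note = float("nan"), "degenerate contingency table"
        else:
            try:
                p = float(stats.chi2_contingency(tab.to_numpy()).pvalue)
                note = ""
            except ValueError:
                p, note = float("nan"), "degenerate contingency table"
        rows.append(
            {
                "variable": name,
                "type": "categorical",
                "cc_yes": int(tab.loc["CC", True]),
                "cc_no": int(tab.loc["CC", False]),
                "home_yes": int(tab.loc["HOME", True]),
                "home_no": int(tab.loc["HOME", False]),
                "p_value": p,
                "test": "chi2",
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def welch_t_statistic(a, b) -> float:
    """Welch's unequal-variance t statistic (kept for hand-check oracles)."""
    return float(stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                                 equal_var=False).statistic)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either a synthetic ``cohort`` config or paths to an abundance TSV and
    metadata CSV. ``stages`` toggles individual stages; disabled stages
    simply leave no outputs. All stage seeds derive from ``seed`` through
    named substreams.
    """

    out_dir: str | Path = "run"
    cohort: CohortConfig | None = None
    abundance_path: str | Path | None = None
    metadata_path: str | Path | None = None
    seed: int = 0
    n_perm: int = 999
    m_imputations: int = 10
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "metrics": True,
            "descriptives": True,
            "impute": True,
            "rda": True,
            "bayes": True,
            "rf": True,
        }
    )
    bayes_taxa: int | list[str] | None = 5
    bayes_kwargs: dict = field(
        default_factory=lambda: {
            "n_chains": 2, "n_warmup": 500, "n_steps": 200, "thin": 4
        }
    )
    rf_kwargs: dict = field(
        default_factory=lambda: {"folds": 10, "repeats": 10, "n_trees": 500}
    )

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        for k in ("abundance_path", "metadata_path"):
            if d[k] is not None:
                d[k] = str(d[k])
        if self.cohort is not None:
            c = dataclasses.asdict(self.cohort)
            c["taxon_mean_logits"] = (
                None
                if self.cohort.taxon_mean_logits is None
                else [float(v) for v in self.cohort.taxon_mean_logits]
            )
            c["effects"] = {k: [float(x) for x in v] for k, v in c["effects"].items()}
            d["cohort"] = c
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["cohort", "impute", "rda", "bayes", "rf"]
    ss = np.random.SeedSequence(seed)
    return {
        n: int(s.generate_state(1)[0] % (2**31 - 1))
        for n, s in zip(names, ss.spawn(len(names)))
    }


def run_full_analysis(config: RunConfig) -> Path:
    """Execute the configured pipeline into ``config.out_dir``.

    Deterministic under a fixed config; a rerun with the same config hash
    reuses stage outputs already present in the directory. Each stage
    failure aborts the run with the stage named and a pointer to its log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seeds = _stage_seeds(config.seed)
    manifest_path = out / "manifest.json"
    cached = {}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash:
            cached = {s: True for s in old.get("stages_completed", [])}

    log_path = out / "run.log"
    log_lines: list[str] = []
    completed: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def run_stage(name: str, fn) -> None:
        if cached.get(name):
            log(f"{name}: cached, skipped")
            completed.append(name)
            return
        try:
            fn()
        except Exception as exc:
            log(f"{name}: FAILED: {exc}")
            log_path.write_text("\n".join(log_lines) + "\n")
            raise RuntimeError(
                f"pipeline stage {name!r} failed ({exc}); see {log_path}"
            ) from exc
        log(f"{name}: done")
        completed.append(name)

    state: dict = {}

    def stage_input():
        if config.cohort is not None:
            cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["cohort"])
            table, metadata, truth = generate_cohort(cohort_cfg)
            write_abundance_table(table, out / "abundance.tsv")
            write_metadata(metadata, out / "metadata.csv")
            (out / "truth.json").write_text(
                json.dumps(
                    {
                        "seed": truth.seed,
                        "effects": {
                            k: [float(x) for x in v] for k, v in truth.effects.items()
                        },
                        "diversity_effects": truth.diversity_effects,
                    },
                    indent=2,
                )
            )
        else:
            if config.abundance_path is None or config.metadata_path is None:
                raise ValueError("either a cohort config or input paths required")
            table = read_abundance_table(config.abundance_path)
            metadata = read_metadata(config.metadata_path)
        state["table"], state["metadata"] = table, metadata

    run_stage("input", stage_input)
    if "table" not in state:  # cached input: reload from disk
        state["table"] = read_abundance_table(out / "abundance.tsv",
                                              scale="relative")
        state["metadata"] = read_metadata(out / "metadata.csv")
    table, metadata = state["table"], state["metadata"]
    metadata = metadata.aligned_to(table.sample_ids)
    rel = to_relative_abundance(table)
    clr = clr_transform(rel)
    H = shannon_diversity(rel)

    if config.stages.get("metrics", True):
        def stage_metrics():
            H.to_frame().to_csv(out / "diversity.csv", index_label="sample_id")
            coefficient_of_variation(rel).to_frame().to_csv(
                out / "cov.csv", index_label="taxon_id"
            )
            write_clr_matrix(clr, out / "clr.tsv")
        run_stage("metrics", stage_metrics)

    if config.stages.get("descriptives", True):
        run_stage(
            "descriptives",
            lambda: descriptives_table(metadata).to_csv(
                out / "descriptives.csv", index=False
            ),
        )

    imputations = None
    if config.stages.get("impute", True):
        def stage_impute():
            nonlocal imputations
            imputations = pmm_impute(
                metadata, m=config.m_imputations, seed=seeds["impute"]
            )
            for k, md in enumerate(imputations, start=1):
                write_metadata(md, out / f"meta_imp_{k:02d}.csv")
            donor = [
                {f"{sid}|{target}": donor for (sid, target), donor in log.items()}
                for log in imputations.donor_log
            ]
            (out / "donor_log.json").write_text(json.dumps(donor, indent=2))
        run_stage("impute", stage_impute)
        if imputations is None and cached.get("impute"):
            imputations = [
                read_metadata(p) for p in sorted(out.glob("meta_imp_*.csv"))
            ]

    if config.stages.get("rda", True):
        def stage_rda():
            covs = covariate_frame(metadata)
            tab = effects_table(
                clr, covs, n_perm=config.n_perm, seed=seeds["rda"],
                subjects=metadata.data["infant_id"].to_numpy(),
            )
            tab.to_csv(out / "table2.csv", index=False)
            from .rda import fit_rda

            keep = covs.notna().all(axis=1).to_numpy()
            covs_c = covs.loc[keep]
            part_blocks = {
                name: cols
                for name, cols in {
                    "Age": ["age"],
                    "Sibling": ["sib"],
                    "Birth-mode": ["csec"],
                    "Breastfeeding": ["bf_before", "bf_during"],
                }.items()
                if all(covs_c[c].std(ddof=0) > 0 for c in cols)
            }
            if len(part_blocks) >= 2:
                part = variance_partition(clr.values[keep], covs_c, part_blocks)
                part.to_frame().to_csv(out / "partition.csv", index=False)
            score_cols = [
                c
                for c in ["age", "sib", "csec", "bf_before", "bf_during"]
                if covs_c[c].std(ddof=0) > 0
            ]
            res = fit_rda(
                clr.values[keep], covs_c[score_cols], compute_scores=True
            )
            scores = pd.concat(
                {
                    "site": res.site_scores.set_axis(
                        np.array(clr.sample_ids)[keep]
                    ),
                    "species": res.species_scores.set_axis(clr.taxon_ids),
                    "biplot": res.biplot_scores,
                }
            )
            scores.to_csv(out / "scores.tsv", sep="\t")
        run_stage("rda", stage_rda)

    if config.stages.get("bayes", True):
        def stage_bayes():
            meta_sets = imputations if imputations is not None else metadata
            spec = RobustModelSpec()
            div_summ, predictive, _ = fit_diversity(
                H, meta_sets, spec,
                seed=seeds["bayes"], **config.bayes_kwargs,
            )
            div_summ.insert(0, "outcome", "shannon")
            order = rel.data.mean().sort_values(ascending=False)
            taxa = config.bayes_taxa
            if isinstance(taxa, int):
                taxa = list(order.index[:taxa])
            taxa_summ = (
                fit_all_taxa(
                    clr, meta_sets, spec, taxa=taxa,
                    seed=seeds["bayes"] + 1, **config.bayes_kwargs,
                )
                if taxa
                else pd.DataFrame()
            )
            if len(taxa_summ):
                taxa_summ = taxa_summ.rename(columns={"taxon": "outcome"})
                cols = ["outcome"] + [c for c in taxa_summ.columns if c != "outcome"]
                taxa_summ = taxa_summ[cols]
            pd.concat([div_summ, taxa_summ], ignore_index=True).to_csv(
                out / "contrasts.csv", index=False
            )
            predictive.to_csv(out / "predictive.csv", index=False)
            diag = {
                "shannon_max_rhat": float(div_summ["max_rhat"].iloc[0]),
                "shannon_converged": bool(div_summ["converged"].iloc[0]),
                "rhat_threshold": 1.05,
            }
            (out / "diagnostics.json").write_text(json.dumps(diag, indent=2))
        run_stage("bayes", stage_bayes)

    if config.stages.get("rf", True):
        def stage_rf():
            post_ids = metadata.data.loc[
                metadata.data.timepoint == "POST", "sample_id"
            ]
            Xpost = rel.data.loc[post_ids]
            labels = metadata.data.set_index("sample_id").loc[post_ids, "group"]
            cv = classify_groups(
                Xpost, labels.to_numpy(), seed=seeds["rf"], **config.rf_kwargs
            )
            (out / "cv.json").write_text(json.dumps(cv.to_dict(), indent=2))
        run_stage("rf", stage_rf)

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages_completed": completed,
        "config": config.to_jsonable(),
        "versions": {
            "ccmicrobiota": _version(),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    log_path.write_text("\n".join(log_lines) + "\n")
    return out
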