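"""One-command orchestration from inputs (files or simulation) to a report bundle.

The bundle mirrors the full analysis: a demographics table with per-group
counts and tests, score comparisons between CYT-high and CYT-low, a GSEA
table, Kaplan-Meier / log-rank outputs per endpoint, two-factor
CYT x exhaustion-marker stratifications, the univariate -> multivariate Cox
table, and a machine-readable run manifest (config hash + seed) that fully
reproduces every table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import CohortTable, ExpressionMatrix, GeneSet, ScoreFrame
from .errors import ConfigError, ImmunocytError
from .features import ScnaThresholds
from .gsea import gsea_collection, gsea_table
from .io import (
    read_clinical,
    read_expression_matrix,
    read_gene_sets,
    read_repertoire,
    read_segments,
    write_score_frame,
)
from .scores import (
    EXHAUSTION_CORE_PANEL,
    build_score_frame,
    dichotomize_by_median,
)
from .simulate import SimConfig, default_config, generate_cohort
from .stats import chi_square_test, mann_whitney, results_table, compare_groups
from .survival import (
    cox_table,
    km_fit,
    km_table,
    log_rank,
    two_factor_stratification,
    univariate_screen_then_multivariate,
)

log = logging.getLogger(__name__)

DEMOGRAPHIC_CATEGORICALS = ("sex", "stage", "inflammation", "etiology", "til_status")


@dataclass
class PipelineConfig:
    """Run configuration: exactly one of ``inputs`` or ``simulate``."""

    outdir: str = "immunocyt_out"
    seed: int = 0
    inputs: dict | None = None          # paths: expression, clinical, segments, repertoire
    simulate: SimConfig | None = None
    endpoints: tuple[str, ...] = ("OS", "DSS", "PFI", "DFI")
    dichotomize_score: str = "cyt"
    exhaustion_markers: tuple[str, ...] = EXHAUSTION_CORE_PANEL.members
    cyt_pseudocount: float = 0.01
    log_pseudocount: float = 1.0
    scna_gain_min: float = 0.6
    scna_loss_max: float = -0.4
    gsea_gene_sets: str | None = None   # GMT path; None -> built-in synthetic sets
    gsea_n_permutations: int = 1000
    gsea_weight: float = 1.0
    gsea_perm_mode: str = "auto"
    cox_endpoint: str = "OS"
    cox_alpha: float = 0.05
    make_plots: bool = True

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError("exactly one of 'inputs' and 'simulate' must be given")
        for ep in (*self.endpoints, self.cox_endpoint):
            if ep not in ("OS", "DSS", "PFI", "DFI"):
                raise ConfigError(f"unknown endpoint {ep!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "inputs"})
        cfg.inputs = raw.get("inputs")
        if sim is not None:
            cfg.simulate = default_config(**sim)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        if self.simulate is not None:
            payload["simulate"] = asdict(self.simulate)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
        return cohort.expression, cohort.clinical, cohort.segments, cohort.repertoire
    paths = config.inputs or {}
    if "expression" not in paths or "clinical" not in paths:
        raise ConfigError("inputs must provide at least 'expression' and 'clinical' paths")
    expr = read_expression_matrix(paths["expression"])
    clinical = read_clinical(paths["clinical"])
    segments = read_segments(paths["segments"]) if paths.get("segments") else None
    repertoire = read_repertoire(paths["repertoire"]) if paths.get("repertoire") else None
    return expr, clinical, segments, repertoire


def _builtin_gene_sets(expr: ExpressionMatrix) -> list[GeneSet]:
    """Synthetic gene sets for simulate-mode GSEA: the planted immune program
    plus size-matched decoy sets."""
    genes = set(expr.genes)
    immune = sorted(g for g in genes if not g.startswith("DECOY"))
    decoys = sorted(g for g in genes if g.startswith("DECOY"))
    sets = [GeneSet("IMMUNE_PROGRAM_SYNTHETIC", "planted immune-heat genes", frozenset(immune))]
    for i in range(3):
        chunk = decoys[30 * i : 30 * (i + 1)]
        if chunk:
            sets.append(
                GeneSet(f"DECOY_SET_{i + 1}_SYNTHETIC", "unloaded decoy genes", frozenset(chunk))
            )
    return sets


def _demographics(clinical: CohortTable, groups: pd.Series) -> pd.DataFrame:
    merged = clinical.data.set_index("sample_id").join(groups.rename("group"), how="inner")
    merged = merged[merged["group"].notna()]
    rows = []
    hi, lo = merged["group"] == "high", merged["group"] == "low"
    if "age" in merged.columns:
        res = mann_whitney(merged.loc[hi, "age"], merged.loc[lo, "age"], mode="normal")
        rows.append(
            {
                "variable": "age",
                "high": f"{merged.loc[hi, 'age'].mean():.1f}±{merged.loc[hi, 'age'].std():.1f}",
                "low": f"{merged.loc[lo, 'age'].mean():.1f}±{merged.loc[lo, 'age'].std():.1f}",
                "test": res.method,
                "p_value": float(f"{res.p_value:.3g}"),
            }
        )
    for col in DEMOGRAPHIC_CATEGORICALS:
        if col not in merged.columns:
            continue
        sub = merged[[col, "group"]].dropna()
        if sub[col].nunique() < 2:
            continue
        table = pd.crosstab(sub[col], sub["group"])
        res = chi_square_test(table.to_numpy())
        levels = list(table.index)
        rows.append(
            {
                "variable": f"{col} ({'/'.join(map(str, levels))})",
                "high": "/".join(str(int(v)) for v in table["high"]) if "high" in table else "",
                "low": "/".join(str(int(v)) for v in table["low"]) if "low" in table else "",
                "test": res.method,
                "p_value": float(f"{res.p_value:.3g}"),
            }
        )
    return pd.DataFrame(rows)


def _km_plot(fits: dict, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, fit in sorted(fits.items()):
        x = np.concatenate([[0.0], np.repeat(fit.event_times, 2)])
        y = np.concatenate([[1.0, 1.0], np.repeat(fit.survival, 2)[:-1]])
        ax.plot(x, y, label=f"{label} (n={fit.n})", drawstyle="default")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Any stage failure aborts with the stage name; the partial manifest of
    completed stages is written before the error propagates.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "immunocyt",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
        "outputs": {},
    }
    stage = "load_inputs"
    try:
        expr, clinical, segments, repertoire = _load_inputs(config)
        manifest["n_samples"] = len(expr.samples)
        manifest["stages"].append(stage)

        stage = "scores"
        frame = build_score_frame(
            expr,
            segments,
            repertoire,
            cyt_pseudocount=config.cyt_pseudocount,
            log_pseudocount=config.log_pseudocount,
            scna_thresholds=ScnaThresholds(config.scna_gain_min, config.scna_loss_max),
            dichotomize=(config.dichotomize_score, "checkpoint_index"),
        )
        # per-marker expression groups for the two-factor stratifications
        for marker in config.exhaustion_markers:
            if marker in expr.data.index:
                values = np.log2(expr.data.loc[marker].astype(float) + 1.0)
                frame.data[f"{marker}_expr"] = values
                frame.data[f"{marker}_expr_group"] = dichotomize_by_median(values)
        write_score_frame(frame, outdir / "scores.tsv")
        manifest["outputs"]["scores"] = "scores.tsv"
        groups = frame.groups(config.dichotomize_score)
        manifest["group_sizes"] = {
            "high": int((groups == "high").sum()),
            "low": int((groups == "low").sum()),
        }
        manifest["stages"].append(stage)

        stage = "demographics"
        demo = _demographics(clinical, groups)
        demo.to_csv(outdir / "demographics.tsv", sep="\t", index=False, lineterminator="\n")
        manifest["outputs"]["demographics"] = "demographics.tsv"
        manifest["stages"].append(stage)

        stage = "score_comparisons"
        score_cols = [
            c for c in frame.data.columns
            if not c.endswith("_group") and c != config.dichotomize_score
        ]
        comparisons = compare_groups(frame, config.dichotomize_score, score_cols, mode="normal")
        results_table(comparisons).to_csv(
            outdir / "score_comparisons.tsv", sep="\t", index=False, lineterminator="\n"
        )
        manifest["outputs"]["score_comparisons"] = "score_comparisons.tsv"
        manifest["stages"].append(stage)

        stage = "gsea"
        if config.gsea_gene_sets:
            gene_sets = read_gene_sets(config.gsea_gene_sets)
        else:
            gene_sets = _builtin_gene_sets(expr)
        gsea_results = gsea_collection(
            expr,
            groups,
            gene_sets,
            n_perm=config.gsea_n_permutations,
            perm_mode=config.gsea_perm_mode,
            weight=config.gsea_weight,
            seed=config.seed,
        )
        gsea_table(gsea_results).to_csv(
            outdir / "gsea.tsv", sep="\t", index=False, lineterminator="\n"
        )
        manifest["outputs"]["gsea"] = "gsea.tsv"
        manifest["stages"].append(stage)

        stage = "survival"
        merged = clinical.data.set_index("sample_id").join(groups.rename("group"), how="inner")
        logrank_rows = []
        for ep in config.endpoints:
            sub = merged[[f"{ep}_time", f"{ep}_event", "group"]].dropna()
            fits = {}
            for label in ("high", "low"):
                mask = sub["group"] == label
                if mask.any():
                    fit = km_fit(sub.loc[mask, f"{ep}_time"], sub.loc[mask, f"{ep}_event"])
                    fits[label] = fit
                    km_table(fit).to_csv(
                        outdir / f"km_{ep}_{label}.tsv", sep="\t", index=False,
                        lineterminator="\n",
                    )
            res = log_rank(sub[f"{ep}_time"], sub[f"{ep}_event"], sub["group"].to_numpy())
            logrank_rows.append(
                {
                    "endpoint": ep,
                    "statistic": res.statistic,
                    "p_value": float(f"{res.p_value:.3g}"),
                    "n_high": int((sub["group"] == "high").sum()),
                    "n_low": int((sub["group"] == "low").sum()),
                    "median_high": fits["high"].median_survival if "high" in fits else "",
                    "median_low": fits["low"].median_survival if "low" in fits else "",
                }
            )
            if config.make_plots:
                _km_plot(fits, outdir / f"km_{ep}.png", f"{ep} by {config.dichotomize_score}")
        pd.DataFrame(logrank_rows).to_csv(
            outdir / "logrank.tsv", sep="\t", index=False, lineterminator="\n"
        )
        manifest["outputs"]["logrank"] = "logrank.tsv"
        manifest["stages"].append(stage)

        stage = "two_factor_stratification"
        strat_rows = []
        for marker in config.exhaustion_markers:
            col = f"{marker}_expr_group"
            if col not in frame.data.columns:
                continue
            strat = two_factor_stratification(
                clinical, frame, config.dichotomize_score, f"{marker}_expr",
                endpoint=config.cox_endpoint,
            )
            strat_rows.append(
                {
                    "marker": marker,
                    "statistic": strat.logrank.statistic,
                    "p_value": float(f"{strat.logrank.p_value:.3g}"),
                    "df": strat.logrank.extras["df"],
                    "group_sizes": json.dumps(strat.group_sizes, sort_keys=True),
                }
            )
            if config.make_plots:
                _km_plot(
                    strat.fits,
                    outdir / f"km_{config.cox_endpoint}_by_{marker}.png",
                    f"{config.cox_endpoint}: {config.dichotomize_score} x {marker}",
                )
        pd.DataFrame(strat_rows).to_csv(
            outdir / "stratification.tsv", sep="\t", index=False, lineterminator="\n"
        )
        manifest["outputs"]["stratification"] = "stratification.tsv"
        manifest["stages"].append(stage)

        stage = "cox"
        uni, multi = univariate_screen_then_multivariate(
            clinical, frame, endpoint=config.cox_endpoint, alpha=config.cox_alpha
        )
        uni_out = uni.copy()
        if not uni_out.empty:
            uni_out["p"] = uni_out["p"].map(lambda v: float(f"{v:.3g}"))
        uni_out.to_csv(outdir / "cox_univariate.tsv", sep="\t", index=False, lineterminator="\n")
        manifest["outputs"]["cox_univariate"] = "cox_univariate.tsv"
        if multi is not None:
            cox_table(multi).to_csv(
                outdir / "cox_multivariate.tsv", sep="\t", index=False, lineterminator="\n"
            )
            manifest["outputs"]["cox_multivariate"] = "cox_multivariate.tsv"
            manifest["cox_converged"] = multi.converged
        manifest["stages"].append(stage)
    except ImmunocytError:
        manifest["failed_stage"] = stage
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.error("pipeline aborted during stage %s", stage)
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = "manifest.json"
    return manifest
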