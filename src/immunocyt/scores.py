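"""Per-sample immune scores and median dichotomization.

The cytolytic activity score (CYT) is the geometric mean of GZMA and PRF1
TPM — a transcriptional proxy for cytotoxic-lymphocyte killing. Panel scores
(APOBEC3 mutagenesis, inhibitory checkpoint index) are the mean of
log2(TPM + pseudocount) across a fixed gene panel. Cohorts are split into
high/low groups at the median: *high* means strictly above the median, so a
tie-free odd-size cohort always has one more low than high sample (e.g.
185 high / 186 low at n = 371).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, RepertoireSummary, ScoreFrame, SegmentProfile
from .errors import AlignmentError, DegenerateInputError, MissingGeneError
from .features import ScnaThresholds, cpk_diversity, scna_event_count

log = logging.getLogger(__name__)

#: explicit alias table (common protein names -> HGNC symbols); exact match only
GENE_ALIASES = {
    "PD-1": "PDCD1",
    "PD1": "PDCD1",
    "PD-L1": "CD274",
    "PDL1": "CD274",
    "PD-L2": "PDCD1LG2",
    "PDL2": "PDCD1LG2",
    "TIM3": "HAVCR2",
    "TIM-3": "HAVCR2",
    "VISTA": "VSIR",
}

CYT_GENES = ("GZMA", "PRF1")


@dataclass(frozen=True)
class GenePanel:
    """An ordered, named panel of gene symbols."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise DegenerateInputError(f"panel {self.name!r} is empty")

    def resolved(self) -> tuple[str, ...]:
        return tuple(GENE_ALIASES.get(g, g) for g in self.members)


APOBEC3_PANEL = GenePanel(
    "apobec3",
    ("APOBEC3A", "APOBEC3B", "APOBEC3C", "APOBEC3D", "APOBEC3F", "APOBEC3G", "APOBEC3H"),
)

#: the 11 inhibitory checkpoint / T-cell exhaustion markers
CHECKPOINT_PANEL = GenePanel(
    "checkpoint",
    ("PDCD1", "CD274", "CTLA4", "IDO1", "IDO2", "LAG3", "HAVCR2",
     "PDCD1LG2", "TIGIT", "ADORA2A", "VSIR"),
)

#: the four-marker exhaustion subset used for two-factor survival stratification
EXHAUSTION_CORE_PANEL = GenePanel("exhaustion_core", ("PDCD1", "CTLA4", "CD274", "LAG3"))

HLA_GENES = ("HLA-A", "HLA-B")


def _require_genes(expr: ExpressionMatrix, genes: tuple[str, ...], what: str) -> None:
    absent = [g for g in genes if g not in expr.data.index]
    if absent:
        raise MissingGeneError(f"{what}: gene(s) absent from expression matrix: {absent}")


def cyt_score(expr: ExpressionMatrix, pseudocount: float = 0.01) -> pd.Series:
    """Cytolytic activity: geometric mean of GZMA and PRF1 TPM.

    Computed in log space as exp(mean(ln(TPM + pseudocount))) − pseudocount is
    *not* subtracted: the score is the geometric mean of the shifted values,
    which with pseudocount 0 is exactly the plain geometric mean (0 whenever
    either gene is 0).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    _require_genes(expr, CYT_GENES, "cyt_score")
    block = expr.data.loc[list(CYT_GENES)].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        score = np.exp(np.log(block + pseudocount).mean(axis=0))
    return pd.Series(score, index=expr.data.columns, name="cyt")


def log_average_score(
    expr: ExpressionMatrix,
    panel: GenePanel,
    pseudocount: float = 1.0,
    base: float = 2.0,
) -> pd.Series:
    """Mean of log_base(TPM + pseudocount) over a gene panel, per sample."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0 for log-average scores")
    genes = panel.resolved()
    _require_genes(expr, genes, f"log_average_score[{panel.name}]")
    block = expr.data.loc[list(genes)].to_numpy(dtype=float)
    score = (np.log(block + pseudocount) / np.log(base)).mean(axis=0)
    return pd.Series(score, index=expr.data.columns, name=panel.name)


def hla_expression(expr: ExpressionMatrix) -> pd.DataFrame:
    """Raw HLA-A / HLA-B TPM per sample (no transform)."""
    _require_genes(expr, HLA_GENES, "hla_expression")
    return pd.DataFrame(
        {
            "hla_a": expr.data.loc["HLA-A"].astype(float),
            "hla_b": expr.data.loc["HLA-B"].astype(float),
        }
    )


def dichotomize_by_median(values: pd.Series) -> pd.Series:
    """Split samples at the median: 'high' iff value > median, else 'low'.

    Ties at the median go to 'low', so tie-free cohorts split into
    floor(n/2) high and ceil(n/2) low.
    """
    values = pd.Series(values)
    if values.isna().any():
        raise DegenerateInputError("cannot dichotomize with missing values")
    if len(values) < 2:
        raise DegenerateInputError("need at least 2 samples to dichotomize")
    cut = float(values.median())
    labels = np.where(values.to_numpy(dtype=float) > cut, "high", "low")
    return pd.Series(labels, index=values.index, name="group")


def build_score_frame(
    expr: ExpressionMatrix,
    segments: list[SegmentProfile] | None = None,
    repertoire: list[RepertoireSummary] | None = None,
    panels: tuple[GenePanel, ...] = (APOBEC3_PANEL, CHECKPOINT_PANEL),
    cyt_pseudocount: float = 0.01,
    log_pseudocount: float = 1.0,
    scna_thresholds: ScnaThresholds | None = None,
    dichotomize: tuple[str, ...] = ("cyt",),
) -> ScoreFrame:
    """Join all per-sample scores into one frame keyed by expression samples.

    Samples missing a modality (no segment profile, no repertoire row) get
    missing values for the affected scores only. Group labels are attached for
    each score named in ``dichotomize``; samples with that score missing stay
    unlabeled.
    """
    thresholds = scna_thresholds or ScnaThresholds()
    samples = expr.samples
    data = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    data["cyt"] = cyt_score(expr, cyt_pseudocount)
    for panel in panels:
        col = "checkpoint_index" if panel.name == "checkpoint" else panel.name
        data[col] = log_average_score(expr, panel, log_pseudocount)
    if all(g in expr.data.index for g in HLA_GENES):
        data[["hla_a", "hla_b"]] = hla_expression(expr)

    if segments is not None:
        by_sample = {p.sample_id: p for p in segments}
        if by_sample and not set(by_sample) & set(samples):
            raise AlignmentError("segment profiles share no sample ids with expression")
        data["scna_events"] = pd.Series(
            {
                s: float(scna_event_count(by_sample[s], thresholds))
                for s in samples
                if s in by_sample
            }
        )
    if repertoire is not None:
        by_sample_r = {r.sample_id: r for r in repertoire}
        if by_sample_r and not set(by_sample_r) & set(samples):
            raise AlignmentError("repertoire rows share no sample ids with expression")
        rows = {s: by_sample_r[s] for s in samples if s in by_sample_r}
        data["tcr_richness"] = pd.Series({s: float(r.tcr_unique_cdr3) for s, r in rows.items()})
        data["bcr_richness"] = pd.Series(
            {s: float(r.bcr_unique_clonotypes) for s, r in rows.items()}
        )
        data["cpk"] = pd.Series(
            {
                s: cpk_diversity(r)
                for s, r in rows.items()
                if r.tcr_total_reads > 0
            }
        )

    for score in dichotomize:
        if score not in data.columns:
            raise MissingGeneError(f"cannot dichotomize unknown score {score!r}")
        values = data[score].dropna()
        labels = dichotomize_by_median(values)
        data[f"{score}_group"] = labels.reindex(data.index)

    provenance = {
        "cyt_pseudocount": cyt_pseudocount,
        "log_pseudocount": log_pseudocount,
        "log_base": 2,
        "scna_gain_min": thresholds.gain_min,
        "scna_loss_max": thresholds.loss_max,
        "dichotomized": ",".join(dichotomize),
    }
    for panel in panels:
        provenance[f"panel_{panel.name}"] = ",".join(panel.resolved())
    return ScoreFrame(data, provenance)
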