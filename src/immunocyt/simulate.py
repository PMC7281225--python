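"""Synthetic cohort generator built on a latent immune-activity factor.

Each sample carries a latent "immune heat" h ~ N(0, 1) that simultaneously
drives every modality the analysis consumes, plus an independent exhaustion
residual e ~ N(0, 1) that separates checkpoint-marker expression from heat:

* expression — log2(TPM+1) of the cytolytic genes (GZMA, PRF1), the seven
  APOBEC3 cytidine deaminases, the eleven inhibitory checkpoint markers and
  HLA-A/B is baseline + (class effect) * h + Gaussian noise, back-transformed
  as max(2^x - 1, 0); 200 decoy genes carry no h loading;
* copy-number burden — the SCNA event count is Poisson with log-mean
  log(base rate) + slope * h (slope negative: hot tumors are more
  genomically quiet), realized as that many supra-threshold segments plus
  three neutral ones;
* repertoire — unique TCR CDR3 clonotypes shift linearly with h over a fixed
  read depth;
* survival — event times are exponential with hazard
  baseline * exp(hazard_log_hr * h + exhaustion_hazard_log_hr * e) per
  endpoint (progression endpoints run at twice the death baseline), censored
  by an independent exponential tuned to the target censoring fraction;
* TIL status is Bernoulli with logit slope * h.

Checkpoint markers load on both axes (checkpoint_effect * h +
exhaustion_axis_effect * e) and the hazard is
baseline * exp(hazard_log_hr * h + exhaustion_hazard_log_hr * e): heat
protects while exhaustion, net of heat, harms. This is the minimal structure
that reproduces every sign pattern the analysis is meant to detect —
including the two-factor stratification in which the score-high/
exhaustion-low stratum fares best and score-low/exhaustion-high fares worst
even though exhaustion markers are marginally higher in score-high tumors.
The generator is deterministic given (config, seed), with an independent
child stream per modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    ENDPOINTS,
    CohortTable,
    ExpressionMatrix,
    RepertoireSummary,
    SegmentProfile,
)
from .errors import ConfigError
from .scores import APOBEC3_PANEL, CHECKPOINT_PANEL, CYT_GENES, HLA_GENES

N_DECOY_GENES = 200
NEUTRAL_SEGMENTS_PER_SAMPLE = 3

#: baseline log2(TPM+1) per gene class
BASELINE_LOG2 = {
    "cyt": 4.0,
    "apobec3": 3.5,
    "checkpoint": 3.0,
    "hla": 8.0,
}

#: marginal category probabilities for clinical covariates (levels, probs,
#: missing fraction), roughly matching a hepatocellular-carcinoma cohort
CLINICAL_MARGINALS = {
    "sex": (("male", "female"), (0.674, 0.326), 0.0),
    "stage": (("I", "II", "III", "IV"), (0.493, 0.248, 0.245, 0.014), 0.065),
    "inflammation": (("none", "mild", "severe"), (0.50, 0.42, 0.08), 0.37),
    "etiology": (("none", "alcohol", "hepB", "hepC", "other"), (0.26, 0.33, 0.23, 0.10, 0.08), 0.05),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Effects are loadings of the latent heat factor h; setting every effect to
    zero (see null_config) yields a cohort with no planted structure, used
    for type-I-error calibration.
    """

    n_samples: int = 371
    seed: int = 0
    heat_effect_expr: float = 1.0      # h loading on GZMA/PRF1/HLA log2 expression
    noise_sd: float = 0.6              # per-gene Gaussian noise on log2 scale
    apobec_effect: float = 0.7         # h loading on APOBEC3 genes
    checkpoint_effect: float = 0.8     # h loading on checkpoint markers
    scna_base_rate: float = 20.0       # Poisson mean of SCNA events at h = 0
    scna_heat_slope: float = -0.3      # log-linear h effect (negative: hot = quiet)
    repertoire_base_tcr: int = 800     # clonotypes at h = 0
    repertoire_base_bcr: int = 150
    repertoire_heat_slope: float = 150.0
    tcr_total_reads: int = 100_000
    hazard_log_hr: float = -0.5        # log hazard ratio per unit h (protective)
    exhaustion_axis_effect: float = 1.0   # loading of the exhaustion residual e on checkpoint markers
    exhaustion_hazard_log_hr: float = 0.6  # harmful log HR per unit e
    censor_rate: float = 0.6           # target fraction censored
    baseline_hazard: float = 0.00845   # per-month death rate (median ~82 months)
    til_logit_slope: float = 1.0
    time_decimals: int = 1             # follow-up resolution in months

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not 0.0 < self.censor_rate < 1.0:
            raise ConfigError("censor_rate must lie in (0, 1)")
        for name in ("scna_base_rate", "baseline_hazard", "tcr_total_reads"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("repertoire_base_tcr", "repertoire_base_bcr"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


def default_config(n_samples: int = 371, seed: int = 0, **overrides) -> SimConfig:
    """The standard study conditions: a protective immune-hot axis."""
    cfg = replace(SimConfig(), n_samples=n_samples, seed=seed, **overrides)
    cfg.validate()
    return cfg


def null_config(n_samples: int, seed: int) -> SimConfig:
    """All effect parameters zero: no planted structure of any kind."""
    cfg = replace(
        SimConfig(),
        n_samples=n_samples,
        seed=seed,
        heat_effect_expr=0.0,
        apobec_effect=0.0,
        checkpoint_effect=0.0,
        scna_heat_slope=0.0,
        repertoire_heat_slope=0.0,
        hazard_log_hr=0.0,
        exhaustion_axis_effect=0.0,
        exhaustion_hazard_log_hr=0.0,
        til_logit_slope=0.0,
    )
    cfg.validate()
    return cfg


@dataclass(frozen=True)
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: CohortTable
    segments: list[SegmentProfile]
    repertoire: list[RepertoireSummary]
    latent_heat: pd.Series = field(repr=False)
    latent_exhaustion: pd.Series = field(repr=False)


def _expression(rng, h, e, cfg, sample_ids):
    classes = [
        (list(CYT_GENES), BASELINE_LOG2["cyt"], cfg.heat_effect_expr, 0.0),
        (list(APOBEC3_PANEL.members), BASELINE_LOG2["apobec3"], cfg.apobec_effect, 0.0),
        (list(CHECKPOINT_PANEL.members), BASELINE_LOG2["checkpoint"],
         cfg.checkpoint_effect, cfg.exhaustion_axis_effect),
        (list(HLA_GENES), BASELINE_LOG2["hla"], cfg.heat_effect_expr, 0.0),
    ]
    decoys = [f"DECOY{i:04d}" for i in range(1, N_DECOY_GENES + 1)]
    decoy_baselines = rng.uniform(2.0, 8.0, size=N_DECOY_GENES)
    classes.append((decoys, decoy_baselines, 0.0, 0.0))

    rows, genes = [], []
    n = len(h)
    for members, baseline, effect, e_effect in classes:
        base = np.broadcast_to(np.atleast_1d(baseline), (len(members),))
        log2x = (
            base[:, None]
            + effect * h[None, :]
            + e_effect * e[None, :]
            + rng.normal(0.0, cfg.noise_sd, size=(len(members), n))
        )
        rows.append(np.maximum(np.exp2(log2x) - 1.0, 0.0))
        genes.extend(members)
    data = pd.DataFrame(np.vstack(rows), index=genes, columns=sample_ids)
    return ExpressionMatrix(data)


def _segments(rng, h, cfg, sample_ids):
    counts = rng.poisson(np.exp(np.log(cfg.scna_base_rate) + cfg.scna_heat_slope * h))
    totals = counts + NEUTRAL_SEGMENTS_PER_SAMPLE
    grand = int(totals.sum())
    chrom = rng.integers(1, 23, size=grand).astype(str)
    start = rng.integers(1, 100_000_000, size=grand)
    length = rng.integers(10_000, 5_000_000, size=grand)
    markers = rng.integers(10, 2000, size=grand)
    # within each sample block, the first `count` segments are the alterations
    means = np.empty(grand)
    offsets = np.concatenate([[0], np.cumsum(totals)])
    alt_mask = np.zeros(grand, dtype=bool)
    for i, k in enumerate(counts):
        alt_mask[offsets[i] : offsets[i] + int(k)] = True
    n_alt = int(alt_mask.sum())
    gains = rng.random(n_alt) < 0.5
    means[alt_mask] = np.where(
        gains, rng.uniform(0.6, 1.5, size=n_alt), rng.uniform(-1.5, -0.4, size=n_alt)
    )
    means[~alt_mask] = rng.uniform(-0.2, 0.2, size=grand - n_alt)
    table = pd.DataFrame(
        {
            "chromosome": chrom,
            "start": start,
            "end": start + length,
            "num_markers": markers,
            "segment_mean": means,
        }
    )
    return [
        SegmentProfile(
            sample_id=sid,
            segments=table.iloc[offsets[i] : offsets[i + 1]].reset_index(drop=True),
        )
        for i, sid in enumerate(sample_ids)
    ]


def _repertoire(rng, h, cfg, sample_ids):
    out = []
    for sid, hi in zip(sample_ids, h):
        tcr = max(0, cfg.repertoire_base_tcr + round(cfg.repertoire_heat_slope * hi))
        bcr_slope = (
            cfg.repertoire_heat_slope * cfg.repertoire_base_bcr / max(cfg.repertoire_base_tcr, 1)
        )
        bcr = max(0, cfg.repertoire_base_bcr + round(bcr_slope * hi))
        out.append(
            RepertoireSummary(
                sample_id=sid,
                tcr_unique_cdr3=min(tcr, cfg.tcr_total_reads),
                tcr_total_reads=cfg.tcr_total_reads,
                bcr_unique_clonotypes=bcr,
            )
        )
    return out


def _endpoint_pair(rng, h, e, cfg, baseline):
    hazard = baseline * np.exp(cfg.hazard_log_hr * h + cfg.exhaustion_hazard_log_hr * e)
    event_time = rng.exponential(1.0 / hazard)
    censor_hazard = baseline * cfg.censor_rate / (1.0 - cfg.censor_rate)
    censor_time = rng.exponential(1.0 / censor_hazard, size=len(h))
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return np.round(time, cfg.time_decimals), event


def _clinical(rng, h, e, cfg, sample_ids):
    n = len(h)
    df = pd.DataFrame({"sample_id": sample_ids})
    df["age"] = np.clip(np.round(rng.normal(59.5, 13.5, size=n), 1), 18.0, 95.0)
    for col, (levels, probs, miss) in CLINICAL_MARGINALS.items():
        values = rng.choice(levels, size=n, p=probs).astype(object)
        if miss > 0:
            values[rng.random(n) < miss] = np.nan
        df[col] = values
    p_til = 1.0 / (1.0 + np.exp(-cfg.til_logit_slope * h))
    df["til_status"] = np.where(rng.random(n) < p_til, "positive", "negative")
    for ep in ENDPOINTS:
        baseline = cfg.baseline_hazard * (2.0 if ep in ("PFI", "DFI") else 1.0)
        time, event = _endpoint_pair(rng, h, e, cfg, baseline)
        df[f"{ep}_time"] = time
        df[f"{ep}_event"] = event
    return CohortTable(df)


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one full synthetic cohort (expression, clinical, SCNA, repertoire).

    Each modality uses an independent child stream of the seed, so e.g. the
    clinical draws do not depend on how many segments were realized.
    """
    config.validate()
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    h = np.random.default_rng([config.seed, 0]).standard_normal(n)
    e = np.random.default_rng([config.seed, 5]).standard_normal(n)
    expr = _expression(np.random.default_rng([config.seed, 1]), h, e, config, sample_ids)
    segments = _segments(np.random.default_rng([config.seed, 2]), h, config, sample_ids)
    repertoire = _repertoire(np.random.default_rng([config.seed, 3]), h, config, sample_ids)
    clinical = _clinical(np.random.default_rng([config.seed, 4]), h, e, config, sample_ids)
    return SyntheticCohort(
        expression=expr,
        clinical=clinical,
        segments=segments,
        repertoire=repertoire,
        latent_heat=pd.Series(h, index=sample_ids, name="h"),
        latent_exhaustion=pd.Series(e, index=sample_ids, name="e"),
    )
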