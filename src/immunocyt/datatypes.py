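"""Domain containers for the pipeline.

All tabular state lives in pandas objects; the thin dataclass wrappers exist
to enforce invariants at construction time and to give each concept a name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    DuplicateKeyError,
    FormatError,
)

ENDPOINTS = ("OS", "DSS", "PFI", "DFI")

#: categorical levels accepted in clinical tables; anything else maps to missing
SEX_LEVELS = ("male", "female")
STAGE_LEVELS = ("I", "II", "III", "IV")
TIL_LEVELS = ("positive", "negative")
INFLAMMATION_LEVELS = ("none", "mild", "severe")
ETIOLOGY_LEVELS = ("none", "alcohol", "hepB", "hepC", "other")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of TPM (non-negative, within-sample normalized).

    ``data`` is indexed by gene symbol with sample ids as columns. Symbols and
    sample ids must be unique; every value must be >= 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DuplicateKeyError(f"duplicate gene symbol: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise DuplicateKeyError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        neg = np.argwhere(values < 0)
        if neg.size:
            g, s = neg[0]
            raise FormatError(
                f"negative TPM for gene {self.data.index[g]!r} "
                f"in sample {self.data.columns[s]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def tpm(self, gene: str, sample: str) -> float:
        return float(self.data.at[gene, sample])


@dataclass(frozen=True)
class CohortTable:
    """Per-sample clinical covariates plus four censored endpoint pairs.

    Columns: ``sample_id``, ``age``, ``sex``, ``stage``, ``til_status``,
    ``inflammation``, ``etiology`` and for each endpoint E in
    OS/DSS/PFI/DFI the pair ``E_time`` (months) / ``E_event`` (1 observed,
    0 censored). Missing values are NaN and are never imputed; samples with
    a missing endpoint are dropped per-analysis, not globally.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" not in df.columns:
            raise FormatError("clinical table lacks a sample_id column")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DuplicateKeyError(f"duplicate sample id: {dup!r}")
        for ep in ENDPOINTS:
            tcol, ecol = f"{ep}_time", f"{ep}_event"
            if tcol not in df.columns or ecol not in df.columns:
                continue
            t = df[tcol]
            if (t.dropna() < 0).any():
                bad = df.loc[t < 0, "sample_id"].iloc[0]
                raise FormatError(f"negative {ep} time for sample {bad!r}")
            orphan = t.notna() & df[ecol].isna()
            if orphan.any():
                bad = df.loc[orphan, "sample_id"].iloc[0]
                raise FormatError(
                    f"{ep} time present without event flag for sample {bad!r}"
                )
            # an event flag without a time is equally malformed
            orphan = df[ecol].notna() & t.isna()
            if orphan.any():
                bad = df.loc[orphan, "sample_id"].iloc[0]
                raise FormatError(
                    f"{ep} event flag present without time for sample {bad!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def endpoint(self, name: str) -> pd.DataFrame:
        """Return (sample_id, time, event) rows with both fields present."""
        if name not in ENDPOINTS:
            raise KeyError(f"unknown endpoint {name!r}; expected one of {ENDPOINTS}")
        sub = self.data[["sample_id", f"{name}_time", f"{name}_event"]].dropna()
        return sub.rename(
            columns={f"{name}_time": "time", f"{name}_event": "event"}
        ).reset_index(drop=True)


SEGMENT_COLUMNS = ("chromosome", "start", "end", "num_markers", "segment_mean")


@dataclass(frozen=True)
class SegmentProfile:
    """One sample's somatic copy-number segments (log2 ratios, 1-based inclusive)."""

    sample_id: str
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.segments
        missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"segment table lacks columns {missing}")
        if len(df):
            start = df["start"].to_numpy()
            end = df["end"].to_numpy()
            bad = np.flatnonzero(end < start)
            if bad.size:
                row = df.iloc[bad[0]]
                raise FormatError(
                    f"segment end < start for sample {self.sample_id!r} "
                    f"({row['chromosome']}:{int(row['start'])}-{int(row['end'])})"
                )
            if (df["num_markers"].to_numpy() <= 0).any():
                raise FormatError(
                    f"non-positive num_markers for sample {self.sample_id!r}"
                )

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class RepertoireSummary:
    """Per-sample TCR/BCR clonotype summary."""

    sample_id: str
    tcr_unique_cdr3: int
    tcr_total_reads: int
    bcr_unique_clonotypes: int

    def __post_init__(self) -> None:
        for name in ("tcr_unique_cdr3", "tcr_total_reads", "bcr_unique_clonotypes"):
            if getattr(self, name) < 0:
                raise FormatError(f"{name} must be non-negative")
        if self.tcr_total_reads > 0 and self.tcr_unique_cdr3 > self.tcr_total_reads:
            raise FormatError(
                f"sample {self.sample_id!r}: unique CDR3 clonotypes "
                f"({self.tcr_unique_cdr3}) exceed total TCR reads "
                f"({self.tcr_total_reads})"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (non-empty)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ScoreFrame:
    """Per-sample derived immune scores plus dichotomization labels.

    ``data`` is indexed by sample id with score columns (cyt, apobec3,
    checkpoint_index, hla_a, hla_b, scna_events, tcr_richness, bcr_richness,
    cpk) and one ``<score>_group`` column ('high'/'low') per dichotomized
    score. ``provenance`` records panels, pseudocounts and log base so every
    serialized frame is self-describing.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise DuplicateKeyError("duplicate sample id in score frame")
        if len(self.data) < 1:
            raise DegenerateInputError("score frame needs at least one sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def groups(self, score: str) -> pd.Series:
        col = f"{score}_group"
        if col not in self.data.columns:
            raise KeyError(f"score {score!r} was not dichotomized")
        return self.data[col]
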