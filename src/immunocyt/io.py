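"""Readers and writers for every external format the pipeline touches.

Dialects: expression as TSV with genes in rows; copy-number segments in the
TCGA SEG dialect (sample, chrom, loc.start, loc.end, num.mark, seg.mean;
1-based inclusive coordinates); gene sets as GMT; clinical and repertoire
tables as TSV with declared headers. Writers are deterministic: the same
object always serializes to the same bytes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ENDPOINTS,
    ETIOLOGY_LEVELS,
    INFLAMMATION_LEVELS,
    SEX_LEVELS,
    STAGE_LEVELS,
    TIL_LEVELS,
    CohortTable,
    ExpressionMatrix,
    GeneSet,
    RepertoireSummary,
    SegmentProfile,
)
from .errors import DuplicateKeyError, FormatError, ParseError

log = logging.getLogger(__name__)

SEG_HEADER = ("sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean")
_SEG_RENAME = {
    "sample": "sample_id",
    "chrom": "chromosome",
    "chromosome": "chromosome",
    "loc.start": "start",
    "start": "start",
    "loc.end": "end",
    "end": "end",
    "num.mark": "num_markers",
    "num_markers": "num_markers",
    "seg.mean": "segment_mean",
    "segment_mean": "segment_mean",
}

#: maps clinical TSV headers to CohortTable fields; extend rather than rename
CLINICAL_COLUMNS = {
    "sample_id": "sample_id",
    "age": "age",
    "sex": "sex",
    "stage": "stage",
    "til_status": "til_status",
    "inflammation": "inflammation",
    "etiology": "etiology",
    **{f"{ep}_{k}": f"{ep}_{k}" for ep in ENDPOINTS for k in ("time", "event")},
}

_CATEGORY_LEVELS = {
    "sex": SEX_LEVELS,
    "stage": STAGE_LEVELS,
    "til_status": TIL_LEVELS,
    "inflammation": INFLAMMATION_LEVELS,
    "etiology": ETIOLOGY_LEVELS,
}


def _numeric_or_parse_error(col: pd.Series, path: Path, what: str) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    bad = out.isna() & col.notna() & (col.astype(str).str.strip() != "")
    if bad.any():
        pos = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric {what} {col.iloc[pos]!r} on data line {pos + 1}"
        )
    return out


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes-in-rows TPM matrix from tab-separated text."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise DuplicateKeyError(f"{path}: duplicate gene symbol {dup!r}")
    numeric = {}
    for sample in raw.columns:
        numeric[sample] = _numeric_or_parse_error(
            raw[sample], path, f"expression value in sample {sample!r}"
        )
    df = pd.DataFrame(numeric, index=raw.index).astype(float)
    df.index.name = None  # writers label the gene column explicitly
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")


def read_segments(path: str | Path) -> list[SegmentProfile]:
    """Read a SEG-style table into one profile per distinct sample.

    Samples with zero rows are absent from the result; callers needing empty
    profiles construct them explicitly.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [_SEG_RENAME.get(c.strip().lower(), c) for c in raw.columns]
    required = {"sample_id", "chromosome", "start", "end", "num_markers", "segment_mean"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: SEG file lacks columns {sorted(missing)}")
    if raw.empty:
        return []
    for col in ("start", "end", "num_markers", "segment_mean"):
        raw[col] = _numeric_or_parse_error(raw[col], path, col)
    raw[["start", "end", "num_markers"]] = raw[["start", "end", "num_markers"]].astype(int)
    bad = raw["end"] < raw["start"]
    if bad.any():
        pos = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"{path}: end < start on data line {pos + 1}")
    profiles = []
    for sample_id, group in raw.groupby("sample_id", sort=False):
        profiles.append(
            SegmentProfile(
                sample_id=str(sample_id),
                segments=group.drop(columns="sample_id").reset_index(drop=True),
            )
        )
    return profiles


def write_segments(profiles: list[SegmentProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        block = p.segments.copy()
        block.insert(0, "sample_id", p.sample_id)
        rows.append(block)
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=["sample_id", "chromosome", "start", "end", "num_markers", "segment_mean"]
        )
    table.columns = SEG_HEADER[:1] + ("chrom", "loc.start", "loc.end", "num.mark", "seg.mean")
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one set per line, tab-separated name, description, members."""
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT needs name, description and at least one member"
                )
            name, description = fields[0], fields[1]
            if name in seen:
                raise DuplicateKeyError(f"{path}: duplicate gene set name {name!r}")
            seen.add(name)
            members = frozenset(m for m in fields[2:] if m.strip())
            if not members:
                raise ParseError(f"{path}: line {lineno} ({name!r}) has no members")
            sets.append(GeneSet(name=name, description=description, members=members))
    return sets


def write_gene_sets(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def read_clinical(path: str | Path) -> CohortTable:
    """Read a clinical TSV using the declared column dictionary.

    Unknown categorical levels map to missing with a logged warning; missing
    counts per column are logged at INFO level. A missing sample_id column is
    fatal.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [c.strip() for c in raw.columns]
    if "sample_id" not in raw.columns:
        raise FormatError(f"{path}: clinical table lacks a sample_id column")
    known = [c for c in raw.columns if c in CLINICAL_COLUMNS]
    df = raw[known].rename(columns=CLINICAL_COLUMNS).copy()

    if "age" in df.columns:
        df["age"] = _numeric_or_parse_error(df["age"], path, "age")
    for col, levels in _CATEGORY_LEVELS.items():
        if col not in df.columns:
            continue
        values = df[col].str.strip()
        unknown = values.notna() & ~values.isin(levels)
        if unknown.any():
            log.warning(
                "%s: %d unknown %s value(s) (e.g. %r) mapped to missing",
                path, int(unknown.sum()), col, values[unknown].iloc[0],
            )
        df[col] = values.where(values.isin(levels))
    for ep in ENDPOINTS:
        for kind in ("time", "event"):
            col = f"{ep}_{kind}"
            if col in df.columns:
                df[col] = _numeric_or_parse_error(df[col], path, col)
    for col in df.columns:
        n_missing = int(df[col].isna().sum())
        if n_missing:
            log.info("%s: column %s has %d missing value(s)", path, col, n_missing)
    return CohortTable(df.reset_index(drop=True))


def write_clinical(cohort: CohortTable, path: str | Path) -> None:
    cohort.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_repertoire(path: str | Path) -> list[RepertoireSummary]:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tcr_unique_cdr3", "tcr_total_reads", "bcr_unique_clonotypes"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: repertoire table lacks columns {sorted(missing)}")
    out = []
    for col in sorted(required - {"sample_id"}):
        raw[col] = _numeric_or_parse_error(raw[col], path, col).astype(int)
    for row in raw.itertuples(index=False):
        out.append(
            RepertoireSummary(
                sample_id=str(row.sample_id),
                tcr_unique_cdr3=int(row.tcr_unique_cdr3),
                tcr_total_reads=int(row.tcr_total_reads),
                bcr_unique_clonotypes=int(row.bcr_unique_clonotypes),
            )
        )
    return out


def write_repertoire(summaries: list[RepertoireSummary], path: str | Path) -> None:
    table = pd.DataFrame(
        [
            (r.sample_id, r.tcr_unique_cdr3, r.tcr_total_reads, r.bcr_unique_clonotypes)
            for r in summaries
        ],
        columns=["sample_id", "tcr_unique_cdr3", "tcr_total_reads", "bcr_unique_clonotypes"],
    )
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_score_frame(frame, path: str | Path) -> None:
    """Serialize a ScoreFrame as TSV with a commented provenance header."""
    with open(path, "w") as fh:
        for key in sorted(frame.provenance):
            fh.write(f"# {key}: {frame.provenance[key]}\n")
        frame.data.to_csv(fh, sep="\t", index_label="sample_id", lineterminator="\n")


def read_score_frame(path: str | Path):
    from .datatypes import ScoreFrame

    provenance = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# "):
            key, _, value = line[2:].rstrip("\n").partition(": ")
            provenance[key] = value
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col="sample_id")
    return ScoreFrame(df, provenance)
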