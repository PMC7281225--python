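"""Copy-number event counting and TCR/BCR repertoire metrics.

An SCNA event is a copy-number segment whose log2 segment mean reaches +0.6
(gain) or −0.4 (loss), boundaries inclusive; the per-sample burden is the
count of qualifying segments. Summing |segment mean| over qualifying segments
is available as an alternate mode but is never the default. Repertoire
diversity is reported as clonotypes per kilo-reads (CPK): unique CDR3
clonotypes per 1000 TCR-region reads.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datatypes import RepertoireSummary, SegmentProfile
from .errors import ConfigError, UndefinedDiversityError


@dataclass(frozen=True)
class ScnaThresholds:
    gain_min: float = 0.6
    loss_max: float = -0.4

    def __post_init__(self) -> None:
        if not (self.gain_min > 0 > self.loss_max):
            raise ConfigError(
                f"need gain_min > 0 > loss_max, got ({self.gain_min}, {self.loss_max})"
            )


def scna_event_count(
    profile: SegmentProfile,
    thresholds: ScnaThresholds | None = None,
    mode: str = "count",
) -> float:
    """Number of segments beyond the gain/loss thresholds (inclusive).

    ``mode='sum_magnitude'`` instead sums |segment_mean| over qualifying
    segments.
    """
    thr = thresholds or ScnaThresholds()
    if mode not in ("count", "sum_magnitude"):
        raise ConfigError(f"unknown SCNA mode {mode!r}")
    if len(profile) == 0:
        return 0 if mode == "count" else 0.0
    means = profile.segments["segment_mean"]
    hit = (means >= thr.gain_min) | (means <= thr.loss_max)
    if mode == "count":
        return int(hit.sum())
    return float(means[hit].abs().sum())


def tcr_richness(rep: RepertoireSummary) -> int:
    """Distinct TCR CDR3 clonotypes detected in the sample."""
    return rep.tcr_unique_cdr3


def bcr_richness(rep: RepertoireSummary) -> int:
    """Distinct BCR clonotypes detected in the sample."""
    return rep.bcr_unique_clonotypes


def cpk_diversity(rep: RepertoireSummary) -> float:
    """Clonotypes per kilo-reads: 1000 * unique CDR3 / total TCR reads."""
    if rep.tcr_total_reads == 0:
        raise UndefinedDiversityError(
            f"sample {rep.sample_id!r}: CPK undefined with zero TCR reads"
        )
    return 1000.0 * rep.tcr_unique_cdr3 / rep.tcr_total_reads
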