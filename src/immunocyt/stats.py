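"""Two-group comparison tests: Mann-Whitney U and Pearson chi-square.

Mann-Whitney uses full enumeration of group assignments for combined sizes
up to 12 (exact two-sided p) and otherwise a tie-corrected normal
approximation with continuity correction. Chi-square is the Pearson r x c
statistic without continuity correction, as used for contingency-table
comparisons of clinical categories between score-high and score-low groups.
All p-values are two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ScoreFrame
from .errors import DegenerateInputError

log = logging.getLogger(__name__)

EXACT_LIMIT = 12  # combined sample size at or below which 'auto' enumerates


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    feature: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 * #ties, via midranks."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided p by enumerating every assignment of the pooled values."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    mu = n1 * (n - n1) / 2.0
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    idx = np.arange(n)
    for chosen in combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(chosen)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if abs(u - mu) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def _normal_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Normal approximation with tie-corrected variance and continuity correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return 1.0
    diff = u_obs - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    return min(1.0, 2.0 * sps.norm.sf(abs(z)))


def mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode``: 'exact' enumerates all C(n, n_x) group assignments, 'normal'
    uses the tie-corrected Gaussian approximation, 'auto' picks exact when
    n_x + n_y <= 12.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise DegenerateInputError("Mann-Whitney needs both groups non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    u = _u_statistic(x, y)
    use_exact = mode == "exact" or (mode == "auto" and len(x) + len(y) <= EXACT_LIMIT)
    if use_exact:
        p = _exact_p(x, y, u)
        method = "mwu_exact"
    else:
        p = _normal_p(x, y, u)
        method = "mwu_normal"
    return TestResult(statistic=u, p_value=p, method=method, n_per_group=(len(x), len(y)))


def chi_square_test(table) -> TestResult:
    """Pearson chi-square on an r x c contingency table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateInputError("contingency table must be at least 2 x 2")
    if (obs < 0).any():
        raise DegenerateInputError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise DegenerateInputError("chi-square undefined with a zero marginal")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult(
        statistic=stat,
        p_value=p,
        method="chi_square",
        n_per_group=tuple(int(r) for r in row),
        extras={"df": df},
    )


def compare_groups(
    frame: ScoreFrame,
    group_by: str = "cyt",
    features: list[str] | None = None,
    mode: str = "auto",
) -> list[TestResult]:
    """Compare features between the high and low groups of a dichotomized score.

    Numeric features get Mann-Whitney; categorical (object dtype) features get
    chi-square on their level x group contingency table. Missing values are
    dropped pairwise per feature; an all-missing feature is skipped with a
    warning.
    """
    labels = frame.groups(group_by)
    data = frame.data
    if features is None:
        features = [
            c for c in data.columns
            if not c.endswith("_group") and c != group_by
        ]
    results: list[TestResult] = []
    for feat in features:
        if feat not in data.columns:
            raise KeyError(f"unknown feature {feat!r}")
        col = data[feat]
        keep = col.notna() & labels.notna()
        if not keep.any():
            log.warning("feature %s has no non-missing values; skipped", feat)
            continue
        sub, lab = col[keep], labels[keep]
        if pd.api.types.is_numeric_dtype(sub):
            res = mann_whitney(sub[lab == "high"], sub[lab == "low"], mode=mode)
        else:
            table = pd.crosstab(sub, lab)
            res = chi_square_test(table.to_numpy())
        results.append(
            TestResult(
                statistic=res.statistic,
                p_value=res.p_value,
                method=res.method,
                n_per_group=res.n_per_group,
                feature=feat,
                extras=res.extras,
            )
        )
    return results


def results_table(results: list[TestResult]) -> pd.DataFrame:
    """Flatten TestResults to the TSV-ready layout (feature, statistic, p, ...)."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "statistic": r.statistic,
                "p_value": float(f"{r.p_value:.3g}"),
                "method": r.method,
                "n_per_group": "/".join(str(n) for n in r.n_per_group),
            }
            for r in results
        ]
    )
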