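"""Gene-set enrichment by the weighted Kolmogorov-Smirnov running sum.

Genes are ranked by the signal-to-noise metric between two phenotype groups
(difference of group means over sum of group standard deviations, computed
on log2(TPM+1), with each standard deviation floored to avoid exploding
ratios for near-constant genes). Walking down the ranked list, set members
("hits") increment a running sum by their |metric|^weight share and
non-members decrement it by 1/(N - N_hits); the enrichment score (ES) is the
signed extremum of the walk. Significance comes from a permutation null —
either random same-size gene sets or phenotype-label shuffles with
re-ranking — with the ES normalized (NES) by the mean |null ES| of matching
sign and the FDR estimated by the classic ratio-of-tails over the pooled
normalized null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet
from .errors import ConfigError, DegenerateInputError, NoOverlapError

log = logging.getLogger(__name__)

DEFAULT_WEIGHT = 1.0
MIN_PERMUTATIONS = 100
PHENOTYPE_MIN_GROUP = 7  # below this per-group size, fall back to gene_set nulls


@dataclass(frozen=True)
class RankedList:
    """Genes sorted by descending ranking metric (ties broken by symbol)."""

    genes: np.ndarray   # unique symbols, descending metric order
    metric: np.ndarray  # per-gene signal-to-noise, same order

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise DegenerateInputError("ranked list contains duplicate genes")
        if np.any(np.diff(self.metric) > 1e-12):
            raise DegenerateInputError("ranking metric must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: tuple[str, ...]
    n_permutations: int
    perm_mode: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.es <= 1.0 + 1e-9:
            raise ValueError(f"ES {self.es} outside [-1, 1]")


def rank_genes(
    expr: ExpressionMatrix,
    groups: pd.Series,
    min_sd: float = 1e-3,
) -> RankedList:
    """Signal-to-noise ranking of all genes between 'high' and 'low' samples.

    The metric is (mean_high - mean_low) / (sd_high + sd_low) on
    log2(TPM + 1); each group's sd is floored at max(min_sd, 0.2 * |group
    mean|). Ties are broken lexicographically by gene symbol so the ordering
    is deterministic.
    """
    groups = groups.dropna()
    high = groups.index[groups == "high"]
    low = groups.index[groups == "low"]
    if len(high) < 2 or len(low) < 2:
        raise DegenerateInputError("each phenotype group needs at least 2 samples")
    logx = np.log2(expr.data.to_numpy(dtype=float) + 1.0)
    cols = pd.Index(expr.samples)
    hi_idx = cols.get_indexer(high)
    lo_idx = cols.get_indexer(low)
    metric = _signal_to_noise(logx, hi_idx, lo_idx, min_sd)
    genes = np.asarray(expr.genes)
    # descending metric; lexicographic symbol order inside ties
    order = np.lexsort((genes, -metric))
    return RankedList(genes=genes[order], metric=metric[order])


def _signal_to_noise(logx, hi_idx, lo_idx, min_sd):
    mu_h = logx[:, hi_idx].mean(axis=1)
    mu_l = logx[:, lo_idx].mean(axis=1)
    sd_h = logx[:, hi_idx].std(axis=1, ddof=1)
    sd_l = logx[:, lo_idx].std(axis=1, ddof=1)
    sd_h = np.maximum(sd_h, np.maximum(min_sd, 0.2 * np.abs(mu_h)))
    sd_l = np.maximum(sd_l, np.maximum(min_sd, 0.2 * np.abs(mu_l)))
    return (mu_h - mu_l) / (sd_h + sd_l)


def _es_from_hits(metric: np.ndarray, hit_mask: np.ndarray, weight: float):
    """Running-sum walk; returns (es, extremum index, running sum)."""
    n = len(metric)
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        # all-hits: the walk climbs to exactly 1 with no miss decrements
        if n_hits == n:
            increments = np.abs(metric) ** weight
            total = increments.sum()
            if total == 0:
                increments = np.ones(n)
                total = float(n)
            running = np.cumsum(increments / total)
            return 1.0, n - 1, running
        raise NoOverlapError("gene set has no overlap with the ranked list")
    increments = np.zeros(n)
    hit_weights = np.abs(metric[hit_mask]) ** weight
    total = hit_weights.sum()
    if total == 0:  # degenerate all-zero metric: fall back to unweighted hits
        hit_weights = np.ones(n_hits)
        total = float(n_hits)
    increments[hit_mask] = hit_weights / total
    increments[~hit_mask] = -1.0 / (n - n_hits)
    running = np.cumsum(increments)
    extremum = int(np.argmax(np.abs(running)))
    # cumsum rounding can overshoot the mathematical bounds by ~1 ulp
    es = float(np.clip(running[extremum], -1.0, 1.0))
    return es, extremum, running


def enrichment_score(
    ranked: RankedList,
    gene_set: GeneSet,
    weight: float = DEFAULT_WEIGHT,
):
    """ES, full running sum and leading edge of one set against a ranking.

    The leading edge is the set members at or before the extremum for a
    positive ES, and at or after it for a negative ES. Members absent from
    the ranked list are dropped (count logged).
    """
    members = gene_set.members & set(ranked.genes)
    dropped = len(gene_set.members) - len(members)
    if dropped:
        log.info("gene set %s: %d member(s) absent from ranking dropped",
                 gene_set.name, dropped)
    if not members:
        raise NoOverlapError(
            f"gene set {gene_set.name!r} has no overlap with the ranked list"
        )
    hit_mask = np.isin(ranked.genes, list(members))
    es, extremum, running = _es_from_hits(ranked.metric, hit_mask, weight)
    if es >= 0:
        lead_mask = hit_mask & (np.arange(len(ranked)) <= extremum)
    else:
        lead_mask = hit_mask & (np.arange(len(ranked)) >= extremum)
    leading_edge = tuple(ranked.genes[lead_mask])
    return es, running, leading_edge


def _null_es_gene_set(ranked, set_size, n_perm, weight, rng):
    n = len(ranked)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        hit_mask = np.zeros(n, dtype=bool)
        hit_mask[rng.choice(n, size=set_size, replace=False)] = True
        nulls[i], _, _ = _es_from_hits(ranked.metric, hit_mask, weight)
    return nulls


def _null_es_phenotype(expr, groups, members, n_perm, weight, min_sd, rng):
    groups = groups.dropna()
    labels = groups.to_numpy().copy()
    cols = pd.Index(expr.samples)
    idx = cols.get_indexer(groups.index)
    logx = np.log2(expr.data.to_numpy(dtype=float) + 1.0)
    genes = np.asarray(expr.genes)
    member_mask_by_gene = np.isin(genes, list(members))
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        rng.shuffle(labels)
        hi = idx[labels == "high"]
        lo = idx[labels == "low"]
        metric = _signal_to_noise(logx, hi, lo, min_sd)
        order = np.lexsort((genes, -metric))
        nulls[i], _, _ = _es_from_hits(metric[order], member_mask_by_gene[order], weight)
    return nulls


def _nes(es: float, nulls: np.ndarray) -> float:
    same_sign = nulls[np.sign(nulls) == np.sign(es)] if es != 0 else nulls
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(nulls).mean()
    return float(es / denom) if denom > 0 else 0.0


def _nominal_p(es: float, nulls: np.ndarray) -> float:
    if es == 0:
        return 1.0
    same_sign = nulls[np.sign(nulls) == np.sign(es)]
    extreme = int((np.abs(same_sign) >= abs(es) - 1e-15).sum())
    return (1 + extreme) / (1 + len(same_sign))


def normalize_and_test(
    es_observed: float,
    ranked: RankedList,
    gene_set: GeneSet,
    n_perm: int = 1000,
    perm_mode: str = "auto",
    seed: int = 0,
    weight: float = DEFAULT_WEIGHT,
    expr: ExpressionMatrix | None = None,
    groups: pd.Series | None = None,
    min_sd: float = 1e-3,
    leading_edge: tuple[str, ...] = (),
    return_nulls: bool = False,
):
    """Permutation NES, nominal p and (single-set) FDR for one observed ES.

    ``perm_mode='gene_set'`` draws random member sets of equal size from the
    ranked genes; ``'phenotype'`` shuffles the group labels and re-ranks
    (requires ``expr`` and ``groups``); ``'auto'`` picks phenotype when both
    groups have at least 7 samples, following common practice for the
    weighted statistic. The nominal p is the add-one-corrected fraction of
    same-sign null ES at least as extreme.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ConfigError(f"need at least {MIN_PERMUTATIONS} permutations, got {n_perm}")
    members = gene_set.members & set(ranked.genes)
    if not members:
        raise NoOverlapError(f"gene set {gene_set.name!r} has no ranked members")
    mode = perm_mode
    if mode == "auto":
        if groups is not None:
            counts = groups.value_counts()
            big_enough = all(counts.get(g, 0) >= PHENOTYPE_MIN_GROUP for g in ("high", "low"))
            mode = "phenotype" if big_enough and expr is not None else "gene_set"
        else:
            mode = "gene_set"
    rng = np.random.default_rng(seed)
    if mode == "gene_set":
        nulls = _null_es_gene_set(ranked, len(members), n_perm, weight, rng)
    elif mode == "phenotype":
        if expr is None or groups is None:
            raise ConfigError("phenotype permutations need expr and groups")
        nulls = _null_es_phenotype(expr, groups, members, n_perm, weight, min_sd, rng)
    else:
        raise ConfigError(f"unknown permutation mode {perm_mode!r}")
    nes = _nes(es_observed, nulls)
    p = _nominal_p(es_observed, nulls)
    # single-set FDR: the pooled-null estimator degenerates to the tail ratio
    null_nes = np.array([_nes(e, nulls) for e in nulls])
    q = _fdr_from_pool(np.array([nes]), null_nes)[0]
    result = GseaResult(
        set_name=gene_set.name,
        es=float(es_observed),
        nes=nes,
        nominal_p=p,
        fdr_q=q,
        leading_edge=tuple(leading_edge),
        n_permutations=n_perm,
        perm_mode=mode,
    )
    if return_nulls:
        return result, null_nes
    return result


def _fdr_from_pool(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Ratio-of-tails FDR over pooled normalized null scores."""
    qs = np.empty(len(obs_nes))
    for i, nes in enumerate(obs_nes):
        if nes >= 0:
            null_tail = (null_nes >= nes).sum() / max((null_nes >= 0).sum(), 1)
            obs_tail = (obs_nes >= nes).sum() / max((obs_nes >= 0).sum(), 1)
        else:
            null_tail = (null_nes <= nes).sum() / max((null_nes < 0).sum(), 1)
            obs_tail = (obs_nes <= nes).sum() / max((obs_nes < 0).sum(), 1)
        qs[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
    return qs


def gsea_collection(
    expr: ExpressionMatrix,
    groups: pd.Series,
    gene_sets: list[GeneSet],
    n_perm: int = 1000,
    perm_mode: str = "auto",
    weight: float = DEFAULT_WEIGHT,
    seed: int = 0,
    min_sd: float = 1e-3,
) -> list[GseaResult]:
    """Run the full engine over a gene-set collection with a shared null pool.

    The FDR q for each set uses the classic pooled estimator: every set's
    permutation null is normalized and pooled, and q is the ratio of the null
    tail to the observed tail beyond each set's NES.
    """
    ranked = rank_genes(expr, groups, min_sd=min_sd)
    results = []
    all_null_nes = []
    obs_nes = []
    rng = np.random.default_rng(seed)
    for gs in gene_sets:
        try:
            es, _, lead = enrichment_score(ranked, gs, weight)
        except NoOverlapError:
            log.warning("gene set %s skipped: no overlap with ranking", gs.name)
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res, null_nes = normalize_and_test(
            es, ranked, gs, n_perm=n_perm, perm_mode=perm_mode, seed=sub_seed,
            weight=weight, expr=expr, groups=groups, min_sd=min_sd,
            leading_edge=lead, return_nulls=True,
        )
        all_null_nes.append(null_nes)
        obs_nes.append(res.nes)
        results.append(res)
    if results:
        qs = _fdr_from_pool(np.array(obs_nes), np.concatenate(all_null_nes))
        results = [
            GseaResult(
                set_name=r.set_name, es=r.es, nes=r.nes, nominal_p=r.nominal_p,
                fdr_q=float(q), leading_edge=r.leading_edge,
                n_permutations=r.n_permutations, perm_mode=r.perm_mode,
            )
            for r, q in zip(results, qs)
        ]
    return results


def gsea_table(results: list[GseaResult]) -> pd.DataFrame:
    """TSV-ready layout mirroring standard GSEA reports."""
    return pd.DataFrame(
        [
            {
                "gene_set": r.set_name,
                "es": r.es,
                "nes": r.nes,
                "p_value": float(f"{r.nominal_p:.3g}"),
                "fdr_q": float(f"{r.fdr_q:.3g}"),
                "n_permutations": r.n_permutations,
                "perm_mode": r.perm_mode,
                "leading_edge": ",".join(r.leading_edge),
            }
            for r in results
        ]
    )
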