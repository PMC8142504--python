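"""Differential expression between subtypes and preranked GSEA.

DEGs are called with a Mann-Whitney test on log2(CPM+1) plus a mean-CPM
fold change, flagged by the joint thresholds p < 0.01, BH-FDR < 0.05 and
|log2FC| > 1. Preranked GSEA uses the weighted running-sum statistic with
a gene-set permutation null and a sign-stratified FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection, log2cpm, cpm


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    expr: ExpressionMatrix,
    labels: pd.Series,
    p_thresh: float = 0.01,
    fdr_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
) -> pd.DataFrame:
    """Differential expression of sub1 vs sub2.

    Returns a per-gene table with log2FC (log2 of the ratio of group mean
    CPM, pseudocount 1), two-sided Mann-Whitney p on log2(CPM+1), BH FDR,
    and the is_deg flag (p < p_thresh AND FDR < fdr_thresh AND
    |log2FC| > lfc_thresh).
    """
    labels = pd.Series(labels).astype(str)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("call_degs requires exactly two groups")
    g1, g2 = groups
    s1 = labels.index[labels == g1]
    s2 = labels.index[labels == g2]
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError("each group needs n >= 3")
    lin = cpm(expr) if expr.unit == "raw_counts" else expr.values
    logv = log2cpm(expr)
    m1 = lin[s1].mean(axis=1)
    m2 = lin[s2].mean(axis=1)
    log2fc = np.log2((m1 + 1.0) / (m2 + 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            logv[s1].to_numpy(), logv[s2].to_numpy(), axis=1,
            alternative="two-sided", method="asymptotic", use_continuity=True,
        )
    p = np.asarray(res.pvalue, dtype=float)
    p[np.isnan(p)] = 1.0  # constant genes
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr}, index=expr.values.index
    )
    table["is_deg"] = (
        (table["p"] < p_thresh)
        & (table["fdr"] < fdr_thresh)
        & (table["log2fc"].abs() > lfc_thresh)
    )
    return table


def rank_by_logfc(deg_table: pd.DataFrame) -> pd.Series:
    """Ranking metric for preranked GSEA: log2FC descending, ties by gene id."""
    order = np.lexsort((deg_table.index.to_numpy(), -deg_table["log2fc"].to_numpy()))
    return deg_table["log2fc"].iloc[order]


@dataclass
class GseaResult:
    table: pd.DataFrame           # per set: es, nes, p, fdr, size, leading_edge
    n_permutations: int
    seed: int


def _es_walk(in_set: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """Signed max deviation of the GSEA running sum and its position.

    ``in_set`` marks hit positions in ranking order; ``weights`` are the
    |score|^w values used for hits.
    """
    n = in_set.size
    n_hit = int(in_set.sum())
    w = np.where(in_set, weights, 0.0)
    tot = w.sum()
    if tot == 0:  # degenerate all-zero scores: fall back to unweighted hits
        w = in_set.astype(float)
        tot = w.sum()
    run = np.cumsum(w / tot - (~in_set) / (n - n_hit))
    imax = int(np.argmax(run))
    imin = int(np.argmin(run))
    if run[imax] >= -run[imin]:
        return float(run[imax]), imax
    return float(run[imin]), imin


def _null_es(rng, n: int, n_hit: int, weights: np.ndarray, n_perm: int) -> np.ndarray:
    """Gene-set permutation null: ES of random same-size sets (vectorised)."""
    out = np.empty(n_perm)
    inv = 1.0 / (n - n_hit)
    for b in range(n_perm):
        pos = rng.choice(n, size=n_hit, replace=False)
        pos.sort()
        w = weights[pos]
        cw = np.cumsum(w) / w.sum()
        # running sum just after each hit, and just before each hit
        after = cw - (pos + 1 - np.arange(1, n_hit + 1)) * inv
        before = np.concatenate(([0.0], cw[:-1])) - (pos - np.arange(n_hit)) * inv
        hi = after.max()
        lo = before.min()
        out[b] = hi if hi >= -lo else lo
    return out


def preranked_gsea(
    ranking: pd.Series,
    gene_sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = 5,
) -> GseaResult:
    """Preranked GSEA with a gene-set permutation null.

    ``ranking`` maps gene -> score; genes are ordered by score descending
    (ties broken by gene id). ES is the signed maximum deviation of the
    weighted running sum; NES divides ES by the mean |null ES| of matching
    sign; nominal p uses the same-sign null with add-one correction; the
    FDR q is the sign-stratified null/observed tail-ratio.
    """
    if ranking.index.duplicated().any():
        raise ValueError("duplicate genes in ranking")
    order = np.lexsort((ranking.index.to_numpy(), -ranking.to_numpy()))
    genes = ranking.index.to_numpy()[order]
    scores = ranking.to_numpy(dtype=float)[order]
    n = len(genes)
    weights = np.abs(scores) ** weight
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    null_by_size: dict[int, np.ndarray] = {}
    for name in sorted(gene_sets.names()):
        members = [g for g in gene_sets[name] if g in gene_pos]
        if len(members) < min_overlap:
            warnings.warn(f"set {name!r}: overlap {len(members)} < {min_overlap}; "
                          "skipped", stacklevel=2)
            continue
        in_set = np.zeros(n, dtype=bool)
        in_set[[gene_pos[g] for g in members]] = True
        es, ipeak = _es_walk(in_set, weights)
        if len(members) not in null_by_size:
            null_by_size[len(members)] = _null_es(rng, n, len(members), weights, n_perm)
        null = null_by_size[len(members)]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        denom = np.abs(same_sign).mean() if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
        if es >= 0:
            leading = [g for g in genes[: ipeak + 1] if g in set(members)]
        else:
            leading = [g for g in genes[ipeak:] if g in set(members)]
        rows.append((name, es, nes, p, len(members), ",".join(leading)))
    table = pd.DataFrame(
        rows, columns=["set", "es", "nes", "p", "size", "leading_edge"]
    ).set_index("set")

    # sign-stratified FDR: compare each observed NES against the pooled
    # null NES of matching sign across all set sizes
    null_nes = []
    for size, null in null_by_size.items():
        pos, neg = null[null >= 0], null[null < 0]
        pmean = pos.mean() if pos.size else np.nan
        nmean = np.abs(neg).mean() if neg.size else np.nan
        scaled = np.where(null >= 0,
                          null / pmean if pmean else np.nan,
                          null / nmean if nmean else np.nan)
        null_nes.append(scaled)
    null_nes = np.concatenate(null_nes) if null_nes else np.array([])
    q = []
    obs = table["nes"].to_numpy()
    for nes in obs:
        if nes >= 0:
            null_tail = np.mean(null_nes >= nes) if null_nes.size else 1.0
            obs_tail = np.mean(obs >= nes)
        else:
            null_tail = np.mean(null_nes <= nes) if null_nes.size else 1.0
            obs_tail = np.mean(obs <= nes)
        q.append(min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0)
    table["fdr"] = q
    table = table.sort_values(["fdr", "nes"], key=lambda s: s.abs() if s.name == "nes"
                              else s, ascending=[True, False])
    return GseaResult(table=table, n_permutations=n_perm, seed=seed)
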