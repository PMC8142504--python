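"""Single-sample enrichment (ssGSEA) and the formula-defined immune scores.

Covers: stromal/immune/ESTIMATE, 28-cell-type NES, the immune (IIS) and
T-cell (TIS) infiltration scores, cytolytic activity (CYT), the
antigen-processing-machinery (APM) score, tumor mutational burden (TMB),
and the checkpoint / interferon-gamma / CD8 expression signatures, plus
the Wilcoxon group test and the strong-correlation rule used to compare
them between subtypes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSetCollection, MafTable, cpm

#: 18-gene antigen processing and presenting machinery signature.
APM_GENES = [
    "HLA-A", "HLA-B", "HLA-C", "TAP1", "TAP2", "TAPBP", "ERAP1", "ERAP2",
    "CANX", "CALR", "B2M", "PDIA3", "PSMB5", "PSMB6", "PSMB7", "PSMB8",
    "PSMB9", "PSMB10",
]

#: Immune-checkpoint signature. The common reading of the checkpoint gene
#: list (HAVCR2 + LAG3); the literal variant with HAVCR/LA3 is available
#: via ``checkpoint_genes(literal=True)``.
CHECKPOINT_GENES = ["CD274", "CTLA4", "HAVCR2", "LAG3", "PDCD1", "PDCD1LG2"]
CHECKPOINT_GENES_LITERAL = ["CD274", "CTLA4", "HAVCR", "LA3", "PDCD1", "PDCD1LG2"]

INFG_GENES = ["CXCL10", "CXCL9", "HLA-DRA", "IDO1", "IFNG", "STAT1"]
CD8_GENES = ["CD8A", "CD8B"]

#: The eight T-cell types averaged into the T-cell infiltration score.
TIS_CELL_TYPES = [
    "Activated CD8 T cell",
    "T helper cell",
    "Effector memory T cell",
    "Central memory T cell",
    "Type 1 T helper cell",
    "Type 2 T helper cell",
    "Type 17 T helper cell",
    "Regulatory T cell",
]

#: Default 28-cell-type panel split used for the IIS (adaptive + innate).
ADAPTIVE_CELL_TYPES = [
    "Activated CD8 T cell", "Effector memory CD8 T cell", "Activated CD4 T cell",
    "T helper cell", "Effector memory T cell", "Central memory T cell",
    "Type 1 T helper cell", "Type 2 T helper cell", "Type 17 T helper cell",
    "Regulatory T cell", "T follicular helper cell", "Gamma delta T cell",
    "Activated B cell", "Immature B cell", "Memory B cell",
]
INNATE_CELL_TYPES = [
    "Natural killer cell", "CD56bright natural killer cell",
    "CD56dim natural killer cell", "Natural killer T cell",
    "Activated dendritic cell", "Plasmacytoid dendritic cell",
    "Immature dendritic cell", "Macrophage", "Monocyte", "Mast cell",
    "Eosinophil", "Neutrophil", "Myeloid derived suppressor cell",
]

#: Nonsynonymous variant classes counted into TMB.
NONSYNONYMOUS_CLASSES = [
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Translation_Start_Site", "Splice_Site", "Frame_Shift_Ins",
    "Frame_Shift_Del", "In_Frame_Ins", "In_Frame_Del",
]


def checkpoint_genes(literal: bool = False) -> list[str]:
    return list(CHECKPOINT_GENES_LITERAL if literal else CHECKPOINT_GENES)


def _sample_ranks(values: pd.DataFrame) -> np.ndarray:
    """Per-sample gene ranks, highest expression -> rank N.

    Ties are broken by lexicographic gene id (a deterministic total order),
    so the statistic is invariant under strictly increasing transforms.
    """
    v = values.to_numpy(dtype=float)
    n, m = v.shape
    # lexicographic tiebreak: sort by (value, reversed gene-id order)
    id_order = np.argsort(values.index.to_numpy())  # ascending gene id
    id_rank = np.empty(n, dtype=float)
    id_rank[id_order] = np.arange(n)
    ranks = np.empty_like(v)
    for j in range(m):
        order = np.lexsort((-id_rank, v[:, j]))  # ascending value, ties: later id first
        ranks[order, j] = np.arange(1, n + 1)
    return ranks


def ssgsea_enrichment(
    expr: ExpressionMatrix | pd.DataFrame,
    gene_sets: GeneSetCollection,
    alpha: float = 0.25,
) -> dict:
    """Per-sample single-sample GSEA enrichment of each gene set.

    For each sample, genes are ranked by expression (rank N = highest).
    With in-set weights rank^alpha, the enrichment score is the sum over
    ranked positions of the difference between the weighted in-set ECDF
    and the uniform out-of-set ECDF. NES is the ES divided by the range
    (max - min) of all ES values of the run.

    Returns ``{"es": DataFrame set x sample, "nes": ..., "alpha": alpha,
    "normalization": range}``; sets with fewer than 2 genes present are
    skipped with a warning.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    n, m = values.shape
    ranks = _sample_ranks(values)
    gene_index = {g: i for i, g in enumerate(values.index)}
    if (values.nunique(axis=0) == 1).any():
        warnings.warn("constant-expression sample: ES computed on tie-broken order",
                      stacklevel=2)

    # positions of genes in descending-rank order per sample
    order_desc = np.argsort(-ranks, axis=0)  # gene indices, best first
    es = {}
    for name in gene_sets.names():
        present = [gene_index[g] for g in gene_sets[name] if g in gene_index]
        if len(present) < 2:
            warnings.warn(f"gene set {name!r} has <2 genes in the matrix; skipped",
                          stacklevel=2)
            continue
        in_set = np.zeros(n, dtype=bool)
        in_set[present] = True
        n_out = n - len(present)
        scores = np.empty(m)
        for j in range(m):
            ordered_in = in_set[order_desc[:, j]]
            w = ranks[order_desc[:, j], j] ** alpha
            w[~ordered_in] = 0.0
            p_in = np.cumsum(w)
            p_in /= p_in[-1]
            p_out = np.cumsum(~ordered_in) / n_out
            scores[j] = np.sum(p_in - p_out)
        es[name] = scores
    es_df = pd.DataFrame(es, index=values.columns).T
    rng_norm = float(es_df.to_numpy().max() - es_df.to_numpy().min()) if es_df.size else 1.0
    if rng_norm == 0:
        rng_norm = 1.0
    nes_df = es_df / rng_norm
    return {"es": es_df, "nes": nes_df, "alpha": alpha, "normalization": rng_norm}


def estimate_scores(
    expr, stromal_set: list[str], immune_set: list[str], alpha: float = 0.25
) -> pd.DataFrame:
    """Stromal and immune ssGSEA scores and their sum (the ESTIMATE score)."""
    coll = GeneSetCollection({"stromal": list(stromal_set), "immune": list(immune_set)})
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    for name in ("stromal", "immune"):
        if not set(coll[name]) & set(values.index):
            raise ValueError(f"{name} gene set has no overlap with the matrix")
    res = ssgsea_enrichment(expr, coll, alpha=alpha)
    out = res["es"].T.copy()
    out["estimate"] = out["stromal"] + out["immune"]
    return out


def iis_tis(
    enrichment: dict,
    adaptive_cells: list[str],
    innate_cells: list[str],
    t_cell_sets: list[str] | None = None,
) -> pd.DataFrame:
    """Immune and T-cell infiltration scores from cell-type NES values.

    IIS = mean NES over adaptive plus innate cell types; TIS = mean NES
    over the eight T-cell types.
    """
    t_cell_sets = list(t_cell_sets) if t_cell_sets is not None else list(TIS_CELL_TYPES)
    nes = enrichment["nes"]
    for name in [*adaptive_cells, *innate_cells, *t_cell_sets]:
        if name not in nes.index:
            raise KeyError(f"cell type {name!r} missing from enrichment result")
    iis_cells = list(dict.fromkeys([*adaptive_cells, *innate_cells]))
    return pd.DataFrame(
        {"IIS": nes.loc[iis_cells].mean(axis=0), "TIS": nes.loc[t_cell_sets].mean(axis=0)}
    )


def cyt_score(expr, offset: float = 0.01) -> pd.Series:
    """Cytolytic activity: geometric mean of GZMA and PRF1 (linear scale)."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if isinstance(expr, ExpressionMatrix) and expr.unit == "raw_counts":
        values = cpm(expr)
    for g in ("GZMA", "PRF1"):
        if g not in values.index:
            raise KeyError(f"gene {g} absent — cannot compute CYT")
    return pd.Series(
        np.sqrt((values.loc["GZMA"] + offset) * (values.loc["PRF1"] + offset)),
        index=values.columns, name="CYT",
    )


def apm_score(expr, apm_set: list[str] | None = None, alpha: float = 0.25) -> pd.Series:
    """Antigen-processing-machinery score, min-max normalized to [0, 1]."""
    apm_set = list(apm_set) if apm_set is not None else list(APM_GENES)
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[1] < 2:
        raise ValueError("APM normalization undefined for a single-sample cohort")
    present = [g for g in apm_set if g in values.index]
    if len(present) < 2:
        raise ValueError("fewer than 2 APM genes present")
    res = ssgsea_enrichment(expr, GeneSetCollection({"APM": apm_set}), alpha=alpha)
    raw = res["es"].loc["APM"]
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        raise ValueError("APM normalization undefined: zero range across samples")
    return ((raw - lo) / (hi - lo)).rename("APM")


def compute_tmb(
    maf: MafTable,
    footprint_mb: float = 35.0,
    nonsyn_classes: list[str] | None = None,
    cohort_samples: list[str] | None = None,
) -> pd.Series:
    """Nonsynonymous variants per megabase, per sample.

    Cohort samples absent from the MAF get TMB = 0 with a warning.
    """
    if footprint_mb <= 0:
        raise ValueError("footprint_mb must be > 0")
    classes = set(nonsyn_classes if nonsyn_classes is not None else NONSYNONYMOUS_CLASSES)
    rec = maf.records
    nonsyn = rec[rec["Variant_Classification"].isin(classes)]
    counts = nonsyn.groupby("Tumor_Sample_Barcode").size()
    if cohort_samples is not None:
        missing = [s for s in cohort_samples if s not in counts.index]
        if missing:
            warnings.warn(f"{len(missing)} cohort samples absent from MAF: TMB=0",
                          stacklevel=2)
        counts = counts.reindex(cohort_samples, fill_value=0)
    return (counts / footprint_mb).rename("TMB")


def signature_mean(expr, genes: list[str]) -> pd.Series:
    """Mean of log2(value+1) over the present signature genes."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if isinstance(expr, ExpressionMatrix) and expr.unit == "raw_counts":
        values = cpm(expr)
    present = [g for g in genes if g in values.index]
    missing = [g for g in genes if g not in values.index]
    if not present:
        raise ValueError("no signature genes present in the matrix")
    if missing:
        warnings.warn(f"signature genes missing from the matrix: {missing}",
                      stacklevel=2)
    return np.log2(values.loc[present] + 1.0).mean(axis=0)


def wilcoxon_test(values, labels) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test between two groups.

    Exact null distribution when both groups have n <= 25 and there are no
    ties; otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("wilcoxon_test requires exactly two groups")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one group is empty")
    no_ties = len(np.unique(values)) == len(values)
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return {"U": float(res.statistic), "p": float(res.pvalue), "method": method}


def pearson_strong(score_table: pd.DataFrame, r_threshold: float = 0.5,
                   p_threshold: float = 0.05) -> pd.DataFrame:
    """Pairwise Pearson correlations with the strong-correlation rule.

    A pair is flagged strong when r > ``r_threshold`` and p < ``p_threshold``
    (t-distributed p on n-2 df). Zero-variance scores yield NA.
    """
    if len(score_table) < 3:
        raise ValueError("need at least 3 samples")
    cols = list(score_table.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            x = score_table[a].to_numpy(dtype=float)
            y = score_table[b].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((a, b, np.nan, np.nan, pd.NA))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((a, b, float(r), float(p),
                         bool(r > r_threshold and p < p_threshold)))
    return pd.DataFrame(rows, columns=["score_a", "score_b", "r", "p", "strong"])


class SSGSEAScorer:
    """Transformer view of ssGSEA: samples x genes in, samples x sets out."""

    def __init__(self, gene_sets: GeneSetCollection | None = None, alpha: float = 0.25):
        self.gene_sets = gene_sets
        self.alpha = alpha

    def get_params(self, deep=True):
        return {"gene_sets": self.gene_sets, "alpha": self.alpha}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        if self.gene_sets is None or len(self.gene_sets) == 0:
            raise ValueError("gene_sets must be provided")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        res = ssgsea_enrichment(X.T, self.gene_sets, alpha=self.alpha)
        self.normalization_ = res["normalization"]
        return res["nes"].T

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
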