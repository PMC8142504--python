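"""Subclass mapping: correspondence between subtypes of two cohorts.

For each pair (i, j) of subtypes across cohorts A and B, the top marker
genes of A's subtype i (by signal-to-noise ratio) are tested for
enrichment at the top of cohort B's subtype-j SNR ranking with an
unweighted Kolmogorov-Smirnov running sum, and symmetrically B -> A.
Permutation p-values (label permutations of the opposite cohort) are
combined across the two directions by Fisher's method and Bonferroni
adjusted by the number of subtype pairs. A small Bonferroni p for a pair
indicates that the two subtypes share an expression program — e.g. a
discovered immune-enriched subtype matching immunotherapy responders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

SNR_SIGMA_FLOOR = 0.2


@dataclass
class SubmapResult:
    p_matrix: pd.DataFrame            # kA x kB Fisher-combined nominal p
    bonferroni_matrix: pd.DataFrame   # p * (kA * kB), capped at 1
    n_markers: int
    n_permutations: int
    seed: int


def _floored_std(x: np.ndarray, axis: int) -> np.ndarray:
    """Group std with the SubMap floor: sigma >= 0.2 |mu| (and >= 0.2 min)."""
    mu = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=0)
    floor = SNR_SIGMA_FLOOR * np.abs(mu)
    floor = np.maximum(floor, SNR_SIGMA_FLOOR)
    return np.maximum(sd, floor)


def snr_ranking(values: pd.DataFrame, labels, target_class) -> pd.Series:
    """Per-gene signal-to-noise ratio of ``target_class`` vs the rest.

    SNR = (mu_target - mu_rest) / (sigma_target + sigma_rest), with each
    sigma floored at 0.2 |mu| to avoid division blow-ups.
    """
    labels = pd.Series(labels)
    mask = (labels == target_class).to_numpy()
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("target class and complement each need n >= 3")
    X = values.to_numpy(dtype=float)
    mu1 = X[:, mask].mean(axis=1)
    mu0 = X[:, ~mask].mean(axis=1)
    s1 = _floored_std(X[:, mask], axis=1)
    s0 = _floored_std(X[:, ~mask], axis=1)
    return pd.Series((mu1 - mu0) / (s1 + s0), index=values.index, name="snr")


def _snr_matrix(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mu1 = X[:, mask].mean(axis=1)
    mu0 = X[:, ~mask].mean(axis=1)
    s1 = _floored_std(X[:, mask], axis=1)
    s0 = _floored_std(X[:, ~mask], axis=1)
    return (mu1 - mu0) / (s1 + s0)


def _ks_es(positions: np.ndarray, n: int) -> float:
    """Unweighted KS enrichment of marker positions in a ranking of n genes."""
    m = positions.size
    pos = np.sort(positions)
    hit = np.arange(1, m + 1) / m
    miss = 1.0 / (n - m)
    after = hit - (pos + 1 - np.arange(1, m + 1)) * miss
    before = np.concatenate(([0.0], hit[:-1])) - (pos - np.arange(m)) * miss
    hi, lo = after.max(), before.min()
    return float(hi if hi >= -lo else lo)


def _rank_transform(values: pd.DataFrame) -> np.ndarray:
    """Within-sample gene ranks (cross-platform harmonization)."""
    X = values.to_numpy(dtype=float)
    return np.apply_along_axis(stats.rankdata, 0, X)


def _direction_pvals(
    Xa, labels_a, classes_a, Xb, labels_b, classes_b, n_markers, n_perm, rng
):
    """p[i, j] = enrichment of A-class-i markers in B-class-j rankings."""
    G = Xa.shape[0]
    n_markers = min(n_markers, G - 1)
    markers = {}
    for ca in classes_a:
        snr = _snr_matrix(Xa, (labels_a == ca))
        markers[ca] = np.argsort(-snr, kind="stable")[:n_markers]

    def es_for_b_labels(lab_b):
        es = np.zeros((len(classes_a), len(classes_b)))
        for j, cb in enumerate(classes_b):
            snr_b = _snr_matrix(Xb, (lab_b == cb))
            order = np.argsort(-snr_b, kind="stable")
            posn = np.empty(G, dtype=int)
            posn[order] = np.arange(G)
            for i, ca in enumerate(classes_a):
                es[i, j] = _ks_es(posn[markers[ca]], G)
        return es

    obs = es_for_b_labels(labels_b)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = rng.permutation(labels_b)
        null = es_for_b_labels(perm)
        exceed += null >= obs
    return (1.0 + exceed) / (1.0 + n_perm)


def submap_correspondence(
    expr_a: ExpressionMatrix | pd.DataFrame,
    labels_a: pd.Series,
    expr_b: ExpressionMatrix | pd.DataFrame,
    labels_b: pd.Series,
    n_markers: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
    min_common_genes: int = 500,
) -> SubmapResult:
    """Mutual marker-enrichment correspondence between two cohorts' subtypes."""
    va = expr_a.values if isinstance(expr_a, ExpressionMatrix) else expr_a
    vb = expr_b.values if isinstance(expr_b, ExpressionMatrix) else expr_b
    common = sorted(set(va.index) & set(vb.index))
    if len(common) < min_common_genes:
        raise ValueError(f"only {len(common)} genes in common "
                         f"(minimum {min_common_genes})")
    labels_a = pd.Series(labels_a).astype(str)
    labels_b = pd.Series(labels_b).astype(str)
    classes_a = sorted(labels_a.unique())
    classes_b = sorted(labels_b.unique())
    for lab, classes in ((labels_a, classes_a), (labels_b, classes_b)):
        counts = lab.value_counts()
        if (counts < 3).any():
            raise ValueError("every subtype needs at least 3 samples")
    Xa = _rank_transform(va.loc[common, labels_a.index])
    Xb = _rank_transform(vb.loc[common, labels_b.index])
    la = labels_a.to_numpy()
    lb = labels_b.to_numpy()
    rng = np.random.default_rng(seed)

    p_ab = _direction_pvals(Xa, la, classes_a, Xb, lb, classes_b,
                            n_markers, n_perm, rng)
    p_ba = _direction_pvals(Xb, lb, classes_b, Xa, la, classes_a,
                            n_markers, n_perm, rng).T

    chi2 = -2.0 * (np.log(p_ab) + np.log(p_ba))
    combined = stats.chi2.sf(chi2, df=4)
    combined = np.maximum(combined, np.finfo(float).tiny)
    p_matrix = pd.DataFrame(combined, index=classes_a, columns=classes_b)
    bonf = np.minimum(combined * (len(classes_a) * len(classes_b)), 1.0)
    bonferroni = pd.DataFrame(bonf, index=classes_a, columns=classes_b)
    return SubmapResult(
        p_matrix=p_matrix, bonferroni_matrix=bonferroni,
        n_markers=n_markers, n_permutations=n_perm, seed=seed,
    )
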