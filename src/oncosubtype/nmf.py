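"""Brunet (KL-divergence) NMF with multi-restart consensus clustering.

The expression matrix A (genes x samples) is factorised as A ~ W H with
multiplicative Kullback-Leibler updates. Sample clusters are read from the
argmax over the columns of H. Stability over random restarts is summarised
in a consensus matrix, from which the cophenetic correlation, dispersion
and mean silhouette guide the choice of the rank k. Cluster names are
harmonized so that sub1 is the immune-enriched cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .io import SubtypeAssignment

_EPS = np.finfo(float).tiny


@dataclass
class NmfFactors:
    """One factorisation A ~ W H at rank k."""

    W: np.ndarray
    H: np.ndarray
    k: int
    objective: float                      # KL divergence D(A || WH)
    n_update_iterations: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)

    def labels(self) -> np.ndarray:
        """Cluster index per sample: argmax over the rows of H."""
        return np.argmax(self.H, axis=0)


@dataclass
class ConsensusSummary:
    """Per-rank consensus matrices and rank-selection metrics."""

    consensus: dict[int, np.ndarray] = field(default_factory=dict)
    cophenetic: dict[int, float] = field(default_factory=dict)
    dispersion: dict[int, float] = field(default_factory=dict)
    silhouette: dict[int, float] = field(default_factory=dict)
    n_restarts: int = 0

    def metrics_frame(self) -> pd.DataFrame:
        ks = sorted(self.consensus)
        return pd.DataFrame(
            {
                "cophenetic": [self.cophenetic[k] for k in ks],
                "dispersion": [self.dispersion[k] for k in ks],
                "silhouette": [self.silhouette[k] for k in ks],
            },
            index=pd.Index(ks, name="rank"),
        )


def kl_divergence(A: np.ndarray, WH: np.ndarray) -> float:
    """Generalised KL divergence D(A||WH) = sum A log(A/WH) - A + WH."""
    WH = np.maximum(WH, _EPS)
    mask = A > 0
    term = np.zeros_like(A)
    term[mask] = A[mask] * np.log(A[mask] / WH[mask])
    return float(term.sum() - A.sum() + WH.sum())


def factorize_brunet(
    A: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 2000,
    check_interval: int = 10,
    stable_checks: int = 40,
) -> NmfFactors:
    """Multiplicative-update KL NMF (Brunet) with connectivity stopping.

    W and H are initialised uniform(0,1] from ``seed``. Updates stop when
    the sample connectivity (argmax over H) is unchanged for
    ``stable_checks`` consecutive checks performed every ``check_interval``
    iterations, or at ``max_iter``. All-zero rows of A are dropped with a
    warning before factorisation (their W rows are returned as zero).
    """
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("A must be nonnegative")
    n, m = A.shape
    if not (1 <= k < min(n, m)):
        raise ValueError(f"rank k={k} out of range for shape {A.shape}")
    zero_rows = A.sum(axis=1) == 0
    if zero_rows.any():
        import warnings

        warnings.warn(f"dropping {int(zero_rows.sum())} all-zero rows", stacklevel=2)
    Ause = A[~zero_rows]
    rng = np.random.default_rng(seed)
    W = 1.0 - rng.random((Ause.shape[0], k))  # uniform (0, 1]
    H = 1.0 - rng.random((k, m))

    history: list[float] = []
    prev_labels = None
    stable = 0
    converged = False
    it = 0
    while it < max_iter:
        for _ in range(min(check_interval, max_iter - it)):
            WH = np.maximum(W @ H, _EPS)
            H *= (W.T @ (Ause / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
            WH = np.maximum(W @ H, _EPS)
            W *= ((Ause / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
            it += 1
        history.append(kl_divergence(Ause, W @ H))
        labels = np.argmax(H, axis=0)
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            stable += 1
            if stable >= stable_checks:
                converged = True
                break
        else:
            stable = 0
        prev_labels = labels

    Wfull = np.zeros((n, k))
    Wfull[~zero_rows] = W
    return NmfFactors(
        W=Wfull,
        H=H,
        k=k,
        objective=history[-1],
        n_update_iterations=it,
        converged=converged,
        objective_history=history,
    )


def connectivity_matrix(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    return (labels[:, None] == labels[None, :]).astype(float)


def build_consensus(
    A: np.ndarray,
    k: int,
    n_restarts: int = 200,
    base_seed: int = 0,
    max_iter: int = 2000,
    labelings=None,
) -> tuple[np.ndarray, NmfFactors | None]:
    """Consensus matrix over random restarts plus the best factorisation.

    C[i, j] is the fraction of restarts in which samples i and j share a
    cluster; the best factorisation is the one with the lowest final KL
    objective. Restart seeds are ``base_seed + restart index``.
    ``labelings`` is a test hook: an iterable of precomputed label vectors
    used in place of running NMF (no best factorisation is returned then).
    """
    if labelings is not None:
        labelings = [np.asarray(l) for l in labelings]
        m = len(labelings[0])
        C = np.zeros((m, m))
        for lab in labelings:
            C += connectivity_matrix(lab)
        return C / len(labelings), None
    m = A.shape[1]
    C = np.zeros((m, m))
    best: NmfFactors | None = None
    for r in range(n_restarts):
        fac = factorize_brunet(A, k, seed=base_seed + r, max_iter=max_iter)
        C += connectivity_matrix(fac.labels())
        if best is None or fac.objective < best.objective:
            best = fac
    return C / n_restarts, best


def rank_metrics(C: np.ndarray, labels: np.ndarray) -> dict:
    """Rank-selection metrics from a consensus matrix.

    cophenetic: Pearson correlation between the off-diagonal consensus
    distances (1 - C) and the cophenetic distances of their average-linkage
    dendrogram. dispersion: mean of 4 (C - 1/2)^2. silhouette: mean
    silhouette width of ``labels`` under the distance 1 - C.
    """
    C = np.asarray(C, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    condensed = squareform(D, checks=False)
    Z = average(condensed)
    if np.ptp(condensed) == 0:
        coph = 1.0  # all distances equal: perfectly preserved ordering
    else:
        coph, _ = cophenet(Z, condensed)
        coph = float(coph)
    dispersion = float(np.mean(4.0 * (C - 0.5) ** 2))
    sil = float(silhouette_score(D, labels, metric="precomputed"))
    return {"cophenetic": coph, "dispersion": dispersion, "mean_silhouette": sil}


def harmonize_labels(
    raw_labels: np.ndarray,
    sample_ids,
    immune_scores: pd.Series | None = None,
    fallback_values: np.ndarray | None = None,
    cohort: str = "",
) -> SubtypeAssignment:
    """Rename clusters so sub1 has the highest mean immune score.

    ``immune_scores`` is a per-sample score (e.g. mean ssGSEA immune NES);
    when absent, ``fallback_values`` (e.g. per-sample mean of the screened
    genes) is used. Remaining clusters are ordered by decreasing score.
    """
    raw_labels = np.asarray(raw_labels)
    sample_ids = list(sample_ids)
    if immune_scores is not None:
        score = immune_scores.reindex(sample_ids).to_numpy(dtype=float)
    elif fallback_values is not None:
        score = np.asarray(fallback_values, dtype=float)
    else:
        raise ValueError("need immune_scores or fallback_values")
    clusters = np.unique(raw_labels)
    means = {c: score[raw_labels == c].mean() for c in clusters}
    order = sorted(clusters, key=lambda c: -means[c])
    rename = {c: f"sub{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series([rename[c] for c in raw_labels], index=sample_ids,
                       name="subtype")
    return SubtypeAssignment(labels, cohort=cohort, k=len(clusters))


def assign_subtypes(
    A: pd.DataFrame,
    rank_range=range(2, 7),
    n_restarts: int = 30,
    seed: int = 0,
    max_iter: int = 2000,
    immune_scores: pd.Series | None = None,
    cohort: str = "",
    center: str | None = "min",
) -> tuple[int, SubtypeAssignment, ConsensusSummary]:
    """Consensus-NMF subtyping with cophenetic rank selection.

    ``A`` is a genes x samples DataFrame of nonnegative values (typically
    log2(CPM+1) of the MAD-filtered screened genes). With the default
    ``center="min"`` each gene's cohort minimum is subtracted first, so
    the factorisation models expression above each gene's baseline rather
    than the (uninformative) shared offset; pass ``center=None`` to
    factorise the raw values. The selected rank is the argmax of the
    cophenetic coefficient (ties -> smaller k); final labels come from the
    best-objective restart at that rank, renamed so that sub1 is the
    cluster with the higher mean immune score (fallback: per-sample mean
    of A).
    """
    Av = A.to_numpy(dtype=float)
    if Av.shape[1] >= 2 and np.allclose(Av, Av[:, [0]]):
        raise ValueError("no cluster structure: all samples identical")
    raw_mean = Av.mean(axis=0)
    if center == "min":
        Av = Av - Av.min(axis=1, keepdims=True)
    elif center is not None:
        raise ValueError("center must be 'min' or None")
    summary = ConsensusSummary(n_restarts=n_restarts)
    best_by_k: dict[int, NmfFactors] = {}
    for idx, k in enumerate(rank_range):
        C, best = build_consensus(
            Av, k, n_restarts=n_restarts,
            base_seed=seed + 100_000 * (idx + 1), max_iter=max_iter,
        )
        m = rank_metrics(C, best.labels())
        summary.consensus[k] = C
        summary.cophenetic[k] = m["cophenetic"]
        summary.dispersion[k] = m["dispersion"]
        summary.silhouette[k] = m["mean_silhouette"]
        best_by_k[k] = best
    ks = sorted(summary.cophenetic)
    selected = max(ks, key=lambda k: (summary.cophenetic[k], -k))
    best = best_by_k[selected]
    assignment = harmonize_labels(
        best.labels(), A.columns, immune_scores=immune_scores,
        fallback_values=raw_mean, cohort=cohort,
    )
    return selected, assignment, summary


class NMFSubtyper:
    """Consensus-NMF clusterer with a scikit-learn estimator surface.

    Parameters mirror :func:`assign_subtypes`. ``fit`` expects X of shape
    (n_samples, n_features) per sklearn convention (the transpose of the
    genes x samples layout used elsewhere).

    Attributes (after fit): ``k_``, ``labels_`` (string sub1..subK),
    ``consensus_``, ``metrics_``.
    """

    def __init__(self, rank_range=(2, 3, 4, 5, 6), n_restarts=30, seed=0,
                 max_iter=2000):
        self.rank_range = rank_range
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_iter = max_iter

    def get_params(self, deep=True):
        return {
            "rank_range": self.rank_range,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        A = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(X.shape[0])])
        k, assignment, summary = assign_subtypes(
            A, rank_range=self.rank_range, n_restarts=self.n_restarts,
            seed=self.seed, max_iter=self.max_iter,
        )
        self.k_ = k
        self.labels_ = assignment.labels.to_numpy()
        self.consensus_ = summary.consensus[k]
        self.metrics_ = summary.metrics_frame()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
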