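"""Co-expression modules: soft-threshold selection by scale-free fit,
topological overlap, static-cut module detection, eigengenes, module-trait
statistics and cross-cohort hub-gene intersection.

The network is unsigned: adjacency = |Pearson correlation|^beta, with beta
chosen as the smallest candidate power whose scale-free fit R^2 reaches a
target (default 0.8). Module detection uses an average-linkage tree on the
TOM dissimilarity with a static height cut (a deliberate simplification of
the dynamic tree cut).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy import stats


@dataclass
class NetworkConfig:
    powers: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_target: float = 0.8
    connectivity_floor: float = 2.0   # powers with mean k below this are ignored
    min_module_size: int = 30
    cut_height_fractions: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.85,
                                               0.90, 0.95, 0.99)
    n_bins: int = 10

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.powers):
            raise ValueError("powers must be positive integers")
        if not 0 < self.scale_free_r2_target <= 1:
            raise ValueError("R^2 target must be in (0, 1]")


@dataclass
class ModuleSet:
    """Gene -> module label (0 = unassigned) plus eigengenes per module."""

    labels: pd.Series
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def module_ids(self) -> list[int]:
        return sorted(set(self.labels.unique()) - {0})

    def genes_of(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def adjacency_matrix(values: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency |cor|^beta with zero diagonal; constant genes dropped."""
    keep = values.std(axis=1) > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} constant genes", stacklevel=2)
    v = values.loc[keep]
    a = np.abs(np.corrcoef(v.to_numpy())) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=v.index, columns=v.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-density fit over equal-occupancy bins.

    p(k) for a bin is the fraction of nodes divided by the bin width (a
    density — with equal-occupancy bins the raw fraction is constant by
    construction). A positive slope (not scale-free) flips the sign of R^2.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        n_bins = max(2, k.size // 2)
    edges = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        width = edges[b + 1] - edges[b]
        if sel.sum() == 0 or width <= 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean() / width))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    if not np.isfinite(r):
        return 0.0
    r2 = float(r**2)
    return -r2 if slope > 0 else r2


def pick_soft_threshold(
    values: pd.DataFrame, config: NetworkConfig | None = None
) -> dict:
    """Choose the soft-thresholding power beta.

    Returns the chosen beta, and per candidate power the signed scale-free
    R^2 and the mean connectivity. beta is the smallest power reaching the
    R^2 target, else the argmax R^2 with a warning.
    """
    config = config or NetworkConfig()
    r2s, mean_k = {}, {}
    for beta in config.powers:
        a = adjacency_matrix(values, beta).to_numpy()
        k = a.sum(axis=0)
        r2s[beta] = scale_free_fit(k, config.n_bins)
        mean_k[beta] = float(k.mean())
    # powers whose network has all but dissolved are never sensible
    usable = [b for b in config.powers
              if mean_k[b] >= config.connectivity_floor] or list(config.powers[:1])
    reaching = [b for b in usable if r2s[b] >= config.scale_free_r2_target]
    if reaching:
        beta = reaching[0]
    else:
        beta = max(usable, key=lambda b: r2s[b])
        warnings.warn(
            f"no usable power reaches R^2 >= {config.scale_free_r2_target}; "
            f"using argmax beta={beta}", stacklevel=2,
        )
    return {"beta": beta, "r2": r2s, "mean_connectivity": mean_k}


def tom_matrix(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap similarity of an adjacency matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    unit diagonal. Input must be symmetric with entries in [0, 1] and a
    zero diagonal.
    """
    is_frame = isinstance(adjacency, pd.DataFrame)
    a = adjacency.to_numpy(dtype=float) if is_frame else np.asarray(adjacency, float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must be in [0, 1]")
    if not np.allclose(np.diag(a), 0):
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    if is_frame:
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def detect_modules(
    diss_tom: pd.DataFrame, config: NetworkConfig | None = None
) -> ModuleSet:
    """Average-linkage modules from TOM dissimilarity with a static cut.

    The tree is cut at the smallest candidate height (fractions of the
    maximum merge height) that yields at least two modules of size >=
    ``min_module_size``; genes in undersized clusters get label 0. Module
    labels are ordered by decreasing size.
    """
    config = config or NetworkConfig()
    genes = diss_tom.index
    if len(genes) < config.min_module_size:
        warnings.warn("fewer genes than min_module_size: all unassigned",
                      stacklevel=2)
        return ModuleSet(pd.Series(0, index=genes, name="module"))
    d = diss_tom.to_numpy(dtype=float)
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    Z = average(squareform(d, checks=False))
    max_h = Z[:, 2].max()
    for frac in sorted(config.cut_height_fractions):
        raw = fcluster(Z, t=frac * max_h, criterion="distance")
        sizes = pd.Series(raw).value_counts()
        big = sizes.index[sizes >= config.min_module_size]
        if len(big) >= 2:
            order = sizes.loc[big].sort_values(ascending=False).index
            rename = {c: i + 1 for i, c in enumerate(order)}
            labels = pd.Series([rename.get(c, 0) for c in raw], index=genes,
                               name="module")
            return ModuleSet(labels)
    warnings.warn("no cut height yields >= 2 valid modules: all unassigned",
                  stacklevel=2)
    return ModuleSet(pd.Series(0, index=genes, name="module"))


def module_stats(
    values: pd.DataFrame, modules: ModuleSet, subtype_indicator: pd.Series
) -> dict:
    """Eigengenes, module-trait correlations, gene significance, membership.

    The eigengene of a module is the first principal component (unit norm)
    of its standardized expression, sign-oriented so its mean correlation
    with the module genes is positive. Gene significance GS is the
    absolute Pearson correlation of each gene with the subtype indicator;
    module membership MM is the correlation of each gene with each
    eigengene.
    """
    ids = modules.module_ids()
    if not ids:
        raise ValueError("no modules to summarise")
    indicator = subtype_indicator.loc[values.columns].to_numpy(dtype=float)
    Z = values.sub(values.mean(axis=1), axis=0)
    sd = values.std(axis=1, ddof=0).replace(0, 1.0)
    Z = Z.div(sd, axis=0)
    eigengenes = {}
    trait_rows = []
    for m in ids:
        sub = Z.loc[modules.genes_of(m)].to_numpy()
        if sub.shape[0] == 1:
            e = sub[0] / np.linalg.norm(sub[0])
        else:
            _, _, vt = np.linalg.svd(sub, full_matrices=False)
            e = vt[0]
        cors = np.array([np.corrcoef(e, g)[0, 1] for g in sub])
        if np.nanmean(cors) < 0:
            e = -e
        eigengenes[m] = e
        r, p = stats.pearsonr(e, indicator)
        trait_rows.append((m, float(r), float(p), sub.shape[0]))
    eig = pd.DataFrame(eigengenes, index=values.columns)
    trait = pd.DataFrame(trait_rows,
                         columns=["module", "r", "p", "size"]).set_index("module")
    Xc = Z.to_numpy()
    gs = np.abs(_row_cor(Xc, indicator))
    gene_sig = pd.Series(gs, index=values.index, name="GS")
    mm = pd.DataFrame(
        {m: _row_cor(Xc, eig[m].to_numpy()) for m in ids}, index=values.index
    )
    return {"eigengenes": eig, "module_trait": trait, "GS": gene_sig, "MM": mm}


def _row_cor(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Xc @ yc) / denom


def hub_and_intersect(
    stats_per_cohort: dict[str, dict],
    modules_per_cohort: dict[str, ModuleSet],
    mm_min: float = 0.8,
    gs_min: float = 0.5,
) -> dict:
    """Hub genes of the most trait-correlated module per cohort, intersected.

    Hubs are genes of that module with |MM| >= mm_min and GS >= gs_min.
    """
    hubs = {}
    for cohort, st in stats_per_cohort.items():
        trait = st["module_trait"]
        best = trait["r"].abs().idxmax()
        genes = modules_per_cohort[cohort].genes_of(best)
        mm = st["MM"].loc[genes, best].abs()
        gs = st["GS"].loc[genes]
        kept = [g for g in genes if mm[g] >= mm_min and gs[g] >= gs_min]
        if not kept:
            warnings.warn(f"cohort {cohort}: no hub genes pass the thresholds",
                          stacklevel=2)
        hubs[cohort] = kept
    lists = list(hubs.values())
    inter = set(lists[0])
    for l in lists[1:]:
        inter &= set(l)
    return {"hubs": hubs, "intersection": sorted(inter)}


class CoexpressionNetwork:
    """Estimator surface: fit(X samples x genes, y subtype indicator)."""

    def __init__(self, config: NetworkConfig | None = None, mm_min=0.8, gs_min=0.5):
        self.config = config
        self.mm_min = mm_min
        self.gs_min = gs_min

    def get_params(self, deep=True):
        return {"config": self.config, "mm_min": self.mm_min, "gs_min": self.gs_min}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame, y):
        config = self.config or NetworkConfig()
        values = X.T  # genes x samples
        pick = pick_soft_threshold(values, config)
        self.beta_ = pick["beta"]
        self.scale_free_r2_ = pick["r2"]
        adj = adjacency_matrix(values, self.beta_)
        tom = tom_matrix(adj)
        self.modules_ = detect_modules(1.0 - tom, config)
        indicator = pd.Series(y, index=X.index)
        self.stats_ = module_stats(values.loc[self.modules_.labels.index],
                                   self.modules_, indicator)
        self.modules_.eigengenes = self.stats_["eigengenes"]
        return self
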