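"""Weighted co-expression module detection in the WGCNA style.

Pipeline: filter low-expression genes (TPM < 1 in >= 90% of samples),
build an unsigned adjacency ``a_ij = |cor_ij|^beta`` with the soft power
chosen by scale-free fit, form the topological overlap matrix (TOM),
cluster genes by average linkage on ``1 - TOM`` with a static tree cut,
summarise each module by its eigengene (first principal component of the
standardised module expression), and merge modules whose eigengenes are
more similar than the merge height (default 0.25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

BACKGROUND = "background"


@dataclass(frozen=True)
class CoexprConfig:
    tpm_min: float = 1.0
    low_fraction: float = 0.9
    powers: tuple = tuple(range(1, 21))
    r2_min: float = 0.9
    cut_height: float | None = None
    min_module_size: int = 30
    merge_height: float = 0.25
    cv_convention: str = "sd_over_mean"   # or "mean_over_sd"

    def validate(self) -> None:
        if not 0 < self.low_fraction <= 1:
            raise ValueError("low_fraction must lie in (0, 1]")
        if not 0 < self.r2_min <= 1:
            raise ValueError("r2_min must lie in (0, 1]")
        if not 0 <= self.merge_height <= 1:
            raise ValueError("merge_height must lie in [0, 1]")
        if self.cv_convention not in ("sd_over_mean", "mean_over_sd"):
            raise ValueError("unknown cv_convention")


@dataclass
class ModuleSet:
    labels: pd.Series                 # gene -> module label
    eigengenes: pd.DataFrame          # samples x modules, unit-norm columns
    sizes: dict = field(default_factory=dict)

    def module_map(self) -> dict:
        return self.labels.to_dict()


# --------------------------------------------------------------------------
# filtering and per-gene summaries
# --------------------------------------------------------------------------

def filter_low_expression(matrix: pd.DataFrame,
                          cfg: CoexprConfig = CoexprConfig()
                          ) -> tuple[pd.DataFrame, dict]:
    """Drop genes with TPM < tpm_min in at least ``low_fraction`` of
    samples.  Returns (kept matrix, counts dict).  Idempotent."""
    cfg.validate()
    if matrix.empty:
        raise ValueError("empty expression matrix")
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    frac_low = (matrix < cfg.tpm_min).mean(axis=1)
    removed = frac_low >= cfg.low_fraction
    kept = matrix.loc[~removed]
    if kept.empty:
        raise ValueError("all genes removed by the expression filter")
    return kept, {"kept": int((~removed).sum()),
                  "removed": int(removed.sum())}


def expression_cv(matrix: pd.DataFrame,
                  cfg: CoexprConfig = CoexprConfig()) -> pd.Series:
    """Per-gene coefficient of variation under the configured convention.

    ``sd_over_mean`` is the standard CV; ``mean_over_sd`` its reciprocal.
    The sample standard deviation (n-1) is used.  Zero variance under
    mean_over_sd yields a missing value.
    """
    cfg.validate()
    if matrix.shape[1] < 2:
        raise ValueError("CV needs at least 2 samples")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    if cfg.cv_convention == "sd_over_mean":
        return sd / mean
    with np.errstate(divide="ignore"):
        out = mean / sd
    return out.mask(sd == 0)


# --------------------------------------------------------------------------
# network construction
# --------------------------------------------------------------------------

def adjacency(matrix: pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned adjacency |pearson|^beta with zero diagonal."""
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ValueError("constant gene rows; filter before building "
                         "the network")
    a = np.abs(np.corrcoef(x)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Squared correlation of log10 p(k) vs log10 k over connectivity bins."""
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = (counts > 0) & (centers > 0)
    if ok.sum() < 3:
        return 0.0
    logk = np.log10(centers[ok])
    logp = np.log10(counts[ok] / counts.sum())
    if np.ptp(logk) == 0 or np.ptp(logp) == 0:
        return 0.0
    r = np.corrcoef(logk, logp)[0, 1]
    return float(r ** 2)


def pick_soft_power(matrix: pd.DataFrame,
                    cfg: CoexprConfig = CoexprConfig()
                    ) -> tuple[int, pd.DataFrame]:
    """Smallest candidate beta whose scale-free fit reaches r2_min; when
    none qualifies, the beta maximising the fit is returned with a warning.

    Returns (beta, table of beta/r2/mean connectivity).
    """
    cfg.validate()
    if matrix.shape[0] < 20 or matrix.shape[1] < 4:
        raise ValueError("need >= 20 genes and >= 4 samples")
    rows = []
    for beta in cfg.powers:
        a = adjacency(matrix, beta)
        k = a.sum(axis=1)
        rows.append({"beta": beta, "r2": scale_free_r2(k),
                     "mean_k": float(k.mean())})
    table = pd.DataFrame(rows).set_index("beta")
    qualifying = table.index[table["r2"] >= cfg.r2_min]
    if len(qualifying):
        return int(qualifying[0]), table
    best = int(table["r2"].idxmax())
    warnings.warn(f"no candidate power reaches R2 >= {cfg.r2_min}; "
                  f"using beta = {best} (R2 = {table.loc[best, 'r2']:.3f})")
    return best, table


def compute_tom(matrix: pd.DataFrame, beta: int) -> np.ndarray:
    """Topological overlap matrix of the unsigned adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    TOM_ii = 1.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = adjacency(matrix, beta)
    if not np.isfinite(a).all():
        raise ValueError("non-finite correlation in adjacency")
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return tom


# --------------------------------------------------------------------------
# module detection
# --------------------------------------------------------------------------

def _eigengene(x: np.ndarray) -> np.ndarray:
    """First principal component of standardised expression (unit norm),
    sign-oriented to correlate positively with mean expression."""
    z = (x - x.mean(axis=1, keepdims=True))
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    ref = x.mean(axis=0)
    if np.std(ref) > 0 and np.corrcoef(e, ref)[0, 1] < 0:
        e = -e
    return e / np.linalg.norm(e)


def detect_modules(tom: np.ndarray, matrix: pd.DataFrame,
                   cfg: CoexprConfig = CoexprConfig()) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static cut, eigengene
    computation and iterative eigengene merging.

    When ``cfg.cut_height`` is None the cut height maximising the number
    of clusters of size >= min_module_size is chosen (lowest such height
    on ties).  Clusters below the size threshold become background.
    Module pairs with eigengene dissimilarity (1 - correlation) below
    ``merge_height`` merge iteratively, closest pair first.
    """
    cfg.validate()
    genes = list(matrix.index)
    n = len(genes)
    if n < cfg.min_module_size:
        warnings.warn("fewer genes than min_module_size; background only")
        return ModuleSet(labels=pd.Series(BACKGROUND, index=genes),
                         eigengenes=pd.DataFrame(index=matrix.columns),
                         sizes={BACKGROUND: n})
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    condensed = d[np.triu_indices(n, k=1)]
    link = hierarchy.linkage(condensed, method="average")

    if cfg.cut_height is not None:
        assign = hierarchy.fcluster(link, t=cfg.cut_height,
                                    criterion="distance")
    else:
        heights = np.unique(link[:, 2])
        candidates = np.concatenate([[0.0], (heights[:-1] + heights[1:]) / 2,
                                     [heights[-1] + 1e-9]])
        # highest cut with the most valid-size modules: peripheral genes
        # join their module rather than splintering into background
        best_assign, best_score = None, (-1, -1.0)
        for h in candidates:
            a = hierarchy.fcluster(link, t=h, criterion="distance")
            sizes = np.bincount(a)
            n_valid = int((sizes >= cfg.min_module_size).sum())
            score = (n_valid, h)
            if score > best_score:
                best_score, best_assign = score, a
        assign = best_assign

    x = matrix.to_numpy(dtype=float)
    modules: dict[str, list[int]] = {}
    for cl in np.unique(assign):
        idx = np.nonzero(assign == cl)[0]
        if len(idx) >= cfg.min_module_size:
            modules[f"M{len(modules) + 1}"] = list(idx)
    labels = pd.Series(BACKGROUND, index=genes, dtype=object)
    eig: dict[str, np.ndarray] = {}
    for name, idx in modules.items():
        labels.iloc[idx] = name
        eig[name] = _eigengene(x[idx])

    # iterative eigengene merge, closest pair below merge_height first
    while len(eig) > 1:
        names = sorted(eig)
        e = np.array([eig[nm] for nm in names])
        c = np.corrcoef(e)
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if 1.0 - c[i, j] >= cfg.merge_height:
            break
        keep_nm, drop_nm = names[i], names[j]
        modules[keep_nm] = sorted(modules[keep_nm] + modules[drop_nm])
        del modules[drop_nm], eig[drop_nm]
        labels.iloc[modules[keep_nm]] = keep_nm
        eig[keep_nm] = _eigengene(x[modules[keep_nm]])

    # relabel in decreasing size order for stable naming
    order = sorted(modules, key=lambda nm: (-len(modules[nm]), nm))
    rename = {old: f"M{i + 1}" for i, old in enumerate(order)}
    labels = labels.map(lambda v: rename.get(v, v))
    eigengenes = pd.DataFrame(
        {rename[nm]: eig[nm] for nm in order}, index=matrix.columns)
    sizes = labels.value_counts().to_dict()
    return ModuleSet(labels=labels, eigengenes=eigengenes, sizes=sizes)


def module_tissue_profile(modules: ModuleSet,
                          metadata: pd.DataFrame) -> pd.DataFrame:
    """Mean eigengene per tissue (modules x tissues) with the top tissue.

    ``metadata`` needs columns ``sample`` and ``tissue`` covering every
    sample in the eigengene table.
    """
    meta = metadata.set_index("sample")
    missing = [s for s in modules.eigengenes.index
               if s not in meta.index or pd.isna(meta.loc[s, "tissue"])]
    if missing:
        raise ValueError(f"missing tissue label for sample(s) {missing}")
    tissues = meta.loc[modules.eigengenes.index, "tissue"]
    prof = modules.eigengenes.groupby(tissues.to_numpy()).mean().T
    prof["top_tissue"] = prof.idxmax(axis=1)
    return prof
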