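"""Signed weighted co-methylation networks.

WGCNA-style analysis of a feature x sample methylation matrix: signed
adjacency A_ij = ((1 + cor(x_i, x_j)) / 2)^beta, topological overlap,
average-linkage clustering of 1 - TOM with a static height cut into
modules, module eigengenes (first principal component of each module's
standardized profiles), and module-trait statistics (Pearson correlation
of eigengenes with tissue indicator traits, module membership, trait
significance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger("medipkit")

# WGCNA-style module color order, assigned by decreasing module size.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
)
UNASSIGNED = "grey"


@dataclass
class NetworkConfig:
    """Knobs for network construction and module detection."""

    power: int = 6
    signed: bool = True
    min_module_size: int = 30
    cut_height: float = 0.95  # fraction of the maximal merge height
    log_pseudocount: float = 1.0

    def __post_init__(self):
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")


# ---------------------------------------------------------------------------
# Transform and soft power
# ---------------------------------------------------------------------------

def log_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """x -> log2(x + pseudocount); monotone, so per-feature rankings of
    samples are preserved."""
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("log_transform: negative input")
    return pd.DataFrame(
        np.log2(vals + pseudocount), index=matrix.index, columns=matrix.columns
    )


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index.

    Bins the connectivity distribution, regresses log10 p(k) on log10 mean
    k over the non-empty bins, and returns R^2 signed by -slope (positive
    when the degree distribution decays, as scale-free topology requires).
    NaN when fewer than 8 usable bins or the connectivities are degenerate.
    """
    k = np.asarray(k, dtype=float)
    if k.std() < 1e-12 or (k <= 0).all():
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    ks, ps = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mk = k[sel].mean()
        if mk <= 0:
            continue
        ks.append(np.log10(mk))
        ps.append(np.log10(sel.mean()))
    if len(ks) < 8:
        return np.nan
    slope, _, r, _, _ = stats.linregress(ks, ps)
    return -np.sign(slope) * r**2


def pick_soft_power(
    matrix: pd.DataFrame,
    powers=range(1, 21),
    signed: bool = True,
    rsq_cut: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-thresholding power by the scale-free topology criterion.

    Returns the smallest candidate power whose signed fit R^2 reaches
    ``rsq_cut``; if none does, the power with the best fit.  The full table
    (power, fit_rsq, mean_k, median_k, max_k) is returned alongside.
    """
    if matrix.shape[1] < 4:
        raise ValueError("pick_soft_power: need >= 4 samples")
    corr = _feature_correlation(matrix.to_numpy(dtype=float))
    rows = []
    for beta in powers:
        A = _corr_to_adjacency(corr, beta, signed)
        k = A.sum(axis=0) - 1.0
        rsq = scale_free_fit(k, n_bins)
        rows.append(
            {"power": int(beta), "fit_rsq": rsq, "mean_k": float(k.mean()),
             "median_k": float(np.median(k)), "max_k": float(k.max())}
        )
    table = pd.DataFrame(rows)
    if table["fit_rsq"].isna().all():
        raise ValueError("pick_soft_power: scale-free fit degenerate for all "
                         "candidate powers (identical connectivities?)")
    ok = table[table["fit_rsq"] >= rsq_cut]
    beta = int(ok["power"].iloc[0]) if len(ok) else int(
        table.loc[table["fit_rsq"].idxmax(), "power"]
    )
    return beta, table


# ---------------------------------------------------------------------------
# Adjacency and topological overlap
# ---------------------------------------------------------------------------

def _feature_correlation(vals: np.ndarray) -> np.ndarray:
    """Pearson correlation between feature profiles (rows)."""
    return np.corrcoef(vals)


def _corr_to_adjacency(corr: np.ndarray, power: int, signed: bool) -> np.ndarray:
    if signed:
        A = ((1.0 + corr) / 2.0) ** power
    else:
        A = np.abs(corr) ** power
    np.fill_diagonal(A, 1.0)
    return np.clip(A, 0.0, 1.0)


def adjacency(
    matrix: pd.DataFrame, config: NetworkConfig
) -> tuple[np.ndarray, pd.Index]:
    """Signed (or unsigned) weighted adjacency between feature profiles.

    Zero-variance features are dropped with a warning.  Returns the
    adjacency and the index of retained features.
    """
    if matrix.shape[1] < 3:
        raise ValueError("adjacency: need >= 3 samples")
    vals = matrix.to_numpy(dtype=float)
    sds = vals.std(axis=1)
    keep = sds > 1e-12  # constant up to float rounding
    if not keep.all():
        logger.warning("adjacency: dropping %d zero-variance features",
                       int((~keep).sum()))
        vals = vals[keep]
    corr = _feature_correlation(vals)
    return _corr_to_adjacency(corr, config.power, config.signed), matrix.index[keep]


def tom(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij)
    with k_i = sum_{u != i} A_iu; TOM_ii = 1.  With unit diagonal,
    sum_{u != i,j} A_iu A_uj = (A @ A)_ij - 2 A_ij, so the numerator is
    (A @ A)_ij - A_ij.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("tom: adjacency must be symmetric")
    k = A.sum(axis=0) - np.diag(A)
    num = A @ A - A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        T = num / den
    T[den <= 0] = 0.0
    np.fill_diagonal(T, 1.0)
    return np.clip((T + T.T) / 2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def detect_modules(T: np.ndarray, feature_ids, config: NetworkConfig) -> pd.Series:
    """Average-linkage clustering of dissTOM = 1 - TOM with a static cut.

    The tree is cut at ``cut_height`` x (maximal merge height); clusters
    smaller than ``min_module_size`` become "grey" (unassigned).  Surviving
    modules are named by decreasing size from the standard color palette.
    """
    d = 1.0 - np.asarray(T, dtype=float)
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(np.clip(d, 0, None), checks=False),
                             method="average")
    cut = config.cut_height * link[:, 2].max()
    raw = hierarchy.fcluster(link, t=cut, criterion="distance")
    counts = pd.Series(raw).value_counts()
    big = counts[counts >= config.min_module_size]
    if len(big) == 0:
        logger.warning("detect_modules: no cluster reaches min_module_size=%d; "
                       "all features unassigned", config.min_module_size)
    if len(counts) == 1:
        logger.warning("detect_modules: all features fall in a single cluster")
    # deterministic naming: by decreasing size, ties by smallest raw label
    order = sorted(big.index, key=lambda lbl: (-big[lbl], lbl))
    name_of = {lbl: MODULE_COLORS[i % len(MODULE_COLORS)] if i < len(MODULE_COLORS)
               else f"module{i + 1}" for i, lbl in enumerate(order)}
    labels = [name_of.get(lbl, UNASSIGNED) for lbl in raw]
    return pd.Series(labels, index=feature_ids, name="module")


# ---------------------------------------------------------------------------
# Eigengenes and trait statistics
# ---------------------------------------------------------------------------

def module_eigengenes(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized profiles.

    Profiles are z-scored per feature across samples; the eigengene is the
    leading right singular vector (sample scores), scaled to unit variance
    and sign-aligned so cor(ME, module mean profile) >= 0.  Returns a
    modules x samples DataFrame (grey excluded).
    """
    mes = {}
    for module in sorted(set(labels) - {UNASSIGNED}):
        feats = labels.index[labels == module]
        sub = matrix.loc[feats].to_numpy(dtype=float)
        sds = sub.std(axis=1)
        if (sds == 0).all():
            raise ValueError(f"module_eigengenes: module {module} has only "
                             "constant profiles")
        sub = sub[sds > 0]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
        # leading right singular vector = PC1 sample scores
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        mean_profile = z.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        me = (me - me.mean()) / me.std(ddof=0)
        mes[module] = me
    if not mes:
        raise ValueError("module_eigengenes: no non-grey modules")
    return pd.DataFrame(mes, index=matrix.columns).T


def module_trait_stats(
    me: pd.DataFrame,
    traits: pd.DataFrame,
    matrix: pd.DataFrame,
    labels: pd.Series,
) -> dict:
    """Module-trait correlations, module membership and trait significance.

    ``traits``: samples x traits one-hot indicators (e.g. tissue).  Returns
    a dict with:
      - "module_trait": per (module, trait) Pearson r and Student-t p-value
        (n - 2 df);
      - "membership": MM(f) = |cor(profile_f, ME of its module)| (NaN for
        grey features);
      - "significance": GS(f, t) = |cor(profile_f, trait_t)|.
    """
    n = me.shape[1]
    if n != len(traits):
        raise ValueError("module_trait_stats: sample mismatch")
    for t in traits.columns:
        if traits[t].std() == 0:
            raise ValueError(f"module_trait_stats: constant trait {t}")
    rows = []
    for module in me.index:
        for t in traits.columns:
            r = float(np.corrcoef(me.loc[module], traits[t].to_numpy(float))[0, 1])
            r_ = min(max(r, -0.9999999), 0.9999999)
            tstat = r_ * np.sqrt((n - 2) / (1 - r_**2))
            p = 2 * stats.t.sf(abs(tstat), n - 2)
            rows.append({"module": module, "trait": t, "r": r, "p_value": float(p)})
    module_trait = pd.DataFrame(rows)

    vals = matrix.to_numpy(dtype=float)
    mm = pd.Series(np.nan, index=matrix.index, name="module_membership")
    for module in me.index:
        feats = labels.index[labels == module]
        e = me.loc[module].to_numpy(float)
        for f in feats:
            x = matrix.loc[f].to_numpy(float)
            if x.std() > 0:
                mm[f] = abs(float(np.corrcoef(x, e)[0, 1]))
    gs = pd.DataFrame(index=matrix.index, columns=traits.columns, dtype=float)
    for t in traits.columns:
        tv = traits[t].to_numpy(float)
        sds = vals.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = ((vals - vals.mean(axis=1, keepdims=True)) @ (tv - tv.mean())) / (
                np.maximum(sds, 1e-300) * tv.std() * vals.shape[1]
            )
        c[sds == 0] = np.nan
        gs[t] = np.abs(c)
    return {"module_trait": module_trait, "membership": mm, "significance": gs}


def tissue_traits(samples: pd.DataFrame, column: str = "tissue_group") -> pd.DataFrame:
    """One-hot tissue indicators per sample."""
    return pd.get_dummies(samples[column]).astype(float)


def top_variance_features(matrix: pd.DataFrame, n: int = 2000) -> pd.DataFrame:
    """Variance-ranked feature subset (keeps TOM memory quadratic but
    desk-scale); ties broken by feature id for determinism."""
    if len(matrix) <= n:
        return matrix
    var = matrix.var(axis=1)
    order = sorted(matrix.index, key=lambda f: (-var[f], str(f)))
    return matrix.loc[order[:n]]
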