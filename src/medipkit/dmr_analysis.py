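"""Feature-level quantification and tissue-specific DMR analysis.

Given a feature universe and per-sample signal (read counts or
CpG-density-corrected bin scores), this module quantifies methylation per
feature, ranks features by a coefficient of variance (CV = SD / (mean + 1))
across tissue groups or samples, tests feature-class enrichment of the most
variable features (observed/expected with a chi-square goodness of fit),
describes sample structure (Pearson correlation, average-linkage
clustering, PCA), quantifies between-individual differences and their
cross-tissue correlation, and computes average genic metaprofiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .coupling_norm import BinGrid

logger = logging.getLogger("medipkit")


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------

@dataclass
class FeatureMethylationMatrix:
    """Features x samples methylation values with aligned metadata.

    ``values``: DataFrame indexed by feature id, columns = sample ids.
    ``features``: per-feature metadata (feature_class, chrom, start, end),
    indexed by feature id.
    ``samples``: per-sample metadata (individual_id, tissue, tissue_group),
    indexed by sample id.
    """

    values: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.equals(self.features.index):
            self.features = self.features.loc[self.values.index]
        if not self.values.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.values.columns]
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FeatureMethylationMatrix: negative values")

    def group_means(self, by: str = "tissue_group") -> pd.DataFrame:
        """Per-group mean profile (features x groups)."""
        groups = self.samples[by]
        return self.values.T.groupby(groups).mean().T


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def quantify_reads(
    reads_by_sample: dict,
    features: pd.DataFrame,
    totals: dict | None = None,
) -> pd.DataFrame:
    """RPKM-style read-depth score per feature and sample.

    value = (reads overlapping the feature) * 1e9 / (total reads * feature
    length in bp) — normalized for total read count and feature length.  A
    read overlaps a feature when their intervals intersect.
    """
    lengths = (features["end"] - features["start"]).to_numpy(np.int64)
    if (lengths <= 0).any():
        raise ValueError("quantify_reads: zero-length feature")
    out = {}
    for sample, reads in reads_by_sample.items():
        total = float(totals[sample]) if totals else float(len(reads))
        if total <= 0:
            raise ValueError(f"quantify_reads: sample {sample} has no reads")
        counts = np.zeros(len(features), dtype=np.int64)
        for chrom, sub in reads.groupby("chrom"):
            sel = features["chrom"] == chrom
            if not sel.any():
                continue
            r_starts = np.sort(sub["start"].to_numpy(np.int64))
            r_ends = np.sort(sub["end"].to_numpy(np.int64))
            f_starts = features.loc[sel, "start"].to_numpy(np.int64)
            f_ends = features.loc[sel, "end"].to_numpy(np.int64)
            # overlap iff read.start < f.end and read.end > f.start
            n = np.searchsorted(r_starts, f_ends, side="left") - np.searchsorted(
                r_ends, f_starts, side="right"
            )
            counts[sel.to_numpy()] = n
        out[sample] = counts * 1e9 / (total * lengths)
    idx = features["name"] if "name" in features.columns else features.index
    return pd.DataFrame(out, index=pd.Index(idx, name="feature"))


def quantify_bins(
    bin_values: np.ndarray,
    grid: BinGrid,
    features: pd.DataFrame,
    sample_ids: list,
    mode: str = "mean_rms",
) -> pd.DataFrame:
    """Feature-level score from bin-level signal.

    mode "mean_rms": nan-mean of scores of bins overlapping the feature.
    mode "rpkm": counts summed over the primary non-overlapping half-grid
    (bins starting at multiples of bin_size, which partition the genome so
    no read is double-counted), scaled as count * 1e9 / (total * length).
    """
    bin_values = np.atleast_2d(np.asarray(bin_values, dtype=float))
    if bin_values.shape[0] == grid.n_bins and bin_values.shape[1] == len(sample_ids):
        pass
    elif bin_values.shape == (len(sample_ids), grid.n_bins):
        bin_values = bin_values.T
    else:
        raise ValueError("quantify_bins: bin_values shape mismatch")
    lengths = (features["end"] - features["start"]).to_numpy(np.int64)
    if (lengths <= 0).any():
        raise ValueError("quantify_bins: zero-length feature")

    if mode == "rpkm":
        primary = grid.starts % grid.bin_size == 0
        totals = bin_values[primary].sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("quantify_bins: sample with zero total count")

    out = np.zeros((len(features), len(sample_ids)))
    for chrom, (lo, hi) in grid.offsets.items():
        sel = (features["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        b_starts = grid.starts[lo:hi]
        b_ends = grid.ends[lo:hi]
        f_starts = features.loc[sel, "start"].to_numpy(np.int64)
        f_ends = features.loc[sel, "end"].to_numpy(np.int64)
        for j, (fs, fe) in enumerate(zip(f_starts, f_ends)):
            if mode == "mean_rms":
                bsel = (b_starts < fe) & (b_ends > fs)
                if bsel.any():
                    with np.errstate(invalid="ignore"):
                        out[np.flatnonzero(sel)[j]] = np.nanmean(
                            bin_values[lo:hi][bsel], axis=0
                        )
            else:  # rpkm on the primary half-grid, bin midpoint inside feature
                mid = (b_starts + b_ends) // 2
                bsel = (b_starts % grid.bin_size == 0) & (mid >= fs) & (mid < fe)
                out[np.flatnonzero(sel)[j]] = bin_values[lo:hi][bsel].sum(axis=0)
    if mode == "rpkm":
        out = out * 1e9 / (totals[None, :] * lengths[:, None])
    out = np.nan_to_num(out, nan=0.0)
    idx = features["name"] if "name" in features.columns else features.index
    return pd.DataFrame(out, index=pd.Index(idx, name="feature"), columns=sample_ids)


# ---------------------------------------------------------------------------
# CV ranking and DMR selection
# ---------------------------------------------------------------------------

def cv_statistic(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Coefficient of variance: SD / (mean + 1), sample SD (n-1)."""
    sd = np.std(values, axis=axis, ddof=1)
    mean = np.mean(values, axis=axis)
    return sd / (mean + 1.0)


def cv_rank(
    matrix: FeatureMethylationMatrix,
    group_by: str = "tissue_group",
) -> pd.DataFrame:
    """Rank features by cross-tissue (or cross-sample) variability.

    With ``group_by`` = "tissue_group" (or "tissue"), CV is computed over
    per-group mean profiles — the 3-way cortex/cerebellum/blood contrast.
    With ``group_by`` = "sample", CV is computed over individual samples.
    Ranks are 1..n in decreasing CV, ties broken by feature id.
    """
    if group_by == "sample":
        profile = matrix.values
    else:
        profile = matrix.group_means(group_by)
    if profile.shape[1] < 2:
        raise ValueError("cv_rank: need at least 2 groups/samples")
    cv = cv_statistic(profile.to_numpy(), axis=1)
    feats = matrix.features
    rec = pd.DataFrame(
        {
            "feature": profile.index,
            "feature_class": feats["feature_class"].to_numpy(),
            "cv": cv,
        }
    )
    for g in profile.columns:
        rec[f"mean_{g}"] = profile[g].to_numpy()
    rec = rec.sort_values(
        ["cv", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    rec["rank"] = np.arange(1, len(rec) + 1)
    return rec


def select_dmrs(
    records: pd.DataFrame,
    top_k: int | None = None,
    cv_gt: float | None = None,
) -> pd.DataFrame:
    """Select the DMR set: either the top-k by CV or all with CV > threshold."""
    if (top_k is None) == (cv_gt is None):
        raise ValueError("select_dmrs: give exactly one of top_k or cv_gt")
    ranked = records.sort_values("rank")
    if top_k is not None:
        if top_k > len(ranked):
            logger.warning(
                "select_dmrs: top_k=%d exceeds %d features; returning all",
                top_k, len(ranked),
            )
            top_k = len(ranked)
        return ranked.head(top_k).reset_index(drop=True)
    return ranked[ranked["cv"] > cv_gt].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Class enrichment
# ---------------------------------------------------------------------------

def enrichment_oe(
    dmr_records: pd.DataFrame,
    all_features: pd.DataFrame,
    class_column: str = "feature_class",
    min_expected: float = 1.0,
) -> pd.DataFrame:
    """Observed/expected feature-class enrichment of a DMR set.

    Expected counts come from genome-wide class proportions:
    E_c = |DMR| * n_c / N.  Classes with E_c < ``min_expected`` are pooled
    into "other" (logged).  A Pearson goodness-of-fit chi-square over the
    resulting classes (df = K - 1) tests departure from proportionality.

    Returns a table with one row per class plus ``chi2``, ``df`` and
    ``p_value`` repeated on every row.
    """
    genome = all_features[class_column].value_counts()
    if len(genome) < 2:
        raise ValueError("enrichment_oe: need >= 2 feature classes")
    n_dmr = len(dmr_records)
    observed = dmr_records[class_column].value_counts().reindex(genome.index, fill_value=0)
    expected = n_dmr * genome / genome.sum()

    pool = expected < min_expected
    if pool.any():
        logger.info("enrichment_oe: pooling %d classes with expected < %g "
                    "into 'other'", int(pool.sum()), min_expected)
        obs = observed[~pool]
        exp = expected[~pool]
        obs.loc["other"] = observed[pool].sum()
        exp.loc["other"] = expected[pool].sum()
        observed, expected = obs, exp
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(observed) - 1
    p = float(stats.chi2.sf(chi2, df))
    return pd.DataFrame(
        {
            "feature_class": observed.index,
            "observed": observed.to_numpy(),
            "expected": expected.to_numpy(),
            "oe": observed.to_numpy() / expected.to_numpy(),
            "chi2": chi2,
            "df": df,
            "p_value": p,
        }
    ).reset_index(drop=True)


def enrichment_2x2(
    dmr_records: pd.DataFrame,
    all_features: pd.DataFrame,
    feature_class: str,
    class_column: str = "feature_class",
) -> dict:
    """Per-class 2x2 chi-square (in/out of DMR set vs in/out of class),
    with Yates continuity correction.  Optional alternative to the K-class
    goodness of fit."""
    in_dmr = set(dmr_records["feature"])
    is_dmr = all_features.index.to_series().isin(in_dmr) if "feature" not in all_features.columns else all_features["name"].isin(in_dmr)
    is_cls = all_features[class_column] == feature_class
    table = np.array(
        [
            [int((is_dmr & is_cls).sum()), int((is_dmr & ~is_cls).sum())],
            [int((~is_dmr & is_cls).sum()), int((~is_dmr & ~is_cls).sum())],
        ]
    )
    chi2, p, df, _ = stats.chi2_contingency(table, correction=True)
    return {"table": table, "chi2": float(chi2), "df": int(df), "p_value": float(p)}


# ---------------------------------------------------------------------------
# Sample structure
# ---------------------------------------------------------------------------

def sample_correlation(matrix: FeatureMethylationMatrix) -> pd.DataFrame:
    """Sample x sample Pearson correlation of methylation profiles."""
    vals = matrix.values.to_numpy(dtype=float)
    sds = vals.std(axis=0)
    if (sds == 0).any():
        bad = matrix.values.columns[sds == 0].tolist()
        raise ValueError(f"sample_correlation: zero-variance sample(s): {bad}")
    corr = np.corrcoef(vals.T)
    return pd.DataFrame(corr, index=matrix.values.columns, columns=matrix.values.columns)


def cluster_samples(corr: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Average-linkage hierarchical clustering on Pearson dissimilarity 1 - r.

    Returns (scipy linkage matrix, leaf order as sample ids).  Sample order
    is canonicalized (sorted by id) before linkage so the result does not
    depend on input column order.
    """
    if corr.isna().any().any():
        raise ValueError("cluster_samples: NaN in correlation matrix")
    order = sorted(corr.columns)
    c = corr.loc[order, order].to_numpy(dtype=float)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    leaves = hierarchy.leaves_list(link)
    return link, [order[i] for i in leaves]


def cut_clusters(link: np.ndarray, sample_ids: list, k: int) -> pd.Series:
    """Cut the dendrogram into k flat clusters (sample id -> cluster label).

    ``sample_ids`` must be the canonical (sorted) order used by
    :func:`cluster_samples`."""
    order = sorted(sample_ids)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=order)


def cluster_purity(assignments: pd.Series, truth: pd.Series) -> float:
    """Fraction of samples whose cluster's majority truth label matches
    their own truth label."""
    df = pd.DataFrame({"cluster": assignments, "truth": truth.loc[assignments.index]})
    correct = 0
    for _, sub in df.groupby("cluster"):
        correct += sub["truth"].value_counts().iloc[0]
    return correct / len(df)


def pca_samples(
    matrix: FeatureMethylationMatrix, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the feature-centered matrix.

    Returns (scores DataFrame samples x components, explained variances,
    non-increasing)."""
    X = matrix.values.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < n_components:
        raise ValueError("pca_samples: fewer samples than components")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("pca_samples: constant matrix")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.values.columns, columns=cols),
        pca.explained_variance_,
    )


# ---------------------------------------------------------------------------
# Between-individual differences
# ---------------------------------------------------------------------------

def individual_differences(
    matrix: FeatureMethylationMatrix,
    ind_a: str,
    ind_b: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature methylation difference between two individuals, per tissue
    group, and the cross-tissue correlation of those differences.

    For each tissue group t (samples of one group averaged, so cortex is the
    mean over its regions): d_t(f) = value(f, ind_a, t) - value(f, ind_b, t).
    Returns (difference table features x groups, correlation table with
    Pearson r and a feature-permutation p-value for every group pair).
    Swapping the individuals negates every difference and leaves the
    correlations unchanged.
    """
    samples = matrix.samples
    groups = sorted(samples["tissue_group"].unique())
    diffs = {}
    for g in groups:
        for ind in (ind_a, ind_b):
            sel = (samples["tissue_group"] == g) & (samples["individual_id"] == ind)
            if not sel.any():
                raise ValueError(
                    f"individual_differences: individual {ind} missing in "
                    f"tissue group {g}"
                )
        a = matrix.values.loc[:, (samples["tissue_group"] == g) & (samples["individual_id"] == ind_a)].mean(axis=1)
        b = matrix.values.loc[:, (samples["tissue_group"] == g) & (samples["individual_id"] == ind_b)].mean(axis=1)
        diffs[g] = a - b
    diff_table = pd.DataFrame(diffs)

    rng = np.random.default_rng(seed)
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            x = diff_table[g1].to_numpy()
            y = diff_table[g2].to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                r = float(np.corrcoef(x, y)[0, 1])
                n_ge = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(len(y))
                    if abs(np.corrcoef(x, y[perm])[0, 1]) >= abs(r):
                        n_ge += 1
            p = (1 + n_ge) / (n_permutations + 1)
            rows.append({"group_a": g1, "group_b": g2, "r": r, "p_value": p})
    return diff_table, pd.DataFrame(rows)


def variability_by_class(
    diff_table: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Mean |between-individual difference| per feature class and tissue
    group — the per-category summary of individual variability."""
    df = diff_table.abs()
    df["feature_class"] = features.loc[diff_table.index, "feature_class"].to_numpy()
    return df.groupby("feature_class").mean()


# ---------------------------------------------------------------------------
# Genic metaprofile
# ---------------------------------------------------------------------------

def metagene_profile(
    scores: np.ndarray,
    grid: BinGrid,
    genes: pd.DataFrame,
    n_body_bins: int = 40,
    flank: int = 2000,
    n_flank_bins: int = 10,
) -> tuple[np.ndarray, int, int]:
    """Average signal profile across gene bodies and fixed-width flanks.

    Each gene body is rescaled to ``n_body_bins`` segments; each flank is
    split into ``n_flank_bins`` windows of ``flank / n_flank_bins`` bp.
    Minus-strand genes are reversed so the profile always runs 5' -> 3'.
    The bin signal is treated as piecewise-constant on the grid's step
    windows; segment values are exact length-weighted means of that step
    function.  Genes with a body shorter than ``n_body_bins`` bp are
    skipped (counted).

    Returns (profile of length 2*n_flank_bins + n_body_bins, genes used,
    genes skipped).
    """
    from .coupling_norm import step_window_values

    if flank < 0:
        raise ValueError("metagene_profile: flank must be >= 0")
    windows = step_window_values(np.asarray(scores, dtype=float), grid)
    # cumulative integral of the step function per chromosome
    integrals = {}
    for chrom, win in windows.items():
        L = grid.chrom_lengths[chrom]
        edges = np.minimum(np.arange(len(win) + 1) * grid.step, L)
        seg = np.nan_to_num(win, nan=0.0) * np.diff(edges)
        wgt = (~np.isnan(win)).astype(float) * np.diff(edges)
        integrals[chrom] = (edges, np.concatenate([[0], np.cumsum(seg)]),
                            np.concatenate([[0], np.cumsum(wgt)]))

    def seg_mean(chrom, a, b):
        edges, cum, cw = integrals[chrom]
        L = edges[-1]
        a, b = max(0, a), min(b, L)
        if b <= a:
            return np.nan
        ia = np.interp(a, edges, cum)
        ib = np.interp(b, edges, cum)
        wa = np.interp(a, edges, cw)
        wb = np.interp(b, edges, cw)
        return (ib - ia) / (wb - wa) if wb > wa else np.nan

    flank_w = flank / n_flank_bins if n_flank_bins else 0
    total = 2 * n_flank_bins + n_body_bins
    profiles = []
    n_skipped = 0
    for row in genes.itertuples(index=False):
        body = row.end - row.start
        if body < n_body_bins:
            n_skipped += 1
            continue
        if row.chrom not in integrals:
            n_skipped += 1
            continue
        vals = np.full(total, np.nan)
        # upstream flank, body segments, downstream flank in + orientation
        for k in range(n_flank_bins):
            vals[k] = seg_mean(row.chrom, row.start - flank + k * flank_w,
                               row.start - flank + (k + 1) * flank_w)
        bounds = row.start + np.round(np.linspace(0, body, n_body_bins + 1)).astype(int)
        for k in range(n_body_bins):
            vals[n_flank_bins + k] = seg_mean(row.chrom, bounds[k], bounds[k + 1])
        for k in range(n_flank_bins):
            vals[n_flank_bins + n_body_bins + k] = seg_mean(
                row.chrom, row.end + k * flank_w, row.end + (k + 1) * flank_w
            )
        if row.strand == "-":
            vals = vals[::-1]
        profiles.append(vals)
    if n_skipped:
        logger.info("metagene_profile: skipped %d genes (short body or "
                    "unknown chromosome)", n_skipped)
    if not profiles:
        return np.full(total, np.nan), 0, n_skipped
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(np.vstack(profiles), axis=0)
    return profile, len(profiles), n_skipped
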