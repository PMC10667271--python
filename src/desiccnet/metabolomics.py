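"""Metabolite fold-change, heatmap-ordering and PCA analyses.

Fold changes are ratios of state means to the hydrated mean, per
metabolite x tissue x state, with a two-sided Welch t-test on log
abundances and BH adjustment within each tissue x state contrast (the
same machinery as the transcript DEG stage, for internal consistency).
A raw-p mode is available since significance marks on reported panels
do not always reflect adjustment. Heatmap ordering uses hierarchical
clustering (Euclidean on z-scored rows, average linkage) and PCA uses
per-metabolite autoscaling — standard choices for GC-MS panels whose
metabolites span orders of magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .diffexpr import adjust_bh

__all__ = ["metabolite_fold_changes", "heatmap_order", "run_pca", "PCAResult"]

logger = logging.getLogger(__name__)


def _impute_zeros(mat: pd.DataFrame) -> pd.DataFrame:
    """Replace zeros by half the metabolite's minimum positive value."""
    out = mat.copy()
    for name, row in out.iterrows():
        vals = row.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError(f"negative abundance for metabolite {name!r}")
        zeros = vals == 0
        if zeros.any():
            positive = vals[~zeros]
            if positive.size == 0:
                raise ValueError(f"metabolite {name!r} is all zero")
            fill = positive.min() / 2.0
            logger.info("imputing %d zero(s) for %s with %g",
                        int(zeros.sum()), name, fill)
            vals[zeros] = fill
            out.loc[name] = vals
    return out


def metabolite_fold_changes(mat: pd.DataFrame, samples: pd.DataFrame,
                            alpha: float = 0.05, adjust: bool = True,
                            reference: str = "hydrated") -> pd.DataFrame:
    """Fold change of each metabolite versus hydrated, per tissue x state.

    Returns a table with columns metabolite, tissue, state, fold_change
    (state mean / hydrated mean, raw scale), p_raw (Welch t on log
    abundances), p_adj (BH within tissue x state; equals p_raw when
    ``adjust=False``) and significant_up (fold_change > 1 and p_adj <
    alpha).
    """
    mat = _impute_zeros(mat)
    log_mat = np.log(mat)
    rows = []
    for tissue in samples["tissue"].unique():
        tsheet = samples[samples["tissue"] == tissue]
        ref_cols = tsheet.loc[tsheet["state"] == reference, "sample_id"].tolist()
        if len(ref_cols) < 2:
            raise ValueError(
                f"missing hydrated reference group for tissue {tissue!r}")
        ref = mat[ref_cols].to_numpy()
        ref_log = log_mat[ref_cols].to_numpy()
        for state in tsheet["state"].unique():
            if state == reference:
                continue
            cols = tsheet.loc[tsheet["state"] == state, "sample_id"].tolist()
            grp = mat[cols].to_numpy()
            grp_log = log_mat[cols].to_numpy()
            fc = grp.mean(axis=1) / ref.mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                _, p_raw = stats.ttest_ind(grp_log, ref_log, axis=1,
                                           equal_var=False)
            p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
            p_adj = adjust_bh(p_raw) if adjust else p_raw
            for i, met in enumerate(mat.index):
                rows.append({
                    "metabolite": met, "tissue": tissue, "state": state,
                    "fold_change": float(fc[i]),
                    "p_raw": float(p_raw[i]), "p_adj": float(p_adj[i]),
                    "significant_up": bool(fc[i] > 1 and p_adj[i] < alpha),
                })
    return pd.DataFrame(rows)


def heatmap_order(mat: pd.DataFrame, metric: str = "euclidean",
                  method: str = "average"):
    """Hierarchical-clustering leaf orders for heatmap display.

    Rows (metabolites) are z-scored before clustering; columns
    (samples) are clustered on the same z-scored matrix. Returns
    ``(row_order, column_order)`` as lists of labels. A constant matrix
    (degenerate distances) returns the input order with a warning.
    """
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    x = mat.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).all():
        logger.warning("constant matrix: returning input order")
        return list(mat.index), list(mat.columns)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=1, keepdims=True)) / sd_safe[:, None]

    def _leaves(data):
        link = hierarchy.linkage(pdist(data, metric=metric), method=method)
        return hierarchy.leaves_list(link)

    row_order = [mat.index[i] for i in _leaves(z)]
    col_order = [mat.columns[i] for i in _leaves(z.T)]
    return row_order, col_order


@dataclass
class PCAResult:
    """Principal-component analysis of a metabolite panel.

    scores: samples x components; loadings: metabolites x components;
    variance_explained: fraction of total variance per component,
    non-increasing.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray


def run_pca(mat: pd.DataFrame, n_components: int | None = None,
            scale: bool = True) -> PCAResult:
    """PCA of samples in metabolite space.

    The metabolite x sample matrix is transposed to samples x
    metabolites, column-centered and (by default) scaled to unit
    variance per metabolite, then decomposed by SVD.
    """
    x = mat.to_numpy(dtype=float).T  # samples x metabolites
    n_samples, n_feat = x.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    max_comp = min(n_samples, n_feat)
    if n_components is None:
        n_components = min(n_samples - 1, n_feat)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(dim)={max_comp}")
    if scale:
        sd = x.std(axis=0, ddof=0)
        x = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    comp_names = [f"PC{i+1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=mat.columns, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=mat.index,
                              columns=comp_names),
        variance_explained=pca.explained_variance_ratio_,
    )
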