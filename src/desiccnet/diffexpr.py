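"""Per-tissue, per-state differential expression against the hydrated
reference.

The enrichment rule: a gene passes if its
absolute fold change is >= 2 (inclusive) AND its Benjamini-Hochberg
adjusted p value is < 0.05 (strict). Expression is assumed to be on
log2 scale, so the fold-change criterion becomes |log2FC| >= 1.

The location test is a two-sided Welch t-test on log2 values — the
minimal defensible choice for triplicate designs — applied gene-wise;
it is isolated in :func:`test_state_vs_hydrated` as a swap point.
Genes with zero variance in both groups are flagged non-testable
(p = NaN) and excluded from the BH family rather than assigned p = 1,
so they do not dilute the correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["test_state_vs_hydrated", "adjust_bh", "filter_degs",
           "tag_categories", "deg_tables_for_tissue", "CATEGORY_VOCABULARY"]

#: Functional-category vocabulary for DEG tagging.
CATEGORY_VOCABULARY = frozenset({
    "MYB", "NAC", "WRKY", "bZIP", "DREB", "LEA", "antioxidant",
    "trehalose/T6P", "autophagy", "energy-metabolism", "signalling",
    "other",
})


def _group_columns(samples: pd.DataFrame, tissue: str, state: str):
    sel = samples[(samples["tissue"] == tissue) & (samples["state"] == state)]
    return sel["sample_id"].tolist()


def test_state_vs_hydrated(expr: pd.DataFrame, samples: pd.DataFrame,
                           tissue: str, state: str,
                           reference: str = "hydrated") -> pd.DataFrame:
    """Gene-wise Welch t-test of one dehydration state versus hydrated.

    Parameters
    ----------
    expr : DataFrame
        genes x samples, log2 scale.
    samples : DataFrame
        sample sheet with sample_id, tissue, state columns.
    tissue, state : str
        The contrast cell; compared against ``reference`` in the same
        tissue.

    Returns
    -------
    DataFrame with one row per gene: gene, tissue, state, log2fc,
    p_raw, p_adj, direction, passes. ``log2fc`` is mean(state) -
    mean(reference). Non-testable genes carry NaN p values and never
    pass. ``p_adj`` is BH within this contrast, over testable genes.
    """
    cols_a = _group_columns(samples, tissue, state)
    cols_b = _group_columns(samples, tissue, reference)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"need >= 2 replicates per group for tissue={tissue!r}, "
            f"state={state!r} vs {reference!r} "
            f"(got {len(cols_a)} and {len(cols_b)})")

    a = expr[cols_a].to_numpy(dtype=float)
    b = expr[cols_b].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p_raw = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p_raw = np.asarray(p_raw, dtype=float)

    # identical values in both groups: no evidence of change
    same = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p_raw[same & (log2fc == 0)] = np.nan  # non-testable, excluded from BH

    p_adj = np.full_like(p_raw, np.nan)
    testable = ~np.isnan(p_raw)
    if testable.any():
        p_adj[testable] = adjust_bh(p_raw[testable])

    table = pd.DataFrame({
        "gene": expr.index,
        "tissue": tissue,
        "state": state,
        "log2fc": log2fc,
        "p_raw": p_raw,
        "p_adj": p_adj,
    })
    return filter_degs(table)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values.

    Order-preserving, capped at 1; input order is retained.

    Raises
    ------
    ValueError
        If any value lies outside [0, 1] or is missing.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1] with no missing values")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(table: pd.DataFrame, fc_threshold: float = 2.0,
                alpha: float = 0.05) -> pd.DataFrame:
    """Apply the DEG rule: |FC| >= fc_threshold AND adjusted p < alpha.

    The fold-change boundary is inclusive and the p boundary strict,
    taken literally. Adds/overwrites ``passes`` and ``direction``
    columns; NaN p_adj never passes.
    """
    out = table.copy()
    lfc_cut = np.log2(fc_threshold)
    p_ok = out["p_adj"].to_numpy() < alpha  # NaN compares False
    fc_ok = np.abs(out["log2fc"].to_numpy()) >= lfc_cut
    passes = p_ok & fc_ok
    out["passes"] = passes
    direction = np.where(out["log2fc"].to_numpy() > 0, "up", "down")
    out["direction"] = np.where(passes, direction, "none")
    return out


def tag_categories(genes, annotation: dict | None = None) -> pd.DataFrame:
    """Attach functional-category labels to genes.

    ``annotation`` maps gene -> set/list of labels from
    :data:`CATEGORY_VOCABULARY`; unannotated genes get ``{"other"}``.
    """
    annotation = annotation or {}
    rows = []
    for g in genes:
        labels = set(annotation.get(g, ())) or {"other"}
        bad = labels - CATEGORY_VOCABULARY
        if bad:
            raise ValueError(f"unknown category labels for {g!r}: {sorted(bad)}")
        rows.append({"gene": g, "categories": frozenset(labels)})
    return pd.DataFrame(rows)


def deg_tables_for_tissue(expr: pd.DataFrame, samples: pd.DataFrame,
                          tissue: str, fc_threshold: float = 2.0,
                          alpha: float = 0.05,
                          reference: str = "hydrated") -> dict:
    """DEG table per non-reference state of one tissue.

    Returns ``{state: DEGTable}`` with the rule applied at the given
    thresholds; BH is applied separately within each contrast.
    """
    states = [s for s in samples.loc[samples["tissue"] == tissue, "state"].unique()
              if s != reference]
    out = {}
    for state in states:
        t = test_state_vs_hydrated(expr, samples, tissue, state, reference)
        out[state] = filter_degs(t, fc_threshold=fc_threshold, alpha=alpha)
    return out
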