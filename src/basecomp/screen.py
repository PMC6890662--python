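"""Systematic screen for tumor- vs TME-expressed transcription factors.

Bulk tumors are mixtures of malignant and microenvironment cells while cancer
cell lines are pure tumor, so two indirect comparisons locate where a TF is
expressed: (1) the Spearman correlation of its expression with tumor purity
across tumor samples, and (2) a two-sample t-test of its within-sample
expression *ranks* in tumors versus cell lines (ranks make the two platforms
comparable; they are computed over the shared gene universe).  A TF is called
TME-specific when it anti-correlates with purity (SCC <= -cutoff) AND ranks
significantly higher in tumors than in cell lines (t > 0, p < cutoff);
tumor-specific is the mirror call.  Everything else stays unclassified.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .compartment import purity_correlation
from .errors import ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["rank_transform", "rank_ttest", "classify_tfs", "screen_tfs"]


def rank_transform(em: ExpressionMatrix) -> pd.DataFrame:
    """Within-sample ascending midranks (rank n = highest expression)."""
    values = em.values
    if values.isna().any().any():
        raise ValidationError("rank transform requires a complete matrix")
    ranks = stats.rankdata(values.to_numpy(), axis=0)
    return pd.DataFrame(ranks, index=values.index, columns=values.columns)


def rank_ttest(
    tumor_ranks: pd.DataFrame,
    cellline_ranks: pd.DataFrame,
    genes: Iterable[str],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-TF two-sample t-test of tumor ranks minus cell-line ranks.

    Positive t = ranked higher in tumor tissue (TME-leaning).  Welch's
    unequal-variance statistic by default; ``equal_var=True`` restores the
    pooled form.  Genes with zero variance and equal means in both groups get
    t = 0, p = 1 and a degenerate flag.
    """
    genes = pd.Index(genes).astype(str)
    if tumor_ranks.shape[1] < 3 or cellline_ranks.shape[1] < 3:
        raise ValidationError("need >= 3 samples per group for the rank t-test")
    missing = genes.difference(tumor_ranks.index).union(genes.difference(cellline_ranks.index))
    if len(missing):
        raise ValidationError(f"TFs absent from a rank matrix: {missing.tolist()[:10]}")
    a = tumor_ranks.loc[genes].to_numpy()
    b = cellline_ranks.loc[genes].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.warning("rank_ttest: %d degenerate TFs (zero variance) set to p=1",
                       int(degenerate.sum()))
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    return pd.DataFrame(
        {"t_stat": t, "p_value": p, "degenerate": degenerate}, index=genes
    )


def classify_tfs(
    res: pd.DataFrame,
    scc_cutoff: float = 0.5,
    p_cutoff: float = 0.001,
) -> pd.DataFrame:
    """Label TFs from combined purity-SCC and rank t-test evidence.

    ``res`` needs columns ``scc_purity``, ``t_stat``, ``p_value``.  Labels:
    ``tme_specific`` (SCC <= -scc_cutoff, t > 0, p < p_cutoff),
    ``tumor_specific`` (SCC >= scc_cutoff, t < 0, p < p_cutoff), else
    ``unclassified``; every TF gets exactly one label.
    """
    for col in ("scc_purity", "t_stat", "p_value"):
        if col not in res.columns:
            raise ValidationError(f"classify_tfs: missing column {col!r}")
    out = res.copy()
    sig = out["p_value"] < p_cutoff
    tme = (out["scc_purity"] <= -scc_cutoff) & (out["t_stat"] > 0) & sig
    tumor = (out["scc_purity"] >= scc_cutoff) & (out["t_stat"] < 0) & sig
    label = np.where(tme, "tme_specific", np.where(tumor, "tumor_specific", "unclassified"))
    out["label"] = label
    out.attrs.update({"scc_cutoff": scc_cutoff, "p_cutoff": p_cutoff})
    return out


def screen_tfs(
    tumor_em: ExpressionMatrix,
    cellline_em: ExpressionMatrix,
    purity: pd.Series,
    tf_list: Iterable[str],
    scc_cutoff: float = 0.5,
    p_cutoff: float = 0.001,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Full screen: purity SCC + tumor-vs-cell-line rank t-test + labels.

    Ranks are computed over the gene universe shared by both matrices so rank
    scales are comparable across platforms.
    """
    tf_list = pd.Index(tf_list).astype(str)
    shared = tumor_em.gene_ids.intersection(cellline_em.gene_ids)
    if shared.empty:
        raise ValidationError("tumor and cell-line matrices share no genes")
    missing_tfs = tf_list.difference(shared)
    if len(missing_tfs):
        logger.warning("screen_tfs: %d TFs absent from the shared universe, dropped",
                       len(missing_tfs))
        tf_list = tf_list.intersection(shared)
    t_sub = ExpressionMatrix(tumor_em.values.loc[shared], normalized=False)
    c_sub = ExpressionMatrix(cellline_em.values.loc[shared], normalized=False)
    scc = purity_correlation(t_sub, purity).reindex(tf_list)
    tt = rank_ttest(rank_transform(t_sub), rank_transform(c_sub), tf_list,
                    equal_var=equal_var)
    res = pd.DataFrame({"scc_purity": scc, "t_stat": tt["t_stat"],
                        "p_value": tt["p_value"]})
    return classify_tfs(res, scc_cutoff=scc_cutoff, p_cutoff=p_cutoff)
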