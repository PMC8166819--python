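"""Immune-cell marker derivation from labeled single-cell counts.

Workflow (per immune cell type): QC-filter cells and genes, one-vs-rest
Wilcoxon rank-sum on log-normalized counts, keep genes with positive log
fold change and BH-adjusted p < 0.05, rank the survivors by the absolute
difference between the fraction of expressing cells in the target type and
in malignant cells (PCT difference), and keep the top 1%.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("tmedissect")


class EmptyResultError(RuntimeError):
    """A filtering step removed everything."""


@dataclass
class MarkerSet:
    """Ordered per-cell-type gene signatures with their ranking score."""

    signatures: dict[str, list[str]] = field(default_factory=dict)
    scores: dict[str, pd.Series] = field(default_factory=dict)

    def to_gmt(self, path: str) -> None:
        from .io import write_gmt

        write_gmt(self.signatures, path)

    @classmethod
    def from_gmt(cls, path: str) -> "MarkerSet":
        from .io import read_gmt

        sigs = read_gmt(path)
        return cls(signatures=sigs, scores={k: pd.Series(dtype=float) for k in sigs})


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def qc_filter(
    sc: ad.AnnData,
    min_features: int = 1000,
    max_features: int = 10000,
    min_cells: int = 3,
) -> ad.AnnData:
    """Remove cells whose detected-feature count lies outside
    ``[min_features, max_features]``, then genes detected in fewer than
    ``min_cells`` of the surviving cells.  Order is preserved.
    """
    if sc.n_obs == 0 or sc.n_vars == 0:
        return sc.copy()
    X = _dense(sc.X)
    n_features = (X > 0).sum(axis=1)
    keep_cells = (n_features >= min_features) & (n_features <= max_features)
    if not keep_cells.any():
        raise EmptyResultError(
            f"all {sc.n_obs} cells removed by the feature-count filter "
            f"[{min_features}, {max_features}]"
        )
    out = sc[keep_cells].copy()
    detected = (_dense(out.X) > 0).sum(axis=0)
    keep_genes = detected >= min_cells
    if not keep_genes.any():
        raise EmptyResultError("all genes removed by the min_cells filter")
    return out[:, keep_genes].copy()


def _lognorm(X: np.ndarray, scale: float = 1e4) -> np.ndarray:
    lib = X.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    return np.log1p(X / lib * scale)


def marker_stats(sc: ad.AnnData, target_type: str) -> pd.DataFrame:
    """One-vs-rest marker statistics for ``target_type``.

    Returns a DataFrame indexed by gene with columns ``log_fold_change``
    (log2, target vs rest, on library-normalized means), ``p_value``
    (two-sided Wilcoxon rank-sum), ``adj_p`` (BH across genes), and the
    expressing-cell fractions ``pct_in``, ``pct_malignant``, ``pct_rest``.
    """
    types = np.asarray(sc.obs["cell_type"].astype(str))
    if target_type not in set(types):
        raise ValueError(f"cell type {target_type!r} not present in the dataset")
    X = _dense(sc.X)
    in_mask = types == target_type
    rest_mask = ~in_mask
    mal_mask = types == "malignant"

    norm = X / np.where(X.sum(axis=1, keepdims=True) == 0, 1, X.sum(axis=1, keepdims=True)) * 1e4
    logn = np.log1p(norm)
    mean_in = norm[in_mask].mean(axis=0)
    mean_rest = norm[rest_mask].mean(axis=0) if rest_mask.any() else np.zeros(sc.n_vars)
    lfc = np.log2((mean_in + 1.0) / (mean_rest + 1.0))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if max(in_mask.sum(), rest_mask.sum()) <= 8:
            # small groups: per-gene call so scipy can pick the exact null
            p = np.array(
                [
                    stats.mannwhitneyu(
                        logn[in_mask, j], logn[rest_mask, j],
                        alternative="two-sided", method="auto",
                    ).pvalue
                    for j in range(logn.shape[1])
                ],
                dtype=float,
            )
        else:
            res = stats.mannwhitneyu(
                logn[in_mask], logn[rest_mask], axis=0, alternative="two-sided",
                method="asymptotic",
            )
            p = np.asarray(res.pvalue, dtype=float)
    # genes constant across all cells: exchangeable null, p = 1 by convention
    constant = X.max(axis=0) == X.min(axis=0)
    p[constant | ~np.isfinite(p)] = 1.0
    lfc[constant] = 0.0
    adj = multipletests(p, method="fdr_bh")[1]

    pct_in = (X[in_mask] > 0).mean(axis=0)
    pct_mal = (X[mal_mask] > 0).mean(axis=0) if mal_mask.any() else np.zeros(sc.n_vars)
    pct_rest = (X[rest_mask] > 0).mean(axis=0) if rest_mask.any() else np.zeros(sc.n_vars)

    out = pd.DataFrame(
        {
            "log_fold_change": lfc,
            "p_value": p,
            "adj_p": adj,
            "pct_in": pct_in,
            "pct_malignant": pct_mal,
            "pct_rest": pct_rest,
        },
        index=pd.Index(sc.var_names, name="gene"),
    )
    out.attrs["cell_type"] = target_type
    return out


def select_markers(stats_df: pd.DataFrame, top_frac: float = 0.01) -> tuple[list[str], pd.Series]:
    """Select the signature: keep genes with positive log fold change and
    adj_p < 0.05, sort by descending |pct_in - pct_malignant| (ties:
    |pct_in - pct_rest|, then gene id) and return the top
    ``ceil(top_frac * n_passing)`` together with their ranking score.
    """
    passing = stats_df[(stats_df["log_fold_change"] > 0) & (stats_df["adj_p"] < 0.05)]
    if passing.empty:
        warnings.warn("no gene passed the significance filter; empty signature", stacklevel=2)
        return [], pd.Series(dtype=float)
    score = (passing["pct_in"] - passing["pct_malignant"]).abs()
    tiebreak = (passing["pct_in"] - passing["pct_rest"]).abs()
    order = pd.DataFrame(
        {"score": score.to_numpy(), "tie": tiebreak.to_numpy(), "gene": list(passing.index)}
    )
    order = order.sort_values(["score", "tie", "gene"], ascending=[False, False, True])
    n = math.ceil(top_frac * len(passing))
    top = order.head(n)
    return top["gene"].tolist(), pd.Series(top["score"].to_numpy(), index=top["gene"].to_numpy())


def derive_marker_sets(
    sc: ad.AnnData,
    top_frac: float = 0.01,
    cell_types: list[str] | None = None,
) -> MarkerSet:
    """Run marker_stats + select_markers for every non-malignant cell type."""
    if cell_types is None:
        cell_types = [t for t in sc.obs["cell_type"].astype(str).unique() if t != "malignant"]
    ms = MarkerSet()
    for t in cell_types:
        stats_df = marker_stats(sc, t)
        genes, scores = select_markers(stats_df, top_frac=top_frac)
        ms.signatures[t] = genes
        ms.scores[t] = scores
    return ms
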