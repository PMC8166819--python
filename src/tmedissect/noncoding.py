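"""Putative mRNA targets/partners of dysregulated noncoding RNAs.

Spearman correlation between each noncoding RNA and all mRNAs, per tumor
type.  lncRNA partners: mRNAs significant (FDR < 0.05) in at least one tumor
type, ranked by the mean |rho| over the tumor types where the pair was
measured; the top 1% are the putative partners, with the edge sign given by
the sign of the mean rho.  miRNA targets: database membership AND negative,
significant correlation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("tmedissect")


def correlate(nc_expr: pd.Series, mrna_expr: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of one noncoding RNA against every mRNA column.

    Average ranks for ties; two-sided p via the t approximation; BH within
    the block.  Constant vectors yield missing values (never zero), logged.
    """
    common = nc_expr.index.intersection(mrna_expr.index)
    if len(common) < 10:
        raise ValueError(f"need >= 10 paired samples, got {len(common)}")
    x = nc_expr.loc[common].to_numpy(dtype=float)
    y = mrna_expr.loc[common].to_numpy(dtype=float)
    n = len(common)

    rho = np.full(y.shape[1], np.nan)
    if np.ptp(x) == 0:
        logger.warning("correlate: constant noncoding RNA vector; all correlations missing")
    else:
        rx = rankdata(x)
        ry = rankdata(y, axis=0)
        const = np.ptp(y, axis=0) == 0
        if const.any():
            logger.warning("correlate: %d constant mRNA column(s) emitted as missing", const.sum())
        rxc = rx - rx.mean()
        ryc = ry - ry.mean(axis=0)
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (rxc @ ryc) / denom
        rho[const] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    fdr = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {"rho": rho, "p_value": p, "fdr": fdr},
        index=pd.Index(mrna_expr.columns, name="gene"),
    )


def correlation_tables(
    nc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    tumor_type: pd.Series,
    sample_mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Long correlation table over (noncoding RNA, mRNA, tumor type).

    BH is applied within each noncoding RNA x tumor type family.  Blocks
    with < 10 paired samples are skipped with a warning.  ``sample_mask``
    restricts to retained (non-median) samples.
    """
    if sample_mask is not None:
        keep = sample_mask[sample_mask].index
        nc_expr = nc_expr.loc[nc_expr.index.intersection(keep)]
    blocks = []
    for tt, idx in nc_expr.groupby(
        tumor_type.reindex(nc_expr.index), observed=True
    ).groups.items():
        mr = mrna_expr.loc[mrna_expr.index.intersection(idx)]
        for nc in nc_expr.columns:
            try:
                res = correlate(nc_expr.loc[idx, nc], mr)
            except ValueError as exc:
                warnings.warn(f"block ({nc}, {tt}) skipped: {exc}", stacklevel=2)
                continue
            res = res.reset_index()
            res["noncoding"] = nc
            res["tumor_type"] = tt
            blocks.append(res)
    if not blocks:
        return pd.DataFrame(columns=["gene", "rho", "p_value", "fdr", "noncoding", "tumor_type"])
    return pd.concat(blocks, ignore_index=True)


@dataclass
class TargetSet:
    """Noncoding RNA -> putative target/partner mRNAs with the edge statistics."""

    targets: dict[str, pd.DataFrame] = field(default_factory=dict)

    def edges(self) -> pd.DataFrame:
        """Signed coexpression network as an edge list (source, target, sign, mean_rho)."""
        rows = []
        for nc, df in self.targets.items():
            for gene, row in df.iterrows():
                rows.append((nc, gene, "+" if row["mean_rho"] > 0 else "-", row["mean_rho"]))
        return pd.DataFrame(rows, columns=["source", "target", "sign", "mean_rho"])


def lncrna_targets(tables: pd.DataFrame, top_frac: float = 0.01) -> TargetSet:
    """Top-1% coexpression partners of each lncRNA.

    Keep mRNAs with FDR < 0.05 in at least one tumor type; rank by the mean
    |rho| over the tumor types where the pair was measured (missing values
    excluded, never zero-filled); return the top ``ceil(top_frac * n_kept)``.
    """
    out = TargetSet()
    if tables.empty:
        return out
    for nc, sub in tables.groupby("noncoding"):
        measured = sub.dropna(subset=["rho"])
        sig_genes = measured.loc[measured["fdr"] < 0.05, "gene"].unique()
        if len(sig_genes) == 0:
            warnings.warn(f"lncRNA {nc!r}: nothing significant", stacklevel=2)
            out.targets[nc] = pd.DataFrame(columns=["mean_abs_rho", "mean_rho"])
            continue
        stats_df = (
            measured[measured["gene"].isin(sig_genes)]
            .groupby("gene")["rho"]
            .agg(mean_abs_rho=lambda r: r.abs().mean(), mean_rho="mean")
        )
        n_top = math.ceil(top_frac * len(stats_df))
        ranked = stats_df.sort_values(
            ["mean_abs_rho", "gene"], ascending=[False, True], kind="stable"
        ).head(n_top)
        out.targets[nc] = ranked
    return out


def mirna_targets(tables: pd.DataFrame, target_db: dict[str, set[str]]) -> TargetSet:
    """Putative miRNA targets: gene in the interaction database AND
    negatively, significantly correlated (rho < 0 and FDR < 0.05 in at least
    one tumor type).  miRNAs absent from the database get an empty set.
    """
    out = TargetSet()
    for mir, sub in tables.groupby("noncoding"):
        if mir not in target_db:
            logger.warning("miRNA %s absent from the target database; empty set", mir)
            out.targets[mir] = pd.DataFrame(columns=["mean_abs_rho", "mean_rho"])
            continue
        db_genes = target_db[mir]
        measured = sub.dropna(subset=["rho"])
        hits = measured[
            measured["gene"].isin(db_genes)
            & (measured["rho"] < 0)
            & (measured["fdr"] < 0.05)
        ]
        if hits.empty:
            out.targets[mir] = pd.DataFrame(columns=["mean_abs_rho", "mean_rho"])
            continue
        pairs = (
            measured[measured["gene"].isin(hits["gene"].unique())]
            .groupby("gene")["rho"]
            .agg(mean_abs_rho=lambda r: r.abs().mean(), mean_rho="mean")
        )
        pairs = pairs[pairs["mean_rho"] < 0]
        out.targets[mir] = pairs.sort_values("mean_rho")
    return out
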