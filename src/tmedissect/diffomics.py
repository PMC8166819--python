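"""Differential multi-omics between inflamed and noninflamed samples.

TMM (trimmed mean of M-values) normalization of count libraries, per-tumor-
type differential expression on log-CPM (Welch t), pan-cancer aggregation
(a molecule counts as a pan-cancer signature member when it passes
|log2FC| > 1.5 and FDR < 0.05 in at least four tumor types), promoter-probe
differential methylation on M-values with the effect reported on the beta
scale, and a generic hypergeometric over-representation test.

Sign convention: positive log fold change = higher in noninflamed samples.
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

from .simulate import PROMOTER_REGIONS

logger = logging.getLogger("tmedissect")

INFLAMED, NONINFLAMED = "inflamed", "noninflamed"


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values, pairwise vs a reference sample)
# ---------------------------------------------------------------------------


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        raise ValueError("sample shares no doubly-nonzero gene with the reference")
    o, r = obs[mask].astype(float), ref[mask].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) variance of M; weights are its inverse
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = m.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n - math.floor(n * logratio_trim)
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n - math.floor(n * sum_trim)
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample TMM normalization factors (samples x genes counts).

    Reference = the sample whose upper-quartile count fraction is closest to
    the mean; 30% of extreme M-values and 5% of extreme A-values are trimmed
    (two-sided); the factor is 2 to the precision-weighted mean of the
    remaining M-values; factors are rescaled to geometric mean 1.
    """
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=1)
    if (lib == 0).any():
        raise ValueError("zero library size")
    f75 = np.array([np.quantile(X[i][X[i] > 0] / lib[i], 0.75) if (X[i] > 0).any() else 0.0
                    for i in range(X.shape[0])])
    ref_i = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(X.shape[0])
    for i in range(X.shape[0]):
        if i == ref_i:
            factors[i] = _tmm_pair(X[i], X[ref_i], lib[i], lib[ref_i])
        else:
            factors[i] = _tmm_pair(X[i], X[ref_i], lib[i], lib[ref_i])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.index, name="tmm_factor")


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    if factors is None:
        factors = tmm_factors(counts)
    eff = counts.sum(axis=1) * factors.loc[counts.index]
    return counts.div(eff, axis=0) * 1e6


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def de_test(counts: pd.DataFrame, labels: pd.Series, prior: float = 0.5) -> pd.DataFrame:
    """Inflamed-vs-noninflamed differential expression for one tumor type.

    ``counts`` is samples x molecules; ``labels`` maps each sample to
    "inflamed" or "noninflamed" (other samples are ignored).  log2FC =
    log2((mean CPM noninflamed + prior) / (mean CPM inflamed + prior)); p
    from a Welch t-test on log2(CPM + prior); BH across molecules.
    """
    labels = labels.reindex(counts.index)
    inf_idx = labels[labels == INFLAMED].index
    non_idx = labels[labels == NONINFLAMED].index
    if len(inf_idx) < 3 or len(non_idx) < 3:
        raise ValueError(
            f"need >= 3 samples per group (got {len(inf_idx)} inflamed, "
            f"{len(non_idx)} noninflamed)"
        )
    sub = counts.loc[list(inf_idx) + list(non_idx)]
    c = cpm(sub)
    m_inf = c.loc[inf_idx].mean(axis=0)
    m_non = c.loc[non_idx].mean(axis=0)
    lfc = np.log2((m_non + prior) / (m_inf + prior))
    logc = np.log2(c + prior)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(
            logc.loc[non_idx].to_numpy(),
            logc.loc[inf_idx].to_numpy(),
            axis=0,
            equal_var=False,
        )
    p = np.asarray(p, dtype=float)
    p[~np.isfinite(p)] = 1.0
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"logFC": lfc.to_numpy(), "p_value": p, "fdr": fdr},
        index=pd.Index(counts.columns, name="molecule"),
    )


def de_by_tumor_type(
    counts: pd.DataFrame,
    labels: pd.Series,
    tumor_type: pd.Series,
    molecule_class: str = "mRNA",
    prior: float = 0.5,
) -> pd.DataFrame:
    """Run de_test per tumor type; returns a long table with columns
    molecule, molecule_class, tumor_type, logFC, p_value, fdr.  Tumor types
    with fewer than 3 samples in either group are skipped with a warning.
    """
    blocks = []
    for tt, idx in counts.groupby(tumor_type.reindex(counts.index), observed=True).groups.items():
        try:
            res = de_test(counts.loc[idx], labels, prior=prior)
        except ValueError as exc:
            warnings.warn(f"tumor type {tt!r} skipped: {exc}", stacklevel=2)
            continue
        res = res.reset_index()
        res["tumor_type"] = tt
        res["molecule_class"] = molecule_class
        blocks.append(res)
    if not blocks:
        return pd.DataFrame(
            columns=["molecule", "logFC", "p_value", "fdr", "tumor_type", "molecule_class"]
        )
    return pd.concat(blocks, ignore_index=True)


@dataclass
class PanCancerSignature:
    """Molecules dysregulated in >= min_types tumor types, with per-type direction."""

    membership: dict[str, dict[str, str]] = field(default_factory=dict)
    #: mean log2FC across the tumor types in which the molecule passed
    mean_logfc: dict[str, float] = field(default_factory=dict)

    @property
    def members(self) -> list[str]:
        return sorted(self.membership)

    def up_in(self, phenotype: str) -> list[str]:
        """Molecules whose majority direction is up in ``phenotype``."""
        key = f"up_in_{phenotype}"
        out = []
        for mol, dirs in self.membership.items():
            votes = list(dirs.values())
            if votes.count(key) * 2 > len(votes):
                out.append(mol)
        return sorted(out)


def pan_cancer_aggregate(
    results: pd.DataFrame,
    lfc: float = 1.5,
    fdr: float = 0.05,
    min_types: int = 4,
) -> PanCancerSignature:
    """Aggregate per-tumor-type DE tables (long format from de_by_tumor_type):
    a molecule is included iff |log2FC| > ``lfc`` and FDR < ``fdr`` in at
    least ``min_types`` tumor types; the direction is recorded per type.
    """
    sig = PanCancerSignature()
    if results.empty:
        return sig
    hits = results[(results["logFC"].abs() > lfc) & (results["fdr"] < fdr)]
    for mol, sub in hits.groupby("molecule"):
        if sub["tumor_type"].nunique() >= min_types:
            sig.membership[mol] = {
                row["tumor_type"]: (
                    "up_in_noninflamed" if row["logFC"] > 0 else "up_in_inflamed"
                )
                for _, row in sub.iterrows()
            }
            sig.mean_logfc[mol] = float(sub["logFC"].mean())
    return sig


# ---------------------------------------------------------------------------
# differential methylation (promoter probes)
# ---------------------------------------------------------------------------


def dmp_test(
    beta: pd.DataFrame,
    labels: pd.Series,
    probe_annot: pd.DataFrame,
    promoter_regions: tuple[str, ...] = PROMOTER_REGIONS,
    delta_threshold: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Promoter differential methylation between inflamed and noninflamed.

    ``beta`` is probes x samples in [0, 1]; only probes annotated to a
    promoter region (TSS1500, TSS200, 5'UTR, 1stExon) are tested.  The test
    is a Welch t on M-values (logit2 of beta, clipped to [1e-3, 1 - 1e-3]);
    the effect ``delta_beta`` is mean noninflamed beta minus mean inflamed
    beta; BH across retained probes; a probe is significant iff
    adj_p < ``alpha`` and |delta_beta| > ``delta_threshold``.
    """
    annotated = beta.index.intersection(probe_annot.index)
    dropped = len(beta.index) - len(annotated)
    if dropped:
        logger.warning("dmp_test: %d probe(s) without annotation dropped", dropped)
    regions = probe_annot.loc[annotated, "region"]
    keep = annotated[regions.isin(promoter_regions)]
    labels = labels.reindex(beta.columns)
    inf_idx = labels[labels == INFLAMED].index
    non_idx = labels[labels == NONINFLAMED].index
    if len(inf_idx) < 2 or len(non_idx) < 2:
        raise ValueError("need >= 2 samples per group")

    b = beta.loc[keep]
    clipped = b.clip(1e-3, 1 - 1e-3)
    m = np.log2(clipped / (1 - clipped))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.ttest_ind(
            m[non_idx].to_numpy(), m[inf_idx].to_numpy(), axis=1, equal_var=False
        )
    p = np.asarray(p, dtype=float)
    p[~np.isfinite(p)] = 1.0
    adj = multipletests(p, method="fdr_bh")[1]
    delta = b[non_idx].mean(axis=1) - b[inf_idx].mean(axis=1)
    out = pd.DataFrame(
        {
            "delta_beta": delta.to_numpy(),
            "p_value": p,
            "adj_p": adj,
            "region": probe_annot.loc[keep, "region"].to_numpy(),
            "gene": probe_annot.loc[keep, "gene"].to_numpy(),
        },
        index=pd.Index(keep, name="probe"),
    )
    out["significant"] = (out["adj_p"] < alpha) & (out["delta_beta"].abs() > delta_threshold)
    return out


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------


def ora_test(
    query: set[str],
    annotation_sets: dict[str, set[str]] | set[str],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each
    annotation set, with fold enrichment = (overlap/|query|) /
    (|set|/|universe|); BH across sets when several are tested.
    """
    if not universe:
        raise ValueError("empty universe")
    single = not isinstance(annotation_sets, dict)
    sets = {"set": set(annotation_sets)} if single else {k: set(v) for k, v in annotation_sets.items()}
    q = set(query) & set(universe)
    big_n = len(universe)
    rows = []
    for name, s in sets.items():
        s = s & set(universe)
        k = len(q & s)
        p = float(stats.hypergeom.sf(k - 1, big_n, len(s), len(q)))
        fold = (k / len(q)) / (len(s) / big_n) if q and s else np.nan
        rows.append((name, k, fold, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "fold_enrichment", "p_value"])
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1] if len(out) else []
    return out.set_index("set")
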