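"""Single-sample immune enrichment scores and hot/cold classification.

The scorer is a single-sample weighted Kolmogorov-Smirnov running-sum
statistic over within-sample expression ranks: walking the genes from the
highest-expressed to the lowest, signature genes add ``rank^tau`` (normalized
by the signature total) and non-signature genes subtract ``1/(N - m)``; the
score is the running-sum value of maximum absolute magnitude, signed, and
lies in [-1, 1].  It is invariant to any strictly monotone transform of a
sample's expression.

Samples are then clustered within tumor type (k-means, k = 3, on z-scored
score columns) into inflamed / median / noninflamed, ordered by mean score;
median samples are excluded from downstream contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .markers import MarkerSet

logger = logging.getLogger("tmedissect")

TME_ORDER = ("noninflamed", "median", "inflamed")


@dataclass
class ImmuneScoreMatrix:
    """Samples x cell-type enrichment scores plus the tumor type of each sample."""

    scores: pd.DataFrame
    tumor_type: pd.Series | None = None
    missing_signatures: list[str] = field(default_factory=list)


@dataclass
class TMELabels:
    """Per-sample TME assignment; ``retained`` masks out the median group."""

    labels: pd.Series
    retained: pd.Series


def _es_core(ranks: np.ndarray, member: np.ndarray, tau: float) -> float:
    n = ranks.shape[0]
    m = int(member.sum())
    order = np.argsort(-ranks, kind="stable")  # highest expression first
    member_sorted = member[order]
    w = ranks[order] ** tau
    denom = w[member_sorted].sum()
    steps = np.where(member_sorted, w / denom, -1.0 / (n - m))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def enrichment_score(sample_ranks: pd.Series, gene_set: list[str], tau: float = 1.0) -> float:
    """Weighted-KS enrichment of ``gene_set`` in one sample's rank vector
    (rank 1 = lowest expression).  Score in [-1, 1]; +1 when the set occupies
    the top ``m`` ranks, -1 when it occupies the bottom ``m``.
    """
    ranks = pd.Series(sample_ranks)
    member = ranks.index.isin(set(gene_set))
    m = int(member.sum())
    if m == 0:
        raise ValueError("gene_set shares no genes with the rank universe")
    if m == len(ranks):
        raise ValueError("gene_set equals the whole universe; statistic undefined")
    return _es_core(ranks.to_numpy(dtype=float), member, tau)


def score_matrix(
    bulk_expr: pd.DataFrame,
    markers: MarkerSet,
    tau: float = 1.0,
    tumor_type: pd.Series | None = None,
) -> ImmuneScoreMatrix:
    """Per-sample enrichment score for every signature in ``markers``.

    ``bulk_expr`` is samples x genes; within-sample ranks use average ranks
    for ties.  Signature genes absent from the bulk universe are dropped with
    a warning; a signature with < 2 genes present yields an all-NaN column,
    flagged in ``missing_signatures``.
    """
    if bulk_expr.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    genes = bulk_expr.columns
    ranks = rankdata(bulk_expr.to_numpy(dtype=float), axis=1)
    cols: dict[str, np.ndarray] = {}
    missing: list[str] = []
    for name, sig in markers.signatures.items():
        present = [g for g in sig if g in set(genes)]
        dropped = len(sig) - len(present)
        if dropped:
            logger.warning("signature %s: %d gene(s) absent from the bulk universe", name, dropped)
        if len(present) < 2:
            warnings.warn(f"signature {name!r} has < 2 genes in the bulk universe", stacklevel=2)
            missing.append(name)
            cols[name] = np.full(bulk_expr.shape[0], np.nan)
            continue
        member = np.asarray(genes.isin(set(present)))
        cols[name] = np.array([_es_core(ranks[i], member, tau) for i in range(ranks.shape[0])])
    scores = pd.DataFrame(cols, index=bulk_expr.index)
    return ImmuneScoreMatrix(scores=scores, tumor_type=tumor_type, missing_signatures=missing)


def classify_tme(
    scores: ImmuneScoreMatrix | pd.DataFrame,
    tumor_type: pd.Series | None = None,
    k: int = 3,
    seed: int = 0,
    n_init: int = 50,
) -> TMELabels:
    """Cluster samples within each tumor type into inflamed/median/noninflamed.

    Score columns are z-scored within tumor type, k-means (k = 3, ``n_init``
    restarts, fixed seed) is run, and the clusters are ordered by the mean
    over their samples of the row-mean z-score: top -> inflamed, middle ->
    median, bottom -> noninflamed.  Median samples are dropped from the
    retained mask.  Tumor types with fewer than ``k`` samples are skipped
    with a warning.
    """
    if isinstance(scores, ImmuneScoreMatrix):
        df = scores.scores
        tumor_type = scores.tumor_type if tumor_type is None else tumor_type
    else:
        df = scores
    if k != 3:
        raise ValueError("the inflamed/median/noninflamed scheme requires k = 3")
    df = df.dropna(axis=1, how="all")
    if tumor_type is None:
        tumor_type = pd.Series("all", index=df.index)
    tumor_type = tumor_type.loc[df.index]

    labels = pd.Series(pd.NA, index=df.index, dtype=object)
    retained = pd.Series(False, index=df.index)
    for tt, idx in df.groupby(tumor_type, observed=True).groups.items():
        block = df.loc[idx]
        if len(block) < k:
            warnings.warn(f"tumor type {tt!r}: fewer samples than k={k}; skipped", stacklevel=2)
            continue
        z = (block - block.mean()) / block.std(ddof=0).replace(0.0, 1.0)
        # winsorize: a single extreme sample must not claim its own cluster
        z = z.clip(-2.5, 2.5)
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        assign = km.fit_predict(z.to_numpy())
        row_mean = z.mean(axis=1).to_numpy()
        cluster_mean = [row_mean[assign == c].mean() for c in range(k)]
        order = np.argsort(cluster_mean)  # low -> high mean score
        name_of = {int(order[i]): TME_ORDER[i] for i in range(k)}
        lab = np.array([name_of[int(c)] for c in assign], dtype=object)
        labels.loc[idx] = lab
        retained.loc[idx] = lab != "median"
    return TMELabels(labels=labels, retained=retained)
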