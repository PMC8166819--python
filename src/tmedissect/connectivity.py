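"""CMAP-style tag-list KS connectivity screening of a disease signature
against drug perturbation rank profiles.

The disease signature is the inflamed-vs-noninflamed transcriptomic
difference: ``up_tags`` = genes up in the inflamed (hot) TME, ``down_tags``
= genes up in the noninflamed (cold) TME.  A positive normalized
connectivity means the drug's profile mimics the inflamed signature, i.e.
the drug is a candidate cold-to-hot converter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("tmedissect")


@dataclass
class DiseaseSignature:
    up_tags: list[str]  # up in inflamed
    down_tags: list[str]  # up in noninflamed

    def validate(self, universe) -> None:
        up, down = set(self.up_tags), set(self.down_tags)
        if not up or not down:
            raise ValueError("both tag lists must be nonempty")
        if up & down:
            raise ValueError("tag lists must be disjoint")
        missing = (up | down) - set(universe)
        if missing:
            raise ValueError(f"{len(missing)} tag gene(s) absent from the drug universe")


def ks_tag_statistic(tag_positions, n_genes: int) -> float:
    """Signed tag-list KS statistic of the classic connectivity-map build.

    ``tag_positions`` are the strictly increasing ranks (1 = most
    up-regulated by the drug) of the t tag genes within a profile of
    ``n_genes``.  With V(j) the j-th position, a = max_j(j/t - V(j)/N) and
    b = max_j(V(j)/N - (j-1)/t); the statistic is a if a > b else -b.
    """
    v = np.asarray(tag_positions, dtype=float)
    t = v.size
    if t == 0 or t >= n_genes:
        raise ValueError("need 1 <= t < N tag positions")
    if np.any(v < 1) or np.any(v > n_genes) or np.any(np.diff(v) <= 0):
        raise ValueError("tag positions must be strictly increasing within 1..N")
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - v / n_genes)
    b = np.max(v / n_genes - (j - 1) / t)
    return float(a if a > b else -b)


def connectivity_screen(sig: DiseaseSignature, db: pd.DataFrame) -> pd.DataFrame:
    """Screen every drug profile in ``db`` (genes x drugs, each column a
    permutation of 1..N) against the disease signature.

    Per drug: ks_up from the up tags, ks_down from the down tags; the raw
    score s = ks_up - ks_down when their signs differ, else 0.  Normalized
    connectivity divides positive scores by the maximum positive s and
    negative scores by the magnitude of the most negative s, so the extreme
    drugs score +/-1.  Positive = drives the inflamed signature (cold-to-hot
    converter).
    """
    sig.validate(db.index)
    n = db.shape[0]
    up_pos = np.sort(db.loc[sig.up_tags].to_numpy(), axis=0)
    down_pos = np.sort(db.loc[sig.down_tags].to_numpy(), axis=0)
    rows = []
    for j, drug in enumerate(db.columns):
        ks_up = ks_tag_statistic(up_pos[:, j], n)
        ks_down = ks_tag_statistic(down_pos[:, j], n)
        s = 0.0 if ks_up * ks_down > 0 else ks_up - ks_down
        rows.append((drug, ks_up, ks_down, s))
    out = pd.DataFrame(rows, columns=["drug", "ks_up", "ks_down", "raw"]).set_index("drug")
    pos_max = out.loc[out["raw"] > 0, "raw"].max()
    neg_min = out.loc[out["raw"] < 0, "raw"].min()
    norm = np.zeros(len(out))
    if np.isfinite(pos_max) and pos_max > 0:
        norm = np.where(out["raw"] > 0, out["raw"] / pos_max, norm)
    if np.isfinite(neg_min) and neg_min < 0:
        norm = np.where(out["raw"] < 0, out["raw"] / abs(neg_min), norm)
    if (out["raw"] == 0).all():
        warnings.warn("all raw connectivity scores are 0", stacklevel=2)
    out["normalized"] = norm
    return out.sort_values("normalized", ascending=False)


def signature_from_pan_cancer(
    pan_sig, universe, max_tags: int = 500
) -> DiseaseSignature:
    """Build the tag lists from a PanCancerSignature, restricted to the drug
    universe; if a list exceeds ``max_tags`` keep the largest |log2FC|.
    """
    universe = set(universe)

    def _trim(genes: list[str]) -> list[str]:
        present = [g for g in genes if g in universe]
        if len(present) > max_tags:
            present = sorted(
                present, key=lambda g: abs(pan_sig.mean_logfc.get(g, 0.0)), reverse=True
            )[:max_tags]
        return present

    return DiseaseSignature(
        up_tags=_trim(pan_sig.up_in("inflamed")),
        down_tags=_trim(pan_sig.up_in("noninflamed")),
    )
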