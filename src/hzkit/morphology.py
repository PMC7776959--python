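"""Leaf-morphometric PCA hybrid index and progeny hybrid-rate scoring.

A scaled, centered PCA over all leaves yields axis-1 scores; scores are
averaged per individual and mapped affinely so the two parental
reference centroids sit at -anchor and +anchor (default 2). Seedlings
scoring inside the open hybrid window (default (-1, 1)) count as hybrid
for the progeny hybridization rate, reported with a Wilson interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import EstimationError, ValidationError
from .io_core import MorphTable, SampleFrame

logger = logging.getLogger(__name__)


@dataclass
class HybridIndex:
    """Per-sample morphological hybrid index.

    On the index scale the reference-P1 centroid sits at ``-anchor`` and
    the reference-P2 centroid at ``+anchor`` exactly, by construction.
    """

    sample_id: str
    index: float
    n_leaves: int
    pc1_var_frac: float


def _pca_axis1(Z: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal axis scores and its variance fraction, via SVD."""
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    scores = U[:, 0] * s[0]
    return scores, float(var[0] / var.sum())


def leaf_pca_index(
    M: MorphTable,
    S: SampleFrame,
    anchor: float = 2.0,
) -> list[HybridIndex]:
    """Compute the PCA-based hybrid index for every sample with leaves.

    Measurement columns are standardized to zero mean / unit variance
    over all leaves (constant columns dropped with a warning), axis-1
    scores averaged per individual, and the result mapped affinely so
    parental reference centroids land at ``-anchor`` (P1) and
    ``+anchor`` (P2).
    """
    M.check_samples_known(S)
    cols = M.measurement_columns
    if len(cols) < 2:
        raise ValidationError("need >= 2 measurement columns")
    X = M.df[cols].to_numpy(dtype=float)
    if len(X) < 3 or M.df["sample_id"].nunique() < 3:
        raise ValidationError("need >= 3 samples with leaves")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        logger.warning("dropping constant measurement columns: %s", dropped)
        X = X[:, keep]
        if X.shape[1] < 2:
            raise ValidationError("fewer than 2 non-constant columns remain")
        sd = sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    scores, var_frac = _pca_axis1(Z)

    per_sample = (pd.DataFrame({"sample_id": M.df["sample_id"], "score": scores})
                  .groupby("sample_id")["score"].agg(["mean", "size"]))

    roles = S.df.set_index("sample_id")["role"]
    p1_ids = [s for s in per_sample.index if roles.get(s) == "reference_P1"]
    p2_ids = [s for s in per_sample.index if roles.get(s) == "reference_P2"]
    if not p1_ids or not p2_ids:
        raise ValidationError("both parental reference pools need measured leaves")
    c1 = float(per_sample.loc[p1_ids, "mean"].mean())
    c2 = float(per_sample.loc[p2_ids, "mean"].mean())
    if np.isclose(c1, c2, atol=1e-9):
        raise EstimationError("parental centroids coincide; index undefined")
    # affine map: c1 -> -anchor, c2 -> +anchor (P1 always negative)
    scale = 2 * anchor / (c2 - c1)

    out = []
    for sid, row in per_sample.iterrows():
        idx = (row["mean"] - (c1 + c2) / 2) * scale
        out.append(HybridIndex(sample_id=str(sid), index=float(idx),
                               n_leaves=int(row["size"]),
                               pc1_var_frac=var_frac))
    return out


def progeny_hybrid_rate(
    indices: np.ndarray,
    lower: float = -1.0,
    upper: float = 1.0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float], int]:
    """Fraction of progeny scoring strictly inside the hybrid window.

    Returns ``(rate, wilson_ci, n)``.
    """
    indices = np.asarray(indices, dtype=float)
    n = len(indices)
    if n < 1:
        raise ValidationError("need at least one progeny index")
    k = int(((indices > lower) & (indices < upper)).sum())
    lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method="wilson")
    return k / n, (float(lo), float(hi)), n
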