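"""Supervised two-pool admixture-proportion (q) estimation.

Given fixed parental allele frequencies, each individual's ancestry
proportion q maximizes a binomial likelihood in which the per-locus
ALT-allele probability is the q-weighted mixture of the two pool
frequencies. The problem is one-dimensional and concave, so bounded
scalar optimization suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr

from .errors import EstimationError, ValidationError
from .io_core import MISSING, GenotypeMatrix, ParentalFrequencies, subset_to_loci

_BINOM_COEF = np.log([1.0, 2.0, 1.0])  # log C(2, g)


@dataclass
class AncestryEstimate:
    """Admixture proportion toward pool 1 with uncertainty.

    ``se`` is derived from the observed Fisher information at the
    optimum and is NaN when the estimate sits on a boundary.
    """

    sample_id: str
    q: float
    se: float
    loglik: float
    n_loci_used: int


def loglik_q(q: float | np.ndarray, g: np.ndarray,
             f1: np.ndarray, f2: np.ndarray) -> float | np.ndarray:
    """Binomial ancestry log-likelihood; vectorized over q."""
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    qv = np.atleast_1d(q)[:, None]
    pi = qv * f1 + (1 - qv) * f2
    ll = (g * np.log(pi) + (2 - g) * np.log1p(-pi)
          + _BINOM_COEF[g]).sum(axis=1)
    return float(ll[0]) if scalar else ll


def estimate_q(
    g: np.ndarray,
    F: ParentalFrequencies,
    sample_id: str = "",
    min_loci: int = 1,
    xatol: float = 1e-6,
) -> AncestryEstimate:
    """Maximum-likelihood q on [0, 1] for one dosage vector.

    Missing loci are excluded from the likelihood. Raises
    :class:`EstimationError` when fewer than ``min_loci`` loci are usable.
    """
    g = np.asarray(g)
    if g.shape != (F.n_loci,):
        raise ValidationError("dosage vector length does not match frequencies")
    usable = g != MISSING
    n_used = int(usable.sum())
    if n_used == 0:
        raise EstimationError("all loci missing")
    if n_used < min_loci:
        raise EstimationError(f"only {n_used} usable loci (< {min_loci})")
    gu = g[usable].astype(int)
    f1, f2 = F.f1[usable], F.f2[usable]

    res = minimize_scalar(lambda q: -loglik_q(q, gu, f1, f2),
                          bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": xatol})
    q_hat = float(res.x)
    ll = float(-res.fun)
    # boundary check against interior endpoints (bounded Brent never
    # returns the exact bound, so compare likelihoods at the bounds too)
    for b in (0.0, 1.0):
        ll_b = loglik_q(b, gu, f1, f2)
        if ll_b > ll:
            q_hat, ll = b, float(ll_b)

    if q_hat <= xatol or q_hat >= 1 - xatol:
        se = float("nan")
    else:
        pi = q_hat * f1 + (1 - q_hat) * f2
        dpi = f1 - f2
        info = float(((gu / pi**2 + (2 - gu) / (1 - pi) ** 2) * dpi**2).sum())
        se = 1.0 / np.sqrt(info) if info > 0 else float("nan")
    return AncestryEstimate(sample_id=sample_id, q=q_hat, se=se,
                            loglik=ll, n_loci_used=n_used)


def estimate_q_all(
    gm: GenotypeMatrix,
    F: ParentalFrequencies,
    sample_ids: list[str] | None = None,
    min_loci: int = 1,
) -> list[AncestryEstimate]:
    """Estimate q for many individuals against fixed parental frequencies."""
    gsub = subset_to_loci(gm, F.locus_ids)
    ids = sample_ids if sample_ids is not None else gsub.sample_ids
    return [estimate_q(gsub.row(sid), F, sample_id=sid, min_loci=min_loci)
            for sid in ids]


def genotype_morphology_correlation(
    q: np.ndarray, m: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between genetic ancestry and a morphological
    hybrid index, with a two-sided p-value.

    Pairs with a NaN in either vector are dropped; at least three
    complete pairs are required.
    """
    q = np.asarray(q, dtype=float)
    m = np.asarray(m, dtype=float)
    if q.shape != m.shape:
        raise ValidationError("vectors must be paired (equal length)")
    ok = np.isfinite(q) & np.isfinite(m)
    if ok.sum() < 3:
        raise ValidationError("need at least 3 complete pairs")
    qv, mv = q[ok], m[ok]
    if np.ptp(qv) == 0 or np.ptp(mv) == 0:
        raise EstimationError("correlation undefined: zero variance")
    r, p = pearsonr(qv, mv)
    return float(r), float(p)
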