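"""Maximum-likelihood assignment to {P1, P2, F1, F2, BC1, BC2}.

Each class implies a distribution over per-locus allele-origin states
(both alleles from pool 1, one from each pool, both from pool 2); the
genotype likelihood under a class is the mixture over those states with
allele draws governed by the parental frequencies. Assignment maximizes
the summed log-likelihood across loci, with a configurable prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigurationError, ContractError, EstimationError
from .io_core import MISSING, GenotypeMatrix, ParentalFrequencies, SampleFrame

logger = logging.getLogger(__name__)

CLASSES = ("P1", "P2", "F1", "F2", "BC1", "BC2")

#: Allele-origin weights over (both-P1, one-each, both-P2) per class.
ORIGIN_WEIGHTS: dict[str, tuple[float, float, float]] = {
    "P1": (1.0, 0.0, 0.0),
    "P2": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC1": (0.5, 0.5, 0.0),
    "BC2": (0.0, 0.5, 0.5),
}

#: Expected pool-1 admixture proportion per class.
CLASS_Q = {"P1": 1.0, "P2": 0.0, "F1": 0.5, "F2": 0.5, "BC1": 0.75, "BC2": 0.25}

#: Classes counted as hybrid in zone composition summaries.
HYBRID_CLASSES = ("F1", "F2", "BC1", "BC2")

#: Four-category variant (backcrosses only, no F2).
CLASS_SETS = {
    "six": CLASSES,
    "four": ("P1", "P2", "F1", "BC1", "BC2"),
}


@dataclass
class ClassAssignment:
    """Per-sample classification result.

    ``posterior`` and ``loglik_by_class`` are keyed by class label;
    ``best_class`` is the posterior argmax with a deterministic tie-break
    in :data:`CLASSES` order.
    """

    sample_id: str
    best_class: str
    posterior: dict[str, float]
    loglik_by_class: dict[str, float]
    n_loci_used: int


def _origin_state_probs(g: np.ndarray, f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """P(g | origin state), stacked as (3, n_loci) for states (11, 12, 22)."""
    p11 = np.where(g == 2, f1 * f1,
                   np.where(g == 1, 2 * f1 * (1 - f1), (1 - f1) ** 2))
    p12 = np.where(g == 2, f1 * f2,
                   np.where(g == 1, f1 * (1 - f2) + (1 - f1) * f2,
                            (1 - f1) * (1 - f2)))
    p22 = np.where(g == 2, f2 * f2,
                   np.where(g == 1, 2 * f2 * (1 - f2), (1 - f2) ** 2))
    return np.stack([p11, p12, p22])


def class_genotype_prob(g: int, f1: float, f2: float, c: str) -> float:
    """P(genotype g | class c) at a single locus.

    ``f1``/``f2`` must lie strictly inside (0, 1) — shrink upstream.
    """
    if not (0 < f1 < 1 and 0 < f2 < 1):
        raise ContractError("parental frequencies must be strictly in (0,1); "
                            "apply shrinkage upstream")
    if c not in ORIGIN_WEIGHTS:
        raise ConfigurationError(f"unknown class {c!r}")
    if g not in (0, 1, 2):
        raise ContractError(f"genotype must be 0/1/2, got {g}")
    w = ORIGIN_WEIGHTS[c]
    probs = _origin_state_probs(np.array([g]), np.array([f1]), np.array([f2]))
    return float(np.dot(w, probs[:, 0]))


def class_logliks(
    g: np.ndarray,
    F: ParentalFrequencies,
    classes: tuple[str, ...] = CLASSES,
) -> tuple[dict[str, float], int]:
    """Per-class total log-likelihood of a dosage vector.

    Loci with missing dosage are excluded from the sums. Returns the
    loglik dict and the number of loci used.
    """
    g = np.asarray(g)
    if g.shape != (F.n_loci,):
        raise ContractError("dosage vector length does not match frequencies")
    usable = g != MISSING
    n_used = int(usable.sum())
    if n_used == 0:
        raise EstimationError("all loci missing for this individual")
    gu = g[usable]
    f1 = F.f1[usable]
    f2 = F.f2[usable]
    p11, p12, p22 = _origin_state_probs(gu, f1, f2)
    out = {}
    for c in classes:
        w = ORIGIN_WEIGHTS[c]
        # grouping the pool-specific terms first makes the pool-swap
        # symmetry (P1<->P2, BC1<->BC2) bitwise exact
        pc = (w[0] * p11 + w[2] * p22) + w[1] * p12
        out[c] = float(np.log(pc).sum())
    return out, n_used


def classify(
    g: np.ndarray,
    F: ParentalFrequencies,
    prior: dict[str, float] | None = None,
    sample_id: str = "",
    classes: tuple[str, ...] = CLASSES,
    min_loci: int = 50,
) -> ClassAssignment:
    """ML/MAP assignment of one individual to a hybrid class.

    ``prior`` defaults to uniform over ``classes``. Posterior is computed
    in log space (log-sum-exp); ties break deterministically in
    :data:`CLASSES` order with a logged warning.
    """
    if prior is None:
        prior = {c: 1.0 / len(classes) for c in classes}
    pr = np.array([prior.get(c, 0.0) for c in classes], dtype=float)
    if (pr < 0).any() or pr.sum() <= 0:
        raise ConfigurationError("prior must be nonnegative and not all zero")
    pr = pr / pr.sum()
    logliks, n_used = class_logliks(g, F, classes)
    if n_used < min_loci:
        raise EstimationError(
            f"only {n_used} usable loci (< {min_loci}); individual excluded "
            "from classification"
        )
    ll = np.array([logliks[c] for c in classes])
    with np.errstate(divide="ignore"):
        logpost = ll + np.log(pr)
    logpost -= logsumexp(logpost)
    post = np.exp(logpost)
    post /= post.sum()
    best_idx = int(np.argmax(post))
    ties = np.flatnonzero(np.isclose(post, post[best_idx], rtol=0, atol=1e-12))
    if len(ties) > 1:
        logger.warning("posterior tie for %s among %s; picking %s",
                       sample_id, [classes[t] for t in ties], classes[ties[0]])
        best_idx = int(ties[0])
    return ClassAssignment(
        sample_id=sample_id,
        best_class=classes[best_idx],
        posterior={c: float(p) for c, p in zip(classes, post)},
        loglik_by_class=logliks,
        n_loci_used=n_used,
    )


def classify_all(
    gm: GenotypeMatrix,
    F: ParentalFrequencies,
    sample_ids: list[str] | None = None,
    prior: dict[str, float] | None = None,
    classes: tuple[str, ...] = CLASSES,
    min_loci: int = 50,
) -> list[ClassAssignment]:
    """Classify many individuals; individuals failing the usable-locus
    threshold are skipped with a logged notice."""
    from .io_core import subset_to_loci

    gsub = subset_to_loci(gm, F.locus_ids)
    ids = sample_ids if sample_ids is not None else gsub.sample_ids
    out = []
    for sid in ids:
        g = gsub.row(sid)
        try:
            out.append(classify(g, F, prior=prior, sample_id=sid,
                                classes=classes, min_loci=min_loci))
        except EstimationError as exc:
            logger.warning("skipping %s: %s", sid, exc)
    return out


def zone_composition(
    assignments: list[ClassAssignment],
    sf: SampleFrame,
) -> dict[str, dict[str, float | int | dict[str, int]]]:
    """Per-habitat proportions of parental / F1 / later-generation classes.

    "Hybrid" covers F1, F2, BC1 and BC2. Habitats with zero classified
    samples are omitted with a log notice. Counts are reported alongside
    the proportions.
    """
    by_id = {a.sample_id: a for a in assignments}
    out: dict[str, dict] = {}
    for habitat in ("desert", "ecotone", "dune"):
        ids = sf.df.loc[sf.df["habitat"] == habitat, "sample_id"]
        assigned = [by_id[s] for s in ids if s in by_id]
        if not assigned:
            logger.info("habitat %s has no classified samples; omitted", habitat)
            continue
        counts = {c: 0 for c in CLASSES}
        for a in assigned:
            counts[a.best_class] += 1
        n = len(assigned)
        n_hyb = sum(counts[c] for c in HYBRID_CLASSES)
        out[habitat] = {
            "n": n,
            "counts": counts,
            "hybrid_fraction": n_hyb / n,
            "parental_fraction": (counts["P1"] + counts["P2"]) / n,
            "f1_among_hybrids": (counts["F1"] / n_hyb) if n_hyb else float("nan"),
        }
    return out
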