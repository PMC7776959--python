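"""Hierarchical log-linear analysis of three-way contingency tables.

Models are specified by their generating class (the maximal margin
terms); fitting is by iterative proportional fitting (IPF) to those
margins; fit is measured by the G^2 deviance against the observed table;
model search is backward stepwise removal of the highest-order term with
the largest non-significant likelihood-ratio p-value, respecting the
hierarchy. Intended for habitat x phenotype x death-cause tables
(burial, herbivory) but works for any three factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
from scipy.stats import chi2

from .errors import ContractError, ValidationError
from .io_core import TransplantTable

logger = logging.getLogger(__name__)

Term = frozenset  # of factor names


@dataclass
class Table3:
    """Counts indexed by three categorical factors.

    ``counts`` has shape ``(len(levels[f]) for f in factors)``;
    ``mask`` (optional) marks structural zeros with 0.
    """

    counts: np.ndarray
    factors: tuple[str, str, str]
    levels: dict[str, list[str]]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValidationError("Table3 requires a 3-dimensional count array")
        shape = tuple(len(self.levels[f]) for f in self.factors)
        if self.counts.shape != shape:
            raise ValidationError(
                f"count shape {self.counts.shape} != level shape {shape}")
        if any(s < 2 for s in shape):
            raise ValidationError("all three dimensions need >= 2 levels")
        if (self.counts < 0).any():
            raise ValidationError("counts must be nonnegative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValidationError("counts must be integers")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=float)
            if self.mask.shape != self.counts.shape:
                raise ValidationError("mask shape mismatch")

    @property
    def n_cells(self) -> int:
        return int(self.counts.size)


def table_from_transplant(
    T: TransplantTable,
    cause: str,
    outcome_factor: str = "died_of_cause",
) -> Table3:
    """Cross-tabulate habitat x phenotype x (died of `cause` yes/no)."""
    df = T.df
    habs = sorted(df["habitat"].unique())
    phes = sorted(df["phenotype"].unique())
    outs = ["no", "yes"]
    counts = np.zeros((len(habs), len(phes), 2))
    for (h, p), sub in df.groupby(["habitat", "phenotype"], observed=True):
        yes = int((sub["death_cause"] == cause).sum())
        counts[habs.index(h), phes.index(p), 1] = yes
        counts[habs.index(h), phes.index(p), 0] = len(sub) - yes
    return Table3(counts, ("habitat", "phenotype", outcome_factor),
                  {"habitat": habs, "phenotype": phes, outcome_factor: outs})


@dataclass
class IpfResult:
    """IPF fit of one hierarchical model."""

    fitted: np.ndarray
    g2: float
    df: int
    model: frozenset  # generating class: frozenset of Terms
    n_iter: int
    converged: bool


@dataclass
class StepRecord:
    term: tuple[str, ...]
    delta_g2: float
    df: int
    p: float
    removed: bool


@dataclass
class StepwiseResult:
    final_model: frozenset
    trail: list[StepRecord] = field(default_factory=list)
    final_fit: IpfResult | None = None
    #: LR test of the single highest-order term at the first step
    three_way_test: tuple[float, int, float] | None = None


def _closure(generators: frozenset) -> set[Term]:
    """All non-empty subsets of any generating term."""
    out: set[Term] = set()
    for g in generators:
        items = sorted(g)
        for r in range(1, len(items) + 1):
            out.update(Term(c) for c in combinations(items, r))
    return out


def _maximal(terms: set[Term]) -> frozenset:
    return frozenset(t for t in terms
                     if not any(t < u for u in terms))


def _validate_model(model, factors) -> frozenset:
    terms = set()
    for t in model:
        t = Term(t)
        if not t:
            raise ContractError("empty margin term")
        unknown = t - set(factors)
        if unknown:
            raise ContractError(f"unknown factors in model term: {sorted(unknown)}")
        terms.add(t)
    if not terms:
        raise ContractError("model needs at least one margin term")
    return _maximal(terms)


def _margin_axes(term: Term, factors) -> tuple[int, ...]:
    """Axes to sum over to get the margin for `term`."""
    return tuple(i for i, f in enumerate(factors) if f not in term)


def model_df(T: Table3, generators: frozenset) -> int:
    """Residual df of a hierarchical model by standard term counting."""
    nlev = {f: len(T.levels[f]) for f in T.factors}
    n_params = 1 + sum(
        int(np.prod([nlev[f] - 1 for f in t])) for t in _closure(generators))
    return T.n_cells - n_params


def ipf_fit(
    T: Table3,
    model,
    tol: float = 1e-8,
    max_iter: int = 20000,
) -> IpfResult:
    """Fit a hierarchical log-linear model by IPF.

    ``model`` is an iterable of margin terms (iterables of factor
    names); it is reduced to its generating class. Iteration stops when
    every fitted margin matches its observed margin to within ``tol``
    (max absolute difference). Sampling zeros are tolerated; structural
    zeros can be declared via ``T.mask``.
    """
    generators = _validate_model(model, T.factors)
    obs = T.counts
    fitted = np.ones_like(obs) * obs.sum() / obs.size
    if T.mask is not None:
        fitted = fitted * (T.mask > 0)
    margins = [( _margin_axes(t, T.factors), obs.sum(axis=_margin_axes(t, T.factors), keepdims=True))
               for t in sorted(generators, key=lambda t: (len(t), sorted(t)))]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for axes, target in margins:
            cur = fitted.sum(axis=axes, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(cur > 0, target / np.where(cur > 0, cur, 1.0), 0.0)
            fitted = fitted * ratio
        err = max(
            float(np.abs(fitted.sum(axis=axes, keepdims=True) - target).max())
            for axes, target in margins)
        if err < tol:
            converged = True
            break
    if not converged:
        logger.warning("IPF did not reach tol=%g in %d iterations", tol, max_iter)
    pos = obs > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        g2 = 2.0 * float(np.sum(obs[pos] * np.log(obs[pos] / fitted[pos])))
    return IpfResult(fitted=fitted, g2=g2, df=model_df(T, generators),
                     model=generators, n_iter=it, converged=converged)


SATURATED = lambda factors: frozenset({Term(factors)})  # noqa: E731


def backward_stepwise(T: Table3, alpha: float = 0.05) -> StepwiseResult:
    """Backward-stepwise model search from the saturated model.

    At each step, among the current maximal (removable) terms, the term
    whose removal gives the largest LR p-value is removed if p > alpha;
    the search stops when every removable term is significant. The
    habitat x phenotype x outcome question is the first-step LR, recorded
    in ``three_way_test``.
    """
    current = _validate_model(SATURATED(T.factors), T.factors)
    fit_cur = ipf_fit(T, current)
    trail: list[StepRecord] = []
    three_way: tuple[float, int, float] | None = None
    while True:
        closure = _closure(current)
        # only interaction terms are removable; main effects always stay
        candidates = sorted((t for t in _maximal(closure) if len(t) >= 2),
                            key=lambda t: (-len(t), sorted(t)))
        best = None
        for term in candidates:
            reduced_closure = set(closure) - {term}
            reduced = _maximal(reduced_closure)
            fit_red = ipf_fit(T, reduced)
            dg2 = fit_red.g2 - fit_cur.g2
            ddf = fit_red.df - fit_cur.df
            if not np.isfinite(dg2) or ddf <= 0:
                logger.warning("term %s inestimable (structural zeros?); "
                               "flagged, not removed", sorted(term))
                continue
            p = float(chi2.sf(max(dg2, 0.0), ddf))
            if len(term) == len(T.factors) and three_way is None:
                three_way = (max(dg2, 0.0), ddf, p)
            if best is None or p > best[1]:
                best = (term, p, dg2, ddf, reduced, fit_red)
        if best is None:
            break
        term, p, dg2, ddf, reduced, fit_red = best
        if p > alpha:
            trail.append(StepRecord(tuple(sorted(term)), max(dg2, 0.0),
                                    ddf, p, removed=True))
            current, fit_cur = reduced, fit_red
        else:
            trail.append(StepRecord(tuple(sorted(term)), max(dg2, 0.0),
                                    ddf, p, removed=False))
            break
    return StepwiseResult(final_model=current, trail=trail,
                          final_fit=fit_cur, three_way_test=three_way)
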