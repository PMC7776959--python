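"""Distance-binned sigmoid (tanh) cline fitting for ancestry.

Individuals are binned into fixed-width bands perpendicular to the
transect, mean ancestry per band forms the response, and a four-parameter
tanh cline (center, width, two tail levels) is fitted by maximum
likelihood with multistart. Width is the inverse-maximum-slope width of
the tanh form. Bootstrap CIs for the width resample individuals within
bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize

from .errors import EstimationError, FitError, ValidationError
from .io_core import SampleFrame


@dataclass
class BandSeries:
    """Mean ancestry per fixed-width transect band.

    ``members`` holds the individual q values of each band so bootstrap
    resampling can operate on individuals, not band means.
    """

    band_center: np.ndarray
    mean_q: np.ndarray
    n: np.ndarray
    band_width: float
    members: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.band_center = np.asarray(self.band_center, dtype=float)
        self.mean_q = np.asarray(self.mean_q, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (len(self.band_center) == len(self.mean_q) == len(self.n)):
            raise ValidationError("band series arrays must be equal length")
        if (self.n < 1).any():
            raise ValidationError("every retained band needs n >= 1")

    @property
    def n_bands(self) -> int:
        return len(self.band_center)


@dataclass
class ClineFit:
    """Fitted tanh cline.

    ``p_left``/``p_right`` are the tail ancestry levels on the negative
    and positive sides of the transect; ``pmin``/``pmax`` are the same
    two values ordered. ``width`` is the inverse of the maximum slope.
    """

    center: float
    width: float
    p_left: float
    p_right: float
    loglik: float
    ci_width: tuple[float, float] | None = None
    error_model: str = "normal"

    @property
    def pmin(self) -> float:
        return min(self.p_left, self.p_right)

    @property
    def pmax(self) -> float:
        return max(self.p_left, self.p_right)


def cline_model(x, center, width, p_left, p_right):
    """Expected ancestry at position(s) x under the tanh cline."""
    x = np.asarray(x, dtype=float)
    s = 0.5 * (1.0 + np.tanh(2.0 * (x - center) / width))
    return p_left + (p_right - p_left) * s


def bin_transect(
    q: np.ndarray,
    positions: np.ndarray,
    band_width: float = 10.0,
) -> BandSeries:
    """Bin individual ancestry into bands anchored at the ecotone midline.

    Bands are the half-open intervals ``(k*w, (k+1)*w]``; empty bands
    are dropped; band means are plain averages of member q.
    """
    q = np.asarray(q, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if band_width <= 0:
        raise ValidationError("band_width must be positive")
    if len(q) != len(positions):
        raise ValidationError("q and positions must be paired")
    if len(q) == 0:
        raise EstimationError("no samples to bin")
    if not np.isfinite(positions).all():
        raise ValidationError("non-finite positions")
    idx = np.ceil(positions / band_width).astype(int) - 1
    centers, means, ns, members = [], [], [], []
    for b in np.unique(idx):
        sel = idx == b
        centers.append((b + 0.5) * band_width)
        members.append(q[sel])
        means.append(float(q[sel].mean()))
        ns.append(int(sel.sum()))
    return BandSeries(np.array(centers), np.array(means), np.array(ns),
                      band_width, members)


def bin_transect_frame(estimates, sf: SampleFrame,
                       band_width: float = 10.0) -> BandSeries:
    """Convenience wrapper pairing :class:`AncestryEstimate` objects with
    positions from a sample frame."""
    q = np.array([e.q for e in estimates])
    pos = np.array([sf.position_of(e.sample_id) for e in estimates])
    return bin_transect(q, pos, band_width)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _normal_profile_loglik(theta, x, y, n):
    """Profiled-sigma normal loglik of band means (variance sigma^2/n)."""
    r = y - cline_model(x, *theta)
    B = len(y)
    s2 = float((n * r * r).sum()) / B
    if s2 <= 0:
        return np.inf * 1.0  # perfect fit; caller special-cases
    return (-0.5 * B * np.log(2 * np.pi * s2) + 0.5 * np.log(n).sum()
            - 0.5 * B)

def _binom_loglik(theta, x, y, n):
    """Pseudo-count binomial loglik: 2n trials, 2n*mean_q successes."""
    p = np.clip(cline_model(x, *theta), 1e-12, 1 - 1e-12)
    return float((2 * n * (y * np.log(p) + (1 - y) * np.log1p(-p))).sum())


def _fit_once(x, y, n, theta0, bounds, error_model):
    lo, hi = bounds
    if error_model == "normal":
        res = least_squares(
            lambda th: np.sqrt(n) * (y - cline_model(x, *th)),
            theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        return res.x, float((res.fun**2).sum()), res.success
    if error_model == "binomial":
        res = minimize(lambda th: -_binom_loglik(th, x, y, n), theta0,
                       bounds=list(zip(lo, hi)), method="L-BFGS-B")
        return res.x, float(res.fun), res.success
    raise ValidationError(f"unknown error model {error_model!r}")


def _multistart(x, y, n, error_model, n_starts_extra=0, theta_init=None):
    span = float(x.max() - x.min())
    span = span if span > 0 else 1.0
    lo = np.array([x.min() - span, 1e-3, 0.0, 0.0])
    hi = np.array([x.max() + span, 10 * span, 1.0, 1.0])
    # tail guesses from the outer thirds of the data
    order = np.argsort(x)
    k = max(1, len(x) // 3)
    p_lo = float(np.clip(y[order[:k]].mean(), 0, 1))
    p_hi = float(np.clip(y[order[-k:]].mean(), 0, 1))
    starts = []
    if theta_init is not None:
        starts.append(np.clip(theta_init, lo, hi))
    for cq in (0.25, 0.5, 0.75, 0.375):
        c0 = x.min() + cq * span
        for w0 in (span / 10, span / 3):
            starts.append(np.array([c0, w0, p_lo, p_hi]))
    best = None
    for th0 in starts:
        try:
            th, obj, ok = _fit_once(x, y, n, th0, (lo, hi), error_model)
        except Exception:
            continue
        if error_model == "normal":
            score = float((n * (y - cline_model(x, *th)) ** 2).sum())
        else:
            score = obj
        if best is None or score < best[1]:
            best = (th, score)
    if best is None:
        raise FitError("cline fit failed to converge from any start")
    return best[0]


def fit_cline(
    B: BandSeries,
    error_model: str = "normal",
    n_boot: int = 500,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> ClineFit:
    """ML fit of the tanh cline to a band series.

    ``error_model`` is either ``"normal"`` (band mean ~ Normal with
    variance sigma^2/n, sigma^2 profiled — weighted least squares as ML)
    or ``"binomial"`` (pseudo-count: 2n trials per band). A percentile
    bootstrap CI for the width resamples individuals within bands
    (``n_boot`` replicates; set 0 to skip; ``seed`` required if > 0).
    """
    if B.n_bands < 5:
        raise EstimationError(
            f"need >= 5 bands spanning both tails, got {B.n_bands}")
    x, y, n = B.band_center, B.mean_q, B.n.astype(float)
    theta = _multistart(x, y, n, error_model)
    if error_model == "normal":
        ll = _normal_profile_loglik(theta, x, y, n)
        if not np.isfinite(ll):
            ll = float("inf")
    else:
        ll = _binom_loglik(theta, x, y, n)

    ci = None
    if n_boot > 0:
        if seed is None:
            raise ValidationError("bootstrap requires a seed")
        if not B.members:
            raise ValidationError("band series lacks member q values; "
                                  "bootstrap needs individuals")
        rng = np.random.default_rng(seed)
        widths = np.empty(n_boot)
        span = float(x.max() - x.min()) or 1.0
        lo = np.array([x.min() - span, 1e-3, 0.0, 0.0])
        hi = np.array([x.max() + span, 10 * span, 1.0, 1.0])
        th0 = np.clip(theta, lo, hi)
        for b in range(n_boot):
            yb = np.array([m[rng.integers(0, len(m), len(m))].mean()
                           for m in B.members])
            try:
                # single start from the point estimate keeps the bootstrap
                # tractable; the resampled surface is close to the original
                thb, _, _ = _fit_once(x, yb, n, th0, (lo, hi), error_model)
                widths[b] = thb[1]
            except Exception:
                widths[b] = np.nan
        ok = widths[np.isfinite(widths)]
        a = 100 * (1 - ci_level) / 2
        ci = (float(np.percentile(ok, a)), float(np.percentile(ok, 100 - a)))

    return ClineFit(center=float(theta[0]), width=float(theta[1]),
                    p_left=float(theta[2]), p_right=float(theta[3]),
                    loglik=float(ll), ci_width=ci, error_model=error_model)


def cline_loglik(fit_or_theta, B: BandSeries,
                 error_model: str = "normal") -> float:
    """Log-likelihood of arbitrary cline parameters on a band series
    (used to compare fitted vs. true generating parameters)."""
    if isinstance(fit_or_theta, ClineFit):
        th = (fit_or_theta.center, fit_or_theta.width,
              fit_or_theta.p_left, fit_or_theta.p_right)
    else:
        th = tuple(fit_or_theta)
    x, y, n = B.band_center, B.mean_q, B.n.astype(float)
    if error_model == "normal":
        return float(_normal_profile_loglik(th, x, y, n))
    return _binom_loglik(th, x, y, n)
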