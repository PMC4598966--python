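"""Trend-curve fitting and the two inflection-based access indices.

The binned nearest-distance counts are treated as observations of a smooth
unimodal curve y = f(x): participant counts first rise with distance from
the provider network, peak, decline, and flatten into a sparse tail.  An
ordinary-least-squares polynomial is fitted to the (bin midpoint, count)
pairs, and two indices are read off its derivatives:

* **PWD (profit-willing distance)** — the first interior root of f' where
  the slope changes + -> - (a local maximum of the fitted curve).  Because
  the index is defined as the distance band holding the *maximum* number of
  participants, the accepted root must also be the global maximum of the
  fitted curve over the fit domain; this rejects spurious ripples in the
  near-zero tail.  When no such root exists (counts monotonically decreasing
  with distance, the sparse-region regime) the PWD is *undetected* — absence
  is a result, not an error.
* **TLD (tolerance-limited distance)** — the first root of f'' beyond the
  PWD where the curvature changes - -> + (concave-down to concave-up: the
  post-peak decline flattening out).  The opposite sign convention is
  available behind a switch.

Each detected root is reported together with its containing bin
[k*w, (k+1)*w) and the buffer radius (k+1)*w, the bin's upper edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial import polynomial as npoly
from numpy.polynomial import Polynomial

from .binning import BinnedDistances
from .points import ValidationError

DEFAULT_DEGREE = 4
DEFAULT_TAIL_QUANTILE = 0.99

#: Fraction of the bin width used as the probe offset delta when classifying
#: a derivative root's sign change, and as the margin inside which boundary
#: roots are rejected as artifacts.
DELTA_FRACTION = 0.01


@dataclass(frozen=True)
class TrendCurve:
    """An OLS polynomial fitted to binned distance counts.

    ``coef`` are power-basis coefficients, ascending order, so
    f(x) = sum_j coef[j] * x**j on the fit domain [domain_lo, domain_hi].
    """

    coef: np.ndarray
    domain_lo: float
    domain_hi: float
    bin_width: float
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "coef", np.asarray(self.coef, dtype=float))

    @property
    def degree(self) -> int:
        return len(self.coef) - 1

    @property
    def delta(self) -> float:
        """Probe offset for sign-change classification (bin_width / 100)."""
        return self.bin_width * DELTA_FRACTION

    def __call__(self, x) -> np.ndarray:
        return npoly.polyval(np.asarray(x, dtype=float), self.coef)

    def derivative(self, order: int = 1) -> np.ndarray:
        return npoly.polyder(self.coef, order)

    def _real_interior_roots(self, dcoef: np.ndarray) -> np.ndarray:
        """Real roots of a derivative, strictly inside the open fit domain.

        Roots come from the companion-matrix eigenvalues; complex pairs are
        discarded when their imaginary magnitude exceeds 1e-8 x the domain
        span, and roots within delta of either domain end are rejected as
        boundary artifacts.
        """
        if len(dcoef) <= 1 or not np.any(dcoef[1:]):
            # constant derivative: no roots (an identically-zero derivative
            # has no isolated sign-change roots either)
            return np.array([])
        r = npoly.polyroots(dcoef)
        span = self.domain_hi - self.domain_lo
        r = r[np.abs(r.imag) < 1e-8 * span].real
        r = r[(r > self.domain_lo + self.delta) & (r < self.domain_hi - self.delta)]
        return np.sort(r)

    def domain_maximum(self) -> float:
        """Maximum of f over the closed fit domain (exact, via critical points)."""
        cand = [self.domain_lo, self.domain_hi]
        d1 = self.derivative(1)
        if len(d1) > 1 and np.any(d1[1:]):
            r = npoly.polyroots(d1)
            r = r[np.abs(r.imag) < 1e-8 * (self.domain_hi - self.domain_lo)].real
            cand.extend(r[(r >= self.domain_lo) & (r <= self.domain_hi)])
        return float(np.max(self(np.asarray(cand))))


@dataclass(frozen=True)
class IndexEstimate:
    """A detected index: the derivative root, its bin, and the buffer radius."""

    root: float
    bin_lo: float
    bin_hi: float
    buffer_radius: float

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "bin_lo": self.bin_lo,
            "bin_hi": self.bin_hi,
            "buffer_radius": self.buffer_radius,
        }


@dataclass(frozen=True)
class InflectionIndices:
    """PWD and TLD results; ``None`` encodes an undetected index."""

    pwd: Optional[IndexEstimate]
    tld: Optional[IndexEstimate]
    #: bin [lo, hi) with the largest raw count, for comparison with the
    #: curve-based PWD (ties: nearest to the origin).
    argmax_bin: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "pwd": self.pwd.to_dict() if self.pwd else None,
            "tld": self.tld.to_dict() if self.tld else None,
            "argmax_bin": list(self.argmax_bin),
        }


def _fit_domain_hi(dist: BinnedDistances, tail_quantile: Optional[float]) -> float:
    counts = dist.counts
    nz = np.nonzero(counts)[0]
    if len(nz) == 0:
        raise ValidationError("cannot fit a trend curve to all-zero counts")
    if tail_quantile is None:
        k = nz[-1]
    else:
        if not 0 < tail_quantile <= 1:
            raise ValidationError(f"tail_quantile must be in (0, 1], got {tail_quantile}")
        cum = np.cumsum(counts)
        k = int(np.searchsorted(cum, tail_quantile * cum[-1]))
        k = min(k, nz[-1])
    return float((k + 1) * dist.bin_width)


def fit_trend_curve(
    dist: BinnedDistances,
    degree: int = DEFAULT_DEGREE,
    tail_quantile: Optional[float] = DEFAULT_TAIL_QUANTILE,
    include_zero_bins: bool = True,
) -> TrendCurve:
    """Fit an OLS polynomial of the given degree to (midpoint, count) pairs.

    The fit domain runs from 0 to the upper edge of the bin containing the
    ``tail_quantile`` quantile of the sample (default: the central 99%), so
    the sparse extreme tail, where counts are 0 or 1, does not destabilise
    the fit; ``tail_quantile=None`` extends the domain to the last nonzero
    bin.  ``include_zero_bins=False`` drops zero-count bins from the fit
    (they are kept by default).

    Raises
    ------
    ValidationError
        If the fit is underdetermined (number of fitted bins <= degree).
    """
    if degree < 2:
        raise ValidationError(f"degree must be >= 2, got {degree}")
    hi = _fit_domain_hi(dist, tail_quantile)
    mids, counts = dist.midpoints, dist.counts
    mask = mids <= hi
    if not include_zero_bins:
        mask &= counts > 0
    x, y = mids[mask], counts[mask]
    if len(x) <= degree:
        raise ValidationError(
            f"underdetermined fit: {len(x)} bins for degree {degree}"
        )
    # Polynomial.fit maps the fit domain onto [-1, 1] internally for
    # conditioning; convert back to power-basis coefficients in meters.
    p = Polynomial.fit(x, y, degree, domain=[0.0, hi])
    coef = p.convert().coef
    coef = np.pad(coef, (0, degree + 1 - len(coef)))  # keep trailing zeros
    rss = float(np.sum((npoly.polyval(x, coef) - y) ** 2))
    return TrendCurve(coef=coef, domain_lo=0.0, domain_hi=hi,
                      bin_width=dist.bin_width, rss=rss, n_points=len(x))


def select_degree_aic(
    dist: BinnedDistances,
    degrees=range(2, 11),
    tail_quantile: Optional[float] = DEFAULT_TAIL_QUANTILE,
    include_zero_bins: bool = True,
) -> int:
    """Pick the fit degree minimising the Gaussian AIC (exploratory option)."""
    best_aic, best_d = np.inf, None
    for d in degrees:
        try:
            c = fit_trend_curve(dist, d, tail_quantile, include_zero_bins)
        except ValidationError:
            continue
        n = c.n_points
        rss = max(c.rss, np.finfo(float).tiny)
        aic = n * np.log(rss / n) + 2 * (d + 1)
        if aic < best_aic:
            best_aic, best_d = aic, d
    if best_d is None:
        raise ValidationError("no candidate degree admits a determined fit")
    return best_d


def report_index_bin(root: float, bin_width: float) -> tuple[float, float, float]:
    """Containing half-open bin [k*w, (k+1)*w) of a root, and the buffer radius.

    The buffer radius is the bin's upper edge (k+1)*w — the convention used
    when an index band like 550-600 m is carried forward as a 600-m buffer.
    """
    if root < 0:
        raise ValidationError(f"root must be nonnegative, got {root}")
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    k = int(np.floor(root / bin_width))
    return k * bin_width, (k + 1) * bin_width, (k + 1) * bin_width


def _first_sign_change_root(
    curve: TrendCurve,
    dcoef: np.ndarray,
    lower_bound: float,
    before_positive: bool,
    peak_maximum: bool = False,
) -> Optional[float]:
    """Smallest interior root of a derivative with the requested sign change.

    The sign is probed at root +/- delta.  ``before_positive=True`` asks for
    + -> - (local maximum of the integrand), ``False`` for - -> +.  With
    ``peak_maximum`` the root must also attain the global maximum of the
    fitted curve over the closed domain.
    """
    roots = curve._real_interior_roots(dcoef)
    roots = roots[roots > lower_bound + curve.delta] if lower_bound > 0 else roots
    if len(roots) == 0:
        return None
    fmax = curve.domain_maximum() if peak_maximum else None
    for r in roots:
        before = npoly.polyval(r - curve.delta, dcoef)
        after = npoly.polyval(r + curve.delta, dcoef)
        if before_positive and not (before > 0 > after):
            continue
        if not before_positive and not (before < 0 < after):
            continue
        if peak_maximum:
            tol = 1e-9 * max(abs(fmax), 1.0)
            if curve(r) < fmax - tol:
                continue
        return float(r)
    return None


def find_pwd(curve: TrendCurve, require_peak_maximum: bool = True) -> Optional[IndexEstimate]:
    """Profit-willing distance: first + -> - root of f' inside the fit domain.

    With ``require_peak_maximum`` (default) the root must be the global
    maximum of the fitted curve — the distance band with the most
    participants — which suppresses spurious tail ripples.  Returns ``None``
    when no qualifying root exists (the undetected, sparse-region regime).
    """
    r = _first_sign_change_root(curve, curve.derivative(1), 0.0,
                                before_positive=True,
                                peak_maximum=require_peak_maximum)
    if r is None:
        return None
    return IndexEstimate(r, *report_index_bin(r, curve.bin_width))


def find_tld(
    curve: TrendCurve,
    pwd: Optional[IndexEstimate] = None,
    convention: str = "down-up",
) -> Optional[IndexEstimate]:
    """Tolerance-limited distance: first qualifying root of f'' beyond the PWD.

    The default ``"down-up"`` convention requires curvature to change
    - -> + (concave-down decline flattening into a concave-up tail).  The
    alternative ``"up-down"`` convention (+ -> -) is kept behind this switch.
    When the PWD is undetected the search starts from the domain origin.
    """
    if convention not in ("down-up", "up-down"):
        raise ValidationError(f"unknown TLD convention {convention!r}")
    lower = pwd.root if pwd is not None else 0.0
    r = _first_sign_change_root(curve, curve.derivative(2), lower,
                                before_positive=(convention == "up-down"))
    if r is None:
        return None
    return IndexEstimate(r, *report_index_bin(r, curve.bin_width))


def find_indices(
    dist: BinnedDistances,
    degree: int = DEFAULT_DEGREE,
    tail_quantile: Optional[float] = DEFAULT_TAIL_QUANTILE,
    include_zero_bins: bool = True,
    require_peak_maximum: bool = True,
    tld_convention: str = "down-up",
) -> tuple[TrendCurve, InflectionIndices]:
    """Fit the trend curve and extract both indices from binned counts."""
    curve = fit_trend_curve(dist, degree, tail_quantile, include_zero_bins)
    pwd = find_pwd(curve, require_peak_maximum)
    tld = find_tld(curve, pwd, tld_convention)
    k = int(np.argmax(dist.counts))  # ties: np.argmax takes the first, nearest origin
    argmax_bin = (k * dist.bin_width, (k + 1) * dist.bin_width)
    return curve, InflectionIndices(pwd=pwd, tld=tld, argmax_bin=argmax_bin)


def indices_report(curve: TrendCurve, indices: InflectionIndices) -> dict:
    """JSON-ready report of a fitted curve and its indices."""
    return {
        "schema_version": 1,
        "degree": curve.degree,
        "coefficients": curve.coef.tolist(),
        "domain": [curve.domain_lo, curve.domain_hi],
        "bin_width": curve.bin_width,
        "rss": curve.rss,
        **indices.to_dict(),
    }
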