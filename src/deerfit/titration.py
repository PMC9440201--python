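"""pK and Hill-coefficient estimation from pH-dependent state populations.

The population f of a tracked conformational state measured across pH is
fitted with a generalized Hill curve,

    f(pH) = f_base + (f_acid - f_base) / (1 + 10^(n (pH - pK))),

whose midpoint pK is the apparent proton-binding constant of the
conformational transition and whose Hill coefficient n reports on the
cooperativity of protonation (n = 1: independent single-site events). Both
plateaus are free by default. Points are weighted by the inverse variance
of their population uncertainties when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .globalfit import GlobalFitResult

__all__ = [
    "TitrationSeries",
    "TitrationFit",
    "HillTitrationModel",
    "hill_fit",
    "hill_curve",
    "titrate_from_fits",
]


def hill_curve(pH, pK: float, n: float, f_acid: float, f_base: float):
    """Generalized Hill titration curve; f -> f_acid as pH << pK."""
    pH = np.asarray(pH, dtype=float)
    return f_base + (f_acid - f_base) / (1.0 + 10.0 ** (n * (pH - pK)))


@dataclass
class TitrationSeries:
    """State population vs pH with 2σ error bars.

    `direction` tags whether the tracked distance peak rises or decreases
    with pH; it is inferred from the data trend when not given.
    """

    pH: np.ndarray
    f: np.ndarray
    sigma2: np.ndarray | None = None  # 2σ uncertainties per point
    direction: str | None = None
    pair: str | None = None

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.pH.shape != self.f.shape:
            raise ValueError("pH and f must have the same length")
        if np.unique(self.pH).size < 4:
            raise ValueError("need at least 4 distinct pH values")
        if np.any((self.f < 0) | (self.f > 1)):
            raise ValueError("populations must lie in [0, 1]")
        if self.sigma2 is not None:
            self.sigma2 = np.asarray(self.sigma2, dtype=float)
            if self.sigma2.shape != self.f.shape:
                raise ValueError("sigma2 and f must have the same length")
            if np.any(self.sigma2 < 0):
                raise ValueError("uncertainties must be nonnegative")
        if self.direction is None:
            slope = np.polyfit(self.pH, self.f, 1)[0]
            self.direction = "rising" if slope >= 0 else "decreasing"


@dataclass
class TitrationFit:
    """Hill-fit estimates with 2σ uncertainties."""

    pK: float
    n: float
    f_acid: float
    f_base: float
    pK_sigma2: float
    n_sigma2: float
    f_acid_sigma2: float
    f_base_sigma2: float
    rss: float
    n_fixed: bool = False
    flags: list[str] = field(default_factory=list)

    def predict(self, pH):
        return hill_curve(pH, self.pK, self.n, self.f_acid, self.f_base)

    def to_dict(self) -> dict:
        return {
            "pK": self.pK,
            "hill_n": self.n,
            "f_acid": self.f_acid,
            "f_base": self.f_base,
            "pK_2sigma": self.pK_sigma2,
            "hill_n_2sigma": self.n_sigma2,
            "f_acid_2sigma": self.f_acid_sigma2,
            "f_base_2sigma": self.f_base_sigma2,
            "rss": self.rss,
            "n_fixed": self.n_fixed,
            "flags": list(self.flags),
        }


class HillTitrationModel(BaseEstimator):
    """Weighted nonlinear least-squares Hill fit of population vs pH.

    Parameters
    ----------
    fix_n : float or None
        If set, the Hill coefficient is held at this value (e.g. 1 for
        independent protonation) and only pK and the plateaus are fitted.

    Attributes (after fit)
    ----------------------
    pK_, n_, f_acid_, f_base_ : point estimates.
    pK_sigma2_, n_sigma2_, ... : 2σ uncertainties.
    result_ : TitrationFit.
    """

    def __init__(self, fix_n: float | None = None):
        self.fix_n = fix_n

    def fit(self, X, y=None, sample_sigma2=None):
        """Fit to `X` = TitrationSeries, or pH array with `y` populations."""
        if isinstance(X, TitrationSeries):
            series = X
        else:
            series = TitrationSeries(np.asarray(X, float).ravel(), y, sample_sigma2)
        pH, f = series.pH, series.f
        spread = float(f.max() - f.min())
        flags = []
        if spread < 1e-3:
            raise ValueError(
                "populations are constant across pH: no transition in range, "
                "pK and n are unidentifiable"
            )
        sig = series.sigma2
        if sig is None or np.all(sig == 0):
            w = np.ones_like(f)
        else:
            floor = max(1e-3, 0.05 * float(np.median(sig[sig > 0])) if np.any(sig > 0) else 1e-3)
            w = 1.0 / np.maximum(sig / 2.0, floor)  # sigma2 is 2σ
            w /= w.max()

        # crude midpoint guess: pH where f crosses the half-range
        half = 0.5 * (f.max() + f.min())
        pK0 = float(pH[np.argmin(np.abs(f - half))])
        f_lo_pH = float(f[np.argmin(pH)])
        f_hi_pH = float(f[np.argmax(pH)])

        fix_n = self.fix_n

        def pack(theta):
            if fix_n is None:
                pK, n, fa, fb = theta
            else:
                pK, fa, fb = theta
                n = fix_n
            return pK, n, fa, fb

        def resid(theta):
            pK, n, fa, fb = pack(theta)
            return w * (hill_curve(pH, pK, n, fa, fb) - f)

        if fix_n is None:
            theta0 = [pK0, 1.0, f_lo_pH, f_hi_pH]
            lo = [pH.min() - 3, -6.0, 0.0, 0.0]
            hi = [pH.max() + 3, 6.0, 1.0, 1.0]
        else:
            theta0 = [pK0, f_lo_pH, f_hi_pH]
            lo = [pH.min() - 3, 0.0, 0.0]
            hi = [pH.max() + 3, 1.0, 1.0]
        best = None
        for start_shift in (0.0, -1.0, 1.0, -2.0, 2.0):
            t0 = np.array(theta0, dtype=float)
            t0[0] = np.clip(t0[0] + start_shift, lo[0], hi[0])
            sol = least_squares(
                resid, t0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
            if best is None or sol.cost < best.cost:
                best = sol
        pK, n, fa, fb = pack(best.x)
        res_unw = hill_curve(pH, pK, n, fa, fb) - f
        rss = float(np.sum(res_unw**2))

        # covariance of the fit parameters (2-sided, from weighted J)
        J = best.jac
        dof = max(len(f) - len(best.x), 1)
        s2 = 2.0 * best.cost / dof
        try:
            cov = s2 * np.linalg.pinv(J.T @ J, rcond=1e-12)
            perr2 = 2.0 * np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            perr2 = np.full(len(best.x), np.nan)
            flags.append("singular covariance")

        if abs(n) < 0.05:
            flags.append("hill coefficient unidentifiable (|n| ~ 0)")

        if fix_n is None:
            pK_e, n_e, fa_e, fb_e = perr2
        else:
            pK_e, fa_e, fb_e = perr2
            n_e = 0.0

        # canonicalize: report n > 0 (the acid/base plateaus carry the sign)
        if n < 0:
            n, fa, fb = -n, fb, fa
            fa_e, fb_e = fb_e, fa_e

        self.result_ = TitrationFit(
            pK=float(pK),
            n=float(n),
            f_acid=float(fa),
            f_base=float(fb),
            pK_sigma2=float(pK_e),
            n_sigma2=float(n_e),
            f_acid_sigma2=float(fa_e),
            f_base_sigma2=float(fb_e),
            rss=rss,
            n_fixed=fix_n is not None,
            flags=flags,
        )
        self.pK_ = self.result_.pK
        self.n_ = self.result_.n
        self.f_acid_ = self.result_.f_acid
        self.f_base_ = self.result_.f_base
        self.pK_sigma2_ = self.result_.pK_sigma2
        self.n_sigma2_ = self.result_.n_sigma2
        return self

    def predict(self, pH):
        return self.result_.predict(pH)


def hill_fit(series: TitrationSeries, fix_n: float | None = None) -> TitrationFit:
    """Functional wrapper over :class:`HillTitrationModel`."""
    return HillTitrationModel(fix_n=fix_n).fit(series).result_


def titrate_from_fits(
    fits,
    selector,
    condition: int | str = 0,
    pair: str | None = None,
) -> TitrationSeries:
    """Assemble a titration series from global-fit results tagged by pH.

    `fits` is a list of (pH, GlobalFitResult) or (pH, GlobalFitResult,
    condition) tuples — the latter picks a condition out of one shared
    global fit. `selector` (component index or center window in nm) must
    resolve exactly one component at every pH.
    """
    pH_vals, f_vals, s2_vals = [], [], []
    for entry in fits:
        pH, res = entry[0], entry[1]
        cond = entry[2] if len(entry) > 2 else condition
        try:
            f, s2 = res.state_population(selector, cond)
        except ValueError as exc:
            raise ValueError(f"selector failed at pH {pH}: {exc}") from exc
        pH_vals.append(pH)
        f_vals.append(f)
        s2_vals.append(s2)
    return TitrationSeries(
        np.array(pH_vals), np.array(f_vals), np.array(s2_vals), pair=pair
    )
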