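"""Single-site binding model and equilibrium dissociation-constant fitting.

Gel-shift and spot-blot titrations of an RNA against increasing protein
concentrations yield a fractional-saturation curve.  Under the single-site
model the bound fraction at protein concentration c is

    f(c) = c / (Kd + c)

so f = 0.5 at c = Kd.  ``fit_kd`` estimates Kd by unweighted nonlinear
least squares in log10(Kd) space, which enforces positivity and makes the
fit scale-invariant; results are apparent Kd values (no cooperativity
unless a Hill coefficient is requested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["BindingCurve", "FitResult", "fraction_bound", "fit_kd", "FittingError"]


class FittingError(RuntimeError):
    """Raised when the least-squares fit cannot produce an estimate."""


@dataclass(frozen=True)
class BindingCurve:
    """A titration: protein concentrations (µM) and bound fractions."""

    concentrations: np.ndarray
    fraction_bound: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations",
                           np.asarray(self.concentrations, dtype=float))
        object.__setattr__(self, "fraction_bound",
                           np.asarray(self.fraction_bound, dtype=float))
        c, f = self.concentrations, self.fraction_bound
        if c.shape != f.shape:
            raise ValueError("concentration and fraction arrays differ in length")
        if (c <= 0).any() or (np.diff(c) <= 0).any():
            raise ValueError("concentrations must be positive and strictly increasing")


@dataclass(frozen=True)
class FitResult:
    kd: float
    kd_stderr: float
    hill: float
    fitted: np.ndarray
    residual_ss: float

    def as_dict(self) -> dict:
        return {"kd": self.kd, "kd_stderr": self.kd_stderr, "hill": self.hill,
                "residual_ss": self.residual_ss}


def fraction_bound(kd: float, conc) -> np.ndarray | float:
    """Single-site bound fraction, conc / (kd + conc)."""
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    conc = np.asarray(conc, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be non-negative")
    out = conc / (kd + conc)
    return float(out) if out.ndim == 0 else out


def _model(conc, log10_kd, n):
    kd = 10.0 ** log10_kd
    cn = conc ** n
    return cn / (kd ** n + cn)


def fit_kd(curve: BindingCurve, hill: bool = False) -> FitResult:
    """Least-squares Kd estimate from a fractional-saturation titration.

    Requires at least 4 points with observations on both sides of
    half-saturation.  The asymptotic standard error of Kd is propagated
    from the log10-space covariance.  With ``hill=True`` a Hill
    coefficient is co-fitted (default fixed at n = 1).
    """
    c, f = curve.concentrations, curve.fraction_bound
    if len(c) < 4:
        raise FittingError(f"need >= 4 titration points, got {len(c)}")
    if not ((f < 0.5).any() and (f > 0.5).any()):
        raise FittingError("titration must span both sides of half-saturation")
    if np.allclose(f, 0.0):
        raise FittingError("all bound fractions are zero")

    # crude initial guess: concentration nearest half-saturation
    k0 = float(c[np.argmin(np.abs(f - 0.5))])
    try:
        if hill:
            popt, pcov = curve_fit(_model, c, f, p0=[np.log10(k0), 1.0],
                                   maxfev=10000)
        else:
            popt, pcov = curve_fit(lambda x, lk: _model(x, lk, 1.0), c, f,
                                   p0=[np.log10(k0)], maxfev=10000)
    except RuntimeError as exc:
        raise FittingError(f"least squares did not converge: {exc}") from exc

    log10_kd = popt[0]
    n = popt[1] if hill else 1.0
    kd = float(10.0 ** log10_kd)
    var = pcov[0, 0]
    stderr = float(np.log(10.0) * kd * np.sqrt(var)) if np.isfinite(var) else float("nan")
    fitted = _model(c, log10_kd, n)
    rss = float(np.sum((f - fitted) ** 2))
    return FitResult(kd=kd, kd_stderr=stderr, hill=float(n),
                     fitted=fitted, residual_ss=rss)
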