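"""Three-parameter Mittag-Leffler (Prabhakar) function and its rate spectrum.

The viscoelastic part of the memory kernel is the generalized Prabhakar
relaxation function

    e_{lam,nu}^{delta}(t/tau) = (t/tau)^(nu-1) E_{lam,nu}^{delta}[-(t/tau)^lam],

where E_{lam,nu}^{delta} is the three-parameter Mittag-Leffler function

    E_{lam,nu}^{delta}(z) = sum_k Gamma(delta+k) z^k
                                   / (Gamma(delta) k! Gamma(lam k + nu)).

For 0 < lam <= 1 and 0 < lam*delta <= nu <= 1 the relaxation function is
completely monotone and can be written as a nonnegative superposition of
exponential decays,

    e_{lam,nu}^{delta}(t/tau) = int_0^inf p(f) exp(-f t) df,

with the relaxation-rate spectrum ``spectrum_p``.

Numerical strategy for E on the negative real axis: the power series is used
where its float64 cancellation estimate meets the accuracy target, the
algebraic large-argument expansion where its optimal-truncation error does,
and an adaptive-precision (mpmath) series bridges the crossover band.  The
target relative accuracy is 1e-10 on x in [0, 1e6].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import mpmath as mp
import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln, rgamma

from .errors import AccuracyError, ParameterDomainError, SingularPointError

__all__ = [
    "MLParameters",
    "cm_region",
    "ml3_negative",
    "gml",
    "spectrum_p",
    "gml_from_spectrum",
]

_RTOL = 1e-11  # internal per-point accuracy target
_MAX_SERIES_TERMS = 420
_MAX_ASYMPTOTIC_TERMS = 220
# float64 series accepted only if max|term|/|sum| is below this
_MAX_CANCELLATION = 1e3


@dataclass(frozen=True)
class MLParameters:
    """Parameters of the Prabhakar kernel component.

    Attributes
    ----------
    lam, nu, delta : float
        Dimensionless exponents of E_{lam,nu}^{delta}.
    tau : float
        Timescale of the retarded response, ps.
    """

    lam: float
    nu: float
    delta: float = 1.0
    tau: float = 1.0

    def __post_init__(self):
        for name in ("lam", "nu", "delta", "tau"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterDomainError(
                    f"MLParameters.{name} must be finite and > 0, got {v!r}"
                )

    @property
    def completely_monotone(self) -> bool:
        """True iff 0 < lam <= 1 and 0 < lam*delta <= nu <= 1."""
        return (0 < self.lam <= 1) and (0 < self.lam * self.delta <= self.nu <= 1)


def cm_region(p: MLParameters) -> bool:
    """Whether ``p`` lies in the complete-monotonicity region of the kernel."""
    return p.completely_monotone


# ---------------------------------------------------------------------------
# E_{lam,nu}^{delta}(-x) on the negative real axis
# ---------------------------------------------------------------------------

def _series_f64(x: float, lam: float, nu: float, delta: float):
    """Float64 power series.  Returns (value, ok, log_max_term)."""
    if x == 0.0:
        return float(rgamma(nu)), True, 0.0
    k = np.arange(_MAX_SERIES_TERMS, dtype=float)
    logt = (
        gammaln(delta + k)
        - gammaln(delta)
        - gammaln(k + 1.0)
        - gammaln(lam * k + nu)
        + k * math.log(x)
    )
    log_max = float(np.max(logt))
    # series not converged within the term cap
    if logt[-1] > log_max - 36.0:
        return math.nan, False, log_max
    sign = np.where(k.astype(np.int64) % 2 == 0, 1.0, -1.0)
    if log_max > 660.0:  # exp would overflow; scaled sum still cancels badly
        return math.nan, False, log_max
    terms = sign * np.exp(logt - log_max)
    total = float(np.sum(terms)) * math.exp(log_max)
    if total == 0.0 or not math.isfinite(total):
        return math.nan, False, log_max
    cancellation = math.exp(log_max) / abs(total)
    return total, cancellation <= _MAX_CANCELLATION, log_max


def _asymptotic(x: float, lam: float, nu: float, delta: float):
    """Large-argument algebraic expansion with optimal truncation.

    E_{lam,nu}^{delta}(-x) ~ x^(-delta)/Gamma(delta)
        * sum_j (-1)^j Gamma(delta+j)/j! / Gamma(nu - lam (delta+j)) x^(-j).

    Returns (value, ok).
    """
    if x <= 1.0:
        return math.nan, False
    lx = math.log(x)
    j = np.arange(_MAX_ASYMPTOTIC_TERMS, dtype=float)
    log_mag = gammaln(delta + j) - gammaln(delta) - gammaln(j + 1.0) - (delta + j) * lx
    z = nu - lam * (delta + j)
    # 1/Gamma(z) via the reflection formula sin(pi z) Gamma(1-z) / pi for
    # z < 1/2, all in log space (direct rgamma overflows at large order);
    # the truncation point is set on the envelope Gamma(1-z)/pi, which does
    # not share the sin zeros of individual coefficients
    refl = z <= 0.5
    sin_piz = np.sin(np.pi * np.mod(z, 2.0))  # reduce the angle first
    with np.errstate(divide="ignore"):
        log_coeff = np.where(
            refl,
            gammaln(np.where(refl, 1.0 - z, 1.0)) - math.log(math.pi)
            + np.log(np.abs(sin_piz)),
            np.log(np.abs(rgamma(np.where(refl, 1.0, z)))),
        )
        log_coeff_env = np.where(
            refl,
            gammaln(np.where(refl, 1.0 - z, 1.0)) - math.log(math.pi),
            log_coeff,
        )
    sign = np.where(refl, np.sign(sin_piz), np.sign(rgamma(np.where(refl, 1.0, z))))
    log_env = log_mag + log_coeff_env
    stop = int(np.argmin(log_env))
    if stop < 3 or log_env[0] > 660.0:
        return math.nan, False
    sl = slice(0, stop + 1)
    terms = ((-1.0) ** j[sl]) * sign[sl] * np.exp(log_mag[sl] + log_coeff[sl])
    total = float(np.sum(terms))
    log_err = float(np.max(log_env[stop : stop + 3]))
    ok = total != 0.0 and log_err <= math.log(_RTOL * abs(total))
    return total, ok


def _series_mp(x: float, lam: float, nu: float, delta: float) -> float:
    """Arbitrary-precision series for the crossover band."""
    # locate the series peak (near k ~ x^(1/lam)) to size the precision:
    # digits lost to cancellation ~ log10(max term / result); the result is
    # bounded below by the leading algebraic terms, of order x^-delta.
    k_peak = x ** (1.0 / lam)
    k = np.arange(int(4 * k_peak) + 50, dtype=float)
    logt = (
        gammaln(delta + k)
        - gammaln(delta)
        - gammaln(k + 1.0)
        - gammaln(lam * k + nu)
        + k * math.log(x)
    )
    log_max = float(np.max(logt))
    guard = 30
    lost = max(0.0, log_max / math.log(10) + (delta + 2) * math.log10(max(x, 1.0)))
    dps = int(lost) + guard
    if dps > 4000:
        raise AccuracyError(
            f"Prabhakar evaluation at x={x:g} needs ~{dps} digits; out of the "
            f"supported range (lam={lam}, nu={nu}, delta={delta})"
        )
    with mp.workdps(dps):
        # promote parameters before any arithmetic: float64 rounding in the
        # gamma arguments is amplified by the series cancellation
        xm, lam_m, nu_m, delta_m = (mp.mpf(v) for v in (x, lam, nu, delta))
        total = mp.mpf(0)
        term = mp.rgamma(nu_m)  # k = 0
        g_prev = mp.gamma(nu_m)
        k = 1
        kmax = 40000
        while k < kmax:
            total += term
            g_cur = mp.gamma(lam_m * k + nu_m)
            term = term * (-xm) * (delta_m + k - 1) / k * (g_prev / g_cur)
            g_prev = g_cur
            if abs(term) < mp.mpf(10) ** (-dps + 3) * (abs(total) + mp.mpf(10) ** (-dps)):
                total += term
                break
            k += 1
        else:
            raise AccuracyError(
                f"Prabhakar series did not converge at x={x:g} "
                f"(lam={lam}, nu={nu}, delta={delta})"
            )
        return float(total)


def _ml3_scalar(x: float, lam: float, nu: float, delta: float) -> float:
    if x == 0.0:
        return float(rgamma(nu))
    val, ok, _ = _series_f64(x, lam, nu, delta)
    if ok:
        return val
    val, ok = _asymptotic(x, lam, nu, delta)
    if ok:
        return val
    return _series_mp(x, lam, nu, delta)


def ml3_negative(x, p: MLParameters):
    """Evaluate E_{lam,nu}^{delta}(-x) for x >= 0.

    Parameters
    ----------
    x : float or array_like
        Nonnegative argument magnitude.
    p : MLParameters
        Exponents (``tau`` is not used here).

    Returns
    -------
    float or ndarray
        E_{lam,nu}^{delta}(-x), continuous in x, relative accuracy about
        1e-10 on x in [0, 1e6].
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ParameterDomainError("ml3_negative requires finite x >= 0")
    out = np.empty(arr.shape, dtype=float)
    for idx in np.ndindex(arr.shape):
        out[idx] = _ml3_scalar(float(arr[idx]), p.lam, p.nu, p.delta)
    if np.isscalar(x) or arr.shape == ():
        return float(out.reshape(())[()])
    return out


def gml(t, p: MLParameters):
    """Generalized Prabhakar relaxation function e_{lam,nu}^{delta}(t/tau).

    e(t/tau) = (t/tau)^(nu-1) * E_{lam,nu}^{delta}[-(t/tau)^lam].
    Dimensionless; completely monotone on t > 0 when ``cm_region(p)`` holds.

    t = 0 is admitted only for nu >= 1 (the function diverges as
    (t/tau)^(nu-1) otherwise).
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ParameterDomainError("gml requires t >= 0")
    if np.any(arr == 0) and p.nu < 1:
        raise SingularPointError("gml(0) is singular for nu < 1")
    u = arr / p.tau
    with np.errstate(divide="ignore"):
        prefac = np.where(arr == 0, 1.0 if p.nu == 1 else 0.0, u ** (p.nu - 1.0))
    e = ml3_negative(u**p.lam, p)
    out = prefac * np.asarray(e)
    if np.isscalar(t) or arr.shape == ():
        return float(np.asarray(out).reshape(())[()])
    return out


# ---------------------------------------------------------------------------
# relaxation-rate spectrum
# ---------------------------------------------------------------------------

def spectrum_p(f, p: MLParameters, check_cm: bool = True):
    """Relaxation-rate spectrum p(f) of the Prabhakar relaxation function.

    p(f) = tau (f tau)^(lam delta - nu)
           * sin[pi (nu - lam delta) + delta theta(f)]
           / ( pi [ (f tau)^(2 lam) + 2 (f tau)^lam cos(pi lam) + 1 ]^(delta/2) )

    with theta(f) = arg[(-f tau)^lam + 1] on the principal branch,
    theta = atan2( sin(pi lam) (f tau)^lam, cos(pi lam) (f tau)^lam + 1 ).

    Units: f in ps^-1, p(f) in ps; int_0^inf p(f) e^{-f t} df = gml(t).
    Nonnegative everywhere when ``cm_region(p)`` holds; outside that region a
    warning is emitted and the density may change sign.
    """
    if check_cm and not p.completely_monotone:
        warnings.warn(
            "spectrum_p evaluated outside the complete-monotonicity region; "
            "the density is not guaranteed nonnegative",
            stacklevel=2,
        )
    arr = np.asarray(f, dtype=float)
    if np.any(arr <= 0):
        raise ParameterDomainError("spectrum_p requires f > 0")
    ft = arr * p.tau
    ftl = ft**p.lam
    theta = np.arctan2(np.sin(np.pi * p.lam) * ftl, np.cos(np.pi * p.lam) * ftl + 1.0)
    num = np.sin(np.pi * (p.nu - p.lam * p.delta) + p.delta * theta)
    den = np.pi * (ft ** (2 * p.lam) + 2 * ftl * np.cos(np.pi * p.lam) + 1.0) ** (
        p.delta / 2.0
    )
    out = p.tau * ft ** (p.lam * p.delta - p.nu) * num / den
    if np.isscalar(f) or arr.shape == ():
        return float(np.asarray(out).reshape(())[()])
    return out


def gml_from_spectrum(t: float, p: MLParameters, epsrel: float = 1e-10) -> float:
    """gml(t) via adaptive quadrature of the spectral superposition.

    Integrates p(f) exp(-f t) on a logarithmic axis; serves as an independent
    route to the relaxation function in the CM region (used for
    cross-validation of the series/asymptotic evaluation).
    """
    if t <= 0:
        raise ParameterDomainError("gml_from_spectrum requires t > 0")
    if not p.completely_monotone:
        raise ParameterDomainError("spectrum route requires CM-region parameters")
    # integrand on u = ln f: p(e^u) e^{-t e^u} e^u; algebraic decay at
    # u -> -inf with exponent 1 + lam*delta - nu > 0, exponential cutoff at
    # large f from e^{-f t}
    low_exp = 1.0 + p.lam * p.delta - p.nu
    u_lo = math.log(1.0 / p.tau) - 45.0 / low_exp
    u_hi = math.log(max(200.0 / t, 10.0 / p.tau))

    def integrand(u):
        fr = math.exp(u)
        return spectrum_p(fr, p, check_cm=False) * math.exp(-fr * t) * fr

    val, _ = quad(
        integrand,
        u_lo,
        u_hi,
        epsabs=0.0,
        epsrel=epsrel,
        limit=400,
        points=[math.log(1.0 / p.tau)] if u_lo < math.log(1.0 / p.tau) < u_hi else None,
    )
    return val
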