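"""The GLE model of lateral diffusion with a Mittag-Leffler memory kernel.

The center of mass of a membrane protein obeys a generalized Langevin
equation

    M dU/dt = - int_0^t zeta(t-u) U(u) du + Xi(t),

with colored Gaussian noise tied to the friction kernel by the
fluctuation-dissipation theorem and a kernel combining an instantaneous
viscous term and a retarded Prabhakar elastic term,

    zeta(t) = M [ omega_s^2 delta(t/tau_s)
                  + omega_0^2 (t/tau)^(nu-1) E_{lam,nu}^{delta}(-(t/tau)^lam) ].

Its Laplace transform is

    zeta_hat(s) = xi_s + xi_p (tau s)^(delta lam - nu) / (1 + (tau s)^lam)^delta,

with xi_s = M omega_s, xi_p = M omega_p and omega_p = omega_0^2 tau.  All
observables follow from the relaxation functions

    g_hat = 1 / (M s + zeta_hat),   H_hat = g_hat / s,   I_hat = g_hat / s^2,

via  Cv(t) = d kB T g(t),  D(t) = kB T H(t),  MSD(t) = 2 d kB T I(t)
(d the spatial dimension, 2 for lateral diffusion).  The relation
delta*lam = nu (the Brownian constraint) makes the long-time diffusion
coefficient finite: D_inf = kB T / (xi_s + xi_p).

Internal units: g/mol, nm, ps, K (see ``constants``); friction converts to
Pa s um and diffusion coefficients to um^2/s at the API boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import FRICTION_TO_PA_S_UM, KB, NM2_PER_PS_TO_UM2_PER_S
from .curves import ObservableCurve
from .errors import ParameterDomainError
from .laplace import TransformFunction, invert
from .mlf import MLParameters

__all__ = [
    "GLEParameters",
    "DerivedParameters",
    "zeta_hat",
    "relaxation_hats",
    "observable",
    "short_time",
    "long_time",
    "d_infinity",
    "derive_parameters",
    "msd_hat_m2",
]

_KERNEL_VARIANTS = ("mittag-leffler", "exponential", "frozen")


@dataclass(frozen=True)
class GLEParameters:
    """Physical parameters of the kernel and bath.

    Attributes
    ----------
    M : float
        Particle mass, g/mol.
    T : float
        Temperature, K.
    omega_s : float
        Frequency of the instantaneous (viscous) friction term, ps^-1;
        1/omega_s is the timescale of the end of the ballistic regime.
    omega_p : float
        Frequency scale of the retarded friction, ps^-1
        (omega_p = omega_0^2 tau with omega_0 the transient-confinement
        frequency).
    tau : float
        Timescale of the retarded (elastic) membrane response, ps.
    lam, nu, delta : float
        Exponents of the Prabhakar kernel component.
    dim : int
        Spatial dimension d (2 for lateral diffusion).
    """

    M: float
    T: float
    omega_s: float
    omega_p: float
    tau: float
    lam: float
    nu: float
    delta: float = 1.0
    dim: int = 2

    def __post_init__(self):
        for name in ("M", "T", "omega_s", "tau", "lam", "nu", "delta"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterDomainError(
                    f"GLEParameters.{name} must be finite and > 0, got {v!r}"
                )
        if not (np.isfinite(self.omega_p) and self.omega_p >= 0):
            raise ParameterDomainError("GLEParameters.omega_p must be >= 0")
        if self.dim not in (1, 2, 3):
            raise ParameterDomainError("dim must be 1, 2 or 3")

    @property
    def ml(self) -> MLParameters:
        return MLParameters(lam=self.lam, nu=self.nu, delta=self.delta, tau=self.tau)

    @property
    def completely_monotone(self) -> bool:
        return self.ml.completely_monotone

    @property
    def brownian_constraint(self) -> bool:
        """True iff delta*lam = nu (finite nonzero long-time diffusion)."""
        return abs(self.delta * self.lam - self.nu) <= 1e-12

    @property
    def kBT(self) -> float:
        """Thermal energy in internal units (amu nm^2 ps^-2 = kJ/mol)."""
        return KB * self.T

    @property
    def xi_s(self) -> float:
        """Viscous friction M*omega_s, internal units g mol^-1 ps^-1."""
        return self.M * self.omega_s

    @property
    def xi_p(self) -> float:
        """Retarded friction M*omega_p, internal units g mol^-1 ps^-1."""
        return self.M * self.omega_p

    @property
    def omega_0(self) -> float:
        """Transient-confinement frequency sqrt(omega_p/tau), ps^-1."""
        return math.sqrt(self.omega_p / self.tau)


@dataclass(frozen=True)
class DerivedParameters:
    """Parameters derived from a fit, in laboratory units."""

    omega0: float  # ps^-1
    tau_s: float  # ps
    xi_s: float  # Pa s um
    xi_p: float  # Pa s um
    phi: float  # dimensionless xi_p / xi_s
    D_inf: float  # um^2/s


def zeta_hat(s, p: GLEParameters, kernel_variant: str = "mittag-leffler"):
    """Laplace transform of the friction kernel, internal units.

    Works elementwise for complex numpy arrays and for mpmath scalars.
    ``kernel_variant`` selects the elastic component: the Prabhakar kernel
    (default), a plain exponential exp(-t/tau) (transient harmonic
    confinement), or the component frozen at 1 (permanent harmonic
    confinement; MSD plateaus at 2 d kB T / (M omega_0^2)).
    """
    if kernel_variant not in _KERNEL_VARIANTS:
        raise ParameterDomainError(f"unknown kernel variant {kernel_variant!r}")
    xi_s = p.xi_s
    if p.omega_p == 0:
        return xi_s + 0.0 * s
    if kernel_variant == "mittag-leffler":
        ts = p.tau * s
        return xi_s + p.xi_p * ts ** (p.delta * p.lam - p.nu) / (1 + ts**p.lam) ** p.delta
    if kernel_variant == "exponential":
        return xi_s + p.xi_p / (1 + p.tau * s)
    # frozen: elastic term is M omega_0^2 * 1(t); transform M omega_0^2 / s
    return xi_s + p.M * p.omega_0**2 / s


def relaxation_hats(s, p: GLEParameters, kernel_variant: str = "mittag-leffler"):
    """The three relaxation-function transforms (g_hat, H_hat, I_hat).

    g_hat = 1/(M s + zeta_hat);  H_hat = g_hat/s;  I_hat = g_hat/s^2.
    H_hat excludes the kB T factor (it is the transform of int_0^t g);
    thermal factors enter only in :func:`observable`.
    """
    g = 1.0 / (p.M * s + zeta_hat(s, p, kernel_variant))
    return g, g / s, g / s**2


def msd_hat_m2(s, theta, M: float, kBT: float, dim: int = 2):
    """Laplace-domain MSD of the fitting model (Brownian constraint built in).

    theta = (omega_s, omega_p, tau, lam, delta); under delta*lam = nu the
    kernel transform simplifies and

        MSD_hat(s) = (2 d kB T / M) / [ s^2 ( s + omega_s
                      + omega_p / (1 + (tau s)^lam)^delta ) ].

    Broadcasts over numpy arrays in both s and theta components.
    """
    omega_s, omega_p, tau, lam, delta = theta
    return (2.0 * dim * kBT / M) / (
        s**2 * (s + omega_s + omega_p / (1.0 + (tau * s) ** lam) ** delta)
    )


def _transform_for(kind: str, p: GLEParameters, kernel_variant: str):
    """Laplace transform of the requested observable (thermal factors in)."""
    d, kBT = p.dim, p.kBT

    if kind == "vacf":
        def F(s):
            g, _, _ = relaxation_hats(s, p, kernel_variant)
            return d * kBT * g
    elif kind == "dcoef":
        def F(s):
            _, H, _ = relaxation_hats(s, p, kernel_variant)
            return kBT * H
    elif kind == "msd":
        def F(s):
            _, _, I = relaxation_hats(s, p, kernel_variant)
            return 2.0 * d * kBT * I
    else:
        raise ParameterDomainError(f"unknown observable kind {kind!r}")
    return TransformFunction(F, 0.0)


def observable(
    kind: str,
    times,
    p: GLEParameters,
    kernel_variant: str = "mittag-leffler",
    method: str = "talbot",
    accuracy_goal: float = 1e-6,
    allow_multiprecision: bool = True,
) -> ObservableCurve:
    """Evaluate a model observable by numerical inverse Laplace transform.

    kind is ``msd`` (2 d kB T I(t), nm^2), ``vacf`` (d kB T g(t),
    nm^2/ps^2) or ``dcoef`` (kB T H(t), nm^2/ps); times in ps, positive and
    sorted.
    """
    t = np.asarray(times, dtype=float)
    F = _transform_for(kind, p, kernel_variant)
    res = invert(
        F,
        t,
        method=method,
        accuracy_goal=accuracy_goal,
        allow_multiprecision=allow_multiprecision,
    )
    values = res.values
    if kind == "msd":
        # inversion noise may leave tiny negatives at the ballistic onset
        values = np.maximum(values, 0.0)
    return ObservableCurve(
        t,
        values,
        kind,
        meta={
            "source": "model",
            "kernel_variant": kernel_variant,
            "ilt_method": method,
            "max_error_estimate": float(np.max(res.error_estimate)),
        },
    )


def short_time(kind: str, t, p: GLEParameters):
    """Leading short-time (ballistic-regime) laws, valid for t << 1/omega_s.

    Cv ~ (d kB T/M)(1 - omega_s t);  D ~ (kB T/M)(1 - omega_s t/2) t;
    MSD ~ (d kB T/M)(1 - omega_s t/3) t^2.
    """
    t = np.asarray(t, dtype=float)
    d, kBT, ws = p.dim, p.kBT, p.omega_s
    if kind == "vacf":
        return d * kBT / p.M * (1.0 - ws * t)
    if kind == "dcoef":
        return kBT / p.M * (1.0 - ws * t / 2.0) * t
    if kind == "msd":
        return d * kBT / p.M * (1.0 - ws * t / 3.0) * t**2
    raise ParameterDomainError(f"unknown observable kind {kind!r}")


def long_time(kind: str, t, p: GLEParameters):
    """Long-time asymptotes under the Brownian constraint delta*lam = nu.

    MSD -> 2 d kB T t/(xi_s + xi_p) (exact slope 2 d D_inf), D -> D_inf, and
    the VACF acquires a negative power-law tail

        Cv(t) ~ (d kB T) delta tau^lam t^(-lam-1) / Gamma(-lam)
                * (xi_p/xi_s^2) / (1 + xi_p/xi_s)^2,

    equivalently with (omega_p/omega_s^2)/(M (1+omega_p/omega_s)^2); both
    algebraically identical forms are evaluated and cross-checked.
    Requires non-integer lam (Gamma(-lam) is singular otherwise; for
    integer lam the tail degenerates since 1/Gamma(0) = 0).
    """
    if not p.brownian_constraint:
        raise ParameterDomainError(
            "long-time asymptotes require the Brownian constraint delta*lam = nu"
        )
    t = np.asarray(t, dtype=float)
    d, kBT = p.dim, p.kBT
    if kind == "msd":
        return 2.0 * d * kBT * t / (p.xi_s + p.xi_p)
    if kind == "dcoef":
        return np.full_like(t, kBT / (p.xi_s + p.xi_p))
    if kind == "vacf":
        if abs(p.lam - round(p.lam)) < 1e-12:
            raise ParameterDomainError(
                "VACF power-law tail requires non-integer lam"
            )
        gamma_neg = math.gamma(-p.lam)
        common = d * kBT * p.delta * p.tau**p.lam * t ** (-p.lam - 1.0) / gamma_neg
        phi = p.xi_p / p.xi_s
        form_xi = common * (p.xi_p / p.xi_s**2) / (1.0 + phi) ** 2
        wr = p.omega_p / p.omega_s
        form_omega = common * (p.omega_p / p.omega_s**2) / (p.M * (1.0 + wr) ** 2)
        assert np.allclose(form_xi, form_omega, rtol=1e-10), "prefactor forms differ"
        return form_xi
    raise ParameterDomainError(f"unknown observable kind {kind!r}")


def d_infinity(p: GLEParameters) -> float:
    """Long-time diffusion coefficient kB T/(xi_s + xi_p), in um^2/s."""
    d_internal = p.kBT / (p.xi_s + p.xi_p)  # nm^2/ps
    return d_internal * NM2_PER_PS_TO_UM2_PER_S


def derive_parameters(p: GLEParameters) -> DerivedParameters:
    """Physical parameters in laboratory units derived from the fit vector."""
    return DerivedParameters(
        omega0=p.omega_0,
        tau_s=1.0 / p.omega_s,
        xi_s=p.xi_s * FRICTION_TO_PA_S_UM,
        xi_p=p.xi_p * FRICTION_TO_PA_S_UM,
        phi=p.xi_p / p.xi_s if p.xi_s > 0 else math.inf,
        D_inf=d_infinity(p),
    )
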