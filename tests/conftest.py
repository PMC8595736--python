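"""Shared fixtures: reference parameter sets and oracles."""

from __future__ import annotations

import numpy as np
import pytest

from glediff import GLEParameters, MLParameters

# Best-fit parameter set of the membrane-protein study (M2 muscarinic
# receptor in a mixed bilayer): the package's standard reference point.
TABLE_PARAMS = dict(
    M=41697.0,        # g/mol
    T=310.0,          # K
    omega_s=0.98,     # ps^-1
    omega_p=447.0,    # ps^-1
    tau=13.4e3,       # ps (13.4 ns)
    lam=0.715,
    nu=0.715,
    delta=1.0,
    dim=2,
)


@pytest.fixture(scope="session")
def ref_params() -> GLEParameters:
    return GLEParameters(**TABLE_PARAMS)


@pytest.fixture(scope="session")
def ref_ml() -> MLParameters:
    return MLParameters(lam=0.715, nu=0.715, delta=1.0, tau=1.0)


def ml3_series_oracle(x: float, lam: float, nu: float, delta: float):
    """Arbitrary-precision power-series oracle for E_{lam,nu}^{delta}(-x).

    Sizes its own working precision from the series peak; independent of the
    package's evaluation path (plain term-by-term summation).
    """
    import mpmath as mp
    from scipy.special import gammaln

    if x == 0:
        return float(mp.rgamma(nu))
    kk = np.arange(int(6.0 * x ** (1.0 / lam)) + 100, dtype=float)
    logt = (
        gammaln(delta + kk) - gammaln(delta) - gammaln(kk + 1.0)
        - gammaln(lam * kk + nu) + kk * np.log(x)
    )
    dps = int(max(0.0, np.max(logt) / np.log(10))
              + (delta + 3) * np.log10(max(x, 1.0))) + 50
    with mp.workdps(dps):
        xm, lam_m, nu_m, delta_m = (mp.mpf(v) for v in (x, lam, nu, delta))
        s = mp.mpf(0)
        term = mp.rgamma(nu_m)
        g_prev = mp.gamma(nu_m)
        for k in range(1, 200000):
            s += term
            g_cur = mp.gamma(lam_m * k + nu_m)
            term = term * (-xm) * (delta_m + k - 1) / k * (g_prev / g_cur)
            g_prev = g_cur
            if k > 10 and abs(term) < mp.mpf(10) ** (-dps + 5) * abs(s):
                break
        return float(s)


@pytest.fixture(scope="session")
def series_oracle():
    return ml3_series_oracle


def random_cm_parameters(rng: np.random.Generator, tau_range=(0.5, 2.0)):
    """Draw one parameter set from the complete-monotonicity region."""
    lam = rng.uniform(0.35, 1.0)
    delta = rng.uniform(0.3, min(1.0 / lam, 3.0))
    nu = rng.uniform(lam * delta, 1.0)
    tau = np.exp(rng.uniform(np.log(tau_range[0]), np.log(tau_range[1])))
    return MLParameters(lam=lam, nu=nu, delta=delta, tau=tau)
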