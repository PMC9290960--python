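import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from toxcea import (
    ProgramConfig,
    default_context,
    default_methodologies,
    default_program,
)


@pytest.fixture(scope="session")
def context():
    """Reference decision context: TRL 1e-6, three-action choice set."""
    return default_context()


@pytest.fixture(scope="session")
def methodologies():
    """The five reference testing methodologies (base case first)."""
    return default_methodologies()


@pytest.fixture(scope="session")
def program():
    """$10M/year, 3% discount, horizons 11-20."""
    return default_program()


@pytest.fixture(scope="session")
def single_horizon_program():
    return ProgramConfig(annual_budget=10.0, discount_rate=0.03, time_horizon=20)


def quadrature_risk(tox, exp):
    """Brute-force population risk by adaptive quadrature in log10 dose.

    Integrates the population dose-response CDF against the received-dose
    density, independently of the closed-form implementation.
    """

    def integrand(u):
        response = norm.cdf((u - tox.mu_tox) / tox.sigma_tox)
        density = norm.pdf(u, loc=exp.mu_exp, scale=exp.sigma_exp)
        return response * density

    lo = exp.mu_exp - 12.0 * exp.sigma_exp
    hi = exp.mu_exp + 12.0 * exp.sigma_exp
    value, _ = quad(integrand, lo, hi, epsabs=1e-12, epsrel=1e-12, limit=200)
    return value


def round_sig(x, n):
    """Round to n significant figures."""
    return float(np.format_float_positional(x, precision=n, fractional=False))
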