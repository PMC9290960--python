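"""Lognormal population-risk engine.

The population risk model assumes that both the individual threshold doses
(the smallest dose at or above which an individual experiences an adverse
effect) and the doses actually received by members of the exposed population
are lognormally distributed.  Working in log10 space, a chemical's toxicity
is summarised by ``(mu_tox, sigma_tox)`` — the log10 geometric mean and
log10 geometric standard deviation of the threshold-dose distribution — and
the exposure by ``(mu_exp, sigma_exp)`` for the received-dose distribution.

Under independence of individual thresholds and individual doses, the
fraction of the population experiencing an adverse effect has the closed
form

    R = Phi( (mu_exp - mu_tox) / sqrt(sigma_exp**2 + sigma_tox**2) )

where ``Phi`` is the standard-normal CDF.  The same expression inverts
analytically: given a target incidence, the potency ``mu_tox`` attaining it
under a fixed exposure is

    mu_tox = mu_exp - Phi^{-1}(R) * sqrt(sigma_exp**2 + sigma_tox**2)

All arithmetic in this package stays in log10 space; conversion to
mg/kg/day happens only at presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import ndtr, ndtri

__all__ = [
    "ToxicityProfile",
    "ExposureProfile",
    "population_risk",
    "mu_tox_at_risk",
]


@dataclass(frozen=True)
class ToxicityProfile:
    """Lognormal distribution of individual threshold doses.

    Parameters
    ----------
    mu_tox
        log10 of the geometric mean threshold dose (log10 mg/kg/day).
        Smaller values mean a more potent (more toxic) chemical.
    sigma_tox
        log10 of the geometric standard deviation (unitless, log10 units);
        must be strictly positive.
    """

    mu_tox: float
    sigma_tox: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu_tox):
            raise ValueError(f"mu_tox must be finite, got {self.mu_tox}")
        if not self.sigma_tox > 0:
            raise ValueError(f"sigma_tox must be > 0, got {self.sigma_tox}")


@dataclass(frozen=True)
class ExposureProfile:
    """Lognormal distribution of doses received by the exposed population.

    Parameters
    ----------
    mu_exp
        log10 of the geometric mean received dose (log10 mg/kg/day).
    sigma_exp
        log10 of the geometric standard deviation (unitless); must be
        strictly positive.
    """

    mu_exp: float
    sigma_exp: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu_exp):
            raise ValueError(f"mu_exp must be finite, got {self.mu_exp}")
        if not self.sigma_exp > 0:
            raise ValueError(f"sigma_exp must be > 0, got {self.sigma_exp}")


def population_risk(tox: ToxicityProfile, exp: ExposureProfile) -> float:
    """Fraction of the population experiencing an adverse effect.

    Evaluates the closed-form lognormal convolution
    ``Phi((mu_exp - mu_tox) / sqrt(sigma_exp^2 + sigma_tox^2))``.

    Returns a risk in [0, 1]; strictly decreasing in ``tox.mu_tox`` and
    strictly increasing in ``exp.mu_exp``.
    """
    z = (exp.mu_exp - tox.mu_tox) / math.hypot(exp.sigma_exp, tox.sigma_tox)
    return float(ndtr(z))


def mu_tox_at_risk(
    target_risk: float, exp: ExposureProfile, sigma_tox: float
) -> float:
    """Potency (log10 GM of threshold doses) at which the population risk
    under ``exp`` equals ``target_risk``.

    This is the analytic inverse of :func:`population_risk` in ``mu_tox``:
    ``mu_exp - Phi^{-1}(target_risk) * sqrt(sigma_exp^2 + sigma_tox^2)``.

    Parameters
    ----------
    target_risk
        Population incidence to attain; must lie strictly in (0, 1).
    exp
        Exposure profile held fixed during the inversion.
    sigma_tox
        log10 GSD of the toxicity distribution (must be > 0).

    Returns
    -------
    float
        ``mu_tox`` in log10 mg/kg/day such that
        ``population_risk(ToxicityProfile(mu_tox, sigma_tox), exp)``
        equals ``target_risk``.
    """
    if not 0.0 < target_risk < 1.0:
        raise ValueError(
            f"target_risk must be in the open interval (0, 1), got {target_risk}"
        )
    if not sigma_tox > 0:
        raise ValueError(f"sigma_tox must be > 0, got {sigma_tox}")
    spread = math.hypot(exp.sigma_exp, sigma_tox)
    return exp.mu_exp - float(ndtri(target_risk)) * spread
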