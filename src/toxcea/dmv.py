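"""Decision-making value: probability of a correct regulatory decision.

A testing methodology does not reveal a chemical's true potency
``mu_tox``; it yields a noisy estimate, modelled here as

    mu_hat ~ Normal(mu_tox + bias, sigma_mu_hat)      (log10 units)

The decision-making value (DMV) of a methodology, conditional on a
decision rule, is the probability that the decision made from ``mu_hat``
coincides with the decision that perfect knowledge of ``mu_tox`` would
produce.  Because both rules partition the potency axis into intervals
(see :mod:`toxcea.decision_framework`), the DMV is the normal probability
mass that the estimate assigns to the truth's own interval — a difference
of normal CDFs at the interval's endpoints.

For the simple rule the interval is one side of ``trl_mu_tox``; for the
complex rule it is the truth's decision region.  A perfectly certain
methodology (``sigma_mu_hat = 0``, zero bias) always has DMV 1, including
the degenerate case of a potency exactly on a threshold, where the point
estimate equals the truth and the shared tie-break puts both in the same
region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .decision_framework import DecisionContext, classify_potency

__all__ = ["TestingMethodology", "dmv_simple", "dmv_complex"]


@dataclass(frozen=True)
class TestingMethodology:
    """Cost, duration, and measurement uncertainty of a toxicity test.

    Parameters
    ----------
    name
        Label used in reports.
    duration_years
        Whole years needed to complete testing of one chemical (>= 1).
    cost_per_chemical
        Total testing cost for one chemical, millions of dollars.
    sigma_mu_hat
        Standard deviation of the potency-estimate error in log10 units;
        0 means a perfectly certain methodology.
    bias
        Mean of (estimate - truth) in log10 units; 0 for an unbiased test.
    """

    name: str
    duration_years: int
    cost_per_chemical: float
    sigma_mu_hat: float
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_years < 1:
            raise ValueError(f"duration_years must be >= 1, got {self.duration_years}")
        if not self.cost_per_chemical > 0:
            raise ValueError(
                f"cost_per_chemical must be > 0, got {self.cost_per_chemical}"
            )
        if self.sigma_mu_hat < 0:
            raise ValueError(f"sigma_mu_hat must be >= 0, got {self.sigma_mu_hat}")


def _interval_probability(
    mu_tox: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    method: TestingMethodology,
) -> np.ndarray:
    """P(estimate in [lo, hi)) for estimate ~ N(mu_tox + bias, sigma)."""
    center = mu_tox + method.bias
    sigma = method.sigma_mu_hat
    if sigma == 0.0:
        # Point estimate: indicator of the (half-open) interval.
        return ((center >= lo) & (center < hi)).astype(float)
    upper = ndtr((hi - center) / sigma)
    lower = ndtr((lo - center) / sigma)
    return upper - lower


def dmv_simple(mu_tox, method: TestingMethodology, context: DecisionContext):
    """DMV under the simple decision rule.

    Probability that the potency estimate falls on the same side of
    ``context.trl_mu_tox`` as the true potency.  Accepts a scalar or
    array of true potencies; returns the matching shape.

    For an unbiased methodology this is ``Phi(|mu_tox - trl_mu_tox| /
    sigma_mu_hat)``; a truth exactly on the threshold gives 0.5 for any
    positive uncertainty, and a zero-uncertainty methodology gives 1.
    """
    mu = np.asarray(mu_tox, dtype=float)
    t = context.trl_mu_tox
    sigma = method.sigma_mu_hat
    if sigma == 0.0:
        est = mu + method.bias
        # same side: "act" iff potency below threshold (risk above TRL)
        out = ((est < t) == (mu < t)).astype(float)
        return out if out.ndim else float(out)

    center = mu + method.bias
    # truth below threshold -> correct iff estimate < t; else estimate >= t
    p_below = ndtr((t - center) / sigma)
    out = np.where(mu < t, p_below, 1.0 - p_below)
    return out if out.ndim else float(out)


def dmv_complex(mu_tox, method: TestingMethodology, context: DecisionContext):
    """DMV under the complex decision rule.

    Probability that the potency estimate lands in the true potency's own
    decision region — no action, one of the K actions, or (below the last
    decision point) the region where no action suffices.  Region
    probabilities are differences of normal CDFs at consecutive
    thresholds.  Accepts a scalar or array of true potencies.
    """
    mu = np.asarray(mu_tox, dtype=float)
    # thresholds ascending: [dp_K, ..., dp_1, trl_mu_tox]
    asc = np.asarray(context.thresholds_descending[::-1])
    idx = np.searchsorted(asc, mu, side="right")
    lo = np.where(idx == 0, -np.inf, asc[np.clip(idx - 1, 0, len(asc) - 1)])
    hi = np.where(idx == len(asc), np.inf, asc[np.clip(idx, 0, len(asc) - 1)])
    if method.sigma_mu_hat == 0.0:
        est = mu + method.bias
        same = classify_potency(est, context) == classify_potency(mu, context)
        out = same.astype(float)
    else:
        out = _interval_probability(mu, lo, hi, method)
    return out if out.ndim else float(out)
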