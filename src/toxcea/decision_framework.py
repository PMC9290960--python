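"""Risk-based regulatory decision rules and their potency-space geometry.

Two decision rules are modelled.  The *simple decision rule* (SDR) asks a
single question: is the uncontrolled population risk above the target risk
level (TRL)?  The *complex decision rule* (CDR) goes further: when the
uncontrolled risk exceeds the TRL, the decisionmaker picks the cheapest
regulatory action from an ordered choice set that brings the risk to or
below the TRL.

Because risk is monotone in potency at fixed exposure, both rules partition
the potency axis into decision regions.  The boundary for "no action" is
the potency ``trl_mu_tox`` at which the uncontrolled risk equals the TRL;
the boundary at which action ``k`` stops being sufficient is the *decision
point* ``dp_mu_tox[k]`` — the potency at which action k's post-control risk
equals the TRL.  With increasingly stringent actions these thresholds
decrease, and action ``k`` is correct exactly on the half-open interval
``[dp_mu_tox[k], dp_mu_tox[k-1])`` (closed at the more-toxic end), with
``dp_mu_tox[0]`` read as ``trl_mu_tox``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .risk_model import ExposureProfile, ToxicityProfile, mu_tox_at_risk, population_risk

__all__ = [
    "RegulatoryAction",
    "DecisionContext",
    "Decision",
    "NoCompliantActionError",
    "NO_COMPLIANT_ACTION",
    "build_context",
    "simple_decision",
    "complex_decision",
]

#: Sentinel region label for potencies so extreme that even the most
#: stringent action cannot reach the TRL.
NO_COMPLIANT_ACTION: int = -1


class NoCompliantActionError(ValueError):
    """Raised when no regulatory action can bring the risk to the TRL."""


@dataclass(frozen=True)
class RegulatoryAction:
    """A regulatory action with its post-control exposure and cost rank.

    Only the *rank* of the action costs matters to the complex rule
    (1 = cheapest); actual monetary costs are never used.
    """

    id: int
    exposure: ExposureProfile
    cost_rank: int

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValueError(f"action id must be >= 1, got {self.id}")
        if self.cost_rank < 1:
            raise ValueError(f"cost_rank must be >= 1, got {self.cost_rank}")


@dataclass(frozen=True)
class Decision:
    """Outcome of a decision rule: 0 for no action, else an action id."""

    choice: int


@dataclass(frozen=True)
class DecisionContext:
    """Target risk level, choice set, and the derived potency thresholds.

    Attributes
    ----------
    trl
        Target risk level (population incidence fraction).
    baseline_exposure
        Exposure profile with no regulatory control.
    actions
        Choice set, ordered by increasing stringency.
    sigma_tox
        log10 GSD of the toxicity distribution, shared by all chemicals.
    trl_mu_tox
        Potency at which the uncontrolled risk equals the TRL.
    dp_mu_tox
        Per-action decision points in potency space, one per action,
        strictly decreasing.
    dp_risk
        Uncontrolled (no-action) risk evaluated at each decision point —
        the risk level at which the selected action changes.
    """

    trl: float
    baseline_exposure: ExposureProfile
    actions: tuple[RegulatoryAction, ...]
    sigma_tox: float
    trl_mu_tox: float = field(repr=False)
    dp_mu_tox: tuple[float, ...] = field(repr=False)
    dp_risk: tuple[float, ...] = field(repr=False)

    @property
    def n_actions(self) -> int:
        return len(self.actions)

    @property
    def thresholds_descending(self) -> tuple[float, ...]:
        """(trl_mu_tox, dp_mu_tox[1], ..., dp_mu_tox[K]) in decreasing order."""
        return (self.trl_mu_tox, *self.dp_mu_tox)

    def classify(self, mu_tox: float) -> int:
        """Correct decision region for a true potency.

        Returns 0 (no action) for ``mu_tox >= trl_mu_tox``, the action id
        whose half-open potency interval contains ``mu_tox`` otherwise, or
        :data:`NO_COMPLIANT_ACTION` below the last decision point.
        """
        return int(classify_potency(np.asarray(mu_tox), self))

    def region_bounds(self, choice: int) -> tuple[float, float]:
        """Potency interval ``[lo, hi)`` on which ``choice`` is correct."""
        thr = self.thresholds_descending
        if choice == 0:
            return thr[0], np.inf
        if choice == NO_COMPLIANT_ACTION:
            return -np.inf, thr[-1]
        if not 1 <= choice <= self.n_actions:
            raise ValueError(f"unknown choice {choice}")
        # choice k is correct on [dp_k, dp_{k-1}); thr is 0-indexed descending
        return thr[choice], thr[choice - 1]


def classify_potency(mu_tox: np.ndarray, context: DecisionContext) -> np.ndarray:
    """Vectorised region lookup: 0, action id, or NO_COMPLIANT_ACTION."""
    asc = np.asarray(context.thresholds_descending[::-1])  # ascending
    idx = np.searchsorted(asc, mu_tox, side="right")  # count of thresholds <= mu
    n = len(asc)  # = K + 1
    choice = np.where(idx == 0, NO_COMPLIANT_ACTION, n - idx)
    return choice


def build_context(
    trl: float,
    baseline_exposure: ExposureProfile,
    actions: Sequence[RegulatoryAction],
    sigma_tox: float,
) -> DecisionContext:
    """Derive the potency-space decision geometry for a choice set.

    Each action's decision point is computed by inverting the risk model
    through that action's post-control exposure profile: ``dp_mu_tox[k]``
    is the potency at which action k's risk exactly equals the TRL, and
    ``dp_risk[k]`` is the uncontrolled risk at that potency.

    Raises
    ------
    ValueError
        If the TRL is outside (0, 1), cost ranks collide, or the derived
        thresholds are not strictly decreasing (ambiguous regions).
    """
    if not 0.0 < trl < 1.0:
        raise ValueError(f"trl must be in (0, 1), got {trl}")
    actions = tuple(actions)
    ranks = [a.cost_rank for a in actions]
    if len(set(ranks)) != len(ranks):
        raise ValueError(f"cost ranks must be unique within a choice set: {ranks}")

    trl_mu = mu_tox_at_risk(trl, baseline_exposure, sigma_tox)
    dp_mu = tuple(mu_tox_at_risk(trl, a.exposure, sigma_tox) for a in actions)

    # decision points must fall strictly with stringency; an action that
    # does not improve on no action may share the TRL threshold (its
    # decision region is then empty)
    if any(hi <= lo for hi, lo in zip(dp_mu, dp_mu[1:])) or (
        dp_mu and dp_mu[0] > trl_mu
    ):
        raise ValueError(
            "decision-point potencies must be strictly decreasing with "
            f"stringency; got trl_mu_tox={trl_mu:.4f}, dp_mu_tox={dp_mu}"
        )

    dp_risk = tuple(
        population_risk(ToxicityProfile(mu, sigma_tox), baseline_exposure)
        for mu in dp_mu
    )
    return DecisionContext(
        trl=trl,
        baseline_exposure=baseline_exposure,
        actions=actions,
        sigma_tox=sigma_tox,
        trl_mu_tox=trl_mu,
        dp_mu_tox=dp_mu,
        dp_risk=dp_risk,
    )


def simple_decision(risk_estimate: float, trl: float) -> Decision:
    """Simple decision rule: act (1) iff the risk strictly exceeds the TRL.

    A risk exactly equal to the TRL is acceptable and returns 0.
    """
    if not 0.0 <= risk_estimate <= 1.0:
        raise ValueError(f"risk_estimate must be in [0, 1], got {risk_estimate}")
    return Decision(1 if risk_estimate > trl else 0)


def complex_decision(
    risk_estimates: Sequence[float], context: DecisionContext
) -> Decision:
    """Complex decision rule: cheapest action bringing risk to the TRL.

    Parameters
    ----------
    risk_estimates
        ``K + 1`` risk values derived from one toxicity estimate: the
        no-action risk first, then the post-control risk under each action
        in ``context.actions`` order.

    Returns
    -------
    Decision
        0 if the no-action risk is already at or below the TRL, otherwise
        the id of the lowest-cost action whose post-control risk is at or
        below the TRL.

    Raises
    ------
    NoCompliantActionError
        If the risk exceeds the TRL and no action can reach it.
    """
    if len(risk_estimates) != context.n_actions + 1:
        raise ValueError(
            f"expected {context.n_actions + 1} risk estimates "
            f"(no-action + {context.n_actions} actions), got {len(risk_estimates)}"
        )
    r0, *rk = risk_estimates
    if r0 <= context.trl:
        return Decision(0)
    compliant = [
        a for a, r in zip(context.actions, rk) if r <= context.trl
    ]
    if not compliant:
        raise NoCompliantActionError(
            f"no action reduces risk {r0:.3g} to TRL {context.trl:.3g}"
        )
    cheapest = min(compliant, key=lambda a: a.cost_rank)
    return Decision(cheapest.id)
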