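"""Discounted cost-effectiveness ratios for toxicity-testing programs.

The cost-effectiveness ratio (CER) of a testing methodology divides the
net present cost of testing by the net present outcome, where the outcome
is the number of discounted years in which the test results support a
correct regulatory decision, each year weighted by the decision-making
value (DMV).  Lower CER is better.

Two accounting levels are provided:

* :func:`single_chemical_cer` — one chemical, one test: the full testing
  cost is charged in year 1 and the DMV accrues in each year after the
  test completes, through the time horizon.  Both sides are discounted at
  ``(1 + r)^-(y - 1)`` (year 1 undiscounted).

* :func:`program_cer` — an annually funded program: a new cohort of
  ``floor(annual_budget / cost_per_chemical)`` chemicals starts testing
  every year from 1 through the time horizon, each cohort's full cost is
  charged (discounted) at its start year, and a chemical started in year
  ``s`` contributes its DMV in every year from ``s + duration`` through
  the horizon.  Cohorts that start too late to finish within the horizon
  still incur their cost; this is what makes shorter-duration tests so
  much more cost-effective at short horizons.  The reported CER is the
  program's discounted cost per discounted correct-decision-year for each
  chemical.

Because the cohort size and the DMV enter the two sides symmetrically,
the per-chemical program CER factorises as ``unit_cer / dmv`` where
``unit_cer`` depends only on cost, duration, discount rate and horizon.
This makes the cost- and DMV-scaling properties exact: a fivefold cheaper
test gives exactly a fivefold lower CER under a fixed budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dmv import TestingMethodology

__all__ = [
    "ProgramConfig",
    "CEResult",
    "discount_factor",
    "single_chemical_cer",
    "program_unit_cer",
    "program_cer",
    "horizon_averaged_cer",
]


@dataclass(frozen=True)
class ProgramConfig:
    """Funding and discounting assumptions for a testing program.

    Parameters
    ----------
    annual_budget
        Constant annual testing budget, millions of dollars per year.
    discount_rate
        Annual discount rate as a fraction (0.03 = 3 %/year).
    time_horizon
        Either a single integer horizon (years) or an inclusive
        ``(first, last)`` range of integer horizons to average over.
    """

    annual_budget: float
    discount_rate: float
    time_horizon: int | tuple[int, int]

    def __post_init__(self) -> None:
        if not self.annual_budget > 0:
            raise ValueError(f"annual_budget must be > 0, got {self.annual_budget}")
        if self.discount_rate < 0:
            raise ValueError(f"discount_rate must be >= 0, got {self.discount_rate}")
        for h in self.horizons:
            if h < 1:
                raise ValueError(f"time horizon years must be >= 1, got {h}")

    @property
    def horizons(self) -> tuple[int, ...]:
        """All integer horizons covered by ``time_horizon``."""
        if isinstance(self.time_horizon, int):
            return (self.time_horizon,)
        first, last = self.time_horizon
        if last < first:
            raise ValueError(f"empty horizon range {self.time_horizon}")
        return tuple(range(first, last + 1))

    @property
    def single_horizon(self) -> int:
        horizons = self.horizons
        if len(horizons) != 1:
            raise ValueError(
                f"a single time horizon is required here, got range {self.time_horizon}"
            )
        return horizons[0]


@dataclass
class CEResult:
    """Per-chemical CERs with population aggregates.

    ``cer`` is in millions of dollars per discounted correct-decision-year
    (lower is better); ``mean_cer`` and ``max_cer`` aggregate over the
    chemical population.
    """

    method: str
    horizons: tuple[int, ...]
    mu_tox: np.ndarray
    dmv: np.ndarray
    cer: np.ndarray
    unit_cer: float
    mean_cer: float = field(init=False)
    max_cer: float = field(init=False)

    def __post_init__(self) -> None:
        self.mu_tox = np.asarray(self.mu_tox, dtype=float)
        self.dmv = np.asarray(self.dmv, dtype=float)
        self.cer = np.asarray(self.cer, dtype=float)
        self.mean_cer = float(np.mean(self.cer))
        self.max_cer = float(np.max(self.cer))


def discount_factor(year: int, rate: float) -> float:
    """Present-value multiplier ``(1 + rate)^-(year - 1)``.

    Year 1 is undiscounted; ``year`` must be >= 1.
    """
    if year < 1:
        raise ValueError(f"year must be >= 1, got {year}")
    return float((1.0 + rate) ** -(year - 1))


def _discounted_years(first: int, last: int, rate: float) -> float:
    """Sum of discount factors over the inclusive year range [first, last]."""
    if last < first:
        return 0.0
    years = np.arange(first, last + 1)
    return float(np.sum((1.0 + rate) ** -(years - 1)))


def single_chemical_cer(
    method: TestingMethodology, dmv: float, config: ProgramConfig
) -> float:
    """CER for testing one chemical with one methodology.

    The full testing cost is charged in year 1 (undiscounted); the
    outcome is ``dmv`` accrued in each year from ``duration + 1`` through
    the horizon, discounted at the program rate.

    Raises
    ------
    ValueError
        If the horizon does not extend past the test duration (no benefit
        years within the horizon).
    """
    horizon = config.single_horizon
    if horizon <= method.duration_years:
        raise ValueError(
            f"no benefit years within horizon: horizon {horizon} <= "
            f"duration {method.duration_years}"
        )
    outcome = dmv * _discounted_years(
        method.duration_years + 1, horizon, config.discount_rate
    )
    return method.cost_per_chemical / outcome


def program_unit_cer(
    method: TestingMethodology, config: ProgramConfig, horizon: int | None = None
) -> float:
    """Program CER per chemical at DMV = 1.

    Cohorts start every year ``s = 1 .. TH`` and are fully funded at
    launch; a chemical started in year ``s`` yields one discounted
    outcome-year for each year in ``[s + duration, TH]``.  The cohort
    size cancels between the cost and outcome totals, leaving

        unit_cer = cost * sum_s d(s) / sum_s sum_{y=s+dur}^{TH} d(y)

    with ``d(y) = (1 + r)^-(y - 1)``.  Divide by a chemical's DMV to get
    its program CER.
    """
    th = config.single_horizon if horizon is None else horizon
    if th <= method.duration_years:
        raise ValueError(
            f"no benefit years within horizon: horizon {th} <= "
            f"duration {method.duration_years}"
        )
    if int(config.annual_budget // method.cost_per_chemical) < 1:
        raise ValueError(
            f"annual budget {config.annual_budget} cannot fund a single "
            f"chemical at cost {method.cost_per_chemical}"
        )
    r = config.discount_rate
    cost = method.cost_per_chemical * _discounted_years(1, th, r)
    outcome = sum(
        _discounted_years(s + method.duration_years, th, r) for s in range(1, th + 1)
    )
    return cost / outcome


def _as_arrays(
    chemicals: Sequence[tuple[float, float]] | Iterable[tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(chemicals), dtype=float)
    if arr.size == 0:
        raise ValueError("chemicals must be non-empty")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("chemicals must be (mu_tox, dmv) pairs")
    return arr[:, 0], arr[:, 1]


def program_cer(
    method: TestingMethodology,
    chemicals: Sequence[tuple[float, float]],
    config: ProgramConfig,
    horizon: int | None = None,
) -> CEResult:
    """Per-chemical program CERs at a single time horizon.

    Parameters
    ----------
    method
        Testing methodology (cost, duration).
    chemicals
        ``(mu_tox, dmv)`` pairs; each chemical's CER is the program unit
        CER divided by its DMV.
    config
        Program funding assumptions; ``horizon`` overrides the config's
        single horizon when given.
    """
    mu, dmv = _as_arrays(chemicals)
    th = config.single_horizon if horizon is None else horizon
    unit = program_unit_cer(method, config, th)
    return CEResult(
        method=method.name,
        horizons=(th,),
        mu_tox=mu,
        dmv=dmv,
        cer=unit / dmv,
        unit_cer=unit,
    )


def horizon_averaged_cer(
    method: TestingMethodology,
    chemicals: Sequence[tuple[float, float]],
    config: ProgramConfig,
) -> CEResult:
    """Per-chemical program CERs averaged over the config's horizon range.

    The arithmetic mean of the per-horizon program CERs is taken for each
    chemical.  Every horizon in the range must exceed the methodology's
    duration.
    """
    mu, dmv = _as_arrays(chemicals)
    units = [program_unit_cer(method, config, th) for th in config.horizons]
    unit = float(np.mean(units))
    return CEResult(
        method=method.name,
        horizons=config.horizons,
        mu_tox=mu,
        dmv=dmv,
        cer=unit / dmv,
        unit_cer=unit,
    )
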