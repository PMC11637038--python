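"""Exact M/M/c and approximate G/G/c waiting-time machinery.

The unit of analysis is a *care event*: a stochastic demand for direct
nursing care issued by one patient.  With Poisson event arrivals at unit
rate ``lambda`` (events per minute), exponentially distributed care
durations with mean ``1/mu`` (minutes) and ``c`` pooled nurses serving
first-come-first-served, the ward is an M/M/c queue.  The quality measure
is TUCA — the expected *time until care arrives*, i.e. the steady-state
expected queueing delay of a care event before a nurse starts serving it:

    TUCA(c, lambda, mu) = C(c, lambda/mu) / (c*mu - lambda)

where ``C`` is Erlang's C formula (the probability an arriving event finds
all ``c`` nurses busy).  For shifts where the Markov assumptions are
doubtful, a Kingman-style G/G/c approximation parameterised by the
coefficients of variation of inter-arrival and service times is provided.

All rates are per minute and all times are minutes; unit conversions are a
reporting concern.

Numerical notes
---------------
Erlang C is evaluated through the Erlang-B recurrence

    B(0, a) = 1,    B(k, a) = a*B(k-1, a) / (k + a*B(k-1, a))

    C(c, a) = B(c, a) / (1 - rho * (1 - B(c, a))),    rho = a / c

which is stable for any server count (no factorials or large powers),
rather than by summing the textbook expression directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "QueueLoad",
    "VariabilityParams",
    "StabilityError",
    "erlang_b",
    "erlang_c",
    "tuca",
    "tuca_kingman",
    "delta_tuca",
]


class StabilityError(ValueError):
    """Raised when a queueing quantity is requested for an overloaded system."""


@dataclass(frozen=True)
class QueueLoad:
    """Unit-level offered work: arrival rate (events/min) and mean care duration (min).

    ``mean_service`` must be positive except in the empty-unit sentinel case
    ``arrival_rate == 0``, where a zero duration is tolerated because no
    event ever waits.
    """

    arrival_rate: float
    mean_service: float

    def __post_init__(self) -> None:
        if not (self.arrival_rate >= 0.0):
            raise ValueError(f"arrival_rate must be >= 0, got {self.arrival_rate}")
        if self.arrival_rate > 0.0 and not (self.mean_service > 0.0):
            raise ValueError(f"mean_service must be > 0, got {self.mean_service}")
        if self.mean_service < 0.0:
            raise ValueError(f"mean_service must be >= 0, got {self.mean_service}")

    @property
    def offered_load(self) -> float:
        """Offered load a = lambda / mu in units of busy nurses (erlangs)."""
        return self.arrival_rate * self.mean_service

    def utilization(self, c: int) -> float:
        """Traffic intensity rho = lambda / (c * mu); stable iff rho < 1."""
        _check_servers(c)
        return self.offered_load / c


@dataclass(frozen=True)
class VariabilityParams:
    """Coefficients of variation of inter-arrival and service times (G/G/c)."""

    cv_arrival: float = 1.0
    cv_service: float = 1.0

    def __post_init__(self) -> None:
        if self.cv_arrival < 0.0 or self.cv_service < 0.0:
            raise ValueError("coefficients of variation must be >= 0")


def _check_servers(c: int) -> None:
    if int(c) != c or c < 1:
        raise ValueError(f"server count must be an integer >= 1, got {c!r}")


def erlang_b(c: int, offered_load: float) -> float:
    """Erlang-B blocking probability via the standard stable recurrence."""
    _check_servers(c)
    if offered_load < 0.0:
        raise ValueError("offered load must be >= 0")
    b = 1.0
    for k in range(1, int(c) + 1):
        b = offered_load * b / (k + offered_load * b)
    return b


def erlang_c(c: int, load: QueueLoad) -> float:
    """Probability that an arriving care event finds all ``c`` nurses busy.

    Requires a stable system (rho < 1).  Strictly decreasing in ``c`` at
    fixed positive load; returns 0 when there are no arrivals.
    """
    _check_servers(c)
    if load.arrival_rate == 0.0:
        return 0.0
    rho = load.utilization(c)
    if rho >= 1.0:
        raise StabilityError(
            f"system unstable: rho = {rho:.4g} >= 1 with c = {c}"
        )
    b = erlang_b(c, load.offered_load)
    return b / (1.0 - rho * (1.0 - b))


def tuca(c: int, load: QueueLoad, *, unstable: str = "inf") -> float:
    """Expected time until care arrives (minutes) in the M/M/c model.

    Parameters
    ----------
    c : nurses on duty.
    load : unit-level arrival rate and mean care duration.
    unstable : ``"inf"`` (default) returns ``math.inf`` for rho >= 1 so that
        policy search naturally avoids overloaded configurations;
        ``"raise"`` raises :class:`StabilityError` instead.
    """
    _check_servers(c)
    if unstable not in ("inf", "raise"):
        raise ValueError("unstable must be 'inf' or 'raise'")
    if load.arrival_rate == 0.0:
        return 0.0
    rho = load.utilization(c)
    if rho >= 1.0:
        if unstable == "inf":
            return math.inf
        raise StabilityError(f"system unstable: rho = {rho:.4g} >= 1 with c = {c}")
    mu = 1.0 / load.mean_service
    return erlang_c(c, load) / (c * mu - load.arrival_rate)


def tuca_kingman(
    c: int,
    load: QueueLoad,
    var: VariabilityParams = VariabilityParams(),
    *,
    unstable: str = "inf",
) -> float:
    """Kingman-style G/G/c approximation of the expected wait (minutes).

        E[W] = (cv_a^2 + cv_s^2)/2 * rho^(sqrt(2(c+1)) - 1) / (c (1 - rho)) * 1/mu

    With ``cv_a = cv_s = 1`` and ``c = 1`` the exponent is 1 and the
    expression collapses to the exact M/M/1 queueing delay.  Deterministic
    flows (both cv = 0) never wait under this approximation.
    """
    _check_servers(c)
    if unstable not in ("inf", "raise"):
        raise ValueError("unstable must be 'inf' or 'raise'")
    if load.arrival_rate == 0.0:
        return 0.0
    rho = load.utilization(c)
    if rho >= 1.0:
        if unstable == "inf":
            return math.inf
        raise StabilityError(f"system unstable: rho = {rho:.4g} >= 1 with c = {c}")
    variability = 0.5 * (var.cv_arrival**2 + var.cv_service**2)
    exponent = math.sqrt(2.0 * (c + 1)) - 1.0
    return variability * rho**exponent / (c * (1.0 - rho)) * load.mean_service


def delta_tuca(
    c: int,
    load: QueueLoad,
    *,
    model: str = "mmc",
    var: VariabilityParams | None = None,
) -> float:
    """Marginal value of one additional nurse: TUCA(c) - TUCA(c+1) >= 0.

    When the system is unstable at ``c`` but stable at ``c+1`` the marginal
    nurse is infinitely valuable and ``inf`` is returned, which preserves
    greedy-allocation semantics at the stability boundary.  If even ``c+1``
    nurses cannot stabilise the load a :class:`StabilityError` is raised.

    ``model`` selects the waiting-time model: ``"mmc"`` (exact Erlang) or
    ``"kingman"`` with variability ``var``.
    """
    _check_servers(c)
    if model == "mmc":
        wait = lambda n: tuca(n, load, unstable="inf")  # noqa: E731
    elif model == "kingman":
        v = var if var is not None else VariabilityParams()
        wait = lambda n: tuca_kingman(n, load, v, unstable="inf")  # noqa: E731
    else:
        raise ValueError(f"unknown model {model!r}")
    w_next = wait(c + 1)
    if math.isinf(w_next):
        raise StabilityError(
            f"system still unstable with c+1 = {c + 1} nurses"
        )
    w_now = wait(c)
    if math.isinf(w_now):
        return math.inf
    return max(w_now - w_next, 0.0)
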