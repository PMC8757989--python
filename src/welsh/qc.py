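"""Completion-error detection and two-round completion flow accounting.

A completion error on a WELSH sheet is a double or missing answer on any of
the four items, or a *paradoxical* answer on the timed items: a declared
walking duration that is strictly longer at a faster pace than at a slower
pace.  Ties across paces are legal.  Paradox is checked on all three ordered
pace pairs (human vs turtle, rabbit vs human, rabbit vs turtle), since the
inconsistency is defined for any faster/slower pair.

Sheets move through a two-round flow: self-completion after a first oral
explanation (possibly with interviewer-corrected errors), a second round of
explanation for those unable to self-complete, and a residual "unable"
state.  :func:`completion_flow_summary` tallies that flow and
:func:`error_rates_by_stratum` produces the per-education error-rate table
with Wilson 95% confidence intervals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .scoring import DOUBLE, MISSING, Pace, RawResponse, Sentinel
from .stats import wilson_ci


class Item(enum.Enum):
    TURTLE = "turtle"
    HUMAN = "human"
    RABBIT = "rabbit"
    PACE = "pace"

    def __repr__(self) -> str:
        return self.name


class ErrorKind(enum.Enum):
    MISSING = "missing"
    DOUBLE = "double"
    PARADOXICAL = "paradoxical"

    def __repr__(self) -> str:
        return self.name


@dataclass(frozen=True)
class ErrorFlag:
    """One detected completion error.

    For paradoxical flags, ``item`` is the faster of the two paces involved
    and ``versus`` the slower one; otherwise ``versus`` is None.
    """

    item: Item
    kind: ErrorKind
    versus: Optional[Item] = None

    def __post_init__(self) -> None:
        if self.kind is ErrorKind.PARADOXICAL and self.item is Item.PACE:
            raise ValueError("paradoxical errors apply only to the timed items")
        if self.kind is not ErrorKind.PARADOXICAL and self.versus is not None:
            raise ValueError("versus is only meaningful for paradoxical flags")


class Status(enum.Enum):
    CLEAN = "clean"
    CORRECTED = "corrected"
    UNABLE = "unable"

    def __repr__(self) -> str:
        return self.name


@dataclass(frozen=True)
class CompletionOutcome:
    """How one sheet resolved: which explanation round, how many corrections."""

    round: int
    n_errors_corrected: int
    status: Status

    def __post_init__(self) -> None:
        if self.round not in (1, 2):
            raise ValueError("round must be 1 or 2")
        if self.status is Status.CLEAN and self.n_errors_corrected != 0:
            raise ValueError("a clean sheet has no corrected errors")
        if self.status is Status.CORRECTED and self.n_errors_corrected < 1:
            raise ValueError("a corrected sheet has at least one corrected error")


@dataclass(frozen=True)
class ErrorRateRow:
    """Errored-sheet proportion for one education stratum, with Wilson 95% CI."""

    stratum: str
    k: int
    n: int
    rate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]

    @property
    def percent(self) -> Optional[float]:
        """Display percentage, rounded half-up to one decimal."""
        return None if self.rate is None else round_half_up(100 * self.rate, 1)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as in the reporting convention."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_half_up(k: int, n: int, ndigits: int = 1) -> float:
    """``100*k/n`` rounded half-up, computed in exact decimal arithmetic."""
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(k) * 100 / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))


# ordered faster/slower pace pairs: (faster item, slower item)
_PARADOX_PAIRS = (
    (Item.HUMAN, Item.TURTLE),
    (Item.RABBIT, Item.HUMAN),
    (Item.RABBIT, Item.TURTLE),
)

_TIMED_ATTRS = {Item.TURTLE: "t_turtle", Item.HUMAN: "t_human", Item.RABBIT: "t_rabbit"}


def detect_errors(resp: RawResponse) -> list[ErrorFlag]:
    """All completion errors on a raw sheet, in stable order.

    Missing/double flags come first in item order (turtle, human, rabbit,
    pace), then paradoxical flags in pair order (human>turtle,
    rabbit>human, rabbit>turtle).  Equal durations across paces are legal.
    """
    flags: list[ErrorFlag] = []
    values = {item: getattr(resp, attr) for item, attr in _TIMED_ATTRS.items()}
    for item in (Item.TURTLE, Item.HUMAN, Item.RABBIT):
        v = values[item]
        if v is MISSING:
            flags.append(ErrorFlag(item, ErrorKind.MISSING))
        elif v is DOUBLE:
            flags.append(ErrorFlag(item, ErrorKind.DOUBLE))
    if resp.pace is MISSING:
        flags.append(ErrorFlag(Item.PACE, ErrorKind.MISSING))
    elif resp.pace is DOUBLE:
        flags.append(ErrorFlag(Item.PACE, ErrorKind.DOUBLE))
    for faster, slower in _PARADOX_PAIRS:
        tf, ts = values[faster], values[slower]
        if isinstance(tf, Sentinel) or isinstance(ts, Sentinel):
            continue
        if tf > ts:
            flags.append(ErrorFlag(faster, ErrorKind.PARADOXICAL, versus=slower))
    return flags


def error_rates_by_stratum(
    groups: Iterable[tuple[str, Sequence[CompletionOutcome]]],
    level: float = 0.95,
) -> list[ErrorRateRow]:
    """Per-stratum errored-sheet rates with Wilson CIs.

    ``groups`` yields ``(stratum label, outcomes)`` pairs; a sheet counts as
    errored when its outcome carries at least one corrected error or ended
    unable.  An empty stratum yields a row with ``n=0`` and undefined rate
    rather than being dropped.
    """
    rows: list[ErrorRateRow] = []
    for stratum, outcomes in groups:
        n = len(outcomes)
        k = sum(
            1
            for o in outcomes
            if o.n_errors_corrected > 0 or o.status is Status.UNABLE
        )
        if n == 0:
            rows.append(ErrorRateRow(stratum, 0, 0, None, None, None))
            continue
        ci = wilson_ci(k, n, level)
        rows.append(ErrorRateRow(stratum, k, n, k / n, ci.low, ci.high))
    return rows


@dataclass(frozen=True)
class FlowCounts:
    """Counts of the two-round completion flow; partitions the input exactly."""

    total: int
    round1_clean: int
    round1_one_error: int
    round1_multi_error: int
    round2_clean: int
    round2_by_errors: tuple[tuple[int, int], ...]  # (n_errors, count), sorted
    unable: int

    @property
    def round1_self_completed(self) -> int:
        return self.round1_clean + self.round1_one_error + self.round1_multi_error

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "round1_self_completed": self.round1_self_completed,
            "round1_clean": self.round1_clean,
            "round1_one_error": self.round1_one_error,
            "round1_multi_error": self.round1_multi_error,
            "round2_clean": self.round2_clean,
            "round2_by_errors": {str(k): v for k, v in self.round2_by_errors},
            "unable": self.unable,
        }


def completion_flow_summary(outcomes: Sequence[CompletionOutcome]) -> FlowCounts:
    """Tally the completion flow; the counts always partition ``outcomes``."""
    r1_clean = r1_one = r1_multi = r2_clean = unable = 0
    r2_errors: dict[int, int] = {}
    for o in outcomes:
        if o.status is Status.UNABLE:
            unable += 1
        elif o.round == 1:
            if o.status is Status.CLEAN:
                r1_clean += 1
            elif o.n_errors_corrected == 1:
                r1_one += 1
            else:
                r1_multi += 1
        else:
            if o.status is Status.CLEAN:
                r2_clean += 1
            else:
                r2_errors[o.n_errors_corrected] = r2_errors.get(o.n_errors_corrected, 0) + 1
    return FlowCounts(
        total=len(outcomes),
        round1_clean=r1_clean,
        round1_one_error=r1_one,
        round1_multi_error=r1_multi,
        round2_clean=r2_clean,
        round2_by_errors=tuple(sorted(r2_errors.items())),
        unable=unable,
    )
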