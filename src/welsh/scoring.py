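"""Scoring engine for the WELSH pictorial walking-capacity questionnaire.

The WELSH (Walking Estimated Limitation Stated by History) instrument asks
for the maximum time (in minutes, marked on a clock dial) a person can walk
at three paces — turtle (slow), human (usual) and rabbit (fast) — and for
the person's usual pace relative to peers (snail, turtle, human or rabbit).

Each timed item is converted to points by counting completed dial intervals:
one point per 5-minute interval up to 20 minutes, then one point per
10-minute interval up to the 60-minute dial limit.  The usual-pace item maps
to a multiplicative coefficient (snail = 1 … rabbit = 4).  The total score is

    S = (1 + p_turtle + p_human + p_rabbit) * c

so a person unable to walk at any pace who rates themselves "much slower"
scores the minimum of 1 (severe impairment); larger scores mean greater
capacity.  Under the default 0-7 point table the maximum is (21 + 1) * 4 = 88.
The instrument's description also mentions a score running "to one hundred";
the two statements are mutually inconsistent and the explicit per-item rule
(points 0-7) is the default here.  An alternative point table reaching 100 is
shipped as :data:`ONE_TO_HUNDRED_TABLE`; see ``docs/methods.md``.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union


class Sentinel(enum.Enum):
    """Non-answer states of a raw questionnaire item."""

    MISSING = "missing"
    DOUBLE = "double"

    def __repr__(self) -> str:  # keep dataclass reprs compact
        return self.name


MISSING = Sentinel.MISSING
DOUBLE = Sentinel.DOUBLE

#: A raw timed-item value: declared minutes, or a completion-error sentinel.
Minutes = Union[int, Sentinel]


class Pace(enum.IntEnum):
    """Usual-pace answer, ordered slowest to fastest."""

    SNAIL = 1
    TURTLE = 2
    HUMAN = 3
    RABBIT = 4

    def __repr__(self) -> str:
        return self.name


class ScoringError(ValueError):
    """Invalid input to the scoring engine."""


class QCRequiredError(ScoringError):
    """A response still containing sentinels was passed to the scorer."""


@dataclass(frozen=True)
class ScoreTable:
    """Configuration of the interval-counting point rule and pace coefficients.

    ``interval_bounds`` are the upper (closed) minute breakpoints of the dial
    intervals; interval ``i`` is ``(bounds[i-1], bounds[i]]`` (with implicit
    lower edge 0) and is worth ``points_per_interval[i]``.  A declared time of
    0 minutes ("unable at this pace") is worth ``zero_point``.

    Interval boundaries are lower-open / upper-closed: exactly 5 minutes
    falls in the first interval (0 points under the default table), exactly
    25 minutes in the fifth (4 points).  This is the completed-interval
    reading of "one point per interval" and is fixed here as configuration.
    """

    interval_bounds: tuple[int, ...] = (5, 10, 15, 20, 30, 40, 50, 60)
    points_per_interval: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    zero_point: int = 0
    pace_coefficients: Mapping[Pace, int] = field(
        default_factory=lambda: {Pace.SNAIL: 1, Pace.TURTLE: 2, Pace.HUMAN: 3, Pace.RABBIT: 4}
    )

    def __post_init__(self) -> None:
        b = self.interval_bounds
        p = self.points_per_interval
        if len(b) != len(p):
            raise ScoringError("interval_bounds and points_per_interval lengths differ")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ScoringError("interval_bounds must be strictly increasing")
        if any(p[i] > p[i + 1] for i in range(len(p) - 1)):
            raise ScoringError("points_per_interval must be non-decreasing")
        coeffs = [self.pace_coefficients[pace] for pace in Pace]
        if any(coeffs[i] >= coeffs[i + 1] for i in range(len(coeffs) - 1)):
            raise ScoringError("pace coefficients must increase with pace rank")

    @property
    def dial_max(self) -> int:
        """Largest minute value representable on the dial."""
        return self.interval_bounds[-1]

    @property
    def max_item_points(self) -> int:
        return max(self.points_per_interval[-1], self.zero_point)

    def to_dict(self) -> dict:
        return {
            "interval_bounds": list(self.interval_bounds),
            "points_per_interval": list(self.points_per_interval),
            "zero_point": self.zero_point,
            "pace_coefficients": {p.name.lower(): c for p, c in self.pace_coefficients.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreTable":
        return cls(
            interval_bounds=tuple(d["interval_bounds"]),
            points_per_interval=tuple(d["points_per_interval"]),
            zero_point=int(d["zero_point"]),
            pace_coefficients={Pace[k.upper()]: int(v) for k, v in d["pace_coefficients"].items()},
        )


#: Default table: items score 0-7, total range 1-88.
DEFAULT_TABLE = ScoreTable()

#: Alternative preset giving 1 point for any answered first interval and 8
#: for the last, so the maximum total is (24 + 1) * 4 = 100 as in the
#: "one to one hundred" description of the score range.
ONE_TO_HUNDRED_TABLE = ScoreTable(points_per_interval=(1, 2, 3, 4, 5, 6, 7, 8))


@dataclass(frozen=True)
class RawResponse:
    """The four pencil marks of one WELSH sheet, possibly missing/double."""

    t_turtle: Minutes
    t_human: Minutes
    t_rabbit: Minutes
    pace: Union[Pace, Sentinel]

    def __post_init__(self) -> None:
        for name in ("t_turtle", "t_human", "t_rabbit"):
            t = getattr(self, name)
            if isinstance(t, Sentinel):
                continue
            if isinstance(t, bool) or not isinstance(t, int):
                raise ScoringError(f"{name} must be a whole number of minutes, got {t!r}")
            if not 0 <= t <= 60:
                raise ScoringError(f"{name}={t} outside dial range [0, 60]")
        if not isinstance(self.pace, (Pace, Sentinel)):
            raise ScoringError(f"pace must be a Pace or sentinel, got {self.pace!r}")

    @property
    def has_sentinel(self) -> bool:
        return any(
            isinstance(v, Sentinel)
            for v in (self.t_turtle, self.t_human, self.t_rabbit, self.pace)
        )


@dataclass(frozen=True)
class ScoredResponse:
    """Item points, pace coefficient and total WELSH score of one sheet."""

    p_turtle: int
    p_human: int
    p_rabbit: int
    coefficient: int
    score: int

    def __post_init__(self) -> None:
        expected = (1 + self.p_turtle + self.p_human + self.p_rabbit) * self.coefficient
        if self.score != expected:
            raise ScoringError(f"score {self.score} != (1+sum points)*c = {expected}")


def points_for_minutes(t: int, table: ScoreTable = DEFAULT_TABLE) -> int:
    """Points for a declared walking time of ``t`` whole minutes.

    ``t = 0`` means "unable at this pace" and scores ``table.zero_point``.
    """
    if isinstance(t, Sentinel):
        raise ScoringError(f"cannot score a {t.name} answer; run QC first")
    if isinstance(t, bool) or not isinstance(t, int):
        raise ScoringError(f"minutes must be a whole number, got {t!r}")
    if not 0 <= t <= table.dial_max:
        raise ScoringError(f"t={t} outside dial range [0, {table.dial_max}]")
    if t == 0:
        return table.zero_point
    for bound, pts in zip(table.interval_bounds, table.points_per_interval):
        if t <= bound:
            return pts
    raise AssertionError("unreachable: t <= dial_max")  # pragma: no cover


def pace_coefficient(pace: Pace, table: ScoreTable = DEFAULT_TABLE) -> int:
    """Multiplicative coefficient for the usual-pace item."""
    if isinstance(pace, Sentinel):
        raise ScoringError(f"cannot score a {pace.name} pace answer; run QC first")
    if not isinstance(pace, Pace):
        raise ScoringError(f"invalid pace {pace!r}")
    return table.pace_coefficients[pace]


def welsh_score(resp: RawResponse, table: ScoreTable = DEFAULT_TABLE) -> ScoredResponse:
    """Score a clean (QC-passed) response: ``S = (1 + sum of points) * c``."""
    if resp.has_sentinel:
        raise QCRequiredError(
            "response contains missing/double answers; resolve completion errors before scoring"
        )
    p1 = points_for_minutes(resp.t_turtle, table)
    p2 = points_for_minutes(resp.t_human, table)
    p3 = points_for_minutes(resp.t_rabbit, table)
    c = pace_coefficient(resp.pace, table)
    return ScoredResponse(p1, p2, p3, c, (1 + p1 + p2 + p3) * c)


def item_point_values(table: ScoreTable = DEFAULT_TABLE) -> tuple[int, ...]:
    """Sorted distinct point values a single timed item can take."""
    return tuple(sorted({table.zero_point, *table.points_per_interval}))


def achievable_scores(table: ScoreTable = DEFAULT_TABLE) -> frozenset[int]:
    """Exact set of attainable total scores, by exhaustive enumeration."""
    pts = item_point_values(table)
    coeffs = set(table.pace_coefficients.values())
    return frozenset(
        (1 + a + b + c) * k
        for a, b, c in itertools.product(pts, repeat=3)
        for k in coeffs
    )


def minutes_for_points(p: int, table: ScoreTable = DEFAULT_TABLE) -> int:
    """A representative declared time scoring exactly ``p`` points.

    Returns the upper bound of the first interval worth ``p`` points
    (or 0 for ``zero_point`` when no interval scores it).  Inverse of
    :func:`points_for_minutes` in the sense that
    ``points_for_minutes(minutes_for_points(p)) == p``.
    """
    for bound, pts in zip(table.interval_bounds, table.points_per_interval):
        if pts == p:
            return bound
    if p == table.zero_point:
        return 0
    raise ScoringError(f"no declared time scores {p} points under this table")
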