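"""Synthetic cohort generator calibrated to the community validation study.

The generator emulates the statistical structure the validation analysis
relies on: eight sex-by-education strata, each with its own sample size,
MWD mean/SD (meters), WELSH score mean/SD (points) and within-stratum
Spearman correlation between score and walking distance, plus
education-dependent completion-error rates and the two-round
explanation/resolution flow.

Dependence model.  Within a stratum, (score, MWD) are drawn from a Gaussian
copula: a bivariate normal whose Pearson correlation is chosen so that its
population *Spearman* correlation equals the stratum target, via the exact
relation rho_S = (6/pi) * asin(rho_P / 2), inverted as
``rho_P = 2 sin(pi * rho_S / 6)`` (:func:`calibrate_rank_rho`).  The score
margin is affinely matched to the target mean/SD and snapped to the nearest
attainable WELSH score; the MWD margin is normal, truncated at 0 m by
resampling.  Raw questionnaire marks are back-solved deterministically from
each assigned score so that the scoring and QC modules are exercised on
realistic sheets and ``welsh_score(raw marks) == stored score`` exactly.

The default configuration (:func:`reference_config`) carries the published
per-stratum summary statistics of the 1723-adult community cohort; its sex
assignment follows the per-sex stratum sizes, which are internally
consistent with the per-sex pooled means (the source tables disagree on
which block is which sex — see ``docs/methods.md``).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .qc import CompletionOutcome, Status, detect_errors
from .records import COMORBIDITY_FIELDS, Education, ParticipantRecord, Sex
from .scoring import (
    DEFAULT_TABLE,
    DOUBLE,
    MISSING,
    Pace,
    RawResponse,
    ScoreTable,
    achievable_scores,
    item_point_values,
    minutes_for_points,
    welsh_score,
)


class ConfigError(ValueError):
    """Inconsistent cohort configuration."""


@dataclass(frozen=True)
class StratumSpec:
    """Target moments and rank correlation for one sex-by-education stratum."""

    sex: Sex
    education: Education
    n: int
    mwd_mean: float   # meters
    mwd_sd: float     # meters
    score_mean: float  # points
    score_sd: float    # points
    rho_target: float  # within-stratum Spearman(score, MWD)
    slope: Optional[float] = None      # published calibration, m per point
    intercept: Optional[float] = None  # published calibration, m

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("stratum size must be >= 1")
        if self.mwd_sd <= 0 or self.score_sd <= 0:
            raise ConfigError("standard deviations must be positive")
        if not abs(self.rho_target) < 1:
            raise ConfigError("|rho_target| must be < 1")


@dataclass(frozen=True)
class ErrorProfile:
    """Completion-error generating process.

    ``error_rate`` gives the per-education probability that a sheet comes
    back with at least one filling error (or ends unable).  Conditional on
    a sheet being errored, ``outcome_probs_given_error`` distributes it over
    (round-1 one error, round-1 two errors, round-2 one/two/three errors,
    unable); conditional on clean, ``p_round1_given_clean`` is the chance it
    was self-completed at the first explanation round.  ``kind_weights``
    draws each injected error's kind (missing, double, paradoxical).
    """

    error_rate: Mapping[Education, float]
    kind_weights: tuple[float, float, float] = (0.5, 0.2, 0.3)
    p_round1_given_clean: float = 1474 / 1534
    outcome_probs_given_error: tuple[float, float, float, float, float, float] = (
        42 / 189, 7 / 189, 94 / 189, 25 / 189, 16 / 189, 5 / 189
    )

    def __post_init__(self) -> None:
        for edu, r in self.error_rate.items():
            if not 0 <= r <= 1:
                raise ConfigError(f"error rate for {edu} outside [0, 1]")
        if not math.isclose(sum(self.outcome_probs_given_error), 1.0, abs_tol=1e-9):
            raise ConfigError("outcome probabilities must sum to 1")
        if any(p < 0 for p in self.outcome_probs_given_error):
            raise ConfigError("outcome probabilities must be non-negative")
        if not 0 <= self.p_round1_given_clean <= 1:
            raise ConfigError("p_round1_given_clean outside [0, 1]")
        if any(w < 0 for w in self.kind_weights) or sum(self.kind_weights) <= 0:
            raise ConfigError("kind weights must be non-negative, not all zero")


def _censored_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """Mean of min(max(X, lo), hi) for X ~ N(mu, sd)."""
    from scipy.stats import norm

    a, b = (lo - mu) / sd, (hi - mu) / sd
    return (lo * norm.cdf(a) + hi * norm.sf(b)
            + mu * (norm.cdf(b) - norm.cdf(a)) - sd * (norm.pdf(b) - norm.pdf(a)))


def _truncated_below_mean(mu: float, sd: float, lo: float) -> float:
    """Mean of X ~ N(mu, sd) conditioned on X >= lo."""
    from scipy.stats import norm

    a = (lo - mu) / sd
    return mu + sd * norm.pdf(a) / norm.sf(a)


def _latent_mean(target: float, sd: float, lo: float, hi: Optional[float]) -> float:
    """Latent normal mean whose boundary-handled mean equals ``target``.

    Snapping scores onto the bounded attainable grid censors the latent
    draw at the grid edges, and resampling negative walking distances
    truncates it below; both shift the realized mean away from the latent
    one.  Solving for the latent mean keeps each stratum's sample mean
    centred on its target.
    """
    from scipy.optimize import brentq

    if hi is None:
        f = lambda mu: _truncated_below_mean(mu, sd, lo) - target
    else:
        f = lambda mu: _censored_normal_mean(mu, sd, lo, hi) - target
    span = 10 * sd
    return float(brentq(f, target - span, target + span, xtol=1e-9))


#: Number of errors injected and flow outcome for each error category.
_ERROR_OUTCOMES = (
    (1, 1, Status.CORRECTED),   # round 1, one error
    (2, 1, Status.CORRECTED),   # round 1, two errors
    (1, 2, Status.CORRECTED),   # round 2, one error
    (2, 2, Status.CORRECTED),   # round 2, two errors
    (3, 2, Status.CORRECTED),   # round 2, three errors
    (4, 2, Status.UNABLE),      # unable: all four items left blank
)


@dataclass(frozen=True)
class CohortConfig:
    """Full generator configuration: strata, error process, table, seed."""

    strata: tuple[StratumSpec, ...]
    error_profile: ErrorProfile
    score_table: ScoreTable = DEFAULT_TABLE
    seed: int = 0

    def __post_init__(self) -> None:
        keys = [(s.sex, s.education) for s in self.strata]
        if len(set(keys)) != len(keys):
            raise ConfigError("duplicate (sex, education) stratum")

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.strata)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "score_table": self.score_table.to_dict(),
            "strata": [
                {
                    "sex": s.sex.value,
                    "education": s.education.value,
                    "n": int(s.n),
                    "mwd_mean": float(s.mwd_mean),
                    "mwd_sd": float(s.mwd_sd),
                    "score_mean": float(s.score_mean),
                    "score_sd": float(s.score_sd),
                    "rho_target": float(s.rho_target),
                    "slope": None if s.slope is None else float(s.slope),
                    "intercept": None if s.intercept is None else float(s.intercept),
                }
                for s in self.strata
            ],
            "error_profile": {
                "error_rate": {e.value: float(r) for e, r in self.error_profile.error_rate.items()},
                "kind_weights": [float(w) for w in self.error_profile.kind_weights],
                "p_round1_given_clean": float(self.error_profile.p_round1_given_clean),
                "outcome_probs_given_error": [
                    float(p) for p in self.error_profile.outcome_probs_given_error
                ],
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        ep = d["error_profile"]
        return cls(
            strata=tuple(
                StratumSpec(
                    sex=Sex(s["sex"]),
                    education=Education(s["education"]),
                    n=int(s["n"]),
                    mwd_mean=float(s["mwd_mean"]),
                    mwd_sd=float(s["mwd_sd"]),
                    score_mean=float(s["score_mean"]),
                    score_sd=float(s["score_sd"]),
                    rho_target=float(s["rho_target"]),
                    slope=None if s.get("slope") is None else float(s["slope"]),
                    intercept=None if s.get("intercept") is None else float(s["intercept"]),
                )
                for s in d["strata"]
            ),
            error_profile=ErrorProfile(
                error_rate={Education(k): float(v) for k, v in ep["error_rate"].items()},
                kind_weights=tuple(ep["kind_weights"]),
                p_round1_given_clean=float(ep["p_round1_given_clean"]),
                outcome_probs_given_error=tuple(ep["outcome_probs_given_error"]),
            ),
            score_table=ScoreTable.from_dict(d["score_table"]),
            seed=int(d["seed"]),
        )

    def content_hash(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def calibrate_rank_rho(rho_spearman: float) -> float:
    """Pearson correlation of a bivariate normal with the given Spearman rho.

    For a bivariate normal, rho_S = (6/pi) asin(rho_P/2); this returns the
    inverse, ``2 sin(pi rho_S / 6)``, so a Gaussian copula parameterized
    with the returned value has the requested rank correlation.
    """
    if not abs(rho_spearman) < 1:
        raise ConfigError("|rho_spearman| must be < 1")
    return 2.0 * math.sin(math.pi * rho_spearman / 6.0)


def _score_decompositions(table: ScoreTable) -> dict[int, tuple[int, int, int, Pace]]:
    """Canonical (p_turtle, p_human, p_rabbit, pace) for every attainable score.

    Preference order: maximize turtle points, then human, then rabbit (so
    declared times are non-increasing with pace and the sheet is
    paradox-free), breaking remaining ties toward the slowest admissible
    pace.  Deterministic by construction.
    """
    pts = sorted(item_point_values(table), reverse=True)
    pts_set = set(pts)
    coeff_to_pace = {c: p for p, c in sorted(table.pace_coefficients.items())}
    out: dict[int, tuple[int, int, int, Pace]] = {}
    for s in sorted(achievable_scores(table)):
        best: Optional[tuple[int, int, int, int]] = None
        for c in sorted(coeff_to_pace):
            if s % c != 0:
                continue
            total = s // c - 1
            if total < 0:
                continue
            # greedy split of `total` points over the three items
            combo = None
            for a in pts:
                if a > total:
                    continue
                for b in pts:
                    if b > total - a:
                        continue
                    if (total - a - b) in pts_set:
                        combo = (a, b, total - a - b)
                        break
                if combo:
                    break
            if combo is None:
                continue
            cand = (*combo, c)
            if best is None or cand[:3] > best[:3]:
                best = cand
        if best is not None:
            out[s] = (best[0], best[1], best[2], coeff_to_pace[best[3]])
    return out


def _response_for_score(score: int, decomp, table: ScoreTable) -> RawResponse:
    p1, p2, p3, pace = decomp[score]
    return RawResponse(
        t_turtle=minutes_for_points(p1, table),
        t_human=minutes_for_points(p2, table),
        t_rabbit=minutes_for_points(p3, table),
        pace=pace,
    )


#: Per-sex demographic marginals of the study population (means/SDs and
#: prevalences): age years, weight kg, height cm, smoking and comorbidity
#: proportions.  Used only as realistic plumbing; no dependence with score
#: or MWD is modelled.
DEMOGRAPHICS: dict[Sex, dict] = {
    Sex.MALE: {
        "age": (44.9, 19.1), "weight": (70.7, 11.0), "height": (173.0, 7.6),
        "smoker": 129 / 969, "hypertension": 103 / 969, "diabetes": 37 / 969,
        "arthrosis": 65 / 969, "pulmonary": 24 / 969, "sickle_cell": 19 / 969,
    },
    Sex.FEMALE: {
        "age": (48.6, 17.2), "weight": (70.2, 14.5), "height": (164.5, 7.2),
        "smoker": 21 / 754, "hypertension": 163 / 754, "diabetes": 41 / 754,
        "arthrosis": 116 / 754, "pulmonary": 32 / 754, "sickle_cell": 20 / 754,
    },
}

_MAX_RESAMPLE = 100


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, size: int) -> np.ndarray:
    """Normal draws resampled until >= low; errors out after a resample cap."""
    x = mean + sd * rng.standard_normal(size)
    for _ in range(_MAX_RESAMPLE):
        bad = x < low
        if not bad.any():
            return x
        x[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
    raise ConfigError(
        f"could not draw values >= {low} from N({mean}, {sd}) in {_MAX_RESAMPLE} rounds"
    )


def generate_stratum(
    spec: StratumSpec,
    table: ScoreTable = DEFAULT_TABLE,
    seed: Union[int, np.random.Generator] = 0,
    id_prefix: str = "",
) -> list[ParticipantRecord]:
    """Draw one stratum of participant records (no completion errors yet).

    Scores are copula-correlated with MWD at the stratum's Spearman target,
    snapped to the nearest attainable WELSH score; raw questionnaire marks
    are back-solved so rescoring them reproduces the stored score exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores_ach = np.array(sorted(achievable_scores(table)))
    if not scores_ach.min() <= spec.score_mean <= scores_ach.max():
        raise ConfigError(
            f"target score mean {spec.score_mean} outside attainable range "
            f"[{scores_ach.min()}, {scores_ach.max()}]"
        )
    decomp = _score_decompositions(table)

    r = calibrate_rank_rho(spec.rho_target)
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, r], [r, 1.0]], size=spec.n,
                                method="cholesky")
    score_mu = _latent_mean(spec.score_mean, spec.score_sd,
                            float(scores_ach.min()), float(scores_ach.max()))
    raw_score = score_mu + spec.score_sd * z[:, 0]
    idx = np.abs(raw_score[:, None] - scores_ach[None, :]).argmin(axis=1)
    scores = scores_ach[idx]

    mwd_mu = _latent_mean(spec.mwd_mean, spec.mwd_sd, 0.0, None)
    mwd = mwd_mu + spec.mwd_sd * z[:, 1]
    for _ in range(_MAX_RESAMPLE):
        bad = mwd < 0
        if not bad.any():
            break
        mwd[bad] = mwd_mu + spec.mwd_sd * rng.standard_normal(int(bad.sum()))
    else:
        raise ConfigError("MWD truncation at 0 m failed to converge")

    demo = DEMOGRAPHICS[spec.sex]
    age = _truncated_normal(rng, *demo["age"], low=20.0, size=spec.n).round(0)
    weight = _truncated_normal(rng, *demo["weight"], low=30.0, size=spec.n).round(1)
    height = _truncated_normal(rng, *demo["height"], low=120.0, size=spec.n).round(1)
    flags = {
        name: rng.random(spec.n) < demo[name]
        for name in ("smoker", *COMORBIDITY_FIELDS)
    }

    records = []
    for i in range(spec.n):
        resp = _response_for_score(int(scores[i]), decomp, table)
        rec = ParticipantRecord(
            id=f"{id_prefix}{spec.sex.value[0]}-{spec.education.value}-{i:04d}",
            sex=spec.sex,
            education=spec.education,
            age=float(age[i]),
            weight_kg=float(weight[i]),
            height_cm=float(height[i]),
            smoker=bool(flags["smoker"][i]),
            **{f: bool(flags[f][i]) for f in COMORBIDITY_FIELDS},
            response=resp,
            score=int(scores[i]),
            mwd=float(round(mwd[i], 1)),
        )
        assert welsh_score(resp, table).score == rec.score
        records.append(rec)
    return records


def _corrupt(resp: RawResponse, n_errors: int, kind_weights, rng: np.random.Generator) -> RawResponse:
    """Apply ``n_errors`` completion errors to a clean sheet.

    ``n_errors >= 4`` is the unable state: all four items come back blank.
    Paradoxical corruption perturbs declared times to violate the pace
    ordering strictly; missing/double overwrite one untouched item.
    """
    if n_errors >= 4:
        return RawResponse(MISSING, MISSING, MISSING, MISSING)
    fields = {"t_turtle": resp.t_turtle, "t_human": resp.t_human,
              "t_rabbit": resp.t_rabbit, "pace": resp.pace}
    touched: set[str] = set()
    weights = np.asarray(kind_weights, dtype=float)
    weights = weights / weights.sum()
    pairs = (("t_human", "t_turtle"), ("t_rabbit", "t_human"), ("t_rabbit", "t_turtle"))
    for _ in range(n_errors):
        kind = rng.choice(3, p=weights)  # 0 missing, 1 double, 2 paradoxical
        if kind == 2:
            usable = [
                (f, s) for f, s in pairs
                if f not in touched and s not in touched
                and isinstance(fields[f], int) and isinstance(fields[s], int)
            ]
            if usable:
                f, s = usable[int(rng.integers(len(usable)))]
                ts = fields[s]
                if ts < 60:
                    fields[f] = min(60, ts + 10)
                else:
                    fields[s] = 50
                    fields[f] = 60
                touched.update((f, s))
                continue
            kind = 0  # no paradox-capable pair left; fall back to missing
        free = [f for f in fields if f not in touched]
        if not free:
            break
        f = free[int(rng.integers(len(free)))]
        fields[f] = MISSING if kind == 0 else DOUBLE
        touched.add(f)
    return RawResponse(fields["t_turtle"], fields["t_human"], fields["t_rabbit"], fields["pace"])


def inject_errors(
    records: Sequence[ParticipantRecord],
    profile: ErrorProfile,
    seed: Union[int, np.random.Generator] = 0,
) -> list[ParticipantRecord]:
    """Attach completion outcomes and first-attempt sheets to clean records.

    Each sheet comes back errored with its education stratum's probability;
    errored sheets are distributed over the two-round flow categories and
    their first-attempt marks corrupted so the QC module can detect every
    injected flag.  The final ``response`` (and score) stay clean, modelling
    investigator correction; ``unable`` sheets keep their score as well
    (scored with the interviewer's help — an analysis switch can exclude
    them downstream).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    outcome_probs = np.asarray(profile.outcome_probs_given_error)
    out: list[ParticipantRecord] = []
    for rec in records:
        rate = profile.error_rate.get(rec.education, 0.0)
        if rng.random() < rate:
            cat = int(rng.choice(len(_ERROR_OUTCOMES), p=outcome_probs))
            n_err, rnd, status = _ERROR_OUTCOMES[cat]
            first = _corrupt(rec.response, n_err, profile.kind_weights, rng)
            # an error is an erroneous *answer*: count distinct flagged items,
            # not flag instances (one paradoxical answer can violate two pairs)
            n_items = len({f.item for f in detect_errors(first)})
            outcome = CompletionOutcome(round=rnd, n_errors_corrected=max(n_items, 1),
                                        status=status)
            out.append(replace(rec, first_attempt=first, outcome=outcome))
        else:
            rnd = 1 if rng.random() < profile.p_round1_given_clean else 2
            outcome = CompletionOutcome(round=rnd, n_errors_corrected=0, status=Status.CLEAN)
            out.append(replace(rec, outcome=outcome))
    return out


def generate_cohort(config: CohortConfig, seed: Optional[int] = None) -> list[ParticipantRecord]:
    """Generate the full cohort: all strata plus injected completion errors.

    ``seed`` overrides ``config.seed`` when given.  Identical seed and
    config give an identical cohort.
    """
    base = config.seed if seed is None else seed
    rng = np.random.default_rng(base)
    records: list[ParticipantRecord] = []
    for spec in config.strata:
        records.extend(generate_stratum(spec, config.score_table, rng))
    return inject_errors(records, config.error_profile, rng)


def reference_config(seed: int = 0) -> CohortConfig:
    """Default configuration: the eight strata of the 1723-adult community
    validation cohort, with published per-stratum moments, rank correlations
    and calibration lines, and per-education completion-error rates.

    Sex labels follow the per-sex stratum sizes (216/125/242/386 male,
    308/108/191/147 female), which are consistent with the per-sex pooled
    walking-distance means; see ``docs/methods.md`` for the label conflict
    in the source tables.
    """
    male, female = Sex.MALE, Sex.FEMALE
    none, prim, sec, uni = (Education.NONE, Education.PRIMARY,
                            Education.SECONDARY, Education.UNIVERSITY)
    strata = (
        # sex, education, n, MWD mean/SD (m), score mean/SD (pts), Spearman, slope, intercept
        StratumSpec(male, none, 216, 351, 136, 47, 24, 0.576, 3.26, 196),
        StratumSpec(male, prim, 125, 376, 129, 52, 24, 0.520, 2.59, 241),
        StratumSpec(male, sec, 242, 428, 127, 60, 20, 0.469, 3.12, 242),
        StratumSpec(male, uni, 386, 466, 129, 66, 16, 0.291, 2.67, 291),
        StratumSpec(female, none, 308, 294, 117, 41, 22, 0.429, 3.04, 171),
        StratumSpec(female, prim, 108, 338, 147, 46, 25, 0.490, 3.17, 192),
        StratumSpec(female, sec, 191, 360, 120, 50, 19, 0.511, 2.17, 252),
        StratumSpec(female, uni, 147, 390, 137, 55, 18, 0.552, 3.86, 176),
    )
    profile = ErrorProfile(
        error_rate={
            Education.NONE: 113 / 524,        # never been to school
            Education.PRIMARY: 32 / 233,
            Education.SECONDARY: 40 / 433,
            Education.UNIVERSITY: 21 / 533,
        },
    )
    return CohortConfig(strata=strata, error_profile=profile, seed=seed)


def config_weighted_means(config: CohortConfig) -> tuple[float, float]:
    """n-weighted (MWD mean, score mean) implied by the stratum targets."""
    n = sum(s.n for s in config.strata)
    mwd = sum(s.n * s.mwd_mean for s in config.strata) / n
    score = sum(s.n * s.score_mean for s in config.strata) / n
    return mwd, score
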