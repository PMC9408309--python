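"""Von Frey up-down estimation of the 50% paw-withdrawal threshold.

The up-down (staircase) procedure presents calibrated filaments in sequence:
after a withdrawal (``X``) the next weaker filament is presented, after no
withdrawal (``O``) the next stronger one, clamped at the ends of the ladder.
Testing runs until six responses have been collected starting from the trial
immediately before the first change in response; the 50% threshold is then

    threshold = 10 ** (x_f + k * delta),

where ``x_f`` is log10 of the final counted force (grams), ``delta`` the mean
log10 spacing of the ladder, and ``k`` a tabulated constant determined by the
response pattern.  Series that never change response are censored at the
corresponding ladder bound.

The bundled k table is derived by constrained maximum likelihood under a
probit response curve whose scale equals one ladder step (the classical
construction for staircase estimators); :func:`pattern_k` regenerates any
entry so the table is fully inspectable and replaceable.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import minimize_scalar

from .errors import EstimationError

__all__ = [
    "CHAPLAN_LADDER",
    "UpDownSeries",
    "UpDownResult",
    "updown_threshold",
    "pattern_k",
    "build_k_table",
    "load_k_table",
    "read_updown_csv",
    "simulate_updown_series",
]

#: Standard rat von Frey filament set (grams), ~0.22 log10-g spacing.
CHAPLAN_LADDER = (0.41, 0.70, 1.20, 2.04, 3.63, 5.50, 8.51, 15.14)

WITHDRAW = "X"
NO_WITHDRAW = "O"

#: Number of counted responses (the trial before the first change, plus five).
COUNTED_TRIALS = 6


@dataclass(frozen=True)
class UpDownSeries:
    """An up-down trial sequence on a fixed filament ladder.

    ``trials`` is an ordered list of ``(force_index, withdrew)`` pairs; the
    sequence must obey the up-down rule (withdrawal steps down, no withdrawal
    steps up, clamped at the ladder ends).
    """

    ladder: tuple[float, ...]
    trials: tuple[tuple[int, bool], ...]

    def __post_init__(self) -> None:
        ladder = tuple(float(f) for f in self.ladder)
        if len(ladder) < 2:
            raise ValueError("ladder needs at least two filament forces")
        if any(f <= 0 for f in ladder) or any(b >= a for b, a in zip(ladder, ladder[1:])):
            raise ValueError("ladder forces must be positive and strictly ascending")
        object.__setattr__(self, "ladder", ladder)
        trials = tuple((int(i), bool(w)) for i, w in self.trials)
        object.__setattr__(self, "trials", trials)
        top = len(ladder) - 1
        for t, (idx, _) in enumerate(trials):
            if not (0 <= idx <= top):
                raise ValueError(f"trial {t}: force index {idx} outside the ladder")
            if t > 0:
                prev_idx, prev_w = trials[t - 1]
                expected = max(0, min(top, prev_idx + (-1 if prev_w else 1)))
                if idx != expected:
                    raise ValueError(
                        f"trial {t}: index {idx} violates the up-down rule (expected {expected})"
                    )

    @property
    def step(self) -> float:
        """Mean log10-gram spacing of the ladder."""
        logs = np.log10(self.ladder)
        return float(np.mean(np.diff(logs)))

    @property
    def responses(self) -> str:
        return "".join(WITHDRAW if w else NO_WITHDRAW for _, w in self.trials)


@dataclass(frozen=True)
class UpDownResult:
    """Estimated 50% withdrawal threshold in grams."""

    threshold_g: float
    censored: bool
    pattern: str | None = None
    k: float | None = None


def pattern_k(pattern: str, sigma_steps: float = 1.0, bound_steps: float = 2.0) -> float:
    """Threshold offset k (in ladder steps) for one counted response pattern.

    The relative filament positions visited by a pattern are fixed by the
    up-down rule, so the 50% point can be estimated by maximum likelihood
    under a probit curve ``P(withdraw at u) = Phi((u - mu)/sigma)`` with
    ``sigma`` expressed in ladder steps.  ``k`` is the ML estimate of ``mu``
    minus the final tested position, constrained to the visited range padded
    by ``bound_steps`` (patterns with perfect separation have flat tails).
    """
    pattern = pattern.strip().upper()
    if not pattern or set(pattern) - {WITHDRAW, NO_WITHDRAW}:
        raise ValueError(f"pattern must be a string over {{X, O}}, got {pattern!r}")
    if len(set(pattern)) < 2:
        raise ValueError("pattern must contain at least one response change")
    u = [0.0]
    for r in pattern[:-1]:
        u.append(u[-1] + (-1.0 if r == WITHDRAW else 1.0))
    u_arr = np.array(u)
    sign = np.array([1.0 if r == WITHDRAW else -1.0 for r in pattern])

    def nll(mu: float) -> float:
        return -float(np.sum(stats.norm.logcdf(sign * (u_arr - mu) / sigma_steps)))

    res = minimize_scalar(
        nll, bounds=(u_arr.min() - bound_steps, u_arr.max() + bound_steps), method="bounded"
    )
    return float(res.x - u_arr[-1])


def build_k_table(length: int = COUNTED_TRIALS) -> dict[str, float]:
    """k for every length-``length`` pattern whose first two responses differ."""
    table = {}
    for bits in range(2**length):
        pattern = "".join(
            WITHDRAW if (bits >> (length - 1 - i)) & 1 else NO_WITHDRAW for i in range(length)
        )
        if pattern[0] == pattern[1]:
            continue
        table[pattern] = round(pattern_k(pattern), 4)
    return table


def load_k_table() -> dict[str, float]:
    """Load the bundled response-pattern -> k table."""
    text = resources.files("oipnkit").joinpath("data/updown_k.json").read_text(encoding="utf-8")
    payload = json.loads(text)
    return {str(k): float(v) for k, v in payload["k"].items()}


def updown_threshold(
    series: UpDownSeries, k_table: Mapping[str, float] | None = None
) -> UpDownResult:
    """50% withdrawal threshold of an up-down series, in grams.

    Applies the stopping rule (six counted responses from the trial before the
    first change), looks up ``k`` for the counted pattern, and evaluates
    ``10**(x_f + k * delta)`` clamped to the ladder range.  A series with no
    response change is censored at the ladder bound its responses imply.
    Trials recorded after the stopping rule fires are ignored with a warning.
    """
    if not series.trials:
        raise EstimationError("series has no trials")
    if k_table is None:
        k_table = load_k_table()
    responses = series.responses
    first = responses[0]
    change = next((t for t, r in enumerate(responses) if r != first), None)
    if change is None:
        # monotone series: withdrawal everywhere -> at/below the weakest
        # filament; no withdrawal anywhere -> at/above the strongest.
        bound = series.ladder[0] if first == WITHDRAW else series.ladder[-1]
        return UpDownResult(threshold_g=bound, censored=True, pattern=responses)
    start = change - 1
    end = start + COUNTED_TRIALS  # exclusive
    if len(series.trials) < end:
        raise EstimationError(
            f"series ended after {len(series.trials)} trials; "
            f"{end} are needed to complete the counted window"
        )
    if len(series.trials) > end:
        warnings.warn(
            f"{len(series.trials) - end} trial(s) after the stopping rule are ignored",
            stacklevel=2,
        )
    window = series.trials[start:end]
    pattern = "".join(WITHDRAW if w else NO_WITHDRAW for _, w in window)
    if pattern not in k_table:
        raise EstimationError(f"no k value for response pattern {pattern!r}")
    k = float(k_table[pattern])
    x_f = math.log10(series.ladder[window[-1][0]])
    threshold = 10.0 ** (x_f + k * series.step)
    threshold = min(max(threshold, series.ladder[0]), series.ladder[-1])
    return UpDownResult(threshold_g=threshold, censored=False, pattern=pattern, k=k)


def simulate_updown_series(
    true_threshold_g: float,
    ladder: Sequence[float] = CHAPLAN_LADDER,
    sigma_log: float | None = None,
    seed: int | None = None,
    max_trials: int = 50,
) -> UpDownSeries:
    """Simulate an up-down series from a probit response curve (testing aid).

    ``P(withdraw | force f) = Phi((log10 f - log10 threshold)/sigma_log)``;
    by default ``sigma_log`` is one ladder step.  The series starts mid-ladder
    and stops when the counted window completes or a bound censors it.
    """
    rng = np.random.default_rng(seed)
    ladder = tuple(float(f) for f in ladder)
    logs = [math.log10(f) for f in ladder]
    if sigma_log is None:
        sigma_log = float(np.mean(np.diff(logs)))
    mu = math.log10(true_threshold_g)
    top = len(ladder) - 1
    idx = len(ladder) // 2
    trials: list[tuple[int, bool]] = []
    change_at = None
    for t in range(max_trials):
        p = float(stats.norm.cdf((logs[idx] - mu) / sigma_log))
        w = bool(rng.random() < p)
        trials.append((idx, w))
        if change_at is None and t > 0 and w != trials[0][1]:
            change_at = t
        if change_at is not None and len(trials) >= change_at - 1 + COUNTED_TRIALS:
            break
        nxt = idx + (-1 if w else 1)
        if nxt < 0 or nxt > top:
            if change_at is None:
                break  # censored at a bound
            nxt = max(0, min(top, nxt))
        idx = nxt
    return UpDownSeries(ladder=ladder, trials=tuple(trials))


def read_updown_csv(path: str | Path, ladder: Sequence[float] | str | Path) -> UpDownSeries:
    """Read a trial series CSV (trial_index, force_g, response in {X, O}).

    ``ladder`` is either the force list itself or a YAML file with a
    top-level ``ladder`` key.  Forces are matched to ladder rungs within a
    relative tolerance of 1e-6.
    """
    if isinstance(ladder, (str, Path)):
        data = yaml.safe_load(Path(ladder).read_text(encoding="utf-8"))
        ladder = data["ladder"] if isinstance(data, dict) else data
    ladder = tuple(float(f) for f in ladder)
    df = pd.read_csv(path, comment="#")
    required = {"trial_index", "force_g", "response"}
    if not required.issubset(df.columns):
        raise ValueError(f"up-down CSV must have columns {sorted(required)}")
    df = df.sort_values("trial_index")
    trials = []
    for _, row in df.iterrows():
        force = float(row["force_g"])
        matches = [i for i, f in enumerate(ladder) if math.isclose(f, force, rel_tol=1e-6)]
        if not matches:
            raise ValueError(f"force {force} g is not on the declared ladder")
        resp = str(row["response"]).strip().upper()
        if resp not in (WITHDRAW, NO_WITHDRAW):
            raise ValueError(f"response must be X or O, got {row['response']!r}")
        trials.append((matches[0], resp == WITHDRAW))
    return UpDownSeries(ladder=ladder, trials=tuple(trials))
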