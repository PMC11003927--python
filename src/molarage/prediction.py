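"""Bayesian age prediction from molar log tissue ratios.

Given a fitted molar-combination model and an individual's observed log
tissue ratios, the posterior age density under a uniform prior on
[14, 23] years is proportional to the multivariate normal likelihood of
the observed subvector evaluated along the age grid.  Predictions are
summarised by the 25th/75th posterior percentiles (whose difference, the
interquartile range, measures prediction sharpness) and by the posterior
probability of being older than 18 years.

Hypothetical observations probe a model's performance without real test
data: six equally spaced points span each tooth's observed response range,
and the four interior ones — colour-coded black, red, green, blue from the
least to the most negative response, i.e. from youngest- to oldest-looking
— serve as standardised inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .cohort import CLASS_ORDER, Cohort, MolarClass, Sex
from .joint import JointParameters, _moments_on_grid, _mvn_logpdf_rows

__all__ = [
    "AgePrior",
    "Observation",
    "PosteriorAgeDistribution",
    "PredictionSummary",
    "HypotheticalSet",
    "DegenerateRangeError",
    "COLOURS",
    "posterior_age",
    "summarize",
    "hypothetical_observations",
    "compare_combinations",
]

#: Hypothetical-observation colours, ordered from least to most negative y
#: (youngest- to oldest-looking).
COLOURS = ("black", "red", "green", "blue")


class DegenerateRangeError(ValueError):
    """Observed response range has zero width; no hypothetical spread exists."""


@dataclass(frozen=True)
class AgePrior:
    """Uniform prior on chronological age, in years (default 14-23)."""

    lower: float = 14.0
    upper: float = 23.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("prior needs lower < upper")


@dataclass(frozen=True)
class Observation:
    """One individual's observed log tissue ratios by molar class."""

    sex: Sex
    y_by_class: Mapping[MolarClass, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        if not self.y_by_class:
            raise ValueError("observation must include at least one molar class")
        if not all(math.isfinite(v) for v in self.y_by_class.values()):
            raise ValueError("observed responses must be finite")

    @property
    def classes(self) -> tuple[MolarClass, ...]:
        return tuple(c for c in CLASS_ORDER if c in self.y_by_class)


class PosteriorAgeDistribution:
    """Normalised posterior density over a uniform age grid.

    Quantiles come from linear interpolation of the cumulative trapezoidal
    integral; tail probabilities from its complement.
    """

    def __init__(self, grid: np.ndarray, density: np.ndarray):
        grid = np.asarray(grid, dtype=float)
        density = np.asarray(density, dtype=float)
        if grid.ndim != 1 or grid.shape != density.shape or len(grid) < 2:
            raise ValueError("grid and density must be matching 1-D arrays")
        if np.any(density < 0):
            raise ValueError("density must be nonnegative")
        norm = np.trapezoid(density, grid)
        if not (norm > 0 and math.isfinite(norm)):
            raise ValueError("density does not integrate to a positive value")
        self.grid = grid
        self.density = density / norm
        cdf = cumulative_trapezoid(self.density, self.grid, initial=0.0)
        self._cdf = cdf / cdf[-1]

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def cdf(self, age: float) -> float:
        if age <= self.grid[0]:
            return 0.0
        if age >= self.grid[-1]:
            return 1.0
        return float(np.interp(age, self.grid, self._cdf))

    def quantile(self, q: float) -> float:
        if not 0.0 <= q <= 1.0:
            raise ValueError("quantile level must lie in [0, 1]")
        return float(np.interp(q, self._cdf, self.grid))

    def prob_above(self, age: float) -> float:
        return 1.0 - self.cdf(age)


@dataclass(frozen=True)
class PredictionSummary:
    """Posterior quartiles, their range, and P(age > 18) for one observation."""

    q25: float
    q75: float
    iqr: float
    p_over_18: float

    def __post_init__(self) -> None:
        if not (self.q25 <= self.q75 and self.iqr >= 0):
            raise ValueError("need q25 <= q75 and iqr >= 0")
        if not 0.0 <= self.p_over_18 <= 1.0:
            raise ValueError("p_over_18 must lie in [0, 1]")


def posterior_age(
    params: JointParameters,
    observation: Observation,
    prior: AgePrior | None = None,
    grid_step: float = 0.005,
    *,
    invert_weights: bool = False,
) -> PosteriorAgeDistribution:
    """Posterior age density for one observation under the uniform prior.

    The density at each grid age is the (multivariate normal) likelihood of
    the observed subvector at that age, normalised by the trapezoidal rule
    over the prior support.  Deterministic for fixed inputs.
    """
    prior = prior if prior is not None else AgePrior()
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    classes = observation.classes
    missing = [c for c in classes if c not in params.tooth_by_class]
    if missing:
        raise ValueError(
            f"observation includes classes not in the model: "
            f"{[c.label for c in missing]}"
        )
    n_steps = max(2, int(round((prior.upper - prior.lower) / grid_step)))
    grid = prior.lower + (prior.upper - prior.lower) * np.arange(n_steps + 1) / n_steps
    y = np.array([observation.y_by_class[c] for c in classes])
    mu, sd, R = _moments_on_grid(params, grid, observation.sex, classes, invert_weights)
    loglik = _mvn_logpdf_rows(y, mu, sd, R)
    m = np.max(loglik)
    if not math.isfinite(m):
        raise ValueError(
            f"likelihood is numerically zero across the whole prior for "
            f"observation {dict(observation.y_by_class)}"
        )
    density = np.exp(loglik - m)
    return PosteriorAgeDistribution(grid, density)


def summarize(
    posterior: PosteriorAgeDistribution, threshold_years: float = 18.0
) -> PredictionSummary:
    """Quartiles, IQR, and the probability of exceeding the age threshold."""
    q25 = posterior.quantile(0.25)
    q75 = posterior.quantile(0.75)
    return PredictionSummary(
        q25=q25, q75=q75, iqr=q75 - q25,
        p_over_18=posterior.prob_above(threshold_years),
    )


@dataclass(frozen=True)
class HypotheticalSet:
    """The four colour-coded hypothetical responses for one tooth and sex."""

    tooth: int
    sex: Sex
    values: Mapping[str, float]  # colour -> y, black > red > green > blue

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        if tuple(self.values) != COLOURS:
            raise ValueError(f"values must be keyed {COLOURS} in order")
        v = [self.values[c] for c in COLOURS]
        if not (v[0] > v[1] > v[2] > v[3]):
            raise ValueError("hypothetical values must descend black > red > green > blue")
        steps = np.diff(v)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("hypothetical values must be equally spaced")


def hypothetical_observations(cohort: Cohort, tooth: int, sex: Sex | str) -> HypotheticalSet:
    """Four equally spaced interior points of the tooth's response range.

    Six points are placed at uniform intervals from the minimum to the
    maximum observed response for the tooth and sex; the four interior
    points are returned as black (= max - step) down to blue (= min + step).
    """
    ys = [r.y for r in cohort.records_for(tooth=tooth, sex=sex)]
    if len(ys) < 2:
        raise ValueError(f"need >= 2 observations of tooth {tooth} for sex {Sex.parse(sex).value}")
    lo, hi = min(ys), max(ys)
    if lo == hi:
        raise DegenerateRangeError(f"tooth {tooth}: all responses equal ({lo})")
    step = (hi - lo) / 5.0
    values = {
        "black": hi - step,
        "red": hi - 2.0 * step,
        "green": hi - 3.0 * step,
        "blue": lo + step,
    }
    return HypotheticalSet(tooth=tooth, sex=Sex.parse(sex), values=values)


def _subsets_in_order(classes: Sequence[MolarClass]) -> list[tuple[MolarClass, ...]]:
    """Singles, then pairs, then the full set — each in class order."""
    cs = [c for c in CLASS_ORDER if c in classes]
    subsets: list[tuple[MolarClass, ...]] = [(c,) for c in cs]
    subsets += [(cs[i], cs[j]) for i in range(len(cs)) for j in range(i + 1, len(cs))]
    if len(cs) > 1:
        subsets.append(tuple(cs))
    return subsets


def compare_combinations(
    params: JointParameters,
    hypothetical_sets: Mapping[MolarClass, HypotheticalSet],
    prior: AgePrior | None = None,
    grid_step: float = 0.005,
    *,
    threshold_years: float = 18.0,
    invert_weights: bool = False,
) -> pd.DataFrame:
    """Prediction summaries for every sub-combination x colour.

    For each nonempty subset of the model's molar classes (7 subsets for a
    three-class model) and each of the four colours, the same-colour
    hypothetical values form the observation; rows report the posterior
    quartiles, IQR and P(> 18).
    """
    for c in params.classes:
        hs = hypothetical_sets.get(c)
        if hs is None:
            raise ValueError(f"no hypothetical set for the {c.label} molar")
        if hs.tooth != params.tooth_by_class[c]:
            raise ValueError(
                f"hypothetical set for {c.label} molar is for tooth {hs.tooth}, "
                f"model uses {params.tooth_by_class[c]}"
            )
    sexes = {hypothetical_sets[c].sex for c in params.classes}
    if len(sexes) != 1:
        raise ValueError("hypothetical sets mix sexes")
    (sex,) = sexes
    rows = []
    for subset in _subsets_in_order(params.classes):
        sub_params = params.subset(subset)
        label = "-".join(str(params.tooth_by_class[c]) for c in subset)
        class_label = "+".join(c.label for c in subset)
        for colour in COLOURS:
            obs = Observation(
                sex, {c: hypothetical_sets[c].values[colour] for c in subset}
            )
            post = posterior_age(
                sub_params, obs, prior, grid_step, invert_weights=invert_weights
            )
            s = summarize(post, threshold_years)
            rows.append(
                {
                    "teeth": label,
                    "classes": class_label,
                    "colour": colour,
                    "q25": s.q25,
                    "q75": s.q75,
                    "iqr": s.iqr,
                    "p_over_18": s.p_over_18,
                }
            )
    return pd.DataFrame(rows)
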