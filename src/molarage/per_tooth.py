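"""Per-tooth heteroscedastic linear model of the log tissue ratio on age.

The model for one tooth is

    y ~ Normal(mu(a, s), sigma^2 / w(a)),
    mu(a, s) = b0 + b1*a + b2*1[s=M] + b3*a*1[s=M],

where the sex structure fixes which of b2/b3 are free and the variance
weight w(a) is 1, 1/a, or a.  Weights follow the weighted-least-squares
convention (weight inversely proportional to the residual variance), so a
"1/age" weight means the variance *grows* linearly with age.  The opposite
reading is available through ``invert_weights`` for sensitivity analysis.

Coefficients are estimated by weighted least squares (statsmodels WLS,
which is the maximum-likelihood estimator for the betas under the model);
sigma uses the ML divide-by-n estimator so that the reported log-likelihood
and AIC are internally consistent.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
import yaml

from .cohort import Cohort, MolarClass, Sex, VALID_FDI_MOLARS

__all__ = [
    "SexStructure",
    "VarianceWeight",
    "ModelConfig",
    "PerToothFit",
    "ToothTissueModel",
    "IdentifiabilityError",
    "mean_response",
    "variance_at",
    "fit_per_tooth",
    "select_config",
    "default_configs",
    "read_configs",
    "write_configs",
]


class IdentifiabilityError(ValueError):
    """The requested model cannot be estimated from the data at hand."""


class SexStructure(enum.Enum):
    """How sex enters the mean: not at all, intercept, slope, or both."""

    COMMON = "COMMON"  # Age
    ADDITIVE = "ADDITIVE"  # Age + gender (sex as intercept offset)
    SLOPES_ONLY = "SLOPES_ONLY"  # Age:gender (sex-specific slopes, common intercept)
    FULL_INTERACTION = "FULL_INTERACTION"  # Age x gender

    @property
    def has_sex_intercept(self) -> bool:
        return self in (SexStructure.ADDITIVE, SexStructure.FULL_INTERACTION)

    @property
    def has_sex_slope(self) -> bool:
        return self in (SexStructure.SLOPES_ONLY, SexStructure.FULL_INTERACTION)

    @property
    def n_betas(self) -> int:
        return 2 + self.has_sex_intercept + self.has_sex_slope


class VarianceWeight(enum.Enum):
    """Observation weight w(age); residual variance is sigma^2 / w(age)."""

    CONSTANT = "CONSTANT"  # w = 1
    INV_AGE = "INV_AGE"  # w = 1/age  (variance grows with age)
    AGE = "AGE"  # w = age    (variance shrinks with age)

    def weight(self, age, invert_weights: bool = False):
        age = np.asarray(age, dtype=float)
        if np.any(age <= 0):
            raise ValueError("age must be > 0 for variance weighting")
        if self is VarianceWeight.CONSTANT:
            w = np.ones_like(age)
        elif self is VarianceWeight.INV_AGE:
            w = 1.0 / age
        else:
            w = age.copy()
        return 1.0 / w if invert_weights else w


# Fixed enumeration order used for AIC tie-breaking.
STRUCTURE_ORDER = (
    SexStructure.COMMON,
    SexStructure.ADDITIVE,
    SexStructure.SLOPES_ONLY,
    SexStructure.FULL_INTERACTION,
)
WEIGHT_ORDER = (VarianceWeight.CONSTANT, VarianceWeight.INV_AGE, VarianceWeight.AGE)


@dataclass(frozen=True)
class ModelConfig:
    """A tooth's regression structure: sex terms and variance weighting."""

    tooth: int
    sex_structure: SexStructure
    variance_weight: VarianceWeight

    def __post_init__(self) -> None:
        if self.tooth not in VALID_FDI_MOLARS:
            raise ValueError(f"invalid FDI molar code: {self.tooth}")

    @property
    def molar_class(self) -> MolarClass:
        return MolarClass.from_fdi(self.tooth)

    @property
    def k(self) -> int:
        """Free parameters counted by AIC: free betas plus one for sigma."""
        return self.sex_structure.n_betas + 1


@dataclass(frozen=True)
class PerToothFit:
    """Fitted per-tooth model: coefficients, residual scale, fit statistics.

    ``beta2``/``beta3`` are structurally zero when the sex structure omits
    them.  ``n``, ``loglik`` and ``aic`` are ``None`` for parameter sets
    loaded from a file rather than fitted to data.
    """

    config: ModelConfig
    beta0: float
    beta1: float
    beta2: float = 0.0
    beta3: float = 0.0
    sigma: float = 1.0
    n: int | None = None
    loglik: float | None = None
    aic: float | None = None

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        s = self.config.sex_structure
        if not s.has_sex_intercept and self.beta2 != 0.0:
            raise ValueError(f"beta2 must be 0 under {s.value}")
        if not s.has_sex_slope and self.beta3 != 0.0:
            raise ValueError(f"beta3 must be 0 under {s.value}")

    def mean(self, age, sex: Sex | str):
        return mean_response(self, age, sex)

    def variance(self, age, invert_weights: bool = False):
        return variance_at(self, age, invert_weights=invert_weights)

    @property
    def betas(self) -> tuple[float, float, float, float]:
        return (self.beta0, self.beta1, self.beta2, self.beta3)


def mean_response(fit: PerToothFit, age, sex: Sex | str):
    """Expected log tissue ratio mu(age, sex); vectorised over age."""
    age = np.asarray(age, dtype=float)
    male = 1.0 if Sex.parse(sex) is Sex.M else 0.0
    out = fit.beta0 + fit.beta1 * age + male * (fit.beta2 + fit.beta3 * age)
    return float(out) if out.ndim == 0 else out


def variance_at(fit: PerToothFit, age, invert_weights: bool = False):
    """Residual variance sigma^2 / w(age); vectorised over age."""
    w = fit.config.variance_weight.weight(age, invert_weights=invert_weights)
    out = fit.sigma**2 / w
    return float(out) if np.ndim(out) == 0 else out


def _design_matrix(age: np.ndarray, male: np.ndarray, structure: SexStructure) -> np.ndarray:
    cols = [np.ones_like(age), age]
    if structure.has_sex_intercept:
        cols.append(male)
    if structure.has_sex_slope:
        cols.append(age * male)
    return np.column_stack(cols)


def _unpack_betas(coef: np.ndarray, structure: SexStructure) -> tuple[float, float, float, float]:
    b0, b1 = float(coef[0]), float(coef[1])
    i = 2
    b2 = b3 = 0.0
    if structure.has_sex_intercept:
        b2 = float(coef[i])
        i += 1
    if structure.has_sex_slope:
        b3 = float(coef[i])
    return b0, b1, b2, b3


def gaussian_loglik(y, mu, sigma2, w) -> float:
    """Sum of Normal(mu, sigma2/w) log-densities; shared with the joint model."""
    y = np.asarray(y, dtype=float)
    var = sigma2 / w
    return float(
        -0.5 * np.sum(np.log(2.0 * np.pi * var)) - 0.5 * np.sum((y - mu) ** 2 / var)
    )


class ToothTissueModel:
    """Heteroscedastic linear model of one tooth's log tissue ratio on age.

    Parameters
    ----------
    cohort
        The cohort providing (age, sex, y) triples for ``config.tooth``.
    config
        Sex structure and variance weighting for this tooth.
    invert_weights
        Flip the variance-weight convention (sensitivity analysis).
    """

    def __init__(self, cohort: Cohort, config: ModelConfig, *, invert_weights: bool = False):
        self.config = config
        self.invert_weights = invert_weights
        age, male, y = cohort.tooth_arrays(config.tooth)
        self.age, self.male, self.y = age, male, y
        n = len(y)
        s = config.sex_structure
        if n < s.n_betas + 1:
            raise IdentifiabilityError(
                f"tooth {config.tooth}: {n} observations are too few for "
                f"{s.value} (need >= {s.n_betas + 1})"
            )
        if (s.has_sex_intercept or s.has_sex_slope) and len(np.unique(male)) < 2:
            terms = [t for t, on in (("sex intercept", s.has_sex_intercept),
                                     ("sex slope", s.has_sex_slope)) if on]
            raise IdentifiabilityError(
                f"tooth {config.tooth}: single sex present; {', '.join(terms)} "
                "term(s) are collinear with the intercept/age columns"
            )
        self.exog = _design_matrix(age, male, s)
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise IdentifiabilityError(
                f"tooth {config.tooth}: rank-deficient design under {s.value}"
            )

    def fit(self) -> PerToothFit:
        w = self.config.variance_weight.weight(self.age, invert_weights=self.invert_weights)
        res = sm.WLS(self.y, self.exog, weights=w).fit()
        b0, b1, b2, b3 = _unpack_betas(np.asarray(res.params), self.config.sex_structure)
        resid = self.y - self.exog @ np.asarray(res.params)
        n = len(self.y)
        sigma2 = float(np.sum(w * resid**2) / n)  # ML estimator
        sigma2 = max(sigma2, 1e-300)  # collinear data: sigma -> 0, loglik -> inf
        ll = gaussian_loglik(self.y, self.y - resid, sigma2, w)
        aic = 2 * self.config.k - 2 * ll
        return PerToothFit(
            config=self.config,
            beta0=b0, beta1=b1, beta2=b2, beta3=b3,
            sigma=math.sqrt(sigma2),
            n=n, loglik=ll, aic=aic,
        )


def fit_per_tooth(cohort: Cohort, config: ModelConfig, *, invert_weights: bool = False) -> PerToothFit:
    """Maximum-likelihood fit of one tooth's model (see :class:`ToothTissueModel`)."""
    return ToothTissueModel(cohort, config, invert_weights=invert_weights).fit()


def select_config(
    cohort: Cohort,
    tooth: int,
    structures: Sequence[SexStructure] = STRUCTURE_ORDER,
    weights: Sequence[VarianceWeight] = WEIGHT_ORDER,
    *,
    invert_weights: bool = False,
) -> ModelConfig:
    """Choose the (sex structure, variance weight) pair minimising AIC.

    Ties are broken in favour of fewer free parameters, then by the fixed
    enumeration order of the candidate lists.  Candidates that cannot be
    fitted (e.g. single-sex data under a sex structure) are skipped; if none
    can be fitted an :class:`IdentifiabilityError` is raised.
    """
    best: tuple[float, int, int, ModelConfig] | None = None
    rank = 0
    for s in structures:
        for wgt in weights:
            rank += 1
            cfg = ModelConfig(tooth, s, wgt)
            try:
                fit = fit_per_tooth(cohort, cfg, invert_weights=invert_weights)
            except IdentifiabilityError:
                continue
            assert fit.aic is not None
            key = (fit.aic, cfg.k, rank)
            if best is None or key < (best[0], best[1], best[2]):
                best = (fit.aic, cfg.k, rank, cfg)
    if best is None:
        raise IdentifiabilityError(f"tooth {tooth}: no candidate configuration is fittable")
    return best[3]


# ---------------------------------------------------------------------------
# Config (de)serialisation and the packaged per-tooth defaults.

def _config_to_dict(cfg: ModelConfig) -> dict:
    return {
        "sex_structure": cfg.sex_structure.value,
        "variance_weight": cfg.variance_weight.value,
    }


def write_configs(configs: Iterable[ModelConfig], path: str | Path) -> None:
    doc = {f"tooth_{c.tooth}": _config_to_dict(c) for c in configs}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def read_configs(path: str | Path) -> dict[int, ModelConfig]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    out: dict[int, ModelConfig] = {}
    for key, block in doc.items():
        if not key.startswith("tooth_"):
            raise ValueError(f"unexpected block {key!r} in config file")
        tooth = int(key.removeprefix("tooth_"))
        out[tooth] = ModelConfig(
            tooth,
            SexStructure(block["sex_structure"]),
            VarianceWeight(block["variance_weight"]),
        )
    return out


def default_configs() -> dict[int, ModelConfig]:
    """The packaged per-tooth model configurations (AIC-selected defaults)."""
    from importlib.resources import files

    path = files("molarage.data").joinpath("default_configs.yaml")
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    return {
        int(k.removeprefix("tooth_")): ModelConfig(
            int(k.removeprefix("tooth_")),
            SexStructure(v["sex_structure"]),
            VarianceWeight(v["variance_weight"]),
        )
        for k, v in doc.items()
    }
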