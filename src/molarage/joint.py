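"""Joint model of 1st/2nd/3rd-molar log tissue ratios with correlations.

One tooth per molar class is combined into a multivariate Gaussian: each
tooth keeps its own per-tooth mean and variance structure, and three
correlation parameters (1st-2nd, 1st-3rd, 2nd-3rd) couple the residuals.
Participants contribute whichever subset of the mapped teeth they possess;
for the Gaussian model, marginalising over the missing teeth is exact, so
the likelihood is a sum of marginal multivariate normal log-densities over
the observed subvectors.  All parameters (betas, sigmas, correlations) are
estimated jointly by maximum likelihood; sigmas are optimised on the log
scale and correlations through the inverse hyperbolic tangent (Fisher z)
transform, with non-positive-definite correlation proposals rejected by a
-inf log-likelihood so the optimiser can back off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
import yaml

from .cohort import CLASS_ORDER, Cohort, MolarClass, Sex
from .per_tooth import (
    IdentifiabilityError,
    ModelConfig,
    PerToothFit,
    SexStructure,
    ToothTissueModel,
    VarianceWeight,
    fit_per_tooth,
    mean_response,
    variance_at,
)

__all__ = [
    "CorrelationSet",
    "JointParameters",
    "JointResults",
    "MolarCombinationModel",
    "NotPositiveDefiniteError",
    "ConvergenceError",
    "mean_and_covariance",
    "joint_loglik",
    "fit_joint",
    "load_parameters",
    "write_parameters",
]

_PAIR_ATTR = {
    (MolarClass.FIRST, MolarClass.SECOND): "rho_12",
    (MolarClass.FIRST, MolarClass.THIRD): "rho_13",
    (MolarClass.SECOND, MolarClass.THIRD): "rho_23",
}


class NotPositiveDefiniteError(ValueError):
    """The proposed correlation triple does not form a valid 3x3 matrix."""


class ConvergenceError(RuntimeError):
    """The joint optimiser failed; carries the optimiser diagnostics."""


@dataclass(frozen=True)
class CorrelationSet:
    """Inter-molar-class correlations (1st-2nd, 1st-3rd, 2nd-3rd)."""

    rho_12: float = 0.0
    rho_13: float = 0.0
    rho_23: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rho_12", "rho_13", "rho_23"):
            v = getattr(self, name)
            if not (-1.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (-1, 1), got {v}")

    def rho(self, a: MolarClass, b: MolarClass) -> float:
        if a is b:
            return 1.0
        key = (a, b) if a < b else (b, a)
        return getattr(self, _PAIR_ATTR[key])

    def matrix(self, classes: Sequence[MolarClass] = CLASS_ORDER) -> np.ndarray:
        k = len(classes)
        R = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                R[i, j] = R[j, i] = self.rho(classes[i], classes[j])
        return R

    def is_positive_definite(self, classes: Sequence[MolarClass] = CLASS_ORDER) -> bool:
        try:
            np.linalg.cholesky(self.matrix(classes))
            return True
        except np.linalg.LinAlgError:
            return False

    def validate_positive_definite(self) -> None:
        if not self.is_positive_definite():
            raise NotPositiveDefiniteError(
                f"correlation triple ({self.rho_12}, {self.rho_13}, {self.rho_23}) "
                "is not positive definite"
            )


@dataclass
class JointParameters:
    """Full parameter set of a molar-combination model.

    ``tooth_by_class`` maps each included molar class to its FDI code (at
    most one tooth per class); ``fits`` holds the per-tooth coefficient
    sets, and ``correlations`` the inter-class correlation triple.
    ``loglik`` is the maximised joint log-likelihood when fitted, else None.
    """

    tooth_by_class: dict[MolarClass, int]
    fits: dict[MolarClass, PerToothFit]
    correlations: CorrelationSet = field(default_factory=CorrelationSet)
    loglik: float | None = None

    def __post_init__(self) -> None:
        if not self.tooth_by_class:
            raise ValueError("tooth_by_class must be nonempty")
        for cls, tooth in self.tooth_by_class.items():
            if MolarClass.from_fdi(tooth) is not cls:
                raise ValueError(f"tooth {tooth} is not a {cls.label} molar")
            fit = self.fits.get(cls)
            if fit is None:
                raise ValueError(f"missing per-tooth fit for {cls.label} molar")
            if fit.config.tooth != tooth:
                raise ValueError(
                    f"fit for {cls.label} molar is for tooth {fit.config.tooth}, "
                    f"expected {tooth}"
                )
        # Positive definiteness of the correlation triple is NOT enforced
        # here: optimisers propose invalid triples and joint_loglik must be
        # able to answer -inf.  File loading does validate (load_parameters).

    @property
    def classes(self) -> tuple[MolarClass, ...]:
        return tuple(c for c in CLASS_ORDER if c in self.tooth_by_class)

    @property
    def label(self) -> str:
        return "-".join(str(self.tooth_by_class[c]) for c in self.classes)

    def subset(self, classes: Sequence[MolarClass]) -> "JointParameters":
        """Restrict the model to a subset of its molar classes."""
        classes = tuple(classes)
        if not set(classes) <= set(self.classes):
            raise ValueError("requested classes are not all in the model")
        return JointParameters(
            {c: self.tooth_by_class[c] for c in classes},
            {c: self.fits[c] for c in classes},
            self.correlations,
        )


def _moments_on_grid(
    params: JointParameters,
    age: np.ndarray,
    sex: Sex | str,
    classes: Sequence[MolarClass],
    invert_weights: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mu, sd, R): per-age means and SDs (n x k) plus the fixed correlation."""
    mu = np.column_stack([mean_response(params.fits[c], age, sex) for c in classes])
    sd = np.column_stack(
        [np.sqrt(variance_at(params.fits[c], age, invert_weights=invert_weights))
         for c in classes]
    )
    R = params.correlations.matrix(classes)
    return mu, sd, R


def mean_and_covariance(
    params: JointParameters,
    age: float,
    sex: Sex | str,
    classes: Sequence[MolarClass] | None = None,
    *,
    invert_weights: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance matrix of the requested classes at one age.

    cov[t, u] = rho_tu * sqrt(Var_t(age) * Var_u(age)).
    """
    classes = tuple(classes) if classes is not None else params.classes
    if not classes:
        raise ValueError("classes must be nonempty")
    missing = [c for c in classes if c not in params.tooth_by_class]
    if missing:
        raise ValueError(f"classes not in model: {[c.label for c in missing]}")
    mu, sd, R = _moments_on_grid(
        params, np.asarray([age], dtype=float), sex, classes, invert_weights
    )
    cov = R * np.outer(sd[0], sd[0])
    return mu[0], cov


def _mvn_logpdf_rows(y: np.ndarray, mu: np.ndarray, sd: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Row-wise MVN log-density with common correlation, per-row means/SDs.

    ``y`` may be (n, k) or (k,) broadcast against (n, k) means.
    """
    k = R.shape[0]
    cho = scipy.linalg.cho_factor(R, lower=True)
    logdetR = 2.0 * np.sum(np.log(np.diag(cho[0])))
    z = (y - mu) / sd
    quad = np.einsum("ij,ij->i", z, scipy.linalg.cho_solve(cho, z.T).T)
    return (
        -0.5 * (k * math.log(2.0 * math.pi) + logdetR)
        - np.sum(np.log(sd), axis=1)
        - 0.5 * quad
    )


def _pattern_arrays(
    cohort: Cohort, tooth_by_class: Mapping[MolarClass, int]
) -> dict[tuple[MolarClass, ...], tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group participants by observed-teeth pattern into (age, male, y) arrays."""
    obs = cohort.observations_by_participant(tooth_by_class)
    rows: dict[tuple[MolarClass, ...], list[tuple[float, float, list[float]]]] = {}
    for part, y_by_class in obs:
        key = tuple(c for c in CLASS_ORDER if c in y_by_class)
        male = 1.0 if part.sex is Sex.M else 0.0
        rows.setdefault(key, []).append((part.age, male, [y_by_class[c] for c in key]))
    return {
        classes: (
            np.array([r[0] for r in rs]),
            np.array([r[1] for r in rs]),
            np.array([r[2] for r in rs]),
        )
        for classes, rs in rows.items()
    }


def _loglik_from_patterns(
    params: JointParameters,
    patterns: Mapping[tuple[MolarClass, ...], tuple[np.ndarray, np.ndarray, np.ndarray]],
    invert_weights: bool = False,
) -> float:
    if not params.correlations.is_positive_definite(params.classes):
        return -math.inf
    total = 0.0
    for classes, (age, male, y) in patterns.items():
        R = params.correlations.matrix(classes)
        mu = np.column_stack(
            [params.fits[c].beta0
             + params.fits[c].beta1 * age
             + male * (params.fits[c].beta2 + params.fits[c].beta3 * age)
             for c in classes]
        )
        sd = np.column_stack(
            [np.sqrt(variance_at(params.fits[c], age, invert_weights=invert_weights))
             for c in classes]
        )
        total += float(np.sum(_mvn_logpdf_rows(y, mu, sd, R)))
    return total


def joint_loglik(
    params: JointParameters, cohort: Cohort, *, invert_weights: bool = False
) -> float:
    """Joint log-likelihood of the cohort under the combination model.

    Each participant contributes the marginal multivariate normal
    log-density of the subset of mapped teeth they possess.  Correlation
    proposals whose matrix is not positive definite yield ``-inf`` (not an
    exception), so optimisers can recover.
    """
    patterns = _pattern_arrays(cohort, params.tooth_by_class)
    return _loglik_from_patterns(params, patterns, invert_weights)


# ---------------------------------------------------------------------------
# Parameter packing for the joint optimiser.

def _pack(params: JointParameters, n_rho: int) -> np.ndarray:
    x: list[float] = []
    for c in params.classes:
        fit = params.fits[c]
        s = fit.config.sex_structure
        x += [fit.beta0, fit.beta1]
        if s.has_sex_intercept:
            x.append(fit.beta2)
        if s.has_sex_slope:
            x.append(fit.beta3)
        x.append(math.log(fit.sigma))
    rhos = [params.correlations.rho_12, params.correlations.rho_13,
            params.correlations.rho_23]
    x += [math.atanh(r) for r in _active_rhos(params.classes, rhos)]
    assert len(x) == sum(params.fits[c].config.sex_structure.n_betas + 1
                         for c in params.classes) + n_rho
    return np.asarray(x)


def _active_pairs(classes: Sequence[MolarClass]) -> list[tuple[MolarClass, MolarClass]]:
    cs = [c for c in CLASS_ORDER if c in classes]
    return [(cs[i], cs[j]) for i in range(len(cs)) for j in range(i + 1, len(cs))]


def _active_rhos(classes: Sequence[MolarClass], rhos: list[float]) -> list[float]:
    by_pair = dict(zip(_PAIR_ATTR, rhos))
    return [by_pair[p] for p in _active_pairs(classes)]


def _unpack(
    x: np.ndarray, template: JointParameters
) -> JointParameters | None:
    """Rebuild JointParameters from the packed vector; None if rhos invalid."""
    i = 0
    fits: dict[MolarClass, PerToothFit] = {}
    for c in template.classes:
        cfg = template.fits[c].config
        s = cfg.sex_structure
        b0, b1 = x[i], x[i + 1]
        i += 2
        b2 = b3 = 0.0
        if s.has_sex_intercept:
            b2 = x[i]
            i += 1
        if s.has_sex_slope:
            b3 = x[i]
            i += 1
        sigma = math.exp(x[i])
        i += 1
        fits[c] = PerToothFit(cfg, float(b0), float(b1), float(b2), float(b3), sigma)
    rho_by_attr = {"rho_12": 0.0, "rho_13": 0.0, "rho_23": 0.0}
    for pair in _active_pairs(template.classes):
        rho_by_attr[_PAIR_ATTR[pair]] = math.tanh(x[i])
        i += 1
    corr = CorrelationSet(**rho_by_attr)
    if not corr.is_positive_definite(template.classes):
        return None
    return JointParameters(dict(template.tooth_by_class), fits, corr)


@dataclass
class JointResults:
    """Fitted molar-combination model: parameters plus fit diagnostics."""

    params: JointParameters
    converged: bool
    n_participants: int
    n_iterations: int
    message: str
    method: str

    @property
    def loglik(self) -> float:
        assert self.params.loglik is not None
        return self.params.loglik

    def save(self, path: str | Path) -> None:
        write_parameters(self.params, path)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Molar combination model {p.label}",
            f"  participants contributing: {self.n_participants}",
            f"  estimation: {self.method} ML, converged={self.converged}",
            f"  joint log-likelihood: {p.loglik:.4f}",
            "",
            f"  {'tooth':>5} {'structure':<17} {'weight':<9} "
            f"{'beta0':>9} {'beta1':>9} {'beta2':>9} {'beta3':>9} {'sigma':>8} {'AIC':>9}",
        ]
        for c in p.classes:
            f = p.fits[c]
            aic = f"{f.aic:9.2f}" if f.aic is not None else "        -"
            lines.append(
                f"  {f.config.tooth:>5} {f.config.sex_structure.value:<17} "
                f"{f.config.variance_weight.value:<9} "
                f"{f.beta0:9.4f} {f.beta1:9.4f} {f.beta2:9.4f} {f.beta3:9.4f} "
                f"{f.sigma:8.4f} {aic}"
            )
        r = p.correlations
        lines += [
            "",
            f"  correlations: 1st-2nd {r.rho_12:.3f}  1st-3rd {r.rho_13:.3f}  "
            f"2nd-3rd {r.rho_23:.3f}",
        ]
        return "\n".join(lines)


class MolarCombinationModel:
    """Joint model of up to three molars (one per class) for one cohort.

    ``fit(method="joint")`` maximises the full likelihood over all betas,
    sigmas and correlations, initialised at the independent per-tooth fits
    with zero correlations.  ``fit(method="two_stage")`` freezes the
    per-tooth fits and maximises over the correlations only.
    """

    def __init__(
        self,
        cohort: Cohort,
        tooth_by_class: Mapping[MolarClass, int],
        configs: Mapping[int, ModelConfig],
        *,
        invert_weights: bool = False,
    ):
        self.cohort = cohort
        self.tooth_by_class = {c: tooth_by_class[c] for c in CLASS_ORDER
                               if c in tooth_by_class}
        for cls, tooth in self.tooth_by_class.items():
            if MolarClass.from_fdi(tooth) is not cls:
                raise ValueError(f"tooth {tooth} is not a {cls.label} molar")
        self.configs = {t: configs[t] for t in self.tooth_by_class.values()}
        self.invert_weights = invert_weights
        obs = cohort.observations_by_participant(self.tooth_by_class)
        self._patterns = _pattern_arrays(cohort, self.tooth_by_class)
        self.n_participants = len(obs)
        if len(self.tooth_by_class) >= 2:
            n_multi = sum(len(y) >= 2 for _, y in obs)
            if n_multi == 0:
                raise IdentifiabilityError(
                    "no participant holds two or more of the mapped teeth: "
                    "correlations are unidentifiable"
                )

    def _independence_fit(self) -> JointParameters:
        fits = {
            c: fit_per_tooth(self.cohort, self.configs[t],
                             invert_weights=self.invert_weights)
            for c, t in self.tooth_by_class.items()
        }
        return JointParameters(dict(self.tooth_by_class), fits, CorrelationSet())

    def fit(self, method: str = "joint", tol: float = 1e-8) -> JointResults:
        if method not in ("joint", "two_stage"):
            raise ValueError("method must be 'joint' or 'two_stage'")
        start = self._independence_fit()
        n_rho = len(_active_pairs(start.classes))

        if method == "joint" or n_rho == 0:
            template = start
            x0 = _pack(start, n_rho)

            def objective(x: np.ndarray) -> float:
                p = _unpack(x, template)
                if p is None:
                    return 1e10
                ll = _loglik_from_patterns(p, self._patterns, self.invert_weights)
                return 1e10 if not math.isfinite(ll) else -ll

        else:  # two-stage: betas and sigmas frozen at the per-tooth fits
            template = start
            x_full = _pack(start, n_rho)
            x_fixed = x_full[:-n_rho]
            x0 = x_full[-n_rho:]

            def objective(z: np.ndarray) -> float:
                p = _unpack(np.concatenate([x_fixed, z]), template)
                if p is None:
                    return 1e10
                ll = _loglik_from_patterns(p, self._patterns, self.invert_weights)
                return 1e10 if not math.isfinite(ll) else -ll

        res = scipy.optimize.minimize(
            objective, x0, method="L-BFGS-B",
            options={"ftol": tol / max(1.0, abs(objective(x0))), "gtol": 1e-7,
                     "maxiter": 2000},
        )
        if not res.success:
            polish = scipy.optimize.minimize(
                objective, res.x, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": tol, "maxiter": 20000},
            )
            if polish.fun <= res.fun:
                res = polish
        if not res.success:
            raise ConvergenceError(
                f"joint ML optimisation failed for {'-'.join(map(str, self.tooth_by_class.values()))}: "
                f"{res.message} (fun={res.fun:.6g}, nit={res.nit})"
            )
        if method == "joint" or n_rho == 0:
            fitted = _unpack(res.x, template)
        else:
            fitted = _unpack(np.concatenate([x_fixed, res.x]), template)
        assert fitted is not None
        fitted.loglik = -float(res.fun)
        # re-attach n/loglik/aic bookkeeping per tooth (univariate, for reporting)
        for c in fitted.classes:
            start_fit = start.fits[c]
            fitted.fits[c] = replace(
                fitted.fits[c], n=start_fit.n, loglik=None, aic=start_fit.aic
            )
        return JointResults(
            params=fitted,
            converged=bool(res.success),
            n_participants=self.n_participants,
            n_iterations=int(res.nit),
            message=str(res.message),
            method=method,
        )


def fit_joint(
    cohort: Cohort,
    tooth_by_class: Mapping[MolarClass, int],
    configs: Mapping[int, ModelConfig],
    *,
    method: str = "joint",
    invert_weights: bool = False,
) -> JointResults:
    """Fit the molar-combination model by maximum likelihood."""
    model = MolarCombinationModel(
        cohort, tooth_by_class, configs, invert_weights=invert_weights
    )
    return model.fit(method=method)


# ---------------------------------------------------------------------------
# Parameter file (de)serialisation.

_CLASS_KEY = {MolarClass.FIRST: "first", MolarClass.SECOND: "second",
              MolarClass.THIRD: "third"}


def write_parameters(params: JointParameters, path: str | Path) -> None:
    doc: dict = {
        "combination": {_CLASS_KEY[c]: params.tooth_by_class[c] for c in params.classes}
    }
    for c in params.classes:
        f = params.fits[c]
        doc[f"tooth_{f.config.tooth}"] = {
            "sex_structure": f.config.sex_structure.value,
            "variance_weight": f.config.variance_weight.value,
            "beta0": float(f.beta0),
            "beta1": float(f.beta1),
            "beta2": float(f.beta2),
            "beta3": float(f.beta3),
            "sigma": float(f.sigma),
        }
    r = params.correlations
    doc["correlations"] = {
        "rho_12": float(r.rho_12), "rho_13": float(r.rho_13), "rho_23": float(r.rho_23)
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_parameters(path: str | Path) -> JointParameters:
    """Load a molar-combination parameter file; validates the correlations.

    The file lists the class->tooth combination, one coefficient block per
    tooth, and the correlation triple; ``loglik`` is left unset.
    """
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        combo = doc["combination"]
        tooth_by_class = {
            cls: int(combo[key]) for cls, key in _CLASS_KEY.items() if key in combo
        }
        fits: dict[MolarClass, PerToothFit] = {}
        for cls, tooth in tooth_by_class.items():
            block = doc[f"tooth_{tooth}"]
            cfg = ModelConfig(
                tooth,
                SexStructure(block["sex_structure"]),
                VarianceWeight(block["variance_weight"]),
            )
            fits[cls] = PerToothFit(
                cfg,
                beta0=float(block["beta0"]), beta1=float(block["beta1"]),
                beta2=float(block.get("beta2", 0.0)),
                beta3=float(block.get("beta3", 0.0)),
                sigma=float(block["sigma"]),
            )
        c = doc["correlations"]
        corr = CorrelationSet(float(c["rho_12"]), float(c["rho_13"]), float(c["rho_23"]))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"parameter file {path} is missing {exc}") from None
    corr.validate_positive_definite()
    return JointParameters(tooth_by_class, fits, corr)


def packaged_synthetic_parameters() -> JointParameters:
    """The packaged synthetic 46-47-18 parameter set (demo/test fixture).

    A synthetic stand-in with realistic magnitudes, not estimates from any
    real cohort; see the fixture file's header comment.
    """
    from importlib.resources import files, as_file

    resource = files("molarage.data").joinpath("params_46_47_18_synthetic.yaml")
    with as_file(resource) as p:
        return load_parameters(p)
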