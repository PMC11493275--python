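"""Allometric above-ground biomass models.

Reference biomass comes from species-group power laws on the composite
predictor DBH^2 * H (DBH in cm, H in m, W in kg).  Nine candidate model
forms predict W from tree height H and crown radius R alone:

========  ======================  ===========
code      form                    family
========  ======================  ===========
Eq1       W = a * H^b             power
Eq2       W = a * R^b             power
Eq3       W = a * (H + R^2)^b     power
Eq4       W = a * (H * R)^b       power
Eq5       W = a * e^(b * (H+R))   exponential
Eq6       W = a * (H+R) + b       linear
Eq7       W = a * ln(H+R) + b     logarithm
Eq8       W = a * (H+R)^b         power
Eq9       W = a*(H+R)^2 +         quadratic
              b*(H+R) + c
========  ======================  ===========

Linear-in-parameter families (Eq6, Eq7, Eq9) are solved in closed form;
the rest by nonlinear least squares on untransformed W, initialised from
an OLS fit in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MODEL_CODES",
    "ModelSpec",
    "FitResult",
    "Metrics",
    "REFERENCE_COEFFICIENTS",
    "species_group",
    "reference_agb",
    "predictor",
    "model_predict",
    "fit_model",
    "evaluate",
]

MODEL_CODES = tuple(f"Eq{i}" for i in range(1, 10))

_FAMILY = {
    "Eq1": "power", "Eq2": "power", "Eq3": "power", "Eq4": "power",
    "Eq5": "exponential", "Eq6": "linear", "Eq7": "logarithm",
    "Eq8": "power", "Eq9": "quadratic",
}

#: Reference allometry coefficients (alpha, beta) per species group for
#: W = alpha * (DBH^2 * H)^beta.
REFERENCE_COEFFICIENTS: Dict[str, Tuple[float, float]] = {
    "larch": (0.1179, 0.815),
    "broadleaf": (0.093, 0.869),
}

_SPECIES_GROUPS = {
    "larch": "larch",
    "ash": "broadleaf",
    "sophora": "broadleaf",
    "broadleaf": "broadleaf",
}


def species_group(species: str) -> str:
    """Map a species name to its reference-allometry group."""
    try:
        return _SPECIES_GROUPS[species.lower()]
    except KeyError:
        raise ValueError(f"unknown species {species!r}; expected one of "
                         f"{sorted(_SPECIES_GROUPS)}") from None


def reference_agb(species, dbh_cm, h_m):
    """Reference above-ground biomass W (kg) from DBH (cm) and H (m)."""
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    h_m = np.asarray(h_m, dtype=float)
    if np.any(dbh_cm <= 0) or np.any(h_m <= 0):
        raise ValueError("DBH and H must be > 0")
    alpha, beta = REFERENCE_COEFFICIENTS[species_group(species)]
    w = alpha * (dbh_cm ** 2 * h_m) ** beta
    if w.ndim == 0:
        return float(w)
    return w


def predictor(code: str, H, R):
    """Evaluate the model form's size predictor x(H, R)."""
    H = np.asarray(H, dtype=float)
    R = np.asarray(R, dtype=float)
    if code == "Eq1":
        return H
    if code == "Eq2":
        return R
    if code == "Eq3":
        return H + R ** 2
    if code == "Eq4":
        return H * R
    if code in ("Eq5", "Eq6", "Eq7", "Eq8", "Eq9"):
        return H + R
    raise ValueError(f"unknown model code {code!r}")


@dataclass
class ModelSpec:
    """One model form with fitted coefficients (a, b[, c])."""

    code: str
    coefficients: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.code not in MODEL_CODES:
            raise ValueError(f"unknown model code {self.code!r}")
        want = 3 if self.code == "Eq9" else 2
        if len(self.coefficients) != want:
            raise ValueError(
                f"{self.code} needs {want} coefficients, got "
                f"{len(self.coefficients)}")

    @property
    def family(self) -> str:
        return _FAMILY[self.code]


def model_predict(spec: ModelSpec, H, R):
    """Predict W (kg) for arrays of H (m) and R (m)."""
    x = predictor(spec.code, H, R)
    fam = spec.family
    if fam == "power":
        a, b = spec.coefficients
        if np.any(x <= 0):
            raise ValueError(f"{spec.code}: non-positive predictor for power form")
        return a * x ** b
    if fam == "exponential":
        a, b = spec.coefficients
        return a * np.exp(b * x)
    if fam == "linear":
        a, b = spec.coefficients
        return a * x + b
    if fam == "logarithm":
        a, b = spec.coefficients
        if np.any(x <= 0):
            raise ValueError(f"{spec.code}: non-positive predictor for log form")
        return a * np.log(x) + b
    if fam == "quadratic":
        a, b, c = spec.coefficients
        return a * x ** 2 + b * x + c
    raise AssertionError(fam)


@dataclass
class Metrics:
    """Goodness-of-fit metrics; NaN marks an undefined value."""

    r2: float
    rmse: float
    rrmse: float


@dataclass
class FitResult:
    """One fitted model with both training-fit and hold-out metrics."""

    spec: ModelSpec
    scenario_id: Optional[int] = None
    n_train: int = 0
    n_test: int = 0
    converged: bool = True
    split_seed: Optional[int] = None
    train_metrics: Optional[Metrics] = None
    test_metrics: Optional[Metrics] = None
    notes: str = ""

    @property
    def coefficients(self) -> Tuple[float, ...]:
        return self.spec.coefficients

    # Headline metrics refer to the held-out set.
    @property
    def r2(self) -> float:
        return self.test_metrics.r2 if self.test_metrics else math.nan

    @property
    def rmse(self) -> float:
        return self.test_metrics.rmse if self.test_metrics else math.nan

    @property
    def rrmse(self) -> float:
        return self.test_metrics.rrmse if self.test_metrics else math.nan


def evaluate(y_hat, y) -> Metrics:
    """R^2, RMSE (same units as y) and rRMSE (percent of mean y).

    R^2 = 1 - SS_res / SS_tot; RMSE = sqrt(mean squared residual);
    rRMSE = 100 * RMSE / mean(y).  Degenerate denominators yield NaN,
    except the all-residuals-zero flat case where R^2 is reported as 0.
    """
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.shape != y.shape:
        raise ValueError("prediction and reference lengths differ")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    resid = y - y_hat
    ss_res = float(np.sum(resid ** 2))
    y_bar = float(np.mean(y))
    ss_tot = float(np.sum((y - y_bar) ** 2))
    if ss_tot == 0.0:
        # Flat reference: define R^2 = 0 when the fit is flat too (up to
        # float round-off), undefined otherwise.
        tiny = 1e-20 * max(1.0, n * y_bar ** 2)
        r2 = 0.0 if ss_res <= tiny else math.nan
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = math.sqrt(ss_res / n)
    rrmse = math.nan if y_bar == 0 else 100.0 * rmse / y_bar
    return Metrics(r2=r2, rmse=rmse, rrmse=rrmse)


def _fit_linear_family(code: str, x: np.ndarray, w: np.ndarray):
    """Closed-form OLS for Eq6/Eq7/Eq9 on the transformed design."""
    if code == "Eq6":
        design = np.column_stack([x, np.ones_like(x)])
    elif code == "Eq7":
        if np.any(x <= 0):
            raise ValueError("Eq7: predictor must be > 0")
        design = np.column_stack([np.log(x), np.ones_like(x)])
    elif code == "Eq9":
        design = np.column_stack([x ** 2, x, np.ones_like(x)])
    else:  # pragma: no cover
        raise AssertionError(code)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError(f"{code}: singular design matrix")
    coef, *_ = np.linalg.lstsq(design, w, rcond=None)
    return tuple(float(c) for c in coef), True


def _loglog_init(x: np.ndarray, w: np.ndarray) -> Tuple[float, float]:
    """log-log OLS initial guess for a power law a * x^b."""
    ok = (x > 0) & (w > 0)
    if ok.sum() < 2:
        return float(np.mean(w)), 1.0
    slope, intercept = np.polyfit(np.log(x[ok]), np.log(w[ok]), 1)
    return float(np.exp(intercept)), float(slope)


def _loglinear_init(x: np.ndarray, w: np.ndarray) -> Tuple[float, float]:
    """log-linear OLS initial guess for a * exp(b * x)."""
    ok = w > 0
    if ok.sum() < 2:
        return float(np.mean(w)), 0.0
    slope, intercept = np.polyfit(x[ok], np.log(w[ok]), 1)
    return float(np.exp(intercept)), float(slope)


def fit_model(code: str, H, R, W, *, ftol: float = 1e-10,
              max_iter: int = 200) -> FitResult:
    """Least-squares fit of one model form on untransformed W.

    Returns a :class:`FitResult` whose ``spec`` holds the coefficients and
    whose ``converged`` flag reflects the optimiser's status (always True
    for the closed-form families).
    """
    H = np.asarray(H, dtype=float).ravel()
    R = np.asarray(R, dtype=float).ravel()
    W = np.asarray(W, dtype=float).ravel()
    if not (len(H) == len(R) == len(W)):
        raise ValueError("H, R, W must have equal length")
    n_coef = 3 if code == "Eq9" else 2
    if len(W) < n_coef + 1:
        raise ValueError(f"{code}: need at least {n_coef + 1} observations")
    if not np.all(np.isfinite(H) & np.isfinite(R) & np.isfinite(W)):
        raise ValueError("non-finite inputs")

    x = predictor(code, H, R)
    fam = _FAMILY[code]

    if fam in ("linear", "logarithm", "quadratic"):
        coef, converged = _fit_linear_family(code, x, W)
        return FitResult(spec=ModelSpec(code, coef), converged=converged)

    if fam == "power":
        if np.any(x <= 0):
            raise ValueError(f"{code}: predictor must be > 0 for power form")
        p0 = _loglog_init(x, W)
        residual = lambda p: p[0] * x ** p[1] - W
    else:  # exponential
        p0 = _loglinear_init(x, W)
        residual = lambda p: p[0] * np.exp(p[1] * x) - W

    res = least_squares(residual, p0, method="trf", ftol=ftol, xtol=ftol,
                        gtol=ftol, max_nfev=max_iter * 10)
    converged = bool(res.status > 0)
    coef = tuple(float(c) for c in res.x)
    return FitResult(spec=ModelSpec(code, coef), converged=converged)
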