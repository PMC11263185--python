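"""QSPR regression of physicochemical properties on topological indices.

Three single-descriptor model forms are supported, with property P and
topological index TI:

* linear:      P = A + B * TI
* quadratic:   P = A + B * TI + C * TI^2
* logarithmic: P = A + B * ln(TI)   (natural log)

Fitting is ordinary least squares (delegated to statsmodels).  Goodness of
fit is reported as the nonnegative multiple correlation r = sqrt(r^2), the
overall F statistic F = (r^2/k) / ((1 - r^2)/(n - k - 1)) with k predictors,
and its upper-tail p-value under F(k, n - k - 1).  r is nonnegative even
when the slope is negative, following the multiple-R convention of standard
statistics packages.

The module follows the statsmodels shape: :class:`QSPRModel` is built from
data and its :meth:`~QSPRModel.fit` returns a :class:`QSPRResults` carrying
estimates, uncertainties and a ``summary()`` table; the one-shot helpers
:func:`fit` and :func:`qspr_report` wrap it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datasets import ANOMALOUS_DENSITY_STRUCTURES
from .indices import TABLE_INDEX_NAMES

__all__ = [
    "MODEL_FORMS",
    "PROPERTY_NAMES",
    "RegressionResult",
    "QSPRModel",
    "QSPRResults",
    "fit",
    "qspr_report",
    "synthetic_qspr_data",
]

MODEL_FORMS = ("linear", "quadratic", "logarithmic")
PROPERTY_NAMES = ("density", "bp", "mp", "mw", "ws")

_FORM_ALIASES = {"log": "logarithmic", "quad": "quadratic", "lin": "linear"}


def _canon_form(form: str) -> str:
    form = _FORM_ALIASES.get(form.lower(), form.lower())
    if form not in MODEL_FORMS:
        raise ValueError(f"unknown model form {form!r}; valid: {MODEL_FORMS}")
    return form


@dataclass(frozen=True)
class RegressionResult:
    """One fitted property-index model with its fit statistics."""

    form: str
    property_name: str
    index_name: str
    A: float
    B: float
    C: float | None
    r: float
    r_squared: float
    F: float
    p: float
    n_obs: int

    def equation(self) -> str:
        """Human-readable model string, e.g. ``mw = 3.754 + 2.934*[M1]``."""
        ti = f"[{self.index_name}]"
        if self.form == "linear":
            rhs = f"{self.A:.3f} + {self.B:.3f}*{ti}"
        elif self.form == "quadratic":
            rhs = f"{self.A:.3f} + {self.B:.3f}*{ti} + {self.C:.3f}*{ti}^2"
        else:
            rhs = f"{self.A:.3f} + {self.B:.3f}*ln{ti}"
        return f"{self.property_name} = {rhs}"


class QSPRModel:
    """Single-descriptor regression model of a property on an index.

    Parameters
    ----------
    endog
        Property values (the dependent variable P).
    exog
        Topological-index values (the descriptor TI); must be positive for
        the logarithmic form.
    form
        One of ``linear``, ``quadratic``, ``logarithmic``.
    """

    def __init__(self, endog, exog, form: str = "linear",
                 property_name: str = "P", index_name: str = "TI"):
        self.form = _canon_form(form)
        y = np.asarray(endog, dtype=float)
        x = np.asarray(exog, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("endog and exog must be 1-d arrays of equal length")
        k = 2 if self.form == "quadratic" else 1
        if len(y) < k + 2:
            raise ValueError(
                f"need at least {k + 2} observations for the {self.form} form"
            )
        if self.form == "logarithmic" and np.any(x <= 0):
            raise ValueError("logarithmic form requires all index values > 0")
        if np.ptp(x) == 0:
            raise ValueError("degenerate fit: index values have zero variance")
        self.endog = y
        self.exog = x
        self.property_name = property_name
        self.index_name = index_name
        self.k_predictors = k

    def _design(self) -> np.ndarray:
        x = self.exog
        if self.form == "linear":
            cols = [x]
        elif self.form == "quadratic":
            cols = [x, x**2]
        else:
            cols = [np.log(x)]
        return sm.add_constant(np.column_stack(cols))

    def fit(self) -> "QSPRResults":
        res = sm.OLS(self.endog, self._design()).fit()
        return QSPRResults(self, res)


class QSPRResults:
    """Fit results: coefficients, multiple R, F test, and a summary table."""

    def __init__(self, model: QSPRModel, sm_results):
        self.model = model
        self._sm = sm_results
        self.params = np.asarray(sm_results.params)
        self.bse = np.asarray(sm_results.bse)
        self.nobs = int(sm_results.nobs)
        rsq = float(sm_results.rsquared)
        # clamp tiny negative values from numerically perfect/degenerate fits
        self.rsquared = min(max(rsq, 0.0), 1.0)
        self.r = math.sqrt(self.rsquared)
        k = model.k_predictors
        self.df_model = k
        self.df_resid = self.nobs - k - 1
        if self.rsquared >= 1.0:
            self.fvalue = math.inf
            self.f_pvalue = 0.0
        else:
            self.fvalue = (self.rsquared / k) / ((1 - self.rsquared) / self.df_resid)
            from scipy import stats

            self.f_pvalue = float(stats.f.sf(self.fvalue, k, self.df_resid))

    @property
    def A(self) -> float:
        return float(self.params[0])

    @property
    def B(self) -> float:
        return float(self.params[1])

    @property
    def C(self) -> float | None:
        return float(self.params[2]) if self.model.form == "quadratic" else None

    def as_record(self) -> RegressionResult:
        return RegressionResult(
            form=self.model.form,
            property_name=self.model.property_name,
            index_name=self.model.index_name,
            A=self.A, B=self.B, C=self.C,
            r=self.r, r_squared=self.rsquared,
            F=self.fvalue, p=self.f_pvalue, n_obs=self.nobs,
        )

    def summary(self) -> str:
        rec = self.as_record()
        names = ["A", "B"] + (["C"] if rec.C is not None else [])
        lines = [
            rec.equation(),
            f"form: {rec.form}   n = {rec.n_obs}",
            f"r = {rec.r:.3f}   r^2 = {rec.r_squared:.3f}   "
            f"F({self.df_model},{self.df_resid}) = {rec.F:.3f}   p = {rec.p:.4f}",
            "coefficients (estimate +/- std err):",
        ]
        for name, est, se in zip(names, self.params, self.bse):
            lines.append(f"  {name} = {est:.4f} +/- {se:.4f}")
        return "\n".join(lines)


def fit(form: str, x, y, property_name: str = "P",
        index_name: str = "TI") -> RegressionResult:
    """OLS fit of one model form; x is the index, y the property."""
    return QSPRModel(y, x, form=form, property_name=property_name,
                     index_name=index_name).fit().as_record()


def qspr_report(
    properties: pd.DataFrame,
    indices: pd.DataFrame,
    forms=MODEL_FORMS,
    property_names=PROPERTY_NAMES,
    index_names=TABLE_INDEX_NAMES,
    exclude_anomalous_density: bool = True,
) -> pd.DataFrame:
    """Batch regression report: one row per (property, index, form) triple.

    Tables align on their shared structure index (at least 3 structures).
    With the default flag, structures with a physically implausible printed
    density are dropped from density fits only.
    """
    common = properties.index.intersection(indices.index)
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} structures shared between tables; need >= 3"
        )
    missing = [p for p in property_names if p not in properties.columns]
    if missing:
        raise ValueError(f"property table lacks column(s): {missing}")
    rows = []
    for prop in property_names:
        keep = common
        if prop == "density" and exclude_anomalous_density:
            keep = common.difference(ANOMALOUS_DENSITY_STRUCTURES)
        y = properties.loc[keep, prop]
        for idx in index_names:
            x = indices.loc[keep, idx]
            for form in forms:
                rec = fit(form, x.to_numpy(), y.to_numpy(),
                          property_name=prop, index_name=idx)
                rows.append({
                    "property": prop, "index": idx, "form": rec.form,
                    "A": rec.A, "B": rec.B, "C": rec.C,
                    "r": rec.r, "r2": rec.r_squared,
                    "F": rec.F, "p": rec.p, "n": rec.n_obs,
                })
    return pd.DataFrame(rows)


def synthetic_qspr_data(
    n: int,
    form: str,
    coefficients,
    noise_sd: float,
    seed: int,
    x_range: tuple[float, float] = (1.0, 50.0),
):
    """Seeded synthetic (x, y) pairs following one model form plus noise.

    ``coefficients`` is (A, B) for linear/logarithmic or (A, B, C) for
    quadratic; x is uniform over the positive ``x_range`` and the noise is
    independent Gaussian with scale ``noise_sd``.
    """
    form = _canon_form(form)
    if n < 5:
        raise ValueError("need n >= 5")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if x_range[0] <= 0:
        raise ValueError("x_range must be positive (log form must be fittable)")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], size=n)
    if form == "linear":
        a, b = coefficients
        mean = a + b * x
    elif form == "quadratic":
        a, b, c = coefficients
        mean = a + b * x + c * x**2
    else:
        a, b = coefficients
        mean = a + b * np.log(x)
    y = mean + rng.normal(0.0, noise_sd, size=n)
    return x, y
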