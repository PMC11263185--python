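"""QSPR regression: model forms, fit statistics, and coefficient recovery."""
import math

import numpy as np
import pytest
from scipy import stats

from mpolyindex import (
    QSPRModel,
    fit,
    qspr_report,
    recomputed_indices,
    synthetic_qspr_data,
)


def test_noiseless_fits_are_exact():
    cases = [
        ("linear", (2.0, 3.0)),
        ("quadratic", (1.0, -2.0, 0.5)),
        ("logarithmic", (4.0, 7.0)),
    ]
    for form, coeffs in cases:
        x, y = synthetic_qspr_data(40, form, coeffs, noise_sd=0.0, seed=3)
        rec = fit(form, x, y)
        got = (rec.A, rec.B) + ((rec.C,) if rec.C is not None else ())
        assert np.allclose(got, coeffs, atol=1e-8)
        assert rec.r == 1.0 and rec.p == 0.0 and math.isinf(rec.F)


def test_linear_r_equals_abs_pearson():
    for seed, slope in [(1, 3.0), (2, -3.0)]:
        x, y = synthetic_qspr_data(30, "linear", (1.0, slope), noise_sd=5.0, seed=seed)
        rec = fit("linear", x, y)
        assert abs(rec.r - abs(stats.pearsonr(x, y)[0])) < 1e-12
        assert rec.r >= 0  # multiple-R convention even for negative slope


def test_f_and_p_consistent():
    x, y = synthetic_qspr_data(25, "quadratic", (1.0, 2.0, -0.1), noise_sd=8.0, seed=5)
    rec = fit("quadratic", x, y)
    k, dfr = 2, rec.n_obs - 3
    assert abs(rec.F - (rec.r_squared / k) / ((1 - rec.r_squared) / dfr)) < 1e-9
    assert abs(rec.p - stats.f.sf(rec.F, k, dfr)) < 1e-10


def test_quadratic_nests_linear_and_recovers_zero_curvature():
    x, y = synthetic_qspr_data(200, "linear", (2.0, 3.0), noise_sd=1.0, seed=11)
    lin = fit("linear", x, y)
    model = QSPRModel(y, x, form="quadratic")
    quad = model.fit()
    assert quad.rsquared >= lin.r_squared
    # true C = 0: estimate within 3 standard errors
    assert abs(quad.C) <= 3 * quad.bse[2]


def test_domain_and_degeneracy_errors():
    with pytest.raises(ValueError, match="> 0"):
        fit("logarithmic", np.array([-1.0, 1, 2, 3, 4]), np.arange(5.0))
    with pytest.raises(ValueError, match="zero variance"):
        fit("linear", np.ones(6), np.arange(6.0))
    with pytest.raises(ValueError, match="at least"):
        fit("quadratic", np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
    with pytest.raises(ValueError, match="unknown model form"):
        fit("cubic", np.arange(5.0) + 1, np.arange(5.0))


def test_synthetic_data_deterministic():
    a = synthetic_qspr_data(20, "linear", (0.0, 1.0), noise_sd=1.0, seed=9)
    b = synthetic_qspr_data(20, "linear", (0.0, 1.0), noise_sd=1.0, seed=9)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_report_cardinality_and_columns(properties, published):
    report = qspr_report(properties, published)
    assert len(report) == 5 * 7 * 3
    assert list(report.columns) == [
        "property", "index", "form", "A", "B", "C", "r", "r2", "F", "p", "n",
    ]
    # density fits drop the anomalous raffinose record by default
    assert set(report.loc[report.property == "density", "n"]) == {7}
    assert set(report.loc[report.property == "mw", "n"]) == {8}


def test_report_with_anomalous_density_kept(properties, published):
    report = qspr_report(properties, published, exclude_anomalous_density=False)
    assert set(report["n"]) == {8}


def test_report_alignment_error(properties, published):
    with pytest.raises(ValueError, match="structures"):
        qspr_report(properties.iloc[:2], published.iloc[-2:])


def test_report_runs_on_recomputed_indices(properties):
    report = qspr_report(properties, recomputed_indices(), forms=("linear",))
    assert len(report) == 35
    row = report[(report.property == "mw") & (report["index"] == "M1")].iloc[0]
    assert row.r > 0.99  # MW tracks size-dependent indices tightly


def test_summary_mentions_fit_statistics():
    x, y = synthetic_qspr_data(30, "linear", (2.0, 3.0), noise_sd=1.0, seed=2)
    text = QSPRModel(y, x, form="linear", property_name="mw",
                     index_name="M1").fit().summary()
    assert "mw" in text and "r =" in text and "F(1,28)" in text


def test_coefficient_recovery_unbiased():
    """Mean estimate over seeded replicates stays within Monte-Carlo error."""
    truth = {"linear": (2.0, 3.0), "logarithmic": (4.0, 7.0),
             "quadratic": (1.0, -2.0, 0.5)}
    n_rep, n_obs, sd = 200, 40, 2.0
    for form, coeffs in truth.items():
        estimates = []
        for rep in range(n_rep):
            x, y = synthetic_qspr_data(n_obs, form, coeffs, noise_sd=sd, seed=10_000 + rep)
            rec = fit(form, x, y)
            estimates.append((rec.A, rec.B) + ((rec.C,) if rec.C is not None else ()))
        est = np.array(estimates)
        mean, sem = est.mean(axis=0), est.std(axis=0, ddof=1) / math.sqrt(n_rep)
        assert np.all(np.abs(mean - np.array(coeffs)) < 4 * sem + 1e-12)
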