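"""Mixed-model association: filters, fits, likelihood-ratio machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from tedosage.assoc import (
    GlmmSpec,
    ModelFit,
    association_scan,
    fit_logistic_glmm,
    heritability_comparison,
    lrt,
    strain_filter,
)
from tedosage.synthetic_data import PhenotypeSimConfig, simulate_phenotypes


def _records(spec):
    """spec: list of (strain, block, n_females, n_atrophied)."""
    rows = []
    for strain, block, n, k in spec:
        rows += [(strain, block, 1)] * k + [(strain, block, 0)] * (n - k)
    return pd.DataFrame(rows, columns=["strain", "block", "atrophied"])


# ----------------------------------------------------------------------
# strain filter
# ----------------------------------------------------------------------

def test_strain_filter_per_block_rule():
    rec = _records(
        [
            ("one_block", "B1", 25, 5),          # excluded: single block
            ("boundary", "B1", 20, 5), ("boundary", "B2", 20, 5),   # retained
            ("uneven", "B1", 19, 5), ("uneven", "B2", 30, 5),       # excluded per-block
        ]
    )
    retained, filtered = strain_filter(rec)
    assert retained == {"boundary"}
    assert set(filtered["strain"]) == {"boundary"}


def test_strain_filter_pooled_rule():
    rec = _records([("uneven", "B1", 19, 5), ("uneven", "B2", 30, 5)])
    retained, _ = strain_filter(rec, per_block=False)
    assert retained == {"uneven"}


# ----------------------------------------------------------------------
# GLMM fitting
# ----------------------------------------------------------------------

def test_intercept_only_closed_form():
    rec = _records([("a", "B1", 100, 50)])
    fit = fit_logistic_glmm(rec, GlmmSpec((), ()))
    assert fit.coefficients["(Intercept)"] == pytest.approx(0.0, abs=1e-8)
    assert fit.log_likelihood == pytest.approx(100 * np.log(0.5))
    assert fit.n_params == 1
    assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2)


def test_no_random_factor_matches_glm_oracle():
    """With no random factors the fit is plain logistic regression;
    statsmodels GLM is the independent oracle."""
    sm = pytest.importorskip("statsmodels.api")
    dos = {f"s{i}": (float(i), 0.0) for i in range(10)}
    cfg = PhenotypeSimConfig(beta0=-1.0, beta_P=0.2, beta_H=0.0, sigma_block=0.0,
                             sigma_strain=0.0, n_blocks=2, blocks_per_strain=2,
                             females_per_strain_block=40, seed=41)
    rec, _ = simulate_phenotypes(cfg, dos)
    cov = pd.DataFrame({"cn": {s: d[0] for s, d in dos.items()}})
    fit = fit_logistic_glmm(rec, GlmmSpec(("cn",), ()), cov)
    X = np.column_stack([np.ones(len(rec)), rec["strain"].map(cov["cn"])])
    oracle = sm.GLM(rec["atrophied"], X, family=sm.families.Binomial()).fit()
    assert fit.log_likelihood == pytest.approx(oracle.llf, abs=1e-4)
    assert fit.coefficients["cn"] == pytest.approx(oracle.params.iloc[1], abs=1e-5)


def test_glmm_recovers_generative_slope():
    dos = {f"s{i:02d}": (float(i % 21), 0.0) for i in range(40)}
    cfg = PhenotypeSimConfig(beta0=-2.0, beta_P=0.3, beta_H=0.0, sigma_block=0.5,
                             sigma_strain=0.0, n_blocks=6, blocks_per_strain=2,
                             females_per_strain_block=50, seed=42)
    rec, _ = simulate_phenotypes(cfg, dos)
    cov = pd.DataFrame({"cn": {s: d[0] for s, d in dos.items()}})
    fit = fit_logistic_glmm(rec, GlmmSpec(("cn",), ("block",)), cov)
    assert fit.converged
    se = fit.standard_errors["cn"]
    assert abs(fit.coefficients["cn"] - 0.3) <= 3 * se
    assert fit.variance_components["block"] >= 0.0


def test_fitted_ll_matches_quadrature_oracle():
    """Reported marginal log-likelihood agrees with an independent
    fixed-grid Gauss-Hermite evaluation within 1e-3 (small design)."""
    dos = {f"s{i}": (float(i), 0.0) for i in range(8)}
    cfg = PhenotypeSimConfig(beta0=-0.5, beta_P=0.1, beta_H=0.0, sigma_block=0.5,
                             sigma_strain=0.0, n_blocks=4, blocks_per_strain=2,
                             females_per_strain_block=25, seed=43)
    rec, _ = simulate_phenotypes(cfg, dos)
    cov = pd.DataFrame({"cn": {s: d[0] for s, d in dos.items()}})
    fit = fit_logistic_glmm(rec, GlmmSpec(("cn",), ("block",)), cov)

    y = rec["atrophied"].to_numpy(float)
    X = np.column_stack([np.ones(len(rec)), rec["strain"].map(cov["cn"])])
    codes = pd.Categorical(rec["block"]).codes
    beta = np.array([fit.coefficients["(Intercept)"], fit.coefficients["cn"]])
    sigma = fit.variance_components["block"] ** 0.5
    t, w = np.polynomial.hermite.hermgauss(201)
    eta0 = X @ beta
    oracle = 0.0
    for g in np.unique(codes):
        m = codes == g
        e = eta0[m][:, None] + (np.sqrt(2.0) * sigma * t)[None, :]
        lp = (y[m][:, None] * e - np.logaddexp(0.0, e)).sum(axis=0)
        oracle += np.log((w / np.sqrt(np.pi)) @ np.exp(lp - lp.max())) + lp.max()
    assert abs(fit.log_likelihood - oracle) < 1e-3


def test_two_random_factors_fit():
    dos = {f"s{i:02d}": (float(i), 0.0) for i in range(12)}
    cfg = PhenotypeSimConfig(beta0=-1.0, beta_P=0.1, beta_H=0.0, sigma_block=0.5,
                             sigma_strain=0.8, n_blocks=4, blocks_per_strain=2,
                             females_per_strain_block=30, seed=44)
    rec, _ = simulate_phenotypes(cfg, dos)
    cov = pd.DataFrame({"cn": {s: d[0] for s, d in dos.items()}})
    fit = fit_logistic_glmm(rec, GlmmSpec(("cn",), ("block", "strain")), cov)
    assert fit.converged
    assert set(fit.variance_components) == {"block", "strain"}
    assert fit.n_params == 2 + 2


def test_rank_deficient_design_names_columns():
    dos = {f"s{i}": (float(i), 0.0) for i in range(6)}
    cfg = PhenotypeSimConfig(n_blocks=2, blocks_per_strain=2,
                             females_per_strain_block=10, seed=45)
    rec, _ = simulate_phenotypes(cfg, dos)
    cov = pd.DataFrame(
        {"cn": {s: d[0] for s, d in dos.items()}, "cn2": {s: 2 * d[0] for s, d in dos.items()}}
    )
    with pytest.raises(ValueError, match="cn"):
        fit_logistic_glmm(rec, GlmmSpec(("cn", "cn2"), ()), cov)


def test_complete_separation_is_flagged_not_silent():
    rec = _records([("a", "B1", 40, 40), ("b", "B1", 40, 0)])
    cov = pd.DataFrame({"x": {"a": 1.0, "b": 0.0}})
    fit = fit_logistic_glmm(rec, GlmmSpec(("x",), ()), cov)
    assert not fit.converged
    assert "separation" in fit.diagnostics


def test_spec_validation():
    with pytest.raises(ValueError):
        GlmmSpec((), ("block", "strain"), strain_fixed=True)
    with pytest.raises(ValueError):
        GlmmSpec((), ("plate",))


# ----------------------------------------------------------------------
# likelihood-ratio tests
# ----------------------------------------------------------------------

def _fake_fit(ll, n_params, fixed=("(Intercept)",), coefs=None):
    coefs = coefs or {name: 0.0 for name in fixed}
    return ModelFit(
        log_likelihood=ll, aic=-2 * ll + 2 * n_params, n_params=n_params,
        coefficients=coefs, standard_errors={k: 1.0 for k in coefs},
        variance_components={}, converged=True, n_obs=100,
        fixed_terms=tuple(fixed), random_terms=(),
    )


def test_lrt_identical_fits():
    null = _fake_fit(-100.0, 2)
    alt = _fake_fit(-100.0, 4, fixed=("(Intercept)", "x"), coefs={"(Intercept)": 0.0, "x": 0.0})
    res = lrt(null, alt)
    assert res.chi2 == 0.0
    assert res.p == pytest.approx(1.0)
    assert res.delta_aic == pytest.approx(2 * 2)


def test_lrt_p_value_matches_numerical_integration():
    """chi2 = 3.84 at 1 df gives p ~ 0.0500; the oracle integrates the
    chi-square density numerically."""
    null = _fake_fit(-100.0, 1)
    alt = _fake_fit(-100.0 + 3.84 / 2, 2, fixed=("(Intercept)", "x"), coefs={"(Intercept)": 0, "x": 1.0})
    res = lrt(null, alt)
    density = lambda x: np.exp(-x / 2) / np.sqrt(2 * np.pi * x)
    oracle, _ = quad(density, 3.84, np.inf)
    assert res.p == pytest.approx(oracle, abs=1e-6)
    assert res.p == pytest.approx(0.0500, abs=5e-4)
    assert res.association_sign == "+"


def test_lrt_heritability_scale_identity():
    """A 32-parameter difference with chi2 = 484.18 implies
    delta_aic = -(484.18 - 64) = -420.18."""
    null = _fake_fit(-1000.0, 2)
    alt = _fake_fit(
        -1000.0 + 484.18 / 2, 34,
        fixed=("(Intercept)",) + tuple(f"strain[s{i}]" for i in range(32)),
    )
    res = lrt(null, alt)
    assert res.chi2 == pytest.approx(484.18)
    assert res.df == 32
    assert res.delta_aic == pytest.approx(-420.18)


def test_lrt_rejects_non_nested():
    a = _fake_fit(-10.0, 2, fixed=("(Intercept)", "x"))
    b = _fake_fit(-9.0, 2, fixed=("(Intercept)", "y"))
    with pytest.raises(ValueError, match="nested"):
        lrt(a, b)


def test_heritability_comparison_df_and_identity():
    dos = {f"s{i:02d}": (0.0, 0.0) for i in range(10)}
    cfg = PhenotypeSimConfig(beta0=-1.0, beta_P=0.0, beta_H=0.0, sigma_block=0.3,
                             sigma_strain=1.0, n_blocks=4, blocks_per_strain=2,
                             females_per_strain_block=25, seed=46)
    rec, _ = simulate_phenotypes(cfg, dos)
    null_fit, alt_fit, res = heritability_comparison(rec)
    assert res.df == 9  # S-1 strain coefficients
    assert res.delta_aic == pytest.approx(-(res.chi2 - 2 * res.df), abs=1e-9)
    assert res.chi2 > 0


# ----------------------------------------------------------------------
# association scan
# ----------------------------------------------------------------------

def _sim_scan_data(seed=47):
    dos = {f"s{i:02d}": (float(i), float((i * 7) % 11)) for i in range(24)}
    cfg = PhenotypeSimConfig(beta0=-2.5, beta_P=0.25, beta_H=0.0, sigma_block=0.4,
                             sigma_strain=0.0, n_blocks=6, blocks_per_strain=2,
                             females_per_strain_block=30, seed=seed)
    rec, _ = simulate_phenotypes(cfg, dos)
    cov = pd.DataFrame(
        {"cn_p": {s: d[0] for s, d in dos.items()}, "cn_h": {s: d[1] for s, d in dos.items()}}
    )
    return rec, cov


def test_scan_detects_true_positive_and_not_null_covariate():
    rec, cov = _sim_scan_data()
    ledger = association_scan(rec, cov, ["cn_p", "cn_h"])
    row_p = ledger[ledger["estimator"] == "cn_p"].iloc[0]
    row_h = ledger[ledger["estimator"] == "cn_h"].iloc[0]
    assert row_p["p"] < 1e-6 and row_p["sign"] == "+"
    assert row_h["p"] > 0.05  # no generative hobo effect at this seed
    assert row_p["converged"]


def test_scan_empty_focal_list_and_constant_estimator():
    rec, cov = _sim_scan_data()
    assert association_scan(rec, cov, []).empty
    cov2 = cov.assign(flat=1.0)
    ledger = association_scan(rec, cov2, ["flat"])
    assert "constant" in ledger.iloc[0]["note"]
    assert np.isnan(ledger.iloc[0]["p"])


def test_scan_warns_on_absent_exclusion_strain():
    rec, cov = _sim_scan_data()
    with pytest.warns(UserWarning, match="absent"):
        association_scan(rec, cov, ["cn_p"], exclude_strains=("nope",))


def test_outlier_exclusion_restores_positive_association():
    """One low-dosage strain with 100% atrophy flips a positive dosage
    association to negative; excluding it restores the significant
    positive association."""
    rows = []
    for i, cn in enumerate(range(2, 26, 2)):
        prop = 0.05 + 0.01 * cn
        for block in ("B1", "B2"):
            k = round(40 * prop) // 2
            rows += [(f"S{i:02d}", block, 1)] * k + [(f"S{i:02d}", block, 0)] * (20 - k)
    for block in ("B1", "B2"):
        rows += [("OUT", block, 1)] * 20
    rec = pd.DataFrame(rows, columns=["strain", "block", "atrophied"])
    cov = pd.DataFrame(
        {"cn_p": {**{f"S{i:02d}": float(cn) for i, cn in enumerate(range(2, 26, 2))}, "OUT": 0.0}}
    )
    full = association_scan(rec, cov, ["cn_p"]).iloc[0]
    excl = association_scan(rec, cov, ["cn_p"], exclude_strains=("OUT",)).iloc[0]
    assert full["sign"] == "-" or full["p"] >= 0.05
    assert excl["sign"] == "+" and excl["p"] < 0.05
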