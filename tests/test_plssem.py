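"""PLS path modeling: closed-form diagnostics, recovery, resampling."""

import numpy as np
import pandas as pd
import pytest

from scdnet.plssem import (
    ModelSpec,
    average_variance_extracted,
    bootstrap_path_significance,
    composite_reliability,
    compute_composite_scores,
    cross_loading_matrix,
    fit_pls_path_model,
    permutation_multigroup_test,
)
from scdnet.synthetic_data import (
    CohortSpec,
    ConstructSpec,
    generate_questionnaire_cohort,
)


def two_construct_spec(beta, n, seed, lam=0.85, p=8, target="Y"):
    return CohortSpec(
        n_subjects_per_group={"G": n},
        constructs=(
            ConstructSpec("X", tuple(f"x{i}" for i in range(p)), (lam,) * p),
            ConstructSpec("Y", tuple(f"y{i}" for i in range(p)), (lam,) * p),
        ),
        target=target,
        paths={"G": {"X": beta}},
        seed=seed,
    )


def two_construct_model(p=8):
    imap = {f"x{i}": "X" for i in range(p)} | {f"y{i}": "Y" for i in range(p)}
    return ModelSpec(constructs=["X", "Y"], indicator_map=imap, inner_paths=[("X", "Y")])


# ----------------------------------------------------------------------
# model specification


def test_model_spec_rejects_cycles_and_orphans():
    with pytest.raises(ValueError, match="acyclic"):
        ModelSpec(["A", "B"], {"a": "A", "b": "B"}, [("A", "B"), ("B", "A")])
    with pytest.raises(ValueError, match="without indicators"):
        ModelSpec(["A", "B"], {"a": "A"}, [("A", "B")])
    with pytest.raises(ValueError, match="tol"):
        ModelSpec(["A", "B"], {"a": "A", "b": "B"}, [("A", "B")], tol=0)


# ----------------------------------------------------------------------
# closed-form diagnostics (hand-evaluated expectations)


@pytest.mark.parametrize(
    "loadings,expected",
    [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.8, 0.8, 0.8), 5.76 / 6.84),  # (2.4)^2 / ((2.4)^2 + 3*0.36)
        ((0.6, 0.7, 0.8), 4.41 / 5.92),
    ],
)
def test_composite_reliability_closed_form(loadings, expected):
    assert composite_reliability(loadings) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "loadings,expected",
    [
        ((1.0, 1.0), 1.0),
        # reported memory-complaints outer loadings -> 0.766, prints as 0.77
        ((0.88, 0.81, 0.74, 0.74, 0.93, 0.91, 0.93, 0.94, 0.93, 0.91), 0.76602),
        # reported neuropsychological-test loadings -> 0.556, prints as 0.56
        ((0.85, 0.75, 0.62), 0.5564666666666667),
    ],
)
def test_average_variance_extracted_closed_form(loadings, expected):
    assert average_variance_extracted(loadings) == pytest.approx(expected, abs=1e-9)


def test_diagnostics_reject_empty_and_out_of_range():
    for fn in (composite_reliability, average_variance_extracted):
        with pytest.raises(ValueError):
            fn([])
        with pytest.raises(ValueError):
            fn([1.2])


def test_fit_diagnostics_match_closed_forms_exactly():
    """rho_c and AVE stored on a fit equal the closed forms on its loadings."""
    cohort = generate_questionnaire_cohort(two_construct_spec(0.4, 300, seed=7))
    fit = fit_pls_path_model(cohort.indicators, two_construct_model())
    for c in fit.model.constructs:
        lam = fit.loadings[[i for i, cc in fit.model.indicator_map.items() if cc == c]]
        assert fit.rho_c[c] == composite_reliability(lam)
        assert fit.ave[c] == average_variance_extracted(lam)
        assert 0.0 <= fit.ave[c] <= 1.0
        assert 0.0 <= fit.rho_c[c] <= 1.0


# ----------------------------------------------------------------------
# fitting


def test_single_indicator_beta_equals_pearson_r():
    """With one indicator per construct, the path is the plain correlation."""
    rng = np.random.default_rng(3)
    x = rng.standard_normal(500)
    y = 0.6 * x + 0.8 * rng.standard_normal(500)
    data = pd.DataFrame({"x": x, "y": y})
    model = ModelSpec(["X", "Y"], {"x": "X", "y": "Y"}, [("X", "Y")])
    fit = fit_pls_path_model(data, model)
    r = np.corrcoef(x, y)[0, 1]
    assert fit.path_coefficients[("X", "Y")] == pytest.approx(r, abs=1e-10)
    assert fit.r_squared["Y"] == pytest.approx(r**2, abs=1e-10)


def test_noiseless_identity_recovers_planted_paths():
    """lambda = 1 indicators equal their latents; beta recovered exactly."""
    spec = CohortSpec(
        n_subjects_per_group={"G": 400},
        constructs=(
            ConstructSpec("X", ("x1", "x2"), (1.0, 1.0)),
            ConstructSpec("Y", ("y1", "y2"), (1.0, 1.0)),
        ),
        target="Y",
        paths={"G": {"X": -0.38}},
        seed=11,
    )
    cohort = generate_questionnaire_cohort(spec)
    # indicators are exact copies of the latents
    lat = cohort.latents
    assert np.allclose(cohort.indicators["x1"], lat["X"])
    model = ModelSpec(
        ["X", "Y"],
        {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"},
        [("X", "Y")],
    )
    fit = fit_pls_path_model(cohort.indicators, model)
    r = np.corrcoef(lat["X"], lat["Y"])[0, 1]
    assert fit.path_coefficients[("X", "Y")] == pytest.approx(r, abs=1e-6)


@pytest.mark.parametrize("beta", [0.0, 0.33, -0.38, 0.4])
def test_planted_path_recovery_large_n(beta):
    """Mean estimate over 5 cohorts of n=2000 recovers the planted path.

    Averaging removes the per-sample chance-capitalization noise of PLS
    weights (~0.04 at this size) and leaves the small attenuation bias.
    """
    est = []
    for seed in range(5):
        cohort = generate_questionnaire_cohort(
            two_construct_spec(beta, 2000, seed=29 + seed)
        )
        fit = fit_pls_path_model(cohort.indicators, two_construct_model())
        assert fit.converged
        est.append(fit.path_coefficients[("X", "Y")])
    assert np.mean(est) == pytest.approx(beta, abs=0.05)


def test_null_paths_stay_small_at_large_n():
    spec = CohortSpec(
        n_subjects_per_group={"G": 2000},
        constructs=(
            ConstructSpec("A", tuple(f"a{i}" for i in range(4)), (0.8,) * 4),
            ConstructSpec("B", tuple(f"b{i}" for i in range(4)), (0.8,) * 4),
            ConstructSpec("Y", tuple(f"y{i}" for i in range(4)), (0.8,) * 4),
        ),
        target="Y",
        paths={"G": {"A": 0.0, "B": 0.0}},
        seed=5,
    )
    cohort = generate_questionnaire_cohort(spec)
    imap = cohort.spec.indicator_map
    model = ModelSpec(["A", "B", "Y"], imap, [("A", "Y"), ("B", "Y")])
    fit = fit_pls_path_model(cohort.indicators, model)
    for v in fit.path_coefficients.values():
        assert abs(v) < 0.05


def test_consistency_bias_shrinks_with_n():
    """Average |beta_hat - beta| at n=2000 is at most half the n=200 value."""
    errs = {200: [], 2000: []}
    for n in errs:
        for seed in range(5):
            cohort = generate_questionnaire_cohort(
                two_construct_spec(0.4, n, seed=100 + seed)
            )
            fit = fit_pls_path_model(cohort.indicators, two_construct_model())
            errs[n].append(abs(fit.path_coefficients[("X", "Y")] - 0.4))
    assert np.mean(errs[2000]) <= np.mean(errs[200]) / 2 + 0.01


def test_scores_standardized_and_zero_variance_rejected():
    cohort = generate_questionnaire_cohort(two_construct_spec(0.3, 150, seed=2))
    fit = fit_pls_path_model(cohort.indicators, two_construct_model())
    sc = fit.scores[["X", "Y"]].to_numpy()
    assert np.allclose(sc.mean(0), 0, atol=1e-10)
    assert np.allclose(sc.std(0, ddof=1), 1, atol=1e-10)

    bad = cohort.indicators.copy()
    bad["x0"] = 1.0
    with pytest.raises(ValueError, match="x0"):
        fit_pls_path_model(bad, two_construct_model())


# ----------------------------------------------------------------------
# cross-loadings and composite scores


def test_cross_loadings_discriminate_orthogonal_constructs():
    spec = CohortSpec(
        n_subjects_per_group={"G": 2000},
        constructs=(
            ConstructSpec("X", tuple(f"x{i}" for i in range(4)), (0.8,) * 4),
            ConstructSpec("Y", tuple(f"y{i}" for i in range(4)), (0.8,) * 4),
        ),
        target="Y",
        paths={"G": {"X": 0.0}},
        seed=17,
    )
    cohort = generate_questionnaire_cohort(spec)
    model = ModelSpec(
        ["X", "Y"], cohort.spec.indicator_map, [("X", "Y")]
    )
    fit = fit_pls_path_model(cohort.indicators, model)
    cl = cross_loading_matrix(cohort.indicators, fit)
    assert bool(cl["discriminant_valid"].all())
    for ind, own in fit.model.indicator_map.items():
        other = [c for c in fit.model.constructs if c != own]
        assert (cl.loc[ind, other].abs() < 0.1).all()
        assert abs(cl.loc[ind, own]) > 0.5


def test_composite_score_is_weighted_standardized_sum():
    cohort = generate_questionnaire_cohort(two_construct_spec(0.4, 200, seed=23))
    fit = fit_pls_path_model(cohort.indicators, two_construct_model())
    cols = [f"y{i}" for i in range(8)]
    X = cohort.indicators[cols].to_numpy(float)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    raw = X @ fit.outer_weights[cols].to_numpy()
    expected = (raw - raw.mean()) / raw.std(ddof=1)
    got = compute_composite_scores(fit, "Y")
    assert np.allclose(got.to_numpy(), expected, atol=1e-10)
    with pytest.raises(KeyError):
        compute_composite_scores(fit, "Z")


def test_higher_composite_means_more_of_the_target_latent():
    """Sign anchoring: the composite correlates positively with the latent."""
    cohort = generate_questionnaire_cohort(two_construct_spec(0.4, 500, seed=31))
    fit = fit_pls_path_model(cohort.indicators, two_construct_model())
    score = compute_composite_scores(fit, "Y")
    r = np.corrcoef(score.to_numpy(), cohort.latents["Y"])[0, 1]
    assert r > 0.9


# ----------------------------------------------------------------------
# resampling


def test_bootstrap_rejects_degenerate_and_warns_on_small_n_boot():
    cohort = generate_questionnaire_cohort(two_construct_spec(0.4, 120, seed=37))
    model = two_construct_model()
    with pytest.raises(ValueError):
        bootstrap_path_significance(cohort.indicators, model, n_boot=1, seed=0)
    with pytest.warns(RuntimeWarning):
        bootstrap_path_significance(cohort.indicators, model, n_boot=50, seed=0)


def test_bootstrap_null_coverage_and_power():
    """95% CI covers 0 ~95% under the null, excludes 0 under beta=0.6."""
    cover = 0
    reps = 60
    for seed in range(reps):
        cohort = generate_questionnaire_cohort(
            two_construct_spec(0.0, 200, seed=1000 + seed)
        )
        bs = bootstrap_path_significance(
            cohort.indicators, two_construct_model(), n_boot=199, seed=seed
        )
        lo, hi = bs.ci_lower[("X", "Y")], bs.ci_upper[("X", "Y")]
        cover += lo <= 0.0 <= hi
    assert 0.88 * reps <= cover  # ~95% nominal, binomial slack at 60 reps

    power = 0
    for seed in range(30):
        cohort = generate_questionnaire_cohort(
            two_construct_spec(0.6, 200, seed=2000 + seed)
        )
        bs = bootstrap_path_significance(
            cohort.indicators, two_construct_model(), n_boot=199, seed=seed
        )
        power += bs.ci_lower[("X", "Y")] > 0.0
    assert power >= 29  # >= 95% of replications


def test_permutation_identical_groups_p_is_one():
    cohort = generate_questionnaire_cohort(two_construct_spec(0.4, 60, seed=41))
    model = two_construct_model()
    res = permutation_multigroup_test(
        cohort.indicators, cohort.indicators.copy(), model, ("X", "Y"),
        n_perm=99, seed=0,
    )
    assert res.observed_diff == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0


def test_permutation_detects_planted_group_difference():
    """beta 0 vs -0.4 at n=50/group: clearly significant at 1000 permutations."""
    spec = CohortSpec(
        n_subjects_per_group={"A": 50, "B": 50},
        constructs=(
            ConstructSpec("X", tuple(f"x{i}" for i in range(8)), (0.85,) * 8),
            ConstructSpec("Y", tuple(f"y{i}" for i in range(8)), (0.85,) * 8),
        ),
        target="Y",
        paths={"A": {"X": 0.0}, "B": {"X": -0.4}},
        seed=47,
    )
    cohort = generate_questionnaire_cohort(spec)
    a = cohort.indicators[cohort.indicators.group == "A"].reset_index(drop=True)
    b = cohort.indicators[cohort.indicators.group == "B"].reset_index(drop=True)
    res = permutation_multigroup_test(
        a, b, two_construct_model(), ("X", "Y"), n_perm=1000, seed=1
    )
    assert res.p_value <= 0.05
    # invariant: p = (count + 1) / (n + 1) implies p >= 1/(n+1), never 0
    assert res.p_value >= 1.0 / (res.n_permutations + 1)
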