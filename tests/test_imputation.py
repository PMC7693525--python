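import numpy as np
import pytest

import qpcrmiss as q
from conftest import make_dataset


def test_mean_impute_uses_group_detected_mean():
    cq = np.array([[30.0, 32.0, np.nan, 25.0, 26.0, 27.0]])
    ds = make_dataset(cq, ["A", "A", "A", "B", "B", "B"])
    imps = q.mean_impute(ds)
    assert imps.m == 1
    assert imps.completed[0][0, 2] == pytest.approx(31.0)
    np.testing.assert_array_equal(imps.completed[0][0, [0, 1, 3, 4, 5]], cq[0, [0, 1, 3, 4, 5]])


def test_imputation_is_identity_without_nondetects():
    rng = np.random.default_rng(2)
    cq = rng.normal(28, 1, (2, 6))
    ds = make_dataset(cq, ["A", "A", "A", "B", "B", "B"])
    for imps in (q.mean_impute(ds), q.si_impute(ds)):
        np.testing.assert_array_equal(imps.completed[0], cq)


def test_si_variance_identity_with_completed_data(sim_fit):
    # the empirical variance of the SI completion around the fitted means
    # must equal sigma2_MLE minus the moment gap, cell for cell
    ds, fit, mech, _ = sim_fit
    si = q.si_impute(ds)
    codes, _ = ds.group_codes()
    mu = si.base_fit.theta[:, codes]
    emp = np.mean((si.completed[0] - mu) ** 2, axis=1)
    np.testing.assert_allclose(
        emp, q.si_variance(ds, si.base_fit, si.base_mech), atol=1e-10
    )


def test_detected_cells_never_change_and_imputed_sit_above_group_mean(sim_fit):
    # under the MNAR truth non-detects concentrate at high Cq, so imputed
    # values land above the detected-replicate mean on the Cq scale
    ds, fit, mech, _ = sim_fit
    imps = q.mi_impute(ds, m=5, sources=("fit", "theta", "epsilon"), seed=3,
                       _fitted=(fit, mech))
    codes, _ = ds.group_codes()
    from qpcrmiss.ecm import _group_means

    det_mean, _ = _group_means(
        np.where(ds.detected, ds.cq, 0.0), ds.detected, codes, len(ds.groups)
    )
    nd = ~ds.detected
    resid = []
    for mat in imps.completed:
        np.testing.assert_array_equal(mat[ds.detected], ds.cq[ds.detected])
        resid.append((mat - det_mean[:, codes])[nd])
    assert np.mean(np.concatenate(resid)) > 0  # sign test on mean residual


def test_mi_reduces_to_si_in_the_degenerate_case(two_group_ds):
    si = q.si_impute(two_group_ds)
    mi = q.mi_impute(two_group_ds, m=1, sources=(), seed=9)
    np.testing.assert_allclose(mi.completed[0], si.completed[0], atol=1e-12)


def test_mi_epsilon_source_injects_residual_variance(sim_fit):
    ds, fit, mech, _ = sim_fit
    imps = q.mi_impute(ds, m=200, sources=("epsilon",), seed=11, _fitted=(fit, mech))
    nd_rows, nd_cols = np.nonzero(~ds.detected)
    stack = np.stack([mat[nd_rows, nd_cols] for mat in imps.completed])
    emp_var = stack.var(axis=0, ddof=1)
    target = fit.sigma2[nd_rows]
    # across-imputation variance of each imputed cell ~ sigma2_i
    ratio = emp_var / target
    assert abs(np.mean(ratio) - 1.0) < 0.15


def test_mi_is_seed_reproducible(two_group_ds):
    a = q.mi_impute(two_group_ds, m=4, sources=("fit", "theta", "epsilon"), seed=21)
    b = q.mi_impute(two_group_ds, m=4, sources=("fit", "theta", "epsilon"), seed=21)
    for x, y in zip(a.completed, b.completed):
        np.testing.assert_array_equal(x, y)


def test_mi_argument_validation(two_group_ds):
    with pytest.raises(ValueError):
        q.mi_impute(two_group_ds, m=0, sources=("epsilon",))
    with pytest.raises(ValueError):
        q.mi_impute(two_group_ds, m=5, sources=())
    with pytest.raises(ValueError):
        q.mi_impute(two_group_ds, m=2, sources=("bogus",))


def test_pooling_rules(two_group_ds):
    ds = two_group_ds.validate()
    est = q.group_mean_estimator(ds)
    # identical completed datasets: between-variance 0, total = within
    si = q.si_impute(ds)
    imps = q.ImputationSet(
        completed=[si.completed[0].copy() for _ in range(3)],
        sources=frozenset({"epsilon"}), m=3, seed=0,
        base_fit=si.base_fit, base_mech=si.base_mech,
    )
    pooled = q.pool_estimates(imps, est)
    np.testing.assert_array_equal(pooled["between"], 0.0)
    np.testing.assert_allclose(pooled["total"], pooled["within"])
    with pytest.raises(ValueError, match="M >= 2"):
        q.pool_estimates(si, est)
    # epsilon-MI: the total variance of a group mean exceeds the SI value
    mi = q.mi_impute(ds, m=40, sources=("epsilon",), seed=2,
                     _fitted=(si.base_fit, si.base_mech))
    pooled_mi = q.pool_estimates(mi, est)
    si_var = est(si.completed[0])[1]
    nd_groups = pooled_mi["between"] > 1e-12  # groups actually containing imputed cells
    assert nd_groups.any()
    assert np.all(pooled_mi["total"][nd_groups] > si_var[nd_groups])
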