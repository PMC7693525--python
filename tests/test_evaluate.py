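import numpy as np
import pytest

import qpcrmiss as q
from qpcrmiss.ecm import FitResult


def _truth():
    return q.SimulationTruth(
        theta=np.array([[30.0, 31.0], [33.0, 34.0]]),
        mu_theta=np.array([30.5, 33.5]),
        sigma2=np.array([0.5, 1.0]),
        beta0=-35.7, beta1=1.0, detection_limit=40.0,
    )


def _fit(theta, sigma2):
    return FitResult(
        theta=np.asarray(theta, float), sigma2=np.asarray(sigma2, float),
        delta=np.zeros(4), loglik_trace=np.zeros(1), converged=True, n_iter=1,
        groups=np.array(["A", "B"]), genes=np.array(["g1", "g2"]),
    )


def test_exact_fit_scores_zero():
    t = _truth()
    sc = q.score_fit(_fit(t.theta, t.sigma2), t, n_replicates=6)
    assert not sc.theta_bias.any() and not sc.sigma2_theta_sqerr.any()


def test_constant_offset_appears_in_every_cell():
    t = _truth()
    sc = q.score_fit(_fit(t.theta + 0.25, t.sigma2), t, n_replicates=6)
    np.testing.assert_allclose(sc.theta_bias, 0.25)
    np.testing.assert_allclose(sc.theta_sqerr, 0.0625)


def test_hand_computed_two_cell_case():
    t = _truth()
    est = t.theta.copy()
    est[0, 0] += 0.1
    est[1, 1] -= 0.2
    sc = q.score_fit(_fit(est, t.sigma2 + np.array([0.06, -0.12])), t, n_replicates=6)
    assert sc.theta_bias[0, 0] == pytest.approx(0.1)
    assert sc.theta_bias[1, 1] == pytest.approx(-0.2)
    assert sc.sigma2_theta_bias[0] == pytest.approx(0.01)
    assert sc.sigma2_theta_sqerr[1] == pytest.approx(0.0004)
    with pytest.raises(ValueError, match="shape"):
        q.score_fit(_fit(t.theta[:1], t.sigma2[:1]), t, 6)


def test_benchmark_smoke_run_single_replicate():
    res = q.run_benchmark(methods=("mean", "direst"), n_reps=1, seed=1,
                          design={"n_genes": 8})
    assert res.n_failed == 0
    assert set(res.summary["method"]) == {"mean", "direst"}
    assert set(res.summary["parameter"]) == {"theta", "sigma2_theta"}
    assert np.isfinite(res.summary.filter(like="q5").to_numpy()).all()
    md = res.markdown()
    assert md.count("|") > 10


def test_benchmark_is_seed_reproducible():
    a = q.run_benchmark(methods=("direst",), n_reps=2, seed=7, design={"n_genes": 6})
    b = q.run_benchmark(methods=("direst",), n_reps=2, seed=7, design={"n_genes": 6})
    np.testing.assert_allclose(
        a.summary.select_dtypes(float).to_numpy(),
        b.summary.select_dtypes(float).to_numpy(),
    )


def test_benchmark_rejects_unknown_method():
    with pytest.raises(ValueError, match="unknown methods"):
        q.run_benchmark(methods=("pemm",), n_reps=1)


def test_external_method_hook_scores_alongside_builtins():
    # an external estimator given as a callable: limit substitution
    def limit_sub(ds):
        codes, groups = ds.group_codes()
        filled = np.where(ds.detected, ds.cq, ds.detection_limit)
        theta = np.stack(
            [filled[:, codes == k].mean(axis=1) for k in range(len(groups))], axis=1
        )
        sigma2 = np.mean((filled - theta[:, codes]) ** 2, axis=1)
        return theta, sigma2

    res = q.run_benchmark(methods=("mean", "limit"), n_reps=2, seed=5,
                          design={"n_genes": 8}, external={"limit": limit_sub})
    assert "limit" in set(res.summary["method"])
    r = res.summary[(res.summary.method == "limit") & (res.summary.parameter == "theta")]
    assert np.isfinite(r.mse_q50.iloc[0])


def test_subprocess_contract_round_trip(tmp_path):
    import sys
    import textwrap

    script = tmp_path / "limit_sub.py"
    script.write_text(textwrap.dedent("""
        import sys
        import pandas as pd
        df = pd.read_csv(sys.argv[1])
        df["cq"] = df["cq"].clip(upper=40.0)
        g = df.groupby(["gene", "sample_type"])["cq"]
        out = g.mean().rename("theta").reset_index()
        var = df.merge(out, on=["gene", "sample_type"])
        var["sq"] = (var["cq"] - var["theta"]) ** 2
        out["sigma2"] = var.groupby("gene")["sq"].mean().reindex(out["gene"]).to_numpy()
        out.to_csv(sys.argv[2], index=False)
    """))
    estimate = q.subprocess_method([sys.executable, str(script)])
    ds, truth = q.simulate_dataset(6, 3, 4, seed=9)
    theta, sigma2 = estimate(ds)
    assert theta.shape == (6, 3)
    assert sigma2.shape == (6,)
    filled = np.where(ds.detected, ds.cq, 40.0)
    codes, _ = ds.group_codes()
    np.testing.assert_allclose(theta[:, 0], filled[:, codes == 0].mean(axis=1))
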