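"""Scoring against simulation truth and the replicated benchmark.

The benchmark reproduces the estimator-comparison design: each of
``n_reps`` replicates simulates a fresh dataset from the generative
model (by default redrawing the generating parameters as well; pass
``truth`` to hold one parameter set fixed across replicates), every
requested method x link combination is fit to the same datasets, and
per-parameter errors are aggregated per cell across replicates.  Reported are the 25th/50th/75th quantiles (linear
interpolation) over cells of the per-cell bias (mean error) and MSE
(mean squared error), for the group means theta and for the variance of
a group mean sigma2_theta = sigma2 / m.

Replicates in which a gene has an all-non-detect sample-type cell --
which the model cannot estimate -- contribute that replicate's remaining
genes only; the offending genes are excluded from that replicate's fit
and scoring and their count is logged.  Replicates themselves are never
discarded, and any hard estimation failure is recorded.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .direct import direst, si_variance
from .ecm import FitResult, _group_means
from .imputation import mi_impute
from .simulate import SimulationTruth, draw_truth, simulate_dataset

logger = logging.getLogger(__name__)

_METHODS = ("mean", "si", "direst", "mi")
_ECM_METHODS = frozenset({"si", "direst", "mi"})


@dataclasses.dataclass
class ScoreResult:
    """Per-parameter errors of a single fit against the truth."""

    theta_bias: np.ndarray  # (genes, groups)
    theta_sqerr: np.ndarray
    sigma2_bias: np.ndarray  # (genes,)
    sigma2_sqerr: np.ndarray
    sigma2_theta_bias: np.ndarray  # (genes,): sigma2 / m scale
    sigma2_theta_sqerr: np.ndarray


def score_fit(fit: FitResult, truth: SimulationTruth, n_replicates: int) -> ScoreResult:
    """Bias and squared error of a fit, per theta cell and per variance.

    ``n_replicates`` is the number of replicates per sample type, which
    converts the residual variance to the variance of a group mean.
    """
    if fit.theta.shape != truth.theta.shape:
        raise ValueError(
            f"shape mismatch: fit {fit.theta.shape} vs truth {truth.theta.shape}"
        )
    tb = fit.theta - truth.theta
    sb = fit.sigma2 - truth.sigma2
    stb = sb / n_replicates
    return ScoreResult(
        theta_bias=tb, theta_sqerr=tb**2,
        sigma2_bias=sb, sigma2_sqerr=sb**2,
        sigma2_theta_bias=stb, sigma2_theta_sqerr=stb**2,
    )


def _method_estimates(method, ds_sub, codes, K, fit, mech, mi_m, mi_sources, mi_seed,
                      external=None):
    """(theta_hat, sigma2_hat) for one method on one replicate dataset."""
    if external and method in external:
        return external[method](ds_sub)
    if method == "mean":
        means, _ = _group_means(
            np.where(ds_sub.detected, ds_sub.cq, 0.0), ds_sub.detected, codes, K
        )
        completed = np.where(ds_sub.detected, ds_sub.cq, means[:, codes])
        sigma2 = np.mean((completed - means[:, codes]) ** 2, axis=1)
        return means, sigma2
    if method == "direst":
        return fit.theta, fit.sigma2
    if method == "si":
        return fit.theta, si_variance(ds_sub, fit, mech)
    if method == "mi":
        imps = mi_impute(
            ds_sub, m=mi_m, sources=mi_sources, seed=mi_seed, _fitted=(fit, mech)
        )
        thetas, sigmas = [], []
        for mat in imps.completed:
            th, _ = _group_means(mat, np.ones_like(mat, dtype=bool), codes, K)
            thetas.append(th)
            sigmas.append(np.mean((mat - th[:, codes]) ** 2, axis=1))
        return np.mean(thetas, axis=0), np.mean(sigmas, axis=0)
    raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")


@dataclasses.dataclass
class BenchmarkResult:
    summary: pd.DataFrame
    per_rep: pd.DataFrame
    truth: SimulationTruth | None  # None when redrawn per replicate
    n_reps: int
    n_failed: int
    n_gene_exclusions: int

    def markdown(self) -> str:
        """Render the quantile table in the layout of the published tables."""
        lines = ["| method | link | parameter | bias q25 | q50 | q75 | MSE q25 | q50 | q75 |",
                 "|---|---|---|---|---|---|---|---|---|"]
        for _, r in self.summary.iterrows():
            lines.append(
                f"| {r['method']} | {r['link']} | {r['parameter']} | "
                f"{r['bias_q25']:.3f} | {r['bias_q50']:.3f} | {r['bias_q75']:.3f} | "
                f"{r['mse_q25']:.3f} | {r['mse_q50']:.3f} | {r['mse_q75']:.3f} |"
            )
        return "\n".join(lines)


def subprocess_method(cmd):
    """Adapter scoring an external estimator through a subprocess contract.

    ``cmd`` is a list of argv tokens; it is invoked as
    ``cmd <input.csv> <output.csv>`` where the input is the long-CSV
    dialect (sentinel non-detects) and the output must be a CSV with
    columns gene, sample_type, theta, sigma2.  Returns a callable usable
    in ``run_benchmark(external=...)``; the external program itself is
    not bundled.
    """
    import subprocess
    import tempfile

    from .dataset import write_dataset

    def estimate(ds):
        codes, groups = ds.group_codes()
        with tempfile.TemporaryDirectory() as td:
            inp = f"{td}/input.csv"
            out = f"{td}/output.csv"
            write_dataset(ds, inp)
            subprocess.run([*cmd, inp, out], check=True)
            tab = pd.read_csv(out)
        tab = tab.set_index(["gene", "sample_type"])
        theta = np.array(
            [[tab.loc[(g, k), "theta"] for k in groups] for g in ds.genes]
        )
        sigma2 = np.array(
            [np.mean([tab.loc[(g, k), "sigma2"] for k in groups]) for g in ds.genes]
        )
        return theta, sigma2

    return estimate


def run_benchmark(
    methods=("direst",),
    n_reps: int = 100,
    design: dict | None = None,
    seed: int = 0,
    links=("logit",),
    mi_m: int = 10,
    mi_sources=("fit", "theta", "epsilon"),
    truth: SimulationTruth | None = None,
    external: dict | None = None,
) -> BenchmarkResult:
    """Replicated simulate -> fit -> score comparison of methods.

    Each replicate calls the simulator afresh with a counter-derived seed
    (so any replicate is reproducible in isolation) and the same datasets
    are used for every method and link.  By default the generating
    parameters are part of what each replicate redraws; supplying
    ``truth`` instead fixes one parameter set for all replicates.  Data
    are always generated under the logistic mechanism; fitting under
    probit/cloglog probes link misspecification.  ``external`` maps extra
    method names to callables ``f(ds) -> (theta, sigma2)`` (see
    :func:`subprocess_method`) scored alongside the built-ins.
    """
    design = {**{"n_genes": 16, "n_groups": 6, "m": 6}, **(design or {})}
    m = design["m"]
    external = external or {}
    unknown = set(methods) - set(_METHODS) - set(external)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    G, K = design["n_genes"], design["n_groups"]
    if truth is not None:
        G, K = truth.theta.shape
    design_overrides = {
        k: v for k, v in design.items() if k not in ("n_genes", "n_groups", "m")
    }

    combos = [(meth, lk) for meth in methods for lk in (links if meth in _ECM_METHODS else ["-"])]
    combos = list(dict.fromkeys(combos))
    acc = {
        c: dict(
            tb=np.zeros((G, K)), tb2=np.zeros((G, K)), tn=np.zeros((G, K)),
            sb=np.zeros(G), sb2=np.zeros(G), sn=np.zeros(G),
        )
        for c in combos
    }
    per_rep_rows = []
    n_failed = 0
    n_excl = 0
    need_ecm = bool(_ECM_METHODS & set(methods))

    for r in range(n_reps):
        ds, truth_r = simulate_dataset(
            n_genes=G, n_groups=K, m=m, truth=truth,
            rng=np.random.default_rng([seed, 1, r]), **design_overrides,
        )
        codes, groups = ds.group_codes()
        det = ds.detected
        keep = np.ones(G, bool)
        for k in range(K):
            keep &= det[:, codes == k].any(axis=1)
        n_excl += int((~keep).sum())
        ds_sub = ds.subset(gene_mask=keep)
        truth_sub = SimulationTruth(
            theta=truth_r.theta[keep], mu_theta=truth_r.mu_theta[keep],
            sigma2=truth_r.sigma2[keep], beta0=truth_r.beta0, beta1=truth_r.beta1,
            detection_limit=truth_r.detection_limit, link=truth_r.link,
        )
        codes_sub, _ = ds_sub.group_codes()
        for lk in links:
            fit = mech = None
            if need_ecm:
                try:
                    fit, mech = direst(ds_sub, link=lk)
                except Exception:
                    logger.exception("replicate %d failed under link %s", r, lk)
                    n_failed += 1
                    continue
            for meth in methods:
                combo = (meth, lk if meth in _ECM_METHODS else "-")
                if combo not in acc:
                    continue
                if meth not in _ECM_METHODS and lk != links[0]:
                    continue  # link-free methods scored once
                theta_hat, sigma2_hat = _method_estimates(
                    meth, ds_sub, codes_sub, K, fit, mech,
                    mi_m, mi_sources, mi_seed=[seed, 2, r], external=external,
                )
                fr = FitResult(
                    theta=theta_hat, sigma2=sigma2_hat, delta=np.zeros(ds_sub.n_samples),
                    loglik_trace=np.zeros(0), converged=True, n_iter=0,
                    groups=groups, genes=ds_sub.genes,
                )
                sc = score_fit(fr, truth_sub, m)
                a = acc[combo]
                a["tb"][keep] += sc.theta_bias
                a["tb2"][keep] += sc.theta_sqerr
                a["tn"][keep] += 1
                a["sb"][keep] += sc.sigma2_theta_bias
                a["sb2"][keep] += sc.sigma2_theta_sqerr
                a["sn"][keep] += 1
                per_rep_rows.append(
                    {
                        "rep": r, "method": meth, "link": combo[1],
                        "theta_bias_median": float(np.median(sc.theta_bias)),
                        "s2theta_bias_mean": float(np.mean(sc.sigma2_theta_bias)),
                        "s2theta_bias_median": float(np.median(sc.sigma2_theta_bias)),
                    }
                )

    rows = []
    for (meth, lk), a in acc.items():
        ok_t = a["tn"] > 0
        ok_s = a["sn"] > 0
        bias_t = a["tb"][ok_t] / a["tn"][ok_t]
        mse_t = a["tb2"][ok_t] / a["tn"][ok_t]
        bias_s = a["sb"][ok_s] / a["sn"][ok_s]
        mse_s = a["sb2"][ok_s] / a["sn"][ok_s]
        for pname, bias, mse in (("theta", bias_t, mse_t), ("sigma2_theta", bias_s, mse_s)):
            q = lambda v, p: float(np.quantile(v, p)) if v.size else np.nan
            rows.append(
                {
                    "method": meth, "link": lk, "parameter": pname,
                    "bias_q25": q(bias, 0.25), "bias_q50": q(bias, 0.5), "bias_q75": q(bias, 0.75),
                    "mse_q25": q(mse, 0.25), "mse_q50": q(mse, 0.5), "mse_q75": q(mse, 0.75),
                }
            )
    logger.info(
        "benchmark done: %d reps, %d failed fits, %d per-replicate gene exclusions",
        n_reps, n_failed, n_excl,
    )
    return BenchmarkResult(
        summary=pd.DataFrame(rows),
        per_rep=pd.DataFrame(per_rep_rows),
        truth=truth, n_reps=n_reps, n_failed=n_failed, n_gene_exclusions=n_excl,
    )
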