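"""Expectation-Conditional-Maximization fit of the MNAR selection model.

The absolute-quantification model for gene i in sample j is

    X_ij = theta_{i k(j)} + delta_j + eps_ij,   eps_ij ~ N(0, sigma2_i)

with k(j) the sample-type (replicate group) of sample j, delta_j an
optional global per-sample shift (sum-to-zero; fixed at 0 by default) and
a common residual variance per gene across sample types.  Non-detects are
missing not at random: the probability of observing a value depends on
the value itself through the shared detection mechanism.

The joint observed-data likelihood of (theta, sigma2, delta, beta)
factors per cell as

    detected:   N(y; mu, sigma2) * Pr(Z=1 | y)
    non-detect: integral N(x; mu, sigma2) * Pr(Z=0 | x) dx

and is maximized by alternating (a) an E-step computing E(W) for each
non-detect under the current parameters, (b) a conditional M-step
updating theta (and delta) from the completed data, (c) a refreshed
E-step for E(W^2) and the variance update, and (d) a refit of the pooled
mechanism on the completed data.  The observed-data log-likelihood is
monitored every iteration; it must be non-decreasing up to tolerance, and
iteration stops when its relative change falls below ``tol``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .dataset import QpcrDataset
from .errors import ConvergenceError, SeparationError
from .mechanism import (
    LINKS,
    MissingMechanism,
    fit_mechanism,
    log_prior,
    log_prior_grad,
    penalized_cov_at,
    standardizer,
)
from .moments import nondetect_moments_many

from scipy import optimize

logger = logging.getLogger(__name__)

_LOG_SQRT2PI = 0.5 * np.log(2.0 * np.pi)


@dataclasses.dataclass
class FitResult:
    """Estimates from the ECM fit.

    ``theta`` is (genes x groups) in cycles, ``sigma2`` the per-gene
    residual variance (cycles^2, Eq.-6-style 1/J maximum-likelihood form),
    ``delta`` the per-sample shifts (all zero unless estimated, in which
    case they sum to zero).  ``se_theta`` is populated by
    :func:`qpcrmiss.direct.direst` from the observed information.
    """

    theta: np.ndarray
    sigma2: np.ndarray
    delta: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    groups: np.ndarray
    genes: np.ndarray
    se_theta: np.ndarray | None = None


def _group_means(values, mask, codes, n_groups):
    """Mean of ``values`` over True entries of ``mask`` per (row, group)."""
    G = values.shape[0]
    sums = np.zeros((G, n_groups))
    counts = np.zeros((G, n_groups))
    vals = np.where(mask, values, 0.0)
    for k in range(n_groups):
        cols = codes == k
        sums[:, k] = vals[:, cols].sum(axis=1)
        counts[:, k] = mask[:, cols].sum(axis=1)
    with np.errstate(invalid="ignore"):
        return sums / counts, counts


def _cell_params(theta, delta, codes, nd_rows, nd_cols):
    return theta[nd_rows, codes[nd_cols]] + delta[nd_cols]


def _mech_cm_step(mech, y_det, nodes_x, nodes_w, xbar, sx, regularize):
    """Conditional maximization for (beta0, beta1).

    Maximizes the expected complete-data log-likelihood of the mechanism,
    E[log Pr(Z | X)]: detected reactions contribute log detect_prob at
    their observed Cq, non-detects contribute the conditional expectation
    of log nondetect_prob over the current E-step grid (``nodes_x`` with
    normalized weights ``nodes_w``; the hard tail above S contributes
    zero since the non-detect probability there is one).  With
    ``regularize`` the frozen-standardization Cauchy prior is added, so
    this step provably increases the monitored penalized objective.
    """
    inv, dinv = LINKS[mech.link]

    def negQ(b):
        eta_d = b[0] + b[1] * y_det
        p_d = np.clip(inv(eta_d), 1e-12, 1.0 - 1e-12)
        eta_n = b[0] + b[1] * nodes_x
        p_n = np.clip(inv(eta_n), 1e-300, 1.0)
        val = np.log1p(-p_d).sum() + (nodes_w * np.log(p_n)).sum()
        if regularize:
            val += log_prior(b[0], b[1], xbar, sx)
        return -val

    def grad(b):
        eta_d = b[0] + b[1] * y_det
        p_d = np.clip(inv(eta_d), 1e-12, 1.0 - 1e-12)
        g_d = -dinv(eta_d) / (1.0 - p_d)
        eta_n = b[0] + b[1] * nodes_x
        p_n = np.clip(inv(eta_n), 1e-300, 1.0)
        g_n = nodes_w * dinv(eta_n) / p_n
        g = np.array([g_d.sum() + g_n.sum(),
                      (g_d * y_det).sum() + (g_n * nodes_x).sum()])
        if regularize:
            g += log_prior_grad(b[0], b[1], xbar, sx)
        return -g

    start = np.array([mech.beta0, mech.beta1])
    res = optimize.minimize(negQ, start, jac=grad, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 200})
    b = res.x if res.fun <= negQ(start) else start
    if np.abs(b).max() > 1e5:
        raise SeparationError(
            "mechanism estimates diverged during ECM; use regularize=True"
        )
    return MissingMechanism(
        link=mech.link, beta0=float(b[0]), beta1=float(b[1]),
        beta_cov=mech.beta_cov, detection_limit=mech.detection_limit,
    )


def observed_loglik(ds, theta, sigma2, delta, mech, codes, log_m0=None):
    """Observed-data log-likelihood of (theta, sigma2, delta, beta)."""
    det = ds.detected
    mu = theta[:, codes] + delta[None, :]
    sd2 = sigma2[:, None]
    with np.errstate(divide="ignore"):
        normal = -_LOG_SQRT2PI - 0.5 * np.log(sd2) - 0.5 * (ds.cq - mu) ** 2 / sd2
        pdet = np.log(np.clip(mech.detect_prob(ds.cq), 1e-300, None))
    ll = np.where(det, normal + pdet, 0.0)[det].sum()
    if log_m0 is None:
        nd_rows, nd_cols = np.nonzero(~det)
        if nd_rows.size:
            _, _, log_m0, _ = nondetect_moments_many(
                _cell_params(theta, delta, codes, nd_rows, nd_cols),
                sigma2[nd_rows], mech,
            )
        else:
            log_m0 = np.zeros(0)
    return ll + log_m0.sum()


def ecm_fit(
    ds: QpcrDataset,
    link: str = "logit",
    max_iter: int = 200,
    tol: float = 1e-8,
    estimate_delta: bool = False,
    mechanism: MissingMechanism | None = None,
    regularize: bool = True,
) -> tuple[FitResult, MissingMechanism]:
    """Fit (theta, sigma2, delta) and the detection mechanism by ECM.

    Parameters
    ----------
    ds
        Validated dataset; every (gene, sample-type) cell must have at
        least one detected replicate.
    link
        Sigmoid family for the mechanism.
    estimate_delta
        Estimate per-sample shifts under a sum-to-zero constraint
        (default off: the shifts are fixed at zero).
    mechanism
        A known mechanism to hold fixed; when given, the mechanism-refit
        step is skipped (used by oracle tests and by multiple imputation,
        which perturbs a fitted mechanism instead of refitting).
    regularize
        Use the weakly-informative-prior mechanism fit (recommended; the
        completed data can be nearly separated).

    Returns
    -------
    (FitResult, MissingMechanism)
        Non-convergence after ``max_iter`` iterations is flagged on the
        result, not raised; a log-likelihood decreasing beyond tolerance
        raises :class:`ConvergenceError` as it indicates a numerical bug.
    """
    ds = ds.copy().validate()
    codes, groups = ds.group_codes()
    K = len(groups)
    det = ds.detected
    nd_rows, nd_cols = np.nonzero(~det)
    any_nd = nd_rows.size > 0

    # initialize non-detect cells at their (gene, group) detected means
    completed = np.where(det, ds.cq, 0.0)
    theta, _ = _group_means(completed, det, codes, K)
    completed[nd_rows, nd_cols] = theta[nd_rows, codes[nd_cols]]
    delta = np.zeros(ds.n_samples)
    sigma2 = np.maximum(
        np.mean((completed - theta[:, codes]) ** 2, axis=1), 1e-6
    )
    fixed_mech = mechanism is not None
    mech = mechanism if fixed_mech else fit_mechanism(
        completed, det, link=link, regularize=regularize,
        detection_limit=ds.detection_limit,
    )
    update_mech = not fixed_mech and any_nd
    # frozen prior standardization: keeps the monitored penalized
    # objective a fixed function of the parameters across iterations
    xbar, sx = standardizer(completed)
    y_det = ds.cq[det]

    trace: list[float] = []
    converged = False
    n_iter = 0
    prev_ll = -np.inf
    ones = np.ones_like(det, dtype=bool)
    for it in range(max_iter + 1):
        # E-step at current parameters (also yields the likelihood monitor)
        if any_nd:
            e_w, e_w2, log_m0, _ = nondetect_moments_many(
                _cell_params(theta, delta, codes, nd_rows, nd_cols),
                sigma2[nd_rows], mech,
            )
            completed[nd_rows, nd_cols] = e_w
        else:
            log_m0 = np.zeros(0)
        ll = observed_loglik(ds, theta, sigma2, delta, mech, codes, log_m0=log_m0)
        if update_mech and regularize:
            ll += log_prior(mech.beta0, mech.beta1, xbar, sx)
        trace.append(ll)
        scale = 1.0 + abs(ll)
        if ll - prev_ll < -1e-6 * scale:
            raise ConvergenceError(
                f"observed-data log-likelihood decreased at iteration {it}: "
                f"{prev_ll:.10g} -> {ll:.10g}"
            )
        if abs(ll - prev_ll) <= tol * scale or it == max_iter:
            converged = abs(ll - prev_ll) <= tol * scale
            break
        prev_ll = ll
        n_iter += 1

        # CM-step A: update theta (and delta) from completed data
        if estimate_delta:
            for _ in range(3):
                theta, _ = _group_means(completed - delta[None, :], ones, codes, K)
                resid = completed - theta[:, codes]
                delta = resid.mean(axis=0)
                delta -= delta.mean()
        else:
            theta, _ = _group_means(completed, ones, codes, K)

        # refreshed E-step at the new means, then CM-step B: variances
        if any_nd:
            e_w, e_w2, _, _ = nondetect_moments_many(
                _cell_params(theta, delta, codes, nd_rows, nd_cols),
                sigma2[nd_rows], mech,
            )
            completed[nd_rows, nd_cols] = e_w
        mu = theta[:, codes] + delta[None, :]
        sq = np.where(det, (ds.cq - mu) ** 2, 0.0)
        if any_nd:
            cell_mu = mu[nd_rows, nd_cols]
            sq[nd_rows, nd_cols] = e_w2 - 2.0 * e_w * cell_mu + cell_mu**2
        sigma2 = np.maximum(sq.mean(axis=1), 1e-10)

        # CM-step C: re-estimate the pooled mechanism from all information,
        # with the E-step refreshed at the just-updated (theta, sigma2)
        if update_mech:
            e_w, _, _, _, (nodes_x, nodes_w) = nondetect_moments_many(
                _cell_params(theta, delta, codes, nd_rows, nd_cols),
                sigma2[nd_rows], mech, return_nodes=True,
            )
            completed[nd_rows, nd_cols] = e_w
            mech = _mech_cm_step(
                mech, y_det, nodes_x.ravel(), nodes_w.ravel(), xbar, sx, regularize
            )

    # polish sigma2 to a fixed point of its own update map (theta and the
    # mechanism held fixed): guarantees that the stored variances equal the
    # ML variance formula evaluated at the stored parameters, so the
    # MLE-vs-SI variance-gap identity holds to numerical precision
    if any_nd:
        mu = theta[:, codes] + delta[None, :]
        sq_det = np.where(det, (ds.cq - mu) ** 2, 0.0)
        cell_mu = mu[nd_rows, nd_cols]
        for _ in range(100):
            e_w, e_w2, _, _ = nondetect_moments_many(cell_mu, sigma2[nd_rows], mech)
            sq = sq_det.copy()
            sq[nd_rows, nd_cols] = e_w2 - 2.0 * e_w * cell_mu + cell_mu**2
            new_sigma2 = np.maximum(sq.mean(axis=1), 1e-10)
            done = np.abs(new_sigma2 - sigma2).max() <= 1e-13 * (1.0 + sigma2.max())
            sigma2 = new_sigma2
            if done:
                break

    if not update_mech:
        pass
    else:
        # sampling covariance of (beta0, beta1) at the fixed point, from the
        # observed information of the (penalized) pooled binary regression
        mech = MissingMechanism(
            link=mech.link, beta0=mech.beta0, beta1=mech.beta1,
            beta_cov=penalized_cov_at(completed, ~det, mech.link,
                                      (mech.beta0, mech.beta1)),
            detection_limit=mech.detection_limit,
        )
    if not converged:
        logger.warning("ECM did not converge in %d iterations", max_iter)
    logger.info("ECM finished: %d iterations, loglik=%.6f, converged=%s",
                n_iter, trace[-1], converged)
    fit = FitResult(
        theta=theta, sigma2=sigma2, delta=delta,
        loglik_trace=np.asarray(trace), converged=converged, n_iter=n_iter,
        groups=groups, genes=ds.genes.copy(),
    )
    return fit, mech


def conditional_expectations(ds: QpcrDataset, fit: FitResult, mech) -> np.ndarray:
    """Completed Cq matrix with each non-detect at E(W | Z=0) under ``fit``.

    Detected cells are returned unchanged; this is the single-imputation
    completion at the ECM fixed point.
    """
    codes, _ = ds.group_codes()
    completed = ds.cq.copy()
    nd_rows, nd_cols = np.nonzero(~ds.detected)
    if nd_rows.size:
        e_w, _, _, _ = nondetect_moments_many(
            _cell_params(fit.theta, fit.delta, codes, nd_rows, nd_cols),
            fit.sigma2[nd_rows], mech,
        )
        completed[nd_rows, nd_cols] = e_w
    return completed
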