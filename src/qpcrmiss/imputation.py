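"""Mean, single, and multiple imputation of qPCR non-detects.

Single imputation (SI) replaces each non-detect by its conditional
expectation E(W | Z=0) at the ECM fixed point; it preserves means but
understates the residual variance because every imputed value sits
exactly at its conditional mean.  Multiple imputation (MI) instead
produces M completed datasets whose spread encodes the imputation
uncertainty, decomposed into three selectable sources:

``fit``
    uncertainty in the detection mechanism -- (beta0, beta1) are redrawn
    from their joint normal sampling distribution;
``theta``
    uncertainty in the expression means -- theta is redrawn from
    N(theta_hat, se(theta_hat)) per (gene, group);
``epsilon``
    biological variability and measurement error -- mean-zero normal
    noise with the gene's residual variance is added to each imputed
    value.

Parameters are drawn first, the conditional expectation of each
non-detect is recomputed under the drawn parameters, and the residual
noise is added last, so the three sources act independently.  The seed
fully determines the output.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dataset import QpcrDataset
from .direct import direst
from .ecm import FitResult, _cell_params, conditional_expectations
from .mechanism import MissingMechanism, draw_mechanism
from .moments import nondetect_moments_many

_VALID_SOURCES = frozenset({"fit", "theta", "epsilon"})


@dataclasses.dataclass
class ImputationSet:
    """M completed Cq matrices plus the provenance of their randomness."""

    completed: list[np.ndarray]
    sources: frozenset
    m: int
    seed: int | None
    base_fit: FitResult | None
    base_mech: MissingMechanism | None

    def __post_init__(self):
        self.sources = frozenset(self.sources)
        bad = self.sources - _VALID_SOURCES
        if bad:
            raise ValueError(f"unknown uncertainty sources: {sorted(bad)}")


def mean_impute(ds: QpcrDataset) -> ImputationSet:
    """Replace each non-detect by its (gene, group) detected-replicate mean.

    The no-model baseline: ignores the missingness mechanism entirely and
    therefore underestimates both the group means (non-detects sit above
    the detected mean on the Cq scale) and the residual variance.
    """
    ds = ds.copy().validate()
    codes, groups = ds.group_codes()
    from .ecm import _group_means

    means, _ = _group_means(np.where(ds.detected, ds.cq, 0.0), ds.detected, codes, len(groups))
    completed = np.where(ds.detected, ds.cq, means[:, codes])
    return ImputationSet(
        completed=[completed], sources=frozenset(), m=1, seed=None,
        base_fit=None, base_mech=None,
    )


def si_impute(ds: QpcrDataset, link: str = "logit", **ecm_kwargs) -> ImputationSet:
    """Single imputation at the ECM fixed point (MNAR-aware).

    Each non-detect becomes E(W | Z=0) under the fitted model.  The
    sample variance of the completed data equals the ML variance minus
    the per-gene variance gap.
    """
    ds = ds.copy().validate()
    fit, mech = direst(ds, link=link, **ecm_kwargs)
    completed = conditional_expectations(ds, fit, mech)
    return ImputationSet(
        completed=[completed], sources=frozenset(), m=1, seed=None,
        base_fit=fit, base_mech=mech,
    )


def mi_impute(
    ds: QpcrDataset,
    link: str = "logit",
    m: int = 10,
    sources=("fit", "theta", "epsilon"),
    seed: int | None = None,
    _fitted: tuple[FitResult, MissingMechanism] | None = None,
    **ecm_kwargs,
) -> ImputationSet:
    """Multiple imputation with selectable uncertainty sources.

    ``m = 1`` with no sources degenerates to single imputation.  The
    fitted mechanism is perturbed, not refit, for the ``fit`` source.
    """
    sources = frozenset(sources)
    if m < 1:
        raise ValueError("m must be >= 1")
    if not sources and m > 1:
        raise ValueError("sources must be non-empty for m > 1 (use si_impute for m = 1)")
    bad = sources - _VALID_SOURCES
    if bad:
        raise ValueError(f"unknown uncertainty sources: {sorted(bad)}")
    ds = ds.copy().validate()
    if _fitted is not None:
        fit, mech = _fitted
        if fit.se_theta is None and "theta" in sources:
            raise ValueError("prefitted result lacks se_theta")
    else:
        fit, mech = direst(ds, link=link, **ecm_kwargs)
    rng = np.random.default_rng(seed)
    codes, _ = ds.group_codes()
    nd_rows, nd_cols = np.nonzero(~ds.detected)
    completed_sets = []
    for _ in range(m):
        mech_m = draw_mechanism(mech, rng) if "fit" in sources else mech
        if "theta" in sources:
            theta_m = fit.theta + fit.se_theta * rng.standard_normal(fit.theta.shape)
        else:
            theta_m = fit.theta
        completed = ds.cq.copy()
        if nd_rows.size:
            e_w, _, _, _ = nondetect_moments_many(
                _cell_params(theta_m, fit.delta, codes, nd_rows, nd_cols),
                fit.sigma2[nd_rows], mech_m,
            )
            if "epsilon" in sources:
                e_w = e_w + np.sqrt(fit.sigma2[nd_rows]) * rng.standard_normal(nd_rows.size)
            completed[nd_rows, nd_cols] = e_w
        completed_sets.append(completed)
    return ImputationSet(
        completed=completed_sets, sources=sources, m=m, seed=seed,
        base_fit=fit, base_mech=mech,
    )


def pool_estimates(imps: ImputationSet, estimator):
    """Combine a per-dataset statistic across imputations by Rubin's rules.

    ``estimator(completed_matrix)`` must return either a point-estimate
    array or an ``(estimate, variance)`` pair.  Returns a dict with the
    pooled point estimate, within- and between-imputation variances, and
    the total variance ``within + (1 + 1/M) * between``.
    """
    if imps.m < 2:
        raise ValueError("pooling requires M >= 2; use single imputation for M = 1")
    ests, variances = [], []
    for mat in imps.completed:
        out = estimator(mat)
        if isinstance(out, tuple):
            est, var = out
        else:
            est, var = out, np.zeros_like(np.asarray(out, dtype=float))
        ests.append(np.asarray(est, dtype=float))
        variances.append(np.asarray(var, dtype=float))
    ests = np.stack(ests)
    variances = np.stack(variances)
    point = ests.mean(axis=0)
    within = variances.mean(axis=0)
    between = ests.var(axis=0, ddof=1)
    total = within + (1.0 + 1.0 / imps.m) * between
    return {"estimate": point, "within": within, "between": between, "total": total}


def group_mean_estimator(ds: QpcrDataset):
    """Estimator factory for :func:`pool_estimates`: per-(gene, group)
    means of a completed matrix with their sampling variances s^2/n."""
    codes, groups = ds.group_codes()
    K = len(groups)

    def estimator(mat):
        mat = np.asarray(mat, dtype=float)
        means = np.empty((mat.shape[0], K))
        variances = np.empty_like(means)
        for k in range(K):
            cols = codes == k
            sub = mat[:, cols]
            means[:, k] = sub.mean(axis=1)
            variances[:, k] = sub.var(axis=1, ddof=1) / cols.sum()
        return means, variances

    return estimator
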