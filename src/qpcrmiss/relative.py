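"""Relative quantification with matched controls and batch effects.

When each batch of test samples ships with a matched control, the
quantity of interest is the expression difference Delta between a test
sample-type and its control (the delta-Cq contrast), and the control
samples double as anchors for per-(gene, batch) offsets gamma::

    X_ij = Delta_{i k(j)} + gamma_{i n(j)} + eps_ij    test samples
    X_ij =                  gamma_{i n(j)} + eps_ij    control samples

with Delta = 0 for the control group by construction.  Non-detects can
occur in controls too, so fitting is a two-step process: (1) handle the
control samples alone under the absolute model, with batches playing the
role of sample types, producing one (or M, for multiple imputation)
completed control set(s); (2) fit the model above to all samples, with
controls completed from step 1 and test-sample non-detects handled by
the same conditional-expectation machinery as the absolute fit.  gamma
is estimated from the control samples within each batch, which the
matched design makes the natural anchor; the global sample shifts are
fixed at zero.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .dataset import QpcrDataset
from .ecm import _group_means
from .errors import ValidationError
from .imputation import mi_impute, si_impute
from .mechanism import MissingMechanism, fit_mechanism
from .moments import nondetect_moments_many

logger = logging.getLogger(__name__)

_LOG_SQRT2PI = 0.5 * np.log(2.0 * np.pi)


@dataclasses.dataclass
class RelativeFit:
    """Estimates of the relative-quantification model.

    ``delta_expr`` covers the non-control sample types (the control
    contrast is identically zero -- see :meth:`delta_full`); ``gamma``
    is per (gene, batch); ``sigma2`` per gene.  ``provenance`` records
    which non-detect handling was used in each step.
    """

    delta_expr: np.ndarray  # (genes, non-control groups)
    gamma: np.ndarray  # (genes, batches)
    sigma2: np.ndarray  # (genes,)
    genes: np.ndarray
    test_groups: np.ndarray
    batches: np.ndarray
    control_group: str
    provenance: dict

    def delta_full(self) -> tuple[np.ndarray, list]:
        """Delta including the control column, which is exactly zero."""
        zero = np.zeros((self.delta_expr.shape[0], 1))
        return (
            np.hstack([zero, self.delta_expr]),
            [self.control_group, *self.test_groups],
        )


def _check_annotations(ds: QpcrDataset):
    if ds.is_control is None or ds.batch is None:
        raise ValidationError("relative quantification needs is_control and batch annotations")
    batches, idx = np.unique(ds.batch, return_index=True)
    batches = ds.batch[np.sort(idx)]
    for b in batches:
        if not (ds.is_control & (ds.batch == b)).any():
            raise ValidationError(f"batch {b!r} has no control sample; gamma is unidentifiable")
    return batches


def _fit_step2(ds, control_completed, mech_link, max_iter=200, tol=1e-8):
    """ECM fit of Delta/gamma/sigma2 on all samples, controls completed."""
    ctrl = ds.is_control
    batches, bidx = np.unique(ds.batch, return_index=True)
    batches = ds.batch[np.sort(bidx)]
    bcode = np.array([list(batches).index(b) for b in ds.batch])
    t_types_all = ds.sample_type[~ctrl]
    _, tidx = np.unique(t_types_all, return_index=True)
    test_groups = t_types_all[np.sort(tidx)]
    kcode = np.full(ds.n_samples, -1)
    for k, g in enumerate(test_groups):
        kcode[(~ctrl) & (ds.sample_type == g)] = k
    K, B = len(test_groups), len(batches)
    G = ds.n_genes

    det = ds.detected.copy()
    completed = np.where(det, ds.cq, 0.0)
    completed[:, ctrl] = control_completed
    obs_mask = det | ctrl[None, :]  # control cells are treated as observed data
    nd_rows, nd_cols = np.nonzero(~obs_mask)  # test-sample non-detects
    # offenders: test (gene, group) with nothing observed
    for k, g in enumerate(test_groups):
        cols = (~ctrl) & (kcode == k)
        bad = ~det[:, cols].any(axis=1)
        if bad.any():
            raise ValidationError(
                f"all replicates non-detect for genes {list(ds.genes[bad][:5])} "
                f"in test group {g!r}"
            )

    ctrl_mask = np.zeros_like(obs_mask)
    ctrl_mask[:, ctrl] = True
    gamma, _ = _group_means(completed, ctrl_mask, bcode, B)
    # initialize test non-detects from detected group means
    delta = np.zeros((G, K))
    mu_of = lambda: np.where(
        ctrl[None, :], gamma[:, bcode],
        gamma[:, bcode] + np.where(kcode[None, :] >= 0, delta[:, np.maximum(kcode, 0)], 0.0),
    )
    resid0 = completed - gamma[:, bcode]
    test_mask = obs_mask & ~ctrl[None, :]
    delta, _ = _group_means(resid0, test_mask, np.maximum(kcode, 0), K)
    completed[nd_rows, nd_cols] = mu_of()[nd_rows, nd_cols]
    sigma2 = np.maximum(np.mean((completed - mu_of()) ** 2, axis=1), 1e-6)
    mech = fit_mechanism(completed, det, link=mech_link, regularize=True,
                         detection_limit=ds.detection_limit)

    prev = -np.inf
    trace = []
    for it in range(max_iter):
        mu = mu_of()
        if nd_rows.size:
            e_w, e_w2, log_m0, _ = nondetect_moments_many(
                mu[nd_rows, nd_cols], sigma2[nd_rows], mech
            )
            completed[nd_rows, nd_cols] = e_w
        else:
            log_m0 = np.zeros(0)
        with np.errstate(divide="ignore"):
            normal = (
                -_LOG_SQRT2PI - 0.5 * np.log(sigma2[:, None])
                - 0.5 * (completed - mu) ** 2 / sigma2[:, None]
            )
            pdet = np.log(np.clip(mech.detect_prob(ds.cq), 1e-300, None))
        ll = normal[obs_mask].sum() + np.where(det, pdet, 0.0)[det].sum() + log_m0.sum()
        trace.append(ll)
        if abs(ll - prev) <= tol * (1.0 + abs(ll)):
            break
        prev = ll
        # CM: gamma from controls, Delta from test samples, sigma2 pooled
        gamma, _ = _group_means(completed, ctrl_mask, bcode, B)
        resid = completed - gamma[:, bcode]
        delta, _ = _group_means(
            resid, ~ctrl[None, :] & np.ones_like(obs_mask), np.maximum(kcode, 0), K
        )
        if nd_rows.size:
            mu = mu_of()
            e_w, e_w2, _, _ = nondetect_moments_many(
                mu[nd_rows, nd_cols], sigma2[nd_rows], mech
            )
            completed[nd_rows, nd_cols] = e_w
            sq = (completed - mu) ** 2
            cm = mu[nd_rows, nd_cols]
            sq[nd_rows, nd_cols] = e_w2 - 2.0 * e_w * cm + cm**2
        else:
            sq = (completed - mu_of()) ** 2
        sigma2 = np.maximum(sq.mean(axis=1), 1e-10)
        mech = fit_mechanism(completed, det, link=mech_link, regularize=True,
                             detection_limit=ds.detection_limit, start=mech)
    return delta, gamma, sigma2, test_groups, batches, trace


def relative_fit(
    ds: QpcrDataset,
    method: str = "direst",
    link: str = "logit",
    mi_opts: dict | None = None,
) -> RelativeFit:
    """Two-step fit of the relative-quantification model.

    Step 1 handles control-sample non-detects under the absolute model
    restricted to controls (batch as the replicate group), using the
    requested method; step 2 fits Delta and gamma jointly on all
    samples.  For ``method="mi"`` step 2 runs once per imputed control
    set and the results are pooled by averaging.
    """
    if method not in ("si", "mi", "direst"):
        raise ValueError("method must be one of 'si', 'mi', 'direst'")
    ds = ds.copy().validate(require_detected_per_group=False)
    batches = _check_annotations(ds)
    ctrl = ds.is_control

    ctrl_ds = ds.subset(sample_mask=ctrl)
    ctrl_ds.sample_type = ctrl_ds.batch.copy()  # gamma: one "group" per batch
    offenders = ctrl_ds.cells_without_detection()
    if offenders:
        raise ValidationError(
            "control samples have all-non-detect genes: "
            + ", ".join(f"({g}, batch {b})" for g, b in offenders[:10])
        )
    mi_opts = {**{"m": 10, "sources": ("fit", "theta", "epsilon"), "seed": None},
               **(mi_opts or {})}
    if method == "mi" and ctrl_ds.detected.all():
        control_sets = [ctrl_ds.cq.copy()]  # nothing to impute
    elif method == "mi":
        control_sets = mi_impute(ctrl_ds, link=link, **mi_opts).completed
    else:
        control_sets = si_impute(ctrl_ds, link=link).completed

    fits = [
        _fit_step2(ds, completed_ctrl, mech_link=link)
        for completed_ctrl in control_sets
    ]
    delta = np.mean([f[0] for f in fits], axis=0)
    gamma = np.mean([f[1] for f in fits], axis=0)
    sigma2 = np.mean([f[2] for f in fits], axis=0)
    test_groups, batches = fits[0][3], fits[0][4]
    ctrl_types = np.unique(ds.sample_type[ctrl])
    return RelativeFit(
        delta_expr=delta, gamma=gamma, sigma2=sigma2,
        genes=ds.genes.copy(), test_groups=test_groups, batches=batches,
        control_group=str(ctrl_types[0]) if len(ctrl_types) else "control",
        provenance={
            "step1": method, "step2": method, "link": link,
            "n_control_sets": len(control_sets),
            **({"mi": mi_opts} if method == "mi" else {}),
        },
    )
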