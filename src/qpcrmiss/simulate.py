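"""Synthetic qPCR data under the MNAR generative model, plus hard masking.

The generator reproduces the study conditions used to benchmark the
estimators: per gene a grand mean ``mu_theta`` is drawn from a truncated
normal (mean 31, sd 3.5, range [20, 40.5] cycles); sample-type means
theta are drawn i.i.d. around it with variance sigma2_theta = 3; the
per-gene residual variances come from Unif(0.06, 1.3); sample shifts are
zero.  Latent values X = theta + eps are turned into non-detects by a
Bernoulli draw from the logistic mechanism with beta0 = -35.7, beta1 = 1
(non-detect log-odds rising one unit per cycle, crossing 1/2 at Cq 35.7)
and, unconditionally, whenever X >= 40.  Non-detects are written with the
sentinel Cq 40, exactly as instrument software would emit them.

:func:`mask_dataset` implements the complementary assessment device:
starting from a fully observed dataset it imposes a new, lower detection
limit and masks every value above it, returning the removed values as
ground truth.  Masked cells are encoded identically to real non-detects
so estimators are blind to their origin.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import QpcrDataset
from .mechanism import LINKS

logger = logging.getLogger(__name__)

DEFAULTS = dict(
    beta0=-35.7,
    beta1=1.0,
    sigma2_low=0.06,
    sigma2_high=1.3,
    sigma2_theta=3.0,
    mu_theta_mean=31.0,
    mu_theta_sd=3.5,
    mu_theta_range=(20.0, 40.5),
    detection_limit=40.0,
)


@dataclasses.dataclass
class SimulationTruth:
    """Generating parameters paired with a simulated dataset for scoring."""

    theta: np.ndarray  # (genes, groups)
    mu_theta: np.ndarray  # per-gene grand means
    sigma2: np.ndarray  # per-gene residual variances
    beta0: float
    beta1: float
    detection_limit: float
    link: str = "logit"
    seed: int | None = None


def draw_truth(
    n_genes: int = 16,
    n_groups: int = 6,
    rng: np.random.Generator | None = None,
    **overrides,
) -> SimulationTruth:
    """Draw one set of generating parameters (theta, sigma2, mechanism)."""
    p = {**DEFAULTS, **{k: v for k, v in overrides.items() if v is not None}}
    lo, hi = p["mu_theta_range"]
    if not lo < hi:
        raise ValueError(f"invalid truncation range {p['mu_theta_range']}")
    rng = np.random.default_rng(rng)
    a = (lo - p["mu_theta_mean"]) / p["mu_theta_sd"]
    b = (hi - p["mu_theta_mean"]) / p["mu_theta_sd"]
    mu_theta = stats.truncnorm.rvs(
        a, b, loc=p["mu_theta_mean"], scale=p["mu_theta_sd"],
        size=n_genes, random_state=rng,
    )
    theta = rng.normal(mu_theta[:, None], np.sqrt(p["sigma2_theta"]), (n_genes, n_groups))
    sigma2 = overrides.get("sigma2")
    if sigma2 is None:
        sigma2 = rng.uniform(p["sigma2_low"], p["sigma2_high"], n_genes)
    else:
        sigma2 = np.broadcast_to(np.asarray(sigma2, dtype=float), (n_genes,)).copy()
    return SimulationTruth(
        theta=theta, mu_theta=mu_theta, sigma2=sigma2,
        beta0=p["beta0"], beta1=p["beta1"],
        detection_limit=p["detection_limit"],
    )


def simulate_dataset(
    n_genes: int = 16,
    n_groups: int = 6,
    m: int = 6,
    seed=None,
    truth: SimulationTruth | None = None,
    rng: np.random.Generator | None = None,
    **overrides,
) -> tuple[QpcrDataset, SimulationTruth]:
    """Simulate one genes x (groups * m replicates) dataset.

    When ``truth`` is supplied only the noise (eps) and the missingness
    indicators are redrawn, so repeated calls give replicate experiments
    under identical generating parameters.  Cells are non-detects when
    the Bernoulli mechanism fires or the latent value reaches the
    detection limit; either way they carry the sentinel Cq.

    Note: the dataset is returned unvalidated -- the generator can
    legitimately produce a (gene, sample-type) cell whose replicates are
    all non-detects, which estimators must reject or the caller drop.
    """
    if m < 2:
        raise ValueError("need at least 2 replicates per sample type")
    if rng is None:
        rng = np.random.default_rng(seed)
    if truth is None:
        truth = draw_truth(n_genes, n_groups, rng=rng, **overrides)
        truth.seed = seed
    n_genes, n_groups = truth.theta.shape
    n = n_groups * m
    codes = np.repeat(np.arange(n_groups), m)
    x = rng.normal(truth.theta[:, codes], np.sqrt(truth.sigma2)[:, None])
    inv, _ = LINKS[truth.link]
    p_miss = inv(truth.beta0 + truth.beta1 * x)
    z = rng.random(x.shape) >= p_miss  # True = detected by the mechanism
    detected = z & (x < truth.detection_limit)
    cq = np.where(detected, x, truth.detection_limit)
    ds = QpcrDataset(
        cq=cq,
        detected=detected,
        genes=np.array([f"gene{i + 1:03d}" for i in range(n_genes)], dtype=object),
        samples=np.array([f"s{j + 1:03d}" for j in range(n)], dtype=object),
        sample_type=np.array([f"T{k + 1}" for k in codes], dtype=object),
        detection_limit=truth.detection_limit,
    )
    ds.cq = np.where(detected, cq, np.nan)
    return ds, truth


def mask_dataset(
    ds: QpcrDataset, threshold: float = 30.0
) -> tuple[QpcrDataset, pd.DataFrame]:
    """Impose a lower detection limit on fully observed genes.

    Genes with any pre-existing non-detect are removed; the detection
    limit becomes ``threshold`` and every value strictly greater than it
    is masked (a value exactly at the threshold is retained).  Genes left
    with a (gene, sample-type) cell containing no detected replicate are
    dropped with a logged warning, since no estimator can handle them.

    Returns the masked dataset and a table of the removed true values
    for scoring recovery.
    """
    complete = ds.detected.all(axis=1)
    if not complete.all():
        logger.info("removing %d genes with pre-existing non-detects", (~complete).sum())
    sub = ds.subset(gene_mask=complete)
    masked = sub.cq > threshold
    detected = sub.detected & ~masked

    codes, groups = sub.group_codes()
    ok = np.ones(sub.n_genes, bool)
    for k in range(len(groups)):
        cols = codes == k
        ok &= detected[:, cols].any(axis=1)
    if not ok.all():
        logger.warning(
            "masking at %.3g left %d genes with an all-masked sample type; dropping them",
            threshold, int((~ok).sum()),
        )
    truth_rows = []
    g_idx, s_idx = np.nonzero(masked & ok[:, None])
    for i, j in zip(g_idx, s_idx):
        truth_rows.append({"gene": sub.genes[i], "sample": sub.samples[j], "cq_true": sub.cq[i, j]})
    out = sub.subset(gene_mask=ok)
    out.detected = detected[ok]
    out.cq = np.where(out.detected, out.cq, np.nan)
    out.detection_limit = float(threshold)
    return out, pd.DataFrame(truth_rows, columns=["gene", "sample", "cq_true"])
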