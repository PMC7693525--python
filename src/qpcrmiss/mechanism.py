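"""The missing-data (detection) mechanism for qPCR non-detects.

The probability that a reaction fails to produce a Cq value is modelled as
a two-parameter sigmoid in the latent Cq value x::

    Pr(non-detect | x) = h(beta0 + beta1 * x)   for x <  S
    Pr(non-detect | x) = 1                      for x >= S

with h the inverse link (logistic by default) and S the hard detection
limit.  beta0 is thus the log-odds (logit link) of a non-detect at x = 0
and beta1 the log odds-ratio per cycle; with beta1 > 0 lowly expressed
targets (high Cq) are more likely to drop out, and detection probability
1 - h(.) is monotone non-increasing in Cq.  Above S detection is
impossible regardless of the sigmoid.

A single mechanism is shared by all genes and samples and is estimated by
pooling every reaction.  Because completed datasets can exhibit perfect
separation between detected and non-detected values (notably after hard
truncation), the default fit maximizes a penalized likelihood with the
weakly-informative heavy-tailed priors of the standardized-coefficient
approach: Cauchy(0, 10) on the intercept and Cauchy(0, 2.5) on the slope
after centering the predictor and scaling it to standard deviation 0.5.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import optimize, special, stats

from .errors import SeparationError

logger = logging.getLogger(__name__)

_CAUCHY_SCALE_INTERCEPT = 10.0
_CAUCHY_SCALE_SLOPE = 2.5


# -- link functions ---------------------------------------------------------

def _logit_inv(eta):
    return special.expit(eta)


def _logit_dinv(eta):
    p = special.expit(eta)
    return p * (1.0 - p)


def _probit_inv(eta):
    return special.ndtr(eta)


def _probit_dinv(eta):
    return np.exp(-0.5 * eta**2) / np.sqrt(2.0 * np.pi)


def _cloglog_inv(eta):
    return -np.expm1(-np.exp(np.clip(eta, -700, 30)))


def _cloglog_dinv(eta):
    eta = np.clip(eta, -700, 30)
    return np.exp(eta - np.exp(eta))


LINKS = {
    "logit": (_logit_inv, _logit_dinv),
    "probit": (_probit_inv, _probit_dinv),
    "cloglog": (_cloglog_inv, _cloglog_dinv),
}


@dataclasses.dataclass
class MissingMechanism:
    """Sigmoidal non-detect probability with a hard limit at S.

    ``beta_cov`` is the 2x2 covariance of (beta0, beta1) from the observed
    information of the (penalized) fit; it drives the mechanism-uncertainty
    source of multiple imputation.
    """

    link: str = "logit"
    beta0: float = 0.0
    beta1: float = 0.0
    beta_cov: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros((2, 2)))
    detection_limit: float = 40.0

    #: locations below S where the detection curve is non-smooth (none for
    #: the sigmoid links); quadrature splits at these points.
    breakpoints: tuple = ()

    def __post_init__(self):
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}; choose from {sorted(LINKS)}")
        self.beta_cov = np.asarray(self.beta_cov, dtype=float)

    def nondetect_prob(self, x):
        """Pr(Z = 0 | X = x); exactly 1 at and above the detection limit."""
        x = np.asarray(x, dtype=float)
        inv, _ = LINKS[self.link]
        p = inv(self.beta0 + self.beta1 * x)
        return np.where(x >= self.detection_limit, 1.0, p)

    def detect_prob(self, x):
        """Pr(Z = 1 | X = x) in [0, 1]; exactly 0 at and above S."""
        return 1.0 - self.nondetect_prob(x)

    @property
    def crossing(self) -> float:
        """Cq at which the sigmoid crosses probability 1/2 (logit/probit)."""
        if self.beta1 == 0:
            return np.nan
        if self.link == "cloglog":
            return (np.log(np.log(2.0)) - self.beta0) / self.beta1
        return -self.beta0 / self.beta1


@dataclasses.dataclass
class StepMechanism:
    """Detection certain below a cutoff, impossible at or above it.

    The limiting case of an infinitely steep sigmoid; this is what hard
    truncation of a complete dataset induces, and it makes the non-detect
    conditional distribution an exactly truncated normal.
    """

    cutoff: float
    detection_limit: float = 40.0

    @property
    def breakpoints(self) -> tuple:
        return (self.cutoff,)

    def nondetect_prob(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x >= min(self.cutoff, self.detection_limit), 1.0, 0.0)

    def detect_prob(self, x):
        return 1.0 - self.nondetect_prob(x)


# -- estimation -------------------------------------------------------------

def standardizer(x) -> tuple[float, float]:
    """Center and scale used by the weakly-informative prior (fixed per fit)."""
    x = np.asarray(x, dtype=float)
    return float(x.mean()), float(x.std())


def log_prior(beta0: float, beta1: float, xbar: float, sx: float):
    """Cauchy log-prior on the standardized coefficients, at raw-scale beta.

    Standardization maps beta to (b0, b1) = (beta0 + beta1*xbar,
    beta1 * 2 * sx), i.e. the intercept at the predictor mean and the
    slope per two standard deviations.
    """
    b0 = beta0 + beta1 * xbar
    b1 = beta1 * 2.0 * sx
    return (
        stats.cauchy.logpdf(b0, scale=_CAUCHY_SCALE_INTERCEPT)
        + stats.cauchy.logpdf(b1, scale=_CAUCHY_SCALE_SLOPE)
    )


def log_prior_grad(beta0: float, beta1: float, xbar: float, sx: float):
    b0 = beta0 + beta1 * xbar
    b1 = beta1 * 2.0 * sx
    d0 = -2.0 * b0 / (_CAUCHY_SCALE_INTERCEPT**2 + b0**2)
    d1 = -2.0 * b1 / (_CAUCHY_SCALE_SLOPE**2 + b1**2)
    return np.array([d0, d0 * xbar + d1 * 2.0 * sx])


def penalized_cov_at(x, y, link, beta):
    """Covariance of (beta0, beta1) from the observed information of the
    penalized Bernoulli log-likelihood, evaluated at ``beta``."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=bool).ravel()
    inv, dinv = LINKS[link]
    xbar, sx = standardizer(x)

    def grad(b):
        eta = b[0] + b[1] * x
        p = np.clip(inv(eta), 1e-12, 1 - 1e-12)
        w = (y - p) * dinv(eta) / (p * (1.0 - p))
        g = np.array([w.sum(), (w * x).sum()]) + log_prior_grad(b[0], b[1], xbar, sx)
        return -g

    b = np.asarray(beta, dtype=float)
    h = 1e-6 * np.maximum(np.abs(b), 1.0)
    H = np.empty((2, 2))
    for i in range(2):
        e = np.zeros(2)
        e[i] = h[i]
        H[:, i] = (grad(b + e) - grad(b - e)) / (2.0 * h[i])
    H = 0.5 * (H + H.T)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((2, 2), np.nan)


def _penalized_fit(x, y, link, start=None):
    """Maximize Bernoulli log-likelihood + Cauchy log-priors on standardized
    coefficients. Returns (beta, cov) on the raw Cq scale."""
    inv, dinv = LINKS[link]
    xbar = x.mean()
    sx = x.std()
    if sx == 0:
        raise SeparationError("mechanism predictor is constant")
    xs = (x - xbar) / (2.0 * sx)

    def negpost(b):
        eta = b[0] + b[1] * xs
        p = np.clip(inv(eta), 1e-12, 1 - 1e-12)
        ll = np.sum(np.where(y, np.log(p), np.log1p(-p)))
        lp = (
            stats.cauchy.logpdf(b[0], scale=_CAUCHY_SCALE_INTERCEPT)
            + stats.cauchy.logpdf(b[1], scale=_CAUCHY_SCALE_SLOPE)
        )
        return -(ll + lp)

    def grad(b):
        eta = b[0] + b[1] * xs
        p = np.clip(inv(eta), 1e-12, 1 - 1e-12)
        w = (y - p) * dinv(eta) / (p * (1.0 - p))
        g0 = w.sum() - 2.0 * b[0] / (_CAUCHY_SCALE_INTERCEPT**2 + b[0] ** 2)
        g1 = (w * xs).sum() - 2.0 * b[1] / (_CAUCHY_SCALE_SLOPE**2 + b[1] ** 2)
        return -np.array([g0, g1])

    if start is not None:
        b0 = np.array([start[0] + start[1] * xbar, start[1] * 2.0 * sx])
    else:
        b0 = np.array([special.logit(np.clip(y.mean(), 1e-3, 1 - 1e-3)), 0.0])
    res = optimize.minimize(negpost, b0, jac=grad, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    b = res.x
    # observed information by finite differences of the analytic gradient
    h = 1e-5 * np.maximum(np.abs(b), 1.0)
    H = np.empty((2, 2))
    for i in range(2):
        e = np.zeros(2)
        e[i] = h[i]
        H[:, i] = (grad(b + e) - grad(b - e)) / (2.0 * h[i])
    H = 0.5 * (H + H.T)
    try:
        cov_std = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_std = np.full((2, 2), np.nan)
    # back-transform to the raw Cq scale: beta1 = b1/(2 sx), beta0 = b0 - b1*xbar/(2 sx)
    J = np.array([[1.0, -xbar / (2.0 * sx)], [0.0, 1.0 / (2.0 * sx)]])
    beta = J @ b
    cov = J @ cov_std @ J.T
    return beta, cov


def _glm_fit(x, y, link):
    import statsmodels.api as sm

    links = {
        "logit": sm.genmod.families.links.Logit(),
        "probit": sm.genmod.families.links.Probit(),
        "cloglog": sm.genmod.families.links.CLogLog(),
    }
    model = sm.GLM(y.astype(float), sm.add_constant(x), family=sm.families.Binomial(links[link]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200)
        except Exception as exc:  # PerfectSeparationError and numeric failures
            raise SeparationError(f"mechanism GLM failed to converge: {exc}") from exc
    beta = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if (
        not np.all(np.isfinite(beta))
        or not np.all(np.isfinite(cov))
        or np.abs(beta).max() > 1e6
        or bse.max() > 1e3  # unbounded likelihood: standard errors explode
    ):
        raise SeparationError("mechanism GLM estimates diverged (perfect separation?)")
    return beta, cov


def fit_mechanism(
    cq_completed,
    detected,
    link: str = "logit",
    regularize: bool = True,
    detection_limit: float = 40.0,
    start: MissingMechanism | None = None,
) -> MissingMechanism:
    """Fit the pooled non-detect mechanism on completed data.

    ``cq_completed`` must hold a value for every cell: the observed Cq for
    detected reactions and the current conditional expectation for
    non-detects.  The binary response is the non-detect indicator (1 - Z),
    regressed on Cq pooled across all genes and samples, since one common
    mechanism is assumed for the whole experiment.

    With ``regularize=True`` (default) the weakly-informative-prior fit is
    used, which stays finite under perfect separation; otherwise an
    ordinary GLM is fit and separation raises :class:`SeparationError`.
    """
    x = np.asarray(cq_completed, dtype=float).ravel()
    y = (~np.asarray(detected, dtype=bool)).ravel()  # 1 = non-detect
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    if (y.all() or not y.any()) and not regularize:
        raise SeparationError("only one response class present; "
                              "use regularize=True for a proper fit")
    if regularize:
        beta, cov = _penalized_fit(x, y, link,
                                   start=None if start is None else (start.beta0, start.beta1))
    else:
        beta, cov = _glm_fit(x, y, link)
    return MissingMechanism(
        link=link, beta0=float(beta[0]), beta1=float(beta[1]),
        beta_cov=cov, detection_limit=detection_limit,
    )


def draw_mechanism(mech: MissingMechanism, rng: np.random.Generator) -> MissingMechanism:
    """Draw (beta0, beta1) jointly from MVN(beta_hat, beta_cov).

    Used by multiple imputation to propagate uncertainty in the estimated
    mechanism.  A singular covariance falls back to a degenerate draw at
    the point estimate, with a warning.
    """
    cov = np.asarray(mech.beta_cov, dtype=float)
    mean = np.array([mech.beta0, mech.beta1])
    try:
        L = np.linalg.cholesky(cov)
        draw = mean + L @ rng.standard_normal(2)
    except np.linalg.LinAlgError:
        if not np.allclose(cov, 0.0):
            warnings.warn("singular beta_cov; drawing at the point estimate")
        draw = mean
    return MissingMechanism(
        link=mech.link, beta0=float(draw[0]), beta1=float(draw[1]),
        beta_cov=cov, detection_limit=mech.detection_limit,
    )
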