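"""Conditional moments of a non-detected Cq value.

Given the absolute-quantification model, a cell's latent Cq value W is
normal with mean mu and variance sigma2; conditioning on the reaction
being a non-detect reweights that normal by the non-detect probability::

    f(w | Z=0)  proportional to  N(w; mu, sigma2) * Pr(Z=0 | w)

where Pr(Z=0|w) is the mechanism sigmoid below the detection limit S and
exactly 1 at and above it.  The E-step of the ECM algorithm, the single
and multiple imputation procedures, and the MLE-vs-SI variance gap all
consume E(W | Z=0) and E(W^2 | Z=0).

The weighted part on (-inf, S) is integrated numerically; the hard tail
on [S, inf), where the weight is identically 1, is added in closed form
from the normal tail moments.  Two integrators are provided: an adaptive
scalar routine (relative tolerance 1e-8, splitting at any mechanism
breakpoints such as a step cutoff) and a fast vectorized fixed-panel
Gauss-Legendre scheme used inside the ECM loop, with extra panels placed
across the sigmoid transition so that steep mechanisms (e.g. after hard
masking) remain accurately resolved.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import integrate, special

from .errors import ConvergenceError

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclasses.dataclass
class ConditionalMoments:
    """First two conditional moments of a non-detected value (cycles)."""

    e_w: float
    e_w2: float
    mass_below_limit: float

    @property
    def var(self) -> float:
        """Conditional variance E(W^2) - E(W)^2; positive by Jensen."""
        return self.e_w2 - self.e_w**2


def _normal_tail(mu, sigma, s):
    """Zeroth/first/second moments of N(mu, sigma^2) restricted to [s, inf)."""
    alpha = (s - mu) / sigma
    m0 = special.ndtr(-alpha)
    phi = np.exp(-0.5 * alpha**2) / _SQRT2PI
    m1 = mu * m0 + sigma * phi
    m2 = (mu**2 + sigma**2) * m0 + sigma * (s + mu) * phi
    return m0, m1, m2


def nondetect_moments(mu: float, sigma2: float, mech) -> ConditionalMoments:
    """Adaptive-quadrature conditional moments for a single cell.

    ``mech`` is any object exposing ``nondetect_prob(x)``, a
    ``detection_limit`` and optionally ``breakpoints`` (locations where
    the weight is non-smooth, used to split the integration interval).
    """
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    sigma = np.sqrt(sigma2)
    s = mech.detection_limit
    lo = mu - 12.0 * sigma
    hi = min(mu + 12.0 * sigma, s)
    below = np.zeros(3)
    if lo < hi:
        pts = [p for p in getattr(mech, "breakpoints", ()) if lo < p < hi]

        def integrand(x, k):
            z = (x - mu) / sigma
            dens = np.exp(-0.5 * z * z) / (_SQRT2PI * sigma)
            return (x - mu) ** k * dens * mech.nondetect_prob(x)

        for k in range(3):
            val, err = integrate.quad(
                integrand, lo, hi, args=(k,), points=pts or None,
                epsabs=1e-14, epsrel=1e-10, limit=200,
            )
            if not np.isfinite(val):
                raise ConvergenceError(f"quadrature failed for cell (mu={mu}, sigma2={sigma2})")
            below[k] = val
    # recentre: below holds integrals of (x-mu)^k; convert to raw moments
    b0, c1, c2 = below
    b1 = mu * b0 + c1
    b2 = c2 + 2.0 * mu * c1 + mu**2 * b0
    t0, t1, t2 = _normal_tail(mu, sigma, s)
    m0 = b0 + t0
    if m0 < 1e-300:
        raise ConvergenceError(
            f"non-detect probability underflows for cell (mu={mu}, sigma2={sigma2})"
        )
    return ConditionalMoments(
        e_w=(b1 + t1) / m0,
        e_w2=(b2 + t2) / m0,
        mass_below_limit=b0 / m0,
    )


# -- fast vectorized path ---------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(12)
_N_SEG = (8, 12, 8)  # panels: left smooth / sigmoid transition / right smooth


def _panel_edges(lo, a, b, hi):
    """Per-cell panel edges: three segments subdivided into fixed counts."""
    parts = []
    for left, right, n in ((lo, a, _N_SEG[0]), (a, b, _N_SEG[1]), (b, hi, _N_SEG[2])):
        t = np.linspace(0.0, 1.0, n + 1)[None, :]
        parts.append(left[:, None] + (right - left)[:, None] * t[:, :-1])
    edges = np.concatenate(parts + [hi[:, None]], axis=1)
    return edges


def nondetect_moments_many(mu, sigma2, mech, return_nodes: bool = False):
    """Vectorized conditional moments for arrays of cells sharing a mechanism.

    Returns ``(e_w, e_w2, log_m0, mass_below)`` arrays.  ``log_m0`` is the
    log marginal non-detect probability of each cell, which the ECM loop
    uses for its observed-data log-likelihood monitor.  With
    ``return_nodes=True`` a fifth element ``(x_nodes, node_weights)`` is
    appended: the below-limit quadrature nodes of every cell together
    with their normalized conditional weights, so that conditional
    expectations of further functions of W (e.g. the expected
    complete-data log-likelihood of the mechanism parameters) can be
    formed on the same grid.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.sqrt(np.atleast_1d(np.asarray(sigma2, dtype=float)))
    s = mech.detection_limit
    lo = mu - 8.0 * sigma
    hi = np.minimum(mu + 8.0 * sigma, s)
    empty = lo >= hi
    hi = np.maximum(hi, lo)  # degenerate (zero-width) domain when empty

    # place the middle segment across the sigmoid transition
    beta1 = getattr(mech, "beta1", 0.0)
    brk = getattr(mech, "breakpoints", ())
    if beta1 != 0.0 and np.isfinite(mech.crossing):
        halfw = 4.0 / abs(beta1)
        a = np.clip(mech.crossing - halfw, lo, hi)
        b = np.clip(mech.crossing + halfw, lo, hi)
    elif brk:
        # align a panel boundary with the discontinuity (step mechanisms)
        a = np.clip(brk[0], lo, hi)
        b = a.copy()
    else:
        a, b = lo.copy(), hi.copy()

    edges = _panel_edges(lo, a, b, hi)  # (cells, P+1)
    lefts = edges[:, :-1]
    widths = np.diff(edges, axis=1)
    # nodes: (cells, P, Q)
    x = lefts[:, :, None] + 0.5 * widths[:, :, None] * (_GL_NODES[None, None, :] + 1.0)
    w_quad = 0.5 * widths[:, :, None] * _GL_WEIGHTS[None, None, :]
    z = (x - mu[:, None, None]) / sigma[:, None, None]
    dens = np.exp(-0.5 * z * z) / (_SQRT2PI * sigma[:, None, None])
    wt = dens * mech.nondetect_prob(x) * w_quad
    xc = x - mu[:, None, None]
    b0 = wt.sum(axis=(1, 2))
    c1 = (wt * xc).sum(axis=(1, 2))
    c2 = (wt * xc * xc).sum(axis=(1, 2))
    b0[empty] = 0.0
    c1[empty] = 0.0
    c2[empty] = 0.0
    b1 = mu * b0 + c1
    b2 = c2 + 2.0 * mu * c1 + mu**2 * b0
    t0, t1, t2 = _normal_tail(mu, sigma, s)
    m0 = b0 + t0
    if np.any(m0 < 1e-300):
        i = int(np.argmin(m0))
        raise ConvergenceError(
            f"non-detect probability underflows for cell (mu={mu[i]}, sigma2={sigma[i]**2})"
        )
    e_w = (b1 + t1) / m0
    e_w2 = (b2 + t2) / m0
    out = (e_w, e_w2, np.log(m0), b0 / m0)
    if return_nodes:
        wt_norm = np.where(empty[:, None, None], 0.0, wt) / m0[:, None, None]
        out = out + ((x.reshape(len(mu), -1), wt_norm.reshape(len(mu), -1)),)
    return out
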