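"""Frank copula primitives: CDF, density, Kendall's tau and conditional sampling.

The Frank copula is the one-parameter Archimedean family

    C_theta(u, v) = -(1/theta) * log(1 + (e^{-theta u} - 1)(e^{-theta v} - 1)
                                         / (e^{-theta} - 1)),   theta != 0,

which is radially symmetric and supports the full range of positive and
negative dependence.  Its association parameter ``theta`` maps one-to-one
onto Kendall's rank correlation via a Debye-type integral,

    tau(theta) = 1 + (4/theta) * ( (1/theta) * int_0^theta t/(e^t - 1) dt - 1 ),

which is strictly increasing and antisymmetric in ``theta``.  ``theta -> 0``
recovers independence; that limit is routed explicitly because the closed
forms are numerically indeterminate near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "THETA_INDEPENDENCE_GUARD",
    "FrankDependence",
    "kendall_tau",
    "theta_from_tau",
    "frank_cdf",
    "frank_logdensity",
    "frank_density",
    "frank_conditional_inverse",
    "sample_frank",
]

#: below this |theta| the copula is treated as the independence copula
THETA_INDEPENDENCE_GUARD = 1e-6


def _debye1(theta: float) -> float:
    """First Debye-type integral (1/theta) * int_0^theta t/(e^t - 1) dt.

    The integrand has a removable singularity at t = 0 (limit 1), patched
    explicitly so adaptive quadrature remains stable for either sign of theta.
    """

    def integrand(t: float) -> float:
        if abs(t) < 1e-12:
            return 1.0 - t / 2.0
        return t / np.expm1(t)

    value, _ = integrate.quad(integrand, 0.0, theta, limit=400)
    return value / theta


def kendall_tau(theta: float) -> float:
    """Kendall's rank correlation implied by the Frank copula parameter.

    Raises
    ------
    ValueError
        If ``theta`` is zero; callers must use the independence limit tau = 0.
    """
    theta = float(theta)
    if theta == 0.0:
        raise ValueError("theta=0 is the independence limit; tau is 0 there by convention")
    return 1.0 + 4.0 / theta * (_debye1(theta) - 1.0)


def theta_from_tau(tau: float) -> float:
    """Numerically invert ``kendall_tau``; defined for 0 < |tau| < 1."""
    tau = float(tau)
    if tau == 0.0:
        raise ValueError("tau=0 corresponds to independence (theta -> 0); not invertible")
    if not -1.0 < tau < 1.0:
        raise ValueError(f"tau must lie strictly inside (-1, 1), got {tau}")
    sign = 1.0 if tau > 0 else -1.0
    target = abs(tau)
    lo, hi = 1e-8, 1.0
    while kendall_tau(hi) < target:
        hi *= 2.0
        if hi > 1e6:  # tau(1e6) is essentially 1; unreachable for valid tau
            raise RuntimeError("failed to bracket theta for tau close to 1")
    theta = optimize.brentq(lambda t: kendall_tau(t) - target, lo, hi, xtol=1e-12, rtol=1e-12)
    return sign * theta


def frank_cdf(u, v, theta):
    """Frank copula function C_theta(u, v) on the unit square."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < 0) or np.any(u > 1) or np.any(v < 0) or np.any(v > 1):
        raise ValueError("copula arguments must lie in [0, 1]")
    theta = float(theta)
    if abs(theta) < THETA_INDEPENDENCE_GUARD:
        return u * v
    out = -np.log1p(np.expm1(-theta * u) * np.expm1(-theta * v) / np.expm1(-theta)) / theta
    # clip tiny negative round-off at the boundary
    return np.clip(out, 0.0, None) if np.ndim(out) else float(max(out, 0.0))


def frank_logdensity(u, v, theta):
    """Log of the Frank copula density c_theta(u, v), numerically stable.

    Written as

        c = -theta * expm1(-theta) * e^{-theta(u+v)} / D^2,
        D = e^{-theta u} + e^{-theta v} - e^{-theta} - e^{-theta(u+v)},

    with log|D| evaluated by a signed log-sum-exp so that large |theta|
    neither overflows nor cancels.  ``theta`` may be an array broadcastable
    against ``u`` and ``v`` (per-observation association parameters); entries
    inside the independence guard contribute log-density 0.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    theta = np.asarray(theta, dtype=float)
    u, v, theta = np.broadcast_arrays(u, v, theta)

    out = np.zeros(u.shape, dtype=float)
    active = np.abs(theta) >= THETA_INDEPENDENCE_GUARD
    if not np.any(active):
        return out if out.ndim else float(out)

    ua, va, ta = u[active], v[active], theta[active]
    e1, e2, e3, e4 = -ta * ua, -ta * va, -ta, -ta * (ua + va)
    m = np.maximum(np.maximum(e1, e2), np.maximum(e3, e4))
    d_scaled = np.exp(e1 - m) + np.exp(e2 - m) - np.exp(e3 - m) - np.exp(e4 - m)
    with np.errstate(divide="ignore"):
        log_abs_d = m + np.log(np.abs(d_scaled))
    # log|theta * expm1(-theta)|: for theta << 0 expm1(-theta) ~ e^{-theta}
    abs_t = np.abs(ta)
    log_num = np.where(
        -ta > 30.0,
        np.log(abs_t) - ta,
        np.log(abs_t * np.abs(np.expm1(-ta))),
    )
    out[active] = log_num - ta * (ua + va) - 2.0 * log_abs_d
    return out if out.ndim else float(out)


def frank_density(u, v, theta):
    """Frank copula density c_theta(u, v); the independence guard returns 1."""
    return np.exp(frank_logdensity(u, v, theta))


def frank_conditional_inverse(w, t, theta):
    """Invert the conditional distribution of the Frank copula.

    Given ``w`` (the conditioning uniform) and a uniform ``t``, returns the
    ``v`` solving dC/du (v | u=w) = t in closed form:

        v = -(1/theta) * log(1 + t * expm1(-theta) / (t + (1-t) e^{-theta w})).

    Used for conditional-inversion sampling of copula pairs.  ``theta`` may
    be an array broadcastable against ``w`` and ``t``; near-zero entries fall
    back to the independence draw ``v = t``.
    """
    w = np.asarray(w, dtype=float)
    t = np.asarray(t, dtype=float)
    theta = np.asarray(theta, dtype=float)
    w, t, theta = np.broadcast_arrays(w, t, theta)

    out = t.astype(float).copy()
    active = np.abs(theta) >= THETA_INDEPENDENCE_GUARD
    if np.any(active):
        wa, tt, ta = w[active], t[active], theta[active]
        denom = tt + (1.0 - tt) * np.exp(-ta * wa)
        out[active] = -np.log1p(tt * np.expm1(-ta) / denom) / ta
    return out if out.ndim else float(out)


def sample_frank(n: int, theta, rng: np.random.Generator):
    """Draw ``n`` pairs (w, s) from the Frank copula by conditional inversion."""
    w = rng.uniform(size=n)
    t = rng.uniform(size=n)
    s = frank_conditional_inverse(w, t, theta)
    return w, s


@dataclass(frozen=True)
class FrankDependence:
    """Association component of the model: the Frank parameter theta.

    ``theta`` must be nonzero in principle; values inside the independence
    guard band are accepted and treated as exact independence throughout.
    """

    theta: float

    def kendall_tau(self) -> float:
        if abs(self.theta) < THETA_INDEPENDENCE_GUARD:
            return 0.0
        return kendall_tau(self.theta)

    @classmethod
    def from_tau(cls, tau: float) -> "FrankDependence":
        return cls(theta=theta_from_tau(tau))

    @property
    def is_independent(self) -> bool:
        return abs(self.theta) < THETA_INDEPENDENCE_GUARD
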