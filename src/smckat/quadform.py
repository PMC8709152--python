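"""Tail probabilities of positive chi-square mixtures.

The score statistic of the kernel-machine test is distributed, under the
null, as ``Q ~ sum_j lambda_j * chisq_1`` with non-negative weights
``lambda_j``.  ``cf_inversion_pvalue`` computes ``P(Q > q)`` by numerical
inversion of the characteristic function (the Gil-Pelaez / Imhof
integral, the construction underlying Davies' method):

    P(Q > q) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du
    theta(u) = (1/2) * sum_j arctan(lambda_j u) - q u / 2
    rho(u)   = prod_j (1 + lambda_j^2 u^2)^(1/4)

The integrand oscillates with asymptotically linear phase ``-qu/2`` and
decays like ``u^(-1 - r/2)``; it is integrated adaptively up to the point
where the phase becomes monotone, then lobe by lobe (one half-period per
lobe), with the near-alternating lobe sums accelerated by repeated
averaging (van Wijngaarden / Euler transformation).  If the requested
accuracy cannot be certified within the lobe budget, callers fall back to
``liu_pvalue`` — the moment-matching approximation of Liu, Tang & Zhang
that matches a non-central chi-square to the first four cumulants.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy.stats import chi2, ncx2

__all__ = ["cf_inversion_pvalue", "liu_pvalue", "CFInversionError"]

_P_FLOOR = 1e-300


class CFInversionError(RuntimeError):
    """The characteristic-function inversion could not reach its accuracy."""


def _phase_turn_point(lam: np.ndarray, q: float) -> float:
    """Smallest u beyond which the phase theta(u) is strictly decreasing."""
    # theta'(u) = 0.5 * sum lam/(1 + lam^2 u^2) - q/2 < 0
    u = 1.0 / max(q, 1e-3)
    for _ in range(200):
        if (lam / (1.0 + (lam * u) ** 2)).sum() < q:
            return u
        u *= 1.5
    return u


def _accelerated_tail(chunks: np.ndarray) -> float:
    """Limit estimate of a (near-)alternating series by repeated averaging."""
    s = np.cumsum(chunks)
    while s.size > 1:
        s = 0.5 * (s[:-1] + s[1:])
    return float(s[0])


def cf_inversion_pvalue(q: float, weights, acc: float = 1e-6) -> float:
    """``P(sum_j weights_j * chisq_1 > q)`` by CF inversion.

    ``weights`` must be non-negative with at least one positive entry.
    Raises :class:`CFInversionError` when the integration cannot certify
    the requested absolute accuracy ``acc``.
    """
    lam = np.asarray(weights, dtype=float).ravel()
    lam = lam[lam > 0]
    if lam.size == 0:
        raise CFInversionError("no positive weights")
    if q <= 0:
        return 1.0
    tol = 0.1 * acc
    limit_at_zero = 0.5 * (lam.sum() - q)

    def integrand(u: float) -> float:
        if u == 0.0:
            return limit_at_zero
        lu = lam * u
        theta = 0.5 * np.arctan(lu).sum() - 0.5 * q * u
        log_rho = 0.25 * np.log1p(lu * lu).sum()
        return np.sin(theta) * np.exp(-log_rho) / u

    u1 = _phase_turn_point(lam, q)
    head, head_err = integrate.quad(
        integrand, 0.0, u1, limit=400, epsabs=tol, epsrel=1e-10
    )
    if head_err > 10 * tol:
        raise CFInversionError("head integral did not converge")

    half_period = 2.0 * np.pi / q  # asymptotic phase rate is q/2
    max_lobes = 600
    r = lam.size
    chunks: list[float] = []
    estimate = head
    prev = np.inf
    stable = 0
    lo = u1
    for k in range(max_lobes):
        hi = lo + half_period
        c, _ = integrate.quad(
            integrand, lo, hi, limit=100, epsabs=tol, epsrel=1e-10
        )
        chunks.append(c)
        lo = hi
        # monotone power-law remainder bound; decisive once rho is large
        envelope = float(np.exp(-0.25 * np.log1p((lam * hi) ** 2).sum()) / hi)
        if envelope * hi * 2.0 / r < tol:
            estimate = head + float(np.sum(chunks))
            stable = 2
            break
        if k >= 2:
            estimate = head + _accelerated_tail(np.asarray(chunks))
            if abs(estimate - prev) < tol:
                stable += 1
                if stable >= 2:
                    break
            else:
                stable = 0
            prev = estimate
    if stable < 2:
        raise CFInversionError("lobe summation did not stabilize")

    p = 0.5 + estimate / np.pi
    if p < -10 * acc or p > 1 + 10 * acc:
        raise CFInversionError(f"inverted probability {p} outside [0, 1]")
    return float(min(max(p, _P_FLOOR), 1.0))


def liu_pvalue(q: float, weights) -> float:
    """Moment-matching (Liu-Tang-Zhang) tail approximation of the mixture."""
    lam = np.asarray(weights, dtype=float).ravel()
    lam = lam[lam > 0]
    if lam.size == 0:
        return 1.0
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s1**2
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2.0 * delta))
    t_star = (q - c1) / np.sqrt(2.0 * c2)
    x = t_star * sigma_x + mu_x
    if delta > 0:
        p = float(ncx2.sf(x, df, delta))
    else:
        p = float(chi2.sf(x, df))
    return float(min(max(p, _P_FLOOR), 1.0))
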