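"""Kernel-machine score test for CNV sequential order vs a binary trait.

Model: ``logit Pr(y_i = 1) = beta0 + Z_i beta + f(P_i)`` where ``f`` is a
random effect with covariance ``tau * K`` and ``K`` is the group-series
similarity matrix.  No association means ``tau = 0``, tested with the
variance-component score statistic

    Q = (y - yhat)' K (y - yhat)

where ``yhat`` comes from the null logistic fit ``beta0 + Z beta``.  Under
the null, Q is a weighted sum of 1-df chi-squares whose weights are the
eigenvalues of ``P^(1/2) K P^(1/2)`` with ``P = V - V X (X'VX)^-1 X' V``,
``V = diag(yhat (1 - yhat))`` and ``X = [1 | Z]`` — the standard
kernel-machine construction.  The tail probability is computed by
characteristic-function inversion with a moment-matching fallback.
"""

from __future__ import annotations

import decimal
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cnv_core import (
    CNVDataError,
    CNVProfile,
    CytobandMap,
    PhenotypeTable,
    filter_region,
    normalize_chrom,
)
from .kernels import KernelMatrix, kernel_matrix
from .quadform import CFInversionError, cf_inversion_pvalue, liu_pvalue

__all__ = [
    "NullModel",
    "TestResult",
    "fit_null_logistic",
    "score_statistic",
    "mixture_weights",
    "davies_pvalue",
    "conditional_moment_pvalue",
    "smckat_test",
    "scan_regions",
    "results_to_frame",
    "write_results_tsv",
]

_EIGEN_DISCARD = 1e-10  # relative floor for kept mixture weights
_P_FLOOR = 1e-300


@dataclass
class NullModel:
    """Null logistic fit ``logit Pr(y=1) = beta0 + Z beta``."""

    coefficients: np.ndarray
    fitted_probabilities: np.ndarray
    design: np.ndarray


@dataclass
class TestResult:
    """Outcome of one association test.

    ``method`` is ``"conditional_moment"`` (small-sample conditional-null
    fit, the default for intercept-only binary models), ``"davies"``
    (chi-square-mixture CF inversion), ``"moment_matching"`` (Liu-type
    fallback after an inversion fault) or ``"degenerate"`` (all-zero
    kernel / no usable mixture weights, reported as p = 1).
    """

    region: str
    Q: float
    weights: np.ndarray
    p_value: float
    method: str
    n_subjects_nonempty: int
    n_cnvs: int
    group_size: int
    degenerate: bool = False
    significant: bool | None = None
    kernel_psd_adjusted: bool = False
    #: chi-square-mixture p-value, kept for diagnostics when the
    #: small-sample conditional-moment p-value is the reported one
    p_value_mixture: float | None = None


def fit_null_logistic(pheno: PhenotypeTable) -> NullModel:
    """Maximum-likelihood logistic fit of the covariate-only null model.

    IRLS via statsmodels GLM (binomial family), tolerance 1e-8, at most 50
    iterations.  Raises on a single phenotype class, a rank-deficient
    design, or (quasi-)perfect separation.
    """
    y = np.asarray(pheno.y, dtype=float)
    if len(np.unique(y)) < 2:
        raise CNVDataError("cannot fit null model: single phenotype class")
    ones = np.ones((len(y), 1))
    if pheno.covariates is None:
        design = ones
    else:
        design = np.hstack([ones, pheno.covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CNVDataError(
            "rank-deficient covariate matrix; remove collinear covariates"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(
            maxiter=50, tol=1e-8
        )
    mu = np.asarray(fit.fittedvalues, dtype=float)
    eps = 1e-10
    if np.all(np.abs(y - mu) < 1e-6):
        raise CNVDataError(
            "perfect separation in the null logistic model; "
            "remove the offending covariate"
        )
    mu = np.clip(mu, eps, 1.0 - eps)
    return NullModel(
        coefficients=np.asarray(fit.params, dtype=float),
        fitted_probabilities=mu,
        design=design,
    )


def score_statistic(
    y: np.ndarray,
    fitted: np.ndarray,
    kernel: KernelMatrix | np.ndarray,
    sample_ids: Sequence[str] | None = None,
) -> float:
    """Quadratic form ``(y - fitted)' K (y - fitted)``.

    When ``kernel`` is a :class:`KernelMatrix` and ``sample_ids`` gives
    the order of ``y``, the orders must match exactly — alignment is by
    sample id, never silently by position.
    """
    if isinstance(kernel, KernelMatrix):
        values = kernel.values
        if sample_ids is not None and list(sample_ids) != kernel.sample_ids:
            raise CNVDataError(
                "sample order of y does not match the kernel matrix; "
                "align by sample_id before testing"
            )
    else:
        values = np.asarray(kernel, dtype=float)
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if values.shape != (len(y), len(y)) or len(y) != len(fitted):
        raise CNVDataError("dimension mismatch between y, fitted and K")
    r = y - fitted
    return float(r @ values @ r)


def mixture_weights(
    kernel: KernelMatrix | np.ndarray, null: NullModel
) -> np.ndarray:
    """Eigen-weights of the null distribution of Q.

    Builds ``P = V - V X (X'VX)^-1 X'V`` from the null fit and returns the
    eigenvalues of ``P^(1/2) K P^(1/2)``, discarding those below
    ``1e-10 * max``.  An empty result signals a degenerate test.
    """
    K = kernel.values if isinstance(kernel, KernelMatrix) else np.asarray(kernel)
    mu = null.fitted_probabilities
    X = null.design
    v = mu * (1.0 - mu)
    VX = X * v[:, None]
    XtVX = X.T @ VX
    P = np.diag(v) - VX @ np.linalg.solve(XtVX, VX.T)
    P = 0.5 * (P + P.T)
    pe, pv = np.linalg.eigh(P)
    pe = np.clip(pe, 0.0, None)
    P_half = (pv * np.sqrt(pe)) @ pv.T
    W = P_half @ K @ P_half
    W = 0.5 * (W + W.T)
    eig = np.linalg.eigvalsh(W)
    top = eig[-1] if eig.size else 0.0
    if top <= 0.0:
        return np.empty(0)
    return np.sort(eig[eig > _EIGEN_DISCARD * top])[::-1]


@dataclass
class _PValue:
    p: float
    method: str


#: internal, fixed resampling seed — the adjusted p-value must be a
#: deterministic function of its inputs
_MOMENT_SEED = 20211126
_MOMENT_RESAMPLES = 500


def conditional_moment_pvalue(
    q: float,
    kernel: KernelMatrix | np.ndarray,
    y: np.ndarray,
    n_resamples: int = _MOMENT_RESAMPLES,
) -> float:
    """Small-sample p-value from the exact conditional (permutation) null.

    For a binary trait with an intercept-only null model, the exact null
    distribution of Q conditional on the case count is the permutation
    distribution of y.  The chi-square-mixture approximation can be badly
    conservative at small d (binary residuals are two-point, not normal,
    and the conditional skewness can even be negative, which no mixture
    of chi-squares can reproduce).  Here the first three conditional
    moments of Q are estimated from label permutations — no model refit
    is needed, each draw is one quadratic form — and the tail comes from
    a three-moment chi-square fit (reflected when the skew is negative,
    normal when it vanishes).  Deterministic: the resampler uses a fixed
    internal seed.
    """
    from scipy.stats import chi2 as _chi2, norm as _norm

    K = kernel.values if isinstance(kernel, KernelMatrix) else np.asarray(kernel)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(_MOMENT_SEED)
    d = len(y)
    perms = np.empty((n_resamples, d))
    for b in range(n_resamples):
        perms[b] = y[rng.permutation(d)]
    resid = perms - perms.mean(axis=1, keepdims=True)
    q_null = np.einsum("bi,ij,bj->b", resid, K, resid)
    mu = float(q_null.mean())
    sd = float(q_null.std(ddof=1))
    if sd <= 0:
        return 1.0
    skew = float(((q_null - mu) ** 3).mean() / sd**3)
    if abs(skew) < 0.05:
        p = float(_norm.sf((q - mu) / sd))
    else:
        df = 8.0 / skew**2
        scale = sd / np.sqrt(2.0 * df)
        if skew > 0:
            p = float(_chi2.sf((q - (mu - scale * df)) / scale, df))
        else:
            p = float(_chi2.cdf(((mu + scale * df) - q) / scale, df))
    return float(min(max(p, _P_FLOOR), 1.0))


def davies_pvalue(q: float, weights, acc: float = 1e-6) -> _PValue:
    """Tail probability ``P(sum_j w_j chisq_1 > q)`` with fallback.

    CF inversion at absolute accuracy ``acc``; on an inversion fault, or a
    result outside (0, 1], the moment-matching approximation is used and
    ``method`` records it.  Empty weights are degenerate: p = 1.
    """
    lam = np.asarray(weights, dtype=float).ravel()
    lam = lam[lam > 0]
    if lam.size == 0:
        return _PValue(p=1.0, method="degenerate")
    try:
        p = cf_inversion_pvalue(q, lam, acc=acc)
        method = "davies"
        if not (0.0 < p <= 1.0):
            raise CFInversionError("p outside (0, 1]")
        if p <= 100.0 * acc:
            # deep tail: re-invert at an accuracy proportionate to p so the
            # relative error stays controlled
            p = cf_inversion_pvalue(q, lam, acc=max(p * 1e-2, 1e-14))
            if p <= 1e-12:
                # beyond what the inversion can certify; analytic tail
                p = liu_pvalue(q, lam)
                method = "moment_matching"
    except CFInversionError:
        p = liu_pvalue(q, lam)
        method = "moment_matching"
    return _PValue(p=float(min(max(p, _P_FLOOR), 1.0)), method=method)


def smckat_test(
    profiles: Sequence[CNVProfile],
    pheno: PhenotypeTable,
    n: int,
    region: str = "genome",
    psd_fix: bool = True,
    sum_bound: str = "max",
    normalized: bool = False,
    precomputed_kernel: KernelMatrix | None = None,
    small_sample: str = "auto",
) -> TestResult:
    """Test association between CNV sequential order and a binary trait.

    Composes kernel construction, the null logistic fit, the score
    statistic, the mixture weights and the tail probability.  The
    phenotype is aligned to the profiles by sample id.  Deterministic
    given its inputs.

    ``small_sample`` controls the null approximation.  With ``"auto"``
    (default), intercept-only models of at most 2000 subjects report the
    conditional-moment p-value (see :func:`conditional_moment_pvalue`),
    which stays calibrated for binary traits at small d where the plain
    chi-square mixture is conservative; the mixture p-value is still
    recorded in ``p_value_mixture``.  ``"never"`` always reports the
    mixture p-value (always used when covariates are present).
    """
    if small_sample not in ("auto", "never"):
        raise CNVDataError(
            f"small_sample must be 'auto' or 'never', got {small_sample!r}"
        )
    ids = [p.sample_id for p in profiles]
    pheno = pheno.reordered(ids)
    n_cases = int(pheno.y.sum())
    if min(n_cases, len(pheno) - n_cases) < 2:
        warnings.warn(
            "fewer than 2 subjects in one phenotype class; "
            "the test is unreliable",
            stacklevel=2,
        )
    if precomputed_kernel is not None:
        kernel = precomputed_kernel
        if kernel.sample_ids != ids:
            raise CNVDataError("precomputed kernel sample order mismatch")
    else:
        kernel = kernel_matrix(
            profiles, n, psd_fix=psd_fix, sum_bound=sum_bound,
            normalized=normalized,
        )
    n_cnvs = sum(len(p) for p in profiles)
    nonempty = int(sum(len(p) >= n for p in profiles))
    if not kernel.values.any():
        return TestResult(
            region=region,
            Q=0.0,
            weights=np.empty(0),
            p_value=1.0,
            method="degenerate",
            n_subjects_nonempty=nonempty,
            n_cnvs=n_cnvs,
            group_size=n,
            degenerate=True,
            kernel_psd_adjusted=kernel.psd_adjusted,
        )
    null = fit_null_logistic(pheno)
    Q = score_statistic(pheno.y, null.fitted_probabilities, kernel, ids)
    weights = mixture_weights(kernel, null)
    pv = davies_pvalue(Q, weights)
    p_value, method, p_mixture = pv.p, pv.method, None
    if (
        small_sample == "auto"
        and pheno.covariates is None
        and len(pheno) <= 2000
        and pv.method != "degenerate"
    ):
        p_mixture = pv.p
        p_value = conditional_moment_pvalue(Q, kernel, pheno.y)
        method = "conditional_moment"
    return TestResult(
        region=region,
        Q=Q,
        weights=weights,
        p_value=p_value,
        method=method,
        n_subjects_nonempty=nonempty,
        n_cnvs=n_cnvs,
        group_size=n,
        degenerate=pv.method == "degenerate",
        kernel_psd_adjusted=kernel.psd_adjusted,
        p_value_mixture=p_mixture,
    )


def bonferroni_threshold(fwer: float, n_regions: int) -> float:
    """Per-test threshold ``fwer / n_regions``."""
    if not 0.0 < fwer < 1.0:
        raise CNVDataError(f"fwer must be in (0, 1), got {fwer}")
    if n_regions < 1:
        raise CNVDataError("need at least one region")
    return fwer / n_regions


def threshold_2sf(threshold: float) -> float:
    """Threshold rounded to two significant figures, for summaries.

    Uses decimal round-half-even on the shortest decimal representation,
    so 0.05/40 reports as 1.2e-3 rather than picking up binary float
    noise in the tie.
    """
    if threshold <= 0:
        return threshold
    exponent = math.floor(math.log10(threshold))
    quantum = decimal.Decimal(1).scaleb(exponent - 1)
    return float(
        decimal.Decimal(repr(threshold)).quantize(
            quantum, rounding=decimal.ROUND_HALF_EVEN
        )
    )


def scan_regions(
    profiles: Sequence[CNVProfile],
    pheno: PhenotypeTable,
    n: int,
    regions: Sequence[str] | CytobandMap,
    fwer: float = 0.05,
    **test_kwargs,
) -> tuple[list[TestResult], float]:
    """Run the test on each region with Bonferroni FWER control.

    ``regions`` is either a list of chromosome labels or a
    :class:`CytobandMap` (every band of every chromosome becomes a
    region).  Returns the per-region results — each flagged significant
    iff ``p < fwer / n_regions`` — and the threshold.  Regions with no
    CNVs in any subject yield a degenerate result (p = 1) and still count
    in the Bonferroni denominator.
    """
    if isinstance(regions, CytobandMap):
        region_list: list[tuple[str, object]] = [
            (label, (chrom, start, end))
            for label, chrom, start, end in regions.regions()
        ]
    else:
        region_list = [(normalize_chrom(r), normalize_chrom(r)) for r in regions]
    if not region_list:
        raise CNVDataError("no regions to scan")
    threshold = bonferroni_threshold(fwer, len(region_list))
    results = []
    for label, region in region_list:
        sub = [filter_region(p, region) for p in profiles]
        result = smckat_test(sub, pheno, n, region=label, **test_kwargs)
        result.significant = result.p_value < threshold
        results.append(result)
    return results, threshold


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Tabulate scan results in the standard output layout."""
    return pd.DataFrame(
        {
            "region": [r.region for r in results],
            "n_cnvs": [r.n_cnvs for r in results],
            "group_size": [r.group_size for r in results],
            "Q": [r.Q for r in results],
            "p_value": [r.p_value for r in results],
            "method": [r.method for r in results],
            "significant_after_bonferroni": [
                bool(r.significant) for r in results
            ],
        }
    )


def write_results_tsv(
    results: Sequence[TestResult], path, threshold: float | None = None
) -> None:
    """Write results as TSV; the Bonferroni threshold goes in a comment."""
    frame = results_to_frame(results)
    with open(path, "w") as fh:
        if threshold is not None:
            fh.write(f"# bonferroni_threshold={threshold_2sf(threshold):.2g}\n")
        frame.to_csv(fh, sep="\t", index=False)
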