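"""Synthetic CNV cohorts, logistic phenotype generators, and the
type-I-error / power evaluation harness.

Two cohort regimes mirror the two biological CNV classes:

* ``rare`` — few, long variants per subject (100 kb to 1 Mb), the regime
  of rare structural variants;
* ``common`` — many, short variants (1 to 50 kb), the regime of copy
  number polymorphisms (population frequency above one percent).

CNVs are placed uniformly on a configurable region; the default region is
a single 20 Mb (rare) or 5 Mb (common) stretch, emulating the CNV-dense
hotspot regions the per-chromosome and per-band scans target (uniform
placement over a whole genome would make profile overlap — and hence any
kernel signal — vanishingly rare).  Deletion dosages are 0 or 1 with
probability 0.5 each; amplification dosages are 3..7 with probability 0.2
each.

Case-control phenotypes come from logistic models over the CNV content of
each profile: the full multi-dimensional model (length, type, dosage and
length x type x dosage interactions) used for the sequential and
non-sequential kernels, and a reduced two-feature model (type indicator
times length) matching the CKAT-style generator, kept for comparison
studies.  All operations are reproducible from their integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cnv_core import (
    AMPLIFICATION,
    DELETION,
    CNVDataError,
    CNVProfile,
    CNVRecord,
    PhenotypeTable,
)
from .association import smckat_test

__all__ = [
    "CohortParams",
    "EffectParams",
    "simulate_cohort",
    "phenotype_eq_full",
    "phenotype_eq_ckat",
    "run_calibration",
    "CalibrationResult",
    "estimate_power",
]

_DELETION_DOSAGES = np.array([0, 1])
_AMPLIFICATION_DOSAGES = np.array([3, 4, 5, 6, 7])


@dataclass(frozen=True)
class CohortParams:
    """Configuration of one synthetic cohort.

    ``length_range`` is sampled log-uniformly (base-pair CNV lengths);
    ``cnvs_per_subject`` is the Poisson mean of the per-subject CNV count;
    ``chromosome_lengths`` maps chromosome label to its length in bp.
    """

    d: int
    regime: str = "rare"
    cnvs_per_subject: float = 4.0
    length_range: tuple[float, float] = (1e5, 1e6)
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"8": 20_000_000}
    )
    p_deletion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise CNVDataError("cohort needs at least one subject")
        if not 0.0 <= self.p_deletion <= 1.0:
            raise CNVDataError("p_deletion must be in [0, 1]")
        lo, hi = self.length_range
        if lo <= 0 or hi < lo:
            raise CNVDataError("invalid CNV length range")

    @classmethod
    def for_regime(cls, regime: str, d: int, seed: int = 0, **overrides):
        """Regime presets: rare = few long CNVs, common = many short ones."""
        presets = {
            "rare": dict(
                cnvs_per_subject=4.0,
                length_range=(1e5, 1e6),
                chromosome_lengths={"8": 20_000_000},
            ),
            "common": dict(
                cnvs_per_subject=30.0,
                length_range=(1e3, 5e4),
                chromosome_lengths={"8": 5_000_000},
            ),
        }
        if regime not in presets:
            raise CNVDataError(
                f"unknown regime {regime!r}; known: {sorted(presets)}"
            )
        kwargs = {**presets[regime], **overrides}
        return cls(d=d, regime=regime, seed=seed, **kwargs)


@dataclass(frozen=True)
class EffectParams:
    """Coefficients of the logistic phenotype models.

    ``beta0`` is the baseline log-odds of disease.  Length effects are per
    megabase (``length_scale`` converts bp); ``beta_del``/``beta_amp`` are
    the per-CNV type effects, constrained to equal magnitude and opposite
    sign by default; ``beta_dsg`` multiplies the distance of dosage from
    the diploid reference; the two three-way coefficients let the length
    and type effect vary with raw dosage.  ``ckat_beta_del`` /
    ``ckat_beta_dup`` parameterize the reduced two-feature model.
    """

    beta0: float = logit(0.3)
    beta_len: float = 0.0
    beta_del: float = 0.0
    beta_amp: float | None = None
    beta_dsg: float = 0.0
    beta_len_del_dsg: float = 0.0
    beta_len_amp_dsg: float = 0.0
    ckat_beta_del: float = 0.0
    ckat_beta_dup: float = 0.0
    length_scale: float = 1e-6
    opposite_sign_constraint: bool = True

    def __post_init__(self) -> None:
        if self.beta_amp is None:
            object.__setattr__(self, "beta_amp", -self.beta_del)
        elif self.opposite_sign_constraint and self.beta_amp != -self.beta_del:
            raise CNVDataError(
                "beta_amp must equal -beta_del under the opposite-sign "
                "constraint (disable opposite_sign_constraint to lift it)"
            )

    @classmethod
    def null(cls, prevalence: float = 0.3) -> "EffectParams":
        """All effect coefficients zero: phenotype independent of CNVs."""
        return cls(beta0=float(logit(prevalence)))

    @classmethod
    def default_alternative(
        cls, scale: float = 1.0, prevalence: float = 0.3
    ) -> "EffectParams":
        """Default non-null effects (see docs/methods.md for the choice).

        The baseline ``beta0`` is centered against the expected effect
        contribution of a default rare-regime profile (4 CNVs, mean
        length 0.391 Mb, mean |dosage - 2| of 2.25, dosage means 0.5 /
        5.0 for deletions / amplifications), so the marginal disease
        prevalence stays near ``prevalence`` while the effects create
        risk heterogeneity between subjects; ``scale`` multiplies every
        effect (and its centering) for power curves.
        """
        beta_len = 0.4 * scale
        beta_del = 0.2 * scale
        beta_dsg = 0.075 * scale
        beta_ldd = 0.15 * scale
        beta_lad = -0.075 * scale
        mean_count, mean_len = 4.0, 0.3909
        offset = (
            beta_len * mean_count * mean_len
            + beta_dsg * mean_count * 2.25
            + beta_ldd * mean_count * mean_len * 0.5 * 0.5
            + beta_lad * mean_count * mean_len * 0.5 * 5.0
        )
        return cls(
            beta0=float(logit(prevalence)) - offset,
            beta_len=beta_len,
            beta_del=beta_del,
            beta_dsg=beta_dsg,
            beta_len_del_dsg=beta_ldd,
            beta_len_amp_dsg=beta_lad,
            ckat_beta_del=0.8 * scale,
            ckat_beta_dup=0.8 * scale,
        )

    def scaled(self, factor: float) -> "EffectParams":
        """Multiply every effect coefficient (not beta0) by ``factor``."""
        return replace(
            self,
            beta_len=self.beta_len * factor,
            beta_del=self.beta_del * factor,
            beta_amp=None,
            beta_dsg=self.beta_dsg * factor,
            beta_len_del_dsg=self.beta_len_del_dsg * factor,
            beta_len_amp_dsg=self.beta_len_amp_dsg * factor,
            ckat_beta_del=self.ckat_beta_del * factor,
            ckat_beta_dup=self.ckat_beta_dup * factor,
        )


def simulate_cohort(params: CohortParams) -> list[CNVProfile]:
    """Draw a cohort of position-sorted CNV profiles.

    Per subject: a Poisson CNV count, log-uniform lengths from the regime
    range, uniform placement on a chromosome chosen proportionally to its
    length, deletion vs amplification with ``p_deletion``, and the
    regime-independent dosage scheme (0/1 at 0.5 each for deletions,
    3..7 at 0.2 each for amplifications).
    """
    rng = np.random.default_rng(params.seed)
    chroms = list(params.chromosome_lengths)
    chrom_sizes = np.array(
        [params.chromosome_lengths[c] for c in chroms], dtype=np.int64
    )
    chrom_p = chrom_sizes / chrom_sizes.sum()
    log_lo, log_hi = np.log(params.length_range[0]), np.log(params.length_range[1])
    width = len(str(params.d))
    profiles = []
    for i in range(params.d):
        count = int(rng.poisson(params.cnvs_per_subject))
        if count == 0:
            profiles.append(CNVProfile(sample_id=f"S{i + 1:0{width}d}"))
            continue
        ci = rng.choice(len(chroms), size=count, p=chrom_p)
        sizes = chrom_sizes[ci]
        lengths = np.exp(rng.uniform(log_lo, log_hi, size=count)).astype(np.int64)
        for attempt in range(100):
            bad = lengths > sizes
            if not bad.any():
                break
            lengths[bad] = np.exp(
                rng.uniform(log_lo, log_hi, size=int(bad.sum()))
            ).astype(np.int64)
        else:
            raise CNVDataError(
                "cannot place a CNV within the configured chromosome "
                "lengths; check length_range vs chromosome_lengths"
            )
        starts = rng.integers(1, sizes - lengths + 2)
        is_del = rng.random(count) < params.p_deletion
        dosages = np.where(
            is_del,
            rng.choice(_DELETION_DOSAGES, size=count),
            rng.choice(_AMPLIFICATION_DOSAGES, size=count),
        )
        records = tuple(
            CNVRecord(
                chrom=chroms[int(c)],
                start=int(s),
                end=int(s + ln - 1),
                cnv_type=DELETION if d_ else AMPLIFICATION,
                dosage=int(dos),
            )
            for c, s, ln, d_, dos in zip(ci, starts, lengths, is_del, dosages)
        )
        profiles.append(
            CNVProfile(sample_id=f"S{i + 1:0{width}d}", records=records)
        )
    return profiles


def _full_model_predictor(
    profiles: Sequence[CNVProfile], effects: EffectParams
) -> np.ndarray:
    eta = np.full(len(profiles), effects.beta0, dtype=float)
    s = effects.length_scale
    for i, profile in enumerate(profiles):
        for r in profile:
            length = (r.end - r.start) * s
            is_del = r.cnv_type == DELETION
            is_amp = r.cnv_type == AMPLIFICATION
            eta[i] += effects.beta_len * length
            eta[i] += effects.beta_del * is_del + effects.beta_amp * is_amp
            eta[i] += effects.beta_dsg * abs(r.dosage - 2)
            eta[i] += effects.beta_len_del_dsg * length * is_del * r.dosage
            eta[i] += effects.beta_len_amp_dsg * length * is_amp * r.dosage
    return eta


def _ckat_model_predictor(
    profiles: Sequence[CNVProfile], effects: EffectParams
) -> np.ndarray:
    eta = np.full(len(profiles), effects.beta0, dtype=float)
    s = effects.length_scale
    for i, profile in enumerate(profiles):
        for r in profile:
            length = (r.end - r.start) * s
            beta = (
                effects.ckat_beta_del
                if r.cnv_type == DELETION
                else effects.ckat_beta_dup
            )
            eta[i] += beta * length
    return eta


def _draw_binary(eta: np.ndarray, seed: int, which: str) -> np.ndarray:
    if not np.isfinite(eta).all():
        raise CNVDataError(
            f"non-finite linear predictor in the {which} phenotype model; "
            "check the effect sizes against length_scale"
        )
    rng = np.random.default_rng(seed)
    return rng.binomial(1, expit(eta)).astype(float)


def phenotype_eq_full(
    profiles: Sequence[CNVProfile], effects: EffectParams, seed: int
) -> np.ndarray:
    """Binary phenotype from the full multi-dimensional logistic model.

    Per subject the linear predictor sums, over its CNVs, a length term,
    deletion/amplification indicator terms, a |dosage - 2| term, and the
    two length x type x dosage interactions, on top of ``beta0``.
    """
    if len(profiles) == 0:
        raise CNVDataError("cannot generate phenotypes for an empty cohort")
    return _draw_binary(
        _full_model_predictor(profiles, effects), seed, "full"
    )


def phenotype_eq_ckat(
    profiles: Sequence[CNVProfile], effects: EffectParams, seed: int
) -> np.ndarray:
    """Binary phenotype from the reduced CKAT-style two-feature model:
    ``beta0 + sum_j (beta_del 1[del] + beta_dup 1[dup]) * length_j``.
    """
    if len(profiles) == 0:
        raise CNVDataError("cannot generate phenotypes for an empty cohort")
    return _draw_binary(
        _ckat_model_predictor(profiles, effects), seed, "ckat"
    )


_PHENOTYPE_MODELS = {"full": phenotype_eq_full, "ckat": phenotype_eq_ckat}


@dataclass
class CalibrationResult:
    """p-values of replicated tests plus summaries for QQ/power analysis."""

    pvalues: np.ndarray
    n_degenerate: int
    scenario: str
    n: int
    d: int
    seed: int

    @property
    def reps(self) -> int:
        return len(self.pvalues)

    def rejection_rate(self, alpha: float) -> float:
        """Empirical rejection rate; failed replicates never reject."""
        p = self.pvalues
        return float(np.nansum(p <= alpha) / len(p))

    def table(self, alphas: Sequence[float]) -> pd.DataFrame:
        rows = []
        m = self.reps
        for alpha in alphas:
            rate = self.rejection_rate(alpha)
            rows.append(
                {
                    "alpha": alpha,
                    "rejection_rate": rate,
                    "binomial_se": float(np.sqrt(alpha * (1 - alpha) / m)),
                    "reps": m,
                }
            )
        return pd.DataFrame(rows)

    def qq_data(self) -> pd.DataFrame:
        """Sorted observed vs expected -log10 p for QQ plotting."""
        p = np.sort(self.pvalues[~np.isnan(self.pvalues)])
        m = len(p)
        expected = (np.arange(1, m + 1) - 0.5) / m
        return pd.DataFrame(
            {
                "expected_neglog10": -np.log10(expected),
                "observed_neglog10": -np.log10(np.clip(p, 1e-300, 1.0)),
            }
        )


def _replicate_seeds(seed: int, reps: int) -> np.ndarray:
    state = np.random.SeedSequence(seed).generate_state(2 * reps)
    return (state & 0x7FFFFFFF).reshape(reps, 2)


def run_calibration(
    scenario: str = "rare",
    reps: int = 2000,
    effects: EffectParams | None = None,
    n: int = 2,
    d: int = 60,
    seed: int = 0,
    phenotype_model: str = "full",
    cohort_overrides: dict | None = None,
) -> CalibrationResult:
    """Replicate simulate -> phenotype -> test and collect p-values.

    With ``effects=None`` (or all-zero effects) this estimates the type-I
    error; with non-null effects it estimates power.  Replicates whose
    phenotype is degenerate (a single class) are recorded as NaN, never
    dropped from the denominator.
    """
    if reps < 1:
        raise CNVDataError("reps must be >= 1")
    if phenotype_model not in _PHENOTYPE_MODELS:
        raise CNVDataError(
            f"unknown phenotype model {phenotype_model!r}; "
            f"known: {sorted(_PHENOTYPE_MODELS)}"
        )
    draw_phenotype = _PHENOTYPE_MODELS[phenotype_model]
    if effects is None:
        effects = EffectParams.null()
    pvalues = np.full(reps, np.nan)
    n_degenerate = 0
    seeds = _replicate_seeds(seed, reps)
    overrides = cohort_overrides or {}
    for rep in range(reps):
        cohort_seed, pheno_seed = (int(s) for s in seeds[rep])
        params = CohortParams.for_regime(
            scenario, d=d, seed=cohort_seed, **overrides
        )
        profiles = simulate_cohort(params)
        y = draw_phenotype(profiles, effects, seed=pheno_seed)
        pheno = PhenotypeTable(
            sample_ids=[p.sample_id for p in profiles], y=y
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = smckat_test(profiles, pheno, n)
        except CNVDataError:
            n_degenerate += 1
            continue
        if result.degenerate:
            n_degenerate += 1
        pvalues[rep] = result.p_value
    return CalibrationResult(
        pvalues=pvalues,
        n_degenerate=n_degenerate,
        scenario=scenario,
        n=n,
        d=d,
        seed=seed,
    )


def estimate_power(
    effects: EffectParams,
    alpha: float = 0.05,
    reps: int = 200,
    scenario: str = "rare",
    n: int = 2,
    d: int = 100,
    seed: int = 0,
    phenotype_model: str = "full",
) -> float:
    """Empirical power at level ``alpha`` under the given effects."""
    result = run_calibration(
        scenario=scenario,
        reps=reps,
        effects=effects,
        n=n,
        d=d,
        seed=seed,
        phenotype_model=phenotype_model,
    )
    return result.rejection_rate(alpha)
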