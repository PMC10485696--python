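"""Synthetic two-sample MR summary statistics with known ground truth.

The generator mirrors the structure the estimators assume: per-variant true
exposure effects gamma_j, true outcome effects
``Gamma_j = true_beta * gamma_j + alpha_j`` where alpha_j is a horizontal
pleiotropic effect (zero for valid instruments), and independent Gaussian
estimation noise in both samples with configurable SE scales (defaults of
order 1e-3, matching typical UK-Biobank-scale instrument extracts).
Instruments are generated mutually independent, i.e. in the post-clumping
state.  Directional (nonzero-mean) and balanced pleiotropy are configurable,
as is a violation of the InSIDE condition (alpha_j correlated with gamma_j).

All randomness flows from a single master seed through spawned child
streams, so any replicate of an experiment is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import estimators
from .records import SummaryStatRecord

_INSIDE_RHO = 0.7  # correlation between alpha_j and gamma_j when InSIDE is violated


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth configuration for one simulated two-sample dataset.

    Defaults emulate a strong-instrument setting: gamma ~ N(0.01, 0.0025)
    with exposure SE 1e-3 gives F statistics around 100, comfortably past
    the F > 10 screen.  ``se_from_n`` switches the exposure/outcome SEs to
    ``1 / sqrt(2 n p (1 - p))`` using the MAF draw, for realism when sample
    sizes rather than SE scales are the natural inputs.
    """

    n_snps: int = 50
    true_beta: float = 0.0
    gamma_mean: float = 0.01
    gamma_sd: float = 0.0025
    gamma_list: Optional[Sequence[float]] = None
    se_exposure_scale: float = 1.0e-3
    se_outcome_scale: float = 2.5e-3
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    inside_violation: bool = False
    maf_range: tuple[float, float] = (0.05, 0.5)
    se_from_n: Optional[tuple[int, int]] = None  # (n_exposure, n_outcome)
    seed: int = 20230825

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        if self.se_exposure_scale <= 0 or self.se_outcome_scale <= 0:
            raise ValueError("SE scales must be positive")
        if not (0 <= self.invalid_fraction <= 1):
            raise ValueError("invalid_fraction must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")


@dataclass(frozen=True)
class SimulationTruth:
    """Config echo plus the realized per-variant ground truth."""

    config: SimulationConfig
    gamma: np.ndarray
    alpha: np.ndarray
    valid: np.ndarray  # boolean per variant

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())


_ALLELES = np.array(list("ACGT"))


def simulate_two_sample(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], SimulationTruth]:
    """Draw one synthetic exposure/outcome summary-statistics pair.

    Observed effects are ``beta_X_j ~ N(gamma_j, se_X_j^2)`` and
    ``beta_Y_j ~ N(true_beta * gamma_j + alpha_j, se_Y_j^2)``; p-values come
    from the normal.  Exactly ``round(invalid_fraction * L)`` variants
    receive pleiotropy.  Fully reproducible from ``config.seed`` when no
    generator is passed.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    L = cfg.n_snps

    if cfg.gamma_list is not None:
        gamma = np.asarray(cfg.gamma_list, dtype=float)
        if len(gamma) != L:
            raise ValueError("gamma_list length must equal n_snps")
    else:
        gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=L)
    if np.all(gamma == 0):
        raise ValueError("all true exposure effects are zero: no instrument strength")

    n_invalid = round(cfg.invalid_fraction * L)
    valid = np.ones(L, dtype=bool)
    if n_invalid:
        valid[rng.choice(L, size=n_invalid, replace=False)] = False

    alpha = np.zeros(L)
    if n_invalid and (cfg.pleiotropy_mean != 0 or cfg.pleiotropy_sd != 0):
        z = rng.normal(size=n_invalid)
        if cfg.inside_violation and cfg.gamma_sd > 0:
            g_std = (gamma[~valid] - cfg.gamma_mean) / cfg.gamma_sd
            z = _INSIDE_RHO * g_std + np.sqrt(1 - _INSIDE_RHO**2) * z
        alpha[~valid] = cfg.pleiotropy_mean + cfg.pleiotropy_sd * z

    maf = rng.uniform(*cfg.maf_range, size=L)
    if cfg.se_from_n is not None:
        n_x, n_y = cfg.se_from_n
        se_x = 1.0 / np.sqrt(2 * n_x * maf * (1 - maf))
        se_y = 1.0 / np.sqrt(2 * n_y * maf * (1 - maf))
    else:
        n_x = n_y = None
        se_x = np.full(L, cfg.se_exposure_scale)
        se_y = np.full(L, cfg.se_outcome_scale)

    big_gamma = cfg.true_beta * gamma + alpha
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(big_gamma, se_y)
    ea = rng.choice(_ALLELES, size=L)
    oa = np.array([_other_allele(a, rng) for a in ea])

    def records(beta, se, n) -> list[SummaryStatRecord]:
        p = 2 * stats.norm.sf(np.abs(beta / se))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        return [
            SummaryStatRecord(
                variant_id=f"sim{j:04d}",
                chrom_pos=f"1: {1_000_000 + 10_000 * j}",
                effect_allele=str(ea[j]),
                other_allele=str(oa[j]),
                eaf=float(maf[j]),
                beta=float(beta[j]),
                se=float(se[j]),
                pval=float(p[j]),
                n=n,
            )
            for j in range(L)
        ]

    truth = SimulationTruth(config=cfg, gamma=gamma, alpha=alpha, valid=valid)
    return records(beta_x, se_x, n_x), records(beta_y, se_y, n_y), truth


def _other_allele(ea: str, rng: np.random.Generator) -> str:
    # Avoid palindromic pairs so synthetic data never hits the ambiguity drop.
    from .records import COMPLEMENT

    choices = [a for a in "ACGT" if a != ea and a != COMPLEMENT[ea]]
    return str(rng.choice(choices))


def _harmonize_sim(exposure, outcome):
    from .sumstats_io import harmonize

    return harmonize(exposure, outcome)


def recovery_experiment(
    config: SimulationConfig,
    n_reps: int,
    estimator_names: Sequence[str] = ("ivw", "egger", "weighted_median"),
    n_boot: int = 200,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Parameter-recovery / type-I-error experiment over simulated replicates.

    For each requested estimator, reports mean bias, RMSE, empirical SE of
    the point estimates, mean model SE, 95% CI coverage of ``true_beta`` and
    the rejection rate of the beta = 0 test at ``alpha_level``.  Replicate
    seeds are spawned deterministically from ``config.seed``; an estimator
    failure in a replicate is counted (``n_failed``) rather than fatal.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    streams = np.random.SeedSequence(config.seed).spawn(n_reps)
    z = estimators.Z_95
    results: dict[str, dict[str, list]] = {
        name: {"beta": [], "se": [], "pval": []} for name in estimator_names
    }
    failures = {name: 0 for name in estimator_names}
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        exposure, outcome, _ = simulate_two_sample(config, rng=rng)
        instruments = _harmonize_sim(exposure, outcome)
        boot_seed = int(stream.generate_state(1)[0] % (2**31))
        for name in estimator_names:
            try:
                if name == "ivw":
                    fit = estimators.ivw(instruments)
                elif name == "egger":
                    fit = estimators.egger(instruments)
                elif name == "weighted_median":
                    fit = estimators.weighted_median(
                        instruments, n_boot=n_boot, seed=boot_seed
                    )
                else:
                    raise ValueError(f"unknown estimator {name!r}")
            except (ValueError, np.linalg.LinAlgError):
                failures[name] += 1
                continue
            results[name]["beta"].append(fit.beta)
            results[name]["se"].append(fit.se)
            results[name]["pval"].append(fit.pval)

    rows = []
    for name in estimator_names:
        beta = np.array(results[name]["beta"])
        se = np.array(results[name]["se"])
        pval = np.array(results[name]["pval"])
        err = beta - config.true_beta
        covered = np.abs(err) <= z * se
        rows.append(
            {
                "estimator": name,
                "n_reps": len(beta),
                "n_failed": failures[name],
                "bias": float(err.mean()) if len(beta) else np.nan,
                "rmse": float(np.sqrt((err**2).mean())) if len(beta) else np.nan,
                "empirical_se": float(beta.std(ddof=1)) if len(beta) > 1 else np.nan,
                "mean_model_se": float(se.mean()) if len(beta) else np.nan,
                "coverage_95": float(covered.mean()) if len(beta) else np.nan,
                "rejection_rate": float((pval < alpha_level).mean()) if len(beta) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
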