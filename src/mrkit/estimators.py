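"""Causal estimators for two-sample MR summary data.

Per-variant Wald ratios are combined by three estimators with distinct
robustness profiles:

* **IVW** — inverse-variance-weighted mean of the Wald ratios, equivalent to
  a zero-intercept weighted regression of outcome on exposure effects.
  Unbiased only when every instrument is valid.
* **MR-Egger** — the same weighted regression with a free intercept; the
  slope is a consistent causal estimate under InSIDE (pleiotropic effects
  independent of instrument strength), and the intercept estimates average
  directional pleiotropy.
* **Weighted median** — the weight-interpolated median of the Wald ratios;
  consistent when valid instruments carry at least half of the total weight.

All estimators use first-order weights ``w_j = beta_X_j**2 / se_Y_j**2``
(equivalently ``1 / se(ratio)**2`` with the first-order ratio SE
``se_Y / |beta_X|``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .records import HarmonizedInstrument, InstrumentSet

Z_95 = float(stats.norm.ppf(0.975))  # 1.959963984540054

VarianceModel = Literal["fixed", "multiplicative_random"]

Instruments = Union[InstrumentSet, Sequence[HarmonizedInstrument]]


@dataclass(frozen=True)
class WaldRatio:
    """Per-variant causal estimate ``beta_Y / beta_X`` with first-order SE."""

    variant_id: str
    ratio: float
    se_first_order: float
    weight: float


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with log-scale and odds-ratio summaries."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    df: int
    or_point: float
    ci_lower: float
    ci_upper: float
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_pval: Optional[float] = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "pval": self.pval,
            "df": self.df,
            "or": self.or_point,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
        }
        if self.intercept is not None:
            d.update(
                intercept=self.intercept,
                intercept_se=self.intercept_se,
                intercept_pval=self.intercept_pval,
            )
        return d


def _arrays(instruments: Instruments) -> tuple[np.ndarray, ...]:
    ins = list(instruments)
    bx = np.array([i.beta_exposure for i in ins])
    sx = np.array([i.se_exposure for i in ins])
    by = np.array([i.beta_outcome for i in ins])
    sy = np.array([i.se_outcome for i in ins])
    return bx, sx, by, sy


def or_ci(beta: float, se: float, level_z: float = Z_95) -> tuple[float, float, float]:
    """Odds ratio ``exp(beta)`` with ``exp(beta -/+ z*se)`` confidence bounds."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return float(np.exp(beta)), float(np.exp(beta - level_z * se)), float(np.exp(beta + level_z * se))


def wald_ratio(instrument: HarmonizedInstrument) -> WaldRatio:
    """Single-variant causal estimate ``beta_Y / beta_X``.

    The first-order SE is ``se_Y / |beta_X|`` (exposure-side uncertainty
    ignored); the IVW weight is its inverse square, ``(beta_X / se_Y)**2``.
    """
    if instrument.beta_exposure == 0:
        raise ValueError(f"{instrument.variant_id}: beta_exposure = 0, ratio undefined")
    se = instrument.se_outcome / abs(instrument.beta_exposure)
    return WaldRatio(
        variant_id=instrument.variant_id,
        ratio=instrument.beta_outcome / instrument.beta_exposure,
        se_first_order=se,
        weight=1.0 / se**2,
    )


def wald_ratios(instruments: Instruments) -> list[WaldRatio]:
    return [wald_ratio(i) for i in instruments]


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median at standardized cumulative weight 0.5.

    Ratios are sorted ascending; the j-th order statistic sits at
    ``p_j = (S_j - w_j / 2) / S_total`` with ``S_j`` the running weight sum,
    and the estimate linearly interpolates the ordered ratios at p = 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    p = (np.cumsum(w) - w / 2) / total
    return float(np.interp(0.5, p, r))


def ivw(
    instruments: Instruments,
    variance_model: VarianceModel = "multiplicative_random",
    allow_underdispersion: bool = True,
    level_z: float = Z_95,
) -> MREstimate:
    """Inverse-variance-weighted estimate ``sum(w_j r_j) / sum(w_j)``.

    ``fixed`` variance uses SE ``(sum w_j)**-0.5``; ``multiplicative_random``
    scales it by ``phi = sqrt(Q / (L - 1))`` with Cochran's Q of the Wald
    ratios, floored at 1 unless ``allow_underdispersion``.  p-values are
    two-sided normal; ``df = L - 1``.
    """
    wr = wald_ratios(instruments)
    L = len(wr)
    if L < 1:
        raise ValueError("IVW requires at least one instrument")
    r = np.array([x.ratio for x in wr])
    w = np.array([x.weight for x in wr])
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r - beta) ** 2))
    phi2 = q / (L - 1) if L > 1 else 1.0
    if variance_model == "fixed":
        se = se_fixed
        phi2_used = 1.0
    elif variance_model == "multiplicative_random":
        phi2_used = phi2 if allow_underdispersion else max(phi2, 1.0)
        se = se_fixed * float(np.sqrt(phi2_used))
    else:
        raise ValueError(f"unknown variance_model {variance_model!r}")
    # exact data (Q = 0) with underdispersion allowed collapses the SE
    se = max(se, np.finfo(float).tiny)
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    orp, lo, hi = or_ci(beta, se, level_z)
    return MREstimate(
        method="IVW",
        beta=beta,
        se=se,
        pval=max(min(pval, 1.0), np.nextafter(0, 1)),
        n_snps=L,
        df=L - 1,
        or_point=orp,
        ci_lower=lo,
        ci_upper=hi,
        metadata={
            "variance_model": variance_model,
            "allow_underdispersion": allow_underdispersion,
            "phi2": phi2_used,
            "se_fixed": se_fixed,
            "cochran_q": q,
            "p_value_distribution": "normal",
            "level_z": level_z,
        },
    )


def _egger_wls(
    bx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    allow_underdispersion: bool,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Weighted least squares of by on bx with intercept, weights 1/sy^2.

    Returns (coef [intercept, slope], SEs, weighted RSS, phi2 used).
    """
    L = len(bx)
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(L), bx])
    xtw = X.T * w
    xtwx = xtw @ X
    if np.linalg.matrix_rank(xtwx) < 2 or np.ptp(bx) == 0:
        raise ValueError("zero variance in exposure betas: slope unidentifiable")
    coef = np.linalg.solve(xtwx, xtw @ by)
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    phi2 = rss / (L - 2)
    phi2_used = phi2 if allow_underdispersion else max(phi2, 1.0)
    cov = np.linalg.inv(xtwx) * phi2_used
    return coef, np.sqrt(np.diag(cov)), rss, phi2_used


def egger(
    instruments: Instruments,
    orient_exposure_positive: bool = True,
    se_model: Literal["t", "normal"] = "t",
    allow_underdispersion: bool = True,
    level_z: float = Z_95,
) -> MREstimate:
    """MR-Egger regression: weighted regression of outcome on exposure betas.

    With orientation on (default) every instrument with a negative exposure
    beta has both betas negated first; the slope is otherwise not invariant
    to the arbitrary choice of effect allele.  The slope estimates the causal
    effect, the intercept the average directional pleiotropy.  SEs use the
    residual scale ``phi^2 = RSS_w / (L - 2)``, floored at 1 unless
    ``allow_underdispersion``; p-values from Student t with L-2 df
    (``se_model="t"``, default) or the normal.
    """
    bx, _, by, sy = _arrays(instruments)
    L = len(bx)
    if L < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    if orient_exposure_positive:
        s = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * s, by * s
    coef, ses, rss, phi2 = _egger_wls(bx, by, sy, allow_underdispersion)
    df = L - 2
    if se_model == "t":
        tail = lambda z: 2 * stats.t.sf(abs(z), df)
    elif se_model == "normal":
        tail = lambda z: 2 * stats.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown se_model {se_model!r}")
    slope, slope_se = float(coef[1]), float(ses[1])
    orp, lo, hi = or_ci(slope, slope_se, level_z)
    return MREstimate(
        method="Egger",
        beta=slope,
        se=slope_se,
        pval=float(tail(slope / slope_se)),
        n_snps=L,
        df=df,
        or_point=orp,
        ci_lower=lo,
        ci_upper=hi,
        intercept=float(coef[0]),
        intercept_se=float(ses[0]),
        intercept_pval=float(tail(coef[0] / ses[0])),
        metadata={
            "orient_exposure_positive": orient_exposure_positive,
            "se_model": se_model,
            "allow_underdispersion": allow_underdispersion,
            "phi2": phi2,
            "weighted_rss": rss,
            "level_z": level_z,
        },
    )


def weighted_median(
    instruments: Instruments,
    n_boot: int = 1000,
    seed: int = 20230825,
    level_z: float = Z_95,
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    The point estimate interpolates the weight-ordered Wald ratios at
    standardized cumulative weight 0.5.  The SE is the standard deviation of
    the estimate over ``n_boot`` replicates that redraw every beta_X and
    beta_Y from normals centered at the observed values with the reported
    SEs; it is seeded for exact reproducibility.  Consistent while valid
    instruments hold >= 50% of the weight.
    """
    bx, sx, by, sy = _arrays(instruments)
    L = len(bx)
    if L < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if np.any(bx == 0):
        raise ValueError("beta_exposure = 0: ratio undefined")
    ratios = by / bx
    weights = (bx / sy) ** 2
    beta = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        boots[b] = _weighted_median_point(by_b / bx_b, (bx_b / sy) ** 2)
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else float("nan")
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    orp, lo, hi = or_ci(beta, se, level_z)
    return MREstimate(
        method="WeightedMedian",
        beta=beta,
        se=se,
        pval=pval,
        n_snps=L,
        df=L - 1,
        or_point=orp,
        ci_lower=lo,
        ci_upper=hi,
        metadata={
            "n_boot": n_boot,
            "seed": seed,
            "p_value_distribution": "normal",
            "level_z": level_z,
        },
    )


def single_wald(
    instrument: HarmonizedInstrument, level_z: float = Z_95
) -> MREstimate:
    """Degenerate one-instrument estimate: the Wald ratio with first-order SE."""
    wr = wald_ratio(instrument)
    pval = float(2 * stats.norm.sf(abs(wr.ratio / wr.se_first_order)))
    orp, lo, hi = or_ci(wr.ratio, wr.se_first_order, level_z)
    return MREstimate(
        method="WaldRatio",
        beta=wr.ratio,
        se=wr.se_first_order,
        pval=pval,
        n_snps=1,
        df=0,
        or_point=orp,
        ci_lower=lo,
        ci_upper=hi,
        metadata={"variant_id": instrument.variant_id, "level_z": level_z},
    )
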