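"""Heterogeneity, pleiotropy and influence diagnostics for MR fits.

Cochran's Q measures dispersion of the per-variant Wald ratios around a
combined fit; ``I^2 = (Q - df) / Q`` is the fraction of that dispersion
attributable to genuine heterogeneity (negative when Q < df, i.e. the
estimates agree more than sampling error alone predicts).  The Egger
intercept tests for average directional pleiotropy, and leave-one-out
re-estimation exposes single-variant influence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    Instruments,
    MREstimate,
    Z_95,
    egger,
    ivw,
    or_ci,
    wald_ratios,
    _arrays,
)
from .records import InstrumentSet


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q with its df, signed I-squared and chi-square tail p-value.

    ``i_squared`` is None when Q = 0 (the formula is undefined); it is stored
    signed, with :meth:`display_magnitude` available for report layers that
    print absolute values.
    """

    method: str
    Q: float
    df: int
    i_squared: Optional[float]
    pval: float

    def display_magnitude(self) -> Optional[float]:
        return None if self.i_squared is None else abs(self.i_squared)


@dataclass
class LeaveOneOutResult:
    """Per-variant leave-one-out IVW estimates plus the all-SNP row."""

    table: pd.DataFrame  # columns: SNP, beta, se, ci_lower, ci_upper
    full_estimate: MREstimate


def cochran_q(instruments: Instruments, fit: MREstimate) -> HeterogeneityStats:
    """Cochran's Q of the instruments around ``fit``.

    For an IVW fit, ``Q = sum w_j (r_j - beta)^2`` over the Wald ratios with
    df = L - 1.  For an Egger fit, Q is the weighted residual sum of squares
    of the intercept regression with df = L - 2 (slope and intercept both
    estimated).  The p-value is the chi-square upper tail of Q at df.
    """
    L = len(list(instruments))
    if fit.method == "IVW":
        wr = wald_ratios(instruments)
        r = np.array([x.ratio for x in wr])
        w = np.array([x.weight for x in wr])
        q = float(np.sum(w * (r - fit.beta) ** 2))
        df = L - 1
    elif fit.method == "Egger":
        bx, _, by, sy = _arrays(instruments)
        if fit.metadata.get("orient_exposure_positive", True):
            s = np.where(bx < 0, -1.0, 1.0)
            bx, by = bx * s, by * s
        resid = by - fit.intercept - fit.beta * bx
        q = float(np.sum(resid**2 / sy**2))
        df = L - 2
    else:
        raise ValueError(f"heterogeneity undefined for method {fit.method!r}")
    if df < 1:
        raise ValueError("heterogeneity requires df >= 1")
    if q == 0:
        return HeterogeneityStats(fit.method, 0.0, df, None, 1.0)
    i2 = (q - df) / q
    return HeterogeneityStats(fit.method, q, df, float(i2), float(stats.chi2.sf(q, df)))


def egger_intercept_test(
    instruments: Instruments, **egger_kwargs
) -> tuple[float, float, float]:
    """Directional-pleiotropy test: the Egger intercept with SE and t p-value.

    An intercept p-value >= 0.05 is conventionally read as no evidence of
    directional pleiotropy.
    """
    fit = egger(instruments, **egger_kwargs)
    return fit.intercept, fit.intercept_se, fit.intercept_pval


def leave_one_out(
    instruments: InstrumentSet, level_z: float = Z_95, **ivw_kwargs
) -> LeaveOneOutResult:
    """Re-fit IVW with each instrument removed in turn.

    Returns one row per dropped variant (input order) plus an ``all`` row;
    requires >= 3 instruments so every reduced set still supports IVW.
    """
    L = len(instruments)
    if L < 3:
        raise ValueError("leave-one-out requires at least 3 instruments")
    full = ivw(instruments, level_z=level_z, **ivw_kwargs)
    rows = []
    for ins in instruments:
        fit = ivw(instruments.drop(ins.variant_id), level_z=level_z, **ivw_kwargs)
        rows.append(
            {
                "SNP": ins.variant_id,
                "beta": fit.beta,
                "se": fit.se,
                "ci_lower_log": fit.beta - level_z * fit.se,
                "ci_upper_log": fit.beta + level_z * fit.se,
            }
        )
    rows.append(
        {
            "SNP": "all",
            "beta": full.beta,
            "se": full.se,
            "ci_lower_log": full.beta - level_z * full.se,
            "ci_upper_log": full.beta + level_z * full.se,
        }
    )
    return LeaveOneOutResult(table=pd.DataFrame(rows), full_estimate=full)


def diagnostic_datasets(
    instruments: Instruments,
    fits: Sequence[MREstimate],
    level_z: float = Z_95,
) -> dict[str, pd.DataFrame]:
    """Plot-ready tables for forest, scatter and funnel diagnostics.

    ``forest``: per-SNP Wald ratio with CI plus one combined row per fit.
    ``scatter``: per-SNP (beta_X, beta_Y) with per-axis CIs, plus per-method
    regression lines (slope, and intercept for Egger).
    ``funnel``: per-SNP ratio against precision ``1 / se(ratio)`` with one
    vertical line per method.  All numbers live in these tables; rendering
    only draws them.
    """
    if not fits:
        raise ValueError("at least one fit is required")
    wr = wald_ratios(instruments)
    bx, sx, by, sy = _arrays(instruments)

    forest_rows = [
        {
            "label": x.variant_id,
            "kind": "snp",
            "beta": x.ratio,
            "ci_lower_log": x.ratio - level_z * x.se_first_order,
            "ci_upper_log": x.ratio + level_z * x.se_first_order,
        }
        for x in wr
    ]
    for fit in fits:
        forest_rows.append(
            {
                "label": fit.method,
                "kind": "combined",
                "beta": fit.beta,
                "ci_lower_log": fit.beta - level_z * fit.se,
                "ci_upper_log": fit.beta + level_z * fit.se,
            }
        )

    scatter = pd.DataFrame(
        {
            "SNP": [x.variant_id for x in wr],
            "beta_exposure": bx,
            "se_exposure": sx,
            "beta_outcome": by,
            "se_outcome": sy,
            "x_lo": bx - level_z * sx,
            "x_hi": bx + level_z * sx,
            "y_lo": by - level_z * sy,
            "y_hi": by + level_z * sy,
        }
    )
    lines = pd.DataFrame(
        {
            "method": [f.method for f in fits],
            "slope": [f.beta for f in fits],
            "intercept": [f.intercept if f.intercept is not None else 0.0 for f in fits],
        }
    )

    funnel = pd.DataFrame(
        {
            "SNP": [x.variant_id for x in wr],
            "ratio": [x.ratio for x in wr],
            "precision": [1.0 / x.se_first_order for x in wr],
        }
    )
    funnel_lines = pd.DataFrame(
        {"method": [f.method for f in fits], "beta": [f.beta for f in fits]}
    )

    return {
        "forest": pd.DataFrame(forest_rows),
        "scatter": scatter,
        "scatter_lines": lines,
        "funnel": funnel,
        "funnel_lines": funnel_lines,
    }
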