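"""Read GWAS summary-statistics tables, harmonize alleles, select instruments.

Input is tab-separated text with a header row.  The default column names are
``SNP, chrom_pos, effect_allele, other_allele, eaf, beta, se, pval, n``; a
``column_map`` argument renames them for other dialects.  A two-block dialect
(shared variant columns plus per-trait beta/SE/P blocks, as printed in
published per-SNP instrument tables) is read by :func:`read_two_block`.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import COMPLEMENT, HarmonizedInstrument, InstrumentSet, SummaryStatRecord

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS: Mapping[str, str] = {
    "variant_id": "SNP",
    "chrom_pos": "chrom_pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

_OPTIONAL_FIELDS = ("other_allele", "eaf", "n", "chrom_pos")


class NoInstrumentsError(RuntimeError):
    """Raised when instrument selection leaves nothing to estimate with."""


def _parse_optional_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip().upper() in ("", "NA", "NAN", "."):
        return None
    return float(value)


def _parse_allele(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().upper()
    if s in ("", "NA", "NAN", "."):
        return None
    return s


def read_sumstats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[SummaryStatRecord]:
    """Read a tab-separated summary-statistics table into records.

    Rows with missing beta or SE, non-positive SE, or unparseable numerics
    are rejected with a logged reason; the remaining rows are returned in
    file order.

    Parameters
    ----------
    path : path-like
        TSV file with header.
    column_map : mapping, optional
        Maps the field names ``variant_id, chrom_pos, effect_allele,
        other_allele, eaf, beta, se, pval, n`` to the file's column names.
        Unspecified fields use :data:`DEFAULT_COLUMNS`.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [cols[f] for f in ("variant_id", "effect_allele", "beta", "se", "pval")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mapped column(s) {missing}")
    if df.empty:
        logger.warning("%s: header-only file, no records read", path)
        return []

    records: list[SummaryStatRecord] = []
    n_rejected = 0
    for idx, row in df.iterrows():
        vid = str(row[cols["variant_id"]])
        try:
            beta = float(row[cols["beta"]])
            se = float(row[cols["se"]])
            pval = float(row[cols["pval"]])
            rec = SummaryStatRecord(
                variant_id=vid,
                chrom_pos=(
                    str(row[cols["chrom_pos"]]) if cols["chrom_pos"] in df.columns else ""
                ),
                effect_allele=_parse_allele(row[cols["effect_allele"]]),
                other_allele=(
                    _parse_allele(row[cols["other_allele"]])
                    if cols["other_allele"] in df.columns
                    else None
                ),
                eaf=(
                    _parse_optional_float(row[cols["eaf"]])
                    if cols["eaf"] in df.columns
                    else None
                ),
                beta=beta,
                se=se,
                pval=pval,
                n=(
                    int(float(row[cols["n"]]))
                    if cols["n"] in df.columns and _parse_optional_float(row[cols["n"]]) is not None
                    else None
                ),
            )
        except (TypeError, ValueError) as exc:
            n_rejected += 1
            logger.warning("%s row %d (%s): rejected — %s", path, idx, vid, exc)
            continue
        records.append(rec)
    if n_rejected:
        logger.warning("%s: rejected %d of %d rows", path, n_rejected, len(df))
    return records


def read_two_block(
    path,
    exposure_prefix: str = "exposure",
    outcome_prefix: str = "outcome",
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord]]:
    """Read a two-block per-SNP table: shared variant columns + per-trait blocks.

    Expected columns: ``SNP, chrom_pos, effect_allele[, other_allele, eaf]``
    plus ``<prefix>_beta, <prefix>_se, <prefix>_pval[, <prefix>_n]`` for each
    of the two traits.
    """
    exp, out = [], []
    for prefix, dest in ((exposure_prefix, exp), (outcome_prefix, out)):
        cmap = {
            "beta": f"{prefix}_beta",
            "se": f"{prefix}_se",
            "pval": f"{prefix}_pval",
            "n": f"{prefix}_n",
        }
        dest.extend(read_sumstats(path, column_map=cmap))
    return exp, out


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic, ``(beta / se)**2``.

    F > 10 is the conventional weak-instrument screen in MR.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def _merge(
    exp: SummaryStatRecord,
    out: SummaryStatRecord,
    beta_outcome: float,
    eaf_outcome: Optional[float],
    flipped: bool,
    palindromic: Optional[bool],
) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        variant_id=exp.variant_id,
        beta_exposure=exp.beta,
        se_exposure=exp.se,
        beta_outcome=beta_outcome,
        se_outcome=out.se,
        eaf=exp.eaf,
        f_stat=f_statistic(exp.beta, exp.se),
        flipped=flipped,
        palindromic=palindromic,
        pval_exposure=exp.pval,
        pval_outcome=out.pval,
        chrom_pos=exp.chrom_pos,
    )


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindrome_eaf_window: float = 0.08,
    drop_palindromic_ambiguous: bool = True,
) -> list[HarmonizedInstrument]:
    """Align outcome effects to the exposure's effect allele, per shared variant.

    Rules, in order: (a) identical allele orientation passes through;
    (b) swapped alleles negate the outcome beta and complement its EAF;
    (c) strand-complemented alleles are complemented first, then (a)/(b);
    (d) palindromic variants (A/T or C/G pairs) are resolved by EAF agreement
    when both frequencies lie outside the ambiguous band
    ``[0.5 - window, 0.5 + window]``, otherwise dropped when
    ``drop_palindromic_ambiguous`` is set.  When the other allele is unknown
    the comparison falls back to effect-allele equality only, with
    ``palindromic = None`` and a warning.  Unresolvable allele pairs are
    dropped with a logged reason, never silently kept.
    """
    out_by_id = {r.variant_id: r for r in outcome}
    harmonized: list[HarmonizedInstrument] = []
    warned_unknown_oa = False
    for exp in exposure:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            continue
        ea_x, oa_x = exp.effect_allele, exp.other_allele
        ea_y, oa_y = out.effect_allele, out.other_allele

        if oa_x is None or oa_y is None:
            # Effect-allele-only fallback; strandedness cannot be assessed.
            if not warned_unknown_oa:
                logger.warning(
                    "other allele unknown for some variants; harmonizing on "
                    "effect-allele equality only (palindromic status unknown)"
                )
                warned_unknown_oa = True
            if ea_y == ea_x or COMPLEMENT[ea_y] == ea_x:
                harmonized.append(_merge(exp, out, out.beta, out.eaf, False, None))
            else:
                harmonized.append(
                    _merge(
                        exp,
                        out,
                        -out.beta,
                        None if out.eaf is None else 1 - out.eaf,
                        True,
                        None,
                    )
                )
            continue

        palindromic = COMPLEMENT[ea_x] == oa_x
        if palindromic:
            # Allele labels cannot distinguish strands; use EAF agreement.
            lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window
            if (
                exp.eaf is None
                or out.eaf is None
                or lo <= exp.eaf <= hi
                or lo <= out.eaf <= hi
            ):
                if drop_palindromic_ambiguous:
                    logger.warning(
                        "%s: palindromic with ambiguous EAF, dropped", exp.variant_id
                    )
                    continue
                logger.warning(
                    "%s: palindromic with ambiguous EAF, kept as-is", exp.variant_id
                )
                harmonized.append(_merge(exp, out, out.beta, out.eaf, False, True))
                continue
            same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
            if same_side:
                harmonized.append(_merge(exp, out, out.beta, out.eaf, False, True))
            else:
                harmonized.append(_merge(exp, out, -out.beta, 1 - out.eaf, True, True))
            continue

        if (ea_y, oa_y) == (ea_x, oa_x):
            harmonized.append(_merge(exp, out, out.beta, out.eaf, False, False))
        elif (ea_y, oa_y) == (oa_x, ea_x):
            harmonized.append(
                _merge(
                    exp,
                    out,
                    -out.beta,
                    None if out.eaf is None else 1 - out.eaf,
                    True,
                    False,
                )
            )
        elif (COMPLEMENT[ea_y], COMPLEMENT[oa_y]) == (ea_x, oa_x):
            harmonized.append(_merge(exp, out, out.beta, out.eaf, False, False))
        elif (COMPLEMENT[ea_y], COMPLEMENT[oa_y]) == (oa_x, ea_x):
            harmonized.append(
                _merge(
                    exp,
                    out,
                    -out.beta,
                    None if out.eaf is None else 1 - out.eaf,
                    True,
                    False,
                )
            )
        else:
            logger.warning(
                "%s: allele pair %s/%s vs %s/%s unresolvable, dropped",
                exp.variant_id,
                ea_x,
                oa_x,
                ea_y,
                oa_y,
            )
    return harmonized


def select_instruments(
    harmonized: Sequence[HarmonizedInstrument],
    p_threshold: float = 5e-8,
    ld_r2: Optional[Mapping[tuple[str, str], float]] = None,
    r2_threshold: float = 0.1,
    f_threshold: float = 10.0,
) -> InstrumentSet:
    """Filter instruments by exposure significance, strength, and LD independence.

    Keeps variants with exposure p-value below ``p_threshold`` and F statistic
    above ``f_threshold``, then greedily clumps: candidates sorted by
    ascending exposure p-value (ties broken by variant_id) are retained iff
    their pairwise r-squared with every already-retained variant is below
    ``r2_threshold``.  Pairs absent from ``ld_r2`` are treated as independent
    with a logged warning.  The returned set preserves the input row order.

    Raises
    ------
    NoInstrumentsError
        If the filters leave no instruments (estimation is impossible),
        distinct from success on genuinely empty input.
    """
    if p_threshold <= 0 or r2_threshold <= 0 or f_threshold < 0:
        raise ValueError("thresholds must be positive")
    candidates = [
        ins
        for ins in harmonized
        if ins.pval_exposure < p_threshold and ins.f_stat > f_threshold
    ]
    if harmonized and not candidates:
        raise NoInstrumentsError(
            f"no instrument passed p < {p_threshold:g} and F > {f_threshold:g}"
        )

    def pair_r2(a: str, b: str) -> Optional[float]:
        if ld_r2 is None:
            return None
        for key in ((a, b), (b, a)):
            if key in ld_r2:
                return float(ld_r2[key])
        return None

    retained: list[HarmonizedInstrument] = []
    warned_missing = False
    for ins in sorted(candidates, key=lambda i: (i.pval_exposure, i.variant_id)):
        independent = True
        for kept in retained:
            r2 = pair_r2(ins.variant_id, kept.variant_id)
            if r2 is None:
                if ld_r2 is not None and not warned_missing:
                    logger.warning(
                        "some variant pairs absent from the LD matrix are "
                        "treated as independent"
                    )
                    warned_missing = True
                continue
            if r2 >= r2_threshold:
                independent = False
                break
        if independent:
            retained.append(ins)
    if harmonized and not retained:
        raise NoInstrumentsError("LD clumping removed every instrument")

    retained_ids = {ins.variant_id for ins in retained}
    ordered = [ins for ins in harmonized if ins.variant_id in retained_ids]
    return InstrumentSet(
        ordered,
        selection={
            "p_threshold": p_threshold,
            "r2_threshold": r2_threshold,
            "f_threshold": f_threshold,
        },
    )


def instruments_to_frame(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Tabulate harmonized instruments (one row per variant)."""
    return pd.DataFrame(
        {
            "SNP": [i.variant_id for i in instruments],
            "chrom_pos": [i.chrom_pos for i in instruments],
            "eaf": [i.eaf for i in instruments],
            "beta_exposure": [i.beta_exposure for i in instruments],
            "se_exposure": [i.se_exposure for i in instruments],
            "pval_exposure": [i.pval_exposure for i in instruments],
            "beta_outcome": [i.beta_outcome for i in instruments],
            "se_outcome": [i.se_outcome for i in instruments],
            "pval_outcome": [i.pval_outcome for i in instruments],
            "flipped": [i.flipped for i in instruments],
            "palindromic": [i.palindromic for i in instruments],
            "F": [i.f_stat for i in instruments],
        }
    )


def write_instruments(instruments: Sequence[HarmonizedInstrument], path) -> None:
    """Write the harmonized-instrument table as TSV."""
    instruments_to_frame(instruments).to_csv(path, sep="\t", index=False)
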