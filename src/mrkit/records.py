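"""Core record types for two-sample Mendelian randomization.

A :class:`SummaryStatRecord` holds one variant's association with one trait,
as read from a GWAS summary-statistics table.  After allele alignment the
exposure and outcome associations of a variant are merged into a
:class:`HarmonizedInstrument`, and the post-selection collection is an
:class:`InstrumentSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

_VALID_ALLELES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association with one trait.

    Parameters
    ----------
    variant_id : str
        rsID (or any unique variant label).
    chrom_pos : str
        Opaque 1-based "chr: position" label; no coordinate arithmetic is
        ever performed on it.
    effect_allele : str
        The allele ``beta`` refers to (A/C/G/T).
    other_allele : str or None
        The non-effect allele, if known.
    eaf : float or None
        Effect-allele frequency in [0, 1].
    beta : float
        Per-allele effect in trait units (log-odds for binary traits).
    se : float
        Standard error of ``beta``; strictly positive.
    pval : float
        Association p-value in (0, 1].
    n : int or None
        Sample size.
    """

    variant_id: str
    chrom_pos: str
    effect_allele: str
    other_allele: Optional[str]
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(
                f"{self.variant_id}: effect_allele must be one of A/C/G/T, "
                f"got {self.effect_allele!r}"
            )
        if self.other_allele is not None:
            if self.other_allele not in _VALID_ALLELES:
                raise ValueError(
                    f"{self.variant_id}: other_allele must be one of A/C/G/T "
                    f"or unknown, got {self.other_allele!r}"
                )
            if self.other_allele == self.effect_allele:
                raise ValueError(
                    f"{self.variant_id}: effect and other allele are equal"
                )
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: beta is not finite")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: pval must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.variant_id}: eaf must be in [0, 1]")

    @property
    def is_palindromic(self) -> Optional[bool]:
        """True for A/T or C/G allele pairs; None when the other allele is unknown."""
        if self.other_allele is None:
            return None
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A variant with exposure and outcome effects on a shared effect allele.

    ``flipped`` records whether the outcome orientation was reversed during
    harmonization; ``palindromic`` is None when the other allele was unknown
    and strandedness could not be assessed.
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: Optional[float]
    f_stat: float
    flipped: bool
    palindromic: Optional[bool]
    pval_exposure: float
    pval_outcome: Optional[float] = None
    chrom_pos: str = ""

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"{self.variant_id}: standard errors must be > 0")
        expected_f = (self.beta_exposure / self.se_exposure) ** 2
        if not np.isclose(self.f_stat, expected_f, rtol=1e-9, atol=1e-12):
            raise ValueError(
                f"{self.variant_id}: f_stat {self.f_stat} inconsistent with "
                f"(beta/se)^2 = {expected_f}"
            )


@dataclass
class InstrumentSet:
    """Ordered, duplicate-free collection of harmonized instruments.

    ``selection`` records the thresholds that produced the set
    (p-value, LD r-squared, F).
    """

    instruments: Sequence[HarmonizedInstrument]
    selection: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [ins.variant_id for ins in self.instruments]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate variant_id in instrument set")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.instruments)

    def __getitem__(self, i: int) -> HarmonizedInstrument:
        return self.instruments[i]

    @property
    def variant_ids(self) -> list[str]:
        return [ins.variant_id for ins in self.instruments]

    @property
    def beta_exposure(self) -> np.ndarray:
        return np.array([ins.beta_exposure for ins in self.instruments])

    @property
    def se_exposure(self) -> np.ndarray:
        return np.array([ins.se_exposure for ins in self.instruments])

    @property
    def beta_outcome(self) -> np.ndarray:
        return np.array([ins.beta_outcome for ins in self.instruments])

    @property
    def se_outcome(self) -> np.ndarray:
        return np.array([ins.se_outcome for ins in self.instruments])

    def drop(self, variant_id: str) -> "InstrumentSet":
        """Return a copy of the set without ``variant_id`` (for leave-one-out)."""
        kept = [ins for ins in self.instruments if ins.variant_id != variant_id]
        if len(kept) == len(self.instruments):
            raise KeyError(variant_id)
        return InstrumentSet(kept, dict(self.selection))
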