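import numpy as np
import pytest

from mrkit.datasets import load_aspirin_hayfever
from mrkit.records import HarmonizedInstrument, InstrumentSet
from mrkit.sumstats_io import harmonize, select_instruments


@pytest.fixture(scope="session")
def aspirin_records():
    """Packaged 7-SNP exposure/outcome record pair."""
    return load_aspirin_hayfever()


@pytest.fixture(scope="session")
def aspirin_instruments(aspirin_records) -> InstrumentSet:
    exposure, outcome = aspirin_records
    return select_instruments(harmonize(exposure, outcome))


def make_instrument(
    vid="v",
    bx=0.01,
    sx=0.001,
    by=0.003,
    sy=0.002,
    eaf=0.3,
    flipped=False,
    palindromic=False,
    pval=1e-10,
) -> HarmonizedInstrument:
    """Hand-rolled harmonized instrument for unit tests."""
    return HarmonizedInstrument(
        variant_id=vid,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        eaf=eaf,
        f_stat=(bx / sx) ** 2,
        flipped=flipped,
        palindromic=palindromic,
        pval_exposure=pval,
    )


def instrument_set_from_arrays(bx, sx, by, sy) -> InstrumentSet:
    """Build an InstrumentSet directly from effect/SE arrays."""
    return InstrumentSet(
        [
            make_instrument(vid=f"v{j}", bx=float(bx[j]), sx=float(sx[j]), by=float(by[j]), sy=float(sy[j]))
            for j in range(len(bx))
        ]
    )


def random_instrument_set(rng: np.random.Generator, L: int) -> InstrumentSet:
    bx = rng.normal(0.01, 0.004, L)
    bx[bx == 0] = 0.001
    sx = rng.uniform(5e-4, 2e-3, L)
    by = rng.normal(0.0, 0.005, L)
    sy = rng.uniform(1e-3, 4e-3, L)
    return instrument_set_from_arrays(bx, sx, by, sy)
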