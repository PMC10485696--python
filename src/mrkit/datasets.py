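"""Packaged instrument extract: aspirin use vs. hayfever/allergic rhinitis.

The bundled fixture is the seven-variant instrument table for the UK
Biobank / Neale-lab GWAS pair used in the published aspirin-use MR analysis
(MR-Base ids ukb-a-132, aspirin use, n = 337,159 as exposure; ukb-a-254,
doctor-diagnosed hayfever or allergic rhinitis, n = 83,529 as outcome).  It
ships as two tiny TSV files in the standard summary-statistics dialect; the
full GWAS datasets are never downloaded.

``PUBLISHED`` collects the values the originating analysis reported for this
extract, used by the reproduction report to flag each quantity as reproduced
or as a documented discrepancy.
"""

from __future__ import annotations

from importlib import resources

from .records import SummaryStatRecord
from .sumstats_io import read_sumstats

EXPOSURE_FILE = "aspirin_use_7snp.tsv"
OUTCOME_FILE = "hayfever_rhinitis_7snp.tsv"

# Values reported in the originating analysis of these datasets.  Several are
# not reproducible from the per-SNP table itself (see docs/methods.md); the
# reproduction report flags those as documented discrepancies.
PUBLISHED = {
    "f_stat": {
        "rs10455872": 78.68497578,
        "rs117733303": 41.97722735,
        "rs1831733": 76.55860496,
        "rs2521501": 30.66181305,
        "rs583104": 40.22202655,
        "rs73015016": 32.78123454,
        "rs7412": 38.51095695,
    },
    "ivw": {"beta": -0.349, "se": 0.1356, "pval": 0.0101, "or": 0.7054, "ci_lower": 0.5408},
    "egger": {
        "beta": -0.3742,
        "se": 0.3809,
        "pval": 0.371,
        "or": 0.6878,
        "ci_lower": 0.3260,
        "ci_upper": 1.4512,
        "intercept": 0.00021,
        "intercept_se": 0.003,
        "intercept_pval": 0.946,
    },
    "weighted_median": {
        "beta": -0.4155,
        "se": 0.1655,
        "pval": 0.0121,
        "or": 0.6600,
        "ci_lower": 0.4772,
    },
    "heterogeneity": {
        "ivw": {"Q": 2.148, "i2_magnitude": 1.793, "pval": 0.9056, "df": 6},
        "egger": {"Q": 2.143, "i2_magnitude": 1.333, "pval": 0.8291, "df": 5},
    },
    "n_snps": 7,
}


def _data_path(name: str):
    return resources.files("mrkit.data").joinpath(name)


def load_aspirin_hayfever() -> tuple[list[SummaryStatRecord], list[SummaryStatRecord]]:
    """Load the packaged 7-SNP exposure and outcome summary statistics."""
    with resources.as_file(_data_path(EXPOSURE_FILE)) as p:
        exposure = read_sumstats(p)
    with resources.as_file(_data_path(OUTCOME_FILE)) as p:
        outcome = read_sumstats(p)
    return exposure, outcome
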