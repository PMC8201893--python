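"""Published reference tables for regression testing and examples.

The packaged TSVs hold the regional results of a published multicenter
retrospective SCLC brain-metastasis cohort (215 patients, 1,033 lesions; 1,026
lesion centroids fell inside the coarse structural parcellation and enter the
tests): region volumes, expected rates, observed counts and rates, z-scores,
and P-values for a coarse ~10-region structural parcellation ("mni") and a
merged fine parcellation with manually added structures ("aal").

Values are stored exactly as printed, including two internal inconsistencies
of the source tables, tagged in the ``flag`` column so tests assert against
recomputation rather than the discrepant cell:

* ``expected_rate_z_inconsistent`` (precentral gyrus): the printed expected
  rate (2.94%) does not reproduce the printed z (3.02; recomputation gives
  ~2.93).
* ``z_rate_rounding_inconsistent`` (amygdala, Heschl's gyrus): the printed z
  disagrees with the two-decimal printed expected rate by more than rounding
  of z itself explains (e.g. amygdala -1.422 printed vs -1.397 recomputed).

The source also quotes a 5.26% cumulative key-structure incidence in one
place and 6.62% in another; the seven per-structure frequencies stored here
sum to 6.62%, which is the figure the fixtures reproduce.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "reference_table",
    "mni_table",
    "aal_table",
    "KEY_STRUCTURE_FREQUENCIES_PCT",
    "TOTAL_LESIONS",
    "N_ASSIGNED",
    "K_ROIS",
    "ALPHA",
]

#: cohort total lesion count
TOTAL_LESIONS = 1033
#: lesions whose centroid fell inside the parcellation (the test denominator n)
N_ASSIGNED = 1026
#: size of the Bonferroni family used by the source analysis
K_ROIS = 53
#: uncorrected significance level
ALPHA = 0.05

#: observed frequencies (%) of the radiosensitive key structures
KEY_STRUCTURE_FREQUENCIES_PCT = {
    "hippocampus": 0.68,
    "parahippocampus": 0.97,
    "brainstem": 2.05,
    "caudatum": 0.68,
    "putamen": 0.68,
    "pallidum": 0.2,
    "thalamus": 1.36,
}


def reference_table(which: str) -> pd.DataFrame:
    """Load a packaged reference table (``"mni"`` or ``"aal"``).

    Columns: region, volume_mm3, expected_rate_pct, observed_count,
    observed_rate_pct, z, p_value, flag (NaN where the printed cell is
    internally consistent).
    """
    which = which.lower()
    if which not in {"mni", "aal"}:
        raise ValueError(f"unknown reference table '{which}'; expected 'mni' or 'aal'")
    ref = resources.files("bmrisk.data").joinpath(f"{which}_reference.tsv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def mni_table() -> pd.DataFrame:
    """Coarse structural-parcellation reference table (10 regions, n = 1,026)."""
    return reference_table("mni")


def aal_table() -> pd.DataFrame:
    """Merged fine-parcellation reference table (22 printed regions, n = 1,026)."""
    return reference_table("aal")
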