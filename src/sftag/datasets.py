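"""Bundled reference data."""

from importlib import resources

import pandas as pd

__all__ = ["load_reference_cohort"]


def load_reference_cohort() -> pd.DataFrame:
    """Reference cohort table: 15 AMD patients and 16 age-matched controls.

    Columns: participant ``id``, ``group`` (AMD/control), visual acuity
    ``logmar``, contrast sensitivity ``logcs``, SSVEP SNR in dB to the
    higher and lower spatial-frequency sets (``ssvep_higher_db``,
    ``ssvep_lower_db``) and the published neuromarker ``log_ratio`` =
    ln(lower/higher linear SNR).  Used to validate the marker algebra
    and as a realistic cohort for examples.
    """
    with resources.files("sftag.data").joinpath("reference_cohort.csv").open() as f:
        return pd.read_csv(f)
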