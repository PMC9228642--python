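"""Packaged reference dataset: published per-formulation rates and kinetics.

``reference_rates.csv`` holds mean ± SD wetting/gel/erosion rates (mm/min)
for seven formulations in two media; ``reference_kinetics.csv`` holds the
fitted kinetic parameters and fit criteria for the two supported models.
Blank cells are ND (not determined).
"""

from importlib.resources import files

import pandas as pd

__all__ = ["load_reference_rates", "load_reference_kinetics"]


def _read(name: str) -> pd.DataFrame:
    with (files(__package__) / name).open("rb") as fh:
        return pd.read_csv(fh)


def load_reference_rates() -> pd.DataFrame:
    """Rates table: formulation_id, medium, kind, mean_rate, sd_rate, n."""
    return _read("reference_rates.csv")


def load_reference_kinetics() -> pd.DataFrame:
    """Kinetics table: per formulation x model, criteria and parameters."""
    return _read("reference_kinetics.csv")
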