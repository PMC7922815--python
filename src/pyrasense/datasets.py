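"""Packaged reference tables for the Baijiu pyrazine study.

All tables are small CSV files shipped with the package:

``ssab_concentrations`` / ``ssab_concentration_rsd``
    Mean triplicate concentrations (μg·L⁻¹) and replicate RSDs (%) of 16
    pyrazines across 11 commercial soy-sauce-aroma Baijiu samples.
``odor_thresholds``
    Per-compound odor thresholds (μg·L⁻¹) in 53% (v/v) ethanol/water, tagged
    with their provenance (measured in-study, literature, or a published
    threshold compilation).
``spike_additions`` / ``spike_design``
    The ten 3-AFC spike experiments: per-compound addition levels into the
    lowest-intensity sample, and the presence/absence grid with the observed
    significance codes.
``dilution_series``
    The nine-step factor-2 volume ladder (mL of pyrazine stock into 15 mL of
    matrix) used for threshold determination.
``mixture_stocks``
    Stock concentrations of the four supra-threshold and four sub-threshold
    pyrazines composing the two mixture bundles.
``mrm_transitions``
    Instrument metadata (MRM transitions, retention times, voltages) for the
    16 pyrazines plus internal standard; reference only, never executed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .oav import read_concentration_table, read_threshold_table


def _path(name: str):
    return resources.files("pyrasense.data").joinpath(name)


def load_concentrations() -> pd.DataFrame:
    """16 pyrazines × 11 Baijiu samples, mean concentrations in μg·L⁻¹."""
    with resources.as_file(_path("ssab_concentrations.csv")) as p:
        return read_concentration_table(p)


def load_concentration_rsd() -> pd.DataFrame:
    """Replicate RSDs (%) matching :func:`load_concentrations`."""
    with resources.as_file(_path("ssab_concentration_rsd.csv")) as p:
        return pd.read_csv(p).set_index("compound").astype(float)


def load_thresholds() -> pd.DataFrame:
    """Odor thresholds (μg·L⁻¹, 53% ethanol/water) for the 16 pyrazines."""
    with resources.as_file(_path("odor_thresholds.csv")) as p:
        return read_threshold_table(p)


def load_spike_additions() -> pd.DataFrame:
    """Spike concentrations (μg·L⁻¹) used in the addition experiments."""
    with resources.as_file(_path("spike_additions.csv")) as p:
        return pd.read_csv(p).set_index("compound")


def load_spike_design() -> pd.DataFrame:
    """Presence/absence grid of the ten spike tests with observed codes."""
    with resources.as_file(_path("spike_design.csv")) as p:
        return pd.read_csv(p).set_index("test")


def load_dilution_series() -> pd.DataFrame:
    """The printed nine-step dose ladder (volumes in mL into 15 mL matrix)."""
    with resources.as_file(_path("dilution_series.csv")) as p:
        return pd.read_csv(p)


def load_mixture_stocks() -> pd.DataFrame:
    """Stock concentrations of the supra-/sub-threshold mixture bundles."""
    with resources.as_file(_path("mixture_stocks.csv")) as p:
        return pd.read_csv(p).set_index("compound")


def load_mrm_transitions() -> pd.DataFrame:
    """Reference UPLC–MS/MS acquisition metadata (not used in computation)."""
    with resources.as_file(_path("mrm_transitions.csv")) as p:
        return pd.read_csv(p)
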