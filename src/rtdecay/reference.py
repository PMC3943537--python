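"""Packaged reference decay-parameter table.

Published room-temperature radiation-damage statistics for 15 model protein
crystal systems: solvent content, resolution limit, dose-rate range and the
per-structure averages and standard deviations of beta (Angstrom^2/MGy),
gamma (1/MGy) and the normalized half-dose D1/2* (MGy).

Eight structures with full statistics serve as the curve-calibration set;
six further structures are held out for validation of the calibrated curve;
the remaining single-measurement entry (TIM) carries no standard deviations
and belongs to neither split.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_reference_parameters",
    "calibration_rows",
    "validation_rows",
    "CALIBRATION_ACRONYMS",
    "VALIDATION_ACRONYMS",
]

CALIBRATION_ACRONYMS = (
    "BPTTR",
    "BPTOH",
    "BPTOL",
    "LYZT",
    "INSR",
    "THER",
    "FAE",
    "6HLNO",
)

VALIDATION_ACRONYMS = ("LYZM", "INSC", "THAU", "TvNiR", "LACV", "bR")


def load_reference_parameters() -> pd.DataFrame:
    """The packaged 15-structure reference table as a DataFrame."""
    ref = resources.files("rtdecay.data") / "reference_parameters.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    table["solvent_fraction"] = table["solvent_percent"] / 100.0
    return table


def _rows_for(acronyms: tuple[str, ...]) -> np.ndarray:
    table = load_reference_parameters().set_index("acronym")
    return np.array(
        [
            (
                table.loc[a, "beta_ave_A2_MGy"],
                table.loc[a, "gamma_ave_MGy"],
                table.loc[a, "dhalf_norm_ave_MGy"],
            )
            for a in acronyms
        ],
        dtype=float,
    )


def calibration_rows() -> np.ndarray:
    """(beta, gamma, D1/2*) triples for the eight calibration structures."""
    return _rows_for(CALIBRATION_ACRONYMS)


def validation_rows() -> np.ndarray:
    """(beta, gamma, D1/2*) triples for the six held-out structures."""
    return _rows_for(VALIDATION_ACRONYMS)
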