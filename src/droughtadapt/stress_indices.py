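"""The six classical drought-stress indices computed from condition means.

Given per-genotype control and stress means (C, T) and the population means
(C̄, T̄), the screening literature defines:

    DC  = T / C                      drought resistance coefficient
    GMP = sqrt(T * C)                geometric mean productivity
    MP  = (T + C) / 2                mean productivity
    SSI = (1 - T/C) / (1 - T̄/C̄)     stress susceptibility index
    STI = C * T / C̄²                 stress tolerance index
    TOL = C - T                      tolerance (absolute loss)

DC, GMP, MP and STI are positively oriented (higher = more drought-adapted);
SSI and TOL are negatively oriented.  All are computed from genotype replicate
means, never per replicate.  Useful algebraic identities (tested as
invariants): STI = (GMP/C̄)², TOL = C(1-DC), SSI = (1-DC)/(1-T̄/C̄).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .phenotype_io import PopulationMeans

logger = logging.getLogger(__name__)

INDEX_NAMES = ["DC", "GMP", "MP", "SSI", "STI", "TOL"]
POSITIVE_INDICES = ["DC", "GMP", "MP", "STI"]
NEGATIVE_INDICES = ["SSI", "TOL"]


def ssi_from_dc(dc: float | np.ndarray, pm: PopulationMeans) -> float | np.ndarray:
    """Stress susceptibility index as a function of the drought coefficient.

    SSI = (1 - DC) / (1 - T̄/C̄); an affine map of DC used for cross-checks:
    the population mean/min/max of DC determine the mean/max/min of SSI.
    """
    ratio = pm.stress_ratio
    if ratio == 1.0:
        raise DegenerateDataError(
            "SSI undefined: population stress ratio T_bar/C_bar equals 1"
        )
    return (1.0 - dc) / (1.0 - ratio)


def compute_stress_indices(
    gm: pd.DataFrame,
    pm: PopulationMeans,
    on_zero_control: str = "abort",
) -> pd.DataFrame:
    """Compute DC, GMP, MP, SSI, STI, TOL for every genotype.

    Parameters
    ----------
    gm : GenotypeMeans frame (columns genotype, C, T).
    pm : population means the ratio-based indices depend on.
    on_zero_control : ``"abort"`` raises on any genotype with C = 0 (DC and
        SSI need division by C); ``"drop"`` excludes such genotypes with a
        logged warning.

    Returns a frame with one row per genotype and columns genotype, DC, GMP,
    MP, SSI, STI, TOL; the population means used are attached in ``.attrs``.
    """
    if on_zero_control not in {"abort", "drop"}:
        raise ValueError("on_zero_control must be 'abort' or 'drop'")
    if pm.c_bar <= 0:
        raise DegenerateDataError("population control mean must be positive")

    zero_c = gm["C"] == 0
    if zero_c.any():
        bad = gm.loc[zero_c, "genotype"].tolist()
        if on_zero_control == "abort":
            raise ValidationError(
                f"genotype(s) with zero control mean: {bad}; DC/SSI undefined"
            )
        logger.warning("excluding %d genotype(s) with zero control mean: %s",
                       len(bad), bad)
        gm = gm.loc[~zero_c].reset_index(drop=True)

    c = gm["C"].to_numpy(float)
    t = gm["T"].to_numpy(float)
    dc = t / c
    out = pd.DataFrame(
        {
            "genotype": gm["genotype"].to_numpy(),
            "DC": dc,
            "GMP": np.sqrt(t * c),
            "MP": (t + c) / 2.0,
            "SSI": ssi_from_dc(dc, pm),
            "STI": c * t / pm.c_bar**2,
            "TOL": c - t,
        }
    )
    out.attrs["population_means"] = pm
    return out


def write_stress_indices(sit: pd.DataFrame, path: str | Path) -> None:
    """Write the index table as tidy CSV with the population means in a sidecar JSON."""
    path = Path(path)
    sit.to_csv(path, index=False, float_format="%.6g")
    pm: PopulationMeans | None = sit.attrs.get("population_means")
    if pm is not None:
        sidecar = path.with_suffix(".population_means.json")
        sidecar.write_text(
            json.dumps(
                {"c_bar": pm.c_bar, "t_bar": pm.t_bar, "n_genotypes": pm.n_genotypes},
                indent=2,
            )
            + "\n"
        )
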