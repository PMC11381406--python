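"""Min-max feature scaling of the six indices and the PI/EI composites.

The six stress indices differ in units, magnitude and direction of action.
Positively oriented indices (DC, GMP, MP, STI) are scaled to [0, 1] with

    x_n = (x - x_min) / (x_max - x_min)

and negatively oriented ones (SSI, TOL) with the reversed map

    y_n = (y_max - y) / (y_max - y_min)

so that after scaling higher always means more drought-adapted.  Bounds are
the observed extremes of the analysed population, recomputed per run and
reported alongside the output.  Two composites summarise the scaled table:

    PI (potential index)  = mean(DCn, GMPn, MPn, STIn)
    EI (elasticity index) = mean(SSIn, TOLn)

both on [0, 1] by construction.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .stress_indices import NEGATIVE_INDICES, POSITIVE_INDICES

logger = logging.getLogger(__name__)

NORMALIZED_COLUMNS = ["DCn", "GMPn", "MPn", "STIn", "SSIn", "TOLn"]


def minmax_scale(
    values: np.ndarray | pd.Series,
    direction: str = "positive",
    on_degenerate: str = "abort",
) -> np.ndarray:
    """Scale a vector to [0, 1], optionally reversing orientation.

    ``direction="positive"`` maps the minimum to 0 and the maximum to 1;
    ``"negative"`` reverses the ends.  A constant column is degenerate: by
    default it aborts, with ``on_degenerate="zeros"`` it yields all zeros
    with a warning.
    """
    if direction not in {"positive", "negative"}:
        raise ValueError("direction must be 'positive' or 'negative'")
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateDataError("min-max scaling needs at least 2 values")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        if on_degenerate == "zeros":
            logger.warning("degenerate column (max == min); emitting zeros")
            return np.zeros_like(v)
        raise DegenerateDataError("degenerate column: max == min")
    if direction == "positive":
        return (v - vmin) / (vmax - vmin)
    return (vmax - v) / (vmax - vmin)


def normalize_indices(
    sit: pd.DataFrame, on_degenerate: str = "abort"
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Feature-scale all six index columns of a StressIndexTable.

    Returns the normalised table (columns genotype, DCn, GMPn, MPn, STIn,
    SSIn, TOLn) and the per-index (min, max) bounds used, so runs on
    different populations remain comparable.
    """
    out = {"genotype": sit["genotype"].to_numpy()}
    bounds: dict[str, tuple[float, float]] = {}
    for name in POSITIVE_INDICES:
        col = sit[name].to_numpy(float)
        bounds[name] = (float(col.min()), float(col.max()))
        out[name + "n"] = minmax_scale(col, "positive", on_degenerate)
    for name in NEGATIVE_INDICES:
        col = sit[name].to_numpy(float)
        bounds[name] = (float(col.min()), float(col.max()))
        out[name + "n"] = minmax_scale(col, "negative", on_degenerate)
    return pd.DataFrame(out), bounds


def compute_composites(nt: pd.DataFrame) -> pd.DataFrame:
    """Build PI and EI as unweighted means of their constituent scaled columns."""
    pos = nt[["DCn", "GMPn", "MPn", "STIn"]].to_numpy(float)
    neg = nt[["SSIn", "TOLn"]].to_numpy(float)
    return pd.DataFrame(
        {
            "genotype": nt["genotype"].to_numpy(),
            "PI": pos.mean(axis=1),
            "EI": neg.mean(axis=1),
        }
    )


def write_normalized_composites(
    nt: pd.DataFrame,
    ci: pd.DataFrame,
    bounds: dict[str, tuple[float, float]],
    path: str | Path,
) -> None:
    path = Path(path)
    merged = nt.merge(ci, on="genotype")
    merged.to_csv(path, index=False, float_format="%.6g")
    sidecar = path.with_suffix(".bounds.json")
    sidecar.write_text(
        json.dumps({k: {"min": lo, "max": hi} for k, (lo, hi) in bounds.items()},
                   indent=2)
        + "\n"
    )
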