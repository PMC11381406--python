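"""Grading, clustering and A-D drought-adaptability typing.

Each genotype's four new indices are graded into five levels (1 = extremely
low ... 5 = extremely high):

* PI and EI already live on [0, 1] and use fixed unit-interval bins
  [0,0.2) -> 1, [0.2,0.4) -> 2, [0.4,0.6) -> 3, [0.6,0.8) -> 4, [0.8,1] -> 5;
* SI and II are unbounded component scores and use five equal-width bins
  over the observed [min, max] range (same boundary convention; the column
  minimum grades 1 and the maximum grades 5).

Genotypes are then split into two adaptability classes by agglomerative
hierarchical clustering (Ward linkage, Euclidean distance) on the 4-vector
of levels, and typed from the SI/II levels:

    A  si >= 3 and ii >= 3   good in both environments
    B  si <  3 and ii >= 3   good only without stress
    C  si >= 3 and ii <  3   good only under stress
    D  si <  3 and ii <  3   poor in both

Level 3 ("medium") is the threshold for "performing well".  Cluster class 1
is deterministically relabelled to the cluster with the higher mean SI level
(the high drought-adapted class).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

LEVEL_COLUMNS = ["si_level", "ii_level", "pi_level", "ei_level"]
_EPS = 1e-12


def grade_unit_interval(v: float | np.ndarray) -> int | np.ndarray:
    """Grade values on [0, 1] into levels 1-5 with right-open bins (last closed)."""
    arr = np.asarray(v, dtype=float)
    if np.any((arr < -_EPS) | (arr > 1 + _EPS)):
        raise ValidationError(f"value(s) outside [0, 1]: {arr[(arr < 0) | (arr > 1)]}")
    arr = np.clip(arr, 0.0, 1.0)
    levels = np.minimum(np.floor(arr * 5.0).astype(int), 4) + 1
    return int(levels) if np.isscalar(v) or np.ndim(v) == 0 else levels


def grade_by_range(values: np.ndarray | pd.Series) -> np.ndarray:
    """Grade a column into five equal-width bins over its observed range."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateDataError("range grading needs at least 2 values")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        raise DegenerateDataError("range grading undefined: max == min")
    return grade_unit_interval((v - vmin) / (vmax - vmin))


def grade_profiles(pci_scores: pd.DataFrame, ci: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype 5-level grades for SI, II (range bins) and PI, EI (unit bins)."""
    merged = pci_scores.merge(ci, on="genotype", validate="one_to_one")
    return pd.DataFrame(
        {
            "genotype": merged["genotype"].to_numpy(),
            "si_level": grade_by_range(merged["SI"]),
            "ii_level": grade_by_range(merged["II"]),
            "pi_level": grade_unit_interval(merged["PI"].to_numpy()),
            "ei_level": grade_unit_interval(merged["EI"].to_numpy()),
        }
    )


def cluster_genotypes(
    gp: pd.DataFrame, k: int = 2, linkage: str = "ward"
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster genotypes on their level 4-vectors; relabel by mean SI level.

    Agglomerative hierarchical clustering with Euclidean distance on
    (si, ii, pi, ei) levels; the tree is cut at ``k`` clusters and labels are
    renumbered so class 1 has the highest mean si_level (descending).

    Returns (labels in 1..k aligned with ``gp`` rows, scipy linkage matrix).
    """
    x = gp[LEVEL_COLUMNS].to_numpy(float)
    if k > len(x):
        raise ValidationError(f"cannot form {k} clusters from {len(x)} genotypes")
    z = hierarchy.linkage(x, method=linkage, metric="euclidean")
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    # deterministic relabel: class 1 = highest mean si_level
    means = {lab: x[raw == lab, 0].mean() for lab in np.unique(raw)}
    ranked = sorted(means, key=lambda lab: (-means[lab], lab))
    remap = {lab: i + 1 for i, lab in enumerate(ranked)}
    return np.array([remap[lab] for lab in raw]), z


def assign_type(si_level: int | np.ndarray, ii_level: int | np.ndarray):
    """Map SI/II levels to adaptability type A/B/C/D (threshold: level >= 3)."""
    si = np.asarray(si_level)
    ii = np.asarray(ii_level)
    if np.any((si < 1) | (si > 5) | (ii < 1) | (ii > 5)):
        raise ValidationError("levels must lie in 1..5")
    out = np.where(
        si >= 3,
        np.where(ii >= 3, "A", "C"),
        np.where(ii >= 3, "B", "D"),
    )
    return str(out) if out.ndim == 0 else out


def call_adaptability(gp: pd.DataFrame, k: int = 2, linkage: str = "ward") -> tuple[pd.DataFrame, np.ndarray]:
    """Full AdaptabilityCall table: levels + cluster class + type per genotype."""
    labels, z = cluster_genotypes(gp, k=k, linkage=linkage)
    calls = gp.copy()
    calls["cluster_class"] = labels
    calls["adapt_type"] = assign_type(gp["si_level"].to_numpy(), gp["ii_level"].to_numpy())
    return calls, z


def select_elites(calls: pd.DataFrame) -> dict[str, list[str]]:
    """Rank type-A genotypes for two breeding priorities.

    ``production_first`` sorts by (si, ii, pi) levels descending;
    ``stability_first`` by (pi, ei, si) descending.  Ties break on genotype
    id so the lists are deterministic.  Empty type A yields empty lists with
    a warning.
    """
    a = calls[calls["adapt_type"] == "A"]
    if a.empty:
        logger.warning("no type-A genotypes; elite lists are empty")
        return {"production_first": [], "stability_first": []}
    prod = a.sort_values(
        ["si_level", "ii_level", "pi_level", "genotype"],
        ascending=[False, False, False, True],
    )["genotype"].tolist()
    stab = a.sort_values(
        ["pi_level", "ei_level", "si_level", "genotype"],
        ascending=[False, False, False, True],
    )["genotype"].tolist()
    return {"production_first": prod, "stability_first": stab}


def dendrogram_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{node.dist:.6g}"
        left, right = walk(node.get_left()), walk(node.get_right())
        return f"({left},{right}):{node.dist:.6g}"

    return f"({walk(tree.get_left())},{walk(tree.get_right())});"


def write_adaptability(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, index=False)


def write_elites(elites: dict[str, list[str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(elites, indent=2) + "\n")
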