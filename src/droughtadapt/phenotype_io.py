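"""Read, validate and summarise replicated control/stress phenotype tables.

The pipeline's sole external input is a long-format table with one row per
(genotype, condition, replicate) measurement of a single trait (e.g. seedling
dry weight in mg).  This module canonicalises that table, reduces it to
per-genotype condition means (C = control mean, T = stress mean), and computes
the population-level trait summary: condition means, between-genotype
coefficients of variation, the percent reduction under stress, and a paired
two-sided t-test of control vs stress genotype means.

CVs are computed over genotype means (between-genotype variation, sample SD
with n-1 denominator), not over raw replicates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

CONTROL = "control"
STRESS = "stress"


@dataclass(frozen=True)
class TraitColumns:
    """Column-name and condition-label configuration for input tables."""

    genotype: str = "genotype"
    condition: str = "condition"
    replicate: str = "replicate"
    value: str = "value"
    control_label: str = "control"
    stress_label: str = "stress"


@dataclass(frozen=True)
class PopulationMeans:
    """Unweighted population means of the per-genotype condition means."""

    c_bar: float
    t_bar: float
    n_genotypes: int

    @property
    def stress_ratio(self) -> float:
        """T_bar / C_bar, the population-level relative performance under stress."""
        return self.t_bar / self.c_bar


@dataclass(frozen=True)
class TraitSummary:
    """Population-level trait summary (condition means, CVs, reduction, paired t)."""

    control_mean: float
    stress_mean: float
    control_cv_pct: float
    stress_cv_pct: float
    percent_reduction: float
    t_statistic: float
    p_value: float
    n_genotypes: int
    degenerate: bool = False


def read_trait_table(
    path: str | Path,
    columns: TraitColumns | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a CSV/TSV phenotype table and return a validated canonical TraitMatrix.

    The returned frame has columns ``genotype`` (str), ``condition``
    (``"control"``/``"stress"``), ``replicate`` (int) and ``value`` (float).
    Rows with missing trait values are dropped with a logged count.

    Raises
    ------
    ConfigurationError
        if a configured column is absent.
    ValidationError
        for negative/non-finite values, duplicate (genotype, condition,
        replicate) triples, unknown condition labels, or a genotype observed
        under only one condition.
    """
    columns = columns or TraitColumns()
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep)

    needed = [columns.genotype, columns.condition, columns.replicate, columns.value]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"input table {path} lacks configured column(s): {missing}; "
            f"found {list(raw.columns)}"
        )

    tm = raw[needed].rename(
        columns={
            columns.genotype: "genotype",
            columns.condition: "condition",
            columns.replicate: "replicate",
            columns.value: "value",
        }
    )

    n_missing = int(tm["value"].isna().sum())
    if n_missing:
        logger.warning("dropping %d row(s) with missing trait values", n_missing)
        tm = tm.dropna(subset=["value"])

    label_map = {columns.control_label: CONTROL, columns.stress_label: STRESS}
    unknown = set(tm["condition"].unique()) - set(label_map)
    if unknown:
        raise ValidationError(
            f"unknown condition label(s) {sorted(map(str, unknown))}; expected "
            f"{columns.control_label!r} or {columns.stress_label!r}"
        )
    tm = tm.assign(
        genotype=tm["genotype"].astype(str),
        condition=tm["condition"].map(label_map),
        replicate=tm["replicate"].astype(int),
        value=tm["value"].astype(float),
    )
    return validate_trait_matrix(tm)


def validate_trait_matrix(tm: pd.DataFrame) -> pd.DataFrame:
    """Enforce TraitMatrix invariants; return the frame unchanged on success."""
    if not np.isfinite(tm["value"]).all():
        raise ValidationError("trait values must be finite")
    if (tm["value"] < 0).any():
        bad = tm.loc[tm["value"] < 0, "genotype"].unique()
        raise ValidationError(f"negative trait value(s) for genotype(s) {list(bad)}")
    if (tm["replicate"] < 1).any():
        raise ValidationError("replicate numbers must be positive integers")
    dup = tm.duplicated(subset=["genotype", "condition", "replicate"])
    if dup.any():
        raise ValidationError(
            f"duplicate (genotype, condition, replicate) triples: "
            f"{tm.loc[dup, ['genotype', 'condition', 'replicate']].values.tolist()[:5]}"
        )
    seen = tm.groupby("genotype", sort=False)["condition"].agg(lambda s: set(s))
    incomplete = seen[seen.map(lambda s: s != {CONTROL, STRESS})]
    if len(incomplete):
        raise ValidationError(
            "genotype(s) observed under only one condition: "
            f"{list(incomplete.index)}"
        )
    return tm.reset_index(drop=True)


def summarize_means(tm: pd.DataFrame) -> tuple[pd.DataFrame, PopulationMeans]:
    """Reduce a TraitMatrix to per-genotype condition means and population means.

    Returns a GenotypeMeans frame with columns ``genotype``, ``C`` (control
    mean) and ``T`` (stress mean), one row per genotype in first-appearance
    order, plus the unweighted PopulationMeans across genotypes.
    """
    wide = (
        tm.groupby(["genotype", "condition"], sort=False)["value"]
        .mean()
        .unstack("condition")
    )
    # preserve input genotype order
    order = tm["genotype"].drop_duplicates().tolist()
    gm = (
        wide.loc[order]
        .rename(columns={CONTROL: "C", STRESS: "T"})[["C", "T"]]
        .rename_axis(columns=None)
        .reset_index()
    )
    pm = PopulationMeans(
        c_bar=float(gm["C"].mean()),
        t_bar=float(gm["T"].mean()),
        n_genotypes=len(gm),
    )
    return gm, pm


def summarize_trait(gm: pd.DataFrame, pm: PopulationMeans) -> TraitSummary:
    """Compute the population trait summary from genotype means.

    CV is the sample SD (ddof=1) of the genotype means divided by their mean,
    in percent.  The paired two-sided t-test compares (C_g, T_g) pairs; if the
    per-genotype differences have zero variance the test is degenerate and p
    is reported as 1 by convention.
    """
    if pm.n_genotypes < 2:
        raise ValidationError("trait summary requires at least 2 genotypes")
    if pm.c_bar == 0 or pm.t_bar == 0:
        raise DegenerateDataError("CV undefined: a population mean is zero")

    c = gm["C"].to_numpy(float)
    t = gm["T"].to_numpy(float)
    control_cv = float(np.std(c, ddof=1) / pm.c_bar * 100.0)
    stress_cv = float(np.std(t, ddof=1) / pm.t_bar * 100.0)
    reduction = float(100.0 * (pm.c_bar - pm.t_bar) / pm.c_bar)

    diff = c - t
    degenerate = bool(np.std(diff, ddof=1) == 0.0)
    if degenerate:
        t_stat, p = float("nan"), 1.0
    else:
        res = stats.ttest_rel(c, t)
        t_stat, p = float(res.statistic), float(res.pvalue)

    return TraitSummary(
        control_mean=pm.c_bar,
        stress_mean=pm.t_bar,
        control_cv_pct=control_cv,
        stress_cv_pct=stress_cv,
        percent_reduction=reduction,
        t_statistic=t_stat,
        p_value=p,
        n_genotypes=pm.n_genotypes,
        degenerate=degenerate,
    )


def write_trait_matrix(tm: pd.DataFrame, path: str | Path) -> None:
    tm.to_csv(path, index=False)


def write_genotype_means(gm: pd.DataFrame, path: str | Path) -> None:
    gm.to_csv(path, index=False, float_format="%.6g")


def write_trait_summary(summary: TraitSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(summary), indent=2) + "\n")
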