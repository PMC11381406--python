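"""PCA of the six stress indices: the SI and II production indices.

The six classical indices are strongly inter-correlated, and their first two
principal components separate two interpretable axes of germplasm behaviour:
performance under stress and performance under non-stress conditions.  The
decomposition here is of the 6x6 *correlation* matrix (each index column is
z-scored first): the indices mix unitless ratios with trait-unit quantities,
so a covariance PCA would be dominated by the large-magnitude columns
(TOL, MP, GMP).

Scores are projections of the standardised data onto unit-norm eigenvectors.
Eigenvector sign is intrinsically arbitrary; it is fixed semantically:

* PC1 is flipped so its correlation with the stress means T is >= 0 and
  defines SI, the stress production index;
* PC2 is flipped so its correlation with the control means C is >= 0 and
  defines II, the ideal production index.

A tie (exactly zero correlation) is resolved by forcing the
largest-magnitude loading positive.  Exactly two components become indices;
all six eigenvalues are reported as explained-variance percentages
(eigenvalue / 6 * 100).

The module also provides the OLS diagnostics regressing each index (and
SI/II) on the per-genotype trait means, whose R² values quantify how well
each index explains trait performance per condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .stress_indices import INDEX_NAMES

__all__ = ["PCIndices", "RegressionFit", "fit_pc_indices", "regress_r2",
           "regression_grid"]


@dataclass
class PCIndices:
    """Result of the two-component index construction.

    Attributes
    ----------
    scores : frame with columns genotype, SI, II (zero-mean, mutually
        orthogonal component scores).
    loadings : 6x6 frame, rows = index names, columns PC1..PC6, each column a
        unit-norm eigenvector of the correlation matrix.
    explained_variance_pct : length-6 array, eigenvalue/6*100 per component,
        descending.
    sign_flips : which of PC1/PC2 were negated to satisfy the orientation
        convention.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_pct: np.ndarray
    sign_flips: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of trait means on one index."""

    index_name: str
    condition: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    degenerate: bool = False


def _correlation_pca(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decompose the correlation matrix of columns of x.

    Returns (eigenvalues descending, eigenvectors as columns, z-scored data).
    Deterministic: no randomised solver paths; eigh on a symmetric matrix.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n < 3:
        raise DegenerateDataError("PCA needs at least 3 observations")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dead = list(np.nonzero(sd == 0)[0])
        raise DegenerateDataError(f"zero-variance column(s) at position(s) {dead}")
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.any(evals < -1e-8):
        raise DegenerateDataError(f"negative eigenvalue beyond tolerance: {evals.min()}")
    evals = np.clip(evals, 0.0, None)
    return evals, evecs, z


def _orient(vec: np.ndarray, scores: np.ndarray, anchor: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Flip (vec, scores) so that corr(scores, anchor) >= 0; tie-break on loadings."""
    a = anchor - anchor.mean()
    c = float(scores @ a)
    if c == 0.0:  # zero correlation: force largest-|loading| positive
        k = int(np.argmax(np.abs(vec)))
        flip = vec[k] < 0
    else:
        flip = c < 0
    if flip:
        return -vec, -scores, True
    return vec, scores, False


def fit_pc_indices(sit: pd.DataFrame, gm: pd.DataFrame) -> PCIndices:
    """Construct SI (PC1) and II (PC2) from a StressIndexTable.

    ``sit`` and ``gm`` are aligned on genotype; ``gm`` supplies the control
    and stress means that anchor the component orientations.
    """
    merged = sit.merge(gm, on="genotype", validate="one_to_one")
    x = merged[INDEX_NAMES].to_numpy(float)
    evals, evecs, z = _correlation_pca(x)
    scores = z @ evecs

    t_anchor = merged["T"].to_numpy(float)
    c_anchor = merged["C"].to_numpy(float)
    flips: dict[str, bool] = {}
    evecs = evecs.copy()
    evecs[:, 0], scores[:, 0], flips["PC1"] = _orient(evecs[:, 0], scores[:, 0], t_anchor)
    evecs[:, 1], scores[:, 1], flips["PC2"] = _orient(evecs[:, 1], scores[:, 1], c_anchor)

    loadings = pd.DataFrame(
        evecs, index=INDEX_NAMES, columns=[f"PC{i + 1}" for i in range(len(evals))]
    )
    score_df = pd.DataFrame(
        {
            "genotype": merged["genotype"].to_numpy(),
            "SI": scores[:, 0],
            "II": scores[:, 1],
        }
    )
    return PCIndices(
        scores=score_df,
        loadings=loadings,
        explained_variance_pct=evals / len(INDEX_NAMES) * 100.0,
        sign_flips=flips,
    )


def regress_r2(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    index_name: str = "",
    condition: str = "",
) -> RegressionFit:
    """OLS of trait means y on index values x; R² is the squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise DegenerateDataError("regression needs at least 3 pairs")
    if np.var(x) == 0:
        raise DegenerateDataError("regression undefined: predictor has zero variance")
    if np.var(y) == 0:
        return RegressionFit(index_name, condition, 0.0, float(y.mean()), 0.0, 1.0,
                             degenerate=True)
    res = stats.linregress(x, y)
    return RegressionFit(
        index_name=index_name,
        condition=condition,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


def regression_grid(sit: pd.DataFrame, pci: PCIndices, gm: pd.DataFrame) -> pd.DataFrame:
    """R² diagnostics: each of the 8 indices vs trait means per condition."""
    merged = sit.merge(pci.scores, on="genotype").merge(gm, on="genotype")
    rows = []
    for name in INDEX_NAMES + ["SI", "II"]:
        for condition, trait_col in [("control", "C"), ("stress", "T")]:
            fit = regress_r2(merged[name], merged[trait_col], name, condition)
            rows.append(fit.__dict__)
    return pd.DataFrame(rows)


def write_pc_indices(pci: PCIndices, scores_path: str | Path,
                     model_path: str | Path) -> None:
    pci.scores.to_csv(scores_path, index=False, float_format="%.6g")
    Path(model_path).write_text(
        json.dumps(
            {
                "loadings": {c: pci.loadings[c].round(9).to_dict()
                             for c in pci.loadings.columns},
                "explained_variance_pct": [round(float(v), 6)
                                           for v in pci.explained_variance_pct],
                "sign_flips": pci.sign_flips,
            },
            indent=2,
        )
        + "\n"
    )
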