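"""Synthetic phenotype populations with the structure the pipeline assumes.

No raw per-genotype trait data are distributed with typical germplasm
screens, so this module generates replicated control/stress tables whose
population statistics match the published screen the defaults are calibrated
to: 206 genotypes x 2 conditions x 3 replicates, control mean 746.90 mg with
a 31.54% between-genotype CV, per-genotype drought coefficient (DC = stress
mean / control mean) on [0.006, 0.962] with mean 0.394.

Generative model, per genotype g:

    C_g  ~ LogNormal(mean=control_mean, CV=control_cv_pct)
    DC_g ~ dc_min + (dc_max - dc_min) * Beta(a, b)
    T_g  = C_g * DC_g
    replicate values = condition mean * multiplicative log-normal noise
                       (mean 1, CV replicate_cv_pct)

DC is simulated directly rather than T independently of C: the screening
logic is built on the C -> T ratio, which makes the drought effect
interpretable and calibratable to the published DC range and mean.  The Beta
shapes are a = m*kappa, b = (1-m)*kappa with m the mean on the unit interval
and kappa the concentration; the default kappa = 4.69 is solved analytically
so that independent C and DC with the default means/CVs imply a stress-side
between-genotype CV of 61.14%, the published value.  A Gaussian copula adds
optional correlation rho between C_g and DC_g (default 0).

The log-normal trait law (not Gaussian) guarantees positivity: at a 31.5% CV
a Gaussian would produce negative dry weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .phenotype_io import CONTROL, STRESS, validate_trait_matrix


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model (trait units are mg by convention)."""

    n_genotypes: int = 206
    n_replicates: int = 3
    control_mean: float = 746.90
    control_cv_pct: float = 31.54
    dc_mean: float = 0.394
    dc_min: float = 0.006
    dc_max: float = 0.962
    dc_concentration: float = 4.69
    replicate_cv_pct: float = 5.0
    c_dc_correlation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genotypes < 2:
            raise ConfigurationError("need at least 2 genotypes")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least 1 replicate")
        if not (0 <= self.dc_min < self.dc_max):
            raise ConfigurationError("require 0 <= dc_min < dc_max")
        if not (self.dc_min < self.dc_mean < self.dc_max):
            raise ConfigurationError(
                f"dc_mean {self.dc_mean} outside open interval "
                f"({self.dc_min}, {self.dc_max}); Beta parameterization infeasible"
            )
        if min(self.control_cv_pct, self.replicate_cv_pct) < 0:
            raise ConfigurationError("CVs must be non-negative")
        if not (-1.0 <= self.c_dc_correlation <= 1.0):
            raise ConfigurationError("c_dc_correlation must lie in [-1, 1]")
        if self.control_mean <= 0:
            raise ConfigurationError("control_mean must be positive")
        if self.dc_concentration <= 0:
            raise ConfigurationError("dc_concentration must be positive")


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv**2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_population(cfg: SyntheticConfig) -> pd.DataFrame:
    """Draw a replicated TraitMatrix from the generative model, seeded."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genotypes

    mu, sigma = _lognormal_params(cfg.control_mean, cfg.control_cv_pct / 100.0)
    m_unit = (cfg.dc_mean - cfg.dc_min) / (cfg.dc_max - cfg.dc_min)
    a = m_unit * cfg.dc_concentration
    b = (1.0 - m_unit) * cfg.dc_concentration

    # Gaussian copula: correlated standard normals -> marginal quantiles
    rho = cfg.c_dc_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    zz = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    c_means = np.exp(mu + sigma * zz[:, 0])
    dc = cfg.dc_min + (cfg.dc_max - cfg.dc_min) * stats.beta.ppf(
        stats.norm.cdf(zz[:, 1]), a, b
    )
    t_means = c_means * dc

    rep_cv = cfg.replicate_cv_pct / 100.0
    if rep_cv > 0:
        s2 = np.log1p(rep_cv**2)
        noise = np.exp(-s2 / 2.0 + np.sqrt(s2)
                       * rng.standard_normal((n, 2, cfg.n_replicates)))
    else:
        noise = np.ones((n, 2, cfg.n_replicates))

    width = len(str(n))
    rows = []
    for i in range(n):
        gid = f"g{i + 1:0{width}d}"
        for j, (cond, mean) in enumerate([(CONTROL, c_means[i]), (STRESS, t_means[i])]):
            for r in range(cfg.n_replicates):
                rows.append((gid, cond, r + 1, mean * noise[i, j, r]))
    tm = pd.DataFrame(rows, columns=["genotype", "condition", "replicate", "value"])
    return validate_trait_matrix(tm)


# Hand-chosen 8-genotype fixture: round-number condition means so every
# downstream index is exactly hand-computable.  Exercises a DC=1 genotype
# (w2), a near-zero stress survivor (w3, DC=0.01), and grading-boundary ties.
_FIXTURE_MEANS = {
    # genotype: (C, T)
    "w1": (400.0, 100.0),
    "w2": (300.0, 300.0),
    "w3": (500.0, 5.0),
    "w4": (800.0, 400.0),
    "w5": (200.0, 150.0),
    "w6": (600.0, 240.0),
    "w7": (1000.0, 200.0),
    "w8": (300.0, 120.0),
}
# symmetric replicate offsets keep every mean exact
_REP_OFFSETS = (-10.0, 0.0, 10.0)


def make_worked_fixture() -> pd.DataFrame:
    """Fixed 8-genotype, 3-replicate TraitMatrix with exactly known means."""
    rows = []
    for gid, (c, t) in _FIXTURE_MEANS.items():
        for cond, mean in [(CONTROL, c), (STRESS, t)]:
            for r, off in enumerate(_REP_OFFSETS, start=1):
                # keep the near-zero stress genotype non-negative
                scale = 1.0 if mean >= 100 else mean / 100.0
                rows.append((gid, cond, r, mean + off * scale))
    tm = pd.DataFrame(rows, columns=["genotype", "condition", "replicate", "value"])
    return validate_trait_matrix(tm)


def write_population(tm: pd.DataFrame, cfg: SyntheticConfig,
                     csv_path: str | Path) -> None:
    """Write the generated table with its config as a JSON sidecar."""
    csv_path = Path(csv_path)
    tm.to_csv(csv_path, index=False)
    csv_path.with_suffix(".config.json").write_text(
        json.dumps(asdict(cfg), indent=2) + "\n"
    )
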