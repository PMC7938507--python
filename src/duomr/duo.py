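"""Mother-child duo regression and instrument-validation statistics.

Offspring birthweight responds both to the fetus's own genotype and to the
mother's genotype acting through the intrauterine environment; the two are
correlated (r ~ 0.5) by transmission. Regressing the outcome jointly on
maternal and fetal genotype at a SNP partitions its effect into a
maternal-specific and a fetal-specific component — the duo analogue of the
structural-equation partition used by large birthweight GWAS.

The module also carries the statistics used to check instruments in an
independent validation cohort: a rank-based inverse-normal transform of the
outcome, covariate-adjusted linear association, and a two-sample effect
heterogeneity z-test between studies.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PartitionedEffect",
    "duo_conditional_regression",
    "inverse_normal_transform",
    "adjusted_association",
    "effect_heterogeneity_test",
]


@dataclass(frozen=True)
class PartitionedEffect:
    """Maternal- and fetal-specific per-allele effects at one SNP.

    ``beta_maternal`` is conditional on fetal genotype and vice versa; both
    in outcome-SD units per effect allele.
    """

    rsid: str
    beta_maternal: float
    se_maternal: float
    beta_fetal: float
    se_fetal: float

    def __post_init__(self) -> None:
        if self.se_maternal <= 0 or self.se_fetal <= 0:
            raise ValueError(f"{self.rsid}: standard errors must be > 0")


def duo_conditional_regression(duo, rsid: str) -> PartitionedEffect:
    """OLS of outcome on maternal and fetal genotype jointly at one SNP.

    ``duo`` is a DuoCohort (see :mod:`duomr.simulate`) or any object with
    ``maternal_genotypes``, ``fetal_genotypes``, ``outcome`` and ``snp_ids``.
    """
    j = list(duo.snp_ids).index(rsid)
    gm = np.asarray(duo.maternal_genotypes[:, j], dtype=float)
    gf = np.asarray(duo.fetal_genotypes[:, j], dtype=float)
    y = np.asarray(duo.outcome, dtype=float)
    if len(gm) != len(y) or len(gf) != len(y):
        raise ValueError("genotype and outcome lengths differ")
    if np.var(gm) == 0 or np.var(gf) == 0:
        raise ValueError(f"{rsid}: constant genotype column")
    X = sm.add_constant(np.column_stack([gm, gf]))
    fit = sm.OLS(y, X).fit()
    return PartitionedEffect(
        rsid=rsid,
        beta_maternal=float(fit.params[1]),
        se_maternal=float(fit.bse[1]),
        beta_fetal=float(fit.params[2]),
        se_fetal=float(fit.bse[2]),
    )


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps (rank - 3/8)/(n + 1/4) through the standard normal quantile; ties
    share their average rank. The result has mean ~0 and variance ~1 and is
    invariant to any monotone rescaling of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D array of measurements")
    if np.unique(x).size < 2:
        raise ValueError("inverse-normal transform undefined for constant input")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def adjusted_association(y, g, covariates=None) -> tuple[float, float, float]:
    """Genotype coefficient from OLS of y on g plus covariates.

    Returns (beta, se, p) for the genotype term, with a t-based two-sided p.
    The design includes an intercept; rank deficiency raises.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    cols = [g]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def effect_heterogeneity_test(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Two-sample z-test for a difference between two independent effects.

    z = (b1 - b2)/sqrt(se1^2 + se2^2), two-sided normal p. Used to compare a
    SNP's exposure effect between the discovery GWAS and a validation
    cohort.
    """
    for v in (b1, se1, b2, se2):
        if not math.isfinite(v):
            raise ValueError("non-finite input")
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be > 0")
    z = (b1 - b2) / math.sqrt(se1**2 + se2**2)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return z, p
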