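"""Approximate conditional estimation from marginal GWAS summary statistics.

When two instruments sit in the same gene region (here the two MTHFR folate
SNPs), the marginal outcome effect of one is contaminated by the other
through linkage disequilibrium. Given marginal per-SNP effects, an external
LD correlation matrix, allele frequencies and the GWAS sample size, the
joint least-squares system can be reconstructed without individual-level
data: with genotype variance v_j = 2 p_j (1 - p_j),

    (X'X)_jk ~= n r_jk sqrt(v_j v_k),     (X'y)_j ~= n v_j beta_j^marginal,

and the conditional effect of a target SNP given a conditioning set C is
its coefficient in the joint regression on {target} + C. The phenotype is
assumed variance-standardized (y'y = n). This is the conditional part of
the GCTA-COJO procedure; stepwise model selection is out of scope.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SnpAssociation

__all__ = ["LdReference", "CollinearityError", "conditional_estimates", "read_ld_reference"]

#: Targets with r^2 above this against any conditioning SNP are rejected.
COLLINEARITY_R2 = 0.9


class CollinearityError(ValueError):
    """Target and conditioning SNP too correlated for identifiable conditioning."""


@dataclass(frozen=True)
class LdReference:
    """LD correlation matrix with allele frequencies from a reference panel."""

    rsids: tuple[str, ...]
    r: np.ndarray
    freqs: np.ndarray
    n_ref: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (len(self.rsids), len(self.rsids)):
            raise ValueError("LD matrix shape does not match rsid list")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(r) > 1 + 1e-10):
            raise ValueError("LD correlations must lie in [-1, 1]")
        eigmin = float(np.linalg.eigvalsh(r).min())
        if eigmin < -1e-8:
            raise ValueError(f"LD matrix not positive semi-definite (min eig {eigmin:.3g})")
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.shape != (len(self.rsids),) or np.any((freqs <= 0) | (freqs >= 1)):
            raise ValueError("frequencies must be in (0, 1), one per rsid")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "freqs", freqs)

    def index(self, rsid: str) -> int:
        try:
            return self.rsids.index(rsid)
        except ValueError:
            raise KeyError(f"{rsid} not in LD reference") from None

    def corr(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)])


def read_ld_reference(matrix_path: str | Path, sidecar_path: str | Path, n_ref: int) -> LdReference:
    """Load an LD reference from a square correlation TSV plus an rsid/freq sidecar.

    The matrix file is tab-delimited with rsids as both header and index;
    the sidecar has columns ``rsid`` and ``freq``.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    side = pd.read_csv(sidecar_path, sep="\t")
    rsids = tuple(mat.columns)
    if tuple(mat.index) != rsids:
        raise ValueError("LD matrix rows and columns must carry identical rsid order")
    freqs = side.set_index("rsid").loc[list(rsids), "freq"].to_numpy(dtype=float)
    return LdReference(rsids=rsids, r=mat.to_numpy(dtype=float), freqs=freqs, n_ref=n_ref)


def conditional_estimates(
    marginal: Sequence[SnpAssociation],
    condition_on: Iterable[str],
    ld: LdReference,
    n_gwas: float,
) -> list[SnpAssociation]:
    """Re-estimate each non-conditioning SNP's effect given the conditioning set.

    For every SNP in ``marginal`` that is not itself in ``condition_on``,
    solves the joint regression of the outcome on {target} + conditioning
    SNPs reconstructed from the marginal betas, the LD correlations and
    2p(1-p) genotype variances, and returns the target's joint coefficient,
    its rescaled SE and a normal two-sided p, as a new SnpAssociation on the
    original alleles. Allele frequencies come from the GWAS row when
    present, else from the LD reference. Output is invariant to the order
    of ``condition_on``.
    """
    cond = sorted(set(condition_on))
    if not cond:
        raise ValueError("conditioning set is empty")
    if n_gwas <= 2:
        raise ValueError("n_gwas must exceed the number of fitted coefficients")
    by_id = {m.rsid: m for m in marginal}
    for rsid in cond:
        if rsid not in by_id:
            raise KeyError(f"conditioning SNP {rsid} not in marginal statistics")
        ld.index(rsid)  # raises if absent from the reference

    def freq(m: SnpAssociation) -> float:
        return m.eaf if m.eaf is not None else float(ld.freqs[ld.index(m.rsid)])

    out: list[SnpAssociation] = []
    for m in marginal:
        if m.rsid in cond:
            continue
        ld.index(m.rsid)
        for c in cond:
            if ld.corr(m.rsid, c) ** 2 > COLLINEARITY_R2:
                raise CollinearityError(
                    f"{m.rsid}: r^2 with conditioning SNP {c} exceeds {COLLINEARITY_R2}"
                )
        snps = [m] + [by_id[c] for c in cond]
        k = len(snps)
        v = np.array([2.0 * freq(s) * (1.0 - freq(s)) for s in snps])
        R = np.array([[ld.corr(a.rsid, b.rsid) for b in snps] for a in snps])
        xtx = n_gwas * R * np.sqrt(np.outer(v, v))
        xty = n_gwas * v * np.array([s.beta for s in snps])
        try:
            beta_joint = np.linalg.solve(xtx, xty)
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(f"{m.rsid}: singular joint system ({exc})") from exc
        # y'y = n under unit phenotypic variance (SD-standardized traits).
        rss = n_gwas - float(beta_joint @ xty)
        sigma2 = max(rss, 0.0) / (n_gwas - k - 1)
        se = max(math.sqrt(sigma2 * xtx_inv[0, 0]), 1e-12)
        b = float(beta_joint[0])
        p = float(min(1.0, max(np.nextafter(0, 1), 2.0 * stats.norm.sf(abs(b / se)))))
        out.append(
            SnpAssociation(
                rsid=m.rsid,
                effect_allele=m.effect_allele,
                other_allele=m.other_allele,
                beta=b,
                se=se,
                eaf=m.eaf,
                pvalue=p,
                n=m.n,
            )
        )
    return out
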