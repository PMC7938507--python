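"""Synthetic mother-child duo cohorts and two-sample GWAS with known truth.

The generator emulates the study design of a maternal two-sample MR of a
micronutrient exposure on offspring birthweight: a handful of independent
biallelic instruments explaining a few percent of exposure variance
(defaults: 10 SNPs, h2 = 5.24%, the serum-B12 figure; folate-like runs use
h2 = 1.3% and 4 SNPs), mothers in Hardy-Weinberg equilibrium transmitting
one allele Mendelianly to each child (maternal-fetal genotype correlation
0.5), a maternal causal effect of the exposure on birthweight (default
0.146 SD/SD), a smaller opposite-sign fetal genetic effect (default
-0.051 SD/SD), optional balanced or directional pleiotropy, and disjoint
exposure and outcome GWAS samples.

Traits are in SD units: the exposure has unit variance by construction and
the outcome's noise variance is chosen analytically so its total variance
is 1, which keeps the configured causal effects on the SD/SD scale without
an empirical rescaling step. All draws are reproducible from the seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .sumstats import SnpAssociation, write_summary_stats

__all__ = [
    "SimulationConfig",
    "DuoCohort",
    "simulate_duos",
    "run_gwas",
    "simulate_study",
    "write_study",
    "simulate_summary_instruments",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for a two-sample mother-child MR study."""

    seed: int
    n_exposure_gwas: int = 45576
    n_outcome_duos: int = 50000
    n_snps: int = 10
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    exposure_h2: float = 0.0524
    beta_maternal_causal: float = 0.146
    beta_fetal_causal: float = -0.051
    pleiotropy_mode: str = "none"
    pleiotropy_scale: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must lie inside (0, 1)")
        if not (0.0 <= self.exposure_h2 < 1.0):
            raise ValueError("exposure_h2 must be in [0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_snps < 1 or self.n_exposure_gwas < 10 or self.n_outcome_duos < 10:
            raise ValueError("sample/instrument counts too small")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class _Architecture:
    """Per-SNP generating constants shared across the disjoint cohorts."""

    snp_ids: tuple[str, ...]
    freqs: np.ndarray           # effect-allele frequencies
    effects: np.ndarray         # per-allele exposure effects (exposure-SD units)
    pleiotropy: np.ndarray      # per-allele direct maternal-path outcome effects


@dataclass
class DuoCohort:
    """Simulated mother-child cohort with phenotypes and a truth manifest."""

    snp_ids: tuple[str, ...]
    maternal_genotypes: np.ndarray  # n x m dosages in {0,1,2}
    fetal_genotypes: np.ndarray
    exposure: np.ndarray            # maternal exposure phenotype, ~N(0,1)
    outcome: np.ndarray             # offspring outcome, ~N(0,1)
    truth: dict

    @property
    def n(self) -> int:
        return self.maternal_genotypes.shape[0]


def _draw_architecture(config: SimulationConfig) -> _Architecture:
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    m = config.n_snps
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=m)
    v = 2.0 * freqs * (1.0 - freqs)
    # Equal variance share per SNP, random sign: a_j = +/- sqrt((h2/m)/v_j).
    signs = rng.choice([-1.0, 1.0], size=m)
    effects = signs * np.sqrt((config.exposure_h2 / m) / v)
    if config.pleiotropy_mode == "balanced":
        pleio = rng.normal(0.0, config.pleiotropy_scale, size=m)
    elif config.pleiotropy_mode == "directional":
        # Directional relative to the exposure-raising allele: after the
        # usual orientation step every instrument pushes the outcome the
        # same way, which is what the Egger intercept detects.
        pleio = np.abs(rng.normal(0.0, config.pleiotropy_scale, size=m)) * signs
    else:
        pleio = np.zeros(m)
    ids = tuple(f"rs{1000 + j}" for j in range(m))
    return _Architecture(ids, freqs, effects, pleio)


def _simulate_cohort(
    config: SimulationConfig, arch: _Architecture, n: int, role: str
) -> DuoCohort:
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1, {"exposure": 0, "outcome": 1}[role]])
    )
    m = config.n_snps
    p, a, alpha = arch.freqs, arch.effects, arch.pleiotropy
    v = 2.0 * p * (1.0 - p)

    gm = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    transmitted = np.where(gm == 2, 1, 0) + (gm == 1) * rng.integers(0, 2, size=(n, m))
    gf = (transmitted + rng.binomial(1, p, size=(n, m))).astype(np.int8)

    exposure_noise_var = 1.0 - config.exposure_h2
    exposure = (gm - 2.0 * p) @ a + rng.normal(0.0, np.sqrt(exposure_noise_var), size=n)

    bm, bf = config.beta_maternal_causal, config.beta_fetal_causal
    h2 = config.exposure_h2
    fetal_score = (gf - 2.0 * p) @ a
    pleio_term = (gm - 2.0 * p) @ alpha
    structural = bm * exposure + bf * fetal_score + pleio_term
    # Analytic variance of the structural part under HWE:
    #   var(E)=1, var(fetal score)=h2, cov(E, fetal score)=h2/2 (transmission),
    #   plus the pleiotropy terms with their covariances through g_m.
    var_struct = (
        bm**2
        + bf**2 * h2
        + bm * bf * h2
        + float(np.sum(alpha**2 * v))
        + 2.0 * bm * float(np.sum(a * alpha * v))
        + bf * float(np.sum(a * alpha * v))
    )
    outcome_noise_var = 1.0 - var_struct
    if outcome_noise_var <= 0:
        raise ValueError(
            "infeasible configuration: structural variance of the outcome is "
            f"{var_struct:.3f} >= 1; reduce effects, h2 or pleiotropy_scale"
        )
    outcome = structural + rng.normal(0.0, np.sqrt(outcome_noise_var), size=n)

    truth = {
        "config": dataclasses.asdict(config),
        "role": role,
        "cohort_key": f"{config.seed}:{role}",
        "n": int(n),
        "snp_ids": list(arch.snp_ids),
        "freqs": arch.freqs.tolist(),
        "exposure_effects": arch.effects.tolist(),
        "pleiotropy_effects": arch.pleiotropy.tolist(),
        "exposure_noise_var": float(exposure_noise_var),
        "outcome_noise_var": float(outcome_noise_var),
    }
    return DuoCohort(arch.snp_ids, gm, gf, exposure, outcome, truth)


def simulate_duos(config: SimulationConfig, role: str = "outcome") -> DuoCohort:
    """Simulate a mother-child duo cohort under the configured model.

    ``role`` selects the sample size (``"outcome"`` -> n_outcome_duos,
    ``"exposure"`` -> n_exposure_gwas) and a disjoint random stream, so the
    two cohorts of a study share the genetic architecture but no samples.
    """
    if role not in ("exposure", "outcome"):
        raise ValueError("role must be 'exposure' or 'outcome'")
    arch = _draw_architecture(config)
    n = config.n_exposure_gwas if role == "exposure" else config.n_outcome_duos
    return _simulate_cohort(config, arch, n, role)


def _marginal_gwas(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP simple linear regression (with intercept)."""
    n, m = G.shape
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(gc**2, axis=0)
    if np.any(sxx == 0):
        raise ValueError("constant genotype column in GWAS")
    beta = gc.T @ yc / sxx
    rss = np.sum(yc**2) - beta**2 * sxx
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    pval = 2.0 * stats.t.sf(np.abs(beta / se), n - 2)
    return beta, se, np.clip(pval, np.nextafter(0, 1), 1.0)


def _duo_gwas(y: np.ndarray, Gm: np.ndarray, Gf: np.ndarray):
    """Vectorized per-SNP joint regression of y on (1, g_m, g_f).

    Closed-form normal-equations solve per SNP; returns
    (beta_m, se_m, p_m, beta_f, se_f, p_f).
    """
    n, m = Gm.shape
    yc = y - y.mean()
    out = np.empty((m, 6))
    for j in range(m):
        x1 = Gm[:, j] - Gm[:, j].mean()
        x2 = Gf[:, j] - Gf[:, j].mean()
        if np.all(x1 == x1[0]) or np.all(x2 == x2[0]):
            raise ValueError(f"constant genotype column at index {j}")
        xtx = np.array(
            [[x1 @ x1, x1 @ x2], [x1 @ x2, x2 @ x2]], dtype=float
        )
        xty = np.array([x1 @ yc, x2 @ yc], dtype=float)
        beta = np.linalg.solve(xtx, xty)
        rss = yc @ yc - beta @ xty
        sigma2 = rss / (n - 3)
        cov = sigma2 * np.linalg.inv(xtx)
        se = np.sqrt(np.diag(cov))
        pv = np.clip(2.0 * stats.t.sf(np.abs(beta / se), n - 3), np.nextafter(0, 1), 1.0)
        out[j] = [beta[0], se[0], pv[0], beta[1], se[1], pv[1]]
    return tuple(out.T)


def run_gwas(cohort: DuoCohort, mode: str) -> dict[str, list[SnpAssociation]]:
    """Emit summary-statistic tables from a simulated cohort.

    ``mode="exposure"`` runs the marginal per-SNP GWAS of the maternal
    exposure (mothers only); ``mode="outcome_maternal_fetal"`` runs the duo
    conditional regression per SNP and returns maternal- and fetal-specific
    tables. Simulated SNPs are reported on fixed A/G alleles with the
    effect allele being the simulated frequency allele.
    """
    freqs = np.asarray(cohort.truth["freqs"])
    n = cohort.n

    def table(beta, se, pval) -> list[SnpAssociation]:
        return [
            SnpAssociation(
                rsid=cohort.snp_ids[j],
                effect_allele="A",
                other_allele="G",
                beta=float(beta[j]),
                se=float(se[j]),
                eaf=float(freqs[j]),
                pvalue=float(pval[j]),
                n=n,
            )
            for j in range(len(cohort.snp_ids))
        ]

    if mode == "exposure":
        b, s, p = _marginal_gwas(cohort.exposure, cohort.maternal_genotypes.astype(float))
        return {"exposure": table(b, s, p)}
    if mode == "outcome_maternal_fetal":
        bm, sm, pm, bf, sf, pf = _duo_gwas(
            cohort.outcome,
            cohort.maternal_genotypes.astype(float),
            cohort.fetal_genotypes.astype(float),
        )
        return {"outcome_maternal": table(bm, sm, pm), "outcome_fetal": table(bf, sf, pf)}
    raise ValueError(f"unknown GWAS mode {mode!r}")


def simulate_study(config: SimulationConfig) -> dict:
    """Simulate the full two-sample design: disjoint exposure and outcome cohorts.

    Returns the exposure GWAS table, maternal- and fetal-specific outcome
    tables, and a truth manifest recording the generating parameters and a
    sample-overlap flag (always False here: the cohorts use disjoint random
    streams).
    """
    exposure_cohort = simulate_duos(config, role="exposure")
    outcome_cohort = simulate_duos(config, role="outcome")
    tables = run_gwas(exposure_cohort, "exposure")
    tables.update(run_gwas(outcome_cohort, "outcome_maternal_fetal"))
    truth = dict(outcome_cohort.truth)
    truth["sample_overlap"] = (
        exposure_cohort.truth["cohort_key"] == outcome_cohort.truth["cohort_key"]
    )
    truth["n_exposure_gwas"] = exposure_cohort.n
    return {"tables": tables, "truth": truth, "cohorts": {"exposure": exposure_cohort, "outcome": outcome_cohort}}


def simulate_summary_instruments(
    n_snps: int,
    theta: float,
    seed: int,
    se_exposure: float = 0.01,
    se_outcome: float = 0.02,
    beta_exposure_scale: float = 0.1,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
):
    """Draw harmonized instruments directly at the summary-statistic level.

    Fast generator for estimator calibration studies: true exposure effects
    are uniform on [0.5, 1.5] x ``beta_exposure_scale`` with random sign,
    observed effects add normal noise at the stated SEs, and the true
    outcome effect of SNP j is theta * beta_j plus a per-SNP pleiotropic
    intercept drawn N(pleiotropy_mean, pleiotropy_sd) oriented to the
    exposure-raising allele (mean 0 gives balanced pleiotropy).
    """
    from .sumstats import HarmonizedInstrument

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=n_snps)
    bx_true = signs * rng.uniform(0.5, 1.5, size=n_snps) * beta_exposure_scale
    alpha = (rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_snps) * signs
             if (pleiotropy_mean or pleiotropy_sd) else np.zeros(n_snps))
    bx = rng.normal(bx_true, se_exposure)
    by = rng.normal(theta * bx_true + alpha, se_outcome)
    return [
        HarmonizedInstrument(
            rsid=f"rs{j}",
            beta_exposure=float(bx[j]),
            se_exposure=se_exposure,
            beta_outcome=float(by[j]),
            se_outcome=se_outcome,
            status="kept",
        )
        for j in range(n_snps)
    ]


def write_study(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write exposure-sumstats.tsv, outcome-maternal.tsv, outcome-fetal.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    paths = {
        "exposure": outdir / "exposure-sumstats.tsv",
        "outcome_maternal": outdir / "outcome-maternal.tsv",
        "outcome_fetal": outdir / "outcome-fetal.tsv",
    }
    for key, path in paths.items():
        write_summary_stats(study["tables"][key], path)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(study["truth"], indent=2, sort_keys=True))
    paths["truth"] = truth_path
    return paths
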