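"""Two-sample Mendelian randomization estimators and diagnostics.

Given L harmonized instruments with SNP-exposure effects beta_X (se_X) and
SNP-outcome effects beta_Y (se_Y), the per-SNP Wald ratio beta_Y/beta_X
estimates the causal effect of the exposure on the outcome under the
instrumental-variable assumptions. This module implements the standard
battery used to combine and stress-test those ratios:

* IVW — inverse-variance-weighted regression of beta_Y on beta_X through
  the origin, the efficient estimate when all instruments are valid;
* MR-Egger — the same regression with an intercept; the intercept estimates
  average directional pleiotropy and the slope a pleiotropy-adjusted effect;
* weighted median — consistent when at least half the weight comes from
  valid instruments;
* simple and weighted mode — consistent when the largest homogeneous
  cluster of ratios comes from valid instruments;
* Cochran's Q heterogeneity test and leave-one-out IVW sensitivity.

IVW and Egger standard errors use multiplicative random-effects scaling
with the residual scale floored at 1: the SE is never deflated below its
fixed-effect value, but is inflated under excess heterogeneity. Egger
p-values use t(L-2); the other estimators use normal inference. These
conventions match the R two-sample MR tooling whose output the battery is
designed to reproduce, and are recorded in each result's ``method`` label.

The statsmodels-style entry point is :class:`MRModel`, whose ``fit`` returns
a single :class:`MrResult` and whose ``fit_all`` returns an
:class:`MRBatteryResults` bundle with a ``summary()`` table.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .sumstats import HarmonizedInstrument, i2_gx, retained

__all__ = [
    "MrResult",
    "HeterogeneityResult",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "leave_one_out",
    "cochran_q",
    "ci_and_p",
    "sd_to_grams",
    "MRModel",
    "MRBatteryResults",
]

Z975 = 1.96  # normal 95% multiplier used for all reported intervals


@dataclass(frozen=True)
class MrResult:
    """One estimator's output for one exposure-outcome pair."""

    method: str
    n_snps: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(f"{self.method}: CI does not bracket the estimate")
        if not (self.se > 0):
            raise ValueError(f"{self.method}: se must be > 0")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.method}: p-value must be in (0, 1]")

    def in_grams(self, sd_grams: float) -> tuple[int, int, int]:
        """Estimate and CI bounds converted to grams (display rounding)."""
        return (
            sd_to_grams(self.estimate, sd_grams),
            sd_to_grams(self.ci_low, sd_grams),
            sd_to_grams(self.ci_high, sd_grams),
        )


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity statistic with its chi-square tail p."""

    q: float
    df: int
    pvalue: float

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("Q must be non-negative")
        if self.df < 1:
            raise ValueError("heterogeneity df must be >= 1")


def ci_and_p(estimate: float, se: float) -> tuple[float, float, float]:
    """Normal-theory 95% CI (estimate +/- 1.96 se) and two-sided p."""
    if not (math.isfinite(estimate) and math.isfinite(se)):
        raise ValueError("non-finite estimate or se")
    if se <= 0:
        raise ValueError("se must be > 0")
    z = estimate / se
    p = min(1.0, max(np.nextafter(0, 1), 2.0 * stats.norm.sf(abs(z))))
    return estimate - Z975 * se, estimate + Z975 * se, float(p)


def sd_to_grams(estimate_sd: float, sd_grams: float = 484.0) -> int:
    """Convert an effect in outcome-SD units to grams of birthweight.

    Uses the study-level SD of birthweight in grams (default 484 g per SD);
    rounds half away from zero for display.
    """
    if not math.isfinite(estimate_sd):
        raise ValueError("non-finite estimate")
    if not (math.isfinite(sd_grams) and sd_grams > 0):
        raise ValueError("sd_grams must be finite and > 0")
    grams = estimate_sd * sd_grams
    return int(math.copysign(math.floor(abs(grams) + 0.5), grams))


def _arrays(instruments: Iterable[HarmonizedInstrument]):
    inst = retained(instruments)
    bx = np.array([i.beta_exposure for i in inst], dtype=float)
    sx = np.array([i.se_exposure for i in inst], dtype=float)
    by = np.array([i.beta_outcome for i in inst], dtype=float)
    sy = np.array([i.se_outcome for i in inst], dtype=float)
    ids = [i.rsid for i in inst]
    return bx, sx, by, sy, ids


def wald_ratio(inst: HarmonizedInstrument) -> MrResult:
    """Single-SNP causal estimate beta_Y/beta_X with first-order SE.

    Uncertainty in the exposure effect is ignored (no-measurement-error
    approximation), so se = se_Y/|beta_X|.
    """
    if not inst.is_retained:
        raise ValueError(f"{inst.rsid}: instrument was dropped during harmonization")
    if inst.beta_exposure == 0:
        raise ValueError(f"{inst.rsid}: zero exposure beta — Wald ratio undefined")
    est = inst.beta_outcome / inst.beta_exposure
    se = inst.se_outcome / abs(inst.beta_exposure)
    lo, hi, p = ci_and_p(est, se)
    return MrResult("wald", 1, est, se, lo, hi, p)


def ivw(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[MrResult, HeterogeneityResult]:
    """Inverse-variance-weighted estimate with Cochran's Q heterogeneity.

    Weighted regression of beta_Y on beta_X through the origin with weights
    1/se_Y^2. The SE uses multiplicative random-effects scaling floored at
    1. With a single instrument the result degrades to the Wald ratio (with
    a warning) and Q is reported as 0 on 1 df.
    """
    inst = retained(instruments)
    if len(inst) < 1:
        raise ValueError("ivw requires at least 1 instrument")
    bx, sx, by, sy, _ = _arrays(inst)
    if np.all(bx == 0):
        raise ValueError("all exposure betas are zero")
    if len(inst) == 1:
        warnings.warn("single instrument: IVW degrades to the Wald ratio", stacklevel=2)
        res = wald_ratio(inst[0])
        res = MrResult("ivw", 1, res.estimate, res.se, res.ci_low, res.ci_high, res.pvalue)
        return res, HeterogeneityResult(0.0, 1, 1.0)
    w = 1.0 / sy**2
    fit = sm.WLS(by, bx[:, None], weights=w).fit()
    bhat = float(fit.params[0])
    se_fixed = math.sqrt(float(fit.normalized_cov_params[0, 0]))
    q = float(np.sum(w * (by - bhat * bx) ** 2))
    df = len(inst) - 1
    sigma2 = q / df
    se = se_fixed * math.sqrt(max(1.0, sigma2))
    lo, hi, p = ci_and_p(bhat, se)
    q_p = float(stats.chi2.sf(q, df))
    return (
        MrResult("ivw", len(inst), bhat, se, lo, hi, p),
        HeterogeneityResult(q, df, max(np.nextafter(0, 1), q_p) if q_p < 1 else 1.0),
    )


def egger(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[MrResult, MrResult, HeterogeneityResult]:
    """MR-Egger regression: (slope, intercept, residual heterogeneity).

    Instruments are oriented so all exposure betas are non-negative (outcome
    beta flipped jointly), then beta_Y is regressed on beta_X with an
    intercept, weights 1/se_Y^2. The intercept estimates average directional
    pleiotropy. SEs use the same multiplicative random-effects floor as IVW;
    p-values use t(L-2); residual Q has L-2 df.
    """
    inst = retained(instruments)
    if len(inst) < 3:
        raise ValueError("egger requires at least 3 instruments")
    bx, sx, by, sy, _ = _arrays(inst)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    df = len(inst) - 2
    sigma2 = float(fit.scale)  # weighted residual variance, Q/(L-2)
    # Fixed-effect SEs from the design, inflated by the floored residual scale.
    se_fixed = np.sqrt(np.diag(fit.normalized_cov_params))
    se_int, se_slope = se_fixed * math.sqrt(max(1.0, sigma2))
    b_int, b_slope = fit.params
    p_slope = float(2.0 * stats.t.sf(abs(b_slope / se_slope), df))
    p_int = float(2.0 * stats.t.sf(abs(b_int / se_int), df))
    q = sigma2 * df
    slope = MrResult(
        "egger_slope", len(inst), float(b_slope), float(se_slope),
        float(b_slope - Z975 * se_slope), float(b_slope + Z975 * se_slope),
        min(1.0, max(np.nextafter(0, 1), p_slope)),
    )
    intercept = MrResult(
        "egger_intercept", len(inst), float(b_int), float(se_int),
        float(b_int - Z975 * se_int), float(b_int + Z975 * se_int),
        min(1.0, max(np.nextafter(0, 1), p_int)),
    )
    het = HeterogeneityResult(float(q), df, float(stats.chi2.sf(q, df)) or np.nextafter(0, 1))
    return slope, intercept, het


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    below = int(np.max(np.nonzero(cum < 0.5)[0]))
    return float(
        r[below]
        + (r[below + 1] - r[below]) * (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    )


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The estimate is the point where the standardized cumulative
    inverse-variance weights of the ordered Wald ratios cross 0.5 (linear
    interpolation). The SE resamples exposure and outcome betas from
    normals centred on the observed values.
    """
    inst = retained(instruments)
    if len(inst) < 3:
        raise ValueError("weighted_median requires at least 3 instruments")
    if n_boot < 100:
        warnings.warn("n_boot < 100: bootstrap SE will be unstable", stacklevel=2)
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed for the bootstrap")
    bx, sx, by, sy, _ = _arrays(inst)
    ratios = by / bx
    weights = (bx / sy) ** 2
    est = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        boots[b] = _weighted_median(by_b / bx_b, (bx_b / sy) ** 2)
    se = float(np.std(boots, ddof=1))
    if se <= 0:
        se = np.nextafter(0, 1)
    lo, hi, p = ci_and_p(est, se)
    return MrResult("weighted_median", len(inst), est, se, lo, hi, p)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Argmax of the weighted normal-kernel density of the Wald ratios.

    Bandwidth is phi times the modified-Silverman scale
    0.9*min(sd, MAD)/L^(1/5) with the normal-consistent MAD; density is
    evaluated on a 512-point grid spanning the ratios +/- 3 bandwidths and
    argmax ties resolve to the smallest ratio.
    """
    L = len(ratios)
    s_mad = stats.median_abs_deviation(ratios, scale="normal")
    s_sd = np.std(ratios, ddof=1)
    s = 0.9 * min(s_sd, s_mad) / L ** 0.2
    h = max(1e-8, phi * s)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    wn = weights / np.sum(weights)
    dens = np.sum(wn[:, None] * stats.norm.pdf(grid[None, :], ratios[:, None], h), axis=0)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    instruments: Sequence[HarmonizedInstrument],
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrResult:
    """Mode-based causal estimate (simple or inverse-variance weighted).

    Consistent when the largest homogeneous cluster of Wald ratios comes
    from valid instruments (zero-modal-pleiotropy assumption). The SE is the
    normal-consistent MAD of a parametric bootstrap of the ratios.
    """
    inst = retained(instruments)
    if len(inst) < 3:
        raise ValueError("mode_estimate requires at least 3 instruments")
    if not (phi > 0):
        raise ValueError("phi must be positive")
    if seed is None:
        raise ValueError("mode_estimate requires an explicit seed for the bootstrap")
    bx, sx, by, sy, _ = _arrays(inst)
    ratios = by / bx
    se_ratios = sy / np.abs(bx)
    weights = 1.0 / se_ratios**2 if weighted else np.ones_like(ratios)
    est = _mode_point(ratios, weights, phi)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        r_b = rng.normal(ratios, se_ratios)
        boots[b] = _mode_point(r_b, weights, phi)
    se = float(stats.median_abs_deviation(boots, scale="normal"))
    if se <= 0:
        se = np.nextafter(0, 1)
    lo, hi, p = ci_and_p(est, se)
    label = "weighted_mode" if weighted else "simple_mode"
    return MrResult(label, len(inst), est, se, lo, hi, p)


def cochran_q(instruments: Sequence[HarmonizedInstrument]) -> HeterogeneityResult:
    """Cochran's Q heterogeneity of per-SNP Wald ratios about the IVW fit.

    Q = sum_i w_i (theta_i - theta_IVW)^2 with theta_i the Wald ratios and
    w_i = (beta_X_i/se_Y_i)^2; df = L-1; upper-tail chi-square p.
    """
    inst = retained(instruments)
    if len(inst) < 2:
        raise ValueError("cochran_q requires at least 2 instruments")
    _, het = ivw(inst)
    return het


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    estimator: Callable[[Sequence[HarmonizedInstrument]], tuple[MrResult, HeterogeneityResult]] = ivw,
) -> list[tuple[str, MrResult]]:
    """One IVW fit per omitted SNP, plus the all-SNP fit (label ``"all"``).

    Ordering follows the input instrument order; the full fit is appended
    last.
    """
    inst = retained(instruments)
    if len(inst) < 3:
        raise ValueError("leave_one_out requires at least 3 instruments")
    out: list[tuple[str, MrResult]] = []
    for i, omitted in enumerate(inst):
        subset = inst[:i] + inst[i + 1 :]
        res, _ = estimator(subset)
        out.append((omitted.rsid, res))
    full, _ = estimator(inst)
    out.append(("all", full))
    return out


class MRModel:
    """Two-sample MR model over a set of harmonized instruments.

    Parameters
    ----------
    instruments
        Harmonized instruments; dropped rows are ignored.
    sd_grams
        Optional grams-per-outcome-SD for unit conversion in summaries.

    Examples
    --------
    >>> model = MRModel(instruments)
    >>> res = model.fit()                 # IVW
    >>> battery = model.fit_all(seed=7)   # full estimator battery
    >>> print(battery.summary())
    """

    METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")

    def __init__(
        self,
        instruments: Sequence[HarmonizedInstrument],
        sd_grams: float | None = None,
    ):
        self.instruments = retained(instruments)
        if not self.instruments:
            raise ValueError("MRModel requires at least one retained instrument")
        self.sd_grams = sd_grams

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sd_grams: float | None = None) -> "MRModel":
        """Build from a DataFrame with columns rsid, beta_exposure,
        se_exposure, beta_outcome, se_outcome (already harmonized)."""
        inst = [
            HarmonizedInstrument(
                rsid=str(row["rsid"]),
                beta_exposure=float(row["beta_exposure"]),
                se_exposure=float(row["se_exposure"]),
                beta_outcome=float(row["beta_outcome"]),
                se_outcome=float(row["se_outcome"]),
                status="kept",
            )
            for _, row in df.iterrows()
        ]
        return cls(inst, sd_grams=sd_grams)

    @property
    def n_instruments(self) -> int:
        return len(self.instruments)

    def fit(self, method: str = "ivw", **kwargs) -> MrResult:
        """Fit one estimator; bootstrap methods need seed= (and accept
        n_boot=, phi=)."""
        if method == "ivw":
            res, _ = ivw(self.instruments)
            return res
        if method == "egger":
            slope, _, _ = egger(self.instruments)
            return slope
        if method == "egger_intercept":
            _, intercept, _ = egger(self.instruments)
            return intercept
        if method == "weighted_median":
            return weighted_median(self.instruments, **kwargs)
        if method == "simple_mode":
            return mode_estimate(self.instruments, weighted=False, **kwargs)
        if method == "weighted_mode":
            return mode_estimate(self.instruments, weighted=True, **kwargs)
        raise ValueError(f"unknown method {method!r}")

    def heterogeneity(self) -> HeterogeneityResult:
        return cochran_q(self.instruments)

    def instrument_strength(self) -> dict:
        """Per-SNP F statistics and (for L>=2) the I2_GX statistic."""
        f = {
            i.rsid: (i.beta_exposure / i.se_exposure) ** 2 for i in self.instruments
        }
        out = {"f_statistics": f, "f_min": min(f.values()), "f_max": max(f.values())}
        if len(self.instruments) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out["i2_gx"] = i2_gx(self.instruments)
            out["i2_gx_weak"] = out["i2_gx"] < 0.9
        return out

    def leave_one_out(self) -> list[tuple[str, MrResult]]:
        return leave_one_out(self.instruments)

    def fit_all(
        self, n_boot: int = 1000, seed: int | None = None, phi: float = 1.0
    ) -> "MRBatteryResults":
        """Run the full estimator battery with guards on instrument counts."""
        results: dict[str, MrResult] = {}
        skipped: dict[str, str] = {}
        L = self.n_instruments
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res_ivw, het = ivw(self.instruments)
        results["ivw"] = res_ivw
        egger_intercept = None
        if L >= 3:
            slope, intercept, _ = egger(self.instruments)
            results["egger"] = slope
            egger_intercept = intercept
            if seed is None:
                raise ValueError("fit_all requires a seed for bootstrap estimators")
            ss = np.random.SeedSequence(seed).spawn(3)
            results["weighted_median"] = weighted_median(
                self.instruments, n_boot=n_boot, seed=ss[0].generate_state(1)[0]
            )
            results["simple_mode"] = mode_estimate(
                self.instruments, weighted=False, phi=phi, n_boot=n_boot,
                seed=ss[1].generate_state(1)[0],
            )
            results["weighted_mode"] = mode_estimate(
                self.instruments, weighted=True, phi=phi, n_boot=n_boot,
                seed=ss[2].generate_state(1)[0],
            )
        else:
            reason = f"not run: insufficient instruments (n={L} < 3)"
            for m in ("egger", "weighted_median", "simple_mode", "weighted_mode"):
                skipped[m] = reason
        loo = leave_one_out(self.instruments) if L >= 3 else None
        return MRBatteryResults(
            model=self,
            results=results,
            egger_intercept=egger_intercept,
            heterogeneity=het if L >= 2 else None,
            leave_one_out_results=loo,
            skipped=skipped,
            strength=self.instrument_strength() if L >= 2 else None,
        )


@dataclass
class MRBatteryResults:
    """Bundle of estimator results, diagnostics and sensitivity fits."""

    model: MRModel
    results: dict[str, MrResult]
    egger_intercept: MrResult | None
    heterogeneity: HeterogeneityResult | None
    leave_one_out_results: list[tuple[str, MrResult]] | None
    skipped: dict[str, str] = field(default_factory=dict)
    strength: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, r in self.results.items():
            row = {
                "method": name,
                "n_snps": r.n_snps,
                "estimate": r.estimate,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "pvalue": r.pvalue,
            }
            if self.model.sd_grams:
                g, gl, gh = r.in_grams(self.model.sd_grams)
                row.update({"grams": g, "grams_ci_low": gl, "grams_ci_high": gh})
            rows.append(row)
        for name, reason in self.skipped.items():
            rows.append({"method": name, "n_snps": self.model.n_instruments, "note": reason})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Two-sample Mendelian randomization", "=" * 50]
        lines.append(f"Instruments: {self.model.n_instruments}")
        if self.strength:
            lines.append(
                f"F statistics: {self.strength['f_min']:.1f} - {self.strength['f_max']:.1f}"
            )
            if "i2_gx" in self.strength:
                flag = "  [< 0.9: MR-Egger caution]" if self.strength["i2_gx_weak"] else ""
                lines.append(f"I2_GX: {self.strength['i2_gx']:.2f}{flag}")
        lines.append("-" * 50)
        lines.append(f"{'method':<18}{'n':>3}{'estimate':>10}{'se':>9}{'p':>11}")
        for name, r in self.results.items():
            lines.append(
                f"{name:<18}{r.n_snps:>3}{r.estimate:>10.4f}{r.se:>9.4f}{r.pvalue:>11.4g}"
            )
        for name, reason in self.skipped.items():
            lines.append(f"{name:<18}   {reason}")
        if self.egger_intercept is not None:
            r = self.egger_intercept
            lines.append(
                f"{'egger_intercept':<18}{r.n_snps:>3}{r.estimate:>10.4f}{r.se:>9.4f}{r.pvalue:>11.4g}"
            )
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(f"Cochran's Q: {h.q:.3f} (df={h.df}, p={h.pvalue:.4g})")
        if self.model.sd_grams and "ivw" in self.results:
            g, gl, gh = self.results["ivw"].in_grams(self.model.sd_grams)
            lines.append(f"IVW in grams (SD = {self.model.sd_grams:g} g): {g} g ({gl} g, {gh} g)")
        return "\n".join(lines)
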