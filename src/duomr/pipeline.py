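"""Study orchestration: harmonize, fit the estimator battery, write reports.

A study is one exposure table (or several) against one or more outcome
tables carrying a role label (maternal- or fetal-specific effects), with
optional LD-proxy substitutions and SNP exclusion sets (e.g. re-running B12
without the pleiotropy-suspect FUT2 variant). Every pair x exclusion-set
combination gets the full battery — instrument strength, IVW, MR-Egger,
weighted median, modes, Cochran's Q, leave-one-out — plus gram conversions
and a structured harmonization log; all randomness derives from the single
configured seed, so re-runs are byte-identical.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import sumstats
from .mr import MRModel, MRBatteryResults
from .sumstats import SummaryStatsError, harmonize, instruments_to_frame, read_summary_stats

__all__ = ["AnalysisConfig", "run_study", "write_report_bundle"]

VALID_ROLES = ("maternal", "fetal", "other")


@dataclass
class AnalysisConfig:
    """Declarative description of a full MR study run."""

    exposures: list[dict]
    outcomes: list[dict]
    seed: int
    proxy_map: dict[str, str] = field(default_factory=dict)
    exclusion_sets: list[dict] = field(default_factory=list)
    palindromic_policy: str = "drop_if_no_eaf"
    n_boot: int = 1000
    phi: float = 1.0
    sd_grams: float = 484.0
    outdir: str | None = None
    scatter_export: bool = True

    def __post_init__(self) -> None:
        if self.sd_grams <= 0:
            raise ValueError("sd_grams must be > 0")
        for spec_ in self.exposures + self.outcomes:
            if "name" not in spec_ or "file" not in spec_:
                raise ValueError("each exposure/outcome needs 'name' and 'file'")
            if not Path(spec_["file"]).exists():
                raise FileNotFoundError(spec_["file"])
        for out in self.outcomes:
            if out.get("role", "other") not in VALID_ROLES:
                raise ValueError(f"invalid outcome role {out.get('role')!r}")
        for ex in self.exclusion_sets:
            if "name" not in ex or "exclude" not in ex:
                raise ValueError("each exclusion set needs 'name' and 'exclude'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _analysis_report(
    instruments, config: AnalysisConfig, seed: int
) -> dict:
    """Battery + diagnostics for one harmonized instrument set."""
    model = MRModel(instruments, sd_grams=config.sd_grams)
    battery = model.fit_all(n_boot=config.n_boot, seed=seed, phi=config.phi)
    report: dict = {
        "n_instruments": model.n_instruments,
        "estimates": battery.to_frame(),
        "summary": battery.summary(),
        "strength": battery.strength,
        "heterogeneity": battery.heterogeneity,
        "egger_intercept": battery.egger_intercept,
        "skipped": battery.skipped,
    }
    if battery.leave_one_out_results is not None:
        report["leave_one_out"] = pd.DataFrame(
            [
                {
                    "omitted": rsid,
                    "n_snps": r.n_snps,
                    "estimate": r.estimate,
                    "se": r.se,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "pvalue": r.pvalue,
                }
                for rsid, r in battery.leave_one_out_results
            ]
        )
    if config.scatter_export:
        ivw_res = battery.results["ivw"]
        report["scatter"] = {
            "points": pd.DataFrame(
                {
                    "rsid": [i.rsid for i in model.instruments],
                    "beta_exposure": [i.beta_exposure for i in model.instruments],
                    "se_exposure": [i.se_exposure for i in model.instruments],
                    "beta_outcome": [i.beta_outcome for i in model.instruments],
                    "se_outcome": [i.se_outcome for i in model.instruments],
                }
            ),
            "ivw_slope": ivw_res.estimate,
        }
    return report


def run_study(config: AnalysisConfig) -> dict:
    """Run every exposure x outcome pair, with and without each exclusion set.

    Returns a nested report bundle
    ``{(exposure, outcome): {"full": report, <exclusion name>: report, "harmonization": frame}}``
    and, when ``config.outdir`` is set, writes TSV/JSON reports under it.
    The bundle is deterministic given the config (including its seed).
    """
    bundle: dict = {"pairs": {}, "config_seed": config.seed}
    analysis_index = 0
    for exp_spec in config.exposures:
        exp = read_summary_stats(exp_spec["file"], exp_spec.get("column_map"))
        for out_spec in config.outcomes:
            out = read_summary_stats(out_spec["file"], out_spec.get("column_map"))
            key = (exp_spec["name"], out_spec["name"])
            harmonized = harmonize(
                exp,
                out,
                proxy_map=config.proxy_map,
                palindromic_policy=config.palindromic_policy,
            )
            pair: dict = {
                "role": out_spec.get("role", "other"),
                "harmonization": instruments_to_frame(harmonized),
            }
            runs = [("full", None)] + [
                (ex["name"], set(ex["exclude"])) for ex in config.exclusion_sets
            ]
            for run_name, excluded in runs:
                inst = [
                    i
                    for i in harmonized
                    if i.is_retained and (excluded is None or i.rsid not in excluded)
                ]
                seed = int(
                    np.random.SeedSequence([config.seed, analysis_index]).generate_state(1)[0]
                    % (2**31)
                )
                analysis_index += 1
                if not inst:
                    raise SummaryStatsError(
                        f"{key} [{run_name}]: no instruments left after exclusions"
                    )
                pair[run_name] = _analysis_report(inst, config, seed)
            bundle["pairs"][key] = pair
    if config.outdir:
        write_report_bundle(bundle, config.outdir)
    return bundle


def _het_dict(h) -> dict | None:
    return None if h is None else {"q": h.q, "df": h.df, "pvalue": h.pvalue}


def _result_dict(r) -> dict | None:
    if r is None:
        return None
    return {
        "method": r.method,
        "n_snps": r.n_snps,
        "estimate": r.estimate,
        "se": r.se,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "pvalue": r.pvalue,
    }


def write_report_bundle(bundle: dict, outdir: str | Path) -> None:
    """Serialize a run_study bundle as TSV + JSON files (full precision)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (exp_name, out_name), pair in bundle["pairs"].items():
        pair_dir = outdir / f"{exp_name}__{out_name}"
        pair_dir.mkdir(parents=True, exist_ok=True)
        pair["harmonization"].to_csv(
            pair_dir / "harmonization.tsv", sep="\t", index=False, float_format="%.10g"
        )
        for run_name, report in pair.items():
            if run_name in ("role", "harmonization"):
                continue
            run_dir = pair_dir / run_name
            run_dir.mkdir(parents=True, exist_ok=True)
            report["estimates"].to_csv(
                run_dir / "estimates.tsv", sep="\t", index=False, float_format="%.10g"
            )
            meta = {
                "role": pair["role"],
                "n_instruments": report["n_instruments"],
                "heterogeneity": _het_dict(report["heterogeneity"]),
                "egger_intercept": _result_dict(report["egger_intercept"]),
                "strength": report["strength"],
                "skipped": report["skipped"],
                "se_conventions": {
                    "ivw_egger": "multiplicative random effects, residual scale floored at 1",
                    "egger_inference": "t(n-2)",
                    "other_inference": "normal",
                    "i2_gx": "unsigned exposure betas, inverse-variance weights",
                },
            }
            (run_dir / "diagnostics.json").write_text(
                json.dumps(meta, indent=2, sort_keys=True)
            )
            (run_dir / "summary.txt").write_text(report["summary"] + "\n")
            if "leave_one_out" in report:
                report["leave_one_out"].to_csv(
                    run_dir / "leave_one_out.tsv", sep="\t", index=False, float_format="%.10g"
                )
            if "scatter" in report:
                report["scatter"]["points"].to_csv(
                    run_dir / "scatter.tsv", sep="\t", index=False, float_format="%.10g"
                )
                (run_dir / "scatter_fit.json").write_text(
                    json.dumps({"ivw_slope": report["scatter"]["ivw_slope"]}, sort_keys=True)
                )
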