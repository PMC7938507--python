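"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample Mendelian randomization starts from two per-SNP association
tables — one for the exposure (here serum B12 or folate), one for the
outcome (maternal- or fetal-specific effects on offspring birthweight) —
that were estimated in different studies and may report effects on
different effect alleles, or even on different strands. This module reads
such tables, checks them, and places exposure and outcome effects on a
shared effect-allele orientation, flagging palindromic (A/T, C/G) variants
whose strand cannot be resolved from allele labels alone.

It also provides the two instrument-strength summaries used before fitting:
the per-SNP approximate F statistic, F = (beta/se)^2, and the I2_GX
statistic that quantifies whether SNP-exposure effects are estimated
precisely enough for MR-Egger regression (values below 0.9 indicate
regression-dilution risk).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpAssociation",
    "HarmonizedInstrument",
    "SummaryStatsError",
    "DEFAULT_COLUMN_MAP",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "retained",
    "f_statistic",
    "i2_gx",
    "instruments_to_frame",
]

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default column names, GWAS-SSF-like; override with an explicit mapping.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pvalue": "p_value",
    "n": "n",
}

#: Palindromic SNPs with an EAF inside this band are frequency-ambiguous.
PALINDROMIC_EAF_BAND = (0.42, 0.58)


class SummaryStatsError(ValueError):
    """Raised for unreadable, structurally invalid or empty summary statistics."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary statistics for one trait.

    beta is the additive effect per copy of ``effect_allele`` on the trait
    in SD units; ``eaf`` is the effect-allele frequency, which may be
    missing (None) — some consortia do not release it.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValueError(
                f"{self.rsid}: alleles must be single bases A/C/G/T, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: non-finite beta")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"{self.rsid}: se must be finite and > 0, got {self.se}")
        if self.eaf is not None:
            if not (math.isfinite(self.eaf) and 0.0 < self.eaf < 1.0):
                raise ValueError(f"{self.rsid}: eaf must be in (0, 1), got {self.eaf}")
        if self.pvalue is not None:
            if not (math.isfinite(self.pvalue) and 0.0 < self.pvalue <= 1.0):
                raise ValueError(f"{self.rsid}: p-value must be in (0, 1], got {self.pvalue}")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.rsid}: n must be positive, got {self.n}")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's exposure and outcome effects on a shared effect allele.

    ``status`` records the harmonization decision; only ``kept`` and
    ``flipped`` rows enter the estimators. ``flipped`` means the outcome
    effect was negated exactly once to put it on the exposure's effect
    allele. ``proxy_used`` names the outcome-side rsid when the exposure
    SNP was looked up through an LD proxy.
    """

    rsid: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float | None
    se_outcome: float | None
    status: str
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    proxy_used: str | None = None
    effect_allele: str | None = None
    other_allele: str | None = None

    VALID_STATUS = (
        "kept",
        "flipped",
        "dropped_palindromic",
        "dropped_missing",
        "dropped_proxy_unresolved",
    )

    def __post_init__(self) -> None:
        if self.status not in self.VALID_STATUS:
            raise ValueError(f"{self.rsid}: unknown status {self.status!r}")
        if self.status in ("kept", "flipped"):
            for name, v in (
                ("beta_outcome", self.beta_outcome),
                ("se_outcome", self.se_outcome),
                ("beta_exposure", self.beta_exposure),
                ("se_exposure", self.se_exposure),
            ):
                if v is None or not math.isfinite(v):
                    raise ValueError(f"{self.rsid}: {name} must be finite when status={self.status}")
            if self.se_outcome <= 0 or self.se_exposure <= 0:
                raise ValueError(f"{self.rsid}: standard errors must be > 0")

    @property
    def is_retained(self) -> bool:
        return self.status in ("kept", "flipped")


def retained(instruments: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """Instruments that survived harmonization (status kept or flipped)."""
    return [i for i in instruments if i.is_retained]


_MISSING_TOKENS = {"", "na", "nan", "none", "."}


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip().lower() in _MISSING_TOKENS


def _coerce_optional_float(value) -> float | None:
    if _is_missing(value):
        return None
    v = float(value)
    return None if math.isnan(v) else v


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SnpAssociation]:
    """Read a tab-delimited summary-statistic table into SnpAssociation records.

    ``column_map`` maps the field names (rsid, effect_allele, other_allele,
    eaf, beta, se, pvalue, n) to the header names actually present in the
    file; unmapped optional fields (eaf, pvalue, n) may be absent. Rows
    violating field invariants are rejected with a warning naming the
    0-based data-row index; reading fails if no valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise SummaryStatsError(f"summary-statistic file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["rsid", "effect_allele", "other_allele", "beta", "se"]
    for key in required:
        if cmap[key] not in df.columns:
            raise SummaryStatsError(f"{path}: mapped column {cmap[key]!r} (for {key}) not in header")
    optional_present = {k: (cmap[k] in df.columns) for k in ("eaf", "pvalue", "n")}

    records: list[SnpAssociation] = []
    for idx, row in df.iterrows():
        try:
            n_raw = row[cmap["n"]] if optional_present["n"] else None
            n_val = None if _is_missing(n_raw) else int(float(n_raw))
            records.append(
                SnpAssociation(
                    rsid=str(row[cmap["rsid"]]).strip(),
                    effect_allele=str(row[cmap["effect_allele"]]).strip(),
                    other_allele=str(row[cmap["other_allele"]]).strip(),
                    beta=float(row[cmap["beta"]]),
                    se=float(row[cmap["se"]]),
                    eaf=_coerce_optional_float(row[cmap["eaf"]]) if optional_present["eaf"] else None,
                    pvalue=_coerce_optional_float(row[cmap["pvalue"]]) if optional_present["pvalue"] else None,
                    n=n_val,
                )
            )
        except (ValueError, TypeError) as exc:
            warnings.warn(f"{path}: rejected row {idx}: {exc}", stacklevel=2)
    if not records:
        raise SummaryStatsError(f"{path}: no valid summary-statistic rows")
    return records


def write_summary_stats(
    records: Sequence[SnpAssociation],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> Path:
    """Write records as a tab-delimited table (full float precision)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    df = pd.DataFrame(
        {
            cmap["rsid"]: [r.rsid for r in records],
            cmap["effect_allele"]: [r.effect_allele for r in records],
            cmap["other_allele"]: [r.other_allele for r in records],
            cmap["eaf"]: [r.eaf for r in records],
            cmap["beta"]: [repr(r.beta) for r in records],
            cmap["se"]: [repr(r.se) for r in records],
            cmap["pvalue"]: [r.pvalue for r in records],
            cmap["n"]: [r.n for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def f_statistic(assoc: SnpAssociation) -> float:
    """Approximate per-SNP instrument-strength F statistic, (beta/se)^2."""
    if not (math.isfinite(assoc.beta) and math.isfinite(assoc.se)):
        raise ValueError(f"{assoc.rsid}: non-finite beta or se")
    return (assoc.beta / assoc.se) ** 2


def i2_gx(instruments: Sequence[HarmonizedInstrument]) -> float:
    """I2_GX instrument-strength statistic for MR-Egger.

    Computed as (Q_GX - (L-1)) / Q_GX where Q_GX is the inverse-variance
    weighted heterogeneity statistic of the |beta_exposure| values (weights
    1/se_exposure^2). Truncated below at 0 for reporting. A warning is
    issued when the value falls below 0.9, the conventional threshold under
    which MR-Egger suffers regression dilution from exposure measurement
    error.
    """
    inst = retained(instruments)
    if len(inst) < 2:
        raise ValueError("i2_gx requires at least 2 retained instruments")
    bx = np.abs(np.array([i.beta_exposure for i in inst], dtype=float))
    w = 1.0 / np.array([i.se_exposure for i in inst], dtype=float) ** 2
    mu = np.sum(w * bx) / np.sum(w)
    q = float(np.sum(w * (bx - mu) ** 2))
    if q <= 0.0:
        warnings.warn("I2_GX degenerate (Q_GX = 0); reporting 0", stacklevel=2)
        return 0.0
    value = max(0.0, (q - (len(inst) - 1)) / q)
    if value < 0.9:
        warnings.warn(
            f"I2_GX = {value:.3f} < 0.9: MR-Egger estimates may be attenuated by "
            "exposure measurement error; interpret with caution",
            stacklevel=2,
        )
    return value


def _match_alleles(
    exp: SnpAssociation, out: SnpAssociation
) -> tuple[str, float | None] | None:
    """Resolve outcome orientation relative to the exposure alleles.

    Returns ("same"|"swapped", outcome eaf on the matched orientation) or
    None when the allele pairs are irreconcilable. Strand flips are handled
    by complementing the outcome alleles before comparison.
    """
    pairs = [
        (out.effect_allele, out.other_allele, out.eaf),
        (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele], out.eaf),
    ]
    for ea, oa, eaf in pairs:
        if (ea, oa) == (exp.effect_allele, exp.other_allele):
            return "same", eaf
        if (ea, oa) == (exp.other_allele, exp.effect_allele):
            return "swapped", eaf
    return None


def harmonize(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    proxy_map: Mapping[str, str] | None = None,
    palindromic_policy: str = "drop_if_no_eaf",
) -> list[HarmonizedInstrument]:
    """Place exposure and outcome effects on a shared effect-allele orientation.

    Every exposure SNP yields exactly one output row, in input order, with a
    status recording its fate. Outcome rows are looked up by rsid, after
    substituting LD proxies from ``proxy_map`` (exposure rsid -> outcome
    rsid). When the outcome's alleles are swapped relative to the exposure,
    the outcome beta is negated and its EAF reflected (status ``flipped``).

    Palindromic (A/T, C/G) SNPs cannot be strand-resolved from alleles:
    they are aligned by allele frequency when both EAFs are available and
    both fall outside the ambiguity band [0.42, 0.58], and dropped when an
    EAF is missing. Under ``palindromic_policy="eaf_infer"`` an EAF inside
    the band also drops the SNP; ``"drop_if_no_eaf"`` keeps band-interior
    SNPs on the allele-frequency alignment with a warning.
    """
    if palindromic_policy not in ("drop_if_no_eaf", "eaf_infer"):
        raise ValueError(f"unknown palindromic_policy {palindromic_policy!r}")
    proxy_map = dict(proxy_map or {})
    exp_ids = [e.rsid for e in exposure]
    if len(set(exp_ids)) != len(exp_ids):
        raise SummaryStatsError("duplicate rsids in exposure table")
    out_ids = [o.rsid for o in outcome]
    if len(set(out_ids)) != len(out_ids):
        raise SummaryStatsError("duplicate rsids in outcome table")
    out_by_id = {o.rsid: o for o in outcome}

    lo_band, hi_band = PALINDROMIC_EAF_BAND
    results: list[HarmonizedInstrument] = []
    for exp in exposure:
        lookup = proxy_map.get(exp.rsid, exp.rsid)
        proxy_used = lookup if lookup != exp.rsid else None
        out = out_by_id.get(lookup)

        def dropped(status: str) -> HarmonizedInstrument:
            return HarmonizedInstrument(
                rsid=exp.rsid,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=None,
                se_outcome=None,
                eaf_exposure=exp.eaf,
                eaf_outcome=None,
                status=status,
                proxy_used=proxy_used,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
            )

        if out is None:
            results.append(dropped("dropped_proxy_unresolved"))
            continue

        if exp.is_palindromic and proxy_used is None:
            if not out.is_palindromic:
                raise SummaryStatsError(
                    f"{exp.rsid}: palindromic in exposure but alleles "
                    f"{out.effect_allele}/{out.other_allele} in outcome — build mismatch?"
                )
            if exp.eaf is None or out.eaf is None:
                results.append(dropped("dropped_palindromic"))
                continue
            ambiguous = (lo_band <= exp.eaf <= hi_band) or (lo_band <= out.eaf <= hi_band)
            if ambiguous:
                if palindromic_policy == "eaf_infer":
                    results.append(dropped("dropped_palindromic"))
                    continue
                warnings.warn(
                    f"{exp.rsid}: palindromic with EAF in the ambiguity band "
                    f"{PALINDROMIC_EAF_BAND}; frequency alignment is unreliable",
                    stacklevel=2,
                )
            # Align by frequency: same side of 0.5 means same effect allele.
            same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
            if same_side:
                beta_out, eaf_out, status = out.beta, out.eaf, "kept"
            else:
                beta_out, eaf_out, status = -out.beta, 1.0 - out.eaf, "flipped"
        else:
            match = None if proxy_used is not None else _match_alleles(exp, out)
            if proxy_used is not None:
                # A proxy is a different variant: allele labels are not
                # comparable, so the caller-supplied orientation is trusted.
                beta_out, eaf_out, status = out.beta, out.eaf, "kept"
            elif match is None:
                raise SummaryStatsError(
                    f"{exp.rsid}: outcome alleles {out.effect_allele}/{out.other_allele} "
                    f"incompatible with exposure {exp.effect_allele}/{exp.other_allele}"
                )
            elif match[0] == "same":
                beta_out, eaf_out, status = out.beta, match[1], "kept"
            else:
                eaf_out = None if match[1] is None else 1.0 - match[1]
                beta_out, status = -out.beta, "flipped"

        if not (math.isfinite(beta_out) and math.isfinite(out.se)):
            results.append(dropped("dropped_missing"))
            continue
        results.append(
            HarmonizedInstrument(
                rsid=exp.rsid,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=float(beta_out),
                se_outcome=out.se,
                eaf_exposure=exp.eaf,
                eaf_outcome=eaf_out,
                status=status,
                proxy_used=proxy_used,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
            )
        )

    if not any(r.is_retained for r in results):
        raise SummaryStatsError("harmonization retained no instruments")
    return results


def instruments_to_frame(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Tabular view of harmonized instruments (one row per exposure SNP)."""
    return pd.DataFrame(
        {
            "rsid": [i.rsid for i in instruments],
            "effect_allele": [i.effect_allele for i in instruments],
            "other_allele": [i.other_allele for i in instruments],
            "beta_exposure": [i.beta_exposure for i in instruments],
            "se_exposure": [i.se_exposure for i in instruments],
            "beta_outcome": [i.beta_outcome for i in instruments],
            "se_outcome": [i.se_outcome for i in instruments],
            "eaf_exposure": [i.eaf_exposure for i in instruments],
            "eaf_outcome": [i.eaf_outcome for i in instruments],
            "status": [i.status for i in instruments],
            "proxy_used": [i.proxy_used for i in instruments],
        }
    )
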