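"""Dietary pesticide risk quotients for honey bees.

A risk quotient (RQ) relates the estimated daily dietary intake of a
pesticide by an adult worker bee to a toxicity endpoint:

    RQ_acute   = (C_nectar [µg/kg] × 140e-6 kg/bee + C_pollen [µg/kg] × 9.6e-6 kg/bee) / LD50 [µg/bee]
    RQ_chronic = (same numerator) / chronic 10-day LC50 or LDD50 [µg/bee/day]

where 140 mg nectar and 9.6 mg pollen are the standard daily consumption
assumptions for an adult worker.  RQ = 1 means the daily intake equals the
dose that kills half a test population.  RQs are compared against regulatory
levels of concern: 0.4 (acute, cage studies), 0.2 (acute, field colonies)
and 0.03 (chronic, field colonies); exceedance is strict (RQ > threshold),
so a value exactly at a threshold counts as a non-exceedance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd

from .synthetic import RESIDUE_COLUMNS, TOXICITY_COLUMNS

__all__ = [
    "ConsumptionConstants",
    "ThresholdRegistry",
    "DEFAULT_CONSTANTS",
    "DEFAULT_THRESHOLDS",
    "RQ_RESULT_COLUMNS",
    "ToxicityError",
    "DataIntegrityError",
    "compute_rq_acute",
    "compute_rq_chronic",
    "select_chronic_endpoint",
    "compute_site_rqs",
    "RQComputation",
    "total_rq",
    "exceedance_report",
]

RQ_RESULT_COLUMNS = [
    "site_id",
    "proximity",
    "year",
    "time_point",
    "compound",
    "kind",
    "rq",
    "endpoint_used",
    "exceeds_acute_field",
    "exceeds_acute_cage",
    "exceeds_chronic",
]


class ToxicityError(ValueError):
    """A toxicity endpoint is missing or non-positive for a compound."""


class DataIntegrityError(ValueError):
    """The residue table violates its schema (e.g. duplicate matrix records)."""


@dataclass(frozen=True)
class ConsumptionConstants:
    """Daily dietary intake of an adult worker bee, in kg per bee per day."""

    nectar_intake_kg: float = 140e-6
    pollen_intake_kg: float = 9.6e-6

    def __post_init__(self) -> None:
        if self.nectar_intake_kg <= 0 or self.pollen_intake_kg <= 0:
            raise ValueError("consumption constants must be strictly positive")


@dataclass(frozen=True)
class ThresholdRegistry:
    """Regulatory RQ levels of concern (dimensionless)."""

    acute_cage: float = 0.4
    acute_field: float = 0.2
    chronic: float = 0.03

    def __post_init__(self) -> None:
        if not (self.chronic < self.acute_field < self.acute_cage):
            raise ValueError("thresholds must satisfy chronic < acute_field < acute_cage")


DEFAULT_CONSTANTS = ConsumptionConstants()
DEFAULT_THRESHOLDS = ThresholdRegistry()


def _daily_intake(nectar_residue: float, pollen_residue: float, constants: ConsumptionConstants) -> float:
    if nectar_residue < 0 or pollen_residue < 0:
        raise ValueError("residue concentrations must be non-negative")
    return nectar_residue * constants.nectar_intake_kg + pollen_residue * constants.pollen_intake_kg


def compute_rq_acute(
    nectar_residue: float,
    pollen_residue: float,
    ld50: float,
    constants: ConsumptionConstants = DEFAULT_CONSTANTS,
) -> float:
    """Acute dietary RQ from µg/kg residues and an acute oral LD50 in µg/bee."""
    if ld50 is None or not np.isfinite(ld50) or ld50 <= 0:
        raise ToxicityError(f"acute oral LD50 must be positive, got {ld50!r}")
    return _daily_intake(nectar_residue, pollen_residue, constants) / ld50


def compute_rq_chronic(
    nectar_residue: float,
    pollen_residue: float,
    chronic_endpoint: float,
    constants: ConsumptionConstants = DEFAULT_CONSTANTS,
) -> float:
    """Chronic dietary RQ; the denominator is a 10-day LC50 or LDD50 in µg/bee/day."""
    if chronic_endpoint is None or not np.isfinite(chronic_endpoint) or chronic_endpoint <= 0:
        raise ToxicityError(f"chronic endpoint must be positive, got {chronic_endpoint!r}")
    return _daily_intake(nectar_residue, pollen_residue, constants) / chronic_endpoint


def select_chronic_endpoint(
    lc50: Optional[float],
    ldd50: Optional[float],
    policy: Literal["min", "lc50", "ldd50"] = "min",
) -> Optional[tuple[float, str]]:
    """Pick the chronic endpoint to use; returns (value, label) or None.

    With the default ``min`` policy the smaller (more conservative, larger RQ)
    of the two endpoints wins when both exist.
    """
    lc = lc50 if lc50 is not None and np.isfinite(lc50) else None
    ldd = ldd50 if ldd50 is not None and np.isfinite(ldd50) else None
    if policy == "lc50":
        return (lc, "lc50") if lc is not None else None
    if policy == "ldd50":
        return (ldd, "ldd50") if ldd is not None else None
    if policy != "min":
        raise ValueError(f"unknown chronic endpoint policy {policy!r}")
    candidates = [(v, label) for v, label in [(lc, "lc50"), (ldd, "ldd50")] if v is not None]
    if not candidates:
        return None
    return min(candidates, key=lambda t: t[0])


@dataclass
class RQComputation:
    """Results of a site-level RQ computation plus any skipped compounds."""

    results: pd.DataFrame
    skipped: pd.DataFrame  # columns: compound, reason

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.results[self.results["kind"] == kind].reset_index(drop=True)


def _toxicity_lookup(tox: pd.DataFrame) -> dict[str, dict]:
    missing = set(TOXICITY_COLUMNS[:4]) - set(tox.columns)
    if missing:
        raise DataIntegrityError(f"toxicity table missing columns: {sorted(missing)}")
    out: dict[str, dict] = {}
    for row in tox.itertuples(index=False):
        rec = row._asdict()
        for key in ("acute_oral_ld50_ug_per_bee", "chronic_lc50_ug_per_bee_day", "chronic_ldd50_ug_per_bee_day"):
            v = rec.get(key)
            if v is not None and not (isinstance(v, float) and np.isnan(v)) and v <= 0:
                raise ToxicityError(f"compound {rec['compound']!r}: endpoint {key} must be positive, got {v}")
            rec[key] = None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
        out[rec["compound"]] = rec
    return out


def compute_site_rqs(
    residues: pd.DataFrame,
    tox: pd.DataFrame,
    constants: ConsumptionConstants = DEFAULT_CONSTANTS,
    registry: ThresholdRegistry = DEFAULT_THRESHOLDS,
    censoring_policy: Literal["zero", "half_lod"] = "zero",
    lod_by_compound: Optional[Mapping[str, float]] = None,
    chronic_policy: Literal["min", "lc50", "ldd50"] = "min",
    chronic_policy_overrides: Optional[Mapping[str, str]] = None,
) -> RQComputation:
    """Per-compound acute and chronic RQs for every site/year/time point group.

    A group (site, year, time point, compound) is scored only when at least
    one matrix record is a detection (``detected`` or ``below_loq``); a
    missing or censored matrix contributes residue 0 under the default
    ``zero`` censoring policy, or LOD/2 under ``half_lod`` (which requires
    ``lod_by_compound``).  Each scored group yields one acute result (LD50)
    and, when a chronic endpoint exists, one chronic result.  Compounds with
    detections but no usable endpoint are reported in ``skipped`` rather
    than raising.
    """
    missing = set(RESIDUE_COLUMNS) - set(residues.columns)
    if missing:
        raise DataIntegrityError(f"residue table missing columns: {sorted(missing)}")
    if (residues["concentration_ug_per_kg"] < 0).any():
        bad = residues.index[residues["concentration_ug_per_kg"] < 0][0]
        raise ValueError(f"negative concentration at row {bad}")
    if censoring_policy not in ("zero", "half_lod"):
        raise ValueError(f"unknown censoring policy {censoring_policy!r}")
    if censoring_policy == "half_lod" and lod_by_compound is None:
        raise ValueError("censoring_policy='half_lod' requires lod_by_compound")

    keys = ["site_id", "proximity", "year", "time_point", "compound"]
    dup = residues.duplicated(subset=keys + ["matrix"])
    if dup.any():
        first = residues.loc[dup.idxmax(), keys + ["matrix"]].to_dict()
        raise DataIntegrityError(f"duplicate matrix record: {first}")

    tox_by_compound = _toxicity_lookup(tox)
    overrides = dict(chronic_policy_overrides or {})

    detected_mask = residues["censoring"].isin(["detected", "below_loq"])

    work = residues.copy()
    if censoring_policy == "half_lod":
        nd = ~detected_mask
        lods = work.loc[nd, "compound"].map(lambda c: lod_by_compound.get(c))
        if lods.isna().any():
            unknown = sorted(work.loc[nd, "compound"][lods.isna()].unique())
            raise ValueError(f"lod_by_compound missing compounds: {unknown}")
        work.loc[nd, "concentration_ug_per_kg"] = lods / 2.0

    rows: list[dict] = []
    skipped: dict[str, str] = {}
    grouped = work.groupby(keys, sort=True)
    any_detection = detected_mask.groupby([residues[k] for k in keys]).any()

    for group_key, block in grouped:
        if not any_detection.loc[group_key]:
            continue
        site_id, proximity, year, time_point, compound = group_key
        by_matrix = block.set_index("matrix")["concentration_ug_per_kg"]
        nectar = float(by_matrix.get("nectar", 0.0))
        pollen = float(by_matrix.get("pollen", 0.0))

        rec = tox_by_compound.get(compound)
        base = {
            "site_id": site_id,
            "proximity": proximity,
            "year": year,
            "time_point": time_point,
            "compound": compound,
        }
        if rec is None:
            skipped[compound] = "compound absent from toxicity table"
            continue

        ld50 = rec["acute_oral_ld50_ug_per_bee"]
        if ld50 is None:
            skipped[compound] = "no acute oral LD50"
        else:
            rq = compute_rq_acute(nectar, pollen, ld50, constants)
            rows.append(
                base
                | {
                    "kind": "acute",
                    "rq": rq,
                    "endpoint_used": "ld50",
                    "exceeds_acute_field": rq > registry.acute_field,
                    "exceeds_acute_cage": rq > registry.acute_cage,
                    "exceeds_chronic": False,
                }
            )

        chosen = select_chronic_endpoint(
            rec["chronic_lc50_ug_per_bee_day"],
            rec["chronic_ldd50_ug_per_bee_day"],
            overrides.get(compound, chronic_policy),  # type: ignore[arg-type]
        )
        if chosen is not None:
            endpoint, label = chosen
            rq = compute_rq_chronic(nectar, pollen, endpoint, constants)
            rows.append(
                base
                | {
                    "kind": "chronic",
                    "rq": rq,
                    "endpoint_used": label,
                    "exceeds_acute_field": False,
                    "exceeds_acute_cage": False,
                    "exceeds_chronic": rq > registry.chronic,
                }
            )

    results = pd.DataFrame(rows, columns=RQ_RESULT_COLUMNS)
    skipped_df = pd.DataFrame(
        sorted(skipped.items()), columns=["compound", "reason"]
    )
    return RQComputation(results=results, skipped=skipped_df)


def total_rq(results: pd.DataFrame, kind: Literal["acute", "chronic"]) -> pd.DataFrame:
    """Sum of RQs of one kind per (site, year, time point), effects additive.

    Groups with no results are absent from the output (a site with no
    detections has no total, rather than a total of zero).
    """
    if kind not in ("acute", "chronic"):
        raise ValueError(f"kind must be 'acute' or 'chronic', got {kind!r}")
    if results.empty:
        return pd.DataFrame(columns=["site_id", "proximity", "year", "time_point", "total_rq"])
    present = set(results["kind"].unique())
    if present - {kind}:
        raise ValueError(f"results contain kinds {sorted(present)}; expected only {kind!r}")
    keys = ["site_id", "proximity", "year", "time_point"]
    ordered = results.sort_values(keys + ["compound"], kind="mergesort")
    totals = ordered.groupby(keys, sort=True)["rq"].sum().reset_index(name="total_rq")
    return totals


def exceedance_report(
    results: pd.DataFrame,
    registry: ThresholdRegistry = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Distinct-site exceedance counts per compound and threshold.

    A site counts once per (compound, threshold) if its RQ strictly exceeds
    the threshold at any year/time point.  Equality with a threshold is a
    non-exceedance.
    """
    thresholds = [
        ("acute", "acute_field", registry.acute_field),
        ("acute", "acute_cage", registry.acute_cage),
        ("chronic", "chronic", registry.chronic),
    ]
    rows = []
    compounds = sorted(results["compound"].unique()) if not results.empty else []
    for compound in compounds:
        sub = results[results["compound"] == compound]
        for kind, name, value in thresholds:
            of_kind = sub[sub["kind"] == kind]
            exceeding = of_kind.loc[of_kind["rq"] > value, "site_id"].nunique()
            rows.append(
                {
                    "compound": compound,
                    "kind": kind,
                    "threshold_name": name,
                    "threshold": value,
                    "n_sites_exceeding": int(exceeding),
                }
            )
    return pd.DataFrame(
        rows, columns=["compound", "kind", "threshold_name", "threshold", "n_sites_exceeding"]
    )
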