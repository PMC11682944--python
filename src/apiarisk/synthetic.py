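"""Seeded synthetic residue tables and toxicity references.

Residue surveys of pollen and nectar are positive, right-skewed and heavily
censored: most compound/site combinations are non-detects, detected values
span orders of magnitude, and analytical labs report a limit of detection
(LOD) and a limit of quantification (LOQ) per compound.  The generator
emulates that structure — a per-compound lognormal concentration model with
a detection probability, LOD/LOQ censoring, and an optional multiplier for
sites far from the focal crop — so the risk and profit stages can be
exercised end-to-end without any external download.

Records are emitted at the apiary (site) level: one pooled sample per site,
matrix, time point and year, mirroring the common field design where the
colonies of an apiary are pooled before multiresidue analysis.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "CompoundSpec",
    "PlantedDetection",
    "SyntheticConfig",
    "RESIDUE_COLUMNS",
    "TOXICITY_COLUMNS",
    "DEFAULT_SEED",
    "default_compounds",
    "default_synthetic_config",
    "generate_residues",
    "default_toxicity_reference",
]

#: Documented residue CSV header (units embedded in column names).
RESIDUE_COLUMNS = [
    "site_id",
    "proximity",
    "year",
    "time_point",
    "matrix",
    "compound",
    "concentration_ug_per_kg",
    "censoring",
]

#: Documented toxicity CSV header.
TOXICITY_COLUMNS = [
    "compound",
    "acute_oral_ld50_ug_per_bee",
    "chronic_lc50_ug_per_bee_day",
    "chronic_ldd50_ug_per_bee_day",
    "source_note",
]

#: Default generator seed; every synthetic run is reproducible by construction.
DEFAULT_SEED = 2021


class CompoundSpec(BaseModel):
    """Concentration model for one pesticide compound.

    Concentrations (µg/kg) are lognormal per matrix; ``detection_prob`` is
    the probability that a given pooled sample contains the compound at all;
    ``far_site_multiplier`` scales concentrations at far sites (1 = no
    near/far difference).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    log_mean_pollen: float = 0.0
    log_sd_pollen: float = Field(1.0, gt=0)
    log_mean_nectar: float = 0.0
    log_sd_nectar: float = Field(1.0, gt=0)
    detection_prob: float = Field(0.5, ge=0, le=1)
    far_site_multiplier: float = Field(1.0, ge=0)
    lod_ug_per_kg: float = Field(0.1, gt=0)
    loq_ug_per_kg: float = Field(0.5, gt=0)

    @model_validator(mode="after")
    def _lod_le_loq(self) -> "CompoundSpec":
        if self.lod_ug_per_kg > self.loq_ug_per_kg:
            raise ValueError(
                f"compound {self.name!r}: lod_ug_per_kg ({self.lod_ug_per_kg}) "
                f"exceeds loq_ug_per_kg ({self.loq_ug_per_kg})"
            )
        return self


class PlantedDetection(BaseModel):
    """Deterministic override forcing a known concentration into the table.

    Used to engineer exact exceedance patterns (e.g. a chronic risk quotient
    above threshold at a chosen set of sites) that a stochastic draw cannot
    guarantee.  Matching records are overwritten with ``concentration_ug_per_kg``
    and marked ``detected``.
    """

    model_config = ConfigDict(frozen=True)

    compound: str
    site_ids: tuple[str, ...]
    matrix: str = "nectar"
    time_point: Optional[str] = None  # None = all time points
    concentration_ug_per_kg: float = Field(gt=0)

    @model_validator(mode="after")
    def _matrix_ok(self) -> "PlantedDetection":
        if self.matrix not in ("pollen", "nectar"):
            raise ValueError(f"matrix must be 'pollen' or 'nectar', got {self.matrix!r}")
        return self


class SyntheticConfig(BaseModel):
    """Full configuration for one synthetic residue survey."""

    model_config = ConfigDict(frozen=True)

    n_near_sites: int = Field(10, ge=1)
    n_far_sites: int = Field(10, ge=1)
    time_points: tuple[str, ...] = ("T2", "T3")
    years: tuple[str, ...] = ("2020", "2021")
    compounds: tuple[CompoundSpec, ...]
    planted: tuple[PlantedDetection, ...] = ()
    seed: int = DEFAULT_SEED

    @model_validator(mode="after")
    def _validate(self) -> "SyntheticConfig":
        if not self.compounds:
            raise ValueError("compounds: at least one compound spec is required")
        if not self.time_points:
            raise ValueError("time_points: at least one time point is required")
        if not self.years:
            raise ValueError("years: at least one year is required")
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            raise ValueError("compounds: duplicate compound names")
        known = set(names)
        sites = set(self.site_ids())
        for p in self.planted:
            if p.compound not in known:
                raise ValueError(f"planted: unknown compound {p.compound!r}")
            missing = set(p.site_ids) - sites
            if missing:
                raise ValueError(f"planted: unknown site ids {sorted(missing)}")
        return self

    def site_ids(self) -> list[str]:
        near = [f"near_{i + 1:02d}" for i in range(self.n_near_sites)]
        far = [f"far_{i + 1:02d}" for i in range(self.n_far_sites)]
        return near + far


# Detection frequencies mirror a two-year, 20-site survey where the two focal
# neonicotinoids (clothianidin, thiamethoxam) were detected disproportionately
# at far sites; fungicides such as fluopyram and flupyradifurone are the most
# ubiquitous compounds.  (frequency, pollen log-mean, nectar log-mean, far multiplier)
_DEFAULT_COMPOUND_TABLE: list[tuple[str, float, float, float, float]] = [
    ("boscalid", 0.41, 2.3, 1.4, 1.0),
    ("chlorantraniliprole", 0.05, 1.0, 0.3, 1.0),
    ("clothianidin", 0.12, -2.5, -3.2, 4.0),
    ("coumaphos", 0.05, 0.8, 0.1, 1.0),
    ("difenoconazole", 0.08, 1.2, 0.5, 1.0),
    ("dimethoate", 0.08, 1.0, 0.4, 1.0),
    ("fenhexamid", 0.05, 1.5, 0.6, 1.0),
    ("flonicamid", 0.08, 1.4, 0.7, 1.0),
    ("fluopyram", 0.59, 2.6, 1.6, 1.0),
    ("flupyradifurone", 0.63, 2.8, 1.8, 1.0),
    ("imidacloprid", 0.38, -0.5, -1.0, 1.0),
    ("linuron", 0.26, 1.8, 0.9, 1.0),
    ("mandipropamid", 0.05, 1.1, 0.4, 1.0),
    ("metconazole", 0.28, 1.9, 1.0, 1.0),
    ("napropamide", 0.05, 1.2, 0.5, 1.0),
    ("novaluron", 0.06, 1.0, 0.3, 1.0),
    ("omethoate", 0.05, 0.7, 0.2, 1.0),
    ("pyraclostrobin", 0.41, 2.2, 1.3, 1.0),
    ("pyrimethanil", 0.46, 2.4, 1.5, 1.0),
    ("thiamethoxam", 0.19, -1.0, -1.5, 3.0),
]


def default_compounds() -> tuple[CompoundSpec, ...]:
    """Specs for the 20 packaged compounds (lognormal params in log µg/kg)."""
    return tuple(
        CompoundSpec(
            name=name,
            log_mean_pollen=lmp,
            log_sd_pollen=0.9,
            log_mean_nectar=lmn,
            log_sd_nectar=0.9,
            detection_prob=p,
            far_site_multiplier=mult,
            lod_ug_per_kg=0.1,
            loq_ug_per_kg=0.5,
        )
        for name, p, lmp, lmn, mult in _DEFAULT_COMPOUND_TABLE
    )


def default_synthetic_config(seed: int = DEFAULT_SEED) -> SyntheticConfig:
    """The packaged survey design: 10 near + 10 far sites, T2/T3, two years."""
    return SyntheticConfig(compounds=default_compounds(), seed=seed)


def generate_residues(config: SyntheticConfig) -> pd.DataFrame:
    """Draw one residue record per site × year × time point × matrix × compound.

    Sampling model per record: with probability ``1 - detection_prob`` the
    record is a non-detect (stored concentration 0, censoring ``below_lod``);
    otherwise the concentration is lognormal with the compound's per-matrix
    parameters, multiplied by ``far_site_multiplier`` at far sites, then
    censored: values below the LOD are stored as 0 (``below_lod``), values
    between LOD and LOQ keep their drawn value but are flagged ``below_loq``.

    Deterministic for a fixed ``config.seed``.

    Returns a DataFrame with :data:`RESIDUE_COLUMNS`.
    """
    rng = np.random.default_rng(config.seed)
    sites = config.site_ids()
    proximity = ["near"] * config.n_near_sites + ["far"] * config.n_far_sites

    grid = pd.MultiIndex.from_product(
        [list(zip(sites, proximity)), config.years, config.time_points, ("pollen", "nectar")],
        names=["site_prox", "year", "time_point", "matrix"],
    ).to_frame(index=False)
    grid[["site_id", "proximity"]] = pd.DataFrame(
        grid.pop("site_prox").tolist(), columns=["site_id", "proximity"]
    )

    frames = []
    for spec in config.compounds:
        block = grid.copy()
        block["compound"] = spec.name
        n = len(block)
        detected = rng.random(n) < spec.detection_prob
        log_mean = np.where(block["matrix"] == "pollen", spec.log_mean_pollen, spec.log_mean_nectar)
        log_sd = np.where(block["matrix"] == "pollen", spec.log_sd_pollen, spec.log_sd_nectar)
        conc = rng.lognormal(mean=log_mean, sigma=log_sd)
        conc = np.where(block["proximity"] == "far", conc * spec.far_site_multiplier, conc)
        conc = np.where(detected, conc, 0.0)

        censoring = np.where(conc >= spec.loq_ug_per_kg, "detected", "below_loq")
        below_lod = conc < spec.lod_ug_per_kg
        censoring = np.where(below_lod, "below_lod", censoring)
        conc = np.where(below_lod, 0.0, conc)

        block["concentration_ug_per_kg"] = conc
        block["censoring"] = censoring
        frames.append(block)

    table = pd.concat(frames, ignore_index=True)

    for plant in config.planted:
        mask = (
            (table["compound"] == plant.compound)
            & table["site_id"].isin(plant.site_ids)
            & (table["matrix"] == plant.matrix)
        )
        if plant.time_point is not None:
            mask &= table["time_point"] == plant.time_point
        table.loc[mask, "concentration_ug_per_kg"] = plant.concentration_ug_per_kg
        table.loc[mask, "censoring"] = "detected"

    order = ["site_id", "year", "time_point", "matrix", "compound"]
    table = table.sort_values(order, kind="mergesort").reset_index(drop=True)
    return table[RESIDUE_COLUMNS]


# Placeholder endpoints, synthetic: order-of-magnitude-plausible for each class
# (neonicotinoids and organophosphates are highly toxic per bee; most fungicides
# and herbicides are orders of magnitude less so).  Chronic 10-day endpoints are
# packaged only for the two systemic neonicotinoids whose chronic dietary risk
# is the usual focus of such surveys.  Substitute a literature-sourced table
# for any real analysis.
_PLACEHOLDER_TOXICITY: list[tuple[str, float, Optional[float], Optional[float]]] = [
    ("boscalid", 166.0, None, None),
    ("chlorantraniliprole", 4.0, None, None),
    ("clothianidin", 0.00368, 0.0011, 0.00095),
    ("coumaphos", 3.0, None, None),
    ("difenoconazole", 100.0, None, None),
    ("dimethoate", 0.152, None, None),
    ("fenhexamid", 102.0, None, None),
    ("flonicamid", 53.3, None, None),
    ("fluopyram", 100.0, None, None),
    ("flupyradifurone", 1.2, None, None),
    ("imidacloprid", 0.0037, None, None),
    ("linuron", 100.0, None, None),
    ("mandipropamid", 200.0, None, None),
    ("metconazole", 90.0, None, None),
    ("napropamide", 100.0, None, None),
    ("novaluron", 100.0, None, None),
    ("omethoate", 0.048, None, None),
    ("pyraclostrobin", 100.0, None, None),
    ("pyrimethanil", 100.0, None, None),
    ("thiamethoxam", 0.005, 0.0048, 0.0041),
]


def default_toxicity_reference() -> pd.DataFrame:
    """Packaged toxicity reference covering the 20 default compounds.

    Endpoints are synthetic placeholders (see ``source_note``); they carry the
    right orders of magnitude for each chemical class so that risk-quotient
    code paths are exercised realistically, but they are not literature values.
    """
    rows = [
        {
            "compound": name,
            "acute_oral_ld50_ug_per_bee": ld50,
            "chronic_lc50_ug_per_bee_day": lc50,
            "chronic_ldd50_ug_per_bee_day": ldd50,
            "source_note": "synthetic placeholder endpoint; substitute literature values",
        }
        for name, ld50, lc50, ldd50 in _PLACEHOLDER_TOXICITY
    ]
    return pd.DataFrame(rows, columns=TOXICITY_COLUMNS)
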