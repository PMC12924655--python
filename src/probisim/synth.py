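"""Synthetic-data generators for every input the pipeline consumes.

All generators are pure functions of (parameters, seed): identical inputs
produce identical outputs, and zero-noise outputs lie exactly on the
declared mean structure.  The module emulates

* gLV-governed coculture trajectories with observation noise (none,
  multiplicative lognormal, or a full serial-dilution plate-count pipeline);
* serial-dilution plate counts with Poisson counting noise;
* temperature-dependent storage-viability curves, including the biphasic
  ambient-temperature profile (growth through day 7, decline from day 10);
* surface-survival decay curves on treated high-density polyethylene;
* inhibition-zone tables with a stated bactericidal fraction, plus the
  bundled 43-strain reference zone table used for exact summary checks.

Between anchor days the storage and surface mean curves interpolate
piecewise-linearly in log10 space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from probisim import glv
from probisim.efficacy import PlateCount, ZoneRecord
from probisim.fit import CocultureDataset

GENERATOR_VERSION = "1.0"


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Coculture trajectories
# ---------------------------------------------------------------------------

def gen_coculture(
    model: glv.CommunityModel,
    times: Sequence[float],
    noise: str = "none",
    sigma: float = 0.05,
    seed: int = 0,
    initial: Sequence[float] | None = None,
    dilution_levels: Sequence[float] | None = None,
    plated_volume: float = 0.05,
    plate_replicates: int = 2,
) -> CocultureDataset:
    """Simulate a coculture and apply an observation model.

    noise:
      "none"        observed equals simulated exactly;
      "lognormal"   observed = simulated * exp(N(0, sigma)) per cell;
      "plate-count" each density is routed through a serial-dilution Poisson
                    plate-count draw and re-enumerated (uncountable -> NaN).

    Metadata records the generating coefficients so recovery studies can
    compare estimates against truth.
    """
    times = np.asarray(times, dtype=float)
    if initial is None:
        initial = glv.default_initial_state(model)
    sim = glv.simulate(model, initial, times=times).abundance
    rng = np.random.default_rng(seed)
    if noise == "none":
        obs = sim.copy()
    elif noise == "lognormal":
        obs = sim * np.exp(rng.normal(0.0, sigma, size=sim.shape))
    elif noise == "plate-count":
        from probisim.efficacy import cfu_from_counts

        obs = np.empty_like(sim)
        for idx, density in np.ndenumerate(sim):
            counts = gen_plate_counts(
                density,
                dilution_levels=dilution_levels,
                plated_volume=plated_volume,
                replicates=plate_replicates,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            est = cfu_from_counts(counts)
            obs[idx] = 10.0 ** est.log10_cfu if est.countable else np.nan
    else:
        raise SynthError(f"unknown noise model {noise!r}")
    it = model.interactions
    return CocultureDataset(
        times=times,
        observed=obs,
        ids=model.ids,
        guilds=model.guilds,
        noise={"model": noise, "sigma": sigma if noise == "lognormal" else None, "seed": seed},
        truth={
            "alpha": it.alpha.tolist(),
            "beta": it.beta.tolist(),
            "gamma": it.gamma.tolist(),
            "delta": it.delta.tolist(),
            "r": [s.r for s in model.strains],
            "K": [s.K for s in model.strains],
        },
    )


# ---------------------------------------------------------------------------
# Plate counts
# ---------------------------------------------------------------------------

def gen_plate_counts(
    true_density: float,
    dilution_levels: Sequence[float] | None = None,
    plated_volume: float = 0.05,
    replicates: int = 2,
    seed: int = 0,
) -> list[PlateCount]:
    """Poisson plate counts across a ten-fold dilution series.

    Colony counts are Poisson with mean density * volume / dilution.  When
    ``dilution_levels`` is omitted, a bracket of three ten-fold levels around
    the level giving ~50 expected colonies is used.
    """
    if true_density < 0:
        raise SynthError("density must be >= 0")
    if dilution_levels is None:
        if true_density > 0:
            center = 10.0 ** round(np.log10(max(true_density * plated_volume / 50.0, 1.0)))
        else:
            center = 1.0
        dilution_levels = [max(center / 10, 1.0), center, center * 10]
    rng = np.random.default_rng(seed)
    out = []
    for dil in dilution_levels:
        mean = true_density * plated_volume / dil
        for rep in range(replicates):
            out.append(
                PlateCount(
                    colonies=int(rng.poisson(mean)),
                    dilution_factor=float(dil),
                    plated_volume=plated_volume,
                    replicate=f"rep{rep + 1}",
                )
            )
    return out


# ---------------------------------------------------------------------------
# Storage-viability curves
# ---------------------------------------------------------------------------

@dataclass
class StorageDecayParams:
    """Per-temperature storage-viability profile (log10 CFU/mL).

    Frozen (-20 C) and refrigerated (4 C) storage decline log-linearly; the
    ambient (24 C) profile is biphasic: rise to a peak at ``peak_day``,
    plateau to ``decline_start_day``, then linear decline.  Default total
    declines at day 365 are 0.46 / 0.89 / 4.51 log10 for -20 / 4 / 24 C.
    """

    initial_log10: float = 7.9
    decline_minus20: float = 0.46   # total log10 decline at day 365
    decline_4c: float = 0.89
    decline_24c: float = 4.51
    rise_24c: float = 0.30          # ambient growth phase amplitude
    peak_day: int = 7
    decline_start_day: int = 10
    noise_sd: float = 0.05
    seed: int = 0
    horizon_day: int = 365

    def __post_init__(self) -> None:
        if min(self.decline_minus20, self.decline_4c, self.decline_24c) < 0:
            raise SynthError("decline rates must be >= 0")
        if not self.peak_day < self.decline_start_day:
            raise SynthError("peak day must precede the decline onset day")
        if self.noise_sd < 0:
            raise SynthError("noise SD must be >= 0")


def storage_mean_curve(params: StorageDecayParams, temperature: str, days: np.ndarray) -> np.ndarray:
    """Deterministic mean log10 CFU/mL for one storage temperature."""
    L0 = params.initial_log10
    T = params.horizon_day
    days = np.asarray(days, dtype=float)
    if temperature in ("-20C", "4C"):
        total = params.decline_minus20 if temperature == "-20C" else params.decline_4c
        return L0 - total * days / T
    if temperature == "24C":
        peak = L0 + params.rise_24c
        anchors_d = np.array([0.0, params.peak_day, params.decline_start_day, float(T)])
        anchors_v = np.array([L0, peak, peak, L0 - params.decline_24c])
        return np.interp(days, anchors_d, anchors_v)
    raise SynthError(f"unknown temperature {temperature!r} (use '-20C', '4C', '24C')")


def gen_storage_curves(
    params: StorageDecayParams | None = None,
    days: Sequence[float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Table of log10 CFU/mL per temperature per day (mean curve + Gaussian noise)."""
    params = params or StorageDecayParams()
    if days is None:
        days = np.array([0, 1, 3, 7, 10, 14, 30, 60, 90, 180, 270, 365], dtype=float)
    days = np.asarray(days, dtype=float)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rows = []
    for temp in ("-20C", "4C", "24C"):
        mean = storage_mean_curve(params, temp, days)
        noisy = mean + rng.normal(0.0, params.noise_sd, size=mean.shape)
        for d, v in zip(days, noisy):
            rows.append({"day": d, "temperature": temp, "log10_cfu_ml": v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Surface-survival curves
# ---------------------------------------------------------------------------

@dataclass
class SurfaceSurvivalParams:
    """Survival of the applied probiotic film on a surface (log10 CFU/cm^2).

    The default anchors encode a 24 h colonization rise followed by a
    monotone decline that stays above the 5-log10 protective floor through
    day 30: 7.07 (day 0), 7.18 (day 1), 6.65 (day 7), 6.05 (day 14),
    5.48 (day 30).
    """

    anchors: dict = field(default_factory=lambda: {0: 7.07, 1: 7.18, 7: 6.65, 14: 6.05, 30: 5.48})
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SynthError("noise SD must be >= 0")
        if not all(np.isfinite(list(self.anchors.values()))):
            raise SynthError("anchor levels must be finite")


def surface_mean_curve(params: SurfaceSurvivalParams, days: np.ndarray) -> np.ndarray:
    d = np.array(sorted(params.anchors), dtype=float)
    v = np.array([params.anchors[k] for k in sorted(params.anchors)], dtype=float)
    return np.interp(np.asarray(days, dtype=float), d, v)


def gen_surface_survival(
    params: SurfaceSurvivalParams | None = None,
    days: Sequence[float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Daily surface-survival table (log10 CFU/cm^2), day 0 through day 30."""
    params = params or SurfaceSurvivalParams()
    if days is None:
        days = np.arange(0, 31, dtype=float)
    days = np.asarray(days, dtype=float)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    mean = surface_mean_curve(params, days)
    noisy = mean + rng.normal(0.0, params.noise_sd, size=mean.shape)
    return pd.DataFrame({"day": days, "log10_cfu_cm2": noisy})


# ---------------------------------------------------------------------------
# Inhibition-zone tables
# ---------------------------------------------------------------------------

def gen_zone_table(
    n: int,
    mean_mm: float = 13.84,
    sd_mm: float = 1.23,
    bactericidal_probability: float = 0.349,
    seed: int = 0,
) -> list[ZoneRecord]:
    """Random zone table: integer-rounded Gaussian diameters, Bernoulli kills."""
    if n < 1:
        raise SynthError("n must be >= 1")
    if sd_mm < 0 or not (0.0 <= bactericidal_probability <= 1.0):
        raise SynthError("invalid sd or probability")
    rng = np.random.default_rng(seed)
    diameters = np.maximum(np.rint(rng.normal(mean_mm, sd_mm, size=n)), 0.0)
    killed = rng.random(n) < bactericidal_probability
    return [
        ZoneRecord(f"strain_{i + 1}", float(d), "Negative" if k else "Positive")
        for i, (d, k) in enumerate(zip(diameters, killed))
    ]


#: Bundled reference inhibition-zone dataset: 43 pathogenic strains, diameter
#: in mm and subculture outcome (Negative = bactericidal, no regrowth).
REFERENCE_ZONE_TABLE: tuple[tuple[str, int, str], ...] = (
    ("Micrococcus luteus strain T-18", 15, "Positive"),
    ("Streptococcus pyogenes strain FF22", 14, "Positive"),
    ("S. anginosus strain T-29", 13, "Negative"),
    ("S. pyogenes strain 70-679", 15, "Negative"),
    ("S. uberis strain T-6", 14, "Negative"),
    ("S. pyogenes strain 71-679", 15, "Positive"),
    ("S. pyogenes strain 71-698", 16, "Positive"),
    ("S. pyogenes strain W-1", 14, "Negative"),
    ("S. equisimilis strain T-148", 15, "Negative"),
    ("Enterococcus faecalis strain 96", 16, "Positive"),
    ("E. faecalis strain 97", 13, "Negative"),
    ("E. faecalis strain 98", 12, "Positive"),
    ("S. dysgalactiae strain 60", 14, "Positive"),
    ("S. dysgalactiae strain 61", 15, "Positive"),
    ("S. dysgalactiae strain 62", 16, "Positive"),
    ("S. agalactiae strain 76", 16, "Positive"),
    ("S. agalactiae strain 77", 14, "Positive"),
    ("S. agalactiae strain 78", 15, "Positive"),
    ("Enterococcus faecalis strain E024", 14, "Positive"),
    ("E. faecalis strain C2", 13, "Negative"),
    ("E. faecalis strain K13b", 13, "Positive"),
    ("Enterococcus faecium strain TE1", 12, "Positive"),
    ("E. faecium strain A10", 14, "Negative"),
    ("E. faecium strain 5A9", 13, "Positive"),
    ("E. faecalis strain JM95", 13, "Positive"),
    ("E. faecalis strain JM101", 12, "Positive"),
    ("E. faecalis strain JM112", 13, "Positive"),
    ("Salmonella enterica serovar Typhi isolate 1", 15, "Positive"),
    ("Salmonella enterica serovar Typhi isolate 2", 13, "Negative"),
    ("Escherichia coli O157 isolate 1", 14, "Positive"),
    ("Enteropathogenic E. coli isolate 1", 12, "Positive"),
    ("Enteroaggregative E. coli isolate 1", 12, "Positive"),
    ("Campylobacter jejuni isolate 1", 13, "Positive"),
    ("Listeria monocytogenes isolate 1", 14, "Negative"),
    ("Methicillin-resistant Staphylococcus aureus isolate 1", 16, "Positive"),
    ("Methicillin-resistant Staphylococcus aureus isolate 2", 15, "Negative"),
    ("Methicillin-resistant Staphylococcus aureus isolate 3", 14, "Positive"),
    ("Shigella dysenteriae isolate 1", 14, "Positive"),
    ("Shigella flexneri isolate 1", 13, "Positive"),
    ("Vibrio cholerae isolate 1", 13, "Negative"),
    ("Vibrio parahaemolyticus isolate 1", 13, "Negative"),
    ("Carbapenem-resistant Pseudomonas aeruginosa isolate 1", 12, "Negative"),
    ("Carbapenem-resistant Pseudomonas aeruginosa isolate 2", 13, "Negative"),
)


def reference_zone_table() -> list[ZoneRecord]:
    """The bundled 43-strain spot-assay reference table as ZoneRecords."""
    return [ZoneRecord(s, float(d), r) for s, d, r in REFERENCE_ZONE_TABLE]


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def write_manifest(path, generator: str, params: dict, seed: int | None) -> None:
    """JSON sidecar recording generator name, parameters and seed."""
    Path(path).write_text(
        json.dumps(
            {
                "generator": generator,
                "version": GENERATOR_VERSION,
                "params": params,
                "seed": seed,
            },
            indent=2,
            default=str,
        )
    )
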