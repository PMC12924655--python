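"""Disinfection-trial arithmetic and statistics.

CFU enumeration from serial-dilution plate counts, log/percentage reduction,
two-sample comparisons, inhibition-zone summaries, bactericidal
classification, and formulation concentration math.

Conventions: sample (n-1) standard deviations throughout; pooled-variance
Student's t by default (Welch behind a flag); colony counts in the closed
countable window [30, 100] are used for enumeration; rounding happens only
in the reporting helpers, never in the arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Closed countable colony window for plate enumeration.
COUNTABLE_WINDOW = (30, 100)

#: Default plated volume in mL (50 uL aliquots).
DEFAULT_PLATED_VOLUME = 0.05

SIGNIFICANCE_LEVEL = 0.05


class EfficacyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateCount:
    """One plate: colony count, ten-fold dilution factor, plated volume (mL)."""

    colonies: int
    dilution_factor: float
    plated_volume: float = DEFAULT_PLATED_VOLUME
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise EfficacyError("colonies must be >= 0")
        if self.dilution_factor < 1:
            raise EfficacyError("dilution_factor must be >= 1")
        if self.plated_volume <= 0:
            raise EfficacyError("plated_volume must be > 0")


@dataclass(frozen=True)
class ZoneRecord:
    """Inhibition-zone record: strain, diameter (mm), subculture outcome."""

    strain: str
    diameter_mm: float
    subculture: str  # "Positive" (regrowth) or "Negative" (bactericidal)

    def __post_init__(self) -> None:
        if self.diameter_mm < 0:
            raise EfficacyError("diameter must be >= 0")
        if self.subculture not in ("Positive", "Negative"):
            raise EfficacyError(f"subculture must be Positive/Negative, got {self.subculture!r}")


@dataclass
class CfuEstimate:
    """Result of plate enumeration: log10 CFU/mL or an explicit uncountable flag."""

    log10_cfu: float | None
    countable: bool
    dilutions_used: list[float] = field(default_factory=list)
    plates_used: int = 0
    plates_rejected: int = 0


@dataclass
class TTestResult:
    t: float
    p: float
    significant: bool
    n_a: int
    n_b: int
    welch: bool = False


@dataclass
class ZoneSummary:
    n: int
    mean_mm: float
    sd_mm: float

    def render(self) -> str:
        return f"{self.mean_mm:.2f} ± {self.sd_mm:.2f} (n = {self.n})"


# ---------------------------------------------------------------------------
# CFU enumeration
# ---------------------------------------------------------------------------

def cfu_from_counts(
    counts: Sequence[PlateCount],
    window: tuple[int, int] = COUNTABLE_WINDOW,
) -> CfuEstimate:
    """Estimate log10 CFU/mL from serial-dilution plate counts.

    Only plates with colony counts in the closed countable window are used.
    Replicates at the same dilution are averaged; density for a dilution
    level is mean_count / plated_volume * dilution_factor.  When several
    dilution levels are countable their log10 densities are averaged.  If no
    plate is countable the result is flagged, never extrapolated.
    """
    if not counts:
        raise EfficacyError("at least one plate count is required")
    lo, hi = window
    valid = [c for c in counts if lo <= c.colonies <= hi]
    rejected = len(counts) - len(valid)
    if not valid:
        return CfuEstimate(
            log10_cfu=None, countable=False, plates_used=0, plates_rejected=rejected
        )
    by_dilution: dict[tuple[float, float], list[int]] = {}
    for c in valid:
        by_dilution.setdefault((c.dilution_factor, c.plated_volume), []).append(c.colonies)
    logs = []
    for (dil, vol), cols in sorted(by_dilution.items()):
        density = (sum(cols) / len(cols)) / vol * dil
        logs.append(math.log10(density))
    return CfuEstimate(
        log10_cfu=float(np.mean(logs)),
        countable=True,
        dilutions_used=sorted({d for d, _ in by_dilution}),
        plates_used=len(valid),
        plates_rejected=rejected,
    )


# ---------------------------------------------------------------------------
# Reductions
# ---------------------------------------------------------------------------

def log_reduction(control, treated):
    """LR = control - treated on the log10 scale; negative values = growth."""
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if not (np.all(np.isfinite(control)) and np.all(np.isfinite(treated))):
        raise EfficacyError("log_reduction requires finite inputs")
    out = control - treated
    return float(out) if out.ndim == 0 else out


def percent_reduction(lr):
    """PR = (1 - 10^-LR) * 100, exact; rounding is a reporting concern."""
    lr = np.asarray(lr, dtype=float)
    if not np.all(np.isfinite(lr)):
        raise EfficacyError("percent_reduction requires finite LR")
    out = (1.0 - 10.0 ** (-lr)) * 100.0
    return float(out) if out.ndim == 0 else out


def summarize_reductions(replicate_lrs: Sequence[float]) -> dict:
    """Mean +/- sample SD over replicate log reductions, plus PR of the mean."""
    arr = np.asarray(replicate_lrs, dtype=float)
    if arr.size < 1:
        raise EfficacyError("need at least one replicate")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {
        "n": int(arr.size),
        "mean_lr": mean,
        "sd_lr": sd,
        "percent_reduction": percent_reduction(mean),
    }


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = SIGNIFICANCE_LEVEL,
    welch: bool = False,
) -> TTestResult:
    """Unpaired two-tailed Student's t-test (pooled variance by default).

    Two identical zero-variance groups return t=0, p=1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EfficacyError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return TTestResult(t=0.0, p=1.0, significant=False, n_a=a.size, n_b=b.size, welch=welch)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(
        t=float(t), p=float(p), significant=bool(p < alpha), n_a=a.size, n_b=b.size, welch=welch
    )


# ---------------------------------------------------------------------------
# Inhibition zones
# ---------------------------------------------------------------------------

def summarize_zones(table: Sequence[ZoneRecord]) -> ZoneSummary:
    """n, arithmetic mean and sample (n-1) SD of zone diameters."""
    if len(table) < 2:
        raise EfficacyError("need at least two zone records for an SD")
    d = np.array([z.diameter_mm for z in table], dtype=float)
    return ZoneSummary(n=d.size, mean_mm=float(d.mean()), sd_mm=float(d.std(ddof=1)))


def bactericidal_fraction(table: Sequence[ZoneRecord]) -> float:
    """Percent of strains with a Negative subculture (no regrowth = killed)."""
    if not table:
        raise EfficacyError("empty zone table")
    neg = sum(1 for z in table if z.subculture == "Negative")
    return 100.0 * neg / len(table)


def zones_to_frame(table: Sequence[ZoneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain": [z.strain for z in table],
            "diameter_mm": [z.diameter_mm for z in table],
            "subculture": [z.subculture for z in table],
        }
    )


def zones_from_frame(df: pd.DataFrame) -> list[ZoneRecord]:
    return [
        ZoneRecord(str(r.strain), float(r.diameter_mm), str(r.subculture))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Formulation arithmetic
# ---------------------------------------------------------------------------

def slurry_concentration(load_cfu_per_g: float, mass_g: float, volume_ml: float) -> float:
    """CFU/mL of a slurry from its gravimetric load: load * mass / volume."""
    if load_cfu_per_g <= 0 or mass_g <= 0 or volume_ml <= 0:
        raise EfficacyError("slurry_concentration requires positive inputs")
    return load_cfu_per_g * mass_g / volume_ml


def mix_concentration(conc_cfu_per_ml: float, ratio_part_a: float, ratio_part_b: float) -> float:
    """Blend concentration when part A (at conc) is mixed a:b with sterile part B."""
    if ratio_part_a < 0 or ratio_part_b < 0 or (ratio_part_a + ratio_part_b) == 0:
        raise EfficacyError("mix ratios must be non-negative with positive total")
    return conc_cfu_per_ml * ratio_part_a / (ratio_part_a + ratio_part_b)
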