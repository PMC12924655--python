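"""Generalized Lotka-Volterra (gLV) probiotic-pathogen community model.

Two guilds of strains are coupled through four interaction families.  With
probiotics indexed i, j and pathogens indexed k, m:

    dP_i/dt = r_i * P_i * (1 - sum_j alpha_ij * P_j / K_i)
              - sum_k beta_ik * P_i * (P_k / N_ref)
    dP_k/dt = r_k * P_k * (1 - sum_m gamma_km * P_m / K_k)
              - sum_i delta_ki * P_k * (P_i / N_ref)

alpha and gamma are intra-guild (dimensionless) competition matrices with a
unit diagonal so the self-term reduces to logistic self-limitation; beta is
the cost that pathogens impose on probiotics and delta the probiotic-driven
pathogen kill.  Cross-guild terms act on densities normalized by a reference
density ``N_ref`` (default 1e8 CFU/unit) so that the conventional coefficient
scale [0, 2] per hour is dimensionally meaningful at CFU-scale abundances.

The module integrates the system with a stiff-capable adaptive solver,
extracts per-pathogen extinction times, calibrates the single-strain fixture
by bisection on delta, and runs the single-strain versus consortium
comparison experiment.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

logger = logging.getLogger(__name__)

# Admissible coefficient ranges enforced by strict-range validation.
GROWTH_RATE_RANGE = (0.05, 1.5)       # per hour
COMPETITION_RANGE = (-1.0, 1.0)       # alpha, gamma (dimensionless)
ANTAGONISM_RANGE = (0.0, 2.0)         # beta, delta (per hour per N_ref)

#: Reference density normalizing the cross-guild interaction terms (CFU/unit).
REFERENCE_DENSITY = 1e8

#: Default integration horizons in hours by model mode.
DEFAULT_HORIZON = {"liquid": 48.0, "surface": 504.0}

#: Default extinction threshold: 1 CFU per unit (CFU/mL liquid, CFU/cm^2 surface).
EXTINCTION_THRESHOLD = 1.0

#: Populations below this are clamped to zero after integration to prevent
#: revival from numerical dust.
NUMERICAL_FLOOR = 1e-6

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-3

GUILDS = ("probiotic", "pathogen")


class GLVError(ValueError):
    """Model construction or integration error."""


class CalibrationError(RuntimeError):
    """Bisection target unattainable within the supplied delta bounds."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrainSpec:
    """One strain: short id, guild, growth rate r (1/h), carrying capacity K."""

    id: str
    guild: str
    r: float
    K: float

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise GLVError(f"guild must be one of {GUILDS}, got {self.guild!r}")
        if not np.isfinite(self.r) or not np.isfinite(self.K):
            raise GLVError(f"non-finite parameter for strain {self.id!r}")
        if self.K <= 0:
            raise GLVError(f"K must be > 0 for strain {self.id!r}")


@dataclass
class InteractionSet:
    """The four interaction matrices.

    alpha : (n_prob, n_prob) probiotic-probiotic competition, dimensionless
    gamma : (n_path, n_path) pathogen-pathogen competition, dimensionless
    beta  : (n_prob, n_path) pathogen-on-probiotic loss, 1/h per N_ref
    delta : (n_path, n_prob) probiotic-on-pathogen loss, 1/h per N_ref
    """

    alpha: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)


@dataclass
class CommunityModel:
    """Ordered strain list plus interactions; mode sets K units and horizon."""

    strains: list[StrainSpec]
    interactions: InteractionSet
    mode: str = "liquid"
    horizon: float | None = None
    reference_density: float = REFERENCE_DENSITY

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.strains]

    @property
    def guilds(self) -> list[str]:
        return [s.guild for s in self.strains]

    @property
    def probiotic_idx(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.strains) if s.guild == "probiotic"], dtype=int)

    @property
    def pathogen_idx(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.strains) if s.guild == "pathogen"], dtype=int)

    @property
    def default_horizon(self) -> float:
        return self.horizon if self.horizon is not None else DEFAULT_HORIZON[self.mode]


@dataclass
class Trajectory:
    """Time grid (hours) x strain-abundance matrix (CFU/unit)."""

    times: np.ndarray
    abundance: np.ndarray  # shape (n_times, n_strains)
    model: CommunityModel

    def column(self, strain_id: str) -> np.ndarray:
        return self.abundance[:, self.model.ids.index(strain_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.abundance, columns=self.model.ids)
        df.insert(0, "time_h", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model: CommunityModel) -> "Trajectory":
        df = pd.read_csv(path)
        times = df["time_h"].to_numpy(float)
        abundance = df[model.ids].to_numpy(float)
        return cls(times=times, abundance=abundance, model=model)


@dataclass
class ExtinctionReport:
    """Per-pathogen extinction time (hours) or None if not extinct in-horizon."""

    times: dict[str, float | None]
    threshold: float
    horizon: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "threshold": self.threshold,
                "horizon_h": self.horizon,
                "extinction_time_h": {
                    k: (None if v is None else float(v)) for k, v in self.times.items()
                },
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def _check_range(name: str, values: np.ndarray, lo: float, hi: float, strict: bool) -> None:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise GLVError(f"non-finite entries in {name}")
    if arr.size and (arr.min() < lo or arr.max() > hi):
        msg = f"{name} outside admissible range [{lo}, {hi}]: min={arr.min()}, max={arr.max()}"
        if strict:
            raise GLVError(msg)
        logger.warning("range relaxation accepted: %s", msg)


def build_model(
    strains: Sequence[StrainSpec],
    interactions: InteractionSet,
    mode: str = "liquid",
    strict_ranges: bool = True,
    horizon: float | None = None,
    reference_density: float = REFERENCE_DENSITY,
) -> CommunityModel:
    """Validate shapes/ranges and assemble a :class:`CommunityModel`.

    With ``strict_ranges`` on, parameters outside the admissible ranges raise
    :class:`GLVError`; off, they are accepted with a logged warning.
    """
    strains = list(strains)
    if not strains:
        raise GLVError("at least one strain is required")
    if mode not in DEFAULT_HORIZON:
        raise GLVError(f"mode must be 'liquid' or 'surface', got {mode!r}")
    n_prob = sum(1 for s in strains if s.guild == "probiotic")
    n_path = sum(1 for s in strains if s.guild == "pathogen")
    it = interactions
    shapes = {
        "alpha": (it.alpha, (n_prob, n_prob)),
        "gamma": (it.gamma, (n_path, n_path)),
        "beta": (it.beta, (n_prob, n_path)),
        "delta": (it.delta, (n_path, n_prob)),
    }
    for name, (arr, want) in shapes.items():
        if arr.shape != want:
            raise GLVError(f"{name} has shape {arr.shape}, expected {want}")
    for name, arr in (("alpha", it.alpha), ("gamma", it.gamma)):
        if arr.size and not np.allclose(np.diag(arr), 1.0, atol=1e-12):
            raise GLVError(f"{name} diagonal must be 1 (logistic self-limitation convention)")
    _check_range("alpha", it.alpha, *COMPETITION_RANGE, strict=strict_ranges)
    _check_range("gamma", it.gamma, *COMPETITION_RANGE, strict=strict_ranges)
    _check_range("beta", it.beta, *ANTAGONISM_RANGE, strict=strict_ranges)
    _check_range("delta", it.delta, *ANTAGONISM_RANGE, strict=strict_ranges)
    for s in strains:
        lo, hi = GROWTH_RATE_RANGE
        if not (lo <= s.r <= hi):
            msg = f"growth rate r={s.r} of {s.id!r} outside [{lo}, {hi}]"
            if strict_ranges:
                raise GLVError(msg)
            logger.warning("range relaxation accepted: %s", msg)
    return CommunityModel(
        strains=strains,
        interactions=interactions,
        mode=mode,
        horizon=horizon,
        reference_density=reference_density,
    )


def model_to_json(model: CommunityModel) -> str:
    it = model.interactions
    return json.dumps(
        {
            "strains": [
                {"id": s.id, "guild": s.guild, "r": s.r, "K": s.K} for s in model.strains
            ],
            "interactions": {
                "alpha": it.alpha.tolist(),
                "gamma": it.gamma.tolist(),
                "beta": it.beta.tolist(),
                "delta": it.delta.tolist(),
            },
            "mode": model.mode,
            "horizon_h": model.horizon,
            "reference_density": model.reference_density,
        },
        indent=2,
    )


def model_from_json(text: str, strict_ranges: bool = True) -> CommunityModel:
    cfg = json.loads(text)
    strains = [StrainSpec(**s) for s in cfg["strains"]]
    it = InteractionSet(**{k: np.asarray(v, float) for k, v in cfg["interactions"].items()})
    return build_model(
        strains,
        it,
        mode=cfg.get("mode", "liquid"),
        strict_ranges=strict_ranges,
        horizon=cfg.get("horizon_h"),
        reference_density=cfg.get("reference_density", REFERENCE_DENSITY),
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _rhs_factory(model: CommunityModel):
    ip = model.probiotic_idx
    ik = model.pathogen_idx
    r = np.array([s.r for s in model.strains])
    K = np.array([s.K for s in model.strains])
    it = model.interactions
    nref = model.reference_density

    def rhs(t: float, P: np.ndarray) -> np.ndarray:
        P = np.maximum(P, 0.0)
        prob = P[ip]
        path = P[ik]
        dP = np.zeros_like(P)
        if ip.size:
            comp = it.alpha @ prob
            loss = (it.beta @ path) / nref if ik.size else 0.0
            dP[ip] = r[ip] * prob * (1.0 - comp / K[ip]) - loss * prob
        if ik.size:
            comp = it.gamma @ path
            kill = (it.delta @ prob) / nref if ip.size else 0.0
            dP[ik] = r[ik] * path * (1.0 - comp / K[ik]) - kill * path
        return dP

    return rhs


def simulate(
    model: CommunityModel,
    initial: Sequence[float],
    horizon: float | None = None,
    output_step: float = 0.1,
    times: Sequence[float] | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the gLV system on a uniform output grid.

    Pass ``times`` (strictly increasing, starting at >= 0) to evaluate on an
    explicit grid instead of the uniform ``output_step`` one.  Populations
    are clamped at zero whenever integration crosses below the numerical
    floor.  Tolerances are configurable; defaults rtol=1e-8, atol=1e-3 CFU.
    """
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (len(model.strains),):
        raise GLVError(f"initial state length {y0.size} != strain count {len(model.strains)}")
    if np.any(y0 < 0):
        raise GLVError("negative initial state")
    if times is not None:
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0) or times[0] < 0:
            raise GLVError("times must be a strictly increasing 1-D grid starting at >= 0")
        T = float(times[-1])
    else:
        T = float(horizon if horizon is not None else model.default_horizon)
        if T <= 0:
            raise GLVError("horizon must be > 0")
        n_out = int(round(T / output_step))
        times = np.linspace(0.0, T, n_out + 1)
    sol = solve_ivp(
        _rhs_factory(model),
        (0.0, T),
        y0,
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise GLVError(f"integrator failure: {sol.message} (t reached {sol.t[-1] if sol.t.size else 0})")
    ab = sol.y.T.copy()
    ab[ab < NUMERICAL_FLOOR] = 0.0
    if times[0] == 0.0:
        ab[0, :] = y0
    return Trajectory(times=times, abundance=ab, model=model)


# ---------------------------------------------------------------------------
# Extinction diagnostics
# ---------------------------------------------------------------------------

def time_to_extinction(
    traj: Trajectory, threshold: float = EXTINCTION_THRESHOLD
) -> ExtinctionReport:
    """Earliest time each pathogen falls below ``threshold`` for good.

    The crossing is linearly interpolated between output points; a pathogen
    that re-exceeds the threshold later in the horizon is not extinct at the
    earlier dip.
    """
    if threshold <= 0:
        raise GLVError("threshold must be > 0")
    ik = traj.model.pathogen_idx
    if ik.size == 0:
        raise GLVError("trajectory contains no pathogen strains")
    out: dict[str, float | None] = {}
    t = traj.times
    for idx in ik:
        x = traj.abundance[:, idx]
        sid = traj.model.strains[idx].id
        if x[0] < threshold:
            out[sid] = 0.0
            continue
        above = np.nonzero(x >= threshold)[0]
        last_above = above[-1]
        if last_above == len(t) - 1:
            out[sid] = None  # not extinct within horizon
            continue
        j = last_above
        x0, x1 = x[j], x[j + 1]
        frac = (x0 - threshold) / (x0 - x1) if x0 != x1 else 1.0
        out[sid] = float(t[j] + frac * (t[j + 1] - t[j]))
    return ExtinctionReport(times=out, threshold=threshold, horizon=float(t[-1]))


# ---------------------------------------------------------------------------
# Default single-strain fixture and calibration
# ---------------------------------------------------------------------------

#: Default single probiotic / single pathogen fixture.  Inocula follow the
#: standardized densities used for probiotic (5e9 CFU/mL) and indicator
#: pathogen (1.5e8 CFU/mL) suspensions; delta is left for calibration.
SINGLE_STRAIN_FIXTURE = {
    "r_probiotic": 0.8,
    "r_pathogen": 0.6,
    "K": 1e9,
    "beta": 0.05,
    "inoculum_probiotic": 5e9,
    "inoculum_pathogen": 1.5e8,
}


def default_single_strain_model(delta: float, fixture: dict | None = None) -> CommunityModel:
    """One probiotic + one pathogen with the default fixture parameters."""
    fx = dict(SINGLE_STRAIN_FIXTURE)
    if fixture:
        fx.update(fixture)
    strains = [
        StrainSpec("probiotic_1", "probiotic", fx["r_probiotic"], fx["K"]),
        StrainSpec("pathogen_1", "pathogen", fx["r_pathogen"], fx["K"]),
    ]
    it = InteractionSet(
        alpha=np.array([[1.0]]),
        gamma=np.array([[1.0]]),
        beta=np.array([[fx["beta"]]]),
        delta=np.array([[delta]]),
    )
    return build_model(strains, it, mode="liquid")


def default_initial_state(model: CommunityModel, fixture: dict | None = None) -> np.ndarray:
    fx = dict(SINGLE_STRAIN_FIXTURE)
    if fixture:
        fx.update(fixture)
    y0 = np.empty(len(model.strains))
    for i, s in enumerate(model.strains):
        y0[i] = fx["inoculum_probiotic"] if s.guild == "probiotic" else fx["inoculum_pathogen"]
    return y0


def _extinction_time_for_delta(
    delta: float,
    fixture: dict | None,
    threshold: float,
    output_step: float,
    horizon: float,
) -> float | None:
    model = default_single_strain_model(delta, fixture)
    y0 = default_initial_state(model, fixture)
    traj = simulate(model, y0, horizon=horizon, output_step=output_step)
    return time_to_extinction(traj, threshold).times["pathogen_1"]


@dataclass
class CalibrationResult:
    model: CommunityModel
    delta: float
    extinction_time: float
    target_time: float
    iterations: int


def calibrate_single_strain(
    target_time: float,
    fixture: dict | None = None,
    search_bounds: tuple[float, float] = ANTAGONISM_RANGE,
    tolerance: float = 0.05,
    threshold: float = EXTINCTION_THRESHOLD,
    output_step: float = 0.02,
    horizon: float = 48.0,
    max_iter: int = 80,
) -> CalibrationResult:
    """Bisect the probiotic-on-pathogen delta to hit a target extinction time.

    Extinction time is strictly decreasing in delta, so plain bisection on
    [lo, hi] converges; the search stops when the simulated time is within
    ``tolerance`` hours (default 0.05 h) of the target.
    """
    lo, hi = search_bounds
    t_hi = _extinction_time_for_delta(hi, fixture, threshold, output_step, horizon)
    if t_hi is None or t_hi > target_time + tolerance:
        raise CalibrationError(
            f"target {target_time} h unattainable: extinction at delta={hi} is "
            f"{t_hi if t_hi is not None else 'absent'} (bracket [{lo}, {hi}])"
        )
    t_lo = _extinction_time_for_delta(lo, fixture, threshold, output_step, horizon)
    if t_lo is not None and t_lo < target_time - tolerance:
        raise CalibrationError(
            f"target {target_time} h unattainable: extinction at delta={lo} is already "
            f"{t_lo} h (bracket [{lo}, {hi}])"
        )
    delta = hi
    t_cur = t_hi
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        t_mid = _extinction_time_for_delta(mid, fixture, threshold, output_step, horizon)
        if t_mid is not None and abs(t_mid - target_time) <= tolerance:
            delta, t_cur = mid, t_mid
            break
        if t_mid is None or t_mid > target_time:
            lo = mid  # too slow, need more kill
        else:
            hi = mid
        delta, t_cur = mid, t_mid
    else:
        raise CalibrationError(
            f"bisection did not reach |t - {target_time}| <= {tolerance} within {max_iter} "
            f"iterations (last delta={delta}, t={t_cur})"
        )
    return CalibrationResult(
        model=default_single_strain_model(delta, fixture),
        delta=float(delta),
        extinction_time=float(t_cur),
        target_time=float(target_time),
        iterations=it,
    )


# ---------------------------------------------------------------------------
# Consortium experiment
# ---------------------------------------------------------------------------

@dataclass
class ConsortiumReport:
    baseline_time: float | None
    consortium_time: float | None
    ratio: float | None
    n_strains: int
    consortium_model: CommunityModel

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_strains": self.n_strains,
                "baseline_extinction_h": self.baseline_time,
                "consortium_extinction_h": self.consortium_time,
                "ratio": self.ratio,
            },
            indent=2,
        )


def expand_consortium(
    baseline: CommunityModel,
    n_strains: int,
    delta_table: Sequence[float] | None = None,
) -> CommunityModel:
    """Replicate the single baseline probiotic ``n_strains`` times.

    The probiotic strains are mutually non-competing (alpha = identity),
    mirroring physical compartmentalization of strains in separate carrier
    beads; each copy gets its delta from ``delta_table`` (default: the
    baseline delta replicated, an equal-ratio blend of identical strains).
    """
    if n_strains < 1:
        raise GLVError("n_strains must be >= 1")
    ip = baseline.probiotic_idx
    ik = baseline.pathogen_idx
    if ip.size != 1 or ik.size != 1:
        raise GLVError("consortium expansion expects a 1-probiotic/1-pathogen baseline")
    prob = baseline.strains[ip[0]]
    path = baseline.strains[ik[0]]
    base_delta = float(baseline.interactions.delta[0, 0])
    base_beta = float(baseline.interactions.beta[0, 0])
    if delta_table is None:
        delta_table = [base_delta] * n_strains
    if len(delta_table) < n_strains:
        raise GLVError("delta_table shorter than n_strains")
    strains = [
        StrainSpec(f"probiotic_{i + 1}", "probiotic", prob.r, prob.K) for i in range(n_strains)
    ] + [path]
    it = InteractionSet(
        alpha=np.eye(n_strains),
        gamma=np.array([[1.0]]),
        beta=np.full((n_strains, 1), base_beta),
        delta=np.array([list(delta_table[:n_strains])]),
    )
    return build_model(
        strains, it, mode=baseline.mode, reference_density=baseline.reference_density
    )


def consortium_experiment(
    baseline: CommunityModel,
    n_strains: int,
    per_strain_inoculum: float = SINGLE_STRAIN_FIXTURE["inoculum_probiotic"],
    pathogen_inoculum: float = SINGLE_STRAIN_FIXTURE["inoculum_pathogen"],
    delta_table: Sequence[float] | None = None,
    threshold: float = EXTINCTION_THRESHOLD,
    output_step: float = 0.02,
    horizon: float = 48.0,
) -> ConsortiumReport:
    """Compare pathogen extinction of the baseline against an n-strain consortium."""
    y0_base = np.array(
        [per_strain_inoculum if s.guild == "probiotic" else pathogen_inoculum
         for s in baseline.strains]
    )
    t_base = time_to_extinction(
        simulate(baseline, y0_base, horizon=horizon, output_step=output_step), threshold
    ).times[baseline.strains[baseline.pathogen_idx[0]].id]

    consortium = expand_consortium(baseline, n_strains, delta_table)
    y0 = np.array(
        [per_strain_inoculum if s.guild == "probiotic" else pathogen_inoculum
         for s in consortium.strains]
    )
    t_cons = time_to_extinction(
        simulate(consortium, y0, horizon=horizon, output_step=output_step), threshold
    ).times[consortium.strains[consortium.pathogen_idx[0]].id]

    ratio = None
    if t_base is not None and t_cons is not None and t_base > 0:
        ratio = t_cons / t_base
    return ConsortiumReport(
        baseline_time=t_base,
        consortium_time=t_cons,
        ratio=ratio,
        n_strains=n_strains,
        consortium_model=consortium,
    )
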