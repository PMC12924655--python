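"""Spatially explicit stochastic agent-based model of surface competition.

Four agent guilds compete on a 2D patch grid (default 100x100 patches of
0.01 cm, a 1 cm^2 arena):

* Type A (Bacillus-like): secretes the antimicrobial lipopeptide field M1;
* Type B (Lactobacillus/Pediococcus-like): secretes the organic-acid field M2;
* Type C (Bifidobacterium-like): oxygen-sensitive, cross-fed by M2 through a
  Hill response;
* Type P: pathogens, killed stochastically where M1 or M2 exceeds its
  threshold (kill probability p_k per timestep).

Each timestep (default 172.8 s, so 500 steps = 24 h) applies, in fixed
order: growth/division (rate proportional to r x nutrient x O2 response x
hydration), secretion, metabolite + O2 diffusion with decay, Hill-boosted
cross-feeding growth of Type C, the antagonism kill draw, biofilm flagging
of patches at or above the occupancy threshold, and starvation death.
Diffusion is an explicit 5-point stencil with no-flux boundaries,
sub-stepped so each substep satisfies D*dt/h^2 <= 0.25.

Randomness: each replicate uses one ``numpy`` Generator seeded with
``seed_base + replicate_index``; draws are consumed in the documented stage
order (growth draws per type A,B,C,P, then daughter-placement draws, then
cross-feeding draws, then kill draws), which makes runs bit-reproducible.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGENT_TYPES = ("A", "B", "C", "P")

#: Integer codes for dominance heatmaps; 0 = empty patch.
HEATMAP_CODES = {"none": 0, "A": 1, "B": 2, "C": 3, "P": 4}

#: Admissible range for the metabolite diffusion coefficient.
DIFFUSION_RANGE = (1e-7, 1e-5)

#: Explicit-scheme stability bound for D*dt/h^2 per substep.
STABILITY_LIMIT = 0.25


class ABMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GridConfig:
    """Arena geometry and initial agent layout."""

    width: int = 100
    height: int = 100
    patch_size: float = 0.01  # cm; 100x100 x 0.01 cm = 1 cm^2 arena
    seed_layout: dict = field(
        default_factory=lambda: {"A": 300, "B": 500, "C": 400, "P": 200}
    )
    placement: str = "uniform"

    def __post_init__(self) -> None:
        if self.width < 10 or self.height < 10:
            raise ABMError("grid must be at least 10x10 patches")
        if self.patch_size <= 0:
            raise ABMError("patch_size must be > 0")
        if any(v < 0 for v in self.seed_layout.values()):
            raise ABMError("layout counts must be >= 0")

    @property
    def n_patches(self) -> int:
        return self.width * self.height


@dataclass
class ABMParams:
    """Process rates and thresholds for one scenario.

    Defaults reproduce the headline behavior of the default scenario:
    500 iterations of 172.8 s = 24 h, metabolite diffusion 1e-6 cm^2/s,
    kill probability 0.2 per timestep, biofilm transition at 20 agents per
    patch, hydration factor 0.6 (film water-activity midpoint).
    """

    timestep_s: float = 172.8
    n_iterations: int = 500
    growth_r: dict = field(
        default_factory=lambda: {"A": 0.60, "B": 0.70, "C": 0.50, "P": 0.60}
    )  # per hour
    secretion_m1: float = 1.0     # concentration units per Type A agent per step
    secretion_m2: float = 1.0     # per Type B agent per step
    diffusion: float = 1e-6       # cm^2/s, admissible 1e-7..1e-5
    decay_m1: float = 0.01        # fraction per step
    decay_m2: float = 0.01
    hill_k_half: float = 40.0     # M2 half-saturation: ~10% of quasi-steady M2 mean
    hill_n: float = 2.0
    theta_m1: float = 160.0       # kill thresholds on local M1 / M2
    theta_m2: float = 160.0
    p_kill: float = 0.2           # per pathogen per timestep above threshold
    threshold_mode: str = "or"    # "or": M1>theta1 OR M2>theta2; "ratio": M1/M2>theta1
    biofilm_threshold: int = 20   # agents per patch
    hydration: float = 0.6        # scalar in [0, 1]
    nutrient_init: float = 1.0
    nutrient_per_division: float = 0.005
    nutrient_inflow: float = 0.0  # per patch per step
    o2_init: float = 1.0
    o2_per_division: float = 0.005
    o2_boundary_relax: float = 0.5
    cross_feed_gain: float = 1.0
    crowding_cap: int = 30        # max agents per patch for daughter placement
    energy_init: float = 10.0     # steps an agent survives with no nutrient
    starvation: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_kill <= 1.0):
            raise ABMError("p_kill must be in [0, 1]")
        if self.biofilm_threshold < 1:
            raise ABMError("biofilm_threshold must be >= 1")
        if not (0.0 <= self.hydration <= 1.0):
            raise ABMError("hydration factor must be in [0, 1]")
        if self.threshold_mode not in ("or", "ratio"):
            raise ABMError("threshold_mode must be 'or' or 'ratio'")
        lo, hi = DIFFUSION_RANGE
        if not (lo <= self.diffusion <= hi):
            logger.warning(
                "diffusion %g cm^2/s outside admissible range [%g, %g]",
                self.diffusion, lo, hi,
            )
        if self.threshold_mode == "ratio":
            logger.warning(
                "threshold_mode='ratio' interprets the antagonism condition as "
                "M1/M2 > theta_m1; the default reads the slash as 'or'"
            )

    @property
    def simulated_hours(self) -> float:
        return self.n_iterations * self.timestep_s / 3600.0


# ---------------------------------------------------------------------------
# World state
# ---------------------------------------------------------------------------

@dataclass
class WorldState:
    """Mutable simulation state: per-patch fields plus the agent roster."""

    config: GridConfig
    params: ABMParams
    nutrient: np.ndarray
    o2: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    biofilm: np.ndarray
    agents: dict            # type -> {"pos": int array (flat), "energy": float array}
    step_index: int
    rng: np.random.Generator
    seed: int

    def counts(self, agent_type: str) -> np.ndarray:
        """Per-patch occupancy grid for one agent type."""
        pos = self.agents[agent_type]["pos"]
        return np.bincount(pos, minlength=self.config.n_patches).reshape(
            self.config.height, self.config.width
        )

    def population(self, agent_type: str) -> int:
        return int(self.agents[agent_type]["pos"].size)

    def occupancy(self) -> np.ndarray:
        occ = np.zeros(self.config.n_patches, dtype=np.int64)
        for t in AGENT_TYPES:
            np.add.at(occ, self.agents[t]["pos"], 1)
        return occ


@dataclass
class ABMResult:
    """Outputs of one replicate."""

    populations: np.ndarray          # (n_iterations+1, 4), columns A,B,C,P
    exclusion_step: int | None
    final_counts: dict               # type -> (H, W) int array
    biofilm: np.ndarray
    seed: int
    n_iterations: int
    timestep_s: float

    def population_frame(self) -> pd.DataFrame:
        steps = np.arange(self.populations.shape[0])
        df = pd.DataFrame(self.populations, columns=[f"count{t}" for t in AGENT_TYPES])
        df.insert(0, "time_h", steps * self.timestep_s / 3600.0)
        df.insert(0, "step", steps)
        return df


@dataclass
class RunSummary:
    results: list[ABMResult]
    exclusion_probability: float
    seed_base: int

    def exclusion_steps(self) -> list[int | None]:
        return [r.exclusion_step for r in self.results]


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def diffuse(field_grid: np.ndarray, D: float, dt: float, patch_size: float) -> np.ndarray:
    """Explicit 5-point-stencil diffusion with no-flux boundaries.

    Sub-steps so each substep satisfies the stability criterion
    D*dt_sub/h^2 <= 0.25; total mass is conserved to floating precision.
    """
    f = np.asarray(field_grid, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ABMError("non-finite field values")
    if D <= 0 or dt <= 0:
        return f.copy()
    coeff = D * dt / patch_size**2
    n_sub = max(1, int(np.ceil(coeff / STABILITY_LIMIT)))
    a = coeff / n_sub
    out = f.copy()
    for _ in range(n_sub):
        p = np.pad(out, 1, mode="edge")  # edge replication = zero-flux walls
        lap = (
            p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * out
        )
        out = out + a * lap
    return out


def hill_response(concentration, k_half: float, n: float):
    """Saturating Hill response c^n / (k_half^n + c^n), in [0, 1)."""
    if k_half <= 0 or n <= 0:
        raise ABMError("hill_response requires k_half > 0 and n > 0")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ABMError("negative concentration")
    cn = c**n
    out = cn / (k_half**n + cn)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def init_world(config: GridConfig, params: ABMParams, seed: int) -> WorldState:
    """Place agents per the layout rule and initialize uniform fields."""
    total = sum(config.seed_layout.get(t, 0) for t in AGENT_TYPES)
    if total > config.n_patches * params.crowding_cap:
        raise ABMError("layout exceeds grid capacity")
    rng = np.random.default_rng(seed)
    agents = {}
    for t in AGENT_TYPES:  # fixed placement order = documented RNG order
        n = int(config.seed_layout.get(t, 0))
        if config.placement == "uniform":
            pos = rng.integers(0, config.n_patches, size=n)
        else:
            raise ABMError(f"unknown placement rule {config.placement!r}")
        agents[t] = {
            "pos": pos.astype(np.int64),
            "energy": np.full(n, params.energy_init, dtype=float),
        }
    shape = (config.height, config.width)
    return WorldState(
        config=config,
        params=params,
        nutrient=np.full(shape, params.nutrient_init, dtype=float),
        o2=np.full(shape, params.o2_init, dtype=float),
        m1=np.zeros(shape),
        m2=np.zeros(shape),
        biofilm=np.zeros(shape, dtype=bool),
        agents=agents,
        step_index=0,
        rng=rng,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# One timestep
# ---------------------------------------------------------------------------

def _divide(
    world: WorldState,
    agent_type: str,
    parent_pos: np.ndarray,
    occ: np.ndarray,
    consume_o2: bool,
) -> None:
    """Spawn daughters for the given parents, respecting the crowding cap.

    Daughters stay in the parent patch when below the cap, otherwise move to
    a random von-Neumann neighbor (clamped at walls); a full neighbor drops
    the division.  Consumes nutrient (and O2 for aerobic types) per division.
    """
    if parent_pos.size == 0:
        return
    cfg, par = world.config, world.params
    W = cfg.width
    target = parent_pos.copy()
    crowded = occ[target] >= par.crowding_cap
    if np.any(crowded):
        dirs = world.rng.integers(0, 4, size=int(crowded.sum()))
        tp = target[crowded]
        x, y = tp % W, tp // W
        x = np.clip(x + np.where(dirs == 0, 1, 0) - np.where(dirs == 1, 1, 0), 0, W - 1)
        y = np.clip(
            y + np.where(dirs == 2, 1, 0) - np.where(dirs == 3, 1, 0), 0, cfg.height - 1
        )
        target[crowded] = y * W + x
    ok = occ[target] < par.crowding_cap
    target = target[ok]
    src = parent_pos[ok]
    if target.size == 0:
        return
    np.add.at(occ, target, 1)
    nut = world.nutrient.reshape(-1)
    np.add.at(nut, src, -par.nutrient_per_division)
    np.maximum(nut, 0.0, out=nut)
    if consume_o2:
        o2 = world.o2.reshape(-1)
        np.add.at(o2, src, -par.o2_per_division)
        np.maximum(o2, 0.0, out=o2)
    a = world.agents[agent_type]
    a["pos"] = np.concatenate([a["pos"], target])
    a["energy"] = np.concatenate([a["energy"], np.full(target.size, par.energy_init)])


def step(world: WorldState, params: ABMParams | None = None) -> WorldState:
    """Advance the world by one timestep (mutates and returns ``world``)."""
    par = params if params is not None else world.params
    cfg = world.config
    rng = world.rng
    dt_h = par.timestep_s / 3600.0
    nut_flat = world.nutrient.reshape(-1)
    occ = world.occupancy()

    # (1) growth/division: r x nutrient x O2 response x hydration
    o2n = np.clip(world.o2 / par.o2_init, 0.0, 1.0).reshape(-1)
    for t in AGENT_TYPES:
        pos = world.agents[t]["pos"]
        if pos.size == 0:
            continue
        nut_f = np.clip(nut_flat[pos] / par.nutrient_init, 0.0, 1.0)
        o2_f = (1.0 - o2n[pos]) if t == "C" else o2n[pos]
        p = np.clip(par.growth_r[t] * dt_h * nut_f * o2_f * par.hydration, 0.0, 1.0)
        dividing = rng.random(pos.size) < p
        _divide(world, t, pos[dividing], occ, consume_o2=(t != "C"))

    # (2) secretion into the local patch
    if world.agents["A"]["pos"].size:
        np.add.at(
            world.m1.reshape(-1), world.agents["A"]["pos"], par.secretion_m1
        )
    if world.agents["B"]["pos"].size:
        np.add.at(
            world.m2.reshape(-1), world.agents["B"]["pos"], par.secretion_m2
        )

    # (3) diffusion with decay; O2 replenished along the boundary
    world.m1 = diffuse(world.m1, par.diffusion, par.timestep_s, cfg.patch_size)
    world.m1 *= 1.0 - par.decay_m1
    world.m2 = diffuse(world.m2, par.diffusion, par.timestep_s, cfg.patch_size)
    world.m2 *= 1.0 - par.decay_m2
    world.o2 = diffuse(world.o2, par.diffusion, par.timestep_s, cfg.patch_size)
    for sl in (np.s_[0, :], np.s_[-1, :], np.s_[:, 0], np.s_[:, -1]):
        world.o2[sl] += par.o2_boundary_relax * (par.o2_init - world.o2[sl])
    if par.nutrient_inflow:
        world.nutrient += par.nutrient_inflow

    # (4) cross-feeding: Hill(M2) boosts Type C division
    posC = world.agents["C"]["pos"]
    if posC.size:
        m2_flat = world.m2.reshape(-1)
        boost = hill_response(m2_flat[posC], par.hill_k_half, par.hill_n)
        nut_f = np.clip(nut_flat[posC] / par.nutrient_init, 0.0, 1.0)
        p = np.clip(
            par.growth_r["C"] * dt_h * par.cross_feed_gain * boost * nut_f * par.hydration,
            0.0,
            1.0,
        )
        dividing = rng.random(posC.size) < p
        _divide(world, "C", posC[dividing], occ, consume_o2=False)

    # (5) antagonism: kill draw for pathogens above threshold
    posP = world.agents["P"]["pos"]
    if posP.size:
        m1_local = world.m1.reshape(-1)[posP]
        m2_local = world.m2.reshape(-1)[posP]
        if par.threshold_mode == "or":
            exposed = (m1_local > par.theta_m1) | (m2_local > par.theta_m2)
        else:  # ratio interpretation behind a flag
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(m2_local > 0, m1_local / m2_local, np.inf)
            exposed = (m1_local > 0) & (ratio > par.theta_m1)
        killed = exposed & (rng.random(posP.size) < par.p_kill)
        if np.any(killed):
            keep = ~killed
            world.agents["P"]["pos"] = posP[keep]
            world.agents["P"]["energy"] = world.agents["P"]["energy"][keep]

    # (6) biofilm transition at the occupancy threshold (sticky flag)
    occ_now = world.occupancy().reshape(cfg.height, cfg.width)
    world.biofilm |= occ_now >= par.biofilm_threshold

    # (7) starvation: biofilm-flagged patches are exempt
    if par.starvation:
        bio_flat = world.biofilm.reshape(-1)
        for t in AGENT_TYPES:
            a = world.agents[t]
            if a["pos"].size == 0:
                continue
            starving = nut_flat[a["pos"]] <= 1e-12
            a["energy"] = a["energy"] - starving.astype(float)
            keep = (a["energy"] > 0) | bio_flat[a["pos"]]
            if not np.all(keep):
                a["pos"] = a["pos"][keep]
                a["energy"] = a["energy"][keep]

    world.step_index += 1
    return world


# ---------------------------------------------------------------------------
# Replicated runs
# ---------------------------------------------------------------------------

def run_one(config: GridConfig, params: ABMParams, seed: int,
            n_iterations: int | None = None) -> ABMResult:
    """Run a single seeded replicate for ``n_iterations`` steps."""
    n_iter = params.n_iterations if n_iterations is None else int(n_iterations)
    world = init_world(config, params, seed)
    pops = np.zeros((n_iter + 1, len(AGENT_TYPES)), dtype=np.int64)
    pops[0] = [world.population(t) for t in AGENT_TYPES]
    for k in range(1, n_iter + 1):
        step(world, params)
        pops[k] = [world.population(t) for t in AGENT_TYPES]
    zero_p = np.nonzero(pops[:, AGENT_TYPES.index("P")] == 0)[0]
    exclusion_step = int(zero_p[0]) if zero_p.size else None
    return ABMResult(
        populations=pops,
        exclusion_step=exclusion_step,
        final_counts={t: world.counts(t) for t in AGENT_TYPES},
        biofilm=world.biofilm.copy(),
        seed=seed,
        n_iterations=n_iter,
        timestep_s=params.timestep_s,
    )


def run(
    config: GridConfig | None = None,
    params: ABMParams | None = None,
    n_replicates: int = 10,
    n_iterations: int | None = None,
    seed_base: int = 0,
) -> RunSummary:
    """Independent seeded replicates; replicate i uses seed_base + i (i=1..n)."""
    if n_replicates < 1:
        raise ABMError("n_replicates must be >= 1")
    config = config or GridConfig()
    params = params or ABMParams()
    results = [
        run_one(config, params, seed_base + i, n_iterations)
        for i in range(1, n_replicates + 1)
    ]
    p_excl = sum(r.exclusion_step is not None for r in results) / n_replicates
    return RunSummary(results=results, exclusion_probability=p_excl, seed_base=seed_base)


# ---------------------------------------------------------------------------
# Spatial summaries
# ---------------------------------------------------------------------------

def dominance_heatmap(result: ABMResult) -> np.ndarray:
    """Winning type per patch at end state, integer-coded (0 = empty).

    Ties break in the fixed priority order A > B > C > P.
    """
    stacks = np.stack([result.final_counts[t] for t in AGENT_TYPES])
    winner = np.argmax(stacks, axis=0) + 1  # argmax takes the first max: A>B>C>P
    empty = stacks.sum(axis=0) == 0
    winner[empty] = HEATMAP_CODES["none"]
    return winner


def halo_metric(result: ABMResult, annulus_fraction: float = 0.2) -> float | None:
    """Type-A peripheral enrichment: (A share in outer annulus)/(A share inside).

    Ratios above 1 indicate the antimicrobial-secreting guild is enriched at
    the arena edge.  Returns None when either region holds no agents.
    """
    if not (0.0 < annulus_fraction < 0.5):
        raise ABMError("annulus_fraction must be in (0, 0.5)")
    some = next(iter(result.final_counts.values()))
    H, W = some.shape
    t = max(1, int(round(annulus_fraction * min(H, W))))
    ring = np.zeros((H, W), dtype=bool)
    ring[:t, :] = ring[-t:, :] = ring[:, :t] = ring[:, -t:] = True
    totals_ring = sum(result.final_counts[x][ring].sum() for x in AGENT_TYPES)
    totals_core = sum(result.final_counts[x][~ring].sum() for x in AGENT_TYPES)
    if totals_ring == 0 or totals_core == 0:
        return None
    share_ring = result.final_counts["A"][ring].sum() / totals_ring
    share_core = result.final_counts["A"][~ring].sum() / totals_core
    if share_core == 0:
        return float("inf") if share_ring > 0 else None
    return float(share_ring / share_core)


# ---------------------------------------------------------------------------
# Sensitivity scan
# ---------------------------------------------------------------------------

def sensitivity_scan(
    config: GridConfig,
    params: ABMParams,
    grid: dict[str, Sequence],
    n_replicates: int = 10,
    n_iterations: int | None = None,
    seed_base: int = 0,
) -> pd.DataFrame:
    """Full-factorial scan over parameter values.

    ``grid`` maps ABMParams field names (e.g. secretion_m1, theta_m1,
    p_kill, diffusion) to value lists.  Cell j runs seeded replicates with
    base seed_base + j*10_000.  Returns one row per cell with the exclusion
    probability and the mean exclusion step among excluding replicates.
    """
    if not grid:
        raise ABMError("parameter grid must be non-empty")
    names = list(grid)
    rows = []
    for j, combo in enumerate(itertools.product(*(grid[n] for n in names))):
        cell = replace(params, **dict(zip(names, combo)))
        summ = run(
            config, cell, n_replicates=n_replicates,
            n_iterations=n_iterations, seed_base=seed_base + j * 10_000,
        )
        steps = [s for s in summ.exclusion_steps() if s is not None]
        row = dict(zip(names, combo))
        row.update(
            exclusion_probability=summ.exclusion_probability,
            mean_exclusion_step=float(np.mean(steps)) if steps else np.nan,
            n_replicates=n_replicates,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Export helpers
# ---------------------------------------------------------------------------

def heatmap_to_csv(heatmap: np.ndarray, path) -> None:
    np.savetxt(path, heatmap, fmt="%d", delimiter=",")


def scenario_to_json(config: GridConfig, params: ABMParams) -> str:
    return json.dumps(
        {
            "grid": {
                "width": config.width,
                "height": config.height,
                "patch_size": config.patch_size,
                "seed_layout": config.seed_layout,
                "placement": config.placement,
            },
            "params": {k: getattr(params, k) for k in ABMParams.__dataclass_fields__},
        },
        indent=2,
    )


def scenario_from_json(text: str) -> tuple[GridConfig, ABMParams]:
    cfg = json.loads(text)
    return GridConfig(**cfg.get("grid", {})), ABMParams(**cfg.get("params", {}))
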