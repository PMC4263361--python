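"""Reaction–diffusion simulation of surface-constrained colony expansion.

The colony is treated as a continuous cell medium of density rho spreading
over a 2D lattice (the agar surface) while consuming a diffusible
nutrient g (glucose):

    d(rho)/dt = div( D(rho, g) grad rho ) + eps * rho * g
                - k_e * rho * Theta(rho - rho_e)
    d(g)/dt   = D_g * laplacian(g) - eps * rho * g

with a nonlinear, gated cell diffusivity

    D(rho, g) = D_1 * rho * g * Theta(rho - rho_0) * Theta(g - g_0)

where Theta is the Heaviside step (1 for positive argument, 0 otherwise,
so Theta(0) = 0).  Cells neither move nor grow where either the local
density or the nutrient falls below its gate; this sharp front plus the
random inoculum seeds the branching ("petal") instability at low
nutrient.  The optional sink term (rate k_e, density gate rho_e) models
cells escaping into the vertical dimension instead of spreading on the
surface, as adhesion-deficient (flo11-like) colonies do; with k_e = 0 the
colony is fully surface-bound (FLO11-like).

All variables are dimensionless (the model is rescaled); integration is
explicit Euler on a square lattice with zero-flux (mirror ghost-cell)
Neumann boundaries and a flux-conservative stencil with face-averaged
diffusivity, so that with growth and escape switched off both total cell
mass and total glucose are conserved to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from colonymorph.masks import ColonyMask, largest_component

#: initial-glucose presets for low/mid/high nutrient sweeps
GLUCOSE_PRESETS = {"low": 0.1, "mid": 0.4, "high": 0.7}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the colony-expansion model (all dimensionless)."""

    grid_size: int = 160
    dt: float = 0.064
    dx: float = 0.8
    d_cell: float = 1.0  # D_1, scale of the nonlinear cell diffusivity
    d_glucose: float = 1.0  # D_g
    growth_rate: float = 1.0  # eps: rate of cell growth = nutrient consumption
    rho0: float = 0.01  # density gate of the diffusivity
    g0: float = 0.014  # glucose gate of the diffusivity
    g_init: float = 0.4
    inoculum_radius: float = 16.0
    inoculum_density: tuple[float, float] = (0.03, 0.09)
    escape_rate: float = 0.0  # k_e; 0 = surface-bound (FLO11-like)
    escape_gate: float | None = None  # rho_e; default = 60th pct of inoculum range
    n_steps: int = 5000
    stop_tolerance: float = 1e-8  # stop when growth per step < tol * total rho
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dx <= 0:
            raise ValueError("dt and dx must be positive")
        if self.rho0 < 0 or self.g0 < 0:
            raise ValueError("gates rho0 and g0 must be >= 0")
        if self.escape_rate < 0:
            raise ValueError("escape_rate must be >= 0")
        lo, hi = self.inoculum_density
        if not (0 <= lo < hi):
            raise ValueError("inoculum_density must satisfy 0 <= lo < hi")
        if self.inoculum_radius > self.grid_size / 2:
            raise ValueError("inoculum circle does not fit inside the grid")

    @property
    def rho_e(self) -> float:
        """Escape gate: 60th percentile of the inoculum density range by default."""
        if self.escape_gate is not None:
            return self.escape_gate
        lo, hi = self.inoculum_density
        return lo + 0.6 * (hi - lo)


@dataclass
class SimState:
    """Cell-density and glucose fields at elapsed (rescaled) time t."""

    rho: np.ndarray
    g: np.ndarray
    t: float = 0.0
    clamped_mass: float = 0.0  # cumulative negative mass removed by clamping

    def totals(self) -> tuple[float, float]:
        return float(self.rho.sum()), float(self.g.sum())


def init_state(config: SimConfig) -> SimState:
    """Uniform glucose; random uniform inoculum density inside a central circle.

    The inoculum values are drawn in row-major site order from a single
    seeded generator, so a fixed seed fixes the state bit-for-bit.
    """
    n = config.grid_size
    g = np.full((n, n), config.g_init, dtype=float)
    rho = np.zeros((n, n), dtype=float)
    c = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    inside = (rr - c) ** 2 + (cc - c) ** 2 <= config.inoculum_radius**2
    rng = np.random.default_rng(config.seed)
    lo, hi = config.inoculum_density
    rho[inside] = rng.uniform(lo, hi, size=int(inside.sum()))
    return SimState(rho=rho, g=g, t=0.0)


def _shifts(padded: np.ndarray):
    """The four Neumann-padded neighbor views of the interior."""
    return (
        padded[:-2, 1:-1],
        padded[2:, 1:-1],
        padded[1:-1, :-2],
        padded[1:-1, 2:],
    )


def step(state: SimState, config: SimConfig) -> SimState:
    """One explicit Euler update; negative undershoots are clamped to zero."""
    rho, g = state.rho, state.g
    inv_dx2 = 1.0 / config.dx**2

    # overflow of an unstable update is diagnosed below, not warned about
    with np.errstate(over="ignore", invalid="ignore"):
        D = config.d_cell * rho * g * ((rho > config.rho0) & (g > config.g0))
        Dp = np.pad(D, 1, mode="edge")
        rp = np.pad(rho, 1, mode="edge")
        div = np.zeros_like(rho)
        for Dn, rn in zip(_shifts(Dp), _shifts(rp)):
            div += 0.5 * (D + Dn) * (rn - rho)
        div *= inv_dx2

        consumption = config.growth_rate * rho * g
        drho = div + consumption
        if config.escape_rate > 0:
            drho = drho - config.escape_rate * rho * (rho > config.rho_e)

        gp = np.pad(g, 1, mode="edge")
        lap = np.zeros_like(g)
        for gn in _shifts(gp):
            lap += gn - g
        lap *= inv_dx2

        rho_new = rho + config.dt * drho
        g_new = g + config.dt * (config.d_glucose * lap - consumption)

    if not (np.all(np.isfinite(rho_new)) and np.all(np.isfinite(g_new))):
        raise FloatingPointError(
            "non-finite field after Euler update: the explicit scheme is unstable "
            "for this dt/dx^2 and diffusivity (CFL violation); reduce dt"
        )

    clamped = float(-rho_new[rho_new < 0].sum() - g_new[g_new < 0].sum())
    np.clip(rho_new, 0.0, None, out=rho_new)
    np.clip(g_new, 0.0, None, out=g_new)
    return SimState(
        rho=rho_new,
        g=g_new,
        t=state.t + config.dt,
        clamped_mass=state.clamped_mass + clamped,
    )


def colony_mask(
    state: SimState, density_threshold: float | None = None, rho0: float = 0.01
) -> ColonyMask:
    """Largest connected region with cell density above threshold (default rho_0)."""
    threshold = rho0 if density_threshold is None else density_threshold
    if threshold <= 0:
        raise ValueError("density threshold must be positive")
    grid = state.rho > threshold
    if not grid.any():
        raise ValueError(f"no site has density above {threshold}; colony mask is empty")
    return ColonyMask(largest_component(grid))


def run(
    config: SimConfig,
    snapshot_every: int = 100,
    keep_snapshots: bool = False,
) -> tuple[pd.DataFrame, list[SimState]]:
    """Integrate the model, recording summary rows every ``snapshot_every`` steps.

    The summary table has columns ``t, area_ratio, p2a, total_rho,
    total_g`` where ``area_ratio`` is colony area over the simulation-box
    area.  Integration ends at ``n_steps`` or earlier once the mass gained
    per step drops below ``stop_tolerance`` times the total cell mass.
    """
    from colonymorph.metrics import compute_p2a

    if config.n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    state = init_state(config)
    box_area = config.grid_size**2
    records: list[dict] = []
    snapshots: list[SimState] = []

    def record(s: SimState) -> None:
        total_rho, total_g = s.totals()
        try:
            mask = colony_mask(s, rho0=config.rho0)
            area_ratio = mask.area / box_area
            p2a = compute_p2a(mask)
        except ValueError:
            area_ratio, p2a = 0.0, np.nan
        records.append(
            {"t": s.t, "area_ratio": area_ratio, "p2a": p2a,
             "total_rho": total_rho, "total_g": total_g}
        )
        if keep_snapshots:
            snapshots.append(SimState(s.rho.copy(), s.g.copy(), s.t, s.clamped_mass))

    record(state)
    for i in range(1, config.n_steps + 1):
        prev_total = float(state.rho.sum())
        state = step(state, config)
        if i % snapshot_every == 0 or i == config.n_steps:
            record(state)
        growth = float(state.rho.sum()) - prev_total
        if config.growth_rate > 0 and abs(growth) < config.stop_tolerance * prev_total:
            if i % snapshot_every != 0 and i != config.n_steps:
                record(state)
            break
    summary = pd.DataFrame(records)
    summary.attrs["config"] = config
    summary.attrs["clamped_mass"] = state.clamped_mass
    return summary, snapshots if keep_snapshots else [state]


def sweep_glucose(
    levels=None, seeds=(0, 1, 2), escape_rate: float = 0.0, **config_kwargs
) -> pd.DataFrame:
    """Final colony area across glucose presets and seeds (ordering studies)."""
    if levels is None:
        levels = GLUCOSE_PRESETS
    rows = []
    for name, g_init in levels.items():
        for seed in seeds:
            cfg = SimConfig(g_init=g_init, seed=seed, escape_rate=escape_rate, **config_kwargs)
            summary, _ = run(cfg)
            rows.append(
                {"level": name, "g_init": g_init, "seed": seed,
                 "final_area_ratio": summary["area_ratio"].iloc[-1],
                 "final_p2a": summary["p2a"].iloc[-1]}
            )
    return pd.DataFrame(rows)


def write_snapshot(state: SimState, out_dir, stem: str = "state") -> None:
    """16-bit TIFF of scaled density plus raw tab-delimited field dumps."""
    from pathlib import Path

    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scale = state.rho.max() or 1.0
    tifffile.imwrite(out_dir / f"{stem}_rho.tif", (state.rho / scale * 65535).astype(np.uint16))
    np.savetxt(out_dir / f"{stem}_rho.tsv", state.rho, delimiter="\t")
    np.savetxt(out_dir / f"{stem}_g.tsv", state.g, delimiter="\t")


def load_config(path) -> SimConfig:
    """Read a flat key-value config file (``name = value`` or ``name: value``)."""
    from pathlib import Path

    kwargs: dict = {}
    text = Path(path).read_text()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, value = line.split(sep, 1)
                break
        else:
            raise ValueError(f"cannot parse config line: {line!r}")
        key = key.strip()
        value = value.strip()
        if key == "inoculum_density":
            parsed = tuple(float(v) for v in value.replace(",", " ").split())
        elif key in ("grid_size", "n_steps", "seed"):
            parsed = int(value)
        elif key == "escape_gate":
            parsed = None if value.lower() in ("none", "") else float(value)
        else:
            parsed = float(value)
        kwargs[key] = parsed
    return SimConfig(**kwargs)
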