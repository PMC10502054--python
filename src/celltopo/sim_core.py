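"""Self-propelled particle model of differential adhesion.

Two (or K) motile cell types move in a periodic square box under a random
self-propulsion force of fixed magnitude and pairwise Morse interactions
whose strength J(T(i), T(j)) depends on the pair of cell types (homotypic
J_BB, J_OO vs heterotypic J_BO). The overdamped equation of motion is

    x_i(t + dt) = x_i(t) + (dt / eta) * (P_i + sum_j F_ij),

with the pair force derived from the Morse potential

    U(r) = -J [ exp(-r / l_A) - (1/4) exp(-r / l_R) ],

cut off beyond ``r_max``. The attraction/repulsion balance puts the
two-cell equilibrium separation at r* ~ 1.009 for the default lengths
(l_A = 14, l_R = 0.5, ratio 1/4), which sets the cell "diameter".

Cells repolarize (redraw a uniform heading) every ``repolarization_period``
steps with a per-cell phase offset, giving run-and-tumble motility.
Optionally cells divide on an internal clock, with contact inhibition:
division is suppressed when more than ``max_neighbors_for_division``
cells sit within ``r_max``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import force_magnitude_table, simulate_block

__all__ = [
    "SimulationConfig",
    "AdhesionTable",
    "Population",
    "PackingError",
    "init_population",
    "morse_potential",
    "pair_force",
    "step_population",
    "attempt_divisions",
    "run_simulation",
    "equilibrium_separation",
]


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place all cells at the
    requested minimum separation."""


@dataclass
class SimulationConfig:
    box_halfwidth: float = 20.0
    dt: float = 0.02
    eta: float = 1.0
    polarization_magnitude: float = 0.005
    repolarization_period: int = 2500
    n_steps: int = 5_000_000
    r_max: float = 1.5
    l_A: float = 14.0
    l_R: float = 0.5
    repulsion_ratio: float = 0.25
    n_cells: int = 200
    type_fractions: tuple = (0.6, 0.4)
    type_names: tuple = ("blue", "orange")
    proliferation_enabled: bool = False
    cell_cycle_steps: int = 80_000
    max_neighbors_for_division: int = 4
    min_init_separation: float = 1.0
    daughter_offset: float = 0.25
    max_cells: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cell_cycle_steps < 1:
            raise ValueError("cell_cycle_steps must be >= 1")
        if len(self.type_fractions) != len(self.type_names):
            raise ValueError("type_fractions and type_names lengths differ")
        if abs(sum(self.type_fractions) - 1.0) > 1e-9:
            raise ValueError("type_fractions must sum to 1")

    @property
    def box_length(self) -> float:
        return 2.0 * self.box_halfwidth

    @property
    def n_types(self) -> int:
        return len(self.type_names)


@dataclass
class AdhesionTable:
    """Symmetric K x K table of nonnegative adhesion magnitudes."""

    J: np.ndarray

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValueError("adhesion table must be square")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("adhesion table must be symmetric")
        if np.any(self.J < 0):
            raise ValueError("adhesion magnitudes must be nonnegative")

    @classmethod
    def from_pairs(cls, j_bb: float, j_oo: float, j_bo: float) -> "AdhesionTable":
        return cls(np.array([[j_bb, j_bo], [j_bo, j_oo]]))


@dataclass
class Population:
    """State of all cells at one instant."""

    positions: np.ndarray          # (N, 2), inside [-half, half)
    polarization_angles: np.ndarray  # (N,) headings in [0, 2*pi)
    types: np.ndarray              # (N,) small ints indexing type_names
    division_clocks: np.ndarray    # (N,) steps since last division
    repolarization_offsets: np.ndarray  # (N,) per-cell phase
    polarization_magnitude: float
    step_index: int = 0

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def polarizations(self) -> np.ndarray:
        """Per-cell polarization force vectors of fixed magnitude."""
        return self.polarization_magnitude * np.column_stack(
            (np.cos(self.polarization_angles), np.sin(self.polarization_angles))
        )

    def type_counts(self, n_types: int) -> np.ndarray:
        return np.bincount(self.types, minlength=n_types)

    def copy(self) -> "Population":
        return Population(
            self.positions.copy(), self.polarization_angles.copy(),
            self.types.copy(), self.division_clocks.copy(),
            self.repolarization_offsets.copy(),
            self.polarization_magnitude, self.step_index,
        )


def _largest_remainder_counts(fractions, n) -> np.ndarray:
    raw = np.asarray(fractions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _min_image(d: np.ndarray, box_l: float) -> np.ndarray:
    return d - np.round(d / box_l) * box_l


def _seed_streams(seed: int):
    ss = np.random.SeedSequence(seed)
    init_ss, run_ss = ss.spawn(2)
    kernel_seed = int(run_ss.generate_state(1)[0] % np.uint32(2**31 - 1))
    return np.random.default_rng(init_ss), kernel_seed


def init_population(config: SimulationConfig) -> Population:
    """Place cells uniformly with rejection sampling at a minimum pairwise
    (periodic) separation; headings uniform; deterministic given the seed.
    """
    rng, _ = _seed_streams(config.seed)
    n = config.n_cells
    box_l = config.box_length
    half = config.box_halfwidth
    sep2 = config.min_init_separation**2
    placed = np.empty((n, 2))
    k = 0
    attempts = 0
    max_attempts = 500 * n + 1000
    while k < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"packing infeasible: placed {k}/{n} cells after "
                f"{attempts} attempts at separation {config.min_init_separation}"
            )
        cand = rng.uniform(-half, half, size=2)
        attempts += 1
        if k:
            d = _min_image(placed[:k] - cand, box_l)
            if np.min(np.einsum("ij,ij->i", d, d)) < sep2:
                continue
        placed[k] = cand
        k += 1
    counts = _largest_remainder_counts(config.type_fractions, n)
    types = np.repeat(np.arange(len(counts), dtype=np.int8), counts)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    offsets = rng.integers(0, config.repolarization_period, size=n)
    if config.proliferation_enabled:
        clocks = rng.integers(0, config.cell_cycle_steps, size=n)
    else:
        clocks = np.zeros(n, dtype=np.int64)
    return Population(
        positions=placed,
        polarization_angles=angles,
        types=types,
        division_clocks=clocks.astype(np.int64),
        repolarization_offsets=offsets.astype(np.int64),
        polarization_magnitude=config.polarization_magnitude,
    )


def morse_potential(r, J, config: SimulationConfig | None = None):
    """Pair potential U(r) = -J [exp(-r/l_A) - ratio * exp(-r/l_R)]."""
    config = config or SimulationConfig()
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation must be nonnegative")
    u = -J * (np.exp(-r / config.l_A)
              - config.repulsion_ratio * np.exp(-r / config.l_R))
    return u if u.shape else float(u)


def _force_magnitude(r, J, config: SimulationConfig):
    """U'(r) scaled by J: positive = attraction toward the partner."""
    return J * (np.exp(-r / config.l_A) / config.l_A
                - config.repulsion_ratio * np.exp(-r / config.l_R) / config.l_R)


def pair_force(x_i, x_j, J, config: SimulationConfig | None = None) -> np.ndarray:
    """Force on cell i exerted by cell j (minimum-image separation).

    Zero beyond ``r_max``; antisymmetric under i <-> j. For coincident
    centers the magnitude is finite but the direction undefined, so the
    zero vector is returned (the simulation kernel instead applies the
    capped magnitude along a random direction).
    """
    config = config or SimulationConfig()
    d = _min_image(np.asarray(x_j, dtype=float) - np.asarray(x_i, dtype=float),
                   config.box_length)
    r = math.hypot(d[0], d[1])
    if r > config.r_max or r == 0.0:
        return np.zeros(2)
    return _force_magnitude(r, J, config) * d / r


def equilibrium_separation(config: SimulationConfig | None = None,
                           tol: float = 1e-12) -> float:
    """Root of U'(r) on (0, r_max) by bisection: the two-cell rest length."""
    config = config or SimulationConfig()
    f = lambda r: _force_magnitude(r, 1.0, config)
    lo, hi = 1e-6, config.r_max
    if f(lo) * f(hi) > 0:
        raise ValueError("no sign change of dU/dr on (0, r_max)")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def step_population(pop: Population, adhesion: AdhesionTable,
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> Population:
    """One synchronous update (readable numpy reference implementation).

    Forces are accumulated from the current positions for every pair, then
    all cells move at once. Cells whose repolarization phase is due at this
    step first redraw a uniform heading. ``run_simulation`` uses the
    compiled kernel instead; a test pins the two paths together.
    """
    new = pop.copy()
    if rng is None:
        rng = np.random.default_rng(pop.step_index)
    due = (pop.step_index + new.repolarization_offsets) \
        % config.repolarization_period == 0
    if np.any(due):
        new.polarization_angles[due] = rng.uniform(0, 2 * np.pi, due.sum())

    x = new.positions
    d = _min_image(x[None, :, :] - x[:, None, :], config.box_length)
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    jmat = adhesion.J[new.types[:, None], new.types[None, :]]
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(
            (r > 0) & (r <= config.r_max),
            _force_magnitude(r, jmat, config) / np.where(r > 0, r, 1.0),
            0.0,
        )
    np.fill_diagonal(coef, 0.0)
    forces = np.einsum("ij,ijk->ik", coef, d)

    disp = (config.dt / config.eta) * (new.polarizations + forces)
    moved = x + disp
    half = config.box_halfwidth
    out = (moved < -half) | (moved >= half)
    if np.any(out):  # wrap only out-of-box coordinates (bitwise no-op inside)
        moved[out] = (moved[out] + half) % config.box_length - half
    new.positions = moved
    new.division_clocks = new.division_clocks + 1
    new.step_index = pop.step_index + 1
    return new


def attempt_divisions(pop: Population, config: SimulationConfig,
                      rng: np.random.Generator) -> Population:
    """Divide every cell whose clock has run out and whose neighbor count
    (cells within ``r_max``) does not exceed the contact-inhibition limit.

    One daughter keeps the mother's position and heading; the other is
    placed ``daughter_offset`` away in a random direction with the
    opposite heading. Both clocks reset.
    """
    x = pop.positions
    d = _min_image(x[None, :, :] - x[:, None, :], config.box_length)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    np.fill_diagonal(r2, np.inf)
    neighbors = (r2 <= config.r_max**2).sum(axis=1)
    can_divide = ((pop.division_clocks >= config.cell_cycle_steps)
                  & (neighbors <= config.max_neighbors_for_division))
    idx = np.nonzero(can_divide)[0]
    new = pop.copy()
    if idx.size == 0:
        return new
    theta = rng.uniform(0, 2 * np.pi, idx.size)
    offs = config.daughter_offset * np.column_stack((np.cos(theta), np.sin(theta)))
    half = config.box_halfwidth
    daughters = (x[idx] + offs + half) % config.box_length - half
    new.division_clocks[idx] = 0
    new.positions = np.vstack([new.positions, daughters])
    new.polarization_angles = np.concatenate(
        [new.polarization_angles, (pop.polarization_angles[idx] + np.pi) % (2 * np.pi)])
    new.types = np.concatenate([new.types, pop.types[idx]])
    new.division_clocks = np.concatenate(
        [new.division_clocks, np.zeros(idx.size, dtype=np.int64)])
    new.repolarization_offsets = np.concatenate(
        [new.repolarization_offsets,
         rng.integers(0, config.repolarization_period, idx.size)])
    return new


def _capacity(config: SimulationConfig, n_steps: int) -> int:
    if not config.proliferation_enabled:
        return config.n_cells
    if config.max_cells is not None:
        return config.max_cells
    doublings = n_steps // config.cell_cycle_steps + 2
    return int(min(config.n_cells * 2**doublings, 30_000))


def run_simulation(config: SimulationConfig, adhesion: AdhesionTable,
                   snapshot_every: int | None = None):
    """Integrate the model for ``config.n_steps`` steps (compiled kernel).

    Returns the final :class:`Population`, or ``(final, snapshots)`` when
    ``snapshot_every`` is given — snapshots is a list of (step, Population).
    Fully reproducible given ``config.seed`` (for a fixed snapshot cadence).
    """
    if adhesion.J.shape[0] != config.n_types:
        raise ValueError("adhesion table size does not match number of types")
    pop = init_population(config)
    total = config.n_steps
    if total == 0:
        return (pop, []) if snapshot_every else pop

    cap = _capacity(config, total)
    pos = np.zeros((cap, 2))
    ang = np.zeros(cap)
    types = np.zeros(cap, np.int8)
    clocks = np.zeros(cap, np.int64)
    offsets = np.zeros(cap, np.int64)
    n = pop.n_cells
    pos[:n] = pop.positions
    ang[:n] = pop.polarization_angles
    types[:n] = pop.types
    clocks[:n] = pop.division_clocks
    offsets[:n] = pop.repolarization_offsets

    ftab = force_magnitude_table(config.r_max, config.l_A, config.l_R,
                                 config.repulsion_ratio)
    coin_mag = abs(1.0 / config.l_A
                   - config.repulsion_ratio / config.l_R)
    _, kernel_seed = _seed_streams(config.seed)
    chunk = snapshot_every or total
    snapshots = []
    done = 0
    block = 0
    while done < total:
        steps = min(chunk, total - done)
        # each block gets its own derived seed so chunked runs stay
        # deterministic for a fixed cadence
        block_seed = (kernel_seed + 0x9E3779B1 * block) % (2**31 - 1)
        n = simulate_block(
            pos, ang, types, offsets, clocks, n, adhesion.J,
            config.polarization_magnitude, config.dt / config.eta,
            config.r_max, config.box_length, config.repolarization_period,
            done, steps, config.proliferation_enabled,
            config.cell_cycle_steps, config.max_neighbors_for_division,
            config.daughter_offset, block_seed, ftab, coin_mag)
        done += steps
        block += 1
        if snapshot_every and (done < total or snapshot_every):
            snap = Population(pos[:n].copy(), ang[:n].copy(), types[:n].copy(),
                              clocks[:n].copy(), offsets[:n].copy(),
                              config.polarization_magnitude, done)
            snapshots.append((done, snap))
        if config.proliferation_enabled and n >= cap:
            warnings.warn("cell capacity reached; divisions suppressed")
    final = Population(pos[:n].copy(), ang[:n].copy(), types[:n].copy(),
                       clocks[:n].copy(), offsets[:n].copy(),
                       config.polarization_magnitude, total)
    return (final, snapshots) if snapshot_every else final
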