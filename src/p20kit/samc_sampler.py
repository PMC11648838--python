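"""Stochastic-approximation flat-histogram sampling of the CG model.

The sampler estimates the log-density-of-states over the exact discrete
interaction levels ``(N_backbone, N_sidechain)``.  A move from the current
level ``a`` to a proposed level ``b`` is accepted with probability

    min(1, exp(log_g[a] - log_g[b]))

and after every step (accepted or not) the log-DOS of the level the system
ends up in is raised by the decaying modification factor

    gamma_t = min(gamma0, t0 / t),

which drives the visitation histogram flat.  Constraint-violating proposals
count as rejected moves.  Once ``gamma_t`` falls below ``gamma_min`` the DOS
is frozen and production runs collect configuration snapshots stratified by
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .prime20_model import (
    BEADS_PER_RESIDUE,
    KIND_INDEX,
    CGSystem,
    InteractionCount,
    InteractionParams,
    default_params,
    get_topology,
    p20_energy,
    unwrap_chain,
    wrap_positions,
)

__all__ = [
    "EnergyLevel",
    "DOSEstimate",
    "SamcConfig",
    "MoveProposal",
    "SnapshotRecord",
    "MOVE_TYPES",
    "gamma_schedule",
    "acceptance_probability",
    "propose_move",
    "samc_step",
    "run_samc",
    "run_production",
    "histogram_diagnostics",
    "HistogramDiagnostics",
]

MOVE_TYPES = ("displacement", "pivot", "chain_rotation", "chain_translation")


@dataclass(frozen=True)
class EnergyLevel:
    """A discrete interaction level; distinct keys stay distinct even when
    their derived energies collide numerically."""

    n_backbone: int
    n_sidechain: int

    @property
    def key(self) -> tuple[int, int]:
        return (self.n_backbone, self.n_sidechain)

    def energy(self, params: InteractionParams | None = None) -> float:
        return p20_energy((self.n_backbone, self.n_sidechain), params)


@dataclass
class DOSEstimate:
    """log-DOS and visitation histogram keyed by exact (nb, ns) levels."""

    log_dos: dict[tuple[int, int], float] = field(default_factory=dict)
    visits: dict[tuple[int, int], int] = field(default_factory=dict)
    t: int = 0
    gamma: float = 0.0
    total_increment: float = 0.0

    def min_log_dos(self) -> float:
        return min(self.log_dos.values()) if self.log_dos else 0.0

    def get_or_init(self, level: tuple[int, int]) -> float:
        """Lazily initialize unseen levels to the current minimum log-DOS."""
        if level not in self.log_dos:
            self.log_dos[level] = self.min_log_dos()
            self.visits.setdefault(level, 0)
        return self.log_dos[level]

    def update(self, level: tuple[int, int], gamma: float) -> None:
        self.get_or_init(level)
        self.log_dos[level] += gamma
        self.visits[level] = self.visits.get(level, 0) + 1
        self.t += 1
        self.gamma = gamma
        self.total_increment += gamma

    def copy(self) -> "DOSEstimate":
        return DOSEstimate(dict(self.log_dos), dict(self.visits), self.t,
                           self.gamma, self.total_increment)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DOSEstimate):
            return NotImplemented
        return (self.log_dos == other.log_dos and self.visits == other.visits
                and self.t == other.t and self.gamma == other.gamma)


@dataclass
class SamcConfig:
    """Sampler knobs.  ``move_mix`` orders probabilities as MOVE_TYPES."""

    gamma0: float = 1.0
    t0: float = 1.0e4
    gamma_min: float = 1.0e-7
    move_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    max_displacement: float = 0.02
    max_pivot_angle: float = math.pi
    max_chain_translation: float = 1.0
    max_chain_rotation: float = math.pi
    seed: int = 0
    snapshot_stride: int = 1000
    snapshot_quota: int = 20

    def __post_init__(self) -> None:
        if not self.gamma0 > 0:
            raise ValueError("gamma0 must be > 0")
        if not self.t0 > 0:
            raise ValueError("t0 must be > 0")
        if not (0 < self.gamma_min < self.gamma0):
            raise ValueError("gamma_min must be in (0, gamma0)")
        if len(self.move_mix) != len(MOVE_TYPES):
            raise ValueError("move_mix needs one probability per move type")
        if any(p < 0 for p in self.move_mix):
            raise ValueError("move probabilities must be >= 0")
        if abs(sum(self.move_mix) - 1.0) > 1e-9:
            raise ValueError("move_mix must sum to 1")
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if self.snapshot_stride < 1 or self.snapshot_quota < 1:
            raise ValueError("snapshot stride and quota must be >= 1")


@dataclass
class MoveProposal:
    move_type: str
    bead_indices: np.ndarray
    old_positions: np.ndarray
    new_positions: np.ndarray
    valid: bool

    def __post_init__(self) -> None:
        self.bead_indices = np.asarray(self.bead_indices, dtype=np.int64)
        if self.bead_indices.size == 0:
            raise ValueError("proposal must affect at least one bead")
        self.old_positions = np.asarray(self.old_positions, dtype=float)
        self.new_positions = np.asarray(self.new_positions, dtype=float)
        if not (np.all(np.isfinite(self.old_positions))
                and np.all(np.isfinite(self.new_positions))):
            raise ValueError("proposal positions must be finite")


@dataclass
class SnapshotRecord:
    """A stored CG configuration with its counts and energy."""

    system: CGSystem
    counts: InteractionCount
    energy: float
    step: int
    run_id: str


def gamma_schedule(t: int, gamma0: float, t0: float) -> float:
    """``min(gamma0, t0 / t)`` with ``t`` in MC steps (1-based)."""
    if t <= 0:
        raise ValueError("t must be >= 1")
    return min(gamma0, t0 / t)


def acceptance_probability(log_dos_current: float, log_dos_proposed: float) -> float:
    """``min(1, g[current] / g[proposed])`` evaluated in log space."""
    if not (math.isfinite(log_dos_current) and math.isfinite(log_dos_proposed)):
        raise ValueError("log-DOS values must be finite")
    if log_dos_proposed <= log_dos_current:
        return 1.0
    return math.exp(log_dos_current - log_dos_proposed)


# -- move generation ----------------------------------------------------------


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            return v / norm


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _pivot_arm(system: CGSystem, chain: int, residue: int, axis_kind: str) -> np.ndarray:
    """Bead indices of the C-terminal arm rotated by a phi/psi pivot.

    phi (axis NH-CA) rotates this residue's CO and SC plus every later
    residue; psi (axis CA-CO) rotates only the later residues.
    """
    n_res = len(system.sequences[chain])
    start = system.chain_slice(chain).start
    later = [start + ri * BEADS_PER_RESIDUE + k
             for ri in range(residue + 1, n_res)
             for k in range(BEADS_PER_RESIDUE)]
    if axis_kind == "phi":
        base = start + residue * BEADS_PER_RESIDUE
        own = [base + KIND_INDEX["CO"], base + KIND_INDEX["SC"]]
        return np.asarray(own + later, dtype=np.int64)
    return np.asarray(later, dtype=np.int64)


def _draw_move(system: CGSystem, config: SamcConfig,
               rng: np.random.Generator) -> tuple[str, np.ndarray, np.ndarray]:
    """Draw one raw move: (type, bead indices, new unwrapped positions)."""
    move = MOVE_TYPES[rng.choice(len(MOVE_TYPES), p=config.move_mix)]
    if move == "displacement":
        bead = int(rng.integers(system.n_beads))
        direction = _random_unit(rng)
        r = rng.uniform(0.0, config.max_displacement)
        new = system.coords[bead] + r * direction
        return move, np.array([bead], dtype=np.int64), new[None, :]
    chain = int(rng.integers(system.n_chains))
    if move == "pivot":
        n_res = len(system.sequences[chain])
        residue = int(rng.integers(n_res))
        axis_kind = "phi" if rng.integers(2) == 0 else "psi"
        arm = _pivot_arm(system, chain, residue, axis_kind)
        if arm.size == 0:  # psi of the last residue rotates nothing
            axis_kind = "phi"
            arm = _pivot_arm(system, chain, residue, axis_kind)
        angle = rng.uniform(-config.max_pivot_angle, config.max_pivot_angle)
        unwrapped = unwrap_chain(system, chain)
        sl = system.chain_slice(chain)
        local = residue * BEADS_PER_RESIDUE
        if axis_kind == "phi":
            p0 = unwrapped[local + KIND_INDEX["NH"]]
            p1 = unwrapped[local + KIND_INDEX["CA"]]
        else:
            p0 = unwrapped[local + KIND_INDEX["CA"]]
            p1 = unwrapped[local + KIND_INDEX["CO"]]
        rot = _rotation_matrix(p1 - p0, angle)
        new = (unwrapped[arm - sl.start] - p0) @ rot.T + p0
        return move, arm, new
    sl = system.chain_slice(chain)
    beads = np.arange(sl.start, sl.stop, dtype=np.int64)
    if move == "chain_translation":
        direction = _random_unit(rng)
        r = rng.uniform(0.0, config.max_chain_translation)
        new = system.coords[sl] + r * direction
        return move, beads, new
    # chain_rotation: rigid rotation about the chain centroid
    unwrapped = unwrap_chain(system, chain)
    centroid = unwrapped.mean(axis=0)
    axis = _random_unit(rng)
    angle = rng.uniform(-config.max_chain_rotation, config.max_chain_rotation)
    rot = _rotation_matrix(axis, angle)
    new = (unwrapped - centroid) @ rot.T + centroid
    return move, beads, new


def propose_move(system: CGSystem, config: SamcConfig, rng: np.random.Generator,
                 params: InteractionParams | None = None) -> MoveProposal:
    """Draw one move and flag whether the trial configuration is valid."""
    if params is None:
        params = default_params()
    topo = get_topology(system, params)
    move, beads, new = _draw_move(system, config, rng)
    trial = system.coords.copy()
    trial[beads] = wrap_positions(new, system.box_length)
    return MoveProposal(move, beads, system.coords[beads].copy(), new,
                        topo.is_valid(trial))


# -- the SAMC step and driver -------------------------------------------------


def samc_step(dos: DOSEstimate, system: CGSystem, config: SamcConfig,
              rng: np.random.Generator,
              params: InteractionParams | None = None,
              proposal: MoveProposal | None = None,
              ) -> tuple[DOSEstimate, CGSystem]:
    """One SAMC step: propose, accept/reject, update the DOS in place.

    Exactly one level (that of the post-decision configuration) receives the
    ``gamma_t`` log-DOS increment and one visitation count; ``t`` advances by
    one.  Invalid proposals take the rejection branch.
    """
    if params is None:
        params = default_params()
    topo = get_topology(system, params)
    gamma = gamma_schedule(dos.t + 1, config.gamma0, config.t0)
    current = topo.count(system.coords)
    if proposal is None:
        proposal = propose_move(system, config, rng, params)
    if proposal.valid:
        trial = system.coords.copy()
        trial[proposal.bead_indices] = wrap_positions(
            proposal.new_positions, system.box_length)
        proposed = topo.count(trial)
        log_cur = dos.get_or_init(current)
        log_new = dos.get_or_init(proposed)
        if rng.random() < acceptance_probability(log_cur, log_new):
            system.coords = trial
            current = proposed
    dos.update(current, gamma)
    return dos, system


def run_samc(system: CGSystem, config: SamcConfig,
             params: InteractionParams | None = None,
             dos: DOSEstimate | None = None,
             callback: Callable[[int, DOSEstimate], None] | None = None,
             callback_stride: int = 100_000) -> DOSEstimate:
    """Run SAMC until ``gamma_t < gamma_min``; deterministic for fixed seed."""
    if params is None:
        params = default_params()
    if dos is None:
        dos = DOSEstimate()
    topo = get_topology(system, params)
    rng = np.random.default_rng(config.seed)
    current = topo.count(system.coords)
    dos.get_or_init(current)
    while True:
        t = dos.t + 1
        gamma = gamma_schedule(t, config.gamma0, config.t0)
        if gamma < config.gamma_min:
            dos.gamma = gamma
            break
        move, beads, new = _draw_move(system, config, rng)
        trial = system.coords.copy()
        trial[beads] = wrap_positions(new, system.box_length)
        valid, nb, ns = topo.evaluate(trial)
        if valid:
            proposed = (nb, ns)
            log_cur = dos.get_or_init(current)
            log_new = dos.get_or_init(proposed)
            if rng.random() < acceptance_probability(log_cur, log_new):
                system.coords = trial
                current = proposed
        dos.update(current, gamma)
        if callback is not None and dos.t % callback_stride == 0:
            callback(dos.t, dos)
    return dos


def run_production(system: CGSystem, dos: DOSEstimate, n_steps: int,
                   config: SamcConfig,
                   rng: np.random.Generator | None = None,
                   params: InteractionParams | None = None,
                   run_id: str = "prod",
                   gamma_min: float | None = None) -> list[SnapshotRecord]:
    """Fixed-DOS sampling with stratified snapshot collection.

    The DOS is read-only.  The first visit to each level is always recorded;
    afterwards snapshots are taken every ``snapshot_stride`` steps into the
    visited level's reservoir, up to ``snapshot_quota`` per level.
    """
    if params is None:
        params = default_params()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if gamma_min is None:
        gamma_min = config.gamma_min
    if dos.gamma >= gamma_min:
        raise ValueError(
            f"DOS not converged: gamma={dos.gamma!r} >= gamma_min={gamma_min!r}")
    topo = get_topology(system, params)
    frozen = dict(dos.log_dos)
    floor = min(frozen.values()) if frozen else 0.0
    current = topo.count(system.coords)
    per_level: dict[tuple[int, int], list[SnapshotRecord]] = {}

    def record(step: int) -> None:
        bucket = per_level.setdefault(current, [])
        if len(bucket) < config.snapshot_quota:
            bucket.append(SnapshotRecord(
                system.copy(), InteractionCount(*current),
                p20_energy(current, params), step, run_id))

    record(0)
    for step in range(1, n_steps + 1):
        move, beads, new = _draw_move(system, config, rng)
        trial = system.coords.copy()
        trial[beads] = wrap_positions(new, system.box_length)
        valid, nb, ns = topo.evaluate(trial)
        if valid:
            proposed = (nb, ns)
            log_cur = frozen.get(current, floor)
            log_new = frozen.get(proposed, floor)
            if rng.random() < acceptance_probability(log_cur, log_new):
                system.coords = trial
                current = proposed
        if current not in per_level or step % config.snapshot_stride == 0:
            record(step)
    return [snap for bucket in per_level.values() for snap in bucket]


# -- histogram diagnostics ----------------------------------------------------


@dataclass
class HistogramDiagnostics:
    bin_centers: np.ndarray
    histogram: np.ndarray
    running_average: np.ndarray
    fft_frequencies: np.ndarray
    fft_power: np.ndarray
    fractional_values: np.ndarray
    fractional_counts: np.ndarray


def histogram_diagnostics(counts: Sequence[tuple[int, int] | InteractionCount],
                          window: float = 0.5,
                          params: InteractionParams | None = None,
                          bin_width: float | None = None) -> HistogramDiagnostics:
    """Energy-histogram diagnostics for an ensemble of interaction counts.

    Returns the binned energy histogram, its truncated centered running
    average over an energy ``window``, the discrete Fourier power spectrum of
    the histogram, and the fractional-part projection computed from the
    integer sidechain counts (never from a floating-point modulo of the
    energies).
    """
    if params is None:
        params = default_params()
    pairs = np.array([c.as_tuple() if isinstance(c, InteractionCount) else tuple(c)
                      for c in counts], dtype=np.int64)
    if pairs.size == 0:
        raise ValueError("counts must be non-empty")
    energies = -params.w_bb * pairs[:, 0] - params.w_sc * pairs[:, 1]
    if bin_width is None:
        bin_width = params.w_sc if params.w_sc > 0 else max(params.w_bb, 1.0)
    emin, emax = float(energies.min()), float(energies.max())
    n_bins = max(1, int(round((emax - emin) / bin_width)) + 1)
    edges = emin - 0.5 * bin_width + np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(energies, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    half = 0.5 * window + 1e-12
    running = np.empty_like(hist, dtype=float)
    for k, c in enumerate(centers):
        mask = np.abs(centers - c) <= half
        running[k] = hist[mask].mean()

    spectrum = np.fft.rfft(hist.astype(float))
    power = np.abs(spectrum) ** 2
    freqs = np.fft.rfftfreq(len(hist), d=bin_width)

    frac = params.w_sc * pairs[:, 1]
    frac = frac - np.floor(frac)
    frac = np.round(frac, 9)
    values, frac_counts = np.unique(frac, return_counts=True)
    return HistogramDiagnostics(centers, hist, running, freqs, power,
                                values, frac_counts)
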