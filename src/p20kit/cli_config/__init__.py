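"""Run configuration, deterministic seed derivation, and text file formats
for DOS estimates and CG snapshot sets."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ..prime20_model import (
    BEAD_KINDS,
    BEADS_PER_RESIDUE,
    KIND_INDEX,
    CGSystem,
    InteractionCount,
    InteractionParams,
)
from ..samc_sampler import DOSEstimate, SamcConfig, SnapshotRecord

__all__ = [
    "RunConfig",
    "RunManifest",
    "ConfigError",
    "FormatError",
    "load_config",
    "config_hash",
    "stage_seed",
    "save_dos",
    "load_dos",
    "save_snapshots",
    "load_snapshots",
]


class ConfigError(ValueError):
    pass


class FormatError(ValueError):
    pass


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ModelSection(_Section):
    """Overrides applied on top of the default interaction parameters."""

    w_bb: float = 1.0
    w_sc: float = 0.08
    hb_well: tuple[float, float] | None = (3.4, 4.5)
    bond_tolerance: float = Field(default=0.02375, gt=0, lt=0.2)
    min_residue_separation: int = Field(default=3, ge=0)

    def to_params(self) -> InteractionParams:
        return InteractionParams(
            w_bb=self.w_bb, w_sc=self.w_sc,
            hb_well=tuple(self.hb_well) if self.hb_well else None,
            bond_tolerance=self.bond_tolerance,
            min_residue_separation=self.min_residue_separation,
        )


class SamplerSection(_Section):
    gamma0: float = Field(default=1.0, gt=0)
    t0: float = Field(default=1.0e4, gt=0)
    gamma_min: float = Field(default=1.0e-7, gt=0)
    move_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    max_displacement: float = Field(default=0.02, gt=0)
    max_pivot_angle: float = Field(default=3.141592653589793, gt=0)
    max_chain_translation: float = Field(default=1.0, gt=0)
    max_chain_rotation: float = Field(default=3.141592653589793, gt=0)
    snapshot_stride: int = Field(default=1000, ge=1)
    snapshot_quota: int = Field(default=20, ge=1)

    @model_validator(mode="after")
    def _check(self):
        if self.gamma_min >= self.gamma0:
            raise ValueError("gamma_min must be < gamma0")
        return self

    def to_samc_config(self, seed: int) -> SamcConfig:
        return SamcConfig(
            gamma0=self.gamma0, t0=self.t0, gamma_min=self.gamma_min,
            move_mix=tuple(self.move_mix),
            max_displacement=self.max_displacement,
            max_pivot_angle=self.max_pivot_angle,
            max_chain_translation=self.max_chain_translation,
            max_chain_rotation=self.max_chain_rotation,
            seed=seed, snapshot_stride=self.snapshot_stride,
            snapshot_quota=self.snapshot_quota,
        )


class BackmapSection(_Section):
    c_o_length: float = Field(default=1.23, gt=0)
    n_h_length: float = Field(default=1.01, gt=0)
    torsion_samples: int = Field(default=36, ge=1)
    clash_fraction: float = Field(default=0.6, gt=0, le=1)
    format: Literal["pdb", "gro"] = "pdb"


class StatsSection(_Section):
    correlation_time: float = Field(default=10.0, gt=0)  # ps
    burn_in: float = Field(default=0.0, ge=0)            # ps discarded upfront
    weighted: bool = False


class RunConfig(_Section):
    """Full pipeline configuration; unknown keys are rejected."""

    sequence: str = "Q" * 26
    n_chains: int = Field(default=2, ge=1)
    box_length: float = Field(default=150.0, gt=0)
    seed: int = 0
    outdir: str = "."
    verbosity: Literal["quiet", "info", "debug"] = "info"
    model: ModelSection = ModelSection()
    sampler: SamplerSection = SamplerSection()
    backmap: BackmapSection = BackmapSection()
    stats: StatsSection = StatsSection()


def load_config(path) -> RunConfig:
    """Load YAML config merged over documented defaults.

    Validation errors name the offending key; an empty file yields defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig(**data)
    except Exception as err:  # pydantic ValidationError carries key names
        raise ConfigError(f"{path}: {err}") from None


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


_STAGES = ("samc", "produce", "backmap", "clashes", "calibrate",
           "trace-stats", "make-trace")


def stage_seed(global_seed: int, stage: str) -> int:
    """Expand one global seed into independent, documented per-stage seeds."""
    if stage not in _STAGES:
        raise ConfigError(f"unknown pipeline stage {stage!r}")
    ss = np.random.SeedSequence(global_seed, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**63))


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline invocation."""

    config_hash: str
    version: str
    stage: str
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    wall_time_s: float = 0.0
    created: float = field(default_factory=time.time)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, indent=1)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")


# -- DOS file format ----------------------------------------------------------

_DOS_MAGIC = "# p20kit-dos v1"


def save_dos(dos: DOSEstimate, path,
             params: InteractionParams | None = None,
             config_digest: str | None = None) -> None:
    """Self-describing text format, one record per level (full precision)."""
    w_bb = params.w_bb if params else 1.0
    w_sc = params.w_sc if params else 0.08
    with open(path, "w") as fh:
        fh.write(_DOS_MAGIC + "\n")
        fh.write(f"# t={dos.t} gamma={dos.gamma!r} "
                 f"total_increment={dos.total_increment!r}\n")
        fh.write(f"# w_bb={w_bb!r} w_sc={w_sc!r}\n")
        if config_digest:
            fh.write(f"# config_hash={config_digest}\n")
        fh.write("# n_backbone n_sidechain energy log_dos visits\n")
        for key in sorted(dos.log_dos):
            nb, ns = key
            energy = -w_bb * nb - w_sc * ns
            fh.write(f"{nb} {ns} {energy!r} {dos.log_dos[key]!r} "
                     f"{dos.visits.get(key, 0)}\n")


def load_dos(path) -> DOSEstimate:
    dos = DOSEstimate()
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or lines[0].strip() != _DOS_MAGIC:
        raise FormatError(f"{path}:1: not a p20kit DOS file")
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# t="):
                try:
                    parts = dict(tok.split("=", 1) for tok in line[2:].split())
                    dos.t = int(parts["t"])
                    dos.gamma = float(parts["gamma"])
                    dos.total_increment = float(parts["total_increment"])
                except (ValueError, KeyError):
                    raise FormatError(f"{path}:{lineno}: malformed header") from None
            continue
        tokens = line.split()
        if len(tokens) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns")
        try:
            nb, ns = int(tokens[0]), int(tokens[1])
            log_dos = float(tokens[3])
            visits = int(tokens[4])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: malformed record") from None
        key = (nb, ns)
        if key in dos.log_dos:
            raise FormatError(f"{path}:{lineno}: duplicate level {key}")
        dos.log_dos[key] = log_dos
        dos.visits[key] = visits
    return dos


# -- snapshot file format -----------------------------------------------------

_SNAP_MAGIC = "# p20kit-snapshots v1"


def save_snapshots(records: list[SnapshotRecord], path,
                   params: InteractionParams | None = None) -> None:
    w_bb = params.w_bb if params else 1.0
    w_sc = params.w_sc if params else 0.08
    with open(path, "w") as fh:
        fh.write(_SNAP_MAGIC + "\n")
        fh.write(f"# w_bb={w_bb!r} w_sc={w_sc!r}\n")
        for rec in records:
            sys_ = rec.system
            fh.write(f"SNAPSHOT step={rec.step} run={rec.run_id} "
                     f"n_backbone={rec.counts.n_backbone} "
                     f"n_sidechain={rec.counts.n_sidechain} "
                     f"energy={rec.energy!r} box={sys_.box_length!r} "
                     f"chains={','.join(sys_.chain_ids)} "
                     f"sequences={','.join(sys_.sequences)}\n")
            for i in range(sys_.n_beads):
                ci = sys_.chain_index[i]
                x, y, z = (float(v) for v in sys_.coords[i])
                fh.write(f"{sys_.chain_ids[ci]} {sys_.residue_index[i]} "
                         f"{BEAD_KINDS[sys_.kind_index[i]]} {x!r} {y!r} {z!r}\n")


def load_snapshots(path) -> list[SnapshotRecord]:
    """Load snapshots; re-verifies the stored energy against the counts."""
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or lines[0].strip() != _SNAP_MAGIC:
        raise FormatError(f"{path}:1: not a p20kit snapshot file")
    w_bb, w_sc = 1.0, 0.08
    records: list[SnapshotRecord] = []
    header: dict | None = None
    beads: list[tuple] = []

    def flush(lineno):
        nonlocal header, beads
        if header is None:
            return
        seqs = header["sequences"]
        expected = sum(len(s) for s in seqs) * BEADS_PER_RESIDUE
        if len(beads) != expected:
            raise FormatError(
                f"{path}:{lineno}: snapshot at step {header['step']} has "
                f"{len(beads)} beads, expected {expected}")
        coords = np.empty((expected, 3))
        chain_order = {cid: k for k, cid in enumerate(header["chains"])}
        for cid, res, kind, x, y, z in beads:
            ci = chain_order[cid]
            offset = sum(len(seqs[k]) for k in range(ci)) * BEADS_PER_RESIDUE
            coords[offset + res * BEADS_PER_RESIDUE + KIND_INDEX[kind]] = (x, y, z)
        system = CGSystem(header["chains"], seqs, coords, header["box"])
        nb, ns = header["nb"], header["ns"]
        expected_e = -w_bb * nb - w_sc * ns
        if abs(header["energy"] - expected_e) > 1e-9:
            raise FormatError(
                f"{path}: snapshot at step {header['step']}: stored energy "
                f"{header['energy']} inconsistent with counts ({nb}, {ns})")
        records.append(SnapshotRecord(system, InteractionCount(nb, ns),
                                      header["energy"], header["step"],
                                      header["run"]))
        header, beads = None, []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "w_bb=" in line:
                try:
                    parts = dict(tok.split("=", 1) for tok in line[2:].split())
                    w_bb = float(parts["w_bb"])
                    w_sc = float(parts["w_sc"])
                except (ValueError, KeyError):
                    raise FormatError(f"{path}:{lineno}: malformed header") from None
            continue
        if line.startswith("SNAPSHOT"):
            flush(lineno)
            try:
                parts = dict(tok.split("=", 1) for tok in line.split()[1:])
                header = {
                    "step": int(parts["step"]),
                    "run": parts["run"],
                    "nb": int(parts["n_backbone"]),
                    "ns": int(parts["n_sidechain"]),
                    "energy": float(parts["energy"]),
                    "box": float(parts["box"]),
                    "chains": parts["chains"].split(","),
                    "sequences": parts["sequences"].split(","),
                }
            except (ValueError, KeyError):
                raise FormatError(f"{path}:{lineno}: malformed snapshot header"
                                  ) from None
            continue
        tokens = line.split()
        if len(tokens) != 6 or header is None:
            raise FormatError(f"{path}:{lineno}: malformed bead record")
        try:
            beads.append((tokens[0], int(tokens[1]), tokens[2],
                          float(tokens[3]), float(tokens[4]), float(tokens[5])))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: malformed bead record") from None
    flush(len(lines))
    return records
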