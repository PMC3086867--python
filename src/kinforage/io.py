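"""Run configuration and plain-text population serialization."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .arena import ArenaConfig
from .genome import N_GENES, Genome
from .relatedness import SCHEME_VOCABULARY


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of an evolution run.

    Defaults reproduce the reference scale: populations of 200 groups of
    8 robots, 500 generations, 20 replicates, 10 evaluation trials,
    mutation 0.005 per bit and crossover 0.005 per founder pair.
    """

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    scheme: str = "r100"
    ratio: float = 0.01
    m: int = 200
    generations: int = 500
    replicates: int = 20
    trials: int = 10
    mutation_rate: float = 0.005
    crossover_rate: float = 0.005
    weight_range: float = 1.0
    seed: int = 1
    out_dir: str = "runs"

    def __post_init__(self):
        if self.scheme not in SCHEME_VOCABULARY:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.ratio < 0:
            raise ValueError("c/b ratio must be nonnegative")
        if min(self.m, self.generations, self.replicates, self.trials) < 1:
            raise ValueError("m, generations, replicates and trials must be >= 1")
        for name in ("mutation_rate", "crossover_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.weight_range <= 0:
            raise ValueError("weight_range must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["arena"] = dataclasses.asdict(self.arena)
        d["arena"]["short_ir_angles_deg"] = list(self.arena.short_ir_angles_deg)
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _reject_unknown(d: dict, allowed, context: str):
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown {context} key(s): {sorted(unknown)}")


def config_from_dict(data: dict | None) -> RunConfig:
    data = dict(data or {})
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    _reject_unknown(data, fields, "config")
    arena_data = dict(data.pop("arena", {}) or {})
    arena_fields = {f.name for f in dataclasses.fields(ArenaConfig)}
    _reject_unknown(arena_data, arena_fields, "arena config")
    if "short_ir_angles_deg" in arena_data:
        arena_data["short_ir_angles_deg"] = tuple(arena_data["short_ir_angles_deg"])
    return RunConfig(arena=ArenaConfig(**arena_data), **data)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def write_manifest(config: RunConfig, path) -> None:
    from . import __version__
    manifest = {"config": config.to_dict(), "config_hash": config.digest(),
                "seed": config.seed, "version": __version__}
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


# ---------------------------------------------------------------------
# Population files: one genome per line, "<group> <33 ints>" or
# "<group> <66 hex chars>"; both forms round-trip losslessly.
# ---------------------------------------------------------------------

def write_population(genes: np.ndarray, groups: np.ndarray, path,
                     fmt: str = "int") -> None:
    """Write genomes with group labels as plain text.

    ``genes`` is (N, 33) uint8 (an (m, n, 33) population is flattened);
    ``groups`` gives the group label of each genome.
    """
    genes = np.asarray(genes, dtype=np.uint8)
    if genes.ndim == 3:
        m, n = genes.shape[:2]
        genes = genes.reshape(m * n, -1)
        if groups is None:
            groups = np.repeat(np.arange(m), n)
    groups = np.asarray(groups)
    if genes.shape[0] != groups.shape[0]:
        raise ValueError("one group label per genome is required")
    if fmt not in ("int", "hex"):
        raise ValueError("fmt must be 'int' or 'hex'")
    with open(path, "w") as fh:
        for g, row in zip(groups, genes):
            if fmt == "hex":
                fh.write(f"{g} {row.tobytes().hex()}\n")
            else:
                fh.write(f"{g} " + " ".join(str(int(v)) for v in row) + "\n")


def read_population(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a population file; returns ((N, 33) uint8 genes, (N,) labels).

    Accepts integer and hex genome lines, also mixed.  Malformed lines
    are reported with their line number.
    """
    genes, labels = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            try:
                if len(tokens) == 2:
                    genes.append(Genome.from_hex(tokens[1]).genes)
                elif len(tokens) == N_GENES + 1:
                    genes.append(Genome([int(t) for t in tokens[1:]]).genes)
                else:
                    raise ValueError(
                        f"expected 2 or {N_GENES + 1} fields, got {len(tokens)}")
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            labels.append(tokens[0])
    if not genes:
        return np.empty((0, N_GENES), dtype=np.uint8), np.empty(0, dtype=object)
    labels = np.asarray(labels)
    try:
        labels = labels.astype(int)
    except ValueError:
        pass
    return np.stack(genes), labels


def write_events(events, path) -> None:
    """Write delivery events (step, world, robot, item, shared) as CSV."""
    with open(path, "w") as fh:
        fh.write("step,world,robot,item,shared\n")
        for step, world, robot, item, shared in events:
            fh.write(f"{int(step)},{int(world)},{int(robot)},{int(item)},{int(shared)}\n")


def population_to_groups(genes: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Reshape a labelled flat population into (m, n, 33) by group label.

    Requires every group to have the same size.
    """
    order = np.argsort(labels, kind="stable")
    genes = np.asarray(genes)[order]
    labels = np.asarray(labels)[order]
    uniq, counts = np.unique(labels, return_counts=True)
    if counts.size == 0:
        raise ValueError("empty population")
    if not (counts == counts[0]).all():
        raise ValueError("groups have unequal sizes")
    return genes.reshape(uniq.size, counts[0], -1)
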