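"""Run configuration and the one-shot analysis driver."""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .hbonds import DEFAULT_ANGLE_MAX, DEFAULT_CUTOFF, detect_hbonds
from .io import (
    read_trajectory,
    write_centers_csv,
    write_centers_pov,
    write_distribution_csv,
    write_metrics_csv,
    write_ring_csv,
)
from .lattice import CrystalSpec, make_ice
from .metrics import OrderRecord, q_per_molecule, rsf
from .pruning import PruneSpec, prune, ring_distribution
from .rings import DEFAULT_MAX_RING, enumerate_rings, ring_centers

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_analysis", "load_config"]


@dataclass
class RunConfig:
    """Everything a reproducible analysis run needs.

    Exactly one of ``input_path`` or ``generate`` must be set.
    """

    input_path: str | None = None
    input_format: str | None = None
    generate: CrystalSpec | None = None
    hbond_cutoff: float = DEFAULT_CUTOFF
    hbond_angle: float = DEFAULT_ANGLE_MAX
    criterion: str = "CA"
    directional: bool = False
    max_ring: int = DEFAULT_MAX_RING
    begin: int = 0
    end: int | None = None
    stride: int = 1
    seed: int = 0
    out_dir: str = "ringorder_out"
    q_mode: str = "nearest4"
    export_centers: str | None = None  # None | "csv" | "pov"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generate is None):
            raise ValueError("set exactly one of input_path or generate")
        if self.hbond_cutoff <= 0 or self.hbond_angle <= 0:
            raise ValueError("thresholds must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def echo(self) -> dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None}


def load_config(path) -> RunConfig:
    """Flat YAML/JSON file mirroring the CLI flags."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "generate" in raw and raw["generate"] is not None:
        raw["generate"] = CrystalSpec(**raw["generate"])
    return RunConfig(**raw)


def _frames(config: RunConfig):
    if config.generate is not None:
        yield make_ice(config.generate)
        return
    it = read_trajectory(config.input_path, config.input_format)
    yield from itertools.islice(it, config.begin, config.end, config.stride)


def run_analysis(config: RunConfig) -> list[OrderRecord]:
    """Analyze every selected frame and write the report bundle.

    Outputs (under ``config.out_dir``): rings.csv, distribution.csv,
    metrics.csv and optionally ring-center exports, all carrying a
    provenance header (tool version + config echo).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.echo()
    spec = PruneSpec(
        criterion=config.criterion,
        directional_only=config.directional,
        max_ring=config.max_ring,
    )
    records: list[OrderRecord] = []
    ring_sets = []
    dist_rows = []
    for frame in _frames(config):
        graph = detect_hbonds(frame, config.hbond_cutoff, config.hbond_angle)
        rings = enumerate_rings(graph, config.max_ring)
        rings.frame_index = frame.frame_index
        pruned = prune(rings, spec)
        dist = ring_distribution(pruned, frame.n_waters)
        q = q_per_molecule(frame, graph, config.q_mode)
        records.append(
            OrderRecord(
                frame_index=frame.frame_index,
                q_per_molecule=q,
                q_mean=float(q.mean()),
                rsf=rsf(prune(rings, PruneSpec("CA", max_ring=config.max_ring)), frame.n_waters)
                if config.criterion != "CA" or config.directional
                else rsf(pruned, frame.n_waters),
                criterion=spec.name,
                n_waters=frame.n_waters,
                ring_counts=pruned.counts_by_size(),
            )
        )
        ring_sets.append(rings)
        for size in sorted(dist.counts):
            dist_rows.append(
                {
                    "frame": frame.frame_index,
                    "criterion": spec.name,
                    "size": size,
                    "count": dist.counts[size],
                    "normalized": dist.normalized[size],
                }
            )
        log.info(
            "frame %d: %d waters, %d H-bonds, %d rings (%d after %s)",
            frame.frame_index,
            frame.n_waters,
            graph.n_edges,
            len(rings),
            len(pruned),
            spec.name,
        )
        if config.export_centers:
            centers = ring_centers(pruned_to_set(pruned, rings), frame)
            base = out / f"centers_{frame.frame_index:05d}"
            if config.export_centers == "csv":
                write_centers_csv(pruned_to_set(pruned, rings), centers, base.with_suffix(".csv"), cfg)
            else:
                write_centers_pov(
                    pruned_to_set(pruned, rings), centers, frame.box, base.with_suffix(".pov"), cfg
                )
    if not records:
        raise ValueError("no frames selected")
    write_ring_csv(ring_sets, out / "rings.csv", cfg)
    write_distribution_csv(dist_rows, out / "distribution.csv", cfg)
    write_metrics_csv(records, out / "metrics.csv", cfg)
    return records


def pruned_to_set(pruned, rings):
    """View a PrunedRingSet as a RingSet (for center computation/export)."""
    from .rings import RingSet

    return RingSet(pruned.rings, rings.max_ring, rings.frame_index)
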