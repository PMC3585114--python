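"""Sweep orchestration: compose the simulation modules into tabular outputs.

Each sweep writes one or more TSV tables plus a JSON manifest recording
every input that shaped the numbers (seed, study design, grids, package
version), because several study-design constants are configuration
choices and their provenance must travel with the output.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import (
    DEFAULT_FREQ_GRID,
    FixationRule,
    initial_frequency_grid,
    quasi_ld,
    run_deterministic,
)
from .gpmaps import CatalogueEntry, build_catalogue
from .ldproj import DEFAULT_R2_GRID, project_map
from .popsim import PopSimConfig, stochastic_power
from .power import DEFAULT_TESTS, StudyDesign, power_sweep
from .varcomp import variance_components

__all__ = ["SweepConfig", "run_figure_sweep", "trajectory_table", "variance_table"]

SWEEP_KINDS = ("trajectories", "variance", "ld_maps", "power_det", "power_stoch")


@dataclass
class SweepConfig:
    kind: str = "trajectories"
    map_ids: Sequence[int] | None = None  # None -> whole catalogue
    freq_grid: Sequence[float] = DEFAULT_FREQ_GRID
    r2_grid: Sequence[float] = DEFAULT_R2_GRID
    design: StudyDesign = field(default_factory=StudyDesign)
    popsim: PopSimConfig = field(default_factory=PopSimConfig)
    max_gen: int = 200
    c: float = 0.5
    N: int = 1000
    seed: int = 0
    outdir: str = "sweep_out"

    def select(self, catalogue: Sequence[CatalogueEntry]) -> list[CatalogueEntry]:
        if self.map_ids is None:
            return list(catalogue)
        wanted = set(self.map_ids)
        return [e for e in catalogue if e.index in wanted]


def trajectory_table(entry: CatalogueEntry, cfg: SweepConfig) -> pd.DataFrame:
    rule = FixationRule(cfg.N)
    frames = []
    for pA0, pB0 in initial_frequency_grid(cfg.freq_grid):
        traj = run_deterministic(
            entry.gpmap, (pA0, pB0, 0.0), c=cfg.c, max_gen=cfg.max_gen, rule=rule
        )
        df = traj.to_frame()
        df.insert(0, "map_id", entry.index)
        df.insert(1, "pA0", pA0)
        df.insert(2, "pB0", pB0)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def variance_table(entry: CatalogueEntry, cfg: SweepConfig) -> pd.DataFrame:
    rule = FixationRule(cfg.N)
    rows = []
    for pA0, pB0 in initial_frequency_grid(cfg.freq_grid):
        traj = run_deterministic(
            entry.gpmap, (pA0, pB0, 0.0), c=cfg.c, max_gen=cfg.max_gen, rule=rule
        )
        for gen, state in enumerate(traj.states):
            if not (0 < state.pA < 1 and 0 < state.pB < 1):
                continue
            if traj.fixed and gen == len(traj.states) - 1:
                continue
            vc = variance_components(entry.gpmap, state)
            D, r2 = quasi_ld(state)
            rows.append(
                {
                    "map_id": entry.index,
                    "pA0": pA0,
                    "pB0": pB0,
                    "gen": gen,
                    **vc.as_dict(),
                    "D": D,
                    "r2": r2,
                }
            )
    return pd.DataFrame(rows)


def _ld_map_table(entry: CatalogueEntry, cfg: SweepConfig) -> pd.DataFrame:
    rows = []
    from .dynamics import state_from_allele_freqs

    state = state_from_allele_freqs(0.5, 0.5, 0.0, c=cfg.c)
    for r2 in cfg.r2_grid:
        r = float(np.sqrt(r2))
        obs = project_map(entry.gpmap, state, r, r)
        for i in range(3):
            for j in range(3):
                rows.append(
                    {
                        "map_id": entry.index,
                        "r2": r2,
                        "row": i,
                        "col": j,
                        "causal": entry.gpmap.values[i, j],
                        "observed": obs.map.values[i, j],
                    }
                )
    return pd.DataFrame(rows)


def run_figure_sweep(kind: str, cfg: SweepConfig) -> dict[str, Path]:
    """Run one sweep kind and write its tables plus a manifest.

    Returns a dict of logical table name to written path.
    """
    if kind not in SWEEP_KINDS:
        raise ValueError(f"unknown sweep kind {kind!r}; choose from {SWEEP_KINDS}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalogue = build_catalogue()
    entries = cfg.select(catalogue)
    written: dict[str, Path] = {}

    if kind == "trajectories":
        df = pd.concat([trajectory_table(e, cfg) for e in entries], ignore_index=True)
        written["trajectories"] = outdir / "trajectories.tsv"
        df.to_csv(written["trajectories"], sep="\t", index=False)
    elif kind == "variance":
        df = pd.concat([variance_table(e, cfg) for e in entries], ignore_index=True)
        written["variance"] = outdir / "variance.tsv"
        df.to_csv(written["variance"], sep="\t", index=False)
    elif kind == "ld_maps":
        df = pd.concat([_ld_map_table(e, cfg) for e in entries], ignore_index=True)
        written["ld_maps"] = outdir / "ld_maps.tsv"
        df.to_csv(written["ld_maps"], sep="\t", index=False)
    elif kind == "power_det":
        df = power_sweep(
            entries,
            freq_grid=initial_frequency_grid(cfg.freq_grid),
            r2_grid=cfg.r2_grid,
            design=cfg.design,
            max_gen=cfg.max_gen,
            c=cfg.c,
            rule=FixationRule(cfg.N),
        )
        written["power_det"] = outdir / "power_det.tsv"
        df.to_csv(written["power_det"], sep="\t", index=False)
    elif kind == "power_stoch":
        frames = []
        rng = np.random.default_rng(cfg.seed)
        for e in entries:
            df = stochastic_power(
                e.gpmap, cfg.popsim, cfg.design, list(DEFAULT_TESTS), seed=rng
            )
            df.insert(0, "map_id", e.index)
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        written["power_stoch"] = outdir / "power_stoch.tsv"
        df.to_csv(written["power_stoch"], sep="\t", index=False)

    manifest = {
        "kind": kind,
        "seed": cfg.seed,
        "map_ids": [e.index for e in entries],
        "freq_grid": list(cfg.freq_grid),
        "r2_grid": list(cfg.r2_grid),
        "design": asdict(cfg.design),
        "popsim": asdict(cfg.popsim),
        "max_gen": cfg.max_gen,
        "c": cfg.c,
        "N": cfg.N,
        "version": __version__,
        "python": platform.python_version(),
        "tables": {k: str(v) for k, v in written.items()},
    }
    manifest_path = outdir / f"manifest_{kind}.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    written["manifest"] = manifest_path
    return written
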