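"""End-to-end orchestration: config, the demo lifespan cohort, and outputs.

``run_atlas`` chains the stages — (optional) demultiplexing, scA/B matrix,
structure typing and staging, contact profiles, and scA/B dynamics — and
writes plain-text tables plus a manifest recording every parameter and
seed, so a rerun of the same config reproduces the statistics byte for
byte.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import select_dynamic_regions, stage_mean_scab, temporal_modes
from .profiles import fraction_long_range, interchrom_enrichment
from .scab import build_scab_matrix
from .staging import embed_cells, stage_abundance, stage_granule_cells
from .synth import make_synthetic_genome, preset_library, simulate_cohort

logger = logging.getLogger(__name__)

# human structural stages peak around these ages (years)
DEMO_STAGE_AGES = (0.2, 1.0, 10.0, 30.0, 80.0)


@dataclass
class RunConfig:
    """Parameters of one atlas run; see field defaults for the demo setup."""

    output_dir: str = "atlas_out"
    seed: int = 0
    # synthetic demo cohort
    demo: bool = True
    species: str = "human"
    cells_per_stage: int = 30
    n_contacts: int = 20_000
    # real-data inputs (used when demo=False)
    assembly_path: str | None = None
    pairs_dir: str | None = None
    reference_bedgraph: str | None = None
    # analysis parameters
    scab_bin_size: int = 1_000_000
    map_bin_size: int = 250_000
    interchrom_bin_size: int = 6_000_000
    n_stages: int = 5
    top_frac: float = 0.20
    min_contacts: int = 5_000
    min_distance: int = 1_000_000
    min_contacts_per_bin: int = 5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.demo:
            for key in ("assembly_path", "pairs_dir", "reference_bedgraph"):
                value = getattr(self, key)
                if value is None:
                    raise ValueError(f"config missing {key} (required when demo=false)")
                if not Path(value).exists():
                    raise ValueError(f"{key} does not exist: {value}")


def _load_cells(config: RunConfig):
    """Either simulate the demo lifespan cohort or load pairs from disk."""
    if config.demo:
        genome = make_synthetic_genome(seed=config.seed)
        lib = preset_library()
        design = [
            (lib[f"{config.species}_granule_S{k + 1}"], config.cells_per_stage, age)
            for k, age in enumerate(DEMO_STAGE_AGES)
        ]
        cells = simulate_cohort(genome, design, config.n_contacts, seed=config.seed)
        return cells, genome.cpg_track, genome.assembly
    from .genome import BinTrack, load_assembly, make_bins, read_pairs

    assembly = load_assembly(config.assembly_path)
    bins = make_bins(assembly, config.scab_bin_size)
    reference = BinTrack.from_bedgraph(config.reference_bedgraph, bins, kind="cpg_density")
    cells = [
        read_pairs(p, assembly, cell_id=p.stem)
        for p in sorted(Path(config.pairs_dir).glob("*.pairs*"))
    ]
    if not cells:
        raise ValueError(f"no .pairs files in {config.pairs_dir}")
    return cells, reference, assembly


def run_atlas(config: RunConfig) -> Path:
    """Run the full pipeline and return the output directory."""
    t0 = time.time()
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage_log: dict = {}

    def _mark(stage):
        stage_log[stage] = round(time.time() - t0, 3)
        logger.info("stage %s done at %.1fs", stage, stage_log[stage])

    try:
        cells, reference, assembly = _load_cells(config)
        _mark("load")

        matrix = build_scab_matrix(
            cells,
            reference,
            min_distance=config.min_distance,
            min_contacts_per_bin=config.min_contacts_per_bin,
            min_contacts=min(config.min_contacts, config.n_contacts if config.demo else 10**9),
        )
        matrix.to_tsv(out / "scab_matrix.tsv", out / "scab_params.json")
        _mark("scab")

        ages = (
            matrix.meta["age"].to_numpy(float)
            if matrix.meta is not None and "age" in matrix.meta
            else None
        )
        stages = stage_granule_cells(matrix, ages=ages, k=config.n_stages)
        emb = embed_cells(matrix, ages=ages)
        assign = pd.DataFrame(
            {
                "cell_id": matrix.cell_ids,
                "stage": stages,
                "x": emb.coords[:, 0],
                "y": emb.coords[:, 1],
            }
        )
        if ages is not None:
            assign["age"] = ages
        assign.to_csv(out / "assignments.tsv", sep="\t", index=False)
        if ages is not None:
            ab = stage_abundance(stages, ages)
            ab.curves.to_csv(out / "stage_abundance.tsv", sep="\t", index_label="age")
        _mark("staging")

        frac = pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in cells],
                "fraction_ge_10mb": [fraction_long_range(c) for c in cells],
                "stage": pd.Series(stages, index=matrix.cell_ids)
                .reindex([c.cell_id for c in cells])
                .to_numpy(),
            }
        )
        frac.to_csv(out / "fraction_long_range.tsv", sep="\t", index=False)
        summary = frac.groupby("stage", dropna=True)["fraction_ge_10mb"].agg(
            ["mean", "std", "count"]
        )
        summary.to_csv(out / "fraction_long_range_by_stage.tsv", sep="\t")
        by_id = {c.cell_id: c for c in cells}
        enr_tables = {}
        for s in sorted(set(stages)):
            group = [by_id[cid] for cid, st in zip(matrix.cell_ids, stages) if st == s]
            if any((~c.is_intra).any() for c in group):
                enr_tables[s] = interchrom_enrichment(group, assembly).to_frame()
        if enr_tables:
            pd.concat(enr_tables, names=["stage", "chrom"]).to_csv(
                out / "interchrom_enrichment.tsv", sep="\t"
            )
        _mark("profiles")

        sm = stage_mean_scab(matrix, stages)
        dyn = select_dynamic_regions(sm, top_frac=config.top_frac)
        modes = temporal_modes(sm, dyn.selected)
        table = sm.means.loc[dyn.selected].copy()
        table.insert(0, "variance", dyn.variance.loc[dyn.selected])
        table.insert(1, "mode", modes)
        table.to_csv(out / "dynamic_regions.tsv", sep="\t", index_label="bin")
        _mark("dynamics")
    except Exception:
        logger.exception("pipeline failed after stages %s", list(stage_log))
        raise

    manifest = {
        "chromatlas_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "config": asdict(config),
        "stage_seconds": stage_log,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
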