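"""End-to-end study pipeline: segment, compare, partition, map, organize.

Runs every analysis stage from one configuration — segmentation into
sequences, the pairwise LSI matrix and its group means, the
order-permutation null with Z-tests, the nested AMOVA on 1 - LSI (both
squared- and raw-distance modes), Mantel tests against geographic
distance, and the immediate-repetition and acoustic-contrast tests — and
writes each result as CSV plus one JSON report holding every statistic,
seed and decision toggle. All randomness flows from a single master seed
recorded in the report, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as vio
from .amova import amova_nested
from .geography import geodesic_matrix, mantel_test
from .organization import (
    contrast_permutation_test,
    contrast_table,
    repetition_permutation_test,
)
from .segmentation import segment_dataset
from .similarity import GROUPS, group_means, pairwise_lsi, permutation_null_lsi
from .synthetic import SyntheticConfig, generate_dataset
from .types import MimeticSequence, StudyDesign

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One replication run: inputs, seeds, permutation counts and toggles."""

    out_dir: str = "vocalseq_results"
    seed: int = 0
    # input: either synthetic generation or files
    synthetic: Optional[SyntheticConfig] = field(default_factory=SyntheticConfig)
    selection_tables: Optional[List[dict]] = None  # [{path, bird_id, population_id}]
    population_map: Optional[str] = None
    coordinates: Optional[str] = None
    population_distances: Optional[str] = None
    # permutation counts
    n_perm_lsi: int = 1000
    n_perm_amova: int = 999
    n_perm_mantel: int = 1000
    n_perm_organization: int = 1000
    # decision toggles
    split_unit_override: Optional[str] = None
    drop_last: str = "per_bout"
    keep_unknown_units: bool = True
    min_sequence_length: int = 1
    group_weighting: str = "pooled"
    square_distances: bool = True
    mantel_alternative: str = "less"
    skip_nonvocal_for_adjacency: bool = False
    pooled_pairs_contrast: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        elif raw.get("selection_tables"):
            raw["synthetic"] = None
        return cls(**raw)

    def toggles(self) -> dict:
        return {
            "split_unit_override": self.split_unit_override,
            "drop_last": self.drop_last,
            "keep_unknown_units": self.keep_unknown_units,
            "min_sequence_length": self.min_sequence_length,
            "group_weighting": self.group_weighting,
            "square_distances": self.square_distances,
            "mantel_alternative": self.mantel_alternative,
            "skip_nonvocal_for_adjacency": self.skip_nonvocal_for_adjacency,
            "pooled_pairs_contrast": self.pooled_pairs_contrast,
        }


def _load_inputs(cfg: RunConfig, seed: int):
    if cfg.synthetic is not None:
        ds = generate_dataset(cfg.synthetic, seed=seed)
        return ds.bouts_by_bird, ds.design
    if not cfg.selection_tables or not cfg.population_map:
        raise ValueError(
            "configuration needs either a synthetic block or "
            "selection_tables + population_map"
        )
    pop_map = vio.read_population_map(cfg.population_map)
    bouts: Dict[str, list] = {}
    for entry in cfg.selection_tables:
        bird = entry["bird_id"]
        bout = vio.read_selection_table(
            entry["path"],
            vio.SelectionTableColumns(**entry.get("columns", {})),
            bird_id=bird,
            population_id=pop_map[bird],
        )
        bouts.setdefault(bird, []).append(bout)
    coords = vio.read_coordinates(cfg.coordinates) if cfg.coordinates else None
    pop_dist = (
        vio.read_distance_matrix(cfg.population_distances)
        if cfg.population_distances
        else None
    )
    design = vio.make_design(pop_map, coords, pop_dist)
    return bouts, design


def _mean_lsi_between(matrix, ids_a, ids_b, labels) -> float:
    la = np.asarray(labels, dtype=object)
    ia = np.flatnonzero(la == ids_a)
    ib = np.flatnonzero(la == ids_b)
    return float(matrix[np.ix_(ia, ib)].mean())


def run_all(cfg: RunConfig) -> dict:
    """Run every stage, write outputs under ``cfg.out_dir``, return the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(cfg.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("lsi", "amova", "mantel", "organization", "synthetic"),
            master.spawn(5),
        )
    }
    report: dict = {
        "master_seed": cfg.seed,
        "stage_seeds": stage_seeds,
        "toggles": cfg.toggles(),
        "n_permutations": {
            "lsi": cfg.n_perm_lsi,
            "amova": cfg.n_perm_amova,
            "mantel": cfg.n_perm_mantel,
            "organization": cfg.n_perm_organization,
        },
    }

    bouts_by_bird, design = _load_inputs(cfg, stage_seeds["synthetic"])

    # --- segmentation ---------------------------------------------------
    sequences, seg_report = segment_dataset(
        bouts_by_bird,
        split_unit=cfg.split_unit_override,
        drop_last=cfg.drop_last,
        keep_unknown=cfg.keep_unknown_units,
        min_sequence_length=cfg.min_sequence_length,
    )
    design.validate_sequences(sequences)
    vio.write_sequences(sequences, out / "sequences.txt")
    report["segmentation"] = seg_report.as_dict()
    report["n_sequences"] = len(sequences)
    report["n_birds"] = len({s.bird_id for s in sequences})
    report["mean_sequences_per_bird"] = len(sequences) / report["n_birds"]
    report["total_units"] = sum(len(s) for s in sequences)

    # --- LSI matrix, group means, permutation null ----------------------
    matrix = pairwise_lsi(sequences)
    pd.DataFrame(matrix.values).to_csv(out / "lsi_matrix.csv", index=False)
    gm = group_means(matrix, weighting=cfg.group_weighting)
    pd.DataFrame(gm.as_rows()).to_csv(out / "table1_group_means.csv", index=False)
    cond = matrix.condensed()
    report["n_pairwise_comparisons"] = matrix.n_pairs
    report["overall_mean_lsi"] = float(cond.mean())
    report["overall_sd_lsi"] = float(cond.std(ddof=1))
    report["group_means"] = {
        g: {"mean": gm.mean[g], "sd": gm.sd[g], "n_pairs": gm.n_pairs[g]}
        for g in GROUPS
    }
    perm = permutation_null_lsi(sequences, cfg.n_perm_lsi, stage_seeds["lsi"])
    report["lsi_permutation"] = {
        g: dataclasses.asdict(perm[g]) for g in GROUPS
    }
    pd.DataFrame(
        [{"group": g, **dataclasses.asdict(perm[g])} for g in GROUPS]
    ).to_csv(out / "lsi_permutation.csv", index=False)

    # --- AMOVA (both distance modes) ------------------------------------
    birds = [s.bird_id for s in sequences]
    pops = [s.population_id for s in sequences]
    report["amova"] = {}
    amova_frames = []
    for mode, squared in (("squared", True), ("raw", False)):
        res = amova_nested(
            matrix.dissimilarity(),
            birds,
            pops,
            n_perm=cfg.n_perm_amova,
            seed=stage_seeds["amova"],
            square_distances=squared,
        )
        rows = pd.DataFrame(res.as_rows())
        rows.insert(0, "distance_mode", mode)
        amova_frames.append(rows)
        report["amova"][mode] = {
            "df": res.df,
            "ssd": res.ssd,
            "variance_components": res.variance_components,
            "pct_variance": res.pct_variance,
            "phi_ct": res.phi_ct,
            "phi_sc": res.phi_sc,
            "phi_st": res.phi_st,
            "p_values": res.p_values,
            "warnings": res.warnings,
        }
    pd.concat(amova_frames).to_csv(out / "table2_amova.csv", index=False)

    # --- geography -------------------------------------------------------
    report["mantel"] = {}
    if design.coordinates:
        mantel_rows = []
        bird_mean: Dict[str, Dict[str, float]] = {}
        bird_ids = sorted({s.bird_id for s in sequences})
        for pop in sorted({s.population_id for s in sequences}):
            pop_birds = [b for b in bird_ids if design.bird_to_population[b] == pop]
            if len(pop_birds) < 3:
                continue
            n = len(pop_birds)
            sim = np.ones((n, n))
            for a in range(n):
                for b in range(a + 1, n):
                    m = _mean_lsi_between(
                        matrix.values, pop_birds[a], pop_birds[b], matrix.bird_ids
                    )
                    sim[a, b] = sim[b, a] = m
            geo, kept = geodesic_matrix(design.coordinates, pop_birds)
            if len(kept) != n:
                sel = [pop_birds.index(k) for k in kept]
                sim = sim[np.ix_(sel, sel)]
            try:
                mr = mantel_test(
                    sim,
                    geo,
                    cfg.n_perm_mantel,
                    stage_seeds["mantel"],
                    alternative=cfg.mantel_alternative,
                )
            except ValueError as exc:
                logger.warning("Mantel test skipped for %s: %s", pop, exc)
                continue
            row = {"scope": pop, **dataclasses.asdict(mr)}
            mantel_rows.append(row)
            report["mantel"][pop] = dataclasses.asdict(mr)
        # between populations: mean LSI between population pairs vs distance
        pop_ids = sorted({s.population_id for s in sequences})
        if len(pop_ids) >= 3:
            npop = len(pop_ids)
            sim = np.ones((npop, npop))
            for a in range(npop):
                for b in range(a + 1, npop):
                    la = np.asarray(matrix.population_ids, dtype=object)
                    ia = np.flatnonzero(la == pop_ids[a])
                    ib = np.flatnonzero(la == pop_ids[b])
                    v = float(matrix.values[np.ix_(ia, ib)].mean())
                    sim[a, b] = sim[b, a] = v
            if design.population_distances:
                geo = np.array(
                    [
                        [design.population_distances[a][b] if a != b else 0.0
                         for b in pop_ids]
                        for a in pop_ids
                    ]
                )
            else:
                centroids = {
                    p: tuple(
                        np.mean(
                            [design.coordinates[b] for b in bird_ids
                             if design.bird_to_population[b] == p],
                            axis=0,
                        )
                    )
                    for p in pop_ids
                }
                geo, _ = geodesic_matrix(centroids, pop_ids)
            mr = mantel_test(
                sim,
                geo,
                cfg.n_perm_mantel,
                stage_seeds["mantel"],
                alternative=cfg.mantel_alternative,
            )
            mantel_rows.append({"scope": "between_populations", **dataclasses.asdict(mr)})
            report["mantel"]["between_populations"] = dataclasses.asdict(mr)
        if mantel_rows:
            pd.DataFrame(mantel_rows).to_csv(out / "mantel.csv", index=False)

    # --- sequence organization ------------------------------------------
    rep = repetition_permutation_test(
        sequences,
        cfg.n_perm_organization,
        stage_seeds["organization"],
        skip_nonvocal_for_adjacency=cfg.skip_nonvocal_for_adjacency,
    )
    report["repetition"] = dataclasses.asdict(rep)
    contrast = contrast_permutation_test(
        sequences,
        cfg.n_perm_organization,
        stage_seeds["organization"],
        group_by="population",
    )
    contrast_table(contrast).to_csv(out / "table3_contrast.csv", index=False)
    report["acoustic_contrast"] = {
        f"{r.group}:{r.variable}": {
            "measured": r.observed_mean,
            "measured_sd": r.observed_sd,
            "expected": r.perm_mean,
            "z": r.z,
            "p": r.p,
        }
        for r in contrast
    }

    (out / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n"
    )
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    return obj
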