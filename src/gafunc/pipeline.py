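"""End-to-end driver: simulate → reduce → standardize → fit → importance.

A single :class:`PipelineConfig` (YAML round-trippable) fixes every stage;
one master seed deterministically derives the per-stage seeds through a
documented counter scheme, so any stage can be rerun in isolation and the
whole report is byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from numpy.random import SeedSequence

from . import io as gio
from .enface import (
    ALL_FEATURES,
    EnFaceMap,
    Feature,
    RAW_FEATURES,
    SegVolume,
    build_enface,
    derive_rora,
    lesion_area,
)
from .grid import EtdrsLabels, StandardGrid, etdrs_labels, foveal_involvement, region_means, standardize
from .importance import (
    ImportanceResult,
    aggregate_by_region,
    collect_importance,
    foveal_shares,
    render_heatmap,
    with_margins,
)
from .model import BootstrapResult, bootstrap_evaluate, build_feature_table, sensitivity_one_eye
from .synth import SynthConfig, generate_cohort

logger = logging.getLogger(__name__)

#: Stage counters for master-seed -> per-stage seed derivation.
STAGE_INDEX = {"simulate": 0, "fit": 1, "one_eye": 2, "permute": 3}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive the deterministic seed of a named pipeline stage (< 2^31)."""
    ss = SeedSequence(entropy=master_seed, spawn_key=(STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """Everything that fixes one pipeline run."""

    seed: int = 0
    threshold: float = 0.5
    resolution: Tuple[int, int] = (49, 49)
    extent_mm: float = 3.0
    downsample_k: int = 7
    outcome: str = "va_letters"
    n_replicates: int = 100
    train_frac: float = 0.8
    split_unit: str = "patient"
    scheme: str = "bootstrap"
    one_eye_per_patient: bool = False
    synth: SynthConfig = field(default_factory=SynthConfig)

    def __post_init__(self) -> None:
        self.resolution = tuple(self.resolution)
        if isinstance(self.synth, Mapping):
            self.synth = SynthConfig(**self.synth)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["resolution"] = list(self.resolution)
        d["synth"] = self.synth.to_dict()
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg_synth = dict(raw.pop("synth", {}))
        from .synth import BetaLLD, BetaVA

        if "beta_va" in cfg_synth:
            cfg_synth["beta_va"] = BetaVA(**cfg_synth["beta_va"])
        if "beta_lld" in cfg_synth:
            cfg_synth["beta_lld"] = BetaLLD(**cfg_synth["beta_lld"])
        if "grid_shape" in cfg_synth:
            cfg_synth["grid_shape"] = tuple(cfg_synth["grid_shape"])
        if "n_seeds_range" in cfg_synth:
            cfg_synth["n_seeds_range"] = tuple(cfg_synth["n_seeds_range"])
        return cls(synth=SynthConfig(**cfg_synth), **raw)


def reduce_volumes(
    volumes: Mapping[str, Mapping[Feature, SegVolume]], threshold: float = 0.5
) -> Tuple[Dict[str, Dict[Feature, EnFaceMap]], pd.DataFrame]:
    """En-face maps (three raw + derived RORA) and the per-eye area table."""
    maps: Dict[str, Dict[Feature, EnFaceMap]] = {}
    rows = []
    for eye_id in sorted(volumes):
        feats = {feat: build_enface(volumes[eye_id][feat]) for feat in RAW_FEATURES}
        feats[Feature.RORA] = derive_rora(
            feats[Feature.RPE_LOSS],
            feats[Feature.PDR],
            feats[Feature.HYPERTRANSMISSION],
        )
        maps[eye_id] = feats
        rows.append(
            {
                "eye_id": eye_id,
                **{
                    f"{feat.value}_area_mm2": lesion_area(feats[feat], threshold)
                    for feat in ALL_FEATURES
                },
            }
        )
    return maps, pd.DataFrame(rows)


def standardize_cohort(
    maps: Mapping[str, Mapping[Feature, EnFaceMap]],
    resolution: Tuple[int, int] = (49, 49),
    extent_mm: float = 3.0,
) -> Dict[str, Dict[Feature, StandardGrid]]:
    """Fovea-centred standard grids for every eye and feature."""
    return {
        eye_id: {
            feat: standardize(m, resolution, extent_mm)
            for feat, m in maps[eye_id].items()
        }
        for eye_id in sorted(maps)
    }


def cohort_sparing_percent(
    grids: Mapping[str, Mapping[Feature, StandardGrid]],
    labels: EtdrsLabels,
    threshold: float = 0.5,
) -> float:
    """Percentage of eyes whose RORA wholly spares the foveal subfield."""
    spared = sum(
        not foveal_involvement(grids[eye][Feature.RORA], labels, threshold)
        for eye in grids
    )
    return 100.0 * spared / len(grids)


def run_pipeline(config: PipelineConfig, outdir: Optional[Path] = None) -> dict:
    """Execute the full synthetic pipeline and assemble the report.

    Stages: simulate → en-face reduction (+areas) → standardization →
    feature table → bootstrapped random forest → importance aggregation.
    The report carries cohort summaries, model metrics, the region x
    feature importance matrix, foveal shares and full provenance. When
    ``outdir`` is given, all tables, the report and the heatmaps are
    written there.
    """
    import sklearn

    synth_cfg = replace(config.synth, rng_seed=stage_seed(config.seed, "simulate"))
    cohort = generate_cohort(synth_cfg)
    n_eyes = len(cohort.outcomes)
    logger.info("simulated %d eyes / %d patients", n_eyes, config.synth.n_patients)

    maps, areas = reduce_volumes(cohort.volumes, config.threshold)
    grids = standardize_cohort(maps, config.resolution, config.extent_mm)
    labels = etdrs_labels(config.resolution, config.extent_mm)

    table = build_feature_table(
        grids, cohort.outcomes, outcome=config.outcome, downsample_k=config.downsample_k
    )
    fit_seed = stage_seed(config.seed, "fit")
    eval_kwargs = dict(
        n_replicates=config.n_replicates,
        train_frac=config.train_frac,
        split_unit=config.split_unit,
        scheme=config.scheme,
    )
    if config.one_eye_per_patient:
        result = sensitivity_one_eye(table, seed=fit_seed, **eval_kwargs)
    else:
        result = bootstrap_evaluate(table, seed=fit_seed, **eval_kwargs)

    imp = collect_importance(result, extent_mm=config.extent_mm)
    region = aggregate_by_region(imp)
    shares = foveal_shares(region)

    area_cols = {feat: f"{feat.value}_area_mm2" for feat in ALL_FEATURES}
    report = {
        "cohort": {
            "n_eyes": int(n_eyes),
            "n_patients": int(cohort.outcomes["patient_id"].nunique()),
            "median_areas_mm2": {
                feat.value: float(areas[col].median()) for feat, col in area_cols.items()
            },
            "foveal_sparing_percent": cohort_sparing_percent(
                grids, labels, config.threshold
            ),
            "outcome_summary": {
                col: {
                    "mean": float(cohort.outcomes[col].mean()),
                    "sd": float(cohort.outcomes[col].std()),
                    "median": float(cohort.outcomes[col].median()),
                }
                for col in ("va_letters", "llva_letters", "lld_letters")
            },
        },
        "model": result.summary,
        "importance_by_region": with_margins(region).round(6).to_dict(),
        "outside_importance_pct": region.attrs["outside_pct"],
        "shares": shares,
        "provenance": {
            "config": config.to_dict(),
            "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_INDEX},
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "sklearn": sklearn.__version__,
            },
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.save_cohort(cohort, outdir / "cohort")
        areas.to_csv(outdir / "areas.csv", index=False)
        mean_rows = []
        for eye_id in sorted(grids):
            for feat, sg in grids[eye_id].items():
                means = region_means(sg, labels)
                mean_rows.append(
                    {"eye_id": eye_id, "feature": feat.value, **means.to_dict()}
                )
        pd.DataFrame(mean_rows).to_csv(outdir / "region_means.csv", index=False)
        with_margins(region).to_csv(outdir / "importance_by_region.csv")
        gio.write_json(result.to_dict(include_importances=False), outdir / "result.json")
        gio.write_json(shares, outdir / "shares.json")
        render_heatmap(imp, outdir / "importance_heatmap.png")
        gio.write_json(report, outdir / "report.json")
    return report
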