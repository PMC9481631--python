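"""Synthetic geographic-atrophy cohorts with a known structure–function law.

Real GA imaging datasets with paired visual-function measurements are not
publicly distributable, so every downstream stage of this package is
exercised on simulated cohorts. The generator emulates the salient
statistics of a large clinical GA cohort:

* per-eye lesion probability rasters for the three raw features, with the
  empirical nesting photoreceptor degeneration ⊃ hypertransmission ⊃
  RPE-loss (on average) and cohort median areas calibrated to published
  values (RPE-loss 7.82 mm², photoreceptor degeneration 14.4 mm²,
  hypertransmission 9.23 mm²; derived RORA lands near 6.22 mm²);
* a fovea-involving-or-sparing spatial distribution, with roughly 15 % of
  eyes wholly sparing the central 1-mm disc at the default seed scatter;
* bilateral eyes that share a patient-level lesion-burden random effect,
  so patient-level evaluation splits are meaningfully different from
  eye-level splits;
* visual acuity (VA), low-luminance visual acuity (LLVA) and low-luminance
  deficit (LLD = VA − LLVA) in ETDRS letters, generated from a configurable
  linear law: VA falls with mean foveal RORA probability and extrafoveal
  RORA area; LLD rises with mean parafoveal photoreceptor degeneration.

Lesion morphology is a deliberately simple texture model — a smoothed
union of radial kernels ("blobs") with a noisy boundary — chosen as the
cheapest construction that produces confluent, fovea-involving-or-sparing
lesions with the required feature nesting. Per-eye feature areas are drawn
from lognormal distributions around the calibration targets and the blob
radii / halo widths are then solved by bisection, so cohort medians track
the targets without hand-tuned intensity constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy.ndimage import distance_transform_edt, gaussian_filter

from . import grid as gridmod
from .enface import (
    DEFAULT_THRESHOLD,
    Feature,
    Laterality,
    RAW_FEATURES,
    SegVolume,
    build_enface,
    derive_rora,
)

#: Published cohort median lesion areas (mm²) used as calibration targets.
DEFAULT_TARGET_MEDIAN_AREAS_MM2: Dict[Feature, float] = {
    Feature.RPE_LOSS: 7.82,
    Feature.PDR: 14.4,
    Feature.HYPERTRANSMISSION: 9.23,
    Feature.RORA: 6.22,
}

#: Soft-boundary width (mm) converting signed lesion fields to probabilities.
_EDGE_WIDTH_MM = 0.06

# rng stream salts: lesions, patient structure, outcome noise
_SALT_LESIONS, _SALT_STRUCTURE, _SALT_OUTCOME = 11, 13, 17


@dataclass
class BetaVA:
    """Linear law for standard visual acuity (ETDRS letters).

    ``va = intercept − foveal_rora * (mean foveal RORA probability)
    − extrafoveal_rora_area * (extrafoveal RORA area, mm²) + noise``,
    clamped to [0, 100].
    """

    intercept_letters: float = 80.0
    foveal_rora_coef: float = 35.0
    extrafoveal_rora_area_coef: float = 0.8


@dataclass
class BetaLLD:
    """Linear law for the low-luminance deficit (ETDRS letters).

    ``lld = intercept + parafoveal_pdr * (mean parafoveal photoreceptor-
    degeneration probability) + noise``, clamped to [0, va]. LLVA is then
    ``va − lld``.
    """

    intercept_letters: float = 0.0
    parafoveal_pdr_coef: float = 38.0


@dataclass
class SynthConfig:
    """Study conditions for a synthetic GA cohort.

    Defaults emulate the published cohort: ~46.5 % of patients contribute
    both eyes (476 eyes from 325 patients), lesion-area medians match the
    published Table of feature areas, and outcome noise is set so that
    bootstrapped random-forest r² lands in the published 0.25–0.46 band.
    """

    n_patients: int = 205
    frac_bilateral: float = 0.465
    grid_shape: Tuple[int, int] = (49, 49)
    field_mm: float = 6.0
    n_seeds_range: Tuple[int, int] = (1, 3)
    target_median_areas_mm2: Dict[Feature, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_MEDIAN_AREAS_MM2)
    )
    #: lognormal sigma of the shared per-eye area multiplier
    area_sigma_log: float = 0.45
    #: lognormal sigma of the patient-level burden shared by fellow eyes
    patient_effect_sigma_log: float = 0.25
    #: SD (mm) of Gaussian seed scatter around the fovea; larger values
    #: increase foveal sparing (the sparing-bias knob)
    seed_scatter_sd_mm: float = 1.15
    #: amplitude (mm) of the hypertransmission boundary perturbation
    ht_noise_mm: float = 0.35
    beta_va: BetaVA = field(default_factory=BetaVA)
    beta_lld: BetaLLD = field(default_factory=BetaLLD)
    noise_sd_letters: float = 15.0
    threshold: float = DEFAULT_THRESHOLD
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.frac_bilateral <= 1.0:
            raise ValueError("frac_bilateral must lie in [0, 1]")
        if self.field_mm <= 0:
            raise ValueError("field_mm must be positive")
        self.target_median_areas_mm2 = {
            Feature(k): float(v) for k, v in self.target_median_areas_mm2.items()
        }
        max_area = self.field_mm**2
        for feat, a in self.target_median_areas_mm2.items():
            if not 0.0 < a <= max_area:
                raise ValueError(f"target area for {feat.value} outside (0, {max_area}]")
        lo, hi = self.n_seeds_range
        if lo < 0 or hi < lo:
            raise ValueError("n_seeds_range must be a non-negative integer range")
        for intercept in (
            self.beta_va.intercept_letters,
            self.beta_lld.intercept_letters,
        ):
            if not 0.0 <= intercept <= 100.0:
                raise ValueError("intercepts must lie in [0, 100] letters")
        if self.noise_sd_letters < 0:
            raise ValueError("noise_sd_letters must be >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target_median_areas_mm2"] = {
            k.value: v for k, v in self.target_median_areas_mm2.items()
        }
        return d


@dataclass
class SynthCohort:
    """A generated cohort: lesion volumes, outcomes, and generating truth."""

    volumes: Dict[str, Dict[Feature, SegVolume]]
    outcomes: pd.DataFrame
    truth: dict
    config: SynthConfig

    @property
    def eye_ids(self) -> Tuple[str, ...]:
        return tuple(self.outcomes["eye_id"])


def _rng(config: SynthConfig, salt: int, index: int = 0) -> Generator:
    return default_rng(SeedSequence(entropy=config.rng_seed, spawn_key=(salt, index)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _bisect_area(fn, lo: float, hi: float, target: float, iters: int = 40) -> float:
    """Solve fn(s) ~= target for a monotone non-decreasing area function."""
    if fn(hi) <= target:
        return hi
    if fn(lo) >= target:
        return lo
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if fn(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _zero_volumes(config: SynthConfig, fovea, laterality) -> Dict[Feature, SegVolume]:
    zero = np.zeros(config.grid_shape)
    return {
        feat: SegVolume(
            feature=feat,
            data=zero.copy(),
            laterality=laterality,
            fovea_xy_mm=fovea,
            field_mm=(config.field_mm, config.field_mm),
        )
        for feat in RAW_FEATURES
    }


def generate_lesions(
    config: SynthConfig,
    eye_index: int,
    burden: float = 1.0,
    laterality: Laterality = Laterality.OD,
    rng: Optional[Generator] = None,
) -> Dict[Feature, SegVolume]:
    """Generate the three raw feature probability rasters for one eye.

    Construction: ``K`` lesion seeds are scattered around the fovea
    (Gaussian scatter, SD ``seed_scatter_sd_mm``); the RPE-loss support is
    the union of radial kernels with a smooth boundary texture, its size
    solved so the thresholded area matches a lognormal draw around the
    calibration target scaled by the patient ``burden``. Photoreceptor
    degeneration is the RPE-loss support dilated by a halo (plus occasional
    independent patches); hypertransmission is the RPE-loss support with a
    perturbed boundary, so the derived RORA (cell-wise minimum) loses thin
    rim regions and falls slightly below the RPE-loss area.

    A degenerate draw with an empty support is resampled a few times, then
    emitted as an (legal) empty lesion.
    """
    if rng is None:
        rng = _rng(config, _SALT_LESIONS, eye_index)
    n = config.grid_shape
    cell = config.field_mm / n[1]
    cell_area = (config.field_mm / n[0]) * (config.field_mm / n[1])
    fovea = tuple(
        np.clip(
            config.field_mm / 2.0 + rng.normal(0.0, 0.1, size=2),
            0.5,
            config.field_mm - 0.5,
        )
    )
    lo, hi = config.n_seeds_range
    targets = config.target_median_areas_mm2

    for _attempt in range(5):
        K = int(rng.integers(lo, hi + 1))
        if K == 0:
            return _zero_volumes(config, fovea, laterality)

        centre = np.array([config.field_mm / 2.0, config.field_mm / 2.0])
        seeds = centre + rng.normal(0.0, config.seed_scatter_sd_mm, size=(K, 2))
        seeds = np.clip(seeds, 0.2, config.field_mm - 0.2)
        rel_r = rng.uniform(0.5, 1.0, size=K)

        # shared lognormal multiplier -> correlated per-eye feature areas
        m = float(np.exp(rng.normal(0.0, config.area_sigma_log))) * burden
        max_a = 0.80 * config.field_mm**2
        a_rpe = float(np.clip(targets[Feature.RPE_LOSS] * m, 0.02, 0.72 * config.field_mm**2))
        a_pdr = float(
            np.clip(
                targets[Feature.PDR] * m * np.exp(rng.normal(0.0, 0.15)),
                1.02 * a_rpe,
                max_a,
            )
        )
        a_ht = float(
            np.clip(
                targets[Feature.HYPERTRANSMISSION] * m * np.exp(rng.normal(0.0, 0.15)),
                0.98 * a_rpe,
                a_pdr,
            )
        )

        X, Y = np.meshgrid(
            (np.arange(n[1]) + 0.5) * (config.field_mm / n[1]),
            (np.arange(n[0]) + 0.5) * (config.field_mm / n[0]),
        )
        dists = np.stack(
            [np.hypot(X - sx, Y - sy) for sx, sy in seeds]
        )  # (K, rows, cols)
        tex = gaussian_filter(rng.standard_normal(n), sigma=3.0)
        tex *= 0.15 / max(tex.std(), 1e-9)

        def rpe_field(s: float) -> np.ndarray:
            return (s * rel_r[:, None, None] - dists).max(axis=0) + tex

        def rpe_area(s: float) -> float:
            return float((rpe_field(s) >= 0).sum()) * cell_area

        s = _bisect_area(rpe_area, 0.05, 10.0, a_rpe)
        f_rpe = rpe_field(s)
        support = f_rpe >= 0
        if support.any():
            break
    else:
        return _zero_volumes(config, fovea, laterality)

    # signed distance to the RPE-loss support boundary (negative inside)
    d_out = distance_transform_edt(~support) * cell
    d_in = distance_transform_edt(support) * cell
    phi = d_out - d_in

    # photoreceptor degeneration: halo dilation plus optional free patches
    patch_field = np.full(n, -np.inf)
    if rng.random() < 0.5:
        for _ in range(int(rng.integers(1, 3))):
            px, py = rng.uniform(0.2, config.field_mm - 0.2, size=2)
            pr = rng.uniform(0.2, 0.7)
            patch_field = np.maximum(patch_field, pr - np.hypot(X - px, Y - py))

    def pdr_area(h: float) -> float:
        return float((np.maximum(h - phi, patch_field) >= 0).sum()) * cell_area

    h = _bisect_area(pdr_area, 0.0, 5.0, a_pdr)
    f_pdr = np.maximum(h - phi, patch_field)

    # hypertransmission: boundary-perturbed copy of the RPE-loss support
    g = gaussian_filter(rng.standard_normal(n), sigma=3.5)
    g *= config.ht_noise_mm / max(g.std(), 1e-9)

    def ht_area(mh: float) -> float:
        return float((mh + g - phi >= 0).sum()) * cell_area

    mh = _bisect_area(ht_area, -2.0, 3.0, a_ht)
    f_ht = mh + g - phi

    fields = {Feature.RPE_LOSS: f_rpe, Feature.PDR: f_pdr, Feature.HYPERTRANSMISSION: f_ht}
    return {
        feat: SegVolume(
            feature=feat,
            data=_sigmoid(fields[feat] / _EDGE_WIDTH_MM),
            laterality=laterality,
            fovea_xy_mm=fovea,
            field_mm=(config.field_mm, config.field_mm),
        )
        for feat in RAW_FEATURES
    }


def eye_covariates(
    eye_volumes: Dict[Feature, SegVolume],
    config: SynthConfig,
    resolution: Optional[Tuple[int, int]] = None,
) -> Dict[str, float]:
    """Spatial covariates entering the structure–function law.

    Returns mean foveal RORA probability, extrafoveal RORA area (mm²) and
    mean parafoveal (inner-ring) photoreceptor-degeneration probability,
    all computed on the fovea-centred standard grid.
    """
    resolution = resolution or config.grid_shape
    maps = {feat: build_enface(v) for feat, v in eye_volumes.items()}
    rora = derive_rora(
        maps[Feature.RPE_LOSS], maps[Feature.PDR], maps[Feature.HYPERTRANSMISSION]
    )
    labels = gridmod.etdrs_labels(resolution, extent_mm=3.0)
    rora_sg = gridmod.standardize(rora, resolution, extent_mm=3.0)
    pdr_sg = gridmod.standardize(maps[Feature.PDR], resolution, extent_mm=3.0)
    rora_means = gridmod.region_means(rora_sg, labels)
    pdr_means = gridmod.region_means(pdr_sg, labels)
    parafoveal = float(
        np.mean([pdr_means[gridmod.REGION_NAMES[lab]] for lab in gridmod.INNER_REGIONS])
    )
    return {
        "foveal_rora_mean": float(rora_means["foveal"]),
        "extrafoveal_rora_area_mm2": gridmod.extrafoveal_area(
            rora_sg, labels, config.threshold
        ),
        "parafoveal_pdr_mean": parafoveal,
        "foveal_involved": gridmod.foveal_involvement(rora_sg, labels, config.threshold),
    }


def generate_outcomes(
    cohort_lesions: Dict[str, Dict[Feature, SegVolume]],
    config: SynthConfig,
    eye_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Generate VA / LLVA / LLD from the lesions under the configured law.

    ``eye_meta`` must carry ``eye_id``, ``patient_id`` and ``eye_side``
    (row order defines the noise stream). The identity
    ``lld = va − llva`` holds exactly on every row by construction.
    """
    rng = _rng(config, _SALT_OUTCOME)
    bva, bll = config.beta_va, config.beta_lld
    rows = []
    for _, meta in eye_meta.iterrows():
        eye_id = meta["eye_id"]
        cov = eye_covariates(cohort_lesions[eye_id], config)
        eps, eps2 = rng.normal(0.0, config.noise_sd_letters, size=2)
        va = float(
            np.clip(
                bva.intercept_letters
                - bva.foveal_rora_coef * cov["foveal_rora_mean"]
                - bva.extrafoveal_rora_area_coef * cov["extrafoveal_rora_area_mm2"]
                + eps,
                0.0,
                100.0,
            )
        )
        lld = float(
            np.clip(
                bll.intercept_letters
                + bll.parafoveal_pdr_coef * cov["parafoveal_pdr_mean"]
                + eps2,
                0.0,
                min(va, 100.0),
            )
        )
        fovea = cohort_lesions[eye_id][Feature.RPE_LOSS].fovea_xy_mm
        rows.append(
            {
                "patient_id": meta["patient_id"],
                "eye_id": eye_id,
                "eye_side": meta["eye_side"],
                "fovea_x_mm": fovea[0],
                "fovea_y_mm": fovea[1],
                "va_letters": va,
                "llva_letters": va - lld,
                "lld_letters": lld,
                **cov,
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Generate a full synthetic cohort under the configured conditions.

    Patients contribute one or both eyes (``frac_bilateral``); fellow eyes
    share a lognormal lesion-burden random effect. All randomness derives
    from ``config.rng_seed``, so identical configurations yield
    bit-identical cohorts.
    """
    rng_struct = _rng(config, _SALT_STRUCTURE)
    meta_rows = []
    volumes: Dict[str, Dict[Feature, SegVolume]] = {}
    truth_eyes = {}
    eye_index = 0
    for pid in range(config.n_patients):
        patient_id = f"P{pid:04d}"
        bilateral = bool(rng_struct.random() < config.frac_bilateral)
        burden = float(np.exp(rng_struct.normal(0.0, config.patient_effect_sigma_log)))
        if bilateral:
            sides = [Laterality.OD, Laterality.OS]
        else:
            sides = [Laterality.OD if rng_struct.random() < 0.5 else Laterality.OS]
        for side in sides:
            eye_id = f"{patient_id}_{side.value}"
            volumes[eye_id] = generate_lesions(
                config, eye_index, burden=burden, laterality=side
            )
            truth_eyes[eye_id] = {"burden": burden}
            meta_rows.append(
                {"patient_id": patient_id, "eye_id": eye_id, "eye_side": side.value}
            )
            eye_index += 1
    eye_meta = pd.DataFrame(meta_rows)
    outcomes = generate_outcomes(volumes, config, eye_meta)
    for eye_id, cov in outcomes.set_index("eye_id")[
        ["foveal_rora_mean", "extrafoveal_rora_area_mm2", "parafoveal_pdr_mean"]
    ].iterrows():
        truth_eyes[eye_id].update(cov.to_dict())
    truth = {"config": config.to_dict(), "eyes": truth_eyes}
    return SynthCohort(volumes=volumes, outcomes=outcomes, truth=truth, config=config)


def recovery_config(seed: int = 0, n_patients: int = 205) -> SynthConfig:
    """Conditions for signal-recovery experiments.

    VA depends *only* on foveal RORA (the extrafoveal area coefficient is
    zeroed) and LLD only on parafoveal photoreceptor degeneration, with
    small outcome noise (5 letters), so the expected importance rankings
    are unambiguous: foveal region and RORA for VA; photoreceptor
    degeneration for LLVA. The PDR effect is made deliberately strong
    relative to the foveal effect so that the low-luminance signal is
    dominated by parafoveal photoreceptor degeneration, mirroring the
    qualitative clinical contrast the recovery experiment is meant to
    detect.
    """
    return SynthConfig(
        n_patients=n_patients,
        beta_va=BetaVA(
            intercept_letters=80.0,
            foveal_rora_coef=25.0,
            extrafoveal_rora_area_coef=0.0,
        ),
        beta_lld=BetaLLD(intercept_letters=0.0, parafoveal_pdr_coef=55.0),
        noise_sd_letters=5.0,
        rng_seed=seed,
    )
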