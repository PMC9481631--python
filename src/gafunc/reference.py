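"""Published reference values for a large clinical GA cohort.

These constants transcribe the reported results of a structure–function
study of geographic atrophy on 476 eyes from 325 patients (a clinical
trial cohort plus a real-world hospital cohort): region-by-feature
random-forest importance tables for standard and low-luminance visual
acuity, cohort median lesion areas, foveal-sparing counts, and the
headline regression metrics. They serve as worked-example inputs for the
aggregation arithmetic and as calibration context for the synthetic
cohorts; they are *data*, not computed results.

Note: a few of the printed marginal sums differ from the cell-wise sums
by ~0.1 due to rounding of the published cells (e.g. the standard-VA
RPE-loss column prints 23.7 while the cells sum to 23.6). The printed
margins are kept separately in ``*_PRINTED_MARGINS`` for that reason.
"""

from __future__ import annotations

import pandas as pd

#: Cohort composition.
TOTAL_EYES = 476
TOTAL_PATIENTS = 325

#: Eyes in which RORA wholly spared the central 1-mm foveal disc.
FOVEAL_SPARING_EYES = 70

#: Cohort median lesion areas (mm²) per feature.
MEDIAN_AREAS_MM2 = {
    "rpe_loss": 7.82,
    "photoreceptor_degeneration": 14.4,
    "hypertransmission": 9.23,
    "rora": 6.22,
}

#: Headline regression metrics (combined cohort / trial cohort).
HEADLINE_METRICS = {
    "va": {"r2": 0.40, "mae": 11.7},
    "llva": {"r2": 0.25, "mae": 12.1},
    "lld": {"r2": 0.25, "mae": 10.1},
}

_REGIONS = [
    "foveal",
    "inner_superior",
    "inner_nasal",
    "inner_inferior",
    "inner_temporal",
    "outer_superior",
    "outer_nasal",
    "outer_inferior",
    "outer_temporal",
]
_FEATURES = ["rpe_loss", "photoreceptor_degeneration", "hypertransmission", "rora"]

#: Region x feature importance (%) for standard visual acuity.
VA_REGION_IMPORTANCE = pd.DataFrame(
    [
        [13.4, 6.4, 8.5, 14.8],
        [2.3, 1.6, 2.5, 3.1],
        [1.7, 1.7, 2.0, 2.6],
        [1.7, 1.6, 1.9, 2.1],
        [1.5, 1.8, 1.7, 2.0],
        [0.8, 1.8, 2.1, 1.4],
        [0.9, 2.1, 2.3, 1.7],
        [0.7, 2.3, 2.4, 1.6],
        [0.6, 1.4, 1.8, 1.2],
    ],
    index=_REGIONS,
    columns=_FEATURES,
)

#: Margins as printed alongside the standard-VA table.
VA_PRINTED_MARGINS = {
    "row_sums": pd.Series(
        [43.1, 9.5, 8.9, 7.3, 7.0, 6.1, 7.0, 7.0, 5.0], index=_REGIONS
    ),
    "column_sums": pd.Series([23.7, 20.7, 25.1, 30.5], index=_FEATURES),
}

#: Region x feature importance (%) for low-luminance visual acuity.
LLVA_REGION_IMPORTANCE = pd.DataFrame(
    [
        [3.0, 12.2, 5.6, 4.8],
        [2.8, 4.0, 2.9, 3.0],
        [1.7, 3.1, 2.2, 2.2],
        [1.9, 4.1, 2.7, 2.9],
        [1.6, 3.3, 2.3, 2.4],
        [0.9, 3.7, 2.7, 1.7],
        [0.9, 3.0, 2.5, 1.7],
        [0.5, 3.0, 2.5, 1.3],
        [0.7, 2.5, 2.5, 1.5],
    ],
    index=_REGIONS,
    columns=_FEATURES,
)

#: Margins as printed alongside the low-luminance-VA table.
LLVA_PRINTED_MARGINS = {
    "row_sums": pd.Series(
        [25.5, 12.7, 9.2, 11.6, 9.5, 8.9, 8.1, 7.3, 7.1], index=_REGIONS
    ),
    "column_sums": pd.Series([13.8, 38.9, 26.0, 21.4], index=_FEATURES),
}


def foveal_sparing_percent(n_spared: int = FOVEAL_SPARING_EYES,
                           n_total: int = TOTAL_EYES) -> float:
    """Foveal-sparing rate as a percentage (default: the published counts)."""
    if n_total <= 0 or not 0 <= n_spared <= n_total:
        raise ValueError("invalid sparing counts")
    return 100.0 * n_spared / n_total
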