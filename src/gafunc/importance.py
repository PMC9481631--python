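"""Spatially resolved random-forest feature importance.

Impurity-based importances (mean decrease of variance, normalized per
forest) are averaged across the bootstrap replicates, renormalized and
expressed as percentage contribution per (feature, grid cell). They are
then aggregated over ETDRS subfields into a 9-region x 4-feature matrix
whose grand total is 100 % (cells outside the 6-mm circle are carried as
an explicit remainder), summarized into foveal vs non-foveal shares, and
rendered as per-feature heatmaps on the fovea-centred grid.

Impurity importance is known to favour high-cardinality / correlated
predictors; a permutation-based cross-check can be obtained by fitting
with ``sklearn.inspection.permutation_importance`` externally, but the
variance-reduction ranking is the primary quantity here.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .enface import Feature
from .grid import EtdrsLabels, FOVEAL, OUTSIDE, REGION_LABELS, REGION_NAMES, etdrs_labels
from .model import BootstrapResult, FEATURE_ORDER, parse_predictor

#: Row label used for the out-of-circle remainder in aggregated tables.
OUTSIDE_ROW = "outside_grid"


@dataclass
class ImportanceResult:
    """Normalized per-(feature, cell) importance percentages.

    ``per_cell[f, i, j]`` is the percentage contribution of feature ``f``
    at standard-grid cell ``(i, j)``; the grand total is 100.
    """

    per_cell: np.ndarray  # (n_features, rows, cols), percentages
    features: Tuple[Feature, ...]
    extent_mm: float
    n_bootstrap_averaged: int
    provenance: dict = dc_field(default_factory=dict)
    per_replicate: Optional[np.ndarray] = None

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return self.per_cell.shape[1:]

    def feature_panel(self, feature: Feature) -> np.ndarray:
        return self.per_cell[self.features.index(Feature(feature))]


def collect_importance(
    result: BootstrapResult,
    extent_mm: float = 3.0,
    keep_replicates: bool = False,
) -> ImportanceResult:
    """Average per-predictor importances over replicates and map to cells.

    The replicate importance vectors are averaged first, then renormalized
    to sum to one and multiplied by 100, and finally reshaped to
    (feature, row, col) using the deterministic feature-major column
    order of the feature table.
    """
    imp = np.asarray(result.importances, dtype=float)
    if imp.ndim != 2 or not imp.size:
        raise ValueError("bootstrap result carries no importance vectors")
    mean = imp.mean(axis=0)
    total = mean.sum()
    if total <= 0:
        raise ValueError("importances sum to zero; nothing to normalize")
    pct = mean / total * 100.0

    parsed = [parse_predictor(c) for c in result.feature_columns]
    rows = 1 + max(p[1] for p in parsed)
    cols = 1 + max(p[2] for p in parsed)
    expected = [
        (feat, i, j) for feat in FEATURE_ORDER for i in range(rows) for j in range(cols)
    ]
    if parsed != expected:
        raise ValueError("feature columns are not in canonical feature-major order")
    per_cell = pct.reshape(len(FEATURE_ORDER), rows, cols)
    return ImportanceResult(
        per_cell=per_cell,
        features=FEATURE_ORDER,
        extent_mm=extent_mm,
        n_bootstrap_averaged=imp.shape[0],
        provenance={
            "outcome": result.outcome,
            "seed": result.seed,
            "scheme": result.scheme,
            "split_unit": result.split_unit,
            "hyperparams": result.hyperparams,
        },
        per_replicate=imp if keep_replicates else None,
    )


def aggregate_by_region(
    imp: ImportanceResult, labels: Optional[EtdrsLabels] = None
) -> pd.DataFrame:
    """Sum per-cell importances over ETDRS subfields.

    Returns a 9-region x 4-feature DataFrame of percentages. Importance
    on cells outside the 6-mm circle is kept as an explicit remainder in
    ``df.attrs["outside_pct"]`` so that matrix total + remainder = 100.
    """
    if labels is None:
        labels = etdrs_labels(imp.grid_shape, extent_mm=imp.extent_mm)
    if labels.labels.shape != imp.grid_shape:
        raise ValueError("ETDRS labels do not match the importance grid shape")
    data: Dict[str, list] = {}
    for k, feat in enumerate(imp.features):
        panel = imp.per_cell[k]
        data[feat.value] = [
            float(panel[labels.labels == lab].sum()) for lab in REGION_LABELS
        ]
    df = pd.DataFrame(data, index=[REGION_NAMES[lab] for lab in REGION_LABELS])
    outside = float(
        sum(
            imp.per_cell[k][labels.labels == OUTSIDE].sum()
            for k in range(len(imp.features))
        )
    )
    df.attrs["outside_pct"] = outside
    return df


def with_margins(region_df: pd.DataFrame) -> pd.DataFrame:
    """Append the Sum row (per feature) and Sum column (per region)."""
    df = region_df.copy()
    df["Sum"] = df.sum(axis=1)
    df.loc["Sum"] = df.sum(axis=0)
    df.attrs.update(region_df.attrs)
    return df


def foveal_shares(region_df: pd.DataFrame) -> Dict[str, float]:
    """Foveal vs non-foveal percentage shares of total importance.

    The foveal share is the foveal row sum of the region matrix; the
    non-foveal share is its complement to 100 (which folds in any
    out-of-circle remainder), so the two always sum to exactly 100.
    """
    body = region_df.drop(index="Sum", columns="Sum", errors="ignore")
    foveal = float(body.loc[REGION_NAMES[FOVEAL]].sum())
    return {"foveal_share": foveal, "nonfoveal_share": 100.0 - foveal}


def render_heatmap(
    imp: ImportanceResult,
    path: Optional[str] = None,
    show_rings: bool = True,
):
    """Render per-feature importance heatmaps on the standard grid.

    One panel per feature with a shared colour scale, the fovea marked at
    the centre and (optionally) the ETDRS ring overlay. Returns the
    matplotlib figure; deterministic for fixed input.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(imp.features)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.4), squeeze=False)
    vmax = float(imp.per_cell.max()) or 1.0
    e = imp.extent_mm
    for ax, feat in zip(axes[0], imp.features):
        panel = imp.feature_panel(feat)
        im = ax.imshow(
            panel,
            extent=(-e, e, -e, e),
            origin="upper",
            vmin=0.0,
            vmax=vmax,
            cmap="inferno",
        )
        ax.plot(0, 0, "w+", markersize=8)
        if show_rings:
            t = np.linspace(0, 2 * np.pi, 181)
            for r_mm in (0.5, 1.5, 3.0):
                ax.plot(r_mm * np.cos(t), r_mm * np.sin(t), "w-", lw=0.5, alpha=0.6)
        ax.set_title(feat.value, fontsize=9)
        ax.set_xlabel("nasal  +x (mm)", fontsize=7)
        ax.tick_params(labelsize=7)
    axes[0][0].set_ylabel("superior  +y (mm)", fontsize=7)
    fig.colorbar(im, ax=axes[0], shrink=0.8, label="% importance")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
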