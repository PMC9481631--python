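"""Bootstrapped random-forest prediction of visual function from lesion maps.

The predictor matrix holds, for every eye, the standard-grid probability of
each of the four features (RPE-loss, photoreceptor degeneration,
hypertransmission, derived RORA) at every grid cell, optionally block-mean
downsampled. Evaluation resamples *patients* with replacement, partitions
the resampled patients 80/20 (all eyes of a patient stay on one side, so
correlated fellow eyes can never leak across the split), fits a random
forest on the training eyes and scores the held-out eyes with the
coefficient of determination (r²) and mean absolute error (MAE, ETDRS
letters). Summaries are medians with 25–75 % quartiles across replicates.

A plain repeated-split scheme without the bootstrap resampling step is
available via ``scheme="split_only"`` for sensitivity analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error, r2_score

from .enface import ALL_FEATURES, Feature
from .grid import StandardGrid

logger = logging.getLogger(__name__)

META_COLUMNS = ("patient_id", "eye_id")

#: Canonical predictor ordering: feature-major, then row-major cell order.
FEATURE_ORDER: Tuple[Feature, ...] = ALL_FEATURES

_PREDICTOR_RE = re.compile(r"^(?P<feature>.+)__r(?P<row>\d+)c(?P<col>\d+)$")

#: Forest settings: the reference library defaults (100 trees, all
#: features considered at each split, unlimited depth).
DEFAULT_RF_PARAMS = {"n_estimators": 100}


def predictor_name(feature: Feature, row: int, col: int) -> str:
    return f"{feature.value}__r{row:02d}c{col:02d}"


def predictor_columns(table: pd.DataFrame) -> List[str]:
    """The predictor columns of a feature table, in canonical order."""
    return [c for c in table.columns if _PREDICTOR_RE.match(c)]


def parse_predictor(name: str) -> Tuple[Feature, int, int]:
    m = _PREDICTOR_RE.match(name)
    if m is None:
        raise ValueError(f"not a predictor column: {name!r}")
    return Feature(m["feature"]), int(m["row"]), int(m["col"])


def block_mean(a: np.ndarray, k: int) -> np.ndarray:
    """Downsample a 2-D array by averaging non-overlapping k x k blocks."""
    a = np.asarray(a, dtype=float)
    r, c = a.shape
    if k < 1 or r % k or c % k:
        raise ValueError(f"block size {k} does not divide grid shape {a.shape}")
    return a.reshape(r // k, k, c // k, k).mean(axis=(1, 3))


def build_feature_table(
    grids: Mapping[str, Mapping[Feature, StandardGrid]],
    outcomes: pd.DataFrame,
    outcome: str = "va_letters",
    downsample_k: int = 1,
) -> pd.DataFrame:
    """Assemble the eye x (feature, cell) predictor table.

    Parameters
    ----------
    grids
        Per-eye mapping feature -> :class:`StandardGrid`; every eye must
        carry all four features on identical geometry.
    outcomes
        Table with ``patient_id``, ``eye_id`` and the outcome column (in
        ETDRS letters). Eyes with a missing outcome are dropped (logged).
    outcome
        Outcome column; short forms (``"va"``) resolve to
        ``"<name>_letters"``.
    downsample_k
        Block-mean downsampling factor; 1 keeps raw cells.

    Column order is deterministic: feature-major in the canonical feature
    order, then row-major over cells — importance vectors can therefore be
    mapped back to (feature, cell) unambiguously.
    """
    if outcome not in outcomes.columns and f"{outcome}_letters" in outcomes.columns:
        outcome = f"{outcome}_letters"
    if outcome not in outcomes.columns:
        raise ValueError(f"outcome column {outcome!r} missing from the outcome table")

    kept = outcomes.dropna(subset=[outcome])
    n_dropped = len(outcomes) - len(kept)
    if n_dropped:
        logger.info("dropped %d eyes lacking outcome %s", n_dropped, outcome)
    if not len(kept):
        raise ValueError(f"no eyes carry the outcome column {outcome!r}")

    shape = None
    rows = []
    names: Optional[List[str]] = None
    for _, meta in kept.iterrows():
        eye = meta["eye_id"]
        feats = grids[eye]
        vec = []
        for feat in FEATURE_ORDER:
            g = feats[feat].grid
            if shape is None:
                shape = g.shape
            elif g.shape != shape:
                raise ValueError("inconsistent standard-grid geometry across eyes")
            ds = block_mean(g, downsample_k)
            vec.append(ds.ravel())
        if names is None:
            r, c = shape[0] // downsample_k, shape[1] // downsample_k
            names = [
                predictor_name(feat, i, j)
                for feat in FEATURE_ORDER
                for i in range(r)
                for j in range(c)
            ]
        rows.append(np.concatenate(vec))

    table = pd.DataFrame(rows, columns=names)
    table.insert(0, "patient_id", kept["patient_id"].to_numpy())
    table.insert(1, "eye_id", kept["eye_id"].to_numpy())
    table[outcome] = kept[outcome].to_numpy()
    table.attrs["outcome"] = outcome
    table.attrs["downsample_k"] = downsample_k
    return table


def outcome_column(table: pd.DataFrame) -> str:
    if "outcome" in table.attrs:
        return table.attrs["outcome"]
    candidates = [c for c in table.columns if c.endswith("_letters")]
    if len(candidates) != 1:
        raise ValueError("cannot infer the outcome column; pass outcome explicitly")
    return candidates[0]


@dataclass
class BootstrapResult:
    """Per-replicate and summary metrics of the bootstrapped evaluation."""

    r2: np.ndarray
    mae: np.ndarray
    importances: np.ndarray  # (n_kept_replicates, n_predictors)
    feature_columns: List[str]
    n_replicates: int
    n_excluded: int
    seed: int
    split_unit: str
    scheme: str
    hyperparams: dict
    outcome: str
    splits: List[Tuple[Tuple, Tuple]] = dc_field(default_factory=list)

    @property
    def summary(self) -> dict:
        q25, q50, q75 = np.percentile(self.mae, [25, 50, 75])
        return {
            "r2": float(np.median(self.r2)),
            "r2_mean": float(np.mean(self.r2)),
            "mae": float(q50),
            "mae_q25": float(q25),
            "mae_q75": float(q75),
            "n_replicates": int(self.n_replicates),
            "n_excluded": int(self.n_excluded),
        }

    def to_dict(self, include_importances: bool = True) -> dict:
        d = {
            "summary": self.summary,
            "r2_per_replicate": self.r2.tolist(),
            "mae_per_replicate": self.mae.tolist(),
            "seed": self.seed,
            "split_unit": self.split_unit,
            "scheme": self.scheme,
            "hyperparams": self.hyperparams,
            "outcome": self.outcome,
            "feature_columns": self.feature_columns,
        }
        if include_importances:
            d["importances"] = self.importances.tolist()
        return d


def bootstrap_evaluate(
    table: pd.DataFrame,
    n_replicates: int = 100,
    train_frac: float = 0.8,
    split_unit: str = "patient",
    scheme: str = "bootstrap",
    seed: int = 0,
    rf_params: Optional[dict] = None,
    keep_splits: bool = False,
) -> BootstrapResult:
    """Bootstrapped random-forest regression of visual function.

    Each replicate resamples the split units (patients by default) with
    replacement, partitions the distinct sampled units ``train_frac`` /
    ``1 − train_frac``, fits a forest on the training eyes (bootstrap
    multiplicity preserved) and scores the held-out eyes. Replicates whose
    training outcome is constant are excluded from the summary (logged);
    an empty test side is redrawn. Fully deterministic for a fixed seed.
    """
    if scheme not in ("bootstrap", "split_only"):
        raise ValueError("scheme must be 'bootstrap' or 'split_only'")
    if split_unit not in ("patient", "eye"):
        raise ValueError("split_unit must be 'patient' or 'eye'")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    outcome = outcome_column(table)
    pred_cols = predictor_columns(table)
    if not pred_cols:
        raise ValueError("table has no predictor columns")
    if table["patient_id"].nunique() < 10:
        raise ValueError("need at least 10 distinct patients")

    X = table[pred_cols].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    unit_col = "patient_id" if split_unit == "patient" else "eye_id"
    units = np.asarray(sorted(table[unit_col].unique()))
    unit_rows = {
        u: np.flatnonzero(table[unit_col].to_numpy() == u) for u in units
    }

    params = dict(DEFAULT_RF_PARAMS)
    params.update(rf_params or {})

    root = SeedSequence(seed)
    child_seqs = root.spawn(n_replicates)
    r2s: List[float] = []
    maes: List[float] = []
    imps: List[np.ndarray] = []
    splits: List[Tuple[Tuple, Tuple]] = []
    n_excluded = 0

    for rep in range(n_replicates):
        rng = default_rng(child_seqs[rep])
        for _redraw in range(50):
            if scheme == "bootstrap":
                sampled = rng.choice(units, size=len(units), replace=True)
                counts = pd.Series(sampled).value_counts().to_dict()
            else:
                counts = {u: 1 for u in units}
            uniq = np.asarray(sorted(counts))
            rng.shuffle(uniq)
            n_train = int(round(train_frac * len(uniq)))
            n_train = min(max(n_train, 1), len(uniq) - 1)
            train_units, test_units = uniq[:n_train], uniq[n_train:]
            train_idx = np.concatenate(
                [np.tile(unit_rows[u], counts[u]) for u in train_units]
            )
            test_idx = np.concatenate([unit_rows[u] for u in test_units])
            if len(test_idx) >= 2:  # r2 needs at least two held-out eyes
                break
        y_train = y[train_idx]
        if np.ptp(y_train) == 0.0:
            logger.info("replicate %d excluded: constant training outcome", rep)
            n_excluded += 1
            continue
        rf = RandomForestRegressor(
            **params, random_state=int(rng.integers(2**31)), n_jobs=1
        )
        rf.fit(X[train_idx], y_train)
        y_hat = rf.predict(X[test_idx])
        r2s.append(r2_score(y[test_idx], y_hat))
        maes.append(mean_absolute_error(y[test_idx], y_hat))
        imps.append(rf.feature_importances_)
        if keep_splits:
            splits.append((tuple(train_units), tuple(test_units)))

    if not r2s:
        raise RuntimeError(
            "every replicate was excluded (constant training outcome); "
            "the outcome carries no variance to model"
        )
    return BootstrapResult(
        r2=np.asarray(r2s),
        mae=np.asarray(maes),
        importances=np.asarray(imps),
        feature_columns=pred_cols,
        n_replicates=n_replicates,
        n_excluded=n_excluded,
        seed=seed,
        split_unit=split_unit,
        scheme=scheme,
        hyperparams=params,
        outcome=outcome,
        splits=splits,
    )


def select_one_eye(
    table: pd.DataFrame, rule: str = "random", seed: int = 0
) -> pd.DataFrame:
    """Keep one eye per patient (``rule``: 'random' seeded, or 'first')."""
    if rule not in ("random", "first"):
        raise ValueError("rule must be 'random' or 'first'")
    rng = default_rng(seed)
    keep: List[int] = []
    for _, idx in table.groupby("patient_id", sort=True).indices.items():
        idx = np.sort(idx)
        keep.append(int(idx[0] if rule == "first" else rng.choice(idx)))
    sub = table.iloc[sorted(keep)].reset_index(drop=True)
    sub.attrs.update(table.attrs)
    return sub


def sensitivity_one_eye(
    table: pd.DataFrame,
    selection_rule: str = "random",
    seed: int = 0,
    **eval_kwargs,
) -> BootstrapResult:
    """Repeat the bootstrapped evaluation with one eye per patient.

    With an all-unilateral cohort the selection is a no-op and the result
    matches :func:`bootstrap_evaluate` at the same seed exactly.
    """
    sub = select_one_eye(table, rule=selection_rule, seed=seed)
    eval_kwargs.setdefault("seed", seed)
    return bootstrap_evaluate(sub, **eval_kwargs)
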