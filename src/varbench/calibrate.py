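"""Decision-threshold calibration by F-beta grid search with bootstrap CIs.

For one tool on one labeled cohort: lay a uniform grid of 100 candidate
thresholds over the observed score range, score each candidate by F-beta of
the strict-comparator calls, and keep the maximizer.  Stability is assessed
by stratified bootstrap (resampling within each class so every replicate
preserves the pathogenic/benign ratio exactly), re-deriving the best
threshold per replicate and reporting the 0.025/0.975 quantiles.  A
published reference threshold falling outside that interval flags the
reference as inadequate for the cohort under study.

Calibration operates on scored variants only; coverage does not enter here
(it re-enters at ranking time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import _as_bool_labels, f_beta_from_counts
from .registry import STRICT_GREATER, STRICT_LESS, ToolSpec

DEFAULT_GRID_SIZE = 100
DEFAULT_N_BOOT = 1000
DEFAULT_BETAS = (0.5, 1.0, 1.5)


@dataclass(frozen=True)
class CalibrationResult:
    """Best F-beta threshold for one tool at one beta, with bootstrap CI."""

    tool: str
    beta: float
    grid: tuple
    best_threshold: float
    best_fbeta: float
    bootstrap_q025: float
    bootstrap_q975: float
    n_bootstrap: int
    reference_threshold: float
    reference_outside_interval: bool


def threshold_grid(scores, n_points: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """``n_points`` evenly spaced thresholds over [min, max] of the scores."""
    s = np.asarray(scores, dtype=float)
    s = s[~np.isnan(s)]
    if s.size < 2 or s.min() == s.max():
        raise ValueError("threshold grid needs at least two distinct scores")
    return np.linspace(float(s.min()), float(s.max()), int(n_points))


def _clean(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    mask = ~np.isnan(s)
    s, y = s[mask], y[mask]
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("calibration requires scored variants of both classes")
    return s, y


def _fbeta_curve(
    s: np.ndarray, y: np.ndarray, grid: np.ndarray, comparator: str, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    """F-beta and number of pathogenic calls at every grid point (vectorized)."""
    if comparator == STRICT_GREATER:
        called = s[None, :] > grid[:, None]
    elif comparator == STRICT_LESS:
        called = s[None, :] < grid[:, None]
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    tp = (called & y[None, :]).sum(axis=1)
    fp = (called & ~y[None, :]).sum(axis=1)
    fn = (~called & y[None, :]).sum(axis=1)
    b2 = beta * beta
    denom = (1.0 + b2) * tp + b2 * fn + fp
    with np.errstate(invalid="ignore"):
        fb = np.where(denom > 0, (1.0 + b2) * tp / np.maximum(denom, 1), 0.0)
    return fb, tp + fp


def best_threshold(
    scores,
    labels,
    comparator: str,
    beta: float,
    grid: np.ndarray | None = None,
    n_points: int = DEFAULT_GRID_SIZE,
) -> tuple[float, float]:
    """Grid-maximizing threshold for F-beta and the attained F-beta.

    Tie rule: among grid points attaining the maximal F-beta, the most
    stringent one wins (fewest variants called pathogenic); any residual tie
    goes to the threshold farthest in the stringent direction.  This makes
    the conservative choice deterministic.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    s, y = _clean(scores, labels)
    if grid is None:
        grid = threshold_grid(s, n_points)
    fb, n_called = _fbeta_curve(s, y, np.asarray(grid, dtype=float), comparator, beta)
    best = fb.max()
    cand = np.flatnonzero(fb == best)
    cand = cand[n_called[cand] == n_called[cand].min()]
    idx = cand[-1] if comparator == STRICT_GREATER else cand[0]
    return float(np.asarray(grid)[idx]), float(best)


def bootstrap_threshold(
    scores,
    labels,
    comparator: str,
    beta: float,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    n_points: int = DEFAULT_GRID_SIZE,
) -> tuple[float, float, np.ndarray]:
    """Stratified bootstrap of the calibrated threshold.

    Each replicate draws, with replacement, exactly n_path scored pathogenic
    and n_benign scored benign variants (the class ratio of the original
    sample is preserved literally), re-lays the grid over the replicate's
    observed range, and re-derives the best threshold.  Returns the 0.025 and
    0.975 empirical quantiles plus the full replicate sample.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    s, y = _clean(scores, labels)
    rng = np.random.default_rng(seed)
    pos, neg = s[y], s[~y]
    thresholds = np.empty(n_boot, dtype=float)
    for b in range(n_boot):
        sp = pos[rng.integers(0, pos.size, pos.size)]
        sn = neg[rng.integers(0, neg.size, neg.size)]
        bs = np.concatenate([sp, sn])
        by = np.concatenate([np.ones(sp.size, bool), np.zeros(sn.size, bool)])
        if bs.min() == bs.max():  # degenerate replicate: keep its only value
            thresholds[b] = bs[0]
            continue
        thresholds[b], _ = best_threshold(
            bs, by, comparator, beta, n_points=n_points
        )
    q025, q975 = np.quantile(thresholds, [0.025, 0.975])
    return float(q025), float(q975), thresholds


def assess_reference(result: CalibrationResult) -> bool:
    """True iff the reference threshold lies outside the closed bootstrap CI."""
    return (
        result.reference_threshold < result.bootstrap_q025
        or result.reference_threshold > result.bootstrap_q975
    )


def calibrate_tool(
    scores,
    labels,
    spec: ToolSpec,
    beta: float,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    n_points: int = DEFAULT_GRID_SIZE,
) -> CalibrationResult:
    """Full calibration of one tool at one beta: grid, best point, bootstrap."""
    s, y = _clean(scores, labels)
    grid = threshold_grid(s, n_points)
    thr, fb = best_threshold(s, y, spec.comparator, beta, grid=grid)
    q025, q975, _ = bootstrap_threshold(
        s, y, spec.comparator, beta, n_boot=n_boot, seed=seed, n_points=n_points
    )
    partial = CalibrationResult(
        tool=spec.name, beta=beta, grid=tuple(float(g) for g in grid),
        best_threshold=thr, best_fbeta=fb,
        bootstrap_q025=q025, bootstrap_q975=q975, n_bootstrap=n_boot,
        reference_threshold=spec.reference_threshold,
        reference_outside_interval=False,
    )
    return CalibrationResult(
        **{**partial.__dict__, "reference_outside_interval": assess_reference(partial)}
    )


def calibration_report(results) -> pd.DataFrame:
    """Wide report: one row per tool, per-beta best (q025, q975) columns."""
    rows: dict[str, dict] = {}
    for r in results:
        row = rows.setdefault(
            r.tool, {"tool": r.tool, "reference_threshold": r.reference_threshold}
        )
        tag = f"beta_{r.beta:g}"
        row[f"threshold_{tag}"] = r.best_threshold
        row[f"q025_{tag}"] = r.bootstrap_q025
        row[f"q975_{tag}"] = r.bootstrap_q975
        row[f"reference_outside_{tag}"] = r.reference_outside_interval
    return pd.DataFrame(list(rows.values()))
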