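"""Per-cancer Spearman correlation between TRIM members and DEGs.

Every (TRIM, DEG) combination is scored by the Spearman rank correlation
over the cancer's tumour samples (configurable to all samples) with a
two-sided p-value from the t approximation; pairs with p below the cutoff
(default 0.01) are flagged significant.  The vectorised screen ranks each
gene once and computes the rank-Pearson matrix in one shot.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_P_CUT = 0.01


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p for two equal-length vectors.

    Ties receive average ranks; the p-value comes from
    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom, with
    p = 0 at |rho| = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _p_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, p)


def correlation_screen(
    dataset: ExpressionDataset,
    trims: list[str],
    degs: list[str],
    p_cut: float = DEFAULT_P_CUT,
    samples: str = "tumor",
) -> pd.DataFrame:
    """Spearman screen of every (TRIM, DEG) pair in one cancer.

    Parameters
    ----------
    samples
        ``"tumor"`` (default) restricts to tumour samples — the disease
        context the correlations are meant to capture — or ``"all"``.

    Returns
    -------
    DataFrame with columns trim, gene, cancer, rho, p, significant.
    Constant-expression genes are skipped with a logged count.
    """
    if not trims or not degs:
        raise ValueError("trim and deg lists must be non-empty")
    missing = (set(trims) | set(degs)) - set(dataset.genes)
    if missing:
        raise ValueError(f"genes absent from dataset: {sorted(missing)[:5]}")
    if samples == "tumor":
        cols = dataset.tumor_samples()
    elif samples == "all":
        cols = dataset.samples
    else:
        raise ValueError("samples must be 'tumor' or 'all'")
    n = len(cols)
    if n < 4:
        raise ValueError("need at least 4 samples for the screen")

    sub = dataset.matrix.loc[list(dict.fromkeys(trims + degs)), cols]
    if sub.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    const = sub.max(axis=1) == sub.min(axis=1)
    n_const_pairs = 0
    if const.any():
        skipped = set(sub.index[const])
        n_const_pairs = sum(t in skipped for t in trims) * len(degs) + sum(
            g in skipped for g in degs
        ) * len([t for t in trims if t not in skipped])
        logger.info(
            "skipping %d constant genes (%d pairs)", int(const.sum()), n_const_pairs
        )
    ranks = sub.rank(axis=1).values
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    idx = {g: i for i, g in enumerate(sub.index)}
    use_trims = [t for t in trims if not const[t]]
    use_degs = [g for g in degs if not const[g]]
    ti = np.array([idx[t] for t in use_trims])
    gi = np.array([idx[g] for g in use_degs])
    num = centered[ti] @ centered[gi].T
    rho = num / np.outer(norms[ti], norms[gi])
    p = _p_from_rho(rho, n)
    out = pd.DataFrame(
        {
            "trim": np.repeat(use_trims, len(use_degs)),
            "gene": np.tile(use_degs, len(use_trims)),
            "cancer": dataset.cancer,
            "rho": rho.ravel(),
            "p": p.ravel(),
        }
    )
    out["significant"] = out["p"] < p_cut
    return out
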