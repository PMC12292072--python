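"""ZRscore prioritisation of predicted CIV-target candidates.

Within a normalisation cohort the docking scores are min-max scaled and
inverted so the strongest binder (most negative zrank_score) maps to 1.
Each candidate's normalised docking affinity and co-expression R are then
projected onto the reference direction R = 2 * zrank_norm:

    ZRscore = (2 * zrank_norm + R) / sqrt(5)

The sqrt(5) denominator is the norm of the projection direction (2, 1),
so the score is the orthogonal projection length onto that line; a plain
/5 would rescale every score by the same positive constant and cannot
change any ranking.  Higher ZRscore = more confident candidate.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .family_db import TRUE

SQRT5 = math.sqrt(5.0)
#: attainable ZRscore range given zrank_norm in [0,1] and R in [-1,1]
ZRSCORE_MIN = -1.0 / SQRT5
ZRSCORE_MAX = 3.0 / SQRT5


def normalize_zrank(scores) -> np.ndarray:
    """Min-max scale docking scores to [0, 1], inverted.

    The most negative (strongest-binding) score maps to 1 and the weakest
    to 0, so that a larger normalised value always means stronger
    predicted binding.
    """
    z = np.asarray(scores, dtype=float)
    if z.size < 2 or np.ptp(z) == 0:
        raise ValueError("normalization cohort needs >= 2 distinct scores")
    return (z.max() - z) / (z.max() - z.min())


def zrscore(zrank_norm, R) -> np.ndarray | float:
    """Projection score (2 * zrank_norm + R) / sqrt(5)."""
    zn = np.asarray(zrank_norm, dtype=float)
    r = np.asarray(R, dtype=float)
    if np.any((zn < 0) | (zn > 1)):
        raise ValueError("zrank_norm must lie in [0, 1]")
    if np.any(np.abs(r) > 1):
        raise ValueError("R must lie in [-1, 1]")
    out = (2.0 * zn + r) / SQRT5
    return float(out) if out.ndim == 0 else out


def rank_candidates(
    predictions: pd.DataFrame,
    docking: pd.DataFrame,
    correlations: pd.DataFrame,
    cohort: str = "trim_cancer",
) -> pd.DataFrame:
    """Sort predicted-TRUE candidates by descending ZRscore.

    Parameters
    ----------
    predictions
        Columns trim, target, cancer, predicted (TRUE/FALSE) and
        optionally model_flags (which model(s) called TRUE).
    docking
        Columns trim, target, zrank_score.
    correlations
        Columns trim, gene, cancer, rho.
    cohort
        ``"trim_cancer"`` normalises docking scores within each
        (trim, cancer) candidate group — matching a per-query
        presentation — or ``"global"`` across all candidates.

    Ties in ZRscore break toward the stronger (more negative) raw docking
    score, then the lexicographically smaller target; the sort is stable.
    """
    cand = predictions[predictions["predicted"] == TRUE].copy()
    if cand.empty:
        return pd.DataFrame(
            columns=[
                "trim", "target", "cancer", "zrank_score", "zrank_norm",
                "R", "ZRscore", "model_flags",
            ]
        )
    m = cand.merge(docking[["trim", "target", "zrank_score"]], on=["trim", "target"], how="left")
    m = m.merge(
        correlations[["trim", "gene", "cancer", "rho"]].rename(columns={"gene": "target", "rho": "R"}),
        on=["trim", "target", "cancer"],
        how="left",
    )
    missing = m[m["zrank_score"].isna() | m["R"].isna()]
    if not missing.empty:
        pairs = [f"({r.trim}, {r.target}, {r.cancer})" for r in missing.head(5).itertuples()]
        raise ValueError(f"missing docking/correlation evidence for: {', '.join(pairs)}")
    if "model_flags" not in m.columns:
        m["model_flags"] = ""
    if cohort == "global":
        m["zrank_norm"] = normalize_zrank(m["zrank_score"].to_numpy())
    elif cohort == "trim_cancer":
        # degenerate cohorts (a single candidate, or all-equal scores)
        # fall back to the global scale rather than erroring out
        global_norm = normalize_zrank(m["zrank_score"].to_numpy())

        def _norm(s: pd.Series) -> np.ndarray:
            z = s.to_numpy()
            if len(z) < 2 or np.ptp(z) == 0:
                return global_norm[s.index.to_numpy()]
            return normalize_zrank(z)

        m["zrank_norm"] = (
            m.groupby(["trim", "cancer"])["zrank_score"].transform(_norm)
        )
    else:
        raise ValueError("cohort must be 'trim_cancer' or 'global'")
    m["ZRscore"] = zrscore(m["zrank_norm"].to_numpy(), m["R"].to_numpy())
    m = m.sort_values(
        by=["ZRscore", "zrank_score", "target"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    cols = ["trim", "target", "cancer", "zrank_score", "zrank_norm", "R", "ZRscore", "model_flags"]
    return m[cols]
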