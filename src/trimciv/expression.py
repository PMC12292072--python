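"""Expression preprocessing and tumour-vs-normal differential expression.

Two omics layers are supported, each with its own preprocessing chain:

* ``MS`` (proteomics intensities):  log2 transform -> drop genes with >50%
  missing values -> k-nearest-neighbour imputation -> moderated DE.
* ``RNASEQ`` (counts):  low-count filter -> TMM normalisation factors ->
  log-CPM -> duplicate-symbol averaging -> moderated DE.

Differential expression uses an empirical-Bayes moderated t: gene-wise
pooled variances are shrunk toward a common prior whose scale and degrees
of freedom are estimated by moment-matching the scaled-F distribution of
the observed variances.  With prior df = 0 the statistic reduces exactly
to the ordinary pooled two-sample t; with prior df = infinity every gene
is tested against the common prior variance.  A gene is called a DEG when
its BH-adjusted p-value falls below ``p_cut`` (default 0.01) and |logFC|
exceeds the layer cutoff (0.5 for MS, 1.0 for RNASEQ); logFC is tumour
minus normal on the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MS = "MS"
RNASEQ = "RNASEQ"

#: Layer-specific |logFC| cutoffs for DEG calling.
DEFAULT_LFC_CUT = {MS: 0.5, RNASEQ: 1.0}
DEFAULT_P_CUT = 0.01


@dataclass
class ExpressionDataset:
    """One cancer's genes x samples matrix with tumour/normal annotation.

    ``matrix`` rows are genes, columns samples; ``group`` maps each sample
    to ``"tumor"`` or ``"normal"``.  The counts layer must be non-negative;
    the proteomics layer may contain missing cells (NaN).
    """

    matrix: pd.DataFrame
    group: pd.Series
    cancer: str
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in (MS, RNASEQ):
            raise ValueError(f"layer must be MS or RNASEQ, got {self.layer!r}")
        if list(self.matrix.columns) != list(self.group.index):
            raise ValueError("matrix columns and group index do not match")
        bad = set(self.group.unique()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown group values: {sorted(bad)}")
        if self.layer == RNASEQ and (self.matrix.values < 0).any():
            raise ValueError("counts layer must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def tumor_samples(self) -> list[str]:
        return list(self.group.index[self.group == "tumor"])

    def to_tsv(self, matrix_path, samples_path) -> None:
        out = self.matrix.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(matrix_path, sep="\t", index=False, float_format="%.10g")
        ann = pd.DataFrame(
            {"sample": self.group.index, "group": self.group.values, "cancer": self.cancer}
        )
        ann.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path, samples_path, layer: str) -> "ExpressionDataset":
        mat = pd.read_csv(matrix_path, sep="\t")
        mat = mat.set_index("gene")
        mat.index.name = None
        ann = pd.read_csv(samples_path, sep="\t")
        group = pd.Series(ann["group"].values, index=ann["sample"].values)
        cancer = str(ann["cancer"].iloc[0])
        return cls(mat, group, cancer, layer)


def log2_transform(matrix: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Elementwise log2(x + offset); missing cells stay missing.

    With the default offset of 0 any non-positive observed value is an
    error — a zero intensity normally denotes missingness, not abundance.
    """
    vals = matrix.values.astype(float)
    observed = ~np.isnan(vals)
    if np.any(vals[observed] + offset <= 0):
        raise ValueError("non-positive values under the chosen log2 offset")
    out = np.full_like(vals, np.nan)
    out[observed] = np.log2(vals[observed] + offset)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_missing(matrix: pd.DataFrame, max_frac: float = 0.5) -> pd.DataFrame:
    """Drop genes whose missing fraction is strictly greater than ``max_frac``.

    A gene missing exactly half its cells is retained under the default.
    """
    if not 0 <= max_frac <= 1:
        raise ValueError("max_frac must lie in [0, 1]")
    frac = matrix.isna().mean(axis=1)
    keep = frac <= max_frac
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_missing removed %d of %d genes", n_removed, len(matrix))
    return matrix.loc[keep]


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing cells from the k nearest gene rows.

    Neighbours are other genes, ranked by Euclidean distance over mutually
    observed samples (rescaled by overlap size); the imputed value is the
    inverse-distance-weighted mean of the neighbours' values in the missing
    sample's column.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        bad = ", ".join(matrix.index[all_missing])
        raise ValueError(f"gene(s) with no observed values: {bad}")
    if not matrix.isna().any().any():
        return matrix.copy()
    imputer = KNNImputer(n_neighbors=min(k, len(matrix) - 1), weights="distance")
    filled = imputer.fit_transform(matrix.values)
    return pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)


def filter_low_counts(
    matrix: pd.DataFrame, group: pd.Series, min_count: int = 10
) -> pd.DataFrame:
    """Drop weakly expressed genes from a counts matrix.

    Keeps genes whose counts-per-million exceed the CPM equivalent of
    ``min_count`` reads in the median-depth library, in at least as many
    samples as the smaller tumour/normal group.  This emulates the usual
    count-filtering rule of RNA-seq DE workflows without porting it
    bit-for-bit.
    """
    lib = matrix.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero-total library in counts matrix")
    cpm = matrix.divide(lib, axis=1) * 1e6
    cpm_cut = min_count / np.median(lib) * 1e6
    min_group = int(group.value_counts().min())
    keep = (cpm >= cpm_cut).sum(axis=1) >= min_group
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_low_counts removed %d of %d genes", n_removed, len(matrix))
    return matrix.loc[keep]


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Trimmed weighted mean of M-values for one library vs the reference."""
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos], ref[pos]
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) variance of M as precision weights
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    ref: str | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per library.

    M-values (log library-depth-adjusted ratios vs a reference sample) are
    doubly trimmed — the most extreme 30% of M and 5% of A values on each
    side are discarded — and averaged with inverse-variance weights.  The
    reference defaults to the sample whose upper-quartile CPM is closest
    to the mean upper quartile.  Factors are rescaled so their geometric
    mean is 1; multiplying each library size by its factor yields the
    effective (composition-corrected) depth.
    """
    vals = counts.values.astype(float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    lib = vals.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero-total library")
    if ref is None:
        # upper-quartile CPM per library (zeros included), closest to the mean
        uq = np.quantile(vals, 0.75, axis=0) / lib
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(counts.columns).index(ref)
    f = np.array(
        [
            _tmm_pair(vals[:, j], vals[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(vals.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns)


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on TMM-corrected library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors
    return np.log2((counts + prior).divide(lib + 1.0, axis=1) * 1e6)


def average_duplicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a gene symbol to their elementwise mean.

    Row order follows the first occurrence of each symbol.
    """
    if not matrix.index.duplicated().any():
        return matrix.copy()
    n_dup = int(matrix.index.duplicated().sum())
    logger.info("averaging %d duplicate gene rows", n_dup)
    order = matrix.index[~matrix.index.duplicated()]
    collapsed = matrix.groupby(level=0, sort=False).mean()
    return collapsed.loc[order]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on the trigamma function (monotone decreasing).
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (prior_df, prior_var) for the gene-variance distribution.

    Matches the first two moments of log(s^2) against a scaled-F model:
    s^2 ~ prior_var * F(df, prior_df).  Returns prior_df = inf when the
    observed spread of log-variances is no larger than expected from the
    residual degrees of freedom alone.
    """
    x = np.asarray(s2, dtype=float)
    x = np.where(x > 1e-300, x, 1e-300)
    z = np.log(x)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        prior_df = 2.0 * _trigamma_inverse(evar)
        prior_var = float(
            np.exp(emean + special.digamma(prior_df / 2.0) - np.log(prior_df / 2.0))
        )
    else:
        prior_df = np.inf
        prior_var = float(np.exp(emean))
    return prior_df, prior_var


def moderated_de(
    dataset: ExpressionDataset,
    lfc_cut: float | None = None,
    p_cut: float = DEFAULT_P_CUT,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated tumour-vs-normal differential expression.

    Parameters
    ----------
    dataset
        Preprocessed expression (complete matrix for MS; TMM log-CPM for
        RNASEQ).
    lfc_cut
        |logFC| cutoff for the DEG flag; defaults to the layer's value.
    prior_df, prior_var
        Override the estimated variance prior.  ``prior_df=0`` disables
        shrinkage (ordinary pooled two-sample t); ``prior_df=inf`` tests
        every gene against ``prior_var``.

    Returns
    -------
    DataFrame with columns gene, logFC, t, p, p_adj, is_deg.
    """
    if lfc_cut is None:
        lfc_cut = DEFAULT_LFC_CUT[dataset.layer]
    groups = dataset.group
    tumor = dataset.matrix.loc[:, groups.index[groups == "tumor"]].values
    normal = dataset.matrix.loc[:, groups.index[groups == "normal"]].values
    n1, n2 = tumor.shape[1], normal.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("moderated_de needs >= 2 samples in each group")
    if np.isnan(tumor).any() or np.isnan(normal).any():
        raise ValueError("matrix contains missing values; impute first")
    lfc = tumor.mean(axis=1) - normal.mean(axis=1)
    df = n1 + n2 - 2
    s2 = (tumor.var(axis=1, ddof=1) * (n1 - 1) + normal.var(axis=1, ddof=1) * (n2 - 1)) / df
    if prior_df is None:
        d0, s0 = fit_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        if np.isinf(d0):
            s0 = prior_var if prior_var is not None else fit_variance_prior(s2, df)[1]
        elif d0 == 0:
            s0 = 0.0
        else:
            s0 = prior_var if prior_var is not None else fit_variance_prior(s2, df)[1]
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "gene": dataset.genes,
            "logFC": lfc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "is_deg": (p_adj < p_cut) & (np.abs(lfc) > lfc_cut),
        }
    )
    return out.reset_index(drop=True)


def preprocess_ms(
    dataset: ExpressionDataset,
    max_missing: float = 0.5,
    k: int = 10,
    offset: float = 0.0,
) -> ExpressionDataset:
    """MS chain: log2 -> missingness filter -> KNN imputation."""
    logger.info("MS preprocessing: log2 -> filter_missing -> knn_impute")
    mat = log2_transform(dataset.matrix, offset=offset)
    mat = filter_missing(mat, max_frac=max_missing)
    mat = knn_impute(mat, k=k)
    return replace(dataset, matrix=mat)


def preprocess_rnaseq(dataset: ExpressionDataset, min_count: int = 10) -> ExpressionDataset:
    """RNASEQ chain: low-count filter -> TMM -> log-CPM -> duplicate averaging."""
    logger.info("RNASEQ preprocessing: filter_low_counts -> tmm -> log_cpm -> average_duplicates")
    counts = filter_low_counts(dataset.matrix, dataset.group, min_count=min_count)
    factors = tmm_factors(counts)
    mat = average_duplicates(log_cpm(counts, factors))
    return replace(dataset, matrix=mat)
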