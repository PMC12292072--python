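"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

Three generators share one root seed and emulate the pipeline's inputs:

* :func:`gen_family` — a TRIM registry (CIV entries end in PRY-SPRY) plus a
  curated pair database with ground-truth planting parameters: each target
  is assigned one partner TRIM; CIV pairs are co-expressed strongly
  (Spearman ~ ``rho_true``), non-CIV pairs more weakly (``rho_noncivil``),
  with per-pair heterogeneity ``rho_sd``; CIV partner targets are planted
  as upregulated DEGs, non-CIV partners with random sign.  Extra decoy
  pairs carry no planted signal.
* :func:`gen_expression` — per cancer, a negative-binomial counts layer
  (gene-wise dispersion decaying with mean, per-sample depth variation)
  and a Gaussian log-intensity proteomics layer with MCAR missingness.
  Planted co-expression uses a Gaussian copula on tumour samples so the
  realised rank correlation tracks the planted Spearman value.
* :func:`gen_docking` — CIV-pair scores from a truncated normal
  (mode around -45, essentially all mass inside -20..-80), non-CIV scores
  uniform over the support; lower = stronger predicted binding.  A small
  fraction of pairs "fail" docking and are omitted, as real docking
  pipelines lose a few percent of structures.

All outputs are byte-reproducible given the same :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .expression import MS, RNASEQ, ExpressionDataset
from .family_db import TrimEntry

_CIV_DOMAINS = (
    ["RING", "BBOX2", "CC", "PRYSPRY"],
    ["RING", "BBOX1", "BBOX2", "CC", "PRYSPRY"],
)
_NONCIV = (
    ("CI", ["RING", "BBOX2", "CC", "COS", "FN3"]),
    ("CV", ["RING", "BBOX2", "CC"]),
    ("CVII", ["RING", "BBOX1", "BBOX2", "CC", "FIL", "NHL"]),
    ("CIII", ["RING", "CC", "COS", "FN3", "PRYSPRY"]),
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    The defaults define a desk-scale pan-cancer cohort: two cancer types,
    100 tumour / 50 normal samples each, 150 candidate targets of which
    70% are planted DEGs at |log2FC| = 2, CIV pairs co-expressed at
    Spearman 0.8 vs 0.45 for other subfamilies (per-pair sd 0.25), and
    subfamily-dependent docking scores on [-90, 0].
    """

    seed: int = 0
    n_civ: int = 12
    n_noncivil: int = 12
    n_targets: int = 150
    cancers: tuple[str, ...] = ("BRCA", "GBM")
    n_tumor: int = 100
    n_normal: int = 50
    frac_deg: float = 0.7
    lfc_effect: float = 2.0
    rho_true: float = 0.8
    rho_noncivil: float = 0.45
    rho_sd: float = 0.25
    dock_civ_mean: float = -45.0
    dock_civ_sd: float = 10.0
    dock_range: tuple[float, float] = (-90.0, 0.0)
    missing_rate: float = 0.1
    dock_fail_rate: float = 0.02
    dock_separated: bool = True
    n_background: int = 200
    n_decoys: int = 60

    def __post_init__(self) -> None:
        if not 0 <= self.frac_deg <= 1:
            raise ValueError("frac_deg must lie in [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if abs(self.rho_true) > 1 or abs(self.rho_noncivil) > 1:
            raise ValueError("planted correlations must lie in [-1, 1]")
        lo, hi = self.dock_range
        if not lo < hi or hi > 0:
            raise ValueError("dock_range must satisfy lo < hi <= 0")
        if self.n_civ < 1 or self.n_noncivil < 1:
            raise ValueError("need at least one TRIM per class")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cancers"] = list(self.cancers)
        d["dock_range"] = list(self.dock_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["cancers"] = tuple(d.get("cancers", cls.cancers))
        d["dock_range"] = tuple(d.get("dock_range", cls.dock_range))
        return cls(**d)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # one independent child stream per generator / cancer / layer
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def gen_family(config: SimConfig) -> tuple[list[TrimEntry], pd.DataFrame]:
    """Registry plus pair database with ground-truth planting columns.

    The pair table carries: ``trim``, ``target``, ``source``,
    ``trim_class`` (CIV / NON_CIV), ``interacting`` (curated pair vs
    decoy), ``planted_rho`` and ``target_lfc`` (0 for non-DEG targets).
    """
    rng = _rng(config, 0)
    registry: list[TrimEntry] = []
    for i in range(config.n_civ):
        registry.append(
            TrimEntry(f"TRIMC{i + 1:02d}", "CIV", list(_CIV_DOMAINS[i % len(_CIV_DOMAINS)]))
        )
    for i in range(config.n_noncivil):
        sub, doms = _NONCIV[i % len(_NONCIV)]
        registry.append(TrimEntry(f"TRIMX{i + 1:02d}", sub, list(doms)))
    # interleave classes so the round-robin target assignment stays balanced
    civ = [e.name for e in registry if e.subfamily == "CIV"]
    non = [e.name for e in registry if e.subfamily != "CIV"]
    trims: list[str] = []
    for k in range(max(len(civ), len(non))):
        if k < len(civ):
            trims.append(civ[k])
        if k < len(non):
            trims.append(non[k])
    targets = [f"TGT{j + 1:03d}" for j in range(config.n_targets)]
    is_civ = {e.name: e.subfamily == "CIV" for e in registry}

    rows = []
    deg_flags = rng.random(config.n_targets) < config.frac_deg
    for j, tgt in enumerate(targets):
        trim = trims[j % len(trims)]
        civ_pair = is_civ[trim]
        mean = config.rho_true if civ_pair else config.rho_noncivil
        rho = float(np.clip(rng.normal(mean, config.rho_sd), -0.95, 0.95))
        if deg_flags[j]:
            sign = 1.0 if civ_pair else float(rng.choice([-1.0, 1.0]))
            lfc = sign * config.lfc_effect
        else:
            lfc = 0.0
        rows.append(
            {
                "trim": trim,
                "target": tgt,
                "source": "synthetic",
                "trim_class": "CIV" if civ_pair else "NON_CIV",
                "interacting": True,
                "planted_rho": rho,
                "target_lfc": lfc,
            }
        )
    lfc_by_target = {r["target"]: r["target_lfc"] for r in rows}
    curated = {(r["trim"], r["target"]) for r in rows}
    n_made = 0
    while n_made < config.n_decoys:
        trim = trims[int(rng.integers(len(trims)))]
        tgt = targets[int(rng.integers(len(targets)))]
        if (trim, tgt) in curated:
            continue
        curated.add((trim, tgt))
        rows.append(
            {
                "trim": trim,
                "target": tgt,
                "source": "synthetic-decoy",
                "trim_class": "CIV" if is_civ[trim] else "NON_CIV",
                "interacting": False,
                "planted_rho": 0.0,
                "target_lfc": lfc_by_target[tgt],
            }
        )
        n_made += 1
    return registry, pd.DataFrame(rows)


def _spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    # Gaussian-copula conversion: Pearson correlation of the latent
    # normals that yields the requested Spearman correlation.
    return 2.0 * np.sin(np.pi * np.asarray(rho_s) / 6.0)


def _latent(config: SimConfig, rng, genes, trims, pair_rho) -> tuple[np.ndarray, np.ndarray]:
    """Latent standard-normal draws with planted tumour co-expression."""
    n_genes = len(genes)
    gi = {g: i for i, g in enumerate(genes)}
    zt = rng.standard_normal((n_genes, config.n_tumor))
    zn = rng.standard_normal((n_genes, config.n_normal))
    for (trim, target), rho_s in pair_rho.items():
        rp = float(_spearman_to_pearson(rho_s))
        eps = rng.standard_normal(config.n_tumor)
        zt[gi[target]] = rp * zt[gi[trim]] + np.sqrt(1.0 - rp**2) * eps
    return zt, zn


def gen_expression(
    config: SimConfig, registry: list[TrimEntry], pairs: pd.DataFrame
) -> dict[tuple[str, str], ExpressionDataset]:
    """One ExpressionDataset per (cancer, layer).

    Counts are negative-binomial with a 1/mean dispersion trend and
    per-sample depth factors; proteomics are positive intensities whose
    log2 values are Gaussian, with MCAR missingness at ``missing_rate``.
    Planted DEG targets are shifted by ``target_lfc`` in tumour samples;
    planted pairs are co-expressed in tumour samples only.
    """
    if config.n_tumor < 2 or config.n_normal < 2:
        raise ValueError("need at least 2 tumour and 2 normal samples")
    trims = [e.name for e in registry]
    targets = sorted(pairs["target"].unique())
    background = [f"BG{j + 1:04d}" for j in range(config.n_background)]
    genes = trims + targets + background
    lfc_by_target = dict(
        pairs.drop_duplicates("target")[["target", "target_lfc"]].values
    )
    lfc = np.array([float(lfc_by_target.get(g, 0.0)) for g in genes])
    pair_rho = {
        (r.trim, r.target): r.planted_rho
        for r in pairs.itertuples()
        if r.interacting and abs(r.planted_rho) > 0
    }

    out: dict[tuple[str, str], ExpressionDataset] = {}
    for ci, cancer in enumerate(config.cancers):
        samples = [f"{cancer}_T{i + 1:03d}" for i in range(config.n_tumor)] + [
            f"{cancer}_N{i + 1:03d}" for i in range(config.n_normal)
        ]
        group = pd.Series(
            ["tumor"] * config.n_tumor + ["normal"] * config.n_normal, index=samples
        )
        for layer_idx, layer in enumerate((MS, RNASEQ)):
            rng = _rng(config, 100 + 10 * ci + layer_idx)
            base = rng.uniform(4.0, 9.0, len(genes))
            zt, zn = _latent(config, rng, genes, trims, pair_rho)
            if layer == RNASEQ:
                depth = rng.uniform(0.7, 1.4, len(samples))
                mean_t = 2.0 ** (base[:, None] + lfc[:, None]) * depth[None, : config.n_tumor]
                mean_n = 2.0 ** base[:, None] * depth[None, config.n_tumor:]
                disp = 0.05 + 10.0 / 2.0**base  # dispersion shrinks with abundance
                size = (1.0 / disp)[:, None]
                u_t = stats.norm.cdf(zt)
                u_n = stats.norm.cdf(zn)
                counts_t = stats.nbinom.ppf(u_t, size, size / (size + mean_t))
                counts_n = stats.nbinom.ppf(u_n, size, size / (size + mean_n))
                mat = pd.DataFrame(
                    np.hstack([counts_t, counts_n]), index=genes, columns=samples
                )
            else:
                sd = rng.uniform(0.6, 1.2, len(genes))
                log_t = base[:, None] + lfc[:, None] + sd[:, None] * zt
                log_n = base[:, None] + sd[:, None] * zn
                vals = 2.0 ** np.hstack([log_t, log_n])
                if config.missing_rate > 0:
                    mask = rng.random(vals.shape) < config.missing_rate
                    vals = np.where(mask, np.nan, vals)
                mat = pd.DataFrame(vals, index=genes, columns=samples)
            out[(cancer, layer)] = ExpressionDataset(mat, group, cancer, layer)
    return out


def gen_docking(config: SimConfig, pairs: pd.DataFrame) -> pd.DataFrame:
    """Docking score table (trim, target, zrank_score).

    CIV pairs draw from a truncated normal concentrated at moderate-to-
    strong affinities; non-CIV pairs draw uniformly over the support.
    With ``dock_separated=False`` every pair draws from the uniform — the
    subfamily signal is ablated while marginals stay in range.  A fraction
    ``dock_fail_rate`` of pairs is dropped to emulate failed docking runs.
    """
    if pairs.empty:
        raise ValueError("pairs table is empty")
    rng = _rng(config, 200)
    lo, hi = config.dock_range
    n = len(pairs)
    uniform = rng.uniform(lo, hi, n)
    a = (lo - config.dock_civ_mean) / config.dock_civ_sd
    b = (hi - config.dock_civ_mean) / config.dock_civ_sd
    civ_scores = stats.truncnorm.rvs(
        a, b, loc=config.dock_civ_mean, scale=config.dock_civ_sd, size=n, random_state=rng
    )
    is_civ = (pairs["trim_class"] == "CIV").values if "trim_class" in pairs else np.zeros(n, bool)
    scores = np.where(is_civ & config.dock_separated, civ_scores, uniform)
    table = pd.DataFrame(
        {"trim": pairs["trim"], "target": pairs["target"], "zrank_score": scores}
    )
    if config.dock_fail_rate > 0:
        ok = rng.random(n) >= config.dock_fail_rate
        table = table[ok]
    return table.reset_index(drop=True)
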