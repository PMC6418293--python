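"""Ensemble gene-set enrichment screening of differential-expression contrasts.

For every (contrast × gene set) pair an ensemble of heterogeneous enrichment
statistics is evaluated and combined into one collective significance:

* **ORA** — hypergeometric over-representation of the set among the top
  fraction of genes ranked by |statistic|;
* **rank-sum** — two-sided Wilcoxon rank-sum comparing |statistic| of set
  members against non-members (exact for small universes);
* **KS permutation** — GSEA-style weighted Kolmogorov–Smirnov running sum
  over the signed ranking, with a gene-label permutation null.

The per-algorithm p-values are combined (Fisher by default) and
Benjamini–Hochberg adjusted across gene sets within each contrast; sets with
adjusted p < 0.05 are flagged enriched.  The gene-level statistic is a Welch
two-sample t by default, but any externally computed per-gene statistic can
be supplied (:class:`ContrastStats` is just a named vector over a universe).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .graph import ConfigurationError, GeneSet, ValidationError

__all__ = [
    "ContrastStats",
    "EnsembleConfig",
    "EnrichmentTable",
    "gene_level_stats",
    "ora_test",
    "ranksum_test",
    "ks_enrichment",
    "combine_pvalues",
    "bh_adjust",
    "ensemble_enrichment",
    "read_expression_tsv",
    "read_design_tsv",
    "read_stats_tsv",
]

logger = logging.getLogger("evfusion.enrichment")

ALGORITHMS = ("ora", "ranksum", "ks_perm")

#: universes at or below this size use the exact rank-sum distribution
RANKSUM_EXACT_MAX = 50


@dataclass
class ContrastStats:
    """One contrast's per-gene signed statistic over an ordered universe."""

    name: str
    universe: list[str]
    stats: np.ndarray

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.universe) != len(self.stats):
            raise ValidationError(
                f"contrast {self.name!r}: {len(self.universe)} genes but "
                f"{len(self.stats)} statistics"
            )
        if len(set(self.universe)) != len(self.universe):
            raise ValidationError(f"contrast {self.name!r}: duplicate gene ids")
        if not np.all(np.isfinite(self.stats)):
            raise ValidationError(
                f"contrast {self.name!r}: non-finite statistics"
            )


@dataclass(frozen=True)
class EnsembleConfig:
    """Which algorithms run, how the KS null is sampled, how p's combine."""

    algorithms: tuple[str, ...] = ALGORITHMS
    ora_selection: float = 0.05
    ks_n_perm: int = 999
    combine_method: str = "fisher"  # fisher | stouffer | wilkinson_median
    rng_seed: int = 0
    significance: float = 0.05
    bh_scope: str = "contrast"  # contrast | global

    def __post_init__(self) -> None:
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ConfigurationError(f"unknown algorithms: {sorted(unknown)}")
        if len(self.algorithms) < 2:
            raise ConfigurationError("the ensemble needs at least 2 algorithms")
        if not 0 < self.ora_selection <= 1:
            raise ConfigurationError("ora_selection must be in (0, 1]")
        if self.ks_n_perm < 99:
            raise ConfigurationError("ks_n_perm must be ≥ 99")
        if self.combine_method not in ("fisher", "stouffer", "wilkinson_median"):
            raise ConfigurationError(
                f"unknown combine_method {self.combine_method!r}"
            )
        if self.bh_scope not in ("contrast", "global"):
            raise ConfigurationError(f"unknown bh_scope {self.bh_scope!r}")


@dataclass
class EnrichmentTable:
    """Long-format (contrast × gene set) ensemble results."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key in sorted(self.metadata):
                fh.write(f"# {key}: {self.metadata[key]}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    def wide(self) -> pd.DataFrame:
        """Contrasts × gene sets matrix of BH-adjusted combined p-values."""
        return self.table.pivot(
            index="contrast", columns="gene_set", values="adjusted_p"
        )


# -- gene-level statistic --------------------------------------------------


def gene_level_stats(
    expression: pd.DataFrame,
    groups: Sequence[str] | pd.Series,
    name: str = "contrast",
    group_order: tuple[str, str] | None = None,
) -> ContrastStats:
    """Per-gene Welch t-statistics (group2 − group1) for a two-group design.

    ``expression`` is genes × samples; ``groups`` assigns each sample column
    to one of exactly two levels.  Level order defaults to order of first
    appearance; rows with missing values are dropped with a warning.
    """
    groups = pd.Series(list(groups), index=expression.columns)
    levels = (
        list(group_order)
        if group_order is not None
        else list(dict.fromkeys(groups))
    )
    if len(set(groups)) != 2 or len(levels) != 2:
        raise ValidationError(
            f"contrast {name!r}: need exactly two groups, got {sorted(set(groups))}"
        )
    g1 = expression.loc[:, groups == levels[0]]
    g2 = expression.loc[:, groups == levels[1]]
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValidationError(
            f"contrast {name!r}: each group needs ≥ 2 samples "
            f"(got {g1.shape[1]} and {g2.shape[1]})"
        )
    keep = expression.notna().all(axis=1)
    if not keep.all():
        logger.warning(
            "contrast %s: dropping %d gene(s) with missing values",
            name,
            int((~keep).sum()),
        )
        g1, g2 = g1.loc[keep], g2.loc[keep]
    t = st.ttest_ind(
        g2.to_numpy(), g1.to_numpy(), axis=1, equal_var=False
    ).statistic
    t = np.where(np.isnan(t), 0.0, t)  # 0/0: identical, zero-variance groups
    t = np.clip(t, -1e15, 1e15)
    return ContrastStats(name, list(g1.index), t)


# -- individual algorithms -------------------------------------------------


def _restrict(gene_set: GeneSet, stats: ContrastStats) -> np.ndarray:
    members = set(gene_set.members)
    return np.array([g in members for g in stats.universe], dtype=bool)


def ora_test(
    gene_set: GeneSet, stats: ContrastStats, cfg: EnsembleConfig | None = None
) -> float:
    """Hypergeometric upper-tail over-representation p-value.

    The "selected" list is the top ``ora_selection`` fraction of the universe
    by |statistic| (ties broken by gene id for determinism); p = P(X ≥ k)
    with universe N, set size K (restricted to the universe), selection n,
    overlap k.
    """
    cfg = cfg or EnsembleConfig()
    member = _restrict(gene_set, stats)
    n_universe = len(stats.universe)
    n_set = int(member.sum())
    if n_set == 0:
        logger.warning(
            "gene set %s shares no genes with contrast %s; ORA p = 1",
            gene_set.name,
            stats.name,
        )
        return 1.0
    n_sel = max(1, int(round(cfg.ora_selection * n_universe)))
    order = sorted(
        range(n_universe),
        key=lambda i: (-abs(stats.stats[i]), stats.universe[i]),
    )
    top = order[:n_sel]
    k = int(member[top].sum())
    return float(st.hypergeom.sf(k - 1, n_universe, n_set, n_sel))


def ranksum_test(gene_set: GeneSet, stats: ContrastStats) -> float:
    """Two-sided Wilcoxon rank-sum p on |statistic|, members vs non-members.

    Exact null distribution for universes of ≤ 50 genes, normal approximation
    with tie correction above that.
    """
    member = _restrict(gene_set, stats)
    if member.sum() == 0 or member.all():
        raise ValidationError(
            f"rank-sum needs ≥ 1 member and ≥ 1 non-member in the universe "
            f"(set {gene_set.name!r}, contrast {stats.name!r})"
        )
    x = np.abs(stats.stats[member])
    y = np.abs(stats.stats[~member])
    method = "exact" if len(stats.universe) <= RANKSUM_EXACT_MAX else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def _es_from_positions(
    positions: np.ndarray, abs_sorted: np.ndarray, n_universe: int
) -> np.ndarray:
    """Enrichment score for each row of member rank-positions.

    The running sum adds the member's normalized |statistic| at each hit and
    subtracts 1/(N−K) at each miss; the score is the extremum of larger
    magnitude (ties resolve positive).  Only hit positions need inspecting:
    the sum rises exactly at hits and local minima sit just before them.
    """
    b, k = positions.shape
    w = abs_sorted[positions]
    wsum = w.sum(axis=1, keepdims=True)
    flat = (wsum == 0).ravel()
    if flat.any():  # all-zero statistics degrade to uniform hit weights
        w[flat] = 1.0
        wsum = w.sum(axis=1, keepdims=True)
    cumw = np.cumsum(w, axis=1) / wsum
    dec = (positions - np.arange(k)[None, :]) / (n_universe - k)
    v_at = cumw - dec
    v_before = cumw - w / wsum - dec
    max_es = v_at.max(axis=1)
    min_es = np.minimum(v_before.min(axis=1), 0.0)
    return np.where(max_es >= -min_es, max_es, min_es)


def ks_enrichment(
    gene_set: GeneSet,
    stats: ContrastStats,
    cfg: EnsembleConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Weighted KS (GSEA-style, weight exponent 1) score and permutation p.

    The universe is sorted by signed statistic descending; the returned p is
    two-sided on |ES| under random member placement.  When the number of
    distinct placements C(N, K) does not exceed ``ks_n_perm`` the null is
    enumerated exhaustively (the p-value is then exact); otherwise
    ``ks_n_perm`` placements are sampled and the add-one estimator is used.
    """
    cfg = cfg or EnsembleConfig()
    member = _restrict(gene_set, stats)
    n_universe = len(stats.universe)
    k = int(member.sum())
    if k == 0:
        raise ValidationError(
            f"gene set {gene_set.name!r} shares no genes with contrast "
            f"{stats.name!r}"
        )
    if k == n_universe:
        raise ValidationError("KS enrichment needs at least one non-member")
    order = sorted(
        range(n_universe),
        key=lambda i: (-stats.stats[i], stats.universe[i]),
    )
    abs_sorted = np.abs(stats.stats[np.array(order)])
    member_sorted = member[np.array(order)]
    obs_pos = np.flatnonzero(member_sorted)[None, :]
    es_obs = float(_es_from_positions(obs_pos, abs_sorted, n_universe)[0])

    tol = 1e-12 + 1e-9 * abs(es_obs)
    if comb(n_universe, k) <= cfg.ks_n_perm:
        all_pos = np.array(
            list(combinations(range(n_universe), k)), dtype=int
        )
        es_null = _es_from_positions(all_pos, abs_sorted, n_universe)
        p = float(
            np.mean(np.abs(es_null) >= abs(es_obs) - tol)
        )  # exact: observed placement is one of the enumerated ones
    else:
        rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
        pos = np.argsort(
            rng.random((cfg.ks_n_perm, n_universe)), axis=1
        )[:, :k]
        pos.sort(axis=1)
        es_null = _es_from_positions(pos, abs_sorted, n_universe)
        exceed = int(np.sum(np.abs(es_null) >= abs(es_obs) - tol))
        p = (1.0 + exceed) / (1.0 + cfg.ks_n_perm)
    return es_obs, p


# -- combination and multiple testing --------------------------------------


def _check_pvalues(ps: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(ps), dtype=float)
    if arr.size == 0 or np.any(arr <= 0) or np.any(arr > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return arr


def combine_pvalues(ps: Sequence[float], method: str = "fisher") -> float:
    """Combine per-algorithm p-values into one collective significance.

    ``fisher``: χ² = −2Σln p on 2m df; ``stouffer``: equal-weight z
    combination; ``wilkinson_median``: Beta tail of the ⌈m/2⌉-th order
    statistic.
    """
    arr = _check_pvalues(ps)
    if arr.size < 2:
        raise ValidationError("need ≥ 2 p-values to combine")
    if method in ("fisher", "stouffer"):
        return float(min(st.combine_pvalues(arr, method=method).pvalue, 1.0))
    if method == "wilkinson_median":
        m = arr.size
        r = (m + 1) // 2
        return float(st.beta.cdf(np.sort(arr)[r - 1], r, m - r + 1))
    raise ConfigurationError(f"unknown combine method {method!r}")


def bh_adjust(ps: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    arr = _check_pvalues(ps)
    return list(multipletests(arr, method="fdr_bh")[1])


# -- ensemble driver -------------------------------------------------------


def ensemble_enrichment(
    sets: Sequence[GeneSet],
    contrasts: Sequence[ContrastStats],
    cfg: EnsembleConfig | None = None,
) -> EnrichmentTable:
    """Run the configured ensemble on every (contrast × gene set) pair.

    BH adjustment is applied across gene sets within each contrast (or
    globally with ``bh_scope="global"``); rows with adjusted p below the
    significance level are flagged.  The KS permutation stream is re-seeded
    per gene-set index, so identical contrasts produce identical rows.
    """
    cfg = cfg or EnsembleConfig()
    rows: list[dict] = []
    for stats in contrasts:
        for j, gene_set in enumerate(sets):
            row: dict = {
                "contrast": stats.name,
                "gene_set": gene_set.name,
                "n_genes": int(_restrict(gene_set, stats).sum()),
            }
            if "ora" in cfg.algorithms:
                row["p_ora"] = ora_test(gene_set, stats, cfg)
            if "ranksum" in cfg.algorithms:
                row["p_ranksum"] = ranksum_test(gene_set, stats)
            if "ks_perm" in cfg.algorithms:
                rng = np.random.default_rng(
                    np.random.SeedSequence([cfg.rng_seed, j])
                )
                es, p_ks = ks_enrichment(gene_set, stats, cfg, rng=rng)
                row["es_ks"] = es
                row["p_ks_perm"] = p_ks
            algo_ps = [
                row[c]
                for c in ("p_ora", "p_ranksum", "p_ks_perm")
                if c in row
            ]
            row["combined_p"] = combine_pvalues(algo_ps, cfg.combine_method)
            rows.append(row)
    df = pd.DataFrame(rows)
    if cfg.bh_scope == "contrast":
        df["adjusted_p"] = df.groupby("contrast", sort=False)[
            "combined_p"
        ].transform(lambda s: bh_adjust(list(s)))
    else:
        df["adjusted_p"] = bh_adjust(list(df["combined_p"]))
    df["significant"] = df["adjusted_p"] < cfg.significance
    metadata = {
        "algorithms": ",".join(cfg.algorithms),
        "ora_selection": cfg.ora_selection,
        "ks_n_perm": cfg.ks_n_perm,
        "combine_method": cfg.combine_method,
        "rng_seed": cfg.rng_seed,
        "significance": cfg.significance,
        "bh_scope": cfg.bh_scope,
    }
    return EnrichmentTable(table=df, metadata=metadata)


# -- file readers ----------------------------------------------------------


def read_expression_tsv(path: str) -> pd.DataFrame:
    """Genes × samples matrix; first column = gene id, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene ids")
    return df


def read_design_tsv(path: str) -> pd.Series:
    """Sample → group mapping from a 2-column (sample, group) TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: design file needs sample and group columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def read_stats_tsv(path: str, name: str | None = None) -> ContrastStats:
    """Precomputed per-gene statistics from a 2-column (gene, statistic) TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: stats file needs gene and statistic columns")
    cname = name or os.path.splitext(os.path.basename(path))[0]
    return ContrastStats(
        cname, list(df.iloc[:, 0].astype(str)), df.iloc[:, 1].to_numpy(float)
    )
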