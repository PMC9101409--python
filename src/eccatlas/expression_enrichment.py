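"""Expression of circle-associated vs genomic genes, and gene-set enrichment.

Per tumor: a gene is expressed when its FPKM exceeds zero; circle vs genome
classes come from gene_content; association between class and expression is
tested by Fisher's exact test, and per-tumor p-values combine by Fisher's
method.  Gene lists for enrichment are SD-thresholded (mean + k*SD); set
enrichment uses Fisher's exact test on the 2x2 in-list x in-set table over
a universe, optionally EASE-modified (overlap decremented by one).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_content import ClassifiedCohort
from .io_formats import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TumorExpressionStats:
    tumor_id: str
    n_circle_genes: int
    n_genome_genes: int
    pct_expressed_circle: float  # NaN when no circle genes
    pct_expressed_genome: float
    mean_fpkm_circle: float  # over expressed genes only; NaN when none
    mean_fpkm_genome: float
    fisher_p: float


def tumor_expression_stats(
    classified: ClassifiedCohort, expr: pd.DataFrame
) -> list[TumorExpressionStats]:
    """Per-tumor expression summary of circle vs genome gene classes.

    Tumors absent from the expression matrix are skipped with a warning (the
    source data lacked RNA-seq for one cancer type, so this is routine).
    """
    out = []
    measured = set(expr.index)
    for tumor in classified.tumor_ids:
        if tumor not in expr.columns:
            logger.warning("tumor %s has no expression data; skipped", tumor)
            continue
        col = expr[tumor]
        circle = sorted((classified.circle_gene_union(tumor) & measured))
        genome = sorted((classified.genome_genes[tumor] & measured))
        c_vals = col.loc[circle].to_numpy(dtype=float)
        g_vals = col.loc[genome].to_numpy(dtype=float)
        c_exp, g_exp = int((c_vals > 0).sum()), int((g_vals > 0).sum())
        table = [[c_exp, len(circle) - c_exp], [g_exp, len(genome) - g_exp]]
        if len(circle) == 0 or len(genome) == 0:
            fisher_p = float("nan")
        else:
            fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        out.append(
            TumorExpressionStats(
                tumor_id=tumor,
                n_circle_genes=len(circle),
                n_genome_genes=len(genome),
                pct_expressed_circle=(100.0 * c_exp / len(circle)
                                      if circle else float("nan")),
                pct_expressed_genome=(100.0 * g_exp / len(genome)
                                      if genome else float("nan")),
                mean_fpkm_circle=(float(c_vals[c_vals > 0].mean())
                                  if c_exp else float("nan")),
                mean_fpkm_genome=(float(g_vals[g_vals > 0].mean())
                                  if g_exp else float("nan")),
                fisher_p=fisher_p,
            )
        )
    return out


def stats_frame(stats_list: Sequence[TumorExpressionStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stats_list]).set_index("tumor_id")


def combine_pvalues_fisher(ps: Sequence[float]) -> float:
    """Fisher's method: X2 = -2*sum(ln p) against chi-square with 2k df."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValidationError("no p-values to combine")
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    res = stats.combine_pvalues(ps, method="fisher")
    return float(res.pvalue)


def per_type_comparison(
    stats_list: Sequence[TumorExpressionStats],
    tumor_type_map: Mapping[str, str],
) -> pd.DataFrame:
    """Paired two-tailed t-tests (circle vs genome, over tumors) per cancer type."""
    rows = []
    df = stats_frame(stats_list)
    df["type"] = [tumor_type_map.get(t, "NA") for t in df.index]
    for ctype, sub in df.groupby("type"):
        sub = sub.dropna(subset=["pct_expressed_circle", "pct_expressed_genome"])
        if len(sub) < 2:
            logger.warning("cancer type %s has < 2 tumors; skipped", ctype)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-variance pairs -> NaN, flagged
            t_pct = stats.ttest_rel(sub["pct_expressed_circle"],
                                    sub["pct_expressed_genome"])
            fp = sub.dropna(subset=["mean_fpkm_circle", "mean_fpkm_genome"])
            t_fpkm = (stats.ttest_rel(fp["mean_fpkm_circle"], fp["mean_fpkm_genome"])
                      if len(fp) >= 2 else None)
        rows.append({
            "type": ctype,
            "n_tumors": len(sub),
            "mean_pct_circle": float(sub["pct_expressed_circle"].mean()),
            "mean_pct_genome": float(sub["pct_expressed_genome"].mean()),
            "t_pct": float(t_pct.statistic),
            "p_pct": float(t_pct.pvalue),
            "t_fpkm": float(t_fpkm.statistic) if t_fpkm else float("nan"),
            "p_fpkm": float(t_fpkm.pvalue) if t_fpkm else float("nan"),
        })
    return pd.DataFrame(rows)


def sd_threshold_list(values: Mapping[str, float], k_sd: float) -> list[str]:
    """Genes whose value exceeds mean + k_sd * sample SD (ddof=1)."""
    if len(values) < 2:
        raise ValidationError("need >= 2 values for an SD threshold")
    keys = list(values)
    arr = np.array([values[k] for k in keys], dtype=float)
    sd = float(arr.std(ddof=1))
    if sd == 0:
        logger.warning("zero variance; SD-threshold list is empty")
        return []
    cutoff = float(arr.mean()) + k_sd * sd
    return [k for k, v in zip(keys, arr) if v > cutoff]


def commonality_ranking(
    classified: ClassifiedCohort, expr: pd.DataFrame
) -> dict[str, int]:
    """Per gene: number of tumors where it is both circle-associated and expressed."""
    counts: dict[str, int] = {g: 0 for g in sorted(classified.all_genes)}
    for tumor in classified.tumor_ids:
        if tumor not in expr.columns:
            continue
        col = expr[tumor]
        for gene in classified.circle_gene_union(tumor):
            if gene in col.index and col.loc[gene] > 0:
                counts[gene] += 1
    return counts


def gene_set_enrichment(
    gene_list: Sequence[str],
    universe: Sequence[str],
    gmt: Mapping[str, set[str]],
    mode: str = "ease",
) -> pd.DataFrame:
    """Fisher's-exact gene-set over-representation.

    mode="standard": one-sided Fisher's exact on the raw 2x2 table.
    mode="ease" (default): the observed overlap is decremented by one before
    the test (floor 0), the conservative "modified Fisher's exact" of the
    EASE/DAVID tradition.
    """
    if mode not in {"standard", "ease"}:
        raise ValidationError(f"unknown enrichment mode {mode!r}")
    gene_set_list = set(gene_list)
    uni = set(universe)
    if not gene_set_list:
        raise ValidationError("empty gene list")
    if not gene_set_list <= uni:
        raise ValidationError("gene list is not a subset of the universe")
    n_list, n_uni = len(gene_set_list), len(uni)
    rows = []
    for name, members in gmt.items():
        members = members & uni
        k = len(gene_set_list & members)
        # EASE penalizes the overlap cell by one (floor 0), leaving the other
        # cells as observed -- the jackknifed table of the EASE/DAVID tradition.
        k_eff = max(k - 1, 0) if mode == "ease" else k
        table = [
            [k_eff, n_list - k],
            [len(members) - k, n_uni - n_list - len(members) + k],
        ]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append({
            "set_name": name,
            "overlap_count": k,
            "list_size": n_list,
            "set_size": len(members),
            "universe_size": n_uni,
            "p": p,
        })
    df = pd.DataFrame(rows).sort_values(["p", "set_name"]).reset_index(drop=True)
    return df


def tally_pathways(
    per_tumor_enrichments: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> pd.Series:
    """Number of tumors in which each set is enriched at p < alpha, descending."""
    counts: dict[str, int] = {}
    for _tumor, df in per_tumor_enrichments.items():
        for _, row in df.iterrows():
            counts.setdefault(row["set_name"], 0)
            if row["p"] < alpha:
                counts[row["set_name"]] += 1
    return pd.Series(counts, name="n_tumors_enriched").sort_values(
        ascending=False, kind="stable"
    )
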