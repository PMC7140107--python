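"""Expression statistics tied to global hypomethylation.

* regularized (Bayesian) two-sample t — per-gene variances are shrunk toward
  a local background estimated from genes of similar average intensity
  (the Baldi-Long form used by Cyber-T style analyses):
  ``s2_reg = (prior_df * s2_bg + (n - 2) * s2_gene) / (prior_df + n - 2)``,
  with the t statistic on the shrunk pooled variance and
  ``prior_df + n - 2`` degrees of freedom.  ``prior_df = 0`` recovers the
  ordinary pooled two-sample t.
* DEG share — percent of differentially expressed genes up-regulated in the
  case group.
* proliferation-normalized expression — per-sample log2 ratio of a gene to a
  canonical proliferation marker (MKI67, PLK1, BUB1, ...), the relevant
  measure of maintenance-methylation capacity in fast-cycling tumors.
* in-block MAD — per-gene median absolute deviation of expression across
  case samples, contrasted between genes inside and outside hypomethylated
  blocks.
* CIN25 score — mean case-vs-reference log2 fold change over a 25-gene
  chromosomal-instability signature (the gene list is an input, not baked in).
* repeat-element summary — per-family (delta expression, delta methylation)
  pairs with quadrant counts and a Spearman trend.

Inputs are assumed log2; apparently linear-scale matrices (values > 30) are
rejected rather than silently transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .block_calling import bh_adjust
from .feature_enrichment import _blocks_intervals
from .genome_intervals import Interval, points_in_set
from .io_formats import ExpressionTable


@dataclass(frozen=True)
class RegTConfig:
    window: int = 101
    prior_df: float = 10.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")


def _check_log_scale(values: pd.DataFrame) -> None:
    if np.nanmax(values.to_numpy()) > 30:
        raise ValueError(
            "expression values exceed 30; matrix looks linear-scale — "
            "log2-transform it before analysis"
        )


def _group_columns(expr: ExpressionTable, groups, labels=None):
    ref_name, case_name = groups
    lab = labels if labels is not None else expr.groups
    ref = [s for s in expr.samples if lab.get(s) == ref_name]
    case = [s for s in expr.samples if lab.get(s) == case_name]
    if len(ref) < 1 or len(case) < 1:
        missing = ref_name if not ref else case_name
        raise ValueError(f"no samples labeled {missing!r} in expression table")
    return ref, case


def regularized_t(
    expr: ExpressionTable,
    groups: tuple[str, str],
    config: RegTConfig = RegTConfig(),
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene (mean_diff, t_reg, p, q) for case minus reference.

    Background variance for each gene is the mean pooled variance of the
    ``window`` genes nearest in average intensity (intensity-ranked sliding
    window, clipped at the ends of the ranking).
    """
    _check_log_scale(expr.values)
    ref, case = _group_columns(expr, groups, labels)
    if len(ref) < 2 or len(case) < 2:
        raise ValueError("regularized t needs >= 2 samples per group")
    x_ref = expr.values[ref].to_numpy()
    x_case = expr.values[case].to_numpy()
    n1, n2 = x_ref.shape[1], x_case.shape[1]
    n = n1 + n2
    mean_diff = x_case.mean(axis=1) - x_ref.mean(axis=1)
    ss = x_ref.var(axis=1, ddof=1) * (n1 - 1) + x_case.var(axis=1, ddof=1) * (n2 - 1)
    s2_gene = ss / (n - 2)

    # local background: mean pooled variance in an intensity-ranked window
    intensity = expr.values.to_numpy().mean(axis=1)
    order = np.argsort(intensity, kind="stable")
    w = min(config.window, len(order))
    half = w // 2
    csum = np.concatenate([[0.0], np.cumsum(s2_gene[order])])
    g = len(order)
    lo = np.clip(np.arange(g) - half, 0, max(g - w, 0))
    hi = lo + w
    bg_sorted = (csum[hi] - csum[lo]) / w
    s2_bg = np.empty(g)
    s2_bg[order] = bg_sorted

    d0 = config.prior_df
    s2_reg = (d0 * s2_bg + (n - 2) * s2_gene) / (d0 + n - 2)
    se = np.sqrt(s2_reg * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / se
    df = d0 + n - 2
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(p), np.where(mean_diff == 0, 1.0, np.nan), p)
    out = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "t_reg": t,
            "p": p,
            "q": bh_adjust(np.nan_to_num(p, nan=1.0)),
        },
        index=expr.values.index,
    )
    if np.isnan(p).any():
        out.loc[np.isnan(p), "q"] = np.nan
    return out


def deg_share(n_deg: int, n_up: int) -> float:
    """Exact percent of DEGs up-regulated in the case group.

    Kept unrounded so the count is recoverable; round to integer for display.
    """
    if n_deg <= 0:
        raise ValueError("deg_share undefined for n_deg = 0")
    if not 0 <= n_up <= n_deg:
        raise ValueError("need 0 <= n_up <= n_deg")
    return 100.0 * n_up / n_deg


def deg_summary(reg: pd.DataFrame, p_cutoff: float = 0.01) -> dict:
    """Count DEGs at a p cutoff and the share up-regulated in the case group."""
    deg = reg[reg["p"] < p_cutoff]
    n_deg = len(deg)
    n_up = int((deg["mean_diff"] > 0).sum())
    return {
        "n_deg": n_deg,
        "n_up_case": n_up,
        "pct_up": round(deg_share(n_deg, n_up)) if n_deg else float("nan"),
    }


def proliferation_normalize(
    expr: ExpressionTable,
    gene: str,
    marker: str,
    groups: tuple[str, str] | None = None,
    labels: dict[str, str] | None = None,
) -> dict:
    """Per-sample log2(gene) - log2(marker) ratios, optionally group-compared.

    On log2 input the ratio is a simple difference.  When ``groups`` is given
    the (ref, case) ratios are compared with a two-sided Mann-Whitney U.
    """
    for g in (gene, marker):
        if g not in expr.values.index:
            raise KeyError(f"gene {g!r} not present in expression matrix")
    ratio = expr.values.loc[gene] - expr.values.loc[marker]
    out = {"gene": gene, "marker": marker, "ratio": ratio}
    if groups is not None:
        ref, case = _group_columns(expr, groups, labels)
        res = stats.mannwhitneyu(ratio[case], ratio[ref], alternative="two-sided")
        out.update(
            {
                "median_ref": float(ratio[ref].median()),
                "median_case": float(ratio[case].median()),
                "U": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    return out


def gene_mad(values: np.ndarray) -> float:
    """median(|x - median(x)|), the raw (unscaled) MAD."""
    v = np.asarray(values, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def mad_in_blocks(
    expr: ExpressionTable,
    gene_coords: dict[str, Interval],
    blocks,
    case_samples: list[str],
    paired: bool = False,
) -> dict:
    """Per-gene expression MAD across case samples, in-block vs out-block.

    Genes are assigned to blocks by midpoint.  The two MAD distributions are
    compared with a two-sided Mann-Whitney U by default; ``paired=True``
    matches in- and out-block genes by mean-expression rank and applies a
    Wilcoxon signed-rank on the pairs.
    """
    genes = [g for g in expr.values.index if g in gene_coords]
    if not genes:
        raise ValueError("no genes with coordinates in the expression matrix")
    block_ivs = _blocks_intervals(blocks)
    pts = [(gene_coords[g].chrom, gene_coords[g].midpoint) for g in genes]
    inside = points_in_set(pts, block_ivs)
    mat = expr.values.loc[genes, case_samples].to_numpy()
    mads = np.median(np.abs(mat - np.median(mat, axis=1, keepdims=True)), axis=1)
    table = pd.DataFrame(
        {"gene": genes, "mad": mads, "group": np.where(inside, "in_block", "out_block")}
    )
    mad_in = mads[inside]
    mad_out = mads[~inside]
    if len(mad_in) == 0:
        raise ValueError("no genes fall inside blocks")
    if len(mad_out) == 0:
        raise ValueError("no genes fall outside blocks")
    if paired:
        mean_expr = expr.values.loc[genes, case_samples].mean(axis=1).to_numpy()
        k = min(len(mad_in), len(mad_out))
        in_sorted = mad_in[np.argsort(mean_expr[inside], kind="stable")][:k]
        out_sorted = mad_out[np.argsort(mean_expr[~inside], kind="stable")][:k]
        res = stats.wilcoxon(in_sorted, out_sorted)
        test = "wilcoxon_rank_matched"
    else:
        res = stats.mannwhitneyu(mad_in, mad_out, alternative="two-sided")
        test = "mannwhitney"
    return {
        "table": table,
        "median_mad_in": float(np.median(mad_in)),
        "median_mad_out": float(np.median(mad_out)),
        "n_in": int(len(mad_in)),
        "n_out": int(len(mad_out)),
        "test": test,
        "p": float(res.pvalue),
    }


def cin25_score(
    expr: ExpressionTable,
    signature_genes: list[str],
    groups: tuple[str, str],
    config: RegTConfig = RegTConfig(),
    labels: dict[str, str] | None = None,
) -> dict:
    """Mean case-vs-reference log2 fold change over a CIN signature.

    Per-gene log2FC is the case-minus-reference mean difference; per-gene p
    comes from the regularized t over the full matrix.  Missing signature
    genes are reported, not fatal, unless none are present.
    """
    present = [g for g in signature_genes if g in expr.values.index]
    missing = [g for g in signature_genes if g not in expr.values.index]
    if not present:
        raise ValueError("none of the signature genes are in the expression matrix")
    reg = regularized_t(expr, groups, config, labels)
    per_gene = reg.loc[present, ["mean_diff", "p"]].rename(
        columns={"mean_diff": "log2fc"}
    )
    return {
        "per_gene": per_gene,
        "score": float(per_gene["log2fc"].mean()),
        "n_significant": int((per_gene["p"] < 0.05).sum()),
        "n_present": len(present),
        "missing": missing,
    }


def re_expression_summary(
    re_expr: pd.Series, re_meth: pd.Series
) -> dict:
    """Join per-repeat-family expression and methylation changes.

    Returns the joined (delta_expression, delta_methylation) table, the count
    of families with increased expression and decreased methylation, and the
    Spearman correlation across families.
    """
    shared = re_expr.index.intersection(re_meth.index)
    if len(shared) == 0:
        raise ValueError("no shared repeat families between the two inputs")
    table = pd.DataFrame(
        {"delta_expression": re_expr[shared], "delta_methylation": re_meth[shared]}
    )
    up_hypo = int(
        ((table["delta_expression"] > 0) & (table["delta_methylation"] < 0)).sum()
    )
    if len(shared) >= 3 and table.nunique().min() > 1:
        rho, p = stats.spearmanr(
            table["delta_methylation"], table["delta_expression"]
        )
    else:
        rho, p = float("nan"), float("nan")
    return {
        "table": table,
        "n_families": int(len(shared)),
        "n_up_expression_hypo_methylation": up_hypo,
        "spearman_rho": float(rho),
        "spearman_p": float(p),
    }
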