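"""CROP-seq analysis stages: singlet sgRNA assignment, knockdown-cell
selection, per-target differential expression, cluster-occupancy enrichment
and Fisher's-exact state-proportion tests.

Cluster labels are consumed as input metadata (clustering itself is upstream
and out of scope here).  Ambient-aware demultiplexing is approximated by a
z-score rule on log1p sgRNA UMI counts with a minimum-UMI floor and a
runner-up exclusion, so only unambiguous single-sgRNA cells are carried
forward — the operational core of combined-caller singlet selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .library_io import CellTensorBundle, LibraryManifest, NTC_LABEL

__all__ = [
    "assign_sgrnas",
    "select_knockdown_cells",
    "knockdown_deg",
    "run_deg_analysis",
    "cluster_occupancy",
    "state_proportion_test",
    "OccupancyMatrix",
]


def _dense(matrix: Union[np.ndarray, sp.spmatrix]) -> np.ndarray:
    if sp.issparse(matrix):
        return np.asarray(matrix.todense())
    return np.asarray(matrix)


def assign_sgrnas(
    sgrna_umi: Union[np.ndarray, sp.spmatrix],
    sgrna_ids: Sequence[str],
    z_cutoff: float = 3.0,
    min_umi: int = 5,
    manifest: Optional[LibraryManifest] = None,
) -> pd.DataFrame:
    """Singlet sgRNA assignment by a z-score rule on log1p UMI counts.

    Per cell, the background is every guide except the single maximum; a
    candidate guide is *called* if its raw count is at least ``min_umi`` and
    its log1p count sits at least ``z_cutoff`` background standard deviations
    above the background mean.  The top guide is assigned iff it is called
    and the runner-up is not; otherwise the cell is left unassigned with
    reason ``no_signal`` (top fails) or ``ambiguous_multiple`` (both pass).

    Returns a DataFrame aligned to cells with columns
    ``assigned_sgrna, reason, z_top`` (plus ``assigned_gene`` when a manifest
    is given).  The assignment is invariant to sgRNA column order.
    """
    counts = _dense(sgrna_umi).astype(float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError(
            "need a cell x sgRNA matrix with at least 2 sgRNA columns "
            "(background undefined otherwise)"
        )
    if counts.shape[1] != len(sgrna_ids):
        raise ValueError("sgrna_ids length mismatch")
    if np.any(counts < 0):
        raise ValueError("sgRNA UMI counts must be nonnegative")

    log_counts = np.log1p(counts)
    # order[:, -1] is the top guide, order[:, -2] the runner-up; ties broken
    # deterministically toward the higher column index via stable sort.
    order = np.argsort(log_counts, axis=1, kind="stable")
    top_j = order[:, -1]
    run_j = order[:, -2]
    rows = np.arange(counts.shape[0])
    bg = log_counts.copy()
    bg[rows, top_j] = np.nan
    with np.errstate(invalid="ignore"):
        bg_mean = np.nanmean(bg, axis=1)
        bg_sd = np.nanstd(bg, axis=1, ddof=0)
    bg_mean = np.nan_to_num(bg_mean)  # 2-column case: single background value
    bg_sd = np.nan_to_num(bg_sd)

    def z_of(values: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (values - bg_mean) / bg_sd
        # degenerate background: any strictly-above-background signal is infinitely
        # separated; at or below background it is not separated at all
        z = np.where(bg_sd == 0, np.where(values > bg_mean, np.inf, -np.inf), z)
        return z

    z_top = z_of(log_counts[rows, top_j])
    z_run = z_of(log_counts[rows, run_j])
    top_called = (counts[rows, top_j] >= min_umi) & (z_top >= z_cutoff)
    run_called = (counts[rows, run_j] >= min_umi) & (z_run >= z_cutoff)

    assigned = top_called & ~run_called
    reason = np.where(assigned, "assigned",
                      np.where(top_called, "ambiguous_multiple", "no_signal"))
    ids = np.asarray(list(sgrna_ids), dtype=object)
    out = pd.DataFrame(
        {
            "assigned_sgrna": np.where(assigned, ids[top_j], ""),
            "reason": reason,
            "z_top": z_top,
        }
    )
    if manifest is not None:
        gene_of = manifest.sgrna_to_gene()
        out["assigned_gene"] = [
            gene_of.get(s, "") if s else "" for s in out["assigned_sgrna"]
        ]
    return out


def lognorm_expression(
    expr: Union[np.ndarray, sp.spmatrix], scale: float = 1e6
) -> np.ndarray:
    """log1p counts-per-``scale`` normalization of a cell x gene matrix."""
    counts = _dense(expr).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        totals = np.where(totals == 0, 1.0, totals)
    return np.log1p(counts * (scale / totals))


class EmptySelection(Exception):
    """No cells are assigned to the requested target (distinct from an error)."""


def select_knockdown_cells(
    expr: Union[np.ndarray, sp.spmatrix],
    genes: Sequence[str],
    assignment: pd.DataFrame,
    target_gene: str,
) -> np.ndarray:
    """Indices of the strongest-knockdown cells for one CRISPRi target.

    Among cells assigned to sgRNAs of ``target_gene``, keep those whose
    normalized (log1p-CPM) target expression lies strictly below the median
    of that same population.  Raises :class:`EmptySelection` when no cell is
    assigned to the target.
    """
    genes = list(genes)
    if target_gene not in genes:
        raise ValueError(f"target gene {target_gene!r} not in expression matrix")
    if "assigned_gene" not in assignment.columns:
        raise ValueError("assignment must carry an assigned_gene column")
    cell_idx = np.flatnonzero((assignment["assigned_gene"] == target_gene).to_numpy())
    if cell_idx.size == 0:
        raise EmptySelection(target_gene)
    norm = lognorm_expression(expr)
    target_expr = norm[cell_idx, genes.index(target_gene)]
    return cell_idx[target_expr < np.median(target_expr)]


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown correction {method!r}")


def knockdown_deg(
    expr: Union[np.ndarray, sp.spmatrix],
    genes: Sequence[str],
    kd_cells: np.ndarray,
    ntc_cells: np.ndarray,
    min_cells: int = 2,
    alpha: float = 0.1,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-gene differential expression between knockdown and NTC cells.

    Expression is log1p-CPM normalized and z-scored per gene across the two
    groups jointly; each gene is then tested with a Welch two-sample t-test.
    The effect is the difference of standardized group means (knockdown minus
    NTC).  P-values are multiplicity-adjusted (Bonferroni by default,
    Benjamini-Hochberg with ``correction="bh"``); a gene is significant iff
    its adjusted p is below ``alpha``.
    """
    kd_cells = np.asarray(kd_cells)
    ntc_cells = np.asarray(ntc_cells)
    if kd_cells.size < min_cells or ntc_cells.size < min_cells:
        raise ValueError(
            f"both groups need >= {min_cells} cells "
            f"(got {kd_cells.size} knockdown, {ntc_cells.size} NTC)"
        )
    norm = lognorm_expression(expr)
    sub = norm[np.concatenate([kd_cells, ntc_cells])]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (sub - mu) / sd_safe
    a = z[: kd_cells.size]
    b = z[kd_cells.size :]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0   # zero-variance genes carry no evidence
    p[sd == 0] = 1.0
    effect = a.mean(axis=0) - b.mean(axis=0)
    p_adj = _adjust(p, correction)
    return pd.DataFrame(
        {
            "gene": list(genes),
            "effect": effect,
            "p_value": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        }
    )


def run_deg_analysis(
    bundle: CellTensorBundle,
    assignment: pd.DataFrame,
    manifest: LibraryManifest,
    min_cells: int = 2,
    alpha: float = 0.1,
    correction: str = "bonferroni",
    top_n: int = 20,
    summary_min_cells: int = 50,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict[str, str]]:
    """Knockdown-vs-NTC differential expression for every library target.

    For each target gene, the strongest-knockdown cells (below-median target
    expression among its assigned cells) are compared against all NTC-assigned
    cells.  Targets whose knockdown population exceeds ``summary_min_cells``
    contribute their ``top_n`` genes by |effect| to the convergence summary;
    smaller targets remain in the full tables only.

    Returns ``(tables_by_target, summary, skipped)`` where ``skipped`` maps
    target -> reason for targets that could not be tested.
    """
    ntc_cells = np.flatnonzero((assignment["assigned_gene"] == NTC_LABEL).to_numpy())
    tables: dict[str, pd.DataFrame] = {}
    summaries = []
    skipped: dict[str, str] = {}
    for target in manifest.target_genes:
        if target not in bundle.genes:
            skipped[target] = "target gene absent from expression matrix"
            continue
        try:
            kd = select_knockdown_cells(bundle.expr, bundle.genes, assignment, target)
        except EmptySelection:
            skipped[target] = "no cells assigned"
            continue
        if kd.size < min_cells or ntc_cells.size < min_cells:
            skipped[target] = f"group below min_cells ({kd.size} knockdown cells)"
            continue
        table = knockdown_deg(
            bundle.expr, bundle.genes, kd, ntc_cells, min_cells, alpha, correction
        )
        table.attrs["n_kd_cells"] = int(kd.size)
        tables[target] = table
        if kd.size > summary_min_cells:
            top = table.reindex(
                table["effect"].abs().sort_values(ascending=False).index
            ).head(top_n)
            top = top.assign(target_gene=target, n_kd_cells=kd.size)
            summaries.append(top)
    summary = (
        pd.concat(summaries, ignore_index=True)
        if summaries
        else pd.DataFrame(
            columns=["gene", "effect", "p_value", "p_adj", "significant",
                     "target_gene", "n_kd_cells"]
        )
    )
    return tables, summary, skipped


@dataclass
class OccupancyMatrix:
    """Cluster occupancy relative to NTC cells.

    ``relative`` holds ``(n_gc / n_g) / (n_NTCc / n_NTC)`` for gene g and
    cluster c (NaN where the NTC proportion is zero); ``counts`` the raw cell
    tallies.  The NTC row is identically 1 wherever defined.
    """

    relative: pd.DataFrame
    counts: pd.DataFrame
    n_excluded_no_cluster: int = 0


def cluster_occupancy(
    assignment: pd.DataFrame,
    cluster_labels: Sequence,
    level: str = "gene",
) -> OccupancyMatrix:
    """Relative cluster occupancy of each perturbation versus NTC cells.

    ``assignment`` must carry ``assigned_sgrna``/``assigned_gene``;
    ``cluster_labels`` is aligned per cell (missing/empty labels are excluded
    with a count).  ``level="gene"`` pools a gene's sgRNAs (default);
    ``level="sgrna"`` keeps guides separate while NTC cells stay pooled as
    the reference.
    """
    if level not in ("gene", "sgrna"):
        raise ValueError("level must be 'gene' or 'sgrna'")
    labels = pd.Series(list(cluster_labels)).astype(object).reset_index(drop=True)
    df = assignment.reset_index(drop=True).copy()
    if len(labels) != len(df):
        raise ValueError("cluster_labels must align with assignment rows")
    df["cluster"] = labels
    df = df[df["assigned_sgrna"] != ""]
    n_no_cluster = int((df["cluster"].isna() | (df["cluster"] == "")).sum())
    df = df[~(df["cluster"].isna() | (df["cluster"] == ""))]
    if not (df["assigned_gene"] == NTC_LABEL).any():
        raise ValueError("no NTC cells among assigned cells; occupancy undefined")

    group_col = "assigned_gene" if level == "gene" else "assigned_sgrna"
    df = df.copy()
    if level == "sgrna":
        # pool NTC guides as the single reference row
        df.loc[df["assigned_gene"] == NTC_LABEL, group_col] = NTC_LABEL
    counts = (
        df.groupby([group_col, "cluster"], sort=True).size().unstack(fill_value=0)
    )
    counts.index.name = "group"
    ntc_counts = counts.loc[NTC_LABEL]
    ntc_prop = ntc_counts / ntc_counts.sum()
    prop = counts.div(counts.sum(axis=1), axis=0)
    relative = prop.div(ntc_prop, axis=1)
    relative[ntc_prop.index[ntc_prop == 0]] = np.nan
    # put NTC first for readability
    order = [NTC_LABEL] + [g for g in counts.index if g != NTC_LABEL]
    return OccupancyMatrix(
        relative=relative.loc[order],
        counts=counts.loc[order],
        n_excluded_no_cluster=n_no_cluster,
    )


def state_proportion_test(table: Union[np.ndarray, Sequence[Sequence[int]]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 (group x in-state) table.

    Returns ``(p_value, odds_ratio)`` with the exact hypergeometric two-sided
    p (sum of tables at most as probable as the observed one) and the sample
    odds ratio ``(a*d)/(b*c)`` (inf when b*c == 0).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 contingency table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has an empty margin")
    res = stats.fisher_exact(t, alternative="two-sided")
    return float(res.pvalue), float(res.statistic)
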