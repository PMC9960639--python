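"""Hurdle-model differential expression and gene-set enrichment.

The two-part (hurdle) model is the standard for full-length scRNA-seq, where
a gene's signal has a detection component and a continuous component:

* logistic part — detection (CPM > 0) ~ group + CDR,
* continuous part — log2(CPM + 1) among detected cells ~ group + CDR,

where CDR, the cellular detection rate (fraction of test genes detected per
cell, standardized), absorbs the dominant technical covariate. Per gene the
two likelihood-ratio statistics are summed and referred to a chi-square with
the summed degrees of freedom. The continuous part's LR is computed as the
chi-square deviate equivalent to the exact F-test p-value, which keeps the
summed-chi-square framework while being exactly calibrated at small cell
numbers. The reported log2 fold-change is the difference of group means of
log2(CPM + 1) over *all* cells (zeros included), matching the symmetric
scale used for heatmaps.

No shrinkage is applied to either part; the continuous part is ordinary
least squares.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from scstress.io import ExpressionMatrix

__all__ = [
    "hurdle_test",
    "compute_cdr",
    "bh_adjust",
    "call_degs",
    "overlap_sets",
    "hypergeom_enrich",
]

#: tiny L2 penalty on non-intercept logistic coefficients: keeps the MLE
#: finite under (quasi-)separation while leaving calibration essentially
#: untouched; invariant under a group-label swap (the group coefficient
#: only changes sign)
_LOGISTIC_RIDGE = 1e-3


def compute_cdr(matrix: ExpressionMatrix, standardize: bool = True) -> pd.Series:
    """Cellular detection rate: per-cell fraction of genes with signal > 0."""
    cdr = (matrix.values > 0).mean(axis=0)
    if standardize:
        sd = cdr.std(ddof=0)
        cdr = (cdr - cdr.mean()) / (sd if sd > 0 else 1.0)
    return cdr.rename("cdr")


# ---------------------------------------------------------------------------
# batched logistic regression (Newton / IRLS across genes)
# ---------------------------------------------------------------------------

def _logistic_loglik_batched(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Maximized Bernoulli log-likelihood per column of Y for design X.

    X is n × p (shared), Y is n × G of 0/1. Newton iterations are run for
    all genes simultaneously. A tiny ridge penalty on the non-intercept
    coefficients keeps near-separated genes finite; the returned value is
    the penalized log-likelihood (the penalty term cancels to first order
    in the full-vs-reduced difference).
    """
    n, p = X.shape
    G = Y.shape[1]
    beta = np.zeros((G, p))
    pen = np.full(p, _LOGISTIC_RIDGE)
    pen[0] = 0.0                      # intercept unpenalized
    pen_mat = np.diag(pen)

    def pll(b: np.ndarray) -> np.ndarray:
        eta = X @ b.T
        return (np.sum(Y * eta - np.logaddexp(0.0, eta), axis=0)
                - 0.5 * np.sum(b**2 * pen, axis=1))

    current = pll(beta)
    for _ in range(100):
        eta = X @ beta.T              # n × G
        mu = special.expit(eta)
        W = mu * (1.0 - mu)
        grad = np.einsum("np,ng->gp", X, Y - mu) - beta * pen
        hess = np.einsum("ni,ng,nj->gij", X, W, X) + pen_mat + np.eye(p) * 1e-8
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("gij,gj->gi", np.linalg.pinv(hess), grad)
        # damped update: halve any step that fails to improve the objective
        scale = np.ones(G)
        for _half in range(30):
            cand = beta + scale[:, None] * step
            new = pll(cand)
            worse = new < current - 1e-12
            if not worse.any():
                break
            scale[worse] *= 0.5
        cand = beta + scale[:, None] * step
        new = pll(cand)
        accept = new >= current
        beta[accept] = cand[accept]
        improved = new[accept] - current[accept]
        current[accept] = new[accept]
        if np.max(np.abs(step)) < 1e-10 or (improved.size and improved.max() < 1e-12):
            break
    return current


def hurdle_test(
    matrix: ExpressionMatrix,
    groups: pd.Series | Mapping[str, str],
    reference: str | None = None,
    covariate: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-part hurdle differential expression between two cell groups.

    Parameters
    ----------
    matrix : CPM expression over the (already filtered) test genes.
    groups : two-level label per cell; ``reference`` names the baseline
        level (default: the lexicographically smaller label). log2FC is
        stressed-minus-reference.
    covariate : per-cell detection-rate covariate; computed from the matrix
        (standardized CDR) when omitted.

    Returns a per-gene table with ``log2fc, p_value, fdr, detect_ref,
    detect_test, df, parts`` where ``parts`` records which model parts were
    testable (``both``, ``logistic``, ``continuous`` or ``none``). Genes
    undetected in all cells get NaN statistics.
    """
    if matrix.unit not in ("CPM", "TPM", "counts"):
        raise ValueError(f"expected an unlogged expression unit, got {matrix.unit}")
    groups = pd.Series(groups).reindex(matrix.cell_ids)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    ref = reference if reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference {ref!r} not among group levels {levels}")
    test_level = [lv for lv in levels if lv != ref][0]
    for lv in levels:
        if (groups == lv).sum() < 3:
            raise ValueError(f"group {lv!r} has fewer than 3 cells")

    V = matrix.values.to_numpy(dtype=float)          # genes × cells
    logv = np.log2(V + 1.0)
    D = (V > 0)
    g = (groups == test_level).to_numpy(dtype=float)
    cdr = (covariate.reindex(matrix.cell_ids) if covariate is not None
           else compute_cdr(matrix)).to_numpy(dtype=float)

    n_cells = V.shape[1]
    X_full = np.column_stack([np.ones(n_cells), g, cdr])
    X_red = np.column_stack([np.ones(n_cells), cdr])

    ref_mask = g == 0
    test_mask = g == 1
    detect_ref = D[:, ref_mask].mean(axis=1)
    detect_test = D[:, test_mask].mean(axis=1)
    log2fc = logv[:, test_mask].mean(axis=1) - logv[:, ref_mask].mean(axis=1)

    n_det = D.sum(axis=1)
    # logistic part testable unless detection is constant across cells
    logistic_ok = (n_det > 0) & (n_det < n_cells)
    # continuous part needs >= 3 detected cells per group and residual df
    det_ref_n = D[:, ref_mask].sum(axis=1)
    det_test_n = D[:, test_mask].sum(axis=1)
    continuous_ok = (det_ref_n >= 3) & (det_test_n >= 3) & (n_det >= 5)

    G = V.shape[0]
    lr = np.zeros(G)
    df = np.zeros(G, dtype=int)

    if logistic_ok.any():
        Y = D[logistic_ok].T.astype(float)           # n × G'
        ll_full = _logistic_loglik_batched(X_full, Y)
        ll_red = _logistic_loglik_batched(X_red, Y)
        lr[logistic_ok] += np.maximum(0.0, 2.0 * (ll_full - ll_red))
        df[logistic_ok] += 1

    for i in np.flatnonzero(continuous_ok):
        mask = D[i]
        y = logv[i, mask]
        Xf = X_full[mask]
        Xr = X_red[mask]
        nd = y.size
        if nd <= Xf.shape[1]:
            continuous_ok[i] = False
            continue
        bf, rss_f = _ols_rss(Xf, y)
        br, rss_r = _ols_rss(Xr, y)
        if rss_f <= 0:
            p_cont = 0.0 if rss_r > rss_f else 1.0
        else:
            F = (rss_r - rss_f) / (rss_f / (nd - Xf.shape[1]))
            p_cont = float(stats.f.sf(max(F, 0.0), 1, nd - Xf.shape[1]))
        lr[i] += float(stats.chi2.isf(np.clip(p_cont, 1e-300, 1.0), 1))
        df[i] += 1

    p = np.where(df > 0, stats.chi2.sf(lr, np.maximum(df, 1)), np.nan)
    parts = np.select(
        [logistic_ok & continuous_ok, logistic_ok, continuous_ok],
        ["both", "logistic", "continuous"], default="none",
    )
    p[n_det == 0] = np.nan
    log2fc_out = log2fc.copy()
    log2fc_out[n_det == 0] = np.nan

    out = pd.DataFrame({
        "log2fc": log2fc_out,
        "p_value": p,
        "detect_ref": detect_ref,
        "detect_test": detect_test,
        "df": df,
        "parts": parts,
    }, index=matrix.gene_ids)
    out["fdr"] = bh_adjust(out["p_value"])
    return out


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return beta, float(np.sum((y - fitted) ** 2))


# ---------------------------------------------------------------------------
# multiple testing & DEG calling
# ---------------------------------------------------------------------------

def bh_adjust(p: Sequence[float] | pd.Series) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values; NaNs pass through.

    Values outside [0, 1] raise. Idempotent on already-adjusted monotone
    inputs and equivariant under permutation.
    """
    arr = np.asarray(p, dtype=float)
    ok = ~np.isnan(arr)
    vals = arr[ok]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full_like(arr, np.nan)
    if vals.size:
        adj[ok] = stats.false_discovery_control(vals, method="bh")
    if isinstance(p, pd.Series):
        return pd.Series(adj, index=p.index, name="fdr")
    return adj


def call_degs(
    result: pd.DataFrame, fdr_max: float = 0.05, min_abs_log2fc: float = 0.5
) -> tuple[set[str], set[str]]:
    """Up- and down-regulated gene sets under strict FDR and |log2FC| cuts.

    A gene at exactly the FDR or fold-change boundary is *not* called.
    """
    sig = result["fdr"] < fdr_max
    up = set(result.index[sig & (result["log2fc"] > min_abs_log2fc)])
    down = set(result.index[sig & (result["log2fc"] < -min_abs_log2fc)])
    return up, down


def overlap_sets(sets: Mapping[str, Iterable]) -> dict[tuple[str, ...], int]:
    """Counts of every disjoint region of the Venn partition of <= 6 sets.

    Keys are sorted tuples of the set names an element belongs to; only
    elements belonging to at least one set are counted.
    """
    names = sorted(sets)
    if len(names) > 6:
        raise ValueError("at most 6 sets supported")
    as_sets = {n: set(sets[n]) for n in names}
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            members = set.intersection(*(as_sets[n] for n in inside))
            for n in names:
                if n not in inside:
                    members -= as_sets[n]
            regions[inside] = len(members)
    return regions


def hypergeom_enrich(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene set against a collection.

    For each named set: population = |universe|, successes = |set ∩
    universe|, draws = |query|, p = P(X >= observed overlap). BH adjustment
    is across the sets of the collection. The query must be a subset of the
    universe; sets are intersected with the universe first.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        extra = sorted(query - universe)[:3]
        raise ValueError(f"query genes outside universe, e.g. {extra}")
    M, N = len(universe), len(query)
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & universe
        overlap = members & query
        k, n = len(overlap), len(members)
        pval = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append({"set": name, "set_size": n, "overlap": k,
                     "p_value": min(pval, 1.0),
                     "overlap_genes": ",".join(sorted(overlap))})
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = bh_adjust(out["p_value"])
    return out
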