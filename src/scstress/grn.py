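"""Promoter extraction, regulatory-network assembly and the TF–target
permutation test.

The network layer consumes externally produced TF→gene hit tables (motif
scanning and curated interaction databases are upstream inputs, not
reimplemented here) and DEG sets, assembles a TF→DEG edge list, classifies
edges as documented or novel against a curated table, and corroborates each
TF's predicted target set with an empirical co-expression test:

1. S = mean |corr(TF, target)| over the TF's N predicted targets;
2. draw N genes from the expression universe (without the TF itself),
   record the mean |corr|;
3. repeat M times (M >= 10,000) for the null distribution;
4. empirical p = (1 + #{null >= S}) / (M + 1).

The pseudocount in step 4 avoids exact-zero p-values from a finite null
sample. Correlation defaults to Spearman, with Pearson as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from scstress.de import bh_adjust
from scstress.io import ExpressionMatrix, GeneModelSet, TFInteractionTable

__all__ = [
    "PermutationResult",
    "TFNetwork",
    "extract_upstream",
    "build_network",
    "classify_known_novel",
    "permutation_test",
    "permutation_test_all",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def extract_upstream(
    models: GeneModelSet,
    genome: Mapping[str, str],
    max_len: int = 1000,
) -> dict[str, str]:
    """Upstream (promoter) sequence per gene, 5'→3' relative to the gene.

    The region extends at most ``max_len`` bp upstream of the gene start,
    truncated at the nearest annotated gene boundary (any strand) and at the
    reference edge. Minus-strand genes take the mirror window downstream in
    reference coordinates, reverse-complemented. Genes with zero upstream
    space yield an empty string.
    """
    out: dict[str, str] = {}
    for ref, genes in models.genes.groupby("ref"):
        if ref not in genome:
            raise KeyError(f"reference {ref!r} absent from genome")
        seq = genome[ref]
        ref_len = len(seq)
        genes = genes.sort_values("start").reset_index(drop=True)
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        for i, row in genes.iterrows():
            if row.strand == "+":
                # nearest boundary upstream = previous gene's end
                prev_end = ends[i - 1] if i > 0 else 0
                space = row.start - 1 - prev_end
                L = min(max_len, space, row.start - 1)
                out[row.gene_id] = seq[row.start - 1 - L: row.start - 1]
            else:
                next_start = starts[i + 1] if i + 1 < len(genes) else ref_len + 1
                space = next_start - 1 - row.end
                L = min(max_len, space, ref_len - row.end)
                window = seq[row.end: row.end + L]
                out[row.gene_id] = _revcomp(window)
    return out


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

@dataclass
class TFNetwork:
    """TF → DEG edge set with per-edge direction and evidence class."""

    edges: pd.DataFrame  # tf_id, target, direction, evidence
    permutation: pd.DataFrame | None = None

    def summary(self) -> dict[str, int]:
        return {
            "n_tfs": int(self.edges["tf_id"].nunique()),
            "n_targets": int(self.edges["target"].nunique()),
            "n_edges": int(len(self.edges)),
        }

    def targets_of(self, tf_id: str) -> set[str]:
        return set(self.edges.loc[self.edges["tf_id"] == tf_id, "target"])


def build_network(
    tf_hits: TFInteractionTable,
    up_degs: Iterable[str],
    down_degs: Iterable[str],
) -> TFNetwork:
    """One edge per (TF, DEG target) hit, direction from the DEG call.

    Hits whose target is not a DEG are dropped; duplicate hits (e.g. several
    motif occurrences in one promoter) collapse to a single edge.
    """
    up, down = set(up_degs), set(down_degs)
    hits = tf_hits.edges[["tf_id", "target"]].drop_duplicates()
    direction = np.select(
        [hits["target"].isin(up), hits["target"].isin(down)],
        ["up", "down"], default="",
    )
    edges = hits.assign(direction=direction, evidence="predicted")
    edges = edges[edges["direction"] != ""].reset_index(drop=True)
    return TFNetwork(edges)


def classify_known_novel(
    network: TFNetwork,
    known: TFInteractionTable,
    excluded_tfs: Iterable[str] = (),
) -> tuple[dict[str, int], pd.DataFrame]:
    """Split predicted edges into documented vs novel against a curated table.

    Edges involving ``excluded_tfs`` (general, TATA-box-binding factors
    whose hits are uninformative) are removed before counting. Returns the
    {documented, novel} counts and the annotated edge table.
    """
    excluded = set(excluded_tfs)
    edges = network.edges[~network.edges["tf_id"].isin(excluded)].copy()
    known_pairs = set(zip(known.edges["tf_id"], known.edges["target"]))
    documented = [
        (tf, tg) in known_pairs for tf, tg in zip(edges["tf_id"], edges["target"])
    ]
    edges["evidence"] = np.where(documented, "documented", "novel")
    counts = {
        "documented": int(np.sum(documented)),
        "novel": int(len(edges) - np.sum(documented)),
    }
    return counts, edges


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Observed mean |correlation| of a TF with its targets vs a sampled null."""

    tf_id: str
    statistic: float          # S: mean absolute correlation over targets
    n_targets: int
    M: int
    p_value: float
    method: str
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.p_value < 0.05


def _abs_correlations(
    matrix: ExpressionMatrix, tf_id: str, gene_ids: Sequence[str], method: str
) -> np.ndarray:
    """|corr(TF, gene)| for each listed gene, across cells."""
    data = matrix.values
    tf = data.loc[tf_id].to_numpy(dtype=float)
    if np.std(tf) == 0:
        raise ValueError(f"TF {tf_id!r} has constant expression; correlation undefined")
    X = data.loc[list(gene_ids)].to_numpy(dtype=float)
    if method == "spearman":
        tf = stats.rankdata(tf)
        X = np.apply_along_axis(stats.rankdata, 1, X)
    elif method != "pearson":
        raise ValueError(f"method must be spearman or pearson, got {method!r}")
    tf_c = tf - tf.mean()
    X_c = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((X_c**2).sum(axis=1)) * np.sqrt((tf_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X_c @ tf_c) / denom
    return np.abs(np.nan_to_num(r, nan=0.0))


def permutation_test(
    matrix: ExpressionMatrix,
    tf_id: str,
    targets: Iterable[str],
    universe: Iterable[str] | None = None,
    M: int = 10_000,
    method: str = "spearman",
    seed: int = 0,
) -> PermutationResult:
    """Empirical test of TF–target co-expression against random gene sets.

    ``universe`` defaults to all genes in the matrix. Null sets of size
    |targets| are sampled without replacement from universe ∖ {tf}; the
    p-value uses the (1+k)/(M+1) estimator with k = #{null mean >= S}.
    """
    targets = sorted(set(targets))
    if len(targets) < 2:
        raise ValueError("need at least 2 targets")
    if M < 1:
        raise ValueError("M must be >= 1")
    pool = sorted(set(universe) if universe is not None else set(matrix.gene_ids))
    pool = [g for g in pool if g != tf_id]
    missing = [t for t in targets if t not in set(pool)]
    if missing:
        raise ValueError(f"targets outside universe: {missing[:3]}")

    abs_r = _abs_correlations(matrix, tf_id, pool, method)
    idx_of = {g: i for i, g in enumerate(pool)}
    target_idx = np.array([idx_of[t] for t in targets])
    S = float(abs_r[target_idx].mean())

    rng = np.random.default_rng(seed)
    N, P = len(targets), len(pool)
    exceed = 0
    chunk = max(1, min(M, int(2e7 / max(P, 1))))
    done = 0
    while done < M:
        m = min(chunk, M - done)
        if N < P:
            keys = rng.random((m, P))
            picks = np.argpartition(keys, N - 1, axis=1)[:, :N]
        else:
            picks = np.tile(np.arange(P), (m, 1))
        null_means = abs_r[picks].mean(axis=1)
        exceed += int(np.sum(null_means >= S))
        done += m
    p = (1 + exceed) / (M + 1)
    return PermutationResult(tf_id, S, N, M, float(p), method)


def permutation_test_all(
    matrix: ExpressionMatrix,
    tf_targets: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
    M: int = 10_000,
    method: str = "spearman",
    seed: int = 0,
) -> pd.DataFrame:
    """Run the permutation test for every TF; BH-adjust across TFs.

    Each TF gets an independent, reproducible random stream derived from
    ``seed``. TFs whose target set is too small (< 2) are skipped.
    """
    rows = []
    for j, tf in enumerate(sorted(tf_targets)):
        targets = set(tf_targets[tf])
        if len(targets) < 2 or tf not in matrix.gene_ids:
            continue
        res = permutation_test(matrix, tf, targets, universe, M, method,
                               seed=(seed + 9973 * (j + 1)) % (2**31))
        rows.append({"tf_id": tf, "statistic": res.statistic,
                     "n_targets": res.n_targets, "M": M, "p_value": res.p_value})
    out = pd.DataFrame(rows).set_index("tf_id") if rows else pd.DataFrame(
        columns=["statistic", "n_targets", "M", "p_value"])
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"])
    return out
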