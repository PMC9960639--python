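"""Library-quality metrics, spike-in diagnostics, saturation and cell filters.

Five per-cell metrics quantify library quality:

* **complexity** — fraction of subsampled mapped reads with distinct
  (reference, start, strand) positions; low values indicate PCR
  over-amplification. Libraries are compared at a fixed subsample (one
  million reads by default; smaller libraries use all reads, flagged).
* **evenness** — mean coefficient of variation of per-base coverage over the
  top-50% expressed genes; 0 means perfectly uniform coverage.
* **gap score** — TPM-weighted mean count of gaps (runs of >= 5 uncovered
  bases) along gene bodies.
* **sensitivity** — number of genes detected with at least 5 reads.
* **bio-reads ratio** — fraction of all reads uniquely mapped to the
  organism genome (vs spike-in and unmapped).

Batch-specific filter presets reproduce the thresholds used in practice for
a two-batch full-length yeast scRNA-seq experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from scstress.io import GeneModelSet, ReadPlacementTable

__all__ = [
    "FilterRule",
    "BATCH1_FILTER",
    "BATCH2_FILTER",
    "SaturationCurve",
    "DetectionLimit",
    "coverage_by_reference",
    "gene_coverage",
    "assign_reads_to_genes",
    "reads_per_gene",
    "compute_complexity",
    "compute_evenness",
    "compute_gap_score",
    "compute_sensitivity",
    "compute_bio_ratio",
    "spikein_rates",
    "spikein_summary",
    "detection_limit",
    "gene_body_bias_profile",
    "saturation_curve",
    "pooled_saturation",
    "filter_cells",
    "library_qc",
]

DEFAULT_COMPLEXITY_SAMPLE = 1_000_000
_COMPARATORS = {
    ">": np.greater,
    "<": np.less,
    ">=": np.greater_equal,
    "<=": np.less_equal,
}


# ---------------------------------------------------------------------------
# coverage helpers
# ---------------------------------------------------------------------------

def coverage_by_reference(
    placements: ReadPlacementTable,
    ref_lengths: Mapping[str, int],
    read_class: str = "biological",
) -> dict[str, np.ndarray]:
    """Per-base coverage arrays (index i = 1-based position i+1) per reference.

    Reads are clipped at reference boundaries.
    """
    arrays = {ref: np.zeros(int(n) + 1) for ref, n in ref_lengths.items()}
    reads = placements.mapped(read_class)
    for ref, sub in reads.groupby("ref", observed=True):
        if ref not in arrays:
            continue
        diff = arrays[ref]
        n = diff.size - 1
        start = np.clip(sub["start"].to_numpy(dtype=int) - 1, 0, n)
        end = np.clip(start + sub["length"].to_numpy(dtype=int), 0, n)
        np.add.at(diff, start, 1.0)
        np.add.at(diff, end, -1.0)
    return {ref: np.cumsum(diff)[:-1] for ref, diff in arrays.items()}


def gene_coverage(
    coverage: Mapping[str, np.ndarray], models: GeneModelSet
) -> dict[str, np.ndarray]:
    """Per-gene coverage slices in reference orientation (gene body only)."""
    out = {}
    for row in models.genes.itertuples(index=False):
        arr = coverage.get(row.ref)
        if arr is None:
            out[row.gene_id] = np.zeros(row.end - row.start + 1)
        else:
            out[row.gene_id] = arr[row.start - 1:row.end].copy()
    return out


def assign_reads_to_genes(
    placements: ReadPlacementTable, models: GeneModelSet
) -> pd.Series:
    """Gene id per biological read (NaN when the read midpoint hits no gene).

    Assignment is by midpoint containment in the (non-overlapping) gene
    bodies of each reference.
    """
    reads = placements.mapped("biological")
    result = pd.Series(pd.NA, index=reads.index, dtype=object)
    for ref, genes in models.genes.groupby("ref"):
        genes = genes.sort_values("start")
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        ids = genes["gene_id"].to_numpy()
        sub = reads[reads["ref"] == ref]
        if sub.empty:
            continue
        mid = (sub["start"].to_numpy() + sub["length"].to_numpy() // 2).astype(int)
        idx = np.searchsorted(starts, mid, side="right") - 1
        ok = (idx >= 0) & (mid <= ends[np.clip(idx, 0, len(ends) - 1)])
        vals = np.where(ok, ids[np.clip(idx, 0, len(ids) - 1)], None)
        result.loc[sub.index] = vals
    return result


def reads_per_gene(
    placements: ReadPlacementTable, models: GeneModelSet
) -> pd.DataFrame:
    """Genes × cells biological read counts (duplicates included)."""
    reads = placements.mapped("biological").copy()
    reads["gene_id"] = assign_reads_to_genes(placements, models)
    reads = reads.dropna(subset=["gene_id"])
    table = reads.groupby(["gene_id", "cell_id"]).size().unstack(fill_value=0)
    cells = placements.cell_ids
    return table.reindex(index=models.gene_ids, columns=cells, fill_value=0).astype(float)


# ---------------------------------------------------------------------------
# the five metrics
# ---------------------------------------------------------------------------

def compute_complexity(
    placements: ReadPlacementTable,
    sample_size: int = DEFAULT_COMPLEXITY_SAMPLE,
    seed: int = 0,
    read_class: str = "biological",
) -> float:
    """Fraction of subsampled mapped reads with distinct start positions.

    ``sample_size`` reads are drawn uniformly without replacement (all reads
    when fewer exist); distinctness is on (reference, start, strand). NaN for
    a cell with no mapped reads of the requested class.
    """
    reads = placements.mapped(read_class)
    n = len(reads)
    if n == 0:
        return float("nan")
    if n > sample_size:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=sample_size, replace=False)
        reads = reads.iloc[idx]
        n = sample_size
    distinct = len(reads[["ref", "start", "strand"]].drop_duplicates())
    return distinct / n


def _top_half_genes(tpm: pd.Series) -> list[str]:
    """Top ⌈n/2⌉ genes by TPM, ties broken lexicographically by gene id."""
    order = sorted(tpm.index, key=lambda g: (-tpm[g], g))
    return order[: math.ceil(len(order) / 2)]


def compute_evenness(
    coverage: Mapping[str, np.ndarray], tpm: pd.Series
) -> float:
    """Mean per-base-coverage CV over the top-50% expressed genes.

    CV uses the population (divide-by-n) standard deviation; zero-coverage
    bases inside the gene body are included; genes with zero mean coverage
    are excluded. NaN when no kept gene has positive mean coverage.
    """
    kept = _top_half_genes(tpm)
    cvs = []
    for g in kept:
        arr = np.asarray(coverage[g], dtype=float)
        mean = arr.mean()
        if mean <= 0:
            continue
        cvs.append(arr.std() / mean)  # numpy std is population sd
    return float(np.mean(cvs)) if cvs else float("nan")


def count_gaps(arr: np.ndarray, min_gap: int = 5) -> int:
    """Maximal zero-coverage runs of length >= min_gap (gene-end runs count)."""
    z = np.concatenate([[0], (np.asarray(arr) == 0).astype(np.int8), [0]])
    d = np.diff(z)
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    return int(np.sum((run_ends - run_starts) >= min_gap))


def compute_gap_score(
    coverage: Mapping[str, np.ndarray], tpm: pd.Series, min_gap: int = 5
) -> float:
    """TPM-weighted mean gap count over genes with TPM > 0 (NaN if all zero)."""
    total = 0.0
    weight = 0.0
    for g, w in tpm.items():
        if w <= 0:
            continue
        total += count_gaps(coverage[g], min_gap) * w
        weight += w
    return total / weight if weight > 0 else float("nan")


def compute_sensitivity(counts: pd.Series | np.ndarray, min_reads: int = 5) -> int:
    """Number of genes with at least ``min_reads`` reads."""
    arr = np.asarray(counts, dtype=float)
    return int(np.sum(arr >= min_reads))


def compute_bio_ratio(placements: ReadPlacementTable) -> float:
    """Fraction of all reads (incl. spike-in and unmapped) that are biological."""
    total = len(placements.reads)
    if total == 0:
        return float("nan")
    return float((placements.reads["read_class"] == "biological").sum() / total)


# ---------------------------------------------------------------------------
# spike-in diagnostics
# ---------------------------------------------------------------------------

def spikein_rates(placements: ReadPlacementTable) -> pd.Series:
    """Per-cell fraction of reads on spike-in references."""
    counts = placements.reads.groupby("cell_id").size()
    spikes = placements.reads[placements.reads["read_class"] == "spikein"] \
        .groupby("cell_id").size()
    return (spikes.reindex(counts.index, fill_value=0) / counts).rename("spikein_rate")


def spikein_summary(
    spike_expr,
    mix: pd.DataFrame,
    spikein_rate: pd.Series | None = None,
    min_rate: float = 0.02,
    min_detected: int = 8,
) -> pd.DataFrame:
    """Per-cell spike-in rate, log-log Pearson correlation, and eligibility.

    ``pcc`` is the Pearson correlation of log2(observed + 1) vs
    log2(concentration) over spikes with non-zero observation (NaN with < 2
    such spikes). A cell is *eligible* for detection-limit analysis iff its
    spike-in rate exceeds ``min_rate`` and it detects at least
    ``min_detected`` distinct spikes.
    """
    values = spike_expr.values if hasattr(spike_expr, "values") and hasattr(spike_expr, "unit") \
        else pd.DataFrame(spike_expr)
    conc = mix.set_index("spike_id")["concentration"].reindex(values.index)
    if conc.isna().any():
        missing = conc.index[conc.isna()][0]
        raise ValueError(f"spike {missing!r} absent from mix table")
    rows = []
    for cell in values.columns:
        obs = values[cell]
        nonzero = obs > 0
        n_det = int(nonzero.sum())
        if n_det >= 2:
            x = np.log2(conc[nonzero].to_numpy())
            y = np.log2(obs[nonzero].to_numpy() + 1.0)
            xc, yc = x - x.mean(), y - y.mean()
            denom = np.sqrt((xc**2).sum() * (yc**2).sum())
            pcc = float((xc * yc).sum() / denom) if denom > 0 else float("nan")
        else:
            pcc = float("nan")
        rate = float(spikein_rate[cell]) if spikein_rate is not None and cell in spikein_rate \
            else float("nan")
        eligible = bool(rate > min_rate) and n_det >= min_detected if spikein_rate is not None \
            else n_det >= min_detected
        rows.append({"cell_id": cell, "spikein_rate": rate, "spikein_pcc": pcc,
                     "n_detected_spikes": n_det, "eligible": eligible})
    return pd.DataFrame(rows).set_index("cell_id")


@dataclass
class DetectionLimit:
    """Concentration at 50% detection probability, with a status flag.

    status: ``ok`` (logistic fit), ``separated`` (perfect separation; the
    smallest always-detected concentration is reported), ``below_min`` /
    ``above_max`` sentinels (all / no spikes detected), ``failed``.
    """

    concentration: float
    status: str
    midpoint_log10: float | None = None
    slope: float | None = None


def detection_limit(
    detected: pd.DataFrame, mix: pd.DataFrame
) -> DetectionLimit:
    """Fit detection probability vs log10(concentration), return the 50% point.

    ``detected`` is a spikes × cells boolean table (eligible cells only);
    observations are pooled over cells. Concentrations of zero are excluded
    from the fit.
    """
    conc = mix.set_index("spike_id")["concentration"].reindex(detected.index)
    ok = conc > 0
    conc = conc[ok]
    det = detected.loc[ok.index[ok]]
    x = np.log10(conc.to_numpy(dtype=float))
    k = det.sum(axis=1).to_numpy(dtype=float)   # detections per spike
    n = float(det.shape[1])
    if k.sum() == k.size * n:
        return DetectionLimit(float(conc.min()), "below_min")
    if k.sum() == 0:
        return DetectionLimit(float(conc.max()), "above_max")

    # perfect separation: every spike above some concentration always
    # detected, every spike below never → no finite MLE slope
    frac = k / n
    order = np.argsort(x)
    f_sorted = frac[order]
    if set(np.unique(f_sorted)) <= {0.0, 1.0} and np.all(np.diff(f_sorted) >= 0):
        limit = float(conc.to_numpy()[order][f_sorted == 1.0].min())
        return DetectionLimit(limit, "separated")

    def nll(params):
        b0, b1 = params
        p = special.expit(b0 + b1 * x)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    res = optimize.minimize(nll, x0=np.array([0.0, 1.0]), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    b0, b1 = res.x
    if not res.success or b1 <= 0:
        return DetectionLimit(float("nan"), "failed")
    mid = -b0 / b1
    return DetectionLimit(float(10.0 ** mid), "ok", midpoint_log10=float(mid), slope=float(b1))


# ---------------------------------------------------------------------------
# gene-body coverage bias
# ---------------------------------------------------------------------------

def gene_body_bias_profile(
    coverage: Mapping[str, np.ndarray],
    models: GeneModelSet,
    n_bins: int = 100,
) -> np.ndarray:
    """Mean relative coverage along the gene body, 5' → 3', in ``n_bins`` bins.

    Minus-strand genes are reversed before binning so position 0 is always
    the 5' end. Each gene's binned profile is normalized to mean 1 and the
    profiles of genes with positive coverage (and length >= n_bins) are
    averaged; the result has mean 1.
    """
    strand = models.genes.set_index("gene_id")["strand"]
    profiles = []
    for g, arr in coverage.items():
        arr = np.asarray(arr, dtype=float)
        if arr.size < n_bins or arr.sum() <= 0:
            continue
        if strand.get(g, "+") == "-":
            arr = arr[::-1]
        binned = np.array([chunk.mean() for chunk in np.array_split(arr, n_bins)])
        profiles.append(binned / binned.mean())
    if not profiles:
        return np.full(n_bins, np.nan)
    return np.mean(profiles, axis=0)


# ---------------------------------------------------------------------------
# saturation
# ---------------------------------------------------------------------------

@dataclass
class SaturationCurve:
    """Detected-gene counts as a function of subsample size."""

    sizes: list[int]
    detected: list[float]
    n_reps: int
    detect_threshold: int
    truncated: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "detected_genes": self.detected})


def saturation_curve(
    placements: ReadPlacementTable,
    models: GeneModelSet,
    sizes: Sequence[int],
    n_reps: int = 10,
    detect_threshold: int = 1,
    seed: int = 0,
) -> SaturationCurve:
    """Mean detected genes over random read subsamples of each size.

    Subsampling is without replacement from the cell's biological reads;
    sizes above the library size are truncated to it (flagged). A gene is
    detected when at least ``detect_threshold`` subsampled reads map to it.
    """
    gene_of_read = assign_reads_to_genes(placements, models).to_numpy()
    total = gene_of_read.size
    rng = np.random.default_rng(seed)
    truncated = any(s > total for s in sizes)
    sizes = [min(int(s), total) for s in sizes]
    means = []
    for size in sizes:
        if size == 0:
            means.append(0.0)
            continue
        reps = []
        for _ in range(n_reps):
            take = gene_of_read[rng.choice(total, size=size, replace=False)]
            take = take[pd.notna(take)]
            if detect_threshold <= 1:
                reps.append(len(set(take)))
            else:
                counts = pd.Series(take).value_counts()
                reps.append(int((counts >= detect_threshold).sum()))
        means.append(float(np.mean(reps)))
    return SaturationCurve(sizes, means, n_reps, detect_threshold, truncated)


def pooled_saturation(
    placements: ReadPlacementTable,
    models: GeneModelSet,
    k_values: Sequence[int],
    n_reps: int = 10,
    detect_threshold: int = 1,
    seed: int = 0,
) -> SaturationCurve:
    """Mean detected genes when pooling reads of random k-subsets of cells."""
    reads = placements.mapped("biological").copy()
    reads["gene_id"] = assign_reads_to_genes(placements, models)
    cells = placements.cell_ids
    per_cell_counts = {
        c: reads[reads["cell_id"] == c].dropna(subset=["gene_id"])
        .groupby("gene_id").size() for c in cells
    }
    rng = np.random.default_rng(seed)
    means = []
    for k in k_values:
        if k > len(cells):
            raise ValueError(f"k={k} exceeds group size {len(cells)}")
        reps = []
        for _ in range(n_reps):
            chosen = rng.choice(len(cells), size=k, replace=False)
            pooled = pd.Series(dtype=float)
            for ci in chosen:
                pooled = pooled.add(per_cell_counts[cells[ci]], fill_value=0)
            reps.append(int((pooled >= detect_threshold).sum()))
        means.append(float(np.mean(reps)))
    return SaturationCurve(list(k_values), means, n_reps, detect_threshold)


# ---------------------------------------------------------------------------
# cell filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterRule:
    """Named thresholds applied to the cells of one batch."""

    batch: str
    thresholds: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for metric, comparator, _ in self.thresholds:
            if comparator not in _COMPARATORS:
                raise ValueError(f"unknown comparator {comparator!r}")


#: batch-1 preset: detection rate > 500 genes, complexity > 0.1,
#: gap score < 0.5, evenness < 1.5 (all strict)
BATCH1_FILTER = FilterRule("batch1", [
    ("sensitivity", ">", 500),
    ("complexity", ">", 0.1),
    ("gap_score", "<", 0.5),
    ("evenness", "<", 1.5),
])

#: batch-2 preset: more than 10,000 uniquely mapped reads (strict)
BATCH2_FILTER = FilterRule("batch2", [
    ("n_uniquely_mapped", ">", 10_000),
])


def filter_cells(
    qc: pd.DataFrame, rules: Iterable[FilterRule]
) -> pd.DataFrame:
    """Apply batch-specific threshold rules; a cell passes iff all hold.

    ``qc`` must have a ``batch`` column plus the metrics each rule names.
    Missing (NaN) metrics fail the cell with reason ``missing metric``.
    Returns the qc table with added ``pass`` and ``fail_reason`` columns;
    cells of batches with no rule fail with reason ``no rule for batch``.
    """
    by_batch = {r.batch: r for r in rules}
    out = qc.copy()
    passes = []
    reasons = []
    for cell, row in qc.iterrows():
        rule = by_batch.get(row.get("batch"))
        if rule is None:
            passes.append(False)
            reasons.append("no rule for batch")
            continue
        reason = ""
        ok = True
        for metric, comparator, value in rule.thresholds:
            x = row.get(metric)
            if x is None or (isinstance(x, float) and math.isnan(x)):
                ok, reason = False, f"missing metric {metric}"
                break
            if not _COMPARATORS[comparator](x, value):
                ok, reason = False, f"{metric} {comparator} {value} violated ({x:.4g})"
                break
        passes.append(ok)
        reasons.append(reason)
    out["pass"] = passes
    out["fail_reason"] = reasons
    return out


# ---------------------------------------------------------------------------
# per-cell QC driver
# ---------------------------------------------------------------------------

def library_qc(
    placements: ReadPlacementTable,
    models: GeneModelSet,
    spike_mix: pd.DataFrame | None = None,
    spike_ref_length: int = 1000,
    cell_batches: pd.Series | None = None,
    mito_genes: set[str] | None = None,
    rrna_genes: set[str] | None = None,
    complexity_sample: int = DEFAULT_COMPLEXITY_SAMPLE,
    min_reads: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Compute the full per-cell QC table from read placements.

    Per cell: the five quality metrics, uniquely-mapped read count, spike-in
    rate and log-log PCC (when a mix table is given), and optional
    mitochondrial / rRNA TPM percentages over user-supplied gene lists.
    TPM for the evenness and gap weighting is computed from the cell's own
    gene read counts and effective lengths.
    """
    from scstress.expr import compute_tpm
    from scstress.io import ExpressionMatrix

    counts = reads_per_gene(placements, models)
    lengths = models.lengths().reindex(counts.index)
    tpm_all = compute_tpm(
        ExpressionMatrix(counts, "counts", gene_lengths=lengths), lengths
    ).values

    rates = spikein_rates(placements)
    rows = []
    for cell in placements.cell_ids:
        cell_pl = placements.for_cell(cell)
        cov_ref = coverage_by_reference(cell_pl, models.ref_lengths)
        cov = gene_coverage(cov_ref, models)
        tpm = tpm_all[cell] if cell in tpm_all.columns else pd.Series(0.0, index=counts.index)
        n_bio = int((cell_pl.reads["read_class"] == "biological").sum())
        row = {
            "cell_id": cell,
            "complexity": compute_complexity(cell_pl, complexity_sample, seed=seed),
            "evenness": compute_evenness(cov, tpm),
            "gap_score": compute_gap_score(cov, tpm),
            "sensitivity": compute_sensitivity(counts[cell] if cell in counts else [], min_reads),
            "bio_ratio": compute_bio_ratio(cell_pl),
            "n_uniquely_mapped": n_bio,
            "spikein_rate": float(rates.get(cell, np.nan)),
        }
        if spike_mix is not None:
            spikes = cell_pl.mapped("spikein")
            sc = spikes.groupby("ref").size().reindex(spike_mix["spike_id"], fill_value=0)
            # TPM over the spike set alone (all spikes share one length)
            total = sc.sum()
            spike_tpm = sc / total * 1e6 if total > 0 else sc.astype(float)
            summ = spikein_summary(
                pd.DataFrame({cell: spike_tpm}), spike_mix,
                spikein_rate=rates,
            )
            row["spikein_pcc"] = float(summ.loc[cell, "spikein_pcc"])
            row["spikein_eligible"] = bool(summ.loc[cell, "eligible"])
        if mito_genes:
            row["mito_pct"] = float(tpm[tpm.index.isin(mito_genes)].sum() / 1e6)
        if rrna_genes:
            row["rrna_pct"] = float(tpm[tpm.index.isin(rrna_genes)].sum() / 1e6)
        if cell_batches is not None:
            row["batch"] = cell_batches.get(cell)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_id")
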