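"""Synthetic-data generator with known ground truth.

Emulates the data structure of a full-length single-cell RNA-seq study of
yeast stress response: per-cell read placements with 3'-end coverage bias and
PCR duplication, negative-binomial counts with logistic dropout, batch
effects and planted condition-specific fold-changes, spike-in observations
proportional to known concentrations, and TF-driven correlated gene modules.
Every planted structure is recorded in :class:`TrueLabels` so downstream
stages can be tested for parameter recovery without any external data.

All generators are deterministic for a given :class:`SimConfig` seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from scstress.io import ExpressionMatrix, GeneModelSet, ReadPlacementTable, TFInteractionTable

__all__ = [
    "SimConfig",
    "TrueLabels",
    "default_spikein_mix",
    "simulate_gene_models",
    "simulate_read_placements",
    "simulate_counts",
    "simulate_spikeins",
    "simulate_tf_modules",
]


def default_spikein_mix(n_spikes: int = 92, log2_min: float = 0.0, log2_max: float = 20.0) -> list[tuple[str, float]]:
    """Synthetic spike-in mix: concentrations evenly spaced on the log2 scale.

    Mimics the wide dynamic range of an ERCC-style external-RNA mix
    (attomoles/µl); the ladder spans ``log2_max - log2_min`` doublings.
    """
    levels = np.linspace(log2_min, log2_max, n_spikes)
    return [(f"SPIKE_{i:03d}", float(2.0 ** lv)) for i, lv in enumerate(levels)]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    The defaults are the reference conditions the test-suite exercises: a
    down-scaled single-cell experiment (1,000 genes, ~90,000 reads per cell,
    of which ~60% map to the genome)
    whose library-quality metrics land in the same regimes as a real
    full-length yeast scRNA-seq batch — average complexity well below 1,
    a TPM-weighted gap score under 0.5 for healthy cells, and a sensitivity
    (genes with >= 5 reads) a comfortable margin above the 500-gene filter
    threshold, so that half-depth / doubled-duplication degraded cells fall
    clearly below it.
    """

    seed: int = 0
    # gene models
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (400, 1000)
    n_references: int = 1
    ref_length: int | None = None  # fixed reference size; error if genes cannot fit
    # cells
    n_cells_per_group: int = 20
    conditions: tuple[str, ...] = ("isotonic", "stress")
    batches: tuple[str, ...] = ("batch1",)
    # read placement
    mean_depth: int = 90_000
    read_length: int = 250
    duplication_rate: float = 0.15
    bias_strength: float = 0.4
    expr_log_sd: float = 2.0  # natural-log sd of per-gene expression weights
    spikein_read_frac: float = 0.10
    unmapped_read_frac: float = 0.30
    # counts
    dropout_midpoint: float = 1.0  # on ln(mean) scale
    dropout_slope: float = 1.0
    de_fraction: float = 0.0
    planted_log2fc: float = 0.0
    dispersion: float = 0.3  # NB dispersion alpha; var = mu + alpha*mu^2
    batch_effect_sd: float = 0.2  # ln-scale per-(gene,batch) offset sd
    count_depth: int = 100_000  # target library size for the count model
    # TF modules
    n_tfs: int = 0
    module_size: int = 20
    module_correlation: float = 0.8
    # spike-ins
    spikein_mix: list[tuple[str, float]] = field(default_factory=default_spikein_mix)
    capture_noise_sd: float = 0.5  # ln-scale sd of per-observation capture noise

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must be positive and ordered")
        for name in ("n_genes", "n_cells_per_group", "n_references", "read_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("duplication_rate", "de_fraction", "spikein_read_frac",
                     "unmapped_read_frac", "module_correlation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be non-negative")
        if self.de_fraction > 0 and len(self.conditions) < 2:
            raise ValueError("de_fraction > 0 requires at least two conditions")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible generator for a named substream."""
        key = zlib.crc32(stream.encode()) % (2**31)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)

    def cell_table(self) -> pd.DataFrame:
        """Cell metadata: one row per cell with condition and batch labels."""
        rows = []
        for cond in self.conditions:
            for i in range(self.n_cells_per_group):
                batch = self.batches[i % len(self.batches)]
                rows.append({"cell_id": f"{cond}_{i:03d}", "condition": cond, "batch": batch})
        return pd.DataFrame(rows).set_index("cell_id")


@dataclass
class TrueLabels:
    """Ground truth of the planted structures.

    ``de_genes`` maps gene id -> signed planted log2 fold-change;
    ``low_quality_cells`` is the set of degraded cells;
    ``tf_modules`` maps TF id -> member gene-id set.
    """

    de_genes: dict[str, float] = field(default_factory=dict)
    low_quality_cells: set[str] = field(default_factory=set)
    tf_modules: dict[str, set[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gene models & genome
# ---------------------------------------------------------------------------

def simulate_gene_models(config: SimConfig) -> GeneModelSet:
    """Generate non-overlapping gene models on linear references.

    Gene lengths are uniform over ``gene_length_range``; intergenic spacings
    are drawn from a mixture of short (50–900 bp) and long (1,100–3,000 bp)
    gaps so that promoter extraction sees intergenic distances both below and
    above the 1,000 bp cap. Strands are assigned at random; genes are
    distributed round-robin over ``n_references``.
    """
    rng = config.rng("gene_models")
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    short = rng.integers(50, 901, size=config.n_genes)
    long = rng.integers(1100, 3001, size=config.n_genes)
    spacings = np.where(rng.random(config.n_genes) < 0.5, short, long)
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")

    n_refs = config.n_references
    records = []
    cursor = {r: 0 for r in range(n_refs)}
    for i in range(config.n_genes):
        ref_idx = i % n_refs
        start = cursor[ref_idx] + int(spacings[i])
        end = start + int(lengths[i]) - 1
        records.append(
            {"gene_id": f"G{i:05d}", "ref": f"chr{ref_idx + 1}",
             "start": start, "end": end, "strand": strands[i],
             "length": int(lengths[i])}
        )
        cursor[ref_idx] = end
    ref_lengths = {f"chr{r + 1}": cursor[r] + 500 for r in range(n_refs)}
    if config.ref_length is not None:
        if max(cursor.values()) + 500 > config.ref_length:
            raise ValueError(
                f"{config.n_genes} genes do not fit on references of length {config.ref_length}"
            )
        ref_lengths = {f"chr{r + 1}": config.ref_length for r in range(n_refs)}
    genes = pd.DataFrame(records)
    return GeneModelSet(genes, ref_lengths=ref_lengths)


def simulate_genome(models: GeneModelSet, config: SimConfig) -> dict[str, str]:
    """Random nucleotide sequences matching the model reference lengths."""
    rng = config.rng("genome")
    bases = np.array(list("ACGT"))
    return {
        ref: "".join(bases[rng.integers(0, 4, size=length)])
        for ref, length in models.ref_lengths.items()
    }


# ---------------------------------------------------------------------------
# expression weights (shared by placements and counts)
# ---------------------------------------------------------------------------

def _expression_weights(config: SimConfig) -> np.ndarray:
    """Per-gene relative expression, lognormal with ln-sd ``expr_log_sd``.

    Heavily skewed (a few genes dominate the library), as in real
    transcriptomes; normalized to sum 1.
    """
    rng = config.rng("expression_weights")
    x = np.exp(rng.normal(0.0, config.expr_log_sd, size=config.n_genes))
    return x / x.sum()


# ---------------------------------------------------------------------------
# read placements
# ---------------------------------------------------------------------------

def _biased_relative_starts(rng: np.random.Generator, n: int, bias: float) -> np.ndarray:
    """Relative start positions in [0, 1) with density ∝ exp(bias·x).

    x = 0 is the 5' end; bias > 0 skews starts toward the 3' end (x → 1),
    emulating the oligo-dT priming bias of full-length protocols. Sampled by
    inverse-CDF; bias = 0 reduces to the uniform distribution.
    """
    u = rng.random(n)
    if bias == 0.0:
        return u
    return np.log1p(u * np.expm1(bias)) / bias


def simulate_read_placements(
    models: GeneModelSet,
    config: SimConfig,
    low_quality_frac: float = 0.0,
    quality_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[ReadPlacementTable, TrueLabels]:
    """Place reads for every cell with 3' bias, duplication and spike-ins.

    Per cell the read budget is Poisson(``mean_depth``), split into
    biological / spike-in / unmapped classes by the configured fractions.
    Biological reads pick a gene proportional to its expression weight and a
    start within the gene body from the 3'-biased density (reads may run past
    the annotated 3' end, as clipped alignments do). A fraction
    ``duplication_rate`` of biological reads are exact PCR copies of an
    already-placed read. Cells flagged low-quality receive half the depth and
    double the duplication rate and are recorded in the returned
    :class:`TrueLabels`. ``quality_overrides`` maps cell_id ->
    (depth_factor, duplication_factor) for explicit control.
    """
    if len(models) == 0:
        raise ValueError("gene model set is empty")
    rng = config.rng("read_placements")
    cells = config.cell_table()
    weights = _expression_weights(config)
    genes = models.genes

    labels = TrueLabels()
    overrides = dict(quality_overrides or {})
    if low_quality_frac > 0:
        n_low = int(round(low_quality_frac * len(cells)))
        low_ids = rng.choice(cells.index.to_numpy(), size=n_low, replace=False)
        for cid in low_ids:
            overrides.setdefault(cid, (0.5, 2.0))
            labels.low_quality_cells.add(str(cid))

    spike_ids = [sid for sid, conc in config.spikein_mix]
    spike_conc = np.array([conc for _, conc in config.spikein_mix], dtype=float)
    spike_p = spike_conc / spike_conc.sum() if spike_conc.sum() > 0 else None
    spike_len = 1000

    gene_start = genes["start"].to_numpy()
    gene_end = genes["end"].to_numpy()
    gene_len = (gene_end - gene_start + 1).astype(int)
    gene_ref = genes["ref"].to_numpy()
    gene_strand = genes["strand"].to_numpy()

    frames: list[pd.DataFrame] = []
    for cell_id, row in cells.iterrows():
        depth_f, dup_f = overrides.get(cell_id, (1.0, 1.0))
        depth = rng.poisson(config.mean_depth * depth_f)
        if depth == 0:
            continue
        dup_rate = min(1.0, config.duplication_rate * dup_f)
        n_unmapped = rng.binomial(depth, config.unmapped_read_frac)
        n_spike = rng.binomial(depth - n_unmapped,
                               config.spikein_read_frac / max(1e-12, 1 - config.unmapped_read_frac))
        n_bio = depth - n_unmapped - n_spike

        # biological reads: originals then PCR copies of already-placed reads
        n_dup = rng.binomial(n_bio, dup_rate) if n_bio > 0 else 0
        n_orig = n_bio - n_dup
        if n_orig == 0 and n_dup > 0:  # cannot copy from nothing
            n_orig, n_dup = n_dup, 0
        gidx = rng.choice(len(genes), size=n_orig, p=weights)
        rel = _biased_relative_starts(rng, n_orig, config.bias_strength)
        # map relative 5'->3' position to genomic start, strand-aware
        offset = np.floor(rel * gene_len[gidx]).astype(int)
        plus = gene_strand[gidx] == "+"
        starts = np.where(plus, gene_start[gidx] + offset, gene_end[gidx] - offset)
        # minus-strand reads extend toward lower coordinates; store leftmost base
        starts = np.where(plus, starts, np.maximum(1, starts - config.read_length + 1))
        bio = pd.DataFrame({
            "cell_id": cell_id,
            "ref": gene_ref[gidx],
            "start": starts.astype(float),
            "length": float(config.read_length),
            "strand": gene_strand[gidx],
            "read_class": "biological",
        })
        if n_dup > 0:
            copies = bio.iloc[rng.integers(0, len(bio), size=n_dup)]
            bio = pd.concat([bio, copies], ignore_index=True)
        frames.append(bio)

        if n_spike > 0 and spike_p is not None:
            sidx = rng.choice(len(spike_ids), size=n_spike, p=spike_p)
            sstart = rng.integers(1, spike_len - config.read_length + 2, size=n_spike)
            frames.append(pd.DataFrame({
                "cell_id": cell_id,
                "ref": np.array(spike_ids)[sidx],
                "start": sstart.astype(float),
                "length": float(config.read_length),
                "strand": "+",
                "read_class": "spikein",
            }))
        if n_unmapped > 0:
            frames.append(pd.DataFrame({
                "cell_id": [cell_id] * n_unmapped,
                "ref": pd.NA,
                "start": np.nan,
                "length": np.nan,
                "strand": pd.NA,
                "read_class": "unmapped",
            }))

    if frames:
        reads = pd.concat(frames, ignore_index=True)
    else:
        reads = pd.DataFrame(columns=["cell_id", "ref", "start", "length", "strand", "read_class"])
    return ReadPlacementTable(reads), labels


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(config: SimConfig) -> tuple[ExpressionMatrix, TrueLabels]:
    """Negative-binomial counts with dropout, batch effects and planted DE.

    Per-gene base means follow the shared lognormal expression profile scaled
    to ``count_depth`` reads per cell. A fraction ``de_fraction`` of genes is
    shifted by ``planted_log2fc`` (random sign per gene) in every
    non-reference condition; the signed effects are recorded in
    :class:`TrueLabels`. Counts are Gamma–Poisson with dispersion
    ``dispersion`` (var = µ + αµ²), then thinned by logistic dropout with
    detection probability expit(slope · (ln µ − midpoint)). Batch effects are
    per-(gene, batch) lognormal offsets with ln-sd ``batch_effect_sd``.
    """
    rng = config.rng("counts")
    weights = _expression_weights(config)
    cells = config.cell_table()
    n_cells = len(cells)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]

    labels = TrueLabels()
    lfc = np.zeros(config.n_genes)
    if config.de_fraction > 0 and config.planted_log2fc != 0:
        n_de = int(round(config.de_fraction * config.n_genes))
        de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        lfc[de_idx] = signs * config.planted_log2fc
        labels.de_genes = {gene_ids[i]: float(lfc[i]) for i in de_idx}

    batch_names = list(config.batches)
    batch_offset = np.exp(rng.normal(0.0, config.batch_effect_sd,
                                     size=(config.n_genes, len(batch_names))))

    cond = cells["condition"].to_numpy()
    batch_idx = np.array([batch_names.index(b) for b in cells["batch"]])
    stressed = (cond != config.conditions[0]).astype(float)

    mu = config.count_depth * weights[:, None] * (2.0 ** (lfc[:, None] * stressed[None, :]))
    mu = mu * batch_offset[:, batch_idx]

    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)

    if config.dropout_slope > 0:
        with np.errstate(divide="ignore"):
            logit = config.dropout_slope * (np.log(np.maximum(mu, 1e-300)) - config.dropout_midpoint)
        p_detect = 1.0 / (1.0 + np.exp(-logit))
        keep = rng.random(mu.shape) < p_detect
        counts = counts * keep

    values = pd.DataFrame(counts, index=gene_ids, columns=cells.index)
    lengths = pd.Series(
        simulate_gene_models(config).lengths().reindex(gene_ids)
    )
    matrix = ExpressionMatrix(values, "counts", gene_lengths=lengths, cell_meta=cells)
    return matrix, labels


# ---------------------------------------------------------------------------
# spike-ins
# ---------------------------------------------------------------------------

def simulate_spikeins(config: SimConfig, n_cells: int) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Spike-in observations proportional to known concentrations with noise.

    Observed value = capture_scale · concentration · exp(ε), ε ~ N(0,
    capture_noise_sd) per (spike, cell); zero-concentration spikes observe 0.
    Returns the observation matrix (TPM-like unit) and the known mix table.
    """
    if not config.spikein_mix:
        raise ValueError("spikein_mix is empty")
    rng = config.rng("spikeins")
    spike_ids = [sid for sid, _ in config.spikein_mix]
    conc = np.array([c for _, c in config.spikein_mix], dtype=float)
    capture_scale = 10.0
    noise = rng.normal(0.0, config.capture_noise_sd, size=(len(conc), n_cells)) \
        if config.capture_noise_sd > 0 else np.zeros((len(conc), n_cells))
    observed = capture_scale * conc[:, None] * np.exp(noise)
    observed[conc == 0, :] = 0.0
    cells = [f"cell_{i:04d}" for i in range(n_cells)]
    matrix = ExpressionMatrix(pd.DataFrame(observed, index=spike_ids, columns=cells), "TPM")
    mix = pd.DataFrame({"spike_id": spike_ids, "concentration": conc})
    return matrix, mix


# ---------------------------------------------------------------------------
# TF modules
# ---------------------------------------------------------------------------

def simulate_tf_modules(config: SimConfig) -> tuple[ExpressionMatrix, TFInteractionTable, TrueLabels]:
    """Correlated gene modules driven by latent per-cell TF activities.

    Each of ``n_tfs`` modules owns ``module_size`` member genes sharing a
    latent factor f_c ~ N(0,1); member expression is
    sqrt(ρ)·f + sqrt(1−ρ)·ε so the pairwise within-module correlation is ρ =
    ``module_correlation``. The TF's own transcript is simulated as a
    separate gene carrying the same latent factor (at the same ρ), emulating
    transcription-level TF regulation. Remaining genes are independent noise.
    Values are emitted on the log2(TPM+1) scale (mean 5, sd 1).
    """
    if config.n_tfs * config.module_size > config.n_genes:
        raise ValueError("n_tfs * module_size exceeds n_genes")
    rng = config.rng("tf_modules")
    cells = config.cell_table()
    n_cells = len(cells)
    rho = config.module_correlation

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    tf_ids = [f"TF{i:03d}" for i in range(config.n_tfs)]
    z = rng.normal(size=(config.n_genes, n_cells))
    expr = z.copy()
    labels = TrueLabels()
    edge_rows = []
    tf_expr = np.empty((config.n_tfs, n_cells))
    for m in range(config.n_tfs):
        members = gene_ids[m * config.module_size:(m + 1) * config.module_size]
        f = rng.normal(size=n_cells)
        sl = slice(m * config.module_size, (m + 1) * config.module_size)
        expr[sl, :] = np.sqrt(rho) * f + np.sqrt(1 - rho) * z[sl, :]
        tf_expr[m, :] = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(size=n_cells)
        labels.tf_modules[tf_ids[m]] = set(members)
        edge_rows += [{"tf_id": tf_ids[m], "target": g, "evidence": "true"} for g in members]

    all_expr = np.vstack([expr, tf_expr]) if config.n_tfs else expr
    values = np.maximum(0.0, 5.0 + all_expr)
    index = gene_ids + tf_ids
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=index, columns=cells.index), "log2TPM1", cell_meta=cells
    )
    edges = pd.DataFrame(edge_rows, columns=["tf_id", "target", "evidence"])
    return matrix, TFInteractionTable(edges), labels


def config_to_dict(config: SimConfig) -> dict:
    """JSON/YAML-serializable view of a config (for manifests)."""
    d = asdict(config)
    d["gene_length_range"] = list(d["gene_length_range"])
    d["conditions"] = list(d["conditions"])
    d["batches"] = list(d["batches"])
    d["spikein_mix"] = [[s, c] for s, c in d["spikein_mix"]]
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    if "gene_length_range" in d:
        d["gene_length_range"] = tuple(d["gene_length_range"])
    if "conditions" in d:
        d["conditions"] = tuple(d["conditions"])
    if "batches" in d:
        d["batches"] = tuple(d["batches"])
    if "spikein_mix" in d:
        d["spikein_mix"] = [(s, float(c)) for s, c in d["spikein_mix"]]
    return SimConfig(**d)
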