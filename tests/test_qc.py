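"""Library-quality metrics against hand values and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from scstress import qc
from scstress.io import GeneModelSet, ReadPlacementTable
from scstress.synth import SimConfig, simulate_gene_models, simulate_read_placements
from tests.conftest import make_placements


# ---------------------------------------------------------------------------
# brute-force oracles (naive loops, independent of the implementation)
# ---------------------------------------------------------------------------

def brute_complexity(reads: pd.DataFrame, sample_size: int, seed: int) -> float:
    reads = reads[reads["read_class"] == "biological"]
    if len(reads) == 0:
        return float("nan")
    if len(reads) > sample_size:
        idx = np.random.default_rng(seed).choice(len(reads), sample_size, replace=False)
        reads = reads.iloc[idx]
    seen = set()
    for row in reads.itertuples(index=False):
        seen.add((row.ref, row.start, row.strand))
    return len(seen) / len(reads)


def brute_coverage(reads: pd.DataFrame, gene) -> list[int]:
    cov = [0] * (gene.end - gene.start + 1)
    for row in reads.itertuples(index=False):
        if row.read_class != "biological" or row.ref != gene.ref:
            continue
        for pos in range(int(row.start), int(row.start + row.length)):
            if gene.start <= pos <= gene.end:
                cov[pos - gene.start] += 1
    return cov


def brute_evenness(coverage: dict, tpm: pd.Series) -> float:
    order = sorted(tpm.index, key=lambda g: (-tpm[g], g))
    kept = order[: math.ceil(len(order) / 2)]
    cvs = []
    for g in kept:
        arr = coverage[g]
        mean = sum(arr) / len(arr)
        if mean <= 0:
            continue
        var = sum((x - mean) ** 2 for x in arr) / len(arr)
        cvs.append(math.sqrt(var) / mean)
    return sum(cvs) / len(cvs) if cvs else float("nan")


def brute_gaps(arr, min_gap=5) -> int:
    count = run = 0
    for x in list(arr) + [1]:
        if x == 0:
            run += 1
        else:
            if run >= min_gap:
                count += 1
            run = 0
    return count


def brute_gap_score(coverage: dict, tpm: pd.Series) -> float:
    num = den = 0.0
    for g, w in tpm.items():
        if w > 0:
            num += brute_gaps(coverage[g]) * w
            den += w
    return num / den if den else float("nan")


# ---------------------------------------------------------------------------
# hand-value cases
# ---------------------------------------------------------------------------

class TestComplexity:
    def test_all_reads_share_one_start(self):
        rows = [("c", "chr1", 100, 50, "+", "biological")] * 10
        assert qc.compute_complexity(make_placements(rows), 10) == pytest.approx(0.1)

    def test_all_distinct(self):
        rows = [("c", "chr1", 100 + i, 50, "+", "biological") for i in range(10)]
        assert qc.compute_complexity(make_placements(rows), 10) == 1.0

    def test_known_start_multiset(self):
        starts = [100, 100, 100, 200, 200, 300, 300, 300, 300, 400]
        rows = [("c", "chr1", s, 50, "+", "biological") for s in starts]
        assert qc.compute_complexity(make_placements(rows), 10) == pytest.approx(0.4)

    def test_no_reads_undefined(self):
        rows = [("c", "chr1", 1, 50, "+", "spikein")]
        assert math.isnan(qc.compute_complexity(make_placements(rows)))

    def test_strand_distinguishes_starts(self):
        rows = [("c", "chr1", 100, 50, "+", "biological"),
                ("c", "chr1", 100, 50, "-", "biological")]
        assert qc.compute_complexity(make_placements(rows), 10) == 1.0


class TestEvenness:
    def test_uniform_coverage_is_zero(self):
        cov = {"a": np.full(50, 3.0), "b": np.full(20, 7.0)}
        tpm = pd.Series({"a": 10.0, "b": 5.0})
        assert qc.compute_evenness(cov, tpm) == 0.0

    def test_mean_of_two_cvs(self):
        # three genes, top ceil(3/2)=2 kept: CVs 0.5 and 1.5 -> mean 1.0.
        # two-level coverage {0, v} with fraction f non-zero has CV=sqrt((1-f)/f)
        cov = {"a": np.array([0.0, 2.0, 2.0, 2.0, 2.0]),   # f=4/5 -> CV 0.5
               "b": np.array([0.0] * 9 + [13.0] * 4),       # f=4/13 -> CV 1.5
               "c": np.ones(4)}
        tpm = pd.Series({"a": 10.0, "b": 8.0, "c": 1.0})
        assert qc.compute_evenness(cov, tpm) == pytest.approx(1.0)

    def test_population_sd_convention(self):
        # length-4 gene [2,0,2,0]: mean 1, population sd 1 -> CV exactly 1.0
        cov = {"a": np.array([2.0, 0.0, 2.0, 0.0])}
        assert qc.compute_evenness(cov, pd.Series({"a": 1.0})) == pytest.approx(1.0)

    def test_top_half_is_ceiling_with_id_ties(self):
        cov = {"a": np.full(4, 2.0), "b": np.array([2.0, 0.0, 2.0, 0.0]),
               "c": np.full(4, 1.0)}
        tpm = pd.Series({"a": 5.0, "b": 5.0, "c": 1.0})
        # ceil(3/2)=2 kept; tie at 5.0 broken by id -> {a, b}; mean CV = (0+1)/2
        assert qc.compute_evenness(cov, tpm) == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        cov = {f"g{i}": rng.poisson(3, size=30).astype(float) + 1 for i in range(6)}
        tpm = pd.Series({f"g{i}": float(i + 1) for i in range(6)})
        a = qc.compute_evenness(cov, tpm)
        b = qc.compute_evenness({g: 7.3 * c for g, c in cov.items()}, tpm)
        assert a == pytest.approx(b, abs=1e-12)


class TestGapScore:
    def test_fully_covered_gene_no_gaps(self):
        assert qc.count_gaps(np.full(100, 1.0)) == 0

    def test_run_length_threshold(self):
        # zero runs of lengths 3, 5 and 7 -> only two count
        arr = np.ones(50)
        arr[2:5] = 0      # length 3
        arr[10:15] = 0    # length 5
        arr[30:37] = 0    # length 7
        assert qc.count_gaps(arr) == 2

    def test_runs_touching_ends_count(self):
        arr = np.ones(20)
        arr[:6] = 0
        arr[-5:] = 0
        assert qc.count_gaps(arr) == 2

    def test_tpm_weighted_mean(self):
        cov = {"a": np.ones(30), "b": np.ones(30)}
        cov["b"][0:5] = 0; cov["b"][7:12] = 0; cov["b"][14:19] = 0; cov["b"][21:26] = 0
        tpm = pd.Series({"a": 3.0, "b": 1.0})
        # gaps {0, 4}, weights {3, 1} -> (0*3 + 4*1)/4 = 1.0
        assert qc.compute_gap_score(cov, tpm) == pytest.approx(1.0)

    def test_tpm_rescaling_invariance(self):
        cov = {"a": np.ones(30), "b": np.zeros(30)}
        tpm = pd.Series({"a": 2.0, "b": 1.0})
        assert qc.compute_gap_score(cov, tpm) == pytest.approx(
            qc.compute_gap_score(cov, tpm * 1000.0))


class TestSensitivityAndBioRatio:
    @pytest.mark.parametrize("counts,expected", [
        ([5, 4, 6, 0], 2),
        ([0, 0, 0], 0),
        ([5] * 100, 100),
    ])
    def test_sensitivity(self, counts, expected):
        assert qc.compute_sensitivity(pd.Series(counts, dtype=float)) == expected

    def test_bio_ratio_mixture(self):
        rows = ([("c", "chr1", 1, 50, "+", "biological")] * 36
                + [("c", "ERCC-1", 1, 50, "+", "spikein")] * 14
                + [("c", None, np.nan, np.nan, None, "unmapped")] * 50)
        assert qc.compute_bio_ratio(make_placements(rows)) == pytest.approx(0.36)

    @pytest.mark.parametrize("cls,expected", [("biological", 1.0), ("spikein", 0.0)])
    def test_bio_ratio_pure(self, cls, expected):
        rows = [("c", "r", 1, 50, "+", cls)] * 5
        assert qc.compute_bio_ratio(make_placements(rows)) == expected


class TestSpikeinSummary:
    def _mix(self, n=10):
        return pd.DataFrame({"spike_id": [f"s{i}" for i in range(n)],
                             "concentration": [2.0 ** i for i in range(n)]})

    def test_proportional_observations_pcc_one(self):
        mix = self._mix()
        obs = pd.DataFrame({"c1": 5.0 * mix["concentration"].to_numpy()},
                           index=mix["spike_id"])
        out = qc.spikein_summary(obs, mix, spikein_rate=pd.Series({"c1": 0.1}))
        assert out.loc["c1", "spikein_pcc"] > 0.999

    def test_eligibility_needs_at_least_8_detected(self):
        mix = self._mix(10)
        vals = np.zeros(10); vals[:7] = 100.0        # 7 non-zero spikes
        obs = pd.DataFrame({"c1": vals}, index=mix["spike_id"])
        out = qc.spikein_summary(obs, mix, spikein_rate=pd.Series({"c1": 0.5}))
        assert not out.loc["c1", "eligible"]
        vals[7] = 100.0                              # 8th detected
        out = qc.spikein_summary(pd.DataFrame({"c1": vals}, index=mix["spike_id"]),
                                 mix, spikein_rate=pd.Series({"c1": 0.5}))
        assert out.loc["c1", "eligible"]

    def test_eligibility_needs_rate_strictly_above_2pct(self):
        mix = self._mix(10)
        obs = pd.DataFrame({"c1": np.full(10, 9.0)}, index=mix["spike_id"])
        low = qc.spikein_summary(obs, mix, spikein_rate=pd.Series({"c1": 0.019}))
        assert not low.loc["c1", "eligible"]
        hi = qc.spikein_summary(obs, mix, spikein_rate=pd.Series({"c1": 0.021}))
        assert hi.loc["c1", "eligible"]

    def test_fewer_than_two_nonzero_pcc_undefined(self):
        mix = self._mix(5)
        vals = np.zeros(5); vals[0] = 3.0
        obs = pd.DataFrame({"c1": vals}, index=mix["spike_id"])
        out = qc.spikein_summary(obs, mix)
        assert math.isnan(out.loc["c1", "spikein_pcc"])


class TestDetectionLimit:
    def _mix(self, concs):
        return pd.DataFrame({"spike_id": [f"s{i}" for i in range(len(concs))],
                             "concentration": concs})

    def test_step_function_returns_step_concentration(self):
        concs = [1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0]
        det = pd.DataFrame({f"c{j}": [c >= 10 for c in concs] for j in range(5)},
                           index=[f"s{i}" for i in range(8)])
        res = qc.detection_limit(det, self._mix(concs))
        assert res.status == "separated"
        assert res.concentration == 10.0

    def test_all_detected_below_min_sentinel(self):
        concs = [1.0, 4.0, 16.0, 64.0, 256.0, 1024.0, 4096.0, 16384.0]
        det = pd.DataFrame(np.ones((8, 4), dtype=bool),
                           index=[f"s{i}" for i in range(8)])
        res = qc.detection_limit(det, self._mix(concs))
        assert res.status == "below_min" and res.concentration == 1.0

    def test_none_detected_above_max_sentinel(self):
        concs = [1.0, 4.0, 16.0, 64.0, 256.0, 1024.0, 4096.0, 16384.0]
        det = pd.DataFrame(np.zeros((8, 4), dtype=bool),
                           index=[f"s{i}" for i in range(8)])
        res = qc.detection_limit(det, self._mix(concs))
        assert res.status == "above_max" and res.concentration == 16384.0

    def test_logistic_midpoint_recovery(self):
        # detection ~ Bernoulli(expit(2·(log10 c − log10 5))) over 1,000 cells
        rng = np.random.default_rng(0)
        concs = np.logspace(-1, 2, 12)
        p = special.expit(2.0 * (np.log10(concs) - np.log10(5.0)))
        det = pd.DataFrame(rng.random((12, 1000)) < p[:, None],
                           index=[f"s{i}" for i in range(12)])
        res = qc.detection_limit(det, self._mix(list(concs)))
        assert res.status == "ok"
        assert res.concentration == pytest.approx(5.0, rel=0.10)


class TestBiasProfile:
    def test_uniform_coverage_flat_profile(self, toy_models):
        cov = {"gA": np.full(100, 2.0), "gB": np.full(100, 5.0)}
        profile = qc.gene_body_bias_profile(cov, toy_models, n_bins=10)
        assert np.allclose(profile, 1.0)

    def test_minus_strand_reversed(self, toy_models):
        # gB is minus-strand: coverage rising along reference coordinates
        # must yield a 5'->3' *decreasing* profile after the strand flip
        cov = {"gB": np.linspace(1, 10, 100)}
        profile = qc.gene_body_bias_profile(cov, toy_models, n_bins=10)
        assert np.all(np.diff(profile) < 0)

    def test_profile_mean_is_one(self, toy_models):
        rng = np.random.default_rng(1)
        cov = {"gA": rng.poisson(4, 100).astype(float),
               "gB": rng.poisson(2, 100).astype(float)}
        profile = qc.gene_body_bias_profile(cov, toy_models, n_bins=20)
        assert profile.mean() == pytest.approx(1.0, abs=1e-9)

    def test_synthetic_bias_detected(self):
        cfg = SimConfig(seed=21, n_genes=50, n_cells_per_group=2,
                        mean_depth=30_000, bias_strength=2.0,
                        spikein_read_frac=0.0, unmapped_read_frac=0.0)
        models = simulate_gene_models(cfg)
        table, _ = simulate_read_placements(models, cfg)
        cov_ref = qc.coverage_by_reference(table, models.ref_lengths)
        cov = qc.gene_coverage(cov_ref, models)
        profile = qc.gene_body_bias_profile(cov, models)
        rho = stats.spearmanr(np.arange(profile.size), profile).statistic
        assert rho > 0.5   # increasing toward the 3' end


@pytest.fixture(scope="module")
def cell_data():
    cfg = SimConfig(seed=30, n_genes=80, n_cells_per_group=3,
                    mean_depth=3000, spikein_read_frac=0.0,
                    unmapped_read_frac=0.0)
    models = simulate_gene_models(cfg)
    table, _ = simulate_read_placements(models, cfg)
    return table, models


class TestSaturation:
    def test_full_size_equals_library_detection(self, cell_data):
        table, models = cell_data
        cell = table.for_cell(table.cell_ids[0])
        n_reads = len(cell.mapped("biological"))
        curve = qc.saturation_curve(cell, models, [n_reads], n_reps=3, seed=1)
        counts = qc.reads_per_gene(cell, models)
        full_detected = int((counts.iloc[:, 0] >= 1).sum())
        assert curve.detected[0] == full_detected

    def test_size_zero_gives_zero(self, cell_data):
        table, models = cell_data
        cell = table.for_cell(table.cell_ids[0])
        curve = qc.saturation_curve(cell, models, [0, 10], n_reps=2, seed=1)
        assert curve.detected[0] == 0.0

    def test_single_gene_library_saturates_at_one(self, toy_models):
        rows = [("c", "chr1", 110 + i, 20, "+", "biological") for i in range(30)]
        curve = qc.saturation_curve(make_placements(rows), toy_models,
                                    [1, 5, 30], n_reps=4, seed=0)
        assert curve.detected == [1.0, 1.0, 1.0]

    def test_oversized_request_truncated_and_flagged(self, cell_data):
        table, models = cell_data
        cell = table.for_cell(table.cell_ids[0])
        n = len(cell.mapped("biological"))
        curve = qc.saturation_curve(cell, models, [n * 10], n_reps=2, seed=1)
        assert curve.truncated and curve.sizes == [n]

    def test_pooled_full_group_equals_union(self, cell_data):
        table, models = cell_data
        k = len(table.cell_ids)
        curve = qc.pooled_saturation(table, models, [k], n_reps=2, seed=3)
        counts = qc.reads_per_gene(table, models)
        union = int(((counts.sum(axis=1)) >= 1).sum())
        assert curve.detected[0] == union

    def test_pooled_k1_is_mean_single_cell_detection(self, cell_data):
        table, models = cell_data
        counts = qc.reads_per_gene(table, models)
        per_cell = (counts >= 1).sum(axis=0)
        curve = qc.pooled_saturation(table, models, [1], n_reps=500, seed=5)
        assert curve.detected[0] == pytest.approx(per_cell.mean(), rel=0.05)

    def test_monotone_in_subsample_size(self, cell_data):
        table, models = cell_data
        cell = table.for_cell(table.cell_ids[1])
        curve = qc.saturation_curve(cell, models, [50, 200, 800], n_reps=50, seed=2)
        assert curve.detected[0] <= curve.detected[1] <= curve.detected[2]


class TestFilterCells:
    def _qc_row(self, **kw):
        base = {"batch": "batch1", "sensitivity": 600, "complexity": 0.5,
                "gap_score": 0.1, "evenness": 0.8, "n_uniquely_mapped": 50_000}
        base.update(kw)
        return base

    def test_batch1_boundary_pass(self):
        table = pd.DataFrame([self._qc_row(sensitivity=501, complexity=0.11,
                                           gap_score=0.49, evenness=1.49)],
                             index=["c1"])
        out = qc.filter_cells(table, [qc.BATCH1_FILTER])
        assert bool(out.loc["c1", "pass"])

    @pytest.mark.parametrize("field,value", [
        ("sensitivity", 500), ("complexity", 0.1),
        ("gap_score", 0.5), ("evenness", 1.5),
    ])
    def test_batch1_thresholds_are_strict(self, field, value):
        table = pd.DataFrame([self._qc_row(**{field: value})], index=["c1"])
        out = qc.filter_cells(table, [qc.BATCH1_FILTER])
        assert not bool(out.loc["c1", "pass"])

    def test_batch2_exactly_10000_fails(self):
        table = pd.DataFrame([{"batch": "batch2", "n_uniquely_mapped": 10_000}],
                             index=["c1"])
        out = qc.filter_cells(table, [qc.BATCH2_FILTER])
        assert not bool(out.loc["c1", "pass"])
        out2 = qc.filter_cells(
            pd.DataFrame([{"batch": "batch2", "n_uniquely_mapped": 10_001}],
                         index=["c2"]), [qc.BATCH2_FILTER])
        assert bool(out2.loc["c2", "pass"])

    def test_missing_metric_fails_with_reason(self):
        row = self._qc_row(); row["evenness"] = float("nan")
        out = qc.filter_cells(pd.DataFrame([row], index=["c1"]), [qc.BATCH1_FILTER])
        assert not bool(out.loc["c1", "pass"])
        assert "missing metric" in out.loc["c1", "fail_reason"]


class TestOracleEquivalence:
    """Each metric equals a naive brute-force recomputation on random libraries."""

    @pytest.mark.parametrize("seed", range(6))
    def test_metrics_match_brute_force(self, seed):
        cfg = SimConfig(seed=100 + seed, n_genes=12, n_cells_per_group=1,
                        conditions=("only",), gene_length_range=(80, 200),
                        mean_depth=400, read_length=40,
                        duplication_rate=0.3, spikein_read_frac=0.1,
                        unmapped_read_frac=0.2)
        models = simulate_gene_models(cfg)
        table, _ = simulate_read_placements(models, cfg)
        cell = table.for_cell(table.cell_ids[0])
        cov_ref = qc.coverage_by_reference(cell, models.ref_lengths)
        cov = qc.gene_coverage(cov_ref, models)
        counts = qc.reads_per_gene(cell, models).iloc[:, 0]
        tpm = (counts / models.lengths()).pipe(lambda r: r / r.sum() * 1e6)

        brute_cov = {g: brute_coverage(cell.reads, row)
                     for g, row in models.genes.set_index("gene_id").iterrows()}
        for g in models.gene_ids:
            assert np.array_equal(cov[g], np.array(brute_cov[g], dtype=float)), g

        assert qc.compute_complexity(cell, 10**6, seed=7) == pytest.approx(
            brute_complexity(cell.reads, 10**6, seed=7), abs=1e-9)
        assert qc.compute_evenness(cov, tpm) == pytest.approx(
            brute_evenness(brute_cov, tpm), abs=1e-9)
        assert qc.compute_gap_score(cov, tpm) == pytest.approx(
            brute_gap_score(brute_cov, tpm), abs=1e-9)
        assert qc.compute_sensitivity(counts) == sum(1 for c in counts if c >= 5)
        bio = sum(1 for c in cell.reads["read_class"] if c == "biological")
        assert qc.compute_bio_ratio(cell) == pytest.approx(
            bio / len(cell.reads), abs=1e-12)
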