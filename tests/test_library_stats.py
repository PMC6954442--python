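import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dipdesign.errors import DesignError
from dipdesign.library_stats import (
    InsertionCountTable,
    coverage_curve,
    deletion_enrichment,
    deletion_frequency,
    frame_direction_enrichment,
    insertion_context_matrices,
    ks_two_sample,
    normalized_insertions_per_residue,
    replicate_spearman,
)
from dipdesign.synthetic_fixtures import SimulationConfig, simulate_deletion_alignments


class TestNormalization:
    def test_uniform_counts_give_ones(self):
        t = InsertionCountTable("g", np.full(40, 25.0))
        assert np.allclose(normalized_insertions_per_residue(t), 1.0)

    def test_degenerate_mass(self):
        t = InsertionCountTable("g", [0, 0, 90, 0, 0, 0])
        v = normalized_insertions_per_residue(t)
        assert v[2] == 6.0 and v.sum() == 6.0

    def test_mean_is_always_one(self, rng):
        t = InsertionCountTable("g", rng.integers(0, 500, size=123).astype(float) + 1)
        assert normalized_insertions_per_residue(t).mean() == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(DesignError):
            normalized_insertions_per_residue(InsertionCountTable("g", np.zeros(5)))


def _brute_force_ks(a, b):
    """sup over all breakpoints of |ECDF_a - ECDF_b|."""
    pts = sorted(set(a) | set(b))
    best = 0.0
    for x in pts:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        best = max(best, abs(fa - fb))
    return best


class TestKS:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_small_sample_matches_breakpoint_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=5), rng.normal(0.5, 1.2, size=5)
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(_brute_force_ks(list(a), list(b)))

    def test_empty_sample_rejected(self):
        with pytest.raises(DesignError):
            ks_two_sample([], [1.0])


class TestCoverage:
    def test_exact_uniform_table(self):
        t = InsertionCountTable("g", np.full(50, 300.0))
        frac = coverage_curve(t, [1, 100, 300, 301])
        assert list(frac) == [1.0, 1.0, 1.0, 0.0]

    def test_half_zero_positions(self):
        counts = np.concatenate([np.zeros(25), np.full(25, 10.0)])
        t = InsertionCountTable("g", counts)
        frac = coverage_curve(t, [1, 5], seed=0)
        assert (frac <= 0.5).all()

    def test_monotone_non_increasing(self, rng):
        t = InsertionCountTable("g", rng.integers(0, 900, size=80).astype(float))
        frac = coverage_curve(t, np.arange(0, 600, 25), seed=1)
        assert (np.diff(frac) <= 0).all()

    def test_seeded_resample_matches_reference_rng(self, rng):
        counts = rng.integers(1, 50, size=30).astype(float)
        t = InsertionCountTable("g", counts)
        frac = coverage_curve(t, [5, 20], normalize_to=40, seed=99)
        ref = np.random.default_rng(99).multinomial(40 * 30, counts / counts.sum())
        expected = np.array([(ref >= 5).mean(), (ref >= 20).mean()])
        assert np.array_equal(frac, expected)


class TestFrameDirection:
    def _calls(self, weights):
        rows = []
        for (f, d), w in weights.items():
            rows.append({"position": 0, "frame": f, "direction": d, "count": w})
        return pd.DataFrame(rows)

    def test_identical_tables_enrichment_one(self):
        calls = self._calls({(f, d): 10 for f in (0, 1, 2) for d in ("plus", "minus")})
        out = frame_direction_enrichment(calls, calls)
        assert np.allclose(out["enrichment"], 1.0)
        assert out["freq_sorted"].sum() == pytest.approx(1.0)

    def test_planted_two_fold_excess(self):
        control = self._calls({(f, d): 10 for f in (0, 1, 2) for d in ("plus", "minus")})
        weights = {(f, d): 10 for f in (0, 1, 2) for d in ("plus", "minus")}
        weights[(0, "plus")] = 25  # 25/75 vs 10/60 -> exactly 2x
        sorted_calls = self._calls(weights)
        out = frame_direction_enrichment(sorted_calls, control)
        row = out[(out.frame == 0) & (out.direction == "plus")]
        assert row["enrichment"].iloc[0] == pytest.approx(2.0)

    def test_zero_control_class_is_missing_not_infinite(self):
        control = self._calls({(f, d): 10 for f in (0, 1, 2) for d in ("plus", "minus")})
        control.loc[(control.frame == 2) & (control.direction == "minus"), "count"] = 0
        sorted_calls = self._calls({(f, d): 10 for f in (0, 1, 2) for d in ("plus", "minus")})
        out = frame_direction_enrichment(sorted_calls, control)
        val = out[(out.frame == 2) & (out.direction == "minus")]["enrichment"].iloc[0]
        assert np.isnan(val)


class TestDeletions:
    def test_counting_synthetic_sam(self, tmp_path):
        cfg = SimulationConfig(seed=0, deletion_rate=0.1, n_reads=1000)
        path = simulate_deletion_alignments(cfg, tmp_path / "dels.sam")
        freq, n_del, n_reads = deletion_frequency(path)
        assert n_reads == 1000
        assert freq == n_del / 1000
        # binomial CI around the generating rate
        se = np.sqrt(0.1 * 0.9 / 1000)
        assert abs(freq - 0.1) < 4 * se

    def test_enrichment_is_ratio_to_control(self, tmp_path):
        paths = {}
        for name, rate, seed in (("control", 0.10, 1), ("sorted", 0.05, 2)):
            cfg = SimulationConfig(seed=seed, deletion_rate=rate, n_reads=4000)
            paths[name] = simulate_deletion_alignments(cfg, tmp_path / f"{name}.sam")
        df = deletion_enrichment(paths, control="control").set_index("sample")
        assert df.loc["control", "enrichment"] == pytest.approx(1.0)
        expected = df.loc["sorted", "frequency"] / df.loc["control", "frequency"]
        assert df.loc["sorted", "enrichment"] == pytest.approx(expected)
        assert df.loc["sorted", "enrichment"] < 1.0  # depletion

    def test_rate_zero(self, tmp_path):
        cfg = SimulationConfig(seed=3, deletion_rate=0.0, n_reads=200)
        path = simulate_deletion_alignments(cfg, tmp_path / "none.sam")
        freq, *_ = deletion_frequency(path)
        assert freq == 0.0

    def test_parameter_recovery_at_depth(self, tmp_path):
        cfg = SimulationConfig(seed=4, deletion_rate=0.41, n_reads=10_000)
        path = simulate_deletion_alignments(cfg, tmp_path / "heavy.sam")
        freq, *_ = deletion_frequency(path)
        se = np.sqrt(0.41 * 0.59 / 10_000)
        assert abs(freq - 0.41) < 4 * se


class TestContextMatrices:
    def test_planted_motif_peaks_at_center(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        # plant CGG immediately after every chosen junction
        sites = sorted(rng.choice(np.arange(100, 2900), size=120, replace=False))
        seq_l = list(seq)
        for s in sites:
            seq_l[s : s + 3] = "CGG"
        seq = "".join(seq_l)
        fg, bg, diff = insertion_context_matrices(sites, seq, window=5)
        assert diff.at[0, "C"] > 0.5 and diff.at[1, "G"] > 0.5 and diff.at[2, "G"] > 0.5

    def test_uniform_sites_give_flat_difference(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        sites = list(rng.integers(10, 3990, size=2000))
        _, _, diff = insertion_context_matrices(sites, seq, window=5)
        assert np.abs(diff.to_numpy()).max() < 0.08

    def test_single_site_one_hot_columns(self):
        seq = "ACGTACGTAC"
        fg, _, _ = insertion_context_matrices([5], seq, window=2)
        assert (fg.sum(axis=1) == 1).all()
        assert fg.at[0, seq[5]] == 1

    def test_empty_sites_rejected(self):
        with pytest.raises(DesignError):
            insertion_context_matrices([], "ACGT")


class TestReplicateSpearman:
    def test_identical_replicates(self):
        v = np.arange(10, dtype=float)
        assert replicate_spearman([v, v]) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        v = np.arange(10, dtype=float)
        assert replicate_spearman([v, v[::-1]]) == pytest.approx(-1.0)

    def test_matches_textbook_rank_formula(self):
        a = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        b = np.array([2.0, 0.5, 6.0, 1.0, 4.0, 7.0])
        # no ties after ranking -> 1 - 6*sum(d^2)/(n(n^2-1))
        ra, rb = sps.rankdata(a), sps.rankdata(b)
        d2 = ((ra - rb) ** 2).sum()
        expected = 1 - 6 * d2 / (6 * 35)
        assert replicate_spearman([a, b]) == pytest.approx(expected)

    def test_nan_positions_zero_filled(self):
        a = np.array([1.0, 2.0, np.nan, 4.0])
        b = np.array([1.0, 2.0, 3.0, 4.0])
        rho = replicate_spearman([a, b], na_as_zero=True)
        ref, _ = sps.spearmanr(np.nan_to_num(a), b)
        assert rho == pytest.approx(ref)

    def test_constant_vector_reported_missing(self):
        assert np.isnan(replicate_spearman([np.ones(5), np.arange(5.0)]))
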