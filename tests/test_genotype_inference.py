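import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methylaudit.errors import BetaDomainError, UnknownIDError
from methylaudit.genotype_inference import (
    BIN_X,
    BIN_Y,
    BIN_Z,
    MISSING,
    UNBINNED,
    BinProfile,
    BinThresholds,
    CandidacyParams,
    assign_bin,
    bin_profile,
    call_genotypes,
    min_binned_count,
    passes_candidacy,
    select_informative_probes,
    top_k,
)
from methylaudit.io_methylation import BetaMatrix
from methylaudit.popgen_stats import hwe_test


class TestAssignBin:
    @pytest.mark.parametrize(
        "beta,expected",
        [
            (0.85, BIN_X),
            (0.50, BIN_Y),
            (0.10, BIN_Z),
            (0.28, UNBINNED),  # the 0.25-0.3 gap
            (0.7, UNBINNED),   # boundaries are strict
            (0.3, UNBINNED),
            (0.25, UNBINNED),
            (1.0, BIN_X),
            (0.0, BIN_Z),
        ],
    )
    def test_bin_assignment(self, beta, expected):
        assert assign_bin(beta) == expected

    def test_missing_passes_through(self):
        assert assign_bin(float("nan")) == MISSING
        assert assign_bin(None) == MISSING

    def test_out_of_range_rejected(self):
        with pytest.raises(BetaDomainError):
            assign_bin(1.3)

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_partition_totality(self, beta):
        # exactly one label for every beta in [0, 1]
        label = assign_bin(beta)
        assert label in (BIN_X, BIN_Y, BIN_Z, UNBINNED)
        memberships = [
            beta > 0.7,
            0.3 < beta < 0.7,
            beta < 0.25,
        ]
        assert sum(memberships) == (0 if label == UNBINNED else 1)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            BinThresholds(x_min=0.2, y_low=0.3, y_high=0.7, z_max=0.25)


class TestBinProfile:
    def test_mixed_row(self):
        profile = bin_profile([0.9, 0.5, 0.1, float("nan")])
        assert profile == BinProfile(1, 1, 1, 0, 1)

    def test_all_high(self):
        profile = bin_profile([0.99] * 10)
        assert profile == BinProfile(10, 0, 0, 0, 0)

    def test_counting_oracle_constructed_row(self):
        row = [0.9] * 60 + [0.5] * 40 + [0.1] * 11
        profile = bin_profile(row)
        assert (profile.n_x, profile.n_y, profile.n_z) == (60, 40, 11)
        assert profile.n_unbinned == 0 and profile.n_missing == 0

    @given(
        st.lists(
            st.one_of(
                st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                st.just(float("nan")),
            ),
            min_size=1,
            max_size=50,
        )
    )
    def test_counts_sum_to_n_samples(self, row):
        profile = bin_profile(row)
        assert profile.n_samples == len(row)


class TestCandidacy:
    def test_threshold_is_106_of_111(self):
        assert min_binned_count(111, 0.95) == 106

    def test_paper_passing_profile(self):
        ok, reason = passes_candidacy(BinProfile(60, 40, 11, 0, 0), 111)
        assert ok and reason == ""

    def test_fails_homozygote_z(self):
        ok, reason = passes_candidacy(BinProfile(100, 5, 3, 3, 0), 111)
        assert not ok
        assert "homozygote-Z" in reason

    def test_fails_binned_fraction(self):
        ok, reason = passes_candidacy(BinProfile(105, 0, 0, 6, 0), 111)
        assert not ok
        assert "binned-fraction" in reason

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CandidacyParams(min_binned_fraction=0.0)
        with pytest.raises(ValueError):
            CandidacyParams(hwe_p_min=1.0)


class TestCallGenotypes:
    def test_bin_to_genotype_mapping(self):
        matrix = BetaMatrix(
            pd.DataFrame(
                [[0.95, 0.5, 0.02, 0.27]],
                index=["cg_a"],
                columns=["s1", "s2", "s3", "s4"],
            )
        )
        calls = call_genotypes(matrix, ["cg_a"])
        row = calls.data.loc["cg_a"]
        assert list(row[["s1", "s2", "s3"]]) == ["CC", "CD", "DD"]
        assert pd.isna(row["s4"])  # unbinned -> missing

    def test_empty_probe_subset(self, small_beta_matrix):
        calls = call_genotypes(small_beta_matrix, [])
        assert calls.data.shape == (0, 2)

    def test_unknown_probe_raises(self, small_beta_matrix):
        with pytest.raises(UnknownIDError, match="cg_nope"):
            call_genotypes(small_beta_matrix, ["cg_nope"])


def brute_force_select(matrix: BetaMatrix, params: CandidacyParams):
    """Literal, scalar reimplementation of the discovery pipeline."""
    selected = []
    for probe_id in matrix.probe_ids:
        labels = [assign_bin(v) for v in matrix.data.loc[probe_id]]
        n_x = labels.count(BIN_X)
        n_y = labels.count(BIN_Y)
        n_z = labels.count(BIN_Z)
        if n_x + n_y + n_z < math.ceil(
            params.min_binned_fraction * matrix.n_samples
        ):
            continue
        if n_x < params.min_homozygote_count or n_z < params.min_homozygote_count:
            continue
        from methylaudit.popgen_stats import GenotypeCounts, observed_heterozygosity

        counts = GenotypeCounts(n_x, n_y, n_z)
        _, p = hwe_test(counts)
        if p > params.hwe_p_min:
            selected.append((probe_id, observed_heterozygosity(counts)))
    selected.sort(key=lambda t: (-t[1], t[0]))
    return [probe_id for probe_id, _ in selected]


class TestSelectInformativeProbes:
    def test_constant_matrix_gives_empty_list(self):
        matrix = BetaMatrix(
            pd.DataFrame(
                np.full((20, 10), 0.8),
                index=[f"cg{i}" for i in range(20)],
                columns=[f"s{j}" for j in range(10)],
            )
        )
        assert select_informative_probes(matrix) == []

    def test_planted_probes_recovered_background_rejected(self):
        from methylaudit.synthetic_data import SimulationConfig, simulate_dataset

        config = SimulationConfig(
            n_samples=111,
            n_snp_probes=50,
            n_background_probes=500,
            maf_range=(0.2, 0.5),
            beta_sd=0.03,
            missing_rate=0.0,
            seed=11,
        )
        matrix, truth = simulate_dataset(config)
        selected = {s.probe_id for s in select_informative_probes(matrix)}
        classes = truth.probes.set_index("probe_id")["probe_class"]
        background = set(classes[classes == "background"].index)
        assert not selected & background

    def test_brute_force_equivalence_on_small_matrices(self):
        rng = np.random.default_rng(5)
        params = CandidacyParams()
        for trial in range(30):
            n_probes = int(rng.integers(1, 21))
            n_samples = int(rng.integers(2, 21))
            # mixture of tri-modal and uniform rows so some probes pass
            values = np.where(
                rng.random((n_probes, n_samples)) < 0.5,
                rng.choice([0.97, 0.5, 0.03], size=(n_probes, n_samples)),
                rng.random((n_probes, n_samples)),
            )
            matrix = BetaMatrix(
                pd.DataFrame(
                    values,
                    index=[f"cg{i:03d}" for i in range(n_probes)],
                    columns=[f"s{j}" for j in range(n_samples)],
                )
            )
            fast = [s.probe_id for s in select_informative_probes(matrix, params)]
            assert fast == brute_force_select(matrix, params)

    def test_high_sensitivity_where_power_allows(self):
        # at MAF >= 0.25 the expected minor-homozygote count (111*q^2 >= 6.9)
        # clears the >= 4 rule with high probability, so recovery is near-total
        from methylaudit.synthetic_data import SimulationConfig, simulate_dataset

        n_true = n_found = 0
        for seed in range(5):
            matrix, truth = simulate_dataset(
                SimulationConfig(
                    n_samples=111, n_snp_probes=200, n_background_probes=0,
                    maf_range=(0.25, 0.5), seed=200 + seed,
                )
            )
            selected = {s.probe_id for s in select_informative_probes(matrix)}
            snp = truth.probes[truth.probes.probe_class == "snp"]
            n_true += len(snp)
            n_found += sum(p in selected for p in snp.probe_id)
        assert n_found / n_true >= 0.95

    def test_monotonicity_in_filter_strictness(self):
        from methylaudit.synthetic_data import SimulationConfig, simulate_dataset

        matrix, _ = simulate_dataset(
            SimulationConfig(
                n_samples=60, n_snp_probes=40, n_background_probes=100,
                maf_range=(0.1, 0.5), seed=13,
            )
        )
        base = {s.probe_id for s in select_informative_probes(matrix)}
        stricter_hwe = {
            s.probe_id
            for s in select_informative_probes(
                matrix, CandidacyParams(hwe_p_min=0.2)
            )
        }
        stricter_hom = {
            s.probe_id
            for s in select_informative_probes(
                matrix, CandidacyParams(min_homozygote_count=10)
            )
        }
        assert stricter_hwe <= base
        assert stricter_hom <= base

    def test_ordering_by_observed_heterozygosity(self):
        from methylaudit.synthetic_data import SimulationConfig, simulate_dataset

        matrix, _ = simulate_dataset(
            SimulationConfig(
                n_samples=111, n_snp_probes=30, n_background_probes=0,
                maf_range=(0.1, 0.5), seed=17,
            )
        )
        summaries = select_informative_probes(matrix)
        hets = [s.het_obs for s in summaries]
        assert hets == sorted(hets, reverse=True)


class TestTopK:
    def test_k_larger_than_list(self):
        assert top_k([], 5) == []

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            top_k([], 0)

    def test_tie_breaks_lexicographically(self):
        from methylaudit.popgen_stats import GenotypeCounts, summarize_counts

        a = summarize_counts("cg_b", GenotypeCounts(30, 50, 31))
        b = summarize_counts("cg_a", GenotypeCounts(30, 50, 31))
        ranked = sorted([a, b], key=lambda s: (-s.het_obs, s.probe_id))
        assert [s.probe_id for s in top_k(ranked, 2)] == ["cg_a", "cg_b"]
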