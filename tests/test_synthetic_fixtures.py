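"""Synthetic genome/coverage/intensity generators and their planted truth."""

import numpy as np
import pytest

from oracles import naive_occurrences
from talerep import (
    ArrayPlan,
    CoverageSpec,
    GenomeSpec,
    annotate_windows,
    compare,
    count_matches,
    example_genome_specs,
    make_genome,
    simulate_coverage,
    simulate_intensities,
    window_genome,
    write_fasta,
)
from talerep.synthetic_fixtures import TELOMERE_UNIT


def one_telomere_spec(seed=0):
    return GenomeSpec(
        chromosome_lengths={"chr1": 10_000},
        plans=(ArrayPlan("TEL", TELOMERE_UNIT, tandem=True, n_arrays=1,
                         units_per_array=50, placement="terminal"),),
        seed=seed,
        query_patterns={"tel8": "AGGGTTAG"},
    )


class TestMakeGenome:
    def test_terminal_telomere_array_length_position_and_planted_count(self):
        genome, ann, truth = make_genome(one_telomere_spec())
        (iv,) = ann.intervals("TEL")
        assert iv.length == 300
        assert iv.end == 10_000  # flush at the chromosome end
        array_seq = genome["chr1"][iv.start : iv.end]
        assert array_seq == TELOMERE_UNIT * 50
        # one 8-mer per 6 bp period; the final unit is too short to host one
        assert len(naive_occurrences(array_seq, "AGGGTTAG")) == 49
        assert truth["tel8"]["forward"] >= 49

    def test_zero_array_spec_is_all_background(self):
        spec = GenomeSpec(chromosome_lengths={"chr1": 5_000}, plans=(), seed=1)
        genome, ann, truth = make_genome(spec)
        assert ann.classes == {}
        assert truth == {}
        assert genome.lengths == {"chr1": 5_000}

    def test_determinism_identical_fasta_bytes(self, tmp_path):
        spec = one_telomere_spec(seed=42)
        for i in (1, 2):
            genome, _, _ = make_genome(spec)
            write_fasta(genome, tmp_path / f"g{i}.fa")
        assert (tmp_path / "g1.fa").read_bytes() == (tmp_path / "g2.fa").read_bytes()

    def test_oversized_array_is_error(self):
        spec = GenomeSpec(
            chromosome_lengths={"chr1": 1_000},
            plans=(ArrayPlan("TEL", TELOMERE_UNIT, tandem=True, n_arrays=1,
                             units_per_array=500, placement="terminal"),),
            seed=0,
        )
        with pytest.raises(ValueError, match="exceeds"):
            make_genome(spec)

    def test_truth_matches_census_end_to_end(self):
        spec = one_telomere_spec(seed=7)
        genome, _, truth = make_genome(spec)
        matches = count_matches(genome, list(spec.query_patterns.items()))
        fwd = sum(m.strand == "+" for m in matches)
        rev = sum(m.strand == "-" for m in matches)
        assert truth["tel8"] == {"forward": fwd, "reverse": rev, "total": fwd + rev}

    def test_substitution_rate_degrades_exact_truth_predictably(self):
        base = one_telomere_spec(seed=3)
        noisy = GenomeSpec(
            chromosome_lengths=base.chromosome_lengths,
            plans=(ArrayPlan("TEL", TELOMERE_UNIT, tandem=True, n_arrays=1,
                             units_per_array=50, placement="terminal",
                             substitution_rate=0.1),),
            seed=3,
            query_patterns=base.query_patterns,
        )
        _, _, clean_truth = make_genome(base)
        _, _, noisy_truth = make_genome(noisy)
        assert noisy_truth["tel8"]["forward"] < clean_truth["tel8"]["forward"]

    def test_shipped_specs_cover_placements_and_junction_target(self):
        specs = example_genome_specs(seed=0)
        placements = {
            p.placement for spec in specs.values() for p in spec.plans
        }
        assert placements == {"terminal", "internal", "dispersed"}
        # a query spanning tandem-unit junctions is planted and found
        genome, ann, truth = make_genome(specs["telomere_small"])
        assert truth["TelR_full"]["forward"] > 0
        assert len("AGGGTTAGGGTTAGG") > len(TELOMERE_UNIT)  # spans >1 unit
        ann.validate_against(genome)


@pytest.fixture(scope="module")
def big_array_genome():
    # one 60 kb satellite array -> >1000 class windows at width 50
    spec = GenomeSpec(
        chromosome_lengths={"chr1": 200_000},
        plans=(ArrayPlan("SAT", "ACGTT" * 10, tandem=True, n_arrays=1,
                         units_per_array=1200, placement="internal"),),
        seed=5,
    )
    genome, ann, _ = make_genome(spec)
    grid = window_genome(genome, width=50)
    classes = annotate_windows(grid, ann)
    in_class = np.array([c == frozenset({"SAT"}) for c in classes])
    assert in_class.sum() >= 1000
    return genome, ann, grid, in_class


class TestSimulateCoverage:

    def test_planted_fold_shifts_ip_mean_by_fold(self, big_array_genome):
        genome, ann, grid, in_class = big_array_genome
        cov = CoverageSpec(depth=100, fold={"SAT": 4.0}, seed=21)
        ip = simulate_coverage(genome, ann, cov, "ip", grid=grid)
        assert ip.values[in_class].mean() == pytest.approx(400, rel=0.05)
        assert ip.values[~in_class].mean() == pytest.approx(100, rel=0.05)

    def test_input_and_notag_ignore_fold_map(self, big_array_genome):
        genome, ann, grid, in_class = big_array_genome
        cov = CoverageSpec(depth=100, fold={"SAT": 4.0}, seed=21)
        for condition in ("input", "notag"):
            track = simulate_coverage(genome, ann, cov, condition, grid=grid)
            assert track.values[in_class].mean() == pytest.approx(100, rel=0.05)

    def test_empty_fold_map_makes_ip_exchangeable_with_input(self, big_array_genome):
        genome, ann, grid, in_class = big_array_genome
        cov = CoverageSpec(depth=100, seed=8)
        ip = simulate_coverage(genome, ann, cov, "ip", grid=grid)
        inp = simulate_coverage(genome, ann, cov, "input", grid=grid)
        assert ip.values[in_class].mean() == pytest.approx(
            inp.values[in_class].mean(), rel=0.05
        )

    def test_negative_binomial_noise_is_overdispersed(self, big_array_genome):
        genome, ann, grid, _ = big_array_genome
        nb = CoverageSpec(depth=100, noise="negative_binomial", dispersion=5, seed=3)
        po = CoverageSpec(depth=100, noise="poisson", seed=3)
        v_nb = simulate_coverage(genome, ann, nb, "input", grid=grid).values.var()
        v_po = simulate_coverage(genome, ann, po, "input", grid=grid).values.var()
        assert v_nb > 2 * v_po

    def test_determinism_per_condition_stream(self, big_array_genome):
        genome, ann, grid, _ = big_array_genome
        cov = CoverageSpec(depth=50, seed=13)
        a = simulate_coverage(genome, ann, cov, "ip", grid=grid)
        b = simulate_coverage(genome, ann, cov, "ip", grid=grid)
        c = simulate_coverage(genome, ann, cov, "input", grid=grid)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


class TestSimulateIntensities:
    def test_null_matrix_gives_uniformish_p_values(self):
        from scipy import stats as ss

        m = simulate_intensities(500, seed=1)
        res = compare(m, equal_var=True)
        assert ss.kstest(res["p_value"], "uniform").statistic < 0.1

    def test_planted_protein_ranks_first_in_most_seeds(self):
        wins = 0
        for seed in range(30):
            m = simulate_intensities(40, effects={"P0012": 8.0}, seed=seed)
            res = compare(m)
            wins += res["p_value"].idxmin() == "P0012"
        assert wins >= 28

    def test_heavy_missingness_excludes_proteins_and_reports_count(self):
        m = simulate_intensities(100, missing_rate=0.6, seed=2)
        res = compare(m)
        assert res.attrs["n_excluded"] > 0
        assert (~res["tested"]).sum() == res.attrs["n_excluded"]

    def test_missingness_is_intensity_dependent(self):
        m = simulate_intensities(2000, missing_rate=0.1, seed=6)
        log2 = np.log2(m.data.to_numpy())
        flat = m.data.to_numpy().flatten()
        missing = np.isnan(flat)
        assert missing.any()
        # missing cells come preferentially from the low-intensity tail:
        # their underlying draw is unobservable, so compare observed rates
        # between matrix halves split by each protein's base abundance
        order = np.argsort(np.nanmean(log2, axis=1))
        low_half = m.data.iloc[order[:1000]].isna().to_numpy().mean()
        high_half = m.data.iloc[order[1000:]].isna().to_numpy().mean()
        assert low_half > high_half

    def test_invalid_rates_and_effects(self):
        with pytest.raises(ValueError):
            simulate_intensities(10, missing_rate=1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_intensities(10, effects={"P0001": -2.0}, seed=0)
        with pytest.raises(ValueError):
            simulate_intensities(10, effects={"P9999": 2.0}, seed=0)
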