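import dataclasses

import numpy as np
import pytest

from viromass.apportion import copies_interval
from viromass.constants import NucleicAcidType
from viromass.profiler import assign_reads, build_profile, parse_blast_tab
from viromass.synthetic import (
    FamilyTruth,
    GroundTruth,
    SimulationConfig,
    library_read_weights,
    simulate_community,
    simulate_direct_counts,
    simulate_dna_masses,
    simulate_hit_table,
    simulate_read_profiles,
)
from viromass.taxonomy import GenomeSizeRange

SS = NucleicAcidType.SSDNA
DS = NucleicAcidType.DSDNA


def single_family_truth(abundance=1e9, kb=1.8, na=SS):
    return GroundTruth((FamilyTruth("fam", na, kb, abundance),))


class TestSimulateCommunity:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=5)
        assert simulate_community(cfg) == simulate_community(cfg)
        other = simulate_community(SimulationConfig(seed=6))
        assert other != simulate_community(cfg)

    def test_pure_dsdna_community(self):
        truth = simulate_community(SimulationConfig(seed=1, n_ss_families=0))
        assert truth.total(SS) == 0.0
        assert all(f.na_type is DS for f in truth.families)

    def test_total_abundance_magnitude_across_seeds(self):
        """Default lognormal parameters keep community totals in the
        10^6-10^10 copies/cm^3 window typical of surface sediment."""
        totals = [
            simulate_community(SimulationConfig(seed=s)).total() for s in range(100)
        ]
        assert min(totals) >= 1e6 and max(totals) <= 1e10

    def test_genome_sizes_within_envelope(self):
        cfg = SimulationConfig(seed=2)
        for f in simulate_community(cfg).families:
            if f.na_type is SS:
                assert 1.8 <= f.genome_kb <= 24.9
            else:
                assert f.genome_kb == 50.0

    def test_truth_taxonomy_resolves_families(self):
        truth = simulate_community(SimulationConfig(seed=3))
        tree = truth.taxonomy()
        assert set(f.name for f in truth.families) <= set(tree.families())

    def test_truth_json_round_trip(self):
        truth = simulate_community(SimulationConfig(seed=4))
        assert GroundTruth.from_json(truth.to_json()) == truth


class TestSimulateDnaMasses:
    def test_closed_form_single_family(self):
        # V=1e9 particles of a 1.8 kb ssDNA genome weigh 0.99 ng total
        cfg = SimulationConfig(seed=0, mass_noise_cv=0.0, s1_carryover_f=0.0)
        ss, ds = simulate_dna_masses(single_family_truth(), cfg)
        assert ss.concentration == pytest.approx(0.99, rel=1e-3)
        assert ds.concentration == 0.0

    def test_full_carryover_moves_all_mass_to_ds_channel(self):
        cfg = SimulationConfig(seed=0, mass_noise_cv=0.0, s1_carryover_f=1.0)
        truth = single_family_truth()
        ss, ds = simulate_dna_masses(truth, cfg)
        assert ds.concentration == pytest.approx(truth.true_mass_ng(SS))

    def test_noise_free_round_trip_recovers_truth_exactly(self):
        cfg = SimulationConfig(seed=9, n_ss_families=1, n_ds_families=0,
                               mass_noise_cv=0.0, s1_carryover_f=0.0)
        truth = simulate_community(cfg)
        fam = truth.families[0]
        ss, _ = simulate_dna_masses(truth, cfg)
        iv = copies_interval(ss, GenomeSizeRange.point(fam.genome_kb))
        assert iv.low == pytest.approx(fam.abundance, rel=1e-12)
        assert iv.is_point

    def test_noise_reproducible_per_seed(self):
        cfg = SimulationConfig(seed=13)
        truth = simulate_community(cfg)
        assert simulate_dna_masses(truth, cfg) == simulate_dna_masses(truth, cfg)

    def test_default_masses_in_study_regime(self):
        """Medians across seeds sit in the measured windows: ssDNA of order
        1.5-3 ng/cm^3, dsDNA an order of magnitude lower."""
        ss_masses, ds_masses = [], []
        for seed in range(50):
            cfg = SimulationConfig(seed=seed)
            truth = simulate_community(cfg)
            ss, ds = simulate_dna_masses(truth, cfg)
            ss_masses.append(ss.concentration)
            ds_masses.append(ds.concentration)
        assert 0.5 <= float(np.median(ss_masses)) <= 10
        assert 0.05 <= float(np.median(ds_masses)) <= 1.5


class TestSimulateReadProfiles:
    def test_single_family_takes_all_reads(self):
        cfg = SimulationConfig(seed=0, mda_ss_bias=1.0)
        profiles = simulate_read_profiles(single_family_truth(), cfg)
        assert profiles["ssDNA"].counts == {"fam": cfg.read_depth}

    def test_equal_weight_families_split_within_4_sd(self):
        truth = GroundTruth(
            (
                FamilyTruth("a", SS, 5.0, 1e8),
                FamilyTruth("b", SS, 5.0, 1e8),
            )
        )
        cfg = SimulationConfig(seed=11, read_depth=10**6)
        counts = simulate_read_profiles(truth, cfg)["ssDNA"].counts
        n = cfg.read_depth
        sd = (n * 0.25) ** 0.5
        assert abs(counts["a"] - n / 2) <= 4 * sd

    def test_mda_bias_strictly_increases_ss_share(self):
        truth = GroundTruth(
            (
                FamilyTruth("s", SS, 5.0, 1e8),
                FamilyTruth("d", DS, 50.0, 1e8),
            )
        )
        shares = []
        for bias in (1.0, 5.0, 20.0):
            cfg = SimulationConfig(seed=0, mda_ss_bias=bias)
            w = library_read_weights(truth, cfg, SS)
            shares.append(w["s"] / (w["s"] + w["d"]))
        assert shares[0] < shares[1] < shares[2]

    def test_ds_library_uses_carryover_for_ss_families(self):
        truth = GroundTruth(
            (
                FamilyTruth("s", SS, 5.0, 1e8),
                FamilyTruth("d", DS, 50.0, 1e8),
            )
        )
        cfg = SimulationConfig(seed=0, s1_carryover_f=0.0)
        profiles = simulate_read_profiles(truth, cfg)
        assert profiles["dsDNA"].counts == {"d": cfg.read_depth}


class TestSimulateDirectCounts:
    def test_only_dsdna_detected_at_zero_ss_efficiency(self):
        truth = GroundTruth(
            (
                FamilyTruth("s", SS, 5.0, 1e9),
                FamilyTruth("d", DS, 50.0, 4e6),
            )
        )
        cfg = SimulationConfig(seed=19, stain_efficiency_ss=0.0,
                               stain_efficiency_ds=1.0)
        counts = simulate_direct_counts(truth, cfg)
        assert counts.viral_particles == pytest.approx(4e6, rel=0.01)

    def test_perfect_staining_counts_whole_community(self):
        truth = single_family_truth(abundance=2e6)
        cfg = SimulationConfig(seed=23, stain_efficiency_ss=1.0,
                               stain_efficiency_ds=1.0)
        counts = simulate_direct_counts(truth, cfg)
        assert counts.viral_particles == pytest.approx(2e6, rel=0.01)

    def test_fold_regime_matches_observed_tens_to_hundreds(self):
        """With default stain efficiencies the ssDNA-truth/direct-count fold
        sits in the tens-to-hundreds regime reported for sediment: median
        within [40, 200] across 100 seeds, every replicate within [5, 1000]."""
        folds = []
        for seed in range(100):
            cfg = SimulationConfig(seed=seed)
            truth = simulate_community(cfg)
            counts = simulate_direct_counts(truth, cfg)
            folds.append(truth.total(SS) / counts.viral_particles)
        assert 40 <= float(np.median(folds)) <= 200
        assert min(folds) >= 5 and max(folds) <= 1000


class TestSimulateHitTable:
    def test_identity_recovery_without_decoys_or_no_hits(self):
        cfg = SimulationConfig(seed=29, read_depth=200, no_hit_fraction=0.0,
                               max_decoy_hits=0)
        truth = simulate_community(cfg)
        tree = truth.taxonomy()
        profile = simulate_read_profiles(truth, cfg)["ssDNA"]
        text, labels = simulate_hit_table(profile, tree, cfg)
        parsed = parse_blast_tab(text.splitlines(True))
        assert not parsed.malformed
        assignments = assign_reads(parsed.hits, tree)
        assert len(assignments) == cfg.read_depth
        for a in assignments:
            assert a.assigned_taxon == labels[a.query_id]

    def test_all_no_hit_gives_fully_unassigned_profile(self):
        cfg = SimulationConfig(seed=31, read_depth=50, no_hit_fraction=1.0)
        truth = simulate_community(cfg)
        tree = truth.taxonomy()
        profile = simulate_read_profiles(truth, cfg)["ssDNA"]
        text, labels = simulate_hit_table(profile, tree, cfg)
        assert text == ""
        assert all(v is None for v in labels.values())

    def test_end_to_end_profile_recovery_within_one_percent(self):
        """With default decoys, recovered family-level composition is within
        1 percentage point (absolute) of the generating composition."""
        cfg = SimulationConfig(seed=7, read_depth=10000, no_hit_fraction=0.2)
        truth = simulate_community(cfg)
        tree = truth.taxonomy()
        generating = simulate_read_profiles(truth, cfg)["ssDNA"]
        text, _ = simulate_hit_table(generating, tree, cfg)
        parsed = parse_blast_tab(text.splitlines(True))
        assignments = assign_reads(parsed.hits, tree)
        recovered = build_profile(assignments, tree, scheme="family",
                                  library_id="rec")
        for family in generating.counts:
            gen_pct = 100.0 * generating.counts[family] / generating.viral_reads
            assert abs(recovered.percent(family) - gen_pct) < 1.0


class TestRandomnessContract:
    def test_ops_reproducible_and_independent(self):
        cfg = SimulationConfig(seed=37)
        truth = simulate_community(cfg)
        masses_a = simulate_dna_masses(truth, cfg)
        # running an unrelated op in between must not perturb the stream
        simulate_direct_counts(truth, cfg)
        simulate_read_profiles(truth, cfg)
        masses_b = simulate_dna_masses(truth, cfg)
        assert masses_a == masses_b

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(mda_ss_bias=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(s1_carryover_f=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(read_depth=0)
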