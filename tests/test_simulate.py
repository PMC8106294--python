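"""Synthetic pool generator: channels, realized counts and truth scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import dp_edit_distance
from aptascreen.clustering import ClusterParams
from aptascreen.counting import count_unique, filter_min_count, compute_rpm
from aptascreen.io import B02_LAYOUT, parse_reads, trim_pool
from aptascreen.screen import EnrichmentRecord
from aptascreen.simulate import (
    FamilySpec,
    PoolSpec,
    default_pool_spec,
    evaluate_recovery,
    generate_pools,
    mutate,
    pool_spec_from_yaml,
    pool_spec_to_yaml,
    random_library_sequence,
)


def rng(seed=0):
    return np.random.default_rng(seed)


class TestRandomLibrarySequence:
    def test_length_and_alphabet(self):
        seq = random_library_sequence(rng(), B02_LAYOUT)
        assert len(seq) == 40 and set(seq) <= set("ACGT")

    def test_reproducible_across_fresh_generators(self):
        assert random_library_sequence(rng(7), B02_LAYOUT) == \
            random_library_sequence(rng(7), B02_LAYOUT)

    def test_base_frequencies_near_uniform(self):
        g = rng(1)
        draws = [random_library_sequence(g, B02_LAYOUT) for _ in range(10_000)]
        joined = "".join(draws)
        for base in "ACGT":
            assert abs(joined.count(base) / len(joined) - 0.25) < 0.01


class TestMutate:
    SEED = "ACGT" * 10

    def test_rate_zero_identity(self):
        assert mutate(self.SEED, 0.0, rng()) == self.SEED

    def test_rate_one_changes_every_base(self):
        out = mutate(self.SEED, 1.0, rng())
        assert len(out) == 40
        assert all(a != b for a, b in zip(self.SEED, out))

    def test_low_rate_cloud_matches_binomial_oracle(self):
        # substitutions per copy ~ Binomial(40, 0.02): mean 0.8 and
        # P(X > 6) ~ 2e-6, so >99% of variants sit within radius 6.
        g = rng(3)
        dists = [dp_edit_distance(self.SEED, mutate(self.SEED, 0.02, g))
                 for _ in range(10_000)]
        assert abs(np.mean(dists) - 0.8) < 0.05
        assert np.mean(np.array(dists) <= 6) > 0.99

    def test_rate_out_of_range(self):
        with pytest.raises(ValueError):
            mutate(self.SEED, 1.5, rng())


def two_family_spec(seed=17, n=50_000):
    g = rng(seed)
    s1 = random_library_sequence(g, B02_LAYOUT)
    s2 = random_library_sequence(g, B02_LAYOUT)
    fams = (
        FamilySpec("f1", s1, target_fraction=0.10, nontarget_fraction=0.01),
        FamilySpec("f2", s2, target_fraction=0.05, nontarget_fraction=0.04),
    )
    return PoolSpec(layout=B02_LAYOUT, n_reads_target=n, n_reads_nontarget=n,
                    families=fams, rng_seed=seed)


class TestGeneratePools:
    def test_realized_counts_within_binomial_bounds(self, tmp_path):
        spec = two_family_spec(seed=17)
        _, _, manifest = generate_pools(spec, tmp_path)
        for fam, row in zip(spec.families, manifest.itertuples(index=False)):
            for pool, frac, n in (("target", fam.target_fraction, 50_000),
                                  ("nontarget", fam.nontarget_fraction, 50_000)):
                realized = getattr(row, f"count_{pool}")
                sd = math.sqrt(n * frac * (1 - frac))
                assert abs(realized - n * frac) <= 3 * sd

    def test_read_files_complete_and_trimmable(self, tmp_path):
        spec = two_family_spec(n=5_000)
        tpath, npath, _ = generate_pools(spec, tmp_path)
        for path in (tpath, npath):
            seqs, stats = trim_pool(parse_reads(path), B02_LAYOUT)
            assert stats.n_input == 5_000
            assert stats.n_extracted == 5_000  # every read carries both anchors

    def test_enrichment_truth_near_fraction_ratio(self, tmp_path):
        spec = two_family_spec(seed=5)
        _, _, manifest = generate_pools(spec, tmp_path)
        row = manifest.set_index("family_id").loc["f1"]
        assert row["realized_enrichment"] == pytest.approx(0.1, abs=0.05)

    def test_byte_identical_on_same_spec(self, tmp_path):
        spec = two_family_spec(n=2_000)
        t1, n1, m1 = generate_pools(spec, tmp_path / "a")
        t2, n2, m2 = generate_pools(spec, tmp_path / "b")
        assert t1.read_bytes() == t2.read_bytes()
        assert n1.read_bytes() == n2.read_bytes()
        pd.testing.assert_frame_equal(m1, m2)

    def test_overfull_fractions_rejected_before_output(self, tmp_path):
        g = rng(0)
        fams = tuple(
            FamilySpec(f"f{i}", random_library_sequence(g, B02_LAYOUT),
                       target_fraction=0.6, nontarget_fraction=0.1)
            for i in range(2)
        )
        with pytest.raises(ValueError, match="sum"):
            PoolSpec(families=fams, rng_seed=0)

    def test_background_only_pool_has_no_recurring_species(self, tmp_path):
        # 4^40 space at 2e4 reads: collisions essentially impossible, so the
        # minimum-read filter empties the pool and the screen finds nothing.
        spec = PoolSpec(n_reads_target=20_000, n_reads_nontarget=1_000,
                        families=(), rng_seed=11)
        tpath, _, manifest = generate_pools(spec, tmp_path)
        assert manifest.empty
        seqs, _ = trim_pool(parse_reads(tpath), B02_LAYOUT)
        pool = filter_min_count(compute_rpm(count_unique(seqs, "t")), 8)
        assert len(pool) == 0

    def test_fasta_output_parses(self, tmp_path):
        spec = two_family_spec(n=500)
        tpath, _, _ = generate_pools(spec, tmp_path, format="fasta")
        assert tpath.suffix == ".fa"
        assert sum(1 for _ in parse_reads(tpath)) == 500

    def test_indel_channel_changes_lengths(self, tmp_path):
        g = rng(0)
        fam = FamilySpec("f", random_library_sequence(g, B02_LAYOUT),
                         target_fraction=0.9, nontarget_fraction=0.9,
                         substitution_rate=0.0, indel_rate=0.2)
        spec = PoolSpec(n_reads_target=300, n_reads_nontarget=300,
                        families=(fam,), rng_seed=2)
        tpath, _, _ = generate_pools(spec, tmp_path)
        _, stats = trim_pool(parse_reads(tpath), B02_LAYOUT)
        assert stats.n_rejected_length > 0  # indels shift insert lengths


class TestEvaluateRecovery:
    def truth(self):
        return pd.DataFrame({
            "family_id": ["f1", "f2", "f3"],
            "seed_sequence": ["A" * 40, "C" * 40, "G" * 40],
            "expected_candidate": [True, True, False],  # f3: below RPM floor
        })

    def cand(self, seq):
        return EnrichmentRecord(seq, 1000.0, 0.0, 0.0)

    def test_perfect_recovery(self):
        res = evaluate_recovery([self.cand("A" * 40), self.cand("C" * 40)],
                                self.truth())
        assert (res.precision, res.recall) == (1.0, 1.0)

    def test_one_spurious_among_two_true(self):
        cands = [self.cand("A" * 40), self.cand("C" * 40), self.cand("T" * 40)]
        res = evaluate_recovery(cands, self.truth())
        assert res.precision == pytest.approx(2 / 3)
        assert res.recall == 1.0

    def test_mutant_candidate_still_matches_family(self):
        near = "A" * 37 + "CCC"  # distance 3 from f1's seed
        res = evaluate_recovery([self.cand(near), self.cand("C" * 40)],
                                self.truth())
        assert (res.precision, res.recall) == (1.0, 1.0)
        assert res.assignments.loc[0, "distance_to_seed"] == 3

    def test_unexpected_family_excluded_from_recall_denominator(self):
        res = evaluate_recovery([self.cand("A" * 40), self.cand("C" * 40)],
                                self.truth())
        assert res.recall == 1.0  # f3 not demanded

    def test_candidate_matching_nonexpected_family_hurts_precision(self):
        res = evaluate_recovery([self.cand("G" * 40)], self.truth())
        assert res.precision == 0.0
        assert res.recall == 0.0

    def test_no_candidates(self):
        res = evaluate_recovery([], self.truth())
        assert res.precision == 1.0 and res.recall == 0.0

    def test_zero_radius_params(self):
        res = evaluate_recovery([self.cand("A" * 39 + "C")], self.truth(),
                                ClusterParams(0))
        assert res.precision == 0.0


class TestPoolSpecYaml:
    def test_round_trip(self, tmp_path):
        spec = two_family_spec(n=1_000)
        path = tmp_path / "spec.yaml"
        pool_spec_to_yaml(spec, path)
        assert pool_spec_from_yaml(path) == spec

    def test_missing_seed_rejected(self, tmp_path):
        path = tmp_path / "spec.yaml"
        path.write_text("layout:\n  five_prime_const: AA\n  three_prime_const: TT\n"
                        "  random_length: 4\n  length_tolerance: 0\n"
                        "n_reads_target: 10\nn_reads_nontarget: 10\n")
        with pytest.raises(ValueError, match="rng_seed"):
            pool_spec_from_yaml(path)


class TestDefaultStudy:
    def test_default_spec_shape(self):
        spec = default_pool_spec(1)
        assert spec.n_reads_target == spec.n_reads_nontarget == 50_000
        assert len(spec.families) == 7
        assert sum(f.expected_candidate for f in spec.families) == 4
        # planted seeds are mutually well-separated: clouds cannot merge
        seeds = [f.seed_sequence for f in spec.families]
        for i, a in enumerate(seeds):
            for b in seeds[i + 1:]:
                assert dp_edit_distance(a, b) >= 16
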