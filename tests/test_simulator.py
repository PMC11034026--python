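"""Markov genome sources, fragmentation, error injection, fold design."""

import numpy as np
import pytest
from scipy import stats

from virokind.io import write_fasta
from virokind.sgt import SequenceRecord, tokenize_trinucleotides
from virokind.simulate import (GROUP_BOUNDS, MarkovSource, build_dataset,
                               fragment_genomes, inject_errors,
                               perturbed_source_pair, sample_genome)


def order0_source(p=(1.0, 0.0, 0.0, 0.0), label="x"):
    return MarkovSource(label=label, transition_probs=np.array([p]), order=0)


class TestMarkovSource:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MarkovSource("x", np.full((16, 4), 0.3), order=2)

    def test_negative_probability_rejected(self):
        t = np.array([[1.2, -0.2, 0.0, 0.0]])
        with pytest.raises(ValueError, match="non-negative"):
            MarkovSource("x", t, order=0)

    def test_degenerate_source_emits_constant_sequence(self):
        rec = sample_genome(order0_source(), 10, np.random.default_rng(0))
        assert rec.bases == "AAAAAAAAAA"

    def test_sampling_deterministic_given_seed(self):
        src, _ = perturbed_source_pair(seed=3)
        a = sample_genome(src, 500, np.random.default_rng(11))
        b = sample_genome(src, 500, np.random.default_rng(11))
        assert a.bases == b.bases

    def test_length_below_order_plus_one_rejected(self):
        src, _ = perturbed_source_pair(seed=0)
        with pytest.raises(ValueError, match="order"):
            sample_genome(src, 2, np.random.default_rng(0))

    def test_empirical_trinucleotides_match_stationary(self):
        """Observed 3-mer frequencies within 3 standard errors of the
        chain's stationary distribution (order-2 source)."""
        src, _ = perturbed_source_pair(seed=9)
        expected = src.stationary_kmer_probs()
        rng = np.random.default_rng(1)
        counts = np.zeros(64)
        total = 0
        for _ in range(60):
            rec = sample_genome(src, 3000, rng)
            t = tokenize_trinucleotides(rec)
            counts += np.bincount(t.codes, minlength=64)
            total += len(t)
        observed = counts / total
        se = np.sqrt(expected * (1 - expected) / total)
        # overlapping 3-mers are positively correlated; allow 4x the iid SE
        assert (np.abs(observed - expected) <= 4 * se + 1e-4).all()


class TestFragmentation:
    @pytest.fixture
    def genomes(self, rng):
        src, _ = perturbed_source_pair(seed=2)
        return [(SequenceRecord(f"g{i}", sample_genome(src, 4000, rng).bases), src.label)
                for i in range(3)]

    @pytest.mark.parametrize("group", list(GROUP_BOUNDS))
    def test_lengths_within_group_bounds(self, genomes, group, rng):
        frags = fragment_genomes(genomes, group, 20, rng)
        lo, hi = GROUP_BOUNDS[group]
        lengths = [len(f.record) for f in frags]
        assert len(frags) == 60
        assert all(lo <= n <= hi for n in lengths)

    def test_zero_fragments_requested(self, genomes, rng):
        assert len(fragment_genomes(genomes, "A", 0, rng)) == 0

    def test_short_genome_skipped_with_warning(self, rng, caplog):
        import logging
        stub = [(SequenceRecord("short", "ACGT" * 100), "x")]  # 400 < 1800
        with caplog.at_level(logging.WARNING):
            frags = fragment_genomes(stub, "D", 5, rng)
        assert len(frags) == 0
        assert any("short" in r.message for r in caplog.records)

    def test_group_d_lengths_uniform_chisquare(self, rng):
        """10,000 group-D lengths: uniformity not rejected at alpha=0.01."""
        src, _ = perturbed_source_pair(seed=4)
        genome = (SequenceRecord("g", sample_genome(src, 3000, rng).bases), src.label)
        frags = fragment_genomes([genome], "D", 10_000, rng)
        lengths = np.array([len(f.record) for f in frags])
        lo, hi = GROUP_BOUNDS["D"]
        counts, _ = np.histogram(lengths, bins=20, range=(lo, hi + 1))
        _, p = stats.chisquare(counts)
        assert p > 0.01


class TestErrorInjection:
    SEQ = SequenceRecord("s", "ACGT" * 2500)

    def test_zero_rates_identity(self, rng):
        out = inject_errors(self.SEQ, 0.0, 0.0, rng)
        assert out.bases == self.SEQ.bases
        assert out.id.startswith("s|err:")

    def test_rates_out_of_range(self, rng):
        with pytest.raises(ValueError, match="sub_rate"):
            inject_errors(self.SEQ, 1.0, 0.0, rng)
        with pytest.raises(ValueError, match="indel_rate"):
            inject_errors(self.SEQ, 0.0, -0.1, rng)

    def test_substitution_count_in_binomial_interval(self, rng):
        n, p = 10_000, 0.15
        out = inject_errors(self.SEQ, p, 0.0, rng)
        mismatches = sum(a != b for a, b in zip(self.SEQ.bases, out.bases))
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= mismatches <= hi

    def test_indel_length_change_within_interval(self, rng):
        n, p = 10_000, 0.10
        out = inject_errors(self.SEQ, 0.0, p, rng)
        delta = len(out.bases) - n
        # insertions - deletions: difference of two Binomial(n, p/2)
        sd = np.sqrt(2 * n * (p / 2) * (1 - p / 2))
        assert abs(delta) <= 2.58 * sd

    def test_substitutions_change_to_different_base(self, rng):
        seq = SequenceRecord("s", "A" * 1000)
        out = inject_errors(seq, 0.5, 0.0, rng)
        changed = [b for b in out.bases if b != "A"]
        assert changed and all(b in "CGT" for b in changed)


class TestBuildDataset:
    def test_fold_design_and_balance(self):
        sources = list(perturbed_source_pair(seed=6))
        ds, manifest = build_dataset(sources, n_genomes=10, genome_length=2000,
                                     groups=["A"], n_fragments=3, k_folds=5, seed=6)
        ds.validate()  # no genome spans folds, lengths in bounds
        assert len(ds) == 2 * 10 * 3
        folds = ds.folds
        labels = np.array(ds.labels)
        for fold in range(5):
            for label in manifest["labels"]:
                gids = {f.source_genome_id for f in ds
                        if f.fold == fold and f.label == label}
                assert len(gids) == 2  # 10 genomes / 5 folds per class
        assert manifest["k_folds"] == 5

    def test_too_many_folds_rejected(self):
        sources = list(perturbed_source_pair(seed=6))
        with pytest.raises(ValueError, match="k_folds"):
            build_dataset(sources, n_genomes=3, genome_length=2000,
                          groups=["A"], n_fragments=1, k_folds=5, seed=0)

    def test_duplicate_labels_rejected(self):
        src, _ = perturbed_source_pair(seed=6)
        with pytest.raises(ValueError, match="distinct"):
            build_dataset([src, src], n_genomes=5, genome_length=2000,
                          groups=["A"], n_fragments=1, k_folds=2, seed=0)

    def test_identical_seed_identical_fasta_bytes(self, tmp_path):
        sources = list(perturbed_source_pair(seed=8))
        files = []
        for name in ("one.fasta", "two.fasta"):
            ds, _ = build_dataset(sources, n_genomes=4, genome_length=1500,
                                  groups=["A"], n_fragments=2, k_folds=2, seed=8)
            path = tmp_path / name
            write_fasta(ds.records, path)
            files.append(path.read_bytes())
        assert files[0] == files[1]
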