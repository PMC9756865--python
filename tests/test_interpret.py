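"""Saliency, learned-feature statistics, embeddings, attention inspection."""

import numpy as np
import pandas as pd
import pytest

from predpair.encoding import encode_question, make_samples
from predpair.interpret import (
    attention_inspection,
    canonical_doublet,
    cluster_embeddings,
    doublet_name,
    embed,
    load_stacking_energies,
    pair_type_frequencies,
    saliency,
    saliency_matrix,
    stack_energy_correlation,
    stacked_pair_frequencies,
)
from predpair.nn import ModelConfig, PredPairNetwork
from predpair.structures import SecondaryStructure


@pytest.fixture(scope="module")
def zero_output_net():
    """A 'trained' network whose logits are constant regardless of input."""
    net = PredPairNetwork(ModelConfig(seed=0))
    net.out_dense.params["W"][:] = 0.0
    net.out_dense.params["b"][:] = 0.0
    net.is_trained = True
    return net


class TestSaliency:
    def test_length_and_requires_trained(self, tiny_trained, hairpin):
        q = encode_question(hairpin, 0)
        row = saliency(tiny_trained.network, q, target=13)
        assert row.shape == (len(hairpin),)
        untrained = PredPairNetwork(ModelConfig(seed=0))
        with pytest.raises(ValueError, match="trained"):
            saliency(untrained, q)

    def test_constant_output_model_has_zero_gradients(self, zero_output_net, hairpin):
        q = encode_question(hairpin, 2)
        row = saliency(zero_output_net, q, target=11)
        np.testing.assert_allclose(row, 0.0, atol=1e-12)
        M = saliency_matrix(zero_output_net, hairpin)
        np.testing.assert_allclose(M, 0.0, atol=1e-12)

    def test_matrix_symmetric(self, tiny_trained, tiny_test_set):
        s = tiny_test_set[0]
        M = saliency_matrix(tiny_trained.network, s)
        assert M.shape == (len(s), len(s))
        np.testing.assert_allclose(M, M.T)
        assert np.isfinite(M).all()

    def test_paired_positions_more_salient_than_random(self, tiny_trained, tiny_test_set):
        """On a trained model, saliency concentrates on true pairs."""
        rng = np.random.default_rng(0)
        pair_vals, rand_vals = [], []
        for s in tiny_test_set[:12]:
            M = saliency_matrix(tiny_trained.network, s)
            paired = s.paired_positions
            unpaired = [k for k in range(len(s)) if k not in paired]
            for i, j in s.pairs:
                pair_vals.append(M[i, j])
                a, b = rng.choice(unpaired, size=2, replace=False)
                rand_vals.append(M[a, b])
        assert np.mean(pair_vals) > np.mean(rand_vals)


class TestPairStatistics:
    def test_single_gc_pair(self):
        freqs = pair_type_frequencies(["GC"], [{(0, 1)}])
        assert freqs == {"CG": 1.0}

    def test_frequencies_sum_to_one(self):
        freqs = pair_type_frequencies(
            ["GCAU", "GGCC"], [{(0, 1), (2, 3)}, {(1, 2)}]
        )
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pair_type_frequencies(["GC"], [set()])

    def test_helix_of_three_gives_two_doublets(self, hairpin):
        counts = stacked_pair_frequencies(
            [hairpin.sequence], [{(0, 13), (1, 12), (2, 11)}]
        )
        assert sum(counts.values()) == 2

    def test_isolated_pairs_give_zero_doublets(self):
        counts = stacked_pair_frequencies(["GCGCGC"], [{(0, 5), (2, 3)}])
        assert sum(counts.values()) == 0

    def test_doublet_counts_match_naive_oracle(self):
        rng = np.random.default_rng(4)
        from predpair.synthetic import gen_stretch_sequences

        structures = gen_stretch_sequences(20, 40, 6, seed=3)
        seqs = [s.sequence for s in structures]
        pair_sets = [s.pairs for s in structures]
        counts = stacked_pair_frequencies(seqs, pair_sets)
        naive = {}
        for s, pairs in zip(seqs, pair_sets):
            for i, j in pairs:
                if (i + 1, j - 1) in pairs:
                    cls = canonical_doublet((s[i], s[j]), (s[i + 1], s[j - 1]))
                    naive[cls] = naive.get(cls, 0) + 1
        assert counts == naive

    def test_doublet_canonicalization_strand_symmetry(self):
        # GC over AU read from the other strand is UA over CG
        a = canonical_doublet(("G", "C"), ("A", "U"))
        b = canonical_doublet(("U", "A"), ("C", "G"))
        assert a == b


class TestStackingEnergies:
    def test_table_covers_all_canonical_doublets(self):
        table = load_stacking_energies()
        assert len(table) == 21
        from predpair.synthetic import PAIR_TYPES

        for p1 in PAIR_TYPES:
            for p2 in PAIR_TYPES:
                assert canonical_doublet(p1, p2) in table

    def test_inverse_ranked_frequencies_give_rho_minus_one(self):
        table = load_stacking_energies()
        classes = sorted(table, key=table.get)[:6]
        # most stable class most frequent
        counts = {cls: 100 - 10 * k for k, cls in enumerate(classes)}
        rho, p = stack_energy_correlation(counts, table)
        assert rho == pytest.approx(-1.0)
        assert p < 0.05

    def test_identical_frequencies_raise(self):
        table = load_stacking_energies()
        counts = {cls: 5 for cls in list(table)[:4]}
        with pytest.raises(ValueError, match="identical"):
            stack_energy_correlation(counts, table)

    def test_too_few_classes_raise(self):
        table = load_stacking_energies()
        with pytest.raises(ValueError, match=">= 3"):
            stack_energy_correlation({list(table)[0]: 3}, table)


class TestEmbeddings:
    def test_length_32(self, tiny_trained, tiny_test_set):
        e = embed(tiny_trained.network, tiny_test_set[0])
        assert e.shape == (32,)
        assert np.isfinite(e).all()

    def test_invariant_to_batch_permutation(self, tiny_trained, tiny_test_set):
        s = tiny_test_set[1]
        batch = make_samples(s)
        net = tiny_trained.network
        acts = net.lstm_activations(batch.questions)
        base = acts.mean(axis=1).mean(axis=0)
        perm = np.random.default_rng(0).permutation(len(batch))
        acts_p = net.lstm_activations(batch.questions[perm])
        np.testing.assert_allclose(
            acts_p.mean(axis=1).mean(axis=0), base, atol=1e-5
        )

    def test_duplicate_questions_change_embedding(self, tiny_trained, tiny_test_set):
        s = tiny_test_set[2]
        batch = make_samples(s)
        net = tiny_trained.network
        acts = net.lstm_activations(batch.questions)
        plain = acts.mean(axis=1).mean(axis=0)
        dup = np.concatenate([batch.questions, batch.questions[:1]], axis=0)
        acts_d = net.lstm_activations(dup)
        weighted = acts_d.mean(axis=1).mean(axis=0)
        assert not np.allclose(weighted, plain, atol=1e-7)

    def test_empty_batch_raises(self, tiny_trained):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="empty"):
                embed(tiny_trained.network, SecondaryStructure("x", "ACGU"))


class TestClusterEmbeddings:
    def test_row_count_and_determinism(self, tmp_path):
        rng = np.random.default_rng(0)
        emb = np.vstack([rng.normal(0, 1, (15, 32)), rng.normal(4, 1, (15, 32))])
        labels = ["a"] * 15 + ["b"] * 15
        with pytest.warns(UserWarning, match="perplexity"):
            c1 = cluster_embeddings(emb, labels, seed=1)
        with pytest.warns(UserWarning, match="perplexity"):
            c2 = cluster_embeddings(
                emb, labels, seed=1, plot_path=tmp_path / "tsne.png"
            )
        assert c1.shape == (30, 2)
        np.testing.assert_allclose(c1, c2)
        assert (tmp_path / "tsne.png").exists()

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cluster_embeddings(np.zeros((1, 32)))


class TestAttentionInspection:
    def test_shape_and_serialization(self, tiny_trained, tiny_test_set, tmp_path):
        df = attention_inspection(tiny_trained.network, tiny_test_set[:5])
        assert df.shape == (5, 5)
        assert list(df.columns) == ["A", "C", "G", "U", "complementary"]
        df.to_csv(tmp_path / "attention.tsv", sep="\t")
        back = pd.read_csv(tmp_path / "attention.tsv", sep="\t", index_col=0)
        assert back.shape == df.shape

    def test_untrained_model_near_uniform_masses(self, tiny_test_set):
        """With random weights the attention is nearly uniform, so mass per
        nucleotide group tracks base composition (~0.25 each)."""
        masses = []
        for seed in range(3):
            net = PredPairNetwork(ModelConfig(seed=seed))
            df = attention_inspection(net, tiny_test_set[:6])
            masses.append(df[list("ACGU")].to_numpy())
        mean_mass = np.mean(masses, axis=0)
        assert np.all(np.abs(mean_mass - 0.25) < 0.12)

    def test_wrong_channel_count_raises(self, tiny_test_set):
        net = PredPairNetwork(ModelConfig(attention_channels=4, seed=0))
        with pytest.raises(ValueError, match="5-channel"):
            attention_inspection(net, tiny_test_set[:2])
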