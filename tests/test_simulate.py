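"""Synthetic-study generator: structure, determinism, planted truth."""

import numpy as np
import pytest

from cernet import diffexpr, simulate
from cernet.binding import revcomp_rna
from cernet.simulate import ConfigError, SynthConfig


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_circ", 0), ("n_mir", -1), ("noise_sd", 0.0),
        ("target_length", 10),  # below mir_length
    ])
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            SynthConfig(**{field: value})

    def test_too_many_planted_triplets(self):
        with pytest.raises(ConfigError, match="n_planted_triplets"):
            SynthConfig(n_circ=5, n_mir=5, n_mrna=5, n_planted_triplets=6)


class TestExpressionGeneration:
    def test_dimensions(self, small_config):
        circ, mir, mrna, _ = simulate.generate_expression(small_config)
        n = 2 * small_config.n_per_group
        assert circ.values.shape == (small_config.n_circ, n)
        assert mir.values.shape == (small_config.n_mir, n)
        assert mrna.values.shape == (small_config.n_mrna, n)

    def test_determinism_byte_identical(self, small_config):
        out1 = simulate.generate_expression(small_config)
        out2 = simulate.generate_expression(small_config)
        for a, b in zip(out1[:3], out2[:3]):
            assert a.values.to_csv() == b.values.to_csv()
        assert out1[3].planted_triplets == out2[3].planted_triplets
        assert out1[3].planted_sites == out2[3].planted_sites

    def test_planted_shift_within_three_standard_errors(self):
        # se of a difference of two 5-sample means at sd 0.2: 0.2*sqrt(2/5)
        config = SynthConfig(de_effect=3.0, noise_sd=0.2, n_per_group=5,
                             seed=123)
        circ, mir, mrna, truth = simulate.generate_expression(config)
        m = {"circ": circ, "mir": mir, "mrna": mrna}
        for profile, feats in truth.de_features.items():
            lfc = diffexpr.log2_fold_change(m[profile])
            for fid, shift in feats:
                assert lfc[fid] == pytest.approx(shift, abs=0.6)

    def test_direction_consistency_of_truth(self, small_config):
        _, _, _, truth = simulate.generate_expression(small_config)
        shifts = {p: dict(f) for p, f in truth.de_features.items()}
        for c, m, g, direction in truth.planted_triplets:
            sc, sm, sg = shifts["circ"][c], shifts["mir"][m], shifts["mrna"][g]
            assert np.sign(sc) == np.sign(sg) == -np.sign(sm)
            assert (direction == "up") == (sc > 0)

    def test_non_planted_features_share_group_means(self, small_config):
        circ, _, _, truth = simulate.generate_expression(small_config)
        de_ids = {f for f, _ in truth.de_features["circ"]}
        lfc = diffexpr.log2_fold_change(circ)
        null_lfc = lfc.drop(list(de_ids))
        # null features: mean difference ~ N(0, noise_sd*sqrt(2/n))
        bound = 4 * small_config.noise_sd * np.sqrt(2 / small_config.n_per_group)
        assert np.all(np.abs(null_lfc) < bound)


class TestSequenceGeneration:
    def test_planted_sites_are_exact_reverse_complements(self, small_config):
        _, _, _, truth = simulate.generate_expression(small_config)
        mir_seqs, circ_seqs, mrna_seqs = simulate.generate_sequences(
            small_config, truth)
        targets = {**circ_seqs, **mrna_seqs}
        assert truth.planted_sites
        for target_id, mir_id, start, end in truth.planted_sites:
            window = targets[target_id][start:end]
            assert window == revcomp_rna(mir_seqs[mir_id])

    def test_alphabet_is_acgu(self, small_config):
        _, _, _, truth = simulate.generate_expression(small_config)
        mir_seqs, circ_seqs, mrna_seqs = simulate.generate_sequences(
            small_config, truth)
        for pool in (mir_seqs, circ_seqs, mrna_seqs):
            for seq in pool.values():
                assert set(seq) <= set("ACGU")

    def test_decoy_windows_below_cap(self, small_config):
        _, _, _, truth = simulate.generate_expression(small_config)
        mir_seqs, circ_seqs, mrna_seqs = simulate.generate_sequences(
            small_config, truth)
        planted_targets = {t for t, _, _, _ in truth.planted_sites}
        targets = {**circ_seqs, **mrna_seqs}
        cap = small_config.decoy_max_complementarity
        L = small_config.mir_length
        pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                 ("G", "U"), ("U", "G")}
        for tid, tseq in targets.items():
            if tid in planted_targets:
                continue
            for mseq in mir_seqs.values():
                rev = mseq[::-1]
                for s in range(len(tseq) - L + 1):
                    frac = sum((rev[k], tseq[s + k]) in pairs
                               for k in range(L)) / L
                    assert frac <= cap, (tid, s, frac)

    def test_sequence_determinism(self, small_config):
        _, _, _, truth = simulate.generate_expression(small_config)
        a = simulate.generate_sequences(small_config, truth)
        b = simulate.generate_sequences(small_config, truth)
        assert a == b


class TestAnnotations:
    def test_planted_pairs_have_evidence(self, small_config):
        _, _, _, truth = simulate.generate_expression(small_config)
        interactions, _, _ = simulate.generate_annotations(small_config, truth)
        flags = interactions.set_index(["mir_id", "gene_id"])
        for _, m, g, _ in truth.planted_triplets:
            assert flags.loc[(m, g)].sum() >= 1

    def test_distractors_with_zero_flags_present(self, small_config):
        _, _, _, truth = simulate.generate_expression(small_config)
        interactions, _, _ = simulate.generate_annotations(small_config, truth)
        evidence = interactions.iloc[:, 2:].sum(axis=1)
        assert (evidence == 0).sum() == small_config.n_unflagged_distractors

    def test_disease_list_overlaps_collection(self, small_config):
        _, _, _, truth = simulate.generate_expression(small_config)
        _, collection, disease = simulate.generate_annotations(small_config,
                                                               truth)
        ids = set(disease["pathway_id"])
        assert ids & set(collection)          # at least one flagged set
        assert set(collection) - ids          # and one set outside the list
        planted_genes = {g for _, _, g, _ in truth.planted_triplets}
        flagged_members = {g for sid in ids & set(collection)
                           for g in collection[sid][1]}
        assert planted_genes & flagged_members


class TestNullCalibration:
    def test_fdr_screen_calibrated_under_global_null(self):
        """With nothing planted, the FDR<0.05 screen stays near its level."""
        fractions = []
        for seed in range(10):
            config = SynthConfig(n_circ=1, n_mir=1, n_mrna=200,
                                 n_planted_triplets=1, de_effect=0.0,
                                 n_extra_de=0, seed=1000 + seed)
            _, _, mrna, _ = simulate.generate_expression(config)
            tab = diffexpr.de_table(mrna)
            fractions.append((tab["fdr"] < 0.05).mean())
        bound = 0.05 + 2 * np.sqrt(0.05 * 0.95 / 200)
        assert np.mean(fractions) <= bound


class TestValidationCohort:
    def test_shapes_and_independence(self, small_config):
        _, _, _, truth = simulate.generate_expression(small_config)
        vmir, vmrna = simulate.generate_validation(small_config, truth)
        assert vmir.values.shape == (small_config.n_mir, 6)
        assert vmrna.values.shape == (small_config.n_mrna, 6)
        # same truth, fresh noise: planted shifts preserved in expectation
        shifts = dict(truth.de_features["mrna"])
        lfc = diffexpr.log2_fold_change(vmrna)
        for fid, shift in shifts.items():
            assert np.sign(lfc[fid]) == np.sign(shift)
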