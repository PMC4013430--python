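"""Generator determinism, perturbation calibration and file round trips."""

import numpy as np
import pytest

from resqa.errors import InputError
from resqa.model_features import assign_secondary_structure
from resqa.prediction_inputs import (
    read_acc_prediction,
    read_fasta,
    read_pssm,
    read_rr_contacts,
    read_ss_prediction,
)
from resqa.synthetic import (
    DecoySpec,
    corrupt_annotations,
    generate_corpus,
    generate_decoy,
    generate_native,
    write_acc_pred,
    write_fasta,
    write_pssm,
    write_rr,
    write_ss_pred,
)


class TestGenerateNative:
    def test_helix_layout_recovered_by_assignment(self):
        spec = DecoySpec(n_targets=1, ss_layout=[("H", 15)], seed=2)
        native, feats, _ = generate_native(spec, 0)
        assert feats.ss3.count("H") >= 11

    def test_deterministic_given_seed(self, tiny_spec):
        a, _, _ = generate_native(tiny_spec, 1)
        b, _, _ = generate_native(tiny_spec, 1)
        np.testing.assert_array_equal(a.coords("CA"), b.coords("CA"))

    def test_zero_length_layout_rejected(self):
        with pytest.raises(InputError):
            generate_native(DecoySpec(ss_layout=[("H", 0)]), 0)

    def test_no_self_clashes(self, tiny_spec):
        native, _, _ = generate_native(tiny_spec, 0)
        ca = native.coords("CA")
        L = len(native)
        for i in range(L):
            for j in range(i + 3, L):
                assert np.linalg.norm(ca[i] - ca[j]) >= 3.5


class TestGenerateDecoy:
    def test_zero_perturbation_is_identity(self, tiny_spec):
        import dataclasses

        native, feats, _ = generate_native(tiny_spec, 0)
        spec = dataclasses.replace(tiny_spec, coord_noise_sigma_a=0.0,
                                   segment_rotation_deg=0.0, hinge_count=0)
        _, dev = generate_decoy(native, spec, seed=1, ss3=feats.ss3)
        assert dev.max() < 1e-8

    def test_mean_deviation_tracks_sigma(self, tiny_spec):
        """Mean deviation within 20% of a Monte-Carlo oracle estimate built
        from independent replicates at the same sigma."""
        import dataclasses

        native, feats, _ = generate_native(tiny_spec, 0)
        spec = dataclasses.replace(tiny_spec, coord_noise_sigma_a=1.0,
                                   segment_rotation_deg=0.0, hinge_count=0)
        profile = np.ones(len(native))

        def ensemble_mean(tag, n):
            means = [
                generate_decoy(native, spec, seed=[tag, s], ss3=feats.ss3,
                               sigma_profile=profile)[1].mean()
                for s in range(n)
            ]
            return float(np.mean(means))

        oracle = ensemble_mean(5, 50)
        check = ensemble_mean(6, 20)
        assert abs(check - oracle) <= 0.2 * oracle
        # magnitude sanity: mean |3-D Gaussian| at sigma=1 is ~1.6 Å before
        # the superposition removes part of it
        assert 0.8 <= oracle <= 1.7

    def test_noisier_region_deviates_more(self, tiny_spec):
        """Residues given a larger sigma deviate more on average (paired
        over seeds)."""
        import dataclasses

        native, feats, _ = generate_native(tiny_spec, 1)
        L = len(native)
        spec = dataclasses.replace(tiny_spec, coord_noise_sigma_a=1.0,
                                   segment_rotation_deg=0.0, hinge_count=0)
        profile = np.full(L, 0.3)
        profile[10:21] = 2.5
        inside, outside = [], []
        for s in range(20):
            _, dev = generate_decoy(native, spec, seed=[77, s], ss3=feats.ss3,
                                    sigma_profile=profile)
            inside.append(dev[10:21].mean())
            outside.append(np.concatenate([dev[:10], dev[21:]]).mean())
        assert np.mean(inside) > np.mean(outside)

    def test_deterministic(self, tiny_spec):
        native, feats, _ = generate_native(tiny_spec, 0)
        a, da = generate_decoy(native, tiny_spec, seed=9, ss3=feats.ss3)
        b, db = generate_decoy(native, tiny_spec, seed=9, ss3=feats.ss3)
        np.testing.assert_array_equal(a.coords("CA"), b.coords("CA"))
        np.testing.assert_array_equal(da, db)


class TestCorruptAnnotations:
    def test_zero_error_rate_preserves_truth(self, tiny_spec):
        import dataclasses

        native, feats, _ = generate_native(tiny_spec, 0)
        seq = "".join(r.aa for r in native.residues)
        spec = dataclasses.replace(tiny_spec, ss_error_rate=0.0,
                                   acc_error_rate=0.0)
        ann = corrupt_annotations(seq, feats, spec, seed=1)
        assert ann.ss3_pred == feats.ss3
        assert ann.exposure2_pred == feats.exposure2

    def test_full_error_rate_flips_everything(self, tiny_spec):
        import dataclasses

        native, feats, _ = generate_native(tiny_spec, 0)
        seq = "".join(r.aa for r in native.residues)
        spec = dataclasses.replace(tiny_spec, ss_error_rate=1.0,
                                   acc_error_rate=1.0)
        ann = corrupt_annotations(seq, feats, spec, seed=1)
        assert all(a != b for a, b in zip(ann.ss3_pred, feats.ss3))
        assert all(a != b for a, b in zip(ann.exposure2_pred, feats.exposure2))

    def test_corruption_prefers_high_deviation_residues(self, tiny_spec):
        import dataclasses

        native, feats, _ = generate_native(tiny_spec, 0)
        seq = "".join(r.aa for r in native.residues)
        L = len(seq)
        dev = np.zeros(L)
        dev[: L // 2] = 10.0  # first half "bad"
        spec = dataclasses.replace(tiny_spec, ss_error_rate=0.3,
                                   deviation_linkage=2.0)
        flips_bad = flips_good = 0
        for s in range(30):
            ann = corrupt_annotations(seq, feats, spec, seed=s, deviations=dev)
            diff = [a != b for a, b in zip(ann.ss3_pred, feats.ss3)]
            flips_bad += sum(diff[: L // 2])
            flips_good += sum(diff[L // 2 :])
        assert flips_bad > flips_good

    def test_contact_probabilities_separate_true_from_false(self, tiny_spec):
        native, feats, _ = generate_native(tiny_spec, 0)
        seq = "".join(r.aa for r in native.residues)
        ann = corrupt_annotations(seq, feats, tiny_spec, seed=3)
        true_ps, false_ps = [], []
        for i, partners in enumerate(feats.contacts):
            for j in partners:
                if j - 1 > i:
                    true_ps.append(ann.contact_prob[i, j - 1])
        for i in range(len(seq)):
            for j in range(i + 6, len(seq)):
                if (j + 1) not in feats.contacts[i] and ann.contact_prob[i, j] > 0:
                    false_ps.append(ann.contact_prob[i, j])
        if true_ps and false_ps:
            assert np.mean(true_ps) > 0.6 > np.mean(false_ps)


class TestFileRoundTrips:
    def test_all_writers_read_back_exactly(self, tiny_spec, tmp_path):
        native, feats, _ = generate_native(tiny_spec, 0)
        seq = "".join(r.aa for r in native.residues)
        ann = corrupt_annotations(seq, feats, tiny_spec, seed=11)
        L = len(seq)

        write_fasta("t0", seq, tmp_path / "t.fasta")
        assert read_fasta(tmp_path / "t.fasta") == ("t0", seq)

        write_ss_pred(ann.ss3_pred, tmp_path / "ss.pred")
        assert read_ss_prediction(tmp_path / "ss.pred", L) == ann.ss3_pred

        write_acc_pred(ann.exposure2_pred, tmp_path / "acc.pred")
        assert read_acc_prediction(tmp_path / "acc.pred", L) == ann.exposure2_pred

        write_rr(seq, ann.contact_prob, tmp_path / "c.rr")
        back = read_rr_contacts(tmp_path / "c.rr", L)
        np.testing.assert_allclose(back, ann.contact_prob, atol=1e-6)

        write_pssm(seq, ann.pssm, tmp_path / "p.pssm")
        back = read_pssm(tmp_path / "p.pssm", L, sequence=seq)
        np.testing.assert_array_equal(back, ann.pssm)


class TestCorpus:
    def test_pure_function_of_spec_and_seed(self, tiny_spec):
        a = generate_corpus(tiny_spec)
        b = generate_corpus(tiny_spec)
        for ba, bb in zip(a, b):
            np.testing.assert_array_equal(
                ba.native.coords("CA"), bb.native.coords("CA")
            )
            assert ba.annotations.ss3_pred == bb.annotations.ss3_pred
            for (ma, da), (mb, db) in zip(ba.decoys, bb.decoys):
                np.testing.assert_array_equal(da, db)

    def test_corruption_correlates_with_deviation(self, tiny_spec):
        """The learnable signal: window feature corruption grows with true
        deviation on every generated corpus."""
        from resqa.feature_encoding import EncodingConfig
        from resqa.pipeline import featurize_bundle

        corpus = generate_corpus(tiny_spec)
        X, y = [], []
        for bundle in corpus:
            for es, (_, dev) in zip(
                featurize_bundle(bundle, EncodingConfig()), bundle.decoys
            ):
                X.append(es.features)
                y.append(dev)
        X = np.vstack(X)
        y = np.concatenate(y)
        info = np.array([b * 23 + k for b in range(15) for k in (20, 21)])
        corruption = 1.0 - X[:, info].mean(axis=1)
        assert np.corrcoef(corruption, y)[0, 1] > 0.2
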