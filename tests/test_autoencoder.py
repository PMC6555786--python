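"""Autoencoder architecture, training, orientation and profile encoding."""

import numpy as np
import pytest

import shiftcodec as sc
from shiftcodec.autoencoder import (
    DEFAULT_HIDDEN_GRID,
    ResidueAutoencoder,
    build_model,
    encode_protein,
    encode_with_fallback,
    stability_scan,
)
from shiftcodec.cs_io import common_scheme
from shiftcodec.errors import (
    CalibrationError,
    ConfigMismatchError,
    FittingError,
    ParameterError,
)


def _auc(scores, positive):
    """Rank-statistic AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = np.asarray(scores)[np.asarray(positive)]
    neg = np.asarray(scores)[~np.asarray(positive)]
    gt = (pos[:, None] > neg[None, :]).mean()
    eq = (pos[:, None] == neg[None, :]).mean()
    return gt + 0.5 * eq


class TestConstruction:
    def test_parameter_count_closed_form(self):
        # (6*100+100)+(100*100+100)+(100+1)+(1*100+100)+(100*100+100)+(100*6+6)
        model = build_model("A", "common", hidden_size=100, seed=0)
        assert model.n_parameters_ == 21807

    def test_seeded_init_bit_identical(self):
        a = build_model("A", "common", seed=42)
        b = build_model("A", "common", seed=42)
        for (Wa, ba), (Wb, bb) in zip(a.weights_, b.weights_):
            assert np.array_equal(Wa, Wb) and np.array_equal(ba, bb)

    @pytest.mark.parametrize("hidden", [10, 150])
    def test_grid_extremes_build_mirrored(self, hidden):
        model = build_model("A", "common", hidden_size=hidden, seed=0)
        shapes = [W.shape for W, _ in model.weights_]
        assert shapes == [
            (6, hidden), (hidden, hidden), (hidden, 1),
            (1, hidden), (hidden, hidden), (hidden, 6),
        ]

    def test_bad_hidden_size_rejected(self):
        with pytest.raises(ParameterError):
            build_model("A", "common", hidden_size=0)

    def test_training_config_validation(self):
        with pytest.raises(ParameterError):
            sc.TrainingConfig(validation_fraction=0.7)
        with pytest.raises(ParameterError):
            sc.TrainingConfig(max_epochs=0)


class TestTraining:
    def test_memorizes_constant_vector(self):
        rng = np.random.default_rng(1)
        X = np.tile(rng.random(6), (200, 1))
        model = ResidueAutoencoder("A", seed=3, max_epochs=300).fit(X)
        assert model.final_val_mse_ < 1e-4

    def test_too_few_samples_errors(self):
        with pytest.raises(FittingError, match=">= 50"):
            ResidueAutoencoder("A").fit(np.random.default_rng(0).random((10, 6)))

    def test_unscaled_data_rejected(self):
        X = np.full((60, 6), 2.0)
        with pytest.raises(ParameterError, match="scaled"):
            ResidueAutoencoder("A").fit(X)

    def test_loss_running_minimum_non_increasing(self, trained_ala):
        hist = np.array(trained_ala.loss_history_)
        running = np.minimum.accumulate(hist)
        assert np.all(np.diff(running) <= 0)
        assert trained_ala.final_val_mse_ <= hist[0]

    def test_reproducible_given_seed(self, ala_training_data):
        X, _, _ = ala_training_data
        m1 = ResidueAutoencoder("A", seed=7, max_epochs=30).fit(X)
        m2 = ResidueAutoencoder("A", seed=7, max_epochs=30).fit(X)
        x = X[:5]
        np.testing.assert_array_equal(m1.transform(x), m2.transform(x))

    def test_two_cluster_reconstruction(self, trained_ala, ala_training_data):
        X, _, _ = ala_training_data
        r = trained_ala.reconstruction_report(X)
        assert np.all(r > 0.9)


class TestOrientation:
    def test_sets_sheet_high(self, trained_ala, ala_training_data):
        X, labels, _ = ala_training_data
        idx = trained_ala.transform(X)
        assert (np.median(idx[labels == "sheet"])
                > np.median(idx[labels == "helix"]))

    def test_idempotent(self, trained_ala, ala_training_data):
        X, labels, _ = ala_training_data
        flag = trained_ala.inverted_
        trained_ala.orient(X, labels)
        assert trained_ala.inverted_ == flag

    def test_inversion_is_involution(self, trained_ala, ala_training_data):
        X, _, _ = ala_training_data
        raw = trained_ala._raw_encode(X[:20])
        oriented = trained_ala.transform(X[:20])
        if trained_ala.inverted_:
            np.testing.assert_allclose(oriented, 1.0 - raw)
        else:
            np.testing.assert_array_equal(oriented, raw)
        np.testing.assert_allclose(1.0 - (1.0 - raw), raw)

    def test_missing_class_errors(self, trained_ala, ala_training_data):
        X, _, _ = ala_training_data
        with pytest.raises(CalibrationError, match="sheet"):
            trained_ala.orient(X[:30], ["helix"] * 30)


class TestEncodeDecode:
    def test_index_strictly_in_unit_interval(self):
        # property over many random inputs and random untrained weights
        model = build_model("A", "common", seed=1)
        X = np.random.default_rng(2).random((10_000, 6))
        idx = model.transform(X)
        assert np.all((idx > 0) & (idx < 1))

    def test_zeroed_bottleneck_gives_half(self):
        model = build_model("A", "common", seed=1)
        W, b = model.weights_[2]
        model.weights_[2] = (np.zeros_like(W), np.zeros_like(b))
        assert model.transform(np.full(6, 0.3)) == pytest.approx(0.5)

    def test_continuity_under_tiny_perturbation(self, trained_ala):
        x = np.full(6, 0.4)
        d = abs(trained_ala.transform(x) - trained_ala.transform(x + 1e-8))
        assert d < 1e-6

    def test_decode_is_deterministic_function(self, trained_ala):
        a = trained_ala.decode(0.3)
        b = trained_ala.decode(0.3)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (6,)
        assert np.all((a > 0) & (a < 1))

    def test_decode_domain_error(self, trained_ala):
        for bad in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(ParameterError):
                trained_ala.decode(bad)

    def test_oriented_decode_matches_raw_involution(self, trained_ala):
        s = 0.27
        raw_arg = 1.0 - s if trained_ala.inverted_ else s
        np.testing.assert_allclose(
            trained_ala.decode(s), trained_ala._raw_decode(np.array([raw_arg]))[0]
        )

    def test_autoencoding_near_identity_on_memorized_vector(self):
        rng = np.random.default_rng(4)
        v = rng.random(6)
        X = np.tile(v, (200, 1))
        model = ResidueAutoencoder("A", seed=5, max_epochs=300).fit(X)
        recon = model.decode(float(model.encode(v)))
        assert np.abs(recon - v).max() < 0.05

    def test_reconstruction_report_identity_and_degenerate(self):
        model = build_model("A", "common", seed=1)
        X = np.random.default_rng(3).random((50, 6))

        class Identity(ResidueAutoencoder):
            def _raw_encode(self, X):
                return np.zeros(len(np.atleast_2d(X)))

            def _raw_decode(self, s):
                return X

        ident = Identity("A")
        ident.weights_ = model.weights_
        np.testing.assert_allclose(ident.reconstruction_report(X), np.ones(6))
        # constant reconstruction -> undefined correlation
        class Constant(Identity):
            def _raw_decode(self, s):
                return np.full((len(X), 6), 0.5)

        const = Constant("A")
        const.weights_ = model.weights_
        assert np.isnan(const.reconstruction_report(X)).all()


class TestEncodeProtein:
    @pytest.fixture(scope="class")
    def small_bundle(self, two_class_pool):
        tables, truth = two_class_pool
        model = sc.ShiftCrypt(scheme="common", max_epochs=100,
                              min_samples=40, seed=5)
        model.fit(tables, labels=truth.labels)
        return model

    def test_empty_table(self, small_bundle):
        profile = small_bundle.transform(sc.ProteinShiftTable("empty", []))
        assert len(profile) == 0

    def test_missing_atom_status(self, small_bundle):
        rec_ok = sc.ShiftRecord(
            "A", 1, "A",
            {"N": 119, "C": 176, "CA": 57, "CB": 38, "H": 8.3, "HA": 4.3},
        )
        rec_bad = sc.ShiftRecord("A", 2, "A", {"N": 119, "C": 176})
        profile = small_bundle.transform(
            sc.ProteinShiftTable("t", [rec_ok, rec_bad])
        )
        assert [e.status for e in profile] == ["ok", "missing_atoms"]
        assert profile.entries[1].index is None
        assert 0 < profile.entries[0].index < 1

    def test_scheme_mismatch_raises(self, small_bundle):
        table = sc.ProteinShiftTable("t", [])
        wrong_scaler = sc.ShiftScaler(scheme="minimal")
        wrong_scaler.ranges_ = {}
        with pytest.raises(ConfigMismatchError):
            encode_protein(table, small_bundle.models_, common_scheme(),
                           wrong_scaler)

    def test_index_separates_classes(self, small_bundle, two_class_pool):
        spec = sc.SyntheticSpec.two_class(
            separation=5.0, n_proteins=4, length=(200, 200), seed=77
        )
        tables, truth = sc.generate_dataset(spec)
        scores, is_sheet = [], []
        for t in tables:
            for e in small_bundle.transform(t):
                if e.status == "ok":
                    scores.append(e.index)
                    is_sheet.append(
                        truth.labels[(t.entry_id, e.chain_id, e.residue_number)]
                        == "sheet"
                    )
        assert _auc(scores, is_sheet) > 0.9

    def test_seed_determinism_end_to_end(self, two_class_pool):
        tables, truth = two_class_pool
        kw = dict(scheme="common", max_epochs=25, min_samples=40, seed=9)
        p1 = sc.ShiftCrypt(**kw).fit(tables, truth.labels).transform(tables[0])
        p2 = sc.ShiftCrypt(**kw).fit(tables, truth.labels).transform(tables[0])
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_bundle_save_load_round_trip(self, small_bundle, two_class_pool,
                                         tmp_path):
        tables, _ = two_class_pool
        small_bundle.save(tmp_path / "bundle")
        loaded = sc.ShiftCrypt.load(tmp_path / "bundle")
        p1 = small_bundle.transform(tables[0])
        p2 = loaded.transform(tables[0])
        assert p1 == p2

    def test_fallback_fills_missing(self, small_bundle, two_class_pool):
        tables, truth = two_class_pool
        minimal = sc.ShiftCrypt(scheme="minimal", max_epochs=60,
                                min_samples=40, seed=5)
        minimal.fit(tables, labels=truth.labels)
        rec = sc.ShiftRecord("A", 1, "A", {"N": 119, "H": 8.3, "CA": 57})
        table = sc.ProteinShiftTable("t", [rec])
        alone = small_bundle.transform(table)
        assert alone.entries[0].status == "missing_atoms"
        filled = encode_with_fallback(table, [small_bundle, minimal])
        assert filled.entries[0].status == "ok"


class TestStabilityScan:
    def test_default_grid_has_15_sizes(self):
        assert len(DEFAULT_HIDDEN_GRID) == 15
        assert DEFAULT_HIDDEN_GRID[0] == 10 and DEFAULT_HIDDEN_GRID[-1] == 150

    def test_single_size_table(self, ala_training_data):
        X, labels, _ = ala_training_data
        table = stability_scan(X, labels, hidden_sizes=[20], seed=1,
                               max_epochs=60)
        assert list(table.index) == [20]
        assert {"median_helix", "median_sheet"} <= set(table.columns)

    def test_scan_orients_every_size(self, ala_training_data):
        # medians land in (0,1) and every model ends up sheet-high
        X, labels, _ = ala_training_data
        table = stability_scan(X, labels, hidden_sizes=[10, 80, 150], seed=1,
                               max_epochs=120)
        assert list(table.index) == [10, 80, 150]
        assert ((table[["median_helix", "median_sheet"]] > 0).all().all()
                and (table[["median_helix", "median_sheet"]] < 1).all().all())
        assert (table["median_sheet"] >= table["median_helix"]).all()

    def test_training_error_annotated_with_size(self):
        X = np.random.default_rng(0).random((10, 6))
        with pytest.raises(FittingError, match="hidden_size=10"):
            stability_scan(X, ["helix"] * 10, hidden_sizes=[10])
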