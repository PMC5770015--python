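"""Synthetic-data generator: sampling, evolution, rendering, taggers, study."""

import json

import numpy as np
import pandas as pd
import pytest

from symsig.complexity import perimetric_complexity
from symsig.errors import ConfigurationError, DataIntegrityError
from symsig.generate import (
    BehaviourModel,
    GroundModel,
    StudyConfig,
    TaggerProfile,
    evolve_signal,
    generate_study,
    jd_table,
    sample_ground,
    simulate_responses,
    simulate_study,
    simulate_tagger,
)
from symsig.glyphs import GlyphLibrary, render_signal
from symsig.ground import jaccard_distance


@pytest.fixture(scope="module")
def ground():
    return GroundModel.build(items=("alpha", "beta", "gamma"), seed=0)


class TestSampleGround:
    def test_degenerate_concentration_gives_identical_samples(self):
        gm = GroundModel.build(items=("x",), seed=0, lam=2.0)
        gm.salience["x"] = [10.0] + [0.0] * (gm.vocab_size - 1)
        gm.item_theta["x"] = 1e6  # all probability mass on one always-drawn tag
        rng = np.random.default_rng(0)
        draws = [sample_ground("x", gm, rng) for _ in range(20)]
        assert all(d == draws[0] for d in draws)
        assert jaccard_distance(draws[0], draws[1]) == 0.0

    def test_diffuse_probabilities_give_high_expected_jd(self):
        gm = GroundModel.build(items=("x",), seed=0, vocab_size=40, lam=3.0)
        gm.salience["x"] = [0.0] * 40
        gm.item_theta["x"] = 0.0  # uniform p = 3/40 over 40 tags
        rng = np.random.default_rng(1)
        est = gm.expected_jd("x", rng, n_pairs=2000)
        assert est > 0.85

    def test_seed_determinism_and_nonempty(self, ground):
        a = sample_ground("alpha", ground, np.random.default_rng(9))
        b = sample_ground("alpha", ground, np.random.default_rng(9))
        assert a == b and len(a) >= 1

    def test_expected_jd_monotone_in_concentration(self):
        means = []
        for theta in (0.5, 2.0, 8.0):
            gm = GroundModel.build(
                items=("a", "b", "c", "d"), seed=3, theta=theta, theta_log_spread=0.0
            )
            rng = np.random.default_rng(42)
            means.append(np.mean([gm.expected_jd(i, rng, 300) for i in gm.items]))
        assert means[0] > means[1] > means[2]


class TestEvolveSignal:
    def test_pure_copy(self, ground):
        prev = frozenset({"A", "B", "C"})
        b = BehaviourModel(rho_reuse=1.0, delta_drop=0.0)
        tags, novel = evolve_signal(prev, "alpha", b, ground, np.random.default_rng(0))
        assert tags == prev and not novel

    def test_full_drop_keeps_one_tag(self, ground):
        prev = frozenset({"A", "B", "C"})
        b = BehaviourModel(rho_reuse=1.0, delta_drop=1.0)
        tags, novel = evolve_signal(prev, "alpha", b, ground, np.random.default_rng(0))
        assert len(tags) == 1 and tags <= prev and not novel

    def test_reconstrual_matches_fresh_sampling_distribution(self, ground):
        """With rho_reuse = 0 the successor is statistically a fresh draw:
        its similarity to the previous signal matches that of two
        independent ground samples (Monte-Carlo)."""
        b = BehaviourModel(rho_reuse=0.0)
        rng = np.random.default_rng(7)
        prev = sample_ground("beta", ground, rng)
        sims_evolved = []
        sims_fresh = []
        for _ in range(2000):
            t, novel = evolve_signal(prev, "beta", b, ground, rng)
            assert novel
            sims_evolved.append(1 - jaccard_distance(prev, t))
            sims_fresh.append(
                1 - jaccard_distance(prev, sample_ground("beta", ground, rng))
            )
        assert np.mean(sims_evolved) == pytest.approx(np.mean(sims_fresh), abs=0.03)


class TestRendering:
    def test_deterministic_bytes(self):
        tags = frozenset({"A:1", "B:2", "C:3"})
        a = render_signal(tags, 0)
        b = render_signal(tags, 0)
        assert (a == b).all()

    def test_simplification_never_increases_ink_or_pc(self):
        tags = frozenset({"WHIP", "HAT", "MAN", "CAR"})
        prev_ink, prev_pc = None, None
        for level in range(4):
            img = render_signal(tags, level)
            res = perimetric_complexity(img)
            if prev_ink is not None:
                assert res.ink <= prev_ink
                assert res.pc <= prev_pc + 1e-9
            prev_ink, prev_pc = res.ink, res.pc

    def test_glyph_ladder_is_nested(self):
        lib = GlyphLibrary()
        for tag in ("MAN", "HAT", "GUN"):
            per_level = []
            for level in range(4):
                img = np.zeros((32, 32), bool)
                lib.render_glyph(tag, level, img, 0, 0)
                per_level.append(img)
            for s in range(3):
                assert (per_level[s + 1] <= per_level[s]).all()  # subset of strokes

    def test_capacity_error(self):
        with pytest.raises(ConfigurationError):
            render_signal(frozenset(str(i) for i in range(30)), 0)

    def test_empty_tags_rejected(self):
        with pytest.raises(ConfigurationError):
            render_signal(frozenset(), 0)


class TestSimulateTagger:
    def test_perfect_tagger_identity_map(self, ground):
        tags = frozenset(ground.vocab("alpha")[:4])
        prof = TaggerProfile("t", 1.0, {t: t for t in ground.vocab("alpha")})
        assert simulate_tagger(tags, prof, np.random.default_rng(0)) == tags

    def test_relabelled_perfect_taggers_agree_on_jd(self):
        """Two perfect taggers with different bijections produce identical
        by-item JD_mu vectors (content insensitivity)."""
        cfg = StudyConfig(n_pairs=4, tagger_detection=1.0)
        d = simulate_study(cfg, seed=5)
        j = d.jd
        t1 = j[j.tagger == "tagger1"].set_index("item").jd_mu
        t2 = j[j.tagger == "tagger2"].set_index("item").jd_mu
        assert np.allclose(t1.sort_index(), t2.sort_index())

    def test_nonbijective_map_rejected(self):
        with pytest.raises(ConfigurationError):
            TaggerProfile("t", 1.0, {"A": "X", "B": "X"})

    def test_partial_detection_expected_overlap(self, ground):
        """Detection p on both sides: E|intersection| = p^2 |S| and
        E|union| = (2p - p^2)|S|, so the expected JD between two taggers'
        codings of the same signal is near 1 - p/(2 - p) for large sets."""
        p = 0.8
        vocab = [f"T{i}" for i in range(400)]
        tags = frozenset(vocab)
        prof1 = TaggerProfile("a", p, {t: t for t in vocab})
        prof2 = TaggerProfile("b", p, {t: t for t in vocab})
        rng = np.random.default_rng(11)
        jds = [
            jaccard_distance(
                simulate_tagger(tags, prof1, rng), simulate_tagger(tags, prof2, rng)
            )
            for _ in range(200)
        ]
        assert np.mean(jds) == pytest.approx(1 - p / (2 - p), abs=0.01)


class TestSimulateResponses:
    def _records(self, n=50):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "signal_id": [f"s{i}" for i in range(n)],
                "jd_true": rng.random(n),
                "fam_sim": np.where(np.arange(n) % 5 == 0, np.nan, rng.random(n)),
                "time_seen": rng.integers(1, 5, n),
                "log_pc": rng.normal(4.5, 0.5, n),
                "is_first_exposure": np.arange(n) % 5 == 0,
            }
        )

    def test_null_model_constant_rating(self):
        rec = self._records()
        b = BehaviourModel(b0=4.2, b_jd=0.0, b_fam=0.0, b_time=0.0, sigma_insight=0.0)
        out = simulate_responses(rec, b, np.random.default_rng(0))
        assert (out.insight == round(4.2)).all()

    def test_noiseless_monotone_in_time(self):
        rec = self._records()
        rec["fam_sim"] = np.nan
        rec["is_first_exposure"] = True
        rec.loc[1:, "is_first_exposure"] = False
        rec["jd_true"] = 0.5
        b = BehaviourModel(b_jd=0.0, b_time=0.8, b_fam=0.0, sigma_insight=0.0)
        out = simulate_responses(rec, b, np.random.default_rng(0))
        grp = out.groupby("time_seen").insight.mean()
        assert (grp.diff().dropna() <= 0).all()

    def test_familiarity_absent_on_first_exposure(self):
        out = simulate_responses(self._records(), BehaviourModel(), np.random.default_rng(0))
        assert out.loc[out.is_first_exposure, "familiarity"].isna().all()
        assert out.insight.between(1, 7).all()
        assert out.accuracy.isin([0, 1]).all()

    def test_missing_covariate_is_integrity_error(self):
        rec = self._records().drop(columns=["log_pc"])
        with pytest.raises(DataIntegrityError, match="log_pc"):
            simulate_responses(rec, BehaviourModel(), np.random.default_rng(0))


class TestSimulateStudy:
    def test_determinism_same_seed(self):
        a = simulate_study(StudyConfig(n_pairs=3), seed=9)
        b = simulate_study(StudyConfig(n_pairs=3), seed=9)
        pd.testing.assert_frame_equal(a.signals, b.signals)
        pd.testing.assert_frame_equal(a.tags, b.tags)
        assert a.truth == b.truth

    def test_theta_knob_decreases_consensus_jd(self):
        means = []
        for theta in (0.5, 2.0, 8.0):
            cfg = StudyConfig(n_pairs=4, theta=theta, theta_log_spread=0.0)
            d = simulate_study(cfg, seed=2)
            cons = d.jd[d.jd.tagger == "consensus"].jd_mu
            means.append(cons.mean())
        assert means[0] > means[1] > means[2]

    def test_truth_roundtrip(self):
        d = simulate_study(StudyConfig(n_pairs=2), seed=4)
        blob = json.loads(json.dumps(d.truth))
        gm = GroundModel.from_dict(blob["ground_model"])
        assert gm == GroundModel.from_dict(d.truth["ground_model"])
        bm = BehaviourModel.from_dict(blob["behaviour_model"])
        assert bm == BehaviourModel(**d.truth["behaviour_model"])
        cfg = StudyConfig.from_dict(blob["config"])
        assert cfg == StudyConfig.from_dict(d.truth["config"])

    def test_zero_pairs_schema_valid(self):
        d = simulate_study(StudyConfig(n_pairs=0), seed=1)
        assert len(d.signals) == 0
        assert {"signal_id", "insight", "accuracy"} <= set(d.signals.columns)
        assert len(d.jd) == 0

    def test_schedule_invariants_hold_in_study(self, default_study):
        sig = default_study.signals
        per_round = sig.groupby(["pair_id", "round"]).size()
        assert (per_round == 10).all()
        # each participant signals 4 rounds per game
        counts = sig.groupby(["pair_id", "signaller_id"])["round"].nunique()
        assert (counts == 4).all()

    def test_generate_study_to_disk(self, tmp_path):
        cfg = StudyConfig(n_pairs=2)
        generate_study(cfg, 3, tmp_path / "out", write_images=True)
        names = {p.name for p in (tmp_path / "out").iterdir()}
        assert {"schedule.csv", "signals.csv", "tags.csv", "jd.csv",
                "responses.csv", "ratings.csv", "truth.json", "images"} <= names
        with pytest.raises(ConfigurationError):
            generate_study(cfg, 3, tmp_path / "out")  # non-empty, no force
        generate_study(cfg, 3, tmp_path / "out", force=True)

    def test_image_bytes_deterministic(self, tmp_path):
        for sub in ("a", "b"):
            generate_study(StudyConfig(n_pairs=1), 5, tmp_path / sub, write_images=True)
        fa = sorted((tmp_path / "a" / "images").iterdir())
        fb = sorted((tmp_path / "b" / "images").iterdir())
        assert [p.name for p in fa] == [p.name for p in fb]
        assert all(x.read_bytes() == y.read_bytes() for x, y in zip(fa, fb))
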