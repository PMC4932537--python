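"""Model matching, library ranking and enrichment statistics."""

import math

import numpy as np
import pytest

import phoregen as pg
from phoregen.errors import PhoregenError
from phoregen.features import FeaturePoint, FeatureType

from conftest import make_point, random_rigid_motion


class TestMatch:
    def test_planted_square_hits(self, square_features):
        model = pg.default_rhomb_model()
        result = pg.match(model, square_features(4.5))
        assert result is not None
        assert result.hit
        assert result.deviation == 0.0

    def test_displaced_corner_deviation(self, square_features):
        """Pulling the projection corner until the adjacent sides reach
        7.0 A gives deviation 7.0 - 5.0 = 2.0 and no hit."""
        h = 4.5 / np.sqrt(2.0)
        y = -math.sqrt(7.0**2 - h**2)
        feats = square_features(4.5, proj_y=y)
        result = pg.match(pg.default_rhomb_model(), feats)
        assert result is not None
        assert not result.hit
        assert result.deviation == pytest.approx(2.0, abs=1e-9)

    def test_rigid_motion_invariance(self, square_features):
        model = pg.default_rhomb_model()
        feats = square_features(4.7)
        base = pg.match(model, feats).deviation
        rng = np.random.default_rng(8)
        for _ in range(10):
            q, t = random_rigid_motion(rng)
            moved = [
                FeaturePoint(f.type, f.position @ q.T + t, f.source_atoms)
                for f in feats
            ]
            assert abs(pg.match(model, moved).deviation - base) < 1e-9

    def test_reflection_invariance(self, square_features):
        model = pg.default_rhomb_model()
        feats = square_features(4.7)
        mirrored = [
            FeaturePoint(f.type, f.position * np.array([-1.0, 1.0, 1.0]),
                         f.source_atoms)
            for f in feats
        ]
        assert abs(
            pg.match(model, mirrored).deviation - pg.match(model, feats).deviation
        ) < 1e-9

    def test_empty_and_type_deficient(self):
        model = pg.default_rhomb_model()
        assert pg.match(model, []) is None
        assert pg.match_bruteforce(model, []) is None
        only_hyd = [make_point("HYD", [i * 4.0, 0, 0], i) for i in range(3)]
        assert pg.match(model, only_hyd) is None


def random_feature_set(rng, n):
    types = ["HYD", "ARO", "DON_PROJ", "ACC_PROJ"]
    return [
        make_point(types[rng.integers(0, 4)], rng.uniform(-6, 6, 3), i)
        for i in range(n)
    ]


def random_model(rng):
    dists = {}
    for pair in [("HYD_a", "HYD_b"), ("HYD_a", "ARO"), ("HYD_a", "PROJ"),
                 ("HYD_b", "ARO"), ("HYD_b", "PROJ"), ("ARO", "PROJ")]:
        lo = float(rng.uniform(0, 6))
        dists[pair] = (lo, lo + float(rng.uniform(0.5, 4)))
    return pg.PharmacophoreModel(distances=dists, planarity_max=5.0)


class TestOracleEquivalence:
    def test_match_equals_bruteforce_on_random_instances(self):
        """Pruned search and exhaustive oracle agree on hit flag,
        deviation and chosen assignment for >=100 randomized sets."""
        rng = np.random.default_rng(1234)
        checked = 0
        while checked < 120:
            model = random_model(rng)
            feats = random_feature_set(rng, int(rng.integers(4, 13)))
            fast = pg.match(model, feats)
            slow = pg.match_bruteforce(model, feats)
            if fast is None or slow is None:
                assert fast is None and slow is None
                continue
            assert fast.deviation == pytest.approx(slow.deviation, abs=1e-12)
            assert fast.hit == slow.hit
            assert fast.feature_indices == slow.feature_indices
            checked += 1

    def test_single_quad_case(self, square_features):
        feats = square_features(4.5)
        fast = pg.match(pg.default_rhomb_model(), feats)
        slow = pg.match_bruteforce(pg.default_rhomb_model(), feats)
        assert fast.feature_indices == slow.feature_indices
        assert fast.deviation == slow.deviation == 0.0


class TestMonotonicity:
    def test_widening_ranges_never_loses_hits(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            model = random_model(rng)
            feats = random_feature_set(rng, 8)
            res = pg.match(model, feats)
            if res is None:
                continue
            widened = pg.PharmacophoreModel(
                distances={
                    pair: (max(0.0, lo - 1.0), hi + 1.0)
                    for pair, (lo, hi) in model.distances.items()
                },
                planarity_max=model.planarity_max,
            )
            res2 = pg.match(widened, feats)
            assert res2 is not None
            assert res2.deviation <= res.deviation
            if res.hit:
                assert res2.hit


class TestScreenLibrary:
    def test_planted_library_all_actives_hit(self):
        spec = pg.PlantedLibrarySpec(
            n_actives=10, n_decoys=90, side=4.5, sigma=0.1, seed=42
        )
        entries, labels = pg.planted_geometry_library(spec)
        report = pg.screen_library(pg.default_rhomb_model(), entries)
        hit_ids = {r.mol_id for r in report.hits}
        assert {i for i, lab in labels.items() if lab} <= hit_ids
        assert not any(lab for i, lab in labels.items() if i not in hit_ids)

    def test_ranking_deterministic_and_total(self):
        spec = pg.PlantedLibrarySpec(n_actives=5, n_decoys=10, sigma=0.2, seed=9)
        entries, _ = pg.planted_geometry_library(spec)
        a = pg.screen_library(pg.default_rhomb_model(), entries)
        b = pg.screen_library(pg.default_rhomb_model(), entries)
        assert a.ranked_ids == b.ranked_ids
        assert sorted(a.ranked_ids) == sorted(i for i, _f in entries)
        assert [r.rank for r in a.rows] == list(range(len(entries)))

    def test_featureless_molecule_ranked_last(self):
        spec = pg.PlantedLibrarySpec(n_actives=3, n_decoys=0, sigma=0.0, seed=1)
        entries, _ = pg.planted_geometry_library(spec)
        entries.append(("empty", [[]]))
        report = pg.screen_library(pg.default_rhomb_model(), entries)
        assert report.ranked_ids[-1] == "empty"
        assert report.rows[-1].match is None

    def test_report_tsv(self, tmp_path, square_features):
        entries = [("sq", [square_features(4.5)])]
        report = pg.screen_library(pg.default_rhomb_model(), entries)
        path = tmp_path / "hits.tsv"
        report.to_tsv(str(path))
        lines = path.read_text().splitlines()
        assert lines[0].startswith("mol_id\thit")
        assert lines[1].split("\t")[0] == "sq"


class TestEnrichmentFactor:
    def test_perfect_ranking_closed_form(self):
        ranked = [f"a{i}" for i in range(10)] + [f"d{i}" for i in range(90)]
        labels = {i: i.startswith("a") for i in ranked}
        assert pg.enrichment_factor(ranked, labels, 0.1) == pytest.approx(10.0)

    def test_all_active(self):
        ranked = [f"a{i}" for i in range(20)]
        labels = {i: True for i in ranked}
        for f in (0.05, 0.25, 1.0):
            assert pg.enrichment_factor(ranked, labels, f) == pytest.approx(1.0)

    def test_random_ranking_expectation(self):
        """Mean EF over 1000 random shuffles is ~1 (Monte Carlo)."""
        ids = [f"m{i}" for i in range(100)]
        labels = {i: k < 10 for k, i in enumerate(ids)}
        rng = np.random.default_rng(2024)
        efs = []
        for _ in range(1000):
            perm = list(rng.permutation(ids))
            efs.append(pg.enrichment_factor(perm, labels, 0.1))
        assert np.mean(efs) == pytest.approx(1.0, abs=0.2)

    def test_zero_actives_error(self):
        ranked = ["a", "b"]
        with pytest.raises(PhoregenError):
            pg.enrichment_factor(ranked, {"a": False, "b": False}, 0.5)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            pg.enrichment_factor(["a"], {"a": True}, 0.0)
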