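import itertools

import numpy as np
import pandas as pd
import pytest

from seed2seedling import (
    FeatureTable,
    PresenceSet,
    ValidationError,
    assign_origin,
    classify_abundance,
    class_transmission_rates,
    detect,
    mean_relative_abundance,
    origin_abundance_fraction,
    origin_membership_fraction,
    prevalence_matrix,
    transmission_success,
    upset_intersections,
)
from seed2seedling.transmission import ORIGIN_CATEGORIES, abundance_pairing, taxon_group_abundance

from conftest import random_feature_table


def pset(key, *asvs):
    return PresenceSet(key, frozenset(asvs))


def random_sets(rng, n_asvs=12):
    universe = [f"a{i}" for i in range(n_asvs)]
    def draw(key):
        k = rng.integers(0, n_asvs + 1)
        return pset(key, *rng.choice(universe, size=k, replace=False))
    return universe, draw


class TestDetect:
    def test_all_zero_absent(self, toy_table):
        s = detect(toy_table, {"compartment": "seed"})
        assert "b" not in s.asvs and "d" not in s.asvs

    def test_min_reps_rule(self):
        counts = pd.DataFrame([[5, 5], [0, 1], [0, 0]],
                              index=["r1", "r2", "r3"], columns=["x", "y"])
        md = pd.DataFrame({"compartment": ["seed"] * 3}, index=counts.index)
        t = FeatureTable(counts, md)
        s = detect(t, {"compartment": "seed"}, min_reps=2)
        assert "x" not in s.asvs      # (5,0,0): one replicate only
        assert "y" in s.asvs          # (5,1,0): two replicates

    def test_min_count_threshold(self, toy_table):
        # root rows: a=(4,0), b=(1,2), c=(1,1), d=(0,0); min_count=2 keeps a and b
        s = detect(toy_table, {"compartment": "root"}, min_count=2)
        assert s.asvs == frozenset({"a", "b"})

    def test_empty_selection_errors(self, toy_table):
        with pytest.raises(ValidationError):
            detect(toy_table, {"compartment": "stem"})

    def test_brute_force_oracle(self, rng):
        """Per-ASV loop over the rule on random tables."""
        for _ in range(50):
            t = random_feature_table(rng, n_samples=5, n_asvs=8)
            mc = int(rng.integers(1, 6))
            mr = int(rng.integers(1, 4))
            comp = t.metadata["compartment"].iloc[0]
            got = detect(t, {"compartment": comp}, min_count=mc, min_reps=mr).asvs
            sub = t.counts[t.metadata["compartment"] == comp]
            expect = {a for a in sub.columns
                      if sum(1 for v in sub[a] if v >= mc) >= mr}
            assert got == frozenset(expect)


class TestPrevalenceUpset:
    def test_matrix_shape_and_shared_row(self):
        m = prevalence_matrix([pset("c1", "A", "B"), pset("c2", "B", "C")])
        assert m.shape == (3, 2)
        assert m.loc["B"].tolist() == [1, 1]

    def test_disjoint_rows(self):
        m = prevalence_matrix([pset("c1", "A"), pset("c2", "B")])
        assert (m.sum(axis=1) <= 1).all()

    def test_column_sums_equal_set_sizes(self, rng):
        for _ in range(20):
            _, draw = random_sets(rng)
            sets = [draw(f"c{i}") for i in range(3)]
            if not any(s.asvs for s in sets):
                continue
            m = prevalence_matrix(sets)
            for s in sets:
                assert m[s.key].sum() == len(s)

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            prevalence_matrix([pset("c", "A"), pset("c", "B")])

    def test_upset_enumeration(self):
        m = prevalence_matrix([pset("c1", "A", "B"), pset("c2", "B", "C")])
        u = upset_intersections(m)
        assert u[("c1",)] == 1 and u[("c2",)] == 1 and u[("c1", "c2")] == 1

    def test_identical_sets_full_combo(self):
        m = prevalence_matrix([pset("c1", "A", "B"), pset("c2", "A", "B")])
        u = upset_intersections(m)
        assert u.to_dict() == {("c1", "c2"): 2}

    def test_counts_sum_to_union(self, rng):
        """Conservation: exclusive counts partition the union."""
        for _ in range(30):
            _, draw = random_sets(rng)
            sets = [draw(f"c{i}") for i in range(int(rng.integers(2, 5)))]
            union = set().union(*(s.asvs for s in sets))
            if not union:
                continue
            u = upset_intersections(prevalence_matrix(sets))
            assert u.sum() == len(union)
            # brute-force oracle: classify each ASV by its exact membership
            expect = {}
            for a in union:
                combo = tuple(s.key for s in sets if a in s.asvs)
                expect[combo] = expect.get(combo, 0) + 1
            assert u.to_dict() == expect


class TestAssignOrigin:
    def test_spec_example(self):
        om = assign_origin(pset("p", "a", "b", "c", "d"), pset("sd", "a", "b"), pset("sl", "b", "c"))
        assert om.categories == {"a": "seed_only", "b": "both", "c": "soil_only", "d": "unknown"}

    def test_empty_sources_all_unknown(self):
        om = assign_origin(pset("p", "x", "y"), pset("sd"), pset("sl"))
        assert set(om.categories.values()) == {"unknown"}

    def test_partition_conservation(self, rng):
        for _ in range(50):
            _, draw = random_sets(rng)
            plant, seed, soil = draw("p"), draw("sd"), draw("sl")
            om = assign_origin(plant, seed, soil)
            sizes = [len(om.members(c)) for c in ORIGIN_CATEGORIES]
            assert sum(sizes) == len(plant)
            assert frozenset().union(*(om.members(c) for c in ORIGIN_CATEGORIES)) == plant.asvs
            # brute-force per-ASV oracle
            for a in plant.asvs:
                want = ("both" if a in seed.asvs and a in soil.asvs
                        else "seed_only" if a in seed.asvs
                        else "soil_only" if a in soil.asvs else "unknown")
                assert om.categories[a] == want

    def test_relabeling_invariance(self, rng):
        _, draw = random_sets(rng)
        plant, seed, soil = draw("p"), draw("sd"), draw("sl")
        ren = {f"a{i}": f"z{i}" for i in range(12)}
        relab = lambda s: pset(s.key, *(ren[a] for a in s.asvs))
        om1 = assign_origin(plant, seed, soil)
        om2 = assign_origin(relab(plant), relab(seed), relab(soil))
        assert {ren[a]: c for a, c in om1.categories.items()} == om2.categories


class TestMembershipFractions:
    def test_quarter_split(self):
        om = assign_origin(pset("p", "a", "b", "c", "d"), pset("sd", "a", "b"), pset("sl", "b", "c"))
        f = origin_membership_fraction(om)
        assert all(f[c] == pytest.approx(0.25) for c in ORIGIN_CATEGORIES)
        assert f["soil_detected"] == pytest.approx(f["soil_only"] + f["both"])
        assert f["seed_detected"] == pytest.approx(f["seed_only"] + f["both"])

    def test_all_unknown(self):
        om = assign_origin(pset("p", "x"), pset("sd"), pset("sl"))
        assert origin_membership_fraction(om)["unknown"] == 1.0

    def test_empty_seedling_errors(self):
        om = assign_origin(pset("p"), pset("sd"), pset("sl"))
        with pytest.raises(ValidationError):
            origin_membership_fraction(om)


class TestMeanRelativeAbundance:
    def _t(self, rows):
        counts = pd.DataFrame(rows, columns=["x", "y"])
        counts.index = [f"s{i}" for i in range(len(counts))]
        md = pd.DataFrame({"compartment": ["root"] * len(counts)}, index=counts.index)
        return FeatureTable(counts, md)

    def test_constant_share(self):
        t = self._t([[10, 90], [10, 90], [10, 90]])
        assert mean_relative_abundance(t, {"compartment": "root"})["x"] == pytest.approx(0.10)

    def test_zero_inclusive_mean(self):
        t = self._t([[30, 70], [0, 100]])
        assert mean_relative_abundance(t, {"compartment": "root"})["x"] == pytest.approx(0.15)

    def test_sums_to_one(self, rng):
        t = random_feature_table(rng, n_samples=4, n_asvs=6)
        t.counts.iloc[0, :] += 1  # avoid all-zero sample
        comp = t.metadata["compartment"].iloc[0]
        rel = mean_relative_abundance(t, {"compartment": comp})
        assert rel.sum() == pytest.approx(1.0, abs=1e-9)


class TestAbundanceFractions:
    def test_dominant_soil_asv(self):
        om = assign_origin(pset("p", "big", "tiny"), pset("sd"), pset("sl", "big"))
        rel = pd.Series({"big": 0.98, "tiny": 0.02})
        f = origin_abundance_fraction(om, rel)
        assert f["soil_only"] == pytest.approx(0.98)

    def test_uniform_equals_membership(self):
        om = assign_origin(pset("p", "a", "b", "c", "d"), pset("sd", "a"), pset("sl", "b"))
        rel = pd.Series(0.25, index=["a", "b", "c", "d"])
        assert origin_abundance_fraction(om, rel) == pytest.approx(origin_membership_fraction(om))

    def test_fractions_sum_to_one(self, rng):
        for _ in range(20):
            _, draw = random_sets(rng)
            plant = draw("p")
            if not plant.asvs:
                continue
            om = assign_origin(plant, draw("sd"), draw("sl"))
            w = rng.random(len(plant)) + 0.01
            rel = pd.Series(w / w.sum(), index=sorted(plant.asvs))
            f = origin_abundance_fraction(om, rel)
            assert sum(f[c] for c in ORIGIN_CATEGORIES) == pytest.approx(1.0, abs=1e-9)


class TestTransmissionSuccess:
    def test_single_replicate(self):
        src = pset("src", *[f"a{i}" for i in range(10)])
        res = transmission_success(src, [pset("p", "a0", "a1", "a2", "zzz")])
        assert res.percentage == pytest.approx(30.0)
        assert res.mean == pytest.approx(30.0) and res.se == 0.0

    def test_disjoint_zero(self):
        res = transmission_success(pset("src", "a"), [pset("p", "b")])
        assert res.percentage == 0.0

    def test_mean_se_hand_value(self):
        src = pset("src", *[f"a{i}" for i in range(10)])
        reps = [
            pset("r1", "a0", "a1"),                  # 20%
            pset("r2", "a0", "a1", "a2"),            # 30%
            pset("r3", "a0", "a1", "a2", "a3"),      # 40%
        ]
        res = transmission_success(src, reps)
        assert res.mean == pytest.approx(30.0)
        assert res.se == pytest.approx(10.0 / np.sqrt(3))
        assert res.percentage == pytest.approx(40.0)  # pooled union = 4/10

    def test_empty_source_errors(self):
        with pytest.raises(ValidationError):
            transmission_success(pset("src"), [pset("p", "a")])

    def test_monotone_in_seedling(self, rng):
        """Enlarging every replicate set never lowers any percentage."""
        _, draw = random_sets(rng)
        for _ in range(25):
            src = draw("src")
            if not src.asvs:
                continue
            reps = [draw(f"r{i}") for i in range(3)]
            bigger = [pset(r.key, *(r.asvs | {"a0", "a1"})) for r in reps]
            r1 = transmission_success(src, reps)
            r2 = transmission_success(src, bigger)
            assert r2.percentage >= r1.percentage and r2.mean >= r1.mean

    def test_brute_force_oracle(self, rng):
        _, draw = random_sets(rng)
        for _ in range(25):
            src = draw("src")
            if not src.asvs:
                continue
            reps = [draw(f"r{i}") for i in range(int(rng.integers(1, 4)))]
            res = transmission_success(src, reps)
            per = [100 * len([a for a in src.asvs if a in r.asvs]) / len(src) for r in reps]
            assert res.per_replicate == pytest.approx(per)
            assert res.mean == pytest.approx(np.mean(per))


class TestClassification:
    def test_thresholds(self):
        rel = pd.Series({"r": 5e-5, "i": 5e-3, "a": 0.02})
        c = classify_abundance(rel)
        assert c.to_dict() == {"r": "rare", "i": "intermediate", "a": "abundant"}

    def test_boundaries_intermediate(self):
        c = classify_abundance(pd.Series({"lo": 1e-4, "hi": 1e-2}))
        assert set(c) == {"intermediate"}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_abundance(pd.Series({"x": 1.5}))


class TestClassRates:
    def test_all_abundant_transmitted(self):
        src = pset("s", "a", "b")
        cls = pd.Series({"a": "abundant", "b": "abundant"})
        out = class_transmission_rates(src, cls, pset("p", "a", "b", "x"))
        assert out["abundant"] == pytest.approx(100.0)

    def test_quarter_rare(self):
        src = pset("s", "a", "b", "c", "d")
        cls = pd.Series("rare", index=["a", "b", "c", "d"])
        out = class_transmission_rates(src, cls, pset("p", "a"))
        assert out["rare"] == pytest.approx(25.0)

    def test_absent_class_is_none(self):
        src = pset("s", "a")
        out = class_transmission_rates(src, pd.Series({"a": "rare"}), pset("p"))
        assert out["abundant"] is None and out["intermediate"] is None
        assert out["rare"] == 0.0

    def test_unclassified_source_errors(self):
        with pytest.raises(ValidationError, match="unclassified"):
            class_transmission_rates(pset("s", "a", "b"), pd.Series({"a": "rare"}), pset("p"))

    def test_brute_force_oracle(self, rng):
        _, draw = random_sets(rng)
        classes = ["rare", "intermediate", "abundant"]
        for _ in range(30):
            src, plant = draw("s"), draw("p")
            if not src.asvs:
                continue
            cls = pd.Series({a: classes[rng.integers(0, 3)] for a in src.asvs})
            out = class_transmission_rates(src, cls, plant)
            for c in classes:
                members = [a for a in src.asvs if cls[a] == c]
                if not members:
                    assert out[c] is None
                else:
                    hits = sum(a in plant.asvs for a in members)
                    assert out[c] == pytest.approx(100.0 * hits / len(members))


class TestAbundancePairing:
    def test_rule_evaluation(self):
        df = abundance_pairing(pd.Series({"a": 0.005}), pd.Series({"a": 0.03}))
        assert bool(df.loc["a", "above_line"]) and bool(df.loc["a", "became_abundant"])
        assert df.loc["a", "source_class"] == "intermediate"

    def test_equal_abundance_not_above(self):
        df = abundance_pairing(pd.Series({"a": 0.01}), pd.Series({"a": 0.01}))
        assert not bool(df.loc["a", "above_line"])

    def test_non_transmitted_excluded(self):
        df = abundance_pairing(pd.Series({"a": 0.1, "b": 0.1}), pd.Series({"a": 0.2, "b": 0.0}))
        assert list(df.index) == ["a"]

    def test_empty_pairing(self):
        df = abundance_pairing(pd.Series(dtype=float), pd.Series(dtype=float))
        assert df.empty


class TestTaxonGroupAbundance:
    def _t(self, counts_rows, genera):
        counts = pd.DataFrame(counts_rows, columns=[f"a{j}" for j in range(len(genera))])
        counts.index = [f"s{i}" for i in range(len(counts))]
        md = pd.DataFrame({"compartment": ["soil"] * len(counts)}, index=counts.index)
        tax = pd.DataFrame({"genus": genera}, index=counts.columns)
        return FeatureTable(counts, md, taxonomy=tax)

    def test_no_match_zero(self):
        t = self._t([[50, 50]], ["Bacillus", "Pseudomonas"])
        mean, se = taxon_group_abundance(t, {"compartment": "soil"}, ["Nitrospira"])
        assert mean == 0.0

    def test_full_match(self):
        t = self._t([[100, 0]], ["Nitrospira", "Bacillus"])
        mean, _ = taxon_group_abundance(t, {"compartment": "soil"}, ["Nitrospira"])
        assert mean == pytest.approx(100.0)

    def test_mean_se_arithmetic(self):
        t = self._t([[4, 96], [6, 94]], ["Nitrosospira", "Bacillus"])
        mean, se = taxon_group_abundance(t, {"compartment": "soil"}, ["Nitrosospira", "Nitrosovibrio"])
        assert mean == pytest.approx(5.0)
        assert se == pytest.approx(1.0)

    def test_missing_taxonomy_errors(self, toy_table):
        with pytest.raises(ValidationError, match="taxonomy"):
            taxon_group_abundance(toy_table, {"compartment": "soil"}, ["Nitrospira"])
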