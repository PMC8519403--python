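import numpy as np
import pandas as pd
import pytest

from famchar.expression_screen import (
    ExpressionMatrix,
    QpcrMeasurement,
    aggregate_ct,
    cluster_profiles,
    effective_expression,
    fold_change_screen,
    relative_expression,
    tissue_specificity,
)


def matrix(data, columns):
    return ExpressionMatrix(pd.DataFrame(data, columns=columns).set_index("gene"))


class TestEffectiveExpression:
    def test_strict_boundary(self):
        m = matrix([("g1", 1.0), ("g2", 2.5), ("g3", 0.0)], ["gene", "leaf"])
        flags = effective_expression(m)
        assert not flags.at["g1", "leaf"]
        assert flags.at["g2", "leaf"]
        assert not flags.at["g3", "leaf"]

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            matrix([("g1", -1.0)], ["gene", "leaf"])

    def test_planted_62_effective(self, default_bundle):
        m = ExpressionMatrix(default_bundle.treatment_fpkm)
        assert int(effective_expression(m).any(axis=1).sum()) == 62

    def test_bruteforce_oracle(self, default_bundle):
        m = ExpressionMatrix(default_bundle.tissue_fpkm)
        flags = effective_expression(m)
        for gene in m.genes:
            for cond in m.conditions:
                assert flags.at[gene, cond] == (m.values.at[gene, cond] > 1.0)


class TestTissueSpecificity:
    def test_categories(self):
        m = matrix(
            [
                ("all", 5.0, 6.0, 7.0),
                ("root_only", 0.2, 0.1, 9.0),
                ("nowhere", 0.2, 0.1, 0.9),
                ("two", 3.0, 0.1, 9.0),
            ],
            ["gene", "leaf", "stem", "root"],
        )
        cats = tissue_specificity(m)
        assert cats["all"] == "all_tissues"
        assert cats["root_only"] == "single:root"
        assert cats["nowhere"] == "none"
        assert cats["two"] == "2_of_3"

    def test_needs_two_tissues(self):
        m = matrix([("g", 5.0)], ["gene", "leaf"])
        with pytest.raises(ValueError):
            tissue_specificity(m)

    def test_planted_tallies(self, default_bundle):
        m = ExpressionMatrix(default_bundle.tissue_fpkm)
        cats = tissue_specificity(m)
        truth = default_bundle.truth["tissue"].set_index("gene_id")
        assert int((cats == "all_tissues").sum()) == 53
        assert int(cats.str.startswith("single:").sum()) == 9
        assert int((cats == "none").sum()) == 2
        for gene, row in truth.iterrows():
            if row.role == "all":
                assert cats[gene] == "all_tissues"
            elif row.role == "none":
                assert cats[gene] == "none"
            elif row.role.startswith("single:"):
                assert cats[gene] == row.role


class TestFoldChangeScreen:
    def test_up_arithmetic(self):
        m = matrix([("g", 10.0, 40.0)], ["gene", "ctrl", "cold"])
        res = fold_change_screen(m, "ctrl", pseudo=1e-9)
        assert len(res) == 1
        r = res[0]
        assert r.direction == "up"
        assert r.max_abs_fold_change == pytest.approx(4.0)
        assert r.in_band

    def test_down_arithmetic(self):
        m = matrix([("g", 10.0, 2.0)], ["gene", "ctrl", "cold"])
        r = fold_change_screen(m, "ctrl", pseudo=1e-9)[0]
        assert r.direction == "down"
        assert r.max_abs_fold_change == pytest.approx(5.0)

    def test_beyond_band_flagged_not_excluded(self):
        m = matrix([("g", 10.0, 80.0)], ["gene", "ctrl", "cold"])
        r = fold_change_screen(m, "ctrl", pseudo=1e-9)[0]
        assert r.direction == "up" and not r.in_band

    def test_non_effective_gene_excluded(self):
        m = matrix([("g", 0.01, 0.09)], ["gene", "ctrl", "cold"])
        assert fold_change_screen(m, "ctrl", pseudo=1e-9) == []

    def test_missing_control_rejected(self):
        m = matrix([("g", 1.0, 2.0)], ["gene", "a", "b"])
        with pytest.raises(ValueError, match="absent"):
            fold_change_screen(m, "zz")

    def test_planted_screen_recovered(self, default_bundle):
        m = ExpressionMatrix(default_bundle.treatment_fpkm)
        res = fold_change_screen(m, "control_25C")
        up = sorted(r.gene for r in res if r.direction == "up")
        down = sorted(r.gene for r in res if r.direction == "down")
        truth = default_bundle.truth["screen"]
        assert up == sorted(truth.query("role == 'up'").gene_id)
        assert down == sorted(truth.query("role == 'down'").gene_id)
        assert len(up) == 6 and len(down) == 4

    def test_gene_order_invariance_and_disjoint(self, default_bundle):
        m = ExpressionMatrix(default_bundle.treatment_fpkm)
        res1 = fold_change_screen(m, "control_25C")
        m2 = ExpressionMatrix(default_bundle.treatment_fpkm.iloc[::-1])
        res2 = fold_change_screen(m2, "control_25C")
        assert sorted(r.gene for r in res1) == sorted(r.gene for r in res2)
        up = {r.gene for r in res1 if r.direction == "up"}
        down = {r.gene for r in res1 if r.direction == "down"}
        assert not up & down


class TestClusterProfiles:
    def _archetype_matrix(self, seed, sigma=0.05, per_group=5):
        rng = np.random.default_rng(seed)
        archetypes = np.array(
            [
                [1.0, 1.0, 8.0, 8.0, 1.0],
                [8.0, 8.0, 1.0, 1.0, 1.0],
                [1.0, 8.0, 1.0, 8.0, 1.0],
                [5.0, 1.0, 1.0, 1.0, 8.0],
            ]
        )
        rows, truth = [], []
        for gi, arch in enumerate(archetypes):
            for j in range(per_group):
                rows.append(arch * np.exp(sigma * rng.standard_normal(5)))
                truth.append(gi)
        idx = [f"g{i}" for i in range(len(rows))]
        df = pd.DataFrame(rows, index=idx, columns=list("abcde"))
        return ExpressionMatrix(df), dict(zip(idx, truth))

    def test_identical_profiles_share_group(self):
        df = pd.DataFrame(
            [[1, 5, 9], [1, 5, 9], [9, 5, 1], [2, 9, 1]],
            index=["g1", "g2", "g3", "g4"],
            columns=["a", "b", "c"],
            dtype=float,
        )
        groups = cluster_profiles(ExpressionMatrix(df), k=3)
        assert groups["g1"] == groups["g2"]

    def test_planted_archetypes_recovered(self):
        recovered = 0
        for seed in range(50):
            m, truth = self._archetype_matrix(seed)
            groups = cluster_profiles(m, k=4)
            # perfect recovery iff the partition matches exactly
            mapping = {}
            ok = True
            for gene, g in groups.items():
                t = truth[gene]
                if g in mapping and mapping[g] != t:
                    ok = False
                    break
                mapping[g] = t
            if ok and len(set(mapping.values())) == 4:
                recovered += 1
        assert recovered >= 48  # >= 95% of 50 seeded replicates

    def test_k_equals_n_singletons(self):
        df = pd.DataFrame(
            [[1, 5, 9], [9, 5, 1], [2, 9, 1], [4, 1, 7]],
            index=["g1", "g2", "g3", "g4"],
            columns=["a", "b", "c"],
            dtype=float,
        )
        groups = cluster_profiles(ExpressionMatrix(df), k=4)
        assert len(set(groups.values())) == 4

    def test_constant_gene_fallback_logged(self, caplog):
        df = pd.DataFrame(
            [[1, 5, 9], [9, 5, 1], [2, 9, 1], [3, 3, 3]],
            index=["g1", "g2", "g3", "flat"],
            columns=["a", "b", "c"],
            dtype=float,
        )
        with caplog.at_level("WARNING"):
            groups = cluster_profiles(ExpressionMatrix(df), k=2)
        assert "flat" in groups
        assert any("Euclidean fallback" in r.message for r in caplog.records)

    def test_row_permutation_invariance_up_to_relabeling(self):
        m, _ = self._archetype_matrix(7)
        g1 = cluster_profiles(m, k=4)
        m2 = ExpressionMatrix(m.values.iloc[::-1])
        g2 = cluster_profiles(m2, k=4)
        part1 = {}
        part2 = {}
        for gene in m.genes:
            part1.setdefault(g1[gene], set()).add(gene)
            part2.setdefault(g2[gene], set()).add(gene)
        assert sorted(map(sorted, part1.values())) == sorted(
            map(sorted, part2.values())
        )


class TestQpcr:
    def test_identity(self):
        s = QpcrMeasurement("g", "cold", 22.0, 18.0)
        c = QpcrMeasurement("g", "ctrl", 24.0, 20.0)
        assert relative_expression(s, c) == pytest.approx(1.0)

    def test_one_cycle_doubles(self):
        s = QpcrMeasurement("g", "cold", 23.0, 20.0)
        c = QpcrMeasurement("g", "ctrl", 24.0, 20.0)
        assert relative_expression(s, c) == pytest.approx(2.0)

    def test_three_point_three_cycles_tenth(self):
        s = QpcrMeasurement("g", "cold", 24.0 + 3.3219, 20.0)
        c = QpcrMeasurement("g", "ctrl", 24.0, 20.0)
        assert relative_expression(s, c) == pytest.approx(0.1, abs=1e-4)

    def test_self_is_one(self):
        s = QpcrMeasurement("g", "cold", 27.3, 19.1)
        assert relative_expression(s, s) == 1.0

    def test_gene_mismatch_rejected(self):
        s = QpcrMeasurement("g1", "cold", 22.0, 18.0)
        c = QpcrMeasurement("g2", "ctrl", 24.0, 20.0)
        with pytest.raises(ValueError, match="mismatch"):
            relative_expression(s, c)

    def test_ct_range_enforced(self):
        with pytest.raises(ValueError):
            QpcrMeasurement("g", "cold", 55.0, 18.0)

    def test_replicate_aggregation(self):
        mean, sd = aggregate_ct([20.0, 21.0, 22.0])
        assert mean == pytest.approx(21.0)
        assert sd == pytest.approx(1.0)
        with pytest.raises(ValueError):
            aggregate_ct([20.0, 21.0])
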