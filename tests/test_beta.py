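import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from urostab.beta import (
    DistanceMatrix,
    bray_curtis,
    distance_matrix,
    permanova,
    single_term_permanova,
)
from urostab.errors import DesignError, UndefinedStatisticError
from urostab.qc import RelAbundanceTable


def rel_table(matrix, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    matrix = matrix / matrix.sum(axis=1, keepdims=True)
    ids = ids or [f"s{i}" for i in range(matrix.shape[0])]
    return RelAbundanceTable(pd.DataFrame(matrix, index=ids))


class TestBrayCurtis:
    def test_identity_disjoint_and_hand_value(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 0], [0, 2]) == 1.0
        assert bray_curtis([2, 2, 0], [0, 2, 2]) == pytest.approx(0.5)

    def test_undefined_for_two_zero_vectors(self):
        with pytest.raises(UndefinedStatisticError):
            bray_curtis([0, 0], [0, 0])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(15), rng.random(15)
        expected = np.abs(x - y).sum() / (x + y).sum()
        assert bray_curtis(x, y) == pytest.approx(expected)
        assert 0.0 <= bray_curtis(x, y) <= 1.0


class TestDistanceMatrix:
    def test_identical_samples(self):
        dm = distance_matrix(rel_table([[1, 1], [1, 1]]))
        assert np.allclose(dm.values, 0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        rel = rel_table(rng.random((6, 12)) + 1e-6)
        dm = distance_matrix(rel)
        arr = rel.data.to_numpy()
        for i, j in itertools.combinations(range(6), 2):
            assert dm.values[i, j] == pytest.approx(bray_curtis(arr[i], arr[j]))

    def test_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 0.4], [0.5, 0.0]]))


def toy_two_group(jitter=0.01, seed=0, n_per_group=3):
    rng = np.random.default_rng(seed)
    base_a = np.array([10.0, 1.0, 1.0, 1.0])
    base_b = np.array([1.0, 1.0, 1.0, 10.0])
    rows = [base_a + rng.random(4) * jitter for _ in range(n_per_group)]
    rows += [base_b + rng.random(4) * jitter for _ in range(n_per_group)]
    rel = rel_table(rows)
    design = pd.DataFrame({"group": ["a"] * n_per_group + ["b"] * n_per_group},
                          index=rel.sample_ids)
    return distance_matrix(rel), design


def classical_f_oracle(dm, labels):
    """Distance-based one-way pseudo-F from within/total squared distances."""
    d2 = dm.values ** 2
    n = dm.n
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    labels = np.asarray(labels)
    for level in np.unique(labels):
        idx = np.flatnonzero(labels == level)
        ss_within += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(np.unique(labels))
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_separated_groups_r2_one_and_min_p(self):
        dm, design = toy_two_group(jitter=1e-6)
        out = permanova(dm, design, ["group"], n_permutations="all")
        row = out[out.term == "group"].iloc[0]
        assert row.R2 == pytest.approx(1.0, abs=1e-4)
        # 72 of the 720 label permutations preserve the two-group partition
        assert row.p_value == pytest.approx(72 / 720)

    def test_exhaustive_matches_independent_enumeration_oracle(self):
        dm, design = toy_two_group(jitter=2.0, seed=7)
        out = permanova(dm, design, ["group"], n_permutations="all")
        row = out[out.term == "group"].iloc[0]
        labels = design["group"].to_numpy()
        f_obs = classical_f_oracle(dm, labels)
        assert row.pseudo_F == pytest.approx(f_obs)
        count = total = 0
        tol = 1e-8 * max(1.0, abs(f_obs))
        for perm in itertools.permutations(range(6)):
            f = classical_f_oracle(dm, labels[list(perm)])
            count += f >= f_obs - tol
            total += 1
        assert row.p_value == pytest.approx(count / total)

    def test_r2_partition_sums_to_one(self):
        dm, design = toy_two_group(jitter=2.0, seed=3)
        out = permanova(dm, design, ["group"], n_permutations=49, seed=0)
        r2 = out.set_index("term").R2
        assert r2["group"] + r2["Residual"] == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= r2["group"] <= 1.0

    def test_gower_identity(self):
        rng = np.random.default_rng(9)
        rel = rel_table(rng.random((7, 10)) + 1e-6)
        dm = distance_matrix(rel)
        out = permanova(
            dm,
            pd.DataFrame({"g": list("aabbccd")}, index=rel.sample_ids),
            ["g"],
            n_permutations=9,
            seed=0,
        )
        ss_total = out[out.term == "Total"].sum_sq.iloc[0]
        n = dm.n
        expected = (dm.values ** 2)[np.triu_indices(n, 1)].sum() / n
        assert ss_total == pytest.approx(expected, abs=1e-9)

    def test_euclidean_two_groups_matches_anova_f(self):
        # for Euclidean distances on 1-D coordinates the pseudo-F equals the
        # classical one-way ANOVA F statistic
        rng = np.random.default_rng(11)
        coords = np.concatenate([rng.normal(0, 1, 4), rng.normal(2, 1, 4)])
        n = len(coords)
        dvals = np.abs(coords[:, None] - coords[None, :])
        dm = DistanceMatrix(tuple(f"s{i}" for i in range(n)), dvals, metric="euclidean")
        design = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4}, index=dm.sample_ids)
        out = permanova(dm, design, ["g"], n_permutations=9, seed=0)
        f_anova = st.f_oneway(coords[:4], coords[4:]).statistic
        assert out[out.term == "g"].pseudo_F.iloc[0] == pytest.approx(f_anova)

    def test_invariant_under_sample_reordering(self):
        dm, design = toy_two_group(jitter=2.0, seed=5)
        out1 = permanova(dm, design, ["group"], n_permutations="all")
        order = [3, 0, 5, 1, 4, 2]
        ids = [dm.sample_ids[i] for i in order]
        dm2 = dm.reorder(ids)
        design2 = design.loc[ids]
        out2 = permanova(dm2, design2, ["group"], n_permutations="all")
        r1 = out1[out1.term == "group"].iloc[0]
        r2 = out2[out2.term == "group"].iloc[0]
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F)
        assert r1.R2 == pytest.approx(r2.R2)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_skbio_pseudo_f(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(21)
        rel = rel_table(rng.random((10, 20)) + 1e-6)
        dm = distance_matrix(rel)
        labels = list("aaabbbccdd")
        design = pd.DataFrame({"g": labels}, index=rel.sample_ids)
        ours = permanova(dm, design, ["g"], n_permutations=9, seed=0)
        theirs = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(dm.values, ids=list(dm.sample_ids)),
            grouping=labels,
            permutations=9,
        )
        assert ours[ours.term == "g"].pseudo_F.iloc[0] == pytest.approx(
            theirs["test statistic"]
        )

    def test_confounded_term_raises(self):
        dm, design = toy_two_group()
        design["copy"] = design["group"]
        with pytest.raises(DesignError, match="confounded"):
            permanova(dm, design, ["group", "copy"], n_permutations=9, seed=0)

    def test_constant_term_raises(self):
        dm, design = toy_two_group()
        design["const"] = 1.0
        with pytest.raises(DesignError, match="constant"):
            permanova(dm, design, ["const"], n_permutations=9, seed=0)

    def test_strata_restricts_permutations(self):
        dm, design = toy_two_group(jitter=2.0, seed=13)
        design["pair"] = ["p1", "p2", "p3"] * 2
        out = permanova(dm, design, ["group"], n_permutations=99, seed=1, strata="pair")
        assert out.attrs["strata"] == "pair"
        assert 0.0 < out[out.term == "group"].p_value.iloc[0] <= 1.0

    def test_single_term_wrapper_matches_individual_fits(self):
        dm, design = toy_two_group(jitter=2.0, seed=17)
        design["x"] = np.arange(6, dtype=float)
        combined = single_term_permanova(dm, design, ["group", "x"], n_permutations=19, seed=4)
        solo = permanova(dm, design, ["x"], n_permutations=19, seed=5)
        assert combined[combined.term == "x"].R2.iloc[0] == pytest.approx(
            solo[solo.term == "x"].R2.iloc[0]
        )
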