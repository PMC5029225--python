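"""Rank-sum test, BH FDR and two-group module comparison."""

import itertools

import numpy as np
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

from modquant import (
    GroupDesign,
    bh_fdr,
    compare_groups,
    comparisons_to_frame,
    generate_abundance,
    generate_module_db,
    mann_whitney_u,
    quantify_all,
)
from modquant.stats import DesignError


def _midranks(values):
    """Pure-Python midranks, independent of scipy."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    return ranks


def enumeration_p(x, y):
    """Exact two-sided p by full enumeration of all C(n+m, n) labelings."""
    combined = list(x) + list(y)
    n = len(x)
    ranks = _midranks(combined)

    def u_of(indices):
        return sum(ranks[i] for i in indices) - n * (n + 1) / 2

    u_obs = u_of(range(n))
    us = [u_of(c) for c in itertools.combinations(range(len(combined)), n)]
    cdf = sum(u <= u_obs for u in us) / len(us)
    sf = sum(u >= u_obs for u in us) / len(us)
    return u_obs, min(1.0, 2.0 * min(cdf, sf))


class TestMannWhitney:
    def test_perfect_separation_small_n(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-15)  # 2 / C(6,3)

    def test_mirror_symmetry(self):
        u_fwd, p_fwd = mann_whitney_u([5, 6], [1, 2])
        u_rev, p_rev = mann_whitney_u([1, 2], [5, 6])
        assert u_fwd == 4.0  # n_a * n_b
        assert u_rev == 0.0
        assert p_fwd == p_rev

    def test_full_ties_give_p_one(self):
        x = [1.0, 2.0, 3.0]
        u, p = mann_whitney_u(x, list(x))
        assert u == pytest.approx(4.5)
        assert p == 1.0

    def test_all_identical_values(self):
        assert mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])[1] == 1.0

    def test_empty_group_is_hard_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])

    def test_exact_agrees_with_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n_a = int(rng.integers(2, 7))
            n_b = int(rng.integers(2, min(9, 12 - n_a)))
            pooled = rng.permutation(rng.normal(size=n_a + n_b))
            x, y = pooled[:n_a], pooled[n_a:]
            u_exp, p_exp = enumeration_p(x, y)
            u_got, p_got = mann_whitney_u(x, y)
            assert u_got == pytest.approx(u_exp, abs=1e-9)
            assert p_got == pytest.approx(p_exp, abs=1e-12)

    def test_exact_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(2, 10)))
            y = rng.normal(size=int(rng.integers(2, 10)))
            res = scipy.stats.mannwhitneyu(x, y, method="exact", alternative="two-sided")
            u_got, p_got = mann_whitney_u(x, y)
            assert u_got == pytest.approx(float(res.statistic))
            assert p_got == pytest.approx(float(res.pvalue), abs=1e-12)

    def test_approximate_path_close_to_scipy_at_large_n(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = rng.normal(0.5, size=25)
        _, p_got = mann_whitney_u(x, y)
        res = scipy.stats.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided")
        assert p_got == pytest.approx(float(res.pvalue), rel=1e-6)

    def test_u_statistic_bounds_and_swap_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=7)
            u_x, p_x = mann_whitney_u(x, y)
            u_y, p_y = mann_whitney_u(y, x)
            assert 0 <= u_x <= 35
            assert u_x + u_y == pytest.approx(35)
            assert p_x == pytest.approx(p_y, abs=1e-12)


class TestBenjaminiHochberg:
    def test_hand_checked_step_up(self):
        q = bh_fdr([0.005, 0.011, 0.02, 0.04])
        assert q == pytest.approx([0.02, 0.022, 0.02 + 2 / 300, 0.04])

    def test_singleton_identity(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])

    def test_constant_vector_unchanged(self):
        assert bh_fdr([0.3] * 5) == pytest.approx([0.3] * 5)

    def test_out_of_range_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 60)))
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_fdr(p) == pytest.approx(expected, abs=1e-12)

    def test_permutation_equivariance_and_monotonicity(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(1e-6, 1, size=25)
        q = bh_fdr(p)
        perm = rng.permutation(25)
        assert bh_fdr(p[perm]) == pytest.approx(q[perm])
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


def _planted_dataset(seed, n_modules=10, effect=4.0, n_per_group=8):
    db = generate_module_db(n_modules, steps_range=(3, 3), alts_range=(1, 1),
                            p_complex=0.0, p_shared=0.0, seed=seed)
    design = GroupDesign(
        assignment={
            **{f"A{i}": "A" for i in range(n_per_group)},
            **{f"B{i}": "B" for i in range(n_per_group)},
        },
        group_a="A",
        group_b="B",
    )
    planted = db.module_ids[seed % n_modules]
    matrix, _ = generate_abundance(db, design, {planted: effect}, seed=seed + 1)
    return db, matrix, design, planted


class TestCompareGroups:
    def test_planted_module_recovered_top_ranked(self):
        hits = 0
        for seed in range(20):
            db, matrix, design, planted = _planted_dataset(seed)
            profile = quantify_all(db, matrix)
            frame = comparisons_to_frame(compare_groups(profile, design))
            hits += frame.iloc[0]["module"] == planted
        assert hits >= 18

    def test_within_group_shuffle_invariance(self, worked_example, worked_profile):
        _, _, design = worked_example
        comps = compare_groups(worked_profile, design)
        shuffled = GroupDesign(
            assignment={s: design.assignment[s] for s in ["H3", "H1", "H4", "H2", "D2", "D4", "D1", "D3"]},
            group_a=design.group_a,
            group_b=design.group_b,
        )
        assert compare_groups(worked_profile, shuffled) == comps

    def test_group_swap_flips_direction_keeps_p_q(self, worked_example, worked_profile):
        _, _, design = worked_example
        fwd = compare_groups(worked_profile, design)
        rev = compare_groups(
            worked_profile,
            GroupDesign(design.assignment, design.group_b, design.group_a),
        )
        for f, r in zip(fwd, rev):
            assert r.u_stat == pytest.approx(f.n_a * f.n_b - f.u_stat)
            assert r.p == pytest.approx(f.p)
            assert r.q == pytest.approx(f.q)
            if f.direction == "up_in_a":
                assert r.direction == "up_in_b"

    def test_prevalence_filter_shrinks_bh_family(self, worked_example, worked_profile):
        _, _, design = worked_example
        comps = compare_groups(worked_profile, design, min_prevalence=1.0)
        by_id = {c.module: c for c in comps}
        assert not by_id["MF0005"].tested  # present in only half the samples
        assert np.isnan(by_id["MF0005"].q)
        tested = [c for c in comps if c.tested]
        assert len(tested) == 5
        # with m=5 the four planted p-values adjust to 5*p/4 instead of 6*p/4
        assert by_id["MF0001"].q == pytest.approx(5 * (2 / 70) / 4)

    def test_direction_none_iff_equal_medians(self, worked_example, worked_profile):
        _, _, design = worked_example
        for c in compare_groups(worked_profile, design):
            if c.direction == "none":
                assert c.median_a == c.median_b
            else:
                assert c.median_a != c.median_b

    def test_small_group_is_hard_error(self, worked_profile):
        design = GroupDesign(
            assignment={"H1": "x", "H2": "y", "H3": "y", "H4": "y",
                        "D1": "y", "D2": "y", "D3": "y", "D4": "x"},
            group_a="x",
            group_b="y",
        )
        # design itself is valid (2 vs 6) but dropping a profiled sample isn't
        with pytest.raises(DesignError):
            compare_groups(worked_profile, GroupDesign(
                {s: "x" if s == "H1" else "y" for s in
                 ["H1", "H2", "H3", "H4", "D1", "D2", "D3"]}, "x", "y"))

    def test_unassigned_profiled_sample_is_hard_error(self, worked_profile):
        with pytest.raises(DesignError, match="without group assignment"):
            compare_groups(worked_profile, GroupDesign(
                {"H1": "x", "H2": "x", "H3": "y", "H4": "y"}, "x", "y"))


class TestGroupDesign:
    def test_requires_two_labels_and_min_sizes(self):
        with pytest.raises(DesignError):
            GroupDesign({"s1": "a", "s2": "a"}, "a", "b")
        with pytest.raises(DesignError):
            GroupDesign({"s1": "a", "s2": "b", "s3": "b"}, "a", "b")

    def test_from_table_orders_labels_by_appearance(self):
        design = GroupDesign.from_table(
            [("s1", "cd"), ("s2", "healthy"), ("s3", "cd"), ("s4", "healthy")]
        )
        assert (design.group_a, design.group_b) == ("cd", "healthy")
        assert design.samples("cd") == ["s1", "s3"]
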