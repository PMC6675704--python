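"""Cut-off optimization, serostatus calls, exact tests, coverage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pepscreen.array_signal import SampleReactivityProfile
from pepscreen.serostats import (
    bonferroni_adjust,
    classify,
    compare_groups,
    coverage,
    fisher_exact_2x2,
    longitudinal_coverage,
    optimize_cutoff,
    percent,
    render_comparison,
    select_top_peptides,
)


def brute_force_cutoff(case, control):
    """Independent exhaustive search over the pooled candidate set, scored
    in exact rational arithmetic."""
    from fractions import Fraction

    case, control = np.asarray(case, float), np.asarray(control, float)
    best = None
    for c in sorted(set(case.tolist()) | set(control.tolist())):
        obj = Fraction(int((case >= c).sum()), case.size) - Fraction(
            int((control >= c).sum()), control.size
        )
        if best is None or obj > best[1]:
            best = (c, obj)
    return best[0], float(best[1])


def enumerate_fisher_p(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = stats.hypergeom.pmf(x, n, row1, col1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestOptimizeCutoff:
    def test_perfect_separation(self):
        res = optimize_cutoff([5, 6, 7], [1, 2, 3])
        assert res.cutoff == 5.0
        assert res.max_difference == pytest.approx(1.0)
        assert res.candidates_evaluated == 6

    def test_identical_groups_tie_breaks_to_smallest(self):
        res = optimize_cutoff([1, 2, 3], [1, 2, 3])
        assert res.max_difference == pytest.approx(0.0)
        assert res.cutoff == 1.0

    def test_interleaved_tie_break(self):
        res = optimize_cutoff([2, 4, 6], [1, 3, 5])
        assert res.max_difference == pytest.approx(1 / 3)
        assert res.cutoff == 2.0  # objective 1/3 also at 4 and 6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            optimize_cutoff([], [1.0])

    def test_degenerate_identical_values_warn(self):
        with pytest.warns(UserWarning, match="identical"):
            res = optimize_cutoff([2.0, 2.0], [2.0])
        assert res.cutoff == 2.0
        assert res.max_difference == pytest.approx(0.0)

    def test_matches_exhaustive_search(self, rng):
        """Oracle equivalence on random instances, objective re-evaluation,
        and antisymmetry under swapping the groups."""
        for _ in range(200):
            case = rng.normal(rng.uniform(0, 3), 1, rng.integers(1, 25))
            control = rng.normal(0, 1, rng.integers(1, 25))
            res = optimize_cutoff(case, control)
            c_star, obj_star = brute_force_cutoff(case, control)
            assert res.cutoff == c_star
            assert res.max_difference == pytest.approx(obj_star, abs=1e-12)
            # re-evaluating the objective at the returned cutoff is exact
            reval = (case >= res.cutoff).mean() - (control >= res.cutoff).mean()
            assert reval == res.max_difference
            # swap: max of (case-control) = -min of (control-case)
            objs = [
                (control >= c).mean() - (case >= c).mean()
                for c in np.unique(np.concatenate([case, control]))
            ]
            assert res.max_difference == pytest.approx(-min(objs), abs=1e-12)

    def test_floor_restricts_candidates(self):
        res = optimize_cutoff([0.5, 0.6, 5.0], [0.4, 0.5, 0.6], min_cutoff=2.0)
        assert res.cutoff == pytest.approx(2.0)

    def test_grid_mode_uses_fixed_step(self):
        res = optimize_cutoff([5.03, 6.2], [1.1, 2.2], grid_step=0.1)
        assert res.cutoff == pytest.approx(round(res.cutoff, 1))
        assert res.max_difference == pytest.approx(1.0)


class TestClassify:
    @pytest.fixture()
    def profile(self):
        return SampleReactivityProfile(
            "s1", "glioma", "preoperative",
            {"MGMT-02": 5.5, "MGMT-04": 3.0, "MGMT-07": float("nan")}, 2,
        )

    def test_boundary_is_positive(self, profile):
        calls = {c.peptide: c for c in classify(profile, {"MGMT-02": 5.5, "MGMT-04": 3.1, "MGMT-07": 2.2})}
        assert calls["MGMT-02"].positive  # SNR == cutoff counts as positive
        assert not calls["MGMT-04"].positive  # 3.0 < 3.1

    def test_missing_snr_produces_no_call(self, profile):
        calls = classify(profile, {"MGMT-02": 5.5, "MGMT-04": 3.1, "MGMT-07": 2.2})
        assert {c.peptide for c in calls} == {"MGMT-02", "MGMT-04"}

    def test_unknown_peptide_rejected(self, profile):
        with pytest.raises(KeyError, match="MGMT-07"):
            classify(profile, {"MGMT-02": 5.5, "MGMT-04": 3.1})


class TestFisher:
    def test_symmetric_table_is_one(self):
        assert fisher_exact_2x2(2, 2, 2, 2) == pytest.approx(1.0)

    def test_published_table_value(self):
        # 8/67 glioma vs 7/311 healthy positives
        assert fisher_exact_2x2(8, 59, 7, 304) == pytest.approx(0.0015, abs=2e-4)

    def test_degenerate_margin_returns_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2(0, 0, 3, 4) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(150):
            a, b, c, d = (int(x) for x in rng.integers(0, 9, 4))
            if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                enumerate_fisher_p(a, b, c, d), rel=1e-9
            )


class TestBonferroni:
    def test_scaling_and_cap(self):
        adj = bonferroni_adjust([0.001, 0.1, 1.0], m=20)
        assert adj == pytest.approx([0.02, 1.0, 1.0])

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 50)
        assert (bonferroni_adjust(p, m=50) >= p).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5], m=1)


def _calls_frame(n_case_pos, n_case, n_ctrl_pos, n_ctrl, peptide="MGMT-02", cutoff=5.5):
    rows = []
    for i in range(n_case):
        rows.append(dict(serum_id=f"g{i}", group="glioma", timepoint="preoperative",
                         peptide=peptide, snr=9.0 if i < n_case_pos else 0.1,
                         cutoff=cutoff, positive=i < n_case_pos))
    for i in range(n_ctrl):
        rows.append(dict(serum_id=f"h{i}", group="healthy", timepoint="preoperative",
                         peptide=peptide, snr=9.0 if i < n_ctrl_pos else 0.1,
                         cutoff=cutoff, positive=i < n_ctrl_pos))
    return pd.DataFrame(rows)


class TestCompareGroups:
    @pytest.mark.parametrize(
        "peptide, case_pos, ctrl_pos, want_case_pct, want_ctrl_pct, want_diff_pct",
        [
            ("MGMT-02", 30, 19, 45, 6, 39),
            ("MGMT-04", 18, 16, 27, 5, 22),
            ("MGMT-18", 16, 15, 24, 5, 19),
        ],
    )
    def test_published_count_rendering(
        self, peptide, case_pos, ctrl_pos, want_case_pct, want_ctrl_pct, want_diff_pct
    ):
        """Whole-percent rates and differences from the published 67-vs-311 counts."""
        calls = _calls_frame(case_pos, 67, ctrl_pos, 311, peptide=peptide)
        comparison = compare_groups(calls, m=20)
        row = comparison.iloc[0]
        assert (row.a, row.a + row.b, row.c, row.c + row.d) == (case_pos, 67, ctrl_pos, 311)
        assert percent(row.case_rate) == want_case_pct
        assert percent(row.control_rate) == want_ctrl_pct
        assert percent(row.difference) == want_diff_pct
        rendered = render_comparison(comparison).iloc[0]
        assert rendered["case"] == f"{case_pos} ({want_case_pct}%)"
        assert rendered["difference"] == f"{want_diff_pct}%"

    def test_identical_groups_null(self):
        calls = _calls_frame(5, 20, 5, 20)
        row = compare_groups(calls).iloc[0]
        assert row.difference == pytest.approx(0.0)
        assert row.p_value == pytest.approx(1.0)

    def test_adjusted_p_uses_panel_size(self):
        calls = _calls_frame(30, 67, 19, 311)
        row = compare_groups(calls, m=20).iloc[0]
        assert row.p_adjusted == pytest.approx(min(1.0, 20 * row.p_value))

    def test_empty_group_rejected(self):
        calls = _calls_frame(3, 5, 0, 0).query("group == 'glioma'")
        with pytest.raises(ValueError, match="control"):
            compare_groups(calls)


class TestCoverage:
    def test_ratio(self):
        s = coverage([True] * 30 + [False] * 37, peptide="MGMT-02")
        assert s.coverage == pytest.approx(30 / 67)

    @pytest.mark.parametrize("flags, expected", [([False] * 5, 0.0), ([True] * 4, 1.0)])
    def test_extremes(self, flags, expected):
        assert coverage(flags).coverage == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            coverage([])


class TestLongitudinal:
    def test_unknown_timepoint_rejected(self):
        calls = _calls_frame(1, 2, 1, 2).assign(timepoint="day_900")
        with pytest.raises(ValueError, match="day_900"):
            longitudinal_coverage(calls)

    def test_single_timepoint_has_no_trajectories(self):
        calls = _calls_frame(5, 10, 2, 20)
        cov, traj = longitudinal_coverage(calls)
        assert len(cov) == 1
        assert traj.empty

    def test_decay_lowers_postop_coverage(self, small_calls):
        """With decay dynamics in the generator, every peptide's day-30
        coverage is at or below its preoperative case coverage."""
        case_calls = small_calls.loc[small_calls["group"] == "glioma"]
        cov, traj = longitudinal_coverage(case_calls)
        wide = cov.pivot(index="peptide", columns="timepoint", values="coverage")
        assert (wide["postop_day30"] <= wide["preoperative"] + 1e-12).all()
        # and strictly lower for at least one of the high-prevalence peptides
        assert wide["postop_day30"].sum() < wide["preoperative"].sum()

    def test_seronegative_patients_never_cross_cutoff(self, small_calls, small_cohort):
        truth = small_cohort.truth
        never_pos = (
            truth.groupby(["serum_id", "peptide"])["true_status"].any().rename("ever")
        )
        merged = small_calls.join(
            never_pos, on=["serum_id", "peptide"]
        )
        silent = merged.loc[(~merged["ever"].astype(bool)) & (merged["group"] == "glioma")]
        # truly seronegative trajectories essentially never cross the cut-off
        assert silent["positive"].mean() < 0.02

    def test_transition_strings(self):
        rows = []
        for tp, snr in [("preoperative", 9.0), ("postop_day30", 0.5), ("recurrence", 9.0)]:
            rows.append(dict(serum_id="p1", group="glioma", timepoint=tp,
                             peptide="MGMT-02", snr=snr, cutoff=2.0, positive=snr >= 2.0))
        cov, traj = longitudinal_coverage(pd.DataFrame(rows))
        assert set(traj["transition"]) == {"+/-/+"}


class TestTopPeptides:
    def test_ranked_by_difference_among_significant(self):
        frame = pd.DataFrame(
            {
                "peptide": ["A", "B", "C", "D"],
                "difference": [0.10, 0.39, 0.22, 0.30],
                "p_adjusted": [0.2, 1e-10, 1e-5, 0.04],
            }
        )
        assert select_top_peptides(frame, alpha=0.05, k=2) == ["B", "D"]
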