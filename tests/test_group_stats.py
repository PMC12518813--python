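import itertools
import math

import numpy as np
import pandas as pd
import pytest

from motifrhythm.errors import InsufficientDataError, ValidationError
from motifrhythm.group_stats import (
    cohens_d,
    length_correlations,
    nest_beat_correlation,
    simulate_null_fwer,
    welch_comparisons,
    welch_pairwise,
)
from motifrhythm.records import SubsetKind


def metrics_frame(groups: dict, parameter_values: dict | None = None) -> pd.DataFrame:
    """Build a minimal metrics table: groups maps subset-kind value ->
    list of parameter values (used for all three parameters unless
    overridden)."""
    rows = []
    for kind, values in groups.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "nest_id": "N01", "bird_id": "b", "role": "tutor",
                    "motif_id": f"{kind}{i}", "subset_kind": kind,
                    "n_elements": 5, "n_iois": 4, "mean_ioi_s": 0.06,
                    "ioi_beat_hz": v, "cv_adj": v, "npvi": v,
                }
            )
    return pd.DataFrame(rows)


def welch_oracle(a, b):
    """Textbook Welch t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    return (a.mean() - b.mean()) / math.sqrt(va + vb)


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def test_welch_t_matches_closed_form_on_hand_example():
    a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 9.0]
    (res,) = welch_pairwise(
        {SubsetKind.TUTOR: np.array(a), SubsetKind.EVERYTHING: np.array(b)},
        "ioi_beat_hz", family_size=1,
    )
    assert res.t_stat == pytest.approx(welch_oracle(a, b), abs=1e-9)


def test_identical_samples_give_null_result():
    a = np.array([1.0, 2.0, 3.0])
    (res,) = welch_pairwise(
        {SubsetKind.TUTOR: a, SubsetKind.EVERYTHING: a.copy()},
        "npvi", family_size=1,
    )
    assert res.t_stat == 0.0
    assert res.p_raw == pytest.approx(1.0)
    assert res.cohens_d == 0.0


def test_five_groups_three_parameters_gives_30_results():
    rng = np.random.default_rng(1)
    groups = {k.value: rng.normal(10, 1, 8).tolist()
              for k in SubsetKind}
    results = welch_comparisons(metrics_frame(groups))
    assert len(results) == 30
    pairs = {(r.group_a, r.group_b) for r in results}
    assert len(pairs) == 10


def test_swapping_groups_flips_t_and_d_signs():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
    (fwd,) = welch_pairwise(
        {SubsetKind.TUTOR: a, SubsetKind.EVERYTHING: b}, "cv_adj", 1
    )
    (rev,) = welch_pairwise(
        {SubsetKind.TUTOR: b, SubsetKind.EVERYTHING: a}, "cv_adj", 1
    )
    assert fwd.t_stat == pytest.approx(-rev.t_stat, rel=1e-12)
    assert fwd.cohens_d == pytest.approx(-rev.cohens_d, rel=1e-12)
    assert fwd.p_raw == pytest.approx(rev.p_raw, rel=1e-12)
    assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a), rel=1e-12)


def test_bonferroni_monotone_and_capped():
    rng = np.random.default_rng(3)
    groups = {k.value: rng.normal(10, 1, 6).tolist() for k in SubsetKind}
    results = welch_comparisons(metrics_frame(groups), family="global")
    assert all(r.p_adj <= 1.0 for r in results)
    ordered = sorted(results, key=lambda r: r.p_raw)
    adj = [r.p_adj for r in ordered]
    assert all(x <= y for x, y in zip(adj, adj[1:]))
    assert all(r.p_adj >= r.p_raw for r in results)


def test_two_group_type_i_error_calibration():
    """Uncorrected Welch test under the null rejects at the nominal rate:
    10000 same-distribution replicates, alpha 0.05 -> 0.05 +/- 0.01."""
    rng = np.random.default_rng(12345)
    rejections = 0
    n_rep = 10000
    for _ in range(n_rep):
        samples = {
            SubsetKind.TUTOR: rng.standard_normal(15),
            SubsetKind.EVERYTHING: rng.standard_normal(15),
        }
        (res,) = welch_pairwise(samples, "ioi_beat_hz", family_size=1)
        rejections += res.p_raw < 0.05
    assert rejections / n_rep == pytest.approx(0.05, abs=0.01)


def test_fwer_helper_runs_and_is_controlled_smoke():
    fwer = simulate_null_fwer(n_replicates=300, rng=np.random.default_rng(7))
    assert 0 <= fwer <= 0.1  # coarse: full-precision check in acceptance suite


class TestNestBeatCorrelation:
    def _frame(self, tutor_beats, tutee_beats):
        rows = []
        for i, (t, u) in enumerate(zip(tutor_beats, tutee_beats)):
            nest = f"N{i:02d}"
            rows.append({"nest_id": nest, "bird_id": nest + "T", "role": "tutor",
                         "motif_id": "m0", "subset_kind": "tutor",
                         "n_elements": 6, "n_iois": 5, "mean_ioi_s": 1 / t,
                         "ioi_beat_hz": t, "cv_adj": 0.5, "npvi": 50.0})
            rows.append({"nest_id": nest, "bird_id": nest + "B1", "role": "tutee",
                         "motif_id": "m0", "subset_kind": "everything",
                         "n_elements": 6, "n_iois": 5, "mean_ioi_s": 1 / u,
                         "ioi_beat_hz": u, "cv_adj": 0.5, "npvi": 50.0})
        return pd.DataFrame(rows)

    def test_exact_copy_gives_r_1(self):
        beats = [12.0, 15.0, 18.0, 21.0]
        nc = nest_beat_correlation(self._frame(beats, beats))
        assert nc.r == pytest.approx(1.0)
        assert len(nc.nest_ids) == 4

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(10, 25, 8)
        u = t / 1.05 + rng.normal(0, 0.5, 8)
        nc = nest_beat_correlation(self._frame(t, u))
        assert nc.r == pytest.approx(pearson_oracle(t, u), abs=1e-9)

    def test_fewer_than_three_nests_rejected(self):
        with pytest.raises(InsufficientDataError):
            nest_beat_correlation(self._frame([12.0, 15.0], [12.0, 15.0]))

    def test_permuted_tutee_beats_have_near_zero_mean_r(self):
        """Destroying the nest pairing leaves no correlation on average
        (2000 permutations of 17 nests)."""
        rng = np.random.default_rng(6)
        t = rng.uniform(10, 25, 17)
        u = t / 1.05 + rng.normal(0, 0.3, 17)
        rs = []
        for _ in range(2000):
            rs.append(pearson_oracle(t, rng.permutation(u)))
        assert abs(np.mean(rs)) < 0.05


class TestLengthCorrelations:
    def _frame(self, n_elements, values):
        rows = []
        for i, (n, v) in enumerate(zip(n_elements, values)):
            rows.append({"nest_id": "N01", "bird_id": "b", "role": "tutor",
                         "motif_id": f"m{i}", "subset_kind": "tutor",
                         "n_elements": n, "n_iois": n - 1, "mean_ioi_s": 0.06,
                         "ioi_beat_hz": v, "cv_adj": v, "npvi": v})
        return pd.DataFrame(rows)

    def test_perfect_negative_relationship(self):
        n = np.arange(4, 14)
        df = length_correlations(self._frame(n, -n.astype(float)))
        assert df["r"].to_numpy() == pytest.approx([-1.0] * 3)

    def test_constant_length_rejected(self):
        with pytest.raises(InsufficientDataError):
            length_correlations(self._frame([5, 5, 5], [1.0, 2.0, 3.0]))

    def test_two_units_rejected(self):
        with pytest.raises(InsufficientDataError):
            length_correlations(self._frame([5, 6], [1.0, 2.0]))


def test_unknown_family_rejected():
    with pytest.raises(ValidationError):
        welch_comparisons(metrics_frame({"tutor": [1, 2], "everything": [1, 2]}),
                          family="fdr")
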