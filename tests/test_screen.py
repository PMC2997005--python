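"""Pearson screen: correlation, p values, BH adjustment and the filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import betainc

from pancmir import (
    ScreenConfig,
    bh_adjust,
    correlation_pvalue,
    pearson_r,
    run_screen,
    run_scopes,
)
from pancmir.predictions import MIRBASE, TARGETSCAN, PredictionSet


def pearson_oracle(x, y):
    """Covariance-formula Pearson coefficient, coded independently.

    Evaluated in 50-digit arithmetic so the naive E[xy] - E[x]E[y] form
    stays exact even on near-constant profiles.
    """
    import mpmath as mp

    with mp.workdps(50):
        x = [mp.mpf(float(v)) for v in x]
        y = [mp.mpf(float(v)) for v in y]
        n = len(x)
        mx = mp.fsum(x) / n
        my = mp.fsum(y) / n
        cov = mp.fsum(a * b for a, b in zip(x, y)) / n - mx * my
        sx = mp.sqrt(mp.fsum(a * a for a in x) / n - mx * mx)
        sy = mp.sqrt(mp.fsum(b * b for b in y) / n - my * my)
        return float(cov / (sx * sy))


def pvalue_oracle(r, n):
    """Two-sided p for H0: r = 0 via the incomplete-beta t-tail form."""
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    t2 = t * t
    if t2 < 1.0:
        return 1.0 - betainc(0.5, df / 2.0, t2 / (df + t2))
    return betainc(df / 2.0, 0.5, df / (df + t2))


def bh_oracle(p):
    """Literal step-up definition: sort, scale by m/i, run the min from
    the top rank down, cap at 1, undo the sort."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    scaled = [p[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for i, idx in enumerate(order):
        out[idx] = min(1.0, scaled[i])
    return out


class TestPearsonR:
    def test_perfect_linear_relations(self):
        assert pearson_r([1, 2, 3], [3, 5, 7]) == pytest.approx(1.0)  # y = 2x + 1
        assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_reference_profile_matches_oracle(self):
        x, y = [1, 2, 3], [6, 5, 1]
        r = pearson_r(x, y)
        assert r == pytest.approx(pearson_oracle(x, y), rel=1e-12)
        assert r == pytest.approx(-0.9449, abs=5e-5)

    def test_zero_variance_marks_undefined(self):
        assert np.isnan(pearson_r([1, 1, 1], [1, 2, 3]))

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
            min_size=3,
            max_size=10,
        )
    )
    def test_oracle_equivalence_property(self, data):
        x = np.asarray([a for a, _ in data])
        y = np.asarray([b for _, b in data])
        # zero spread — or spread so small its square underflows — makes the
        # product-moment denominator vanish at working precision
        if ((x - x.mean()) ** 2).sum() == 0 or ((y - y.mean()) ** 2).sum() == 0:
            assert np.isnan(pearson_r(x, y))
            return
        expected = pearson_oracle(x, y)
        assert pearson_r(x, y) == pytest.approx(expected, rel=1e-10, abs=1e-10)


class TestCorrelationPvalue:
    def test_null_and_limit_conventions(self):
        assert correlation_pvalue(0.0, 5) == 1.0
        assert correlation_pvalue(1.0, 3) == 0.0
        assert correlation_pvalue(-1.0, 3) == 0.0

    def test_reference_value_matches_oracle(self):
        assert correlation_pvalue(-0.9, 3) == pytest.approx(
            pvalue_oracle(-0.9, 3), rel=1e-12
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            correlation_pvalue(0.5, 2)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        r=st.floats(1e-6, 0.999999),
        sign=st.sampled_from([-1.0, 1.0]),
        n=st.integers(min_value=3, max_value=50),
    )
    def test_oracle_equivalence_property(self, r, sign, n):
        assert correlation_pvalue(sign * r, n) == pytest.approx(
            pvalue_oracle(sign * r, n), rel=1e-10, abs=1e-300
        )


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_executed_step_up(self):
        # 0.01*4/1, 0.02*4/2, 0.03*4/3 all min-capped by 0.04*4/4
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_ps_stay_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_adjusted_never_below_raw_and_capped(self):
        rng = np.random.default_rng(11)
        p = rng.random(100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_brute_force_equivalence_many_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(bh_oracle(p), rel=1e-12)


def _profiles(rows, columns=("P1", "P2", "P3")):
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(columns))


def _predictions(source, pairs):
    return PredictionSet(
        source,
        pd.DataFrame(sorted(set(pairs)), columns=["mirna_id", "gene_id"]),
    )


@pytest.fixture
def toy_screen_inputs():
    mirna = _profiles(
        {
            "miR-up": [1.0, 4.0, 16.0],
            "miR-down": [16.0, 4.0, 1.0],
            "miR-flat": [2.0, 2.0, 2.0],
        }
    )
    genes = _profiles(
        {
            "GANTI": [900.0, 700.0, 100.0],   # anti-parallel to miR-up
            "GPOS": [100.0, 400.0, 1600.0],   # parallel to miR-up
            "GWEAK": [300.0, 120.0, 250.0],   # weak relation
            "GFLAT": [50.0, 50.0, 50.0],
        }
    )
    groups = {"miR-up": "I", "miR-down": "II", "miR-flat": "III"}
    return mirna, genes, groups


class TestRunScreen:
    def test_only_predicted_pairs_reported(self, toy_screen_inputs):
        mirna, genes, groups = toy_screen_inputs
        pred = _predictions(TARGETSCAN, [("miR-up", "GANTI")])
        res = run_screen(mirna, genes, pred, groups)
        reported = set(zip(res.records["mirna_id"], res.records["gene_id"]))
        assert reported <= pred.pair_set

    def test_strong_negative_pair_passes_all_filters(self, toy_screen_inputs):
        mirna, genes, groups = toy_screen_inputs
        pred = _predictions(TARGETSCAN, [("miR-up", "GANTI")])
        res = run_screen(mirna, genes, pred, groups)
        assert len(res.records) == 1
        rec = res.records.iloc[0]
        assert rec["r"] < 0 and rec["r_squared"] >= 0.8
        assert rec["p_adj"] >= rec["p_raw"]

    def test_positive_correlation_excluded(self, toy_screen_inputs):
        mirna, genes, groups = toy_screen_inputs
        pred = _predictions(TARGETSCAN, [("miR-up", "GPOS")])
        res = run_screen(mirna, genes, pred, groups)
        assert len(res.records) == 0
        assert res.candidates.iloc[0]["r"] > 0.9

    def test_moderate_negative_fails_r_squared_threshold(self):
        mirna = _profiles({"miR-d": [10.0, 9.0, 2.0]})
        genes = _profiles({"G": [1.0, 6.0, 5.0]})
        pred = _predictions(TARGETSCAN, [("miR-d", "G")])
        res = run_screen(
            mirna, genes, pred, {"miR-d": "II"}, ScreenConfig(use_adjusted_p=False)
        )
        rec = res.candidates.iloc[0]
        assert rec["r"] < 0 and rec["r_squared"] < 0.8
        assert len(res.records) == 0

    def test_group_three_mirnas_never_screened(self, toy_screen_inputs):
        mirna, genes, groups = toy_screen_inputs
        pred = _predictions(TARGETSCAN, [("miR-flat", "GANTI")])
        res = run_screen(mirna, genes, pred, groups)
        assert len(res.candidates) == 0
        assert (res.skipped["reason"] == "mirna not in group I/II").all()

    def test_zero_variance_gene_skipped_not_zeroed(self, toy_screen_inputs):
        mirna, genes, groups = toy_screen_inputs
        pred = _predictions(TARGETSCAN, [("miR-up", "GFLAT")])
        res = run_screen(mirna, genes, pred, groups)
        assert len(res.candidates) == 0
        assert "zero-variance" in res.skipped.iloc[0]["reason"]

    def test_candidate_order_invariance(self, toy_screen_inputs):
        mirna, genes, groups = toy_screen_inputs
        pairs = [
            ("miR-up", "GANTI"),
            ("miR-up", "GWEAK"),
            ("miR-down", "GPOS"),
            ("miR-down", "GWEAK"),
        ]
        a = run_screen(mirna, genes, _predictions(TARGETSCAN, pairs), groups)
        b = run_screen(
            mirna, genes, _predictions(TARGETSCAN, pairs[::-1]), groups
        )
        key = ["mirna_id", "gene_id"]
        pd.testing.assert_frame_equal(
            a.candidates.sort_values(key).reset_index(drop=True),
            b.candidates.sort_values(key).reset_index(drop=True),
        )

    def test_intersection_scope_is_subset_of_single_scopes(self, toy_screen_inputs):
        mirna, genes, groups = toy_screen_inputs
        mb = _predictions(
            MIRBASE, [("miR-up", "GANTI"), ("miR-down", "GPOS"), ("miR-up", "GWEAK")]
        )
        ts = _predictions(
            TARGETSCAN, [("miR-up", "GANTI"), ("miR-down", "GWEAK")]
        )
        cfg = ScreenConfig(use_adjusted_p=False)
        scopes = run_scopes(mirna, genes, mb, ts, groups, cfg)
        both = set(
            zip(scopes["BOTH"].records["mirna_id"], scopes["BOTH"].records["gene_id"])
        )
        for single in ("MIRBASE", "TARGETSCAN"):
            rec = scopes[single].records
            assert both <= set(zip(rec["mirna_id"], rec["gene_id"]))

    def test_manifest_counts_are_consistent(self, toy_screen_inputs):
        mirna, genes, groups = toy_screen_inputs
        pairs = [("miR-up", "GANTI"), ("miR-up", "GPOS"), ("miR-flat", "GWEAK")]
        res = run_screen(mirna, genes, _predictions(TARGETSCAN, pairs), groups)
        manifest = res.manifest
        assert manifest["family_size"] == 2
        assert manifest["skipped"] == 1
        assert manifest["reported"] == len(res.records)

    def test_mismatched_period_counts_rejected(self, toy_screen_inputs):
        mirna, genes, groups = toy_screen_inputs
        with pytest.raises(ValueError, match="align"):
            run_screen(
                mirna,
                genes[["P1", "P2"]],
                _predictions(TARGETSCAN, [("miR-up", "GANTI")]),
                groups,
            )
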