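"""Used–available table construction, weights and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from elkrsf.design import (
    AVAILABLE_WEIGHT,
    USED_WEIGHT,
    DegenerateCovariateError,
    build_second_order_table,
    build_third_order_table,
    covariate_correlations,
    read_table,
    standardize_covariates,
    write_table,
)
from elkrsf.telemetry import filter_foraging_locations


def test_second_order_counts_and_weights(small_study, small_home_ranges):
    ids = list(small_home_ranges)[:3]
    hrs = {i: small_home_ranges[i] for i in ids}
    pop = small_home_ranges[ids[0]]  # any polygon covering the individuals works
    table, _ = build_second_order_table(
        hrs, {i: small_home_ranges[i] for i in ids}, small_study.de,
        small_study.lion, small_study.wolf, seed=5,
    )
    assert len(table) == 3 * (500 + 1000)
    counts = table.groupby(["individual_id", "used"]).size()
    for i in ids:
        assert counts[(i, 1)] == 500
        assert counts[(i, 0)] == 1000
    assert (table.loc[table.used == 1, "weight"] == USED_WEIGHT).all()
    assert (table.loc[table.used == 0, "weight"] == AVAILABLE_WEIGHT).all()


def test_second_order_points_inside_polygons(small_study, small_home_ranges):
    ind = list(small_home_ranges)[0]
    hr = small_home_ranges[ind]
    table, _ = build_second_order_table(
        {ind: hr}, hr, small_study.de, small_study.lion, small_study.wolf,
        n_used=100, n_avail=200, seed=5, standardize=False,
    )
    used = table[table.used == 1]
    assert hr.contains(used["x"].to_numpy(), used["y"].to_numpy()).all()


def test_second_order_reproducible(small_study, small_home_ranges):
    ind = list(small_home_ranges)[0]
    hr = {ind: small_home_ranges[ind]}
    args = (hr, small_home_ranges[ind], small_study.de, small_study.lion, small_study.wolf)
    t1, _ = build_second_order_table(*args, n_used=50, n_avail=100, seed=9)
    t2, _ = build_second_order_table(*args, n_used=50, n_avail=100, seed=9)
    pd.testing.assert_frame_equal(t1, t2)


def test_third_order_ratio(small_study, small_home_ranges):
    forage = filter_foraging_locations(small_study.telemetry)
    ids = list(small_home_ranges)[:2]
    hrs = {i: small_home_ranges[i] for i in ids}
    table, _ = build_third_order_table(
        forage, hrs, small_study.de, small_study.lion, small_study.wolf,
        ratio=10, seed=3,
    )
    for i in ids:
        n_used = len(forage[forage.animal_id == i])
        sub = table[table.individual_id == i]
        assert (sub.used == 1).sum() == n_used
        assert (sub.used == 0).sum() == 10 * n_used


def test_third_order_excludes_empty_individual(small_study, small_home_ranges, caplog):
    forage = filter_foraging_locations(small_study.telemetry)
    ids = list(small_home_ranges)[:2]
    forage = forage[forage.animal_id == ids[0]]  # second individual has no rows
    hrs = {i: small_home_ranges[i] for i in ids}
    with caplog.at_level("WARNING"):
        table, _ = build_third_order_table(
            forage, hrs, small_study.de, small_study.lion, small_study.wolf, seed=3
        )
    assert set(table.individual_id) == {ids[0]}
    assert any(ids[1] in r.message for r in caplog.records)


def test_standardize_hand_example():
    df = pd.DataFrame({"de": [1.0, 2.0, 3.0], "ml": [0.0, 1.0, 2.0],
                       "wf": [5.0, 6.0, 10.0]})
    out, consts = standardize_covariates(df)
    # sample sd of (1,2,3) is exactly 1, so the column becomes (-1, 0, 1)
    np.testing.assert_allclose(out["de"], [-1.0, 0.0, 1.0], atol=1e-12)
    assert consts.sds["de"] == pytest.approx(1.0)
    for c in ("de", "ml", "wf"):
        assert out[c].mean() == pytest.approx(0.0, abs=1e-10)
        assert out[c].std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_standardize_idempotent_and_invertible():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(rng.normal(3, 2, size=(50, 3)), columns=["de", "ml", "wf"])
    out, consts = standardize_covariates(df)
    again, _ = standardize_covariates(out)
    pd.testing.assert_frame_equal(again, out, atol=1e-10)
    back = consts.invert(out)
    pd.testing.assert_frame_equal(back, df, atol=1e-10)


def test_constant_column_rejected():
    df = pd.DataFrame({"de": [1.0, 1.0, 1.0], "ml": [0.0, 1.0, 2.0],
                       "wf": [0.0, 2.0, 1.0]})
    with pytest.raises(DegenerateCovariateError):
        standardize_covariates(df)


def test_collinear_covariates_warn():
    df = pd.DataFrame({"de": [1.0, 2.0, 3.0, 4.0]})
    df["ml"] = 2 * df["de"]  # |r| = 1
    df["wf"] = [0.0, 3.0, 1.0, 2.0]
    with pytest.warns(UserWarning, match="correlated"):
        _, _ = standardize_covariates(df)
    r2 = covariate_correlations(df).loc[("de", "ml"), "r2"]
    assert r2 == pytest.approx(1.0)


@settings(max_examples=25, deadline=None)
@given(
    arrays(np.float64, (20, 3), elements=st.floats(-50, 50)).filter(
        lambda a: all(np.std(a[:, j]) > 1e-6 for j in range(3))
    )
)
def test_standardize_roundtrip_property(a):
    df = pd.DataFrame(a, columns=["de", "ml", "wf"])
    out, consts = standardize_covariates(df)
    back = consts.invert(out)
    np.testing.assert_allclose(back.to_numpy(), a, atol=1e-8)


def test_table_csv_roundtrip(tmp_path, small_third_order):
    table, consts = small_third_order
    path = tmp_path / "table.csv"
    write_table(table, consts, path, seed=8)
    back, back_consts = read_table(path)
    np.testing.assert_allclose(
        back[["used", "weight", "de", "ml", "wf"]].to_numpy(),
        table[["used", "weight", "de", "ml", "wf"]].to_numpy(),
    )
    assert back_consts.means == consts.means
    assert back_consts.sds == consts.sds
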