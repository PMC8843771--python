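import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from benthosom.data import (ValidationError, hellinger_transform,
                            log_environment, log_transform, read_community,
                            read_environment, standardize, write_community,
                            write_environment, EnvMatrix)
from benthosom.synthetic import generate


def test_community_round_trip(toy_community, tmp_path):
    path = tmp_path / "community.tsv"
    write_community(toy_community, path)
    back = read_community(path)
    pd.testing.assert_frame_equal(back.abundance, toy_community.abundance)
    pd.testing.assert_series_equal(back.biomass, toy_community.biomass,
                                   check_names=False)
    assert back.meta["season"].tolist() == ["spring", "autumn"]


def test_community_round_trip_on_generated_data(tmp_path):
    com, _, _ = generate(seed=5)
    path = tmp_path / "community.tsv"
    write_community(com, path)
    back = read_community(path)
    pd.testing.assert_frame_equal(back.abundance, com.abundance)


def test_duplicate_site_error_names_site(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text("site_id,lake,season,biomass_g_m2,taxA\n"
                    "s1,A,spring,1.0,4\n"
                    "s1,A,summer,2.0,5\n")
    with pytest.raises(ValidationError, match="s1"):
        read_community(path)


def test_negative_abundance_rejected(tmp_path):
    path = tmp_path / "neg.csv"
    path.write_text("site_id,lake,season,biomass_g_m2,taxA\ns1,A,spring,1.0,-4\n")
    with pytest.raises(ValidationError, match="negative"):
        read_community(path)


def test_missing_cell_rejected(tmp_path):
    path = tmp_path / "na.csv"
    path.write_text("site_id,lake,season,biomass_g_m2,taxA,taxB\n"
                    "s1,A,spring,1.0,4,\n")
    with pytest.raises(ValidationError, match="missing"):
        read_community(path)


def test_environment_ph_exempt_from_positivity(tmp_path):
    path = tmp_path / "env.csv"
    path.write_text("site_id,pH,COND\ns1,8.5,500\ns2,8.5,600\n")
    env = read_environment(path)
    assert env.values.loc["s1", "pH"] == 8.5


def test_environment_nonpositive_log_variable_rejected(tmp_path):
    path = tmp_path / "env.csv"
    path.write_text("site_id,pH,COND\ns1,8.5,0\n")
    with pytest.raises(ValidationError, match="COND"):
        read_environment(path)


def test_environment_round_trip(tmp_path):
    _, env, _ = generate(seed=5)
    path = tmp_path / "env.tsv"
    write_environment(env, path)
    back = read_environment(path)
    pd.testing.assert_frame_equal(back.values, env.values)


@pytest.mark.parametrize("value,expected", [(0.0, 0.0), (np.e - 1.0, 1.0)])
def test_log_abundance_values(value, expected):
    assert log_transform(np.array([value]))[0] == pytest.approx(expected)


def test_log_environment_of_one_is_zero():
    assert log_transform(np.array([1.0]), applied_to="environment")[0] == 0.0


def test_log_domain_violations():
    with pytest.raises(ValidationError):
        log_transform(np.array([-0.1]))
    with pytest.raises(ValidationError):
        log_transform(np.array([0.0]), applied_to="environment")


def test_log_exp_inverse_recovers_input():
    x = np.array([0.0, 1.0, 16.0, 2000.0])
    assert np.allclose(np.expm1(log_transform(x)), x, atol=1e-12)


def test_log_environment_skips_ph():
    env = pd.DataFrame({"pH": [8.5, 8.6], "COND": [np.e, np.e ** 2]})
    out = log_environment(EnvMatrix(values=env))
    assert out["pH"].tolist() == [8.5, 8.6]
    assert np.allclose(out["COND"], [1.0, 2.0])


@pytest.mark.parametrize("row,expected", [
    ([4.0, 0.0], [1.0, 0.0]),
    ([1.0, 1.0, 1.0, 1.0], [0.5, 0.5, 0.5, 0.5]),
    ([9.0, 16.0], [0.6, 0.8]),
])
def test_hellinger_known_rows(row, expected):
    out = hellinger_transform(pd.DataFrame([row]))
    assert np.allclose(out.to_numpy()[0], expected, atol=1e-12)


def test_hellinger_zero_row_names_site():
    df = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["ok", "empty"])
    with pytest.raises(ValidationError, match="empty"):
        hellinger_transform(df)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.lists(st.floats(min_value=0, max_value=1e4), min_size=3,
                         max_size=3), min_size=1, max_size=8))
def test_hellinger_rows_unit_sum_of_squares(rows):
    df = pd.DataFrame(rows)
    df = df[df.sum(axis=1) > 0]
    if df.empty:
        return
    out = hellinger_transform(df)
    assert np.allclose((out.to_numpy() ** 2).sum(axis=1), 1.0, atol=1e-12)


def test_standardize_simple_column():
    out = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
    assert out["a"].mean() == pytest.approx(0.0, abs=1e-12)
    assert out["a"].std(ddof=1) == pytest.approx(1.0)


def test_standardize_idempotent():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(3, 2, (20, 3)))
    once = standardize(df)
    twice = standardize(once)
    assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


def test_standardized_covariance_equals_correlation():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(30, 4)) @ rng.normal(size=(4, 4)))
    z = standardize(df)
    assert np.allclose(np.cov(z.to_numpy(), rowvar=False),
                       np.corrcoef(df.to_numpy(), rowvar=False), atol=1e-10)


def test_standardize_constant_column_rejected():
    with pytest.raises(ValidationError):
        standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))
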