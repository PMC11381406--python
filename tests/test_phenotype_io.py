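import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from droughtadapt import (
    ConfigurationError,
    DegenerateDataError,
    PopulationMeans,
    TraitColumns,
    ValidationError,
    read_trait_table,
    summarize_means,
    summarize_trait,
)
from droughtadapt.phenotype_io import write_trait_matrix


def test_round_trip_is_bit_identical(worked_tm, tmp_path):
    """write -> read -> summarize reproduces the in-memory summary exactly."""
    path = tmp_path / "traits.csv"
    write_trait_matrix(worked_tm, path)
    tm2 = read_trait_table(path)
    gm1, pm1 = summarize_means(worked_tm)
    gm2, pm2 = summarize_means(tm2)
    pd.testing.assert_frame_equal(gm1, gm2)
    assert pm1 == pm2


def test_custom_columns_and_tsv(worked_tm, tmp_path):
    renamed = worked_tm.rename(
        columns={"genotype": "acc", "condition": "trt", "replicate": "rep",
                 "value": "dw_mg"}
    ).replace({"trt": {"control": "CK", "stress": "PEG"}})
    path = tmp_path / "traits.tsv"
    renamed.to_csv(path, sep="\t", index=False)
    cols = TraitColumns(genotype="acc", condition="trt", replicate="rep",
                        value="dw_mg", control_label="CK", stress_label="PEG")
    tm = read_trait_table(path, cols)
    gm, pm = summarize_means(tm)
    assert pm == summarize_means(worked_tm)[1]


def test_missing_column_is_configuration_error(worked_tm, tmp_path):
    path = tmp_path / "broken.csv"
    worked_tm.drop(columns=["condition"]).to_csv(path, index=False)
    with pytest.raises(ConfigurationError, match="condition"):
        read_trait_table(path)


def test_one_condition_genotype_error_names_it(worked_tm, tmp_path):
    broken = worked_tm[~((worked_tm.genotype == "w3") &
                         (worked_tm.condition == "stress"))]
    broken = broken.replace({"genotype": {"w3": "g9"}})
    path = tmp_path / "broken.csv"
    broken.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="g9"):
        read_trait_table(path)


def test_negative_value_rejected(worked_tm, tmp_path):
    bad = worked_tm.copy()
    bad.loc[0, "value"] = -1.0
    path = tmp_path / "bad.csv"
    bad.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="negative"):
        read_trait_table(path)


def test_duplicate_triples_rejected(worked_tm, tmp_path):
    path = tmp_path / "dup.csv"
    pd.concat([worked_tm, worked_tm.iloc[[0]]]).to_csv(path, index=False)
    with pytest.raises(ValidationError, match="duplicate"):
        read_trait_table(path)


def test_missing_values_dropped_with_logged_count(worked_tm, tmp_path, caplog):
    holey = worked_tm.copy()
    holey.loc[1, "value"] = np.nan
    path = tmp_path / "holey.csv"
    holey.to_csv(path, index=False)
    with caplog.at_level("WARNING"):
        tm = read_trait_table(path)
    assert len(tm) == len(worked_tm) - 1
    assert "1 row" in caplog.text


@pytest.mark.parametrize(
    "control_reps, stress_reps, exp_c, exp_t",
    [
        ([100, 200, 300], [50, 50, 50], 200.0, 50.0),
        ([10], [10], 10.0, 10.0),
        ([1, 2], [3, 4, 5], 1.5, 4.0),  # unequal replicate counts
    ],
)
def test_replicate_means(control_reps, stress_reps, exp_c, exp_t):
    rows = [("g", "control", i + 1, v) for i, v in enumerate(control_reps)]
    rows += [("g", "stress", i + 1, v) for i, v in enumerate(stress_reps)]
    rows += [("h", "control", 1, 1.0), ("h", "stress", 1, 1.0)]
    tm = pd.DataFrame(rows, columns=["genotype", "condition", "replicate", "value"])
    gm, _ = summarize_means(tm)
    row = gm.set_index("genotype").loc["g"]
    assert row["C"] == exp_c and row["T"] == exp_t


def test_population_means_are_unweighted():
    gm = pd.DataFrame({"genotype": ["a", "b"], "C": [400.0, 800.0], "T": [100.0, 300.0]})
    _, pm = summarize_means(
        pd.DataFrame(
            [(g, cond, 1, v)
             for g, c, t in gm.itertuples(index=False)
             for cond, v in [("control", c), ("stress", t)]],
            columns=["genotype", "condition", "replicate", "value"],
        )
    )
    assert pm == PopulationMeans(600.0, 200.0, 2)


def test_cv_hand_example():
    """Genotype means {1,2,3}: sample SD 1, mean 2 -> CV 50%."""
    gm = pd.DataFrame({"genotype": list("abc"), "C": [1.0, 2.0, 3.0],
                       "T": [1.0, 2.0, 3.0]})
    s = summarize_trait(gm, PopulationMeans(2.0, 2.0, 3))
    assert s.control_cv_pct == pytest.approx(50.0)
    assert s.stress_cv_pct == pytest.approx(50.0)


def test_percent_reduction_matches_published_population():
    """Population means 746.90 -> 285.40 mg correspond to a 61.79% reduction."""
    gm = pd.DataFrame({"genotype": ["a", "b"],
                       "C": [846.90, 646.90], "T": [385.40, 185.40]})
    s = summarize_trait(gm, PopulationMeans(746.90, 285.40, 2))
    assert s.percent_reduction == pytest.approx(61.79, abs=0.01)


def test_degenerate_ttest_flagged_with_p_one():
    gm = pd.DataFrame({"genotype": list("abc"), "C": [5.0, 5.0, 5.0],
                       "T": [5.0, 5.0, 5.0]})
    s = summarize_trait(gm, PopulationMeans(5.0, 5.0, 3))
    assert s.degenerate and s.p_value == 1.0 and s.control_cv_pct == 0.0


def test_zero_mean_cv_undefined():
    gm = pd.DataFrame({"genotype": ["a", "b"], "C": [1.0, 2.0], "T": [0.0, 0.0]})
    with pytest.raises(DegenerateDataError):
        summarize_trait(gm, PopulationMeans(1.5, 0.0, 2))


@given(scale=st.floats(0.01, 1e4), seed=st.integers(0, 2**16))
@settings(max_examples=30, deadline=None)
def test_percent_reduction_scale_invariant(scale, seed):
    rng = np.random.default_rng(seed)
    n = 5
    c = rng.uniform(10, 100, n)
    t = rng.uniform(1, 90, n)
    gm1 = pd.DataFrame({"genotype": [f"g{i}" for i in range(n)], "C": c, "T": t})
    gm2 = gm1.assign(C=c * scale, T=t * scale)
    pm1 = PopulationMeans(c.mean(), t.mean(), n)
    pm2 = PopulationMeans(c.mean() * scale, t.mean() * scale, n)
    s1, s2 = summarize_trait(gm1, pm1), summarize_trait(gm2, pm2)
    assert s1.percent_reduction == pytest.approx(s2.percent_reduction, rel=1e-9)


@given(seed=st.integers(0, 2**16))
@settings(max_examples=30, deadline=None)
def test_t_statistic_sign_matches_mean_difference(seed):
    rng = np.random.default_rng(seed)
    n = 8
    c = rng.uniform(10, 100, n)
    t = c + rng.normal(0, 20, n)
    gm = pd.DataFrame({"genotype": [f"g{i}" for i in range(n)], "C": c, "T": t})
    s = summarize_trait(gm, PopulationMeans(c.mean(), t.mean(), n))
    if not s.degenerate and (c - t).mean() != 0:
        assert np.sign(s.t_statistic) == np.sign((c - t).mean())
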