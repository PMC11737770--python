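"""Presence-absence matrix pipeline."""

import numpy as np
import pandas as pd
import pytest

from cooccur_affinity import (
    PrepConfig,
    Table2x2,
    dataprep,
    interval_set,
    ml_alpha,
    pairwise_affinity,
    read_matrix,
    sample_matrix,
    squareform,
    traditional_indices,
)


@pytest.fixture
def binary_df():
    return sample_matrix(5, 30, [12, 15, 8, 20, 15],
                         pair_alphas={(0, 1): 2.0}, rng=11)


@pytest.fixture
def abundance_df():
    return pd.DataFrame(
        [[0.0, 2.5, 1.0, 3.0], [1.0, 1.0, 0.0, 4.0], [2.0, 0.0, 1.0, 1.0]],
        index=["spA", "spB", "spC"],
        columns=["s1", "s2", "s3", "s4"],
    )


def test_dataprep_binary_passthrough(binary_df):
    out = dataprep(binary_df, PrepConfig())
    pd.testing.assert_frame_equal(out, binary_df)


def test_dataprep_threshold_boundary_semantics(abundance_df):
    absence = dataprep(
        abundance_df,
        PrepConfig(datatype="abundance", threshold=1.0,
                   class0_rule="absence-at-threshold"),
    )
    presence = dataprep(
        abundance_df,
        PrepConfig(datatype="abundance", threshold=1.0,
                   class0_rule="presence-at-threshold"),
    )
    # cells equal to the threshold flip between the two rules
    assert absence.loc["spB", "s1"] == 0
    assert presence.loc["spB", "s1"] == 1
    assert absence.loc["spA", "s2"] == presence.loc["spA", "s2"] == 1


def test_dataprep_rejects_nonbinary_values(abundance_df):
    with pytest.raises(ValueError, match="declared binary"):
        dataprep(abundance_df, PrepConfig(datatype="binary"))


def test_dataprep_rejects_missing_and_negative():
    df = pd.DataFrame([[1, 0], [0, np.nan]], index=["a", "b"], columns=["x", "y"])
    with pytest.raises(ValueError, match="missing value"):
        dataprep(df, PrepConfig())
    df2 = pd.DataFrame([[1, 0], [0, -1]], index=["a", "b"], columns=["x", "y"])
    with pytest.raises(ValueError, match="negative"):
        dataprep(df2, PrepConfig())


def test_dataprep_selection_and_unknown_labels(binary_df):
    out = dataprep(binary_df, PrepConfig(selection=["sp1", "sp3"]))
    assert list(out.index) == ["sp1", "sp3"]
    with pytest.raises(KeyError, match="nope"):
        dataprep(binary_df, PrepConfig(selection=["nope"]))


def test_records_match_componentwise_analysis(binary_df):
    """Each pairwise record equals the direct 2x2 analysis of its table."""
    records, prepped = pairwise_affinity(binary_df, PrepConfig())
    assert len(records) == 10
    for _, r in records.iterrows():
        t = Table2x2.from_counts(r["X"], r["mA"], r["mB"], r["N"])
        est = ml_alpha(t)
        ints = interval_set(t)
        idx = traditional_indices(t)
        assert r["alpha_mle"] == pytest.approx(est.estimate)
        assert r["blaker_lo"] == pytest.approx(ints.ci_blaker.lower)
        assert r["midp_hi"] == pytest.approx(ints.ci_midp.upper)
        assert r["jaccard"] == pytest.approx(idx.jaccard)
        assert r["X"] <= min(r["mA"], r["mB"])
        assert r["X"] >= r["mA"] + r["mB"] - r["N"]


def test_identical_and_disjoint_rows_flagged_extreme():
    df = pd.DataFrame(
        [[1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]],
        index=["a", "b", "c"],
        columns=[f"s{i}" for i in range(6)],
    )
    records, _ = pairwise_affinity(df, PrepConfig())
    ab = records[(records.entity_1 == "a") & (records.entity_2 == "b")].iloc[0]
    assert ab["X"] == 3 and ab["is_extreme_high"]
    assert ab["alpha_mle"] == pytest.approx(np.log(2 * 36))
    ac = records[(records.entity_1 == "a") & (records.entity_2 == "c")].iloc[0]
    assert ac["X"] == 0 and ac["is_extreme_low"]


def test_prevalence_zero_entity_reported_missing_not_dropped():
    df = pd.DataFrame(
        [[1, 0, 1, 0], [0, 0, 0, 0], [1, 1, 0, 0]],
        index=["a", "empty", "c"],
        columns=["s1", "s2", "s3", "s4"],
    )
    records, _ = pairwise_affinity(df, PrepConfig())
    row = records[(records.entity_1 == "a") & (records.entity_2 == "empty")].iloc[0]
    assert row["degenerate"]
    assert np.isnan(row["alpha_mle"])
    assert "not estimable" in row["reason"]
    # indices still defined where denominators allow
    assert row["jaccard"] == 0.0


def test_axis_duality_and_permutation_invariance(binary_df):
    by_cols, _ = pairwise_affinity(binary_df.T, PrepConfig(axis="cols"))
    by_rows, _ = pairwise_affinity(binary_df, PrepConfig(axis="rows"))
    pd.testing.assert_frame_equal(by_cols, by_rows)
    shuffled = binary_df.sample(frac=1, random_state=3)
    by_rows_shuffled, _ = pairwise_affinity(shuffled, PrepConfig())
    pd.testing.assert_frame_equal(by_rows, by_rows_shuffled)


def test_too_few_entities_errors(binary_df):
    with pytest.raises(ValueError, match="at least 2"):
        pairwise_affinity(binary_df.iloc[:1], PrepConfig())


def test_squareform_symmetric_with_nan_diagonal(binary_df):
    records, _ = pairwise_affinity(binary_df, PrepConfig())
    sq = squareform(records, "alpha_mle")
    assert list(sq.index) == sorted(binary_df.index)
    np.testing.assert_allclose(sq.values, sq.values.T)
    assert np.isnan(np.diag(sq.values)).all()
    r = records.iloc[3]
    assert sq.loc[r["entity_1"], r["entity_2"]] == pytest.approx(r["alpha_mle"])
    with pytest.raises(KeyError):
        squareform(records, "entity_1")


def test_read_matrix_round_trip(tmp_path, binary_df):
    p = tmp_path / "m.csv"
    binary_df.to_csv(p)
    df = read_matrix(p)
    pd.testing.assert_frame_equal(df, binary_df)
    # headerless mode generates labels
    p2 = tmp_path / "raw.csv"
    binary_df.to_csv(p2, header=False, index=False)
    df2 = read_matrix(p2, header=False)
    assert df2.shape == binary_df.shape
    assert list(df2.index)[:2] == ["r1", "r2"]
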