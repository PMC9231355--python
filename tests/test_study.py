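import numpy as np
import pandas as pd
import pytest

from dosestab import CANONICAL_ORDER, ErrorModel, PhantomSettings, ProtocolSpec
from dosestab import StabilityStudy, generate_cohort
from dosestab.pipeline import extract_patient_features
from dosestab.stability import CV_CATEGORIES


def _tidy_table(n_patients=3, groups=(2, 10), replicates=2, seed=0,
                zero_baseline=False, invalid_feature=False):
    """Hand-built complete tidy feature table with controllable quirks."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(1, 10, size=(n_patients, len(CANONICAL_ORDER)))
    if zero_baseline:
        base[0, 0] = 0.0
    rows = []
    for p in range(n_patients):
        for grp, reps in [("original", [-1])] + [
            (str(g), range(replicates)) for g in groups
        ]:
            for r in reps:
                noise = 0.0 if grp == "original" else rng.normal(0, 0.05, len(base[p]))
                for k, (cls, name) in enumerate(CANONICAL_ORDER):
                    valid = not (invalid_feature and (cls, name) == ("ngtdm", "Busyness"))
                    rows.append((p, "GTV", grp, r, cls, name,
                                 base[p, k] + (noise[k] if grp != "original" else 0.0),
                                 valid))
    return pd.DataFrame(rows, columns=[
        "patient", "roi", "fraction_group", "replicate",
        "feature_class", "feature_name", "value", "valid",
    ])


def test_fit_produces_complete_partitioned_tables():
    study = StabilityStudy(_tidy_table())
    res = study.fit()
    assert len(res.cv_table) == 2 * 93
    assert len(res.icc_table) == 2 * 93
    assert len(res.pd_table) == 2 * 93
    assert len(res.fraction_consistency) == 93
    counts = res.cv_category_counts
    assert (counts[list(CV_CATEGORIES) + ["undefined"]].sum(axis=1) == 93).all()
    assert res.icc_table["icc"].notna().all()
    assert res.icc_table["icc"].between(-1, 1).all()
    assert "Dosiomic feature stability" in res.summary()


def test_zero_baseline_patient_excluded_from_pd():
    res = StabilityStudy(_tidy_table(zero_baseline=True)).fit()
    first = res.pd_table[
        (res.pd_table["feature_class"] == CANONICAL_ORDER[0][0])
        & (res.pd_table["feature_name"] == CANONICAL_ORDER[0][1])
    ]
    assert (first["n_excluded"] == 1).all()
    assert first["pd_percent"].notna().all()  # other patients still average


def test_invalid_feature_reported_undefined():
    res = StabilityStudy(_tidy_table(invalid_feature=True)).fit()
    row = res.cv_table[(res.cv_table["feature_name"] == "Busyness")
                       & (res.cv_table["feature_class"] == "ngtdm")]
    assert (row["cv_category"] == "undefined").all()
    icc_row = res.icc_table[(res.icc_table["feature_name"] == "Busyness")
                            & (res.icc_table["feature_class"] == "ngtdm")]
    assert icc_row["icc"].isna().all()
    counts = res.cv_category_counts
    assert (counts["undefined"] == 1).all()
    assert (counts[list(CV_CATEGORIES) + ["undefined"]].sum(axis=1) == 93).all()


def test_incomplete_table_rejected():
    table = _tidy_table()
    with pytest.raises(ValueError, match="93"):
        StabilityStudy(table.iloc[:-1])
    with pytest.raises(ValueError, match="baseline"):
        StabilityStudy(table[table["fraction_group"] != "original"])
    with pytest.raises(ValueError, match="missing columns"):
        StabilityStudy(table.drop(columns="valid"))


def test_unstable_feature_binning():
    res = StabilityStudy(_tidy_table(seed=5)).fit()
    unstable = res.unstable_features(threshold=0.9)
    assert (unstable["icc"] < 0.9).all()
    assert set(unstable["icc_bin"].unique()) <= {
        "ICC < 0.5", "0.5 <= ICC < 0.75", "0.75 <= ICC < 0.9",
    }


def test_zero_error_protocol_gives_zero_cv_and_pd():
    """With no setup error every replicate equals the plan, so the study must
    report CV = 0, PD = 0 and perfect agreement for every defined feature."""
    settings = PhantomSettings(shape=(48, 48, 48), gtv_radius_mm=10.0)
    cohort = generate_cohort(2, base_seed=21, settings=settings)
    protocol = ProtocolSpec(fraction_groups=(2, 3), replicates=2, base_seed=21)
    model = ErrorModel(sd=(0.0, 0.0, 0.0))
    frames = [
        extract_patient_features(p, grid, masks, protocol, model, None)
        for p, (grid, masks) in enumerate(cohort)
    ]
    res = StabilityStudy(pd.concat(frames, ignore_index=True)).fit()
    defined = res.cv_table["cv_category"] != "undefined"
    assert defined.any()
    assert np.allclose(res.cv_table.loc[defined, "cv_percent"], 0.0, atol=1e-6)
    assert (res.cv_table.loc[defined, "cv_category"] == "very small").all()
    ok_pd = res.pd_table["pd_percent"].notna()
    assert np.allclose(res.pd_table.loc[ok_pd, "pd_percent"], 0.0, atol=1e-6)
    ok_icc = res.icc_table["icc"].notna()
    assert np.all(res.icc_table.loc[ok_icc, "icc"] > 0.999999)
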