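import numpy as np
import pandas as pd
import pytest
from scipy import stats

import genderdx as gx


@pytest.fixture(scope="session")
def score_bundle():
    """Full gender-score derivation at n=50,000 with 200 informative codes.

    Shared across tests that probe different properties of the same
    derivation (score calibration, Spearman agreement with the latent
    truth, screening recovery).
    """
    config = gx.SimConfig(n_persons=50_000, seed=101)
    cohort, lifetable, truth = gx.simulate_cohort(config)
    fold = gx.split_cohort(cohort, seed=101)
    cohort = cohort.assign(fold=fold)
    matrices = {
        f: gx.build_indicator_matrix(cohort[cohort["fold"] == f])
        for f in ("train", "valid", "test")
    }
    sexes = {
        f: cohort.loc[cohort["fold"] == f, "sex"].to_numpy()
        for f in ("train", "valid", "test")
    }
    kept = gx.filter_codes(
        matrices["train"], sexes["train"], matrices["valid"], sexes["valid"]
    )
    train_m = matrices["train"].subset_codes(kept)
    valid_m = matrices["valid"].subset_codes(kept)
    screen_train = gx.univariate_screen(train_m, sexes["train"])
    screen_valid = gx.univariate_screen(valid_m, sexes["valid"])
    selection = gx.select_codes(screen_train, screen_valid)
    selected = selection.loc[selection["selected"] == 1, "code"].tolist()
    model = gx.fit_score_model(train_m, sexes["train"], selected)
    train_scores = gx.score_persons(model, train_m)
    test_scores = gx.score_persons(model, matrices["test"])
    return {
        "config": config,
        "cohort": cohort,
        "truth": truth,
        "selection": selection,
        "selected": selected,
        "model": model,
        "train_sex": sexes["train"],
        "train_scores": train_scores,
        "test_scores": test_scores,
        "truth_test_scores": truth.bayes_optimal_score[
            (cohort["fold"] == "test").to_numpy()
        ],
        "screen_train": screen_train,
    }


@pytest.fixture()
def tiny_cohort():
    """Hand-written six-person cohort exercising every schema field."""
    return pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(6)],
            "sex": [1, 0, 1, 0, 1, 0],
            "age": [25, 40, 33, 61, 16, 50],
            "year": [2005, 2010, 2010, 2015, 2018, 2003],
            "codes": ["X1|Y2", "Y2", "X1", "", "X1|X1", "Z9"],
            "adg_score": [2.0, 1.0, np.nan, 3.0, 0.0, 2.0],
            "rurality": [0, 1, 0, 0, 1, 0],
            "income_quintile": [1, 3, 5, 2, 4, 3],
            "los_days": [3.0, 5.5, 2.0, np.nan, 1.0, 10.0],
            "severity": ["severe", "mild", "severe", "unknown", "severe", "moderate"],
            "mechanism": ["falls", "mvc", "struck", "falls", "cyclist", "other"],
            "death_within_30d": [0.0, 0.0, 1.0, 0.0, np.nan, 0.0],
            "followup_days": [30.0, 30.0, 4.0, 30.0, np.nan, 30.0],
            "discharge_location": ["home", None, "rehab", "home", "other", "ltc"],
            "sublocation": ["", "", "", "", "other_ama", ""],
            "record_source": ["acute", "ed", "acute", "acute", "acute", "acute"],
        }
    )


def two_proportion_z(k1, n1, k2, n2):
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se > 0, (p1 - p2) / se, 0.0)


def spearman(a, b) -> float:
    return float(stats.spearmanr(a, b).statistic)
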