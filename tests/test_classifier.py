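"""MVP classifier training/scoring and the validation diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest

import episignkit as ek
from episignkit.errors import AlignmentError, TrainingError
from episignkit.io_qc import BetaMatrix


def test_fold_partition_contract(planted_cohort, trained_model):
    sheet = planted_cohort.samples
    db = sheet.ids_in_group("database")
    membership = trained_model.fold_membership
    assert set(membership) == set(db)
    assert set(membership.values()) <= {0, 1, 2, 3}
    assert len(trained_model.folds) == 4
    # same seed -> identical fold assignment
    pool = ek.TrainingPool(
        sheet.ids_in_group("case"), sheet.ids_in_group("control"), db
    )
    model2 = ek.train_mvp(
        trained_model.episignature, planted_cohort.beta, pool, seed=7
    )
    assert model2.fold_membership == membership


def test_training_separability(planted_cohort, trained_model):
    sheet = planted_cohort.samples
    case, ctrl = sheet.ids_in_group("case"), sheet.ids_in_group("control")
    scores = ek.score_samples(trained_model, planted_cohort.beta, case + ctrl)
    s = scores.set_index("sample_id")["score"]
    assert (s.loc[case] > 0.9).all()
    assert (s.loc[ctrl] < 0.1).all()
    assert s.between(0, 1).all()


def test_database_samples_scored_by_held_out_fold(planted_cohort, trained_model):
    sheet = planted_cohort.samples
    db = sheet.ids_in_group("database")[:8]
    scores = ek.score_samples(trained_model, planted_cohort.beta, db)
    for _, row in scores.iterrows():
        assert row["held_out_fold"] == trained_model.fold_membership[row["sample_id"]]
        assert len(row["per_fold_scores"]) == 1


def test_mixture_sample_scores_between_pure_means(planted_cohort, trained_model):
    """A 50/50 case/control probe-mean mixture lands strictly between the
    pure group scores (the behaviour expected of partial signatures)."""
    sheet = planted_cohort.samples
    case, ctrl = sheet.ids_in_group("case"), sheet.ids_in_group("control")
    beta = planted_cohort.beta
    case_mean = beta.values[case].mean(axis=1)
    ctrl_mean = beta.values[ctrl].mean(axis=1)
    mix = 0.5 * (case_mean + ctrl_mean)
    aug = BetaMatrix(
        pd.concat(
            [beta.values,
             pd.DataFrame({"pure_case": case_mean, "pure_ctrl": ctrl_mean, "mix": mix})],
            axis=1,
        )
    )
    s = ek.score_samples(trained_model, aug, ["pure_case", "pure_ctrl", "mix"])
    s = s.set_index("sample_id")["score"]
    assert s["pure_ctrl"] < s["mix"] < s["pure_case"]


def test_score_unknown_sample_rejected(planted_cohort, trained_model):
    with pytest.raises(AlignmentError):
        ek.score_samples(trained_model, planted_cohort.beta, ["nope"])


def test_too_few_database_samples(planted_cohort, planted_signature):
    sheet = planted_cohort.samples
    with pytest.raises(TrainingError):
        ek.train_mvp(
            planted_signature, planted_cohort.beta,
            ek.TrainingPool(
                sheet.ids_in_group("case"), sheet.ids_in_group("control"),
                sheet.ids_in_group("database")[:2],
            ),
        )


def test_held_out_replicates_rank_correctly():
    """Cases held out of training outscore held-out controls pairwise."""
    cfg = ek.SimulationConfig(
        n_cases=36, n_controls=104, n_database=60, n_probes=5000,
        n_signature=150, seed=21,
    )
    c = ek.generate_cohort(cfg)
    sheet = c.samples
    all_cases = sheet.ids_in_group("case")
    all_ctrls = sheet.ids_in_group("control")
    train_cases, held_cases = all_cases[:16], all_cases[16:]
    train_ctrls, held_ctrls = all_ctrls[:64], all_ctrls[64:84]
    sub = sheet.data[
        sheet.data["sample_id"].isin(train_cases + train_ctrls)
    ].reset_index(drop=True)
    stats = ek.differential_analysis(
        c.beta.subset_samples(train_cases + train_ctrls),
        ek.SampleSheet(sub),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        episig = ek.select_probes(stats, c.beta, train_cases, train_ctrls)
    model = ek.train_mvp(
        episig, c.beta,
        ek.TrainingPool(train_cases, train_ctrls, sheet.ids_in_group("database")),
        seed=2,
    )
    s = ek.score_samples(model, c.beta, held_cases + held_ctrls).set_index("sample_id")["score"]
    wins = sum(
        s[hc] > s[hk] for hc, hk in zip(held_cases, held_ctrls)
    )
    assert wins == len(held_cases)  # 20/20 paired draws


def test_loocv_report_shape_and_recovery(planted_cohort):
    sheet = planted_cohort.samples
    cases = sheet.ids_in_group("case")[:6]
    ctrls = sheet.ids_in_group("control")
    pool = ek.TrainingPool(cases, ctrls, sheet.ids_in_group("database"))
    report = ek.loocv_discovery(planted_cohort.beta, sheet, pool, seed=1)
    assert len(report) == 6
    assert (report["held_out_score"] > 0.5).all()
    assert (report["jaccard_vs_full"] > 0.5).all()


# ---------------------------------------------------------------------------
# MDS and clustering


def _beta_from(mat, sample_ids):
    return BetaMatrix(
        pd.DataFrame(
            mat, index=[f"cg{i}" for i in range(mat.shape[0])], columns=sample_ids
        )
    )


def test_mds_equilateral_triangle():
    # three mutually equidistant one-hot-ish samples
    mat = np.array([[0.9, 0.1, 0.1], [0.1, 0.9, 0.1], [0.1, 0.1, 0.9]])
    coords = ek.mds_embedding(_beta_from(mat, ["a", "b", "c"]), ["a", "b", "c"])
    from scipy.spatial.distance import pdist

    d = pdist(coords.to_numpy())
    assert np.allclose(d, d[0], atol=1e-9)


def test_mds_duplicate_sample_identical_coords():
    rng = np.random.default_rng(0)
    mat = rng.uniform(0, 1, size=(20, 3))
    mat = np.column_stack([mat, mat[:, 0]])
    coords = ek.mds_embedding(_beta_from(mat, ["a", "b", "c", "a2"]), ["a", "b", "c", "a2"])
    assert np.allclose(coords.loc["a"], coords.loc["a2"], atol=1e-9)


def test_mds_separates_clusters(planted_cohort, planted_signature):
    sheet = planted_cohort.samples
    case, ctrl = sheet.ids_in_group("case"), sheet.ids_in_group("control")
    beta = planted_cohort.beta.subset_probes(planted_signature.probe_ids)
    coords = ek.mds_embedding(beta, case + ctrl)
    cm = coords.loc[case].mean()
    km = coords.loc[ctrl].mean()
    between = np.linalg.norm(cm - km)
    within = np.concatenate(
        [np.linalg.norm(coords.loc[case] - cm, axis=1),
         np.linalg.norm(coords.loc[ctrl] - km, axis=1)]
    ).mean()
    assert between > 5 * within


def test_hierarchical_cases_form_subtree():
    from scipy.cluster.hierarchy import fcluster

    pure = 0
    for seed in range(10):
        cfg = ek.SimulationConfig(
            n_probes=1000, n_signature=100, n_database=0, n_controls=32, seed=300 + seed
        )
        c = ek.generate_cohort(cfg)
        sheet = c.samples
        case, ctrl = sheet.ids_in_group("case"), sheet.ids_in_group("control")
        beta = c.beta.subset_probes(sorted(c.truth_probes))
        Z, leaves = ek.hierarchical_order(beta, case + ctrl)
        labels = fcluster(Z, t=2, criterion="maxclust")
        ordered = sorted(case + ctrl)
        case_labels = {labels[ordered.index(s)] for s in case}
        ctrl_labels = {labels[ordered.index(s)] for s in ctrl}
        pure += len(case_labels) == 1 and case_labels.isdisjoint(ctrl_labels)
    assert pure >= 9


def test_hierarchical_two_samples_and_order_invariance():
    rng = np.random.default_rng(2)
    mat = rng.uniform(0, 1, size=(30, 4))
    ids = ["a", "b", "c", "d"]
    Z1, _ = ek.hierarchical_order(_beta_from(mat, ids), ids)
    Z2, _ = ek.hierarchical_order(_beta_from(mat, ids), ids[::-1])
    assert np.allclose(sorted(Z1[:, 2]), sorted(Z2[:, 2]), atol=1e-9)
    Z, leaves = ek.hierarchical_order(_beta_from(mat[:, :2], ["a", "b"]), ["a", "b"])
    assert Z.shape[0] == 1 and set(leaves) == {"a", "b"}
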