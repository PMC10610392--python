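"""Ward clustering into tolerance categories and LDA validation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import adjusted_rand_score

from metsel import datasets
from metsel.classify import (
    agreement_table,
    lda_fit,
    lda_loo,
    ward_cluster,
)
from metsel.errors import MetselError


def gaussian_groups(k=3, per=8, p=4, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, size=(k, p))
    X = np.vstack([centers[i] + rng.normal(size=(per, p)) for i in range(k)])
    labels = np.repeat([f"grp{i}" for i in range(k)], per)
    idx = [f"G{i:02d}" for i in range(k * per)]
    return (
        pd.DataFrame(X, index=idx, columns=[f"t{j}" for j in range(p)]),
        pd.Series(labels, index=idx),
    )


def test_well_separated_groups_recovered_exactly():
    X, truth = gaussian_groups(k=5, per=5, sep=10.0, seed=1)
    X["GY"] = X["t0"]
    res = ward_cluster(X, k=5)
    assert adjusted_rand_score(truth, res.labels) == 1.0
    assert sorted(res.labels.unique()) == sorted(
        ["HT", "T", "M", "S", "HS"]
    )


def test_categories_ordered_by_descending_gy():
    X, _ = gaussian_groups(k=5, per=4, sep=8.0, seed=2)
    X["GY"] = X["t0"]
    res = ward_cluster(X, k=5)
    means = res.cluster_means["GY"]
    order = [c for c in ["HT", "T", "M", "S", "HS"] if c in means.index]
    assert (means.reindex(order).diff().dropna() < 0).all()


def test_cluster_invariant_to_row_order():
    X, _ = gaussian_groups(k=4, per=5, sep=6.0, seed=3)
    X["GY"] = X["t1"]
    res1 = ward_cluster(X, k=4)
    shuffled = X.sample(frac=1.0, random_state=0)
    res2 = ward_cluster(shuffled, k=4)
    joined = pd.concat(
        [res1.labels.rename("a"), res2.labels.rename("b")], axis=1
    )
    assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0


def test_duplicate_rows_merge_at_height_zero():
    X, _ = gaussian_groups(k=2, per=4, sep=5.0, seed=4)
    X["GY"] = X["t0"]
    X.iloc[1] = X.iloc[0]
    res = ward_cluster(X, k=2)
    assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    tiny = X.iloc[[0, 0, 0, 2, 2, 2]].copy()
    tiny.index = list("abcdef")
    with pytest.raises(MetselError):
        ward_cluster(tiny, k=5)


def test_standardization_and_heatmap_clipping():
    X, _ = gaussian_groups(k=3, per=6, sep=9.0, seed=5)
    X["GY"] = X["t2"]
    res = ward_cluster(X, k=3)
    assert np.allclose(res.standardized.mean(), 0.0, atol=1e-12)
    assert np.allclose(res.standardized.std(ddof=1), 1.0, atol=1e-12)
    assert res.heatmap.to_numpy().max() <= 3.0
    assert res.heatmap.to_numpy().min() >= -3.0
    assert set(res.row_order) == set(X.index)


def test_lda_separable_groups_resubstitution_perfect():
    X, labels = gaussian_groups(k=2, per=10, p=1, sep=10.0, seed=6)
    model = lda_fit(X, labels)
    report = model.classify(X)
    assert report.percent_correct == 100.0
    assert report.misclassified == []
    # decision boundary lies between the group means on the predictor
    m = model.means["t0"]
    assert m.min() < m.mean() < m.max()


def test_posteriors_sum_to_one_and_argmax_consistent():
    X, labels = gaussian_groups(k=3, per=6, sep=2.0, seed=7)
    model = lda_fit(X, labels)
    post = model.posterior(X)
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)
    report = model.classify(X)
    assert (post.idxmax(axis=1) == report.table["posterior"]).all()


def test_identical_groups_posterior_near_priors():
    rng = np.random.default_rng(8)
    post_means = []
    for _ in range(200):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        labels = pd.Series(["u"] * 20 + ["v"] * 10, index=X.index)
        model = lda_fit(X, labels)
        post_means.append(model.posterior(X).mean())
    avg = pd.concat(post_means, axis=1).mean(axis=1)
    assert avg["u"] == pytest.approx(2 / 3, abs=0.05)
    assert avg["v"] == pytest.approx(1 / 3, abs=0.05)


def test_wide_predictor_matrix_uses_pseudo_inverse():
    rng = np.random.default_rng(9)
    X = pd.DataFrame(rng.normal(size=(20, 20)),
                     columns=[f"t{j}" for j in range(20)])
    labels = pd.Series(
        ["a"] * 5 + ["b"] * 5 + ["c"] * 4 + ["d"] * 3 + ["e"] * 3,
        index=X.index,
    )
    model = lda_fit(X, labels)
    assert model.pseudo_inverted
    report = model.classify(X)
    assert report.percent_correct == 100.0


def test_lda_matches_sklearn_on_nonsingular_data():
    X, labels = gaussian_groups(k=3, per=10, p=3, sep=3.0, seed=10)
    model = lda_fit(X, labels, prior_mode="proportional")
    ours = model.posterior(X)
    sk = LinearDiscriminantAnalysis(solver="svd")
    sk.fit(X, labels)
    theirs = pd.DataFrame(sk.predict_proba(X), index=X.index,
                          columns=sk.classes_)
    assert np.allclose(ours[theirs.columns], theirs, atol=1e-6)


def test_affine_invariance_of_decisions():
    X, labels = gaussian_groups(k=3, per=8, p=3, sep=3.0, seed=11)
    base = lda_fit(X, labels).classify(X).table["posterior"]
    X2 = X * np.array([3.0, 0.2, 11.0]) + np.array([5.0, -2.0, 0.4])
    moved = lda_fit(X2, labels).classify(X2).table["posterior"]
    assert (base == moved).all()


def test_loo_matches_brute_force_refit_loop():
    X, labels = gaussian_groups(k=3, per=5, p=2, sep=2.5, seed=12)
    report = lda_loo(X, labels)
    for idx in X.index:
        mask = X.index != idx
        model = lda_fit(X[mask], labels[mask])
        expected = model.posterior(X.loc[[idx]]).idxmax(axis=1).iloc[0]
        assert report.table.loc[idx, "posterior"] == expected


def test_loo_never_beats_resubstitution_on_average():
    resub_scores, loo_scores = [], []
    for seed in range(100):
        X, labels = gaussian_groups(k=3, per=5, p=2, sep=1.0,
                                    seed=100 + seed)
        model = lda_fit(X, labels)
        resub_scores.append(model.classify(X).percent_correct)
        loo_scores.append(lda_loo(X, labels).percent_correct)
    assert np.mean(loo_scores) <= np.mean(resub_scores)


def test_separable_case_loo_equals_resubstitution():
    X, labels = gaussian_groups(k=2, per=12, p=2, sep=15.0, seed=13)
    model = lda_fit(X, labels)
    assert model.classify(X).percent_correct == 100.0
    assert lda_loo(X, labels).percent_correct == 100.0


def test_agreement_table_and_moved_items():
    prior = pd.Series(list("aabb"), index=list("wxyz"))
    same = agreement_table(prior, prior)
    assert same["percent_correct"] == 100.0
    moved = prior.copy()
    moved["w"] = "b"
    out = agreement_table(prior, moved)
    assert out["percent_correct"] == 75.0
    assert out["moved"] == [{"item": "w", "from": "a", "to": "b"}]
    with pytest.raises(ValueError):
        agreement_table(prior, pd.Series(list("aacc"), index=list("wxyz")))


def test_published_prior_posterior_misclassified_set():
    table = datasets.load_smlr_table()
    out = agreement_table(table["prior_group"], table["posterior_group"])
    assert out["percent_correct"] == 75.0
    assert sorted(m["item"] for m in out["moved"]) == [
        "G04", "G07", "G12", "G17", "G20",
    ]


def test_published_predictors_lda_agreement_documented():
    """LDA refit on the printed genotype-mean predictors: the computed
    resubstitution agreement under both prior conventions, deterministic
    and well below the published summary figure (whose fit evidently used
    unprinted replicate-level data) — the discrepancy is asserted, not
    hidden."""
    table = datasets.load_smlr_table()
    X = table[["DH", "TKW", "CT", "Pn"]]
    labels = table["prior_group"]
    results = {}
    for mode in ("proportional", "equal"):
        model = lda_fit(X, labels, prior_mode=mode)
        results[mode] = model.classify(X).percent_correct
    assert results["proportional"] == pytest.approx(35.0)
    assert results["equal"] == pytest.approx(35.0)
    # the printed misclassified set is a subset of ours in both modes
    for mode in ("proportional", "equal"):
        model = lda_fit(X, labels, prior_mode=mode)
        mis = set(model.classify(X).misclassified)
        assert {"G04", "G07", "G12", "G17", "G20"} <= mis
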