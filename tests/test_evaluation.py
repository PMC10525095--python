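"""Study protocol: patient-wise stratified splits, five-fold CV, bootstrap
re-training, and the Wilcoxon signed-rank comparison."""

from dataclasses import dataclass

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from vitstack.evaluation import (BootstrapDistribution, SplitError,
                                 bootstrap_train_eval, compare_models,
                                 five_fold_cv, stratified_split)
from conftest import make_manifest


class TestStratifiedSplit:
    def test_112_cohort_gives_22_test_lesions(self):
        man = make_manifest()
        plan = stratified_split(man, 0.2, seed=3)
        assert len(plan.indices("test")) == 22
        assert len(plan.indices("train")) == 90

    def test_no_patient_leakage(self):
        man = make_manifest(seed=5)
        for seed in range(3):
            plan = stratified_split(man, 0.2, seed=seed)
            test_p = set(man.loc[plan.indices("test"), "patient_id"])
            train_p = set(man.loc[plan.indices("train"), "patient_id"])
            assert not (test_p & train_p)

    def test_per_stratum_counts_follow_largest_remainder(self):
        man = make_manifest(seed=1)
        plan = stratified_split(man, 0.2, seed=0)
        test = man.loc[plan.indices("test")]
        sizes = man.groupby(["label", "zone"]).size()
        # independent largest-remainder apportionment of 22 across strata
        quotas = {k: v * 22 / 112 for k, v in sizes.items()}
        counts = {k: int(np.floor(q)) for k, q in quotas.items()}
        short = 22 - sum(counts.values())
        for k in sorted(quotas, key=lambda k: quotas[k] - counts[k],
                        reverse=True)[:short]:
            counts[k] += 1
        observed = test.groupby(["label", "zone"]).size().to_dict()
        assert observed == {k: v for k, v in counts.items() if v > 0}

    def test_zero_fraction_puts_everything_in_train(self):
        man = make_manifest()
        plan = stratified_split(man, 0.0, seed=0)
        assert len(plan.indices("test")) == 0
        assert len(plan.indices("train")) == 112

    def test_infeasible_stratum_signalled(self):
        import pandas as pd
        # one giant patient owns the whole sole stratum: no pure subset fits
        man = pd.DataFrame({"patient_id": ["P0"] * 10,
                            "label": [0] * 10, "zone": ["PZ"] * 10})
        with pytest.raises(SplitError):
            stratified_split(man, 0.2, seed=0)

    def test_seeded_reproducibility(self):
        man = make_manifest()
        a = stratified_split(man, 0.2, seed=9)
        b = stratified_split(man, 0.2, seed=9)
        assert a.assignment == b.assignment


class TestFiveFold:
    def test_partition_property(self):
        man = make_manifest()
        plans = five_fold_cv(man, seed=2)
        all_val = sorted(i for p in plans for i in p.indices("val"))
        assert all_val == list(range(112))

    def test_90_lesion_folds_are_18_each(self):
        man = make_manifest().iloc[:90].reset_index(drop=True)
        plans = five_fold_cv(man, seed=1)
        sizes = sorted(len(p.indices("val")) for p in plans)
        assert all(17 <= s <= 19 for s in sizes)
        assert sum(sizes) == 90

    def test_patient_wise_folds(self):
        man = make_manifest(seed=3)
        plans = five_fold_cv(man, seed=0)
        for p in plans:
            val_p = set(man.loc[p.indices("val"), "patient_id"])
            train_p = set(man.loc[p.indices("train"), "patient_id"])
            assert not (val_p & train_p)

    def test_stratum_spread_across_folds_is_tight(self):
        # single-lesion patients: each (grade, zone) stratum spreads across
        # folds within one lesion; multi-lesion patients loosen this slightly
        man = make_manifest(n=110, n_patients=110, n_lg=76,
                            zone_counts=(49, 46, 15), seed=2)
        plans = five_fold_cv(man, seed=4)
        for label in (0, 1):
            for zone in ("PZ", "AS", "TZ"):
                counts = []
                for p in plans:
                    sub = man.loc[p.indices("val")]
                    counts.append(int(((sub.label == label)
                                       & (sub.zone == zone)).sum()))
                assert max(counts) - min(counts) <= 1

    def test_same_seed_identical_folds(self):
        man = make_manifest()
        a = five_fold_cv(man, seed=7)
        b = five_fold_cv(man, seed=7)
        for pa, pb in zip(a, b):
            assert pa.assignment == pb.assignment

    def test_too_few_patients_rejected(self):
        import pandas as pd
        man = pd.DataFrame({"patient_id": ["P0", "P1", "P2"] ,
                            "label": [0, 1, 0], "zone": ["PZ"] * 3})
        with pytest.raises(ValueError):
            five_fold_cv(man, seed=0)


@dataclass(frozen=True)
class Rec:
    """A minimal item: one scalar feature and a label."""

    x: float
    label: int


def linear_builder(train, seed):
    X = np.array([[r.x] for r in train])
    y = np.array([r.label for r in train])
    if y.min() == y.max():  # degenerate resample: constant predictor
        return lambda items: np.full(len(items), 0.5 + 1e-6 * y[0])
    clf = LogisticRegression().fit(X, y)
    return lambda items: clf.predict_proba(
        np.array([[r.x] for r in items]))[:, 1]


def toy_population(n=60, seed=0):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=n)
    x = rng.normal(loc=1.5 * labels, scale=1.0)
    return [Rec(float(v), int(l)) for v, l in zip(x, labels)]


class TestBootstrap:
    def test_100_values_median_and_percentile_ci(self):
        pop = toy_population()
        dists = bootstrap_train_eval(pop[:40], pop[40:], linear_builder,
                                     n=100, seed=1)
        assert set(dists) == {"specificity", "sensitivity",
                              "balanced_accuracy", "auroc", "auprc", "csp",
                              "cse", "bs", "bsnc", "bspc"}
        for d in dists.values():
            assert len(d.values) == 100
            assert d.median == pytest.approx(np.percentile(d.values, 50))
            assert d.ci_low == pytest.approx(np.percentile(d.values, 2.5))
            assert d.ci_high == pytest.approx(np.percentile(d.values, 97.5))
            assert d.ci_low <= d.median <= d.ci_high

    def test_constant_model_zero_width_ci(self):
        pop = toy_population()

        def constant_builder(train, seed):
            return lambda items: np.array([0.9 if r.label else 0.1
                                           for r in items])

        dists = bootstrap_train_eval(pop[:40], pop[40:], constant_builder,
                                     n=20, seed=2)
        for d in dists.values():
            assert d.ci_high - d.ci_low == 0.0

    def test_seeded_reproducibility(self):
        pop = toy_population()
        a = bootstrap_train_eval(pop[:40], pop[40:], linear_builder, n=10, seed=5)
        b = bootstrap_train_eval(pop[:40], pop[40:], linear_builder, n=10, seed=5)
        for m in a:
            assert np.array_equal(a[m].values, b[m].values)

    def test_invalid_n_rejected(self):
        pop = toy_population()
        with pytest.raises(ValueError):
            bootstrap_train_eval(pop[:40], pop[40:], linear_builder, n=0)


def signed_rank_oracle(diff):
    """Hand-rolled Wilcoxon W: rank |nonzero diffs|, return min rank sum."""
    d = np.asarray([x for x in diff if x != 0], dtype=float)
    order = np.argsort(np.abs(d), kind="stable")
    ranks = np.empty(len(d))
    sorted_abs = np.abs(d)[order]
    i = 0
    while i < len(d):
        j = i
        while j < len(d) and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2  # average rank for ties (1-based)
        i = j
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    return min(w_pos, w_neg)


class TestCompareModels:
    def test_identical_distributions_reported_degenerate(self):
        v = np.linspace(0.1, 0.9, 30)
        r = compare_models(v, v.copy())
        assert r.degenerate and r.W == 0.0 and r.p == 1.0 and not r.significant

    def test_large_constant_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=100)
        r = compare_models(a, a + 10.0)
        assert r.p < 0.001 and r.significant

    def test_statistic_matches_hand_ranked_oracle(self):
        a = np.array([0.62, 0.55, 0.70, 0.48, 0.66, 0.59, 0.71, 0.53, 0.64, 0.60])
        b = np.array([0.58, 0.57, 0.64, 0.50, 0.61, 0.59, 0.77, 0.49, 0.60, 0.66])
        r = compare_models(a, b)
        assert r.W == pytest.approx(signed_rank_oracle(a - b))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_models(np.ones(5), np.ones(6))

    def test_shapiro_pvalues_recorded(self):
        rng = np.random.default_rng(1)
        r = compare_models(rng.normal(size=50), rng.uniform(size=50))
        assert 0 <= r.shapiro_p_a <= 1 and 0 <= r.shapiro_p_b <= 1
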