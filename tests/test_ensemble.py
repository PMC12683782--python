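"""Uniform and learned stacking, SMOTE rebalancing, meta-model training."""

import numpy as np
import pandas as pd
import pytest

import ensembleage as ea
from ensembleage.ensemble import assign_age_bins


def _table(values, clocks, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"S{i}" for i in range(values.shape[0])]
    return ea.PredictionTable(
        ages=pd.DataFrame(values, index=samples, columns=clocks)
    )


class TestEnsembleNaive:
    def test_mean_of_six(self):
        t = _table(
            [[10, 20, 30, 40, 50, 60]],
            ["AltumAge", "Han2020", "Horvath", "SkinBlood", "YingCausAge",
             "Zhang2019"],
        )
        assert ea.ensemble_naive(t).iloc[0] == 35.0

    def test_single_clock_selection_is_identity(self):
        t = _table([[42.0, 7.0]], ["A", "B"])
        assert ea.ensemble_naive(t, ["A"]).iloc[0] == 42.0

    def test_default_selection_excludes_hannum_and_phenoage(self):
        names = list(ea.PUBLISHED_CLOCK_NAMES)
        vals = np.arange(8, dtype=float)[None, :]
        t = _table(vals, names)
        expected = np.mean(
            [vals[0, names.index(n)] for n in ea.DEFAULT_NAIVE_SELECTION]
        )
        assert ea.ensemble_naive(t).iloc[0] == expected
        assert set(ea.DEFAULT_NAIVE_SELECTION) == set(names) - {
            "Hannum",
            "PhenoAge",
        }

    def test_unknown_clock_rejected(self):
        t = _table([[1.0]], ["A"])
        with pytest.raises(ea.UsageError):
            ea.ensemble_naive(t, ["Nope"])

    def test_equals_brute_force_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, size=(20, 8))
        names = [f"C{i}" for i in range(8)]
        t = _table(vals, names)
        sel = names[1:6]
        out = ea.ensemble_naive(t, sel)
        brute = vals[:, 1:6].mean(axis=1)
        np.testing.assert_allclose(out.to_numpy(), brute, atol=1e-12)


class TestEnsembleLrPredict:
    def test_zero_predictions_return_packaged_intercept(self):
        model = ea.load_paper_model()
        t = _table(np.zeros((1, 8)), list(model.clock_names))
        assert ea.ensemble_lr_predict(t, model).iloc[0] == 19.28

    def test_constant_fifty_prediction(self):
        model = ea.load_paper_model()
        t = _table(np.full((1, 8), 50.0), list(model.clock_names))
        # 50 * sum(w) + 19.28, with sum(w) = 0.53
        assert ea.ensemble_lr_predict(t, model).iloc[0] == pytest.approx(
            45.78, abs=1e-9
        )

    def test_zero_weights_return_intercept_for_any_table(self):
        model = ea.EnsembleLRModel(("A", "B"), np.zeros(2), 5.0)
        rng = np.random.default_rng(1)
        t = _table(rng.uniform(0, 90, size=(6, 2)), ["A", "B"])
        assert (ea.ensemble_lr_predict(t, model) == 5.0).all()

    def test_matches_by_name_not_position(self):
        model = ea.EnsembleLRModel(("A", "B"), np.array([1.0, 0.0]), 0.0)
        t = _table([[7.0, 3.0]], ["B", "A"])  # reversed column order
        assert ea.ensemble_lr_predict(t, model).iloc[0] == 3.0

    def test_missing_column_named_in_error(self):
        model = ea.EnsembleLRModel(("A", "B"), np.ones(2), 0.0)
        t = _table([[1.0]], ["A"])
        with pytest.raises(ea.UsageError, match="B"):
            ea.ensemble_lr_predict(t, model)

    def test_affine_in_base_predictions(self):
        rng = np.random.default_rng(2)
        model = ea.EnsembleLRModel(
            ("A", "B", "C"), rng.normal(size=3), float(rng.normal())
        )
        vals = rng.uniform(20, 80, size=(10, 3))
        t1 = _table(vals, ["A", "B", "C"])
        t2 = _table(2 * vals, ["A", "B", "C"])
        p1 = ea.ensemble_lr_predict(t1, model).to_numpy()
        p2 = ea.ensemble_lr_predict(t2, model).to_numpy()
        np.testing.assert_allclose(
            p2, 2 * p1 - model.intercept, atol=1e-9
        )

    def test_model_json_round_trip(self, tmp_path):
        model = ea.EnsembleLRModel(
            ("A", "B"), np.array([0.25, -0.5]), 12.5, alpha=0.1,
            provenance="test",
        )
        path = tmp_path / "m.json"
        model.to_json(path)
        back = ea.EnsembleLRModel.from_json(path)
        assert back.clock_names == model.clock_names
        assert (back.weights == model.weights).all()
        assert back.intercept == model.intercept


def _imbalanced_cohort(seed=17, n=240):
    spec = ea.CohortSpec(
        n_samples=n,
        n_cpgs=30,
        n_age_cpgs=14,
        noise_sd=0.02,
        seed=seed,
        age_distribution=ea.AgeDistribution.gtex_like_midheavy,
    )
    matrix, meta = ea.generate_cohort(spec)
    return spec, matrix, meta.ages_for(matrix.sample_ids)


class TestSmote:
    def test_bins_equalized_to_target(self):
        _, matrix, ages = _imbalanced_cohort()
        cfg = ea.SmoteConfig(seed=0)
        aug, aug_ages, flags = ea.smote_oversample(matrix, ages, cfg)
        bins = assign_age_bins(aug_ages, cfg.age_bins)
        counts = np.bincount(bins)
        assert (counts == counts.max()).all()
        assert flags.sum() == aug.n_samples - matrix.n_samples

    def test_synthetic_betas_are_convex_combinations(self):
        _, matrix, ages = _imbalanced_cohort(seed=18)
        aug, _, flags = ea.smote_oversample(
            matrix, ages, ea.SmoteConfig(seed=1)
        )
        synth = aug.betas.loc[flags].to_numpy()
        lo = matrix.betas.to_numpy().min()
        hi = matrix.betas.to_numpy().max()
        assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()
        assert ((synth >= 0) & (synth <= 1)).all()

    def test_two_member_bin_interpolates_on_segment(self):
        cols = [f"cg{j:08d}" for j in range(1, 4)]
        df = pd.DataFrame(
            [[0.2, 0.4, 0.6], [0.4, 0.8, 0.2], [0.5, 0.5, 0.5],
             [0.55, 0.45, 0.5], [0.5, 0.55, 0.45]],
            index=[f"S{i}" for i in range(5)],
            columns=cols,
        )
        # bin [20,30) has exactly two members; [40,50) has three
        ages = pd.Series([22.0, 28.0, 44.0, 45.0, 46.0], index=df.index)
        with pytest.warns(UserWarning, match="k_neighbors reduced"):
            aug, aug_ages, flags = ea.smote_oversample(
                ea.MethylationMatrix(df),
                ages,
                ea.SmoteConfig(k_neighbors=5, seed=2),
            )
        synth = aug.betas.loc[flags]
        p, q = df.iloc[0].to_numpy(), df.iloc[1].to_numpy()
        for _, row in synth.iterrows():
            x = row.to_numpy()
            if not (22.0 <= aug_ages[row.name] <= 28.0):
                continue  # synthetic sample from the other bin
            # on the segment: x = p + u (q - p) with one consistent u
            with np.errstate(divide="ignore", invalid="ignore"):
                u = (x - p) / (q - p)
            u = u[np.isfinite(u)]
            assert np.allclose(u, u[0], atol=1e-9)
            assert 0.0 <= u[0] <= 1.0

    def test_interpolated_age_stays_in_parent_bin(self):
        _, matrix, ages = _imbalanced_cohort(seed=19)
        cfg = ea.SmoteConfig(seed=3)
        aug, aug_ages, flags = ea.smote_oversample(matrix, ages, cfg)
        real_bins = assign_age_bins(ages, cfg.age_bins)
        synth_ages = aug_ages[flags.to_numpy()]
        for b in np.unique(real_bins):
            in_bin = ages[real_bins == b]
            sel = (synth_ages >= cfg.age_bins[b]) & (
                synth_ages <= cfg.age_bins[b + 1]
            )
            # every synthetic age in this bin is within the real span
            sub = synth_ages[sel.to_numpy()]
            if len(sub):
                assert sub.min() >= in_bin.min() - 1e-9
                assert sub.max() <= in_bin.max() + 1e-9

    def test_reproducible_under_seed(self):
        _, matrix, ages = _imbalanced_cohort(seed=20)
        cfg = ea.SmoteConfig(seed=5)
        a1, ages1, _ = ea.smote_oversample(matrix, ages, cfg)
        a2, ages2, _ = ea.smote_oversample(matrix, ages, cfg)
        assert (a1.betas.to_numpy() == a2.betas.to_numpy()).all()
        assert (ages1.to_numpy() == ages2.to_numpy()).all()

    def test_single_member_bin_duplicated_with_warning(self):
        cols = ["cg00000001"]
        df = pd.DataFrame(
            [[0.2], [0.5], [0.6], [0.7]],
            index=["A", "B", "C", "D"],
            columns=cols,
        )
        ages = pd.Series([25.0, 45.0, 46.0, 47.0], index=df.index)
        with pytest.warns(UserWarning, match="single sample"):
            aug, aug_ages, flags = ea.smote_oversample(
                ea.MethylationMatrix(df), ages, ea.SmoteConfig(seed=0)
            )
        assert (aug.betas.loc[flags, "cg00000001"] == 0.2).all()

    def test_requires_complete_matrix(self, small_matrix):
        ages = pd.Series([30.0, 40.0, 50.0], index=small_matrix.sample_ids)
        with pytest.raises(ea.StateError):
            ea.smote_oversample(small_matrix, ages, ea.SmoteConfig())


def _closed_form_ridge(X, y, alpha):
    """Independent oracle: (X'X + aI)^-1 X'y with unpenalized intercept,
    via centering."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    w = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(X.shape[1]), Xc.T @ yc)
    b = y.mean() - X.mean(axis=0) @ w
    return w, b


class TestTrainEnsembleLr:
    def test_recovers_known_mixture_at_tiny_alpha(self):
        """True age = 0.5*clockA + 0.5*clockB exactly, with the two
        clocks' errors varying independently (clockA also loads on
        age-independent CpGs, clockB cancels that load)."""
        rng = np.random.default_rng(31)
        n, m_age, m_noise = 200, 8, 8
        ages = rng.uniform(20, 80, size=n)
        slopes = np.where(np.arange(m_age) % 2 == 0, 0.5, -0.5)
        age_betas = 0.5 + slopes[None, :] * (ages[:, None] - 50.0) / 100.0
        noise_betas = rng.uniform(0.2, 0.8, size=(n, m_noise))
        cols = [f"cg{j:08d}" for j in range(1, m_age + m_noise + 1)]
        matrix = ea.MethylationMatrix(
            pd.DataFrame(
                np.column_stack([age_betas, noise_betas]),
                index=[f"S{i}" for i in range(n)],
                columns=cols,
            )
        )
        # exact oracle over the age CpGs, zero-padded on the noise CpGs
        w_oracle = np.concatenate(
            [100.0 / (m_age * slopes), np.zeros(m_noise)]
        )
        b_oracle = 50.0 - np.sum(100.0 * 0.5 / (m_age * slopes))
        # clockA = age + 8*(noise betas sum - centering); clockB cancels it
        w_a = w_oracle + np.concatenate(
            [np.zeros(m_age), np.full(m_noise, 8.0)]
        )
        a = ea.ClockDefinition(
            "clockA", cols, w_a, b_oracle - 8.0 * m_noise * 0.5
        )
        b = ea.ClockDefinition(
            "clockB", cols, 2.0 * w_oracle - w_a,
            2.0 * b_oracle - a.intercept,
        )
        model, _ = ea.train_ensemble_lr(
            matrix,
            pd.Series(ages, index=matrix.sample_ids),
            [a, b],
            alpha=1e-6,
            split=0.8,
            seed=0,
        )
        np.testing.assert_allclose(model.weights, [0.5, 0.5], atol=0.01)

    def test_matches_closed_form_ridge_on_same_split(self):
        spec = ea.CohortSpec(
            n_samples=160, n_cpgs=24, n_age_cpgs=12, noise_sd=0.03, seed=32
        )
        matrix, meta = ea.generate_cohort(spec)
        ages = meta.ages_for(matrix.sample_ids)
        clocks = [
            ea.generate_oracle_clock(spec),
            ea.generate_distractor_clock(spec, 61, "D1"),
            ea.generate_distractor_clock(spec, 62, "D2"),
        ]
        alpha, seed = 0.1, 4
        cfg = ea.SmoteConfig(seed=seed)
        model, _ = ea.train_ensemble_lr(
            matrix, ages, clocks, alpha=alpha, split=0.8, seed=seed,
            smote=cfg,
        )
        # replicate the pipeline deterministically and solve in closed form
        from sklearn.model_selection import train_test_split

        union = sorted(set().union(*(c.cpg_set for c in clocks)))
        keep = [c for c in matrix.betas.columns if c in set(union)]
        restricted = ea.MethylationMatrix(matrix.betas[keep])
        aug, aug_ages, _ = ea.smote_oversample(restricted, ages, cfg)
        table = ea.predict_all(aug, clocks)
        X = table.ages.to_numpy()
        y = aug_ages.to_numpy()
        strata = assign_age_bins(aug_ages, cfg.age_bins)
        idx = np.arange(len(y))
        tr, _te = train_test_split(
            idx, train_size=0.8, random_state=seed, stratify=strata
        )
        w, b = _closed_form_ridge(X[tr], y[tr], alpha)
        np.testing.assert_allclose(model.weights, w, atol=1e-6)
        assert model.intercept == pytest.approx(b, abs=1e-6)

    def test_split_sizes_are_80_20(self):
        spec = ea.CohortSpec(
            n_samples=150, n_cpgs=20, n_age_cpgs=10, noise_sd=0.02, seed=33
        )
        matrix, meta = ea.generate_cohort(spec)
        ages = meta.ages_for(matrix.sample_ids)
        clocks = [ea.generate_oracle_clock(spec)]
        _, report = ea.train_ensemble_lr(
            matrix, ages, clocks, split=0.8, seed=1
        )
        aug, _, _ = ea.smote_oversample(
            matrix, ages, ea.SmoteConfig(seed=1)
        )
        assert report.n == round(0.2 * aug.n_samples)

    def test_collinear_base_predictions_stay_finite(self):
        spec = ea.CohortSpec(
            n_samples=120, n_cpgs=20, n_age_cpgs=10, noise_sd=0.01, seed=34
        )
        matrix, meta = ea.generate_cohort(spec)
        ages = meta.ages_for(matrix.sample_ids)
        oracle = ea.generate_oracle_clock(spec)
        twin = ea.ClockDefinition(
            "Twin", oracle.cpg_ids, oracle.weights.copy(), oracle.intercept
        )
        model, _ = ea.train_ensemble_lr(
            matrix, ages, [oracle, twin], alpha=0.1, seed=2
        )
        assert np.isfinite(model.weights).all()
        assert np.isfinite(model.intercept)

    def test_too_few_samples_rejected(self):
        spec = ea.CohortSpec(
            n_samples=12, n_cpgs=10, n_age_cpgs=6, noise_sd=0.01, seed=35
        )
        matrix, meta = ea.generate_cohort(spec)
        ages = meta.ages_for(matrix.sample_ids)
        clocks = [
            ea.generate_distractor_clock(spec, s, f"D{s}")
            for s in range(70, 74)
        ]
        with pytest.raises(ea.UsageError):
            ea.train_ensemble_lr(matrix, ages, clocks, seed=0)

    def test_parameter_recovery_on_stacked_noise(self):
        """Base predictions with known generative stacking weights and
        2y Gaussian noise: ridge at alpha=0.1, n=1000 recovers the
        weights within 0.1."""
        rng = np.random.default_rng(99)
        n, names = 1000, ("A", "B", "C", "D")
        true_w = np.array([0.5, 0.3, 0.15, 0.05])
        ages = rng.uniform(20, 80, size=n)
        base = np.column_stack(
            [ages + rng.normal(0, 2.0, size=n) for _ in names]
        )
        y = base @ true_w + rng.normal(0, 2.0, size=n)
        from sklearn.linear_model import Ridge

        ridge = Ridge(alpha=0.1).fit(base, y)
        w_cf, b_cf = _closed_form_ridge(base, y, 0.1)
        np.testing.assert_allclose(ridge.coef_, w_cf, atol=1e-8)
        assert np.abs(ridge.coef_ - true_w).max() < 0.1
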