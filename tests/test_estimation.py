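"""Mixed-effects machinery: likelihood approximation, residuals, shrinkage."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from dalbapk import (
    EstimationConfig,
    StudyDataset,
    cwres,
    dalbavancin_reference_model,
    evaluate,
    exclude_outliers,
    fit,
    heuristic_initial_model,
    marginal_ofv,
    bootstrap,
)
from dalbapk.estimation import eta_shrinkage_from_ebes
from dalbapk.pk import concentration, Regimen
from dalbapk.population import allometric_scale
from dalbapk.study import StudyDesignConfig, generate_study

from _oracles import quadrature_ofv


def single_subject_dataset(model, weight=70.0, times=(12.0, 300.0), dv=None):
    reg = Regimen.single(1500.0)
    if dv is None:
        dv = concentration(allometric_scale(model, weight), reg, list(times))
    rows = [
        {"ID": 1, "TIME": 0.0, "EVID": 1, "AMT": 1500.0, "DUR": 0.5,
         "DV": np.nan, "WT": weight}
    ]
    for t, v in zip(times, dv):
        rows.append(
            {"ID": 1, "TIME": t, "EVID": 0, "AMT": np.nan, "DUR": np.nan,
             "DV": v, "WT": weight}
        )
    return StudyDataset(pd.DataFrame(rows))


class TestMarginalOFV:
    def test_zero_omega_limit_is_least_squares_deviance(self, reference_model):
        """With no random effects the OFV collapses to the proportional-error
        deviance at the typical parameters."""
        model = replace(reference_model, omega_cv=(1e-9, 1e-9, 1e-9, 1e-9))
        dv = np.array([250.0, 40.0])
        ds = single_subject_dataset(model, dv=dv)
        ofv = marginal_ofv(ds, model)
        pred = concentration(
            allometric_scale(model, 70.0), Regimen.single(1500.0), [12.0, 300.0]
        )
        s2 = (model.resid_b * pred) ** 2 + 1e-6
        expected = float(np.sum(np.log(2 * np.pi * s2) + (dv - pred) ** 2 / s2))
        assert ofv == pytest.approx(expected, rel=1e-4)

    def test_matches_quadrature_oracle(self, reference_model, toy_dataset):
        """Laplace approximation within 2% of dense numerical integration."""
        laplace = marginal_ofv(toy_dataset, reference_model)
        quad = quadrature_ofv(toy_dataset, reference_model, n_nodes=25)
        assert laplace == pytest.approx(quad, rel=0.02)

    def test_duplicating_a_subject_doubles_its_contribution(
        self, reference_model, toy_dataset
    ):
        events = toy_dataset.events
        only_one = StudyDataset(events[events["ID"] == 1])
        dup = events[events["ID"] == 1].copy()
        dup["ID"] = 99
        doubled = StudyDataset(pd.concat([events, dup], ignore_index=True))
        assert marginal_ofv(doubled, reference_model) == pytest.approx(
            marginal_ofv(toy_dataset, reference_model)
            + marginal_ofv(only_one, reference_model),
            rel=1e-8,
        )

    def test_invariant_to_subject_relabeling(self, reference_model, toy_dataset):
        relabeled = toy_dataset.events.copy()
        relabeled["ID"] = relabeled["ID"].map({1: "c", 2: "a", 3: "b"})
        relabeled = relabeled.sort_values(["ID", "TIME"]).reset_index(drop=True)
        assert marginal_ofv(
            StudyDataset(relabeled), reference_model
        ) == pytest.approx(marginal_ofv(toy_dataset, reference_model), rel=1e-8)


class TestResiduals:
    def test_cwres_zero_for_exact_observations(self, reference_model):
        ds = single_subject_dataset(reference_model)  # DV = typical prediction
        res = evaluate(ds, reference_model)
        assert np.abs(res.residuals["CWRES"]).max() < 0.05
        table = cwres(ds, res)
        assert list(table.columns) == ["ID", "TIME", "DV", "CWRES", "row"]

    def test_cwres_calibrated_on_simulated_data(self, reference_model):
        """Under the generating model CWRES is approximately standard normal."""
        ds, _ = generate_study(
            reference_model, StudyDesignConfig(n_subjects=30, seed=91)
        )
        res = evaluate(ds, reference_model)
        cw = res.residuals["CWRES"].to_numpy()
        assert cw.size >= 150
        assert abs(cw.mean()) < 0.1
        assert 0.85 < cw.std() < 1.15

    def test_gross_outlier_flagged(self, reference_model):
        ds, truth = generate_study(
            reference_model,
            StudyDesignConfig(n_subjects=20, seed=7, outlier_count=3,
                              outlier_fold=10.0),
        )
        res = evaluate(ds, reference_model)
        flagged = res.residuals[res.residuals["CWRES"].abs() > 3.0]
        assert set(truth["injected_outlier_rows"]) <= set(flagged["row"])

    def test_exclude_outliers_bookkeeping(self, reference_model):
        ds, truth = generate_study(
            reference_model,
            StudyDesignConfig(n_subjects=20, seed=7, outlier_count=3,
                              outlier_fold=10.0),
        )
        res = evaluate(ds, reference_model)
        report = exclude_outliers(ds, res, refit=False)
        assert report.n_removed == len(report.removed)
        assert (
            ds.n_observations - report.reduced_dataset.n_observations
            == report.n_removed
        )
        assert set(truth["injected_outlier_rows"]) <= set(report.removed["row"])

    def test_no_outliers_leaves_dataset_unchanged(self, reference_model):
        ds = single_subject_dataset(reference_model)
        res = evaluate(ds, reference_model)
        report = exclude_outliers(ds, res)
        assert report.n_removed == 0
        assert report.delta_ofv == 0.0
        assert report.reduced_dataset.n_observations == ds.n_observations


class TestShrinkage:
    def test_all_zero_ebes_full_shrinkage(self):
        shr = eta_shrinkage_from_ebes(np.zeros((20, 4)), np.full(4, 0.2))
        np.testing.assert_allclose(shr, 100.0)

    def test_well_dispersed_ebes_low_shrinkage(self):
        rng = np.random.default_rng(0)
        omegas = np.array([0.2, 0.2, 0.5, 0.3])
        ebes = rng.normal(0.0, 1.0, size=(2000, 4)) * omegas
        shr = eta_shrinkage_from_ebes(ebes, omegas)
        assert np.abs(shr).max() < 5.0

    def test_zero_omega_reported_undefined(self):
        shr = eta_shrinkage_from_ebes(np.zeros((5, 4)), np.array([0.2, 0.0, 0.2, 0.2]))
        assert np.isnan(shr[1])


class TestFit:
    def test_recovers_on_small_rich_dataset(self, reference_model):
        """Short end-to-end sanity fit; the full recovery experiment lives in
        the acceptance suite."""
        ds, _ = generate_study(
            reference_model,
            StudyDesignConfig(n_subjects=12, rich_sampling=True,
                              weight_sampler="uniform", seed=31),
        )
        res = fit(
            ds, initial=reference_model,
            config=EstimationConfig(compute_rse=False, outer_maxiter=60),
        )
        assert np.isfinite(res.ofv)
        rel = np.abs(
            res.model.theta.as_array() / reference_model.theta.as_array() - 1.0
        )
        assert rel[0] < 0.25  # clearance well identified even at n=12
        assert rel[1] < 0.25

    def test_heuristic_initials_are_valid(self, reference_model):
        ds, _ = generate_study(
            reference_model, StudyDesignConfig(n_subjects=10, seed=3)
        )
        init = heuristic_initial_model(ds, template=reference_model)
        assert np.all(init.theta.as_array() > 0)
        # clearance heuristic lands within an order of magnitude
        assert 0.002 < init.theta.cl < 0.3


class TestBootstrap:
    def test_small_bootstrap_deterministic_and_ordered(self, reference_model):
        ds, _ = generate_study(
            reference_model,
            StudyDesignConfig(n_subjects=6, rich_sampling=True, seed=13),
        )
        cfg = EstimationConfig(compute_rse=False, outer_maxiter=25)
        s1 = bootstrap(ds, reference_model, cfg, seed=5, n_replicates=2)
        s2 = bootstrap(ds, reference_model, cfg, seed=5, n_replicates=2)
        pd.testing.assert_frame_equal(s1.table, s2.table)
        assert s1.n_converged >= 1
        t = s1.table
        assert (t["ci_lower"] <= t["median"]).all()
        assert (t["median"] <= t["ci_upper"]).all()
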