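"""Mixed-effects layer: MAP PK, Laplace marginal likelihood, pcVPC diagnostics."""

import numpy as np
import pytest

from psomipd import (
    CohortConfig,
    FitSettings,
    Patient,
    PopulationModel,
    PDPopulation,
    PopulationPDModel,
    apply_covariates,
    generate_cohort,
    map_individual_pk,
    pcvpc,
    pk_concentration,
)
from psomipd.cohort import build_dosing_history
from psomipd.estimation import SubjectWork, marginal_loglik, objective_value
from psomipd.pkpd import DoseEvent, Regimen


def _works(cohort, settings=None):
    settings = settings or FitSettings()
    return [SubjectWork(sp.patient, sp.pk_individual, settings) for sp in cohort]


TRUTH = {"kout": 0.016, "imax": 0.97, "omega_kout": 0.5587, "sigma_pd": 0.86}


class TestMapIndividualPK:
    def test_no_observations_returns_typical(self, pk_pop):
        p = Patient("x", 92.0, 14.0, doses=build_dosing_history(Regimen(90, 12), 400))
        ind, eta = map_individual_pk(p, pk_pop)
        expected = apply_covariates(pk_pop, 92.0)
        assert ind == expected
        assert all(v == 0.0 for v in eta.values())

    def test_observation_at_typical_prediction_gives_zero_eta(self, pk_pop):
        doses = build_dosing_history(Regimen(90, 12), 400)
        typical = apply_covariates(pk_pop, 92.0)
        t = np.array([300.0])
        y = pk_concentration(typical, doses, t)
        p = Patient("x", 92.0, 14.0, doses=doses, pk_times=t, pk_conc=y)
        _, eta = map_individual_pk(p, pk_pop)
        assert max(abs(v) for v in eta.values()) < 1e-3

    def test_rich_noise_free_data_recovers_high_clearance(self, pk_pop):
        doses = build_dosing_history(Regimen(90, 12), 400)
        truth = apply_covariates(pk_pop, 92.0, {"cl": np.log(1.5)})
        t = np.linspace(200.0, 380.0, 30)
        y = pk_concentration(truth, doses, t)
        p = Patient("x", 92.0, 14.0, doses=doses, pk_times=t, pk_conc=y)
        ind, _ = map_individual_pk(p, pk_pop)
        assert ind.cl == pytest.approx(truth.cl, rel=0.05)

    def test_blq_only_patient_falls_back_to_typical(self, pk_pop):
        doses = build_dosing_history(Regimen(45, 20), 400)
        p = Patient("x", 80.0, 10.0, doses=doses,
                    pk_times=np.array([250.0]), pk_conc=np.array([0.3]),
                    pk_cens=np.array([-1]))
        ind, eta = map_individual_pk(p, pk_pop)
        assert ind == apply_covariates(pk_pop, 80.0)


class TestMarginalLikelihood:
    def test_quadrature_matches_brute_force_single_subject(self, rich_cohort):
        """One subject, one random effect: GH integral vs dense trapezoid."""
        sp = rich_cohort[0]
        settings = FitSettings(estimate_baseline_eta=False)
        work = SubjectWork(sp.patient, sp.pk_individual, settings)
        gh = marginal_loglik(work, TRUTH, 0.07, method="gh", estimate_baseline=False)

        inh = work.inhibition_grid(TRUTH["imax"], 0.07)
        grid = np.linspace(-4.0, 4.0, 4001)
        logf = np.array([
            work.joint_loglik(np.array([e, 0.0]), TRUTH, inh, estimate_baseline=False)
            for e in grid
        ])
        m = logf.max()
        brute = m + np.log(np.trapezoid(np.exp(logf - m), grid))
        assert gh == pytest.approx(brute, abs=1e-3)

    def test_laplace_close_to_quadrature(self, rich_cohort):
        sp = rich_cohort[1]
        work = SubjectWork(sp.patient, sp.pk_individual, FitSettings())
        la = marginal_loglik(work, TRUTH, 0.07, method="laplace")
        work.eta_hat = np.zeros(2)
        gh = marginal_loglik(work, TRUTH, 0.07, method="gh")
        assert la == pytest.approx(gh, abs=0.2)

    def test_objective_additive_over_duplicated_subjects(self, rich_cohort):
        works = _works(rich_cohort[:3])
        single = objective_value(works, TRUTH, 0.07)
        doubled = objective_value(_works(rich_cohort[:3] + rich_cohort[:3]), TRUTH, 0.07)
        assert doubled == pytest.approx(2 * single, rel=1e-6)

    def test_objective_invariant_under_subject_permutation(self, rich_cohort):
        fwd = objective_value(_works(rich_cohort), TRUTH, 0.07)
        rev = objective_value(_works(rich_cohort[::-1]), TRUTH, 0.07)
        assert abs(fwd - rev) < 1e-9

    def test_non_finite_contribution_names_subject(self, rich_cohort):
        sp = rich_cohort[0]
        bad = Patient(
            "BADSUBJ", sp.patient.weight_kg, sp.patient.baseline_pasi,
            doses=sp.patient.doses, pd_times=np.array([100.0]),
            pd_pasi=np.array([np.nan]),
        )
        work = SubjectWork(bad, sp.pk_individual, FitSettings())
        with pytest.raises(FloatingPointError, match="BADSUBJ"):
            objective_value([work], TRUTH, 0.07)


@pytest.fixture(scope="module")
def fit12(rich_cohort):
    patients = [sp.patient for sp in rich_cohort]
    pk = {sp.patient.patient_id: sp.pk_individual for sp in rich_cohort}
    model = PopulationPDModel(patients, pk,
                              settings=FitSettings(n_starts=2, maxiter=300))
    return model, model.fit()


class TestPopulationFit:
    def test_recovery_order_of_magnitude(self, fit12):
        # n = 12 is small; assert generous recovery bands around the truths
        _, res = fit12
        assert 0.008 < res.params["kout"] < 0.032
        assert res.params["imax"] > 0.85
        assert 0.55 < res.params["sigma_pd"] < 1.25

    def test_objective_is_local_minimum(self, fit12):
        model, res = fit12
        base = res.objective
        theta = dict(res.params)
        for key, fac in [("kout", 1.5), ("imax", 0.9), ("omega_kout", 2.0),
                         ("sigma_pd", 1.4)]:
            pert = dict(theta)
            pert[key] = theta[key] * fac
            assert model.objective(pert) >= base - 1e-6

    def test_rse_reported_nonnegative(self, fit12):
        _, res = fit12
        finite = res.rse.dropna()
        assert (finite >= 0).all()
        assert np.isfinite(res.objective)

    def test_summary_reports_iiv_as_percent(self, fit12):
        _, res = fit12
        assert "IIV kout (%)" in res.summary()
        assert "0.07" in res.summary()  # fixed IC50 shown

    def test_zero_heterogeneity_shrinks_omega(self):
        truths = PopulationModel(pd=PDPopulation(omega_kout=1e-9))
        cohort = generate_cohort(
            CohortConfig(n_patients=10, rich_pd_sampling=True, truths=truths), seed=5
        )
        patients = [sp.patient for sp in cohort]
        pk = {sp.patient.patient_id: sp.pk_individual for sp in cohort}
        res = PopulationPDModel(
            patients, pk, settings=FitSettings(n_starts=1, maxiter=300)
        ).fit(compute_rse=False)
        assert res.params["omega_kout"] < 0.1

    def test_doubling_residual_noise_doubles_sigma_estimate(self):
        # error-scale recovery: fits at half and full residual noise should
        # return sigma estimates in roughly a 1:2 ratio
        est = {}
        for sig in (0.43, 0.86):
            truths = PopulationModel(pd=PDPopulation(sigma_pd=sig))
            cohort = generate_cohort(
                CohortConfig(n_patients=12, rich_pd_sampling=True, truths=truths),
                seed=21,
            )
            patients = [sp.patient for sp in cohort]
            pk = {sp.patient.patient_id: sp.pk_individual for sp in cohort}
            res = PopulationPDModel(
                patients, pk, settings=FitSettings(n_starts=1, maxiter=300)
            ).fit(compute_rse=False)
            est[sig] = res.params["sigma_pd"]
        assert est[0.86] / est[0.43] == pytest.approx(2.0, rel=0.2)

    def test_cohort_without_pd_rejected(self, rich_cohort):
        sp = rich_cohort[0]
        p = Patient("x", 90.0, 12.0, doses=sp.patient.doses)
        with pytest.raises(ValueError):
            PopulationPDModel([p], {"x": sp.pk_individual})


class TestPcVpc:
    def test_identity_correction_when_predictions_equal(self, small_cohort):
        # identical patients observed at one shared time have identical
        # population predictions, so the prediction correction is the identity
        # and the observed median equals the raw median
        sp = small_cohort[0]
        p = sp.patient
        vals = [3.0, 5.0, 9.0]
        clones = [
            Patient(f"c{i}", p.weight_kg, p.baseline_pasi, doses=p.doses,
                    pd_times=np.array([182.0]), pd_pasi=np.array([v]))
            for i, v in enumerate(vals)
        ]
        pk = {f"c{i}": sp.pk_individual for i in range(3)}
        table = pcvpc(clones, pk, PDPopulation(), n_sim=100, n_bins=1, seed=0)
        med = table[table.percentile == 50.0]
        assert float(med["observed"].iloc[0]) == pytest.approx(np.median(vals))

    def test_deterministic_under_seed(self, small_cohort):
        patients = [sp.patient for sp in small_cohort]
        pk = {sp.patient.patient_id: sp.pk_individual for sp in small_cohort}
        t1 = pcvpc(patients, pk, PDPopulation(), n_sim=100, seed=42)
        t2 = pcvpc(patients, pk, PDPopulation(), n_sim=100, seed=42)
        assert t1.equals(t2)

    def test_self_simulated_data_covered_by_band(self):
        # data simulated from the model itself should mostly fall inside the
        # simulated-median band; within one cohort the bins shift together
        # (shared random effects), so coverage is pooled over replicate
        # cohorts rather than asserted per cohort
        coverages = []
        for seed in range(10):
            cohort = generate_cohort(
                CohortConfig(n_patients=20, rich_pd_sampling=True), seed=seed
            )
            patients = [sp.patient for sp in cohort]
            pk = {sp.patient.patient_id: sp.pk_individual for sp in cohort}
            table = pcvpc(patients, pk, PDPopulation(), n_sim=100, n_bins=5, seed=9)
            med = table[table.percentile == 50.0]
            coverages.append(
                ((med.observed >= med.sim_lo) & (med.observed <= med.sim_hi)).mean()
            )
        assert np.mean(coverages) >= 0.6

    def test_n_sim_floor_enforced(self, small_cohort):
        patients = [sp.patient for sp in small_cohort]
        pk = {sp.patient.patient_id: sp.pk_individual for sp in small_cohort}
        with pytest.raises(ValueError):
            pcvpc(patients, pk, PDPopulation(), n_sim=50)
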