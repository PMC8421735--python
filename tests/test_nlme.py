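"""Unit tests for the estimation engine: BLQ policies, likelihood terms,
marginal objective, fitting and the covariate screen plumbing."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from meropk import nlme
from meropk.nlme import (
    EventRecord,
    ModelDataError,
    PKDataset,
    apply_blq,
    covariate_screen,
    fit,
    lrt_decision,
    ofv,
    subject_loglik,
)
from meropk.pk_core import PatientCovariates
from meropk.synthetic import CohortSpec, TrialDesign, sample_cohort, simulate_trial


def _toy_subject(blq_times=(), obs_times=(2.0, 4.0), value=5.0):
    records = [
        EventRecord(subject_id="A", time=0.0, kind="dose", amount=200.0, rate=200.0)
    ]
    for t in obs_times:
        records.append(
            EventRecord(subject_id="A", time=t, kind="plasma_obs", value=value)
        )
    for t in blq_times:
        records.append(
            EventRecord(subject_id="A", time=t, kind="plasma_obs", blq=True)
        )
    records.sort(key=lambda r: (r.time, r.kind == "dose"))
    covs = {"A": PatientCovariates(bodyweight=10.0, ecrcl=90.0)}
    return PKDataset(records=records, covariates=covs)


class TestApplyBLQ:
    def test_m6_toy_rule(self):
        ds = _toy_subject(blq_times=(6.0, 8.0))
        out = apply_blq(ds, "M6")
        obs = [r for r in out.records if r.is_obs]
        assert len(obs) == 3  # two quantified + first BLQ imputed, second dropped
        imputed = [r for r in obs if r.time == 6.0]
        assert len(imputed) == 1
        assert imputed[0].value == pytest.approx(0.1)  # LLOQ/2 = 0.2/2
        assert not imputed[0].blq
        assert not any(r.time == 8.0 for r in obs)

    def test_m1_drops_all(self):
        ds = _toy_subject(blq_times=(6.0, 8.0))
        out = apply_blq(ds, "M1")
        assert sum(r.is_obs for r in out.records) == 2

    def test_m3_keeps_flagged(self):
        ds = _toy_subject(blq_times=(6.0, 8.0))
        out = apply_blq(ds, "M3")
        obs = [r for r in out.records if r.is_obs]
        assert len(obs) == 4
        assert sum(r.blq for r in obs) == 2

    def test_no_blq_all_methods_identical(self):
        ds = _toy_subject()
        for m in ("M1", "M3", "M6"):
            out = apply_blq(ds, m)
            assert [
                (r.time, r.kind, r.value, r.blq) for r in out.records
            ] == [(r.time, r.kind, r.value, r.blq) for r in ds.records]

    def test_usable_record_count(self):
        # 225 observations of which 35 BLQ: M1 leaves 190 usable records
        records, covs = [], {}
        n_blq = 0
        for i in range(25):
            sid = f"S{i}"
            covs[sid] = PatientCovariates(bodyweight=10.0, ecrcl=90.0)
            records.append(
                EventRecord(
                    subject_id=sid, time=0.0, kind="dose", amount=200.0, rate=200.0
                )
            )
            for j in range(9):
                blq = n_blq < 35 and j >= 7
                n_blq += blq
                records.append(
                    EventRecord(
                        subject_id=sid,
                        time=1.0 + j,
                        kind="plasma_obs",
                        value=None if blq else 5.0,
                        blq=blq,
                    )
                )
        ds = PKDataset(records=records, covariates=covs)
        assert sum(r.is_obs for r in ds.records) == 225
        assert sum(r.blq for r in ds.records) == 35
        out = apply_blq(ds, "M1")
        assert sum(r.is_obs for r in out.records) == 190

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            apply_blq(_toy_subject(), "M2")


class TestSubjectLoglik:
    def test_zero_residual_closed_form(self, p4):
        from meropk.pk_core import (
            IndividualParams,
            InfusionSegment,
            concentration,
            typical_clearance,
            typical_volume,
        )

        cov = PatientCovariates(bodyweight=10.0, ecrcl=90.0)
        ind = IndividualParams(
            cl=typical_clearance(cov, p4), v1=typical_volume(cov, p4)
        )
        pred = concentration(2.0, [InfusionSegment(0.0, 1.0, 200.0)], ind)
        records = [
            EventRecord(
                subject_id="A", time=0.0, kind="dose", amount=200.0, rate=200.0
            ),
            EventRecord(
                subject_id="A", time=2.0, kind="plasma_obs", value=float(pred)
            ),
        ]
        ll = subject_loglik(records, cov, p4)
        expected = -0.5 * math.log(2 * math.pi * p4.sigma_plasma**2)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_sigma_label_matters(self, p4):
        cov = PatientCovariates(bodyweight=10.0, ecrcl=30.0, on_crrt=True)
        base = [
            EventRecord(
                subject_id="A", time=0.0, kind="dose", amount=200.0, rate=200.0
            )
        ]
        as_plasma = base + [
            EventRecord(subject_id="A", time=2.0, kind="plasma_obs", value=3.0)
        ]
        as_effluent = base + [
            EventRecord(subject_id="A", time=2.0, kind="effluent_obs", value=3.0)
        ]
        assert subject_loglik(as_plasma, cov, p4) != pytest.approx(
            subject_loglik(as_effluent, cov, p4)
        )

    def test_observation_before_input_flagged(self, p4):
        cov = PatientCovariates(bodyweight=10.0, ecrcl=90.0)
        records = [
            EventRecord(
                subject_id="A", time=5.0, kind="dose", amount=200.0, rate=200.0
            ),
            EventRecord(subject_id="A", time=5.0, kind="plasma_obs", value=3.0),
        ]
        with pytest.raises(ModelDataError):
            subject_loglik(records, cov, p4)

    def test_m3_term_matches_numeric_integration(self, p4):
        # censored contribution = P(ln C_obs < ln LLOQ | pred, sigma)
        cov = PatientCovariates(bodyweight=10.0, ecrcl=90.0)
        records = [
            EventRecord(
                subject_id="A", time=0.0, kind="dose", amount=200.0, rate=200.0
            ),
            EventRecord(subject_id="A", time=7.5, kind="plasma_obs", blq=True),
        ]
        ll = subject_loglik(records, cov, p4, blq_method="M3")
        from meropk.pk_core import (
            IndividualParams,
            InfusionSegment,
            concentration,
            typical_clearance,
            typical_volume,
        )

        ind = IndividualParams(
            cl=typical_clearance(cov, p4), v1=typical_volume(cov, p4)
        )
        pred = concentration(7.5, [InfusionSegment(0.0, 1.0, 200.0)], ind)
        mass, err = quad(
            lambda x: norm.pdf(x, math.log(pred), p4.sigma_plasma),
            -60.0,
            math.log(0.2),
            epsabs=1e-13,
            epsrel=1e-13,
        )
        assert ll == pytest.approx(math.log(mass), abs=1e-8)


class TestOFV:
    def test_degenerate_omega_equals_fixed_eta_loglik(self, p4):
        ds = _toy_subject()
        p0 = replace(p4, omega_cl=0.0, omega_v1=0.0)
        got = ofv(ds, p0, blq_method="M3")
        by_subject = -2.0 * subject_loglik(
            [r for r in ds.records], ds.covariates["A"], p0, etas=(0.0, 0.0),
            blq_method="M3",
        )
        assert got == pytest.approx(by_subject, abs=1e-8)

    def test_one_subject_toy_vs_quadrature(self, p4):
        # observations near the typical profile: 9.0 mg/L at 2 h, 3.0 at 6 h
        records = [
            EventRecord(
                subject_id="A", time=0.0, kind="dose", amount=200.0, rate=200.0
            ),
            EventRecord(subject_id="A", time=2.0, kind="plasma_obs", value=9.0),
            EventRecord(subject_id="A", time=6.0, kind="plasma_obs", value=3.0),
        ]
        ds = PKDataset(
            records=records,
            covariates={"A": PatientCovariates(bodyweight=10.0, ecrcl=90.0)},
        )
        got = ofv(ds, p4, blq_method="M3")
        oracle = _aghq_ofv(ds, p4, blq_method="M3")
        assert got == pytest.approx(oracle, abs=0.1)

    def test_m3_equals_m1_without_blq(self, p4, small_ds):
        # on a dataset with no BLQ records, the M3 likelihood is the M1 one
        stripped = PKDataset(
            records=[r for r in small_ds.records if not (r.is_obs and r.blq)],
            covariates=small_ds.covariates,
        )
        assert ofv(stripped, p4, blq_method="M3") == pytest.approx(
            ofv(stripped, p4, blq_method="M1"), abs=1e-6
        )

    def test_subject_order_invariance(self, p4, small_ds):
        ids = small_ds.subject_ids()
        reordered = []
        for sid in reversed(ids):
            reordered.extend(
                [r for r in small_ds.records if r.subject_id == sid]
            )
        ds2 = PKDataset(records=reordered, covariates=small_ds.covariates)
        assert ofv(ds2, p4) == pytest.approx(ofv(small_ds, p4), abs=1e-8)

    def test_unknown_approx(self, p4, small_ds):
        with pytest.raises(ValueError):
            ofv(small_ds, p4, approx="saem")

    def test_foce_i_alias(self, p4, small_ds):
        assert ofv(small_ds, p4, approx="foce_i") == pytest.approx(
            ofv(small_ds, p4, approx="laplace")
        )


def _aghq_ofv(ds, p, blq_method="M6", n_nodes=30):
    """Adaptive Gauss-Hermite quadrature oracle for the marginal OFV."""
    from meropk.nlme import _BatchModel

    bm = _BatchModel(ds, blq_method=blq_method)
    om = np.array([max(p.omega_cl, 1e-8), max(p.omega_v1, 1e-8)])
    eta_hat, q0, _H, ok = bm.inner_modes(p)
    assert ok.all()
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    Z = np.array([[a, b] for a in z for b in z])  # (n^2, 2)
    W = np.array([wa * wb for wa in w for wb in w])
    total = 0.0
    for s in range(bm.S):
        # curvature at the mode for the adaptive transform
        _, _, H = bm._q_grad_hess(
            p, eta_hat[s : s + 1], (), om[0], om[1], idx=np.array([s])
        )
        Hs = H[0]
        L = np.linalg.cholesky(np.linalg.inv(Hs))
        etas = eta_hat[s] + math.sqrt(2.0) * Z @ L.T
        lf = bm.loglik(
            p, etas[None, :, :].repeat(1, axis=0), idx=np.array([s])
        )[0]
        prior = -0.5 * np.sum((etas / om) ** 2, axis=1) - np.log(
            2 * math.pi * om[0] * om[1]
        )
        logg = lf + prior + np.sum(Z**2, axis=1)
        m = logg.max()
        integral = (
            2.0 ** (2 / 2)
            * abs(np.linalg.det(L))
            * np.exp(m)
            * np.sum(W * np.exp(logg - m))
        )
        total += -2.0 * math.log(integral)
    return total


class TestFit:
    def test_refit_is_fixed_point(self, small_ds, p4):
        res = fit(small_ds, blq_method="M6")
        assert res.converged
        again = fit(small_ds, init=res.params, blq_method="M6")
        assert abs(again.ofv - res.ofv) < 0.01

    def test_noiseless_identifiability(self, p4):
        # data simulated with omega=0 and tiny sigma recover theta to <1%
        spec = CohortSpec(n_subjects=10, n_ecls=5, n_high_dose=2, n_two_step=5)
        cohort = sample_cohort(spec, seed=41)
        truth = replace(
            p4, omega_cl=0.0, omega_v1=0.0, sigma_plasma=0.02,
            sigma_effluent=0.02,
        )
        design = TrialDesign(lloq=1e-8)
        ds = simulate_trial(cohort, truth, design, seed=42, spec=spec)
        init = replace(
            truth,
            cl_typical=5.0,
            v1_typical=15.0,
            ecrcl_slope=0.002,
            sc=0.4,
            sigma_plasma=0.1,
            sigma_effluent=0.1,
        )
        res = fit(
            ds,
            init=init,
            fixed=nlme.DEFAULT_FIXED | {"omega_cl", "omega_v1"},
            blq_method="M3",
            maxfev=4000,
        )
        assert res.converged
        assert res.params.cl_typical == pytest.approx(7.6, rel=0.01)
        assert res.params.v1_typical == pytest.approx(21.4, rel=0.01)
        assert res.params.ecrcl_slope == pytest.approx(0.0035, rel=0.05)

    def test_nonconverged_flag_reported(self, small_ds):
        res = fit(small_ds, blq_method="M6", maxfev=5)
        assert not res.converged
        assert np.isfinite(res.ofv)


class TestLRT:
    def test_forward_threshold(self):
        assert lrt_decision(-3.85, 1, "forward")
        assert not lrt_decision(-3.5, 1, "forward")

    def test_backward_elimination(self):
        # removal raising OFV by 5.466 fails the 10.83 retention bar
        assert not lrt_decision(5.466, 1, "backward")
        assert lrt_decision(10.84, 1, "backward")

    def test_invalid(self):
        with pytest.raises(ValueError):
            lrt_decision(-5.0, 0, "forward")
        with pytest.raises(ValueError):
            lrt_decision(-5.0, 1, "sideways")


class TestScreenPlumbing:
    def test_no_candidates_base_only(self, small_ds):
        base = fit(small_ds, blq_method="M6")
        out = covariate_screen(small_ds, base, [])
        assert out.included == ()
        assert [s.stage for s in out.trace].count("forward") >= 1
        assert out.final.ofv <= base.ofv + 1e-9

    def test_requires_converged_base(self, small_ds):
        bad = fit(small_ds, blq_method="M6", maxfev=5)
        with pytest.raises(ValueError):
            covariate_screen(small_ds, bad, [])


class TestDatasetValidation:
    def test_orphan_observation(self):
        with pytest.raises(ModelDataError):
            PKDataset(
                records=[
                    EventRecord(
                        subject_id="A",
                        time=1.0,
                        kind="plasma_obs",
                        value=1.0,
                    )
                ],
                covariates={},
            )

    def test_observation_before_dose(self):
        covs = {"A": PatientCovariates(bodyweight=10.0, ecrcl=90.0)}
        with pytest.raises(ModelDataError):
            PKDataset(
                records=[
                    EventRecord(
                        subject_id="A", time=0.5, kind="plasma_obs", value=1.0
                    ),
                    EventRecord(
                        subject_id="A",
                        time=1.0,
                        kind="dose",
                        amount=200.0,
                        rate=200.0,
                    ),
                ],
                covariates=covs,
            )

    def test_effluent_requires_crrt(self):
        covs = {"A": PatientCovariates(bodyweight=10.0, ecrcl=90.0)}
        with pytest.raises(ModelDataError):
            PKDataset(
                records=[
                    EventRecord(
                        subject_id="A",
                        time=0.0,
                        kind="dose",
                        amount=200.0,
                        rate=200.0,
                    ),
                    EventRecord(
                        subject_id="A",
                        time=2.0,
                        kind="effluent_obs",
                        value=1.0,
                    ),
                ],
                covariates=covs,
            )
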