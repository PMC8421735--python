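"""Shared fixtures: packaged parameters, small synthetic datasets, helpers."""

from __future__ import annotations

import numpy as np
import pytest

from meropk import nlme
from meropk.io import final_params
from meropk.synthetic import CohortSpec, TrialDesign, sample_cohort, simulate_trial


@pytest.fixture(scope="session")
def p4():
    """The packaged final-model population parameters."""
    return final_params()


@pytest.fixture(scope="session")
def trial_ds(p4):
    """One 25-subject synthetic trial at the packaged parameters."""
    cohort = sample_cohort(CohortSpec(), seed=31)
    return simulate_trial(cohort, p4, TrialDesign(), seed=32, spec=CohortSpec())


@pytest.fixture(scope="session")
def small_ds(p4):
    """A fast 8-subject trial for fitting tests."""
    spec = CohortSpec(n_subjects=8, n_ecls=4, n_high_dose=1, n_two_step=4)
    cohort = sample_cohort(spec, seed=7)
    return simulate_trial(cohort, p4, TrialDesign(), seed=8, spec=spec)


def make_small_random_dataset(rng, p):
    """A tiny dataset (<=5 subjects, 4 obs each) for quadrature oracles.

    Each subject gets an informative sampling design (one early, one mid,
    two late samples).  With sparse late-only designs the conditional
    density of the random effects is intrinsically skewed and *any* Laplace
    variant deviates from the exact integral by O(1) — verified against
    brute-force 2-D integration — so the oracle comparison is only
    diagnostic for implementation correctness on informative designs.
    """
    from meropk.pk_core import PatientCovariates
    from meropk.nlme import EventRecord, PKDataset

    n_sub = int(rng.integers(2, 6))
    records, covs = [], {}
    for i in range(n_sub):
        sid = f"Q{i}"
        bw = float(rng.uniform(5, 30))
        on_crrt = bool(rng.random() < 0.4)
        covs[sid] = PatientCovariates(
            bodyweight=bw,
            ecrcl=float(rng.uniform(20, 150)),
            on_crrt=on_crrt,
        )
        dose = 20.0 * bw
        records.append(
            EventRecord(subject_id=sid, time=0.0, kind="dose", amount=dose, rate=dose)
        )
        times = np.sort(
            np.concatenate(
                [
                    rng.uniform(0.5, 1.5, 1),
                    rng.uniform(1.5, 3.0, 1),
                    rng.uniform(3.0, 8.0, 2),
                ]
            )
        )
        from meropk.pk_core import typical_clearance, typical_volume

        cl = typical_clearance(covs[sid], p) * np.exp(rng.normal(0, p.omega_cl))
        v1 = typical_volume(covs[sid], p) * np.exp(rng.normal(0, p.omega_v1))
        from meropk.pk_core import InfusionSegment, IndividualParams, concentration

        segs = [InfusionSegment(0.0, 1.0, dose)]
        ind = IndividualParams(cl=cl, v1=v1)
        for t in times:
            pred = concentration(float(t), segs, ind)
            val = pred * np.exp(rng.normal(0, p.sigma_plasma))
            blq = val < nlme.LLOQ_DEFAULT
            records.append(
                EventRecord(
                    subject_id=sid,
                    time=float(t),
                    kind="plasma_obs",
                    value=None if blq else float(val),
                    blq=bool(blq),
                )
            )
    return PKDataset(records=records, covariates=covs)
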