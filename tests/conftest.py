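import numpy as np
import pandas as pd
import pytest

from meropk import (
    DemographicsSpec,
    PopulationModel,
    Regimen,
    ResidualSpec,
    SamplingSchedule,
    individual_params,
    sample_cohort,
    simulate_tdm,
)
from meropk.cohort import TDMDataset


@pytest.fixture(scope="session")
def model():
    """The published final model with its default parameters."""
    return PopulationModel()


@pytest.fixture(scope="session")
def typical_ip(model):
    """Typical subject at the reference CRCL (47.7 mL/min), eta = 0."""
    return individual_params(model, 47.7)


@pytest.fixture(scope="session")
def q8h_regimen():
    """The study's standard regimen: 1 g q8h infused over 2 h."""
    return Regimen(1000.0, 8.0, 2.0)


def make_dataset(
    n_subjects,
    seed,
    model=None,
    n_samples=3,
    nominal_times=None,
    regimen=None,
):
    """Simulate a TDM dataset under the (possibly modified) study design."""
    model = model or PopulationModel()
    kwargs = {}
    if regimen is not None:
        kwargs["regimen"] = regimen
    if nominal_times is not None:
        kwargs["nominal_times"] = nominal_times
    schedule = SamplingSchedule(samples_per_subject=n_samples, **kwargs)
    spec = DemographicsSpec(n_subjects=n_subjects)
    subjects = sample_cohort(spec, model, seed)
    return simulate_tdm(subjects, model, schedule, seed + 1)


def toy_dataset(subject_specs, dose=1000.0, tau=8.0, tinf=2.0, crcl=47.7):
    """Hand-built dataset from explicit (times, concentrations) per subject."""
    rows = []
    cov = {"AGE": 60.0, "SEX": 1, "WT": 60.0, "CRCL": crcl, "HD": 0}
    for sid, (times, dvs) in enumerate(subject_specs, start=1):
        rows.append(
            dict(ID=sid, TIME=0.0, AMT=dose, RATE=dose / tinf, II=tau, EVID=1,
                 MDV=1, DV=np.nan, DILUTE=0, **cov)
        )
        for t, dv in zip(times, dvs):
            rows.append(
                dict(ID=sid, TIME=float(t), AMT=0.0, RATE=0.0, II=0.0, EVID=0,
                     MDV=0, DV=float(dv), DILUTE=0, **cov)
            )
    return TDMDataset(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_fitted(model):
    """A 100-subject dataset with all four sampling times and its fit,
    shared across diagnostic tests (fitting is the expensive step)."""
    from meropk import fit, published_covariates

    ds = make_dataset(100, seed=11, model=model, n_samples=4,
                      nominal_times=(2.0, 4.0, 6.0, 7.5))
    res = fit(ds, residual="additive", covariates=published_covariates(47.7),
              init=model, compute_rse=False)
    return ds, res
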