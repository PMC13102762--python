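"""Synthetic therapeutic-drug-monitoring cohort generator.

Emulates the study design that produced the meropenem dataset: 44 adults with
severe postoperative infections on 1.0 g q8h infused over 2-2.5 h, sampled at
steady state 30 min before a dose and 2 (or 2.5), 4 and 6 h after the start of
an infusion, with roughly three samples per patient.  Demographics follow the
reported truncated-normal summaries; concentrations are generated from the
population model with interindividual and residual variability.

The generator writes/reads NONMEM-convention CSV (ID, TIME, AMT, RATE, EVID,
MDV, DV plus covariate columns), so every downstream stage is testable without
any external data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_pk import PopulationModel, Regimen, conc_steady_state

__all__ = [
    "TruncatedNormal",
    "DemographicsSpec",
    "SamplingSchedule",
    "Subject",
    "TDMDataset",
    "sample_cohort",
    "simulate_tdm",
    "write_dataset",
    "read_dataset",
    "study_dataset",
]

#: Assay calibration range reused as quantification limits, mg/L.
LLOQ = 0.5
ULOQ = 80.0

COLUMNS = [
    "ID",
    "TIME",
    "AMT",
    "RATE",
    "II",
    "EVID",
    "MDV",
    "DV",
    "DILUTE",
    "AGE",
    "SEX",
    "WT",
    "CRCL",
    "HD",
]


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) truncated to [lower, upper]."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("truncation range is empty")
        if not self.lower <= self.mean <= self.upper:
            raise ValueError(
                f"mean {self.mean} outside truncation range "
                f"[{self.lower}, {self.upper}]"
            )
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def _frozen(self):
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=n, random_state=rng)

    @property
    def truncated_mean(self) -> float:
        """Exact mean of the truncated distribution (not the location ``mean``)."""
        return float(self._frozen().mean())


#: CRCL distribution as reported in the cohort summary (mean 54.3 mL/min).
CRCL_COHORT = TruncatedNormal(54.3, 29.6, 11.9, 136.0)
#: Alternative preset centred on the tabulated/model reference value 47.7.
CRCL_TABLE = TruncatedNormal(47.7, 29.6, 11.9, 136.0)


@dataclass(frozen=True)
class DemographicsSpec:
    """Covariate distributions of the simulated cohort (study defaults)."""

    n_subjects: int = 44
    age: TruncatedNormal = TruncatedNormal(68.5, 14.8, 20.0, 91.0)
    weight: TruncatedNormal = TruncatedNormal(56.7, 9.04, 40.0, 81.0)
    male_fraction: float = 0.70
    crcl: TruncatedNormal = CRCL_COHORT
    hd_fraction: float = 7 / 44  # 15.91% on hemodialysis

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for frac in (self.male_fraction, self.hd_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class SamplingSchedule:
    """Dosing regimen and nominal sampling times of the TDM design.

    ``nominal_times`` are hours after the start of a steady-state infusion; a
    negative time means a pre-dose sample and is wrapped to tau + time (the
    -0.5 h draw becomes tau - 0.5 within the interval).
    """

    regimen: Regimen = field(default_factory=lambda: Regimen(1000.0, 8.0, 2.0))
    nominal_times: tuple[float, ...] | None = None
    samples_per_subject: int = 3

    def __post_init__(self) -> None:
        if self.nominal_times is None:
            times = (-0.5, self.regimen.tinf_h, 4.0, 6.0)
            object.__setattr__(self, "nominal_times", times)
        tau = self.regimen.tau_h
        for t in self.nominal_times:
            if not -tau < t <= tau:
                raise ValueError(f"nominal time {t} outside (-tau, tau]")
        if not 1 <= self.samples_per_subject <= len(self.nominal_times):
            raise ValueError("samples_per_subject exceeds available nominal times")

    @property
    def interval_times(self) -> tuple[float, ...]:
        """Nominal times mapped into [0, tau) of the steady-state interval."""
        tau = self.regimen.tau_h
        return tuple(t if t >= 0 else tau + t for t in self.nominal_times)


@dataclass(frozen=True)
class Subject:
    """One virtual patient: covariates plus latent random effects."""

    id: int
    age: float
    weight: float
    sex: str
    crcl: float
    hd: int
    eta_cl: float
    eta_vc: float


def sample_cohort(
    spec: DemographicsSpec,
    model: PopulationModel,
    seed: int,
) -> list[Subject]:
    """Draw a virtual cohort: covariates from the truncated demographic
    distributions, (etaCL, etaVc) from the model's IIV covariance.

    Covariates are drawn independently of each other and of CRCL; CRCL is
    sampled directly from its reported distribution rather than reconstructed
    from age/weight/creatinine.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    ages = spec.age.sample(n, rng)
    weights = spec.weight.sample(n, rng)
    sexes = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    crcls = spec.crcl.sample(n, rng)
    hds = (rng.random(n) < spec.hd_fraction).astype(int)
    etas = rng.multivariate_normal(np.zeros(2), model.omega, size=n)
    return [
        Subject(
            id=i + 1,
            age=float(ages[i]),
            weight=float(weights[i]),
            sex=str(sexes[i]),
            crcl=float(crcls[i]),
            hd=int(hds[i]),
            eta_cl=float(etas[i, 0]),
            eta_vc=float(etas[i, 1]),
        )
        for i in range(n)
    ]


@dataclass
class TDMDataset:
    """NONMEM-style longitudinal dataset: dose events, observations, covariates."""

    df: pd.DataFrame
    lloq: float = LLOQ
    uloq: float = ULOQ
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")
        doses = self.df[self.df.EVID == 1]
        obs = self.df[self.df.EVID == 0]
        if (doses.AMT <= 0).any() or (doses.RATE <= 0).any():
            bad = doses.index[(doses.AMT <= 0) | (doses.RATE <= 0)].tolist()
            raise ValueError(f"dose rows must have AMT>0 and RATE>0 (rows {bad})")
        if doses.DV.notna().any():
            bad = doses.index[doses.DV.notna()].tolist()
            raise ValueError(f"dose rows must have missing DV (rows {bad})")
        if not obs.MDV.isin([0, 1]).all():
            bad = obs.index[~obs.MDV.isin([0, 1])].tolist()
            raise ValueError(f"observation rows need MDV in {{0,1}} (rows {bad})")
        for sid, grp in self.df.groupby("ID"):
            if not grp.TIME.is_monotonic_increasing:
                raise ValueError(f"TIME not nondecreasing within subject {sid}")

    @property
    def observations(self) -> pd.DataFrame:
        return self.df[self.df.EVID == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.df[self.df.EVID == 1]

    @property
    def n_subjects(self) -> int:
        return self.df.ID.nunique()

    def __eq__(self, other) -> bool:  # round-trip contract
        if not isinstance(other, TDMDataset):
            return NotImplemented
        return (
            self.lloq == other.lloq
            and self.uloq == other.uloq
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )


def simulate_tdm(
    subjects: Sequence[Subject],
    model: PopulationModel,
    schedule: SamplingSchedule,
    seed: int,
    lloq: float = LLOQ,
    uloq: float = ULOQ,
) -> TDMDataset:
    """Simulate steady-state TDM observations for a sampled cohort.

    Per subject: one dose event (the steady-state infusion, TIME 0) and
    ``samples_per_subject`` observation times drawn without replacement from
    the nominal schedule.  True concentrations come from the analytic
    steady-state profile with the subject's (etaCL, etaVc); residual noise
    follows the model's ResidualSpec, with negative concentrations redrawn so
    the error model stays unbiased near the quantification limit.  DV below
    LLOQ is flagged MDV=1 (value retained); DV above ULOQ keeps MDV=0 but sets
    the DILUTE flag.
    """
    rng = np.random.default_rng(seed)
    reg = schedule.regimen
    interval_times = np.asarray(schedule.interval_times)
    rows: list[dict] = []
    for subj in subjects:
        cl = (
            model.theta_cl
            * (subj.crcl / model.crcl_ref) ** model.theta_cov
            * np.exp(subj.eta_cl)
        )
        vc = model.theta_vc * np.exp(subj.eta_vc)
        cov = {
            "AGE": subj.age,
            "SEX": 1 if subj.sex == "male" else 0,
            "WT": subj.weight,
            "CRCL": subj.crcl,
            "HD": subj.hd,
        }
        rows.append(
            {
                "ID": subj.id,
                "TIME": 0.0,
                "AMT": reg.dose_mg,
                "RATE": reg.rate_mg_h,
                "II": reg.tau_h,
                "EVID": 1,
                "MDV": 1,
                "DV": np.nan,
                "DILUTE": 0,
                **cov,
            }
        )
        k = schedule.samples_per_subject
        times = np.sort(rng.choice(interval_times, size=k, replace=False))
        for t in times:
            f = float(conc_steady_state(cl, vc, reg.dose_mg, reg.tau_h, reg.tinf_h, t))
            dv = _add_residual(f, model.residual, rng)
            rows.append(
                {
                    "ID": subj.id,
                    "TIME": float(t),
                    "AMT": 0.0,
                    "RATE": 0.0,
                    "II": 0.0,
                    "EVID": 0,
                    "MDV": 1 if dv < lloq else 0,
                    "DV": dv,
                    "DILUTE": 1 if dv > uloq else 0,
                    **cov,
                }
            )
    df = pd.DataFrame(rows, columns=COLUMNS)
    return TDMDataset(df=df, lloq=lloq, uloq=uloq, seed=seed)


def _add_residual(f: float, residual, rng: np.random.Generator) -> float:
    """One noisy observation of true concentration ``f``; negatives redrawn."""
    sd = float(np.sqrt(residual.variance(f)))
    if sd == 0.0:
        return f
    for _ in range(1000):
        dv = f + sd * rng.standard_normal()
        if dv >= 0:
            return dv
    raise RuntimeError("could not draw a nonnegative concentration")


def write_dataset(ds: TDMDataset, path: str | Path) -> None:
    """Write the dataset as CSV with a metadata comment header."""
    path = Path(path)
    with path.open("w") as fh:
        seed = "" if ds.seed is None else f" seed={ds.seed}"
        fh.write(f"# meropk TDM dataset lloq={ds.lloq} uloq={ds.uloq}{seed}\n")
        # %.17g round-trips float64 exactly, so read(write(ds)) == ds
        ds.df.to_csv(fh, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> TDMDataset:
    """Read a dataset written by :func:`write_dataset` (or hand-built CSV)."""
    path = Path(path)
    lloq, uloq, seed = LLOQ, ULOQ, None
    text = path.read_text()
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        for tok in line.lstrip("# ").split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                if key == "lloq":
                    lloq = float(val)
                elif key == "uloq":
                    uloq = float(val)
                elif key == "seed":
                    seed = int(val)
    try:
        df = pd.read_csv(
            io.StringIO("\n".join(lines[body_start:])),
            float_precision="round_trip",
        )
    except Exception as exc:  # pandas error types vary; re-raise with context
        raise ValueError(f"malformed dataset CSV {path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df[list(df.columns)]
    bad = df.index[df.TIME.isna() | df.ID.isna()]
    if len(bad):
        # +2: one header comment offset handled separately; report CSV line
        raise ValueError(f"{path}: unparseable rows at data rows {bad.tolist()}")
    df["ID"] = df.ID.astype(int)
    for col in ("EVID", "MDV", "DILUTE", "SEX", "HD"):
        df[col] = df[col].astype(int)
    for col in ("TIME", "AMT", "RATE", "II", "DV", "AGE", "WT", "CRCL"):
        df[col] = df[col].astype(float)
    try:
        return TDMDataset(df=df, lloq=lloq, uloq=uloq, seed=seed)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def study_dataset(
    n_subjects: int = 44,
    seed: int = 0,
    model: PopulationModel | None = None,
    schedule: SamplingSchedule | None = None,
    spec: DemographicsSpec | None = None,
) -> TDMDataset:
    """Convenience wrapper: sample a cohort and simulate its TDM observations."""
    model = model or PopulationModel()
    schedule = schedule or SamplingSchedule()
    spec = spec or DemographicsSpec()
    if spec.n_subjects != n_subjects:
        spec = replace(spec, n_subjects=n_subjects)
    subjects = sample_cohort(spec, model, seed)
    return simulate_tdm(subjects, model, schedule, seed + 1, LLOQ, ULOQ)
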