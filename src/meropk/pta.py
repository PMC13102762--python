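"""Monte Carlo probability of target attainment (PTA) and dosing advice.

For each renal stratum a cohort of virtual subjects is drawn (CRCL uniform
within the stratum, correlated log-normal IIV on CL and Vc, no residual error:
attainment concerns true exposure) and steady-state fT>threshold is evaluated
in closed form for every regimen of the simulation grid.  PTA is the fraction
of subjects meeting each PK/PD target at each MIC; a cell passes when
PTA >= 90%.  The same virtual subjects are reused across regimens, MICs and
targets (common random numbers), so the monotonicity of attainment in MIC,
dose and target stringency holds surely, not just in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_pk import (
    FULL_INTERVAL_TOL,
    PKTarget,
    PopulationModel,
    Regimen,
    STUDY_TARGETS,
    _ft_above_arrays,
)
from .renal import STRATA, RenalStratum

__all__ = [
    "ScenarioGrid",
    "PTAResult",
    "SafetyThresholds",
    "simulate_pta",
    "recommend",
    "safety_flags",
    "plot_pta",
]

#: CRCL sampling interval per stratum label; the open-ended bottom band uses
#: [5, 10) and the top band is capped at 140 mL/min.
STRATUM_CRCL_RANGE = {
    "<10": (5.0, 10.0),
    "10-25": (10.0, 26.0),
    "26-50": (26.0, 51.0),
    "51-90": (51.0, 91.0),
    "91-140": (91.0, 140.0),
}


@dataclass(frozen=True)
class ScenarioGrid:
    """The simulation grid: 3 doses x 3 intervals x 2 infusion durations,
    5 renal strata, 4 MICs and 4 PK/PD targets; 500 subjects per stratum."""

    doses: tuple[float, ...] = (500.0, 1000.0, 2000.0)
    intervals: tuple[float, ...] = (6.0, 8.0, 12.0)
    infusion_durations: tuple[float, ...] = (0.5, 2.0)
    strata: tuple[RenalStratum, ...] = STRATA
    mics: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    targets: tuple[PKTarget, ...] = STUDY_TARGETS
    n_subjects_per_cell: int = 500
    pta_threshold: float = 0.90
    free_fraction: float = 1.0
    crcl_sampling: str = "uniform"  # uniform | midpoint | boundary
    include_residual: bool = False

    def __post_init__(self) -> None:
        if not (self.doses and self.intervals and self.infusion_durations
                and self.strata and self.mics and self.targets):
            raise ValueError("scenario grid must be nonempty")
        if not 0 < self.pta_threshold < 1:
            raise ValueError("PTA threshold must lie in (0, 1)")
        if not 0 < self.free_fraction <= 1:
            raise ValueError("free fraction must lie in (0, 1]")
        if self.crcl_sampling not in ("uniform", "midpoint", "boundary"):
            raise ValueError(f"unknown CRCL sampling {self.crcl_sampling!r}")

    @property
    def regimens(self) -> tuple[Regimen, ...]:
        return tuple(
            Regimen(d, tau, tinf)
            for d in self.doses
            for tau in self.intervals
            for tinf in self.infusion_durations
        )


@dataclass(frozen=True)
class PTAResult:
    """Attainment probability for one (regimen, stratum, MIC, target) cell."""

    regimen: Regimen
    stratum: str
    mic: float
    target: PKTarget
    pta: float
    n: int
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.pta <= 1:
            raise ValueError("PTA must lie in [0, 1]")


@dataclass(frozen=True)
class SafetyThresholds:
    """Literature trough thresholds associated with toxicity risk, mg/L."""

    neurotoxicity_trough: float = 64.2
    nephrotoxicity_trough: float = 44.45

    def __post_init__(self) -> None:
        if min(self.neurotoxicity_trough, self.nephrotoxicity_trough) <= 0:
            raise ValueError("toxicity thresholds must be positive")


def _draw_stratum_subjects(
    model: PopulationModel,
    stratum: RenalStratum,
    n: int,
    seed: int,
    s_idx: int,
    crcl_sampling: str,
):
    """Virtual subjects of one stratum: (cl, vc) arrays, deterministic per
    (seed, stratum).  Individual CL applies the covariate model to the drawn
    CRCL; (etaCL, etaVc) come from the model's IIV covariance."""
    rng = np.random.default_rng([seed, s_idx])
    lo, hi = STRATUM_CRCL_RANGE[stratum.label]
    if crcl_sampling == "uniform":
        crcl = rng.uniform(lo, hi, size=n)
    elif crcl_sampling == "midpoint":
        crcl = np.full(n, 0.5 * (lo + hi))
    else:  # boundary: half at each endpoint
        crcl = np.where(np.arange(n) % 2 == 0, lo, hi)
    eta = rng.multivariate_normal(np.zeros(2), model.omega, size=n)
    cl = (
        model.theta_cl
        * (crcl / model.crcl_ref) ** model.theta_cov
        * np.exp(eta[:, 0])
    )
    vc = model.theta_vc * np.exp(eta[:, 1])
    return cl, vc


def _attain_fraction(ft: np.ndarray, frac: float) -> float:
    if frac >= 1.0:
        return float(np.mean(ft >= 1.0 - FULL_INTERVAL_TOL))
    return float(np.mean(ft >= frac))


def simulate_pta(
    model: PopulationModel,
    grid: ScenarioGrid | None = None,
    seed: int = 0,
) -> list[PTAResult]:
    """PTA for every (regimen, stratum, MIC, target) cell of the grid."""
    grid = grid or ScenarioGrid()
    results: list[PTAResult] = []
    n = grid.n_subjects_per_cell
    thresholds = sorted(
        {mic * t.mic_mult / grid.free_fraction
         for mic in grid.mics for t in grid.targets}
    )
    for s_idx, stratum in enumerate(grid.strata):
        cl, vc = _draw_stratum_subjects(
            model, stratum, n, seed, s_idx, grid.crcl_sampling
        )
        for reg in grid.regimens:
            ft_by_threshold = {
                thr: _ft_above_arrays(
                    cl, vc, reg.dose_mg, reg.tau_h, reg.tinf_h, thr
                )
                for thr in thresholds
            }
            for mic in grid.mics:
                for target in grid.targets:
                    thr = mic * target.mic_mult / grid.free_fraction
                    pta = _attain_fraction(ft_by_threshold[thr], target.frac)
                    results.append(
                        PTAResult(
                            regimen=reg,
                            stratum=stratum.label,
                            mic=mic,
                            target=target,
                            pta=pta,
                            n=n,
                            seed=seed,
                        )
                    )
    return results


def pta_table(results: Sequence[PTAResult]) -> pd.DataFrame:
    """Long-format table of PTA results."""
    return pd.DataFrame(
        {
            "dose_mg": r.regimen.dose_mg,
            "tau_h": r.regimen.tau_h,
            "tinf_h": r.regimen.tinf_h,
            "stratum": r.stratum,
            "mic": r.mic,
            "target": r.target.label,
            "pta": r.pta,
            "n": r.n,
            "seed": r.seed,
        }
        for r in results
    )


def _regimen_order_key(reg: Regimen) -> tuple:
    # daily dose ascending, then per-dose amount, then infusion duration
    return (reg.daily_dose_mg, reg.dose_mg, reg.tinf_h)


def _cell_label(attaining: list[Regimen], all_regimens: Sequence[Regimen]) -> str:
    if not attaining:
        return "None"
    if len(attaining) == len(all_regimens):
        return "All"
    best = min(attaining, key=_regimen_order_key)
    # "(2 h)" marks cells where only the prolonged infusion attains at that
    # dose and interval; the 0.5-h infusion is the unmarked default.
    short_ok = any(
        r.dose_mg == best.dose_mg and r.tau_h == best.tau_h and r.tinf_h < 2.0
        for r in attaining
    )
    label = f"{best.dose_mg:g} mg q{best.tau_h:g}h"
    if not short_ok:
        label += " (2 h)"
    return label


def recommend(
    results: Sequence[PTAResult],
    grid: ScenarioGrid | None = None,
) -> pd.DataFrame:
    """Dosing-recommendation table: per (target, MIC, stratum), "All" when
    every regimen reaches the PTA threshold, "None" when none does, otherwise
    the minimal attaining regimen (lowest daily dose, then per-dose amount,
    then infusion duration)."""
    grid = grid or ScenarioGrid()
    regs = grid.regimens
    cells: dict[tuple, list[Regimen]] = {}
    seen: set[tuple] = set()
    for r in results:
        key = (r.target.label, r.mic, r.stratum)
        seen.add(key + (r.regimen,))
        if r.pta >= grid.pta_threshold:
            cells.setdefault(key, []).append(r.regimen)
    missing = [
        (t.label, mic, s.label, reg.label)
        for t in grid.targets
        for mic in grid.mics
        for s in grid.strata
        for reg in regs
        if (t.label, mic, s.label, reg) not in seen
    ]
    if missing:
        raise ValueError(f"PTA results incomplete; missing cells: {missing[:5]}"
                         f"{' ...' if len(missing) > 5 else ''}")
    rows = []
    for target in grid.targets:
        for mic in grid.mics:
            row = {"target": target.label, "mic": mic}
            for stratum in grid.strata:
                attaining = cells.get((target.label, mic, stratum.label), [])
                row[stratum.label] = _cell_label(attaining, regs)
            rows.append(row)
    return pd.DataFrame(rows)


def recommendation_json(table: pd.DataFrame, path: str | Path) -> None:
    payload = [
        {k: (v if not isinstance(v, np.generic) else v.item())
         for k, v in row.items()}
        for row in table.to_dict(orient="records")
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def safety_flags(
    model: PopulationModel,
    regimen: Regimen,
    stratum: RenalStratum | str,
    thresholds: SafetyThresholds | None = None,
    n: int = 500,
    seed: int = 0,
    crcl_sampling: str = "uniform",
) -> dict:
    """Fraction of virtual subjects whose steady-state trough exceeds the
    neurotoxicity (64.2 mg/L) and nephrotoxicity (44.45 mg/L) thresholds."""
    thresholds = thresholds or SafetyThresholds()
    if isinstance(stratum, str):
        stratum = next(s for s in STRATA if s.label == stratum)
    s_idx = STRATA.index(stratum)
    cl, vc = _draw_stratum_subjects(model, stratum, n, seed, s_idx, crcl_sampling)
    ke = cl / vc
    plateau = regimen.rate_mg_h / cl
    acc = -np.expm1(-ke * regimen.tau_h)
    trough = (
        plateau * (-np.expm1(-ke * regimen.tinf_h))
        * np.exp(-ke * (regimen.tau_h - regimen.tinf_h)) / acc
    )
    return {
        "neurotoxicity": float(np.mean(trough > thresholds.neurotoxicity_trough)),
        "nephrotoxicity": float(np.mean(trough > thresholds.nephrotoxicity_trough)),
        "n": n,
        "seed": seed,
    }


def plot_pta(
    results: Sequence[PTAResult],
    path: str | Path,
    grid: ScenarioGrid | None = None,
) -> None:
    """PTA-vs-MIC panels, one row per target and one column per stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = grid or ScenarioGrid()
    tbl = pta_table(results)
    targets = [t.label for t in grid.targets]
    strata = [s.label for s in grid.strata]
    fig, axes = plt.subplots(
        len(targets), len(strata),
        figsize=(3 * len(strata), 2.4 * len(targets)),
        sharex=True, sharey=True, squeeze=False,
    )
    for i, target in enumerate(targets):
        for j, stratum in enumerate(strata):
            ax = axes[i][j]
            sub = tbl[(tbl.target == target) & (tbl.stratum == stratum)]
            for (dose, tau, tinf), reg_df in sub.groupby(
                ["dose_mg", "tau_h", "tinf_h"]
            ):
                reg_df = reg_df.sort_values("mic")
                ax.plot(reg_df.mic, 100 * reg_df.pta, marker="o", markersize=2,
                        linewidth=0.8,
                        label=f"{dose:g} q{tau:g}h/{tinf:g}h")
            ax.axhline(100 * grid.pta_threshold, color="grey", linestyle=":",
                       linewidth=0.8)
            ax.set_xscale("log", base=2)
            if i == 0:
                ax.set_title(f"CRCL {stratum}", fontsize=9)
            if j == 0:
                ax.set_ylabel(f"{target}\nPTA (%)", fontsize=8)
            if i == len(targets) - 1:
                ax.set_xlabel("MIC (mg/L)", fontsize=8)
    axes[0][0].legend(fontsize=4, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
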