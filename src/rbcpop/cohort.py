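"""Synthetic subjects and serial single-cell CBCs for a controlled-blood-loss study.

Each subject is a ground-truth parameterization of the population model plus
a reticulocyte (birth) distribution.  The study schedule mirrors the design
the analysis assumes: four baseline draws on alternating days, removal of
~10% of circulating cells (volume- and hemoglobin-independent, so the shape
of P(v, h) is untouched and only the count concentration responds), then
draws ~1.5 and ~21 days later.  After the loss the dynamic parameters shift
multiplicatively — production-like spread (D_v up), faster drift (alpha up),
and an inward clearance boundary (v_c down) — and relax back exponentially.

Ground truth that no real study can observe directly is recorded alongside:
the per-segment parameters and the mean-RBC-age trajectory M_RBC(t) from
age-moment tracking in the solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import defaults
from .grid import DensityField, Grid
from .model import ModelParams, NormalizationContext
from .solver import integrate_tracked
from .stats import CBCRecord, CellSample, SubjectSeries

__all__ = [
    "ReticSpec",
    "ResponseShift",
    "SubjectTruth",
    "StudySchedule",
    "make_subject",
    "simulate_subject",
    "make_cohort",
    "params_at",
]


@dataclass(frozen=True)
class ReticSpec:
    """Bivariate Gaussian reticulocyte (v, h) distribution in raw units (fL, pg)."""

    mean_v: float
    mean_h: float
    sd_v: float
    sd_h: float
    corr: float

    def __post_init__(self) -> None:
        if not (-1.0 < self.corr < 1.0):
            raise ValueError("corr must lie in (-1, 1)")
        if min(self.mean_v, self.mean_h, self.sd_v, self.sd_h) <= 0:
            raise ValueError("retic means and sds must be positive")

    def density_on(self, grid: Grid) -> DensityField:
        """Analytic unit-mass birth density evaluated at cell centers."""
        X, Y = grid.meshgrid()
        v = X * grid.ctx.v_bar
        h = Y * grid.ctx.h_bar
        zv = (v - self.mean_v) / self.sd_v
        zh = (h - self.mean_h) / self.sd_h
        rho = self.corr
        q = (zv**2 - 2 * rho * zv * zh + zh**2) / (1 - rho**2)
        dens = np.exp(-0.5 * q)
        total = dens.sum()
        if total <= 0:
            raise ValueError("retic density has no support on the grid")
        return DensityField(dens / total, grid)

    def sample(self, n: int, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
        cov = np.array(
            [
                [self.sd_v**2, self.corr * self.sd_v * self.sd_h],
                [self.corr * self.sd_v * self.sd_h, self.sd_h**2],
            ]
        )
        vh = rng.multivariate_normal([self.mean_v, self.mean_h], cov, size=n)
        return vh[:, 0], vh[:, 1]


@dataclass(frozen=True)
class ResponseShift:
    """Post-loss multiplicative parameter shifts and their relaxation times.

    Physiologic responses have k_alpha, k_Dv >= 1 (faster drift, more
    production-like spread) and k_vc <= 1 (delayed clearance).  tau_days is
    the exponential relaxation time constant for the D_v and v_c shifts;
    None means the shift persists.  The drift-magnitude shift relaxes on its
    own, faster clock tau_alpha_days: in the study's reading a fitted alpha
    increase largely reflects a longer true lifespan against the fixed
    nominal LS, which a literal drift speedup cannot represent — applied
    literally for weeks it would dominate the mean-age response with the
    wrong sign, so the generator treats it as an acute, quickly-normalizing
    change while the production-spread and clearance-boundary shifts persist
    (consistent with CHDW and reticulocytes still being elevated at +21 d).
    """

    k_alpha: float = 2.0
    k_Dv: float = 4.0
    k_vc: float = 0.9
    tau_days: Optional[float] = 10.0
    tau_alpha_days: Optional[float] = 3.0

    def __post_init__(self) -> None:
        if self.k_alpha < 1.0 or self.k_Dv < 1.0:
            raise ValueError("k_alpha and k_Dv must be >= 1 for a physiologic response")
        if self.k_vc > 1.0:
            raise ValueError("k_vc must be <= 1 for a physiologic response")


@dataclass
class SubjectTruth:
    """Ground truth for one synthetic subject."""

    subject_id: str
    baseline_params: ModelParams
    retic_spec: ReticSpec
    shift: ResponseShift
    loss_fraction: float
    ctx: NormalizationContext
    birth_rate: float = defaults.BIRTH_RATE
    rbc_concentration: float = defaults.RBC_CONCENTRATION
    mrbc_trajectory: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.loss_fraction < 0.2:
            raise ValueError("loss_fraction must lie in [0, 0.2)")

    def to_json_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "baseline_params": self.baseline_params.to_json_dict(),
            "retic_spec": vars(self.retic_spec).copy(),
            "shift": {
                "k_alpha": self.shift.k_alpha,
                "k_Dv": self.shift.k_Dv,
                "k_vc": self.shift.k_vc,
                "tau_days": self.shift.tau_days,
            },
            "loss_fraction": self.loss_fraction,
            "ctx": self.ctx.to_json_dict(),
            "birth_rate": self.birth_rate,
            "rbc_concentration": self.rbc_concentration,
            "mrbc_trajectory": [[t, m] for t, m in self.mrbc_trajectory],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SubjectTruth":
        return cls(
            subject_id=d["subject_id"],
            baseline_params=ModelParams.from_json_dict(d["baseline_params"]),
            retic_spec=ReticSpec(**d["retic_spec"]),
            shift=ResponseShift(**d["shift"]),
            loss_fraction=d["loss_fraction"],
            ctx=NormalizationContext.from_json_dict(d["ctx"]),
            birth_rate=d["birth_rate"],
            rbc_concentration=d["rbc_concentration"],
            mrbc_trajectory=[(t, m) for t, m in d["mrbc_trajectory"]],
        )


@dataclass(frozen=True)
class StudySchedule:
    """Draw times (days), the loss event, and the cells sampled per draw."""

    baseline_times: Tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
    loss_time: float = 8.0
    post_times: Tuple[float, ...] = (9.5, 29.0)
    cells_per_draw: int = 50_000

    def __post_init__(self) -> None:
        times = list(self.baseline_times) + list(self.post_times)
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("draw times must be strictly increasing")
        if self.baseline_times and self.loss_time <= self.baseline_times[-1]:
            raise ValueError("loss must occur after the last baseline draw")
        if self.post_times and self.post_times[0] <= self.loss_time:
            raise ValueError("post-loss draws must follow the loss")

    def draw_times(self) -> Tuple[float, ...]:
        return tuple(self.baseline_times) + tuple(self.post_times)


# -- subject construction ---------------------------------------------------

#: log-normal jitter (SD of log) for subject-level baseline parameters.  v_c
#: gets a much tighter spread: lifespan is roughly (distance to boundary) /
#: (drift speed), so a 15% spread in v_c would imply implausible inter-subject
#: lifespan variation; 4% keeps lifespans within the physiologic 90-120 d band.
BASELINE_JITTER = {
    "alpha": 0.15, "beta_v": 0.15, "beta_h": 0.15,
    "D_v": 0.15, "D_h": 0.15, "v_c": 0.04,
}

#: cohort spread of the post-loss shift factors around the median response
#: (k_alpha 2, k_Dv 4, k_vc 0.9).  Subjects vary mainly along a single latent
#: production <-> clearance balance axis z: production-dominated responders
#: (z > 0) show a larger D_v rise and little clearance delay, while
#: clearance-dominated responders (z < 0) pull the boundary v_c in further
#: and spread less.  The drift-magnitude factor varies independently and
#: little.  Values are SDs of log-factors per unit z.
SHIFT_SPREAD = {"balance_Dv": 0.60, "balance_vc": 0.15, "k_alpha": 0.05}


def make_subject(seed: int, overrides: Optional[dict] = None) -> SubjectTruth:
    """Draw one subject's ground truth; deterministic given the seed.

    ``overrides`` may replace any SubjectTruth field after jittering (pass
    e.g. ``{"shift": ResponseShift(...)}`` or ``{"jitter": 0.0}`` to disable
    the baseline-parameter jitter entirely).
    """
    overrides = dict(overrides or {})
    jitter_scale = overrides.pop("jitter", 1.0)
    rng = np.random.default_rng(seed)

    base = defaults.default_params()
    # jitter draws truncated at 2 SD: a 3-sigma draw on alpha or v_c would
    # imply an unphysiological lifespan (weeks or half a year)
    jit = {
        k: float(np.exp(np.clip(rng.normal(0.0, s * jitter_scale), -2 * s, 2 * s)))
        for k, s in BASELINE_JITTER.items()
    }
    params = ModelParams(
        alpha=base.alpha * jit["alpha"],
        beta_v=base.beta_v * jit["beta_v"],
        beta_h=base.beta_h * jit["beta_h"],
        D_v=base.D_v * jit["D_v"],
        D_h=base.D_h * jit["D_h"],
        v_c=min(base.v_c * jit["v_c"], 0.95),
    )

    retic = ReticSpec(
        mean_v=defaults.RETIC_MEAN_V * float(np.exp(rng.normal(0.0, 0.03 * jitter_scale))),
        mean_h=defaults.RETIC_MEAN_H * float(np.exp(rng.normal(0.0, 0.03 * jitter_scale))),
        sd_v=defaults.RETIC_SD_V * float(np.exp(rng.normal(0.0, 0.10 * jitter_scale))),
        sd_h=defaults.RETIC_SD_H * float(np.exp(rng.normal(0.0, 0.10 * jitter_scale))),
        corr=float(np.clip(defaults.RETIC_CORR + rng.normal(0.0, 0.05 * jitter_scale), 0.0, 0.9)),
    )

    z = float(np.clip(rng.standard_normal(), -2.0, 2.0))  # latent production <-> clearance balance
    shift = ResponseShift(
        k_alpha=max(1.0, 2.0 * float(np.exp(rng.normal(0.0, SHIFT_SPREAD["k_alpha"] * jitter_scale)))),
        k_Dv=max(1.0, 4.0 * float(np.exp(SHIFT_SPREAD["balance_Dv"] * z * jitter_scale))),
        k_vc=min(1.0, 0.9 * float(np.exp(SHIFT_SPREAD["balance_vc"] * z * jitter_scale))),
        tau_days=10.0,
    )

    truth = SubjectTruth(
        subject_id=f"S{seed:05d}",
        baseline_params=params,
        retic_spec=retic,
        shift=shift,
        loss_fraction=0.10,
        ctx=defaults.default_ctx(),
        rbc_concentration=defaults.RBC_CONCENTRATION
        * float(np.exp(rng.normal(0.0, 0.05 * jitter_scale))),
    )
    for k, v in overrides.items():
        truth = replace(truth, **{k: v})
    return truth


def params_at(truth: SubjectTruth, t: float, loss_time: float) -> ModelParams:
    """Dynamic parameters at time t: baseline before the loss, then the
    multiplicative shift relaxing as ``1 + (k - 1) e^{-(t - t_loss)/tau}``."""
    if t < loss_time:
        return truth.baseline_params
    s = truth.shift

    def decay(tau: Optional[float]) -> float:
        if tau is None:
            return 1.0
        return float(np.exp(-(t - loss_time) / tau))

    d = decay(s.tau_days)
    d_alpha = decay(s.tau_alpha_days)
    return truth.baseline_params.scaled(
        k_alpha=1.0 + (s.k_alpha - 1.0) * d_alpha,
        k_Dv=1.0 + (s.k_Dv - 1.0) * d,
        k_vc=1.0 + (s.k_vc - 1.0) * d,
    )


# -- simulation -------------------------------------------------------------


def _sample_draw(
    P: DensityField,
    R: DensityField,
    n: int,
    rng: np.random.Generator,
) -> CellSample:
    """Multinomial draw of n cells from P with within-cell uniform jitter.

    Each sampled cell is flagged as a reticulocyte with probability equal to
    the local detectable-retic share R/P of its grid cell.
    """
    grid = P.grid
    p = P.values.ravel()
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot sample from an empty density")
    counts = rng.multinomial(n, p / total)
    idx = np.repeat(np.arange(p.size), counts)
    i, j = np.unravel_index(idx, P.values.shape)
    x = grid.x_edges[i] + rng.random(n) * grid.dx
    y = grid.y_edges[j] + rng.random(n) * grid.dy
    with np.errstate(divide="ignore", invalid="ignore"):
        retic_p = np.where(P.values > 0, np.clip(R.values / np.maximum(P.values, 1e-300), 0.0, 1.0), 0.0)
    retic = rng.random(n) < retic_p[i, j]
    return CellSample(v=x * grid.ctx.v_bar, h=y * grid.ctx.h_bar, retic=retic)


def simulate_subject(
    truth: SubjectTruth,
    schedule: StudySchedule = StudySchedule(),
    seed: int = 0,
    grid: Optional[Grid] = None,
    spinup_days: float = 160.0,
    post_loss_substep: float = 0.5,
    kappa: float = defaults.KAPPA,
) -> SubjectSeries:
    """Simulate one subject's serial CBCs; fills ``truth.mrbc_trajectory``.

    The population density P, its age moment Q, and the detectable-retic pool
    R are spun up to steady state under the baseline parameters, evolved
    through the draw schedule, scaled uniformly by (1 - loss_fraction) at the
    loss (shape preserved), and evolved post-loss with the relaxing parameter
    shift refreshed every ``post_loss_substep`` days.  Count concentration is
    conc0 * (mass / baseline mass) / blood-volume factor, with plasma refilled
    linearly over PLASMA_REFILL_DAYS.
    """
    if grid is None:
        grid = defaults.sim_grid(truth.ctx)
    elif grid.ctx != truth.ctx:
        grid = grid.with_ctx(truth.ctx)
    rng = np.random.default_rng(seed)
    birth = truth.retic_spec.density_on(grid)
    retic_decay = 1.0 / defaults.TAU_RETIC

    P = DensityField.zeros(grid)
    Q = DensityField.zeros(grid)
    R = DensityField.zeros(grid)
    P, Q, R = integrate_tracked(
        P, Q, R, truth.baseline_params, birth, truth.birth_rate,
        -spinup_days, 0.0, kappa=kappa, retic_decay=retic_decay,
    )
    mass0 = P.mass
    conc0 = truth.rbc_concentration

    # event list: (time, kind)
    events: List[Tuple[float, str]] = [(t, "draw") for t in schedule.draw_times()]
    events.append((schedule.loss_time, "loss"))
    end_time = max(t for t, _ in events)
    # post-loss parameter refresh points
    t = schedule.loss_time
    while t < end_time:
        t += post_loss_substep
        events.append((min(t, end_time), "refresh"))
    events.sort()

    truth.mrbc_trajectory = [(0.0, Q.mass / P.mass)]
    records: List[CBCRecord] = []
    t_now = 0.0
    for t_ev, kind in events:
        if t_ev > t_now:
            p_now = params_at(truth, 0.5 * (t_now + t_ev), schedule.loss_time)
            P, Q, R = integrate_tracked(
                P, Q, R, p_now, birth, truth.birth_rate, t_now, t_ev,
                kappa=kappa, retic_decay=retic_decay,
            )
            t_now = t_ev
        if kind == "loss":
            keep = 1.0 - truth.loss_fraction
            P = DensityField(P.values * keep, grid, t_now)
            Q = DensityField(Q.values * keep, grid, t_now)
            R = DensityField(R.values * keep, grid, t_now)
            truth.mrbc_trajectory.append((t_now, Q.mass / P.mass))
        elif kind == "draw":
            cells = _sample_draw(P, R, schedule.cells_per_draw, rng)
            bv = _blood_volume_factor(t_now, schedule.loss_time, truth.loss_fraction)
            conc = conc0 * (P.mass / mass0) / bv
            records.append(CBCRecord(time=t_now, cells=cells, rbc_concentration=conc))
            truth.mrbc_trajectory.append((t_now, Q.mass / P.mass))
    truth.mrbc_trajectory.sort()
    return SubjectSeries(subject_id=truth.subject_id, records=records,
                         loss_time=schedule.loss_time)


def _blood_volume_factor(t: float, loss_time: float, loss_fraction: float) -> float:
    """Relative intravascular volume: drops with the loss, refills linearly."""
    if t < loss_time:
        return 1.0
    refill = min((t - loss_time) / defaults.PLASMA_REFILL_DAYS, 1.0)
    return 1.0 - loss_fraction * (1.0 - refill)


# -- cohort -----------------------------------------------------------------


def make_cohort(
    n: int,
    seed: int,
    schedule: StudySchedule = StudySchedule(),
    outdir: Optional[Path] = None,
    grid: Optional[Grid] = None,
    overrides: Optional[dict] = None,
) -> List[Tuple[SubjectTruth, SubjectSeries]]:
    """Generate n independent subjects with per-subject seeds from the master seed.

    When ``outdir`` is given, writes ``cells.csv`` (subject_id, time_days,
    v_fL, h_pg, is_retic), ``draws.csv`` (per-draw metadata), and
    ``truth.json``.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=n)
    out: List[Tuple[SubjectTruth, SubjectSeries]] = []
    for k, s in enumerate(subject_seeds):
        truth = make_subject(int(s), overrides=overrides)
        truth = replace(truth, subject_id=f"S{k:03d}")
        series = simulate_subject(truth, schedule, seed=int(s) + 1, grid=grid)
        out.append((truth, series))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cell_frames = []
        meta_rows = []
        for truth, series in out:
            for rec in series.records:
                df = rec.cells.to_dataframe()
                df.insert(0, "time_days", rec.time)
                df.insert(0, "subject_id", truth.subject_id)
                cell_frames.append(df)
                meta_rows.append(
                    {
                        "subject_id": truth.subject_id,
                        "time_days": rec.time,
                        "rbc_conc_1e6_per_uL": rec.rbc_concentration,
                    }
                )
        pd.concat(cell_frames, ignore_index=True).to_csv(outdir / "cells.csv", index=False)
        pd.DataFrame(meta_rows).to_csv(outdir / "draws.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump([t.to_json_dict() for t, _ in out], fh, indent=1)
    return out


def load_cohort_series(outdir: Path, loss_time: float) -> List[SubjectSeries]:
    """Rebuild SubjectSeries objects from the cells/draws CSVs written by make_cohort."""
    outdir = Path(outdir)
    cells = pd.read_csv(outdir / "cells.csv")
    meta = pd.read_csv(outdir / "draws.csv").set_index(["subject_id", "time_days"])
    series = []
    for sid, sdf in cells.groupby("subject_id", sort=True):
        records = []
        for t, tdf in sdf.groupby("time_days", sort=True):
            conc = float(meta.loc[(sid, t), "rbc_conc_1e6_per_uL"])
            records.append(
                CBCRecord(time=float(t), cells=CellSample.from_dataframe(tdf), rbc_concentration=conc)
            )
        series.append(SubjectSeries(subject_id=str(sid), records=records, loss_time=loss_time))
    return series
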