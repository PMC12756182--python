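"""One-site binding analysis of isothermal titration calorimetry data.

Model
-----
A receptor M in the cell (volume ``V0``) is titrated with a ligand X from
the syringe. After injection ``i`` the perfusion-cell (displaced volume)
corrections give total concentrations

    Mtot_i = M0 (1 - d_i/2) / (1 + d_i/2),   Xtot_i = X0 d_i / (1 + d_i/2)

with ``d_i`` the cumulative injected volume divided by ``V0``. The 1:1
mass-action equilibrium with stoichiometry ``n`` and dissociation constant
``Kd`` has bound complex

    [MX]_i = ((a + Kd) - sqrt((a + Kd)^2 - 4 n Mtot_i Xtot_i)) / 2,
    a = n Mtot_i + Xtot_i,

the cumulative heat is Q_i = dH * V0 * [MX]_i, and the measured heat of
injection ``i`` is the finite difference with the displaced-volume term

    q_i = Q_i - Q_{i-1} + (v_i/V0) (Q_i + Q_{i-1}) / 2 + c,

where ``c`` is a constant per-injection offset absorbing residual dilution
heat. This is the de facto single-site formulation of MicroCal/PEAQ
analysis software.

Units: volumes in microlitres, concentrations in micromolar, dH in
kcal/mol, heats in microcalories (dH * V0[uL] * C[uM] * 1e-3 ucal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

_HEAT_SCALE = 1e-3  # kcal/mol * uL * uM -> ucal

#: the instrument protocol used throughout: 200 uL cell, one 0.4 uL priming
#: shot followed by 18 aliquots of 2 uL
PAPER_V0_UL = 200.0
PAPER_INJECTIONS_UL = (0.4,) + (2.0,) * 18
PAPER_CELL_UM = 22.0
PAPER_SYRINGE_UM = 200.0


@dataclass(frozen=True)
class InjectionSchedule:
    v0: float  # cell volume, uL
    volumes: tuple[float, ...]  # per-injection volumes, uL

    def __post_init__(self) -> None:
        if self.v0 <= 0 or not self.volumes or any(v <= 0 for v in self.volumes):
            raise ValueError("volumes must be positive and schedule non-empty")

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.volumes)


def paper_schedule() -> InjectionSchedule:
    return InjectionSchedule(PAPER_V0_UL, PAPER_INJECTIONS_UL)


@dataclass(frozen=True)
class ITCExperiment:
    schedule: InjectionSchedule
    cell_conc: float  # M0, uM
    syringe_conc: float  # X0, uM
    heats: tuple[float, ...]  # integrated heat per injection, ucal
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        if self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("concentrations must be positive")
        if len(self.heats) != len(self.schedule.volumes):
            raise ValueError("one heat per injection required")


@dataclass(frozen=True)
class BindingParams:
    kd: float  # dissociation constant, uM
    dh: float  # molar enthalpy, kcal/mol
    n: float  # stoichiometry
    offset: float = 0.0  # per-injection dilution-heat offset, ucal

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.n <= 0:
            raise ValueError("Kd and n must be positive")

    @property
    def ka(self) -> float:
        return 1.0 / self.kd


@dataclass
class BindingFit:
    params: BindingParams
    stderr: dict  # per-parameter standard errors (kd se on the Kd scale)
    log10_kd_se: float
    residuals: np.ndarray
    ssr: float
    converged: bool
    n_points: int
    message: str = ""

    def kd_interval(self, z: float = 1.959964) -> tuple[float, float]:
        """Confidence interval for Kd, computed on the log10 scale."""
        lk = np.log10(self.params.kd)
        return (10 ** (lk - z * self.log10_kd_se), 10 ** (lk + z * self.log10_kd_se))


def concentrations_after(
    schedule: InjectionSchedule, m0: float, x0: float, i: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cell concentrations of both species after each injection.

    With ``i`` given (1-based injection number) returns the pair of scalars
    after that injection; ``i=0`` returns the pre-titration state (M0, 0).
    """
    dv = schedule.cumulative
    if np.any(dv >= 2 * schedule.v0):
        raise ValueError("cumulative injected volume >= 2*V0: model invalid")
    d = dv / schedule.v0
    mtot = m0 * (1 - d / 2) / (1 + d / 2)
    xtot = x0 * d / (1 + d / 2)
    if i is None:
        return mtot, xtot
    if i == 0:
        return m0, 0.0
    return float(mtot[i - 1]), float(xtot[i - 1])


def bound_concentration(mtot, xtot, kd):
    """Bound complex [MX] from total concentrations via the mass-action quadratic.

    Accepts scalars or arrays. The discriminant is clamped at zero against
    roundoff; the result satisfies 0 <= [MX] <= min(Mtot, Xtot).
    """
    if np.any(np.asarray(kd) <= 0):
        raise ValueError("Kd must be positive")
    mtot = np.asarray(mtot, dtype=float)
    xtot = np.asarray(xtot, dtype=float)
    if np.any(mtot < 0) or np.any(xtot < 0):
        raise ValueError("concentrations must be non-negative")
    s = mtot + xtot + kd
    disc = np.clip(s * s - 4.0 * mtot * xtot, 0.0, None)
    mx = (s - np.sqrt(disc)) / 2.0
    return np.minimum(mx, np.minimum(mtot, xtot))


def model_heats(params: BindingParams, experiment: ITCExperiment) -> np.ndarray:
    """Predicted integrated heat per injection (ucal)."""
    sched = experiment.schedule
    mtot, xtot = concentrations_after(sched, experiment.cell_conc, experiment.syringe_conc)
    mx = bound_concentration(params.n * mtot, xtot, params.kd)
    q_cum = params.dh * sched.v0 * mx * _HEAT_SCALE
    q_prev = np.concatenate([[0.0], q_cum[:-1]])
    v = np.asarray(sched.volumes)
    return q_cum - q_prev + (v / sched.v0) * (q_cum + q_prev) / 2.0 + params.offset


def simulate_titration(
    params: BindingParams,
    schedule: Optional[InjectionSchedule] = None,
    m0: float = PAPER_CELL_UM,
    x0: float = PAPER_SYRINGE_UM,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ITCExperiment:
    """Generate a titration: model heats plus i.i.d. Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    schedule = schedule or paper_schedule()
    clean = ITCExperiment(schedule, m0, x0, tuple([0.0] * len(schedule.volumes)))
    q = model_heats(params, clean)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sd, size=q.shape)
    return ITCExperiment(schedule, m0, x0, tuple(float(x) for x in q))


class OneSiteBindingModel:
    """Least-squares one-site fit of integrated ITC heats.

    Estimator-style interface: construct with options, call :meth:`fit` on an
    :class:`ITCExperiment`, read the fitted parameters from trailing-underscore
    attributes (``kd_`` in uM, ``dh_`` kcal/mol, ``n_``, ``offset_`` ucal) or
    the full :class:`BindingFit` in ``fit_result_``.

    The objective is multimodal at low signal-to-noise, so the optimiser is
    restarted from a deterministic list of log-spaced Kd values spanning
    1 nM - 1 mM; the first injection (the small priming shot) is excluded
    from the fit by default.

    Parameters
    ----------
    exclude_first : bool
        Drop injection 1 from the residuals (universal ITC practice for the
        priming shot).
    fixed_offset : {"fit", "last3", "zero"}
        ``"fit"`` treats the dilution offset c as a free parameter;
        ``"last3"`` pre-estimates it as the mean of the final 3 heats and
        holds it fixed; ``"zero"`` holds it at exactly 0 — the convention of
        the instrument analysis software for heats whose constant dilution
        contribution was already subtracted from the baselines.
    """

    #: deterministic multi-start grid for Kd, uM
    KD_STARTS = tuple(float(x) for x in np.logspace(-3, 3, 7))

    def __init__(
        self,
        exclude_first: bool = True,
        fixed_offset: str = "fit",
        n_bounds: tuple[float, float] = (0.05, 20.0),
        log10_kd_bounds: tuple[float, float] = (-4.0, 4.0),
    ):
        self.exclude_first = exclude_first
        self.fixed_offset = fixed_offset
        self.n_bounds = n_bounds
        self.log10_kd_bounds = log10_kd_bounds

    def get_params(self) -> dict:
        return {
            "exclude_first": self.exclude_first,
            "fixed_offset": self.fixed_offset,
            "n_bounds": self.n_bounds,
            "log10_kd_bounds": self.log10_kd_bounds,
        }

    def set_params(self, **kwargs) -> "OneSiteBindingModel":
        for k, v in kwargs.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals -----------------------------------------------------------

    def _mask(self, experiment: ITCExperiment, fit_mask) -> np.ndarray:
        m = np.ones(len(experiment.heats), dtype=bool)
        if fit_mask is not None:
            m = np.asarray(fit_mask, dtype=bool)
            if m.shape != (len(experiment.heats),):
                raise ValueError("fit_mask length mismatch")
        elif self.exclude_first:
            m[0] = False
        return m

    def fit(
        self,
        experiment: ITCExperiment,
        init: Optional[BindingParams] = None,
        fit_mask: Optional[Sequence[bool]] = None,
    ) -> "OneSiteBindingModel":
        mask = self._mask(experiment, fit_mask)
        if int(mask.sum()) < 5:
            raise ValueError("need >= 5 usable injections")
        q_obs = np.asarray(experiment.heats, dtype=float)
        if np.ptp(q_obs[mask]) < 1e-12 * max(1.0, np.abs(q_obs[mask]).max()):
            self.fit_result_ = BindingFit(
                params=BindingParams(1.0, 0.0, 1.0, float(q_obs[mask].mean())),
                stderr={}, log10_kd_se=np.inf, residuals=np.zeros(int(mask.sum())),
                ssr=0.0, converged=False, n_points=int(mask.sum()),
                message="degenerate data: all heats equal (unidentifiable)",
            )
            self.converged_ = False
            return self

        fit_c = self.fixed_offset == "fit"
        if fit_c or self.fixed_offset == "zero":
            c_fixed = 0.0
        elif self.fixed_offset == "last3":
            c_fixed = float(np.mean(q_obs[-3:]))
        else:
            raise ValueError(f"unknown fixed_offset mode {self.fixed_offset!r}")

        def residuals(theta: np.ndarray) -> np.ndarray:
            lkd, dh, n = theta[0], theta[1], theta[2]
            c = theta[3] if fit_c else c_fixed
            p = BindingParams(10.0 ** lkd, dh if dh != 0 else 1e-30, max(n, 1e-9), c)
            return model_heats(p, experiment)[mask] - q_obs[mask]

        # crude dH scale: total heat over the amount of complex formed at saturation
        mtot, xtot = concentrations_after(
            experiment.schedule, experiment.cell_conc, experiment.syringe_conc
        )
        sat = min(mtot[-1], xtot[-1])
        dh0 = float(np.sum(q_obs[mask])) / (experiment.schedule.v0 * sat * _HEAT_SCALE)
        dh0 = dh0 if abs(dh0) > 1e-9 else -1.0

        lo = [self.log10_kd_bounds[0], -1e4, self.n_bounds[0]]
        hi = [self.log10_kd_bounds[1], 1e4, self.n_bounds[1]]
        if fit_c:
            span = float(np.abs(q_obs).max())
            lo.append(-10 * span - 1.0)
            hi.append(10 * span + 1.0)

        starts = []
        if init is not None:
            starts.append(
                [np.log10(init.kd), init.dh, init.n] + ([init.offset] if fit_c else [])
            )
        for kd0 in self.KD_STARTS:
            starts.append([np.log10(kd0), dh0, 1.0] + ([0.0] if fit_c else []))

        best = None
        for x0_ in starts:
            x0c = np.clip(x0_, lo, hi)
            try:
                res = least_squares(residuals, x0c, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("optimization failed from every start")

        theta = best.x
        ssr = float(2 * best.cost)
        m = int(mask.sum())
        p_free = len(theta)
        dof = max(m - p_free, 1)
        # covariance from local curvature (Gauss-Newton J'J)
        J = best.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (ssr / dof)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(p_free, np.inf)

        kd = 10.0 ** theta[0]
        c_hat = theta[3] if fit_c else c_fixed
        params = BindingParams(kd, theta[1], theta[2], float(c_hat))
        stderr = {
            "kd": float(np.log(10) * kd * se[0]),  # delta method, Kd scale
            "dh": float(se[1]),
            "n": float(se[2]),
            "offset": float(se[3]) if fit_c else 0.0,
        }
        converged = bool(best.status > 0)
        self.fit_result_ = BindingFit(
            params=params,
            stderr=stderr,
            log10_kd_se=float(se[0]),
            residuals=residuals(theta),
            ssr=ssr,
            converged=converged,
            n_points=m,
            message=best.message,
        )
        self.kd_ = params.kd
        self.dh_ = params.dh
        self.n_ = params.n
        self.offset_ = params.offset
        self.converged_ = converged
        return self

    def predict(self, experiment: ITCExperiment) -> np.ndarray:
        if not hasattr(self, "fit_result_"):
            raise RuntimeError("call fit() first")
        return model_heats(self.fit_result_.params, experiment)


def fit_one_site(
    experiment: ITCExperiment,
    init: Optional[BindingParams] = None,
    fit_mask: Optional[Sequence[bool]] = None,
    **options,
) -> BindingFit:
    """Fit a one-site binding model; see :class:`OneSiteBindingModel`."""
    model = OneSiteBindingModel(**options)
    model.fit(experiment, init=init, fit_mask=fit_mask)
    return model.fit_result_


def read_heats_csv(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read an integrated-heat CSV with columns injection_index, volume_uL, heat_ucal."""
    import pandas as pd

    df = pd.read_csv(path)
    need = {"injection_index", "volume_uL", "heat_ucal"}
    if need - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    df = df.sort_values("injection_index")
    return df["volume_uL"].to_numpy(float), df["heat_ucal"].to_numpy(float)
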