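"""Kinetic simulator of intravascular Hb / Hb:Hp binding and clearance.

The model is a single well-stirred plasma compartment.  Unbound Hb enters by
zero-order infusion, binds endogenous or infused Hp irreversibly, and is
otherwise eliminated first-order (lumped renal loss and extravasation).  The
Hb:Hp complex is confined to plasma and eliminated either first-order or by
a saturable (Michaelis-Menten) macrophage pathway:

    d[Hb]/dt   = In_Hb(t)/V - k_on [Hb][Hp] - k_el_free [Hb]
    d[Hp]/dt   = In_Hp(t)/V - k_on [Hb][Hp]
    d[HbHp]/dt = k_on [Hb][Hp] - E([HbHp])

with E(c) = k_el_complex * c  or  vmax * c / (km + c).

All state variables are micromolar heme (binding-site) equivalents.  A
fourth state accumulates eliminated heme so that mass balance can be checked
to integrator tolerance at any time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .config import StudyConfig
from .units import hb_grams_to_umol_heme, hp_grams_to_umol_binding

__all__ = [
    "ConcentrationProfile",
    "GroundTruth",
    "infusion_rate",
    "simulate_subject",
    "simulate_study",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when the stiff integrator fails; carries the offending config."""


@dataclass
class ConcentrationProfile:
    """Per-subject concentration-time series of one plasma analyte.

    ``conc_uM`` is micromolar heme; missing (below-LOQ) samples are NaN.
    """

    subject_id: str
    analyte: str  # 'free_hb', 'bound_hb' or 'total_hb'
    times_h: np.ndarray
    conc_uM: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        if self.times_h.shape != self.conc_uM.shape:
            raise ValueError("times and concentrations must have the same length")
        finite = self.conc_uM[np.isfinite(self.conc_uM)]
        if np.any(finite < 0):
            raise ValueError("concentrations must be >= 0")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_h": self.times_h, "conc_uM": self.conc_uM})


@dataclass
class GroundTruth:
    """Noise-free truth stored with every simulated subject.

    ``k_terminal``, ``cl_L_per_h`` and ``v_L`` are per-analyte dictionaries
    of the true terminal rate (1/h), elimination clearance (L/h) and
    distribution volume (L).  The dense trajectories allow mass-balance and
    recovery scoring at any time.
    """

    k_terminal: dict
    cl_L_per_h: dict
    v_L: dict
    dense_t_h: np.ndarray
    dense_free_uM: np.ndarray
    dense_bound_uM: np.ndarray
    dense_hp_uM: np.ndarray
    dense_eliminated_uM: np.ndarray
    dose_umol_heme: float
    sampled_free_uM: np.ndarray = field(default=None)
    sampled_bound_uM: np.ndarray = field(default=None)


def infusion_rate(t, dose_umol: float, start_h: float, duration_h: float):
    """Zero-order infusion rate (umol/h) at time(s) ``t``.

    Constant ``dose/duration`` on ``[start, start+duration)``, zero outside;
    its integral over all time equals the dose.
    """
    if dose_umol < 0:
        raise ValueError(f"dose must be >= 0, got {dose_umol}")
    if duration_h <= 0:
        raise ValueError(f"duration must be > 0, got {duration_h}")
    t = np.asarray(t, dtype=float)
    rate = np.where((t >= start_h) & (t < start_h + duration_h),
                    dose_umol / duration_h, 0.0)
    return rate if rate.ndim else float(rate)


def _elimination(config: StudyConfig):
    if config.complex_clearance_mode == "first_order":
        return lambda c: config.k_el_complex * c
    vmax, km = config.vmax, config.km
    return lambda c: vmax * c / (km + c)


def _integrate(config: StudyConfig, t_end: float):
    """Integrate the model over [0, t_end]; returns (dense_t, dense_y).

    Integration is split at the infusion switch times so the stiff solver
    never steps across a rate discontinuity.
    """
    V = config.plasma_volume_L
    hb_dose = hb_grams_to_umol_heme(config.hb_dose_g)
    hp_dose = hp_grams_to_umol_binding(config.hp_dose_g, config.hp_binding_umol_per_g)
    t_hb = config.hb_infusion_h
    t_hp = t_hb + (config.hp_infusion_h if hp_dose > 0 else 0.0)
    rate_hb = hb_dose / config.hb_infusion_h
    rate_hp = hp_dose / config.hp_infusion_h if hp_dose > 0 else 0.0
    elim = _elimination(config)
    k_on, k_el_free = config.k_on, config.k_el_free

    def rhs(t, y, in_hb, in_hp):
        hb, hp, c, _ = y
        bind = k_on * hb * hp
        return (
            in_hb / V - bind - k_el_free * hb,
            in_hp / V - bind,
            bind - elim(c),
            k_el_free * hb + elim(c),
        )

    breaks = sorted({0.0, min(t_hb, t_end), min(t_hp, t_end), t_end})
    y0 = np.array([0.0, config.basal_hp_uM, 0.0, 0.0])
    ts, ys = [np.array([0.0])], [y0[:, None]]
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)
        in_hb = rate_hb if mid < t_hb else 0.0
        in_hp = rate_hp if (t_hb <= mid < t_hp) else 0.0
        t_eval = np.linspace(a, b, max(int(np.ceil((b - a) * 40)), 20) + 1)
        sol = solve_ivp(rhs, (a, b), y0, method="BDF", rtol=1e-8, atol=1e-12,
                        t_eval=t_eval, args=(in_hb, in_hp))
        if not sol.success:
            raise SimulationError(
                f"stiff integration failed on [{a}, {b}]: {sol.message}; "
                f"config={config.to_dict()}"
            )
        y0 = sol.y[:, -1]
        ts.append(sol.t[1:])
        ys.append(sol.y[:, 1:])
    dense_t = np.concatenate(ts)
    dense_y = np.concatenate(ys, axis=1)
    return dense_t, dense_y


def _sample(dense_t, dense_row, schedule):
    return np.interp(np.asarray(schedule, float), dense_t, dense_row)


def simulate_subject(config: StudyConfig, subject_seed: int,
                     subject_id: str = "s0"):
    """Simulate one subject; returns (free profile, bound profile, truth).

    Sampled concentrations carry multiplicative lognormal error with
    CV = ``config.noise_cv``; post-dose values below ``config.loq_uM`` are
    reported missing (NaN).  The t=0 baseline is exactly 0 for both
    exogenous analytes.  The returned :class:`GroundTruth` is noise-free.
    """
    schedule = np.asarray(config.schedule_h, dtype=float)
    dense_t, dense_y = _integrate(config, schedule[-1])
    free_true = np.clip(_sample(dense_t, dense_y[0], schedule), 0.0, None)
    bound_true = np.clip(_sample(dense_t, dense_y[2], schedule), 0.0, None)
    free_true[schedule == 0.0] = 0.0
    bound_true[schedule == 0.0] = 0.0

    rng = np.random.default_rng(subject_seed)
    cv = config.noise_cv

    def noisy(truth):
        if cv > 0:
            sigma = np.sqrt(np.log1p(cv**2))
            mult = np.exp(rng.normal(0.0, sigma, truth.shape) - sigma**2 / 2.0)
            obs = truth * mult
        else:
            obs = truth.copy()
        out = obs.copy()
        post = schedule > 0
        out[post & (obs < config.loq_uM)] = np.nan
        out[~post] = truth[~post]
        return out

    free = ConcentrationProfile(subject_id, "free_hb", schedule, noisy(free_true))
    bound = ConcentrationProfile(subject_id, "bound_hb", schedule, noisy(bound_true))

    V = config.plasma_volume_L
    hp_end = float(dense_y[1, -1])
    if config.complex_clearance_mode == "first_order":
        k_bound = config.k_el_complex
    else:
        k_bound = config.vmax / config.km  # low-concentration (terminal) limit
    k_free = config.k_el_free + config.k_on * hp_end
    truth = GroundTruth(
        k_terminal={"free_hb": k_free, "bound_hb": k_bound},
        cl_L_per_h={"free_hb": config.k_el_free * V, "bound_hb": k_bound * V},
        v_L={"free_hb": V, "bound_hb": V},
        dense_t_h=dense_t,
        dense_free_uM=dense_y[0],
        dense_bound_uM=dense_y[2],
        dense_hp_uM=dense_y[1],
        dense_eliminated_uM=dense_y[3],
        dose_umol_heme=hb_grams_to_umol_heme(config.hb_dose_g),
        sampled_free_uM=free_true,
        sampled_bound_uM=bound_true,
    )
    return free, bound, truth


def simulate_study(config: StudyConfig):
    """Simulate all subjects of one group.

    Deterministic given ``config.seed``; subject seeds are
    ``seed + subject index``.  Returns a list of
    (free profile, bound profile, GroundTruth) triples.
    """
    out = []
    for i in range(config.n_subjects):
        sid = f"s{i + 1:02d}"
        out.append(simulate_subject(config, config.seed + i, subject_id=sid))
    return out


def total_profile(free: ConcentrationProfile,
                  bound: ConcentrationProfile) -> ConcentrationProfile:
    """Pool unbound and bound heme into a total-heme profile.

    A sample is the sum of the available analytes; it is missing only when
    both are missing.
    """
    f = np.nan_to_num(free.conc_uM, nan=0.0)
    b = np.nan_to_num(bound.conc_uM, nan=0.0)
    tot = f + b
    both_missing = np.isnan(free.conc_uM) & np.isnan(bound.conc_uM)
    tot[both_missing] = np.nan
    return ConcentrationProfile(free.subject_id, "total_hb", free.times_h, tot)
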