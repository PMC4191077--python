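"""Non-compartmental pharmacokinetic analysis (NCA).

Per-subject parameters are estimated model-free from a concentration-time
profile and a heme-equivalent dose:

* Cmax - greatest observed concentration (ties broken to the earlier time);
* AUC(0-Clast) - linear trapezoidal rule to the last measurable sample;
* terminal rate k - ordinary least squares of ln(C) on t over the selected
  terminal points (default: best adjusted-r^2 search over the last 3..8
  quantifiable points, ties resolved toward more points);
* AUC(Clast-inf) = Clast / k, AUC(0-inf) = AUC(0-Clast) + AUC(Clast-inf);
* CL = dose / AUC(0-inf);  Vc = dose / Cmax;  t1/2 = ln(2) * Vc / CL.

The half-life definition t1/2 = ln2*Vc/CL (algebraically
ln2*AUC(0-inf)/Cmax) is the study's own reporting convention; the
conventional ln2/k is kept as a secondary diagnostic.  Samples below the
limit of quantification are treated as missing (never zero) except for the
retained pre-dose baseline.

The module follows the Model/Results idiom: build a
:class:`NonCompartmentalModel` from data, call :meth:`fit`, and read the
estimates from the returned :class:`NCAResults` (with a ``summary()``
table).  Group aggregation reports mean +/- SEM per parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .simulate import ConcentrationProfile
from .units import hb_grams_to_umol_heme

__all__ = [
    "PKParameters",
    "GroupSummary",
    "NonCompartmentalModel",
    "NCAResults",
    "cmax",
    "auc_linear_trapezoid",
    "terminal_slope",
    "auc_extrapolate",
    "nca_subject",
    "aggregate_group",
    "TerminalFitError",
    "hb_grams_to_umol_heme",
]

LN2 = math.log(2.0)


class TerminalFitError(ValueError):
    """Raised when no valid (decaying) terminal phase can be fitted."""


@dataclass
class PKParameters:
    """One subject's NCA estimates.

    The four defining identities hold exactly by construction:
    ``auc_0_inf = auc_0_clast + auc_clast_inf``; ``cl = dose/auc_0_inf``;
    ``vc = dose/cmax``; ``t_half = ln2*vc/cl``.
    """

    cmax_uM: float
    tmax_h: float
    auc_0_clast: float
    auc_clast_inf: float
    auc_0_inf: float
    k_terminal: float
    cl_L_per_h: float
    vc_L: float
    t_half_h: float
    t_half_terminal_h: float  # conventional ln2/k, diagnostic only
    n_terminal_points: int
    r_squared: float
    dose_umol_heme: float

    _TABLE_FIELDS = ("cmax_uM", "auc_0_inf", "cl_L_per_h", "vc_L", "t_half_h")


def cmax(profile: ConcentrationProfile):
    """(Cmax, tmax): greatest observed concentration; ties -> earliest time."""
    c = profile.conc_uM
    ok = np.isfinite(c)
    if not ok.any():
        raise ValueError("profile has no observed concentrations")
    i = int(np.nanargmax(c))  # argmax returns the first index on ties
    return float(c[i]), float(profile.times_h[i])


def auc_linear_trapezoid(times_h, conc_uM) -> float:
    """Linear trapezoidal AUC from the first to the last non-missing sample.

    Missing intermediate samples are spanned by a single trapezoid.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc_uM, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    ok = np.isfinite(c)
    if ok.sum() < 2:
        raise ValueError("need at least two non-missing samples for the AUC")
    t, c = t[ok], c[ok]
    return float(np.trapezoid(c, t))


def terminal_slope(times_h, conc_uM, selection: int | None = None,
                   max_points: int = 8):
    """Terminal log-linear rate: OLS of ln(C) on t.

    ``selection`` fixes the number of terminal points; by default the last
    3..``max_points`` positive samples are searched for the best adjusted
    r^2 (ties, within 1e-9, go to the larger point count).  Returns
    ``(k, r_squared, n_points)`` with ``k = -slope > 0``; rising terminal
    data raise :class:`TerminalFitError`.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc_uM, dtype=float)
    usable = np.isfinite(c) & (c > 0)
    tu, cu = t[usable], np.log(c[usable])
    if tu.size < 3:
        raise TerminalFitError(
            f"need >= 3 positive terminal samples, have {tu.size}")

    def fit_last(m):
        x, y = tu[-m:], cu[-m:]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        return -float(slope), r2, adj

    if selection is not None:
        if not 3 <= selection <= tu.size:
            raise TerminalFitError(
                f"fixed selection {selection} outside [3, {tu.size}]")
        candidates = [selection]
    else:
        candidates = range(3, min(max_points, tu.size) + 1)

    best = None
    for m in candidates:
        k, r2, adj = fit_last(m)
        if k <= 0:
            continue
        if best is None or adj > best[0] + 1e-9 or (
                abs(adj - best[0]) <= 1e-9 and m > best[3]):
            best = (adj, k, r2, m)
    if best is None:
        raise TerminalFitError("terminal phase is not decaying (k <= 0)")
    _, k, r2, m = best
    return k, r2, m


def auc_extrapolate(c_last_uM: float, k: float) -> float:
    """Extrapolated tail area AUC(Clast-inf) = Clast / k."""
    if k <= 0:
        raise ValueError(f"terminal rate must be > 0, got {k}")
    if c_last_uM < 0:
        raise ValueError(f"Clast must be >= 0, got {c_last_uM}")
    return c_last_uM / k


class NonCompartmentalModel:
    """NCA of one concentration-time profile against a heme-equivalent dose.

    Parameters
    ----------
    times_h, conc_uM : sampling times (h) and concentrations (uM heme);
        NaN marks missing/below-LOQ samples.
    dose_umol_heme : administered dose in umol heme equivalents.
    loq_uM : quantification limit; positive post-baseline values below it
        are additionally treated as missing.
    terminal_points : optional fixed terminal point count (default:
        adjusted-r^2 search over the last 3..8 points).
    """

    def __init__(self, times_h, conc_uM, dose_umol_heme: float,
                 loq_uM: float = 0.0, terminal_points: int | None = None):
        self.times_h = np.asarray(times_h, dtype=float)
        conc = np.asarray(conc_uM, dtype=float).copy()
        if dose_umol_heme <= 0:
            raise ValueError("dose must be > 0")
        if self.times_h.shape != conc.shape:
            raise ValueError("times and concentrations must match in length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        below = np.isfinite(conc) & (conc > 0) & (conc < loq_uM)
        conc[below] = np.nan
        self.conc_uM = conc
        self.dose_umol_heme = float(dose_umol_heme)
        self.loq_uM = float(loq_uM)
        self.terminal_points = terminal_points

    @classmethod
    def from_profile(cls, profile: ConcentrationProfile, dose_umol_heme: float,
                     **kw) -> "NonCompartmentalModel":
        return cls(profile.times_h, profile.conc_uM, dose_umol_heme, **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose_umol_heme: float,
                       time_col: str = "time_h", conc_col: str = "conc_uM",
                       **kw) -> "NonCompartmentalModel":
        return cls(df[time_col].to_numpy(), df[conc_col].to_numpy(),
                   dose_umol_heme, **kw)

    def fit(self) -> "NCAResults":
        t, c = self.times_h, self.conc_uM
        cm, tm = cmax(ConcentrationProfile("_", "_", t, c))
        auc_obs = auc_linear_trapezoid(t, c)
        # slope is fitted on positive quantifiable samples only
        k, r2, npts = terminal_slope(t, c, selection=self.terminal_points)
        ok = np.isfinite(c) & (c > 0)
        c_last = float(c[ok][-1])
        auc_tail = auc_extrapolate(c_last, k)
        auc_inf = auc_obs + auc_tail
        cl = self.dose_umol_heme / auc_inf
        vc = self.dose_umol_heme / cm
        params = PKParameters(
            cmax_uM=cm,
            tmax_h=tm,
            auc_0_clast=auc_obs,
            auc_clast_inf=auc_tail,
            auc_0_inf=auc_inf,
            k_terminal=k,
            cl_L_per_h=cl,
            vc_L=vc,
            t_half_h=LN2 * vc / cl,
            t_half_terminal_h=LN2 / k,
            n_terminal_points=npts,
            r_squared=r2,
            dose_umol_heme=self.dose_umol_heme,
        )
        return NCAResults(self, params)


class NCAResults:
    """Estimates from :meth:`NonCompartmentalModel.fit`.

    Parameter values are exposed both through ``.params`` (a
    :class:`PKParameters`) and as attributes (``results.cl_L_per_h`` etc.).
    """

    def __init__(self, model: NonCompartmentalModel, params: PKParameters):
        self.model = model
        self.params = params

    def __getattr__(self, name):
        params = self.__dict__.get("params")
        if params is not None and hasattr(params, name):
            return getattr(params, name)
        raise AttributeError(name)

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self.params, f.name)
                          for f in dc_fields(PKParameters)})

    def extrapolated_fraction(self) -> float:
        """AUC(Clast-inf) as a fraction of AUC(0-inf)."""
        return self.params.auc_clast_inf / self.params.auc_0_inf

    def summary(self) -> str:
        p = self.params
        lines = [
            "Non-compartmental PK analysis",
            "=" * 46,
            f"dose             {p.dose_umol_heme:12.4g} umol heme",
            f"Cmax             {p.cmax_uM:12.4g} umol/L  (tmax {p.tmax_h:g} h)",
            f"AUC(0-Clast)     {p.auc_0_clast:12.4g} h*umol/L",
            f"AUC(Clast-inf)   {p.auc_clast_inf:12.4g} h*umol/L "
            f"({100 * self.extrapolated_fraction():.1f}% of total)",
            f"AUC(0-inf)       {p.auc_0_inf:12.4g} h*umol/L",
            f"k (terminal)     {p.k_terminal:12.4g} 1/h  "
            f"(n={p.n_terminal_points}, r^2={p.r_squared:.4f})",
            f"CL               {p.cl_L_per_h:12.4g} L/h",
            f"Vc               {p.vc_L:12.4g} L",
            f"t1/2 (ln2*Vc/CL) {p.t_half_h:12.4g} h",
            f"t1/2 (ln2/k)     {p.t_half_terminal_h:12.4g} h",
        ]
        return "\n".join(lines)


def nca_subject(profile: ConcentrationProfile, dose_umol_heme: float,
                loq_uM: float = 0.0,
                terminal_points: int | None = None) -> PKParameters:
    """Functional wrapper: full per-subject NCA in one call."""
    model = NonCompartmentalModel.from_profile(
        profile, dose_umol_heme, loq_uM=loq_uM, terminal_points=terminal_points)
    return model.fit().params


@dataclass
class GroupSummary:
    """Per-parameter mean +/- SEM across the subjects of one group."""

    n: int
    mean: dict
    sem: dict

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"mean": self.mean, "sem": self.sem})
        df.index.name = "parameter"
        return df


def aggregate_group(params_list) -> GroupSummary:
    """Mean and SEM (sd/sqrt(n), ddof=1) of each PK parameter over subjects.

    With a single subject the SEM is reported missing (NaN).  Accepts
    :class:`PKParameters` or :class:`NCAResults` items.
    """
    if len(params_list) == 0:
        raise ValueError("cannot aggregate an empty group")
    rows = []
    for p in params_list:
        if isinstance(p, NCAResults):
            p = p.params
        rows.append({f.name: getattr(p, f.name) for f in dc_fields(PKParameters)})
    df = pd.DataFrame(rows)
    n = len(df)
    mean = df.mean().to_dict()
    if n > 1:
        sem = (df.std(ddof=1) / math.sqrt(n)).to_dict()
    else:
        sem = {k: float("nan") for k in mean}
    return GroupSummary(n=n, mean=mean, sem=sem)
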