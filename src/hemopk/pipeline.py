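"""End-to-end study reproduction: simulate -> measure -> partition -> NCA.

For every arm of a study design the pipeline simulates per-subject unbound
and bound heme profiles, pushes each sample through the forward measurement
chain (absorbance spectrum -> spectral speciation -> total heme; SEC
chromatogram -> peak integration -> percent free -> free/bound split), runs
the per-subject non-compartmental analysis on each analyte, and aggregates
mean +/- SEM group tables.  A bypass mode runs the NCA directly on the
simulated concentrations, which guards the measurement stages against bias.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import StudyArm, StudyConfig, reference_study
from .nca import NonCompartmentalModel, aggregate_group, TerminalFitError
from .sec import generate_chromatogram, integrate_peaks, percent_free, \
    speciate_concentration
from .simulate import ConcentrationProfile, simulate_study, total_profile
from .spectra import ExtinctionTable, Spectrum, blank_correct, fit_species, \
    forward_spectrum
from .units import hb_grams_to_umol_heme

log = logging.getLogger("hemopk")

REPORT_COLUMNS = ["cmax_uM", "auc_0_inf", "cl_L_per_h", "vc_L", "t_half_h"]


@dataclass
class RunManifest:
    """Traceability record written next to every study run."""

    config_hash: str
    seed: int
    version: str
    outputs: dict
    started: str
    finished: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _config_hash(arms) -> str:
    blob = yaml.safe_dump([{**a.config.to_dict(), "name": a.name,
                            "analytes": list(a.analytes),
                            "phenotype": a.phenotype} for a in arms],
                          sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_study_file(path) -> list[StudyArm]:
    """Read a multi-arm study design from YAML.

    Layout: optional ``defaults`` mapping of StudyConfig overrides plus an
    ``arms`` list of mappings with ``name``, optional ``analytes``,
    ``phenotype`` and per-arm StudyConfig overrides.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    defaults = doc.get("defaults", {})
    arms = []
    for spec in doc["arms"]:
        spec = dict(spec)
        name = spec.pop("name")
        analytes = tuple(spec.pop("analytes", ("free", "bound")))
        phenotype = spec.pop("phenotype", "dog")
        cfg = StudyConfig.from_dict({**defaults, **spec})
        arms.append(StudyArm(name, cfg, analytes, phenotype))
    if len({a.name for a in arms}) != len(arms):
        raise ValueError("arm names must be unique")
    return arms


def measure_sample(free_uM: float, bound_uM: float, phenotype: str,
                   table: ExtinctionTable, blank: Spectrum,
                   chrom_noise_sd: float = 0.0, seed: int | None = None):
    """One sample through the full measurement chain.

    Returns the recovered (free_uM, bound_uM).  The plasma spectrum is built
    from total heme (as ferrous heme), overlaid on the turbidity blank and
    blank-corrected before speciation; the SEC chromatogram is generated,
    integrated and partitioned.
    """
    total_true = free_uM + bound_uM
    sample = forward_spectrum({"ferrous": total_true}, table)
    sample = Spectrum(sample.wavelengths_nm,
                      sample.absorbance_AU + np.interp(
                          sample.wavelengths_nm, blank.wavelengths_nm,
                          blank.absorbance_AU))
    corrected = blank_correct(sample, blank)
    total_meas = fit_species(corrected, table).total_heme_uM
    chrom = generate_chromatogram(free_uM, bound_uM, phenotype,
                                  noise_sd=chrom_noise_sd, seed=seed)
    pct = percent_free(integrate_peaks(chrom))
    if np.isnan(pct):
        # no peaks at all: a heme-free sample measures 0, anything else is
        # a genuinely unreadable (missing) sample
        if total_meas < 1e-9:
            return 0.0, 0.0
        return float("nan"), float("nan")
    split = speciate_concentration(total_meas, min(max(pct, 0.0), 100.0))
    return split.free_uM, split.bound_uM


def default_blank(table: ExtinctionTable | None = None) -> Spectrum:
    """Gently sloping turbidity baseline used as the pre-dose plasma blank."""
    if table is None:
        table = ExtinctionTable.default()
    lam = table.wavelengths_nm
    absorb = 0.05 * (lam[-1] - lam) / (lam[-1] - lam[0]) + 0.01
    return Spectrum(lam.copy(), absorb)


def run_arm(arm: StudyArm, bypass_measurement: bool = False,
            chrom_noise_sd: float = 0.0):
    """Simulate and analyze one arm.

    Returns ``(per_subject_df, summaries, profiles)`` where ``summaries``
    maps analyte -> GroupSummary (an analyte with no analyzable subject is
    omitted) and ``profiles`` maps analyte -> list of profiles.
    """
    table = ExtinctionTable.default()
    blank = default_blank(table)
    dose = hb_grams_to_umol_heme(arm.config.hb_dose_g)
    subjects = simulate_study(arm.config)

    analyte_profiles: dict[str, list[ConcentrationProfile]] = {
        a: [] for a in arm.analytes}
    for free, bound, _truth in subjects:
        if not bypass_measurement:
            f_meas = np.full_like(free.conc_uM, np.nan)
            b_meas = np.full_like(bound.conc_uM, np.nan)
            for i, t in enumerate(free.times_h):
                f = 0.0 if np.isnan(free.conc_uM[i]) else free.conc_uM[i]
                b = 0.0 if np.isnan(bound.conc_uM[i]) else bound.conc_uM[i]
                fm, bm = measure_sample(f, b, arm.phenotype, table, blank,
                                        chrom_noise_sd,
                                        seed=arm.config.seed + i)
                f_meas[i], b_meas[i] = max(fm, 0.0), max(bm, 0.0)
            post = free.times_h > 0
            f_meas[post & (f_meas < arm.config.loq_uM)] = np.nan
            b_meas[post & (b_meas < arm.config.loq_uM)] = np.nan
            free = ConcentrationProfile(free.subject_id, "free_hb",
                                        free.times_h, f_meas)
            bound = ConcentrationProfile(bound.subject_id, "bound_hb",
                                         bound.times_h, b_meas)
        made = {"free": free, "bound": bound,
                "total": total_profile(free, bound)}
        for a in arm.analytes:
            analyte_profiles[a].append(made[a])

    rows, summaries = [], {}
    for analyte, profiles in analyte_profiles.items():
        fits = []
        for prof in profiles:
            try:
                res = NonCompartmentalModel.from_profile(
                    prof, dose, loq_uM=arm.config.loq_uM).fit()
            except (TerminalFitError, ValueError) as exc:
                log.warning("arm %s subject %s analyte %s: NCA unavailable (%s)",
                            arm.name, prof.subject_id, analyte, exc)
                rows.append({"arm": arm.name, "subject": prof.subject_id,
                             "analyte": analyte, "status": f"failed: {exc}"})
                continue
            fits.append(res)
            row = {"arm": arm.name, "subject": prof.subject_id,
                   "analyte": analyte, "status": "ok"}
            row.update(res.to_series().to_dict())
            rows.append(row)
        if fits:
            summaries[analyte] = aggregate_group(fits)
    return pd.DataFrame(rows), summaries, analyte_profiles


def run_study(arms_or_config, out_dir, seed: int | None = None,
              bypass_measurement: bool = False) -> RunManifest:
    """Run a full multi-arm study and write all stage outputs as CSV.

    ``arms_or_config`` is a list of :class:`StudyArm`, a YAML study file
    path, or None for the packaged seven-arm reference design.  ``seed``
    re-seeds every arm (arm index spaced) when given.  A failing arm is
    logged and skipped; remaining arms continue.
    """
    from pathlib import Path

    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if arms_or_config is None:
        arms = reference_study(seed=seed or 0)
    elif isinstance(arms_or_config, (str, Path)):
        arms = load_study_file(arms_or_config)
    else:
        arms = list(arms_or_config)
    if seed is not None:
        arms = [StudyArm(a.name, a.config.replace(seed=seed + 100 * (i + 1)),
                         a.analytes, a.phenotype)
                for i, a in enumerate(arms)]

    outputs = {}
    subject_tables, summary_rows = [], []
    failed = []
    for arm in arms:
        try:
            df, summaries, profiles = run_arm(
                arm, bypass_measurement=bypass_measurement)
        except Exception as exc:  # keep remaining arms running
            log.error("arm %s failed: %s", arm.name, exc)
            failed.append(arm.name)
            continue
        arm_dir = out / arm.name
        arm_dir.mkdir(exist_ok=True)
        for analyte, profs in profiles.items():
            for prof in profs:
                p = arm_dir / f"{prof.subject_id}_{analyte}.csv"
                prof.to_frame().to_csv(p, index=False)
        subject_tables.append(df)
        for analyte, summ in summaries.items():
            for param in REPORT_COLUMNS:
                summary_rows.append({
                    "arm": arm.name, "analyte": analyte, "parameter": param,
                    "mean": summ.mean[param], "sem": summ.sem[param],
                    "n": summ.n,
                })
        outputs[arm.name] = str(arm_dir)

    subjects_df = (pd.concat(subject_tables, ignore_index=True)
                   if subject_tables else pd.DataFrame())
    subjects_path = out / "pk_subjects.csv"
    subjects_df.to_csv(subjects_path, index=False)
    summary_df = pd.DataFrame(summary_rows)
    summary_path = out / "pk_summary.csv"
    summary_df.to_csv(summary_path, index=False)
    outputs["pk_subjects"] = str(subjects_path)
    outputs["pk_summary"] = str(summary_path)

    manifest = RunManifest(
        config_hash=_config_hash(arms),
        seed=seed if seed is not None else arms[0].config.seed,
        version=__version__,
        outputs=outputs,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.to_json(out / "manifest.json")
    if failed:
        raise RuntimeError(f"arms failed: {failed} (others completed)")
    return manifest


def plot_profiles(profiles_by_analyte: dict, out_path, arm_name: str = ""):
    """Mean +/- SEM concentration-time plot with terminal exponential fits.

    One trace per analyte; each trace is overlaid with the single
    exponential ``C = Clast * exp(-k (t - tlast))`` implied by the terminal
    log-linear fit of the mean profile.  Returns the figure path, or None
    when every analyte is empty.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .nca import terminal_slope

    any_data = False
    fig, ax = plt.subplots(figsize=(6, 4))
    for analyte, profiles in profiles_by_analyte.items():
        if not profiles:
            log.warning("no profiles for analyte %s; skipped", analyte)
            continue
        any_data = True
        times = profiles[0].times_h
        mat = np.vstack([p.conc_uM for p in profiles])
        mean = np.nanmean(mat, axis=0)
        n_obs = np.sum(np.isfinite(mat), axis=0)
        with np.errstate(invalid="ignore"):
            sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(
                np.maximum(n_obs, 1))
        line = ax.errorbar(times, mean, yerr=sem, marker="o", ms=3,
                           capsize=2, ls="-", lw=0.8, label=analyte)
        try:
            k, _, npts = terminal_slope(times, mean)
            ok = np.isfinite(mean) & (mean > 0)
            t_last, c_last = times[ok][-1], mean[ok][-1]
            tt = np.linspace(times[ok][-npts], t_last, 50)
            ax.plot(tt, c_last * np.exp(-k * (tt - t_last)), "--",
                    color=line[0].get_color(), lw=1.2)
        except Exception:
            pass
    if not any_data:
        plt.close(fig)
        log.warning("nothing to plot for %s", arm_name)
        return None
    ax.set_xlabel("time (h)")
    ax.set_ylabel("plasma heme (μmol/L)")
    ax.set_title(arm_name)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
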