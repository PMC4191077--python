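"""Study configuration: dosing regimens, kinetic parameters, sampling schedule.

A :class:`StudyConfig` fully determines one simulated treatment group
(dose sizes, infusion durations, binding/elimination kinetics, noise level,
number of subjects and random seed).  :func:`reference_study` builds the
seven-arm beagle study design that the simulator emulates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .units import HP_BINDING_UMOL_PER_G

#: Sampling schedule in hours: pre-dose baseline plus 21 post-dose draws
#: from 5 minutes to 60 hours (22 points in total).
DEFAULT_SCHEDULE_H: tuple[float, ...] = (
    0.0, 5.0 / 60.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0,
    5.0, 6.0, 8.0, 12.0, 16.0, 24.0, 32.0, 36.0, 48.0, 60.0,
)

VALID_CLEARANCE_MODES = ("first_order", "michaelis_menten")
VALID_PHENOTYPES = ("dog", "human_dimeric", "human_multimeric")


@dataclass
class StudyConfig:
    """Configuration of one simulated treatment group.

    Concentrations are micromolar heme equivalents; times are hours.

    Parameters
    ----------
    hb_dose_g : Hb bolus mass (g), infused at a zero-order rate.
    hp_dose_g : Hp dose mass (g); 0 means no exogenous Hp.
    hb_infusion_min, hp_infusion_min : infusion durations in minutes.  The Hp
        infusion starts when the Hb infusion ends.
    plasma_volume_L : physical plasma volume of the central compartment.
    basal_hp_uM : endogenous Hp at t=0, in heme binding-site equivalents.
    k_on : bimolecular association rate, L/(umol*h).  Binding is irreversible.
    k_el_free : first-order disappearance rate of unbound Hb (1/h), lumping
        renal loss and extravasation.
    complex_clearance_mode : 'first_order' or 'michaelis_menten' elimination
        of the Hb:Hp complex.
    k_el_complex : first-order complex elimination rate (1/h).
    vmax, km : Michaelis-Menten parameters, umol/(L*h) and umol/L.
    hp_binding_umol_per_g : Hp gram -> umol binding-site conversion.
    noise_cv : proportional (lognormal) assay error coefficient of variation.
    loq_uM : limit of quantification; post-dose samples below it are missing.
    n_subjects : subjects in the group.
    seed : study-level random seed; subject seeds are seed + subject index.
    schedule_h : strictly increasing sampling times (h), starting at 0.
    """

    hb_dose_g: float = 4.0
    hp_dose_g: float = 0.0
    hb_infusion_min: float = 10.0
    hp_infusion_min: float = 10.0
    plasma_volume_L: float = 0.6
    basal_hp_uM: float = 150.0
    k_on: float = 1.0
    k_el_free: float = 2.0
    complex_clearance_mode: str = "first_order"
    k_el_complex: float = 0.058
    vmax: float = 30.0
    km: float = 50.0
    hp_binding_umol_per_g: float = HP_BINDING_UMOL_PER_G
    noise_cv: float = 0.10
    loq_uM: float = 1.0
    n_subjects: int = 6
    seed: int = 0
    schedule_h: tuple[float, ...] = DEFAULT_SCHEDULE_H

    def __post_init__(self) -> None:
        self.schedule_h = tuple(float(t) for t in self.schedule_h)
        for name in (
            "hb_dose_g", "hp_dose_g", "plasma_volume_L", "basal_hp_uM",
            "k_on", "k_el_free", "k_el_complex", "vmax", "km",
            "noise_cv", "loq_uM",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.plasma_volume_L <= 0:
            raise ValueError("plasma_volume_L must be > 0")
        if self.hb_infusion_min <= 0 or self.hp_infusion_min <= 0:
            raise ValueError("infusion durations must be > 0")
        if self.complex_clearance_mode not in VALID_CLEARANCE_MODES:
            raise ValueError(
                f"complex_clearance_mode must be one of {VALID_CLEARANCE_MODES}, "
                f"got {self.complex_clearance_mode!r}"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        sched = self.schedule_h
        if len(sched) < 2 or any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule_h must be strictly increasing with >= 2 points")
        if sched[0] != 0.0:
            raise ValueError("schedule_h must start with the t=0 baseline")

    # -- derived quantities ------------------------------------------------
    @property
    def hb_infusion_h(self) -> float:
        return self.hb_infusion_min / 60.0

    @property
    def hp_infusion_h(self) -> float:
        return self.hp_infusion_min / 60.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule_h"] = list(self.schedule_h)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown StudyConfig keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "StudyConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class StudyArm:
    """One named treatment group with its configuration and analyte list.

    ``analytes`` selects which profiles are analyzed: 'total' for groups
    where unbound and bound heme are pooled, or ('free', 'bound').
    ``phenotype`` controls the retention-time structure of the forward
    chromatogram model for the bound complex.
    """

    name: str
    config: StudyConfig
    analytes: tuple[str, ...] = ("free", "bound")
    phenotype: str = "dog"

    def __post_init__(self) -> None:
        if self.phenotype not in VALID_PHENOTYPES:
            raise ValueError(
                f"phenotype must be one of {VALID_PHENOTYPES}, got {self.phenotype!r}"
            )
        for a in self.analytes:
            if a not in ("free", "bound", "total"):
                raise ValueError(f"unknown analyte {a!r}")


def reference_study(seed: int = 0, n_small: int = 4, n_large: int = 6) -> list[StudyArm]:
    """The seven-arm beagle study design.

    Every arm doses 4 g Hb over 10 min.  Arms with Hp dose 4 g Hp over the
    following 10 min.  Glucocorticoid (prednisone) pre-treatment is emulated
    purely as an elevated endogenous Hp pool (360 vs 150 uM binding-site
    equivalents); it has no other kinetic effect.  Dog and human Hb share one
    parameter set: in vivo their kinetics were indistinguishable.
    """
    base = StudyConfig(seed=seed)
    normal, pred = 150.0, 360.0
    arms = [
        StudyArm("dog_hb", base.replace(basal_hp_uM=normal, n_subjects=n_small,
                                        seed=seed + 100), ("total",), "dog"),
        StudyArm("human_hb", base.replace(basal_hp_uM=normal, n_subjects=n_small,
                                          seed=seed + 200), ("total",), "dog"),
        StudyArm("prednisone_dog_hb",
                 base.replace(basal_hp_uM=pred, n_subjects=n_large, seed=seed + 300),
                 ("free", "bound"), "dog"),
        StudyArm("prednisone_human_hb",
                 base.replace(basal_hp_uM=pred, n_subjects=n_large, seed=seed + 400),
                 ("free", "bound"), "dog"),
        StudyArm("human_hb_dimeric_hp",
                 base.replace(basal_hp_uM=normal, hp_dose_g=4.0, n_subjects=n_large,
                              seed=seed + 500), ("free", "bound"), "human_dimeric"),
        StudyArm("human_hb_multimeric_hp",
                 base.replace(basal_hp_uM=normal, hp_dose_g=4.0, n_subjects=n_large,
                              seed=seed + 600), ("free", "bound"), "human_multimeric"),
        StudyArm("prednisone_human_hb_multimeric_hp",
                 base.replace(basal_hp_uM=pred, hp_dose_g=4.0, n_subjects=n_large,
                              seed=seed + 700), ("free", "bound"), "human_multimeric"),
    ]
    return arms
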