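"""Dose and unit conversions for heme-based dosing.

All plasma concentrations in this package are expressed as micromolar heme
equivalents: one hemoglobin (Hb) tetramer carries four heme groups, and one
gram-equivalent of haptoglobin (Hp) is expressed through the amount of Hb
heme it can bind.
"""

from __future__ import annotations

#: Molecular weight of the Hb tetramer (g/mol).
HB_MW_G_PER_MOL = 64458.0

#: Heme groups per Hb tetramer.
HEMES_PER_TETRAMER = 4

#: Hp binding capacity in micromol heme-equivalents per gram of Hp.
#: Chosen so that a 4 g Hp dose binds a 4 g Hb dose at 1:1 gram stoichiometry.
HP_BINDING_UMOL_PER_G = 1e6 * HEMES_PER_TETRAMER / HB_MW_G_PER_MOL


def hb_grams_to_umol_heme(
    grams: float,
    hb_mw_g_per_mol: float = HB_MW_G_PER_MOL,
    hemes_per_tetramer: int = HEMES_PER_TETRAMER,
) -> float:
    """Convert a mass of Hb (grams) to micromoles of heme.

    Parameters
    ----------
    grams : mass of Hb tetramer.
    hb_mw_g_per_mol : tetramer molecular weight, default 64 458 g/mol.
    hemes_per_tetramer : hemes per tetramer, default 4.
    """
    if grams < 0:
        raise ValueError(f"Hb mass must be >= 0, got {grams}")
    if hb_mw_g_per_mol <= 0:
        raise ValueError(f"Hb molecular weight must be > 0, got {hb_mw_g_per_mol}")
    return grams / hb_mw_g_per_mol * hemes_per_tetramer * 1e6


def hp_grams_to_umol_binding(
    grams: float,
    binding_umol_per_g: float = HP_BINDING_UMOL_PER_G,
) -> float:
    """Convert a mass of Hp (grams) to micromoles of heme binding-site equivalents."""
    if grams < 0:
        raise ValueError(f"Hp mass must be >= 0, got {grams}")
    if binding_umol_per_g <= 0:
        raise ValueError(f"binding capacity must be > 0, got {binding_umol_per_g}")
    return grams * binding_umol_per_g


def dose_grams_from_volume(volume_ml: float, concentration_g_per_dl: float) -> float:
    """Administered protein mass (g) from solution volume (ml) and concentration (g/dl)."""
    if volume_ml < 0 or concentration_g_per_dl < 0:
        raise ValueError("volume and concentration must be >= 0")
    return volume_ml / 100.0 * concentration_g_per_dl
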