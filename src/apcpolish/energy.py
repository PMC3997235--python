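"""Energy-density adjustment and energy unit conversion.

Food intakes in g/day are re-expressed as grams per fixed daily energy,
``intake / energy * 4186`` — grams per 4,186 kJ (1,000 kcal) per day.
This removes between-group differences in total consumption before the
two-way decomposition.  The adjustment is applied to cell means (mean
intake over mean energy); per-subject adjustment before aggregation is
available through the microdata generator and gives slightly different
cell values, since a ratio of means is not a mean of ratios.
"""

from __future__ import annotations

import numpy as np

#: Reference daily energy: 4,186 kJ = 1,000 kcal.
REFERENCE_ENERGY_KJ: float = 4186.0

#: Thermochemical kilocalorie, kJ per kcal.
KCAL_TO_KJ_FACTOR: float = 4.186


def energy_adjust(intake, energy_kj, reference_energy_kj: float = REFERENCE_ENERGY_KJ):
    """Energy-density adjust an intake: g/day -> g per 4,186 kJ per day.

    Parameters
    ----------
    intake
        Mean food intake in g/day, scalar or array; must be >= 0.
    energy_kj
        Mean energy intake in kJ/day, scalar or array; must be > 0.
    reference_energy_kj
        The fixed daily energy to scale to.  Default 4,186 kJ.

    Returns
    -------
    Adjusted intake at full precision, same shape as the inputs.
    """
    intake = np.asarray(intake, dtype=float)
    energy_kj = np.asarray(energy_kj, dtype=float)
    if np.any(~np.isfinite(intake)) or np.any(~np.isfinite(energy_kj)):
        raise ValueError("intake and energy must be finite")
    if np.any(intake < 0):
        raise ValueError("intake must be non-negative")
    if np.any(energy_kj <= 0):
        raise ValueError("energy must be strictly positive")
    out = intake / energy_kj * reference_energy_kj
    return float(out) if out.ndim == 0 else out


def inverse_energy_adjust(adjusted, energy_kj,
                          reference_energy_kj: float = REFERENCE_ENERGY_KJ):
    """Invert :func:`energy_adjust`: recover g/day from g per 4,186 kJ."""
    adjusted = np.asarray(adjusted, dtype=float)
    energy_kj = np.asarray(energy_kj, dtype=float)
    out = adjusted * energy_kj / reference_energy_kj
    return float(out) if out.ndim == 0 else out


def kcal_to_kj(value, factor: float = KCAL_TO_KJ_FACTOR):
    """Convert kcal to kJ (factor 4.186, so 1,980 kcal -> 8,288 kJ)."""
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("energy in kcal must be non-negative")
    out = value * factor
    return float(out) if out.ndim == 0 else out
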