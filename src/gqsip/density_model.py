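"""Isotope substitution model for DNA in a CsCl gradient.

Closed-form maps among GC content, buoyant density, mean nucleotide
molecular weight, and 13C atom fraction excess (AFE), in both directions.

The physical picture: the buoyant density of unlabeled DNA is a linear
function of its GC content; incorporating heavy carbon raises the mean
molecular weight of a nucleotide, and the relative mass increase translates
into a proportional buoyant-density increase.  Comparing a taxon's weighted
mean density between an unlabeled and a labeled treatment therefore yields
its isotope enrichment, with the GC effect absorbed by the paired
unlabeled density.

All functions accept scalars or numpy arrays and are exact inverses of one
another (see ``density_from_afe``), which the simulator exploits as a
forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IsotopeModelConstants",
    "DEFAULT_CONSTANTS",
    "DENSITY_RANGE",
    "gc_from_light_density",
    "gc_out_of_range",
    "mw_light",
    "mw_heavy_max_13c",
    "afe_from_densities",
    "density_from_afe",
]

#: plausible buoyant densities for DNA in CsCl (g/ml); inputs outside are rejected
DENSITY_RANGE = (1.55, 1.85)


@dataclass(frozen=True)
class IsotopeModelConstants:
    """Constants of the standard 13C qSIP parameterization.

    density = density_intercept + density_slope * GC  (unlabeled DNA, g/ml)
    M_light = mw_intercept + mw_gc_slope * GC         (g/mol per nucleotide)
    M_heavymax - M_light = dmw_max_intercept + dmw_max_gc_slope * GC
                                                      (full 13C substitution)
    nat_abund_13c: natural 13C atom fraction subtracted as background.

    Frozen; alternative parameterizations (e.g. 18O, 15N) are supplied as a
    new instance, never by mutating this one.
    """

    density_intercept: float = 1.646057  # g/ml
    density_slope: float = 0.083506  # g/ml per GC fraction
    mw_gc_slope: float = 0.496  # g/mol per GC fraction
    mw_intercept: float = 307.691  # g/mol
    dmw_max_intercept: float = 9.974564  # g/mol
    dmw_max_gc_slope: float = -0.4987282  # g/mol per GC fraction
    nat_abund_13c: float = 0.01111233  # atom fraction


DEFAULT_CONSTANTS = IsotopeModelConstants()


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return arr


def _check_density(w: np.ndarray, name: str) -> None:
    lo, hi = DENSITY_RANGE
    if np.any((w <= lo) | (w >= hi)):
        raise ValueError(
            f"{name} outside plausible DNA buoyant density range {DENSITY_RANGE} g/ml"
        )


def _ret(x: np.ndarray, scalar: bool):
    return float(x) if scalar else x


def gc_from_light_density(w_light, constants: IsotopeModelConstants = DEFAULT_CONSTANTS):
    """GC content inferred from unlabeled buoyant density.

    Returns the GC fraction unclamped; values outside [0, 1] can arise from
    noisy density estimates and are flagged downstream via
    :func:`gc_out_of_range`, never silently clamped.
    """
    scalar = np.isscalar(w_light) or np.ndim(w_light) == 0
    w = _as_array(w_light, "w_light")
    _check_density(w, "w_light")
    g = (w - constants.density_intercept) / constants.density_slope
    return _ret(g, scalar)


def gc_out_of_range(g) -> np.ndarray:
    """Boolean flag for GC estimates outside the physical [0, 1] range."""
    g = np.asarray(g, dtype=float)
    return (g < 0.0) | (g > 1.0)


def mw_light(g, constants: IsotopeModelConstants = DEFAULT_CONSTANTS):
    """Mean molecular weight (g/mol) of a nucleotide of unlabeled DNA."""
    scalar = np.isscalar(g) or np.ndim(g) == 0
    g = _as_array(g, "g")
    return _ret(constants.mw_gc_slope * g + constants.mw_intercept, scalar)


def mw_heavy_max_13c(g, m_light, constants: IsotopeModelConstants = DEFAULT_CONSTANTS):
    """Maximum nucleotide molecular weight under full 13C substitution.

    The increment over M_light decreases (slightly) with GC because G:C
    pairs carry marginally fewer carbon atoms per unit mass.
    """
    scalar = (np.isscalar(g) or np.ndim(g) == 0) and (
        np.isscalar(m_light) or np.ndim(m_light) == 0
    )
    g = _as_array(g, "g")
    m_light = _as_array(m_light, "m_light")
    out = m_light + constants.dmw_max_intercept + constants.dmw_max_gc_slope * g
    return _ret(out, scalar)


def afe_from_densities(
    w_light, w_lab, constants: IsotopeModelConstants = DEFAULT_CONSTANTS
):
    """13C atom fraction excess from the labeled/unlabeled density pair.

    GC is inferred from ``w_light``; the labeled molecular weight follows
    from the relative density shift, M_lab = M_light * (W_lab / W_light);
    the atom fraction excess is the fractional progress toward full
    substitution scaled by (1 - natural 13C abundance).  Negative values
    (W_lab < W_light, i.e. measurement noise) are returned as-is.

    Multiply by 100 for APE (atom percent excess).
    """
    scalar = (np.isscalar(w_light) or np.ndim(w_light) == 0) and (
        np.isscalar(w_lab) or np.ndim(w_lab) == 0
    )
    wl = _as_array(w_light, "w_light")
    wb = _as_array(w_lab, "w_lab")
    _check_density(wl, "w_light")
    _check_density(wb, "w_lab")
    g = (wl - constants.density_intercept) / constants.density_slope
    m_light = constants.mw_gc_slope * g + constants.mw_intercept
    m_heavymax = m_light + constants.dmw_max_intercept + constants.dmw_max_gc_slope * g
    m_lab = m_light * (wb / wl)
    a = (m_lab - m_light) / (m_heavymax - m_light) * (1.0 - constants.nat_abund_13c)
    return _ret(a, scalar)


def density_from_afe(
    g, a, w_light=None, constants: IsotopeModelConstants = DEFAULT_CONSTANTS
):
    """Buoyant density of DNA with GC fraction ``g`` at atom fraction excess ``a``.

    Exact inverse of :func:`afe_from_densities`; used by the simulator as
    the forward model.  If ``w_light`` is not supplied it is computed from
    ``g`` via the linear GC-density relation.
    """
    scalar = (np.isscalar(g) or np.ndim(g) == 0) and (np.isscalar(a) or np.ndim(a) == 0)
    g = _as_array(g, "g")
    a = _as_array(a, "a")
    a_max = 1.0 - constants.nat_abund_13c
    if np.any((a < 0.0) | (a > a_max + 1e-12)):
        raise ValueError(f"atom fraction excess must lie in [0, {a_max:.8f}]")
    if w_light is None:
        wl = constants.density_intercept + constants.density_slope * g
    else:
        scalar = scalar and (np.isscalar(w_light) or np.ndim(w_light) == 0)
        wl = _as_array(w_light, "w_light")
        _check_density(wl, "w_light")
    m_light = constants.mw_gc_slope * g + constants.mw_intercept
    m_heavymax = m_light + constants.dmw_max_intercept + constants.dmw_max_gc_slope * g
    m_lab = m_light + (a / a_max) * (m_heavymax - m_light)
    return _ret(wl * m_lab / m_light, scalar)
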