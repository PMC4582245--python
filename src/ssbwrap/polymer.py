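"""Force-extension models for the dsDNA/ssDNA tether.

The tether in the wrapping experiments is a 3260-bp dsDNA handle pair in
series with a 70-nt poly(dT) binding site.  The dsDNA segment follows the
extensible worm-like chain (XWLC): the Marko-Siggia interpolation with an
enthalpic ``F/K`` stretch term, solved numerically for extension at a given
force.  The ssDNA segment follows a snake-like-chain style elasticity law:
a low-force power regime crossing C1-continuously into logarithmic growth
at higher force, calibrated to pass exactly through 0.5 nm/nt at 20 pN
(35 nm for 70 nt) and 0.334 nm/nt at 5 pN.

All forces are in pN, lengths in nm, energies in pN nm.  The extension
change on wrapping is reported compaction-positive: ``bare - wrapped``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from ssbwrap.geometry import effective_size

#: Boltzmann constant in pN nm / K.
KB = 0.01380649

#: Default thermal energy, pN nm (23 C room).
KBT_DEFAULT = 4.09

PROTEIN_SIZE_NM = 6.5  # maximum entry/exit separation on the SSB tetramer


class CalibrationWarning(UserWarning):
    """Force outside the calibrated validity range of an elasticity law."""


@dataclass(frozen=True)
class SnakeLikeChain:
    """Calibrated ssDNA elasticity law (extension per nucleotide vs force).

    Above ``crossover_force`` the law is logarithmic,
    ``xi(F) = a + b ln F``, fixed by the two calibration anchors.  Below it
    the law is a power regime ``xi(F) = xi_c (F/F_c)^gamma`` with ``gamma``
    chosen for continuity of value and slope at the crossover.

    Parameters
    ----------
    anchor_force, anchor_extension
        High-force calibration anchor, reproduced exactly
        (default 0.5 nm/nt at 20 pN, i.e. 35 nm for 70 nt).
    ref_force, ref_extension
        Second anchor fixing the logarithmic slope
        (default 0.334 nm/nt at 5 pN).
    crossover_force
        Force at which the power regime hands over to the log regime.
    valid_range
        Calibrated validity range in pN; evaluation outside it carries a
        :class:`CalibrationWarning`.
    """

    anchor_force: float = 20.0
    anchor_extension: float = 0.5
    ref_force: float = 5.0
    ref_extension: float = 0.334
    crossover_force: float = 5.0
    valid_range: tuple[float, float] = (0.1, 30.0)

    def __post_init__(self) -> None:
        if self.anchor_force <= self.ref_force:
            raise ValueError("anchor_force must exceed ref_force")
        if min(self.anchor_extension, self.ref_extension) <= 0:
            raise ValueError("calibration extensions must be positive")

    @property
    def _log_slope(self) -> float:
        return (self.anchor_extension - self.ref_extension) / math.log(
            self.anchor_force / self.ref_force
        )

    @property
    def _log_offset(self) -> float:
        return self.ref_extension - self._log_slope * math.log(self.ref_force)

    @property
    def _xi_crossover(self) -> float:
        return self._log_offset + self._log_slope * math.log(self.crossover_force)

    @property
    def _power_exponent(self) -> float:
        return self._log_slope / self._xi_crossover

    def extension_per_nt(self, force) -> np.ndarray | float:
        """ssDNA extension per nucleotide (nm/nt) at tension ``force`` (pN)."""
        f = np.asarray(force, dtype=float)
        if np.any(f < 0):
            raise ValueError("force must be non-negative")
        lo, hi = self.valid_range
        if np.any((f > 0) & ((f < lo) | (f > hi))):
            warnings.warn(
                f"force outside calibrated ssDNA range [{lo}, {hi}] pN",
                CalibrationWarning,
                stacklevel=2,
            )
        fc, xic, gamma = self.crossover_force, self._xi_crossover, self._power_exponent
        with np.errstate(divide="ignore", invalid="ignore"):
            low = xic * np.power(np.maximum(f, 1e-300) / fc, gamma)
            high = self._log_offset + self._log_slope * np.log(np.maximum(f, 1e-300))
        out = np.where(f < fc, low, high)
        out = np.where(f == 0, 0.0, out)
        return out.item() if np.isscalar(force) or np.ndim(force) == 0 else out

    def stretch_integral(self, force) -> np.ndarray | float:
        """Analytic per-nucleotide stretch integral ``int_0^F xi(F') dF'`` (pN nm/nt)."""
        f = np.asarray(force, dtype=float)
        if np.any(f < 0):
            raise ValueError("force must be non-negative")
        fc, xic, gamma = self.crossover_force, self._xi_crossover, self._power_exponent
        a, b = self._log_offset, self._log_slope
        f_low = np.minimum(f, fc)
        part_low = xic * fc / (gamma + 1.0) * np.power(f_low / fc, gamma + 1.0)
        fh = np.maximum(f, fc)
        part_high = a * (fh - fc) + b * (fh * np.log(fh) - fh - fc * math.log(fc) + fc)
        out = part_low + np.where(f > fc, part_high, 0.0)
        return out.item() if np.isscalar(force) or np.ndim(force) == 0 else out


@dataclass(frozen=True)
class PolymerParams:
    """Elasticity constants of the tether plus the thermal energy scale.

    ``thermal_energy`` (pN nm) and ``temperature`` (K) are locked together
    through ``kB``; supply either, the other is derived.
    """

    dsdna_persistence_length: float = 53.0  # nm
    dsdna_stretch_modulus: float = 1200.0  # pN
    dsdna_contour_per_bp: float = 0.338  # nm/bp
    ssdna: SnakeLikeChain = field(default_factory=SnakeLikeChain)
    thermal_energy: float = KBT_DEFAULT  # pN nm
    temperature: float | None = None  # K

    def __post_init__(self) -> None:
        if self.temperature is not None:
            object.__setattr__(self, "thermal_energy", KB * self.temperature)
        else:
            object.__setattr__(self, "temperature", self.thermal_energy / KB)
        for name in ("dsdna_persistence_length", "dsdna_stretch_modulus",
                     "dsdna_contour_per_bp", "thermal_energy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if abs(self.thermal_energy - KB * self.temperature) > 1e-9 * self.thermal_energy:
            raise ValueError("thermal_energy inconsistent with temperature")

    @property
    def kbt(self) -> float:
        return self.thermal_energy


@dataclass(frozen=True)
class TetherComposition:
    """Tether makeup: dsDNA handle length, ssDNA site length, wrapped count."""

    n_ds: int = 3260  # bp
    n_ss: int = 70  # nt
    n_wrapped: int = 0  # nt

    def __post_init__(self) -> None:
        if min(self.n_ds, self.n_ss, self.n_wrapped) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_wrapped > self.n_ss:
            raise ValueError("n_wrapped cannot exceed n_ss")


def _ms_force_of_fraction(frac: float) -> float:
    """Marko-Siggia dimensionless force ``F P / kBT`` at entropic fraction ``frac``."""
    return 0.25 / (1.0 - frac) ** 2 - 0.25 + frac


def dsdna_extension_per_bp(force, params: PolymerParams | None = None):
    """dsDNA extension per base pair (nm/bp) from the XWLC at tension ``force``.

    Solves the Marko-Siggia interpolation for the entropic fraction by
    bracketed root finding and adds the enthalpic ``F/K`` term.  Strictly
    increasing in force; 0 at zero force by convention.
    """
    params = params or PolymerParams()
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    scaled = f * params.dsdna_persistence_length / params.thermal_energy
    flat = np.atleast_1d(scaled).ravel()
    fracs = np.empty_like(flat)
    for i, s in enumerate(flat):
        if s <= 0:
            fracs[i] = 0.0
            continue
        fracs[i] = brentq(lambda l: _ms_force_of_fraction(l) - s, 0.0, 1.0 - 1e-14,
                          xtol=1e-13, rtol=8.9e-16)
    fracs = fracs.reshape(np.shape(scaled))
    out = params.dsdna_contour_per_bp * (fracs + f / params.dsdna_stretch_modulus)
    return out.item() if np.ndim(force) == 0 else out


def ssdna_extension_per_nt(force, params: PolymerParams | None = None):
    """ssDNA extension per nucleotide (nm/nt); see :class:`SnakeLikeChain`."""
    params = params or PolymerParams()
    return params.ssdna.extension_per_nt(force)


def bare_extension(force, comp: TetherComposition, params: PolymerParams | None = None):
    """Extension (nm) of the protein-free tether: ``xi_ds N_ds + xi_ss N_ss``."""
    params = params or PolymerParams()
    return (dsdna_extension_per_bp(force, params) * comp.n_ds
            + ssdna_extension_per_nt(force, params) * comp.n_ss)


def wrapped_extension(force, comp: TetherComposition, x_ssb: float,
                      params: PolymerParams | None = None):
    """Extension (nm) of the tether with ``comp.n_wrapped`` nt wrapped by SSB.

    ``x_ssb`` is the entry/exit separation of the wrapped ssDNA on the
    protein (nm); its orientation-averaged projection adds to the tether.
    """
    params = params or PolymerParams()
    if not 0.0 <= x_ssb <= PROTEIN_SIZE_NM:
        raise ValueError(f"x_ssb must lie in [0, {PROTEIN_SIZE_NM}] nm")
    # no wrap means no complex on the tether: the size term vanishes
    xeff = (effective_size(x_ssb, force, params.thermal_energy)
            if comp.n_wrapped > 0 else 0.0)
    return (dsdna_extension_per_bp(force, params) * comp.n_ds
            + ssdna_extension_per_nt(force, params) * (comp.n_ss - comp.n_wrapped)
            + xeff)


def extension_change(force, n_wrapped, x_ssb: float,
                     params: PolymerParams | None = None):
    """Compaction on wrapping (nm, positive): ``xi_ss N_w - x_SSB^eff``.

    Zero for ``n_wrapped = 0`` (no complex on the tether).
    """
    params = params or PolymerParams()
    nw = np.asarray(n_wrapped, dtype=float)
    out = np.where(nw > 0,
                   ssdna_extension_per_nt(force, params) * nw
                   - effective_size(x_ssb, force, params.thermal_energy),
                   0.0)
    return out.item() if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# cached force grids for integral evaluation

_GRID_STEP = 0.01  # pN
_GRID_MAX = 30.0


@lru_cache(maxsize=8)
def _dsdna_grid(key: tuple) -> tuple[np.ndarray, np.ndarray]:
    p, k, c, kbt = key
    params = PolymerParams(dsdna_persistence_length=p, dsdna_stretch_modulus=k,
                           dsdna_contour_per_bp=c, thermal_energy=kbt)
    forces = np.arange(0.0, _GRID_MAX + _GRID_STEP / 2, _GRID_STEP)
    return forces, np.asarray(dsdna_extension_per_bp(forces, params))


def dsdna_extension_per_bp_interp(force, params: PolymerParams | None = None):
    """Grid-memoized XWLC extension per bp (0.01 pN grid, linear interpolation)."""
    params = params or PolymerParams()
    key = (params.dsdna_persistence_length, params.dsdna_stretch_modulus,
           params.dsdna_contour_per_bp, params.thermal_energy)
    grid_f, grid_x = _dsdna_grid(key)
    return np.interp(force, grid_f, grid_x)


def dsdna_stretch_integral(force, params: PolymerParams | None = None):
    """Per-bp stretch integral ``int_0^F xi_ds dF'`` (pN nm/bp) by grid trapezoid."""
    params = params or PolymerParams()
    key = (params.dsdna_persistence_length, params.dsdna_stretch_modulus,
           params.dsdna_contour_per_bp, params.thermal_energy)
    grid_f, grid_x = _dsdna_grid(key)
    cum = np.concatenate([[0.0], np.cumsum((grid_x[1:] + grid_x[:-1]) / 2) * _GRID_STEP])
    return np.interp(force, grid_f, cum)
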