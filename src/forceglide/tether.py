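"""Extensible worm-like-chain (eWLC) mechanics for the dsDNA tether.

In the force-gliding assay each kinesin is anchored to the coverslip through a
532 nm dsDNA tether.  The motor's displacement from its anchor therefore
reports the tension it carries: displacement minus a fixed 20 nm offset (QD,
protein and PEG sizes) gives the DNA extension, and the worm-like chain maps
extension to force.

Two functional forms are exposed side by side:

* the Marko–Siggia interpolation ``F(x)`` (optionally with an enthalpic
  stretch correction, ``l = x/Lc - F/K0``), accurate at low-to-moderate force
  and the form used for the pipeline's force traces, and
* the high-force series ``x(F) = Lc (1 - 1/2 sqrt(kBT/(F Lp)) + F/K0)``,
  the standard optical-trap fitting form, used for pull curves.

Both are strictly monotone on their domains, so inverses are obtained by
bracketed root-finding.  Analytic stiffnesses (dF/dx) are provided for each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "TetherModel",
    "ms_force",
    "ms_stiffness",
    "extensible_ms_force",
    "ewlc_extension",
    "ewlc_force",
    "ewlc_stiffness",
    "displacement_to_force",
    "ForceLookup",
]


@dataclass(frozen=True)
class TetherModel:
    """Parameters of the dsDNA tether (a 1565 bp duplex in the assay).

    Attributes
    ----------
    persistence_length : float
        Lp in nm (default 50, standard dsDNA).
    contour_length : float
        Lc in nm (default 532, i.e. 1565 bp x 0.34 nm/bp).
    stretch_modulus : float
        Enthalpic stretch modulus K0 in pN (default 1200).
    thermal_energy : float
        kBT in pN nm (default 4.14, ~300 K).
    distance_offset : float
        Offset subtracted from the anchor-to-motor displacement to obtain the
        DNA extension, in nm (default 20; accounts for QD and linker sizes).
    """

    persistence_length: float = 50.0
    contour_length: float = 532.0
    stretch_modulus: float = 1200.0
    thermal_energy: float = 4.14
    distance_offset: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "persistence_length",
            "contour_length",
            "stretch_modulus",
            "thermal_energy",
            "distance_offset",
        ):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.distance_offset >= self.contour_length:
            raise ValueError("distance_offset must be smaller than contour_length")

    @property
    def force_scale(self) -> float:
        """kBT/Lp in pN — the entropic force scale of the chain."""
        return self.thermal_energy / self.persistence_length


def _check_extension(extension, contour_length: float) -> np.ndarray:
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0):
        raise ValueError("extension must be non-negative")
    if np.any(x >= contour_length):
        raise ValueError(
            "extension must be below the contour length for the inextensible form"
        )
    return x


def ms_force(extension, model: TetherModel = TetherModel()):
    """Marko–Siggia interpolation force at a given extension.

    F = (kBT/Lp) [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ],  0 <= x < Lc.
    """
    x = _check_extension(extension, model.contour_length)
    l = x / model.contour_length
    f = model.force_scale * (0.25 / (1.0 - l) ** 2 - 0.25 + l)
    return f if f.ndim else float(f)


def ms_stiffness(extension, model: TetherModel = TetherModel()):
    """Analytic derivative dF/dx of :func:`ms_force`, in pN/nm.

    dF/dx = (kBT/Lp) [ 1/(2 Lc (1 - x/Lc)^3) + 1/Lc ].
    """
    x = _check_extension(extension, model.contour_length)
    lc = model.contour_length
    l = x / lc
    k = model.force_scale * (0.5 / (lc * (1.0 - l) ** 3) + 1.0 / lc)
    return k if k.ndim else float(k)


def extensible_ms_force(extension, model: TetherModel = TetherModel()):
    """Full extensible Marko–Siggia force: solve F = MS(x/Lc - F/K0).

    The enthalpic term permits extensions at and slightly beyond the contour
    length; the root is unique because the right-hand side is decreasing in F.
    """

    def solve_one(x: float) -> float:
        if x == 0.0:
            return 0.0
        lc, k0, fs = model.contour_length, model.stretch_modulus, model.force_scale

        def g(f: float) -> float:
            l = x / lc - f / k0
            if l >= 1.0:
                # inside the entropic divergence: force must exceed f
                return -np.inf
            return f - fs * (0.25 / (1.0 - l) ** 2 - 0.25 + l)

        hi = 1.0
        while g(hi) < 0:
            hi *= 2.0
            if hi > 1e7:
                raise ValueError(
                    f"extension {x} nm unreachable: no eWLC force below 1e7 pN "
                    "(check units; extensions are in nm)"
                )
        lo = 0.0
        return brentq(g, lo, hi, xtol=1e-12, rtol=1e-14)

    x = np.asarray(extension, dtype=float)
    if np.any(x < 0):
        raise ValueError("extension must be non-negative")
    if x.ndim == 0:
        return solve_one(float(x))
    return np.array([solve_one(v) for v in x.ravel()]).reshape(x.shape)


def ewlc_extension(force, model: TetherModel = TetherModel()):
    """High-force eWLC extension x(F) = Lc (1 - 1/2 sqrt(kBT/(F Lp)) + F/K0)."""
    f = np.asarray(force, dtype=float)
    if np.any(f <= 0):
        raise ValueError("force must be strictly positive")
    x = model.contour_length * (
        1.0
        - 0.5 * np.sqrt(model.thermal_energy / (f * model.persistence_length))
        + f / model.stretch_modulus
    )
    return x if x.ndim else float(x)


_F_BRACKET = (0.05, 100.0)


def ewlc_force(extension, model: TetherModel = TetherModel()):
    """Numeric inverse of :func:`ewlc_extension` by bracketed root-finding.

    Valid for extensions reachable with forces in [0.05, 100] pN.
    """
    lo, hi = _F_BRACKET
    xlo, xhi = ewlc_extension(lo, model), ewlc_extension(hi, model)

    def solve_one(x: float) -> float:
        if not (xlo <= x <= xhi):
            raise ValueError(
                f"extension {x} nm outside the invertible range "
                f"[{xlo:.1f}, {xhi:.1f}] nm (F in [0.05, 100] pN)"
            )
        return brentq(lambda f: ewlc_extension(f, model) - x, lo, hi,
                      xtol=1e-12, rtol=1e-14)

    x = np.asarray(extension, dtype=float)
    if x.ndim == 0:
        return solve_one(float(x))
    return np.array([solve_one(v) for v in x.ravel()]).reshape(x.shape)


def ewlc_stiffness(extension, model: TetherModel = TetherModel()):
    """Stiffness dF/dx of the high-force eWLC at a given extension, pN/nm.

    Computed as 1/(dx/dF) with the analytic
    dx/dF = Lc [ 1/4 sqrt(kBT/Lp) F^(-3/2) + 1/K0 ] at F = ewlc_force(x).
    """
    f = np.asarray(ewlc_force(extension, model), dtype=float)
    dxdf = model.contour_length * (
        0.25 * np.sqrt(model.thermal_energy / model.persistence_length) * f ** -1.5
        + 1.0 / model.stretch_modulus
    )
    k = 1.0 / dxdf
    return k if k.ndim else float(k)


def displacement_to_force(displacement, model: TetherModel = TetherModel()):
    """Tension from the motor's displacement magnitude from its anchor.

    The distance offset is subtracted first; displacements at or below the
    offset carry zero force (slack tether).  Forces come from the full
    extensible Marko–Siggia relation.  Sign conventions (drive vs resist) are
    the caller's business — this takes a magnitude.
    """
    d = np.asarray(displacement, dtype=float)
    if np.any(d < 0):
        raise ValueError("displacement magnitude must be non-negative")
    ext = np.maximum(0.0, d - model.distance_offset)
    f = extensible_ms_force(ext, model)
    return f if np.ndim(f) else float(f)


class ForceLookup:
    """Fast tabulated displacement→force map for simulation inner loops.

    Precomputes the full extensible Marko–Siggia force on a fine extension
    grid and interpolates monotonically (PCHIP).  Accurate to <1e-3 pN over
    the tabulated range; used where per-step root-finding would dominate
    runtime.
    """

    def __init__(self, model: TetherModel = TetherModel(),
                 max_extension: float | None = None, n: int = 4096):
        self.model = model
        if max_extension is None:
            # comfortably past the contour length: forces of tens of pN
            max_extension = model.contour_length * 1.1
        grid = np.linspace(0.0, max_extension, n)
        forces = extensible_ms_force(grid, model)
        self._interp = PchipInterpolator(grid, forces, extrapolate=False)
        self.max_extension = max_extension

    def force(self, displacement):
        """Force (pN) at a displacement magnitude (nm), offset included."""
        d = np.asarray(displacement, dtype=float)
        ext = np.clip(np.abs(d) - self.model.distance_offset, 0.0,
                      self.max_extension)
        out = self._interp(ext)
        return out if out.ndim else float(out)
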