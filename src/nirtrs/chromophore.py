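"""Hemoglobin spectral unmixing.

Per-wavelength absorption coefficients are mapped to oxy-, deoxy- and
total-hemoglobin concentrations by ordinary least squares over the
modified Beer-Lambert composition

    mua(lambda) = ln(10) * [eps_oxy(lambda) C_oxy + eps_deoxy(lambda) C_deoxy]
                  + background(lambda)

with concentrations in micromolar and extinction coefficients converted to
1/(mM mm). The forward map :func:`mua_from_hb` exists so a simulator can
generate absorption triplets whose unmixing is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExtinctionTable", "HbState", "mua_from_hb", "unmix"]

LN10 = float(np.log(10.0))

# Molar extinction coefficients of human hemoglobin, 1/(cm M), 750-850 nm,
# from the standard compiled in-vitro spectra (Prahl/Oregon compilation
# lineage, 10 nm spacing, linearly interpolated between rows). The oxy and
# deoxy curves cross near 800 nm (isosbestic point).
_WL_NM = np.array([750.0, 760, 770, 780, 790, 800, 810, 820, 830, 840, 850])
_EPS_OXY_CM_M = np.array(
    [518.4, 586.36, 650.0, 710.0, 756.0, 816.0, 864.0, 916.0, 974.0, 1022.0, 1058.0]
)
_EPS_DEOXY_CM_M = np.array(
    [1405.2, 1548.5, 1311.9, 1075.4, 948.0, 800.0, 757.0, 730.0, 712.0, 700.0, 691.3]
)


@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction coefficients of the two hemoglobin species.

    ``wavelengths`` in nm; ``eps_oxy``/``eps_deoxy`` in 1/(mM mm);
    ``background`` an optional fixed absorption per wavelength (e.g. water),
    zero by default. Lookup at arbitrary wavelengths is linear interpolation
    within the table's range.
    """

    wavelengths: np.ndarray
    eps_oxy: np.ndarray
    eps_deoxy: np.ndarray
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        eo = np.asarray(self.eps_oxy, dtype=float)
        ed = np.asarray(self.eps_deoxy, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "eps_oxy", eo)
        object.__setattr__(self, "eps_deoxy", ed)
        if wl.size < 2:
            raise ValueError("extinction table needs at least 2 wavelengths")
        if np.unique(wl).size != wl.size:
            raise ValueError("extinction table wavelengths must be distinct")
        if wl.shape != eo.shape or wl.shape != ed.shape:
            raise ValueError("extinction table columns must have equal length")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            object.__setattr__(self, "background", bg)
            if bg.shape != wl.shape:
                raise ValueError("background must match the wavelength column")

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """The embedded 750-850 nm hemoglobin compilation, converted from
        1/(cm M) to 1/(mM mm) (factor 1e-4)."""
        return cls(
            wavelengths=_WL_NM.copy(),
            eps_oxy=_EPS_OXY_CM_M * 1e-4,
            eps_deoxy=_EPS_DEOXY_CM_M * 1e-4,
        )

    def _interp(self, col: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        if np.any(wl < self.wavelengths.min()) or np.any(wl > self.wavelengths.max()):
            raise ValueError(
                f"wavelengths {wl} outside table range "
                f"[{self.wavelengths.min()}, {self.wavelengths.max()}] nm"
            )
        return np.interp(wl, self.wavelengths, col)

    def design_matrix(self, wavelengths: np.ndarray) -> np.ndarray:
        """ln(10)-scaled (n_wavelengths, 2) design mapping (C_oxy, C_deoxy)
        in mM to absorption in 1/mm."""
        a = np.column_stack(
            [
                self._interp(self.eps_oxy, wavelengths),
                self._interp(self.eps_deoxy, wavelengths),
            ]
        )
        return LN10 * a

    def background_at(self, wavelengths: np.ndarray) -> np.ndarray:
        if self.background is None:
            return np.zeros(np.asarray(wavelengths).shape, dtype=float)
        return self._interp(self.background, wavelengths)


@dataclass(frozen=True)
class HbState:
    """Oxy/deoxy hemoglobin concentrations in micromolar.

    ``total`` and ``so2`` are derived; negative concentrations are kept
    as-is (an unmixing can legitimately return them under noise) and
    flagged through :attr:`physical`.
    """

    oxy: float
    deoxy: float

    @property
    def total(self) -> float:
        return self.oxy + self.deoxy

    @property
    def so2(self) -> float:
        """Oxygen saturation fraction; NaN when total is zero."""
        return self.oxy / self.total if self.total != 0 else float("nan")

    @property
    def physical(self) -> bool:
        return self.oxy >= 0 and self.deoxy >= 0


def mua_from_hb(
    state: HbState,
    wavelengths: np.ndarray,
    table: ExtinctionTable | None = None,
) -> np.ndarray:
    """Absorption coefficients (1/mm) at the given wavelengths for a
    hemoglobin state. Linear in concentrations."""
    table = table or ExtinctionTable.default()
    if not (np.isfinite(state.oxy) and np.isfinite(state.deoxy)):
        raise ValueError(f"concentrations must be finite, got {state}")
    conc_mm = np.array([state.oxy, state.deoxy]) * 1e-3  # uM -> mM
    return table.design_matrix(wavelengths) @ conc_mm + table.background_at(wavelengths)


def unmix(
    mua: np.ndarray,
    wavelengths: np.ndarray,
    table: ExtinctionTable | None = None,
) -> HbState:
    """Least-squares hemoglobin concentrations from per-wavelength absorption.

    Solves the (typically 3-equation, 2-unknown) linear system jointly over
    all wavelengths. Raises if fewer than two wavelengths are given or the
    design is rank-deficient (collinear extinction rows).
    """
    table = table or ExtinctionTable.default()
    mua = np.asarray(mua, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if mua.shape != wavelengths.shape:
        raise ValueError("mua and wavelengths must have equal length")
    if mua.size < 2:
        raise ValueError("unmixing needs at least 2 wavelengths")
    a = table.design_matrix(wavelengths)
    if np.linalg.matrix_rank(a) < 2:
        raise ValueError(
            f"extinction design is rank-deficient at wavelengths {wavelengths}: "
            "oxy and deoxy columns are collinear"
        )
    rhs = mua - table.background_at(wavelengths)
    conc_mm, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    return HbState(oxy=float(conc_mm[0] * 1e3), deoxy=float(conc_mm[1] * 1e3))
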