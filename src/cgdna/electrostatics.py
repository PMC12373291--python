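"""Screened-Coulomb electrostatics with structure-based charge renormalization.

Phosphate beads repel through a Debye-Hueckel potential

    Uel = sum_{i<j} Qi Qj e^2 / (4 pi eps0 eps(T) rij) * exp(-rij / lD),

where the reduced charges ``Qi = 1 - fi`` come from counterion condensation
(CC) theory with a structure-based correction: the baseline neutralization
``fbar = 1 - b / (nu * lB)`` is redistributed over the chain through a
softmax in the local reduced potential ``phi_i`` (computed in thermal units
through the Bjerrum length), so compact and extended parts of a fold carry
different effective charge while the chain total ``sum fi = N * fbar`` is
preserved.  Mixed Na+/Mg2+ solutions are handled by solving each valence
separately and blending with the tightly-bound-ion partition fraction
``x = [1+] / ([1+] + alpha [2+])``, ``alpha = (8.1 - 64.8/N)(5.2 - ln[1+])``.

Units: kcal/mol, Angstrom, degrees Celsius at the API surface (Kelvin
internally where Boltzmann factors appear).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .cg_model import CGConformation

__all__ = [
    "COULOMB_KCAL_A",
    "BOLTZMANN_KCAL",
    "AVOGADRO_PER_LITER_A3",
    "IonCondition",
    "ChargeState",
    "ScreeningParams",
    "dielectric",
    "bjerrum_length",
    "debye_length",
    "cc_baseline_fraction",
    "mixed_ion_fraction",
    "solve_charge_fractions",
    "electrostatic_energy",
    "charge_table",
]

#: e^2 / (4 pi eps0) in kcal/mol * Angstrom
COULOMB_KCAL_A = 332.0637128
#: Boltzmann constant, kcal/mol/K
BOLTZMANN_KCAL = 1.987204259e-3
#: ion number density per Angstrom^3 for a 1 M solution
AVOGADRO_PER_LITER_A3 = 6.02214076e-4

#: default backbone charge spacing (A); tunable via IonCondition.b_spacing
DEFAULT_B_SPACING = 4.4


def celsius_to_kelvin(t: float) -> float:
    return t + 273.15


def dielectric(T: float) -> float:
    """Temperature-dependent dielectric constant of water, T in Celsius.

    Empirical pure-water permittivity polynomial (the form used throughout
    the three-site CG DNA lineage):
    eps = 87.740 - 0.4008 T + 9.398e-4 T^2 - 1.410e-6 T^3.
    """
    if not -20.0 <= T <= 150.0:
        raise ValueError(f"temperature {T} C outside supported range [-20, 150]")
    return 87.740 - 0.4008 * T + 9.398e-4 * T * T - 1.410e-6 * T ** 3


def bjerrum_length(T: float) -> float:
    """lB = e^2 / (4 pi eps0 eps(T) kB T_K), in Angstrom; ~7.1 A at 25 C."""
    tk = celsius_to_kelvin(T)
    return COULOMB_KCAL_A / (dielectric(T) * BOLTZMANN_KCAL * tk)


@dataclass(frozen=True)
class IonCondition:
    """Bulk ionic condition: [Na+] and [Mg2+] in molar, temperature in Celsius."""

    conc_mono: float
    conc_di: float = 0.0
    temperature: float = 25.0
    b_spacing: float = DEFAULT_B_SPACING

    def __post_init__(self) -> None:
        if self.conc_mono < 0 or self.conc_di < 0:
            raise ValueError("concentrations must be >= 0")

    def at_temperature(self, T: float) -> "IonCondition":
        return replace(self, temperature=T)

    @property
    def ionic_strength(self) -> float:
        """I = sum ci zi^2 / 2 over all ions incl. chloride counterions (molar)."""
        return self.conc_mono + 3.0 * self.conc_di


def debye_length(ion: IonCondition) -> float:
    """lD = (8 pi lB NA I)^(-1/2), in Angstrom; ~9.6 A for 0.1 M NaCl at 25 C."""
    i_molar = ion.ionic_strength
    if i_molar <= 0:
        raise ValueError("zero ionic strength: screening length undefined")
    lb = bjerrum_length(ion.temperature)
    kappa2 = 8.0 * np.pi * lb * AVOGADRO_PER_LITER_A3 * i_molar
    return float(1.0 / np.sqrt(kappa2))


def cc_baseline_fraction(valence: int, b: float, lB: float) -> float:
    """Counterion-condensation average neutralization fbar = 1 - b/(nu*lB),
    clamped to [0, 1]."""
    if b <= 0 or lB <= 0:
        raise ValueError("b and lB must be positive")
    if valence not in (1, 2):
        raise ValueError("valence must be 1 or 2")
    return float(np.clip(1.0 - b / (valence * lB), 0.0, 1.0))


def mixed_ion_fraction(ion: IonCondition, N: int) -> tuple[float, float]:
    """TBI-fitted monovalent contribution fraction x and partition alpha.

    alpha = (8.1 - 64.8/N)(5.2 - ln[1+]);  x = [1+] / ([1+] + alpha [2+]).
    For N <= 8 the first factor is non-positive: alpha is clamped to 0 with
    a warning (x = 1, pure-monovalent behaviour).
    """
    if ion.conc_mono <= 0:
        raise ValueError("mixed-ion partition requires [1+] > 0")
    size_factor = 8.1 - 64.8 / N
    alpha = size_factor * (5.2 - np.log(ion.conc_mono))
    if alpha <= 0:
        warnings.warn(
            f"chain length N={N} makes alpha non-positive; clamping to 0 "
            "(pure monovalent limit)", stacklevel=2)
        return 1.0, 0.0
    if ion.conc_di == 0:
        return 1.0, float(alpha)
    x = ion.conc_mono / (ion.conc_mono + alpha * ion.conc_di)
    return float(x), float(alpha)


@dataclass(frozen=True)
class ScreeningParams:
    """Derived screening quantities for one ionic condition and chain length."""

    lD: float
    lB: float
    eps: float
    b: float
    x: float
    alpha: float

    def __post_init__(self) -> None:
        if self.lD <= 0 or self.lB <= 0:
            raise ValueError("screening lengths must be positive")
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("x outside [0, 1]")


def screening_params(ion: IonCondition, N: int) -> ScreeningParams:
    lb = bjerrum_length(ion.temperature)
    ld = debye_length(ion)
    if ion.conc_di > 0:
        x, alpha = mixed_ion_fraction(ion, N)
    else:
        x, alpha = 1.0, 0.0
    return ScreeningParams(lD=ld, lB=lb, eps=dielectric(ion.temperature),
                           b=ion.b_spacing, x=x, alpha=alpha)


@dataclass
class ChargeState:
    """Per-phosphate neutralization state: f, Q = 1 - f, reduced potential phi."""

    f: np.ndarray
    Q: np.ndarray
    phi: np.ndarray
    converged: bool
    iterations: int

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if np.any(self.f < -1e-12) or np.any(self.f > 1.0 + 1e-12):
            raise ValueError("neutralization fractions outside [0, 1]")
        if not np.allclose(self.Q, 1.0 - self.f, atol=1e-9):
            raise ValueError("Q != 1 - f")

    @classmethod
    def neutral(cls, n: int) -> "ChargeState":
        """Fully neutralized chain (all Q = 0); useful for decomposition tests."""
        return cls(np.ones(n), np.zeros(n), np.zeros(n), True, 0)

    @classmethod
    def bare(cls, n: int) -> "ChargeState":
        """Unscreened chain (all Q = 1)."""
        return cls(np.zeros(n), np.ones(n), np.zeros(n), True, 0)


def _phi_matrix(p_coords: np.ndarray, lB: float, lD: float) -> np.ndarray:
    """Kernel M_ij = lB * exp(-rij/lD) / rij (i != j), in thermal units."""
    d = np.linalg.norm(p_coords[:, None, :] - p_coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return lB * np.exp(-d / lD) / d


def _budgeted_softmax(w: np.ndarray, budget: float) -> np.ndarray:
    """Distribute *budget* proportionally to weights w with per-bead cap 1.

    Beads whose proportional share exceeds 1 are pinned there and the
    remainder is redistributed over the free beads, so the chain total (and
    hence the CC average) is preserved exactly while 0 <= f_i <= 1.
    """
    n = w.shape[0]
    out = np.zeros(n)
    free = np.ones(n, dtype=bool)
    remaining = budget
    for _ in range(n):
        if remaining <= 0 or not free.any():
            break
        share = remaining * w[free] / w[free].sum()
        over = share >= 1.0
        if not over.any():
            out[free] = share
            return out
        idx = np.nonzero(free)[0][over]
        out[idx] = 1.0
        free[idx] = False
        remaining = budget - (~free).sum()
    return out


def _solve_single_valence(kernel: np.ndarray, fbar: float, valence: int,
                          f0: np.ndarray | None, tol: float, damping: float,
                          max_iter: int):
    n = kernel.shape[0]
    if fbar == 0.0:
        return np.zeros(n), kernel @ np.ones(n), True, 0
    f = np.full(n, fbar) if f0 is None else np.clip(np.asarray(f0, float), 0.0, 1.0)
    phi = kernel @ (1.0 - f)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        phi = kernel @ (1.0 - f)
        w = np.exp(-valence * (phi - phi.mean()))  # mean-shift for stability
        target = _budgeted_softmax(w, n * fbar)
        delta = np.max(np.abs(target - f))
        f = (1.0 - damping) * f + damping * target
        if delta < tol:
            converged = True
            break
    return f, phi, converged, it


def solve_charge_fractions(conf: CGConformation, ion: IonCondition,
                           prev: ChargeState | None = None, *,
                           tol: float = 1e-4, damping: float = 0.5,
                           max_iter: int = 200) -> ChargeState:
    """Solve the structure-based neutralization fixed point for a conformation.

    For each valence present, iterates f -> softmax(-nu * phi(f)) scaled to
    preserve ``sum f = N * fbar`` (damped fixed-point iteration, warm-started
    from *prev* when given); mixed solutions blend per-valence results as
    ``f = x * f1 + (1 - x) * f2``.  Returns the best iterate with
    ``converged=False`` and a warning if the tolerance is not met.
    """
    p = conf.beads_of_kind("P")
    sp = screening_params(ion, conf.n_nt)
    kernel = _phi_matrix(p, sp.lB, sp.lD)
    f0 = prev.f if prev is not None else None

    parts = []
    total_iter = 0
    all_conv = True
    weights = [(1, sp.x)] if ion.conc_di > 0 else [(1, 1.0)]
    if ion.conc_di > 0:
        weights.append((2, 1.0 - sp.x))
    for valence, wgt in weights:
        if wgt == 0.0:
            continue
        fbar = cc_baseline_fraction(valence, sp.b, sp.lB)
        f_v, phi_v, conv, it = _solve_single_valence(
            kernel, fbar, valence, f0, tol, damping, max_iter)
        parts.append((wgt, f_v, phi_v))
        total_iter += it
        all_conv = all_conv and conv
    f = sum(w * fv for w, fv, _ in parts)
    phi = sum(w * pv for w, _, pv in parts)
    f = np.clip(f, 0.0, 1.0)
    if not all_conv:
        warnings.warn("charge-fraction iteration did not converge; "
                      "returning best iterate", stacklevel=2)
    return ChargeState(f=f, Q=1.0 - f, phi=np.asarray(phi), converged=all_conv,
                       iterations=total_iter)


def electrostatic_energy(conf: CGConformation, charge: ChargeState,
                         ion: IonCondition) -> float:
    """Uel over P-bead pairs; >= 0 (like charges), kcal/mol."""
    p = conf.beads_of_kind("P")
    if charge.Q.shape[0] != p.shape[0]:
        raise ValueError("charge state sized to a different conformation")
    if p.shape[0] < 2:
        return 0.0
    d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
    iu = np.triu_indices(p.shape[0], k=1)
    dij = d[iu]
    if np.any(dij < 1.0):
        raise ValueError("coincident P beads: excluded-volume regime")
    eps = dielectric(ion.temperature)
    ld = debye_length(ion)
    qq = np.outer(charge.Q, charge.Q)[iu]
    u = COULOMB_KCAL_A / eps * qq / dij * np.exp(-dij / ld)
    return float(u.sum())


def charge_table(conf: CGConformation, state: ChargeState):
    """Per-phosphate f/Q/phi diagnostic table (pandas DataFrame; TSV-ready)."""
    import pandas as pd

    return pd.DataFrame({
        "residue": np.arange(conf.n_nt),
        "base": list(conf.sequence.residues),
        "f": state.f,
        "Q": state.Q,
        "phi": state.phi,
    })
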