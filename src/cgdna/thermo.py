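"""Thermal-stability analysis: stem-retention states, WHAM, melting fits.

Conformations from a replica-exchange run are classified by which stems of
the folded secondary structure they retain (a 3-way junction gives 2^3 = 8
states: folded F, unfolded U and six intermediates; a 4-way junction gives
16).  The (state, energy-bin) microstate histograms from all replicas are
combined by the weighted histogram analysis method:

    p0(j,k) = sum_i n_i(j,k) / sum_i N_i Z_i c_i(k),
    1/Z_i   = sum_{j,k} c_i(k) p0(j,k),
    c_i(k)  = exp[(beta_target - beta_i) E_k],

iterated to self-consistency at every target temperature; state fractions
are the marginals f_Sj(T) = sum_k p0(j,k).  The folded and unfolded
fractions are then fitted to two-state sigmoids

    fF(T) = 1 / (1 + exp((T - Tm1)/dT1)),
    fU(T) = 1 - 1 / (1 + exp((T - Tm2)/dT2)),

whose midpoints are the two melting temperatures (folded->intermediate and
intermediate->unfolded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .cg_model import BasePairSet
from .electrostatics import BOLTZMANN_KCAL, celsius_to_kelvin
from .forcefield import stems_of

__all__ = [
    "StemDefinition",
    "StateLabel",
    "WhamResult",
    "MeltingResult",
    "define_stems",
    "classify_state",
    "label_trajectories",
    "wham",
    "state_fractions",
    "fit_two_state",
    "pathway_summary",
    "redefine_folded",
    "assign_primes",
]


@dataclass(frozen=True)
class StemDefinition:
    """The stems of the folded secondary structure (disjoint runs of pairs)."""

    stems: tuple[tuple[tuple[int, int], ...], ...]

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for stem in self.stems:
            for p in stem:
                if p in seen:
                    raise ValueError("stems must be disjoint")
                seen.add(p)

    @property
    def n_stems(self) -> int:
        return len(self.stems)


def define_stems(folded_pairs: BasePairSet, *, min_stem_len: int = 2,
                 drop_short: bool = True) -> StemDefinition:
    """Decompose a folded pair set into stems (maximal runs of stacked pairs).

    Runs shorter than *min_stem_len* are dropped by default (they represent
    transient single pairs, not stems); set ``drop_short=False`` to keep
    them as stems of their own.
    """
    if len(folded_pairs) == 0:
        raise ValueError("cannot define stems from an empty pair set")
    runs = stems_of(folded_pairs)
    stems = [tuple(r) for r in runs if len(r) >= min_stem_len or not drop_short]
    if not stems:
        raise ValueError("no stem of the required minimum length")
    return StemDefinition(tuple(stems))


@dataclass(frozen=True)
class StateLabel:
    """A stem-retention state: which stems (by index) are still formed."""

    retained: frozenset[int]
    n_stems: int

    @property
    def name(self) -> str:
        """Subset-based canonical name: F, U, or Im<retained indices>."""
        if len(self.retained) == self.n_stems:
            return "F"
        if not self.retained:
            return "U"
        melted = self.n_stems - len(self.retained)
        kept = "".join(str(s + 1) for s in sorted(self.retained))
        return f"I{melted}<{kept}>"

    def __str__(self) -> str:
        return self.name


def classify_state(pairs: BasePairSet, stems: StemDefinition,
                   retention_frac: float = 0.5) -> StateLabel:
    """Stem s is retained iff the fraction of its pairs present >= threshold."""
    retained = set()
    present = pairs.pairs
    for s, stem in enumerate(stems.stems):
        kept = sum(1 for p in stem if p in present)
        if kept / len(stem) >= retention_frac:
            retained.add(s)
    return StateLabel(frozenset(retained), stems.n_stems)


def label_trajectories(trajectories, stems: StemDefinition,
                       retention_frac: float = 0.5) -> list[list[str]]:
    """State-label every sample of every trajectory (list per trajectory)."""
    return [[classify_state(s.pairs, stems, retention_frac).name
             for s in traj.samples] for traj in trajectories]


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

@dataclass
class WhamResult:
    states: list[str]
    e_centers: np.ndarray
    t_grid: np.ndarray
    p0: dict[float, np.ndarray]       # T -> (J, K) microstate probabilities
    Z: dict[float, np.ndarray]        # T -> per-replica normalizers
    fractions: pd.DataFrame           # index T, columns states


def _energy_bins(energies: np.ndarray, n_bins: int):
    """Equal-width bins with the pooled min/max at the first/last bin centers."""
    emin, emax = float(energies.min()), float(energies.max())
    if emax == emin:
        emax = emin + 1e-6
    pad = (emax - emin) / (2.0 * (n_bins - 1))
    edges = np.linspace(emin - pad, emax + pad, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def wham(trajectories, stems: StemDefinition | None = None, *,
         labels: list[list[str]] | None = None, n_energy_bins: int = 100,
         t_grid=None, retention_frac: float = 0.5, tol: float = 1e-8,
         max_iter: int = 100_000) -> WhamResult:
    """Multi-histogram reweighting of (state, energy) microstates.

    Each trajectory must come from one simulation temperature.  States come
    from *labels* (one list per trajectory) or are classified on the fly
    from *stems*.  The self-consistent equations are iterated per target
    temperature to ``max |Delta ln Z_i| < tol``; a non-convergence raises
    with the residual.  Empty bins are allowed.  With a single replica the
    result at its own temperature reduces to the empirical histogram.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    if labels is None:
        if stems is None:
            raise ValueError("either stems or labels must be given")
        labels = label_trajectories(trajectories, stems, retention_frac)
    temps = np.array([tr.temperature for tr in trajectories])
    if t_grid is None:
        t_grid = np.linspace(temps.min(), temps.max(), 35)
    t_grid = np.asarray(t_grid, dtype=float)

    pooled = np.concatenate([tr.energies for tr in trajectories])
    edges, centers = _energy_bins(pooled, n_energy_bins)
    states = sorted({lab for labs in labels for lab in labs})
    s_index = {s: k for k, s in enumerate(states)}
    J, K = len(states), n_energy_bins

    M = len(trajectories)
    n = np.zeros((M, J, K))
    for i, (tr, labs) in enumerate(zip(trajectories, labels)):
        e = tr.energies
        kbin = np.clip(np.searchsorted(edges, e, side="right") - 1, 0, K - 1)
        for lab, k in zip(labs, kbin):
            n[i, s_index[lab], k] += 1.0
    N = n.sum(axis=(1, 2))
    n_sum = n.sum(axis=0)  # (J, K)

    betas = 1.0 / (BOLTZMANN_KCAL * celsius_to_kelvin(temps))
    e_shift = centers - centers.mean()  # overall shift cancels in Z*c products

    p0: dict[float, np.ndarray] = {}
    Zs: dict[float, np.ndarray] = {}
    frac = np.zeros((len(t_grid), J))
    lnZ = np.zeros(M)
    for ti, T in enumerate(t_grid):
        bt = 1.0 / (BOLTZMANN_KCAL * celsius_to_kelvin(T))
        c = np.exp((bt - betas)[:, None] * e_shift[None, :])  # (M, K)
        for it in range(max_iter):
            denom = (N[:, None] * np.exp(lnZ)[:, None] * c).sum(axis=0)  # (K,)
            p = n_sum / denom[None, :]
            p /= p.sum()
            lnZ_new = -np.log((c * p.sum(axis=0)[None, :]).sum(axis=1))
            delta = np.max(np.abs(lnZ_new - lnZ))
            lnZ = lnZ_new
            if delta < tol:
                break
        else:
            raise RuntimeError(
                f"WHAM failed to converge at T={T:.2f} C: residual {delta:.3e}")
        key = float(T)
        p0[key] = p
        Zs[key] = np.exp(lnZ)
        frac[ti] = p.sum(axis=1)

    fractions = pd.DataFrame(frac, index=t_grid, columns=states)
    return WhamResult(states=states, e_centers=centers, t_grid=t_grid,
                      p0=p0, Z=Zs, fractions=fractions)


def state_fractions(result: WhamResult, t_grid=None) -> pd.DataFrame:
    """Per-state fractions f_Sj(T) = sum_k p0(j,k); rows sum to 1."""
    if t_grid is None:
        return result.fractions.copy()
    t_grid = np.asarray(t_grid, dtype=float)
    missing = [t for t in t_grid if float(t) not in result.p0]
    if missing:
        raise KeyError(f"temperatures not in the WHAM grid: {missing}")
    rows = [result.p0[float(t)].sum(axis=1) for t in t_grid]
    return pd.DataFrame(rows, index=t_grid, columns=result.states)


# ---------------------------------------------------------------------------
# two-state melting fits
# ---------------------------------------------------------------------------

@dataclass
class MeltingResult:
    Tm1: float
    dT1: float
    Tm2: float
    dT2: float
    fit_fF: np.ndarray
    fit_fU: np.ndarray
    t_grid: np.ndarray
    pathway: str = ""
    warnings: list[str] = field(default_factory=list)


def _sigmoid_folded(T, Tm, dT):
    return 1.0 / (1.0 + np.exp((T - Tm) / dT))


def _fit_sigmoid(t: np.ndarray, f: np.ndarray, increasing: bool):
    y = 1.0 - f if increasing else f
    if np.ptp(y) < 1e-12:
        raise ValueError("fraction curve is constant; two-state fit rejected")
    tm0 = float(t[np.argmin(np.abs(y - 0.5))])
    span = float(t.max() - t.min())
    popt, _ = curve_fit(_sigmoid_folded, t, y, p0=[tm0, 5.0],
                        bounds=([t.min() - 30.0, 1e-3],
                                [t.max() + 30.0, 200.0]), maxfev=20000)
    return float(popt[0]), float(popt[1])


def fit_two_state(t_grid, f_folded, f_unfolded) -> MeltingResult:
    """Nonlinear least-squares fit of the two melting sigmoids.

    Tm1/dT1 from the folded fraction, Tm2/dT2 from the unfolded fraction;
    each Tm is the 0.5-crossing of its fitted sigmoid.  If a fitted Tm lies
    outside the simulated span, an extrapolation warning is attached.
    """
    t = np.asarray(t_grid, dtype=float)
    ff = np.asarray(f_folded, dtype=float)
    fu = np.asarray(f_unfolded, dtype=float)
    if t.size < 8:
        raise ValueError("need fractions on at least 8 temperatures")
    tm1, dt1 = _fit_sigmoid(t, ff, increasing=False)
    tm2, dt2 = _fit_sigmoid(t, fu, increasing=True)
    warns = []
    for tm, nm in ((tm1, "Tm1"), (tm2, "Tm2")):
        if not t.min() <= tm <= t.max():
            warns.append(f"{nm}={tm:.1f} C lies outside the simulated "
                         f"temperature span [{t.min():.0f}, {t.max():.0f}]; "
                         "extrapolated")
    return MeltingResult(
        Tm1=tm1, dT1=dt1, Tm2=tm2, dT2=dt2,
        fit_fF=_sigmoid_folded(t, tm1, dt1),
        fit_fU=1.0 - _sigmoid_folded(t, tm2, dt2),
        t_grid=t, warnings=warns)


# ---------------------------------------------------------------------------
# pathways and state relabeling
# ---------------------------------------------------------------------------

def pathway_summary(fractions: pd.DataFrame) -> tuple[str, pd.DataFrame]:
    """Dominant unfolding pathway from temperature-resolved state fractions.

    The pathway is the deduplicated sequence of maximal-fraction states from
    the lowest to the highest temperature; the returned table lists, per
    state, its peak fraction and the temperature of the peak.
    """
    argmax = fractions.idxmax(axis=1)
    path: list[str] = []
    for s in argmax:
        if not path or path[-1] != s:
            if s in path:  # hysteresis-free: ignore returns to earlier states
                continue
            path.append(s)
    notes = pd.DataFrame({
        "peak_fraction": fractions.max(axis=0),
        "peak_T": fractions.idxmax(axis=0),
    })
    return " -> ".join(path), notes


def redefine_folded(stems_to_fold: frozenset[int] | set[int]):
    """Relabeling rule: states retaining a superset of *stems_to_fold* are F.

    Returns a function mapping a state-label string (subset-based names as
    produced by :class:`StateLabel`) to its relabeled name.  With the full
    stem set this is the identity; the empty subset makes every state F
    (downstream two-state fits then reject the constant curve).
    """
    required = frozenset(stems_to_fold)

    def rule(name: str, n_stems: int | None = None) -> str:
        retained = _retained_from_name(name, n_stems)
        if retained is None:
            return name
        return "F" if required <= retained else name

    return rule


def _retained_from_name(name: str, n_stems: int | None):
    if name == "F":
        return frozenset(range(n_stems)) if n_stems is not None else None
    if name == "U":
        return frozenset()
    if name.startswith("I") and "<" in name:
        kept = name[name.index("<") + 1:name.index(">")]
        return frozenset(int(ch) - 1 for ch in kept)
    return None


def folded_fraction(fractions: pd.DataFrame, rule=None,
                    n_stems: int | None = None) -> pd.Series:
    """f_F(T), optionally under a redefined-folded relabeling rule."""
    if rule is None:
        return fractions.get("F", pd.Series(0.0, index=fractions.index))
    cols = [c for c in fractions.columns if rule(c, n_stems) == "F"]
    return fractions[cols].sum(axis=1)


def assign_primes(fractions: pd.DataFrame) -> dict[str, str]:
    """Report-time renaming: In states ranked by peak fraction get primes.

    Within each melted-stem count m, the highest-peak state is named Im, the
    second Im', the third Im'', etc.; F and U keep their names.
    """
    peaks = fractions.max(axis=0)
    out: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for name in fractions.columns:
        if name in ("F", "U"):
            out[name] = name
            continue
        m = name.split("<")[0]
        groups.setdefault(m, []).append(name)
    for m, names in groups.items():
        ranked = sorted(names, key=lambda s: -peaks[s])
        for rank, s in enumerate(ranked):
            out[s] = m + "′" * rank
    return out
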