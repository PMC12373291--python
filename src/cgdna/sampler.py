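"""Pivot-move Metropolis Monte Carlo and replica-exchange (REMC) sampling.

Each replica evolves by pivot moves: a random backbone bead is chosen and
one side of the chain is rigidly rotated about a random axis through it
(a lighter base-twist move rotates a single base bead about its sugar).
Moves are accepted by the Metropolis criterion at the replica temperature.
Because the potential is temperature-dependent (through the screened
electrostics), replica exchange uses the generalized criterion

    p = min(1, exp(-Delta)),
    Delta = bj*E(xi,Tj) + bi*E(xj,Ti) - bi*E(xi,Ti) - bj*E(xj,Tj),

which requires cross-evaluating each conformation's energy at the partner
rung; the cross-evaluation recomputes the dielectric, Debye length and CC
baseline at the partner temperature and rescales the per-phosphate
neutralization pattern accordingly.

The default ladder is ten rungs from 25 to 110 C.  Energies are maintained
incrementally (cross-terms only for the pairwise sums) and the bookkeeping
is contractually equal to a from-scratch evaluation; a periodic internal
spot-check enforces this during long runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cg_model import BasePairSet, CGConformation, Sequence, init_conformation
from .electrostatics import (BOLTZMANN_KCAL, ChargeState, IonCondition,
                             celsius_to_kelvin, debye_length, dielectric,
                             electrostatic_energy, screening_params,
                             cc_baseline_fraction, solve_charge_fractions)
from .ensemble import PairDetectionConfig, detect_base_pairs
from .forcefield import (ForceFieldParams, RegionMap, _exclusion_mask,
                         _wca_energy, base_pair_energy, base_stack_energy,
                         bonded_energy, coaxial_stack_energy,
                         mechanical_energy, total_energy)

__all__ = [
    "DEFAULT_LADDER",
    "TemperatureLadder",
    "RunSchedule",
    "TrajectorySample",
    "ReplicaTrajectory",
    "ReplicaState",
    "pivot_move",
    "base_twist_move",
    "metropolis_accept",
    "exchange_delta",
    "exchange_delta_terms",
    "run_remc",
    "run_fixed_temperature",
    "MCWalker",
]

#: the ten-rung production temperature ladder (Celsius)
DEFAULT_LADDER = (25.0, 31.0, 37.0, 45.0, 54.0, 64.0, 74.0, 86.0, 98.0, 110.0)


@dataclass(frozen=True)
class TemperatureLadder:
    temperatures: tuple[float, ...] = DEFAULT_LADDER

    def __post_init__(self) -> None:
        ts = tuple(self.temperatures)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("ladder temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", ts)

    def __len__(self) -> int:
        return len(self.temperatures)

    def __getitem__(self, i: int) -> float:
        return self.temperatures[i]


@dataclass
class RunSchedule:
    """Monte Carlo run configuration (sweep = one attempted move per residue)."""

    n_sweeps: int = 2000
    burn_in: int = 500
    sample_stride: int = 5
    exchange_stride: int = 100
    coord_stride: int = 1          # record coordinates every k-th sample
    el_update_stride: int = 100    # charge refresh cadence, in MC moves
    max_angle_deg: float = 60.0    # initial pivot amplitude (auto-tuned)
    base_move_prob: float = 0.2
    displacement_prob: float = 0.2
    displacement_sigma: float = 0.15  # A, single-bead local move
    target_acceptance: float = 0.30
    n_workers: int = 1             # trajectories are deterministic per worker count


@dataclass
class TrajectorySample:
    step: int
    energy: float
    pairs: BasePairSet
    coords: np.ndarray | None = None
    f: np.ndarray | None = None
    label: str | None = None


@dataclass
class ReplicaTrajectory:
    """Time-ordered samples recorded at one rung temperature."""

    temperature: float
    sequence: Sequence
    samples: list[TrajectorySample] = field(default_factory=list)

    def append(self, s: TrajectorySample) -> None:
        if self.samples and s.step <= self.samples[-1].step:
            raise ValueError("samples must be strictly increasing in step")
        self.samples.append(s)

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.samples])


@dataclass
class ReplicaState:
    conformation: CGConformation
    pairs: BasePairSet
    regions: RegionMap
    charge: ChargeState
    energy: float
    temperature_index: int
    rng: np.random.Generator


# ---------------------------------------------------------------------------
# elementary moves
# ---------------------------------------------------------------------------

def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def pivot_move(conf: CGConformation, rng: np.random.Generator,
               max_angle_deg: float = 60.0):
    """Rotate one side of the chain rigidly about a random backbone bead.

    Returns ``(proposal, moved)`` where *moved* is a boolean bead mask.
    The pivot bead itself stays fixed, so the bond through it keeps its
    length and only angles/dihedrals at the pivot change; all intra-segment
    geometry is preserved exactly.
    """
    if conf.n_nt < 2:
        raise ValueError("pivot move needs a chain of length >= 2")
    nb = conf.n_beads
    # pivot on a backbone bead (P or C): bead index not congruent 2 mod 3
    backbone = [i for i in range(nb) if i % 3 != 2]
    pivot = int(rng.choice(backbone))
    downstream = bool(rng.integers(0, 2))
    angle = np.deg2rad(rng.normal(0.0, max_angle_deg))
    axis = rng.normal(size=3)
    while np.linalg.norm(axis) < 1e-12:
        axis = rng.normal(size=3)
    moved = np.zeros(nb, dtype=bool)
    if downstream:
        moved[pivot + 1:] = True
    else:
        moved[:pivot] = True
    # never propose the empty move (pivot at a chain end with nothing beyond)
    if not moved.any():
        return conf.copy(), moved
    rot = _rotation_matrix(axis, angle)
    x = conf.coords.copy()
    origin = x[pivot]
    x[moved] = (x[moved] - origin) @ rot.T + origin
    return CGConformation(conf.sequence, x, conf.chain_breaks), moved


def base_twist_move(conf: CGConformation, rng: np.random.Generator,
                    max_angle_deg: float = 90.0):
    """Rotate a single base bead about a random axis through its sugar bead."""
    i = int(rng.integers(0, conf.n_nt))
    angle = np.deg2rad(rng.normal(0.0, max_angle_deg))
    axis = rng.normal(size=3)
    while np.linalg.norm(axis) < 1e-12:
        axis = rng.normal(size=3)
    moved = np.zeros(conf.n_beads, dtype=bool)
    moved[3 * i + 2] = True
    rot = _rotation_matrix(axis, angle)
    x = conf.coords.copy()
    origin = x[3 * i + 1]
    x[3 * i + 2] = (x[3 * i + 2] - origin) @ rot.T + origin
    return CGConformation(conf.sequence, x, conf.chain_breaks), moved


def bead_displacement_move(conf: CGConformation, rng: np.random.Generator,
                           sigma: float = 0.15):
    """Displace a single bead by a small Gaussian step.

    The local move that lets bond lengths and angles fluctuate (pivot moves
    preserve every bond length exactly); essential for thermal equilibration
    of the harmonic terms and for refinement of distorted geometries.
    """
    i = int(rng.integers(0, conf.n_beads))
    moved = np.zeros(conf.n_beads, dtype=bool)
    moved[i] = True
    x = conf.coords.copy()
    x[i] = x[i] + rng.normal(scale=sigma, size=3)
    return CGConformation(conf.sequence, x, conf.chain_breaks), moved


def metropolis_accept(dU: float, T: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dU / kB T_K)); T in Celsius."""
    if not np.isfinite(dU):
        return False
    if dU <= 0:
        return True
    beta = 1.0 / (BOLTZMANN_KCAL * celsius_to_kelvin(T))
    return bool(rng.random() < np.exp(-beta * dU))


# ---------------------------------------------------------------------------
# temperature-dependent energy cross-evaluation and exchange criterion
# ---------------------------------------------------------------------------

def _blended_fbar(ion: IonCondition, n_nt: int, T: float) -> float:
    sp = screening_params(ion.at_temperature(T), n_nt)
    fbar1 = cc_baseline_fraction(1, sp.b, sp.lB)
    if ion.conc_di == 0:
        return fbar1
    fbar2 = cc_baseline_fraction(2, sp.b, sp.lB)
    return sp.x * fbar1 + (1.0 - sp.x) * fbar2


def rescale_charge(charge: ChargeState, ion: IonCondition, n_nt: int,
                   T_from: float, T_to: float) -> ChargeState:
    """Carry a neutralization pattern to another temperature.

    The spatial pattern of f is kept and rescaled by the ratio of blended CC
    baselines at the two temperatures (an exact re-solve is available via
    :func:`cgdna.electrostatics.solve_charge_fractions`).
    """
    f_from = _blended_fbar(ion, n_nt, T_from)
    f_to = _blended_fbar(ion, n_nt, T_to)
    ratio = f_to / f_from if f_from > 0 else 1.0
    f = np.clip(charge.f * ratio, 0.0, 1.0)
    return ChargeState(f=f, Q=1.0 - f, phi=charge.phi.copy(),
                       converged=charge.converged, iterations=charge.iterations)


def energy_at_temperature(conf: CGConformation, pairs: BasePairSet,
                          regions: RegionMap, params: ForceFieldParams,
                          ion: IonCondition, charge: ChargeState,
                          T_own: float, T_eval: float, *,
                          exact_resolve: bool = False) -> float:
    """E(x, T): the temperature-dependent potential of conformation x at T."""
    if exact_resolve:
        ch = solve_charge_fractions(conf, ion.at_temperature(T_eval))
    else:
        ch = rescale_charge(charge, ion, conf.n_nt, T_own, T_eval)
    return total_energy(conf, pairs, regions, params, ion, T_eval, ch)


def exchange_delta_terms(e_ii: float, e_jj: float, e_ij: float, e_ji: float,
                         T_i: float, T_j: float) -> float:
    """Generalized exchange exponent from the four cross-evaluated energies.

    ``e_ij`` denotes E(x_i, T_j).  For a temperature-independent potential
    this reduces to (beta_i - beta_j) * (E(x_j) - E(x_i)).
    """
    bi = 1.0 / (BOLTZMANN_KCAL * celsius_to_kelvin(T_i))
    bj = 1.0 / (BOLTZMANN_KCAL * celsius_to_kelvin(T_j))
    return bj * e_ij + bi * e_ji - bi * e_ii - bj * e_jj


def exchange_delta(state_i: ReplicaState, state_j: ReplicaState,
                   ladder: TemperatureLadder, params: ForceFieldParams,
                   ion: IonCondition, *, exact_resolve: bool = False) -> float:
    """Exchange exponent Delta for two replicas adjacent on the ladder."""
    if abs(state_i.temperature_index - state_j.temperature_index) != 1:
        raise ValueError("exchange requires adjacent ladder rungs")
    t_i = ladder[state_i.temperature_index]
    t_j = ladder[state_j.temperature_index]
    e_ii = state_i.energy
    e_jj = state_j.energy
    e_ij = energy_at_temperature(state_i.conformation, state_i.pairs,
                                 state_i.regions, params, ion, state_i.charge,
                                 t_i, t_j, exact_resolve=exact_resolve)
    e_ji = energy_at_temperature(state_j.conformation, state_j.pairs,
                                 state_j.regions, params, ion, state_j.charge,
                                 t_j, t_i, exact_resolve=exact_resolve)
    return exchange_delta_terms(e_ii, e_jj, e_ij, e_ji, t_i, t_j)


# ---------------------------------------------------------------------------
# incremental energy bookkeeping
# ---------------------------------------------------------------------------

def _exc_cross(x_new: np.ndarray, x_old: np.ndarray, radii: np.ndarray,
               moved: np.ndarray, mask: np.ndarray, eps: float) -> float:
    """Change in excluded-volume energy from moved-vs-static bead pairs."""
    mi = np.nonzero(moved)[0]
    si = np.nonzero(~moved)[0]
    if mi.size == 0 or si.size == 0:
        return 0.0
    sub = mask[np.ix_(mi, si)] | mask[np.ix_(si, mi)].T
    sigma = radii[mi][:, None] + radii[si][None, :]
    d_new = np.linalg.norm(x_new[mi][:, None, :] - x_new[si][None, :, :], axis=-1)
    d_old = np.linalg.norm(x_old[mi][:, None, :] - x_old[si][None, :, :], axis=-1)
    e_new = _wca_energy(d_new[sub], sigma[sub], eps)
    e_old = _wca_energy(d_old[sub], sigma[sub], eps)
    return float(e_new.sum() - e_old.sum())


def _el_cross(x_new: np.ndarray, x_old: np.ndarray, moved: np.ndarray,
              Q: np.ndarray, eps: float, lD: float) -> float:
    """Change in screened-Coulomb energy from moved-vs-static P-bead pairs."""
    from .electrostatics import COULOMB_KCAL_A

    p_idx = np.arange(0, x_new.shape[0], 3)
    pm = p_idx[moved[p_idx]]
    ps = p_idx[~moved[p_idx]]
    if pm.size == 0 or ps.size == 0:
        return 0.0
    qq = np.outer(Q[pm // 3], Q[ps // 3])
    d_new = np.linalg.norm(x_new[pm][:, None, :] - x_new[ps][None, :, :], axis=-1)
    d_old = np.linalg.norm(x_old[pm][:, None, :] - x_old[ps][None, :, :], axis=-1)
    d_new = np.maximum(d_new, 1e-6)
    d_old = np.maximum(d_old, 1e-6)
    e_new = (qq / d_new * np.exp(-d_new / lD)).sum()
    e_old = (qq / d_old * np.exp(-d_old / lD)).sum()
    return float(COULOMB_KCAL_A / eps * (e_new - e_old))


def incremental_delta(conf_old: CGConformation, conf_new: CGConformation,
                      moved: np.ndarray, pairs_old: BasePairSet,
                      pairs_new: BasePairSet, regions: RegionMap,
                      params: ForceFieldParams, ion: IonCondition, T: float,
                      charge: ChargeState, excl_mask: np.ndarray) -> float:
    """Incremental total-energy change for a rigid-block move.

    Pairwise sums (excluded volume, electrostatics with frozen charges) are
    updated from moved-vs-static cross terms only; the short-ranged pairing,
    stacking and coaxial terms plus the O(N) bonded terms are re-evaluated
    in full.  Equals ``total_energy(new) - total_energy(old)`` exactly.
    """
    du = (bonded_energy(conf_new, params, regions)
          - bonded_energy(conf_old, params, regions))
    du += (base_pair_energy(conf_new, pairs_new, params)
           - base_pair_energy(conf_old, pairs_old, params))
    du += (base_stack_energy(conf_new, pairs_new, params)
           - base_stack_energy(conf_old, pairs_old, params))
    du += (coaxial_stack_energy(conf_new, pairs_new, params)
           - coaxial_stack_energy(conf_old, pairs_old, params))
    radii = conf_old.bead_radii()
    du += _exc_cross(conf_new.coords, conf_old.coords, radii, moved,
                     excl_mask, params.nonbonded.exc_epsilon)
    ion_t = ion.at_temperature(T)
    du += _el_cross(conf_new.coords, conf_old.coords, moved, charge.Q,
                    dielectric(T), debye_length(ion_t))
    return float(du)


# ---------------------------------------------------------------------------
# walker and drivers
# ---------------------------------------------------------------------------

class MCWalker:
    """One fixed-temperature Metropolis walker with energy bookkeeping."""

    def __init__(self, conf: CGConformation, ion: IonCondition,
                 params: ForceFieldParams, temperature: float,
                 rng: np.random.Generator, schedule: RunSchedule,
                 helix_regions: bool = False, preserve_pairs: bool = False,
                 detection: PairDetectionConfig = PairDetectionConfig()):
        self.preserve_pairs = preserve_pairs
        self.greedy = False  # downhill-only acceptance (quench mode)
        self.ion = ion
        self.params = params
        self.T = temperature
        self.rng = rng
        self.schedule = schedule
        self.helix_regions = helix_regions
        self.detection = detection
        self.sigma = schedule.max_angle_deg
        self.move_count = 0
        self.accepted = 0
        self.attempted = 0
        self.excl_mask = _exclusion_mask(conf)
        self.set_conformation(conf)
        # pairs present on entry are pinned when preserve_pairs is set
        self.required_pairs = frozenset(self.pairs.pairs)

    # -- state management -------------------------------------------------
    def set_conformation(self, conf: CGConformation,
                         charge: ChargeState | None = None) -> None:
        self.conf = conf
        self.pairs = detect_base_pairs(conf, self.detection)
        self.regions = self._regions_for(self.pairs)
        self.charge = charge if charge is not None else self._solve_charge(None)
        self.energy = total_energy(self.conf, self.pairs, self.regions,
                                   self.params, self.ion, self.T, self.charge)

    def _regions_for(self, pairs: BasePairSet) -> RegionMap:
        if self.helix_regions:
            return RegionMap.from_pairs(self.conf.n_nt, pairs)
        return RegionMap.all_loop(self.conf.n_nt)

    def _solve_charge(self, prev: ChargeState | None) -> ChargeState:
        return solve_charge_fractions(self.conf,
                                      self.ion.at_temperature(self.T), prev)

    def refresh_charge(self) -> None:
        self.charge = self._solve_charge(self.charge)
        self.energy = total_energy(self.conf, self.pairs, self.regions,
                                   self.params, self.ion, self.T, self.charge)

    # -- moves -------------------------------------------------------------
    def _propose(self):
        u = self.rng.random()
        displ = self.schedule.displacement_prob
        if u < displ or self.conf.n_nt < 2:
            return bead_displacement_move(self.conf, self.rng,
                                          self.schedule.displacement_sigma)
        if u < displ + self.schedule.base_move_prob:
            return base_twist_move(self.conf, self.rng)
        return pivot_move(self.conf, self.rng, self.sigma)

    def step(self) -> bool:
        """One attempted move; returns True if accepted."""
        self.attempted += 1
        self.move_count += 1
        proposal, moved = self._propose()
        if not moved.any():
            return True  # identity move: dU = 0, always accepted
        if self._p_bead_collision(proposal, moved):
            return False  # deep in the excluded-volume regime: auto-reject
        new_pairs = detect_base_pairs(proposal, self.detection)
        if self.preserve_pairs and not new_pairs.pairs >= self.required_pairs:
            return False  # refinement contract: pairing preserved or improved
        regions = self.regions
        if self.helix_regions and new_pairs != self.pairs:
            # score the proposal under its own region assignment
            du = (total_energy(proposal, new_pairs,
                               self._region_map(proposal, new_pairs),
                               self.params, self.ion, self.T, self.charge)
                  - self.energy)
        else:
            du = incremental_delta(self.conf, proposal, moved, self.pairs,
                                   new_pairs, regions, self.params, self.ion,
                                   self.T, self.charge, self.excl_mask)
        accepted = (du <= 0.0) if self.greedy \
            else metropolis_accept(du, self.T, self.rng)
        if accepted:
            pair_change = new_pairs != self.pairs
            self.conf = proposal
            self.pairs = new_pairs
            if self.helix_regions and pair_change:
                self.regions = self._regions_for(new_pairs)
            self.energy += du
            self.accepted += 1
            if pair_change:
                self.refresh_charge()
        if self.move_count % self.schedule.el_update_stride == 0:
            self.refresh_charge()
        return accepted

    @staticmethod
    def _p_bead_collision(conf: CGConformation, moved: np.ndarray,
                          dmin: float = 1.05) -> bool:
        p_idx = np.arange(0, conf.n_beads, 3)
        pm = p_idx[moved[p_idx]]
        ps = p_idx[~moved[p_idx]]
        if pm.size == 0 or ps.size == 0:
            return False
        x = conf.coords
        d = np.linalg.norm(x[pm][:, None, :] - x[ps][None, :, :], axis=-1)
        return bool(d.min() < dmin)

    def _region_map(self, conf: CGConformation, pairs: BasePairSet) -> RegionMap:
        return (RegionMap.from_pairs(conf.n_nt, pairs) if self.helix_regions
                else RegionMap.all_loop(conf.n_nt))

    def sweep(self) -> None:
        for _ in range(self.conf.n_nt):
            self.step()

    def tune(self) -> None:
        """Nudge the pivot amplitude toward the target acceptance rate."""
        if self.attempted < 20:
            return
        rate = self.accepted / self.attempted
        if rate > self.schedule.target_acceptance + 0.05:
            self.sigma = min(self.sigma * 1.15, 150.0)
        elif rate < self.schedule.target_acceptance - 0.05:
            self.sigma = max(self.sigma / 1.15, 2.0)
        self.accepted = 0
        self.attempted = 0

    def verify_energy(self, atol: float = 1e-6) -> None:
        full = total_energy(self.conf, self.pairs, self.regions, self.params,
                            self.ion, self.T, self.charge)
        if abs(full - self.energy) > atol:
            raise AssertionError(
                f"energy bookkeeping drift: cached {self.energy}, full {full}")
        self.energy = full


def run_fixed_temperature(conf: CGConformation, ion: IonCondition,
                          params: ForceFieldParams, schedule: RunSchedule,
                          *, seed: int = 0, temperature: float = 25.0,
                          helix_regions: bool = False,
                          preserve_pairs: bool = False,
                          return_best: bool = False,
                          quench_sweeps: int = 0):
    """Plain Metropolis MC at one temperature; returns the best or last state.

    With ``helix_regions`` the stiff helix bonded set scores currently paired
    residues (the refinement mode); otherwise the loop set scores everything
    (the folding mode).  ``quench_sweeps`` adds a downhill-only stage from
    the best state found, settling soft modes into the local minimum.
    """
    rng = np.random.default_rng(seed)
    walker = MCWalker(conf, ion, params, temperature, rng, schedule,
                      helix_regions=helix_regions,
                      preserve_pairs=preserve_pairs)
    if quench_sweeps:
        # pre-relaxation: settle into the starting basin before sampling
        walker.greedy = True
        for _ in range(quench_sweeps):
            walker.sweep()
        walker.greedy = False
    best = walker.conf.copy()
    best_energy = walker.energy
    for sweep in range(1, schedule.n_sweeps + 1):
        walker.sweep()
        if sweep <= schedule.burn_in and sweep % 25 == 0:
            walker.tune()
        if walker.energy < best_energy:
            best_energy = walker.energy
            best = walker.conf.copy()
        if sweep % 1000 == 0:
            walker.verify_energy()
    if quench_sweeps:
        walker.set_conformation(best)
        walker.greedy = True
        walker.sigma = min(walker.sigma, 10.0)
        for _ in range(quench_sweeps):
            walker.sweep()
        if walker.energy < best_energy:
            best_energy = walker.energy
            best = walker.conf.copy()
    return best if return_best else walker.conf.copy()


def run_remc(seq: Sequence, ion: IonCondition,
             ladder: TemperatureLadder = TemperatureLadder(),
             schedule: RunSchedule = RunSchedule(), seed: int = 0,
             params: ForceFieldParams | None = None,
             *, exact_exchange_resolve: bool = False
             ) -> list[ReplicaTrajectory]:
    """Replica-exchange MC folding run; one trajectory per ladder rung.

    Replicas start from independent random self-avoiding coils, evolve by
    pivot/base-twist Metropolis sweeps, and attempt exchanges between
    adjacent rungs every ``exchange_stride`` sweeps with alternating parity.
    Samples (energy, base-pair set, coordinates, neutralization fractions)
    are recorded after burn-in at a fixed stride.  Deterministic for a fixed
    seed in single-worker mode.
    """
    if params is None:
        params = ForceFieldParams.load_default()
    n_rungs = len(ladder)
    walkers = []
    for r in range(n_rungs):
        conf = init_conformation(seq, (seed * 1009 + 7 * r + 1) % (2 ** 31))
        rng = np.random.default_rng([seed, r])
        walkers.append(MCWalker(conf, ion, params, ladder[r], rng, schedule))
    ex_rng = np.random.default_rng([seed, 10 ** 6])
    trajs = [ReplicaTrajectory(temperature=ladder[r], sequence=seq)
             for r in range(n_rungs)]
    exchange_attempts = 0
    exchange_accepts = 0

    for sweep in range(1, schedule.n_sweeps + 1):
        for w in walkers:
            w.sweep()
        if sweep <= schedule.burn_in and sweep % 25 == 0:
            for w in walkers:
                w.tune()
        if sweep % schedule.exchange_stride == 0 and n_rungs > 1:
            parity = (sweep // schedule.exchange_stride) % 2
            for r in range(parity, n_rungs - 1, 2):
                wi, wj = walkers[r], walkers[r + 1]
                si = ReplicaState(wi.conf, wi.pairs, wi.regions, wi.charge,
                                  wi.energy, r, wi.rng)
                sj = ReplicaState(wj.conf, wj.pairs, wj.regions, wj.charge,
                                  wj.energy, r + 1, wj.rng)
                delta = exchange_delta(si, sj, ladder, params, ion,
                                       exact_resolve=exact_exchange_resolve)
                exchange_attempts += 1
                if ex_rng.random() < np.exp(-min(delta, 700.0)):
                    exchange_accepts += 1
                    ci, cj = wi.conf, wj.conf
                    wi.set_conformation(cj)
                    wj.set_conformation(ci)
        if sweep > schedule.burn_in and \
                (sweep - schedule.burn_in) % schedule.sample_stride == 0:
            k = (sweep - schedule.burn_in) // schedule.sample_stride
            for r, w in enumerate(walkers):
                keep_coords = (k % schedule.coord_stride == 0)
                trajs[r].append(TrajectorySample(
                    step=sweep, energy=w.energy, pairs=w.pairs,
                    coords=w.conf.coords.copy() if keep_coords else None,
                    f=w.charge.f.copy() if keep_coords else None))
        if sweep % 1000 == 0:
            for w in walkers:
                w.verify_energy()
    if exchange_attempts:
        rate = exchange_accepts / exchange_attempts
        if rate < 0.02:
            warnings.warn(f"low replica-exchange acceptance ({rate:.3f}); "
                          "consider a denser ladder", stacklevel=2)
    return trajs
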