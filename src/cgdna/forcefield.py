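"""Coarse-grained DNA force field.

Total energy of a chain:

    U = Ub + Ua + Ud + Uexc + Ubp + Ubs + Ucs + Uel

* ``Ub/Ua/Ud`` -- harmonic bonds, harmonic angles and ``k(1 - cos(phi-phi0))``
  dihedrals over the P-C-N backbone graph.  Two complete bonded parameter
  sets exist: *loop* (soft, used throughout folding) and *helix* (stiff,
  B-form equilibria, applied to base-paired regions during final
  refinement only).
* ``Uexc`` -- WCA (truncated-shifted Lennard-Jones) excluded volume between
  all non-bonded bead pairs, contact distance = sum of vdW radii.
* ``Ubp`` -- Watson-Crick pairing well: a Gaussian in the N-N distance
  modulated by smooth base-orientation factors; depth is pair-type
  dependent (G-C deeper than A-T).
* ``Ubs`` -- sequence-dependent stacking reward for adjacent base pairs
  (i,j),(i+1,j-1); dimer-step depths follow nearest-neighbor thermodynamic
  trends and already fold in the fitted stacking-entropy penalty.
* ``Ucs`` -- coaxial stacking between terminal base pairs of distinct stems
  across a junction, same geometric form as Ubs.
* ``Uel`` -- screened Coulomb between reduced P charges; lives in
  :mod:`cgdna.electrostatics` and is summed in by :func:`total_energy`.

All constants are loaded from editable YAML files shipped with the package
(``data/bonded_loop.yaml``, ``data/bonded_helix.yaml``,
``data/nonbonded.yaml``); the physics code contains no hard-coded magic
numbers.  Energies are kcal/mol, lengths Angstrom, angles degrees in the
files and radians internally.
"""

from __future__ import annotations

import hashlib
import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cg_model import BEADS_PER_NT, BasePairSet, CGConformation
from .electrostatics import ChargeState, IonCondition, electrostatic_energy

__all__ = [
    "BondedParams",
    "NonbondedParams",
    "ForceFieldParams",
    "RegionMap",
    "bonded_energy",
    "excluded_volume_energy",
    "base_pair_energy",
    "base_stack_energy",
    "coaxial_stack_energy",
    "mechanical_energy",
    "total_energy",
    "stems_of",
]

#: nonbonded interactions are cut off beyond this distance (A)
DEFAULT_CUTOFF = 18.0


@dataclass
class BondedParams:
    """One complete bonded parameter set (helix or loop).

    ``bonds``: key -> (r0 [A], k [kcal/mol/A^2]);
    ``angles``: key -> (theta0 [rad], k [kcal/mol/rad^2]);
    ``dihedrals``: key -> (phi0 [rad], k [kcal/mol]) for k*(1-cos(phi-phi0)).
    """

    bonds: dict[str, tuple[float, float]]
    angles: dict[str, tuple[float, float]]
    dihedrals: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for key, (r0, k) in self.bonds.items():
            if r0 <= 0 or k < 0:
                raise ValueError(f"bad bond parameters for {key}: r0={r0}, k={k}")
        for table in (self.angles, self.dihedrals):
            for key, (_, k) in table.items():
                if k < 0:
                    raise ValueError(f"negative force constant for {key}")

    @classmethod
    def from_dict(cls, d: dict) -> "BondedParams":
        bonds = {k: (float(v["r0"]), float(v["k"])) for k, v in d["bonds"].items()}
        angles = {k: (np.deg2rad(float(v["theta0"])), float(v["k"]))
                  for k, v in d["angles"].items()}
        dihedrals = {k: (np.deg2rad(float(v["phi0"])), float(v["k"]))
                     for k, v in d["dihedrals"].items()}
        return cls(bonds, angles, dihedrals)

    def to_dict(self) -> dict:
        return {
            "bonds": {k: {"r0": float(r0), "k": float(kk)}
                      for k, (r0, kk) in self.bonds.items()},
            "angles": {k: {"theta0": float(np.rad2deg(t0)), "k": float(kk)}
                       for k, (t0, kk) in self.angles.items()},
            "dihedrals": {k: {"phi0": float(np.rad2deg(p0)), "k": float(kk)}
                          for k, (p0, kk) in self.dihedrals.items()},
        }


@dataclass
class NonbondedParams:
    """Excluded-volume, pairing, stacking and coaxial-stacking constants."""

    exc_epsilon: float
    bp_depth: dict[str, float]      # "AT"/"GC" -> well depth (kcal/mol, positive)
    bp_d0: float                    # N-N target distance (A)
    bp_sigma: float                 # Gaussian width (A)
    bp_orient_lo: float             # smoothstep window on facing alignment
    bp_orient_hi: float
    bs_depth: dict[str, float]      # dimer step (5'->3') -> depth (kcal/mol)
    bs_d0: float                    # pair-midpoint stacking distance (A)
    bs_sigma: float
    cs_depth: float
    cs_d0: float
    cs_sigma: float
    cs_align_lo: float
    cs_align_hi: float
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        for k, v in self.bp_depth.items():
            if k not in ("AT", "GC"):
                raise ValueError(f"pairing energies defined only for WC types, got {k}")
            if not np.isfinite(v):
                raise ValueError("non-finite well depth")

    @classmethod
    def from_dict(cls, d: dict) -> "NonbondedParams":
        return cls(
            exc_epsilon=float(d["excluded_volume"]["epsilon"]),
            bp_depth={k: float(v) for k, v in d["base_pair"]["depth"].items()},
            bp_d0=float(d["base_pair"]["d0"]),
            bp_sigma=float(d["base_pair"]["sigma"]),
            bp_orient_lo=float(d["base_pair"]["orient_lo"]),
            bp_orient_hi=float(d["base_pair"]["orient_hi"]),
            bs_depth={k: float(v) for k, v in d["base_stack"]["depth"].items()},
            bs_d0=float(d["base_stack"]["d0"]),
            bs_sigma=float(d["base_stack"]["sigma"]),
            cs_depth=float(d["coaxial_stack"]["depth"]),
            cs_d0=float(d["coaxial_stack"]["d0"]),
            cs_sigma=float(d["coaxial_stack"]["sigma"]),
            cs_align_lo=float(d["coaxial_stack"]["align_lo"]),
            cs_align_hi=float(d["coaxial_stack"]["align_hi"]),
            cutoff=float(d.get("cutoff", DEFAULT_CUTOFF)),
        )

    def to_dict(self) -> dict:
        return {
            "excluded_volume": {"epsilon": self.exc_epsilon},
            "base_pair": {"depth": dict(self.bp_depth), "d0": self.bp_d0,
                          "sigma": self.bp_sigma, "orient_lo": self.bp_orient_lo,
                          "orient_hi": self.bp_orient_hi},
            "base_stack": {"depth": dict(self.bs_depth), "d0": self.bs_d0,
                           "sigma": self.bs_sigma},
            "coaxial_stack": {"depth": self.cs_depth, "d0": self.cs_d0,
                              "sigma": self.cs_sigma, "align_lo": self.cs_align_lo,
                              "align_hi": self.cs_align_hi},
            "cutoff": self.cutoff,
        }

    def pair_depth(self, a: str, b: str) -> float:
        key = "".join(sorted((a, b)))
        if key == "AT":
            return self.bp_depth["AT"]
        if key == "CG":
            return self.bp_depth["GC"]
        raise KeyError(f"no pairing energy for {a}-{b}")


@dataclass
class ForceFieldParams:
    bonded_helix: BondedParams
    bonded_loop: BondedParams
    nonbonded: NonbondedParams

    @classmethod
    def load_default(cls) -> "ForceFieldParams":
        pkg = resources.files("cgdna") / "data"
        return cls(
            bonded_helix=BondedParams.from_dict(
                yaml.safe_load((pkg / "bonded_helix.yaml").read_text())),
            bonded_loop=BondedParams.from_dict(
                yaml.safe_load((pkg / "bonded_loop.yaml").read_text())),
            nonbonded=NonbondedParams.from_dict(
                yaml.safe_load((pkg / "nonbonded.yaml").read_text())),
        )

    @classmethod
    def load(cls, helix_path, loop_path, nonbonded_path) -> "ForceFieldParams":
        with open(helix_path) as fh:
            helix = BondedParams.from_dict(yaml.safe_load(fh))
        with open(loop_path) as fh:
            loop = BondedParams.from_dict(yaml.safe_load(fh))
        with open(nonbonded_path) as fh:
            nb = NonbondedParams.from_dict(yaml.safe_load(fh))
        return cls(helix, loop, nb)

    def checksum(self) -> str:
        """Short deterministic checksum of the parameter content, for run logs."""
        blob = yaml.safe_dump(
            {"helix": self.bonded_helix.to_dict(),
             "loop": self.bonded_loop.to_dict(),
             "nonbonded": self.nonbonded.to_dict()}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class RegionMap:
    """Per-nucleotide helical/loop flags, consistent with a base-pair set."""

    def __init__(self, n_nt: int, helical=()):
        self.helical = np.zeros(n_nt, dtype=bool)
        self.helical[list(helical)] = True

    @classmethod
    def all_loop(cls, n_nt: int) -> "RegionMap":
        return cls(n_nt)

    @classmethod
    def from_pairs(cls, n_nt: int, pairs: BasePairSet) -> "RegionMap":
        return cls(n_nt, pairs.paired_residues())

    def is_helical(self, i: int) -> bool:
        return bool(self.helical[i])


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _angle(a, b, c) -> float:
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(a, b, c, d) -> float:
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def _smoothstep(x: float, lo: float, hi: float) -> float:
    if x <= lo:
        return 0.0
    if x >= hi:
        return 1.0
    t = (x - lo) / (hi - lo)
    return t * t * (3.0 - 2.0 * t)


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=128)
def _bonded_terms_cached(n: int, chain_breaks: frozenset):
    class _Topo:  # minimal stand-in carrying what the enumeration needs
        n_nt = n
        pass
    topo = _Topo()
    topo.chain_breaks = chain_breaks
    return _enumerate_bonded_terms(topo)


def _bonded_terms(conf: CGConformation):
    return _bonded_terms_cached(conf.n_nt, conf.chain_breaks)


def _enumerate_bonded_terms(conf):
    """Enumerate (kind, key, bead indices, residues involved) bonded terms."""
    n = conf.n_nt
    terms = []
    P = lambda i: 3 * i
    C = lambda i: 3 * i + 1
    N = lambda i: 3 * i + 2
    for i in range(n):
        terms.append(("bond", "PC", (P(i), C(i)), (i,)))
        terms.append(("bond", "CN", (C(i), N(i)), (i,)))
    for i in range(n - 1):
        if i in conf.chain_breaks:
            continue
        terms.append(("bond", "CP", (C(i), P(i + 1)), (i, i + 1)))
        terms.append(("angle", "PCP", (P(i), C(i), P(i + 1)), (i, i + 1)))
        terms.append(("angle", "NCP", (N(i), C(i), P(i + 1)), (i, i + 1)))
        terms.append(("angle", "CPC", (C(i), P(i + 1), C(i + 1)), (i, i + 1)))
        terms.append(("dihedral", "PCPC", (P(i), C(i), P(i + 1), C(i + 1)), (i, i + 1)))
        terms.append(("dihedral", "CPCN", (C(i), P(i + 1), C(i + 1), N(i + 1)), (i, i + 1)))
    for i in range(n):
        terms.append(("angle", "PCN", (P(i), C(i), N(i)), (i,)))
    for i in range(n - 2):
        if i in conf.chain_breaks or (i + 1) in conf.chain_breaks:
            continue
        terms.append(("dihedral", "CPCP",
                      (C(i), P(i + 1), C(i + 1), P(i + 2)), (i, i + 1, i + 2)))
    return terms


@lru_cache(maxsize=128)
def _bonded_arrays(n: int, chain_breaks: frozenset):
    """Index arrays for vectorized bonded evaluation, grouped by term kind."""
    terms = _bonded_terms_cached(n, chain_breaks)
    out = {}
    for kind, width in (("bond", 2), ("angle", 3), ("dihedral", 4)):
        sel = [t for t in terms if t[0] == kind]
        idx = np.array([t[2] for t in sel], dtype=int).reshape(-1, width)
        keys = [t[1] for t in sel]
        res = [t[3] for t in sel]
        out[kind] = (idx, keys, res)
    return out


def _param_columns(keys, table_loop, table_helix):
    """(x0_loop, k_loop, x0_helix, k_helix) arrays aligned with the term list."""
    x0l = np.array([table_loop[k][0] for k in keys])
    kl = np.array([table_loop[k][1] for k in keys])
    x0h = np.array([table_helix[k][0] for k in keys])
    kh = np.array([table_helix[k][1] for k in keys])
    return x0l, kl, x0h, kh


def _helix_term_mask(res_lists, helical: np.ndarray) -> np.ndarray:
    return np.array([all(helical[r] for r in rs) for rs in res_lists])


def bonded_energy(conf: CGConformation, params: ForceFieldParams,
                  regions: RegionMap) -> float:
    """Ub + Ua + Ud with the loop set on loop residues, helix set on helical ones.

    A term uses the helix parameters iff every residue it touches is
    currently base-paired (helical); any loop participation selects the
    loop set.
    """
    if regions.helical.shape[0] != conf.n_nt:
        raise ValueError("region map size incompatible with conformation")
    x = conf.coords
    arrays = _bonded_arrays(conf.n_nt, conf.chain_breaks)
    total = 0.0

    idx, keys, res = arrays["bond"]
    if len(keys):
        x0l, kl, x0h, kh = _param_columns(keys, params.bonded_loop.bonds,
                                          params.bonded_helix.bonds)
        hmask = _helix_term_mask(res, regions.helical)
        r0 = np.where(hmask, x0h, x0l)
        k = np.where(hmask, kh, kl)
        r = np.linalg.norm(x[idx[:, 0]] - x[idx[:, 1]], axis=1)
        total += float(np.sum(k * (r - r0) ** 2))

    idx, keys, res = arrays["angle"]
    if len(keys):
        x0l, kl, x0h, kh = _param_columns(keys, params.bonded_loop.angles,
                                          params.bonded_helix.angles)
        hmask = _helix_term_mask(res, regions.helical)
        t0 = np.where(hmask, x0h, x0l)
        k = np.where(hmask, kh, kl)
        u = x[idx[:, 0]] - x[idx[:, 1]]
        v = x[idx[:, 2]] - x[idx[:, 1]]
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        th = np.arccos(np.clip(cosang, -1.0, 1.0))
        total += float(np.sum(k * (th - t0) ** 2))

    idx, keys, res = arrays["dihedral"]
    if len(keys):
        x0l, kl, x0h, kh = _param_columns(keys, params.bonded_loop.dihedrals,
                                          params.bonded_helix.dihedrals)
        hmask = _helix_term_mask(res, regions.helical)
        p0 = np.where(hmask, x0h, x0l)
        k = np.where(hmask, kh, kl)
        b1 = x[idx[:, 1]] - x[idx[:, 0]]
        b2 = x[idx[:, 2]] - x[idx[:, 1]]
        b3 = x[idx[:, 3]] - x[idx[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
        ph = np.arctan2(np.einsum("ij,ij->i", m1, n2),
                        np.einsum("ij,ij->i", n1, n2))
        total += float(np.sum(k * (1.0 - np.cos(ph - p0))))
    return float(total)


# ---------------------------------------------------------------------------
# excluded volume
# ---------------------------------------------------------------------------

def _bonded_exclusions(conf: CGConformation) -> set[tuple[int, int]]:
    """Bead pairs excluded from nonbonded terms: 1-2 and 1-3 neighbours."""
    excl: set[tuple[int, int]] = set()
    for kind, _, beads, _ in _bonded_terms(conf):
        if kind == "bond":
            i, j = beads
            excl.add((min(i, j), max(i, j)))
        elif kind == "angle":
            i, _, j = beads
            excl.add((min(i, j), max(i, j)))
    return excl


@lru_cache(maxsize=128)
def _exclusion_mask_cached(n_nt: int, chain_breaks: frozenset) -> np.ndarray:
    """Upper-triangular mask of nonbonded bead pairs.

    Pairs within three bonds on the bonded graph (1-2, 1-3 and 1-4
    neighbours) are excluded, the usual convention so that bonded terms and
    excluded volume do not fight over the same coordinates.
    """
    nb = 3 * n_nt
    adj: list[set[int]] = [set() for _ in range(nb)]
    for kind, _, beads, _ in _bonded_terms_cached(n_nt, chain_breaks):
        if kind == "bond":
            i, j = beads
            adj[i].add(j)
            adj[j].add(i)
    mask = np.triu(np.ones((nb, nb), dtype=bool), k=1)
    for start in range(nb):
        seen = {start: 0}
        frontier = [start]
        for depth in range(1, 4):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        for v in seen:
            if v > start:
                mask[start, v] = False
    mask.setflags(write=False)
    return mask


def _exclusion_mask(conf: CGConformation) -> np.ndarray:
    return _exclusion_mask_cached(conf.n_nt, conf.chain_breaks)


def _wca_energy(d: np.ndarray, sigma: np.ndarray, eps: float) -> np.ndarray:
    """WCA repulsion: 4*eps*((s/r)^12-(s/r)^6)+eps for r < 2^(1/6)*s, else 0."""
    out = np.zeros_like(d)
    rcut = 2.0 ** (1.0 / 6.0) * sigma
    m = d < rcut
    if np.any(m):
        sr6 = (sigma[m] / np.maximum(d[m], 1e-6)) ** 6
        out[m] = 4.0 * eps * (sr6 * sr6 - sr6) + eps
    return out


def excluded_volume_energy(conf: CGConformation, params: ForceFieldParams) -> float:
    """Pairwise WCA repulsion over all non-bonded bead pairs (Uexc)."""
    x = conf.coords
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    radii = conf.bead_radii()
    sigma = radii[:, None] + radii[None, :]
    mask = _exclusion_mask(conf)
    e = _wca_energy(d[mask], sigma[mask], params.nonbonded.exc_epsilon)
    return float(e.sum())


# ---------------------------------------------------------------------------
# base pairing / stacking / coaxial stacking
# ---------------------------------------------------------------------------

def _pair_geometry_factor(conf: CGConformation, i: int, j: int,
                          nb: NonbondedParams) -> float:
    """Distance+orientation modulation of the pairing well, in [0, 1]."""
    ni = conf.bead(i, "N")
    nj = conf.bead(j, "N")
    ci = conf.bead(i, "C")
    cj = conf.bead(j, "C")
    dv = nj - ni
    d = np.linalg.norm(dv)
    if d > nb.cutoff or d < 1e-6:
        return 0.0
    gd = np.exp(-((d - nb.bp_d0) ** 2) / (2.0 * nb.bp_sigma ** 2))
    ui = ni - ci
    ui /= np.linalg.norm(ui)
    uj = nj - cj
    uj /= np.linalg.norm(uj)
    wi = _smoothstep(float(np.dot(ui, dv / d)), nb.bp_orient_lo, nb.bp_orient_hi)
    wj = _smoothstep(float(np.dot(uj, -dv / d)), nb.bp_orient_lo, nb.bp_orient_hi)
    return float(gd * wi * wj)


def base_pair_energy(conf: CGConformation, pairs: BasePairSet,
                     params: ForceFieldParams) -> float:
    """Ubp: sum of WC pairing wells; <= 0, exactly -depth at ideal geometry."""
    nb = params.nonbonded
    total = 0.0
    for i, j in pairs:
        # re-assert the canonical-pair contract against this sequence
        depth = nb.pair_depth(conf.sequence[i], conf.sequence[j])
        sep = conf.same_strand_separation(i, j)
        if sep is not None and sep < 4:
            raise ValueError(f"pair ({i},{j}) violates minimum separation")
        total -= depth * _pair_geometry_factor(conf, i, j, nb)
    return float(total)


def _pair_midpoint(conf: CGConformation, pair: tuple[int, int]) -> np.ndarray:
    i, j = pair
    return 0.5 * (conf.bead(i, "N") + conf.bead(j, "N"))


def _pair_axis(conf: CGConformation, pair: tuple[int, int]) -> np.ndarray:
    i, j = pair
    v = conf.bead(j, "N") - conf.bead(i, "N")
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else v


def _stack_geometry_factor(dc: float, d0: float, sigma: float,
                           cutoff: float) -> float:
    if dc > cutoff:
        return 0.0
    return float(np.exp(-((dc - d0) ** 2) / (2.0 * sigma ** 2)))


def stems_of(pairs: BasePairSet) -> list[list[tuple[int, int]]]:
    """Decompose a pair set into stems: maximal runs (i,j),(i+1,j-1),..."""
    remaining = sorted(pairs.pairs)
    pairset = set(remaining)
    stems = []
    used: set[tuple[int, int]] = set()
    for p in remaining:
        if p in used:
            continue
        i, j = p
        if (i - 1, j + 1) in pairset:  # not the start of a run
            continue
        stem = []
        while (i, j) in pairset:
            stem.append((i, j))
            used.add((i, j))
            i, j = i + 1, j - 1
        stems.append(stem)
    return stems


def base_stack_energy(conf: CGConformation, pairs: BasePairSet,
                      params: ForceFieldParams) -> float:
    """Ubs: sequence-dependent reward for adjacent base pairs at helical geometry."""
    nb = params.nonbonded
    pairset = set(pairs.pairs)
    total = 0.0
    for i, j in pairset:
        q = (i + 1, j - 1)
        if q not in pairset:
            continue
        step = conf.sequence[i] + conf.sequence[i + 1]
        depth = nb.bs_depth[step]
        dc = float(np.linalg.norm(_pair_midpoint(conf, (i, j)) -
                                  _pair_midpoint(conf, q)))
        total -= depth * _stack_geometry_factor(dc, nb.bs_d0, nb.bs_sigma, nb.cutoff)
    return float(total)


def coaxial_stack_energy(conf: CGConformation, pairs: BasePairSet,
                         params: ForceFieldParams) -> float:
    """Ucs: reward for mutually stacked terminal pairs of distinct stems."""
    nb = params.nonbonded
    stems = stems_of(pairs)
    if len(stems) < 2:
        return 0.0
    total = 0.0
    for a in range(len(stems)):
        for b in range(a + 1, len(stems)):
            best = 0.0
            for p in (stems[a][0], stems[a][-1]):
                for q in (stems[b][0], stems[b][-1]):
                    dc = float(np.linalg.norm(_pair_midpoint(conf, p) -
                                              _pair_midpoint(conf, q)))
                    g = _stack_geometry_factor(dc, nb.cs_d0, nb.cs_sigma, nb.cutoff)
                    if g == 0.0:
                        continue
                    align = abs(float(np.dot(_pair_axis(conf, p),
                                             _pair_axis(conf, q))))
                    w = _smoothstep(align, nb.cs_align_lo, nb.cs_align_hi)
                    best = max(best, g * w)
            total -= nb.cs_depth * best
    return float(total)


# ---------------------------------------------------------------------------
# totals
# ---------------------------------------------------------------------------

def mechanical_energy(conf: CGConformation, pairs: BasePairSet,
                      regions: RegionMap, params: ForceFieldParams) -> float:
    """All temperature-independent terms: Ub+Ua+Ud+Uexc+Ubp+Ubs+Ucs."""
    return (bonded_energy(conf, params, regions)
            + excluded_volume_energy(conf, params)
            + base_pair_energy(conf, pairs, params)
            + base_stack_energy(conf, pairs, params)
            + coaxial_stack_energy(conf, pairs, params))


def total_energy(conf: CGConformation, pairs: BasePairSet, regions: RegionMap,
                 params: ForceFieldParams, ion: IonCondition, T: float,
                 charge: ChargeState) -> float:
    """Full Eq.-1-style energy; temperature enters only through Uel."""
    u = mechanical_energy(conf, pairs, regions, params)
    ion_t = ion.at_temperature(T)
    u += electrostatic_energy(conf, charge, ion_t)
    return float(u)
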