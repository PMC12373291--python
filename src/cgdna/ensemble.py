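"""Structure-ensemble analysis: base-pair detection, scoring, clustering,
top-model selection and refinement.

Base pairs are always read off 3D geometry (never predicted from sequence
alone): a Watson-Crick-complementary residue pair counts as paired when the
base-bead distance and mutual base orientation fall inside configurable
windows whose defaults match the ideal-duplex generator.  Scoring metrics
are the field's standard ones: least-squares superposition RMSD, base-pair
F1 (harmonic mean of precision and sensitivity), and radius of gyration.

Top-model selection follows an iterative largest-cluster protocol: from the
lowest-energy decoys at the coldest replica, repeatedly extract the largest
cluster within a threshold of 0.1 A per nucleotide (5 A for a 50-mer),
then report the medoids of the three largest clusters plus the single
lowest-energy decoy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cg_model import BasePairSet, CGConformation, is_wc
from .electrostatics import IonCondition, solve_charge_fractions
from .forcefield import ForceFieldParams, RegionMap

__all__ = [
    "PairDetectionConfig",
    "ClusterResult",
    "ScoreReport",
    "detect_base_pairs",
    "kabsch_superpose",
    "rmsd",
    "f1_score",
    "radius_of_gyration",
    "cluster_threshold",
    "cluster_structures",
    "select_top_models",
    "refine",
    "neutralization_stats",
]


@dataclass(frozen=True)
class PairDetectionConfig:
    """Geometric windows for pair detection (defaults fit the ideal duplex)."""

    d0: float = 8.9095        # target N-N distance, A
    window: float = 1.5       # accepted |d - d0|, A
    orient_min: float = 0.40  # minimum facing alignment of both bases
    min_separation: int = 4   # minimum |j - i| on an unbroken strand


from functools import lru_cache


@lru_cache(maxsize=64)
def _candidate_mask(residues: str, breaks: frozenset, min_separation: int):
    """Static (geometry-independent) candidate matrix: complementary pairs at
    allowed same-strand separation, upper triangle only."""
    n = len(residues)
    ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if not is_wc(residues[i], residues[j]):
                continue
            if not any(i <= b < j for b in breaks) and j - i < min_separation:
                continue
            ok[i, j] = True
    return ok


def detect_base_pairs(conf: CGConformation,
                      config: PairDetectionConfig = PairDetectionConfig()
                      ) -> BasePairSet:
    """Detect Watson-Crick base pairs from CG geometry.

    Candidates must be complementary, separated by at least three intervening
    residues on the same strand (cross-strand pairs over a chain break are
    exempt), with N-N distance inside ``d0 +/- window`` and both bases
    facing each other.  Each residue keeps at most one partner; conflicts
    resolve best-geometry-first.
    """
    npos = conf.beads_of_kind("N")
    cpos = conf.beads_of_kind("C")
    u = npos - cpos
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    diff = npos[None, :, :] - npos[:, None, :]
    d = np.linalg.norm(diff, axis=-1)

    mask = _candidate_mask(conf.sequence.residues, conf.chain_breaks,
                           config.min_separation).copy()
    mask &= np.abs(d - config.d0) <= config.window
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        return BasePairSet([], conf)
    dv = diff[ii, jj] / d[ii, jj][:, None]
    ai = np.einsum("kd,kd->k", u[ii], dv)
    aj = np.einsum("kd,kd->k", u[jj], -dv)
    keep = (ai >= config.orient_min) & (aj >= config.orient_min)
    ii, jj = ii[keep], jj[keep]
    score = np.abs(d[ii, jj] - config.d0) + (1.0 - ai[keep]) + (1.0 - aj[keep])
    order = np.argsort(score, kind="stable")
    taken: set[int] = set()
    pairs = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in taken or j in taken:
            continue
        taken.update((i, j))
        pairs.append((i, j))
    return BasePairSet(pairs, conf)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares superposition (Kabsch): returns (rotated+shifted mobile, rmsd)."""
    if mobile.shape != target.shape:
        raise ValueError("coordinate sets differ in shape")
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    dmat = np.diag([1.0, 1.0, sign])
    rot = vt.T @ dmat @ u.T
    moved = mc @ rot.T + target.mean(axis=0)
    return moved, float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))


def _select_coords(conf: CGConformation, bead_selection) -> np.ndarray:
    if bead_selection is None or bead_selection == "all":
        return conf.coords
    kinds = conf.bead_kinds()
    sel = np.isin(kinds, list(bead_selection))
    return conf.coords[sel]


def rmsd(a: CGConformation, b: CGConformation, bead_selection=None) -> float:
    """Optimal-superposition RMSD between two conformations (A)."""
    xa = _select_coords(a, bead_selection)
    xb = _select_coords(b, bead_selection)
    if xa.shape != xb.shape:
        raise ValueError("conformations have different selected-bead counts")
    return kabsch_superpose(xa, xb)[1]


def coords_rmsd(xa: np.ndarray, xb: np.ndarray) -> float:
    return kabsch_superpose(xa, xb)[1]


def f1_score(pred: BasePairSet, native: BasePairSet) -> tuple[float, float, float]:
    """(F1, precision, sensitivity) of predicted vs native base pairs.

    F1 = 2*PR*SN/(PR+SN); by convention F1 = 0 when there are no true
    positives.
    """
    tp = len(pred.pairs & native.pairs)
    fp = len(pred.pairs - native.pairs)
    fn = len(native.pairs - pred.pairs)
    pr = tp / (tp + fp) if tp + fp else 0.0
    sn = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2.0 * pr * sn / (pr + sn) if tp else 0.0
    return f1, pr, sn


def radius_of_gyration(conf: CGConformation) -> float:
    """Mass-uniform Rg over all beads (A)."""
    x = conf.coords
    c = x.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((x - c) ** 2, axis=1))))


@dataclass
class ScoreReport:
    rmsd: float
    f1: float
    precision: float
    sensitivity: float
    rg: float

    def __post_init__(self) -> None:
        for v in (self.f1, self.precision, self.sensitivity):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.rmsd < 0 or self.rg < 0:
            raise ValueError("rmsd and rg must be >= 0")


def score_structures(pred: CGConformation, native: CGConformation,
                     bead_selection=None) -> ScoreReport:
    f1, pr, sn = f1_score(detect_base_pairs(pred), detect_base_pairs(native))
    return ScoreReport(rmsd=rmsd(pred, native, bead_selection), f1=f1,
                       precision=pr, sensitivity=sn,
                       rg=radius_of_gyration(pred))


# ---------------------------------------------------------------------------
# clustering & model selection
# ---------------------------------------------------------------------------

def cluster_threshold(n_nt: int, per_nt: float = 0.1) -> float:
    """Clustering RMSD threshold: 0.1 A times sequence length (5 A at 50 nt)."""
    return per_nt * n_nt


@dataclass
class ClusterResult:
    clusters: list[list[int]]       # member indices, largest first
    medoids: list[int]
    threshold: float


def _pairwise_rmsd(coord_list: list[np.ndarray]) -> np.ndarray:
    n = len(coord_list)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = coords_rmsd(coord_list[i], coord_list[j])
    return d


def cluster_structures(coord_list: list[np.ndarray], threshold: float) -> ClusterResult:
    """Iterative largest-cluster extraction under an RMSD threshold.

    Repeatedly finds the structure with the most neighbours within
    *threshold*, removes it and its neighbours as one cluster, until all
    structures are assigned.  Deterministic given input order (ties keep the
    lowest index).  Medoids minimize total intra-cluster RMSD.
    """
    d = _pairwise_rmsd(coord_list)
    alive = list(range(len(coord_list)))
    clusters: list[list[int]] = []
    medoids: list[int] = []
    while alive:
        sub = d[np.ix_(alive, alive)]
        within = sub <= threshold
        counts = within.sum(axis=1)
        center = int(np.argmax(counts))  # first max wins: deterministic
        members = [alive[k] for k in np.nonzero(within[center])[0]]
        msub = d[np.ix_(members, members)]
        medoid = members[int(np.argmin(msub.sum(axis=1)))]
        clusters.append(members)
        medoids.append(medoid)
        alive = [a for a in alive if a not in set(members)]
    order = sorted(range(len(clusters)), key=lambda k: -len(clusters[k]))
    return ClusterResult(clusters=[clusters[k] for k in order],
                         medoids=[medoids[k] for k in order],
                         threshold=threshold)


def select_top_models(trajectory, n_pool: int = 1000,
                      threshold_per_nt: float = 0.1,
                      rank_lowest_energy_first: bool = False):
    """Select top CG models from the coldest-replica trajectory.

    Pools the *n_pool* lowest-energy frames with coordinates, clusters them
    at ``threshold_per_nt * length``, and returns the medoids of the three
    largest clusters followed by the lowest-energy decoy (deduplicated).
    With ``rank_lowest_energy_first`` the lowest-energy decoy is promoted to
    the top instead.
    """
    import warnings

    frames = [s for s in trajectory.samples if s.coords is not None]
    if not frames:
        raise ValueError("trajectory carries no coordinate frames")
    if len(frames) < n_pool:
        warnings.warn(f"only {len(frames)} coordinate frames available "
                      f"(requested pool {n_pool}); using all", stacklevel=2)
    frames.sort(key=lambda s: s.energy)
    pool = frames[:n_pool]
    seq = trajectory.sequence
    thr = cluster_threshold(len(seq), threshold_per_nt)
    res = cluster_structures([f.coords for f in pool], thr)
    picks = [pool[m] for m in res.medoids[:3]]
    lowest = pool[0]
    ranked = picks + [lowest] if lowest not in picks else picks
    if rank_lowest_energy_first and lowest in ranked:
        ranked.remove(lowest)
        ranked.insert(0, lowest)
    out = []
    for f in ranked:
        out.append(CGConformation(seq, f.coords.copy()))
    return out, res


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def refine(conf: CGConformation, params: ForceFieldParams, ion: IonCondition,
           schedule=None, *, seed: int = 0,
           temperature: float = 25.0) -> CGConformation:
    """Room-temperature MC refinement with helix parameters on paired regions.

    Runs fixed-temperature Metropolis sampling from *conf*, scoring paired
    residues with the stiff helix bonded set and the rest with the loop set;
    the best-energy conformation seen is returned, so the output energy
    never exceeds the input energy.  A zero-step schedule is the identity.
    """
    from . import sampler  # local import: sampler depends on this module

    if schedule is None:
        schedule = sampler.RunSchedule(n_sweeps=200, burn_in=0, sample_stride=10)
    if schedule.n_sweeps == 0:
        return conf.copy()
    return sampler.run_fixed_temperature(
        conf, ion, params, schedule, seed=seed, temperature=temperature,
        helix_regions=True, preserve_pairs=True, return_best=True,
        quench_sweeps=max(200, schedule.n_sweeps))


# ---------------------------------------------------------------------------
# neutralization statistics
# ---------------------------------------------------------------------------

def neutralization_stats(trajectory, labels, ion: IonCondition):
    """Per-state ensemble means of the neutralization fraction and Rg.

    *labels* maps each coordinate-bearing sample (in order) to a state name.
    States with no frames are absent from the result (not reported as zero).
    Returns ``{state: {"mean_f": float, "mean_rg": float, "n_frames": int}}``.
    """
    frames = [s for s in trajectory.samples if s.coords is not None]
    if len(frames) != len(labels):
        raise ValueError("one label per coordinate frame required")
    acc: dict[str, list[tuple[float, float]]] = {}
    seq = trajectory.sequence
    for s, lab in zip(frames, labels):
        c = CGConformation(seq, s.coords)
        if s.f is not None:
            fmean = float(np.mean(s.f))
        else:
            fmean = float(np.mean(solve_charge_fractions(c, ion).f))
        x = c.coords
        rg = float(np.sqrt(np.mean(np.sum((x - x.mean(0)) ** 2, axis=1))))
        acc.setdefault(lab, []).append((fmean, rg))
    return {lab: {"mean_f": float(np.mean([a for a, _ in vals])),
                  "mean_rg": float(np.mean([b for _, b in vals])),
                  "n_frames": len(vals)}
            for lab, vals in acc.items()}
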