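"""Deterministic test inputs: benchmark sequences and synthetic generators.

Everything here is generated programmatically at call time; the module also
serves as the package's synthetic-data generator for validation studies
(planted decoy pools for clustering, analytic two-level replica
trajectories for WHAM, hairpin folding sequences).
"""

from __future__ import annotations

import numpy as np

from .cg_model import (CGConformation, Sequence, ideal_helix, init_conformation,
                       parse_sequence, reverse_complement)
from .electrostatics import BOLTZMANN_KCAL, celsius_to_kelvin
from .sampler import ReplicaTrajectory, TrajectorySample
from .cg_model import BasePairSet

__all__ = ["SEQ_3WJ", "SEQ_4WJ", "SEQ_HAIRPIN12", "fixture_suite",
           "planted_decoys", "wham_twolevel", "boltzmann_twolevel_fraction"]

#: benchmark three-way-junction sequence (printed as 38 letters)
SEQ_3WJ = "GAAATTGCGCTTTTTGCGCGTGCTTTTTGCACAATTTC"
#: benchmark four-way-junction sequence, 53 nt
SEQ_4WJ = "GAAATTGCGCTTTTTGCGCATATCTTTTTGATAGGTGCTTTTTGCACAATTTC"
#: minimal hairpin: 4-bp GC-rich stem, T4 loop
SEQ_HAIRPIN12 = "GCGCTTTTGCGC"


def planted_decoys(n_families: int = 3, per_family: int = 20, n_nt: int = 10,
                   seed: int = 0, spread: float = 0.3, separation: float = 40.0):
    """Decoy pool with planted geometric families for clustering tests.

    Families are well-separated rigid geometries; members jitter around
    their family template by *spread* A RMS.  Returns (coords list, labels).
    """
    rng = np.random.default_rng(seed)
    templates = []
    for fam in range(n_families):
        base = init_conformation(Sequence("A" * n_nt), 100 + fam).coords
        base = base * (1.0 + 0.4 * fam) + fam * separation
        templates.append(base)
    coords, labels = [], []
    for fam, tpl in enumerate(templates):
        for _ in range(per_family):
            coords.append(tpl + rng.normal(scale=spread, size=tpl.shape))
            labels.append(fam)
    order = rng.permutation(len(coords))
    return [coords[i] for i in order], [labels[i] for i in order]


def boltzmann_twolevel_fraction(T: float, e_a: float, e_b: float) -> float:
    """Exact fraction of state A for a two-level system at T (Celsius)."""
    beta = 1.0 / (BOLTZMANN_KCAL * celsius_to_kelvin(T))
    wa = np.exp(-beta * e_a)
    wb = np.exp(-beta * e_b)
    return float(wa / (wa + wb))


def wham_twolevel(temperatures=(25.0, 45.0, 74.0, 110.0), n_samples: int = 20000,
                  e_a: float = -1.0, e_b: float = 1.0, seed: int = 0):
    """Analytic two-level replica trajectories for WHAM validation.

    Each replica holds the exact Boltzmann proportions of two microstates
    ("A" at energy *e_a*, "B" at *e_b*) at its own temperature, assigned
    deterministically (counts rounded from exact fractions, order shuffled
    per seed), so reweighted fractions are computable in closed form.
    Returns (trajectories, labels) ready for :func:`cgdna.thermo.wham`.
    """
    rng = np.random.default_rng(seed)
    seq = Sequence("ACGT")
    trajs, labels = [], []
    for T in temperatures:
        fa = boltzmann_twolevel_fraction(T, e_a, e_b)
        n_a = int(round(n_samples * fa))
        labs = ["A"] * n_a + ["B"] * (n_samples - n_a)
        rng.shuffle(labs)
        tr = ReplicaTrajectory(temperature=T, sequence=seq)
        for step, lab in enumerate(labs, start=1):
            tr.append(TrajectorySample(step=step,
                                       energy=e_a if lab == "A" else e_b,
                                       pairs=BasePairSet([])))
        trajs.append(tr)
        labels.append(labs)
    return trajs, labels


def fixture_suite(name: str, seed: int = 0):
    """Named deterministic fixtures used across tests and demonstrations."""
    if name == "3wj_benchmark":
        return parse_sequence(SEQ_3WJ, name="3WJ")
    if name == "4wj_benchmark":
        return parse_sequence(SEQ_4WJ, name="4WJ")
    if name == "hairpin12":
        return parse_sequence(SEQ_HAIRPIN12, name="hairpin12")
    if name == "ideal_helix6":
        a = parse_sequence("GCGATC")
        return ideal_helix(a, Sequence(reverse_complement(a)))
    if name == "random_coil38":
        return init_conformation(parse_sequence(SEQ_3WJ), seed)
    if name == "decoys3":
        return planted_decoys(seed=seed)
    if name == "wham_twolevel":
        return wham_twolevel(seed=seed)
    raise KeyError(f"unknown fixture {name!r}")
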