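"""Three-bead coarse-grained DNA representation.

Each nucleotide is reduced to three beads: P (phosphate), C (sugar, centred
on C4') and N (base, centred on N1 for pyrimidines / N9 for purines).  Beads
are hard-ish spheres with van der Waals radii of 1.9 A (P), 1.7 A (C) and
2.2 A (N); only the P bead carries charge (-1 e).  Coordinates are in
Angstrom in a right-handed, non-periodic frame.

The module owns the chain topology (which bead bonds to which), sequence
parsing, the random self-avoiding initial-conformation generator used to
seed folding runs, and an ideal B-form duplex generator used as a geometric
reference and test fixture.  Duplexes are represented as a single chain with
a recorded chain break, so residue indexing stays uniform.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VDW_RADII",
    "P_CHARGE",
    "BEADS_PER_NT",
    "Sequence",
    "CGConformation",
    "BasePairSet",
    "AlphabetError",
    "ChainGenerationError",
    "parse_sequence",
    "complement",
    "reverse_complement",
    "init_conformation",
    "ideal_helix",
    "HELIX_GEOMETRY",
    "write_cg_pdb",
    "read_cg_pdb",
]

#: van der Waals radii of the three bead kinds (Angstrom).
VDW_RADII = {"P": 1.9, "C": 1.7, "N": 2.2}

#: charge of the phosphate bead, elementary-charge units.
P_CHARGE = -1.0

BEADS_PER_NT = 3

_BEAD_ORDER = ("P", "C", "N")

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

_ALPHABET = frozenset("ACGT")


class AlphabetError(ValueError):
    """Raised when a sequence contains a letter outside {A, C, G, T}."""


class ChainGenerationError(RuntimeError):
    """Raised when a self-avoiding chain cannot be placed within the retry budget."""


@dataclass(frozen=True)
class Sequence:
    """A validated DNA sequence (strict {A,C,G,T} alphabet)."""

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in _ALPHABET:
                raise AlphabetError(
                    f"invalid character {ch!r} at position {pos}: alphabet is A/C/G/T"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        return self.residues[i]


def parse_sequence(text: str, name: str = "") -> Sequence:
    """Parse a raw or single-record FASTA string into a :class:`Sequence`.

    FASTA headers are stripped (the first header names the sequence unless
    *name* is given); whitespace is removed and letters are uppercased.
    """
    if not text or not text.strip():
        raise ValueError("empty sequence input")
    lines = text.strip().splitlines()
    chunks: list[str] = []
    header = ""
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if chunks:
                raise ValueError("multi-record FASTA not supported; one sequence only")
            header = line[1:].strip()
        else:
            chunks.append(line)
    seq = "".join(chunks).upper().replace(" ", "")
    return Sequence(seq, name=name or header)


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str | Sequence) -> str:
    s = seq.residues if isinstance(seq, Sequence) else seq
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def is_wc(a: str, b: str) -> bool:
    """True for Watson-Crick complementary letters (A-T or G-C, either order)."""
    return _COMPLEMENT[a] == b


@dataclass
class CGConformation:
    """CG coordinates for one DNA chain.

    ``coords`` has shape (3*n_nt, 3); bead ``3*i + k`` is the P/C/N bead
    (k = 0/1/2) of nucleotide ``i``.  ``chain_breaks`` lists residue indices
    ``i`` after which the backbone is interrupted (no bonded terms between
    residues ``i`` and ``i+1``); this is how duplex fixtures carry two
    strands under a single uniform numbering.
    """

    sequence: Sequence
    coords: np.ndarray
    chain_breaks: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (BEADS_PER_NT * len(self.sequence), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} incompatible with "
                f"{len(self.sequence)}-nt sequence"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.chain_breaks = frozenset(int(i) for i in self.chain_breaks)

    @property
    def n_nt(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def bead(self, residue: int, kind: str) -> np.ndarray:
        return self.coords[BEADS_PER_NT * residue + _BEAD_ORDER.index(kind)]

    def beads_of_kind(self, kind: str) -> np.ndarray:
        """All coordinates of one bead kind, shape (n_nt, 3)."""
        return self.coords[_BEAD_ORDER.index(kind)::BEADS_PER_NT]

    def bead_kinds(self) -> np.ndarray:
        """Array of bead-kind labels aligned with ``coords`` rows."""
        return np.array(list(_BEAD_ORDER) * self.n_nt)

    def bead_radii(self) -> np.ndarray:
        return np.array([VDW_RADII[k] for k in _BEAD_ORDER] * self.n_nt)

    def bonded_between(self, i: int, j: int) -> bool:
        """Whether residues i and j (=i+1) are backbone-connected."""
        lo = min(i, j)
        return abs(i - j) == 1 and lo not in self.chain_breaks

    def same_strand_separation(self, i: int, j: int) -> int | None:
        """|j - i| if no chain break lies between residues i and j, else None."""
        lo, hi = sorted((i, j))
        for b in self.chain_breaks:
            if lo <= b < hi:
                return None
        return hi - lo

    def copy(self) -> "CGConformation":
        return CGConformation(self.sequence, self.coords.copy(), self.chain_breaks)


class BasePairSet:
    """A set of Watson-Crick base pairs (i, j) with i < j.

    Invariants: each residue participates in at most one pair; paired bases
    are complementary; same-strand partners are separated by at least three
    intervening residues (pairs across a chain break are exempt, which is
    what permits duplex fixtures).  Validation against complementarity and
    separation needs the conformation/sequence and is performed on
    construction when one is supplied.
    """

    def __init__(self, pairs, conf: CGConformation | None = None):
        norm = frozenset((min(i, j), max(i, j)) for i, j in pairs)
        seen: set[int] = set()
        for i, j in norm:
            if i == j:
                raise ValueError(f"degenerate pair ({i},{j})")
            for x in (i, j):
                if x in seen:
                    raise ValueError(f"residue {x} appears in more than one pair")
                seen.add(x)
        if conf is not None:
            for i, j in norm:
                a, b = conf.sequence[i], conf.sequence[j]
                if not is_wc(a, b):
                    raise ValueError(
                        f"pair ({i},{j}) is {a}-{b}: only canonical A-T/G-C allowed"
                    )
                sep = conf.same_strand_separation(i, j)
                if sep is not None and sep < 4:
                    raise ValueError(
                        f"pair ({i},{j}) separated by fewer than three intervening "
                        "residues on the same strand"
                    )
        self.pairs: frozenset[tuple[int, int]] = norm

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs))

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def __eq__(self, other) -> bool:
        return isinstance(other, BasePairSet) and self.pairs == other.pairs

    def __hash__(self) -> int:
        return hash(self.pairs)

    def __repr__(self) -> str:
        return f"BasePairSet({sorted(self.pairs)})"

    def partner(self, i: int) -> int | None:
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None

    def paired_residues(self) -> frozenset[int]:
        return frozenset(x for p in self.pairs for x in p)


# ---------------------------------------------------------------------------
# Ideal B-form helix generator
# ---------------------------------------------------------------------------

#: Parametric cylindrical geometry of the CG ideal B-form duplex.  Radii and
#: phase offsets are chosen so bond lengths fall in the 3.3-4.0 A range of the
#: CG mapping, the cross-pair N-N distance is 8.9 A and the cross-strand P-P
#: width is ~17.8 A, i.e. B-form-like.
HELIX_GEOMETRY = {
    "rise": 3.38,        # A per base pair
    "twist": 36.0,       # degrees per base pair
    "r_P": 8.9,          # A, radius of P beads
    "r_C": 7.7,          # A, radius of C beads
    "r_N": 6.3,          # A, radius of N beads
    "delta_P": -24.0,    # degrees, P phase offset from nucleotide phase
    "delta_C": 0.0,
    "delta_N": 25.0,
    "pair_phase": 140.0, # degrees between paired nucleotides' phases
}


def _helix_bead(i: int, delta: float, radius: float, *, phase0: float = 0.0,
                sign: float = 1.0) -> np.ndarray:
    g = HELIX_GEOMETRY
    ang = math.radians(phase0 + g["twist"] * i + sign * delta)
    return np.array([radius * math.cos(ang), radius * math.sin(ang), g["rise"] * i])


def ideal_helix(seq_a: Sequence, seq_b: Sequence) -> CGConformation:
    """Build an ideal B-form CG duplex from two complementary strands.

    *seq_b* must be the reverse complement of *seq_a*.  The result is a
    single chain: residues ``0..n-1`` are strand A (5'->3'), residues
    ``n..2n-1`` strand B (5'->3'), with a chain break after residue ``n-1``.
    Base pair partners are ``(i, 2n-1-i)``.
    """
    if seq_b.residues != reverse_complement(seq_a):
        raise ValueError("seq_b is not the reverse complement of seq_a")
    n = len(seq_a)
    g = HELIX_GEOMETRY
    coords = np.empty((2 * n * BEADS_PER_NT, 3))
    for i in range(n):
        for k, kind in enumerate(_BEAD_ORDER):
            coords[BEADS_PER_NT * i + k] = _helix_bead(
                i, g[f"delta_{kind}"], g[f"r_{kind}"])
    # strand B: rigid (dyad-rotated) copy of a standard strand; residue m of
    # strand B pairs with residue i = n-1-m of strand A, sits at the same z
    # with mirrored phase offsets.
    for m in range(n):
        i = n - 1 - m
        for k, kind in enumerate(_BEAD_ORDER):
            coords[BEADS_PER_NT * (n + m) + k] = _helix_bead(
                i, g[f"delta_{kind}"], g[f"r_{kind}"],
                phase0=g["pair_phase"], sign=-1.0)
    seq = Sequence(seq_a.residues + seq_b.residues,
                   name=(seq_a.name or "duplex"))
    return CGConformation(seq, coords, chain_breaks=frozenset({n - 1}))


def helix_base_pairs(conf: CGConformation) -> BasePairSet:
    """The by-construction pair set of an :func:`ideal_helix` duplex."""
    n = conf.n_nt // 2
    return BasePairSet([(i, conf.n_nt - 1 - i) for i in range(n)], conf)


# ---------------------------------------------------------------------------
# Random self-avoiding initial conformation
# ---------------------------------------------------------------------------

# Loop-region equilibrium internal coordinates used for chain growth (the
# same values the loop bonded parameter set carries; kept in sync by a test).
_GROW_BONDS = {"PC": 3.7, "CN": 3.3, "CP": 4.0}
_GROW_ANGLE_PCP = 112.0   # P_i - C_i - P_{i+1}, degrees
_GROW_ANGLE_CPC = 105.0   # C_i - P_{i+1} - C_{i+1}
_GROW_ANGLE_NCB = 108.0   # N off the backbone plane

#: allowed overlap below the sum of vdW radii during growth/clash checks (A)
OVERLAP_TOL = 0.4


def _place_from_internal(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                         bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates (NeRF)."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # collinear predecessors: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _clashes(pos: np.ndarray, radius: float, placed: np.ndarray,
             radii: np.ndarray, skip: int) -> bool:
    """Clash test of a candidate bead against all already-placed beads,
    ignoring the last *skip* beads (bonded neighbours)."""
    if placed.shape[0] <= skip:
        return False
    other = placed[: placed.shape[0] - skip]
    orad = radii[: placed.shape[0] - skip]
    d = np.linalg.norm(other - pos, axis=1)
    return bool(np.any(d < (orad + radius) - OVERLAP_TOL))


def init_conformation(seq: Sequence, rng_seed: int, *,
                      max_retries: int = 500, max_restarts: int = 20) -> CGConformation:
    """Grow a random self-avoiding CG chain near the loop equilibria.

    Backbone beads are placed sequentially by internal coordinates (loop
    equilibrium bond lengths and angles, uniformly random dihedrals); each
    placement is rejected and retried (up to *max_retries* per bead) if it
    overlaps an already-placed bead by more than the overlap tolerance.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(rng_seed)
    n = len(seq)
    for _ in range(max_restarts):
        coords = _try_grow(n, rng, max_retries)
        if coords is not None:
            return CGConformation(seq, coords)
    raise ChainGenerationError(
        f"could not place {n}-nt chain without clashes "
        f"({max_restarts} restarts x {max_retries} retries)")


def _try_grow(n: int, rng, max_retries: int) -> np.ndarray | None:
    coords = np.zeros((BEADS_PER_NT * n, 3))
    radii = np.empty(BEADS_PER_NT * n)
    for i in range(n):
        radii[3 * i:3 * i + 3] = [VDW_RADII[k] for k in _BEAD_ORDER]

    # first residue: P at origin, C along x, N placed off
    coords[0] = [0.0, 0.0, 0.0]
    coords[1] = [_GROW_BONDS["PC"], 0.0, 0.0]
    ang = math.radians(_GROW_ANGLE_NCB)
    coords[2] = coords[1] + _GROW_BONDS["CN"] * np.array(
        [-math.cos(ang), math.sin(ang), 0.0])
    n_placed = 3
    for i in range(1, n):
        prev_p, prev_c, prev_n = coords[3 * (i - 1):3 * i]
        before = coords[max(0, 3 * (i - 2)):3 * (i - 1)]
        # P_i from (P_{i-1}, C_{i-1}) then C_i then N_i, with clash retries
        ok = False
        for _ in range(max_retries):
            dih = rng.uniform(0.0, 360.0)
            anchor = before[0] if len(before) else prev_n
            p = _place_from_internal(anchor, prev_p, prev_c,
                                     _GROW_BONDS["CP"], _GROW_ANGLE_PCP, dih)
            dih2 = rng.uniform(0.0, 360.0)
            c = _place_from_internal(prev_p, prev_c, p,
                                     _GROW_BONDS["PC"], _GROW_ANGLE_CPC, dih2)
            dih3 = rng.uniform(0.0, 360.0)
            nb = _place_from_internal(prev_c, p, c,
                                      _GROW_BONDS["CN"], _GROW_ANGLE_NCB, dih3)
            placed = coords[:n_placed]
            pr = radii[:n_placed]
            if (_clashes(p, VDW_RADII["P"], placed, pr, skip=2)
                    or _clashes(c, VDW_RADII["C"], np.vstack([placed, [p]]),
                                np.append(pr, VDW_RADII["P"]), skip=2)
                    or _clashes(nb, VDW_RADII["N"], np.vstack([placed, [p], [c]]),
                                np.append(pr, [VDW_RADII["P"], VDW_RADII["C"]]),
                                skip=2)):
                continue
            coords[3 * i] = p
            coords[3 * i + 1] = c
            coords[3 * i + 2] = nb
            n_placed += 3
            ok = True
            break
        if not ok:
            return None
    return coords


#: loop-set equilibrium dihedrals (degrees) used by the deterministic
#: reference chain; the loop bonded parameter file carries the same values.
_LOOP_DIHEDRALS = {"PCPC": -150.0, "CPCP": 170.0, "NCPC": 60.0}


def loop_reference_chain(seq: Sequence) -> CGConformation:
    """Deterministic chain sitting exactly at the loop bonded equilibria.

    Built by internal-coordinate placement with every bond, angle and
    dihedral at its loop equilibrium value; by construction its loop-set
    bonded energy is zero, which anchors tests of the bonded terms.
    """
    n = len(seq)
    coords = np.zeros((BEADS_PER_NT * n, 3))
    coords[0] = [0.0, 0.0, 0.0]
    coords[1] = [_GROW_BONDS["PC"], 0.0, 0.0]
    ang = math.radians(_GROW_ANGLE_NCB)
    coords[2] = coords[1] + _GROW_BONDS["CN"] * np.array(
        [-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        prev_p, prev_c, prev_n = coords[3 * (i - 1):3 * i]
        anchor = coords[3 * (i - 2) + 1] if i >= 2 else prev_n
        p = _place_from_internal(anchor, prev_p, prev_c, _GROW_BONDS["CP"],
                                 _GROW_ANGLE_PCP,
                                 _LOOP_DIHEDRALS["CPCP"] if i >= 2 else 45.0)
        c = _place_from_internal(prev_p, prev_c, p, _GROW_BONDS["PC"],
                                 _GROW_ANGLE_CPC, _LOOP_DIHEDRALS["PCPC"])
        nb = _place_from_internal(prev_c, p, c, _GROW_BONDS["CN"],
                                  _GROW_ANGLE_NCB, _LOOP_DIHEDRALS["NCPC"])
        coords[3 * i:3 * i + 3] = [p, c, nb]
    if n >= 3:
        # re-place the first base in the same local backbone frame as an
        # interior residue, so every bonded coordinate sits at equilibrium
        frame0 = _frame_from_points(coords[0], coords[1], coords[3])
        frame1 = _frame_from_points(coords[3], coords[4], coords[6])
        local_n1 = frame1.T @ (coords[5] - coords[4])
        coords[2] = coords[1] + frame0 @ local_n1
    return CGConformation(seq, coords)


def _frame_from_points(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Orthonormal frame (columns) spanned by points (a, b, c), origin b."""
    e1 = a - b
    e1 /= np.linalg.norm(e1)
    e2 = c - b
    e2 = e2 - np.dot(e2, e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


# ---------------------------------------------------------------------------
# CG-PDB serialization
# ---------------------------------------------------------------------------

_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_PDB_ATOM = {"P": "P", "C": "C4'"}


def _n_atom_name(base: str) -> str:
    return "N9" if base in "AG" else "N1"


def write_cg_pdb(conf: CGConformation, path_or_handle) -> None:
    """Write a CG conformation as PDB (atoms P, C4', N1/N9; residues DA/DC/DG/DT).

    Chain breaks are rendered as chain-ID changes (A, B, ...) plus TER records
    so generic viewers draw separate strands.
    """
    own = isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__")
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        chain_ids = "ABCDEFGH"
        chain = 0
        serial = 1
        for i in range(conf.n_nt):
            base = conf.sequence[i]
            res = _RESNAME[base]
            for k, kind in enumerate(_BEAD_ORDER):
                name = _PDB_ATOM.get(kind) or _n_atom_name(base)
                x, y, z = conf.coords[BEADS_PER_NT * i + k]
                elem = "P" if kind == "P" else ("C" if kind == "C" else "N")
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s} {res:>3s} {chain_ids[chain]}"
                    f"{i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {elem:>2s}\n")
                serial += 1
            if i in conf.chain_breaks:
                fh.write("TER\n")
                chain = min(chain + 1, len(chain_ids) - 1)
        fh.write("TER\nEND\n")
    finally:
        if own:
            fh.close()


def cg_pdb_string(conf: CGConformation) -> str:
    buf = io.StringIO()
    write_cg_pdb(conf, buf)
    return buf.getvalue()


def read_cg_pdb(path_or_handle) -> CGConformation:
    """Read a CG-PDB written by :func:`write_cg_pdb` back into a conformation."""
    own = isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__")
    fh = open(path_or_handle) if own else path_or_handle
    try:
        residues: list[str] = []
        coords: list[list[float]] = []
        breaks: set[int] = set()
        rev = {v: k for k, v in _RESNAME.items()}
        last_chain = None
        for line in fh:
            if line.startswith("ATOM"):
                res = line[17:20].strip()
                chain = line[21]
                name = line[12:16].strip()
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                if name == "P":
                    if last_chain is not None and chain != last_chain and residues:
                        breaks.add(len(residues) - 1)
                    last_chain = chain
                    residues.append(rev[res])
                coords.append(xyz)
        seq = Sequence("".join(residues))
        return CGConformation(seq, np.array(coords), chain_breaks=frozenset(breaks))
    finally:
        if own:
            fh.close()
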