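"""Fragment-based all-atom reconstruction from CG models.

Each unpaired nucleotide (and each Watson-Crick base pair, as one unit) is
replaced by an all-atom template fragment: the fragment whose CG-projected
anchor atoms (P, C4', N1/N9 of every residue in the fragment) superpose
onto the target CG beads with the smallest RMSD is rigidly placed.  The
library holds five non-redundant templates per key -- one key per base-pair
type (G-C, A-T, C-G, T-A) and per single nucleotide (A, G, C, T).

The default library is synthetic: idealized fragments generated from the
package's parametric B-form geometry (ring atoms as planar polygons with
~1.39 A bonds, backbone atoms placed at idealized internal coordinates,
variants differing in the 5'-tail torsion).  Users may instead build a
library from curated DNA PDB files via :func:`fragments_from_pdb` and
:func:`build_library`.  Chemical-accuracy refinement of the rebuilt model
is deliberately out of scope (an external all-atom refiner can be run on
the output PDB).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cg_model import (BEADS_PER_NT, BasePairSet, CGConformation, Sequence,
                       ideal_helix, reverse_complement)
from .ensemble import kabsch_superpose

__all__ = [
    "Fragment",
    "FragmentLibrary",
    "AllAtomStructure",
    "default_library",
    "build_library",
    "select_representatives",
    "fragments_from_pdb",
    "rebuild",
]

_PAIR_KEYS = ("GC", "AT", "CG", "TA")
_NT_KEYS = ("A", "G", "C", "T")

_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}


@dataclass
class Fragment:
    """One all-atom template with its CG anchor atoms.

    ``atoms``: (name, residue_slot, element) records; ``coords``: (n, 3);
    ``anchors``: indices of the P/C4'/N1-or-N9 atoms, residue-major
    (3 anchors per residue slot).
    """

    key: str
    atoms: list[tuple[str, int, str]]
    coords: np.ndarray
    anchors: tuple[int, ...]

    def anchor_coords(self) -> np.ndarray:
        return self.coords[list(self.anchors)]

    def cg_projection(self) -> np.ndarray:
        """The CG bead coordinates this fragment projects to (its anchors)."""
        return self.anchor_coords().copy()


@dataclass
class FragmentLibrary:
    """Five templates per base-pair type and per single-nucleotide type."""

    entries: dict[str, list[Fragment]]

    def templates(self, key: str) -> list[Fragment]:
        if key not in self.entries:
            raise KeyError(f"fragment library has no templates for key {key!r}")
        return self.entries[key]

    def validate(self) -> None:
        for key, frags in self.entries.items():
            if len(frags) != 5:
                raise ValueError(f"key {key}: expected 5 templates, got {len(frags)}")
            for fr in frags:
                n_res = 2 if len(key) == 2 else 1
                if len(fr.anchors) != 3 * n_res:
                    raise ValueError(f"key {key}: bad anchor count")


# ---------------------------------------------------------------------------
# idealized geometry helpers
# ---------------------------------------------------------------------------

def _ring_atoms(base: str, n_pos: np.ndarray, b1: np.ndarray, b2: np.ndarray):
    """Planar idealized base ring in the (b1, b2) plane with N1/N9 at n_pos.

    Bond length 1.39 A; purines get a fused pentagon+hexagon, pyrimidines a
    hexagon; exocyclic atoms sit radially outward.  Synthetic idealized
    geometry, not a crystallographic base.
    """
    s = 1.39
    atoms: list[tuple[str, np.ndarray]] = []

    if base in "CT":
        center = n_pos + s * b1
        names = ["N1", "C2", "N3", "C4", "C5", "C6"]
        for k, nm in enumerate(names):
            atoms.append((nm, center + _rotate_in_plane(n_pos - center, b1, b2,
                                                        60.0 * k)))
        ring = dict(atoms)
        def outward(a):
            v = ring[a] - center
            return ring[a] + 1.25 * v / np.linalg.norm(v)
        atoms.append(("O2", outward("C2")))
        if base == "C":
            atoms.append(("N4", outward("C4")))
        else:
            atoms.append(("O4", outward("C4")))
            atoms.append(("C7", outward("C5")))
    else:
        # pentagon N9-C4-C5-N7-C8 with N9 at the glycosidic position
        r5 = s / (2.0 * np.sin(np.pi / 5.0))
        center5 = n_pos + r5 * b1
        pent_names = ["N9", "C4", "C5", "N7", "C8"]
        pent = {}
        for k, nm in enumerate(pent_names):
            pent[nm] = center5 + _rotate_in_plane(n_pos - center5, b1, b2,
                                                  72.0 * k)
        # hexagon fused across the C4-C5 edge, on the far side from center5
        mid = 0.5 * (pent["C4"] + pent["C5"])
        away = mid - center5
        away /= np.linalg.norm(away)
        center6 = mid + s * np.sqrt(3.0) / 2.0 * away
        hex_names = ["C4", "N3", "C2", "N1", "C6", "C5"]
        hexa = {}
        for k, nm in enumerate(hex_names):
            hexa[nm] = center6 + _rotate_in_plane(pent["C4"] - center6, b1, b2,
                                                  60.0 * k)
        ring = {**hexa, **pent}
        for nm in ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"]:
            atoms.append((nm, ring[nm]))
        def outward6(a):
            v = ring[a] - center6
            return ring[a] + 1.30 * v / np.linalg.norm(v)
        if base == "A":
            atoms.append(("N6", outward6("C6")))
        else:
            atoms.append(("O6", outward6("C6")))
            atoms.append(("N2", outward6("C2")))
    return atoms


def _rotate_in_plane(v: np.ndarray, b1: np.ndarray, b2: np.ndarray,
                     deg: float) -> np.ndarray:
    """Rotate v within the (b1, b2) plane by deg (its normal component is 0)."""
    x, y = np.dot(v, b1), np.dot(v, b2)
    a = np.deg2rad(deg)
    xr = x * np.cos(a) - y * np.sin(a)
    yr = x * np.sin(a) + y * np.cos(a)
    return xr * b1 + yr * b2


def _residue_atoms(p0, c4, n, p_next, base, axis_point):
    """Idealized all-atom content of one nucleotide in the CG frame."""
    e1 = c4 - p0
    L = np.linalg.norm(e1)
    e1 /= L
    perp = n - p0
    perp = perp - np.dot(perp, e1) * e1
    perp /= np.linalg.norm(perp)
    atoms = [("P", p0.copy()),
             ("O5'", p0 + 1.158 * e1 * (L / 3.645) + 1.09 * perp),
             ("C5'", p0 + 2.598 * e1 * (L / 3.645) + 1.09 * perp),
             ("C4'", c4.copy())]
    # sugar toward the base
    g1 = n - c4
    Lg = np.linalg.norm(g1)
    g1 /= Lg
    gp = p0 - c4
    gp = gp - np.dot(gp, g1) * g1
    gp /= np.linalg.norm(gp)
    atoms.append(("O4'", c4 + 1.05 * g1 + 0.98 * gp))
    atoms.append(("C1'", c4 + 2.168 * g1 * (Lg / 3.324) + 0.907 * gp))
    # 3' exit toward the next phosphate
    e3 = p_next - c4
    e3 /= np.linalg.norm(e3)
    e3p = n - c4
    e3p = e3p - np.dot(e3p, e3) * e3
    e3p /= np.linalg.norm(e3p)
    c3 = c4 + 1.20 * e3 + 0.95 * e3p
    atoms.append(("C3'", c3))
    to_c3 = c3 - p_next
    atoms.append(("O3'", p_next + 1.60 * to_c3 / np.linalg.norm(to_c3)))
    # base plane: perpendicular to the local helix axis (z of the template
    # frame); the ring extends from the glycosidic nitrogen away from the
    # sugar C1' (i.e. toward the pairing interface near the helix axis)
    c1 = atoms[5][1]
    zhat = np.array([0.0, 0.0, 1.0])
    b1 = -(c1 - n)
    b1 = b1 - np.dot(b1, zhat) * zhat
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(zhat, b1)
    atoms.extend(_ring_atoms(base, n, b1, b2))
    return atoms


def _tail_rotation(atoms, coords, c4_idx, n_idx, angle_deg, tail_names):
    """Rotate the 5' tail about the C4'-N axis (template variant generator)."""
    axis = coords[n_idx] - coords[c4_idx]
    axis /= np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)
    out = coords.copy()
    origin = coords[c4_idx]
    for idx, (nm, slot, _) in enumerate(atoms):
        if nm in tail_names:
            out[idx] = (coords[idx] - origin) @ rot.T + origin
    return out


_VARIANT_ANGLES = (0.0, -20.0, -10.0, 10.0, 20.0)
_TAIL = {"P", "O5'", "C5'"}


def _glyco_n(base: str) -> str:
    return "N9" if base in "AG" else "N1"


def _fragment_from_duplex(key: str) -> Fragment:
    """Base fragment (variant 0) for a key, cut from an ideal duplex context."""
    single = len(key) == 1
    b_i = key[0]
    seq_a = "A" + b_i + "AA"
    dup = ideal_helix(Sequence(seq_a), Sequence(reverse_complement(seq_a)))
    if not single:
        # rebuild the context so the partner base matches the requested key
        b_j = key[1]
        from .cg_model import _COMPLEMENT
        if _COMPLEMENT[b_i] != b_j:
            raise ValueError(f"non-WC pair key {key!r}")
    n_nt = 4
    i = 1                      # interior residue of strand A
    j = 2 * n_nt - 1 - i       # its partner on strand B
    res_slots = []
    res_slots.append((0, b_i, i, i + 1))
    if not single:
        res_slots.append((1, key[1], j, j + 1))
    atoms: list[tuple[str, int, str]] = []
    coords: list[np.ndarray] = []
    for slot, base, ridx, nextidx in res_slots:
        p0 = dup.bead(ridx, "P")
        c4 = dup.bead(ridx, "C")
        nn = dup.bead(ridx, "N")
        p_next = dup.bead(nextidx, "P")
        axis_point = np.array([0.0, 0.0, nn[2]])
        for nm, xyz in _residue_atoms(p0, c4, nn, p_next, base, axis_point):
            atoms.append((nm, slot, nm[0]))
            coords.append(xyz)
    coords = np.array(coords)
    # anchor order per residue slot: P, C4', glycosidic N
    anchors = []
    for slot, base, *_ in res_slots:
        for want in ("P", "C4'", _glyco_n(base)):
            for idx, (nm, sl, _) in enumerate(atoms):
                if sl == slot and nm == want:
                    anchors.append(idx)
                    break
    return Fragment(key=key, atoms=atoms, coords=coords, anchors=tuple(anchors))


def _make_variants(base_frag: Fragment) -> list[Fragment]:
    """Five templates per key, differing in the 5'-tail orientation.

    The tail (P, O5', C5') is tilted about an axis through C4' perpendicular
    to the P-C4'-N plane, which changes the P-C4'-N anchor angle (a sugar
    repuckering proxy): the anchor triangles of the variants are mutually
    incongruent, so minimal-anchor-RMSD template selection is well posed.
    """
    out = []
    slots = sorted({sl for _, sl, _ in base_frag.atoms})
    for ang in _VARIANT_ANGLES:
        coords = base_frag.coords.copy()
        for slot in slots:
            c4_idx = next(i for i, (nm, sl, _) in enumerate(base_frag.atoms)
                          if sl == slot and nm == "C4'")
            n_idx = next(i for i, (nm, sl, _) in enumerate(base_frag.atoms)
                         if sl == slot and nm in ("N1", "N9")
                         and _is_glyco(base_frag, i))
            p_idx = next(i for i, (nm, sl, _) in enumerate(base_frag.atoms)
                         if sl == slot and nm == "P")
            axis = np.cross(coords[p_idx] - coords[c4_idx],
                            coords[n_idx] - coords[c4_idx])
            idxs = [i for i, (nm, sl, _) in enumerate(base_frag.atoms)
                    if sl == slot and nm in _TAIL]
            coords = _rotate_subset(coords, idxs, coords[c4_idx], axis, ang)
        out.append(Fragment(base_frag.key, list(base_frag.atoms), coords,
                            base_frag.anchors))
    return out


def _is_glyco(frag: Fragment, idx: int) -> bool:
    return idx in frag.anchors


def _rotate_subset(coords, idxs, origin, axis, angle_deg):
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)
    out = coords.copy()
    out[idxs] = (coords[idxs] - origin) @ rot.T + origin
    return out


_DEFAULT_LIB: FragmentLibrary | None = None


def default_library() -> FragmentLibrary:
    """The bundled synthetic ideal-geometry fragment library (cached)."""
    global _DEFAULT_LIB
    if _DEFAULT_LIB is None:
        entries = {}
        for key in _NT_KEYS + _PAIR_KEYS:
            entries[key] = _make_variants(_fragment_from_duplex(key))
        lib = FragmentLibrary(entries)
        lib.validate()
        _DEFAULT_LIB = lib
    return _DEFAULT_LIB


# ---------------------------------------------------------------------------
# library construction from candidate fragments
# ---------------------------------------------------------------------------

def _fragment_rmsd(a: Fragment, b: Fragment) -> float:
    if len(a.atoms) != len(b.atoms):
        return np.inf
    return kabsch_superpose(a.coords, b.coords)[1]


def select_representatives(fragments: list[Fragment], k: int = 5,
                           redundancy_tol: float = 1e-3) -> list[Fragment]:
    """Pick up to *k* maximally diverse, non-redundant fragments.

    Greedy max-min selection on mutual all-atom RMSD; near-duplicates
    (RMSD < tol to an already-selected fragment) are skipped.  Fewer than
    *k* distinct candidates triggers a warning and returns all of them.
    """
    if not fragments:
        raise ValueError("no candidate fragments")
    chosen = [fragments[0]]
    while len(chosen) < k:
        best, best_d = None, -1.0
        for fr in fragments:
            d = min(_fragment_rmsd(fr, c) for c in chosen)
            if d > best_d:
                best, best_d = fr, d
        if best is None or best_d < redundancy_tol:
            warnings.warn(
                f"only {len(chosen)} non-redundant fragments available "
                f"(requested {k})", stacklevel=2)
            break
        chosen.append(best)
    return chosen


def build_library(candidates: dict[str, list[Fragment]],
                  k: int = 5) -> FragmentLibrary:
    """Cluster candidate fragments per key and keep k diverse representatives."""
    entries = {}
    for key, frags in candidates.items():
        if len(frags) < k:
            warnings.warn(f"key {key}: fewer than {k} candidates; keeping all",
                          stacklevel=2)
            entries[key] = list(frags)
        else:
            entries[key] = select_representatives(frags, k)
    return FragmentLibrary(entries)


def fragments_from_pdb(path) -> dict[str, list[Fragment]]:
    """Extract single-nucleotide candidate fragments from a DNA PDB file."""
    rev = {v: k for k, v in _RESNAME.items()}
    residues: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    resnames: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            resname = line[17:20].strip()
            if resname not in rev:
                continue
            key = (line[21], int(line[22:26]))
            name = line[12:16].strip()
            xyz = np.array([float(line[30:38]), float(line[38:46]),
                            float(line[46:54])])
            residues.setdefault(key, {})[name] = xyz
            resnames[key] = rev[resname]
    out: dict[str, list[Fragment]] = {}
    for key, amap in residues.items():
        base = resnames[key]
        need = ("P", "C4'", _glyco_n(base))
        if not all(nm in amap for nm in need):
            continue
        names = sorted(amap)
        coords = np.array([amap[nm] for nm in names])
        atoms = [(nm, 0, nm[0]) for nm in names]
        anchors = tuple(names.index(nm) for nm in need)
        out.setdefault(base, []).append(
            Fragment(key=base, atoms=atoms, coords=coords, anchors=anchors))
    return out


# ---------------------------------------------------------------------------
# rebuilding
# ---------------------------------------------------------------------------

@dataclass
class AllAtomStructure:
    """Rebuilt all-atom model with residue mapping back to CG indices."""

    sequence: Sequence
    atoms: list[tuple[str, str, int, str]]   # (name, resname, cg_index, element)
    coords: np.ndarray
    clash_residues: list[int] = field(default_factory=list)

    def n_atoms(self) -> int:
        return len(self.atoms)

    def min_interatomic_distance(self) -> float:
        d = np.linalg.norm(self.coords[:, None, :] - self.coords[None, :, :],
                           axis=-1)
        iu = np.triu_indices(len(self.coords), k=1)
        return float(d[iu].min())

    def to_pdb(self, path_or_handle) -> None:
        own = isinstance(path_or_handle, (str, bytes)) or hasattr(
            path_or_handle, "__fspath__")
        fh = open(path_or_handle, "w") if own else path_or_handle
        try:
            last = None
            for serial, ((nm, res, ri, el), xyz) in enumerate(
                    zip(self.atoms, self.coords), start=1):
                if last is not None and ri < last:
                    fh.write("TER\n")
                last = ri
                fh.write(
                    f"ATOM  {serial:5d} {nm:<4s} {res:>3s} A{ri + 1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}"
                    f"{0.0:6.2f}          {el:>2s}\n")
            fh.write("TER\nEND\n")
        finally:
            if own:
                fh.close()


def _anchor_targets(conf: CGConformation, residues: list[int]) -> np.ndarray:
    rows = []
    for r in residues:
        rows.extend(conf.coords[BEADS_PER_NT * r:BEADS_PER_NT * r + 3])
    return np.array(rows)


def _fit_fragment(frag: Fragment, target: np.ndarray):
    """Superpose the fragment's anchors onto target beads; returns
    (transformed all-atom coords, anchor RMSD)."""
    anchors = frag.anchor_coords()
    mc = anchors - anchors.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, sign]) @ u.T
    moved_anchors = mc @ rot.T + target.mean(axis=0)
    arms = float(np.sqrt(np.mean(np.sum((moved_anchors - target) ** 2, axis=1))))
    allc = (frag.coords - anchors.mean(axis=0)) @ rot.T + target.mean(axis=0)
    return allc, arms


def rebuild(conf: CGConformation, pairs: BasePairSet,
            lib: FragmentLibrary | None = None, *,
            clash_threshold: float = 1.0) -> AllAtomStructure:
    """Rebuild an all-atom structure from a CG conformation.

    Paired residues are rebuilt jointly from base-pair fragments, unpaired
    residues from single-nucleotide fragments; for each unit the library
    template minimizing the anchor RMSD is rigidly placed.  Residues whose
    atoms end closer than *clash_threshold* to atoms of other units are
    flagged in ``clash_residues`` (resolution is left to external
    refinement).
    """
    if lib is None:
        lib = default_library()
    units: list[tuple[str, list[int]]] = []
    partner = {}
    for i, j in pairs:
        partner[i] = j
    done: set[int] = set()
    for i in range(conf.n_nt):
        if i in done:
            continue
        if i in partner:
            j = partner[i]
            units.append((conf.sequence[i] + conf.sequence[j], [i, j]))
            done.update((i, j))
        else:
            units.append((conf.sequence[i], [i]))
            done.add(i)
    placed: dict[int, list[tuple[str, str, np.ndarray]]] = {}
    for key, residues in units:
        frags = lib.templates(key)
        target = _anchor_targets(conf, residues)
        best, best_rmsd, best_coords = None, np.inf, None
        for fr in frags:
            coords, arms = _fit_fragment(fr, target)
            if arms < best_rmsd:
                best, best_rmsd, best_coords = fr, arms, coords
        for (nm, slot, el), xyz in zip(best.atoms, best_coords):
            ri = residues[slot]
            placed.setdefault(ri, []).append(
                (nm, _RESNAME[conf.sequence[ri]], xyz))
    atoms: list[tuple[str, str, int, str]] = []
    coords: list[np.ndarray] = []
    owner: list[int] = []
    for ri in range(conf.n_nt):
        for nm, res, xyz in placed[ri]:
            atoms.append((nm, res, ri, nm[0]))
            coords.append(xyz)
            owner.append(ri)
    coords = np.array(coords)
    owner = np.array(owner)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    clash = (d < clash_threshold) & (owner[:, None] != owner[None, :])
    clash_res = sorted(set(owner[np.any(clash, axis=1)].tolist()))
    if clash_res:
        warnings.warn(f"steric clashes near residues {clash_res}; "
                      "external refinement recommended", stacklevel=2)
    return AllAtomStructure(sequence=conf.sequence, atoms=atoms, coords=coords,
                            clash_residues=list(clash_res))
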