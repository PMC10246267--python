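"""HOLE-style pore-radius profiling and constriction-residue identification.

At each axial slice the sphere center is optimized in-plane to maximize the
clearance ``min_i(|p - x_i| - r_i)`` (maximal inscribed sphere constrained
to the slice plane), warm-started from the previous slice with a ring of
extra starts.  Minima of the resulting radius profile locate pore
constrictions; residues whose atoms touch the inscribed sphere line them.

Residue numbering is always reported exactly as found in the input file.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, signal
from scipy.spatial import cKDTree

import biotite.sequence as bseq
import biotite.sequence.align as balign
import biotite.sequence.io.fasta as bfasta
import biotite.structure as bstruct
import biotite.structure.io.pdb as bpdb
import biotite.structure.io.pdbx as bpdbx

# Bondi van der Waals radii (A); overridable per call
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90, "B": 1.92,
}

# S6-region residue-number windows (author numbering) for the two channel
# structures analyzed; used only to tag residues with their domain.
DOMAIN_ANNOTATIONS = {
    "6A95": {"DI": (330, 470), "DII": (640, 790), "DIII": (1000, 1160),
             "DIV": (1310, 1450)},
    "7XVF": {"DI": (320, 450), "DII": (850, 1010), "DIII": (1340, 1500),
             "DIV": (1640, 1800)},
}


@dataclass
class Structure:
    """Heavy-atom coordinates with vdW radii and residue bookkeeping."""

    coords: np.ndarray            # (n, 3) A
    radii: np.ndarray             # (n,) A
    elements: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    atom_names: np.ndarray
    domains: dict = field(default_factory=dict)   # name -> (lo, hi) res id

    def __post_init__(self) -> None:
        if np.any(self.radii <= 0):
            raise ValueError("vdW radii must be > 0")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.radii)

    def domain_of(self, res_id: int) -> str | None:
        for name, (lo, hi) in self.domains.items():
            if lo <= res_id <= hi:
                return name
        return None

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation).T
        if translation is not None:
            coords = coords + np.asarray(translation)
        return Structure(coords, self.radii, self.elements, self.res_names,
                         self.res_ids, self.chain_ids, self.atom_names,
                         dict(self.domains))


@dataclass
class Minimum:
    z: float
    radius: float
    center: np.ndarray
    lining: list = field(default_factory=list)


@dataclass
class PoreProfile:
    """Axial coordinate vs maximal inscribed sphere radius."""

    z: np.ndarray                 # A, along the pore axis
    radius: np.ndarray            # A
    centers: np.ndarray           # (n, 3) A, original frame
    axis: np.ndarray
    minima: list = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        data = np.column_stack([self.z, self.radius])
        np.savetxt(path, data, fmt="%.4f", delimiter="\t",
                   header="z_A\tradius_A", comments="")


@dataclass
class ConstrictionReport:
    minima: list                  # all detected minima, sorted by z
    pairs: list                   # [(min_a, min_b)] flagged two-tier gates


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_structure(path: str | Path, radius_overrides: dict | None = None,
                   include_hetero: bool = False,
                   domains: dict | None = None) -> Structure:
    """Read a PDB/mmCIF file into a heavy-atom :class:`Structure`.

    Hydrogens, waters and (by default) hetero records are dropped.  Unknown
    elements raise unless a radius override is supplied.  For recognized
    accessions (file stem) the DI-DIV domain windows are annotated
    automatically.
    """
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif", ".pdbx"):
        cif = bpdbx.CIFFile.read(str(path))
        atoms = bpdbx.get_structure(cif, model=1)
    else:
        pdb = bpdb.PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)

    keep = atoms.element != "H"
    keep &= ~np.isin(atoms.res_name, ("HOH", "WAT", "DOD"))
    if not include_hetero:
        keep &= ~atoms.hetero
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise ValueError(f"no atoms left after filtering {path}")

    table = dict(BONDI_RADII)
    if radius_overrides:
        table.update({k.upper(): v for k, v in radius_overrides.items()})
    elements = np.char.upper(atoms.element.astype(str))
    unknown = sorted(set(elements) - set(table))
    if unknown:
        names = [f"{e}({n})" for e, n in
                 zip(elements, atoms.atom_name) if e in unknown][:10]
        raise ValueError(
            f"unknown element(s) {unknown} without radius override; "
            f"example atoms: {names}")
    radii = np.array([table[e] for e in elements])

    stem = path.stem.upper()
    auto_domains = DOMAIN_ANNOTATIONS.get(stem, {})
    return Structure(
        coords=np.asarray(atoms.coord, dtype=float),
        radii=radii,
        elements=elements,
        res_names=atoms.res_name.astype(str),
        res_ids=atoms.res_id.astype(int),
        chain_ids=atoms.chain_id.astype(str),
        atom_names=atoms.atom_name.astype(str),
        domains=domains if domains is not None else auto_domains,
    )


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------

def _axis_frame(axis) -> np.ndarray:
    """Rotation matrix whose last row is the unit pore axis."""
    w = np.asarray(axis, dtype=float)
    w = w / np.linalg.norm(w)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(w @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.vstack([u, v, w])


class _Clearance:
    """min over atoms of (center distance - vdW radius), via a KD-tree."""

    def __init__(self, coords: np.ndarray, radii: np.ndarray):
        self.tree = cKDTree(coords)
        self.radii = radii
        self.k = min(64, len(radii))

    def __call__(self, point: np.ndarray) -> float:
        d, idx = self.tree.query(point, k=self.k)
        return float(np.min(d - self.radii[idx]))


def _optimize_slice(clearance: _Clearance, z: float, start_xy: np.ndarray,
                    n_starts: int, ring_radius: float = 1.0):
    def neg(xy):
        return -clearance(np.array([xy[0], xy[1], z]))

    starts = [start_xy]
    n_ring = max(n_starts - 1, 0)
    for j in range(n_ring):
        angle = 2 * np.pi * j / max(n_ring, 1)
        starts.append(start_xy + ring_radius * np.array(
            [np.cos(angle), np.sin(angle)]))
    best_xy, best_r = None, -np.inf
    for s in starts:
        res = optimize.minimize(neg, s, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxiter": 400})
        if -res.fun > best_r:
            best_r, best_xy = -res.fun, res.x
    return best_xy, best_r


def trace_pore(structure: Structure, seed_point, axis=(0.0, 0.0, 1.0),
               step: float = 0.25, escape_radius: float = 10.0,
               n_starts: int = 16, max_shift: float = 2.0) -> PoreProfile:
    """Trace the maximal-inscribed-sphere radius along the pore.

    Starts at ``seed_point`` (must be inside the lumen) and marches in both
    axial directions until the radius exceeds ``escape_radius``.  A center
    jump larger than ``max_shift`` between adjacent slices is treated as a
    sideways escape and raises with the last good slice.
    """
    frame = _axis_frame(axis)
    rot = structure.transformed(rotation=frame)
    seed = frame @ np.asarray(seed_point, dtype=float)
    clearance = _Clearance(rot.coords, rot.radii)

    if clearance(seed) <= 0:
        raise ValueError(f"seed point {seed_point} lies inside an atom")

    def march(direction: int):
        rows = []
        xy = seed[:2].copy()
        z = seed[2] + (direction * step if direction != 0 else 0.0)
        prev_xy = xy
        while True:
            new_xy, r = _optimize_slice(clearance, z, prev_xy, n_starts)
            if np.linalg.norm(new_xy - prev_xy) > max_shift:
                raise RuntimeError(
                    f"pore trace escaped sideways at z={z:.2f} A "
                    f"(last good slice z={z - direction * step:.2f}, "
                    f"r={rows[-1][1]:.2f} A)" if rows else
                    f"pore trace escaped sideways at z={z:.2f} A")
            rows.append((z, r, new_xy[0], new_xy[1]))
            if r > escape_radius:
                break
            if direction == 0:
                break
            prev_xy = new_xy
            z += direction * step
        return rows

    center_row = march(0)
    up = march(+1)
    down = march(-1)
    rows = sorted(down + center_row + up, key=lambda r: r[0])
    z = np.array([r[0] for r in rows])
    radius = np.array([r[1] for r in rows])
    centers_rot = np.array([[r[2], r[3], r[0]] for r in rows])
    centers = centers_rot @ frame          # back to the original frame
    return PoreProfile(z=z, radius=radius, centers=centers,
                       axis=np.asarray(axis, dtype=float) / np.linalg.norm(axis))


def find_constrictions(profile: PoreProfile, prominence: float = 0.3,
                       max_separation: float = 8.0) -> ConstrictionReport:
    """Detect radius minima and flag two-tier pairs.

    Minima with the given prominence are kept; pairs of adjacent minima
    within ``max_separation`` along the axis (about one helical turn plus
    margin) are flagged as a two-tier gate.
    """
    if len(profile.z) < 20:
        raise ValueError("profile too short (< 20 slices)")
    idx, _ = signal.find_peaks(-profile.radius, prominence=prominence)
    minima = [Minimum(z=float(profile.z[i]), radius=float(profile.radius[i]),
                      center=profile.centers[i]) for i in idx]
    minima.sort(key=lambda m: m.z)
    pairs = []
    for a, b in zip(minima, minima[1:]):
        if b.z - a.z <= max_separation:
            pairs.append((a, b))
    profile.minima = minima
    return ConstrictionReport(minima=minima, pairs=pairs)


def lining_residues(structure: Structure, minimum: Minimum,
                    contact_margin: float = 1.5) -> list:
    """Residues whose atom surfaces lie within ``contact_margin`` of the sphere.

    Returns one entry per residue: (chain_id, res_id, res_name, domain),
    deduplicated, sorted by residue id.
    """
    d = np.linalg.norm(structure.coords - minimum.center, axis=1)
    gap = d - structure.radii - minimum.radius
    touch = gap <= contact_margin
    seen = {}
    for chain, rid, rname in zip(structure.chain_ids[touch],
                                 structure.res_ids[touch],
                                 structure.res_names[touch]):
        key = (str(chain), int(rid))
        if key not in seen:
            seen[key] = (str(chain), int(rid), str(rname),
                         structure.domain_of(int(rid)))
    return sorted(seen.values(), key=lambda r: (r[0], r[1]))


# ---------------------------------------------------------------------------
# cross-isoform residue mapping
# ---------------------------------------------------------------------------

def read_fasta_sequence(path: str | Path) -> str:
    fasta = bfasta.FastaFile.read(str(path))
    sequences = list(fasta.values())
    if not sequences:
        raise ValueError(f"no sequences in {path}")
    return str(sequences[0])


def map_residues(query_seq: str, ref_seq: str, ref_positions,
                 ref_start: int = 1, query_start: int = 1,
                 gap_open: int = 10, gap_extend: int = 1,
                 min_identity: float = 0.30):
    """Map reference residue positions onto a query via global alignment.

    Sequences are amino-acid strings (or FASTA-read results) of >= 15
    residues; positions use author numbering with ``ref_start``/
    ``query_start`` giving the number of each sequence's first residue.
    Returns ``(mapping, identity, warnings)`` where unmapped (gapped)
    positions map to ``None``.
    """
    query_seq = str(query_seq).upper()
    ref_seq = str(ref_seq).upper()
    if len(query_seq) < 15 or len(ref_seq) < 15:
        raise ValueError("sequences must be >= 15 residues")
    q = bseq.ProteinSequence(query_seq)
    r = bseq.ProteinSequence(ref_seq)
    matrix = balign.SubstitutionMatrix.std_protein_matrix()   # BLOSUM62
    alignment = balign.align_optimal(
        q, r, matrix, gap_penalty=(-abs(gap_open), -abs(gap_extend)),
        terminal_penalty=False)[0]
    identity = balign.get_sequence_identity(alignment)

    warn = []
    if identity < min_identity:
        warn.append(f"alignment identity {identity:.2f} below {min_identity:.2f}")
        _warnings.warn(warn[-1])

    trace = alignment.trace
    ref_col = {int(ref_idx): int(q_idx)
               for q_idx, ref_idx in trace if ref_idx != -1}
    mapping = {}
    for pos in ref_positions:
        ref_idx = pos - ref_start
        if ref_idx < 0 or ref_idx >= len(ref_seq):
            raise ValueError(f"reference position {pos} outside sequence")
        q_idx = ref_col.get(ref_idx, -1)
        mapping[pos] = (q_idx + query_start) if q_idx >= 0 else None
    return mapping, float(identity), warn
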