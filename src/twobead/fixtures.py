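"""Deterministic synthetic structures for testing and demonstration.

These fixtures replace downloaded PDB structures: an ideal helix (Calpha
trace with the 1-3 distance at the equilibrium helix spacing), an ideal
sheet (constant backbone torsion at the equilibrium beta value), a random
coil, a two-helix "fold" with a designed hydrophobic core, and a toy
helix + peptide complex with a hydrophobic interface patch. Side-chain
beads are placed by the package's own threading, so every fixture is a
fully valid :class:`~twobead.structure.CoarseStructure`. An all-atom PDB
emitter produces files whose coarse-graining round-trips the fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3

from ._geometry import place_from_internal
from .params import ParameterSet, default_params
from .sidechain import ThreadingConfig, thread
from .structure import CoarseStructure, neighbor_exposure

KINDS = ("ideal_helix", "ideal_sheet", "coil", "two_domain_fold", "toy_complex")

# small hydrophobics for designed cores (bulky side chains cannot always
# escape steric clashes with a single azimuthal degree of freedom)
_HYDROPHOBIC_CYCLE = "AVIALV"
_POLAR_CYCLE = "ESNDTQKSTE"
_DEFAULT_CYCLE = "ALEKIVDSTM"
_RESIDUE_VOLUME = 190.0  # A^3 per residue, confinement of the globule walk
_WALK_CLASH = 5.2        # A, minimum Calpha-Calpha distance in the walk


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n_residues: int = 20
    sequence: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unsupported fixture kind {self.kind!r}; one of {KINDS}")
        if self.n_residues < 5:
            raise ValueError("fixtures need at least 5 residues")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")


def _default_sequence(n: int) -> str:
    return (_DEFAULT_CYCLE * (n // len(_DEFAULT_CYCLE) + 1))[:n]


def _helix_trace(n: int, params: ParameterSet, reverse: bool = False) -> np.ndarray:
    """Calpha helix with pitch solved so r_{i,i+2} equals the equilibrium
    helix distance r_h (radius 2.3 A, 100 deg per residue)."""
    radius, step = 2.3, np.radians(100.0)
    chord = 2.0 * radius * np.sin(step)  # in-plane part of the 1-3 distance
    rh = params.constants.r_h
    rise = np.sqrt(max(rh**2 - chord**2, 1e-9)) / 2.0
    i = np.arange(n)
    z = i * rise * (-1 if reverse else 1)
    ang = i * step
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), z])


def _sheet_trace(n: int) -> np.ndarray:
    """Chain with constant bend angle and backbone torsion of 210 deg."""
    bond, ang, tors = 3.8, 2.2, np.radians(210.0)
    pts = [np.zeros(3), np.array([bond, 0.0, 0.0])]
    pts.append(pts[1] + bond * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0]))
    for _ in range(3, n):
        pts.append(place_from_internal(pts[-3], pts[-2], pts[-1], bond, ang, tors))
    return np.array(pts)


def _coil_trace(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    bond = 3.8
    pts = [np.zeros(3), np.array([bond, 0.0, 0.0]),
           np.array([bond + bond * np.cos(2.0), bond * np.sin(2.0), 0.0])]
    while len(pts) < n:
        for _ in range(80):
            ang = rng.uniform(1.6, 2.6)
            tors = rng.uniform(-np.pi, np.pi)
            cand = place_from_internal(pts[-3], pts[-2], pts[-1], bond, ang, tors)
            d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)
            if np.all(d > 4.0):
                break
        pts.append(cand)
    return np.array(pts)


def _globule_trace(
    n: int,
    seed: int,
    start: np.ndarray,
    center: np.ndarray,
    radius: float,
    obstacles: np.ndarray | None = None,
) -> np.ndarray:
    """Self-avoiding walk confined to a sphere: a compact domain.

    ``obstacles`` are fixed points (e.g. an already-built sibling domain)
    the walk must also avoid. When no admissible continuation is found the
    least-clashing candidate is taken (repaired later by the generator's
    rejection loop)."""
    rng = np.random.default_rng(seed)
    start = np.asarray(start, dtype=float)
    center = np.asarray(center, dtype=float)
    bond = 3.8
    pts = [start, start + np.array([bond, 0.0, 0.0])]
    pts.append(pts[1] + bond * np.array([np.cos(np.pi - 2.0), np.sin(np.pi - 2.0), 0.0]))
    while len(pts) < n:
        best, fallback, fb_score = None, None, -np.inf
        avoid = np.array(pts[:-1])
        if obstacles is not None and len(obstacles):
            avoid = np.vstack([avoid, obstacles])
        for _ in range(400):
            ang = rng.uniform(1.6, 2.6)
            tors = rng.uniform(-np.pi, np.pi)
            cand = place_from_internal(pts[-3], pts[-2], pts[-1], bond, ang, tors)
            mind = float(np.linalg.norm(avoid - cand, axis=1).min())
            inside = np.linalg.norm(cand - center) < radius
            score = mind - (0.0 if inside else 100.0)
            if score > fb_score:
                fb_score, fallback = score, cand
            if mind > _WALK_CLASH and inside:
                best = cand
                break
        pts.append(best if best is not None else fallback)
    return np.array(pts)


def _design_sequence(ca: np.ndarray, params: ParameterSet) -> str:
    """Hydrophobic letters at the most occluded positions, polar elsewhere."""
    exposure = neighbor_exposure(ca, params)
    cut = np.median(exposure)
    seq, nh, npol = [], 0, 0
    for e in exposure:
        if e < cut:
            seq.append(_HYDROPHOBIC_CYCLE[nh % len(_HYDROPHOBIC_CYCLE)]); nh += 1
        else:
            seq.append(_POLAR_CYCLE[npol % len(_POLAR_CYCLE)]); npol += 1
    return "".join(seq)


def _finish(spec: FixtureSpec, ca: np.ndarray, params: ParameterSet,
            sequence: str | None = None) -> CoarseStructure:
    seq = sequence or spec.sequence or _default_sequence(len(ca))
    trace = CoarseStructure(  # bare Calpha trace (poly-Gly placeholder sequence)
        sequence="G" * len(ca), ca=ca, cb=np.full_like(ca, np.nan),
        radii=np.full(len(ca), np.nan), provenance=f"synthetic:{spec.kind}",
    )
    cfg = ThreadingConfig(n_steps=30, seed=spec.seed)
    out = thread(seq, trace, cfg, params)
    out.provenance = f"synthetic:{spec.kind}"
    return out


def make_fixture(spec: FixtureSpec, params: ParameterSet | None = None):
    """Build the coarse structure (or structure pair, for ``toy_complex``)."""
    params = params or default_params()
    n = spec.n_residues
    if spec.kind == "ideal_helix":
        return _finish(spec, _helix_trace(n, params), params)
    if spec.kind == "ideal_sheet":
        return _finish(spec, _sheet_trace(n), params)
    if spec.kind == "coil":
        return _finish(spec, _coil_trace(n, spec.seed), params)
    if spec.kind == "two_domain_fold":
        return _make_two_domain(spec, params)
    if spec.kind == "toy_complex":
        return make_toy_complex(spec, params)
    raise ValueError(f"unsupported fixture kind {spec.kind!r}")


def _two_domain_trace(n: int, seed: int) -> np.ndarray:
    """Two touching compact sub-globules joined in sequence."""
    na = n // 2
    nb = n - na
    r = lambda m: (3.0 * _RESIDUE_VOLUME * m / (4.0 * np.pi)) ** (1.0 / 3.0)
    ra, rb = r(na), r(nb)
    a = _globule_trace(na, seed, np.zeros(3), np.array([ra * 0.5, 0.0, 0.0]), ra)
    join = a[-1] + np.array([3.8, 0.0, 0.0])
    b = _globule_trace(nb, seed + 1, join,
                       join + np.array([rb * 0.6, 0.0, 0.0]), rb,
                       obstacles=a[:-1])
    return np.vstack([a, b])


def _make_two_domain(spec: FixtureSpec, params: ParameterSet) -> CoarseStructure:
    """Compact two-lobed fold with a designed hydrophobic core.

    The walk occasionally produces side-chain packings no azimuth can
    repair, so conformations are rejection-sampled deterministically
    (sub-seeds derived from spec.seed) until the designed sequence threads
    without steric strain and the fold has a non-trivial contact map and
    some genuinely buried residues.
    """
    from .physics import v_lj
    from .structure import contact_map as _cmap

    n = spec.n_residues
    for attempt in range(60):
        sub = spec.seed + 1000 * attempt
        ca = _two_domain_trace(n, sub)
        # forced walk fallbacks can leave backbone-level clashes; filter on
        # the minimum non-neighbour Calpha-Calpha distance before threading
        d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
        iu, ju = np.triu_indices(n, k=2)
        if d[iu, ju].min() < 4.5:
            continue
        seq = spec.sequence or _design_sequence(ca, params)
        built = _finish(spec, ca, params, sequence=seq)
        buried = (neighbor_exposure(built.interaction_centers, params)
                  < params.constants.burial_sasa).sum()
        if (v_lj(built, params) < 0.0
                and _cmap(built).n_contacts >= max(6, n // 5)
                and buried >= 2):
            return built
    raise RuntimeError(f"no admissible two-domain conformation found for seed {spec.seed}")


def make_toy_complex(
    spec: FixtureSpec, params: ParameterSet | None = None
) -> tuple[CoarseStructure, CoarseStructure]:
    """Helix receptor plus an 11-residue extended peptide lying against it,
    with hydrophobic residues facing the interface on both sides."""
    params = params or default_params()
    n = spec.n_residues
    rec_ca = _helix_trace(n, params)
    rec_seq = spec.sequence or _design_receptor_sequence(rec_ca)
    receptor = _finish(FixtureSpec("ideal_helix", n, rec_seq, spec.seed),
                       rec_ca, params, sequence=rec_seq)

    m = 11
    zmid = rec_ca[:, 2].mean()
    pep_ca = np.column_stack([
        np.full(m, 7.2),
        np.zeros(m),
        zmid + (np.arange(m) - (m - 1) / 2.0) * 3.5,
    ])
    pep_seq = "SSILVIVLISS"  # hydrophobic patch in the middle
    bvec = params.bond_lengths(pep_seq)  # side chains face the receptor
    pep_cb = pep_ca + np.column_stack([-bvec, np.zeros(m), np.zeros(m)])
    peptide = CoarseStructure(
        sequence=pep_seq, ca=pep_ca, cb=pep_cb,
        radii=params.radii(pep_seq), provenance="synthetic:toy_complex_peptide",
    )
    return receptor, peptide


def _design_receptor_sequence(ca: np.ndarray) -> str:
    """Hydrophobic letters on the helix face pointing toward +x (the
    peptide side), polar letters elsewhere."""
    seq, nh, npol = [], 0, 0
    for xyz in ca:
        if xyz[0] > 1.2:  # azimuth near the interface
            seq.append(_HYDROPHOBIC_CYCLE[nh % len(_HYDROPHOBIC_CYCLE)]); nh += 1
        else:
            seq.append(_POLAR_CYCLE[npol % len(_POLAR_CYCLE)]); npol += 1
    return "".join(seq)


def dock_peptide(
    fold: CoarseStructure,
    sequence: str = "SSILVIVLISS",
    params: ParameterSet | None = None,
) -> CoarseStructure:
    """Place an extended peptide against a fold's surface, deterministically.

    The peptide runs parallel to the fold's longest principal axis, offset
    along its thinnest axis, side chains facing the fold; the offset is the
    largest one giving at least three inter-molecular contacts without
    steric strain (scanned inward in 0.25 A steps).
    """
    from .physics import _inter_lj
    from .structure import inter_contact_map

    params = params or default_params()
    centers = fold.interaction_centers
    mid = centers.mean(axis=0)
    _, _, vt = np.linalg.svd(centers - mid)
    w, u = vt[0], vt[2]              # longest / thinnest directions
    m = len(sequence)
    b = params.bond_lengths(sequence)
    span = (np.arange(m) - (m - 1) / 2.0) * 3.5
    for direction in (u, -u, vt[1], -vt[1]):
        extent = float(((centers - mid) @ direction).max())
        for d in np.arange(extent + 8.0, extent, -0.25):
            ca = mid + d * direction + span[:, None] * w
            cb = ca - b[:, None] * direction
            pep = CoarseStructure(sequence, ca, cb, params.radii(sequence),
                                  provenance="synthetic:docked_peptide")
            if (inter_contact_map(fold, pep).n_contacts >= 3
                    and _inter_lj(fold, pep, params) < 0.0):
                return pep
    raise RuntimeError("could not dock the peptide without steric strain")


# ------------------------- all-atom emission --------------------------
def make_all_atom_fixture(spec: FixtureSpec, params: ParameterSet | None = None) -> str:
    """Minimal single-chain PDB text whose coarse-graining reproduces the
    fixture: CA at the Calpha bead, and two pseudo side-chain atoms (CB, CG)
    placed so that centroid(CA, CB, CG) is the Cbeta bead centre."""
    params = params or default_params()
    if spec.kind == "toy_complex":
        raise ValueError("all-atom emission covers single-chain fixtures only")
    cs = make_fixture(spec, params)
    return coarse_to_pdb(cs)


def coarse_to_pdb(cs: CoarseStructure, chain_id: str = "A", start_serial: int = 1) -> str:
    """Render a coarse structure as synthetic all-atom-like PDB text."""
    lines = []
    serial = start_serial
    delta = np.array([0.0, 0.0, 0.5])
    for i, aa in enumerate(cs.sequence):
        res3 = protein_letters_1to3[aa].upper()
        ca = cs.ca[i]
        atoms = [("N", ca + np.array([-0.8, 1.1, 0.0])),
                 ("CA", ca),
                 ("C", ca + np.array([1.2, 0.7, 0.0])),
                 ("O", ca + np.array([1.4, 1.9, 0.0]))]
        if aa != "G":
            target = cs.cb[i]
            mid = (3.0 * target - ca) / 2.0
            atoms += [("CB", mid + delta), ("CG", mid - delta)]
        for name, xyz in atoms:
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res3:>3s} {chain_id}{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
                f"{name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(cs: CoarseStructure, path: str | Path, chain_id: str = "A") -> None:
    Path(path).write_text(coarse_to_pdb(cs, chain_id))
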