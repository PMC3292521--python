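"""The two-bead coarse-grained representation.

Each residue carries a backbone bead (Calpha, radius 1.8 A, centred on the
Calpha atom) and, for every residue but glycine, a side-chain bead (Cbeta)
centred on the centroid of the side-chain atoms including Calpha, with a
residue-dependent radius. Derived geometry follows the standard conventions
of this representation: ``theta_i`` is the Calpha(i-1)-Calpha(i)-Cbeta(i)
bend angle (defined for i >= 2, non-glycine), and ``phi_i`` is the backbone
torsion over Calpha(i-1..i+2) (defined for 2 <= i <= N-2, 1-based).

Solvent exposure is approximated by a neighbour-vector scheme: the resultant
of distance-weighted unit vectors from a residue's side-chain bead to the
surrounding beads, whose magnitude maps linearly to an exposure fraction in
[0, 1] (an isotropically surrounded bead has a vanishing resultant, an
unobstructed one a maximal resultant).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa, protein_letters_3to1

from ._geometry import angle, dihedral
from .params import ParameterSet, default_params

# common nonstandard -> parent mappings accepted during ingestion
_NONSTANDARD = {"MSE": "M", "SEC": "C", "PYL": "K", "HSD": "H", "HSE": "H"}
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
CHAIN_BREAK_DISTANCE = 4.5  # A, Calpha-Calpha


@dataclass
class CoarseStructure:
    """An ordered chain of two-bead residues.

    ``cb`` rows and ``radii`` entries are NaN for glycine (no side-chain
    bead). ``theta``/``phi`` are NaN where undefined.
    """

    sequence: str
    ca: np.ndarray               # (N, 3)
    cb: np.ndarray               # (N, 3), NaN rows for Gly
    radii: np.ndarray            # (N,), NaN for Gly
    provenance: str = "synthetic"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.cb = np.asarray(self.cb, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        n = len(self.sequence)
        if self.ca.shape != (n, 3) or self.cb.shape != (n, 3):
            raise ValueError("coordinate arrays must be (N, 3) with N = |sequence|")
        if not np.all(np.isfinite(self.ca)):
            raise ValueError("non-finite Calpha coordinates")
        has = self.has_cb
        if not np.all(np.isfinite(self.cb[has])):
            raise ValueError("non-finite Cbeta coordinates")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def has_cb(self) -> np.ndarray:
        return np.array([a != "G" for a in self.sequence], dtype=bool)

    @property
    def interaction_centers(self) -> np.ndarray:
        """Cbeta centres with Calpha substituted for glycine."""
        out = self.cb.copy()
        gly = ~self.has_cb
        out[gly] = self.ca[gly]
        return out

    @property
    def theta(self) -> np.ndarray:
        """Bend angles Calpha(i-1)-Calpha(i)-Cbeta(i), NaN where undefined."""
        th = np.full(self.n, np.nan)
        has = self.has_cb
        for i in range(1, self.n):
            if has[i]:
                th[i] = angle(self.ca[i - 1], self.ca[i], self.cb[i])
        return th

    @property
    def phi(self) -> np.ndarray:
        """Backbone torsions over Calpha(i-1..i+2), radians, NaN where undefined."""
        ph = np.full(self.n, np.nan)
        for i in range(1, self.n - 2):
            ph[i] = dihedral(self.ca[i - 1], self.ca[i], self.ca[i + 1], self.ca[i + 2])
        return ph

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CoarseStructure":
        """Rigid-body copy: x -> R x + t."""
        cb = np.where(self.has_cb[:, None], self.cb @ rotation.T + translation, np.nan)
        return CoarseStructure(
            sequence=self.sequence,
            ca=self.ca @ rotation.T + translation,
            cb=cb,
            radii=self.radii.copy(),
            provenance=self.provenance,
            warnings=list(self.warnings),
        )

    # tabular round trip ------------------------------------------------
    def to_table(self, path: str | Path | None = None) -> str:
        rows = []
        for i, aa in enumerate(self.sequence):
            cb = self.cb[i] if self.has_cb[i] else (np.nan, np.nan, np.nan)
            rows.append(
                {
                    "index": i + 1, "aa": aa,
                    "ca_x": self.ca[i, 0], "ca_y": self.ca[i, 1], "ca_z": self.ca[i, 2],
                    "cb_x": cb[0], "cb_y": cb[1], "cb_z": cb[2],
                    "radius": self.radii[i],
                }
            )
        df = pd.DataFrame(rows)
        text = df.to_csv(sep="\t", index=False, float_format="%.9f", na_rep="NA")
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_table(cls, source: str | Path, provenance: str = "table") -> "CoarseStructure":
        if isinstance(source, Path) or "\t" not in str(source):
            source = Path(source).read_text()
        df = pd.read_csv(io.StringIO(source), sep="\t", na_values=["NA"])
        seq = "".join(df["aa"])
        ca = df[["ca_x", "ca_y", "ca_z"]].to_numpy()
        cb = df[["cb_x", "cb_y", "cb_z"]].to_numpy()
        return cls(seq, ca, cb, df["radius"].to_numpy(), provenance=provenance)


# ----------------------------------------------------------------------
@dataclass
class ContactMap:
    """Boolean residue-residue contact map.

    Square (intra-molecular, with a minimum sequence separation) or
    rectangular (inter-molecular, no separation filter: ``min_sep`` None).
    """

    contacts: np.ndarray
    cutoff: float
    min_sep: int | None = None

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=bool)

    @property
    def n(self) -> int:
        return self.contacts.shape[0]

    @property
    def n_contacts(self) -> int:
        if self.min_sep is None:
            return int(self.contacts.sum())
        return int(np.triu(self.contacts).sum())

    def pairs(self) -> np.ndarray:
        """Contacting index pairs; upper-triangle only for square maps."""
        if self.min_sep is None:
            return np.argwhere(self.contacts)
        return np.argwhere(np.triu(self.contacts))


def contact_map(structure: CoarseStructure, cutoff: float = 4.5, min_sep: int = 4) -> ContactMap:
    """Intra-molecular contacts: Cbeta-Cbeta (Calpha for Gly) distance below
    ``cutoff`` and primary-sequence separation strictly greater than ``min_sep``."""
    centers = structure.interaction_centers
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    idx = np.arange(structure.n)
    sep_ok = np.abs(idx[:, None] - idx[None, :]) > min_sep
    return ContactMap(contacts=(d < cutoff) & sep_ok, cutoff=cutoff, min_sep=min_sep)


def inter_contact_map(a: CoarseStructure, b: CoarseStructure, cutoff: float = 4.5) -> ContactMap:
    """Rectangular inter-molecular contact map (no separation filter)."""
    ca_ = a.interaction_centers
    cb_ = b.interaction_centers
    d = np.linalg.norm(ca_[:, None, :] - cb_[None, :, :], axis=-1)
    return ContactMap(contacts=d < cutoff, cutoff=cutoff, min_sep=None)


# ----------------------------------------------------------------------
def neighbor_exposure(points: np.ndarray, params: ParameterSet | None = None) -> np.ndarray:
    """Neighbour-vector exposure of each point against all the others.

    Each neighbour within ``neighbor_cutoff`` contributes a unit vector from
    the focal point, weighted 1 inside ``neighbor_inner`` and ramping
    linearly to 0 at the cutoff; the normalised resultant magnitude is
    mapped linearly onto [0, 1]. A symmetric but *sparse* neighbourhood
    (e.g. an extended chain, where the two chain directions cancel) must
    not read as buried, so the burial implied by a small resultant is
    damped by the neighbour weight sum relative to
    ``neighbor_count_ref``: exposure = 1 - (1 - NV) * min(1, W/W_ref).
    """
    params = params or default_params()
    c = params.constants
    points = np.asarray(points, dtype=float)
    n = len(points)
    out = np.ones(n)
    for i in range(n):
        vec = points - points[i]
        dist = np.linalg.norm(vec, axis=1)
        mask = (dist > 0) & (dist < c.neighbor_cutoff)
        if not mask.any():
            warnings.warn(f"bead {i} has no neighbours within {c.neighbor_cutoff} A; "
                          "treated as fully exposed")
            continue
        d = dist[mask]
        w = np.clip((c.neighbor_cutoff - d) / (c.neighbor_cutoff - c.neighbor_inner), 0.0, 1.0)
        units = vec[mask] / d[:, None]
        resultant = np.linalg.norm((w[:, None] * units).sum(axis=0)) / w.sum()
        nv = np.clip((resultant - c.sasa_lo) / (c.sasa_hi - c.sasa_lo), 0.0, 1.0)
        density = min(1.0, w.sum() / c.neighbor_count_ref)
        out[i] = 1.0 - (1.0 - nv) * density
    return out


def sasa_fraction(structure: CoarseStructure, params: ParameterSet | None = None) -> np.ndarray:
    """Per-residue solvent-exposure fraction in [0, 1]."""
    if structure.n < 1:
        raise ValueError("empty structure")
    return neighbor_exposure(structure.interaction_centers, params)


def sasa_fraction_complex(
    a: CoarseStructure, b: CoarseStructure, params: ParameterSet | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exposure fractions of both molecules evaluated in the complex frame."""
    pts = np.vstack([a.interaction_centers, b.interaction_centers])
    frac = neighbor_exposure(pts, params)
    return frac[: a.n], frac[a.n:]


# ----------------------------------------------------------------------
def coarse_grain(
    source: str | Path,
    chain: str | None = None,
    params: ParameterSet | None = None,
) -> CoarseStructure:
    """Reduce a single-chain all-atom PDB file to the two-bead representation.

    Reads the first model, one chain (the first, unless ``chain`` is given),
    altloc 'A' when alternates exist. Nonstandard residues are mapped to
    their parents where known and rejected otherwise. A missing Calpha is an
    error; Calpha-Calpha gaps above 4.5 A are recorded as chain-break
    warnings in the structure's provenance.
    """
    params = params or default_params()
    parser = PDBParser(QUIET=True)
    struct = parser.get_structure("x", str(source))
    model = next(iter(struct))
    if chain is None:
        ch = next(iter(model))
    else:
        ch = model[chain]

    seq, ca_list, cb_list, radii, warns = [], [], [], [], []
    index = 0
    for res in ch:
        if res.id[0] != " " and res.get_resname() not in _NONSTANDARD:
            continue  # waters / het groups
        name = res.get_resname()
        if name in _NONSTANDARD:
            aa = _NONSTANDARD[name]
        elif is_aa(res, standard=True):
            aa = protein_letters_3to1[name]
        else:
            raise ValueError(f"unmappable nonstandard residue {name} at position {index + 1}")
        index += 1
        atoms = {}
        for atom in res.get_atoms():
            a = atom
            if atom.is_disordered():
                try:
                    a = atom.disordered_get("A")
                except KeyError:
                    a = atom.disordered_get_list()[0]
            atoms[a.get_name()] = a.get_coord().astype(float)
        if "CA" not in atoms:
            raise ValueError(f"residue {index} ({name}) is missing its Calpha atom")
        ca = atoms["CA"]
        seq.append(aa)
        ca_list.append(ca)
        if aa == "G":
            cb_list.append(np.full(3, np.nan))
            radii.append(np.nan)
        else:
            side = [xyz for nm, xyz in atoms.items()
                    if nm not in _BACKBONE_ATOMS and not nm.startswith("H")]
            pts = np.array([ca] + side)  # centroid includes the Calpha atom
            if len(side) == 0:
                warns.append(f"residue {index} ({aa}) has no side-chain atoms; "
                             "Cbeta placed at Calpha")
            cb_list.append(pts.mean(axis=0))
            radii.append(params[aa].r)

    ca_arr = np.array(ca_list)
    gaps = np.linalg.norm(np.diff(ca_arr, axis=0), axis=1)
    for i, g in enumerate(gaps):
        if g > CHAIN_BREAK_DISTANCE:
            warns.append(f"chain break between residues {i + 1} and {i + 2} "
                         f"(Calpha-Calpha {g:.2f} A)")
    tag = f"{Path(str(source)).stem}:{ch.id}"
    return CoarseStructure(
        sequence="".join(seq),
        ca=ca_arr,
        cb=np.array(cb_list),
        radii=np.array(radii),
        provenance=tag,
        warnings=warns,
    )
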