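"""Residue-level parameter tables and model constants.

All per-residue inputs of the two-bead model live in a single versioned TSV
(:data:`DEFAULT_PARAM_FILE`): bead geometry (Calpha--Cbeta bond length ``b``,
bead radius ``r``, equilibrium bend angle ``theta0``), the shifted
Kyte--Doolittle hydropathy parameter ``h`` (which doubles as the like-pair
Lennard-Jones well depth), helix and beta force constants, and formal charge.
The polarity index is derived, not stored: ``p = (h_max - h_min) - h``.

Tables are loadable by name (shipped file) or by path, so every scale can be
swapped without touching code.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CA_RADIUS = 1.8  # Angstrom, backbone bead

DEFAULT_PARAM_FILE = "residue_params.tsv"
DEFAULT_CONTACT_FILE = "contact_energies_synthetic.tsv"


@dataclass(frozen=True)
class ResidueParams:
    """Parameters of one residue type.

    ``b`` and ``r`` are ``None`` for glycine, which has no side-chain bead.
    ``p`` is the polarity index, ``(h_max - h_min) - h`` over the whole table.
    """

    type: str
    b: float | None
    r: float | None
    theta0: float
    h: float
    p: float
    helix_prop: float
    beta_prop: float
    charge: int


@dataclass(frozen=True)
class PhysicsConstants:
    """Constants of the physics-based potential (all overridable)."""

    k_theta: float = 10.0        # kJ/mol/rad^2, bend force constant
    r_h: float = 5.5             # A, equilibrium helix inter-bead distance
    c_b: float = 0.01            # beta-term scaling constant
    phi_b: float = 210.0         # degrees, equilibrium beta torsion
    c_c: float = 1000.0          # ionic-term scaling constant
    dielectric: float = 3.0      # protein-interior dielectric
    burial_sasa: float = 0.25    # SASA fraction below which a residue is buried
    r_ss: float = 4.5            # A, max Cbeta-Cbeta distance of a disulfide
    eps_ca: float = 1.0          # LJ well depth of the backbone bead
    # NeighborVector adaptation (the two-bead mapping is a declared approximation)
    neighbor_cutoff: float = 10.0   # A, neighbour sphere
    neighbor_inner: float = 3.3     # A, full-weight distance
    sasa_lo: float = 0.0            # resultant magnitude mapped to exposure 0
    sasa_hi: float = 1.0            # resultant magnitude mapped to exposure 1
    neighbor_count_ref: float = 6.0  # weight sum at which burial saturates
    # (the typical neighbour weight sum at the interior of a compact domain
    # at one interaction centre per residue, ~190 A^3/residue)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("twobead") / "data" / name)


def load_param_table(source: str | Path = DEFAULT_PARAM_FILE) -> dict[str, ResidueParams]:
    """Load a residue parameter table by shipped name or filesystem path."""
    path = Path(source)
    if not path.exists():
        path = _data_path(str(source))
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    df = df.set_index("aa")
    missing = set(AMINO_ACIDS) - set(df.index)
    if missing:
        raise ValueError(f"parameter table {path} lacks residues: {sorted(missing)}")
    h = df["h"].astype(float)
    span = float(h.max() - h.min())
    table = {}
    for aa, row in df.iterrows():
        b = None if pd.isna(row["b"]) else float(row["b"])
        r = None if pd.isna(row["r"]) else float(row["r"])
        table[aa] = ResidueParams(
            type=aa,
            b=b,
            r=r,
            theta0=float(row["theta0"]),
            h=float(row["h"]),
            p=span - float(row["h"]),
            helix_prop=float(row["helix_k"]),
            beta_prop=float(row["beta_k"]),
            charge=int(row["q"]),
        )
    return table


def load_contact_matrix(source: str | Path = DEFAULT_CONTACT_FILE) -> "ContactMatrix":
    """Load a 20x20 contact-energy matrix (whitespace-separated, labelled)."""
    path = Path(source)
    if not path.exists():
        path = _data_path(str(source))
    df = pd.read_csv(path, sep=r"\s+", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)].astype(float)
    return ContactMatrix(u=df, source=str(path.name))


@dataclass
class ContactMatrix:
    """Symmetric 20x20 residue-pair contact energies ``U_ab``."""

    u: pd.DataFrame
    source: str = "unnamed"
    _arr: np.ndarray = field(init=False, repr=False)
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        arr = self.u.to_numpy(dtype=float)
        if arr.shape != (20, 20):
            raise ValueError("contact matrix must be 20x20")
        if not np.allclose(arr, arr.T):
            raise ValueError("contact matrix must be symmetric")
        if not np.all(np.isfinite(arr)):
            raise ValueError("contact matrix must be finite")
        self._arr = arr
        self._index = {aa: i for i, aa in enumerate(self.u.index)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        try:
            return float(self._arr[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"unknown residue letter {exc}") from None

    def encode(self, sequence: str) -> np.ndarray:
        """Integer-encode ``sequence`` against the matrix alphabet."""
        try:
            return np.array([self._index[a] for a in sequence], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown residue letter {exc}") from None

    @property
    def array(self) -> np.ndarray:
        return self._arr


class ParameterSet:
    """Bundle of residue table + physics constants used throughout the package."""

    def __init__(
        self,
        residues: dict[str, ResidueParams] | None = None,
        constants: PhysicsConstants | None = None,
    ) -> None:
        self.residues = residues if residues is not None else load_param_table()
        self.constants = constants if constants is not None else PhysicsConstants()

    def __getitem__(self, aa: str) -> ResidueParams:
        try:
            return self.residues[aa]
        except KeyError:
            raise KeyError(f"unknown residue letter {aa!r}") from None

    def with_constants(self, **kwargs) -> "ParameterSet":
        return ParameterSet(self.residues, replace(self.constants, **kwargs))

    # vectorised per-sequence lookups --------------------------------------
    def radii(self, sequence: str) -> np.ndarray:
        """Cbeta radii; glycine positions get NaN (no side-chain bead)."""
        return np.array(
            [self[a].r if self[a].r is not None else np.nan for a in sequence]
        )

    def bond_lengths(self, sequence: str) -> np.ndarray:
        return np.array(
            [self[a].b if self[a].b is not None else np.nan for a in sequence]
        )

    def theta0(self, sequence: str) -> np.ndarray:
        return np.array([self[a].theta0 for a in sequence])

    def hydropathy(self, sequence: str) -> np.ndarray:
        return np.array([self[a].h for a in sequence])

    def polarity(self, sequence: str) -> np.ndarray:
        return np.array([self[a].p for a in sequence])

    def helix_prop(self, sequence: str) -> np.ndarray:
        return np.array([self[a].helix_prop for a in sequence])

    def beta_prop(self, sequence: str) -> np.ndarray:
        return np.array([self[a].beta_prop for a in sequence])

    def charges(self, sequence: str) -> np.ndarray:
        return np.array([self[a].charge for a in sequence], dtype=float)


_DEFAULT: ParameterSet | None = None


def default_params() -> ParameterSet:
    """Process-wide default :class:`ParameterSet` (lazily loaded)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ParameterSet()
    return _DEFAULT
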