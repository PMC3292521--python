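"""Fold and binding specificity against alternative states.

The specificity of a sequence for its native state is measured as a
Z-score against a distribution G of alternative-state scores,

    Z_fold = (<G> - G_nat) / sigma(G),     S_gap = <G> - G_nat,

where the location <G> is the median and the dispersal sigma(G) the
difference between the median and the first quartile — robust estimators,
because threading random sequences or shuffling geometry produces heavily
right-skewed score distributions (steric clashes) in which only the
low-score tail matters. During sequence evolution the dispersal is frozen
at its starting value, so S_gap is proportional to Z_fold.

Alternative states follow the random-energy-model construction: geometry
decoys independently permute each class of structural measurement of the
native state (physics model), contact decoys redraw the contact map with
the native contact count (informational model), and random sequences are
drawn uniformly over the 20 amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .informational import score_bind_info, score_fold_info
from .params import AMINO_ACIDS, ContactMatrix, ParameterSet, default_params
from .physics import (
    PERMUTABLE,
    Measurements,
    WeightVector,
    bind_terms,
    extract_measurements,
    fold_terms,
    total_bind,
    total_fold,
)
from .structure import ContactMap, CoarseStructure, contact_map, inter_contact_map


# ----------------------------------------------------------------------
class ScoreDistribution:
    """A set of alternative-state scores with robust location/dispersal.

    Quartiles use linear interpolation (type 7), the convention the
    resulting Z values depend on.
    """

    def __init__(self, values) -> None:
        self.set_values(values)

    def set_values(self, values) -> None:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError("a score distribution needs at least 2 values")
        self.values = v
        self.location = float(np.quantile(v, 0.5, method="linear"))
        self.dispersal = float(self.location - np.quantile(v, 0.25, method="linear"))

    @property
    def n(self) -> int:
        return self.values.size


def z_fold(g_nat: float, g: ScoreDistribution) -> float:
    """(location - native) / dispersal; higher = more specific."""
    if g.dispersal == 0:
        raise ValueError("zero dispersal: Z-score undefined")
    return (g.location - g_nat) / g.dispersal


def s_gap(g_nat: float, g: ScoreDistribution) -> float:
    """The un-normalised score gap, location - native."""
    return g.location - g_nat


def z_bind(g_nat_bind: float, g_bind: ScoreDistribution) -> float:
    """Binding Z-score against random partner sequences; same estimator."""
    return z_fold(g_nat_bind, g_bind)


# ------------------------------- decoys -------------------------------
@dataclass(frozen=True)
class GeometryDecoy:
    """One random-energy-model decoy: a reproducible permutation of every
    measurement class, regenerated deterministically from its seed for
    whatever class lengths the scored bundle has (sequences with different
    glycine content change bead counts)."""

    seed: int

    def apply(self, m: Measurements) -> Measurements:
        perms = {}
        for idx, name in enumerate(PERMUTABLE):
            arr = getattr(m, name)
            if name in ("theta", "phi"):
                length = int(np.isfinite(arr).sum())
            else:
                length = len(arr)
            if length <= 1:
                continue
            rng = np.random.default_rng([self.seed, idx, length])
            perms[name] = rng.permutation(length)
        return m.permuted(perms)


@dataclass
class DecoySet:
    kind: str                    # geometry_shuffle | contact_shuffle | random_sequence
    members: list
    seed: int


def _member_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n)


def make_geometry_decoys(structure: CoarseStructure | Measurements, n: int,
                         seed: int) -> DecoySet:
    """n permutation decoys of the native structure's measurements."""
    if n < 1:
        raise ValueError("n must be >= 1")
    members = [GeometryDecoy(int(s)) for s in _member_seeds(seed, n)]
    return DecoySet(kind="geometry_shuffle", members=members, seed=seed)


def make_contact_decoys(cmap: ContactMap, n: int, seed: int) -> DecoySet:
    """n contact maps with the native contact count, pairs redrawn uniformly
    among those exceeding the sequence-separation rule."""
    if cmap.min_sep is None:
        raise ValueError("contact decoys need an intra-molecular map")
    nres = cmap.n
    iu, ju = np.triu_indices(nres, k=cmap.min_sep + 1)
    admissible = np.column_stack([iu, ju])
    k = cmap.n_contacts
    members = []
    for s in _member_seeds(seed, n):
        rng = np.random.default_rng(int(s))
        chosen = admissible[rng.choice(len(admissible), size=k, replace=False)]
        mat = np.zeros((nres, nres), dtype=bool)
        mat[chosen[:, 0], chosen[:, 1]] = True
        mat |= mat.T
        members.append(ContactMap(contacts=mat, cutoff=cmap.cutoff, min_sep=cmap.min_sep))
    return DecoySet(kind="contact_shuffle", members=members, seed=seed)


def make_random_sequences(n_len: int, count: int, seed: int) -> list[str]:
    """count i.i.d. uniform sequences of length n_len over the 20 letters."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    return ["".join(row) for row in letters[rng.integers(0, 20, size=(count, n_len))]]


# ---------------------------- gap scorers -----------------------------
class GapScorer:
    """S_gap / Z_fold evaluator with a fixed decoy reference and frozen
    dispersal, as used during sequence sampling and evolution.

    ``model`` is ``"physics"`` (geometry decoys, weighted seven-term score)
    or ``"info"`` (contact decoys, contact potential). For the informational
    model the native conformation's contact map is reused for every
    candidate sequence by default (the score depends on the conformation
    only through its map); ``rethread=True`` re-threads and rebuilds it.
    """

    def __init__(
        self,
        conformation: CoarseStructure,
        model: str = "physics",
        weights: WeightVector | None = None,
        u: ContactMatrix | None = None,
        n_decoys: int = 100,
        seed: int = 0,
        params: ParameterSet | None = None,
        thread_config=None,
        rethread: bool = False,
    ) -> None:
        if model not in ("physics", "info"):
            raise ValueError("model must be 'physics' or 'info'")
        self.model = model
        self.conformation = conformation
        self.params = params or default_params()
        self.thread_config = thread_config
        self.rethread = rethread
        if model == "physics":
            if weights is None:
                raise ValueError("physics model needs a WeightVector")
            self.weights = weights
            self.decoys = make_geometry_decoys(conformation, n_decoys, seed)
        else:
            from .params import load_contact_matrix
            self.u = u if u is not None else load_contact_matrix()
            self.native_cmap = contact_map(conformation)
            self.decoys = make_contact_decoys(self.native_cmap, n_decoys, seed)
            # cache decoy pair lists for fast re-scoring
            self._decoy_pairs = [d.pairs() for d in self.decoys.members]
        g0 = ScoreDistribution(self._decoy_scores(conformation.sequence))
        self.frozen_dispersal = g0.dispersal

    # -- internals ------------------------------------------------------
    def _threaded(self, sequence: str) -> CoarseStructure:
        if sequence == self.conformation.sequence:
            return self.conformation
        from .sidechain import thread
        return thread(sequence, self.conformation, self.thread_config, self.params)

    def _decoy_scores(self, sequence: str,
                      structure: CoarseStructure | None = None) -> np.ndarray:
        if self.model == "physics":
            structure = structure if structure is not None else self._threaded(sequence)
            m = extract_measurements(structure, self.params)
            w = self.weights
            return np.array([
                total_fold(fold_terms(d.apply(m), self.params), w)
                for d in self.decoys.members
            ])
        code = self.u.encode(sequence)
        arr = self.u.array
        return np.array([
            arr[code[p[:, 0]], code[p[:, 1]]].sum() if len(p) else 0.0
            for p in self._decoy_pairs
        ])

    # -- public ---------------------------------------------------------
    def g_nat(self, sequence: str,
              structure: CoarseStructure | None = None) -> float:
        if self.model == "physics":
            structure = structure if structure is not None else self._threaded(sequence)
            tv = fold_terms(structure, self.params)
            return total_fold(tv, self.weights)
        if self.rethread:
            cmap = contact_map(self._threaded(sequence))
        else:
            cmap = self.native_cmap
        return score_fold_info(sequence, cmap, self.u)

    def s_gap(self, sequence: str,
              structure: CoarseStructure | None = None) -> float:
        if self.model == "physics" and structure is None:
            structure = self._threaded(sequence)
        g = ScoreDistribution(self._decoy_scores(sequence, structure))
        return g.location - self.g_nat(sequence, structure)

    def z_fold(self, sequence: str) -> float:
        if self.frozen_dispersal == 0:
            raise ValueError("zero frozen dispersal: Z undefined")
        return self.s_gap(sequence) / self.frozen_dispersal

    def threaded(self, sequence: str) -> CoarseStructure:
        """The sequence threaded onto the scorer's conformation."""
        return self._threaded(sequence)


class BindScorer:
    """Binding score of the (protein, ligand) complex for varied sequences,
    with the two conformations held fixed in the complex frame."""

    def __init__(
        self,
        protein: CoarseStructure,
        ligand: CoarseStructure,
        model: str = "physics",
        weights: WeightVector | None = None,
        u: ContactMatrix | None = None,
        params: ParameterSet | None = None,
        thread_config=None,
    ) -> None:
        if model not in ("physics", "info"):
            raise ValueError("model must be 'physics' or 'info'")
        self.model = model
        self.protein = protein
        self.ligand = ligand
        self.params = params or default_params()
        self.thread_config = thread_config
        if model == "physics":
            if weights is None:
                raise ValueError("physics model needs a WeightVector")
            self.weights = weights
        else:
            from .params import load_contact_matrix
            self.u = u if u is not None else load_contact_matrix()
            self.inter_cmap = inter_contact_map(protein, ligand)

    def score(self, protein_seq: str | None = None, ligand_seq: str | None = None,
              ligand_conformation: CoarseStructure | None = None,
              protein_structure: CoarseStructure | None = None) -> float:
        """Lower = stronger predicted binding. Changed sequences are threaded
        through their fixed conformations (physics) or rescored on the fixed
        inter-molecular contact map (informational). A caller that has
        already threaded the protein may pass ``protein_structure``."""
        pseq = protein_seq or self.protein.sequence
        lseq = ligand_seq or self.ligand.sequence
        lig = ligand_conformation or self.ligand
        if self.model == "info":
            return score_bind_info(pseq, lseq, self.inter_cmap, self.u)
        from .sidechain import thread
        if protein_structure is not None:
            prot = protein_structure
        elif pseq == self.protein.sequence:
            prot = self.protein
        else:
            prot = thread(pseq, self.protein, self.thread_config, self.params)
        lg = lig if lseq == lig.sequence else thread(lseq, lig, self.thread_config, self.params)
        tv = bind_terms(prot, lg, self.params)
        return total_bind(tv, self.weights)
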