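"""Per-protein weight selection by Metropolis-Hastings MCMC.

The weights of the physics-based score are chosen to maximise the fold
(or binding) specificity Z against a cached table of alternative-state
term scores: 1000 geometry decoys of the native structure (G_struct) and
1000 random sequences threaded through the native conformation (G_seq),
plus the native state itself. Because the table caches raw per-term
scores, evaluating Z for a candidate weight vector is a reweighting (one
matrix-vector product), not a rescoring.

Before optimisation each term column is affinely rescaled so all term
distributions span an equal range (the native row is included in the
min/max and mapped by the same transform). The chain accepts uphill moves
always and downhill moves with probability exp(dZ / T); proposals are
positive-mean Gaussian perturbations as printed (a biased random walk —
reproduced faithfully, with a mean-zero switch), and proposals leaving
the open box (0,1)^d are rejected outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterSet, default_params
from .physics import (
    BIND_TERMS,
    FOLD_TERMS,
    WeightVector,
    bind_terms,
    extract_measurements,
    fold_terms,
)
from .specificity import make_geometry_decoys, make_random_sequences
from .structure import CoarseStructure


@dataclass
class ReferenceTable:
    """Cached per-state term scores. Row 0 is the native state; the rest are
    alternatives. ``sign`` carries each term's sign in the total (the
    solvation-change term enters the binding score negatively)."""

    table: np.ndarray                 # (1 + n_alt, d)
    terms: tuple[str, ...]
    sign: np.ndarray
    n_struct: int = 0
    n_seq: int = 0

    @property
    def native(self) -> np.ndarray:
        return self.table[0]

    @property
    def alternatives(self) -> np.ndarray:
        return self.table[1:]


def z_from_table(table: ReferenceTable, weights: WeightVector | np.ndarray) -> float:
    """Specificity Z of a weight vector against the cached states, using the
    robust (median, median-minus-first-quartile) estimators."""
    w = weights.as_array(table.terms) if isinstance(weights, WeightVector) else np.asarray(weights)
    totals = table.table @ (w * table.sign)
    nat, alt = totals[0], totals[1:]
    loc = float(np.quantile(alt, 0.5, method="linear"))
    disp = loc - float(np.quantile(alt, 0.25, method="linear"))
    gap = loc - nat
    if disp == 0.0:
        return 0.0 if gap == 0.0 else float(np.copysign(np.inf, gap))
    return gap / disp


def build_reference_scores(
    native: CoarseStructure,
    n_struct: int = 1000,
    n_seq: int = 1000,
    seed: int = 0,
    params: ParameterSet | None = None,
    thread_config=None,
) -> ReferenceTable:
    """Fold-specificity reference: native + geometry decoys + threaded
    random sequences, as raw seven-term score rows."""
    from .sidechain import thread

    params = params or default_params()
    rows = [fold_terms(native, params).as_array(FOLD_TERMS)]
    if n_struct > 0:
        m = extract_measurements(native, params)
        for d in make_geometry_decoys(native, n_struct, seed).members:
            rows.append(fold_terms(d.apply(m), params).as_array(FOLD_TERMS))
    for s in make_random_sequences(native.n, n_seq, seed + 1):
        threaded = thread(s, native, thread_config, params)
        rows.append(fold_terms(threaded, params).as_array(FOLD_TERMS))
    return ReferenceTable(
        table=np.array(rows), terms=FOLD_TERMS, sign=np.ones(len(FOLD_TERMS)),
        n_struct=n_struct, n_seq=n_seq,
    )


def build_binding_reference_scores(
    protein: CoarseStructure,
    ligand: CoarseStructure,
    n_seq: int = 1000,
    seed: int = 0,
    params: ParameterSet | None = None,
    thread_config=None,
    vary: str = "ligand",
) -> ReferenceTable:
    """Binding reference: native complex + random sequences threaded through
    one partner's fixed conformation (the other partner fully constant)."""
    from .sidechain import thread

    params = params or default_params()
    if vary not in ("ligand", "protein"):
        raise ValueError("vary must be 'ligand' or 'protein'")
    rows = [bind_terms(protein, ligand, params).as_array(BIND_TERMS)]
    varied = ligand if vary == "ligand" else protein
    for s in make_random_sequences(varied.n, n_seq, seed):
        t = thread(s, varied, thread_config, params)
        pair = (protein, t) if vary == "ligand" else (t, ligand)
        rows.append(bind_terms(*pair, params).as_array(BIND_TERMS))
    sign = np.array([1.0, 1.0, -1.0])  # blj, bion, -bdsolv
    return ReferenceTable(table=np.array(rows), terms=BIND_TERMS, sign=sign,
                          n_struct=0, n_seq=n_seq)


def rescale_terms(table: ReferenceTable) -> ReferenceTable:
    """Affinely map every term column onto [0, 1] over all states (native
    included), so the term-specific score ranges are equal. Zero-range
    columns are left untouched with a warning. Idempotent."""
    t = table.table.astype(float).copy()
    for k in range(t.shape[1]):
        lo, hi = t[:, k].min(), t[:, k].max()
        if hi == lo:
            warnings.warn(f"term {table.terms[k]!r} has zero range; left unrescaled")
            continue
        t[:, k] = (t[:, k] - lo) / (hi - lo)
    return ReferenceTable(table=t, terms=table.terms, sign=table.sign.copy(),
                          n_struct=table.n_struct, n_seq=table.n_seq)


# ------------------------------- MCMC ---------------------------------
def accept_move(delta_z: float, t: float, rng: np.random.Generator) -> bool:
    """Metropolis rule on Z: uphill always, downhill with exp(dZ/T)."""
    if delta_z > 0:
        return True
    return bool(rng.random() < np.exp(delta_z / t))


@dataclass
class WeightChain:
    """Trajectory of a weight-optimisation chain and its best state."""

    terms: tuple[str, ...]
    weights: np.ndarray            # (n_kept, d) states after each attempted move
    z: np.ndarray                  # (n_kept,)
    t: float
    n_attempted: int
    seed: int
    best_weights: WeightVector = field(init=False)
    best_z: float = field(init=False)

    def __post_init__(self) -> None:
        k = int(np.argmax(self.z))
        self.best_z = float(self.z[k])
        self.best_weights = WeightVector(dict(zip(self.terms, self.weights[k])))

    def summary(self) -> pd.DataFrame:
        rows = [{"term": t, "best_weight": self.best_weights[t]} for t in self.terms]
        df = pd.DataFrame(rows)
        df.attrs["best_z"] = self.best_z
        df.attrs["n_attempted"] = self.n_attempted
        df.attrs["temperature"] = self.t
        return df


def optimize_weights(
    table: ReferenceTable,
    t: float = 0.1,
    n_moves: int = 100_000,
    proposal_mean: float = 0.1,
    proposal_var: float = 0.1,
    seed: int = 0,
    init: float | np.ndarray = 0.5,
) -> WeightChain:
    """Metropolis-Hastings walk over the open box (0,1)^d maximising Z.

    The state after every attempted move is recorded (rejections repeat the
    previous state), and the largest-Z state is retained as the result.
    """
    rng = np.random.default_rng(seed)
    d = len(table.terms)
    theta = np.full(d, float(init)) if np.isscalar(init) else np.asarray(init, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= 1):
        raise ValueError("initial weights must lie in the open interval (0,1)")
    z = z_from_table(table, theta)
    sd = np.sqrt(proposal_var)

    traj_w = np.empty((n_moves + 1, d))
    traj_z = np.empty(n_moves + 1)
    traj_w[0], traj_z[0] = theta, z
    for k in range(1, n_moves + 1):
        prop = theta + rng.normal(proposal_mean, sd, size=d)
        if np.all((prop > 0.0) & (prop < 1.0)):
            z_new = z_from_table(table, prop)
            if accept_move(z_new - z, t, rng):
                theta, z = prop, z_new
        # out-of-bounds proposals are rejected outright but count as attempted
        traj_w[k], traj_z[k] = theta, z
    return WeightChain(terms=table.terms, weights=traj_w, z=traj_z,
                       t=t, n_attempted=n_moves, seed=seed)


def optimize_binding_weights(
    protein: CoarseStructure,
    ligand: CoarseStructure,
    n_seq: int = 1000,
    t: float = 0.1,
    n_moves: int = 100_000,
    seed: int = 0,
    params: ParameterSet | None = None,
    thread_config=None,
    rescale: bool = True,
    **mcmc_kwargs,
) -> WeightChain:
    """Choose binding-term weights maximising Z_bind over random partner
    sequences (sequence specificity in one binding partner)."""
    table = build_binding_reference_scores(
        protein, ligand, n_seq=n_seq, seed=seed, params=params,
        thread_config=thread_config,
    )
    if rescale:
        table = rescale_terms(table)
    return optimize_weights(table, t=t, n_moves=n_moves, seed=seed + 1, **mcmc_kwargs)
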