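"""Side-chain bead placement: thread a sequence onto a fixed backbone.

Given a Calpha trace and a target sequence, each non-glycine residue's
Cbeta bead is placed at the tabulated bond length and equilibrium bend
angle, leaving a single free degree of freedom per residue — the azimuth
about the local backbone axis. The azimuths are refined by Metropolis MCMC
against the pairwise Lennard-Jones energy of the placed beads, with the
backbone held rigid throughout. The lowest-energy configuration seen is
tracked and a closing greedy grid sweep escapes residual local minima, so
the result is never worse than the initialised placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import orthonormal_frame
from .params import CA_RADIUS, ParameterSet, default_params
from .structure import CoarseStructure


@dataclass
class ThreadingConfig:
    n_steps: int = 50        # MCMC sweeps over the chain
    t_thread: float = 0.1    # acceptance temperature, LJ units
    sigma: float = 0.3       # rad, Gaussian azimuth proposal width
    seed: int = 0
    final_grid: int = 60     # azimuth grid of the closing greedy sweep (0 = off)

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.t_thread <= 0:
            raise ValueError("t_thread must be positive")


def _axis(ca: np.ndarray, i: int) -> np.ndarray:
    """Reference backbone axis for residue i: towards the preceding Calpha
    (mirrored at the N terminus)."""
    if i > 0:
        return ca[i - 1] - ca[i]
    return ca[i] - ca[i + 1]


def thread(
    sequence: str,
    conformation: CoarseStructure,
    config: ThreadingConfig | None = None,
    params: ParameterSet | None = None,
) -> CoarseStructure:
    """Thread ``sequence`` onto the backbone of ``conformation``.

    The returned structure has bitwise-identical Calpha coordinates and
    freshly placed Cbeta beads; deterministic given ``config.seed``.
    """
    config = config or ThreadingConfig()
    params = params or default_params()
    if len(sequence) != conformation.n:
        raise ValueError(
            f"sequence length {len(sequence)} != conformation length {conformation.n}"
        )
    ca = conformation.ca.copy()
    n = len(sequence)
    radii = params.radii(sequence)
    has_cb = np.array([a != "G" for a in sequence], dtype=bool)
    movable = np.flatnonzero(has_cb)

    cb = np.full((n, 3), np.nan)
    if movable.size == 0:
        return CoarseStructure(sequence, ca, cb, radii,
                               provenance=f"threaded:{conformation.provenance}")

    rng = np.random.default_rng(config.seed)
    b = params.bond_lengths(sequence)
    th0 = params.theta0(sequence)
    eps_cb = params.hydropathy(sequence)

    # local frames and azimuth placement, one per movable residue
    frames = {}
    for i in movable:
        a, e2, e3 = orthonormal_frame(_axis(ca, i))
        frames[i] = (np.cos(th0[i]) * a, np.sin(th0[i]) * e2, np.sin(th0[i]) * e3)

    def place(i: int, psi_vals: np.ndarray) -> np.ndarray:
        """Cbeta positions of residue i for an array of azimuths, (K, 3)."""
        fa, f2, f3 = frames[i]
        psi_vals = np.atleast_1d(psi_vals)
        d = fa[None, :] + np.cos(psi_vals)[:, None] * f2 + np.sin(psi_vals)[:, None] * f3
        return ca[i] + b[i] * d

    # flat bead table: rows 0..n-1 are Calpha, then one row per movable Cbeta
    m = movable.size
    cb_row = {int(i): n + k for k, i in enumerate(movable)}
    beads = np.empty((n + m, 3))
    beads[:n] = ca
    bead_rad = np.concatenate([np.full(n, CA_RADIUS), radii[movable]])
    bead_eps = np.concatenate([np.full(n, params.constants.eps_ca), eps_cb[movable]])

    # per-residue interaction vectors (exclude own Calpha and own Cbeta)
    masks, sigs, epss = {}, {}, {}
    for i in movable:
        mask = np.ones(n + m, dtype=bool)
        mask[i] = False
        mask[cb_row[i]] = False
        masks[i] = mask
        sigs[i] = radii[i] + bead_rad[mask]
        epss[i] = 4.0 * np.sqrt(eps_cb[i] * bead_eps[mask])

    def energies(i: int, positions: np.ndarray) -> np.ndarray:
        """LJ energy of residue i's Cbeta at each candidate position."""
        others = beads[masks[i]]
        d = np.linalg.norm(positions[:, None, :] - others[None, :, :], axis=-1)
        if np.any(d == 0):
            raise ValueError("coincident beads in Lennard-Jones evaluation")
        sr6 = (sigs[i] / d) ** 6
        return (epss[i] * (sr6 * sr6 - sr6)).sum(axis=1)

    # initial azimuth: point the side chain away from the local chain axis
    # (the centroid of a +/-4-residue backbone window)
    psi = np.zeros(n)
    for i in movable:
        a, e2, e3 = orthonormal_frame(_axis(ca, i))
        lo, hi = max(0, i - 4), min(n, i + 5)
        out = ca[i] - ca[lo:hi].mean(axis=0)
        y, z = np.dot(out, e2), np.dot(out, e3)
        psi[i] = np.arctan2(z, y) if (abs(y) > 1e-12 or abs(z) > 1e-12) else 0.0
        cb[i] = place(i, psi[i])[0]
        beads[cb_row[i]] = cb[i]

    # energy tracked relative to the initial placement: only *changes*
    # drive acceptance and best-state bookkeeping
    total = 0.0
    best_total = 0.0
    best_cb = cb.copy()

    for _ in range(config.n_steps):
        for i in rng.permutation(movable):
            psi_new = psi[i] + rng.normal(0.0, config.sigma)
            pair = energies(i, np.vstack([cb[i], place(i, psi_new)[0]]))
            delta = float(pair[1] - pair[0])
            if delta <= 0 or rng.random() < np.exp(-delta / config.t_thread):
                psi[i] = psi_new
                cb[i] = place(i, psi_new)[0]
                beads[cb_row[i]] = cb[i]
                total += delta
                if total < best_total:
                    best_total = total
                    best_cb = cb.copy()

    # restore the best state seen by the Metropolis walk
    cb = best_cb.copy()
    for i in movable:
        beads[cb_row[i]] = cb[i]

    if config.final_grid:
        # closing greedy sweeps: per residue, take the best azimuth on a
        # fixed grid if it beats the current placement (escapes local
        # minima; deterministic)
        grid = np.linspace(0.0, 2.0 * np.pi, config.final_grid, endpoint=False)
        for _ in range(2):
            improved = False
            for i in movable:
                cand = np.vstack([cb[i], place(i, grid)])
                e = energies(i, cand)
                k = int(np.argmin(e))
                if k > 0 and e[k] < e[0] - 1e-12:
                    cb[i] = cand[k]
                    beads[cb_row[i]] = cb[i]
                    improved = True
            if not improved:
                break

    return CoarseStructure(sequence, ca, cb, radii,
                           provenance=f"threaded:{conformation.provenance}")
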