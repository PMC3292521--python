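"""Sequence-space exploration of the fold-score landscape.

Sequences are sampled by Metropolis MCMC on the fold score gap S_gap: a
proposal substitutes a single residue, uphill moves are always accepted
and downhill moves with probability exp(dS_gap / T). High temperatures
(info 10, physics 50) give nearly score-independent sampling; low
temperatures (info 0.1, physics 1.5) walk into local optima where most
substitutions are destabilising. Chain divergence from the start sequence
can be capped as a fraction of differing positions.

Also here: Sammon projection of sampled sequences into two dimensions and
per-position Shannon information content of a sample (sequence-logo
numbers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .params import AMINO_ACIDS
from .specificity import GapScorer
from .structure import CoarseStructure

DEFAULT_TEMPERATURES = {  # (high, low) sampling temperatures per scorer
    "info": (10.0, 0.1),
    "physics": (50.0, 1.5),
}


@dataclass
class SamplerConfig:
    scorer: str = "physics"              # physics | info
    t: float = 1.5
    max_divergence: float | None = None  # fraction of positions, or None
    n_steps: int = 1000
    seed: int = 0
    thin: tuple[int, int] = (4, 100)     # (stride over unique samples, keep_last)
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("temperature must be positive")
        if self.thin[0] < 1:
            raise ValueError("thinning stride must be >= 1")


@dataclass
class SampleResult:
    samples: list[tuple[str, float]]   # unique accepted states, first occurrence
    acceptance_rate: float
    n_steps: int
    seed: int
    occupancy: dict[str, int] | None = None   # per-state visit counts, if recorded

    def sequences(self) -> list[str]:
        return [s for s, _ in self.samples]


def _as_scorer(gap_scorer, conformation, config, **scorer_kwargs):
    if gap_scorer is None:
        if conformation is None:
            raise ValueError("either a gap scorer or a conformation is required")
        gap_scorer = GapScorer(conformation, model=config.scorer, **scorer_kwargs)
    if hasattr(gap_scorer, "s_gap"):
        return gap_scorer.s_gap
    return gap_scorer


def sample_sequences(
    start_seq: str,
    conformation: CoarseStructure | None,
    config: SamplerConfig,
    gap_scorer=None,
    record_occupancy: bool = False,
    **scorer_kwargs,
) -> SampleResult:
    """Metropolis chain over single-residue substitutions, scored by S_gap.

    ``gap_scorer`` may be a :class:`~twobead.specificity.GapScorer` or any
    callable ``sequence -> S_gap``; by default one is built from the
    conformation. Proposals pushing the divergence from the start sequence
    above ``max_divergence`` are rejected. Returns the unique accepted
    states (start included) with their scores, in order of first visit.
    """
    score = _as_scorer(gap_scorer, conformation, config, **scorer_kwargs)
    rng = np.random.default_rng(config.seed)
    n = len(start_seq)
    letters = config.alphabet

    current = list(start_seq)
    s_cur = score(start_seq)
    seen: dict[str, float] = {start_seq: s_cur}
    order = [start_seq]
    divergence = 0
    accepted = 0
    occupancy: dict[str, int] | None = {} if record_occupancy else None

    for _ in range(config.n_steps):
        if occupancy is not None:
            cur = "".join(current)
            occupancy[cur] = occupancy.get(cur, 0) + 1
        i = int(rng.integers(n))
        old = current[i]
        choices = [a for a in letters if a != old]
        new = choices[int(rng.integers(len(choices)))]
        was_native = current[i] == start_seq[i]
        d_new = divergence + (1 if was_native and new != start_seq[i] else 0) \
            - (1 if not was_native and new == start_seq[i] else 0)
        if config.max_divergence is not None and d_new / n > config.max_divergence:
            continue
        current[i] = new
        cand = "".join(current)
        s_new = seen.get(cand)
        if s_new is None:
            s_new = score(cand)
        delta = s_new - s_cur
        if delta > 0 or rng.random() < np.exp(delta / config.t):
            s_cur = s_new
            divergence = d_new
            accepted += 1
            if cand not in seen:
                seen[cand] = s_new
                order.append(cand)
        else:
            current[i] = old
    return SampleResult(
        samples=[(s, seen[s]) for s in order],
        acceptance_rate=accepted / config.n_steps if config.n_steps else 0.0,
        n_steps=config.n_steps,
        seed=config.seed,
        occupancy=occupancy,
    )


def find_stable_optima(
    start_seq: str,
    conformation: CoarseStructure | None,
    config: SamplerConfig,
    n_chains: int = 10,
    gap_scorer=None,
    **scorer_kwargs,
) -> list[tuple[str, float]]:
    """Pool replicate low-temperature chains without divergence caps, thinned
    to every ``stride``-th unique sample with the final ``keep_last`` kept
    per chain (10 chains x 100 kept = 1000 stable-optimum sequences)."""
    stride, keep_last = config.thin
    pooled: list[tuple[str, float]] = []
    for c in range(n_chains):
        cfg = SamplerConfig(
            scorer=config.scorer, t=config.t, max_divergence=None,
            n_steps=config.n_steps, seed=config.seed + c, thin=config.thin,
            alphabet=config.alphabet,
        )
        res = sample_sequences(start_seq, conformation, cfg, gap_scorer, **scorer_kwargs)
        thinned = res.samples[::stride]
        if len(thinned) < keep_last:
            warnings.warn(
                f"chain {c}: only {len(thinned)} thinned unique samples "
                f"(< {keep_last}); keeping what exists"
            )
            pooled.extend(thinned)
        else:
            pooled.extend(thinned[-keep_last:])
    return pooled


# --------------------------- Sammon mapping ---------------------------
@dataclass
class SammonResult:
    coords: np.ndarray         # (n, 2), one row per input point
    stress: float
    stress_history: np.ndarray


def _hamming_matrix(seqs: list[str]) -> np.ndarray:
    arr = np.array([list(s) for s in seqs])
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(float)


def sammon_map(data, seed: int = 0, max_iter: int = 500) -> SammonResult:
    """Project points into 2-D minimising the Sammon stress.

    ``data`` may be an (n, d) coordinate array, a square symmetric distance
    matrix, or a list of equal-length sequences (Hamming distances).
    Duplicate points are embedded once and share coordinates (a warning is
    issued). Stress is minimised by L-BFGS from a seeded random start; the
    recorded stress history is non-increasing.
    """
    if isinstance(data, (list, tuple)) and data and isinstance(data[0], str):
        dist = _hamming_matrix(list(data))
    else:
        a = np.asarray(data, dtype=float)
        if a.ndim != 2:
            raise ValueError("need 2-D input")
        if a.shape[0] == a.shape[1] and np.allclose(a, a.T) and np.allclose(np.diag(a), 0):
            dist = a
        else:
            dist = np.linalg.norm(a[:, None, :] - a[None, :, :], axis=-1)

    n = dist.shape[0]
    if n < 3:
        raise ValueError("Sammon mapping needs at least 3 points")

    # collapse duplicates (zero off-diagonal distance)
    rep = np.arange(n)
    for i in range(n):
        for j in range(i):
            if dist[i, j] == 0 and rep[i] == i:
                rep[i] = rep[j]
    uniq = np.flatnonzero(rep == np.arange(n))
    if len(uniq) < n:
        warnings.warn(f"{n - len(uniq)} duplicate points share embedded coordinates")
    if len(uniq) < 3:
        raise ValueError("fewer than 3 distinct points")
    d = dist[np.ix_(uniq, uniq)]
    m = len(uniq)
    iu, ju = np.triu_indices(m, k=1)
    delta = d[iu, ju]
    c = delta.sum()

    def stress_and_grad(flat: np.ndarray):
        y = flat.reshape(m, 2)
        diff = y[iu] - y[ju]
        dd = np.linalg.norm(diff, axis=1)
        dd = np.maximum(dd, 1e-12)
        err = dd - delta
        stress = float(np.sum(err**2 / delta) / c)
        coef = 2.0 * err / (delta * dd) / c
        g = np.zeros((m, 2))
        contrib = coef[:, None] * diff
        np.add.at(g, iu, contrib)
        np.add.at(g, ju, -contrib)
        return stress, g.ravel()

    rng = np.random.default_rng(seed)
    y0 = rng.normal(scale=delta.mean() / 2.0, size=(m, 2)).ravel()
    history = []
    res = minimize(
        stress_and_grad, y0, jac=True, method="L-BFGS-B",
        callback=lambda xk: history.append(stress_and_grad(xk)[0]),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-12},
    )
    coords_u = res.x.reshape(m, 2)
    # map every input point (duplicates included) to its representative
    pos = {u: k for k, u in enumerate(uniq)}
    coords = np.array([coords_u[pos[rep[i]]] for i in range(n)])
    hist = np.array(history) if history else np.array([res.fun])
    return SammonResult(coords=coords, stress=float(res.fun),
                        stress_history=np.minimum.accumulate(hist))


# ------------------------ information content -------------------------
@dataclass
class InformationContent:
    bits: np.ndarray           # per-position log2(20) - H
    consensus: str
    flagged: np.ndarray        # positions above the bits threshold
    threshold: float


def information_content(sequences: list[str], threshold: float = 2.0) -> InformationContent:
    """Per-position Shannon information (bits out of log2(20)) and consensus
    of an aligned, equal-length sequence set."""
    if not sequences:
        raise ValueError("empty sequence set")
    n = len(sequences[0])
    if any(len(s) != n for s in sequences):
        raise ValueError("sequences must have equal length")
    arr = np.array([list(s) for s in sequences])
    maxbits = np.log2(20.0)
    bits = np.empty(n)
    consensus = []
    for j in range(n):
        letters, counts = np.unique(arr[:, j], return_counts=True)
        p = counts / counts.sum()
        h = float(-(p * np.log2(p)).sum())
        bits[j] = maxbits - h
        consensus.append(letters[np.argmax(counts)])
    return InformationContent(bits=bits, consensus="".join(consensus),
                              flagged=np.flatnonzero(bits > threshold),
                              threshold=threshold)


# ------------------------ temperature matching ------------------------
def calibrate_temperature(
    acceptance_fn,
    target: float,
    t_lo: float,
    t_hi: float,
    tol: float = 0.02,
    max_iter: int = 40,
) -> float:
    """Bisection for the temperature at which ``acceptance_fn(T)`` matches a
    target acceptance frequency within ``tol`` (acceptance is monotone
    non-decreasing in T). Used to transfer sampling temperatures between
    the informational and physics-based scorers."""
    lo, hi = t_lo, t_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = acceptance_fn(mid)
        if abs(f - target) <= tol:
            return mid
        if f < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
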