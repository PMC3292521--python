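"""Forward population simulation under truncation selection.

A population of haploid organisms, each carrying one protein-coding gene,
evolves by per-base mutation (transitions twice as probable as
transversions), translation, threading through the native conformation,
and fitness-weighted resampling at constant population size. Fitness is a
three-level truncation scheme frozen against the starting sequence:

    w(s) = 0    if S_gap(s) < S_gap_start  or  V_bind(s) > V_bind_start
         = 0.9  if the thresholds hold but the decoy ligand also binds
                (V_decoy(s) <= V_bind_start)
         = 1    otherwise

i.e. destabilising the fold or the native complex is lethal, acquiring
affinity for a non-functional decoy ligand is mildly deleterious, and
everything else is neutral. Premature stop codons are lethal (a truncated
protein cannot meet the fold threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .params import ParameterSet, default_params
from .specificity import BindScorer, GapScorer
from .structure import CoarseStructure

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _codons in AA_TO_CODONS.values():
    _codons.sort()

DECOY_SEQUENCES = {"info": "IWMTIYMIIIT", "physics": "RLPTIYICITG"}


# --------------------------- basic genetics ---------------------------
def translate(dna: str) -> tuple[str, bool]:
    """Standard-code translation; returns (protein, premature_stop_flag).

    Stops appear as '*' in the protein. The gene is assumed to carry no
    terminal stop codon (length = 3 x protein length), so any stop is
    premature.
    """
    if len(dna) % 3 != 0:
        raise ValueError("DNA length must be divisible by 3")
    bad = set(dna) - set(_BASES)
    if bad:
        raise ValueError(f"non-ACGT symbols in DNA: {sorted(bad)}")
    protein = "".join(CODON_TO_AA[dna[i:i + 3]] for i in range(0, len(dna), 3))
    return protein, "*" in protein


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniformly random synonymous codon per residue."""
    out = []
    for aa in protein:
        codons = AA_TO_CODONS.get(aa)
        if codons is None:
            raise ValueError(f"cannot reverse-translate letter {aa!r}")
        out.append(codons[int(rng.integers(len(codons)))])
    return "".join(out)


def _mutate_array(arr: np.ndarray, mu: float, ts_tv_ratio: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Kimura-style mutation on an integer-coded base array (in place copy).

    Each base mutates independently with probability ``mu``; conditional on
    mutation the transition has probability ratio/(ratio+1) and each of the
    two transversions 1/(2(ratio+1)), so the aggregate
    transition:transversion ratio equals ``ts_tv_ratio``.
    """
    out = arr.copy()
    mask = rng.random(arr.shape) < mu
    k = int(mask.sum())
    if k == 0:
        return out
    b = out[mask]
    p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0)
    is_ts = rng.random(k) < p_ts
    new = np.empty(k, dtype=out.dtype)
    new[is_ts] = b[is_ts] ^ 2                      # A<->G, C<->T
    r = rng.integers(2, size=k)
    tv = (1 - (b % 2)) + 2 * r                     # the two cross-class bases
    new[~is_ts] = tv[~is_ts]
    out[mask] = new
    return out


def mutate_dna(dna: str, mu: float, ts_tv_ratio: float,
               rng: np.random.Generator) -> str:
    """Mutate one DNA string under the transition-biased point model."""
    arr = np.array([_BASE_INDEX[b] for b in dna], dtype=np.uint8)
    out = _mutate_array(arr, mu, ts_tv_ratio, rng)
    return "".join(_BASES[i] for i in out)


# ------------------------------ fitness -------------------------------
@dataclass(frozen=True)
class FitnessThresholds:
    """Scores of the starting sequence, frozen at generation 0."""

    s_gap_start: float
    v_bind_start: float


def fitness(scores: dict[str, float], thresholds: FitnessThresholds) -> float:
    """The three-level truncation rule on precomputed scores."""
    if scores["s_gap"] < thresholds.s_gap_start or scores["v_bind"] > thresholds.v_bind_start:
        return 0.0
    if scores["v_decoy"] <= thresholds.v_bind_start:
        return 0.9
    return 1.0


def make_decoy_ligand(
    model: str,
    ligand_conformation: CoarseStructure,
    params: ParameterSet | None = None,
    thread_config=None,
    decoy_seq: str | None = None,
) -> tuple[str, CoarseStructure]:
    """The non-functional decoy ligand: the model-specific decoy sequence
    threaded through the native ligand conformation."""
    from .sidechain import thread

    seq = decoy_seq or DECOY_SEQUENCES[model]
    if len(seq) != ligand_conformation.n:
        raise ValueError(
            f"decoy sequence length {len(seq)} != ligand length {ligand_conformation.n}; "
            "pass decoy_seq explicitly for non-native ligands"
        )
    return seq, thread(seq, ligand_conformation, thread_config, params or default_params())


class FitnessModel:
    """Scoring bundle for the truncation fitness: fold gap against fixed
    decoys (frozen dispersal), binding to the native ligand, and binding to
    the decoy ligand threaded through the native ligand conformation."""

    def __init__(
        self,
        gap_scorer: GapScorer,
        bind_scorer: BindScorer,
        decoy_seq: str | None = None,
        params: ParameterSet | None = None,
        thread_config=None,
    ) -> None:
        self.gap_scorer = gap_scorer
        self.bind_scorer = bind_scorer
        self.decoy_seq, self.decoy_structure = make_decoy_ligand(
            gap_scorer.model, bind_scorer.ligand, params, thread_config, decoy_seq
        )
        self.thresholds: FitnessThresholds | None = None
        self._cache: dict[str, dict[str, float]] = {}

    def evaluate(self, protein: str) -> dict[str, float]:
        """Fold gap and both binding scores; the protein is threaded once
        and shared between scorers. Cached per protein sequence, so
        synonymous genotypes never rescore."""
        cached = self._cache.get(protein)
        if cached is not None:
            return cached
        structure = None
        if self.gap_scorer.model == "physics":
            structure = self.gap_scorer.threaded(protein)
        scores = {
            "s_gap": self.gap_scorer.s_gap(protein, structure),
            "v_bind": self.bind_scorer.score(
                protein_seq=protein, protein_structure=structure),
            "v_decoy": self.bind_scorer.score(
                protein_seq=protein, ligand_seq=self.decoy_seq,
                ligand_conformation=self.decoy_structure,
                protein_structure=structure,
            ),
        }
        self._cache[protein] = scores
        return scores

    def freeze_thresholds(self, start_protein: str) -> FitnessThresholds:
        s = self.evaluate(start_protein)
        self.thresholds = FitnessThresholds(s_gap_start=s["s_gap"],
                                            v_bind_start=s["v_bind"])
        return self.thresholds

    def fitness(self, protein: str) -> float:
        if self.thresholds is None:
            raise RuntimeError("thresholds not frozen; call freeze_thresholds first")
        if "*" in protein:
            return 0.0
        return fitness(self.evaluate(protein), self.thresholds)


# ------------------------------ simulation ----------------------------
@dataclass
class SimulationConfig:
    pop_size: int = 1000
    generations: int = 200_000
    mu: float = 1e-5                 # per bp per generation
    ts_tv_ratio: float = 2.0
    n_replicates: int = 10
    decoy_seq: str | None = None
    seed: int = 0
    checkpoint_every: int = 1000

    def __post_init__(self) -> None:
        if min(self.pop_size, self.generations, self.checkpoint_every) < 1 or self.mu < 0:
            raise ValueError("invalid simulation configuration")


@dataclass
class Checkpoint:
    generation: int
    most_common_dna: str
    most_common_protein: str
    most_common_freq: float
    allele_freqs: dict[str, float]
    mean_fitness: float
    mean_scores: dict[str, float]
    population: np.ndarray = field(repr=False)
    rng_state: dict = field(repr=False, default_factory=dict)


@dataclass
class EvolutionRun:
    checkpoints: list[Checkpoint]
    config: SimulationConfig
    start_dna: str

    @property
    def final(self) -> Checkpoint:
        return self.checkpoints[-1]


def _encode(dna: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in dna], dtype=np.uint8)


def _decode(row: np.ndarray) -> str:
    return "".join(_BASES[i] for i in row)


def evolve(
    config: SimulationConfig,
    fitness_fn: Callable[[str], float],
    start_dna: str,
    scores_fn: Callable[[str], dict] | None = None,
    resume_from: Checkpoint | None = None,
) -> EvolutionRun:
    """Wright-Fisher-style simulation: mutate every organism, recompute
    fitness only for changed genotypes (cached by DNA), resample with
    probability proportional to fitness at constant size, checkpoint
    periodically. A checkpoint carries the population and RNG state, so
    resuming reproduces the original trajectory bitwise.
    """
    protein0, stop0 = translate(start_dna)
    if stop0:
        raise ValueError("start DNA contains a stop codon")
    if fitness_fn(protein0) != 1.0:
        raise ValueError("starting sequence must have fitness 1")

    rng = np.random.default_rng(config.seed)
    n = config.pop_size
    if resume_from is not None:
        pop = resume_from.population.copy()
        rng.bit_generator.state = resume_from.rng_state
        gen0 = resume_from.generation
    else:
        pop = np.tile(_encode(start_dna), (n, 1))
        gen0 = 0

    fit_cache: dict[bytes, float] = {}
    score_cache: dict[bytes, dict] = {}

    def fitness_of(row: np.ndarray) -> float:
        key = row.tobytes()
        w = fit_cache.get(key)
        if w is None:
            protein, stop = translate(_decode(row))
            w = 0.0 if stop else fitness_fn(protein)
            fit_cache[key] = w
        return w

    checkpoints: list[Checkpoint] = []

    def record(gen: int) -> None:
        keys, counts = np.unique(pop, axis=0, return_counts=True)
        order = np.argsort(counts)[::-1]
        top = keys[order[0]]
        dna = _decode(top)
        freqs = {_decode(keys[i]): counts[i] / n for i in order}
        ws = np.array([fitness_of(r) for r in pop])
        means: dict[str, float] = {}
        if scores_fn is not None:
            per_allele = {}
            for i in order:
                k = keys[i].tobytes()
                if k not in score_cache:
                    prot, stop = translate(_decode(keys[i]))
                    score_cache[k] = {} if stop else scores_fn(prot)
                per_allele[k] = score_cache[k]
            acc: dict[str, float] = {}
            tot = 0
            for i in order:
                sc = per_allele[keys[i].tobytes()]
                if not sc:
                    continue
                tot += counts[i]
                for name, v in sc.items():
                    acc[name] = acc.get(name, 0.0) + v * counts[i]
            means = {name: v / tot for name, v in acc.items()} if tot else {}
        checkpoints.append(Checkpoint(
            generation=gen,
            most_common_dna=dna,
            most_common_protein=translate(dna)[0],
            most_common_freq=float(counts[order[0]] / n),
            allele_freqs=freqs,
            mean_fitness=float(ws.mean()),
            mean_scores=means,
            population=pop.copy(),
            rng_state=rng.bit_generator.state,
        ))

    for gen in range(gen0 + 1, gen0 + config.generations + 1):
        pop = _mutate_array(pop, config.mu, config.ts_tv_ratio, rng)
        ws = np.array([fitness_of(r) for r in pop])
        total = ws.sum()
        if total == 0:
            raise RuntimeError(
                f"population extinct at generation {gen}: all fitnesses are zero"
            )
        idx = rng.choice(n, size=n, p=ws / total)
        pop = pop[idx]
        if gen % config.checkpoint_every == 0 or gen == gen0 + config.generations:
            record(gen)

    return EvolutionRun(checkpoints=checkpoints, config=config, start_dna=start_dna)
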