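"""Post-simulation analytics.

Structural site classes (binding / core / surface), the
Pamilo-Bianchi-Li (PBL) estimator of nonsynonymous and synonymous
divergence with Kimura two-parameter correction, hydrophobicity
partitioning of the site classes, and a likelihood comparison of
rate-homogeneity vs gamma-distributed vs invariant-sites models of
per-site substitution counts.

The rate-heterogeneity comparison deliberately works on site substitution
counts across replicate lineages rather than a full phylogenetic
likelihood: the replicate design is star-shaped, so no tree exists to
integrate over.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc, gammaln
from scipy.stats import gamma as gamma_dist

from .evolution import CODON_TO_AA
from .params import ParameterSet, default_params
from .structure import CoarseStructure, inter_contact_map, sasa_fraction

HYDROPHOBIC_SET = frozenset("AVLIMFWC")  # positive-hydropathy residues

_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


# --------------------------- site classes -----------------------------
@dataclass
class SiteClassMap:
    """Exhaustive, exclusive per-position labels; binding overrides burial."""

    labels: list[str]                 # each in {"core", "surface", "binding"}
    thresholds: dict[str, float]

    def positions(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.array(self.labels) == label)


def classify_sites(
    protein: CoarseStructure,
    ligand: CoarseStructure,
    params: ParameterSet | None = None,
    contact_cutoff: float = 4.5,
) -> SiteClassMap:
    """binding = any inter-molecular side-chain contact below the cutoff;
    core = non-binding residues buried below the ionic-term threshold
    (exposure computed on the unbound protein); surface = the rest."""
    params = params or default_params()
    burial = params.constants.burial_sasa
    inter = inter_contact_map(protein, ligand, cutoff=contact_cutoff)
    is_binding = inter.contacts.any(axis=1)
    sasa = sasa_fraction(protein, params)
    labels = []
    for i in range(protein.n):
        if is_binding[i]:
            labels.append("binding")
        elif sasa[i] < burial:
            labels.append("core")
        else:
            labels.append("surface")
    return SiteClassMap(labels=labels,
                        thresholds={"contact_cutoff": contact_cutoff, "burial_sasa": burial})


def hydrophobic_fraction(
    protein_seq: str,
    site_classes: SiteClassMap,
    hydrophobic: frozenset[str] = HYDROPHOBIC_SET,
) -> dict[str, float | None]:
    """Percentage of hydrophobic residues in the core and surface classes
    (None for an empty class)."""
    out: dict[str, float | None] = {}
    for label in ("core", "surface"):
        pos = site_classes.positions(label)
        if len(pos) == 0:
            out[label] = None
            continue
        out[label] = 100.0 * sum(protein_seq[i] in hydrophobic for i in pos) / len(pos)
    return out


# ------------------------------ PBL dN/dS ------------------------------
def _site_degeneracy(codon: str) -> list[int]:
    """Per-position degeneracy class (0, 2 or 4) of a sense codon: the
    number of synonymous single-base alternatives (changes to stops count
    as nonsynonymous); 0 syn -> 0-fold, 3 syn -> 4-fold, else 2-fold."""
    aa = CODON_TO_AA[codon]
    classes = []
    for k in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[k]:
                continue
            alt = codon[:k] + b + codon[k + 1:]
            if CODON_TO_AA[alt] == aa and aa != "*":
                syn += 1
        classes.append(4 if syn == 3 else (2 if syn >= 1 else 0))
    return classes


def _codon_paths(a: str, b: str) -> list[list[tuple[str, int, str]]]:
    """All orderings of the single-base changes from codon a to codon b,
    as lists of (from_codon, position, to_codon) steps. Pathways through
    stop codons are excluded unless every pathway hits a stop."""
    diff = [k for k in range(3) if a[k] != b[k]]
    all_paths, clean_paths = [], []
    for order in permutations(diff):
        cur = a
        steps = []
        through_stop = False
        for k in order:
            nxt = cur[:k] + b[k] + cur[k + 1:]
            steps.append((cur, k, nxt))
            if CODON_TO_AA[nxt] == "*" and nxt != b:
                through_stop = True
            cur = nxt
        all_paths.append(steps)
        if not through_stop:
            clean_paths.append(steps)
    return clean_paths if clean_paths else all_paths


def _k2p_components(p: float, q: float) -> tuple[float, float]:
    """Kimura 2-parameter transition (A) and transversion (B) distances.

    Each component saturates (NaN) independently: B only needs 1-2q > 0,
    A needs both logs defined."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    b = 0.5 * np.log(1.0 / w2) if w2 > 0.0 else np.nan
    if w1 <= 0.0 or w2 <= 0.0:
        return np.nan, b
    a = 0.5 * np.log(1.0 / w1) - 0.25 * np.log(1.0 / w2)
    return a, b


@dataclass
class DnDsResult:
    dn: float
    ds: float
    ratio: float | None           # None when dS is zero or undefined


def dnds_pbl(seq_dna_a: str, seq_dna_b: str, site_mask=None) -> DnDsResult:
    """Pamilo-Bianchi-Li dN/dS between two in-frame coding sequences.

    Sites are classed by degeneracy (counts averaged over the two
    sequences); transitional/transversional differences are tallied per
    class, averaging over all minimal substitution pathways within each
    codon (each step contributing half to the site class of its source and
    half to that of its target codon, which makes the estimator symmetric);
    per-class K2P correction then combines into

        dS = (L2 A2 + L4 A4) / (L2 + L4) + B4
        dN = A0 + (L0 B0 + L2 B2) / (L0 + L2).
    """
    if len(seq_dna_a) != len(seq_dna_b) or len(seq_dna_a) % 3 != 0:
        raise ValueError("sequences must be equal-length and in frame")
    n_codons = len(seq_dna_a) // 3
    if site_mask is None:
        site_mask = np.ones(n_codons, dtype=bool)
    site_mask = np.asarray(site_mask, dtype=bool)
    if site_mask.shape != (n_codons,):
        raise ValueError("site_mask length must equal the codon count")

    classes = (0, 2, 4)
    L = {c: 0.0 for c in classes}       # site counts, averaged over sequences
    S = {c: 0.0 for c in classes}       # transitional differences
    V = {c: 0.0 for c in classes}       # transversional differences

    for idx in np.flatnonzero(site_mask):
        ca = seq_dna_a[3 * idx: 3 * idx + 3]
        cb = seq_dna_b[3 * idx: 3 * idx + 3]
        if CODON_TO_AA[ca] == "*" or CODON_TO_AA[cb] == "*":
            continue  # stop codons carry no comparable sites
        da, db = _site_degeneracy(ca), _site_degeneracy(cb)
        for k in range(3):
            L[da[k]] += 0.5
            L[db[k]] += 0.5
        if ca == cb:
            continue
        paths = _codon_paths(ca, cb)
        wpath = 1.0 / len(paths)
        for steps in paths:
            for frm, k, to in steps:
                tally = S if _is_transition(frm[k], to[k]) else V
                tally[_site_degeneracy(frm)[k]] += 0.5 * wpath
                tally[_site_degeneracy(to)[k]] += 0.5 * wpath

    A, B = {}, {}
    for c in classes:
        if L[c] > 0:
            A[c], B[c] = _k2p_components(S[c] / L[c], V[c] / L[c])
        else:
            A[c], B[c] = 0.0, 0.0

    l24 = L[2] + L[4]
    l02 = L[0] + L[2]
    ds = (L[2] * A[2] + L[4] * A[4]) / l24 + B[4] if l24 > 0 else np.nan
    dn = A[0] + (L[0] * B[0] + L[2] * B[2]) / l02 if l02 > 0 else np.nan
    if not np.isfinite(ds) or not np.isfinite(dn) or ds <= 0.0:
        ratio = None
    else:
        ratio = dn / ds
    return DnDsResult(dn=float(dn), ds=float(ds), ratio=ratio)


# ------------------------ rate heterogeneity ---------------------------
@dataclass
class RateModelReport:
    supports: dict[str, float]        # Akaike weights: equal / gamma / invariant
    alpha: float | None               # gamma shape, when estimable
    p_invariant: float | None
    site_rates: np.ndarray | None     # posterior mean relative rate per site
    criterion: str
    loglik: dict[str, float]


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rate of each of k equal-probability categories of a gamma
    distribution with shape alpha and mean 1."""
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1.0 / alpha)
    # partial expectations via the regularised incomplete gamma of shape a+1
    upper = gammainc(alpha + 1.0, edges[1:] * alpha)
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    return (upper - lower) * k


def _poisson_logpmf(c: np.ndarray, lam: float) -> np.ndarray:
    return c * np.log(lam) - lam - gammaln(c + 1.0)


def substitution_counts(sequences: list[str], reference: str) -> np.ndarray:
    """Per-site count of lineages differing from the reference."""
    if any(len(s) != len(reference) for s in sequences):
        raise ValueError("aligned sequences must match the reference length")
    arr = np.array([list(s) for s in sequences])
    ref = np.array(list(reference))
    return (arr != ref[None, :]).sum(axis=0).astype(float)


def rate_heterogeneity(
    data,
    reference: str | None = None,
    criterion: str = "aic",
    n_categories: int = 4,
) -> RateModelReport:
    """Compare equal-rates, discrete-gamma and invariant-sites models of
    per-site substitution counts by maximum likelihood.

    ``data`` is either a 1-D array of per-site counts, or a list of aligned
    sequences together with ``reference`` (counts of lineages differing
    from the reference per site). Supports are information-criterion
    weights (AIC by default; AICc/BIC selectable).
    """
    if reference is not None:
        counts = substitution_counts(list(data), reference)
    else:
        counts = np.asarray(data, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("need counts for at least 2 sites")
    n = len(counts)

    if np.all(counts == 0):
        return RateModelReport(
            supports={"equal": 1.0, "gamma": 0.0, "invariant": 0.0},
            alpha=None, p_invariant=None, site_rates=None,
            criterion=criterion, loglik={},
        )

    mean = counts.mean()

    # (a) single-rate Poisson
    ll_equal = float(_poisson_logpmf(counts, mean).sum())

    # (b) discrete-gamma mixture
    def nll_gamma(x):
        lam, alpha = np.exp(x)
        if not (1e-6 < alpha < 1e4):
            return 1e12
        rates = discrete_gamma_rates(alpha, n_categories)
        comp = np.array([_poisson_logpmf(counts, lam * r) for r in np.maximum(rates, 1e-12)])
        m = comp.max(axis=0)
        ll = m + np.log(np.mean(np.exp(comp - m), axis=0))
        return -float(ll.sum())

    best_g = None
    for a0 in (0.3, 1.0, 3.0):
        res = minimize(nll_gamma, np.log([mean, a0]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        if best_g is None or res.fun < best_g.fun:
            best_g = res
    lam_g, alpha_hat = np.exp(best_g.x)
    ll_gamma = -float(best_g.fun)

    # (c) single rate plus an invariant class
    def nll_inv(x):
        p0 = 1.0 / (1.0 + np.exp(-x[0]))
        lam = np.exp(x[1])
        lp = _poisson_logpmf(counts, lam)
        with np.errstate(divide="ignore"):
            ll = np.logaddexp(np.log(p0) + np.where(counts == 0, 0.0, -np.inf),
                              np.log1p(-p0) + lp)
        return -float(ll.sum())

    frac0 = max(min((counts == 0).mean(), 0.98), 0.02)
    res_i = minimize(nll_inv, [np.log(frac0 / (1 - frac0)), np.log(max(mean, 1e-3))],
                     method="Nelder-Mead",
                     options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    p_inv = float(1.0 / (1.0 + np.exp(-res_i.x[0])))
    ll_inv = -float(res_i.fun)

    lls = {"equal": ll_equal, "gamma": ll_gamma, "invariant": ll_inv}
    ks = {"equal": 1, "gamma": 2, "invariant": 2}
    crit = {}
    for name, ll in lls.items():
        k = ks[name]
        if criterion == "aic":
            crit[name] = 2 * k - 2 * ll
        elif criterion == "aicc":
            crit[name] = 2 * k - 2 * ll + 2 * k * (k + 1) / max(n - k - 1, 1)
        elif criterion == "bic":
            crit[name] = k * np.log(n) - 2 * ll
        else:
            raise ValueError("criterion must be aic, aicc or bic")
    cmin = min(crit.values())
    raw = {name: np.exp(-(c - cmin) / 2.0) for name, c in crit.items()}
    tot = sum(raw.values())
    supports = {name: float(v / tot) for name, v in raw.items()}

    # posterior mean relative rate per site under the gamma fit
    rates = discrete_gamma_rates(alpha_hat, n_categories)
    comp = np.array([_poisson_logpmf(counts, lam_g * r) for r in np.maximum(rates, 1e-12)])
    m = comp.max(axis=0)
    post = np.exp(comp - m)
    post /= post.sum(axis=0)
    site_rates = (post * rates[:, None]).sum(axis=0)

    # a shape estimate at the upper search bound means the gamma mixture has
    # degenerated to equal rates; report the shape as inestimable
    alpha_out = float(alpha_hat) if alpha_hat < 1e3 else None
    return RateModelReport(
        supports=supports, alpha=alpha_out, p_invariant=p_inv,
        site_rates=site_rates, criterion=criterion, loglik=lls,
    )
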