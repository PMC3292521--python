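"""The physics-based scoring function.

Folding is scored by a seven-term weighted sum

    V(s, c) = w_bend V_bend + w_LJ V_LJ + w_helix V_helix + w_beta V_beta
              + w_ion V_ion + w_solv V_solv + w_SS V_SS

and binding by a three-term sum over inter-molecular interactions

    V(s1, c1, s2, c2) = w'_LJ V'_LJ + w'_ion V'_ion - w_dsolv V_dsolv,

with V_dsolv the solvation change on complexation (separate minus complex).
Lower scores are better in both cases.

Every folding term is computed from a :class:`Measurements` bundle — the
flat arrays of bend angles, torsions, helix 1-3/1-4 distances, bead-pair
distances, exposure fractions and cysteine-pair distances the printed
formulas consume. Random-energy-model decoys are permutations of those
arrays, so scoring a decoy never needs decoy coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._geometry import wrap_degrees
from .params import CA_RADIUS, ParameterSet, default_params
from .structure import CoarseStructure, sasa_fraction, sasa_fraction_complex

FOLD_TERMS = ("bend", "lj", "helix", "beta", "ion", "solv", "ss")
BIND_TERMS = ("blj", "bion", "bdsolv")

# measurement classes that a geometry decoy may permute independently
PERMUTABLE = ("theta", "phi", "r13", "r14", "lj_r", "ion_r", "sasa", "ss_r")


@dataclass
class TermVector:
    """Raw per-term scores (unweighted)."""

    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self, order: tuple[str, ...]) -> np.ndarray:
        return np.array([self.values[t] for t in order])


@dataclass(frozen=True)
class WeightVector:
    """One weight per term, each restricted to the open interval (0, 1)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for name, w in self.values.items():
            if not (0.0 < w < 1.0):
                raise ValueError(f"weight {name}={w} outside the open interval (0,1)")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.values)

    def as_array(self, order: tuple[str, ...]) -> np.ndarray:
        return np.array([self.values[t] for t in order])

    @classmethod
    def uniform(cls, terms: tuple[str, ...] = FOLD_TERMS, value: float = 0.5) -> "WeightVector":
        return cls({t: value for t in terms})


def total_fold(tv: TermVector, w: WeightVector) -> float:
    return float(sum(w[t] * tv[t] for t in FOLD_TERMS))


def total_bind(tv: TermVector, w: WeightVector) -> float:
    return float(w["blj"] * tv["blj"] + w["bion"] * tv["bion"]
                 - w["bdsolv"] * tv["bdsolv"])


# ----------------------------------------------------------------------
@dataclass
class Measurements:
    """Flat geometric/solvation measurements of one (sequence, conformation).

    Arrays in :data:`PERMUTABLE` are what a random-energy-model decoy
    shuffles; everything else (equilibria, propensities, pair identities)
    is pinned to sequence positions.
    """

    sequence: str
    theta: np.ndarray        # (N,) bend angles, NaN undefined
    theta0: np.ndarray       # (N,) equilibrium bend angles
    phi: np.ndarray          # (N,) torsions (radians), NaN undefined
    beta_k: np.ndarray       # (N,) beta force constants
    r13: np.ndarray          # helix 1-3 Calpha distances, one per summed i
    r14: np.ndarray          # helix 1-4 Calpha distances
    k13: np.ndarray          # averaged helix constants (3 residues)
    k14: np.ndarray          # averaged helix constants (4 residues)
    lj_r: np.ndarray         # bead-pair distances
    lj_sig: np.ndarray       # matching collision diameters
    lj_eps: np.ndarray       # matching well depths
    ion_i: np.ndarray        # charged-pair member indices
    ion_j: np.ndarray
    ion_qq: np.ndarray       # charge products
    ion_r: np.ndarray        # charged-pair Cbeta distances
    sasa: np.ndarray         # (N,) exposure fractions
    h: np.ndarray            # (N,) hydropathy parameters
    p: np.ndarray            # (N,) polarity indices
    ss_r: np.ndarray         # cysteine-pair Cbeta distances

    def permuted(self, perms: dict[str, np.ndarray]) -> "Measurements":
        """Copy with each named measurement class permuted.

        ``theta``/``phi`` permutations act on the defined entries only; the
        others act on their whole array.
        """
        kw = {}
        for name, idx in perms.items():
            arr = getattr(self, name).copy()
            if name in ("theta", "phi"):
                defined = np.flatnonzero(np.isfinite(arr))
                arr[defined] = arr[defined[idx]]
            else:
                arr = arr[idx]
            kw[name] = arr
        return replace(self, **kw)


def _lj_pairs(structure: CoarseStructure, params: ParameterSet):
    """Bead list and pair arrays for V_LJ: every Calpha, plus Cbeta for
    non-glycine residues; pairs within one residue and directly bonded
    Calpha neighbours are excluded."""
    n = structure.n
    pos, rad, eps, res, kind = [], [], [], [], []
    hs = params.hydropathy(structure.sequence)
    for i in range(n):
        pos.append(structure.ca[i]); rad.append(CA_RADIUS)
        eps.append(params.constants.eps_ca); res.append(i); kind.append(0)
    for i in np.flatnonzero(structure.has_cb):
        pos.append(structure.cb[i]); rad.append(structure.radii[i])
        eps.append(hs[i]); res.append(i); kind.append(1)
    pos = np.array(pos); rad = np.array(rad); eps = np.array(eps)
    res = np.array(res); kind = np.array(kind)
    m = len(pos)
    iu, ju = np.triu_indices(m, k=1)
    same_res = res[iu] == res[ju]
    bonded = (kind[iu] == 0) & (kind[ju] == 0) & (np.abs(res[iu] - res[ju]) == 1)
    keep = ~(same_res | bonded)
    iu, ju = iu[keep], ju[keep]
    r = np.linalg.norm(pos[iu] - pos[ju], axis=1)
    sig = rad[iu] + rad[ju]
    e = np.sqrt(eps[iu] * eps[ju])
    return r, sig, e


def extract_measurements(
    structure: CoarseStructure,
    params: ParameterSet | None = None,
    sasa: np.ndarray | None = None,
) -> Measurements:
    """Pull every input of the folding terms out of a coarse structure."""
    params = params or default_params()
    seq = structure.sequence
    n = structure.n
    if sasa is None:
        sasa = sasa_fraction(structure, params)

    ca = structure.ca
    helix_k = params.helix_prop(seq)
    r13, r14, k13, k14 = [], [], [], []
    for j in range(2, n - 3):  # 1-based i = 3 .. N-3
        r13.append(np.linalg.norm(ca[j] - ca[j + 2]))
        r14.append(np.linalg.norm(ca[j] - ca[j + 3]))
        k13.append(helix_k[j : j + 3].mean())
        k14.append(helix_k[j : j + 4].mean())

    lj_r, lj_sig, lj_eps = _lj_pairs(structure, params)

    centers = structure.interaction_centers
    q = params.charges(seq)
    charged = np.flatnonzero(q != 0)
    ion_i, ion_j, ion_qq, ion_r = [], [], [], []
    for a in range(len(charged)):
        for b in range(a + 1, len(charged)):
            i, j = charged[a], charged[b]
            ion_i.append(i); ion_j.append(j)
            ion_qq.append(q[i] * q[j])
            ion_r.append(np.linalg.norm(centers[i] - centers[j]))

    cys = np.flatnonzero(np.array(list(seq)) == "C")
    ss_r = [np.linalg.norm(centers[i] - centers[j])
            for a, i in enumerate(cys) for j in cys[a + 1:]]

    return Measurements(
        sequence=seq,
        theta=structure.theta,
        theta0=params.theta0(seq),
        phi=structure.phi,
        beta_k=params.beta_prop(seq),
        r13=np.array(r13), r14=np.array(r14),
        k13=np.array(k13), k14=np.array(k14),
        lj_r=lj_r, lj_sig=lj_sig, lj_eps=lj_eps,
        ion_i=np.array(ion_i, dtype=int), ion_j=np.array(ion_j, dtype=int),
        ion_qq=np.array(ion_qq, dtype=float), ion_r=np.array(ion_r, dtype=float),
        sasa=np.asarray(sasa, dtype=float),
        h=params.hydropathy(seq), p=params.polarity(seq),
        ss_r=np.array(ss_r, dtype=float),
    )


def _as_measurements(x, params: ParameterSet | None) -> Measurements:
    if isinstance(x, Measurements):
        return x
    return extract_measurements(x, params)


# ------------------------------- terms --------------------------------
def v_bend(x, params: ParameterSet | None = None) -> float:
    """Harmonic bending energy; the two printed half-K sums, so interior
    angles contribute twice (the second occurrence against the preceding
    residue's equilibrium). Terms with an undefined angle are skipped."""
    params = params or default_params()
    m = _as_measurements(x, params)
    k = params.constants.k_theta
    th, th0 = m.theta, m.theta0
    ok = np.isfinite(th)
    s1 = np.sum(0.5 * k * (th[ok] - th0[ok]) ** 2)          # i = 2..N (1-based)
    ok2 = ok[1:]                                             # theta_{i+1} vs theta0(i)
    s2 = np.sum(0.5 * k * (th[1:][ok2] - th0[:-1][ok2]) ** 2)
    return float(s1 + s2)


def v_lj(x, params: ParameterSet | None = None) -> float:
    """Pairwise Lennard-Jones energy over all bead pairs."""
    m = _as_measurements(x, params)
    if np.any(m.lj_r == 0):
        raise ValueError("coincident beads in Lennard-Jones evaluation")
    sr6 = (m.lj_sig / m.lj_r) ** 6
    return float(np.sum(4.0 * m.lj_eps * (sr6 * sr6 - sr6)))


def v_helix(x, params: ParameterSet | None = None) -> float:
    """Harmonic restraint of 1-3 and 1-4 Calpha distances to the
    equilibrium helix distance, stiffness from averaged helix propensities."""
    params = params or default_params()
    m = _as_measurements(x, params)
    rh = params.constants.r_h
    return float(np.sum(0.5 * m.k13 * (m.r13 - rh) ** 2)
                 + np.sum(0.5 * m.k14 * (m.r14 - rh) ** 2))


def v_beta(x, params: ParameterSet | None = None) -> float:
    """Harmonic restraint of the backbone torsion to the equilibrium beta
    value (210 deg), angle differences wrapped on the circle."""
    params = params or default_params()
    m = _as_measurements(x, params)
    c = params.constants
    ok = np.flatnonzero(np.isfinite(m.phi))
    if ok.size == 0:
        return 0.0
    # K^{1-4}: mean beta propensity over residues i-1..i+2 (defined phi
    # positions are 1..N-3 zero-based, so the window always fits)
    k14 = np.array([m.beta_k[j - 1 : j + 3].mean() for j in ok])
    d = wrap_degrees(np.degrees(m.phi[ok]) - c.phi_b)
    return float(np.sum(k14 * c.c_b * np.asarray(d) ** 2))


def v_ion(x, params: ParameterSet | None = None) -> float:
    """Screened Coulomb energy over buried charged pairs (both members with
    exposure below the burial threshold)."""
    params = params or default_params()
    m = _as_measurements(x, params)
    c = params.constants
    if len(m.ion_r) == 0:
        return 0.0
    buried = (m.sasa[m.ion_i] < c.burial_sasa) & (m.sasa[m.ion_j] < c.burial_sasa)
    if not buried.any():
        return 0.0
    return float(np.sum(c.c_c * m.ion_qq[buried] / (c.dielectric * m.ion_r[buried])))


def v_solv(x, params: ParameterSet | None = None) -> float:
    """Implicit solvation: h_i weighted by exposure plus the polarity index
    weighted by burial, summed over residues."""
    m = _as_measurements(x, params)
    return float(np.sum(m.h * m.sasa + m.p * (1.0 - m.sasa)))


def v_ss(x, params: ParameterSet | None = None) -> float:
    """-1 per cysteine pair with Cbeta centres closer than r_SS."""
    params = params or default_params()
    m = _as_measurements(x, params)
    if len(m.ss_r) == 0:
        return 0.0
    return float(-np.sum(m.ss_r < params.constants.r_ss))


def fold_terms(x, params: ParameterSet | None = None) -> TermVector:
    """All seven folding terms of a structure or measurement bundle."""
    params = params or default_params()
    m = _as_measurements(x, params)
    return TermVector({
        "bend": v_bend(m, params),
        "lj": v_lj(m, params),
        "helix": v_helix(m, params),
        "beta": v_beta(m, params),
        "ion": v_ion(m, params),
        "solv": v_solv(m, params),
        "ss": v_ss(m, params),
    })


def score_fold_physics(
    sequence: str,
    conformation: CoarseStructure,
    weights: WeightVector,
    params: ParameterSet | None = None,
    thread_config=None,
) -> tuple[TermVector, float]:
    """Score a sequence against a backbone conformation (threading first
    when the sequence differs from the conformation's own)."""
    params = params or default_params()
    if sequence == conformation.sequence:
        structure = conformation
    else:
        from .sidechain import thread
        structure = thread(sequence, conformation, thread_config, params)
    tv = fold_terms(structure, params)
    return tv, total_fold(tv, weights)


# ------------------------------ binding -------------------------------
def _inter_lj(a: CoarseStructure, b: CoarseStructure, params: ParameterSet) -> float:
    """LJ over inter-molecular bead pairs (no exclusions)."""
    def beads(s: CoarseStructure):
        pos = [s.ca[i] for i in range(s.n)]
        rad = [CA_RADIUS] * s.n
        eps = [params.constants.eps_ca] * s.n
        hs = params.hydropathy(s.sequence)
        for i in np.flatnonzero(s.has_cb):
            pos.append(s.cb[i]); rad.append(s.radii[i]); eps.append(hs[i])
        return np.array(pos), np.array(rad), np.array(eps)

    pa, ra, ea = beads(a)
    pb, rb, eb = beads(b)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    if np.any(d == 0):
        raise ValueError("coincident beads across the interface")
    sig = ra[:, None] + rb[None, :]
    eps = np.sqrt(ea[:, None] * eb[None, :])
    sr6 = (sig / d) ** 6
    return float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))


def bind_terms(
    protein: CoarseStructure,
    ligand: CoarseStructure,
    params: ParameterSet | None = None,
) -> TermVector:
    """Raw binding terms: inter-molecular LJ, buried inter-molecular
    electrostatics (burial judged in the complex frame), and the solvation
    change V_dsolv = V_solv(separate parts) - V_solv(complex)."""
    params = params or default_params()
    c = params.constants

    blj = _inter_lj(protein, ligand, params)

    sasa_a, sasa_b = sasa_fraction_complex(protein, ligand, params)
    qa = params.charges(protein.sequence)
    qb = params.charges(ligand.sequence)
    ca_ = protein.interaction_centers
    cb_ = ligand.interaction_centers
    bion = 0.0
    for i in np.flatnonzero(qa != 0):
        if sasa_a[i] >= c.burial_sasa:
            continue
        for j in np.flatnonzero(qb != 0):
            if sasa_b[j] >= c.burial_sasa:
                continue
            r = np.linalg.norm(ca_[i] - cb_[j])
            bion += c.c_c * qa[i] * qb[j] / (c.dielectric * r)

    def solv_with(s: CoarseStructure, sasa: np.ndarray) -> float:
        return float(np.sum(params.hydropathy(s.sequence) * sasa
                            + params.polarity(s.sequence) * (1.0 - sasa)))

    solv_sep = (solv_with(protein, sasa_fraction(protein, params))
                + solv_with(ligand, sasa_fraction(ligand, params)))
    solv_cplx = solv_with(protein, sasa_a) + solv_with(ligand, sasa_b)
    bdsolv = solv_sep - solv_cplx

    return TermVector({"blj": blj, "bion": float(bion), "bdsolv": bdsolv})


def score_bind_physics(
    protein: CoarseStructure,
    ligand: CoarseStructure,
    weights: WeightVector,
    params: ParameterSet | None = None,
) -> tuple[TermVector, float]:
    """Binding score of a positioned complex; lower is better."""
    tv = bind_terms(protein, ligand, params)
    return tv, total_bind(tv, weights)
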