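"""Site classification, PBL dN/dS, hydrophobicity, rate heterogeneity."""

from itertools import permutations

import numpy as np
import pytest

from twobead.analysis import (
    HYDROPHOBIC_SET,
    classify_sites,
    discrete_gamma_rates,
    dnds_pbl,
    hydrophobic_fraction,
    rate_heterogeneity,
)
from twobead.evolution import CODON_TO_AA, reverse_translate


# --------------------------- site classes -----------------------------
class TestSiteClasses:
    def test_labels_partition_positions(self, docked):
        fold, pep = docked
        classes = classify_sites(fold, pep)
        assert len(classes.labels) == fold.n
        assert set(classes.labels) <= {"core", "surface", "binding"}

    def test_binding_residues_touch_the_ligand(self, docked):
        import twobead as tb

        fold, pep = docked
        classes = classify_sites(fold, pep)
        icm = tb.inter_contact_map(fold, pep)
        touching = set(np.flatnonzero(icm.contacts.any(axis=1)))
        assert set(classes.positions("binding")) == touching
        assert len(touching) >= 2

    def test_extended_chain_has_no_core(self, params):
        import twobead as tb
        from twobead.structure import CoarseStructure

        n = 15
        ca = np.column_stack([np.arange(n) * 3.8, np.zeros(n), np.zeros(n)])
        cb = ca + np.array([0.0, 1.2, 0.0])
        chain = CoarseStructure("A" * n, ca, cb, params.radii("A" * n))
        far = CoarseStructure("A" * n, ca + 500.0, cb + 500.0, params.radii("A" * n))
        classes = classify_sites(chain, far)
        assert len(classes.positions("core")) == 0


class TestHydrophobicFraction:
    def test_extremes(self, docked):
        fold, pep = docked
        classes = classify_sites(fold, pep)
        assert hydrophobic_fraction("L" * fold.n, classes)["core"] == 100.0
        assert hydrophobic_fraction("D" * fold.n, classes)["surface"] == 0.0

    def test_hand_count(self, docked):
        fold, pep = docked
        classes = classify_sites(fold, pep)
        seq = fold.sequence
        for label in ("core", "surface"):
            pos = classes.positions(label)
            expect = 100.0 * sum(seq[i] in HYDROPHOBIC_SET for i in pos) / len(pos)
            assert hydrophobic_fraction(seq, classes)[label] == pytest.approx(expect)

    def test_empty_class_flagged(self, docked):
        from twobead.analysis import SiteClassMap

        classes = SiteClassMap(labels=["surface"] * 5, thresholds={})
        out = hydrophobic_fraction("AAAAA", classes)
        assert out["core"] is None


# ------------------------------ PBL dN/dS ------------------------------
def _oracle_pbl(a, b):
    """Independent literal implementation: degeneracy classes, exhaustive
    pathway enumeration, K2P per class, PBL combination."""
    def degeneracy(codon):
        aa = CODON_TO_AA[codon]
        out = []
        for k in range(3):
            syn = sum(
                CODON_TO_AA[codon[:k] + x + codon[k + 1:]] == aa
                for x in "ACGT" if x != codon[k]
            ) if aa != "*" else 0
            out.append(0 if syn == 0 else (4 if syn == 3 else 2))
        return out

    def is_ts(x, y):
        return (x in "AG") == (y in "AG")

    L = {0: 0.0, 2: 0.0, 4: 0.0}
    S = {0: 0.0, 2: 0.0, 4: 0.0}
    V = {0: 0.0, 2: 0.0, 4: 0.0}
    for c in range(len(a) // 3):
        ca, cb = a[3 * c: 3 * c + 3], b[3 * c: 3 * c + 3]
        if CODON_TO_AA[ca] == "*" or CODON_TO_AA[cb] == "*":
            continue
        for k in range(3):
            L[degeneracy(ca)[k]] += 0.5
            L[degeneracy(cb)[k]] += 0.5
        diff = [k for k in range(3) if ca[k] != cb[k]]
        if not diff:
            continue
        paths = []
        for order in permutations(diff):
            cur, steps, stop = ca, [], False
            for k in order:
                nxt = cur[:k] + cb[k] + cur[k + 1:]
                steps.append((cur, k, nxt))
                if CODON_TO_AA[nxt] == "*" and nxt != cb:
                    stop = True
                cur = nxt
            paths.append((steps, stop))
        clean = [s for s, flag in paths if not flag]
        use = clean if clean else [s for s, _ in paths]
        for steps in use:
            for frm, k, to in steps:
                tgt = S if is_ts(frm[k], to[k]) else V
                tgt[degeneracy(frm)[k]] += 0.5 / len(use)
                tgt[degeneracy(to)[k]] += 0.5 / len(use)

    def k2p(p, q):
        w1, w2 = 1 - 2 * p - q, 1 - 2 * q
        return (0.5 * np.log(1 / w1) - 0.25 * np.log(1 / w2), 0.5 * np.log(1 / w2))

    A, B = {}, {}
    for c in (0, 2, 4):
        A[c], B[c] = k2p(S[c] / L[c], V[c] / L[c]) if L[c] > 0 else (0.0, 0.0)
    ds = (L[2] * A[2] + L[4] * A[4]) / (L[2] + L[4]) + B[4]
    dn = A[0] + (L[0] * B[0] + L[2] * B[2]) / (L[0] + L[2])
    return dn, ds


class TestDnDs:
    def test_identical_sequences(self):
        dna = "ATGGCTAAACTG" * 5
        r = dnds_pbl(dna, dna)
        assert r.dn == 0.0 and r.ds == 0.0 and r.ratio is None

    def test_single_synonymous_transition(self):
        rng = np.random.default_rng(0)
        prot = "MGAVILKDESTQHRNWYFPC" * 15   # ~300 codons
        a = reverse_translate(prot, rng)
        # find a GGT glycine codon and flip its third base to GGC
        idx = a.find("GGT")
        idx -= idx % 3
        while a[idx:idx + 3] != "GGT":
            idx = a.find("GGT", idx + 1)
            idx -= idx % 3
        b = a[:idx + 2] + "C" + a[idx + 3:]
        r = dnds_pbl(a, b)
        assert r.dn == 0.0 and r.ds > 0.0 and r.ratio == 0.0

    def test_matches_pathway_oracle(self):
        # ~22-codon genes with moderate mixed syn/nonsyn divergence,
        # including one codon with two differences (pathway averaging)
        a = ("ATGGCTGTGATCCTGAAAGATGAATCCACGCAGCATCGCAACTGGTATTTT"
             "CCGTGCGGAGCAAGT")
        edits = {1: "GCC",   # A, synonymous transition
                 2: "GTT",   # V, synonymous transversion
                 5: "AGA",   # K->R nonsynonymous
                 7: "GAT",   # E->D nonsynonymous
                 16: "TTC",  # F, synonymous
                 19: "GCT"}  # G->A via two changes: pathways averaged
        b = "".join(edits.get(i, a[3 * i: 3 * i + 3]) for i in range(len(a) // 3))
        assert len(a) == len(b) == 66
        r = dnds_pbl(a, b)
        dn_o, ds_o = _oracle_pbl(a, b)
        assert np.isfinite(r.dn) and np.isfinite(r.ds)
        assert r.dn == pytest.approx(dn_o, rel=1e-10)
        assert r.ds == pytest.approx(ds_o, rel=1e-10)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        a = reverse_translate("MAVILKDESTQHRNWYFPCG", rng)
        edits = {2: "GTC", 3: "CTG", 6: "GAG", 12: "AAA", 18: "AGT"}
        b = "".join(edits.get(i, a[3 * i: 3 * i + 3]) for i in range(20))
        r1, r2 = dnds_pbl(a, b), dnds_pbl(b, a)
        assert np.isfinite(r1.dn) and np.isfinite(r1.ds)
        assert r1.dn == pytest.approx(r2.dn, rel=1e-12)
        assert r1.ds == pytest.approx(r2.ds, rel=1e-12)

    def test_site_mask_restricts_codons(self):
        rng = np.random.default_rng(4)
        a = reverse_translate("MAVILKDEST", rng)
        # one synonymous change inside the mask, one nonsyn change outside
        b = a[:8] + ("C" if a[8] != "C" else "T") + a[9:]
        b = b[:24] + "CAT" + b[27:]            # codon 9 (outside mask)
        mask = np.zeros(10, dtype=bool)
        mask[:5] = True
        r_in = dnds_pbl(a, b, mask)
        r_all = dnds_pbl(a, b)
        assert np.isfinite(r_in.ds)
        # the masked estimate sees only the codon-2 silent change
        assert r_in.dn == 0.0 and r_in.ds > 0.0
        assert r_all.dn > 0.0

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dnds_pbl("ATGG", "ATGG")


# ------------------------ rate heterogeneity ---------------------------
class TestRateHeterogeneity:
    def test_discrete_gamma_categories_have_unit_mean(self):
        for alpha in (0.2, 1.0, 3.0):
            rates = discrete_gamma_rates(alpha)
            assert rates.mean() == pytest.approx(1.0, rel=1e-6)
            assert np.all(np.diff(rates) > 0)

    def test_equal_rates_recovered(self):
        wins = 0
        for seed in range(10):
            counts = np.random.default_rng(seed).poisson(3.0, size=100)
            rep = rate_heterogeneity(counts)
            if rep.supports["equal"] > 0.5:
                wins += 1
        assert wins >= 9

    def test_gamma_rates_recovered(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            lam = rng.gamma(0.5, scale=1 / 0.5, size=150) * 4.0
            counts = rng.poisson(lam)
            rep = rate_heterogeneity(counts)
            best = max(rep.supports, key=rep.supports.get)
            if best in ("gamma", "invariant") and rep.supports["gamma"] > rep.supports["equal"] \
                    and 0.25 <= rep.alpha <= 1.0:
                wins += 1
        assert wins >= 8

    def test_invariant_sites_recovered(self):
        rng = np.random.default_rng(7)
        counts = np.concatenate([np.zeros(50), rng.poisson(5.0, size=50)])
        rep = rate_heterogeneity(counts)
        assert max(rep.supports, key=rep.supports.get) == "invariant"
        assert rep.p_invariant == pytest.approx(0.5, abs=0.15)

    def test_all_identical_alignment_convention(self):
        rep = rate_heterogeneity(np.zeros(40))
        assert rep.supports["equal"] == 1.0
        assert rep.alpha is None

    def test_sequence_interface(self):
        ref = "MAVILK"
        seqs = ["MAVILK", "MAVILR", "MTVILK", "MAVILK"]
        rep = rate_heterogeneity(seqs, reference=ref)
        assert rep.supports  # runs end to end on tiny alignments

    def test_alpha_recovery_within_factor_two(self):
        """Median alpha estimate across seeds within 2x of truth."""
        for alpha in (0.2, 1.0, 3.0):
            est = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                lam = rng.gamma(alpha, scale=1 / alpha, size=200) * 5.0
                counts = rng.poisson(lam)
                est.append(rate_heterogeneity(counts).alpha)
            med = np.median(est)
            assert alpha / 2 <= med <= alpha * 2
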