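"""Knowledge-based contact potential.

Folding:   E(s, c)  = sum_{i<j} U[a_i, a_j] C(i, j), with C the Cbeta
contact map of the conformation (4.5 A cutoff, sequence separation > 4).
Binding:   the same sum over the rectangular inter-molecular contact map.

``U`` is a symmetric 20x20 contact-energy matrix, loadable from file; the
shipped default is a synthetic hydrophobic-attraction stand-in (see the
data file header).
"""

from __future__ import annotations

import numpy as np

from .params import ContactMatrix, load_contact_matrix
from .structure import ContactMap

__all__ = ["score_fold_info", "score_bind_info", "ContactMatrix", "load_contact_matrix"]


def score_fold_info(sequence: str, cmap: ContactMap, u: ContactMatrix) -> float:
    """Contact energy of a sequence on an intra-molecular contact map."""
    if len(sequence) != cmap.n:
        raise ValueError(f"sequence length {len(sequence)} != contact map size {cmap.n}")
    if cmap.min_sep is None:
        raise ValueError("score_fold_info requires an intra-molecular (square) map")
    code = u.encode(sequence)
    pairs = cmap.pairs()
    if len(pairs) == 0:
        return 0.0
    return float(u.array[code[pairs[:, 0]], code[pairs[:, 1]]].sum())


def score_bind_info(seq1: str, seq2: str, inter_cmap: ContactMap, u: ContactMatrix) -> float:
    """Contact energy across an inter-molecular (rectangular) contact map."""
    if inter_cmap.contacts.shape != (len(seq1), len(seq2)):
        raise ValueError("inter-molecular map shape does not match the sequences")
    c1 = u.encode(seq1)
    c2 = u.encode(seq2)
    pairs = np.argwhere(inter_cmap.contacts)
    if len(pairs) == 0:
        return 0.0
    return float(u.array[c1[pairs[:, 0]], c2[pairs[:, 1]]].sum())
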