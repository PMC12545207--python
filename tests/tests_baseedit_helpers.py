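"""Shared helpers for base-editing tests: toy gene models and an
independent brute-force guide-enumeration oracle."""

import numpy as np

from cropscreen.baseedit import GeneModel
from cropscreen.baseedit.models import revcomp


def random_sequence(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


def toy_gene(rng=None, n=300, seed=0):
    """Random two-exon gene model with a clean CDS (no internal stops)."""
    rng = rng or np.random.default_rng(seed)
    while True:
        seq = random_sequence(rng, n)
        third = n // 3
        e1 = (20, 20 + third)
        e2 = (n - 20 - third, n - 20)
        cds_len1 = (third // 2) // 3 * 3
        cds = [(e1[0] + 6, e1[0] + 6 + cds_len1), (e2[0], e2[0] + cds_len1)]
        try:
            return GeneModel("toy", seq, [e1, e2], cds)
        except ValueError:
            continue


def brute_force_enumeration(model, pam_mode):
    """Oracle: enumerate minus-strand guides by scanning the reverse complement."""
    seq = model.sequence
    rc = revcomp(seq)
    n = len(seq)
    found = set()
    for i in range(n - 19):
        pam = seq[i + 20 : i + 23]
        if (pam_mode == "pamless" or (len(pam) == 3 and pam[1] == "G" and pam[2] == "G")) \
                and model.overlaps_design_region(i, i + 20):
            found.add((seq[i : i + 20], "+", i))
    for j in range(n - 19):
        pam = rc[j + 20 : j + 23]
        lo = n - 20 - j  # genomic window of a minus-strand 20-mer at rc offset j
        if (pam_mode == "pamless" or (len(pam) == 3 and pam[1] == "G" and pam[2] == "G")) \
                and model.overlaps_design_region(lo, lo + 20):
            found.add((rc[j : j + 20], "-", lo))
    return found
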