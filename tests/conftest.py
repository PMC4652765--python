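"""Shared fixtures and the independent brute-force motif oracle."""

from __future__ import annotations

import numpy as np
import pytest

# -- brute-force GQ enumerator (oracle) --------------------------------------
# Deliberately naive: explicit nested loops over every 4-tract/3-loop
# decomposition, validity checked character by character.  Kept independent
# of the package scanner so the two can cross-check each other.


def brute_force_decompositions(seq, min_tract=3, loop_min=1, loop_max=7):
    seq = seq.upper()
    n = len(seq)

    def all_g(i, j):
        return all(seq[k] == "G" for k in range(i, j))

    out = set()
    for s1 in range(n):
        for e1 in range(s1 + min_tract, n + 1):
            if not all_g(s1, e1):
                break
            for g1 in range(loop_min, loop_max + 1):
                s2 = e1 + g1
                for e2 in range(s2 + min_tract, n + 1):
                    if not all_g(s2, e2):
                        break
                    for g2 in range(loop_min, loop_max + 1):
                        s3 = e2 + g2
                        for e3 in range(s3 + min_tract, n + 1):
                            if not all_g(s3, e3):
                                break
                            for g3 in range(loop_min, loop_max + 1):
                                s4 = e3 + g3
                                for e4 in range(s4 + min_tract, n + 1):
                                    if not all_g(s4, e4):
                                        break
                                    out.add(
                                        (
                                            (s1, s2, s3, s4),
                                            (e1 - s1, e2 - s2, e3 - s3, e4 - s4),
                                        )
                                    )
    return out


def random_g_rich_sequence(rng, length, n_weight=0.02):
    """Random sequence biased toward G so motifs actually occur."""
    alphabet = np.array(list("ACGTN"))
    probs = np.array([0.2, 0.2, 0.38, 0.2, n_weight])
    probs = probs / probs.sum()
    return "".join(rng.choice(alphabet, size=length, p=probs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# -- canonical construct sequences (ssDNA GQ strand) -------------------------

CONSTRUCT_SEQUENCES = {
    "1-3-3": "GGGTGGGTTTGGGTTTGGG",
    "1-4-4": "GGGTGGGTTTTGGGTTTTGGG",
    "1-5-5": "GGGTGGGTTTTTGGGTTTTTGGG",
    "TTA3": "GGGTTAGGGTTAGGGTTAGGG",
}


@pytest.fixture
def construct_sequences():
    return dict(CONSTRUCT_SEQUENCES)
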