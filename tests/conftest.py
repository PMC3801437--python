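import math

import numpy as np
import pytest

from isrekit.matrices import BASES, canonical_isre_matrix
from isrekit.promoters import reverse_complement


@pytest.fixture(scope="session")
def isre_pwm():
    return canonical_isre_matrix()


@pytest.fixture(scope="session")
def uniform_bg():
    return np.full(4, 0.25)


def random_dna(rng: np.random.Generator, n: int, p=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=list(p)))


def brute_scan_scores(seq: str, probs: np.ndarray, bg: np.ndarray):
    """Independent brute-force enumeration of PWM placement scores.

    Returns {(offset, strand): bits} over every placement on both strands,
    skipping placements that overlap a non-ACGT base.  Offsets are in
    window-forward coordinates; minus-strand scores are computed on the
    reverse complement read 5'->3'.
    """
    L = probs.shape[0]
    idx = {b: i for i, b in enumerate(BASES)}
    out = {}
    for strand in "+-":
        s = seq.upper() if strand == "+" else reverse_complement(seq).upper()
        for j in range(len(s) - L + 1):
            sub = s[j : j + L]
            if any(b not in idx for b in sub):
                continue
            score = sum(
                math.log2(probs[i][idx[b]] / bg[idx[b]]) for i, b in enumerate(sub)
            )
            off = j if strand == "+" else len(seq) - L - j
            out[(off, strand)] = score
    return out


def brute_clover_score(seqs, probs, bg, both_strands=True) -> float:
    """Independent brute-force CLOVER-style set score."""
    per_seq = []
    for seq in seqs:
        scores = brute_scan_scores(seq, probs, bg)
        lrs = [
            2.0**v
            for (off, strand), v in scores.items()
            if both_strands or strand == "+"
        ]
        per_seq.append(math.log(sum(lrs) / len(lrs)))
    return sum(per_seq) / len(per_seq)
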