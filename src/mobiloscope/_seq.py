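"""Small shared DNA-string helpers used by the simulator and the aligner."""

from __future__ import annotations

import numpy as np

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTacgtN", b"TGCAtgcaN")


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform i.i.d. DNA string of the given length."""
    if length < 0:
        raise ValueError("length must be non-negative")
    return rng.choice(_ALPHABET, size=length).tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply uniform substitutions at the given per-base rate (no indels).

    Substitutions always change the base (drawn from the three alternatives),
    so the realized divergence equals the rate in expectation.
    """
    if rate < 0 or rate > 1:
        raise ValueError("substitution rate must be in [0, 1]")
    if rate == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n == 0:
        return seq
    # shift by 1..3 positions within the alphabet: always a different base
    idx = np.searchsorted(_ALPHABET, arr[hit])
    arr[hit] = _ALPHABET[(idx + rng.integers(1, 4, size=n)) % 4]
    return arr.tobytes().decode("ascii")


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
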