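"""Small DNA-string helpers shared across the package.

Sequences are plain upper-case python strings over {A,C,G,T,N}; hot paths
work on uint8 numpy arrays with the encoding A=0, C=1, G=2, T=3, N=4.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"

_COMP = str.maketrans("ACGTN", "TGCAN")

# byte -> code lookup; anything outside ACGT maps to 4 (N)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0,C=1,G=2,T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def mutate_bernoulli(arr: np.ndarray, rate: float, rng: np.random.Generator,
                     protect: np.ndarray | None = None) -> np.ndarray:
    """Per-site substitutions at probability `rate`; N positions untouched.

    The substituted base is drawn uniformly from the three alternatives.
    `protect` is an optional boolean mask of positions never mutated.
    """
    out = arr.copy()
    mask = rng.random(arr.size) < rate
    mask &= arr < 4
    if protect is not None:
        mask &= ~protect
    idx = np.nonzero(mask)[0]
    if idx.size:
        out[idx] = (out[idx] + rng.integers(1, 4, size=idx.size, dtype=np.uint8)) % 4
    return out


def mutate_exact(arr: np.ndarray, n_subs: int, rng: np.random.Generator,
                 protect: np.ndarray | None = None) -> np.ndarray:
    """Apply exactly `n_subs` substitutions at distinct eligible positions."""
    eligible = arr < 4
    if protect is not None:
        eligible &= ~protect
    pos = np.nonzero(eligible)[0]
    if n_subs > pos.size:
        raise ValueError(f"cannot place {n_subs} substitutions in {pos.size} eligible sites")
    out = arr.copy()
    chosen = rng.choice(pos, size=n_subs, replace=False)
    out[chosen] = (out[chosen] + rng.integers(1, 4, size=n_subs, dtype=np.uint8)) % 4
    return out


def find_n_runs(seq: str, min_len: int = 1) -> list[tuple[int, int]]:
    """0-based half-open intervals of N runs of at least `min_len`."""
    arr = encode(seq) == 4
    if not arr.any():
        return []
    padded = np.concatenate(([False], arr, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]
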