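"""Canonical k-mer primitives shared by the pipeline phases.

A canonical k-mer is the lexicographic minimum of a k-mer and its reverse
complement, which makes every downstream summary strand-invariant.  Three
representations coexist:

* canonical k-mer **strings** — used for the long (w = 36) uniqueness
  fingerprints of virtual contigs, where 4**w overflows machine integers;
* canonical k-mer **codes** — base-4 integer encodings (k <= 31 fits in
  int64), used for the short seed k-mers of the reference index;
* canonical **index tables** — dense lookup from any base-4 q-mer code to
  its canonical slot, used to accumulate q-mer composition profiles.

Windows containing N are skipped everywhere: an ambiguous base must never
manufacture a match.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"
# byte value -> base code; N (and anything else) -> 4 so it poisons windows
_BYTE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BYTE_CODE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(sequence: str, k: int) -> set[str]:
    """Set of canonical k-mer strings of ``sequence``.

    Every length-k window free of N is replaced by min(window,
    revcomp(window)).  A sequence shorter than k yields the empty set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    if n < k:
        return set()
    rc = revcomp(seq)
    has_n = "N" in seq
    out: set[str] = set()
    for i in range(n - k + 1):
        km = seq[i : i + k]
        if has_n and "N" in km:
            continue
        rkm = rc[n - k - i : n - i]
        out.add(km if km <= rkm else rkm)
    return out


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence to int64 base codes (A=0,C=1,G=2,T=3; other=4)."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _BYTE_CODE[raw]


def canonical_codes(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of ``seq`` (requires k <= 31).

    The code of a window is its base-4 value; the canonical code is the
    minimum of the window's code and its reverse complement's code.
    Windows containing N are dropped.
    """
    if not 1 <= k <= 31:
        raise ValueError("canonical_codes requires 1 <= k <= 31")
    b = encode_bases(seq)
    n = b.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.int64)
    rev = np.zeros(m, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    for j in range(k):
        col = b[j : j + m]
        valid &= col < 4
        # forward: position j contributes 4^(k-1-j)
        fwd += np.where(col < 4, col, 0) * (4 ** (k - 1 - j))
        # reverse complement: complement of position j lands at weight 4^j
        rev += np.where(col < 4, 3 - col, 0) * (4**j)
    canon = np.minimum(fwd, rev)[valid]
    return np.unique(canon)


@lru_cache(maxsize=None)
def canonical_index(q: int) -> tuple[np.ndarray, tuple[str, ...]]:
    """Canonical slot table for q-mers.

    Returns ``(lut, kmers)`` where ``kmers`` is the lexicographically
    sorted tuple of canonical q-mer strings (dimension 136 for q=4, 512
    for q=5) and ``lut`` maps any base-4 q-mer code to the index of its
    canonical representative in ``kmers``.
    """
    all_kmers = ["".join(p) for p in product(_BASES, repeat=q)]
    canon = sorted({min(k, revcomp(k)) for k in all_kmers})
    slot = {k: i for i, k in enumerate(canon)}
    lut = np.empty(4**q, dtype=np.int64)
    for code, km in enumerate(all_kmers):
        lut[code] = slot[min(km, revcomp(km))]
    return lut, tuple(canon)


def profile_dimension(q: int) -> int:
    return len(canonical_index(q)[1])


def count_qmers_in_wmers(wmers, q: int, w: int | None = None) -> np.ndarray:
    """Canonical q-mer occurrence counts over a collection of w-mers.

    Each w-mer contributes its ``w - q + 1`` windows; counting over the
    *distinct* w-mer set of a virtual contig is what removes duplicate
    read coverage from the composition estimate.  All w-mers must share
    one length and be N-free (guaranteed by :func:`canonical_kmers`).
    """
    wlist = sorted(wmers) if not isinstance(wmers, (list, tuple)) else list(wmers)
    if not wlist:
        return np.zeros(profile_dimension(q), dtype=np.int64)
    if w is None:
        w = len(wlist[0])
    blob = "".join(wlist)
    b = encode_bases(blob).reshape(len(wlist), w)
    if (b >= 4).any():
        raise ValueError("w-mers must be N-free")
    m = w - q + 1
    codes = np.zeros((len(wlist), m), dtype=np.int64)
    for j in range(q):
        codes += b[:, j : j + m] * (4 ** (q - 1 - j))
    lut, canon = canonical_index(q)
    return np.bincount(lut[codes.ravel()], minlength=len(canon))
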