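"""Fixed-length strings over a finite alphabet and Hamming-ball combinatorics.

Everything downstream (consensus decisions, samplers, the window graph)
reduces to Hamming distances between equal-length strings. For power-of-two
alphabets (DNA, binary) strings are packed into single 64-bit words, so a
distance is an XOR, a bit-fold and a popcount; packing is MSB-first with
symbols in alphabet order, which makes integer order coincide with
lexicographic order — a property the consensus search relies on to break
witness ties deterministically.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations, product
from math import comb

import numpy as np

__all__ = [
    "Alphabet",
    "DNA",
    "BINARY",
    "PackedSpace",
    "hamming",
    "ball_size",
    "enumerate_ball",
    "sample_ball_uniform",
    "as_code_matrix",
]


class Alphabet:
    """An ordered alphabet of distinct single-character symbols."""

    def __init__(self, symbols: str):
        if len(symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")
        if len(set(symbols)) != len(symbols):
            raise ValueError("alphabet symbols must be distinct")
        self.symbols = str(symbols)
        self._index = {c: i for i, c in enumerate(symbols)}
        # case-insensitive lookup when unambiguous (DNA practice: acgt == ACGT)
        for c, i in list(self._index.items()):
            for alt in (c.lower(), c.upper()):
                self._index.setdefault(alt, i)
        self._decode = np.frombuffer(symbols.encode("ascii"), dtype=np.uint8)

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def is_power_of_two(self) -> bool:
        return self.size & (self.size - 1) == 0

    def encode(self, s: str) -> np.ndarray:
        """Map a string to a uint8 code vector; raises on foreign characters."""
        try:
            return np.array([self._index[c] for c in s], dtype=np.uint8)
        except KeyError as e:
            raise ValueError(
                f"character {e.args[0]!r} not in alphabet {self.symbols!r}"
            ) from None

    def decode(self, codes: np.ndarray) -> str:
        return self._decode[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alphabet({self.symbols!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Alphabet) and other.symbols == self.symbols

    def __hash__(self) -> int:
        return hash(self.symbols)


DNA = Alphabet("ACGT")
BINARY = Alphabet("01")


def infer_alphabet(strings) -> Alphabet:
    chars = set().union(*(set(s.upper()) for s in strings))
    if chars <= set("ACGT"):
        return DNA
    if chars <= set("01"):
        return BINARY
    raise ValueError(f"cannot infer alphabet for characters {sorted(chars)}")


def as_code_matrix(strings, alphabet: Alphabet | None = None):
    """Normalise a sequence of equal-length strings (or a code matrix) to
    an (n, l) uint8 matrix plus its alphabet."""
    if isinstance(strings, np.ndarray):
        if alphabet is None:
            raise ValueError("alphabet required for a raw code matrix")
        codes = np.atleast_2d(np.asarray(strings, dtype=np.uint8))
        if (codes >= alphabet.size).any():
            raise ValueError("code matrix contains values outside the alphabet")
        return codes, alphabet
    strings = list(strings)
    if not strings:
        raise ValueError("empty string set")
    if alphabet is None:
        alphabet = infer_alphabet(strings)
    lens = {len(s) for s in strings}
    if len(lens) != 1:
        raise ValueError(f"strings must share one length, got lengths {sorted(lens)}")
    return np.stack([alphabet.encode(s) for s in strings]), alphabet


# ---------------------------------------------------------------------------
# scalar operations


def hamming(a, b, alphabet: Alphabet | None = None) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if isinstance(a, str) != isinstance(b, str):
        raise ValueError("hamming arguments must both be strings or both code arrays")
    if isinstance(a, str):
        if len(a) != len(b):
            raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
        alpha = alphabet or infer_alphabet([a, b])
        return int(np.count_nonzero(alpha.encode(a) != alpha.encode(b)))
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def ball_size(l: int, d: int, sigma: int = 4) -> int:
    """|B(c, d)| = sum_{k<=d} C(l,k) (sigma-1)^k, for any center c."""
    if not 0 <= d <= l:
        raise ValueError(f"need 0 <= d <= l, got d={d}, l={l}")
    if sigma < 2:
        raise ValueError("sigma >= 2 required")
    return sum(comb(l, k) * (sigma - 1) ** k for k in range(d + 1))


@lru_cache(maxsize=64)
def _ball_class_probs(l: int, r: int, sigma: int):
    """P(distance-to-center = k) for k = 0..r under the uniform ball law."""
    w = np.array([comb(l, k) * (sigma - 1) ** k for k in range(r + 1)], dtype=float)
    return w / w.sum()


def enumerate_ball(center, radius: int, alphabet: Alphabet | None = None):
    """Yield every string at Hamming distance <= radius from ``center``, once.

    Order is: by distance class, positions in combination order, substituted
    symbols in alphabet order (not globally lexicographic).
    """
    if isinstance(center, str):
        alpha = alphabet or infer_alphabet([center])
        codes = alpha.encode(center)
    else:
        if alphabet is None:
            raise ValueError("alphabet required for code-array center")
        alpha, codes = alphabet, np.asarray(center, dtype=np.uint8)
    l = len(codes)
    if not 0 <= radius <= l:
        raise ValueError(f"radius must be in [0, {l}]")
    others = [
        [s for s in range(alpha.size) if s != c] for c in codes
    ]
    yield alpha.decode(codes)
    for k in range(1, radius + 1):
        for pos in combinations(range(l), k):
            for vals in product(*(others[p] for p in pos)):
                out = codes.copy()
                out[list(pos)] = vals
                yield alpha.decode(out)


def sample_ball_uniform(center, radius: int, rng, alphabet: Alphabet | None = None, size=None):
    """Draw uniformly from the Hamming ball around ``center``.

    Exactly uniform without enumerating the ball: the mutation count k is
    drawn with probability C(l,k)(sigma-1)^k / |B|, then a uniform k-subset of
    positions, then an independent uniform non-center symbol at each.
    """
    if isinstance(center, str):
        alpha = alphabet or infer_alphabet([center])
        codes = alpha.encode(center)
    else:
        if alphabet is None:
            raise ValueError("alphabet required for code-array center")
        alpha, codes = alphabet, np.asarray(center, dtype=np.uint8)
    l = len(codes)
    if not 0 <= radius <= l:
        raise ValueError(f"radius must be in [0, {l}]")
    probs = _ball_class_probs(l, radius, alpha.size)
    n = 1 if size is None else int(size)
    out = np.broadcast_to(codes, (n, l)).copy()
    ks = rng.choice(radius + 1, size=n, p=probs)
    for row, k in enumerate(ks):
        if k == 0:
            continue
        pos = rng.choice(l, size=k, replace=False)
        # uniform over the sigma-1 symbols differing from the center's
        out[row, pos] = (codes[pos] + 1 + rng.integers(0, alpha.size - 1, size=k)) % alpha.size
    strings = [alpha.decode(row) for row in out]
    return strings[0] if size is None else strings


# ---------------------------------------------------------------------------
# packed engine (power-of-two alphabets)


class PackedSpace:
    """Length-l strings over a 2^b-symbol alphabet packed into uint64 words.

    Symbol i of the string occupies bits [b*(l-1-i), b*(l-i)) — MSB-first —
    so unsigned integer comparison of packed values equals lexicographic
    comparison of the strings. XOR of two packed values has a nonzero field
    exactly at mismatching positions, giving a word-parallel Hamming distance.
    """

    #: refuse to materialise balls bigger than this many masks (~4 GB)
    MAX_BALL = 500_000_000

    def __init__(self, length: int, alphabet: Alphabet = DNA):
        if not alphabet.is_power_of_two:
            raise ValueError("PackedSpace requires a power-of-two alphabet size")
        bits = (alphabet.size - 1).bit_length()
        if length * bits > 63:
            raise ValueError(f"l={length} with {bits}-bit symbols exceeds one word")
        self.l = int(length)
        self.alphabet = alphabet
        self.sigma = alphabet.size
        self.bits = bits
        self.shifts = (bits * (length - 1 - np.arange(length))).astype(np.uint64)
        lsb = np.uint64(0)
        for s in self.shifts:
            lsb |= np.uint64(1) << s
        self._lsb_mask = lsb
        self._mask_cache: dict[int, np.ndarray] = {}

    # -- conversions ------------------------------------------------------

    def pack(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes, dtype=np.uint64)
        return (codes << self.shifts).sum(axis=-1, dtype=np.uint64)

    def unpack(self, packed: np.ndarray) -> np.ndarray:
        packed = np.asarray(packed, dtype=np.uint64)
        sym_mask = np.uint64(self.sigma - 1)
        return ((packed[..., None] >> self.shifts) & sym_mask).astype(np.uint8)

    def pack_str(self, s: str) -> np.uint64:
        return self.pack(self.alphabet.encode(s))

    def decode(self, packed) -> str:
        return self.alphabet.decode(self.unpack(packed))

    def pack_windows(self, codes: np.ndarray) -> np.ndarray:
        """Packed values of every length-l window of a longer code vector."""
        m = len(codes)
        if m < self.l:
            raise ValueError(f"sequence of length {m} shorter than l={self.l}")
        out = np.zeros(m - self.l + 1, dtype=np.uint64)
        for i in range(self.l):
            out |= codes[i : m - self.l + 1 + i].astype(np.uint64) << self.shifts[i]
        return out

    # -- distances --------------------------------------------------------

    def hamming(self, a, b) -> np.ndarray:
        """Elementwise (broadcasting) Hamming distance of packed values."""
        x = np.bitwise_xor(np.asarray(a, dtype=np.uint64), np.asarray(b, dtype=np.uint64))
        folded = x
        for s in range(1, self.bits):
            folded = folded | (x >> np.uint64(s))
        return np.bitwise_count(folded & self._lsb_mask)

    # -- balls ------------------------------------------------------------

    def ball_masks(self, radius: int) -> np.ndarray:
        """All XOR masks delta with weight(delta) <= radius: B(c,r) = c ^ masks.

        Masks are materialised once per radius and cached; they are shared by
        every center, which is what makes repeated consensus scans cheap.
        """
        if radius not in self._mask_cache:
            n_masks = ball_size(self.l, radius, self.sigma)
            if n_masks > self.MAX_BALL:
                raise ValueError(
                    f"ball of size {n_masks} at (l={self.l}, r={radius}) too large to enumerate"
                )
            chunks = [np.zeros(1, dtype=np.uint64)]
            nonzero = np.arange(1, self.sigma, dtype=np.uint64)
            for k in range(1, radius + 1):
                pos_sets = np.array(list(combinations(range(self.l), k)), dtype=np.int64)
                # all (sigma-1)^k substitution patterns as base-(sigma-1) digits
                n_vals = (self.sigma - 1) ** k
                digits = np.empty((n_vals, k), dtype=np.uint64)
                idx = np.arange(n_vals)
                for col in range(k):
                    digits[:, col] = nonzero[(idx // (self.sigma - 1) ** col) % (self.sigma - 1)]
                shifts = self.shifts[pos_sets]  # (C, k)
                masks = (digits[None, :, :] << shifts[:, None, :]).sum(axis=2, dtype=np.uint64)
                chunks.append(masks.ravel())
            self._mask_cache[radius] = np.concatenate(chunks)
        return self._mask_cache[radius]

    def sample_ball(self, centers, radius: int, rng) -> np.ndarray:
        """One uniform ball draw per entry of ``centers`` (packed, any shape)."""
        centers = np.asarray(centers, dtype=np.uint64)
        size = centers.size
        if size == 0:
            return centers.copy()
        probs = _ball_class_probs(self.l, radius, self.sigma)
        ks = rng.choice(radius + 1, size=size, p=probs)
        # uniform k-subset of positions via the random-key argsort trick
        order = np.argsort(rng.random((size, self.l)), axis=1)
        sel = np.arange(self.l)[None, :] < ks[:, None]
        vals = rng.integers(1, self.sigma, size=(size, self.l), dtype=np.uint64)
        masks = np.zeros(size, dtype=np.uint64)
        rows = np.broadcast_to(np.arange(size)[:, None], (size, self.l))
        np.bitwise_or.at(
            masks, rows[sel], vals[sel] << self.shifts[order[sel]]
        )
        return (centers.ravel() ^ masks).reshape(centers.shape)

    def random(self, size, rng) -> np.ndarray:
        """Uniform packed strings."""
        codes = rng.integers(0, self.sigma, size=(int(np.prod(size)), self.l), dtype=np.uint8)
        return self.pack(codes).reshape(size)


@lru_cache(maxsize=32)
def packed_space(length: int, alphabet: Alphabet = DNA) -> PackedSpace:
    """Shared PackedSpace instances so ball-mask tables are built once per
    (length, alphabet) — the consensus scan at (18, 6) alone owns ~16M
    masks, which must not be regenerated per call."""
    return PackedSpace(length, alphabet)
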