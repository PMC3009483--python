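"""Set-level definitions and the exact consensus-string (radius) decision.

A set S of l-length strings is *pairwise bounded* for a radius d when every
pair is within Hamming distance 2d; it is a *motif set* when some string c
(the consensus) is within d of every member, and a *decoy set* when it is
pairwise bounded but has no consensus. The *weight* of S is the sum of all
pairwise Hamming distances. Deciding consensus existence is NP-complete in
general; here it is solved exactly by scanning the radius-d ball around one
member, which is complete because any consensus lies within d of every
member, in particular the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqcore import Alphabet, as_code_matrix, enumerate_ball, packed_space

__all__ = ["ConsensusResult", "weight", "is_pairwise_bounded", "consensus_exists"]

_CHUNK = 1 << 22  # candidate strings filtered per block


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of the exact consensus decision.

    When witnesses exist, ``witness`` is the best-fitting one: smallest
    maximum distance to the members, ties broken by lexicographic order.
    ``max_distance`` is that witness's largest distance to any member (<= d).
    """

    exists: bool
    witness: str | None = None
    max_distance: int | None = None


def _pairwise_distance_matrix(codes: np.ndarray) -> np.ndarray:
    return np.count_nonzero(codes[:, None, :] != codes[None, :, :], axis=2)


def weight(strings, alphabet: Alphabet | None = None) -> int:
    """Sum of Hamming distances over all unordered pairs of the set."""
    codes, _ = as_code_matrix(strings, alphabet)
    dm = _pairwise_distance_matrix(codes)
    return int(dm.sum() // 2)


def is_pairwise_bounded(strings, d: int, alphabet: Alphabet | None = None) -> bool:
    """True iff every pair of strings is within Hamming distance 2d."""
    codes, _ = as_code_matrix(strings, alphabet)
    return bool(_pairwise_distance_matrix(codes).max(initial=0) <= 2 * d)


def consensus_exists(strings, d: int, alphabet: Alphabet | None = None) -> ConsensusResult:
    """Exact decision: does some string sit within distance d of every member?

    Scans B(s_1, d), rejecting candidates string by string with the members
    ordered by decreasing distance to s_1 so that most candidates die on the
    first comparison. Invariant to permutations of the input.
    """
    codes, alpha = as_code_matrix(strings, alphabet)
    n, l = codes.shape
    if not 0 <= d <= l:
        raise ValueError(f"need 0 <= d <= l, got d={d}, l={l}")
    if alpha.is_power_of_two and (alpha.size - 1).bit_length() * l <= 63:
        return _consensus_packed(codes, d, alpha)
    return _consensus_generic(codes, d, alpha)


def _consensus_packed(codes: np.ndarray, d: int, alpha: Alphabet) -> ConsensusResult:
    space = packed_space(codes.shape[1], alpha)
    packed = space.pack(codes)
    d1 = space.hamming(packed[0], packed)
    order = np.argsort(-d1, kind="stable")
    masks = space.ball_masks(d)
    best = None  # (max distance, packed value): tightest witness, then lex
    for lo in range(0, len(masks), _CHUNK):
        cands = packed[0] ^ masks[lo : lo + _CHUNK]
        for i in order:
            cands = cands[space.hamming(cands, packed[i]) <= d]
            if cands.size == 0:
                break
        if cands.size:
            maxd = space.hamming(cands[:, None], packed[None, :]).max(axis=1)
            k = np.lexsort((cands, maxd))[0]
            cand_best = (int(maxd[k]), int(cands[k]))
            best = cand_best if best is None else min(best, cand_best)
    if best is None:
        return ConsensusResult(False)
    return ConsensusResult(
        True,
        witness=space.decode(np.uint64(best[1])),
        max_distance=best[0],
    )


def _consensus_generic(codes: np.ndarray, d: int, alpha: Alphabet) -> ConsensusResult:
    # plain ball scan for alphabets without a packed representation
    best = None  # (max distance, string)
    for cand in enumerate_ball(codes[0], d, alpha):
        cc = alpha.encode(cand)
        dists = np.count_nonzero(cc != codes, axis=1)
        if dists.max() <= d:
            key = (int(dists.max()), cand)
            best = key if best is None else min(best, key)
    if best is None:
        return ConsensusResult(False)
    return ConsensusResult(True, witness=best[1], max_distance=best[0])
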