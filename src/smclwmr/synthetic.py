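"""Planted (l, d)-motif instance generation and the success metric.

An instance hides a uniform random l-mer consensus: each of n occurrences
mutates the consensus at exactly d uniformly chosen positions, but the
replacement base is drawn uniformly from all four bases — a "mutation" may
silently restore the original, so realised distances are *at most* d with
mean 3d/4 substitutions. Each occurrence overwrites a uniformly placed
window of an i.i.d.-uniform background string of length m (default 600).
Recovery is scored with the performance coefficient |K ∩ P| / |K ∪ P| over
planted (K) versus predicted (P) base positions, one occurrence per string.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqcore import DNA

__all__ = ["PlantedInstance", "SuccessScore", "generate_instance",
           "success_rate", "run_benchmark"]

DEFAULT_M = 600


@dataclass(frozen=True)
class PlantedInstance:
    """Background strings with a hidden planted motif (the ground truth)."""

    strings: tuple  # n sequences of length m
    consensus: str  # hidden consensus, length l
    offsets: tuple  # n planted 0-based offsets
    n: int
    m: int
    l: int
    d: int
    seed: int | None = None


@dataclass(frozen=True)
class SuccessScore:
    """Performance coefficient |K ∩ P| / |K ∪ P| over base positions."""

    value: float
    k_size: int
    p_size: int
    intersection: int


def generate_instance(n: int, m: int, l: int, d: int, seed=None) -> PlantedInstance:
    """One planted (l, d) instance; deterministic for a fixed seed."""
    if m < l:
        raise ValueError(f"need m >= l, got m={m}, l={l}")
    if not 0 <= d <= l:
        raise ValueError(f"need 0 <= d <= l, got d={d}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cons = rng.integers(0, 4, size=l, dtype=np.uint8)
    strings = rng.integers(0, 4, size=(n, m), dtype=np.uint8)
    offsets = rng.integers(0, m - l + 1, size=n)
    for i in range(n):
        occ = cons.copy()
        if d:
            pos = rng.choice(l, size=d, replace=False)
            occ[pos] = rng.integers(0, 4, size=d, dtype=np.uint8)
        strings[i, offsets[i] : offsets[i] + l] = occ
    return PlantedInstance(
        strings=tuple(DNA.decode(row) for row in strings),
        consensus=DNA.decode(cons),
        offsets=tuple(int(o) for o in offsets),
        n=n, m=m, l=l, d=d,
        seed=seed if isinstance(seed, int) else None,
    )


def success_rate(truth: PlantedInstance, predicted) -> SuccessScore:
    """Score predicted occurrences (at most one offset per string).

    ``predicted`` maps string index -> 0-based offset (dict, or a sequence
    of (i, j) pairs such as MotifReport.occurrences, or an array of offsets
    for all strings).
    """
    if isinstance(predicted, dict):
        pairs = predicted.items()
    else:
        predicted = list(predicted)
        if predicted and np.isscalar(predicted[0]):
            pairs = enumerate(predicted)
        else:
            pairs = predicted
    K = {
        (i, c)
        for i, off in enumerate(truth.offsets)
        for c in range(off, off + truth.l)
    }
    P = set()
    seen = set()
    for i, j in pairs:
        i, j = int(i), int(j)
        if i in seen:
            raise ValueError(f"multiple predictions for string {i}")
        seen.add(i)
        if not (0 <= i < truth.n and 0 <= j <= truth.m - truth.l):
            raise ValueError(f"prediction ({i}, {j}) out of range")
        P.update((i, c) for c in range(j, j + truth.l))
    inter = len(K & P)
    union = len(K | P)
    return SuccessScore(inter / union if union else 1.0, len(K), len(P), inter)


def run_benchmark(cells, instances_per_cell: int, n: int, m: int, seed: int,
                  finder_factory=None, **finder_params) -> pd.DataFrame:
    """Mean success of the full pipeline over a grid of (l, d) cells.

    Per-instance failures (no motif reported) score 0 and are flagged.
    Returns one row per cell: l, d, instances, mean_success, failures.
    """
    from .pipeline import MotifFinder  # deferred: heavy import chain

    ss = np.random.SeedSequence(seed)
    records = []
    for l, d in cells:
        scores = []
        failures = 0
        for child in ss.spawn(instances_per_cell):
            inst_rng = np.random.default_rng(child)
            inst = generate_instance(n, m, l, d, inst_rng)
            if finder_factory is not None:
                finder = finder_factory(l, d)
            else:
                finder = MotifFinder(l=l, d=d, **finder_params)
            finder.fit(list(inst.strings))
            if finder.reports_:
                scores.append(
                    success_rate(inst, finder.reports_[0].occurrences).value
                )
            else:
                scores.append(0.0)
                failures += 1
        records.append(
            {
                "l": l,
                "d": d,
                "instances": instances_per_cell,
                "mean_success": float(np.mean(scores)),
                "failures": failures,
            }
        )
    return pd.DataFrame.from_records(records)
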