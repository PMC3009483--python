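"""Weight-distribution estimation and the statistical threshold classifier.

The consensus-string decision is NP-complete, but the *weight* of a
pairwise-bounded set (the sum of its pairwise Hamming distances) is cheap.
If the weight laws W_m of random motif sets and W_d of random decoy sets are
well separated, the weight alone classifies most sets: fit normals
N(mu_m, sd_m^2) and N(mu_d, sd_d^2), place alpha_m at the upper 1% tail of
W_m and alpha_d at the lower 1% tail of W_d (both floored to integers), and
label a set MOTIF when w <= alpha_m, DECOY when w >= alpha_d. When
alpha_m < alpha_d fails, the weight carries too little signal and every set
must go to the exact decision instead — the classifier reports this rather
than guessing. (Under uniform decoy sampling the two laws overlap
substantially at (l=15, d=4, n=20), so the deferring path is the honest
common case there; see docs/methods.md.)
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .samplers import (
    GIBBS_SWEEPS,
    _set_weights,
    decoy_sets_packed,
    motif_sets_packed,
)
from .seqcore import DNA, Alphabet, packed_space

__all__ = [
    "MOTIF",
    "DECOY",
    "AMBIGUOUS",
    "WeightDistribution",
    "ThresholdEntry",
    "UnseparatedThresholdsError",
    "estimate_weight_distribution",
    "compute_thresholds",
    "classify_by_weight",
    "ThresholdTable",
    "WeightThresholdClassifier",
]

MOTIF = "motif"
DECOY = "decoy"
AMBIGUOUS = "ambiguous"

#: 99th percentile of the standard normal; tail mass 0.01 on each side
DEFAULT_TAIL = 0.01


@dataclass(frozen=True)
class WeightDistribution:
    """Sample mean/sd of the weight of one class of random sets."""

    class_label: str  # MOTIF or DECOY
    l: int
    d: int
    n: int
    mean: float
    sd: float
    n_samples: int


@dataclass(frozen=True)
class ThresholdEntry:
    """One row of the pre-calculated threshold table."""

    l: int
    d: int
    n: int
    mu_m: float
    sd_m: float
    mu_d: float
    sd_d: float
    alpha_m: int
    alpha_d: int
    n_samples: int = 0
    seed: int | None = None

    @property
    def separated(self) -> bool:
        return self.alpha_m < self.alpha_d


class UnseparatedThresholdsError(ValueError):
    """The fitted weight distributions overlap (alpha_m >= alpha_d); weight
    classification is unusable and callers must fall back to the exact
    consensus decision."""


def estimate_weight_distribution(class_label: str, l: int, d: int, n: int,
                                 n_samples: int, rng,
                                 method: str = "auto",
                                 sweeps: int = GIBBS_SWEEPS,
                                 alphabet: Alphabet = DNA) -> WeightDistribution:
    """Sample mean and sd (n-1 denominator) of the weight over freshly
    sampled motif or decoy sets."""
    if n_samples < 2:
        raise ValueError("n_samples >= 2 required")
    space = packed_space(l, alphabet)
    if class_label == MOTIF:
        _, sets = motif_sets_packed(space, d, n, n_samples, rng)
    elif class_label == DECOY:
        sets, _ = decoy_sets_packed(space, d, n, n_samples, rng,
                                    method=method, sweeps=sweeps)
    else:
        raise ValueError(f"unknown class label {class_label!r}")
    w = _set_weights(space, sets).astype(float)
    return WeightDistribution(class_label, l, d, n, float(w.mean()),
                              float(w.std(ddof=1)), n_samples)


def compute_thresholds(wm: WeightDistribution, wd: WeightDistribution,
                       tail: float = DEFAULT_TAIL,
                       n_samples: int = 0, seed: int | None = None) -> ThresholdEntry:
    """Tail points of the fitted normals, floored to integers.

    alpha_m carries ``tail`` upper-tail mass under N(mu_m, sd_m^2) and
    alpha_d the same lower-tail mass under N(mu_d, sd_d^2), so a fresh
    motif (decoy) set receives the *wrong* definite label with probability
    at most ~``tail`` under the normal fit.
    """
    if (wm.l, wm.d, wm.n) != (wd.l, wd.d, wd.n):
        raise ValueError("motif and decoy distributions disagree on (l, d, n)")
    if not 0 < tail < 0.5:
        raise ValueError("tail must be in (0, 0.5)")
    if wm.sd <= 0 and wd.sd <= 0 and wm.mean == wd.mean:
        raise ValueError("degenerate distributions: identical point masses")
    z = float(norm.ppf(1 - tail))
    return ThresholdEntry(
        l=wm.l, d=wm.d, n=wm.n,
        mu_m=wm.mean, sd_m=wm.sd, mu_d=wd.mean, sd_d=wd.sd,
        alpha_m=floor(wm.mean + z * wm.sd),
        alpha_d=floor(wd.mean - z * wd.sd),
        n_samples=n_samples, seed=seed,
    )


def classify_by_weight(w: int, entry: ThresholdEntry) -> str:
    """MOTIF if w <= alpha_m, DECOY if w >= alpha_d, else AMBIGUOUS.

    Requires a separated entry; otherwise raises so that the caller routes
    the set to the exact consensus decision.
    """
    if not entry.separated:
        raise UnseparatedThresholdsError(
            f"thresholds at (l={entry.l}, d={entry.d}, n={entry.n}) are not "
            f"separated (alpha_m={entry.alpha_m} >= alpha_d={entry.alpha_d}); "
            "use the exact consensus decision"
        )
    if w <= entry.alpha_m:
        return MOTIF
    if w >= entry.alpha_d:
        return DECOY
    return AMBIGUOUS


# ---------------------------------------------------------------------------
# threshold table


_COLUMNS = ["l", "d", "n", "mu_m", "sd_m", "mu_d", "sd_d",
            "alpha_m", "alpha_d", "n_samples", "seed"]


class ThresholdTable:
    """A persisted set of ThresholdEntry rows keyed by (l, d, n).

    Lookups of absent tuples optionally fall back to on-the-fly estimation
    (1000 samples per class by default), with a logged warning.
    """

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = pd.DataFrame(columns=_COLUMNS)
        self.frame = frame.reset_index(drop=True)
        self._index = {
            (int(r.l), int(r.d), int(r.n)): i
            for i, r in self.frame.iterrows()
        }

    # -- construction -----------------------------------------------------

    @classmethod
    def load(cls, path) -> "ThresholdTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def default(cls) -> "ThresholdTable":
        """The table shipped with the package, regenerated by
        scripts/build_table.py from this implementation's own samplers."""
        ref = importlib.resources.files("smclwmr") / "data" / "default_thresholds.tsv"
        with importlib.resources.as_file(ref) as p:
            return cls.load(p)

    @staticmethod
    def reference_frame() -> pd.DataFrame:
        """Reference weight statistics published for the original sMCL-WMR
        program, for comparison only (several rows are internally
        inconsistent; see docs/methods.md)."""
        ref = importlib.resources.files("smclwmr") / "data" / "reference_thresholds.tsv"
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", comment="#")

    def save(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    # -- access -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def get(self, l: int, d: int, n: int) -> ThresholdEntry | None:
        i = self._index.get((l, d, n))
        if i is None:
            return None
        r = self.frame.loc[i]
        return ThresholdEntry(
            l=int(r.l), d=int(r.d), n=int(r.n),
            mu_m=float(r.mu_m), sd_m=float(r.sd_m),
            mu_d=float(r.mu_d), sd_d=float(r.sd_d),
            alpha_m=int(r.alpha_m), alpha_d=int(r.alpha_d),
            n_samples=int(r.get("n_samples", 0)),
            seed=None if pd.isna(r.get("seed")) else int(r.get("seed")),
        )

    def add(self, entry: ThresholdEntry) -> None:
        row = {c: getattr(entry, c) for c in _COLUMNS}
        if self.frame.empty:
            self.frame = pd.DataFrame([row])
        else:
            self.frame = pd.concat(
                [self.frame, pd.DataFrame([row])], ignore_index=True
            )
        self._index[(entry.l, entry.d, entry.n)] = len(self.frame) - 1

    def lookup(self, l: int, d: int, n: int, rng=None,
               n_samples: int = 1000, tail: float = DEFAULT_TAIL,
               sweeps: int = GIBBS_SWEEPS) -> ThresholdEntry:
        """Return the (l, d, n) entry, estimating it on the fly when absent."""
        entry = self.get(l, d, n)
        if entry is not None:
            return entry
        if rng is None:
            raise KeyError(f"no threshold entry for (l={l}, d={d}, n={n}) "
                           "and no rng supplied for on-the-fly estimation")
        warnings.warn(
            f"threshold entry (l={l}, d={d}, n={n}) absent; estimating from "
            f"{n_samples} samples per class", stacklevel=2
        )
        wm = estimate_weight_distribution(MOTIF, l, d, n, n_samples, rng)
        wd = estimate_weight_distribution(DECOY, l, d, n, n_samples, rng,
                                          sweeps=sweeps)
        entry = compute_thresholds(wm, wd, tail=tail, n_samples=n_samples)
        self.add(entry)
        return entry

    @classmethod
    def build(cls, tuples, n_samples: int, rng, tail: float = DEFAULT_TAIL,
              sweeps: int = GIBBS_SWEEPS, seed: int | None = None) -> "ThresholdTable":
        """Estimate entries for every (l, d, n); per-tuple sampler failures
        are recorded as warnings, not fatal to the rest of the table."""
        table = cls()
        for l, d, n in tuples:
            try:
                wm = estimate_weight_distribution(MOTIF, l, d, n, n_samples, rng)
                wd = estimate_weight_distribution(DECOY, l, d, n, n_samples, rng,
                                                 sweeps=sweeps)
                table.add(compute_thresholds(wm, wd, tail=tail,
                                             n_samples=n_samples, seed=seed))
            except Exception as e:  # noqa: BLE001 — per-tuple isolation
                warnings.warn(f"threshold estimation failed at ({l},{d},{n}): {e}")
        return table


# ---------------------------------------------------------------------------
# estimator facade


class WeightThresholdClassifier(BaseEstimator):
    """Weight-threshold classifier for pairwise-bounded string sets.

    scikit-learn style: ``fit`` either consumes labelled training weights
    (X = weights, y = 'motif'/'decoy' labels) or, when called without data,
    samples its own training sets at (l, d, n); ``predict`` maps weights to
    'motif' / 'decoy' / 'ambiguous'.

    Parameters
    ----------
    l, d, n : problem parameters (string length, radius, set size).
    n_samples : training sets per class when fit() samples its own data.
    tail : normal tail mass placed outside each threshold (default 0.01).
    method : decoy sampling route, 'auto' | 'rejection' | 'gibbs'.
    random_state : seed for self-sampled training data.
    """

    def __init__(self, l: int = 15, d: int = 4, n: int = 20,
                 n_samples: int = 1000, tail: float = DEFAULT_TAIL,
                 method: str = "auto", sweeps: int = GIBBS_SWEEPS,
                 random_state: int | None = None):
        self.l = l
        self.d = d
        self.n = n
        self.n_samples = n_samples
        self.tail = tail
        self.method = method
        self.sweeps = sweeps
        self.random_state = random_state

    def fit(self, X=None, y=None):
        if X is None:
            rng = np.random.default_rng(self.random_state)
            wm = estimate_weight_distribution(
                MOTIF, self.l, self.d, self.n, self.n_samples, rng)
            wd = estimate_weight_distribution(
                DECOY, self.l, self.d, self.n, self.n_samples, rng,
                method=self.method, sweeps=self.sweeps)
        else:
            w = np.asarray(X, dtype=float).ravel()
            y = np.asarray(y)
            if w.shape != y.shape:
                raise ValueError("X and y must have matching shapes")
            parts = {}
            for label in (MOTIF, DECOY):
                sel = w[y == label]
                if sel.size < 2:
                    raise ValueError(f"need >= 2 training weights for {label!r}")
                parts[label] = WeightDistribution(
                    label, self.l, self.d, self.n,
                    float(sel.mean()), float(sel.std(ddof=1)), int(sel.size))
            wm, wd = parts[MOTIF], parts[DECOY]
        entry = compute_thresholds(wm, wd, tail=self.tail,
                                   n_samples=wm.n_samples)
        self.motif_distribution_ = wm
        self.decoy_distribution_ = wd
        self.entry_ = entry
        self.alpha_m_ = entry.alpha_m
        self.alpha_d_ = entry.alpha_d
        self.separated_ = entry.separated
        return self

    def predict(self, X):
        """Labels for an array of set weights; raises
        UnseparatedThresholdsError when the fitted entry is unusable."""
        if not hasattr(self, "entry_"):
            raise RuntimeError("classifier is not fitted")
        w = np.asarray(X, dtype=float).ravel()
        return np.array([classify_by_weight(v, self.entry_) for v in w])
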