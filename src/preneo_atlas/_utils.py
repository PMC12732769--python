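"""Small numeric helpers shared across modules."""

from __future__ import annotations

import hashlib

import numpy as np
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

STAGES = ("Normal", "PRE", "PDAC")


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (empty-safe)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def densify(x) -> np.ndarray:
    """Return a C-contiguous dense float array from dense or sparse input."""
    if sp.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two 1-D vectors; NaN when either is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from one root seed.

    Lets each generator component (cells, bulk, reference, ...) be
    regenerated on its own without consuming another component's draws.
    """
    digest = hashlib.sha256(name.encode("utf8")).digest()
    key = int.from_bytes(digest[:4], "little") % (2**31)
    ss = np.random.SeedSequence(seed, spawn_key=(key,))
    return np.random.default_rng(ss)
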