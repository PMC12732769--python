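"""Stage-specific immune-subtype abundance tables and correlation networks.

Relative abundances are fractions of each sample's immune cells; edges are
Spearman correlations across samples within a stage, classified as
positive (rho > 0.5), negative (rho < -0.5) or weak (|rho| <= 0.5), the
classification the atlas figures use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputDataError

LOW_CELL_FLAG = 20


def abundance_table(samples: np.ndarray, stages: np.ndarray,
                    subtypes: np.ndarray,
                    immune_types: set | None = None) -> pd.DataFrame:
    """Per-(stage, sample) immune-subtype fractions.

    ``immune_types`` restricts the denominator to immune cells (all labels
    when omitted).  Samples with zero immune cells are excluded with a
    warning; samples under 20 immune cells are flagged.
    """
    df = pd.DataFrame({"sample": np.asarray(samples),
                       "stage": np.asarray(stages),
                       "subtype": np.asarray(subtypes)})
    if immune_types is not None:
        df = df[df["subtype"].isin(immune_types)]
    if df.empty:
        raise InputDataError("no immune cells present")
    counts = df.groupby(["stage", "sample"])["subtype"] \
               .value_counts().unstack(fill_value=0)
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} samples without immune cells excluded")
        counts = counts[~empty]
        totals = totals[~empty]
    frac = counts.div(totals, axis=0)
    frac["n_immune"] = totals
    frac["low_cells"] = totals < LOW_CELL_FLAG
    return frac


@dataclass
class NetworkEdge:
    subtype_a: str
    subtype_b: str
    rho: float
    edge_class: str
    n_samples: int


def classify_rho(rho: float) -> str:
    if rho > 0.5:
        return "positive"
    if rho < -0.5:
        return "negative"
    return "weak"


def stage_network(table: pd.DataFrame, stage: str,
                  min_samples: int = 5) -> list[NetworkEdge]:
    """All-pairs Spearman network over per-sample fractions within a stage.

    Constant subtypes have undefined rho; their edges are omitted with a
    warning.  Edges are unordered pairs, no self-edges.
    """
    sub = table.loc[table.index.get_level_values("stage") == stage]
    value_cols = [c for c in sub.columns if c not in ("n_immune", "low_cells")]
    n = len(sub)
    if n < min_samples:
        raise InputDataError(
            f"stage {stage!r} has {n} samples; need >= {min_samples}")
    edges = []
    for i, a in enumerate(value_cols):
        for b in value_cols[i + 1:]:
            xa, xb = sub[a].to_numpy(), sub[b].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                warnings.warn(f"constant subtype in pair ({a}, {b}); edge omitted")
                continue
            rho = float(stats.spearmanr(xa, xb).statistic)
            edges.append(NetworkEdge(a, b, rho, classify_rho(rho), n))
    return edges


def edges_to_frame(edges: list[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in edges])
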