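"""Positional-smoothing copy-number inference and malignancy designation.

CNV profiles are inferred per cell as smoothed log2 expression ratios
against a reference cell population (B cells in the intended usage), in
genomic gene order: per-gene log2 ratio with pseudocount, clipping,
chromosome-wise centred moving average truncated at chromosome ends,
denoising against the reference residual spread, and per-cell median
re-centering.  A cell's CNV burden is the mean squared deviation of its
profile from zero; PDAC-stage cells whose burden exceeds the reference by
``k_sd`` standard deviations are called malignant.  Preneoplastic
subclusters (> 50 % PRE cells) whose mean expression profile correlates
with the malignant mean profile above ``r_min`` are designated malignant
preneoplastic clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import densify, pearson
from .errors import InputDataError


@dataclass
class CnvProfiles:
    matrix: np.ndarray            # cells x ordered genes, smoothed log2 dosage
    gene_order: np.ndarray        # indices into the input gene axis
    chromosomes: np.ndarray       # chromosome label per ordered gene
    burden: np.ndarray            # per-cell mean squared deviation
    reference_mask: np.ndarray


def _moving_average(M: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along axis 1, truncated at the ends."""
    if window <= 1:
        return M.copy()
    n = M.shape[1]
    half = window // 2
    cs = np.zeros((M.shape[0], n + 1))
    np.cumsum(M, axis=1, out=cs[:, 1:])
    starts = np.maximum(np.arange(n) - half, 0)
    ends = np.minimum(np.arange(n) + half + 1, n)
    return (cs[:, ends] - cs[:, starts]) / (ends - starts)


def infer_cnv(counts, gene_map: pd.DataFrame, reference_mask: np.ndarray,
              gene_names, window: int = 51, expr_min: float = 0.1,
              clip: float = 3.0, pseudocount: float = 1.0) -> CnvProfiles:
    """Infer per-cell smoothed relative-dosage profiles.

    ``gene_map`` must carry ``chromosome`` and ``start`` columns indexed by
    gene name; genes missing from the map are dropped (with a warning when
    coverage falls below 90 %).  ``reference_mask`` marks the reference
    population (>= 20 cells required).
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.sum() < 20:
        raise InputDataError("reference population needs at least 20 cells")
    X = densify(counts)
    gene_names = np.asarray(gene_names)

    mapped = np.isin(gene_names, gene_map.index)
    if mapped.mean() < 0.9:
        warnings.warn(f"gene map covers only {mapped.mean():.0%} of genes")
    # library-size normalise to the median total so expression is comparable
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise InputDataError("cells with zero total count present")
    X = X * (np.median(totals) / totals[:, None])

    mean_expr = X.mean(axis=0)
    keep = mapped & (mean_expr >= expr_min)
    if keep.sum() < window:
        raise InputDataError("too few genes retained for smoothing")
    kept_names = gene_names[keep]
    sub = gene_map.loc[kept_names]
    order_local = np.lexsort((sub["start"].to_numpy(),
                              sub["chromosome"].to_numpy()))
    gene_order = np.where(keep)[0][order_local]
    chroms = sub["chromosome"].to_numpy()[order_local]

    ref_mean = X[reference_mask][:, gene_order].mean(axis=0)
    ratio = np.log2((X[:, gene_order] + pseudocount) / (ref_mean + pseudocount))
    ratio = np.clip(ratio, -clip, clip)

    smooth = np.empty_like(ratio)
    for c in pd.unique(chroms):
        cols = np.where(chroms == c)[0]
        smooth[:, cols] = _moving_average(ratio[:, cols], window)

    sd_ref = smooth[reference_mask].std()
    if sd_ref > 0:
        smooth[np.abs(smooth) <= sd_ref] = 0.0
    smooth -= np.median(smooth, axis=1, keepdims=True)
    burden = (smooth ** 2).mean(axis=1)
    return CnvProfiles(matrix=smooth, gene_order=gene_order,
                       chromosomes=chroms, burden=burden,
                       reference_mask=reference_mask)


def call_malignant(profiles: CnvProfiles, stages: np.ndarray,
                   k_sd: float = 3.0, eligible_stage: str = "PDAC",
                   floor: float = 1e-3) -> np.ndarray:
    """Flag cells with CNV burden beyond the reference distribution.

    malignant <=> burden > mean(ref burden) + k_sd * SD(ref burden), with
    eligibility restricted to ``eligible_stage`` cells.  A zero-variance
    reference falls back to a fixed burden floor.
    """
    ref_b = profiles.burden[profiles.reference_mask]
    mu, sd = ref_b.mean(), ref_b.std()
    if sd == 0:
        warnings.warn("reference burden has zero variance; using fixed floor")
        threshold = mu + floor
    else:
        threshold = mu + k_sd * sd
    stages = np.asarray(stages)
    return (profiles.burden > threshold) & (stages == eligible_stage)


@dataclass
class MalignancyCall:
    cluster: object
    n_cells: int
    pre_fraction: float
    r: float
    designation: str


def designate_malignant_pre(normalized: np.ndarray, subclusters: np.ndarray,
                            stages: np.ndarray, malignant_mask: np.ndarray,
                            hvgs=None, r_min: float = 0.75,
                            pre_min: float = 0.5,
                            cnv_profiles: CnvProfiles | None = None
                            ) -> list[MalignancyCall]:
    """Designate preneoplastic and malignant-PRE subclusters.

    A subcluster is preneoplastic when strictly more than ``pre_min`` of
    its cells come from the PRE stage; a preneoplastic subcluster becomes
    malignant-PRE when the Pearson correlation between its mean expression
    profile (over ``hvgs``, log-normalised) and the malignant cells' mean
    profile strictly exceeds ``r_min``.  Passing ``cnv_profiles`` switches
    the correlation to the smoothed CNV profiles instead (the alternative
    reading of "expression profile").
    """
    malignant_mask = np.asarray(malignant_mask, dtype=bool)
    if malignant_mask.sum() == 0:
        raise InputDataError(
            "no malignant cells; run call_malignant before designation")
    stages = np.asarray(stages)
    subclusters = np.asarray(subclusters)
    if cnv_profiles is not None:
        M = cnv_profiles.matrix
    else:
        M = densify(normalized)
        if hvgs is not None:
            M = M[:, np.asarray(hvgs)]
    mal_profile = M[malignant_mask].mean(axis=0)

    calls = []
    for c in pd.unique(subclusters):
        mask = subclusters == c
        pre_frac = float((stages[mask] == "PRE").mean())
        r = pearson(M[mask].mean(axis=0), mal_profile)
        if pre_frac <= pre_min:
            designation = "not_preneoplastic"
        elif r > r_min:
            designation = "malignant_pre"
        else:
            designation = "preneoplastic"
        calls.append(MalignancyCall(cluster=c, n_cells=int(mask.sum()),
                                    pre_fraction=pre_frac, r=r,
                                    designation=designation))
    return calls
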