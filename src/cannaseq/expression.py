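"""RPKM expression matrices, tissue clustering and the trichome-enrichment
adjustment for between-strain comparisons.

Cannabinoids are made in glandular trichomes, so bulk mid-flower RNA-Seq
comparisons between strains confound pathway regulation with trichome
density.  The adjustment used here selects, from the most abundant
transcripts in a trichome-enriched reference sample, those with the greatest
mid-flower-versus-vegetative expression difference; the median between-strain
log2 ratio of this trichome-predominant set (excluding the cannabinoid
pathway genes themselves) estimates the trichome-density ratio and is
subtracted from per-gene fold-changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

DEFAULT_PSEUDOCOUNT = 0.25  # RPKM added before log2


@dataclass
class ExpressionMatrix:
    """Transcripts x samples RPKM with raw counts and tissue roles.

    RPKM = count / ((length/1e3) * (library_size/1e6)) with library size the
    total assigned reads of the sample; the declared pseudocount is the only
    one ever used for log2 transforms of this matrix.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    rpkm: pd.DataFrame
    roles: dict[str, str]
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def log2_rpkm(self) -> pd.DataFrame:
        return np.log2(self.rpkm + self.pseudocount)

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s, r in self.roles.items() if r == role]


@dataclass
class TrichomeAdjustment:
    candidate_pool_ids: list[str]
    selected_ids: list[str]
    excluded_ids: list[str] = field(default_factory=list)
    factor_log2: float | None = None


def compute_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    roles: dict[str, str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ExpressionMatrix:
    """Exact RPKM from a counts table (transcripts x samples)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every transcript needs a positive length")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"zero library size for samples {bad}")
    rpkm = counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)
    roles = roles or {s: s for s in counts.columns}
    return ExpressionMatrix(counts=counts, lengths=lengths, rpkm=rpkm,
                            roles=dict(roles), pseudocount=pseudocount)


def invert_rpkm(m: ExpressionMatrix) -> pd.DataFrame:
    """Recover the original counts from an ExpressionMatrix (exactness check)."""
    lib = m.counts.sum(axis=0)
    return m.rpkm.mul(m.lengths / 1e3, axis=0).mul(lib / 1e6, axis=1)


def cluster_expression(m: ExpressionMatrix):
    """Average-linkage agglomerative clustering of transcripts on
    1 - Pearson correlation of log2 RPKM rows.

    Constant rows (zero variance) are assigned zero distance to each other
    and maximal distance (2.0) to everything else, and are reported back.
    Returns (linkage matrix, leaf order, list of constant transcript ids).
    """
    data = m.log2_rpkm().to_numpy(dtype=float)
    if data.shape[0] < 2:
        raise ValueError("clustering needs at least two transcripts")
    sd = data.std(axis=1)
    constant = sd == 0
    centered = data - data.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd * data.shape[1])
    z = centered / denom[:, None]
    corr = z @ z.T * data.shape[1]
    dist = 1.0 - corr
    dist[constant, :] = 2.0
    dist[:, constant] = 2.0
    both = np.ix_(constant, constant)
    dist[both] = 0.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    order = [m.rpkm.index[i] for i in leaves_list(Z)]
    const_ids = [m.rpkm.index[i] for i in np.where(constant)[0]]
    return Z, order, const_ids


def select_trichome_genes(
    m: ExpressionMatrix,
    reference_sample: str,
    pool_size: int = 1000,
    select_size: int = 100,
) -> TrichomeAdjustment:
    """Select trichome-predominant transcripts.

    Pool: the ``pool_size`` most abundant transcripts in ``reference_sample``
    (a trichome-enriched dataset).  Selected: the ``select_size`` pool members
    with the greatest log2 difference between mid-flower expression and the
    maximum across root/shoot/stem.  Ties break by transcript id; with fewer
    than ``pool_size`` expressed transcripts the whole expressed set is used.
    """
    for role in ("mid_flower", "root", "shoot", "stem"):
        if not m.samples_with_role(role):
            raise ValueError(f"missing tissue role {role!r}")
    ref = m.rpkm[reference_sample]
    expressed = ref[ref > 0]
    pool = (
        expressed.sort_values(ascending=False, kind="mergesort")
        .iloc[:pool_size]
        .index.tolist()
    )
    lg = m.log2_rpkm()
    flower = lg[m.samples_with_role("mid_flower")].max(axis=1)
    veg_samples = sum((m.samples_with_role(r) for r in ("root", "shoot", "stem")), [])
    veg = lg[veg_samples].max(axis=1)
    score = (flower - veg).loc[pool]
    ranked = score.sort_values(ascending=False, kind="mergesort")
    # deterministic tie-break by id within equal scores
    ranked = ranked.iloc[
        np.lexsort((np.array(ranked.index), -ranked.to_numpy()))
    ] if ranked.duplicated().any() else ranked
    selected = ranked.index[:select_size].tolist()
    return TrichomeAdjustment(candidate_pool_ids=pool, selected_ids=selected)


def trichome_adjustment_factor(
    adj: TrichomeAdjustment,
    rpkm_a: pd.Series,
    rpkm_b: pd.Series,
    exclude: Sequence[str] = (),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Median log2 (strain A / strain B) over the selected trichome genes
    after excluding the pathway genes; the estimate of the between-strain
    trichome-density ratio."""
    use = [g for g in adj.selected_ids if g not in set(exclude)]
    if not use:
        raise ValueError("no genes left after exclusion")
    ratios = np.log2(rpkm_a.loc[use] + pseudocount) - np.log2(
        rpkm_b.loc[use] + pseudocount
    )
    factor = float(np.median(ratios))
    adj.excluded_ids = [g for g in adj.selected_ids if g in set(exclude)]
    adj.factor_log2 = factor
    return factor


def adjusted_fold_changes(
    rpkm_a: pd.Series,
    rpkm_b: pd.Series,
    factor_log2: float,
    panel: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-gene log2(A/B) minus the trichome factor, in panel order."""
    panel = list(panel)
    raw = np.log2(rpkm_a.loc[panel] + pseudocount) - np.log2(
        rpkm_b.loc[panel] + pseudocount
    )
    return raw - factor_log2
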