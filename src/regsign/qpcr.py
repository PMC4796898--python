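"""Relative-quantification qPCR statistics for littermate-pair designs.

Quantification uses the 2^-ddCt estimator: within each littermate pair the
target gene's Ct is normalised by a reference gene (the Hprt role) in both
genotypes, and the difference of differences is exponentiated,

    rel = 2 ** -[(Ct_tgt,mut - Ct_ref,mut) - (Ct_tgt,wt - Ct_ref,wt)]

so the wildtype of each pair is 1 by construction and the mutant value is
the pair's expression ratio.  Pairs are quality-controlled with a sensory
tissue marker (the Jag1/Ngfr role): a pair is kept only when the marker's
relative expression is within a tolerance (default 30%) of 1.

Significance testing is an exact two-sided Wilcoxon rank-sum test — the
group sizes here (3-6 littermate pairs) are far too small for asymptotic
approximations — followed by Benjamini-Hochberg adjustment across the
tested gene family.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # per-group size up to which the exact distribution is enumerated


@dataclass(frozen=True)
class QpcrPair:
    """Ct values for one wildtype/mutant littermate pair and one target gene."""

    pair_id: str
    gene: str
    ct_target_wt: float
    ct_target_mut: float
    ct_ref_wt: float
    ct_ref_mut: float
    ct_qc_wt: float | None = None
    ct_qc_mut: float | None = None

    def __post_init__(self) -> None:
        for name in ("ct_target_wt", "ct_target_mut", "ct_ref_wt", "ct_ref_mut"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v <= 0:
                raise ValueError(f"pair {self.pair_id}, gene {self.gene}: invalid {name}={v!r}")


def relative_expression(pair: QpcrPair) -> float:
    """Mutant-vs-wildtype expression ratio of the pair's target gene (2^-ddCt)."""
    ddct = (pair.ct_target_mut - pair.ct_ref_mut) - (pair.ct_target_wt - pair.ct_ref_wt)
    return float(2.0 ** (-ddct))


def qc_relative_expression(pair: QpcrPair) -> float:
    """2^-ddCt of the pair's QC marker gene."""
    if pair.ct_qc_wt is None or pair.ct_qc_mut is None:
        raise ValueError(f"pair {pair.pair_id}: no QC-gene Ct values")
    ddct = (pair.ct_qc_mut - pair.ct_ref_mut) - (pair.ct_qc_wt - pair.ct_ref_wt)
    return float(2.0 ** (-ddct))


def qc_filter_pairs(
    pairs: list[QpcrPair], tolerance: float = 0.30
) -> tuple[list[QpcrPair], list[tuple[str, float]]]:
    """Retain pairs whose QC-marker ratio is within ``tolerance`` of 1.

    Returns (retained pairs, exclusion log of (pair_id, offending ratio)).
    """
    if not pairs:
        logger.warning("qc_filter_pairs called with no pairs")
        return [], []
    kept, excluded = [], []
    for p in pairs:
        ratio = qc_relative_expression(p)
        if abs(ratio - 1.0) <= tolerance:
            kept.append(p)
        else:
            excluded.append((p.pair_id, ratio))
            logger.info("pair %s excluded: QC ratio %.3f outside 1±%.2f", p.pair_id, ratio, tolerance)
    return kept, excluded


# -- exact Wilcoxon rank-sum ---------------------------------------------


def _exact_ranksum_p(scaled_ranks: np.ndarray, n1: int, w_obs: int) -> float:
    """Two-sided exact p for rank-sum ``w_obs`` of a size-``n1`` group.

    ``scaled_ranks`` are the pooled mid-ranks times 2 (integers, so tied
    rank structure is enumerated exactly).  The permutation distribution of
    the subset sum is built by dynamic programming over (subset size, sum).
    """
    total_sum = int(scaled_ranks.sum())
    # counts[k, s] = number of size-k subsets of the ranks with sum s
    counts = np.zeros((n1 + 1, total_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in scaled_ranks:
        r = int(r)
        counts[1:, r:] += counts[:-1, : total_sum + 1 - r]
    dist = counts[n1]
    n_total = dist.sum()  # == C(n1+n2, n1)
    lower = dist[: w_obs + 1].sum() / n_total
    upper = dist[w_obs:].sum() / n_total
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_exact(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation p for group sizes up to 12 (ties handled by mid-ranks
    with exact enumeration over the observed tie structure); the normal
    approximation with tie correction and continuity correction is used for
    larger groups.  Two-sided p = min(1, 2*min(lower tail, upper tail)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_exact requires two non-empty groups")
    if max(x.size, y.size) > EXACT_MAX_N:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    scaled = np.rint(2 * ranks).astype(int)
    w_obs = int(scaled[: x.size].sum())
    return _exact_ranksum_p(scaled, x.size, w_obs)


def wilcoxon_bruteforce(x, y) -> float:
    """Independent oracle: enumerate every label assignment explicitly.

    Exponential in the pooled size; intended for cross-checking
    :func:`wilcoxon_exact` at tiny n only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    w_obs = ranks[:n1].sum()
    sums = np.array([ranks[list(c)].sum() for c in itertools.combinations(range(pooled.size), n1)])
    eps = 1e-9
    lower = np.mean(sums <= w_obs + eps)
    upper = np.mean(sums >= w_obs - eps)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adj
    return out


def to_fold_change(relative_expression: float) -> float:
    """Map an expression ratio to the signed fold-change convention.

    Ratios >= 1 are reported as-is; ratios < 1 as -1/ratio, so a halving is
    -2.0 and |fold change| >= 1 always.  Rounding is the caller's concern.
    """
    r = float(relative_expression)
    if not math.isfinite(r) or r <= 0:
        raise ValueError(f"relative expression must be positive, got {r!r}")
    return r if r >= 1.0 else -1.0 / r


def from_fold_change(fc: float) -> float:
    """Inverse of :func:`to_fold_change` (fc >= 1 -> fc, fc <= -1 -> -1/fc)."""
    fc = float(fc)
    if abs(fc) < 1.0:
        raise ValueError(f"signed fold change must satisfy |fc| >= 1, got {fc!r}")
    return fc if fc >= 1.0 else -1.0 / fc


# -- per-gene analysis over a Ct table ------------------------------------


@dataclass
class GeneTestResult:
    gene: str
    wt_values: list[float]
    mut_values: list[float]
    p_raw: float
    p_adj: float = float("nan")
    fold_change: float = float("nan")
    excluded_pairs: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_wt(self) -> int:
        return len(self.wt_values)

    @property
    def n_mut(self) -> int:
        return len(self.mut_values)


def pairs_from_table(
    table: pd.DataFrame, gene: str, reference: str, qc: str | None = None
) -> list[QpcrPair]:
    """Assemble :class:`QpcrPair` objects for one target gene from a long Ct table.

    The table has columns pair_id, genotype (wt/hom), gene, ct.  Pairs
    missing any required Ct raise, naming the pair and gene.
    """
    pairs: list[QpcrPair] = []
    idx = table.set_index(["pair_id", "genotype", "gene"])["ct"]

    def _get(pair_id, genotype, g, required=True):
        try:
            v = idx.loc[(pair_id, genotype, g)]
        except KeyError:
            if required:
                raise ValueError(f"missing Ct for pair {pair_id}, genotype {genotype}, gene {g}")
            return None
        if isinstance(v, pd.Series):
            raise ValueError(f"duplicate Ct rows for pair {pair_id}, genotype {genotype}, gene {g}")
        return float(v)

    for pair_id in sorted(table["pair_id"].unique()):
        pairs.append(
            QpcrPair(
                pair_id=str(pair_id),
                gene=gene,
                ct_target_wt=_get(pair_id, "wt", gene),
                ct_target_mut=_get(pair_id, "hom", gene),
                ct_ref_wt=_get(pair_id, "wt", reference),
                ct_ref_mut=_get(pair_id, "hom", reference),
                ct_qc_wt=_get(pair_id, "wt", qc, required=False) if qc else None,
                ct_qc_mut=_get(pair_id, "hom", qc, required=False) if qc else None,
            )
        )
    return pairs


def analyze_qpcr(
    table: pd.DataFrame,
    reference: str = "Hprt",
    qc: str | None = "Jag1",
    tolerance: float = 0.30,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Full qPCR panel analysis: QC filter, 2^-ddCt, exact Wilcoxon, BH.

    Per pair the wildtype value is 1 by construction and the mutant value is
    the pair's relative expression; the two groups are compared with the
    exact rank-sum test.  BH adjustment runs across all genes analysed in
    this call — the adjustment family is therefore chosen explicitly by what
    the caller passes in ``genes``.
    """
    special = {reference} | ({qc} if qc else set())
    if genes is None:
        genes = [g for g in sorted(table["gene"].unique()) if g not in special]
    results: list[GeneTestResult] = []
    for gene in genes:
        pairs = pairs_from_table(table, gene, reference, qc)
        excluded: list[tuple[str, float]] = []
        if qc:
            pairs, excluded = qc_filter_pairs(pairs, tolerance)
        if not pairs:
            logger.warning("gene %s: no pairs survive QC; skipped", gene)
            continue
        mut = [relative_expression(p) for p in pairs]
        wt = [1.0] * len(mut)
        res = GeneTestResult(gene, wt, mut, p_raw=wilcoxon_exact(wt, mut))
        res.fold_change = to_fold_change(float(np.mean(mut)))
        res.excluded_pairs = excluded
        results.append(res)
    if not results:
        return pd.DataFrame(
            columns=["gene", "n_wt", "n_hom", "mean_hom", "sd_hom", "p_raw", "p_adj", "fold_change"]
        )
    padj = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, padj):
        r.p_adj = float(a)
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "n_wt": [r.n_wt for r in results],
            "n_hom": [r.n_mut for r in results],
            "mean_hom": [float(np.mean(r.mut_values)) for r in results],
            "sd_hom": [float(np.std(r.mut_values, ddof=1)) if r.n_mut > 1 else 0.0 for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "fold_change": [r.fold_change for r in results],
        }
    )
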