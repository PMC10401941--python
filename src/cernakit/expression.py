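"""Expression-side validation of a sponge circuit from bulk RNA-seq counts.

Implements a compact, fully documented differential-expression stack —
mean-CPM filtering, median-of-ratios size factors, pseudocount log2 fold
changes, Welch t tests on log2 normalized counts, Benjamini-Hochberg
adjustment — plus the set-level statistics the circuit argument rests on:
target-set ECDF shift (two-sample Kolmogorov-Smirnov), sign-concordance
Venn counts between two genotype contrasts, threshold-defined responsive
gene sets, hierarchical clustering of samples on a gene set, and 2^-dCt
quantification for qPCR.

The DE stack is a deliberate, documented substitute for a negative-binomial
Wald engine: the circuit-level quantities consumed downstream (fold-change
signs, ECDF shifts, set memberships) are robust to the choice, and every
step here is reproducible from this file alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io import check_samples_match

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Gene-by-sample non-negative integer counts plus sample metadata."""

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if np.any(values < 0):
            raise ValueError("count matrix contains negative entries")
        check_samples_match(self.counts, self.samples)
        # keep metadata in column order for deterministic group selection
        order = {s: i for i, s in enumerate(self.counts.columns)}
        self.samples = (
            self.samples.assign(_o=self.samples["sample_id"].map(order))
            .sort_values("_o")
            .drop(columns="_o")
            .reset_index(drop=True)
        )

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def sample_ids(self, **conditions: str) -> list[str]:
        """Sample ids matching all metadata conditions, e.g. genotype="WT"."""
        mask = pd.Series(True, index=self.samples.index)
        for col, val in conditions.items():
            mask &= self.samples[col] == val
        return self.samples.loc[mask, "sample_id"].tolist()


def cpm_filter(cm: CountMatrix, min_mean_cpm: float = 2.0) -> CountMatrix:
    """Drop genes whose mean counts-per-million across all samples is < threshold.

    The boundary is inclusive: mean CPM exactly at the threshold is kept.
    """
    lib = cm.library_sizes
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"library size zero for samples {bad}")
    cpm = cm.counts * 1e6 / lib
    keep = cpm.mean(axis=1) >= min_mean_cpm
    if not keep.any():
        raise ValueError("CPM filter removed every gene")
    out = CountMatrix(cm.counts.loc[keep].copy(), cm.samples.copy())
    out.counts.attrs["n_kept"] = int(keep.sum())
    out.counts.attrs["n_removed"] = int((~keep).sum())
    return out


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Per-sample median-of-ratios size factors.

    factor_j = median over reference genes of count_gj / geomean_g, where
    the reference set is the genes with nonzero counts in every sample.
    """
    values = counts.to_numpy(float)
    ref = np.all(values > 0, axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; cannot form the "
            "median-of-ratios reference (consider a pseudo-reference)"
        )
    logs = np.log(values[ref])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    return counts / size_factors


def gene_log2fc(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """log2[(mean_A + pc) / (mean_B + pc)] of size-factor-normalized counts.

    The contrast is labelled "A_vs_B": positive values mean higher in A.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    norm = normalized_counts(counts, size_factors)
    mean_a = norm[list(samples_a)].mean(axis=1)
    mean_b = norm[list(samples_b)].mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pd.DataFrame(
        {"log2fc": lfc, "mean_norm_a": mean_a, "mean_norm_b": mean_b}
    )


def gene_de_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.Series:
    """Welch t test per gene on log2(normalized count + pseudocount).

    Degenerate genes (zero variance in both groups) get p = 1 when the
    group means are equal and p = 0 otherwise.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    norm = normalized_counts(counts, size_factors)
    xa = np.log2(norm[list(samples_a)].to_numpy(float) + pseudocount)
    xb = np.log2(norm[list(samples_b)].to_numpy(float) + pseudocount)
    import warnings

    with warnings.catch_warnings():
        # degenerate (constant) genes are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    var_a, var_b = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    equal_means = np.isclose(xa.mean(axis=1), xb.mean(axis=1))
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0
    return pd.Series(p, index=counts.index, name="p_value")


def bh_adjust(pvalues: Iterable[float]) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN inputs stay NaN."""
    if isinstance(pvalues, pd.Series):
        index = pvalues.index
        p = pvalues.to_numpy(float)
    else:
        index = None
        p = np.asarray(list(pvalues), dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.Series(out, index=index, name="padj") if index is not None else out


def differential_expression(
    cm: CountMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    label: str = "A_vs_B",
    pseudocount: float = 0.5,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Full DE table for one contrast: log2fc, p, padj, group means."""
    sf = (
        size_factors
        if size_factors is not None
        else size_factors_median_of_ratios(cm.counts)
    )
    table = gene_log2fc(cm.counts, sf, samples_a, samples_b, pseudocount)
    table["p_value"] = gene_de_test(cm.counts, sf, samples_a, samples_b, pseudocount)
    table["padj"] = bh_adjust(table["p_value"])
    table.attrs["contrast"] = label
    return table


@dataclass(frozen=True)
class KSResult:
    """Two-sample KS comparison of target vs background log2 fold changes."""

    statistic: float
    p_value: float
    n_target: int
    n_background: int
    direction: int  # sign of (median target - median background)


def ecdf_shift_test(
    de: pd.DataFrame,
    targets: Iterable[str],
    background: Iterable[str] | None = None,
) -> KSResult:
    """Two-sample KS test on log2fc: target genes vs all other tested genes.

    ``direction`` is the sign of the median difference (+1 when targets sit
    at higher fold changes than background).
    """
    target_set = set(targets)
    tested = set(de.index)
    t_genes = sorted(target_set & tested)
    b_genes = (
        sorted(set(background) & tested - target_set)
        if background is not None
        else sorted(tested - target_set)
    )
    if len(t_genes) < 2:
        raise ValueError(f"need >= 2 tested target genes, got {len(t_genes)}")
    if not b_genes:
        raise ValueError("background gene set is empty")
    t_vals = de.loc[t_genes, "log2fc"].to_numpy(float)
    b_vals = de.loc[b_genes, "log2fc"].to_numpy(float)
    res = stats.ks_2samp(t_vals, b_vals, alternative="two-sided", method="asymp")
    direction = int(np.sign(np.median(t_vals) - np.median(b_vals)))
    return KSResult(
        float(res.statistic), float(res.pvalue), len(t_genes), len(b_genes), direction
    )


@dataclass(frozen=True)
class VennCounts:
    """Sign-concordance partition of a target set across two contrasts.

    "down in scr" means contrast-1 log2fc > 0 (higher in control);
    "up in ko" means contrast-2 log2fc < 0 (higher in knockout).
    Strict inequalities; genes at exactly 0 fall into neither circle.
    """

    n_targets: int
    n_down_in_scr: int
    n_up_in_ko: int
    n_both: int
    n_neither: int
    missing: tuple[str, ...] = ()

    @property
    def n_union(self) -> int:
        return self.n_down_in_scr + self.n_up_in_ko - self.n_both

    def percentages(self) -> dict[str, float]:
        d = self.n_targets
        if d == 0:
            return {}
        return {
            "down_in_scr": 100.0 * self.n_down_in_scr / d,
            "up_in_ko": 100.0 * self.n_up_in_ko / d,
            "both": 100.0 * self.n_both / d,
            "union": 100.0 * self.n_union / d,
            "neither": 100.0 * self.n_neither / d,
        }


def concordance_venn(
    de_scr: pd.DataFrame,
    de_ko: pd.DataFrame,
    targets: Iterable[str],
) -> VennCounts:
    """Classify each target gene by sign concordance across the two contrasts.

    ``de_scr`` is the control-vs-sponge-mutant contrast (positive = down in
    the mutant); ``de_ko`` is the control-vs-miRNA-knockout contrast
    (negative = up in the knockout).  Target genes absent from either table
    are reported and excluded from the denominator.
    """
    targets = sorted(set(targets))
    present = [g for g in targets if g in de_scr.index and g in de_ko.index]
    missing = tuple(g for g in targets if g not in present)
    if missing:
        logger.warning("%d target genes missing from DE tables", len(missing))
    scr_lfc = de_scr.loc[present, "log2fc"].to_numpy(float)
    ko_lfc = de_ko.loc[present, "log2fc"].to_numpy(float)
    down = scr_lfc > 0
    up = ko_lfc < 0
    return VennCounts(
        n_targets=len(present),
        n_down_in_scr=int(down.sum()),
        n_up_in_ko=int(up.sum()),
        n_both=int((down & up).sum()),
        n_neither=int((~down & ~up).sum()),
        missing=missing,
    )


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    genes: tuple[str, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids in a GeneSet must be unique")


def threshold_gene_set(
    de: pd.DataFrame,
    lfc_min: float = 1.5,
    padj_max: float = 0.001,
    set_id: str = "responsive",
) -> GeneSet:
    """Genes with log2fc > lfc_min and padj < padj_max (both strict)."""
    mask = (de["log2fc"] > lfc_min) & (de["padj"] < padj_max)
    return GeneSet(
        set_id=set_id,
        genes=tuple(de.index[mask]),
        provenance={"lfc_min": lfc_min, "padj_max": padj_max, "n_tested": len(de)},
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray
    sample_ids: list[str]
    labels: pd.Series  # flat cluster label per sample at the requested k
    leaf_order: list[str]
    dropped_genes: list[str]


def cluster_samples(
    expr: pd.DataFrame,
    gene_set: Iterable[str],
    k: int = 2,
) -> ClusterResult:
    """Hierarchically cluster samples on z-scored expression of a gene set.

    Rows (genes) are z-scored across samples; samples are clustered on
    Euclidean distance with complete linkage (the classic heatmap default).
    Constant genes are dropped with a warning.  scipy's agglomeration is
    deterministic for a fixed input ordering, and samples are kept in their
    input (column) order, so leaf order and labels are reproducible.
    """
    genes = [g for g in gene_set if g in expr.index]
    sub = expr.loc[genes]
    sd = sub.std(axis=1, ddof=0)
    dropped = sub.index[sd == 0].tolist()
    if dropped:
        logger.warning("dropping %d constant genes before z-scoring", len(dropped))
        sub = sub.loc[sd > 0]
    if len(sub) < 2:
        raise ValueError(f"need >= 2 variable genes in the set, got {len(sub)}")
    if sub.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {sub.shape[1]}")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
    X = z.T.to_numpy(float)  # samples x genes
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    sample_ids = list(sub.columns)
    order = [sample_ids[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(
        linkage=Z,
        sample_ids=sample_ids,
        labels=pd.Series(labels, index=sample_ids, name="cluster"),
        leaf_order=order,
        dropped_genes=dropped,
    )


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch heights."""
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - (0 if node.left.is_leaf() else node.left.dist)
        dr = node.dist - (0 if node.right.is_leaf() else node.right.dist)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"


def qpcr_rel_expr(
    ct_target: float | Iterable[float],
    ct_reference: float | Iterable[float],
) -> float:
    """Relative expression 2^-(Ct_target - Ct_reference).

    Technical duplicates may be passed as iterables; they are averaged
    before the delta-Ct subtraction.
    """

    def _mean(x) -> float:
        if np.iterable(x) and not isinstance(x, (str, bytes)):
            return float(np.mean(list(x)))
        return float(x)

    ct_t, ct_r = _mean(ct_target), _mean(ct_reference)
    if not (math.isfinite(ct_t) and math.isfinite(ct_r)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (-(ct_t - ct_r))
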