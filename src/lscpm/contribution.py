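"""Edge-level contribution weights and network-anatomy enrichment.

Because PCA and ridge regression are both linear, each fold model trained on
PC scores is equivalent to a linear model on the original edges: the edge
weight vector of fold f is ``w_f = transform @ beta_f`` (E values; the
intercept carries no edge information and is excluded).  Across the k folds
this yields k weights per edge; a one-sample t-test against zero (df = k-1,
two-sided) with Bonferroni correction over all E edges flags edges that
contribute consistently, signed by the mean weight.

Network anatomy asks whether the positively (resp. negatively) contributing
edge set piles up within or between particular resting-state networks more
than chance: for each of the 45 unordered network pairs (9 within + 36
between for nine networks), an upper-tail hypergeometric test of the overlap
between the significant set and the pair's edges, Bonferroni-corrected over
45 comparisons at alpha = 0.025 per sign family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import NETWORK_LABELS, NetworkPartition, edge_pairs, n_edges
from .exceptions import DataError, ParameterError, PreconditionError
from .predict import FittedPipeline

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Back-projection
# ---------------------------------------------------------------------------

def backproject(pipeline: FittedPipeline) -> np.ndarray:
    """Edge-space weights, one column per fold model: ``W[:, f] = T @ beta_f``.

    The identity ``b_f + w_f' (x - center) == b_f + beta_f' project(x)`` holds
    exactly for every input x, so edge-space and PC-space predictions agree.
    """
    if pipeline.pca is None:
        raise DataError("pipeline carries no PCA model; fit with fit_pipeline")
    folds = pipeline.folds
    betas = np.column_stack([f.coefficients for f in folds])  # K x F
    if betas.shape[0] != pipeline.pca.transform.shape[1]:
        raise RuntimeError("coefficient length does not match PCA components")
    return pipeline.pca.transform @ betas  # E x F


# ---------------------------------------------------------------------------
# Per-edge one-sample t-tests
# ---------------------------------------------------------------------------

@dataclass
class EdgeContributionTable:
    """Per-edge fold weights, t statistics, p-values and significance flags."""

    fold_weights: np.ndarray  # E x F
    mean_weight: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    sign: np.ndarray  # +1 / -1 (0 only for exactly-zero mean)
    degenerate: np.ndarray  # zero across-fold variance
    alpha: float

    @property
    def n_edges(self) -> int:
        return self.fold_weights.shape[0]

    @property
    def positive_significant(self) -> np.ndarray:
        return np.nonzero(self.significant & (self.sign > 0))[0]

    @property
    def negative_significant(self) -> np.ndarray:
        return np.nonzero(self.significant & (self.sign < 0))[0]

    def to_frame(self, n_rois: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "mean_weight": self.mean_weight,
                "t": self.t_stat,
                "p": self.p_value,
                "significant": self.significant,
                "sign": self.sign,
            }
        )
        df.index.name = "edge"
        if n_rois is not None:
            rows, cols = edge_pairs(n_rois)
            df.insert(0, "roi_i", rows)
            df.insert(1, "roi_j", cols)
        return df


def contribution_test(
    weight_matrix: np.ndarray, alpha: float = 0.05
) -> EdgeContributionTable:
    """One-sample t-test of each edge's fold weights against zero.

    Two-sided p with df = folds - 1; the Bonferroni threshold is alpha / E.
    Degenerate edges (zero across-fold variance) get p = 1 when the mean is
    also zero and p = 0 (flagged, trivially significant) otherwise.
    """
    w = np.asarray(weight_matrix, dtype=float)
    if w.ndim != 2 or w.shape[1] < 2:
        raise PreconditionError("need an E x folds matrix with >= 2 folds")
    e, f = w.shape
    mean = w.mean(axis=1)
    sd = w.std(axis=1, ddof=1)
    degenerate = np.ptp(w, axis=1) == 0  # exactly constant across folds
    mean[degenerate] = w[degenerate, 0]  # exact value, no float noise
    sd[degenerate] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(f))
    p = np.empty(e)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=f - 1)
    p[degenerate & (mean == 0)] = 1.0
    p[degenerate & (mean != 0)] = 0.0
    t[degenerate & (mean == 0)] = 0.0
    t[degenerate & (mean != 0)] = np.sign(mean[degenerate & (mean != 0)]) * np.inf
    if degenerate.any():
        logger.warning(
            "%d edge(s) with zero across-fold weight variance", int(degenerate.sum())
        )
    threshold = alpha / e
    significant = p < threshold
    table = EdgeContributionTable(
        fold_weights=w,
        mean_weight=mean,
        t_stat=t,
        p_value=p,
        significant=significant,
        sign=np.sign(mean),
        degenerate=degenerate,
        alpha=alpha,
    )
    logger.info(
        "significant contributors: %d positive, %d negative (of %d edges, "
        "threshold p < %.3g)",
        table.positive_significant.size, table.negative_significant.size,
        e, threshold,
    )
    return table


# ---------------------------------------------------------------------------
# Network pair categories
# ---------------------------------------------------------------------------

def network_pair_labels(
    labels: tuple[str, ...] = NETWORK_LABELS,
) -> list[tuple[str, str]]:
    """The unordered network-pair categories: within pairs first, then
    between pairs — C(m,2) + m = 45 categories for nine networks."""
    within = [(x, x) for x in labels]
    between = list(itertools.combinations(labels, 2))
    return within + between


def edge_pair_map(
    partition: NetworkPartition, n_rois: int | None = None
) -> np.ndarray:
    """Category index (into ``network_pair_labels()``) for every edge."""
    if n_rois is not None and partition.n_rois != n_rois:
        raise DataError(
            f"partition labels {partition.n_rois} ROIs, expected {n_rois}"
        )
    net_idx = partition.label_indices()
    pair_lut = {
        tuple(sorted((NETWORK_LABELS.index(a), NETWORK_LABELS.index(b)))): c
        for c, (a, b) in enumerate(network_pair_labels())
    }
    rows, cols = edge_pairs(partition.n_rois)
    keys = np.minimum(net_idx[rows], net_idx[cols]) * len(NETWORK_LABELS) + np.maximum(
        net_idx[rows], net_idx[cols]
    )
    flat_lut = np.full(len(NETWORK_LABELS) ** 2, -1, dtype=int)
    for (a, b), c in pair_lut.items():
        flat_lut[a * len(NETWORK_LABELS) + b] = c
    return flat_lut[keys]


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentTable:
    """45 network-pair rows of overlap counts and hypergeometric p-values."""

    frame: pd.DataFrame
    set_label: str
    alpha: float

    @property
    def significant_pairs(self) -> list[str]:
        return self.frame.loc[self.frame["significant"], "pair"].tolist()


def enrichment(
    sig_edges: np.ndarray,
    pair_map: np.ndarray,
    alpha: float = 0.025,
    set_label: str = "positive",
    n_categories: int | None = None,
) -> EnrichmentTable:
    """Upper-tail hypergeometric enrichment of a significant-edge set over
    network-pair categories.

    For category c with K_c member edges in a population of E edges and a
    tested set of size n_sig, the overlap k_c is scored by
    ``p = P(X >= k_c), X ~ Hypergeom(E, K_c, n_sig)`` (the survival function
    at ``k_c - 1``).  The Bonferroni threshold is alpha / n_categories.
    """
    pair_map = np.asarray(pair_map, dtype=int)
    e = pair_map.size
    n_cat = (
        n_categories
        if n_categories is not None
        else len(network_pair_labels())
    )
    sig_edges = np.asarray(sig_edges, dtype=int)
    if sig_edges.size and (sig_edges.min() < 0 or sig_edges.max() >= e):
        raise DataError("significant edge index outside the edge population")
    if sig_edges.size != np.unique(sig_edges).size:
        raise DataError("significant edge set contains duplicates")
    n_sig = sig_edges.size
    if n_sig == 0:
        logger.warning("empty significant-edge set; all enrichment p = 1")

    k_pop = np.bincount(pair_map, minlength=n_cat)  # K_c
    k_hit = np.bincount(pair_map[sig_edges], minlength=n_cat)  # k_c
    # P(X >= k) = sf(k - 1)
    p = stats.hypergeom.sf(k_hit - 1, e, k_pop, n_sig)
    p = np.clip(p, 0.0, 1.0)
    labels = network_pair_labels()[:n_cat] if n_cat == len(network_pair_labels()) else None
    if labels is None:
        pair_names = [f"cat{c}" for c in range(n_cat)]
        kinds = ["?"] * n_cat
    else:
        pair_names = [f"{a}-{b}" for a, b in labels]
        kinds = ["within" if a == b else "between" for a, b in labels]
    frame = pd.DataFrame(
        {
            "pair": pair_names,
            "kind": kinds,
            "K_pair": k_pop,
            "n_sig": n_sig,
            "overlap": k_hit,
            "p": p,
            "likelihood": 1.0 - p,
            "significant": p < alpha / n_cat,
        }
    )
    return EnrichmentTable(frame=frame, set_label=set_label, alpha=alpha)


def enrichment_by_sign(
    table: EdgeContributionTable,
    partition: NetworkPartition,
    alpha: float = 0.025,
) -> dict[str, EnrichmentTable]:
    """Run the network-pair enrichment separately on the positively and
    negatively contributing significant edge sets (hence alpha = 0.05 / 2
    per family by default)."""
    if n_edges(partition.n_rois) != table.n_edges:
        raise DataError("partition and contribution table disagree on E")
    pair_map = edge_pair_map(partition)
    return {
        "positive": enrichment(
            table.positive_significant, pair_map, alpha, "positive"
        ),
        "negative": enrichment(
            table.negative_significant, pair_map, alpha, "negative"
        ),
    }


def network_matrix_summary(
    table: EdgeContributionTable, partition: NetworkPartition
) -> pd.DataFrame:
    """9 x 9 matrix of signed significant-edge counts (positive minus
    negative) per network pair, for heatmap rendering."""
    pair_map = edge_pair_map(partition)
    labels = network_pair_labels()
    mat = np.zeros((len(NETWORK_LABELS), len(NETWORK_LABELS)), dtype=int)
    for edges, s in (
        (table.positive_significant, 1),
        (table.negative_significant, -1),
    ):
        counts = np.bincount(pair_map[edges], minlength=len(labels))
        for c, (a, b) in enumerate(labels):
            i, j = NETWORK_LABELS.index(a), NETWORK_LABELS.index(b)
            mat[i, j] += s * counts[c]
            if i != j:
                mat[j, i] += s * counts[c]
    return pd.DataFrame(mat, index=NETWORK_LABELS, columns=NETWORK_LABELS)


def plot_network_matrix(summary: pd.DataFrame, path=None):
    """Basic diverging heatmap of the 9 x 9 network summary matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    vmax = max(1, np.abs(summary.values).max())
    im = ax.imshow(summary.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(summary.columns)), summary.columns, rotation=45)
    ax.set_yticks(range(len(summary.index)), summary.index)
    fig.colorbar(im, ax=ax, label="signed significant-edge count")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
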