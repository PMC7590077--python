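"""Abstaining dual-metric nearest-neighbour spectral matching (submodel A).

The primary identification stage compares each query spectrum against
every library spectrum with two complementary similarity measures:
Euclidean distance (sensitive to feature magnitude, hence concentration)
and Pearson correlation (sensitive to feature shape).  Up to nine
neighbours per metric are accepted, but only if they pass hard thresholds
(distance <= 0.1, correlation >= 0.98 on SNV + first-derivative spectra).
If no neighbour passes, the model *abstains* — the mechanism that keeps
novel compounds from being force-matched to the library.

Accepted neighbours (at most 9 + 9, duplicates counted twice) vote on the
sample identity, and the predicted cocaine concentration is the plain
average of their known concentrations.

Before any matching, replicate-inconsistent library scans are flagged as
outliers from their principal-component scores: a scan is discarded when
its mean score-space distance to the other scans of the same sample
exceeds that sample's 99 % quantile.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import AbstractSet, NamedTuple

import numpy as np
from scipy.stats import norm
from sklearn.decomposition import PCA

from .spectral_core import LabeledLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "OutlierConfig",
    "KnnConfig",
    "Neighbor",
    "NeighborSet",
    "KnnResult",
    "flag_outliers",
    "query_neighbors",
    "knn_predict",
]


@dataclass(frozen=True)
class OutlierConfig:
    """Replicate-outlier flagging rule.

    ``quantile_method`` selects how the per-sample 99 % quantile of the
    per-scan mean distances is estimated.  ``"lognormal"`` (default) fits
    a lognormal to the means — the natural parametric family for a
    positive, right-skewed distance statistic — and can flag several
    corrupted replicates per sample while keeping the clean flag rate
    near 1 %.  ``"normal"`` uses the Gaussian quantile
    ``mean + z_q * sd``.  ``"empirical"`` uses the linearly interpolated
    order statistic, which by construction can flag at most the top ~1 %
    of replicates of every sample, corrupted or not.
    """

    n_components: int = 3
    quantile: float = 0.99
    quantile_method: str = "lognormal"

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.quantile_method not in ("lognormal", "normal", "empirical"):
            raise ValueError(
                "quantile_method must be 'lognormal', 'normal' or 'empirical'"
            )


@dataclass(frozen=True)
class KnnConfig:
    """Neighbour caps and acceptance thresholds for the dual kNN."""

    k_distance: int = 9
    k_correlation: int = 9
    max_distance: float = 0.1
    min_correlation: float = 0.98

    def __post_init__(self) -> None:
        if self.k_distance < 1 or self.k_correlation < 1:
            raise ValueError("k must be >= 1")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not -1.0 <= self.min_correlation <= 1.0:
            raise ValueError("min_correlation must be in [-1, 1]")


class Neighbor(NamedTuple):
    """One accepted library neighbour (library row reference)."""

    row: int
    distance: float
    correlation: float


@dataclass
class NeighborSet:
    """Accepted neighbours from both metrics, sorted best-first."""

    by_distance: list[Neighbor] = field(default_factory=list)
    by_correlation: list[Neighbor] = field(default_factory=list)

    @property
    def combined(self) -> list[Neighbor]:
        """Union as a multiset: a scan accepted by both metrics counts twice."""
        return self.by_distance + self.by_correlation

    @property
    def is_empty(self) -> bool:
        return not (self.by_distance or self.by_correlation)


@dataclass
class KnnResult:
    """Outcome of the kNN stage for one query scan."""

    status: str  # "ok" | "no_match"
    predicted_identity: str | None
    predicted_conc_wt_pct: float | None
    neighbor_set: NeighborSet

    @property
    def mean_neighbor_distance(self) -> float | None:
        if self.neighbor_set.is_empty:
            return None
        return float(np.mean([n.distance for n in self.neighbor_set.combined]))


def flag_outliers(
    library: LabeledLibrary, config: OutlierConfig | None = None
) -> np.ndarray:
    """Boolean mask of replicate-outlier scans, aligned with library rows.

    A PCA is fitted once on the full preprocessed matrix (mean-centred, no
    scaling).  Within each sample, each scan's mean Euclidean distance to
    the sample's other scans is computed on the leading PC scores, and
    scans strictly above the sample's 99 % quantile of those means are
    flagged.  Samples with a single scan are never flagged.
    """
    if config is None:
        config = OutlierConfig()
    X = library.matrix
    n_comp = min(config.n_components, X.shape[0], X.shape[1])
    if n_comp < config.n_components:
        warnings.warn(
            f"library supports only {n_comp} principal component(s); "
            f"requested {config.n_components}",
            RuntimeWarning,
            stacklevel=2,
        )
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)

    mask = np.zeros(X.shape[0], dtype=bool)
    sample_ids = library.sample_ids
    for sid in np.unique(sample_ids):
        idx = np.nonzero(sample_ids == sid)[0]
        if idx.size < 2:
            continue
        pts = scores[idx]
        dists = np.sqrt(
            np.maximum(
                ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1), 0.0
            )
        )
        mean_d = dists.sum(axis=1) / (idx.size - 1)
        # numerically identical replicates carry no spread signal
        tol = 1e-8 * max(1.0, float(np.abs(pts).max()))
        if np.all(mean_d <= tol):
            continue
        if config.quantile_method == "empirical":
            cutoff = float(np.quantile(mean_d, config.quantile))
        elif config.quantile_method == "normal":
            sd = mean_d.std(ddof=1)
            cutoff = float(mean_d.mean() + norm.ppf(config.quantile) * sd)
        else:  # lognormal
            if np.any(mean_d <= tol):
                # some scans coincide: fall back to flagging nothing
                cutoff = float(mean_d.max())
            else:
                lm = np.log(mean_d)
                cutoff = float(
                    np.exp(lm.mean() + norm.ppf(config.quantile) * lm.std(ddof=1))
                )
        mask[idx[mean_d > cutoff]] = True
    return mask


def query_neighbors(
    query: np.ndarray,
    library: LabeledLibrary,
    config: KnnConfig | None = None,
    excluded_sample_ids: AbstractSet[str] = frozenset(),
    candidate_mask: np.ndarray | None = None,
) -> NeighborSet:
    """Rank the library against one preprocessed query spectrum.

    Returns up to ``k_distance`` nearest scans within ``max_distance`` and
    up to ``k_correlation`` most-correlated scans above
    ``min_correlation`` (both thresholds inclusive).  Rows of excluded
    samples — e.g. the query's own sample under leave-one-sample-out
    cross-validation — and rows where ``candidate_mask`` is False (e.g.
    flagged outliers) are removed before ranking.  Ties break by library
    row order.
    """
    if config is None:
        config = KnnConfig()
    q = np.asarray(query, dtype=float)
    if q.ndim != 1 or q.size != library.matrix.shape[1]:
        raise ValueError(
            f"query length {q.size} does not match library width "
            f"{library.matrix.shape[1]} (tag={library.preprocess_tag!r})"
        )
    keep = np.ones(library.n_scans, dtype=bool)
    if candidate_mask is not None:
        keep &= np.asarray(candidate_mask, dtype=bool)
    if excluded_sample_ids:
        keep &= ~np.isin(library.sample_ids, list(excluded_sample_ids))
    rows = np.nonzero(keep)[0]
    if rows.size == 0:
        return NeighborSet()

    M = library.matrix[rows]
    diffs = M - q
    dist = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))

    qc = q - q.mean()
    qn = np.sqrt(qc @ qc)
    Mc = M - M.mean(axis=1, keepdims=True)
    Mn = np.sqrt(np.einsum("ij,ij->i", Mc, Mc))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Mc @ qc) / (Mn * qn)
    corr = np.where(np.isfinite(corr), corr, -np.inf)

    by_distance: list[Neighbor] = []
    order = np.argsort(dist, kind="stable")
    for j in order[: config.k_distance]:
        if dist[j] <= config.max_distance:
            by_distance.append(
                Neighbor(int(rows[j]), float(dist[j]), float(corr[j]))
            )

    by_correlation: list[Neighbor] = []
    order = np.argsort(-corr, kind="stable")
    for j in order[: config.k_correlation]:
        if corr[j] >= config.min_correlation:
            by_correlation.append(
                Neighbor(int(rows[j]), float(dist[j]), float(corr[j]))
            )
    return NeighborSet(by_distance=by_distance, by_correlation=by_correlation)


def knn_predict(neighbors: NeighborSet, library: LabeledLibrary) -> KnnResult:
    """Identity vote + concentration average over the combined neighbours.

    Identity is the modal composition label over the combined multiset
    (a scan selected by both metrics counts twice); ties break towards the
    identity with the smallest mean Euclidean distance.  Concentration is
    the arithmetic mean of the neighbours' known cocaine weight percents.
    An empty neighbour set yields an abstention (``status="no_match"``).
    """
    if neighbors.is_empty:
        return KnnResult("no_match", None, None, neighbors)
    combined = neighbors.combined
    identities = [library.meta_for_row(n.row).identity for n in combined]
    counts = Counter(identities)
    top = max(counts.values())
    tied = [ident for ident, c in counts.items() if c == top]
    if len(tied) == 1:
        identity = tied[0]
    else:
        mean_dist = {
            ident: np.mean(
                [n.distance for n, i in zip(combined, identities) if i == ident]
            )
            for ident in tied
        }
        identity = min(tied, key=lambda i: (mean_dist[i], i))
    conc = float(
        np.mean([library.meta_for_row(n.row).cocaine_wt_pct for n in combined])
    )
    return KnnResult("ok", identity, conc, neighbors)
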