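"""Per-individual risk features and the two-pathway decision machinery.

Features are the number of variant-containing genes in each of two focal
pathways plus the main-graph node fraction.  Individuals are clustered into
two groups by average-linkage hierarchical clustering on the two counts, a
maximum-margin linear boundary is fitted in the same plane, and an explicit
threshold rule (> 15 genes in the first pathway AND > 10 in the second)
flags high-risk individuals; a main-graph fraction > 0.60 is reported as a
parallel supporting criterion rather than a conjunct.

The published classifier details are from an unavailable supplement; the
reconstruction is a hard-margin linear SVM on the two counts (soft margin
with C = 1 when the data are not separable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.svm import SVC

from . import network_analysis, pathway_analysis
from .errors import ArgumentError

PI3K_MIN = 15
CANCER_MIN = 10
FRACTION_MIN = 0.60


@dataclass(frozen=True)
class RiskFeatures:
    individual_id: str
    n_pi3k_genes: int
    n_cancer_pathway_genes: int
    main_fraction: float
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.n_pi3k_genes < 0 or self.n_cancer_pathway_genes < 0:
            raise ArgumentError("gene counts must be non-negative")


@dataclass(frozen=True)
class LinearBoundary:
    weights: tuple[float, float]
    intercept: float
    margin: float
    hard: bool  # True when fitted as (effectively) hard margin on separable data

    def decide(self, n_pi3k: float, n_cancer: float) -> int:
        """Side of the boundary: +1 / -1 matching the training labels."""
        v = self.weights[0] * n_pi3k + self.weights[1] * n_cancer + self.intercept
        return 1 if v > 0 else -1


def extract_features(
    individual_id: str,
    gene_set: Iterable[str],
    db: pathway_analysis.PathwayDB,
    edges: pd.DataFrame,
    pi3k_id: str,
    cancer_id: str,
    label: str = "unknown",
    score_threshold: float = network_analysis.DEFAULT_THRESHOLD,
    channels: Sequence[str] = network_analysis.DEFAULT_CHANNELS,
) -> RiskFeatures:
    """Assemble the three risk features for one individual's gene set."""
    for pid in (pi3k_id, cancer_id):
        if pid not in db.pathways:
            raise ArgumentError(f"pathway {pid!r} not in database")
    genes = set(gene_set)
    counts = pathway_analysis.pathway_counts(genes, db)
    if genes:
        _, fraction = network_analysis.main_fraction_point(
            genes, edges, score_threshold, channels
        )
    else:
        fraction = 0.0
    return RiskFeatures(
        individual_id=individual_id,
        n_pi3k_genes=counts[pi3k_id],
        n_cancer_pathway_genes=counts[cancer_id],
        main_fraction=fraction,
        label=label,
    )


def cluster_two_groups(
    features: Sequence[RiskFeatures],
) -> tuple[set[str], set[str]]:
    """Split individuals into two groups by agglomerative clustering on the
    two pathway counts (Euclidean distance, average linkage).

    The returned pair is ordered so the group containing the individual with
    the lexicographically smallest id comes first.
    """
    if len(features) < 2:
        raise ArgumentError("clustering needs at least 2 individuals")
    order = sorted(features, key=lambda f: f.individual_id)
    x = np.array(
        [[f.n_pi3k_genes, f.n_cancer_pathway_genes] for f in order], dtype=float
    )
    labels = fcluster(linkage(x, method="average"), t=2, criterion="maxclust")
    g1 = {f.individual_id for f, lab in zip(order, labels) if lab == labels[0]}
    g2 = {f.individual_id for f, lab in zip(order, labels) if lab != labels[0]}
    return g1, g2


def fit_boundary(
    features: Sequence[RiskFeatures],
    labels: Sequence[int],
    soft_c: float = 1.0,
) -> LinearBoundary:
    """Maximum-margin line in the (n_pi3k, n_cancer) plane.

    Separable data get a hard margin (large-C limit); otherwise a soft
    margin with penalty ``soft_c`` is used.  Deterministic.
    """
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ArgumentError("both classes must be present")
    x = np.array(
        [[f.n_pi3k_genes, f.n_cancer_pathway_genes] for f in features], dtype=float
    )
    # hard-margin probe: large C with a finite iteration cap, because libsvm
    # does not terminate at huge C on non-separable data
    clf = SVC(kernel="linear", C=1e9, max_iter=1_000_000)
    clf.fit(x, y)
    hard = bool((clf.predict(x) == y).all())
    if not hard:
        clf = SVC(kernel="linear", C=soft_c)
        clf.fit(x, y)
    w = clf.coef_[0]
    norm = float(np.hypot(w[0], w[1]))
    if norm == 0:
        raise ArgumentError("degenerate boundary (zero weight vector)")
    return LinearBoundary(
        weights=(float(w[0]), float(w[1])),
        intercept=float(clf.intercept_[0]),
        margin=1.0 / norm,
        hard=hard,
    )


@dataclass(frozen=True)
class RiskCall:
    individual_id: str
    risk: str  # high_risk | low_risk
    fraction_flag: bool  # supporting criterion: main fraction above threshold


def decision_rule(
    features: RiskFeatures,
    pi3k_min: int = PI3K_MIN,
    cancer_min: int = CANCER_MIN,
    fraction_min: float = FRACTION_MIN,
) -> RiskCall:
    """Explicit threshold rule: high risk iff strictly more than ``pi3k_min``
    genes in the first pathway AND strictly more than ``cancer_min`` in the
    second.  The main-graph fraction criterion is reported separately."""
    high = (
        features.n_pi3k_genes > pi3k_min
        and features.n_cancer_pathway_genes > cancer_min
    )
    return RiskCall(
        individual_id=features.individual_id,
        risk="high_risk" if high else "low_risk",
        fraction_flag=features.main_fraction > fraction_min,
    )
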