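"""Fungal community tables: relative abundance, Hellinger transform, taxon selection.

Soil mycorrhizal communities are compositional: per tree, taxon abundances
(AMF virtual taxa or EMF genera) sum to the sequencing depth.  The growth
model consumes Hellinger-transformed relative abundances — the elementwise
square root of the composition — which places community vectors on the unit
sphere so Euclidean distance between transformed rows equals the Hellinger
distance between compositions.  Of the full taxon table only the seven most
important taxa enter the model; importance is scored from a PCA of the
centered Hellinger matrix (absolute loadings on the first three components,
weighted by each component's explained-variance fraction).  That weighting
rule is this package's own deterministic stand-in for an ordination-guided
choice; an abundance-ranking alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "TaxaSelection",
    "relative_abundance",
    "hellinger_transform",
    "select_dominant_taxa",
    "coverage_summary",
]


@dataclass
class CommunityMatrix:
    """Trees x taxa abundance matrix with an explicit transformation state.

    ``state`` is one of ``"counts"``, ``"relative"`` (rows sum to 1) or
    ``"hellinger"`` (rows have unit Euclidean norm).
    """

    tree_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray = field(repr=False)
    state: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.tree_ids), len(self.taxon_ids)):
            raise ValueError("values shape does not match tree/taxon ids")
        if np.any(np.isnan(self.values)):
            raise ValueError("NaN abundance")
        if np.any(self.values < 0):
            raise ValueError("negative abundance")
        if self.state not in ("counts", "relative", "hellinger"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "relative" and not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("relative state requires unit row sums")
        if self.state == "hellinger" and not np.allclose(
            np.sum(self.values**2, axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("hellinger state requires unit row norms")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tree_ids, columns=self.taxon_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, state: str = "counts") -> "CommunityMatrix":
        return cls(
            tree_ids=[str(i) for i in df.index],
            taxon_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            state=state,
        )


@dataclass
class TaxaSelection:
    """Outcome of dominant-taxon selection.

    ``selected`` is ordered by decreasing importance; ``coverage`` holds the
    per-tree fraction of the community (relative abundance) represented by
    the selected taxa.
    """

    selected: list[str]
    importance_scores: pd.Series
    coverage: pd.Series


def relative_abundance(m: CommunityMatrix) -> CommunityMatrix:
    """Convert counts to relative abundances (rows sum to 1)."""
    sums = m.values.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero abundance row for tree {m.tree_ids[zero[0]]}")
    return CommunityMatrix(m.tree_ids, m.taxon_ids, m.values / sums[:, None], "relative")


def hellinger_transform(m: CommunityMatrix) -> CommunityMatrix:
    """Elementwise square root of relative abundances (unit-norm rows)."""
    if m.state != "relative":
        raise ValueError("hellinger_transform expects a relative-abundance matrix")
    return CommunityMatrix(m.tree_ids, m.taxon_ids, np.sqrt(m.values), "hellinger")


def _pca_importance(values: np.ndarray, n_components: int) -> np.ndarray:
    """Importance per taxon from the first ``n_components`` PCA axes.

    importance_j = sum_c |loading_{j,c}| * varfrac_c, computed from the SVD of
    the column-centered matrix.  Scores use absolute loadings, so the SVD sign
    ambiguity cannot affect them.
    """
    x = values - values.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        return np.zeros(values.shape[1])
    k = min(n_components, s.size)
    varfrac = var[:k] / total
    return np.abs(vt[:k]).T @ varfrac


def select_dominant_taxa(
    m: CommunityMatrix,
    k: int = 7,
    n_components: int = 3,
    method: str = "pca",
) -> TaxaSelection:
    """Select the ``k`` most important taxa of a Hellinger matrix.

    ``method="pca"`` scores taxa by variance-weighted absolute PCA loadings;
    ``method="abundance"`` ranks by mean Hellinger abundance.  Ties are broken
    by higher mean Hellinger abundance, then lexically by taxon id.  Per-tree
    coverage is the summed relative abundance (squared Hellinger values) of
    the selected taxa.
    """
    if m.state != "hellinger":
        raise ValueError("select_dominant_taxa expects a hellinger matrix")
    n_taxa = len(m.taxon_ids)
    if n_taxa < k:
        raise ValueError(f"need at least k={k} taxa, have {n_taxa}")
    if len(m.tree_ids) < n_components + 1:
        raise ValueError("need at least n_components + 1 trees")
    mean_ab = m.values.mean(axis=0)
    if method == "pca":
        importance = _pca_importance(m.values, n_components)
    elif method == "abundance":
        importance = mean_ab.copy()
    else:
        raise ValueError(f"unknown method {method!r}")
    order = sorted(
        range(n_taxa), key=lambda j: (-importance[j], -mean_ab[j], m.taxon_ids[j])
    )
    selected_idx = order[:k]
    coverage = np.sum(m.values[:, selected_idx] ** 2, axis=1)
    return TaxaSelection(
        selected=[m.taxon_ids[j] for j in selected_idx],
        importance_scores=pd.Series(importance, index=m.taxon_ids, name="importance"),
        coverage=pd.Series(coverage, index=m.tree_ids, name="coverage"),
    )


def coverage_summary(selection: TaxaSelection) -> tuple[float, float]:
    """Mean and sample SD of the per-tree coverage fractions."""
    cov = selection.coverage.to_numpy()
    sd = float(np.std(cov, ddof=1)) if cov.size > 1 else 0.0
    return float(np.mean(cov)), sd
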