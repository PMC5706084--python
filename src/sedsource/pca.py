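"""Variance-covariance principal component analysis in two orientations.

The classical orientation treats chemicals as variables and positions as
observations; the screening orientation transposes this and treats *sampling
positions* as the variables, so that positions whose concentration profile
departs from the shared diffuse-contamination pattern surface as extreme
coordinates on the leading components.  Covariance (not correlation) is the
default: the matrices analysed are hazard or risk quotients, already on a
common dimensionless scale, and the spread itself is informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import ChemicalRegistry, ContaminationMatrix
from . import outliers as _outliers

__all__ = [
    "PCAResult",
    "OutlierRanking",
    "covariance_pca",
    "variable_variance_weights",
    "eliminate_dominant_and_rerun",
    "scree_select",
    "rank_score_outliers",
    "subset_pca",
]

CHEMICALS_AS_VARIABLES = "chemicals_as_variables"
SAMPLES_AS_VARIABLES = "samples_as_variables"


@dataclass
class PCAResult:
    """Eigendecomposition of a variance-covariance matrix.

    ``loadings`` holds the orthonormal eigenvectors (variables x components);
    ``scores`` the projections of the centered observations.  In the
    samples-as-variables orientation the PCA *variables* are positions, and
    :meth:`variable_coordinates` gives each variable's covariance-scaled
    coordinate ``loading * sqrt(eigenvalue)`` on the leading components —
    the quantity read off a score plot when hunting outlying positions.
    """

    orientation: str
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    variable_weights: pd.Series
    total_variance: float = field(default=0.0)

    @property
    def variables(self) -> list[str]:
        return list(self.loadings.index)

    def variable_coordinates(self, n_components: int) -> pd.DataFrame:
        if n_components < 1 or n_components > len(self.eigenvalues):
            raise ValueError(
                f"n_components must be in [1, {len(self.eigenvalues)}], "
                f"got {n_components}"
            )
        lam = np.sqrt(np.clip(self.eigenvalues[:n_components], 0.0, None))
        coords = self.loadings.iloc[:, :n_components] * lam
        return coords


@dataclass
class OutlierRanking:
    """Positions ranked by their distance from the bulk in component space."""

    ranking: list[tuple[str, float]]
    selected: list[str]
    method: str
    cutoff: float
    n_components: int

    @property
    def positions(self) -> list[str]:
        return [p for p, _ in self.ranking]

    @property
    def distances(self) -> list[float]:
        return [d for _, d in self.ranking]


def _orient(matrix: ContaminationMatrix, orientation: str) -> pd.DataFrame:
    """Observations in rows, variables in columns for the chosen orientation."""
    if orientation == CHEMICALS_AS_VARIABLES:
        return matrix.data
    if orientation == SAMPLES_AS_VARIABLES:
        return matrix.data.T
    raise ValueError(f"unknown orientation {orientation!r}")


def covariance_pca(
    matrix: ContaminationMatrix,
    orientation: str = CHEMICALS_AS_VARIABLES,
    use_correlation: bool = False,
) -> PCAResult:
    """Eigendecomposition of the variance-covariance matrix.

    Columns (variables) are mean-centered but not scaled; missing cells are
    handled by pairwise-complete covariance (an approximation — the resulting
    matrix may have slightly negative trailing eigenvalues, which are clipped
    to zero when forming explained-variance fractions).  Scores are computed
    from mean-imputed centered data when cells are missing.
    """
    if matrix.value_kind not in ("hq", "risk_quotient"):
        raise ValueError(
            "covariance_pca expects a normalised (hq or risk_quotient) matrix"
        )
    X = _orient(matrix, orientation)
    if X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 variables and 2 observations")

    frac_missing = X.isna().mean()
    bad = frac_missing[frac_missing > 0.5]
    if len(bad):
        warnings.warn(
            f"variables with >50% missing values: {list(bad.index)}", stacklevel=2
        )

    C = X.corr(min_periods=2) if use_correlation else X.cov(min_periods=2)
    if C.isna().any().any():
        raise ValueError("covariance undefined for some variable pair (too few data)")
    Cv = C.to_numpy()
    total = float(np.trace(Cv))
    if total <= 0 or not np.isfinite(total):
        raise ValueError("matrix has zero total variance (constant data)")

    eigval, eigvec = np.linalg.eigh(Cv)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # eigenvector sign is arbitrary: orient so the largest-|.| element is positive
    for k in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[i, k] < 0:
            eigvec[:, k] = -eigvec[:, k]

    clipped = np.clip(eigval, 0.0, None)
    frac = clipped / clipped.sum()

    comp_names = [f"PC{k + 1}" for k in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=X.columns, columns=comp_names)

    centered = X - X.mean()
    scores = pd.DataFrame(
        centered.fillna(0.0).to_numpy() @ eigvec, index=X.index, columns=comp_names
    )
    weights = pd.Series(np.diag(Cv) / total, index=X.columns)

    return PCAResult(
        orientation=orientation,
        eigenvalues=eigval,
        explained_fraction=frac,
        loadings=loadings,
        scores=scores,
        variable_weights=weights,
        total_variance=total,
    )


def variable_variance_weights(result: PCAResult) -> pd.Series:
    """Percentage of the overall variance carried by each chemical.

    The diagonal of the covariance matrix over its trace, as percentages
    summing to 100.  A single chemical with a very large weight signals a
    dominant (usually nonpoint) pollutant whose spread swamps the rest of
    the dataset and is a candidate for elimination and re-analysis.
    """
    if result.orientation != CHEMICALS_AS_VARIABLES:
        raise ValueError("variance weights are defined for chemicals-as-variables PCA")
    return result.variable_weights * 100.0


def eliminate_dominant_and_rerun(
    matrix: ContaminationMatrix,
    variable: str,
    orientation: str = CHEMICALS_AS_VARIABLES,
) -> PCAResult:
    """Drop one chemical's column and recompute the PCA on the rest.

    Used after a dominant diffuse pollutant is identified: removing it lets
    the secondary variance structure (the actual point-source signal) emerge.
    """
    reduced = matrix.drop_chemical(variable)
    if len(reduced.chemicals) < 2:
        raise ValueError("removing the variable leaves fewer than 2 chemicals")
    return covariance_pca(reduced, orientation=orientation)


def scree_select(
    eigenvalues: Sequence[float],
    rule: str = "cumulative",
    threshold: float = 0.95,
) -> int:
    """Number of components to retain from a descending eigenvalue spectrum.

    ``cumulative`` (default) keeps the smallest k whose cumulative explained
    fraction reaches ``threshold``; ``largest_drop`` keeps everything before
    the largest relative gap, the automated analogue of reading a scree-plot
    elbow by eye.
    """
    lam = np.clip(np.asarray(list(eigenvalues), dtype=float), 0.0, None)
    if lam.size == 0:
        raise ValueError("empty eigenvalue spectrum")
    if rule == "cumulative":
        frac = np.cumsum(lam) / lam.sum()
        return int(np.searchsorted(frac, threshold - 1e-12) + 1)
    if rule == "largest_drop":
        if lam.size == 1:
            return 1
        prev = np.where(lam[:-1] > 0, lam[:-1], np.inf)
        drops = (lam[:-1] - lam[1:]) / prev
        return int(np.argmax(drops) + 1)
    raise ValueError(f"unknown scree rule {rule!r}")


def rank_score_outliers(
    result: PCAResult,
    n_components: int = 2,
    method: str = "robust_distance",
    cutoff: float = 4.0,
) -> OutlierRanking:
    """Rank positions by how far they sit from the bulk in component space.

    Operates on the samples-as-variables orientation, where each position has
    a coordinate ``loading * sqrt(eigenvalue)`` per retained component.

    ``robust_distance`` scores each position's coordinate on each component
    with the MAD-based On statistic and combines components by the maximum;
    positions with On >= ``cutoff`` on any retained component are selected.
    ``per_pc_extreme`` ranks by the largest absolute coordinate and selects
    the single most extreme position per component (the by-eye reading of a
    score plot).
    """
    if result.orientation != SAMPLES_AS_VARIABLES:
        raise ValueError("outlier ranking requires samples-as-variables orientation")
    coords = result.variable_coordinates(n_components)
    positions = list(coords.index)
    # components with numerically-zero eigenvalues carry only rounding noise;
    # scoring ratios of that noise would fabricate outliers
    lam = np.clip(result.eigenvalues[:n_components], 0.0, None)
    live = lam > 1e-10 * max(float(result.eigenvalues[0]), 1e-300)

    def _component_on(v: np.ndarray) -> np.ndarray:
        med = np.median(v)
        dev = np.abs(v - med)
        # deviations at rounding level of the coordinate scale are not signal
        tol = 1e-9 * max(float(np.max(np.abs(v))), 1e-300)
        dev[dev < tol] = 0.0
        m = float(np.median(dev))
        if m <= tol:
            return np.where(dev == 0.0, 0.0, np.inf)
        return dev / m

    if method == "robust_distance":
        per_comp = np.column_stack(
            [
                _component_on(coords[c].to_numpy())
                if live[k]
                else np.zeros(len(positions))
                for k, c in enumerate(coords.columns)
            ]
        )
        dist = per_comp.max(axis=1)
        selected = [p for p, d in zip(positions, dist) if d >= cutoff]
    elif method == "per_pc_extreme":
        absc = coords.abs()
        dist = absc.max(axis=1).to_numpy()
        selected = sorted(
            {str(absc[c].idxmax()) for k, c in enumerate(absc.columns) if live[k]}
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    order = np.argsort(-dist, kind="stable")
    ranking = [(positions[i], float(dist[i])) for i in order]
    selected = sorted(selected, key=lambda p: -dist[positions.index(p)])
    return OutlierRanking(
        ranking=ranking,
        selected=selected,
        method=method,
        cutoff=cutoff,
        n_components=n_components,
    )


def subset_pca(
    matrix: ContaminationMatrix,
    chem_classes: Iterable,
    registry: ChemicalRegistry,
    orientation: str = SAMPLES_AS_VARIABLES,
) -> PCAResult:
    """PCA restricted to the chemicals of the requested classes.

    Running the screening PCA separately on, e.g., PAH/hydrocarbons versus
    heavy metals disentangles sources whose fingerprints live in different
    chemical families.
    """
    names = [c for c in registry.of_classes(chem_classes) if c in matrix.chemicals]
    if not names:
        raise ValueError("no chemicals of the requested classes in the matrix")
    return covariance_pca(matrix.subset(names), orientation=orientation)
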