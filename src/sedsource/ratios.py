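"""Ratio-matching fingerprints and band-based clustering of positions.

Samples polluted by the same source keep similar ratios between trace
pollutant concentrations even when absolute levels differ by dilution with
inert material.  Each sample is therefore summarised by the strictly-upper
triangle of its m x m pairwise concentration ratio matrix (m(m-1)/2 entries);
two samples are compared by dividing corresponding ratios, and a pair of
ratios "matches" when the quotient falls inside an acceptance band around 1
(default 0.90-1.10).  Positions linked by a high fraction of matching ratios
cluster together; positions near an isolated discharge come out as singleton
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence

import math

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data import ContaminationMatrix

__all__ = [
    "RatioMatrix",
    "PairSimilarity",
    "ClusterSet",
    "ratio_matrix",
    "ratio_matrix_from_row",
    "compare",
    "cluster",
]


@dataclass(frozen=True)
class RatioMatrix:
    """Upper-triangular pairwise concentration ratios of one sample.

    ``ratios`` maps index pairs (i, j) with i < j (indices into ``chemicals``)
    to c_i / c_j.  Pairs involving missing, zero or below-detection-limit
    concentrations are absent (masked): a ratio built on a censored value is
    not fingerprint evidence.
    """

    position: str
    chemicals: tuple[str, ...]
    ratios: Mapping[tuple[int, int], float]

    def __post_init__(self) -> None:
        for (i, j), r in self.ratios.items():
            if not (i < j):
                raise ValueError(f"ratio index pair {(i, j)} not upper-triangular")
            if not (math.isfinite(r) and r > 0):
                raise ValueError(f"ratio {(i, j)} not finite positive: {r}")


@dataclass(frozen=True)
class PairSimilarity:
    """Elementwise comparison of two ratio fingerprints.

    ``in_band_fraction`` is the share of jointly unmasked ratio pairs whose
    quotient falls inside the acceptance band.
    """

    pair: tuple[str, str]
    quotients: Mapping[tuple[int, int], float]
    in_band_fraction: float
    n_compared: int


@dataclass
class ClusterSet:
    """Groups of positions sharing a ratio fingerprint, plus singletons."""

    clusters: list[frozenset[str]]
    singletons: list[str]
    band: tuple[float, float]
    link_threshold: float
    chem_subset: tuple[str, ...] | None = None
    similarity: "np.ndarray | None" = field(default=None, repr=False)
    positions: tuple[str, ...] | None = field(default=None, repr=False)

    @property
    def all_positions(self) -> frozenset[str]:
        out: set[str] = set(self.singletons)
        for c in self.clusters:
            out |= c
        return frozenset(out)

    def cluster_of(self, position: str) -> frozenset[str] | None:
        for c in self.clusters:
            if position in c:
                return c
        return None


def ratio_matrix(
    concentrations: Mapping[str, float | None],
    chemicals: Sequence[str],
    bdl: Iterable[str] = (),
) -> RatioMatrix:
    """Build one sample's upper-triangular ratio fingerprint.

    Only chemicals with a positive, measured, above-detection-limit value
    participate; all other pairs are masked.
    """
    bdl = set(bdl)
    valid = [
        k
        for k, c in enumerate(chemicals)
        if c in concentrations
        and concentrations[c] is not None
        and np.isfinite(concentrations[c])
        and concentrations[c] > 0
        and c not in bdl
    ]
    if len(valid) < 2:
        raise ValueError("fewer than 2 valid chemicals: no ratios can be formed")
    ratios: dict[tuple[int, int], float] = {}
    for a, i in enumerate(valid):
        for j in valid[a + 1 :]:
            ratios[(i, j)] = float(concentrations[chemicals[i]]) / float(
                concentrations[chemicals[j]]
            )
    return RatioMatrix(position="", chemicals=tuple(chemicals), ratios=ratios)


def ratio_matrix_from_row(
    matrix: ContaminationMatrix, position: str, chemicals: Sequence[str] | None = None
) -> RatioMatrix:
    """Fingerprint of one matrix row, masking BDL-only and missing cells."""
    chems = list(chemicals) if chemicals is not None else matrix.chemicals
    row = matrix.data.loc[position]
    bdl_row = matrix.bdl_mask.loc[position]
    conc = {c: (None if np.isnan(row[c]) else float(row[c])) for c in chems}
    bdl = {c for c in chems if bool(bdl_row[c])}
    rm = ratio_matrix(conc, chems, bdl=bdl)
    return RatioMatrix(position=position, chemicals=rm.chemicals, ratios=rm.ratios)


def _in_band(r: float, band: tuple[float, float], mode: str) -> bool:
    low, high = band
    if mode == "symmetric":
        # reciprocal-symmetric reading of the band: min(r, 1/r) >= low,
        # i.e. |log r| <= |log low| — comparison order then cannot matter
        return min(r, 1.0 / r) >= low
    if mode == "literal":
        return low <= r <= high
    raise ValueError(f"unknown band mode {mode!r}")


def compare(
    a: RatioMatrix,
    b: RatioMatrix,
    band: tuple[float, float] = (0.90, 1.10),
    mode: str = "symmetric",
) -> PairSimilarity:
    """Elementwise quotient of two fingerprints and its in-band fraction.

    Only ratio pairs present (unmasked) in both fingerprints are compared.
    Under the default symmetric band the result is order-independent:
    swapping ``a`` and ``b`` reciprocates every quotient but flips no
    in-band decision.
    """
    if a.chemicals != b.chemicals:
        raise ValueError("fingerprints use different chemical orderings")
    if band[0] >= band[1]:
        raise ValueError(f"band low must be < high, got {band}")
    common = set(a.ratios) & set(b.ratios)
    if not common:
        raise ValueError(
            f"fingerprints of {a.position!r} and {b.position!r} share no unmasked pair"
        )
    quotients = {k: a.ratios[k] / b.ratios[k] for k in sorted(common)}
    n_in = sum(_in_band(r, band, mode) for r in quotients.values())
    return PairSimilarity(
        pair=(a.position, b.position),
        quotients=quotients,
        in_band_fraction=n_in / len(common),
        n_compared=len(common),
    )


def cluster(
    matrix: ContaminationMatrix,
    band: tuple[float, float] = (0.90, 1.10),
    link_threshold: float = 0.90,
    chem_subset: Sequence[str] | None = None,
    positions: Sequence[str] | None = None,
    mode: str = "symmetric",
    method: str = "components",
    min_compared: int = 3,
) -> ClusterSet:
    """Group positions whose ratio fingerprints match within the band.

    Two positions are linked when at least ``link_threshold`` of their jointly
    unmasked ratio quotients fall inside the acceptance band, provided at
    least ``min_compared`` ratios could be compared at all — agreement on one
    or two surviving ratios is too little fingerprint evidence to merge
    positions when the rest of the subset is masked.  ``components``
    (default) returns connected components of the link graph; ``average``
    cuts an average-linkage dendrogram on 1 - in_band_fraction at
    1 - link_threshold.  Positions with no link (or with fewer than two valid
    chemicals in the subset) are returned as singletons.
    """
    if band[0] >= band[1]:
        raise ValueError(f"band low must be < high, got {band}")
    pos = list(positions) if positions is not None else matrix.points
    if len(pos) < 2:
        raise ValueError("need at least 2 positions to cluster")
    chems = list(chem_subset) if chem_subset is not None else matrix.chemicals

    fps: dict[str, RatioMatrix] = {}
    for p in pos:
        try:
            fps[p] = ratio_matrix_from_row(matrix, p, chems)
        except ValueError:
            continue  # too few valid chemicals: stays a singleton

    usable = [p for p in pos if p in fps]
    n = len(usable)
    sim = np.zeros((n, n))
    np.fill_diagonal(sim, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                ps = compare(fps[usable[i]], fps[usable[j]], band=band, mode=mode)
            except ValueError:
                continue  # disjoint masks: no comparable evidence, no link
            if ps.n_compared < min_compared:
                continue
            sim[i, j] = sim[j, i] = ps.in_band_fraction

    if method == "components":
        g = nx.Graph()
        g.add_nodes_from(usable)
        for i in range(n):
            for j in range(i + 1, n):
                if sim[i, j] >= link_threshold:
                    g.add_edge(usable[i], usable[j])
        groups = [frozenset(c) for c in nx.connected_components(g)]
    elif method == "average":
        if n >= 2:
            dist = squareform(1.0 - sim, checks=False)
            labels = fcluster(
                linkage(dist, method="average"), 1.0 - link_threshold, criterion="distance"
            )
            groups = [
                frozenset(np.array(usable)[labels == lab]) for lab in np.unique(labels)
            ]
        else:
            groups = [frozenset(usable)] if usable else []
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    clusters = sorted(
        (g for g in groups if len(g) >= 2), key=lambda s: (-len(s), sorted(s))
    )
    in_cluster = set().union(*clusters) if clusters else set()
    singletons = sorted(set(pos) - in_cluster)
    return ClusterSet(
        clusters=clusters,
        singletons=singletons,
        band=band,
        link_threshold=link_threshold,
        chem_subset=tuple(chems),
        similarity=sim,
        positions=tuple(usable),
    )
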