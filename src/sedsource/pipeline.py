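"""End-to-end orchestration of the source-identification procedure.

The pipeline chains the stages:

* Step 0 — chemicals-as-variables covariance PCA on hazard quotients,
  per-chemical variance weights, optional elimination of the dominant
  (nonpoint) pollutant and PCA re-run;
* Step 1 — samples-as-variables PCA with score-based outlier ranking, plus
  separate runs for the PAH/hydrocarbon and heavy-metal families;
* Step 2 — MAD/On screening of every (position, chemical) cell at the
  configured cutoff, naming the offending chemicals per flagged position;
* Step 3 — ratio-matching cluster runs, one per chemical subset (class-based
  subsets plus subsets hypothesised from Step 2's offending chemicals);
* Step 5 — PNEC risk normalisation and risk-oriented ranking.

(The map-reading attribution step between 3 and 5 is a human task: the
closest this package comes is joining flagged positions against a
user-supplied position -> facility table.)

Everything is importable; the examples/ scripts show typical driving code.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .data import (
    AliasTable,
    ChemClass,
    ChemicalRegistry,
    ContaminationMatrix,
    SampleRecord,
    aggregate_to_matrix,
    compute_hq,
)
from . import pca as _pca
from . import outliers as _outliers
from . import ratios as _ratios
from . import risk as _risk
from . import synthetic as _synthetic

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "simulate_and_run"]


@dataclass
class PipelineConfig:
    """Tunable knobs of the full procedure, with study-matched defaults."""

    aggregator: str = "mean"
    eliminate_dominant: str | None = "auto"  # None, "auto", or a chemical name
    dominant_weight_floor: float = 50.0  # auto elimination only above this weight (%)
    scree_rule: str = "cumulative"
    scree_threshold: float = 0.95
    n_components: int | None = None  # None -> max(2, scree k)
    on_cutoff: float = 4.0
    outlier_method: str = "robust_distance"
    band: tuple[float, float] = (0.90, 1.10)
    band_mode: str = "symmetric"
    link_threshold: float = 0.90
    chem_subsets: Mapping[str, Sequence[str]] | None = None  # extra explicit runs
    derive_subsets_from_step2: bool = True
    run_risk: bool = True
    risk_on_missing: str = "drop"
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["chem_subsets"] is not None:
            d["chem_subsets"] = {k: list(v) for k, v in d["chem_subsets"].items()}
        d["band"] = list(d["band"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All stage artifacts of one pipeline run."""

    raw_matrix: ContaminationMatrix
    hq_matrix: ContaminationMatrix
    chem_pca: _pca.PCAResult
    variance_weights: pd.Series
    eliminated: str | None
    chem_pca_reduced: _pca.PCAResult | None
    sample_pca: _pca.PCAResult
    n_components: int
    outlier_ranking: _pca.OutlierRanking
    subset_pcas: dict[str, _pca.PCAResult]
    outlier_report: _outliers.OutlierReport
    clusters: dict[str, _ratios.ClusterSet]
    risk_matrix: ContaminationMatrix | None
    risk_ranking: _risk.RiskRanking | None
    pnec_audit: dict | None
    manifest: dict


def _auto_subsets(
    report: _outliers.OutlierReport, registry: ChemicalRegistry, matrix: ContaminationMatrix
) -> dict[str, list[str]]:
    """Cluster-run subsets: class families plus Step-2 hypothesised fingerprints."""
    subsets: dict[str, list[str]] = {}
    metals = [c for c in registry.of_classes([ChemClass.HEAVY_METAL]) if c in matrix.chemicals]
    pah_hc = [
        c
        for c in registry.of_classes(
            [ChemClass.PAH, ChemClass.HYDROCARBON, ChemClass.AGGREGATE]
        )
        if c in matrix.chemicals
    ]
    if len(metals) >= 2:
        subsets["metals"] = metals
    if len(pah_hc) >= 2:
        subsets["pah_hc"] = pah_hc
    seen: set[frozenset[str]] = set()
    for pos in report.ordered_sources:
        chems = [c for c in report.per_source_chemicals[pos] if c in matrix.chemicals]
        key = frozenset(chems)
        if len(chems) >= 2 and key not in seen:
            seen.add(key)
            subsets[f"step2_{pos}"] = sorted(chems)
    return subsets


def run_pipeline(
    records: Sequence[SampleRecord],
    registry: ChemicalRegistry,
    aliases: AliasTable | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run Steps 0-3 and 5 over a set of sample records."""
    config = config or PipelineConfig()
    aliases = aliases or AliasTable.identity()

    # Step 0: aggregate, normalise, chemical PCA, dominant elimination
    raw = aggregate_to_matrix(records, aliases, aggregator=config.aggregator)
    hq = compute_hq(raw, registry)
    chem_pca = _pca.covariance_pca(hq, orientation=_pca.CHEMICALS_AS_VARIABLES)
    weights = _pca.variable_variance_weights(chem_pca)

    eliminated: str | None = None
    chem_pca_reduced: _pca.PCAResult | None = None
    if config.eliminate_dominant == "auto":
        top = str(weights.idxmax())
        if weights[top] >= config.dominant_weight_floor:
            eliminated = top
    elif config.eliminate_dominant is not None:
        eliminated = config.eliminate_dominant
    if eliminated is not None:
        chem_pca_reduced = _pca.eliminate_dominant_and_rerun(hq, eliminated)

    # Step 1: samples-as-variables PCA, outlier ranking, class-subset PCAs
    sample_pca = _pca.covariance_pca(hq, orientation=_pca.SAMPLES_AS_VARIABLES)
    k_scree = _pca.scree_select(
        sample_pca.eigenvalues, rule=config.scree_rule, threshold=config.scree_threshold
    )
    n_comp = config.n_components if config.n_components is not None else max(2, k_scree)
    n_comp = min(n_comp, len(sample_pca.eigenvalues))
    ranking = _pca.rank_score_outliers(
        sample_pca,
        n_components=n_comp,
        method=config.outlier_method,
        cutoff=config.on_cutoff,
    )
    subset_pcas: dict[str, _pca.PCAResult] = {}
    for name, classes in (
        ("pah_hc", [ChemClass.PAH, ChemClass.HYDROCARBON, ChemClass.AGGREGATE]),
        ("metals", [ChemClass.HEAVY_METAL]),
    ):
        try:
            subset_pcas[name] = _pca.subset_pca(hq, classes, registry)
        except ValueError as exc:
            warnings.warn(f"subset PCA {name!r} skipped: {exc}", stacklevel=2)

    # Step 2: MAD/On screen
    report = _outliers.identify_point_sources(hq, cutoff=config.on_cutoff)

    # Step 3: ratio-matching cluster runs over the Step-2 flagged set (the
    # outlier set consumed here is exactly the Step-2 report, no recomputation)
    subsets: dict[str, Sequence[str]] = {}
    if config.derive_subsets_from_step2:
        subsets.update(_auto_subsets(report, registry, raw))
    if config.chem_subsets:
        subsets.update(config.chem_subsets)
    clusters: dict[str, _ratios.ClusterSet] = {}
    flagged = report.ordered_sources
    if len(flagged) >= 2:
        for name, chems in subsets.items():
            # a subset run concerns the positions flagged for that subset's
            # chemistry; positions whose exceedances lie elsewhere are pure
            # background in these ratios and would only contribute chance links
            run_positions = [
                p
                for p in flagged
                if set(report.per_source_chemicals[p]) & set(chems)
            ]
            if len(run_positions) < 2:
                continue
            try:
                clusters[name] = _ratios.cluster(
                    raw,
                    band=config.band,
                    link_threshold=config.link_threshold,
                    chem_subset=list(chems),
                    positions=run_positions,
                    mode=config.band_mode,
                )
            except ValueError as exc:
                warnings.warn(f"cluster run {name!r} skipped: {exc}", stacklevel=2)

    # Step 5: PNEC risk ranking
    risk_matrix = risk_ranking = audit = None
    if config.run_risk:
        risk_matrix = _risk.risk_normalize(raw, registry, on_missing=config.risk_on_missing)
        risk_ranking = _risk.rank_by_risk(
            risk_matrix, n_components=n_comp, cutoff=config.on_cutoff
        )
        audit = _risk.pnec_audit(registry, raw.chemicals)

    manifest = {
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_records": len(records),
        "n_positions": len(raw.points),
        "n_chemicals": len(raw.chemicals),
        "eliminated": eliminated,
        "scree_k": int(k_scree),
        "n_components": int(n_comp),
        "flagged_sources": list(report.ordered_sources),
        "cluster_runs": sorted(subsets),
    }

    result = PipelineResult(
        raw_matrix=raw,
        hq_matrix=hq,
        chem_pca=chem_pca,
        variance_weights=weights,
        eliminated=eliminated,
        chem_pca_reduced=chem_pca_reduced,
        sample_pca=sample_pca,
        n_components=n_comp,
        outlier_ranking=ranking,
        subset_pcas=subset_pcas,
        outlier_report=report,
        clusters=clusters,
        risk_matrix=risk_matrix,
        risk_ranking=risk_ranking,
        pnec_audit=audit,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir))
    return result


def _write_bundle(result: PipelineResult, out: Path) -> None:
    """Write stage artifacts as CSV/JSON under ``out``."""
    out.mkdir(parents=True, exist_ok=True)
    result.raw_matrix.data.to_csv(out / "matrix_raw.csv")
    result.hq_matrix.data.to_csv(out / "matrix_hq.csv")
    result.variance_weights.rename("weight_pct").to_csv(out / "variance_weights.csv")
    pd.DataFrame(
        {
            "eigenvalue": result.sample_pca.eigenvalues,
            "explained_fraction": result.sample_pca.explained_fraction,
        }
    ).to_csv(out / "sample_pca_eigenvalues.csv", index=False)
    result.outlier_report.scores.to_csv(out / "on_scores.csv")
    with open(out / "sources.json", "w") as fh:
        json.dump(
            {
                "cutoff": result.outlier_report.cutoff,
                "ordered_sources": result.outlier_report.ordered_sources,
                "per_source_chemicals": result.outlier_report.per_source_chemicals,
                "pca_selected": result.outlier_ranking.selected,
            },
            fh,
            indent=2,
        )
    with open(out / "clusters.json", "w") as fh:
        json.dump(
            {
                name: {
                    "clusters": [sorted(c) for c in cs.clusters],
                    "singletons": cs.singletons,
                    "chem_subset": list(cs.chem_subset or ()),
                }
                for name, cs in result.clusters.items()
            },
            fh,
            indent=2,
        )
    if result.risk_ranking is not None:
        result.risk_matrix.data.to_csv(out / "matrix_risk.csv")
        with open(out / "risk.json", "w") as fh:
            json.dump(
                {
                    "highest_risk": result.risk_ranking.highest_risk,
                    "ranking": result.risk_ranking.ranking.ranking,
                    "pnec_audit": result.pnec_audit,
                },
                fh,
                indent=2,
            )
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def _match_cluster_runs(
    truth: _synthetic.GroundTruth, result: PipelineResult
) -> dict[str, _ratios.ClusterSet]:
    """Pick, per planted source, the cluster run best matching its signature."""
    matched: dict[str, _ratios.ClusterSet] = {}
    for src in truth.sources:
        sig = set(src.signature)
        best, best_score = None, 0.0
        for cs in result.clusters.values():
            sub = set(cs.chem_subset or ())
            if not sub:
                continue
            score = len(sig & sub) / len(sig | sub)
            if score > best_score:
                best, best_score = cs, score
        if best is not None:
            matched[src.name] = best
    return matched


def simulate_and_run(
    scenario: _synthetic.SyntheticScenario,
    config: PipelineConfig | None = None,
) -> tuple[PipelineResult, _synthetic.RecoveryMetrics]:
    """Generate a synthetic dataset, run the pipeline and score recovery."""
    records, truth = _synthetic.generate(scenario)
    result = run_pipeline(records, scenario.registry(), config=config)
    clusters = _match_cluster_runs(truth, result)
    metrics = _synthetic.score_recovery(
        truth, report=result.outlier_report, clusters=clusters or None
    )
    return result, metrics
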