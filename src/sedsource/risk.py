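"""PNEC-based risk screening of sampling positions.

Concentrations are normalised by each chemical's predicted no-effect
concentration for sediment, PNEC_sediment.  Where no sediment PNEC is
supplied directly it is derived from the water-phase PNEC via equilibrium
partitioning,

    PNEC_sediment [mg/kg] = Kp [L/kg] * PNEC_water [mg/L],

and the water-phase PNEC itself may come from acute aquatic toxicity
endpoints through the assessment-factor convention, PNEC_water =
min(endpoint / AF).  The resulting risk-quotient matrix is screened with the
same samples-as-variables covariance PCA used for source identification:
the positions projecting farthest from the bulk are the highest-risk ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from collections.abc import Sequence

from .data import (
    ChemicalProfile,
    ChemicalRegistry,
    ContaminationMatrix,
    ValidationError,
)
from . import pca as _pca

__all__ = [
    "RiskRanking",
    "pnec_sediment",
    "pnec_from_af",
    "resolve_pnec",
    "pnec_audit",
    "risk_normalize",
    "rank_by_risk",
]


def pnec_sediment(kp: float, pnec_water: float) -> float:
    """Sediment PNEC (mg/kg) by equilibrium partitioning from the water phase."""
    if not kp > 0:
        raise ValidationError(f"kp must be > 0, got {kp}")
    if not pnec_water > 0:
        raise ValidationError(f"pnec_water must be > 0, got {pnec_water}")
    return kp * pnec_water


def pnec_from_af(endpoints: Sequence[tuple[float, float]]) -> float:
    """Water-phase PNEC (mg/L) from acute endpoints by assessment factors.

    The standard technical-guidance rule: divide each toxicity endpoint by
    its assessment factor and take the minimum.
    """
    if not endpoints:
        raise ValidationError("no toxicity endpoints supplied")
    quotients = []
    for conc, af in endpoints:
        if not af > 0:
            raise ValidationError(f"assessment factor must be > 0, got {af}")
        if not conc > 0:
            raise ValidationError(f"endpoint concentration must be > 0, got {conc}")
        quotients.append(conc / af)
    return min(quotients)


def resolve_pnec(profile: ChemicalProfile) -> tuple[float, str] | None:
    """Resolve a sediment PNEC for one chemical, or None.

    Resolution order: explicit sediment PNEC, then Kp x PNEC_water, then
    Kp x (assessment-factor PNEC_water from endpoints).  Returns the value
    in mg/kg together with the path used, for the audit trail.
    """
    if profile.pnec_sediment is not None:
        return profile.pnec_sediment, "explicit_sediment_pnec"
    if profile.kp is not None and profile.pnec_water is not None:
        return pnec_sediment(profile.kp, profile.pnec_water), "kp_times_pnec_water"
    if profile.kp is not None and profile.toxicity_endpoints:
        pw = pnec_from_af(profile.toxicity_endpoints)
        return pnec_sediment(profile.kp, pw), "kp_times_af_derived"
    return None


def pnec_audit(registry: ChemicalRegistry, chemicals: Sequence[str]) -> dict[str, dict]:
    """Per-chemical record of which PNEC path was used and the value obtained."""
    audit: dict[str, dict] = {}
    for c in chemicals:
        res = resolve_pnec(registry[c])
        if res is None:
            audit[c] = {"path": "unresolved", "pnec_sediment_mg_kg": None}
        else:
            value, path = res
            audit[c] = {"path": path, "pnec_sediment_mg_kg": value}
    return audit


def risk_normalize(
    matrix: ContaminationMatrix,
    registry: ChemicalRegistry,
    on_missing: str = "drop",
) -> ContaminationMatrix:
    """Divide raw concentrations by each chemical's sediment PNEC.

    Chemicals with no resolvable PNEC (typically aggregates like a summed-PAH
    column) are dropped with a warning by default; pass ``on_missing="raise"``
    to fail instead.
    """
    if matrix.value_kind != "raw":
        raise ValidationError("risk_normalize expects a raw concentration matrix")
    if on_missing not in ("drop", "raise"):
        raise ValueError(f"on_missing must be 'drop' or 'raise', got {on_missing!r}")
    pnecs: dict[str, float] = {}
    unresolved: list[str] = []
    for c in matrix.chemicals:
        res = resolve_pnec(registry[c])
        if res is None:
            unresolved.append(c)
        else:
            pnecs[c] = res[0]
    if unresolved:
        if on_missing == "raise":
            raise ValidationError(f"no resolvable PNEC for chemicals: {unresolved}")
        warnings.warn(
            f"dropping chemicals with no resolvable PNEC: {unresolved}", stacklevel=2
        )
    keep = [c for c in matrix.chemicals if c in pnecs]
    sub = matrix.subset(keep)
    data = sub.data / pd.Series(pnecs)
    return ContaminationMatrix(
        data,
        value_kind="risk_quotient",
        bdl_mask=sub.bdl_mask,
        campaign_coverage=sub.campaign_coverage,
    )


@dataclass
class RiskRanking:
    """Positions ranked by risk-quotient PCA distance from the bulk."""

    matrix: ContaminationMatrix
    pca: _pca.PCAResult
    ranking: _pca.OutlierRanking

    @property
    def ranked_positions(self) -> list[str]:
        return self.ranking.positions

    @property
    def highest_risk(self) -> list[str]:
        return self.ranking.selected


def rank_by_risk(
    matrix: ContaminationMatrix,
    n_components: int = 2,
    cutoff: float = 4.0,
    method: str = "robust_distance",
) -> RiskRanking:
    """Samples-as-variables PCA on the risk matrix, then outlier ranking."""
    if matrix.value_kind != "risk_quotient":
        raise ValidationError("rank_by_risk expects a risk_quotient matrix")
    result = _pca.covariance_pca(matrix, orientation=_pca.SAMPLES_AS_VARIABLES)
    n_components = min(n_components, len(result.eigenvalues))
    ranking = _pca.rank_score_outliers(
        result, n_components=n_components, method=method, cutoff=cutoff
    )
    return RiskRanking(matrix=matrix, pca=result, ranking=ranking)
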