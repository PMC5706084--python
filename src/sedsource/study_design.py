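"""Roster arithmetic for the four-campaign harbour monitoring design.

A multi-year monitoring programme revisits sampling points across campaigns,
renames near-duplicate points, and merges co-located "bis" stations.  This
module encodes such a design — four campaigns collecting 83, 103, 27 and 22
samples over 24, 37, 10 and 10 point visits — and the naming rules under
which the 81 raw point visits collapse to 68 independent positions:

* seven first-campaign points (A1..A4, B1..B3) were re-occupied at different
  locations in campaign 2; the first-campaign ones carry an ``01`` suffix and
  stay distinct;
* three station pairs (F2/F2bis, F4/F4bis, F5/F5bis) are co-located and merge
  via the alias table;
* the fourth campaign added no new points: its 10 visits reuse existing
  positions, with 28 chemicals searched and 5 replicate samples at each of 3
  selected points (22 samples in total).

The roster is synthetic in its point names beyond the documented ones; it is
a bookkeeping template, not the (undeposited) measured dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import AliasTable

__all__ = ["CampaignDesign", "STUDY_DESIGN", "roster_point_visits", "alias_table"]


@dataclass(frozen=True)
class CampaignDesign:
    campaign_id: str
    collected_samples: int
    sampling_points: int
    n_heavy_metals: int
    n_pah: int  # individual congeners + the summed aggregate
    n_hydrocarbons: int

    @property
    def n_chemicals(self) -> int:
        return self.n_heavy_metals + self.n_pah + self.n_hydrocarbons


STUDY_DESIGN: tuple[CampaignDesign, ...] = (
    CampaignDesign("c1", 83, 24, 11, 10 + 1, 2),
    CampaignDesign("c2", 103, 37, 11, 10 + 1, 2),
    CampaignDesign("c3", 27, 10, 11, 10 + 1, 2),
    CampaignDesign("c4", 22, 10, 11, 14 + 1, 2),
)

# Campaign-4 revisits: existing positions only, three of them with 5 replicas.
CAMPAIGN4_POINTS: tuple[str, ...] = (
    "A3", "B2", "B7", "B8", "B9", "E301", "E501", "G101", "INT701", "INT801",
)
CAMPAIGN4_REPLICATED: tuple[str, ...] = ("B2", "INT801", "E301")
CAMPAIGN4_REPLICAS: int = 5

_BIS_PAIRS = ("F2", "F4", "F5")


def alias_table() -> AliasTable:
    """Merge each co-located ``bis`` station into its parent position."""
    return AliasTable({f"{p}bis": p for p in _BIS_PAIRS})


def roster_point_visits() -> dict[str, list[str]]:
    """Raw point names visited per campaign (synthetic template roster).

    Counts per campaign match the study design; duplicate-name rules match
    the documented conventions.  Campaign 1 contributes the suffixed
    A1_01..B3_01 among its 24 points; campaign 2 contributes 37 points
    including the re-occupied A/B names and the three ``bis`` stations;
    campaign 3 adds 10 new stations; campaign 4 revisits 10 existing ones.
    """
    c1 = [f"{x}_01" for x in ("A1", "A2", "A3", "A4", "B1", "B2", "B3")]
    c1 += [f"C{i}" for i in range(1, 11)]  # C1..C10
    c1 += [f"D{i}" for i in range(1, 8)]  # D1..D7
    assert len(c1) == 24

    c2 = ["A1", "A2", "A3", "A4", "B1", "B2", "B3"]
    c2 += [f"B{i}" for i in range(4, 10)]  # B4..B9
    c2 += ["F1", "F2", "F2bis", "F3", "F4", "F4bis", "F5", "F5bis", "F6"]
    c2 += ["E301", "E501", "G101"]
    c2 += [f"E{i}" for i in range(1, 9)]  # E1..E8
    c2 += ["INT1", "INT2", "INT3", "INT4"]
    assert len(c2) == 37

    c3 = ["INT701", "INT801", "INT1bis", "INT2bis"]
    c3 += [f"G{i}" for i in range(1, 7)]  # G1..G6
    assert len(c3) == 10

    c4 = list(CAMPAIGN4_POINTS)
    assert len(c4) == 10

    return {"c1": c1, "c2": c2, "c3": c3, "c4": c4}
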