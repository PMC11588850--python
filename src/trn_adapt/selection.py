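"""Regulator knockout scoring, candidate selection, and adaptation categories.

Regulators are scored for knockout-and-evolve experiments by three criteria:
regulon size, the growth-rate defect of the knockout on the growth
condition, and how well the regulator's iModulon explains its regulon's
expression variance.  A combined growth-impact score summarizes the
expected benefit of losing the regulator: the summed growth impact of the
genes it represses minus that of the genes it activates (removing a
repressor of growth-important genes should help; removing an activator
should hurt).

After evolution, each knockout strain falls into one of four adaptation
categories:

* ``i``   — the regulator was inactive on the growth condition; growth
  recovers without regulator-specific mutations.
* ``ii``  — the regulator was active; growth recovers anyway, without
  regulator-specific mutations (overlapping regulators compensate).
* ``iii`` — the regulator was active; recovery proceeds through convergent
  mutations targeting the regulator's own network.
* ``iv``  — the regulator was active and growth does not recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from trn_adapt.errors import DegenerateStatisticError, InvalidSpecError
from trn_adapt.network import RegulonTable

CATEGORIES = ("i", "ii", "iii", "iv")


@dataclass
class GrowthImpactTable:
    """gene -> relative growth-rate defect of the gene's deletion.

    0 means no defect, 1 means no growth; small negative values (down to
    -0.5) are allowed for deletions that grow faster than wildtype.
    """

    impacts: pd.Series

    def __post_init__(self) -> None:
        vals = self.impacts.to_numpy(dtype=float)
        if ((vals < -0.5) | (vals > 1)).any():
            raise InvalidSpecError("growth impacts must lie in [-0.5, 1]")

    @classmethod
    def from_csv(cls, path: str | Path, column_map: Mapping[str, str] | None = None) -> "GrowthImpactTable":
        df = pd.read_csv(path)
        if column_map:
            df = df.rename(columns={v: k for k, v in column_map.items()})
        return cls(df.set_index("gene")["defect"].astype(float))

    def to_csv(self, path: str | Path) -> None:
        self.impacts.rename("defect").rename_axis("gene").to_csv(path)


@dataclass
class SelectionRecord:
    regulator: str
    regulon_size: int
    ko_growth_defect: float
    imodulon_r2: float
    impact_score: float
    impact_zscore: float = np.nan
    selected: bool = False


def regulon_size(regulon: RegulonTable, tf: str) -> int:
    """Number of distinct annotated targets of ``tf`` (0 if absent)."""
    return len(regulon.targets_of(tf))


def impact_score(
    regulon: RegulonTable,
    impacts: GrowthImpactTable,
    tf: str,
    dual_policy: str = "exclude",
) -> tuple[float, int]:
    """Summed growth impact of repressed targets minus activated targets.

    Dual-effect targets are excluded by default (``dual_policy="exclude"``);
    ``"both"`` counts them in both sums (net zero contribution).  Targets
    lacking an impact value are skipped; their count is returned alongside
    the score.
    """
    recs = regulon.records[regulon.records["regulator"] == tf]
    score = 0.0
    n_scored = 0
    n_missing = 0
    for tgt, effect in recs[["target", "effect"]].itertuples(index=False):
        if effect == "dual" and dual_policy == "exclude":
            continue
        if tgt not in impacts.impacts.index:
            n_missing += 1
            continue
        w = float(impacts.impacts[tgt])
        if effect == "repression":
            score += w
        elif effect == "activation":
            score -= w
        else:  # dual under "both": +w - w = 0, still counts as scored
            pass
        n_scored += 1
    if n_scored == 0:
        raise InvalidSpecError(f"{tf!r} has no scored targets with known impacts")
    return score, n_missing


def impact_zscores(scores: Mapping[str, float]) -> dict:
    """Standardize scores across regulators: (s - mean) / sd, sd with n-1."""
    if len(scores) < 3:
        raise InvalidSpecError("need >= 3 regulators to standardize scores")
    vals = np.array(list(scores.values()), dtype=float)
    sd = vals.std(ddof=1)
    if sd == 0:
        raise DegenerateStatisticError("impact scores have zero variance")
    mean = vals.mean()
    return {tf: float((s - mean) / sd) for tf, s in scores.items()}


def select_candidates(
    records: Sequence[SelectionRecord], defect_threshold: float = 0.20
) -> list[SelectionRecord]:
    """Keep regulators whose knockout growth defect meets the threshold.

    Returns records with ``ko_growth_defect >= defect_threshold`` (default
    20%), sorted by defect descending, each with ``selected=True`` set.
    Ties sort by regulator id so the result is invariant to input order.
    """
    if not records:
        raise InvalidSpecError("no selection records")
    kept = [r for r in records if r.ko_growth_defect >= defect_threshold]
    kept.sort(key=lambda r: (-r.ko_growth_defect, r.regulator))
    return [
        SelectionRecord(
            regulator=r.regulator,
            regulon_size=r.regulon_size,
            ko_growth_defect=r.ko_growth_defect,
            imodulon_r2=r.imodulon_r2,
            impact_score=r.impact_score,
            impact_zscore=r.impact_zscore,
            selected=True,
        )
        for r in kept
    ]


def classify_ko(
    basal_wt_activity: float,
    activity_threshold: float,
    has_regulator_specific_convergence: bool,
    growth_recovered: bool,
) -> str:
    """Assign the four-way adaptation category of a knockout strain.

    ``iv`` if growth never recovered; otherwise ``i`` if the regulator was
    inactive on the growth condition (wildtype basal activity below the
    threshold), ``iii`` if recovery came with regulator-specific convergent
    mutations, else ``ii``.
    """
    if not growth_recovered:
        return "iv"
    if basal_wt_activity < activity_threshold:
        return "i"
    if has_regulator_specific_convergence:
        return "iii"
    return "ii"


def default_activity_threshold(
    reference_basal: Iterable[float], fraction: float = 0.10
) -> float:
    """Activity cutoff below which a regulator counts as inactive.

    Default: 10% of the iModulon's maximum basal activity over the
    reference compendium, so "inactive" is judged relative to the dynamic
    range the regulator displays across conditions.
    """
    ref = np.asarray(list(reference_basal), dtype=float)
    if ref.size == 0:
        raise InvalidSpecError("reference basal activities are empty")
    return float(fraction * ref.max())


def selection_report(records: Sequence[SelectionRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
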