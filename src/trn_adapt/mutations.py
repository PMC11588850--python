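"""Convergent-mutation detection across independent evolution lineages.

Each knockout strain is evolved in several independent lineages; isolates
(and endpoint populations) are sequenced and their mutations tabulated.  A
mutation is *convergent* when the same gene or labelled region is hit in at
least two independent lineages — independent replication is the signature
of selection rather than drift.  Mutations are grouped by their gene/region
label rather than exact coordinate, so independent hits to the same
promoter region count together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from trn_adapt.errors import DegenerateStatisticError, InvalidSpecError

COLUMNS = (
    "strain", "ko", "lineage", "stage", "sample_type",
    "gene", "position", "allele", "frequency",
)


@dataclass(frozen=True)
class MutationTable:
    """Per-sample mutation records.

    Columns: strain, ko (knockout background), lineage, stage
    (midpoint/endpoint), sample_type (isolate/population), gene (gene or
    labelled region), position (1-based), allele, frequency in (0, 1].
    Isolate records must have frequency 1; (position, allele) pairs are
    unique within a sample.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.records.columns)
        if missing:
            raise InvalidSpecError(f"mutation table missing columns: {sorted(missing)}")
        if len(self.records):
            freq = self.records["frequency"].astype(float)
            if ((freq <= 0) | (freq > 1)).any():
                raise InvalidSpecError("frequencies must lie in (0, 1]")
            iso = self.records["sample_type"] == "isolate"
            if (freq[iso] != 1).any():
                raise InvalidSpecError("isolate records must have frequency 1")
            dup = self.records.duplicated(
                subset=["strain", "sample_type", "stage", "position", "allele"]
            )
            if dup.any():
                raise InvalidSpecError("(position, allele) pairs must be unique per sample")

    @classmethod
    def from_tsv(cls, path: str | Path, column_map: Mapping[str, str] | None = None) -> "MutationTable":
        df = pd.read_csv(path, sep="\t")
        if column_map:
            df = df.rename(columns={v: k for k, v in column_map.items()})
        return cls(df[list(COLUMNS)])

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def convergent_mutations(
    table: MutationTable,
    ko: str,
    min_lineages: int = 2,
    gene_set: Iterable[str] | None = None,
    frequency_floor: float = 0.05,
    key: str = "gene",
) -> pd.DataFrame:
    """Genes/regions mutated in at least ``min_lineages`` independent lineages.

    Records for the given knockout background are grouped by the gene or
    region label (``key="gene"``; ``key="position"`` groups by exact
    coordinate instead) and the number of DISTINCT lineages containing at
    least one record is counted.  Population records below the
    ``frequency_floor`` are ignored (a low floor keeps genuine low-frequency
    sweeps while dropping sequencing noise).  ``gene_set`` optionally
    restricts the output, e.g. to the knocked-out regulator's regulon.
    """
    recs = table.records[table.records["ko"] == ko]
    if recs.empty:
        raise InvalidSpecError(f"no mutation records for knockout {ko!r}")
    recs = recs[recs["frequency"].astype(float) >= frequency_floor]
    counts = recs.groupby(key)["lineage"].nunique()
    hits = counts[counts >= min_lineages]
    if gene_set is not None:
        keep = set(gene_set)
        hits = hits[hits.index.isin(keep)]
    out = hits.rename("n_lineages").rename_axis(key).reset_index()
    return out.sort_values(["n_lineages", key], ascending=[False, True]).reset_index(drop=True)


def jaccard_agreement(
    isolate_records: pd.DataFrame, population_records: pd.DataFrame, key: str = "position_allele"
) -> float:
    """Jaccard index of the mutation sets of an isolate and its population.

    Sets are keyed by (position, allele) by default (``key="gene"`` uses
    gene labels).  Both sets empty is a degenerate case and is signalled
    rather than returned as 1.
    """
    def _keys(df: pd.DataFrame) -> set:
        if df.empty:
            return set()
        if key == "gene":
            return set(df["gene"])
        return set(zip(df["position"], df["allele"]))

    a, b = _keys(isolate_records), _keys(population_records)
    if not a and not b:
        raise DegenerateStatisticError("both mutation sets are empty")
    return len(a & b) / len(a | b)


def mutation_summary(
    table: MutationTable, exclude_strains: Sequence[str] = ()
) -> tuple[float, pd.Series]:
    """Mean mutation count per sequenced isolate, plus per-strain counts.

    ``exclude_strains`` removes known hypermutators before averaging.
    """
    iso = table.records[table.records["sample_type"] == "isolate"]
    iso = iso[~iso["strain"].isin(set(exclude_strains))]
    if iso.empty:
        raise InvalidSpecError("no isolate records remain after exclusions")
    per_strain = iso.groupby("strain").size().rename("n_mutations")
    return float(per_strain.mean()), per_strain
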