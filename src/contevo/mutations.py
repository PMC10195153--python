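"""Per-population mutation tables: parsing, validation, filtering, reshaping.

The canonical interchange format is a tab-separated table with one row per
mutation call in one population, as produced downstream of a polymorphism-mode
variant caller (e.g. breseq).  Columns::

    population_id  founder_id  pathway  region_id  region_kind  mutation_type
    effect  position  frequency  origin

``region_id`` is a gene name or an intergenic span named ``"geneA/geneB"``.
Statistics downstream operate at this region level: multiple hits in the same
region of one population collapse to presence.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PATHWAYS = ("rho", "rpoB", "ancestor")
REGION_KINDS = ("genic", "intergenic", "pseudogene")
MUTATION_TYPES = ("point", "indel", "large_deletion")
EFFECTS = (
    "nonsynonymous",
    "synonymous",
    "frameshift",
    "intergenic",
    "pseudogene",
    "large_deletion",
    "other",
)
ORIGINS = ("phase1_founder", "phase2")

#: threshold for "segregating" mutations; inclusive (frequency of 5% or higher)
SEGREGATING_THRESHOLD = 0.05
#: threshold for "fixed" mutations; exclusive (frequency strictly above 85%)
FIXED_THRESHOLD = 0.85

MUTATION_TABLE_COLUMNS = [
    "population_id",
    "founder_id",
    "pathway",
    "region_id",
    "region_kind",
    "mutation_type",
    "effect",
    "position",
    "frequency",
    "origin",
]


@dataclass(frozen=True)
class MutationRecord:
    """One polymorphism call in one population."""

    population_id: str
    founder_id: str
    pathway: str
    region_id: str
    region_kind: str
    mutation_type: str
    effect: str
    position: int
    frequency: float
    origin: str

    def validate(self, row: int | None = None) -> None:
        where = "" if row is None else f" (row {row})"
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}{where}")
        if self.region_kind not in REGION_KINDS:
            raise ValueError(f"unknown region_kind {self.region_kind!r}{where}")
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation_type {self.mutation_type!r}{where}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}{where}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}{where}")
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError(
                f"frequency {self.frequency} outside [0, 1]{where}"
            )
        if self.position < 1:
            raise ValueError(f"position {self.position} is not 1-based{where}")


@dataclass(frozen=True)
class GroupLabeling:
    """Total mapping population -> (pathway, founder genotype)."""

    mapping: Mapping[str, tuple[str, str]]

    @classmethod
    def from_records(cls, records: Iterable[MutationRecord]) -> "GroupLabeling":
        mapping: dict[str, tuple[str, str]] = {}
        for rec in records:
            prev = mapping.get(rec.population_id)
            cur = (rec.pathway, rec.founder_id)
            if prev is not None and prev != cur:
                raise ValueError(
                    f"population {rec.population_id} has inconsistent labels "
                    f"{prev} vs {cur}"
                )
            mapping[rec.population_id] = cur
        return cls(mapping=mapping)

    @property
    def populations(self) -> list[str]:
        return sorted(self.mapping)

    def pathway(self, population_id: str) -> str:
        return self.mapping[population_id][0]

    def founder(self, population_id: str) -> str:
        return self.mapping[population_id][1]

    def pathways(self) -> list[str]:
        return sorted({p for p, _ in self.mapping.values()})

    def restrict(self, populations: Iterable[str]) -> "GroupLabeling":
        pops = set(populations)
        return GroupLabeling({p: v for p, v in self.mapping.items() if p in pops})


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Populations x regions binary matrix at a chosen frequency threshold.

    ``table`` has population ids as the index and region ids as columns; an
    entry is 1 iff the population carries at least one qualifying mutation in
    the region.  Columns are guaranteed non-zero; rows may be all-zero (a
    population can lack, e.g., fixed mutations).
    """

    table: pd.DataFrame
    threshold_mode: str
    threshold: float
    origin_filter: str = "phase2"

    @property
    def populations(self) -> list[str]:
        return list(self.table.index)

    @property
    def regions(self) -> list[str]:
        return list(self.table.columns)

    def region_sets(self) -> dict[str, frozenset[str]]:
        cols = np.asarray(self.table.columns)
        values = self.table.to_numpy(dtype=bool)
        return {
            pop: frozenset(cols[row])
            for pop, row in zip(self.table.index, values)
        }


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records], columns=MUTATION_TABLE_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[MutationRecord]:
    missing = [c for c in MUTATION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing required column(s): {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = MutationRecord(
            population_id=str(row.population_id),
            founder_id=str(row.founder_id),
            pathway=str(row.pathway),
            region_id=str(row.region_id),
            region_kind=str(row.region_kind),
            mutation_type=str(row.mutation_type),
            effect=str(row.effect),
            position=int(row.position),
            frequency=float(row.frequency),
            origin=str(row.origin),
        )
        rec.validate(row=i + 2)  # 1-based with header line
        records.append(rec)
    return records


def read_mutation_table(path) -> list[MutationRecord]:
    """Read and validate the canonical TSV; raises on bad enum values or
    out-of-range frequencies, naming the offending line."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False,
        float_precision="round_trip",
    )
    if df.empty and set(MUTATION_TABLE_COLUMNS) <= set(df.columns):
        return []
    return frame_to_records(df)


def write_mutation_table(records: Iterable[MutationRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def filter_by_frequency(
    records: Sequence[MutationRecord],
    min_freq: float,
    strict: bool = False,
    phase2_only: bool = True,
) -> list[MutationRecord]:
    """Keep records with frequency >= min_freq (or > if ``strict``).

    Founder-origin (phase 1) records are excluded from Phase-2 mutation sets
    by default.
    """
    if not (0.0 <= min_freq <= 1.0):
        raise ValueError(f"min_freq {min_freq} outside [0, 1]")
    out = []
    for rec in records:
        if phase2_only and rec.origin != "phase2":
            continue
        ok = rec.frequency > min_freq if strict else rec.frequency >= min_freq
        if ok:
            out.append(rec)
    return out


def segregating(records: Sequence[MutationRecord],
                threshold: float = SEGREGATING_THRESHOLD) -> list[MutationRecord]:
    """Phase-2 mutations at frequency ``threshold`` or higher (inclusive)."""
    return filter_by_frequency(records, threshold, strict=False)


def fixed(records: Sequence[MutationRecord],
          threshold: float = FIXED_THRESHOLD) -> list[MutationRecord]:
    """Phase-2 mutations at frequency strictly above ``threshold``."""
    return filter_by_frequency(records, threshold, strict=True)


def presence_absence(
    records: Sequence[MutationRecord],
    threshold_mode: str = "segregating",
    segregating_threshold: float = SEGREGATING_THRESHOLD,
    fixed_threshold: float = FIXED_THRESHOLD,
    populations: Sequence[str] | None = None,
) -> PresenceAbsenceMatrix:
    """Binary populations x regions matrix of Phase-2 mutations.

    ``threshold_mode`` is ``"segregating"`` (frequency >= 5%, inclusive) or
    ``"fixed"`` (frequency > 85%, exclusive).  All populations present in
    ``records`` (or the explicit ``populations`` list) appear as rows even if
    they carry no qualifying mutation.
    """
    if threshold_mode == "segregating":
        kept = segregating(records, segregating_threshold)
        threshold = segregating_threshold
    elif threshold_mode == "fixed":
        kept = fixed(records, fixed_threshold)
        threshold = fixed_threshold
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    if populations is None:
        populations = sorted({r.population_id for r in records})
    if len(set(populations)) != len(populations):
        raise ValueError("duplicate population ids")
    if not kept:
        raise ValueError(
            f"no mutations qualify under threshold_mode={threshold_mode!r}"
        )
    regions = sorted({r.region_id for r in kept})
    table = pd.DataFrame(
        0, index=list(populations), columns=regions, dtype=np.int8
    )
    for rec in kept:
        if rec.population_id in table.index:
            table.at[rec.population_id, rec.region_id] = 1
    # drop columns only mutated in excluded populations
    table = table.loc[:, table.sum(axis=0) > 0]
    return PresenceAbsenceMatrix(
        table=table, threshold_mode=threshold_mode, threshold=threshold
    )


def type_spectrum(
    records: Sequence[MutationRecord],
    labeling: GroupLabeling | None = None,
) -> pd.DataFrame:
    """Contingency table of effect categories (rows) per pathway (columns).

    Counts records (population x mutation), not unique events.
    """
    if labeling is None:
        labeling = GroupLabeling.from_records(records)
    rows = [(r.effect, labeling.pathway(r.population_id)) for r in records]
    df = pd.DataFrame(rows, columns=["effect", "pathway"])
    table = pd.crosstab(df["effect"], df["pathway"])
    return table.reindex(
        index=[e for e in EFFECTS if e in table.index],
        columns=sorted(table.columns),
    )


def per_population_counts(records: Sequence[MutationRecord]) -> pd.Series:
    """Number of records per population."""
    counts = pd.Series([r.population_id for r in records]).value_counts()
    return counts.sort_index()


@dataclass(frozen=True)
class InheritanceReport:
    """Founder-mutation inheritance check; violations flag candidate
    cross-contamination."""

    n_populations: int
    n_checked: int
    violations: list[tuple[str, str, str, float | None]] = field(
        default_factory=list
    )

    @property
    def ok(self) -> bool:
        return not self.violations


def check_founder_inheritance(
    records: Sequence[MutationRecord],
    founder_genotypes: Mapping[str, Iterable[str]],
    threshold: float = FIXED_THRESHOLD,
) -> InheritanceReport:
    """Verify every founder-defining mutation is fixed in every descendant.

    ``founder_genotypes`` maps founder id -> region ids of its defining
    mutations.  A violation is recorded when a founder region is absent from a
    descendant population or present only below ``threshold`` frequency; each
    violation is ``(population, founder, region, observed_frequency_or_None)``.
    """
    pop_founder: dict[str, str] = {}
    best_freq: dict[tuple[str, str], float] = {}
    for rec in records:
        pop_founder.setdefault(rec.population_id, rec.founder_id)
        key = (rec.population_id, rec.region_id)
        best_freq[key] = max(best_freq.get(key, 0.0), rec.frequency)

    violations: list[tuple[str, str, str, float | None]] = []
    n_checked = 0
    for pop, founder in sorted(pop_founder.items()):
        if founder not in founder_genotypes:
            raise ValueError(f"population {pop} has unknown founder {founder!r}")
        for region in founder_genotypes[founder]:
            n_checked += 1
            freq = best_freq.get((pop, region))
            if freq is None:
                violations.append((pop, founder, region, None))
            elif freq <= threshold:
                violations.append((pop, founder, region, freq))
    return InheritanceReport(
        n_populations=len(pop_founder),
        n_checked=n_checked,
        violations=violations,
    )
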