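"""rMATS event tables: parsing, significance filtering, direction calls.

rMATS reports one TSV per event kind (SE, RI, A5SS, A3SS, MXE).  Start
columns named ``*_0base``/``*ES`` are 0-based starts and ``*End``/``*EE``
are exclusive ends, so the files are already half-open and no coordinate
shift is applied.

``IncLevelDifference`` is IncLevel(group 1) - IncLevel(group 2); which
biological condition was group 1 is a mandatory configuration choice
(``g1_is_wildtype``) because every direction-stratified result inverts
with it.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)


class EventKind(str, enum.Enum):
    SE = "SE"
    RI = "RI"
    A5SS = "A5SS"
    A3SS = "A3SS"
    MXE = "MXE"


class Direction(str, enum.Enum):
    """Change of the mis-splicing phenomenon in the mutant: more retention
    (RI) / more skipping (SE) / more inclusion of the variable form (others),
    versus less."""

    INCREASED_IN_MUTANT = "increased_in_mutant"
    DECREASED_IN_MUTANT = "decreased_in_mutant"


# kind -> interval columns as (name, start_col, end_col)
_COORD_COLUMNS: dict[EventKind, list[tuple[str, str, str]]] = {
    EventKind.SE: [
        ("skipped_exon", "exonStart_0base", "exonEnd"),
        ("upstream_exon", "upstreamES", "upstreamEE"),
        ("downstream_exon", "downstreamES", "downstreamEE"),
    ],
    EventKind.RI: [
        ("ri_exon", "riExonStart_0base", "riExonEnd"),
        ("upstream_exon", "upstreamES", "upstreamEE"),
        ("downstream_exon", "downstreamES", "downstreamEE"),
    ],
    EventKind.A5SS: [
        ("long_exon", "longExonStart_0base", "longExonEnd"),
        ("short_exon", "shortES", "shortEE"),
        ("flanking_exon", "flankingES", "flankingEE"),
    ],
    EventKind.A3SS: [
        ("long_exon", "longExonStart_0base", "longExonEnd"),
        ("short_exon", "shortES", "shortEE"),
        ("flanking_exon", "flankingES", "flankingEE"),
    ],
    EventKind.MXE: [
        ("exon1", "1stExonStart_0base", "1stExonEnd"),
        ("exon2", "2ndExonStart_0base", "2ndExonEnd"),
        ("upstream_exon", "upstreamES", "upstreamEE"),
        ("downstream_exon", "downstreamES", "downstreamEE"),
    ],
}

_STAT_COLUMNS = ["PValue", "FDR", "IncLevelDifference"]


@dataclass
class SpliceEvent:
    """One rMATS event row."""

    event_id: str
    kind: EventKind
    gene_id: str
    chrom: str
    strand: str
    coords: dict[str, tuple[int, int]]
    p_value: float
    fdr: float
    inc_level_diff: float
    direction: Direction | None = None

    def span(self) -> tuple[int, int]:
        """Leftmost start to rightmost end over all coordinate intervals."""
        return (
            min(s for s, _ in self.coords.values()),
            max(e for _, e in self.coords.values()),
        )


def parse_rmats_table(path, kind: EventKind | str) -> list[SpliceEvent]:
    """Parse one rMATS TSV into :class:`SpliceEvent` objects.

    Rows with non-numeric PValue/FDR/IncLevelDifference (rMATS "NA") are
    dropped with a warning.  A missing required column is a hard error
    naming the column.
    """
    kind = EventKind(kind)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = (
        ["ID", "GeneID", "chr", "strand"]
        + [c for _, s, e in _COORD_COLUMNS[kind] for c in (s, e)]
        + _STAT_COLUMNS
    )
    for col in required:
        if col not in df.columns:
            raise ValueError(f"rMATS {kind.value} table {path}: missing column {col!r}")

    events: list[SpliceEvent] = []
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            p = float(row["PValue"])
            fdr = float(row["FDR"])
            ild = float(row["IncLevelDifference"])
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        coords = {
            name: (int(row[s]), int(row[e])) for name, s, e in _COORD_COLUMNS[kind]
        }
        gid = str(row["GeneID"]).strip().strip('"')
        events.append(
            SpliceEvent(
                event_id=f"{kind.value}:{row['ID']}",
                kind=kind,
                gene_id=gid,
                chrom=str(row["chr"]),
                strand=str(row["strand"]),
                coords=coords,
                p_value=p,
                fdr=fdr,
                inc_level_diff=ild,
            )
        )
    if n_dropped:
        log.warning(
            "%s: dropped %d rows with non-numeric PValue/FDR/IncLevelDifference",
            path,
            n_dropped,
        )
    return events


def filter_events(
    events: list[SpliceEvent], p_max: float = 0.05, fdr_max: float = 0.05
) -> list[SpliceEvent]:
    """Keep events with p_value < p_max AND fdr < fdr_max (both strict)."""
    return [ev for ev in events if ev.p_value < p_max and ev.fdr < fdr_max]


def classify_direction(event: SpliceEvent, g1_is_wildtype: bool) -> Direction:
    """Direction of the splicing change in the mutant.

    With group 1 = wild type, IncLevelDifference < 0 means inclusion is
    higher in the mutant: more retention for RI, but *less* skipping for SE
    (inclusion is exon inclusion there).  A zero difference is ambiguous
    after the significance filter and is an error.
    """
    d = event.inc_level_diff
    if d == 0:
        raise ValueError(f"{event.event_id}: IncLevelDifference is zero; ambiguous")
    inclusion_up_in_mutant = (d < 0) if g1_is_wildtype else (d > 0)
    if event.kind == EventKind.SE:
        # the phenomenon is skipping: opposite of inclusion
        up = not inclusion_up_in_mutant
    else:
        up = inclusion_up_in_mutant
    return Direction.INCREASED_IN_MUTANT if up else Direction.DECREASED_IN_MUTANT


def classify_all(events: list[SpliceEvent], g1_is_wildtype: bool) -> None:
    for ev in events:
        ev.direction = classify_direction(ev, g1_is_wildtype)


@dataclass
class MultiEventSummary:
    """Which event kinds each gene shows, Venn-style."""

    gene_kinds: dict[str, set[EventKind]]
    combination_counts: Counter
    n_multi_kind: int


def multi_event_summary(per_kind: dict[EventKind, list[SpliceEvent]]) -> MultiEventSummary:
    """Summarize genes by the set of event kinds they display.

    ``combination_counts`` tallies genes per exact kind-combination (keyed by
    a sorted tuple of kind names); ``n_multi_kind`` counts genes showing at
    least two distinct kinds.
    """
    gene_kinds: dict[str, set[EventKind]] = {}
    for kind, evs in per_kind.items():
        for ev in evs:
            gene_kinds.setdefault(ev.gene_id, set()).add(EventKind(kind))
    combos = Counter(
        tuple(sorted(k.value for k in kinds)) for kinds in gene_kinds.values()
    )
    n_multi = sum(1 for kinds in gene_kinds.values() if len(kinds) >= 2)
    return MultiEventSummary(gene_kinds, combos, n_multi)
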