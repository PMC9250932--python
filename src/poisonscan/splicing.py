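"""rMATS-dialect splicing event tables: parsing, significance filtering,
direction calls and CLIP-peak intersection.

Sign convention (fixed package-wide): ``delta_psi = PSI(knockdown) -
PSI(control)``.  An event with ``delta_psi < 0`` loses inclusion when the
RNA-binding protein is depleted, i.e. its inclusion is *supported* by the
protein; ``delta_psi > 0`` means inclusion is *repressed* by it.  A poison
exon whose inclusion rises upon knockdown is therefore repressed_by the
factor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .errors import ParseError, ValidationError
from .intervals import GenomicInterval
from .clip import ClipPeak

EVENT_TYPES = ("CE", "RI", "A3SS", "A5SS", "MXE")

SUPPORTED = "supported_by_RBM17"
REPRESSED = "repressed_by_RBM17"

#: type-specific coordinate columns of the rMATS output dialect (0-based starts)
DIALECT_COORDS: dict[str, tuple[str, ...]] = {
    "CE": (
        "exonStart_0base",
        "exonEnd",
        "upstreamES",
        "upstreamEE",
        "downstreamES",
        "downstreamEE",
    ),
    "RI": (
        "riExonStart_0base",
        "riExonEnd",
        "upstreamES",
        "upstreamEE",
        "downstreamES",
        "downstreamEE",
    ),
    "A3SS": (
        "longExonStart_0base",
        "longExonEnd",
        "shortES",
        "shortEE",
        "flankingES",
        "flankingEE",
    ),
    "A5SS": (
        "longExonStart_0base",
        "longExonEnd",
        "shortES",
        "shortEE",
        "flankingES",
        "flankingEE",
    ),
    "MXE": (
        "1stExonStart_0base",
        "1stExonEnd",
        "2ndExonStart_0base",
        "2ndExonEnd",
        "upstreamES",
        "upstreamEE",
        "downstreamES",
        "downstreamEE",
    ),
}


@dataclass
class SplicingEvent:
    event_type: str
    event_id: str
    gene_id: str
    contig: str
    strand: str
    coords: dict[str, int]
    delta_psi: float
    fdr: float
    pvalue: float = float("nan")
    direction: str | None = None
    bound: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if abs(self.delta_psi) > 1 + 1e-9:
            raise ValidationError(f"|delta_psi| > 1 for event {self.event_id}")

    @property
    def footprint(self) -> GenomicInterval:
        """Event footprint: span from the outermost flanking-exon boundary to
        the other, i.e. the alternative region plus both flanking introns and
        exons."""
        values = list(self.coords.values())
        return GenomicInterval(self.contig, min(values), max(values), self.strand)


# ---------------------------------------------------------------------------
# parsing


def read_event_table(path, event_type: str) -> list[SplicingEvent]:
    """Read one rMATS-dialect TSV for ``event_type``."""
    if event_type not in EVENT_TYPES:
        raise ValidationError(f"unknown event type {event_type!r}")
    df = pd.read_csv(path, sep="\t")
    need = set(DIALECT_COORDS[event_type]) | {
        "ID",
        "GeneID",
        "chr",
        "strand",
        "IncLevelDifference",
        "PValue",
        "FDR",
    }
    missing = need - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    events = []
    for i, r in enumerate(df.itertuples(index=False), 2):  # header is line 1
        # zip against df.columns: itertuples mangles leading-digit names
        row = dict(zip(df.columns, r))
        if pd.isna(row["FDR"]) or pd.isna(row["IncLevelDifference"]):
            raise ParseError(f"{path}:{i}: missing FDR or IncLevelDifference")
        coords = {c: int(row[c]) for c in DIALECT_COORDS[event_type]}
        events.append(
            SplicingEvent(
                event_type=event_type,
                event_id=f"{event_type}_{row['ID']}",
                gene_id=str(row["GeneID"]),
                contig=str(row["chr"]),
                strand=str(row["strand"]),
                coords=coords,
                delta_psi=float(row["IncLevelDifference"]),
                fdr=float(row["FDR"]),
                pvalue=float(row["PValue"]),
            )
        )
    return events


def collapse_duplicates(events: list[SplicingEvent]) -> list[SplicingEvent]:
    """Drop duplicate records (same type + coordinates), keeping smallest FDR."""
    best: dict[tuple, SplicingEvent] = {}
    for ev in events:
        key = (ev.event_type, ev.contig, ev.strand, tuple(sorted(ev.coords.items())))
        if key not in best or ev.fdr < best[key].fdr:
            best[key] = ev
    return sorted(best.values(), key=lambda e: e.event_id)


# ---------------------------------------------------------------------------
# filtering / direction / tallies


def filter_events(
    events: list[SplicingEvent], fdr_max: float = 0.1, dpsi_min: float = 0.05
) -> list[SplicingEvent]:
    """Keep events with ``fdr < fdr_max`` and ``|delta_psi| > dpsi_min``
    (both strict, as printed)."""
    return [e for e in events if e.fdr < fdr_max and abs(e.delta_psi) > dpsi_min]


def classify_direction(event: SplicingEvent) -> str:
    """delta_psi < 0 -> inclusion supported by the factor; > 0 -> repressed."""
    if event.delta_psi < 0:
        return SUPPORTED
    if event.delta_psi > 0:
        return REPRESSED
    raise ValidationError(
        f"direction undefined for delta_psi == 0 (event {event.event_id})"
    )


def with_directions(events: list[SplicingEvent]) -> list[SplicingEvent]:
    return [replace(e, direction=classify_direction(e)) for e in events]


def tally_types(events: list[SplicingEvent]) -> pd.DataFrame:
    """Two-way count table event_type x direction (all types/directions kept)."""
    table = pd.DataFrame(
        0, index=list(EVENT_TYPES), columns=[SUPPORTED, REPRESSED], dtype=int
    )
    for e in events:
        d = e.direction or classify_direction(e)
        table.loc[e.event_type, d] += 1
    return table


# ---------------------------------------------------------------------------
# CLIP intersection


def overlap_events_with_peaks(
    events: list[SplicingEvent], peaks: list[ClipPeak]
) -> list[SplicingEvent]:
    """Set ``bound`` on events whose footprint overlaps >= 1 peak interval;
    strand must match when the peak declares one."""
    out = []
    for ev in events:
        fp = ev.footprint
        bound = False
        for pk in peaks:
            iv = pk.interval
            if not fp.overlaps(iv):
                continue
            if iv.strand in ("+", "-") and iv.strand != ev.strand:
                continue
            bound = True
            break
        out.append(replace(ev, bound=bound))
    return out


def events_to_table(events: list[SplicingEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "event_type": e.event_type,
                "gene_id": e.gene_id,
                "chr": e.contig,
                "strand": e.strand,
                "footprint_start": e.footprint.start,
                "footprint_end": e.footprint.end,
                "delta_psi": e.delta_psi,
                "fdr": e.fdr,
                "direction": e.direction,
                "bound": e.bound,
            }
        )
    return pd.DataFrame(rows)
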