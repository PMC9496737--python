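"""Intron-retention events: PSI computation and differential prioritization.

PSI (percent spliced in) for a retained intron is defined here as

    psi = intron_confidence / (intron_confidence + junction_reads)

where ``intron_confidence`` is the mean number of alignments spanning the
intron body and ``junction_reads`` the spliced-junction read support.  An
event is prioritized when intron confidence exceeds a strict threshold
(default > 5) in at least one group, the between-group PSI difference
reaches a configurable minimum, and the intron is absent from a
normal-tissue blacklist.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import FormatError, JunctionRecord, TranscriptModel

logger = logging.getLogger(__name__)

EVENT_TYPES = {
    "exon_skip",
    "intron_retention",
    "alt_3prime",
    "alt_5prime",
    "multi_exon_skip",
    "mutually_exclusive",
}

DEFAULT_MIN_CONFIDENCE = 5.0  # strict: must exceed
DEFAULT_MIN_DELTA_PSI = 0.1


@dataclass
class SpliceEvent:
    """One typed alternative-splicing event with per-group evidence.

    ``junctions`` holds the event's intron interval(s) as 0-based half-open
    genomic coordinates; for intron retention there is exactly one, the
    retained intron.  Per-group dicts share the same group keys.
    """

    event_id: str
    event_type: str
    gene_id: str
    contig: str
    strand: str
    junctions: list[tuple[int, int]]
    intron_confidence: dict[str, float] = field(default_factory=dict)
    junction_reads: dict[str, float] = field(default_factory=dict)
    psi: dict[str, float | None] = field(default_factory=dict)
    flagged: bool = False  # set when PSI is undefined in some group

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise FormatError(f"unknown event type {self.event_type!r}")
        for g, p in self.psi.items():
            if p is not None and not 0.0 <= p <= 1.0:
                raise FormatError(f"{self.event_id}: PSI {p} outside [0, 1] in group {g}")
        for g, c in self.intron_confidence.items():
            if c < 0:
                raise FormatError(f"{self.event_id}: negative confidence in group {g}")

    @property
    def intron(self) -> tuple[int, int]:
        return self.junctions[0]

    @property
    def groups(self) -> list[str]:
        return sorted(self.psi or self.intron_confidence)

    def delta_psi(self) -> float | None:
        """Largest between-group PSI difference; None if < 2 defined groups."""
        vals = [p for p in self.psi.values() if p is not None]
        if len(vals) < 2:
            return None
        return max(vals) - min(vals)


def compute_psi(intron_confidence: float, junction_reads: float) -> float | None:
    """PSI of a retained intron; None (undefined) when both counts are zero."""
    if intron_confidence < 0 or junction_reads < 0:
        raise ValueError("counts must be non-negative")
    total = intron_confidence + junction_reads
    if total == 0:
        return None
    return intron_confidence / total


def detect_ir_events(
    junction_records: Mapping[str, Sequence[JunctionRecord]],
    intron_coverage: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    min_evidence: float = 1.0,
    group_of: Mapping[str, str] | None = None,
) -> list[SpliceEvent]:
    """Build IR candidates from per-sample intron coverage and junction reads.

    A minimal stand-in for splice-graph IR detection: one candidate per
    annotated intron whose mean spanning-alignment coverage reaches
    ``min_evidence`` in at least one sample.  ``intron_coverage`` columns:
    contig, intron_start (1-based), intron_end, sample, coverage.
    ``group_of`` maps sample -> group (default: each sample is its own
    group); group confidence is the mean over its samples, junction reads
    the sum.
    """
    samples = sorted(junction_records)
    if group_of is None:
        group_of = {s: s for s in samples}
    annotated: dict[tuple[str, int, int], str] = {}
    for t in transcripts:
        for s, e in t.introns():
            annotated.setdefault((t.contig, s, e), t.gene_id)
    # junction read support per (intron, sample)
    jr: dict[tuple[str, int, int], dict[str, float]] = {}
    for sample, records in junction_records.items():
        for r in records:
            key = (r.contig, *r.interval)
            jr.setdefault(key, {})[sample] = jr.get(key, {}).get(sample, 0) + r.unique_reads
    cov: dict[tuple[str, int, int], dict[str, float]] = {}
    for row in intron_coverage.itertuples(index=False):
        key = (str(row.contig), int(row.intron_start) - 1, int(row.intron_end))
        cov.setdefault(key, {})[str(row.sample)] = float(row.coverage)

    events = []
    for key in sorted(cov):
        if key not in annotated:
            continue
        per_sample = cov[key]
        if max(per_sample.values(), default=0.0) < min_evidence:
            continue
        groups = sorted({group_of[s] for s in samples})
        conf = {
            g: float(pd.Series(
                [per_sample.get(s, 0.0) for s in samples if group_of[s] == g]
            ).mean())
            for g in groups
        }
        reads = {
            g: float(sum(jr.get(key, {}).get(s, 0.0) for s in samples if group_of[s] == g))
            for g in groups
        }
        psi = {g: compute_psi(conf[g], reads[g]) for g in groups}
        contig, s0, e0 = key
        events.append(
            SpliceEvent(
                event_id=f"IR_{contig}_{s0 + 1}_{e0}",
                event_type="intron_retention",
                gene_id=annotated[key],
                contig=contig,
                strand=next(
                    t.strand for t in transcripts
                    if t.contig == contig and (s0, e0) in t.introns()
                ),
                junctions=[(s0, e0)],
                intron_confidence=conf,
                junction_reads=reads,
                psi=psi,
                flagged=any(p is None for p in psi.values()),
            )
        )
    return events


def ir_priority_filter(
    events: Iterable[SpliceEvent],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    min_delta_psi: float = DEFAULT_MIN_DELTA_PSI,
    normal_blacklist: set[tuple[str, int, int]] | None = None,
) -> list[SpliceEvent]:
    """Prioritize differential IR events.

    Kept iff intron confidence STRICTLY exceeds ``min_confidence`` in at
    least one group, the between-group PSI difference is >=
    ``min_delta_psi``, and the intron is not in the normal-tissue blacklist
    (0-based half-open intervals).  Idempotent.
    """
    blacklist = normal_blacklist or set()
    kept = []
    for ev in events:
        if max(ev.intron_confidence.values(), default=0.0) <= min_confidence:
            continue
        d = ev.delta_psi()
        # tolerance keeps the inclusive boundary exact under float subtraction
        if d is None or d < min_delta_psi - 1e-9:
            continue
        if (ev.contig, *ev.intron) in blacklist:
            continue
        kept.append(ev)
    return kept


def export_validation_targets(
    events: Iterable[SpliceEvent], transcripts: Sequence[TranscriptModel]
) -> pd.DataFrame:
    """Flanking-exon intervals and expected RT-PCR amplicon sizes per event.

    The exon:exon amplicon spans both flanking exons; the retention amplicon
    additionally contains the intron, so it is larger by the intron length
    (the two bands of a retention gel).  Raises for an intron that matches
    no transcript.
    """
    rows = []
    for ev in events:
        s0, e0 = ev.intron
        host = None
        for t in transcripts:
            if t.contig == ev.contig and (s0, e0) in t.introns():
                host = t
                break
        if host is None:
            raise ValueError(
                f"{ev.event_id}: intron {ev.contig}:{s0 + 1}-{e0} not found in any transcript"
            )
        up = next(iv for iv in host.exons if iv[1] == s0)
        down = next(iv for iv in host.exons if iv[0] == e0)
        ee = (up[1] - up[0]) + (down[1] - down[0])
        rows.append(
            {
                "event_id": ev.event_id,
                "gene_id": ev.gene_id,
                "contig": ev.contig,
                "upstream_exon_start": up[0],
                "upstream_exon_end": up[1],
                "downstream_exon_start": down[0],
                "downstream_exon_end": down[1],
                "intron_length": e0 - s0,
                "amplicon_ee": ee,
                "amplicon_ir": ee + (e0 - s0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shared event-table TSV dialect

_EVENT_COLS = [
    "event_id", "type", "gene", "contig", "strand", "coords",
    "groupA_intron_conf", "groupB_intron_conf", "groupA_psi", "groupB_psi",
]


def _fmt_coords(junctions: Sequence[tuple[int, int]]) -> str:
    # rendered 1-based inclusive, comma-separated
    return ",".join(f"{s + 1}-{e}" for s, e in junctions)


def _parse_coords(text: str) -> list[tuple[int, int]]:
    out = []
    for part in text.split(","):
        a, b = part.split("-")
        out.append((int(a) - 1, int(b)))
    return out


def write_event_table(
    events: Sequence[SpliceEvent], path, groups: Sequence[str] | None = None
) -> None:
    """Write the shared two-group event TSV (coords 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_EVENT_COLS) + "\n")
        for ev in events:
            gs = list(groups) if groups else ev.groups
            if len(gs) != 2:
                raise ValueError(f"{ev.event_id}: event table requires exactly 2 groups")
            ga, gb = gs
            pa, pb = ev.psi.get(ga), ev.psi.get(gb)
            fh.write(
                "\t".join(
                    [
                        ev.event_id, ev.event_type, ev.gene_id, ev.contig, ev.strand,
                        _fmt_coords(ev.junctions),
                        f"{ev.intron_confidence.get(ga, 0):g}",
                        f"{ev.intron_confidence.get(gb, 0):g}",
                        "NA" if pa is None else f"{pa:.6g}",
                        "NA" if pb is None else f"{pb:.6g}",
                    ]
                )
                + "\n"
            )


def read_event_table(path, groups: Sequence[str] = ("A", "B")) -> list[SpliceEvent]:
    """Read the shared event TSV into :class:`SpliceEvent` objects."""
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    missing = [c for c in _EVENT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    ga, gb = groups
    events = []
    for i, row in df.iterrows():
        try:
            psi_a = None if row["groupA_psi"] in ("NA", "", None) or pd.isna(row["groupA_psi"]) \
                else float(row["groupA_psi"])
            psi_b = None if row["groupB_psi"] in ("NA", "", None) or pd.isna(row["groupB_psi"]) \
                else float(row["groupB_psi"])
            conf_a = float(row["groupA_intron_conf"])
            conf_b = float(row["groupB_intron_conf"])
            events.append(
                SpliceEvent(
                    event_id=row["event_id"],
                    event_type=row["type"],
                    gene_id=row["gene"],
                    contig=row["contig"],
                    strand=row["strand"],
                    junctions=_parse_coords(row["coords"]),
                    intron_confidence={ga: conf_a, gb: conf_b},
                    junction_reads={},
                    psi={ga: psi_a, gb: psi_b},
                    flagged=psi_a is None or psi_b is None,
                )
            )
        except (ValueError, KeyError, FormatError) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return events
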