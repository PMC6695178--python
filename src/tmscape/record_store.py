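"""Reading, validating and filtering topology-annotated membrane-protein records.

Two on-disk representations are supported:

* UniProt/Swiss-Prot flat-file text (``ID``/``AC``/``OC``/``PE``/``CC``/``KW``/
  ``FT TRANSMEM``/``SQ`` lines), parsed with Biopython's Swiss-Prot reader.
* A line-delimited fixture format (one JSON object per line) that
  round-trips :class:`MPRecord` losslessly and is what the synthetic-data
  generator emits.

All helix coordinates are 1-based and inclusive on both ends, following
UniProt feature-table conventions; no other module converts coordinates.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SwissProt
from Bio.SeqFeature import ExactPosition

from .amino_acids import VALID_SEQUENCE_LETTERS

logger = logging.getLogger(__name__)

MULTI_PASS_TAG = "Multi-pass membrane protein [SL-9909]"
SINGLE_PASS_TAG = "Single-pass membrane protein [SL-9904]"

#: Phrases found in CC SUBCELLULAR LOCATION / KW lines mapped to the
#: canonical tag (with its controlled-vocabulary SL code) stored on records.
_CANONICAL_TAGS: Mapping[str, str] = {
    "Multi-pass membrane protein": MULTI_PASS_TAG,
    "Single-pass membrane protein": SINGLE_PASS_TAG,
}


class RecordError(ValueError):
    """Base class for record-level problems; carries the offending entry id."""


class ParseError(RecordError):
    pass


class ValidationError(RecordError):
    pass


class FixtureError(RecordError):
    """Schema violation in the line-delimited fixture format."""


class HelixKind(str, enum.Enum):
    HELICAL = "helical"
    DISCONTINUOUS = "discontinuously_helical"


@dataclass(frozen=True, order=True)
class HelixSpan:
    """A transmembrane helix as a 1-based inclusive residue interval."""

    start: int
    end: int
    kind: HelixKind = HelixKind.HELICAL

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"invalid helix span ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def center(self) -> int:
        """Central residue index; even-length helices are centered one
        residue toward the N-terminus (floor of the midpoint)."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class MPRecord:
    """One membrane protein: sequence, taxonomy, evidence level and helices."""

    id: str
    sequence: str
    lineage: Tuple[str, ...]
    location_tag: str
    existence_code: int
    helices: Tuple[HelixSpan, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lineage", tuple(self.lineage))
        object.__setattr__(self, "helices", tuple(self.helices))
        if not self.helices:
            raise ValidationError(f"{self.id}: record must have at least one helix")
        if not 1 <= self.existence_code <= 5:
            raise ValidationError(
                f"{self.id}: existence code {self.existence_code} outside 1-5"
            )
        bad = set(self.sequence.upper()) - VALID_SEQUENCE_LETTERS
        if bad:
            raise ValidationError(f"{self.id}: invalid sequence letters {sorted(bad)}")
        prev_end = 0
        for h in self.helices:
            if h.start <= prev_end:
                raise ValidationError(
                    f"{self.id}: helix spans overlap or are unsorted at ({h.start}, {h.end})"
                )
            prev_end = h.end
        if self.helices[-1].end > len(self.sequence):
            raise ValidationError(
                f"{self.id}: helix span ({self.helices[-1].start}, "
                f"{self.helices[-1].end}) exceeds sequence length {len(self.sequence)}"
            )

    @property
    def n(self) -> int:
        """Number of annotated transmembrane helices."""
        return len(self.helices)

    def with_helices(self, helices: Sequence[HelixSpan]) -> "MPRecord":
        return replace(self, helices=tuple(sorted(helices)))


@dataclass(frozen=True)
class FilterCriteria:
    """Record-retention rules: location tags, evidence codes, taxon, helix kinds.

    ``substring_match`` switches location-tag matching from exact string
    equality (the default, which includes the SL code) to a permissive
    containment test for flat-file dialects that omit the code.
    """

    allowed_location_tags: frozenset = frozenset({MULTI_PASS_TAG, SINGLE_PASS_TAG})
    allowed_existence_codes: frozenset = frozenset({1, 2, 3})
    taxon: Optional[str] = None
    allowed_helix_kinds: frozenset = frozenset(
        {HelixKind.HELICAL, HelixKind.DISCONTINUOUS}
    )
    substring_match: bool = False

    def __post_init__(self) -> None:
        if not self.allowed_location_tags or not self.allowed_existence_codes:
            raise ValidationError("criteria sets must be non-empty")
        if not self.allowed_helix_kinds:
            raise ValidationError("criteria sets must be non-empty")

    def tag_matches(self, tag: str) -> bool:
        if self.substring_match:
            return any(allowed in tag or tag in allowed for allowed in self.allowed_location_tags)
        return tag in self.allowed_location_tags


DEFAULT_CRITERIA = FilterCriteria()


@dataclass
class FilterResult:
    """Retained records plus a per-criterion tally of removals.

    A record failing several criteria is attributed to the first failing
    one, in the fixed order: location_tag, existence_code, taxon,
    helix_kind.
    """

    records: List[MPRecord]
    removed: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def apply_filter(records: Iterable[MPRecord], criteria: FilterCriteria = DEFAULT_CRITERIA) -> FilterResult:
    """Filter records, reporting how many each criterion removed.

    The helix-kind criterion restricts each record to helices of allowed
    kinds; a record with no allowed helix left is removed. The taxon
    criterion matches any name in the lineage (no cross-check cleanup of
    foreign entries beyond that).
    """
    kept: List[MPRecord] = []
    removed = {"location_tag": 0, "existence_code": 0, "taxon": 0, "helix_kind": 0}
    for rec in records:
        if not criteria.tag_matches(rec.location_tag):
            removed["location_tag"] += 1
            continue
        if rec.existence_code not in criteria.allowed_existence_codes:
            removed["existence_code"] += 1
            continue
        if criteria.taxon is not None and criteria.taxon not in rec.lineage:
            removed["taxon"] += 1
            continue
        allowed = [h for h in rec.helices if h.kind in criteria.allowed_helix_kinds]
        if not allowed:
            removed["helix_kind"] += 1
            continue
        kept.append(rec if len(allowed) == rec.n else rec.with_helices(allowed))
    return FilterResult(records=kept, removed=removed)


def filter_records(records: Iterable[MPRecord], criteria: FilterCriteria = DEFAULT_CRITERIA) -> List[MPRecord]:
    """Return the records satisfying all criteria (order preserved)."""
    return apply_filter(records, criteria).records


# ---------------------------------------------------------------------------
# UniProt flat-file input


def _location_tag(record: SwissProt.Record) -> str:
    texts = [c for c in record.comments if c.startswith("SUBCELLULAR LOCATION")]
    texts.extend(record.keywords)
    for text in texts:
        for phrase, canonical in _CANONICAL_TAGS.items():
            if phrase in text:
                return canonical
    return texts[0] if texts else ""


def _helix_kind(note: str) -> Optional[HelixKind]:
    note_l = note.lower()
    if note_l.startswith("discontinuously helical"):
        return HelixKind.DISCONTINUOUS
    if note_l.startswith("helical"):
        return HelixKind.HELICAL
    return None


def parse_flatfile(stream: IO[str]) -> List[MPRecord]:
    """Parse UniProt-style flat-file entries into :class:`MPRecord` objects.

    Entries without any TRANSMEM feature are excluded. Entries whose
    TRANSMEM positions are not plain residue numbers (``<1``, ``?`` ...)
    are skipped with a log message; a span exceeding the sequence raises
    :class:`ValidationError` naming the entry.
    """
    out: List[MPRecord] = []
    try:
        entries = list(SwissProt.parse(stream))
    except (SwissProt.SwissProtParserError, ValueError) as exc:  # pragma: no cover - message path
        raise ParseError(f"malformed flat-file input: {exc}") from exc
    for entry in entries:
        entry_id = entry.entry_name or (entry.accessions[0] if entry.accessions else "?")
        spans: List[HelixSpan] = []
        parseable = True
        for feat in entry.features:
            if feat.type != "TRANSMEM":
                continue
            loc = feat.location
            # fuzzy positions ("<1", "?", "?12") are not usable coordinates
            if type(loc.start) is not ExactPosition or type(loc.end) is not ExactPosition:
                logger.warning("%s: unparseable TRANSMEM span %r; entry skipped", entry_id, loc)
                parseable = False
                break
            start = int(loc.start) + 1  # Biopython exposes 0-based starts
            end = int(loc.end)
            kind = _helix_kind(str(feat.qualifiers.get("note", "Helical")))
            if kind is None:
                logger.warning(
                    "%s: TRANSMEM note %r is not a helical annotation; span ignored",
                    entry_id, feat.qualifiers.get("note"),
                )
                continue
            spans.append(HelixSpan(start=start, end=end, kind=kind))
        if not parseable or not spans:
            continue
        try:
            existence = int(entry.protein_existence)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{entry_id}: unreadable PE line") from exc
        out.append(
            MPRecord(
                id=entry_id,
                sequence=entry.sequence,
                lineage=tuple(entry.organism_classification),
                location_tag=_location_tag(entry),
                existence_code=existence,
                helices=tuple(sorted(spans)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fixture format: one JSON object per line, lossless round-trip

_FIXTURE_FIELDS = ("id", "sequence", "lineage", "location_tag", "existence_code", "helices")


def record_to_dict(record: MPRecord) -> dict:
    return {
        "id": record.id,
        "sequence": record.sequence,
        "lineage": list(record.lineage),
        "location_tag": record.location_tag,
        "existence_code": record.existence_code,
        "helices": [[h.start, h.end, h.kind.value] for h in record.helices],
    }


def record_from_dict(obj: dict) -> MPRecord:
    missing = [k for k in _FIXTURE_FIELDS if k not in obj]
    if missing:
        raise FixtureError(f"missing fields {missing}")
    helices = tuple(
        HelixSpan(start=int(s), end=int(e), kind=HelixKind(k)) for s, e, k in obj["helices"]
    )
    return MPRecord(
        id=str(obj["id"]),
        sequence=str(obj["sequence"]),
        lineage=tuple(obj["lineage"]),
        location_tag=str(obj["location_tag"]),
        existence_code=int(obj["existence_code"]),
        helices=helices,
    )


def write_fixture(records: Iterable[MPRecord], stream: IO[str]) -> None:
    """Write records in the line-delimited fixture format (one JSON/line)."""
    for rec in records:
        stream.write(json.dumps(record_to_dict(rec), sort_keys=True) + "\n")


def parse_fixture(stream: IO[str]) -> List[MPRecord]:
    """Read fixture records; schema violations report the line number."""
    out: List[MPRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
            out.append(record_from_dict(obj))
        except (json.JSONDecodeError, FixtureError, ValidationError, ValueError, TypeError) as exc:
            raise FixtureError(f"line {lineno}: {exc}") from exc
    return out
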