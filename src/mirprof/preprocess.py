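"""Raw reads/tags -> collapsed, length-filtered, FASTA-encoded sRNA library.

Illumina-style small-RNA reads of fixed delivered length (33/35 nt) carry a
variable remnant of the 3' adapter whenever the insert is shorter than the
read. Trimming cuts at the full adapter when present, else at the longest
read suffix that equals an adapter prefix of at least ``min_prefix`` nt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats_io import TagFileRecord

DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_MIN_LEN = 11  # keep reads strictly longer than 10 nt


@dataclass(frozen=True)
class AdapterSpec:
    sequence: str = DEFAULT_ADAPTER
    min_prefix: int = 5

    def __post_init__(self):
        if not (1 <= self.min_prefix <= len(self.sequence)):
            raise ValueError("min_prefix must be in [1, len(adapter)]")


@dataclass
class SmallRNATag:
    """A unique trimmed sequence with summed frequency in one sample."""

    id: int
    sequence: str
    frequency: int
    sample: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


def trim_adapter(read: str, adapter: AdapterSpec) -> tuple[str, bool]:
    """Cut ``read`` at the 3' adapter; returns (insert, trimmed_flag).

    The leftmost full-adapter occurrence wins; otherwise the longest read
    suffix equal to an adapter prefix of >= min_prefix nt. Matching is exact.
    """
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    pos = read.find(adapter.sequence)
    if pos >= 0:
        return read[:pos], True
    max_l = min(len(adapter.sequence) - 1, len(read))
    for l in range(max_l, adapter.min_prefix - 1, -1):
        if read.endswith(adapter.sequence[:l]):
            return read[: len(read) - l], True
    return read, False


def trim_tags(
    records: Iterable[TagFileRecord], adapter: AdapterSpec
) -> list[tuple[str, int]]:
    """Trim every tag-file record; returns (trimmed sequence, frequency) pairs."""
    return [(trim_adapter(r.sequence, adapter)[0], r.frequency) for r in records]


def collapse_tags(
    trimmed: Iterable[tuple[str, int]], sample: str = ""
) -> list[SmallRNATag]:
    """Sum frequencies of identical trimmed sequences.

    Output is ordered by descending frequency, ties broken lexicographically
    by sequence; ids are assigned consecutively (from 1) in that order, so the
    collapsed library is deterministic.
    """
    totals: dict[str, int] = {}
    for seq, freq in trimmed:
        totals[seq] = totals.get(seq, 0) + freq
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        SmallRNATag(id=i, sequence=seq, frequency=freq, sample=sample)
        for i, (seq, freq) in enumerate(ordered, start=1)
    ]


def length_filter(
    tags: Sequence[SmallRNATag], min_keep_len: int = DEFAULT_MIN_LEN
) -> tuple[list[SmallRNATag], int]:
    """Keep tags of length >= min_keep_len; also return the dropped-tag count."""
    kept = [t for t in tags if t.length >= min_keep_len]
    return kept, len(tags) - len(kept)


def to_processed_fasta(tags: Iterable[SmallRNATag]) -> list[tuple[str, str]]:
    """Encode tags as FASTA records with header tag<id>_L<length>_F<frequency>."""
    return [(f"tag{t.id}_L{t.length}_F{t.frequency}", t.sequence) for t in tags]


def parse_processed_header(header: str) -> tuple[int, int, int]:
    """Inverse of the processed-FASTA header encoding: (id, length, frequency)."""
    if not header.startswith("tag"):
        raise ValueError(f"not a processed-tag header: {header!r}")
    body = header[3:]
    id_part, l_part, f_part = body.split("_")
    if not (l_part.startswith("L") and f_part.startswith("F")):
        raise ValueError(f"not a processed-tag header: {header!r}")
    return int(id_part), int(l_part[1:]), int(f_part[1:])


def from_processed_fasta(records: Iterable[tuple[str, str]], sample: str = "") -> list[SmallRNATag]:
    tags = []
    for header, seq in records:
        tag_id, length, freq = parse_processed_header(header)
        if length != len(seq):
            raise ValueError(f"header length {length} != sequence length {len(seq)}")
        tags.append(SmallRNATag(id=tag_id, sequence=seq, frequency=freq, sample=sample))
    return tags


def preprocess_reads(
    raw: Iterable[str] | None = None,
    tag_records: Iterable[TagFileRecord] | None = None,
    adapter: AdapterSpec = AdapterSpec(),
    min_len: int = DEFAULT_MIN_LEN,
    sample: str = "",
) -> tuple[list[SmallRNATag], dict]:
    """Full preprocessing stage: trim, collapse, length-filter.

    Accepts either raw reads (each with implicit frequency 1) or tag-file
    records; re-collapsing always runs after trimming. Returns the processed
    tags and a small stats dict (raw/kept/dropped totals).
    """
    if (raw is None) == (tag_records is None):
        raise ValueError("provide exactly one of raw reads or tag records")
    if raw is not None:
        pairs = [(r, 1) for r in raw]
        pairs = [(trim_adapter(s, adapter)[0], f) for s, f in pairs]
    else:
        pairs = trim_tags(tag_records, adapter)
    total_raw = sum(f for _, f in pairs)
    collapsed = collapse_tags(pairs, sample=sample)
    kept, n_dropped = length_filter(collapsed, min_keep_len=min_len)
    # re-number ids after filtering so they stay consecutive
    kept = [
        SmallRNATag(id=i, sequence=t.sequence, frequency=t.frequency, sample=sample)
        for i, t in enumerate(kept, start=1)
    ]
    stats = {
        "total_raw_frequency": total_raw,
        "kept_tags": len(kept),
        "kept_frequency": sum(t.frequency for t in kept),
        "dropped_tags": n_dropped,
        "dropped_frequency": total_raw - sum(t.frequency for t in kept),
    }
    return kept, stats
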