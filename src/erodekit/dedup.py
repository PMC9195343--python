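"""PCR-duplicate removal for merged (single-end-like) ancient/historical reads.

Short ancient-DNA fragments are sequenced as overlapping read pairs and
merged into single sequences before mapping, so both fragment ends are
observed. Two merged reads are PCR duplicates of each other iff they map to
the same reference, with identical start AND end coordinates, on the same
strand. This is stricter than start-only duplicate marking and is the
appropriate rule when the full fragment is observed.

This stage *removes* duplicates (keeps one representative per cluster); it
does not mark them. Modern paired-end duplicate marking (Picard territory)
is out of scope and non-merged records are rejected.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats import AlignmentRecord

DuplicateKey = tuple[str, int, int, str]


@dataclass(frozen=True)
class DuplicateCluster:
    key: DuplicateKey
    members: tuple[AlignmentRecord, ...]
    representative: AlignmentRecord

    def __post_init__(self) -> None:
        assert self.representative in self.members
        assert all(
            (m.ref_name, m.start, m.end, m.strand) == self.key for m in self.members
        )


class NotDeduplicatableError(ValueError):
    """Record stream contains a record this stage cannot deduplicate."""


def _check(rec: AlignmentRecord) -> None:
    if not rec.is_primary:
        raise NotDeduplicatableError(
            f"non-primary alignment in dedup stream: {rec.query_name}"
        )
    if not rec.is_merged:
        raise NotDeduplicatableError(
            f"non-merged (paired) read in dedup stream: {rec.query_name}; "
            "paired-end duplicate marking is out of scope (use Picard)"
        )


def _representative(members: Sequence[AlignmentRecord]) -> AlignmentRecord:
    # best evidence first: quality sum, then mapq; name breaks remaining ties
    return min(
        members,
        key=lambda r: (-sum(r.base_qualities), -r.mapq, r.query_name),
    )


def cluster_merged_alignments(
    records: Iterable[AlignmentRecord],
) -> list[DuplicateCluster]:
    """Group merged primary alignments by (ref, start, end, strand)."""
    groups: dict[DuplicateKey, list[AlignmentRecord]] = {}
    for rec in records:
        _check(rec)
        groups.setdefault((rec.ref_name, rec.start, rec.end, rec.strand), []).append(
            rec
        )
    return [
        DuplicateCluster(key, tuple(members), _representative(members))
        for key, members in sorted(groups.items())
    ]


def remove_duplicates(
    records: Iterable[AlignmentRecord],
) -> tuple[list[AlignmentRecord], int, dict[int, int]]:
    """Keep one representative per duplicate cluster.

    Returns (kept records sorted by (ref, start, end), number removed,
    cluster-size histogram {size: n_clusters}).
    """
    clusters = cluster_merged_alignments(records)
    kept = sorted(
        (c.representative for c in clusters),
        key=lambda r: (r.ref_name, r.start, r.end),
    )
    n_input = sum(len(c.members) for c in clusters)
    histogram = dict(Counter(len(c.members) for c in clusters))
    return kept, n_input - len(clusters), histogram
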