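"""Guide quantification for reporter-sorted pooled CRISPR screens.

Raw amplicon reads carry a 20-nt protospacer flanked by fixed vector
backbone sequences.  This module extracts the protospacer by anchoring on
the 5' backbone adapter, assigns it to a guide library by exact (or
uniquely-resolvable mismatch) dictionary lookup, accumulates guide x
sorted-bin count tables, computes library representation QC, and applies
the per-screen low-count filter used before hit calling.

Coordinates and sequences are plain Python strings over {A, C, G, T};
counts are kept in a pandas DataFrame indexed by guide id with a
(screen, bin) column MultiIndex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

#: sentinel gene label for non-targeting control guides
NON_TARGETING = "NT"

#: sorted-bin labels: reporter-positive and reporter-negative populations
REPORTER_POS = "REPORTER_POS"
REPORTER_NEG = "REPORTER_NEG"
BINS = (REPORTER_POS, REPORTER_NEG)

#: vector backbone sequences flanking the protospacer in the amplicon
DEFAULT_FIVE_ADAPTER = "GACGAAACACCG"
DEFAULT_THREE_ADAPTER = "GTTTTAGAGCTA"

PROTOSPACER_LENGTH = 20


class AmbiguousLibraryError(ValueError):
    """Raised when a guide library contains duplicated sequences."""


@dataclass(frozen=True)
class GuideEntry:
    guide_id: str
    sequence: str
    gene: str

    @property
    def is_non_targeting(self) -> bool:
        return self.gene == NON_TARGETING


class GuideLibrary:
    """The screen's sgRNA universe: sequences, gene mapping, NT flags.

    Parameters
    ----------
    entries
        ``(guide_id, sequence, gene)`` triples; ``gene`` equal to
        :data:`NON_TARGETING` marks a non-targeting control.

    Raises
    ------
    ValueError
        On duplicate guide ids or sequences of the wrong length.
    AmbiguousLibraryError
        On duplicate sequences (two guides that cannot be told apart).
    """

    def __init__(self, entries: Iterable[tuple[str, str, str]]):
        self.entries: list[GuideEntry] = []
        seen_ids: set[str] = set()
        seq_to_id: dict[str, str] = {}
        dup_seqs: set[str] = set()
        for guide_id, sequence, gene in entries:
            sequence = sequence.upper()
            if len(sequence) != PROTOSPACER_LENGTH:
                raise ValueError(
                    f"guide {guide_id!r}: sequence length {len(sequence)} != "
                    f"{PROTOSPACER_LENGTH}"
                )
            if set(sequence) - set("ACGT"):
                raise ValueError(f"guide {guide_id!r}: non-ACGT sequence")
            if guide_id in seen_ids:
                raise ValueError(f"duplicate guide_id {guide_id!r}")
            seen_ids.add(guide_id)
            if sequence in seq_to_id:
                dup_seqs.add(sequence)
            seq_to_id[sequence] = guide_id
            self.entries.append(GuideEntry(guide_id, sequence, gene))
        if dup_seqs:
            raise AmbiguousLibraryError(
                f"{len(dup_seqs)} sequences shared by multiple guides"
            )
        self._seq_to_id = seq_to_id
        self._id_to_entry = {e.guide_id: e for e in self.entries}
        # 2-bit encoding of every sequence, for vectorized Hamming search
        self._encoded = _encode_sequences([e.sequence for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, guide_id: str) -> bool:
        return guide_id in self._id_to_entry

    @property
    def guide_ids(self) -> list[str]:
        return [e.guide_id for e in self.entries]

    @property
    def non_targeting_ids(self) -> list[str]:
        return [e.guide_id for e in self.entries if e.is_non_targeting]

    def gene_of(self, guide_id: str) -> str:
        return self._id_to_entry[guide_id].gene

    def sequence_of(self, guide_id: str) -> str:
        return self._id_to_entry[guide_id].sequence

    def lookup_exact(self, sequence: str) -> Optional[str]:
        return self._seq_to_id.get(sequence)

    @classmethod
    def from_csv(cls, path) -> "GuideLibrary":
        """Read a library table with columns guide_id, sequence, gene.

        Separator is sniffed (comma or tab)."""
        df = pd.read_csv(path, sep=None, engine="python")
        required = {"guide_id", "sequence", "gene"}
        if not required.issubset(df.columns):
            raise ValueError(f"library file must have columns {sorted(required)}")
        return cls(
            (str(r.guide_id), str(r.sequence), str(r.gene))
            for r in df.itertuples(index=False)
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [(e.guide_id, e.sequence, e.gene) for e in self.entries],
            columns=["guide_id", "sequence", "gene"],
        ).to_csv(path, index=False)


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length DNA strings as a (n, L) uint8 matrix."""
    if not seqs:
        return np.zeros((0, PROTOSPACER_LENGTH), dtype=np.uint8)
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


@dataclass
class ReadRecord:
    """A sequencing read: id, sequence, optional quality string."""

    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty read sequence")


def _hamming_leq(a: str, b: str, budget: int) -> bool:
    """True if Hamming(a, b) <= budget (equal lengths assumed)."""
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return False
    return True


def extract_protospacer(
    read: ReadRecord | str,
    five_adapter: str = DEFAULT_FIVE_ADAPTER,
    three_adapter: str = DEFAULT_THREE_ADAPTER,
    max_adapter_mismatch: int = 1,
) -> Optional[str]:
    """Extract the 20-nt protospacer anchored on the 5' backbone adapter.

    The leftmost occurrence of the 5' adapter within the mismatch budget
    anchors the window; the 20 bases immediately following it are
    returned.  Reads with no 5' anchor, or with fewer than 20 bases after
    it, yield ``None`` (to be tallied as unextracted by the caller).  The
    3' adapter, when the read is long enough to contain it, is expected
    immediately after the window; its absence does not change the window.
    """
    if not five_adapter:
        raise ValueError("five_adapter must be non-empty")
    if max_adapter_mismatch < 0:
        raise ValueError("max_adapter_mismatch must be >= 0")
    seq = read.sequence if isinstance(read, ReadRecord) else read
    seq = seq.upper()
    la = len(five_adapter)
    anchor = None
    if max_adapter_mismatch == 0:
        pos = seq.find(five_adapter)
        if pos >= 0:
            anchor = pos
    else:
        for pos in range(len(seq) - la + 1):
            if _hamming_leq(seq[pos : pos + la], five_adapter, max_adapter_mismatch):
                anchor = pos
                break
    if anchor is None:
        return None
    start = anchor + la
    if len(seq) - start < PROTOSPACER_LENGTH:
        return None
    return seq[start : start + PROTOSPACER_LENGTH]


UNASSIGNED = None


def assign_guide(
    protospacer: str, library: GuideLibrary, max_mismatch: int = 0
) -> Optional[str]:
    """Assign a protospacer to a guide id, or ``None`` if unassignable.

    An exact match always wins.  With ``max_mismatch > 0`` a protospacer
    is assigned to the unique library sequence within that Hamming
    distance; ties (two equally-close guides) are unassigned.
    """
    if len(protospacer) != PROTOSPACER_LENGTH:
        raise ValueError("protospacer must be 20 nt")
    hit = library.lookup_exact(protospacer)
    if hit is not None:
        return hit
    if max_mismatch <= 0 or len(library) == 0:
        return UNASSIGNED
    query = np.frombuffer(protospacer.encode(), dtype=np.uint8)
    dists = (library._encoded != query[None, :]).sum(axis=1)
    within = np.flatnonzero(dists <= max_mismatch)
    if len(within) == 1:
        return library.entries[int(within[0])].guide_id
    return UNASSIGNED


@dataclass
class CountStats:
    total: int = 0
    assigned: int = 0
    unassigned: int = 0
    unextracted: int = 0

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "assigned": self.assigned,
            "unassigned": self.unassigned,
            "unextracted": self.unextracted,
        }


def count_reads(
    reads: Iterable[ReadRecord | str],
    library: GuideLibrary,
    five_adapter: str = DEFAULT_FIVE_ADAPTER,
    three_adapter: str = DEFAULT_THREE_ADAPTER,
    max_adapter_mismatch: int = 1,
    max_mismatch: int = 0,
) -> tuple[pd.Series, CountStats]:
    """Count one sample's reads into a per-guide column.

    Returns the per-guide counts (a Series indexed like the library) and
    extraction/assignment tallies; ``assigned + unassigned + unextracted
    == total`` always holds.
    """
    counts = {gid: 0 for gid in library.guide_ids}
    stats = CountStats()
    for read in reads:
        stats.total += 1
        proto = extract_protospacer(
            read, five_adapter, three_adapter, max_adapter_mismatch
        )
        if proto is None:
            stats.unextracted += 1
            continue
        gid = assign_guide(proto, library, max_mismatch)
        if gid is None:
            stats.unassigned += 1
        else:
            stats.assigned += 1
            counts[gid] += 1
    if stats.total == 0:
        import warnings

        warnings.warn("empty read stream: zero count column", stacklevel=2)
    return pd.Series(counts, name="count", dtype=np.int64), stats


class CountTable:
    """Guide x (screen, sorted-bin) integer read counts.

    Wraps a DataFrame whose index is guide_id and whose columns are a
    ``(screen_id, bin)`` MultiIndex with bins in :data:`BINS`.
    """

    def __init__(self, counts: pd.DataFrame, library: Optional[GuideLibrary] = None):
        if not isinstance(counts.columns, pd.MultiIndex) or counts.columns.nlevels != 2:
            raise ValueError("counts must have a (screen, bin) column MultiIndex")
        bad_bins = set(counts.columns.get_level_values(1)) - set(BINS)
        if bad_bins:
            raise ValueError(f"unknown bins: {sorted(bad_bins)}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if library is not None:
            missing = set(counts.index) - set(library.guide_ids)
            if missing:
                raise ValueError(
                    f"{len(missing)} guides absent from library, e.g. "
                    f"{sorted(missing)[:3]}"
                )
        self.counts = counts.astype(np.int64)
        self.counts.index.name = "guide_id"
        self.library = library

    @property
    def guides(self) -> list[str]:
        return list(self.counts.index)

    @property
    def screens(self) -> list[str]:
        return list(dict.fromkeys(self.counts.columns.get_level_values(0)))

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def screen_counts(self, screen_id: str) -> pd.DataFrame:
        """The (guides x bins) sub-table for one screen."""
        return self.counts[screen_id]

    @classmethod
    def from_columns(
        cls,
        columns: dict[tuple[str, str], pd.Series],
        library: Optional[GuideLibrary] = None,
    ) -> "CountTable":
        df = pd.DataFrame(columns)
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["screen", "bin"])
        return cls(df.fillna(0), library)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.columns = [f"{s}:{b}" for s, b in out.columns]
        out.index.name = "guide_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, library: Optional[GuideLibrary] = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        cols = []
        for c in df.columns:
            screen, _, bin_ = c.partition(":")
            if bin_ not in BINS:
                raise ValueError(f"bad column header {c!r}: expected screen:bin")
            cols.append((screen, bin_))
        df.columns = pd.MultiIndex.from_tuples(cols, names=["screen", "bin"])
        return cls(df, library)


@dataclass
class LibraryQC:
    """Library representation metrics.

    fraction_perfect_match
        Reads whose protospacer exactly matches a library sequence, over
        all reads.
    fraction_undetected
        Guides with zero counts, over all guides.
    skew_ratio
        90th / 10th nearest-rank percentile of the guide count vector;
        ``inf`` (with ``skew_undefined``) when the 10th percentile is 0.
    """

    fraction_perfect_match: float
    fraction_undetected: float
    skew_ratio: float
    skew_undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "fraction_perfect_match": self.fraction_perfect_match,
            "fraction_undetected": self.fraction_undetected,
            "skew_ratio": self.skew_ratio,
            "skew_undefined": self.skew_undefined,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values))
    if len(v) == 0:
        raise ValueError("empty vector")
    rank = int(np.ceil(pct / 100.0 * len(v)))
    rank = min(max(rank, 1), len(v))
    return float(v[rank - 1])


def library_qc(
    counts: pd.Series, library: GuideLibrary, total_reads: int, perfect_matches: int
) -> LibraryQC:
    """Compute representation QC for one sample's guide count column.

    A well-constructed library is expected to show >90% perfectly
    matching reads, <0.5% undetected guides and a skew ratio below 10.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    vec = counts.reindex(library.guide_ids).fillna(0).to_numpy()
    undetected = float((vec == 0).sum() / len(vec))
    p10 = nearest_rank_percentile(vec, 10)
    p90 = nearest_rank_percentile(vec, 90)
    if p10 == 0:
        skew, undef = float("inf"), True
    else:
        skew, undef = p90 / p10, False
    return LibraryQC(perfect_matches / total_reads, undetected, skew, undef)


def filter_low_counts(
    table: CountTable, threshold: int
) -> dict[str, list[str]]:
    """Per-screen low-count guide filter.

    Within each screen a guide is dropped when its count is strictly
    below ``threshold`` in *either* sorted bin.  Returns the retained
    guide list per screen (counts themselves are untouched); raises when
    a screen retains no guides at all.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    retained: dict[str, list[str]] = {}
    for screen in table.screens:
        sub = table.screen_counts(screen)
        for b in BINS:
            if b not in sub.columns:
                raise ValueError(f"screen {screen!r} lacks bin {b}")
        keep = (sub[REPORTER_POS] >= threshold) & (sub[REPORTER_NEG] >= threshold)
        kept = list(sub.index[keep])
        if not kept:
            raise ValueError(
                f"all guides filtered out in screen {screen!r} at threshold {threshold}"
            )
        retained[screen] = kept
    return retained


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream reads from a FASTQ file (plain or gzip)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # '+'
            qual = fh.readline().strip()
            yield ReadRecord(header.strip().lstrip("@"), seq, qual or None)
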