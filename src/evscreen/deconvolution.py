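"""FASTQ deconvolution: reads -> element-level count matrices.

Barcode reads (RNA-derived) are trimmed to a fixed-length fragment and
matched against the 5' prefixes of the library barcodes by Hamming
distance: every element at the minimum distance is counted, provided that
minimum is within the mismatch tolerance (best-hit-within-k, ties all
counted, i.e. multi-mapping reads contribute to every tied element).
Because the mature bEXOmiR starts with the barcode and ends in the
constant EXO motif, the leading 14 nt are the informative part of a read.

sgRNA reads (genomic DNA-derived) are matched exactly after stripping a
constant 5' anchor; no mismatches are tolerated.

Library sizes here (<= a few 10^5 barcodes) make an index-free packed
Hamming scan tractable, so no external aligner is involved.
"""

from __future__ import annotations

import gzip
import json
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._encoding import onehot_codes, seq_to_indices
from .errors import EvscreenError
from .library_model import Library

#: Constant vector-derived sequence immediately 5' of the protospacer in
#: sgRNA reads (BsmBI-style cloning overhang); configurable per run.
DEFAULT_SGRNA_ANCHOR = "CACCG"


@dataclass
class SampleStats:
    """Per-sample read accounting. ``assigned + dropped == total``; column
    sums can exceed ``assigned`` when reads tie between barcodes."""

    total: int = 0
    assigned: int = 0
    multi_assigned: int = 0
    dropped: int = 0


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, bases, qualities) from plain or gzipped FASTQ."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence, rec.quality or ""


def trim_rna_read(bases: str, trim_len: int = 14, offset: int = 0) -> str | None:
    """Return ``bases[offset:offset+trim_len]`` or None if the read is too
    short (dropped reads are data, tallied by the caller)."""
    if len(bases) < offset + trim_len:
        return None
    return bases[offset:offset + trim_len]


class BarcodeMatcher:
    """Mismatch-tolerant nearest-prefix matcher over a library's barcodes."""

    def __init__(self, lib: Library | Sequence[str], trim_len: int = 14,
                 max_mismatch: int = 2):
        if isinstance(lib, Library):
            barcodes = lib.barcodes
            self.element_ids = np.asarray(lib.element_ids, dtype=object)
        else:
            barcodes = list(lib)
            self.element_ids = np.asarray([f"bc{i}" for i in range(len(barcodes))],
                                          dtype=object)
        if not barcodes:
            raise EvscreenError("empty barcode set")
        if any(len(b) < trim_len for b in barcodes):
            raise EvscreenError(f"all barcodes must be >= trim_len ({trim_len}) nt")
        self.trim_len = trim_len
        self.max_mismatch = max_mismatch
        prefixes = [b[:trim_len].upper() for b in barcodes]
        idx = np.stack([seq_to_indices(p) for p in prefixes])
        self.codes = onehot_codes(idx)

    def _encode_fragments(self, fragments: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        idx = np.stack([seq_to_indices(f, allow_ambiguous=True) for f in fragments])
        n_amb = (idx == 255).sum(axis=1).astype(np.uint64)
        return onehot_codes(idx), n_amb

    def assign(self, fragment: str) -> set[str]:
        """Element ids at the minimum Hamming distance (if <= max_mismatch)."""
        if len(fragment) != self.trim_len:
            raise EvscreenError(f"fragment length {len(fragment)} != trim_len {self.trim_len}")
        codes, n_amb = self._encode_fragments([fragment])
        # ambiguous read positions contribute 1 popcount bit; full mismatch = 2
        d2 = np.bitwise_count(self.codes ^ codes[0]) + n_amb[0]
        dmin = int(d2.min()) // 2
        if dmin > self.max_mismatch:
            return set()
        return set(self.element_ids[d2 == d2.min()])

    def assign_batch(self, fragments: Sequence[str]) -> list[np.ndarray]:
        """Vectorised assignment; returns per-fragment arrays of row indices
        into the library (empty when nothing is within tolerance)."""
        if not fragments:
            return []
        codes, n_amb = self._encode_fragments(fragments)
        K = len(self.codes)
        chunk = max(1, 4_000_000 // K)
        out: list[np.ndarray] = []
        lim = np.uint64(2 * self.max_mismatch)
        for s in range(0, len(codes), chunk):
            block = codes[s:s + chunk]
            d2 = np.bitwise_count(block[:, None] ^ self.codes[None, :])
            d2 += n_amb[s:s + chunk, None]
            dmin = d2.min(axis=1)
            for r in range(block.shape[0]):
                if dmin[r] > lim:
                    out.append(np.empty(0, dtype=np.int64))
                else:
                    out.append(np.flatnonzero(d2[r] == dmin[r]))
        return out


def assign_barcode(fragment: str, lib: Library, max_mismatch: int = 2) -> set[str]:
    """One-shot wrapper around :class:`BarcodeMatcher` for a single fragment."""
    return BarcodeMatcher(lib, trim_len=len(fragment), max_mismatch=max_mismatch).assign(fragment)


def count_barcode_reads(reads: Iterable[tuple[str, str, str]] | Iterable[tuple[str, str]],
                        lib: Library, trim_len: int = 14, max_mismatch: int = 2,
                        offset: int = 0,
                        matcher: BarcodeMatcher | None = None) -> tuple[pd.Series, SampleStats]:
    """Count one RNA sample's reads against the library barcodes."""
    m = matcher or BarcodeMatcher(lib, trim_len=trim_len, max_mismatch=max_mismatch)
    stats = SampleStats()
    counts = np.zeros(len(m.element_ids), dtype=np.int64)
    batch: list[str] = []

    def flush() -> None:
        for hits in m.assign_batch(batch):
            if hits.size:
                stats.assigned += 1
                if hits.size > 1:
                    stats.multi_assigned += 1
                counts[hits] += 1
            else:
                stats.dropped += 1
        batch.clear()

    for rec in reads:
        bases = rec[1]
        stats.total += 1
        frag = trim_rna_read(bases, trim_len=m.trim_len, offset=offset)
        if frag is None:
            stats.dropped += 1
            continue
        batch.append(frag)
        if len(batch) >= 16384:
            flush()
    flush()
    return pd.Series(counts, index=m.element_ids, name="count"), stats


def count_sgrnas(reads: Iterable[tuple[str, str, str]] | Iterable[tuple[str, str]],
                 lib: Library, anchor: str = DEFAULT_SGRNA_ANCHOR) -> tuple[pd.Series, SampleStats]:
    """Exact-match sgRNA counting after locating/stripping the 5' anchor.

    Reads whose anchor is missing, or whose protospacer matches no library
    sgRNA exactly, are dropped (and tallied).
    """
    by_seq = {el.sgrna_seq: i for i, el in enumerate(lib.elements)}
    if len(by_seq) != len(lib.elements):
        raise EvscreenError("sgRNA sequences must be unique in the library")
    lengths = sorted({len(s) for s in by_seq})
    stats = SampleStats()
    counts = np.zeros(len(lib.elements), dtype=np.int64)
    for rec in reads:
        bases = rec[1]
        stats.total += 1
        if anchor:
            pos = bases.find(anchor)
            if pos < 0:
                stats.dropped += 1
                continue
            start = pos + len(anchor)
        else:
            start = 0
        hit = None
        for L in lengths:
            hit = by_seq.get(bases[start:start + L])
            if hit is not None:
                break
        if hit is None:
            stats.dropped += 1
        else:
            stats.assigned += 1
            counts[hit] += 1
    return pd.Series(counts, index=lib.element_ids, name="count"), stats


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Elements x samples integer counts plus per-sample read accounting."""

    counts: pd.DataFrame
    metadata: dict[str, SampleStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def sample(self, name: str) -> pd.Series:
        return self.counts[name]

    def to_tsv(self, path, metadata_path=None) -> None:
        df = self.counts.copy()
        df.index.name = "element_id"
        df.to_csv(path, sep="\t")
        if metadata_path is not None:
            with open(metadata_path, "w", encoding="utf-8") as fh:
                json.dump({k: asdict(v) for k, v in self.metadata.items()}, fh, indent=1)

    @classmethod
    def from_tsv(cls, path, metadata_path=None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="element_id")
        meta: dict[str, SampleStats] = {}
        if metadata_path is not None:
            with open(metadata_path, encoding="utf-8") as fh:
                meta = {k: SampleStats(**v) for k, v in json.load(fh).items()}
        return cls(df.astype(np.int64), meta)


def count_screen(samples: Sequence[tuple[str, object]] | Mapping[str, object],
                 lib: Library, mode: str = "barcode", trim_len: int = 14,
                 max_mismatch: int = 2, offset: int = 0,
                 anchor: str = DEFAULT_SGRNA_ANCHOR) -> CountMatrix:
    """Count every sample's FASTQ file(s) into one matrix column each.

    ``samples`` is a sequence of ``(sample_name, path_or_paths)`` pairs (or a
    mapping); duplicate sample names raise. ``mode`` selects barcode (RNA)
    or sgrna (DNA) counting.
    """
    pairs = list(samples.items()) if isinstance(samples, Mapping) else list(samples)
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise EvscreenError("duplicate sample label")
    if mode not in ("barcode", "sgrna"):
        raise EvscreenError("mode must be 'barcode' or 'sgrna'")
    matcher = (BarcodeMatcher(lib, trim_len=trim_len, max_mismatch=max_mismatch)
               if mode == "barcode" else None)
    columns: dict[str, pd.Series] = {}
    meta: dict[str, SampleStats] = {}
    for name, paths in pairs:
        if isinstance(paths, (str, bytes)) or not isinstance(paths, (list, tuple)):
            paths = [paths]
        total = pd.Series(0, index=lib.element_ids, dtype=np.int64)
        stats = SampleStats()
        for p in paths:
            reads = read_fastq(p)
            if mode == "barcode":
                col, st = count_barcode_reads(reads, lib, matcher=matcher, offset=offset)
            else:
                col, st = count_sgrnas(reads, lib, anchor=anchor)
            total = total.add(col, fill_value=0).astype(np.int64)
            stats.total += st.total
            stats.assigned += st.assigned
            stats.multi_assigned += st.multi_assigned
            stats.dropped += st.dropped
        columns[name] = total
        meta[name] = stats
    return CountMatrix(pd.DataFrame(columns), meta)
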