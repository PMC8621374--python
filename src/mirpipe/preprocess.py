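"""Raw-read cleaning, tag collapsing and per-library summary statistics.

Raw small-RNA reads are adapter-ligated instrument reads; cleaning locates
and trims the 3' adapter, discards contaminated / low-quality / homopolymer /
out-of-range reads with a full accounting of every removal reason, and the
surviving inserts are collapsed into unique sequence tags with per-library
(replicate-averaged) counts.  Summary statistics mirror the usual library
QC table: raw reads, clean reads and percentage, Q20 percentage, mapped reads
and percentage, and miRNA read totals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

DISCARD_REASONS = (
    "no_adapter",
    "adapter5_contamination",
    "low_quality",
    "homopolymer",
    "too_short",
    "too_long",
)


@dataclass
class CleanResult:
    """Cleaned inserts of one FASTQ replicate plus the discard tally."""

    reads: list
    n_raw: int
    discards: Counter
    q20_bases: int = 0  # bases with Q >= 20 among retained inserts
    total_bases: int = 0

    @property
    def n_clean(self) -> int:
        return len(self.reads)

    @property
    def q20_pct(self) -> float:
        if self.total_bases == 0:
            return 0.0
        return 100.0 * self.q20_bases / self.total_bases


def _find_adapter(seq: str, adapter: str, seed_len: int = 8, max_mismatch: int = 1) -> int:
    """Leftmost start of the 3' adapter in `seq`, or -1.

    Exact match of the adapter prefix (min(seed_len, len) bases) is tried
    first; failing that, a scan allowing one mismatch in the seed.
    """
    seed = adapter[: max(seed_len, 1)]
    pos = seq.find(seed)
    if pos >= 0:
        return pos
    if max_mismatch < 1:
        return -1
    k = len(seed)
    for i in range(len(seq) - k + 1):
        mm = 0
        for a, b in zip(seq[i : i + k], seed):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return i
    return -1


def parse_fastq(path):
    """Minimal strict FASTQ iterator yielding (seq, qual) tuples."""
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record at index {idx} in {path}")
            idx += 1
            yield seq.upper(), qual


def clean_reads(
    fastq_path,
    adapter3: str,
    adapter5: str | None = None,
    *,
    min_len: int = 18,
    max_len: int = 30,
    max_lowq_frac: float = 0.10,
    q_threshold: int = 20,
    homopolymer_frac: float = 0.80,
    adapter_seed: int = 8,
) -> CleanResult:
    """Trim the 3' adapter and filter reads; tally every discard reason.

    A read is discarded if: the 3' adapter is absent; the 5' adapter is found
    internally; more than `max_lowq_frac` of insert bases are below Q20; a
    single base makes up >= `homopolymer_frac` of the insert; or the trimmed
    insert is outside [min_len, max_len].  Retained + discarded = input.
    """
    reads: list[str] = []
    discards: Counter = Counter()
    n_raw = 0
    q20_bases = 0
    total_bases = 0
    qcut = chr(33 + q_threshold)
    for seq, qual in parse_fastq(fastq_path):
        n_raw += 1
        pos = _find_adapter(seq, adapter3, seed_len=adapter_seed)
        if pos < 0:
            discards["no_adapter"] += 1
            continue
        insert = seq[:pos]
        iqual = qual[:pos]
        if adapter5 and adapter5 in seq:
            discards["adapter5_contamination"] += 1
            continue
        if insert:
            n_low = sum(1 for c in iqual if c < qcut)
            if n_low / len(insert) > max_lowq_frac:
                discards["low_quality"] += 1
                continue
            top = max(insert.count(b) for b in "ACGT")
            if top / len(insert) >= homopolymer_frac:
                discards["homopolymer"] += 1
                continue
        if len(insert) < min_len:
            discards["too_short"] += 1
            continue
        if len(insert) > max_len:
            discards["too_long"] += 1
            continue
        if "N" in insert:
            discards["low_quality"] += 1
            continue
        reads.append(insert)
        q20_bases += sum(1 for c in iqual if c >= qcut)
        total_bases += len(insert)
    return CleanResult(
        reads=reads, n_raw=n_raw, discards=discards, q20_bases=q20_bases, total_bases=total_bases
    )


def collapse_tags(clean_per_library: dict) -> pd.DataFrame:
    """Collapse cleaned reads into unique tags with replicate-averaged counts.

    `clean_per_library` maps library_id -> list of per-replicate read lists.
    Returns a DataFrame indexed by tag sequence with one count column per
    library; replicate counts are averaged, so half-integer counts appear
    whenever the two replicates disagree by an odd number.
    """
    libraries = list(clean_per_library)
    per_lib_counts = {}
    all_tags = set()
    for lib, replicates in clean_per_library.items():
        counters = [Counter(reads) for reads in replicates]
        n_rep = max(len(counters), 1)
        merged: dict[str, float] = {}
        for c in counters:
            for tag, n in c.items():
                merged[tag] = merged.get(tag, 0.0) + n / n_rep
        per_lib_counts[lib] = merged
        all_tags.update(merged)
    tags = sorted(all_tags)  # deterministic order
    data = {
        lib: [per_lib_counts[lib].get(tag, 0.0) for tag in tags] for lib in libraries
    }
    df = pd.DataFrame(data, index=pd.Index(tags, name="sequence"))
    df.insert(0, "length", [len(t) for t in tags])
    return df


@dataclass
class LibraryStats:
    """Per-library sequencing summary (raw/clean/mapped/miRNA accounting)."""

    library_id: str
    raw_reads: float
    clean_reads: float
    q20_pct: float
    mapped_reads: float = 0.0
    known_mirna_reads: float = 0.0
    novel_mirna_reads: float = 0.0
    length_histogram: dict = field(default_factory=dict)

    @staticmethod
    def _pct(numerator: float, denominator: float) -> float:
        if denominator == 0:
            import warnings

            warnings.warn("zero denominator in percentage; reporting 0")
            return 0.0
        return round(100.0 * numerator / denominator, 2)

    @property
    def mirna_reads_total(self) -> float:
        return self.known_mirna_reads + self.novel_mirna_reads

    @property
    def clean_pct(self) -> float:
        return self._pct(self.clean_reads, self.raw_reads)

    @property
    def mapped_pct(self) -> float:
        return self._pct(self.mapped_reads, self.clean_reads)


def library_stats(
    library_id: str,
    *,
    raw_reads: float,
    clean_reads: float,
    q20_pct: float = 0.0,
    mapped_reads: float = 0.0,
    known_mirna_reads: float = 0.0,
    novel_mirna_reads: float = 0.0,
    length_histogram: dict | None = None,
) -> LibraryStats:
    """Assemble a :class:`LibraryStats`; percentages recompute from counts."""
    return LibraryStats(
        library_id=library_id,
        raw_reads=raw_reads,
        clean_reads=clean_reads,
        q20_pct=round(q20_pct, 2),
        mapped_reads=mapped_reads,
        known_mirna_reads=known_mirna_reads,
        novel_mirna_reads=novel_mirna_reads,
        length_histogram=length_histogram or {},
    )


def length_distribution(
    tags: pd.DataFrame, libraries: list | None = None, min_len: int = 18, max_len: int = 30
) -> dict:
    """Length histograms per library, by read count and by unique tag.

    Returns {library: DataFrame(index=length, columns=[reads, tags, read_frac,
    tag_frac])}; fractions sum to 1 for non-empty libraries.
    """
    if libraries is None:
        libraries = [c for c in tags.columns if c != "length"]
    lengths = range(min_len, max_len + 1)
    out = {}
    for lib in libraries:
        by_reads = {length: 0.0 for length in lengths}
        by_tags = {length: 0 for length in lengths}
        sub = tags[tags[lib] > 0]
        for length, count in zip(sub["length"], sub[lib]):
            if min_len <= length <= max_len:
                by_reads[length] += count
                by_tags[length] += 1
        df = pd.DataFrame(
            {"reads": by_reads, "tags": by_tags}, index=pd.Index(lengths, name="length")
        )
        tot_r, tot_t = df["reads"].sum(), df["tags"].sum()
        df["read_frac"] = df["reads"] / tot_r if tot_r else 0.0
        df["tag_frac"] = df["tags"] / tot_t if tot_t else 0.0
        out[lib] = df
    return out


def write_tags(tags: pd.DataFrame, fasta_path, tsv_path) -> None:
    """Emit collapsed tags as FASTA plus a count-table TSV sidecar."""
    from .util import write_fasta

    names = [f"tag{i + 1:07d}" for i in range(len(tags))]
    write_fasta(fasta_path, zip(names, tags.index))
    out = tags.copy()
    out.insert(0, "tag_id", names)
    out.to_csv(tsv_path, sep="\t")
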