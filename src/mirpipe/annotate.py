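"""Genome mapping, ncRNA exclusion and known-miRNA assignment for tags.

Tags are aligned to the genome on both strands allowing up to two mismatches
with a pigeonhole seed index (any hit with <= 2 mismatches over an 18+ nt tag
contains an exact seed in one of its thirds), keeping only the best
(fewest-mismatch) stratum and discarding tags whose best stratum is not
unique — the classic "-v 2 -best -strata -m 1" contract.  Aligned tags
overlapping an annotated ncRNA locus over at least 90% of their length are
categorized as that ncRNA class and removed; survivors are matched against
the mature-miRNA reference (<= 2 mismatches, best ungapped offset) to split
known from novel-candidate tags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .util import encode, revcomp

#: deterministic precedence when a tag overlaps two ncRNA classes at >= 90%
NCRNA_PRECEDENCE = ("rRNA", "tRNA", "snRNA", "snoRNA", "siRNA", "phasiRNA", "NOR")


@dataclass(frozen=True)
class GenomeAlignment:
    tag: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class KnownAssignment:
    tag: str
    mature_id: str
    mismatches: int
    family: str | None = None


class GenomeIndex:
    """Exact k-mer index over one or more chromosomes (both strands via tag rc)."""

    def __init__(self, genome: dict, k: int = 6):
        self.k = k
        self.chroms = {c: s.upper() for c, s in genome.items()}
        self.arrays = {c: encode(s) for c, s in self.chroms.items()}
        self.index: dict[str, list] = {}
        for chrom, seq in self.chroms.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((chrom, i))

    def candidates(self, tag: str) -> set:
        """All (chrom, start) genome starts that could hold the tag with <= 2
        mismatches, by the pigeonhole principle over the tag's thirds."""
        L = len(tag)
        k = self.k
        thirds = [0, L // 3, 2 * L // 3]
        out = set()
        for off in thirds:
            probe = tag[off : off + k]
            if len(probe) < k:
                continue
            for chrom, pos in self.index.get(probe, ()):
                start = pos - off
                if 0 <= start <= len(self.chroms[chrom]) - L:
                    out.add((chrom, start))
        return out


def map_tags(
    tags, genome: dict, max_mismatch: int = 2, index: GenomeIndex | None = None
) -> tuple[dict, dict]:
    """Align tags to the genome; best-stratum, unique-hit contract.

    Returns ``(alignments, status)`` where `alignments` maps tag ->
    :class:`GenomeAlignment` for uniquely mapped tags and `status` maps every
    tag to one of "unique", "multi", "unmapped".  Tags containing characters
    outside ACGTN are rejected with a ``ValueError`` naming the tag.
    """
    if index is None:
        index = GenomeIndex(genome)
    alignments: dict[str, GenomeAlignment] = {}
    status: dict[str, str] = {}
    for tag in tags:
        if any(c not in "ACGTN" for c in tag.upper()):
            raise ValueError(f"tag with invalid characters: {tag}")
        tag = tag.upper()
        L = len(tag)
        hits = []
        for strand in "+-":
            query = tag if strand == "+" else revcomp(tag)
            qarr = encode(query)
            for chrom, start in sorted(index.candidates(query)):
                mm = int((index.arrays[chrom][start : start + L] != qarr).sum())
                if mm <= max_mismatch:
                    hits.append((mm, chrom, start, strand))
        if not hits:
            status[tag] = "unmapped"
            continue
        best = min(h[0] for h in hits)
        stratum = [h for h in hits if h[0] == best]
        if len(stratum) > 1:
            status[tag] = "multi"
            continue
        mm, chrom, start, strand = stratum[0]
        alignments[tag] = GenomeAlignment(
            tag=tag, chrom=chrom, start=start, end=start + L, strand=strand, mismatches=mm
        )
        status[tag] = "unique"
    return alignments, status


def brute_force_map(tags, genome: dict, max_mismatch: int = 2) -> tuple[dict, dict]:
    """Exhaustive Hamming scan over every offset/strand (oracle; small genomes)."""
    alignments: dict[str, GenomeAlignment] = {}
    status: dict[str, str] = {}
    arrays = {c: encode(s.upper()) for c, s in genome.items()}
    windows = {}  # (chrom, L) -> sliding windows view
    for tag in tags:
        tag = tag.upper()
        L = len(tag)
        hits = []
        for strand in "+-":
            query = tag if strand == "+" else revcomp(tag)
            qarr = encode(query)
            for chrom, garr in arrays.items():
                if len(garr) < L:
                    continue
                key = (chrom, L)
                if key not in windows:
                    windows[key] = np.lib.stride_tricks.sliding_window_view(garr, L)
                mms = (windows[key] != qarr).sum(axis=1)
                for start in np.nonzero(mms <= max_mismatch)[0]:
                    hits.append((int(mms[start]), chrom, int(start), strand))
        if not hits:
            status[tag] = "unmapped"
            continue
        best = min(h[0] for h in hits)
        stratum = [h for h in hits if h[0] == best]
        if len(stratum) > 1:
            status[tag] = "multi"
            continue
        mm, chrom, start, strand = stratum[0]
        alignments[tag] = GenomeAlignment(
            tag=tag, chrom=chrom, start=start, end=start + L, strand=strand, mismatches=mm
        )
        status[tag] = "unique"
    return alignments, status


def exclude_ncrna(
    alignments: dict,
    intervals,
    *,
    min_overlap_frac: float = 0.9,
    strand_aware: bool = True,
) -> tuple[dict, dict]:
    """Categorize tags overlapping annotated ncRNA loci; return survivors.

    `intervals` holds (chrom, start, end, name, rna_class, strand) rows.  A
    tag is assigned the class of any interval covering >= 90% of the tag's
    length (same strand when `strand_aware`); ties across classes resolve by
    :data:`NCRNA_PRECEDENCE`.  Returns ``(categorized, survivors)`` as
    {tag: rna_class} and {tag: GenomeAlignment}.
    """
    by_key: dict[tuple, list] = {}
    for chrom, start, end, _name, rna_class, strand in intervals:
        by_key.setdefault((chrom, strand), []).append((start, end, rna_class))
    rank = {c: i for i, c in enumerate(NCRNA_PRECEDENCE)}
    categorized: dict[str, str] = {}
    survivors: dict[str, "GenomeAlignment"] = {}
    for tag, aln in alignments.items():
        L = aln.end - aln.start
        hits = []
        keys = [(aln.chrom, aln.strand)] if strand_aware else [
            (aln.chrom, "+"), (aln.chrom, "-")
        ]
        for key in keys:
            for start, end, rna_class in by_key.get(key, ()):
                ov = min(aln.end, end) - max(aln.start, start)
                if ov / L >= min_overlap_frac:
                    hits.append(rna_class)
        if hits:
            categorized[tag] = min(hits, key=lambda c: rank.get(c, len(rank)))
        else:
            survivors[tag] = aln
    return categorized, survivors


def match_known(
    tags, matures: dict, max_mismatch: int = 2, max_len_diff: int = 2
) -> tuple[dict, list]:
    """Ungapped best-offset match of tags against the mature reference.

    Each tag is compared with every mature of compatible length (difference
    <= `max_len_diff`); the shorter sequence slides over the longer and the
    minimum-mismatch offset is used.  Assignment goes to the minimum-mismatch
    mature with <= `max_mismatch`; ties break lexicographically by mature id.
    Returns ``({tag: KnownAssignment}, [unmatched tags])``.
    """
    mature_arrs = {mid: encode(seq.upper().replace("U", "T")) for mid, seq in matures.items()}
    assigned: dict[str, KnownAssignment] = {}
    unmatched: list[str] = []
    for tag in tags:
        tarr = encode(tag.upper().replace("U", "T"))
        best: tuple[int, str] | None = None
        for mid in sorted(mature_arrs):
            marr = mature_arrs[mid]
            if abs(len(marr) - len(tarr)) > max_len_diff:
                continue
            short, long_ = (tarr, marr) if len(tarr) <= len(marr) else (marr, tarr)
            mm_min = None
            for off in range(len(long_) - len(short) + 1):
                mm = int((long_[off : off + len(short)] != short).sum())
                if mm_min is None or mm < mm_min:
                    mm_min = mm
            if mm_min is not None and mm_min <= max_mismatch:
                cand = (mm_min, mid)
                if best is None or cand < best:
                    best = cand
        if best is None:
            unmatched.append(tag)
        else:
            assigned[tag] = KnownAssignment(tag=tag, mature_id=best[1], mismatches=best[0])
    return assigned, unmatched


def assign_family_and_conservation(
    assignments: dict, family_table: pd.DataFrame, species_table: pd.DataFrame
) -> pd.DataFrame:
    """Family membership and species-occurrence counts for known miRNAs.

    Returns a DataFrame indexed by family with columns `members` (matched
    mature ids in the family) and `n_species` (count of species carrying the
    family; an empty occurrence row means the family is specific to the own
    species and counts 1).  Matures missing from the family table are grouped
    under "no known family" with a warning.
    """
    import warnings

    fam_of = dict(zip(family_table["mature_id"], family_table["family"]))
    rows: dict[str, set] = {}
    for a in assignments.values():
        fam = fam_of.get(a.mature_id)
        if fam is None:
            warnings.warn(f"mature {a.mature_id} missing from family table")
            fam = "no known family"
        rows.setdefault(fam, set()).add(a.mature_id)
    data = []
    for fam in sorted(rows):
        if fam in species_table.index:
            n_species = max(int(species_table.loc[fam].sum()), 1)
        else:
            n_species = 1
        data.append((fam, len(rows[fam]), n_species))
    return pd.DataFrame(data, columns=["family", "members", "n_species"]).set_index("family")
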