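"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

#: integer encoding used throughout: A=0, C=1, G=2, T/U=3, other=4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
_ENCODE[ord("U")] = 3


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (T alphabet)."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(RNA_COMPLEMENT)[::-1]


def transcribe(seq: str) -> str:
    """DNA (T alphabet) to RNA (U alphabet)."""
    return seq.replace("T", "U").replace("t", "u")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T/U=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gc_percent(seq: str) -> float:
    """G+C content as a percentage of sequence length."""
    if not seq:
        return 0.0
    gc = sum(1 for c in seq.upper() if c in "GC")
    return 100.0 * gc / len(seq)


def write_fasta(path, records) -> None:
    """Write (id, seq) pairs as FASTA with 70-column wrapping."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} dict (first token of header)."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out
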