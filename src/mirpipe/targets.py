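"""miRNA target prediction by complementarity penalty scoring.

Transcripts are scanned for sites reverse-complementary to the mature: at
each offset the aligned duplex is scored with the plant-miRNA convention —
mismatch penalty 1, G:U wobble 0.5, both doubled at mature positions 2-13
(5' seed-proximal region) — and sites with penalty <= `max_penalty` (default
4.0) and at most `max_mismatches` (default 3) true mismatches are reported.
A miRNA with no qualifying site still reports its single best (lowest
penalty) site, flagged `is_best_match`, so every miRNA has a putative target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .util import encode

# penalty lookup: rows mature base, cols transcript base (A,C,G,T/U)
# complementary (A:U, C:G, G:C, U:A) -> 0; G:U wobble (G with T, U with G) -> 0.5
_PENALTY = np.ones((5, 5))
for _m, _t in ((0, 3), (1, 2), (2, 1), (3, 0)):
    _PENALTY[_m, _t] = 0.0
_PENALTY[2, 3] = 0.5  # mature G : transcript U
_PENALTY[3, 2] = 0.5  # mature U : transcript G
_PENALTY[4, :] = 1.0
_PENALTY[:, 4] = 1.0

_IS_MISMATCH = (_PENALTY == 1.0)


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    site_start: int  # transcript coordinates, 0-based half-open
    site_end: int
    penalty_score: float
    mismatches: int
    gu_pairs: int
    is_best_match: bool = False


def _site_scores(mature: str, transcript: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Penalty, mismatch and G:U counts for every offset of one transcript."""
    m = encode(mature.upper().replace("U", "T"))
    t = encode(transcript.upper().replace("U", "T"))
    L = len(m)
    if len(t) < L:
        empty = np.empty(0)
        return empty, empty, empty
    windows = np.lib.stride_tricks.sliding_window_view(t, L)[:, ::-1]
    # mature position k (5'->3') pairs the site base at distance k from its 3' end
    pen = _PENALTY[m[None, :], windows]
    mism = _IS_MISMATCH[m[None, :], windows]
    weights = np.ones(L)
    weights[1:13] = 2.0  # mature positions 2-13 (1-based)
    scores = (pen * weights[None, :]).sum(axis=1)
    mismatches = mism.sum(axis=1)
    gu = (pen == 0.5).sum(axis=1)
    return scores, mismatches, gu


def predict_targets(
    mirna_id: str,
    mature_seq: str,
    transcripts: dict,
    *,
    max_penalty: float = 4.0,
    max_mismatches: int = 3,
    report_best_if_none: bool = True,
) -> list[TargetHit]:
    """Scan all transcripts for target sites of one mature miRNA.

    Returns qualifying hits sorted by (penalty, transcript, position); the
    miRNA's overall lowest-penalty site carries ``is_best_match=True``.  When
    no site qualifies and `report_best_if_none`, that single best site is
    returned on its own (the "best match as putative target" rule).
    """
    if len(mature_seq) < 18:
        raise ValueError("mature sequence shorter than 18 nt")
    hits: list[TargetHit] = []
    best: TargetHit | None = None
    L = len(mature_seq)
    for tid in sorted(transcripts):
        scores, mismatches, gu = _site_scores(mature_seq, transcripts[tid])
        if scores.size == 0:
            continue
        qualify = np.nonzero((scores <= max_penalty) & (mismatches <= max_mismatches))[0]
        for off in qualify:
            hits.append(
                TargetHit(
                    mirna_id=mirna_id,
                    transcript_id=tid,
                    site_start=int(off),
                    site_end=int(off) + L,
                    penalty_score=float(scores[off]),
                    mismatches=int(mismatches[off]),
                    gu_pairs=int(gu[off]),
                )
            )
        off = int(scores.argmin())
        cand = TargetHit(
            mirna_id=mirna_id,
            transcript_id=tid,
            site_start=off,
            site_end=off + L,
            penalty_score=float(scores[off]),
            mismatches=int(mismatches[off]),
            gu_pairs=int(gu[off]),
        )
        if best is None or cand.penalty_score < best.penalty_score:
            best = cand
    hits.sort(key=lambda h: (h.penalty_score, h.transcript_id, h.site_start))
    if hits:
        for h in hits:
            if (
                h.penalty_score == best.penalty_score
                and h.transcript_id == best.transcript_id
                and h.site_start == best.site_start
            ):
                h.is_best_match = True
        return hits
    if report_best_if_none and best is not None:
        best.is_best_match = True
        return [best]
    return []
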