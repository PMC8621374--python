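"""Six-criterion miRNA calling with per-library TPM.

A candidate mature (a known-matched tag group or a novel tag with a valid
hairpin) becomes a called miRNA iff it passes all of:

1. abundance: TPM >= `min_tpm` (default 100) in at least one library, where
   TPM = count * 1e6 / total genome-mapped reads of that library;
2. length: 20 <= mature length <= 24 nt;
3. arm ratio: counts for both arms evaluable and the 5p/3p (or 3p/5p) count
   ratio above 0.9 — by default the literal reading, max(r, 1/r) > 0.9,
   which reduces to "both arms detected"; a strict mode tests min/max;
4. stability: precursor MFE below -37 kJ/mol;
5. index: MFEI above 0.85;
6. structure: a valid miRNA-like hairpin geometry.

Criteria 4-6 are waived for reference-matched (known) miRNAs by default:
those are accepted by identity to the mature reference, as annotation
pipelines do.  Every rejected candidate records its first failing criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CRITERIA = ("tpm", "length", "arm_ratio", "mfe", "mfei", "hairpin")


def tpm(count: float, total_mapped: float) -> float:
    """Transcripts per million: count * 1e6 / total genome-mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count * 1e6 / total_mapped


@dataclass
class MiRNACandidate:
    """Everything the six-criterion filter needs about one candidate."""

    mirna_id: str
    status: str  # "known" / "novel"
    mature_seq: str
    arm: str  # "5p" / "3p" / "?"
    counts: dict  # library -> replicate-averaged mature count
    counts_5p: dict  # library -> 5p-arm count (0 if undetected)
    counts_3p: dict
    precursor_id: str | None = None
    hairpin: object | None = None  # HairpinEvaluation of the best precursor
    family: str | None = None


@dataclass
class MiRNARecord:
    mirna_id: str
    status: str
    mature_seq: str
    length: int
    arm: str
    precursor_id: str | None
    family: str | None
    counts: dict
    tpm: dict
    criteria_flags: dict = field(default_factory=dict)


@dataclass
class RejectedCandidate:
    mirna_id: str
    status: str
    failed_criterion: str
    criteria_flags: dict


def evaluate_criteria(
    cand: MiRNACandidate,
    totals: dict,
    *,
    min_tpm: float = 100.0,
    min_len: int = 20,
    max_len: int = 24,
    arm_ratio_min: float = 0.9,
    strict_arm_ratio: bool = False,
    mfe_kj_max: float = -37.0,
    mfei_min: float = 0.85,
    waive_structure_for_known: bool = True,
) -> tuple[dict, dict]:
    """Per-criterion pass/fail flags and TPM values for one candidate.

    Threshold senses follow the printed rules exactly: TPM >= 100 passes,
    MFE(kJ/mol) must be strictly below -37, MFEI strictly above 0.85, arm
    ratio strictly above 0.9.
    """
    tpms = {lib: tpm(c, totals[lib]) for lib, c in cand.counts.items()}
    flags: dict[str, bool] = {}
    flags["tpm"] = any(v >= min_tpm for v in tpms.values())
    flags["length"] = min_len <= len(cand.mature_seq) <= max_len
    c5 = sum(cand.counts_5p.values())
    c3 = sum(cand.counts_3p.values())
    if c5 > 0 and c3 > 0:
        r = c5 / c3
        ratio = min(r, 1 / r) if strict_arm_ratio else max(r, 1 / r)
        flags["arm_ratio"] = ratio > arm_ratio_min
    else:
        flags["arm_ratio"] = False
    hp = cand.hairpin
    waived = cand.status == "known" and waive_structure_for_known
    if waived:
        flags["mfe"] = flags["mfei"] = flags["hairpin"] = True
    elif hp is None:
        flags["mfe"] = flags["mfei"] = flags["hairpin"] = False
    else:
        flags["mfe"] = hp.mfe_kj < mfe_kj_max
        flags["mfei"] = hp.mfei > mfei_min
        flags["hairpin"] = bool(hp.valid_hairpin)
    return flags, tpms


def call_mirnas(candidates, totals: dict, **thresholds) -> tuple[list, list]:
    """Apply the six-criterion filter to candidates.

    `totals` maps library -> total genome-mapped reads (the TPM denominator).
    Returns ``(records, rejected)``; each record carries all six flags
    (all pass), each rejection its first failing criterion in filter order.
    """
    records: list[MiRNARecord] = []
    rejected: list[RejectedCandidate] = []
    for cand in candidates:
        flags, tpms = evaluate_criteria(cand, totals, **thresholds)
        if all(flags.values()):
            records.append(
                MiRNARecord(
                    mirna_id=cand.mirna_id,
                    status=cand.status,
                    mature_seq=cand.mature_seq,
                    length=len(cand.mature_seq),
                    arm=cand.arm,
                    precursor_id=cand.precursor_id,
                    family=cand.family,
                    counts=dict(cand.counts),
                    tpm={k: round(v, 4) for k, v in tpms.items()},
                    criteria_flags=flags,
                )
            )
        else:
            first_fail = next(c for c in CRITERIA if not flags[c])
            rejected.append(
                RejectedCandidate(
                    mirna_id=cand.mirna_id,
                    status=cand.status,
                    failed_criterion=first_fail,
                    criteria_flags=flags,
                )
            )
    return records, rejected
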