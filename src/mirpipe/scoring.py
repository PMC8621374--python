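"""Scoring pipeline output against the simulator's planted ground truth."""

from __future__ import annotations

import pandas as pd

from .simulate import GENOTYPES, GroundTruth


def recovery_rate(mirna_table: pd.DataFrame, truth: GroundTruth) -> tuple[float, dict]:
    """Fraction of planted miRNAs recovered as called miRNAs.

    A planted miRNA counts as recovered when any called record's mature
    sequence matches one of its arms (T alphabet, exact).  Returns
    ``(fraction, {mirna_id: recovered})``.
    """
    called = set(mirna_table["mature_seq"].str.upper().str.replace("U", "T"))
    hits = {}
    for mid, m in truth.mirnas.items():
        hits[mid] = m.mature_5p.upper() in called or m.mature_3p.upper() in called
    frac = sum(hits.values()) / len(hits) if hits else 0.0
    return frac, hits


def de_class_accuracy(
    mirna_table: pd.DataFrame,
    de_tables: dict,
    truth: GroundTruth,
    *,
    lfc_filter=None,
) -> tuple[float, pd.DataFrame]:
    """Agreement between called DE classes and the intended classes.

    Each (planted miRNA, genotype) pair whose intended |log2fc| satisfies
    `lfc_filter` (a predicate on |lfc|; default: all) is scored if the miRNA
    was recovered: the called class of its mature record must equal the class
    implied by the intended fold change.  Returns (accuracy, detail table).
    """
    seq_to_record = {}
    for _, row in mirna_table.iterrows():
        seq_to_record.setdefault(row["mature_seq"].upper().replace("U", "T"), row["mirna_id"])
    rows = []
    for mid, m in truth.mirnas.items():
        rec_id = seq_to_record.get(m.mature_5p.upper()) or seq_to_record.get(
            m.mature_3p.upper()
        )
        for g in GENOTYPES:
            lfc = m.lfc[g]
            if lfc_filter is not None and not lfc_filter(abs(lfc)):
                continue
            intended = m.intended_class(g)
            if rec_id is None or rec_id not in de_tables[g].index:
                rows.append((mid, g, lfc, intended, None, False))
                continue
            called = de_tables[g].loc[rec_id, "de_class"]
            rows.append((mid, g, lfc, intended, called, called == intended))
    detail = pd.DataFrame(
        rows, columns=["mirna_id", "genotype", "lfc", "intended", "called", "correct"]
    )
    acc = detail["correct"].mean() if len(detail) else 0.0
    return float(acc), detail
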