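"""Per-genotype differential expression of miRNAs between NaCl and control.

Normalization is TPM; the effect size is log2((treated + c)/(control + c))
with a small pseudocount c; significance comes from an exact conditional
binomial test of the treated count against the combined count, with success
probability given by the ratio of library totals (the Poisson-conditional
construction that two-library count DE tests reduce to).  A miRNA is called
up-regulated iff log2fc >= 1 and p <= 0.01, down-regulated iff log2fc <= -1
and p <= 0.01, and unchanged otherwise (including log2fc = 0 exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

CLASSES = ("up", "unchanged", "down")


@dataclass
class ExpressionRecord:
    mirna_id: str
    genotype: str
    norm_control: float
    norm_treated: float
    log2fc: float
    p_value: float
    de_class: str


def log2_fold_change(treated_norm: float, control_norm: float, pseudocount: float = 0.01) -> float:
    """log2((treated + c) / (control + c)); both zero -> 0 by convention."""
    import math

    if treated_norm < 0 or control_norm < 0:
        raise ValueError("normalized values must be non-negative")
    if treated_norm == 0 and control_norm == 0:
        return 0.0
    return math.log2((treated_norm + pseudocount) / (control_norm + pseudocount))


def _round_half_even(x: float) -> int:
    return int(round(x))  # Python rounds half to even


def de_test(
    count_treated: float, count_control: float, n_treated: float, n_control: float
) -> float:
    """Two-sided exact conditional binomial p-value for a two-library count pair.

    Conditions on n = treated + control successes; under the null the treated
    count is Binomial(n, N_t / (N_t + N_c)).  Half-integer replicate-averaged
    counts are rounded half-to-even before testing.  Both counts zero -> 1.
    """
    if n_treated <= 0 or n_control <= 0:
        raise ValueError("library totals must be positive")
    x = _round_half_even(count_treated)
    n = x + _round_half_even(count_control)
    if n == 0:
        return 1.0
    p0 = n_treated / (n_treated + n_control)
    return float(stats.binomtest(x, n, p0).pvalue)


def classify(log2fc: float, p_value: float, *, lfc_min: float = 1.0, p_max: float = 0.01) -> str:
    """Expression class: DE calls need both the fold-change and the p gate."""
    if log2fc >= lfc_min and p_value <= p_max:
        return "up"
    if log2fc <= -lfc_min and p_value <= p_max:
        return "down"
    return "unchanged"


def genotype_de_table(
    counts: pd.DataFrame,
    *,
    genotype: str,
    control_lib: str,
    treated_lib: str,
    totals: dict,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """DE table for one genotype from a per-miRNA count DataFrame.

    `counts` is indexed by miRNA id with one column per library (replicate-
    averaged counts); `totals` holds per-library genome-mapped totals used
    both for TPM normalization and as exact-test margins.
    """
    from .discovery import tpm

    rows = []
    for mid, row in counts.iterrows():
        c_ctl, c_trt = float(row[control_lib]), float(row[treated_lib])
        norm_ctl = tpm(c_ctl, totals[control_lib])
        norm_trt = tpm(c_trt, totals[treated_lib])
        lfc = log2_fold_change(norm_trt, norm_ctl, pseudocount)
        p = de_test(c_trt, c_ctl, totals[treated_lib], totals[control_lib])
        rows.append((mid, genotype, norm_ctl, norm_trt, lfc, p, classify(lfc, p)))
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "genotype",
            "norm_control",
            "norm_treated",
            "log2fc",
            "p_value",
            "de_class",
        ],
    ).set_index("mirna_id")


def overlap_sets(records_a: pd.DataFrame, records_b: pd.DataFrame) -> dict:
    """Cross-genotype 3x3 contingency of DE classes plus per-class Venn counts.

    Both tables must carry a `de_class` column indexed by miRNA id; universes
    are restricted to the intersection with a warning when they differ.
    """
    import warnings

    shared = records_a.index.intersection(records_b.index)
    if len(shared) != len(records_a) or len(shared) != len(records_b):
        warnings.warn("miRNA universes differ; restricting to intersection")
    a = records_a.loc[shared, "de_class"]
    b = records_b.loc[shared, "de_class"]
    table = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for ca, cb in zip(a, b):
        table.loc[ca, cb] += 1
    venn = {}
    for cls in CLASSES:
        in_a = set(a[a == cls].index)
        in_b = set(b[b == cls].index)
        venn[cls] = {
            "both": len(in_a & in_b),
            "a_only": len(in_a - in_b),
            "b_only": len(in_b - in_a),
        }
    return {"contingency": table, "venn": venn, "n": len(shared)}
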