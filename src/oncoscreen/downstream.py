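"""Downstream formula helpers: comparative-Ct qPCR, DEG filtering, tumor burden.

Small, exactly defined arithmetic used after the screens: relative gene
expression by the comparative-Ct (2^-ddCt) method normalized to a
reference gene, threshold filtering of an externally produced
differential-expression table, and caliper-based tumor-volume and
percent-reduction computations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def ddct_fold_change(
    target_ct_treated: float,
    ref_ct_treated: float,
    target_ct_control: float,
    ref_ct_control: float,
) -> float:
    """Relative expression by the comparative-Ct method.

    dCt = Ct(target) - Ct(reference) within each condition;
    ddCt = dCt(treated) - dCt(control); returns 2^(-ddCt).
    """
    cts = (target_ct_treated, ref_ct_treated, target_ct_control, ref_ct_control)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    dct_treated = target_ct_treated - ref_ct_treated
    dct_control = target_ct_control - ref_ct_control
    return float(2.0 ** (-(dct_treated - dct_control)))


def ddct_table(
    ct_table: pd.DataFrame,
    reference_gene: str = "GAPDH",
    control_condition: str = "control",
    treated_condition: str = "treated",
) -> pd.DataFrame:
    """Per-gene 2^-ddCt fold changes from a long Ct table.

    Expects columns (sample, gene, ct, condition); replicate Ct values
    are averaged per (gene, condition) before forming dCt.
    """
    for col in ("gene", "ct", "condition"):
        if col not in ct_table.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    ct = ct_table.copy()
    ct["ct"] = ct["ct"].astype(float)
    if ((ct["ct"] < 10) | (ct["ct"] > 40)).any():
        warnings.warn("Ct values outside the typical 10-40 cycle range", stacklevel=2)
    means = ct.groupby(["gene", "condition"])["ct"].mean().unstack("condition")
    for cond in (control_condition, treated_condition):
        if cond not in means.columns:
            raise ValueError(f"condition {cond!r} absent from Ct table")
    if reference_gene not in means.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    rows = []
    for gene in means.index:
        if gene == reference_gene:
            continue
        rows.append(
            {
                "gene": gene,
                "fold_change": ddct_fold_change(
                    means.loc[gene, treated_condition],
                    means.loc[reference_gene, treated_condition],
                    means.loc[gene, control_condition],
                    means.loc[reference_gene, control_condition],
                ),
            }
        )
    return pd.DataFrame(rows)


def deg_filter(
    records: pd.DataFrame, lfc_cutoff: float = 1.0, padj_cutoff: float = 0.05
) -> pd.DataFrame:
    """Differentially expressed genes: |log2FC| >= cutoff AND padj <= cutoff (both inclusive)."""
    for col in ("log2fc", "padj"):
        if col not in records.columns:
            raise ValueError(f"DE table missing column {col!r}")
    padj = records["padj"].astype(float)
    if ((padj < 0) | (padj > 1)).any():
        raise ValueError("adjusted p-values must lie in [0, 1]")
    mask = (records["log2fc"].astype(float).abs() >= lfc_cutoff) & (padj <= padj_cutoff)
    return records[mask].copy()


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume (length x width^2) / 2, in mm^3.

    Length is the longer axis by convention; swapped arguments are
    corrected with a warning so the result is order-invariant.
    """
    length = float(length)
    width = float(width)
    if length <= 0 or width <= 0:
        raise ValueError("tumor dimensions must be positive")
    if width > length:
        warnings.warn("width > length; swapping to keep length the longer axis", stacklevel=2)
        length, width = width, length
    return length * width * width / 2.0


def percent_reduction(v_start: float, v_end: float) -> float:
    """Percent tumor-volume reduction relative to the treatment-start volume."""
    v_start = float(v_start)
    if v_start <= 0:
        raise ValueError("starting volume must be positive")
    return 100.0 * (v_start - float(v_end)) / v_start
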