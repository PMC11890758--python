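"""Screen-level orchestration: annotated plate tables in, result tables out.

Glues the per-module operations into the two screen workflows:

* :func:`analyze_bret_screen` — white/black plate tables + map ->
  per-replicate saturation fits, per-gene AUC/FOC scores, hit table;
* :func:`analyze_htip_screen` — paired-arm viability table + map ->
  per-compound percent-of-control, selectivity index, sensitizer table;
* :func:`analyze_dose_table` — (grouped) dose/response table -> 4PL fits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    DegenerateControlError,
    FormatError,
    InsufficientDataError,
    InsufficientReplicatesError,
    JoinError,
)
from .htip import (
    DEFAULT_SI_CUTOFF,
    compound_results_frame,
    fit_4pl,
    nominate_sensitizers,
    percent_of_control,
    selectivity_index,
)
from .plate_io import join_plate_map
from .saturation import (
    DEFAULT_FOC_CUTOFF,
    DEFAULT_P_CUTOFF,
    PPIScore,
    SaturationFit,
    call_hits,
    fit_saturation,
    saturation_auc,
    score_from_aucs,
    scores_to_frame,
)
from .simulate import BASELINE_CONSTRUCT, CTRL1_CONSTRUCT, CTRL2_CONSTRUCT


def analyze_bret_screen(
    white: pd.DataFrame,
    black: pd.DataFrame,
    plate_map: pd.DataFrame,
    *,
    foc_cutoff: float = DEFAULT_FOC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    geometry: int = 1536,
    donor: str = "bait",
    ctrl1_construct: str = CTRL1_CONSTRUCT,
    ctrl2_construct: str = CTRL2_CONSTRUCT,
    baseline_construct: str = BASELINE_CONSTRUCT,
) -> dict[str, pd.DataFrame]:
    """Score every candidate pair of a BRET saturation screen.

    The white table carries L460/F535, the black table Venus FI from the
    side-by-side plate; wells are paired by (well, construct, replicate).
    Net BRET subtracts the mean donor-only baseline ratio; each replicate
    titration series is fitted after the negative-value exclusion and
    integrated over a screen-wide common [0, x_max] window.

    Returns ``{"scores": ..., "hits": ..., "fits": ...}``.
    """
    aw = join_plate_map(white, plate_map, geometry)
    ab = join_plate_map(black, plate_map, geometry)

    base = aw[aw["construct_or_compound"] == baseline_construct]
    if len(base) == 0:
        raise FormatError(f"no donor-only baseline wells (construct {baseline_construct!r})")
    baseline_ratio = float((base["F535"] / base["L460"]).mean())

    pairs = aw[aw["construct_or_compound"] != baseline_construct]
    key = ["well", "construct_or_compound", "replicate"]
    merged = pairs.merge(
        ab[key + ["venus_fi"]], on=key, how="left", validate="one_to_one"
    )
    orphan = merged[merged["venus_fi"].isna()]
    if len(orphan):
        wells = list(orphan[["plate_id", "well"]].itertuples(index=False, name=None))
        raise JoinError(
            f"{len(wells)} white-plate well(s) lack a matching Venus FI well: {wells[:20]}",
            wells=wells,
        )
    merged = merged.copy()
    merged["x"] = merged["venus_fi"] / merged["L460"]
    merged["y"] = merged["F535"] / merged["L460"] - baseline_ratio
    merged["usable"] = (merged["x"] >= 0) & (merged["y"] >= 0)

    if not merged["usable"].any():
        raise InsufficientDataError("no usable titration points in the screen")

    # fit every replicate series once; AUCs are integrated later because the
    # common window is per comparison (gene + both controls), not screen-wide
    fit_rows = []
    fits: dict[str, list[SaturationFit]] = {}
    bounds: dict[str, list[float]] = {}  # per-replicate max usable x
    constructs = list(dict.fromkeys(merged["construct_or_compound"]))
    for construct in constructs:
        fits[construct] = []
        bounds[construct] = []
        sub = merged[merged["construct_or_compound"] == construct]
        for rep, curve in sub.groupby("replicate"):
            row = {"construct": construct, "replicate": int(rep)}
            try:
                fit = fit_saturation((curve["x"].to_numpy(), curve["y"].to_numpy()))
            except InsufficientDataError:
                row.update(
                    bret_max=np.nan, bret50=np.nan, n_points_used=0,
                    rss=np.nan, converged=False, max_usable_x=np.nan,
                )
                fit_rows.append(row)
                continue
            if fit.converged or fit.bret_max == 0.0:
                fits[construct].append(fit)
                bounds[construct].append(
                    float(curve.loc[curve["usable"], "x"].max())
                )
            row.update(
                bret_max=fit.bret_max, bret50=fit.bret50,
                n_points_used=fit.n_points_used, rss=fit.rss,
                converged=fit.converged,
                max_usable_x=float(curve.loc[curve["usable"], "x"].max()),
            )
            fit_rows.append(row)

    for name, construct in (("ctrl1", ctrl1_construct), ("ctrl2", ctrl2_construct)):
        if construct not in fits:
            raise FormatError(f"control series {name} (construct {construct!r}) absent from map")
        if len(fits[construct]) < 2:
            raise InsufficientReplicatesError(
                f"control series {name} has {len(fits[construct])} usable replicate fit(s)"
            )

    def aucs_at(construct, x_max):
        return [
            0.0 if f.bret_max == 0.0 else saturation_auc(f, x_max) for f in fits[construct]
        ]

    ctrl_bounds = bounds[ctrl1_construct] + bounds[ctrl2_construct]
    gene_order = list(
        dict.fromkeys(merged.loc[merged["role"] == "ppi", "construct_or_compound"])
    )
    scores = []
    for gene in gene_order:
        if len(fits[gene]) < 2:
            # exclusion rule consumed the series; score stays non-callable
            scores.append(
                PPIScore(
                    donor, gene, [], [], [], float("nan"),
                    float("nan"), float("nan"), False, callable=False,
                )
            )
            continue
        x_max = min(bounds[gene] + ctrl_bounds)
        scores.append(
            score_from_aucs(
                aucs_at(gene, x_max),
                aucs_at(ctrl1_construct, x_max),
                aucs_at(ctrl2_construct, x_max),
                donor=donor,
                acceptor=gene,
                x_max=x_max,
                foc_cutoff=foc_cutoff,
                p_cutoff=p_cutoff,
            )
        )
    scores_df = scores_to_frame(scores)
    return {
        "scores": scores_df,
        "hits": call_hits(scores_df) if len(scores_df) else scores_df,
        "fits": pd.DataFrame(fit_rows),
    }


def analyze_htip_screen(
    measurements: pd.DataFrame,
    plate_map: pd.DataFrame,
    *,
    si_cutoff: float = DEFAULT_SI_CUTOFF,
    geometry: int = 384,
) -> dict[str, pd.DataFrame]:
    """Score a paired-arm co-culture screen.

    Percent of control is computed per compound well against its own
    plate's DMSO blank and positive control means, averaged over
    replicates within each arm; the selectivity index is the ratio of
    arm means.  Returns ``{"results": ..., "sensitizers": ...}``.
    """
    ann = join_plate_map(measurements, plate_map, geometry)
    arms = set(ann["condition"])
    for arm in ("minus_pbmc", "plus_pbmc"):
        if arm not in arms:
            raise FormatError(f"screen is missing the {arm} arm")

    pc_rows = []
    for (arm, plate), sub in ann.groupby(["condition", "plate_id"], sort=False):
        blanks = sub.loc[sub["role"] == "blank", "viability_signal"]
        positives = sub.loc[sub["role"] == "positive", "viability_signal"]
        if len(blanks) == 0 or len(positives) == 0:
            raise FormatError(f"plate {plate!r} lacks blank or positive control wells")
        s_blank, s_positive = float(blanks.mean()), float(positives.mean())
        if s_positive == s_blank:
            raise DegenerateControlError(f"plate {plate!r}: S_positive equals S_blank")
        wells = sub[sub["role"] == "compound"]
        for _, w in wells.iterrows():
            pc_rows.append(
                {
                    "compound": w["construct_or_compound"],
                    "condition": arm,
                    "replicate": w["replicate"],
                    "percent_of_control": percent_of_control(
                        w["viability_signal"], s_blank, s_positive
                    ),
                }
            )
    pc = pd.DataFrame(pc_rows)
    arm_means = (
        pc.groupby(["compound", "condition"], sort=False)["percent_of_control"]
        .mean()
        .unstack("condition")
    )
    compounds = list(dict.fromkeys(pc["compound"]))
    results = pd.DataFrame(
        {
            "compound": compounds,
            "pc_minus": [float(arm_means.loc[c, "minus_pbmc"]) for c in compounds],
            "pc_plus": [float(arm_means.loc[c, "plus_pbmc"]) for c in compounds],
        }
    )
    results["selectivity"] = [
        selectivity_index(m, p) for m, p in zip(results["pc_minus"], results["pc_plus"])
    ]
    results = compound_results_frame(results)
    return {"results": results, "sensitizers": nominate_sensitizers(results, si_cutoff)}


def analyze_dose_table(table: pd.DataFrame, group_column: str | None = None) -> pd.DataFrame:
    """Fit 4PL curves to a dose/response table, optionally per group."""
    for col in ("dose", "response"):
        if col not in table.columns:
            raise FormatError(f"dose table missing column {col!r}")
    groups = (
        [(None, table)] if group_column is None else list(table.groupby(group_column, sort=False))
    )
    rows = []
    for name, sub in groups:
        fit = fit_4pl(sub["dose"].to_numpy(float), sub["response"].to_numpy(float))
        row = {} if name is None else {group_column: name}
        row.update(
            top=fit.top, bottom=fit.bottom, hill=fit.hill,
            ic50=fit.ic50, r2=fit.r2, converged=fit.converged,
        )
        rows.append(row)
    return pd.DataFrame(rows)
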