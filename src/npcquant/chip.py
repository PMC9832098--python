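"""Comparative-Ct quantification of ChIP-qPCR enrichment and luciferase ratios.

ChIP enrichment is quantified against a non-related antibody (NRA)
negative-control immunoprecipitation: each antibody's bound-fraction Ct
is first normalized to its own input (delta Ct), and the fold
enrichment of the specific IP over the NRA is ``e**(dCt_NRA - dCt_IP)``
with amplification efficiency ``e`` (2.0, perfect doubling, by
default).  A region is called positive only when the raw bound-fraction
Ct of the IP is below that of the NRA in at least two distinct
dilutions of the amplified material.

Dual-luciferase reporter activity is the ratio of firefly to Renilla
luminescence, optionally expressed relative to a reference ratio.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "delta_ct",
    "fold_enrichment",
    "positivity_call",
    "differential_enrichment",
    "luciferase_ratio",
    "luciferase_table",
    "quantify_enrichment",
]


def delta_ct(ct_bound: float, ct_input: float) -> float:
    """Input normalization: dCt = Ct(bound) - Ct(input) for one antibody."""
    if ct_bound is None or ct_input is None or np.isnan(ct_bound) or np.isnan(ct_input):
        raise ValueError("both bound and input Ct are required")
    return float(ct_bound) - float(ct_input)


def fold_enrichment(delta_ct_ip: float, delta_ct_nra: float,
                    efficiency: float = 2.0) -> float:
    """Comparative-Ct fold enrichment of the IP relative to the NRA control."""
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    return float(efficiency ** (delta_ct_nra - delta_ct_ip))


def positivity_call(records: pd.DataFrame) -> dict:
    """Dilution-series positivity rule for one region/condition.

    ``records`` holds bound-fraction rows with columns ``antibody``
    (IP/NRA), ``dilution`` and ``ct`` (replicates already averaged or
    not; they are averaged per dilution here).  The call is positive iff
    Ct(IP) < Ct(NRA), strictly, in at least two distinct dilutions.
    Fewer than two dilutions with both antibodies present yields status
    ``insufficient`` rather than a negative call.
    """
    bound = records[records.get("fraction", "bound") == "bound"] \
        if "fraction" in records.columns else records
    per = bound.groupby(["dilution", "antibody"])["ct"].mean().unstack("antibody")
    usable = per.dropna(subset=["IP", "NRA"]) if {"IP", "NRA"} <= set(per.columns) \
        else per.iloc[0:0]
    n_usable = int(len(usable))
    n_pos = int((usable["IP"] < usable["NRA"]).sum()) if n_usable else 0
    if n_usable < 2:
        return {"status": "insufficient", "positive": False,
                "n_dilutions": n_usable, "n_dilutions_ip_below_nra": n_pos}
    return {"status": "ok", "positive": n_pos >= 2,
            "n_dilutions": n_usable, "n_dilutions_ip_below_nra": n_pos}


def differential_enrichment(fold_diff: float, fold_pro: float) -> float:
    """Ratio of fold enrichments between conditions (e.g. DIFF over PRO)."""
    if fold_pro is None or not np.isfinite(fold_pro) or fold_pro == 0:
        log.warning("differential_enrichment: reference fold undefined or zero")
        return float("nan")
    return float(fold_diff) / float(fold_pro)


def luciferase_ratio(firefly: float, renilla: float,
                     reference_ratio: float | None = None) -> dict:
    """Firefly/Renilla activity, optionally relative to a reference ratio."""
    if renilla <= 0:
        raise ValueError("Renilla luminescence must be positive")
    activity = float(firefly) / float(renilla)
    out = {"activity": activity}
    if reference_ratio is not None:
        if reference_ratio <= 0:
            raise ValueError("reference ratio must be positive")
        out["relative_activity"] = activity / float(reference_ratio)
    return out


def luciferase_table(df: pd.DataFrame, reference_condition: str | None = None
                     ) -> pd.DataFrame:
    """Row-wise firefly/Renilla ratios for a (sample, firefly, renilla[, condition]) table.

    When ``reference_condition`` is given, activities are additionally
    expressed relative to the mean activity of that condition.
    """
    out = df.copy()
    if (out["renilla"] <= 0).any():
        raise ValueError("Renilla luminescence must be positive in every row")
    out["activity"] = out["firefly"] / out["renilla"]
    if reference_condition is not None:
        ref = out.loc[out["condition"] == reference_condition, "activity"].mean()
        if not np.isfinite(ref) or ref <= 0:
            raise ValueError("reference condition has no usable activity")
        out["relative_activity"] = out["activity"] / ref
    return out


def quantify_enrichment(ct_table: pd.DataFrame, efficiency: float = 2.0
                        ) -> pd.DataFrame:
    """Full comparative-Ct pipeline over a tidy Ct table.

    Expects columns ``region, condition, antibody (IP|NRA), fraction
    (bound|input), dilution, ct`` (an optional ``replicate`` column is
    averaged out).  Replicate Cts are averaged per well first, then per
    antibody dCt = mean Ct(bound) - mean Ct(input) across dilutions
    (dilution offsets are common to both fractions and cancel), and
    fold enrichment = efficiency**(dCt_NRA - dCt_IP).  The dilution
    positivity rule is evaluated on the raw bound-fraction Cts.

    Returns one row per (region, condition) with ``fold_enrichment_ip``,
    ``ip_over_nra_ratio`` (identical quantity, kept under the name used
    for reporting), ``positive_call`` and ``positivity_status``.
    """
    required = {"region", "condition", "antibody", "fraction", "dilution", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    rows = []
    for (region, condition), grp in ct_table.groupby(["region", "condition"]):
        means = grp.groupby(["antibody", "fraction"])["ct"].mean()
        for ab in ("IP", "NRA"):
            for fr in ("bound", "input"):
                if (ab, fr) not in means.index:
                    raise ValueError(
                        f"missing Ct record: region={region!r} condition={condition!r} "
                        f"antibody={ab} fraction={fr}")
        d_ip = delta_ct(means[("IP", "bound")], means[("IP", "input")])
        d_nra = delta_ct(means[("NRA", "bound")], means[("NRA", "input")])
        fold = fold_enrichment(d_ip, d_nra, efficiency=efficiency)
        call = positivity_call(grp[grp["fraction"] == "bound"])
        rows.append({"region": region, "condition": condition,
                     "fold_enrichment_ip": fold,
                     "ip_over_nra_ratio": fold,
                     "positive_call": bool(call["positive"]),
                     "positivity_status": call["status"]})
    return pd.DataFrame(rows)
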