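"""Quantification of the heterologous odorant plate screen.

Wells carry raw reporter fluorescence (arbitrary units, SEAP/CRE readout).
For each receptor x odorant x concentration cell the response is the double
background subtraction

    R = (F_or+odorant - F_empty+odorant) - (F_or_basal - F_empty_basal)

with the four F terms taken as means over replicate wells.  A cell is a hit
when R strictly exceeds the fixed threshold (default 3e5 AU); the potency
class of a receptor-odorant pair is set by the lowest tested concentration
that is a hit (10 uM = high, 100 uM = mid, 1000 uM = low).  Plates whose
GFP transfection control falls below 70% are excluded before any response
is computed.  Rho-tagged and untagged constructs of the same receptor are
always distinct conditions and are never pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

HIT_THRESHOLD_AU = 3e5
QC_MIN_TRANSFECTION = 0.70
SCREEN_CONCENTRATIONS_UM = (10.0, 100.0, 1000.0)
POTENCY_BY_CONC = {10.0: "high", 100.0: "mid", 1000.0: "low"}

#: columns of the tab-separated well-level plate format
WELL_COLUMNS = [
    "plate_id",
    "well",
    "construct",  # 'or' | 'empty_vector' | 'gfp_control'
    "or_name",
    "rho_tagged",
    "odorant",
    "concentration_uM",
    "replicate",
    "fluorescence_AU",
    "gfp_fraction",  # filled on gfp_control wells only
]


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    gfp_transfection_fraction: float
    passed: bool


@dataclass(frozen=True)
class HitCall:
    or_name: str
    rho_tagged: bool
    odorant: str
    is_hit: Mapping[float, bool]  # concentration -> hit flag (evaluated cells only)
    lowest_effective_concentration_uM: Optional[float]
    potency_class: str  # 'high' | 'mid' | 'low' | 'none'


@dataclass
class ScreenSummary:
    n_odorants_responding: int
    n_odorants_hit_at_10uM: int
    n_ors_hit_at_10uM: int
    n_ors_responding: int
    tuning_breadth: dict  # (or_name, rho_tagged) -> number of odorants hit


def compute_response(
    f_or_odorant: float,
    f_empty_odorant: float,
    f_or_basal: float,
    f_empty_basal: float,
) -> float:
    """Background-double-subtracted response; negatives are preserved."""
    for v in (f_or_odorant, f_empty_odorant, f_or_basal, f_empty_basal):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError("all four fluorescence terms are required")
    return (f_or_odorant - f_empty_odorant) - (f_or_basal - f_empty_basal)


def call_hit(r_au: float, threshold: float = HIT_THRESHOLD_AU) -> bool:
    """Strict inequality: a response exactly at the threshold is not a hit."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return r_au > threshold


def aggregate_replicates(values: Sequence[float]) -> tuple[float, Optional[float], int]:
    """(mean, sem, n); sem is None for a single replicate."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no replicate values")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size >= 2 else None
    return mean, sem, int(v.size)


def normalize_profile(values: Mapping) -> dict:
    """Scale to percent of the maximum response across the set.

    Refused when no value is positive (there is no maximum response to
    normalize to).  Negative responses stay negative.
    """
    vals = dict(values)
    if not vals:
        raise ValueError("empty response set")
    mx = max(vals.values())
    if mx <= 0:
        raise ValueError("normalization refused: no positive response in the set")
    return {k: 100.0 * v / mx for k, v in vals.items()}


def lowest_effective_concentration(
    hits: Mapping[float, bool]
) -> tuple[Optional[float], str]:
    """Minimum tested concentration with a hit, mapped to its potency class."""
    if not hits:
        raise ValueError("no evaluated concentrations")
    effective = sorted(c for c, h in hits.items() if h)
    if not effective:
        return None, "none"
    lec = effective[0]
    return lec, POTENCY_BY_CONC.get(lec, "low")


def qc_plate(plate_id: str, gfp_fraction: float, minimum: float = QC_MIN_TRANSFECTION) -> PlateQC:
    if not (0.0 <= gfp_fraction <= 1.0):
        raise ValueError(f"gfp fraction {gfp_fraction} outside [0, 1]")
    return PlateQC(plate_id, gfp_fraction, gfp_fraction >= minimum)


# ---------------------------------------------------------------------------
# dataset-level pipeline


def read_plate_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(WELL_COLUMNS[:9]) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    if "gfp_fraction" not in df.columns:
        df["gfp_fraction"] = np.nan
    return df


def plate_qc_table(wells: pd.DataFrame, minimum: float = QC_MIN_TRANSFECTION) -> list[PlateQC]:
    out = []
    for plate_id, grp in wells.groupby("plate_id", sort=True):
        gfp = grp.loc[grp["construct"] == "gfp_control", "gfp_fraction"].dropna()
        frac = float(gfp.mean()) if len(gfp) else 1.0  # no control wells: pass
        out.append(qc_plate(str(plate_id), frac, minimum))
    return out


def response_table(
    wells: pd.DataFrame,
    qc_minimum: float = QC_MIN_TRANSFECTION,
) -> tuple[pd.DataFrame, list[PlateQC]]:
    """Per (OR, tag, odorant, concentration) responses from well-level data.

    The four F terms of the response formula are condition means over
    replicate wells; basal and empty-vector terms are taken from the same
    plate as the odorant wells.  A cell missing any term is kept in the
    table with ``evaluable=False`` and an NA response, never a silent zero.
    The s.e.m. is computed over replicate-paired responses when all four
    conditions share the same replicate count.
    """
    qc = plate_qc_table(wells, qc_minimum)
    failed = {q.plate_id for q in qc if not q.passed}
    w = wells[~wells["plate_id"].astype(str).isin(failed)].copy()
    w["rho_tagged"] = w["rho_tagged"].astype(bool)

    ors = w[(w["construct"] == "or") & (w["concentration_uM"] > 0)]
    cell_keys = ["plate_id", "or_name", "rho_tagged", "odorant", "concentration_uM"]
    f_or_od = (
        ors.groupby(cell_keys)["fluorescence_AU"].agg(["mean", "size"]).reset_index()
        .rename(columns={"mean": "f_or_od", "size": "n_replicates"})
    )
    f_or_basal = (
        w[(w["construct"] == "or") & (w["concentration_uM"] == 0)]
        .groupby(["plate_id", "or_name", "rho_tagged"])["fluorescence_AU"].mean()
        .rename("f_or_basal").reset_index()
    )
    f_empty_od = (
        w[(w["construct"] == "empty_vector") & (w["concentration_uM"] > 0)]
        .groupby(["plate_id", "odorant", "concentration_uM"])["fluorescence_AU"].mean()
        .rename("f_empty_od").reset_index()
    )
    f_empty_basal = (
        w[(w["construct"] == "empty_vector") & (w["concentration_uM"] == 0)]
        .groupby(["plate_id"])["fluorescence_AU"].mean()
        .rename("f_empty_basal").reset_index()
    )
    out = (
        f_or_od.merge(f_or_basal, on=["plate_id", "or_name", "rho_tagged"], how="left")
        .merge(f_empty_od, on=["plate_id", "odorant", "concentration_uM"], how="left")
        .merge(f_empty_basal, on=["plate_id"], how="left")
    )
    terms = out[["f_or_od", "f_empty_od", "f_or_basal", "f_empty_basal"]]
    out["evaluable"] = terms.notna().all(axis=1)
    # the response formula, applied to the condition means
    out["R_AU"] = np.where(
        out["evaluable"],
        (out["f_or_od"] - out["f_empty_od"]) - (out["f_or_basal"] - out["f_empty_basal"]),
        np.nan,
    )
    out.loc[~out["evaluable"], "n_replicates"] = 0

    # s.e.m. over replicate-paired responses where every condition has the
    # same replicate structure
    rep_keys = cell_keys + ["replicate"]
    rep = ors[rep_keys + ["fluorescence_AU"]].rename(columns={"fluorescence_AU": "r_or_od"})
    rep = rep.merge(
        w[(w["construct"] == "or") & (w["concentration_uM"] == 0)][
            ["plate_id", "or_name", "rho_tagged", "replicate", "fluorescence_AU"]
        ].rename(columns={"fluorescence_AU": "r_or_basal"}),
        on=["plate_id", "or_name", "rho_tagged", "replicate"],
        how="left",
    ).merge(
        w[(w["construct"] == "empty_vector") & (w["concentration_uM"] > 0)][
            ["plate_id", "odorant", "concentration_uM", "replicate", "fluorescence_AU"]
        ].rename(columns={"fluorescence_AU": "r_empty_od"}),
        on=["plate_id", "odorant", "concentration_uM", "replicate"],
        how="left",
    ).merge(
        w[(w["construct"] == "empty_vector") & (w["concentration_uM"] == 0)][
            ["plate_id", "replicate", "fluorescence_AU"]
        ].rename(columns={"fluorescence_AU": "r_empty_basal"}),
        on=["plate_id", "replicate"],
        how="left",
    )
    rep["r"] = (rep["r_or_od"] - rep["r_empty_od"]) - (
        rep["r_or_basal"] - rep["r_empty_basal"]
    )
    sem = (
        rep.groupby(cell_keys)["r"]
        .agg(lambda v: v.std(ddof=1) / np.sqrt(v.notna().sum()) if v.notna().sum() >= 2 else np.nan)
        .rename("sem_AU")
        .reset_index()
    )
    out = out.merge(sem, on=cell_keys, how="left")
    cols = cell_keys + ["R_AU", "sem_AU", "n_replicates", "evaluable"]
    return out[cols].sort_values(cell_keys, ignore_index=True), qc


def hit_calls(
    responses: pd.DataFrame, threshold: float = HIT_THRESHOLD_AU
) -> list[HitCall]:
    """Hit/potency calls per (OR, tag, odorant) from a response table."""
    out = []
    evaluable = responses[responses["evaluable"]]
    for (or_name, tagged, odorant), grp in evaluable.groupby(
        ["or_name", "rho_tagged", "odorant"], sort=True
    ):
        flags = {
            float(row.concentration_uM): call_hit(row.R_AU, threshold)
            for row in grp.itertuples()
        }
        lec, potency = lowest_effective_concentration(flags)
        out.append(HitCall(or_name, bool(tagged), odorant, flags, lec, potency))
    return out


def potency_matrix(calls: Iterable[HitCall]) -> pd.DataFrame:
    """Rows = (OR, tag state), columns = odorants, values = potency class."""
    calls = list(calls)
    rows = sorted({(c.or_name, c.rho_tagged) for c in calls})
    odorants = sorted({c.odorant for c in calls})
    mat = pd.DataFrame("none", index=pd.MultiIndex.from_tuples(rows, names=["or_name", "rho_tagged"]), columns=odorants)
    for c in calls:
        mat.loc[(c.or_name, c.rho_tagged), c.odorant] = c.potency_class
    return mat


def summarize_screen(calls: Iterable[HitCall]) -> ScreenSummary:
    """Screen-level counts: responding odorants, 10-uM responders, tuning breadth.

    A receptor counts as responding if either tag state responds; tuning
    breadth is reported per (receptor, tag state) and never pooled.
    """
    calls = list(calls)
    od_resp, od_10 = set(), set()
    or_resp, or_10 = set(), set()
    breadth: dict = {}
    for c in calls:
        breadth.setdefault((c.or_name, c.rho_tagged), 0)
        if c.potency_class != "none":
            od_resp.add(c.odorant)
            or_resp.add(c.or_name)
            breadth[(c.or_name, c.rho_tagged)] += 1
        if c.is_hit.get(10.0, False):
            od_10.add(c.odorant)
            or_10.add(c.or_name)
    return ScreenSummary(
        n_odorants_responding=len(od_resp),
        n_odorants_hit_at_10uM=len(od_10),
        n_ors_hit_at_10uM=len(or_10),
        n_ors_responding=len(or_resp),
        tuning_breadth=breadth,
    )


def normalize_dose_response(
    responses: pd.DataFrame,
    or_names: Sequence[str],
    odorant: str,
    rho_tagged: Optional[bool] = None,
) -> pd.DataFrame:
    """Percent-of-maximum dose-response profile for a set of receptors."""
    sel = responses[
        responses["evaluable"]
        & responses["or_name"].isin(or_names)
        & (responses["odorant"] == odorant)
    ]
    if rho_tagged is not None:
        sel = sel[sel["rho_tagged"] == rho_tagged]
    if sel.empty:
        raise ValueError(f"no evaluable responses for odorant {odorant!r}")
    keyed = {
        (r.or_name, r.rho_tagged, r.concentration_uM): r.R_AU
        for r in sel.itertuples()
    }
    normed = normalize_profile(keyed)
    out = sel.copy()
    out["pct_of_max"] = [
        normed[(r.or_name, r.rho_tagged, r.concentration_uM)] for r in sel.itertuples()
    ]
    return out[["or_name", "rho_tagged", "odorant", "concentration_uM", "R_AU", "pct_of_max"]]
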