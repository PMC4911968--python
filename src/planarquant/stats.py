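"""Cohort evaluation statistics and report assembly.

Summarises per-subject quantification rows into two tables: per background
ROI, the mean background-to-true-background ratio (BTR) with its CV and the
negative-net-count fractions for both planar methods; and per ROI and
method, the mean relative activity concentration against the volumetric
reference, restricted to ROIs whose negative-count fraction is at most the
inclusion threshold (10% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Columns expected in the per-subject quantification rows.
ROW_COLUMNS = [
    "subject",
    "side",
    "bg_label",
    "btr",
    "a_net",
    "p_net",
    "conjv_negative",
    "postv_negative",
    "ac_conjv",
    "ac_postv",
    "ac_spect",
]

TABLE1_COLUMNS = ["roi", "side", "mean_btr", "cv_pct", "cnc_pct", "pnc_pct"]
FIG4_COLUMNS = [
    "roi",
    "side",
    "method",
    "mean_rel_ac",
    "cv_pct",
    "n",
    "p_value",
    "significant",
]


@dataclass(frozen=True)
class StudyReport:
    table1: pd.DataFrame
    fig4: pd.DataFrame
    inclusion_threshold_pct: float = 10.0


def btr(bg_conc: float, tb_conc: float) -> float:
    """Background-to-true-background concentration ratio."""
    if tb_conc <= 0:
        raise ValueError("true-background concentration must be > 0")
    return bg_conc / tb_conc


def coefficient_of_variation(values) -> float:
    """Sample CV in percent: 100 * sd(n-1) / mean."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def negative_fraction(flags) -> float:
    """Percentage of true flags."""
    f = np.asarray(flags, dtype=bool)
    if f.size == 0:
        raise ValueError("negative_fraction needs at least one flag")
    return float(100.0 * f.sum() / f.size)


def relative_ac(method_ac: float, spect_ac: float) -> float:
    """Planar estimate relative to the volumetric reference."""
    if spect_ac <= 0:
        raise ValueError("reference concentration must be > 0")
    return method_ac / spect_ac


def paired_t_test(a, b) -> float:
    """Two-sided paired t-test p-value.

    t = mean(d) / (sd(d) / sqrt(n)) with d = a - b, Student t with n - 1
    degrees of freedom.  All-zero differences return p = 1 by convention.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        return 1.0 if np.allclose(d, 0) else 0.0
    t = d.mean() / (sd / np.sqrt(n))
    return float(2.0 * sps.t.sf(abs(t), df=n - 1))


def build_study_report(
    rows: pd.DataFrame,
    inclusion_threshold_pct: float = 10.0,
    alpha: float = 0.05,
) -> StudyReport:
    """Aggregate per-subject rows into the two cohort summary tables.

    Per (ROI, side): mean BTR, its CV, and the ConjV/PostV negative-count
    percentages.  Per (ROI, side, method): mean and CV of the relative AC
    over subjects valid for that method, reported only when the ROI's
    negative fraction is at most ``inclusion_threshold_pct``; the p-value
    is a paired t-test between the two methods over subjects valid under
    both.  Deterministic and permutation-invariant over subjects.
    """
    missing = [c for c in ROW_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"rows are missing columns {missing}")
    if rows["subject"].nunique() < 2:
        raise ValueError("study report needs at least two subjects")

    table1_rows = []
    fig4_rows = []
    for (roi, side), grp in sorted(
        rows.groupby(["bg_label", "side"]), key=lambda kv: (_roi_key(kv[0][0]), kv[0][1])
    ):
        grp = grp.sort_values("subject")
        cnc = negative_fraction(grp["conjv_negative"])
        pnc = negative_fraction(grp["postv_negative"])
        table1_rows.append(
            {
                "roi": roi,
                "side": side,
                "mean_btr": float(grp["btr"].mean()),
                "cv_pct": coefficient_of_variation(grp["btr"]),
                "cnc_pct": cnc,
                "pnc_pct": pnc,
            }
        )

        rel_conjv = (grp["ac_conjv"] / grp["ac_spect"])[~grp["conjv_negative"]]
        rel_postv = (grp["ac_postv"] / grp["ac_spect"])[~grp["postv_negative"]]
        both = ~grp["conjv_negative"] & ~grp["postv_negative"]
        if both.sum() >= 2:
            p = paired_t_test(
                (grp["ac_conjv"] / grp["ac_spect"])[both],
                (grp["ac_postv"] / grp["ac_spect"])[both],
            )
        else:
            p = np.nan
        for method, frac, rel in (
            ("ConjV", cnc, rel_conjv),
            ("PostV", pnc, rel_postv),
        ):
            if frac > inclusion_threshold_pct:
                continue
            fig4_rows.append(
                {
                    "roi": roi,
                    "side": side,
                    "method": method,
                    "mean_rel_ac": float(rel.mean()) if len(rel) else np.nan,
                    "cv_pct": coefficient_of_variation(rel)
                    if len(rel) >= 2
                    else np.nan,
                    "n": int(len(rel)),
                    "p_value": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )

    table1 = pd.DataFrame(table1_rows, columns=TABLE1_COLUMNS)
    fig4 = pd.DataFrame(fig4_rows, columns=FIG4_COLUMNS)
    return StudyReport(
        table1=table1, fig4=fig4, inclusion_threshold_pct=inclusion_threshold_pct
    )


def _roi_key(label: str):
    """Sort B2 before B10: numeric suffix when present."""
    if label.startswith("B") and label[1:].isdigit():
        return (0, int(label[1:]))
    return (1, label)
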