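"""Step-one differential-recruitment screen over SNP allele pairs.

For every REF/non-REF pair the replicate spot fluorescences are compared
with a two-sided t-test, run independently per probe orientation to absorb
orientation-specific effects; the two orientation p-values are combined with
Fisher's method (chi-square with 4 df) and Benjamini-Hochberg adjusted
across all pairs of the experiment.  The effect size is the delta z-score —
mean non-REF z minus mean REF z — so positive values are gains of
recruitment introduced by the non-REF allele and negative values losses.
A pair is a reproducible hit only when q < 0.05 independently in both
technical replicates with a concordant direction of effect.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import ArrayManifest
from .quantify import ZScoreResult, zscore_pipeline

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300

SCREEN_COLUMNS = [
    "rsid",
    "qtl_class",
    "t_plus",
    "p_plus",
    "t_minus",
    "p_minus",
    "p_fisher",
    "q",
    "z_ref",
    "z_nonref",
    "delta_z",
    "direction",
]


def orientation_ttest(
    ref_spots: Sequence[float],
    nonref_spots: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided t-test comparing REF vs non-REF replicate fluorescences.

    Welch (unequal variance) by default; Student's pooled test behind the
    flag.  Degenerate zero-variance inputs fall back to the convention
    p = 1 for equal means and p = 0 (with a warning) otherwise.
    """
    a = np.asarray(ref_spots, dtype=float)
    b = np.asarray(nonref_spots, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 spots per allele")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero variance with different means: p set to 0")
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def fisher_combine(p_plus: float, p_minus: float) -> float:
    """Fisher's method for the two orientation p-values.

    X = -2(ln p+ + ln p-) is chi-square with 4 degrees of freedom under the
    null; zero inputs are clamped to 1e-300 with a warning.
    """
    ps = []
    for p in (p_plus, p_minus):
        if not 0 <= p <= 1:
            raise ValueError(f"p-value out of [0,1]: {p}")
        if p == 0:
            warnings.warn("p = 0 clamped to 1e-300 before Fisher combination")
            p = P_FLOOR
        ps.append(p)
    x = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    return float(stats.chi2.sf(x, df=4))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def delta_zscore(
    z_ref: Sequence[float] | float, z_nonref: Sequence[float] | float
) -> float:
    """Mean non-REF z minus mean REF z (means taken over orientations)."""
    return float(np.mean(z_nonref) - np.mean(z_ref))


def screen(
    manifest: ArrayManifest,
    intensities: pd.DataFrame,
    label: str = "",
    equal_var: bool = False,
    zres: ZScoreResult | None = None,
) -> pd.DataFrame:
    """Run the step-one screen on one experiment.

    Returns one row per SNP pair ordered by rsid with per-orientation t/p,
    the Fisher-combined p, BH q (family = all testable pairs in this
    experiment), allele z-scores and delta z.  Pairs with insufficient
    replicates carry NA statistics and are excluded from the BH family.
    """
    if manifest.design_class != "snp":
        raise ValueError("screen requires a SNP pair design")
    if zres is None:
        zres = zscore_pipeline(manifest, intensities, metadata={"label": label})
    agg = zres.table
    qtl = manifest.params.get("qtl_class", {})
    pairs = agg.loc[agg["probe_class"].isin(["ref", "nonref"])]
    by_key = {
        (r["locus_id"], r["probe_class"], r["orientation"]): r
        for _, r in pairs.iterrows()
    }
    rsids = sorted(pairs["locus_id"].unique())
    rows = []
    for rsid in rsids:
        rec: dict = {"rsid": rsid, "qtl_class": qtl.get(rsid, "NA")}
        try:
            per_orient = {}
            zs = {"ref": [], "nonref": []}
            for orientation, tag in (("+", "plus"), ("-", "minus")):
                ref = by_key[(rsid, "ref", orientation)]
                nonref = by_key[(rsid, "nonref", orientation)]
                if not (ref["ok"] and nonref["ok"]):
                    raise KeyError("insufficient replicates")
                t, p = orientation_ttest(
                    ref["spots"], nonref["spots"], equal_var=equal_var
                )
                per_orient[tag] = (t, p)
                zs["ref"].append(ref["z"])
                zs["nonref"].append(nonref["z"])
            rec.update(
                t_plus=per_orient["plus"][0],
                p_plus=per_orient["plus"][1],
                t_minus=per_orient["minus"][0],
                p_minus=per_orient["minus"][1],
                p_fisher=fisher_combine(per_orient["plus"][1], per_orient["minus"][1]),
                z_ref=float(np.mean(zs["ref"])),
                z_nonref=float(np.mean(zs["nonref"])),
            )
            rec["delta_z"] = delta_zscore(zs["ref"], zs["nonref"])
            rec["direction"] = "gain" if rec["delta_z"] > 0 else "loss"
        except KeyError:
            logger.warning("pair %s skipped: insufficient replicates", rsid)
            rec.update(
                {
                    k: np.nan
                    for k in (
                        "t_plus", "p_plus", "t_minus", "p_minus",
                        "p_fisher", "z_ref", "z_nonref", "delta_z",
                    )
                }
            )
            rec["direction"] = "NA"
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    testable = out["p_fisher"].notna()
    if testable.any():
        out.loc[testable, "q"] = bh_adjust(out.loc[testable, "p_fisher"].to_numpy())
    return out[SCREEN_COLUMNS]


def reproducible_hits(
    stats_rep1: pd.DataFrame,
    stats_rep2: pd.DataFrame,
    q_thresh: float = 0.05,
    factor: str = "factor",
) -> pd.DataFrame:
    """Call gains/losses reproducible across two technical replicates.

    A call is made only when q < q_thresh in both replicates and the delta-z
    signs agree; everything else is 'none'.
    """
    s1 = stats_rep1.set_index("rsid")
    s2 = stats_rep2.set_index("rsid")
    if set(s1.index) != set(s2.index):
        raise ValueError("replicates cover different rsid sets")
    rows = []
    for rsid in sorted(s1.index):
        q1, q2 = s1.at[rsid, "q"], s2.at[rsid, "q"]
        dz1, dz2 = s1.at[rsid, "delta_z"], s2.at[rsid, "delta_z"]
        call = "none"
        if (
            pd.notna(q1) and pd.notna(q2)
            and q1 < q_thresh and q2 < q_thresh
            and pd.notna(dz1) and pd.notna(dz2)
            and np.sign(dz1) == np.sign(dz2) and dz1 != 0
        ):
            call = "gain" if dz1 > 0 else "loss"
        rows.append(
            {
                "rsid": rsid,
                "factor": factor,
                "q_rep1": q1,
                "q_rep2": q2,
                "dz_rep1": dz1,
                "dz_rep2": dz2,
                "concordant": bool(
                    pd.notna(dz1) and pd.notna(dz2) and np.sign(dz1) == np.sign(dz2)
                ),
                "call": call,
            }
        )
    return pd.DataFrame(rows)


def summarize_screen(
    calls: pd.DataFrame, qtl_class: Mapping[str, str] | None = None
) -> dict:
    """Tally reproducible calls across factors.

    A locus called gain by one factor and loss by another (or both at one
    factor) counts as 'both'; gains + losses + both = total called loci.
    Per-QTL-class counts are of loci with at least one reproducible call.
    """
    called = calls.loc[calls["call"].isin(["gain", "loss"])]
    per_locus = called.groupby("rsid")["call"].agg(set)
    gains = int(sum(c == {"gain"} for c in per_locus))
    losses = int(sum(c == {"loss"} for c in per_locus))
    both = int(sum(c == {"gain", "loss"} for c in per_locus))
    summary = {
        "gains": gains,
        "losses": losses,
        "both": both,
        "total_called": int(len(per_locus)),
        "n_loci_screened": int(calls["rsid"].nunique()),
        "per_factor": {
            f: int(g.loc[g["call"] != "none", "rsid"].nunique())
            for f, g in calls.groupby("factor")
        },
    }
    if qtl_class is not None:
        per_class: dict[str, int] = {}
        for rsid in per_locus.index:
            per_class[qtl_class.get(rsid, "NA")] = (
                per_class.get(qtl_class.get(rsid, "NA"), 0) + 1
            )
        summary["per_qtl_class"] = per_class
    assert summary["gains"] + summary["losses"] + summary["both"] == summary["total_called"]
    return summary
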