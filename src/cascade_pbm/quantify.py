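"""Spot ingestion, replicate aggregation and background-referenced z-scores.

Every probe's mean fluorescence is standardized against the empirical
distribution of the background probes:

    z = (x - mean(background)) / sd(background)

with the sample (n-1) standard deviation, computed separately for each
orientation by default (scanner and strand effects are orientation-specific;
a pooled background is available).  Background probes receive z-scores
against their own distribution, so on a null array they have mean 0 and unit
variance by construction.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ArrayManifest

logger = logging.getLogger(__name__)

MIN_BACKGROUND = 30

ZSCORE_COLUMNS = [
    "target_id",
    "locus_id",
    "probe_class",
    "orientation",
    "n_spots",
    "mean_fluor",
    "z",
]


@dataclass
class ZScoreResult:
    """Per-probe z-scores plus the background summary they were computed
    against."""

    table: pd.DataFrame = field(repr=False)
    background: dict  # {"per_orientation": bool, "log_scale": bool,
    #                   "summary": {orientation_or_'pooled': {mean, sd, n}}}
    metadata: dict = field(default_factory=dict)

    def target_z(self) -> pd.Series:
        """Orientation-averaged z per target (used for motif assembly and
        delta-z effect sizes)."""
        return self.table.groupby("target_id")["z"].mean()

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# cascade-pbm zscores v1\n")
            self.table.to_csv(fh, sep="\t", index=False, na_rep="NA")
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as jh:
            json.dump(
                {"background": self.background, "metadata": self.metadata},
                jh,
                indent=2,
                sort_keys=True,
            )
            jh.write("\n")


def read_intensities(
    path, manifest: ArrayManifest, format: str = "auto"
) -> pd.DataFrame:
    """Read a spot-level fluorescence table (plain TSV or GenePix-style GPR).

    Rows are joined to the manifest by probe_id; unknown probe ids are an
    error.  Rows with missing or negative fluorescence are excluded with a
    logged count.
    """
    path = str(path)
    if format == "auto":
        format = "gpr" if path.lower().endswith(".gpr") else "tsv"
    if format == "gpr":
        with open(path) as fh:
            lines = fh.readlines()
        hdr = next(
            (i for i, l in enumerate(lines) if l.startswith("Block") or l.startswith('"Block"')),
            None,
        )
        if hdr is None:
            raise ValueError(f"{path}: no GPR data header (Block/Column/Row) found")
        raw = pd.read_csv(io.StringIO("".join(lines[hdr:])), sep="\t")
        raw.columns = [c.strip('"') for c in raw.columns]
        if "F635 Median" not in raw.columns or "ID" not in raw.columns:
            raise ValueError(f"{path}: GPR table lacks ID / 'F635 Median' columns")
        table = pd.DataFrame(
            {"probe_id": raw["ID"], "fluorescence": raw["F635 Median"]}
        )
    elif format == "tsv":
        table = pd.read_csv(
            path, sep="\t", comment="#", na_values=["NA"], keep_default_na=True
        )
        if "probe_id" not in table.columns or "fluorescence" not in table.columns:
            raise ValueError(f"{path}: need probe_id and fluorescence columns")
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(table) == 0:
        raise ValueError(f"{path}: empty intensity table")
    known = set(manifest.probes["probe_id"])
    unknown = [p for p in table["probe_id"].unique() if p not in known]
    if unknown:
        raise ValueError(
            f"{path}: {len(unknown)} probe ids not in manifest, first 10: "
            + ", ".join(map(str, unknown[:10]))
        )
    bad = table["fluorescence"].isna() | (table["fluorescence"] < 0)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: excluded %d spots with missing/negative fluorescence", path, n_bad)
    table = table.loc[~bad].copy()
    table.attrs["n_excluded"] = n_bad
    # align manifest annotation
    ann = manifest.probes.set_index("probe_id")
    for col in ("orientation", "replicate"):
        table[col] = ann.loc[table["probe_id"], col].to_numpy()
    return table.reset_index(drop=True)


def aggregate_spots(
    table: pd.DataFrame, manifest: ArrayManifest, statistic: str = "mean"
) -> pd.DataFrame:
    """Collapse replicate spots to one row per (target, orientation).

    The raw spot vector is retained (the differential screen's t-tests need
    it); probes with fewer than 2 surviving spots are flagged not-ok and are
    excluded from downstream testing.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    ann = manifest.probes.set_index("probe_id")
    joined = table.copy()
    for col in ("target_id", "locus_id", "probe_class", "tile_index", "tile_offset",
                "sv_position", "sv_base", "target_seq"):
        joined[col] = ann.loc[joined["probe_id"], col].to_numpy()
    agg_fn = np.mean if statistic == "mean" else np.median
    rows = []
    grouped = joined.sort_values("replicate").groupby(
        ["target_id", "orientation"], sort=True
    )
    for (target_id, orientation), g in grouped:
        spots = g["fluorescence"].to_numpy(dtype=float)
        rows.append(
            {
                "target_id": target_id,
                "orientation": orientation,
                "locus_id": g["locus_id"].iloc[0],
                "probe_class": g["probe_class"].iloc[0],
                "tile_index": g["tile_index"].iloc[0],
                "tile_offset": g["tile_offset"].iloc[0],
                "sv_position": g["sv_position"].iloc[0],
                "sv_base": g["sv_base"].iloc[0],
                "target_seq": g["target_seq"].iloc[0],
                "n_spots": len(spots),
                "mean_fluor": float(agg_fn(spots)),
                "spots": spots,
                "ok": len(spots) >= 2,
            }
        )
    agg = pd.DataFrame(rows)
    n_insufficient = int((~agg["ok"]).sum())
    if n_insufficient:
        logger.warning("%d probes flagged 'insufficient replicates'", n_insufficient)
    return agg


def background_zscore(
    agg: pd.DataFrame,
    per_orientation: bool = True,
    log_scale: bool = False,
    metadata: dict | None = None,
    min_background: int = MIN_BACKGROUND,
) -> ZScoreResult:
    """Z-score every probe mean against the background-probe distribution."""
    agg = agg.copy()
    x = agg["mean_fluor"].to_numpy(dtype=float)
    if log_scale:
        if (x <= 0).any():
            raise ValueError("log-scale z-scores need strictly positive means")
        x = np.log(x)
    is_bg = (agg["probe_class"] == "background").to_numpy()
    if is_bg.sum() < min_background:
        raise ValueError(
            f"need >= {min_background} background probes, got {int(is_bg.sum())}"
        )
    z = np.empty(len(agg))
    summary: dict[str, dict] = {}
    groups = (
        [(o, (agg["orientation"] == o).to_numpy()) for o in sorted(agg["orientation"].unique())]
        if per_orientation
        else [("pooled", np.ones(len(agg), dtype=bool))]
    )
    for label, mask in groups:
        bg = x[mask & is_bg]
        if len(bg) < 2:
            raise ValueError(f"background group {label!r} has < 2 probes")
        mu, sd = float(np.mean(bg)), float(np.std(bg, ddof=1))
        if sd == 0:
            raise ValueError("degenerate background: zero standard deviation")
        z[mask] = (x[mask] - mu) / sd
        summary[label] = {"mean": mu, "sd": sd, "n": int(len(bg))}
    agg["z"] = z
    background = {
        "per_orientation": per_orientation,
        "log_scale": log_scale,
        "summary": summary,
    }
    return ZScoreResult(table=agg, background=background, metadata=metadata or {})


def zscore_pipeline(
    manifest: ArrayManifest,
    intensities: pd.DataFrame,
    per_orientation: bool = True,
    log_scale: bool = False,
    statistic: str = "mean",
    metadata: dict | None = None,
) -> ZScoreResult:
    """aggregate_spots + background_zscore in one call."""
    agg = aggregate_spots(intensities, manifest, statistic=statistic)
    return background_zscore(
        agg, per_orientation=per_orientation, log_scale=log_scale, metadata=metadata
    )
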