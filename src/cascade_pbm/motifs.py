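"""Step-two motif construction from single-variant probe z-scores.

A locus (one 26-base target, or one tile of a larger region) yields an
L x 4 matrix: the reference base at each position carries the seed probe's
z-score, every other base the corresponding single-variant probe's z-score.
Two rules from the screen design apply:

* reset rule — a variant z above 1.645 (the ~95% point of the background
  distribution under normality) whose seed z is at or below 1.645 is reset
  to the seed value, so sites created de novo by the variant do not
  masquerade as genomic recruitment sites;
* seed threshold — stand-alone locus motifs are only reported when the seed
  z reaches 1.5.

Tiled regions are integrated position by position with a weighted mean over
all tiles covering the position, each tile weighted by its seed (reference
genomic) z-score.  The displayed logo matrix is the delta z: each row
centred on its median across the four bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ArrayManifest
from .quantify import ZScoreResult
from .seq import ALPHABET, BASE_INDEX

logger = logging.getLogger(__name__)

SV_RESET_THRESH = 1.645
SEED_Z_THRESH = 1.5
WEIGHT_FLOOR = 0.01


@dataclass
class RecruitmentMotif:
    """Position x base recruitment z-scores for one locus or region."""

    locus_id: str
    positions: np.ndarray  # offsets within the designed region
    ref_bases: str
    z_matrix: np.ndarray  # L x 4, ACGT columns
    seed_z: np.ndarray  # per-position seed weight (scalar broadcast for one tile)
    factor: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.z_matrix = np.asarray(self.z_matrix, dtype=float)
        self.seed_z = np.atleast_1d(np.asarray(self.seed_z, dtype=float))
        L = len(self.positions)
        if self.z_matrix.shape != (L, 4):
            raise ValueError("z_matrix must be L x 4")
        if len(self.ref_bases) != L:
            raise ValueError("ref_bases length mismatch")
        if len(self.seed_z) == 1:
            self.seed_z = np.full(L, self.seed_z[0])

    @property
    def delta_matrix(self) -> np.ndarray:
        return delta_logo(self.z_matrix)

    def to_long(self) -> pd.DataFrame:
        """Long-form table: one row per (position, base)."""
        rows = []
        dm = self.delta_matrix
        for i, pos in enumerate(self.positions):
            for k, base in enumerate(ALPHABET):
                rows.append(
                    {
                        "locus_id": self.locus_id,
                        "position": int(pos),
                        "ref_base": self.ref_bases[i],
                        "base": base,
                        "z": self.z_matrix[i, k],
                        "delta_z": dm[i, k],
                        "seed_z": self.seed_z[i],
                        "factor": self.factor,
                        "condition": self.condition,
                    }
                )
        return pd.DataFrame(rows)


def sv_reset(
    z_sv: float, z_seed: float, thresh: float = SV_RESET_THRESH
) -> float:
    """Reset rule: a variant z above threshold is pulled back to the seed z
    when the seed itself is at or below threshold; otherwise unchanged."""
    if z_sv > thresh and z_seed <= thresh:
        return z_seed
    return z_sv


def delta_logo(z_matrix: np.ndarray) -> np.ndarray:
    """Per position, the z-scores centred on their median across the four
    bases (for 4 values, the mean of the middle two order statistics)."""
    z = np.asarray(z_matrix, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z_matrix contains non-finite values")
    return z - np.median(z, axis=1, keepdims=True)


def _tile_groups(manifest: ArrayManifest, locus_id: str) -> pd.DataFrame:
    t = manifest.targets()
    t = t.loc[(t["locus_id"] == locus_id) & (t["probe_class"].isin(["seed", "sv"]))]
    if len(t) == 0:
        raise ValueError(f"locus {locus_id!r} has no seed/SV probes in manifest")
    return t


def locus_z_matrix(
    manifest: ArrayManifest,
    zres: ZScoreResult,
    locus_id: str,
    tile_index: int | None = None,
    seed_thresh: float | None = SEED_Z_THRESH,
    sv_thresh: float = SV_RESET_THRESH,
) -> RecruitmentMotif | None:
    """Assemble the L x 4 z-matrix for one locus (or one tile of it).

    Z-scores are averaged over the two probe orientations; the reset rule is
    applied to every variant cell.  Returns None (logging the reason) when a
    seed threshold is given and the seed z falls below it.
    """
    targets = _tile_groups(manifest, locus_id)
    if tile_index is not None:
        targets = targets.loc[targets["tile_index"] == tile_index]
        if len(targets) == 0:
            raise ValueError(f"{locus_id}: no tile {tile_index}")
    elif targets["tile_index"].notna().any() and targets["tile_index"].nunique() > 1:
        raise ValueError(
            f"{locus_id} is tiled; pass tile_index or use build_cre_motif"
        )
    tz = zres.target_z()
    seed_rows = targets.loc[targets["probe_class"] == "seed"]
    if len(seed_rows) != 1:
        raise ValueError(f"{locus_id}: expected one seed target, got {len(seed_rows)}")
    seed = seed_rows.iloc[0]
    seed_seq = seed["target_seq"]
    z_seed = float(tz[seed["target_id"]])
    if seed_thresh is not None and z_seed < seed_thresh:
        logger.info(
            "%s: below seed threshold (z=%.3f < %.3f), no motif reported",
            locus_id, z_seed, seed_thresh,
        )
        return None
    L = len(seed_seq)
    z = np.full((L, 4), np.nan)
    sv = targets.loc[targets["probe_class"] == "sv"].set_index(
        ["sv_position", "sv_base"]
    )
    for pos in range(L):
        ref_base = seed_seq[pos]
        z[pos, BASE_INDEX[ref_base]] = z_seed
        for base in ALPHABET:
            if base == ref_base:
                continue
            try:
                tid = sv.at[(pos, base), "target_id"]
            except KeyError:
                raise ValueError(
                    f"{locus_id}: missing SV probe at position {pos} base {base}"
                ) from None
            z[pos, BASE_INDEX[base]] = sv_reset(float(tz[tid]), z_seed, sv_thresh)
    offset = int(seed["tile_offset"]) if pd.notna(seed["tile_offset"]) else 0
    return RecruitmentMotif(
        locus_id=locus_id,
        positions=offset + np.arange(L),
        ref_bases=seed_seq,
        z_matrix=z,
        seed_z=np.array([z_seed]),
    )


def integrate_tiles(
    tile_motifs: list[RecruitmentMotif],
    weight_floor: float = WEIGHT_FLOOR,
) -> RecruitmentMotif:
    """Seed-z-weighted mean of overlapping tile matrices.

    At every position/base the integrated z is the mean over all covering
    tiles weighted by each tile's seed z (floored at ``weight_floor`` so
    non-positive seeds cannot flip the average).  The reference base must
    agree wherever tiles overlap.
    """
    if not tile_motifs:
        raise ValueError("no tile motifs to integrate")
    pos_min = min(int(m.positions.min()) for m in tile_motifs)
    pos_max = max(int(m.positions.max()) for m in tile_motifs)
    L = pos_max - pos_min + 1
    num = np.zeros((L, 4))
    den = np.zeros((L, 4))
    wseed_num = np.zeros(L)
    wseed_den = np.zeros(L)
    ref = [""] * L
    for m in tile_motifs:
        w = max(float(m.seed_z[0]), weight_floor)
        for i, pos in enumerate(m.positions):
            j = int(pos) - pos_min
            if ref[j] and ref[j] != m.ref_bases[i]:
                raise ValueError(
                    f"reference-base conflict at position {pos}: "
                    f"{ref[j]} vs {m.ref_bases[i]} ({m.locus_id})"
                )
            ref[j] = m.ref_bases[i]
            num[j] += w * m.z_matrix[i]
            den[j] += w
            wseed_num[j] += w * float(m.seed_z[i])
            wseed_den[j] += w
    if any(r == "" for r in ref):
        raise ValueError("tile spans leave gaps in the integrated region")
    z = num / den
    m0 = tile_motifs[0]
    return RecruitmentMotif(
        locus_id=m0.locus_id,
        positions=np.arange(pos_min, pos_max + 1),
        ref_bases="".join(ref),
        z_matrix=z,
        seed_z=wseed_num / wseed_den,
        factor=m0.factor,
        condition=m0.condition,
    )


def build_cre_motif(
    manifest: ArrayManifest,
    zres: ZScoreResult,
    locus_id: str | None = None,
    sv_thresh: float = SV_RESET_THRESH,
    weight_floor: float = WEIGHT_FLOOR,
    factor: str = "",
    condition: str = "",
) -> RecruitmentMotif:
    """Region-wide recruitment motif: per-tile matrices (reset rule applied,
    no per-tile seed gating — every tile contributes, weighted by its seed z)
    integrated across overlapping positions."""
    if locus_id is None:
        loci = [
            l
            for l in manifest.targets()["locus_id"].unique()
            if not str(l).startswith("bg")
        ]
        if len(loci) != 1:
            raise ValueError(f"specify locus_id; manifest has {loci}")
        locus_id = loci[0]
    targets = _tile_groups(manifest, locus_id)
    tile_indices = sorted(targets["tile_index"].dropna().unique())
    if not tile_indices:
        tile_indices = [None]
    motifs = []
    for ti in tile_indices:
        m = locus_z_matrix(
            manifest,
            zres,
            locus_id,
            tile_index=None if ti is None else int(ti),
            seed_thresh=None,
            sv_thresh=sv_thresh,
        )
        motifs.append(m)
    out = integrate_tiles(motifs, weight_floor=weight_floor)
    out.factor = factor
    out.condition = condition
    return out


def delta_axis_limits(motifs: list[RecruitmentMotif]) -> tuple[float, float]:
    """Global (min, max) delta z across experiments of one factor, for
    matched display scaling of logo tracks."""
    if not motifs:
        raise ValueError("no motifs")
    deltas = np.concatenate([m.delta_matrix.ravel() for m in motifs])
    return float(deltas.min()), float(deltas.max())


def write_motif_tsv(motifs: list[RecruitmentMotif], path) -> None:
    """Long-form motif export: locus, position, base, z, delta_z, seed_z."""
    df = pd.concat([m.to_long() for m in motifs], ignore_index=True)
    with open(path, "w") as fh:
        fh.write("# cascade-pbm motifs v1\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
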