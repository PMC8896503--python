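"""Boltzmann conversion of recruitment z-matrices to probability PWMs and
Euclidean-distance matching against TF motif libraries.

A recruitment z-matrix is energy-like: the Boltzmann transform

    P[i,k] = exp(beta * z[i,k]) / sum_k exp(beta * z[i,k])

turns it into a position probability matrix comparable to published TF
binding models.  The inverse temperature is scaled to the experiment,
beta = 30 / max(z) over all probes of the experiment, which absorbs
antibody-efficiency differences between factors.  Matching slides the query
over each library motif on both strands and scores the mean per-column
Euclidean distance over the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq import ALPHABET

MIN_OVERLAP = 4
BETA_NUMERATOR = 30.0


@dataclass
class PWM:
    """A position probability matrix over ACGT columns."""

    motif_id: str
    matrix: np.ndarray = field(repr=False)
    beta: float | None = None
    source: str = "cascade"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        if (m < 0).any() or not np.isfinite(m).all():
            raise ValueError(f"{self.motif_id}: probabilities must be finite and >= 0")
        sums = m.sum(axis=1)
        if (sums <= 0).any():
            raise ValueError(f"{self.motif_id}: zero-sum row")
        self.matrix = m / sums[:, None]

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            matrix=self.matrix[::-1, ::-1],
            beta=self.beta,
            source=self.source,
        )


@dataclass
class MotifMatch:
    query_id: str
    target_id: str
    offset: int
    strand: str
    distance: float
    overlap_len: int


def beta_from_experiment(z_all) -> float:
    """Experiment-scaled inverse temperature: 30 over the maximum z-score
    observed anywhere in the experiment."""
    zmax = float(np.nanmax(np.asarray(z_all, dtype=float)))
    if zmax <= 0:
        raise ValueError("no positive signal; PWM conversion undefined")
    return BETA_NUMERATOR / zmax


def boltzmann_pwm(z_matrix, beta: float, motif_id: str = "motif") -> PWM:
    """Row-wise Boltzmann (softmax) transform of a z-matrix, overflow-safe."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    z = np.asarray(z_matrix, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z-matrix must be finite")
    e = beta * z
    e -= e.max(axis=1, keepdims=True)
    p = np.exp(e)
    p /= p.sum(axis=1, keepdims=True)
    return PWM(motif_id=motif_id, matrix=p, beta=beta)


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------


def meme_text(pwms: list[PWM], background: np.ndarray | None = None) -> str:
    """Render PWMs in MEME minimal motif format."""
    if not pwms:
        raise ValueError("no PWMs to write")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)),
        "",
    ]
    for pwm in pwms:
        lines.append(f"MOTIF {pwm.motif_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {len(pwm)} "
            f"nsites= 20 E= 0"
        )
        for row in pwm.matrix:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        lines.append("")
    return "\n".join(lines)


def write_meme(pwms: list[PWM], path, background: np.ndarray | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(meme_text(pwms, background))


def read_meme(path) -> list[PWM]:
    """Parse a MEME minimal-format motif file; rows are renormalized to 1."""
    with open(path) as fh:
        lines = fh.readlines()
    if not any(l.strip() for l in lines):
        raise ValueError(f"{path}: empty MEME file")
    if not any(l.strip().startswith("MEME version") for l in lines):
        raise ValueError(f"{path}: line 1: missing 'MEME version' header")
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {i + 1}: MOTIF line without a name")
            motif_id = parts[1]
            # find the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    raise ValueError(
                        f"{path}: line {j + 1}: motif {motif_id} has no matrix"
                    )
                j += 1
            if j == len(lines):
                raise ValueError(f"{path}: motif {motif_id} has no matrix block")
            header = lines[j].strip()
            w = None
            toks = header.replace("=", "= ").split()
            for k, tok in enumerate(toks):
                if tok == "w=" and k + 1 < len(toks):
                    w = int(toks[k + 1])
            rows = []
            j += 1
            while j < len(lines):
                s = lines[j].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = s.split()
                if len(vals) != 4:
                    raise ValueError(
                        f"{path}: line {j + 1}: expected 4 probabilities, got {len(vals)}"
                    )
                try:
                    rows.append([float(v) for v in vals])
                except ValueError as err:
                    raise ValueError(f"{path}: line {j + 1}: {err}") from None
                j += 1
            if w is not None and len(rows) != w:
                raise ValueError(
                    f"{path}: motif {motif_id}: header says w= {w} but "
                    f"{len(rows)} rows found"
                )
            if not rows:
                raise ValueError(f"{path}: motif {motif_id}: empty matrix")
            pwms.append(PWM(motif_id=motif_id, matrix=np.array(rows), source="library"))
            i = j
        else:
            i += 1
    if not pwms:
        raise ValueError(f"{path}: no motifs found")
    return pwms


# ---------------------------------------------------------------------------
# Euclidean-distance matching
# ---------------------------------------------------------------------------


def _best_alignment(
    q: np.ndarray, t: np.ndarray, min_overlap: int
) -> tuple[float, int, int]:
    """Best (distance, offset, overlap) sliding q over t; offset is the
    position of q's first column relative to t's first column."""
    lq, lt = len(q), len(t)
    best = (np.inf, 0, 0)
    for offset in range(-(lq - min_overlap), lt - min_overlap + 1):
        t_lo, t_hi = max(0, offset), min(lt, offset + lq)
        if t_hi - t_lo < min_overlap:
            continue
        q_lo = t_lo - offset
        qo = q[q_lo : q_lo + (t_hi - t_lo)]
        to = t[t_lo:t_hi]
        d = float(np.mean(np.linalg.norm(qo - to, axis=1)))
        if d < best[0]:
            best = (d, offset, t_hi - t_lo)
    return best


def ed_match(
    query: PWM, library: list[PWM], min_overlap: int = MIN_OVERLAP
) -> list[MotifMatch]:
    """Rank library motifs by mean per-column Euclidean distance to the query.

    All offsets with at least ``min_overlap`` overlapping columns are scanned
    on both strands (the minus strand compares against the
    reverse-complemented library matrix); each library motif contributes its
    best alignment, and matches are returned sorted ascending by distance.
    """
    if len(query) < min_overlap:
        raise ValueError(f"query shorter than min_overlap ({min_overlap})")
    matches = []
    for lib in library:
        candidates = []
        for strand, mat in (("+", lib.matrix), ("-", lib.reverse_complement().matrix)):
            d, offset, ov = _best_alignment(query.matrix, mat, min_overlap)
            candidates.append(
                MotifMatch(
                    query_id=query.motif_id,
                    target_id=lib.motif_id,
                    offset=offset,
                    strand=strand,
                    distance=d,
                    overlap_len=ov,
                )
            )
        matches.append(min(candidates, key=lambda m: (m.distance, m.strand)))
    matches.sort(key=lambda m: (m.distance, m.target_id))
    return matches
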