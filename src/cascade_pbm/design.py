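"""Probe design for cofactor-recruitment microarrays.

A design turns input sequence (a regulatory element, a SNP list, or a TF
consensus site) into a complete array manifest: every spotted probe with its
target sequence, orientation and replicate number.  Three design classes are
supported:

``cre``
    A regulatory region is tiled with 26-base targets at a 5-base step; every
    tile is accompanied by all 3*26 single-variant (SV) targets so a
    recruitment motif can be read out at single-nucleotide resolution.
``snp``
    Each SNP is represented by a pair of 26-base targets centred on the
    variant (13 bases + SNP + 12 bases), one per allele.
``tfbs``
    A TF consensus site padded by 2 random bases per side and embedded at the
    5' end of a 34-base non-repeating backbone.

Every 26-base target is embedded in a 60-base probe:
``GCCTAG`` + target (26) + ``CTAG`` + 24-base primer-binding site, and each
target is spotted in both orientations (+ and reverse complement) with 5
replicate spots per orientation.  Random background targets provide the
empirical null distribution used for z-scoring downstream.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seq import ALPHABET, random_dna, revcomp, validate_dna

TILE_LEN = 26
TILE_STEP = 5
FLANK5 = "GCCTAG"
FLANK3 = "CTAG"
#: 24-base primer-binding site terminating every probe (the reverse
#: complement of the double-stranding primer that is annealed to it).
PRIMER_SITE = "GTCTTGATTCGCTTGACGCTGCTG"
#: The double-stranding primer itself, 5'->3'.
DS_PRIMER = "CAGCAGCGCTCAAGGAATCAAGAC"
N_REPLICATES = 5
N_BACKGROUND = 500
TFBS_TARGET_LEN = 34
GC_CAP = "GC"
PROBE_LEN = 60

QTL_CLASSES = ("basal_eQTL", "caQTL_eQTL", "GWAS_caQTL", "GWAS_eQTL", "response_eQTL")

MANIFEST_COLUMNS = [
    "probe_id",
    "target_id",
    "locus_id",
    "probe_class",
    "tile_index",
    "tile_offset",
    "sv_position",
    "sv_base",
    "orientation",
    "replicate",
    "target_seq",
    "probe_seq",
]


@dataclass
class GenomicTarget:
    """A target sequence, optionally anchored to coordinates.

    ``start``/``end`` are 0-based half-open offsets, either genomic or (for
    tiles) within the designed region.
    """

    locus_id: str
    target_seq: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str = "+"
    tile_index: int | None = None

    def __post_init__(self) -> None:
        self.target_seq = validate_dna(self.target_seq, f"target {self.locus_id}")
        if self.start is not None and self.end is not None:
            if self.end - self.start != len(self.target_seq):
                raise ValueError(
                    f"{self.locus_id}: end-start ({self.end - self.start}) "
                    f"!= sequence length ({len(self.target_seq)})"
                )


@dataclass
class Variant:
    """One entry of an exhaustive single-variant enumeration."""

    target_seq: str
    sv_position: int | None  # None marks the unmutated seed
    sv_base: str | None


@dataclass
class SnpSpec:
    """A SNP to screen: REF/non-REF alleles with their +strand flanks."""

    rsid: str
    ref_allele: str
    nonref_allele: str
    flank5_seq: str  # 13 bases upstream on the + strand
    flank3_seq: str  # 12 bases downstream
    qtl_class: str = "basal_eQTL"
    chrom: str | None = None
    pos: int | None = None  # 1-based SNP coordinate

    SV_OFFSET = 13  # 0-based position of the allele within the 26-mer

    def __post_init__(self) -> None:
        self.ref_allele = validate_dna(self.ref_allele, f"{self.rsid} ref allele")
        self.nonref_allele = validate_dna(
            self.nonref_allele, f"{self.rsid} nonref allele"
        )
        self.flank5_seq = validate_dna(self.flank5_seq, f"{self.rsid} 5' flank")
        self.flank3_seq = validate_dna(self.flank3_seq, f"{self.rsid} 3' flank")
        if len(self.ref_allele) != 1 or len(self.nonref_allele) != 1:
            raise ValueError(f"{self.rsid}: alleles must be single bases")
        if self.ref_allele == self.nonref_allele:
            raise ValueError(f"{self.rsid}: REF and non-REF alleles are identical")
        if len(self.flank5_seq) != 13 or len(self.flank3_seq) != 12:
            raise ValueError(
                f"{self.rsid}: flanks must be 13 and 12 bases "
                f"(got {len(self.flank5_seq)}, {len(self.flank3_seq)})"
            )

    @property
    def ref_target(self) -> str:
        return self.flank5_seq + self.ref_allele + self.flank3_seq

    @property
    def nonref_target(self) -> str:
        return self.flank5_seq + self.nonref_allele + self.flank3_seq

    @classmethod
    def from_target(
        cls,
        rsid: str,
        target: str,
        nonref_allele: str,
        ref_allele: str | None = None,
        **kw,
    ) -> "SnpSpec":
        """Build a spec from a full 26-mer centred at the SNP.

        If ``ref_allele`` is given it must match the embedded base at the SNP
        position.
        """
        target = validate_dna(target, f"{rsid} target")
        if len(target) != TILE_LEN:
            raise ValueError(f"{rsid}: target must be 26 bases, got {len(target)}")
        embedded = target[cls.SV_OFFSET]
        if ref_allele is not None and ref_allele.upper() != embedded:
            raise ValueError(
                f"{rsid}: REF allele {ref_allele} inconsistent with "
                f"flank-embedded base {embedded} at the SNP position"
            )
        return cls(
            rsid=rsid,
            ref_allele=embedded,
            nonref_allele=nonref_allele,
            flank5_seq=target[: cls.SV_OFFSET],
            flank3_seq=target[cls.SV_OFFSET + 1 :],
            **kw,
        )


@dataclass
class ArrayManifest:
    """A complete array design: parameters plus one row per spotted probe."""

    design_name: str
    design_class: str  # cre | snp | tfbs
    params: dict
    probes: pd.DataFrame = field(repr=False)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_targets(self) -> int:
        return self.probes["target_id"].nunique()

    def targets(self, include_background: bool = True) -> pd.DataFrame:
        """One row per distinct target (collapsing orientations/replicates)."""
        t = self.probes.drop_duplicates("target_id")
        if not include_background:
            t = t[t["probe_class"] != "background"]
        return t.reset_index(drop=True)

    def to_tsv(self, path) -> None:
        header = (
            "# cascade-pbm manifest v1\n"
            f"# design_name={self.design_name}\n"
            f"# design_class={self.design_class}\n"
            f"# params={json.dumps(self.params, sort_keys=True)}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.probes.to_csv(fh, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "ArrayManifest":
        meta: dict[str, str] = {}
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    body = line[1:].strip()
                    if "=" in body:
                        k, v = body.split("=", 1)
                        meta[k.strip()] = v.strip()
                else:
                    lines.append(line)
        probes = pd.read_csv(
            io.StringIO("".join(lines)),
            sep="\t",
            na_values=["NA"],
            keep_default_na=False,
        )
        for col in ("tile_index", "tile_offset", "sv_position", "replicate"):
            probes[col] = probes[col].astype("Int64")
        return cls(
            design_name=meta.get("design_name", "design"),
            design_class=meta.get("design_class", "cre"),
            params=json.loads(meta.get("params", "{}")),
            probes=probes,
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def tile_region(
    seq: str,
    tile_len: int = TILE_LEN,
    step: int = TILE_STEP,
    locus_id: str = "region",
) -> list[GenomicTarget]:
    """Tile a region 5'->3' with fixed-length targets at a regular step.

    Tiles start at offsets 0, step, 2*step, ...  When the final regular tile
    does not reach the 3' end, one extra tile anchored at ``len(seq) -
    tile_len`` is appended so that every base is covered.
    """
    seq = validate_dna(seq, locus_id)
    if step < 1:
        raise ValueError("step must be >= 1")
    if len(seq) < tile_len:
        raise ValueError(
            f"region shorter than tile: {len(seq)} < {tile_len} ({locus_id})"
        )
    last = len(seq) - tile_len
    offsets = list(range(0, last + 1, step))
    if offsets[-1] != last:
        offsets.append(last)
    return [
        GenomicTarget(
            locus_id=locus_id,
            target_seq=seq[off : off + tile_len],
            start=off,
            end=off + tile_len,
            tile_index=i,
        )
        for i, off in enumerate(offsets)
    ]


def enumerate_sv(target: GenomicTarget | str) -> list[Variant]:
    """Seed plus every single-base variant of a target.

    For a length-L target this yields 1 + 3L entries: the unmutated seed
    followed, position by position, by the three alternative bases in
    alphabetical order.
    """
    seq = target.target_seq if isinstance(target, GenomicTarget) else target
    seq = validate_dna(seq)
    if not seq:
        raise ValueError("empty target")
    out = [Variant(target_seq=seq, sv_position=None, sv_base=None)]
    for pos, ref_base in enumerate(seq):
        for base in ALPHABET:
            if base == ref_base:
                continue
            out.append(
                Variant(
                    target_seq=seq[:pos] + base + seq[pos + 1 :],
                    sv_position=pos,
                    sv_base=base,
                )
            )
    return out


def assemble_probe(
    target_seq: str,
    orientation: str = "+",
    flank5: str = FLANK5,
    flank3: str = FLANK3,
    primer: str = PRIMER_SITE,
) -> str:
    """Embed a 26-base target in the full 60-base probe.

    The minus orientation spots the reverse complement of the target between
    the same flanks; the probe always ends with the primer-binding site.
    """
    target_seq = validate_dna(target_seq, "target")
    for name, part, want in (
        ("flank5", flank5, 6),
        ("flank3", flank3, 4),
        ("primer", primer, 24),
        ("target", target_seq, TILE_LEN),
    ):
        if len(part) != want:
            raise ValueError(f"{name} must be {want} bases, got {len(part)}")
    if orientation not in ("+", "-"):
        raise ValueError(f"orientation must be '+' or '-', got {orientation!r}")
    core = target_seq if orientation == "+" else revcomp(target_seq)
    return flank5 + core + flank3 + primer


def make_background(
    n: int,
    rng_seed: int | np.random.Generator = 0,
    source: Mapping[str, str] | None = None,
    length: int = TILE_LEN,
) -> list[GenomicTarget]:
    """Random background targets: genome-sampled when a source is given,
    i.i.d. uniform ACGT otherwise."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    out: list[GenomicTarget] = []
    if source is not None:
        names = sorted(k for k, v in source.items() if len(v) >= length)
        if not names:
            raise ValueError(f"no source sequence of length >= {length}")
        weights = np.array([len(source[k]) - length + 1 for k in names], dtype=float)
        weights /= weights.sum()
        i = 0
        attempts = 0
        while i < n:
            attempts += 1
            if attempts > 100 * max(n, 1):
                raise ValueError("could not sample ACGT-only background windows")
            name = names[rng.choice(len(names), p=weights)]
            seq = source[name].upper()
            off = int(rng.integers(0, len(seq) - length + 1))
            window = seq[off : off + length]
            if set(window) - set(ALPHABET):
                continue
            out.append(
                GenomicTarget(
                    locus_id=f"bg{i:04d}",
                    target_seq=window,
                    chrom=name,
                    start=off,
                    end=off + length,
                )
            )
            i += 1
    else:
        for i in range(n):
            out.append(
                GenomicTarget(locus_id=f"bg{i:04d}", target_seq=random_dna(length, rng))
            )
    return out


# ---------------------------------------------------------------------------
# manifest assembly
# ---------------------------------------------------------------------------


def _expand_targets(
    target_rows: list[dict],
    n_replicates: int,
    flank5: str = FLANK5,
    flank3: str = FLANK3,
    primer: str = PRIMER_SITE,
) -> pd.DataFrame:
    """Expand target records to spotted probes: 2 orientations x replicates."""
    rows = []
    for t in target_rows:
        for orientation in ("+", "-"):
            probe_seq = assemble_probe(
                t["target_seq"], orientation, flank5, flank3, primer
            )
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "probe_id": f"{t['target_id']};{orientation}{rep}",
                        **t,
                        "orientation": orientation,
                        "replicate": rep,
                        "probe_seq": probe_seq,
                    }
                )
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    for col in ("tile_index", "tile_offset", "sv_position", "replicate"):
        df[col] = df[col].astype("Int64")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id generated: {dup}")
    return df


def _background_rows(backgrounds: Iterable[GenomicTarget]) -> list[dict]:
    return [
        {
            "target_id": f"{bg.locus_id}:bg",
            "locus_id": bg.locus_id,
            "probe_class": "background",
            "tile_index": None,
            "tile_offset": None,
            "sv_position": None,
            "sv_base": None,
            "target_seq": bg.target_seq,
        }
        for bg in backgrounds
    ]


def design_cre_array(
    seq: str | Mapping[str, str],
    n_background: int = N_BACKGROUND,
    rng_seed: int = 0,
    design_name: str = "cre_design",
    tile_len: int = TILE_LEN,
    step: int = TILE_STEP,
    n_replicates: int = N_REPLICATES,
    background_source: Mapping[str, str] | None = None,
) -> ArrayManifest:
    """Design a tiling + exhaustive single-variant array for one or more
    regulatory regions.

    For T tiles the design holds T seed targets and 3 * tile_len variant
    targets per tile (duplicate sequences from overlapping tiles are kept as
    distinct records), plus ``n_background`` random background targets.
    """
    seqs = {"cre": seq} if isinstance(seq, str) else dict(seq)
    target_rows: list[dict] = []
    for locus_id in seqs:
        tiles = tile_region(seqs[locus_id], tile_len, step, locus_id=locus_id)
        for tile in tiles:
            prefix = f"{locus_id}:t{tile.tile_index:03d}"
            for v in enumerate_sv(tile):
                if v.sv_position is None:
                    target_id, probe_class = f"{prefix}:seed", "seed"
                else:
                    target_id = f"{prefix}:p{v.sv_position:02d}{v.sv_base}"
                    probe_class = "sv"
                target_rows.append(
                    {
                        "target_id": target_id,
                        "locus_id": locus_id,
                        "probe_class": probe_class,
                        "tile_index": tile.tile_index,
                        "tile_offset": tile.start,
                        "sv_position": v.sv_position,
                        "sv_base": v.sv_base,
                        "target_seq": v.target_seq,
                    }
                )
    rng = np.random.default_rng(rng_seed)
    target_rows += _background_rows(
        make_background(n_background, rng, source=background_source, length=tile_len)
    )
    params = {
        "tile_len": tile_len,
        "step": step,
        "n_background": n_background,
        "n_replicates": n_replicates,
        "flank5": FLANK5,
        "flank3": FLANK3,
        "primer": PRIMER_SITE,
        "rng_seed": rng_seed,
    }
    return ArrayManifest(
        design_name=design_name,
        design_class="cre",
        params=params,
        probes=_expand_targets(target_rows, n_replicates),
    )


def design_snp_array(
    snps: Sequence[SnpSpec],
    n_background: int = N_BACKGROUND,
    rng_seed: int = 0,
    design_name: str = "snp_design",
    n_replicates: int = N_REPLICATES,
    background_source: Mapping[str, str] | None = None,
) -> ArrayManifest:
    """Design a REF/non-REF pair screen: one pair of 26-base targets per SNP."""
    seen: set[str] = set()
    target_rows: list[dict] = []
    for snp in snps:
        if snp.rsid in seen:
            raise ValueError(f"duplicate rsID: {snp.rsid}")
        seen.add(snp.rsid)
        for probe_class, tseq, base in (
            ("ref", snp.ref_target, snp.ref_allele),
            ("nonref", snp.nonref_target, snp.nonref_allele),
        ):
            target_rows.append(
                {
                    "target_id": f"{snp.rsid}:{probe_class}",
                    "locus_id": snp.rsid,
                    "probe_class": probe_class,
                    "tile_index": None,
                    "tile_offset": None,
                    "sv_position": SnpSpec.SV_OFFSET,
                    "sv_base": base,
                    "target_seq": tseq,
                }
            )
    rng = np.random.default_rng(rng_seed)
    target_rows += _background_rows(
        make_background(n_background, rng, source=background_source)
    )
    params = {
        "n_snps": len(snps),
        "n_background": n_background,
        "n_replicates": n_replicates,
        "flank5": FLANK5,
        "flank3": FLANK3,
        "primer": PRIMER_SITE,
        "rng_seed": rng_seed,
        "qtl_class": {s.rsid: s.qtl_class for s in snps},
    }
    return ArrayManifest(
        design_name=design_name,
        design_class="snp",
        params=params,
        probes=_expand_targets(target_rows, n_replicates),
    )


def make_backbone(rng: np.random.Generator, length: int = TFBS_TARGET_LEN) -> str:
    """Random backbone in which no two adjacent positions share a base."""
    bases = list(ALPHABET)
    out = [str(rng.choice(bases))]
    for _ in range(length - 1):
        choices = [b for b in bases if b != out[-1]]
        out.append(str(rng.choice(choices)))
    return "".join(out)


def _nonrepeating_pad(
    rng: np.random.Generator, before: str | None, after: str | None, n: int = 2
) -> str:
    """n random bases, none equal to its neighbour (including the given
    flanking bases when present)."""
    out: list[str] = []
    prev = before
    for i in range(n):
        avoid = {prev}
        if i == n - 1 and after is not None:
            avoid.add(after)
        choices = [b for b in ALPHABET if b not in avoid]
        pick = str(rng.choice(choices))
        out.append(pick)
        prev = pick
    return "".join(out)


def design_tfbs_probe(
    consensus: str,
    rng_seed: int | np.random.Generator = 0,
    name: str = "tfbs",
    probe_class: str = "tfbs_consensus",
) -> dict:
    """Build one TFBS probe record: 2-base pads around the consensus,
    embedded at the 5' end of a 34-base non-repeating backbone, capped with
    GC and terminated by the primer site (60 bases total)."""
    consensus = validate_dna(consensus, "consensus")
    if len(consensus) + 4 > TFBS_TARGET_LEN:
        raise ValueError(
            f"consensus too long: {len(consensus)} + 4 pad bases exceeds "
            f"{TFBS_TARGET_LEN}-base target"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    backbone = make_backbone(rng)
    pad5 = _nonrepeating_pad(rng, before=None, after=consensus[0])
    insert_end = 2 + len(consensus) + 2
    after = backbone[insert_end] if insert_end < len(backbone) else None
    pad3 = _nonrepeating_pad(rng, before=consensus[-1], after=after)
    target = pad5 + consensus + pad3 + backbone[insert_end:]
    assert len(target) == TFBS_TARGET_LEN
    probe_seq = GC_CAP + target + PRIMER_SITE
    assert len(probe_seq) == PROBE_LEN
    return {
        "target_id": f"{name}:{probe_class}",
        "locus_id": name,
        "probe_class": probe_class,
        "tile_index": None,
        "tile_offset": None,
        "sv_position": None,
        "sv_base": None,
        "target_seq": target,
        "probe_seq": probe_seq,
    }


def design_tfbs_array(
    consensus_seqs: Mapping[str, str],
    n_background: int = N_BACKGROUND,
    rng_seed: int = 0,
    design_name: str = "tfbs_design",
    n_replicates: int = N_REPLICATES,
) -> ArrayManifest:
    """TFBS consensus array: one padded-backbone probe per consensus plus
    34-base background targets, spotted in one orientation (the site sits at
    the free end of the probe by construction)."""
    rng = np.random.default_rng(rng_seed)
    rows = []
    for name in consensus_seqs:
        rec = design_tfbs_probe(consensus_seqs[name], rng, name=name)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "probe_id": f"{rec['target_id']};+{rep}",
                    **{k: rec[k] for k in rec},
                    "orientation": "+",
                    "replicate": rep,
                }
            )
    for bg in make_background(n_background, rng, length=TFBS_TARGET_LEN):
        probe_seq = GC_CAP + bg.target_seq + PRIMER_SITE
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "probe_id": f"{bg.locus_id}:bg;+{rep}",
                    "target_id": f"{bg.locus_id}:bg",
                    "locus_id": bg.locus_id,
                    "probe_class": "background",
                    "tile_index": None,
                    "tile_offset": None,
                    "sv_position": None,
                    "sv_base": None,
                    "target_seq": bg.target_seq,
                    "orientation": "+",
                    "replicate": rep,
                    "probe_seq": probe_seq,
                }
            )
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    for col in ("tile_index", "tile_offset", "sv_position", "replicate"):
        df[col] = df[col].astype("Int64")
    params = {
        "n_background": n_background,
        "n_replicates": n_replicates,
        "target_len": TFBS_TARGET_LEN,
        "rng_seed": rng_seed,
    }
    return ArrayManifest(
        design_name=design_name, design_class="tfbs", params=params, probes=df
    )


def expected_cre_target_count(n_tiles: int, tile_len: int = TILE_LEN) -> int:
    """Non-background target count of a tiling design: T seeds plus 3 variant
    bases at each of tile_len positions per tile."""
    return n_tiles * (1 + 3 * tile_len)


def tiled_span(n_tiles: int, tile_len: int = TILE_LEN, step: int = TILE_STEP) -> int:
    """Bases of unique sequence covered by n contiguous tiles at the given
    step: tile_len + (n-1)*step."""
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    return tile_len + (n_tiles - 1) * step
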