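"""Synthetic spot-level fluorescence with the statistical structure the
downstream analysis assumes.

The generative model is a single planted TF-cofactor complex: each probe's
target sequence is scanned on both strands with an additive position/base
score matrix ``w``; the best window score ``s`` drives a saturating
(logistic) occupancy, which sets the expected fluorescence

    mu = B + A * exp(s) / (K + exp(s)),

so probes with no site sit at the baseline ``B`` and perfect sites approach
``B + A``.  Each spot then receives multiplicative log-normal noise and,
optionally, an orientation-specific bias factor — PBM intensities are
non-negative, saturating and dominated by multiplicative noise, which is
what this reproduces.  Background probes are random sequence and get
whatever score they happen to contain, matching the empirical-background
z-scoring philosophy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .design import (
    ArrayManifest,
    SnpSpec,
    design_snp_array,
    N_BACKGROUND,
)
from .seq import ALPHABET, encode, random_dna, revcomp

INTENSITY_COLUMNS = ["probe_id", "spot_index", "orientation", "replicate", "fluorescence"]


@dataclass
class PlantedComplex:
    """Parameters of one planted recruitment complex.

    ``motif_energy`` is an m x 4 score matrix over ACGT columns (higher =
    stronger recruitment); ``amplitude`` and ``baseline`` are in the same
    normalized fluorescence units as the output; ``noise_sigma`` is the
    standard deviation of the log-normal spot noise on the log scale;
    ``occupancy_scale`` K sets the score at half-saturation (s = ln K).
    """

    motif_energy: np.ndarray
    amplitude: float = 500.0
    baseline: float = 100.0
    noise_sigma: float = 0.2
    orientation_bias: float = 1.0
    occupancy_scale: float = 1.0

    def __post_init__(self) -> None:
        self.motif_energy = np.asarray(self.motif_energy, dtype=float)
        if self.motif_energy.ndim != 2 or self.motif_energy.shape[1] != 4:
            raise ValueError("motif_energy must be an m x 4 matrix (ACGT columns)")
        if self.amplitude < 0 or self.baseline <= 0:
            raise ValueError("amplitude must be >= 0 and baseline > 0")
        if self.noise_sigma < 0 or self.occupancy_scale <= 0:
            raise ValueError("noise_sigma must be >= 0 and occupancy_scale > 0")

    @property
    def motif_len(self) -> int:
        return self.motif_energy.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[k] for k in self.motif_energy.argmax(axis=1))

    def to_yaml(self, path) -> None:
        doc = {
            "alphabet": ALPHABET,
            "motif_energy": self.motif_energy.tolist(),
            "amplitude": float(self.amplitude),
            "baseline": float(self.baseline),
            "noise_sigma": float(self.noise_sigma),
            "orientation_bias": float(self.orientation_bias),
            "occupancy_scale": float(self.occupancy_scale),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PlantedComplex":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc.get("alphabet", ALPHABET) != ALPHABET:
            raise ValueError("planted complex alphabet must be ACGT")
        return cls(
            motif_energy=np.asarray(doc["motif_energy"], dtype=float),
            amplitude=float(doc.get("amplitude", 500.0)),
            baseline=float(doc.get("baseline", 100.0)),
            noise_sigma=float(doc.get("noise_sigma", 0.2)),
            orientation_bias=float(doc.get("orientation_bias", 1.0)),
            occupancy_scale=float(doc.get("occupancy_scale", 1.0)),
        )


def consensus_energy_matrix(
    consensus: str, match: float = 2.0, mismatch: float = 0.0
) -> np.ndarray:
    """Score matrix awarding ``match`` to the consensus base at each position
    and ``mismatch`` elsewhere."""
    w = np.full((len(consensus), 4), float(mismatch))
    w[np.arange(len(consensus)), encode(consensus)] = float(match)
    return w


def ets_like_complex(**overrides) -> PlantedComplex:
    """Default planted complex: an 8-bp ETS-like site (GGAA core) at a signal
    scale producing seed z-scores in the tens, with half-saturation half a
    mismatch below the consensus score so a single-base change spans most of
    the occupancy range."""
    w = consensus_energy_matrix("ACAGGAAG", match=3.0)
    params = dict(
        motif_energy=w,
        amplitude=500.0,
        baseline=100.0,
        noise_sigma=0.2,
        orientation_bias=1.0,
        occupancy_scale=float(np.exp(22.5)),  # ln K = consensus score - 1.5
    )
    params.update(overrides)
    return PlantedComplex(**params)


def irf_like_complex(**overrides) -> PlantedComplex:
    """Second planted complex with an ISRE-like core, for two-site regions."""
    w = consensus_energy_matrix("TTTCACTTTC", match=3.0)
    params = dict(
        motif_energy=w,
        amplitude=500.0,
        baseline=100.0,
        noise_sigma=0.2,
        orientation_bias=1.0,
        occupancy_scale=float(np.exp(28.5)),
    )
    params.update(overrides)
    return PlantedComplex(**params)


def site_score(seq: str, w: np.ndarray) -> float:
    """Best additive window score of ``w`` over both strands of ``seq``."""
    w = np.asarray(w, dtype=float)
    m = w.shape[0]
    if len(seq) < m:
        raise ValueError(f"sequence shorter than motif: {len(seq)} < {m}")
    best = -np.inf
    for s in (seq, revcomp(seq)):
        idx = encode(s)
        n_win = len(s) - m + 1
        # rows i of w indexed by the base at each window offset
        windows = np.lib.stride_tricks.sliding_window_view(idx, m)
        scores = w[np.arange(m), windows].sum(axis=1)
        best = max(best, float(scores.max())) if n_win else best
    return best


def expected_signal(seq: str, planted: PlantedComplex) -> float:
    """Expected (noise-free) fluorescence of a target under the planted
    complex: baseline plus amplitude times logistic occupancy."""
    s = site_score(seq, planted.motif_energy)
    occ = np.exp(s) / (planted.occupancy_scale + np.exp(s))
    return planted.baseline + planted.amplitude * float(occ)


def simulate_array(
    manifest: ArrayManifest,
    planted: PlantedComplex,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate one scanned array: a fluorescence row for every manifest spot.

    Replicate spots of a probe share the expected signal and differ only by
    log-normal noise; minus-orientation spots are additionally scaled by the
    orientation bias.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(rng_seed)
    probes = manifest.probes
    # expected signal per distinct oriented core (replicates share it)
    mu_cache: dict[str, float] = {}
    mus = np.empty(len(probes))
    for i, (tseq, orient) in enumerate(
        zip(probes["target_seq"], probes["orientation"])
    ):
        core = tseq if orient == "+" else revcomp(tseq)
        if core not in mu_cache:
            mu_cache[core] = expected_signal(core, planted)
        mus[i] = mu_cache[core]
    noise = (
        np.exp(rng.normal(0.0, planted.noise_sigma, size=len(probes)))
        if planted.noise_sigma > 0
        else np.ones(len(probes))
    )
    bias = np.where(probes["orientation"] == "-", planted.orientation_bias, 1.0)
    table = pd.DataFrame(
        {
            "probe_id": probes["probe_id"].to_numpy(),
            "spot_index": np.arange(len(probes)),
            "orientation": probes["orientation"].to_numpy(),
            "replicate": probes["replicate"].to_numpy(),
            "fluorescence": mus * noise * bias,
        }
    )
    return table


def random_snp_specs(
    n: int,
    rng: np.random.Generator,
    qtl_class: str = "basal_eQTL",
    prefix: str = "rs",
) -> list[SnpSpec]:
    """Random SNP specs with uniform-random flanks and alleles."""
    specs = []
    for i in range(n):
        target = random_dna(26, rng)
        ref = target[13]
        nonref = str(rng.choice([b for b in ALPHABET if b != ref]))
        specs.append(
            SnpSpec.from_target(
                f"{prefix}{i:05d}", target, nonref_allele=nonref, qtl_class=qtl_class
            )
        )
    return specs


def make_null_screen(
    n_pairs: int,
    rng_seed: int = 0,
    n_background: int = N_BACKGROUND,
    n_replicate_arrays: int = 2,
    planted: PlantedComplex | None = None,
) -> tuple[ArrayManifest, list[pd.DataFrame]]:
    """Null SNP screen: REF and non-REF alleles with identical expected signal.

    By default the planted complex carries a zero energy matrix, so every
    probe shares one expected signal and allele pairs differ only through
    noise; a custom complex (e.g. with orientation bias) may be supplied, in
    which case it is stripped to a motif-free version so the null holds.
    Returns the manifest and ``n_replicate_arrays`` independent intensity
    tables.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    base = planted if planted is not None else ets_like_complex()
    null_complex = replace(base, motif_energy=np.zeros_like(base.motif_energy))
    rng = np.random.default_rng(rng_seed)
    snps = random_snp_specs(n_pairs, rng)
    manifest = design_snp_array(
        snps,
        n_background=n_background,
        rng_seed=int(rng.integers(2**31)),
        design_name="null_screen",
    )
    tables = [
        simulate_array(manifest, null_complex, rng_seed=int(rng.integers(2**31)))
        for _ in range(n_replicate_arrays)
    ]
    return manifest, tables


def make_planted_screen(
    n_pairs: int,
    n_gains: int,
    rng_seed: int = 0,
    planted: PlantedComplex | None = None,
    n_background: int = N_BACKGROUND,
    n_replicate_arrays: int = 2,
) -> tuple[ArrayManifest, list[pd.DataFrame], list[str]]:
    """SNP screen with true gain-of-recruitment effects planted at the first
    ``n_gains`` pairs.

    For a gain pair, the REF target carries the planted consensus with a
    single mismatch at the SNP position and the non-REF allele restores the
    consensus base, so the non-REF allele creates the stronger site.  The
    remaining pairs are motif-free nulls.  Returns (manifest, intensity
    tables, rsids of the planted gains).
    """
    if not 0 <= n_gains <= n_pairs:
        raise ValueError("need 0 <= n_gains <= n_pairs")
    pl = planted if planted is not None else ets_like_complex()
    cons = pl.consensus
    m = len(cons)
    rng = np.random.default_rng(rng_seed)
    specs: list[SnpSpec] = []
    gain_ids: list[str] = []
    # place the site so that the SNP (offset 13) falls on a consensus position
    site_start = 13 - m // 2
    snp_in_site = 13 - site_start
    for i in range(n_gains):
        rsid = f"rs{i:05d}"
        flank = random_dna(26, rng)
        ref_base = str(rng.choice([b for b in ALPHABET if b != cons[snp_in_site]]))
        site = cons[:snp_in_site] + ref_base + cons[snp_in_site + 1 :]
        target = flank[:site_start] + site + flank[site_start + m :]
        specs.append(
            SnpSpec.from_target(rsid, target, nonref_allele=cons[snp_in_site])
        )
        gain_ids.append(rsid)
    specs += random_snp_specs(n_pairs - n_gains, rng, prefix="rsnull")
    manifest = design_snp_array(
        specs,
        n_background=n_background,
        rng_seed=int(rng.integers(2**31)),
        design_name="planted_screen",
    )
    tables = [
        simulate_array(manifest, pl, rng_seed=int(rng.integers(2**31)))
        for _ in range(n_replicate_arrays)
    ]
    return manifest, tables, gain_ids


def synthetic_cre(
    length: int = 166,
    rng_seed: int = 0,
    sites: dict[int, str] | None = None,
) -> str:
    """Random regulatory-region sequence with consensus sites written in at
    the given offsets (synthetic stand-in for a real promoter segment)."""
    rng = np.random.default_rng(rng_seed)
    seq = list(random_dna(length, rng))
    for offset, cons in (sites or {}).items():
        if offset < 0 or offset + len(cons) > length:
            raise ValueError(f"site at {offset} does not fit in length {length}")
        seq[offset : offset + len(cons)] = list(cons)
    return "".join(seq)


def write_intensities(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write an intensity table as TSV with a comment header."""
    with open(path, "w") as fh:
        fh.write("# cascade-pbm intensities v1\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        table.to_csv(fh, sep="\t", index=False, na_rep="NA")


def write_gpr(table: pd.DataFrame, path) -> None:
    """Minimal GenePix-flavoured export (Block/Column/Row/Name/ID/F635
    Median) for reader testing."""
    n = len(table)
    gpr = pd.DataFrame(
        {
            "Block": np.ones(n, dtype=int),
            "Column": np.arange(n) % 100 + 1,
            "Row": np.arange(n) // 100 + 1,
            "Name": table["probe_id"].to_numpy(),
            "ID": table["probe_id"].to_numpy(),
            "F635 Median": table["fluorescence"].to_numpy(),
        }
    )
    with open(path, "w") as fh:
        fh.write("ATF\t1.0\n2\t6\n")
        fh.write('"Type=GenePix Results 3"\n')
        fh.write('"Scanner=synthetic"\n')
        gpr.to_csv(fh, sep="\t", index=False)
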