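"""Synthetic cohorts with known ground truth.

Every pipeline stage is exercised on data from this module: a random
reference genome, per-sample SNV sets drawn from a mixture of three
mutational signatures, intra-chromosomal rearrangements drawn from three
rearrangement signatures split by segment size around 1 Mb, breakpoint
counts over a feature-driven negative-binomial background with optional
planted hotspot clusters, and phenotypes coupled to the exposures
(driver-mutation probability rising logistically with the third
signature's contribution; fusions concentrated in its top decile; TIL
abundances linear in the contributions).

The default truth profiles echo the biology they stand in for without
claiming numeric fidelity to any published catalog: an APOBEC-like
profile (C>T and C>G at TpC), a smoking-like profile (broad C>A), and a
diffuse profile dominated by C>T and T>C; rearrangement signatures RS1
(large deletions/inversions, >1 Mb), RS2 (large duplications, >1 Mb) and
RS3 (events <1 Mb).

Everything is deterministic given (config, seed), and each generator
serializes its ground truth as JSON next to the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .hotspots import make_bins
from .io_formats import RearrangementRecord, write_rearrangements
from .mutation_catalog import (
    BASES,
    N_CHANNELS,
    SUBSTITUTION_CLASSES,
    reverse_complement,
)
from .rearrangements import N_CATEGORIES, SIZE_BIN_EDGES, SV_ORDER

_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# default ground-truth profiles


def default_ms_profiles() -> np.ndarray:
    """96 x 3 mutational-signature truth matrix (columns sum to 1)."""
    P = np.zeros((N_CHANNELS, 3))
    # MS1: APOBEC-like, C>T and C>G at TpC (5' T)
    for cls in (1, 2):  # C>G, C>T
        for three in range(4):
            P[16 * cls + 4 * 3 + three, 0] = 1.0
    P[:, 0] += 0.02  # faint background over all channels
    # MS2: smoking-like, broad C>A with mild 3' preference
    for five in range(4):
        for three in range(4):
            P[16 * 0 + 4 * five + three, 1] = 1.0 + 0.5 * (three == 1)
    P[:, 1] += 0.03
    # MS3: diffuse, predominance of C>T and T>C; the TpC C>T contexts stay
    # at background level so the profile is distinguishable from MS1
    P[:, 2] = 0.25
    for cls in (2, 4):  # C>T, T>C
        for five in range(4):
            if cls == 2 and five == 3:
                continue
            for three in range(4):
                P[16 * cls + 4 * five + three, 2] = 1.0
    return P / P.sum(axis=0)


def default_rs_profiles() -> np.ndarray:
    """15 x 3 rearrangement-signature truth matrix (columns sum to 1).

    Category order is type-major (DEL, DUP, INV) x size bins
    (1-10kb, 10-100kb, 100kb-1Mb, 1-10Mb, >10Mb).
    """
    P = np.zeros((N_CATEGORIES, 3))
    # RS1: large deletions and inversions (>1 Mb)
    P[[3, 4, 13, 14], 0] = (0.35, 0.25, 0.25, 0.15)
    # RS2: large duplications (>1 Mb)
    P[[8, 9], 1] = (0.6, 0.4)
    # RS3: small events (<1 Mb) of all three types
    P[[0, 1, 2, 5, 6, 7, 10, 11, 12], 2] = (
        0.18, 0.14, 0.08, 0.12, 0.10, 0.06, 0.14, 0.12, 0.06,
    )
    return P / P.sum(axis=0)


@dataclass
class GroundTruth:
    """Everything the generators drew from, serialized next to the data."""

    ms_profiles: list | None = None          # 96 x 3
    rs_profiles: list | None = None          # 15 x 3
    ms_exposures: dict | None = None         # sample -> length-3 counts
    rs_exposures: dict | None = None
    ms_channel_counts: dict | None = None    # sample -> length-96 drawn counts
    rs_category_counts: dict | None = None   # sample -> length-15 drawn counts
    hotspot_intervals: list = field(default_factory=list)  # (chrom, start, end, multiplier)
    background: dict | None = None           # {"m":, "w":, "dispersion":}
    phenotype_model: dict | None = None
    til_model: dict | None = None
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# reference genome


def generate_reference(
    out_fasta: str | Path,
    n_contigs: int = 2,
    contig_length: int = 1_000_000,
    gc: float = 0.41,
    seed: int = 0,
) -> Path:
    """Write a random FASTA (i.i.d. bases at the stated GC) plus .fai index."""
    if contig_length < 10_000:
        raise ValueError("contig_length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out_fasta = Path(out_fasta)
    with open(out_fasta, "w") as fh:
        for c in range(n_contigs):
            seq = rng.choice(list(BASES), size=contig_length, p=p)
            fh.write(f">chr{c + 1}\n")
            s = "".join(seq)
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")
    from pyfaidx import Faidx

    Faidx(str(out_fasta))
    return out_fasta


# ---------------------------------------------------------------------------
# exposures and in-memory catalogs


def draw_exposures(
    rng: np.random.Generator,
    n_samples: int,
    events_per_sample: int,
    concentration: float = 0.8,
    n_signatures: int = 3,
) -> np.ndarray:
    """Per-sample signature event counts: Dirichlet proportions times the
    per-sample total, rounded to integers preserving the total."""
    props = rng.dirichlet(np.full(n_signatures, concentration), size=n_samples)
    counts = np.floor(props * events_per_sample).astype(int)
    short = events_per_sample - counts.sum(axis=1)
    for i in range(n_samples):  # give remainders to the largest proportions
        extra = np.argsort(props[i])[::-1][: short[i]]
        counts[i, extra] += 1
    return counts


def simulate_catalog(
    profiles: np.ndarray,
    exposures: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Draw a channels x samples count catalog from signature mixtures.

    ``profiles``: channels x r (columns sum to 1); ``exposures``:
    samples x r integer event counts.
    """
    rng = np.random.default_rng(seed)
    n_channels, r = profiles.shape
    n_samples = exposures.shape[0]
    V = np.zeros((n_channels, n_samples), dtype=np.int64)
    for j in range(n_samples):
        for s in range(r):
            n = int(exposures[j, s])
            if n > 0:
                V[:, j] += rng.multinomial(n, profiles[:, s])
    return V


# ---------------------------------------------------------------------------
# mutation cohort (VCF emission)


def _channel_contexts(channel: int) -> tuple[str, str, str, str]:
    """(pyrimidine ctx, pyrimidine alt, purine ctx, purine alt) of a channel."""
    cls, rest = divmod(channel, 16)
    five, three = divmod(rest, 4)
    ref, alt = SUBSTITUTION_CLASSES[cls].split(">")
    ctx = BASES[five] + ref + BASES[three]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return ctx, alt, reverse_complement(ctx), comp[alt]


def _trimer_site_index(sequence: str) -> dict[str, np.ndarray]:
    """Map each 3-mer to the (0-based) interior positions where it occurs."""
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for b, i in _BASE_TO_INT.items():
        lut[ord(b)] = i
    enc = lut[codes]
    tri = 16 * enc[:-2] + 4 * enc[1:-1] + enc[2:]
    order = np.argsort(tri, kind="stable")
    sorted_tri = tri[order]
    index: dict[str, np.ndarray] = {}
    bounds = np.searchsorted(sorted_tri, np.arange(65))
    for code in range(64):
        lo, hi = bounds[code], bounds[code + 1]
        if hi > lo:
            f, mid, t = code // 16, (code // 4) % 4, code % 4
            key = BASES[f] + BASES[mid] + BASES[t]
            index[key] = order[lo:hi] + 1  # center position, 0-based
    return index


def generate_mutation_cohort(
    reference_fasta: str | Path,
    out_dir: str | Path,
    n_samples: int = 92,
    mutations_per_sample: int = 2000,
    ms_profiles: np.ndarray | None = None,
    concentration: float = 0.8,
    seed: int = 0,
) -> tuple[list[Path], GroundTruth]:
    """Emit per-sample VCFs whose rebuilt catalog equals the drawn channel
    counts exactly.

    Each mutation's channel is drawn from the sample's signature mixture,
    then placed at a uniformly chosen reference site carrying the required
    trinucleotide context (either strand); a site is never reused within a
    sample.
    """
    from pyfaidx import Fasta

    profiles = default_ms_profiles() if ms_profiles is None else np.asarray(ms_profiles)
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fasta = Fasta(str(reference_fasta), as_raw=True, sequence_always_upper=True)
    contigs = list(fasta.keys())
    site_index = {c: _trimer_site_index(str(fasta[c][:])) for c in contigs}

    exposures = draw_exposures(rng, n_samples, mutations_per_sample,
                               concentration, profiles.shape[1])
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    paths: list[Path] = []
    truth_exp: dict[str, list[int]] = {}
    truth_counts: dict[str, list[int]] = {}

    header = (
        "##fileformat=VCFv4.2\n"
        + "".join(f"##contig=<ID={c},length={len(fasta[c])}>\n" for c in contigs)
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    for j, sid in enumerate(sample_ids):
        counts = np.zeros(N_CHANNELS, dtype=np.int64)
        for s in range(profiles.shape[1]):
            n = int(exposures[j, s])
            if n > 0:
                counts += rng.multinomial(n, profiles[:, s])
        truth_exp[sid] = [int(x) for x in exposures[j]]
        truth_counts[sid] = [int(x) for x in counts]
        used: set[tuple[str, int]] = set()
        rows: list[tuple[str, int, str, str]] = []
        for channel in np.nonzero(counts)[0]:
            need = int(counts[channel])
            pyr_ctx, pyr_alt, pur_ctx, pur_alt = _channel_contexts(int(channel))
            pools = []  # (contig, positions, ref_is_pyrimidine)
            for c in contigs:
                if pyr_ctx in site_index[c]:
                    pools.append((c, site_index[c][pyr_ctx], True))
                if pur_ctx in site_index[c] and pur_ctx != pyr_ctx:
                    pools.append((c, site_index[c][pur_ctx], False))
            total_sites = sum(len(p[1]) for p in pools)
            if total_sites == 0:
                raise ValueError(
                    f"required context {pyr_ctx!r} (or its reverse complement) "
                    "absent from reference"
                )
            placed = 0
            attempts = 0
            while placed < need:
                attempts += 1
                if attempts > 50 * need + 1000:
                    raise ValueError(
                        f"cannot place {need} mutations with context {pyr_ctx!r}: "
                        "too few distinct sites"
                    )
                k = rng.integers(total_sites)
                for c, positions, is_pyr in pools:
                    if k < len(positions):
                        pos0 = int(positions[k])
                        key = (c, pos0)
                        if key in used:
                            break
                        used.add(key)
                        ctx = pyr_ctx if is_pyr else pur_ctx
                        alt = pyr_alt if is_pyr else pur_alt
                        rows.append((c, pos0 + 1, ctx[1], alt))
                        placed += 1
                        break
                    k -= len(positions)
        rows.sort(key=lambda r: (contigs.index(r[0]), r[1]))
        path = out_dir / f"{sid}.vcf"
        with open(path, "w") as fh:
            fh.write(header)
            for chrom, pos, ref, alt in rows:
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
        paths.append(path)

    truth = GroundTruth(
        ms_profiles=profiles.tolist(), ms_exposures=truth_exp,
        ms_channel_counts=truth_counts, seed=seed,
    )
    truth.to_json(out_dir / "truth_mutations.json")
    return paths, truth


# ---------------------------------------------------------------------------
# rearrangement cohort (BEDPE emission)


def _draw_size(rng: np.random.Generator, bin_idx: int, max_size: int) -> int:
    lo = SIZE_BIN_EDGES[bin_idx]
    hi = SIZE_BIN_EDGES[bin_idx + 1] if bin_idx + 1 < len(SIZE_BIN_EDGES) else 5e7
    hi = min(hi, max_size)
    if hi <= lo:
        raise ValueError(f"contigs too short for size bin starting at {lo:.0f} bp")
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi - 1))))


def generate_rearrangement_cohort(
    out_bedpe: str | Path,
    contig_lengths: dict[str, int] | None = None,
    n_samples: int = 92,
    events_per_sample: int = 126,
    rs_profiles: np.ndarray | None = None,
    hotspot_intervals: list[tuple[str, int, int, float]] | None = None,
    concentration: float = 0.8,
    tra_per_sample: int = 0,
    seed: int = 0,
) -> tuple[list[RearrangementRecord], GroundTruth]:
    """Emit a cohort BEDPE drawn from the rearrangement-signature mixture.

    Event categories come from the per-sample mixture; sizes are
    log-uniform within the drawn size bin; left breakpoints are uniform
    over the genome except inside ``hotspot_intervals``, whose sampling
    weight is multiplied by the stated factor. The emitted records
    round-trip through category classification to the drawn categories
    exactly.
    """
    profiles = default_rs_profiles() if rs_profiles is None else np.asarray(rs_profiles)
    contig_lengths = contig_lengths or {f"chr{i + 1}": 60_000_000 for i in range(10)}
    hotspot_intervals = hotspot_intervals or []
    for chrom, start, end, _mult in hotspot_intervals:
        if chrom not in contig_lengths or end > contig_lengths[chrom]:
            raise ValueError(f"hotspot interval {chrom}:{start}-{end} outside contigs")
    rng = np.random.default_rng(seed)

    # piecewise-constant left-breakpoint weights over contigs
    pieces: list[tuple[str, int, int, float]] = []
    for chrom, length in contig_lengths.items():
        cuts = sorted(
            {0, length}
            | {s for c, s, e, _ in hotspot_intervals if c == chrom}
            | {e for c, s, e, _ in hotspot_intervals if c == chrom}
        )
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            mult = 1.0
            for c, s, e, m in hotspot_intervals:
                if c == chrom and s <= lo and hi <= e:
                    mult = m
            pieces.append((chrom, lo, hi, mult))
    weights = np.array([(hi - lo) * m for _, lo, hi, m in pieces], dtype=float)
    weights /= weights.sum()

    exposures = draw_exposures(rng, n_samples, events_per_sample,
                               concentration, profiles.shape[1])
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    records: list[RearrangementRecord] = []
    truth_exp: dict[str, list[int]] = {}
    truth_cats: dict[str, list[int]] = {}
    max_len = max(contig_lengths.values())
    contigs = list(contig_lengths)

    for j, sid in enumerate(sample_ids):
        truth_exp[sid] = [int(x) for x in exposures[j]]
        cat_counts = np.zeros(N_CATEGORIES, dtype=np.int64)
        for s in range(profiles.shape[1]):
            n = int(exposures[j, s])
            if n > 0:
                cat_counts += rng.multinomial(n, profiles[:, s])
        truth_cats[sid] = [int(x) for x in cat_counts]
        for cat in np.nonzero(cat_counts)[0]:
            sv_type = SV_ORDER[cat // 5]
            bin_idx = cat % 5
            for _ in range(int(cat_counts[cat])):
                size = _draw_size(rng, bin_idx, max_len - 2)
                while True:
                    k = rng.choice(len(pieces), p=weights)
                    chrom, lo, hi, _m = pieces[k]
                    if contig_lengths[chrom] - size <= 1:
                        continue
                    pos1 = int(rng.integers(lo + 1, hi + 1))
                    if pos1 + size <= contig_lengths[chrom]:
                        break
                records.append(RearrangementRecord(
                    sample_id=sid, chrom1=chrom, pos1=pos1,
                    chrom2=chrom, pos2=pos1 + size, sv_type=sv_type,
                ))
        for _ in range(tra_per_sample):
            c1, c2 = rng.choice(contigs, size=2, replace=False)
            records.append(RearrangementRecord(
                sample_id=sid, chrom1=str(c1),
                pos1=int(rng.integers(1, contig_lengths[str(c1)])),
                chrom2=str(c2), pos2=int(rng.integers(1, contig_lengths[str(c2)])),
                sv_type="TRA",
            ))

    write_rearrangements(records, out_bedpe)
    truth = GroundTruth(
        rs_profiles=profiles.tolist(), rs_exposures=truth_exp,
        rs_category_counts=truth_cats,
        hotspot_intervals=[list(h) for h in hotspot_intervals], seed=seed,
    )
    truth.to_json(Path(out_bedpe).with_suffix(".truth.json"))
    return records, truth


# ---------------------------------------------------------------------------
# genomic bins, feature tracks and breakpoint background


def generate_features(
    contig_lengths: dict[str, int],
    bin_size: int = 500_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bins with three fabricated feature tracks, z-normalized.

    ``timing`` is a smooth sinusoid-like track (replication-timing
    analogue), ``repeats`` a blocky track (repeat-density analogue) and
    ``noise`` white noise.
    """
    rng = np.random.default_rng(seed)
    bins = make_bins(contig_lengths, bin_size)
    n = len(bins)
    t = np.arange(n)
    timing = np.sin(2 * np.pi * t / 37) + 0.3 * np.sin(2 * np.pi * t / 11)
    blocks = rng.choice([0.0, 1.0, 2.0], size=max(1, n // 8 + 1))
    repeats = np.repeat(blocks, 8)[:n] + rng.normal(0, 0.1, n)
    noise = rng.normal(0, 1, n)
    bins["timing"] = timing
    bins["repeats"] = repeats
    bins["noise"] = noise
    from .hotspots import normalize_features

    return normalize_features(bins, ["timing", "repeats", "noise"])


def simulate_breakpoints(
    bins: pd.DataFrame,
    feature_cols: list[str],
    m: float = 1.0,
    w: tuple[float, ...] = (0.5, -0.3, 0.0),
    dispersion: float = 0.3,
    clusters: list[tuple[str, int, int, int]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list]:
    """Draw per-bin breakpoint counts from the NB background
    b_i = exp(m + w . f_i) and scatter positions uniformly within bins;
    optionally inject ``clusters`` of (chrom, start, end, n) extra
    breakpoints placed uniformly inside each interval.

    Returns (bins with an ``observed`` column, Breakpoint list).
    """
    from .hotspots import Breakpoint

    rng = np.random.default_rng(seed)
    F = bins[feature_cols].to_numpy(dtype=float)
    mu = np.exp(m + F @ np.asarray(w, dtype=float)[: F.shape[1]])
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    positions: dict[str, list[int]] = {}
    for (chrom, start, end), c in zip(
        bins[["chrom", "start", "end"]].itertuples(index=False, name=None), counts
    ):
        if c > 0:
            positions.setdefault(chrom, []).extend(
                int(p) for p in rng.integers(start + 1, end + 1, size=c)
            )
    for chrom, start, end, n_extra in clusters or []:
        positions.setdefault(chrom, []).extend(
            int(p) for p in rng.integers(start + 1, end + 1, size=n_extra)
        )
    breakpoints = []
    for chrom in sorted(positions):
        prev = None
        for pos in sorted(positions[chrom]):
            imd = None if prev is None else pos - prev
            breakpoints.append(Breakpoint(chrom=chrom, pos=pos, sample_id="sim", imd=imd))
            prev = pos
    if clusters:
        # cluster breakpoints must show up in the per-bin counts too
        from .hotspots import count_breakpoints

        out = count_breakpoints(bins, breakpoints)
    else:
        out = bins.copy()
        out["observed"] = counts
    return out, breakpoints


# ---------------------------------------------------------------------------
# phenotypes


DEFAULT_TIL_TYPES = ("B_cell", "CD4_T", "CD8_T", "neutrophil", "macrophage", "dendritic")


def generate_phenotypes(
    contributions: pd.DataFrame,
    driver_intercept: float = -2.5,
    driver_slope: float = 5.0,
    n_fusions: int = 6,
    fusion_enrichment: float = 4.6,
    til_coupling: dict[str, tuple[str, float]] | None = None,
    til_noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Cohort table with phenotypes coupled to signature contributions.

    ``contributions``: signatures x samples (columns sum to 1); the last
    row plays the diffuse-signature role. Driver status is Bernoulli with
    logit linear in that contribution; each of ``n_fusions`` fusion
    carriers falls in the top contribution decile with probability
    ``fusion_enrichment`` times the decile's share of samples
    (``fusion_enrichment=1`` is uniform placement); TIL abundances are
    linear in a chosen signature's contribution plus truncated Gaussian
    noise.
    """
    rng = np.random.default_rng(seed)
    samples = list(contributions.columns)
    n = len(samples)
    sig_names = list(contributions.index)
    focal = sig_names[-1]
    c_focal = contributions.loc[focal].to_numpy(dtype=float)

    driver_p = expit(driver_intercept + driver_slope * c_focal)
    driver = rng.random(n) < driver_p

    decile_cut = np.quantile(c_focal, 0.9)
    top = np.where(c_focal >= decile_cut)[0]
    rest = np.where(c_focal < decile_cut)[0]
    p_top = min(1.0, fusion_enrichment * len(top) / n)
    fusion = np.zeros(n, dtype=bool)
    pool_top = list(rng.permutation(top))
    pool_rest = list(rng.permutation(rest))
    carriers: list[int] = []
    while len(carriers) < min(n_fusions, n):
        if pool_top and (rng.random() < p_top or not pool_rest):
            carriers.append(int(pool_top.pop()))
        else:
            carriers.append(int(pool_rest.pop()))
    fusion[carriers] = True

    til_coupling = til_coupling or {"B_cell": (focal, 0.6), "CD4_T": (focal, 0.4)}
    tils = {}
    for ct in DEFAULT_TIL_TYPES:
        base = 0.2 + rng.normal(0, til_noise_sd, n)
        if ct in til_coupling:
            sig, coef = til_coupling[ct]
            base = base + coef * contributions.loc[sig].to_numpy(dtype=float)
        tils[f"til_{ct}"] = np.maximum(base, 0.0)

    # histology coupled to the focal vs smoking-like contrast, smoking to MS2
    c2 = contributions.iloc[1].to_numpy(dtype=float) if len(sig_names) > 1 else 0.0
    histology = np.where(rng.random(n) < expit(0.3 + 2.0 * (c_focal - c2)), "AD", "SCC")
    smoking = np.where(rng.random(n) < expit(-0.5 + 2.5 * c2), "smoker", "never")
    sex = np.where(rng.random(n) < 0.5, "F", "M")

    cohort = pd.DataFrame({
        "sample_id": samples,
        "histology": histology,
        "smoking": smoking,
        "sex": sex,
        "driver_status": driver.astype(int),
        "fusion_status": fusion.astype(int),
        **{k: v for k, v in tils.items()},
    })
    truth = GroundTruth(
        phenotype_model={
            "driver_intercept": driver_intercept, "driver_slope": driver_slope,
            "n_fusions": n_fusions, "fusion_enrichment": fusion_enrichment,
            "focal_signature": focal,
        },
        til_model={ct: list(v) for ct, v in til_coupling.items()},
        seed=seed,
    )
    return cohort, truth
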