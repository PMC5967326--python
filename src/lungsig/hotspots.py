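"""Rearrangement breakpoint hotspots.

Both ends of every rearrangement contribute a breakpoint. Breakpoints are
sorted per chromosome and each gets an inter-rearrangement distance (IMD):
the distance to the breakpoint immediately preceding it (the first
breakpoint of a chromosome has no IMD). Piecewise-constant fitting (PCF)
segments the ordered log10(IMD) sequence into constant-mean stretches; a
segment is a putative hotspot when

  (a) its mean IMD is at most half the genome-wide mean IMD, i.e. its
      breakpoint density is at least twice the genome-wide level, and
  (b) its observed breakpoint count exceeds the count expected from a
      negative-binomial background model fitted on 0.5-Mb genomic bins
      with z-normalized feature tracks:  b_i = exp(m + sum_k w_k f_ik).

The PCF here is the exact minimizer (dynamic program) of

    sum_segments SSE(segment) + gamma * (#segments)

subject to every segment containing at least k_min values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .io_formats import RearrangementRecord

logger = logging.getLogger(__name__)

BIN_SIZE_DEFAULT = 500_000


@dataclass
class PCFParams:
    """Segmentation parameters; i is carried for config compatibility but
    unused by the exact dynamic program."""

    gamma: float = 8.0
    kmin: int = 8
    i: int = 2

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.kmin < 2:
            raise ValueError("kmin must be >= 2")


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int
    sample_id: str
    imd: int | None  # None for the first breakpoint of a chromosome


@dataclass
class Segment:
    chrom: str
    start_idx: int   # index into the chromosome's breakpoint list
    end_idx: int     # inclusive
    mean_log_imd: float


@dataclass
class BackgroundModel:
    """Negative-binomial (log link) background for per-bin breakpoint counts.

    ``expected(f) = exp(m + w . f)``; dispersion alpha parameterizes
    Var = mu + alpha * mu^2 (alpha -> 0 is the Poisson limit).
    """

    m: float
    w: np.ndarray
    dispersion: float
    feature_names: list[str] = field(default_factory=list)
    family: str = "negative_binomial"

    def expected(self, features: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(features, dtype=float))
        if f.shape[1] != len(self.w):
            raise ValueError(f"feature length {f.shape[1]} != {len(self.w)}")
        return np.exp(self.m + f @ self.w)

    def tail_probability(self, observed: float, expected: float) -> float:
        """P(X >= observed) under the fitted count distribution."""
        k = int(np.ceil(observed))
        if self.dispersion <= 1e-8:
            return float(st.poisson.sf(k - 1, expected))
        n = 1.0 / self.dispersion
        p = n / (n + expected)
        return float(st.nbinom.sf(k - 1, n, p))


@dataclass
class Hotspot:
    chrom: str
    start: int
    end: int
    n_breakpoints: int
    mean_imd: float
    expected_count: float
    density_ratio: float
    tail_probability: float
    q_value: float = np.nan


def compute_imd(records: Iterable[RearrangementRecord]) -> list[Breakpoint]:
    """Collect both breakpoints of every rearrangement (translocations
    included) and compute per-chromosome IMDs after sorting by position."""
    raw: list[tuple[str, int, str]] = []
    for rec in records:
        raw.append((rec.chrom1, rec.pos1, rec.sample_id))
        raw.append((rec.chrom2, rec.pos2, rec.sample_id))
    out: list[Breakpoint] = []
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, pos, sid in raw:
        by_chrom.setdefault(chrom, []).append((pos, sid))
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom])
        prev: int | None = None
        for pos, sid in entries:
            imd = None if prev is None else pos - prev
            out.append(Breakpoint(chrom=chrom, pos=pos, sample_id=sid, imd=imd))
            prev = pos
    return out


def pcf_segment(values: Sequence[float], params: PCFParams) -> list[tuple[int, int, float]]:
    """Exact penalized least-squares segmentation.

    Returns (start_idx, end_idx_inclusive, mean) triples partitioning the
    sequence, minimizing total within-segment SSE + gamma per segment with
    every segment at least ``kmin`` long. Sequences shorter than ``kmin``
    come back as a single segment.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    n = len(v)
    if n == 0:
        return []
    if n < params.kmin:
        return [(0, n - 1, float(v.mean()))]

    csum = np.concatenate([[0.0], np.cumsum(v)])
    csq = np.concatenate([[0.0], np.cumsum(v * v)])

    def sse(i: int, j: int) -> float:
        # SSE of v[i:j] (half-open), O(1) via prefix sums
        s = csum[j] - csum[i]
        q = csq[j] - csq[i]
        return q - s * s / (j - i)

    kmin = params.kmin
    INF = np.inf
    cost = np.full(n + 1, INF)
    back = np.full(n + 1, -1, dtype=int)
    cost[0] = 0.0
    for j in range(kmin, n + 1):
        # last segment is v[i:j] with j - i >= kmin
        for i in range(0, j - kmin + 1):
            if cost[i] == INF:
                continue
            c = cost[i] + sse(i, j) + params.gamma
            if c < cost[j]:
                cost[j] = c
                back[j] = i
    segments: list[tuple[int, int, float]] = []
    j = n
    while j > 0:
        i = int(back[j])
        segments.append((i, j - 1, float((csum[j] - csum[i]) / (j - i))))
        j = i
    segments.reverse()
    return segments


def make_bins(contig_lengths: dict[str, int], bin_size: int = BIN_SIZE_DEFAULT) -> pd.DataFrame:
    """Non-overlapping genomic bins (0-based half-open) covering each contig."""
    rows = []
    for chrom, length in contig_lengths.items():
        for start in range(0, length, bin_size):
            rows.append((chrom, start, min(start + bin_size, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def normalize_features(bins: pd.DataFrame, feature_cols: Sequence[str]) -> pd.DataFrame:
    """Z-normalize each feature to mean 0, sd 1 across bins."""
    out = bins.copy()
    for col in feature_cols:
        x = out[col].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"feature {col!r} is constant; cannot z-normalize")
        out[col] = (x - x.mean()) / sd
    return out


def count_breakpoints(bins: pd.DataFrame, breakpoints: Sequence[Breakpoint]) -> pd.DataFrame:
    """Attach an ``observed`` breakpoint count column to the bin table."""
    out = bins.copy()
    out["observed"] = 0
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom, grp in pd.DataFrame(
        [(b.chrom, b.pos) for b in breakpoints], columns=["chrom", "pos"]
    ).groupby("chrom"):
        pos_by_chrom[chrom] = np.sort(grp["pos"].to_numpy())
    for chrom, idx in out.groupby("chrom").groups.items():
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            continue
        starts = out.loc[idx, "start"].to_numpy()
        ends = out.loc[idx, "end"].to_numpy()
        # breakpoint pos is 1-based: bin [start, end) covers pos in (start, end]
        out.loc[idx, "observed"] = (
            np.searchsorted(pos, ends, side="right")
            - np.searchsorted(pos, starts, side="right")
        )
    return out


def fit_background(
    bins: pd.DataFrame,
    feature_cols: Sequence[str],
    observed_col: str = "observed",
) -> BackgroundModel:
    """Maximum-likelihood negative-binomial regression of per-bin counts
    on z-normalized features (log link, NB2 variance).

    Falls back to Poisson when the dispersion estimate collapses to zero
    or the NB fit fails to converge (logged).
    """
    clean = bins.dropna(subset=list(feature_cols))
    n_dropped = len(bins) - len(clean)
    if n_dropped:
        logger.info("dropped %d bins with undefined features", n_dropped)
    y = clean[observed_col].to_numpy(dtype=float)
    X = sm.add_constant(clean[list(feature_cols)].to_numpy(dtype=float))
    if len(y) < 10 * len(feature_cols):
        raise ValueError(f"need >= {10 * len(feature_cols)} bins, got {len(y)}")
    try:
        res = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
        alpha = float(res.params[-1])
        if not res.mle_retvals.get("converged", False) or not np.isfinite(alpha):
            raise RuntimeError("NB fit did not converge")
        if alpha <= 1e-6:
            raise RuntimeError("dispersion collapsed to zero")
        coefs = res.params[:-1]
        family = "negative_binomial"
    except Exception as exc:
        logger.info("falling back to Poisson background: %s", exc)
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        coefs = res.params
        alpha = 0.0
        family = "poisson"
    return BackgroundModel(
        m=float(coefs[0]), w=np.asarray(coefs[1:], dtype=float), dispersion=alpha,
        feature_names=list(feature_cols), family=family,
    )


def expected_breakpoints(model: BackgroundModel, features: Sequence[float]) -> float:
    """Expected breakpoint count b = exp(m + sum_k w_k f_k) for one bin."""
    return float(model.expected(np.asarray(features, dtype=float))[0])


def _expected_in_interval(
    model: BackgroundModel, bins: pd.DataFrame, chrom: str, start: int, end: int
) -> float:
    """Summed background expectation of every bin overlapping
    [start, end] (1-based inclusive). Whole bins are summed, which makes
    the hotspot criterion conservative for regions smaller than a bin."""
    sub = bins[bins["chrom"] == chrom]
    if sub.empty:
        return 0.0
    b_start = sub["start"].to_numpy()
    b_end = sub["end"].to_numpy()
    mask = (np.minimum(b_end, end) - np.maximum(b_start, start - 1)) > 0
    if not mask.any():
        return 0.0
    feats = sub.loc[mask, model.feature_names].to_numpy(dtype=float)
    return float(model.expected(feats).sum())


def call_hotspots(
    breakpoints: Sequence[Breakpoint],
    model: BackgroundModel,
    bins: pd.DataFrame,
    params: PCFParams | None = None,
) -> list[Hotspot]:
    """Segment per-chromosome log10(IMD) and call hotspot segments.

    A segment qualifies when its mean IMD is at most half the genome-wide
    mean IMD and its breakpoint count exceeds the feature-adjusted
    background expectation. The NB tail probability of each qualifying
    segment is reported with a Benjamini-Hochberg q-value across segments.
    """
    params = params or PCFParams()
    imds_all = np.array([b.imd for b in breakpoints if b.imd is not None], dtype=float)
    if imds_all.size == 0:
        return []
    genome_mean_imd = float(imds_all.mean())

    by_chrom: dict[str, list[Breakpoint]] = {}
    for b in breakpoints:
        by_chrom.setdefault(b.chrom, []).append(b)

    candidates: list[Hotspot] = []
    all_segments: list[Hotspot] = []
    for chrom in sorted(by_chrom):
        bps = sorted(by_chrom[chrom], key=lambda b: b.pos)
        with_imd = [b for b in bps if b.imd is not None]
        if len(with_imd) < params.kmin:
            continue
        log_imd = np.log10(np.maximum([b.imd for b in with_imd], 1.0))
        for s_idx, e_idx, _mean in pcf_segment(log_imd, params):
            seg_bps = with_imd[s_idx : e_idx + 1]
            # region runs from the anchor breakpoint (the one preceding the
            # first IMD of the segment) to the last breakpoint
            anchor_pos = seg_bps[0].pos - seg_bps[0].imd
            start, end = anchor_pos, seg_bps[-1].pos
            n_bp = len(seg_bps) + 1
            mean_imd = float(np.mean([b.imd for b in seg_bps]))
            expected = _expected_in_interval(model, bins, chrom, start, end)
            hs = Hotspot(
                chrom=chrom, start=start, end=end, n_breakpoints=n_bp,
                mean_imd=mean_imd, expected_count=expected,
                density_ratio=genome_mean_imd / mean_imd if mean_imd > 0 else np.inf,
                tail_probability=model.tail_probability(n_bp, expected)
                if expected > 0 else np.nan,
            )
            all_segments.append(hs)
            if mean_imd <= genome_mean_imd / 2 and n_bp > expected and n_bp >= params.kmin:
                candidates.append(hs)

    if candidates:
        from .stats import bh_fdr

        pvals = np.array([h.tail_probability for h in candidates], dtype=float)
        finite = np.isfinite(pvals)
        qvals = np.full_like(pvals, np.nan)
        if finite.any():
            qvals[finite] = bh_fdr(pvals[finite])
        for h, q in zip(candidates, qvals):
            h.q_value = float(q)
    return candidates


def hotspots_to_frame(hotspots: Sequence[Hotspot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": h.chrom, "start": h.start, "end": h.end,
                "n_breakpoints": h.n_breakpoints, "mean_imd": h.mean_imd,
                "expected_count": h.expected_count,
                "density_ratio": h.density_ratio,
                "tail_probability": h.tail_probability, "q_value": h.q_value,
            }
            for h in hotspots
        ]
    )
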