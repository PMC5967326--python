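"""Signature extraction by non-negative matrix factorization.

A catalog V (channels x samples) of mutation or rearrangement counts is
factorized as V ~ W H with W >= 0 (channels x rank, the signature
profiles) and H >= 0 (rank x samples, the exposures). The objective is the
generalized Kullback-Leibler divergence

    D(V || WH) = sum_ij V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij,

the Poisson log-likelihood up to a constant, which is the natural fit
criterion for count catalogs. Optimization uses the classical
multiplicative updates, which never increase D; the best of several
random restarts is kept. Profiles are rescaled to column sum 1 with a
compensating rescale of the exposures, so an exposure is measured in
mutations (or rearrangements) attributed to that signature.

A sample's *contribution* vector is its exposure column normalized to sum
1, and a sample is *dominant* for a signature when that signature's
contribution strictly exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EPS = np.finfo(np.float64).tiny


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH); 0 iff V == WH."""
    mask = V > 0
    term = np.zeros_like(WH)
    term[mask] = V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))
    return float(term.sum() - V.sum() + WH.sum())


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two non-negative profile vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


@dataclass
class SignatureModel:
    """Result of one NMF factorization of a catalog."""

    profiles: np.ndarray        # channels x rank, columns sum to 1
    exposures: np.ndarray       # rank x samples, >= 0
    rank: int
    divergence: float
    n_iter: int = 0
    converged: bool = True
    sample_ids: list[str] = field(default_factory=list)
    signature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.signature_names:
            self.signature_names = [f"S{i + 1}" for i in range(self.rank)]

    def reconstruction(self) -> np.ndarray:
        return self.profiles @ self.exposures

    def contributions(self) -> np.ndarray:
        """Rank x samples matrix of per-sample signature contributions.

        Each column sums to 1; columns of all-zero exposure are NaN
        (flagged undefined).
        """
        totals = self.exposures.sum(axis=0)
        out = np.full_like(self.exposures, np.nan, dtype=float)
        ok = totals > 0
        out[:, ok] = self.exposures[:, ok] / totals[ok]
        return out

    def contributions_frame(self) -> pd.DataFrame:
        cols = self.sample_ids or [f"sample{i}" for i in range(self.exposures.shape[1])]
        return pd.DataFrame(self.contributions(), index=self.signature_names, columns=cols)


def _multiplicative_updates(
    V: np.ndarray, W: np.ndarray, H: np.ndarray, max_iter: int, tol: float,
    check_every: int = 10,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    prev = kl_divergence(V, W @ H)
    div = prev
    converged = False
    it = 0
    ones = np.ones_like(V)
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.T @ ones, _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(ones @ H.T, _EPS)
        if it % check_every == 0 or it == max_iter:
            div = kl_divergence(V, W @ H)
            denom = max(abs(prev), 1.0)
            if abs(prev - div) / denom < tol:
                converged = True
                break
            prev = div
    return W, H, div, it, converged


def _normalize(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    return W / scale, H * scale[:, None]


def extract_signatures(
    catalog: np.ndarray,
    rank: int,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-8,
    sample_ids: list[str] | None = None,
) -> SignatureModel:
    """Best-of-restarts KL-NMF factorization of a channels x samples catalog.

    Deterministic given ``seed``: each restart draws its initialization from
    an independent child of ``numpy.random.SeedSequence(seed)``.
    """
    V = np.asarray(catalog, dtype=float)
    if V.ndim != 2:
        raise ValueError("catalog must be 2-D (channels x samples)")
    if (V < 0).any():
        raise ValueError("catalog must be non-negative")
    if V.sum() == 0:
        raise ValueError("all-zero catalog cannot be factorized")
    if (V.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one positive entry")
    n_channels, n_samples = V.shape
    if not (1 <= rank < min(n_channels, n_samples)):
        raise ValueError(f"rank {rank} outside [1, {min(n_channels, n_samples) - 1}]")

    mean = V.mean()
    best: tuple[float, np.ndarray, np.ndarray, int, bool] | None = None
    for child in np.random.SeedSequence(seed).spawn(restarts):
        rng = np.random.default_rng(child)
        W0 = rng.uniform(0.1, 1.0, size=(n_channels, rank)) * np.sqrt(mean / rank)
        H0 = rng.uniform(0.1, 1.0, size=(rank, n_samples)) * np.sqrt(mean / rank)
        W, H, div, it, conv = _multiplicative_updates(V, W0, H0, max_iter, tol)
        if best is None or div < best[0]:
            best = (div, W, H, it, conv)
    div, W, H, it, conv = best
    if not conv:
        import logging

        logging.getLogger(__name__).warning(
            "NMF did not converge within %d iterations (divergence %.6g)", max_iter, div
        )
    W, H = _normalize(W, H)
    return SignatureModel(
        profiles=W, exposures=H, rank=rank, divergence=div, n_iter=it,
        converged=conv, sample_ids=list(sample_ids or []),
    )


def match_signatures(reference: np.ndarray, candidate: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy maximum-cosine pairing of candidate columns to reference columns.

    Returns (reference column, candidate column, cosine) triples, one per
    reference column. Adequate for the small ranks (<= 5) used here.
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    sims = np.zeros((ref.shape[1], cand.shape[1]))
    for i in range(ref.shape[1]):
        for j in range(cand.shape[1]):
            sims[i, j] = cosine_similarity(ref[:, i], cand[:, j])
    pairs: list[tuple[int, int, float]] = []
    used_r: set[int] = set()
    used_c: set[int] = set()
    flat = sorted(
        ((sims[i, j], i, j) for i in range(sims.shape[0]) for j in range(sims.shape[1])),
        reverse=True,
    )
    for s, i, j in flat:
        if i in used_r or j in used_c:
            continue
        pairs.append((i, j, s))
        used_r.add(i)
        used_c.add(j)
        if len(pairs) == min(sims.shape):
            break
    return sorted(pairs)


def select_rank(
    catalog: np.ndarray,
    candidate_ranks: list[int],
    restarts: int = 20,
    seed: int = 0,
    stability_threshold: float = 0.9,
    distinctness_threshold: float = 0.95,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> tuple[int, pd.DataFrame]:
    """Choose the factorization rank by restart stability.

    For each candidate rank, all restarts are matched to the best-fit
    solution by greedy cosine assignment. Each signature's reproducibility
    is its mean matched cosine across restarts; the rank's *stability* is
    the minimum reproducibility over its signatures, so one spurious
    component disqualifies the rank. A rank is also disqualified when its
    best solution contains two near-duplicate signatures (pairwise cosine
    above ``distinctness_threshold``), the overfitting mode of degenerate
    catalogs. The chosen rank is the largest candidate that is both stable
    and distinct; the returned table reports every quantity per rank.
    """
    if not candidate_ranks:
        raise ValueError("candidate_ranks must be non-empty")
    V = np.asarray(catalog, dtype=float)
    rows = []
    for rank in candidate_ranks:
        if rank == 1:
            model = extract_signatures(V, 1, restarts=1, seed=seed,
                                       max_iter=max_iter, tol=tol)
            rows.append({"rank": 1, "divergence": model.divergence,
                         "stability": 1.0, "mean_cosine": 1.0,
                         "max_inter_cosine": 0.0})
            continue
        solutions = []
        for child in np.random.SeedSequence((seed, rank)).spawn(restarts):
            child_seed = int(child.generate_state(1)[0] % (2**31))
            m = extract_signatures(V, rank, restarts=1, seed=child_seed,
                                   max_iter=max_iter, tol=tol)
            solutions.append(m)
        best = min(solutions, key=lambda m: m.divergence)
        per_signature: list[list[float]] = [[] for _ in range(rank)]
        for m in solutions:
            if m is best:
                continue
            for i, _j, s in match_signatures(best.profiles, m.profiles):
                per_signature[i].append(s)
        repro = [float(np.mean(c)) if c else 1.0 for c in per_signature]
        inter = max(
            cosine_similarity(best.profiles[:, i], best.profiles[:, j])
            for i in range(rank) for j in range(i + 1, rank)
        )
        rows.append({
            "rank": rank, "divergence": best.divergence,
            "stability": float(np.min(repro)),
            "mean_cosine": float(np.mean([s for c in per_signature for s in c]) if any(per_signature) else 1.0),
            "max_inter_cosine": float(inter),
        })
    table = pd.DataFrame(rows)
    eligible = table[
        (table["stability"] >= stability_threshold)
        & (table["max_inter_cosine"] <= distinctness_threshold)
    ]
    chosen = int(eligible["rank"].max()) if len(eligible) else int(table["rank"].min())
    return chosen, table


def dominant_signature(contrib: np.ndarray, threshold: float = 0.5,
                       names: list[str] | None = None) -> str:
    """Label of the unique signature with contribution strictly above the
    threshold, else ``"none"``. A sample at exactly the threshold is not
    dominant."""
    contrib = np.asarray(contrib, dtype=float)
    if np.isnan(contrib).any():
        return "none"
    idx = int(np.argmax(contrib))
    if contrib[idx] > threshold:
        return names[idx] if names else f"S{idx + 1}"
    return "none"


def dominance_labels(model: SignatureModel, threshold: float = 0.5) -> pd.Series:
    contrib = model.contributions()
    cols = model.sample_ids or [f"sample{i}" for i in range(contrib.shape[1])]
    labels = [
        dominant_signature(contrib[:, j], threshold, model.signature_names)
        for j in range(contrib.shape[1])
    ]
    return pd.Series(labels, index=cols, name="dominant_signature")
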