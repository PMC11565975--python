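"""Cosine and modified-cosine spectral similarity and greedy clustering.

Scores follow the molecular-networking convention: intensities are
square-root scaled then L2-normalized per spectrum, and the score is the sum
of products over a one-to-one peak pairing within a fragment m/z tolerance.
The modified cosine additionally admits pairs offset by the precursor mass
difference, so a headgroup reference spectrum can be compared against its
acyl conjugates.  Pairing is greedy best-pairs-first by default; an exact
maximum-weight assignment is available behind ``pairing="exact"``.

Clustering is a deterministic single-pass merge of near-identical spectra
(the de-duplication step of library construction): spectra are visited in
canonical (precursor, identifier) order and join the first cluster whose
consensus they match; clusters below ``min_cluster_size`` are reported
separately and excluded from the kept set, implementing the
"observed at least twice" rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra_io import Spectrum

__all__ = [
    "SimilarityResult",
    "SpectrumCluster",
    "ClusteringResult",
    "cosine",
    "modified_cosine",
    "consensus_spectrum",
    "cluster_spectra",
]

Scaling = Literal["sqrt", "raw"]
Pairing = Literal["greedy", "exact"]


@dataclass(frozen=True)
class SimilarityResult:
    score: float
    matched_peaks: int
    pairing: tuple[tuple[int, int, bool], ...]  # (index in a, index in b, shifted)


def _weights(s: Spectrum, scaling: Scaling) -> np.ndarray:
    w = np.sqrt(s.intensities) if scaling == "sqrt" else s.intensities.astype(float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("spectrum has zero total intensity")
    return w / norm


def _candidate_pairs(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float,
    wa: np.ndarray,
    wb: np.ndarray,
    shift: float | None,
) -> list[tuple[float, int, int, bool]]:
    """(weight, i, j, shifted) for every peak pair within tolerance.

    When a pair qualifies both directly and via the precursor-difference
    shift it is recorded once, as unshifted.
    """
    pairs: dict[tuple[int, int], tuple[float, bool]] = {}
    offsets: list[tuple[float, bool]] = [(0.0, False)]
    if shift is not None and abs(shift) > 0:
        offsets.append((shift, True))
    for delta, shifted in offsets:
        # peak i in a pairs with peak j in b when mz_a ~= mz_b + delta
        lo = np.searchsorted(b.mz, a.mz - delta - frag_tol, side="left")
        hi = np.searchsorted(b.mz, a.mz - delta + frag_tol, side="right")
        for i in range(len(a)):
            for j in range(lo[i], hi[i]):
                key = (i, int(j))
                if key not in pairs:
                    pairs[key] = (float(wa[i] * wb[j]), shifted)
    return [(w, i, j, s) for (i, j), (w, s) in pairs.items()]


def _pair_greedy(
    pairs: list[tuple[float, int, int, bool]]
) -> list[tuple[int, int, bool]]:
    chosen: list[tuple[int, int, bool]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for w, i, j, shifted in sorted(pairs, key=lambda p: (-p[0], p[1], p[2])):
        if i not in used_a and j not in used_b:
            chosen.append((i, j, shifted))
            used_a.add(i)
            used_b.add(j)
    return chosen


def _pair_exact(
    pairs: list[tuple[float, int, int, bool]]
) -> list[tuple[int, int, bool]]:
    """Maximum-total-weight one-to-one pairing via the assignment problem."""
    if not pairs:
        return []
    a_idx = sorted({i for _, i, _, _ in pairs})
    b_idx = sorted({j for _, _, j, _ in pairs})
    a_pos = {i: k for k, i in enumerate(a_idx)}
    b_pos = {j: k for k, j in enumerate(b_idx)}
    cost = np.zeros((len(a_idx), len(b_idx)))
    flag = {}
    for w, i, j, shifted in pairs:
        cost[a_pos[i], b_pos[j]] = -w
        flag[(i, j)] = shifted
    rows, cols = linear_sum_assignment(cost)
    out = []
    for r, c in zip(rows, cols):
        if cost[r, c] < 0:  # only pairs that were actually within tolerance
            i, j = a_idx[r], b_idx[c]
            out.append((i, j, flag[(i, j)]))
    return sorted(out)


def _score(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float,
    min_matched: int,
    scaling: Scaling,
    pairing: Pairing,
    shift: float | None,
) -> SimilarityResult:
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot score an empty spectrum")
    wa, wb = _weights(a, scaling), _weights(b, scaling)
    pairs = _candidate_pairs(a, b, frag_tol, wa, wb, shift)
    chosen = _pair_exact(pairs) if pairing == "exact" else _pair_greedy(pairs)
    score = float(sum(wa[i] * wb[j] for i, j, _ in chosen))
    score = min(score, 1.0)  # guard against fp roundoff at identity
    if len(chosen) < min_matched:
        score = 0.0
    return SimilarityResult(
        score=score, matched_peaks=len(chosen), pairing=tuple(sorted(chosen))
    )


def cosine(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float = 0.02,
    min_matched: int = 1,
    scaling: Scaling = "sqrt",
    pairing: Pairing = "greedy",
) -> SimilarityResult:
    """Plain cosine: peaks pair only at equal m/z (within tolerance).

    The score is forced to 0 when fewer than ``min_matched`` peak pairs are
    found, mirroring library-search minimum-matched-fragment settings.
    """
    return _score(a, b, frag_tol, min_matched, scaling, pairing, shift=None)


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float = 0.02,
    min_matched: int = 1,
    scaling: Scaling = "sqrt",
    pairing: Pairing = "greedy",
) -> SimilarityResult:
    """Cosine that also pairs peaks offset by the precursor m/z difference."""
    shift = a.precursor_mz - b.precursor_mz
    return _score(a, b, frag_tol, min_matched, scaling, pairing, shift=shift)


def consensus_spectrum(
    members: Sequence[Spectrum], frag_tol: float = 0.02
) -> Spectrum:
    """Merge member spectra: peaks within ``frag_tol`` are collapsed to their
    intensity-weighted mean m/z with summed intensity, rescaled to max 1.

    The consensus precursor is the (total-)intensity-weighted mean of the
    member precursors.  Deterministic for a fixed member order.
    """
    if not members:
        raise ValueError("empty member list")
    all_mz = np.concatenate([m.mz for m in members])
    all_int = np.concatenate([m.intensities for m in members])
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int = all_mz[order], all_int[order]

    merged_mz: list[float] = []
    merged_int: list[float] = []
    g_mz_sum = g_int = 0.0
    g_mean = None
    for mz, inten in zip(all_mz, all_int):
        if g_mean is not None and mz - g_mean <= frag_tol:
            g_mz_sum += mz * inten
            g_int += inten
            g_mean = g_mz_sum / g_int if g_int > 0 else mz
        else:
            if g_mean is not None:
                merged_mz.append(g_mean)
                merged_int.append(g_int)
            g_mz_sum, g_int = mz * inten, inten
            g_mean = g_mz_sum / g_int if g_int > 0 else mz
    if g_mean is not None:
        merged_mz.append(g_mean)
        merged_int.append(g_int)

    inten = np.asarray(merged_int)
    if inten.size and inten.max() > 0:
        inten = inten / inten.max()
    totals = np.array([m.intensities.sum() for m in members])
    if totals.sum() > 0:
        prec = float(np.average([m.precursor_mz for m in members], weights=totals))
    else:
        prec = float(np.mean([m.precursor_mz for m in members]))
    return Spectrum(
        precursor_mz=prec,
        mz=np.asarray(merged_mz),
        intensities=inten,
        charge=members[0].charge,
        identifier=f"consensus::{members[0].identifier}",
        source_file=members[0].source_file,
    )


@dataclass
class SpectrumCluster:
    members: list[str]
    consensus: Spectrum
    annotation: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusteringResult:
    kept: list[SpectrumCluster]
    discarded: list[SpectrumCluster]

    @property
    def total_members(self) -> int:
        return sum(c.size for c in self.kept) + sum(c.size for c in self.discarded)


def cluster_spectra(
    spectra: Iterable[Spectrum],
    precursor_tol: float = 0.02,
    score_threshold: float = 0.95,
    min_cluster_size: int = 2,
    frag_tol: float = 0.02,
    scaling: Scaling = "raw",
) -> ClusteringResult:
    """Greedy single-pass clustering of near-identical spectra.

    Spectra are sorted by (precursor m/z, identifier); each joins the first
    existing cluster with a compatible consensus precursor and cosine score
    at or above ``score_threshold``, else seeds a new cluster.  Clusters
    smaller than ``min_cluster_size`` go to ``discarded``.

    De-duplication compares raw intensity patterns by default: replicate
    acquisitions of one compound should agree in their dominant peaks, and
    the square-root compression used for cross-compound library matching
    would let low-level background peaks erode that agreement.
    """
    ordered = sorted(spectra, key=lambda s: (s.precursor_mz, s.identifier))
    clusters: list[tuple[SpectrumCluster, list[Spectrum]]] = []
    for s in ordered:
        placed = False
        for cluster, member_spectra in clusters:
            if abs(cluster.consensus.precursor_mz - s.precursor_mz) > precursor_tol:
                continue
            if len(s) == 0:
                continue
            sim = cosine(
                cluster.consensus, s, frag_tol=frag_tol, min_matched=1,
                scaling=scaling,
            )
            if sim.score >= score_threshold:
                cluster.members.append(s.identifier)
                member_spectra.append(s)
                cluster.consensus = consensus_spectrum(member_spectra, frag_tol)
                placed = True
                break
        if not placed:
            clusters.append(
                (
                    SpectrumCluster(
                        members=[s.identifier],
                        consensus=consensus_spectrum([s], frag_tol),
                    ),
                    [s],
                )
            )
    kept = [c for c, _ in clusters if c.size >= min_cluster_size]
    discarded = [c for c, _ in clusters if c.size < min_cluster_size]
    return ClusteringResult(kept=kept, discarded=discarded)
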