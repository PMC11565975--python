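"""Cosine/modified-cosine scoring, pairing oracles, consensus, clustering."""

import math

import numpy as np
import pytest

from nacyl.similarity import (
    cluster_spectra,
    consensus_spectrum,
    cosine,
    modified_cosine,
)
from nacyl.spectra_io import Spectrum

from oracles import best_pairing_score


def spec(peaks, prec=500.0, ident="s"):
    mz, inten = zip(*peaks)
    return Spectrum(
        precursor_mz=prec,
        mz=np.asarray(mz, dtype=float),
        intensities=np.asarray(inten, dtype=float),
        identifier=ident,
    )


def random_spectrum(rng, n_peaks, prec=None):
    n = int(rng.integers(2, n_peaks + 1))
    mz = np.sort(rng.uniform(60, 480, size=n))
    inten = rng.uniform(1, 1000, size=n)
    prec = prec if prec is not None else float(rng.uniform(200, 600))
    return Spectrum(precursor_mz=prec, mz=mz, intensities=inten)


def test_self_similarity_is_one():
    s = spec([(100, 10), (200, 30), (300, 5)])
    r = cosine(s, s, min_matched=1)
    assert r.score == pytest.approx(1.0, abs=1e-12)
    assert r.matched_peaks == 3


def test_disjoint_spectra_score_zero():
    a = spec([(100, 10), (200, 10)])
    b = spec([(150, 10), (250, 10)])
    assert cosine(a, b).score == 0.0


def test_hand_computed_half():
    """A={100,200}, B={100,300}, unit intensities: dot = 1/sqrt2 * 1/sqrt2."""
    a = spec([(100, 1), (200, 1)])
    b = spec([(100, 1), (300, 1)])
    r = cosine(a, b, min_matched=1)
    assert r.score == pytest.approx(0.5, abs=1e-12)
    assert r.matched_peaks == 1


def test_min_matched_zeroes_score():
    a = spec([(100, 1), (200, 1)])
    b = spec([(100, 1), (300, 1)])
    assert cosine(a, b, min_matched=2).score == 0.0


def test_cosine_symmetry(rng):
    for _ in range(20):
        a, b = random_spectrum(rng, 8), random_spectrum(rng, 8)
        assert cosine(a, b).score == pytest.approx(cosine(b, a).score, abs=1e-12)


def test_empty_spectrum_errors():
    a = spec([(100, 1)])
    empty = Spectrum(precursor_mz=10.0, mz=np.empty(0), intensities=np.empty(0))
    with pytest.raises(ValueError):
        cosine(a, empty)


def test_modified_cosine_pure_shift():
    """A spectrum shifted wholesale (peaks + precursor) still scores 1."""
    a = spec([(100, 10), (200, 30), (300, 5)], prec=400.0)
    delta = 14.0157
    b = spec([(m + delta, i) for m, i in [(100, 10), (200, 30), (300, 5)]],
             prec=400.0 + delta)
    r = modified_cosine(b, a, min_matched=1)
    assert r.score == pytest.approx(1.0, abs=1e-12)
    assert all(shifted for _, _, shifted in r.pairing)


def test_modified_cosine_equals_cosine_at_zero_delta(rng):
    for _ in range(20):
        prec = float(rng.uniform(200, 500))
        a, b = random_spectrum(rng, 8, prec), random_spectrum(rng, 8, prec)
        rc, rm = cosine(a, b), modified_cosine(a, b)
        assert rm.score == rc.score
        assert rm.pairing == rc.pairing


def test_modified_cosine_never_below_cosine(rng):
    """Shift pairs only add pairing candidates (exact assignment)."""
    for _ in range(30):
        a, b = random_spectrum(rng, 7), random_spectrum(rng, 7)
        rc = cosine(a, b, pairing="exact")
        rm = modified_cosine(a, b, pairing="exact")
        assert rm.score >= rc.score - 1e-12


def test_exact_pairing_matches_brute_force(rng):
    """Exact-assignment scores equal exhaustive enumeration, cosine and
    modified cosine, on random small spectra."""
    for k in range(150):
        a, b = random_spectrum(rng, 8), random_spectrum(rng, 8)
        tol = 25.0  # wide tolerance so pairings genuinely compete
        wa = np.sqrt(a.intensities) / np.linalg.norm(np.sqrt(a.intensities))
        wb = np.sqrt(b.intensities) / np.linalg.norm(np.sqrt(b.intensities))
        r = cosine(a, b, frag_tol=tol, min_matched=1, pairing="exact")
        expected, _ = best_pairing_score(a.mz, wa, b.mz, wb, tol)
        assert r.score == pytest.approx(min(expected, 1.0), abs=1e-9)
        shift = a.precursor_mz - b.precursor_mz
        rm = modified_cosine(a, b, frag_tol=tol, min_matched=1, pairing="exact")
        expected_m, _ = best_pairing_score(a.mz, wa, b.mz, wb, tol, shift=shift)
        assert rm.score == pytest.approx(min(expected_m, 1.0), abs=1e-9)


def test_greedy_close_to_exact(rng):
    for _ in range(50):
        a, b = random_spectrum(rng, 8), random_spectrum(rng, 8)
        g = cosine(a, b, pairing="greedy").score
        e = cosine(a, b, pairing="exact").score
        assert g <= e + 1e-12


def test_against_matchms_reference():
    """Independent cross-check of the modified cosine against matchms."""
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    a = spec([(100.0, 100), (150.0, 400), (200.0, 900)], prec=300.0)
    b = spec([(100.0, 120), (164.0157, 300), (214.0157, 800)], prec=314.0157)
    ours = modified_cosine(b, a, frag_tol=0.02, min_matched=1, scaling="raw")
    ma = matchms.Spectrum(
        mz=a.mz, intensities=a.intensities,
        metadata={"precursor_mz": a.precursor_mz}, metadata_harmonization=False,
    )
    mb = matchms.Spectrum(
        mz=b.mz, intensities=b.intensities,
        metadata={"precursor_mz": b.precursor_mz}, metadata_harmonization=False,
    )
    res = ModifiedCosine(tolerance=0.02, intensity_power=1.0, mz_power=0.0).pair(mb, ma)
    assert ours.score == pytest.approx(float(res["score"]), abs=1e-9)
    assert ours.matched_peaks == int(res["matches"])


def test_consensus_single_member_rescaled():
    s = spec([(100, 10), (200, 40)])
    c = consensus_spectrum([s])
    assert list(c.mz) == [100, 200]
    assert list(c.intensities) == [0.25, 1.0]
    assert c.precursor_mz == s.precursor_mz


def test_consensus_identical_members():
    s = spec([(100, 10), (200, 40)])
    c = consensus_spectrum([s, s])
    assert list(c.mz) == [100, 200]
    assert list(c.intensities) == [0.25, 1.0]


def test_consensus_merges_offset_peaks():
    """Two members offset by +0.005 Da merge at the weighted mean m/z."""
    a = spec([(100.000, 10)])
    b = spec([(100.005, 30)])
    c = consensus_spectrum([a, b], frag_tol=0.02)
    assert len(c) == 1
    assert c.mz[0] == pytest.approx((100.000 * 10 + 100.005 * 30) / 40, abs=1e-9)
    assert c.intensities[0] == 1.0


def test_consensus_empty_errors():
    with pytest.raises(ValueError):
        consensus_spectrum([])


def test_cluster_keep_at_least_twice_rule():
    s = spec([(100, 10), (200, 40)], ident="a")
    copies = [s.with_identifier(f"copy{i}") for i in range(3)]
    lone = spec([(150, 5), (350, 20)], prec=720.0, ident="lone")
    result = cluster_spectra(copies + [lone], min_cluster_size=2)
    assert len(result.kept) == 1
    assert result.kept[0].size == 3
    assert len(result.discarded) == 1
    assert result.total_members == 4


def test_cluster_all_distinct_returns_nothing():
    spectra = [
        spec([(100 + i * 7, 10), (200 + i * 11, 20)], prec=300.0 + 10 * i,
             ident=f"d{i}")
        for i in range(5)
    ]
    result = cluster_spectra(spectra, min_cluster_size=2)
    assert result.kept == []
    assert len(result.discarded) == 5


def test_cluster_recovers_replicate_structure(registry):
    """Noisy replicates cluster by compound, matching ground truth."""
    from nacyl.synth import SimulationConfig, simulate_dataset

    config = SimulationConfig(seed=11, n_lipids=5, replicates=2, n_decoys=0)
    ds = simulate_dataset(config, registry)
    result = cluster_spectra(ds.spectra, min_cluster_size=2)
    assert len(result.kept) == 5
    truth = dict(zip(ds.truth["spectrum_id"], ds.truth["candidate"]))
    for cluster in result.kept:
        labels = {truth[m] for m in cluster.members}
        assert len(labels) == 1  # members agree with ground truth


def test_cluster_threshold_monotonicity(registry):
    """Raising the score threshold never merges clusters."""
    from nacyl.synth import SimulationConfig, simulate_dataset

    ds = simulate_dataset(
        SimulationConfig(seed=13, n_lipids=6, replicates=3, n_decoys=5), registry
    )
    lo = cluster_spectra(ds.spectra, score_threshold=0.8, min_cluster_size=1)
    hi = cluster_spectra(ds.spectra, score_threshold=0.99, min_cluster_size=1)
    n_lo = len(lo.kept) + len(lo.discarded)
    n_hi = len(hi.kept) + len(hi.discarded)
    assert n_hi >= n_lo
    assert lo.total_members == hi.total_members == len(ds.spectra)
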