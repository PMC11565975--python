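"""Library cascade: reference filter, end-to-end build, FDR estimation."""

import numpy as np
import pytest

from nacyl.chem_core import AcylChain, condense, enumerate_candidates
from nacyl.library_builder import (
    FASST,
    GNPS_LIBRARY,
    LibraryConfig,
    build_library,
    estimate_fdr,
    headgroup_reference_spectra,
    reference_filter,
    refilter_spectra,
)
from nacyl.query_engine import build_query
from nacyl.similarity import SpectrumCluster
from nacyl.spectra_io import Spectrum
from nacyl.synth import SimulationConfig, simulate_dataset, simulate_spectrum


def spec(peaks, prec=500.0, ident="s"):
    mz, inten = zip(*peaks)
    return Spectrum(
        precursor_mz=prec,
        mz=np.asarray(mz, dtype=float),
        intensities=np.asarray(inten, dtype=float),
        identifier=ident,
    )


def test_search_presets_mirror_published_settings():
    assert GNPS_LIBRARY.min_matched == 6 and GNPS_LIBRARY.score_threshold == 0.7
    assert FASST.min_matched == 4
    assert GNPS_LIBRARY.frag_tol == FASST.frag_tol == 0.02


def test_reference_filter_identical_cluster_kept():
    ref = spec([(100, 10), (200, 30), (250, 5), (300, 8)], ident="ref")
    cluster = SpectrumCluster(members=["m1", "m2"], consensus=ref,
                              annotation="histamine-C2:0")
    records, decisions = reference_filter(
        [cluster], synthetic_refs={"histamine-C2:0": ref}
    )
    assert len(records) == 1
    assert decisions[0].kept and decisions[0].best_score == pytest.approx(1.0)
    assert decisions[0].comparator == "synthetic_reference"
    assert records[0].n_observations == 2


def test_reference_filter_below_threshold_dropped():
    ref = spec([(100, 10), (200, 30), (250, 5), (300, 8)], ident="ref")
    # shares only two of four peaks with the reference -> score < 0.7
    poor = spec([(100, 10), (200, 30), (400, 100), (450, 90)], ident="c")
    cluster = SpectrumCluster(members=["m"], consensus=poor, annotation="x-C2:0")
    records, decisions = reference_filter(
        [cluster], synthetic_refs={"x-C2:0": ref}, min_matched=1
    )
    assert records == []
    assert not decisions[0].kept
    assert decisions[0].best_score < 0.7


def test_reference_filter_headgroup_fallback(registry, heads_by_name):
    """Without a per-candidate standard, modified cosine against the
    headgroup reference absorbs the acyl shift."""
    head = heads_by_name["histamine"]
    lipid = condense(head, AcylChain(10, 0))
    s = simulate_spectrum(
        lipid, SimulationConfig(seed=4, n_noise_peaks=0), np.random.default_rng(4),
        registry,
    )
    cluster = SpectrumCluster(members=["m"], consensus=s,
                              annotation=lipid.display_name)
    records, decisions = reference_filter(
        [cluster], headgroup_refs=headgroup_reference_spectra(registry)
    )
    assert len(records) == 1
    assert decisions[0].comparator == "headgroup_reference"
    assert decisions[0].best_score >= 0.7


def test_reference_filter_missing_reference_errors():
    cluster = SpectrumCluster(
        members=["m"], consensus=spec([(100, 1)]), annotation="nope-C2:0"
    )
    with pytest.raises(KeyError):
        reference_filter([cluster], synthetic_refs={}, headgroup_refs={})


def test_refilter_spectra_is_reference_filter_on_singletons():
    ref = spec([(100, 10), (200, 30), (250, 5), (300, 8)], ident="ref")
    good = (ref.with_identifier("raw1"), "x-C2:0")
    bad = (spec([(400, 5), (500, 50)], ident="raw2"), "x-C2:0")
    records, decisions = refilter_spectra(
        [good, bad], synthetic_refs={"x-C2:0": ref}, min_matched=1
    )
    assert [d.kept for d in decisions] == [True, False]
    assert len(records) == 1


def test_build_library_spikein_exact(registry):
    """20 spiked lipids x 3 replicates + 50 decoys -> exactly 20 records."""
    ds = simulate_dataset(SimulationConfig(seed=1), registry)
    result = build_library(ds.spectra, registry)
    truth = sorted({l.display_name for l in ds.lipids})
    assert sorted(r.annotation for r in result.records) == truth
    decoy_ids = set(ds.truth.loc[ds.truth["candidate"] == "", "spectrum_id"])
    for rec in result.records:
        assert not (set(rec.provenance) & decoy_ids)
        assert rec.n_observations >= 2


def test_build_library_singletons_yield_empty_library(registry):
    ds = simulate_dataset(
        SimulationConfig(seed=2, n_lipids=5, replicates=1, n_decoys=0), registry
    )
    result = build_library(ds.spectra, registry)
    assert result.records == []
    assert result.audit["clusters_discarded"] == 5


def test_build_library_empty_input(registry):
    result = build_library([], registry)
    assert result.records == []
    assert result.audit["spectra_in"] == 0
    assert all(v == 0 for v in result.audit.values())


def test_audit_conservation(registry):
    ds = simulate_dataset(SimulationConfig(seed=6), registry)
    audit = build_library(ds.spectra, registry).audit
    assert audit["spectra_in"] == audit["spectra_matched"] + audit["spectra_unmatched"]
    assert audit["clusters_formed"] == (
        audit["clusters_kept"] + audit["clusters_discarded"]
    )
    assert audit["library_records"] <= audit["clusters_kept"]
    assert audit["library_records"] + audit["clusters_filtered_out"] == (
        audit["clusters_kept"]
    )


def test_raising_threshold_never_grows_library(registry):
    ds = simulate_dataset(SimulationConfig(seed=8), registry)
    sizes = []
    for thr in (0.5, 0.7, 0.9, 0.99):
        config = LibraryConfig(filter_threshold=thr)
        sizes.append(len(build_library(ds.spectra, registry, config).records))
    assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# FDR estimation
# ---------------------------------------------------------------------------


def _library_entry(registry, head, chain=(2, 0), label=None, suspect=False):
    heads = {h.name: h for h in registry}
    lipid = condense(heads[head], AcylChain(*chain))
    s = simulate_spectrum(
        lipid, SimulationConfig(seed=9, n_noise_peaks=0),
        np.random.default_rng(9), registry,
    )
    return (s, label or head, suspect)


def test_fdr_simple_arithmetic(registry, heads_by_name):
    head = heads_by_name["histamine"]
    q = build_query(head, enumerate_candidates([head]))
    entries = [
        _library_entry(registry, "histamine", (n, 0)) for n in range(2, 12)
    ]
    # one mislabeled entry: spectrum fragments like histamine, label differs
    entries.append(_library_entry(registry, "histamine", (12, 0), label="cadaverine"))
    report = estimate_fdr(q, entries)
    assert report.n_matches == 11
    assert report.n_false == 1
    assert report.fdr == pytest.approx(1 / 11)


def test_fdr_isomer_equivalence_counts_true(registry, heads_by_name):
    """Isomeric headgroups in one equivalence set are mutual true positives."""
    ala = heads_by_name["alanine"]
    q = build_query(ala, enumerate_candidates([ala]))
    entries = [
        _library_entry(registry, "alanine", (3, 0)),
        _library_entry(registry, "alanine", (4, 0), label="sarcosine"),
    ]
    without = estimate_fdr(q, entries)
    assert without.n_false == 1
    with_equiv = estimate_fdr(
        q, entries, equivalence_sets=[{"alanine", "sarcosine", "beta-alanine"}]
    )
    assert with_equiv.n_false == 0
    assert with_equiv.fdr == 0.0


def test_fdr_suspect_entries_excluded(registry, heads_by_name):
    head = heads_by_name["histamine"]
    q = build_query(head, enumerate_candidates([head]))
    entries = [
        _library_entry(registry, "histamine", (n, 0), suspect=True)
        for n in range(2, 6)
    ]
    report = estimate_fdr(q, entries)
    assert report.n_matches == 0
    assert report.fdr is None  # no data, not zero
    assert report.excluded_suspect == 4


def test_fdr_no_matches_reports_no_data(registry, heads_by_name):
    head = heads_by_name["serotonin"]
    q = build_query(head, enumerate_candidates([head]))
    entries = [_library_entry(registry, "histamine", (2, 0))]
    report = estimate_fdr(q, entries)
    assert report.n_matches == 0 and report.fdr is None
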