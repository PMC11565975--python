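"""End-to-end spectral-library construction and headgroup-consistency FDR.

The cascade: fragment-pattern queries retrieve candidate spectra, these are
de-duplicated into clusters (keeping only those observed at least twice),
and each cluster must finally resemble a reference — plain cosine against a
per-candidate synthetic-standard spectrum when one exists, otherwise
modified cosine against the headgroup reference (the precursor-difference
shift absorbs the acyl chain).  Clusters scoring at or above the threshold
become library records; every decision is logged.

FDR here is headgroup consistency: a query run over an annotated library
counts a match as false when the hit's headgroup contradicts the query's,
honoring declared isomer-equivalence sets and excluding suspect
(propagation-derived) entries from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem_core import Headgroup, PROTON_MASS, enumerate_candidates, monoisotopic_mass
from .query_engine import QuerySpec, build_query, match_spectrum, run_queries
from .similarity import (
    ClusteringResult,
    SpectrumCluster,
    cluster_spectra,
    cosine,
    modified_cosine,
)
from .spectra_io import LibraryRecord, Spectrum

__all__ = [
    "SearchParams",
    "GNPS_LIBRARY",
    "FASST",
    "FilterDecision",
    "FdrReport",
    "LibraryConfig",
    "LibraryBuildResult",
    "headgroup_reference_spectra",
    "reference_filter",
    "refilter_spectra",
    "build_library",
    "estimate_fdr",
]


@dataclass(frozen=True)
class SearchParams:
    """A named set of spectral-search settings."""

    score_threshold: float = 0.7
    min_matched: int = 6
    frag_tol: float = 0.02
    precursor_tol: float = 0.02


#: Library-search preset: cosine > 0.7, 6 matched fragments, 0.02 Da.
GNPS_LIBRARY = SearchParams(min_matched=6)
#: Repository-search preset: cosine > 0.7, 4 matched fragments, 0.02 Da.
FASST = SearchParams(min_matched=4)


@dataclass(frozen=True)
class FilterDecision:
    candidate: str
    stage: str  # query | cluster | reference_filter
    kept: bool
    best_score: float
    comparator: str  # synthetic_reference | headgroup_reference


@dataclass(frozen=True)
class FdrReport:
    headgroup: str
    n_matches: int
    n_false: int
    fdr: float | None  # None = no data (no countable matches)
    excluded_suspect: int = 0


def headgroup_reference_spectra(
    registry: Sequence[Headgroup]
) -> dict[str, Spectrum]:
    """Theoretical headgroup reference spectra built from the registry:
    the diagnostic fragments at unit intensity, precursor [head+H]+."""
    refs = {}
    for head in registry:
        mzs = sorted(f.mz for f in head.diagnostic_fragments)
        refs[head.name] = Spectrum(
            precursor_mz=monoisotopic_mass(head.formula) + PROTON_MASS,
            mz=np.asarray(mzs),
            intensities=np.ones(len(mzs)),
            identifier=f"headgroup_ref::{head.name}",
        )
    return refs


def _head_of(candidate: str) -> str:
    return candidate.rsplit("-C", 1)[0]


def reference_filter(
    clusters: Sequence[SpectrumCluster],
    synthetic_refs: Mapping[str, Spectrum] | None = None,
    headgroup_refs: Mapping[str, Spectrum] | None = None,
    threshold: float = 0.7,
    min_matched: int = 4,
    frag_tol: float = 0.02,
) -> tuple[list[LibraryRecord], list[FilterDecision]]:
    """Score annotated clusters against references; keep those >= threshold.

    Per cluster: plain cosine against ``synthetic_refs[candidate]`` when
    present, else modified cosine against ``headgroup_refs[head]``.  A
    candidate resolvable to neither reference is an error.
    """
    synthetic_refs = synthetic_refs or {}
    headgroup_refs = headgroup_refs or {}
    records: list[LibraryRecord] = []
    decisions: list[FilterDecision] = []
    for cluster in clusters:
        if not cluster.annotation:
            raise ValueError("cluster without candidate annotation")
        name = cluster.annotation
        if name in synthetic_refs:
            ref = synthetic_refs[name]
            comparator = "synthetic_reference"
            sim = cosine(cluster.consensus, ref, frag_tol, min_matched)
        else:
            head = _head_of(name)
            if head not in headgroup_refs:
                raise KeyError(f"no synthetic or headgroup reference for {name!r}")
            ref = headgroup_refs[head]
            comparator = "headgroup_reference"
            # headgroup refs carry few ions; cap the matched-peak floor there
            eff_min = min(min_matched, len(ref))
            sim = modified_cosine(cluster.consensus, ref, frag_tol, eff_min)
        kept = sim.score >= threshold
        decisions.append(
            FilterDecision(
                candidate=name,
                stage="reference_filter",
                kept=kept,
                best_score=sim.score,
                comparator=comparator,
            )
        )
        if kept:
            records.append(
                LibraryRecord(
                    spectrum=cluster.consensus,
                    annotation=name,
                    provenance=tuple(cluster.members),
                    n_observations=cluster.size,
                )
            )
    return records, decisions


def refilter_spectra(
    annotated_spectra: Sequence[tuple[Spectrum, str]],
    synthetic_refs: Mapping[str, Spectrum] | None = None,
    headgroup_refs: Mapping[str, Spectrum] | None = None,
    threshold: float = 0.7,
    min_matched: int = 4,
    frag_tol: float = 0.02,
) -> tuple[list[LibraryRecord], list[FilterDecision]]:
    """The raw-spectrum re-filter: the reference filter applied to
    unclustered (spectrum, candidate) pairs, dropping anything below the
    cosine threshold."""
    singletons = [
        SpectrumCluster(
            members=[s.identifier], consensus=s, annotation=candidate
        )
        for s, candidate in annotated_spectra
    ]
    return reference_filter(
        singletons, synthetic_refs, headgroup_refs, threshold, min_matched, frag_tol
    )


@dataclass
class LibraryConfig:
    min_c: int = 2
    max_c: int = 30
    max_db: int = 4
    precursor_tol: float = 0.02
    cluster_score_threshold: float = 0.95
    min_cluster_size: int = 2
    filter_threshold: float = 0.7
    filter_min_matched: int = 4
    frag_tol: float = 0.02


@dataclass
class LibraryBuildResult:
    records: list[LibraryRecord]
    decisions: list[FilterDecision]
    audit: dict[str, int]


def build_library(
    spectra: Iterable[Spectrum],
    registry: Sequence[Headgroup],
    config: LibraryConfig | None = None,
    synthetic_refs: Mapping[str, Spectrum] | None = None,
) -> LibraryBuildResult:
    """Query -> cluster (keep >= min size) -> reference-filter, with audit.

    Deterministic and idempotent for fixed inputs and config.  When no
    per-candidate synthetic reference spectra are supplied, clusters fall
    back to modified cosine against theoretical headgroup references.
    """
    config = config or LibraryConfig()
    spectra = list(spectra)
    candidates = enumerate_candidates(
        registry, config.min_c, config.max_c, config.max_db
    )
    by_head: dict[str, list] = {}
    for cand in candidates:
        by_head.setdefault(cand.headgroup.name, []).append(cand)
    heads = {h.name: h for h in registry}
    queries = [
        build_query(heads[name], cands, config.precursor_tol)
        for name, cands in by_head.items()
    ]

    matches = run_queries(queries, spectra)
    matched_ids = set(matches["spectrum_id"])
    by_id = {s.identifier: s for s in spectra}

    # cluster matched spectra within each assigned candidate
    n_formed = n_kept = n_discarded = 0
    annotated_clusters: list[SpectrumCluster] = []
    for candidate, group in matches.groupby("candidate", sort=True):
        members = [by_id[sid] for sid in group["spectrum_id"]]
        result = cluster_spectra(
            members,
            precursor_tol=config.precursor_tol,
            score_threshold=config.cluster_score_threshold,
            min_cluster_size=config.min_cluster_size,
            frag_tol=config.frag_tol,
        )
        n_formed += len(result.kept) + len(result.discarded)
        n_kept += len(result.kept)
        n_discarded += len(result.discarded)
        for cluster in result.kept:
            cluster.annotation = str(candidate)
            annotated_clusters.append(cluster)

    records, decisions = reference_filter(
        annotated_clusters,
        synthetic_refs=synthetic_refs,
        headgroup_refs=headgroup_reference_spectra(registry),
        threshold=config.filter_threshold,
        min_matched=config.filter_min_matched,
        frag_tol=config.frag_tol,
    )
    audit = {
        "spectra_in": len(spectra),
        "spectra_matched": len(matched_ids),
        "spectra_unmatched": len(spectra) - len(matched_ids),
        "match_rows": len(matches),
        "clusters_formed": n_formed,
        "clusters_kept": n_kept,
        "clusters_discarded": n_discarded,
        "library_records": len(records),
        "clusters_filtered_out": n_kept - len(records),
    }
    return LibraryBuildResult(records=records, decisions=decisions, audit=audit)


def estimate_fdr(
    query: QuerySpec,
    annotated_library: Sequence[tuple],
    search_params: SearchParams = GNPS_LIBRARY,
    equivalence_sets: Sequence[set[str]] = (),
) -> FdrReport:
    """Headgroup-consistency FDR of one query against a labeled library.

    ``annotated_library`` holds ``(Spectrum, headgroup_label)`` or
    ``(Spectrum, headgroup_label, suspect_flag)`` tuples.  Matches against
    suspect entries are excluded from the denominator; isomer headgroups in
    a shared equivalence set count as true positives for each other.  An
    empty countable match set yields ``fdr=None`` (no data), never 0.
    """
    q = QuerySpec(
        headgroup=query.headgroup,
        precursor_list=query.precursor_list,
        precursor_tolerance=search_params.precursor_tol,
        required_fragments=query.required_fragments,
    )
    equivalent = {query.headgroup}
    for group in equivalence_sets:
        if query.headgroup in group:
            equivalent |= set(group)
    n_matches = n_false = n_suspect = 0
    for entry in annotated_library:
        spectrum, label = entry[0], entry[1]
        suspect = bool(entry[2]) if len(entry) > 2 else False
        if match_spectrum(q, spectrum) is None:
            continue
        if suspect:
            n_suspect += 1
            continue
        n_matches += 1
        if label not in equivalent:
            n_false += 1
    fdr = (n_false / n_matches) if n_matches > 0 else None
    return FdrReport(
        headgroup=query.headgroup,
        n_matches=n_matches,
        n_false=n_false,
        fdr=fdr,
        excluded_suspect=n_suspect,
    )
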