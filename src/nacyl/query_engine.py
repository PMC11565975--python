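"""Fragment-pattern queries over spectrum streams.

Each headgroup gets one query: a precursor-inclusion list holding every
theoretical [M+H]+ in its candidate chain series, plus a conjunction of
required diagnostic fragment conditions.  A spectrum matches when its
precursor falls within tolerance of some candidate AND every required
fragment is present above its relative-intensity floor.  Acyl-chain
(acylium) fragments are deliberately never required: headgroup ions carry
the diagnostic signal while the lipid-side ions are weak or absent.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .chem_core import FragmentSpec, Headgroup, NAcylLipid
from .spectra_io import Spectrum

__all__ = [
    "FragmentCondition",
    "QuerySpec",
    "QueryMatch",
    "build_query",
    "render_query_text",
    "parse_query_text",
    "match_spectrum",
    "run_queries",
    "queries_to_json",
    "queries_from_json",
]

# A fragment condition is structurally identical to the registry's
# diagnostic-fragment spec; alias it so query code reads naturally.
FragmentCondition = FragmentSpec


@dataclass(frozen=True)
class QuerySpec:
    """Precursor inclusion list + conjunctive fragment conditions."""

    headgroup: str
    precursor_list: tuple[tuple[str, float], ...]
    precursor_tolerance: float = 0.02
    required_fragments: tuple[FragmentCondition, ...] = ()

    def __post_init__(self) -> None:
        if not self.precursor_list:
            raise ValueError("empty precursor list")
        if any(mz <= 0 for _, mz in self.precursor_list):
            raise ValueError("non-positive precursor m/z")
        if self.precursor_tolerance <= 0:
            raise ValueError("precursor tolerance must be positive")


@dataclass(frozen=True)
class QueryMatch:
    """One spectrum satisfying one query."""

    spectrum_id: str
    candidate: str
    precursor_error: float
    matched_fragments: int
    source_file: str = ""
    headgroup: str = ""


def build_query(
    head: Headgroup,
    candidates: Sequence[NAcylLipid],
    precursor_tol: float = 0.02,
) -> QuerySpec:
    """Assemble the query for one headgroup from its candidate series."""
    if not candidates:
        raise ValueError("no candidates supplied")
    wrong = {c.headgroup.name for c in candidates} - {head.name}
    if wrong:
        raise ValueError(f"candidates from other headgroups: {sorted(wrong)}")
    precursors = tuple(
        (c.display_name, c.precursor_mz)
        for c in sorted(candidates, key=lambda c: (c.chain.n_carbons, c.chain.n_double_bonds))
    )
    return QuerySpec(
        headgroup=head.name,
        precursor_list=precursors,
        precursor_tolerance=precursor_tol,
        required_fragments=tuple(head.diagnostic_fragments),
    )


def render_query_text(q: QuerySpec) -> str:
    """Human-readable QUERY...WHERE... rendering of the predicate.

    Parseable back by :func:`parse_query_text`; candidate names ride along
    as a comment clause so the round-trip is lossless.
    """
    prec = " OR ".join(f"{mz:.6f}" for _, mz in q.precursor_list)
    names = ",".join(name for name, _ in q.precursor_list)
    clauses = [f"MS2PREC=({prec}):TOLERANCEMZ={q.precursor_tolerance:g}"]
    for f in q.required_fragments:
        clauses.append(
            f"MS2PROD={f.mz:.6f}:TOLERANCEMZ={f.tolerance:g}"
            f":INTENSITYPERCENT={100 * f.min_relative_intensity:g}"
        )
    return (
        f"QUERY scaninfo(MS2DATA) WHERE {' AND '.join(clauses)}"
        f" # HEAD={q.headgroup} NAMES={names}"
    )


_PREC_RE = re.compile(r"MS2PREC=\(([^)]*)\):TOLERANCEMZ=([\d.eE+-]+)")
_PROD_RE = re.compile(
    r"MS2PROD=([\d.eE+-]+):TOLERANCEMZ=([\d.eE+-]+):INTENSITYPERCENT=([\d.eE+-]+)"
)
_META_RE = re.compile(r"# HEAD=(.*) NAMES=(.*)$")


def parse_query_text(text: str) -> QuerySpec:
    """Companion reader for :func:`render_query_text`."""
    meta = _META_RE.search(text)
    prec = _PREC_RE.search(text)
    if not meta or not prec:
        raise ValueError("unparseable query text")
    names = meta.group(2).split(",") if meta.group(2) else []
    mzs = [float(x) for x in prec.group(1).split(" OR ")]
    if len(names) != len(mzs):
        raise ValueError("precursor name/mz count mismatch")
    frags = tuple(
        FragmentCondition(
            mz=float(m), tolerance=float(t), min_relative_intensity=float(p) / 100
        )
        for m, t, p in _PROD_RE.findall(text)
    )
    return QuerySpec(
        headgroup=meta.group(1),
        precursor_list=tuple(zip(names, mzs)),
        precursor_tolerance=float(prec.group(2)),
        required_fragments=frags,
    )


def _fragment_present(s: Spectrum, cond: FragmentCondition, base: float) -> bool:
    lo = np.searchsorted(s.mz, cond.mz - cond.tolerance, side="left")
    hi = np.searchsorted(s.mz, cond.mz + cond.tolerance, side="right")
    if lo >= hi:
        return False
    floor = cond.min_relative_intensity * base
    return bool(np.any(s.intensities[lo:hi] >= floor))


def match_spectrum(q: QuerySpec, s: Spectrum) -> QueryMatch | None:
    """Evaluate one spectrum against one query; None means no match.

    Candidate assignment: smallest absolute precursor error; exact ties go
    to the candidate earlier in the (chain-sorted) precursor list.
    """
    if len(s) == 0:
        return None
    errors = [(abs(s.precursor_mz - mz), i) for i, (_, mz) in enumerate(q.precursor_list)]
    best_err, best_i = min(errors)
    if best_err > q.precursor_tolerance:
        return None
    base = s.base_peak_intensity
    n_matched = 0
    for cond in q.required_fragments:
        if not _fragment_present(s, cond, base):
            return None
        n_matched += 1
    name, mz = q.precursor_list[best_i]
    return QueryMatch(
        spectrum_id=s.identifier,
        candidate=name,
        precursor_error=s.precursor_mz - mz,
        matched_fragments=n_matched,
        source_file=s.source_file,
        headgroup=q.headgroup,
    )


MATCH_COLUMNS = [
    "headgroup",
    "candidate",
    "spectrum_id",
    "source_file",
    "precursor_error",
    "matched_fragments",
]


def run_queries(
    queries: Sequence[QuerySpec], spectra: Iterable[Spectrum]
) -> pd.DataFrame:
    """Run every query over a spectrum stream; one row per (query, spectrum)
    match, in input order.  The stream is traversed once."""
    rows = []
    for s in spectra:
        for q in queries:
            m = match_spectrum(q, s)
            if m is not None:
                rows.append(
                    (
                        m.headgroup,
                        m.candidate,
                        m.spectrum_id,
                        m.source_file,
                        m.precursor_error,
                        m.matched_fragments,
                    )
                )
    return pd.DataFrame(rows, columns=MATCH_COLUMNS)


# --------------------------------------------------------------------------
# JSON (canonical) serialization
# --------------------------------------------------------------------------

def queries_to_json(queries: Sequence[QuerySpec], path: str | Path) -> None:
    payload = [
        {
            "headgroup": q.headgroup,
            "precursor_tolerance": q.precursor_tolerance,
            "precursors": [{"name": n, "mz": mz} for n, mz in q.precursor_list],
            "required_fragments": [
                {
                    "mz": f.mz,
                    "tolerance": f.tolerance,
                    "min_relative_intensity": f.min_relative_intensity,
                }
                for f in q.required_fragments
            ],
        }
        for q in queries
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def queries_from_json(path: str | Path) -> list[QuerySpec]:
    payload = json.loads(Path(path).read_text())
    return [
        QuerySpec(
            headgroup=item["headgroup"],
            precursor_list=tuple((p["name"], p["mz"]) for p in item["precursors"]),
            precursor_tolerance=item["precursor_tolerance"],
            required_fragments=tuple(
                FragmentCondition(
                    mz=f["mz"],
                    tolerance=f["tolerance"],
                    min_relative_intensity=f["min_relative_intensity"],
                )
                for f in item["required_fragments"]
            ),
        )
        for item in payload
    ]
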