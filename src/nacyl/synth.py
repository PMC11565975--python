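"""Synthetic-data generation: the test bed for the whole pipeline.

Spectra follow the family fragmentation model: every conjugate of a
headgroup shares the headgroup's diagnostic fragment ions, while the
precursor moves with the acyl chain.  A simulated lipid spectrum therefore
holds the registry's diagnostic fragments (at configurable relative
intensities), a precursor-related peak, and uniform background noise
peaks.  Decoys reuse plausible precursor m/z values but have their
"fragments" displaced by many times the fragment tolerance, and background
noise is kept away from every registry fragment position, so a decoy can
never satisfy a query by construction.

Everything is driven by a single integer seed through one
``numpy.random.Generator``; outputs are byte-identical across runs.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    Headgroup,
    NAcylLipid,
    condense,
    default_registry,
    enumerate_chains,
)
from .spectra_io import Spectrum, write_mgf

__all__ = [
    "SimulationConfig",
    "FeatureTableConfig",
    "SimulatedDataset",
    "query_safe_headgroups",
    "simulate_spectrum",
    "simulate_decoy",
    "simulate_dataset",
    "simulate_feature_table",
    "write_dataset",
    "write_mzml_minimal",
]


@dataclass
class SimulationConfig:
    """Study conditions for spike-in spectrum simulation.

    Defaults mirror the end-to-end validation scenario: 20 spiked lipids in
    3 replicate spectra each plus 50 decoys, peak jitter well under the
    0.02 Da fragment tolerance, fragment relative intensities 0.2-1.0
    (far above the 1% intensity floor), and weak uniform noise peaks.
    """

    seed: int = 0
    n_lipids: int = 20
    replicates: int = 3
    n_decoys: int = 50
    mz_jitter_sd: float = 0.003
    intensity_cv: float = 0.1
    n_noise_peaks: int = 6
    noise_max_rel: float = 0.02
    fragment_rel_range: tuple[float, float] = (0.2, 1.0)
    precursor_rel: float = 0.5
    decoy_displacement: float = 0.5  # >= 5x the 0.02 Da tolerance
    blank_contaminants: tuple[str, ...] = ()
    n_blank_files: int = 0


def query_safe_headgroups(registry: Sequence[Headgroup]) -> list[Headgroup]:
    """Headgroups usable as unambiguous spike-in ground truth.

    Drops isomeric heads (duplicated formulas, e.g. leucine/isoleucine)
    and heads whose diagnostic fragments fall within 0.1 Da of another
    head's, so a spiked spectrum matches exactly one query.
    """
    formula_counts: dict[str, int] = {}
    for h in registry:
        key = h.formula.hill()
        formula_counts[key] = formula_counts.get(key, 0) + 1
    unique = [h for h in registry if formula_counts[h.formula.hill()] == 1]
    safe: list[Headgroup] = []
    taken_mz: list[float] = []
    for h in unique:
        mzs = [f.mz for f in h.diagnostic_fragments]
        if all(abs(mz - t) > 0.1 for mz in mzs for t in taken_mz):
            safe.append(h)
            taken_mz.extend(mzs)
    return safe


def _forbidden_positions(registry: Sequence[Headgroup]) -> np.ndarray:
    return np.asarray(
        sorted(f.mz for h in registry for f in h.diagnostic_fragments)
    )


def _fragment_profile(
    head: Headgroup, config: SimulationConfig
) -> np.ndarray:
    """Per-headgroup fragment relative intensities, reproducible across
    replicates: drawn once from an RNG keyed on (seed, headgroup name)."""
    import zlib

    key = (zlib.crc32(head.name.encode()) + config.seed) % (2**31)
    rng = np.random.default_rng(key)
    lo, hi = config.fragment_rel_range
    return rng.uniform(lo, hi, size=len(head.diagnostic_fragments))


def _noise_peaks(
    rng: np.random.Generator,
    config: SimulationConfig,
    upper: float,
    forbidden: np.ndarray,
    base_intensity: float,
) -> tuple[list[float], list[float]]:
    mzs, intens = [], []
    tries = 0
    while len(mzs) < config.n_noise_peaks and tries < 50 * config.n_noise_peaks:
        tries += 1
        mz = float(rng.uniform(50.0, max(60.0, upper)))
        if forbidden.size and np.min(np.abs(forbidden - mz)) < 0.1:
            continue  # keep noise clear of every diagnostic fragment position
        mzs.append(mz)
        intens.append(float(rng.uniform(0.0, config.noise_max_rel)) * base_intensity)
    return mzs, intens


def simulate_spectrum(
    lipid: NAcylLipid,
    config: SimulationConfig,
    rng: np.random.Generator,
    registry: Sequence[Headgroup] | None = None,
    identifier: str = "",
    source_file: str = "",
) -> Spectrum:
    """One replicate MS/MS spectrum of a lipid under the family model.

    The relative-intensity profile of the diagnostic fragments is a fixed
    property of the headgroup (fragmentation patterns are reproducible
    compound characteristics); replicates differ only by multiplicative
    intensity noise, m/z jitter and background peaks.
    """
    forbidden = _forbidden_positions(registry) if registry else np.empty(0)
    mzs: list[float] = []
    intens: list[float] = []
    base = 1000.0
    profile = _fragment_profile(lipid.headgroup, config)
    for frag, rel in zip(lipid.headgroup.diagnostic_fragments, profile):
        mzs.append(frag.mz + float(rng.normal(0.0, config.mz_jitter_sd)))
        intens.append(rel * base * float(rng.lognormal(0.0, config.intensity_cv)))
    mzs.append(lipid.precursor_mz + float(rng.normal(0.0, config.mz_jitter_sd)))
    intens.append(config.precursor_rel * base)
    noise_mz, noise_int = _noise_peaks(
        rng, config, lipid.precursor_mz, forbidden, base
    )
    mzs += noise_mz
    intens += noise_int
    return Spectrum(
        precursor_mz=lipid.precursor_mz,
        mz=np.asarray(mzs),
        intensities=np.asarray(intens),
        identifier=identifier or f"sim::{lipid.display_name}",
        source_file=source_file,
    )


def simulate_decoy(
    precursor_mz: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    registry: Sequence[Headgroup] | None = None,
    identifier: str = "",
    source_file: str = "",
) -> Spectrum:
    """A decoy: plausible precursor, fragments displaced off every
    diagnostic position by ``decoy_displacement`` (>= 5x tolerance)."""
    forbidden = _forbidden_positions(registry) if registry else np.empty(0)
    base = 1000.0
    mzs = [
        100.0 + config.decoy_displacement + float(rng.uniform(0, 30)),
        150.0 + config.decoy_displacement + float(rng.uniform(0, 30)),
    ]
    if forbidden.size:
        nudged = []
        for mz in mzs:
            while np.min(np.abs(forbidden - mz)) < 0.1:
                mz += 0.3
            nudged.append(mz)
        mzs = nudged
    intens = [base, 0.6 * base]
    noise_mz, noise_int = _noise_peaks(rng, config, precursor_mz, forbidden, base)
    return Spectrum(
        precursor_mz=precursor_mz,
        mz=np.asarray(mzs + noise_mz),
        intensities=np.asarray(intens + noise_int),
        identifier=identifier or "sim::decoy",
        source_file=source_file,
    )


@dataclass
class SimulatedDataset:
    spectra: list[Spectrum]
    truth: pd.DataFrame  # spectrum_id, candidate (or "" for decoys), file_id
    metadata: pd.DataFrame  # file_id, is_blank_or_qc, is_cell_line, taxon
    lipids: list[NAcylLipid]


def simulate_dataset(
    config: SimulationConfig,
    registry: Sequence[Headgroup] | None = None,
) -> SimulatedDataset:
    """Spike-in dataset: lipids x replicates, decoys, optional blank files.

    Lipids are drawn from query-safe headgroups with chains sampled over
    the full C2-C30, d <= 4 space.  Each replicate lands in its own
    synthetic sample file; blank files carry the configured contaminant
    candidates so contamination filter rules can be exercised.
    """
    registry = list(registry) if registry is not None else default_registry()
    rng = np.random.default_rng(config.seed)
    safe = query_safe_headgroups(registry)
    if config.n_lipids > len(safe):
        raise ValueError(
            f"only {len(safe)} query-safe headgroups for {config.n_lipids} lipids"
        )
    chains = enumerate_chains()
    head_idx = rng.choice(len(safe), size=config.n_lipids, replace=False)
    lipids = [
        condense(safe[int(i)], chains[int(rng.integers(len(chains)))])
        for i in head_idx
    ]

    spectra: list[Spectrum] = []
    truth_rows: list[tuple[str, str, str]] = []
    for li, lipid in enumerate(lipids):
        for rep in range(config.replicates):
            file_id = f"sample_{li:03d}_{rep}"
            sid = f"spikein::{lipid.display_name}::rep{rep}"
            spectra.append(
                simulate_spectrum(
                    lipid, config, rng, registry, identifier=sid,
                    source_file=file_id,
                )
            )
            truth_rows.append((sid, lipid.display_name, file_id))
    all_precursors = [c.precursor_mz for c in (condense(h, ch) for h in safe for ch in chains[:8])]
    for di in range(config.n_decoys):
        file_id = f"decoy_{di:03d}"
        sid = f"decoy::{di}"
        prec = float(all_precursors[int(rng.integers(len(all_precursors)))])
        spectra.append(
            simulate_decoy(
                prec, config, rng, registry, identifier=sid, source_file=file_id
            )
        )
        truth_rows.append((sid, "", file_id))

    meta_rows = [
        (fid, False, False, "synthetic sample")
        for fid in dict.fromkeys(r[2] for r in truth_rows)
    ]
    if config.n_blank_files and config.blank_contaminants:
        by_name = {}
        for h in registry:
            for ch in chains:
                lip = condense(h, ch)
                if lip.display_name in config.blank_contaminants:
                    by_name[lip.display_name] = lip
        for bi in range(config.n_blank_files):
            file_id = f"blank_{bi:03d}"
            meta_rows.append((file_id, True, False, "blank"))
            for name, lip in by_name.items():
                sid = f"blank::{name}::{bi}"
                spectra.append(
                    simulate_spectrum(
                        lip, config, rng, registry, identifier=sid,
                        source_file=file_id,
                    )
                )
                truth_rows.append((sid, name, file_id))

    truth = pd.DataFrame(truth_rows, columns=["spectrum_id", "candidate", "file_id"])
    metadata = pd.DataFrame(
        meta_rows, columns=["file_id", "is_blank_or_qc", "is_cell_line", "taxon"]
    )
    return SimulatedDataset(
        spectra=spectra, truth=truth, metadata=metadata, lipids=lipids
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mgf(dataset.spectra, out / "spectra.mgf")
    dataset.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    dataset.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)


@dataclass
class FeatureTableConfig:
    """Grouped peak-area table emulating a feature-quantification export.

    Log-normal areas (median ~1e6, ln-scale sd 1.0) with a multiplicative
    effect on designated features in the second group; optional zero
    inflation to exercise the imputation policies.
    """

    seed: int = 0
    n_features: int = 20
    n_effect_features: int = 5
    n_per_group: tuple[int, int] = (20, 20)
    effect_size: float = 4.0
    log_sd: float = 1.0
    baseline_median: float = 1e6
    zero_fraction: float = 0.0
    group_names: tuple[str, str] = ("control", "case")


def simulate_feature_table(
    config: FeatureTableConfig,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, float]]:
    """Returns (features x samples table, sample->group map, feature->effect)."""
    rng = np.random.default_rng(config.seed)
    g0, g1 = config.group_names
    n0, n1 = config.n_per_group
    samples = [f"{g0}_{i}" for i in range(n0)] + [f"{g1}_{i}" for i in range(n1)]
    groups = {s: (g0 if i < n0 else g1) for i, s in enumerate(samples)}
    features = [f"feature_{i:03d}" for i in range(config.n_features)]
    effects = {
        f: (config.effect_size if i < config.n_effect_features else 1.0)
        for i, f in enumerate(features)
    }
    mu = np.log(config.baseline_median)
    data = np.empty((config.n_features, len(samples)))
    for fi, f in enumerate(features):
        base = rng.lognormal(mean=mu, sigma=config.log_sd, size=len(samples))
        base[n0:] *= effects[f]
        if config.zero_fraction > 0:
            zeros = rng.random(len(samples)) < config.zero_fraction
            base[zeros] = 0.0
        data[fi] = base
    table = pd.DataFrame(data, index=features, columns=samples)
    return table, groups, effects


# ---------------------------------------------------------------------------
# Minimal mzML writer (uncompressed 64-bit floats), for fixtures only.
# ---------------------------------------------------------------------------

def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def write_mzml_minimal(
    path: str | Path,
    ms2_spectra: Sequence[Spectrum],
    n_ms1: int = 0,
) -> None:
    """Write a minimal mzML file holding the given MS2 spectra plus
    ``n_ms1`` empty MS1 survey scans.  Fixture-grade: uncompressed 64-bit
    float arrays, just enough CV terms for standard readers."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<run id="synthetic_run">',
    ]
    entries: list[tuple[int, Spectrum | None]] = [(1, None)] * n_ms1 + [
        (2, s) for s in ms2_spectra
    ]
    lines.append(f'<spectrumList count="{len(entries)}">')
    for idx, (level, s) in enumerate(entries):
        mz = s.mz if s is not None else np.asarray([100.0])
        inten = s.intensities if s is not None else np.asarray([1.0])
        lines.append(
            f'<spectrum index="{idx}" id="scan={idx + 1}" '
            f'defaultArrayLength="{len(mz)}">'
        )
        lines.append(
            f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
            f'value="{level}"/>'
        )
        lines.append(
            '<cvParam cvRef="MS" accession="MS:1000127" '
            'name="centroid spectrum" value=""/>'
        )
        if level == 2 and s is not None:
            lines += [
                '<precursorList count="1"><precursor>',
                '<selectedIonList count="1"><selectedIon>',
                f'<cvParam cvRef="MS" accession="MS:1000744" '
                f'name="selected ion m/z" value="{s.precursor_mz:.6f}"/>',
                f'<cvParam cvRef="MS" accession="MS:1000041" '
                f'name="charge state" value="{s.charge}"/>',
                "</selectedIon></selectedIonList>",
                "</precursor></precursorList>",
            ]
        lines.append('<binaryDataArrayList count="2">')
        for arr, acc, name in (
            (mz, "MS:1000514", "m/z array"),
            (inten, "MS:1000515", "intensity array"),
        ):
            b64 = _b64_doubles(np.asarray(arr))
            lines += [
                f'<binaryDataArray encodedLength="{len(b64)}">',
                '<cvParam cvRef="MS" accession="MS:1000523" '
                'name="64-bit float" value=""/>',
                '<cvParam cvRef="MS" accession="MS:1000576" '
                'name="no compression" value=""/>',
                f'<cvParam cvRef="MS" accession="{acc}" name="{name}" value=""/>',
                f"<binary>{b64}</binary>",
                "</binaryDataArray>",
            ]
        lines.append("</binaryDataArrayList>")
        lines.append("</spectrum>")
    lines += ["</spectrumList>", "</run>", "</mzML>"]
    Path(path).write_text("\n".join(lines))
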