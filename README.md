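# nacyl

Discovery, spectral-library construction and quantification of **N-acyl
lipids** from tandem mass spectrometry data.

N-acyl lipids are conjugates of an amine-bearing headgroup (an amino acid,
polyamine, neurotransmitter or hormone) and a fatty acid Cn:d, joined by an
amide bond. Many of them — especially short-chain fatty acid conjugates
made at the microbiome–diet interface — are absent from lipid structural
databases, so conventional library search cannot annotate them. This
toolkit implements the alternative: *pattern-based* retrieval. Because the
acyl chain fragments poorly, the MS/MS spectrum of every member of a
headgroup family is dominated by the same diagnostic headgroup ions, while
the precursor m/z moves with the chain. A query that demands (a) a
precursor inside a theoretical [M+H]+ inclusion list and (b) every
diagnostic headgroup fragment above an intensity floor retrieves the whole
conjugate family at once.

The package is aimed at metabolomics researchers mining untargeted LC-MS/MS
data (their own or repository-scale match tables) for amine–fatty acid
conjugates, and at anyone building a curated MS/MS library for such a
compound family.

## What it does

- **Combinatorial enumeration** (`nacyl.chem_core`) — headgroup registry ×
  acyl chains C2–C30 with 0–4 double bonds (validity rule n ≥ 2d + 1),
  giving 129 chains per headgroup and 8,256 candidates over the packaged
  64-headgroup registry. Formulas follow head + CnH(2n−2d)O2 − H2O; the
  precursor is the protonated molecule (monoisotopic mass + 1.007276 Da).
- **Spectrum I/O** (`nacyl.spectra_io`) — MGF and mzML (MS2) reading, MGF
  and NIST MSP writing; gzip transparent.
- **Fragment-pattern queries** (`nacyl.query_engine`) — one query per
  headgroup: precursor inclusion list plus conjunctive diagnostic-fragment
  conditions (default 0.02 Da tolerances, 1% relative-intensity floor).
- **Similarity and clustering** (`nacyl.similarity`) — cosine and modified
  cosine (precursor-difference shift) with greedy or exact peak assignment;
  greedy single-pass clustering with consensus spectra and the
  "observed at least twice" rule.
- **Library cascade and FDR** (`nacyl.library_builder`) — query → cluster →
  reference filter (cosine ≥ 0.7 against a synthetic standard, else
  modified cosine against the headgroup reference), with a per-stage audit
  and headgroup-consistency FDR reports honouring isomer-equivalence sets
  and excluding suspect entries.
- **Repository evidence filters** (`nacyl.repo_annotate`) — metadata joins
  and the per-candidate rules (cell-line exclusion, ≥3 occurrences, ≤5%
  blank/QC fraction) with `microbe` / `plant` / `food` presets, chain-length
  classes and occurrence matrices.
- **Group statistics** (`nacyl.stats_group`) — median log2 fold changes
  with explicit zero policies, exact/asymptotic Mann–Whitney U and
  Kruskal–Wallis tests, Benjamini–Hochberg correction, volcano
  classification (p < 0.05, |log2FC| > 2).
- **Quantification** (`nacyl.quant`) — internal-standard response ratios,
  polynomial calibration, LOD = 3.3·Sb/a and LOQ = 10·Sb/a from replicate
  curves, spike recovery with the 80–120% band, percent RSD.
- **Synthetic data** (`nacyl.synth`) — seeded spike-in spectra, decoys,
  blank channels and grouped feature tables with known ground truth, so the
  whole pipeline is testable without external data.

## Worked example

```python
from nacyl import default_registry, enumerate_candidates, condense, AcylChain
from nacyl.synth import SimulationConfig, simulate_dataset
from nacyl.library_builder import build_library

registry = default_registry()                      # 64 headgroups
candidates = enumerate_candidates(registry)        # 8,256 conjugates

heads = {h.name: h for h in registry}
lipid = condense(heads["histamine"], AcylChain(3, 0))
print(lipid.display_name, lipid.formula.hill(),
      f"{lipid.monoisotopic_mass:.6f}", f"{lipid.precursor_mz:.6f}")
# histamine-C3:0 C8H13N3O 167.105862 168.113138

# spike-in: 20 lipids x 3 replicate spectra + 50 decoys
dataset = simulate_dataset(SimulationConfig(seed=1), registry)
result = build_library(dataset.spectra, registry)
print(result.audit)
# {'spectra_in': 110, 'spectra_matched': 60, 'spectra_unmatched': 50,
#  'match_rows': 60, 'clusters_formed': 20, 'clusters_kept': 20,
#  'clusters_discarded': 0, 'library_records': 20, 'clusters_filtered_out': 0}
```

All 60 spiked replicate spectra (and none of the 50 decoys) are retrieved
by the queries, cluster into one consensus per compound, pass the reference
filter, and yield exactly the 20 true library records.

The same pipeline is available from the shell:

```sh
nacyl simulate spectra --seed 4 --lipids 5 -o data/
nacyl queries build -o queries.json
nacyl query -q queries.json -i data/spectra.mgf -o matches.tsv
nacyl library build -i data/spectra.mgf -o library.msp --audit audit.tsv
nacyl annotate filter -i matches_meta.tsv --preset microbe -o kept.tsv
nacyl stats compare -i features.csv -m samples.tsv \
    --groups group:control,case --test mwu -o stats.tsv
```

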