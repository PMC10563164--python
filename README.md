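# clirms

Analysis pipeline for isotope-labeled protein–RNA cross-linking mass
spectrometry data. Starting from an RNA sequence and a labeling scheme,
the package enumerates every RNA-derived peptide modification that can
occur, groups the species into parallel searches by their expected
light/heavy delta mass, generates engine-agnostic search parameter sets
and decoy protein databases, detects light/heavy precursor scan pairs in
mzXML runs, consolidates and reranks cross-link spectrum matches
(XLSMs), controls the false discovery rate three ways (observed
target–decoy FDR with q-values, transferred per-RNA-composition FDR
with an observed-FDR fallback, and Percolator/mokapot-compatible PIN
export), refines results with a data-driven mass-error window, and
produces protein-centric and RNA-centric reports. A synthetic-data
module generates statistically realistic fixtures so the whole pipeline
is testable without any raw data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(FDR oracle equivalence, FDP calibration, pair-finder closed loop, mass
oracles, end-to-end run, ...).

## Command line

```sh
# enumerate adducts and group them into parallel searches
clirms adducts --rna UCUCU --scheme metabolic_13C15N --losses default --out adducts.tsv

# parameter files + manifest (+ light-only search) from a YAML config
clirms paramgen --config run.yaml

# decoy protein database (reverse, shuffle, or both)
clirms decoydb --in target.fasta --mode reverse_then_shuffle --seed 42 --out decoys.fasta

# light/heavy precursor scan pairs at the adduct table's delta masses
clirms pairs --mzxml run.mzXML --adducts adducts.tsv --out pairs.tsv

# +10 m/z decoy dataset
clirms mzshift --in run.mzXML --out run_decoy.mzXML --shift 10

# synthetic fixtures (XLSM table, ground truth, precursor run, pair ledger)
clirms simulate --preset fox1_like --seed 7 --out fixtures/

# consolidate + rerank, then FDR / PIN export / reporting
clirms consolidate --in fixtures/xlsms.tsv --out all_xlsms.tsv
clirms fdr --in all_xlsms.tsv --method observed --alpha 0.01 --out fdr_curve.tsv
clirms fdr --in all_xlsms.tsv --method transferred --out bin_thresholds.tsv
clirms topin --in all_xlsms.tsv --out run.pin
clirms report --in all_xlsms.tsv --rna UGCAUGU --out-dir report/
```

The paramgen YAML mirrors `clirms.orchestration.SearchConfig`:

```yaml
fasta_paths: [target.fasta]
rna_sequence: UCUCU
scheme: metabolic_13C15N
spectrum_files: [a.mzXML]
output_dir: searches
```

## Layout

| module | responsibility |
| --- | --- |
| `clirms.adduct_chem` | elemental formulas, adduct enumeration, delta-mass grouping, covering-RNA design sequences |
| `clirms.orchestration` | parameter file trees, manifests, light-only searches, decoy FASTA |
| `clirms.spectra` | mzXML I/O, isotope scan-pair detection, m/z-shift decoy runs |
| `clirms.results` | XLSM parsing, per-scan reranking, unique-ID collapse, mass-error window |
| `clirms.fdr` | observed FDR + q-values, transferred per-bin FDR, PIN export |
| `clirms.report` | site×adduct matrices, RNA position profiles, summary CSV |
| `clirms.synthdata` | seeded synthetic XLSM tables and precursor runs |
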