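# totikit

A toolkit for characterizing totivirus genomes and their small-RNA
footprints, built around the two Geotrichum candidum totiviruses
GcTV2-Gc6 and GcTV4-Gc6 (GenBank OR250782 / OR250783):

- **Genome annotation** (`totikit.orfs`): ORF discovery (AUG-initiated,
  stop-terminated, longest-per-stop), UTR/intergenic layout derivation,
  GC content, translation, and average-mass protein weight estimates.
- **−1 programmed ribosomal frameshift detection** (`totikit.prf`):
  canonical XXXYYYZ slippery-heptamer scanning near the ORF1 stop,
  exhaustive H-type (crossing two-stem) pseudoknot enumeration downstream
  of the heptamer under a simple documented energy model, spacer
  assembly, and derivation of the CP–RdRp fusion protein produced by the
  −1 slip (the final heptamer base is re-read in the new frame).
- **Conserved-motif anchoring** (`totikit.motifs`): affine-gap global
  alignment against packaged reference proteins to transfer conserved
  positions (the capsid cap-snatching histidine; RdRp motif blocks
  including GDD). The packaged references are synthetic stand-ins that
  carry the documented conserved positions; they are not the GenBank
  sequences.
- **Small-RNA profiling** (`totikit.srna`): exhaustive mismatch-tolerant
  (Hamming, ≤1 mismatch by default) read mapping on both strands,
  per-length × mismatch-class tables (lengths 10–30 plus ">30"),
  perfect-match fractions, and usRNA (13–19 nt) / siRNA (20–24 nt)
  classification.
- **Synthetic data** (`totikit.simulate`): generators for totivirus-like
  genomes with fully known planted structure (ORFs, heptamer, pseudoknot,
  GDD, His anchor), host background sequence, and small-RNA read sets
  with planted 0/1 mismatches — every dataset ships with a truth record
  for exact recovery testing.
- **Pipeline** (`totikit.pipeline` / `totikit.cli`): a deterministic
  annotate → prf-scan → motif-scan → srna-profile run with a consolidated
  JSON report.

A note on orientation: the H-type pseudoknot is searched *downstream* of
the slippery heptamer, consistent with both reported totivirus elements
(heptamer 1958–1964 with pseudoknot 1969–2023; heptamer 1943–1949 with
pseudoknot 1977–1997) and the −1 PRF literature.

The pseudoknot energy model is intentionally simple and reproducible
(GC −3.0, AU −2.0, GU −1.0 kcal/mol per pair; +0.2 kcal/mol per unpaired
loop nucleotide; +7.0 kcal/mol initiation penalty). It ranks candidates
deterministically; it is not a thermodynamic folding prediction.

## Tests

```sh
python -m pytest -q tests/
```

One acceptance test
(`test_acceptance.py::TestCriterion5TableConsistency::test_gctv4_fraction_as_printed`)
fails by design: the published perfect-match percentage for GcTV4 (0.75%)
is a truncation of 841/111335 = 0.7554%, which rounds to 0.76 under the
half-up rule used consistently here. See the test body for details.

## CLI

```sh
totikit annotate --fasta genome.fa --min-aa 100 --out report/
totikit prf-scan --fasta genome.fa --out prf.json
totikit motif-scan --protein cp.faa --role cp --out motifs.tsv
totikit srna-profile --reads srna.fastq --viral viruses.fa --out profile/
totikit simulate genome --layout gctv2 --seed 1 --out sim/
totikit simulate reads --targets sim/genome.fa --n-reads 10000 --out simreads/
totikit run --config run.yaml
```

`totikit run` reads a YAML config (keys: `genome_fasta`, optional
`reads_fastq`/`reads_fasta`/`host_fasta`, `out_dir`, `min_aa`,
`max_upstream`, `spacer_bounds`, `max_mm`, `pk_*` pseudoknot parameters);
exit codes are 0 (success), 2 (config error), 3 (stage failure).

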