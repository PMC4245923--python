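# hlarray

HLA class I typing from tiling oligonucleotide probe arrays.

Clinical HLA typing of the class I loci (HLA-A, -B, -C) must discriminate
thousands of allelic variants that are >85% identical across loci and >98%
identical within allele groups. `hlarray` implements a complete array-based
typing method for laboratories and methods developers working with
sequence-specific oligonucleotide probe (SSOP) microarrays:

- **Probe design** — the complete overlapping probe set for an allele
  catalog: one probe per position of every allele, shifted by a single
  nucleotide, with each probe's length tuned (20–60 nt) so its melting
  temperature `Tm = 64.9 + 41·(nG + nC − 16.4)/L` is as close as possible to
  the hybridization target of 64.2 °C; identical probes are deduplicated with
  full (allele, position) placement maps.
- **Signal processing** — per-array normalization onto a fixed scale
  (min 1, mean 1,000, max 20,000) via `Sn = min(S − Rmin + F, F·20000)/F`
  with the scaling factor *F* solved numerically; window-median error
  correction along each allele's overlapping-probe track; per-probe
  positivity thresholds (10% of maximal signal, or learned empirically from
  a knowledgebase); degradation and uninformative-probe QC.
- **Three-stage calling** — (1) *serotype determination*: allele groups are
  ranked per locus by `Neg(ST) = Σ Neg(x)/k`, the average number of negative
  probes over the k = min(5, N) best-supported alleles, with a homozygosity
  rule (`Neg(ST₂) − Neg(ST₁) ≥ 20`) and redundant-serotype elimination;
  (2) *genotype determination*: pairwise win counting between alleles of the
  surviving groups (`AvgWins(x)`), knowledgebase template lookup, and the
  knowledge-based rule `Weight(x) = AvgWins(x) − Neg(x) > WeightThreshold(x)`;
  (3) *ambiguity removal*: candidate genotypes compared by position-wise
  signal sums `Sig(G, p)`, reporting every genotype within 20 wins of the
  best.
- **Template knowledgebase** — typed arrays stored as templates; new arrays
  matched whole-array by Pearson correlation with a serotype-mismatch veto
  (identity when r > 0.975 with 0 mismatches); empirical thresholds and
  weight tables regenerate from the stored templates.
- **Hybridization simulator** — synthetic allele catalogs with realistic
  similarity structure and signal simulation covering the documented error
  modes: probe masking (including an engineered fully masked decoy),
  homozygous and same-group heterozygous samples, degraded arrays, mixed
  samples, and negative controls.

Calls that land in the classes where array typing is known to err —
homozygous loci and two alleles of one group — are flagged for confirmatory
sequencing rather than silently reported.

## Worked example

Simulate a small cohort against a synthetic catalog (3 loci × 8 allele
groups × 4 alleles) and type it from the raw signal files:

```sh
hlarray simulate --n 4 --out demo --seed 7 --scenario-mix "clean=0.75,homozygous=0.25"
hlarray type --signals demo/signals --fasta demo/catalog.fasta \
             --serogroups demo/serogroups.tsv --out demo/typed
```

```
wrote 4 arrays over 9078 probes to demo
typed 4 arrays -> demo/typed/cohort.tsv
```

`demo/typed/cohort.tsv` then holds one row per sample with two allele calls
per locus:

```
sample  A_1      A_2      B_1      B_2      C_1      C_2      flags       provenance
S0000   A*07:01  A*08:03  B*02:03  B*03:04  C*04:02  C*05:01              knowledge-based
S0001   A*05:03  A*07:04  B*02:01  B*03:02  C*03:02  C*07:02              knowledge-based
S0002   A*05:03  A*08:02  B*04:01  B*05:03  C*04:04  C*05:03              knowledge-based
S0003   A*01:01  A*07:02  B*02:04  B*06:03  C*08:02  Nil      homozygous  knowledge-based
```

Every call matches the simulated truth in `demo/manifest.tsv`. Sample S0003
was simulated homozygous at locus C: the second call is `Nil` (one confirmed
allele) and the result carries the `homozygous` flag, meaning a real sample
would be sent for validation sequencing. Per-sample JSON files contain the
full audit trail: serotype ranks, eliminations with margins, comparison
vectors, wins and template correlations.

The same functionality is available as a library (`hlarray.run_typing`,
`hlarray.build_probe_set`, `hlarray.simulate_array`, ...), including the
knowledgebase path: add confirmed typings with `Knowledgebase.add_template`
and replicate arrays of a stored sample short-circuit to a template match
(provenance `template`) instead of the knowledge-based path.

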