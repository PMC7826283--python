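# m5ckit

A toolkit for mapping and interpreting methyltransferase-dependent m5C
sites in mRNA, built around the CTC[CT]A consensus motif (the methylated
cytosine is the first base of the motif). It implements the computational
stages of a site-mapping study as a tested, reusable pipeline and ships
ground-truth simulators so every stage can be exercised end-to-end at desk
scale:

- **`m5ckit.core_io`** — FASTA/FASTQ/GTF/BED/bedGraph/SAM-subset readers
  and writers, the transcript model, and the coordinate conventions
  (0-based half-open internally; GTF 1-based closed on disk).
- **`m5ckit.synthetic_data`** — transcriptomes with planted motif sites
  (optionally inside explicit stem-loops), truncation-style reads with the
  split 6-nt random barcode and PCR duplicates, bisulfite-converted reads
  with per-site stoichiometry and conversion-resistant artifact reads,
  triplet-periodic ribosome footprints with termination and readthrough,
  and negative-binomial count matrices with known fold changes.
- **`m5ckit.miclip`** — demultiplexing and PCR deduplication, truncation
  position assignment to the closest cytosine within ±2 nt, RPM
  normalization, the >50-RPM-in-2-of-3-replicates filter, and feature
  annotation with 50-nt window summaries.
- **`m5ckit.bsseq`** — three-letter (C/T-collapsed) alignment, the CCA-trim
  retry pass, the >1/3-methylated-cytosines artifact filter, per-cytosine
  methylation extraction, tRNA reference construction and multi-mapper
  resolution, and capped (5-read, exact-rational) site-level
  quantification around the motif.
- **`m5ckit.riboseq`** — footprint length/frame/periodicity filtering
  (lengths 27–29), nine-codon position profiles (−5..+3, 0 = A-site),
  codon enrichment between conditions, offset-12 P-site coverage tracks,
  and motif positioning within footprints.
- **`m5ckit.occupancy`** — ±flank coverage matrices around sites,
  upstream/downstream signal classification at ±1.96·SE, coding-sequence
  annotation profiles, and a 1000-draw randomized motif control with a
  percentile envelope.
- **`m5ckit.motif_structure`** — motif scanning, a simplified hairpin
  free-energy screen with a −5 kcal/mol stem-loop threshold (pluggable
  external folding engine), transcriptome-wide predicted-element
  enumeration, in-frame stop-codon frequency between the annotated stop
  and a 3′UTR site versus a downstream control, and stop-codon context
  distributions.
- **`m5ckit.diffexpr`** — CPM ≥ 1 expression filtering, a simplified
  fold-change/SE estimator, the translation-efficiency statistic
  `T = |log2FC_Ribo − log2FC_RNA| / sqrt(SE²_Ribo + SE²_RNA)` with
  two-tailed normal p-values and Benjamini–Hochberg correction, and
  Fisher odds-ratio overlap of target genes with differentially expressed
  genes across an RPM-threshold sweep.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end criteria (site recovery
precision/recall, bisulfite stoichiometry recovery, capping identity,
codon register, occupancy classification, TE calibration, Fisher oracle
equivalence, readthrough null, and randomized oracle equivalences).

## CLI

All stages are also exposed through a `click` CLI:

```sh
m5ckit simulate transcriptome --n-genes 50 --seed 1 --out sim/
m5ckit simulate miclip --truth sim/truth.json --fasta sim/transcriptome.fa \
    --depth 100 --pcr-dup-rate 0.5 --seed 1 --out rep1.fq
m5ckit miclip callsites --fastq rep1.fq --fastq rep2.fq --fastq rep3.fq \
    --fasta sim/transcriptome.fa --out-bed sites.bed --out-rpm rpm.tsv
m5ckit bsseq quantify --fastq bs.fq --fasta sim/transcriptome.fa \
    --sites sites.bed --out-report cytosines.tsv --out-profile profile.tsv
m5ckit ribo profile --sam fp.sam --fasta sim/transcriptome.fa \
    --gtf sim/transcriptome.gtf --out-prefix ribo
m5ckit occupancy classify --track ribo.psite.plus.bedgraph --sites sites.bed \
    --flank 300 --out classes.tsv
m5ckit seq predict --fasta sim/transcriptome.fa --gtf sim/transcriptome.gtf \
    --sites sites.bed --out predicted.bed
m5ckit diff te --rna rna_counts.tsv --ribo ribo_counts.tsv --out te.tsv
```

## Conventions

- Coordinates are 0-based half-open everywhere internally; GTF is
  converted on read/write, BED/bedGraph pass through unchanged.
- The truncation position of a read is the base immediately 5′ of its
  5′-most aligned base; equidistant cytosines in the ±2 nt window
  tie-break upstream.
- The P-site nucleotide is read offset 12 (0-based); the nine profile
  codons occupy read positions 1–27 with the A-site as codon position 0.
- Alignments are exchanged as a minimal SAM-subset text format (full-length
  matches, NM tag); coverage tracks as bedGraph.
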