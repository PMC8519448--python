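# hapmotif

Variant- and haplotype-aware scanning of transcription-factor motifs (PWMs)
over pangenome variation graphs.

`hapmotif` builds a per-chromosome sequence graph from a reference FASTA and
a phased VCF (SNPs and indels become bubbles anchored on the reference, with
one explicit path per sample haplotype), then slides a motif-width window
along the reference and haplotype paths (or along every recombinant walk),
scores each k-mer with an integer-scaled log-odds matrix whose attainable
totals span [0, 1000], assigns exact P-values by dynamic programming over
the scaled score distribution, converts them to q-values with the
Benjamini–Hochberg procedure over all scanned k-mer paths, and reports each
occurrence with its haplotype count and a `ref` / `non.ref` flag. Reports
are written as FIMO-style TSV, a UCSC-loadable GFF3 custom track, and HTML.

## Command-line usage

Build per-chromosome graphs (GFA v1 text, one file per chromosome):

```bash
hapmotif buildvg --reference genome.fa --vcf phased.vcf --out graphs/
```

Scan graphs for motif occurrences inside BED regions:

```bash
hapmotif findmotif \
    --graph graphs/ \
    --motif CTCF.jaspar \
    --bedfile peaks.bed \
    --pvalue-threshold 1e-4 \
    --out results/
```

Useful flags: `--recomb` scans every recombinant path instead of only the
observed haplotypes; `--background`, `--pseudocount` control the scoring
model; `--no-qvalue` / `--qvalue-threshold` control multiple-testing output;
`--cores N` scans chromosomes in parallel with byte-identical output.
Motif files may be JASPAR (bracketed or plain) or MEME minimal format.

## Library layout

- `hapmotif.motif_io` — JASPAR/MEME parsing, backgrounds, pseudocount
  normalisation.
- `hapmotif.scoring` — log-odds PSSM, [0, 1000] integer scaling, exact DP
  P-values, Benjamini–Hochberg, reverse-complement matrices.
- `hapmotif.genome_graph` — graph construction from FASTA+VCF, haplotype
  threading, GFA v1 round trip, region windows.
- `hapmotif.path_scan` — k-mer window enumeration (haplotype and recombinant
  modes) and per-site aggregation.
- `hapmotif.pipeline` — end-to-end scan, significance filtering, per-site
  classification (ref-only / non-ref-only / shared-modulated / shared-equal).
- `hapmotif.reports` — TSV / GFF3 / HTML writers.
- `hapmotif.fixtures` — deterministic toy FASTA/VCF/BED/motif generation
  with planted sites and an independent expected-hit oracle.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(scaled-score range, exhaustive P-value oracle, linear-scan equivalence,
haplotype-string oracle, BH correctness, planted-site recovery, recombinant
superset, determinism).

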