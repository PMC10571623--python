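# mrmod

Training-data-free detection of cis-regulatory modules (CRMs) from genomic
sequence. The pipeline scans sequences with a position-weight-matrix library
on both strands, converts per-position binding-site density into z-scores,
calls modules by thresholded seeding (z > 2.33) with gap-limited extension
along positive-z positions, constructs control regions whose length multiset
exactly matches the sub-250 bp prediction subset, and evaluates predictions
against reference region sets (overlap sensitivity, odds ratios with Woolf
CIs and chi-square tests, positional-shuffle nulls).

Supporting machinery: exact PWM score distributions with Patser-style
automatic cutoffs, ALLR/OLAP motif-redundancy consolidation, genomic-feature
annotation, hypergeometric gene-set enrichment, a region-by-factor count
matrix (Matrix Market), and a synthetic-fixture generator (background
sequence with implanted motif clusters plus truth BED) so everything is
testable offline.

## CLI

All commands run under a single `mrmod` entry point. Exit codes: 0 success,
1 usage error, 2 data error.

```sh
# synthetic fixture: FASTA + truth/site BEDs (+ .fai)
mrmod simulate --config sim.yaml --motifs motifs.jaspar --seed 1 --out sim/

# motif scan -> sites.bed (optionally per-record coverage bedGraph)
mrmod scan --fasta sim/sim.fa --motifs motifs.jaspar \
    --threshold-mode patser-default --out scan/

# full caller: scan -> coverage -> z -> CRM BED
mrmod call --fasta sim/sim.fa --motifs motifs.jaspar --z 2.33 --gap 30 \
    --out crms.bed

# redundancy consolidation of a motif library
mrmod consolidate --motifs motifs.jaspar --allr 6.57 --olap 68.1 --out cons/

# length-matched controls carved from non-CRM space
mrmod controls --crms crms.bed --fai sim/sim.fa.fai --cap 250 --trim 40 \
    --pad 5 --min-gap 400 --seed 1 --out ctrl/

# overlap statistics (optionally with a positional-shuffle null)
mrmod evaluate --refs sim/truth.bed --pred crms.bed \
    --ctrl ctrl/controls.bed --policy 1bp --null-reps 10000 \
    --fai sim/sim.fa.fai --seed 1 --out eval.tsv

# gene-set enrichment and the region-by-factor matrix
mrmod enrich --query query.txt --gene-sets sets.gmt --population pop.txt \
    --out enrich.tsv
mrmod tfmatrix --crms crms.bed --sites scan/sites.bed --map pwm2tf.tsv \
    --out tfmat
```

Motif files may be JASPAR raw-count or MEME minimal format. Region files are
plain BED (0-based half-open); annotation is GFF3/GTF.

## Layout

- `src/mrmod/pwm.py` — PWM model, log-odds scoring, exact score
  distributions, automatic thresholds, ALLR/OLAP consolidation
- `src/mrmod/scan.py` — two-strand scanning, coverage tracks
- `src/mrmod/call.py` — z-scores, seed/extension calling, end-to-end runner
- `src/mrmod/controls.py` — complement/gap-filter/carve control construction
- `src/mrmod/evaluate.py` — overlap statistics, shuffle null, feature
  annotation, enrichment, region-by-factor matrix
- `src/mrmod/simulate.py` — synthetic fixtures, dinucleotide shuffle
- `src/mrmod/cli.py` — subcommand front-end
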