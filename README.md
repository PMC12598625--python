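# probecap

A self-contained toolkit for **probe-capture targeted metagenomics** of
functional marker genes (nitrogen- and methane-cycling families such as
*amoA*, *nosZ*, *mcrA*): design capture probe panels, build mock communities
with controlled weighted GC mol%, simulate hybridization capture with an
optional GC-dependent efficiency model, classify captured reads by six-frame
translated homology, and score how faithfully the recovered gene profile
matches the ground truth.

No external databases or downloads are needed — the `mock_community` module
synthesizes reference genes, strain genomes and truth coordinates for every
fixture the rest of the pipeline consumes.

## Modules

| module | contents |
| --- | --- |
| `probecap.target_registry` | 14-family gene registry (homolog groups, decoy labels), PSSM profiles with Gumbel-calibrated E-values, profile search, 100%-identity dereplication |
| `probecap.probe_design` | greedy identity clustering (default 80%), up to six unique 50-mer probes per cluster, panel assembly/dedup |
| `probecap.mock_community` | weighted-GC math, KL-minimal mass fractions for a target GC, expected per-family abundances, synthetic strain genomes with planted genes |
| `probecap.capture_sim` | fragmentation (630 bp inserts), logistic-identity × linear-GC capture model, paired PE300 reads with truth labels |
| `probecap.read_classify` | six-frame translation, ≥60% identity protein matching, ≤4 matches/direction, ≤15 aa overlap, best-E collapse, homolog disambiguation |
| `probecap.evaluate` | expected-vs-observed Pearson r, homolog-aware precision/recall, 90%-identity binning, rarefaction with exact hypergeometric cross-check |
| `probecap.workbench` | `RunConfig`, per-stage seeds, end-to-end benchmark pipeline |

## CLI

```bash
probecap bench --seed 1 --out runs/                 # full pipeline, one command
probecap design --targets targets.fasta --threshold 0.80 --k 50 \
    --max-probes 6 --tm-target 47 --out panel/
probecap mock --strains strains.tsv --target-gc 53 --out mock/
probecap capture --design mock/mock_design.json --genomes genomes.fasta \
    --panel panel/ --truth truth.bed --out reads/
probecap classify --reads reads/captured_R1.fastq reads/captured_R2.fastq \
    --db proteins.fasta --min-id 60 --max-hits 4 --max-overlap 15 --out cls/
probecap evaluate --design mock/mock_design.json \
    --abundance cls/abundance.tsv --out eval.json
```

Target FASTA and protein FASTA carry family labels as `family=<name>` header
tokens. All coordinates in outputs (BED truth, hit intervals) are 0-based,
half-open; exit codes are 0/1/2 (ok / validation error / stage failure).

## Notes on scale

The toolkit reproduces the *method contracts* at desk scale. Quantities that
depend on wet-lab capture efficiencies or large public databases (panel size
of ~264k probes, on-target percentages of real libraries, field-sample
diversity counts) are out of scope; simulator defaults for the capture model
are configurable knobs, not fitted constants.
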