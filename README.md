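# asmram

Tools for right-sizing metagenome-assembler memory requests and for
core-microbiome ubiquity analysis:

* **k-mer features** (`asmram.kmer`) — read-set statistics (bases, GC,
  lengths) and canonical k-mer spectrum features (totals, distinct counts,
  per-frequency mass mean/SD/max, 5%/95% tail sums) for k = 13/21/71,
  interoperable with KMC two-column histogram files.
* **model pipeline** (`asmram.pipeline`) — peak-RAM regression per assembler
  parameter setting: Pearson correlation screening (r > 0.6, P < 0.05),
  10-fold cross-validation of six regressor families (linear, SVM, decision
  tree, voting, random forest, extremely randomized trees), exhaustive grid
  search, importance-based feature pruning, and a bootstrap-calibrated
  non-negative bias added to every prediction to guard against
  under-allocation. Models persist as a zip bundle (JSON metadata + joblib
  payload).
* **allocation** (`asmram.allocation`) — map a biased prediction to the
  smallest sufficient VM flavor, escalate to the next-larger flavor on
  out-of-memory failure, and simulate/compare fixed, optimum, and predicted
  allocation policies over a fleet with total-RAM accounting.
* **core microbiome** (`asmram.coremicro`) — Q1 − 1.5×IQR genome-coverage
  sample filter, ubiquity–abundance curves, global core (> 60% of samples),
  two-stage regional core (> 90% of a country's samples in ≥ 80% of a
  region's countries), and per-species top-abundance shares.
* **synthetic data** (`asmram.synth`) — seeded generators for genomes, FASTQ
  read sets, training tables with a planted linear RAM response, and
  abundance tables with planted global/regional core species; every
  generator is byte-reproducible and ships its ground truth as JSON.

## CLI

```bash
# feature extraction from FASTQ (gzip auto-detected by magic bytes)
asmram features --reads R1.fastq.gz --reads2 R2.fastq.gz --k 13,21,71 \
    --diversity 8.1 --out features.tsv

# train / evaluate a peak-RAM model (TSV with dataset_id, features, observed_peak_ram_gb)
asmram train --table train.tsv --mode meta-sensitive --out model.bundle
asmram evaluate --table test.tsv --model model.bundle

# flavor selection and fleet simulation
asmram predict --model model.bundle --features features.tsv --out pred.tsv
asmram simulate --peaks peaks.tsv --predictions pred.tsv \
    --fixed 14,29,58,113 --out report.tsv --plot policies.svg

# core-microbiome analysis
asmram coremicro --abundance ab.tsv --metadata meta.tsv \
    --global-ubiquity 0.6 --per-country 0.9 --country-fraction 0.8 --out report/

# synthetic fixtures
asmram synth reads --n-genomes 5 --n-reads 1000 --seed 1 --out fixtures/
asmram synth table --n-datasets 300 --seed 1 --out fixtures/
asmram synth abundance --samples-per-country 10 --seed 1 --out fixtures/
```

Flavor catalogs are YAML lists (`- {name: medium, ram_gb: 29}`); the default
catalog is 14/29/58/113 GB.

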