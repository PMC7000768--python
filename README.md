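# cas13screen

Toolkit for pooled CRISPR/Cas13 survival-challenge screens in which every
targeting guide is paired with a 3-base central-mismatch control. Covers the
full desk side of such a screen:

- **guide design** (`cas13screen.design`) — enumerate 28-mer spacers per
  transcript under GC (40–60%, inclusive), homopolymer (≤3), dinucleotide-run
  (≤2), repeat-mask and uniqueness (>0.7) filters; pick a spacing-maximal
  subset; derive mismatch controls by complementing spacer bases 12–14 and
  AAAC/AAAA cloning oligos.
- **quantification** (`cas13screen.quant`) — exact-substring spacer counting
  in amplicon FASTQ (both orientations, once per guide per read), zero→1
  replacement *before* total normalization, CPM scaling, log2 transform.
- **library QC** (`cas13screen.qc`) — coverage (fraction of guides detected)
  and evenness (90th/10th nearest-rank percentile of detected-guide counts).
- **screen inference** (`cas13screen.inference`) — per-guide D−ND contrasts
  between +Dox and matched −Dox libraries (same drug/batch/split), per-pair
  T−MT contrasts (targeting minus mismatch, cancelling sequence-independent
  Dox effects), per-transcript median T−MT, paired t-test of targeting vs
  mismatch D−ND values, Benjamini–Hochberg adjustment per drug, and
  permissive (raw p) / strict (adjusted p) depleted/enriched/ns calls with a
  marginal annotation for adjusted p in [0.05, 0.1).
- **expression response** (`cas13screen.expression`) — drug-induced fold
  changes `log2((NRC+1)/(NRC_DMSO+1))`, strong (>0.58 at both timepoints) /
  weak (>0 at both) target tiers, and two-sample group comparisons.
- **simulation** (`cas13screen.simulate`) — fully seeded generators for
  manifests, screen count tables (multiplicative per-round survival with
  drug bottlenecks, Beta-distributed guide efficacies, 3 batches × 2 splits,
  negative-binomial sequencing noise), amplicon FASTQ with exact bookkeeping,
  and expression tables with known tier labels.

A note on test sidedness: with the direction chosen from the data, a
one-sided paired t-test at level α has true size 2α. The default
(`alternative="auto"`) therefore reports the observed-direction tail
probability doubled — numerically the two-sided p — alongside the
direction, keeping the stated α calibrated; pure one-sided variants are
available via `alternative="less"/"greater"`.

## CLI

```sh
cas13screen --version
cas13screen simulate --config sim.yaml --seed 1 --out-dir sim/        # synthetic bundle
cas13screen design --fasta tx.fa --mask mask.bed --uniqueness u.tsv --out manifest.tsv
cas13screen count --manifest manifest.tsv --meta meta.tsv --out counts.tsv
cas13screen qc --counts counts.tsv --manifest manifest.tsv --out qc.tsv
cas13screen screen --log2 log2.tsv --meta meta.tsv --manifest manifest.tsv --alpha 0.05 --out calls.tsv
cas13screen expression --nrc nrc.tsv --out fc.tsv
cas13screen run --manifest manifest.tsv --meta meta.tsv --counts counts.tsv --out-dir out/
```

Exit codes: 0 ok, 1 user error, 2 internal error. `simulate` accepts a YAML
config overriding any `SimulationDesign` field, e.g.

```yaml
n_vlinc: 2
pairs_per_vlinc: 10
drugs:
  etoposide: {survival: 0.094, rounds: 1}
effects:
  vlinc01: {etoposide: -2.0}
```

All tables are TSV; FASTQ may be gzipped. Manifest coordinates are 1-based
inclusive; BED inputs are 0-based half-open.

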