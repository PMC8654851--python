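# rgenseq

Detection of CRISPR–Cas9 cleavage sites — on- and off-target — from the
read-end pileup signature they leave in an **amplification-free** sequencing
library, together with a faithful simulator of that library's chemistry so
every stage of the pipeline can be validated against planted ground truth.

## The problem and the signal

In vitro off-target screens digest purified genomic DNA with a Cas9:sgRNA
ribonucleoprotein (an RGEN) and sequence the products. In an
amplification-free protocol, a special first adapter is ligated only to
enzyme-cut ends, and the matching second adapter to fragmented ends, so only
molecules carrying one cut end and one fragmented end form clusters —
every read is an independent cut molecule, with no PCR duplicates or
coverage bias.

Cas9 cuts bluntly **3 bp upstream of the NGG PAM**. In the alignment this
produces a distinctive signature: forward reads whose 5′ ends pile up at
the breakpoint on one side, and reverse reads whose 5′ ends pile up at
breakpoint − 1 on the other. `rgenseq` scans the genome for this
signature, scores each candidate with the **window score**

> S(c) = number of read 5′ ends (both strands) in the 10-bp window
> [c − 5, c + 5)

and accepts a candidate as a cut site when a protospacer+PAM placement on
either strand — at up to 7 mismatches from the guide — implies a
breakpoint within 2 bp of the pileup. The per-copy cleavage probability in
the simulator follows single-turnover Hill saturation,

> p = Cʰ / (Cʰ + Kʰ)

with RGEN concentration C (nM) and per-site affinity K (the concentration
of half-maximal cleavage), which reproduces the sigmoid site-recovery curve
and the rise-then-fall of median scores with increasing enzyme.

## Worked example

Simulate a small library with two planted sites (a perfect target, K = 8 nM,
and a 2-mismatch off-target, K = 32 nM) and call cut sites from the
resulting SAM:

```
$ rgenseq simulate --guide ACGTACGTACGTACGTACGT --genome-length 50000 \
    --genome-copies 300 --sites "0:+:8,2:-:32" --seed 4 --out-dir simtest
750 reads -> simtest/reads.sam

$ rgenseq call --sam simtest/reads.sam --fasta simtest/genome.fa \
    --guide ACGTACGTACGTACGTACGT --out simtest/sites.bed
2 sites -> simtest/sites.bed

$ cat simtest/sites.bed
#chrom  start   end     name    score   strand  mismatches      matched_seq
chr_sim 30916   30917   site_0000       413     +       0       ACGTACGTACGTACGTACGTGGG
chr_sim 46916   46917   site_0001       337     -       2       ACGTACGTACCTACGTAGGTTGG
```

Both planted sites are recovered at their exact breakpoints. The window
scores (413 and 337 read ends) track the sites' cleaved-molecule counts:
at 64 nM the K = 8 nM target is cut in ~89 % of the 300 copies and the
K = 32 nM off-target in ~67 %, and each cleaved molecule contributes up to
two reads surviving 80 % ligation efficiency. The `mismatches` column
counts Hamming mismatches of the matched 23-mer (protospacer+PAM, last
three bases) against the guide.

The built-in end-to-end benchmark prints the package's headline metrics:

```
$ rgenseq benchmark --seed 11
n_reads_standard            2.224e+05
recall_low_mismatch         100
modal_pam_offset_bp         3
replicate_score_r2          0.9967
median_skew_end_repair_on   0.2595
median_skew_end_repair_off  25.42
```

i.e. on a 1-Mb genome with 12 planted sites (0–6 mismatches, ~222k reads)
every ≤3-mismatch site is recovered, the pileups sit exactly 3 bp from the
PAM, window scores of independently simulated replicate libraries correlate
with R² ≈ 0.997, and skipping the end-repair step raises the median flank
skewness from ~0.3 % to ~25 %.

## Package layout

| module | contents |
| --- | --- |
| `rgenseq.synthetic_data` | genome generation, site planting, Hill cleavage, read emission (SAM/FASTA/BED writers) |
| `rgenseq.align_io` | read-5′-end track extraction from SAM/BAM, BED6+ site I/O, (nested) subsampling |
| `rgenseq.cutsite_caller` | window scoring, candidate detection, guide/PAM matching, exhaustive genome scan |
| `rgenseq.diagnostics` | flank skewness, productive-read fraction, saturation curves, concentration response, score stats by mismatch group |
| `rgenseq.site_compare` | tolerance merging, UpSet distinct/intersect counts, replicate score correlation |
| `rgenseq.cli` | `rgenseq simulate / call / diagnose / compare / benchmark` |

See `docs/methods.md` for the model, its assumptions, and all numeric
conventions.
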