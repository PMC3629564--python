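# aluclip

Quantitative iCLIP analysis of competition between RNA-binding proteins,
built around the biology of hnRNP C and U2AF65 at Alu elements.

Antisense Alu elements in introns carry two uridine tracts — transcribed
from the element's poly(A) linker and tail — that mimic the polypyrimidine
tract upstream of a 3′ splice site. The splicing factor U2AF65 can
recognize these cryptic signals; hnRNP C binds long continuous U-tracts
and blocks U2AF65 from them, suppressing Alu exonization. `aluclip`
implements the computational side of this analysis for anyone quantifying
such competition from iCLIP-style crosslink data: binding-site calling,
occupancy normalization, differential binding between knockdown and
control, Alu-exon discovery, positional RNA maps and motif enrichment, and
an evolutionary selection statistic on U-tract lengths — together with a
synthetic-data generator that plants the competition structure so every
step can be validated end to end.

## Core quantities

* **Binding sites.** For crosslinked position *i* within a gene, the
  height *h(i)* is the number of crosslink events within ±*f* nt. Placing
  the gene's *n* events uniformly at random (R iterations) gives
  FDR(*h*) = E[#randomized positions with height ≥ *h*] / #observed
  positions with height ≥ *h*. Positions with FDR below the threshold
  (default 5%; flank 10 nt for broad binders such as hnRNP C, 5 nt for
  focused binders such as U2AF65) merge into sites when within one flank
  of each other; the summit is the position with the most events.
* **Normalized occupancy.** site events / (gene total in-site events ×
  gene length); for broad binders the numerator is restricted to an
  11-nt window centred on the summit.
* **Differential binding.** log₂(occ_KD/occ_Ctrl) after median-of-ratios
  size-factor correction, with categories *up*/*down* at |log₂FC| ≥ 2
  (at least four-fold) and *unchanged* at |log₂FC| < 0.1.
* **Combiner.** A change is reproducible across two knockdowns when
  p < 0.01 in at least one, p < 0.05 in the other, and the fold changes
  agree in direction.
* **U-tract selection statistic.** For each length L, the fraction of
  exonized elements with a U-tract of ≥ L uridines divided by the same
  fraction in nonexonized antisense elements from the same genes, with a
  chi-square (or Fisher) p-value per L.

## Worked example

```python
from aluclip import SimConfig, simulate_dataset
from aluclip.occupancy import competition_summary

cfg = SimConfig(n_genes=50, seed=7)            # suppression s = 0.8
genome, truth, tracks, counts = simulate_dataset(cfg)
table = competition_summary(truth, tracks, iterations=50, seed=7)

on = table[table.overlaps_tract]
off = table[~table.overlaps_tract]
print(f"{len(table)} U2AF65 sites called; {len(on)} overlap an occupied U-tract")
print(f"mean log2(KD/Ctrl): tract sites {on.log2fc.mean():+.2f}, "
      f"other sites {off.log2fc.mean():+.2f}")
print(table.category.value_counts().to_string())
```

prints

```
3737 U2AF65 sites called; 198 overlap an occupied U-tract
mean log2(KD/Ctrl): tract sites +0.37, other sites +0.04
category
other        3053
unchanged     502
up            130
down           52
```

U2AF65 sites that overlap a planted hnRNP-C-occupied U-tract gain binding
once the competitor is removed (+0.37 log₂ units on average), while the
remaining sites are centred near zero — the competition signature the
pipeline is designed to detect.

A file-level interface covers the pipeline steps:

```bash
aluclip simulate --config cfg.yaml --out sim/ --seed 4
aluclip callpeaks --track sim/xl_U2AF65_ctrl.bed --genes sim/genes.gtf \
        --flank 5 --iterations 100 --seed 7 --out sites.tsv
aluclip diffbind --sites sites.tsv --genes sim/genes.gtf \
        --ctrl sim/xl_U2AF65_ctrl.bed \
        --kd sim/xl_U2AF65_kd1.bed --kd sim/xl_U2AF65_kd2.bed --out diff.tsv
aluclip utract-ratio --exonized ex.tsv --control ct.tsv --lengths 3:12 --out ratio.tsv
```

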