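# vlincscan

Tools for calling **very long intergenic non-coding RNA regions (vlincRNAs)**
from RNA-seq coverage and for testing whether their promoters associate with
chromatin-state annotations and LTR retroviral repeats.

vlincRNAs are transcribed regions of 50 kb up to ~1 Mb lying outside
annotated genes. They are called directly from coverage — either
strand-specific "contig" tracks (blocks of overlapping mapped reads with a
per-contig base count) or unstranded per-base density tracks — rather than
from assembled transcripts. Their hallmark biology is promoter-driven,
highly cell-type-specific expression, with promoters frequently embedded in
endogenous-retrovirus LTRs in malignant and pluripotent cells. `vlincscan`
implements the full coordinate-space analysis for this class of RNA:
region calling, promoter and repeat annotation, binomial overlap-enrichment
statistics on an explicit genomic null, expression quantification and
specificity indices — plus a synthetic-data generator that plants ground
truth so every stage is testable without external downloads.

Intended users: computational genomics groups analysing long non-coding
transcription from coverage tracks, and anyone needing a calibrated
overlap-enrichment statistic for genomic interval sets.

## The statistics at the core

**Region calling (strand-specific).** Contigs overlapping same-strand gene
bodies are removed; survivors are merged across gaps ≤ 1 kb; merged blocks
< 50 kb are discarded; remaining regions are merged across gaps ≤ 5 kb.
The unstranded caller instead zeroes gene positions in a density track,
thresholds at the nearest-rank 80th percentile of the remaining nonzero
per-base densities, merges across ≤ 500 bp (or 1 kb) gaps and keeps regions
≥ 50 kb.

**Overlap enrichment.** For N tested regions with a subject feature set
(promoters, another region set, SNPs), each region *i* gets a success
probability

    p_i = Occupied_space_i / (|Space_i| − V)

where `Space_i` is the genome minus an *anti-space* (genes, blacklist,
optionally inter-gene gaps < 50 kb) whose intervals are extended by the
region's length L_i (one-sided at the 5' side, or symmetric L_i/2 for
set-vs-set tests), `Occupied_space_i` is the part of `Space_i` covered by
the subject features extended ±5 kb, and V is the total tested-region
length. Subtracting V makes the estimate an explicit upper bound
(conservative) under multiple tested regions. With m = Σ p_i and n observed
overlaps, the p-value is the exact binomial tail P(ξ ≥ n) for
ξ ~ B(N, m/N), computed in log space so magnitudes far below 1e-300 stay
finite. Repeat-family tests operate on clusters of same-family copies with
p = |region promoters| / |eligible-space promoters|; the strand-resolved
variant reports the upper bound B(N⁺+N⁻, max(p⁺, p⁻)).

**Expression.** Per-region counts are summed contig base counts
(strand-specific, contigs with counts > 1e6 discarded as artifacts),
normalised to 2e10 sequenced bases and 1e6 bases of region length. Tissue
specificity is the ratio of the highest to the second-highest expresser
after replacing zeros with the dataset-wide minimum nonzero value.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
from vlincscan.synthetic import SimParams, simulate_annotation, emit_contigs
from vlincscan.caller import call_from_contigs
from vlincscan.annotation import classify_promoter_repeats, assign_promoters_to_vlincs
from vlincscan.enrichment import test_promoter_overlap_stranded

sim = simulate_annotation(SimParams(seed=1, n_planted_vlincs=8))
contigs = emit_contigs(sim)
vlincs = call_from_contigs(contigs["malig1"], sim.gene_set, sample="malig1")
print(f"called {len(vlincs)} regions; lengths {sorted(v.length for v in vlincs)}")

proms = classify_promoter_repeats(sim.promoters_by_line["malig1"], sim.repeats)
assignments = assign_promoters_to_vlincs(vlincs, proms)
print(sum(1 for a in assignments if a.promoter_indices), "promoter-associated,",
      sum(a.ltr_driven for a in assignments), "LTR-driven")

res = test_promoter_overlap_stranded(vlincs, proms, sim.gene_set,
                                     sim.blacklist, sim.genome)
print(f"N={res.N} n={res.n_observed} m={res.m_expected:.2f} "
      f"fold={res.fold:.1f} log10p={res.log10_p:.1f}")
```

prints

```
called 8 regions; lengths [59959, 72442, 88636, 123471, 183419, 194911, 323125, 449300]
8 promoter-associated, 2 LTR-driven
N=8 n=8 m=0.11 fold=72.5 log10p=-14.9
```

All eight planted regions (50–450 kb) are recovered with exact boundaries,
every one is associated with the Active promoter planted at its 5'
boundary, two of those promoters contain an embedded LTR, and the promoter
association is 72-fold above the genomic-null expectation of 0.11 regions
(p ≈ 1e-15).

The same analysis runs from the shell:

```bash
vlincscan simulate --seed 1 --out simdir/
vlincscan call-contigs --contigs simdir/contigs.malig1.bed \
    --genes simdir/genes.bed --out vlincs.bed --sample malig1
vlincscan run --config demo.yaml      # full pipeline from a YAML config
```

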