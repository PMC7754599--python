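# repeatome

Comparative repeatome analysis for closely related taxa: transposable-element
(TE) divergence landscapes, read-based repeat quantification, cross-sample
satellite DNA (satDNA) family definition, library-hypothesis statistics,
tandem-repeat structure, and recent-TE expression labeling — with a
ground-truthed synthetic repeatome generator so every stage can be validated
end to end without raw sequencing data.

The package is aimed at researchers comparing the repetitive fraction of
several related genomes (races, subspecies, or young species) who want to
ask: which repeat families are shared, which have recently amplified or
contracted in particular lineages, and which TEs are recently active and
transcribed.

## The models at the core

**Kimura 2-parameter (K2P) distance.** Each repeat copy's divergence from its
family consensus is measured with the two-state substitution model

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

where *P* and *Q* are the proportions of transition (A↔G, C↔T) and
transversion differences over compared sites. A **repeat landscape** bins
repeat-derived bp by K2P in 1% intervals; copies below 5% divergence are
treated as *recent* and below 1% as *very recent*, since low divergence from
the consensus implies recent insertion.

**satDNA families and the library hypothesis.** Tandem-repeat monomers have
arbitrary phase and strand, so monomer comparisons are rotation- and
reverse-complement-invariant (alignment against the doubled partner, both
strands). Monomers are merged into families under the **80-80-80 rule**
(≥ 80% identity over ≥ 80% of the shorter monomer and ≥ 80 aligned bp,
relaxed proportionally for short monomers), with single-linkage merging
across samples. The *library hypothesis* — related lineages share an
ancestral collection of satDNA families whose copy numbers drift
independently — is assessed from the presence/absence matrix, the
coefficient of variation of genome proportions across samples
(cv = sd/mean × 100; cv > 80% flags differential amplification), and
Kruskal–Wallis tests on the per-family divergence profiles.

**Genome proportion (GP).** Abundance is quantified by masking a subsample of
read pairs against the combined repeat library and reporting masked bp /
total sampled bp, with roll-ups from family to superfamily, class, and
total.

**Recent-TE expression.** Annotated copies with K2P < 5% define the
recent-TE annotation; aligned RNA-seq reads are counted per TE subfamily
with fractional assignment of multi-family reads, normalized with
median-of-ratios size factors, and labeled MBTE/FBTE (male-/female-biased)
when |log2FC| > 0 with Benjamini–Hochberg adjusted P < 0.05.

## Worked example

The closed-loop experiment simulates four 1 Mb races sharing an ancestral
satDNA library of 12 families (9 present in all races), with family 1
amplified 5-fold in race 1 at 2% divergence, then runs the full pipeline
(read simulation → masking → monomer clustering → library matrix → cv and
Kruskal–Wallis statistics) and compares against the planted truth:

```bash
$ repeatome --seed 1 closed-loop
{
  "n_families": 12,
  "n_shared": 9,
  "amplified_family": "satDNA-1",
  "amplified_cv": 98.0708060808906,
  "amplified_flagged": true,
  "modal_bin_amplified": 2,
  "planted_divergence_bin": 2,
  "planted_n_families": 12,
  "planted_n_shared": 9
}
```

Reading the output: the pipeline recovered all 12 planted families and the
9-family shared core exactly; the amplified family was assembled as
`satDNA-1` (families are numbered by descending pooled abundance, so the
amplified family ranks first), its genome-proportion cv across races is
98% — above the 80% differential-amplification threshold — and the modal
1% divergence bin of its landscape is bin 2, matching the planted 2%
divergence.

Other entry points: `repeatome simulate` (write a synthetic race panel to
disk), `repeatome quantify` (GP table from FASTQ reads and a library
FASTA), `repeatome satlib` (presence matrix + family statistics),
`repeatome landscape` (divergence landscape from a RepeatMasker-style
`.align` file), `repeatome trstruct` (tandem array and higher-order-repeat
reports). Every command takes `--seed`, `--out-dir`, and `--log-level`.

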