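# nexuspause

Analysis toolkit for **reporter-ChIP-nexus** measurements of RNA
polymerase II promoter-proximal pausing in *Drosophila*: from barcoded,
aligned reads to strand-separated exonuclease stop-base profiles,
triptolide-retention quantification of pausing stability on reporter
plasmids, and genome-scale stratification of paused-Pol II half-lives
by core promoter elements (TATA box, initiator, Inr-G/Inr-nonG
variants, pausing elements).

## The measurement and the model

ChIP-nexus digests immunoprecipitated chromatin with lambda
exonuclease, so the 5′ end of each read marks the exonuclease **stop
base** at a protein–DNA crosslink boundary. On a promoter this resolves
Pol II at the site of initiation (the TSS, +1) from Pol II paused
30–50 bp downstream.

Triptolide blocks new initiation; paused Pol II then decays by first
order kinetics. For a treatment of *t* minutes and a pausing half-life
*h*, the retained fraction of pause signal is

```
retention = Total_Pol_sig(triptolide) / Total_Pol_sig(control) = 2^(−t/h)
h = −t · ln 2 / ln(retention)
```

where `Total_Pol_sig` is the strand-combined stop-base signal in a
301-bp window around the reporter TSS after reads-per-million
normalization to the library's genome-aligned read count. Because the
control and treated libraries come from one transfection pool and are
normalized to genome reads, the ratio is independent of transfection
efficiency and sequencing depth.

Core promoter elements are annotated by positional IUPAC consensus
matching with at most one mismatch: TATA box `STATAWAWR` fully inside
−40..−20, initiator `TCAKTY` anchored at −2..+4 (A at +1), and the
downstream pausing-element consensi `CSARCSSA`, `KCGGTTSK`, `KCGRWCG`.
Initiators are split by the base at +2 into **Inr-G** (literal G) and
**Inr-nonG** variants; promoter classes ("TATA": TATA box and half-life
< 30 min; "stably paused": no TATA box and half-life ≥ 60 min) feed
sequence-composition analyses (position frequency matrices, information
content, G-at-+2 frequencies with Fisher's exact test) and half-life
stratification by element combination (Wilcoxon rank-sum, exact for
small samples).

A synthetic-data module generates promoter cohorts with elements
planted at canonical positions, half-lives drawn log-normally around
per-combination medians, ChIP-nexus-like reads (initiation and pause
peaks, Poisson counts, exponential decay under triptolide, PCR
duplicates sharing barcodes, paired libraries sharing one transfection
pool), and qPCR Ct tables — with ground truth for parameter-recovery
tests.

## Worked example

Simulate a reporter carrying a canonical Inr-G initiator with a true
pausing half-life of 60 min, a paired control/triptolide library set
(60 min treatment), and back-calculate the half-life:

```python
from nexuspause import (ElementSpec, SimReadParams, TriptolideDecay,
                        make_promoter, profile_from_reads,
                        simulate_library_pair)

seq, truth = make_promoter([ElementSpec("INR", force_plus2="G")],
                           length=300, tss_offset=150, seed=1,
                           true_halflife_min=60.0, promoter_id="pk_reporter")

params = SimReadParams(n_pause_reads=100_000, n_init_reads=2_000)
(ctrl_reads, ctrl_genome), (trt_reads, trt_genome) = simulate_library_pair(
    truth, params, treat_min=60.0, seed=5)

model = TriptolideDecay(
    profile_from_reads(ctrl_reads, "pk_reporter", truth.length, ctrl_genome),
    profile_from_reads(trt_reads, "pk_reporter", truth.length, trt_genome),
    tss_index=truth.tss_index, treat_min=60.0, construct_id="pk_reporter")
print(model.fit().summary())
```

```
Paused Pol II stability: pk_reporter
============================================
  triptolide treatment      60 min
  Total_Pol_sig control     102305.447
  Total_Pol_sig treated     50005.700
  retention ratio           0.4888
  est. half-life (min)      58.1
```

After one half-life of treatment about half the windowed pause signal
remains (retention 0.49), and inverting the decay law recovers the
planted 60-minute half-life within Poisson noise.

The same operations are exposed on the command line
(`nexuspause simulate | profile | stability | annotate | stratify |
classes | logo | g2test | tss5p | qpcr | validate`). For example,
stratifying a simulated four-group cohort:

```
$ nexuspause simulate --mode cohort --n-per-group 100 \
      --groups "Inr-G,Inr-nonG,pausing,TATA" --seed 42 --out cohort
$ nexuspause stratify --fasta cohort/promoters.fasta --tss-index 150 \
      --halflives cohort/halflives.tsv --mode exclusive --out strat.tsv
   label   n  median_min
   Inr-G 100   44.196074
 pausing 100   18.552439
Inr-nonG 100   13.466357
    TATA 100   12.838684
```

Promoters carrying an Inr-G initiator pause about three times longer
than Inr-nonG or TATA promoters, matching the planted group medians.

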