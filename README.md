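# acascan

Anti-CRISPR–associated (**Aca**) proteins are small helix-turn-helix
repressors encoded downstream of anti-CRISPR (**acr**) genes on phages and
other mobile genetic elements; they autorepress the *acr–aca* operon by
binding inverted-repeat (IR) operator sites inside the operon's σ70
promoter. `acascan` is an analysis pipeline for surveying this regulatory
architecture in annotated bacterial genomes: it scans for Aca/Acr family
homologs, calls operons, classifies each aca-like gene as acr-associated,
proximal or solo, extracts promoters, predicts −35/−10 core elements and
IRs (IR1 = inside the core promoter, IR2 = outside it), discovers shared
promoter motifs, builds the aca×acr family association network, and
contrasts associated versus solo homologs statistically.

It is aimed at researchers studying acr regulation who need a transparent,
fully testable desk-scale implementation of this workflow. Every stage is
exercised end-to-end on synthetic communities with planted ground truth, so
the whole pipeline is verifiable without any database downloads.

## The core methods

* **Family scanning** — position-specific log-odds profiles
  (score(a) = log₂(((f_a + pc·bg_a)/(1+pc))/bg_a) per column) slid ungapped
  over CDS translations; per-family thresholds calibrated on background-only
  genomes.
* **Operon rule** — same-strand CDS with ≤ 55 intervening bases share an
  operon; association is decided in the operon first, then a ±5 kb
  neighborhood.
* **Promoters** — 400 bp upstream of the operon leader; σ70 core elements by
  consensus-PWM scan (TTGACA/TATAAT, spacer 15–19 penalised 0.5 bits/base
  from 17); IRs by exhaustive mismatch-tolerant enumeration reporting only
  maximal repeats; motifs by a strand-aware Gibbs sampler (OOPS/ZOOPS) with
  phase-shift moves.
* **Statistics** — Welch's t-test for associated-vs-solo contrasts
  (>40 % coverage filter, strict), neighbor joining on 1 − identity for
  family trees, Newick export.

See `docs/methods.md` for the full model descriptions and assumptions.

## Worked example

```bash
python analysis/01_simulate_community.py
python analysis/02_scan_and_classify.py
```

prints, for the default community (10 contigs, 5 planted acr–aca operons,
5 solo aca genes, 50 background CDS, seed 11):

```
community: 10 contigs, 67 CDS
planted: 5 acr-aca operons, 5 solo aca, 10 promoters
hits: 17 (10 aca loci, 7 acr loci)
association: 5 acr-associated, 0 proximal, 5 solo
network edges: [{'a': 'AcaS1', 'b': 'AcrC1', 'weight': 3}, {'a': 'AcaS1', 'b': 'AcrK1', 'weight': 3}]
```

Every planted aca locus is found (10 hits, no false positives), the five
operonic ones are labelled acr-associated and the five isolated ones solo,
and the network records how often the aca family co-occurs with each acr
family in an operon. `analysis/03_promoters_and_irs.py` then verifies the
promoter layer against the generator's manifest:

```
recovered 10/10 windows, 10/10 exact core elements, 10/10 planted IRs as IR1
```

i.e. every 400 bp promoter window, every planted −35/−10 pair and every
planted IR is recovered, with the IR classified IR1 because it overlaps the
core promoter — the configuration consistent with repression by operator
occlusion. `analysis/04_motif_discovery.py` benchmarks the Gibbs sampler
(planted 18-mers recovered in 100 % of seeds, ~31 bits of information
content versus ~12 on background), and `analysis/05_family_statistics.py`
shows the associated-vs-solo identity contrast on a community built with
more divergent solo members:

```
AcaS1: identity Welch t=7.57, df=6.4, p=0.0002
 AcaS1 associated  5  mean_identity 0.903
 AcaS1       solo  5  mean_identity 0.691
```

The same stages are available as CLI subcommands
(`acascan simulate|run|scan|cluster|context|promoters|motifs|stats`).

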