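# vdjrep

Simulation and annotation of single-cell IgG heavy-chain V(D)J
repertoires.

Some non-B cell types transcribe immunoglobulin heavy chains. When such a
repertoire is characterised at the single-cell level — a handful of cloned
Sanger sequences per sorted cell, aligned against germline IGHV/IGHD/IGHJ
segments — the questions are always the same: which germline segments were
used and how often, what are the non-templated N additions at the V–D and
D–J junctions, how much somatic hypermutation (SHM) is there and does it
carry the antigen-driven signatures (RGYW/WRCY hotspot motifs, CDR > FR
concentration), what fraction of rearrangements is nonfunctional, how many
distinct rearrangement patterns does one cell express, and do different
cells — even different donors — share rearrangements with identical
junctions? `vdjrep` implements that entire desk-scale workflow, plus a
V(D)J recombination simulator that generates synthetic single-cell
repertoires with ground truth, so every stage is testable without any
sequencing data.

## What's in the box

| module | role |
| --- | --- |
| `vdjrep.germline` | germline segment reference (FASTA + metadata TSV) with IMGT-style region delimitation; a packaged synthetic reference covering families VH1–7, DH1–7, JH1–6 |
| `vdjrep.simulator` | V(D)J recombination with trims and N additions, hotspot/CDR-biased SHM, nonfunctional rearrangements, 1–3 patterns per cell over 4–8 colony sequences, shared clonotypes; full truth table |
| `vdjrep.annotator` | V/D/J assignment by local alignment (match +2, mismatch −1, gap −4/−1; D needs ≥5 consecutive exact matches), junction and CDR3 delineation, productivity classification, per-region mutation calling over the FR2→JH window |
| `vdjrep.shm` | hotspot scanning, hotspot mutation fraction, CDR-vs-FR paired rates with a paired t-test, SHM frequency binning |
| `vdjrep.repstats` | detection rates, usage tables and chi-square comparison, patterns per cell, shared identical-junction sets, CDR3-length Gaussian fit with R², genomic 3′-concentration of V usage |
| `vdjrep.cli` | `vdjrep simulate \| annotate \| analyze` |

The model of a rearrangement is the classic one: a sequence is
`V[:−t_v] + N1 + D[t_5:−t_3] + N2 + J[t_j:]`, productive iff the conserved
FR3 Cys and J-Trp codons are in frame with no intervening stop. SHM places
independent per-position substitutions with probability ∝
`hotspot_bias^[in RGYW/WRCY] × cdr_bias^[in CDR]`, scaled so the expected
per-sequence rate equals a drawn target rate. A sequence is "mutated" when
its germline-aligned mismatch frequency over FR2→JH is ≥ 2%. Two presets
bundle the study conditions: `ptec-like` (71% VH1 usage concentrated at the
3′ end of the locus, SHM 2.9–20.5% with ~60% of sequences in 5–10%, 5.8%
nonfunctional, 86.8/11.0/2.2% of cells with 1/2/>2 patterns, public
clonotypes on) and `bcell-like` (diverse VH3/VH4-heavy usage spanning the
locus, 3.9% nonfunctional, no sharing).

## Worked example

```bash
vdjrep simulate --preset ptec-like --seed 7 --out run/
vdjrep annotate --in run/repertoire.fasta --truth run/truth.tsv --out run/annotations.tsv
vdjrep analyze --in run/annotations.tsv --out run/reports/
```

The annotate step logs the accuracy against the simulator's truth table:

```
INFO vdjrep: accuracy report: {'n': 247, 'v_accuracy': 1.0, 'd_accuracy': 0.9352,
             'j_accuracy': 1.0, 'productivity_agreement': 1.0}
```

and `run/reports/summary.json` holds the repertoire summary; for seed 7 at
20 cells per donor it contains (abridged):

```json
"productivity": {"nonfunctional": 22, "total": 247, "percent_nonfunctional": 8.9},
"usage":        {"V_family": {"frequencies": {"VH1": 0.735, "VH3": 0.143, ...}}},
"shm":          {"hotspot_fraction": 0.8873,
                 "cdr_vs_fr": {"mean_cdr_rate": 0.090, "mean_fr_rate": 0.046,
                               "paired_t": 9.75, "pvalue": 3.4e-19}}
```

— 8.9% of colony sequences are nonfunctional at this small scale (the
preset rate is 5.8%), 73.5% of distinct patterns use a VH1 gene, ~89% of
somatic mutations fall in RGYW/WRCY hotspot windows, and mutation rates
are significantly higher in the CDRs than in the framework regions — the
annotation pipeline recovers the biased, antigen-selected character the
simulator put in.

The same objects are available as a library: `make_config` /
`simulate_repertoire`, `annotate_many`, and `analyze_annotations`, which
returns a `RepertoireSummary` with every statistic as a typed object.

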