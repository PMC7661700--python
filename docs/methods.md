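# Methods

## Scope and model

`vdjrep` analyses rearranged immunoglobulin heavy-chain (IgH) variable
regions at the single-cell level and simulates them. A rearrangement is
modelled as

    sequence = V[: |V|−t_v] + N1 + D[t_5 : |D|−t_3] + N2 + J[t_j :]

with exonucleolytic trims `t` and non-templated N additions at the V–D and
D–J junctions. Emitted sequences are FR2→JH amplicons — they start at the
germline FR2 boundary of the V gene and end at the 3′ end of the J segment
— matching the window that nested-PCR single-cell protocols amplify with an
FR2-anchored primer. All coordinates are 0-based half-open; CDR3 is
delimited IMGT-style from the codon after the conserved FR3 cysteine to the
codon before the conserved J tryptophan, anchors excluded.

## Germline reference

The packaged reference is **synthetic**: 33 V genes (families VH1–VH7,
including a 5′-distal IGHV3-53…IGHV3-74 block), 15 D genes (DH1–DH7) and
IGHJ1–6, one allele per gene, with IMGT-style names and genomic order
indices mirroring the human IGH locus layout (rank 0 = IGHV6-1, the most
JH-proximal V). V sequences are 297 nt of stop-free sense codons with fixed
region boundaries (FR1 25 / CDR1 8 / FR2 17 / CDR2 8 / FR3 38 codons, then
TGT and two CDR3 codons); J segments are a 4–8 nt CDR3 tail, TGG, and a
10-codon stop-free FR4; D segments are 20–28 nt constructed so that no
5-mer occurs in two different D genes, which makes the annotator's
"≥5 consecutive exact matches" D rule unambiguous on unmutated sequences.
Real germline V genes are mutually similar within families; random
sequences are not, so segment-assignment accuracies measured here are upper
bounds on what the same aligner would achieve against a real database. The
generator (`synthesize_reference`) is deterministic; the shipped files are
its seed-20201112 output.

## Simulator

One `numpy` generator seeded once per run drives every draw; identical
configs produce byte-identical outputs.

Per cell: the number of distinct rearrangement patterns is drawn from
`patterns_per_cell_dist` (default preset 0.868/0.110/0.022 for 1/2/>2);
each pattern is replicated over 4–8 colony sequences (uniform), each
pattern getting at least one colony; colony replicates are exact copies by
default (`colony_error_rate` adds optional per-base noise, default 0,
because identical colony sequences are collapsed to one pattern anyway).

Per pattern: segments are drawn from the configured usage vectors, trims
uniformly in `0..trim_max` (default 4; V 3′ and J 5′ trims are capped so
the CDR3 anchor codons survive), N lengths from a geometric with mean 6 nt
capped at 15 (no junction-length distribution is reported for this kind of
data; geometric/mean-6 is an engineering default), N bases uniform over
ACGT (no P-nucleotides). The D–J insert is padded by 0–2 random bases to
bring the J-Trp codon in frame, and junction bases are redrawn (then, if
necessary, the whole rearrangement) until the amplicon is stop-free, so
every baseline rearrangement is productive.

Nonfunctional rearrangements: with probability `p_nonfunctional`
(preset 0.058) a pattern is made nonfunctional, half by writing a random
stop codon over a clean in-frame codon (recorded as mutations), half by
changing the N2 length by ±1 (frameshift). The draw happens per pattern —
nonfunctionality is a property of the transcript, not of a colony — so
colony-level counts are cluster-correlated and the generator-recovery test
is binomial at the pattern level.

SHM: a per-sequence target rate is drawn from a piecewise-uniform mixture;
the `ptec-shm` preset puts 20/60/20% of mass on 2.9–5 / 5–10 / 10–20.5%.
Each germline-templated position (V, D and J portions; N bases are never
mutated) then flips independently with probability proportional to
`hotspot_bias^[in RGYW/WRCY window] × cdr_bias^[in CDR]`, scaled so the
expected mutation count is `rate × (#templated positions)`. Hotspot windows
are scanned on the pre-mutation sequence (AID reads the germline context).
The substituted base is uniform over the three alternatives except ones
that would create an in-frame stop (at least one non-stop alternative
always exists), keeping the nonfunctional fraction at its configured value.
`hotspot_bias` defaults to 32 in the presets, the closed-form value
`0.9(1−f)/(0.1 f)` at the reference's masked fraction f ≈ 0.22, which makes
~90% of mutations fall in hotspot windows; `cdr_bias` defaults to 4, enough
for the CDR-vs-FR paired t-test to reject at the study scale.

Shared clonotypes: a global pool of `shared_pool_size` (12) rearrangement
cores is sampled up front; each productive pattern draws from the pool with
probability `p_shared_clone` (preset 0.15). A pool clone carries one frozen
hypermutated copy, so every cell expressing it emits the identical
sequence — identical junctions *and* identical mutations. This mirrors the
observation that public rearrangements present with the same CDR3 and
similar mutation patterns across donors, and it is what makes
identical-junction sharing detectable after annotation; giving each cell
independent SHM was tried and perturbs the inferred junction keys often
enough to hide most sharing.

What the generator does **not** model: P-nucleotides, insertions/deletions
from SHM, transition/transversion bias, strand-polarised AID targeting,
allelic variation, transcript abundance, or sequencing error. Passing tests
therefore demonstrate that the analysis recovers the statistical structure
above, not that it is robust to every artefact of real Sanger data.

## Annotator

Local alignment uses Biopython's `PairwiseAligner` with match +2,
mismatch −1, gap open −4, gap extend −1. All segments of a class are
scored; the full alignment is computed for the best (ties break by lower
genomic rank, then name). V or J below score 40 is a per-sequence
annotation failure, recorded and skipped. The J search is restricted
downstream of the V match; D is searched only in the V→J window and called
when some D gene has ≥5 consecutive exact matches (longest match wins),
else "unassigned" and the whole insert is reported as one junction string.

Four deterministic refinements keep alignment artefacts out of the calls:

1. the V alignment's 3′ end and the J alignment's 5′ start are trimmed back
   until they end in 5 consecutive matches, so junction-crossing extensions
   of the local alignment are not miscalled as somatic mutations;
2. the D exact-match core is extended along its diagonal across the window
   and the same edge rule applied, so mutations *inside* the retained D are
   still called (a pure exact-match D interval would hide them);
3. anchor codons (FR3 Cys, J Trp) clipped out of a local alignment by
   nearby mutations are re-located by ungapped extension along the
   alignment's main (longest-block) diagonal;
4. the reading frame is taken from that main diagonal — terminal blocks a
   few columns long can sit on a false diagonal when mutations cluster near
   an alignment end.

Productivity: out-of-frame if the J-Trp codon is not ≡ 0 (mod 3) in the V
frame; else stop-codon if any in-frame stop lies between the V match start
and the J end; else productive. Mutations are mismatches in
germline-aligned columns from FR2 to the J end — never in N regions — with
region labels FR2/CDR2/FR3/CDR3/FR4 (the anchor codons count as FR3 and FR4
respectively); frequency is mismatches / aligned columns × 100 and
`mutated_status` is frequency ≥ 2%. Hotspot flags are computed on the
inferred germline sequence (query with called mutations reverted). Cell
patterns are keyed by `(v_call, d_call, j_call, n1, n2)`: colonies that
differ only by SHM collapse to one pattern. Whether two same-junction
variants should ever count separately is a convention choice; the key used
here ignores SHM entirely.

Known measurement bias: per-sequence mutation frequencies run ~10% below
the generator's drawn rates (edge trimming and residual junction losses),
so e.g. a drawn 60% share in the 5–10% bin measures as ~46–56%.

## Repertoire statistics

Percentages are computed in exact rational arithmetic (`fractions` +
`decimal`) and rounded half-up, pooled detection to integer precision and
everything else to one decimal; raw fractions are retained in machine
output. Usage is counted once per distinct cell pattern, not per colony
sequence, so clonal resequencing cannot inflate frequencies. Chi-square
comparisons use Pearson's statistic on the 2×k zero-filled union of labels
(`scipy.stats.chi2_contingency`, no continuity correction); labels with
zero counts in both tables are an error. The paired t-test is the closed
formula `t = mean(d)/(sd(d)/√n)` with n−1 df (cross-checked against
`scipy.stats.ttest_rel` in the tests). The CDR3 length fit is least-squares
`A·exp(−(x−μ)²/2σ²)` on amino-acid length *frequencies*
(`scipy.optimize.curve_fit`, deterministic initialisation: A = max
frequency, μ/σ = weighted moments), with R² = 1 − SS_res/SS_tot. The
genomic concentration statistic is the usage-weighted mean normalised
genomic rank in [0, 1] (0 = fully 3′-proximal): the `ptec-like` preset sits
near 0.40, `bcell-like` near 0.51. At the default 100-cell scale the CDR3
histogram carries heavy colony duplication, so R² values are noisy
(bcell ≈ 0.7–0.95); only the ordering ptec < bcell is a stable property.

## Problem sizes

Defaults everywhere are the study scale: 2 donors × 50 cells, 4–8 colonies
per cell (≈ 550–650 sequences per repertoire). Generator-recovery tests
that need i.i.d. draws switch sharing off and use 1 000–5 000 single-colony
patterns. The hotspot scanner is verified exactly against a brute-force
window oracle on 1 000 random sequences, and chi-square type-I error on
1 000 null replicates.

## Limitations

The reference is synthetic, so absolute assignment accuracies overstate
performance against real, mutually similar germline genes. Detection rate
is always 100% on simulated input (the simulator emits no Ig-negative
cells; negatives enter via `all_cell_ids` when analysing real data).
Light chains, allele-level calls, SHM indels and 10x-style droplet data are
out of scope.
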