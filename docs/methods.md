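# Methods

## The census model

The pipeline treats a lichen metagenome as a sample from a mixed community
and asks three questions per organism: was its genome recovered (MAG tier),
was its SSU rRNA assembled (assembly tier), and was its SSU rRNA present in
the raw reads (read tier). The central quantitative fact the package is
built around is that these tiers have very different detection thresholds
in sequencing depth, so shallow metagenomes systematically understate
organismal presence at the MAG tier while the read tier remains informative.

### Coverage and presence

For an organism contributing a mass fraction *f* of the DNA in a sample
sequenced to *D* total base pairs, with genome size *G*, the per-base depth
is *c = D·f/G*. Under the Lander–Waterman model, the expected breadth of
coverage (fraction of positions hit by ≥ 1 read) is `1 − exp(−c)`. A MAG is
called present when breadth ≥ 0.5, inclusive at the boundary ("at least 50%
covered"), so the MAG-recovery threshold sits at effective depth
c = ln 2 ≈ 0.69. Depth of coverage is computed as
`n_reads × read_length / mag_length`.

Mixtures of closely related strains fragment assemblies and depress
effective coverage. The simulator models this with a single knob: effective
depth `c_eff = c / m^p` for strain multiplicity *m* and penalty exponent
*p* (default 1). No quantitative model of strain effects is established for
these data; the divisor form is deliberately the simplest function that is
monotone in both arguments, and the exponent is configurable.

### rRNA detection

SSU rRNA genes occur in multiple copies (rDNA tandem arrays of tens to
hundreds of copies in fungi and algae; 2–5 operons in the bacteria modeled
here). The number of reads overlapping any rRNA copy is Poisson with mean
`λ = (c·G/L) · copies · (len_rRNA + L − 1)/G`, i.e. the organism's read
count times the per-read hit probability. Read-tier detection requires
≥ `min_rrna_reads` hits (default 1). Assembly-tier detection additionally
requires the rRNA locus itself to be assemblable; since the locus is
multicopy its local coverage is `c_eff × copies`, and the gate is
`c_eff × copies ≥ 1`. Two consequences follow and are enforced as tested
invariants: assembly-tier detection implies read-tier detection, and for
any organism with ≥ 1 rRNA copy the read tier detects at lower depth than
whole-MAG recovery — the ordering read ≥ assembly ≥ MAG that motivates
tiered screening in the first place. (For a hypothetical single-copy locus
the assembly gate is stricter than MAG recovery; no simulated organism is
in that regime.)

### Quality, deduplication, dereplication

Genome quality is summarized as `QS = completeness − 5 × contamination`;
QS ≥ 50 (inclusive) is the minimum for a usable MAG, and "near complete"
means completeness ≥ 95% and contamination ≤ 10% (both inclusive,
configurable — sources differ on strictness at these boundaries, so the
bounds are parameters with these defaults).

Identical re-deposited metagenomes are removed one per duplicate pair;
overlapping pairs are resolved transitively (one survivor per connected
component), preferring an explicitly flagged member and falling back to the
lexicographically smallest id for determinism.

Dereplication into species representatives is greedy and centroid-based,
mirroring score-ranked representative selection: MAGs sorted by descending
QS (ties by id) either join the first established representative at
ANI ≥ 95% and AF ≥ 30% (prokaryotes) / 40% (eukaryotes) or found a new
cluster. AF is symmetrized as the maximum of the two directions; a missing
ANI record means no match. Greedy centroid clustering (rather than single
linkage) keeps representative choice deterministic and reproducible.

### LFS identification and the cascade

The lichen fungal symbiont MAG in each sample is the deepest fungal MAG
present (the dominant symbiont carries most of the DNA), ties broken by id.
Verification compares the MAG's lineage with the lineage expected from the
sample's declared lichen name. Manual tree inspection cannot be automated
faithfully, so "position on the tree" is operationalized as
lineage-consistency with the declared name; conflicts are flagged rather
than silently resolved. A mismatch can be repaired by another present
fungal MAG that does match (reassigned) or by an alternate declared name
such as the sequencing library name (name-corrected); otherwise the sample
is flagged misassigned and excluded from Dataset 2, while its MAGs remain
in overall occurrence counts with the flag propagated downstream.
Dataset 1 is all samples with ≥ 1 present MAG; Dataset 2 is the subset with
a verified (or repaired) LFS call.

### Frequency, prevalence, networks

Frequency of a taxon at a rank is the sum of occurrences of its member
species-level lineages; the lineage count is the number of members with ≥ 1
occurrence; a missing genus assignment falls back to "&lt;Family&gt; gen.
sp." so unnamed genera stay distinct. Prevalence percentages are integers,
rounded half away from zero — a fixed convention chosen for determinism
(no reported percentage sits near a half). Rankings break ties
alphabetically. Detection heatmap outputs are reduced to tables with a
minimum group size filter (default 4 metagenomes). Co-occurrence networks
(built on Dataset 2) connect two lineages with an edge weighted by the
number of metagenomes containing both; zero-weight pairs and never-present
lineages are omitted.

No statistics are computed on relative occurrence frequencies: sequencing
depth is too uneven across samples for such comparisons to be meaningful,
so the package reports counts and leaves inference to the user's design.

### KEGG module grammar and completeness

A module definition is parsed with a recursive-descent parser: top-level
spaces separate sequential blocks (AND), commas separate alternatives (OR,
binding tighter than space), `+` joins obligatory complex subunits (binding
tighter than comma), `-` marks optional components excluded from
requirements, parentheses nest arbitrarily, `--` is the missing-step
placeholder (an always-absent leaf), and `M#####` leaves are nested module
references resolved through an explicit expansion mapping (evaluation
raises rather than guesses when unresolved). Completeness is the fraction
of top-level blocks satisfied; blocks consisting solely of optional
components are excluded from the denominator. "Allowing one missing gene"
is interpreted literally as a single-KO rescue — the module is flagged when
adding one KO would complete it; a per-block variant can be expressed by
comparing `n_present_blocks` to `n_blocks − 1`. Parse → serialize → parse
is a fixed point, and the evaluator is checked exhaustively against an
independent truth-table oracle for definitions with ≤ 4 distinct KOs.

### Vitamin trophy and complementarity

Trophy rules are data, not code: a YAML file lists, per vitamin, synthesis
modules, salvage modules and named KO-conjunction alternatives (e.g. the
thiMDE trio as an alternative salvage route). A genome is a prototroph if
any synthesis route is complete, salvage-only if only a salvage route is,
partial if its best route fraction is strictly between 0 and 1, and
auxotroph otherwise. Because "complete" may or may not tolerate one missing
gene, both a strict status and a relaxed (one-missing-gene) status are
computed and reported side by side. Cobalamin dependence follows the
methionine synthases: metE only → independent, both → facultative, metH
only → dependent, neither → unknown. Biotin rules are scoped to the
ring-assembly modules (M00123/M00950) because pimelate-moiety synthesis is
too enzymatically diverse to screen reliably.

Cross-feeding is assessed only inside highly complete metagenomes — those
with near-complete present MAGs of the LFS, a photobiont (alga or
cyanobacterium; either qualifies in tripartite lichens) and at least one
focal bacterium. For each vitamin the LFS cannot synthesize, co-occurring
prototrophs are listed as providers; organisms with partial pathways are
reported separately and never count as complementing (the stricter
reading).

## The synthetic data generator

The generator emulates the structure the census assumes, with defaults
fixed at what the modeled system looks like:

* 100 samples per bundle; sequencing depth log-uniform over 1e6–1e12 bp
  (six decades, strongly favoring shallow metagenomes on a log scale).
* Each sample: one LFS (genome 28–45 Mb, 45–70% of DNA, rDNA 40–120
  copies); a trebouxiophyte alga (50–70 Mb, 2–10%, 100–400 rDNA copies,
  strain multiplicity 1–2) in ~85% of samples, a cyanobacterium (6–9 Mb)
  as sole photobiont in the rest and as a third partner in a minority; a
  basidiomycete yeast at a planted 1:100 depth ratio to the LFS in half the
  samples; and 4–10 bacteria (3–7 Mb, 2–5 rRNA operons) drawn from a fixed
  16-species pool weighted toward the acetic-acid bacteria, beijerinckias,
  sphingomonads and acidobacteria, sharing 5–25% of the DNA.
* 5 duplicate pairs (byte-identical coverage rows under a new sample id)
  and 4 misidentified samples (declared lichen name drawn from a different
  LFS genus) are planted per 100 samples.
* Vitamin trophy statuses are planted per organism (most LFSs biotin
  auxotrophs; bacteria ~43% biotin prototrophs, mostly thiamine auxotrophs
  or salvage-only; algae partial-to-complete for biotin and thiamine,
  partial for cobalamin with planted metE/metH combinations) by
  constructing KO sets from the synthetic module definitions, whose routes
  use disjoint KO pools so statuses are independently recoverable.
* All randomness flows through one seeded generator; identical
  configuration yields a byte-identical bundle.

What the simulator does **not** model: read-level errors and FASTQ data,
assembly-graph artifacts beyond the strain-multiplicity divisor, binning
contamination, phylogenetic signal, or correlated community composition
across samples. Passing the planted-truth tests therefore demonstrates
that the census machinery is correct and deterministic given its inputs,
not that upstream assembly and binning of real reads behave ideally.

## Numerical and procedural choices

* Integer percentages: round half away from zero.
* All tie-breaks (LFS depth ties, frequency ranking, dereplication order)
  are lexicographic for run-to-run stability; outputs are written with
  sorted primary keys so reruns are byte-identical.
* Degenerate inputs fail loudly: zero genome or MAG length, breadth outside
  [0, 1], unknown taxonomic ranks, empty denominators, unresolved module
  references and malformed definitions all raise with the offending
  position or cell named.
* The study-scale worked example (480 → 437 → 375 → 330) is generated
  programmatically from its stage counts and run through the real cascade
  machinery, not hard-coded.
* Problem sizes used by the test suite and acceptance script — 40–100
  sample bundles, 50-depth × 200-replicate detection sweeps, 20 random
  dereplication tables of ≤ 15 genomes, exhaustive truth tables over ≤ 4
  KOs — were chosen as the smallest sizes at which every property is
  exercised with comfortable statistical margin.

## Known limitations

* The strain-multiplicity penalty is illustrative; real strain mixtures
  interact with assemblers in ways no closed-form model captures.
* LFS verification by declared-name lineage consistency cannot reproduce
  judgment calls made from tree topology; borderline cases surface as
  flags.
* The shipped module definitions and KO ids are synthetic stand-ins; real
  analyses must supply genuine definitions and rules.
* The `+`/`-` edge-case semantics of other module-completeness tools are
  not documented; fidelity here is to the stated percentage-of-blocks
  definition, checked against an independent oracle, not to any tool's
  quirks.
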