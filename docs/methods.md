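# Methods

## The problem and the model

Total-DNA shotgun sequencing of a plant leaf yields a mixture of three
genomes at very different molar amounts: hundreds of plastid copies and
tens of mitochondrial copies per nuclear genome copy. After de novo
assembly, a contig's mean read depth is therefore a proxy for the copy
number of the genome it came from. `orgc` exploits this to pull complete
circular organellar genomes out of the mixed assembly without any organelle
isolation:

1. **Classification.** Two fold-coverage thresholds split contigs into
   chloroplast (depth ≥ `t_high`), mitochondrial (`t_low` < depth <
   `t_high`, an open interval) and nuclear (depth ≤ `t_low`) classes.
   Defaults are `t_high = 60` and `t_low = 20`, chosen for class depth
   means near 87× (cp), 43× (mt) and 9× (nuclear); `depth_histogram` is
   the diagnostic for re-choosing them on other datasets.
2. **Repeat exemption.** A collapsed repeat contig violates the rule: a
   two-copy mitochondrial repeat sits near 86×, i.e. in the chloroplast
   band. Because depth cannot identify such contigs, they are recognized
   *structurally*: a contig with ≥ 2 well-supported joins at **both** ends
   is flagged `UNRESOLVED_REPEAT` and exempted from thresholding; it is
   adopted into whichever class's component absorbs it during extraction.
3. **Seeding and extraction.** Conserved organellar sequences (essential
   mitochondrial genes, plastid references) identify seed contigs by
   shared canonical k-mers (defaults `k = 31`, `min_hits = 5`; matching
   is alignment-free, deterministic and monotone in `min_hits`). The
   class component is everything reachable from the seeds through
   same-class or unresolved-repeat contigs. During mitochondrial
   extraction, a chloroplast-labelled contig whose two ends both join
   mt-class contigs is retained (plastid DNA transferred into the mt
   genome); chloroplast contigs on purely chloroplast paths are not.
4. **Pruning.** Contigs of the wrong class and edges supported by fewer
   than `min_support = 2` spanning reads are deleted (single chimeric
   reads produce support-1 joins). Forks — alternative internal paths
   sharing start and end contigs, enumerated up to `max_branch_len = 5`
   internal contigs — are settled by keeping the branch whose
   length-weighted mean depth is closest to the reference depth of the
   class's non-fork contigs; ties break by total edge support, then
   lexicographically. Every removal is logged, and replaying the log
   reproduces the pruned graph exactly.
5. **Multiplicity.** The single-copy base depth of the pruned class graph
   is its length-weighted median contig depth (robust to the short
   low-depth tail). A contig whose depth is within 0.35 relative
   deviation of m × base for an integer m ≥ 2 is assigned multiplicity m
   (the plastid IR sits "nearly", not exactly, at 2×; the tolerance is
   configurable). One refinement pass re-estimates the base after
   excluding flagged contigs.
6. **Circularization.** The genome is a closed walk traversing each
   contig exactly its multiplicity times and using every edge of the
   pruned graph. The search is exhaustive backtracking over contig ends —
   pruned organellar graphs have tens of nodes, so completeness is cheap —
   and reports all solutions up to rotation and full reversal, capped at
   `max_solutions = 16` with a warning (further ambiguity is resolved with
   mate pairs, never guessed). In a plastid circle the multiplicity-2 run
   is the inverted repeat; the longer single-copy arc is the LSC, the
   shorter the SSC (equal lengths: the first-traversed arc is called LSC,
   logged).
7. **Repeat resolution.** When dispersed repeats leave the walk
   ambiguous, candidate mate-pair links between each repeat's flanking
   contigs decide it. The decision is formalized as a **maximum-weight
   perfect matching**: per repeat, the set of candidate flank pairings of
   maximum total mate-pair count in which every flanking contig appears
   exactly once. Selected rows are the major links, the rest minor links
   (reported, never assembled — multipartite isoforms are out of scope).
   A tie at the maximum, or no perfect matching, is an error demanding a
   manual decision rather than an arbitrary one. Wiring one repeat copy
   between each selected flank pair (depth shared equally, sequence
   duplicated, so length × multiplicity is conserved) yields the master
   circle, which admits a unique closed walk.
8. **Reconstruction.** Oriented contig sequences are concatenated around
   the walk (reverse steps contribute the reverse complement); a join may
   insert one gap/insert base, from the edge's recorded gap or an explicit
   gap policy — Newbler-style contig joins are otherwise zero-gap. GC% is
   computed over A/C/G/T only (N excluded) and rounded to two decimals in
   reports. Contig statistics (count, total bp, N50) count a collapsed
   repeat once, with the per-traversal step count reported separately.

### Circular comparison and the IR isomer pair

Circular assemblies have no natural origin or strand, so sequences are
compared in **canonical form**: the lexicographically smallest string over
all rotations of the sequence and of its reverse complement (least
rotation found with Booth's algorithm, O(n)).

A quadripartite plastid graph admits exactly two closed walks up to
rotation and reversal: the planted configuration and the one with the SSC
arc flipped. This is not a search artifact — the two IR "flip-flop"
isomers interconvert in vivo and co-exist in plastid preparations, and no
contig graph (nor read set, short of spanning an entire IR) can
distinguish them. The pipeline deterministically reports the canonically
smallest walk; correctness of a plastid assembly is therefore judged
against the two-element isomer set of the truth. Isomer enumeration
beyond this pair, and sub-genomic mitochondrial circles, are explicitly
out of scope.

## The synthetic data generator

`simulate` plants the study conditions end to end:

* **cp**: 16 kb quadripartite circle (LSC 8 kb + IR 3 kb + SSC 2 kb +
  IR), single-copy depth 87×;
* **mt**: 40 kb circle with two dispersed 2-copy repeats (600 bp direct,
  450 bp inverted), depth 43×, unique separators of ≥ 800 bp so every
  repeat copy has distinct flanks;
* **nuclear**: 200 kb of linear background in 20 fragments, depth 9×.

Sizes are scaled about tenfold down from real organellar genomes: they
exercise every code path (collapsed IR, dispersed direct and inverted
repeats, background, spurious links) while keeping a 50-seed end-to-end
suite in tens of seconds; depths are the observed class means of the
motivating leaf dataset. Shredding cuts unique regions at exponentially
spaced breakpoints (mean 1 kb, minimum 150 bp, forced breakpoints at
repeat boundaries and at least two contigs between consecutive repeat
copies); identical repeat copies collapse into one contig at
copies × depth, as an overlap assembler collapses them. Per-contig depth
gets Gaussian noise (sd 3×); adjacent contigs are joined with support
2 + Poisson(depth/3); six spurious support-1 cross-genome links are
injected per dataset. Mate-pair counts are Poisson: 50 per true flank
pairing, 5 per wrong pairing (the wrong rows form an alternative
matching, mirroring how spurious pairings appear in real candidate
tables).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing errors and homopolymer artifacts
(contig sequences are exact genome substrings), chimeric contigs,
plastid-to-mitochondrion and organelle-to-nucleus transferred segments
(the extraction rule for embedded cp contigs is unit-tested on
hand-built graphs instead), nuclear repeat families, and coverage biases
along the genome. Real candidate link tables may also pair flanks across
more than two repeat copies; the matching formulation generalizes, but
the generator only plants 2-copy repeats.

The subsampling experiment draws reads (300 bp) from genomes with
probability proportional to depth × length and evaluates per-position
coverage on the planted organellar genomes directly, rather than
re-assembling at every data point; samples at successive data points are
nested, so coverage curves are monotone by construction. Absolute
saturation thresholds depend on the planted copy-number ratios and do not
transfer to any real dataset; the reproducible content is the shape:
0% at 0 Mbp, saturation at 100.00% once sampled mass is a couple of
dozen times the organellar genome mass, and the higher-copy plastid
saturating before the mitochondrion.

## Numerical and interface choices

* Coordinates are 0-based half-open; sequences are uppercase A/C/G/T/N,
  anything else is rejected.
* Edges join contig *ends* (5'/3') and are stored unordered; orientation
  belongs to walks. GFA 1 carries depth as `DP:f:`, read/support counts
  as `RC:i:`, gap bases as private `gp:i:`/`gb:Z:` tags. The
  tab-separated "AllContigGraph" dialect reader is table-driven
  (`Dialect454`) because the vendor layout is not publicly specified;
  unknown record types are skipped with a counted warning.
* The link-table reader carries a blank repeat-id field down from the
  previous row, matching the layout of published tables.
* `graph_stats` N50 is the largest length L such that contigs ≥ L hold at
  least half the total bases (the convention that matches the printed
  worked values).
* Walk search, matching and fork resolution are exhaustive rather than
  heuristic; all are bounded (solution cap, ≤ 16 flanks per repeat,
  branch length cap) and deterministic, with logged tie-breaks.

## Known limitations

* Depth thresholds are global constants per run; strong within-genome
  coverage bias would need locally adaptive classification.
* Repeat flagging by end-degree assumes spurious joins are weak
  (support < 2); a well-supported chimeric join could mimic a repeat.
* `apply_major_links` assumes each flanking contig joins the repeat at
  one end; a flank touching both repeat ends (possible in very small
  circles) is wired through whichever end is recorded first.
* Multiplicities above what the candidate rows support, and repeats whose
  copies differ (diverged repeats), are out of scope: copies must be
  collapsed and byte-identical for the expansion bookkeeping to hold.
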