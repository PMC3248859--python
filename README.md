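# orgc — organellar genome assembly from whole-genome shotgun contig graphs

Plant cells carry hundreds of copies of the chloroplast genome and tens of
copies of the mitochondrial genome per nuclear copy, so in total-DNA
shotgun sequencing the per-contig read depth of a de novo assembly tracks
which genome a contig came from. `orgc` turns that observation into a
complete assembly procedure: it recovers finished, circular chloroplast
and mitochondrial genomes directly from a mixed whole-genome assembly's
contig graph — no organelle isolation, no reference-guided scaffolding.

It is aimed at anyone assembling plant organellar genomes from shotgun
data (or studying the procedure itself): the input is an assembly contig
graph with per-contig mean read depth (GFA 1, or the tab-separated
"AllContigGraph" dialect emitted alongside 454/Newbler assemblies),
contig sequences in FASTA, and — when dispersed repeats make the circle
ambiguous — a table of candidate mate-pair links between repeat flanks.

## The method in brief

With class depth means like 87× (cp), 43× (mt) and 9× (nuclear), two
thresholds classify contigs: **CP** at depth ≥ 60, **MT** on the open
interval 20 < depth < 60, **NUCLEAR** at depth ≤ 20. Collapsed repeat
contigs (a two-copy mt repeat sits at ~86×) are exempted via a structural
flag and adopted into a class by graph context. Conserved-gene k-mer
seeding extracts each class component; false links (wrong class, or
support < 2) and depth-inconsistent fork branches are pruned; repeat
multiplicity m is read off the depth ratio to the class's length-weighted
median depth; and the genome is the closed walk traversing each contig m
times, found by exhaustive backtracking. A plastid walk's multiplicity-2
run is the inverted repeat, and the longer/shorter single-copy arcs are
the LSC/SSC.

When dispersed repeats leave several walks, candidate mate-pair links
decide the order: per repeat the selected **major links** are the set of
flank pairings of maximum total link count covering each flanking contig
exactly once — a maximum-weight perfect matching; the remaining **minor
links** are reported but not assembled. Expanding each repeat copy along
its major links yields the master circle, and concatenating oriented
contig sequences (plus occasional single gap/insert bases at joins)
yields the circular genome, compared in canonical rotation/strand form.

A first-class synthetic module plants the whole scenario — quadripartite
cp genome, mt genome with dispersed direct/inverted repeats, nuclear
background, depth noise, spurious cross-genome links, mate-pair counts —
and keeps the ground truth for validation, including a desk-scale version
of the "how much sequencing is enough" subsampling experiment. See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Assemble both organellar genomes from a planted synthetic dataset:

```python
from orgc.simulate import simulate_dataset
from orgc.pipeline import run_pipeline
from orgc.build import canonical_form

ds = simulate_dataset(seed=1)
result = run_pipeline(ds.graph, cp_reference=ds.cp_reference,
                      mt_reference=ds.mt_reference, link_table=ds.link_table)
for name, asm in result.assemblies.items():
    r = asm.report
    print(f"{name}: {r.genome_length:,} bp  GC {r.gc_percent}%  "
          f"{r.n_contigs} contigs (N50 {r.n50:,} bp)")
    if asm.annotation:
        a = asm.annotation
        print(f"    LSC {a.lsc_len:,} / IR {a.ir_len:,} / SSC {a.ssc_len:,}")
    print("    matches planted genome:",
          canonical_form(asm.sequence) in ds.truth.acceptable_canonical_forms(name))
```

prints

```
cp: 16,000 bp  GC 37.59%  10 contigs (N50 2,336 bp)
    LSC 8,000 / IR 3,000 / SSC 2,000
    matches planted genome: True
mt: 40,000 bp  GC 42.92%  42 contigs (N50 2,408 bp)
    matches planted genome: True
```

The 16,000 bp plastid is reassembled from 10 contigs with its
quadripartite structure annotated (the IR contig counted once in the
contig stats, traversed twice in the circle), and the 40,000 bp
mitochondrial master circle is recovered after its two dispersed repeats
are placed by their major mate-pair links; both circular sequences equal
the planted genomes in canonical form.

The same stages are available as a CLI for on-disk data:

```sh
orgc simulate --seed 1 --out-dir sim/
orgc classify --graph sim/graph.gfa --out labels.tsv
orgc prune    --graph sim/graph.gfa --labels labels.tsv --class-label cp --out cp.gfa
orgc circle   --graph cp.gfa --out circle.json
orgc build    --graph cp.gfa --circle circle.json --out cp_genome.fasta
orgc repeats  --graph sim/graph.gfa --links sim/links.tsv --out master.gfa
```

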