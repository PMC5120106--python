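# albomito

Mitogenome haplogroup analysis for the Asian tiger mosquito
(*Aedes albopictus*).

The tiger mosquito, a competent vector of dengue, chikungunya, Zika and
West Nile viruses, has spread from East Asia to every continent except
Antarctica in four decades. Its mitochondrial DNA falls into named
haplogroups (A1, A2, A3 and their nested sub-branches, A1 > A1a > A1a1 …),
and the geographic distribution of those haplogroups traces the sources
and routes of the invasion. Most published population data, however, are
short partial sequences of the COI and ND5 genes — so assigning them to
haplogroups requires diagnostic marker panels derived from a
whole-coding-region phylogeny.

`albomito` provides that workflow as a tested library and CLI, for
molecular ecologists and students working with mosquito (or other insect)
mtDNA:

* **Mutation notation & I/O** — the positional notation of mitochondrial
  phylogenetics (`1578C` = transversion to C at np 1578, `7210@` = back
  mutation, `100d`, `3808.1`, `4890h`), FASTA/TSV readers, and explicit
  coordinate frames with alignment-derived conversion.
* **Haplogroup tree & parsimony** — a rooted tree with per-branch mutation
  lists (shipped fixture: the 27-mitogenome *A. albopictus* phylogeny),
  exact small parsimony on multifurcating trees (Hartigan/Fitch, missing
  data as universal state sets), and exhaustive most-parsimonious search
  for ≤9 taxa. Total tree length is the unrooted parsimony score
  `L = Σ_sites min #changes`.
* **Diagnostic marker panels** — per-haplogroup presence/absence motifs
  restricted to assayable COI/ND5 windows, with recurrent mutations
  excluded (e.g. A3 = COI 1503, 1578C, 1676C, 1704, 1964; A1a1a1 =
  *absence* of 1536 and 2165).
* **Fragment classification** — deepest-satisfiable-haplogroup calls for
  partial sequences, with missing data handled conservatively and an
  "others" bucket for anything unclassifiable.
* **Population statistics** — haplogroup frequency tables with regional
  roll-ups, and COI barcode divergence as the p-distance
  `p = #differing / #compared sites` over the standard 658-bp window.
* **Control-region annotation** — detection of the two tandem-repeat
  classes (type I ~190 bp, type II ~42 bp units) and the conserved
  poly-T / poly-T+GC / poly-A blocks, reporting repeat copy numbers.
* **Synthetic data** — seeded generators for mitogenomes evolved along the
  tree, partial fragments, population samples at specified haplogroup
  frequencies, and control regions with chosen repeat copy numbers, so the
  whole pipeline is testable without downloads.

## Worked example

```python
import albomito as am

tree = am.HaplogroupTree.load_fixture()          # 27-leaf haplogroup tree
panel = am.derive_marker_panel(tree)             # diagnostic markers
genomes = am.simulate_along_tree(tree, seed=1)   # synthetic mitogenomes
reference = genomes.node_seqs[tree.reference_leaf]

print(panel.to_dataframe().query("haplogroup == 'A3'"))

table1 = am.load_fixture_table("table1")
print("A1:", am.haplogroup_members(table1["haplogroup"], "A1"),
      "A2:", am.haplogroup_members(table1["haplogroup"], "A2"),
      "A3:", am.haplogroup_members(table1["haplogroup"], "A3"))

d = am.max_intraspecific_divergence(genomes.leaves)
print(f"max barcode divergence: {d:.3f}")

frags = am.sample_fragments({"sample1": genomes.node_seqs["A1a1a1a1"]},
                            window="COI")
calls = am.classify_batch(frags, panel, reference)
print(calls[["id", "call", "confidence", "supporting"]].to_string(index=False))

seq, truth = am.simulate_control_region(7, 5, per_copy_noise=0.02, seed=1)
print("repeat copies:", am.annotate_control_region(seq).copies)
```

prints

```
  haplogroup marker      mode window  start   end
1         A3   1503  presence    COI   1450  2600
2         A3  1578C  presence    COI   1450  2600
3         A3  1676C  presence    COI   1450  2600
4         A3   1704  presence    COI   1450  2600
5         A3   1964  presence    COI   1450  2600
A1: 21 A2: 5 A3: 1
max barcode divergence: 0.012
     id     call confidence            supporting
sample1 A1a1a1a1       full 1536@,2165@,2015,1823
repeat copies: (7, 5)
```

Reading the output: the A3 panel is the five COI transitions/transversions
that distinguish the Taiwanese A3 mitogenome; of the 27 study samples 21
nest under A1, 5 under A2 and 1 under A3; the most divergent pair of
simulated mitogenomes differs at 8 of 658 barcode sites (p = 0.012); a COI
fragment from an A1a1a1a1 genome is called to that sub-branch with full
confidence, supported by the observed absences at 1536/2165 plus the
derived 2015 and 1823 states; and a control region simulated with 7 type I
and 5 type II repeat copies is annotated back to exactly (7, 5).

The same operations are available from the shell:

```bash
albomito markers                     # marker panel as TSV
albomito simulate --seed 1 --out sim.fasta
albomito classify sim.fasta --seed 1
albomito map-mutations sim.fasta     # parsimony branch mapping
albomito simulate --seed 2 --control-region 7 5 --out cr.fasta
albomito repeats cr.fasta            # BED-like repeat annotation
albomito freq-table calls.tsv
```

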