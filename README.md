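# mitogeo

Mitogenome phylogeography for population studies of human mitochondrial
DNA: haplogroup-resolved population structure, detection of
region-specific founder clades, and strict-clock coalescence dating —
with a coalescent simulator that provides ground truth for every stage.

## Who this is for

Population geneticists analysing panels of complete mitogenomes (or
HVS-I control-region haplotypes) sampled from a focal region together
with a labelled comparative panel. The package answers three questions:

1. **Structure** — how diverse is each sampled locality, and is variation
   among localities significant? (haplotype/nucleotide diversity, AMOVA,
   pairwise Φst with permutation tests, haplogroup-frequency PCA)
2. **Founder clades** — which lineages inside each haplogroup are
   specific to the focal region? A focal-specific clade is a set of ≥ 2
   focal sequences in one haplogroup sharing at least one non-recurrent
   mutation absent from every other sequence considered.
3. **Timing** — how old is each clade, and when (at the latest) did its
   lineage arrive? Both dates come from the rho statistic under a strict
   molecular clock.

## The statistics at the core

**Carrier-set clade detection.** For every unmasked mutation v let C(v)
be its carrier set. Keep v when C(v) is non-empty, contains only
focal-region samples, and |C(v)| ≥ 2; group kept mutations by identical
carrier set and emit the maximal sets as clades. This makes the
"shared private mutation" clade definition mechanical, and is verified
in tests against exhaustive subset enumeration.

**Rho dating.** With clade root haplotype inferred as the strict
intersection of member profiles, ρ is the mean number of derived
mutations per member, and

    TMRCA = ρ / (µ · L),      σ_ρ = √(ρ/n)

with µ = 2.355 × 10⁻⁸ substitutions/site/year (a purifying-selection-
corrected rate) and L = 16,569. Internal mode dates the clade's own
founder; external mode re-infers the root over members plus the closest
non-focal sequence, an upper bound on the lineage's arrival time.
Uncertainty comes from an expanded-percentile bootstrap over members.

**AMOVA.** One-level analysis of molecular variance on pairwise
mutation-count distances, variance components for unequal group sizes,
Φst = σ²_a/(σ²_a + σ²_w), and a whole-label permutation test with the
(b+1)/(m+1) p-value.

## Worked example

Simulate a planted clade with known ages (internal TMRCA 2,000 y, split
from its European sister lineage 6,000 y), detect it, and date it:

```python
import mitogeo as mg

ref = mg.ReferenceGenome.synthetic(seed=0)
spec = mg.SimCladeSpec(
    label="demo", n_focal_by_locality={"Batna": 4, "Khenchela": 2},
    n_external=3, external_region="Europe",
    true_internal_tmrca_years=2000, true_split_years=6000,
    tree_shape="coalescent", n_anchor_mutations=2)
records, metadata, truth = mg.simulate_clade(spec, seed=11, reference=ref)
profiles = mg.profiles_from_records(records, ref)
meta = {m.sample_id: m for m in metadata}

clades = mg.find_focal_clades(profiles, meta, "NorthAfrica", mg.default_mask())
clade = mg.attach_closest_externals(clades, profiles, meta, "NorthAfrica")[0]
print("members:", sorted(clade.member_ids))
print("defining mutations:", sorted(clade.defining_mutations))
print("closest external:", clade.closest_external)

by_id = {p.sample_id: p for p in profiles}
internal, external = mg.date_clade(clade, by_id, seed=5)
print(f"internal TMRCA: {internal.tmrca_years:.0f} y "
      f"(95% CI {internal.ci95_years[0]:.0f}-{internal.ci95_years[1]:.0f})")
print(f"external date:  {external.tmrca_years:.0f} y "
      f"(95% CI {external.ci95_years[0]:.0f}-{external.ci95_years[1]:.0f})")
```

Output:

```
members: ['demo_F1_Batna', 'demo_F2_Batna', 'demo_F3_Batna', 'demo_F4_Batna', 'demo_F5_Khenchela', 'demo_F6_Khenchela']
defining mutations: ['C1561T', 'C7417T']
closest external: ('demo_X2', 'Europe', 3)
internal TMRCA: 854 y (95% CI 0-3417)
external date:  5492 y (95% CI 4027-7322)
```

All six planted focal samples are recovered exactly, defined by the two
anchor mutations placed on the clade's stem. The single-replicate
internal estimate (854 y) is noisy, as the wide CI says it should be —
with only ρ ≈ 0.3 expected mutations per member, one draw carries little
information; averaged over replicates the estimator is unbiased (see the
reproduction script below). The external date (5,492 y, CI including
6,000) brackets the true split.

The same analysis runs from the shell over FASTA + TSV inputs:

```bash
mitogeo simulate --config sim.yaml --seed 6 --outdir panel/
mitogeo run --config run.yaml --seed 4 --outdir results/
```

`run` executes qc → classify → diversity/structure → clades → dating and
writes one TSV per stage plus a manifest with input checksums; re-running
the same config reproduces byte-identical numbers.

## Data conventions

* Coordinates are 1-based, intervals closed, mutations in phylotree
  style (`A16183C`, `309.1C`, `16189d`) relative to the rCRS coordinate
  frame. Input mitogenomes must be pre-aligned to reference coordinates;
  use the variant-table input when insertions matter (FASTA cannot carry
  them).
* `N` and IUPAC ambiguity codes are missing data, excluded pairwise from
  all counts.
* The haplogroup tree is data (TSV: node, parent, space-separated
  defining mutations, `!` marking back-mutations). A small synthetic toy
  tree ships for tests; supply a phylotree-derived tree for real data.
* A default recurrent-site mask (16182, 16183, 16519, the 309/315/573
  and 16193 insertion hotspots) ships as data and is user-overridable.
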