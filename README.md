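# crustpipe

Analysis pipeline for biocrust (biological soil crust) microbial ecology.
Moss-biocrust studies fractionate the crust into sublayer soils (BS, with
sieve-size classes BS_0.2, BS_0.5), sifted biocrust-layer soils (BSS,
BSS_0.2) and moss rhizoid soil (BRS), then ask how microbial resource
limitation, community diversity and co-occurrence structure differ across
fractions. `crustpipe` implements the full computational chain of such a
study on top of plain-text inputs, plus a synthetic-data generator with
known ground truth so every stage is testable without a sequencing run.

## What it computes

**Extracellular enzyme activities (EEA).** Fluorometric microplate assays
with methylumbelliferone-linked substrates, eight replicate wells per role
(assay, sample control, quench control, reference standard, negative
control, blank). With role means *f*, *f_b*, *f_q*, *f_r*, *f_s*:

    q  = (f_q − f_b) / f_r              quench coefficient
    e  = f_r / (c·V2)                   emission coefficient (per nmol)
    F  = (f − f_b)/q − f_s              corrected fluorescence
    Ab = F·V / (e·V1·t·m)               activity, nmol g⁻¹ dry soil h⁻¹

with V = 125 mL suspension, V1 = 0.2 mL per well, t = 4 h incubation,
m = dry mass of the 2 g wet-soil aliquot, c = 10 μM and V2 = 50 μL of
reference standard.

**Ecoenzymatic stoichiometry and the vector model.** Four enzymes index
C, N and P acquisition: β-1,4-glucosidase (BG), leucine aminopeptidase +
β-1,4-N-acetylglucosaminidase (LAP + NAG) and acid phosphatase (AP).
Stoichiometric ratios are ln(BG):ln(LAP+NAG), ln(BG):ln(AP) and
ln(LAP+NAG):ln(AP). Each sample maps to

    x = BG/(BG+AP),  y = BG/(BG+LAP+NAG)
    length = √(x² + y²)   (relative C limitation)
    angle  = degrees(arctan(y/x))

where angle < 45° indicates relative N limitation, > 45° P limitation.

**Diversity.** ASV tables are rarefied to the minimum sample depth, then
Chao1 and Shannon indices, Bray–Curtis dissimilarity, principal
coordinates analysis and a PERMANOVA permutation test for group
separation.

**Group statistics.** One-way ANOVA with Tukey HSD and compact letter
displays for chemistry/EEA/alpha diversity; Kruskal–Wallis with pairwise
rank-sum tests for taxon abundances; Benjamini–Hochberg FDR throughout.

**Co-occurrence networks.** Features below 0.1 % mean relative abundance
are combined into an OTHER bin; Spearman correlations of relative
abundances are BH-FDR corrected over all candidate pairs; edges require
|ρ| ≥ 0.6 and adjusted p < 0.05 (optional presence/absence co-occurrence
filter). The signed graph is summarized by edge and node counts, the
percentage of positive links, average clustering coefficient, density
2E/(N(N−1)) and average degree 2E/N.

## Worked example

Simulate one rhizoid-soil sample's four enzyme plates and run them
through the activity and vector chain:

```python
from crustpipe.simulate import SimulationDesign, simulate_plate
from crustpipe.fluorometry import process_assay
from crustpipe.stoichiometry import ActivityProfile, limitation_vector

design = SimulationDesign(seed=42)
rng = design.rng()
acts = {}
for enz in ("BG", "LAP", "NAG", "AP"):
    readings, truth = simulate_plate(design, "BRS", enz, rng=rng)
    res = process_assay(readings)
    acts[enz] = res.Ab
    print(f"{enz}: q={res.q:.3f} F={res.F:.1f} Ab={res.Ab:.2f} (truth {truth['Ab']:.1f})")

v = limitation_vector(ActivityProfile(sample_id="BRS_r1", **acts))
print(f"length={v.length:.4f} angle={v.angle:.3f} class={v.limitation_class}")
```

prints

```
BG: q=0.788 F=3450.2 Ab=147.27 (truth 150.0)
LAP: q=0.792 F=3002.9 Ab=129.96 (truth 130.0)
NAG: q=0.786 F=2558.3 Ab=109.53 (truth 110.0)
AP: q=0.822 F=882.1 Ab=39.07 (truth 40.0)
length=0.8773 angle=25.724 class=N-limited
```

The recovered activities sit within the 5 % well noise of their true
values; the vector angle of 25.7° (< 45°) classifies the sample as
N-limited, and the long vector (0.88) reflects strong relative C
limitation — the expected signature of rhizoid soil, which has the
highest BG and lowest AP of the six fractions.

The same chain is available from the shell:

```sh
crustpipe simulate --seed 42 --out-dir synthetic
crustpipe run-all --plates synthetic/plates.csv \
    --features synthetic/feature_table.tsv \
    --metadata synthetic/metadata.tsv \
    --chemistry synthetic/chemistry.tsv --out-dir results
```

which writes activity, stoichiometry, diversity, PERMANOVA, group-test
and per-group network tables (edge lists, GraphML, property table) plus a
log of all seeds and thresholds.

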