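# syntronet

Inference and validation statistics for syntrophic partnerships between
anaerobic methanotrophic archaea (ANME) and seep-associated sulfate-reducing
bacteria (SRB), built as a reusable, tested Python library with a thin CLI.

Consortia of ANME and SRB perform the anaerobic oxidation of methane in marine
sediments, and which SRB clade partners which ANME subtype is a central
ecological question. `syntronet` implements the complete statistical chain by
which such partnerships are discovered and validated from sequence surveys and
single-consortium measurements:

1. **OTU pipeline** — classic OTU-table / BIOM-style JSON I/O, contaminant
   blacklisting, the rare-OTU rule (drop OTUs never reaching 10 reads in any
   library), and ordered-rule clade labeling of SILVA-style lineages
   (including the alias mapping of *Desulfococcus*-labeled OTUs into the
   SEEP-SRB1g clade).
2. **SparCC correlation inference** — compositional correlations from
   log-ratio variances t_ij = Var[log(f_i/f_j)] via the sparsity
   approximation ρ_ij = (ω_i² + ω_j² − t_ij)/(2ω_iω_j), with Dirichlet
   resampling, pair-exclusion iterations, and permutation **pseudo-p values**:
   p = (1 + #{ρ_null ≥ ρ_obs})/(B + 1) over B = 100 per-OTU permutations, so
   p < 0.01 means the observed coefficient beat every null dataset.
3. **Partnership network** — percentile edge filter, cohesive-block
   decomposition (Moody–White structural cohesion: nested node sets of
   strictly increasing vertex connectivity), and the chord-diagram quantity:
   counts of ANME–SRB edges inside nested blocks per (ANME subtype, SRB clade).
4. **Sort specificity** — χ² independence test (Σ(O−E)²/E, df = (r−1)(c−1),
   no continuity correction) and conditional partner fractions for
   flow-sorted single consortia.
5. **Isotope imaging** — per-cell ¹⁵N atom percent from ion-count rasters
   (ratio-of-sums over ROI pixels), interior/exterior classification by
   distance to the consortium boundary, and Pearson / Manders colocalization
   for two-channel fluorescence images.
6. **Reaction-diffusion model** — steady-state ammonium around a consortium,
   D∇²C = kC, with depletion length λ = √(D/k), closed-form and verified
   finite-difference profiles, and the depth at which the concentration falls
   below the diazotrophy-induction threshold C*.
7. **Synthetic data** — generators with known ground truth for every input
   (compositional OTU tables with planted partner pairs, sorted-consortium
   tables, Poisson nanoSIMS scenes, controlled-overlap two-channel images),
   so the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
import pandas as pd
import syntronet as sn
from syntronet import network as net

# A 300-sample x 60-OTU survey with a planted ANME-2b--SEEP-SRB1g module
# (five partner pairs at basis correlation 0.9).
table = sn.gen_otu_table(sn.partnership_demo_config(seed=0))

rho = sn.sparcc_correlations(table, seed=1)          # SparCC point estimates
corr = sn.bootstrap_pseudo_p(table, rho, B=100, seed=2)
sig = sn.significant_pairs(corr, alpha=0.01)          # pseudo-p < 0.01 edges

meta = pd.DataFrame({"clade": list(table.clade)}, index=list(table.otu_ids))
G = net.build_network(net.percentile_filter(sig, q=0.0), meta)
tree = net.cohesive_blocks(G)
pm = net.partnership_matrix(tree, G)

print(round(float(rho[0, 1]), 3))   # estimate for one planted 0.9 pair
print(len(sig))                     # significant edges
print(pm.argmax_cell(), pm.total)   # dominant partnership cell
```

Output:

```
0.823
33
('ANME-2b', 'SEEP-SRB1g') 5
```

The planted correlation of 0.9 is recovered at 0.82 (compositional estimates
are slightly attenuated), 33 OTU pairs beat all 100 permutation nulls, and the
partnership matrix attributes exactly the five planted ANME-2b–SEEP-SRB1g
edges to nested cohesive blocks, making that cell the arg-max.

On the specificity side:

```python
ct = sn.ContingencyTable(
    counts=np.array([[8, 3], [1, 18]]),
    row_labels=("ANME-2b", "ANME-other"),
    col_labels=("SEEP-SRB1g", "SRB-other"),
)
frac = sn.partner_fractions(ct, "srb", "SEEP-SRB1g")
print(frac[frac.partner == "ANME-2b"].percent.round(1).item())  # 88.9
```

i.e. 8 of 9 SEEP-SRB1g sorts carry ANME-2b as the archaeal partner.

## Command line

```bash
syntronet simulate otu --seed 0 --out table.tsv
syntronet filter table.tsv --min-reads 10 --out filtered.tsv
syntronet sparcc filtered.tsv --bootstraps 100 --alpha 0.01 --seed 1 --out corr.csv
syntronet network corr.csv --table filtered.tsv --percentile 99 --out netdir/
syntronet chi2 sorts.csv --focal ANME-2b
syntronet rd --k 19.8 --c0 30 --cstar 25 --geometry planar_semi_infinite
```

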