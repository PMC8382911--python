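# haloasr

Ancestral-protein resurrection workflow for halophilic enzyme families, built
around the evolutionary history of halobacterial malate dehydrogenase
(MalDH). Halobacteria survive molar intracellular KCl by the "salt-in"
strategy, which leaves a proteome-wide signature: strongly acidic protein
surfaces (an excess of D+E over K+R residues) and enzymes whose folded state
depends on salt concentration. `haloasr` implements, end to end and on
synthetic data with known truth, the computational arc that resurrection
studies of such enzymes follow:

1. **Simulate** a dated (ultrametric) species tree, a gene history with
   duplications, horizontal transfers and losses (DTL) along it, and a
   protein alignment evolved under an empirical amino-acid model (LG) with
   discrete-gamma rate variation, indels, and an acidic "halophilic"
   stationary composition — plus sigmoidal folded-fraction vs. salt curves.
2. **Filter** alignment columns (drop columns with >20% gaps; strip
   fast-evolving sites in 10% steps ranked by posterior mean rate).
3. **Infer** a gene tree (pairwise maximum-likelihood distances + neighbor
   joining + midpoint rooting) and clade support (conditional clade
   probabilities from a tree sample).
4. **Reconcile** the gene tree against the time-sliced dated species tree by
   a minimum-cost DTL dynamic program (transfers only between
   contemporaneous branches).
5. **Reconstruct** marginal ancestral sequences: per node and site the
   posterior probability (PP) of each amino acid given the tip data,
   P(x_v = a | data) ∝ inside_v(a) · outside_v(a), mixed over gamma
   categories; the maximum-PP state is reported, and ancestral gaps inferred
   by Fitch parsimony on the presence/absence character are substituted in.
6. **Measure** halophily proxies: the DE/KR ratio (D+E)/(K+R), the stability
   midpoint M^f½ from a two-parameter logistic fit
   f(c) = 1/(1 + exp(−(c − m)/w)), and trajectory tables of metric values
   against replacement counts accumulated since the root ancestor.

Every stage is a pure function of its inputs and a seed, so the whole
pipeline is byte-reproducible and every inference step can be scored against
the simulation truth.

## Worked example

```bash
haloasr run-all --seed 4 --outdir demo_out
```

prints (abridged):

```
{
 "mean_ancestor_identity": 0.9635714285714286,
 "mean_well_identified": 0.9021428571428572,
 "mean_de_kr": 3.142895299145299,
 "tree_rf_distance": 0,
 "event_precision": 1.0,
 "event_recall": 1.0
}
```

meaning: across all internal nodes of the simulated family, the composed
ancestral sequences match the simulated truth at ~96% of sites; ~90% of
ancestral sites are "well identified" (MAP PP > 0.9); the extant sequences
carry the halophilic DE/KR > 2 signature; the NJ tree recovered the true
topology exactly; and the parsimony reconciliation recovered the simulated
duplication/transfer/loss events with full precision and recall (losses on
fully extinct lineages are unrecoverable in general and lower the recall on
richer histories). All stage artifacts (trees, alignments, profiles, event
tables) are written under `demo_out/`.

The same steps are available as a narrated analysis sequence:

```bash
python analysis/01_simulate_family.py
python analysis/02_filter_columns.py
python analysis/03_infer_and_reconcile.py
python analysis/04_ancestral_reconstruction.py
python analysis/05_halophily_trajectories.py
```

which writes its tables under `results/analysis/` (ancestor recovery per
node, reconciliation events vs. truth, and the M^f½/DE-KR trajectory along a
root-to-leaf lineage).

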