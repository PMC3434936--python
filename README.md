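# paeml — maximum-likelihood taxon-area analysis

`paeml` infers the historical relationships of geographic areas from
species presence/absence data, and reconstructs the history of each
individual species on the resulting area tree. It is built for regional
floristic (or faunistic) data sets of the kind a botanist assembles over
years of survey work: a binary matrix whose rows are areas, whose columns
are species, and whose cell (i, j) is 1 when species j occurs in area i.

The analysis treats areas as the "taxa" of a phylogenetic inference and
species as binary characters. Where classical parsimony analysis of
endemicity stops at a most-parsimonious area cladogram, `paeml` fits the
two-state symmetric Mk model by maximum likelihood — gains (0 → 1) and
losses (1 → 0) equally probable, stationary frequencies (½, ½), so over a
branch of length *t*

    P(same) = ½(1 + e^(−2t)),   P(differ) = ½(1 − e^(−2t)),

with discrete-gamma rate heterogeneity across species (Γ(α, α), 4
classes) and an optional invariant-character class. Because absences are
data under this model, all-zero columns — hypothetical extinct species —
are informative, which supports two things parsimony cannot do: rooting
with an all-zero artificial outgroup that behaves like an empty ancestral
area, and "extinct taxa" scenarios that probe how robust the area tree is
to an unobserved palaeoflora. Individual species histories are then drawn
by stochastic character mapping: exact endpoint-conditioned sampling of
the continuous-time chain along every branch, summarised as per-node
presence probabilities and per-branch expected gains (dispersal) and
losses (local extinction).

Alongside the core there are Fitch parsimony scoring (tree length,
ensemble CI/RI), heuristic tree search (random-addition starts, SPR/NNI
hill climbing) with nonparametric bootstrap over species columns, Lundberg
rooting on the species-poorest area, UPGMA similarity clustering, a
synthetic-data generator with a 13-area fixture emulating a Lower Volga
Valley-type survey (1018 species, 23 narrow endemics), and CSV/NEXUS/
Newick/SIMMAP I/O. See `docs/methods.md` for the model details and
numerical choices.

## Worked example

```python
from paeml import (SearchConfig, add_allzero_outgroup, fitch_length,
                   lvv_fixture, run_scenarios, search)

matrix = lvv_fixture(n_species=300, n_endemics=8, seed=1)   # 13 areas
rooted = add_allzero_outgroup(matrix)

mp = search(rooted, SearchConfig(objective="parsimony", n_starts=10, seed=1))
score = fitch_length(mp.trees[0], rooted)
print(f"MP: length={score.length}, CI={score.ci:.3f}, RI={score.ri:.3f}")

ml = search(rooted, SearchConfig(objective="likelihood", gamma=True,
                                 n_starts=2, seed=1))
print(f"ML: -lnL={-ml.score:.3f}, alpha={ml.fit.gamma_shape:.3f}")

for r in run_scenarios(matrix, SearchConfig(objective="likelihood",
                                            gamma=True, n_starts=1, seed=2)):
    print(f"extinct taxa: {r.n_extinct:4d}  -lnL: {-r.log_likelihood:9.3f}  "
          f"RF to baseline: {r.rf_to_baseline}")
```

prints

```
MP: length=613, CI=0.489, RI=0.472
ML: -lnL=1855.235, alpha=1.219
extinct taxa:    0  -lnL:  1873.536  RF to baseline: 0
extinct taxa:  150  -lnL:  2180.775  RF to baseline: 4
extinct taxa:  300  -lnL:  2414.472  RF to baseline: 4
extinct taxa:  450  -lnL:  2615.149  RF to baseline: 10
extinct taxa:  600  -lnL:  2785.927  RF to baseline: 4
```

The parsimony tree costs 613 presence/absence changes; CI = 0.489 means
roughly half the change budget is homoplasy (independent gains or losses
of the same species in different areas), which is normal for occurrence
data. The ML fit's α ≈ 1.2 says species turn over at moderately
heterogeneous rates. Appending all-zero "extinct" columns makes −lnL grow
(each column contributes a negative log term) while the parsimony length
would not move at all; the Robinson–Foulds distances show which
augmentation levels leave the area relationships intact (0 = identical
topology) and which perturb them. The scenario lnL values are exactly the
quantity to compare across augmentation levels of the same matrix.

Per-species histories (`map_character`), the MP-versus-stochastic-map
contrast (`mp_ancestral_states`), UPGMA clustering and the rest are shown
in `examples/` — one short script per capability, each printing the
numbers it computes and a line on what they mean. A thin command-line
interface wraps the same functions (`paeml --help`; subcommands
`simulate fixture search mp-score ml bootstrap upgma scenarios map
workflow`).

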