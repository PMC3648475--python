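# figsel

Ecogeographic germplasm subsetting and trait-based validation for drought
adaptation screening in faba bean (*Vicia faba* L.) genetic resources.

Genebanks hold far more accessions than any physiology lab can evaluate.
The Focused Identification of Germplasm Strategy (FIGS) selects candidate
accessions using the climate of their collection sites, on the premise
that landraces carry the signature of the selection pressures — here,
seasonal moisture availability — of the environments they evolved in.
`figsel` implements the full workflow for the wet/dry contrast:

1. **Set construction** (`figsel.figs_selection`) — from a passport table
   joined to eight site agro-climatic variables (`precyr`, `ariyr`,
   `tminyr`, `tmaxyr`, `bio4`, `bio15`, `bio16`, `bio19`): a **dry set**
   (rain band 300–550 mm/yr, one accession per site, average-linkage
   clustering on squared Euclidean distances cut at 20 groups, pruning of
   clusters with mean aridity index above 0.6 or below 0.1, bio15 > 50,
   round-robin pick by ascending precipitation up to 201 accessions) and a
   **wet set** (> 800 mm/yr, the 201 sites with the highest aridity index).
2. **Trait derivation** (`figsel.trait_derivation`) — replicate-level leaf
   measurements to 16 accession-level analysis variables, including
   SA = SL·SW, SAAL = SA·SD, RWC% = (FW−DW)/(TW−DW)·100, intrinsic
   WUE = A_net/g_s, leaflet/canopy temperature depression, and the
   *minor*/*equina*/*major* seed-size class.
3. **Set comparison** (`figsel.set_comparison_stats`) — pooled two-sample
   t-tests per trait, from raw values or from printed summary statistics:
   t = (x̄_dry − x̄_wet)/√(s²_wet/n + s²_dry/n), df = 2n − 2.
4. **Classification harness** (`figsel.classification_eval`) — standardize
   the combined data, split 2/3–1/3 at random, train CART, random-forest
   and RBF-SVM classifiers, score the held-out third, repeat 10×; metrics
   are ROC-AUC (midrank/Mann–Whitney form), sensitivity, specificity,
   omission rate, correct classification rate and Cohen's kappa, plus
   Gini-impurity and permutation variable importance.
5. **Synthetic data** (`figsel.synthetic_data`) — a seeded genebank-like
   climate table and wet/dry trait tables drawn from the bundled per-set
   reference means and SDs, so the whole pipeline is testable without any
   external data.

A `figs` command-line tool (`simulate`, `select`, `derive`, `compare`,
`evaluate`, `report`, `run`) orchestrates the stages with YAML config and
a hash manifest for reproducibility.

## Worked example

```python
import figsel as F
from figsel.reference import ANALYSIS_VARIABLES
from figsel.synthetic_data import GeneratorConfig, gen_collection, gen_bundle

# climate-based selection on a synthetic 2,000-site genebank
collection = gen_collection(GeneratorConfig(n_sites=2000, seed=1))
dry = F.select_dry_set(collection, F.SelectionConfig(seed=1))
print(len(dry.members), {k: v["kept"] for k, v in dry.dropped.items()})

# trait data at the reference effect sizes, 201 accessions per set
bundle = gen_bundle(GeneratorConfig(seed=7), mode="trait_only")
X = bundle.traits[list(ANALYSIS_VARIABLES)]
y = bundle.traits["label"]
for fam, s in F.run_harness(X, y, n_runs=10, seed=7).items():
    print(f"{fam:14s} AUC {s.mean['auc']:.3f}  kappa {s.mean['kappa']:.3f}")
```

prints

```
201 {'rain_band': 1973, 'one_per_site': 996, 'aridity_prune': 994, 'bio15': 809, 'round_robin': 201}
tree           AUC 0.887  kappa 0.753
random_forest  AUC 0.990  kappa 0.891
svm_rbf        AUC 0.999  kappa 0.970
```

The first line traces the dry-set funnel: 1,973 accessions inside the
rain band, 996 sites after the one-per-site draw, 994 left after aridity
pruning, 809 above the bio15 cut, and exactly 201 selected. The harness
lines show that all three classifier families recover the climate-based
membership from the measured traits far above the AUC ≥ 0.7 / kappa ≥ 0.4
bars — the trait data carry the ecotypic signal. The same contrast drives
the t-tests: `figsel.set_comparison_stats.reference_comparison_table()`
recomputes, e.g., t = 6.65 for stomatal length and t = 9.91 for leaflet
area from the bundled per-set summaries (reported: 6.63 and 9.86).

Command-line equivalent:

```sh
figs run --seed 7 --out-dir out/   # simulate → select → derive → compare → evaluate → report
```

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions, what the synthetic generator does and does not emulate, and
known limitations.
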