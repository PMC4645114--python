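# ensemblevs

Ensemble virtual-screening toolkit: qualify multiple receptor structures,
derive receptor–ligand pharmacophore models and fit values, fuse
per-structure docking scores and fit values with a Laplacian-corrected naive
Bayesian classifier, then rank, filter, cluster and report candidate
inhibitors.

Docking itself is out of scope — per-structure score tables are ingested as
CSV. A deterministic fixture generator produces a complete synthetic
campaign (active/decoy library, correlated docking-score channels,
zero-inflated fit-value channels, redock RMSDs) so the full funnel runs
offline.

## Modules

| module | purpose |
| --- | --- |
| `ensemblevs.chemio` | SMILES/SDF/CSV readers & writers, fixture generator, bundled assay panel |
| `ensemblevs.structure_qc` | pose RMSD (optional symmetry correction), one-sided Mann–Whitney discrimination power, structure qualification |
| `ensemblevs.pharmacophore` | SMARTS feature perception, conformer generation, model derivation, selectivity, fit-value mapping |
| `ensemblevs.fusion` | feature-matrix assembly, diversity-picked training sets, equal-frequency binning, naive Bayes training/scoring/ranking |
| `ensemblevs.screen_eval` | ROC AUC, confusion metrics, hit rates, potency counts, top-N hit-list overlap |
| `ensemblevs.chemfilters` | MACCS/ECFP6 fingerprints, Tanimoto, single-linkage clustering, Rule-of-Five, REOS, scaffold search |
| `ensemblevs.pipeline` | the full campaign funnel (QC → features → train → rank → filter → cluster → report) |

## CLI

Everything is behind one entry point, `ensemble-vs`:

```sh
# generate a synthetic campaign fixture as plain-text files
ensemble-vs fixtures --out-dir fx --seed 7 --n-actives 100 --with-structures

# qualify structures (redock RMSD + score separation)
ensemble-vs qc --scores-dir fx/scores --actives fx/actives.txt \
    --rmsd-csv fx/rmsd.csv --rmsd-max 2.0 --logp-max -20

# train / rank with the Bayes fusion model
ensemble-vs train --matrix X.csv --labels y.csv --out model.json
ensemble-vs rank --model model.json --matrix X.csv --top 100

# evaluation, filtering, clustering, scaffold search
ensemble-vs eval --scores s.csv --labels y.csv
ensemble-vs overlap --a rankA.csv --b rankB.csv --n 500
ensemble-vs filter --library lib.smi --rules ro5,reos
ensemble-vs cluster --library lib.smi --threshold 0.85
ensemble-vs scaffold --smarts 'c1ccc(-c2ccnc3[nH]ccc23)cc1' --library lib.smi

# pharmacophore fit values
ensemble-vs fit --model pharm.json --library lib.sdf --out fits.csv

# the whole funnel from a YAML config
ensemble-vs run --config campaign.yaml --out report.json
```

A minimal `campaign.yaml` running entirely on generated fixtures:

```yaml
seed: 7
top_n: 100
cluster_threshold: 0.85
fixture:
  n_actives: 120
  decoy_ratio: 20
  n_structures: 9
  n_failing_structures: 1
  with_structures: true
```

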