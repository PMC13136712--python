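# featkit

Feature representations, imbalance-aware gradient-boosted-tree models and
explainability tooling for CRISPR guide activity prediction.

## The problem

CRISPR/Cas9 cleaves not only its intended target but also partially
complementary *off-target sites* (OTS), and base editors vary widely in how
efficiently they edit. Predicting both behaviours from sequence is a
feature-engineering problem before it is a modelling problem: the same
gradient-boosted-tree learner behaves very differently depending on how the
gRNA–DNA relationship is encoded.

`featkit` implements eight sequence encodings and the machinery around them
for two tasks:

* **Knockout (KO)** — paired records `(gRNA, aligned off-target, read
  count)` from cleavage screens. Classification (active site: read count
  > 100) and regression (log read count). About 97% of candidate sites are
  inactive, so evaluation centres on the area under the precision-recall
  curve (AUPR) and training uses class weights
  `w_active = n_inactive / n_total`.
* **Base editing (BE)** — single-gRNA records with a proliferation z-score
  from a screen. Regression on z, or classification of strongly effective
  guides (z < −2).

### Encodings

| id | input | idea | features (L = 23) |
|--------|--------|------------------------------------------------|-----|
| NPM | pair | per-position one-hot over 16 (guide, target) base pairs | 368 |
| BULGES | pair | NPM over {A,C,G,T,−}: handles insertion/deletion bulges | 575 |
| LEP | pair | per-position integer label 0–15 of the base pair | 23 |
| MM | pair | binary mismatch indicator per position | 23 |
| 8XL | pair | one-hot(guide) ⧺ one-hot(off-target) | 184 |
| OH | either | positional one-hot; pairs combined by bitwise OR | 92 |
| OH5C | either | OH plus a fifth channel for gap/N | 115 |
| KMER | either | overlapping trimer counts (64, or 63 compact) | 64/63 |

Each encoding may be augmented with an explicit integer `distance` feature
(the Hamming distance between guide and off-target), giving the
`-seq-dist` model variants. Engineered biophysical descriptors (GC%,
Wallace-rule melting temperature, RNAfold minimum free energy) are also
available.

Models are XGBoost ensembles evaluated with guide-grouped cross-validation
(all records of a guide are held out together, so no sequence context leaks
between training and test). Explainability combines exact TreeSHAP
attributions with first-order accumulated local effects (ALE) of the
distance feature.

Because the real screens (CHANGE-seq, GUIDE-seq, and base-editor
proliferation screens) are large downloads, the package ships a synthetic
data module that reproduces their statistical structure — 23-nt sequences,
up to six mismatches, ~3% active prevalence, heavy-tailed negative-binomial
read counts, and z-scores driven by PAM-proximal positional effects — so
the full pipeline is testable offline.

## Worked example

```python
from featkit.synthetic_data import KOSimParams, simulate_ko
from featkit.encoders import EncoderSpec
from featkit.modeling import make_folds, run_experiment, ModelSpec
from featkit.metrics import format_mean_sd

table = simulate_ko(KOSimParams(seed=1))          # 20 guides x 500 sites
print(f"simulated {len(table)} sites, active fraction "
      f"{table.provenance['achieved_prevalence']:.3f}")
folds = make_folds(table.guide_ids, "leave_k_groups_out", k=5, seed=1)
for with_distance in (False, True):
    enc = EncoderSpec("OH", with_distance=with_distance)
    result = run_experiment(table, enc, "classification", folds, ModelSpec(seed=1))
    tag = "OH-seq-dist" if with_distance else "OH-seq     "
    print(f"{tag}  AUPR {format_mean_sd(result.aggregate['aupr'])}  "
          f"AUROC {format_mean_sd(result.aggregate['auroc'])}")
```

prints

```
simulated 10000 sites, active fraction 0.034
OH-seq       AUPR 0.349±0.066  AUROC 0.875±0.047
OH-seq-dist  AUPR 0.897±0.065  AUROC 0.997±0.003
```

The jump from 0.349 to 0.897 is the headline behaviour: adding the explicit
mismatch count transforms a sequence-only one-hot model, because under
heavy imbalance the trees cannot fully reassemble the mismatch count from
92 OR-encoded bits. The same models, explained:

```python
report = shap_attributions(model, feats)   # full-data -seq-dist model
curve  = ale_curve(model, feats, "distance")
```

```
top features by mean |SHAP|: distance, pos5_C, pos9_T
distance ALE: [12.22  8.75  3.2  -0.5  -0.5  -0.5  -0.5 ]
```

`distance` dominates the attribution ranking and its ALE falls steeply over
the first three mismatches — the model has learned that each additional
mismatch destabilizes cleavage, most sharply near the well-matched end of
the range.

The same pipeline is scriptable from the shell:

```bash
featkit simulate --task ko --seed 1 -o ko.tsv
featkit encode --encoding oh --with-distance -i ko.tsv -o features.tsv
featkit train --task ko --encoding oh --with-distance --cv k-group --k 5 \
              --seed 1 -i ko.tsv --out run/
featkit explain -m run/model.json -i features.tsv --ale distance -o explain/
```

## Layout

```
src/featkit/core_io.py         domain types, TSV/CSV + FASTA I/O
src/featkit/encoders.py        the eight encodings + biophysical features
src/featkit/preprocess.py      labeling, log transform, class weights
src/featkit/synthetic_data.py  KO and BE screen simulators
src/featkit/modeling.py        grouped CV, XGBoost training, random search
src/featkit/metrics.py         AUPR/AUROC, regression and tail-error reports
src/featkit/explain.py         TreeSHAP attributions, ALE curves
src/featkit/cli.py             `featkit` command-line interface
docs/methods.md                model and simulator documentation
```
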