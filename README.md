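# ctstage

Information extraction from free-text Chinese chest CT reports for lung-cancer
staging: the pipeline recognises 14 clinical entity types with character-level
neural taggers, classifies 4 relation types between same-sentence entity
pairs, and feeds the resulting (entity, relation, entity) triples into a
rule engine that answers a 22-question staging/diagnosis catalogue per report.

Because real clinical corpora cannot ship with the code, the package includes
a first-class **synthetic report generator**: each generated report is rendered
from a latent clinical scenario (primary tumor, invasions, satellite nodules,
lymph-node stations, effusion, ...) with gold brat-standoff annotations and
oracle answers computed directly from the latent state. The full pipeline is
trained, evaluated, and audited against these oracles offline.

## Components

| module | what it does |
| --- | --- |
| `ctstage.schema` | entity/relation type enums, the admissible-relation map, the 22-question catalogue (shipped as YAML data files, overridable via `--schema`) |
| `ctstage.corpus` | brat standoff read/write, character-level BIO conversion, CoNLL export, deterministic 70/10/20 splitting |
| `ctstage.synthetic` | scenario sampling, report rendering, oracle answers, corpus generation |
| `ctstage.crf` | linear-chain CRF from scratch (forward algorithm, Viterbi, batched NLL gradients, BIO-constrained decoding) |
| `ctstage.ner` | Bi-LSTM-CRF and ID-CNN-CRF character taggers with segmentation-position embeddings, early stopping, seeded training |
| `ctstage.rc` | attention-Bi-LSTM relation classifier over entity-marked text with the relation-sign constraint (RSC): the pair's single admissible relation tag is prepended to the input, and predictions are hard-masked to `{admissible, NoRelation}` |
| `ctstage.postprocess` | assembles triples into finding graphs, parses sizes/locations (sides, lobes, nodal stations/regions), answers all 22 questions |
| `ctstage.evaluate` | per-class P/R/F1 with macro/micro averages for NER (exact *and* inexact span matching), RC, and QA, plus Cohen's kappa |
| `ctstage.cli` | `ctstage` command-line entry point |
| `ctstage.nn` | the minimal numpy autograd engine backing the models (no deep-learning framework required) |

Note on inexact NER matching: a prediction counts as correct when it overlaps
any same-type gold mention, and the recall numerator counts every matched
prediction without deduplicating gold — so inexact recall can exceed 100%.
This is deliberate and mirrors the published evaluation behaviour.

## CLI

```bash
# generate a 500-report synthetic corpus with gold annotations + answers
ctstage generate --n 500 --seed 42 --out corpus/

# train the taggers / the relation classifier (70/10/20 split internally)
ctstage train-ner --corpus corpus/ --arch bilstm_crf --seed 42 --model ner.npz
ctstage train-rc  --corpus corpus/ --rsc --seed 42 --model rc.npz

# predict entities + relations for raw reports, then answer the catalogue
ctstage predict --model ner.npz --rc-model rc.npz --in corpus/ --out pred/
ctstage answer  --in pred/ --out answers_pred.tsv

# score against gold
ctstage evaluate --task ner --scheme inexact --gold corpus/ --pred pred/
ctstage evaluate --task qa --gold corpus/answers_gold.tsv --pred answers_pred.tsv

# or everything at once (writes corpus, models, predictions, metrics, manifest)
ctstage run-all --workdir run1 --n 500 --seed 42
```

`run-all` accepts `--use-gold-entities` (evaluate RC/PP on gold entity input)
and `--no-rsc` (ablate the relation sign constraint).

## Reproducibility

Every stochastic component (generator, parameter init, batch shuffling,
dropout) is driven by an explicit integer seed; identical seeds give
bit-identical corpora, training trajectories, and metrics. Model checkpoints
are single `.npz` files with the config embedded.
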