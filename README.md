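# pluribool

Discrete (Boolean) modelling of the human pluripotency gene-regulatory
network: from a signed, literature-style topology to executable logic,
expression-based validation, network reconstruction from time series, and
in-silico knockdown prediction.

Human embryonic stem cells hold their identity through a core circuit of
transcription factors (POU5F1/OCT4, SOX2, NANOG) embedded in a wider web of
differentiation genes, epigenetic factors and signalling inputs.  Many of
the interesting perturbations of that circuit cannot be run in the lab, for
practical and ethical reasons.  `pluribool` is for systems-biology
researchers who want to ask those questions in silico: it turns a signed
regulatory network into a synchronous Boolean model, checks the model
against binarized single-cell expression, refines it with rules learned
from time series, and predicts the outcome of single and combinatorial gene
knockdowns.

## The model

Each gene *i* carries a binary state and an update rule built from its
regulators.  Activators are OR-joined, inhibitors are OR-joined under a
veto, and the two clauses are AND-joined:

```
psi_i = (A1 | A2 | ... | An) & !(I1 | I2 | ... | Im)
```

so a single active inhibitor silences the gene regardless of how many
activators are on.  Obligate dimer partners (POU5F1+SOX2 by default) are
AND-joined wherever they co-regulate a target.  Genes with no regulators
are inputs and hold their state.  All genes update simultaneously
(synchronous update); every trajectory ends in an attractor — a fixed point
or cycle read as a stable cellular phenotype.  Sampling N random initial
states assigns each attractor a basin weight B_i, and the maximum-weight
attractor is the model's stable phenotype.

Expression enters through binarization: per-gene bimodality is scored by a
peak/antimode amplitude in [0, 1], bimodal genes are split by 1-D 2-means
with threshold rho (state 1 where expression exceeds rho), unimodal genes
get one gene-level state from a pooled 2-means, and a Pearson chi-square
tests whether the binary state depends on gene category.  Rules are
validated by plugging observed states into each psi_i, re-learned from
time-series transitions by best-fit truth-table search, and reconciled with
the curated topology by a Jaccard-plus-sign similarity.  A knockdown clamps
genes to 0 throughout the simulation and classifies every gene *i* by
comparing its state G_iu in the unperturbed and G_ip in the perturbed
stable phenotype: up-regulated (0 to 1), down-regulated (1 to 0), else
unchanged.

The packaged 45-node pluripotency network is a documented synthetic
reconstruction (see `src/pluribool/data/edge_provenance.synthetic.tsv`),
not a curated edge list taken from the literature.

## Worked example

```python
import pluribool as pb

network, model = pb.pluripotency_fixture(integrated=True)
print(pb.network_stats(network).n_nodes)      # 45

aset = pb.sample_attractors(model, n_starts=100, seed=1)
stable = aset.max_basin.collapsed
print({g: stable[g] for g in ("POU5F1", "SOX2", "NANOG")})
# {'POU5F1': 1, 'SOX2': 1, 'NANOG': 1}     <- pluripotent steady state

kd = pb.perturbation_experiment(model, ["POU5F1"], n_starts=100, seed=1)
print(len(kd.downregulated), len(kd.upregulated))   # 19 11
print("NANOG" in kd.downregulated)                  # True
```

The knockdown output means: clamping POU5F1 OFF collapses the pluripotent
phenotype (19 genes switch off, including NANOG and SOX2) and de-represses
11 lineage genes (GATA4/GATA6 endoderm arm, BMP4-driven mesoderm markers).
MYC and TERT oscillate in the synchronous attractor (MYC carries a negative
auto-regulatory loop) and are excluded from the up/down classification.

The same workflow is available as numbered drivers (`analysis/01...05`,
writing tables under `results/`), as a configurable pipeline
(`pluribool run config.yaml`) and as per-stage subcommands
(`pluribool logic|binarize|validate|infer|integrate|simulate|perturb|synth`).

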