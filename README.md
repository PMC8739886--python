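# parcelgnn

Graph-neural-network cortical surface parcellation: learn vertex-wise
cortical area labels from resting-state functional-connectivity features
distributed over a triangulated surface mesh.

Individual cortical parcellations matter because areal boundaries vary
across people, yet most pipelines assign every subject the same group
atlas. Given training subjects whose surfaces are in vertex correspondence
and carry known labels, `parcelgnn` trains a vertex classifier that
transfers to new subjects from their resting-state data alone. The surface
mesh is treated as a graph G = (V, E); features are a vertex's Pearson
correlations with the mean time series of each region of a coarse
anatomical atlas (optionally dual-regression component loadings), the
first three graph-Laplacian eigenvector embeddings as intrinsic
coordinates, and scalar maps (thickness, curvature, sulcal depth, myelin).

Four architectures are implemented on a built-in numpy autodiff engine:

* **baseline** — vertex-wise MLP, no graph information;
* **GCN** — first-order spectral convolution, H ← σ(D̃^{−½}(A+I)D̃^{−½} H W);
* **GAT** — multi-head neighborhood attention,
  α_ij = softmax_j(LeakyReLU(aᵀ[Wh_i ‖ Wh_j]));
* **JKGAT** — GAT with jumping-knowledge aggregation of all layer
  embeddings (concat / max-pool / bidirectional-LSTM attention).

A vertex-wise spatial prior (the per-vertex union of labels seen in
training) masks test-time logits so impossible labels get probability
exactly 0. Evaluation covers accuracy, areal Dice reproducibility,
boundary-distance error profiles, functional/scalar homogeneity, consensus
maps, mean probability maps, and bootstrap standard errors. A synthetic
cohort generator (icosphere mesh, geodesic-Voronoi parcels,
parcel-structured time series with correlated fingerprints for neighboring
areas) makes the whole pipeline runnable without any imaging data.

## Worked example

```python
from parcelgnn.synthetic import SyntheticConfig, make_cohort
from parcelgnn.pipeline import cohort_dataset, predict_labels
from parcelgnn.models import ModelSpec
from parcelgnn.training import TrainingConfig, train
from parcelgnn.prior import build_prior
from parcelgnn.evaluation import accuracy, mean_dice

cohort = make_cohort(SyntheticConfig(
    mesh_subdivisions=2, num_parcels=6, num_subjects=8,
    timepoints=120, snr=3.0, seed=0))
data = cohort_dataset(cohort, n_train=5, n_val=1)
spec = ModelSpec(architecture="gat", in_features=data.feature_width,
                 num_classes=6)
model = train(spec, data, TrainingConfig(max_epochs=40, patience=40,
                                         l2_penalty=0.0, seed=0))
prior = build_prior([cohort.subject_labels[i] for i in data.split["train"]],
                    num_classes=6)
for i in data.split["test"]:
    g, x, y = data.samples[i]
    pred, probs = predict_labels(model, g, x, prior=prior)
    print(f"subject {i}: accuracy {accuracy(pred, y)[0]:.1f}%, "
          f"Dice vs truth {mean_dice(pred, y):.3f}")
```

Output:

```
subject 6: accuracy 100.0%, Dice vs truth 1.000
subject 7: accuracy 100.0%, Dice vs truth 1.000
```

A 162-vertex cohort at SNR 3 is an easy task once spectral and scalar
features are included — the accuracy is the per-vertex fraction of
correctly recovered parcel labels on held-out subjects, and Dice 1.0 means
every areal vertex set matches the ground truth exactly. The
connectivity-only task on the larger benchmark cohort (below) is the
discriminating one.

The same pipeline is scriptable from the shell:

```bash
parcelgnn simulate --config sim.yaml --out cohort/ --seed 1
parcelgnn features --mesh cohort/mesh.surf.txt --ts cohort/sub-00_ses-0.ts.tsv \
    --atlas cohort/atlas.label.txt --out sub-00.features.tsv
parcelgnn train --config train.yaml --out model.ckpt --seed 1
parcelgnn predict --model model.ckpt --mesh cohort/mesh.surf.txt \
    --features sub-00.features.tsv --prior prior.txt --out sub-00.pred.label.txt
parcelgnn evaluate --pred sub-00.pred.label.txt --truth cohort/sub-00.label.txt \
    --mesh cohort/mesh.surf.txt --out report.json
parcelgnn run --out run/ --seed 1 --arch gat   # end-to-end in one call
```

GIFTI (`.surf.gii`, `.label.gii`, `.func.gii`) and plain-text formats are
both supported.

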